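# likertcomp

Compositional analysis of bipolar Likert-scale data, and Monte-Carlo
power studies of paired and unpaired two-sample t-tests when the data
come from heavy-tailed processes.

## The problem

A bipolar Likert item (e.g. "not at all" … "very much", coded 1…K)
measures a latent trait on a continuum `[0, 100]`. Because no item
wording covers the whole continuum, a fraction `p` — the psychometric
*limit of quantification* (LOQ) — is unreachable, and the K categories
embed into `[100·p/2, 100·(1 − p/2)]` as the "star scale" RS\*. A star
value `x*` and its complement `100 − x*` (magnitude of agreement vs.
disagreement) form a two-part *composition*, so the natural geometry of
the data is the Aitchison geometry of the simplex, not the Euclidean
line. The isometric log-ratio transform

```
z = √½ · ln( x* / (100 − x*) )
```

maps responses to the real line where t-tests are geometrically coherent
(`ilr` / `inverse_ilr` in this package, for general D-part compositions
too).

When means of item responses are approximately normal, this
compositional treatment is known to help. This package asks the opposite
question: **what happens to the power of two-sample t-tests when the
means are heavy-tailed** (Laplace-distributed, finite variance — i.e.
when the central limit theorem has not kicked in)? It simulates means on
the ilr scale, replaces them with the nearest *achievable* questionnaire
mean — in parallel on the ilr scale and, via the inverse transform, on
the original response scale — applies the same t-test to both datasets,
and estimates

```
ΔPower = Power^ilr − Power^orig .
```

Audience: psychometricians, health-economics and healthcare researchers
who analyze Likert questionnaires, and methodologists studying
compositional data analysis.

## Worked example

The five-point scale at LOQ `p = 0.05` embeds as
`{2.5, 26.25, 50, 73.75, 97.5}` (step width 23.75); its ilr image is
`{−2.59, −0.73, 0, 0.73, 2.59}`. With `I = 2` items the achievable means
on the star scale are `{2.5, 14.38, 26.25, 38.13, 50, 61.88, 73.75,
85.63, 97.5}`, corresponding one-to-one with the original-scale means
`{1, 1.5, …, 5}`:

```python
import likertcomp as lc

system = lc.ScaleSystem.create(K=5, p=0.05)
spm_ilr = lc.enumerate_possible_means(system.ilr_values, I=2, scale_tag="ILR")
spm_star = lc.enumerate_possible_means(system.star.values, I=2, scale_tag="RS*")

pair = lc.snap_both_paths(0.82, system, spm_ilr, spm_star)
# SnappedPair(mu_ilr=0.7304519159389652, mu_orig=4.0)
```

A simulated ilr-scale mean of 0.82 back-transforms to 76.13 on the star
scale, snaps to the achievable star mean 73.75, and therefore reports
the familiar questionnaire mean **4.0**; on the ilr path it snaps to the
nearest achievable ilr mean **0.73**.

One power scenario from the shell:

```
$ likertcomp run --test unpaired --K 5 --p 0.05 --items 2 \
      --n1 100 --n2 100 --var-a 1.28 --var-b 1.28 --effect 0.4 \
      --runs 1000 --seed 1
{
  ...
  "power_ilr": 0.826,
  "power_orig": 0.906,
  "delta_power": -0.08000000000000007
}
```

Reading: at effect size d = 0.4 with heavy-tailed, high-variance data,
the test on compositional (ilr) means rejects the null in 82.6% of runs
versus 90.6% on the ordinary response-scale means — the compositional
treatment *loses* eight percentage points of power in this regime,
because the ilr scale stretches the edge regions exactly where
heavy-tailed data cluster.

Full study grid (3600 scenarios; ~30 s at 500 runs/scenario) and a
findings summary:

```
likertcomp grid --out results.csv --seed 1 --runs 500
likertcomp report --results results.csv --aggregates-prefix agg_
```

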