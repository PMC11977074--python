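# Methods

## The measurement model

A bipolar Likert item measures a latent trait whose manifestations span a
continuum, the *trait scale* (TS) `[L, U]`, fixed here at `[0, 100]` so the
total mass is `kappa = 100`. The item offers `K` ordered response
categories, the *response scale* (RS) `{1, ..., K}` with unit spacing. No
item wording can reach the extremes of the trait continuum: a fraction
`p in (0, 1)` of the TS — the *limit of quantification* (LOQ) — is
inaccessible, split symmetrically into edge areas of width `p/2` at each
end. Embedding the RS into the accessible part of the TS gives the *star
scale* RS\*: `K` equidistant values from `lLOQ = 100 p/2` to
`uLOQ = 100 (1 - p/2)` with step width `sw = (uLOQ - lLOQ)/(K - 1)`.

A star value `x*` expresses the magnitude of agreement; its complement
`100 - x*` the magnitude of disagreement. The pair `(x*, 100 - x*)` is a
two-part composition on the simplex, so Euclidean statistics applied to
`x*` directly ignore the data's relative (Aitchison) geometry. The
isometric log-ratio (ilr) transform

    z = sqrt(1/2) * ln( x* / (100 - x*) )

maps the simplex isometrically to the real line, where means, t-tests and
regression are geometrically coherent. The package implements the general
`D`-part balances `z_s = sqrt(s/(s+1)) ln(gmean(x_1..x_s)/x_{s+1})` and
their softmax-form inverse, although the study itself only exercises
`D = 2`.

Because `p > 0`, scale values never touch the simplex boundary and no
zero-replacement strategy is needed; boundary compositions are rejected as
invalid input rather than clamped.

## Possible means and snapping

A questionnaire of `I` items produces a mean of `I` responses, which can
only take finitely many values: the *set of possible means* (SPM). On the
equidistant RS this set has exactly `I (K - 1) + 1` elements; on the ilr
scale the category values are irregularly spaced and the SPM has up to
`C(K + I - 1, I)` elements. SPMs are enumerated over combinations with
replacement from the exact (unrounded) scale values, sorted, and merged
with an absolute tolerance of `1e-9` (symmetric scales produce genuinely
coincident means through different response multisets; anything closer
than the tolerance is treated as a floating-point duplicate). A cap of
`10^6` multisets guards against accidental combinatorial blow-up; the
study grids stay around `C(11, 6) = 462`.

Each simulated continuous mean is replaced by its nearest achievable mean
("snapping") along two paths that both start from the same raw value:

* **ilr path** — Euclidean nearest element of the ilr SPM;
* **orig path** — inverse-ilr to the star scale, Euclidean nearest element
  of the RS\* SPM, then the affine map `1 + (m - lLOQ)/sw` to the original
  RS mean.

Using the Euclidean metric on RS\* is a deliberate modelling choice, not
an oversight: the orig path emulates everyday practice, where means are
computed without regard for the compositional structure, and the study
quantifies the consequences. Nearest-neighbour ties break toward the
smaller element — a fixed deterministic rule; ties sit exactly at SPM
midpoints and occur with probability zero under the continuous DGP.
Values outside the support clamp to the nearest extreme.

## Data-generating process

Simulated ilr-scale means are drawn from the Laplace (double-exponential)
distribution, density `f(x) = exp(-|x - mu|/b)/(2b)`, mean `mu`, variance
`2 b^2` — the heavy-tailed but finite-variance benchmark for a failing
central limit theorem. Sampling is by the closed-form inverse CDF applied
to the generator's uniform stream, so the draw sequence is reproducible
from a seed regardless of any library's internal sampler; the sampler is
cross-checked against the reference Laplace distribution with a
Kolmogorov–Smirnov test at `n = 10^5`.

Group locations realize a target Cohen's d exactly at the population
level: `mu_a = +d sqrt((s2_a + s2_b)/2)/2`, `mu_b = -mu_a`, with the
group variances `s2_a <= s2_b`. The group with the smaller variance
carries the positive location; by the mirror symmetry of scales, DGP and
two-sided tests, the opposite pairing is distributionally equivalent. In
paired scenarios the two groups are sampled independently — no
within-pair correlation is imposed, as none is part of the model; under
independence the realized paired effect size `d_z` relates to the nominal
grid value by a factor `1/sqrt(2)`, which is accepted as part of the
design rather than re-scaled away.

## Tests and power estimation

The null hypothesis is `H0: mu_a - mu_b = 0`, two-sided, at `alpha = 0.05`
by default (configurable; 0.05 is the field convention). Three variants:
Student's pooled-variance unpaired test (`df = n1 + n2 - 2`), Welch's
unpaired test with Satterthwaite degrees of freedom, and the paired test
(one-sample t on differences, `df = n - 1`). Welch applies if and only if
the *population* variances of the scenario differ — no pre-testing on
samples. Snapped samples can be constant, so degenerate cases carry
explicit conventions: zero standard error with equal means gives `p = 1`;
with unequal means `p = 0`.

Each scenario runs `n_runs` Monte-Carlo repetitions (default 1000); every
repetition draws fresh samples for both groups, snaps them along both
paths and applies the same test variant to the ilr dataset and to the
original-scale dataset. Rejection proportions estimate `Power^ilr` and
`Power^orig`; their difference `ΔPower = Power^ilr - Power^orig` is the
quantity of interest. The engine is vectorized over repetitions
(`(n_runs, N)` sample blocks, `searchsorted`-based snapping, row-wise
test statistics), which runs the full 3600-scenario grid at 500
repetitions in about half a minute on one CPU.

Reproducibility contract: a grid run derives one substream per scenario
from the master seed via `SeedSequence(master, spawn_key=(index,))`
(masked below 2^31); identical inputs give bit-identical power tables.

## The replication grid

`K in {4, 5, 6}`, `p in {0.05, 0.1, 0.2}`, `I in {1, 2, 4, 6}`,
`N1 = N2 in {50, 100}`, the 10 unordered variance pairs
`s2_a <= s2_b` from `{0.08, 0.32, 0.72, 1.28}` (Laplace scales
`b in {0.2, 0.4, 0.6, 0.8}`), and `d in {0.2, 0.4, 0.6, 0.8, 1.0}` —
3600 scenarios per test type. Aggregations summarize `ΔPower` per design
factor with Tukey boxplot conventions (type-7 quartiles, whiskers at the
most extreme points within 1.5 IQR); medians rather than spline fits are
used as the factor-level summary, and raw tables are exported for any
external smoothing or plotting.

## What the simulation does and does not emulate

The generator produces *means of ilr-transformed item responses* directly
from the Laplace law; it does not simulate individual item responses,
inter-item correlation structure, response styles (acquiescence, central
tendency), or measurement error in `p`. Passing tests therefore
demonstrate the internal consistency of the scale model, transform,
snapping and testing machinery, and the behaviour of t-test power under
the stated DGP — not that real questionnaire data follow a Laplace law
(the heavy-tailed DGP is an extreme benchmark, arguably of reduced
practical relevance precisely because finite scales bound the support).

## Numerical choices

* Internal arithmetic is full double precision; comparisons with printed
  reference values round half-away-from-zero to 2 decimals (the rounding
  convention of the reference tables, not of Python's `round`).
* The bivariate inverse ilr uses the logistic form
  `x* = kappa * expit(sqrt(2) z)`, stable for arbitrarily large `|z|`;
  the general-D inverse goes through a softmax for the same reason.
* SPM deduplication tolerance `1e-9` absolute; ilr scale values are
  irrational, so collisions beyond the designed symmetry are measure-zero
  while floating error is not.
* Findings-report operationalizations: "|ΔPower| decreases with p" means
  non-increasing at every step (within float tolerance — medians of
  rejection proportions can tie exactly at modest run counts) and
  strictly smaller at the largest `p`; "K matters little" means the range
  of medians across `K` is below the range across total variance.

## Observed behaviour worth knowing

On the full mixed-variance grid the largest median `|ΔPower|` occurs at
total variance `s2 = 1.36` (the 0.08/1.28 pair), not at the maximum 2.56:
variance *heterogeneity* — a nearly constant group paired with a widely
dispersed one under Welch's test — drives larger compositional-path
losses than total variance alone. Restricted to the homoskedastic pairs,
median `|ΔPower|` increases monotonically in total variance (0.006,
0.012, 0.014, 0.014 at `s2 = 0.16, 0.64, 1.44, 2.56` with 500
repetitions). Null-size calibration of all three test variants is within
three Monte-Carlo standard errors of `alpha` at `10^4` repetitions, so
this is a power phenomenon, not a size artifact.

## Problem sizes used in the shipped checks

The test suite runs the full 3600-scenario unpaired grid at 500
repetitions per scenario (about 30 s) and the null-calibration scenarios
at 10^4 repetitions; `scripts/acceptance.py` re-runs the grid at 300
repetitions. These sizes give Monte-Carlo standard errors of about
0.016–0.029 per power estimate, small enough for the directional and
location claims the package asserts.

## Known limitations

* Only symmetric LOQs and unit-spaced response scales are modelled.
* No within-pair correlation for paired designs (see above).
* The alr/clr/logit transforms, nearly identical to ilr in the bivariate
  case, are not implemented.
* Spline-smoothed visualization of `ΔPower` curves is out of scope; the
  aggregate tables carry the same information.
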