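# Methods

This note documents the models, defaults and numerical choices behind
`nemavoid`, and what the synthetic-data tests do and do not establish about
real data.

## Behavioral scoring

Backing time into a dried repellent drop is the tail-assay readout; the
response index normalizes it to same-day controls. Two normalizations are
implemented: the SDS-only ratio for wild type (the SDS positive control is
100 % by definition, asserted bit-exact) and the buffer-and-SDS double ratio
for mutants. The two coincide algebraically whenever the mutant and
wild-type buffer means are equal; the tests assert this identity to 1e-12
relative. Per-day mode computes each index within an assay day against the
same-day control and averages days with equal weight — the pooled mode is
available behind a flag but same-day normalization is the default because
controls are run alongside each day's experimental groups. Censored animals
(those still backing at the observation cap, default 20 s) enter group means
at the cap value; the censoring fraction is visible via the record flags.
No survival model is fitted — at study-like means (2–10 s) censoring at
20 s is rare.

## Inference battery

- **z-test** for two proportions: pooled variance, no continuity
  correction. Expected cell counts below 5 produce a warning, not an error.
- **t-test**: classical pooled-variance two-sample t (df = n₁+n₂−2).
  Zero pooled variance is handled explicitly: equal means → t = 0, p = 1;
  unequal means → ±∞ sentinel with p = 0.
- **ANOVA + Tukey**: F from `scipy.stats.f_oneway`; pairwise family-wise
  p-values from `scipy.stats.tukey_hsd`, with the studentized-range q
  statistic computed in-package and cross-checked against the
  studentized-range distribution in tests.
- **Hochberg step-up**: implemented from the recursion
  adj(m) = p(m), adj(i) = min(adj(i+1), (m−i+1)·p(i)), capped at 1,
  returned in input order. Tests verify equivalence with the closed form
  min_{j≥i}(m−j+1)·p_(j) on grid vectors and with
  `statsmodels.multipletests("simes-hochberg")` on random vectors.
  Families are declared explicitly in the analysis plan (one family per
  figure-panel comparison set), never inferred from the data.
- **Significance codes**: \*\*\* / \*\* / \* / ns at 0.001 / 0.01 / 0.05,
  always derived from the adjusted p whenever the family has more than one
  comparison.
- **Power**: two-sample t power from the noncentral t (df = 2n−2,
  noncentrality d·√(n/2)); the per-group sample size is the smallest
  integer n reaching the target power, found by upward scan (d = 0.8,
  α = 0.05, power = 0.8 gives n = 26). The two-proportion sample size uses
  the arcsine effect size h with n = round(2·(z₁₋α/₂ + z_power)²/h²)
  (p₁ = 0.3, p₂ = 0.8 gives h ≈ 1.055 and n = 14). The alternative
  convention that reports the per-group n of the pooled formula without the
  factor 2 would give ≈ 8; the implemented form is the one consistent with
  the per-group numbers above.

## Calcium pipeline

ΔF/F₀ uses the single 0.5 s frame at stimulus onset (t = 15 s) as F₀ by
default, exactly as the acquisition protocol defines baseline; a
mean-over-[10, 15] s option exists because single-frame baselines are
noise-sensitive (off by default). Buffer-control correction subtracts the
pointwise mean of the buffer-control group's ΔF/F traces from each
treatment trace; applied to the control group itself the corrected group
mean is identically zero (asserted to 1e-12). AUC is the trapezoid integral
over [15, 75] s inclusive on the uniform 0.5 s grid, in %·s; negative areas
are kept, not clipped. Traces with gaps or non-uniform sampling are
rejected at construction rather than interpolated — interpolation would
fabricate signal on a nominally uniform acquisition. The whole pipeline is
invariant to uniform intensity rescaling (tested to 1e-10 relative), so
arbitrary-unit inputs are safe.

## LC-MS quantification

Monoisotopic m/z is computed from a built-in table of monoisotopic atomic
masses (H, C, N, O, S, P, Na, K, Cl) with the electron mass subtracted per
positive charge: m/z = (Σ count·mass − z·mₑ)/|z|; charge 0 returns the
neutral mass for validation against tabulated values (cross-checked against
pyteomics to 1e-6 u). EIC extraction sums centroid intensities within
|m/z − target| ≤ target·ppm·1e-6 per scan, window closed on both sides
(boundary centroids included), default ±100 ppm. Integration is trapezoidal
over an explicit, user-supplied retention-time window — peak picking is
deliberately out of scope, mirroring manual integration practice; the
optional linear baseline subtracts the chord between window endpoints and
floors the corrected signal at zero. `relative_abundance` exposes both
operands (sample and control area) and a single detection floor; when the
control is below the floor the ratio is ∞ and the detection flag carries
the information.

## Synthetic-data generator

The generator emulates the measured quantities only, not locomotion or
neural dynamics. Defaults are the study-like conditions:

- **Backing times**: Gamma with the group's mean and coefficient of
  variation ("dispersion"); positive support and right skew are the
  minimal realistic latency model. Defaults in the demo: buffer 10 s
  (cv 0.25), SDS 2 s, repellent 3 s (cv 0.4), 40 animals per group;
  dispersion 0 is the exact noise-free limit. Latency variances are not
  published, so the cvs are chosen for realism (low variation in buffer,
  proportionally tighter spread at short latencies) and are not tuned to
  any published statistic.
- **Head responses**: Bernoulli, buffer 0.2 and repellent 0.8 — the
  proportions the assays are powered for.
- **Chemotaxis plates**: multinomial allocation into experimental /
  control / elsewhere.
- **GCaMP traces**: baseline minus optional linear bleach, plus a
  stimulus-locked difference-of-exponentials transient
  A·(e^(−t/τ_decay) − e^(−t/τ_rise)) scaled so its peak equals
  amplitude·baseline (defaults τ_rise 2 s, τ_decay 10 s, amplitude 0.5,
  i.e. a 50 % ΔF/F response), plus i.i.d. Gaussian noise; 0.5 s sampling
  on the 15/60 s protocol is fixed.
- **MS runs**: one centroid per configured peak per scan with Gaussian
  elution profile and Gaussian ppm-scale m/z jitter, plus uniform
  noise-floor centroids; intensities are never negative.

Every generator call takes one explicit seed and opens its own RNG stream;
fixed seed ⇒ bit-identical output. In the CLI all stage seeds are split
from one root seed with `numpy.random.SeedSequence`.

What passing synthetic tests show: the scoring equations, adjustment
procedures and integrators are correct, the test battery is calibrated
(type-I error at nominal α under a Gamma null), and configured effects are
recovered. What they do not show: robustness to real-data pathologies the
generator omits — day-to-day drift beyond a simple multiplicative factor,
adaptation within a session, motion artifacts in traces, chromatographic
tailing or coeluting isobars.

## Sizes and tolerances used in the checks

Null calibration uses 10,000 replicates (per-group n = 20 for t, 40 for z,
3×10 for ANOVA-Tukey), asserting rates within 3 Monte-Carlo standard
errors of 0.05. Effect-size recovery uses 300 replicates of 40 animals per
group at configured d = 2.8 (buffer Gamma mean 10 s cv 0.2 vs repellent
mean 4.4 s cv 0.4545, equal sd 2.0 s); replicate estimates carry the
standard Hedges small-sample correction J = 1 − 3/(4·df − 1) before the
3-SE comparison, since the raw estimator's known O(1/n) bias is a property
of Cohen's d, not of the pipeline. The Hochberg oracle check is exhaustive
on the 0.01 grid for vectors of length ≤ 2 and uses 4,000 seeded grid
vectors per length for 3–5. Gaussian-peak round-trip areas are required to
match the analytic integral within 1 % at 1 s scan spacing.
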