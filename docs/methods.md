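# Methods

This note records the models, numerical choices and open design decisions
behind `synscape`, and what the synthetic-screen benchmarks do and do not
demonstrate.

## Screen data model

A screen is a long table of well-level measurements keyed by (cell line,
drug A, drug B or none, concentration tier, replicate) with two readouts:
viability (cell count, % of DMSO control) and cPARP (% of
cleaved-PARP-positive nuclei, normalised to DMSO control). Values above
100% are legal (growth stimulation) and preserved. Pairs are stored
unordered with lexicographic canonicalisation, so keys are deterministic.
A combination row is scoreable only if both constituents have single-agent
rows at the same (line, tier); incomplete rows are retained but excluded
from synergy scoring with a logged count. Replicates are averaged at
scoring time; raw replicates feed the residual tests.

## Bliss synergy

Scores are computed on the percent scale,
`score = min(p_a,100)·min(p_b,100)/100 − p_ab`, identical in exact
arithmetic to `100·(v_a·v_b − v_ab)` on fractions. Clipping at 100 applies
to the expected value only (Bliss independence is a statement about
probabilities); the observed combination term is never clipped. Threshold
comparisons are strict (`>`): a score of exactly 40.0 is not a hit.

Synthetic lethality at record level requires singles > 80%, combination
< 50% **and** the record to be a synergy hit; the standalone predicate
`call_synthetic_lethal` implements only the three viability thresholds.
The reported synthetic-lethality rate is therefore a fraction of synergy
hits, which is the denominator that makes the quantity comparable across
screens. Breadth summaries default to the standard tier (configurable);
the low tier is scored identically.

## Viability→cPARP dual regression and outlier calls

Each line is fitted over **all** of its measurements (singles,
combinations, controls, both tiers) with two families on the percent
scales:

* exponential `f(x) = a·exp(−x/τ)` — initialised at `a₀ = max(y)`,
  `τ₀ = range(x)/2`, τ bounded in (10⁻⁶, 10⁶), three τ restarts; repeated
  non-convergence excludes the family;
* linear `f(x) = a·x + τ` — ordinary least squares.

Selection is by Pearson correlation between fitted and observed values;
exact ties and exponential failures select linear, because the linear
family is the τ→∞ limit of the exponential one and has no boundary
pathologies. Degenerate inputs (constant y, constant x, < 4 points for the
exponential) are refused explicitly.

Outlier ("unexpectedly apoptotic") calls test each combination's residuals
against all other residuals of the same line, one-sided for elevated cPARP.
Two numerical choices matter:

1. **Residual scale.** cPARP well-to-well variation is multiplicative
   (wells range over orders of magnitude; the display convention for such
   data is log scale). Residuals for testing are therefore
   `log(obs+1) − log(fit+1)`, where the fit is a refit of the *selected*
   family by least squares on the log scale. Without the refit, raw-scale
   least squares over-weights high-cPARP wells and leaves an x-dependent
   bias in log residuals that measurably distorts the test's null
   calibration (false-positive rate drifting above alpha).
2. **Robust background for single wells.** With one replicate the focal
   "sample" is a single residual, z-scored against the line's residual
   distribution. Centre and scale use median and 1.4826·MAD: a planted
   fraction q of genuine outliers at +k SD inflates the classical SD by
   √(1+q·k²) (≈ 1.28 at q = 4%, k = 4), which would deflate every z-score;
   the robust scale is immune and remains consistent under a normal null.
   Focal groups of ≥ 2 replicates use the one-sided Welch t-test against
   the rest of the line.

Significance defaults to alpha 0.05 with optional Benjamini–Hochberg
adjustment across combinations within each line. A line whose background
residual spread is below 10⁻⁶ (noise-free data) is apoptosis-quiet and
yields no calls. Kinetics labels: *slow* iff the combination's mean
viability stays > 80% of control, else *fast*. The drug-pair network keeps
one edge per flagged pair (tiers and kinetics as attributes); node degree
counts flagged partnerships.

## Differential synergy (SAM-style)

`d = (mean_A − mean_B)/(s + s0)` with the equal-variance pooled SE and
`s0` = median per-combination SE — a deterministic simplification of the
classic coefficient-of-variation grid search with similar damping
behaviour. With `s0 = 0` the statistic reduces exactly to the two-sample
t statistic.

False-discovery estimation permutes the line labels (exhaustively whenever
the number of distinct assignments does not exceed the requested
permutation count, making the result seed-independent). For the i-th
largest |d|, `q_i = (1 + median over permutations of #{|d_perm| ≥ |d_i|})
/ i`, clipped to [0, 1] and monotonised so q never increases with |d|. The
add-one pseudo-count is the usual "the observed labelling is itself a
permutation" convention; without it the top-ranked row's q collapses to
zero in roughly half of fully null matrices (the median exceedance of an
observed maximum is 0 with probability ≈ ½), producing spurious calls.
With it, a fully null matrix is essentially never called, while a block of
k genuinely shifted combinations (whose permuted statistics collapse
toward zero) reaches q ≈ 1/k after monotonisation — well under any
practical FDR target for k ≳ 10. The procedure is deliberately
conservative under the global null; with very few true positives (k ≤ 2)
it will not call them, a documented trade-off.

## Dose-response and combination index

Secondary assays use the four-parameter logistic on log₁₀ dose with
bounded parameters (hill ∈ [0.1, 10], IC50 within ±2 decades of the tested
range). Designs with < 5 doses or < 2 decades of range are fitted but
flagged; flat data (< 0.05 response range) is flagged with undefined IC50;
classification refuses flagged fits rather than guessing. Curve inversion
is the closed-form logistic inverse; requested effects outside
(bottom, top) raise, and fits with attached data refuse doses beyond 10×
the tested range rather than extrapolate.

The combination index uses the mutually exclusive Chou–Talalay form
`CI = d1/D1 + d2/D2` (no cross-term), the only form computable without an
interaction assumption. Summary CI defaults to the mean over affected
fractions 0.5/0.75/0.9. IC50-shift vs E_max-boost classification compares
the single-agent curve with the curve in the partner's presence: potency
shift iff the IC50 ratio ≥ 2 with |ΔE_max| < 0.2; efficacy boost iff
ΔE_max ≥ 0.2 (E_max = 1 − bottom).

## Synthetic screens: what they emulate, and what not

Defaults reproduce the full screen geometry — 108 drugs (5,778 pairs), 36
lines, two tiers, single replicate — and these study conditions:

* **Singles**: logit-normal true viabilities,
  `sigmoid(logit(base) + drug_effect + line_effect)` with base 0.85
  (standard tier) / 0.93 (low tier), drug SD 0.9, line SD 0.4. Mean
  standard-tier single-agent viability ≈ 0.8, emulating a dose run-in
  calibrated to > 70% viability while keeping genuinely active drugs.
* **Null combinations**: exact Bliss products of the noise-free singles,
  sharing the scorer's expectation expression bit-for-bit, so a noise-free
  null screen scores identically zero — the scorer's algebra is validated
  exactly, not approximately.
* **Noise**: additive on the viability fraction (SD 0.05 default), clipped
  to [0, 1.2]; log-normal multiplicative on cPARP (SD 0.20 on the log
  scale).
* **Planted landscape** (when not overridden): ~5% of pairs synergistic
  with truncated-geometric breadth (P(breadth ≤ 3) ≈ 0.56 — most synergies
  private), deltas U(0.45, 0.7); one broad MDR-inhibitor-like sensitizer
  multiplying combination kill ×3 in half the lines; cPARP outliers in 4%
  of combination wells at +4 SD; 6 of 36 lines labelled resistant.
  Auto-planting is feasibility-aware: events are placed only where the
  null combination viability can absorb the full delta (≥ delta + 5
  points), so every auto-planted event carries its nominal Bliss drop.
  Explicitly supplied plants are applied subtract-then-clip, and the
  ground truth records each event's *realized* Bliss drop for honest
  recovery accounting.
* **cPARP relations**: per line, exponential or linear (50/50), anchored
  at f(100) ≈ 100 so DMSO-level wells sit at control-level cPARP.

Limitations to keep in mind when reading the benchmarks: plate-position
and edge-well artifacts, imaging noise, batch effects and replicate
correlation are not modelled; measurement noise is homoscedastic on each
scale; and feasibility-aware planting biases planted synergies toward
pairs with inert singles, so the simulated landscape's synthetic-lethality
fraction among hits (~40%) is far higher than a real screen's (well below
1%) — the synthetic-lethality *machinery* is validated by construction
against brute-force filtering, not by reproducing a realistic rate.
Passing recovery benchmarks therefore demonstrates correctness and
calibration of the estimators under the stated noise model, not robustness
to every artifact of real plates.

Benchmark problem sizes (chosen to exercise each stage at meaningful
statistical resolution): full 108×36 geometry for the combinatorial and
exact-null checks; 40×12 for landscape recovery; 24×8 with 4% planted
outliers for apoptosis power; 16×24 (more lines, the clustering unit of
the outlier test) for null calibration; 107 combinations × 36 lines with
1000 permutations for the differential design.

## Determinism

Every stochastic component draws from a single `numpy` Generator seeded
from the configuration or CLI `--seed`; identical seeds give byte-identical
datasets and outputs. Exhaustive permutation enumeration is used whenever
feasible, removing seed dependence from the differential analysis on small
designs.
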