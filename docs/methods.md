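# Methods

## Data model and normalization

A screen is a set of dose-matrix blocks, one per (library compound, anchor
drug) pair. Each block holds raw replicate signal over a full factorial dose
grid whose first level on each axis is the vehicle (dose 0). All
concentrations are stored in molar; 6×6 blocks use five 5-fold serial
dilutions plus vehicle, 10×10 blocks nine serial steps plus vehicle with a
default step of √10 (configurable) so that nine steps span four orders of
magnitude.

Normalization is percent-of-control: every replicate well is divided by the
replicate-mean vehicle/vehicle signal, so the mean normalized vehicle well is
exactly 1. Viability above control (stimulation) is retained in `v` but the
fraction affected `fa = clip(1 − v, 0, 1)` is clamped, because `fa` feeds
`log(fa/fu)`, which is undefined outside (0, 1). Replicates aggregate by
arithmetic mean with the standard error of the mean reported; per-replicate
grids are kept for QC. An activity readout (e.g. caspase) can be expressed
per unit of surviving cells by elementwise division with the matched
viability matrix; wells below a viability floor (default 0.01) are masked,
since the ratio becomes pure noise once essentially no cells remain.

## Single-agent fitting

The median-effect model `fa/fu = (D/Dm)^m` linearizes to a straight line of
`log(fa/fu)` on `log D`. The fit censors, in order:

1. levels whose clamped `fa` sits at the clamp boundary `[1e−4, 1 − 1e−4]`
   (fully inactive or fully effective wells — no information for the line);
2. doses above a ceiling (default 10 µM; activity requiring more is not
   considered pharmacologically meaningful);
3. top dose levels on a **saturated plateau**: walking down from the top
   dose, levels are dropped while the `fa` increment from the level below is
   under 0.04, always keeping at least three points. Drugs with a
   partial-efficacy floor (`emax > 0`) plateau below `fa = 1`; the plateau is
   outside the median-effect model, and keeping those points flattens the
   fitted line and badly inflates extrapolated `Dx`, which in turn biases
   combination indices low for everything (measured ~2–3× on
   Bliss-independent pairs).

The line itself is **weighted** least squares with delta-method weights
`(fa(1 − fa))²`: the variance of `logit(fa)` scales as
`var(fa)/(fa(1 − fa))²`, so extreme-`fa` levels, whose logit is
noise-dominated, contribute little. The weighting leaves noise-free model
data exactly recovered and, under the package's reference noise conditions
(CV 10%, triplicate, 6-level design), brings the median relative `Dm` error
from ~22% to ~12%. A nonlinear least-squares variant of the same model is
available (`method="nonlinear"`) and agrees with the linearization to 1e−6
on clean data. Compounds with fewer than two usable levels, or a
non-positive slope, are flagged "inactive/unfittable" rather than forced.

IC50s are reported from the median-effect fit at `fa = 0.5` (i.e. `Dm`), not
from the 4PL midpoint, for consistency with the CI machinery; the 4PL fit
(fixed initialization: e0 = 1, emax = min v, ec50 = geometric-mid dose,
slope = 1) is retained as a QC companion with a median-effect fallback for
its EC50 when it does not converge.

## Synergy scoring

Excess HSA and delta Bliss are computed on replicate-mean viability over
interior wells (negative = synergy); each surface is summarized by the sum
over its negative wells only, so antagonistic wells do not cancel synergy.

The combination index is the two-term Chou–Talalay form
`CI = dA/DxA(fa_obs) + dB/DxB(fa_obs)` per well (no third product term — the
mutually-exclusive form commonly reported). Collapsing the CI surface to one
scalar for a matrix (non-fixed-ratio) design is a genuine design choice:

- The evaluation band is `fa ∈ [0.25, 0.75]`, with its upper edge capped at
  the largest `fa` either single agent reached on its own axis. Beyond that
  cap both `Dx` values are pure extrapolations of the median-effect line,
  which is exactly where partial-efficacy drugs break it.
- The default policy reports the **median CI over band wells**. The
  alternatives — the band minimum and the diagonal well nearest `fa = 0.5` —
  are implemented and recorded in every report, but the band minimum of ~15
  noisy per-well values is biased far below the true CI (measured
  false-positive rates above 0.3 at 10% noise where the median stays below
  0.01), so it is not the default.
- If every scoreable well is deeper than the band (an over-effective
  combination — typically the strongest synergists), the well nearest
  `fa = 0.5` is scored and the pair flagged `band-fallback`; only a pair
  with no measurable combination effect anywhere is left CI-undefined
  (`no-effect-band`).

Beta is the maximal-efficacy ratio
`β = v(top, top) / min(v(top, 0), v(0, top))`: β < 1 iff the combination
beats the best single agent's maximal observed effect. When the best single
agent already reduces viability below 0.01 there is no headroom to measure
and β is undefined (`singles-saturating`).

Hits require a defined CI strictly below 0.5 **and** a defined β strictly
below 1. Pairs with undefined scalars are reported with flags and listed
separately; they are excluded from the gate in either direction, and the
triage denominator counts only scoreable pairs. Hits rank by CI ascending,
ties broken by the delta-Bliss negative sum, then pair id, making exports
byte-deterministic.

## Synthetic screens and what they do (not) show

The generator draws single-agent curves
`v(d) = emax + (1 − emax)/(1 + (d/ec50)^slope)` and builds combination
surfaces in three modes:

- `bliss_independent` — `v = vA·vB` (the null);
- `hsa_equal` — `v = min(vA, vB)`;
- `potency_shift` — Loewe-style synergy of strength ψ ≥ 1: interior wells
  solve `ψ·(dA/DxA(fa) + dB/DxB(fa)) = 1` with `Dx` the pure median-effect
  inversion of each agent's true (ec50, slope). ψ = 1 is exact Loewe
  additivity (for a drug against itself, the surface is the single-agent
  curve evaluated at dA + dB), and a pipeline with exact single-agent fits
  recovers CI = 1/ψ at every interior well — giving brute-force-checkable
  targets. The shift applies to interior wells only; matrix edges always
  show the unshifted singles (otherwise the fitted singles would absorb the
  shift and CI would revert to 1). The combination's efficacy floor deepens
  to `emaxA·emaxB` so that genuine synergists also clear the β gate, which a
  pure potency shift capped at the singles' floors cannot.

Replicate noise is multiplicative lognormal with unit mean (keeps signal
positive; CV is exact, verified empirically at 100 replicates). Raw signal
is viability × 1000 arbitrary units, vehicle wells included.

Library screens fix the anchor on the B axis of every block. The anchor's
parameters — ec50 1 µM, slope 1.5, emax 0.1 — model a weak-but-fittable
single agent: the anchor class in this screening design has minimal
single-agent activity, but CI needs a measurable anchor curve. Compound
ec50s are log-uniform across the design's nonzero dose span, slopes uniform
in [0.5, 3], emax uniform in [0, 0.4]; synergist ψ is uniform in [2, 8].
Each compound's dilution range is centered on its own activity (top dose =
ec50 × factor², capped at 10 µM), as screening labs choose ranges from
single-agent pre-screens; a fixed 10 µM top for everything leaves potent
full-efficacy compounds saturated below the β floor and distorts their fits.
MoA class labels concentrate synergists in a few classes so class
aggregation has signal.

Default problem sizes keep the whole suite fast while leaving the estimates
stable: property checks use 50–100 random curve draws; triage performance
uses ten 200-compound screens (10% synergists, triplicate 6×6, CV 10%).
Under those conditions the pipeline measures sensitivity ≈ 0.95–0.98 and
false-positive rate ≈ 0.003 (thresholds CI < 0.5, β < 1).

What the simulations do **not** capture: plate-position and edge effects,
systematic (non-independent) replicate error, dispensing artifacts, readout
crosstalk between viability and apoptosis channels, and interaction shapes
outside the three generative modes (e.g. efficacy-only synergy without
potency shift, or dose-ratio-dependent synergy). Passing tests demonstrate
correctness of the scoring and triage machinery under the stated noise
model, not robustness of hit calls on real plates.

## Numerical choices and degenerate inputs

- Loewe surface solving uses bracketed Brent root-finding on `fa` in
  (1e−12, 1 − 1e−12) with tight tolerances; out-of-bracket cases resolve to
  no effect / full effect analytically.
- CSVs are written with round-trip float precision (`%.17g`) and read with
  pandas' `round_trip` parser, so write∘read is the identity on doses and
  signals; file headers carry the tool version and a hash of the
  analysis-relevant configuration (output paths excluded).
- Fits are deterministic: fixed initializations, no random restarts.
  Identical inputs, config and seed give byte-identical exports.
- Degenerate inputs fail loudly and specifically: missing CSV columns are
  named; ragged grids list their missing wells; non-positive vehicle means,
  negative signals, mixed anchors and unknown CI policies each raise typed
  errors.

## Known limitations

- With partial-efficacy singles (emax well above 0), the median-effect
  extrapolation biases CI low even after plateau censoring; a rare
  borderline Bliss-null pair (~2% at emax ≈ 0.35) can cross the 0.5 gate
  without noise. This is a property of the Chou–Talalay framework applied to
  partial agonists, documented rather than patched; the β gate does not
  screen it out because Bliss independence itself deepens the combined
  floor.
- β compares only the top-dose corner; it is noisy when singles approach
  saturation and is undefined past the 0.01 floor.
- The scalar CI of a matrix design depends on the collapse policy; reports
  record the policy and the well used so downstream consumers can
  recompute.
- No statistical null (resampling) is attached to the synergy sums; they
  rank, they do not test.
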