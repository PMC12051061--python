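# Methods

## The correlation model

The unit of inference is the triple (feature *f*, taste category *c*,
segment *w*), where a segment is a contiguous window of 5–9 ordered
fractions. Feature intensities restricted to a window are often strongly
skewed (an elution profile spans orders of magnitude), while windows near
an elution apex can look symmetric; consolidated taste intensities are
sums of ordinal scores with many exact zeros. No single correlation
statistic suits both regimes, hence the gate: each window's two vectors
are screened with a Shapiro–Wilk test (Royston's AS R94 approximation),
and Kendall's τ_b is used when **either** vector deviates from normality
at p < 0.05, Pearson's r otherwise. The "either" reading is the
conservative one — the linear-model statistic is trusted only when both
inputs look normal; a `gate_mode="both"` switch gives the laxer reading.

p-values: Kendall's exact two-sided permutation p is computed for
tie-free windows with n ≤ 9 from the inversion-count (Mahonian) null
distribution; windows with ties (ubiquitous in taste vectors) use the
tie-corrected normal approximation. Pearson p comes from
t = r√((n−2)/(1−r²)) on n−2 df. Both match scipy's reference
implementations to ~1e-12 (enforced by tests). All raw p-values from the
whole batch of triples are Benjamini–Hochberg adjusted **once** — not per
category or per length — because the hypothesis family is the full sweep.

Retention keeps adjusted p < 0.05 **and** signed coefficient > 0.95. The
signed reading follows the scientific goal (a taste *caused by* a
compound rises with it); absolute-value retention is a flag. Refinement
then requires ≥ 4 of the window's fractions to be among the feature's
top-5 intensities over *all* fractions, ties at the 5th value included.
This kills the most seductive artefact of windowed correlation: two
monotone flanks of *different* peaks correlate perfectly, but only
windows straddling the feature's own apex survive the rank rule.

Degenerate windows (either vector constant, e.g. a taste absent from the
whole window) are skipped and counted, not scored as zero: a constant
vector carries no ordering information and any coefficient assigned to it
would be an invention.

Missing feature cells are left-censored detections, imputed as half the
feature's minimum observed value (per feature, preserving each ion's
dynamic range; a global-minimum mode exists). Features seen in fewer than
5 fractions are dropped before imputation.

## NMR session design

Fractions are compared through ¹H spectra alone. Processing: linear
interpolation onto a uniform grid over 0–14.85 ppm whose resolution is the
median native point spacing; total-intensity normalization (probabilistic
quotient available — the choice only removes scale and the downstream
distance is scale-sensitive, so the simplest remover is the default);
Lorentzian least-squares refinement of local maxima; consensus peak
centers built by single-linkage merging of all fitted centers closer than
the 0.01-ppm integration width (on sorted 1-D centers single linkage is
exact adjacent-gap chaining); trapezoidal integration over ±0.005 ppm
around each consensus center, per sample.

Clustering operates on √(areas) with the Canberra distance
Σ|u−v|/(|u|+|v|) (0/0 terms contribute 0) and the ward.D2 Lance–Williams
recurrence, cut into k = 7 clusters. A caveat stated openly: ward.D2
assumes Euclidean dissimilarities and Canberra is not Euclidean, so the
Ward variance interpretation is heuristic here; the recurrence itself is
well defined and is applied verbatim (scipy's `linkage(…, "ward")` on the
precomputed condensed matrix; a naive O(n³) replay of the recurrence
serves as the test oracle). Cluster labels are renumbered by median
position in the fraction order, which makes them invariant to input
permutation and naturally aligned with the polarity gradient. Sessions
take one cluster per week, split into consecutive chunks of ≤ 7 fractions.
Manual ppm re-referencing of drifting samples is a per-sample offset in
the run configuration, not an algorithm.

## Sensory consolidation

"Reported" means score > 0; the data model never records zeros (a zero
score and a non-report are indistinguishable in free profiling). The
consensus rule keeps a (fraction, category) cell only when ≥ 2 distinct
panelists reported it. Repeated reports by one panelist for the same cell
collapse to their maximum before summation, so the "sum over panelists"
cannot be dominated by one enthusiastic scorer. Mass normalization
divides each fraction's row by its dry mass; category shares are ratios
of (optionally normalized) column sums. The descriptor network links two
raw descriptors when they were assigned to the same fraction, weighted by
the number of such fractions. Working concentrations follow the dosing
arithmetic of a fractionation campaign: base 3 mg/L × the fraction's mass
share × a per-cluster adjustment factor (e.g. 1/50 for a hyper-potent
cluster, 2 for the most massive one).

## The synthetic generator

The generator emulates the *data layout and noise structure* of a real
campaign, with a known ground truth:

* **Elution**: Gaussian profiles in fraction index — contiguous
  equal-volume cuts of a smooth gradient make smooth unimodal spill-over
  the realistic shape. Widths are drawn from σ ∈ [1.5, 2.0] fractions
  (FWHM ≈ 3.5–4.7 cuts), so a compound is quantifiable in ~9–11
  consecutive fractions: wide enough that 9-fraction windows see a graded
  profile, narrow enough that compounds more than ~2 fractions apart are
  statistically distinguishable.
* **Features**: one per compound; intensity = abundance × profile ×
  lognormal noise (CV 0.1, a routine LC-MS quantification precision);
  values below the detection limit are recorded as missing. Abundances
  are lognormal over ~2 decades; planted actives sit in the upper range,
  as taste-driving constituents of an enriched extract do.
* **NMR**: each compound family (iridoid, xanthone, flavonoid,
  triterpene) carries a characteristic shift motif; a compound's spectrum
  is the motif plus a private resonance, all Lorentzians; a fraction's
  spectrum is the concentration-weighted sum plus baseline noise.
* **Panel**: perceived intensity follows a saturating Hill-type response
  scale·S/(S + K) with K = 0.4 stimulus units and planted potencies
  0.45–0.65, placing a peak-eluting active mid-scale (≈ 5–6 of 10) — the
  synthetic analogue of a real campaign's working-concentration
  calibration, which dilutes hyper-potent material precisely to keep the
  panel in its dynamic range. Per-panelist Gaussian noise (sd 1) is added
  before rounding to the 0–10 integer scale; zero scores emit no record.
  Reporting is probabilistic: the detection probability rises from a 5%
  false-alarm floor (a trained panel's sporadic spurious reports — these
  also make the no-actives null world produce *some* records, so
  false-discovery control is testable rather than vacuous) towards 1 as
  the stimulus grows.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: adduct/isotope feature redundancy
and ion-identity structure, retention-time drift, inter-panelist scale
differences and session effects, taste mixtures/suppression between
categories, NMR phasing/baseline artefacts, and any annotation layer.
Recovery of planted pairs here demonstrates the statistic's mechanics,
not instrument-grade sensitivity.

Determinism: every generator derives its randomness from the ground-truth
seed through named substreams, so identical arguments give bit-identical
outputs, and the full pipeline is reproducible from the single run seed.

## Problem sizes and numerical choices

The default scenario (50 fractions × 300 features × 10 categories × 220
segments) yields ~650k triples of which typically ~5×10⁴ are non-constant
and computed — small enough that the whole pipeline runs in seconds on
one core, large enough that the BH batch behaves like the real sweep.
Statistical kernels are vectorized over windows of a common length
(Shapiro–Wilk weights depend only on n; Kendall concordance uses pairwise
sign products; exact null tables are precomputed per n). The oracle
equivalence tests run the same records through naive per-record loops.

Tie-breaks and edge cases are fixed deliberately: top-5 rank sets include
all fractions tying the 5th value; records are emitted in a sorted
canonical order so reports are byte-stable; an all-missing feature is an
error rather than silently imputed; Canberra 0/0 terms are zero; W is
clipped into (0, 1]; BH is clipped at 1.

## Known limitations

* The ±0.95 retention bar on τ_b means tie-free Kendall windows only pass
  at τ = 1 for n ≤ 9; with ties, τ_b can fall strictly between 0.944 and
  1. This step behaviour is inherent to rank statistics on short windows.
* Under realistic panel noise the default scenario sits close to the
  detection boundary by design: recovery of every planted active is the
  expected outcome, not a mathematical certainty, and co-eluting inert
  features are legitimately indistinguishable from the causal feature.
* ward.D2 on Canberra dissimilarities has no variance interpretation (see
  above); it is retained because it is the field's established recipe for
  this task.
* The panel model is a stand-in: no quantitative panelist model exists
  for free descriptive profiling of fractionated extracts, so the
  dose-response family and its parameters describe this package's
  synthetic world, not any real panel.
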