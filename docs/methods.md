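# Methods

## Scope and model

`nirsconn` implements a resting-state functional-connectivity analysis of
prefrontal-cortex fNIRS recordings in a paired (pre/post) design, for three
shift-work groups measured before and after their shifts. The analysis
chain is:

1. **Optical preprocessing.** Dual-wavelength (690/830 nm) intensities are
   converted to optical-density changes, ΔOD(t) = −log10(I(t)/I_ref);
   band-pass filtered to the hemodynamic band 0.02–0.1 Hz; despiked by a
   discrete-wavelet outlier rule; and converted to oxy-/deoxy-hemoglobin
   concentration changes with the modified Beer–Lambert law (MBLL),
   ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF, solved per sample as a
   2×2 linear system. Only oxy-Hb is carried forward (better sensitivity to
   regional blood-flow changes).
2. **Connectivity.** The edge weight between channels i and j is the
   Pearson correlation COR(x_i, x_j) of their oxy-Hb time courses; per
   subject/session this gives a 22×22 symmetric matrix with unit diagonal.
   Group matrices are plain element-wise averages. The headline scalar is
   the mean of the 231 upper-triangle entries.
3. **Edge statistics.** Each edge's per-subject pre/post values enter a
   two-sided paired t-test (df = n−1); the 231 p-values are corrected with
   the Benjamini–Hochberg step-up procedure at q = 0.05. The group-level
   mean-COR comparison is the same paired t-test on per-subject mean-COR
   scalars.
4. **Graph topology.** Binary networks come either from an absolute cut
   (COR > 0.7, strict) or from a density threshold T that keeps the
   ⌊T·231⌋ strongest edges; the sweep T = 0.1, …, 0.9 yields per-threshold
   clustering coefficient (Cnet), global efficiency (Eglobal), local
   efficiency (Eloc, mean and nodal), characteristic path length (Lp), and
   nodal betweenness centrality. Small-worldness is
   σ = γ/λ with γ = Cnet/Cran and λ = Lnet/Lran, where Cran, Lran are means
   over 100 matched random networks generated by Maslov–Sneppen
   degree-preserving double-edge swaps (10 swaps per edge).

## Montage

The fixed montage covers the prefrontal cortex with 15 optodes (7 sources,
8 detectors, 30 mm separation) defining 22 channels, partitioned into
dlPFC (Brodmann 9/46: channels 1–6, 8, 9, 14, 18), FPC (Brodmann 10:
7, 10–13, 15–17) and OFC (Brodmann 11: 19–22), with published MNI
coordinates per channel. The table's final column (a registration
probability in [0, 1]) is stored as metadata only. The channel→optode
pairing is not published; the packaged assignment is a reconstructed
standard 3×5 alternating grid and is never consumed by any computation.

## Synthetic cohorts

No recordings were released with the study, so every downstream stage is
validated by parameter recovery on synthetic paired cohorts with planted
ground truth:

* **Hemodynamic signal.** White Gaussian noise per channel is filtered with
  the *same* Butterworth band design used in preprocessing, standardized,
  and mixed through the symmetric square root of the target correlation
  matrix — so the planted quantity is exactly the population Pearson
  correlation the pipeline estimates. Targets are ROI-block matrices
  (`within_r` inside each ROI, `between_r` elsewhere), repaired to the
  nearest valid correlation matrix by eigenvalue clipping when needed.
* **Nuisance.** Independent per-channel cardiac (1.2 Hz), respiratory
  (0.3 Hz) and Mayer-wave (0.1 Hz) oscillators with random phases and
  amplitudes (0.5, 0.4, 0.3 signal-SD units), a linear drift (half-excursion
  SD 1 signal-SD), broadband white noise (0.4), and Poisson motion spikes
  (0.5/min, amplitude SD 3) shaped as a 0.4 s boxcar with a 1.5 s
  exponential recovery. Amplitudes were chosen once as representative of
  raw prefrontal fNIRS (cardiac pulsation comparable to the hemodynamic
  signal; in-band Mayer contamination small but nonzero).
* **Defaults = study conditions.** 300 s recordings at 7.4074 Hz, 22
  channels, group sizes 17/18/19, paired pre/post sessions, morning and
  afternoon groups with a planted within-ROI decrease (0.8 → 0.6 at
  between-ROI 0.3) and the night group with the reverse increase.
* **Inverse MBLL.** `hb_to_intensity` is the exact algebraic inverse of the
  forward law, so concentration → intensity → concentration round trips are
  exact to 1e−9.

What the generator does **not** emulate: task-evoked responses and balloon
type hemodynamics, scalp/superficial physiology shared across channels,
wavelength-dependent DPF, spatially correlated motion, or non-Gaussian
vigilance drifts. Passing parameter-recovery tests therefore demonstrates
the correctness of the estimators under the stated covariance model, not
robustness to every artifact of field recordings.

## Numerical and design choices

* **Baseline for ΔOD.** Referencing intensities to their temporal mean
  forces mean(10^−ΔOD) = 1 per trace, which means an arbitrary target ΔOD
  can only be recovered up to a per-trace additive constant. Synthetic
  recordings therefore carry their known baseline
  (`intensity_to_od(..., baseline="stored")`), making the MBLL round trip an
  identity; on real data the residual constant is removed by the band-pass
  (applied in OD space, equivalent under MBLL linearity to filtering
  intensity-derived signals). Concentrations are ΔmM; separation is
  converted to cm inside the MBLL step.
* **Filter.** 4th-order Butterworth band-pass applied forward-backward
  (zero phase). Contract (tested): a 0.05 Hz tone passes within 10%, a
  1.2 Hz tone is attenuated ≥ 10×, a linear ramp ≥ 20× over the central 80%
  of samples. Inputs shorter than the padding window (28 samples) are
  rejected.
* **Despiking.** Daubechies filter of length 10 (the orthogonal wavelet of
  the configured support); per detail level, coefficients are z-scored
  robustly (median/MAD — a large spike would inflate a plain SD enough to
  mask itself) and zeroed when their two-sided Gaussian tail probability
  falls below 1e−4. The `alpha` parameter is carried for compatibility and
  does not enter the rule. The contract is behavioural: a planted 10-SD
  spike's residual after correction is ≤ 30% of its original deviation,
  while spike-free signals are preserved (r ≥ 0.99).
* **Extinction coefficients.** Not part of the study's printed record;
  shipped as an editable JSON table with standard compendium values
  (Gratzer/Cope): ε(HbO, 690) = 0.276, ε(HbR, 690) = 2.05196,
  ε(HbO, 830) = 0.974, ε(HbR, 830) = 0.69304 mM⁻¹cm⁻¹. One DPF (6.53) is
  used for both wavelengths; wavelength-specific DPFs are a config option.
* **Degenerate statistics.** Zero-variance paired differences with non-zero
  mean are flagged and excluded from the FDR family rather than assigned
  p = 0; identical pre/post vectors give t = 0, p = 1. Constant channels
  raise an error naming the channel (never a silent 0).
* **Thresholding.** The absolute cut is strict (an entry exactly at 0.7 is
  not an edge); negative correlations are retained in matrices but can
  never pass the positive cut. Density thresholding breaks ties at the cut
  by ascending (i, j) order, making edge sets deterministic and nested
  across T. T is interpreted as density (fraction of strongest edges) for
  the sweep — the only reading under which efficiency provably rises with
  T — with the absolute-r mode used for the 0.7 display network. An
  optional Fisher-z variant of both averaging and thresholding exists but
  is off by default.
* **Disconnected graphs.** Efficiencies use the 1/∞ = 0 convention; Lp is
  the mean over connected pairs only and is NaN on edgeless graphs
  (recorded as missing in sweeps; AUC renormalizes over the thresholds
  actually defined, so a constant curve has AUC equal to that constant).
  Nodes of degree < 2 contribute 0 to clustering and local efficiency.
* **Betweenness.** Normalized by (n−1)(n−2) over ordered pairs — for
  undirected graphs this equals the conventional normalized centrality; a
  halved (unordered) variant is available.
* **Nodal group tests.** The sweep is collapsed to one value per node per
  subject by trapezoid AUC over T (the study does not state its reduction;
  AUC is the standard sparsity-sweep summary). Nodal tests are presented
  uncorrected at α = 0.05, matching the per-node presentation convention;
  edge-wise tests are FDR-corrected.
* **Small-world nulls.** "Matched" random networks are operationalized as
  degree-preserving rewirings (the standard null in the graph-theory
  literature this metric comes from); graphs too constrained to swap (e.g.
  triangles) are returned unchanged with a degenerate flag, and σ is NaN
  with an `undefined` flag when the null clustering vanishes.
* **Determinism.** Every stochastic component (simulation, cohort seeds,
  rewiring) is a pure function of an explicit seed; per-subject and
  per-null seeds are spawned from master seeds through `default_rng`.
  All text output uses a fixed float format, so identical seeds give
  byte-identical numeric outputs.

## Sampling error of band-limited correlations

A 0.02–0.1 Hz Gaussian process observed for 300 s carries only a few dozen
effective samples (spectral degrees of freedom ≈ 2T(∫G)²/∫G² ≈ 48 for the
squared filter response, with additional finite-window inflation at this
duration; Monte-Carlo gives SD(r) ≈ 0.33 between independent channels).
Parameter-recovery tolerances in the test suite are set from this oracle —
e.g. seed-averaged recovery bounds scale as SD/√(n_seeds) — rather than
from the nominal 2222-sample count, which would be off by roughly an order
of magnitude. This is also why paired cohorts of 17–19 subjects detect
within-ROI correlation shifts of 0.2 reliably in direction but not every
single edge.

## Problem sizes

Default analyses use the full study geometry (22 channels, 300 s at
7.4074 Hz, group sizes 17/18/19, 100 nulls, 9-point sweep). The test suite
exercises reduced replicate counts where a property is statistical (e.g. 50
cohort replicates for direction recovery, 100 for FDR control, 20 seeds for
small-world families) and reduced cohort sizes for pure plumbing checks
(e.g. run-twice byte-identity with 3 subjects per group and 25 nulls);
these sizes are the package's own choice of Monte-Carlo precision. A full
paper-scale synthetic run (54 subjects × 2 sessions with sweeps and 100
nulls per group network) completes in a few minutes on one CPU core.

## Known limitations

* The wavelet despiking rule is a normative reconstruction: the cited
  toolbox's exact use of its four parameters is not documented in the
  source text, so the rule here is defined (and tested) by its planted-spike
  behaviour.
* Group comparisons are within-group paired tests only; between-group
  (unpaired) contrasts, NBS-style cluster correction, partial correlation
  and coherence connectivity, and weighted-graph metrics are out of scope.
* The study's printed group-level numbers (mean-COR values, per-edge
  p-values, nodal means) derive from unreleased recordings and cannot be
  reproduced numerically; the pipeline reproduces their *structure* and
  direction on synthetic cohorts with known truth.
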