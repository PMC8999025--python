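# nirsconn

Resting-state fNIRS functional-connectivity analysis of the prefrontal
cortex in a paired (pre/post) design — built for studies that measure the
same subjects before and after an intervention or work shift and ask how
their prefrontal connectivity and network topology changed.

The package covers the full chain from raw dual-wavelength optical
intensities to network statistics:

* **Preprocessing** — optical density, zero-phase 0.02–0.1 Hz Butterworth
  band-pass, wavelet despiking of motion transients, and the modified
  Beer–Lambert law (DPF 6.53, 30 mm separation) yielding oxy-Hb
  concentration changes for 22 prefrontal channels (dlPFC / FPC / OFC,
  Brodmann 9/46, 10, 11).
* **Connectivity** — Pearson correlation matrices
  `COR(x_i, x_j) = Σ(x_i−x̄_i)(x_j−x̄_j) / √(Σ(x_i−x̄_i)² Σ(x_j−x̄_j)²)`
  per subject/session, group averages, mean-COR scalars, and binarization
  at COR > 0.7.
* **Paired statistics** — per-edge two-sided paired t-tests with
  Benjamini–Hochberg FDR at q < 0.05, and the group-level mean-COR paired
  comparison.
* **Graph topology** — clustering coefficient, global/local efficiency,
  characteristic path length and betweenness centrality over a density
  threshold sweep T = 0.1…0.9, and small-worldness σ = γ/λ
  (γ = C/C_ran, λ = L/L_ran) against 100 degree-preserving random networks.
* **Synthetic cohorts** — paired recordings with a *planted* ROI-block
  correlation structure plus cardiac/respiratory/Mayer oscillations, drift,
  white noise and motion spikes, so that every stage has a
  parameter-recovery test with known ground truth.

## Worked example

```python
from nirsconn import synthetic
from nirsconn.model import PairedConnectivityModel

# morning-shift-like cohort: within-ROI correlation drops 0.8 -> 0.6
truth_pre = synthetic.make_block_correlation(0.8, 0.3)
truth_post = synthetic.make_block_correlation(0.6, 0.3)
cohort = synthetic.generate_paired_cohort(17, truth_pre, truth_post, seed=1)

res = PairedConnectivityModel.from_cohort(cohort).fit(n_null=100, seed=1)
print(res.summary())
```

prints (exact numbers are seed-dependent):

```
Paired resting-state connectivity analysis
==============================================
group: morning    subjects: 17 (paired pre/post)

mean COR pre : 0.4345
mean COR post: 0.3679
paired t = 1.759, p = 0.09769

edge-wise paired t-tests: 56 of 231 edges significant at BH-FDR q < 0.05
binary network (r > 0.7): 72 edges pre, 0 post

small-world at density T = 0.3 (100 degree-preserving nulls):
  pre : gamma = 3.119, lambda = 0.623, sigma = 5.007
  post: gamma = 2.966, lambda = 0.616, sigma = 4.819

nodal betweenness, p < 0.05 (uncorrected): CH06, CH14
nodal local efficiency, p < 0.05 (uncorrected): CH03, CH13, CH14, CH19
```

Reading this: the planted within-ROI decrease shows up as a drop in mean
COR (0.43 → 0.37) and in 56 FDR-significant edges; the modular planted
structure makes the thresholded network strongly small-world (σ ≈ 5 ≫ 1);
and the per-node tests flag channels whose betweenness/local-efficiency
AUC over the threshold sweep moved between sessions.

`res.edge_frame()` gives the per-edge table (edge, ROI pair, t, p, FDR
flag) sorted by p; `res.nodal_bc` / `res.nodal_eloc` the per-channel
tables; matrices and networks export to TSV and BrainNet-Viewer
`.node`/`.edge` text formats via `nirsconn.io`.

There is also a CLI:

```bash
nirsconn run-all --seed 1 --out myrun        # 3 groups (17/18/19), full analysis
nirsconn simulate --n-subjects 17 --seed 1 --out cohort/
nirsconn connect cohort/*_pre_hb.tsv --out conn/
nirsconn demographics
```

`run-all` writes, per group: per-subject oxy-Hb and connectivity TSVs,
group mean matrices, the 0.7-threshold network, the edge-test table, the
metric sweep, the small-world summary, nodal comparisons, and a JSON
manifest with every parameter and seed (identical seeds give byte-identical
numeric outputs).

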