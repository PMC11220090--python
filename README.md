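# saltgrip

Quantifying the continuum of zinc-finger transcription-factor retention on
native chromatin.

## The problem

Formaldehyde-crosslinked ChIP (X-ChIP) accumulates short-lived binding events
over the ~10-minute fixation window, so the measured occupancy compresses the
true spectrum of residence times a TF such as CTCF has across its motifs.  On
*native* (uncrosslinked) chromatin, protein–DNA contacts survive only on their
intrinsic affinity, and a series of increasingly stringent perturbations —
rising salt concentration during native ChIP, or zinc depletion for
zinc-finger TFs — strips weakly retained sites first.  `saltgrip` implements
the analysis stack for this experimental design, for computational biologists
working with MNase-footprint fragment data and binned contact matrices:

- **Footprints** — V-plots (fragment length vs. midpoint offset from a site
  center), inside-V footprint fractions, fragment-length spectra, and
  strand-oriented scaled 5′/3′ digestion-boundary pileups.
- **S-score (Salt Tolerance Score)** — the package's core model.  Per-motif
  ChIP signal across the ordered salt series (75/150/225 mM NaCl) is
  log2(1 + x)-transformed and column-standardized; the first principal
  component, oriented so the highest-stringency loading is positive, scores
  each motif's retention:

  ```
  z_ic = (log2(1 + x_ic) − μ_c) / σ_c ,   S_i = Σ_c z_ic · v_c  (v = PC1)
  ```

- **Motif grammar** — PWM scanning with *exact* score p-values (dynamic
  programming over a discretized score lattice, equal to exhaustive k-mer
  enumeration), and annotation of upstream/downstream auxiliary motifs
  (U-/D-motifs, canonically 5–6 bp upstream of the CTCF core motif).
- **Occupancy** — per-motif signal matrices, a transparent Poisson peak
  caller, salt-nesting classification (N1/N2/N3/X), and lost/stable/gained
  differential calls (FDR < 0.05, |log2FC| ≥ 1).
- **Retention analyses** — X-ChIP-signal-matched sampling and k-group
  S-score grading, cumulative-rank curves and AUC comparison of competing
  retention metrics (two-sided Wilcoxon rank-sum tests).
- **Structure** — expected-by-distance, O/E normalization, diamond insulation
  scores, paired boundary-stability tests, local pileups and aggregate peak
  analysis (APA) of loop strength between conditions (e.g. DMSO vs. the zinc
  chelator TPA).
- **Synthetic data** — a first-class generator that emulates the statistical
  structure the analyses assume: a latent per-motif retention continuum,
  logistic salt-dependent occupancy loss with nested peak sets, crosslink
  accumulation of transient binding, retention-coupled auxiliary motifs, and
  contact maps whose loop/boundary stability tracks anchor retention.

## Worked example

Fit the salt-tolerance model on a synthetic salt series and compare the score
with the latent truth:

```python
from saltgrip import SimConfig, simulate_truth, simulate_fragment_library, SaltToleranceModel
from saltgrip.occupancy import quantify_signal_matrix
from scipy.stats import spearmanr

cfg = SimConfig(seed=1)
catalog, truth, genome = simulate_truth(cfg)
libraries = {
    cond: simulate_fragment_library(truth, catalog, cond, cfg)
    for cond in cfg.salt_labels
}
model = SaltToleranceModel.from_libraries(libraries, catalog, window=80)
results = model.fit()
print(results.summary())
rho = spearmanr(results.sscore, truth.motifs["retention"]).statistic
print(f"Spearman(S-score, latent retention) = {rho:.3f}")
```

prints

```
Salt Tolerance Score (PC1 of salt-series signal)
================================================
motifs:        2000
conditions:    75mM, 150mM, 225mM
preprocessing: log2(1+x), column z-score (ddof=1)

PC1 loadings (sign: highest stringency positive):
          75mM: +0.5571
         150mM: +0.6247
         225mM: +0.5471

variance explained:
  PC1: 0.7855
  PC2: 0.1708
  PC3: 0.0437

Spearman(S-score, latent retention) = 0.983
```

All three salt conditions load positively on PC1 (the score averages
retention information across the series, weighting the mid-stringency
condition highest), PC1 carries ~79% of the standardized variance, and the
score recovers the planted retention ranking almost perfectly.  Downstream,
`results.matched_grouping(xchip_signal, k=6)` grades motifs into six groups
with matched X-ChIP signal but strictly decreasing S-score, and
`saltgrip.retention.rank_metric_comparison` shows the S-score explains
auxiliary-motif presence better than the crosslink-compressed X-ChIP signal.

A CLI mirrors the library (`saltgrip simulate`, `coverage`, `vplot`,
`endpileup`, `scan`, `sscore`, `group`, `rankeval`, `structure`).

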