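"""Score a signature on single-cell data and split cells at the bimodal cutoff.

Simulates a UMI matrix whose malignant cells carry a two-state latent
signature level, applies the standard cell filters and log-normalization,
scores each cell, and fits a two-component Gaussian mixture to find the
cutoff where the component densities intersect.
"""

from budsig import qc, scoring
from budsig.simulate import BimodalParams, generate_single_cell

umi, meta, signature = generate_single_cell(
    n_cells=3000,
    cell_type_mix={"malignant": 0.6, "fibroblast": 0.2, "immune": 0.2},
    bimodal_params=BimodalParams(means=(0.0, 5.0), sds=(1.0, 1.0), weights=(0.5, 0.5)),
    seed=2,
)
norm, report = qc.sc_preprocess(umi)
print(f"cells: {report.n_cells_in} -> {report.n_cells_out} "
      f"(removed {report.n_low_genes} low-coverage, {report.n_high_mito} high-mito)")

scores = scoring.score_signature(norm, signature)
malignant = scores[meta.loc[norm.samples, "cell_type"] == "malignant"]
others = scores[meta.loc[norm.samples, "cell_type"] != "malignant"]
print(f"mean score: malignant {malignant.mean():.2f} vs other cell types {others.mean():.2f}")

fit = scoring.fit_bimodal_cutoff(malignant, seed=0)
labels = scoring.classify(malignant, fit.cutoff)
print(f"bimodal fit converged={fit.converged}: components at {fit.mu1:.2f} and "
      f"{fit.mu2:.2f}, density-intersection cutoff {fit.cutoff:.2f}")
print(f"classification: {(labels == 'high').sum()} signature-high, "
      f"{(labels == 'low').sum()} signature-low malignant cells "
      "(the high fraction mirrors the planted 50/50 state mixture)")
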