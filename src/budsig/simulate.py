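"""Synthetic data generators with the statistical structure the analysis assumes.

Every downstream stage is exercised against data produced here, so the
generators encode the analysis' core assumptions explicitly:

* segment counts are negative-binomial around library-scaled gene means,
  with negative-control probes drawn from a background that carries no
  biological signal;
* budding cases contribute bud, budding-bulk and adjacent-stroma segments,
  non-budding cases contribute non-budding-bulk segments, and both
  contribute immune segments — the paired/unpaired contrast design;
* a configurable set of signature genes is overexpressed in bud segments
  only, and gene pairs can be given a condition-gated case-level
  correlation via a shared latent factor;
* single-cell signature states are a two-component mixture (bimodal TBS);
* bulk cohorts couple a latent bud fraction to signature expression, a
  Poisson tumor-bud count and an exponential survival time;
* compound screens couple viability log-fold changes linearly to the
  signature score.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix, SegmentCountMatrix, SignatureDef, SurvivalCohort
from .enrichment import GeneSetCatalog

#: default segment design: (segment_type, compartment) per case class
BUDDING_SEGMENT_TYPES = (
    ("bud", "tumor"),
    ("bud", "stroma"),
    ("bulk_budding", "tumor"),
    ("bulk_budding", "stroma"),
    ("immune", "immune"),
)
NONBUDDING_SEGMENT_TYPES = (
    ("bulk_nonbudding", "tumor"),
    ("bulk_nonbudding", "stroma"),
    ("immune", "immune"),
)


@dataclass
class CorrPair:
    """A gene pair given a case-level correlation in one condition only."""

    gene_a: str
    gene_b: str
    condition: str  # "bud_only" or "bulk_only"
    target_rho: float

    def __post_init__(self) -> None:
        if self.condition not in ("bud_only", "bulk_only"):
            raise ValueError("condition must be 'bud_only' or 'bulk_only'")
        if not -1 < self.target_rho < 1:
            raise ValueError("target_rho must be in (-1, 1)")


@dataclass
class SpatialSimConfig:
    """Study-design parameters of the spatial generator.

    Defaults mirror the reference cohort: 24 budding and 19 non-budding
    cases, bud/bulk/stroma/immune segments per case, negative-binomial
    counts with moderate overdispersion and a low negative-probe background.
    """

    n_budding_cases: int = 24
    n_nonbudding_cases: int = 19
    n_genes: int = 300
    n_negative_probes: int = 30
    segments_per_type: int = 2
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    library_size_log_sd: float = 0.30
    nb_dispersion: float = 0.10
    neg_probe_mean: float = 3.0
    planted_signature: dict[str, float] = field(default_factory=dict)  # gene -> fold >= 1
    planted_corr_pairs: list[CorrPair] = field(default_factory=list)
    corr_effect_log_sd: float = 1.5
    qc_fail_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_budding_cases", "n_nonbudding_cases", "n_genes", "n_negative_probes", "segments_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.neg_probe_mean <= 0:
            raise ValueError("neg_probe_mean must be > 0")
        for fold in self.planted_signature.values():
            if fold < 1:
                raise ValueError("planted fold effects must be >= 1")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture; var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_spatial(config: SpatialSimConfig) -> SegmentCountMatrix:
    """Generate a segment count matrix with probe annotation and QC metadata.

    Bud segments of budding cases carry the planted fold effects; planted
    correlation pairs receive a shared per-case latent factor, applied on the
    log-mean scale in the gated condition only (the latent correlation is
    inflated slightly to compensate for count-noise attenuation, so the
    case-level correlation lands near the configured target).
    """
    genes = config.gene_ids()
    gene_set = set(genes)
    for g in config.planted_signature:
        if g not in gene_set:
            raise ValueError(f"planted signature gene {g!r} not in gene universe")
    for pair in config.planted_corr_pairs:
        for g in (pair.gene_a, pair.gene_b):
            if g not in gene_set:
                raise ValueError(f"planted correlation gene {g!r} not in gene universe")

    rng = np.random.default_rng(config.seed)
    gene_log_mean = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    fold_log = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, fold in config.planted_signature.items():
        fold_log[gene_pos[g]] = np.log(fold)

    # per-case latent factors for the planted correlation pairs; the latent
    # (Pearson) correlation is boosted by the expected noise-to-signal ratio
    # of the aggregated counts so the achieved case-level rho tracks target
    n_cases = config.n_budding_cases + config.n_nonbudding_cases
    case_ids = [f"C{i + 1:03d}" for i in range(n_cases)]
    budding_cases = set(case_ids[: config.n_budding_cases])
    s2 = config.corr_effect_log_sd**2
    typical_mu = float(np.exp(config.baseline_log_mean))
    noise_var = (1.0 / typical_mu + config.nb_dispersion + config.library_size_log_sd**2) / config.segments_per_type
    pair_latents: list[tuple[CorrPair, dict[str, tuple[float, float]]]] = []
    for pair in config.planted_corr_pairs:
        rho_lat = np.clip(pair.target_rho * (1 + noise_var / s2), -0.999, 0.999)
        f = rng.normal(size=n_cases)
        ea = rng.normal(size=n_cases)
        eb = rng.normal(size=n_cases)
        a = np.sqrt(abs(rho_lat)) * f + np.sqrt(1 - abs(rho_lat)) * ea
        b = np.sign(rho_lat) * np.sqrt(abs(rho_lat)) * f + np.sqrt(1 - abs(rho_lat)) * eb
        pair_latents.append((pair, {case_ids[i]: (a[i], b[i]) for i in range(n_cases)}))

    rows = []
    meta_rows = []
    seg_counter = 0
    for case in case_ids:
        is_budding = case in budding_cases
        seg_types = BUDDING_SEGMENT_TYPES if is_budding else NONBUDDING_SEGMENT_TYPES
        for seg_type, comp in seg_types:
            for rep in range(config.segments_per_type):
                seg_counter += 1
                seg_id = f"S{seg_counter:04d}"
                lib = np.exp(rng.normal(0.0, config.library_size_log_sd))
                log_mu = gene_log_mean.copy()
                if seg_type == "bud" and comp == "tumor" and is_budding:
                    log_mu = log_mu + fold_log
                gated = "bud_only" if (seg_type == "bud" and comp == "tumor") else (
                    "bulk_only" if (seg_type == "bulk_budding" and comp == "tumor") else None
                )
                if gated is not None:
                    for pair, latents in pair_latents:
                        if pair.condition == gated:
                            la, lb = latents[case]
                            log_mu[gene_pos[pair.gene_a]] += config.corr_effect_log_sd * la
                            log_mu[gene_pos[pair.gene_b]] += config.corr_effect_log_sd * lb
                gene_counts = _nb_draw(rng, lib * np.exp(log_mu), config.nb_dispersion)
                neg_counts = _nb_draw(
                    rng, np.full(config.n_negative_probes, lib * config.neg_probe_mean), config.nb_dispersion
                )
                rows.append((seg_id, np.concatenate([gene_counts, neg_counts])))

                # QC metrics with independent Bernoulli failure injection
                metrics = {
                    "raw_reads": int(rng.normal(200_000, 30_000)),
                    "stitched_frac": float(np.clip(rng.normal(0.95, 0.02), 0, 1)),
                    "aligned_frac": float(np.clip(rng.normal(0.88, 0.03), 0, 1)),
                    "saturation_frac": float(np.clip(rng.normal(0.75, 0.08), 0, 1)),
                    "ntc_count": int(rng.poisson(100)),
                }
                fails = {
                    "raw_reads": 20_000,
                    "stitched_frac": 0.60,
                    "aligned_frac": 0.50,
                    "saturation_frac": 0.30,
                    "ntc_count": 2_500,
                }
                for metric, fail_value in fails.items():
                    if rng.random() < config.qc_fail_frac:
                        metrics[metric] = fail_value
                meta_rows.append(
                    {
                        "segment_id": seg_id,
                        "case_id": case,
                        "run_id": f"R{1 + (seg_counter - 1) % 3}",
                        "roi_id": f"{case}_{seg_type}_{rep + 1}",
                        "segment_type": seg_type,
                        "compartment": comp,
                        **metrics,
                    }
                )

    probe_ids = genes + [f"NegPrb{i + 1:03d}" for i in range(config.n_negative_probes)]
    counts = pd.DataFrame(
        np.vstack([r[1] for r in rows]), index=[r[0] for r in rows], columns=probe_ids
    )
    counts.index.name = "segment_id"
    probes = pd.DataFrame(
        {
            "gene_symbol": genes + [f"Neg{i + 1:03d}" for i in range(config.n_negative_probes)],
            "is_negative_control": [False] * config.n_genes + [True] * config.n_negative_probes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    meta = pd.DataFrame(meta_rows).set_index("segment_id")
    return SegmentCountMatrix(counts=counts, probes=probes, meta=meta)


@dataclass
class BimodalParams:
    """Two-component latent signature state of malignant cells."""

    means: tuple[float, float] = (0.0, 5.0)
    sds: tuple[float, float] = (1.0, 1.0)
    weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {sum(self.weights)}")
        if min(self.sds) <= 0:
            raise ValueError("component sds must be > 0")


def generate_single_cell(
    n_cells: int,
    cell_type_mix: dict[str, float],
    bimodal_params: BimodalParams,
    seed: int = 0,
    n_genes: int = 500,
    n_signature_genes: int = 28,
    n_mito_genes: int = 10,
    frac_low_coverage: float = 0.02,
    frac_high_mito: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame, SignatureDef]:
    """Simulate a UMI matrix whose malignant cells have a bimodal signature state.

    Malignant cells draw a latent state from the two-component mixture; the
    signature genes' Poisson rates scale with that state, so the per-cell
    mean log-normalized signature expression inherits the bimodality.
    Non-malignant cells sit at a low baseline.  A small fraction of cells is
    injected with low coverage or high mitochondrial content so the standard
    cell filters have something to remove.  Returns (UMI matrix, cell
    metadata, signature definition).
    """
    if abs(sum(cell_type_mix.values()) - 1.0) > 1e-9:
        raise ValueError("cell_type_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    sig_genes = [f"SIG{i + 1:02d}" for i in range(n_signature_genes)]
    other_genes = [f"BG{i + 1:03d}" for i in range(max(0, n_genes - n_signature_genes))]
    mito_genes = [f"MT-{i + 1}" for i in range(n_mito_genes)]
    all_genes = sig_genes + other_genes + mito_genes

    types = list(cell_type_mix)
    probs = np.array([cell_type_mix[t] for t in types])
    cell_types = rng.choice(types, size=n_cells, p=probs)
    comp = rng.choice([0, 1], size=n_cells, p=list(bimodal_params.weights))
    latent = rng.normal(
        np.array(bimodal_params.means)[comp], np.array(bimodal_params.sds)[comp]
    )

    base_log = rng.normal(1.0, 0.5, len(other_genes))
    mat = np.zeros((n_cells, len(all_genes)), dtype=np.int64)
    for idx in range(n_cells):
        malignant = cell_types[idx] == "malignant"
        sig_rate = np.exp(2.0 + latent[idx]) if malignant else np.exp(0.5)
        rates = np.concatenate(
            [
                np.full(len(sig_genes), sig_rate),
                np.exp(base_log),
                np.full(len(mito_genes), 1.0),
            ]
        )
        if rng.random() < frac_high_mito:
            rates[-len(mito_genes):] *= 50.0
        if rng.random() < frac_low_coverage:
            rates *= 0.02
        mat[idx] = rng.poisson(rates)

    cells = pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)], name="cell_id")
    umi = pd.DataFrame(mat, index=cells, columns=all_genes)
    meta = pd.DataFrame(
        {
            "cell_type": cell_types,
            "latent_state": latent,
            "component": comp,
        },
        index=cells,
    )
    signature = SignatureDef(name="TBS_sim", genes=sig_genes)
    return umi, meta, signature


@dataclass
class CohortSimConfig:
    """Bulk cohort with signature-linked tumor-bud counts and survival."""

    n_samples: int = 300
    true_hr: float = 1.5
    baseline_hazard: float = 0.02  # events per month in the low group
    censoring_rate: float = 0.3
    budding_score_link: float = 1.5  # slope of log TB rate on latent bud fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("true_hr and baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


def _solve_admin_censor_time(rate_mix: np.ndarray, target: float) -> float:
    """t_max of Uniform(0, t_max) administrative censoring hitting the target rate."""

    def expected_censored(tmax: float) -> float:
        m = 1.0 / rate_mix  # exponential means
        # P(C < T) with C ~ U(0,tmax), T ~ Exp(1/m): (m/tmax)(1 - exp(-tmax/m))
        return float(np.mean(m / tmax * (1 - np.exp(-tmax / m))))

    lo, hi = 1e-6, 1e8
    return float(optimize.brentq(lambda t: expected_censored(t) - target, lo, hi, xtol=1e-6))


def generate_bulk_survival(
    config: CohortSimConfig,
    signature: SignatureDef,
    n_background_genes: int = 50,
    effect_size: float = 2.0,
) -> tuple[ExpressionMatrix, SurvivalCohort, pd.Series]:
    """Simulate a bulk cohort: expression, survival and histological bud counts.

    A latent bud fraction u ~ Uniform(0,1) per sample drives (a) the
    signature genes' expression (log2 scale, slope ``effect_size``), (b) a
    Poisson tumor-bud count with log-rate slope ``budding_score_link``, and
    (c) exponential survival with hazard ``baseline_hazard * true_hr**high``
    where ``high = (u > 0.5)``.  Censoring is uniform administrative with
    the cutoff solved to match ``censoring_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = pd.Index([f"T{i + 1:04d}" for i in range(n)], name="sample_id")
    u = rng.uniform(0, 1, n)
    high = (u > 0.5).astype(int)

    base = rng.normal(5.0, 1.0, len(signature.genes))
    sig_log2 = base[None, :] + effect_size * u[:, None] + rng.normal(0, 0.5, (n, len(signature.genes)))
    bg_genes = [f"BGB{i + 1:03d}" for i in range(n_background_genes)]
    bg_log2 = rng.normal(5.0, 1.0, (n, n_background_genes))
    values = np.concatenate([2.0**sig_log2, 2.0**bg_log2], axis=1)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=samples, columns=list(signature.genes) + bg_genes),
        norm="raw",
    )

    tb = pd.Series(
        rng.poisson(np.exp(np.log(2.0) + config.budding_score_link * (u - 0.5) * 2)),
        index=samples,
        name="tb_count",
    )

    rate = config.baseline_hazard * config.true_hr**high
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        tmax = _solve_admin_censor_time(rate, config.censoring_rate)
        c = rng.uniform(0, tmax, n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    cohort = SurvivalCohort(
        pd.DataFrame(
            {
                "time": np.maximum(time, 1e-6),
                "event": event,
                "latent_high": high,
                "age": rng.normal(62, 10, n).round(1),
                "sex": rng.choice(["f", "m"], n),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
            },
            index=samples,
        )
    )
    return expr, cohort, tb


def generate_drug_panel(
    n_lines: int,
    n_compounds: int,
    effect_map: dict[str, float],
    seed: int = 0,
    signature: SignatureDef | None = None,
    noise_sd: float = 0.2,
    missing_frac: float = 0.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate cell-line expression and a compound-viability LFC matrix.

    Each line has a latent signature level; each compound's LFC is
    ``intercept + slope * latent + noise`` with the slope taken from
    ``effect_map`` (0 for compounds not listed).  Entries go missing at
    random with probability ``missing_frac``.
    """
    rng = np.random.default_rng(seed)
    lines = pd.Index([f"L{i + 1:03d}" for i in range(n_lines)], name="cell_line")
    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    unknown = set(effect_map) - set(compounds)
    if unknown:
        raise ValueError(f"effect_map names unknown compounds: {sorted(unknown)[:5]}")
    latent = rng.normal(0, 1, n_lines)

    sig = signature or SignatureDef(name="TBS_sim", genes=[f"SIG{i + 1:02d}" for i in range(28)])
    sig_log2 = 5.0 + latent[:, None] + rng.normal(0, 0.2, (n_lines, len(sig.genes)))
    expr = ExpressionMatrix(
        values=pd.DataFrame(2.0**sig_log2, index=lines, columns=sig.genes), norm="raw"
    )

    lfc = np.empty((n_lines, n_compounds))
    for j, compound in enumerate(compounds):
        slope = effect_map.get(compound, 0.0)
        lfc[:, j] = rng.normal(-0.1, 0.05) + slope * latent + rng.normal(0, noise_sd, n_lines)
    lfc_df = pd.DataFrame(lfc, index=lines, columns=compounds)
    if missing_frac > 0:
        mask = rng.random(lfc_df.shape) < missing_frac
        lfc_df = lfc_df.mask(mask)
    return expr, lfc_df


def generate_geneset_catalog(
    gene_universe,
    n_sets: int,
    planted_set,
    seed: int = 0,
    set_size: int = 200,
    planted_overlap: int | None = None,
) -> GeneSetCatalog:
    """Random gene-set catalog plus one set enriched for a planted gene list.

    The planted set contains ``planted_overlap`` genes of ``planted_set``
    (all of them by default) topped up with random universe genes to
    ``set_size``.
    """
    universe = list(gene_universe)
    planted = [g for g in planted_set if g in set(universe)]
    if len(planted) != len(list(planted_set)):
        raise ValueError("planted_set must be a subset of the gene universe")
    rng = np.random.default_rng(seed)
    catalog = GeneSetCatalog()
    for i in range(n_sets):
        size = min(set_size, len(universe))
        catalog[f"RANDOM_SET_{i + 1:02d}"] = sorted(rng.choice(universe, size=size, replace=False))
    take = len(planted) if planted_overlap is None else planted_overlap
    chosen = sorted(rng.choice(planted, size=take, replace=False))
    # filler excludes every planted gene so the overlap is exactly `take`
    filler_pool = sorted(set(universe) - set(planted))
    filler = sorted(rng.choice(filler_pool, size=max(0, set_size - take), replace=False))
    catalog["PLANTED_SET"] = chosen + filler
    return catalog


__all__ = [
    "SpatialSimConfig",
    "CorrPair",
    "BimodalParams",
    "CohortSimConfig",
    "generate_spatial",
    "generate_single_cell",
    "generate_bulk_survival",
    "generate_drug_panel",
    "generate_geneset_catalog",
    "BUDDING_SEGMENT_TYPES",
    "NONBUDDING_SEGMENT_TYPES",
]
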