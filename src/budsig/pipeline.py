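"""End-to-end pipeline: simulate -> qc -> dgea -> signature -> score -> enrich -> diffcorr -> evaluate.

The pipeline is configured by a schema-validated YAML/dict config in which
every analysis threshold defaults to its standard value (40,000 reads;
80% stitched; 70% aligned; 50% saturation; 1,000 NTC counts; 5%/10% LOQ
detection; fold change 1.5 at FDR 5%; |rho| > 0.8 at FDR 1%; 100,000
permutations; |dZ| >= 1.4).  Each stage writes plain-text outputs into the
output directory and registers them in a manifest holding parameters and
sha256 checksums — no timestamps — so re-running an identical config
produces a byte-identical manifest.  Stages can be resumed from disk with
``from_stage``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import dgea, diffcorr, evaluate, qc, scoring, simulate
from .containers import ExpressionMatrix, SegmentCountMatrix, SignatureDef
from .enrichment import enrich, write_gmt

STAGES = ("simulate", "qc", "dgea", "signature", "score", "enrich", "diffcorr", "evaluate")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpatialParams(_Strict):
    n_budding_cases: int = 24
    n_nonbudding_cases: int = 19
    n_genes: int = 300
    n_negative_probes: int = 30
    segments_per_type: int = 2
    n_planted_genes: int = 28
    planted_fold: float = 2.5
    qc_fail_frac: float = 0.05


class QCParams(_Strict):
    min_reads: int = 40_000
    min_stitched: float = 0.80
    min_aligned: float = 0.70
    min_saturation: float = 0.50
    max_ntc: int = 1_000
    min_gene_detect_frac_per_segment: float = 0.05
    min_segment_detect_frac_per_gene: float = 0.10


class DGEAParams(_Strict):
    fc_threshold: float = 1.5
    fdr: float = 0.05


class DiffcorrParams(_Strict):
    rho_min: float = 0.8
    fdr: float = 0.01
    n_perm: int = 100_000
    min_abs_dz: float = 1.4
    max_genes: int = 100  # top variable genes entering the pair scan


class EnrichParams(_Strict):
    n_sets: int = 20
    set_size: int = 50


class EvaluateParams(_Strict):
    n_samples: int = 300
    true_hr: float = 1.5
    censoring_rate: float = 0.3
    n_lines: int = 60
    n_compounds: int = 20
    drug_slope: float = -0.8


class PipelineConfig(_Strict):
    outdir: str
    seed: int = 0
    spatial: SpatialParams = SpatialParams()
    qc: QCParams = QCParams()
    dgea: DGEAParams = DGEAParams()
    diffcorr: DiffcorrParams = DiffcorrParams()
    enrich: EnrichParams = EnrichParams()
    evaluate: EvaluateParams = EvaluateParams()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in sorted(outputs)},
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"stages": self.stages}, indent=2, sort_keys=True) + "\n")
        return path


def _group_path(outdir: Path, key: tuple[str, str]) -> Path:
    return outdir / f"case_matrix_{key[0]}_{key[1]}.tsv"


def run_pipeline(config: PipelineConfig, from_stage: str | None = None) -> Path:
    """Execute the pipeline; returns the path of the written manifest.

    ``from_stage`` resumes at the named stage, reading every earlier stage's
    outputs back from the output directory (they must exist).
    """
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; expected one of {STAGES}")
    start = STAGES.index(from_stage) if from_stage else 0
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    if start > 0:
        prior_path = outdir / "manifest.json"
        if not prior_path.exists():
            raise FileNotFoundError(f"cannot resume from {from_stage!r}: no manifest in {outdir}")
        manifest.stages = json.loads(prior_path.read_text())["stages"]

    sp = config.spatial
    width = len(str(sp.n_genes))
    planted = [f"G{i + 1:0{width}d}" for i in range(sp.n_planted_genes)]

    # ---- simulate -------------------------------------------------------
    if start <= STAGES.index("simulate"):
        sim_cfg = simulate.SpatialSimConfig(
            n_budding_cases=sp.n_budding_cases,
            n_nonbudding_cases=sp.n_nonbudding_cases,
            n_genes=sp.n_genes,
            n_negative_probes=sp.n_negative_probes,
            segments_per_type=sp.segments_per_type,
            planted_signature={g: sp.planted_fold for g in planted},
            qc_fail_frac=sp.qc_fail_frac,
            seed=config.seed,
        )
        matrix = simulate.generate_spatial(sim_cfg)
        matrix.write(outdir)
        manifest.record(
            "simulate",
            sim_cfg.__dict__ | {"planted_signature": {g: sp.planted_fold for g in planted}},
            [outdir / f"segments_{s}.tsv" for s in ("counts", "probes", "meta")],
        )
    else:
        matrix = SegmentCountMatrix.read(
            outdir / "segments_counts.tsv", outdir / "segments_probes.tsv", outdir / "segments_meta.tsv"
        )

    # ---- qc -------------------------------------------------------------
    thresholds = qc.QCThresholds(**config.qc.model_dump())
    if start <= STAGES.index("qc"):
        kept, report = qc.filter_segments(matrix, thresholds)
        loq_table = qc.compute_loq_table(kept)
        filtered = qc.filter_by_loq(kept, loq_table, thresholds)
        norm = qc.q3_normalize(filtered)
        case_mats = qc.aggregate_case_level(norm, filtered.meta)
        outputs = []
        report.to_csv(outdir / "qc_report.tsv", sep="\t")
        loq_table.to_csv(outdir / "loq_table.tsv", sep="\t")
        norm.values.to_csv(outdir / "q3_matrix.tsv", sep="\t", float_format="%.17g")
        filtered.meta.to_csv(outdir / "q3_meta.tsv", sep="\t")
        outputs += [outdir / "qc_report.tsv", outdir / "loq_table.tsv", outdir / "q3_matrix.tsv", outdir / "q3_meta.tsv"]
        for key, mat in case_mats.items():
            p = _group_path(outdir, key)
            mat.to_csv(p, sep="\t", float_format="%.17g")
            outputs.append(p)
        summary = {
            "n_segments_in": int(matrix.counts.shape[0]),
            "n_segments_post_seq_qc": int(kept.counts.shape[0]),
            "n_segments_post_loq": int(filtered.counts.shape[0]),
            "n_genes_post_loq": int(len(filtered.gene_probes)),
        }
        (outdir / "qc_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        outputs.append(outdir / "qc_summary.json")
        manifest.record("qc", config.qc.model_dump(), outputs)
    else:
        norm = ExpressionMatrix.read(outdir / "q3_matrix.tsv", norm="q3")
        meta = pd.read_csv(outdir / "q3_meta.tsv", sep="\t", index_col=0)
        case_mats = qc.aggregate_case_level(norm, meta)

    # ---- dgea -----------------------------------------------------------
    contrasts = [
        dgea.ContrastSpec(c.name, c.group_a, c.group_b, c.paired, config.dgea.fc_threshold, config.dgea.fdr)
        for c in dgea.default_signature_contrasts()
    ]
    if start <= STAGES.index("dgea"):
        tables = {}
        outputs = []
        for contrast in contrasts:
            table = dgea.run_contrast(case_mats, contrast)
            tables[contrast.name] = table
            p = outdir / f"dgea_{contrast.name}.tsv"
            table.to_csv(p, sep="\t")
            outputs.append(p)
        manifest.record("dgea", config.dgea.model_dump(), outputs)
    else:
        tables = {
            c.name: pd.read_csv(outdir / f"dgea_{c.name}.tsv", sep="\t", index_col=0) for c in contrasts
        }

    # ---- signature ------------------------------------------------------
    if start <= STAGES.index("signature"):
        sig_up, sig_down = dgea.derive_signature(tables)
        if sig_up is None:
            raise RuntimeError("signature stage: no gene up in every contrast")
        sig_up.write(outdir / "signature_up.txt")
        prov = {
            "name": sig_up.name,
            "n_up": len(sig_up.genes),
            "n_down": 0 if sig_down is None else len(sig_down.genes),
            "contrasts": sig_up.provenance,
        }
        (outdir / "signature_provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
        outputs = [outdir / "signature_up.txt", outdir / "signature_provenance.json"]
        if sig_down is not None:
            sig_down.write(outdir / "signature_down.txt")
            outputs.append(outdir / "signature_down.txt")
        manifest.record("signature", {}, outputs)
    else:
        sig_up = SignatureDef.read(outdir / "signature_up.txt", name="TBS")

    # ---- score ----------------------------------------------------------
    if start <= STAGES.index("score"):
        norm_mat = norm if start <= STAGES.index("qc") else ExpressionMatrix.read(outdir / "q3_matrix.tsv", norm="q3")
        seg_scores = scoring.score_signature(norm_mat, sig_up)
        seg_scores.rename("tbs").to_frame().to_csv(outdir / "scores_segments.tsv", sep="\t", float_format="%.17g")
        manifest.record("score", {"signature": sig_up.genes}, [outdir / "scores_segments.tsv"])
    else:
        seg_scores = pd.read_csv(outdir / "scores_segments.tsv", sep="\t", index_col=0)["tbs"]

    # ---- enrich ---------------------------------------------------------
    if start <= STAGES.index("enrich"):
        universe = list(norm.genes) if hasattr(norm, "genes") else list(norm.values.columns)
        catalog = simulate.generate_geneset_catalog(
            universe, config.enrich.n_sets, sig_up.genes, seed=config.seed + 1, set_size=config.enrich.set_size
        )
        write_gmt(catalog, outdir / "catalog.gmt")
        table = enrich(sig_up.genes, catalog)
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        manifest.record("enrich", config.enrich.model_dump(), [outdir / "catalog.gmt", outdir / "enrichment.tsv"])

    # ---- diffcorr -------------------------------------------------------
    if start <= STAGES.index("diffcorr"):
        dc = config.diffcorr
        bud = case_mats[("bud", "tumor")]
        bulk = case_mats[("bulk_budding", "tumor")]
        shared = bud.index.intersection(bulk.index)
        bud, bulk = bud.loc[shared], bulk.loc[shared]
        # restrict the O(G^2) pair scan to the most variable genes
        var = (bud.var() + bulk.var()).sort_values(ascending=False)
        genes = sorted(var.index[: dc.max_genes])
        bud, bulk = bud[genes], bulk[genes]
        pairing = diffcorr.CompartmentPairing("tumor-tumor", a_x=bud, a_y=bud, b_x=bulk, b_y=bulk)
        cands = diffcorr.candidate_pairs(pairing, rho_min=dc.rho_min, fdr=dc.fdr)
        outputs = []
        if cands.empty:
            (outdir / "diffcorr_edges.tsv").write_text(
                "gene_x\tgene_y\trho_a\trho_b\tz_a\tz_b\tdz\tp_emp\tq\tchange\tsign_flip\n"
            )
            outputs.append(outdir / "diffcorr_edges.tsv")
        else:
            edges = diffcorr.permutation_test(pairing, cands, n_perm=dc.n_perm, seed=config.seed + 2)
            selected = diffcorr.select_differential(edges, fdr=dc.fdr, min_abs_dz=dc.min_abs_dz)
            selected.to_csv(outdir / "diffcorr_edges.tsv", sep="\t", index=False)
            outputs.append(outdir / "diffcorr_edges.tsv")
            if not selected.empty:
                import networkx as nx

                graph, _ = diffcorr.build_network(selected, "tumor", "tumor")
                # GraphML needs scalar node ids and attributes
                flat = nx.relabel_nodes(graph, {n: f"{n[0]}|{n[1]}" for n in graph.nodes})
                flat.graph.clear()
                nx.write_graphml(flat, outdir / "diffcorr_network.graphml", named_key_ids=True)
                nodes = pd.DataFrame(
                    [{"node": f"{g}|{c}", **attrs} for (g, c), attrs in graph.nodes(data=True)]
                )
                nodes.to_csv(outdir / "diffcorr_nodes.tsv", sep="\t", index=False)
                outputs += [outdir / "diffcorr_network.graphml", outdir / "diffcorr_nodes.tsv"]
        manifest.record("diffcorr", dc.model_dump(), outputs)

    # ---- evaluate -------------------------------------------------------
    if start <= STAGES.index("evaluate"):
        ev = config.evaluate
        outputs = []
        # ROC: TBS separating bud segments from everything else
        meta = pd.read_csv(outdir / "q3_meta.tsv", sep="\t", index_col=0).loc[seg_scores.index]
        labels = pd.Series(
            ((meta["segment_type"] == "bud") & (meta["compartment"] == "tumor")).astype(int),
            index=seg_scores.index,
        )
        roc = evaluate.roc_auc(seg_scores, labels)
        (outdir / "roc.json").write_text(
            json.dumps(
                {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high, "p": roc.p,
                 "n_pos": roc.n_pos, "n_neg": roc.n_neg},
                indent=2, sort_keys=True,
            ) + "\n"
        )
        outputs.append(outdir / "roc.json")

        # survival on a synthetic bulk cohort expressing the derived signature
        cohort_cfg = simulate.CohortSimConfig(
            n_samples=ev.n_samples, true_hr=ev.true_hr, censoring_rate=ev.censoring_rate, seed=config.seed + 3
        )
        expr, cohort, tb = simulate.generate_bulk_survival(cohort_cfg, sig_up)
        bulk_scores = scoring.score_signature(expr, sig_up)
        median_split = scoring.classify(bulk_scores, float(bulk_scores.median()))
        km_table, logrank_p = evaluate.km_logrank(cohort, median_split)
        km_table.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        high = (median_split == "high").astype(int).rename("tbs_high").to_frame()
        cox = evaluate.cox_model(cohort, ["tbs_high"], data=high)
        cox.to_csv(outdir / "cox.tsv", sep="\t")
        cutoff, profile = evaluate.survival_cutoff_optimize(bulk_scores, cohort)
        profile.to_csv(outdir / "cutoff_profile.tsv", sep="\t", index=False)
        budding = scoring.classify_budding_bulk(tb)
        budding.to_csv(outdir / "budding_classes.tsv", sep="\t")
        (outdir / "survival_summary.json").write_text(
            json.dumps(
                {"logrank_p_median_split": logrank_p, "optimized_cutoff": cutoff,
                 "cox_hr_tbs_high": float(cox.loc["tbs_high", "hr"])},
                indent=2, sort_keys=True,
            ) + "\n"
        )
        outputs += [outdir / p for p in ("km_curves.tsv", "cox.tsv", "cutoff_profile.tsv",
                                         "budding_classes.tsv", "survival_summary.json")]

        # drug screen on a synthetic compound panel
        effect_map = {"CPD001": ev.drug_slope}
        panel_expr, lfc = simulate.generate_drug_panel(
            ev.n_lines, ev.n_compounds, effect_map, seed=config.seed + 4, signature=sig_up
        )
        line_scores = scoring.score_signature(panel_expr, sig_up)
        screen = evaluate.drug_screen(line_scores, lfc)
        screen.to_csv(outdir / "drug_screen.tsv", sep="\t")
        outputs.append(outdir / "drug_screen.tsv")
        manifest.record("evaluate", ev.model_dump(), outputs)

    return manifest.write()


__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]
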