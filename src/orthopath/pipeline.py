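"""Orchestration of the full analysis workflow.

Per study: log2 check, per-feature effect sizes and DE p-values.  Per
feature: REML overall effect and combined p-value, BH-FDR within each data
type (mRNA and miRNA panels are disjoint), then DE selection — FDR below the
cutoff, then the largest |SMD| up to a fixed fraction of the measured
features.  Every pathway is augmented with miRNA->target edges and scored by
impact analysis (P_NDE over the union universe of measured mRNAs and
miRNAs, P_PERT from a per-pathway seeded permutation stream), and the
pathways are ranked by their combined, FDR-adjusted p-values.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from orthopath import io_formats
from orthopath.gene_stats import de_test_per_study, study_effects_table
from orthopath.impact_analysis import ImpactInput, PathwayScore, analyze_pathway
from orthopath.io_formats import (
    ExpressionStudy,
    TargetMap,
    normalize_mirna_id,
    read_expression_study,
    read_pathways,
    read_target_map,
    write_results,
)
from orthopath.meta_combine import MetaFeature, MetaInput, bh_fdr, combine_feature
from orthopath.pathway_graph import PathwayGraph, augment_pathway

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and parameters of one analysis run.

    mrna_studies / mirna_studies are lists of (matrix_path, groups_path,
    study_id) triples.  de_fdr and de_top_frac encode the DE-selection rule:
    FDR-significant features, then the largest |overall SMD| up to
    de_top_frac of the measured features of that data type.
    """

    mrna_studies: list[tuple[str, str, str]]
    mirna_studies: list[tuple[str, str, str]] = field(default_factory=list)
    targets_path: str | None = None
    pathways_path: str | None = None
    pathway_nodes_path: str | None = None
    out_path: str | None = None
    de_fdr: float = 0.05
    de_top_frac: float = 0.10
    combiner: str = "add_clt"
    test_method: str = "moderated_t"
    n_perm: int = 2000
    seed: int = 0
    weight_table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.de_fdr < 1):
            raise ValueError("de_fdr must be in (0,1)")
        if not (0 < self.de_top_frac <= 1):
            raise ValueError("de_top_frac must be in (0,1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not self.mrna_studies:
            raise ValueError("at least one mRNA study is required")


def select_de(
    features: list[MetaFeature],
    de_fdr: float,
    de_top_frac: float,
    n_measured: int,
) -> set[str]:
    """Pick DE features: FDR-significant, then largest |overall SMD|.

    At most floor(de_top_frac * n_measured) features are returned ("up to"
    semantics — fewer when fewer are significant).  Ties on |mu_hat| break
    by smaller combined p, then lexicographic id.
    """
    if n_measured < len(features):
        raise ValueError("n_measured cannot be below the number of features")
    cap = int(math.floor(de_top_frac * n_measured))
    candidates = [f for f in features if f.fdr < de_fdr]
    candidates.sort(key=lambda f: (-abs(f.mu_hat), f.p_combined, f.feature_id))
    return {f.feature_id for f in candidates[:cap]}


def meta_analyze_studies(
    studies: list[ExpressionStudy],
    combiner: str = "add_clt",
    test_method: str = "moderated_t",
) -> list[MetaFeature]:
    """Per-feature meta-analysis across one panel of same-type studies.

    Feature ids of miRNA studies are lowercased before matching across
    studies.  A feature is combined over the studies in which it is
    measurable; FDR is filled over the panel's features.
    """
    norm = (
        normalize_mirna_id
        if studies and studies[0].data_type == "mirna"
        else (lambda x: x)
    )
    per_feature: dict[str, dict[str, list[float]]] = {}
    for study in studies:
        eff = study_effects_table(study)
        pvals = de_test_per_study(study, method=test_method)
        for feat in eff.index:
            if feat not in pvals:
                continue
            key = norm(feat)
            rec = per_feature.setdefault(key, {"y": [], "v": [], "p": []})
            rec["y"].append(float(eff.at[feat, "g"]))
            rec["v"].append(float(eff.at[feat, "se_g"]) ** 2)
            rec["p"].append(max(pvals[feat], 1e-300))
    metas = [
        combine_feature(
            MetaInput(feature_id=fid, y=rec["y"], v=rec["v"], p=rec["p"]),
            method=combiner,
        )
        for fid, rec in sorted(per_feature.items())
    ]
    if metas:
        fdrs = bh_fdr([f.p_combined for f in metas])
        for f, q in zip(metas, fdrs):
            f.fdr = float(q)
    return metas


def _pathway_seed(master_seed: int, pathway_id: str) -> int:
    """Per-pathway permutation seed: stable under pathway additions."""
    return (master_seed * 1_000_003 + zlib.crc32(pathway_id.encode())) % (2**31)


def analyze_collection(
    mrna_studies: list[ExpressionStudy],
    mirna_studies: list[ExpressionStudy],
    targets: TargetMap,
    pathways: list[PathwayGraph],
    de_fdr: float = 0.05,
    de_top_frac: float = 0.10,
    combiner: str = "add_clt",
    test_method: str = "moderated_t",
    n_perm: int = 2000,
    seed: int = 0,
    weight_table: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Library entry point: full analysis on in-memory studies.

    Returns the ranked result table and a detail dict (meta features per
    data type, DE sets, per-pathway scores, skipped pathways).
    """
    mrna_studies = [io_formats.ensure_log2(s) for s in mrna_studies]
    mirna_studies = [io_formats.ensure_log2(s) for s in mirna_studies]

    meta_mrna = meta_analyze_studies(mrna_studies, combiner, test_method)
    meta_mirna = meta_analyze_studies(mirna_studies, combiner, test_method)

    de_mrna = select_de(meta_mrna, de_fdr, de_top_frac, len(meta_mrna))
    de_mirna = select_de(meta_mirna, de_fdr, de_top_frac, len(meta_mirna))
    for f in meta_mrna:
        f.is_de = f.feature_id in de_mrna
    for f in meta_mirna:
        f.is_de = f.feature_id in de_mirna

    all_meta = {f.feature_id: f for f in meta_mrna + meta_mirna}
    de_nodes = de_mrna | de_mirna
    delta_e = {
        fid: (f.mu_hat if fid in de_nodes else 0.0) for fid, f in all_meta.items()
    }
    universe_size = len(all_meta)
    universe_de = len(de_nodes)

    augmented = [augment_pathway(p, targets) for p in pathways]
    if not any(n in delta_e for p in augmented for n in p.nodes):
        raise ValueError(
            "no overlap between measured features and any pathway node"
        )

    scores: list[PathwayScore] = []
    for p in augmented:
        score = analyze_pathway(
            ImpactInput(
                graph=p,
                delta_e=delta_e,
                de_nodes=de_nodes,
                universe_size=universe_size,
                universe_de=universe_de,
            ),
            n_perm=n_perm,
            seed=_pathway_seed(seed, p.pathway_id),
            weight_table=weight_table,
        )
        scores.append(score)

    kept = [s for s in scores if not s.singular]
    skipped = [s for s in scores if s.singular]
    for s in skipped:
        logger.warning("pathway %s skipped (singular propagation system)", s.pathway_id)
    table = rank_results(kept, {p.pathway_id: p.name for p in augmented})
    details = {
        "meta_mrna": meta_mrna,
        "meta_mirna": meta_mirna,
        "de_mrna": de_mrna,
        "de_mirna": de_mirna,
        "scores": scores,
        "skipped": [s.pathway_id for s in skipped],
    }
    return table, details


def rank_results(
    scores: list[PathwayScore], names: dict[str, str] | None = None
) -> pd.DataFrame:
    """BH-FDR across pathways and deterministic ranking.

    Sort ascending by combined p; ties break by larger |total accumulation|
    then pathway id; ranks are 1..K.
    """
    if not scores:
        return pd.DataFrame(columns=io_formats.RESULT_COLUMNS)
    names = names or {}
    fdrs = bh_fdr([s.p_combined for s in scores])
    rows = [
        {
            "pathway_id": s.pathway_id,
            "pathway_name": names.get(s.pathway_id, s.pathway_id),
            "p_nde": s.p_nde,
            "p_pert": s.p_pert,
            "p_combined": s.p_combined,
            "fdr": float(q),
            "acc_total": s.acc_total,
        }
        for s, q in zip(scores, fdrs)
    ]
    rows.sort(
        key=lambda r: (
            r["p_combined"],
            -abs(r["acc_total"]) if np.isfinite(r["acc_total"]) else 0.0,
            r["pathway_id"],
        )
    )
    table = pd.DataFrame(rows)
    table["rank"] = np.arange(1, len(rows) + 1)
    return table[io_formats.RESULT_COLUMNS + ["acc_total"]]


def run_orthogonal_analysis(config: RunConfig) -> pd.DataFrame:
    """File-based runner: read inputs, analyze, optionally write results."""
    mrna = [
        read_expression_study(m, g, sid, "mrna") for m, g, sid in config.mrna_studies
    ]
    mirna = [
        read_expression_study(m, g, sid, "mirna") for m, g, sid in config.mirna_studies
    ]
    targets = (
        read_target_map(config.targets_path) if config.targets_path else TargetMap()
    )
    if config.pathways_path is None:
        raise ValueError("a pathway edge file is required")
    pathways = read_pathways(config.pathways_path, config.pathway_nodes_path)
    table, _ = analyze_collection(
        mrna,
        mirna,
        targets,
        pathways,
        de_fdr=config.de_fdr,
        de_top_frac=config.de_top_frac,
        combiner=config.combiner,
        test_method=config.test_method,
        n_perm=config.n_perm,
        seed=config.seed,
        weight_table=config.weight_table,
    )
    if config.out_path:
        write_results(table, config.out_path)
    return table


def discover_studies(
    spec: str, groups_suffix: str = ".groups.tsv"
) -> list[tuple[str, str, str]]:
    """Resolve a directory or comma-separated list into study triples.

    A directory contributes every ``*.tsv`` that is not a group file; each
    matrix ``X.tsv`` pairs with ``X<groups_suffix>`` and gets study id
    ``X``.
    """
    path = Path(spec)
    if path.is_dir():
        matrices = sorted(
            p
            for p in path.glob("*.tsv")
            if not p.name.endswith(groups_suffix)
            and not p.name.endswith(".groups.tsv")
        )
    else:
        matrices = [Path(s) for s in spec.split(",") if s]
    out = []
    for m in matrices:
        stem = m.name[: -len(".tsv")] if m.name.endswith(".tsv") else m.name
        groups = m.with_name(stem + groups_suffix)
        if not groups.exists():
            raise FileNotFoundError(f"no group file {groups} for matrix {m}")
        out.append((str(m), str(groups), stem))
    if not out:
        raise FileNotFoundError(f"no study matrices found in {spec}")
    return out
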