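"""Synthetic multi-study expression collections with known ground truth.

The generator emulates the statistical structure the framework assumes:
several independent two-group studies per data type, log2-scale Gaussian
intensities, and a designated ("planted") pathway whose genes carry a real
effect.  Each planted feature's study-level true effect is drawn around a
central standardized mean difference mu_effect with between-study variance
tau2 — the random-effects model the meta-analysis step estimates — and is
injected on the noise-SD scale so the population SMD in study s equals the
drawn effect by construction.  Planted miRNAs target planted genes
(repression) and carry effects of the opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from orthopath.io_formats import ExpressionStudy, TargetMap, write_expression_study
from orthopath.pathway_graph import PathwayGraph

WIRINGS = ("chain", "random_dag")


@dataclass
class SimConfig:
    """Parameters of a simulated collection.

    Defaults describe a desk-scale benchmark: 5 mRNA and 3 miRNA studies of
    10 samples per group, 10 disjoint 10-gene pathways, a planted central
    effect of 1.0 with between-study variance 0.05, and unit noise SD.
    """

    n_mrna_studies: int = 5
    n_mirna_studies: int = 3
    samples_per_group: int | list[int] = 10
    n_genes: int = 200
    n_mirnas: int = 40
    n_pathways: int = 10
    genes_per_pathway: int = 10
    wiring: str = "random_dag"
    planted_pathway: str = "path01"
    mu_effect: float = 1.0
    tau2: float = 0.05
    frac_de_on_planted: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wiring not in WIRINGS:
            raise ValueError(f"wiring must be one of {WIRINGS}")
        if not (0 < self.frac_de_on_planted <= 1):
            raise ValueError("frac_de_on_planted must be in (0,1]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathway genes exceed n_genes")


def make_toy_knowledge(
    n_pathways: int,
    genes_per: int,
    wiring: str = "random_dag",
    seed: int = 0,
    n_mirnas_per_pathway: int = 2,
) -> tuple[list[PathwayGraph], TargetMap]:
    """Disjoint toy pathways plus a covering miRNA target map.

    ``chain`` wiring connects each pathway's genes in a line with
    activation edges; ``random_dag`` keeps the chain backbone (so no node
    is isolated) and adds forward skip edges — only from lower to higher
    index, guaranteeing acyclicity — with mixed activation/repression
    types.  Each pathway receives miRNAs targeting at least two of its
    genes (repression).
    """
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    rng = np.random.default_rng(seed)
    graphs: list[PathwayGraph] = []
    targets = TargetMap()
    for p in range(n_pathways):
        pid = f"path{p + 1:02d}"
        genes = [f"GENE_{pid}_{i + 1:03d}" for i in range(genes_per)]
        g = PathwayGraph(pathway_id=pid, name=f"Toy pathway {p + 1}")
        for gene in genes:
            g.add_node(gene, "gene")
        for i in range(genes_per - 1):
            g.add_edge(genes[i], genes[i + 1], "activation")
        if wiring == "random_dag":
            for i in range(genes_per):
                for j in range(i + 2, genes_per):
                    if rng.random() < 0.15:
                        rel = "activation" if rng.random() < 0.7 else "repression"
                        g.add_edge(genes[i], genes[j], rel)
        graphs.append(g)
        n_targets = max(2, min(3, genes_per))
        for k in range(n_mirnas_per_pathway):
            mirna = f"hsa-mir-{pid}{chr(ord('a') + k)}"
            chosen = rng.choice(genes_per, size=n_targets, replace=False)
            for ci in sorted(chosen):
                targets.add(mirna, genes[ci], "repression")
    return graphs, targets


def _simulate_study(
    rng: np.random.Generator,
    study_id: str,
    features: list[str],
    baselines: np.ndarray,
    central_effects: np.ndarray,
    tau2: float,
    noise_sd: float,
    n_per_group: int,
    data_type: str,
) -> ExpressionStudy:
    """One two-group study under the random-effects model.

    Study-level true effects delta ~ N(central, tau2) per feature (zero
    stays exactly zero); disease samples are shifted by delta*noise_sd so
    the population SMD equals delta.
    """
    n_feat = len(features)
    delta = np.where(
        central_effects != 0.0,
        rng.normal(central_effects, np.sqrt(tau2), size=n_feat),
        0.0,
    )
    control = rng.normal(
        baselines[:, None], noise_sd, size=(n_feat, n_per_group)
    )
    disease = rng.normal(
        (baselines + delta * noise_sd)[:, None], noise_sd, size=(n_feat, n_per_group)
    )
    samples = [f"{study_id}_D{i + 1}" for i in range(n_per_group)] + [
        f"{study_id}_C{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: ("disease" if s.split("_")[-1].startswith("D") else "control") for s in samples}
    return ExpressionStudy(
        study_id=study_id,
        features=list(features),
        samples=samples,
        values=np.hstack([disease, control]),
        groups=groups,
        data_type=data_type,
    )


def simulate_collection(
    config: SimConfig,
) -> tuple[
    list[ExpressionStudy],
    list[ExpressionStudy],
    TargetMap,
    list[PathwayGraph],
    dict,
]:
    """Generate a full multi-study collection with ground truth.

    Returns (mRNA studies, miRNA studies, target map, pathways, truth).
    The truth record lists the planted pathway, the DE feature ids, and
    each feature's central effect.  Fully reproducible from ``config.seed``.
    """
    children = np.random.SeedSequence(config.seed).spawn(
        2 + config.n_mrna_studies + config.n_mirna_studies
    )
    k_key, b_key, study_keys = children[0], children[1], children[2:]
    graphs, targets = make_toy_knowledge(
        config.n_pathways,
        config.genes_per_pathway,
        config.wiring,
        seed=k_key,
    )
    planted = next(
        (g for g in graphs if g.pathway_id == config.planted_pathway), None
    )
    if planted is None:
        raise ValueError(f"planted pathway '{config.planted_pathway}' not generated")

    pathway_genes = sorted({n for g in graphs for n in g.gene_nodes()})
    n_extra = config.n_genes - len(pathway_genes)
    genes = pathway_genes + [f"GENE_BG_{i + 1:04d}" for i in range(n_extra)]
    mirnas = sorted(targets.mirnas())
    n_extra_mir = config.n_mirnas - len(mirnas)
    if n_extra_mir < 0:
        raise ValueError("n_mirnas smaller than the number of pathway miRNAs")
    mirnas = mirnas + [f"hsa-mir-bg-{i + 1:03d}" for i in range(n_extra_mir)]

    planted_genes = sorted(planted.gene_nodes())
    n_de_genes = max(1, int(round(config.frac_de_on_planted * len(planted_genes))))
    de_genes = planted_genes[:n_de_genes]
    de_mirnas = sorted(
        m for m in targets.mirnas() if targets.targets_of(m) & set(planted_genes)
    )

    gene_effects = np.array(
        [config.mu_effect if g in de_genes else 0.0 for g in genes]
    )
    mirna_effects = np.array(
        [-config.mu_effect if m in de_mirnas else 0.0 for m in mirnas]
    )

    brng = np.random.default_rng(b_key)
    gene_base = brng.normal(8.0, 2.0, size=len(genes))
    mirna_base = brng.normal(8.0, 2.0, size=len(mirnas))

    if isinstance(config.samples_per_group, int):
        n_per = [config.samples_per_group] * (
            config.n_mrna_studies + config.n_mirna_studies
        )
    else:
        n_per = list(config.samples_per_group)

    mrna_studies = [
        _simulate_study(
            np.random.default_rng(study_keys[s]),
            f"sim_mrna_{s + 1}",
            genes,
            gene_base,
            gene_effects,
            config.tau2,
            config.noise_sd,
            n_per[s],
            "mrna",
        )
        for s in range(config.n_mrna_studies)
    ]
    mirna_studies = [
        _simulate_study(
            np.random.default_rng(study_keys[config.n_mrna_studies + s]),
            f"sim_mirna_{s + 1}",
            mirnas,
            mirna_base,
            mirna_effects,
            config.tau2,
            config.noise_sd,
            n_per[config.n_mrna_studies + s],
            "mirna",
        )
        for s in range(config.n_mirna_studies)
    ]
    truth = {
        "planted_pathway": config.planted_pathway,
        "de_features": sorted(de_genes) + sorted(de_mirnas),
        "central_effects": {
            **{g: config.mu_effect for g in de_genes},
            **{m: -config.mu_effect for m in de_mirnas},
        },
    }
    return mrna_studies, mirna_studies, targets, graphs, truth


def write_collection(
    out_dir: str | Path,
    mrna_studies: list[ExpressionStudy],
    mirna_studies: list[ExpressionStudy],
    targets: TargetMap,
    graphs: list[PathwayGraph],
    truth: dict,
) -> dict[str, Path]:
    """Write a simulated collection in the tool's TSV dialects.

    Layout: ``mrna/<id>.tsv`` + ``mrna/<id>.groups.tsv`` (same for mirna),
    ``targets.tsv``, ``pathways.tsv``, ``pathway_nodes.tsv``, ``truth.tsv``.
    """
    out = Path(out_dir)
    (out / "mrna").mkdir(parents=True, exist_ok=True)
    (out / "mirna").mkdir(parents=True, exist_ok=True)
    for study in mrna_studies:
        write_expression_study(
            study,
            out / "mrna" / f"{study.study_id}.tsv",
            out / "mrna" / f"{study.study_id}.groups.tsv",
        )
    for study in mirna_studies:
        write_expression_study(
            study,
            out / "mirna" / f"{study.study_id}.tsv",
            out / "mirna" / f"{study.study_id}.groups.tsv",
        )
    pd.DataFrame(
        [
            {"mirna_id": m, "gene_id": g, "interaction": rel}
            for (m, g), rel in sorted(targets.records.items())
        ]
    ).to_csv(out / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"pathway_id": g.pathway_id, "src": s, "dst": d, "type": r}
            for g in graphs
            for s, d, r in sorted(g.edges)
        ]
    ).to_csv(out / "pathways.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"pathway_id": g.pathway_id, "node_id": n, "node_type": t}
            for g in graphs
            for n, t in sorted(g.nodes.items())
        ]
    ).to_csv(out / "pathway_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "feature_id": f,
                "central_effect": truth["central_effects"][f],
                "planted_pathway": truth["planted_pathway"],
            }
            for f in truth["de_features"]
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    return {
        "mrna": out / "mrna",
        "mirna": out / "mirna",
        "targets": out / "targets.tsv",
        "pathways": out / "pathways.tsv",
        "pathway_nodes": out / "pathway_nodes.tsv",
        "truth": out / "truth.tsv",
    }
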