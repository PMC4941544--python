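"""Readers and writers for the tab-separated formats the tool consumes.

All files are tab-delimited UTF-8 with a "." decimal separator and no
quoting.  Expression matrices are features x samples with a ``feature_id``
first column; group files map sample ids to ``control``/``disease``; the
miRNA target table has columns ``mirna_id``, ``gene_id`` and an optional
``interaction``; pathways are typed directed edge lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from orthopath.pathway_graph import PathwayGraph

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"control", "disease"})
VALID_DATA_TYPES = frozenset({"mrna", "mirna"})

#: relations understood out of the box; others must be mapped explicitly
EDGE_TYPE_VOCABULARY = frozenset(
    {"activation", "expression", "repression", "inhibition", "binding"}
)


def normalize_mirna_id(mirna_id: str) -> str:
    """Lowercase a miRNA identifier.

    miRNA nomenclature is case-inconsistent across sources (``hsa-miR-21``
    vs ``HSA-MIR-21``); gene symbols, by contrast, are compared
    case-sensitively and pass through unchanged elsewhere.
    """
    return mirna_id.strip().lower()


@dataclass
class ExpressionStudy:
    """One study's log2 feature-by-sample matrix with two-group labels.

    Attributes
    ----------
    study_id : str
        Identifier of the study (e.g. a GEO accession).
    features : list of str
        Ordered feature identifiers (genes or miRNAs), no duplicates.
    samples : list of str
        Ordered sample identifiers.
    values : ndarray of shape (n_features, n_samples)
        log2 intensities; NaN marks missing cells.
    groups : dict
        Sample id -> ``"control"`` or ``"disease"``.
    data_type : str
        ``"mrna"`` or ``"mirna"``.
    log2_rescaled : bool
        Whether :func:`ensure_log2` applied the log transform.
    """

    study_id: str
    features: list[str]
    samples: list[str]
    values: np.ndarray
    groups: dict[str, str]
    data_type: str
    log2_rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"study {self.study_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.features)} features x {len(self.samples)} samples"
            )
        if self.data_type not in VALID_DATA_TYPES:
            raise ValueError(f"data_type must be one of {sorted(VALID_DATA_TYPES)}")
        dupes = _duplicates(self.features)
        if dupes:
            raise ValueError(f"study {self.study_id}: duplicate feature ids {dupes}")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(
                f"study {self.study_id}: samples missing a group label: {missing}"
            )
        bad = {s: g for s, g in self.groups.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"study {self.study_id}: unknown group labels {bad}")
        for grp in sorted(VALID_GROUPS):
            n = sum(1 for s in self.samples if self.groups[s] == grp)
            if n < 2:
                raise ValueError(
                    f"study {self.study_id}: group '{grp}' has {n} samples (need >= 2)"
                )

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to ``group``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.groups[s] == group],
            dtype=int,
        )


@dataclass
class TargetMap:
    """Deduplicated miRNA -> target-gene interaction records.

    miRNA ids are normalized to lowercase; gene ids are kept verbatim.
    ``records`` maps ``(mirna_id, gene_id)`` to the interaction type.
    """

    records: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, mirna_id: str, gene_id: str, interaction: str = "repression") -> None:
        if interaction not in EDGE_TYPE_VOCABULARY:
            raise ValueError(
                f"interaction '{interaction}' not in vocabulary "
                f"{sorted(EDGE_TYPE_VOCABULARY)}"
            )
        self.records[(normalize_mirna_id(mirna_id), gene_id.strip())] = interaction

    def targets_of(self, mirna_id: str) -> set[str]:
        m = normalize_mirna_id(mirna_id)
        return {g for (mi, g) in self.records if mi == m}

    def mirnas(self) -> set[str]:
        return {mi for (mi, _g) in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in ids:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def read_expression_study(
    matrix_path: str | Path,
    groups_path: str | Path,
    study_id: str,
    data_type: str,
) -> ExpressionStudy:
    """Read a feature-by-sample log2 matrix and its two-group sample labels.

    The matrix file must have ``feature_id`` as first column header and one
    column per sample; ``NA`` cells become NaN.  Every matrix sample must
    appear in the group file with a ``control``/``disease`` label.
    """
    mat = pd.read_csv(
        matrix_path,
        sep="\t",
        dtype={0: str},
        na_values=["NA"],
        float_precision="round_trip",
    )
    if mat.columns[0] != "feature_id":
        raise ValueError(
            f"{matrix_path}: first column header must be 'feature_id', "
            f"got '{mat.columns[0]}'"
        )
    grp = pd.read_csv(groups_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in grp.columns:
            raise ValueError(f"{groups_path}: missing required column '{col}'")
    groups = dict(zip(grp["sample_id"], grp["group"]))
    samples = [str(c) for c in mat.columns[1:]]
    unlabeled = [s for s in samples if s not in groups]
    if unlabeled:
        raise ValueError(
            f"{groups_path}: no group label for matrix sample(s) {unlabeled}"
        )
    features = mat["feature_id"].tolist()
    values = mat.iloc[:, 1:].to_numpy(dtype=float)
    return ExpressionStudy(
        study_id=study_id,
        features=features,
        samples=samples,
        values=values,
        groups={s: groups[s] for s in samples},
        data_type=data_type,
    )


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, groups_path: str | Path
) -> None:
    """Write a study back to the matrix/group TSV dialect (full float repr)."""
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(study.samples) + "\n")
        for i, feat in enumerate(study.features):
            cells = [
                "NA" if np.isnan(v) else repr(float(v)) for v in study.values[i]
            ]
            fh.write(feat + "\t" + "\t".join(cells) + "\n")
    with open(groups_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s in study.samples:
            fh.write(f"{s}\t{study.groups[s]}\n")


def ensure_log2(study: ExpressionStudy, threshold: float = 50.0) -> ExpressionStudy:
    """Rescale a matrix to log2 if it looks like raw intensities.

    If the matrix maximum exceeds ``threshold`` every value x is replaced by
    log2(x + 1); otherwise the study is returned unchanged.  The +1 offset
    guards zeros.  Idempotent: a log2-scale matrix stays below the threshold.
    """
    vals = study.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        warnings.warn(f"study {study.study_id}: all values missing; left unchanged")
        return study
    if finite.max() <= threshold:
        return study
    if finite.min() <= -1:
        raise ValueError(
            f"study {study.study_id}: values <= -1 present; cannot apply log2(x+1)"
        )
    rescaled = ExpressionStudy(
        study_id=study.study_id,
        features=list(study.features),
        samples=list(study.samples),
        values=np.log2(vals + 1.0),
        groups=dict(study.groups),
        data_type=study.data_type,
        log2_rescaled=True,
    )
    logger.info("study %s rescaled to log2 scale", study.study_id)
    return rescaled


def read_target_map(path: str | Path) -> TargetMap:
    """Read a miRNA-target interaction table.

    Columns ``mirna_id`` and ``gene_id`` are required; a missing or empty
    ``interaction`` column defaults to ``repression`` (the translational
    blockage a miRNA exerts on its target).  Duplicate pairs collapse to one
    record; miRNA ids are lowercased.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    has_inter = "interaction" in df.columns
    tm = TargetMap()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        mirna, gene = row.mirna_id, row.gene_id
        if not isinstance(mirna, str) or not isinstance(gene, str) or not mirna or not gene:
            raise ValueError(f"{path}: malformed row at line {lineno}")
        inter = getattr(row, "interaction", None) if has_inter else None
        if inter is None or (isinstance(inter, float) and np.isnan(inter)) or inter == "":
            inter = "repression"
        try:
            tm.add(mirna, gene, inter)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return tm


def read_pathways(
    edges_path: str | Path, nodes_path: str | Path | None = None
) -> list[PathwayGraph]:
    """Read pathways from a typed edge list plus an optional node list.

    The edge file has columns ``pathway_id, src, dst, type``; the node file
    (columns ``pathway_id, node_id, node_type``) supplies isolated nodes and
    node types.  Nodes default to type ``gene``.  One graph is returned per
    distinct pathway id, in first-appearance order.
    """
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("pathway_id", "src", "dst", "type"):
        if col not in edges.columns:
            raise ValueError(f"{edges_path}: missing required column '{col}'")
    node_rows = None
    if nodes_path is not None:
        node_rows = pd.read_csv(nodes_path, sep="\t", dtype=str)
        for col in ("pathway_id", "node_id", "node_type"):
            if col not in node_rows.columns:
                raise ValueError(f"{nodes_path}: missing required column '{col}'")

    graphs: dict[str, PathwayGraph] = {}
    for lineno, row in enumerate(edges.itertuples(index=False), start=2):
        if row.type not in EDGE_TYPE_VOCABULARY:
            raise ValueError(
                f"{edges_path}: line {lineno}: edge type '{row.type}' not in "
                f"vocabulary {sorted(EDGE_TYPE_VOCABULARY)}"
            )
        g = graphs.setdefault(
            row.pathway_id, PathwayGraph(pathway_id=row.pathway_id, name=row.pathway_id)
        )
        if (row.src, row.dst, row.type) in g.edges:
            warnings.warn(
                f"{edges_path}: line {lineno}: duplicate edge "
                f"({row.src}, {row.dst}, {row.type}) collapsed"
            )
            continue
        g.add_edge(row.src, row.dst, row.type)
    if node_rows is not None:
        for row in node_rows.itertuples(index=False):
            g = graphs.setdefault(
                row.pathway_id,
                PathwayGraph(pathway_id=row.pathway_id, name=row.pathway_id),
            )
            g.add_node(row.node_id, row.node_type)
    return list(graphs.values())


RESULT_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "p_nde",
    "p_pert",
    "p_combined",
    "fdr",
    "rank",
]


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked pathway result table as TSV.

    p-values are printed in scientific notation with 8 significant digits so
    that re-reading reproduces the ranking exactly.
    """
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns {missing}")
    out = table[RESULT_COLUMNS].copy()
    for col in ("p_nde", "p_pert", "p_combined", "fdr"):
        out[col] = out[col].map(lambda v: f"{v:.7e}")
    out["rank"] = out["rank"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
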