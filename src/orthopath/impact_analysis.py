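"""Topology-based pathway scoring.

A pathway's evidence of impact is two-fold: over-representation of
differentially expressed (DE) features among its measured nodes (P_NDE,
hypergeometric tail) and perturbation propagated through its topology
(P_PERT).  The perturbation factor of a node g,

    PF(g) = dE(g) + sum_{u upstream of g} beta_ug * PF(u) / N_ds(u),

is solved as the linear system (I - M) PF = dE with M_gu = beta_ug/N_ds(u);
the net accumulation Acc(g) = PF(g) - dE(g) sums to the pathway's total
perturbation, whose null distribution is built by permuting the observed
expression changes over the pathway's measured nodes.  The two p-values are
combined with the product rule (survival function of a product of two
independent uniforms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from orthopath.pathway_graph import PathwayGraph, downstream_counts, edge_weight


class SingularPathwayError(RuntimeError):
    """The propagation system (I - M) is singular even after damping."""


@dataclass
class ImpactInput:
    """Inputs for scoring one pathway.

    delta_e maps *measured* node ids to their expression change (the REML
    overall standardized mean difference for DE nodes, 0 for measured
    non-DE nodes); pathway nodes absent from delta_e are unmeasured, get
    dE = 0, and do not count toward the measured total.  universe_size and
    universe_de describe all measured / all DE features genome-wide (mRNA
    and miRNA together).
    """

    graph: PathwayGraph
    delta_e: dict[str, float]
    de_nodes: set[str] = field(default_factory=set)
    universe_size: int = 0
    universe_de: int = 0

    def measured_on_pathway(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n in self.delta_e)

    def de_on_pathway(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n in self.de_nodes)


@dataclass
class PathwayScore:
    """Per-pathway evidence summary."""

    pathway_id: str
    p_nde: float
    p_pert: float
    p_combined: float
    acc_total: float
    n_de_on_pathway: int
    singular: bool = False


def p_nde(
    pathway_measured: int,
    pathway_de: int,
    universe_size: int,
    universe_de: int,
) -> float:
    """Hypergeometric over-representation tail P(X >= pathway_de).

    X counts DE features in a draw of ``pathway_measured`` features from a
    universe of ``universe_size`` containing ``universe_de`` DE features.
    """
    if not (0 <= pathway_de <= pathway_measured <= universe_size):
        raise ValueError(
            f"inconsistent counts: de={pathway_de}, measured={pathway_measured}, "
            f"universe={universe_size}"
        )
    if not (0 <= universe_de <= universe_size):
        raise ValueError(
            f"inconsistent universe: de={universe_de}, size={universe_size}"
        )
    if pathway_de == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(pathway_de - 1, universe_size, universe_de, pathway_measured)
    )


def _propagation_matrix(
    graph: PathwayGraph, weight_table: dict[str, float] | None
) -> tuple[list[str], np.ndarray]:
    """Node order and M with M[g,u] = sum of beta_ug / N_ds(u) over relations."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    nds = downstream_counts(graph)
    m = np.zeros((len(nodes), len(nodes)))
    for src, dst, rel in graph.edges:
        beta = edge_weight(rel, weight_table)
        m[idx[dst], idx[src]] += beta / nds[src]
    return nodes, m


def _solve_system(m: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    a = np.eye(m.shape[0]) - m
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError:
        sol = None
    if sol is None or not np.all(np.isfinite(sol)):
        # a feedback loop with net gain 1 makes (I - M) singular; damp once
        a = np.eye(m.shape[0]) - 0.99 * m
        try:
            sol = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError as exc:
            raise SingularPathwayError("propagation system singular") from exc
        if not np.all(np.isfinite(sol)):
            raise SingularPathwayError("propagation system singular")
        warnings.warn("singular propagation system damped by 0.99")
    return sol


def solve_perturbation(
    inp: ImpactInput, weight_table: dict[str, float] | None = None
) -> tuple[dict[str, float], dict[str, float], float]:
    """Solve the perturbation-factor linear system for one pathway.

    Returns (PF per node, Acc per node, total accumulation).  Acc(g) =
    PF(g) - dE(g); the total is the signed sum over all nodes.
    """
    nodes, m = _propagation_matrix(inp.graph, weight_table)
    de = np.array([inp.delta_e.get(n, 0.0) for n in nodes])
    pf = _solve_system(m, de)
    acc = pf - de
    return (
        dict(zip(nodes, pf.tolist())),
        dict(zip(nodes, acc.tolist())),
        float(acc.sum()),
    )


def _acc_weights(
    graph: PathwayGraph, weight_table: dict[str, float] | None
) -> tuple[list[str], np.ndarray]:
    """Per-node coefficients s with acc_total = s . dE.

    acc_total is linear in dE: Acc = ((I-M)^-1 - I) dE, so
    s = ones^T (I-M)^-1 - ones^T, obtained from one transposed solve.  This
    makes each permutation of the null a dot product instead of a solve.
    """
    nodes, m = _propagation_matrix(graph, weight_table)
    ones = np.ones(len(nodes))
    t = _solve_system(m.T, ones)
    return nodes, t - ones


def p_pert(
    inp: ImpactInput,
    n_perm: int = 2000,
    seed: int | None = None,
    weight_table: dict[str, float] | None = None,
    global_pool: np.ndarray | None = None,
) -> tuple[float, float]:
    """Permutation p-value of the total accumulated perturbation.

    The null reassigns the observed nonzero expression changes uniformly at
    random over the pathway's measured nodes (or resamples them from
    ``global_pool``, the genome-wide vector of changes, when given) and
    recomputes the total accumulation; the p-value is two-sided around the
    null median with a +1 pseudo-count.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nodes, s = _acc_weights(inp.graph, weight_table)
    coeff = {n: c for n, c in zip(nodes, s)}
    de_vec = np.array([inp.delta_e.get(n, 0.0) for n in nodes])
    acc_obs = float(np.dot(s, de_vec))
    measured = inp.measured_on_pathway()
    de_on = [n for n in inp.de_on_pathway() if n in inp.delta_e]
    values = np.array([inp.delta_e[n] for n in de_on], dtype=float)
    if values.size == 0 or len(measured) == 0 or np.all(values == 0.0):
        return 1.0, acc_obs
    s_measured = np.array([coeff[n] for n in measured])
    rng = np.random.default_rng(seed)
    k = min(values.size, len(measured))
    null = np.empty(n_perm)
    if global_pool is not None:
        pool = np.asarray(global_pool, dtype=float)
        for i in range(n_perm):
            idx = rng.choice(len(measured), size=k, replace=False)
            null[i] = np.dot(s_measured[idx], rng.choice(pool, size=k, replace=False))
    else:
        for i in range(n_perm):
            idx = rng.choice(len(measured), size=k, replace=False)
            null[i] = np.dot(s_measured[idx], values[:k])
    med = float(np.median(null))
    n_extreme = int(np.sum(np.abs(null - med) >= abs(acc_obs - med)))
    return (1.0 + n_extreme) / (1.0 + n_perm), acc_obs


def combine_evidence(p_nde_val: float, p_pert_val: float) -> float:
    """Combine the two evidence p-values with the product rule.

    For independent uniforms, P(U1*U2 <= c) = c - c*ln(c); the combined
    p-value is that survival probability at c = p_nde * p_pert.
    """
    for name, p in (("p_nde", p_nde_val), ("p_pert", p_pert_val)):
        if not (0 < p <= 1):
            raise ValueError(f"{name} must be in (0,1], got {p}")
    c = p_nde_val * p_pert_val
    if c <= 0:
        warnings.warn("product of evidence p-values underflowed; clamped")
        c = 1e-300
    return float(c - c * math.log(c))


def analyze_pathway(
    inp: ImpactInput,
    n_perm: int = 2000,
    seed: int | None = None,
    weight_table: dict[str, float] | None = None,
) -> PathwayScore:
    """Score one pathway: P_NDE, P_PERT, their combination, and Acc total.

    Genes and miRNAs are counted alike: the universe is the union of
    measured mRNA and miRNA features.  A pathway whose propagation system
    stays singular after damping is flagged and scored with p_pert = 1.
    """
    measured = inp.measured_on_pathway()
    de_nodes = inp.de_on_pathway()
    pn = p_nde(len(measured), len(de_nodes), inp.universe_size, inp.universe_de)
    try:
        pp, acc_obs = p_pert(
            inp, n_perm=n_perm, seed=seed, weight_table=weight_table
        )
        singular = False
    except SingularPathwayError:
        warnings.warn(
            f"pathway {inp.graph.pathway_id}: singular propagation system; "
            "perturbation evidence unavailable (p_pert = 1)"
        )
        pp, acc_obs, singular = 1.0, float("nan"), True
    return PathwayScore(
        pathway_id=inp.graph.pathway_id,
        p_nde=pn,
        p_pert=pp,
        p_combined=combine_evidence(pn, pp),
        acc_total=acc_obs,
        n_de_on_pathway=len(de_nodes),
        singular=singular,
    )
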