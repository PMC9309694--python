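"""ceRNA (lncRNA-miRNA-mRNA) network inference.

A lncRNA acting as a competing endogenous RNA "sponges" miRNAs shared with an
mRNA, relieving its repression.  The inference screens candidate interactions
in three steps over differentially expressed features:

1. negative co-expression — a predicted (miRNA, lncRNA) or (miRNA, mRNA)
   target pair is kept iff Spearman rank correlation (SCC) < 0 across all
   samples of both groups;
2. positive co-expression — a (lncRNA, mRNA) pair sharing at least one
   surviving miRNA is kept iff Pearson correlation (PCC) > 0.5;
3. sponge overlap — the shared-miRNA count x between the K miRNAs sponged by
   the lncRNA and the n miRNAs targeting the mRNA, in a universe of N
   differentially expressed miRNAs, is tested with the hypergeometric upper
   tail P[X >= x]; pairs with p < 0.05 are retained.

Retained pairs are assembled into a tripartite network (lncRNA-miRNA and
miRNA-mRNA edges only) with per-node regulation directions, exportable to
Cytoscape formats via :mod:`cernet.seqio`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._hypergeom import hypergeom_upper_tail
from .seqio import ExpressionMatrix, TargetTable, ValidationError

__all__ = [
    "CorrelationRecord",
    "CeRNAPair",
    "spearman",
    "pearson",
    "screen_mirna_pairs",
    "screen_lnc_mrna_pairs",
    "sponge_test",
    "build_cerna_pairs",
    "assemble_network",
    "network_from_axes",
    "mrna_partners_via",
    "pair_table",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class CorrelationRecord:
    """One correlation between two expression profiles.

    ``defined`` is False when either vector is constant (the coefficient is
    undefined); such pairs fail every screen rather than erroring the run.
    """

    id_a: str
    id_b: str
    kind: str  # "SCC" or "PCC"
    value: float
    n: int
    defined: bool = True


def _corr(x: np.ndarray, y: np.ndarray, kind: str, id_a: str, id_b: str) -> CorrelationRecord:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlation inputs must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(id_a, id_b, kind, np.nan, len(x), defined=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "SCC":
            value = stats.spearmanr(x, y).statistic
        else:
            value = stats.pearsonr(x, y).statistic
    defined = bool(np.isfinite(value))
    return CorrelationRecord(id_a, id_b, kind, float(value), len(x), defined=defined)


def spearman(x: Sequence[float], y: Sequence[float], id_a: str = "x", id_b: str = "y") -> CorrelationRecord:
    """Spearman rank correlation (mid-ranks for ties)."""
    return _corr(np.asarray(x), np.asarray(y), "SCC", id_a, id_b)


def pearson(x: Sequence[float], y: Sequence[float], id_a: str = "x", id_b: str = "y") -> CorrelationRecord:
    """Pearson sample moment correlation."""
    return _corr(np.asarray(x), np.asarray(y), "PCC", id_a, id_b)


def _aligned(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix) -> list[str]:
    if list(expr_a.samples) != list(expr_b.samples):
        if set(expr_a.samples) != set(expr_b.samples):
            raise ValidationError("expression matrices do not share samples")
    return list(expr_a.samples)


def _expression(matrix: ExpressionMatrix, expression: pd.DataFrame | None) -> pd.DataFrame:
    if expression is None:
        from .diffexpr import log_expression

        return log_expression(matrix)
    return expression.loc[matrix.features]


def screen_mirna_pairs(
    expr_mir: ExpressionMatrix,
    expr_other: ExpressionMatrix,
    targets: TargetTable,
    scc_max: float = 0.0,
    expression_mir: pd.DataFrame | None = None,
    expression_other: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep predicted (miRNA, target) pairs with SCC strictly below ``scc_max``.

    Correlations are computed across all samples pooled over both groups, on
    log2 normalized expression (supply ``expression_*`` to reuse values
    normalized on the full matrices; by default they are derived from the
    given matrices).  The matrices are expected to be restricted to
    differentially expressed features already; only pairs present in both
    matrices and the target table are considered.  Undefined
    (constant-profile) correlations fail the screen.
    """
    samples = _aligned(expr_mir, expr_other)
    sub = targets.restrict(expr_mir.features, expr_other.features)
    rows = []
    mir_arr = _expression(expr_mir, expression_mir)[samples]
    oth_arr = _expression(expr_other, expression_other)[samples]
    for mirna, target, cls in sub.pairs[["mirna", "target", "target_class"]].itertuples(
        index=False
    ):
        if cls != expr_other.rna_class:
            continue
        rec = spearman(
            mir_arr.loc[mirna].to_numpy(), oth_arr.loc[target].to_numpy(), mirna, target
        )
        if rec.defined and rec.value < scc_max:
            rows.append(
                {"mirna": mirna, "target": target, "target_class": cls, "scc": rec.value}
            )
    return pd.DataFrame(rows, columns=["mirna", "target", "target_class", "scc"])


@dataclass
class CeRNAPair:
    """A candidate lncRNA-mRNA ceRNA pair with its sponge-test bookkeeping.

    K / n are the miRNAs (post anti-correlation screen) targeting the lncRNA
    and mRNA respectively, x their overlap, N the universe size.
    """

    lncrna: str
    mrna: str
    shared_mirnas: frozenset[str]
    K: int
    n: int
    N: int
    x: int
    pcc: float
    scc_lnc: dict[str, float] = field(default_factory=dict)
    scc_mrna: dict[str, float] = field(default_factory=dict)
    p_sponge: float = np.nan

    def __post_init__(self):
        if self.x > min(self.K, self.n):
            raise ValidationError(
                f"pair {self.lncrna}-{self.mrna}: x={self.x} exceeds min(K, n)"
            )
        if max(self.K, self.n) > self.N:
            raise ValidationError(
                f"pair {self.lncrna}-{self.mrna}: K/n exceed universe N={self.N}"
            )


def sponge_test(pair: CeRNAPair) -> float:
    """Hypergeometric upper-tail p for the shared-sponge overlap of a pair."""
    return hypergeom_upper_tail(pair.x, pair.N, pair.K, pair.n)


def screen_lnc_mrna_pairs(
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    screened_lnc: pd.DataFrame,
    screened_mrna: pd.DataFrame,
    pcc_min: float = 0.5,
    expression_lnc: pd.DataFrame | None = None,
    expression_mrna: pd.DataFrame | None = None,
) -> list[CeRNAPair]:
    """Candidate pairs sharing >= 1 screened miRNA, kept iff PCC > ``pcc_min``.

    ``screened_lnc`` / ``screened_mrna`` are the outputs of
    :func:`screen_mirna_pairs` for the two classes; PCC is computed on log2
    normalized expression.  The sponge-test fields (K, n, N, x) are filled
    here; p_sponge is left for :func:`sponge_test`.
    """
    samples = _aligned(expr_lnc, expr_mrna)
    mir_by_lnc: dict[str, dict[str, float]] = {}
    for m, t, s in screened_lnc[["mirna", "target", "scc"]].itertuples(index=False):
        mir_by_lnc.setdefault(t, {})[m] = s
    mir_by_mrna: dict[str, dict[str, float]] = {}
    for m, t, s in screened_mrna[["mirna", "target", "scc"]].itertuples(index=False):
        mir_by_mrna.setdefault(t, {})[m] = s
    universe = set(screened_lnc["mirna"]) | set(screened_mrna["mirna"])
    N = len(universe)
    lnc_arr = _expression(expr_lnc, expression_lnc)[samples]
    mrna_arr = _expression(expr_mrna, expression_mrna)[samples]
    pairs: list[CeRNAPair] = []
    for lnc, lnc_mirs in sorted(mir_by_lnc.items()):
        for mrna, mrna_mirs in sorted(mir_by_mrna.items()):
            shared = set(lnc_mirs) & set(mrna_mirs)
            if not shared:
                continue
            rec = pearson(
                lnc_arr.loc[lnc].to_numpy(), mrna_arr.loc[mrna].to_numpy(), lnc, mrna
            )
            if not rec.defined or not rec.value > pcc_min:
                continue
            pairs.append(
                CeRNAPair(
                    lncrna=lnc,
                    mrna=mrna,
                    shared_mirnas=frozenset(shared),
                    K=len(lnc_mirs),
                    n=len(mrna_mirs),
                    N=N,
                    x=len(shared),
                    pcc=rec.value,
                    scc_lnc=dict(lnc_mirs),
                    scc_mrna=dict(mrna_mirs),
                )
            )
    return pairs


def build_cerna_pairs(
    expr_lnc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    targets: TargetTable,
    scc_max: float = 0.0,
    pcc_min: float = 0.5,
    sponge_alpha: float = 0.05,
    expression_lnc: pd.DataFrame | None = None,
    expression_mir: pd.DataFrame | None = None,
    expression_mrna: pd.DataFrame | None = None,
) -> list[CeRNAPair]:
    """Run the three screens end to end on DE-restricted matrices.

    Returns the retained pairs (p_sponge < ``sponge_alpha``) with all
    correlation and overlap metadata filled in.
    """
    screened_lnc = screen_mirna_pairs(
        expr_mir, expr_lnc, targets, scc_max=scc_max,
        expression_mir=expression_mir, expression_other=expression_lnc,
    )
    screened_mrna = screen_mirna_pairs(
        expr_mir, expr_mrna, targets, scc_max=scc_max,
        expression_mir=expression_mir, expression_other=expression_mrna,
    )
    candidates = screen_lnc_mrna_pairs(
        expr_lnc, expr_mrna, screened_lnc, screened_mrna, pcc_min=pcc_min,
        expression_lnc=expression_lnc, expression_mrna=expression_mrna,
    )
    retained = []
    for pair in candidates:
        pair.p_sponge = sponge_test(pair)
        if pair.p_sponge < sponge_alpha:
            retained.append(pair)
    return retained


def assemble_network(
    pairs: Iterable[CeRNAPair], directions: Mapping[str, str]
) -> nx.Graph:
    """Tripartite lncRNA-miRNA-mRNA graph from retained ceRNA pairs.

    Nodes carry ``rna_class`` and regulation ``direction``; lncRNA-miRNA
    edges carry the sponge SCC, miRNA-mRNA edges the repression SCC, both
    annotated with the supporting pair's PCC and sponge p.  miRNA nodes not
    on a complete lncRNA-miRNA-mRNA path are pruned.  Output is independent
    of the order pairs are supplied in.
    """
    G = nx.Graph()
    for pair in sorted(pairs, key=lambda p: (p.lncrna, p.mrna)):
        for node, cls in ((pair.lncrna, "lncRNA"), (pair.mrna, "mRNA")):
            if node not in directions:
                raise ValidationError(f"no DE direction for node {node!r}")
            G.add_node(node, rna_class=cls, direction=directions[node])
        for mir in sorted(pair.shared_mirnas):
            if mir not in directions:
                raise ValidationError(f"no DE direction for node {mir!r}")
            G.add_node(mir, rna_class="miRNA", direction=directions[mir])
            G.add_edge(
                pair.lncrna,
                mir,
                interaction="sponge",
                scc=float(pair.scc_lnc.get(mir, np.nan)),
                pcc=float(pair.pcc),
                p_sponge=float(pair.p_sponge),
            )
            G.add_edge(
                mir,
                pair.mrna,
                interaction="represses",
                scc=float(pair.scc_mrna.get(mir, np.nan)),
                pcc=float(pair.pcc),
                p_sponge=float(pair.p_sponge),
            )
    prune = [
        n
        for n, d in G.nodes(data=True)
        if d["rna_class"] == "miRNA"
        and not (
            any(G.nodes[v]["rna_class"] == "lncRNA" for v in G[n])
            and any(G.nodes[v]["rna_class"] == "mRNA" for v in G[n])
        )
    ]
    G.remove_nodes_from(prune)
    return G


def network_from_axes(
    lncrna: str,
    axes: Mapping[str, Sequence[str]],
    directions: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Build a ceRNA network directly from per-miRNA mRNA lists.

    Convenience constructor for literature-derived networks where only the
    edge lists (lncRNA -> miRNA -> mRNAs) are known, without correlation or
    sponge-test metadata.  All nodes default to direction "up" unless given.
    """
    directions = dict(directions or {})
    G = nx.Graph()
    G.add_node(lncrna, rna_class="lncRNA", direction=directions.get(lncrna, "up"))
    for mir, mrnas in axes.items():
        G.add_node(mir, rna_class="miRNA", direction=directions.get(mir, "down"))
        G.add_edge(lncrna, mir, interaction="sponge")
        for mrna in mrnas:
            G.add_node(mrna, rna_class="mRNA", direction=directions.get(mrna, "up"))
            G.add_edge(mir, mrna, interaction="represses")
    return G


def mrna_partners_via(G: nx.Graph, lncrna: str, mirna: str) -> set[str]:
    """mRNAs reachable from ``lncrna`` through the single miRNA ``mirna``."""
    if mirna not in G[lncrna]:
        return set()
    return {v for v in G[mirna] if G.nodes[v]["rna_class"] == "mRNA"}


def pair_table(pairs: Iterable[CeRNAPair]) -> pd.DataFrame:
    """Flat per-pair summary (lncRNA, mRNA, x, K, n, N, PCC, p_sponge)."""
    return pd.DataFrame(
        [
            {
                "lncrna": p.lncrna,
                "mrna": p.mrna,
                "shared_mirnas": ",".join(sorted(p.shared_mirnas)),
                "x": p.x,
                "K": p.K,
                "n": p.n,
                "N": p.N,
                "pcc": p.pcc,
                "p_sponge": p.p_sponge,
            }
            for p in sorted(pairs, key=lambda q: (q.lncrna, q.mrna))
        ],
        columns=["lncrna", "mrna", "shared_mirnas", "x", "K", "n", "N", "pcc", "p_sponge"],
    )


@dataclass
class PipelineResult:
    """End-to-end output: DE tables, retained pairs and the network."""

    de_lnc: pd.DataFrame
    de_mir: pd.DataFrame
    de_mrna: pd.DataFrame
    pairs: list[CeRNAPair]
    network: nx.Graph


def run_pipeline(
    expr_lnc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    targets: TargetTable,
    lfc_lnc: float = 1.0,
    lfc_mir: float = 2.0,
    lfc_mrna: float = 2.0,
    p_threshold: float = 0.05,
    scc_max: float = 0.0,
    pcc_min: float = 0.5,
    sponge_alpha: float = 0.05,
) -> PipelineResult:
    """Differential expression -> three screens -> network, with defaults
    matching the study design (|log2FC| > 2 for miRNA/mRNA, fold change > 2
    for lncRNAs, raw p < 0.05 everywhere)."""
    from . import diffexpr

    de_tables = {}
    de_features = {}
    expression = {}
    for name, mat, lfc in (
        ("lnc", expr_lnc, lfc_lnc),
        ("mir", expr_mir, lfc_mir),
        ("mrna", expr_mrna, lfc_mrna),
    ):
        factors = diffexpr.normalization_factors(mat)
        res = diffexpr.exact_test(mat, factors=factors)
        res = diffexpr.apply_de_filter(res, lfc_threshold=lfc, p_threshold=p_threshold)
        de_tables[name] = res
        de_features[name] = set(res.loc[res["passes_de"], "feature_id"])
        # normalize on the full matrix; screens then subset rows
        expression[name] = diffexpr.log_expression(mat, factors)
    sub_lnc = expr_lnc.subset(de_features["lnc"])
    sub_mir = expr_mir.subset(de_features["mir"])
    sub_mrna = expr_mrna.subset(de_features["mrna"])
    pairs = build_cerna_pairs(
        sub_lnc,
        sub_mir,
        sub_mrna,
        targets,
        scc_max=scc_max,
        pcc_min=pcc_min,
        sponge_alpha=sponge_alpha,
        expression_lnc=expression["lnc"],
        expression_mir=expression["mir"],
        expression_mrna=expression["mrna"],
    )
    directions = {}
    for res in de_tables.values():
        directions.update(zip(res["feature_id"], res["direction"]))
    network = assemble_network(pairs, directions)
    return PipelineResult(
        de_lnc=de_tables["lnc"],
        de_mir=de_tables["mir"],
        de_mrna=de_tables["mrna"],
        pairs=pairs,
        network=network,
    )
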