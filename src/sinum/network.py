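"""Downstream statistics on single-cell networks.

Covers edge-set overlap with reference protein-protein interaction (PPI)
networks, scale-free topology fitting, hub calling, Fisher enrichment of
hubs/edges in a cell type, marker screening (differential network degree
without differential expression), per-label aggregate networks, and degree
trajectories across time points.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegreeMatrix, SingleCellNetwork
from .preprocess import ExpressionMatrix, ValidationError

Edge = tuple[str, str]


def _norm_edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceNetwork:
    """Undirected reference edge set over gene symbols (e.g. a PPI network)."""

    edges: set[Edge]

    @property
    def node_set(self) -> set[str]:
        return {g for e in self.edges for g in e}

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, upper_case: bool = False) -> "ReferenceNetwork":
        """Two-column TSV of symbols; '#' comments; self-loops dropped."""
        edges: set[Edge] = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValidationError(f"reference edge line needs 2 columns: {line!r}")
                a, b = parts[0], parts[1]
                if upper_case:
                    a, b = a.upper(), b.upper()
                if a != b:
                    edges.add(_norm_edge(a, b))
        return cls(edges=edges)


def overlap_coefficient(a: set[Edge], b: set[Edge]) -> float:
    """|a & b| / min(|a|, |b|) on unordered, case-sensitive symbol pairs."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty edge sets")
    a = {_norm_edge(*e) for e in a}
    b = {_norm_edge(*e) for e in b}
    return len(a & b) / min(len(a), len(b))


def scn_edge_symbols(scn: SingleCellNetwork, gene_ids: list[str]) -> set[Edge]:
    """An SCN's edges as unordered gene-symbol pairs."""
    return {_norm_edge(gene_ids[i], gene_ids[j]) for i, j in scn.edges}


# ---------------------------------------------------------------------------
# scale-free topology


@dataclass
class PowerLawFit:
    """OLS fit of log10 P(k) on log10 k; gamma is the degree exponent."""

    gamma: float
    r_squared: float
    fitted_points: np.ndarray  # (d, 2) columns: log10 k, log10 P(k)


def scale_free_fit(degrees, log_binning: bool = False) -> PowerLawFit:
    """Fit P(k) ~ k^-gamma on the empirical degree distribution.

    Uses degrees k >= 1 only; P(k) is the fraction of nodes with degree
    exactly k among all nodes supplied (raw distinct-degree frequencies by
    default; ``log_binning`` pools counts into logarithmic bins for heavy
    tails).  gamma = -slope, r_squared = R^2 of the regression.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    n_nodes = len(degrees)
    pos = degrees[degrees >= 1]
    ks, counts = np.unique(pos, return_counts=True)
    if log_binning and len(ks) >= 3:
        edges = np.logspace(0, np.log10(ks.max() + 1), num=max(4, int(np.log2(ks.max())) + 2))
        idx = np.digitize(ks, edges) - 1
        k_binned, p_binned = [], []
        for b in np.unique(idx):
            sel = idx == b
            width = edges[b + 1] - edges[b] if b + 1 < len(edges) else 1.0
            k_binned.append(np.exp(np.mean(np.log(ks[sel]))))
            p_binned.append(counts[sel].sum() / n_nodes / width)
        ks, pk = np.array(k_binned), np.array(p_binned)
    else:
        pk = counts / n_nodes
    if len(ks) < 3:
        raise ValueError(
            f"scale-free fit needs >= 3 distinct positive degrees, got {len(ks)}"
        )
    x = np.log10(ks)
    y = np.log10(pk)
    fit = stats.linregress(x, y)
    return PowerLawFit(
        gamma=-float(fit.slope),
        r_squared=float(fit.rvalue) ** 2,
        fitted_points=np.column_stack([x, y]),
    )


def match_network_scale(
    target_edge_count: int,
    reference: ReferenceNetwork,
    confidence: dict[Edge, float],
) -> set[Edge]:
    """Top reference edges by confidence, matching a target edge count.

    Reference edges with no score rank below all scored ones; ties are
    broken by lexicographic edge name so the selection is deterministic.
    """
    if target_edge_count > len(reference.edges):
        raise ValueError(
            f"target {target_edge_count} exceeds reference size {len(reference.edges)}"
        )
    conf = {_norm_edge(*e): s for e, s in confidence.items()}
    ranked = sorted(
        reference.edges,
        key=lambda e: (-conf.get(e, -np.inf), e),
    )
    return set(ranked[:target_edge_count])


# ---------------------------------------------------------------------------
# hubs and enrichment


def hubs(scn_degrees: np.ndarray, fraction: float = 0.25) -> set[int]:
    """Genes whose degree falls in the top ``fraction`` of all nodes.

    The cutoff is the degree of the ceil(fraction * m)-th highest node;
    every gene tied with the cutoff is a hub.
    """
    d = np.asarray(scn_degrees, dtype=float)
    m = len(d)
    if m < 4:
        raise ValueError("hub calling needs at least 4 genes")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    h = max(1, int(np.ceil(fraction * m)))
    cutoff = np.sort(d)[::-1][h - 1]
    return set(np.nonzero(d >= cutoff)[0].tolist())


@dataclass
class EnrichmentResult:
    """One-sided Fisher's exact test on a 2x2 presence table."""

    odds_ratio: float
    p_value: float
    table: np.ndarray  # [[a, b], [c, d]]


def fisher_p(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    _, p = stats.fisher_exact(np.array([[a, b], [c, d]]), alternative=alternative)
    return float(p)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # ad/bc with a=0 -> 0 and bc=0 (a>0) -> inf
    if a == 0:
        return 0.0
    if b * c == 0:
        return float(np.inf)
    return (a * d) / (b * c)


def _hub_indicator(scns: list[SingleCellNetwork], m: int, fraction: float) -> np.ndarray:
    """(m, n) bool: is gene g a hub of cell c's SCN."""
    out = np.zeros((m, len(scns)), dtype=bool)
    for c, scn in enumerate(scns):
        deg = np.zeros(m)
        for (i, j) in scn.edges:
            deg[i] += 1
            deg[j] += 1
        out[list(hubs(deg, fraction)), c] = True
    return out


def _split_cells(cell_labels, target_label: str) -> np.ndarray:
    labels = np.asarray([str(x) for x in cell_labels])
    in_target = labels == str(target_label)
    if not in_target.any():
        raise ValueError(f"label {target_label!r} not present")
    return in_target


def hub_enrichment(
    gene: int,
    scns: list[SingleCellNetwork],
    cell_labels,
    target_label: str,
    m: int | None = None,
    hub_fraction: float = 0.25,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Is the gene a hub more often in target-type cells than in the rest?

    2x2 table of (cell in target type) x (gene is a hub of that cell's SCN),
    tested with a one-sided (greater) Fisher's exact test by default.
    """
    if m is None:
        m = 1 + max((g for s in scns for e in s.edges for g in e), default=gene)
    in_target = _split_cells(cell_labels, target_label)
    is_hub = _hub_indicator(scns, m, hub_fraction)[gene]
    return _enrich(in_target, is_hub, alternative)


def edge_enrichment(
    edge: tuple[int, int],
    scns: list[SingleCellNetwork],
    cell_labels,
    target_label: str,
    alternative: str = "greater",
) -> EnrichmentResult:
    """As :func:`hub_enrichment`, on per-cell presence of one edge."""
    i, j = min(edge), max(edge)
    in_target = _split_cells(cell_labels, target_label)
    present = np.array([(i, j) in s.edges for s in scns])
    return _enrich(in_target, present, alternative)


def _enrich(in_target: np.ndarray, positive: np.ndarray, alternative: str) -> EnrichmentResult:
    a = int((in_target & positive).sum())
    b = int((in_target & ~positive).sum())
    c = int((~in_target & positive).sum())
    d = int((~in_target & ~positive).sum())
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    return EnrichmentResult(odds_ratio=_odds_ratio(a, b, c, d),
                            p_value=fisher_p(a, b, c, d, alternative), table=table)


# ---------------------------------------------------------------------------
# marker screening


def marker_screen(
    dm: DegreeMatrix,
    gem: ExpressionMatrix,
    scns: list[SingleCellNetwork],
    cell_labels,
    target_label: str,
    alpha: float = 0.05,
    hub_fraction: float = 0.25,
) -> pd.DataFrame:
    """Genes that mark a cell type at the network level but not in expression.

    A gene is reported when (i) its hub-enrichment Fisher p, BH-adjusted
    across all genes, is below ``alpha``, and (ii) a two-sided rank-sum test
    finds no expression difference between target and other cells
    (raw p >= alpha — deliberately unadjusted, which is conservative for a
    claim of "no difference").  Rows are sorted by enrichment odds ratio,
    descending.
    """
    from statsmodels.stats.multitest import multipletests

    if dm.gene_ids != gem.gene_ids or dm.cell_ids != gem.cell_ids:
        raise ValidationError("degree matrix and expression matrix are misaligned")
    if len(scns) != gem.n_cells:
        raise ValidationError("SCN list does not match the cell axis")
    in_target = _split_cells(cell_labels, target_label)
    m = gem.n_genes
    is_hub = _hub_indicator(scns, m, hub_fraction)

    rows = []
    for g in range(m):
        enr = _enrich(in_target, is_hub[g], "greater")
        x = gem.values[g, in_target]
        y = gem.values[g, ~in_target]
        expr_p = float(stats.ranksums(x, y).pvalue)
        rows.append((gem.gene_ids[g], enr.odds_ratio, enr.p_value, expr_p))
    df = pd.DataFrame(rows, columns=["gene_id", "odds_ratio", "hub_p", "expr_p"])
    df["hub_p_bh"] = multipletests(df["hub_p"], method="fdr_bh")[1]
    keep = (df["hub_p_bh"] < alpha) & (df["expr_p"] >= alpha)
    out = df[keep].sort_values("odds_ratio", ascending=False, kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregate networks and trajectories


@dataclass
class AggregateNetwork:
    """Edges present in more than ``min_fraction`` of one label's cells."""

    label: str
    edges: dict[tuple[int, int], float]  # pair -> presence frequency


def aggregate_network(
    scns: list[SingleCellNetwork],
    cell_labels,
    label: str,
    min_fraction: float = 0.7,
    gene_subset: set[int] | None = None,
) -> AggregateNetwork:
    """Aggregate the SCNs of one label into a consensus network.

    An edge survives iff its presence frequency among that label's cells is
    strictly greater than ``min_fraction``.
    """
    in_label = _split_cells(cell_labels, label)
    if gene_subset is not None and len(gene_subset) < 2:
        raise ValueError("gene_subset must contain at least 2 genes")
    group = [s for s, t in zip(scns, in_label) if t]
    counts: dict[tuple[int, int], int] = {}
    for scn in group:
        for e in scn.edges:
            if gene_subset is not None and not (e[0] in gene_subset and e[1] in gene_subset):
                continue
            counts[e] = counts.get(e, 0) + 1
    n_cells = len(group)
    edges = {
        e: c / n_cells for e, c in counts.items() if c / n_cells > min_fraction
    }
    return AggregateNetwork(label=str(label), edges=edges)


def degree_trajectory(
    dm: DegreeMatrix,
    cell_labels,
    genes: list[str],
) -> pd.DataFrame:
    """Mean degree per gene per label, plus the label of maximal mean degree.

    Ties for the maximum resolve to the lexicographically first label and
    are flagged in the ``argmax_tied`` column.
    """
    labels = np.asarray([str(x) for x in cell_labels])
    unique_labels = sorted(set(labels))
    index = {g: i for i, g in enumerate(dm.gene_ids)}
    rows = []
    for g in genes:
        if g not in index:
            raise ValueError(f"gene {g!r} not in degree matrix")
        gi = index[g]
        means = {
            lab: float(dm.values[gi, labels == lab].mean()) for lab in unique_labels
        }
        best = max(means.values())
        argmax_labels = [lab for lab in unique_labels if means[lab] == best]
        row = {"gene_id": g, **means,
               "argmax_label": argmax_labels[0],
               "argmax_tied": len(argmax_labels) > 1}
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_to_graphml(agg: AggregateNetwork, gene_ids: list[str],
                         path: str | os.PathLike) -> None:
    """Export an aggregate network as GraphML (edge attribute: frequency)."""
    import networkx as nx

    g = nx.Graph(label=agg.label)
    for (i, j), freq in sorted(agg.edges.items()):
        g.add_edge(gene_ids[i], gene_ids[j], frequency=float(freq))
    nx.write_graphml(g, os.fspath(path))


def per_label_degrees(dm: DegreeMatrix, cell_labels, gene: str) -> dict[str, np.ndarray]:
    """Per-cell degree values of one gene, grouped by label (for violins)."""
    labels = np.asarray([str(x) for x in cell_labels])
    gi = dm.gene_ids.index(gene)
    return {lab: dm.values[gi, labels == lab] for lab in sorted(set(labels))}
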