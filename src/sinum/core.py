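"""The SINUM statistic: grid-based local mutual information per cell.

For every unordered gene pair (X, Y) and every cell c, a local mutual
information score is computed from the cell's neighborhood in the X-Y
scatter of all n cells:

1.  Each gene's expression axis is split into ``GR = floor(sqrt(n) + 1/2)``
    equal-width grid bins spanning that gene's [min, max] over all cells.
2.  The tentative neighborhood of cell c along one axis is the value
    interval spanned by the ``k = ceil(box_size * n)`` cells whose
    expression is nearest to c's (c itself included).
3.  The tentative interval is expanded outward to the nearest grid
    boundaries: the final neighborhood is the inclusive range of bins the
    interval intersects.
4.  Local entropies are computed over the bins of the final neighborhoods
    with probabilities substituted by frequencies n_x / n (natural log),
    and the local MI is ``I = H_X + H_Y - H_XY`` where the joint term runs
    over the grid rectangle intersecting both neighborhoods.
5.  Per pair, the n local MI scores are standardized across cells
    (z = (I - mean) / sd, population sd); an edge is called in cell c
    when z exceeds the threshold (strictly).

The per-cell edge sets form n single-cell networks (SCNs); counting each
gene's edges per cell gives the degree matrix (DM), an m x n matrix aligned
with the expression matrix.

The implementation streams pair by pair (never materializing an
m x m x n tensor); each pair costs O(n + GR^2) after an O(m n log n)
per-gene precomputation, so full inference is O(m^2 n).
"""

from __future__ import annotations

import gzip
import math
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ExpressionMatrix, ValidationError

__all__ = [
    "GridSpec",
    "NeighborhoodBox",
    "PairMIProfile",
    "SingleCellNetwork",
    "DegreeMatrix",
    "compute_grid_count",
    "build_grid",
    "tentative_neighborhood",
    "snap_to_grid",
    "local_mi",
    "pair_profile",
    "infer_scns",
    "degree_matrix",
    "write_scns",
    "write_degree_matrix",
]


# ---------------------------------------------------------------------------
# grid construction


def compute_grid_count(n: int) -> int:
    """Number of equal-width grid bins per axis: floor(sqrt(n) + 1/2), >= 1."""
    if n < 1:
        raise ValueError(f"cell count must be >= 1, got {n}")
    return max(1, math.floor(math.sqrt(n) + 0.5))


@dataclass
class GridSpec:
    """Per-gene equal-width bin edges.

    ``edges_per_gene`` has shape ``(m, GR + 1)``; row g spans gene g's
    [min, max] expression over all cells.  A constant gene yields a single
    degenerate zero-width bin and is flagged in ``degenerate``.
    """

    grid_count: int
    edges_per_gene: np.ndarray
    degenerate: np.ndarray  # (m,) bool

    def gene_edges(self, gene: int) -> np.ndarray:
        return self.edges_per_gene[gene]


def build_grid(gem: ExpressionMatrix) -> GridSpec:
    """Equal-width grid over each gene's observed expression range."""
    values = gem.values
    m, n = values.shape
    gr = compute_grid_count(n)
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    degenerate = hi <= lo
    # linspace per gene; degenerate genes get GR+1 copies of the constant
    frac = np.linspace(0.0, 1.0, gr + 1)
    edges = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
    edges[:, 0] = lo
    edges[:, -1] = hi
    return GridSpec(grid_count=gr, edges_per_gene=edges, degenerate=degenerate)


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin assignment under the half-open convention (last bin closed).

    A value lying exactly on an internal edge belongs to the bin on its
    right; values equal to the last edge fall in the last bin.
    """
    gr = len(edges) - 1
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, gr - 1)


# ---------------------------------------------------------------------------
# neighborhoods


def tentative_neighborhood(values: np.ndarray, cell: int, box_size: float) -> tuple[float, float]:
    """Value interval spanned by the k = ceil(box_size * n) nearest cells.

    Nearest in expression value to the target cell, target included; ties
    broken toward the lower value.  Returns the closed interval
    ``[min, max]`` of the selected values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    k = _neighborhood_size(n, box_size)
    s = np.sort(values, kind="stable")
    start = int(_window_starts(s, np.array([values[cell]]), k)[0])
    return float(s[start]), float(s[start + k - 1])


def _neighborhood_size(n: int, box_size: float) -> int:
    if not 0.0 < box_size <= 1.0:
        raise ValueError(f"box_size must be in (0, 1], got {box_size}")
    k = math.ceil(box_size * n)
    if k < 1:
        raise ValueError(f"box_size * n = {box_size * n} < 1: neighborhood empty")
    return min(k, n)


def _window_starts(sorted_vals: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest window for each query value.

    Vectorized binary search over candidate starts; equidistant boundary
    candidates resolve to the lower value.
    """
    n = len(sorted_vals)
    lo = np.zeros(len(x), dtype=np.int64)
    hi = np.full(len(x), n - k, dtype=np.int64)
    while True:
        active = lo < hi
        if not active.any():
            break
        mid = np.where(active, (lo + hi) // 2, 0)
        go_right = (x - sorted_vals[mid]) > (sorted_vals[mid + k] - x)
        lo = np.where(active & go_right, mid + 1, lo)
        hi = np.where(active & ~go_right, mid, hi)
    return lo


def _split_window_starts(ranks: np.ndarray, n: int, k: int) -> np.ndarray:
    """Rank-centered window (CSN-style half-above/half-below alternative)."""
    half = (k - 1) // 2
    return np.clip(ranks - half, 0, n - k)


@dataclass
class NeighborhoodBox:
    """Final (grid-snapped) neighborhood of one cell along one gene's axis."""

    bin_range: tuple[int, int]
    member_count_per_bin: np.ndarray
    gene_index: int | None = None
    cell_index: int | None = None

    @property
    def member_count(self) -> int:
        return int(self.member_count_per_bin.sum())


def snap_to_grid(
    interval: tuple[float, float],
    gene_edges: np.ndarray,
    values: np.ndarray | None = None,
    gene_index: int | None = None,
    cell_index: int | None = None,
) -> NeighborhoodBox:
    """Expand a value interval outward to the grid bins it intersects.

    Returns the inclusive bin range; per-bin member counts are taken over
    all n cells when ``values`` is supplied.
    """
    lo, hi = interval
    if hi < lo:
        raise ValueError("interval upper bound below lower bound")
    first = int(_bin_indices(np.array([lo]), gene_edges)[0])
    last = int(_bin_indices(np.array([hi]), gene_edges)[0])
    if values is not None:
        bins = _bin_indices(np.asarray(values, dtype=float), gene_edges)
        counts = np.bincount(
            bins[(bins >= first) & (bins <= last)] - first,
            minlength=last - first + 1,
        )
    else:
        counts = np.zeros(last - first + 1, dtype=int)
    return NeighborhoodBox(
        bin_range=(first, last),
        member_count_per_bin=counts,
        gene_index=gene_index,
        cell_index=cell_index,
    )


# ---------------------------------------------------------------------------
# per-gene precomputation shared by all pairs


class _GeneContext:
    """Everything pair evaluation needs about one gene, computed once.

    ``first`` / ``last`` are each cell's final-neighborhood bin range;
    ``h_prefix`` holds prefix sums of the per-bin entropy terms
    -(count/n) log(count/n), so the marginal local entropy of any bin range
    is a two-element difference.
    """

    __slots__ = ("bins", "counts", "first", "last", "h_marginal", "degenerate")

    def __init__(
        self,
        values: np.ndarray,
        edges: np.ndarray,
        degenerate: bool,
        box_size: float,
        neighborhood: str,
    ) -> None:
        n = len(values)
        gr = len(edges) - 1
        self.degenerate = degenerate
        self.bins = _bin_indices(values, edges) if not degenerate else np.zeros(n, dtype=np.int64)
        self.counts = np.bincount(self.bins, minlength=gr)
        k = _neighborhood_size(n, box_size)
        order = np.argsort(values, kind="stable")
        s = values[order]
        if neighborhood == "nearest":
            starts = _window_starts(s, values, k)
        elif neighborhood == "split":
            ranks = np.empty(n, dtype=np.int64)
            ranks[order] = np.arange(n)
            starts = _split_window_starts(ranks, n, k)
        else:
            raise ValueError(f"unknown neighborhood mode {neighborhood!r}")
        lo_vals = s[starts]
        hi_vals = s[starts + k - 1]
        if degenerate:
            self.first = np.zeros(n, dtype=np.int64)
            self.last = np.zeros(n, dtype=np.int64)
        else:
            self.first = _bin_indices(lo_vals, edges)
            self.last = _bin_indices(hi_vals, edges)
        h_terms = _entropy_terms(self.counts, n)
        prefix = np.concatenate([[0.0], np.cumsum(h_terms)])
        self.h_marginal = prefix[self.last + 1] - prefix[self.first]


def _entropy_terms(counts: np.ndarray, n: int) -> np.ndarray:
    """-(c/n) log(c/n) per bin, with 0 log 0 := 0 (natural log)."""
    p = counts / n
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = -p[nz] * np.log(p[nz])
    return out


# ---------------------------------------------------------------------------
# local MI and pair profiles


def local_mi(
    gem: ExpressionMatrix,
    grid: GridSpec,
    gene_x: int,
    gene_y: int,
    cell: int,
    box_size: float,
    neighborhood: str = "nearest",
) -> float:
    """Local MI of one gene pair in one cell (natural log).

    Degenerate (constant) genes carry no information; pairs involving one
    return 0 by definition.
    """
    if grid.degenerate[gene_x] or grid.degenerate[gene_y]:
        return 0.0
    profile = pair_profile(gem, grid, gene_x, gene_y, box_size, neighborhood)
    return float(profile.mi_per_cell[cell])


@dataclass
class PairMIProfile:
    """Per-cell local MI scores of one gene pair and their standardization."""

    gene_x: int
    gene_y: int
    mi_per_cell: np.ndarray
    mean: float
    sd: float
    z_per_cell: np.ndarray


def pair_profile(
    gem: ExpressionMatrix,
    grid: GridSpec,
    gene_x: int,
    gene_y: int,
    box_size: float,
    neighborhood: str = "nearest",
    sd_mode: str = "population",
) -> PairMIProfile:
    """Local MI in every cell for one pair, with the cross-cell z-scores.

    ``sd_mode`` selects the population (divide by n, default) or sample
    (n - 1) standard deviation used in the standardization.  When the MI
    profile is constant (sd = 0) all z-scores are defined as 0, so the pair
    can never pass a non-negative edge threshold.
    """
    if gene_x == gene_y:
        raise ValueError("self-pairs are not defined")
    ctx_x = _GeneContext(gem.values[gene_x], grid.gene_edges(gene_x),
                         bool(grid.degenerate[gene_x]), box_size, neighborhood)
    ctx_y = _GeneContext(gem.values[gene_y], grid.gene_edges(gene_y),
                         bool(grid.degenerate[gene_y]), box_size, neighborhood)
    mi = _pair_mi_vector(ctx_x, ctx_y, gem.n_cells)
    mean, sd, z = _standardize(mi, sd_mode)
    return PairMIProfile(
        gene_x=gene_x, gene_y=gene_y, mi_per_cell=mi, mean=mean, sd=sd, z_per_cell=z
    )


def _pair_mi_vector(ctx_x: _GeneContext, ctx_y: _GeneContext, n: int) -> np.ndarray:
    """Vector of local MI over all cells for one gene pair.

    The joint entropy over each cell's neighborhood rectangle is a 2-D
    prefix-sum lookup on the per-bin entropy terms of the joint count grid.
    """
    if ctx_x.degenerate or ctx_y.degenerate:
        return np.zeros(n)
    gx = len(ctx_x.counts)
    gy = len(ctx_y.counts)
    joint_counts = np.bincount(
        ctx_x.bins * gy + ctx_y.bins, minlength=gx * gy
    ).reshape(gx, gy)
    h_terms = _entropy_terms(joint_counts, n)
    prefix = np.zeros((gx + 1, gy + 1))
    prefix[1:, 1:] = h_terms.cumsum(axis=0).cumsum(axis=1)
    fx, lx = ctx_x.first, ctx_x.last
    fy, ly = ctx_y.first, ctx_y.last
    h_joint = (
        prefix[lx + 1, ly + 1]
        - prefix[fx, ly + 1]
        - prefix[lx + 1, fy]
        + prefix[fx, fy]
    )
    return ctx_x.h_marginal + ctx_y.h_marginal - h_joint


def _standardize(mi: np.ndarray, sd_mode: str) -> tuple[float, float, np.ndarray]:
    mean = float(mi.mean())
    ddof = 0 if sd_mode == "population" else 1
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    sd = float(mi.std(ddof=ddof))
    if sd > 0:
        z = (mi - mean) / sd
    else:
        z = np.zeros_like(mi)
    return mean, sd, z


# ---------------------------------------------------------------------------
# network inference


@dataclass
class SingleCellNetwork:
    """Undirected per-cell edge set with z-scores; pairs stored (i, j), i < j."""

    cell_id: str
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def edge_count(self) -> int:
        return len(self.edges)


def infer_scns(
    gem: ExpressionMatrix,
    box_size: float = 0.2,
    z_threshold: float = 0.0,
    pair_restriction: list[tuple[str, str]] | None = None,
    neighborhood: str = "nearest",
    drop_zero_edges: bool = False,
    sd_mode: str = "population",
    threads: int = 1,
) -> list[SingleCellNetwork]:
    """Infer one single-cell network per cell.

    Evaluates every unordered pair of non-degenerate genes (all
    m(m-1)/2 pairs, or only those listed in ``pair_restriction``, a list of
    gene-id pairs; pairs that do not map onto the matrix are dropped).  An
    edge (X, Y) is present in cell c iff z_XY(c) > z_threshold (strict).
    ``drop_zero_edges`` additionally suppresses edges incident to a gene
    with zero expression in that cell.  Results are independent of
    ``threads``.
    """
    if not gem.is_log_transformed:
        raise ValidationError("infer_scns expects a log-transformed matrix")
    m, n = gem.values.shape
    _neighborhood_size(n, box_size)  # validates box_size
    grid = build_grid(gem)
    contexts = [
        _GeneContext(gem.values[g], grid.gene_edges(g), bool(grid.degenerate[g]),
                     box_size, neighborhood)
        for g in range(m)
    ]
    pairs = _resolve_pairs(gem, grid, pair_restriction)

    def eval_pair(pair: tuple[int, int]):
        i, j = pair
        mi = _pair_mi_vector(contexts[i], contexts[j], n)
        _, _, z = _standardize(mi, sd_mode)
        hit = z > z_threshold
        if drop_zero_edges:
            hit &= (gem.values[i] > 0) & (gem.values[j] > 0)
        cells = np.nonzero(hit)[0]
        return i, j, cells, z[cells]

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(eval_pair, pairs, chunksize=64))
    else:
        results = [eval_pair(p) for p in pairs]

    scns = [SingleCellNetwork(cell_id=cid) for cid in gem.cell_ids]
    for i, j, cells, zvals in results:
        for c, zv in zip(cells.tolist(), zvals.tolist()):
            scns[c].edges[(i, j)] = zv
    return scns


def _resolve_pairs(
    gem: ExpressionMatrix,
    grid: GridSpec,
    pair_restriction: list[tuple[str, str]] | None,
) -> list[tuple[int, int]]:
    m = gem.n_genes
    ok = ~grid.degenerate
    if pair_restriction is None:
        return [(i, j) for i in range(m) if ok[i] for j in range(i + 1, m) if ok[j]]
    index = {g: i for i, g in enumerate(gem.gene_ids)}
    pairs: set[tuple[int, int]] = set()
    dropped = 0
    for a, b in pair_restriction:
        ia, ib = index.get(str(a)), index.get(str(b))
        if ia is None or ib is None or ia == ib:
            dropped += 1
            continue
        if not (ok[ia] and ok[ib]):
            continue
        pairs.add((min(ia, ib), max(ia, ib)))
    if not pairs:
        raise ValidationError(
            f"no restriction pair maps onto the matrix ({dropped} unmatched)"
        )
    return sorted(pairs)


# ---------------------------------------------------------------------------
# degree matrix


@dataclass
class DegreeMatrix:
    """Per-cell gene degrees; same shape and id ordering as the source GEM."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    transform: str = "raw"


def degree_matrix(
    scns: list[SingleCellNetwork],
    gem: ExpressionMatrix,
    transform: str = "raw",
) -> DegreeMatrix:
    """Count each gene's edges per cell; optional log10(d + 1) transform."""
    m, n = gem.values.shape
    if len(scns) != n or any(s.cell_id != c for s, c in zip(scns, gem.cell_ids)):
        raise ValidationError("SCN list is not aligned with the matrix cells")
    if transform not in ("raw", "log10p1"):
        raise ValueError(f"unknown transform {transform!r}")
    dm = np.zeros((m, n))
    for c, scn in enumerate(scns):
        if not scn.edges:
            continue
        idx = np.fromiter(
            (g for pair in scn.edges for g in pair), dtype=np.int64,
            count=2 * len(scn.edges),
        )
        np.add.at(dm[:, c], idx, 1.0)
    if transform == "log10p1":
        dm = np.log10(dm + 1.0)
    return DegreeMatrix(values=dm, gene_ids=list(gem.gene_ids),
                        cell_ids=list(gem.cell_ids), transform=transform)


# ---------------------------------------------------------------------------
# output


def write_scns(
    scns: list[SingleCellNetwork],
    gem: ExpressionMatrix,
    path: str | os.PathLike,
    compress: bool | None = None,
) -> None:
    """Write all SCN edges as TSV (cell_id, gene_a, gene_b, z).

    gene_a < gene_b lexicographically per row; gzip when the path ends in
    .gz (or ``compress`` is set).
    """
    path = os.fspath(path)
    if compress is None:
        compress = path.endswith(".gz")
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        fh.write("cell_id\tgene_a\tgene_b\tz\n")
        for scn in scns:
            rows = []
            for (i, j), z in scn.edges.items():
                a, b = sorted((gem.gene_ids[i], gem.gene_ids[j]))
                rows.append((a, b, z))
            for a, b, z in sorted(rows):
                fh.write(f"{scn.cell_id}\t{a}\t{b}\t{z:.10g}\n")


def write_degree_matrix(dm: DegreeMatrix, path: str | os.PathLike) -> None:
    import pandas as pd

    pd.DataFrame(dm.values, index=dm.gene_ids, columns=dm.cell_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )
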