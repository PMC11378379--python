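"""Independent explicit-loop oracles used to validate the vectorized code.

Everything here is written with plain Python loops and scalar math from
first principles (grid counts, nearest-k neighborhoods, frequency
entropies, hypergeometric tail sums) so the oracles share no code path
with the package implementation.
"""

import math


def oracle_grid_count(n):
    return max(1, math.floor(math.sqrt(n) + 0.5))


def oracle_edges(values, gr):
    lo = min(values)
    hi = max(values)
    return [lo + (hi - lo) * i / gr for i in range(gr + 1)]


def oracle_bin(v, edges):
    # half-open bins, value on an internal edge belongs to the right bin,
    # last bin closed
    gr = len(edges) - 1
    for b in range(gr - 1):
        if edges[b] <= v < edges[b + 1]:
            return b
    return gr - 1


def oracle_neighborhood(values, cell, box_size):
    """Interval spanned by the k nearest cells (ties: lower value, then index)."""
    n = len(values)
    k = math.ceil(box_size * n)
    x = values[cell]
    order = sorted(range(n), key=lambda i: (abs(values[i] - x), values[i], i))
    chosen = [values[i] for i in order[:k]]
    return min(chosen), max(chosen)


def oracle_pair_mi(values_x, values_y, box_size, log=math.log):
    """Local MI of one gene pair in every cell, by direct counting."""
    n = len(values_x)
    gr = oracle_grid_count(n)
    ex = oracle_edges(values_x, gr)
    ey = oracle_edges(values_y, gr)
    bx = [oracle_bin(v, ex) for v in values_x]
    by = [oracle_bin(v, ey) for v in values_y]
    counts_x = [bx.count(b) for b in range(gr)]
    counts_y = [by.count(b) for b in range(gr)]
    joint = [[0] * gr for _ in range(gr)]
    for i in range(n):
        joint[bx[i]][by[i]] += 1

    def f(count):
        if count == 0:
            return 0.0
        p = count / n
        return -p * log(p)

    out = []
    for c in range(n):
        lo_x, hi_x = oracle_neighborhood(values_x, c, box_size)
        lo_y, hi_y = oracle_neighborhood(values_y, c, box_size)
        fx, lx = oracle_bin(lo_x, ex), oracle_bin(hi_x, ex)
        fy, ly = oracle_bin(lo_y, ey), oracle_bin(hi_y, ey)
        h_x = sum(f(counts_x[b]) for b in range(fx, lx + 1))
        h_y = sum(f(counts_y[b]) for b in range(fy, ly + 1))
        h_xy = sum(
            f(joint[a][b]) for a in range(fx, lx + 1) for b in range(fy, ly + 1)
        )
        out.append(h_x + h_y - h_xy)
    return out


def oracle_standardize(mi):
    n = len(mi)
    mu = sum(mi) / n
    var = sum((v - mu) ** 2 for v in mi) / n
    sd = math.sqrt(var)
    if sd == 0:
        return [0.0] * n
    return [(v - mu) / sd for v in mi]


def oracle_fisher_greater(a, b, c, d):
    """One-sided (greater) Fisher p by explicit hypergeometric summation."""
    r1, r2 = a + b, c + d
    col1 = a + c
    total = r1 + r2
    denom = math.comb(total, col1)
    p = 0.0
    for k in range(a, min(r1, col1) + 1):
        if col1 - k > r2:
            continue
        p += math.comb(r1, k) * math.comb(r2, col1 - k) / denom
    return p
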