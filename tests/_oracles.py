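"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths (and numpy where
practical) so agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction


# --------------------------------------------------------------------------
# Intensity-binned outlier statistic, pure-Python
# --------------------------------------------------------------------------

def _percentile_linear(values: list[float], q: float) -> float:
    """Linear interpolation between closest ranks, written from scratch."""
    ordered = sorted(values)
    if len(ordered) == 1:
        return ordered[0]
    h = (len(ordered) - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(ordered) - 1)
    return ordered[lo] + (h - lo) * (ordered[hi] - ordered[lo])


def brute_force_sig_b(
    log_ratios: dict[str, float],
    intensities: dict[str, float],
    bin_size: int,
) -> dict[str, tuple[float, str]]:
    """Percentile + erfc per intensity bin, straight from the definition."""
    order = sorted(log_ratios, key=lambda pid: (-intensities[pid], pid))
    n = len(order)
    if n < 2 * bin_size:
        bins = [(0, n)]
    else:
        bins = []
        start = 0
        while start < n:
            bins.append((start, min(start + bin_size, n)))
            start += bin_size
        if bins[-1][1] - bins[-1][0] < bin_size / 2:
            merged = (bins[-2][0], bins[-1][1])
            bins = bins[:-2] + [merged]
    out: dict[str, tuple[float, str]] = {}
    for start, stop in bins:
        values = [log_ratios[pid] for pid in order[start:stop]]
        r15 = _percentile_linear(values, 15.87)
        r50 = _percentile_linear(values, 50.0)
        r84 = _percentile_linear(values, 84.13)
        for pid in order[start:stop]:
            r = log_ratios[pid]
            if r >= r50:
                side, spread, dist = "above_median", r84 - r50, r - r50
            else:
                side, spread, dist = "below_median", r50 - r15, r50 - r
            if spread <= 0:
                if all(v == r50 for v in values):
                    out[pid] = (1.0, side)
                    continue
                raise ValueError("degenerate bin")
            z = dist / spread
            out[pid] = (0.5 * math.erfc(z / math.sqrt(2.0)), side)
    return out


# --------------------------------------------------------------------------
# Exact hypergeometric tail with rational arithmetic
# --------------------------------------------------------------------------

def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) summed term by term with exact Fractions."""
    total = Fraction(0)
    denominator = math.comb(N, n)
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          denominator)
    return float(min(total, Fraction(1)))


# --------------------------------------------------------------------------
# Exhaustive simple-path enumeration on adjacency dicts
# --------------------------------------------------------------------------

def exhaustive_bridge_paths(
    adjacency: dict[str, set[str]],
    bait: str,
    members: set[str],
    max_steps: int,
) -> list[tuple[str, ...]]:
    """All simple paths of <= max_steps edges from bait to a pathway member
    with no member as intermediate, by plain recursion over every branch."""
    found: list[tuple[str, ...]] = []

    def walk(path: tuple[str, ...]) -> None:
        if len(path) - 1 > max_steps:
            return
        last = path[-1]
        if len(path) > 1 and last in members:
            found.append(path)
            return
        if len(path) - 1 == max_steps:
            return
        for nxt in adjacency.get(last, ()):  # order irrelevant; sorted later
            if nxt not in path:
                walk(path + (nxt,))

    walk((bait,))
    return sorted(found, key=lambda p: (len(p), p))


# --------------------------------------------------------------------------
# Connected components by union-find
# --------------------------------------------------------------------------

def union_find_components(
    nodes: set[str], edges: list[tuple[str, str]]
) -> list[set[str]]:
    parent = {node: node for node in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for node in nodes:
        groups.setdefault(find(node), set()).add(node)
    return [group for group in groups.values() if len(group) >= 2]
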