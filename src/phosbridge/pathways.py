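"""Guilt-by-association pathway enrichment of bait prey sets.

Each bait's preys are tested for over-representation of annotation gene
sets (KEGG-like, supplied in GMT format) with an exact one-sided
hypergeometric test, and the bait is labeled with its best pathway when
that pathway's raw p-value falls strictly below alpha (default 0.005).
No multiple-testing correction is applied by default; a Benjamini-Hochberg
option is available.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (one pathway / annotation term)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"annotation set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one set in one prey list.

    k preys of n fall in the set of size K drawn from a background of N;
    p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """

    bait: str
    pathway: str
    k: int
    n: int
    K: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError("overlap k out of range")
        if not (0 < self.p <= 1):
            raise ValidationError("p must be in (0, 1]")


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n), in log-space.

    N: background size, K: annotated genes, n: draws (prey-set size),
    k: observed overlap. Accumulates log pmf terms with logsumexp so small
    tails keep full relative precision.
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValidationError(
            f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    denominator = _log_comb(N, n)
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - denominator
        for i in range(k, hi + 1)
        if n - i <= N - K
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


def read_gmt(path) -> list[AnnotationSet]:
    """Read annotation sets from GMT (name <tab> description <tab> members...)."""
    sets: list[AnnotationSet] = []
    with open(path) as handle:
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3 or not cols[0]:
                continue
            members = frozenset(m.strip().upper() for m in cols[2:] if m.strip())
            if members:
                sets.append(AnnotationSet(name=cols[0], members=members))
    return sets


def enrich_pathways(
    preys: Iterable[str],
    sets: Sequence[AnnotationSet],
    background: Iterable[str],
    bait: str = "",
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Test one bait's prey set against every annotation set.

    Preys outside the background are dropped (logged). One result per set
    with overlap k >= 1, sorted by ascending p then name; ties broken by
    name. With ``bh_correct`` the p field carries Benjamini-Hochberg
    adjusted values (off by default, matching the published procedure of a
    raw-p cutoff).
    """
    background = {b.upper() for b in background}
    if not background:
        raise ValidationError("background is empty")
    preys = {p.upper() for p in preys}
    dropped = preys - background
    if dropped:
        logger.info("bait %s: %d preys outside background dropped",
                    bait or "?", len(dropped))
    preys &= background
    n, N = len(preys), len(background)

    results = []
    for aset in sets:
        members = aset.members & background
        k = len(preys & members)
        if k < 1 or not members:
            continue
        results.append(
            EnrichmentResult(
                bait=bait, pathway=aset.name, k=k, n=n, K=len(members), N=N,
                p=hypergeometric_tail(k, n, len(members), N),
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway))
    if bh_correct and results:
        m = len(results)
        adjusted = []
        running_min = 1.0
        for rank in range(m, 0, -1):
            r = results[rank - 1]
            running_min = min(running_min, r.p * m / rank)
            adjusted.append(
                EnrichmentResult(bait=r.bait, pathway=r.pathway, k=r.k,
                                 n=r.n, K=r.K, N=r.N, p=min(1.0, running_min))
            )
        results = sorted(adjusted, key=lambda r: (r.p, r.pathway))
    return results


def assign_bait_label(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.005,
) -> Optional[str]:
    """The bait's pathway label: best result with p strictly below alpha,
    or None (a bait not significantly associated to any pathway)."""
    if not results:
        return None
    best = min(results, key=lambda r: (r.p, r.pathway))
    return best.pathway if best.p < alpha else None


def write_enrichment_results_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["bait", "pathway", "k", "n", "K", "N", "p"])
        for r in results:
            writer.writerow([r.bait, r.pathway, r.k, r.n, r.K, r.N,
                             f"{r.p:.6g}"])
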