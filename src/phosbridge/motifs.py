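"""Short-linear-motif scanners used as supporting evidence for bridges.

Two motif classes matter for the adapter hypotheses this package emits:
class-II polyproline SH3-binding stretches (GRB2-type specificity) and
atypical C-terminal PDZ-binding motifs of the form L-[DE]-Phi, with Phi a
hydrophobic residue.
"""

from __future__ import annotations

import re

from .types import ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: core class-II polyproline pattern; a match is extended rightwards over
#: any contiguous run of P/R/K, capturing the full proline-rich stretch
SH3_CORE_PATTERN = r"[RK]P.{2,3}P..P"

#: hydrophobic residues accepted at the C-terminal Phi position
HYDROPHOBIC = frozenset("AVLIMFWY")


def _check_sequence(sequence: str, min_length: int = 1) -> str:
    sequence = sequence.strip().upper()
    invalid = set(sequence) - AMINO_ACIDS
    if invalid:
        raise ValidationError(
            f"invalid amino-acid characters: {''.join(sorted(invalid))}"
        )
    if len(sequence) < min_length:
        raise ValidationError(f"sequence shorter than {min_length} residues")
    return sequence


def scan_sh3_motif(
    sequence: str,
    core_pattern: str = SH3_CORE_PATTERN,
) -> list[tuple[int, int, str]]:
    """Find class-II polyproline SH3-binding motifs.

    Each match of ``core_pattern`` is extended to the right across the
    maximal contiguous run of P/R/K residues, so the reported interval
    covers the whole proline-rich stretch (e.g. the full 11-mer
    RPPPPYPPPRP rather than only its core). When the core pattern finds
    nothing, a permissive fallback reports any 7-residue window that
    contains a PxxP and at least four prolines. Overlapping matches are all
    reported; coordinates are 1-based inclusive.
    """
    sequence = _check_sequence(sequence)
    pattern = re.compile(core_pattern)
    hits: list[tuple[int, int, str]] = []
    pos = 0
    while True:
        m = pattern.search(sequence, pos)
        if m is None:
            break
        end = m.end()
        while end < len(sequence) and sequence[end] in "PRK":
            end += 1
        hits.append((m.start() + 1, end, sequence[m.start():end]))
        pos = m.start() + 1
    if hits:
        return _dedup(hits)
    # fallback: proline-rich 7-mers carrying a PxxP
    pxxp = re.compile(r"P..P")
    for start in range(len(sequence) - 6):
        window = sequence[start:start + 7]
        if window.count("P") >= 4 and pxxp.search(window):
            hits.append((start + 1, start + 7, window))
    return _dedup(hits)


def _dedup(hits: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    return sorted(set(hits))


def scan_pdz_cterm_motif(sequence: str) -> bool:
    """True when the C-terminus matches the atypical PDZ-binding motif
    L-[DE]-Phi (Phi hydrophobic), i.e. the last three residues are
    leucine, then aspartate or glutamate, then a hydrophobic residue."""
    sequence = _check_sequence(sequence, min_length=3)
    l, de, phi = sequence[-3], sequence[-2], sequence[-1]
    return l == "L" and de in "DE" and phi in HYDROPHOBIC
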