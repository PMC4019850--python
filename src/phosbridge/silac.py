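"""SILAC AP-MS enrichment calling.

Turns a per-bait protein-group quantification table into enrichment calls:
log2 ratios are median-centered per experiment, an intensity-binned outlier
probability ("significance B") is computed per protein, and a prey is called
significantly enriched when it was quantified by at least two unique
peptides, its bait/control fold ratio strictly exceeds 1.9 and its outlier
probability is strictly below 0.1 on the upper side of its intensity bin.
Non-enriched proteins are retained as the equal-abundance contaminant
background. Enriched preys are further classified by their response to
TNF-alpha treatment using the same thresholds on the TNF/untreated channel.
"""

from __future__ import annotations

import csv
import logging
import math
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.special import erfc

from .types import (
    BinSpreadError,
    EmptyInputError,
    EnrichmentCall,
    EnrichmentThresholds,
    FormatError,
    ProteinGroup,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: semantic field -> default column name in protein-group tables
DEFAULT_DIALECT: dict[str, str] = {
    "protein_id": "protein_id",
    "unique_peptides": "unique_peptides",
    "intensity": "intensity",
    "ratio_bait_vs_ctrl": "ratio_bait_ctrl",
    "ratio_tnf_vs_ctrl": "ratio_tnf_ctrl",
    "ratio_tnf_vs_untreated": "ratio_tnf_untreated",
    "contaminant": "contaminant",
    "reverse": "reverse",
}

_MANDATORY_FIELDS = ("protein_id", "unique_peptides", "intensity",
                     "ratio_bait_vs_ctrl")
_FLAG_TRUE = {"+", "1", "true", "yes", "x"}

RATIO_CHANNELS = ("ratio_bait_vs_ctrl", "ratio_tnf_vs_ctrl",
                  "ratio_tnf_vs_untreated")


def read_protein_groups(
    path,
    dialect: Optional[Mapping[str, str]] = None,
) -> list[ProteinGroup]:
    """Read a tab-delimited protein-group table into :class:`ProteinGroup`s.

    ``dialect`` maps semantic field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names used in the file. Rows flagged in the contaminant or
    reverse(-decoy) columns are dropped; missing ratio cells become absent
    values, never zero.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for field in _MANDATORY_FIELDS:
            if cols[field] not in header:
                raise FormatError(
                    f"{path}: missing mandatory column {cols[field]!r} "
                    f"(for field {field!r})"
                )
        groups: list[ProteinGroup] = []
        n_flagged = 0
        for line_no, row in enumerate(reader, start=2):
            if _is_flagged(row, cols.get("contaminant")) or _is_flagged(
                row, cols.get("reverse")
            ):
                n_flagged += 1
                continue
            try:
                groups.append(
                    ProteinGroup(
                        protein_id=row[cols["protein_id"]].strip().upper(),
                        unique_peptides=int(row[cols["unique_peptides"]]),
                        intensity=float(row[cols["intensity"]]),
                        ratio_bait_vs_ctrl=_ratio(row, cols["ratio_bait_vs_ctrl"]),
                        ratio_tnf_vs_ctrl=_opt_ratio(
                            row, cols.get("ratio_tnf_vs_ctrl")
                        ),
                        ratio_tnf_vs_untreated=_opt_ratio(
                            row, cols.get("ratio_tnf_vs_untreated")
                        ),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    if n_flagged:
        logger.info("%s: dropped %d contaminant/reverse rows", path, n_flagged)
    seen: set[str] = set()
    for g in groups:
        if g.protein_id in seen:
            raise ValidationError(f"{path}: duplicate protein_id {g.protein_id}")
        seen.add(g.protein_id)
    return groups


def _is_flagged(row: Mapping[str, str], col: Optional[str]) -> bool:
    if not col or col not in row or row[col] is None:
        return False
    return row[col].strip().lower() in _FLAG_TRUE


def _ratio(row: Mapping[str, str], col: str) -> float:
    value = float(row[col])
    if not value > 0:
        raise ValidationError(f"ratio column {col!r} must be > 0, got {value}")
    return value


def _opt_ratio(row: Mapping[str, str], col: Optional[str]) -> Optional[float]:
    if not col or col not in row:
        return None
    cell = (row[col] or "").strip()
    if cell in ("", "NA", "NaN", "nan"):
        return None
    return _ratio(row, col)


def normalize_log_ratios(
    groups: Iterable[ProteinGroup],
    channel: str = "ratio_bait_vs_ctrl",
) -> dict[str, float]:
    """Median-center the log2 ratios of one SILAC channel.

    Returns ``protein_id -> log2(ratio) - median(log2 ratios)`` over the
    proteins where the channel is present; the median of the returned values
    is exactly 0.
    """
    if channel not in RATIO_CHANNELS:
        raise ValueError(f"unknown ratio channel {channel!r}")
    raw = {
        g.protein_id: math.log2(getattr(g, channel))
        for g in groups
        if getattr(g, channel) is not None
    }
    if not raw:
        raise EmptyInputError(f"no protein has channel {channel!r} quantified")
    center = float(np.median(list(raw.values())))
    return {pid: value - center for pid, value in raw.items()}


# --------------------------------------------------------------------------
# Significance B
# --------------------------------------------------------------------------

def _percentile(sorted_values: np.ndarray, q: float) -> float:
    # linear interpolation between closest ranks (numpy default definition)
    return float(np.percentile(sorted_values, q))


def _bin_boundaries(n: int, bin_size: int) -> list[tuple[int, int]]:
    """Consecutive [start, stop) rank bins; a short tail (< bin_size/2) is
    merged into its neighbor; fewer than 2*bin_size proteins -> one bin."""
    if n < 2 * bin_size:
        return [(0, n)]
    edges = list(range(0, n, bin_size))
    bins = [(s, min(s + bin_size, n)) for s in edges]
    last_start, last_stop = bins[-1]
    if last_stop - last_start < bin_size / 2:
        prev_start, _ = bins[-2]
        bins = bins[:-2] + [(prev_start, last_stop)]
    return bins


def significance_b(
    log_ratios: Mapping[str, float],
    intensities: Mapping[str, float],
    bin_size: int = 300,
) -> dict[str, tuple[float, str]]:
    """Intensity-binned outlier probability of each protein's log ratio.

    Proteins are ranked by decreasing intensity (ties broken by protein_id)
    and split into consecutive bins of ``bin_size``. Within each bin, with
    r50, r84.13 and r15.87 the log-ratio percentiles, the standardized
    distance is ``z = (r - r50)/(r84.13 - r50)`` above the median and
    ``z = (r50 - r)/(r50 - r15.87)`` below, and
    ``sig_b = 0.5 * erfc(z / sqrt(2))`` — the Gaussian upper-tail
    probability of z. Returns ``protein_id -> (sig_b, side)``.
    """
    if set(log_ratios) != set(intensities):
        raise ValidationError("log_ratios and intensities must share keys")
    if not log_ratios:
        raise EmptyInputError("no proteins to score")

    order = sorted(log_ratios, key=lambda pid: (-intensities[pid], pid))
    ratios = np.array([log_ratios[pid] for pid in order], dtype=float)

    out: dict[str, tuple[float, str]] = {}
    for start, stop in _bin_boundaries(len(order), bin_size):
        values = ratios[start:stop]
        r15, r50, r84 = (
            _percentile(values, 15.87),
            _percentile(values, 50.0),
            _percentile(values, 84.13),
        )
        upper_spread = r84 - r50
        lower_spread = r50 - r15
        constant_bin = bool(np.all(values == r50))
        for idx in range(start, stop):
            r = ratios[idx]
            if r >= r50:
                side = "above_median"
                spread = upper_spread
                distance = r - r50
            else:
                side = "below_median"
                spread = lower_spread
                distance = r50 - r
            if spread <= 0:
                if constant_bin:
                    out[order[idx]] = (1.0, side)
                    continue
                raise BinSpreadError(
                    f"bin [{start}:{stop}) has zero "
                    f"{'upper' if side == 'above_median' else 'lower'} spread "
                    "with non-constant ratios"
                )
            z = distance / spread
            out[order[idx]] = (float(0.5 * erfc(z / math.sqrt(2.0))), side)
    return out


# --------------------------------------------------------------------------
# Thresholding and TNF regulation
# --------------------------------------------------------------------------

def apply_enrichment_filter(
    groups: Iterable[ProteinGroup],
    sig: Mapping[str, tuple[float, str]],
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    log_ratios: Optional[Mapping[str, float]] = None,
) -> list[EnrichmentCall]:
    """Call each protein enriched or background.

    Enriched requires, all strictly: >= ``min_unique_peptides`` unique
    peptides, bait/control ratio > ``min_ratio`` (natural fold scale, as
    published), sig_b < ``max_sig_b`` and the protein on the upper side of
    its bin. Everything else is retained with ``enriched=False`` — the
    equal-abundance background. ``log_ratios`` (normalized) are recorded on
    the calls; raw log2 ratios are used if not given.
    """
    calls: list[EnrichmentCall] = []
    for g in groups:
        if g.protein_id not in sig:
            raise ValidationError(
                f"protein {g.protein_id} missing from significance map"
            )
        sig_b, side = sig[g.protein_id]
        if log_ratios is not None and g.protein_id in log_ratios:
            log_ratio = log_ratios[g.protein_id]
        else:
            log_ratio = math.log2(g.ratio_bait_vs_ctrl)
        enriched = (
            g.unique_peptides >= thresholds.min_unique_peptides
            and g.ratio_bait_vs_ctrl > thresholds.min_ratio
            and sig_b < thresholds.max_sig_b
            and side == "above_median"
        )
        calls.append(
            EnrichmentCall(
                protein_id=g.protein_id,
                log_ratio=log_ratio,
                sig_b=sig_b,
                side=side,
                enriched=enriched,
            )
        )
    return calls


def classify_tnf_regulation(
    call: EnrichmentCall,
    group: ProteinGroup,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    tnf_sig_b: Optional[float] = None,
) -> str:
    """Classify an enriched prey's response to TNF-alpha treatment.

    Reuses the enrichment thresholds on the TNF/untreated channel:
    ``tnf_positive`` when the ratio exceeds ``min_ratio`` and its own
    significance B (``tnf_sig_b``, computed on that channel) is below
    ``max_sig_b``; ``tnf_negative`` symmetrically below ``1/min_ratio``;
    otherwise (including absent data) ``tnf_independent``.
    """
    if not call.enriched:
        raise ValidationError("TNF regulation applies to enriched calls only")
    ratio = group.ratio_tnf_vs_untreated
    if ratio is None or tnf_sig_b is None:
        return "tnf_independent"
    if ratio > thresholds.min_ratio and tnf_sig_b < thresholds.max_sig_b:
        return "tnf_positive"
    if ratio < 1.0 / thresholds.min_ratio and tnf_sig_b < thresholds.max_sig_b:
        return "tnf_negative"
    return "tnf_independent"


def call_enrichment(
    groups: list[ProteinGroup],
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> list[EnrichmentCall]:
    """Full per-bait enrichment analysis: normalize, score, filter, classify.

    Significance B on the TNF/untreated channel is computed only when at
    least one protein has that channel; proteins without it default to
    ``tnf_independent``.
    """
    log_ratios = normalize_log_ratios(groups, "ratio_bait_vs_ctrl")
    intensities = {g.protein_id: g.intensity for g in groups
                   if g.protein_id in log_ratios}
    sig = significance_b(log_ratios, intensities, thresholds.bin_size)
    calls = apply_enrichment_filter(
        (g for g in groups if g.protein_id in log_ratios),
        sig, thresholds, log_ratios,
    )

    tnf_sig: dict[str, tuple[float, str]] = {}
    try:
        tnf_log = normalize_log_ratios(groups, "ratio_tnf_vs_untreated")
    except EmptyInputError:
        tnf_log = {}
    if tnf_log:
        tnf_int = {g.protein_id: g.intensity for g in groups
                   if g.protein_id in tnf_log}
        tnf_sig = significance_b(tnf_log, tnf_int, thresholds.bin_size)

    by_id = {g.protein_id: g for g in groups}
    out: list[EnrichmentCall] = []
    for call in calls:
        if not call.enriched:
            out.append(call)
            continue
        sig_b = tnf_sig.get(call.protein_id, (None,))[0]
        regulation = classify_tnf_regulation(
            call, by_id[call.protein_id], thresholds, sig_b
        )
        out.append(
            EnrichmentCall(
                protein_id=call.protein_id,
                log_ratio=call.log_ratio,
                sig_b=call.sig_b,
                side=call.side,
                enriched=True,
                regulation=regulation,
            )
        )
    return out


def write_enrichment_tsv(calls: list[EnrichmentCall], path) -> None:
    """Write the per-bait enrichment table (one row per quantified protein)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "log_ratio", "sig_b", "side",
                         "enriched", "regulation"])
        for c in sorted(calls, key=lambda c: c.protein_id):
            writer.writerow([
                c.protein_id, f"{c.log_ratio:.6g}", f"{c.sig_b:.6g}",
                c.side, int(c.enriched), c.regulation or "",
            ])
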