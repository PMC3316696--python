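"""Sequence quality control for the barcode matrix.

Three filters guard against short reads and pseudogene (NUMT) contamination:

* a minimum-length rule — a record must cover at least 90% of the standard
  barcoding region (600 of 664 bp by default);
* an internal stop-codon screen under the vertebrate mitochondrial code —
  genuine mitochondrial COI is stop-free in frame, so an in-frame stop is the
  classic NUMT signature;
* a divergence-outlier screen — a record whose minimum distance to every
  other record exceeds a cutoff is of doubtful origin (contamination, NUMT,
  misalignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .seqio import Alignment

__all__ = [
    "QCReport",
    "length_filter",
    "detect_frame",
    "stop_codon_filter",
    "divergence_outlier_filter",
    "combine_reports",
    "stop_codons",
]

TOO_SHORT = "too_short"
INTERNAL_STOP = "internal_stop"
DIVERGENCE_OUTLIER = "divergence_outlier"

DEFAULT_MIN_LENGTH = 600
DEFAULT_OUTLIER_CUTOFF = 0.35  # K2p units; "suspiciously high" stand-in


@dataclass
class QCReport:
    """Per-record QC outcome. ``passed`` holds iff ``reasons`` is empty."""

    id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def stop_codons(code_table: int) -> frozenset[str]:
    """Stop codons of an NCBI translation table (2 = vertebrate mitochondrial)."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code_table]
    except KeyError:
        raise ValueError(f"unknown genetic code table: {code_table}") from None
    return frozenset(table.stop_codons)


def length_filter(alignment: Alignment, min_length: int = DEFAULT_MIN_LENGTH) -> list[QCReport]:
    """Flag records with fewer than ``min_length`` non-gap characters."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [
        QCReport(r.id, [TOO_SHORT] if r.ungapped_length < min_length else [])
        for r in alignment.records
    ]


def _codons(seq: str, offset: int):
    """Complete codons from ``offset``, with their start column (0-based)."""
    for start in range(offset, len(seq) - 2, 3):
        yield start, seq[start : start + 3]


def _count_stops(seq: str, offset: int, stops: frozenset[str]) -> int:
    return sum(1 for _, codon in _codons(seq.upper(), offset) if codon in stops)


def detect_frame(alignment: Alignment) -> int:
    """Reading-frame offset minimising total in-frame stop codons.

    Returns the offset in {0, 1, 2}; ties break to the smallest offset.
    """
    stops = stop_codons(alignment.code_table)
    totals = [
        sum(_count_stops(r.seq, offset, stops) for r in alignment.records)
        for offset in (0, 1, 2)
    ]
    return int(np.argmin(totals))


def stop_codon_filter(alignment: Alignment) -> list[QCReport]:
    """Flag records with an internal in-frame stop codon.

    Codons containing gaps or ambiguity codes cannot be called as stops and
    are skipped; the final complete codon of each record is exempt (a terminal
    stop is legitimate).
    """
    stops = stop_codons(alignment.code_table)
    offset = alignment.frame_offset
    reports = []
    for r in alignment.records:
        codons = list(_codons(r.seq.upper(), offset))
        internal = codons[:-1]  # terminal codon exempt
        hit = any(codon in stops for _, codon in internal)
        reports.append(QCReport(r.id, [INTERNAL_STOP] if hit else []))
    return reports


def divergence_outlier_filter(
    alignment: Alignment,
    distance_matrix,
    cutoff: float = DEFAULT_OUTLIER_CUTOFF,
) -> list[QCReport]:
    """Flag records whose minimum distance to every other record exceeds ``cutoff``.

    Undefined (saturated) distances count as exceeding any finite cutoff: a
    record that is saturated against everything is flagged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(alignment) < 2:
        raise ValueError("outlier screen needs at least 2 records")
    d = distance_matrix.as_array()
    index = {label: i for i, label in enumerate(distance_matrix.labels)}
    reports = []
    for r in alignment.records:
        i = index[r.id]
        others = np.delete(d[i], i)
        defined = others[~np.isnan(others)]
        is_outlier = defined.size == 0 or float(defined.min()) > cutoff
        reports.append(QCReport(r.id, [DIVERGENCE_OUTLIER] if is_outlier else []))
    return reports


def combine_reports(*report_lists: list[QCReport]) -> list[QCReport]:
    """Merge per-filter reports into one report per record (reason union)."""
    merged: dict[str, QCReport] = {}
    order: list[str] = []
    for reports in report_lists:
        for rep in reports:
            if rep.id not in merged:
                merged[rep.id] = QCReport(rep.id, [])
                order.append(rep.id)
            for reason in rep.reasons:
                if reason not in merged[rep.id].reasons:
                    merged[rep.id].reasons.append(reason)
    return [merged[i] for i in order]
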