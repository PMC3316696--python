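"""Sequence records, alignments, and FASTA/TSV input-output.

The pipeline operates on a pre-aligned COI barcode matrix (the ~650-bp 5'
Folmer region) together with a per-record taxonomy table. Records carry a
three-level taxonomy (species, genus, family) and an identification status:
``nominal`` for well-identified species, ``candidate`` for specimens labelled
with open nomenclature ("sp.", "aff."), and ``unidentified`` for specimens
that could not be assigned to any nominal species.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Status",
    "SequenceRecord",
    "Alignment",
    "read_fasta_with_metadata",
    "write_fasta_with_metadata",
    "infer_status",
]

# Default open-nomenclature markers flagging a record as a candidate species.
DEFAULT_CANDIDATE_MARKERS = ("sp.", "aff.")

METADATA_COLUMNS = ["id", "species", "genus", "family", "status", "voucher", "locality"]

# base -> integer code used by the vectorised distance kernels; anything not
# A/C/G/T (gaps, ambiguity codes) maps to -1 and is excluded pairwise.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class Status(str, enum.Enum):
    NOMINAL = "nominal"
    CANDIDATE = "candidate"
    UNIDENTIFIED = "unidentified"


def infer_status(species: str, markers: tuple[str, ...] = DEFAULT_CANDIDATE_MARKERS) -> Status:
    """Infer identification status from the species label.

    A label containing an open-nomenclature token such as ``sp.`` or ``aff.``
    (case-insensitive, matched as a whole token) marks a candidate species.
    """
    tokens = re.split(r"\s+", species.strip().lower())
    for marker in markers:
        if marker.lower() in tokens:
            return Status.CANDIDATE
    return Status.NOMINAL


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    species: str
    genus: str
    family: str
    status: Status = Status.NOMINAL
    voucher: str | None = None
    locality: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not self.family or not self.genus:
            raise ValueError(f"record {self.id!r}: family and genus are required")

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap nucleotide characters (counts ambiguity codes)."""
        return sum(1 for c in self.seq if c not in "-.")


class Alignment:
    """An aligned set of records sharing a coordinate system.

    Parameters
    ----------
    records:
        Equal-length :class:`SequenceRecord` objects.
    frame_offset:
        0-based column index where the first complete codon starts.
    code_table:
        NCBI genetic-code table id (default 2, vertebrate mitochondrial).
    """

    MAX_COLUMNS = 664  # standard COI barcode region

    def __init__(self, records: list[SequenceRecord], frame_offset: int = 0, code_table: int = 2):
        if not records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [r.id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate record id(s): {sorted(dupes)}")
        if frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        self.records = list(records)
        self.frame_offset = frame_offset
        self.code_table = code_table
        self._encoded: np.ndarray | None = None

    # -- basic container behaviour -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def encoded(self) -> np.ndarray:
        """(n_records, n_columns) int8 matrix; A/C/G/T -> 0..3, other -> -1."""
        if self._encoded is None:
            mat = np.full((len(self.records), self.n_columns), -1, dtype=np.int8)
            for i, r in enumerate(self.records):
                for j, c in enumerate(r.seq.upper()):
                    mat[i, j] = _BASE_CODE.get(c, -1)
            self._encoded = mat
        return self._encoded

    def subset(self, ids: list[str]) -> "Alignment":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        missing = keep - {r.id for r in recs}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(recs, frame_offset=self.frame_offset, code_table=self.code_table)

    def truncate(self, length: int) -> "Alignment":
        """Keep alignment columns 1..length (frame bookkeeping preserved)."""
        if not 1 <= length <= self.n_columns:
            raise ValueError(f"length {length} outside 1..{self.n_columns}")
        recs = [replace(r, seq=r.seq[:length]) for r in self.records]
        return Alignment(recs, frame_offset=self.frame_offset, code_table=self.code_table)

    def taxonomy(self) -> dict[str, tuple[str, str, str]]:
        """leaf id -> (species, genus, family)."""
        return {r.id: (r.species, r.genus, r.family) for r in self.records}


def read_fasta_with_metadata(
    fasta_path: str | Path,
    tsv_path: str | Path,
    candidate_markers: tuple[str, ...] = DEFAULT_CANDIDATE_MARKERS,
    code_table: int = 2,
) -> Alignment:
    """Read an aligned FASTA plus its tab-separated metadata table.

    The TSV must carry columns ``id``, ``species``, ``genus``, ``family``;
    ``status``, ``voucher`` and ``locality`` are optional. A missing status
    column (or empty cell) is inferred from open-nomenclature markers in the
    species label. Every FASTA entry must have a metadata row.
    """
    meta = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "species", "genus", "family"}
    if missing := required - set(meta.columns):
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata id(s): {dupes}")
    rows = meta.set_index("id")

    records = []
    seen = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id: {entry.id}")
        seen.add(entry.id)
        if entry.id not in rows.index:
            raise ValueError(f"FASTA id {entry.id!r} has no metadata row")
        row = rows.loc[entry.id]
        status_str = str(row["status"]).strip() if "status" in rows.columns else ""
        if status_str:
            try:
                status = Status(status_str.lower())
            except ValueError:
                raise ValueError(f"record {entry.id!r}: unknown status {status_str!r}") from None
        else:
            status = infer_status(row["species"], candidate_markers)
        records.append(
            SequenceRecord(
                id=entry.id,
                seq=str(entry.seq).upper(),
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                status=status,
                voucher=(row.get("voucher") or None) if "voucher" in rows.columns else None,
                locality=(row.get("locality") or None) if "locality" in rows.columns else None,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    return Alignment(records, code_table=code_table)


def write_fasta_with_metadata(alignment: Alignment, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write the alignment back to FASTA + metadata TSV (round-trip safe)."""
    entries = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in alignment.records
    ]
    SeqIO.write(entries, str(fasta_path), "fasta")
    rows = [
        {
            "id": r.id,
            "species": r.species,
            "genus": r.genus,
            "family": r.family,
            "status": r.status.value,
            "voucher": r.voucher or "",
            "locality": r.locality or "",
        }
        for r in alignment.records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
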