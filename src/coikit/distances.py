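"""Pairwise p and Kimura 2-parameter (K2p) distances.

The K2p model distinguishes transitions (A<->G, C<->T; proportion P among
comparable sites) from transversions (proportion Q) and corrects observed
divergence for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are excluded
pair by pair (pairwise deletion). When a log argument is non-positive the
distance is saturated and reported as undefined (NaN) rather than silently
substituted — saturation must stay visible downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment, _BASE_CODE

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "site_counts",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "saturation_table",
    "pairwise_distance_array",
]


@dataclass(frozen=True)
class SiteCounts:
    """Comparable-site and mismatch counts for one sequence pair."""

    comparable: int
    transitions: int
    transversions: int

    def __post_init__(self):
        if min(self.comparable, self.transitions, self.transversions) < 0:
            raise ValueError("counts must be non-negative")
        if self.transitions + self.transversions > self.comparable:
            raise ValueError("mismatches exceed comparable sites")

    @property
    def P(self) -> float:
        return self.transitions / self.comparable

    @property
    def Q(self) -> float:
        return self.transversions / self.comparable


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


def site_counts(seq_a: str, seq_b: str) -> SiteCounts:
    """Count comparable sites, transitions and transversions under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}")
    a, b = _encode(seq_a), _encode(seq_b)
    both = (a >= 0) & (b >= 0)
    mismatch = both & (a != b)
    # purines are A (0) and G (2): a mismatch within a chemical class is a transition
    ts = mismatch & ((a % 2) == (b % 2))
    return SiteCounts(
        comparable=int(both.sum()),
        transitions=int(ts.sum()),
        transversions=int((mismatch & ~ts).sum()),
    )


def p_distance(counts: SiteCounts) -> float:
    """Raw proportion of differing sites among comparable sites."""
    if counts.comparable == 0:
        raise ValueError("no comparable sites (no overlap)")
    return (counts.transitions + counts.transversions) / counts.comparable


def k2p_distance(counts: SiteCounts) -> float:
    """Kimura 2-parameter distance; NaN where the correction is undefined."""
    if counts.comparable == 0:
        raise ValueError("no comparable sites (no overlap)")
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_distance_array(encoded: np.ndarray, model: str = "k2p") -> np.ndarray:
    """All-pairs distance matrix from an encoded (n, L) int8 matrix.

    Vectorised row-sweep kernel shared by the one-shot matrix computation and
    the bootstrap loop. Undefined K2p entries and zero-overlap pairs are NaN.
    """
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown model: {model}")
    n = encoded.shape[0]
    valid = encoded >= 0
    parity = encoded % 2  # purine/pyrimidine class; junk where invalid, masked below
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        both = valid[i] & valid[rest]
        comparable = both.sum(axis=1).astype(np.float64)
        mismatch = (encoded[i] != encoded[rest]) & both
        ts = (mismatch & (parity[i] == parity[rest])).sum(axis=1)
        tv = mismatch.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / comparable
            Q = tv / comparable
            if model == "p":
                row = P + Q
            else:
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                row = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                    - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                    np.nan,
                )
        row = np.where(comparable > 0, row, np.nan)
        d[i, rest] = row
        d[rest, i] = row
    return d


class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined entries as NaN."""

    def __init__(self, labels: list[str], array: np.ndarray, model: str):
        array = np.asarray(array, dtype=np.float64)
        if array.shape != (len(labels), len(labels)):
            raise ValueError("array shape does not match labels")
        self.labels = list(labels)
        self._array = array
        self.model = model

    def as_array(self) -> np.ndarray:
        return self._array

    @property
    def n_undefined(self) -> int:
        """Number of undefined unordered pairs."""
        return int(np.isnan(self._array[np.triu_indices(len(self.labels), k=1)]).sum())

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self._array[i, j])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self._array[np.ix_(idx, idx)], self.model)

    # -- writers -----------------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                rows.append(
                    {
                        "id_a": a,
                        "id_b": self.labels[j],
                        "model": self.model,
                        "distance": self._array[i, j],
                    }
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "model", "distance"])

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    def write_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self._array, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def read_square_tsv(cls, path: str | Path, model: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), model)


def distance_matrix(alignment: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix over the alignment (pairwise deletion)."""
    if len(alignment) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    arr = pairwise_distance_array(alignment.encoded(), model=model)
    dm = DistanceMatrix(alignment.ids, arr, model)
    if dm.n_undefined:
        warnings.warn(
            f"{dm.n_undefined} undefined {model} distance(s) (saturated or no overlap)",
            stacklevel=2,
        )
    return dm


def saturation_table(alignment: Alignment) -> pd.DataFrame:
    """One row per unordered pair with defined K2p: (pair ids, k2p, P, Q).

    The P-vs-distance and Q-vs-distance scatter this feeds visualises
    substitution saturation: transitions plateau at high divergence while
    transversions keep accumulating.
    """
    if len(alignment) < 2:
        raise ValueError("saturation table needs at least 2 records")
    rows = []
    records = alignment.records
    for i in range(len(records) - 1):
        for j in range(i + 1, len(records)):
            counts = site_counts(records[i].seq, records[j].seq)
            if counts.comparable == 0:
                continue
            d = k2p_distance(counts)
            if math.isnan(d):
                continue
            rows.append(
                {
                    "id_a": records[i].id,
                    "id_b": records[j].id,
                    "k2p": d,
                    "P": counts.P,
                    "Q": counts.Q,
                }
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "k2p", "P", "Q"])
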