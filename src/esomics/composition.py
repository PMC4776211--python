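"""Tetranucleotide frequency (TNF) vectors for contig binning.

A genome's 4-mer composition is a strand-agnostic compositional signature
that separates genomes in a mixed community. Counts are accumulated over
every 4-bp window, windows containing an ambiguous base (N) are skipped,
and each tetramer is collapsed onto the lexicographic minimum of itself and
its reverse complement, giving 136 canonical tetramers (16 palindromes plus
120 collapsed pairs). Rows are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _enumerate_canonical() -> tuple[list[str], np.ndarray]:
    """All 256 tetramers collapsed by reverse complement.

    Returns the sorted canonical tetramer list (length 136) and a length-256
    array mapping every tetramer code to its canonical column index.
    """
    all_tets = ["".join(t) for t in __import__("itertools").product(_BASES, repeat=4)]
    canon = sorted({min(t, reverse_complement(t)) for t in all_tets})
    col = {t: i for i, t in enumerate(canon)}
    mapping = np.empty(256, dtype=np.int64)
    for code, t in enumerate(all_tets):
        mapping[code] = col[min(t, reverse_complement(t))]
    return canon, mapping


CANONICAL_TETRAMERS, _CANON_MAP = _enumerate_canonical()
N_CANONICAL = len(CANONICAL_TETRAMERS)  # 136


class EmptyMatrixError(ValueError):
    """Raised when no contig passes the minimum-length filter."""


@dataclass
class TnfMatrix:
    """Per-contig canonical tetranucleotide frequency vectors.

    Attributes
    ----------
    contig_ids : list of str
        Row labels, in input order.
    vectors : ndarray of shape (n_contigs, 136)
        Row-normalized canonical 4-mer frequencies. A row is all-zero only
        if the contig had no countable (N-free) window.
    lengths : ndarray of int
        Contig lengths in bp.
    """

    contig_ids: list[str]
    vectors: np.ndarray
    lengths: np.ndarray

    def __len__(self) -> int:
        return len(self.contig_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=self.contig_ids, columns=CANONICAL_TETRAMERS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lengths: Sequence[int] | None = None) -> "TnfMatrix":
        if list(df.columns) != CANONICAL_TETRAMERS:
            raise ValueError("expected the 136 canonical tetramer columns")
        n = len(df)
        lens = np.asarray(lengths if lengths is not None else np.zeros(n), dtype=np.int64)
        return cls(list(df.index), df.to_numpy(dtype=float), lens)


def count_tetramers(seq: str) -> np.ndarray:
    """Raw canonical tetramer counts for one sequence (N windows skipped)."""
    s = seq.upper()
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    b = lut[codes]
    if len(b) < 4:
        return np.zeros(N_CANONICAL, dtype=np.int64)
    w = b[:-3] * 64 + b[1:-2] * 16 + b[2:-1] * 4 + b[3:]
    valid = (b[:-3] >= 0) & (b[1:-2] >= 0) & (b[2:-1] >= 0) & (b[3:] >= 0)
    counts256 = np.bincount(w[valid], minlength=256)
    out = np.zeros(N_CANONICAL, dtype=np.int64)
    np.add.at(out, _CANON_MAP, counts256)
    return out


def tnf(
    contigs: Mapping[str, str] | Iterable[tuple[str, str]],
    min_len: int = 3000,
) -> TnfMatrix:
    """Compute the TNF matrix over contigs of length >= ``min_len``.

    Parameters
    ----------
    contigs : mapping or iterable of (contig_id, sequence)
    min_len : int
        Contigs shorter than this are excluded. The training set for the
        self-organizing map conventionally uses 3000 bp; 1000-2999 bp
        contigs are computed separately for projection.
    """
    items = contigs.items() if isinstance(contigs, Mapping) else contigs
    ids: list[str] = []
    rows: list[np.ndarray] = []
    lens: list[int] = []
    for cid, seq in items:
        if len(seq) < min_len:
            continue
        counts = count_tetramers(seq)
        total = counts.sum()
        vec = counts / total if total > 0 else counts.astype(float)
        ids.append(cid)
        rows.append(vec)
        lens.append(len(seq))
    if not ids:
        raise EmptyMatrixError(f"no contig of length >= {min_len}")
    return TnfMatrix(ids, np.vstack(rows), np.asarray(lens, dtype=np.int64))
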