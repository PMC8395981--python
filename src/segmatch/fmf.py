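"""Normalized frequency of matching fragments (FMF).

Raw pair match counts depend quadratically on section lengths.  The raw
count for sections A and B is first turned into a density per
(10 kb x 10 kb) of sequence, then rescaled by a single global constant so
that the mean over unordered off-diagonal section pairs equals 1.  Rank
correlations downstream are unaffected by the global constant; the density
step corrects for unequal section lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import PairMatchTable
from .sections import SectionSet

DEFAULT_CHUNK = 10_000


@dataclass
class FmfMatrix:
    """Symmetric normalized matching-fragment frequencies (diagonal 0)."""

    sections: SectionSet
    L: int
    values: np.ndarray  # (N, N) float
    normalization_constant: float
    chunk_size: int = DEFAULT_CHUNK
    all_zero: bool = False

    @property
    def labels(self) -> list[str]:
        return self.sections.labels


def normalize_fmf(
    raw: PairMatchTable, ss: SectionSet | None = None, chunk_size: int = DEFAULT_CHUNK
) -> FmfMatrix:
    """Normalize a raw match-count table to mean-1 FMF values.

    ``d(A,B) = raw(A,B) / (w_A * w_B)`` with ``w_X = len(X)/chunk_size``;
    FMF is ``d`` divided by its mean over unordered off-diagonal pairs.
    An all-zero table yields all-zero FMF with the ``all_zero`` flag set.
    """
    ss = ss if ss is not None else raw.sections
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    lengths = np.array([s.length for s in ss], dtype=float)
    if (lengths == 0).any():
        raise ValueError("zero-length section")
    w = lengths / chunk_size
    dens = raw.counts / np.outer(w, w)
    np.fill_diagonal(dens, 0.0)
    iu = np.triu_indices(len(ss), k=1)
    mean_d = dens[iu].mean()
    if mean_d == 0.0:
        return FmfMatrix(
            sections=ss,
            L=raw.L,
            values=np.zeros_like(dens),
            normalization_constant=0.0,
            chunk_size=chunk_size,
            all_zero=True,
        )
    return FmfMatrix(
        sections=ss,
        L=raw.L,
        values=dens / mean_d,
        normalization_constant=1.0 / mean_d,
        chunk_size=chunk_size,
    )


def fmf_tot(m: FmfMatrix) -> np.ndarray:
    """Per-section total FMF: row sums excluding the diagonal."""
    v = m.values.copy()
    np.fill_diagonal(v, 0.0)
    return v.sum(axis=1)


def write_fmf_tsv(m: FmfMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="section")


def read_fmf_tsv(path: str | Path, sections: SectionSet, L: int) -> FmfMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != sections.labels or list(df.columns) != sections.labels:
        raise ValueError("FMF matrix labels do not match the section set")
    vals = df.to_numpy(dtype=float)
    return FmfMatrix(
        sections=sections,
        L=L,
        values=vals,
        normalization_constant=float("nan"),
        all_zero=not vals.any(),
    )
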