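"""Frequency-of-ectopic-contacts (FEC) matrices and chromatin features.

FEC matrices are measured externally (microscopy of squashed polytene
preparations) and enter the analysis as symmetric labeled integer TSV
matrices, one per fly strain.  This module also computes per-section
contact totals, the binarized presence/absence matrix, and the chromatin
feature index summarizing binary features that predispose a section to
ectopic pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sections import SectionSet

log = logging.getLogger(__name__)


@dataclass
class FecMatrix:
    """Symmetric non-negative integer contact counts per section pair."""

    labels: list[str]
    counts: np.ndarray  # (N, N) int64
    strain: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative FEC counts")
        if not (self.counts == self.counts.T).all():
            raise ValueError("FEC matrix not symmetric")


def read_fec(
    path: str | Path,
    sections: SectionSet | None = None,
    strain: str = "",
    subset: bool = False,
) -> FecMatrix:
    """Read a labeled symmetric FEC matrix from TSV.

    Asymmetric input is an error (offending cells listed).  When a section
    set is given, labels must match it exactly; with ``subset=True`` the
    intersection is taken instead (missing labels are otherwise an error).
    Diagonal entries are forced to 0 with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    labels = [str(x) for x in df.index]
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: non-integer cell in FEC matrix: {e}") from None
    if not np.array_equal(df.to_numpy(dtype=float), counts):
        raise ValueError(f"{path}: non-integer cell in FEC matrix")
    asym = np.argwhere(counts != counts.T)
    if len(asym):
        cells = ", ".join(
            f"({labels[i]},{labels[j]})={counts[i, j]} vs {counts[j, i]}"
            for i, j in asym[:10]
            if i < j
        )
        raise ValueError(f"{path}: asymmetric FEC matrix at {cells}")
    if np.diag(counts).any():
        log.warning("%s: nonzero diagonal entries forced to 0", path)
        np.fill_diagonal(counts, 0)
    if sections is not None:
        want = sections.labels
        if set(labels) != set(want):
            missing = sorted(set(want) - set(labels))
            extra = sorted(set(labels) - set(want))
            if not subset:
                raise ValueError(
                    f"{path}: label mismatch against section table "
                    f"(missing {missing}, unexpected {extra})"
                )
            keep = [l for l in want if l in set(labels)]
            idx = [labels.index(l) for l in keep]
            counts = counts[np.ix_(idx, idx)]
            labels = keep
        else:
            idx = [labels.index(l) for l in want]
            counts = counts[np.ix_(idx, idx)]
            labels = list(want)
    return FecMatrix(labels=labels, counts=counts, strain=strain)


def write_fec(m: FecMatrix, path: str | Path) -> None:
    pd.DataFrame(m.counts, index=m.labels, columns=m.labels).to_csv(
        path, sep="\t", index_label="section"
    )


def fec_tot(m: FecMatrix) -> np.ndarray:
    """Per-section total contacts: row sums excluding the diagonal."""
    c = m.counts.copy()
    np.fill_diagonal(c, 0)
    return c.sum(axis=1)


def binarize(m: FecMatrix) -> FecMatrix:
    """Presence (1) / absence (0) of any contact per pair; idempotent."""
    return FecMatrix(
        labels=list(m.labels), counts=(m.counts > 0).astype(np.int64), strain=m.strain
    )


def feature_index(table: pd.DataFrame) -> pd.DataFrame:
    """Per-section chromatin feature summary.

    ``table`` is indexed by section label with one 0/1 column per feature
    (five in the reference design: satellite hybridization sites, ectopic
    conjugation, weak points, late replication, giant palindromes).  Adds
    ``F_SUM`` (row sum) and ``Ind = F_SUM / 10``.
    """
    vals = table.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("feature table cells must be 0 or 1")
    out = table.copy()
    out["F_SUM"] = vals.sum(axis=1)
    out["Ind"] = out["F_SUM"] / 10.0
    return out


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return feature_index(df)
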