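"""Distance-zone analysis.

Ectopic contacts form mostly between sections that are chromosomally close,
so the whole-chromosome correlation summary is recomputed inside sliding
windows (*zones*) of D consecutive sections, step 1 section.  For a
chromosome of N sections there are N - D + 1 zones of length D; each zone
yields its own R/P for specific and unspecific correlations restricted to
zone members (specific n = D-1, unspecific n = D-2), and per D the zone
values form a sampling whose means give the difference curves
R_DIFF = mean R_SP - mean R_UN and P_DIFF likewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_N,
    CorrSet,
    _specific,
    _unspecific,
    summarize,
)
from .fec import FecMatrix
from .fmf import FmfMatrix

DEFAULT_ZONE_LENGTHS = tuple(range(10, 117))  # D = 10..116, step 1
DEFAULT_ZONE_L = (10, 30, 50)


@dataclass(frozen=True)
class Zone:
    """D consecutive sections starting at 0-based section index ``start``."""

    start: int
    D: int

    @property
    def members(self) -> range:
        return range(self.start, self.start + self.D)


def enumerate_zones(N: int, D: int) -> list[Zone]:
    """All zones of length D on an N-section chromosome (N - D + 1 of them)."""
    if not 2 <= D <= N:
        raise ValueError(f"zone length D={D} outside [2, {N}]")
    return [Zone(start=i, D=D) for i in range(N - D + 1)]


@dataclass
class ZoneSweepResult:
    """Per-zone and per-D aggregated zone statistics.

    ``zones``: one row per (L, D, zone) with zone-level R_SP/R_UN/P_SP/P_UN
    (nan where no valid estimate).  ``aggregate()`` reduces over zones.
    """

    strain: str
    exclude_repeats: bool
    zones: pd.DataFrame
    N: int
    samplings: dict[tuple[int, int, str], list[float]] = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for (L, D), grp in self.zones.groupby(["L", "D"]):
            r_sp = grp["R_SP"].dropna()
            r_un = grp["R_UN"].dropna()
            p_sp = grp["P_SP"].dropna()
            p_un = grp["P_UN"].dropna()
            rows.append(
                {
                    "strain": self.strain,
                    "filter": self.exclude_repeats,
                    "L": L,
                    "D": D,
                    "n_zones": len(grp),
                    "R_SP": r_sp.mean() if len(r_sp) else math.nan,
                    "R_UN": r_un.mean() if len(r_un) else math.nan,
                    "P_SP": p_sp.mean() if len(p_sp) else math.nan,
                    "P_UN": p_un.mean() if len(p_un) else math.nan,
                }
            )
        df = pd.DataFrame(rows)
        df["R_DIFF"] = df["R_SP"] - df["R_UN"]
        df["P_DIFF"] = df["P_SP"] - df["P_UN"]
        return df


def zone_sweep(
    fec: FecMatrix,
    fmf_by_L: dict[int, FmfMatrix],
    D_values: tuple[int, ...] | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    exclude_repeats: bool = False,
) -> ZoneSweepResult:
    """Zone-restricted R/P sweep for one strain.

    ``fmf_by_L`` maps fragment length to the FMF matrix computed at that
    length (typically L in {10, 30, 50}).  Zones with no valid estimate
    contribute nan (excluded from samplings, counted in the zone table).
    """
    labels = fec.labels
    N = len(labels)
    if D_values is None:
        D_values = tuple(d for d in range(10, N - 2) if d <= N)
    rows = []
    samplings: dict[tuple[int, int, str], list[float]] = {}
    for L, fmf in sorted(fmf_by_L.items()):
        if fmf.labels != labels:
            raise ValueError("FEC and FMF labels differ")
        for D in D_values:
            for z in enumerate_zones(N, D):
                idx = np.asarray(z.members)
                sub_fec = fec.counts[np.ix_(idx, idx)]
                sub_fmf = fmf.values[np.ix_(idx, idx)]
                sub_labels = [labels[i] for i in idx]
                sp = summarize(
                    CorrSet("specific", _specific(sub_fec, sub_fmf, sub_labels, min_n)),
                    alpha,
                )
                un = summarize(
                    CorrSet(
                        "unspecific", _unspecific(sub_fec, sub_fmf, sub_labels, min_n)
                    ),
                    alpha,
                )
                rows.append(
                    {
                        "L": L,
                        "D": D,
                        "zone_start": z.start,
                        "R_SP": sp.R,
                        "R_UN": un.R,
                        "P_SP": sp.P,
                        "P_UN": un.P,
                        "n_valid_SP": sp.n_valid,
                        "n_valid_UN": un.n_valid,
                    }
                )
                for name, val in (
                    ("R_SP", sp.R),
                    ("R_UN", un.R),
                    ("P_SP", sp.P),
                    ("P_UN", un.P),
                ):
                    if not math.isnan(val):
                        samplings.setdefault((L, D, name), []).append(val)
    return ZoneSweepResult(
        strain=fec.strain,
        exclude_repeats=exclude_repeats,
        zones=pd.DataFrame(rows),
        N=N,
        samplings=samplings,
    )
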