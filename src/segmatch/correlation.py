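"""Spearman correlation screening of contact (FEC) vs matching (FMF) matrices.

For an anchor section A, the *specific* correlation compares the contact
profile FEC(A,·) with the matching profile FMF(A,·) over all partner
sections B != A.  The *unspecific* control correlates FEC(A,·) with the
matching profile of a different anchor, FMF(B,·), over the common partners
C not in {A, B} — a shuffle that estimates how often a significant
correlation arises by chance.  Per condition (strain, fragment length L,
repeat filter, correlation type) the estimates are summarized by R, the
mean of significant rho values, and P, the proportion of significant tests
among valid ones.

Ties get average ranks; the two-sided p-value uses the t approximation
with n-2 degrees of freedom.  An estimate is invalid when either vector is
constant (frequent here: FEC matrices are mostly zero, and FMF rows vanish
at large L) or when fewer than ``min_n`` partners are available.
No multiple-testing correction is applied by default; the screening design
reports raw p < alpha, with an optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .fec import FecMatrix
from .fmf import FmfMatrix, normalize_fmf
from .matching import MatchConfig, build_match_tables
from .sections import SectionSet

DEFAULT_MIN_N = 5
DEFAULT_ALPHA = 0.05
SWEEP_LENGTHS = tuple(range(10, 61, 5))


@dataclass(frozen=True)
class CorrEstimate:
    """One Spearman estimate, anchored on a section or an ordered pair."""

    anchor: str | tuple[str, str]
    rho: float
    p: float
    n: int
    valid: bool


@dataclass
class CorrSet:
    kind: str  # "specific" | "unspecific"
    estimates: list[CorrEstimate]

    def __len__(self) -> int:
        return len(self.estimates)

    def __iter__(self):
        return iter(self.estimates)


@dataclass(frozen=True)
class Condition:
    strain: str
    L: int
    exclude_repeats: bool
    corr_type: str


@dataclass
class SummaryPoint:
    """R/P aggregates of one correlation set under one condition.

    ``R`` is the mean rho over significant estimates (nan when none);
    ``P = n_signif / n_valid`` (nan when no valid estimate).  The
    significant-rho sampling is retained for downstream group tests.
    """

    condition: Condition | None
    R: float
    R_se: float
    P: float
    P_se: float
    n_signif: int
    n_valid: int
    rho_signif: list[float] = field(default_factory=list)


def spearman(
    x: np.ndarray, y: np.ndarray, anchor: str | tuple[str, str] = "", min_n: int = DEFAULT_MIN_N
) -> CorrEstimate:
    """Spearman rho with average-rank ties and the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < min_n or np.all(x == x[0]) or np.all(y == y[0]):
        return CorrEstimate(anchor=anchor, rho=math.nan, p=math.nan, n=n, valid=False)
    rho, p = stats.spearmanr(x, y)
    if not math.isfinite(rho):
        return CorrEstimate(anchor=anchor, rho=math.nan, p=math.nan, n=n, valid=False)
    return CorrEstimate(anchor=anchor, rho=float(rho), p=float(p), n=n, valid=True)


def _check_labels(fec: FecMatrix, fmf: FmfMatrix) -> list[str]:
    if fec.labels != fmf.labels:
        raise ValueError("FEC and FMF section labels differ")
    return list(fec.labels)


def specific_correlations(
    fec: FecMatrix, fmf: FmfMatrix, min_n: int = DEFAULT_MIN_N
) -> CorrSet:
    """One estimate per anchor A over partners B != A (n = N-1)."""
    labels = _check_labels(fec, fmf)
    ests = _specific(fec.counts, fmf.values, labels, min_n)
    return CorrSet(kind="specific", estimates=ests)


def _specific(fec_arr, fmf_arr, labels, min_n) -> list[CorrEstimate]:
    N = len(labels)
    out = []
    for a in range(N):
        mask = np.arange(N) != a
        out.append(
            spearman(fec_arr[a, mask], fmf_arr[a, mask], anchor=labels[a], min_n=min_n)
        )
    return out


def unspecific_correlations(
    fec: FecMatrix, fmf: FmfMatrix, min_n: int = DEFAULT_MIN_N
) -> CorrSet:
    """One estimate per ordered pair (A, B), A != B, over common partners
    C not in {A, B} (n = N-2); N(N-1) estimates in total."""
    labels = _check_labels(fec, fmf)
    ests = _unspecific(fec.counts, fmf.values, labels, min_n)
    return CorrSet(kind="unspecific", estimates=ests)


def _unspecific(fec_arr, fmf_arr, labels, min_n) -> list[CorrEstimate]:
    N = len(labels)
    out = []
    for a, b in permutations(range(N), 2):
        mask = np.ones(N, dtype=bool)
        mask[[a, b]] = False
        out.append(
            spearman(
                fec_arr[a, mask],
                fmf_arr[b, mask],
                anchor=(labels[a], labels[b]),
                min_n=min_n,
            )
        )
    return out


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """BH-adjusted p-values (optional alternative to raw thresholding)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = n - rank_from_top
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return adj.tolist()


def summarize(
    cs: CorrSet, alpha: float = DEFAULT_ALPHA, condition: Condition | None = None
) -> SummaryPoint:
    """R (mean significant rho, with SE) and P (significant share of valid,
    with binomial SE) for one correlation set."""
    valid = [e for e in cs if e.valid]
    sig = [e for e in valid if e.p < alpha]
    n_valid, n_signif = len(valid), len(sig)
    if n_signif:
        rhos = np.array([e.rho for e in sig])
        R = float(rhos.mean())
        R_se = float(rhos.std(ddof=1) / math.sqrt(n_signif)) if n_signif > 1 else math.nan
    else:
        R, R_se = math.nan, math.nan
    if n_valid:
        P = n_signif / n_valid
        P_se = math.sqrt(P * (1 - P) / n_valid)
    else:
        P, P_se = math.nan, math.nan
    return SummaryPoint(
        condition=condition,
        R=R,
        R_se=R_se,
        P=P,
        P_se=P_se,
        n_signif=n_signif,
        n_valid=n_valid,
        rho_signif=[e.rho for e in sig],
    )


@dataclass
class SweepResult:
    """Grid of SummaryPoints over L x filter x type (x strain) plus the
    per-section significance table behind the specific correlations."""

    points: list[SummaryPoint]
    section_signif: pd.DataFrame  # strain, L, filter, section, rho, p, significant
    fmf_by: dict[tuple[int, bool], FmfMatrix] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            c = pt.condition
            rows.append(
                {
                    "strain": c.strain,
                    "L": c.L,
                    "filter": c.exclude_repeats,
                    "type": c.corr_type,
                    "R": pt.R,
                    "R_se": pt.R_se,
                    "P": pt.P,
                    "P_se": pt.P_se,
                    "n_signif": pt.n_signif,
                    "n_valid": pt.n_valid,
                }
            )
        return pd.DataFrame(rows)


def sweep_lengths(
    ss: SectionSet,
    fecs: dict[str, FecMatrix],
    L_list: tuple[int, ...] = SWEEP_LENGTHS,
    filters: tuple[bool, ...] = (False, True),
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    chunk_size: int = 10_000,
    keep_fmf: bool = True,
) -> SweepResult:
    """Full condition grid: per L and filter, build FMF once, then
    specific/unspecific summaries per strain."""
    points: list[SummaryPoint] = []
    sig_rows = []
    fmf_by: dict[tuple[int, bool], FmfMatrix] = {}
    for L in L_list:
        for filt in filters:
            cfg = MatchConfig(L=L, exclude_repeats=filt)
            table, _ = build_match_tables(ss, cfg, keep_pair_fragments=False)
            fmf = normalize_fmf(table, ss, chunk_size=chunk_size)
            if keep_fmf:
                fmf_by[(L, filt)] = fmf
            for strain, fec in fecs.items():
                sp = specific_correlations(fec, fmf, min_n=min_n)
                un = unspecific_correlations(fec, fmf, min_n=min_n)
                points.append(
                    summarize(sp, alpha, Condition(strain, L, filt, "specific"))
                )
                points.append(
                    summarize(un, alpha, Condition(strain, L, filt, "unspecific"))
                )
                for e in sp:
                    sig_rows.append(
                        {
                            "strain": strain,
                            "L": L,
                            "filter": filt,
                            "section": e.anchor,
                            "rho": e.rho,
                            "p": e.p,
                            "valid": e.valid,
                            "significant": bool(e.valid and e.p < alpha),
                        }
                    )
    return SweepResult(
        points=points, section_signif=pd.DataFrame(sig_rows), fmf_by=fmf_by
    )
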