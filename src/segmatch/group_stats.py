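"""Group comparisons across analysis conditions.

R samplings (significant rho values per condition, or zone-level R/P values
per D) are compared with a two-sided Mann-Whitney U test; P proportions
with a chi-square test for two sample proportions (2x2 table, df = 1, no
continuity correction by default).  Comparisons vary exactly one factor at
a time: strain, correlation type, repeat filter, or fragment length against
the L = 50 reference.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import SweepResult
from .zones import ZoneSweepResult

ALPHA = 0.05


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, continuity: bool = False
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    Exact enumeration when min(n, m) <= 8 and there are no ties; otherwise
    the normal approximation with tie correction.  Fully tied data (zero
    variance) yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sampling")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=continuity
        )
    p = float(res.pvalue)
    if math.isnan(p):  # all observations tied: no discrimination possible
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def chisq_two_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Chi-square comparison of proportions k1/n1 vs k2/n2 (df = 1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts outside [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():  # degenerate margin: equal proportions
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def _mw_row(base: dict, x, y) -> dict:
    row = dict(base)
    row["test"] = "mannwhitney_R"
    if len(x) == 0 or len(y) == 0:
        row.update(statistic=math.nan, p=math.nan, computable=False, significant=False)
    else:
        u, p = mann_whitney_u(np.asarray(x), np.asarray(y))
        row.update(statistic=u, p=p, computable=True, significant=p < ALPHA)
    return row


def _chisq_row(base: dict, k1, n1, k2, n2) -> dict:
    row = dict(base)
    row["test"] = "chisq_P"
    if n1 == 0 or n2 == 0:
        row.update(statistic=math.nan, p=math.nan, computable=False, significant=False)
    else:
        s, p = chisq_two_proportions(k1, n1, k2, n2)
        row.update(statistic=s, p=p, computable=True, significant=p < ALPHA)
    return row


def compare_sweep(sweep: SweepResult, ref_L: int = 50) -> pd.DataFrame:
    """Comparison table for a whole-chromosome sweep.

    Rows: per fragment length, contrasts varying exactly one of strain /
    type / filter; plus, per condition, the contrast against the same
    condition at the reference length (L = ``ref_L`` when present).
    """
    by_cond = {p.condition: p for p in sweep.points}
    keys = list(by_cond)
    rows = []
    for a, b in combinations(keys, 2):
        diffs = [
            f
            for f in ("strain", "L", "exclude_repeats", "corr_type")
            if getattr(a, f) != getattr(b, f)
        ]
        if len(diffs) != 1:
            continue
        factor = diffs[0]
        if factor == "L" and not (getattr(a, "L") == ref_L or getattr(b, "L") == ref_L):
            continue  # L axis: only contrasts against the reference length
        pa, pb = by_cond[a], by_cond[b]
        base = {
            "factor": factor,
            "level_a": str(getattr(a, factor)),
            "level_b": str(getattr(b, factor)),
            "strain": a.strain if factor != "strain" else "*",
            "L": a.L if factor != "L" else -1,
            "filter": a.exclude_repeats if factor != "exclude_repeats" else None,
            "type": a.corr_type if factor != "corr_type" else "*",
        }
        rows.append(_mw_row(base, pa.rho_signif, pb.rho_signif))
        rows.append(
            _chisq_row(base, pa.n_signif, pa.n_valid, pb.n_signif, pb.n_valid)
        )
    return pd.DataFrame(rows)


def compare_zone_sweeps(results: dict[str, ZoneSweepResult]) -> pd.DataFrame:
    """Comparison table for zone sweeps, keyed by condition tag (e.g. strain).

    Per (L, D): specific-vs-unspecific contrast within each tag, and
    between-tag contrasts of the same statistic; both R and P zone samplings
    are tested with Mann-Whitney (they are samplings over zones).
    """
    rows = []
    tags = list(results)
    for tag in tags:
        res = results[tag]
        lds = {(L, D) for (L, D, _name) in res.samplings}
        for L, D in sorted(lds):
            for stat in ("R", "P"):
                x = res.samplings.get((L, D, f"{stat}_SP"), [])
                y = res.samplings.get((L, D, f"{stat}_UN"), [])
                base = {
                    "factor": "corr_type",
                    "level_a": "specific",
                    "level_b": "unspecific",
                    "strain": tag,
                    "L": L,
                    "D": D,
                    "statistic_name": stat,
                }
                rows.append(_mw_row(base, x, y))
    for ta, tb in combinations(tags, 2):
        ra, rb = results[ta], results[tb]
        common = sorted(set(ra.samplings) & set(rb.samplings))
        for key in common:
            L, D, name = key
            base = {
                "factor": "strain",
                "level_a": ta,
                "level_b": tb,
                "strain": "*",
                "L": L,
                "D": D,
                "statistic_name": name,
            }
            rows.append(_mw_row(base, ra.samplings[key], rb.samplings[key]))
    df = pd.DataFrame(rows)
    if len(df):
        df = df[df["test"] == "mannwhitney_R"].drop(columns=["test"])
    return df


def compare_all(
    sweep: SweepResult | ZoneSweepResult | dict[str, ZoneSweepResult],
    ref_L: int = 50,
) -> pd.DataFrame:
    """Dispatch to the appropriate comparison table builder."""
    if isinstance(sweep, SweepResult):
        return compare_sweep(sweep, ref_L=ref_L)
    if isinstance(sweep, ZoneSweepResult):
        return compare_zone_sweeps({sweep.strain or "strain": sweep})
    return compare_zone_sweeps(sweep)
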