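"""Exponential growth-rate estimation from OD750 time series.

A rate is reported only for cultures that sustained growth for at least three
population doublings (log2 of max over first positive OD).  The rate is the
least-squares slope of ln(OD) versus time over the best exponential-phase
window: the longest contiguous run of >= ``min_window`` points maximizing the
fitted slope subject to R^2 >= 0.95, falling back to the full positive-OD
series when no window qualifies.

Rate comparisons between strain x treatment groups use Welch's unequal-
variance t-test on replicate rates with Benjamini-Hochberg (step-up) FDR
adjustment across the comparison family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthSeries:
    strain: str
    treatment: str
    replicate: str
    time_h: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.size < 3:
            raise ValueError("need >= 3 time points")
        if not np.all(np.diff(self.time_h) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD must be nonnegative")


@dataclass
class RateEstimate:
    strain: str
    treatment: str
    replicate: str
    status: str  # 'estimated' | 'no-sustained-growth' | 'bleached'
    rate: float | None = None  # per hour
    intercept: float | None = None
    window: tuple | None = None  # index range, half-open
    doublings: float = 0.0
    r_squared: float | None = None


def _fit_window(t: np.ndarray, ln_od: np.ndarray):
    slope, intercept, r, *_ = stats.linregress(t, ln_od)
    return slope, intercept, r * r


def fit_rate(s: GrowthSeries, min_doublings: float = 3.0,
             min_window: int = 3, min_r2: float = 0.95) -> RateEstimate:
    """Estimate the exponential growth rate of one OD series.

    Cultures not reaching ``min_doublings`` population doublings get status
    'no-sustained-growth' and no rate.
    """
    pos = s.od > 0
    if not pos.any():
        return RateEstimate(s.strain, s.treatment, s.replicate,
                            "no-sustained-growth")
    first_pos = float(s.od[pos][0])
    doublings = math.log2(float(s.od.max()) / first_pos) if first_pos > 0 else 0.0
    if doublings < min_doublings:
        return RateEstimate(s.strain, s.treatment, s.replicate,
                            "no-sustained-growth", doublings=doublings)
    t = s.time_h[pos]
    ln_od = np.log(s.od[pos])
    idx = np.flatnonzero(pos)
    n = t.size
    best = None  # (slope, intercept, r2, lo, hi); ties keep the longer window
    for length in range(n, min_window - 1, -1):
        for lo in range(0, n - length + 1):
            hi = lo + length
            slope, intercept, r2 = _fit_window(t[lo:hi], ln_od[lo:hi])
            if r2 >= min_r2 and (best is None or slope > best[0] + 1e-15):
                best = (slope, intercept, r2, lo, hi)
    if best is None:
        slope, intercept, r2 = _fit_window(t, ln_od)
        best = (slope, intercept, r2, 0, n)
    slope, intercept, r2, lo, hi = best
    return RateEstimate(s.strain, s.treatment, s.replicate, "estimated",
                        rate=slope, intercept=intercept,
                        window=(int(idx[lo]), int(idx[hi - 1]) + 1),
                        doublings=doublings, r_squared=r2)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_rates(groups: dict, pairs: list) -> pd.DataFrame:
    """Welch t-tests on replicate rates for designated group pairs, BH-adjusted.

    ``groups`` maps label -> list of replicate rates; pairs with a group
    holding fewer than 2 estimates are reported 'not-comparable' (their p is
    NaN and excluded from the adjustment family).
    """
    rows = []
    for a, b in pairs:
        ra = np.asarray(groups.get(a, []), dtype=float)
        rb = np.asarray(groups.get(b, []), dtype=float)
        if ra.size < 2 or rb.size < 2:
            rows.append((a, b, np.nan, "not-comparable"))
            continue
        if (np.ptp(ra) == 0 and np.ptp(rb) == 0
                and ra.mean() == rb.mean()):
            p = 1.0  # identical constant groups: no evidence of difference
        else:
            p = float(stats.ttest_ind(ra, rb, equal_var=False).pvalue)
            if math.isnan(p):
                p = 1.0
        rows.append((a, b, p, "compared"))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw", "status"])
    mask = df["status"] == "compared"
    adj = np.full(len(df), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = bh_adjust(df.loc[mask, "p_raw"].to_numpy())
    df["p_adjusted"] = adj
    return df


def read_od_table(path: str) -> list:
    """TSV (strain, treatment, replicate, time_h, od750) -> GrowthSeries list."""
    df = pd.read_csv(path, sep="\t")
    need = {"strain", "treatment", "replicate", "time_h", "od750"}
    if not need.issubset(df.columns):
        raise ValueError(f"OD table needs columns {sorted(need)}")
    out = []
    for (st, tr, rep), grp in df.groupby(["strain", "treatment", "replicate"],
                                         sort=True):
        grp = grp.sort_values("time_h")
        out.append(GrowthSeries(str(st), str(tr), str(rep),
                                grp["time_h"].to_numpy(),
                                grp["od750"].to_numpy()))
    return out


def estimates_table(estimates: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "strain": e.strain, "treatment": e.treatment, "replicate": e.replicate,
        "status": e.status, "rate_per_h": e.rate, "doublings": e.doublings,
        "r_squared": e.r_squared,
        "window_start": None if e.window is None else e.window[0],
        "window_end": None if e.window is None else e.window[1],
    } for e in estimates])
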