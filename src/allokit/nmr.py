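"""Amide chemical-shift thermometry.

The amide proton temperature coefficient ∂δ(HN)/∂T (ppb/K) is the slope of
the chemical shift against temperature; in proteins it is typically a few
ppb/K negative, and a change of slope with temperature ("curvature") signals
a temperature-dependent conformational change of the residue's environment.
Curvature is detected with an extra-sum-of-squares F-test comparing a linear
fit (null) against a quadratic fit:

    F = ((RSS_lin - RSS_quad) / 1) / (RSS_quad / (n - 3)),  p ~ F(1, n - 3)

Slopes are evaluated inside two temperature windows (defaults: 292.92-302.73 K
around 30 °C and 307.62-322.41 K around 50 °C, endpoints inclusive): with
exactly two points the slope is the plain difference quotient
(δ(T2) - δ(T1)) / (T2 - T1), with more points the least-squares slope.  Sign
convention: a shift decreasing with temperature gives a negative coefficient.

Shift tables are long-format DataFrames with columns residue, nucleus,
temperature_K, shift_ppm, source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "WINDOW_30C",
    "WINDOW_50C",
    "TempCoefficientResult",
    "temperature_coefficient",
    "extra_ss_ftest",
    "curvature_test",
    "shift_agreement",
    "ensemble_average_shifts",
]

WINDOW_30C = (292.92, 302.73)
WINDOW_50C = (307.62, 322.41)

SHIFT_COLUMNS = ["residue", "nucleus", "temperature_K", "shift_ppm"]


@dataclass(frozen=True)
class TempCoefficientResult:
    """Per-residue thermometry summary."""

    residue: str
    nucleus: str
    slope_30: float             # ppb/K in the low window
    slope_50: float             # ppb/K in the high window
    delta_slope: float          # |slope_50 - slope_30|
    curvature: bool             # p < alpha for the quadratic term
    f_statistic: float
    p_value: float
    n_points: int
    alpha: float = 0.05


def _series(table: pd.DataFrame, residue: str, nucleus: str
            ) -> tuple[np.ndarray, np.ndarray]:
    sel = table[(table["residue"] == residue) & (table["nucleus"] == nucleus)]
    sel = sel.sort_values("temperature_K")
    return sel["temperature_K"].to_numpy(float), sel["shift_ppm"].to_numpy(float)


def temperature_coefficient(table: pd.DataFrame, residue: str,
                            nucleus: str = "HN",
                            window: tuple[float, float] | None = None) -> float:
    """Temperature coefficient (ppb/K) for one residue inside a window.

    Window membership is endpoint-inclusive; ``None`` uses every temperature.
    Two points give the exact difference quotient, more give the
    least-squares slope.  Shifts enter in ppm; the result is scaled to ppb/K.
    """
    t, d = _series(table, residue, nucleus)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, d = t[keep], d[keep]
    if len(t) < 2:
        raise InsufficientDataError(
            f"residue {residue}: {len(t)} point(s) in window; need >= 2")
    if len(t) == 2:
        slope_ppm = (d[1] - d[0]) / (t[1] - t[0])
    else:
        slope_ppm = np.polyfit(t, d, 1)[0]
    return float(slope_ppm * 1000.0)


def extra_ss_ftest(t: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Extra-sum-of-squares F-test, linear (null) vs quadratic fit.

    Temperatures are centered before fitting for conditioning.  Returns
    ``(F, p)`` with p from F(1, n-3).  A perfect linear fit (both RSS zero)
    returns p = 1 — no evidence of curvature.
    """
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    n = len(t)
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 temperatures for the curvature F-test, got {n}")
    tc = t - t.mean()
    rss_lin = _rss(np.column_stack([np.ones(n), tc]), d)
    rss_quad = _rss(np.column_stack([np.ones(n), tc, tc ** 2]), d)
    if rss_quad <= 1e-30:
        if rss_lin <= 1e-30:
            return 0.0, 1.0     # degenerate perfect fits
        return np.inf, 0.0
    f = (rss_lin - rss_quad) / (rss_quad / (n - 3))
    f = max(f, 0.0)
    return float(f), float(stats.f.sf(f, 1, n - 3))


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def curvature_test(table: pd.DataFrame, residue: str, nucleus: str = "HN",
                   alpha: float = 0.05,
                   window_low: tuple[float, float] = WINDOW_30C,
                   window_high: tuple[float, float] = WINDOW_50C
                   ) -> TempCoefficientResult:
    """Full thermometry summary for one residue.

    Combines the two window slopes with the curvature F-test over all
    temperatures; the curvature flag is ``p < alpha``.
    """
    t, d = _series(table, residue, nucleus)
    f, p = extra_ss_ftest(t, d)
    slope_lo = temperature_coefficient(table, residue, nucleus, window_low)
    slope_hi = temperature_coefficient(table, residue, nucleus, window_high)
    return TempCoefficientResult(
        residue=residue, nucleus=nucleus, slope_30=slope_lo, slope_50=slope_hi,
        delta_slope=abs(slope_hi - slope_lo), curvature=bool(p < alpha),
        f_statistic=f, p_value=p, n_points=len(t), alpha=alpha)


def shift_agreement(computed: pd.DataFrame, experimental: pd.DataFrame,
                    nucleus: str = "CA") -> dict:
    """Computed-vs-experimental shift correlation for one nucleus.

    Matches rows on residue label; returns the Pearson r over matched pairs,
    the per-residue residuals (computed - experimental, ppm) and the residues
    present on only one side (e.g. hard to assign experimentally).
    """
    comp = computed[computed["nucleus"] == nucleus]
    expe = experimental[experimental["nucleus"] == nucleus]
    merged = comp.merge(expe, on="residue", suffixes=("_comp", "_exp"))
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} matched residues for nucleus {nucleus}; need >= 3")
    r, _ = stats.pearsonr(merged["shift_ppm_comp"], merged["shift_ppm_exp"])
    residuals = pd.Series(
        (merged["shift_ppm_comp"] - merged["shift_ppm_exp"]).to_numpy(),
        index=merged["residue"].to_numpy())
    return {
        "pearson_r": float(r),
        "n_matched": int(len(merged)),
        "residuals": residuals,
        "unmatched_computed": sorted(set(comp["residue"]) - set(expe["residue"])),
        "unmatched_experimental": sorted(set(expe["residue"]) - set(comp["residue"])),
    }


def ensemble_average_shifts(per_frame_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-frame predicted shift tables into one computed table.

    Arithmetic mean per (residue, nucleus); the frame count and the
    across-frame standard deviation are recorded alongside.
    """
    if not per_frame_tables:
        raise ValueError("no per-frame shift tables given")
    stacked = pd.concat(per_frame_tables, ignore_index=True)
    grouped = stacked.groupby(["residue", "nucleus"], sort=False)["shift_ppm"]
    out = grouped.agg(shift_ppm="mean", shift_sd="std", n_frames="count").reset_index()
    out["shift_sd"] = out["shift_sd"].fillna(0.0)
    out["source"] = "computed"
    return out
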