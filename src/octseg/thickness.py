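"""Epidermal thickness (ET) measurement and agreement analysis.

ET is measured per image column as the vertical extent of the epidermis
band — last foreground row minus first foreground row plus one — and
summarized as the mean over columns that contain any epidermis; columns
with no foreground are excluded from the mean rather than zero-filled.
The pixel mean converts to micrometres through an explicit axial pixel
pitch (default 5.5 um/px), which is always carried alongside the result.

Agreement between a manual and an automated ET series is assessed the
standard way for method-comparison studies: Pearson correlation of the
paired values, and a Bland-Altman analysis reporting the mean difference
(bias) and 95% limits of agreement (bias +/- 1.96 x sample SD of the
differences, n-1 denominator).

A paired t-test utility compares segmentation metrics across B-scan
positions within an OCT volume (peripheral 25%/75% vs central 50%),
flagging significance at p < 0.05. Zero-variance differences are handled
explicitly: all-zero differences report p = 1; constant non-zero
differences are reported as degenerate rather than as a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ThicknessProfile", "AgreementStats", "thickness_profile",
           "compare_thickness", "position_comparison"]


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-column epidermal thickness for one mask.

    ``per_column_px`` is float with NaN marking columns without epidermis;
    ``mean_px`` averages the defined columns only.
    """

    per_column_px: np.ndarray
    mean_px: float
    axial_pitch_um: float

    @property
    def mean_um(self) -> float:
        return self.mean_px * self.axial_pitch_um


@dataclass(frozen=True)
class AgreementStats:
    bias_um: float
    loa_low_um: float
    loa_high_um: float
    sd_um: float
    pearson_r: float
    pearson_p: float
    n: int
    means_um: np.ndarray        # Bland-Altman x-coordinates
    differences_um: np.ndarray  # Bland-Altman y-coordinates


def thickness_profile(mask: np.ndarray, axial_pitch_um: float = 5.5,
                      strict_single_run: bool = False) -> ThicknessProfile:
    """Measure per-column epidermal thickness from a binary mask.

    Thickness spans from the first to the last foreground row in each
    column (the outer envelope between the upper and lower epidermal
    boundaries), so a column fragmented by noise still yields one value;
    ``strict_single_run=True`` raises instead when a column holds more
    than one foreground run.
    """
    if axial_pitch_um <= 0:
        raise ValueError("axial_pitch_um must be positive")
    m = np.asarray(mask) > 0
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    h, w = m.shape
    any_fg = m.any(axis=0)
    if not any_fg.any():
        raise ValueError("no epidermis detected: mask is entirely background")
    first = m.argmax(axis=0)
    last = h - 1 - m[::-1].argmax(axis=0)
    if strict_single_run:
        runs_start = m & ~np.vstack([np.zeros(w, bool), m[:-1]])
        multi = (runs_start.sum(axis=0) > 1) & any_fg
        if multi.any():
            raise ValueError(
                f"columns with multiple foreground runs: {np.where(multi)[0].tolist()}")
    per_col = np.where(any_fg, (last - first + 1).astype(np.float64), np.nan)
    return ThicknessProfile(per_column_px=per_col,
                            mean_px=float(np.nanmean(per_col)),
                            axial_pitch_um=axial_pitch_um)


def compare_thickness(manual_ets_um, auto_ets_um) -> AgreementStats:
    """Bland-Altman and Pearson agreement between paired ET series (um)."""
    manual = np.asarray(manual_ets_um, dtype=np.float64)
    auto = np.asarray(auto_ets_um, dtype=np.float64)
    if manual.shape != auto.shape or manual.ndim != 1:
        raise ValueError("manual and automated ET lists must be equal-length 1-D")
    n = manual.size
    if n < 3:
        raise ValueError("agreement analysis needs at least 3 pairs")
    diff = auto - manual
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(manual) == 0 or np.ptp(auto) == 0:
        r, p = float("nan"), float("nan")  # correlation undefined for constants
    else:
        r, p = stats.pearsonr(manual, auto)
    return AgreementStats(bias_um=bias,
                          loa_low_um=bias - 1.96 * sd,
                          loa_high_um=bias + 1.96 * sd,
                          sd_um=sd,
                          pearson_r=float(r), pearson_p=float(p), n=n,
                          means_um=(manual + auto) / 2.0,
                          differences_um=diff)


_POSITION_PAIRS = ((25, 50), (75, 50), (25, 75))


def position_comparison(metric_table: pd.DataFrame,
                        metrics: list[str] | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests of per-image metrics across B-scan slice positions.

    ``metric_table`` needs columns ``image_id``, ``position`` (25/50/75)
    and one column per metric. Every image must appear at each compared
    position. Returns one row per (metric, position pair) with the two
    position means, t, p, and a significance flag at ``alpha``; degenerate
    constant non-zero differences get a marker instead of a p-value.
    """
    df = metric_table.copy()
    required = {"image_id", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"metric table must contain columns {sorted(required)}")
    if metrics is None:
        metrics = [c for c in df.columns if c not in required]
    rows = []
    for pos_a, pos_b in _POSITION_PAIRS:
        a = df[df["position"] == pos_a].set_index("image_id")
        b = df[df["position"] == pos_b].set_index("image_id")
        unmatched = sorted(set(a.index) ^ set(b.index))
        if unmatched:
            raise ValueError(f"unpaired image identifiers at positions "
                             f"{pos_a}/{pos_b}: {unmatched}")
        common = a.index
        for metric in metrics:
            x = a.loc[common, metric].to_numpy(dtype=np.float64)
            y = b.loc[common, metric].to_numpy(dtype=np.float64)
            diff = x - y
            row = {"metric": metric, "position_a": pos_a, "position_b": pos_b,
                   "mean_a": float(x.mean()), "mean_b": float(y.mean()),
                   "n": len(diff)}
            if np.allclose(diff, 0):
                row.update(t=0.0, p=1.0, significant=False, note="")
            elif np.allclose(diff, diff.mean()):
                row.update(t=float("nan"), p=float("nan"), significant=False,
                           note="degenerate: constant nonzero difference")
            else:
                t, p = stats.ttest_rel(x, y)
                row.update(t=float(t), p=float(p),
                           significant=bool(p < alpha), note="")
            rows.append(row)
    return pd.DataFrame(rows)
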