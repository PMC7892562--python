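"""Nucleosome spacing and phasing from averaged dyad profiles.

Spacing is the slope of the ordinary least-squares regression of the first
five metagene peak offsets on nucleosome index (+1..+5). Phasing is read
out as peak height over flanking-trough depth; when the mean ratio over
peaks +2..+5 drops below a threshold the spacing is declared ND (not
determined) because the peaks are too weak to measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nucspacer.profile_builder import AlignedProfile, gaussian_smooth

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Called nucleosome peaks +1..+n on a smoothed average dyad profile.

    peaks: list of (index k, offset bp, smoothed height); troughs: list of
    (offset, depth) minima between consecutive peaks.
    """

    peaks: list[tuple[int, int, float]]
    troughs: list[tuple[int, float]]
    search_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        offs = [p[1] for p in self.peaks]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("peak offsets must be strictly increasing")

    @property
    def offsets(self) -> list[int]:
        return [p[1] for p in self.peaks]

    @property
    def heights(self) -> list[float]:
        return [p[2] for p in self.peaks]


@dataclass
class PhasingMetrics:
    """Peak/trough diagnostics of nucleosome positioning strength."""

    peak_heights: list[float]
    trough_depths: list[float]
    mean_peak_trough_ratio: float
    decay_ratio: float  # height(+n) / height(+1)


@dataclass
class SpacingEstimate:
    """Regression-derived nucleosome spacing with OK/ND status.

    spacing_bp is the OLS slope (bp per nucleosome index), None when
    status == 'ND'. Full precision is retained; display rounding is left
    to `spacing_display`.
    """

    spacing_bp: float | None
    intercept_bp: float | None
    n_peaks_used: int
    r_squared: float | None
    status: str  # {OK, ND}
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("OK", "ND"):
            raise ValueError("status must be OK or ND")
        if self.status == "OK" and (
            self.spacing_bp is None or not 100 <= self.spacing_bp <= 250
        ):
            raise ValueError("OK estimate requires spacing in [100, 250] bp")
        if self.status == "ND":
            self.spacing_bp = None


def spacing_display(est: SpacingEstimate) -> str:
    """Spacing rounded to the nearest bp, or 'ND'."""
    if est.status == "ND" or est.spacing_bp is None:
        return "ND"
    return str(int(round(est.spacing_bp)))


def call_peaks(
    profile: AlignedProfile,
    n_peaks: int = 5,
    first_window: tuple[int, int] = (-50, 50),
    step_window: tuple[int, int] = (110, 220),
    smooth_bw: float = 10.0,
) -> PeakSet:
    """Call the first n nucleosome peaks on a smoothed dyad profile.

    Peak 1 is the (leftmost) argmax within first_window around offset 0;
    peak k is the argmax within [p_{k-1} + step_lo, p_{k-1} + step_hi].
    Troughs are the minima between consecutive peaks.
    """
    if profile.track_kind != "dyad":
        raise ValueError("peak calling expects a dyad-density profile")
    smoothed = gaussian_smooth(profile.values, smooth_bw)
    if np.allclose(smoothed, smoothed[0]):
        raise ValueError("no peaks: profile is flat")
    lo, hi = profile.window_lo, profile.window_hi

    def argmax_in(w_lo: int, w_hi: int) -> tuple[int, float]:
        if w_lo < lo or w_hi > hi:
            raise ValueError(
                f"peak search window [{w_lo}, {w_hi}] exceeds profile range [{lo}, {hi}]"
            )
        seg = smoothed[w_lo - lo : w_hi - lo + 1]
        i = int(np.argmax(seg))  # leftmost maximum
        return w_lo + i, float(seg[i])

    peaks: list[tuple[int, int, float]] = []
    off, h = argmax_in(first_window[0], first_window[1])
    peaks.append((1, off, h))
    for k in range(2, n_peaks + 1):
        prev = peaks[-1][1]
        off, h = argmax_in(prev + step_window[0], prev + step_window[1])
        peaks.append((k, off, h))

    troughs: list[tuple[int, float]] = []
    for (_, a, _), (_, b, _) in zip(peaks, peaks[1:]):
        seg = smoothed[a - lo : b - lo + 1]
        i = int(np.argmin(seg))
        troughs.append((a + i, float(seg[i])))

    return PeakSet(
        peaks=peaks,
        troughs=troughs,
        search_params={
            "first_window": tuple(first_window),
            "step_window": tuple(step_window),
            "smooth_bw": smooth_bw,
        },
    )


def phasing_metrics(profile: AlignedProfile, peaks: PeakSet) -> PhasingMetrics:
    """Peak-height and trough-depth diagnostics for a called peak set.

    mean_peak_trough_ratio averages, over peaks +2..+n, each peak height
    divided by the mean of its flanking trough depths (the last peak has
    only a left trough). Higher ratios mean sharper phasing.
    """
    heights = peaks.heights
    depths = [t[1] for t in peaks.troughs]
    ratios: list[float] = []
    for k in range(2, len(heights) + 1):
        flanks = [depths[k - 2]]
        if k - 1 < len(depths):
            flanks.append(depths[k - 1])
        if min(flanks) == 0:
            logger.warning("zero trough depth at peak %d; ratio reported as +inf", k)
            ratios.append(math.inf)
        else:
            ratios.append(heights[k - 1] / float(np.mean(flanks)))
    return PhasingMetrics(
        peak_heights=heights,
        trough_depths=depths,
        mean_peak_trough_ratio=float(np.mean(ratios)),
        decay_ratio=heights[-1] / heights[0],
    )


def estimate_spacing(
    peaks: PeakSet,
    phasing: PhasingMetrics,
    nd_ratio_threshold: float = 1.10,
) -> SpacingEstimate:
    """OLS regression of peak offset on nucleosome index; ND when weak.

    The slope is the average nucleosome spacing. Status is ND when fewer
    than five peaks are available, when the mean peak-to-trough ratio is
    below nd_ratio_threshold (phasing too weak), or when the slope falls
    outside the plausible 100-250 bp repeat-length range.
    """
    if len(peaks.peaks) < 5:
        return SpacingEstimate(None, None, len(peaks.peaks), None, "ND",
                               reason="fewer than 5 peaks")
    idx = np.array([p[0] for p in peaks.peaks], dtype=float)
    off = np.array([p[1] for p in peaks.peaks], dtype=float)
    res = stats.linregress(idx, off)
    slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    if phasing.mean_peak_trough_ratio < nd_ratio_threshold:
        return SpacingEstimate(
            None, None, len(peaks.peaks), r2, "ND",
            reason=f"phasing too weak (peak/trough ratio "
                   f"{phasing.mean_peak_trough_ratio:.3f} < {nd_ratio_threshold})",
        )
    if not 100 <= slope <= 250:
        return SpacingEstimate(
            None, None, len(peaks.peaks), r2, "ND",
            reason=f"slope {slope:.1f} bp outside plausible repeat-length range",
        )
    return SpacingEstimate(slope, intercept, len(peaks.peaks), r2, "OK")


def shift_from_spacing_change(
    spacing_old: float, spacing_new: float, nucleosome_index: int
) -> float:
    """Cumulative downstream shift of nucleosome k when spacing changes.

    The +1 nucleosome is held fixed, so a spacing change of d bp displaces
    nucleosome k by (k - 1) * d bp: a 160 -> 165 bp change moves +2 by
    5 bp, +3 by 10 bp, +4 by 15 bp.
    """
    if nucleosome_index < 1:
        raise ValueError("nucleosome_index must be >= 1")
    return (nucleosome_index - 1) * (spacing_new - spacing_old)


def compare_replicates(
    estimates: Mapping[str, Sequence[SpacingEstimate]],
) -> pd.DataFrame:
    """Tabulate replicate spacings per sample with their spread and ND flags.

    Returns one row per sample: replicate spacings (bp, full precision),
    the max-min difference over OK replicates (NaN when any replicate is
    ND) and a per-replicate ND flag string.
    """
    rows = []
    for sample, ests in estimates.items():
        if not ests:
            raise ValueError(f"sample {sample!r} has no estimates")
        spacings = [e.spacing_bp for e in ests]
        any_nd = any(e.status == "ND" for e in ests)
        ok_vals = [s for s in spacings if s is not None]
        diff = (max(ok_vals) - min(ok_vals)) if (ok_vals and not any_nd) else float("nan")
        rows.append(
            {
                "sample": sample,
                "n_replicates": len(ests),
                "spacings": [spacing_display(e) for e in ests],
                "difference_bp": diff,
                "any_nd": any_nd,
            }
        )
    return pd.DataFrame(rows)
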