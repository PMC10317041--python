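"""ROI statistics of the dynamic oxygen-17 experiment.

The quantities the reference analysis reports from a 30-minute,
three-phase inhalation run:

* per-ROI mean signal per frame, normalised to the mean of the baseline
  phase (first five one-minute frames);
* the mean of five data points around the second switch (back to room
  air, i.e. the point of longest 17O2 inhalation) — the "relative signal
  increase" of a region;
* the baseline coefficient of variation (sample standard deviation of
  the first baseline points relative to their mean) — the noise yardstick
  against which any stroke-vs-control difference must be judged;
* mirrored control ROIs (left-right reflection of the stroke mask about
  the midsagittal plane) and a CSF safety margin (the ventricle mask
  dilated twice is subtracted from stroke and control ROIs to limit
  spill-in from metabolically inactive CSF);
* the Dice coefficient between two segmentations of the same structure;
* voxel-wise relative 17O increase maps, (end-inhalation - baseline) /
  baseline, on Hamming-filtered, eightfold zero-filled reconstructions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .recon import ImageFrame, ImageSeries, zero_fill
from .timecourse import RegionTimeCourse

__all__ = [
    "AnalysisConfig",
    "roi_mean_series",
    "normalize_to_baseline",
    "mean_around_switch",
    "baseline_cv",
    "mirror_mask",
    "exclude_ventricle_margin",
    "dice",
    "relative_increase_map",
    "roi_contrast",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Counts and factors steering the ROI analysis (reference defaults:
    5 baseline frames, 5 frames around the second switch, 2 ventricle
    dilations, 3 one-minute frames per condition image, eightfold
    zero-filling, 10% baseline floor for increase maps)."""

    n_baseline_frames: int = 5
    n_switch_frames: int = 5
    ventricle_dilations: int = 2
    frames_per_condition: int = 3
    zero_fill_factor: int = 8
    baseline_floor_frac: float = 0.1

    def __post_init__(self) -> None:
        counts = (
            self.n_baseline_frames,
            self.n_switch_frames,
            self.frames_per_condition,
            self.zero_fill_factor,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all analysis counts must be >= 1")
        if self.ventricle_dilations < 0:
            raise ValueError("dilation count must be nonnegative")


def roi_mean_series(series: ImageSeries, mask: np.ndarray, region: str = "") -> RegionTimeCourse:
    """Arithmetic mean of the magnitude frames over ``mask``, per frame."""
    mask = np.asarray(mask, dtype=bool)
    if tuple(mask.shape) != series.grid.shape:
        raise ValueError("mask does not match the series grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    values = np.array([f.data[mask].mean() for f in series.frames])
    return RegionTimeCourse(region=region, values=values, frame_times_s=series.mid_times_s)


def normalize_to_baseline(tc: RegionTimeCourse, n_baseline: int) -> RegionTimeCourse:
    """Divide every value by the mean of the first ``n_baseline`` values."""
    if n_baseline < 1 or n_baseline > len(tc):
        raise ValueError("baseline window must fit inside the series")
    base = tc.values[:n_baseline].mean()
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return tc.with_values(tc.values / base, normalized=True)


def _switch_center_frame(frame_times_s: np.ndarray, switch_time_s: float) -> int:
    # frame whose mid-time is nearest the switch; on a tie the later frame
    # wins, which under the half-open [start, end) frame convention is the
    # frame that contains the switch instant
    d = np.abs(frame_times_s - switch_time_s)
    candidates = np.nonzero(d == d.min())[0]
    return int(candidates[-1])


def mean_around_switch(
    tc: RegionTimeCourse, switch_time_s: float, n_points: int = 5
) -> float:
    """Mean of ``n_points`` frames centred on the second switch.

    For the default five points: two frames before the centre frame, the
    centre frame (the one nearest — and on ties containing — the switch
    instant) and two frames after.
    """
    if n_points < 1:
        raise ValueError("need at least one point")
    center = _switch_center_frame(tc.frame_times_s, switch_time_s)
    start = center - (n_points - 1) // 2
    stop = start + n_points
    if start < 0 or stop > len(tc):
        raise ValueError("switch window extends outside the series")
    return float(tc.values[start:stop].mean())


def baseline_cv(tc: RegionTimeCourse, n_points: int = 5) -> float:
    """Baseline variability in percent: sample (n-1) standard deviation of
    the first ``n_points`` values divided by their mean, times 100."""
    if n_points < 2:
        raise ValueError("need at least two points for a standard deviation")
    if n_points > len(tc):
        raise ValueError("fewer frames than requested baseline points")
    head = tc.values[:n_points]
    return float(head.std(ddof=1) / head.mean() * 100.0)


def mirror_mask(mask: np.ndarray) -> np.ndarray:
    """Left-right reflection about the central voxel plane of axis 0."""
    return np.asarray(mask)[::-1, :, :].copy()


def exclude_ventricle_margin(
    roi: np.ndarray, ventricles: np.ndarray, n_dilations: int = 2
) -> np.ndarray:
    """Remove from ``roi`` the ventricle mask dilated ``n_dilations`` times.

    Dilation uses the 6-connected (face-neighbour) structuring element,
    one voxel per iteration — the most conservative CSF safety margin.
    An empty result is legal and only logged.
    """
    roi = np.asarray(roi, dtype=bool)
    ventricles = np.asarray(ventricles, dtype=bool)
    if roi.shape != ventricles.shape:
        raise ValueError("masks must share one grid")
    margin = ventricles
    if n_dilations > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        margin = ndimage.binary_dilation(ventricles, structure=struct, iterations=n_dilations)
    out = roi & ~margin
    if not out.any():
        log.warning("ROI is empty after subtracting the dilated ventricle margin")
    return out


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def relative_increase_map(
    baseline: ImageFrame,
    end_inhalation: ImageFrame,
    zero_fill_factor: int = 8,
    baseline_floor_frac: float = 0.1,
) -> np.ndarray:
    """Voxel-wise relative 17O signal increase map.

    Both condition images (each reconstructed from a few minutes of
    projections, Hamming filtered) are zero-filled, then
    ``(end - baseline) / baseline`` is computed voxel-wise.  Voxels whose
    baseline falls below ``baseline_floor_frac`` times the in-brain median
    baseline are set to NaN: outside the head the division is meaningless.
    The in-brain median is taken over voxels above 10% of the baseline
    maximum.
    """
    if baseline.grid != end_inhalation.grid:
        raise ValueError("condition images must share one grid")
    base = zero_fill(baseline, zero_fill_factor).data
    end = zero_fill(end_inhalation, zero_fill_factor).data
    rough_brain = base > 0.1 * base.max()
    floor = baseline_floor_frac * np.median(base[rough_brain])
    out = np.full(base.shape, np.nan)
    ok = base >= floor
    out[ok] = (end[ok] - base[ok]) / base[ok]
    return out


def roi_contrast(test_value: float, control_value: float) -> float:
    """Percent signal deficit of a test ROI relative to its control:
    ``(1 - test/control) * 100`` — positive when the test region (e.g.
    stroke) shows less increase than its mirrored control."""
    if test_value <= 0 or control_value <= 0:
        raise ValueError("ROI values must be positive")
    return (1.0 - test_value / control_value) * 100.0
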