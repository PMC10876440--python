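"""Marker-gated intensity quantification and geometry measurements.

Multi-channel 3D stacks of ciliated chordotonal neurons are quantified by
segmenting the marker channel (e.g., an Iav antibody stain that labels the
proximal cilium) into region masks, averaging the target-channel intensity
inside those masks per volume (per antenna), normalizing each batch to its
control median, and comparing groups with the Mann-Whitney U test.  A small
geometry helper measures the deviation-from-collinear bending angle between
a dendrite and the cilium projecting from it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure

__all__ = [
    "LabeledVolume",
    "RegionStats",
    "GroupComparison",
    "segment_marker_regions",
    "region_intensity_stats",
    "normalize_to_control",
    "dilation_positive_fraction",
    "bending_angle",
    "compare_groups",
]


@dataclass
class LabeledVolume:
    """Named 3D channels with voxel calibration and a group label."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]
    group_label: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class RegionStats:
    """Per-region target means and their per-volume (per-antenna) average."""

    per_region: pd.DataFrame
    volume_mean: float
    group_label: str = ""


@dataclass
class GroupComparison:
    group_a: np.ndarray
    group_b: np.ndarray
    u_statistic: float
    p_value: float
    median_percent_change: float


def segment_marker_regions(
    vol: LabeledVolume, marker_channel: str = "marker", min_voxels: int = 30
) -> list[np.ndarray]:
    """Otsu-threshold the marker channel and return 26-connected component
    masks with at least ``min_voxels`` voxels, ordered by label."""
    if marker_channel not in vol.channels:
        raise KeyError(f"no channel named {marker_channel!r}")
    arr = vol.channels[marker_channel]
    if np.ptp(arr) == 0:
        raise ValueError("no threshold: marker channel is constant")
    thr = filters.threshold_otsu(arr)
    labels = measure.label(arr > thr, connectivity=3)
    masks = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_voxels:
            masks.append(mask)
    return masks


def region_intensity_stats(
    vol: LabeledVolume, masks: list[np.ndarray], target_channel: str = "target"
) -> RegionStats:
    """Mean target intensity per region mask and their per-volume average."""
    if target_channel not in vol.channels:
        raise KeyError(f"no channel named {target_channel!r}")
    target = vol.channels[target_channel]
    rows = []
    for i, mask in enumerate(masks):
        if mask.shape != target.shape:
            raise ValueError("mask shape does not match volume")
        rows.append(
            {
                "region_id": i,
                "voxel_count": int(mask.sum()),
                "target_mean_intensity": float(target[mask].mean()) if mask.any() else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=["region_id", "voxel_count", "target_mean_intensity"])
    vol_mean = float(df["target_mean_intensity"].mean()) if len(df) else np.nan
    return RegionStats(df, vol_mean, vol.group_label)


def normalize_to_control(
    values: np.ndarray, control_values: np.ndarray
) -> np.ndarray:
    """Divide every value by the control-group median (per experiment batch)."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control group is empty")
    med = float(np.median(control_values))
    if med == 0:
        raise ValueError("control median is zero")
    return np.asarray(values, dtype=float) / med


def dilation_positive_fraction(
    volumes: list[LabeledVolume],
    masks: list[list[np.ndarray]],
    target_channel: str = "target",
    positivity_k: float = 2.0,
) -> float:
    """Percentage of cilia whose dilation-mask mean target intensity exceeds
    background mean + ``positivity_k`` * background SD.

    ``masks[i]`` holds the per-cilium dilation masks of ``volumes[i]``;
    background statistics are taken from voxels outside every mask.
    """
    n_total = 0
    n_positive = 0
    for vol, vol_masks in zip(volumes, masks):
        target = vol.channels[target_channel]
        outside = np.ones(target.shape, dtype=bool)
        for m in vol_masks:
            outside &= ~m
        bg_mean = float(target[outside].mean())
        bg_sd = float(target[outside].std())
        cutoff = bg_mean + positivity_k * bg_sd
        for m in vol_masks:
            if not m.any():
                continue
            n_total += 1
            if float(target[m].mean()) > cutoff:
                n_positive += 1
    if n_total == 0:
        raise ValueError("no cilia to score")
    return 100.0 * n_positive / n_total


def _principal_direction(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 points per segment")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("coincident points: no direction defined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def bending_angle(dendrite_pts: np.ndarray, cilium_pts: np.ndarray) -> float:
    """Deviation-from-collinear angle (degrees, in [0, 90]) between the
    principal axes of the dendrite and cilium point sets.

    0 means the cilium continues the dendrite's line; 90 means perpendicular.
    """
    d1 = _principal_direction(dendrite_pts)
    d2 = _principal_direction(cilium_pts)
    cos = np.clip(abs(float(np.dot(d1, d2))), 0.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def compare_groups(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups.

    Uses the exact null distribution when both groups have <= 8 values and no
    ties are present; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a = float(np.median(a))
    change = (
        100.0 * (float(np.median(b)) - med_a) / med_a if med_a != 0 else np.nan
    )
    return GroupComparison(
        group_a=a,
        group_b=b,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_percent_change=change,
    )
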