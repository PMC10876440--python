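"""Kymograph construction and IFT-train kinematics.

A kymograph is a space-time image built by sampling a time-lapse movie
along the ciliary arc (base at arc coordinate 0).  Moving intraflagellar
transport (IFT) trains appear as sloped streaks; the slope is the train
velocity, the streak thickness its length.  This module builds the
kymograph, splits it into anterograde / retrograde / static components by
quadrant Fourier filtering, extracts train tracks, and computes per-train
velocity, length (FWHM), stall, and encounter (pass/pause) statistics.

Conventions
-----------
* anterograde = motion toward increasing arc coordinate (base -> tip)
* kymograph row index = frame (time), column index = arc sample (space),
  both 0-based; arc samples are spaced at 1 pixel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.signal.windows import hann

__all__ = [
    "MovieStack",
    "CiliumPath",
    "Kymograph",
    "DirectionalKymographs",
    "TrainTrack",
    "EncounterEvent",
    "TrainStats",
    "build_kymograph",
    "separate_directions",
    "extract_tracks",
    "track_velocity",
    "detect_stalls",
    "train_length",
    "particles_per_train",
    "find_encounters",
    "summarize_trains",
]

#: default axial repeat spacing of IFT-B particles along a train, nm
DEFAULT_PARTICLE_SPACING_NM = 6.17


@dataclass
class MovieStack:
    """Time-lapse movie: ``data`` has axes (frame, y, x)."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("movie must be a 3D (t, y, x) array with >= 2 frames")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame interval and pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class CiliumPath:
    """Polyline from ciliary base (vertex 0) to tip, in (y, x) pixel coordinates."""

    points: np.ndarray
    width_px: int = 3

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("path needs >= 2 (y, x) vertices")
        if self.arc_length() < 2.0:
            raise ValueError("path arc length must be >= 2 px")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Kymograph:
    """Space-time matrix: rows = frames, columns = arc samples (1 px spacing)."""

    matrix: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("kymograph contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class DirectionalKymographs:
    anterograde: Kymograph
    retrograde: Kymograph
    static: Kymograph


@dataclass
class TrainTrack:
    """One extracted IFT train.

    ``samples`` is an (n, 2) array of (frame, arc_position_um) with subpixel
    positions.  ``velocity_um_s`` is the signed robust (LAD) slope; its sign
    follows the arc coordinate (positive = anterograde).  ``stalls`` are
    (start_frame, end_frame) spans of near-zero motion.
    """

    id: int
    direction: str
    samples: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    velocity_um_s: float = np.nan
    length_nm: float = np.nan
    stalls: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.direction not in ("anterograde", "retrograde"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(self.samples) < 2:
            raise ValueError("track needs >= 2 samples")
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def positions_um(self) -> np.ndarray:
        return self.samples[:, 1]

    def speed_um_s(self) -> float:
        return abs(self.velocity_um_s)


@dataclass
class EncounterEvent:
    retro_id: int
    antero_id: int
    frame: float
    arc_position_um: float
    outcome: str  # "pass" | "pause"
    pause_duration_s: float = 0.0


@dataclass
class TrainStats:
    """Flat summary of a set of tracks, per direction plus encounter fractions."""

    per_direction: dict
    fraction_retro_with_stall: float | None
    fraction_pause_on_encounter: float | None

    def to_frame(self):
        import pandas as pd

        rows = []
        for direction, d in self.per_direction.items():
            row = {"direction": direction}
            row.update(d)
            rows.append(row)
        df = pd.DataFrame(rows)
        df["fraction_retro_with_stall"] = self.fraction_retro_with_stall
        df["fraction_pause_on_encounter"] = self.fraction_pause_on_encounter
        return df


# ---------------------------------------------------------------------------
# kymograph construction


def _sample_path(path: CiliumPath) -> tuple[np.ndarray, np.ndarray]:
    """Resample the polyline at 1 px arc spacing; return points and unit normals."""
    pts = path.points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    s = np.arange(0.0, total + 1e-9, 1.0)
    ys = np.interp(s, arc, pts[:, 0])
    xs = np.interp(s, arc, pts[:, 1])
    samples = np.column_stack([ys, xs])
    # tangents by central differences, normals perpendicular
    tang = np.gradient(samples, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang = tang / norm
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return samples, normals


def build_kymograph(stack: MovieStack, path: CiliumPath) -> Kymograph:
    """Sample the movie along ``path``; value at (t, s) is the maximum over
    ``width_px`` perpendicular offsets at arc position s in frame t."""
    samples, normals = _sample_path(path)
    offsets = np.arange(path.width_px) - (path.width_px - 1) / 2.0
    # coords: (n_samples, n_offsets, 2)
    coords = samples[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    ny, nx = stack.data.shape[1:]
    out_y = (coords[..., 0] < -0.5) | (coords[..., 0] > ny - 0.5)
    out_x = (coords[..., 1] < -0.5) | (coords[..., 1] > nx - 0.5)
    if np.any(out_y | out_x):
        bad_sample = int(np.argwhere(out_y | out_x)[0, 0])
        # map offending arc sample back to nearest original vertex
        pts = path.points
        d = np.linalg.norm(pts - samples[bad_sample], axis=1)
        raise ValueError(
            f"path exits image bounds near vertex {int(np.argmin(d))} "
            f"(arc sample {bad_sample})"
        )
    flat = coords.reshape(-1, 2).T  # (2, n_samples*n_offsets)
    n_s, n_o = coords.shape[:2]
    matrix = np.empty((stack.n_frames, n_s), dtype=float)
    for t in range(stack.n_frames):
        vals = ndimage.map_coordinates(
            stack.data[t].astype(float), flat, order=1, mode="nearest"
        )
        matrix[t] = vals.reshape(n_s, n_o).max(axis=1)
    return Kymograph(matrix, stack.pixel_size_um, stack.frame_interval_s)


# ---------------------------------------------------------------------------
# directional separation


def _quadrant_masks(nt: int, ns: int) -> tuple[np.ndarray, np.ndarray]:
    """Fourier-quadrant weights for anterograde / retrograde components.

    A feature moving toward increasing arc coordinate has its energy in the
    quadrants where sign(f_time) * sign(f_space) < 0.  Zero-frequency and
    Nyquist lines carry no direction; their energy is split evenly so that a
    space-axis flip swaps the two outputs exactly.
    """
    ft = np.fft.fftfreq(nt)[:, None]
    fs = np.fft.fftfreq(ns)[None, :]
    st = np.sign(ft)
    ss = np.sign(fs)
    if nt % 2 == 0:
        st[nt // 2, 0] = 0.0  # Nyquist row is sign-ambiguous
    if ns % 2 == 0:
        ss[0, ns // 2] = 0.0
    prod = st * ss
    antero = np.where(prod < 0, 1.0, np.where(prod == 0, 0.5, 0.0))
    retro = np.where(prod > 0, 1.0, np.where(prod == 0, 0.5, 0.0))
    return antero, retro


def separate_directions(kymo: Kymograph) -> DirectionalKymographs:
    """Split a kymograph into anterograde, retrograde, and static components.

    The static component is the per-column temporal median.  The remainder is
    Hann-windowed, 2D-FFT'd, and the two frequency-quadrant pairs are
    inverse-transformed separately; negative values are clipped to zero.
    """
    m = kymo.matrix
    nt, ns = m.shape
    if nt < 8 or ns < 8:
        raise ValueError("need >= 8 frames and >= 8 spatial samples")
    static = np.median(m, axis=0, keepdims=True)
    resid = m - static
    # reflect-pad so the image sits in the window's well-conditioned centre;
    # reflection keeps the array continuous at the FFT's periodic boundary
    pt, ps = nt // 2, ns // 2
    padded = np.pad(resid, ((pt, nt - pt), (ps, ns - ps)), mode="reflect")
    w2d = np.outer(hann(2 * nt, sym=True), hann(2 * ns, sym=True))
    w2d = np.maximum(w2d, 1e-3)
    spec = np.fft.fft2(padded * w2d)
    mask_a, mask_r = _quadrant_masks(2 * nt, 2 * ns)
    antero = (np.fft.ifft2(spec * mask_a).real / w2d)[pt : pt + nt, ps : ps + ns]
    retro = (np.fft.ifft2(spec * mask_r).real / w2d)[pt : pt + nt, ps : ps + ns]
    antero = np.clip(antero, 0.0, None)
    retro = np.clip(retro, 0.0, None)
    cal = (kymo.pixel_size_um, kymo.frame_interval_s)
    return DirectionalKymographs(
        anterograde=Kymograph(antero, *cal),
        retrograde=Kymograph(retro, *cal),
        static=Kymograph(np.broadcast_to(static, m.shape).copy(), *cal),
    )


# ---------------------------------------------------------------------------
# track extraction


def _component_centroids(
    weights: np.ndarray, labels: np.ndarray, lab: int
) -> np.ndarray:
    """Per-frame intensity-weighted centroid of one connected component."""
    idx = np.argwhere(labels == lab)
    frames = np.unique(idx[:, 0])
    out = np.empty((len(frames), 2))
    for i, t in enumerate(frames):
        cols = idx[idx[:, 0] == t, 1]
        w = weights[t, cols]
        tot = w.sum()
        if tot <= 0:  # equal-intensity plateau fallback: midpoint
            c = cols.mean()
        else:
            c = float((cols * w).sum() / tot)
        out[i] = (t, c)
    return out


def _link_fragments(
    frags: list[np.ndarray],
    max_gap_frames: int,
    link_radius_px: float,
    direction_sign: float,
) -> list[np.ndarray]:
    """Greedy gap-closing: join fragments whose start continues another
    fragment's end either in place (a pause) or along its velocity
    (occlusion).  Links that would jump against the travel direction are
    rejected."""
    frags = sorted(frags, key=lambda a: a[0, 0])
    used = [False] * len(frags)
    merged: list[np.ndarray] = []
    for i, f in enumerate(frags):
        if used[i]:
            continue
        cur = f
        used[i] = True
        extended = True
        while extended:
            extended = False
            t_end, s_end = cur[-1]
            if len(cur) >= 2:
                span = cur[-1, 0] - cur[0, 0]
                v = (cur[-1, 1] - cur[0, 1]) / span if span > 0 else 0.0
            else:
                v = 0.0
            if v * direction_sign < 0:
                v = 0.0  # corrupted fragment slope: fall back to pause-only
            best = None
            for j, g in enumerate(frags):
                if used[j]:
                    continue
                dt = g[0, 0] - t_end
                if dt <= 0 or dt > max_gap_frames:
                    continue
                ds = g[0, 1] - s_end
                if ds * direction_sign < -link_radius_px:
                    continue  # would jump backwards along the track
                # pause hypothesis (stationary) or continued-motion hypothesis
                err = min(abs(ds), abs(ds - v * dt))
                if err <= link_radius_px and (best is None or err < best[0]):
                    best = (err, j)
            if best is not None:
                j = best[1]
                cur = np.vstack([cur, frags[j]])
                used[j] = True
                extended = True
        merged.append(cur)
    return merged


def extract_tracks(
    dk: DirectionalKymographs,
    min_frames: int = 5,
    intensity_k: float = 2.0,
    max_gap_frames: int = 20,
    link_radius_px: float = 3.0,
    v_stall_um_s: float = 0.05,
    min_stall_frames: int = 3,
) -> list[TrainTrack]:
    """Detect trains in each directional kymograph, take 8-connected
    components in (t, s), form per-frame subpixel centroids, close short
    gaps, and keep tracks spanning >= ``min_frames`` frames.

    Each directional kymograph is thresholded at its own mean +
    ``intensity_k`` SD.  Three pruning rules then keep artefacts from
    masquerading as trains: (1) a component must average at least half the
    opposite direction's intensity over its own pixels — the speckle that a
    bright streak's filter ringing leaks into the wrong-direction kymograph
    fails this dominance test, while a genuine train crossing an opposite
    one passes it; (2) components smaller than ``min_component_px`` pixels
    are dropped before linking; (3) a finished track must have samples in at
    least half of the frames it spans (noise chains stitched across gaps are
    sparse; real trains are visible almost every frame, pauses included).
    """
    min_component_px = 8
    dominance_ratio = 0.5
    tracks: list[TrainTrack] = []
    next_id = 0
    struct = np.ones((3, 3), dtype=bool)
    for direction, km, opp in (
        ("anterograde", dk.anterograde, dk.retrograde),
        ("retrograde", dk.retrograde, dk.anterograde),
    ):
        m = km.matrix
        thr = m.mean() + intensity_k * m.std()
        if not np.any(m > thr):
            continue
        # ringing sidelobes sit slightly displaced from the streak they leak
        # from, so the dominance test compares against the local maximum of
        # the opposite direction rather than its value at the same pixel
        opp_local = ndimage.maximum_filter(opp.matrix, size=(3, 5))
        labels, n_lab = ndimage.label(m > thr, structure=struct)
        sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)
        frags = []
        for lab in range(1, n_lab + 1):
            if sizes[lab] < min_component_px:
                continue
            where = labels == lab
            if m[where].mean() < dominance_ratio * opp_local[where].mean():
                continue
            cent = _component_centroids(m, labels, lab)
            if len(cent) >= 2:
                frags.append(cent)
        sign = 1.0 if direction == "anterograde" else -1.0
        for cent in _link_fragments(frags, max_gap_frames, link_radius_px, sign):
            span = cent[-1, 0] - cent[0, 0] + 1
            if span < min_frames or len(cent) < 5:
                continue
            if len(cent) / span < 0.5:
                continue
            # running median tames single-frame centroid noise before
            # slopes and stalls are measured
            cols = ndimage.median_filter(cent[:, 1], size=5, mode="nearest")
            samples = np.column_stack([cent[:, 0], cols * km.pixel_size_um])
            track = TrainTrack(
                id=next_id,
                direction=direction,
                samples=samples,
                frame_interval_s=km.frame_interval_s,
                pixel_size_um=km.pixel_size_um,
            )
            track.stalls = detect_stalls(track, v_stall_um_s, min_stall_frames)
            speed = track_velocity(track)
            sign = 1.0 if direction == "anterograde" else -1.0
            track.velocity_um_s = sign * speed
            tracks.append(track)
            next_id += 1
    return tracks


def _lad_fit(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Least-absolute-deviations line fit, seeded from ordinary least squares."""
    A = np.column_stack([t, np.ones_like(t)])
    beta0, *_ = np.linalg.lstsq(A, s, rcond=None)

    def cost(b):
        return np.abs(s - b[0] * t - b[1]).sum()

    res = optimize.minimize(
        cost,
        beta0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 4000},
    )
    return float(res.x[0]), float(res.x[1])


def track_velocity(track: TrainTrack) -> float:
    """Robust (LAD) travel speed of a track in um/s over its non-stalled
    samples.

    Samples are split into contiguous moving segments at the stall spans and
    each segment gets its own LAD slope; the track speed is the
    duration-weighted median of the segment slopes.  (A single line through
    pause-separated segments would return the chord slope — the average
    including pauses — rather than the speed while moving.)  Returns the
    magnitude; the signed value is kept on the track itself.
    """
    if len(track.samples) < 5:
        raise ValueError("velocity needs >= 5 samples")
    frames = track.frames
    if np.ptp(frames) == 0:
        raise ValueError("degenerate track: all samples in one frame")
    keep = np.ones(len(frames), dtype=bool)
    for start, end in track.stalls:
        keep &= ~((frames >= start) & (frames <= end))
    if keep.sum() < 3:  # fully stalled track: slope over everything
        keep[:] = True
    return abs(
        _travel_speed(
            frames, track.positions_um, keep, track.frame_interval_s
        )
    )


def _travel_speed(
    frames: np.ndarray, positions: np.ndarray, keep: np.ndarray, dt_s: float
) -> float:
    """Duration-weighted median of per-segment LAD slopes over the kept
    (non-stalled) samples; contiguous runs of kept samples form segments."""
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        idx = np.arange(len(frames))
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    segments = np.split(idx, breaks + 1)
    slopes, weights = [], []
    for seg in segments:
        if len(seg) < 3 or frames[seg[-1]] == frames[seg[0]]:
            continue
        t = frames[seg] * dt_s
        s = positions[seg]
        slope, _ = _lad_fit(t, s)
        slopes.append(slope)
        weights.append(t[-1] - t[0])
    if not slopes:
        t = frames[idx] * dt_s
        slope, _ = _lad_fit(t, positions[idx])
        return float(slope)
    order = np.argsort(slopes)
    slopes_a = np.asarray(slopes)[order]
    weights_a = np.asarray(weights)[order]
    cum = np.cumsum(weights_a)
    i_med = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(slopes_a[min(i_med, len(slopes_a) - 1)])


def detect_stalls(
    track: TrainTrack,
    v_stall_um_s: float = 0.05,
    min_stall_frames: int = 3,
    relative_fraction: float = 0.25,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive low inter-sample speeds covering at least
    ``min_stall_frames`` frames.

    Speeds are measured by central differences over +/- 1 sample, which
    suppresses single-frame centroid jitter.  The stall threshold is the
    larger of ``v_stall_um_s`` and ``relative_fraction`` times the track's
    own travel speed: directional filtering renders a paused sub-resolution
    train as slowed rather than perfectly stationary, so an absolute
    threshold alone misses genuine pauses on fast tracks.  The travel speed
    and the stall set are co-estimated by a short fixed-point iteration
    (LAD slope over non-stalled samples).
    """
    f = track.frames
    s = track.positions_um
    n = len(f)
    if n < 2:
        return []
    half = min(1, n - 1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    span_s = (f[hi] - f[lo]) * track.frame_interval_s
    speeds = np.abs(s[hi] - s[lo]) / span_s

    def runs(slow: np.ndarray) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        i = 0
        while i < n:
            if slow[i]:
                j = i
                while j + 1 < n and slow[j + 1]:
                    j += 1
                start, end = int(f[i]), int(f[j])
                if end - start >= min_stall_frames:
                    out.append((start, end))
                i = j + 1
            else:
                i += 1
        return out

    t_s = f * track.frame_interval_s
    chord, _ = _lad_fit(t_s, s)
    # a track that pauses often has a misleadingly low chord slope; the upper
    # quartile of window speeds still reflects the moving segments
    speed_est = max(abs(chord), float(np.percentile(speeds, 75)))
    stalls: list[tuple[int, int]] = []
    for _ in range(3):
        thr = max(v_stall_um_s, relative_fraction * speed_est)
        stalls = runs(speeds < thr)
        keep = np.ones(n, dtype=bool)
        for start, end in stalls:
            keep &= ~((f >= start) & (f <= end))
        speed_est = abs(
            _travel_speed(f, s, keep, track.frame_interval_s)
        )
    return stalls


def train_length(
    track: TrainTrack, kymo: Kymograph, window_px: int = 20
) -> float:
    """Mean FWHM of the spatial intensity profile through the track, in nm.

    Per sampled frame the background-subtracted profile of the (merged)
    kymograph row is probed around the track position; the full width at half
    maximum is found by linear interpolation.  Frames whose profile never
    falls below half maximum inside a ``window_px`` window are skipped.
    """
    m = kymo.matrix
    nt, ns = m.shape
    half_w = window_px // 2
    widths = []
    for frame, pos_um in track.samples:
        t = int(round(frame))
        if not (0 <= t < nt):
            raise ValueError("track sample outside kymograph bounds")
        col = pos_um / kymo.pixel_size_um
        c = int(round(col))
        if not (0 <= c < ns):
            raise ValueError("track sample outside kymograph bounds")
        row = m[t].astype(float)
        prof = row - np.median(row)
        lo, hi = max(0, c - half_w), min(ns, c + half_w + 1)
        seg = prof[lo:hi]
        pk_rel = int(np.argmax(seg[max(0, c - lo - 2) : c - lo + 3])) + max(
            0, c - lo - 2
        )
        peak = seg[pk_rel]
        if peak <= 0:
            continue
        half = peak / 2.0
        # walk outward to half-max crossings, subpixel by linear interpolation
        left = None
        for i in range(pk_rel, 0, -1):
            if seg[i - 1] < half <= seg[i]:
                left = (i - 1) + (half - seg[i - 1]) / (seg[i] - seg[i - 1])
                break
        right = None
        for i in range(pk_rel, len(seg) - 1):
            if seg[i + 1] < half <= seg[i]:
                right = i + (seg[i] - half) / (seg[i] - seg[i + 1])
                break
        if left is None or right is None:
            continue  # profile never falls below half max inside the window
        widths.append(right - left)
    if not widths:
        raise ValueError("no frame yielded a valid FWHM")
    return float(np.mean(widths) * kymo.pixel_size_um * 1000.0)


def particles_per_train(
    length_nm: float, spacing_nm: float = DEFAULT_PARTICLE_SPACING_NM
) -> int:
    """Number of IFT-B particles in a train of the given length, assuming one
    particle per ``spacing_nm`` of train length (axial repeat of the IFT-B
    polymer)."""
    if length_nm < 0:
        raise ValueError("length must be >= 0")
    if spacing_nm <= 0:
        raise ValueError("spacing must be > 0")
    return int(round(length_nm / spacing_nm))


# ---------------------------------------------------------------------------
# encounters


def find_encounters(
    tracks: list[TrainTrack],
    space_tol_px: float = 2.0,
    time_tol_frames: int = 2,
    stall_smear_frames: int = 4,
) -> list[EncounterEvent]:
    """Pair every retrograde track against every anterograde track and emit
    one event per trajectory intersection.

    The outcome is ``pause`` when the retrograde track either has a stall
    overlapping [t* - tol, t* + tol] around the crossing frame t*, or moves
    at less than 50% of its own travel speed in the +/- 5 frames around t*;
    otherwise ``pass``.  The stall tolerance is ``time_tol_frames`` widened
    by ``stall_smear_frames``, the systematic onset delay of stall detection
    (its speed window smooths the moving-to-paused transition over a few
    frames); the local-speed test catches pauses whose stall run fell below
    the minimum-length cut.

    Crossings at a track's very first or last sample are rejected, as are
    pairs involving tracks spanning fewer than ``min_span_frames`` frames:
    short track stubs at the movie or cilium boundaries otherwise produce
    spurious events.
    """
    interior_frames = 1
    min_span_frames = 10
    retro = [t for t in tracks if t.direction == "retrograde"]
    antero = [t for t in tracks if t.direction == "anterograde"]
    events: list[EncounterEvent] = []
    retro = [t for t in retro if t.frames[-1] - t.frames[0] >= min_span_frames]
    antero = [t for t in antero if t.frames[-1] - t.frames[0] >= min_span_frames]
    for r in retro:
        for a in antero:
            t0 = max(r.frames[0], a.frames[0])
            t1 = min(r.frames[-1], a.frames[-1])
            if t1 - t0 < 1:
                continue
            grid = np.arange(np.ceil(t0), np.floor(t1) + 1)
            if len(grid) < 2:
                continue
            sr = np.interp(grid, r.frames, r.positions_um)
            sa = np.interp(grid, a.frames, a.positions_um)
            d = sr - sa
            cross = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) <= 0)[0]
            if len(cross) == 0:
                # near-touch within tolerance also counts
                i_min = int(np.argmin(np.abs(d)))
                if abs(d[i_min]) > space_tol_px * r.pixel_size_um:
                    continue
                t_star = float(grid[i_min])
                s_star = float((sr[i_min] + sa[i_min]) / 2.0)
            else:
                i = int(cross[0])
                denom = d[i] - d[i + 1]
                frac = d[i] / denom if denom != 0 else 0.5
                t_star = float(grid[i] + frac)
                s_star = float(sr[i] + frac * (sr[i + 1] - sr[i]))
            if (
                t_star - max(r.frames[0], a.frames[0]) < interior_frames
                or min(r.frames[-1], a.frames[-1]) - t_star < interior_frames
            ):
                continue
            outcome = "pass"
            pause_s = 0.0
            tol = time_tol_frames + stall_smear_frames
            for start, end in r.stalls:
                if start - tol <= t_star <= end + tol:
                    outcome = "pause"
                    pause_s = (end - start) * r.frame_interval_s
                    break
            if outcome == "pass":
                lo_f = max(r.frames[0], t_star - 5)
                hi_f = min(r.frames[-1], t_star + 5)
                if hi_f - lo_f >= 3:
                    s0, s1 = np.interp([lo_f, hi_f], r.frames, r.positions_um)
                    local = abs(s1 - s0) / ((hi_f - lo_f) * r.frame_interval_s)
                    if local < 0.5 * max(r.speed_um_s(), 0.3):
                        outcome = "pause"
                        pause_s = (hi_f - lo_f) * r.frame_interval_s
            events.append(
                EncounterEvent(r.id, a.id, t_star, s_star, outcome, pause_s)
            )
    return events


# ---------------------------------------------------------------------------
# summary


def _direction_summary(tracks: list[TrainTrack], spacing_nm: float) -> dict:
    speeds = np.array([t.speed_um_s() for t in tracks])
    lengths = np.array([t.length_nm for t in tracks])
    lengths = lengths[np.isfinite(lengths)]
    d: dict = {"n_tracks": len(tracks)}
    if len(speeds):
        q1, q3 = np.percentile(speeds, [25, 75])
        d.update(
            velocity_median_um_s=float(np.median(speeds)),
            velocity_mean_um_s=float(np.mean(speeds)),
            velocity_iqr_um_s=float(q3 - q1),
        )
    if len(lengths):
        d.update(
            length_mean_nm=float(np.mean(lengths)),
            length_min_nm=float(np.min(lengths)),
            length_max_nm=float(np.max(lengths)),
            particles_mean=float(
                np.mean([particles_per_train(x, spacing_nm) for x in lengths])
            ),
        )
    return d


def summarize_trains(
    tracks: list[TrainTrack],
    encounters: list[EncounterEvent] | None = None,
    spacing_nm: float = DEFAULT_PARTICLE_SPACING_NM,
) -> TrainStats:
    """Per-direction velocity/length/particle summaries plus stall and
    encounter-pause fractions.  Fractions are ``None`` when undefined."""
    encounters = encounters or []
    per_dir = {}
    for direction in ("anterograde", "retrograde"):
        sub = [t for t in tracks if t.direction == direction]
        per_dir[direction] = _direction_summary(sub, spacing_nm)
    retro = [t for t in tracks if t.direction == "retrograde"]
    frac_stall = (
        float(np.mean([1.0 if t.stalls else 0.0 for t in retro])) if retro else None
    )
    frac_pause = (
        float(np.mean([1.0 if e.outcome == "pause" else 0.0 for e in encounters]))
        if encounters
        else None
    )
    return TrainStats(per_dir, frac_stall, frac_pause)
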