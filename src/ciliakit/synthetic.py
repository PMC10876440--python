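"""Synthetic-data generators with known ground truth.

Three families of inputs are emulated so that every downstream analysis can
be tested without external recordings:

* bidirectional sub-resolution IFT trains moving on a 1D ciliary track,
  rendered with a Gaussian PSF and Poisson photon noise
  (:func:`simulate_ift_movie`);
* thermal (or actively amplified) harmonic-oscillator displacement traces of
  the antennal sound receiver (:func:`simulate_thermal_trace`) and forced
  tone-stimulus response sweeps (:func:`simulate_forced_responses`);
* two-channel 3D image volumes with marker-defined elongated regions and a
  configurable target-channel reduction (:func:`simulate_quant_volume`).

Every generator is deterministic given (config, seed) and returns a
:class:`GroundTruth` record alongside its output.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .kymo import MovieStack
from .mechanics import (
    BOLTZMANN_J_PER_K,
    DEFAULT_MASS_KG,
    MechTrace,
    StimulusResponse,
)
from .quant import LabeledVolume

__all__ = [
    "IFTSimConfig",
    "MechSimConfig",
    "TrainRecord",
    "EncounterRecord",
    "GroundTruth",
    "simulate_ift_movie",
    "simulate_thermal_trace",
    "simulate_forced_responses",
    "simulate_quant_volume",
]


@dataclass
class IFTSimConfig:
    """Parameters of the IFT-movie generator.

    Defaults follow the live-imaging study conditions: 120 ms frame interval,
    anterograde trains at 0.22 um/s averaging 358 nm, retrograde trains at
    1.2 um/s averaging 237 nm, and 76% of retrograde trains pausing when they
    encounter an anterograde train.  The live-imaging pixel size is not
    printed in the source protocol; 0.13 um/px is adopted (configurable).
    """

    n_frames: int = 500
    frame_interval_s: float = 0.12
    pixel_size_um: float = 0.13
    cilium_length_um: float = 5.0
    antero_speed_um_s: float = 0.22
    retro_speed_um_s: float = 1.2
    antero_injection_rate_hz: float = 0.06
    retro_injection_rate_hz: float = 0.08
    antero_length_nm: float = 358.0
    retro_length_nm: float = 237.0
    length_spread_nm: float = 60.0
    pause_prob: float = 0.76
    pause_duration_s: float = 1.2
    psf_sigma_um: float = 0.15
    background: float = 20.0
    photons_per_train: float = 2000.0
    read_noise_sd: float = 0.0
    image_height_px: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in (
            "frame_interval_s",
            "pixel_size_um",
            "cilium_length_um",
            "antero_speed_um_s",
            "retro_speed_um_s",
            "antero_length_nm",
            "retro_length_nm",
            "psf_sigma_um",
            "photons_per_train",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("antero_injection_rate_hz", "retro_injection_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must lie in [0, 1]")
        if self.pause_duration_s < 0:
            raise ValueError("pause_duration_s must be >= 0")
        # cilium must be resolvable: at least two PSF FWHMs long
        if self.cilium_length_um < 2 * 2.355 * self.psf_sigma_um:
            raise ValueError("cilium shorter than two PSF widths")


@dataclass
class MechSimConfig:
    """Parameters of the antennal-oscillator generator.

    ``active_force_factor`` multiplies the thermal force-noise amplitude:
    1 is a passive receiver in equilibrium; a > 1 emulates active
    amplification (fluctuation energy scales as a^2).
    """

    mass_kg: float = DEFAULT_MASS_KG
    f0_hz: float = 300.0
    Q: float = 2.0
    temperature_K: float = 298.0
    active_force_factor: float = 1.0
    duration_s: float = 60.0
    sample_rate_hz: float = 6000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("mass_kg", "f0_hz", "Q", "duration_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.temperature_K < 0:
            raise ValueError("temperature must be >= 0")
        if self.active_force_factor < 0:
            raise ValueError("active_force_factor must be >= 0")
        if self.sample_rate_hz < 20.0 * self.f0_hz:
            raise ValueError("sample_rate must be >= 20 * f0 (integration stability)")


@dataclass
class TrainRecord:
    """Ground-truth trajectory of one simulated train."""

    id: int
    direction: str
    entry_frame: int
    speed_um_s: float
    length_nm: float
    frames: list[int] = field(default_factory=list)
    positions_um: list[float] = field(default_factory=list)
    pause_events: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class EncounterRecord:
    retro_id: int
    antero_id: int
    frame: float
    arc_um: float
    outcome: str


@dataclass
class GroundTruth:
    """Serializable truth record accompanying every generated object."""

    true_tracks: list[TrainRecord] = field(default_factory=list)
    true_encounters: list[EncounterRecord] = field(default_factory=list)
    true_mech: dict = field(default_factory=dict)
    true_quant: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"cannot serialize {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=default, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        tracks = [TrainRecord(**{**t, "pause_events": [tuple(p) for p in t["pause_events"]]})
                  for t in d.get("true_tracks", [])]
        encounters = [EncounterRecord(**e) for e in d.get("true_encounters", [])]
        return cls(tracks, encounters, d.get("true_mech", {}), d.get("true_quant", {}))


# ---------------------------------------------------------------------------
# IFT movie


def _boxcar_gauss_profile(
    x_px: np.ndarray, center_px: float, length_px: float, sigma_px: float
) -> np.ndarray:
    """Boxcar of total mass 1 convolved with a Gaussian PSF (closed form)."""
    a = (x_px - center_px + length_px / 2.0) / (np.sqrt(2.0) * sigma_px)
    b = (x_px - center_px - length_px / 2.0) / (np.sqrt(2.0) * sigma_px)
    return (special.erf(a) - special.erf(b)) / (2.0 * length_px)


def simulate_ift_movie(
    config: IFTSimConfig, apply_noise: bool = True
) -> tuple[MovieStack, GroundTruth]:
    """Simulate bidirectional IFT trains on a straight 1D ciliary track.

    Anterograde trains enter at the base (arc 0) and run tip-ward at the
    configured speed; retrograde trains enter at the tip and run base-ward.
    When a retrograde train crosses an anterograde one it pauses with
    probability ``pause_prob`` for ``pause_duration_s`` (anterograde trains
    never pause).  Trains are rendered as boxcars of their length convolved
    with a Gaussian PSF, placed on a Gaussian transverse profile; Poisson
    photon noise (and optional Gaussian read noise) is applied last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_s
    L = config.cilium_length_um
    px = config.pixel_size_um
    pause_frames = max(1, int(round(config.pause_duration_s / dt))) if (
        config.pause_duration_s > 0
    ) else 0

    active: list[dict] = []
    done: list[dict] = []
    encounters: list[EncounterRecord] = []
    next_id = 0
    speed = {"anterograde": config.antero_speed_um_s, "retrograde": -config.retro_speed_um_s}
    mean_len = {"anterograde": config.antero_length_nm, "retrograde": config.retro_length_nm}
    exit_margin = 3.0 * config.psf_sigma_um + 1.5 * max(
        config.antero_length_nm, config.retro_length_nm
    ) / 1000.0

    for t in range(config.n_frames):
        # inject new trains
        for direction, rate in (
            ("anterograde", config.antero_injection_rate_hz),
            ("retrograde", config.retro_injection_rate_hz),
        ):
            for _ in range(rng.poisson(rate * dt)):
                length = float(
                    np.clip(
                        rng.normal(mean_len[direction], config.length_spread_nm),
                        40.0,
                        None,
                    )
                )
                active.append(
                    {
                        "rec": TrainRecord(
                            id=next_id,
                            direction=direction,
                            entry_frame=t,
                            speed_um_s=abs(speed[direction]),
                            length_nm=length,
                        ),
                        "pos": 0.0 if direction == "anterograde" else L,
                        "pause_until": -1,
                        "partners": set(),
                    }
                )
                next_id += 1
        # record positions at this frame
        for tr in active:
            tr["rec"].frames.append(t)
            tr["rec"].positions_um.append(tr["pos"])
        # advance to t+1
        prev = {tr["rec"].id: tr["pos"] for tr in active}
        for tr in active:
            if t + 1 >= tr["pause_until"]:
                tr["pos"] += speed[tr["rec"].direction] * dt
        # retro-antero crossings between t and t+1
        retro = [tr for tr in active if tr["rec"].direction == "retrograde"]
        antero = [tr for tr in active if tr["rec"].direction == "anterograde"]
        for r in retro:
            for a in antero:
                if a["rec"].id in r["partners"]:
                    continue
                d0 = prev[r["rec"].id] - prev[a["rec"].id]
                d1 = r["pos"] - a["pos"]
                if d0 * d1 > 0:
                    continue
                r["partners"].add(a["rec"].id)
                frac = d0 / (d0 - d1) if d0 != d1 else 0.5
                t_star = t + frac
                s_star = prev[r["rec"].id] + frac * (r["pos"] - prev[r["rec"].id])
                if t + 1 < r["pause_until"]:
                    # crossing hit an already-paused train
                    outcome = "pause"
                elif pause_frames > 0 and rng.random() < config.pause_prob:
                    outcome = "pause"
                    r["pause_until"] = t + 1 + pause_frames
                    r["pos"] = prev[r["rec"].id]  # freeze at pre-step position
                    r["rec"].pause_events.append(
                        (t + 1, t + 1 + pause_frames, float(r["pos"]))
                    )
                else:
                    outcome = "pass"
                encounters.append(
                    EncounterRecord(
                        r["rec"].id, a["rec"].id, float(t_star), float(s_star), outcome
                    )
                )
        # retire trains that left the track
        still = []
        for tr in active:
            if -exit_margin <= tr["pos"] <= L + exit_margin:
                still.append(tr)
            else:
                done.append(tr)
        active = still
    done.extend(active)
    done.sort(key=lambda tr: tr["rec"].id)
    records = [tr["rec"] for tr in done]

    # --- render ---------------------------------------------------------
    margin_px = int(np.ceil(exit_margin / px)) + 2
    nx = int(round(L / px)) + 2 * margin_px
    ny = config.image_height_px
    y0 = (ny - 1) / 2.0
    sigma_px = config.psf_sigma_um / px
    x_px = np.arange(nx, dtype=float)
    y_gauss = np.exp(-((np.arange(ny) - y0) ** 2) / (2.0 * sigma_px**2))
    y_gauss /= y_gauss.sum()
    clean = np.full((config.n_frames, ny, nx), float(config.background))
    for rec in records:
        len_px = max(rec.length_nm / 1000.0 / px, 1e-3)
        # fluorophore content scales with the number of IFT particles, hence
        # with train length: photons_per_train refers to a train of the mean
        # anterograde length, so longer (anterograde) trains are brighter in
        # total while every train has the same brightness per unit length
        photons = config.photons_per_train * rec.length_nm / config.antero_length_nm
        for f, pos in zip(rec.frames, rec.positions_um):
            c = margin_px + pos / px
            prof = _boxcar_gauss_profile(x_px, c, len_px, sigma_px)
            clean[f] += photons * y_gauss[:, None] * prof[None, :]
    if apply_noise:
        data = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if config.read_noise_sd > 0:
            data += rng.normal(0.0, config.read_noise_sd, size=data.shape)
            data = np.clip(data, 0.0, None)
    else:
        data = clean
    stack = MovieStack(data, config.frame_interval_s, config.pixel_size_um)
    truth = GroundTruth(
        true_tracks=records,
        true_encounters=encounters,
        true_quant={"margin_px": margin_px},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# mechanics


def simulate_thermal_trace(config: MechSimConfig) -> tuple[MechTrace, GroundTruth]:
    """Underdamped Langevin trajectory of the antennal oscillator.

    Integrates m x'' = -Ks x - gamma x' + a F_th(t) with Ks = m (2 pi f0)^2,
    gamma = m 2 pi f0 / Q and one-sided thermal force PSD 4 gamma kB T, using
    a semi-implicit (symplectic) Euler step at dt = 1/(50 f0), then decimates
    to ``sample_rate_hz``.  Expected fluctuation energy is a^2 kB T.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.mass_kg
    w0 = 2.0 * np.pi * config.f0_hz
    Ks = m * w0**2
    gamma = m * w0 / config.Q
    # integration rate: integer multiple of the output rate, >= 50 f0
    factor = int(np.ceil(50.0 * config.f0_hz / config.sample_rate_hz))
    fs_sim = factor * config.sample_rate_hz
    dt = 1.0 / fs_sim
    if dt > 1.0 / (20.0 * config.f0_hz):
        raise ValueError("integration step too coarse (dt > 1/(20 f0))")
    n_sim = int(round(config.duration_s * fs_sim))
    # discrete white force: two-sided PSD 2 gamma kB T -> var 2 gamma kB T / dt
    amp = config.active_force_factor * np.sqrt(
        2.0 * gamma * BOLTZMANN_J_PER_K * config.temperature_K / dt
    )
    force = amp * rng.standard_normal(n_sim)
    # semi-implicit Euler collapses to a linear 2nd-order recursion in x:
    #   x[n+1] = (2 - dt*g/m - dt^2 w0^2) x[n] - (1 - dt*g/m) x[n-1] + dt^2/m F[n]
    c = dt * gamma / m
    a1 = -(2.0 - c - (dt * w0) ** 2)
    a2 = 1.0 - c
    x = signal.lfilter([dt**2 / m], [1.0, a1, a2], force)
    x = x[::factor]
    trace = MechTrace(
        values=x,
        sample_rate_hz=config.sample_rate_hz,
        kind="displacement_m",
        temperature_K=config.temperature_K,
    )
    truth = GroundTruth(
        true_mech={
            "f0_hz": config.f0_hz,
            "Q": config.Q,
            "Ks_N_per_m": Ks,
            "gamma": gamma,
            "mass_kg": m,
            "expected_energy_kBT": config.active_force_factor**2,
            "expected_msd_m2": (
                config.active_force_factor**2
                * BOLTZMANN_J_PER_K
                * config.temperature_K
                / Ks
            ),
        }
    )
    return trace, truth


def default_spv_levels(
    spv_min_m_s: float = 1.0e-6, span_db: float = 96.0, step_db: float = 6.0
) -> np.ndarray:
    """Stimulus particle-velocity ladder: ``span_db`` in ``step_db`` steps
    (the default 96 dB / 6 dB sweep has 17 levels)."""
    n = int(round(span_db / step_db)) + 1
    return spv_min_m_s * 10.0 ** (step_db * np.arange(n) / 20.0)


def simulate_forced_responses(
    config: MechSimConfig,
    spv_levels: np.ndarray | None = None,
    gain_max: float = 1.0,
    gain_min: float = 1.0,
) -> StimulusResponse:
    """Tone-stimulus displacement amplitudes across an intensity sweep.

    The per-level displacement follows X = SPV * g(SPV) / (2 pi f0) where the
    gain g interpolates sigmoidally on log-SPV from ``gain_max`` at the lowest
    level to ``gain_min`` at the highest (a compressive, actively amplified
    receiver); gain_max = gain_min models a passive linear receiver.
    """
    config.validate()
    if spv_levels is None:
        spv_levels = default_spv_levels()
    spv = np.asarray(spv_levels, dtype=float)
    if spv.size == 0:
        raise ValueError("empty stimulus level list")
    if np.any(spv <= 0) or np.any(np.diff(spv) <= 0):
        raise ValueError("spv_levels must be positive and ascending")
    if not gain_max >= gain_min > 0:
        raise ValueError("need gain_max >= gain_min > 0")
    logs = np.log10(spv)
    if logs[-1] > logs[0]:
        mid = (logs[0] + logs[-1]) / 2.0
        width = (logs[-1] - logs[0]) / 12.0  # saturates at the sweep ends
        g = gain_min + (gain_max - gain_min) / (1.0 + np.exp((logs - mid) / width))
    else:
        g = np.full_like(logs, gain_max)
    disp = spv * g / (2.0 * np.pi * config.f0_hz)
    return StimulusResponse(spv, disp, config.f0_hz)


# ---------------------------------------------------------------------------
# quantification volumes


def simulate_quant_volume(
    reduction_fraction: float,
    n_regions: int = 8,
    seed: int = 0,
    n_per_group: int = 10,
    shape: tuple[int, int, int] = (16, 48, 48),
    marker_level: float = 120.0,
    target_level: float = 100.0,
    background: float = 10.0,
    voxel_noise_sd: float = 4.0,
    volume_cv: float = 0.04,
    dilation_positive_fraction: float | None = None,
) -> tuple[list[LabeledVolume], GroundTruth]:
    """Two groups of two-channel volumes with a known target-channel reduction.

    Each volume carries ``n_regions`` elongated (cilium-like) regions defined
    by the marker channel.  The target channel inside the regions of the
    "knockdown" group is (1 - reduction_fraction) times the control level;
    a per-volume lognormal staining factor (CV ``volume_cv``) and additive
    voxel noise emulate experiment-to-experiment variability.  If
    ``dilation_positive_fraction`` is set, that fraction of regions carries a
    bright target spot in a small "ciliary dilation" sub-mask at the region
    tip, and the truth records which.
    """
    if not 0.0 <= reduction_fraction < 1.0:
        raise ValueError("reduction_fraction must lie in [0, 1)")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    volumes: list[LabeledVolume] = []
    truth_masks = []
    truth_dilation = []
    groups = ["control"] * n_per_group + ["knockdown"] * n_per_group
    # lay regions on a grid with jitter so masks stay disjoint and
    # non-adjacent (>= 2 empty planes between rows under 26-connectivity)
    n_side = int(np.ceil(np.sqrt(n_regions)))
    n_rows = int(np.ceil(n_regions / n_side))
    cell_x = nx // n_side
    cell_z = max((nz - 4) // max(n_rows, 1), 5)
    for group in groups:
        marker = np.full(shape, background, dtype=float)
        target = np.full(shape, background, dtype=float)
        labels = np.zeros(shape, dtype=np.int32)
        factor = rng.lognormal(0.0, volume_cv)
        level = target_level * factor
        if group == "knockdown":
            level *= 1.0 - reduction_fraction
        dil_flags = []
        for k in range(n_regions):
            gz, gx = divmod(k, n_side)
            z0 = min(2 + gz * cell_z + rng.integers(0, 2), nz - 3)
            x0 = int(np.clip(gx * cell_x + cell_x // 2 + rng.integers(-1, 2), 2, nx - 3))
            y_start = int(rng.integers(4, 10))
            y_len = int(rng.integers(18, min(30, ny - y_start - 2)))
            zz, yy, xx = np.ogrid[:nz, :ny, :nx]
            body = (
                (np.abs(zz - z0) <= 1)
                & (yy >= y_start)
                & (yy < y_start + y_len)
                & (np.abs(xx - x0) <= 1)
            )
            labels[body] = k + 1
            marker[body] = marker_level
            target[body] = level
            if dilation_positive_fraction is not None:
                # small dilation sub-mask at the region tip
                dil = (
                    (np.abs(zz - z0) <= 1)
                    & (yy >= y_start + y_len)
                    & (yy < y_start + y_len + 3)
                    & (np.abs(xx - x0) <= 1)
                )
                positive = bool(rng.random() < dilation_positive_fraction)
                if positive:
                    target[dil] = level * 2.0
                dil_flags.append((dil, positive))
        marker += rng.normal(0.0, voxel_noise_sd, size=shape)
        target += rng.normal(0.0, voxel_noise_sd, size=shape)
        volumes.append(
            LabeledVolume(
                channels={
                    "marker": np.clip(marker, 0, None),
                    "target": np.clip(target, 0, None),
                },
                voxel_size_um=(0.4, 0.13, 0.13),
                group_label=group,
            )
        )
        truth_masks.append(labels)
        truth_dilation.append(dil_flags)
    truth = GroundTruth(
        true_quant={
            "reduction_fraction": reduction_fraction,
            "expected_ratio": 1.0 - reduction_fraction,
            "groups": groups,
            "region_masks": truth_masks,
            "dilation": truth_dilation,
            "n_regions": n_regions,
        }
    )
    return volumes, truth
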