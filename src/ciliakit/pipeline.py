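"""Reproducible runs: configuration, stage orchestration, and manifests.

A :class:`RunConfig` names the stages to execute and the parameter blocks for
each module; a single mandatory seed is expanded into independent per-stage
streams (inserting a stage does not perturb the randomness of the others).
Every output file is listed, with its SHA-256, in ``manifest.json``; rerunning
the same config and seed reproduces identical tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, kymo, mechanics, quant, synthetic

__all__ = ["RunConfig", "ResultBundle", "run_pipeline"]

KNOWN_STAGES = (
    "simulate_ift",
    "analyze_kymo",
    "simulate_mech",
    "analyze_mech",
    "simulate_quant",
    "quantify",
)

# independent, stable per-stage seed offsets derived from the global seed
_STAGE_STREAM = {name: i for i, name in enumerate(KNOWN_STAGES)}


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    stages: list[str]
    synthetic: dict = field(default_factory=dict)
    kymo: dict = field(default_factory=dict)
    mechanics: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must declare a seed")
        cfg = cls(**d)
        for st in cfg.stages:
            if st not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {st!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultBundle:
    out_dir: Path
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.out_dir / name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([global_seed, _STAGE_STREAM[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_simulate_ift(cfg: RunConfig, out: Path) -> list[Path]:
    params = dict(cfg.synthetic.get("ift", {}))
    params.setdefault("seed", _stage_seed(cfg.seed, "simulate_ift"))
    sim = synthetic.IFTSimConfig(**params)
    stack, truth = synthetic.simulate_ift_movie(sim)
    movie_path = out / "ift_movie.tif"
    truth_path = out / "ift_truth.json"
    io.write_movie(stack, movie_path)
    io.write_truth(truth, truth_path)
    return [movie_path, truth_path]


def _stage_analyze_kymo(cfg: RunConfig, out: Path) -> list[Path]:
    params = cfg.kymo
    movie = cfg.inputs.get("movie", str(out / "ift_movie.tif"))
    stack = io.read_movie(
        movie,
        pixel_size_um=params.get("pixel_size_um"),
        frame_interval_s=params.get("frame_interval_s"),
    )
    path_file = cfg.inputs.get("path")
    if path_file:
        pts = pd.read_csv(path_file)[["y", "x"]].to_numpy()
    else:  # default: straight horizontal path through the image centre row
        ny, nx = stack.data.shape[1:]
        pts = np.array([[(ny - 1) / 2, 0.0], [(ny - 1) / 2, nx - 1.0]])
    path = kymo.CiliumPath(pts, width_px=int(params.get("width_px", 3)))
    km = kymo.build_kymograph(stack, path)
    dk = kymo.separate_directions(km)
    tracks = kymo.extract_tracks(
        dk,
        min_frames=int(params.get("min_frames", 5)),
        intensity_k=float(params.get("intensity_k", 2.0)),
    )
    for t in tracks:
        try:
            t.length_nm = kymo.train_length(t, km)
        except ValueError:
            t.length_nm = float("nan")
    encounters = kymo.find_encounters(
        tracks,
        space_tol_px=float(params.get("space_tol_px", 2.0)),
        time_tol_frames=int(params.get("time_tol_frames", 2)),
    )
    stats = kymo.summarize_trains(tracks, encounters)
    files = []
    io.write_kymograph(km, out / "kymograph.tif")
    files.append(out / "kymograph.tif")
    track_rows = [
        {
            "id": t.id,
            "direction": t.direction,
            "velocity_um_s": t.velocity_um_s,
            "speed_um_s": t.speed_um_s(),
            "length_nm": t.length_nm,
            "n_samples": len(t.samples),
            "start_frame": t.frames[0],
            "end_frame": t.frames[-1],
            "n_stalls": len(t.stalls),
        }
        for t in tracks
    ]
    pd.DataFrame(
        track_rows,
        columns=[
            "id", "direction", "velocity_um_s", "speed_um_s", "length_nm",
            "n_samples", "start_frame", "end_frame", "n_stalls",
        ],
    ).to_csv(out / "tracks.csv", index=False)
    files.append(out / "tracks.csv")
    enc_rows = [dataclasses.asdict(e) for e in encounters]
    pd.DataFrame(
        enc_rows,
        columns=[
            "retro_id", "antero_id", "frame", "arc_position_um",
            "outcome", "pause_duration_s",
        ],
    ).to_csv(out / "encounters.csv", index=False)
    files.append(out / "encounters.csv")
    stats.to_frame().to_csv(out / "train_stats.csv", index=False)
    files.append(out / "train_stats.csv")
    return files


def _stage_simulate_mech(cfg: RunConfig, out: Path) -> list[Path]:
    params = dict(cfg.synthetic.get("mech", {}))
    params.setdefault("seed", _stage_seed(cfg.seed, "simulate_mech"))
    sim = synthetic.MechSimConfig(**params)
    trace, truth = synthetic.simulate_thermal_trace(sim)
    io.write_trace(trace, out / "mech_trace.csv")
    io.write_truth(truth, out / "mech_truth.json")
    gain_block = cfg.synthetic.get("gain", {})
    files = [out / "mech_trace.csv", out / "mech_truth.json"]
    if gain_block:
        resp = synthetic.simulate_forced_responses(
            sim,
            gain_max=float(gain_block.get("gain_max", 1.0)),
            gain_min=float(gain_block.get("gain_min", 1.0)),
        )
        io.write_responses(resp, out / "responses.csv")
        files.append(out / "responses.csv")
    return files


def _stage_analyze_mech(cfg: RunConfig, out: Path) -> list[Path]:
    params = cfg.mechanics
    trace_file = cfg.inputs.get("trace", str(out / "mech_trace.csv"))
    trace = io.read_trace(trace_file, temperature_K=float(params.get("temperature_K", 298.0)))
    band = tuple(params.get("band_hz", mechanics.DEFAULT_BAND_HZ))
    psd = mechanics.displacement_psd(trace, band_hz=band)
    fit = mechanics.fit_sho(psd, m_kg=float(params.get("m_kg", mechanics.DEFAULT_MASS_KG)))
    energy = mechanics.fluctuation_energy(fit, psd, trace.temperature_K)
    report = {**dataclasses.asdict(fit), **dataclasses.asdict(energy)}
    (out / "sho_fit.json").write_text(json.dumps(report, indent=1), encoding="utf-8")
    pd.DataFrame(
        {"frequency_hz": psd.frequencies_hz, "psd_m2_per_hz": psd.psd_m2_per_hz}
    ).to_csv(out / "psd.csv", index=False)
    files = [out / "sho_fit.json", out / "psd.csv"]
    resp_file = cfg.inputs.get("responses", out / "responses.csv")
    if Path(resp_file).exists():
        resp = io.read_responses(resp_file)
        gc = mechanics.gain_curve(resp)
        pd.DataFrame(
            {"spv_m_s": resp.spv_m_s, "gain": gc.gains}
        ).to_csv(out / "gain_curve.csv", index=False)
        (out / "gain.json").write_text(
            json.dumps(
                {
                    "gain_max": gc.gain_max,
                    "gain_min": gc.gain_min,
                    "sensitivity": gc.sensitivity,
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        files += [out / "gain_curve.csv", out / "gain.json"]
    return files


def _stage_simulate_quant(cfg: RunConfig, out: Path) -> list[Path]:
    params = dict(cfg.synthetic.get("quant", {}))
    params.setdefault("seed", _stage_seed(cfg.seed, "simulate_quant"))
    volumes, truth = synthetic.simulate_quant_volume(**params)
    import tifffile

    files = []
    for i, vol in enumerate(volumes):
        arr = np.stack([vol.channels["marker"], vol.channels["target"]]).astype(
            np.float32
        )
        p = out / f"volume_{i:02d}_{vol.group_label}.tif"
        tifffile.imwrite(p, arr, metadata={"axes": "CZYX"})
        files.append(p)
    truth.true_quant["region_masks"] = [m.tolist() for m in truth.true_quant["region_masks"]]
    truth.true_quant.pop("dilation", None)
    io.write_truth(truth, out / "quant_truth.json")
    files.append(out / "quant_truth.json")
    return files


def _stage_quantify(cfg: RunConfig, out: Path) -> list[Path]:
    import tifffile

    params = cfg.quant
    vol_files = sorted(out.glob("volume_*.tif"))
    if not vol_files:
        raise FileNotFoundError("no volume_*.tif inputs for quantify stage")
    rows = []
    for p in vol_files:
        arr = tifffile.imread(p)
        group = "knockdown" if "knockdown" in p.name else "control"
        vol = quant.LabeledVolume(
            channels={"marker": arr[0], "target": arr[1]},
            voxel_size_um=(0.4, 0.13, 0.13),
            group_label=group,
        )
        masks = quant.segment_marker_regions(
            vol, min_voxels=int(params.get("min_voxels", 30))
        )
        rs = quant.region_intensity_stats(vol, masks)
        rows.append({"file": p.name, "group": group, "volume_mean": rs.volume_mean})
    df = pd.DataFrame(rows)
    control = df.loc[df.group == "control", "volume_mean"].to_numpy()
    df["normalized"] = quant.normalize_to_control(df["volume_mean"].to_numpy(), control)
    df.to_csv(out / "volume_means.csv", index=False)
    kd = df.loc[df.group == "knockdown", "normalized"].to_numpy()
    ctrl = df.loc[df.group == "control", "normalized"].to_numpy()
    files = [out / "volume_means.csv"]
    if len(kd) >= 3 and len(ctrl) >= 3:
        cmp_res = quant.compare_groups(ctrl, kd)
        (out / "group_comparison.json").write_text(
            json.dumps(
                {
                    "U": cmp_res.u_statistic,
                    "p_value": cmp_res.p_value,
                    "median_percent_change": cmp_res.median_percent_change,
                    "knockdown_median_normalized": float(np.median(kd)),
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        files.append(out / "group_comparison.json")
    return files


_STAGE_FUNCS = {
    "simulate_ift": _stage_simulate_ift,
    "analyze_kymo": _stage_analyze_kymo,
    "simulate_mech": _stage_simulate_mech,
    "analyze_mech": _stage_analyze_mech,
    "simulate_quant": _stage_simulate_quant,
    "quantify": _stage_quantify,
}


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the configured stages in order and write a manifest.

    A stage failure aborts the run with the stage name attached to the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stage in config.stages:
        try:
            written += _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "tool": "ciliakit",
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return ResultBundle(out, manifest)
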