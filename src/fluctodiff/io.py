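"""Self-describing delimited-text formats for trajectories and statistics.

Every file carries its metadata in ``#``-prefixed header lines of the form
``# key = value``; columns are tab-separated. Coordinates are stored in nm
and times in ns; readers convert declared alternative units (μs, Å) on the
way in. Binary molecular-dynamics formats are deliberately unsupported —
conversion to these tables happens upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CovariateSeries, Ensemble, StateSeries, Trajectory
from .dispcorr import DAFCurve
from .ergodicity import RSDCurve
from .msd import MSDCurve
from .propagator import PropagatorHist
from .segmentation import SegmentationResult, TemporalDiffusivitySeries

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_ensemble",
    "write_ensemble",
    "write_covariate",
    "read_covariate",
    "write_state_series",
    "write_msd_curve",
    "write_daf_curve",
    "write_rsd_curve",
    "write_propagator",
    "write_temporal_diffusivity",
    "write_segmentation",
]

_TIME_UNITS = {"ns": 1.0, "us": 1.0e3, "μs": 1.0e3, "ps": 1.0e-3, "s": 1.0e9}
_LENGTH_UNITS = {"nm": 1.0, "angstrom": 0.1, "A": 0.1, "um": 1.0e3, "μm": 1.0e3}


def _parse_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def _write_header(fh, meta: dict) -> None:
    for key, val in meta.items():
        fh.write(f"# {key} = {val}\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory TSV (``t  x  y [z]`` with a ``#`` metadata header).

    The header must declare ``time_unit`` and ``length_unit`` (or the file is
    rejected); sampling must be uniform to 1e-9 relative tolerance, and any
    non-finite coordinate is reported with its data row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, n_header = _parse_header(path)
    if "time_unit" not in meta or "length_unit" not in meta:
        raise ValueError(f"{path}: header must declare time_unit and length_unit")
    t_scale = _TIME_UNITS.get(meta["time_unit"])
    l_scale = _LENGTH_UNITS.get(meta["length_unit"])
    if t_scale is None or l_scale is None:
        raise ValueError(
            f"{path}: unsupported units {meta['time_unit']!r}/{meta['length_unit']!r}"
        )
    table = pd.read_csv(path, sep="\t", comment="#", header=None, float_precision="round_trip")
    if table.shape[1] < 2 or table.shape[1] > 4:
        raise ValueError(f"{path}: expected 2-4 columns (t, x[, y[, z]]), got {table.shape[1]}")
    arr = table.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        row = int(bad[0, 0]) + n_header + 1
        raise ValueError(f"{path}: non-finite value at line {row}")
    times = arr[:, 0] * t_scale
    positions = arr[:, 1:] * l_scale
    return Trajectory(times=times, positions=positions, traj_id=meta.get("id", path.stem))


def write_trajectory(traj: Trajectory, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        meta = {
            "id": traj.traj_id or path.stem,
            "time_unit": "ns",
            "length_unit": "nm",
            "dt_ns": repr(traj.dt),
            "dim": traj.dim,
            "n_steps": traj.n_steps,
            "diffusivity_unit_note": "1 nm^2/ns = 1e3 um^2/s",
        }
        meta.update(extra_meta or {})
        _write_header(fh, meta)
        for t, row in zip(traj.times, traj.positions):
            fh.write("\t".join([repr(float(t))] + [repr(float(v)) for v in row]) + "\n")


def write_ensemble(ensemble: Ensemble, directory, manifest_name: str = "ensemble.json") -> Path:
    """Write member TSVs plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    members = []
    for i, traj in enumerate(ensemble):
        name = f"{traj.traj_id or f'traj-{i}'}.tsv"
        write_trajectory(traj, directory / name)
        members.append(name)
    manifest = {
        "members": members,
        "time_unit": "ns",
        "length_unit": "nm",
        "n_trajectories": len(ensemble),
    }
    mpath = directory / manifest_name
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_ensemble(manifest_path, require_homogeneous: bool = False) -> Ensemble:
    """Load an ensemble from a JSON manifest listing member trajectory files."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    members = manifest.get("members", [])
    if not members:
        raise ValueError(f"{manifest_path}: manifest lists no members")
    trajs = tuple(read_trajectory(manifest_path.parent / m) for m in members)
    ens = Ensemble(trajs)
    if require_homogeneous:
        ens.require_homogeneous(f"ensemble {manifest_path}")
    return ens


def write_covariate(cov: CovariateSeries, path) -> None:
    with open(Path(path), "w") as fh:
        _write_header(fh, {"time_unit": "ns", "column_1": "t_ns", "column_2": "count"})
        for t, v in zip(cov.times, cov.values):
            fh.write(f"{t!r}\t{v!r}\n")


def read_covariate(path) -> CovariateSeries:
    table = pd.read_csv(
        Path(path), sep="\t", comment="#", header=None, float_precision="round_trip"
    )
    arr = table.to_numpy(dtype=float)
    return CovariateSeries(times=arr[:, 0], values=arr[:, 1])


def write_state_series(states: StateSeries, path) -> None:
    """TSV of sojourn intervals: start time, end time, label."""
    edges = np.concatenate(([0.0], states.switch_times, [states.t_end]))
    with open(Path(path), "w") as fh:
        _write_header(
            fh, {"time_unit": "ns", "columns": "t_start_ns\tt_end_ns\tlabel"}
        )
        for a, b, lab in zip(edges[:-1], edges[1:], states.labels):
            fh.write(f"{a!r}\t{b!r}\t{lab}\n")


def _write_curve(path, meta: dict, columns: list[np.ndarray], names: list[str]) -> None:
    with open(Path(path), "w") as fh:
        meta = {**meta, "columns": "\t".join(names)}
        _write_header(fh, meta)
        for row in zip(*columns):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_msd_curve(curve: MSDCurve, path, extra_meta: dict | None = None) -> None:
    meta = {
        "kind": curve.kind,
        "measurement_time_ns": curve.measurement_time,
        "n_trajectories": curve.n_trajectories,
        "units": "lag ns, msd nm^2 (1 nm^2/ns = 1e3 um^2/s)",
    }
    meta.update(extra_meta or {})
    _write_curve(path, meta, [curve.lags, curve.values], ["lag_ns", "msd_nm2"])


def write_daf_curve(curve: DAFCurve, path, extra_meta: dict | None = None) -> None:
    meta = {"lag_ns": curve.lag, "averaging": curve.averaging}
    meta.update(extra_meta or {})
    _write_curve(
        path,
        meta,
        [curve.t_grid, curve.raw, curve.normalized],
        ["t_ns", "daf_raw_nm2_ns2", "daf_normalized"],
    )


def write_rsd_curve(curve: RSDCurve, path, extra_meta: dict | None = None) -> None:
    meta = {"lag_ns": curve.lag, "n_trajectories": curve.n_trajectories}
    meta.update(extra_meta or {})
    _write_curve(path, meta, [curve.t_grid, curve.values], ["t_ns", "rsd"])


def write_propagator(hist: PropagatorHist, path, extra_meta: dict | None = None) -> None:
    meta = {"lag_ns": hist.lag, "sigma_nm": hist.sigma, "n_samples": hist.n_samples}
    meta.update(extra_meta or {})
    _write_curve(path, meta, [hist.bin_centers, hist.densities], ["x_tilde", "density"])


def write_temporal_diffusivity(
    series: TemporalDiffusivitySeries, path, extra_meta: dict | None = None
) -> None:
    meta = {
        "lag_ns": series.lag,
        "window_ns": series.window,
        "d_a_um2_s": series.d_a,
        "units": "t ns, D um^2/s (1 nm^2/ns = 1e3 um^2/s)",
    }
    meta.update(extra_meta or {})
    _write_curve(path, meta, [series.t_grid, series.values], ["t_ns", "d_um2_s"])


def write_segmentation(result: SegmentationResult, path) -> None:
    """Serialize a segmentation result as JSON."""
    payload = {
        "units": {"time": "ns", "diffusivity": "um^2/s"},
        "short_lag_ns": result.short_lag,
        "t_c_ns": result.t_c,
        "d_a_um2_s": result.d_a,
        "n_merged_segments": result.n_merged,
        "renewal_times_ns": result.renewal_times.tolist(),
        "segment_bounds_ns": result.bounds.tolist(),
        "labels": list(result.labels),
        "segment_d_um2_s": result.segment_d.tolist(),
    }
    if result.covariate_means is not None:
        payload["covariate_means"] = result.covariate_means.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))
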