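"""Data model and file I/O for patch-clamp sweeps, recordings and feature tables.

Canonical units everywhere inside the package: millivolts (current clamp),
picoamps (voltage clamp and stimuli), milliseconds, megaohms.  Unit conversion
happens only at the I/O boundary (a CSV manifest may declare volts or seconds;
values are rescaled on read).

Two on-disk dialects are supported:

* an HDF5 bundle — one group per sweep, sweep samples as a float64 dataset,
  stimulus/mode/dt as attributes;
* a CSV directory — one ``sweep_NNN.csv`` (``time_ms,value`` columns) per
  sweep plus a ``manifest.json`` carrying dt, stimulus metadata, mode, group
  labels and declared units.

Both round-trip sample-exactly (float64 end to end; the CSV dialect prints
``%.17g`` floats and parses them in round-trip mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "StimulusStep",
    "Sweep",
    "Recording",
    "StepProtocol",
    "default_step_protocol",
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

#: multiplicative factors to canonical units, keyed by declared unit string
_UNIT_SCALE = {
    "mV": 1.0, "V": 1000.0, "uV": 1e-3,
    "pA": 1.0, "nA": 1000.0,
    "ms": 1.0, "s": 1000.0,
    "MOhm": 1.0, "Mohm": 1.0,
}


class ValidationError(ValueError):
    """An invariant of the data model was violated; message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class StimulusStep:
    """A rectangular current step riding on a holding current."""

    amplitude: float          # pA
    onset: float              # ms from sweep start
    duration: float = 250.0   # ms
    holding_current: float = 0.0  # pA

    def __post_init__(self) -> None:
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.onset >= 0, "onset", "must be >= 0")

    @property
    def end(self) -> float:
        """Time of step termination (ms)."""
        return self.onset + self.duration


@dataclass
class Sweep:
    """One uniformly sampled trace: voltage (mV, current clamp) or current (pA)."""

    samples: np.ndarray
    dt: float                 # ms
    stimulus: StimulusStep
    mode: str = CURRENT_CLAMP

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        _require(self.dt > 0, "dt", "must be > 0")
        _require(self.samples.ndim == 1, "samples", "must be 1-D")
        _require(bool(np.all(np.isfinite(self.samples))), "samples",
                 "must be finite")
        _require(self.mode in (CURRENT_CLAMP, VOLTAGE_CLAMP), "mode",
                 f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total sweep duration (ms)."""
        return self.n * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms; sample 0 is the time origin."""
        return np.arange(self.n) * self.dt

    def post_step_span(self) -> float:
        """Recorded time after stimulus termination (ms)."""
        return self.duration - self.stimulus.end


@dataclass
class Recording:
    """An ordered bundle of sweeps from one cell, with cohort metadata."""

    cell_id: str
    animal_id: str
    group: str
    sweeps: list[Sweep] = field(default_factory=list)
    holding_potential: float | None = None       # mV, voltage clamp only
    access_resistance_series: np.ndarray | None = None  # (k, 2): time s, Ra MΩ

    def __post_init__(self) -> None:
        _require(bool(self.group), "group", "label must be non-empty")
        if self.sweeps:
            dt0, mode0 = self.sweeps[0].dt, self.sweeps[0].mode
            for i, sw in enumerate(self.sweeps):
                _require(sw.dt == dt0, "dt",
                         f"sweep {i} dt {sw.dt} != sweep 0 dt {dt0}")
                _require(sw.mode == mode0, "mode",
                         f"sweep {i} mode {sw.mode} != {mode0}")
        if self.access_resistance_series is not None:
            ra = np.asarray(self.access_resistance_series, dtype=np.float64)
            _require(ra.ndim == 2 and ra.shape[1] == 2,
                     "access_resistance_series", "must be (k, 2)")
            self.access_resistance_series = ra

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    @property
    def mode(self) -> str:
        return self.sweeps[0].mode

    def sweep_at(self, amplitude: float, atol: float = 1e-6) -> Sweep:
        """Return the sweep whose step amplitude matches (pA)."""
        for sw in self.sweeps:
            if abs(sw.stimulus.amplitude - amplitude) <= atol:
                return sw
        raise ValidationError(
            f"stimulus.amplitude: no sweep at {amplitude} pA in recording "
            f"{self.cell_id}")


@dataclass(frozen=True)
class StepProtocol:
    """The family of current-step amplitudes applied to each cell."""

    amplitudes: tuple[float, ...]
    step_duration: float = 250.0  # ms
    description: str = ""

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "amplitudes", amps)
        _require(all(b > a for a, b in zip(amps, amps[1:])),
                 "amplitudes", "must be strictly increasing")
        _require(self.step_duration > 0, "step_duration", "must be > 0")


def default_step_protocol() -> StepProtocol:
    """20 steps, −250 → 700 pA in 50 pA increments, 250 ms each."""
    return StepProtocol(
        amplitudes=tuple(float(a) for a in range(-250, 701, 50)),
        step_duration=250.0,
        description="-250..700 pA, 50 pA increments, 250 ms",
    )


# ---------------------------------------------------------------------------
# recording writers / readers
# ---------------------------------------------------------------------------

#: minimum post-step span (ms) the AHP baseline window requires
MIN_AHP_POST_STEP_MS = 700.0


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or a CSV directory.

    Current-clamp sweeps shorter than 700 ms post-step trigger a warning (the
    AHP baseline window would not fit) but are still written.
    """
    import warnings

    path = Path(path)
    if recording.mode == CURRENT_CLAMP:
        for i, sw in enumerate(recording.sweeps):
            if sw.post_step_span() < MIN_AHP_POST_STEP_MS:
                warnings.warn(
                    f"sweep {i}: only {sw.post_step_span():.0f} ms recorded "
                    f"post-step; AHP windows need >= {MIN_AHP_POST_STEP_MS:.0f} ms",
                    stacklevel=2)
                break
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(recording, path)
    else:
        _write_csv_dir(recording, path)


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (either dialect)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        if not path.is_file():
            raise FileNotFoundError(path)
        return _read_hdf5(path)
    if path.is_dir():
        return _read_csv_dir(path)
    raise ValidationError(f"path: unknown recording dialect for {path}")


def _write_hdf5(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = rec.cell_id
        f.attrs["animal_id"] = rec.animal_id
        f.attrs["group"] = rec.group
        if rec.holding_potential is not None:
            f.attrs["holding_potential_mV"] = float(rec.holding_potential)
        if rec.access_resistance_series is not None:
            f.create_dataset("access_resistance",
                             data=rec.access_resistance_series)
        for i, sw in enumerate(rec.sweeps):
            g = f.create_group(f"sweeps/{i:03d}")
            g.create_dataset("samples", data=sw.samples)
            g.attrs["dt_ms"] = sw.dt
            g.attrs["mode"] = sw.mode
            g.attrs["stim_amplitude_pA"] = sw.stimulus.amplitude
            g.attrs["stim_onset_ms"] = sw.stimulus.onset
            g.attrs["stim_duration_ms"] = sw.stimulus.duration
            g.attrs["stim_holding_pA"] = sw.stimulus.holding_current


def _read_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        required = ["cell_id", "animal_id", "group"]
        missing = [k for k in required if k not in f.attrs]
        if missing:
            raise ValidationError(
                f"metadata: missing required keys {missing} in {path}")
        sweeps = []
        if "sweeps" in f:
            for key in sorted(f["sweeps"]):
                g = f[f"sweeps/{key}"]
                stim = StimulusStep(
                    amplitude=float(g.attrs["stim_amplitude_pA"]),
                    onset=float(g.attrs["stim_onset_ms"]),
                    duration=float(g.attrs["stim_duration_ms"]),
                    holding_current=float(g.attrs["stim_holding_pA"]),
                )
                sweeps.append(Sweep(samples=g["samples"][...],
                                    dt=float(g.attrs["dt_ms"]),
                                    stimulus=stim, mode=str(g.attrs["mode"])))
        ra = f["access_resistance"][...] if "access_resistance" in f else None
        return Recording(
            cell_id=str(f.attrs["cell_id"]),
            animal_id=str(f.attrs["animal_id"]),
            group=str(f.attrs["group"]),
            sweeps=sweeps,
            holding_potential=(float(f.attrs["holding_potential_mV"])
                               if "holding_potential_mV" in f.attrs else None),
            access_resistance_series=ra,
        )


def _write_csv_dir(rec: Recording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cell_id": rec.cell_id,
        "animal_id": rec.animal_id,
        "group": rec.group,
        "holding_potential_mV": rec.holding_potential,
        "units": {"value": "mV" if rec.mode == CURRENT_CLAMP else "pA",
                  "time": "ms"},
        "sweeps": [],
    }
    if rec.access_resistance_series is not None:
        manifest["access_resistance"] = [
            [float(t), float(r)] for t, r in rec.access_resistance_series]
    for i, sw in enumerate(rec.sweeps):
        name = f"sweep_{i:03d}.csv"
        with open(path / name, "w") as fh:
            fh.write("time_ms,value\n")
            for t, v in zip(sw.time, sw.samples):
                # %.17g round-trips float64 exactly
                fh.write(f"{t:.17g},{v:.17g}\n")
        manifest["sweeps"].append({
            "file": name, "dt_ms": sw.dt, "mode": sw.mode,
            "stim_amplitude_pA": sw.stimulus.amplitude,
            "stim_onset_ms": sw.stimulus.onset,
            "stim_duration_ms": sw.stimulus.duration,
            "stim_holding_pA": sw.stimulus.holding_current,
        })
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _read_csv_dir(path: Path) -> Recording:
    mf_path = path / "manifest.json"
    if not mf_path.is_file():
        raise ValidationError(f"manifest: {mf_path} not found")
    with open(mf_path) as fh:
        mf = json.load(fh)
    missing = [k for k in ("cell_id", "animal_id", "group", "sweeps")
               if k not in mf]
    if missing:
        raise ValidationError(f"manifest: missing required keys {missing}")
    units = mf.get("units", {})
    vscale = _unit_scale(units.get("value", "mV"))
    tscale = _unit_scale(units.get("time", "ms"))
    sweeps = []
    for entry in mf["sweeps"]:
        df = pd.read_csv(path / entry["file"], float_precision="round_trip")
        if df.shape[1] < 2 or df.isna().any().any():
            raise ValidationError(f"sweep file {entry['file']}: truncated or "
                                  "malformed; no partial recording returned")
        stim = StimulusStep(
            amplitude=float(entry["stim_amplitude_pA"]),
            onset=float(entry["stim_onset_ms"]),
            duration=float(entry["stim_duration_ms"]),
            holding_current=float(entry.get("stim_holding_pA", 0.0)),
        )
        sweeps.append(Sweep(samples=df.iloc[:, 1].to_numpy() * vscale,
                            dt=float(entry["dt_ms"]) * tscale,
                            stimulus=stim, mode=entry["mode"]))
    ra = mf.get("access_resistance")
    return Recording(
        cell_id=mf["cell_id"], animal_id=mf["animal_id"], group=mf["group"],
        sweeps=sweeps,
        holding_potential=mf.get("holding_potential_mV"),
        access_resistance_series=(np.asarray(ra, float) if ra else None),
    )


def _unit_scale(unit: str) -> float:
    try:
        return _UNIT_SCALE[unit]
    except KeyError:
        raise ValidationError(f"units: unknown unit {unit!r}") from None


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(rows: Iterable[Mapping[str, object]],
                        path: str | Path,
                        header_comment: str | None = None,
                        columns: Sequence[str] | None = None) -> None:
    """Write per-cell feature records to CSV: header + one row per cell.

    All records must share a schema (same keys); column order follows the
    first record (or ``columns`` for an empty collection, which yields a
    header-only file).  An optional ``# comment`` line (e.g. the analysis
    window parameters) precedes the header.
    """
    rows = list(rows)
    path = Path(path)
    if rows:
        schema = list(rows[0].keys())
        for i, r in enumerate(rows):
            if list(r.keys()) != schema:
                raise ValidationError(
                    f"rows: record {i} schema {list(r.keys())} != {schema}")
        df = pd.DataFrame(rows, columns=schema)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
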