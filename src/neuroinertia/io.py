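"""File formats: the HDF5 study container, EDF import/export, CSV tables.

The container is a single hierarchical file holding recordings (with their
ground-truth state trajectories), feature sets, accuracy traces and the
final report, each stamped with the metadata needed to regenerate it.
Human-facing tables (masks, spectra, accuracies) are exported as CSV; the
report as JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .inertia_analysis import AccuracyTrace
from .spectral_features import FeatureSet
from .synthetic_data import (
    ConcentrationSchedule,
    RecordingSegment,
    StateTrajectory,
    SyntheticRecording,
)

__all__ = [
    "StudyContainer",
    "write_edf",
    "read_edf",
    "export_mask_csv",
    "export_accuracy_csv",
]


class StudyContainer:
    """Thin h5py wrapper with typed save/load helpers.

    Round-trip contract: integer data bit-exact, floats preserved at their
    stored dtype (float64 is used for everything but raw signals).
    """

    def __init__(self, path, mode: str = "a"):
        import h5py

        self.path = str(path)
        self._h5 = h5py.File(self.path, mode)

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def has(self, key: str) -> bool:
        return key in self._h5

    # -- recordings --------------------------------------------------------

    def save_recording(self, rec: SyntheticRecording):
        grp = self._h5.require_group(f"recordings/{rec.individual_id}/{rec.arm}")
        for k in list(grp.keys()):
            del grp[k]
        grp.attrs.update({
            "individual_id": rec.individual_id, "arm": rec.arm, "fs": rec.fs,
            "seed": rec.seed,
            "channel_names": json.dumps(list(rec.channel_names)),
            "schedule_breakpoints": json.dumps(list(rec.schedule.breakpoints)),
            "schedule_duration_s": rec.schedule.duration_s,
        })
        for i, seg in enumerate(rec.segments):
            sg = grp.create_group(f"segment{i}")
            sg.attrs["t_start_s"] = seg.t_start_s
            sg.create_dataset("eeg", data=seg.eeg)
            sg.create_dataset("emg", data=seg.emg)
        tg = grp.create_group("trajectory")
        tg.attrs["dt"] = rec.traj.dt
        tg.attrs["t0"] = rec.traj.t0
        tg.create_dataset("x", data=rec.traj.x)
        tg.create_dataset("s", data=rec.traj.s)
        grp.create_dataset(
            "artifact_times",
            data=np.array([t for t, _ in rec.artifact_times], dtype=float))
        grp.attrs["artifact_channels"] = json.dumps(
            [ch for _, ch in rec.artifact_times])
        grp.create_dataset(
            "emg_burst_times", data=np.array(rec.emg_burst_times, dtype=float)
            if rec.emg_burst_times else np.zeros((0, 2)))

    def load_recording(self, individual_id, arm: str) -> SyntheticRecording:
        grp = self._h5[f"recordings/{individual_id}/{arm}"]
        schedule = ConcentrationSchedule(
            breakpoints=tuple(tuple(bp) for bp in
                              json.loads(grp.attrs["schedule_breakpoints"])),
            duration_s=float(grp.attrs["schedule_duration_s"]),
            arm=str(grp.attrs["arm"]),
        )
        segments = []
        i = 0
        while f"segment{i}" in grp:
            sg = grp[f"segment{i}"]
            segments.append(RecordingSegment(
                t_start_s=float(sg.attrs["t_start_s"]),
                eeg=sg["eeg"][...], emg=sg["emg"][...]))
            i += 1
        tg = grp["trajectory"]
        traj = StateTrajectory(dt=float(tg.attrs["dt"]), x=tg["x"][...],
                               s=tg["s"][...], t0=float(tg.attrs["t0"]))
        art_ch = json.loads(grp.attrs["artifact_channels"])
        return SyntheticRecording(
            individual_id=grp.attrs["individual_id"],
            arm=str(grp.attrs["arm"]), schedule=schedule,
            fs=float(grp.attrs["fs"]),
            channel_names=tuple(json.loads(grp.attrs["channel_names"])),
            segments=segments, traj=traj, seed=int(grp.attrs["seed"]),
            artifact_times=list(zip(grp["artifact_times"][...].tolist(), art_ch)),
            emg_burst_times=[tuple(r) for r in grp["emg_burst_times"][...]],
        )

    # -- features / traces / report ---------------------------------------

    def save_feature_set(self, individual_id, fs: FeatureSet):
        grp = self._h5.require_group(f"features/{individual_id}")
        for k in list(grp.keys()):
            del grp[k]
        grp.create_dataset("scores", data=fs.scores)
        grp.create_dataset("loadings", data=fs.loadings)
        grp.create_dataset("explained_variance_ratio",
                           data=fs.explained_variance_ratio)
        grp.create_dataset("centering", data=fs.centering)
        grp.create_dataset("time_s", data=fs.meta["time_s"].to_numpy())
        grp.create_dataset("step_time_s", data=fs.meta["step_time_s"].to_numpy())
        grp.attrs["sources"] = json.dumps(fs.meta["source"].tolist())

    def load_feature_set(self, individual_id) -> FeatureSet:
        grp = self._h5[f"features/{individual_id}"]
        meta = pd.DataFrame({
            "source": json.loads(grp.attrs["sources"]),
            "time_s": grp["time_s"][...],
            "step_time_s": grp["step_time_s"][...],
        })
        return FeatureSet(
            scores=grp["scores"][...], loadings=grp["loadings"][...],
            explained_variance_ratio=grp["explained_variance_ratio"][...],
            centering=grp["centering"][...], meta=meta,
        )

    def save_trace(self, individual_id, trace: AccuracyTrace):
        tag = f"{trace.method}-{'null' if trace.null else 'real'}"
        grp = self._h5.require_group(f"traces/{individual_id}/{tag}")
        for k in list(grp.keys()):
            del grp[k]
        for col in ("classifier", "accuracy", "i_correct", "i_total",
                    "e_correct", "e_total"):
            grp.create_dataset(col, data=trace.table[col].to_numpy())
        grp.attrs["periods"] = json.dumps(trace.table["period"].tolist())
        grp.attrs["periods_min"] = json.dumps([list(p) for p in trace.periods_min])
        grp.attrs["method"] = trace.method
        grp.attrs["null"] = trace.null

    def load_trace(self, individual_id, method: str, null: bool) -> AccuracyTrace:
        tag = f"{method}-{'null' if null else 'real'}"
        grp = self._h5[f"traces/{individual_id}/{tag}"]
        table = pd.DataFrame({
            col: grp[col][...]
            for col in ("classifier", "accuracy", "i_correct", "i_total",
                        "e_correct", "e_total")
        })
        table.insert(1, "period", json.loads(grp.attrs["periods"]))
        return AccuracyTrace(
            table=table,
            periods_min=tuple(tuple(p) for p in
                              json.loads(grp.attrs["periods_min"])),
            individual=individual_id, method=str(grp.attrs["method"]),
            null=bool(grp.attrs["null"]),
        )

    def save_report(self, report_json: str):
        if "report" in self._h5:
            del self._h5["report"]
        self._h5.create_dataset("report", data=report_json)

    def load_report(self) -> str:
        raw = self._h5["report"][()]
        return raw.decode() if isinstance(raw, bytes) else str(raw)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def write_edf(path, signals: np.ndarray, fs: float, channel_names,
              physical_dim: str = "uV"):
    """Write a minimal EDF file (16-bit samples, 1-s data records).

    Physical ranges are set per channel from the data; samples beyond a
    whole second are dropped (EDF stores whole records).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    ns, fs_i = signals.shape[0], int(round(fs))
    n_records = signals.shape[1] // fs_i
    if n_records < 1:
        raise ValueError("need at least one second of signal for EDF export")
    phys_min = signals.min(axis=1)
    phys_max = signals.max(axis=1)
    span = np.maximum(phys_max - phys_min, 1e-6)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("synthetic", 80),
        _edf_field("neuroinertia export", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(name, 16) for name in channel_names),
        b"".join(_edf_field("synthetic", 80) for _ in range(ns)),
        b"".join(_edf_field(physical_dim, 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_min[i]:.3f}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(f"{phys_max[i]:.3f}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
        b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(fs_i, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    # re-read the 8-char physical min/max fields so quantization uses the
    # exact values a reader will parse
    pmin = np.array([float(f"{phys_min[i]:.3f}"[:8]) for i in range(ns)])
    pmax = np.array([float(f"{phys_max[i]:.3f}"[:8]) for i in range(ns)])
    span = np.maximum(pmax - pmin, 1e-6)
    gain = (dig_max - dig_min) / span
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_records):
            for ch in range(ns):
                chunk = signals[ch, r * fs_i:(r + 1) * fs_i]
                dig = np.clip(np.round((chunk - pmin[ch]) * gain[ch]) + dig_min,
                              dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())


def read_edf(path, channel_map: dict):
    """Read an EDF/EDF+ file and map named channels to analysis roles.

    ``channel_map`` maps role (e.g. "M2", "V1", "EMG") -> channel label in
    the file.  Returns ``(signals, fs)`` with signals a dict role -> array
    in uV.  Unmapped channels are ignored; a missing mapped channel raises
    with its name.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = raw.ch_names
    signals = {}
    for role, label in channel_map.items():
        if label not in available:
            raise KeyError(
                f"channel {label!r} (role {role}) not found in {path}; "
                f"available: {available}"
            )
        data = raw.get_data(picks=[label], units="uV")[0]
        signals[role] = data
    return signals, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------

def export_mask_csv(path, masks, channel: str):
    """Write window-level masks as BED-like intervals (start_s, end_s,
    channel); ``masks`` is an iterable of ArtifactMask."""
    rows = []
    for am in masks:
        times = am.window_times()
        for t, bad in zip(times, am.mask):
            if bad:
                rows.append({"start_s": t, "end_s": t + am.window_s,
                             "channel": channel})
    pd.DataFrame(rows, columns=["start_s", "end_s", "channel"]).to_csv(
        path, index=False)


def export_accuracy_csv(path, traces):
    """Concatenate accuracy tables (one row per classifier x period)."""
    frames = []
    for trace in traces:
        t = trace.table.copy()
        t["individual"] = trace.individual
        t["method"] = trace.method
        t["null"] = trace.null
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
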