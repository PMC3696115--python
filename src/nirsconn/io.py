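"""Readers and writers for recordings, metadata, matrices, and configuration.

Primary on-disk formats are plain delimited text: recordings as one time
column plus one column per channel per wavelength (``ch%03d_od785`` /
``ch%03d_od830``), metadata and result tables as CSV, configuration as a
flat ``key = value`` file.  A minimal reader/writer pair for the SNIRF
(HDF5) container is provided for interoperability with acquisition
software.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .artifacts import ArtifactPolicy
from .cohort import SubjectRecord
from .connectivity import ConnectivityMatrix
from .hemodynamics import FilterSpec, OpticalRecording
from .inference import InferenceConfig


def _od_columns(n_channels: int, wavelengths_nm) -> list[str]:
    cols = []
    for ch in range(1, n_channels + 1):
        for wl in wavelengths_nm:
            cols.append(f"ch{ch:03d}_od{int(round(wl))}")
    return cols


def write_recording(recording: OpticalRecording, path) -> None:
    """Write one recording as a delimited table (time_s + per-channel OD columns)."""
    n_t, n_ch, _ = recording.od.shape
    cols = _od_columns(n_ch, recording.wavelengths_nm)
    flat = recording.od.reshape(n_t, n_ch * 2)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "time_s", recording.times_s)
    df.to_csv(path, index=False, float_format="%.10g")


def read_recording(
    path, wavelengths_nm=(785.0, 830.0), subject_id: str | None = None
) -> OpticalRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'time_s'")
    data_cols = [c for c in df.columns if c != "time_s"]
    chan_ids = sorted(
        {int(c[2:5]) for c in data_cols if c.startswith("ch") and c[2:5].isdigit()}
    )
    if not chan_ids:
        raise ValueError(f"{path.name}: no channel OD columns found")
    n_ch = max(chan_ids)
    expected = _od_columns(n_ch, wavelengths_nm)
    missing = sorted(set(expected) - set(data_cols))
    if missing:
        raise ValueError(f"{path.name}: missing wavelength column(s) {missing[:4]}")
    times = df["time_s"].to_numpy()
    if len(times) < 2:
        raise ValueError(f"{path.name}: too few samples")
    dt = float(np.median(np.diff(times)))
    od = df[expected].to_numpy().reshape(len(df), n_ch, 2)
    return OpticalRecording(
        subject_id=subject_id or path.stem,
        od=od,
        sample_interval_s=dt,
        wavelengths_nm=tuple(wavelengths_nm),
    )


def write_metadata(subjects: list[SubjectRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in subjects]).to_csv(path, index=False)


def read_metadata(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "ga_weeks", "ca_days", "pma_weeks"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    subjects = []
    for row in df.itertuples():
        hc = getattr(row, "head_circumference_cm", None)
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                ga_weeks=float(row.ga_weeks),
                ca_days=int(row.ca_days),
                pma_weeks=float(row.pma_weeks),
                head_circumference_cm=None if hc is None or pd.isna(hc) else float(hc),
            )
        )
    return subjects


def write_matrix(matrix: ConnectivityMatrix, path, which: str = "z") -> None:
    """Write a square connectivity matrix with a 1-based channel header."""
    arr = getattr(matrix, which)
    cols = [str(i) for i in range(1, matrix.n_channels + 1)]
    pd.DataFrame(arr, columns=cols).to_csv(path, index=False, float_format="%.10g")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy()


# -- flat key = value configuration ------------------------------------------


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")


def read_config(path) -> dict:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def pipeline_config_from_flat(flat: dict) -> "PipelineConfig":
    """Rebuild a PipelineConfig from a flat ``section.key`` mapping."""
    groups: dict[str, dict] = {"filter": {}, "artifact": {}, "inference": {}, "": {}}
    for key, value in flat.items():
        section, _, name = key.partition(".")
        if name and section in groups:
            groups[section][name] = _coerce(value)
        else:
            groups[""][key] = _coerce(value)
    top = groups[""]
    return PipelineConfig(
        filter=FilterSpec(**groups["filter"]),
        artifact=ArtifactPolicy(**groups["artifact"]),
        inference=InferenceConfig(**groups["inference"]),
        layout_path=top.get("layout_path") or None,
        seed=int(top.get("seed", 0)),
        output_dir=str(top.get("output_dir", "results")),
    )


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through the flat format."""

    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    artifact: ArtifactPolicy = dataclasses.field(default_factory=ArtifactPolicy)
    inference: InferenceConfig = dataclasses.field(default_factory=InferenceConfig)
    layout_path: str | None = None
    seed: int = 0
    output_dir: str = "results"

    def to_flat(self) -> dict:
        flat: dict[str, object] = {}
        for section, obj in (
            ("filter", self.filter),
            ("artifact", self.artifact),
            ("inference", self.inference),
        ):
            for f in dataclasses.fields(obj):
                flat[f"{section}.{f.name}"] = getattr(obj, f.name)
        if self.layout_path:
            flat["layout_path"] = self.layout_path
        flat["seed"] = self.seed
        flat["output_dir"] = self.output_dir
        return flat

    def content_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        flat = {k: str(v) for k, v in self.to_flat().items() if k != "output_dir"}
        text = json.dumps(flat, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# -- SNIRF (HDF5) container ---------------------------------------------------


def write_snirf(recording: OpticalRecording, path) -> None:
    """Write a minimal SNIRF file (one data block, CW amplitude-style layout)."""
    import h5py

    n_t, n_ch, _ = recording.od.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths_nm))
        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=recording.od.reshape(n_t, n_ch * 2)
        )
        data.create_dataset("time", data=recording.times_s)
        for ch in range(n_ch):
            for wl in range(2):
                ml = data.create_group(f"measurementList{ch * 2 + wl + 1}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=99999)  # processed ΔOD


def read_snirf(path, subject_id: str | None = None) -> OpticalRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        ts = np.asarray(data["dataTimeSeries"])
        times = np.asarray(data["time"])
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]).tolist())
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        src = [int(np.asarray(data[m]["sourceIndex"])) for m in ml_names]
        wli = [int(np.asarray(data[m]["wavelengthIndex"])) for m in ml_names]
    n_ch = len(set(src))
    od = np.empty((ts.shape[0], n_ch, 2))
    chan_ids = sorted(set(src))
    for col, (s, w) in enumerate(zip(src, wli)):
        od[:, chan_ids.index(s), w - 1] = ts[:, col]
    dt = float(np.median(np.diff(times)))
    return OpticalRecording(
        subject_id=subject_id or path.stem,
        od=od,
        sample_interval_s=dt,
        wavelengths_nm=wavelengths,
    )
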