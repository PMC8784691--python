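"""Readers and writers for the package's on-disk formats.

Waveforms: two-column CSV (time_ms, pressure_mmhg) plus a JSON metadata
sidecar.  Biaxial records: one CSV per protocol (time, marker x/y in
mm, force channels in N) plus a JSON sidecar with reference dimensions
and the protocol ratio.  Histology: one TIFF per section plus a JSON
manifest with depth positions and pixel size.  Strain/stress and EFE
tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fiber_ensemble import EFECurve, RecruitmentResult
from .hemodynamics import PressureWaveform
from .kinematics import BiaxialRecord, MarkerFrame
from .synthetic import SectionImage

__all__ = [
    "write_waveform", "read_waveform",
    "write_biaxial_record", "read_biaxial_record",
    "write_states_table", "read_states_table",
    "write_efe_curve", "read_efe_curve",
    "write_recruitment", "write_histology_stack", "read_histology_stack",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


# -- waveforms -------------------------------------------------------------

def write_waveform(w: PressureWaveform, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_ms": w.time, "pressure_mmhg": w.pressure}).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    _write_json(
        csv_path.with_suffix(".json"),
        {"sampling_rate_hz": w.sampling_rate, "meta": w.meta},
    )


def read_waveform(csv_path: str | Path) -> PressureWaveform:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = csv_path.with_suffix(".json")
    if side.exists():
        info = json.loads(side.read_text())
        rate, meta = info["sampling_rate_hz"], info.get("meta", {})
    else:
        dt = float(np.median(np.diff(df["time_ms"])))
        rate, meta = 1000.0 / dt, {}
    return PressureWaveform(
        time=df["time_ms"].to_numpy(), pressure=df["pressure_mmhg"].to_numpy(),
        sampling_rate=rate, meta=meta,
    )


# -- biaxial records -------------------------------------------------------

def write_biaxial_record(rec: BiaxialRecord, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    rows = []
    for k, (frame, (fc, fl)) in enumerate(zip(rec.frames, rec.forces)):
        row = {"time": frame.time if frame.time is not None else float(k)}
        for i, (x, y) in enumerate(frame.positions, start=1):
            row[f"x{i}_mm"], row[f"y{i}_mm"] = x, y
        row["force_circ_n"], row["force_long_n"] = fc, fl
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.12g")
    _write_json(
        csv_path.with_suffix(".json"),
        {
            "length_circ_mm": rec.length_circ,
            "length_long_mm": rec.length_long,
            "thickness_mm": rec.thickness,
            "protocol_ratio": rec.protocol_ratio,
            "reference_markers_mm": rec.reference.positions,
        },
    )


def read_biaxial_record(csv_path: str | Path) -> BiaxialRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    frames = []
    for _, row in df.iterrows():
        pos = np.array([[row[f"x{i}_mm"], row[f"y{i}_mm"]] for i in range(1, 5)])
        frames.append(MarkerFrame(positions=pos, time=float(row["time"])))
    return BiaxialRecord(
        reference=MarkerFrame(positions=np.array(side["reference_markers_mm"])),
        frames=frames,
        forces=df[["force_circ_n", "force_long_n"]].to_numpy(),
        length_circ=side["length_circ_mm"],
        length_long=side["length_long_mm"],
        thickness=side["thickness_mm"],
        protocol_ratio=side["protocol_ratio"],
    )


# -- tables ----------------------------------------------------------------

def write_states_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_states_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_efe_curve(curve: EFECurve, path: str | Path) -> None:
    pd.DataFrame({"E": curve.E, "S_EFE": curve.S, "TM_EFE": curve.TM}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_efe_curve(path: str | Path) -> EFECurve:
    df = pd.read_csv(path)
    return EFECurve(
        E=df["E"].to_numpy(), S=df["S_EFE"].to_numpy(), TM=df["TM_EFE"].to_numpy()
    )


def write_recruitment(rec: RecruitmentResult | None, path: str | Path) -> None:
    payload = {"detected": rec is not None}
    if rec is not None:
        payload.update(asdict(rec))
    _write_json(Path(path), payload)


# -- histology -------------------------------------------------------------

def write_histology_stack(
    sections: list[SectionImage], out_dir: str | Path, prefix: str = "section"
) -> Path:
    """Write one TIFF per section plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sec in enumerate(sections):
        name = f"{prefix}_{i:03d}.tif"
        tifffile.imwrite(out_dir / name, sec.rgb)
        entries.append(
            {"file": name, "depth_um": sec.depth_um, "pixel_size_um": sec.pixel_size_um}
        )
    manifest = out_dir / f"{prefix}_manifest.json"
    _write_json(manifest, {"sections": entries})
    return manifest


def read_histology_stack(manifest_path: str | Path) -> list[SectionImage]:
    manifest_path = Path(manifest_path)
    info = json.loads(manifest_path.read_text())
    sections = []
    for entry in info["sections"]:
        rgb = tifffile.imread(manifest_path.parent / entry["file"])
        sections.append(
            SectionImage(
                rgb=rgb, depth_um=entry["depth_um"],
                pixel_size_um=entry.get("pixel_size_um", 1.0),
            )
        )
    return sections
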