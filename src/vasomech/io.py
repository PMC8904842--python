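"""Readers and writers for the plain-text interchange formats.

Tensile records are CSV files with ``# key=value`` header comments for the
specimen geometry followed by ``displacement_mm,force_N`` columns.  Contours
and marker traces are two-column CSVs (``x_um,y_um``) with an optional JSON
sidecar for scale/label metadata.  Triplicate angle measurements use a
long-format CSV (``sample_id,replicate,alpha_deg``).  Dose-response series
are ``agent,dose_M,tension_mN_per_mm`` CSVs with a JSON metadata sidecar.
ROI polygons are JSON ``[[x, y], ...]`` in 0-based pixel coordinates (y
down); stain matrices are YAML with rows per stain and columns R,G,B OD.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .histology import StainMatrix
from .residual import MarkerTrace, RingContour
from .tensile import TensileRecord
from .vasoreactivity import CCRCRecord

__all__ = [
    "read_tensile_csv",
    "write_tensile_csv",
    "read_contour_csv",
    "write_contour_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_angles_csv",
    "write_angles_csv",
    "read_ccrc_csv",
    "write_ccrc_csv",
    "read_roi_json",
    "write_roi_json",
    "read_stain_yaml",
    "write_stain_yaml",
    "read_image",
    "write_image",
    "write_sidecar_json",
]


def _read_header_comments(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def write_tensile_csv(path, record: TensileRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f"# l0_mm={record.l0}\n# w0_mm={record.w0}\n# e0_mm={record.e0}\n")
        if record.specimen_id:
            fh.write(f"# specimen_id={record.specimen_id}\n")
        pd.DataFrame(
            {"displacement_mm": record.displacement, "force_N": record.force}
        ).to_csv(fh, index=False)


def read_tensile_csv(path) -> TensileRecord:
    meta = _read_header_comments(path)
    for key in ("l0_mm", "w0_mm", "e0_mm"):
        if key not in meta:
            raise ValueError(f"tensile CSV missing header comment '# {key}=...'")
    df = pd.read_csv(path, comment="#")
    return TensileRecord(
        l0=float(meta["l0_mm"]),
        w0=float(meta["w0_mm"]),
        e0=float(meta["e0_mm"]),
        displacement=df["displacement_mm"].to_numpy(),
        force=df["force_N"].to_numpy(),
        specimen_id=meta.get("specimen_id", ""),
    )


def write_contour_csv(path, contour: RingContour, sidecar: dict | None = None) -> None:
    pd.DataFrame({"x_um": contour.points[:, 0], "y_um": contour.points[:, 1]}).to_csv(
        path, index=False
    )
    meta = {"closed": bool(contour.closed)}
    if sidecar:
        meta.update(sidecar)
    write_sidecar_json(Path(path).with_suffix(".json"), meta)


def read_contour_csv(path) -> RingContour:
    df = pd.read_csv(path)
    closed = False
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        closed = bool(json.loads(sidecar.read_text()).get("closed", False))
    return RingContour(df[["x_um", "y_um"]].to_numpy(), closed=closed)


def write_trace_csv(path, trace: MarkerTrace) -> None:
    pd.DataFrame({"x_um": trace.points[:, 0], "y_um": trace.points[:, 1]}).to_csv(
        path, index=False
    )
    write_sidecar_json(
        Path(path).with_suffix(".json"), {"scale": trace.scale, "label": trace.label}
    )


def read_trace_csv(path) -> MarkerTrace:
    df = pd.read_csv(path)
    scale, label = 1.0, ""
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        scale = float(meta.get("scale", 1.0))
        label = meta.get("label", "")
    return MarkerTrace(df[["x_um", "y_um"]].to_numpy(), scale=scale, label=label)


def write_angles_csv(path, angles: dict) -> None:
    """``angles`` maps sample_id -> iterable of replicate angle readings."""
    rows = [
        {"sample_id": sid, "replicate": i + 1, "alpha_deg": float(a)}
        for sid, reps in angles.items()
        for i, a in enumerate(reps)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_angles_csv(path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[sid] = grp.sort_values("replicate")["alpha_deg"].to_list()
    return out


def write_ccrc_csv(path, record: CCRCRecord) -> None:
    pd.DataFrame(
        {
            "agent": record.agent,
            "dose_M": record.doses,
            "tension_mN_per_mm": record.tensions,
        }
    ).to_csv(path, index=False)
    meta = {
        "segment_length_mm": record.segment_length,
        "basal_tension_mN_per_mm": record.basal_tension,
        "kmax_tension_mN_per_mm": record.kmax_tension,
        "preconstriction_tension_mN_per_mm": record.preconstriction_tension,
    }
    write_sidecar_json(Path(path).with_suffix(".json"), meta)


def read_ccrc_csv(path, meta_path=None) -> CCRCRecord:
    df = pd.read_csv(path)
    meta_path = Path(meta_path) if meta_path else Path(path).with_suffix(".json")
    if not meta_path.exists():
        raise ValueError(f"CCRC metadata JSON not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    return CCRCRecord(
        agent=str(df["agent"].iloc[0]),
        doses=df["dose_M"].to_numpy(),
        tensions=df["tension_mN_per_mm"].to_numpy(),
        segment_length=float(meta["segment_length_mm"]),
        basal_tension=float(meta["basal_tension_mN_per_mm"]),
        kmax_tension=meta.get("kmax_tension_mN_per_mm"),
        preconstriction_tension=meta.get("preconstriction_tension_mN_per_mm"),
    )


def write_roi_json(path, polygon) -> None:
    Path(path).write_text(json.dumps(np.asarray(polygon, dtype=float).tolist()))


def read_roi_json(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text()), dtype=float)


def write_stain_yaml(path, stains: StainMatrix) -> None:
    payload = {
        name: [float(v) for v in row]
        for name, row in zip(stains.names, stains.matrix)
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_stain_yaml(path) -> StainMatrix:
    payload = yaml.safe_load(Path(path).read_text())
    names = tuple(payload.keys())
    if len(names) != 3:
        raise ValueError("stain YAML must define exactly 3 stains")
    return StainMatrix(np.array([payload[n] for n in names], dtype=float), names=names)


def write_image(path, pixels: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = (arr * 255).astype(np.uint8)
    iio.imwrite(path, arr)


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


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


def write_sidecar_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
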