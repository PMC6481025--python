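"""Readers and writers for the pipeline's on-disk formats.

Images are 8-bit TIFF (lossless, the acquisition format) or PNG. Traces
are CSV with header ``segment_id,point_index,x,y`` in 0-based pixel
coordinates (x rightward, y downward) at full float precision. Subjects
and metrics are flat CSV tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import SubjectRecord
from .synth import VesselImage

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_traces",
    "write_traces",
    "read_subjects",
    "write_subjects",
    "read_metrics",
    "write_metrics",
]


class FormatError(ValueError):
    """Unsupported or malformed input file."""


def read_image(path, site: Optional[str] = None, eye: Optional[str] = None) -> VesselImage:
    """Read an 8-bit TIFF or PNG raster.

    Raises :class:`FormatError` for other formats or bit depths.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        raise FormatError(f"unsupported image format {suffix!r}: expected TIFF or PNG")
    if arr.dtype != np.uint8:
        raise FormatError(
            f"unsupported bit depth {arr.dtype}: the pipeline requires 8-bit images"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]  # drop alpha
    return VesselImage(pixels=arr, site=site, eye=eye)


def write_image(path, image: VesselImage) -> None:
    """Write as lossless TIFF or PNG according to the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    elif suffix == ".png":
        from PIL import Image

        Image.fromarray(image.pixels).save(path)
    else:
        raise FormatError(f"unsupported image format {suffix!r}")


def write_traces(path, traces: Dict[str, np.ndarray]) -> None:
    """Write polylines keyed by segment id as a trace CSV."""
    rows = []
    for seg_id, pts in traces.items():
        pts = np.asarray(pts, dtype=float)
        for i, (x, y) in enumerate(pts):
            rows.append((str(seg_id), i, repr(float(x)), repr(float(y))))
    df = pd.DataFrame(rows, columns=["segment_id", "point_index", "x", "y"])
    df.to_csv(path, index=False)


def read_traces(path) -> Dict[str, np.ndarray]:
    """Read a trace CSV back into ``{segment_id: (N, 2) polyline}``.

    Rows are re-sorted by point_index within each segment; duplicate or
    non-contiguous indexes and segments with fewer than 3 points are
    rejected.
    """
    df = pd.read_csv(path, dtype={"segment_id": str})
    required = {"segment_id", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"trace CSV must have columns {sorted(required)}")
    out: Dict[str, np.ndarray] = {}
    for seg_id, g in df.groupby("segment_id", sort=True):
        g = g.sort_values("point_index")
        idx = g["point_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise FormatError(f"segment {seg_id!r}: duplicate point_index")
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(f"segment {seg_id!r}: point_index not contiguous from 0")
        if len(idx) < 3:
            raise FormatError(f"segment {seg_id!r}: fewer than 3 points")
        out[str(seg_id)] = g[["x", "y"]].to_numpy(dtype=float)
    return out


_SUBJECT_COLS = [
    "subject_id", "group", "sex", "age", "gfr", "mwt", "nyha", "stroke",
    "phenotype", "mutation", "therapy",
]


def write_subjects(path, records: Sequence[SubjectRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
                "age": r.age, "gfr": r.gfr, "mwt": r.mwt, "nyha": r.nyha,
                "stroke": ("yes" if r.stroke else "no") if r.stroke is not None else None,
                "phenotype": r.phenotype, "mutation": r.mutation, "therapy": r.therapy,
            }
            for r in records
        ],
        columns=_SUBJECT_COLS,
    )
    df.to_csv(path, index=False)


def _opt(v, cast=float):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return cast(v)


def read_subjects(path) -> List[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "sex", "age"}
    if not required.issubset(df.columns):
        raise FormatError(f"subjects CSV must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        stroke = row.get("stroke")
        if isinstance(stroke, str):
            stroke = stroke.strip().lower() in ("yes", "true", "1")
        else:
            stroke = _opt(stroke, bool)
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                gfr=_opt(row.get("gfr")),
                mwt=_opt(row.get("mwt")),
                nyha=_opt(row.get("nyha"), int),
                stroke=stroke,
                phenotype=_opt(row.get("phenotype"), str),
                mutation=_opt(row.get("mutation"), str),
                therapy=_opt(row.get("therapy"), str),
            )
        )
    return records


_METRIC_COLS = [
    "subject_id", "group", "sex", "age", "eye", "site", "segment_id",
    "arc_length_px", "soam", "pad", "i2e",
]


def write_metrics(path, results) -> None:
    """Write a list of TortuosityResult (or a prepared DataFrame) as CSV."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([r.as_dict() for r in results])
    df = df[[c for c in _METRIC_COLS if c in df.columns]]
    df.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "segment_id": str})
    required = {"subject_id", "eye", "site", "segment_id", "soam", "pad", "i2e"}
    if not required.issubset(df.columns):
        raise FormatError(f"metrics CSV must have columns {sorted(required)}")
    return df
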