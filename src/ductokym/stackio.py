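"""Containers and file I/O: image stacks, analysis lines, schedules, results.

Conventions
-----------
* Coordinates are 0-based, continuous, ordered ``(col=x, row=y)``; pixel
  centers sit at integer coordinates.
* The time of frame ``i`` is ``i * frame_interval_s`` (first frame at t=0).
* Intensities live on a common floating scale in [0, 1]; stacks are written
  as 16-bit grayscale multi-page TIFF (value = intensity * 65535, rounded).
* All CSV output is comma-separated UTF-8 with a mandatory header row and
  "." as the decimal mark; column names carry units (``time_s``,
  ``prominence_px``, ``bpm``).

Readers reject rather than guess: a stack without a frame interval (from an
explicit argument, a JSON sidecar, or the TIFF description tag — in that
order of precedence) is an error, because every downstream number has units
of beats per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: scale used when quantizing [0, 1] floats to 16-bit TIFF samples
TIFF_SCALE = 65535


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """A time-lapse movie held as a frames x rows x cols intensity array.

    Attributes
    ----------
    data : ndarray, shape (frames, rows, cols)
        Intensities on the common [0, 1] float scale.
    frame_interval_s : float
        Seconds between consecutive frames (dt).
    pixel_size_um : float or None
        Physical pixel size if known; all geometry stays in pixel units
        when it is not.
    origin_label : str
        Free-form provenance note (file path, preset name, ...).
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float | None = None
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be frames x rows x cols")
        if self.data.shape[0] < 2:
            raise ValueError("stack must contain >= 2 frames")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds (frame i at i*dt)."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class AnalysisLine:
    """A sampling line along which a kymograph is extracted.

    ``kind`` is "transverse" (crosses both duct walls; used for diameter
    tracking) or "longitudinal" (runs along the lumen; used for flow).
    ``endpoints`` are two continuous (col, row) points.  ``width_px``
    averages over that many parallel 1-px offsets perpendicular to the
    line.  ``axial_station_col`` is the representative axial position of a
    transverse line, used when comparing event timing across stations.
    """

    id: str
    kind: str
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    width_px: int = 1
    axial_station_col: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("transverse", "longitudinal"):
            raise ValueError(f"unknown line kind {self.kind!r}")
        p0, p1 = (np.asarray(p, dtype=float) for p in self.endpoints)
        if np.allclose(p0, p1):
            raise ValueError(f"line {self.id!r}: endpoints must be distinct")
        if self.width_px < 1 or int(self.width_px) != self.width_px:
            raise ValueError("width_px must be an integer >= 1")
        self.endpoints = (tuple(p0), tuple(p1))
        if self.axial_station_col is None and self.kind == "transverse":
            self.axial_station_col = 0.5 * (p0[0] + p1[0])

    @property
    def length_px(self) -> float:
        p0, p1 = (np.asarray(p) for p in self.endpoints)
        return float(np.hypot(*(p1 - p0)))

    def reversed(self) -> "AnalysisLine":
        return AnalysisLine(
            id=self.id,
            kind=self.kind,
            endpoints=(self.endpoints[1], self.endpoints[0]),
            width_px=self.width_px,
            axial_station_col=self.axial_station_col,
        )


@dataclass
class DrugSchedule:
    """Ordered list of (time_s, label) drug additions.

    Times must be strictly increasing; validation against the recording
    duration happens where the duration is known (epoch statistics).
    """

    additions: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.additions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")

    def __iter__(self):
        return iter(self.additions)

    def __len__(self) -> int:
        return len(self.additions)


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: MovieStack, path: str | Path,
                ground_truth: dict | None = None) -> Path:
    """Write a stack as multi-page 16-bit grayscale TIFF plus JSON sidecar.

    The sidecar carries ``frame_interval_s`` (and ground truth when given)
    so a written movie can be re-read without external metadata.  Returns
    the TIFF path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raw = np.clip(stack.data, 0.0, 1.0)
    pages = np.round(raw * TIFF_SCALE).astype(np.uint16)
    description = json.dumps({"frame_interval_s": stack.frame_interval_s})
    tifffile.imwrite(path, pages, photometric="minisblack",
                     description=description)
    sidecar: dict = {"frame_interval_s": stack.frame_interval_s}
    if stack.pixel_size_um is not None:
        sidecar["pixel_size_um"] = stack.pixel_size_um
    if ground_truth is not None:
        sidecar.update(ground_truth)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path,
               frame_interval_s: float | None = None) -> MovieStack:
    """Read a multi-page TIFF as a :class:`MovieStack`.

    The frame interval is taken from, in order of precedence, the
    ``frame_interval_s`` argument, a JSON sidecar next to the file, or a
    JSON document in the TIFF description tag.  Raises if none supplies it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        description = tif.pages[0].description or ""
    if len(pages) < 2:
        raise ValueError(f"{path}: stack must contain >= 2 frames")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: mixed frame shapes {sorted(shapes)}")
    arr = np.stack(pages)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        data = arr.astype(np.float64) / scale
    else:
        data = arr.astype(np.float64)

    dt = frame_interval_s
    if dt is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            dt = meta.get("frame_interval_s")
    if dt is None and description:
        try:
            dt = json.loads(description).get("frame_interval_s")
        except (json.JSONDecodeError, AttributeError):
            dt = None
    if dt is None:
        raise ValueError(
            f"{path}: frame interval not found; pass frame_interval_s "
            "(CLI: --frame-interval) or provide a JSON sidecar"
        )
    return MovieStack(data=data, frame_interval_s=float(dt),
                      origin_label=str(path))


# ---------------------------------------------------------------------------
# line / schedule config
# ---------------------------------------------------------------------------

def _line_to_dict(line: AnalysisLine) -> dict:
    d = {
        "id": line.id,
        "kind": line.kind,
        "endpoints": [list(map(float, p)) for p in line.endpoints],
        "width_px": int(line.width_px),
    }
    if line.axial_station_col is not None:
        d["axial_station_col"] = float(line.axial_station_col)
    return d


def _line_from_dict(d: dict) -> AnalysisLine:
    return AnalysisLine(
        id=str(d["id"]),
        kind=str(d["kind"]),
        endpoints=(tuple(d["endpoints"][0]), tuple(d["endpoints"][1])),
        width_px=int(d.get("width_px", 1)),
        axial_station_col=d.get("axial_station_col"),
    )


def write_lines(lines: Sequence[AnalysisLine], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"lines": [_line_to_dict(l) for l in lines]}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))
    return path


def read_lines(path: str | Path) -> list[AnalysisLine]:
    """Read analysis lines from YAML or JSON config."""
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    entries = payload["lines"] if isinstance(payload, dict) else payload
    return [_line_from_dict(d) for d in entries]


def read_schedule(path: str | Path) -> DrugSchedule:
    """Read a drug schedule from YAML/JSON: list of {time_s, label}."""
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    entries = payload["schedule"] if isinstance(payload, dict) else payload
    additions = [(float(d["time_s"]), str(d["label"])) for d in entries]
    return DrugSchedule(additions=additions)


def write_schedule(schedule: DrugSchedule, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schedule": [{"time_s": t, "label": lab}
                            for t, lab in schedule]}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["line_id", "time_s", "prominence_px", "width_s",
                 "axial_station_col"]


def write_events_csv(events: Iterable, path: str | Path) -> Path:
    """Write detected contraction events as CSV (header always present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "line_id": e.line_id,
            "time_s": e.time_s,
            "prominence_px": e.prominence_px,
            "width_s": e.width_s,
            "axial_station_col": e.axial_station_col,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_kymograph_image(matrix: np.ndarray, path: str | Path) -> Path:
    """Export a kymograph matrix as TIFF (16-bit) or PNG (8-bit, rescaled)."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.round(np.clip(matrix, 0, 1) * TIFF_SCALE).astype(np.uint16),
        )
    else:
        lo, hi = float(np.min(matrix)), float(np.max(matrix))
        span = hi - lo if hi > lo else 1.0
        img = np.round((matrix - lo) / span * 255).astype(np.uint8)
        iio.imwrite(path, img)
    return path
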