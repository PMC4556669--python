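"""Readers and writers for the external formats the pipeline touches.

Conventions used throughout the package
---------------------------------------
* Image coordinates are 0-based ``(y, x)`` with the origin at the top-left
  pixel centre.  Sub-pixel (float) coordinates are accepted everywhere.
* Hyperstacks are held in canonical ``(T, C, Z, Y, X)`` order.
* Default spatial calibration is 32/150 µm per pixel and 10 min between
  timepoints — the acquisition geometry of the photoconversion assay this
  package quantifies (a 150-pixel retrograde trace spans 32 µm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_FRAME_INTERVAL_MIN",
    "TimelapseStack",
    "TracePath",
    "SequenceRecord",
    "ChannelCountError",
    "CalibrationError",
    "NonLinearTraceError",
    "DegenerateTraceError",
    "read_hyperstack",
    "write_hyperstack",
    "read_trace",
    "write_trace_csv",
    "read_fasta",
    "write_fasta",
]

#: µm per pixel when metadata carries no calibration (150 px = 32 µm).
DEFAULT_PIXEL_SIZE_UM = 32.0 / 150.0
#: minutes between post-conversion z-stacks.
DEFAULT_FRAME_INTERVAL_MIN = 10.0

IUPAC_NT = set("ACGTURYSWKMBDHVN")


class ChannelCountError(ValueError):
    """Raised when a stack does not carry the two required channels."""


class CalibrationError(ValueError):
    """Raised when calibration is required but neither metadata nor caller supplies it."""


class NonLinearTraceError(ValueError):
    """Raised for branched or unordered SWC traces."""


class DegenerateTraceError(ValueError):
    """Raised for traces with fewer than two points."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimelapseStack:
    """A two-channel timelapse of z-stacks in canonical (T, C, Z, Y, X) order.

    ``channel_roles`` maps ``"green"`` (unconverted Kaede) and ``"red"``
    (converted Kaede) to channel indices.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    channel_roles: dict = field(default_factory=lambda: {"green": 0, "red": 1})
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 5:
            raise ValueError(f"frames must be 5-D (T,C,Z,Y,X), got {self.frames.ndim}-D")
        if any(d < 1 for d in self.frames.shape):
            raise ValueError("all dimensions must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")
        roles = set(self.channel_roles)
        if roles != {"green", "red"}:
            raise ChannelCountError(f"channel_roles must name green and red, got {roles}")
        if len(set(self.channel_roles.values())) != 2:
            raise ChannelCountError("green and red must map to distinct channels")
        if self.frames.shape[1] < 2:
            raise ChannelCountError(
                f"channel count: need >= 2 channels, got {self.frames.shape[1]}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.frames.min() < 0 or self.frames.max() > 2 ** self.bit_depth - 1:
            raise ValueError("intensities outside bit-depth range")

    @property
    def n_timepoints(self) -> int:
        return self.frames.shape[0]

    def channel(self, role: str, timepoint: int) -> np.ndarray:
        """One timepoint's z-stack (Z, Y, X) for the given channel role."""
        return self.frames[timepoint, self.channel_roles[role]]

    def green(self, timepoint: int) -> np.ndarray:
        return self.channel("green", timepoint)

    def red(self, timepoint: int) -> np.ndarray:
        return self.channel("red", timepoint)


@dataclass
class TracePath:
    """An ordered retrograde neurite trace; point 0 is the growth-cone tip."""

    points: np.ndarray  # (N, 2) float, (y, x), 0-based
    timepoint_index: int = 0
    oriented_retrograde: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array of (y, x)")
        if len(self.points) < 2:
            raise DegenerateTraceError("degenerate trace: fewer than 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> float:
        """Total polyline length in pixels."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (IUPAC alphabet, case preserved)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = [i for i, c in enumerate(self.sequence.upper()) if c not in IUPAC_NT]
        if bad:
            raise ValueError(f"invalid alphabet characters at positions {bad[:10]}")

    def normalized(self) -> str:
        """Uppercase DNA alphabet (U -> T)."""
        return self.sequence.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# hyperstack I/O
# ---------------------------------------------------------------------------

def write_hyperstack(stack: TimelapseStack, path) -> None:
    """Write as an ImageJ-dialect hyperstack TIFF; lossless with read_hyperstack."""
    data = np.moveaxis(stack.frames, 1, 2)  # ImageJ expects TZCYX
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    info = json.dumps(
        {"channel_roles": stack.channel_roles, "bit_depth": stack.bit_depth}
    )
    tifffile.imwrite(
        path,
        data.astype(dtype),
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={
            "axes": "TZCYX",
            "unit": "um",
            "finterval": stack.frame_interval_min,
            "Info": info,
        },
    )


def read_hyperstack(
    path,
    axis_order_hint: str | None = None,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    channel_roles: dict | None = None,
    strict_calibration: bool = False,
) -> TimelapseStack:
    """Read an ImageJ-hyperstack or OME TIFF into canonical (T,C,Z,Y,X) order.

    Calibration is taken from metadata when present, then from the keyword
    arguments, then from the package defaults (32/150 µm/px, 10 min/frame).
    With ``strict_calibration=True`` a file without calibration metadata and
    without caller-supplied values raises :class:`CalibrationError`.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = axis_order_hint or series.axes
        if len(axes) != data.ndim:
            raise CalibrationError(
                f"calibration required: axis metadata {axes!r} does not match "
                f"{data.ndim}-D data and no usable axis_order_hint was given"
            )
        # expand to the full TCZYX set
        order = []
        for ax in axes.upper().replace("S", "C").replace("Q", "Z"):
            if ax not in "TCZYX" or ax in order:
                raise CalibrationError(f"calibration required: unsupported axis {ax!r}")
            order.append(ax)
        for ax in "TCZYX":
            if ax not in order:
                data = data[np.newaxis]
                order.insert(0, ax)
        data = np.transpose(data, [order.index(ax) for ax in "TCZYX"])

        meta_px = meta_dt = None
        roles = channel_roles
        bit_depth = None
        ij = tif.imagej_metadata or {}
        if "finterval" in ij:
            meta_dt = float(ij["finterval"])
        if ij.get("Info"):
            try:
                info = json.loads(ij["Info"])
                roles = roles or {k: int(v) for k, v in info["channel_roles"].items()}
                bit_depth = info.get("bit_depth")
            except (ValueError, KeyError, TypeError):
                pass
        page = tif.pages[0]
        # a resolution tag is only meaningful with a declared unit (TIFF's
        # default ResolutionUnit NONE with 1/1 just means "uncalibrated")
        res_unit = page.tags["ResolutionUnit"].value if "ResolutionUnit" in page.tags else 1
        has_unit = (getattr(res_unit, "value", res_unit) not in (0, 1)) or bool(ij.get("unit"))
        if has_unit and "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                meta_px = den / num

    if data.shape[1] < 2:
        raise ChannelCountError(f"channel count: need >= 2 channels, got {data.shape[1]}")

    px = meta_px or pixel_size_um
    dt = meta_dt or frame_interval_min
    if strict_calibration and (px is None or dt is None):
        raise CalibrationError("calibration required: no metadata and no values supplied")
    if bit_depth is None:
        bit_depth = 8 if data.dtype == np.uint8 else 16
    return TimelapseStack(
        frames=data,
        pixel_size_um=px if px is not None else DEFAULT_PIXEL_SIZE_UM,
        frame_interval_min=dt if dt is not None else DEFAULT_FRAME_INTERVAL_MIN,
        channel_roles=roles or {"green": 0, "red": 1},
        bit_depth=bit_depth,
    )


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def write_trace_csv(traces, path) -> None:
    """Write traces as CSV with columns timepoint,y,x (tip-first row order)."""
    if isinstance(traces, TracePath):
        traces = [traces]
    rows = []
    for tr in traces:
        for y, x in tr.points:
            rows.append((tr.timepoint_index, y, x))
    pd.DataFrame(rows, columns=["timepoint", "y", "x"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def _read_trace_csv(path) -> list[TracePath]:
    df = pd.read_csv(path)
    missing = {"timepoint", "y", "x"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for tp, grp in df.groupby("timepoint", sort=True):
        pts = grp[["y", "x"]].to_numpy(float)
        if len(pts) < 2:
            raise DegenerateTraceError(f"degenerate trace at timepoint {tp}")
        traces.append(TracePath(points=pts, timepoint_index=int(tp)))
    return traces


def _read_trace_swc(path, timepoint_index: int = 0) -> list[TracePath]:
    # SWC: id type x y z radius parent; only geometry and parent order are used
    nodes: dict[int, tuple[float, float, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        nid, parent = int(f[0]), int(f[6])
        x, y = float(f[2]), float(f[3])
        nodes[nid] = (y, x, parent)
    if len(nodes) < 2:
        raise DegenerateTraceError("degenerate trace: fewer than 2 SWC nodes")
    children: dict[int, list[int]] = {}
    roots = []
    for nid, (_, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            children.setdefault(parent, []).append(nid)
    if len(roots) != 1:
        raise NonLinearTraceError(f"non-linear trace: {len(roots)} root nodes")
    if any(len(c) > 1 for c in children.values()):
        raise NonLinearTraceError("non-linear trace: branch node present")
    pts, nid = [], roots[0]
    while True:
        y, x, _ = nodes[nid]
        pts.append((y, x))
        nxt = children.get(nid)
        if not nxt:
            break
        nid = nxt[0]
    if len(pts) != len(nodes):
        raise NonLinearTraceError("non-linear trace: disconnected nodes")
    return [TracePath(points=np.array(pts), timepoint_index=timepoint_index)]


def read_trace(path, format: str | None = None) -> list[TracePath]:
    """Read traces (one :class:`TracePath` per timepoint), ordered tip-first.

    ``format`` is ``"csv"`` or ``"swc"``; inferred from the suffix if omitted.
    The SWC root node is taken to be the growth-cone tip.
    """
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_trace_csv(path)
    if fmt == "swc":
        return _read_trace_swc(path)
    raise ValueError(f"unknown trace format {fmt!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, normalize: bool = False) -> list[SequenceRecord]:
    """Read FASTA records in file order; ``normalize`` applies uppercase U->T."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if normalize:
            seq = seq.upper().replace("U", "T")
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r}; both kept", stacklevel=2)
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")
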