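"""Shared experiment containers and file input/output.

Three-cube sensitized-emission FRET experiments acquire three wide-field
channels per time point: donor excitation / donor emission (``I_DD``), donor
excitation / acceptor emission (``I_DA``, the FRET channel) and acceptor
excitation / acceptor emission (``I_AA``).  This module defines the in-memory
containers for such stacks, condition protocols and regions of interest, and
reads/writes the plain formats the pipeline touches (multi-page TIFF, ROI
JSON, protocol CSV, YAML config).

Coordinate convention
---------------------
Images are row-major and 0-based.  ROI polygon vertices are given as
``[x, y]`` pairs in pixel-center coordinates; a pixel belongs to a polygon ROI
iff its center lies inside or on the polygon boundary (scanline
rasterization).  A rectangle spanning vertices (0,0)-(4,4) therefore contains
exactly 25 pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as _draw_polygon

from .errors import CoverageError, FormatError, LayoutError, ValidationError

CANONICAL_CHANNELS = ("I_DD", "I_DA", "I_AA")

#: Defaults for every numeric knob in the pipeline; a user config file
#: (YAML) overrides individual keys.
DEFAULT_CONFIG: dict = {
    "timestamp_spacing_s": 10.0,      # acquisition cadence when TIFF lacks times
    "pixel_binning": 8,
    "exposure_ms": 100.0,
    "saturation_level": None,          # None -> dtype max of the TIFF
    "channel_layout": ["I_DD", "I_DA", "I_AA"],
    "processing": {
        "rolling_ball_radius_px": 50,
        "gaussian_sigma_px": 2.0,
        "threshold": 1.0,
        "unsharp_sigma_px": 3.0,
        "unsharp_weight": 0.7,
        "saturation_margin": 1.0,
        "background_method": "label",  # "label" | "rolling_ball" | "offset"
    },
    "calibration": {
        "method": "regression_slope",
        "min_valid_pixels": 100,
        "purity_ceiling_sd": 2.0,
    },
    "sefret": {
        "baseline_condition": "iso",
    },
    "ratio": {
        "floor_sd": 3.0,
    },
    "bleach": {
        "qc_ceiling": 0.10,
        "overlap_bleached": 0.8,
        "overlap_control": 0.05,
    },
    "stats": {
        "alpha_levels": [0.05, 0.005, 0.0005],
    },
    "pcf": {
        "v_select_mv": -80.0,
        "window_frac": [0.5, 0.9],
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Return the default config, deep-merged with an optional YAML file."""
    cfg = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_merge(cfg, user)
    return cfg


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _deep_merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_merge(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ThreeCubeStack:
    """Time-lapse triple-channel intensity stack (the raw measurement).

    All three grids share one ``(T, H, W)`` shape; intensities are in
    arbitrary detector units and must be non-negative.
    """

    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    timestamps: np.ndarray
    pixel_binning: int = 8
    exposure_ms: float = 100.0
    saturation_level: float = 65535.0
    channel_names: tuple = CANONICAL_CHANNELS

    def __post_init__(self):
        self.i_dd = np.asarray(self.i_dd, dtype=float)
        self.i_da = np.asarray(self.i_da, dtype=float)
        self.i_aa = np.asarray(self.i_aa, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not (self.i_dd.shape == self.i_da.shape == self.i_aa.shape):
            raise ValidationError("channel grids must share one shape")
        if self.i_dd.ndim != 3:
            raise ValidationError("channel grids must be T x H x W")
        if len(self.timestamps) != self.i_dd.shape[0]:
            raise ValidationError("timestamps length must equal T")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        for name, arr in (("i_dd", self.i_dd), ("i_da", self.i_da), ("i_aa", self.i_aa)):
            if np.any(arr < 0):
                raise ValidationError(f"negative intensities in {name}")
        if self.saturation_level <= 0:
            raise ValidationError("saturation_level must be positive")
        if self.pixel_binning < 1:
            raise ValidationError("pixel_binning must be a positive integer")
        if self.exposure_ms <= 0:
            raise ValidationError("exposure_ms must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.i_dd.shape[0]

    @property
    def image_shape(self) -> tuple:
        return self.i_dd.shape[1:]

    def frame(self, t: int) -> tuple:
        """Return the (i_dd, i_da, i_aa) images at time index ``t``."""
        return self.i_dd[t], self.i_da[t], self.i_aa[t]


@dataclass
class ProtocolSegment:
    start_s: float
    end_s: float
    condition: str
    osmolarity_mosm: float


@dataclass
class ConditionProtocol:
    """Ordered, contiguous buffer-condition segments tiling an experiment."""

    segments: Sequence[ProtocolSegment]

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s.start_s)
        for s in segs:
            if s.end_s <= s.start_s:
                raise ValidationError("protocol segment with end <= start")
            if s.osmolarity_mosm <= 0:
                raise ValidationError("osmolarity must be positive")
        for a, b in zip(segs[:-1], segs[1:]):
            if not np.isclose(a.end_s, b.start_s):
                raise ValidationError("protocol segments must tile time without gaps")
        self.segments = list(segs)

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    def condition_at(self, t_s: float) -> str:
        for s in self.segments:
            if s.start_s <= t_s < s.end_s:
                return s.condition
        if np.isclose(t_s, self.end_s):
            return self.segments[-1].condition
        raise CoverageError(f"time {t_s} s outside protocol [{self.start_s}, {self.end_s}]")

    def labels_for(self, timestamps: Sequence[float]) -> list:
        return [self.condition_at(t) for t in timestamps]


ROI_KINDS = ("cell", "golgi", "bleach_region", "line")


@dataclass
class Roi:
    """A single region of interest: polygon, pixel mask, or 2-point line."""

    roi_id: str
    kind: str
    polygon: np.ndarray | None = None      # (N, 2) array of [x, y]
    mask: np.ndarray | None = None         # bool (H, W), rasterized lazily
    endpoints: np.ndarray | None = None    # (2, 2) [x, y] pairs for lines

    def __post_init__(self):
        if self.kind not in ROI_KINDS:
            raise ValidationError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "line":
            pts = np.asarray(self.endpoints if self.endpoints is not None else self.polygon,
                             dtype=float)
            if pts.shape != (2, 2):
                raise ValidationError("a line ROI must have exactly two endpoints")
            self.endpoints = pts
            self.polygon = None


@dataclass
class RoiSet:
    rois: Sequence[Roi]
    image_shape: tuple

    def __post_init__(self):
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate roi_id in RoiSet")
        h, w = self.image_shape
        for roi in self.rois:
            pts = roi.endpoints if roi.kind == "line" else roi.polygon
            if pts is not None:
                pts = np.asarray(pts, dtype=float)
                x, y = pts[:, 0], pts[:, 1]
                if np.any(x < 0) or np.any(y < 0) or np.any(x > w - 1) or np.any(y > h - 1):
                    raise ValidationError(f"ROI {roi.roi_id} extends outside image bounds")
            if roi.mask is not None and roi.mask.shape != tuple(self.image_shape):
                raise ValidationError(f"ROI {roi.roi_id} mask shape mismatch")
            if roi.kind != "line" and roi.mask is None:
                roi.mask = rasterize_polygon(roi.polygon, self.image_shape)

    def of_kind(self, kind: str) -> list:
        return [r for r in self.rois if r.kind == kind]

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)


def rasterize_polygon(poly_xy: np.ndarray, shape: tuple) -> np.ndarray:
    """Rasterize an ``[x, y]`` vertex list to a boolean mask.

    Vertices are pixel-center coordinates; boundary pixels are included, so a
    rectangle (0,0)-(4,4) covers a 5x5 block of 25 pixels.
    """
    poly_xy = np.asarray(poly_xy, dtype=float)
    if poly_xy.ndim != 2 or poly_xy.shape[1] != 2 or len(poly_xy) < 3:
        raise ValidationError("polygon needs >= 3 [x, y] vertices")
    rr, cc = _draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=tuple(shape))
    mask = np.zeros(tuple(shape), dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def write_three_cube_tiff(path: str | Path, stack: ThreeCubeStack,
                          layout: Sequence[str] = CANONICAL_CHANNELS) -> None:
    """Write a stack as a multi-page TIFF, channel-major per time point."""
    order = [CANONICAL_CHANNELS.index(c) for c in layout]
    chans = (stack.i_dd, stack.i_da, stack.i_aa)
    pages = []
    for t in range(stack.n_timepoints):
        for idx in order:
            pages.append(chans[idx][t].astype(np.float32))
    meta = {
        "timestamps": list(map(float, stack.timestamps)),
        "pixel_binning": int(stack.pixel_binning),
        "exposure_ms": float(stack.exposure_ms),
        "saturation_level": float(stack.saturation_level),
        "channel_layout": list(layout),
    }
    tifffile.imwrite(str(path), np.stack(pages), metadata=meta,
                     photometric="minisblack")


def read_three_cube_tiff(path: str | Path,
                         layout: Sequence[str] | None = None,
                         config: dict | None = None) -> ThreeCubeStack:
    """Read a multi-page TIFF into a validated :class:`ThreeCubeStack`.

    Pages are interpreted channel-major within each time point using
    ``layout`` (default from config).  Acquisition metadata absent from the
    TIFF falls back to config defaults: 10 s timestamp spacing, 8x8 binning,
    100 ms exposure, dtype-max saturation.
    """
    cfg = config or DEFAULT_CONFIG
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            pages = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            dtype = tf.pages[0].dtype
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"not a readable TIFF: {path}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 3 != 0:
        raise LayoutError(f"page count {pages.shape[0]} not divisible by 3")
    if layout is None:
        layout = meta.get("channel_layout") or cfg["channel_layout"]
    if sorted(layout) != sorted(CANONICAL_CHANNELS):
        raise LayoutError(f"layout {layout} must name the three canonical channels")
    n_t = pages.shape[0] // 3
    by_name = {}
    for i, name in enumerate(layout):
        by_name[name] = pages[i::3][:n_t]
    timestamps = meta.get("timestamps")
    if timestamps is None:
        timestamps = np.arange(n_t) * float(cfg["timestamp_spacing_s"])
    saturation = meta.get("saturation_level")
    if saturation is None:
        saturation = cfg["saturation_level"]
    if saturation is None:
        saturation = float(np.iinfo(dtype).max) if np.issubdtype(dtype, np.integer) \
            else float(np.finfo(dtype).max)
    if np.any(by_name["I_DD"] < 0) or np.any(by_name["I_DA"] < 0) or np.any(by_name["I_AA"] < 0):
        raise ValidationError("negative intensities in TIFF")
    return ThreeCubeStack(
        i_dd=by_name["I_DD"], i_da=by_name["I_DA"], i_aa=by_name["I_AA"],
        timestamps=np.asarray(timestamps, dtype=float),
        pixel_binning=int(meta.get("pixel_binning", cfg["pixel_binning"])),
        exposure_ms=float(meta.get("exposure_ms", cfg["exposure_ms"])),
        saturation_level=float(saturation),
    )


def read_roi_set(path: str | Path, image_shape: tuple | None = None) -> RoiSet:
    """Read the ROI JSON dialect: ``{"image_shape": [H, W], "rois": [...]}``.

    Each ROI record carries ``roi_id``, ``kind`` and either ``polygon``
    (list of [x, y]) or, for lines, two ``endpoints``.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid ROI JSON: {path}") from exc
    shape = tuple(doc.get("image_shape") or image_shape or ())
    if len(shape) != 2:
        raise FormatError("ROI file must declare image_shape [H, W]")
    rois = []
    for rec in doc.get("rois", []):
        kind = rec.get("kind", "cell")
        if kind == "line":
            rois.append(Roi(roi_id=str(rec["roi_id"]), kind="line",
                            endpoints=np.asarray(rec.get("endpoints") or rec.get("polygon"),
                                                 dtype=float)))
        else:
            rois.append(Roi(roi_id=str(rec["roi_id"]), kind=kind,
                            polygon=np.asarray(rec["polygon"], dtype=float)))
    return RoiSet(rois=rois, image_shape=shape)


def write_roi_set(path: str | Path, roi_set: RoiSet) -> None:
    recs = []
    for roi in roi_set:
        if roi.kind == "line":
            recs.append({"roi_id": roi.roi_id, "kind": "line",
                         "endpoints": np.asarray(roi.endpoints).tolist()})
        else:
            recs.append({"roi_id": roi.roi_id, "kind": roi.kind,
                         "polygon": np.asarray(roi.polygon).tolist()})
    with open(path, "w") as fh:
        json.dump({"image_shape": list(roi_set.image_shape), "rois": recs}, fh, indent=1)


def read_protocol_csv(path: str | Path) -> ConditionProtocol:
    """Read a protocol CSV with columns start_s, end_s, condition, osmolarity_mOsm."""
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "condition", "osmolarity_mOsm"}
    if not required.issubset(df.columns):
        raise FormatError(f"protocol CSV must have columns {sorted(required)}")
    segs = [ProtocolSegment(float(r.start_s), float(r.end_s), str(r.condition),
                            float(r.osmolarity_mOsm))
            for r in df.itertuples()]
    return ConditionProtocol(segments=segs)


def write_protocol_csv(path: str | Path, protocol: ConditionProtocol) -> None:
    pd.DataFrame(
        [{"start_s": s.start_s, "end_s": s.end_s, "condition": s.condition,
          "osmolarity_mOsm": s.osmolarity_mosm} for s in protocol.segments]
    ).to_csv(path, index=False)


def default_protocol(iso_s: float = 70.0, hypo_s: float = 90.0,
                     recovery_s: float = 120.0) -> ConditionProtocol:
    """Isotonic -> hypotonic -> isotonic buffer-exchange protocol.

    Mirrors the standard swelling experiment: isotonic 340 mOsm baseline,
    switch to 250 mOsm hypotonic, return to isotonic for recovery.
    """
    return ConditionProtocol(segments=[
        ProtocolSegment(0.0, iso_s, "iso", 340.0),
        ProtocolSegment(iso_s, iso_s + hypo_s, "hypo", 250.0),
        ProtocolSegment(iso_s + hypo_s, iso_s + hypo_s + recovery_s, "iso", 340.0),
    ])
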