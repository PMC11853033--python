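"""Calibrated luminance maps and the image-analysis stage.

A :class:`LuminanceMap` holds a 2D grid of photometric luminance values
(cd/m²) obtained by applying a linear calibration factor to raw sensor
counts.  On top of it this module implements the four image operations of
the screening pipeline: band segmentation into pseudo-color classes,
connected-component focus detection, per-field luminance summaries and
background-evenness estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "LuminanceMap",
    "MeasurementField",
    "LuminanceBand",
    "BandSegmentation",
    "Focus",
    "SampleSummary",
    "load_luminance_map",
    "save_luminance_map",
    "segment_by_bands",
    "detect_foci",
    "summarize",
    "illumination_evenness",
    "render_pseudo_color",
]

Connectivity = Literal[4, 8]

#: Default lesion band lower bound (cd/m²).  Healthy tissue peaks around
#: 500–520 cd/m²; lesion luminance starts near 630 cd/m².  A configuration
#: default, not a measured constant.
DEFAULT_LESION_LOW = 630.0

#: Minimum focus area in pixels used to suppress single-pixel specular noise.
DEFAULT_MIN_AREA_PX = 5


@dataclass(frozen=True)
class LuminanceMap:
    """A calibrated 2D luminance image.

    Parameters
    ----------
    values
        Luminance in cd/m², shape ``(height, width)``, finite and >= 0.
    calibration_factor
        Linear raw-count -> cd/m² scale applied at load time.
    pixel_pitch
        Optional physical pixel size in mm/pixel; enables mm² areas.
    source
        Optional provenance string (file path).
    """

    values: np.ndarray
    calibration_factor: float = 1.0
    pixel_pitch: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"luminance map must be 2D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("luminance map must have at least one pixel")
        if not np.all(np.isfinite(values)):
            raise ValueError("luminance values must be finite")
        if np.any(values < 0):
            raise ValueError("luminance values must be non-negative")
        if not self.calibration_factor > 0:
            raise ValueError("calibration_factor must be positive")
        if self.pixel_pitch is not None and not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "values", values)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class MeasurementField:
    """Boolean region-of-interest mask congruent with a luminance map."""

    mask: np.ndarray
    provenance: str = "explicit mask"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("measurement-field mask must be 2D")
        if not mask.any():
            raise ValueError("measurement field must contain at least one pixel")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def whole_image(cls, lum_map: LuminanceMap) -> "MeasurementField":
        return cls(np.ones(lum_map.shape, dtype=bool), provenance="whole image")

    @classmethod
    def rectangle(
        cls, shape: tuple[int, int], top: int, left: int, height: int, width: int
    ) -> "MeasurementField":
        mask = np.zeros(shape, dtype=bool)
        mask[top : top + height, left : left + width] = True
        return cls(mask, provenance="rectangle")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, lum_map: LuminanceMap) -> None:
        if self.mask.shape != lum_map.shape:
            raise ValueError(
                f"field shape {self.mask.shape} does not match map shape {lum_map.shape}"
            )


@dataclass(frozen=True)
class LuminanceBand:
    """Half-open luminance interval [low, high) with a display color.

    A pixel exactly at a boundary belongs to the upper band, so adjacent
    bands always partition the axis.
    """

    label: str
    low: float
    high: float
    pseudo_color: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band '{self.label}': low ({self.low}) must be < high ({self.high})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.low) & (values < self.high)


#: Conventional two-band pseudo-color scheme: green = no lesions,
#: blue = neoplastic.
def default_bands(lesion_low: float = DEFAULT_LESION_LOW, lesion_high: float = 1e6) -> list[LuminanceBand]:
    return [
        LuminanceBand("no_lesions", 0.0, lesion_low, (0, 170, 0)),
        LuminanceBand("neoplastic", lesion_low, lesion_high, (0, 0, 220)),
    ]


@dataclass(frozen=True)
class BandSegmentation:
    """Pseudo-color partition of a measurement field.

    ``band_index`` is an integer grid: ``-1`` marks pixels outside the field
    or outside every band; ``i >= 0`` indexes into ``bands``.
    """

    band_index: np.ndarray
    bands: tuple[LuminanceBand, ...]
    pixel_counts: tuple[int, ...]
    field: MeasurementField

    @property
    def unassigned_count(self) -> int:
        return self.field.n_pixels - sum(self.pixel_counts)

    def count_for(self, label: str) -> int:
        for band, count in zip(self.bands, self.pixel_counts):
            if band.label == label:
                return count
        raise KeyError(label)


@dataclass(frozen=True)
class Focus:
    """One connected lesion-band region."""

    pixel_indices: frozenset[tuple[int, int]]
    area_px: int
    centroid: tuple[float, float]
    mean_luminance: float
    max_luminance: float
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.area_px != len(self.pixel_indices):
            raise ValueError("area_px must equal the number of focus pixels")
        if self.mean_luminance > self.max_luminance + 1e-9:
            raise ValueError("mean_luminance cannot exceed max_luminance")

    def to_dict(self) -> dict:
        rec = {
            "area_px": self.area_px,
            "centroid": [round(c, 4) for c in self.centroid],
            "mean_luminance": self.mean_luminance,
            "max_luminance": self.max_luminance,
        }
        if self.area_mm2 is not None:
            rec["area_mm2"] = self.area_mm2
        return rec


@dataclass(frozen=True)
class SampleSummary:
    """Min/mean/max luminance over a measurement field."""

    l_min: float
    l_mean: float
    l_max: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (self.l_min <= self.l_mean + 1e-12 and self.l_mean <= self.l_max + 1e-12):
            raise ValueError("summary must satisfy l_min <= l_mean <= l_max")

    def to_dict(self) -> dict:
        return {
            "l_min": self.l_min,
            "l_mean": self.l_mean,
            "l_max": self.l_max,
            "n_pixels": self.n_pixels,
        }


# ---------------------------------------------------------------------------
# I/O


def _read_raster(path: Path, channel: int | None) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    elif suffix in (".csv", ".txt", ".tsv"):
        delimiter = "\t" if suffix == ".tsv" else ","
        raw = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    else:
        raw = np.asarray(Image.open(path))
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel image; pass an explicit channel index"
            )
        raw = raw[..., channel]
    elif raw.ndim != 2:
        raise ValueError(f"{path}: expected a 2D single-channel raster, got ndim={raw.ndim}")
    return raw


def load_luminance_map(
    path: str | Path,
    calibration_factor: float,
    *,
    pixel_pitch: float | None = None,
    channel: int | None = None,
) -> LuminanceMap:
    """Load a raster (16/8-bit TIFF/PNG or delimited grid) as a luminance map.

    Raw counts are multiplied by ``calibration_factor`` to obtain cd/m².
    """
    if not calibration_factor > 0:
        raise ValueError("calibration_factor must be positive")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_raster(path, channel)
    values = raw.astype(np.float64) * calibration_factor
    return LuminanceMap(values, calibration_factor, pixel_pitch, source=str(path))


def save_luminance_map(lum_map: LuminanceMap, path: str | Path) -> Path:
    """Write the map as a 16-bit single-channel TIFF of raw counts.

    Raw counts are ``values / calibration_factor`` rounded to the nearest
    integer; reloading with the same factor round-trips maps whose values
    originate from 16-bit data.
    """
    path = Path(path)
    raw = lum_map.values / lum_map.calibration_factor
    raw = np.round(raw)
    if raw.max() > np.iinfo(np.uint16).max:
        raise ValueError("raw counts exceed 16-bit range; adjust calibration_factor")
    tifffile.imwrite(path, raw.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# Analysis operations


def _check_bands_disjoint(bands: Sequence[LuminanceBand]) -> None:
    intervals = sorted((b.low, b.high, b.label) for b in bands)
    for (lo1, hi1, lab1), (lo2, hi2, lab2) in zip(intervals, intervals[1:]):
        if lo2 < hi1:
            raise ValueError(f"bands '{lab1}' and '{lab2}' overlap")


def segment_by_bands(
    lum_map: LuminanceMap,
    fld: MeasurementField,
    bands: Sequence[LuminanceBand],
) -> BandSegmentation:
    """Assign every in-field pixel to its half-open luminance band.

    Pixels outside all bands (or outside the field) are marked ``-1``.
    Per-band counts plus the unassigned count always equal the field size.
    """
    fld.check_congruent(lum_map)
    _check_bands_disjoint(bands)
    band_index = np.full(lum_map.shape, -1, dtype=np.int32)
    counts = []
    for i, band in enumerate(bands):
        hit = band.contains(lum_map.values) & fld.mask
        band_index[hit] = i
        counts.append(int(hit.sum()))
    return BandSegmentation(band_index, tuple(bands), tuple(counts), fld)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def detect_foci(
    lum_map: LuminanceMap,
    fld: MeasurementField,
    lesion_band: LuminanceBand,
    *,
    connectivity: Connectivity = 8,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> list[Focus]:
    """Find connected lesion-band regions inside the measurement field.

    Components smaller than ``min_area_px`` are discarded; the result is
    sorted by descending area (ties by descending max luminance).
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    fld.check_congruent(lum_map)
    lesion_mask = lesion_band.contains(lum_map.values) & fld.mask
    labels, n_components = ndimage.label(lesion_mask, structure=_STRUCTURES[connectivity])
    foci: list[Focus] = []
    for lab in range(1, n_components + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if area < min_area_px:
            continue
        lum = lum_map.values[rows, cols]
        area_mm2 = None
        if lum_map.pixel_pitch is not None:
            area_mm2 = float(area * lum_map.pixel_pitch**2)
        foci.append(
            Focus(
                pixel_indices=frozenset(zip(rows.tolist(), cols.tolist())),
                area_px=int(area),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_luminance=float(lum.mean()),
                max_luminance=float(lum.max()),
                area_mm2=area_mm2,
            )
        )
    foci.sort(key=lambda f: (-f.area_px, -f.max_luminance))
    return foci


def summarize(lum_map: LuminanceMap, fld: MeasurementField) -> SampleSummary:
    """Min/mean/max luminance over the in-field pixels."""
    fld.check_congruent(lum_map)
    vals = lum_map.values[fld.mask]
    return SampleSummary(
        l_min=float(vals.min()),
        l_mean=float(vals.mean()),
        l_max=float(vals.max()),
        n_pixels=int(vals.size),
    )


def illumination_evenness(lum_map: LuminanceMap, background_field: MeasurementField) -> float:
    """Background evenness as ``100 * L_min / L_max`` over the field (%).

    The most conservative of the common uniformity metrics; values near
    100 indicate a well-behaved diffuse background.
    """
    background_field.check_congruent(lum_map)
    vals = lum_map.values[background_field.mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin <= 0:
        raise ValueError("background contains a zero-valued pixel; evenness undefined")
    return 100.0 * vmin / vmax


def render_pseudo_color(
    segmentation: BandSegmentation,
    *,
    neutral_color: tuple[int, int, int] = (40, 40, 40),
) -> np.ndarray:
    """Paint each pixel with its band's pseudo-color; unassigned pixels
    get ``neutral_color``.  Returns an (H, W, 3) uint8 array writable as PNG.
    """
    h, w = segmentation.band_index.shape
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[...] = neutral_color
    for i, band in enumerate(segmentation.bands):
        rgb[segmentation.band_index == i] = band.pseudo_color
    return rgb


def write_png(rgb: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path


def sample_report(
    lum_map: LuminanceMap,
    fld: MeasurementField,
    bands: Sequence[LuminanceBand],
    lesion_band: LuminanceBand,
    *,
    connectivity: Connectivity = 8,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> dict:
    """JSON-serialisable per-sample report combining all image-stage results."""
    summary = summarize(lum_map, fld)
    seg = segment_by_bands(lum_map, fld, bands)
    foci = detect_foci(
        lum_map, fld, lesion_band, connectivity=connectivity, min_area_px=min_area_px
    )
    return {
        **summary.to_dict(),
        "band_counts": {b.label: c for b, c in zip(seg.bands, seg.pixel_counts)},
        "unassigned_count": seg.unassigned_count,
        "foci": [f.to_dict() for f in foci],
    }


def report_to_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
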