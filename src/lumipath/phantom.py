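"""Synthetic luminance-map phantoms and cohort fixtures.

Phantoms emulate the measurement bench: an evenly illuminated diffuse
background, an elliptical tissue region at a healthy base level
(~500-520 cd/m²), and optional lesion foci rendered as plateaus at a
configurable peak (630-1130 cd/m² depending on variant), plus additive
noise and specular artifacts.  Every generator is deterministic given its
seed and returns a ground-truth annotation alongside the rendered map.

The module also ships a fixed 48-sample cohort of per-sample maximum
luminance (Lmax) values reconstructed from published cumulative
threshold-assignment counts, used as the reference fixture throughout the
diagnostic tests.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .image import LuminanceMap

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortRecord",
    "generate_phantom",
    "generate_cohort",
    "fixture_lmax_table2",
    "write_cohort_csv",
    "read_cohort_csv",
]

LesionVariant = Literal["none", "advanced_central", "single_focus", "multifocal_diffuse"]

GROUP_POSITIVE = "with_lesions"
GROUP_NEGATIVE = "without_lesions"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic luminance phantom.

    ``lesion_foci`` is a list of ``((row, col), radius_px)`` disks; when
    empty and the variant is not ``none``, a variant-dependent default
    layout inside the tissue ellipse is used.
    """

    shape: tuple[int, int] = (128, 128)
    background_level: float = 1000.0
    background_evenness: float = 0.98
    tissue_center: tuple[float, float] | None = None
    tissue_semi_axes: tuple[float, float] | None = None
    tissue_level: float = 510.0
    lesion_variant: LesionVariant = "none"
    lesion_peak: float = 900.0
    lesion_foci: tuple[tuple[tuple[float, float], float], ...] = ()
    lesion_falloff_px: float = 0.0
    noise_sd: float = 0.0
    specular_count: int = 0
    specular_peak: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ValueError("phantom must be at least 8x8")
        if not (0.0 < self.background_evenness <= 1.0):
            raise ValueError("background_evenness must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lesion_variant != "none" and not self.lesion_peak > self.tissue_level:
            raise ValueError("lesion_peak must exceed tissue_level")
        if self.tissue_level <= 0 or self.background_level <= 0:
            raise ValueError("levels must be positive")

    def resolved_tissue(self) -> tuple[tuple[float, float], tuple[float, float]]:
        rows, cols = self.shape
        center = self.tissue_center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
        semi = self.tissue_semi_axes or (rows * 0.35, cols * 0.35)
        return center, semi

    def resolved_foci(self) -> tuple[tuple[tuple[float, float], float], ...]:
        if self.lesion_variant == "none":
            return ()
        if self.lesion_foci:
            return self.lesion_foci
        (cr, cc), (sr, sc) = self.resolved_tissue()
        if self.lesion_variant == "advanced_central":
            return (((cr, cc), 0.6 * min(sr, sc)),)
        if self.lesion_variant == "single_focus":
            return (((cr, cc), 0.25 * min(sr, sc)),)
        # multifocal_diffuse: three small disks spread through the tissue
        r = 0.18 * min(sr, sc)
        return (
            ((cr - 0.45 * sr, cc - 0.35 * sc), r),
            ((cr + 0.40 * sr, cc - 0.10 * sc), r),
            ((cr - 0.05 * sr, cc + 0.45 * sc), r),
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one phantom: masks and per-focus descriptors."""

    tissue_mask: np.ndarray
    lesion_mask: np.ndarray
    foci: tuple[dict, ...]  # each: {"center", "radius_px", "area_px", "peak"}
    lesion_peak: float
    tissue_level: float

    def to_dict(self) -> dict:
        return {
            "lesion_peak": self.lesion_peak,
            "tissue_level": self.tissue_level,
            "n_foci": len(self.foci),
            "foci": list(self.foci),
            "lesion_area_px": int(self.lesion_mask.sum()),
        }


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[LuminanceMap, PhantomTruth]:
    """Render a phantom and its ground-truth annotation.

    Rendering order: smooth background gradient achieving the requested
    evenness, tissue ellipse at ``tissue_level``, lesion plateaus at
    ``lesion_peak`` (with optional cosine falloff over ``lesion_falloff_px``
    outside the plateau), specular spikes, then additive zero-mean Gaussian
    noise clipped at 0.  Deterministic given ``spec.seed``.
    """
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)

    # Background: linear horizontal ramp from evenness*level to level, so
    # min/max over the background equals the requested evenness exactly
    # (before noise).
    ramp = np.linspace(spec.background_evenness, 1.0, cols)
    values = np.tile(spec.background_level * ramp, (rows, 1)).astype(np.float64)

    center, semi = spec.resolved_tissue()
    tissue_mask = _ellipse_mask(spec.shape, center, semi)
    values[tissue_mask] = spec.tissue_level

    foci_spec = spec.resolved_foci()
    lesion_mask = np.zeros(spec.shape, dtype=bool)
    truth_foci: list[dict] = []
    for (fr, fc), radius in foci_spec:
        disk = _disk_mask(spec.shape, (fr, fc), radius)
        if not (disk <= tissue_mask).all():
            raise ValueError(f"lesion focus at ({fr}, {fc}) r={radius} extends outside the tissue region")
        values[disk] = spec.lesion_peak
        if spec.lesion_falloff_px > 0:
            rr, cc = np.ogrid[:rows, :cols]
            dist = np.sqrt((rr - fr) ** 2 + (cc - fc) ** 2)
            ring = (dist > radius) & (dist < radius + spec.lesion_falloff_px) & tissue_mask & ~lesion_mask
            t = (dist[ring] - radius) / spec.lesion_falloff_px
            shoulder = spec.tissue_level + (spec.lesion_peak - spec.tissue_level) * 0.5 * (
                1.0 + np.cos(np.pi * t)
            )
            values[ring] = np.maximum(values[ring], shoulder)
        lesion_mask |= disk
        truth_foci.append(
            {
                "center": [float(fr), float(fc)],
                "radius_px": float(radius),
                "area_px": int(disk.sum()),
                "peak": float(spec.lesion_peak),
            }
        )

    if spec.specular_count > 0:
        bg_rows, bg_cols = np.nonzero(~tissue_mask)
        pick = rng.choice(bg_rows.size, size=min(spec.specular_count, bg_rows.size), replace=False)
        values[bg_rows[pick], bg_cols[pick]] = spec.specular_peak

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)

    lum_map = LuminanceMap(values, calibration_factor=1.0)
    truth = PhantomTruth(
        tissue_mask=tissue_mask,
        lesion_mask=lesion_mask,
        foci=tuple(truth_foci),
        lesion_peak=spec.lesion_peak,
        tissue_level=spec.tissue_level,
    )
    return lum_map, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortRecord:
    """One sample's maximum field luminance with its reference label."""

    sample_id: str
    group: str
    l_max: float

    def __post_init__(self) -> None:
        if self.group not in (GROUP_POSITIVE, GROUP_NEGATIVE):
            raise ValueError(f"group must be '{GROUP_POSITIVE}' or '{GROUP_NEGATIVE}'")
        if not self.l_max > 0:
            raise ValueError("l_max must be positive")

    @property
    def is_positive(self) -> bool:
        return self.group == GROUP_POSITIVE


def generate_cohort(
    n_pos: int,
    n_neg: int,
    pos_lmax_distribution,
    neg_lmax_distribution,
    seed: int,
) -> list[CohortRecord]:
    """Sample a synthetic cohort of per-sample Lmax values.

    Distributions are scipy.stats frozen distributions (anything exposing
    ``rvs(size=, random_state=)``).  Draws are clipped to a tiny positive
    floor so records remain valid.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must both be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.atleast_1d(pos_lmax_distribution.rvs(size=n_pos, random_state=rng))
    neg = np.atleast_1d(neg_lmax_distribution.rvs(size=n_neg, random_state=rng))
    records = [
        CohortRecord(f"P{i + 1:03d}", GROUP_POSITIVE, float(max(v, 1e-9)))
        for i, v in enumerate(pos)
    ]
    records += [
        CohortRecord(f"N{i + 1:03d}", GROUP_NEGATIVE, float(max(v, 1e-9)))
        for i, v in enumerate(neg)
    ]
    return records


# Reference fixture: 48 Lmax values whose threshold assignments under the
# rule "positive <=> Lmax <= t", t in {1070,...,1130}, reproduce the
# published cumulative counts exactly.  Bin representatives are midpoints;
# the open end bins use bound -/+ 20 cd/m².  Tests depend only on bin
# membership, never on the representative values themselves.
_FIXTURE_POS_BINS: tuple[tuple[float, int], ...] = (
    (1050.0, 18),  # Lmax <= 1070
    (1075.0, 2),   # (1070, 1080]
    (1085.0, 2),   # (1080, 1090]
    (1150.0, 5),   # > 1130
)
_FIXTURE_NEG_BINS: tuple[tuple[float, int], ...] = (
    (1050.0, 1),   # Lmax <= 1070
    (1105.0, 3),   # (1100, 1110]
    (1115.0, 2),   # (1110, 1120]
    (1125.0, 1),   # (1120, 1130]
    (1150.0, 14),  # > 1130
)

#: The published threshold grid (cd/m²).
FIXTURE_THRESHOLDS: tuple[float, ...] = (1070, 1080, 1090, 1100, 1110, 1120, 1130)


def fixture_lmax_table2() -> list[CohortRecord]:
    """The fixed 48-record reference cohort (27 positive, 21 negative)."""
    records: list[CohortRecord] = []
    i = 0
    for value, count in _FIXTURE_POS_BINS:
        for _ in range(count):
            i += 1
            records.append(CohortRecord(f"P{i:03d}", GROUP_POSITIVE, value))
    i = 0
    for value, count in _FIXTURE_NEG_BINS:
        for _ in range(count):
            i += 1
            records.append(CohortRecord(f"N{i:03d}", GROUP_NEGATIVE, value))
    return records


def fixture_phantom_specs(
    *, shape: tuple[int, int] = (64, 64), seed: int = 0
) -> list[tuple[str, str, PhantomSpec]]:
    """Noise-free phantom specs whose field Lmax equals each fixture record's
    Lmax, enabling an image-level end-to-end reproduction of the cohort.
    """
    specs = []
    for rec in fixture_lmax_table2():
        spec = PhantomSpec(
            shape=shape,
            background_level=400.0,
            background_evenness=0.98,
            tissue_level=510.0,
            lesion_variant="single_focus",
            lesion_peak=rec.l_max,
            noise_sd=0.0,
            seed=seed,
        )
        specs.append((rec.sample_id, rec.group, spec))
    return specs


# ---------------------------------------------------------------------------
# CSV / sidecar I/O

COHORT_HEADER = ["sample_id", "group", "l_max"]


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for rec in records:
            writer.writerow([rec.sample_id, rec.group, repr(rec.l_max)])
    return path


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != COHORT_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(COHORT_HEADER)}, got {reader.fieldnames}"
            )
        return [
            CohortRecord(row["sample_id"], row["group"], float(row["l_max"])) for row in reader
        ]


def write_truth_sidecar(truth: PhantomTruth, group: str, path: str | Path) -> Path:
    path = Path(path)
    payload = {"group": group, **truth.to_dict()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
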