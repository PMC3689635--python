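"""Synthetic stained-mucosa patch generator.

Real dye-concentration series on excised stomach mucosa are photographic
data that are not shipped with this package, so end-to-end behaviour is
exercised on synthetic patches that reproduce the two properties the
scores respond to:

* a **correlated texture field** standing in for the glandular mucosa
  pattern: Gaussian white noise smoothed with a Gaussian kernel of a
  configurable correlation length, normalized to zero mean and unit
  standard deviation, then scaled by a texture amplitude;
* a **planted lesion**: an ellipse whose intensity offset relative to the
  surrounding tissue follows the dye dose-response.

The dose-response itself is a unimodal bump

    f(c) = (c / c_star)**k * exp(k * (1 - c / c_star))

with ``f(0) = 0``, a unique maximum ``f(c_star) = 1`` and a decay past the
optimum whose sharpness is set by the oversaturation rate ``k``: beyond
``c_star`` extra dye pools everywhere, washing out both the lesion
contrast and the texture enhancement.  Healthy uptake, lesion uptake and
the texture gain all share this bump with their own amplitudes, so both
scores peak at the planted optimal concentration ``c_star``.  The curve
shape is a modelling choice; only the peak location is treated as
recoverable ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_model import RegionPair

__all__ = [
    "StainResponseModel",
    "SyntheticParams",
    "PatchRecord",
    "generate_patch",
    "generate_design",
    "default_models",
]


@dataclass(frozen=True)
class StainResponseModel:
    """Dose-response of one stain on one tissue type.

    Parameters
    ----------
    c_star
        Planted optimal concentration (%), the ground truth the pipeline
        should recover.
    healthy_amplitude
        Intensity shift (gray levels) of healthy mucosa at ``c_star``;
        negative values darken the tissue, as absorbed dye does.
    contrast_amplitude
        Additional dye-induced shift of lesion tissue relative to healthy
        tissue at ``c_star`` (gray levels).
    lesion_baseline
        Intrinsic lesion-to-background shift (gray levels) present at any
        concentration: a depressed lesion is faintly visible even
        unstained.
    texture_gain_amplitude
        Peak relative increase of the texture amplitude: the gain is 1 at
        ``c = 0`` and ``1 + texture_gain_amplitude`` at ``c_star``.
    oversaturation_rate
        Shape parameter ``k`` of the dose-response bump; larger values
        make the peak sharper and the collapse past ``c_star`` faster.
    """

    c_star: float
    healthy_amplitude: float = -10.0
    contrast_amplitude: float = -50.0
    lesion_baseline: float = -10.0
    texture_gain_amplitude: float = 1.0
    oversaturation_rate: float = 2.0

    def __post_init__(self) -> None:
        if not self.c_star > 0:
            raise ValueError("c_star must be positive")
        if not self.oversaturation_rate > 0:
            raise ValueError("oversaturation_rate must be positive")

    def _bump(self, c: float) -> float:
        if c <= 0:
            return 0.0
        u = c / self.c_star
        k = self.oversaturation_rate
        return float(u**k * np.exp(k * (1.0 - u)))

    def healthy_uptake(self, c: float) -> float:
        """Intensity shift of healthy mucosa at concentration ``c`` (%)."""
        return self.healthy_amplitude * self._bump(c)

    def lesion_uptake(self, c: float) -> float:
        """Intensity shift of lesion tissue at concentration ``c`` (%)."""
        return (
            self.healthy_uptake(c)
            + self.lesion_baseline
            + self.contrast_amplitude * self._bump(c)
        )

    def texture_gain(self, c: float) -> float:
        """Multiplier on the texture amplitude; 1 at c=0, maximal at c_star."""
        return 1.0 + self.texture_gain_amplitude * self._bump(c)


def default_models() -> dict[tuple[str, str], StainResponseModel]:
    """Default stain models per (stain, anatomical region).

    A methylene-blue-like absorptive stain peaks at 0.4% in both regions
    and acts mainly on texture; an indigo-carmine-like contrast stain
    pools in the depressed lesion (strong negative lesion shift) with a
    region-dependent optimum: 0.2% on thin-mucus fundus tissue, 0.6% on
    the mucus-rich pylorus.  These are generator settings mirroring
    reported dose-response peaks, not claims about real tissue.
    """
    methylene = dict(
        healthy_amplitude=-25.0,
        contrast_amplitude=0.0,
        lesion_baseline=0.0,
        texture_gain_amplitude=1.0,
        oversaturation_rate=2.0,
    )
    indigo = dict(
        healthy_amplitude=-10.0,
        contrast_amplitude=-50.0,
        lesion_baseline=-10.0,
        texture_gain_amplitude=0.3,
        oversaturation_rate=2.0,
    )
    return {
        ("methylene_blue", "fundus"): StainResponseModel(c_star=0.4, **methylene),
        ("methylene_blue", "pylorus"): StainResponseModel(c_star=0.4, **methylene),
        ("indigo_carmine", "fundus"): StainResponseModel(c_star=0.2, **indigo),
        ("indigo_carmine", "pylorus"): StainResponseModel(c_star=0.6, **indigo),
    }


@dataclass(frozen=True)
class SyntheticParams:
    """Geometry and noise settings of one synthetic patch.

    The default 256x256 canvas keeps the largest sampling radius (50 px)
    comfortably inside the image while staying fast; real patch
    photographs are larger (1400x1200) and the size is configurable.
    """

    image_size: tuple[int, int] = (256, 256)  # (v, h)
    base_intensity: float = 120.0
    texture_correlation_length: float = 3.0  # pixels (Gaussian sigma)
    texture_amplitude: float = 10.0  # gray levels (std of the field)
    lesion_type: str = "0-IIc"  # "0-IIc" depressed | "0-Ip" protruding
    lesion_center: tuple[float, float] = (128.0, 128.0)  # (x, y)
    lesion_axes: tuple[float, float] = (40.0, 28.0)  # semi-axes (x, y)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        v, h = self.image_size
        cx, cy = self.lesion_center
        ax, ay = self.lesion_axes
        if cx - ax < 0 or cx + ax > h - 1 or cy - ay < 0 or cy + ay > v - 1:
            raise ValueError("lesion geometry extends outside image bounds")
        if self.lesion_type not in ("0-IIc", "0-Ip"):
            raise ValueError("lesion_type must be '0-IIc' or '0-Ip'")


@dataclass
class PatchRecord:
    """One synthetic mucosa patch with its experimental metadata."""

    image: np.ndarray
    regions: RegionPair
    stain: str
    concentration: float
    anatomical_region: str
    replicate_id: int
    seed: int
    lesion_type: str = "0-IIc"
    image_path: str | None = None
    annotation_path: str | None = None


def _child_seed(master_seed: int, stain: str, region: str, concentration: float, replicate_id: int) -> int:
    """Deterministic, order-independent per-patch seed below 2**31."""
    key = f"{stain}|{region}|{concentration:.6f}|{replicate_id}"
    return (int(master_seed) * 2654435761 + zlib.crc32(key.encode())) % (2**31 - 1)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    v, h = shape
    ys, xs = np.mgrid[0:v, 0:h]
    cx, cy = center
    ax, ay = axes
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0


def _ground_truth_regions(params: SyntheticParams) -> RegionPair:
    """Annotation polygons: a ring-sampled ellipse inside the lesion and a
    rectangle in the upper-left background, clear of the lesion."""
    cx, cy = params.lesion_center
    ax, ay = params.lesion_axes
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    lesion_poly = [
        (cx + 0.7 * ax * np.cos(a), cy + 0.7 * ay * np.sin(a)) for a in ang
    ]
    v, h = params.image_size
    x0, y0 = 0.06 * h, 0.06 * v
    x1, y1 = 0.30 * h, 0.30 * v
    healthy_poly = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    return RegionPair.from_polygons(lesion_poly, healthy_poly, params.image_size)


def generate_patch(
    params: SyntheticParams,
    model: StainResponseModel,
    stain: str,
    concentration: float,
    region: str = "fundus",
    replicate_id: int = 0,
) -> PatchRecord:
    """Render one synthetic stained patch.

    The image is built as base intensity + correlated texture field scaled
    by the dose-dependent texture gain + region-specific uptake shifts
    (healthy everywhere, lesion uptake over the lesion ellipse, with a
    1-pixel smoothed edge) + white Gaussian noise, clipped to [0, 255].
    Output is bit-identical for identical seed and arguments.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    v, h = params.image_size
    rng = np.random.default_rng(params.seed)

    field_raw = gaussian_filter(
        rng.standard_normal((v, h)), sigma=params.texture_correlation_length
    )
    field_raw -= field_raw.mean()
    sd = field_raw.std()
    texture = field_raw / sd if sd > 0 else field_raw

    lesion = _ellipse_mask((v, h), params.lesion_center, params.lesion_axes)
    lesion_soft = gaussian_filter(lesion.astype(float), sigma=1.0)

    gain = model.texture_gain(concentration)
    img = np.full((v, h), params.base_intensity, dtype=float)
    img += params.texture_amplitude * gain * texture
    img += model.healthy_uptake(concentration)
    img += (model.lesion_uptake(concentration) - model.healthy_uptake(concentration)) * lesion_soft
    if params.lesion_type == "0-Ip":
        # protruding pseudopolyp catches more light than the flat mucosa
        img += 8.0 * lesion_soft
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=(v, h))
    np.clip(img, 0.0, 255.0, out=img)

    return PatchRecord(
        image=img,
        regions=_ground_truth_regions(params),
        stain=stain,
        concentration=float(concentration),
        anatomical_region=region,
        replicate_id=replicate_id,
        seed=params.seed,
        lesion_type=params.lesion_type,
    )


def generate_design(
    design: "ExperimentDesign",
    params: SyntheticParams | None = None,
    models: dict[tuple[str, str], StainResponseModel] | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[PatchRecord]:
    """Generate one patch per design cell and replicate.

    Per-patch seeds are derived deterministically from ``master_seed`` and
    the cell coordinates, so regeneration is reproducible and independent
    of enumeration order.  When ``out_dir`` is given, PNG images,
    annotation JSON files and a ``manifest.csv`` are written there.
    """
    from .pipeline import ExperimentDesign  # local import avoids a cycle

    if not isinstance(design, ExperimentDesign):
        raise TypeError("design must be an ExperimentDesign")
    params = params or SyntheticParams()
    models = models or default_models()

    records: list[PatchRecord] = []
    seen: set[tuple[str, str, float, int]] = set()
    for cell in design.cells:
        model = models[(cell.stain, cell.region)]
        for conc in cell.concentrations:
            for rep in range(1, cell.replicates + 1):
                key = (cell.stain, cell.region, float(conc), rep)
                if key in seen:
                    raise ValueError(f"duplicate design cell/replicate {key}")
                seen.add(key)
                seed = _child_seed(master_seed, cell.stain, cell.region, conc, rep)
                records.append(
                    generate_patch(
                        replace(params, seed=seed),
                        model,
                        stain=cell.stain,
                        concentration=conc,
                        region=cell.region,
                        replicate_id=rep,
                    )
                )

    if out_dir is not None:
        _write_design(records, Path(out_dir))
    return records


def _write_design(records: Iterable[PatchRecord], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = (
            f"{rec.stain}_{rec.anatomical_region}_"
            f"c{rec.concentration:.1f}_r{rec.replicate_id}"
        )
        img_path = out_dir / f"{stem}.png"
        ann_path = out_dir / f"{stem}.json"
        iio.imwrite(img_path, np.round(rec.image).astype(np.uint8))
        rec.regions.to_json(ann_path)
        rec.image_path = str(img_path)
        rec.annotation_path = str(ann_path)
        rows.append(
            {
                "image_path": str(img_path),
                "annotation_path": str(ann_path),
                "stain": rec.stain,
                "concentration": rec.concentration,
                "region": rec.anatomical_region,
                "replicate": rec.replicate_id,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
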