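"""Concentration-series design, aggregation and optimum finding.

An experiment is a set of design cells, one per (stain, anatomical
region), each holding a strictly increasing concentration grid (including
0 for the unstained baseline) and a replicate count.  Each stain is bound
to the score that measures what it is applied for: contrast stains
(indigo-carmine-like, pooling in depressed lesions) are scored with the
lesion-to-background contrast I_c; absorptive stains (methylene-blue-like)
are scored with the multi-radius texture variance var(R,N)_g.

Per concentration the replicate scores are averaged; the optimal
concentration is the grid argmax of the mean score, with ties broken
toward the lowest concentration (minimal dye exposure); no interpolation
between grid points is attempted.  The improvement over the unstained
baseline is reported as a percent increase:

    100 * (optimal_mean - unstained_mean) / unstained_mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contrast import contrast_score
from .image_model import load_image, load_regions
from .synthetic import PatchRecord
from .texture import DEFAULT_NEIGHBORS, DEFAULT_RADII, multi_radius_score

__all__ = [
    "DesignCell",
    "ExperimentDesign",
    "ConcentrationSummary",
    "aggregate",
    "find_optimal_concentration",
    "percent_increase",
    "summarize_cell",
    "score_records",
    "run_pipeline",
]


@dataclass(frozen=True)
class DesignCell:
    """One (stain, region) arm of the experiment."""

    stain: str
    region: str
    concentrations: tuple[float, ...]
    replicates: int
    score: str  # "contrast" | "texture"

    def __post_init__(self) -> None:
        grid = self.concentrations
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("concentration grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.score not in ("contrast", "texture"):
            raise ValueError("score must be 'contrast' or 'texture'")


def _grid(stop: float, step: float = 0.2) -> tuple[float, ...]:
    n = int(round(stop / step))
    return tuple(round(i * step, 10) for i in range(n + 1))


@dataclass
class ExperimentDesign:
    """The full experiment: a list of design cells."""

    cells: list[DesignCell]

    @property
    def n_patches(self) -> int:
        return sum(len(c.concentrations) * c.replicates for c in self.cells)

    @classmethod
    def indigo_printed(cls) -> "ExperimentDesign":
        """Contrast-stain series: both regions, 0-1.6% in 0.2% steps,
        5 replicates -> 90 patches."""
        return cls(
            cells=[
                DesignCell("indigo_carmine", region, _grid(1.6), 5, "contrast")
                for region in ("fundus", "pylorus")
            ]
        )

    @classmethod
    def methylene_printed(cls) -> "ExperimentDesign":
        """Texture-stain series: fundus 0-2.0%, pylorus 0-1.6% in 0.2%
        steps, 5 replicates -> 100 patches."""
        return cls(
            cells=[
                DesignCell("methylene_blue", "fundus", _grid(2.0), 5, "texture"),
                DesignCell("methylene_blue", "pylorus", _grid(1.6), 5, "texture"),
            ]
        )

    @classmethod
    def full_printed(cls) -> "ExperimentDesign":
        """Both stain series combined -> 190 patches."""
        return cls(cells=cls.indigo_printed().cells + cls.methylene_printed().cells)


@dataclass
class ConcentrationSummary:
    """Aggregated scores for one (stain, region) cell."""

    stain: str
    region: str
    score_type: str
    per_concentration: dict[float, float]  # concentration -> mean score
    replicate_scores: dict[float, list[float]]
    optimal_concentration: float | None
    optimal_mean_score: float | None
    unstained_mean_score: float | None
    percent_increase: float | None
    tie: bool = False
    replicate_sd: dict[float, float] = field(default_factory=dict)


def aggregate(scores: Iterable[tuple[float, float]]) -> dict[float, float]:
    """Per-concentration arithmetic mean, preserving first-seen grid order."""
    groups: dict[float, list[float]] = {}
    for conc, score in scores:
        groups.setdefault(float(conc), []).append(float(score))
    if not groups:
        raise ValueError("no scores to aggregate")
    return {c: float(np.mean(v)) for c, v in groups.items()}


def find_optimal_concentration(
    means: Mapping[float, float],
) -> tuple[float, float, bool]:
    """Grid argmax of the mean score.

    Returns ``(concentration, mean_score, tie)``; ties are broken toward
    the lowest concentration and flagged.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 concentrations to find an optimum")
    best_score = max(means.values())
    tied = sorted(c for c, s in means.items() if s == best_score)
    return tied[0], best_score, len(tied) > 1


def percent_increase(optimal_mean: float, unstained_mean: float) -> float:
    """Percent increase of the optimal score over the unstained baseline."""
    if unstained_mean <= 0:
        raise ValueError("unstained baseline score must be positive")
    return 100.0 * (optimal_mean - unstained_mean) / unstained_mean


def summarize_cell(
    cell: DesignCell,
    scores: Sequence[tuple[float, float]],
) -> ConcentrationSummary:
    """Aggregate one cell's (concentration, score) pairs into a summary."""
    groups: dict[float, list[float]] = {}
    for conc, score in scores:
        groups.setdefault(float(conc), []).append(float(score))
    means = {c: float(np.mean(v)) for c, v in groups.items()}
    sds = {c: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for c, v in groups.items()}

    optimal = opt_mean = pct = None
    tie = False
    if len(means) >= 2:
        optimal, opt_mean, tie = find_optimal_concentration(means)
    else:
        warnings.warn(
            f"cell ({cell.stain}, {cell.region}) has a single concentration; "
            "no optimum reported",
            stacklevel=2,
        )
    unstained = means.get(0.0)
    if optimal is not None and unstained is not None and unstained > 0:
        pct = percent_increase(opt_mean, unstained)
    return ConcentrationSummary(
        stain=cell.stain,
        region=cell.region,
        score_type=cell.score,
        per_concentration=means,
        replicate_scores=groups,
        optimal_concentration=optimal,
        optimal_mean_score=opt_mean,
        unstained_mean_score=unstained,
        percent_increase=pct,
        tie=tie,
        replicate_sd=sds,
    )


def _score_patch(
    record: PatchRecord,
    score_type: str,
    radii: tuple[float, ...],
    N: int,
    stat: str,
) -> float:
    if score_type == "contrast":
        return contrast_score(record.image, record.regions, stat=stat).i_c
    return multi_radius_score(record.image, radii=radii, N=N).averaged


def score_records(
    records: Sequence[PatchRecord],
    design: ExperimentDesign,
    radii: tuple[float, ...] = DEFAULT_RADII,
    N: int = DEFAULT_NEIGHBORS,
    stat: str = "mean",
) -> tuple[pd.DataFrame, dict[tuple[str, str], ConcentrationSummary]]:
    """Score in-memory patch records against a design.

    Returns the long-format score table (one row per patch) and one
    :class:`ConcentrationSummary` per (stain, region) cell.
    """
    cell_map = {(c.stain, c.region): c for c in design.cells}
    rows = []
    for rec in records:
        key = (rec.stain, rec.anatomical_region)
        if key not in cell_map:
            raise ValueError(f"record {key} does not match any design cell")
        cell = cell_map[key]
        value = _score_patch(rec, cell.score, radii, N, stat)
        rows.append(
            {
                "stain": rec.stain,
                "region": rec.anatomical_region,
                "concentration": rec.concentration,
                "replicate": rec.replicate_id,
                "score_type": cell.score,
                "score": value,
            }
        )
    table = pd.DataFrame(rows)

    summaries: dict[tuple[str, str], ConcentrationSummary] = {}
    for key, cell in cell_map.items():
        sub = table[(table["stain"] == key[0]) & (table["region"] == key[1])]
        expected = {round(float(c), 10) for c in cell.concentrations}
        present = {round(float(c), 10) for c in sub["concentration"]}
        missing = expected - present
        if missing:
            raise ValueError(
                f"design cell ({cell.stain}, {cell.region}) is missing "
                f"concentrations {sorted(missing)}"
            )
        summaries[key] = summarize_cell(
            cell, list(zip(sub["concentration"], sub["score"]))
        )
    return table, summaries


def _load_manifest(manifest: str | Path) -> pd.DataFrame:
    table = pd.read_csv(manifest)
    required = {"image_path", "annotation_path", "stain", "concentration", "region", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return table


def run_pipeline(
    manifest: str | Path,
    design: ExperimentDesign,
    out_dir: str | Path | None = None,
    radii: tuple[float, ...] = DEFAULT_RADII,
    N: int = DEFAULT_NEIGHBORS,
    stat: str = "mean",
    plot: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ConcentrationSummary]]:
    """Score a manifest of image files and summarize per design cell.

    Reads every image (and, for contrast cells, its annotation JSON)
    listed in the manifest CSV, scores it with the cell's score, and
    aggregates.  When ``out_dir`` is given, writes ``scores.csv`` (long
    format), ``summary.json`` (optima and percent increases) and, if
    ``plot`` is set, a per-concentration score plot.
    """
    table = _load_manifest(manifest)
    cell_map = {(c.stain, c.region): c for c in design.cells}

    records: list[PatchRecord] = []
    for row in table.itertuples(index=False):
        key = (row.stain, row.region)
        if key not in cell_map:
            raise ValueError(f"manifest row {key} does not match any design cell")
        try:
            img = load_image(row.image_path)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"unreadable image {row.image_path}") from exc
        regions = None
        if cell_map[key].score == "contrast":
            regions = load_regions(row.annotation_path, img.shape)
        records.append(
            PatchRecord(
                image=img,
                regions=regions if regions is not None else _dummy_regions(img.shape),
                stain=row.stain,
                concentration=float(row.concentration),
                anatomical_region=row.region,
                replicate_id=int(row.replicate),
                seed=-1,
                image_path=row.image_path,
                annotation_path=str(row.annotation_path),
            )
        )
    scores, summaries = score_records(records, design, radii=radii, N=N, stat=stat)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out_dir / "scores.csv", index=False)
        payload = {
            f"{stain}/{region}": {
                "score_type": s.score_type,
                "per_concentration_mean": {str(c): m for c, m in sorted(s.per_concentration.items())},
                "optimal_concentration": s.optimal_concentration,
                "optimal_mean_score": s.optimal_mean_score,
                "unstained_mean_score": s.unstained_mean_score,
                "percent_increase": s.percent_increase,
                "tie": s.tie,
            }
            for (stain, region), s in summaries.items()
        }
        (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        if plot:
            _plot_summaries(summaries, out_dir / "concentration_scores.png")
    return scores, summaries


def _dummy_regions(shape: tuple[int, int]):
    # texture cells never read the regions; a minimal valid placeholder
    from .image_model import RegionPair

    lesion = np.zeros(shape, dtype=bool)
    healthy = np.zeros(shape, dtype=bool)
    lesion[0, 0] = True
    healthy[0, 1] = True
    return RegionPair(lesion, healthy)


def _plot_summaries(
    summaries: Mapping[tuple[str, str], ConcentrationSummary], path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (stain, region), s in sorted(summaries.items()):
        concs = sorted(s.per_concentration)
        ax.plot(
            concs,
            [s.per_concentration[c] for c in concs],
            marker="o",
            label=f"{stain} / {region} ({s.score_type})",
        )
    ax.set_xlabel("dye concentration [%]")
    ax.set_ylabel("mean score")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
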