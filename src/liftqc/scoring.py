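"""Printability scoring and window mapping.

Each of the four criteria is normalised to [0, 1] and combined into a
single indexed score by a weighted mean (equal weights by default).  Only
the droplet diameter needs an explicit normalisation: it is inversely
normalised against a reference diameter ``d_ref`` — the 10th percentile
of the diameters of a polymer-free ink printed on plastic — so that
smaller droplets score higher.  A condition with overall score above the
acceptability threshold (0.5 by default) lies inside the printability
window.

Conditions that transferred nothing are kept as the categorical state
``no_transfer`` — never coerced to a score of zero — and unscreened
conditions are carried explicitly so window maps can show all three
states.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .droplets import PrintCriteria
from .errors import NoTransferError, ValidationError
from .types import PrintCondition, STATUS_NO_TRANSFER, STATUS_UNSCREENED

__all__ = [
    "ScoreConfig",
    "PrintabilityScores",
    "WindowMap",
    "normalize_diameter",
    "normalize_diameter_linear",
    "compute_reference",
    "overall_score",
    "build_window_map",
    "repeatability_cv",
]

ConditionKey = Tuple[float, float, float, str]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters.

    diameter_reference : float
        Reference diameter ``d_ref`` (µm); use :func:`compute_reference`
        on a polymer-free calibration print to obtain it.
    acceptability_threshold : float
        Overall score above which a condition is acceptable (default 0.5).
    weights : 4-tuple
        Non-negative weights for (diameter, efficiency, circularity,
        satellite), normalised to sum to 1.  Equal by default.
    diameter_norm : {"reciprocal", "linear"}
        ``reciprocal`` uses min(1, d_ref/d); ``linear`` uses
        1 − (d − d_ref)/(d_max − d_ref) clipped to [0, 1] and requires
        ``diameter_max``.
    """

    diameter_reference: float
    acceptability_threshold: float = 0.5
    weights: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    diameter_norm: str = "reciprocal"
    diameter_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter_reference <= 0:
            raise ValidationError("diameter_reference must be > 0 µm")
        if not (0.0 < self.acceptability_threshold < 1.0):
            raise ValidationError("acceptability_threshold must lie in (0, 1)")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be four non-negative values")
        object.__setattr__(self, "weights", tuple(w / w.sum()))
        if self.diameter_norm not in ("reciprocal", "linear"):
            raise ValidationError("diameter_norm must be 'reciprocal' or 'linear'")
        if self.diameter_norm == "linear" and (
            self.diameter_max is None or self.diameter_max <= self.diameter_reference
        ):
            raise ValidationError("linear normalisation needs diameter_max > d_ref")


@dataclass(frozen=True)
class PrintabilityScores:
    """The four normalised criteria and their weighted mean."""

    diameter_score: float
    efficiency_score: float
    circularity_score: float
    satellite_score: float
    overall: float

    def __post_init__(self) -> None:
        for name in (
            "diameter_score",
            "efficiency_score",
            "circularity_score",
            "satellite_score",
            "overall",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def acceptable(self, threshold: float = 0.5) -> bool:
        return self.overall > threshold


def normalize_diameter(mean_diameter: float, d_ref: float) -> float:
    """Inverse diameter normalisation min(1, d_ref / d).

    Equals 1 at (and below) the reference diameter and decreases strictly
    for larger droplets; scale-free, no global maximum required.
    """
    if mean_diameter <= 0 or d_ref <= 0:
        raise ValidationError("diameters must be > 0 µm")
    return min(1.0, d_ref / mean_diameter)


def normalize_diameter_linear(mean_diameter: float, d_ref: float, d_max: float) -> float:
    """Linear alternative: 1 − (d − d_ref)/(d_max − d_ref), clipped."""
    if mean_diameter <= 0 or d_ref <= 0:
        raise ValidationError("diameters must be > 0 µm")
    if d_max <= d_ref:
        raise ValidationError("d_max must exceed d_ref")
    return float(np.clip(1.0 - (mean_diameter - d_ref) / (d_max - d_ref), 0.0, 1.0))


def compute_reference(diameters: Sequence[float]) -> float:
    """Reference diameter: the 10th percentile of a calibration
    distribution (linear interpolation between order statistics), which
    excludes small-end outliers while still rewarding small droplets."""
    d = np.asarray(list(diameters), dtype=float)
    if d.size < 10:
        raise ValidationError("need at least 10 diameters for a stable reference")
    if np.any(d <= 0):
        raise ValidationError("diameters must be > 0 µm")
    return float(np.percentile(d, 10))


def overall_score(criteria: PrintCriteria, config: ScoreConfig) -> PrintabilityScores:
    """Combine the four criteria into the indexed printability score.

    Raises :class:`NoTransferError` for a print without main droplets;
    window-map assembly records that state separately.
    """
    if criteria.no_transfer:
        raise NoTransferError("no main droplets: overall score undefined")
    if criteria.satellite_score is None:
        raise ValidationError("criteria missing a satellite score")
    if config.diameter_norm == "reciprocal":
        ds = normalize_diameter(criteria.mean_diameter, config.diameter_reference)
    else:
        ds = normalize_diameter_linear(
            criteria.mean_diameter, config.diameter_reference, config.diameter_max
        )
    comps = (
        ds,
        criteria.efficiency,
        float(np.clip(criteria.mean_circularity, 0.0, 1.0)),
        criteria.satellite_score,
    )
    overall = float(np.dot(config.weights, comps))
    return PrintabilityScores(*comps, overall=overall)


@dataclass
class WindowMap:
    """Grid of printing conditions → score or categorical state.

    ``cells`` maps a condition key (energy µJ, DDR mm, volume µL, ink) to
    a :class:`PrintabilityScores` or one of the strings ``no_transfer`` /
    ``unscreened``.  The printability window is the set of screened cells
    whose overall score exceeds the threshold.
    """

    cells: Dict[ConditionKey, Union[PrintabilityScores, str]]
    threshold: float = 0.5
    axes: Dict[str, Tuple[float, ...]] = field(default_factory=dict)

    def window(self) -> Set[ConditionKey]:
        return {
            k
            for k, v in self.cells.items()
            if isinstance(v, PrintabilityScores) and v.overall > self.threshold
        }

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for (e, ddr, vol, ink), v in sorted(self.cells.items(), key=str):
            row = {
                "laser_energy_uJ": e,
                "ddr_mm": ddr,
                "loading_volume_uL": vol,
                "ink": ink,
            }
            if isinstance(v, PrintabilityScores):
                row.update(
                    status="scored",
                    diameter_score=v.diameter_score,
                    efficiency_score=v.efficiency_score,
                    circularity_score=v.circularity_score,
                    satellite_score=v.satellite_score,
                    overall=v.overall,
                    in_window=v.overall > self.threshold,
                )
            else:
                row.update(status=v, in_window=False)
            rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, path: str, ddr: Optional[float] = None) -> None:
        """Heatmap of overall score over (energy, DDR) for one loading
        volume/ink slice; no-transfer cells light gray, unscreened dark."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        if ddr is not None:
            df = df[df["ddr_mm"] == ddr]
        energies = sorted(df["laser_energy_uJ"].unique())
        ddrs = sorted(df["ddr_mm"].unique())
        grid = np.full((len(ddrs), len(energies)), np.nan)
        state = np.zeros_like(grid)  # 1 = no_transfer, 2 = unscreened
        for _, r in df.iterrows():
            i, j = ddrs.index(r["ddr_mm"]), energies.index(r["laser_energy_uJ"])
            if r["status"] == "scored":
                grid[i, j] = r["overall"]
            else:
                state[i, j] = 1 if r["status"] == "no_transfer" else 2
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(energies), 1 + 0.6 * len(ddrs)))
        im = ax.imshow(grid, vmin=0, vmax=1, cmap="viridis", aspect="auto")
        for i in range(len(ddrs)):
            for j in range(len(energies)):
                if state[i, j] == 1:
                    ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color="0.85"))
                elif state[i, j] == 2:
                    ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color="0.4"))
        ax.set_xticks(range(len(energies)), [f"{e:g}" for e in energies])
        ax.set_yticks(range(len(ddrs)), [f"{d:g}" for d in ddrs])
        ax.set_xlabel("laser energy (µJ)")
        ax.set_ylabel("DDR (mm)")
        fig.colorbar(im, ax=ax, label="overall score")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_window_map(
    scored: Sequence[Tuple[PrintCondition, Optional[PrintabilityScores]]],
    threshold: float = 0.5,
) -> WindowMap:
    """Assemble a window map from per-condition scores.

    ``None`` (or a condition with status ``no_transfer``) records the
    no-transfer state; status ``unscreened`` is carried through.
    Duplicate condition keys are an error.
    """
    cells: Dict[ConditionKey, Union[PrintabilityScores, str]] = {}
    for cond, scores in scored:
        key = cond.key
        if key in cells:
            raise ValidationError(f"duplicate condition {key}")
        if cond.status == STATUS_UNSCREENED:
            cells[key] = STATUS_UNSCREENED
        elif scores is None or cond.status == STATUS_NO_TRANSFER:
            cells[key] = STATUS_NO_TRANSFER
        else:
            cells[key] = scores
    axes = {
        "laser_energy_uJ": tuple(sorted({k[0] for k in cells})),
        "ddr_mm": tuple(sorted({k[1] for k in cells})),
        "loading_volume_uL": tuple(sorted({k[2] for k in cells})),
        "ink": tuple(sorted({k[3] for k in cells})),
    }
    return WindowMap(cells=cells, threshold=threshold, axes=axes)


def repeatability_cv(diameters_by_replicate: Sequence[Sequence[float]]) -> float:
    """Coefficient of variation of droplet diameter for one condition.

    Pools main-droplet diameters across replicate prints; CV = sample
    standard deviation (n−1) over mean.  Requires ≥ 2 values and a
    nonzero mean.
    """
    pooled = np.asarray(
        [v for rep in diameters_by_replicate for v in rep], dtype=float
    )
    if pooled.size < 2:
        raise ValidationError("need at least 2 diameters for a CV")
    mean = pooled.mean()
    if mean == 0:
        raise ValidationError("CV undefined for zero mean diameter")
    return float(pooled.std(ddof=1) / mean)
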