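"""Droplet detection, satellite classification and per-print criteria.

The four criteria that feed the printability score are computed here:
mean droplet diameter, transfer efficiency (fraction of CAD targets that
received a main droplet), mean circularity of the main droplets, and the
five-level satellite score.

Detection is a classical pipeline (Otsu threshold, 8-connected
components, small-object removal); label masks from any external
segmenter can be supplied instead and are honoured as-is, including
pre-flagged satellites.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters, measure

from .errors import NoTransferError, ValidationError
from .io import observations_from_labels
from .types import (
    DropletObservation,
    PatternDesign,
    PrintRecord,
    STATUS_NO_TRANSFER,
)

__all__ = [
    "PrintCriteria",
    "detect_droplets",
    "classify_satellites",
    "satellite_rubric",
    "compute_print_criteria",
    "pool_criteria",
]

#: The five admissible satellite scores (worst to best).
RUBRIC_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PrintCriteria:
    """The four raw criteria of a print (or pooled replicates).

    ``mean_diameter``/``mean_circularity`` are over main droplets only;
    ``efficiency`` is matched mains over expected target positions.
    """

    mean_diameter: float  # µm, nan when no mains
    diameter_values: Tuple[float, ...]
    efficiency: float
    mean_circularity: float
    satellite_score: Optional[float]
    n_main: int
    n_satellite: int
    n_expected: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValidationError("efficiency must lie in [0, 1]")
        if self.satellite_score is not None and self.satellite_score not in RUBRIC_LEVELS:
            raise ValidationError(f"satellite_score must be one of {RUBRIC_LEVELS}")

    @property
    def no_transfer(self) -> bool:
        return self.n_main == 0


def detect_droplets(
    image: np.ndarray,
    pixel_size: float,
    min_area: float = 25.0,
) -> List[DropletObservation]:
    """Detect bright droplets in a grayscale image.

    Otsu threshold → 8-connected components → components smaller than
    ``min_area`` (µm²) discarded → metrics converted to µm.  A constant
    image yields zero detections with a warning, not an error.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0 µm/px")
    min_area_px = max(1.0, min_area / pixel_size**2)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("expected a single-plane image")
    if np.ptp(image) == 0:
        warnings.warn("constant image: no droplets detected", stacklevel=2)
        return []
    thr = filters.threshold_otsu(image)
    labels = measure.label(image > thr, connectivity=2)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in measure.regionprops(labels):
        keep[rp.label] = rp.area >= min_area_px
    labels = np.where(keep[labels], labels, 0)
    # relabel sequentially so callers get dense ids
    labels = measure.label(labels > 0, connectivity=2)
    return observations_from_labels(labels, pixel_size)


def classify_satellites(
    droplets: Sequence[DropletObservation],
    design: PatternDesign,
    tol_radius: Optional[float] = None,
) -> List[DropletObservation]:
    """Assign main droplets to CAD targets and flag everything else.

    For each target position, the largest detection within ``tol_radius``
    becomes the main droplet (ties on area broken by smaller distance to
    the target); every other detection is a satellite.  A detection is
    only eligible for its nearest target, so one blob never claims two
    positions.  ``tol_radius`` defaults to a quarter of the nominal
    spacing and must stay below half of it.
    """
    if design.nominal_spacing is not None:
        if tol_radius is None:
            tol_radius = design.nominal_spacing / 4.0
        if tol_radius >= design.nominal_spacing / 2.0:
            raise ValidationError("tol_radius must be < nominal_spacing / 2")
    elif tol_radius is None:
        raise ValidationError("tol_radius required when spacing is undefined")

    targets = design.positions_array()
    tree = cKDTree(targets)
    cents = np.asarray([d.centroid for d in droplets], dtype=float).reshape(-1, 2)
    if len(droplets) == 0:
        return []
    dist, nearest = tree.query(cents)

    main_of: dict[int, int] = {}  # target index -> droplet index
    for i, d in enumerate(droplets):
        if dist[i] > tol_radius:
            continue
        t = int(nearest[i])
        j = main_of.get(t)
        if j is None:
            main_of[t] = i
            continue
        better = droplets[i].area > droplets[j].area or (
            droplets[i].area == droplets[j].area and dist[i] < dist[j]
        )
        if better:
            main_of[t] = i

    mains = {i: t for t, i in main_of.items()}
    out: List[DropletObservation] = []
    for i, d in enumerate(droplets):
        if i in mains:
            out.append(d.replace(is_satellite=False, matched_target_index=mains[i]))
        else:
            out.append(
                d.replace(
                    is_satellite=True,
                    matched_target_index=int(nearest[i]) if dist[i] <= tol_radius else None,
                )
            )
    return out


def satellite_rubric(
    n_main: int,
    n_satellite: int,
    satellite_area_fraction: Optional[float] = None,
    override: Optional[float] = None,
) -> float:
    """Five-level satellite grade.

    The verbal grading scale — 0 only satellites, 0.25 droplets with a lot
    of small satellites, 0.5 droplets with equally sized satellites, 0.75
    droplets with some small satellites, 1 droplets without satellites —
    is made computable with two numeric boundaries: satellites whose mean
    area reaches half the mean main-droplet area count as "equally sized"
    (→ 0.5), and a satellite-to-main count ratio above 1 counts as "a lot"
    (→ 0.25).  ``override`` bypasses the mapping for manual grading.
    """
    if override is not None:
        if override not in RUBRIC_LEVELS:
            raise ValidationError(f"override must be one of {RUBRIC_LEVELS}")
        return override
    if n_main < 0 or n_satellite < 0:
        raise ValidationError("counts must be >= 0")
    if n_main == 0 and n_satellite == 0:
        raise NoTransferError("no droplets at all: satellite score undefined")
    if n_main == 0:
        return 0.0
    if n_satellite == 0:
        return 1.0
    if satellite_area_fraction is not None and satellite_area_fraction >= 0.5:
        return 0.5
    if n_satellite / n_main > 1.0:
        return 0.25
    return 0.75


def _criteria_from_parts(
    mains: Sequence[DropletObservation],
    satellites: Sequence[DropletObservation],
    n_expected: int,
    satellite_override: Optional[float],
) -> PrintCriteria:
    n_main, n_sat = len(mains), len(satellites)
    if n_main == 0:
        return PrintCriteria(
            mean_diameter=float("nan"),
            diameter_values=(),
            efficiency=0.0,
            mean_circularity=float("nan"),
            satellite_score=0.0 if n_sat else None,
            n_main=0,
            n_satellite=n_sat,
            n_expected=n_expected,
        )
    diams = tuple(d.equivalent_diameter for d in mains)
    frac = None
    if n_sat:
        mean_main_area = float(np.mean([d.area for d in mains]))
        frac = float(np.mean([d.area for d in satellites])) / mean_main_area
    score = satellite_rubric(n_main, n_sat, frac, override=satellite_override)
    return PrintCriteria(
        mean_diameter=float(np.mean(diams)),
        diameter_values=diams,
        efficiency=n_main / n_expected,
        mean_circularity=float(np.mean([d.circularity for d in mains])),
        satellite_score=score,
        n_main=n_main,
        n_satellite=n_sat,
        n_expected=n_expected,
    )


def compute_print_criteria(
    record: PrintRecord, satellite_override: Optional[float] = None
) -> PrintCriteria:
    """Reduce a classified print to its four criteria.

    A ``no_transfer`` print (or one with no matched mains) yields
    efficiency 0 with NaN diameter/circularity; downstream scoring keeps
    that as a distinct categorical state rather than a score of zero.
    """
    n_expected = record.design.droplets_per_print
    if record.condition.status == STATUS_NO_TRANSFER:
        return _criteria_from_parts((), (), n_expected, satellite_override)
    return _criteria_from_parts(
        record.mains, record.satellites, n_expected, satellite_override
    )


def pool_criteria(
    parts: Sequence[PrintCriteria], satellite_override: Optional[float] = None
) -> PrintCriteria:
    """Pool replicate prints of one condition into a single criteria set.

    Diameters are pooled across replicates; efficiency is total matched
    mains over total expected positions (e.g. 3 replicate 4×4 grids → 48
    expected droplets); circularity is the main-droplet-weighted mean; the
    satellite grade is recomputed from pooled counts and the pooled
    satellite/main area ratio.
    """
    if len(parts) == 0:
        raise ValidationError("no criteria to pool")
    n_expected = sum(p.n_expected for p in parts)
    n_main = sum(p.n_main for p in parts)
    n_sat = sum(p.n_satellite for p in parts)
    if n_main == 0:
        return PrintCriteria(
            mean_diameter=float("nan"),
            diameter_values=(),
            efficiency=0.0,
            mean_circularity=float("nan"),
            satellite_score=0.0 if n_sat else None,
            n_main=0,
            n_satellite=n_sat,
            n_expected=n_expected,
        )
    diams = tuple(v for p in parts for v in p.diameter_values)
    circ = (
        sum(p.mean_circularity * p.n_main for p in parts if p.n_main) / n_main
    )
    # Reconstruct a pooled area fraction from per-print rubric inputs is
    # not possible from the reduced criteria alone; grade from the pooled
    # counts, treating any replicate graded 0.5 (equally sized) as binding.
    frac = 0.5 if any(p.satellite_score == 0.5 for p in parts) else None
    score = satellite_rubric(n_main, n_sat, frac, override=satellite_override)
    return PrintCriteria(
        mean_diameter=float(np.mean(diams)),
        diameter_values=diams,
        efficiency=n_main / n_expected,
        mean_circularity=float(circ),
        satellite_score=score,
        n_main=n_main,
        n_satellite=n_sat,
        n_expected=n_expected,
    )
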