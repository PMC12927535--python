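"""Domain types shared by every module.

Conventions
-----------
* Image coordinates are (x right, y down), origin at the centre of the
  top-left pixel, 0-based.  All metric quantities are in micrometres after
  scaling by the pixel size.
* Volumes are canonically nanolitres (1 nL = 1e-6 mL = 1e6 µm³),
  concentrations cells/mL, laser energy µJ, donor–receiver distance (DDR)
  mm, donor loading volume µL, viscosity mPa·s.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "InkSpec",
    "PrintCondition",
    "PatternDesign",
    "DropletObservation",
    "PrintRecord",
    "JetState",
    "STATUS_SCORED",
    "STATUS_NO_TRANSFER",
    "STATUS_UNSCREENED",
    "observation_from_geometry",
]

STATUS_SCORED = "scored"
STATUS_NO_TRANSFER = "no_transfer"
STATUS_UNSCREENED = "unscreened"
_STATUSES = (STATUS_SCORED, STATUS_NO_TRANSFER, STATUS_UNSCREENED)


@dataclass(frozen=True)
class InkSpec:
    """Physical description of a bioink.

    Parameters
    ----------
    density_rho : float
        Fluid density in kg/m³.
    surface_tension_sigma : float
        Surface tension in N/m.
    viscosity : float
        Dynamic viscosity in mPa·s (printable inks span roughly 1–1000).
    cell_concentration : float, optional
        Cell concentration of the suspension in cells/mL.
    """

    name: str = "aqueous"
    density_rho: float = 1000.0
    surface_tension_sigma: float = 0.072
    viscosity: float = 1.0
    cell_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.density_rho <= 0:
            raise ValidationError("density_rho must be > 0 kg/m^3")
        if self.surface_tension_sigma <= 0:
            raise ValidationError("surface_tension_sigma must be > 0 N/m")
        if self.viscosity <= 0:
            raise ValidationError("viscosity must be > 0 mPa·s")
        if self.cell_concentration is not None and self.cell_concentration < 0:
            raise ValidationError("cell_concentration must be >= 0 cells/mL")


@dataclass(frozen=True)
class JetState:
    """Kinematics of the transfer jet used for the Weber number."""

    velocity: float  # m/s
    length_scale: float  # m

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValidationError("jet velocity must be >= 0 m/s")
        if self.length_scale <= 0:
            raise ValidationError("jet length scale must be > 0 m")


@dataclass(frozen=True)
class PrintCondition:
    """One printing condition: ink plus process parameters.

    ``status`` distinguishes conditions that produced measurable droplets
    (``scored``), conditions screened but yielding no deposition
    (``no_transfer``) and conditions never screened (``unscreened``).
    """

    ink: InkSpec = field(default_factory=InkSpec)
    laser_energy: float = 5.0  # µJ
    ddr: float = 1.0  # mm
    loading_volume: float = 10.0  # µL
    status: str = STATUS_SCORED

    def __post_init__(self) -> None:
        if self.laser_energy < 0:
            raise ValidationError("laser_energy must be >= 0 µJ")
        if self.ddr <= 0:
            raise ValidationError("ddr must be > 0 mm")
        if self.loading_volume <= 0:
            raise ValidationError("loading_volume must be > 0 µL")
        if self.status not in _STATUSES:
            raise ValidationError(f"status must be one of {_STATUSES}")

    @property
    def key(self) -> Tuple[float, float, float, str]:
        """Hashable grid key (energy, DDR, volume, ink name)."""
        return (self.laser_energy, self.ddr, self.loading_volume, self.ink.name)


@dataclass(frozen=True)
class PatternDesign:
    """CAD target layout: droplet centroid positions in µm.

    ``nominal_spacing`` is the designed inter-droplet distance; ``None``
    flags a design (e.g. a single droplet) where spacing is undefined.
    """

    target_positions: Tuple[Tuple[float, float], ...]
    nominal_spacing: Optional[float] = None
    replicates: int = 1

    def __post_init__(self) -> None:
        pos = [tuple(map(float, p)) for p in self.target_positions]
        if len(pos) == 0:
            raise ValidationError("design needs at least one target position")
        if len(set(pos)) != len(pos):
            raise ValidationError("target positions must be unique")
        object.__setattr__(self, "target_positions", tuple(pos))
        if self.nominal_spacing is not None and self.nominal_spacing <= 0:
            raise ValidationError("nominal_spacing must be > 0 µm")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @property
    def droplets_per_print(self) -> int:
        return len(self.target_positions)

    def positions_array(self) -> np.ndarray:
        return np.asarray(self.target_positions, dtype=float)

    @classmethod
    def grid(
        cls,
        nx: int = 4,
        ny: int = 4,
        spacing: float = 500.0,
        origin: Tuple[float, float] = (0.0, 0.0),
        replicates: int = 1,
    ) -> "PatternDesign":
        """Regular ``nx`` × ``ny`` grid, e.g. the screening 4×4 layout at
        500 µm spacing."""
        ox, oy = origin
        pos = tuple(
            (ox + i * spacing, oy + j * spacing)
            for j in range(ny)
            for i in range(nx)
        )
        return cls(pos, nominal_spacing=float(spacing), replicates=replicates)

    @staticmethod
    def infer_spacing(positions: np.ndarray) -> Optional[float]:
        """Modal nearest-neighbour distance, or None for a single point."""
        positions = np.asarray(positions, dtype=float)
        if len(positions) < 2:
            return None
        tree = cKDTree(positions)
        d, _ = tree.query(positions, k=2)
        nn = np.round(d[:, 1], 6)
        vals, counts = np.unique(nn, return_counts=True)
        return float(vals[np.argmax(counts)])


@dataclass(frozen=True)
class DropletObservation:
    """One detected object in a print image (main droplet or satellite)."""

    label_id: int
    centroid: Tuple[float, float]  # (x, y) µm
    area: float  # µm²
    perimeter: float  # µm
    equivalent_diameter: float  # µm
    circularity: float  # dimensionless, clipped to [0, 1]
    is_satellite: bool = False
    matched_target_index: Optional[int] = None
    cell_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError("droplet area must be > 0 µm²")
        if not (0.0 <= self.circularity <= 1.0):
            raise ValidationError("circularity must lie in [0, 1]")
        if self.cell_count is not None and self.cell_count < 0:
            raise ValidationError("cell_count must be >= 0")

    def replace(self, **kw) -> "DropletObservation":
        return replace(self, **kw)


def observation_from_geometry(
    label_id: int,
    centroid_xy_um: Tuple[float, float],
    area_um2: float,
    perimeter_um: float,
    **kw,
) -> DropletObservation:
    """Build an observation from raw geometry, deriving the equivalent
    diameter ``2·sqrt(A/π)`` and circularity ``4πA/P²`` (clipped to [0, 1];
    a zero perimeter, e.g. a single-pixel label, is treated as a perfect
    disk)."""
    if area_um2 <= 0:
        raise ValidationError("area must be > 0 µm²")
    eq_d = 2.0 * math.sqrt(area_um2 / math.pi)
    if perimeter_um > 0:
        circ = min(1.0, max(0.0, 4.0 * math.pi * area_um2 / perimeter_um**2))
    else:
        circ = 1.0
    return DropletObservation(
        label_id=int(label_id),
        centroid=(float(centroid_xy_um[0]), float(centroid_xy_um[1])),
        area=float(area_um2),
        perimeter=float(perimeter_um),
        equivalent_diameter=eq_d,
        circularity=circ,
        **kw,
    )


@dataclass(frozen=True)
class PrintRecord:
    """A single print: condition, target design and detected droplets."""

    condition: PrintCondition
    design: PatternDesign
    droplets: Tuple[DropletObservation, ...]
    pixel_size: float = 1.0  # µm/px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0 µm/px")
        object.__setattr__(self, "droplets", tuple(self.droplets))
        if self.condition.status == STATUS_NO_TRANSFER and self.droplets:
            raise ValidationError("no_transfer prints cannot carry droplets")
        n = self.design.droplets_per_print
        seen = set()
        for d in self.droplets:
            idx = d.matched_target_index
            if idx is None:
                continue
            if not (0 <= idx < n):
                raise ValidationError(f"matched_target_index {idx} out of range")
            if not d.is_satellite:
                if idx in seen:
                    raise ValidationError(
                        f"target {idx} matched by more than one main droplet"
                    )
                seen.add(idx)

    @property
    def mains(self) -> Tuple[DropletObservation, ...]:
        return tuple(
            d
            for d in self.droplets
            if not d.is_satellite and d.matched_target_index is not None
        )

    @property
    def satellites(self) -> Tuple[DropletObservation, ...]:
        return tuple(d for d in self.droplets if d.is_satellite)
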