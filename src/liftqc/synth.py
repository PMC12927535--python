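"""Synthetic prints, cell loadings and network images with ground truth.

Everything downstream — detection, scoring, window mapping, fidelity,
skeleton morphometrics, Poisson fitting — is testable against these
generators, which plant a known truth and are bit-reproducible under a
seed.

Default print parameters emulate the reference printing condition of a
low-viscosity aqueous ink: 4×4 droplet grids at 500 µm spacing, ~70 µm
droplets with ~10% diameter scatter, a few µm of placement jitter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from skimage import draw as skdraw

from .errors import ValidationError
from .io import observations_from_labels
from .types import (
    InkSpec,
    PatternDesign,
    PrintCondition,
    PrintRecord,
    STATUS_NO_TRANSFER,
    STATUS_SCORED,
)

__all__ = [
    "SynthPrintParams",
    "QualitySurface",
    "generate_print",
    "generate_cell_loadings",
    "generate_network_image",
    "generate_parameter_sweep",
    "monotone_quality_surface",
]

ML_PER_NL = 1e-6


@dataclass(frozen=True)
class SynthPrintParams:
    """Knobs of the synthetic print generator.

    transfer_prob : fraction of targets that receive a main droplet
    mean_diameter / diameter_cv : truncated-normal droplet diameters (µm)
    placement_jitter_sd : isotropic centroid jitter (µm)
    satellite_rate : expected satellites per realised main droplet
    satellite_diameter_frac : satellite diameter as fraction of parent's
    ellipticity : 0 for disks; e>0 draws ellipses with axis ratio
        (1−e) at preserved area
    pixel_size : rasterization scale (µm/px)
    """

    design: PatternDesign
    transfer_prob: float = 1.0
    mean_diameter: float = 70.0
    diameter_cv: float = 0.1
    placement_jitter_sd: float = 5.0
    satellite_rate: float = 0.0
    satellite_diameter_frac: float = 0.2
    ellipticity: float = 0.0
    pixel_size: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.transfer_prob <= 1.0):
            raise ValidationError("transfer_prob must lie in [0, 1]")
        if self.mean_diameter <= 0:
            raise ValidationError("mean_diameter must be > 0 µm")
        if self.diameter_cv < 0 or self.placement_jitter_sd < 0:
            raise ValidationError("diameter_cv and jitter must be >= 0")
        if self.satellite_rate < 0:
            raise ValidationError("satellite_rate must be >= 0")
        if not (0.0 < self.satellite_diameter_frac < 1.0):
            raise ValidationError("satellite_diameter_frac must lie in (0, 1)")
        if not (0.0 <= self.ellipticity < 1.0):
            raise ValidationError("ellipticity must lie in [0, 1)")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0 µm/px")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal(mean, sd) resampled until > lo (cheap for cv ≤ 0.3)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    raise ValidationError("truncated normal failed: sd too large for mean")


def _draw_ellipse(
    canvas: np.ndarray,
    label: int,
    cx_um: float,
    cy_um: float,
    diameter_um: float,
    ellipticity: float,
    rotation: float,
    pixel_size: float,
) -> Optional[np.ndarray]:
    """Rasterize an area-preserving ellipse; returns flat indices drawn,
    or None on collision with existing labels."""
    r_um = diameter_um / 2.0
    major = r_um / math.sqrt(1.0 - ellipticity) / pixel_size
    minor = r_um * math.sqrt(1.0 - ellipticity) / pixel_size
    major = max(major, 0.6)
    minor = max(minor, 0.6)
    rr, cc = skdraw.ellipse(
        cy_um / pixel_size, cx_um / pixel_size, major, minor,
        shape=canvas.shape, rotation=rotation,
    )
    if rr.size == 0:
        return None
    if np.any(canvas[rr, cc] != 0):
        return None
    canvas[rr, cc] = label
    return np.ravel_multi_index((rr, cc), canvas.shape)


def generate_print(
    params: SynthPrintParams,
    condition: Optional[PrintCondition] = None,
) -> Tuple[np.ndarray, PrintRecord]:
    """Generate one synthetic print: a 16-bit label mask and its ground
    truth.

    Each target independently receives a main droplet with probability
    ``transfer_prob``; realised droplets get truncated-normal diameters,
    isotropic Normal jitter on the centroid, and Poisson(satellite_rate)
    satellites placed uniformly in an annulus within 3 main radii of the
    parent (never on a target).  The record's observations are measured
    off the rasterized mask and carry true match indices and satellite
    flags.  Identical seeds give bit-identical output.  A droplet that
    cannot be placed without overlap after 100 attempts raises (the
    density is degenerate).
    """
    rng = np.random.default_rng(params.seed)
    design = params.design
    px = params.pixel_size
    pos = design.positions_array()
    margin = 2.0 * params.mean_diameter + 3.0 * params.placement_jitter_sd
    origin = pos.min(axis=0) - margin
    extent = pos.max(axis=0) - pos.min(axis=0) + 2 * margin
    shape = (int(math.ceil(extent[1] / px)) + 1, int(math.ceil(extent[0] / px)) + 1)
    canvas = np.zeros(shape, dtype=np.uint16)

    truth: Dict[int, Tuple[bool, Optional[int]]] = {}  # label -> (is_sat, target)
    label = 0
    mains: List[Tuple[int, float, float, float]] = []  # target, cx, cy, d

    for t, (tx, ty) in enumerate(pos - origin):
        if rng.random() >= params.transfer_prob:
            continue
        placed = False
        for _ in range(100):
            d = _truncated_normal(
                rng, params.mean_diameter, params.diameter_cv * params.mean_diameter, px
            )
            jx, jy = rng.normal(0.0, params.placement_jitter_sd, size=2)
            rot = rng.uniform(0, math.pi) if params.ellipticity > 0 else 0.0
            if _draw_ellipse(
                canvas, label + 1, tx + jx, ty + jy, d, params.ellipticity, rot, px
            ) is not None:
                label += 1
                truth[label] = (False, t)
                mains.append((t, tx + jx, ty + jy, d))
                placed = True
                break
        if not placed:
            raise ValidationError("could not place droplet without overlap (degenerate density)")

    for t, cx, cy, d in mains:
        n_sat = rng.poisson(params.satellite_rate)
        for _ in range(n_sat):
            d_sat = max(params.satellite_diameter_frac * d, px)
            placed = False
            for _ in range(100):
                r_par = d / 2.0
                rad = r_par * rng.uniform(1.3, 3.0)
                ang = rng.uniform(0, 2 * math.pi)
                sx, sy = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
                if not (0 <= sx / px < shape[1] and 0 <= sy / px < shape[0]):
                    continue
                if _draw_ellipse(canvas, label + 1, sx, sy, d_sat, 0.0, 0.0, px) is not None:
                    label += 1
                    truth[label] = (True, t)
                    placed = True
                    break
            if not placed:
                raise ValidationError("could not place satellite without overlap")

    status = STATUS_SCORED if mains else STATUS_NO_TRANSFER
    if condition is None:
        condition = PrintCondition(status=status)
    elif condition.status == STATUS_SCORED and not mains:
        condition = replace(condition, status=STATUS_NO_TRANSFER)

    obs = observations_from_labels(canvas, px)
    annotated = []
    for o in obs:
        is_sat, t = truth[o.label_id]
        annotated.append(
            o.replace(is_satellite=is_sat, matched_target_index=t)
        )
    record = PrintRecord(
        condition=condition,
        design=PatternDesign(
            tuple((x - origin[0], y - origin[1]) for x, y in design.target_positions),
            nominal_spacing=design.nominal_spacing,
            replicates=design.replicates,
        ),
        droplets=tuple(annotated),
        pixel_size=px,
    )
    return canvas, record


def generate_cell_loadings(
    n_droplets: int, volume_nl: float, concentration: float, seed: int = 0
) -> np.ndarray:
    """I.i.d. Poisson cells-per-droplet counts with λ = V(mL)·C."""
    if n_droplets < 0:
        raise ValidationError("n_droplets must be >= 0")
    if volume_nl <= 0:
        raise ValidationError("volume must be > 0 nL")
    if concentration < 0:
        raise ValidationError("concentration must be >= 0 cells/mL")
    lam = volume_nl * ML_PER_NL * concentration
    rng = np.random.default_rng(seed)
    return rng.poisson(lam, size=n_droplets)


def _segment_junctions(
    segments: Sequence[Tuple[Tuple[float, float], Tuple[float, float]]],
    tol: float = 1e-6,
) -> int:
    """Ground-truth junction count: points where >= 3 branches meet.

    Each segment contributes 2 branches at an interior crossing point and
    1 branch at one of its endpoints."""
    from shapely.geometry import LineString, Point

    lines = [LineString([a, b]) for a, b in segments]
    candidates: List[Tuple[float, float]] = []
    for a, b in segments:
        candidates.extend([a, b])
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            pts = [inter] if inter.geom_type == "Point" else list(getattr(inter, "geoms", []))
            for p in pts:
                if p.geom_type == "Point":
                    candidates.append((p.x, p.y))
    # merge candidate points
    merged: List[Tuple[float, float]] = []
    for p in candidates:
        if not any(math.dist(p, q) < 1e-3 for q in merged):
            merged.append(p)
    n_junctions = 0
    for q in merged:
        degree = 0
        pq = Point(q)
        for (a, b), line in zip(segments, lines):
            on_line = line.distance(pq) < 1e-3
            if not on_line:
                continue
            at_end = math.dist(q, a) < 1e-3 or math.dist(q, b) < 1e-3
            degree += 1 if at_end else 2
        if degree >= 3:
            n_junctions += 1
    return n_junctions


def generate_network_image(
    segments: Sequence[Tuple[Tuple[float, float], Tuple[float, float]]],
    thickness: float,
    pixel_size: float,
    noise_sd: float = 5.0,
    seed: int = 0,
    canvas_um: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, Dict[str, object]]:
    """Grayscale image of bright strokes on a dark background plus the
    ground truth.

    Returns ``(image, truth)`` with truth carrying ``total_length_um``
    (sum of segment lengths), ``n_junctions`` (points where ≥ 3 branches
    meet, crossings included) and the clean binary ``mask``.  An empty
    segment list gives a pure-noise image with zero truth.
    """
    if thickness < pixel_size:
        raise ValidationError("thickness must be >= pixel_size")
    rng = np.random.default_rng(seed)
    if canvas_um is None:
        if segments:
            arr = np.asarray([p for s in segments for p in s], dtype=float)
            canvas_um = (arr[:, 0].max() + 4 * thickness, arr[:, 1].max() + 4 * thickness)
        else:
            canvas_um = (200.0, 200.0)
    shape = (
        int(math.ceil(canvas_um[1] / pixel_size)) + 1,
        int(math.ceil(canvas_um[0] / pixel_size)) + 1,
    )
    mask = np.zeros(shape, dtype=bool)
    if segments:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        px_pts = np.stack([xx * pixel_size, yy * pixel_size], axis=-1)
        half = thickness / 2.0
        for (x1, y1), (x2, y2) in segments:
            a = np.array([x1, y1])
            ab = np.array([x2 - x1, y2 - y1])
            L2 = float(ab @ ab)
            if L2 == 0:
                continue
            t = np.clip(((px_pts - a) @ ab) / L2, 0.0, 1.0)
            near = a + t[..., None] * ab
            dist = np.linalg.norm(px_pts - near, axis=-1)
            mask |= dist <= half
    img = np.where(mask, 200.0, 20.0)
    img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    total = float(sum(math.dist(a, b) for a, b in segments))
    truth = {
        "total_length_um": total,
        "n_junctions": _segment_junctions(segments) if segments else 0,
        "mask": mask,
    }
    return img, truth


@dataclass(frozen=True)
class QualitySurface:
    """Phenomenological quality surface over printing conditions.

    Maps each condition to the generator parameters it should exhibit,
    together with the set of conditions planted to score above the
    acceptability threshold.  Within a DDR slice, parameters degrade
    monotonically with laser energy, mimicking chaotic jetting at high
    energies.
    """

    cells: Mapping[PrintCondition, SynthPrintParams]
    planted_window: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise ValidationError("quality surface has no conditions")
        if not self.planted_window:
            raise ValidationError("planted_window must be non-empty")
        keys = {c.key for c in self.cells}
        if not set(self.planted_window) <= keys:
            raise ValidationError("planted_window references unknown conditions")


def monotone_quality_surface(
    design: Optional[PatternDesign] = None,
    energies: Sequence[float] = (4, 6, 8, 10, 12, 14),
    ddrs: Sequence[float] = (1.0, 2.0),
    good_max_energy: float = 8.0,
    loading_volume: float = 10.0,
    ink: Optional[InkSpec] = None,
    mean_diameter: float = 70.0,
    pixel_size: float = 5.0,
) -> QualitySurface:
    """A planted surface where quality degrades monotonically with laser
    energy past ``good_max_energy`` (the designated optimum sits at the
    low-energy end): transfer probability falls, droplets grow and
    satellites multiply, as observed when jetting turns chaotic."""
    ink = ink or InkSpec()
    cells: Dict[PrintCondition, SynthPrintParams] = {}
    window = set()
    for ddr in ddrs:
        good = [e for e in energies if e <= good_max_energy]
        for e in energies:
            cond = PrintCondition(
                ink=ink, laser_energy=float(e), ddr=float(ddr), loading_volume=loading_volume
            )
            if e <= good_max_energy:
                rank = good.index(e)
                p = SynthPrintParams(
                    design=design or PatternDesign.grid(),
                    transfer_prob=1.0 - 0.02 * rank,
                    mean_diameter=mean_diameter * (1.0 + 0.05 * rank),
                    diameter_cv=0.08,
                    placement_jitter_sd=4.0,
                    satellite_rate=0.05 * rank,
                    ellipticity=0.02 * rank,
                    pixel_size=pixel_size,
                )
                window.add(cond.key)
            else:
                k = sorted(e2 for e2 in energies if e2 > good_max_energy).index(e)
                p = SynthPrintParams(
                    design=design or PatternDesign.grid(),
                    transfer_prob=max(0.05, 0.25 - 0.1 * k),
                    mean_diameter=mean_diameter * (2.3 + 0.4 * k),
                    diameter_cv=0.2,
                    placement_jitter_sd=10.0,
                    satellite_rate=2.5 + 0.5 * k,
                    ellipticity=0.3,
                    pixel_size=pixel_size,
                )
            cells[cond] = p
    return QualitySurface(cells=cells, planted_window=frozenset(window))


def generate_parameter_sweep(
    surface: QualitySurface,
    replicates: int = 3,
    seed: int = 0,
) -> List[Tuple[PrintCondition, np.ndarray, PrintRecord]]:
    """Generate ``replicates`` prints per surface condition (default 3,
    i.e. 3 × 4×4 grids = 48 expected droplets per condition).

    A single global seed fans out into independent per-print substreams
    keyed by condition and replicate index, so the sweep is deterministic
    yet decorrelated across conditions.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    conds = sorted(surface.cells, key=lambda c: c.key)
    children = ss.spawn(len(conds) * replicates)
    out = []
    for i, cond in enumerate(conds):
        base = surface.cells[cond]
        for j in range(replicates):
            child_seed = int(children[i * replicates + j].generate_state(1)[0] % (2**31))
            mask, record = generate_print(replace(base, seed=child_seed), condition=cond)
            out.append((cond, mask, record))
    return out
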