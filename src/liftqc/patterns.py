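"""Pattern fidelity, coverage, retention and network morphometrics.

Fidelity compares measured inter-droplet distances against the CAD
design; coverage measures deposited area over a region of interest;
retention reads mean gray values in boxes at 0/±300 µm from the CAD
centerline; skeleton morphometrics quantify vessel-like networks (total
and average segment length, junction count); viability and cell-shape
circularity summarise two-channel live/dead masks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import ValidationError
from .io import observations_from_labels
from .types import DropletObservation, PatternDesign, PrintRecord

__all__ = [
    "FidelityReport",
    "NetworkMetrics",
    "RetentionReport",
    "design_adjacency",
    "fidelity",
    "fidelity_from_record",
    "coverage_fraction",
    "roi_retention",
    "skeleton_morphometrics",
    "quantify_viability",
    "cell_circularity",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class FidelityReport:
    """Deviation between measured and target inter-droplet distances.

    ``fidelity_percent`` uses the nominal spacing as denominator,
    ``fidelity_percent_pairwise`` the per-pair target distance; both are
    floored at 0.  The raw deviations (µm) are always carried along.
    """

    deviations: Tuple[float, ...]
    mean_abs_deviation: float
    fidelity_percent: float
    fidelity_percent_pairwise: float
    n_pairs: int


@dataclass(frozen=True)
class NetworkMetrics:
    """Skeleton-level morphometrics of a vessel-like network."""

    total_length: float  # µm
    n_segments: int
    average_length: float  # µm
    n_junctions: int


@dataclass(frozen=True)
class RetentionReport:
    """Mean gray value at the CAD centerline and at flanking offsets."""

    mean_gray: Dict[float, float]  # offset µm -> mean intensity
    retention_ratio: float  # centre / mean of flanks


def design_adjacency(
    design: PatternDesign, tolerance: float = 0.1
) -> List[Tuple[int, int]]:
    """Pairs of design targets at the nominal spacing ± ``tolerance``
    (fractional).  These are the "inter-droplet distances" evaluated by
    :func:`fidelity`."""
    if design.nominal_spacing is None:
        raise ValidationError("design has no nominal spacing")
    pos = design.positions_array()
    s = design.nominal_spacing
    tree = cKDTree(pos)
    pairs = []
    for i, j in sorted(tree.query_pairs(r=(1.0 + tolerance) * s)):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d >= (1.0 - tolerance) * s:
            pairs.append((i, j))
    return pairs


def fidelity(
    measured: Mapping[int, Tuple[float, float]], design: PatternDesign
) -> FidelityReport:
    """Print fidelity from matched droplet centroids.

    For every adjacent design pair with both ends matched, the absolute
    deviation between measured and target centroid distance is recorded;
    fidelity = 100·(1 − mean deviation / spacing), floored at 0.  Being a
    function of distances only, the result is invariant to translation
    and rotation of the print.
    """
    if len(measured) < 2:
        raise ValidationError("need at least 2 matched droplets")
    pos = design.positions_array()
    devs, rels = [], []
    for i, j in design_adjacency(design):
        if i in measured and j in measured:
            target_d = float(np.linalg.norm(pos[i] - pos[j]))
            meas_d = float(
                np.linalg.norm(np.subtract(measured[i], measured[j]))
            )
            devs.append(abs(meas_d - target_d))
            rels.append(abs(meas_d - target_d) / target_d)
    if not devs:
        raise ValidationError("no adjacent design pair has both ends matched")
    mad = float(np.mean(devs))
    pct = max(0.0, 100.0 * (1.0 - mad / design.nominal_spacing))
    pct_pair = max(0.0, 100.0 * (1.0 - float(np.mean(rels))))
    return FidelityReport(
        deviations=tuple(devs),
        mean_abs_deviation=mad,
        fidelity_percent=pct,
        fidelity_percent_pairwise=pct_pair,
        n_pairs=len(devs),
    )


def fidelity_from_record(record: PrintRecord) -> FidelityReport:
    """Convenience wrapper taking matched centroids off a classified print."""
    measured = {
        d.matched_target_index: d.centroid
        for d in record.mains
    }
    return fidelity(measured, record.design)


def coverage_fraction(
    droplets: Sequence[DropletObservation],
    roi: Tuple[float, float, float, float],
) -> float:
    """Fraction of a rectangular ROI (x0, y0, x1, y1 in µm) covered by
    droplets, each modelled as a disk of its equivalent diameter centred
    on its centroid and clipped to the ROI.  Additive over disjoint
    droplets; capped at 1."""
    from shapely.geometry import Point, box

    x0, y0, x1, y1 = roi
    rect = box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
    if rect.area <= 0:
        raise ValidationError("ROI must have positive area")
    covered = 0.0
    for d in droplets:
        disk = Point(d.centroid).buffer(d.equivalent_diameter / 2.0, quad_segs=64)
        covered += disk.intersection(rect).area
    return min(1.0, covered / rect.area)


def _polyline_point_and_normal(
    centerline: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Point at half arc length of a polyline and its unit normal."""
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("centerline must be a polyline of >= 2 points")
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    if total == 0:
        raise ValidationError("degenerate centerline")
    half = total / 2.0
    acc = 0.0
    for k, L in enumerate(seglen):
        if acc + L >= half:
            t = (half - acc) / L
            p = pts[k] + t * seg[k]
            tangent = seg[k] / L
            normal = np.array([-tangent[1], tangent[0]])
            return p, normal
        acc += L
    return pts[-1], np.array([0.0, 1.0])


def roi_retention(
    image: np.ndarray,
    centerline: Sequence[Tuple[float, float]],
    pixel_size: float,
    box_halfwidth: float = 150.0,
    offsets: Sequence[float] = (0.0, 300.0, -300.0),
) -> RetentionReport:
    """Mean gray value in square ROIs placed normal to the CAD centerline.

    Boxes of side ``2·box_halfwidth`` µm are centred at the polyline
    midpoint displaced along its normal by each offset (defaults 0 and
    ±300 µm).  The retention ratio is the on-line mean over the average
    of the flanking means; a box falling outside the image is an error.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    img = np.asarray(image, dtype=float)
    centre, normal = _polyline_point_and_normal(np.asarray(centerline))
    means: Dict[float, float] = {}
    for off in offsets:
        cx, cy = centre + off * normal
        c0 = int(round((cx - box_halfwidth) / pixel_size))
        c1 = int(round((cx + box_halfwidth) / pixel_size))
        r0 = int(round((cy - box_halfwidth) / pixel_size))
        r1 = int(round((cy + box_halfwidth) / pixel_size))
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            raise ValidationError(f"ROI at offset {off} µm falls outside the image")
        means[float(off)] = float(img[r0:r1, c0:c1].mean())
    flanks = [v for k, v in means.items() if k != 0.0]
    centre_mean = means.get(0.0, float("nan"))
    flank_mean = float(np.mean(flanks)) if flanks else float("nan")
    ratio = centre_mean / flank_mean if flank_mean > 0 else math.inf
    return RetentionReport(mean_gray=means, retention_ratio=ratio)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton with √2 diagonal weights.

    Diagonal edges that are shortcut by a shared orthogonal neighbour are
    dropped so that L-corners do not form spurious triangles."""
    coords = set(map(tuple, np.argwhere(skel)))
    G = nx.Graph()
    G.add_nodes_from(coords)
    for (r, c) in coords:
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb in coords:
                G.add_edge((r, c), nb, weight=1.0)
        for dr, dc in ((1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb in coords:
                if (r, c + dc) in coords or (r + dr, c) in coords:
                    continue  # orthogonal path exists
                G.add_edge((r, c), nb, weight=SQRT2)
    return G


def skeleton_morphometrics(
    mask: np.ndarray,
    pixel_size: float,
    junction_merge_radius: int = 3,
    prune_px: int = 3,
) -> NetworkMetrics:
    """Skeletonize a binary network mask and measure it.

    Junctions are skeleton pixels with ≥ 3 skeleton neighbours, merged
    within ``junction_merge_radius`` pixels to avoid double-counting
    thick-skeleton artifacts.  Segments are skeleton arcs between
    junctions/endpoints; arc length counts diagonal steps as √2 pixels;
    segments shorter than ``prune_px`` pixels are pruned.  An empty mask
    yields all-zero metrics.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return NetworkMetrics(0.0, 0, 0.0, 0)
    skel = morphology.skeletonize(mask)
    G = _skeleton_graph(skel)
    junction_px = [n for n in G if G.degree(n) >= 3]

    # merge nearby junction pixels into clusters
    clusters: List[set] = []
    if junction_px:
        jarr = np.asarray(junction_px, dtype=float)
        jt = cKDTree(jarr)
        H = nx.Graph()
        H.add_nodes_from(range(len(junction_px)))
        H.add_edges_from(jt.query_pairs(r=junction_merge_radius))
        clusters = [set(junction_px[i] for i in comp) for comp in nx.connected_components(H)]
    junction_nodes = set().union(*clusters) if clusters else set()

    # segments: connected arcs once junction pixels are removed, plus the
    # edges that attach each arc back to its junction(s)
    S = G.copy()
    S.remove_nodes_from(junction_nodes)
    seg_lengths: List[float] = []
    for comp in nx.connected_components(S):
        length = sum(
            d["weight"] for u, v, d in S.subgraph(comp).edges(data=True)
        )
        for u in comp:
            for v in G.neighbors(u):
                if v in junction_nodes:
                    length += G[u][v]["weight"]
        seg_lengths.append(length)
    # arcs made entirely of junction-cluster pixels (tiny bridges) vanish;
    # that is the intended thick-skeleton cleanup
    seg_lengths = [L for L in seg_lengths if L >= prune_px]
    total = sum(seg_lengths) * pixel_size
    n_seg = len(seg_lengths)
    avg = total / n_seg if n_seg else 0.0
    return NetworkMetrics(
        total_length=float(total),
        n_segments=n_seg,
        average_length=float(avg),
        n_junctions=len(clusters),
    )


def _count_objects(mask: np.ndarray, min_area: int) -> int:
    mask = np.asarray(mask)
    if np.issubdtype(mask.dtype, np.integer) and mask.max() > 1:
        labels = mask
    else:
        labels = measure.label(mask.astype(bool), connectivity=2)
    return sum(1 for rp in measure.regionprops(labels) if rp.area >= min_area)


def quantify_viability(
    live_mask: np.ndarray, dead_mask: np.ndarray, min_area: int = 1
) -> float:
    """Viable fraction from two-channel particle counting:
    n_live / (n_live + n_dead), each channel's objects filtered by
    ``min_area`` (px).  Undefined (error) when both counts are zero."""
    live = np.asarray(live_mask)
    dead = np.asarray(dead_mask)
    if live.shape != dead.shape:
        raise ValidationError("live and dead masks must have the same shape")
    n_live = _count_objects(live, min_area)
    n_dead = _count_objects(dead, min_area)
    if n_live + n_dead == 0:
        raise ValidationError("no objects in either channel: viability undefined")
    return n_live / (n_live + n_dead)


def cell_circularity(
    labels: np.ndarray, pixel_size: float
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Per-cell circularity (4πA/P², clipped to [0, 1]) and a mean ± sd
    summary, reusing the droplet measurement pipeline."""
    obs = observations_from_labels(np.asarray(labels), pixel_size)
    if not obs:
        raise ValidationError("no labelled cells")
    vals = np.asarray([o.circularity for o in obs])
    summary = {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "n": int(vals.size),
    }
    return vals, summary
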