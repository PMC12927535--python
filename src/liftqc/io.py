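"""Readers and writers for masks, pattern designs and metric tables.

Supported external formats: single-plane TIFF/PNG images, 16-bit integer
label-mask TIFFs, CSV tables with a header row, and JSON documents with
unit-suffixed keys (``x_um`` etc.).
"""
from __future__ import annotations

import json
import os
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from skimage import measure

from .errors import FormatError, ValidationError
from .types import DropletObservation, PatternDesign, observation_from_geometry

__all__ = [
    "read_image",
    "write_image",
    "read_label_mask",
    "observations_from_labels",
    "read_pattern_design",
    "write_pattern_design",
    "write_metrics_table",
    "read_metrics_table",
]

_METRIC_COLUMNS = [
    "ink",
    "laser_energy_uJ",
    "ddr_mm",
    "loading_volume_uL",
    "status",
    "replicate",
    "n_main",
    "n_satellite",
    "mean_diameter_um",
    "efficiency",
    "mean_circularity",
    "satellite_score",
    "diameter_score",
    "overall",
]


def _is_tiff(path: str) -> bool:
    return os.path.splitext(str(path))[1].lower() in (".tif", ".tiff")


def read_image(path: Union[str, os.PathLike]) -> np.ndarray:
    """Read a single-plane grayscale image (TIFF or PNG)."""
    if _is_tiff(path):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # collapse RGB(A)
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise FormatError(f"expected a single-plane image, got shape {img.shape}")
    return img


def write_image(path: Union[str, os.PathLike], image: np.ndarray) -> None:
    """Write an image; label masks go to 16-bit integer TIFF."""
    image = np.asarray(image)
    if _is_tiff(path):
        import tifffile

        if np.issubdtype(image.dtype, np.integer) or image.dtype == bool:
            image = image.astype(np.uint16)
        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.astype(np.uint8))


def observations_from_labels(
    labels: np.ndarray, pixel_size: float
) -> List[DropletObservation]:
    """Measure every nonzero label of an integer mask.

    Centroid, area and perimeter are converted to µm with ``pixel_size``;
    equivalent diameter and circularity are derived from them.  Label ids
    are preserved; satellite flags start out ``False``.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0 µm/px")
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise FormatError("label mask must be a single plane")
    if not np.issubdtype(labels.dtype, np.integer):
        if np.issubdtype(labels.dtype, np.floating) and np.all(
            labels == np.round(labels)
        ):
            labels = labels.astype(np.int64)
        else:
            raise FormatError("label mask must be integer-valued")
    out: List[DropletObservation] = []
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid  # (row, col) -> (y, x)
        out.append(
            observation_from_geometry(
                label_id=rp.label,
                centroid_xy_um=(cx * pixel_size, cy * pixel_size),
                area_um2=rp.area * pixel_size**2,
                perimeter_um=rp.perimeter * pixel_size,
            )
        )
    return out


def read_label_mask(
    path: Union[str, os.PathLike], pixel_size: float
) -> List[DropletObservation]:
    """Read an integer label mask (background 0) into droplet observations.

    An all-zero mask returns an empty list; a non-integer image raises
    :class:`~liftqc.errors.FormatError`.
    """
    if _is_tiff(path):
        import tifffile

        labels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        labels = iio.imread(path)
    return observations_from_labels(np.asarray(labels), pixel_size)


def _design_from_positions(positions, nominal_spacing=None, replicates=1):
    pos = [tuple(map(float, p)) for p in positions]
    if len(pos) != len(set(pos)):
        raise ValidationError("pattern design contains duplicate positions")
    if nominal_spacing is None:
        nominal_spacing = PatternDesign.infer_spacing(np.asarray(pos))
    return PatternDesign(tuple(pos), nominal_spacing=nominal_spacing, replicates=replicates)


def read_pattern_design(path: Union[str, os.PathLike]) -> PatternDesign:
    """Read target droplet centroids (µm) from CSV (``x_um,y_um`` or
    ``x,y`` columns) or JSON (``{"positions": [[x, y], ...]}``).

    The nominal spacing is taken from the file when present, otherwise
    inferred as the modal nearest-neighbour distance.  Duplicate positions
    are a validation error.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        if "positions" not in doc:
            raise FormatError("design JSON must contain a 'positions' array")
        return _design_from_positions(
            doc["positions"],
            nominal_spacing=doc.get("nominal_spacing_um"),
            replicates=int(doc.get("replicates", 1)),
        )
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for xc, yc in (("x_um", "y_um"), ("x", "y")):
        if xc in cols and yc in cols:
            pos = df[[cols[xc], cols[yc]]].to_numpy(dtype=float)
            break
    else:
        raise FormatError("design CSV needs x_um/y_um (or x/y) columns")
    spacing = None
    if "nominal_spacing_um" in cols:
        spacing = float(df[cols["nominal_spacing_um"]].iloc[0])
    return _design_from_positions(pos, nominal_spacing=spacing)


def write_pattern_design(design: PatternDesign, path: Union[str, os.PathLike]) -> None:
    df = pd.DataFrame(design.positions_array(), columns=["x_um", "y_um"])
    if design.nominal_spacing is not None:
        df["nominal_spacing_um"] = design.nominal_spacing
    df.to_csv(path, index=False)


def write_metrics_table(
    records: Sequence[Dict[str, object]], path: Union[str, os.PathLike]
) -> None:
    """Write one row per scored (condition, replicate) to CSV.

    Each record is a flat mapping; the canonical criterion/score columns
    come first, extra provenance columns are appended verbatim.  The table
    round-trips losslessly through :func:`read_metrics_table`.
    """
    if len(records) == 0:
        raise ValidationError("cannot write an empty metrics table")
    df = pd.DataFrame(list(records))
    ordered = [c for c in _METRIC_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + extra].to_csv(path, index=False, float_format="%.12g")


def read_metrics_table(path: Union[str, os.PathLike]) -> List[Dict[str, object]]:
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError("metrics table has no rows")
    return df.to_dict(orient="records")
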