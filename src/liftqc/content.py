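"""Droplet content statistics and jetting arithmetic.

Cell encapsulation in printed droplets is Poissonian: with droplet
volume V and ink concentration C the expected cells per droplet is
λ = V·C, and P(k) = e^(−λ) λ^k / k!.  Volumes are estimated from printed
cell counts (V = N_cells / (C_ink · N_droplets)) and converted to an
equivalent spherical diameter, d = (6V/π)^(1/3).

Unit canon: volumes in nL (1 nL = 1e-6 mL = 1e6 µm³), concentrations in
cells/mL.  Conversions happen once, at the boundaries of this module.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .types import InkSpec, JetState

__all__ = [
    "ML_PER_NL",
    "UM3_PER_NL",
    "ContentModel",
    "CountHistogram",
    "estimate_droplet_volume",
    "sphere_diameter_from_volume",
    "sphere_volume_from_diameter",
    "poisson_predict",
    "PoissonFit",
    "fit_poisson",
    "classify_regime",
    "predict_pattern_cells",
    "weber_number",
    "donor_dilution",
]

ML_PER_NL = 1e-6
UM3_PER_NL = 1e6
#: Concentration separating the single-cell (low) from the multicell
#: (high) loading regime, cells/mL; the boundary itself is "low".
REGIME_BOUNDARY = 1e7


@dataclass(frozen=True)
class ContentModel:
    """Droplet volume + ink concentration → Poisson loading rate.

    ``volume_models`` optionally carries {min, avg, max} droplet volumes
    (nL) for pattern-level cell-count prediction under volume
    variability.
    """

    droplet_volume: float  # nL
    concentration: float  # cells/mL
    volume_models: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValidationError("droplet_volume must be > 0 nL")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0 cells/mL")
        if self.volume_models is not None:
            vm = dict(self.volume_models)
            missing = {"min", "avg", "max"} - vm.keys()
            if missing:
                raise ValidationError(f"volume_models missing {sorted(missing)}")
            if any(v <= 0 for v in vm.values()):
                raise ValidationError("volume_models entries must be > 0 nL")
            object.__setattr__(self, "volume_models", vm)

    @property
    def lam(self) -> float:
        """Expected cells per droplet, λ = V(mL)·C."""
        return self.droplet_volume * ML_PER_NL * self.concentration


@dataclass(frozen=True)
class CountHistogram:
    """Occurrence counts of cells-per-droplet values."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        c = {int(k): int(v) for k, v in self.counts.items()}
        if any(k < 0 for k in c) or any(v < 0 for v in c.values()):
            raise ValidationError("histogram keys and counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n_droplets(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        n = self.n_droplets
        if n == 0:
            raise ValidationError("empty histogram")
        return sum(k * v for k, v in self.counts.items()) / n

    @classmethod
    def from_counts(cls, per_droplet_counts) -> "CountHistogram":
        vals, occ = np.unique(np.asarray(per_droplet_counts, dtype=int), return_counts=True)
        return cls(dict(zip(vals.tolist(), occ.tolist())))


def estimate_droplet_volume(
    n_cells_total: int, c_ink: float, n_droplets: int
) -> float:
    """Average droplet volume (nL) from printed cell counts:
    V = N_cells / (C_ink · N_droplets).

    Works on any substrate because it relies on counting, not on droplet
    spreading.  Zero printed cells yields 0 nL with a warning.
    """
    if c_ink <= 0:
        raise ValidationError("c_ink must be > 0 cells/mL")
    if n_droplets <= 0:
        raise ValidationError("n_droplets must be > 0")
    if n_cells_total < 0:
        raise ValidationError("n_cells_total must be >= 0")
    if n_cells_total == 0:
        warnings.warn("zero printed cells: volume estimate is 0 nL", stacklevel=2)
    v_ml = n_cells_total / (c_ink * n_droplets)
    return v_ml / ML_PER_NL


def sphere_diameter_from_volume(volume_nl: float) -> float:
    """Diameter (µm) of a sphere of the given volume (nL)."""
    if volume_nl <= 0:
        raise ValidationError("volume must be > 0 nL")
    v_um3 = volume_nl * UM3_PER_NL
    return (6.0 * v_um3 / math.pi) ** (1.0 / 3.0)


def sphere_volume_from_diameter(diameter_um: float) -> float:
    """Volume (nL) of a sphere of the given diameter (µm)."""
    if diameter_um <= 0:
        raise ValidationError("diameter must be > 0 µm")
    return math.pi / 6.0 * diameter_um**3 / UM3_PER_NL


def poisson_predict(model: ContentModel, k_max: int = 10) -> Tuple[np.ndarray, float]:
    """Predicted cells-per-droplet distribution P(0..k_max) and the tail
    mass beyond ``k_max``."""
    if k_max < 0:
        raise ValidationError("k_max must be >= 0")
    k = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(k, model.lam)
    tail = float(stats.poisson.sf(k_max, model.lam))
    return pmf, tail


@dataclass(frozen=True)
class PoissonFit:
    """Result of fitting a Poisson model to an observed count histogram."""

    lambda_hat: float
    chi2: Optional[float]
    dof: Optional[int]
    p_value: Optional[float]
    degenerate: bool = False


def fit_poisson(hist: CountHistogram, min_expected: float = 5.0) -> PoissonFit:
    """MLE + chi-squared goodness of fit for Poisson loading.

    λ̂ is the sample mean.  Expected counts are pooled from the upper tail
    downwards until every bin has expectation ≥ ``min_expected``; degrees
    of freedom are bins − 2 (one parameter estimated).  Fits with fewer
    than 3 usable bins (e.g. an all-zero histogram) are flagged
    degenerate with no test statistic.
    """
    n = hist.n_droplets
    if n < 10:
        raise ValidationError("need >= 10 droplets to fit")
    lam = hist.mean
    if lam == 0:
        return PoissonFit(0.0, None, None, None, degenerate=True)

    k_obs_max = max(hist.counts)
    ks = np.arange(k_obs_max + 1)
    expected = stats.poisson.pmf(ks, lam) * n
    observed = np.array([hist.counts.get(int(k), 0) for k in ks], dtype=float)
    # open upper tail bin
    expected = np.append(expected, stats.poisson.sf(k_obs_max, lam) * n)
    observed = np.append(observed, 0.0)
    # pool from the right until every bin expectation >= min_expected
    exp_b, obs_b = [], []
    acc_e = acc_o = 0.0
    for e, o in zip(expected[::-1], observed[::-1]):
        acc_e += e
        acc_o += o
        if acc_e >= min_expected:
            exp_b.append(acc_e)
            obs_b.append(acc_o)
            acc_e = acc_o = 0.0
    if acc_e > 0 and exp_b:
        exp_b[-1] += acc_e
        obs_b[-1] += acc_o
    exp_b = np.array(exp_b[::-1])
    obs_b = np.array(obs_b[::-1])
    dof = len(exp_b) - 2
    if dof < 1:
        return PoissonFit(lam, None, None, None, degenerate=True)
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    p = float(stats.chi2.sf(chi2, dof))
    return PoissonFit(lam, chi2, dof, p)


def classify_regime(concentration: float) -> str:
    """Loading regime: ``low`` (single-cell territory) for concentrations
    ≤ 1e7 cells/mL inclusive, ``high`` (multicell) above."""
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    return "low" if concentration <= REGIME_BOUNDARY else "high"


def predict_pattern_cells(
    n_droplets: int,
    model: ContentModel,
    reference: Optional[Tuple[int, "ContentModel"]] = None,
) -> Dict[str, float]:
    """Expected total cells in a pattern under min/avg/max volume models.

    Expected cells = N_droplets · V(mL) · C for each volume model.  When
    ``reference`` (a reference pattern's droplet count and model) is
    given, every value is divided by the reference's avg-model total, so
    the reference condition reads 1.
    """
    if n_droplets < 0:
        raise ValidationError("n_droplets must be >= 0")
    if model.volume_models is None:
        raise ValidationError("model.volume_models {min, avg, max} required")
    out = {
        name: n_droplets * v * ML_PER_NL * model.concentration
        for name, v in model.volume_models.items()
    }
    if reference is not None:
        n_ref, m_ref = reference
        if m_ref.volume_models is None:
            raise ValidationError("reference model needs volume_models")
        denom = n_ref * m_ref.volume_models["avg"] * ML_PER_NL * m_ref.concentration
        if denom == 0:
            raise ValidationError("reference prediction is zero; cannot normalize")
        out = {k: v / denom for k, v in out.items()}
    return out


def weber_number(ink: InkSpec, jet: JetState) -> float:
    """Weber number We = ρ v² L / σ, the inertial to surface-tension
    force ratio that governs the jetting regime."""
    return ink.density_rho * jet.velocity**2 * jet.length_scale / ink.surface_tension_sigma


def donor_dilution(stock_c: float, stock_volume: float, diluent_volume: float) -> float:
    """Concentration after loading ``stock_volume`` µL of suspension onto
    ``diluent_volume`` µL already on the donor slide:
    C = C_stock · V_stock / (V_stock + V_diluent)."""
    if stock_c < 0:
        raise ValidationError("stock_c must be >= 0")
    if stock_volume <= 0 or diluent_volume < 0:
        raise ValidationError("volumes must be positive (diluent may be 0)")
    return stock_c * stock_volume / (stock_volume + diluent_volume)
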