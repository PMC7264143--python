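"""Clonogenic survival analysis for broad-beam and microbeam fields.

Implements the linear-quadratic (LQ) model of clonogenic survival,

    SF(D) = exp(-alpha*D - beta*D**2),

its constrained weighted least-squares fit to assay-derived survival
points, iso-survival dose inversion, the radiation enhancement ratio at
10% survival (RER10), and a two-population mixture model for spatially
fractionated microbeam fields in which a fraction ``f_peak`` of cells
sits inside the beamlets (receiving ``valley_dose * PVDR``) and the rest
sits in the valleys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear

__all__ = [
    "AssayRecord",
    "LQParams",
    "SurvivalPoint",
    "MixtureFieldSpec",
    "plating_efficiency",
    "surviving_fraction",
    "lq_survival",
    "fit_lq",
    "dose_at_survival",
    "rer",
    "mixture_survival",
]


@dataclass(frozen=True)
class AssayRecord:
    """One clonogenic assay condition: replicate dishes at a single dose.

    Colony counts are not bounded above by the seeding number (colonies
    are scored after many doubling times); only non-negativity is
    enforced.
    """

    condition: str
    dose_gy: float
    seeded: int
    colonies: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose must be >= 0 Gy, got {self.dose_gy}")
        if self.seeded < 1:
            raise ValueError(f"cells seeded must be >= 1, got {self.seeded}")
        if len(self.colonies) < 1:
            raise ValueError("at least one dish is required")
        if any(c < 0 for c in self.colonies):
            raise ValueError("colony counts must be >= 0")
        object.__setattr__(self, "colonies", tuple(float(c) for c in self.colonies))


@dataclass(frozen=True)
class LQParams:
    """Fitted linear-quadratic parameters for one treatment condition.

    alpha is the linear radiosensitivity (Gy^-1), beta the quadratic
    term (Gy^-2); both are constrained non-negative.
    """

    alpha: float
    beta: float
    alpha_se: float = 0.0
    beta_se: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.alpha_se < 0 or self.beta_se < 0:
            raise ValueError("standard errors must be >= 0")


@dataclass(frozen=True)
class SurvivalPoint:
    """Surviving fraction at one dose, with spread across replicates."""

    dose_gy: float
    sf: float
    sf_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError("dose must be >= 0")
        if not 0 < self.sf <= 1 + 1e-12:
            # SF slightly above 1 can occur by sampling noise; reject only
            # clearly invalid values. SF must be positive for the log fit.
            if self.sf <= 0:
                raise ValueError(f"surviving fraction must be > 0, got {self.sf}")
        if self.sf_sd < 0:
            raise ValueError("sf standard deviation must be >= 0")


@dataclass(frozen=True)
class MixtureFieldSpec:
    """Geometry of the two-population microbeam survival model.

    f_peak is the areal fraction of cells inside beamlets (beam width /
    pitch, 50/400 = 0.125 for the reference array); pvdr the
    peak-to-valley dose ratio.
    """

    f_peak: float = 0.125
    pvdr: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_peak <= 1:
            raise ValueError("f_peak must lie in [0, 1]")
        if self.pvdr < 1:
            raise ValueError("PVDR must be >= 1")


def plating_efficiency(record: AssayRecord) -> float:
    """Mean fraction of seeded cells forming a countable colony."""
    return float(np.mean(record.colonies)) / record.seeded


def surviving_fraction(irradiated: AssayRecord, control: AssayRecord) -> SurvivalPoint:
    """Surviving fraction: plating efficiency relative to unirradiated control.

    SF = PE_irr / PE_control. The spread is propagated from the per-dish
    scatter of both records by first-order ratio rules, with the dish
    standard deviation (not the standard error) as the input spread.

    Raises
    ------
    ValueError
        If the control plating efficiency is zero (the ratio is undefined).
    """
    pe_c = plating_efficiency(control)
    if pe_c == 0:
        raise ValueError("control plating efficiency is zero; SF undefined")
    pe_i = plating_efficiency(irradiated)
    sf = pe_i / pe_c

    def _rel_sd(rec: AssayRecord, pe: float) -> float:
        if len(rec.colonies) < 2 or pe == 0:
            return 0.0
        sd = float(np.std(rec.colonies, ddof=1)) / rec.seeded
        return sd / pe

    sf_sd = sf * math.hypot(_rel_sd(irradiated, pe_i), _rel_sd(control, pe_c))
    # Zero-survival dishes cannot enter a log-linear fit; keep SF strictly
    # positive by flooring at a vanishing value only if exactly zero.
    if sf == 0:
        raise ValueError(
            "irradiated record has zero colonies in every dish; "
            "SF = 0 cannot be represented as a survival point"
        )
    return SurvivalPoint(dose_gy=irradiated.dose_gy, sf=sf, sf_sd=sf_sd)


def lq_survival(params: LQParams, dose_gy: float) -> float:
    """LQ surviving fraction exp(-alpha*D - beta*D^2) at a dose in Gy."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    return math.exp(-params.alpha * dose_gy - params.beta * dose_gy**2)


def fit_lq(points: Sequence[SurvivalPoint], condition: str = "") -> LQParams:
    """Fit the LQ model by constrained weighted least squares.

    Regresses -ln SF on (D, D^2) with alpha, beta >= 0. Weights are
    inverse variances of ln SF obtained from the survival-point spreads
    (var(ln SF) ~= (sd/SF)^2); points without a spread get unit weight.
    Standard errors come from the weighted normal-equation covariance,
    scaled by the reduced chi-square when the spreads are absent or
    uninformative.

    Requires at least 3 points spanning at least 2 distinct positive
    doses.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 survival points to fit alpha and beta")
    doses = np.array([p.dose_gy for p in pts], dtype=float)
    sf = np.array([p.sf for p in pts], dtype=float)
    sds = np.array([p.sf_sd for p in pts], dtype=float)
    positive = doses > 0
    if len(np.unique(doses[positive])) < 2:
        raise ValueError("need >= 2 distinct positive doses to separate alpha and beta")

    y = -np.log(sf)
    A = np.column_stack([doses, doses**2])

    rel = np.divide(sds, sf, out=np.zeros_like(sds), where=sf > 0)
    have_weights = np.all(rel > 0)
    w = 1.0 / rel**2 if have_weights else np.ones_like(y)

    sw = np.sqrt(w)
    res = lsq_linear(A * sw[:, None], y * sw, bounds=(0.0, np.inf),
                     method="bvls", tol=1e-14)
    alpha, beta = res.x

    # Covariance of the (unconstrained) weighted normal equations; at an
    # active bound this is an approximation, which the reporting accepts.
    ata = (A * w[:, None]).T @ A
    try:
        cov = np.linalg.inv(ata)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by dose check
        raise ValueError("degenerate design matrix; doses do not span the model") from exc
    dof = max(len(pts) - 2, 1)
    resid = y - A @ res.x
    chi2 = float(resid @ (w * resid))
    if not have_weights:
        cov = cov * (chi2 / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return LQParams(
        alpha=float(alpha),
        beta=float(beta),
        alpha_se=float(se[0]),
        beta_se=float(se[1]),
        condition=condition,
    )


def dose_at_survival(params: LQParams, level: float) -> float:
    """Dose at which LQ survival crosses ``level`` (e.g. 0.1 for D10).

    Solves beta*D^2 + alpha*D + ln(level) = 0 for the unique positive
    root; falls back to the linear closed form when beta = 0.
    """
    if not 0 < level <= 1:
        raise ValueError("survival level must lie in (0, 1]")
    if level == 1:
        return 0.0
    if params.alpha == 0 and params.beta == 0:
        raise ValueError("alpha = beta = 0: survival never falls below 1")
    c = math.log(level)  # negative
    if params.beta == 0:
        return -c / params.alpha
    disc = params.alpha**2 - 4 * params.beta * c
    return (-params.alpha + math.sqrt(disc)) / (2 * params.beta)


def rer(reference: LQParams, test: LQParams, level: float = 0.1) -> float:
    """Radiation enhancement ratio at a survival level (default 10%).

    Ratio of the reference-treatment dose to the test-treatment dose
    required to reach the same survival; > 1 means the test treatment is
    more lethal per Gy.
    """
    return dose_at_survival(reference, level) / dose_at_survival(test, level)


def mixture_survival(
    bb: LQParams, field_spec: MixtureFieldSpec, valley_dose_gy: float
) -> float:
    """Two-population survival of a microbeam field at a valley dose.

    Cells in the valleys (fraction 1 - f_peak) survive as a broad beam
    at the valley dose; cells inside beamlets see valley_dose * PVDR:

        SF = (1 - f_peak) * SF_bb(Dv) + f_peak * SF_bb(Dv * PVDR)
    """
    if valley_dose_gy < 0:
        raise ValueError("valley dose must be >= 0")
    return (1.0 - field_spec.f_peak) * lq_survival(bb, valley_dose_gy) + (
        field_spec.f_peak * lq_survival(bb, valley_dose_gy * field_spec.pvdr)
    )
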