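"""Modified von Bertalanffy growth: prediction and per-sex least squares.

Body length follows

    SVL(t) = SVL_max - (SVL_max - SVL_met) * exp(-k * (t - t_met))

an asymptotic rise from the size at metamorphosis SVL_met (reached at
age t_met, in years) toward the asymptotic maximum SVL_max, at rate k
(per year). Fitting holds the metamorphosis anchor (SVL_met, t_met)
fixed — here the published population values 12.7 mm and 0.3 yr — and
estimates only (SVL_max, k) by nonlinear least squares, so two free
parameters can be supported even by small skeletochronological samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .records import LifeStage, Sex, StudyDataset

__all__ = [
    "GrowthParams",
    "GrowthFit",
    "InsufficientDataError",
    "DEFAULT_SVL_MET",
    "DEFAULT_T_MET",
    "vb_predict",
    "vb_fit",
    "fit_by_sex",
]

DEFAULT_SVL_MET = 12.7  # mm, mean size of newly metamorphosed froglets
DEFAULT_T_MET = 0.3  # yr, age at metamorphosis


class InsufficientDataError(ValueError):
    """Fewer distinct ages than free parameters + 1."""


@dataclass(frozen=True)
class GrowthParams:
    svl_max: float
    k: float
    svl_met: float = DEFAULT_SVL_MET
    t_met: float = DEFAULT_T_MET

    def __post_init__(self) -> None:
        if not (self.svl_max > self.svl_met > 0):
            raise ValueError(f"need svl_max > svl_met > 0, got {self.svl_max}, {self.svl_met}")
        if not self.k > 0:
            raise ValueError(f"growth rate k must be > 0, got {self.k}")
        if self.t_met < 0:
            raise ValueError(f"t_met must be >= 0, got {self.t_met}")


@dataclass(frozen=True)
class GrowthFit:
    params: GrowthParams
    rss: float
    n_obs: int
    converged: bool
    se: tuple[float, float] | None  # (se_svl_max, se_k), when computable


def vb_predict(params: GrowthParams, t):
    """Predicted SVL (mm) at age(s) ``t`` years; requires t >= t_met.

    Accepts a scalar or array and returns the same shape; the curve is
    strictly increasing in t and bounded in [svl_met, svl_max).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < params.t_met):
        raise ValueError(f"ages below t_met = {params.t_met} are outside the model domain")
    # anchored form: algebraically identical to
    # svl_max - (svl_max - svl_met)·exp(-k(t - t_met)) but exact at t = t_met
    out = params.svl_met + (params.svl_max - params.svl_met) * (
        -np.expm1(-params.k * (t_arr - params.t_met))
    )
    return out if out.ndim else float(out)


def vb_fit(
    ages,
    svls,
    svl_met: float = DEFAULT_SVL_MET,
    t_met: float = DEFAULT_T_MET,
    init: tuple[float, float] | None = None,
) -> GrowthFit:
    """Least-squares fit of (svl_max, k) with the metamorphosis anchor fixed.

    Parameters
    ----------
    ages, svls : array-like
        Paired observations (years, mm); at least 3 distinct ages, all
        >= ``t_met``.
    init : (svl_max0, k0), optional
        Starting point; defaults to 1.1 × max observed SVL and 0.2/yr.

    Deterministic given data and init. A fit that stops without meeting
    the optimizer tolerance is returned with ``converged=False`` rather
    than raised.
    """
    ages = np.asarray(ages, dtype=float)
    svls = np.asarray(svls, dtype=float)
    if ages.shape != svls.shape or ages.ndim != 1:
        raise ValueError("ages and svls must be equal-length 1-D sequences")
    if np.unique(ages).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct ages to fit (svl_max, k), got {np.unique(ages).size}"
        )
    if np.any(ages < t_met):
        raise ValueError(f"all ages must be >= t_met = {t_met}")

    if init is None:
        init = (1.1 * float(svls.max()), 0.2)
    x0 = np.clip(
        np.asarray(init, dtype=float),
        [svl_met + 1e-6, 1e-6],
        [np.inf, 10.0],
    )

    def residuals(theta):
        svl_max, k = theta
        pred = svl_max - (svl_max - svl_met) * np.exp(-k * (ages - t_met))
        return pred - svls

    sol = least_squares(
        residuals,
        x0,
        bounds=([svl_met + 1e-9, 1e-9], [np.inf, 10.0]),
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
    )
    rss = float(np.sum(sol.fun**2))
    se = None
    n = ages.size
    if n > 2:
        # asymptotic SEs from the Jacobian at the solution
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / (n - 2))
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = (float(np.sqrt(diag[0])), float(np.sqrt(diag[1])))
        except np.linalg.LinAlgError:
            se = None
    params = GrowthParams(float(sol.x[0]), float(sol.x[1]), svl_met, t_met)
    return GrowthFit(params=params, rss=rss, n_obs=int(n), converged=bool(sol.success), se=se)


_MEASURED_STAGES = (LifeStage.ADULT, LifeStage.SUBADULT, LifeStage.JUVENILE)


def fit_by_sex(
    dataset: StudyDataset,
    svl_met: float = DEFAULT_SVL_MET,
    t_met: float = DEFAULT_T_MET,
    init: tuple[float, float] | None = None,
) -> dict[Sex, GrowthFit]:
    """Independent growth fits for males and females.

    All life stages with a measured age and SVL enter each sex's fit
    (juveniles of unknown sex enter neither). A sex without enough
    distinct ages is omitted with a warning; the k ordering between
    sexes is left to the caller/report layer.
    """
    fits: dict[Sex, GrowthFit] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        recs = [r for r in dataset if r.sex == sex and r.life_stage in _MEASURED_STAGES]
        ages = [r.age_years for r in recs]
        svls = [r.svl_mm for r in recs]
        try:
            fits[sex] = vb_fit(ages, svls, svl_met=svl_met, t_met=t_met, init=init)
        except (InsufficientDataError, ValueError) as exc:
            warnings.warn(f"growth fit skipped for {sex.name.lower()}: {exc}", stacklevel=2)
    return fits
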