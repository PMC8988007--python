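"""Phase-diagram assembly and saturation-concentration estimation.

The saturation concentration c_sat of a phase-separating protein is estimated
from settled-condensate volume versus total protein concentration: above
c_sat the settled volume grows linearly with concentration, so the
x-intercept of an ordinary least-squares fit over the conditions with
measurable volume estimates c_sat. Reentrant behavior (condensation rising
then falling as DNA is titrated) is classified from replicate-mean volumes,
and the dilute-phase scaling of a tagged protein discriminates
single-component (homotypic) from multicomponent (heterotypic) condensation.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .synthetic import DILUTE_MODELS
from .types import CsatFit, DiluteSeries, PhaseDiagram

__all__ = [
    "fit_csat",
    "min_visible_concentration",
    "classify_reentrance",
    "fit_dilute_models",
    "local_concentration",
    "InsufficientDataError",
    "NoTrendError",
]

AVOGADRO = 6.02214076e23


class InsufficientDataError(ValueError):
    """Too few usable conditions for the requested fit."""


class NoTrendError(ValueError):
    """Settled volume does not increase with concentration."""


def fit_csat(
    volumes: list[tuple[float, float]],
    min_detectable: float = 0.0,
) -> CsatFit:
    """Saturation concentration from the x-intercept of a linear volume fit.

    Parameters
    ----------
    volumes : list of (concentration μM, total settled volume per area)
        One entry per field/replicate; replicates at the same concentration
        are kept as separate points.
    min_detectable : float
        Conditions at or below this volume are treated as "no measurable
        condensates" and excluded from the regression.

    Returns
    -------
    CsatFit with c_sat = −intercept/slope and its standard error from the
    delta method applied to the OLS coefficient covariance.
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("volumes must be (conc, volume) pairs")
    usable = arr[arr[:, 1] > min_detectable]
    if len(usable) < 3 or len(np.unique(usable[:, 0])) < 3:
        raise InsufficientDataError(
            f"need >= 3 conditions with volume above {min_detectable}, "
            f"got {len(np.unique(usable[:, 0])) if len(usable) else 0}"
        )
    conc, vol = usable[:, 0], usable[:, 1]
    X = sm.add_constant(conc)
    fit = sm.OLS(vol, X).fit()
    b0, b1 = fit.params
    if b1 <= 0:
        raise NoTrendError(
            "settled volume does not increase with concentration; "
            "no phase-separation trend to extrapolate"
        )
    c_sat = -b0 / b1
    cov = np.asarray(fit.cov_params())
    # delta method for f = -b0/b1: grad = (-1/b1, b0/b1²)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ cov @ grad)
    se = np.sqrt(max(var, 0.0))
    return CsatFit(
        c_sat=float(c_sat),
        c_sat_se=float(se),
        slope=float(b1),
        intercept=float(b0),
        fit_range=(float(conc.min()), float(conc.max())),
        n_points=len(usable),
    )


def min_visible_concentration(
    volumes: list[tuple[float, float]],
    min_detectable: float = 0.0,
) -> float | None:
    """Lowest tested concentration with measurable condensate volume.

    Used when too few conditions phase-separate for a regression; returns
    ``None`` when no condition qualifies.
    """
    arr = np.asarray(volumes, dtype=float)
    visible = arr[arr[:, 1] > min_detectable]
    if len(visible) == 0:
        return None
    return float(visible[:, 0].min())


def classify_reentrance(
    diagram: PhaseDiagram,
    axis: str = "dna_conc",
) -> str:
    """Classify volume response along the DNA axis at fixed protein.

    Returns one of ``reentrant``, ``monotone_increase``, ``monotone_decrease``
    or ``flat``. Reentrance requires an interior maximum of the replicate-mean
    volume exceeding both endpoints by more than the pooled replicate SD;
    monotone labels require Spearman |ρ| ≥ 0.8 on the means with the matching
    sign. The classification is invariant to uniform volume rescaling.
    """
    if axis != "dna_conc":
        raise ValueError("only the DNA-concentration axis is supported")
    pts = diagram.points
    if pts["protein_conc_uM"].nunique() > 1:
        raise ValueError("mixed protein concentrations; fix protein to classify")
    grouped = pts.groupby("dna_conc_uM")["volume_per_area_um"]
    means = grouped.mean()
    if len(means) < 4:
        raise InsufficientDataError("need >= 4 DNA concentrations")
    order = means.sort_index()
    y = order.to_numpy()
    x = order.index.to_numpy()
    sds = grouped.std(ddof=1).dropna()
    pooled_sd = float(np.sqrt((sds**2).mean())) if len(sds) else 0.0
    i_max = int(np.argmax(y))
    if 0 < i_max < len(y) - 1:
        if (y[i_max] - y[0] > pooled_sd) and (y[i_max] - y[-1] > pooled_sd):
            return "reentrant"
    if np.allclose(y, y[0]):
        return "flat"
    rho = stats.spearmanr(x, y).statistic
    if rho >= 0.8:
        return "monotone_increase"
    if rho <= -0.8:
        return "monotone_decrease"
    return "flat"


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC with small-sample correction
    if rss <= 0:
        rss = 1e-300
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / denom


_MODEL_SETUP = {
    # name -> (param names, bounds, start generator)
    "homotypic": (
        ("c_star", "endogenous"),
        ([0.0, 0.0], [np.inf, np.inf]),
        lambda c_tot, c_dil, u: (
            np.quantile(c_dil, 0.5 + 0.4 * u[0]) * (1 + u[1]),
            0.1 + 3 * u[2],
        ),
    ),
    "heterotypic": (
        ("A", "K"),
        ([0.0, 1e-6], [np.inf, np.inf]),
        lambda c_tot, c_dil, u: (
            (c_tot.max() - c_dil.max()) * (0.5 + u[0]),
            c_tot.max() * (0.1 + u[1]),
        ),
    ),
}


def fit_dilute_models(
    series: DiluteSeries,
    n_starts: int = 5,
    seed: int = 0,
    delta_aicc: float = 2.0,
) -> DiluteSeries:
    """Fit both dilute-phase scaling models and select by AICc.

    Both registered models (homotypic buffering with an endogenous-protein
    offset; heterotypically stabilized sublinear scaling) are fitted by
    nonlinear least squares from ``n_starts`` seeded starting points; the
    model with the lower small-sample-corrected information criterion wins,
    with |ΔAICc| < ``delta_aicc`` declared ``indeterminate``.
    """
    c_tot, c_dil = series.c_tot, series.c_dil
    n = len(c_tot)
    if n < 6:
        raise InsufficientDataError("need >= 6 (c_tot, c_dil) points")
    if c_tot.max() < 3 * max(c_tot.min(), 1e-12):
        raise InsufficientDataError("c_tot must span at least a 3-fold range")
    rng = np.random.default_rng(seed)
    results: dict[str, float] = {}
    rsses: dict[str, float] = {}
    params: dict[str, dict[str, float]] = {}
    # below this, a model reproduces the data to numerical precision and
    # information criteria carry no evidence
    rss_floor = n * (1e-8 * max(np.abs(c_dil).max(), 1.0)) ** 2
    for name, model in DILUTE_MODELS.items():
        pnames, (lb, ub), starts = _MODEL_SETUP[name]
        best_rss, best_p = np.inf, None
        for _ in range(n_starts):
            u = rng.uniform(0, 1, 3)
            p0 = np.clip(starts(c_tot, c_dil, u), lb, ub)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        model, c_tot, c_dil, p0=p0, bounds=(lb, ub),
                        maxfev=5000,
                    )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((model(c_tot, *popt) - c_dil) ** 2))
            if rss < best_rss:
                best_rss, best_p = rss, popt
        if best_p is None:
            continue
        rsses[name] = best_rss
        results[name] = _aicc(max(best_rss, rss_floor), n, len(pnames))
        params[name] = dict(zip(pnames, map(float, best_p)))
    if not results:
        raise RuntimeError("neither dilute-phase model converged")
    if len(results) == 1:
        selected = next(iter(results))
    elif all(r <= rss_floor for r in rsses.values()):
        # both models reproduce the data exactly (e.g. c_tot below the
        # homotypic threshold, where the models coincide)
        selected = "indeterminate"
    else:
        ranked = sorted(results, key=results.get)
        selected = (
            "indeterminate"
            if abs(results[ranked[0]] - results[ranked[1]]) < delta_aicc
            else ranked[0]
        )
    return DiluteSeries(
        c_tot=c_tot, c_dil=c_dil, fitted_model=selected,
        criterion=results, fit_params=params,
    )


def local_concentration(n_molecules: float, radius: float) -> float:
    """Concentration (μM) of ``n_molecules`` in a sphere of ``radius`` μm.

    c = n / (N_A · V); 1 μm³ = 1e-15 L. E.g. ~1,000 protein copies confined
    to a 100 nm-radius punctum correspond to ~400 μM.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    volume_l = 4.0 / 3.0 * np.pi * radius**3 * 1e-15
    molar = n_molecules / (AVOGADRO * volume_l)
    return molar * 1e6
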