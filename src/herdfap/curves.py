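"""Herd-level lactation and somatic-cell curves and per-cow relative levels.

Milk (energy-corrected, kg/day) follows a Wood-type curve extended with a
pregnancy decline, one parameter set per (herd, parity group):

    f_ECM(t) = alpha_m * a * t^b * exp(-(c + I_P d (t - t_P)) * t)

where ``t`` is days in milk, ``I_P`` indicates pregnancy and ``t_P`` the
conception day.  The flattened typesetting of this curve admits a second
reading in which the pregnancy term is not multiplied by ``t``; both are
implemented (``parse='literal'`` default, ``'additive'`` alternative) and the
choice is carried in the parameter objects and the serialized model.

Total somatic cells (tSCC = SCC * milk) follow a Wilmink-inspired
double-exponential, fitted on the log scale:

    f_tSCC(t) = exp( exp(alpha_c * a + b t) + d exp(-exp(c) t) - e )

with ``e`` Euler's number (absorbable into ``a``).  The cow's level
``alpha_c`` sits inside the inner exponential, so small deviations from 1
translate to large multiplicative tSCC differences; the inverse mapping
:func:`invert_scc_level` recovers a per-record level estimate used by the
exponential-smoothing machinery.

Each cow is reduced to one level per quantity per lactation (``alpha_m``,
``alpha_c``), relative to the herd-average cow: herd parameters are fitted
first with all levels fixed at 1, then the individual levels with herd
parameters fixed.  At least six test days are required to fit a level;
lactations below that keep the default level 1 (or a dam-derived prior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import DomainError, FitError, InsufficientDataError

logger = logging.getLogger(__name__)

_EULER = float(np.e)
#: clamp for the log-scale tSCC exponent; triggering it is logged
_LOG_TSCC_MAX = 80.0

MILK_PARSES = ("literal", "additive")
SCC_PARSES = ("nested",)


@dataclass
class MilkCurveParams:
    """Wood-type ECM curve parameters for one (herd, parity group)."""

    a: float
    b: float
    c: float
    d: float
    parity_group: str = "1"
    parse: str = "literal"


@dataclass
class SccCurveParams:
    """Double-exponential tSCC curve parameters for one (herd, parity group)."""

    a: float
    b: float
    c: float
    d: float
    parity_group: str = "1"
    parse: str = "nested"


@dataclass
class FittedLevel:
    """One fitted cow level (one quantity, one lactation)."""

    alpha: float
    n_points: int
    fittable: bool
    sse: float = float("nan")


@dataclass
class FitDiagnostics:
    converged: bool
    residual_sd: float
    n_records: int
    n_lactations: int
    cost: float = float("nan")


def eval_milk_curve(params: MilkCurveParams, alpha_m, dim, pregnant=False, dim_p=None):
    """Evaluate the ECM curve (kg/day); strictly proportional to ``alpha_m``.

    ``pregnant``/``dim_p`` may be scalars or arrays; the pregnancy decline is
    active only for days at or after conception (the term is clamped at zero
    before ``dim_p``).
    """
    t = np.asarray(dim, dtype=float)
    if (t == 0).any() and params.b < 0:
        raise DomainError("dim = 0 with b < 0 is singular")
    ip = np.asarray(pregnant, dtype=bool)
    tp = np.zeros_like(t) if dim_p is None else np.asarray(dim_p, dtype=float)
    tp = np.where(ip, tp, 0.0)
    preg_days = np.where(ip, np.maximum(t - tp, 0.0), 0.0)
    if params.parse == "literal":
        expo = -(params.c + params.d * preg_days) * t
    elif params.parse == "additive":
        expo = -params.c * t - params.d * preg_days
    else:  # pragma: no cover - guarded at construction
        raise ValueError(f"unknown milk parse {params.parse!r}")
    with np.errstate(divide="ignore"):
        out = np.asarray(alpha_m, dtype=float) * params.a * t**params.b * np.exp(expo)
    return float(out) if out.ndim == 0 else out


def log_scc_curve(params: SccCurveParams, alpha_c, dim):
    """log f_tSCC(t): exp(alpha*a + b t) + d exp(-exp(c) t) - e, clamped."""
    t = np.asarray(dim, dtype=float)
    inner = np.asarray(alpha_c, dtype=float) * params.a + params.b * t
    wil = params.d * np.exp(-np.exp(params.c) * t)
    out = np.exp(np.minimum(inner, np.log(_LOG_TSCC_MAX * 4))) + wil - _EULER
    clipped = out > _LOG_TSCC_MAX
    if np.any(clipped):
        # routine during optimizer exploration of extreme levels
        logger.debug("log-tSCC exponent clamped for %d point(s)", int(np.sum(clipped)))
        out = np.minimum(out, _LOG_TSCC_MAX)
    return out


def eval_scc_curve(params: SccCurveParams, alpha_c, dim):
    """Evaluate the tSCC curve ((x1000 cells/mL)*kg); strictly positive."""
    out = np.exp(log_scc_curve(params, alpha_c, dim))
    return float(out) if out.ndim == 0 else out


def invert_milk_level(params: MilkCurveParams, ecm, dim, pregnant=False, dim_p=None):
    """Per-record relative milk level: observed ECM / herd-average curve."""
    base = eval_milk_curve(params, 1.0, dim, pregnant, dim_p)
    return np.asarray(ecm, dtype=float) / base


def invert_scc_level(params: SccCurveParams, tscc, dim):
    """Per-record Eq.-level alpha_c estimate from one observed tSCC.

    Solves ``log tscc = exp(alpha*a + b t) + d exp(-exp(c) t) - e`` for alpha.
    Returns NaN where the observation is outside the curve's range (the
    argument of the outer log would be non-positive).
    """
    t = np.asarray(dim, dtype=float)
    y = np.log(np.asarray(tscc, dtype=float))
    g = y + _EULER - params.d * np.exp(-np.exp(params.c) * t)
    with np.errstate(invalid="ignore"):
        out = np.where(g > 0, (np.log(np.maximum(g, 1e-300)) - params.b * t) / params.a, np.nan)
    return float(out) if out.ndim == 0 else out


def _milk_p0(dim, y):
    b0, c0, d0 = 0.2, 0.002, 1e-6
    shape = dim**b0 * np.exp(-c0 * dim)
    a0 = max(np.mean(y) / max(np.mean(shape), 1e-9), 1e-3)
    return np.array([a0, b0, c0, d0])


def _scc_p0(dim, logy):
    med = np.median(logy)
    a0 = np.log(max(med + _EULER, 1.1))
    return np.array([a0, 0.0, -3.0, 1.0])


def fit_herd_curve(
    df,
    family: str,
    min_lactations: int = 20,
    parse: str = "literal",
    n_starts: int = 5,
    seed: int = 0,
    parity_group: str = "1",
    fixed_d: float | None = None,
):
    """Fit the herd-average curve for one (herd, parity group).

    All cow levels are held at 1; milk is fitted on the natural scale, tSCC
    on the log scale (variance stabilisation).  Uses trust-region least
    squares with ``n_starts`` multi-starts from perturbed Wood-type initial
    values.

    For milk, ``fixed_d`` freezes the pregnancy-decline rate at a given
    value (e.g. an across-herd estimate) and fits only (a, b, c): within a
    single herd most records come from pregnant cows, so the baseline decay
    and the pregnancy decline are nearly collinear and the unconstrained
    non-pregnant curve level is poorly determined.

    Parameters
    ----------
    df : DataFrame
        Derived records (needs ``dim``, ``ecm_kg`` or ``tscc``, ``pregnant``,
        ``dim_p``, ``cow_id``, ``parity``) for one herd and parity group.
    family : {'milk', 'scc'}

    Returns
    -------
    (params, FitDiagnostics)

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_lactations`` distinct cow-lactations.
    FitError
        No start converged; carries the best attempt.
    """
    n_lact = df.groupby(["cow_id", "parity"]).ngroups
    if n_lact < min_lactations:
        raise InsufficientDataError(
            f"{n_lact} lactation(s) in group, need {min_lactations}"
        )
    dim = df["dim"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    if family == "milk":
        y = df["ecm_kg"].to_numpy(dtype=float)
        preg = df["pregnant"].to_numpy(dtype=bool)
        dim_p = df["dim_p"].fillna(0.0).to_numpy(dtype=float)
        p0 = _milk_p0(dim, y)
        lb = np.array([1e-3, -1.0, -0.01, -1e-4])
        ub = np.array([1e4, 2.0, 0.05, 1e-3])
        if fixed_d is not None:
            p0, lb, ub = p0[:3], lb[:3], ub[:3]

            def resid(p):
                par = MilkCurveParams(*p, fixed_d, parity_group=parity_group, parse=parse)
                return eval_milk_curve(par, 1.0, dim, preg, dim_p) - y

            make = lambda p: MilkCurveParams(
                *p, fixed_d, parity_group=parity_group, parse=parse
            )
        else:

            def resid(p):
                par = MilkCurveParams(*p, parity_group=parity_group, parse=parse)
                return eval_milk_curve(par, 1.0, dim, preg, dim_p) - y

            make = lambda p: MilkCurveParams(*p, parity_group=parity_group, parse=parse)
    elif family == "scc":
        y = np.log(df["tscc"].to_numpy(dtype=float))
        p0 = _scc_p0(dim, y)
        lb = np.array([0.5, -0.02, -8.0, -5.0])
        ub = np.array([5.0, 0.02, 0.0, 10.0])

        def resid(p):
            par = SccCurveParams(*p, parity_group=parity_group)
            return log_scc_curve(par, 1.0, dim) - y

        make = lambda p: SccCurveParams(*p, parity_group=parity_group)
    else:
        raise ValueError(f"unknown family {family!r}")

    best = None
    for k in range(n_starts):
        start = p0 if k == 0 else np.clip(
            p0 * rng.normal(1.0, 0.2, size=p0.size)
            + rng.normal(0.0, 0.05, size=p0.size) * (ub - lb) / 10,
            lb,
            ub,
        )
        try:
            sol = least_squares(resid, start, bounds=(lb, ub), method="trf", max_nfev=2000)
        except Exception:  # numerical failure on this start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(f"all {n_starts} starts failed for {family} herd curve")
    params = make(best.x)
    diag = FitDiagnostics(
        converged=bool(best.success),
        residual_sd=float(np.std(best.fun)),
        n_records=len(df),
        n_lactations=int(n_lact),
        cost=float(best.cost),
    )
    if not best.success:
        raise FitError(f"{family} herd curve did not converge", best_params=params)
    return params, diag


def fit_cow_level(
    df,
    params,
    family: str,
    min_points: int = 6,
    default_alpha: float = 1.0,
) -> FittedLevel:
    """Fit one cow-lactation's relative level with herd parameters fixed.

    Milk: closed-form least-squares ratio (the level scales the curve
    linearly).  tSCC: one-dimensional least squares on the log scale (the
    level sits inside the exponent).  Lactations with fewer than
    ``min_points`` records are not fitted and keep ``default_alpha``
    (1, or a dam-derived prior supplied by the caller).
    """
    n = len(df)
    if n < min_points:
        return FittedLevel(alpha=default_alpha, n_points=n, fittable=False)
    dim = df["dim"].to_numpy(dtype=float)
    if family == "milk":
        y = df["ecm_kg"].to_numpy(dtype=float)
        if not np.any(y > 0):
            raise DomainError("all milk records are zero")
        f1 = eval_milk_curve(
            params,
            1.0,
            dim,
            df["pregnant"].to_numpy(dtype=bool),
            df["dim_p"].fillna(0.0).to_numpy(dtype=float),
        )
        alpha = float(np.sum(y * f1) / np.sum(f1 * f1))
        sse = float(np.sum((y - alpha * f1) ** 2))
        return FittedLevel(alpha=alpha, n_points=n, fittable=True, sse=sse)
    if family == "scc":
        logy = np.log(df["tscc"].to_numpy(dtype=float))

        def sse_of(alpha):
            return float(np.sum((log_scc_curve(params, alpha, dim) - logy) ** 2))

        sol = minimize_scalar(sse_of, bounds=(0.01, 3.0), method="bounded")
        return FittedLevel(
            alpha=float(sol.x), n_points=n, fittable=True, sse=float(sol.fun)
        )
    raise ValueError(f"unknown family {family!r}")
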