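"""Temporal machinery: inter-lactation correlations, survival, smoothing.

Three questions about a cow's future are answered here:

* *How does her level carry over to the next lactation?*  Deviations from
  the herd-average level regress toward 1 between lactations:
  ``alpha_l - 1 = xi * (alpha_j - 1)`` with ``xi`` the no-intercept
  regression slope of later on earlier deviations (typical value ~0.3).

* *Will she reach another lactation at all?*  The probability of surviving
  to at least one further lactation, as a function of days open, is a
  generalised-logistic (Richards) decay

      S(t) = A - A / [1 + (2^nu - 1) exp(-B (t - M))]^(1/nu)

  which equals A/2 at t = M, approaches A for small days open and 0 for very
  large days open.  Given survival past lactation j, the distribution of the
  final lactation reached is the fraction vector ``gamma`` (sums to 1).

* *What is her current level?*  Each test-day record yields a noisy relative
  level; exponential smoothing ``x~_t = lambda x_t + (1 - lambda) x~_{t-1}``
  tracks it.  The smoothing constant is estimated by a grid search
  minimising the squared distance between the smoothed value at each time
  point and the mean of all future observations of the same cow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ZeroVarianceError


@dataclass
class SurvivalParams:
    """Richards-decay survival parameters for one (herd, parity group[, yield group])."""

    A: float
    B: float
    nu: float
    M: float
    parity_group: str = "1"
    yield_group: str = "alpha_ge_1"


@dataclass
class SmoothedLevel:
    """State of one exponentially smoothed relative level."""

    value: float
    lam: float
    n_updates: int = 0


def predict_next_alpha(alpha, xi):
    """Level carried to a future lactation: ``1 + xi * (alpha - 1)``."""
    return 1.0 + xi * (np.asarray(alpha, dtype=float) - 1.0)


def fit_correlation(alpha_from, alpha_to) -> float:
    """No-intercept regression slope of (alpha_to - 1) on (alpha_from - 1).

    Raises :class:`ZeroVarianceError` when the predictor deviations are all
    zero, and :class:`InsufficientDataError` on empty input.
    """
    x = np.asarray(alpha_from, dtype=float) - 1.0
    y = np.asarray(alpha_to, dtype=float) - 1.0
    if len(x) == 0:
        raise InsufficientDataError("no lactation pairs")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ZeroVarianceError("predictor deviations are identically zero")
    return float(np.sum(x * y) / sxx)


def eval_survival(params: SurvivalParams, dim_open):
    """Probability of at least one further lactation at the given days open."""
    t = np.asarray(dim_open, dtype=float)
    z = np.exp(np.clip(-params.B * (t - params.M), -500, 500))
    out = params.A - params.A / (1.0 + (2.0**params.nu - 1.0) * z) ** (1.0 / params.nu)
    return float(out) if out.ndim == 0 else out


def fit_survival(
    days_open,
    survived,
    bin_width: float = 30.0,
    parity_group: str = "1",
    yield_group: str = "alpha_ge_1",
    n_starts: int = 5,
    seed: int = 0,
) -> SurvivalParams:
    """Least-squares fit of the Richards decay to empirical survival fractions.

    Days open are binned (width ``bin_width``); the fraction surviving in
    each bin is fitted weighted by the square root of the bin count.
    """
    t = np.asarray(days_open, dtype=float)
    s = np.asarray(survived, dtype=float)
    if len(t) < 10:
        raise InsufficientDataError(f"{len(t)} outcomes, need >= 10")
    edges = np.arange(t.min(), t.max() + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.array([t.min(), (t.min() + t.max()) / 2, t.max() + 1e-9])
    idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    keep = counts > 0
    frac = np.bincount(idx, weights=s, minlength=len(edges) - 1)[keep] / counts[keep]
    mid = (0.5 * (edges[:-1] + edges[1:]))[keep]
    w = np.sqrt(counts[keep].astype(float))

    if np.all(s == 1):  # degenerate: nobody is culled over the observed range
        return SurvivalParams(
            A=1.0, B=0.1, nu=1.0, M=float(t.max() + 1000.0),
            parity_group=parity_group, yield_group=yield_group,
        )

    lb = np.array([0.2, 5e-4, 0.2, 0.0])
    ub = np.array([1.0, 0.2, 5.0, 600.0])
    a0 = min(float(frac.max()) * 1.05, 1.0)
    # initial midpoint: where the empirical fraction crosses half its maximum
    below = mid[frac <= a0 / 2]
    m0 = float(below.min()) if len(below) else float(mid.max())
    p0 = np.clip(np.array([a0, 0.01, 1.0, m0]), lb, ub)
    rng = np.random.default_rng(seed)

    def resid(p):
        par = SurvivalParams(*p)
        return w * (eval_survival(par, mid) - frac)

    best = None
    for k in range(n_starts):
        start = p0 if k == 0 else np.clip(p0 * rng.normal(1.0, 0.25, size=4), lb, ub)
        try:
            sol = least_squares(resid, start, bounds=(lb, ub), method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all survival fit starts failed")
    params = SurvivalParams(
        *best.x, parity_group=parity_group, yield_group=yield_group
    )
    if not best.success:
        raise FitError("survival fit did not converge", best_params=params)
    return params


def fit_gamma(final_parities, n_max: int = 8) -> dict:
    """Distribution of the final lactation reached, from completed histories.

    Parameters
    ----------
    final_parities : array-like of int
        The final parity reached by each cow whose full history is known.
    n_max : int
        Horizon; mass beyond ``n_max`` is folded into ``n_max``.

    Returns
    -------
    dict
        ``{j: {l: fraction}}`` for each from-parity ``j``: among cows that
        survived past ``j`` (final parity > j), the normalised distribution
        of their final parity ``l`` in ``(j, n_max]``.
    """
    fp = np.minimum(np.asarray(final_parities, dtype=int), n_max)
    if len(fp) == 0:
        raise InsufficientDataError("no completed histories")
    out = {}
    for j in range(1, n_max):
        beyond = fp[fp > j]
        if len(beyond) == 0:
            continue
        ls, cnt = np.unique(beyond, return_counts=True)
        out[j] = {int(l): float(c) / len(beyond) for l, c in zip(ls, cnt)}
    return out


def fit_gamma_censored(parity, survived, censored, n_max: int = 8) -> dict:
    """Censoring-aware gamma via product-limit continuation probabilities.

    Each row is one cow-lactation: its ``parity``, whether the cow reached a
    further lactation (``survived``), and whether the outcome is unknown
    because the observation window ended first (``censored``).  Per-parity
    continuation probabilities are estimated from uncensored lactations and
    the final-parity distribution assembled from them, mass beyond ``n_max``
    folded into ``n_max``.
    """
    p = np.asarray(parity, dtype=int)
    s = np.asarray(survived, dtype=bool)
    c = np.asarray(censored, dtype=bool)
    use = ~c
    if not use.any():
        raise InsufficientDataError("no uncensored lactation outcomes")
    cont = {}
    last = None
    for j in range(1, n_max):
        m = use & (p == j)
        if m.sum() >= 5:
            cont[j] = float(s[m].mean())
            last = cont[j]
        else:
            cont[j] = last if last is not None else float(s[use].mean())
    out = {}
    for j in range(1, n_max):
        gam, reach = {}, 1.0
        for l in range(j + 1, n_max):
            # reach = P(final >= l | survived past j); stop at l w.p. (1 - cont_l)
            gam[l] = reach * (1.0 - cont[l])
            reach *= cont[l]
        gam[n_max] = reach
        out[j] = gam
    return out


def update_smoothed(state: SmoothedLevel, x_t: float) -> SmoothedLevel:
    """One exponential-smoothing update: ``lam * x_t + (1 - lam) * value``."""
    if not 0.0 <= state.lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    return replace(
        state,
        value=state.lam * float(x_t) + (1.0 - state.lam) * state.value,
        n_updates=state.n_updates + 1,
    )


def smooth_series(xs, lam: float, x0: float = 1.0) -> np.ndarray:
    """Smoothed value after each observation of ``xs`` (vectorised helper)."""
    xs = np.asarray(xs, dtype=float)
    out = np.empty_like(xs)
    v = x0
    for i, x in enumerate(xs):
        v = lam * x + (1.0 - lam) * v
        out[i] = v
    return out


def estimate_lambda(sequences, grid=None, x0: float = 1.0):
    """Grid-search estimate of the smoothing constant.

    For every sequence and every time point with a nonempty future, the
    objective accumulates ``(smoothed value so far - mean of all future
    observations)**2``; the grid value minimising the total is returned.

    Parameters
    ----------
    sequences : iterable of 1-d arrays
        Per-cow relative-level series in time order (>= 3 points each;
        shorter sequences are ignored).
    grid : array, optional
        Candidate lambdas; default 0.00, 0.01, ..., 1.00.

    Returns
    -------
    (lam, sse) : float and the objective evaluated on the grid.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    sse = np.zeros_like(grid)
    used = 0
    for xs in sequences:
        xs = np.asarray(xs, dtype=float)
        xs = xs[np.isfinite(xs)]
        T = len(xs)
        if T < 3:
            continue
        used += 1
        # future means: fut[n] = mean(xs[n+1:]) for n = 0..T-2
        rev_cum = np.cumsum(xs[::-1])[::-1]
        fut = (rev_cum[1:] ) / np.arange(T - 1, 0, -1)
        v = np.full_like(grid, x0)
        for n in range(T - 1):
            v = grid * xs[n] + (1.0 - grid) * v
            sse += (v - fut[n]) ** 2
    if used == 0:
        raise InsufficientDataError("no usable sequences (need >= 3 points)")
    return float(grid[int(np.argmin(sse))]), sse
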