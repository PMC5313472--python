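"""Assembling the future average production (FAP) of a cow.

The expected remaining life of a cow is a mixture of life courses: she
finishes the current lactation and is either culled at dry-off or survives
(probability ``S`` at her current days open) to further lactations, with
the final lactation reached distributed as ``gamma``.  Each course has a
total production (daily predicted PVM summed over days in milk) and a total
duration (milking days plus dry periods), and FAP is the survival-weighted
mean of production per day alive:

    FAP = (1 - S) FAP_C
          + S * sum_{l=j+1}^{n} gamma_jl *
            (FP_C + sum_{m=j+1}^{l} FP_m^F) / (T_RC + (l - j) T_S)

* ``FP_C``: predicted PVM summed over the remaining current lactation, from
  the cow's DIM to her predicted last day in milk ``DIM_L`` (conception day
  + gestation - dry period for pregnant cows; for open cows the maximum of
  that rule applied at the expected conception day, never less than the
  standard 61 + 282 - 56 = 287).
* ``T_RC = DIM_L - DIM + dry``: remaining time in the current parity,
  including the dry period.
* ``FP_m^F``: a future lactation's production, summed over the standard
  lactation (day 3 to 287) with the cow's smoothed levels shrunk toward 1
  by the inter-lactation correlations ``xi``.
* ``T_S = gestation + days-to-conception = 343``: standard parity duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelIncompleteError
from .pricing import predict_pvm_curve


@dataclass
class ReproConstants:
    """Reproduction calendar constants (days)."""

    gestation: int = 282
    dry_period: int = 56
    days_to_conception: int = 61
    n_max_future_lactations: int = 8
    #: standard parity duration; defaults to gestation + days_to_conception
    t_s: int | None = None
    #: if True, predict the current-lactation remainder and future lactations
    #: with the pregnancy decline active from the (assumed) conception day;
    #: default keeps the curve at the cow's actual recorded pregnancy state
    #: and evaluates hypothetical future lactations without a pregnancy term
    assume_future_conception: bool = False

    def __post_init__(self):
        if self.t_s is None:
            self.t_s = self.gestation + self.days_to_conception
        for name in ("gestation", "dry_period", "days_to_conception",
                     "n_max_future_lactations", "t_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def standard_dim_l(self) -> int:
        """Last day in milk of a standard lactation: 61 + 282 - 56 = 287."""
        return self.days_to_conception + self.gestation - self.dry_period


@dataclass
class CowState:
    """A cow's state at one prediction date."""

    cow_id: str
    herd_id: str
    parity: int
    dim: int
    pregnant: bool
    dim_p: float | None
    alpha_m_tilde: float
    alpha_c_tilde: float


@dataclass
class FAPResult:
    """FAP and every intermediate term for one cow-day."""

    dim_l: int
    fp_c: float
    fap_c: float
    fp_f: dict = field(default_factory=dict)
    fap_f: dict = field(default_factory=dict)
    survival: float = 0.0
    gamma: dict = field(default_factory=dict)
    fap: float = 0.0


def predict_dim_l(state: CowState, constants: ReproConstants) -> int:
    """Predicted last day in milk of the current lactation.

    Pregnant: ``dim_p + gestation - dry``.  Open: ``max(dim + gestation -
    dry, 61 + gestation - dry)`` (the cow is assumed to conceive at the
    standard day or, if already past it, immediately).
    """
    g_minus_dry = constants.gestation - constants.dry_period
    if state.pregnant:
        return int(round(state.dim_p + g_minus_dry))
    return int(max(state.dim + g_minus_dry,
                   constants.days_to_conception + g_minus_dry))


def _pg(model, parity: int) -> str:
    return "3+" if parity >= 3 else str(parity)


def _pvm_days(model, parity, t, alpha_m, alpha_c, pregnant, dim_p):
    pg = _pg(model, parity)
    try:
        mp = model.milk_curves[pg]
        sp = model.scc_curves[pg]
    except KeyError as exc:
        raise ModelIncompleteError(f"no fitted curves for parity group {pg}") from exc
    return predict_pvm_curve(
        t, mp, sp, alpha_m, alpha_c, model.bulk, model.scheme,
        pregnant=pregnant, dim_p=dim_p,
    )


def fap_current(state: CowState, model, constants: ReproConstants | None = None):
    """(FP_C, FAP_C): production and average over the remaining current lactation."""
    c = constants or model.constants
    dim_l = predict_dim_l(state, c)
    t_rc = max(dim_l - state.dim, 0) + c.dry_period
    if state.dim > dim_l:
        warnings.warn("prediction day past predicted dry-off; FP_C = 0")
        return 0.0, 0.0, dim_l, t_rc
    t = np.arange(state.dim, dim_l + 1, dtype=float)
    if c.assume_future_conception:
        dim_p = state.dim_p if state.pregnant else dim_l - (c.gestation - c.dry_period)
        pvm = _pvm_days(model, state.parity, t, state.alpha_m_tilde,
                        state.alpha_c_tilde, True, float(dim_p))
    else:
        pvm = _pvm_days(model, state.parity, t, state.alpha_m_tilde,
                        state.alpha_c_tilde, state.pregnant,
                        state.dim_p if state.pregnant else None)
    fp_c = float(np.sum(pvm))
    return fp_c, fp_c / t_rc, dim_l, t_rc


def fap_future(state: CowState, model, l: int, constants: ReproConstants | None = None):
    """(FP_jl^F, FAP_jl^F): a future lactation's production over the standard calendar.

    The smoothed levels are shrunk toward 1 by the (possibly chained)
    correlation between lactation ``state.parity`` and ``l`` before the
    standard-lactation sum from day 3 to 287.
    """
    c = constants or model.constants
    j = state.parity
    if l <= j:
        raise ValueError("future lactation must exceed current parity")
    if l > c.n_max_future_lactations:
        raise ValueError(
            f"lactation {l} exceeds horizon {c.n_max_future_lactations}"
        )
    xi_m = model.xi(j, l, "milk")
    xi_c = model.xi(j, l, "scc")
    am = 1.0 + xi_m * (state.alpha_m_tilde - 1.0)
    ac = 1.0 + xi_c * (state.alpha_c_tilde - 1.0)
    t = np.arange(3, c.standard_dim_l + 1, dtype=float)
    if c.assume_future_conception:
        pvm = _pvm_days(model, l, t, am, ac, True, float(c.days_to_conception))
    else:
        pvm = _pvm_days(model, l, t, am, ac, False, None)
    fp = float(np.sum(pvm))
    return fp, fp / c.t_s


def fap(state: CowState, model, constants: ReproConstants | None = None) -> FAPResult:
    """Survival-weighted future average production for one cow-day.

    Survival is evaluated at the cow's days open: her current DIM when open,
    her conception day when pregnant (she stopped being open at conception).
    """
    c = constants or model.constants
    j = state.parity
    fp_c, fap_c, dim_l, t_rc = fap_current(state, model, c)
    n = c.n_max_future_lactations

    if j >= n:
        s = 0.0
        gam = {}
    else:
        surv = model.survival_for(_pg(model, j))
        from .dynamics import eval_survival

        days_open = state.dim_p if state.pregnant else state.dim
        s = float(eval_survival(surv, float(days_open)))
        gam = model.gamma_for(j)
        if gam is None:
            raise ModelIncompleteError(f"no gamma distribution for parity {j}")

    res = FAPResult(dim_l=dim_l, fp_c=fp_c, fap_c=fap_c, survival=s, gamma=dict(gam) if j < n else {})
    if s == 0.0:
        res.fap = fap_c
        return res

    future_fp = {}
    for m in range(j + 1, n + 1):
        fp_m, fap_m = fap_future(state, model, m, c)
        future_fp[m] = fp_m
        res.fp_f[m] = fp_m
        res.fap_f[m] = fap_m

    total = (1.0 - s) * fap_c
    cum = 0.0
    for l in range(j + 1, n + 1):
        w = gam.get(l, 0.0)
        cum += future_fp[l]
        if w == 0.0:
            continue
        total += s * w * (fp_c + cum) / (t_rc + (l - j) * c.t_s)
    res.fap = total
    return res


def fap_table(records: pd.DataFrame, model,
              constants: ReproConstants | None = None, since=None) -> pd.DataFrame:
    """Per cow-day FAP for the records of one herd.

    Smooths the per-record relative levels through the herd curves first
    (:func:`herdfap.model.smooth_cow_levels`), then evaluates :func:`fap`
    at each test day.  Returns one row per input record with the cow state,
    FAP and its main components.  ``since`` restricts the output to test
    days at or after that date while still smoothing over the full history.
    """
    from .model import smooth_cow_levels

    c = constants or model.constants
    sm = smooth_cow_levels(records, model)
    if since is not None:
        sm = sm[sm["test_date"] >= pd.Timestamp(since)]
    rows = []
    for r in sm.itertuples():
        state = CowState(
            cow_id=r.cow_id, herd_id=r.herd_id, parity=int(r.parity),
            dim=int(r.dim), pregnant=bool(r.pregnant),
            dim_p=float(r.dim_p) if np.isfinite(r.dim_p) else None,
            alpha_m_tilde=float(r.alpha_m_tilde), alpha_c_tilde=float(r.alpha_c_tilde),
        )
        res = fap(state, model, c)
        rows.append({
            "herd_id": r.herd_id, "cow_id": r.cow_id, "test_date": r.test_date,
            "parity": state.parity, "dim": state.dim, "pregnant": state.pregnant,
            "alpha_m_tilde": state.alpha_m_tilde, "alpha_c_tilde": state.alpha_c_tilde,
            "dim_l": res.dim_l, "fp_c": res.fp_c, "fap_c": res.fap_c,
            "survival": res.survival, "fap": res.fap,
        })
    return pd.DataFrame(rows)
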