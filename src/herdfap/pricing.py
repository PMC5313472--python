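"""Production value of milk: bulk-tank SCC pricing correction.

Danish milk processors pay a percentage correction on the milk price driven
by the bulk-tank somatic cell count (SCC_B), in stepwise bands (e.g. +2%
below 200,000 cells/mL, -4% between 400,000 and 500,000).  Because a price
change is equivalent to a yield change of the same percentage, corrections
are kept in percent of kg milk.

A single cow moves the bulk tank only marginally, and less so in a large
herd.  Her production value of milk (PVM, kg/day) is therefore her ECM plus
the whole-herd price effect of *removing* her from the tank:

    PVM_c = ECM_c + [f(SCC_B) - f(SCC_B + Delta_c SCC_B)] * Sum_i ECM_i

where ``Delta_c SCC_B`` is the bulk SCC without the cow minus with her
(negative for a high-cell cow), and ``f`` is the pricing step function made
continuous by linear interpolation through the band-midpoint anchors, with
linear extrapolation beyond the outermost anchors, so that every marginal
change has a price impact.

Prediction-time PVM (:func:`predict_pvm_curve`) evaluates the same formula
with curve-predicted ECM and tSCC for the cow while the herd's bulk SCC and
totals are frozen at their training-period values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: Default pricing bands as (upper SCC bound x1000/mL, correction %); the
#: first band starts at 0.  The +2% (below 200) and -4% (400-500) anchors
#: follow the published Danish scheme; the intermediate bands are a
#: configurable convention.
DEFAULT_PRICE_STEPS = [(200.0, 2.0), (300.0, 0.0), (400.0, -2.0), (500.0, -4.0)]


@dataclass
class PriceScheme:
    """Continuous, non-increasing SCC_B -> % price correction."""

    anchors_scc: np.ndarray
    anchors_pct: np.ndarray
    steps: list = field(default_factory=list)

    def correction(self, scc_b):
        """Percent price correction at bulk SCC ``scc_b`` (x1000 cells/mL)."""
        x = np.asarray(scc_b, dtype=float)
        xs, ys = self.anchors_scc, self.anchors_pct
        out = np.interp(x, xs, ys)
        if len(xs) > 1:
            lo = x < xs[0]
            hi = x > xs[-1]
            out = np.where(
                lo, ys[0] + (ys[1] - ys[0]) / (xs[1] - xs[0]) * (x - xs[0]), out
            )
            out = np.where(
                hi, ys[-1] + (ys[-1] - ys[-2]) / (xs[-1] - xs[-2]) * (x - xs[-1]), out
            )
        return float(out) if out.ndim == 0 else out


def build_price_function(steps=None) -> PriceScheme:
    """Build the interpolated scheme from ordered (upper bound, percent) bands.

    Anchors are placed at band midpoints; corrections must be non-increasing
    and bounds strictly increasing.
    """
    if steps is None:
        steps = DEFAULT_PRICE_STEPS
    uppers = np.asarray([u for u, _ in steps], dtype=float)
    pcts = np.asarray([p for _, p in steps], dtype=float)
    if np.any(np.diff(uppers) <= 0):
        raise DomainError("band upper bounds must be strictly increasing")
    if np.any(np.diff(pcts) > 0):
        raise DomainError("price corrections must be non-increasing in SCC")
    lowers = np.concatenate([[0.0], uppers[:-1]])
    mids = 0.5 * (lowers + uppers)
    return PriceScheme(anchors_scc=mids, anchors_pct=pcts, steps=list(steps))


@dataclass
class BulkOperatingPoint:
    """Frozen herd-day bulk-tank state used during prediction."""

    scc_b: float          # milk-weighted bulk SCC, x1000 cells/mL
    total_milk: float     # kg raw milk per test day
    total_ecm: float      # kg ECM per test day


def bulk_scc(scc, milk):
    """Milk-weighted mean SCC of a herd day."""
    milk = np.asarray(milk, dtype=float)
    tot = milk.sum()
    if tot <= 0:
        raise DomainError("zero total milk on herd day")
    return float(np.sum(np.asarray(scc, dtype=float) * milk) / tot)


def delta_bulk_scc(index_c: int, scc, milk):
    """Change in bulk SCC when cow ``index_c`` is removed from the herd day.

    ``scc`` and ``milk`` are the herd-day arrays *including* the cow.
    Negative when the cow's SCC exceeds the milk-weighted bulk mean.  For a
    single-cow herd the bulk without the cow is defined as 0, giving
    ``-scc_c``.
    """
    scc = np.asarray(scc, dtype=float)
    milk = np.asarray(milk, dtype=float)
    if milk.sum() <= 0:
        raise DomainError("zero total milk on herd day")
    with_cow = np.sum(scc * milk) / milk.sum()
    rest_milk = milk.sum() - milk[index_c]
    if rest_milk <= 0:
        return float(-with_cow)
    without = (np.sum(scc * milk) - scc[index_c] * milk[index_c]) / rest_milk
    return float(without - with_cow)


def compute_pvm(index_c: int, scc, milk, ecm, scheme: PriceScheme):
    """Realized PVM (kg/day) of cow ``index_c`` on one herd day."""
    ecm = np.asarray(ecm, dtype=float)
    if len(ecm) == 0:
        raise DomainError("empty herd day")
    sb = bulk_scc(scc, milk)
    delta = delta_bulk_scc(index_c, scc, milk)
    corr = (scheme.correction(sb) - scheme.correction(sb + delta)) / 100.0
    return float(ecm[index_c] + corr * ecm.sum())


def compute_pvm_day(scc, milk, ecm, scheme: PriceScheme):
    """Vectorised realized PVM for every cow of one herd day."""
    scc = np.asarray(scc, dtype=float)
    milk = np.asarray(milk, dtype=float)
    ecm = np.asarray(ecm, dtype=float)
    if len(ecm) == 0:
        raise DomainError("empty herd day")
    tot_milk = milk.sum()
    if tot_milk <= 0:
        raise DomainError("zero total milk on herd day")
    tcells = np.sum(scc * milk)
    sb = tcells / tot_milk
    rest_milk = tot_milk - milk
    with np.errstate(divide="ignore", invalid="ignore"):
        without = np.where(
            rest_milk > 0, (tcells - scc * milk) / np.where(rest_milk > 0, rest_milk, 1.0), 0.0
        )
    delta = without - sb
    corr = (scheme.correction(sb) - scheme.correction(sb + delta)) / 100.0
    return ecm + corr * ecm.sum()


def predict_pvm_curve(
    t,
    milk_params,
    scc_params,
    alpha_m,
    alpha_c,
    bulk: BulkOperatingPoint,
    scheme: PriceScheme,
    pregnant=False,
    dim_p=None,
):
    """Predicted PVM (kg/day) at days in milk ``t`` for one cow.

    The cow's ECM and tSCC come from the herd curves at her smoothed levels;
    the herd's bulk SCC and totals stay at the frozen training-period
    operating point.  Predicted ECM is converted to a raw-milk proxy with
    the herd's ECM/milk ratio before entering the bulk-mixing delta, and
    tSCC back to SCC per mL by dividing by that milk.  Days with zero
    predicted milk get PVM 0.
    """
    from .curves import eval_milk_curve, eval_scc_curve  # local import, no cycle at module load

    t = np.asarray(t, dtype=float)
    ecm_t = np.atleast_1d(eval_milk_curve(milk_params, alpha_m, t, pregnant, dim_p))
    tscc_t = np.atleast_1d(eval_scc_curve(scc_params, alpha_c, t))
    ecm_per_milk = bulk.total_ecm / bulk.total_milk if bulk.total_milk > 0 else 1.0
    milk_t = ecm_t / ecm_per_milk
    ok = milk_t > 0
    scc_t = np.zeros_like(milk_t)
    scc_t[ok] = tscc_t[ok] / milk_t[ok]

    rest = np.maximum(bulk.total_milk - milk_t, 1e-9)
    without = (bulk.scc_b * bulk.total_milk - scc_t * milk_t) / rest
    delta = without - bulk.scc_b
    corr = (scheme.correction(bulk.scc_b) - scheme.correction(bulk.scc_b + delta)) / 100.0
    pvm = np.where(ok, ecm_t + corr * bulk.total_ecm, 0.0)
    return pvm if np.ndim(t) else float(pvm[0])
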