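"""Seeded synthetic herd-recording datasets with known ground truth.

The generator emulates the structure of national milk-recording data:
herds are tested 6 or 11 times per year; at each test every lactating cow
contributes milk kg, fat %, protein %, SCC and reproduction status.  Cows
carry a persistent multiplicative milk level (N(1, 0.4) around the herd
curve) and a lognormal tSCC level (median 1, log-sd 0.385, i.e. a ~0.4
multiplicative spread), both with AR(1) carry-over (coefficient xi = 0.3)
between lactations.  Conception day is drawn as 21 + Gamma(1.3, 30.77) days
(mean 61); survival to a further lactation is Bernoulli with the Richards
decay evaluated at the conception day; culled cows are replaced by fresh
heifers so herd size stays roughly constant.

Default herd-curve parameters are calibrated so per-parity mean ECM lands
at typical Holstein herd medians (25.7 / 29.1 / 30.3 kg for parities
1 / 2 / 3+) — a realism calibration, not a fit.  Everything is reproducible
from the config seed, and the emitted records come with a
:class:`TruthBundle` holding every latent quantity for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .curves import MilkCurveParams, SccCurveParams, eval_milk_curve, eval_scc_curve
from .dynamics import SurvivalParams, eval_survival
from .errors import ConfigError
from .io import CANONICAL_COLUMNS, ECM_FAT, ECM_INTERCEPT, ECM_PROTEIN

#: Target 305-day mean ECM per parity group (kg/day), typical herd medians.
TARGET_MEAN_ECM = {"1": 25.7, "2": 29.1, "3+": 30.3}

_WOOD_B, _WOOD_C, _PREG_D = 0.17, 0.002, 3.0e-6
_SCC_DEFAULTS = {  # inner-exp level a per parity group; SCC rises with parity
    "1": 2.25, "2": 2.32, "3+": 2.36,
}
_SCC_B, _SCC_C, _SCC_D = 0.0005, -2.8, 1.5

# One survival law for all parities: the fraction of cows reaching a further
# lactation declines with days open from ~0.73 (conception at the voluntary
# waiting period) through A/2 at 145 d; gives parity proportions near the
# typical 0.40/0.28/0.17/0.15 split.
DEFAULT_SURVIVAL = {
    pg: SurvivalParams(A=0.93, B=0.0120, nu=1.3, M=145.0, parity_group=pg)
    for pg in ("1", "2", "3+")
}


def _calibrated_milk_curves() -> dict:
    """Wood curves whose 305-day mean hits the per-parity ECM targets."""
    t = np.arange(1, 306, dtype=float)
    shape_mean = float(np.mean(t**_WOOD_B * np.exp(-_WOOD_C * t)))
    return {
        pg: MilkCurveParams(
            a=TARGET_MEAN_ECM[pg] / shape_mean, b=_WOOD_B, c=_WOOD_C, d=_PREG_D,
            parity_group=pg,
        )
        for pg in TARGET_MEAN_ECM
    }


def _default_scc_curves() -> dict:
    return {
        pg: SccCurveParams(a=a, b=_SCC_B, c=_SCC_C, d=_SCC_D, parity_group=pg)
        for pg, a in _SCC_DEFAULTS.items()
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic herds."""

    n_herds: int = 1
    cows_per_herd: int = 100
    years: float = 4.0
    tests_per_year: int = 11
    start_date: date = date(2006, 1, 1)
    seed: int = 12345

    alpha_m_sd: float = 0.4          # milk level spread around 1
    alpha_m_min: float = 0.05   # physiological floor; almost never binds
    log_level_c_sd: float = 0.385    # lognormal tSCC level, median 1, sd ~0.4
    xi_milk: float = 0.3             # AR(1) carry-over between lactations
    xi_scc: float = 0.3
    ecm_noise_sd: float = 2.0        # test-day ECM noise, kg
    log_tscc_noise_sd: float = 0.3

    conception_shift: float = 21.0   # voluntary waiting period, days
    conception_shape: float = 1.3    # Gamma shape/scale: mean 61 d overall
    conception_scale: float = 30.77
    gestation: int = 282
    dry_period: int = 56
    max_parity: int = 8
    min_dim_recorded: int = 5

    fat_mean: float = 4.2
    fat_sd: float = 0.25
    protein_mean: float = 3.4
    protein_sd: float = 0.12

    milk_curves: dict = field(default_factory=_calibrated_milk_curves)
    scc_curves: dict = field(default_factory=_default_scc_curves)
    survival: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL))

    def validate(self) -> None:
        if self.tests_per_year not in (6, 11):
            raise ConfigError("tests_per_year must be 6 or 11")
        for name in ("n_herds", "cows_per_herd", "years"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("alpha_m_sd", "log_level_c_sd", "ecm_noise_sd",
                     "log_tscc_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class TruthBundle:
    """Latent ground truth matching the emitted records."""

    config: GeneratorConfig
    lactations: pd.DataFrame   # one row per cow-lactation with true levels & fate
    milk_curves: dict
    scc_curves: dict
    survival: dict


def _pg(parity: int) -> str:
    return "3+" if parity >= 3 else str(parity)


def _draw_alpha_m(rng, prev, cfg):
    if prev is None:
        a = rng.normal(1.0, cfg.alpha_m_sd)
    else:
        sd = cfg.alpha_m_sd * np.sqrt(max(1.0 - cfg.xi_milk**2, 0.0))
        a = 1.0 + cfg.xi_milk * (prev - 1.0) + rng.normal(0.0, sd)
    return float(max(a, cfg.alpha_m_min))


def _draw_log_level_c(rng, prev, cfg):
    if prev is None:
        return float(rng.normal(0.0, cfg.log_level_c_sd))
    sd = cfg.log_level_c_sd * np.sqrt(max(1.0 - cfg.xi_scc**2, 0.0))
    return float(cfg.xi_scc * prev + rng.normal(0.0, sd))


def _draw_dim_p(rng, cfg) -> int:
    return int(round(cfg.conception_shift
                     + rng.gamma(cfg.conception_shape, cfg.conception_scale)))


def simulate_herds(config: GeneratorConfig | None = None):
    """Generate records and ground truth for ``config.n_herds`` herds.

    Returns
    -------
    (records, truth) : DataFrame in the canonical recording schema (sorted
    by herd, cow, date) and the matching :class:`TruthBundle`.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_date)
    horizon = int(round(cfg.years * 365.25))
    test_days = np.round(np.arange(0, horizon, 365.25 / cfg.tests_per_year)).astype(int)

    # steady-state-ish initial parity distribution from the survival defaults
    mean_s = {pg: float(np.mean([eval_survival(cfg.survival[pg], _draw_dim_p(rng, cfg))
                                 for _ in range(200)]))
              for pg in cfg.survival}
    w, probs = 1.0, []
    for p in range(1, cfg.max_parity + 1):
        probs.append(w)
        w *= mean_s[_pg(p)]
    probs = np.array(probs) / np.sum(probs)

    rec_rows, lact_rows = [], []
    for h in range(cfg.n_herds):
        herd_id = f"H{h + 1:03d}"
        cow_counter = 0
        active = []  # (cow_id, parity, calving_day, alpha_m, logL_c, dim_p, survives)

        def new_lactation(cow_id, parity, calving_day, prev_am, prev_lc):
            am = _draw_alpha_m(rng, prev_am, cfg)
            lc = _draw_log_level_c(rng, prev_lc, cfg)
            dim_p = _draw_dim_p(rng, cfg)
            s = eval_survival(cfg.survival[_pg(parity)], float(dim_p))
            survives = bool(rng.random() < s) and parity < cfg.max_parity
            return [cow_id, parity, calving_day, am, lc, dim_p, survives]

        for _ in range(cfg.cows_per_herd):
            cow_counter += 1
            parity = int(rng.choice(np.arange(1, cfg.max_parity + 1), p=probs))
            dim0 = int(rng.integers(cfg.min_dim_recorded, 320))
            lac = new_lactation(f"{herd_id}C{cow_counter:04d}", parity, -dim0, None, None)
            active.append(lac)

        while active:
            lac = active.pop()
            cow_id, parity, calving, am, lc, dim_p, survives = lac
            dim_l = dim_p + cfg.gestation - cfg.dry_period
            lact_rows.append({
                "herd_id": herd_id, "cow_id": cow_id, "parity": parity,
                "calving_day": calving, "alpha_m": am, "log_level_c": lc,
                "dim_p": dim_p, "dim_l": dim_l, "survived": survives,
            })
            days = test_days[(test_days >= calving + cfg.min_dim_recorded)
                             & (test_days <= calving + dim_l)]
            if len(days):
                dim = (days - calving).astype(float)
                pg = _pg(parity)
                preg = dim >= dim_p
                ecm_true = eval_milk_curve(cfg.milk_curves[pg], am, dim, preg,
                                           np.full_like(dim, float(dim_p)))
                ecm_obs = np.maximum(
                    ecm_true + rng.normal(0.0, cfg.ecm_noise_sd, len(dim)), 0.5
                )
                fat = np.maximum(rng.normal(cfg.fat_mean, cfg.fat_sd, len(dim)), 2.0)
                prot = np.maximum(rng.normal(cfg.protein_mean, cfg.protein_sd, len(dim)), 2.0)
                milk = ecm_obs / (ECM_FAT * fat + ECM_PROTEIN * prot + ECM_INTERCEPT)
                tscc = (np.exp(lc) * eval_scc_curve(cfg.scc_curves[pg], 1.0, dim)
                        * np.exp(rng.normal(0.0, cfg.log_tscc_noise_sd, len(dim))))
                scc = tscc / milk
                for k in range(len(dim)):
                    rec_rows.append((
                        herd_id, cow_id, start + pd.Timedelta(days=int(days[k])),
                        parity, int(dim[k]), float(milk[k]), float(fat[k]),
                        float(prot[k]), float(scc[k]), bool(preg[k]),
                        float(dim_p) if preg[k] else np.nan, None,
                    ))
            next_calving = calving + dim_p + cfg.gestation
            if next_calving < horizon:
                if survives:
                    active.append(new_lactation(cow_id, parity + 1, next_calving, am, lc))
                else:  # replacement heifer enters at the culled cow's exit
                    cow_counter += 1
                    active.append(new_lactation(
                        f"{herd_id}C{cow_counter:04d}", 1, next_calving, None, None,
                    ))

    records = pd.DataFrame(rec_rows, columns=CANONICAL_COLUMNS)
    records = records.sort_values(["herd_id", "cow_id", "test_date"], kind="mergesort")
    records = records.reset_index(drop=True)
    truth = TruthBundle(
        config=cfg,
        lactations=pd.DataFrame(lact_rows),
        milk_curves=dict(cfg.milk_curves),
        scc_curves=dict(cfg.scc_curves),
        survival=dict(cfg.survival),
    )
    return records, truth


def train_test_split(records: pd.DataFrame, split_date, min_cows_per_test: float = 50.0):
    """Partition records at ``split_date``; cows may span both halves.

    Herds whose training period averages fewer than ``min_cows_per_test``
    lactating cows per test date are excluded from both halves (pass
    ``min_cows_per_test=0`` to keep everything).
    """
    split = pd.Timestamp(split_date)
    train = records[records["test_date"] < split]
    test = records[records["test_date"] >= split]
    if min_cows_per_test > 0 and len(train):
        per_herd = train.groupby("herd_id").apply(
            lambda g: g.groupby("test_date")["cow_id"].nunique().mean(),
            include_groups=False,
        )
        keep = set(per_herd[per_herd >= min_cows_per_test].index)
        train = train[train["herd_id"].isin(keep)]
        test = test[test["herd_id"].isin(keep)]
    return train.reset_index(drop=True), test.reset_index(drop=True)
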