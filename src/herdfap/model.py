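"""The fitted HerdModel: per-herd parameters and the fitting pipeline.

Fitting one herd proceeds bottom-up:

1. derive ECM/tSCC per record and flag fittable cow-lactations (>= 6 points);
2. fit the herd-average milk and tSCC curves per parity group (1, 2, 3+)
   with all cow levels fixed at 1;
3. fit each fittable cow-lactation's relative levels (alpha_m, alpha_c)
   with herd parameters fixed;
4. regress consecutive-lactation level deviations to get the correlations
   xi (per parity step, pooled across steps as fallback);
5. fit the survival decay per parity group on cows at or above herd-average
   milk level (below-average cows are culled for reasons beyond days open);
6. estimate gamma (final-lactation distribution) with censoring-aware
   product-limit continuation probabilities;
7. estimate the smoothing constants lambda (milk, scc) by grid search on
   per-record relative-level sequences;
8. freeze the bulk-tank operating point (milk-weighted bulk SCC, total milk
   and ECM per test day, averaged over training test days).

The model serializes to YAML, round-tripping floats exactly (shortest-repr),
with the curve-parse conventions recorded in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import curves as _curves
from . import dynamics as _dyn
from . import io as _io
from .engine import ReproConstants
from .errors import InsufficientDataError, ModelIncompleteError
from .pricing import (
    DEFAULT_PRICE_STEPS,
    BulkOperatingPoint,
    PriceScheme,
    build_price_function,
)

PARITY_GROUPS = ("1", "2", "3+")


@dataclass
class FitConfig:
    """Knobs of the fitting pipeline (defaults follow the method's conventions)."""

    min_points: int = 6            # test days needed to fit a cow level
    min_lactations: int = 20       # lactations needed to fit a herd curve
    min_pairs: int = 10            # pairs needed for a per-step xi estimate
    survival_bin_width: float = 30.0
    #: binary outcomes needed before a stratum gets its own 4-parameter
    #: survival fit; below this the pooled (all-parity) fit is used
    min_survival_outcomes: int = 150
    #: usable outcomes a herd needs before its own survival/gamma estimates
    #: are trusted; below this, multi-herd fits (fit_models) substitute the
    #: across-herd pooled estimates.  Single-herd fits are unaffected.
    min_herd_outcomes_own_dynamics: int = 400
    #: estimate one smoothing constant across herds (the default); per-herd
    #: lambdas apply only when fitting a single herd in isolation
    global_lambda: bool = True
    milk_parse: str = "literal"
    n_starts: int = 5
    seed: int = 0
    price_steps: list = field(default_factory=lambda: list(DEFAULT_PRICE_STEPS))
    constants: ReproConstants = field(default_factory=ReproConstants)
    dam_xi: float = 0.3            # dam->offspring level correlation for priors


@dataclass
class HerdModel:
    """Everything fitted for one herd, sufficient to compute FAP."""

    herd_id: str
    milk_curves: dict            # parity_group -> MilkCurveParams
    scc_curves: dict             # parity_group -> SccCurveParams
    xi_milk: dict                # parity step j -> slope (j = 1, 2, 3 meaning 3+)
    xi_scc: dict
    survival: dict               # parity_group -> SurvivalParams
    gamma: dict                  # from-parity j -> {final parity l: weight}
    lambda_milk: float
    lambda_scc: float
    bulk: BulkOperatingPoint
    scheme: PriceScheme
    constants: ReproConstants = field(default_factory=ReproConstants)
    metadata: dict = field(default_factory=dict)

    # -- accessors -----------------------------------------------------
    def _xi_step(self, m: int, family: str) -> float:
        table = self.xi_milk if family == "milk" else self.xi_scc
        key = min(m, 3)
        if key in table:
            return table[key]
        if "pooled" in table:
            return table["pooled"]
        raise ModelIncompleteError(f"no xi estimate for parity step {m} ({family})")

    def xi(self, j: int, l: int, family: str) -> float:
        """Correlation between lactations j and l; chained product of the
        per-step estimates when l > j + 1."""
        out = 1.0
        for m in range(j, l):
            out *= self._xi_step(m, family)
        return out

    def survival_for(self, parity_group: str):
        try:
            return self.survival[parity_group]
        except KeyError as exc:
            raise ModelIncompleteError(
                f"no survival fit for parity group {parity_group}"
            ) from exc

    def gamma_for(self, j: int):
        return self.gamma.get(j)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def _py(obj):
            if isinstance(obj, dict):
                return {k: _py(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_py(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.bool_):
                return bool(obj)
            return obj

        return _py({
            "herd_id": self.herd_id,
            "milk_curves": {k: asdict(v) for k, v in self.milk_curves.items()},
            "scc_curves": {k: asdict(v) for k, v in self.scc_curves.items()},
            "xi_milk": {str(k): v for k, v in self.xi_milk.items()},
            "xi_scc": {str(k): v for k, v in self.xi_scc.items()},
            "survival": {k: asdict(v) for k, v in self.survival.items()},
            "gamma": {int(j): {int(l): w for l, w in g.items()} for j, g in self.gamma.items()},
            "lambda_milk": self.lambda_milk,
            "lambda_scc": self.lambda_scc,
            "bulk": asdict(self.bulk),
            "price_steps": [[float(u), float(p)] for u, p in self.scheme.steps],
            "constants": asdict(self.constants),
            "metadata": self.metadata,
        })

    @classmethod
    def from_dict(cls, d: dict) -> "HerdModel":
        def _xi(t):
            return {("pooled" if k == "pooled" else int(k)): v for k, v in t.items()}

        return cls(
            herd_id=d["herd_id"],
            milk_curves={k: _curves.MilkCurveParams(**v) for k, v in d["milk_curves"].items()},
            scc_curves={k: _curves.SccCurveParams(**v) for k, v in d["scc_curves"].items()},
            xi_milk=_xi(d["xi_milk"]),
            xi_scc=_xi(d["xi_scc"]),
            survival={k: _dyn.SurvivalParams(**v) for k, v in d["survival"].items()},
            gamma={int(j): {int(l): w for l, w in g.items()} for j, g in d["gamma"].items()},
            lambda_milk=d["lambda_milk"],
            lambda_scc=d["lambda_scc"],
            bulk=BulkOperatingPoint(**d["bulk"]),
            scheme=build_price_function([tuple(s) for s in d["price_steps"]]),
            constants=ReproConstants(**d["constants"]),
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "HerdModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------


def _fit_cow_levels(df: pd.DataFrame, milk_curves, scc_curves, cfg: FitConfig) -> pd.DataFrame:
    rows = []
    for (cow, parity), g in df.groupby(["cow_id", "parity"], sort=False):
        pg = "3+" if parity >= 3 else str(parity)
        lm = _curves.fit_cow_level(g, milk_curves[pg], "milk", cfg.min_points)
        lc = _curves.fit_cow_level(g, scc_curves[pg], "scc", cfg.min_points)
        rows.append({
            "cow_id": cow, "parity": int(parity), "parity_group": pg,
            "alpha_m": lm.alpha, "alpha_c": lc.alpha,
            "n_points": lm.n_points, "fittable": lm.fittable,
            "first_date": g["test_date"].min(), "last_date": g["test_date"].max(),
            "dim_p": g["dim_p"].dropna().iloc[0] if g["dim_p"].notna().any() else np.nan,
            "last_dim": int(g["dim"].max()),
        })
    return pd.DataFrame(rows)


def _fit_xi(levels: pd.DataFrame, family: str, cfg: FitConfig) -> dict:
    col = "alpha_m" if family == "milk" else "alpha_c"
    fit = levels[levels["fittable"]]
    pairs = {1: ([], []), 2: ([], []), 3: ([], [])}
    for _, g in fit.groupby("cow_id", sort=False):
        g = g.sort_values("parity")
        ps = g["parity"].to_numpy()
        al = g[col].to_numpy()
        for i in range(len(ps) - 1):
            if ps[i + 1] == ps[i] + 1:
                key = min(int(ps[i]), 3)
                pairs[key][0].append(al[i])
                pairs[key][1].append(al[i + 1])
    out = {}
    all_from, all_to = [], []
    for key, (fr, to) in pairs.items():
        all_from.extend(fr)
        all_to.extend(to)
        if len(fr) >= cfg.min_pairs:
            try:
                out[key] = _dyn.fit_correlation(fr, to)
            except Exception:
                pass
    if all_from:
        try:
            out["pooled"] = _dyn.fit_correlation(all_from, all_to)
        except Exception:
            pass
    return out


def _survival_cohort(levels: pd.DataFrame, records: pd.DataFrame, constants: ReproConstants):
    """Per-lactation (days open at conception, survived, censored) outcomes.

    A lactation is censored when its expected next calving would fall past
    the end of the observed window, so the outcome cannot be known.
    """
    data_end = records["test_date"].max()
    next_parity = {
        (r.cow_id, int(r.parity)): True
        for r in levels.itertuples()
    }
    rows = []
    for r in levels.itertuples():
        if not np.isfinite(r.dim_p):
            continue
        survived = (r.cow_id, int(r.parity) + 1) in next_parity
        # expected next calving: calving (= last_date - last_dim) + conception + gestation
        next_calving = r.last_date + pd.Timedelta(
            days=int(r.dim_p + constants.gestation - r.last_dim)
        )
        censored = (not survived) and (next_calving + pd.Timedelta(days=45) > data_end)
        rows.append({
            "cow_id": r.cow_id, "parity": int(r.parity), "parity_group": r.parity_group,
            "alpha_m": r.alpha_m, "fittable": r.fittable,
            "days_open": float(r.dim_p), "survived": survived, "censored": censored,
        })
    return pd.DataFrame(rows)


def _fit_survival_groups(cohort: pd.DataFrame, cfg: FitConfig) -> dict:
    """Final survival estimate per parity group, on cows with alpha_m >= 1."""
    out = {}
    if not len(cohort):
        return out
    use = cohort[(~cohort["censored"]) & cohort["fittable"] & (cohort["alpha_m"] >= 1.0)]
    pooled = None
    if len(use) >= 10:
        try:
            pooled = _dyn.fit_survival(
                use["days_open"], use["survived"],
                bin_width=cfg.survival_bin_width, parity_group="pooled",
                n_starts=cfg.n_starts, seed=cfg.seed,
            )
        except Exception:
            pooled = None
    for pg in PARITY_GROUPS:
        sub = use[use["parity_group"] == pg]
        params = None
        if len(sub) >= cfg.min_survival_outcomes:
            try:
                params = _dyn.fit_survival(
                    sub["days_open"], sub["survived"],
                    bin_width=cfg.survival_bin_width, parity_group=pg,
                    n_starts=cfg.n_starts, seed=cfg.seed,
                )
            except Exception:
                params = None
        if params is None and pooled is not None:
            params = _dyn.SurvivalParams(
                A=pooled.A, B=pooled.B, nu=pooled.nu, M=pooled.M,
                parity_group=pg, yield_group="pooled_fallback",
            )
        if params is not None:
            out[pg] = params
    return out


def fit_survival_by_yield(cohort: pd.DataFrame, cfg: FitConfig | None = None,
                          bins=(0.9, 1.1)) -> dict:
    """Exploratory survival fits stratified by milk-level bins (<0.9, 0.9-1.1, >1.1)."""
    cfg = cfg or FitConfig()
    lo, hi = bins
    labels = {}
    use = cohort[(~cohort["censored"]) & cohort["fittable"]]
    groups = {
        f"<{lo}": use[use["alpha_m"] < lo],
        f"{lo}-{hi}": use[(use["alpha_m"] >= lo) & (use["alpha_m"] <= hi)],
        f">{hi}": use[use["alpha_m"] > hi],
    }
    for name, sub in groups.items():
        if len(sub) >= cfg.min_survival_outcomes:
            try:
                labels[name] = _dyn.fit_survival(
                    sub["days_open"], sub["survived"],
                    bin_width=cfg.survival_bin_width, yield_group=name,
                    n_starts=cfg.n_starts, seed=cfg.seed,
                )
            except Exception:
                pass
    return labels


def _level_sequences(df: pd.DataFrame, milk_curves, scc_curves):
    """Per-cow time-ordered per-record relative-level series (milk, scc)."""
    seq_m, seq_c = [], []
    for _, g in df.groupby("cow_id", sort=False):
        g = g.sort_values("test_date")
        xm = np.empty(len(g))
        xc = np.empty(len(g))
        for i, r in enumerate(g.itertuples()):
            pg = "3+" if r.parity >= 3 else str(r.parity)
            xm[i] = _curves.invert_milk_level(
                milk_curves[pg], r.ecm_kg, r.dim, r.pregnant,
                r.dim_p if np.isfinite(r.dim_p) else None,
            )
            xc[i] = _curves.invert_scc_level(scc_curves[pg], r.tscc, r.dim)
        seq_m.append(xm)
        seq_c.append(xc[np.isfinite(xc)])
    return seq_m, seq_c


def _bulk_operating_point(df: pd.DataFrame) -> BulkOperatingPoint:
    per_day = df.groupby("test_date").apply(
        lambda g: pd.Series({
            "scc_b": float(np.sum(g["scc"] * g["milk_kg"]) / np.sum(g["milk_kg"])),
            "milk": float(g["milk_kg"].sum()),
            "ecm": float(g["ecm_kg"].sum()),
        }),
        include_groups=False,
    )
    return BulkOperatingPoint(
        scc_b=float(per_day["scc_b"].mean()),
        total_milk=float(per_day["milk"].mean()),
        total_ecm=float(per_day["ecm"].mean()),
    )


def fit_herd_model(records: pd.DataFrame, cfg: FitConfig | None = None) -> HerdModel:
    """Fit the full model for one herd's training records."""
    model, _ = _fit_herd(records, cfg)
    return model


def _fit_herd(records: pd.DataFrame, cfg: FitConfig | None = None,
              fixed_milk_d: dict | None = None):
    """Fit one herd; also return the artifacts multi-herd pooling needs."""
    cfg = cfg or FitConfig()
    herds = records["herd_id"].unique()
    if len(herds) != 1:
        raise ValueError("fit_herd_model expects records of exactly one herd")
    herd_id = str(herds[0])
    df = records if "ecm_kg" in records.columns else _io.derive_records(records)
    df = _io.filter_fittable(df, cfg.min_points)

    milk_curves, scc_curves = {}, {}
    for pg in PARITY_GROUPS:
        sub = df[df["parity_group"] == pg]
        if not len(sub):
            continue
        try:
            milk_curves[pg], _ = _curves.fit_herd_curve(
                sub, "milk", cfg.min_lactations, parse=cfg.milk_parse,
                n_starts=cfg.n_starts, seed=cfg.seed, parity_group=pg,
                fixed_d=(fixed_milk_d or {}).get(pg),
            )
            scc_curves[pg], _ = _curves.fit_herd_curve(
                sub, "scc", cfg.min_lactations,
                n_starts=cfg.n_starts, seed=cfg.seed, parity_group=pg,
            )
        except InsufficientDataError:
            continue
    if not milk_curves:
        raise InsufficientDataError(f"no parity group of herd {herd_id} is fittable")
    for pg in PARITY_GROUPS:  # thin groups borrow the nearest fitted group
        if pg not in milk_curves:
            donor = next(g for g in ("2", "1", "3+") if g in milk_curves)
            milk_curves[pg] = milk_curves[donor]
            scc_curves[pg] = scc_curves[donor]

    levels = _fit_cow_levels(df, milk_curves, scc_curves, cfg)
    xi_milk = _fit_xi(levels, "milk", cfg)
    xi_scc = _fit_xi(levels, "scc", cfg)

    cohort = _survival_cohort(levels, df, cfg.constants)
    survival = _fit_survival_groups(cohort, cfg)

    if len(cohort):
        gamma = _dyn.fit_gamma_censored(
            cohort["parity"], cohort["survived"], cohort["censored"],
            n_max=cfg.constants.n_max_future_lactations,
        )
    else:
        gamma = {}

    seq_m, seq_c = _level_sequences(df, milk_curves, scc_curves)
    lam_m, _ = _dyn.estimate_lambda(seq_m)
    lam_c, _ = _dyn.estimate_lambda(seq_c)

    model = HerdModel(
        herd_id=herd_id,
        milk_curves=milk_curves,
        scc_curves=scc_curves,
        xi_milk=xi_milk,
        xi_scc=xi_scc,
        survival=survival,
        gamma=gamma,
        lambda_milk=lam_m,
        lambda_scc=lam_c,
        bulk=_bulk_operating_point(df),
        scheme=build_price_function(cfg.price_steps),
        constants=cfg.constants,
        metadata={"milk_parse": cfg.milk_parse, "scc_parse": "nested"},
    )
    artifacts = {"cohort": cohort, "seq_m": seq_m, "seq_c": seq_c}
    return model, artifacts


def fit_models(records: pd.DataFrame, cfg: FitConfig | None = None) -> dict:
    """Fit a HerdModel per herd; returns ``{herd_id: HerdModel}``.

    The survival decay and the final-lactation distribution are estimated
    per herd only when the herd contributes enough lactation outcomes
    (``min_herd_outcomes_own_dynamics``); thinner herds get the across-herd
    pooled estimates — a 4-parameter sigmoid on a few hundred binary
    outcomes is dominated by noise.  The smoothing constants default to one
    global pair (``global_lambda``).  The milk curves' pregnancy-decline
    rate is estimated across herds per parity group (median of the per-herd
    free fits) and the herd curves refitted with it fixed: pregnancy
    decline is cow biology shared by all herds, and freezing it removes a
    near-collinearity that otherwise leaves each herd's non-pregnant curve
    level poorly determined.
    """
    cfg = cfg or FitConfig()
    groups = {str(h): g for h, g in records.groupby("herd_id", sort=True)}

    fixed_d = None
    if len(groups) > 1:
        d_hat = {pg: [] for pg in PARITY_GROUPS}
        for g in groups.values():
            d = g if "ecm_kg" in g.columns else _io.derive_records(g)
            for pg in PARITY_GROUPS:
                sub = d[d["parity_group"] == pg]
                try:
                    params, _ = _curves.fit_herd_curve(
                        sub, "milk", cfg.min_lactations, parse=cfg.milk_parse,
                        n_starts=cfg.n_starts, seed=cfg.seed, parity_group=pg,
                    )
                    d_hat[pg].append(params.d)
                except (InsufficientDataError, Exception):
                    continue
        fixed_d = {
            pg: float(np.median(v)) for pg, v in d_hat.items() if len(v) >= 2
        }

    fitted = {
        h: _fit_herd(g, cfg, fixed_milk_d=fixed_d) for h, g in groups.items()
    }
    models = {h: m for h, (m, _) in fitted.items()}
    if len(models) > 1:
        cohorts = pd.concat(
            [a["cohort"] for _, a in fitted.values() if len(a["cohort"])],
            ignore_index=True,
        )
        pooled_surv = _fit_survival_groups(cohorts, cfg)
        pooled_gamma = _dyn.fit_gamma_censored(
            cohorts["parity"], cohorts["survived"], cohorts["censored"],
            n_max=cfg.constants.n_max_future_lactations,
        ) if len(cohorts) else {}
        if cfg.global_lambda:
            lam_m, _ = _dyn.estimate_lambda(
                [s for _, a in fitted.values() for s in a["seq_m"]]
            )
            lam_c, _ = _dyn.estimate_lambda(
                [s for _, a in fitted.values() for s in a["seq_c"]]
            )
        for h, (model, art) in fitted.items():
            cohort = art["cohort"]
            n_usable = int((~cohort["censored"]).sum()) if len(cohort) else 0
            if n_usable < cfg.min_herd_outcomes_own_dynamics:
                if pooled_surv:
                    model.survival = pooled_surv
                if pooled_gamma:
                    model.gamma = pooled_gamma
            if cfg.global_lambda:
                model.lambda_milk, model.lambda_scc = lam_m, lam_c
    return models


def smooth_cow_levels(records: pd.DataFrame, model: HerdModel) -> pd.DataFrame:
    """Exponentially smoothed levels after each record of each cow.

    Every record is converted to a relative level against the herd curve of
    its parity group and folded into the running smoothed estimates
    (initialised at 1).  Returns the records with ``alpha_m_tilde`` and
    ``alpha_c_tilde`` columns (state including the current record).
    """
    df = records if "ecm_kg" in records.columns else _io.derive_records(records)
    out = []
    for _, g in df.groupby("cow_id", sort=False):
        g = g.sort_values("test_date").copy()
        vm, vc = 1.0, 1.0
        am = np.empty(len(g))
        ac = np.empty(len(g))
        for i, r in enumerate(g.itertuples()):
            pg = "3+" if r.parity >= 3 else str(r.parity)
            xm = _curves.invert_milk_level(
                model.milk_curves[pg], r.ecm_kg, r.dim, r.pregnant,
                r.dim_p if np.isfinite(r.dim_p) else None,
            )
            vm = model.lambda_milk * float(xm) + (1 - model.lambda_milk) * vm
            xc = _curves.invert_scc_level(model.scc_curves[pg], r.tscc, r.dim)
            if np.isfinite(xc):
                vc = model.lambda_scc * float(xc) + (1 - model.lambda_scc) * vc
            am[i] = vm
            ac[i] = vc
        g["alpha_m_tilde"] = am
        g["alpha_c_tilde"] = ac
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["herd_id", "cow_id", "test_date"]).reset_index(drop=True)
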