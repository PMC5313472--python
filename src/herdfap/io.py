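"""Reading, writing and validating herd-recording tables.

The canonical table has one row per cow per herd-test day.  Columns:

==============  =======================================================
``herd_id``     herd identifier (string)
``cow_id``      cow identifier (string)
``test_date``   calendar date of the herd test (ISO)
``parity``      lactation number, integer >= 1
``dim``         days in milk at the test, integer >= 0
``milk_kg``     milk yield, kg/day
``fat_pct``     milk fat, percent
``protein_pct`` milk protein, percent
``scc``         somatic cell count, x1000 cells/mL
``pregnant``    boolean pregnancy status at the test date
``dim_p``       days in milk at conception (present iff pregnant)
``dam_id``      optional dam identifier
==============  =======================================================

Arbitrary national recording exports are adapted through a column-mapping
dict ``{canonical_name: source_name}``.  Rows failing validation are never
silently dropped: they are collected into a rejects report (with the source
row number and a reason) written as a side-car file next to the input.

Derived per-record quantities:

* energy-corrected milk ``ECM = milk * (0.122 fat + 0.077 protein + 0.249)`` (kg/day),
* total test-day somatic cells ``tSCC = SCC * milk`` ((x1000 cells/mL) * kg).

SCC is expressed as x1000 cells/mL throughout the package (so the 200,000
cells/mL pricing threshold is 200 in these units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

#: Energy-corrected milk coefficients (kg basis): fat %, protein %, intercept.
ECM_FAT, ECM_PROTEIN, ECM_INTERCEPT = 0.122, 0.077, 0.249

REQUIRED_COLUMNS = [
    "herd_id",
    "cow_id",
    "test_date",
    "parity",
    "dim",
    "milk_kg",
    "fat_pct",
    "protein_pct",
    "scc",
    "pregnant",
    "dim_p",
]
OPTIONAL_COLUMNS = ["dam_id"]
CANONICAL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def compute_ecm(milk_kg, fat_pct, protein_pct):
    """Energy-corrected milk, kg/day.

    ``ECM = milk * (0.122 fat + 0.077 protein + 0.249)`` with fat and protein
    in percent.  Accepts scalars or arrays; raises :class:`DomainError` on
    negative inputs.
    """
    milk = np.asarray(milk_kg, dtype=float)
    fat = np.asarray(fat_pct, dtype=float)
    prot = np.asarray(protein_pct, dtype=float)
    if (milk < 0).any() or (fat < 0).any() or (prot < 0).any():
        raise DomainError("milk, fat and protein must be non-negative")
    out = milk * (ECM_FAT * fat + ECM_PROTEIN * prot + ECM_INTERCEPT)
    return float(out) if out.ndim == 0 else out


def compute_tscc(scc, milk_kg):
    """Total test-day somatic cells, (x1000 cells/mL) * kg: ``SCC * milk``."""
    s = np.asarray(scc, dtype=float)
    m = np.asarray(milk_kg, dtype=float)
    if (s < 0).any() or (m < 0).any():
        raise DomainError("scc and milk must be non-negative")
    out = s * m
    return float(out) if out.ndim == 0 else out


def derive_records(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``ecm_kg``, ``tscc`` and ``parity_group`` columns."""
    out = df.copy()
    out["ecm_kg"] = compute_ecm(out["milk_kg"], out["fat_pct"], out["protein_pct"])
    out["tscc"] = compute_tscc(out["scc"], out["milk_kg"])
    out["parity_group"] = parity_group(out["parity"])
    return out


def parity_group(parity):
    """Map lactation numbers to the herd-curve groups '1', '2', '3+'."""
    p = np.asarray(parity)
    out = np.where(p >= 3, "3+", p.astype(str))
    if np.ndim(parity) == 0:
        return str(out)
    return pd.Series(out, index=getattr(parity, "index", None), name="parity_group")


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def _validate_row(row) -> str | None:
    """Return a reason string if the row is invalid, else None."""
    if row["parity"] < 1:
        return "parity < 1"
    if row["dim"] < 0:
        return "dim < 0"
    if not row["milk_kg"] > 0:
        return "milk_kg <= 0 (dry or missing milk weight)"
    for col in ("fat_pct", "protein_pct", "scc"):
        if row[col] < 0:
            return f"{col} < 0"
    if row["pregnant"]:
        if pd.isna(row["dim_p"]):
            return "pregnant without dim_p"
        if row["dim_p"] > row["dim"]:
            return "dim_p > dim"
    return None


def read_herd_records(
    path,
    column_map: dict | None = None,
    sep: str = ",",
    rejects_path=None,
):
    """Read a delimited herd-recording file into the canonical table.

    Parameters
    ----------
    path : str or Path
        Delimited text file.
    column_map : dict, optional
        ``{canonical_name: source_name}`` renaming applied before validation.
    sep : str
        Field separator.
    rejects_path : str or Path, optional
        Where to write the rejects report.  Defaults to ``<path>.rejects.csv``
        (only written when rejects exist).

    Returns
    -------
    DataFrame
        Valid records, sorted by (herd_id, cow_id, test_date).  The rejects
        report is attached as ``df.attrs["rejects"]`` (a list of
        ``{"row", "reason"}`` dicts).

    Raises
    ------
    ConfigError
        If a mandatory column is missing after mapping (names the column).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"mandatory column(s) missing: {', '.join(missing)}")
    if "dam_id" not in raw.columns:
        raw["dam_id"] = ""

    rows, rejects = [], []
    for idx, r in raw.iterrows():
        try:
            rec = {
                "herd_id": str(r["herd_id"]),
                "cow_id": str(r["cow_id"]),
                "test_date": pd.Timestamp(r["test_date"]),
                "parity": int(r["parity"]),
                "dim": int(float(r["dim"])),
                "milk_kg": float(r["milk_kg"]),
                "fat_pct": float(r["fat_pct"]),
                "protein_pct": float(r["protein_pct"]),
                "scc": float(r["scc"]),
                "pregnant": _parse_bool(r["pregnant"]),
                "dim_p": float(r["dim_p"]) if str(r["dim_p"]).strip() else np.nan,
                "dam_id": str(r["dam_id"]) or None,
            }
        except (ValueError, TypeError) as exc:
            rejects.append({"row": idx + 1, "reason": f"unparseable: {exc}"})
            continue
        reason = _validate_row(rec)
        if reason is not None:
            rejects.append({"row": idx + 1, "reason": reason})
        else:
            rows.append(rec)

    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    if len(df):
        df = df.sort_values(["herd_id", "cow_id", "test_date"], kind="mergesort")
        df = df.reset_index(drop=True)
    # plain list of dicts: DataFrame-valued attrs break pandas concat
    df.attrs["rejects"] = rejects
    if rejects:
        out = rejects_path if rejects_path is not None else f"{path}.rejects.csv"
        pd.DataFrame(rejects, columns=["row", "reason"]).to_csv(out, index=False)
    return df


def write_herd_records(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write the canonical columns of ``df`` as delimited text (lossless round trip)."""
    out = df[CANONICAL_COLUMNS].copy()
    out["test_date"] = pd.to_datetime(out["test_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False)


def filter_fittable(df: pd.DataFrame, min_points: int = 6) -> pd.DataFrame:
    """Flag cow-lactations with enough test days to fit an individual level.

    Adds a boolean ``fittable`` column: a (herd, cow, parity) lactation is
    fittable when it has at least ``min_points`` milk records.  No records
    are dropped.
    """
    out = df.copy()
    if not len(out):
        out["fittable"] = pd.Series(dtype=bool)
        return out
    counts = out.groupby(["herd_id", "cow_id", "parity"])["test_date"].transform("size")
    out["fittable"] = counts >= min_points
    return out
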