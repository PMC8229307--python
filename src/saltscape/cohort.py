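"""Intake estimation and cohort filtering for georeferenced FFQ surveys.

Sodium from a food-frequency questionnaire (FFQ) is calibrated against 24-h
urine collections with sex-specific affine equations expressed on the salt
scale and converted to sodium with 1 g Na = 2.54 g NaCl:

    male:   (8.2  + 0.38 * ffq_na) / 2.54
    female: (4.55 + 0.67 * ffq_na) / 2.54

The Na:K ratio is calibrated sodium (g/day) divided by potassium (g/day).

Exclusion filters reproduce a population-survey cleaning pass: out-of-region
residence, age outside 20-74 (inclusive bounds, a pinned convention), missing
socio-demographics / intakes / zone income, and extreme total energy
(strictly below 850 or above 4500 kcal/day). Each participant is attributed
to the first rule it fails, in that fixed order, so per-rule counts are
reproducible; the retained set itself is order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SALT_PER_NA",
    "PARTICIPANT_COLUMNS",
    "EXCLUSION_RULES",
    "ExclusionReport",
    "calibrate_na",
    "na_k_ratio",
    "add_outcomes",
    "apply_exclusions",
    "read_participants_csv",
    "write_participants_csv",
]

SALT_PER_NA = 2.54  # g salt (NaCl) per g sodium

_CAL = {"male": (8.2, 0.38), "female": (4.55, 0.67)}

PARTICIPANT_COLUMNS = [
    "id", "x", "y", "year", "age", "sex", "civil_status", "occupation",
    "education", "nationality", "ffq_na", "k_intake", "energy", "zone_id",
]

EXCLUSION_RULES = [
    "outside_region",
    "age_out_of_range",
    "missing_civil_status",
    "missing_occupation",
    "missing_education",
    "missing_nationality",
    "missing_intake",
    "missing_zone_income",
    "extreme_energy",
]


@dataclass
class ExclusionReport:
    counts: dict  # rule -> excluded count (first-failing attribution)
    first_rule: pd.Series  # participant id -> rule or "retained"
    retained: int

    @property
    def excluded(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "excluded": self.counts[r]} for r in EXCLUSION_RULES]
        rows.append({"rule": "retained", "excluded": self.retained})
        return pd.DataFrame(rows)


def calibrate_na(ffq_na, sex):
    """Calibrated sodium intake in g/day from raw FFQ sodium.

    Vectorized over arrays; ``sex`` is "male"/"female" (scalar or array).
    Strictly increasing in ``ffq_na`` for either sex.
    """
    ffq = np.asarray(ffq_na, dtype=float)
    if np.any(ffq < 0):
        raise ValueError("ffq_na must be non-negative")
    sex_arr = np.asarray(sex)
    if sex_arr.ndim == 0:
        if sex_arr.item() not in _CAL:
            raise ValueError(f"unknown sex code: {sex_arr.item()!r}")
        a, b = _CAL[sex_arr.item()]
        out = (a + b * ffq) / SALT_PER_NA
        return float(out) if np.isscalar(ffq_na) else out
    bad = ~np.isin(sex_arr, list(_CAL))
    if bad.any():
        raise ValueError(f"unknown sex code: {sex_arr[bad][0]!r}")
    a = np.where(sex_arr == "male", _CAL["male"][0], _CAL["female"][0])
    b = np.where(sex_arr == "male", _CAL["male"][1], _CAL["female"][1])
    return (a + b * ffq) / SALT_PER_NA


def na_k_ratio(na, k):
    """Sodium-to-potassium intake ratio (both g/day)."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError("k intake must be strictly positive")
    out = np.asarray(na, dtype=float) / k_arr
    return float(out) if np.isscalar(na) and np.isscalar(k) else out


def add_outcomes(participants: pd.DataFrame) -> pd.DataFrame:
    """Attach calibrated na_intake and na_k_ratio columns."""
    df = participants.copy()
    ok = df["ffq_na"].notna() & df["k_intake"].notna() & df["sex"].notna()
    na_cal = np.full(len(df), np.nan)
    na_cal[ok.to_numpy()] = calibrate_na(
        df.loc[ok, "ffq_na"].to_numpy(), df.loc[ok, "sex"].to_numpy()
    )
    df["na_intake"] = na_cal
    with np.errstate(divide="ignore", invalid="ignore"):
        df["na_k_ratio"] = df["na_intake"] / df["k_intake"]
    return df


def _in_rectangle(df: pd.DataFrame, region) -> pd.Series:
    (x0, y0), (x1, y1) = region
    return (
        (df["x"] >= x0) & (df["x"] <= x1) & (df["y"] >= y0) & (df["y"] <= y1)
    )


def apply_exclusions(
    participants: pd.DataFrame,
    region=None,
    zone_income: pd.DataFrame | None = None,
    region_test=None,
):
    """Filter a participant table; return (retained DataFrame, ExclusionReport).

    Parameters
    ----------
    participants : DataFrame
        Must carry :data:`PARTICIPANT_COLUMNS`; intake outcomes are added
        if absent.
    region : ((x0, y0), (x1, y1)) or None
        Rectangle in meters; None disables the residence rule.
    zone_income : DataFrame or None
        Columns (zone_id, year, income); participants whose assigned income
        year/zone pair is absent fail the zone-income rule. None disables it.
    region_test : callable or None
        Hook accepting the DataFrame and returning a boolean inside-mask;
        overrides the rectangle test (e.g. for polygon membership).
    """
    from .food_env import assign_income_year

    df = participants.reset_index(drop=True)
    if "na_intake" not in df.columns:
        df = add_outcomes(df)
    n = len(df)

    if region_test is not None:
        inside = pd.Series(np.asarray(region_test(df), dtype=bool))
    elif region is not None:
        inside = _in_rectangle(df, region)
    else:
        inside = pd.Series(True, index=df.index)

    if zone_income is not None:
        inc_years = df["year"].map(lambda y: assign_income_year(int(y)))
        known = set(zip(zone_income["zone_id"], zone_income["year"]))
        has_income = pd.Series(
            [
                (z, iy) in known and pd.notna(z)
                for z, iy in zip(df["zone_id"], inc_years)
            ],
            index=df.index,
        )
    else:
        has_income = pd.Series(True, index=df.index)

    fails = {
        "outside_region": ~inside,
        "age_out_of_range": (df["age"] < 20) | (df["age"] > 74),
        "missing_civil_status": df["civil_status"].isna(),
        "missing_occupation": df["occupation"].isna(),
        "missing_education": df["education"].isna(),
        "missing_nationality": df["nationality"].isna(),
        "missing_intake": df["na_intake"].isna() | df["k_intake"].isna(),
        "missing_zone_income": ~has_income,
        "extreme_energy": df["energy"].isna()
        | (df["energy"] < 850)
        | (df["energy"] > 4500),
    }

    first_rule = pd.Series("retained", index=df.index, dtype=object)
    for rule in EXCLUSION_RULES:
        mask = fails[rule].to_numpy() & (first_rule == "retained").to_numpy()
        first_rule[mask] = rule

    counts = {r: int((first_rule == r).sum()) for r in EXCLUSION_RULES}
    retained_mask = first_rule == "retained"
    retained = df[retained_mask].reset_index(drop=True)
    report = ExclusionReport(
        counts=counts,
        first_rule=pd.Series(first_rule.values, index=df["id"].values),
        retained=int(retained_mask.sum()),
    )
    assert report.retained + report.excluded == n
    return retained, report


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant CSV missing columns: {missing}")
    return df


def write_participants_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
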