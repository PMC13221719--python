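"""Data-editing rules producing analysis-ready cohort datasets.

Every rule is a pure subsetting operation: records are removed or flagged,
never altered, and each removal is logged with the rule that fired and the
offending value.  The rules, applied per cohort dataset:

* methane below 4 g/d removed; then methane beyond +-3 SD of the cohort mean
  removed (single pass, mean/SD computed after the hard threshold);
* CO2 above 2,500 g/d keeps the record for methane traits but invalidates it
  for CO2-based traits;
* contemporary groups (flock x measurement date x PAC run) with fewer than
  five distinct animals dropped;
* body weight windows: growing 25-80 kg, ewes 55-100 kg;
* cohort age windows: growing 105-600 d, ewes 380-3,850 d;
* intake records within +-30 d of the methane measurement, +-3 SD screened;
* carcass weight 15-26 kg, slaughter at 100-450 d of age, within 30 d of a
  methane record, with only the methane record closest to slaughter paired;
* CT scans within 3 d of the methane record, rows beyond +-3 SD on any CT
  trait dropped;
* growth rates retained only between 150 and 350 g/d.

All date windows are inclusive at both ends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CH4_MIN_G_D = 4.0
CO2_MAX_G_D = 2500.0
SD_MULTIPLE = 3.0
MIN_GROUP_SIZE = 5
WEIGHT_WINDOWS = {"growing": (25.0, 80.0), "ewe": (55.0, 100.0)}
AGE_WINDOWS_D = {"growing": (105, 600), "ewe": (380, 3850)}
CARCASS_WINDOW_KG = (15.0, 26.0)
SLAUGHTER_AGE_D = (100, 450)
SLAUGHTER_PAIR_D = 30
DMI_PAIR_D = 30
CT_PAIR_D = 3
ADG_WINDOW_G_D = (150.0, 350.0)

_EXCL_COLS = ["record_id", "table", "rule", "value"]


def _log(rows, ids, table, rule, values):
    for rid, val in zip(ids, values):
        rows.append({"record_id": rid, "table": table, "rule": rule, "value": val})


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=_EXCL_COLS)


def assign_contemporary_groups(records: pd.DataFrame):
    """Annotate records with their contemporary-group key and size.

    The key is flock x measurement date x PAC run; the size counts distinct
    animals.  Records missing any key field are rejected and logged.
    Returns (annotated records, exclusion log).
    """
    excl: list[dict] = []
    key_fields = ["flock_id", "measurement_date", "pac_run", "animal_id"]
    bad = records[key_fields].isna().any(axis=1)
    if bad.any():
        _log(excl, records.loc[bad, "record_id"], "emissions", "missing_group_key",
             [None] * int(bad.sum()))
    out = records.loc[~bad].copy()
    dates = pd.to_datetime(out["measurement_date"]).dt.date.astype(str)
    out["cg_key"] = (out["flock_id"].astype(str) + "|" + dates
                     + "|" + out["pac_run"].astype(int).astype(str))
    sizes = out.groupby("cg_key")["animal_id"].nunique()
    out["cg_size"] = out["cg_key"].map(sizes)
    return out, pd.DataFrame(excl, columns=_EXCL_COLS)


def filter_cohort_eligibility(records: pd.DataFrame):
    """Drop records whose measurement age lies outside the cohort window."""
    excl: list[dict] = []
    keep = pd.Series(True, index=records.index)
    for cohort, (lo, hi) in AGE_WINDOWS_D.items():
        mask = (records["cohort"] == cohort) & ~records["age_days"].between(lo, hi)
        if mask.any():
            _log(excl, records.loc[mask, "record_id"], "emissions", "age_window",
                 records.loc[mask, "age_days"].tolist())
            keep &= ~mask
    return records.loc[keep].copy(), pd.DataFrame(excl, columns=_EXCL_COLS)


def apply_emission_filters(records: pd.DataFrame, cohort: str | None = None,
                           ch4_min: float = CH4_MIN_G_D,
                           co2_max: float = CO2_MAX_G_D,
                           sd_multiple: float = SD_MULTIPLE):
    """Gas-record edits: hard methane floor, +-3 SD screen, CO2 validity flag.

    ``cohort`` restricts the +-3 SD computation to one dataset; if None the
    screen is computed within each cohort present.  Returns
    (filtered records with a ``co2_valid`` column, exclusion log).
    """
    if not len(records):
        return records.assign(co2_valid=pd.Series(dtype=bool)), _empty_log()
    excl: list[dict] = []
    df = records if cohort is None else records[records["cohort"] == cohort]
    df = df.copy()

    low = df["ch4_g_d"] < ch4_min
    _log(excl, df.loc[low, "record_id"], "emissions", "ch4_below_4",
         df.loc[low, "ch4_g_d"].tolist())
    df = df.loc[~low]

    keep = pd.Series(True, index=df.index)
    for _, grp in df.groupby("cohort"):
        mu, sd = grp["ch4_g_d"].mean(), grp["ch4_g_d"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        out = (grp["ch4_g_d"] - mu).abs() > sd_multiple * sd
        if out.any():
            _log(excl, grp.loc[out, "record_id"], "emissions", "ch4_3sd",
                 grp.loc[out, "ch4_g_d"].tolist())
            keep.loc[grp.index[out]] = False
    df = df.loc[keep].copy()

    high_co2 = df["co2_g_d"] > co2_max
    df["co2_valid"] = ~high_co2
    _log(excl, df.loc[high_co2, "record_id"], "emissions", "co2_above_2500",
         df.loc[high_co2, "co2_g_d"].tolist())
    return df, pd.DataFrame(excl, columns=_EXCL_COLS)


def filter_small_groups(records: pd.DataFrame, min_size: int = MIN_GROUP_SIZE):
    """Drop contemporary groups with fewer than ``min_size`` distinct animals.

    Sizes are recomputed on the current record set, so this is meant to run
    after the emission filters.
    """
    excl: list[dict] = []
    sizes = records.groupby("cg_key")["animal_id"].nunique()
    out = records.copy()
    out["cg_size"] = out["cg_key"].map(sizes)
    small = out["cg_size"] < min_size
    _log(excl, out.loc[small, "record_id"], "emissions", "cg_below_min_size",
         out.loc[small, "cg_size"].tolist())
    return out.loc[~small].copy(), pd.DataFrame(excl, columns=_EXCL_COLS)


def _sd_screen(values: pd.Series) -> pd.Series:
    mu, sd = values.mean(), values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(True, index=values.index)
    return (values - mu).abs() <= SD_MULTIPLE * sd


def _pair_nearest(records, table, date_col, max_days, prefer="abs"):
    """For each methane record, the row of ``table`` (same animal) nearest in
    date within ``max_days``; ties break toward the earlier date.  Returns a
    Series of table row indices aligned to ``records.index`` (NaN = no match)."""
    matches = pd.Series(np.nan, index=records.index)
    if not len(table):
        return matches
    by_animal = {a: g for a, g in table.groupby("animal_id")}
    for i, row in records.iterrows():
        g = by_animal.get(row["animal_id"])
        if g is None:
            continue
        diff = (pd.to_datetime(g[date_col]) - pd.Timestamp(row["measurement_date"])).dt.days
        ok = diff.abs() <= max_days
        if not ok.any():
            continue
        cand = g.loc[ok]
        order = np.lexsort((pd.to_datetime(cand[date_col]).values.astype("int64"),
                            diff[ok].abs().values))
        matches.loc[i] = cand.index[order[0]]
    return matches


def apply_weight_and_window_filters(
    records: pd.DataFrame,
    dmi: pd.DataFrame | None = None,
    carcass: pd.DataFrame | None = None,
    ct: pd.DataFrame | None = None,
):
    """Weight windows plus production-table screening and record pairing.

    Returns (records with paired production columns, exclusion log).  Paired
    columns added where data exist: ``dmi_kg_d``, ``carcass_weight_kg``,
    ``age_at_slaughter_d``, and the CT trait columns.
    """
    excl: list[dict] = []
    out = records.copy()
    keep = pd.Series(True, index=out.index)
    for cohort, (lo, hi) in WEIGHT_WINDOWS.items():
        mask = (out["cohort"] == cohort) & ~out["body_weight_kg"].between(lo, hi)
        if mask.any():
            _log(excl, out.loc[mask, "record_id"], "emissions", "weight_window",
                 out.loc[mask, "body_weight_kg"].tolist())
            keep &= ~mask
    out = out.loc[keep].copy()

    known = set(out["animal_id"])

    if dmi is not None and len(dmi):
        dmi = dmi.copy()
        orphan = ~dmi["animal_id"].isin(known)
        _log(excl, dmi.loc[orphan, "animal_id"], "dmi", "unlinkable_animal",
             dmi.loc[orphan, "dmi_kg_d"].tolist())
        dmi = dmi.loc[~orphan]
        ok = _sd_screen(dmi["dmi_kg_d"])
        _log(excl, dmi.loc[~ok, "animal_id"], "dmi", "dmi_3sd",
             dmi.loc[~ok, "dmi_kg_d"].tolist())
        dmi = dmi.loc[ok]
        match = _pair_nearest(out, dmi, "date", DMI_PAIR_D)
        out["dmi_kg_d"] = match.map(
            lambda j: dmi.loc[j, "dmi_kg_d"] if pd.notna(j) else np.nan
        )

    if carcass is not None and len(carcass):
        carcass = carcass.copy()
        orphan = ~carcass["animal_id"].isin(known)
        _log(excl, carcass.loc[orphan, "animal_id"], "carcass", "unlinkable_animal",
             [None] * int(orphan.sum()))
        carcass = carcass.loc[~orphan]
        bad_w = ~carcass["carcass_weight_kg"].between(*CARCASS_WINDOW_KG)
        _log(excl, carcass.loc[bad_w, "animal_id"], "carcass", "carcass_weight_window",
             carcass.loc[bad_w, "carcass_weight_kg"].tolist())
        bad_a = ~carcass["age_at_slaughter_d"].between(*SLAUGHTER_AGE_D)
        _log(excl, carcass.loc[bad_a & ~bad_w, "animal_id"], "carcass",
             "slaughter_age_window",
             carcass.loc[bad_a & ~bad_w, "age_at_slaughter_d"].tolist())
        carcass = carcass.loc[~(bad_w | bad_a)]
        out["carcass_weight_kg"] = np.nan
        out["age_at_slaughter_d"] = np.nan
        # one methane record per slaughter: the closest within the 30-d window
        for _, crow in carcass.iterrows():
            sub = out[out["animal_id"] == crow["animal_id"]]
            diff = (pd.Timestamp(crow["slaughter_date"])
                    - pd.to_datetime(sub["measurement_date"])).dt.days
            ok = diff.abs() <= SLAUGHTER_PAIR_D
            if not ok.any():
                continue
            cand = sub.loc[ok]
            j = cand.index[np.lexsort(
                (pd.to_datetime(cand["measurement_date"]).values.astype("int64"),
                 diff[ok].abs().values))[0]]
            out.loc[j, "carcass_weight_kg"] = crow["carcass_weight_kg"]
            out.loc[j, "age_at_slaughter_d"] = crow["age_at_slaughter_d"]

    if ct is not None and len(ct):
        ct = ct.copy()
        orphan = ~ct["animal_id"].isin(known)
        _log(excl, ct.loc[orphan, "animal_id"], "ct", "unlinkable_animal",
             [None] * int(orphan.sum()))
        ct = ct.loc[~orphan]
        trait_cols = ["fat_mass_kg", "muscle_mass_kg", "kill_out_pct",
                      "muscle_fat_ratio", "rumen_volume_l"]
        ok = pd.Series(True, index=ct.index)
        for c in trait_cols:
            ok &= _sd_screen(ct[c])
        _log(excl, ct.loc[~ok, "animal_id"], "ct", "ct_3sd",
             [None] * int((~ok).sum()))
        ct = ct.loc[ok]
        match = _pair_nearest(out, ct, "scan_date", CT_PAIR_D)
        for c in trait_cols:
            out[c] = match.map(lambda j: ct.loc[j, c] if pd.notna(j) else np.nan)

    return out, pd.DataFrame(excl, columns=_EXCL_COLS)


def apply_adg_filter(covariates: pd.DataFrame):
    """Blank growth rates outside the 150-350 g/d plausibility band."""
    excl: list[dict] = []
    out = covariates.copy()
    if "adg_g_d" not in out.columns:
        return out, _empty_log()
    bad = out["adg_g_d"].notna() & ~out["adg_g_d"].between(*ADG_WINDOW_G_D)
    _log(excl, out.loc[bad, "record_id"], "covariates", "adg_window",
         out.loc[bad, "adg_g_d"].tolist())
    out.loc[bad, "adg_g_d"] = np.nan
    return out, pd.DataFrame(excl, columns=_EXCL_COLS)
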