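"""Absolute and ratio methane traits.

Each ratio trait is a plain quotient of daily methane (or CO2) and one
production trait, computed per eligible record:

    MI_BW  = CH4 / body weight            (g/d per kg)
    MI_MBW = CH4 / body weight^0.75
    MI_ADG = CH4 / average daily gain     (ADG in kg/d)
    MI_CW  = CH4 / cold carcass weight
    MI_MM  = CH4 / CT muscle mass
    MI_FM  = CH4 / CT fat mass
    MI_KO  = CH4 / predicted kill-out proportion
    MI_MF  = CH4 / muscle-to-fat ratio
    MI_Rumen = CH4 / rumen volume         (g/d per litre)
    MY     = CH4 / DMI                    (g per kg dry matter)
    CH4/(CH4+CO2) = CH4 / (CH4 + CO2)     (dimensionless)
    CO2 yield = CO2 / DMI                 (g per kg dry matter)

Intake-denominator traits use DMI in kg/d, and MI_ADG uses ADG in kg/d, which
keeps the trait scales consistent with typical field reports (methane yield
~11 g/kg DM at 14 g/d CH4 and 1.5 kg/d intake).  Ewes carry only MI_BW,
MI_MBW, MY, CH4/(CH4+CO2) and CO2 yield among the ratios; the CT-, carcass-
and growth-based intensities are growing-animal traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROWING_RATIOS = ["mi_bw", "mi_mbw", "mi_adg", "mi_cw", "mi_mm", "mi_fm",
                  "mi_ko", "mi_mf", "mi_rumen", "my", "ch4_fraction", "co2_yield"]
EWE_RATIOS = ["mi_bw", "mi_mbw", "my", "ch4_fraction", "co2_yield"]


def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den
    out[den.isna() | (den <= 0)] = np.nan
    return out


def compute_ratio_traits(records: pd.DataFrame,
                         covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per record with the absolute trait and every eligible ratio.

    ``records`` is the QC-filtered emission table with paired production
    columns (``dmi_kg_d``, ``carcass_weight_kg``, CT traits) where available;
    ``covariates`` contributes per-record MBW and ADG.  A trait is absent
    (NaN) whenever its denominator is absent, non-positive, or not defined for
    the cohort.  CO2-based traits are absent where the CO2 record is invalid.
    """
    df = records.copy()
    if covariates is not None:
        cols = [c for c in ("mbw_kg", "adg_g_d") if c in covariates.columns]
        df = df.merge(covariates[["record_id", *cols]], on="record_id", how="left")
    if "mbw_kg" not in df.columns:
        df["mbw_kg"] = df["body_weight_kg"] ** 0.75

    out = pd.DataFrame({
        "record_id": df["record_id"],
        "animal_id": df["animal_id"],
        "cohort": df["cohort"],
        "ch4_g_d": df["ch4_g_d"],
    })
    ch4 = df["ch4_g_d"]
    nan = pd.Series(np.nan, index=df.index)
    co2 = df["co2_g_d"].where(df.get("co2_valid", pd.Series(True, index=df.index)))
    dmi = df.get("dmi_kg_d", nan)

    out["mi_bw"] = _ratio(ch4, df["body_weight_kg"])
    out["mi_mbw"] = _ratio(ch4, df["mbw_kg"])
    out["my"] = _ratio(ch4, dmi)
    out["ch4_fraction"] = _ratio(ch4, ch4 + co2)
    out["co2_yield"] = _ratio(co2, dmi)

    grow = df["cohort"] == "growing"
    adg_kg = df.get("adg_g_d", nan) / 1000.0
    out["mi_adg"] = _ratio(ch4, adg_kg).where(grow)
    out["mi_cw"] = _ratio(ch4, df.get("carcass_weight_kg", nan)).where(grow)
    out["mi_mm"] = _ratio(ch4, df.get("muscle_mass_kg", nan)).where(grow)
    out["mi_fm"] = _ratio(ch4, df.get("fat_mass_kg", nan)).where(grow)
    out["mi_ko"] = _ratio(ch4, df.get("kill_out_pct", nan)).where(grow)
    out["mi_mf"] = _ratio(ch4, df.get("muscle_fat_ratio", nan)).where(grow)
    out["mi_rumen"] = _ratio(ch4, df.get("rumen_volume_l", nan)).where(grow)

    ewe = ~grow
    for c in set(GROWING_RATIOS) - set(EWE_RATIOS):
        out.loc[ewe, c] = np.nan
    return out


def trait_summary(traits: pd.DataFrame, trait_cols: list[str] | None = None) -> pd.DataFrame:
    """Descriptive summary per trait: records, animals, mean, SD, range, CV.

    CV = 100 * SD / mean, reported absent for mean-zero traits (the residual
    methane traits are centred by construction, so their CV is undefined).
    """
    if not len(traits):
        raise ValueError("no rows to summarise")
    if trait_cols is None:
        skip = {"record_id", "animal_id", "cohort"}
        trait_cols = [c for c in traits.columns if c not in skip]
    rows = []
    for c in trait_cols:
        v = traits[c]
        ok = v.notna()
        n = int(ok.sum())
        if n == 0:
            rows.append({"trait": c, "n_records": 0, "n_animals": 0, "mean": np.nan,
                         "sd": np.nan, "min": np.nan, "max": np.nan, "cv": np.nan})
            continue
        mean = float(v[ok].mean())
        sd = float(v[ok].std(ddof=1)) if n > 1 else 0.0
        cv = 100.0 * sd / mean if abs(mean) > 1e-8 else np.nan
        rows.append({
            "trait": c,
            "n_records": n,
            "n_animals": int(traits.loc[ok, "animal_id"].nunique()),
            "mean": mean, "sd": sd,
            "min": float(v[ok].min()), "max": float(v[ok].max()),
            "cv": cv,
        })
    return pd.DataFrame(rows)
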