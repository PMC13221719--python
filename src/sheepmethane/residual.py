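"""Residual methane traits: deviations from a mixed-model prediction.

A residual methane trait RMT_x is what is left of a record's daily methane
after adjusting for systematic effects (sex, litter sizes, age class,
lactation status, heterosis, recombination loss, breed proportions) plus one
or more production traits x, with contemporary group and animal fitted as
random intercepts.  By default the trait is the conditional residual

    RMT = y - X b - CG BLUP - animal BLUP,

whose sum is exactly zero whenever the model carries an intercept (the first
mixed-model equation is X'(y - X b - Z u) = 0), so the trait is centred at
0.00 and exactly uncorrelated with every covariate in the model by
construction.  ``mode="keep_animal"`` instead retains the animal BLUP in the
trait (y - X b - CG BLUP), reading the permanent animal effect as part of the
animal's methane identity rather than as noise; that variant is centred only
approximately on unbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import FitResult, ModelSpec, RankDeficiencyError, fit_lmm

#: production-trait column(s) per residual trait, growing animals
GROWING_RMT = {
    "RMT_BW": ["body_weight_kg"],
    "RMT_MBW": ["mbw_kg"],
    "RMT_DMI": ["dmi_kg_d"],
    "RMT_MBW+DMI": ["mbw_kg", "dmi_kg_d"],
    "RMT_ADG": ["adg_kg_d"],
    "RMT_CW": ["carcass_weight_kg"],
    "RMT_MBW+ADG": ["mbw_kg", "adg_kg_d"],
}
#: ewe residual traits
EWE_RMT = {
    "RMT_BW": ["body_weight_kg"],
    "RMT_MBW": ["mbw_kg"],
    "RMT_DMI": ["dmi_kg_d"],
    "RMT_MBW+DMI": ["mbw_kg", "dmi_kg_d"],
}

GROWING_BREEDS = ["Belclare", "Blackface Mountain", "Charollais", "Cheviot",
                  "Lleyn", "Texel", "Other"]  # Suffolk is the reference
EWE_BREEDS = ["Belclare", "Charollais", "Cheviot", "Lleyn", "Texel", "Vendeen",
              "Other"]


@dataclass
class ResidualTraitSpec:
    """A named residual trait: cohort, production terms, and base model."""

    name: str
    cohort: str
    production_terms: list

    @classmethod
    def for_trait(cls, name: str, cohort: str) -> "ResidualTraitSpec":
        table = GROWING_RMT if cohort == "growing" else EWE_RMT
        if name not in table:
            raise ValueError(
                f"{name!r} is not a {cohort} residual trait; choose from {sorted(table)}"
            )
        return cls(name=name, cohort=cohort, production_terms=list(table[name]))

    def model_spec(self) -> ModelSpec:
        if self.cohort == "growing":
            factors = {"sex": "female", "birth_litter_size": "1",
                       "rearing_litter_size": "1", "age_months": None}
            breeds = GROWING_BREEDS
        else:
            factors = {"age_years": None, "lactation_status": "dry",
                       "birth_litter_size": "1", "rearing_litter_size": "1"}
            breeds = EWE_BREEDS
        covs = (["recombination", "heterosis"]
                + [f"breed_{b}" for b in breeds]
                + self.production_terms)
        return ModelSpec(response="ch4_g_d", factors=factors, covariates=covs,
                         random_terms=["cg_key", "animal_id"], cohort=self.cohort)


def prepare_model_frame(records: pd.DataFrame, covariates: pd.DataFrame,
                        animals: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """Join records, covariates and animal profiles into one model frame.

    Age classes: months (floor of age/30.437, clamped to 4-19) for growing
    animals, years (floor of age/365.25, clamped to 1-7 with 7 meaning >=7)
    for ewes.  Litter-size classes are capped at 3 (meaning >=3).
    """
    df = records.merge(covariates.drop(columns=["animal_id"]), on="record_id",
                       how="left")
    animal_cols = [c for c in ("animal_id", "sex", "birth_litter_size",
                               "rearing_litter_size") if c in animals.columns]
    df = df.merge(animals[animal_cols], on="animal_id", how="left")
    df = df[df["cohort"] == cohort].copy()
    if cohort == "growing":
        df["age_months"] = np.clip(df["age_days"] // 30.437, 4, 19).astype(int).astype(str)
    else:
        df["age_years"] = np.clip(df["age_days"] // 365.25, 1, 7).astype(int).astype(str)
    for c in ("birth_litter_size", "rearing_litter_size"):
        df[c] = np.minimum(df[c].astype(int), 3).astype(str)
    if "adg_g_d" in df.columns:
        df["adg_kg_d"] = df["adg_g_d"] / 1000.0
    breeds = GROWING_BREEDS if cohort == "growing" else EWE_BREEDS
    for b in breeds:
        col = f"breed_{b}"
        if col not in df.columns:
            df[col] = 0.0
        df[col] = df[col].fillna(0.0)
    return df


def derive_residual_trait(
    spec: ResidualTraitSpec,
    frame: pd.DataFrame,
    mode: str = "conditional",
    rtol: float = 1e-10,
    max_iter: int = 30000,
):
    """Fit the trait's mixed model and return per-record residual values.

    ``frame`` comes from :func:`prepare_model_frame`.  Records missing any
    production term are excluded from this trait only.  Returns
    (Series of residual values in g/d indexed by record_id, FitResult).
    """
    if mode not in ("conditional", "keep_animal"):
        raise ValueError(f"unknown residual mode {mode!r}")
    if (frame["cohort"] != spec.cohort).any():
        raise ValueError(f"{spec.name} is a {spec.cohort} trait; frame mixes cohorts")
    mspec = spec.model_spec()
    terms = [*mspec.factors, *mspec.covariates, mspec.response, *mspec.random_terms]
    complete = frame.dropna(subset=[t for t in terms if t in frame.columns])
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise KeyError(f"model frame lacks columns {missing}")
    fit = fit_lmm(mspec, complete, rtol=rtol, max_iter=max_iter).require_converged()
    resid = complete["ch4_g_d"].to_numpy() - fit.fitted_fixed()
    resid -= fit.blup_per_record("cg_key")
    if mode == "conditional":
        resid -= fit.blup_per_record("animal_id")
    values = pd.Series(resid, index=complete["record_id"].to_numpy(), name=spec.name)
    return values, fit


def derive_all_residual_traits(frame: pd.DataFrame, cohort: str,
                               mode: str = "conditional") -> tuple:
    """All residual traits defined for ``cohort`` as one record x trait table."""
    if mode not in ("conditional", "keep_animal"):
        raise ValueError(f"unknown residual mode {mode!r}")
    table = GROWING_RMT if cohort == "growing" else EWE_RMT
    out = pd.DataFrame(index=pd.Index(frame["record_id"], name="record_id"))
    fits: dict[str, FitResult] = {}
    for name in table:
        spec = ResidualTraitSpec.for_trait(name, cohort)
        needed = [t for t in spec.production_terms if t in frame.columns]
        if len(needed) < len(spec.production_terms):
            continue  # production table absent from this run
        if frame.dropna(subset=spec.production_terms).empty:
            continue
        try:
            values, fit = derive_residual_trait(spec, frame, mode=mode)
        except (ValueError, RankDeficiencyError):
            # too few complete records to identify this trait's model
            continue
        out[name] = values.reindex(out.index)
        fits[name] = fit
    return out.reset_index(), fits
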