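"""Synthetic flock generator.

Emulates the structure of a pasture-based sheep methane study measured with
portable accumulation chambers (PACs): animals nested in flocks, measured in
sessions (flock x date), 12 chamber slots per run, repeated records for a
subset of animals, and linked production tables (intake, weights, slaughter,
CT, maternal).  Methane per record is built additively,

    CH4 = mu + fixed effects + trait links + CG effect + animal effect + residual,

with the contemporary-group, animal, and residual variances set directly in
the configuration, so parameter-recovery tests have a known truth.  A
``truth`` table carrying every latent component is returned alongside the
observable tables.

The defaults describe a growing-lamb dataset on the scale typical of
chamber-measured flocks: mean methane near 14 g/d with phenotypic SD ~5 g/d,
repeatability
sigma_a^2/(sigma_a^2+sigma_e^2) = 0.26, DMI mean 1.5 kg/d with CV ~39%, body
weights inside the 25-80 kg window.  ``default_config("ewe")`` switches to the
mature-ewe scale (mean ~21 g/d, repeatability 0.34, 55-100 kg weights).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (
    KNOWN_BREEDS,
    BreedVector,
    animal_breed_fractions,
    heterosis_coefficient,
    recombination_loss,
)

BREED_SAMPLING_WEIGHTS = {
    # marginal breed frequencies used to draw parental compositions
    "Texel": 0.30, "Suffolk": 0.22, "Belclare": 0.15, "Cheviot": 0.09,
    "Charollais": 0.08, "Lleyn": 0.06, "Blackface Mountain": 0.04,
    "Vendeen": 0.03, "Other": 0.03,
}

PAC_CAPACITY = 12


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated cohort dataset."""

    cohort: str = "growing"
    n_flocks: int = 8
    n_animals: int = 1000
    #: distribution of methane-record counts per animal
    records_per_animal: dict = field(
        default_factory=lambda: {1: 0.72, 2: 0.12, 3: 0.06, 4: 0.06, 5: 0.04}
    )
    variance_components: dict = field(
        default_factory=lambda: {"cg_var": 7.5, "animal_var": 4.94, "resid_var": 14.06}
    )
    fixed_effects: dict = field(
        default_factory=lambda: {
            "mu": 13.7,
            "sex_effect": 0.8,             # males minus females, g/d
            "lactation_effect": 0.0,       # lactating minus dry (ewes), g/d
            "birth_litter_effects": {1: 0.0, 2: 0.3, 3: 0.5},
            "rearing_litter_effects": {1: 0.0, 2: 0.25, 3: 0.4},
            "age_slope": 0.15,             # g/d per month (growing) or year (ewes)
            "heterosis_slope": -0.5,
            "recombination_slope": 0.3,
            "breed_effects": {
                "Charollais": -2.1, "Belclare": -1.0, "Cheviot": -1.5, "Texel": 0.5
            },                             # g/d per unit breed proportion, vs Suffolk
        }
    )
    trait_links: dict = field(
        default_factory=lambda: {"ch4_per_kg_mbw": 0.25, "ch4_per_kg_dmi": 2.0}
    )
    body_weight: dict = field(
        default_factory=lambda: {
            "mean": 42.0, "animal_sd": 8.0, "record_sd": 1.2,
            "growth_rate_mean": 0.25, "growth_rate_sd": 0.055,  # kg/d
            "window": (25.0, 80.0),
        }
    )
    dmi: dict = field(
        default_factory=lambda: {
            "mean": 1.53, "sd": 0.55, "per_kg_bw": 0.02,
            "fraction_measured": 0.10, "measurement_sd": 0.12, "outlier_rate": 0.02,
        }
    )
    co2: dict = field(
        default_factory=lambda: {
            "mean": 690.0, "per_g_ch4": 10.0, "per_kg_bw": 6.0, "sd": 120.0,
            "outlier_rate": 0.003,
        }
    )
    production: dict = field(
        default_factory=lambda: {
            "weights_fraction": 0.55, "carcass_fraction": 0.30, "ct_fraction": 0.25
        }
    )
    female_fraction: float = 0.63
    lactating_fraction: float = 0.26
    seed: int = 0

    def validate(self) -> None:
        if self.cohort not in ("growing", "ewe"):
            raise ConfigurationError(f"unknown cohort {self.cohort!r}")
        if self.n_animals < 1 or self.n_flocks < 1:
            raise ConfigurationError("empty cohort: n_animals and n_flocks must be >= 1")
        for k, v in self.variance_components.items():
            if v < 0:
                raise ConfigurationError(f"negative variance {k}={v}")
        if not self.records_per_animal:
            raise ConfigurationError("records_per_animal distribution is empty")
        for k, p in self.records_per_animal.items():
            if int(k) < 1 or p < 0:
                raise ConfigurationError("records_per_animal needs counts >= 1, probs >= 0")
        tot = sum(self.records_per_animal.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(f"records_per_animal probabilities sum to {tot}")
        for frac in (self.female_fraction, self.lactating_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")


def default_config(cohort: str = "growing", seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort-specific default configuration.

    Ewe defaults: mean methane ~21 g/d (SD ~8), repeatability 0.34, body
    weight 55-100 kg, pasture DMI mean 1.86 kg/d, 26% of records during
    lactation.  Any field can be overridden by keyword.
    """
    cfg = SimulationConfig(cohort=cohort, seed=seed)
    if cohort == "ewe":
        cfg.variance_components = {"cg_var": 17.0, "animal_var": 15.0, "resid_var": 29.0}
        cfg.fixed_effects = {
            **cfg.fixed_effects,
            "mu": 20.8, "sex_effect": 0.0, "lactation_effect": 1.0, "age_slope": 0.2,
            "breed_effects": {"Charollais": -1.0, "Belclare": -2.2, "Cheviot": -4.4,
                              "Texel": 0.5},
        }
        cfg.body_weight = {
            "mean": 75.0, "animal_sd": 8.5, "record_sd": 2.0,
            "growth_rate_mean": 0.0, "growth_rate_sd": 0.0, "window": (55.0, 100.0),
        }
        cfg.dmi = {**cfg.dmi, "mean": 1.86, "sd": 0.65, "per_kg_bw": 0.03}
        cfg.co2 = {**cfg.co2, "mean": 1000.0, "per_kg_bw": 4.0, "sd": 160.0}
        cfg.production = {"weights_fraction": 0.0, "carcass_fraction": 0.0,
                          "ct_fraction": 0.0}
        cfg.female_fraction = 1.0
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigurationError(f"unknown configuration field {k!r}")
        setattr(cfg, k, v)
    return cfg


def repeatability_config(cohort: str, R: float, total_var: float | None = None,
                         seed: int = 0, **overrides) -> SimulationConfig:
    """Configuration whose true animal-variance fraction is exactly ``R``.

    ``R`` partitions the non-group variance: animal_var = R * V and
    resid_var = (1 - R) * V with V the cohort default animal+residual total.
    Every systematic effect and trait link is switched off: sex, breed and
    body-weight effects are animal-level constants that would silently add to
    the between-animal variance, so leaving them on would make the realised
    fraction differ from the nominal ``R`` this configuration promises.
    """
    cfg = default_config(cohort, seed=seed, **overrides)
    if total_var is None:
        vc = cfg.variance_components
        total_var = vc["animal_var"] + vc["resid_var"]
    cfg.variance_components = {
        "cg_var": cfg.variance_components["cg_var"],
        "animal_var": R * total_var,
        "resid_var": (1.0 - R) * total_var,
    }
    cfg.fixed_effects = {
        **cfg.fixed_effects,
        "sex_effect": 0.0, "lactation_effect": 0.0, "age_slope": 0.0,
        "heterosis_slope": 0.0, "recombination_slope": 0.0, "breed_effects": {},
        "birth_litter_effects": {1: 0.0, 2: 0.0, 3: 0.0},
        "rearing_litter_effects": {1: 0.0, 2: 0.0, 3: 0.0},
    }
    cfg.trait_links = {"ch4_per_kg_mbw": 0.0, "ch4_per_kg_dmi": 0.0}
    return cfg


# ---------------------------------------------------------------------------


def _sample_parent(rng: np.random.Generator) -> BreedVector:
    """Purebred (50%), F1 (25%), or Dirichlet 3-breed composite (25%)."""
    names = list(BREED_SAMPLING_WEIGHTS)
    probs = np.array(list(BREED_SAMPLING_WEIGHTS.values()))
    probs = probs / probs.sum()
    kind = rng.random()
    if kind < 0.50:
        b = rng.choice(names, p=probs)
        return BreedVector({b: 1.0})
    if kind < 0.75:
        a, b = rng.choice(names, size=2, replace=False, p=probs)
        return BreedVector({a: 0.5, b: 0.5})
    picks = rng.choice(names, size=3, replace=False, p=probs)
    w = rng.dirichlet(np.ones(3))
    return BreedVector(dict(zip(picks, np.round(w / w.sum(), 6) / np.round(w / w.sum(), 6).sum())))


def simulate_flocks(config: SimulationConfig) -> dict:
    """Generate a dataset bundle with the configured statistical structure.

    Returns a dict of DataFrames: ``animals``, ``emissions``, ``dmi``,
    ``weights``, ``carcass``, ``ct``, ``maternal``, ``truth``.  Identical
    configuration and seed give byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort = config.cohort
    growing = cohort == "growing"
    fe = config.fixed_effects
    vc = config.variance_components
    bw_cfg = config.body_weight

    n = config.n_animals
    ids = [f"{'G' if growing else 'E'}{i:05d}" for i in range(1, n + 1)]
    flocks = rng.integers(0, config.n_flocks, size=n)
    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")
    if not growing:
        sexes = np.full(n, "female")
    birth_ls = rng.choice([1, 2, 3], size=n, p=[0.35, 0.50, 0.15])
    rear_ls = np.minimum(birth_ls, rng.choice([1, 2, 3], size=n, p=[0.40, 0.50, 0.10]))

    counts_k = np.array(sorted(config.records_per_animal), dtype=int)
    counts_p = np.array([config.records_per_animal[int(k)] for k in counts_k], float)
    counts_p = counts_p / counts_p.sum()
    n_records = rng.choice(counts_k, size=n, p=counts_p)

    parents = [( _sample_parent(rng), _sample_parent(rng)) for _ in range(n)]
    het = np.array([heterosis_coefficient(s, d) for s, d in parents])
    rec = np.array([recombination_loss(s, d) for s, d in parents])
    breed_frac = [animal_breed_fractions(s, d) for s, d in parents]

    # sessions: flock x date; an animal's records land on consecutive sessions
    sessions: dict[int, list[pd.Timestamp]] = {}
    max_r = int(n_records.max())
    for f in range(config.n_flocks):
        nf_rec = int(n_records[flocks == f].sum())
        n_sess = max(max_r, int(np.ceil(nf_rec / 24.0)), 2)
        year = 2019 + f % 6
        offs = np.sort(rng.choice(np.arange(0, 271), size=min(n_sess, 271), replace=False))
        sessions[f] = [pd.Timestamp(f"{year}-03-01") + pd.Timedelta(days=int(o)) for o in offs]

    animal_sessions = []
    for i in range(n):
        sess = sessions[int(flocks[i])]
        r = int(n_records[i])
        start = int(rng.integers(0, max(len(sess) - r, 0) + 1))
        animal_sessions.append(list(range(start, start + r)))

    # ages and birth dates anchored to the first measurement
    if growing:
        age0 = np.clip(rng.normal(210, 45, n), 110, 420).round()
    else:
        years = rng.choice(np.arange(1, 8), size=n,
                           p=[0.18, 0.20, 0.18, 0.15, 0.12, 0.09, 0.08])
        age0 = np.clip(years * 365 + rng.uniform(20, 300, n), 385, 3500).round()
    first_dates = [sessions[int(flocks[i])][animal_sessions[i][0]] for i in range(n)]
    birth_dates = [d - pd.Timedelta(days=int(a)) for d, a in zip(first_dates, age0)]

    base_bw = rng.normal(bw_cfg["mean"], bw_cfg["animal_sd"], n)
    growth = rng.normal(bw_cfg["growth_rate_mean"], bw_cfg["growth_rate_sd"] or 0.0, n)
    animal_eff = rng.normal(0.0, np.sqrt(vc["animal_var"]), n)

    lo, hi = bw_cfg["window"]
    eps = 1e-3
    rows = []
    for i in range(n):
        sess = sessions[int(flocks[i])]
        d0 = sess[animal_sessions[i][0]]
        for s in animal_sessions[i]:
            date = sess[s]
            dt = (date - d0).days
            bw = base_bw[i] + growth[i] * dt + rng.normal(0.0, bw_cfg["record_sd"])
            bw = float(np.clip(bw, lo + eps, hi - eps))
            rows.append({"animal_idx": i, "flock_id": f"F{int(flocks[i]) + 1:02d}",
                         "session": s, "measurement_date": date,
                         "body_weight_kg": bw,
                         "age_days": int((date - birth_dates[i]).days)})
    emissions = pd.DataFrame(rows)

    # chamber runs within each session; the remainder run may fall under 5 head
    emissions["pac_run"] = 0
    cg_labels = pd.Series(index=emissions.index, dtype=object)
    for (fid, date), grp in emissions.groupby(["flock_id", "measurement_date"], sort=True):
        order = grp.index.to_numpy()
        rng.shuffle(order)
        run_no = np.arange(len(order)) // PAC_CAPACITY + 1
        emissions.loc[order, "pac_run"] = run_no
        for idx, r in zip(order, run_no):
            cg_labels.loc[idx] = f"{fid}|{date.date()}|{r}"
    emissions["pac_run"] = emissions["pac_run"].astype(int)

    cg_keys = sorted(cg_labels.unique())
    cg_effects = dict(zip(cg_keys, rng.normal(0.0, np.sqrt(vc["cg_var"]), len(cg_keys))))

    mbw = emissions["body_weight_kg"].to_numpy() ** 0.75
    idx = emissions["animal_idx"].to_numpy()
    latent_dmi = (config.dmi["mean"]
                  + config.dmi["per_kg_bw"] * (emissions["body_weight_kg"].to_numpy()
                                               - bw_cfg["mean"])
                  + rng.normal(0.0, config.dmi["sd"], len(emissions)))
    latent_dmi = np.clip(latent_dmi, 0.30, None)

    fixed = np.full(len(emissions), fe["mu"], dtype=float)
    if growing:
        fixed += np.where(sexes[idx] == "male", fe["sex_effect"], 0.0)
        fixed += fe["age_slope"] * (emissions["age_days"].to_numpy() / 30.437 - 7.0)
    else:
        lactating = rng.random(len(emissions)) < config.lactating_fraction
        fixed += np.where(lactating, fe["lactation_effect"], 0.0)
        fixed += fe["age_slope"] * (emissions["age_days"].to_numpy() / 365.25 - 3.8)
    fixed += np.vectorize(lambda i: fe["birth_litter_effects"][int(birth_ls[i])])(idx)
    fixed += np.vectorize(lambda i: fe["rearing_litter_effects"][int(rear_ls[i])])(idx)
    fixed += fe["heterosis_slope"] * het[idx] + fe["recombination_slope"] * rec[idx]
    breed_term = np.array([
        sum(fe["breed_effects"].get(b, 0.0) * f for b, f in breed_frac[i].items())
        for i in idx
    ])
    fixed += breed_term
    fixed += config.trait_links["ch4_per_kg_mbw"] * (mbw - mbw.mean())
    fixed += config.trait_links["ch4_per_kg_dmi"] * (latent_dmi - latent_dmi.mean())

    cg_eff = cg_labels.map(cg_effects).to_numpy(dtype=float)
    resid = rng.normal(0.0, np.sqrt(vc["resid_var"]), len(emissions))
    ch4 = fixed + cg_eff + animal_eff[idx] + resid

    co2 = (config.co2["mean"]
           + config.co2["per_g_ch4"] * (ch4 - ch4.mean())
           + config.co2["per_kg_bw"] * (emissions["body_weight_kg"].to_numpy()
                                        - bw_cfg["mean"])
           + rng.normal(0.0, config.co2["sd"], len(emissions)))
    hot = rng.random(len(emissions)) < config.co2["outlier_rate"]
    co2 = np.where(hot, co2 * rng.uniform(2.5, 4.0, len(emissions)), co2)
    co2 = np.clip(co2, 50.0, None)

    emissions["animal_id"] = [ids[i] for i in idx]
    emissions["record_id"] = [f"R{k:06d}" for k in range(1, len(emissions) + 1)]
    emissions["ch4_g_d"] = ch4
    emissions["co2_g_d"] = co2
    emissions["cohort"] = cohort
    if not growing:
        emissions["lactation_status"] = np.where(lactating, "lactating", "dry")
    truth = pd.DataFrame({
        "record_id": emissions["record_id"],
        "fixed_part": fixed,
        "cg_effect": cg_eff,
        "animal_effect": animal_eff[idx],
        "residual": resid,
        "latent_dmi_kg_d": latent_dmi,
    })

    animals = pd.DataFrame({
        "animal_id": ids,
        "flock_id": [f"F{f + 1:02d}" for f in flocks],
        "sex": sexes,
        "birth_date": birth_dates,
        "birth_litter_size": birth_ls,
        "rearing_litter_size": rear_ls,
        "n_lambings": 0 if growing else rng.integers(1, 6, n),
    })
    for role, k in (("sire", 0), ("dam", 1)):
        for b in KNOWN_BREEDS:
            animals[f"{role}_{b}"] = [p[k][b] for p in parents]
    if growing:
        animals["weaning_weight_kg"] = np.round(
            35.0 + 0.30 * (base_bw - bw_cfg["mean"]) + rng.normal(0.0, 3.0, n), 2
        )

    dmi_rows, weight_rows, carcass_rows, ct_rows, maternal_rows = [], [], [], [], []
    first_rec = emissions.groupby("animal_idx").first()
    last_rec = emissions.groupby("animal_idx").last()

    dmi_sel = rng.random(n) < config.dmi["fraction_measured"]
    for i in np.where(dmi_sel)[0]:
        n_meas = 1 if growing else (2 if rng.random() < 0.9 else 1)
        anchor = first_rec.loc[i, "measurement_date"]
        for _ in range(n_meas):
            off = int(rng.integers(-25, 26))
            if rng.random() < 0.05:
                off = int(np.sign(off or 1) * rng.integers(31, 45))
            val = truth.loc[emissions["animal_idx"] == i, "latent_dmi_kg_d"].iloc[0]
            val = val + rng.normal(0.0, config.dmi["measurement_sd"])
            if rng.random() < config.dmi["outlier_rate"]:
                val *= 2.5
            dmi_rows.append({"animal_id": ids[i],
                             "date": anchor + pd.Timedelta(days=off),
                             "dmi_kg_d": round(max(val, 0.2), 3)})

    if growing:
        w_sel = rng.random(n) < config.production["weights_fraction"]
        for i in np.where(w_sel)[0]:
            anchor = first_rec.loc[i, "measurement_date"]
            k = int(rng.integers(3, 6))
            offs = np.sort(rng.choice(np.arange(-100, 101), size=k, replace=False))
            for off in offs:
                w = (base_bw[i] + growth[i] * float(off)
                     + rng.normal(0.0, 0.8))
                weight_rows.append({"animal_id": ids[i],
                                    "date": anchor + pd.Timedelta(days=int(off)),
                                    "weight_kg": round(max(w, 5.0), 2)})
        c_sel = rng.random(n) < config.production["carcass_fraction"]
        for i in np.where(c_sel)[0]:
            last_date = last_rec.loc[i, "measurement_date"]
            s_date = last_date + pd.Timedelta(days=int(rng.integers(3, 41)))
            bw_last = last_rec.loc[i, "body_weight_kg"]
            cw = 0.42 * bw_last + rng.normal(0.0, 1.3)
            carcass_rows.append({
                "animal_id": ids[i], "slaughter_date": s_date,
                "carcass_weight_kg": round(float(cw), 2),
                "age_at_slaughter_d": int((s_date - birth_dates[i]).days),
            })
        t_sel = rng.random(n) < config.production["ct_fraction"]
        for i in np.where(t_sel)[0]:
            anchor = first_rec.loc[i, "measurement_date"]
            bw0 = first_rec.loc[i, "body_weight_kg"]
            muscle = max(0.27 * bw0 + rng.normal(0.0, 1.5), 3.0)
            fat = max(0.08 * bw0 + rng.normal(0.0, 1.0), 0.5)
            ct_rows.append({
                "animal_id": ids[i],
                "scan_date": anchor + pd.Timedelta(days=int(rng.integers(-5, 6))),
                "fat_mass_kg": round(fat, 2),
                "muscle_mass_kg": round(muscle, 2),
                "kill_out_pct": round(float(np.clip(rng.normal(0.45, 0.04), 0.30, 0.60)), 3),
                "muscle_fat_ratio": round(muscle / fat, 3),
                "rumen_volume_l": round(float(np.clip(0.14 * bw0 + rng.normal(0.0, 1.0),
                                                      1.5, 13.0)), 2),
            })
    else:
        born = rng.choice([1, 2, 3], size=n, p=[0.30, 0.52, 0.18])
        reared = np.maximum(1, born - (rng.random(n) < 0.15))
        for i in range(n):
            maternal_rows.append({
                "animal_id": ids[i],
                "n_lambs_born": int(born[i]),
                "n_lambs_reared": int(reared[i]),
                "litter_weaning_weight_kg": round(29.0 * reared[i] + rng.normal(0.0, 4.0), 1),
                "bcs": int(np.clip(np.round(rng.normal(3.0, 0.7)), 1, 5)),
                "mating_weight_kg": round(base_bw[i] + rng.normal(0.0, 3.0), 1),
            })

    cols = ["record_id", "animal_id", "flock_id", "measurement_date", "pac_run",
            "ch4_g_d", "co2_g_d", "body_weight_kg", "age_days", "cohort"]
    if not growing:
        cols.append("lactation_status")
    emissions = emissions[cols].copy()
    emissions["ch4_g_d"] = emissions["ch4_g_d"].round(6)
    emissions["co2_g_d"] = emissions["co2_g_d"].round(4)
    emissions["body_weight_kg"] = emissions["body_weight_kg"].round(3)

    def _df(rows, columns):
        return pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)

    return {
        "animals": animals,
        "emissions": emissions,
        "dmi": _df(dmi_rows, ["animal_id", "date", "dmi_kg_d"]),
        "weights": _df(weight_rows, ["animal_id", "date", "weight_kg"]),
        "carcass": _df(carcass_rows, ["animal_id", "slaughter_date",
                                      "carcass_weight_kg", "age_at_slaughter_d"]),
        "ct": _df(ct_rows, ["animal_id", "scan_date", "fat_mass_kg", "muscle_mass_kg",
                            "kill_out_pct", "muscle_fat_ratio", "rumen_volume_l"]),
        "maternal": _df(maternal_rows, ["animal_id", "n_lambs_born", "n_lambs_reared",
                                        "litter_weaning_weight_kg", "bcs",
                                        "mating_weight_kg"]),
        "truth": truth,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["body_weight"]["window"] = list(d["body_weight"]["window"])
    return d
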