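"""Derived covariates: crossbreeding coefficients, metabolic body weight, growth rate.

Heterosis and recombination-loss coefficients summarise an animal's expected
non-additive breed composition from the breed fractions of its sire and dam.
Metabolic body weight is the classic interspecies metabolic-rate scaling
``BW^0.75``.  Average daily gain is the OLS slope of repeated body weights in
a window around the methane measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Breeds tracked explicitly; anything else is pooled into "Other".
KNOWN_BREEDS = (
    "Belclare",
    "Blackface Mountain",
    "Charollais",
    "Cheviot",
    "Lleyn",
    "Suffolk",
    "Texel",
    "Vendeen",
    "Other",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BreedVector:
    """Breed composition of a single parent: breed name -> proportion.

    Proportions must be non-negative and sum to 1 (within ``1e-9``).  Breeds
    outside :data:`KNOWN_BREEDS` are pooled into ``"Other"`` at construction.
    """

    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        pooled: dict[str, float] = {}
        for breed, frac in self.fractions.items():
            frac = float(frac)
            if frac < 0:
                raise ValueError(f"negative breed fraction for {breed!r}: {frac}")
            key = breed if breed in KNOWN_BREEDS else "Other"
            pooled[key] = pooled.get(key, 0.0) + frac
        total = sum(pooled.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"breed fractions sum to {total!r}, expected 1")
        object.__setattr__(self, "fractions", pooled)

    def __getitem__(self, breed: str) -> float:
        return self.fractions.get(breed, 0.0)

    @property
    def breeds(self) -> set[str]:
        return {b for b, f in self.fractions.items() if f > 0}


def heterosis_coefficient(sire: BreedVector, dam: BreedVector) -> float:
    """Expected fraction of loci carrying alleles from two different breeds.

    ``1 - sum_i sire_i * dam_i`` over the union of parental breeds.  A purebred
    mating within one breed gives 0; a first cross between two distinct
    purebreds gives 1.
    """
    shared = sire.breeds | dam.breeds
    return 1.0 - sum(sire[b] * dam[b] for b in shared)


def recombination_loss(sire: BreedVector, dam: BreedVector) -> float:
    """Expected loss of favourable breed epistatic combinations.

    ``1 - (sum_i sire_i^2 + sum_i dam_i^2) / 2``.  Zero iff both parents are
    purebred (of any breeds); it grows as either parent becomes more admixed.
    """
    ss = sum(f * f for f in sire.fractions.values())
    sd = sum(f * f for f in dam.fractions.values())
    return 1.0 - (ss + sd) / 2.0


def animal_breed_fractions(sire: BreedVector, dam: BreedVector) -> dict[str, float]:
    """Breed composition of the offspring: mid-parent breed fractions."""
    breeds = sire.breeds | dam.breeds
    return {b: (sire[b] + dam[b]) / 2.0 for b in breeds}


def metabolic_body_weight(bw):
    """Metabolic body weight ``BW^0.75`` (kg). Accepts scalars or arrays."""
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    out = bw**0.75
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WeightSeries:
    """Repeated body weights of one animal as (date, kg) pairs.

    Dates must be strictly increasing, weights positive.  Duplicate dates with
    conflicting weights are rejected; exact duplicates are collapsed.
    """

    animal_id: str
    dates: tuple
    weights: tuple

    @classmethod
    def from_records(cls, animal_id: str, records: Iterable[tuple]) -> "WeightSeries":
        seen: dict[pd.Timestamp, float] = {}
        for d, w in records:
            d = pd.Timestamp(d)
            w = float(w)
            if w <= 0:
                raise ValueError(f"non-positive weight {w} for {animal_id}")
            if d in seen and abs(seen[d] - w) > 1e-9:
                raise ValueError(
                    f"conflicting weights on {d.date()} for {animal_id}: {seen[d]} vs {w}"
                )
            seen[d] = w
        dates = tuple(sorted(seen))
        return cls(animal_id, dates, tuple(seen[d] for d in dates))


def average_daily_gain(
    series: WeightSeries,
    methane_date,
    window_days: int = 120,
) -> float | None:
    """OLS growth rate (g/d) from weights within ``±window_days`` of the methane date.

    Returns None when fewer than two weights fall inside the window (the trait
    is then unavailable for that record).  The regression abscissa is days
    since the first in-window weight; the slope is converted kg/d -> g/d.
    Values outside the plausibility band used downstream (150-350 g/d) are
    still returned here -- retention is a QC decision, not a computation one.
    """
    methane_date = pd.Timestamp(methane_date)
    lo = methane_date - pd.Timedelta(days=window_days)
    hi = methane_date + pd.Timedelta(days=window_days)
    pts = [(d, w) for d, w in zip(series.dates, series.weights) if lo <= d <= hi]
    if len(pts) < 2:
        return None
    t0 = pts[0][0]
    x = np.array([(d - t0).days for d, _ in pts], dtype=float)
    y = np.array([w for _, w in pts], dtype=float)
    if np.ptp(x) == 0:
        return None
    slope = np.polyfit(x, y, 1)[0]  # kg/d
    return float(slope * 1000.0)


def compute_covariates(
    animals: pd.DataFrame,
    emissions: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    adg_window_days: int = 120,
) -> pd.DataFrame:
    """Per-record covariate table: heterosis, recombination, MBW, ADG.

    ``animals`` must carry ``sire_<breed>`` / ``dam_<breed>`` columns;
    ``emissions`` one row per methane record with ``body_weight_kg`` and
    ``measurement_date``.  ADG is only computed where a weight series exists.
    """
    sire_cols = {c: c[len("sire_") :] for c in animals.columns if c.startswith("sire_")}
    dam_cols = {c: c[len("dam_") :] for c in animals.columns if c.startswith("dam_")}
    per_animal = {}
    for rowd in animals.to_dict("records"):
        sire = BreedVector({b: rowd[c] for c, b in sire_cols.items()})
        dam = BreedVector({b: rowd[c] for c, b in dam_cols.items()})
        rec = {
            "heterosis": heterosis_coefficient(sire, dam),
            "recombination": recombination_loss(sire, dam),
        }
        for b, f in animal_breed_fractions(sire, dam).items():
            rec[f"breed_{b}"] = f
        per_animal[rowd["animal_id"]] = rec

    series_by_animal: dict[str, WeightSeries] = {}
    if weights is not None and len(weights):
        for aid, grp in weights.groupby("animal_id"):
            series_by_animal[aid] = WeightSeries.from_records(
                aid, zip(grp["date"], grp["weight_kg"])
            )

    out = []
    for rowd in emissions.to_dict("records"):
        aid = rowd["animal_id"]
        rec = {
            "record_id": rowd["record_id"],
            "animal_id": aid,
            "mbw_kg": metabolic_body_weight(rowd["body_weight_kg"]),
        }
        rec.update(per_animal.get(aid, {}))
        if aid in series_by_animal:
            adg = average_daily_gain(
                series_by_animal[aid], rowd["measurement_date"], adg_window_days
            )
            if adg is not None:
                rec["adg_g_d"] = adg
        out.append(rec)
    df = pd.DataFrame(out)
    breed_cols = [c for c in df.columns if c.startswith("breed_")]
    df[breed_cols] = df[breed_cols].fillna(0.0)
    return df
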