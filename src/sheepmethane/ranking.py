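"""Correlations among metrics and the top-quartile selection comparison.

Correlations are record-level Pearson coefficients over pairwise-complete
records, with the large-sample standard error sqrt((1 - r^2)/(n - 2)).

The selection comparison ranks animals under several methane metrics: each
animal is represented by its most efficient (lowest) record per metric,
animals are sorted ascending, and the best round(0.25 n) are selected; group
means of intake, methane, weight and cohort-specific traits are then compared
across the per-metric selections with Welch t-tests, Holm-adjusted, and
annotated with compact significance letters.  The selected groups overlap in
membership (an animal can be efficient under several metrics); the letters
are descriptive, not independent-sample inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RANKING_METRICS = ("ch4_g_d", "mi_mbw", "my", "RMT_MBW+DMI")


@dataclass
class CorrelationCell:
    trait_a: str
    trait_b: str
    r: float | None
    se: float | None
    n: int


def correlate(values_a, values_b, name_a: str = "a", name_b: str = "b") -> CorrelationCell:
    """Pearson correlation over pairwise-complete observations."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = int(a.size)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationCell(name_a, name_b, None, None, n)
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    se = float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))
    return CorrelationCell(name_a, name_b, r, se, n)


def correlation_table(df: pd.DataFrame, cols_a, cols_b=None, min_n: int = 3) -> pd.DataFrame:
    """Long-format correlation table between two sets of trait columns."""
    cols_b = list(cols_b) if cols_b is not None else list(cols_a)
    rows = []
    for a in cols_a:
        for b in cols_b:
            if a == b:
                continue
            ok = df[[a, b]].dropna()
            if len(ok) < min_n:
                continue
            cell = correlate(ok[a], ok[b], a, b)
            rows.append({"trait_a": a, "trait_b": b, "r": cell.r, "se": cell.se,
                         "n": cell.n})
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "se", "n"])


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def _significance_letters(groups: list, pairs: dict) -> dict:
    """Compact letter display: groups sharing a letter do not differ (p >= .05)."""
    letters: dict[str, str] = {g: "" for g in groups}
    cliques: list[set] = []
    for g in groups:
        placed = False
        for clique in cliques:
            if all(pairs.get(frozenset((g, h)), 1.0) >= 0.05 for h in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def rank_top_quartile(
    data: pd.DataFrame,
    metrics=DEFAULT_RANKING_METRICS,
    group_traits=("dmi_kg_d", "ch4_g_d", "body_weight_kg"),
    quantile: float = 0.25,
) -> pd.DataFrame:
    """Top-quartile selection under each metric, with group trait means.

    ``data`` has one row per record with metric and trait columns plus
    ``animal_id``.  Only animals with complete data for every metric (on at
    least one record per metric) enter; each animal's ranking record per
    metric is its minimum.  Ties at the quartile boundary break by ascending
    animal id.  Returns one row per metric with the selected ids, group means
    and SDs over the selected animals' ranking records, and Holm-adjusted
    Welch significance letters per trait in ``.attrs["letters"]``.
    """
    metrics = list(metrics)
    per_animal = {}
    for m in metrics:
        sub = data.dropna(subset=[m])
        if not len(sub):
            raise ValueError(f"metric {m!r} has no complete records")
        best = sub.loc[sub.groupby("animal_id")[m].idxmin()]
        per_animal[m] = best.set_index("animal_id")
    complete = sorted(set.intersection(*(set(v.index) for v in per_animal.values())))
    n = len(complete)
    if n < 8:
        raise ValueError(f"only {n} complete-case animals; need >= 8")
    k = _round_half_away(quantile * n)

    selections: dict[str, pd.DataFrame] = {}
    rows = []
    for m in metrics:
        best = per_animal[m].loc[complete]
        order = best.sort_values([m, "animal_id"], kind="mergesort")
        chosen = order.iloc[:k]
        selections[m] = chosen
        row = {"metric": m, "n_complete": n, "n_selected": k,
               "selected_ids": ";".join(chosen.index)}
        for t in group_traits:
            if t in chosen.columns:
                v = chosen[t].dropna()
                row[f"{t}_mean"] = float(v.mean()) if len(v) else np.nan
                row[f"{t}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        rows.append(row)
    report = pd.DataFrame(rows)

    letters: dict[str, dict] = {}
    for t in group_traits:
        raw = {}
        for i, ma in enumerate(metrics):
            for mb in metrics[i + 1:]:
                va = selections[ma][t].dropna() if t in selections[ma] else pd.Series(dtype=float)
                vb = selections[mb][t].dropna() if t in selections[mb] else pd.Series(dtype=float)
                if len(va) > 1 and len(vb) > 1:
                    raw[frozenset((ma, mb))] = stats.ttest_ind(va, vb, equal_var=False).pvalue
        if raw:
            keys = list(raw)
            pvals = [raw[k_] for k_ in keys]
            adj = _holm(pvals)
            letters[t] = _significance_letters(metrics, dict(zip(keys, adj)))
    report.attrs["letters"] = letters
    return report


def _holm(pvals):
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()
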