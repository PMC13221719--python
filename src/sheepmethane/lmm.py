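"""Linear mixed models with crossed random intercepts, fitted by EM-REML.

This is the computational core of the package: every residual methane trait,
repeatability estimate, and marginal-mean comparison rests on it.  The model is

    y = X b + Z_1 u_1 + ... + Z_k u_k + e,
    u_r ~ N(0, sigma_r^2 I),   e ~ N(0, sigma_e^2 I),

with X a full-rank fixed-effect design (intercept, categorical factors with a
declared reference level, continuous covariates) and each Z_r an indicator
matrix for a grouping factor (contemporary group, animal).  Variance
components are estimated by EM iterations on Henderson's mixed-model
equations; the EM update for sigma_r^2 is

    sigma_r^2  <-  ( u_r' u_r + sigma_e^2 tr(C^rr) ) / q_r

where C^rr is the block of the inverse MME coefficient matrix for u_r, and
sigma_e^2 <- e'y / (n - rank(X)).  EM is monotone in the restricted
likelihood and respects the parameter boundary, at the price of linear
convergence -- which is cheap here because each iteration reduces to a dense
solve of dimension p + q_small after absorbing the largest random factor
through its (diagonal) block.  Grouping that factor's levels by record count
makes the absorbed cross-product a small sum of precomputed matrices, so the
per-iteration cost is essentially independent of the number of animals.

Variances are floored at ``VAR_FLOOR`` rather than allowed negative;
convergence is declared when the largest relative component change drops
below ``rtol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import sparse, stats

VAR_FLOOR = 1e-10


class RankDeficiencyError(ValueError):
    """Fixed-effect design is singular; names the aliased columns."""


class ConvergenceError(RuntimeError):
    """A fit flagged as non-converged was used where convergence is required."""


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``factors`` maps a categorical column to its reference level (None picks
    the first level in sorted order).  ``random_terms`` are grouping columns
    fitted as independent random intercepts.
    """

    response: str
    factors: dict = field(default_factory=dict)
    covariates: list = field(default_factory=list)
    random_terms: list = field(default_factory=list)
    cohort: str | None = None


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    columns: list
    covariate_means: dict
    factor_levels: dict        # factor -> list of levels (reference first)
    factor_columns: dict       # factor -> {level: column index or None for ref}
    random_codes: dict         # term -> integer codes per record
    random_levels: dict        # term -> level labels


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Construct the design matrices for ``spec`` from ``data``.

    All referenced columns must be present and complete (no NaN); rows with
    missing values must be dropped by the caller so that record bookkeeping
    stays explicit.
    """
    needed = [spec.response, *spec.factors, *spec.covariates, *spec.random_terms]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"model terms absent from data: {missing}")
    sub = data[needed]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"NaN values in model terms {bad}; drop incomplete rows first")

    n = len(data)
    y = data[spec.response].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    factor_levels: dict = {}
    factor_columns: dict = {}
    for fac, ref in spec.factors.items():
        vals = data[fac].astype(str)
        levels = sorted(vals.unique())
        ref = str(ref) if ref is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from factor {fac!r}")
        levels = [ref] + [l for l in levels if l != ref]
        factor_levels[fac] = levels
        factor_columns[fac] = {ref: None}
        for lev in levels[1:]:
            factor_columns[fac][lev] = len(names)
            names.append(f"{fac}[{lev}]")
            cols.append((vals == lev).to_numpy(dtype=float))
    covariate_means = {}
    for cov in spec.covariates:
        v = data[cov].to_numpy(dtype=float)
        covariate_means[cov] = float(v.mean())
        names.append(cov)
        cols.append(v)
    X = np.column_stack(cols)

    _check_full_rank(X, names)

    random_codes, random_levels = {}, {}
    for term in spec.random_terms:
        codes, levels = pd.factorize(data[term], sort=True)
        if len(levels) < 2:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")
        random_codes[term] = codes.astype(np.int64)
        random_levels[term] = list(levels)
    return Design(y, X, names, covariate_means, factor_levels, factor_columns,
                  random_codes, random_levels)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (d[0] if d.size else 0.0)
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )


# ---------------------------------------------------------------------------
# EM-REML core
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged mixed-model fit: estimates, components, predictions."""

    beta: pd.Series
    beta_se: pd.Series
    beta_cov: pd.DataFrame
    varcomps: dict                 # term -> sigma^2, plus "residual"
    blups: dict                    # term -> Series of level predictions
    reml_loglik: float
    n_iterations: int
    converged: bool
    n: int
    design: Design
    spec: ModelSpec

    def require_converged(self) -> "FitResult":
        if not self.converged:
            raise ConvergenceError(
                "REML did not converge; refusing downstream use of this fit"
            )
        return self

    def fitted_fixed(self) -> np.ndarray:
        """X @ beta per record of the fitting data."""
        return self.design.X @ self.beta.to_numpy()

    def blup_per_record(self, term: str) -> np.ndarray:
        return self.blups[term].to_numpy()[self.design.random_codes[term]]


def _em_reml(y, X, random_codes: dict, rtol=1e-10, max_iter=30000,
             init: dict | None = None):
    """EM-REML on Henderson's MME, absorbing the largest random factor.

    Returns (beta, beta_cov_unscaled, varcomps, blups, loglik, iters, converged)
    where beta_cov_unscaled * sigma_e^2 is Cov(beta).
    """
    n, p = X.shape
    if n - p < 1:
        raise ValueError(
            f"too few records (n={n}) to estimate a residual variance alongside "
            f"{p} fixed-effect columns"
        )
    terms = list(random_codes)
    qs = {t: int(random_codes[t].max()) + 1 for t in terms}
    for t in terms:
        if qs[t] >= n:
            raise ValueError(
                f"random term {t!r} has one record per level; its variance is "
                "confounded with the residual and cannot be estimated"
            )

    if not terms:  # plain OLS via the same REML bookkeeping
        XtX = X.T @ X
        Xty = X.T @ y
        beta = sla.solve(XtX, Xty, assume_a="pos")
        sse = float(y @ y - beta @ Xty)
        sig_e = max(sse / (n - p), VAR_FLOOR)
        sign, logdet = np.linalg.slogdet(XtX)
        m2l = ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(sig_e)
               + logdet + sse / sig_e)
        cov_unscaled = sla.inv(XtX)
        return (beta, cov_unscaled, {"residual": sig_e}, {}, -0.5 * m2l, 0, True)

    # absorb the factor with the most levels; the rest join X in the T block
    absorb = max(terms, key=lambda t: qs[t])
    kept = [t for t in terms if t != absorb]
    q2 = qs[absorb]
    codes2 = random_codes[absorb]

    blocks = [X] + [
        sparse.csr_matrix(
            (np.ones(n), (np.arange(n), random_codes[t])), shape=(n, qs[t])
        ).toarray()
        for t in kept
    ]
    W = np.column_stack(blocks)
    m = W.shape[1]
    kept_slices = {}
    off = p
    for t in kept:
        kept_slices[t] = slice(off, off + qs[t])
        off += qs[t]

    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    Z2 = sparse.csr_matrix((np.ones(n), (np.arange(n), codes2)), shape=(n, q2))
    U = W.T @ Z2            # m x q2, dense
    U = np.asarray(U)
    y2 = np.asarray(Z2.T @ y).ravel()
    counts2 = np.bincount(codes2, minlength=q2).astype(float)
    # group absorbed levels by record count: A_c = U_c U_c', B uses 1/(c+lam)^2
    groups = []
    for c in np.unique(counts2):
        idx = np.where(counts2 == c)[0]
        Uc = U[:, idx]
        groups.append((float(c), Uc @ Uc.T))

    q_tot = sum(qs.values())

    def _floor(v: float, ref: float = 0.0) -> float:
        # Snap near-boundary values exactly to the floor so iteration settles:
        # the EM map's derivative tends to 1 at a zero variance, so components
        # below any meaningful fraction of the reference scale would otherwise
        # crawl forever without reaching it.
        return VAR_FLOOR if v < max(2 * VAR_FLOOR, 1e-8 * ref) else v

    def _step(sig, sig_e):
        """One MME solve at (sig, sig_e): EM updates + restricted loglik."""
        lam2 = sig_e / sig[absorb]
        d2 = counts2 + lam2
        T = WtW.copy()
        for t in kept:
            sl = kept_slices[t]
            T[sl, sl] += np.eye(qs[t]) * (sig_e / sig[t])
        S = T.copy()
        B = np.zeros_like(S)
        for c, Ac in groups:
            S -= Ac / (c + lam2)
            B += Ac / (c + lam2) ** 2
        rhs = Wty - U @ (y2 / d2)
        cf = sla.cho_factor(S)
        a = sla.cho_solve(cf, rhs)
        u2 = (y2 - U.T @ a) / d2
        sse = float(yty - a @ Wty - u2 @ y2)
        Sinv = sla.cho_solve(cf, np.eye(m))

        logdet_C = float(np.sum(np.log(d2)) + 2 * np.sum(np.log(np.diag(cf[0]))))
        m2l = ((n - p) * np.log(2 * np.pi)
               + (n - p - q_tot) * np.log(sig_e)
               + sum(qs[t] * np.log(sig[t]) for t in terms)
               + logdet_C + max(sse, 0.0) / sig_e)

        new_e = _floor(sse / (n - p), vary)
        new = {}
        for t in kept:
            sl = kept_slices[t]
            u1 = a[sl]
            tr = float(np.trace(Sinv[sl, sl]))
            new[t] = _floor((u1 @ u1 + sig_e * tr) / qs[t], new_e)
        tr2 = float(np.sum(1.0 / d2) + np.sum(Sinv * B))
        new[absorb] = _floor((u2 @ u2 + sig_e * tr2) / q2, new_e)
        return new, new_e, -0.5 * m2l, (a, u2, sse, Sinv)

    vary = float(np.var(y)) or 1.0
    sig = {t: vary / (2 * len(terms)) for t in terms}
    sig_e = vary / 2
    if init:
        sig_e = float(init.get("residual", sig_e))
        for t in terms:
            sig[t] = float(init.get(t, sig[t]))
    sig = {t: max(v, VAR_FLOOR) for t, v in sig.items()}
    sig_e = max(sig_e, VAR_FLOOR)

    converged = False
    it = 0
    history: list[np.ndarray] = []
    order = terms + ["residual"]
    cur_ll = -np.inf
    for it in range(1, max_iter + 1):
        new, new_e, cur_ll, _ = _step(sig, sig_e)

        rel = abs(new_e - sig_e) / max(sig_e, 1e-12)
        for t in terms:
            rel = max(rel, abs(new[t] - sig[t]) / max(sig[t], 1e-12))
        if sig_e == new_e == VAR_FLOOR:
            rel = min(rel, 0.0)  # residual pinned at the floor
        sig_e, sig = new_e, new
        if rel < rtol:
            converged = True
            break

        # Aitken extrapolation every 10 iterations: EM converges linearly, and
        # crawls when a component heads for the boundary; the jump is accepted
        # only if the restricted likelihood does not decrease.
        history.append(np.array([sig[t] for t in terms] + [sig_e]))
        if it % 10 == 0 and len(history) >= 3:
            s0, s1, s2 = history[-3], history[-2], history[-1]
            denom = s1 - s0
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(np.abs(denom) > 0, (s2 - s1) / denom, 0.0)
            ok_r = (r > 0) & (r < 1 - 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = np.where(ok_r, s1 + (s2 - s1) / np.where(ok_r, 1 - r, 1.0), s2)
            cand = np.maximum(cand, VAR_FLOOR)
            cand = np.where(cand < 2 * VAR_FLOOR, VAR_FLOOR, cand)
            if np.any(cand != s2):
                c_sig = {t: float(cand[i]) for i, t in enumerate(terms)}
                c_e = float(cand[-1])
                try:
                    _, _, c_ll, _ = _step(c_sig, c_e)
                except np.linalg.LinAlgError:
                    c_ll = -np.inf
                if c_ll >= cur_ll - 1e-12:
                    sig, sig_e = c_sig, c_e
                    history.clear()

    # final solve + likelihood at the converged components
    _, _, loglik, (a, u2, sse, Sinv) = _step(sig, sig_e)
    beta = a[:p]
    blups = {absorb: u2}
    for t in kept:
        blups[t] = a[kept_slices[t]]
    varcomps = {**sig, "residual": sig_e}
    return beta, Sinv[:p, :p], varcomps, blups, loglik, it, converged


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, rtol: float = 1e-10,
            max_iter: int = 30000) -> FitResult:
    """Fit ``spec`` to ``data`` by EM-REML and return a :class:`FitResult`."""
    design = build_design(data, spec)
    beta, cov_u, varcomps, blups, loglik, iters, converged = _em_reml(
        design.y, design.X, design.random_codes, rtol=rtol, max_iter=max_iter
    )
    sig_e = varcomps["residual"]
    beta_cov = pd.DataFrame(cov_u * sig_e, index=design.columns, columns=design.columns)
    beta_s = pd.Series(beta, index=design.columns)
    beta_se = pd.Series(np.sqrt(np.diag(beta_cov.to_numpy())), index=design.columns)
    blup_series = {
        t: pd.Series(v, index=design.random_levels[t]) for t, v in blups.items()
    }
    return FitResult(beta_s, beta_se, beta_cov, varcomps, blup_series,
                     loglik, iters, converged, len(data), design, spec)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------


def estimate_repeatability(
    data: pd.DataFrame,
    response: str,
    factors: dict | None = None,
    covariates: list | None = None,
    animal: str = "animal_id",
    contemporary_group: str | None = "cg_key",
    n_bootstrap: int = 200,
    seed: int = 0,
    rtol: float = 1e-10,
    max_iter: int = 30000,
) -> dict:
    """Repeatability R = sigma_a^2 / (sigma_a^2 + sigma_e^2) of ``response``.

    The model fits a random animal intercept and, by default, a random
    contemporary-group intercept; the group variance is excluded from the
    denominator, so R measures the within-group fraction of variance that is
    permanent between-animal.  Pass ``contemporary_group=None`` for the
    animal-plus-residual-only variant.  The standard error comes from a
    parametric bootstrap (simulate from the fitted model, refit, take the SD
    of the replicate estimates); pass ``n_bootstrap=0`` to skip it.
    """
    counts = data[animal].value_counts()
    if (counts < 2).all():
        raise ValueError("repeatability is unidentifiable: no animal has repeated records")
    random_terms = [animal] if contemporary_group is None else [contemporary_group, animal]
    spec = ModelSpec(response=response, factors=factors or {},
                     covariates=covariates or [], random_terms=random_terms)
    fit = fit_lmm(spec, data, rtol=rtol, max_iter=max_iter).require_converged()
    sig_a = fit.varcomps[animal]
    sig_e = fit.varcomps["residual"]
    R = sig_a / (sig_a + sig_e)
    out = {"R": float(R), "SE": None, "fit": fit}
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        des = fit.design
        mu = des.X @ fit.beta.to_numpy()
        reps = []
        for _ in range(n_bootstrap):
            yb = mu + rng.normal(0.0, np.sqrt(sig_e), len(mu))
            for term in random_terms:
                q = len(des.random_levels[term])
                u = rng.normal(0.0, np.sqrt(fit.varcomps[term]), q)
                yb = yb + u[des.random_codes[term]]
            _, _, vc, _, _, _, ok = _em_reml(
                yb, des.X, des.random_codes, rtol=max(rtol, 1e-8), max_iter=max_iter
            )
            if ok:
                reps.append(vc[animal] / (vc[animal] + vc["residual"]))
        if len(reps) >= 2:
            out["SE"] = float(np.std(reps, ddof=1))
    return out


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------


def marginal_means(fit: FitResult, factor: str) -> pd.DataFrame:
    """Estimated marginal means for the levels of a fixed categorical factor.

    Continuous covariates are held at their sample means, the other factors at
    their reference levels, and random effects at their population average of
    zero.  Pairwise level differences are tested with a Wald z statistic.
    The result carries the pairwise table in ``.attrs["pairwise"]``.
    """
    des = fit.design
    if factor not in des.factor_levels:
        raise KeyError(f"{factor!r} is not a fixed categorical factor of this model")
    p = len(des.columns)
    rows = {}
    for level in des.factor_levels[factor]:
        r = np.zeros(p)
        r[0] = 1.0
        j = des.factor_columns[factor][level]
        if j is not None:
            r[j] = 1.0
        for cov, mean in des.covariate_means.items():
            r[des.columns.index(cov)] = mean
        rows[level] = r
    beta = fit.beta.to_numpy()
    cov = fit.beta_cov.to_numpy()
    table = pd.DataFrame(
        {
            "level": list(rows),
            "emm": [float(r @ beta) for r in rows.values()],
            "se": [float(np.sqrt(r @ cov @ r)) for r in rows.values()],
        }
    )
    pairs = []
    levels = list(rows)
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            d = rows[la] - rows[lb]
            est = float(d @ beta)
            se = float(np.sqrt(d @ cov @ d))
            z = est / se if se > 0 else np.inf * np.sign(est or 1)
            pval = float(2 * stats.norm.sf(abs(z)))
            pairs.append({"a": la, "b": lb, "difference": est, "se": se,
                          "z": z, "p_value": pval})
    table.attrs["pairwise"] = pd.DataFrame(pairs)
    return table
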