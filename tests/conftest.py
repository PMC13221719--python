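"""Shared fixtures: small synthetic datasets and fitted pipeline artifacts."""

import numpy as np
import pandas as pd
import pytest

from sheepmethane import default_config, simulate_flocks
from sheepmethane.covariates import compute_covariates
from sheepmethane import qc
from sheepmethane.residual import prepare_model_frame


def run_qc(bundle, cohort):
    """The standard editing sequence used by the pipeline."""
    rec = bundle["emissions"]
    rec, _ = qc.filter_cohort_eligibility(rec)
    rec, _ = qc.assign_contemporary_groups(rec)
    rec, _ = qc.apply_emission_filters(rec, cohort=cohort)
    rec, _ = qc.filter_small_groups(rec)
    rec, _ = qc.apply_weight_and_window_filters(
        rec, dmi=bundle.get("dmi"), carcass=bundle.get("carcass"),
        ct=bundle.get("ct"))
    return rec


def prepared_cohort(cohort, seed, n_animals):
    """Simulate -> QC -> covariates -> model frame, returned as a dict."""
    cfg = default_config(cohort, seed=seed, n_animals=n_animals)
    bundle = simulate_flocks(cfg)
    records = run_qc(bundle, cohort)
    cov = compute_covariates(bundle["animals"], records, bundle.get("weights"))
    cov, _ = qc.apply_adg_filter(cov)
    frame = prepare_model_frame(records, cov, bundle["animals"], cohort)
    return {"config": cfg, "bundle": bundle, "records": records,
            "covariates": cov, "frame": frame}


@pytest.fixture(scope="session")
def growing_data():
    return prepared_cohort("growing", seed=11, n_animals=1500)


@pytest.fixture(scope="session")
def ewe_data():
    return prepared_cohort("ewe", seed=12, n_animals=1200)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent dense-matrix REML oracle (never calls the package's solver)
# ---------------------------------------------------------------------------


def dense_reml_loglik(y, X, codes_list, sigmas, sig_e):
    """Restricted log-likelihood evaluated through the full n x n covariance."""
    n, p = X.shape
    V = sig_e * np.eye(n)
    for codes, s2 in zip(codes_list, sigmas):
        Z = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)
        V += s2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_X + r @ Vi @ r))


def brute_force_reml(y, X, codes_list, floor=1e-10):
    """Maximize the dense restricted likelihood by multistart Nelder-Mead in
    log-variance space, with a boundary scan for each component at the floor."""
    from itertools import product

    from scipy.optimize import minimize

    k = len(codes_list) + 1
    vary = max(np.var(y), 1e-8)

    def nll(theta):
        s = np.exp(theta)
        return -dense_reml_loglik(y, X, codes_list, s[:-1], s[-1])

    starts = [np.log(np.full(k, vary / k)),
              np.log(np.full(k, vary)),
              np.log(np.concatenate([np.full(k - 1, vary / 10), [vary]]))]
    # boundary starts: any subset of the random components pinned near zero
    for pins in product([False, True], repeat=k - 1):
        if any(pins):
            v = np.full(k, vary / k)
            v[:-1][np.array(pins)] = floor
            starts.append(np.log(v))
    best = None
    for s0 in starts:
        res = minimize(nll, s0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 40000, "maxfev": 40000})
        if best is None or res.fun < best.fun:
            best = res
    s = np.exp(best.x)
    s = np.where(s < 2 * floor, floor, s)
    return {"sigmas": s[:-1], "sig_e": float(s[-1]), "loglik": -float(best.fun)}
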