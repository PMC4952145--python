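"""Simulation studies and brute-force oracles for pipeline validation.

Every function here measures a property of the implementation by Monte
Carlo or by comparison against a definition-level computation that shares no
code with the fitting path: pseudo-inverse solves, physical leave-one-out
refits, quadrature for the chi-square tail.  Used by the test suite and the
acceptance script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .data import build_design
from .identify import build_pd_matrix, consolidate, run_all_cells
from .regression import (
    ModelFit,
    fit_ols,
    likelihood_ratio_test,
    studentized_residuals,
)
from .simulate import default_study_config, generate_panel


# ---------------------------------------------------------------------------
# Definition-level oracles (independent of the SVD fitting path)


def pinv_oracle(y: np.ndarray, X: np.ndarray) -> dict:
    """Direct-formula OLS: pseudo-inverse coefficients, hat diagonal from the
    projection matrix, R^2 and Gaussian log-likelihood from their definitions."""
    beta = np.linalg.pinv(X) @ y
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    fitted = H @ y
    resid = y - fitted
    rss = float(resid @ resid)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    return {
        "coefficients": beta,
        "hat_diag": np.diag(H),
        "residuals": resid,
        "r_squared": 1.0 - rss / tss,
        "log_likelihood": -(n / 2.0) * (np.log(2 * np.pi) + np.log(rss / n) + 1.0),
    }


def loo_studentized_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Externally studentized residuals by physically deleting each unit,
    refitting, and standardizing the held-out prediction error."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        beta_i = np.linalg.pinv(Xi) @ yi
        resid_i = yi - Xi @ beta_i
        p = np.linalg.matrix_rank(Xi)
        s2_i = float(resid_i @ resid_i) / (len(yi) - p)
        xi = X[i]
        pred_var = s2_i * (1.0 + xi @ np.linalg.pinv(Xi.T @ Xi) @ xi)
        out[i] = (y[i] - xi @ beta_i) / np.sqrt(pred_var)
    return out


def loo_cooks_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cook's distance from its definition: the shift in fitted values when
    each unit is deleted, scaled by p * sigma2_unbiased."""
    n = len(y)
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    p = np.linalg.matrix_rank(X)
    s2 = float(resid @ resid) / (n - p)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.pinv(X[keep]) @ y[keep]
        d = beta - beta_i
        out[i] = float(d @ (X.T @ X) @ d) / (p * s2)
    return out


def chi2_sf_quadrature(x: float, df: int) -> float:
    """Upper-tail chi-square probability by numerical integration of the density."""
    val, _ = integrate.quad(lambda u: stats.chi2.pdf(u, df), x, np.inf)
    return val


# ---------------------------------------------------------------------------
# Oracle-equivalence sweeps


def _random_problem(rng: np.random.Generator, n: int, p: int, rank_deficient: bool):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    if rank_deficient:
        X[:, -1] = X[:, 1] + 2.0 * X[:, 2]  # exact collinearity
    beta = rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n)
    return y, X


def ols_oracle_equivalence(
    n_problems: int = 100, n: int = 50, p: int = 6, seed: int = 0
) -> dict:
    """Max |difference| between fit_ols and the pseudo-inverse oracle over
    seeded random problems, one of them exactly rank-deficient."""
    rng = np.random.default_rng(seed)
    worst = {"coefficients": 0.0, "hat_diag": 0.0, "r_squared": 0.0, "log_likelihood": 0.0}
    for k in range(n_problems):
        deficient = k == n_problems - 1
        y, X = _random_problem(rng, n, p, deficient)
        fit = fit_ols(y, X, list(range(n)))
        oracle = pinv_oracle(y, X)
        worst["coefficients"] = max(
            worst["coefficients"], float(np.max(np.abs(fit.coefficients - oracle["coefficients"])))
        )
        worst["hat_diag"] = max(
            worst["hat_diag"], float(np.max(np.abs(fit.hat_diag - oracle["hat_diag"])))
        )
        worst["r_squared"] = max(worst["r_squared"], abs(fit.r_squared - oracle["r_squared"]))
        worst["log_likelihood"] = max(
            worst["log_likelihood"], abs(fit.log_likelihood - oracle["log_likelihood"])
        )
    return worst


def studentized_oracle_equivalence(
    n_problems: int = 100, n: int = 50, p: int = 6, seed: int = 0
) -> float:
    """Max |closed-form - leave-one-out refit| externally studentized residual."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        y, X = _random_problem(rng, n, p, rank_deficient=False)
        fit = fit_ols(y, X, list(range(n)))
        t = studentized_residuals(fit)
        t_oracle = loo_studentized_oracle(y, X)
        worst = max(worst, float(np.max(np.abs(t - t_oracle))))
    return worst


# ---------------------------------------------------------------------------
# Null calibration studies


@dataclass
class LRTCalibration:
    rejection_rate: float
    n_panels: int
    min_statistic: float
    exact_rate: float  # closed-form finite-sample rate of the chi-square LRT


def lrt_null_calibration(
    n_panels: int = 2000,
    n: int = 60,
    q: int = 3,
    n_base_covariates: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> LRTCalibration:
    """Type-I error of the LRT when the added coefficients are truly zero.

    Each panel regresses y (linear in the base covariates plus noise) on the
    base design, then on the base plus q irrelevant columns.  Also reports
    the exact finite-sample rejection rate implied by the F distribution of
    the nested RSS ratio — the chi-square reference is anticonservative in
    small samples, and this closed form quantifies by how much.
    """
    rng = np.random.default_rng(seed)
    crit = stats.chi2.ppf(1.0 - alpha, q)
    p_full = 1 + n_base_covariates + q
    rejections = 0
    min_stat = np.inf
    for _ in range(n_panels):
        Z = rng.standard_normal((n, n_base_covariates))
        Xq = rng.standard_normal((n, q))
        y = 1.0 + Z @ np.full(n_base_covariates, 0.5) + rng.standard_normal(n)
        X1 = np.column_stack([np.ones(n), Z])
        X2 = np.column_stack([X1, Xq])
        f1 = fit_ols(y, X1, list(range(n)))
        f2 = fit_ols(y, X2, list(range(n)))
        res = likelihood_ratio_test(f1, f2)
        min_stat = min(min_stat, 2.0 * (f2.log_likelihood - f1.log_likelihood))
        if res.p_value < alpha:
            rejections += 1
    d = n - p_full
    f_crit = (np.exp(crit / n) - 1.0) * d / q
    exact = float(stats.f.sf(f_crit, q, d))
    return LRTCalibration(
        rejection_rate=rejections / n_panels,
        n_panels=n_panels,
        min_statistic=float(min_stat),
        exact_rate=exact,
    )


@dataclass
class NullTailResult:
    observed_fraction: float
    expected_fraction: float  # pooled Student-t lower tail at the threshold
    mc_se: float
    n_replicates: int


def null_residual_tail(
    replicates: int = 500, threshold: float = -1.0, seed: int = 0
) -> NullTailResult:
    """Fraction of full-model externally studentized residuals below the
    threshold on deviant-free default panels, against the pooled
    Student-t(n-p-1) lower tail."""
    fractions = []
    expected_num = expected_den = 0.0
    first = True
    for r in range(replicates):
        cfg = default_study_config(seed + r)
        cfg = dataclasses.replace(cfg, planted=())
        panel, _ = generate_panel(cfg)
        n_below = n_total = 0
        for state in panel.states:
            for year in panel.years:
                sub = panel.stratum(state, year)
                X, names = build_design(sub, panel.role_map, include_mechanism=True)
                ids = list(sub[panel.role_map.id_var])
                for outcome in panel.role_map.outcome_vars:
                    fit = fit_ols(sub[outcome].to_numpy(float), X, ids, names)
                    t = studentized_residuals(fit)
                    n_below += int(np.sum(t < threshold))
                    n_total += len(t)
                    if first:
                        df = fit.n - fit.p - 1
                        expected_num += fit.n * stats.t.cdf(threshold, df)
                        expected_den += fit.n
        first = False
        fractions.append(n_below / n_total)
    fractions = np.asarray(fractions)
    return NullTailResult(
        observed_fraction=float(fractions.mean()),
        expected_fraction=float(expected_num / expected_den),
        mc_se=float(fractions.std(ddof=1) / np.sqrt(replicates)),
        n_replicates=replicates,
    )


# ---------------------------------------------------------------------------
# Planted-deviant recovery


@dataclass
class RecoveryResult:
    sensitivity_multi: float
    single_cell_exclusion: float
    n_replicates: int
    n_multi_trials: int
    n_single_trials: int
    mean_pd_count: float


def planted_recovery(
    replicates: int = 200, threshold: float = -1.0, min_cells: int = 2, seed: int = 0
) -> RecoveryResult:
    """Consolidated-set recovery of planted deviants on the default config.

    sensitivity_multi: fraction of jurisdictions planted in >= 2 cells that
    enter the consolidated set.  single_cell_exclusion: fraction of
    jurisdictions planted in exactly one cell that stay out of it.
    """
    multi_hit = multi_tot = single_out = single_tot = 0
    pd_counts = []
    for r in range(replicates):
        cfg = default_study_config(seed + r)
        panel, truth = generate_panel(cfg)
        results = run_all_cells(panel, threshold=threshold)
        pd_set = consolidate(build_pd_matrix(results.results), min_cells, results.results)
        pd_counts.append(len(pd_set.members))
        for jid, cells in truth.planted_jurisdictions().items():
            if len(cells) >= 2:
                multi_tot += 1
                multi_hit += int(jid in pd_set)
            else:
                single_tot += 1
                single_out += int(jid not in pd_set)
    return RecoveryResult(
        sensitivity_multi=multi_hit / multi_tot,
        single_cell_exclusion=single_out / single_tot,
        n_replicates=replicates,
        n_multi_trials=multi_tot,
        n_single_trials=single_tot,
        mean_pd_count=float(np.mean(pd_counts)),
    )


# ---------------------------------------------------------------------------
# Parameter recovery


@dataclass
class CoverageResult:
    coverage: float
    max_bias_z: float  # max |mean estimate - truth| / MC standard error
    n_replicates: int
    n_coefficients: int


def coefficient_recovery(
    replicates: int = 500,
    state: str = "FL",
    outcome: str = "teen_birth_rate",
    year: int = 2009,
    seed: int = 0,
) -> CoverageResult:
    """Bias and 95% interval coverage of full-model coefficient estimates on
    deviant-free default panels, against the generator's raw-scale truth."""
    estimates = []
    covered = []
    truth_vec = None
    for r in range(replicates):
        cfg = default_study_config(seed + r)
        cfg = dataclasses.replace(
            cfg, states=tuple(s for s in cfg.states if s.name == state), planted=()
        )
        panel, truth = generate_panel(cfg)
        sub = panel.stratum(state, year)
        X, names = build_design(sub, panel.role_map, include_mechanism=True)
        fit = fit_ols(
            sub[outcome].to_numpy(float), X, list(sub[panel.role_map.id_var]), names
        )
        if truth_vec is None:
            tc = truth.true_coefficients[outcome]
            truth_vec = np.array([tc.get(name, 0.0) for name in names])
        estimates.append(fit.coefficients)
        ci = fit.conf_int(0.95)
        covered.append((ci[:, 0] <= truth_vec) & (truth_vec <= ci[:, 1]))
    est = np.asarray(estimates)
    cov = np.asarray(covered, dtype=float)
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(replicates)
    bias_z = np.abs(est.mean(axis=0) - truth_vec) / mc_se
    return CoverageResult(
        coverage=float(cov.mean()),
        max_bias_z=float(bias_z.max()),
        n_replicates=replicates,
        n_coefficients=est.shape[1],
    )
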