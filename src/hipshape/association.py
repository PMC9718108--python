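"""Per-mode logistic association with cluster-robust (GEE) inference.

Each standardized shape-mode score is regressed on a binary MRI outcome,
one model per (mode, outcome) pair, both crude and adjusted for age, BMI and
symptomatic status.  Because the two hips of one participant are correlated,
estimation uses generalized estimating equations (Liang-Zeger) with an
exchangeable working correlation by default and sandwich (robust) standard
errors.  Effects are reported as odds ratios per 1 SD of shape-mode score
with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

Z_95 = 1.96  # Wald multiplier used for all reported 95% intervals


class SeparationError(RuntimeError):
    """The likelihood is maximised at infinity (perfect/quasi separation)."""


class RankDeficientError(ValueError):
    """The design matrix does not have full column rank."""


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray          # inverse Fisher information
    n_obs: int
    iterations: int
    converged: bool

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic_irls(
    design, outcomes, tol: float = 1e-10, max_iter: int = 100
) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton scoring), tolerance ``tol`` on coefficient change.

    Serves as the independence reference for the GEE fit.  Raises
    :class:`SeparationError` when coefficients diverge and
    :class:`RankDeficientError` on a rank-deficient design.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcomes, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("design must be (n, p) with one outcome per row")
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise RankDeficientError(f"design matrix is rank deficient (p={p})")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        if np.max(np.abs(eta)) > 30.0:
            raise SeparationError(
                "logistic fit diverging (|linear predictor| > 30); "
                "data are likely perfectly separated"
            )
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = x.T @ (w[:, None] * x)
        score = x.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        raise SeparationError(f"IRLS did not converge in {max_iter} iterations")

    mu = expit(x @ beta)
    w = mu * (1.0 - mu)
    info = x.T @ (w[:, None] * x)
    return LogisticFit(
        params=beta, cov=np.linalg.inv(info), n_obs=n, iterations=it, converged=True
    )


@dataclass
class GEEFit:
    """Liang-Zeger GEE fit for a logistic marginal model."""

    params: np.ndarray
    cov_robust: np.ndarray   # sandwich B^-1 M B^-1
    cov_model: np.ndarray    # model-based phi * B^-1
    alpha: float             # working exchangeable correlation estimate
    scale: float             # Pearson dispersion phi
    n_clusters: int
    n_obs: int
    iterations: int
    converged: bool
    working: str

    def robust_bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))


def _group_by_size(cluster_ids) -> dict[int, np.ndarray]:
    """Map cluster size -> (n_clusters_of_that_size, size) index arrays."""
    ids = np.asarray(cluster_ids)
    _, inverse, counts = np.unique(ids, return_inverse=True, return_counts=True)
    order = np.argsort(inverse, kind="stable")
    out: dict[int, list[np.ndarray]] = {}
    start = 0
    for c in counts:
        out.setdefault(int(c), []).append(order[start:start + c])
        start += c
    return {s: np.stack(members) for s, members in out.items()}


def _exchangeable_rinv(size: int, alpha: float) -> np.ndarray:
    if size == 1:
        return np.ones((1, 1))
    return (np.eye(size) - (alpha / (1.0 + (size - 1) * alpha)) * np.ones((size, size))) / (
        1.0 - alpha
    )


def fit_gee_logistic(
    design,
    outcomes,
    cluster_ids,
    working: str = "exchangeable",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> GEEFit:
    """Marginal logistic regression with clustered observations.

    Fisher scoring on the estimating equations with working covariance
    ``V_i = A_i^{1/2} R(alpha) A_i^{1/2}``; the exchangeable correlation
    ``alpha`` is re-estimated each iteration by the moment estimator from
    within-cluster cross-products of standardized Pearson residuals, and is
    clipped to (-0.99, 0.99) with a warning if needed.  The fit is
    initialised at the independence IRLS solution.  The robust covariance is
    the sandwich ``B^-1 M B^-1`` with bread ``B = sum D_i' V_i^-1 D_i`` and
    meat ``M = sum D_i' V_i^-1 r_i r_i' V_i^-1 D_i``.
    """
    if working not in ("exchangeable", "independence"):
        raise ValueError(f"working must be 'exchangeable' or 'independence', got {working!r}")
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcomes, dtype=float).ravel()
    n, p = x.shape
    groups = _group_by_size(cluster_ids)
    n_clusters = sum(idx.shape[0] for idx in groups.values())
    n_pairs = sum(idx.shape[0] * s * (s - 1) // 2 for s, idx in groups.items())

    beta = fit_logistic_irls(x, y, tol=tol).params

    def moments(beta):
        eta = x @ beta
        mu = expit(eta)
        v = np.clip(mu * (1.0 - mu), 1e-12, None)
        res = y - mu
        pearson = res / np.sqrt(v)
        phi = float((pearson**2).sum() / (n - p))
        alpha = 0.0
        if working == "exchangeable" and n_pairs > p:
            num = 0.0
            for s, idx in groups.items():
                if s > 1:
                    e = pearson[idx]
                    num += float(((e.sum(axis=1) ** 2 - (e**2).sum(axis=1)) / 2.0).sum())
            alpha = num / ((n_pairs - p) * phi)
            if not -0.99 < alpha < 0.99:
                warnings.warn(f"working correlation estimate {alpha:.3f} clipped to (-0.99, 0.99)")
                alpha = float(np.clip(alpha, -0.99, 0.99))
        return mu, v, res, phi, alpha

    def assemble(beta, alpha):
        mu = expit(x @ beta)
        v = np.clip(mu * (1.0 - mu), 1e-12, None)
        res = y - mu
        bread = np.zeros((p, p))
        u_vec = np.zeros(p)
        meat = np.zeros((p, p))
        for s, idx in groups.items():
            xg = x[idx]                      # (m, s, p)
            sq = np.sqrt(v[idx])             # (m, s)
            a1 = sq[..., None] * xg          # A^{1/2} X
            b = res[idx] / sq                # A^{-1/2} r
            rinv = _exchangeable_rinv(s, alpha)
            t = np.einsum("st,mtp->msp", rinv, a1)
            bread += np.einsum("msp,msq->pq", a1, t)
            g = np.einsum("msp,ms->mp", t, b)  # per-cluster D'V^-1 r
            u_vec += g.sum(axis=0)
            meat += g.T @ g
        return bread, u_vec, meat

    converged = False
    alpha = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        _, _, _, phi, alpha = moments(beta)
        bread, u_vec, _ = assemble(beta, alpha)
        try:
            delta = np.linalg.solve(bread, u_vec)
        except np.linalg.LinAlgError as exc:
            raise RankDeficientError(f"singular GEE bread matrix: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GEE did not converge within {max_iter} iterations")

    _, _, _, phi, alpha = moments(beta)
    bread, _, meat = assemble(beta, alpha)
    bread_inv = np.linalg.inv(bread)
    return GEEFit(
        params=beta,
        cov_robust=bread_inv @ meat @ bread_inv,
        cov_model=phi * bread_inv,
        alpha=alpha,
        scale=phi,
        n_clusters=n_clusters,
        n_obs=n,
        iterations=it,
        converged=converged,
        working=working,
    )


def or_per_sd(fit: GEEFit | LogisticFit, exposure_term: int = 1):
    """Odds ratio per 1 SD of the exposure with robust Wald 95% CI and p.

    ``exposure_term`` indexes the coefficient (1 = first term after the
    intercept).  Values are returned unrounded; reporting rounds to 2
    decimals.
    """
    beta = float(fit.params[exposure_term])
    cov = fit.cov_robust if isinstance(fit, GEEFit) else fit.cov
    se = float(np.sqrt(cov[exposure_term, exposure_term]))
    z = beta / se if se > 0 else np.inf
    p = 2.0 * float(norm.sf(abs(z)))
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
        p,
    )


def or_at_k_sd(or_per_sd_value: float, k: float) -> float:
    """Odds ratio at ``k`` SDs from the mean given a per-SD odds ratio.

    A hip scoring k SDs on a mode has odds ratio OR^k relative to the mean
    shape; for a protective per-SD OR and negative k this equals
    (1/OR)^|k|.  Reported to 2 decimals.
    """
    if or_per_sd_value <= 0:
        raise ValueError("per-SD odds ratio must be positive")
    return round(float(or_per_sd_value) ** k, 2)


def bonferroni_alpha(n_modes: int) -> float:
    """Family-wise significance threshold 0.05 / n tested modes (4 decimals)."""
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    return round(0.05 / n_modes, 4)


def build_covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Adjustment block: age, BMI, and symptomatic-status indicators.

    Status enters as two dummies (symptomatic, other) against the
    asymptomatic reference — the contralateral "other" hips of symptomatic
    participants stay distinct from truly asymptomatic hips.
    """
    status = covariates["symptomatic_status"]
    unknown = set(status) - {"symptomatic", "other", "asymptomatic"}
    if unknown:
        raise ValueError(f"unknown status level(s): {sorted(unknown)}")
    return np.column_stack(
        [
            covariates["age"].to_numpy(float),
            covariates["bmi"].to_numpy(float),
            (status == "symptomatic").to_numpy(float),
            (status == "other").to_numpy(float),
        ]
    )


def run_association_scan(
    std_scores,
    outcomes: dict,
    covariates: pd.DataFrame,
    cluster_ids,
    selected_modes,
    working: str = "exchangeable",
) -> pd.DataFrame:
    """One crude and one adjusted GEE logistic model per (mode, outcome).

    ``std_scores`` is an (n, m) array or DataFrame of standardized mode
    scores; ``outcomes`` maps outcome name -> boolean array; ``selected_modes``
    are 0-based column indices into the score matrix.  Rows with missing
    covariates are dropped per model (complete case) with a log of the count.
    Fit failures (e.g. separation on a degenerate outcome) flag the row as
    failed instead of aborting the scan.
    """
    scores = np.asarray(std_scores, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    n = scores.shape[0]
    selected_modes = list(selected_modes)
    alpha_bonf = bonferroni_alpha(len(selected_modes)) if selected_modes else np.nan

    cov_block = build_covariate_design(covariates)
    complete = np.isfinite(cov_block).all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} of {n} hips with missing covariates"
        )

    rows = []
    for outcome_name, y in outcomes.items():
        y = np.asarray(y, dtype=float).ravel()
        for m in selected_modes:
            row = {"mode": int(m) + 1, "outcome": outcome_name, "failed": False}
            expo = scores[:, m]
            try:
                crude = fit_gee_logistic(
                    np.column_stack([np.ones(n), expo]), y, cluster_ids, working
                )
                o, lo, hi, p = or_per_sd(crude, 1)
                row.update(or_=o, ci_low=lo, ci_high=hi, p=p)

                keep = complete
                design = np.column_stack(
                    [np.ones(n), expo, cov_block]
                )[keep]
                adj = fit_gee_logistic(design, y[keep], cluster_ids[keep], working)
                ao, alo, ahi, ap = or_per_sd(adj, 1)
                row.update(aor=ao, aci_low=alo, aci_high=ahi, ap=ap)
                row["sig_05"] = ap < 0.05
                row["sig_bonferroni"] = ap < alpha_bonf
            except (SeparationError, RankDeficientError) as exc:
                row.update(
                    failed=True,
                    or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                    aor=np.nan, aci_low=np.nan, aci_high=np.nan, ap=np.nan,
                    sig_05=False, sig_bonferroni=False,
                )
                warnings.warn(f"mode {m + 1} / {outcome_name}: fit failed ({exc})")
            rows.append(row)

    cols = [
        "mode", "outcome", "or_", "ci_low", "ci_high", "p",
        "aor", "aci_low", "aci_high", "ap", "sig_05", "sig_bonferroni", "failed",
    ]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["outcome", "mode"], kind="stable"
    ).reset_index(drop=True)


def _simulate_power(
    log_or: float,
    z_scores: np.ndarray,
    u_expanded: np.ndarray,
    uniforms: np.ndarray,
    cluster_ids: np.ndarray,
    baseline_logit: float,
    alpha: float,
    working: str,
) -> float:
    """Empirical Wald rejection rate over pre-drawn replicate randomness."""
    n_rep, n = z_scores.shape
    ones = np.ones(n)
    hits = 0
    for r in range(n_rep):
        z = z_scores[r]
        p_true = expit(baseline_logit + log_or * z + u_expanded[r])
        y = (uniforms[r] < p_true).astype(float)
        try:
            fit = fit_gee_logistic(np.column_stack([ones, z]), y, cluster_ids, working)
        except (SeparationError, RankDeficientError):
            continue
        _, _, _, p = or_per_sd(fit, 1)
        if p < alpha:
            hits += 1
    return hits / n_rep


def minimal_detectable_or(
    n_hips: int,
    prevalence: float,
    power: float = 0.8,
    alpha: float = 0.05,
    cluster_structure: str = "paired",
    sigma_u: float = 0.5,
    n_replicates: int = 2000,
    seed: int = 0,
    max_or: float = 6.0,
) -> tuple[float, float]:
    """Smallest per-SD odds ratio detectable with the target power, by
    simulation and bisection; returns ``(OR, 1/OR)``.

    Cohorts are simulated with a standard-normal exposure per hip, paired-hip
    clusters sharing a Normal(0, sigma_u^2) random intercept
    (``cluster_structure='paired'``) or independent hips
    (``'independent'``), and outcomes from a logistic model whose intercept
    is the logit of the target prevalence.  Power at a candidate log-OR is
    the empirical Wald rejection rate over ``n_replicates`` cohorts with
    common random numbers; bisection then finds the crossing.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if cluster_structure not in ("paired", "independent"):
        raise ValueError("cluster_structure must be 'paired' or 'independent'")

    rng = np.random.default_rng(seed)
    if cluster_structure == "paired":
        n_clusters = (n_hips + 1) // 2
        cluster_ids = np.repeat(np.arange(n_clusters), 2)[:n_hips]
        working = "exchangeable"
    else:
        n_clusters = n_hips
        cluster_ids = np.arange(n_hips)
        working = "independence"
        sigma_u = 0.0

    z_scores = rng.standard_normal((n_replicates, n_hips))
    u = rng.normal(0.0, sigma_u, size=(n_replicates, n_clusters)) if sigma_u > 0 else np.zeros(
        (n_replicates, n_clusters)
    )
    u_expanded = u[:, cluster_ids]
    uniforms = rng.random((n_replicates, n_hips))
    baseline = float(np.log(prevalence / (1.0 - prevalence)))

    def power_at(log_or: float) -> float:
        return _simulate_power(
            log_or, z_scores, u_expanded, uniforms, cluster_ids, baseline, alpha, working
        )

    lo, hi = 0.0, float(np.log(1.5))
    while power_at(hi) < power:
        hi *= 1.6
        if hi > np.log(max_or):
            raise RuntimeError(
                f"bisection bracket failure: power {power:.2f} not reached "
                f"below OR {max_or}"
            )
    for _ in range(10):
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= power:
            hi = mid
        else:
            lo = mid
    log_star = 0.5 * (lo + hi)
    return float(np.exp(log_star)), float(np.exp(-log_star))


__all__ = [
    "LogisticFit",
    "GEEFit",
    "SeparationError",
    "RankDeficientError",
    "fit_logistic_irls",
    "fit_gee_logistic",
    "or_per_sd",
    "or_at_k_sd",
    "bonferroni_alpha",
    "build_covariate_design",
    "run_association_scan",
    "minimal_detectable_or",
    "Z_95",
]
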