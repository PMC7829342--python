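"""Bayesian multilevel (mixed-effects) models fitted by blocked Gibbs sampling.

The observation model is the Gaussian linear mixed model

    y = X beta + Z u + eps,   u_p ~ N(0, Sigma_u),   eps ~ N(0, sigma^2 I)

with person-specific varying effects ``u_p`` sharing a full covariance
``Sigma_u``.  The multivariate variant stacks five questionnaire subscales
with a free 5x5 residual covariance and one joint covariance over all
subscale-specific varying effects.

Priors are weakly informative and conjugate: Gaussian priors on the
population coefficients (scaled by sd(y)/sd(x)), and the hierarchical
inverse-Wishart family of Huang & Wand (2013) on every (co)variance, which
has half-t marginals on standard deviations and — at nu = 2 — uniform
marginals on correlations.

The sampler combines three kinds of moves, all exact:

* a collapsed Gaussian draw of the population coefficients with the
  varying effects integrated out (per-person Woodbury identities on
  precomputed cross-products), followed by the exact Gaussian conditional
  for the varying effects;
* conjugate inverse-gamma / inverse-Wishart updates of the variance
  parameters given the varying effects;
* univariate slice-sampling moves on each log variance against the
  varying-effects-marginalized likelihood, which break the funnel-shaped
  coupling between a variance component and its effects when the
  component is close to zero (the varying effects are refreshed from
  their exact conditional afterwards, keeping the chain's stationary
  distribution intact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import DesignMatrices, build_design, fixed_matrix_for
from .study import ValidationError

try:  # sklearn is optional at runtime; get_params/set_params come for free
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass


# ---------------------------------------------------------------------------
# numerics helpers


def _inv_gamma(rng: np.random.Generator, shape: float, rate, size=None):
    """Draw from InvGamma(shape, rate) (rate parameterization)."""
    return np.asarray(rate) / rng.gamma(shape, 1.0, size=size)


def _chol_sample(rng: np.random.Generator, mean: np.ndarray,
                 prec_chol: np.ndarray) -> np.ndarray:
    """Sample N(mean, prec^-1) given the Cholesky factor of the precision."""
    z = rng.standard_normal(mean.shape)
    return mean + np.linalg.solve(prec_chol.T, z)


def _invwishart_rvs(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    out = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(out)


def _safe_cholesky(mat: np.ndarray) -> np.ndarray:
    """Cholesky with a small jitter retry (degenerate, e.g. noise-free, data)."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        scale = float(np.trace(mat)) / mat.shape[0]
        for exp in (-12, -10, -8, -6):
            try:
                return np.linalg.cholesky(mat + 10.0**exp * scale * np.eye(mat.shape[0]))
            except np.linalg.LinAlgError:
                continue
        raise


def _slice_sample(rng: np.random.Generator, x0: float, logf, w: float = 1.5,
                  max_steps: int = 30) -> float:
    """One univariate slice-sampling update (Neal 2003, step-out + shrink)."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0
    level = f0 + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) < level:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < level:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= level:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def pointwise_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                     sigma: float, Z: np.ndarray | None = None,
                     u: np.ndarray | None = None,
                     group_index: np.ndarray | None = None) -> np.ndarray:
    """Per-observation Gaussian log density conditional on all effects."""
    mu = X @ beta
    if Z is not None and u is not None:
        mu = mu + np.einsum("ij,ij->i", Z, u[group_index])
    return stats.norm.logpdf(y, mu, sigma)


def _beta_prior(X: np.ndarray, y: np.ndarray, scale: float):
    """Weakly-informative Gaussian prior per design column.

    Intercept-like (constant) columns get mean ybar and sd 10*sd(y); all
    others get mean 0 and sd ``scale * sd(y)/sd(x)``.
    """
    sd_y = float(np.std(y)) or 1.0
    ybar = float(np.mean(y))
    means = np.zeros(X.shape[1])
    sds = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        sd_x = float(np.std(X[:, j]))
        if sd_x == 0.0:
            means[j] = ybar if np.all(X[:, j] == 1.0) else 0.0
            sds[j] = 10.0 * sd_y
        else:
            sds[j] = scale * sd_y / sd_x
    return means, sds


def _sorted_group_rows(group_index: np.ndarray, n_groups: int) -> list[np.ndarray]:
    return [np.flatnonzero(group_index == j) for j in range(n_groups)]


@dataclass
class ConvergenceReport:
    """Split-R-hat and effective sample size per parameter."""

    table: pd.DataFrame
    max_rhat: float
    min_ess: float
    passed: bool
    notes: list[str]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        state = "PASS" if self.passed else "FAIL"
        return (f"ConvergenceReport({state}: max R-hat={self.max_rhat:.4f}, "
                f"min bulk ESS={self.min_ess:.0f})")


# ---------------------------------------------------------------------------
# univariate model


class BayesianMixedModel(BaseEstimator):
    """Gaussian multilevel regression with a Wilkinson-style formula.

    Parameters
    ----------
    formula:
        e.g. ``"Amplitude ~ Condition*Task*(Session + Session2) +
        (1 + (Session + Session2)*Task | Person)"``.  Factors are
        treatment-coded (references: control / feedback1 / negativity);
        Session and Time are centered at the midpoint of their observed
        range before powers.
    draws, warmup, chains:
        Post-warmup draws per chain, warmup iterations, number of chains
        (two or more; chain ``c`` uses the spawned seed stream
        ``(seed, c)``).
    nu, beta_scale, sd_scale:
        Huang-Wand degrees of freedom (nu=2: uniform marginal
        correlations, half-t(2) marginals on sds), population-coefficient
        prior scale in units of sd(y)/sd(x), and half-t scale multiplier
        for sigma and the varying-effect sds in units of sd(y).
    """

    def __init__(self, formula: str, draws: int = 1000, warmup: int = 500,
                 chains: int = 2, seed: int = 0, nu: float = 2.0,
                 beta_scale: float = 2.5, sd_scale: float = 2.5,
                 rhat_threshold: float = 1.05, compute_loglik: bool = True):
        self.formula = formula
        self.draws = draws
        self.warmup = warmup
        self.chains = chains
        self.seed = seed
        self.nu = nu
        self.beta_scale = beta_scale
        self.sd_scale = sd_scale
        self.rhat_threshold = rhat_threshold
        self.compute_loglik = compute_loglik

    def fit(self, data: pd.DataFrame, y=None) -> "BayesianMixedModel":
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required (split R-hat)")
        design = build_design(self.formula, data)
        outcome = design.parsed.outcome
        if outcome not in data.columns:
            raise ValidationError(f"outcome column {outcome!r} missing from data")
        yvec = np.asarray(pd.to_numeric(data[outcome]), dtype=float)
        if not np.isfinite(yvec).all():
            raise ValidationError("outcome contains non-finite values; drop "
                                  "flagged/missing rows before fitting")
        self.design_ = design
        self.y_ = yvec
        self._run_chains(yvec, design)
        self._diagnose()
        return self

    def _run_chains(self, y: np.ndarray, design: DesignMatrices) -> None:
        X, Z, g = design.X, design.Z, design.group_index
        n, p = X.shape
        q = design.n_varying
        J = design.n_groups
        b_mean, b_sd = _beta_prior(X, y, self.beta_scale)
        sd_y = float(np.std(y)) or 1.0
        A = self.sd_scale * sd_y
        nu = self.nu

        XtX = X.T @ X
        Xty = X.T @ y
        # relative floor keeps the sampler stable on (near-)noise-free data
        sigma2_floor = max(1e-7 * float(np.var(y)), 1e-12)
        if q:
            rows = _sorted_group_rows(g, J)
            ZtZ = np.stack([Z[r].T @ Z[r] for r in rows])
            XtZ = np.stack([X[r].T @ Z[r] for r in rows])
            Zty = np.stack([Z[r].T @ y[r] for r in rows])
            XtX_p = np.stack([X[r].T @ X[r] for r in rows])
            Xty_p = np.stack([X[r].T @ y[r] for r in rows])
            yty_p = np.array([y[r] @ y[r] for r in rows])
            n_p = np.array([len(r) for r in rows], dtype=float)

        S = self.draws
        beta_all = np.empty((self.chains, S, p))
        sigma_all = np.empty((self.chains, S))
        u_all = np.empty((self.chains, S, J, q)) if q else None
        sig_u_all = np.empty((self.chains, S, q, q)) if q else None
        ll_all = np.empty((self.chains, S, n)) if self.compute_loglik else None

        def marginal_loglik(sigma2: float, tau: np.ndarray, Om_inv: np.ndarray,
                            logdet_Om: float, Zr: np.ndarray, rtr: np.ndarray) -> float:
            """Person-marginal Gaussian log likelihood given beta.

            Uses det(V_p) = sigma2^{n_p} det(Sigma_u) det(M_p) and
            r' V^-1 r = (r'r - (Z'r)' M^-1 (Z'r) / sigma2) / sigma2 with
            M_p = Sigma_u^-1 + Z_p'Z_p / sigma2.
            """
            Su_inv = Om_inv / np.outer(tau, tau)
            M = Su_inv[None] + ZtZ / sigma2
            L = np.linalg.cholesky(M)
            logdet_M = 2.0 * np.log(np.einsum("jii->ji", L)).sum(axis=1)
            sol = np.linalg.solve(M, Zr[..., None])[..., 0]
            quad = (rtr - np.einsum("jq,jq->j", Zr, sol) / sigma2) / sigma2
            logdet_Su = logdet_Om + 2.0 * np.log(tau).sum()
            logdet_V = n_p * np.log(sigma2) + logdet_Su + logdet_M
            return float(-0.5 * (n_p * np.log(2 * np.pi) + logdet_V + quad).sum())

        for c in range(self.chains):
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), c]))
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            sigma2 = max(float(np.var(y - X @ beta)), 1e-8)
            a_sig = 1.0
            if q:
                tau = np.full(q, 0.1 * sd_y)
                Omega = np.eye(q)
                Om_inv = np.eye(q)
                logdet_Om = 0.0
                a_tau = np.ones(q)
                u = np.zeros((J, q))
            Zu = np.zeros(n)

            for it in range(self.warmup + S):
                # --- collapsed draw of beta (varying effects marginalized)
                if q:
                    Su_inv = Om_inv / np.outer(tau, tau)
                    Minv = np.linalg.inv(Su_inv[None] + ZtZ / sigma2)
                    prec_b = (XtX / sigma2
                              - np.einsum("jpq,jqr,jsr->ps", XtZ, Minv, XtZ) / sigma2**2
                              + np.diag(1.0 / b_sd**2))
                    lin_b = (Xty / sigma2
                             - np.einsum("jpq,jqr,jr->p", XtZ, Minv, Zty) / sigma2**2
                             + b_mean / b_sd**2)
                else:
                    prec_b = XtX / sigma2 + np.diag(1.0 / b_sd**2)
                    lin_b = Xty / sigma2 + b_mean / b_sd**2
                prec_b = (prec_b + prec_b.T) / 2.0
                chol_b = _safe_cholesky(prec_b)
                beta = _chol_sample(rng, np.linalg.solve(prec_b, lin_b), chol_b)

                if q:
                    # sufficient statistics of the residual r = y - X beta
                    Zr = Zty - np.einsum("jpq,p->jq", XtZ, beta)
                    rtr = (yty_p - 2.0 * Xty_p @ beta
                           + np.einsum("p,jpr,r->j", beta, XtX_p, beta))

                    # exact conditional for the varying effects
                    rhs = Zr / sigma2
                    mean_u = np.einsum("jqr,jr->jq", Minv, rhs)
                    Lm = np.linalg.cholesky(Minv)
                    u = mean_u + np.einsum("jqr,jr->jq", Lm,
                                           rng.standard_normal((J, q)))
                    Zu = np.einsum("ij,ij->i", Z, u[g])

                # --- conjugate variance updates given (beta, u)
                resid = y - X @ beta - Zu
                sigma2 = max(float(_inv_gamma(rng, (nu + n) / 2.0,
                                              nu / a_sig + resid @ resid / 2.0)),
                             sigma2_floor)
                if q:
                    S_u = u.T @ u
                    scale = 2.0 * nu * np.diag(1.0 / a_tau) + S_u
                    Sig_u = _invwishart_rvs(rng, nu + q - 1 + J, scale)
                    tau = np.sqrt(np.diag(Sig_u))
                    Omega = Sig_u / np.outer(tau, tau)
                    Om_inv = np.linalg.inv(Omega)
                    _, logdet_Om = np.linalg.slogdet(Omega)

                    # --- marginal slice moves on the log variances
                    # (funnel-breakers; u is refreshed afterwards)
                    def logf_sigma(t: float) -> float:
                        s2 = np.exp(t)
                        return (-(nu / 2.0) * t - (nu / a_sig) / s2
                                + marginal_loglik(s2, tau, Om_inv, logdet_Om, Zr, rtr))

                    sigma2 = max(float(np.exp(_slice_sample(rng, np.log(sigma2),
                                                            logf_sigma))),
                                 sigma2_floor)

                    for k in range(q):
                        c_k = nu * Om_inv[k, k] / a_tau[k]

                        def logf_tau(t: float, k: int = k, c_k: float = c_k) -> float:
                            tk = tau.copy()
                            tk[k] = np.exp(0.5 * t)
                            return (-((nu + q - 1) / 2.0) * t - c_k * np.exp(-t)
                                    + marginal_loglik(sigma2, tk, Om_inv,
                                                      logdet_Om, Zr, rtr))

                        t_new = _slice_sample(rng, 2.0 * np.log(tau[k]), logf_tau)
                        tau[k] = np.exp(0.5 * t_new)

                    # latent Huang-Wand scales
                    Su_inv_diag = np.diag(Om_inv) / tau**2
                    a_tau = _inv_gamma(rng, (nu + q) / 2.0,
                                       nu * Su_inv_diag + 1.0 / A**2, size=q)

                    # refresh varying effects under the updated variances
                    Su_inv = Om_inv / np.outer(tau, tau)
                    Minv = np.linalg.inv(Su_inv[None] + ZtZ / sigma2)
                    mean_u = np.einsum("jqr,jr->jq", Minv, Zr / sigma2)
                    Lm = np.linalg.cholesky(Minv)
                    u = mean_u + np.einsum("jqr,jr->jq", Lm,
                                           rng.standard_normal((J, q)))
                    Zu = np.einsum("ij,ij->i", Z, u[g])
                    resid = y - X @ beta - Zu

                a_sig = float(_inv_gamma(rng, (nu + 1) / 2.0,
                                         nu / sigma2 + 1.0 / A**2))

                s = it - self.warmup
                if s >= 0:
                    beta_all[c, s] = beta
                    sigma_all[c, s] = np.sqrt(sigma2)
                    if q:
                        u_all[c, s] = u
                        sig_u_all[c, s] = np.outer(tau, tau) * Omega
                    if self.compute_loglik:
                        ll_all[c, s] = stats.norm.logpdf(y, X @ beta + Zu,
                                                         np.sqrt(sigma2))

        self.beta_draws_ = beta_all
        self.sigma_draws_ = sigma_all
        self.u_draws_ = u_all
        self.sigma_u_draws_ = sig_u_all
        if q:
            tau_d = np.sqrt(np.einsum("csii->csi", sig_u_all))
            self.tau_draws_ = tau_d
            self.omega_draws_ = sig_u_all / (tau_d[..., :, None] * tau_d[..., None, :])
        else:
            self.tau_draws_ = self.omega_draws_ = None
        self.loglik_ = ll_all
        self.n_obs_ = len(y)

    def _diagnose(self) -> None:
        report = check_convergence(self, threshold=self.rhat_threshold)
        self.rhat_ = report.table.set_index("parameter")["rhat"]
        self.ess_ = report.table.set_index("parameter")["ess_bulk"]
        self.converged_ = report.passed
        self.warnings_ = list(report.notes)

    # -- prediction ---------------------------------------------------------

    def predict_draws(self, newdata: pd.DataFrame) -> np.ndarray:
        """Population-level expectation X beta per posterior draw.

        Varying effects are marginalized at zero.  Returns an array of
        shape (total draws, n_rows).
        """
        self._check_fitted()
        Xn = fixed_matrix_for(self.design_, newdata)
        beta = self.beta_draws_.reshape(-1, self.beta_draws_.shape[-1])
        return beta @ Xn.T

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Posterior-mean prediction (population level)."""
        return self.predict_draws(newdata).mean(axis=0)

    def prior_predictive(self, data: pd.DataFrame, n_draws: int = 200,
                         seed: int | None = None) -> np.ndarray:
        """Simulate outcomes under the priors (prior-predictive check)."""
        design = build_design(self.formula, data)
        y0 = np.asarray(pd.to_numeric(data[design.parsed.outcome]), dtype=float)
        b_mean, b_sd = _beta_prior(design.X, y0, self.beta_scale)
        sd_y = float(np.std(y0)) or 1.0
        A = self.sd_scale * sd_y
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = np.empty((n_draws, len(y0)))
        q, J = design.n_varying, design.n_groups
        for s in range(n_draws):
            beta = rng.normal(b_mean, b_sd)
            sigma = np.abs(stats.t.rvs(self.nu, scale=A, random_state=rng))
            mu = design.X @ beta
            if q:
                tau = np.abs(stats.t.rvs(self.nu, scale=A, size=q, random_state=rng))
                u = rng.standard_normal((J, q)) * tau
                mu = mu + np.einsum("ij,ij->i", design.Z, u[design.group_index])
            out[s] = mu + rng.normal(0.0, sigma, size=len(y0))
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta_draws_"):
            raise ValidationError("model is not fitted; call fit(data) first")

    @property
    def n_draws_total_(self) -> int:
        self._check_fitted()
        return self.beta_draws_.shape[0] * self.beta_draws_.shape[1]


# ---------------------------------------------------------------------------
# multivariate subscale model


class MultivariateSRSModel(BaseEstimator):
    """Multivariate multilevel model for the five SRS subscales.

    Each subscale follows the same fixed formula (no coefficients shared
    across subscales); residuals are correlated across subscales through a
    free 5x5 covariance, and all subscale-specific varying effects share a
    single joint covariance (3 terms x 5 subscales = 15-dimensional for
    the quadratic model).  Requires a balanced design (equal occasions
    per person).
    """

    def __init__(self, formula: str,
                 outcomes: tuple[str, ...] = ("SA", "SCOG", "SCOM", "SM", "AM"),
                 draws: int = 1000, warmup: int = 500, chains: int = 2,
                 seed: int = 0, nu: float = 2.0, beta_scale: float = 2.5,
                 sd_scale: float = 2.5, rhat_threshold: float = 1.05,
                 compute_loglik: bool = True):
        self.formula = formula
        self.outcomes = outcomes
        self.draws = draws
        self.warmup = warmup
        self.chains = chains
        self.seed = seed
        self.nu = nu
        self.beta_scale = beta_scale
        self.sd_scale = sd_scale
        self.rhat_threshold = rhat_threshold
        self.compute_loglik = compute_loglik

    def fit(self, data: pd.DataFrame, y=None) -> "MultivariateSRSModel":
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required (split R-hat)")
        missing = [o for o in self.outcomes if o not in data.columns]
        if missing:
            raise ValidationError(f"outcome columns missing from data: {missing}")
        df = data.copy()
        design = build_design(self.formula.replace("Score", self.outcomes[0], 1), df)
        Y = np.asarray(df[list(self.outcomes)], dtype=float)
        if not np.isfinite(Y).all():
            raise ValidationError("outcomes contain non-finite values")
        self.design_ = design
        self.Y_ = Y
        self._run_chains(Y, design)
        self._diagnose()
        return self

    def _run_chains(self, Y: np.ndarray, design: DesignMatrices) -> None:
        X, Z, g = design.X, design.Z, design.group_index
        n, p = X.shape
        m = Y.shape[1]
        q0 = design.n_varying
        q = m * q0
        J = design.n_groups
        nu = self.nu

        prior_means = np.empty((p, m))
        prior_sds = np.empty((p, m))
        A_out = np.empty(m)
        for s in range(m):
            prior_means[:, s], prior_sds[:, s] = _beta_prior(X, Y[:, s], self.beta_scale)
            A_out[s] = self.sd_scale * (float(np.std(Y[:, s])) or 1.0)
        A_u = np.repeat(A_out, q0)  # subscale-major ordering of joint effects

        rows = _sorted_group_rows(g, J)
        sizes = {len(r) for r in rows}
        if len(sizes) != 1:
            raise ValidationError("multivariate model requires a balanced design "
                                  "(equal occasions per person)")
        T_per = sizes.pop()
        mT = m * T_per
        # constant per-person blocks (subscale-major vec ordering throughout)
        Xp = np.stack([X[r] for r in rows])               # (J, T, p)
        Zp = np.stack([Z[r] for r in rows])               # (J, T, q0)
        Yp = np.stack([Y[r] for r in rows])               # (J, T, m)
        ZtZ = np.einsum("jta,jtb->jab", Zp, Zp)
        Xt = np.stack([np.kron(np.eye(m), Xp[j]) for j in range(J)])  # (J, mT, pm)
        Kt = np.stack([np.kron(np.eye(m), Zp[j]) for j in range(J)])  # (J, mT, q)
        yt = np.stack([Yp[j].reshape(-1, order="F") for j in range(J)])

        S = self.draws
        B_all = np.empty((self.chains, S, p, m))
        U_all = np.empty((self.chains, S, J, q))
        Se_all = np.empty((self.chains, S, m, m))
        Su_all = np.empty((self.chains, S, q, q))
        ll_all = np.empty((self.chains, S, n)) if self.compute_loglik else None

        vb = prior_sds.reshape(-1, order="F") ** 2  # vec(B), subscale-major
        mb = prior_means.reshape(-1, order="F")
        I_T = np.eye(T_per)

        def marginal_loglik(Sig_e: np.ndarray, Sig_u: np.ndarray,
                            rt: np.ndarray) -> float:
            """Marginal Gaussian log likelihood of the stacked residuals."""
            V = np.kron(Sig_e, I_T)[None] + (Kt @ Sig_u) @ np.transpose(Kt, (0, 2, 1))
            L = np.linalg.cholesky(V)
            logdet = 2.0 * np.log(np.einsum("jii->ji", L)).sum(axis=1)
            sol = np.linalg.solve(L, rt[..., None])[..., 0]
            quad = np.einsum("ja,ja->j", sol, sol)
            return float(-0.5 * (mT * np.log(2 * np.pi) + logdet + quad).sum())

        for c in range(self.chains):
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 100 + c]))
            B = np.linalg.lstsq(X, Y, rcond=None)[0]
            E0 = Y - X @ B
            Sig_e = np.cov(E0.T) + 1e-6 * np.eye(m)
            Sig_e_inv = np.linalg.inv(Sig_e)
            a_e = np.ones(m)
            tau_u = A_u / 10.0
            Om_u = np.eye(q)
            Om_u_inv = np.eye(q)
            a_u = np.ones(q)
            U = np.zeros((J, q))
            ZU = np.zeros((n, m))

            for it in range(self.warmup + S):
                Sig_u = np.outer(tau_u, tau_u) * Om_u

                # --- collapsed draw of B (varying effects marginalized)
                V = (np.kron(Sig_e, I_T)[None]
                     + (Kt @ Sig_u) @ np.transpose(Kt, (0, 2, 1)))
                rhs = np.concatenate([Xt, yt[:, :, None]], axis=2)
                sol = np.linalg.solve(V, rhs)
                prec_b = np.einsum("jab,jac->bc", Xt, sol[:, :, :-1]) + np.diag(1.0 / vb)
                lin_b = np.einsum("jab,ja->b", Xt, sol[:, :, -1]) + mb / vb
                prec_b = (prec_b + prec_b.T) / 2.0
                chol_b = _safe_cholesky(prec_b)
                vecB = _chol_sample(rng, np.linalg.solve(prec_b, lin_b), chol_b)
                B = vecB.reshape(p, m, order="F")

                # stacked per-person residuals given B
                rt = yt - np.einsum("jab,b->ja", Xt, vecB)

                # --- joint varying effects per person given B
                Su_inv = Om_u_inv / np.outer(tau_u, tau_u)
                Rp = Yp - np.einsum("jta,ab->jtb", Xp, B)
                Tmat = np.einsum("jta,jtb->jab", Zp, Rp)
                lin = np.matmul(Tmat, Sig_e_inv)
                lin = np.transpose(lin, (0, 2, 1)).reshape(J, q)
                prec = (np.einsum("ab,jcd->jacbd", Sig_e_inv, ZtZ)
                        .reshape(J, q, q) + Su_inv[None])
                chol = np.linalg.cholesky(prec)
                mean_u = np.linalg.solve(prec, lin[..., None])[..., 0]
                U = mean_u + np.linalg.solve(
                    np.transpose(chol, (0, 2, 1)),
                    rng.standard_normal((J, q))[..., None])[..., 0]
                Ug = U[g].reshape(n, m, q0)
                ZU = np.einsum("ij,isj->is", Z, Ug)

                # --- residual covariance across subscales (conjugate)
                E = Y - X @ B - ZU
                scale_e = 2.0 * nu * np.diag(1.0 / a_e) + E.T @ E
                Sig_e = _invwishart_rvs(rng, nu + m - 1 + n, scale_e)
                Sig_e_inv = np.linalg.inv(Sig_e)
                a_e = _inv_gamma(rng, (nu + m) / 2.0,
                                 nu * np.diag(Sig_e_inv) + 1.0 / A_out**2, size=m)

                # --- joint varying-effect covariance (conjugate)
                S_u = U.T @ U
                scale_u = 2.0 * nu * np.diag(1.0 / a_u) + S_u
                Sig_u = _invwishart_rvs(rng, nu + q - 1 + J, scale_u)
                tau_u = np.sqrt(np.diag(Sig_u))
                Om_u = Sig_u / np.outer(tau_u, tau_u)
                Om_u_inv = np.linalg.inv(Om_u)

                # --- marginal slice moves on the varying-effect log scales
                for k in range(q):
                    c_k = nu * Om_u_inv[k, k] / a_u[k]

                    def logf_tau(t: float, k: int = k, c_k: float = c_k) -> float:
                        tk = tau_u.copy()
                        tk[k] = np.exp(0.5 * t)
                        Sk = np.outer(tk, tk) * Om_u
                        return (-((nu + q - 1) / 2.0) * t - c_k * np.exp(-t)
                                + marginal_loglik(Sig_e, Sk, rt))

                    t_new = _slice_sample(rng, 2.0 * np.log(tau_u[k]), logf_tau)
                    tau_u[k] = np.exp(0.5 * t_new)

                Su_inv_diag = np.diag(Om_u_inv) / tau_u**2
                a_u = _inv_gamma(rng, (nu + q) / 2.0,
                                 nu * Su_inv_diag + 1.0 / A_u**2, size=q)

                # refresh varying effects under the updated covariance
                Su_inv = Om_u_inv / np.outer(tau_u, tau_u)
                prec = (np.einsum("ab,jcd->jacbd", Sig_e_inv, ZtZ)
                        .reshape(J, q, q) + Su_inv[None])
                chol = np.linalg.cholesky(prec)
                mean_u = np.linalg.solve(prec, lin[..., None])[..., 0]
                U = mean_u + np.linalg.solve(
                    np.transpose(chol, (0, 2, 1)),
                    rng.standard_normal((J, q))[..., None])[..., 0]
                Ug = U[g].reshape(n, m, q0)
                ZU = np.einsum("ij,isj->is", Z, Ug)
                E = Y - X @ B - ZU

                s_idx = it - self.warmup
                if s_idx >= 0:
                    B_all[c, s_idx] = B
                    U_all[c, s_idx] = U
                    Se_all[c, s_idx] = Sig_e
                    Su_all[c, s_idx] = np.outer(tau_u, tau_u) * Om_u
                    if self.compute_loglik:
                        L_e = np.linalg.cholesky(Sig_e)
                        sol_e = np.linalg.solve(L_e, E.T)
                        ll_all[c, s_idx] = (
                            -0.5 * m * np.log(2 * np.pi)
                            - np.log(np.diag(L_e)).sum()
                            - 0.5 * (sol_e**2).sum(axis=0)
                        )

        self.beta_draws_ = B_all
        self.u_draws_ = U_all
        self.sigma_e_draws_ = Se_all
        self.sigma_u_draws_ = Su_all
        self.loglik_ = ll_all
        self.n_obs_ = n

    def _diagnose(self) -> None:
        report = check_convergence(self, threshold=self.rhat_threshold)
        self.rhat_ = report.table.set_index("parameter")["rhat"]
        self.ess_ = report.table.set_index("parameter")["ess_bulk"]
        self.converged_ = report.passed
        self.warnings_ = list(report.notes)

    def predict_draws(self, newdata: pd.DataFrame) -> np.ndarray:
        """Population expectations; shape (total draws, n_rows, n_subscales)."""
        if not hasattr(self, "beta_draws_"):
            raise ValidationError("model is not fitted; call fit(data) first")
        Xn = fixed_matrix_for(self.design_, newdata)
        c, s, p, m = self.beta_draws_.shape
        B = self.beta_draws_.reshape(c * s, p, m)
        return np.einsum("ij,sjm->sim", Xn, B)

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        return self.predict_draws(newdata).mean(axis=0)


# ---------------------------------------------------------------------------
# convergence diagnostics


def _posterior_dict(fit) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    beta = fit.beta_draws_
    if beta.ndim == 4:  # multivariate: (c, s, p, m)
        for mi, name in enumerate(fit.outcomes):
            for j, col in enumerate(fit.design_.columns):
                out[f"b[{name}:{col}]"] = beta[:, :, j, mi]
        tau = np.sqrt(np.einsum("csii->csi", fit.sigma_e_draws_))
        for mi, name in enumerate(fit.outcomes):
            out[f"sigma[{name}]"] = tau[:, :, mi]
    else:
        for j, col in enumerate(fit.design_.columns):
            out[f"b[{col}]"] = beta[:, :, j]
        out["sigma"] = fit.sigma_draws_
        if fit.tau_draws_ is not None:
            for k, col in enumerate(fit.design_.z_columns):
                out[f"tau[{col}]"] = fit.tau_draws_[:, :, k]
    return out


def check_convergence(fit, threshold: float = 1.05) -> ConvergenceReport:
    """Split-R-hat and bulk ESS for every reported parameter.

    Fails (``passed=False``) when any R-hat exceeds ``threshold`` or is
    ill-defined (zero-variance chains yield NaN, which is flagged rather
    than silently passed).  Requires at least two chains.
    """
    import warnings

    import arviz as az

    params = _posterior_dict(fit)
    first = next(iter(params.values()))
    if first.shape[0] < 2:
        raise ValidationError("split R-hat requires at least 2 chains")
    rows = []
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=params)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    for name in params:
        r = float(rhat[name].values)
        e = float(ess[name].values)
        rows.append((name, r, e))
        if np.isnan(r):
            notes.append(f"R-hat ill-defined for {name} (zero-variance chains)")
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
    finite = table["rhat"].dropna()
    max_rhat = float(finite.max()) if len(finite) else float("nan")
    min_ess = float(table["ess_bulk"].min())
    passed = bool(len(finite) == len(table) and (finite <= threshold).all())
    if not passed and not notes:
        bad = table.loc[table["rhat"] > threshold, "parameter"].tolist()
        notes.append(f"R-hat above {threshold}: {bad}")
    return ConvergenceReport(table=table, max_rhat=max_rhat, min_ess=min_ess,
                             passed=passed, notes=notes)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter from (n_chains, n_draws) draws.

    Reference implementation of the rank-free split formula; used as an
    independent check of the arviz-backed report.
    """
    chains = np.asarray(chains, dtype=float)
    c, s = chains.shape
    half = s // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    mtot, ndraw = splits.shape
    means = splits.mean(axis=1)
    B = ndraw * means.var(ddof=1)
    W = splits.var(axis=1, ddof=1).mean()
    if W == 0:
        return float("nan")
    var_plus = (ndraw - 1) / ndraw * W + B / ndraw
    return float(np.sqrt(var_plus / W))
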