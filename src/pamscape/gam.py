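"""Quasi-binomial penalized-spline presence models.

Daily acoustic presence — the proportion of recorded hours per day with at
least one detection, with the recorded hours as binomial trials — is
modelled on the logit scale as a sum of smooth functions of the
environmental covariates:

    logit E[y_t] = β₀ + Σ_j f_j(x_jt),    Var[y_t] = φ·μ(1−μ)/n_t

Each f_j is a low-rank thin-plate-type spline: a cubic radial basis
|x − κ|³ on k knots with the usual sum-to-zero/orthogonality constraints
absorbed, plus an unpenalized linear part; the penalty is the thin-plate
bending energy of the radial coefficients. Smoothing parameters are chosen
by a restricted-maximum-likelihood criterion evaluated on the working
Gaussian model of the penalized IRLS fit (performance iteration), and the
quasi-binomial dispersion φ comes from the Pearson statistic.

The fitting-object idiom: ``PresenceGAM(y, trials, X).fit()`` returns a
:class:`PresenceGAMResults` with coefficients, smooth-term effective
degrees of freedom, approximate p-values, dispersion, partial-effect
curves with 95% intervals, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class ConvergenceError(RuntimeError):
    pass


def _tps_basis(x: np.ndarray, knots: np.ndarray):
    """Constrained cubic radial basis and its penalty for one covariate.

    Returns (columns, penalty): ``columns`` has one unpenalized linear
    column followed by k−2 penalized radial columns; ``penalty`` is the
    (k−2)×(k−2) bending-energy matrix of the radial block.
    """
    k = knots.size
    E = np.abs(knots[:, None] - knots[None, :]) ** 3
    C = np.vstack([np.ones(k), knots])  # Σδ = 0, Σδκ = 0
    # null space of the constraints
    _, _, vt = np.linalg.svd(C, full_matrices=True)
    Z = vt[2:].T  # k × (k−2)
    B = np.abs(x[:, None] - knots[None, :]) ** 3 @ Z
    S = Z.T @ E @ Z
    S = 0.5 * (S + S.T)
    return np.column_stack([x, B]), S


@dataclass
class _SmoothTerm:
    name: str
    columns: slice  # location in the full design matrix
    penalty: np.ndarray  # penalty for the radial block (offset by 1 col)
    knots: np.ndarray
    x_mean: float
    x_scale: float
    col_means: np.ndarray

    def design(self, x_raw: np.ndarray) -> np.ndarray:
        x = (np.asarray(x_raw, dtype=float) - self.x_mean) / self.x_scale
        if self.penalty.size == 0:  # degenerate covariate: linear term only
            cols = x[:, None]
        else:
            cols, _ = _tps_basis(x, self.knots)
        return cols - self.col_means[None, :]


class PresenceGAM:
    """Quasi-binomial GAM for daily proportional presence.

    Parameters
    ----------
    proportions : array of daily presence proportions in [0, 1].
    trials : array of recorded hours per day (binomial weights).
    predictors : DataFrame of covariates; one spline per column.
    k : basis dimension per smooth (default 10).
    """

    def __init__(
        self,
        proportions,
        trials,
        predictors: pd.DataFrame,
        *,
        k: int = 10,
    ):
        y = np.asarray(proportions, dtype=float)
        n = np.asarray(trials, dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.any(n < 1):
            raise ValueError("trials must be ≥ 1")
        X = predictors.astype(float)
        if X.isna().any().any():
            raise ValueError("missing covariate values; apply listwise deletion first")
        if len(X) != y.size or n.size != y.size:
            raise ValueError("response, trials and predictors must align")
        self.y = y
        self.trials = n
        self.predictors = X
        self.k = int(k)
        self._build_design()

    @classmethod
    def from_daily(
        cls, daily: pd.DataFrame, species: str, covariates: pd.DataFrame, *, k: int = 10
    ) -> "PresenceGAM":
        """Build from tidy daily presence (date, species, positive/recorded)."""
        d = daily[daily["species"] == species].set_index("date")
        joined = d.join(covariates, how="inner").dropna()
        return cls(
            joined["positive_hours"] / joined["recorded_hours"],
            joined["recorded_hours"],
            joined[covariates.columns],
            k=k,
        )

    def _build_design(self) -> None:
        n_obs = self.y.size
        blocks = [np.ones((n_obs, 1))]
        self.terms: list[_SmoothTerm] = []
        start = 1
        for name in self.predictors.columns:
            raw = self.predictors[name].values.astype(float)
            mu, sd = raw.mean(), raw.std()
            sd = sd if sd > 0 else 1.0
            x = (raw - mu) / sd
            qs = np.linspace(0, 1, self.k)
            knots = np.unique(np.quantile(x, qs))
            if np.unique(x).size < 2:
                raise ValueError(f"covariate {name!r} is constant")
            if knots.size < 4:
                # too few distinct values for a spline: linear term only
                cols, S = x[:, None], np.zeros((0, 0))
            else:
                cols, S = _tps_basis(x, knots)
            col_means = cols.mean(axis=0)
            cols = cols - col_means[None, :]
            width = cols.shape[1]
            self.terms.append(
                _SmoothTerm(
                    name=name,
                    columns=slice(start, start + width),
                    penalty=S,
                    knots=knots,
                    x_mean=mu,
                    x_scale=sd,
                    col_means=col_means,
                )
            )
            blocks.append(cols)
            start += width
        self.design = np.column_stack(blocks)
        self.n_coef = self.design.shape[1]

    def _penalty_full(self, log_lambda: np.ndarray) -> np.ndarray:
        S = np.zeros((self.n_coef, self.n_coef))
        for lam, term in zip(np.exp(log_lambda), self.terms):
            if term.penalty.size == 0:
                continue
            sl = slice(term.columns.start + 1, term.columns.stop)  # radial block
            S[sl, sl] += lam * term.penalty
        return S

    def _pirls(self, S: np.ndarray, beta0=None, max_iter: int = 100, tol: float = 1e-9):
        """Penalized IRLS for the quasi-binomial logit model."""
        X, y, n = self.design, self.y, self.trials
        beta = np.zeros(self.n_coef) if beta0 is None else beta0.copy()
        eta = X @ beta
        dev = np.inf
        for _ in range(max_iter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, 1e-8, 1.0 - 1e-8)
            w = n * mu * (1.0 - mu)
            z = eta + (y - mu) / (mu * (1.0 - mu))
            XtW = X.T * w
            A = XtW @ X + S
            beta_new = np.linalg.solve(A, XtW @ z)
            eta_new = X @ beta_new
            dev_new = self._deviance(eta_new) + beta_new @ S @ beta_new
            if not np.isfinite(dev_new):
                raise ConvergenceError("penalized IRLS diverged (non-finite deviance)")
            done = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
            beta, eta, dev = beta_new, eta_new, dev_new
            if done:
                return beta, eta, A, w, z
        raise ConvergenceError(f"penalized IRLS did not converge in {max_iter} iterations")

    def _deviance(self, eta: np.ndarray) -> float:
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        y, n = self.y, self.trials
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(n * (t1 + t2)))

    def _reml(self, log_lambda: np.ndarray, state: dict) -> float:
        """Working-model REML criterion (performance iteration)."""
        log_lambda = np.clip(log_lambda, -12.0, 18.0)
        S = self._penalty_full(log_lambda)
        try:
            beta, eta, A, w, z = self._pirls(S, beta0=state.get("beta"))
        except (ConvergenceError, np.linalg.LinAlgError):
            return 1e10
        state["beta"] = beta
        n_obs = self.y.size
        rss_p = float(w @ (z - self.design @ beta) ** 2 + beta @ S @ beta)
        # null space: intercept + one linear column per smooth
        m_null = 1 + len(self.terms)
        phi = max(rss_p / max(n_obs - m_null, 1), 1e-12)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e10
        logdet_s = 0.0
        for lam_log, term in zip(log_lambda, self.terms):
            p_j = term.penalty.shape[0]
            if p_j == 0:
                continue
            sign_j, ld_j = np.linalg.slogdet(term.penalty)
            logdet_s += p_j * lam_log + ld_j
        # Gaussian REML of the working model at the converged fit, with the
        # working dispersion plugged in (performance iteration)
        return 0.5 * (
            rss_p / phi
            + logdet_a
            - logdet_s
            + (n_obs - m_null) * np.log(2.0 * np.pi * phi)
        )

    def fit(self, *, method: str = "reml", maxiter: int = 200) -> "PresenceGAMResults":
        """Estimate smoothing parameters and coefficients.

        ``method='reml'`` optimizes the working-model REML criterion over
        log smoothing parameters with Nelder–Mead; ``method='fixed'`` keeps
        λ = 1 for every term.
        """
        n_terms = len(self.terms)
        state: dict = {}
        if method == "fixed":
            loglam = np.zeros(n_terms)
        elif method == "reml":
            x0 = np.full(n_terms, 2.0)
            res = optimize.minimize(
                self._reml,
                x0,
                args=(state,),
                method="Nelder-Mead",
                options={"maxiter": maxiter * n_terms, "xatol": 1e-3, "fatol": 1e-4},
            )
            loglam = np.clip(res.x, -12.0, 18.0)
        else:
            raise ValueError(f"unknown method {method!r}")

        S = self._penalty_full(loglam)
        beta, eta, A, w, z = self._pirls(S, beta0=state.get("beta"))
        A_inv = np.linalg.inv(A)
        XtWX = (self.design.T * w) @ self.design
        F = A_inv @ XtWX  # edf matrix
        edf = np.diag(F)
        edf_total = float(edf.sum())
        mu = 1.0 / (1.0 + np.exp(-eta))
        pearson = float(
            np.sum(self.trials * (self.y - mu) ** 2 / np.clip(mu * (1 - mu), 1e-10, None))
        )
        phi = pearson / max(self.y.size - edf_total, 1.0)
        cov = phi * A_inv  # Bayesian posterior covariance of β

        return PresenceGAMResults(
            model=self,
            params=beta,
            cov_params=cov,
            smoothing=np.exp(loglam),
            edf_by_coef=edf,
            dispersion=phi,
            fitted_values=mu,
            linear_predictor=eta,
            deviance=self._deviance(eta),
        )


@dataclass
class PresenceGAMResults:
    """Fitted presence GAM: coefficients, smooths, dispersion, intervals."""

    model: PresenceGAM
    params: np.ndarray
    cov_params: np.ndarray
    smoothing: np.ndarray
    edf_by_coef: np.ndarray
    dispersion: float
    fitted_values: np.ndarray
    linear_predictor: np.ndarray
    deviance: float

    @property
    def edf(self) -> pd.Series:
        """Effective degrees of freedom per smooth term (incl. linear part)."""
        return pd.Series(
            {t.name: float(self.edf_by_coef[t.columns].sum()) for t in self.model.terms}
        )

    @property
    def penalized_edf(self) -> pd.Series:
        """EDF of the penalized (wiggly) part of each smooth only."""
        out = {}
        for t in self.model.terms:
            sl = slice(t.columns.start + 1, t.columns.stop)
            out[t.name] = float(self.edf_by_coef[sl].sum())
        return pd.Series(out)

    @property
    def edf_total(self) -> float:
        return float(self.edf_by_coef.sum())

    def quasi_aic(self) -> float:
        """QAIC = deviance/φ + 2·edf (for AIC-style term comparison)."""
        return self.deviance / self.dispersion + 2.0 * self.edf_total

    def term_pvalue(self, name: str) -> float:
        """Approximate Wald test that the whole smooth is zero (quasi-F)."""
        term = next(t for t in self.model.terms if t.name == name)
        sl = term.columns
        b = self.params[sl]
        V = self.cov_params[sl, sl]
        r = max(1.0, round(float(self.edf_by_coef[sl].sum())))
        stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b) / r
        df_resid = max(self.model.y.size - self.edf_total, 1.0)
        return float(stats.f.sf(stat, r, df_resid))

    def spline_effect(self, name: str, grid=None, *, n_points: int = 100):
        """Centered partial effect of one covariate on the link scale.

        Returns a DataFrame (x, effect, lower, upper) with pointwise 95%
        Bayesian intervals. The effect is centred so its average over the
        observed covariate values is zero (sum-to-zero identifiability).
        """
        term = next((t for t in self.model.terms if t.name == name), None)
        if term is None:
            raise KeyError(f"covariate {name!r} not in the fitted model")
        if grid is None:
            x_obs = self.model.predictors[name].values.astype(float)
            grid = np.linspace(x_obs.min(), x_obs.max(), n_points)
        grid = np.asarray(grid, dtype=float)
        Xg = term.design(grid)
        b = self.params[term.columns]
        V = self.cov_params[term.columns, term.columns]
        eff = Xg @ b
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        zq = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {"x": grid, "effect": eff, "lower": eff - zq * se, "upper": eff + zq * se}
        )

    def summary(self) -> str:
        lines = [
            "Quasi-binomial penalized-spline presence model",
            f"  n = {self.model.y.size}, total edf = {self.edf_total:.2f}, "
            f"dispersion = {self.dispersion:.3f}",
            f"  deviance = {self.deviance:.2f}, QAIC = {self.quasi_aic():.2f}",
            "  smooth        edf    lambda      p-value",
        ]
        for t, lam in zip(self.model.terms, self.smoothing):
            lines.append(
                f"  s({t.name:<10}) {self.edf[t.name]:5.2f}  {lam:9.3g}  "
                f"{self.term_pvalue(t.name):9.4f}"
            )
        return "\n".join(lines)

    def plot_splines(self, axes=None):
        """Panel of partial-effect curves with 95% intervals."""
        import matplotlib.pyplot as plt

        names = [t.name for t in self.model.terms]
        if axes is None:
            _, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2))
            axes = np.atleast_1d(axes)
        for ax, name in zip(axes, names):
            eff = self.spline_effect(name)
            ax.plot(eff["x"], eff["effect"], "k-")
            ax.fill_between(eff["x"], eff["lower"], eff["upper"], alpha=0.3)
            ax.set_xlabel(name)
            ax.set_ylabel(f"s({name})")
        return axes


def backward_select(model: PresenceGAM, *, verbose: bool = False) -> PresenceGAMResults:
    """Drop smooths that do not improve the QAIC (backward elimination).

    Mirrors selecting only predictors that improve the model fit: terms are
    removed one at a time while removal lowers the QAIC.
    """
    cols = list(model.predictors.columns)
    best = model.fit()
    improved = True
    while improved and len(cols) > 1:
        improved = False
        for name in list(cols):
            trial_cols = [c for c in cols if c != name]
            trial = PresenceGAM(
                model.y, model.trials, model.predictors[trial_cols], k=model.k
            ).fit()
            if trial.quasi_aic() < best.quasi_aic():
                best, cols, improved = trial, trial_cols, True
                if verbose:
                    print(f"dropped {name}: QAIC {best.quasi_aic():.2f}")
                break
    return best
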