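"""Constrained correspondence analysis and collinearity screening.

CCA relates a site × species abundance table to environmental predictors:
the chi-square-standardized abundance residuals are projected onto the
row-weighted span of the predictors and the projection is decomposed by
SVD. Constrained eigenvalues measure the species-composition inertia
explained by the environment; the remainder is unconstrained.

The model/results split follows the fitting-object idiom: ``CCA(Y, X)``
holds data, ``.fit()`` returns a :class:`CCAResults` with eigenvalues,
scores, biplot arrows and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 − R²_j).

    Each predictor is regressed (with intercept) on all the others. Exactly
    collinear predictors report ``inf``. Values near 1 indicate no
    collinearity; above 10, strong collinearity.
    """
    X = predictors.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    import statsmodels.api as sm

    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col).values)
        r2 = sm.OLS(X[col].values, others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class CCAResults:
    """Eigenvalues, inertia decomposition and (type-2 scaled) scores."""

    eigenvalues: np.ndarray  # constrained, non-increasing
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    species_scores: pd.DataFrame  # species × axes
    site_scores: pd.DataFrame  # sites × axes (linear-combination scores)
    biplot_scores: pd.DataFrame  # predictors × axes
    model: "CCA" = dc_field(repr=False, default=None)

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia

    def summary(self) -> str:
        lines = [
            "Constrained correspondence analysis",
            f"  sites: {self.site_scores.shape[0]}, species: {self.species_scores.shape[0]}, "
            f"predictors: {self.biplot_scores.shape[0]}",
            f"  total inertia:       {self.total_inertia:.4f}",
            f"  constrained inertia: {self.constrained_inertia:.4f} "
            f"({100 * self.constrained_inertia / self.total_inertia:.1f}%)",
            "  axis  eigenvalue  proportion",
        ]
        for i, ev in enumerate(self.eigenvalues):
            lines.append(f"  CCA{i + 1}   {ev:.4f}      {ev / self.total_inertia:.3f}")
        return "\n".join(lines)

    def plot_biplot(self, ax=None, arrow_scale: float = 1.0):
        """Species points and predictor arrows on the first two axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        sp = self.species_scores
        ax.scatter(sp.iloc[:, 0], sp.iloc[:, 1], c="k", s=12)
        for name, row in sp.iterrows():
            ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=9)
        for name, row in self.biplot_scores.iterrows():
            ax.annotate(
                "",
                xy=(arrow_scale * row.iloc[0], arrow_scale * row.iloc[1]),
                xytext=(0, 0),
                arrowprops=dict(color="red", arrowstyle="->"),
            )
            ax.annotate(str(name), (arrow_scale * row.iloc[0], arrow_scale * row.iloc[1]),
                        color="red", fontsize=9)
        p = self.proportion_explained
        ax.set_xlabel(f"CCA1 ({100 * p[0]:.1f}%)")
        if p.size > 1:
            ax.set_ylabel(f"CCA2 ({100 * p[1]:.1f}%)")
        ax.axhline(0, lw=0.5, c="grey")
        ax.axvline(0, lw=0.5, c="grey")
        return ax


class CCA:
    """Constrained correspondence analysis of a community matrix.

    Parameters
    ----------
    community : DataFrame (days × species) of non-negative abundances
        (here daily positive hours, 0–24).
    predictors : DataFrame (days × predictors) of environmental covariates.
    """

    def __init__(self, community: pd.DataFrame, predictors: pd.DataFrame):
        Y = community.astype(float)
        X = predictors.astype(float)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("community and predictors must share rows")
        if (Y.values < 0).any():
            raise ValueError("negative abundances")
        zero_rows = Y.index[Y.sum(axis=1) == 0].tolist()
        if zero_rows:
            raise ValueError(f"all-zero community rows (undefined chi-square): {zero_rows[:5]}")
        zero_cols = Y.columns[Y.sum(axis=0) == 0].tolist()
        if zero_cols:
            raise ValueError(f"all-zero species columns: {zero_cols}")
        if Y.shape[0] <= X.shape[1]:
            raise ValueError("need more sites than predictors")
        self.community = Y
        self.predictors = X

    @classmethod
    def from_dataframes(cls, daily_presence: pd.DataFrame, covariates: pd.DataFrame) -> "CCA":
        """Align on common dates and drop rows with missing covariates."""
        common = daily_presence.index.intersection(covariates.index)
        X = covariates.loc[common].dropna()
        return cls(daily_presence.loc[X.index], X)

    def fit(self) -> CCAResults:
        Y = self.community.values
        X = self.predictors.values
        total = Y.sum()
        P = Y / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))

        # row-weighted, centred predictors: Xs = √r · (X − x̄_w)
        xbar = r @ X
        Xs = np.sqrt(r)[:, None] * (X - xbar)
        # projection of Q onto span(Xs)
        U_x, _, _ = np.linalg.svd(Xs, full_matrices=False)
        rank = int(np.sum(np.linalg.svd(Xs, compute_uv=False) > 1e-10 * max(1.0, abs(Xs).max())))
        U_x = U_x[:, :rank]
        fitted = U_x @ (U_x.T @ Q)

        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        pos = s > 1e-12
        n_axes = min(int(pos.sum()), rank, Y.shape[1] - 1)
        U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
        eig = s**2

        resid = Q - fitted
        s_r = np.linalg.svd(resid, compute_uv=False)
        eig_u = (s_r**2)[s_r**2 > 1e-12]

        axes = [f"CCA{i + 1}" for i in range(n_axes)]
        # type-2 (species) scaling: species scores carry the eigenvalue scale
        spec = (Vt.T / np.sqrt(c)[:, None]) * s[None, :]
        sites = U / np.sqrt(r)[:, None]
        # biplot arrows: correlations of the standardized constraints with
        # the constrained site axes
        norms = np.linalg.norm(Xs, axis=0, keepdims=True)
        Xs_norm = np.divide(Xs, norms, out=np.zeros_like(Xs), where=norms > 0)
        bip = Xs_norm.T @ U

        return CCAResults(
            eigenvalues=eig,
            unconstrained_eigenvalues=eig_u,
            total_inertia=float((Q**2).sum()),
            species_scores=pd.DataFrame(spec, index=self.community.columns, columns=axes),
            site_scores=pd.DataFrame(sites, index=self.community.index, columns=axes),
            biplot_scores=pd.DataFrame(bip, index=self.predictors.columns, columns=axes),
            model=self,
        )
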