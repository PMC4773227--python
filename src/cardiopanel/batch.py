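"""Batch adjustment and cohort-merge diagnostics.

Merging cohorts processed in different laboratories introduces
non-biological location/scale differences per gene.  The adjustment here is
the parametric empirical-Bayes location/scale model: per gene g and batch i,

    x_gij = alpha_g + X beta_g + gamma_gi + delta_gi * eps_gij,

where gamma_gi (additive) has a normal prior across genes and delta_gi^2
(multiplicative) an inverse-gamma prior, both with method-of-moments
hyper-parameters and iteratively refined posterior estimates.  The class
label is kept as a covariate in the standardisation design so case/control
signal is not removed when batches are confounded with cohorts.

Diagnostics: classical (Torgerson) multidimensional scaling of the sample
distance matrix, quantile normalisation, and per-chip five-number summaries
for QC boxplots.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datasets import CASE, ExpressionDataset

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


class BatchModel:
    """Fitted location/scale batch model; ``transform`` removes the effects."""

    def __init__(self, data: ExpressionDataset, max_iter: int = 100, tol: float = 1e-4):
        if data.batch is None:
            raise ValueError("dataset has no batch assignment")
        self.batches = list(pd.unique(data.batch))
        if len(self.batches) < 2:
            raise ValueError("batch adjustment needs >= 2 batches")
        sizes = data.batch.value_counts()
        small = [b for b in self.batches if sizes[b] < 2]
        if small:
            raise ValueError(f"batch(es) with < 2 samples: {small}")
        self.data = data
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> "BatchAdjustmentResult":
        data = self.data
        x = data.values.to_numpy()  # genes x samples
        n_genes, n = x.shape
        batch_ids = data.batch.to_numpy()
        batch_cols = {b: np.flatnonzero(batch_ids == b) for b in self.batches}
        n_per = np.array([batch_cols[b].size for b in self.batches], float)

        # design: batch one-hot + class covariate
        design_batch = np.column_stack(
            [(batch_ids == b).astype(float) for b in self.batches])
        covariate = (data.labels == CASE).to_numpy(float)[:, None]
        if np.all(covariate == covariate[0]):
            covariate = np.empty((n, 0))  # single-class cohort: no covariate
        design = np.hstack([design_batch, covariate])

        b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # (B+c) x genes
        n_b = len(self.batches)
        grand_mean = (n_per / n) @ b_hat[:n_b]
        resid = x - (design @ b_hat).T
        var_pooled = (resid**2).mean(axis=1)
        n_floored = int((var_pooled < _VAR_FLOOR).sum())
        if n_floored:
            logger.warning("flooring %d near-zero gene variances at %g",
                           n_floored, _VAR_FLOOR)
        var_pooled = np.maximum(var_pooled, _VAR_FLOOR)

        stand_mean = grand_mean[:, None] + (covariate @ b_hat[n_b:]).T
        z = (x - stand_mean) / np.sqrt(var_pooled)[:, None]

        gamma_star = np.zeros((n_b, n_genes))
        delta_star = np.ones((n_b, n_genes))
        self.prior_params = []
        for i, b in enumerate(self.batches):
            cols = batch_cols[b]
            zb = z[:, cols]
            gamma_hat = zb.mean(axis=1)
            delta_hat = zb.var(axis=1, ddof=1)
            delta_hat = np.maximum(delta_hat, _VAR_FLOOR)
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
            s2 = max(s2, _VAR_FLOOR)
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            g, d2 = self._iterate_eb(zb, gamma_hat, delta_hat, gamma_bar,
                                     tau2, a_prior, b_prior)
            gamma_star[i], delta_star[i] = g, d2
            self.prior_params.append(
                {"batch": b, "gamma_bar": gamma_bar, "tau2": tau2,
                 "a_prior": a_prior, "b_prior": b_prior})

        adjusted = z.copy()
        for i, b in enumerate(self.batches):
            cols = batch_cols[b]
            adjusted[:, cols] = (adjusted[:, cols] - gamma_star[i][:, None]) / \
                np.sqrt(delta_star[i])[:, None]
        adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

        out = ExpressionDataset(
            values=pd.DataFrame(adjusted, index=data.values.index,
                                columns=data.values.columns),
            labels=data.labels.copy(), batch=data.batch.copy(),
            truth=data.truth, clean_values=data.clean_values, name=data.name)
        return BatchAdjustmentResult(
            adjusted=out, gamma_star=gamma_star, delta_star=delta_star,
            grand_mean=grand_mean, var_pooled=var_pooled,
            batches=self.batches, prior_params=self.prior_params)

    def _iterate_eb(self, zb, gamma_hat, delta_hat, gamma_bar, tau2,
                    a_prior, b_prior):
        n_i = zb.shape[1]
        gamma = gamma_hat.copy()
        delta2 = delta_hat.copy()
        for _ in range(self.max_iter):
            gamma_new = (n_i * tau2 * gamma_hat + delta2 * gamma_bar) / \
                (n_i * tau2 + delta2)
            ss = ((zb - gamma_new[:, None]) ** 2).sum(axis=1)
            delta_new = (0.5 * ss + b_prior) / (n_i / 2.0 + a_prior - 1.0)
            change = max(np.abs(gamma_new - gamma).max(initial=0),
                         np.abs(delta_new - delta2).max(initial=0))
            gamma, delta2 = gamma_new, delta_new
            if change < self.tol:
                break
        return gamma, np.maximum(delta2, _VAR_FLOOR)


class BatchAdjustmentResult:
    def __init__(self, adjusted, gamma_star, delta_star, grand_mean,
                 var_pooled, batches, prior_params):
        self.adjusted = adjusted
        self.gamma_star = gamma_star
        self.delta_star = delta_star
        self.grand_mean = grand_mean
        self.var_pooled = var_pooled
        self.batches = batches
        self.prior_params = prior_params

    def summary(self) -> str:
        lines = ["Empirical-Bayes batch adjustment (parametric location/scale)"]
        for i, b in enumerate(self.batches):
            lines.append(
                f"  batch {b}: mean |gamma*| {np.abs(self.gamma_star[i]).mean():.4f}, "
                f"mean delta*^2 {self.delta_star[i].mean():.4f}")
        return "\n".join(lines)


def combat_adjust(data: ExpressionDataset) -> ExpressionDataset:
    """Remove per-batch location/scale effects; dimensions are unchanged."""
    return BatchModel(data).fit().adjusted


# ---------------------------------------------------------------------------
# diagnostics

def mds_coords(data: ExpressionDataset, features: list[str] | int | None = None,
               n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) scaling of the sample Euclidean distance matrix.

    ``features`` may be an explicit probe list, ``None`` (all probes), or an
    integer n meaning "the n least differentially expressed probes" (the n
    smallest |moderated t| between the classes) — the panel used to check
    that residual structure is not class-driven.  Coordinates are defined up
    to rotation/reflection.
    """
    if data.n_samples < n_dims + 1:
        raise ValueError("need more samples than embedding dimensions")
    if isinstance(features, int):
        from .discovery import ModeratedTTest

        table = ModeratedTTest(data).fit().table
        order = table.assign(_abs_t=table["t_mod"].abs(), _id=table.index.astype(str))
        order = order.sort_values(["_abs_t", "_id"], kind="stable")
        features = list(order.index[:features])
    x = data.values.to_numpy() if features is None else data.values.loc[features].to_numpy()

    sq = (x**2).sum(axis=0)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x.T @ x), 0.0)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    eigval, eigvec = linalg.eigh(gram)
    idx = np.argsort(eigval)[::-1][:n_dims]
    lam = np.maximum(eigval[idx], 0.0)
    coords = eigvec[:, idx] * np.sqrt(lam)[None, :]
    return pd.DataFrame(coords, index=data.sample_ids,
                        columns=[f"dim{i + 1}" for i in range(n_dims)])


def batch_separation(coords: pd.DataFrame, batch: pd.Series, dim: str = "dim1") -> float:
    """Ratio of between-batch centroid gap to within-batch spread on one axis.

    > 1 means the batches are visibly separated along that MDS dimension.
    """
    axis = coords[dim]
    groups = [axis[batch == b] for b in pd.unique(batch)]
    centroids = [g.mean() for g in groups]
    gap = max(centroids) - min(centroids)
    spread = float(np.mean([g.std(ddof=1) for g in groups]))
    return gap / max(spread, 1e-12)


def quantile_normalise(data: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the common (across-sample mean) distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties take the mean of their would-be quantile values.
    """
    x = data.values.to_numpy()
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(x.shape[0], dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return ExpressionDataset(
        values=pd.DataFrame(out, index=data.values.index, columns=data.values.columns),
        labels=data.labels.copy(), batch=None if data.batch is None else data.batch.copy(),
        truth=data.truth, name=data.name)


def log2_transform(data: ExpressionDataset, offset: float = 1.0) -> ExpressionDataset:
    """log2(x + offset) for raw-intensity matrices."""
    return ExpressionDataset(
        values=np.log2(data.values + offset),
        labels=data.labels.copy(),
        batch=None if data.batch is None else data.batch.copy(),
        truth=data.truth, name=data.name)


def qc_boxplot_stats(data: ExpressionDataset) -> pd.DataFrame:
    """Per-sample five-number summary (min, Q1, median, Q3, max)."""
    q = np.percentile(data.values.to_numpy(), [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(q.T, index=data.sample_ids,
                        columns=["min", "q1", "median", "q3", "max"])
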