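"""Differential-feature discovery: moderated t-statistics and ranked lists.

The model is the standard two-group empirical-Bayes hierarchy for gene-wise
variances: the residual variance s2_g of each probe is shrunk toward a
global prior s0^2 estimated across probes, with the amount of shrinkage set
by the prior degrees of freedom d0,

    s2_post = (d0*s0^2 + df*s2_g) / (d0 + df),
    t_mod   = diff_g / sqrt(s2_post * (1/n_case + 1/n_control)),

with t_mod referred to a t distribution on d0 + df degrees of freedom
(a normal when d0 is infinite).  The hyper-parameters (d0, s0^2) are
estimated by moment matching on log s2 using digamma/trigamma identities of
the log-F marginal distribution, inverting the trigamma by bisection.

Two ranked discovery lists are produced: Method 1 keeps probes with a
Benjamini-Hochberg adjusted p-value below alpha, ranked by p; Method 2
repeats Method 1 in a leave-one-out manner and ranks probes by how many
folds declared them significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import CASE, CONTROL, ExpressionDataset


@dataclass(frozen=True)
class EBPrior:
    """Variance-prior hyper-parameters: d0 may be math.inf."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if not self.s0sq > 0:
            raise ValueError("prior variance scale must be positive")


def fit_two_group(data: ExpressionDataset) -> pd.DataFrame:
    """Per-probe group means, difference, pooled residual variance and df.

    Equivalent to fitting a gene-wise linear model with a two-level group
    factor: diff = mean(case) - mean(control), s2 the pooled residual
    variance on df = n_case + n_control - 2 degrees of freedom.
    """
    counts = data.class_counts()
    n1, n0 = counts[CASE], counts[CONTROL]
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each class needs >= 2 samples (got case={n1}, control={n0})")
    x = data.values.to_numpy()
    is_case = (data.labels == CASE).to_numpy()
    xc, xn = x[:, is_case], x[:, ~is_case]
    mean_case = xc.mean(axis=1)
    mean_control = xn.mean(axis=1)
    ss = ((xc - mean_case[:, None]) ** 2).sum(axis=1) + \
         ((xn - mean_control[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "diff": mean_case - mean_control,
            "s2": ss / df,
            "df": float(df),
        },
        index=data.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection (trigamma is decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    trig = lambda x: float(special.polygamma(1, x))
    if y >= trig(lo):
        return lo
    if y <= trig(hi):
        return hi
    for _ in range(200):
        mid = math.sqrt(lo * hi)  # bisect in log space
        if trig(mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return math.sqrt(lo * hi)


def estimate_prior(s2: np.ndarray, df: float) -> EBPrior:
    """Moment-match (d0, s0^2) from observed gene variances.

    Under the hierarchy, s2_g ~ s0^2 * F(df, d0), so with z = log s2:
        Var(z)  = trigamma(df/2) + trigamma(d0/2)
        E(z)    = log s0^2 + digamma(df/2) - digamma(d0/2)
                  - log(df/2) + log(d0/2)
    Excess spread of z beyond trigamma(df/2) identifies d0; none (or
    negative) excess means no evidence of variance heterogeneity and d0 is
    reported infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero; cannot estimate a variance prior")
    if positive.size < 10:
        raise ValueError("need >= 10 probes with positive variance")
    z = np.log(positive)
    e, v = float(z.mean()), float(z.var(ddof=1))
    half_df = df / 2.0
    excess = v - float(special.polygamma(1, half_df))
    if excess <= 0:
        d0 = math.inf
        s0sq = math.exp(e - float(special.digamma(half_df)) + math.log(half_df))
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0sq = math.exp(
            e
            - float(special.digamma(half_df))
            + float(special.digamma(half_d0))
            + math.log(half_df)
            - math.log(half_d0)
        )
    return EBPrior(d0=d0, s0sq=s0sq)


def moderated_t(stats_table: pd.DataFrame, prior: EBPrior,
                n_case: int, n_control: int) -> pd.DataFrame:
    """Add t_mod, p to a fit_two_group table under a given variance prior."""
    out = stats_table.copy()
    df = out["df"].to_numpy()
    s2 = out["s2"].to_numpy()
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
        total_df = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)
        total_df = prior.d0 + df
    se = np.sqrt(s2_post * (1.0 / n_case + 1.0 / n_control))
    diff = out["diff"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["p"] = p
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ModeratedTTest:
    """Two-group moderated-t model for one expression dataset.

    Statsmodels-style usage::

        results = ModeratedTTest(data).fit()
        results.table          # per-probe statistics
        results.prior          # estimated (d0, s0^2)
        results.summary()

    A prior may be supplied to bypass estimation (e.g. d0=0 reduces t_mod to
    the ordinary pooled two-sample t).
    """

    def __init__(self, data: ExpressionDataset):
        self.data = data
        counts = data.class_counts()
        self.n_case = counts[CASE]
        self.n_control = counts[CONTROL]

    def fit(self, prior: EBPrior | None = None) -> "DifferentialExpressionResults":
        base = fit_two_group(self.data)
        if prior is None:
            prior = estimate_prior(base["s2"].to_numpy(), float(base["df"].iloc[0]))
        table = moderated_t(base, prior, self.n_case, self.n_control)
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        return DifferentialExpressionResults(table=table, prior=prior, model=self)


@dataclass
class DifferentialExpressionResults:
    table: pd.DataFrame
    prior: EBPrior
    model: ModeratedTTest

    def ranked(self) -> pd.DataFrame:
        """All probes ordered by (p ascending, probe id) — rank 1 = strongest."""
        out = self.table.copy()
        out["_id"] = out.index.astype(str)
        out = out.sort_values(["p", "_id"], kind="stable").drop(columns="_id")
        return out

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        ranked = self.ranked()
        return ranked[ranked["p_adj"] < alpha]

    def top_table(self, n: int = 10) -> pd.DataFrame:
        return self.ranked().head(n)[["diff", "t_mod", "p", "p_adj"]]

    def summary(self, n: int = 10) -> str:
        counts = f"{self.model.n_case} case vs {self.model.n_control} control"
        d0 = "inf" if math.isinf(self.prior.d0) else f"{self.prior.d0:.3g}"
        lines = [
            "Moderated two-group t-test",
            f"  samples:        {counts}",
            f"  probes:         {len(self.table)}",
            f"  prior d0:       {d0}",
            f"  prior s0^2:     {self.prior.s0sq:.4g}",
            f"  significant at BH 0.05: {int((self.table['p_adj'] < 0.05).sum())}",
            "",
            self.top_table(n).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _as_ranked_frame(table: pd.DataFrame, extra_cols: list[str]) -> pd.DataFrame:
    out = table.reset_index().rename(columns={"index": "probe_id"})
    cols = ["probe_id"] + [c for c in extra_cols if c in out.columns]
    return out[cols]


def discovery_method1(data: ExpressionDataset, alpha: float = 0.05,
                      cap: int = 636) -> pd.DataFrame:
    """P-value-based selection: BH-significant probes ranked by p.

    Returns a ranked table (probe_id, diff, t_mod, p, p_adj); at most
    ``cap`` probes are kept, possibly fewer.
    """
    results = ModeratedTTest(data).fit()
    sig = results.significant(alpha)
    return _as_ranked_frame(sig.head(cap), ["diff", "t_mod", "p", "p_adj"])


def discovery_method2(data: ExpressionDataset, alpha: float = 0.05,
                      top_n: int = 636) -> pd.DataFrame:
    """Leave-one-out t-test selection by appearance count.

    Each sample is left out in turn; Method-1-style significance is computed
    on the remaining samples; a probe's score is the number of folds in
    which it was BH-significant at ``alpha``.  Probes that never appear are
    dropped; the rest are ranked by descending count (ties by probe id) and
    the top ``top_n`` returned.
    """
    if data.n_samples < 3:
        raise ValueError("need >= 3 samples for leave-one-out discovery")
    counts = data.class_counts()
    if min(counts.values()) < 3:
        raise ValueError("each class needs >= 3 samples so every fold keeps >= 2")
    appearance = pd.Series(0, index=data.values.index, dtype=int)
    p_sum = pd.Series(0.0, index=data.values.index)
    for sample in data.sample_ids:
        rest = [s for s in data.sample_ids if s != sample]
        fold = data.subset_samples(rest)
        res = ModeratedTTest(fold).fit()
        sig = res.table.index[res.table["p_adj"] < alpha]
        appearance.loc[sig] += 1
        p_sum += res.table["p"]
    table = pd.DataFrame({
        "appearance_count": appearance,
        "mean_p": p_sum / data.n_samples,
    })
    table = table[table["appearance_count"] > 0]
    table["_id"] = table.index.astype(str)
    table = table.sort_values(["appearance_count", "_id"],
                              ascending=[False, True], kind="stable")
    table = table.drop(columns="_id").head(top_n)
    return _as_ranked_frame(table, ["appearance_count", "mean_p"])
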