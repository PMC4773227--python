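"""Expression-data containers and the synthetic-cohort generator.

The generator emulates small two-class blood-transcriptome cohorts
(case/control, tens of samples, hundreds to tens of thousands of probes)
on the log2 scale: per-probe baseline levels, gene-wise residual variances
drawn from a scaled inverse-chi-square hierarchy (the prior assumed by the
moderated t-statistic), a minority of truly differential probes with a mean
shift in cases, optional per-batch location/scale distortions, and partial
probe loss when a panel is carried to another array platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

#: Log2 baseline expression distribution (microarray-typical).
_BASELINE_MEAN = 8.0
_BASELINE_SD = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic two-class cohort.

    Defaults mirror the scale of the discovery cohort the pipeline is built
    for: 15 cases vs 15 controls, ~1,000 probes of which a small minority are
    truly differential with a 2-unit log2 shift, and gene variances from a
    scaled inverse-chi-square prior with 4 degrees of freedom and scale 0.25
    (residual SD around 0.5 on the log2 scale, typical for blood arrays).
    """

    n_probes: int = 1000
    n_case: int = 15
    n_control: int = 15
    n_de: int = 50
    effect_size: float = 2.0
    d0_true: float = 4.0
    s0sq_true: float = 0.25
    batch_design: tuple[tuple[str, float, float], ...] = ()
    mapping_keep_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 0 or self.n_case < 0 or self.n_control < 0 or self.n_de < 0:
            raise ValueError("counts must be non-negative")
        if self.n_de > self.n_probes:
            raise ValueError(f"n_de={self.n_de} exceeds n_probes={self.n_probes}")
        if not (self.d0_true > 0 and self.s0sq_true > 0):
            raise ValueError("variance hyper-parameters must be positive")
        if not 0.0 <= self.mapping_keep_fraction <= 1.0:
            raise ValueError("mapping_keep_fraction must lie in [0, 1]")


@dataclass
class ExpressionDataset:
    """A probes x samples log2 expression matrix with sample metadata.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns.
    ``labels`` is a Series over the same sample ids with values ``case`` /
    ``control``.  ``batch`` (optional) assigns each sample a batch id.
    ``truth`` (optional) records the planted differential probes of a
    synthetic cohort; ``clean_values`` retains the batch-free matrix after
    batches are planted, so adjustment can be scored against ground truth.
    """

    values: pd.DataFrame
    labels: pd.Series
    batch: pd.Series | None = None
    truth: frozenset[str] | None = None
    clean_values: pd.DataFrame | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if list(self.labels.index) != list(self.values.columns):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("every sample needs a class label")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)
            if self.batch.isna().any():
                raise ValueError("every sample needs a batch id when batches are set")
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {CASE: int(c.get(CASE, 0)), CONTROL: int(c.get(CONTROL, 0))}

    def subset_samples(self, sample_ids: list[str], name: str | None = None) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values[sample_ids].copy(),
            labels=self.labels.loc[sample_ids].copy(),
            batch=None if self.batch is None else self.batch.loc[sample_ids].copy(),
            truth=self.truth,
            name=name or self.name,
        )

    def subset_probes(self, probe_ids: list[str], name: str | None = None) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.loc[probe_ids].copy(),
            labels=self.labels.copy(),
            batch=None if self.batch is None else self.batch.copy(),
            truth=self.truth,
            name=name or self.name,
        )


def _probe_id(i: int, width: int) -> str:
    return f"PS{i:0{width}d}"


def draw_gene_params(config: SyntheticConfig, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe baselines mu_g ~ N(8, 2) and variances from the scaled
    inverse-chi-square prior sigma_g^2 ~ d0*s0sq / chi2(d0)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_probes)
    sigma2 = config.d0_true * config.s0sq_true / rng.chisquare(config.d0_true, size=config.n_probes)
    return mu, sigma2


def generate_dataset(
    config: SyntheticConfig,
    name: str = "synthetic",
    gene_params: tuple[np.ndarray, np.ndarray] | None = None,
    sample_prefix: str = "S",
) -> ExpressionDataset:
    """Draw one cohort from the generative model.

    Per probe g: baseline mu_g ~ N(8, 2); variance sigma_g^2 ~ scaled
    inverse-chi-square(d0_true, s0sq_true), i.e. d0*s0sq / chi2(d0).
    Sample j: x_gj = mu_g + delta_g * 1[j is case] + e_gj, e_gj ~ N(0, sigma_g).
    The first ``n_de`` probes carry delta_g = effect_size; all others 0.

    ``gene_params`` lets several cohorts share the same gene-level truth
    (baselines and variances) while drawing independent sampling noise.
    """
    rng = np.random.default_rng(config.seed)
    p, n1, n0 = config.n_probes, config.n_case, config.n_control
    n = n1 + n0
    width = max(4, len(str(max(p, 1))))
    probes = [_probe_id(i, width) for i in range(p)]
    samples = [f"{sample_prefix}{j:03d}" for j in range(n)]
    labels = pd.Series([CASE] * n1 + [CONTROL] * n0, index=samples, name="label")

    mu, sigma2 = draw_gene_params(config) if gene_params is None else gene_params
    # burn the gene-parameter draws so shared-truth cohorts stay independent
    rng = np.random.default_rng(rng.integers(2**31))
    x = mu[:, None] + rng.standard_normal((p, n)) * np.sqrt(sigma2)[:, None]
    x[: config.n_de, :n1] += config.effect_size

    values = pd.DataFrame(x, index=probes, columns=samples)
    truth = frozenset(probes[: config.n_de])
    data = ExpressionDataset(values=values, labels=labels, truth=truth, name=name)
    if config.batch_design:
        n_batches = len(config.batch_design)
        assignment = pd.Series(
            [config.batch_design[j % n_batches][0] for j in range(n)],
            index=samples, name="batch",
        )
        data = plant_batches(data, config.batch_design, seed=config.seed + 1,
                             assignment=assignment)
    return data


def plant_batches(
    data: ExpressionDataset,
    design: tuple[tuple[str, float, float], ...],
    seed: int,
    assignment: pd.Series | None = None,
) -> ExpressionDataset:
    """Superimpose per-batch, per-gene location/scale distortions.

    For batch b with design entry (id, add_sd, mult_disp) and gene g:
    additive offset gamma_gb ~ N(0, add_sd) and multiplicative factor
    delta_gb = exp(N(0, mult_disp)) (positive by construction) act on the
    gene-centred residuals:  x' = mean_g + (x - mean_g) * delta_gb + gamma_gb.
    The pre-batch matrix is kept in ``clean_values`` for recovery scoring.
    """
    if assignment is None:
        if data.batch is None:
            raise ValueError("no batch assignment available")
        assignment = data.batch
    assignment = assignment.reindex(data.values.columns)
    known = {b for b, _, _ in design}
    unknown = set(assignment.unique()) - known
    if unknown:
        raise ValueError(f"unknown batch id(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    x = data.values.to_numpy(copy=True)
    clean = data.values.copy()
    gene_mean = x.mean(axis=1, keepdims=True)
    for batch_id, add_sd, mult_disp in design:
        cols = np.flatnonzero((assignment == batch_id).to_numpy())
        gamma = rng.normal(0.0, add_sd, size=x.shape[0]) if add_sd > 0 else np.zeros(x.shape[0])
        if mult_disp > 0:
            delta = np.exp(rng.normal(0.0, mult_disp, size=x.shape[0]))
        else:
            delta = np.ones(x.shape[0])
        if cols.size:
            x[:, cols] = gene_mean + (x[:, cols] - gene_mean) * delta[:, None] + gamma[:, None]
    return ExpressionDataset(
        values=pd.DataFrame(x, index=data.values.index, columns=data.values.columns),
        labels=data.labels.copy(),
        batch=assignment.copy(),
        truth=data.truth,
        clean_values=clean,
        name=data.name,
    )


def apply_platform_mask(
    data: ExpressionDataset, keep_fraction: float, seed: int
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate cross-platform probe mapping loss.

    Each probe is independently retained with probability ``keep_fraction``;
    retained probes map to a renamed target id, dropped probes are reported
    as unmapped.  Returns the masked dataset and the mapping table
    (columns: source_id, target_id with NA for unmapped probes).
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(data.n_probes) < keep_fraction
    source = np.asarray(data.probe_ids, dtype=object)
    target = np.where(keep, np.char.add("T_", source.astype(str)), None)
    mapping = pd.DataFrame({"source_id": source, "target_id": target})
    kept = [p for p, k in zip(data.probe_ids, keep) if k]
    masked = data.subset_probes(kept)
    masked.values.index = ["T_" + p for p in kept]
    if masked.truth is not None:
        masked.truth = frozenset("T_" + p for p in masked.truth if p in set(kept))
    return masked, mapping


def train_test_validation_triplet(
    config: SyntheticConfig,
    n_test_case: int = 11,
    n_test_control: int = 6,
    n_valid_case: int | None = None,
    n_valid_control: int | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Three independent cohorts sharing the planted effects and probe panel.

    The probe panel, baselines, variances and planted effects are shared;
    the sampling noise is independent (seeded off ``config.seed``).
    Mirrors the discovery / selection / validation cohort roles.
    """
    params = draw_gene_params(config)
    train = generate_dataset(config, name="train", gene_params=params, sample_prefix="TR")
    test_cfg = replace(config, n_case=n_test_case, n_control=n_test_control,
                       seed=config.seed + 101)
    valid_cfg = replace(
        config,
        n_case=n_valid_case or config.n_case,
        n_control=n_valid_control or config.n_control,
        seed=config.seed + 202,
    )
    test = generate_dataset(test_cfg, name="test", gene_params=params, sample_prefix="TE")
    valid = generate_dataset(valid_cfg, name="validation", gene_params=params, sample_prefix="VA")
    return train, test, valid
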