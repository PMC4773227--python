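"""Readers/writers for on-disk artefacts and cross-platform feature mapping.

All tabular formats are TSV with mandatory headers, probes as rows and
samples as columns (microarray convention).  Readers validate and raise
named errors instead of silently coercing; writers are deterministic so a
written file round-trips bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset


class FormatError(ValueError):
    """Base class for malformed on-disk artefacts."""


class DuplicateProbeError(FormatError):
    """An expression or feature table repeats a probe id."""


class LabelMismatchError(FormatError):
    """Sample ids of the expression matrix and the labels table disagree."""


class NonNumericDataError(FormatError):
    """An expression cell could not be parsed as a number."""


# ---------------------------------------------------------------------------
# expression matrices + labels

def write_expression(data: ExpressionDataset, expr_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    df = data.values.copy()
    df.index.name = "probe_id"
    df.to_csv(expr_path, sep="\t", float_format="%.10g")
    if labels_path is not None:
        write_labels(data, labels_path)


def write_labels(data: ExpressionDataset, path: str | Path) -> None:
    table = pd.DataFrame({"sample_id": data.sample_ids,
                          "label": data.labels.to_numpy()})
    if data.batch is not None:
        table["batch"] = data.batch.to_numpy()
    table.to_csv(path, sep="\t", index=False)


def read_expression(expr_path: str | Path, labels_path: str | Path,
                    name: str | None = None) -> ExpressionDataset:
    """Read an expression TSV plus its labels TSV into an ExpressionDataset."""
    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateProbeError(f"duplicated probe id(s): {dups[:5]}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise NonNumericDataError(f"non-numeric expression cell in {expr_path}: {exc}") from None
    values.index.name = None
    if np.isnan(values.to_numpy()).any():
        raise NonNumericDataError(f"missing value in expression matrix {expr_path}")

    labels_table = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sample_id", "label"}
    if not required <= set(labels_table.columns):
        raise FormatError(f"labels file needs columns {sorted(required)}")
    labels_table = labels_table.set_index("sample_id")
    missing = [s for s in values.columns if s not in labels_table.index]
    extra = [s for s in labels_table.index if s not in values.columns]
    if missing or extra:
        raise LabelMismatchError(
            f"sample ids disagree: missing labels for {missing[:5]}, "
            f"labels without samples {extra[:5]}")
    labels = labels_table["label"].reindex(values.columns)
    batch = None
    if "batch" in labels_table.columns and labels_table["batch"].notna().all():
        batch = labels_table["batch"].reindex(values.columns)
    return ExpressionDataset(values=values, labels=labels, batch=batch,
                             name=name or Path(expr_path).stem)


def write_truth(data: ExpressionDataset, path: str | Path) -> None:
    probes = sorted(data.truth) if data.truth else []
    pd.DataFrame({"probe_id": probes}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ranked feature lists

def write_feature_list(features: pd.DataFrame | list[str], path: str | Path) -> None:
    """Write a ranked feature table (rank 1 = most significant).

    Accepts either a plain ordered list of probe ids or a DataFrame with a
    ``probe_id`` column and optional per-probe statistics columns
    (p, p_adj, appearance_count, delta_sr ...).
    """
    if isinstance(features, list):
        features = pd.DataFrame({"probe_id": features})
    if features["probe_id"].duplicated().any():
        raise DuplicateProbeError("feature list repeats a probe id")
    out = features.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_list(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in table.columns:
        raise FormatError("feature list needs a probe_id column")
    if table["probe_id"].duplicated().any():
        raise DuplicateProbeError("feature list repeats a probe id")
    return table.drop(columns=[c for c in ("rank",) if c in table.columns])


# ---------------------------------------------------------------------------
# probe mapping

@dataclass(frozen=True)
class MappingReport:
    """Bookkeeping of a cross-platform panel transfer."""

    n_input: int
    n_mapped: int
    n_unmapped: int
    n_mapped_but_absent: int

    @property
    def n_usable(self) -> int:
        return self.n_mapped - self.n_mapped_but_absent


def read_mapping(path: str | Path) -> dict[str, str | None]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source_id", "target_id"} <= set(table.columns):
        raise FormatError("mapping file needs columns source_id, target_id")
    if table["source_id"].duplicated().any():
        raise FormatError("mapping source ids must be unique")
    return {
        row.source_id: (None if pd.isna(row.target_id) else row.target_id)
        for row in table.itertuples()
    }


def write_mapping(mapping: dict[str, str | None] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(mapping, dict):
        mapping = pd.DataFrame(
            {"source_id": list(mapping), "target_id": list(mapping.values())})
    mapping.to_csv(path, sep="\t", index=False, na_rep="NA")


def map_features(
    features: list[str],
    mapping: dict[str, str | None] | None,
    available: set[str] | list[str],
) -> tuple[list[str], MappingReport]:
    """Carry a ranked panel onto another platform.

    Keeps only features that both map and exist among ``available`` probe
    ids, preserving the original ranking order.  ``mapping=None`` means the
    identity map (same platform).  An empty usable panel is legal and simply
    reported.
    """
    available = set(available)
    usable: list[str] = []
    n_mapped = n_unmapped = n_absent = 0
    for probe in features:
        target = probe if mapping is None else mapping.get(probe)
        if target is None:
            n_unmapped += 1
            continue
        n_mapped += 1
        if target in available:
            usable.append(target)
        else:
            n_absent += 1
    report = MappingReport(n_input=len(features), n_mapped=n_mapped,
                           n_unmapped=n_unmapped, n_mapped_but_absent=n_absent)
    return usable, report


# ---------------------------------------------------------------------------
# results JSON

def write_results_json(path: str | Path, *, dataset: str, classifier: str,
                       n_folds: int, confusion, metrics) -> None:
    """Emit the evaluation record for one dataset/classifier pair.

    Schema: {dataset, classifier, n_folds, confusion:{tp,fp,tn,fn},
    metrics:{sr,sens,spec,ppv,npv}, ci:{sr:[lo,hi],...}}.
    """
    payload = {
        "dataset": dataset,
        "classifier": classifier,
        "n_folds": n_folds,
        "confusion": {"tp": confusion.tp, "fp": confusion.fp,
                      "tn": confusion.tn, "fn": confusion.fn},
        "metrics": {"sr": metrics.sr, "sens": metrics.sensitivity,
                    "spec": metrics.specificity, "ppv": metrics.ppv,
                    "npv": metrics.npv},
        "ci": {k: list(v) if v is not None else None
               for k, v in metrics.ci.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
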