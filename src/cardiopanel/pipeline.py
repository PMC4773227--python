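"""End-to-end panel discovery: discovery -> optimisation -> selection -> validation.

The flow mirrors a multi-cohort classifier study: two ranked feature lists
are discovered on a training cohort; three optimisers reduce each list,
giving six candidate panels; the candidate with the best success rate on a
held-out selection cohort becomes the final classifier; the final panel is
then validated on independent cohorts, blind (cross-cohort, batch-adjusted)
or by balanced repeated LOOCV, after cross-platform feature mapping.

Every run emits a manifest (inputs, hashes, parameters, seeds) so the
multi-cohort bookkeeping is reproducible and the role separation
(discovery / selection / validation cohorts never mix) is checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import CASE, CONTROL, ExpressionDataset
from .discovery import discovery_method1, discovery_method2
from .io import MappingReport, map_features, write_feature_list
from .knn import (FoldOutcomes, MetricsReport, balanced_loocv, blind_validate,
                  evaluate, loocv, roc_point)
from .optimise import (optimise_fittest_crossover, optimise_greedy,
                       optimise_random_crossover)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Knobs of the whole flow, with the defaults used throughout."""

    alpha: float = 0.05
    cap: int = 636
    k: int = 3
    subset_size: int = 53
    n_generations: int = 3
    m: int = 25
    q: int = 5
    n_repeats: int = 15
    n_selection_splits: int = 15
    seed: int = 0


@dataclass
class Candidate:
    candidate_id: str
    discovery_method: str
    optimiser: str
    features: list[str]
    selection_sr: float = float("nan")


@dataclass
class ValidationRecord:
    dataset: str
    mode: str  # "blind" | "loocv"
    mapping_report: MappingReport | None
    n_features_used: int
    report: MetricsReport | None
    roc: tuple[float, float] | None
    skipped: bool = False


def _hash_dataset(data: ExpressionDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.values.to_numpy()).tobytes())
    h.update(",".join(data.sample_ids).encode())
    h.update(",".join(data.labels).encode())
    return h.hexdigest()[:16]


def run_discovery_phase(train: ExpressionDataset, params: PipelineParams
                        ) -> dict[str, pd.DataFrame]:
    """Both ranked discovery lists from the training cohort."""
    t0 = time.perf_counter()
    d1 = discovery_method1(train, alpha=params.alpha, cap=params.cap)
    d2 = discovery_method2(train, alpha=params.alpha, top_n=params.cap)
    logger.info("discovery: %d (method 1) / %d (method 2) probes in %.1fs",
                len(d1), len(d2), time.perf_counter() - t0)
    if len(d1) == 0 or len(d2) == 0:
        logger.warning("a discovery list is empty; downstream stages may skip")
    return {"d1": d1, "d2": d2}


def run_optimisation_phase(train: ExpressionDataset, selection: ExpressionDataset,
                           lists: dict[str, pd.DataFrame], params: PipelineParams
                           ) -> list[Candidate]:
    """Six candidate panels (3 optimisers x 2 discovery lists), each scored
    on the selection cohort with the same KNN settings."""
    candidates: list[Candidate] = []
    for disc_name, ranked in lists.items():
        features = ranked["probe_id"].tolist()
        if len(features) < 2:
            logger.warning("discovery list %s has < 2 features; skipped", disc_name)
            continue
        subset_size = min(params.subset_size, len(features))
        runs = {
            "opt1": lambda: optimise_greedy(features, train, k=params.k),
            "opt2": lambda: optimise_random_crossover(
                features, train, subset_size=subset_size,
                n_generations=params.n_generations, m=params.m, k=params.k,
                seed=params.seed),
            "opt3": lambda: optimise_fittest_crossover(
                features, train, subset_size=subset_size,
                n_generations=params.n_generations, m=params.m,
                q=min(params.q, max(1, subset_size - 1)), k=params.k,
                seed=params.seed),
        }
        for opt_name, run in runs.items():
            t0 = time.perf_counter()
            result = run()
            folds = blind_validate(train, selection, result.features, k=params.k)
            cid = f"{opt_name.capitalize()}{disc_name.upper()}"
            candidates.append(Candidate(
                candidate_id=cid, discovery_method=disc_name,
                optimiser=opt_name, features=result.features,
                selection_sr=folds.sr))
            logger.info("%s: %d features, selection SR %.0f%% (%.1fs)",
                        cid, len(result.features), folds.sr,
                        time.perf_counter() - t0)
    candidates.sort(key=lambda c: (-c.selection_sr, len(c.features), c.candidate_id))
    return candidates


def candidate_table(candidates: list[Candidate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"candidate_id": c.candidate_id, "discovery": c.discovery_method,
         "optimiser": c.optimiser, "n_features": len(c.features),
         "selection_sr": c.selection_sr}
        for c in candidates])


def _stratified_splits(cohort: ExpressionDataset, n_splits: int, seed: int
                       ) -> list[tuple[list[str], list[str]]]:
    cases = [s for s in cohort.sample_ids if cohort.labels[s] == CASE]
    controls = [s for s in cohort.sample_ids if cohort.labels[s] == CONTROL]
    splits = []
    for rep in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        tr = (sorted(rng.choice(cases, size=len(cases) // 2, replace=False).tolist())
              + sorted(rng.choice(controls, size=len(controls) // 2, replace=False).tolist()))
        te = [s for s in cohort.sample_ids if s not in set(tr)]
        splits.append((tr, te))
    return splits


def select_final(candidates: list[Candidate],
                 train: ExpressionDataset | None = None,
                 test: ExpressionDataset | None = None,
                 cohort: ExpressionDataset | None = None,
                 n_splits: int = 15, seed: int = 0, k: int = 3) -> Candidate:
    """Pick the final classifier among the candidates.

    With a fixed (train, test) pair the candidate with the highest test SR
    wins.  With a single cohort, ``n_splits`` random stratified half-splits
    are evaluated and the mean SR decides.  Ties go to the shorter panel,
    then the candidate id.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    scored: list[tuple[float, int, str, Candidate]] = []
    for cand in candidates:
        if cohort is not None:
            srs = []
            for tr_ids, te_ids in _stratified_splits(cohort, n_splits, seed):
                tr = cohort.subset_samples(tr_ids)
                te = cohort.subset_samples(te_ids)
                srs.append(blind_validate(tr, te, cand.features, k=k).sr)
            sr = float(np.mean(srs))
        elif train is not None and test is not None:
            sr = blind_validate(train, test, cand.features, k=k).sr
        else:
            sr = cand.selection_sr
        scored.append((sr, len(cand.features), cand.candidate_id, cand))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    best = scored[0][3]
    best.selection_sr = scored[0][0]
    return best


def run_validation_phase(final: Candidate, train: ExpressionDataset,
                         validations: list[dict], params: PipelineParams
                         ) -> list[ValidationRecord]:
    """Validate the final panel on each declared cohort.

    Each entry of ``validations`` is {"data": ExpressionDataset,
    "mode": "blind"|"loocv", "mapping": dict or None}.  Blind runs are
    batch-adjusted (batch = dataset of origin); LOOCV runs use balanced
    repeated subsampling.  A cohort with no usable feature after mapping is
    skipped with a warning rather than failing the run.
    """
    records: list[ValidationRecord] = []
    for entry in validations:
        data: ExpressionDataset = entry["data"]
        mode = entry["mode"]
        mapping = entry.get("mapping")
        usable, map_report = map_features(final.features, mapping,
                                          set(data.values.index))
        if not usable:
            logger.warning("validation cohort %s: no usable features; skipped",
                           data.name)
            records.append(ValidationRecord(
                dataset=data.name, mode=mode, mapping_report=map_report,
                n_features_used=0, report=None, roc=None, skipped=True))
            continue
        if len(usable) < len(final.features):
            logger.warning("validation cohort %s: reduced panel %d/%d features",
                           data.name, len(usable), len(final.features))
        if mode == "blind":
            if mapping is None:
                folds = blind_validate(train, data, usable, k=params.k,
                                       adjust_batches=True)
            else:
                folds = _blind_mapped(train, data, final.features, mapping,
                                      usable, params.k)
            report = evaluate(folds)
        elif mode == "loocv":
            report = balanced_loocv(data, usable, k=params.k,
                                    n_repeats=params.n_repeats, seed=params.seed)
        else:
            raise ValueError(f"unknown validation mode: {mode}")
        try:
            roc = roc_point(report)
        except ValueError:
            roc = None
        records.append(ValidationRecord(
            dataset=data.name, mode=mode, mapping_report=map_report,
            n_features_used=len(usable), report=report, roc=roc))
    return records


def _blind_mapped(train, data, features, mapping, usable, k) -> FoldOutcomes:
    """Blind validation across platforms: rename the training probes to the
    target platform's ids over the usable panel, then adjust and classify."""
    source_for = {mapping[f]: f for f in features if mapping.get(f) in set(usable)}
    sub = train.subset_probes([source_for[t] for t in usable])
    sub.values.index = usable
    return blind_validate(sub, data, usable, k=k, adjust_batches=True)


@dataclass
class PipelineResult:
    manifest: dict
    lists: dict[str, pd.DataFrame]
    candidates: list[Candidate]
    final: Candidate
    validations: list[ValidationRecord] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Panel-discovery pipeline",
            f"  discovery lists: {len(self.lists['d1'])} (method 1), "
            f"{len(self.lists['d2'])} (method 2)",
            "",
            candidate_table(self.candidates).to_string(index=False),
            "",
            f"  final classifier: {self.final.candidate_id} "
            f"({len(self.final.features)} features, "
            f"selection SR {self.final.selection_sr:.0f}%)",
        ]
        for rec in self.validations:
            if rec.skipped:
                lines.append(f"  validation {rec.dataset} [{rec.mode}]: skipped "
                             "(no usable features)")
            else:
                lines.append(
                    f"  validation {rec.dataset} [{rec.mode}], "
                    f"{rec.n_features_used} features: SR {rec.report.sr:.0f}%")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2,
                                                      sort_keys=True) + "\n")
        for name, table in self.lists.items():
            write_feature_list(table, out / f"discovery_{name}.tsv")
        candidate_table(self.candidates).to_csv(out / "candidates.tsv",
                                                sep="\t", index=False)
        write_feature_list(self.final.features, out / "final_classifier.tsv")
        results = []
        for rec in self.validations:
            entry = {"dataset": rec.dataset, "mode": rec.mode,
                     "n_features_used": rec.n_features_used,
                     "skipped": rec.skipped}
            if rec.report is not None:
                entry["metrics"] = rec.report.rounded()
                entry["ci"] = {m: list(b) for m, b in rec.report.ci.items() if b}
                entry["roc"] = list(rec.roc) if rec.roc else None
            results.append(entry)
        (out / "validation.json").write_text(json.dumps(results, indent=2) + "\n")


def run_pipeline(train: ExpressionDataset, selection: ExpressionDataset,
                 validations: list[dict] | None = None,
                 params: PipelineParams | None = None) -> PipelineResult:
    """The full flow on in-memory cohorts; see the module docstring."""
    params = params or PipelineParams()
    validations = validations or []
    manifest = {
        "version": __version__,
        "params": asdict(params),
        "roles": {
            "discovery-train": train.name,
            "selection-test": selection.name,
            "validation": [v["data"].name for v in validations],
        },
        "hashes": {
            train.name: _hash_dataset(train),
            selection.name: _hash_dataset(selection),
            **{v["data"].name: _hash_dataset(v["data"]) for v in validations},
        },
    }
    role_names = [train.name, selection.name] + [v["data"].name for v in validations]
    if len(set(role_names)) != len(role_names):
        raise ValueError("cohort roles must be disjoint (duplicate cohort names)")
    lists = run_discovery_phase(train, params)
    candidates = run_optimisation_phase(train, selection, lists, params)
    final = select_final(candidates, train=train, test=selection, k=params.k,
                         n_splits=params.n_selection_splits, seed=params.seed)
    records = run_validation_phase(final, train, validations, params)
    return PipelineResult(manifest=manifest, lists=lists, candidates=candidates,
                          final=final, validations=records)
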