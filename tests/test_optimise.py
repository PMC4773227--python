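"""Panel-optimiser behaviour: traces, crossover algebra, planted-signal recovery."""

import numpy as np
import pandas as pd
import pytest

from cardiopanel import (CASE, CONTROL, ExpressionDataset, SyntheticConfig,
                         generate_dataset, loocv, optimise_fittest_crossover,
                         optimise_greedy, optimise_random_crossover,
                         prune_subset, select_top, two_point_crossover)
from cardiopanel.optimise import _PanelScorer
from conftest import make_dataset


@pytest.fixture(scope="module")
def signal_cohort():
    return generate_dataset(SyntheticConfig(n_probes=200, n_de=10, seed=3))


def test_greedy_trace_is_monotone_and_rejections_recorded(signal_cohort):
    result = optimise_greedy(list(signal_cohort.probe_ids), signal_cohort)
    srs = result.trace.accepted_sr_sequence()
    assert all(a <= b for a, b in zip(srs, srs[1:]))
    for step in result.trace.steps:
        assert step.delta_sr == step.sr_after - step.sr_before
        assert step.accepted == (step.delta_sr >= 0)
    # every returned feature came from the input list, no duplicates
    assert len(set(result.features)) == len(result.features)
    assert set(result.features) <= set(signal_cohort.probe_ids)


def test_greedy_keeps_perfect_separator_and_rejects_breakers(separable_dataset):
    # one perfectly separating feature followed by adversarial noise
    rng = np.random.default_rng(2)
    sep = separable_dataset.values.iloc[0]
    noise = rng.normal(2.0, 4.0, size=(20, len(sep)))
    values = pd.DataFrame(
        np.vstack([sep.to_numpy(), noise]),
        index=["GOOD"] + [f"N{i}" for i in range(20)],
        columns=separable_dataset.sample_ids)
    data = ExpressionDataset(values=values, labels=separable_dataset.labels.copy())
    result = optimise_greedy(list(values.index), data)
    assert result.sr == 100.0
    assert "GOOD" in result.features
    assert any(not s.accepted for s in result.trace.steps) or len(result.features) == 21


def test_greedy_identical_copies_all_retained(separable_dataset):
    row = separable_dataset.values.iloc[[0]]
    values = pd.concat([row] * 6)
    values.index = [f"C{i}" for i in range(6)]
    data = ExpressionDataset(values=values, labels=separable_dataset.labels.copy())
    result = optimise_greedy(list(values.index), data)
    assert result.features == list(values.index)
    assert all(s.delta_sr == 0.0 for s in result.trace.steps)


def test_greedy_two_feature_boundary(separable_dataset):
    result = optimise_greedy(separable_dataset.probe_ids[:2], separable_dataset)
    assert result.features == separable_dataset.probe_ids[:2]
    assert result.trace.steps == []
    with pytest.raises(ValueError):
        optimise_greedy(separable_dataset.probe_ids[:1], separable_dataset)


def test_prune_marks_adversarial_feature(separable_dataset):
    # distance-dominating label-free noise destroys a separating panel
    rng = np.random.default_rng(13)
    good = separable_dataset.values.iloc[0]
    bad = rng.normal(0.0, 50.0, size=len(good))
    values = pd.DataFrame(
        [good.to_numpy(), good.to_numpy() + 0.01, bad],
        index=["G1", "G2", "BAD"], columns=separable_dataset.sample_ids)
    data = ExpressionDataset(values=values, labels=separable_dataset.labels.copy())
    annotated = prune_subset(["G1", "G2", "BAD"], data)
    by_name = dict(zip(annotated.members, annotated.eliminated))
    assert by_name["BAD"] and not by_name["G1"]
    assert annotated.delta_sr[2] < 0
    assert annotated.working_sr == 100.0  # the marked member is excluded


def test_prune_singleton_uses_chance_baseline(separable_dataset):
    annotated = prune_subset([separable_dataset.probe_ids[0]], separable_dataset)
    scorer = _PanelScorer(separable_dataset)
    assert annotated.delta_sr[0] == pytest.approx(
        annotated.working_sr - scorer.baseline_sr)


def test_select_top_flags_short_population(signal_cohort):
    annotated = [prune_subset(signal_cohort.probe_ids[:5], signal_cohort)]
    result = select_top(annotated, signal_cohort, m=25)
    assert result.truncated and len(result.features) == 5


def test_two_point_crossover_hand_traced_and_conserving():
    a = ["1", "2", "3", "4", "5", "6"]
    b = ["7", "8", "9", "10", "11", "12"]
    a2, b2 = two_point_crossover(a, b, seed=0, cuts=(2, 4))
    assert a2 == ["1", "2", "9", "10", "5", "6"]
    assert b2 == ["7", "8", "3", "4", "11", "12"]
    rng = np.random.default_rng(1)
    for _ in range(20):
        a2, b2 = two_point_crossover(a, b, rng)
        assert sorted(a2 + b2) == sorted(a + b)
        assert len(a2) == len(b2) == 6
    with pytest.raises(ValueError):
        two_point_crossover(a, b[:3], seed=0)


@pytest.mark.parametrize("optimiser,kwargs", [
    (optimise_random_crossover, {}),
    (optimise_fittest_crossover, {"q": 5}),
])
def test_evolutionary_recovery_of_planted_signal(optimiser, kwargs):
    for seed in range(1, 6):
        data = generate_dataset(SyntheticConfig(n_probes=200, n_de=10, seed=seed))
        ranked = list(data.probe_ids)
        result = optimiser(ranked, data, subset_size=53, n_generations=3,
                           m=25, seed=seed, **kwargs)
        assert len(set(result.features) & data.truth) >= 8
        assert result.sr >= loocv(data, ranked).sr  # beats the unoptimised list
        assert len(result.features) == 25


def test_evolutionary_determinism(signal_cohort):
    ranked = list(signal_cohort.probe_ids)
    runs = [optimise_random_crossover(ranked, signal_cohort, subset_size=40,
                                      n_generations=2, seed=7) for _ in range(2)]
    assert runs[0].features == runs[1].features
    assert runs[0].sr == runs[1].sr
    assert [g.subset_srs for g in runs[0].trace.generations] == \
           [g.subset_srs for g in runs[1].trace.generations]


def test_zero_generations_equals_prune_plus_select(signal_cohort):
    ranked = list(signal_cohort.probe_ids)
    evolved = optimise_random_crossover(ranked, signal_cohort, subset_size=53,
                                        n_generations=0, m=25, seed=1)
    scorer_result = select_top(
        [prune_subset(ranked[i:i + 53], signal_cohort) for i in range(0, 200, 53)],
        signal_cohort, m=25,
        original_rank={p: i for i, p in enumerate(ranked)})
    assert evolved.features == scorer_result.features


def test_fittest_crossover_single_subset_is_noop(signal_cohort):
    ranked = list(signal_cohort.probe_ids)[:40]
    single = optimise_fittest_crossover(ranked, signal_cohort, subset_size=40,
                                        n_generations=2, m=25, q=5, seed=1)
    none = optimise_fittest_crossover(ranked, signal_cohort, subset_size=40,
                                      n_generations=0, m=25, q=5, seed=1)
    assert single.features == none.features


def test_crossover_never_shrinks_subsets(signal_cohort):
    ranked = list(signal_cohort.probe_ids)
    result = optimise_fittest_crossover(ranked, signal_cohort, subset_size=50,
                                        n_generations=2, m=25, q=5, seed=2)
    for gen in result.trace.generations:
        assert all(len(s) == 50 for s in gen.subsets)


def test_optimiser_input_validation(signal_cohort):
    ranked = list(signal_cohort.probe_ids)
    with pytest.raises(ValueError):
        optimise_random_crossover(ranked, signal_cohort, subset_size=1)
    with pytest.raises(ValueError):
        optimise_random_crossover(ranked[:10], signal_cohort, subset_size=53)
    with pytest.raises(ValueError):
        optimise_fittest_crossover(ranked, signal_cohort, subset_size=10, q=10)
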