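"""CPT estimation: thresholds, discretization, the per-rule arithmetic and
its agreement with literal transcriptions of the published derivations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from wntbn.estimation import (
    compute_threshold,
    discretize,
    estimate_cpt_dact3,
    estimate_cpt_sample_me,
    estimate_cpt_sample_me_trcmplx,
    estimate_cpt_sample_only,
    estimate_cpt_sample_trcmplx,
    estimate_cpt_trcmplx_only,
    estimate_gene_cpt,
    tabulate_class_states,
    train_network,
)
from wntbn.parameters import TrainingConfig
from wntbn.synthetic import ExpressionDataset, GeneratorConfig, generate_cohort
from wntbn.tables import CountTable, column_index, smooth_and_normalize

TOY_VALUES = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
TOY_LABELS = np.array([-1, -1, -1, 1, 1, 1])


@pytest.mark.parametrize(
    "values,expected",
    [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5), ([5, 5, 5, 5], 5.0)],
)
def test_threshold_is_sample_median(values, expected):
    assert compute_threshold(np.asarray(values, float)) == expected


def test_threshold_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        compute_threshold(np.array([]))
    with pytest.raises(ValueError):
        compute_threshold(np.array([1.0, np.nan]))


@pytest.mark.parametrize(
    "value,threshold,state",
    [(0.9, 1.0, 1), (1.1, 1.0, 2), (1.0, 1.0, 2)],  # tie goes to active
)
def test_discretize_strict_below_rule(value, threshold, state):
    assert discretize(value, threshold) == state


def test_tabulate_toy_counts():
    cs = tabulate_class_states(TOY_VALUES, TOY_LABELS, 3.5)
    assert (cs.a, cs.b, cs.c, cs.d) == (0, 3, 3, 0)
    assert cs.n_normal == 3 and cs.n_tumor == 3


def test_tabulate_degenerate_inputs():
    cs = tabulate_class_states(TOY_VALUES, TOY_LABELS, 100.0)  # all below
    assert cs.a == cs.b == 0
    cs = tabulate_class_states(TOY_VALUES, np.ones(6, int), 3.5)  # single class
    assert cs.a == cs.c == 0 and cs.b + cs.d == 6


def test_smoothing_examples():
    t = CountTable("g", ("P",), np.array([[0.0, 1.0], [0.0, 0.0]]))
    ct = smooth_and_normalize(t, 1.0)
    np.testing.assert_allclose(ct.probs[:, 0], [0.5, 0.5])
    np.testing.assert_allclose(ct.probs[:, 1], [2 / 3, 1 / 3])


def test_smoothing_rejects_bad_inputs():
    with pytest.raises(ValueError):
        CountTable("g", (), np.array([[-1.0], [0.0]]))
    t = CountTable("g", (), np.array([[1.0], [1.0]]))
    with pytest.raises(ValueError):
        smooth_and_normalize(t, 0.0)


class TestWorkedFixture:
    """Every rule reproduces the hand-derived fragments of the toy data."""

    def test_fixture_self_description(self, toy_fixture):
        dataset, expected = toy_fixture
        assert list(dataset.labels) == [-1, -1, -1, 1, 1, 1]
        assert compute_threshold(dataset.matrix[0]) == expected["median"]

    @pytest.mark.parametrize(
        "key,make",
        [
            ("sample_only", lambda v, y: estimate_cpt_sample_only(v, y)),
            ("sample_trcmplx_p05", lambda v, y: estimate_cpt_sample_trcmplx(v, y, 0.5)),
            (
                "sample_me_trcmplx_p05",
                lambda v, y: estimate_cpt_sample_me_trcmplx(v, y, 0.5),
            ),
            ("sample_me", lambda v, y: estimate_cpt_sample_me(v, y)),
            ("dact3", lambda v, y: estimate_cpt_dact3(v, y)),
            ("trcmplx_only", lambda v, y: estimate_cpt_trcmplx_only(v, y)),
        ],
    )
    def test_rule_fragments(self, toy_fixture, key, make):
        dataset, expected = toy_fixture
        ct = make(dataset.matrix[0], dataset.labels)
        for parent_states, (p_off, p_on) in expected[key].items():
            col = ct.column(parent_states)
            np.testing.assert_allclose(col, [p_off, p_on], atol=1e-12)


def _random_toy(rng):
    n = int(rng.integers(4, 17))
    values = rng.normal(size=n)
    labels = np.where(rng.random(n) < 0.5, -1, 1)
    labels[0], labels[1] = -1, 1  # force both classes
    return values, labels


@pytest.mark.parametrize(
    "rule,oracle,needs_p",
    [
        (estimate_cpt_sample_only, oracles.oracle_sample_only, False),
        (estimate_cpt_trcmplx_only, oracles.oracle_trcmplx_only, False),
        (estimate_cpt_sample_trcmplx, oracles.oracle_sample_trcmplx, True),
        (estimate_cpt_sample_me_trcmplx, oracles.oracle_sample_me_trcmplx, True),
        (estimate_cpt_sample_me, oracles.oracle_sample_me, False),
        (estimate_cpt_dact3, oracles.oracle_dact3, False),
    ],
)
def test_rules_match_prose_transcription_oracles(rule, oracle, needs_p):
    """100 random toy datasets per rule against an independently coded
    literal transcription of the rule's published derivation."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        values, labels = _random_toy(rng)
        if needs_p:
            p = float(rng.uniform(0.05, 0.95))
            got = rule(values, labels, p)
            want = oracle(values, labels, p)
        else:
            got = rule(values, labels)
            want = oracle(values, labels)
        np.testing.assert_allclose(got.probs, want, atol=1e-12)


def test_all_columns_are_proper_distributions_strictly_inside_unit_interval():
    rng = np.random.default_rng(13)
    for _ in range(25):
        values, labels = _random_toy(rng)
        for ct in (
            estimate_cpt_sample_only(values, labels),
            estimate_cpt_sample_trcmplx(values, labels, 0.3),
            estimate_cpt_sample_me_trcmplx(values, labels, 0.7),
            estimate_cpt_sample_me(values, labels),
            estimate_cpt_dact3(values, labels),
            estimate_cpt_trcmplx_only(values, labels),
        ):
            np.testing.assert_allclose(ct.probs.sum(axis=0), 1.0, atol=1e-12)
            assert np.all(ct.probs > 0) and np.all(ct.probs < 1)


def test_single_class_training_gives_uniform_missing_columns():
    values = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.ones(4, int)
    ct = estimate_cpt_sample_only(values, labels)
    np.testing.assert_allclose(ct.column((1,)), [0.5, 0.5])


def test_class_swap_symmetry_mirrors_columns():
    rng = np.random.default_rng(3)
    values, labels = _random_toy(rng)
    a = estimate_cpt_sample_only(values, labels)
    b = estimate_cpt_sample_only(values, -labels)
    np.testing.assert_allclose(a.column((1,)), b.column((2,)))
    np.testing.assert_allclose(a.column((2,)), b.column((1,)))


def test_monotone_in_actives_in_normal():
    """Shifting active samples from tumor into normal (total fixed, median
    fixed at 1) weakly increases the smoothed Pr(active | normal-side
    column) of every rule."""
    n = 8

    def dataset(k):  # k actives in normal, 8 - k in tumor
        normal = [2.0] * k + [0.0] * (n - k)
        tumor = [2.0] * (n - k) + [0.0] * k
        return np.array(normal + tumor), np.array([-1] * n + [1] * n)

    rules = {
        "sample_only": lambda v, y: estimate_cpt_sample_only(v, y).prob(2, (1,)),
        "sample_trcmplx": lambda v, y: estimate_cpt_sample_trcmplx(v, y, 0.4).prob(2, (1, 1)),
        "sample_me_trcmplx": lambda v, y: estimate_cpt_sample_me_trcmplx(v, y, 0.4).prob(2, (1, 1, 1)),
        "sample_me": lambda v, y: estimate_cpt_sample_me(v, y).prob(2, (1, 1)),
        "dact3": lambda v, y: estimate_cpt_dact3(v, y).prob(2, (1, 2, 1)),
        "trcmplx_only": lambda v, y: estimate_cpt_trcmplx_only(v, y).prob(2, (1,)),
    }
    for name, entry in rules.items():
        series = [entry(*dataset(k)) for k in range(n + 1)]
        assert all(
            later >= earlier - 1e-12 for earlier, later in zip(series, series[1:])
        ), f"{name} not monotone: {series}"


def test_etgn_bounds_rejected():
    with pytest.raises(ValueError):
        estimate_cpt_sample_trcmplx(TOY_VALUES, TOY_LABELS, 1.0)
    with pytest.raises(ValueError):
        estimate_cpt_sample_me_trcmplx(TOY_VALUES, TOY_LABELS, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=30),
    st.integers(0, 2**31 - 1),
)
def test_smoothed_tables_always_proper(values_list, seed):
    rng = np.random.default_rng(seed)
    values = np.asarray(values_list)
    labels = np.where(rng.random(len(values)) < 0.5, -1, 1)
    ct = estimate_cpt_sample_only(values, labels)
    np.testing.assert_allclose(ct.probs.sum(axis=0), 1.0, atol=1e-12)
    assert np.all(ct.probs > 0) and np.all(ct.probs < 1)


class TestTrainNetwork:
    def test_fixed_priors_assigned_verbatim(self, small_cohort):
        dataset, _ = small_cohort
        net = train_network(dataset, "t1")
        np.testing.assert_allclose(net.table("Sample").probs[:, 0], [0.5, 0.5])
        np.testing.assert_allclose(net.table("TCF4").probs[:, 0], [0.1, 0.9])
        np.testing.assert_allclose(
            net.table("DVL2").probs, [[0.01, 0.99], [0.99, 0.01]]
        )
        np.testing.assert_allclose(net.table("MeDACT1").probs[:, 0], [0.837, 0.163])

    def test_thresholds_are_training_medians(self, small_cohort):
        dataset, _ = small_cohort
        net = train_network(dataset, "t2")
        for r, gene in enumerate(dataset.genes):
            assert net.discretization.threshold(gene) == np.median(dataset.matrix[r])

    def test_every_node_has_a_matching_table(self, small_cohort):
        dataset, _ = small_cohort
        for variant in ("t1", "t2", "p1"):
            net = train_network(dataset, variant)
            assert set(net.parameters) == set(net.topology.node_names)

    def test_rejects_single_class_and_missing_gene(self, small_cohort):
        dataset, _ = small_cohort
        bad = ExpressionDataset(
            genes=dataset.genes,
            matrix=dataset.matrix,
            labels=np.ones(dataset.n_samples, int),
        )
        with pytest.raises(ValueError, match="both normal and tumor"):
            train_network(bad, "t2")
        partial = ExpressionDataset(
            genes=dataset.genes[:-1],
            matrix=dataset.matrix[:-1],
            labels=dataset.labels,
        )
        with pytest.raises(ValueError, match="no expression row"):
            train_network(partial, "t2")

    def test_single_parent_recovery_from_large_noiseless_cohort(self):
        """Count-smoothed single-parent estimates recover the generating
        class-conditional activity within 0.05 at n=2000/class and near-zero
        emission noise (the printed single-parent tables are class-symmetric,
        so the median split is informative)."""
        dataset, truth = generate_cohort(
            GeneratorConfig(n_normal=2000, n_tumor=2000, sigma=0.02, seed=17)
        )
        net = train_network(dataset, "t1", TrainingConfig(smoothing_on="counts"))
        from wntbn.parameters import reference_network

        ref = reference_network()
        for gene in ("DKK2", "DKK3-1", "DKK3-2", "SFRP3", "LEF1"):
            est = net.table(gene).probs
            want = ref.table(gene).probs
            np.testing.assert_allclose(est, want, atol=0.05)
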