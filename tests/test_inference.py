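"""Exact inference: worked examples, hand calculations and equivalence of
the elimination path with the full-joint enumeration oracle."""

from __future__ import annotations

import numpy as np
import pytest

import wntbn as w
from wntbn import inference
from wntbn.tables import ConditionalTable
from wntbn.topology import ModelTopology, NodeSpec
from conftest import random_network


def _net(nodes, tables):
    topo = ModelTopology(variant="t1", nodes=tuple(nodes))
    return w.TrainedNetwork(topology=topo, parameters=tables)


class TestWorkedExamples:
    def test_empty_evidence_returns_root_priors(self, ref_net):
        assert w.posterior_marginal(ref_net, {}, "Sample").probs == (0.5, 0.5)
        np.testing.assert_allclose(
            w.posterior_marginal(ref_net, {}, "TCF4").probs, (0.1, 0.9), atol=1e-12
        )
        np.testing.assert_allclose(
            w.posterior_marginal(ref_net, {}, "H3K27me3").probs,
            (0.2391, 0.7609),
            atol=1e-12,
        )

    def test_dvl2_given_inactive_dact3(self, ref_net):
        post = w.posterior_marginal(ref_net, {"DACT3": 1}, "DVL2")
        assert post.prob(2) == pytest.approx(0.99, abs=1e-9)

    def test_trcmplx_given_active_machinery(self, ref_net):
        post = w.posterior_marginal(
            ref_net, {"TCF4": 2, "LEF1": 2, "BETACAT": 2}, "TRCMPLX"
        )
        assert post.prob(2) == pytest.approx(0.99, abs=1e-9)

    def test_dact3_evidence_swings_dvl2(self, ref_net):
        hi = w.posterior_marginal(ref_net, {"DACT3": 1}, "DVL2").prob(2)
        lo = w.posterior_marginal(ref_net, {"DACT3": 2}, "DVL2").prob(2)
        assert (lo, hi) == (pytest.approx(0.01), pytest.approx(0.99))

    def test_irrelevant_evidence_leaves_marginal_unchanged(self, ref_net):
        # MeDKK4 is an isolated root in the default topology
        base = w.posterior_marginal(ref_net, {}, "TRCMPLX").probs
        cond = w.posterior_marginal(ref_net, {"MeDKK4": 2}, "TRCMPLX").probs
        np.testing.assert_allclose(base, cond, atol=1e-12)


def test_collider_matches_hand_bayes_inversion():
    """A -> C <- B with known tables; Pr(A=2 | C=2) computed by hand."""
    pa, pb = 0.3, 0.6  # Pr(A=2), Pr(B=2)
    # Pr(C=2 | A, B) columns ordered (A fastest): (1,1),(2,1),(1,2),(2,2)
    pc = np.array([0.1, 0.7, 0.4, 0.9])
    nodes = [
        NodeSpec("A", "gene", ("ia", "a")),
        NodeSpec("B", "gene", ("ia", "a")),
        NodeSpec("C", "gene", ("ia", "a"), ("A", "B")),
    ]
    tables = {
        "A": ConditionalTable("A", (), np.array([[1 - pa], [pa]])),
        "B": ConditionalTable("B", (), np.array([[1 - pb], [pb]])),
        "C": ConditionalTable("C", ("A", "B"), np.vstack([1 - pc, pc])),
    }
    net = _net(nodes, tables)
    # hand enumeration of Pr(A=2, C=2) and Pr(C=2)
    joint_a2 = pa * ((1 - pb) * 0.7 + pb * 0.9)
    z = (
        (1 - pa) * (1 - pb) * 0.1
        + pa * (1 - pb) * 0.7
        + (1 - pa) * pb * 0.4
        + pa * pb * 0.9
    )
    want = joint_a2 / z
    got = w.posterior_marginal(net, {"C": 2}, "A").prob(2)
    assert got == pytest.approx(want, abs=1e-12)
    # and the independent enumeration oracle agrees
    assert w.brute_force_marginal(net, {"C": 2}, "A").prob(2) == pytest.approx(
        want, abs=1e-12
    )


def test_single_root_brute_force():
    nodes = [NodeSpec("A", "gene", ("ia", "a"))]
    tables = {"A": ConditionalTable("A", (), np.array([[0.3], [0.7]]))}
    net = _net(nodes, tables)
    np.testing.assert_allclose(
        w.brute_force_marginal(net, {}, "A").probs, (0.3, 0.7), atol=1e-15
    )


def test_clamping_all_parents_reproduces_cpt_column(ref_net):
    ct = ref_net.table("MYC")
    for states in ((1, 1), (2, 1), (1, 2), (2, 2)):
        evidence = dict(zip(ct.parents, states))
        post = w.posterior_marginal(ref_net, evidence, "MYC")
        np.testing.assert_allclose(post.probs, ct.column(states), atol=1e-9)


def test_posterior_sums_to_one_and_fresh_engine_per_call(ref_net):
    before = inference.engine_build_count()
    for ev in ({}, {"DACT3": 1}, {"SFRP3": 2, "LEF1": 1}):
        post = w.posterior_marginal(ref_net, ev, "TRCMPLX")
        assert sum(post.probs) == pytest.approx(1.0, abs=1e-9)
    assert inference.engine_build_count() - before == 3


def test_impossible_evidence_raises():
    nodes = [
        NodeSpec("A", "gene", ("ia", "a")),
        NodeSpec("B", "gene", ("ia", "a"), ("A",)),
    ]
    tables = {
        "A": ConditionalTable("A", (), np.array([[1.0], [0.0]])),
        "B": ConditionalTable("B", ("A",), np.array([[0.2, 0.8], [0.8, 0.2]])),
    }
    net = _net(nodes, tables)
    with pytest.raises(w.ImpossibleEvidenceError):
        w.posterior_marginal(net, {"A": 2}, "B")
    with pytest.raises(w.ImpossibleEvidenceError):
        w.brute_force_marginal(net, {"A": 2}, "B")


def test_evidence_validation(ref_net):
    with pytest.raises(KeyError):
        w.posterior_marginal(ref_net, {"NOSUCH": 1}, "TRCMPLX")
    with pytest.raises(ValueError):
        w.posterior_marginal(ref_net, {"DACT3": 3}, "TRCMPLX")
    with pytest.raises(KeyError):
        w.posterior_marginal(ref_net, {}, "NOSUCH")


def test_brute_force_refuses_large_networks(ref_net):
    with pytest.raises(ValueError, match="guard"):
        w.brute_force_marginal(ref_net, {}, "TRCMPLX")  # 34 nodes


class TestOracleEquivalence:
    """Variable elimination equals full-joint enumeration within 1e-9."""

    def test_full_t2_network(self, small_cohort):
        dataset, _ = small_cohort
        net = w.train_network(dataset, "t2")
        rng = np.random.default_rng(21)
        genes = list(net.topology.gene_nodes)
        for _ in range(3):
            picked = rng.choice(genes, size=6, replace=False)
            ev = {g: int(rng.integers(1, 3)) for g in picked}
            for node in ("TRCMPLX", "Sample"):
                a = w.posterior_marginal(net, ev, node).probs
                b = w.brute_force_marginal(net, ev, node).probs
                np.testing.assert_allclose(a, b, atol=1e-9)

    def test_full_p1_network(self, small_cohort):
        dataset, _ = small_cohort
        net = w.train_network(dataset, "p1")
        rng = np.random.default_rng(22)
        genes = list(net.topology.gene_nodes)
        for _ in range(3):
            picked = rng.choice(genes, size=6, replace=False)
            ev = {g: int(rng.integers(1, 3)) for g in picked}
            a = w.posterior_marginal(net, ev, "TRCMPLX").probs
            b = w.brute_force_marginal(net, ev, "TRCMPLX").probs
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_fifty_random_subnetworks(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            net = random_network(rng, int(rng.integers(3, 16)))
            names = list(net.topology.node_names)
            n_ev = int(rng.integers(0, min(4, len(names) - 1) + 1))
            ev_nodes = rng.choice(names, size=n_ev, replace=False) if n_ev else []
            ev = {v: int(rng.integers(1, 3)) for v in ev_nodes}
            target = rng.choice([v for v in names if v not in ev])
            a = w.posterior_marginal(net, ev, str(target)).probs
            b = w.brute_force_marginal(net, ev, str(target)).probs
            np.testing.assert_allclose(a, b, atol=1e-9)
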