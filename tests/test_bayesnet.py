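"""CPT fitting, BIC, K2 search, enumeration inference, sampling.

Oracles here are deliberately naive: the full joint table is assembled by
looping over every assignment, and the BIC is recomputed with dictionary
grouping — independent of the vectorised implementation they check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import sleepnets as sn
from sleepnets.bayesnet import (CPT, DiscreteBayesianNetwork, NetworkStructure,
                                bic_score, fit_parameters, k2_search,
                                random_network, stage_constraints)


# ---------------------------------------------------------------------- oracles

def joint_table_oracle(net):
    """Full joint by explicit looping over assignments."""
    order = net.structure.order
    cards = [net.structure.cards[v] for v in order]
    pos = {v: i for i, v in enumerate(order)}
    joint = np.zeros(cards)
    for assignment in itertools.product(*(range(c) for c in cards)):
        p = 1.0
        for v in order:
            cpt = net.cpts[v]
            idx = tuple(assignment[pos[q]] for q in cpt.parents + [v])
            p *= cpt.probs[idx]
        joint[assignment] = p
    return joint


def posterior_oracle(net, target, evidence):
    joint = joint_table_oracle(net)
    order = net.structure.order
    for v, val in evidence.items():
        sl = [slice(None)] * joint.ndim
        sl[order.index(v)] = slice(val, val + 1)
        keep = np.zeros_like(joint)
        keep[tuple(sl)] = joint[tuple(sl)]
        joint = keep
    sum_axes = tuple(i for i, v in enumerate(order) if v != target)
    vec = joint.sum(axis=sum_axes)
    return vec / vec.sum()


def bic_oracle(data, structure):
    """Naive BIC: dictionary grouping + explicit parameter count
    (unconstrained structures only)."""
    n = len(data)
    total = 0.0
    for v in structure.order:
        parents = structure.parents[v]
        card = structure.cards[v]
        groups = {}
        for _, row in data.iterrows():
            key = tuple(row[p] for p in parents)
            groups.setdefault(key, []).append(row[v])
        for vals in groups.values():
            m = len(vals)
            for c in range(card):
                k = vals.count(c)
                if k:
                    total += k * np.log(k / m)
        n_configs = int(np.prod([structure.cards[p] for p in parents]))
        total -= 0.5 * np.log(n) * n_configs * (card - 1)
    return total


def _structure(order, cards, parents, constraints=()):
    return NetworkStructure(order=list(order), cards=dict(cards),
                            parents={k: list(v) for k, v in parents.items()},
                            constraints=list(constraints))


# ------------------------------------------------------------------- parameters

class TestFitParameters:
    def test_mle_rows(self):
        data = pd.DataFrame({"A": [0, 0, 1, 1]})
        net = fit_parameters(_structure(["A"], {"A": 2}, {}), data, 0.0)
        np.testing.assert_allclose(net.cpts["A"].probs, [0.5, 0.5])
        data = pd.DataFrame({"A": [0, 0, 0, 1]})
        net = fit_parameters(_structure(["A"], {"A": 2}, {}), data, 0.0)
        np.testing.assert_allclose(net.cpts["A"].probs, [0.75, 0.25])

    def test_unseen_parent_config_is_uniform_under_prior(self):
        data = pd.DataFrame({"A": [0, 0], "B": [0, 1]})
        st = _structure(["A", "B"], {"A": 2, "B": 4}, {"B": ["A"]})
        net = fit_parameters(st, data, pseudo_count=1.0)
        np.testing.assert_allclose(net.cpts["B"].probs[1], [0.25] * 4)

    def test_structural_zero_rows(self):
        data = pd.DataFrame({"stage_t1": [0, 0, 1], "stage_t": [1, 2, 0]})
        st = _structure(["stage_t1", "stage_t"], {"stage_t1": 5, "stage_t": 5},
                        {"stage_t": ["stage_t1"]},
                        constraints=[("stage_t", "stage_t1")])
        net = fit_parameters(st, data, pseudo_count=1.0)
        probs = net.cpts["stage_t"].probs
        assert np.all(np.diag(probs) == 0.0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_missing_variable(self):
        with pytest.raises(ValueError, match="missing variable"):
            fit_parameters(_structure(["A"], {"A": 2}, {}),
                           pd.DataFrame({"B": [0]}), 0.0)


# -------------------------------------------------------------------------- BIC

class TestBIC:
    def test_single_binary_variable_hand_value(self):
        # counts [2,2]: LL = 4 ln 0.5, penalty = (ln 4)/2 * 1
        data = pd.DataFrame({"A": [0, 0, 1, 1]})
        score = bic_score(_structure(["A"], {"A": 2}, {}), data)
        assert score == pytest.approx(4 * np.log(0.5) - np.log(4) / 2)
        assert score == pytest.approx(-3.4657, abs=1e-4)

    def test_matches_naive_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cards = {"A": 2, "B": 3, "C": 2}
            data = pd.DataFrame({v: rng.integers(0, c, 60)
                                 for v, c in cards.items()})
            st = _structure(["A", "B", "C"], cards,
                            {"B": ["A"], "C": ["A", "B"]})
            assert bic_score(st, data) == pytest.approx(bic_oracle(data, st))

    def test_irrelevant_parent_lowers_score(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"A": rng.integers(0, 2, 10_000),
                             "B": rng.integers(0, 2, 10_000)})
        cards = {"A": 2, "B": 2}
        indep = bic_score(_structure(["A", "B"], cards, {}), data)
        spurious = bic_score(_structure(["A", "B"], cards, {"B": ["A"]}), data)
        assert spurious < indep

    def test_true_dependence_raises_score(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 10_000)
        b = np.where(rng.random(10_000) < 0.9, a, 1 - a)
        data = pd.DataFrame({"A": a, "B": b})
        cards = {"A": 2, "B": 2}
        indep = bic_score(_structure(["A", "B"], cards, {}), data)
        dep = bic_score(_structure(["A", "B"], cards, {"B": ["A"]}), data)
        assert dep > indep

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="no data"):
            bic_score(_structure(["A"], {"A": 2}, {}), pd.DataFrame({"A": []}))


# --------------------------------------------------------------------------- K2

class TestK2:
    def test_recovers_single_edge(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 20_000)
        b = (a + (rng.random(20_000) < 0.15)) % 3
        data = pd.DataFrame({"A": a, "B": b})
        st = k2_search(data, ["A", "B"], cards={"A": 3, "B": 3}, constraints=[])
        assert st.edges() == {("A", "B")}

    def test_independent_variables_stay_unconnected(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({v: rng.integers(0, 3, 5_000) for v in "ABC"})
        st = k2_search(data, ["A", "B", "C"],
                       cards={v: 3 for v in "ABC"}, constraints=[])
        assert st.edges() == set()

    def test_edges_respect_node_order(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, n_vars=5)
        data = net.sample(5_000, seed=1)
        st = k2_search(data, net.structure.order,
                       cards=net.structure.cards, constraints=[])
        pos = {v: i for i, v in enumerate(net.structure.order)}
        assert all(pos[p] < pos[c] for p, c in st.edges())

    def test_duplicate_order_rejected(self):
        with pytest.raises(ValueError, match="invalid order"):
            k2_search(pd.DataFrame({"A": [0, 1]}), ["A", "A"],
                      cards={"A": 2}, constraints=[])

    def test_max_parents_cap(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, n_vars=5, p_edge=1.0, max_parents=2)
        data = net.sample(20_000, seed=2)
        st = k2_search(data, net.structure.order, cards=net.structure.cards,
                       constraints=[], max_parents=1)
        assert max(len(ps) for ps in st.parents.values()) <= 1


# -------------------------------------------------------------------- inference

class TestInference:
    def _toy_net(self, seed=0, n_vars=4):
        return random_network(np.random.default_rng(seed), n_vars=n_vars)

    def test_full_parent_evidence_returns_cpt_row(self):
        net = self._toy_net(1)
        child = next(v for v in net.structure.order if net.structure.parents[v])
        # leaf child with evidence on *all* other variables reduces to a
        # CPT row only when nothing downstream depends on the child
        children_of = [v for v in net.structure.order
                       if child in net.structure.parents[v]]
        if children_of:
            pytest.skip("sampled child is not a leaf in this seed")
        ev = {p: 0 for p in net.structure.parents[child]}
        got = net.posterior(child, ev)
        want = net.cpts[child].probs[tuple(0 for _ in net.structure.parents[child])]
        np.testing.assert_allclose(got, want)

    def test_marginal_matches_joint_oracle(self):
        net = self._toy_net(2)
        for target in net.structure.order:
            np.testing.assert_allclose(net.posterior(target),
                                       posterior_oracle(net, target, {}),
                                       atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_posterior_matches_joint_oracle_under_evidence(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_vars=5, card=3)
        order = net.structure.order
        target = order[int(rng.integers(len(order)))]
        others = [v for v in order if v != target]
        ev_vars = [v for v in others if rng.random() < 0.6]
        ev = {v: int(rng.integers(net.structure.cards[v])) for v in ev_vars}
        np.testing.assert_allclose(net.posterior(target, ev),
                                   posterior_oracle(net, target, ev),
                                   atol=1e-10)

    def test_bayes_rule_by_hand(self):
        # Age -> Stage with known tables; observe the stage, read off age
        st = _structure(["age", "stage"], {"age": 2, "stage": 2},
                        {"stage": ["age"]})
        prior = np.array([0.7, 0.3])
        lik = np.array([[0.9, 0.1], [0.4, 0.6]])
        cpts = {
            "age": CPT("age", [], prior, np.ones(2, bool), np.ones((), bool)),
            "stage": CPT("stage", ["age"], lik, np.ones((2, 2), bool),
                         np.ones(2, bool)),
        }
        net = DiscreteBayesianNetwork(st, cpts, n_train=0, pseudo_count=0)
        post = net.posterior("age", {"stage": 1})
        hand = prior * lik[:, 1]
        np.testing.assert_allclose(post, hand / hand.sum())

    def test_evidence_independent_of_target_leaves_prior(self):
        st = _structure(["A", "B"], {"A": 2, "B": 2}, {})
        cpts = {
            "A": CPT("A", [], np.array([0.6, 0.4]), np.ones(2, bool),
                     np.ones((), bool)),
            "B": CPT("B", [], np.array([0.5, 0.5]), np.ones(2, bool),
                     np.ones((), bool)),
        }
        net = DiscreteBayesianNetwork(st, cpts, 0, 0)
        np.testing.assert_allclose(net.posterior("A", {"B": 1}), [0.6, 0.4])

    def test_deterministic_child_concentrates_posterior(self):
        st = _structure(["A", "B"], {"A": 2, "B": 2}, {"B": ["A"]})
        cpts = {
            "A": CPT("A", [], np.array([0.5, 0.5]), np.ones(2, bool),
                     np.ones((), bool)),
            "B": CPT("B", ["A"], np.eye(2), np.ones((2, 2), bool),
                     np.ones(2, bool)),
        }
        net = DiscreteBayesianNetwork(st, cpts, 0, 0)
        np.testing.assert_allclose(net.posterior("A", {"B": 1}), [0.0, 1.0])

    def test_impossible_evidence(self):
        st = _structure(["A", "B"], {"A": 2, "B": 2}, {"B": ["A"]})
        cpts = {
            "A": CPT("A", [], np.array([1.0, 0.0]), np.ones(2, bool),
                     np.ones((), bool)),
            "B": CPT("B", ["A"], np.array([[1.0, 0.0], [0.0, 1.0]]),
                     np.ones((2, 2), bool), np.ones(2, bool)),
        }
        net = DiscreteBayesianNetwork(st, cpts, 0, 0)
        with pytest.raises(ValueError, match="impossible evidence"):
            net.posterior("A", {"B": 1})

    def test_invalid_evidence_value(self):
        net = self._toy_net(3)
        v = net.structure.order[0]
        t = net.structure.order[-1]
        with pytest.raises(ValueError, match="invalid evidence"):
            net.posterior(t, {v: 99})


# --------------------------------------------------------------------- sampling

class TestSampling:
    def test_zero_samples(self):
        net = random_network(np.random.default_rng(0))
        assert len(net.sample(0, seed=1)) == 0

    def test_reproducible(self):
        net = random_network(np.random.default_rng(0))
        pd.testing.assert_frame_equal(net.sample(500, seed=7),
                                      net.sample(500, seed=7))

    def test_frequencies_match_cpts(self):
        net = random_network(np.random.default_rng(4), n_vars=3)
        data = net.sample(100_000, seed=3)
        root = net.structure.order[0]
        freq = np.bincount(data[root], minlength=net.structure.cards[root]) / len(data)
        np.testing.assert_allclose(freq, net.cpts[root].probs, atol=0.01)

    def test_sample_then_refit_recovers_cpts(self):
        net = random_network(np.random.default_rng(9), n_vars=4)
        data = net.sample(100_000, seed=5)
        refit = fit_parameters(net.structure, data, pseudo_count=0.0)
        for v in net.structure.order:
            np.testing.assert_allclose(refit.cpts[v].probs, net.cpts[v].probs,
                                       atol=0.01)


# ----------------------------------------------------------------- round trips

def test_network_json_round_trip():
    net = random_network(np.random.default_rng(11), n_vars=4)
    back = DiscreteBayesianNetwork.from_dict(net.to_dict())
    for v in net.structure.order:
        np.testing.assert_allclose(back.cpts[v].probs, net.cpts[v].probs)
    assert back.structure.edges() == net.structure.edges()


# ------------------------------------------------------------------- classifier

class TestClassifier:
    def test_fit_predict_on_planted_dependence(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 3, 8_000)
        y = (a + (rng.random(8_000) < 0.1)) % 3
        X = pd.DataFrame({"A": a})
        clf = sn.BayesianNetworkClassifier(target="Y", node_order=["A", "Y"])
        clf.fit(X, y)
        acc = (clf.predict(X) == y).mean()
        assert acc > 0.85
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_sklearn_contract(self):
        clf = sn.BayesianNetworkClassifier(pseudo_count=2.0)
        assert clone(clf).get_params()["pseudo_count"] == 2.0

    def test_rejects_missing_codes(self):
        X = pd.DataFrame({"stage_t1": [-1, 0]})
        clf = sn.BayesianNetworkClassifier()
        with pytest.raises(ValueError, match="missing"):
            clf.fit(X, np.array([0, 1]))

    def test_stage_constraints_active(self):
        assert stage_constraints(["stage_t", "stage_t1", "dur_t"]) == [
            ("stage_t", "stage_t1")]
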