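"""Person-period transform, percentile binning, node scores and exact
structure search (including a brute-force all-DAGs oracle)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from frailtypaths.abn import (
    DagResult, NodeSpec, compare_parent_limits, discretize_percentile,
    learn_structure, score_node, to_person_period,
)
from frailtypaths.simulate import GeneratorConfig, generate_cohort


def all_dags(nodes):
    """Every DAG over ``nodes`` as a dict node -> parent tuple."""
    n = len(nodes)
    arcs = [(a, b) for a in nodes for b in nodes if a != b]
    for mask in range(1 << len(arcs)):
        chosen = [arcs[i] for i in range(len(arcs)) if mask >> i & 1]
        g = {v: tuple(sorted(p for p, c in chosen if c == v)) for v in nodes}
        # acyclicity by repeated sink removal
        remaining = set(nodes)
        deps = {v: set(g[v]) for v in nodes}
        while True:
            free = [v for v in remaining if not (deps[v] & remaining)]
            if not free:
                break
            remaining -= set(free)
        if not remaining:
            yield g


class TestPersonPeriod:
    def test_death_mid_third_interval(self):
        df = pd.DataFrame({"subject_id": [0], "followup_time": [4.5],
                           "event": [1]})
        pp = to_person_period(df, 2.0)
        assert len(pp) == 3
        assert pp["period_event"].tolist() == [0, 0, 1]
        assert pp["period_index"].tolist() == [1, 2, 3]

    def test_censoring_on_boundary_half_open(self):
        df = pd.DataFrame({"subject_id": [0], "followup_time": [4.0],
                           "event": [0]})
        pp = to_person_period(df, 2.0)
        assert len(pp) == 2
        assert pp["period_event"].sum() == 0

    def test_conservation_on_random_cohorts(self):
        for seed in range(5):
            df = generate_cohort(GeneratorConfig(n_subjects=300, seed=seed))
            pp = to_person_period(df, 2.0)
            assert pp["period_event"].sum() == df["event"].sum()
            expect_rows = np.where(
                df["event"] == 1,
                np.floor(df["followup_time"] / 2.0) + 1,
                np.ceil(df["followup_time"] / 2.0)).sum()
            assert len(pp) == expect_rows

    def test_baseline_covariates_carried_forward(self):
        df = pd.DataFrame({"subject_id": [7], "followup_time": [5.0],
                           "event": [0], "age": [61.0]})
        pp = to_person_period(df, 2.0, baseline_cols=["subject_id", "age"])
        assert (pp["age"] == 61.0).all() and (pp["subject_id"] == 7).all()

    def test_negative_followup_rejected(self):
        df = pd.DataFrame({"subject_id": [0], "followup_time": [-1.0],
                           "event": [0]})
        with pytest.raises(ValueError, match="negative"):
            to_person_period(df)


class TestDiscretize:
    def test_tertiles_of_one_to_nine(self):
        rep, codes, edges = discretize_percentile(np.arange(1, 10), 3)
        assert np.allclose(rep, np.repeat([2.0, 5.0, 8.0], 3))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            discretize_percentile([1, 2, 3], 1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize_percentile([5.0] * 10, 3)

    def test_representatives_monotone_in_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        rep, _, _ = discretize_percentile(x, 5)
        order = np.argsort(x)
        assert (np.diff(rep[order]) >= 0).all()


class TestScoreNode:
    def test_hand_gaussian_score(self):
        """y = (0,1), no parents: sigma2hat = 0.25, k = 2."""
        data = pd.DataFrame({"y": [0.0, 1.0]})
        score = score_node(NodeSpec("y", "gaussian"), (), data)
        ll = -(math.log(2 * math.pi * 0.25) + 1.0)
        assert score == pytest.approx(ll - math.log(2), abs=1e-12)

    def test_copy_parent_penalty_arithmetic(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"y": rng.normal(size=100)})
        data["x"] = data["y"] + 1e-8 * rng.normal(size=100)
        s0 = score_node(NodeSpec("y", "gaussian"), (), data)
        s1 = score_node(NodeSpec("y", "gaussian"), ("x",), data)
        # unpenalised logL rises; the BIC delta is logL gain minus half log n
        assert s1 - s0 > 0.5 * math.log(100)  # near-copy parent: huge gain

    def test_pure_noise_parent_usually_penalised(self):
        rng = np.random.default_rng(2)
        worse = 0
        reps = 50
        for _ in range(reps):
            data = pd.DataFrame({"y": rng.normal(size=2000),
                                 "z": rng.normal(size=2000)})
            s0 = score_node(NodeSpec("y", "gaussian"), (), data)
            s1 = score_node(NodeSpec("y", "gaussian"), ("z",), data)
            worse += s1 < s0
        assert worse >= 0.9 * reps

    def test_binomial_score_matches_bernoulli_loglik(self):
        data = pd.DataFrame({"y": [0.0, 0.0, 1.0, 1.0, 1.0]})
        score = score_node(NodeSpec("y", "binomial"), (), data)
        p = 0.6
        ll = 3 * math.log(p) + 2 * math.log(1 - p)
        assert score == pytest.approx(ll - 0.5 * math.log(5), abs=1e-6)

    def test_own_parent_rejected(self):
        data = pd.DataFrame({"y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="own parent"):
            score_node(NodeSpec("y", "gaussian"), ("y",), data)


def _specs(cols, binomial=(), exo=(), sink=()):
    out = []
    for c in cols:
        fam = "binomial" if c in binomial else "gaussian"
        role = "exogenous" if c in exo else ("sink" if c in sink
                                             else "endogenous")
        out.append(NodeSpec(c, fam, role))
    return out


class TestLearnStructure:
    def test_independent_nodes_give_empty_graph(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        dag = learn_structure(data, _specs(["a", "b"]), parent_limit=1)
        assert dag.arcs == []

    def test_chain_recovery(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.normal(size=n)
            m = 0.8 * x + rng.normal(size=n)
            y = 0.8 * m + rng.normal(size=n)
            data = pd.DataFrame({"x": x, "m": m, "y": y})
            dag = learn_structure(data, _specs(["x", "m", "y"]), 2)
            skel = {tuple(sorted(a)) for a in dag.arcs}
            hits += skel == {("m", "x"), ("m", "y")}
        assert hits >= 19

    def test_matches_brute_force_enumeration(self):
        """Total score equals exhaustive maximisation over all DAGs."""
        rng = np.random.default_rng(4)
        n = 300
        a = rng.normal(size=n)
        b = 0.7 * a + rng.normal(size=n)
        c = (rng.uniform(size=n) < 1 / (1 + np.exp(-b))).astype(float)
        d = 0.5 * c + rng.normal(size=n)
        data = pd.DataFrame({"a": a, "b": b, "c": c, "d": d})
        specs = _specs(["a", "b", "c", "d"], binomial=("c",))
        for limit in (1, 2, 3):
            dag = learn_structure(data, specs, limit)
            cache = {}

            def local(v, ps):
                key = (v, ps)
                if key not in cache:
                    spec = next(s for s in specs if s.name == v)
                    cache[key] = score_node(spec, ps, data)
                return cache[key]

            best = -np.inf
            for g in all_dags(["a", "b", "c", "d"]):
                if any(len(ps) > limit for ps in g.values()):
                    continue
                best = max(best, sum(local(v, ps) for v, ps in g.items()))
            assert dag.total_score == pytest.approx(best, abs=1e-9)

    def test_role_constraints_respected(self):
        rng = np.random.default_rng(5)
        n = 3000
        x = rng.normal(size=n)
        s = (rng.uniform(size=n) < 0.5).astype(float)
        y = 1.0 * x + 0.8 * s + rng.normal(size=n)
        death = (rng.uniform(size=n)
                 < 1 / (1 + np.exp(-(-2 + y)))).astype(float)
        data = pd.DataFrame({"x": x, "s": s, "y": y, "death": death})
        dag = learn_structure(
            data, _specs(["x", "s", "y", "death"], binomial=("s", "death"),
                         exo=("x", "s"), sink=("death",)), 2)
        assert dag.parents["x"] == () and dag.parents["s"] == ()
        assert all("death" not in ps for ps in dag.parents.values())
        assert set(dag.parents["death"]) <= {"x", "s", "y"}

    def test_banned_and_required_arcs(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": y})
        specs = _specs(["x", "y"])
        banned = learn_structure(data, specs, 1,
                                 banned_arcs=[("x", "y"), ("y", "x")])
        assert banned.arcs == []
        required = learn_structure(data, specs, 1,
                                   required_arcs=[("y", "x")])
        assert required.arcs == [("y", "x")]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": y})
        dag1 = learn_structure(data, _specs(["x", "y"]), 1)
        dag2 = learn_structure(data.sample(frac=1, random_state=0),
                               _specs(["x", "y"]), 1)
        assert dag1.parents == dag2.parents
        assert dag1.total_score == pytest.approx(dag2.total_score, abs=1e-9)

    def test_node_bound_enforced(self):
        data = pd.DataFrame(np.random.default_rng(8).normal(size=(10, 15)),
                            columns=[f"v{i}" for i in range(15)])
        with pytest.raises(ValueError, match="exceeds"):
            learn_structure(data, _specs(list(data.columns)), 1)

    def test_dot_and_json_outputs(self):
        dag = DagResult(parents={"a": (), "b": ("a",)},
                        node_scores={"a": -1.0, "b": -2.0},
                        total_score=-3.0, parent_limit=1)
        dot = dag.to_dot()
        assert '"a" -> "b";' in dot
        assert '"parents"' in dag.to_json()


class TestCompareParentLimits:
    @staticmethod
    def _chain_data(seed=9, n=4000):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        m = 0.9 * x + rng.normal(size=n)
        y = 0.9 * m + rng.normal(size=n)
        return pd.DataFrame({"x": x, "m": m, "y": y})

    def test_max_indegree_one_selects_limit_one(self):
        data = self._chain_data()
        table, selected, results = compare_parent_limits(
            data, _specs(["x", "m", "y"]), limits=(1, 2))
        assert selected == 1
        assert results[2].total_score <= results[1].total_score + 1e-6

    def test_score_non_decreasing_in_limit(self):
        df = generate_cohort(GeneratorConfig(n_subjects=800, seed=10))
        data = df[["age", "ses_z", "grimage_eaa", "pace"]].astype(float)
        table, _, _ = compare_parent_limits(
            data, _specs(list(data.columns)), limits=(1, 2, 3))
        assert (np.diff(table["total_score"]) >= -1e-9).all()

    def test_steadily_improving_scores_select_largest(self, monkeypatch):
        import frailtypaths.abn as abn_mod
        fake = {1: DagResult({}, {}, -100.0, 1),
                2: DagResult({}, {}, -50.0, 2),
                3: DagResult({}, {}, -10.0, 3)}
        monkeypatch.setattr(abn_mod, "learn_structure",
                            lambda *a, **k: fake[a[2] if len(a) > 2 else k["parent_limit"]])
        table, selected, _ = abn_mod.compare_parent_limits(
            pd.DataFrame(), [], limits=(1, 2, 3))
        assert selected == 3
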