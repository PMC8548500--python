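import numpy as np
import pytest

from hetmda import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    disease_semantic_similarity,
    gip_similarity,
    integrate_similarity,
    mirna_functional_similarity,
    semantic_contributions,
)
from hetmda.errors import AlignmentError, InputError, StructureError

import oracles


def chain_dag(term, parents):
    """term -> parents[0] -> parents[1] -> ..."""
    nodes = [term, *parents]
    edges = {(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)}
    return DiseaseDAG(term, frozenset(nodes), frozenset(edges))


def random_dag(rng, n_nodes):
    """Random ancestor closure: node 0 is the term; edges only point upward."""
    term = "t00"
    names = [f"t{i:02d}" for i in range(n_nodes)]
    edges = set()
    for i in range(1, n_nodes):
        # every non-term node gets >=1 child among the lower-numbered nodes
        n_children = rng.integers(1, min(i, 3) + 1)
        for c in rng.choice(i, size=n_children, replace=False):
            edges.add((names[c], names[i]))
    return DiseaseDAG(term, frozenset(names), frozenset(edges))


class TestSemanticContributions:
    def test_single_node(self):
        dag = DiseaseDAG("d", frozenset({"d"}), frozenset())
        assert semantic_contributions(dag) == {"d": 1.0}

    def test_chain_decays_by_depth(self):
        dag = chain_dag("d", ["p", "g"])
        assert semantic_contributions(dag, 0.5) == {"d": 1.0, "p": 0.5, "g": 0.25}

    def test_diamond_takes_max_over_paths(self):
        edges = {("d", "p1"), ("d", "p2"), ("p1", "g"), ("p2", "g")}
        dag = DiseaseDAG("d", frozenset({"d", "p1", "p2", "g"}), frozenset(edges))
        assert semantic_contributions(dag, 0.5) == {
            "d": 1.0, "p1": 0.5, "p2": 0.5, "g": 0.25,
        }

    def test_unreachable_ancestor_is_structural_error(self):
        dag = DiseaseDAG.__new__(DiseaseDAG)
        object.__setattr__(dag, "term_id", "d")
        object.__setattr__(dag, "ancestors", frozenset({"d", "orphan"}))
        object.__setattr__(dag, "edges", frozenset())
        with pytest.raises(StructureError):
            semantic_contributions(dag)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(2, 13)))
        delta = float(rng.uniform(0.2, 0.9))
        got = semantic_contributions(dag, delta)
        want = oracles.all_paths_contribution(dag.ancestors, dag.edges, dag.term_id, delta)
        assert got.keys() == want.keys()
        for t in got:
            assert got[t] == pytest.approx(want[t], abs=1e-12)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self):
        sim = disease_semantic_similarity({"x": chain_dag("x", ["p", "g"])}, 0.5)
        assert sim.loc("x", "x") == 1.0

    def test_siblings_under_shared_parent(self):
        d1 = chain_dag("x", ["p"])
        d2 = DiseaseDAG("y", frozenset({"y", "p"}), frozenset({("y", "p")}))
        sim = disease_semantic_similarity({"x": d1, "y": d2}, 0.5)
        assert sim.loc("x", "y") == pytest.approx((0.5 + 0.5) / 3.0)

    def test_child_parent_value(self):
        dags = {
            "d": chain_dag("d", ["p"]),
            "p": DiseaseDAG("p", frozenset({"p"}), frozenset()),
        }
        sim = disease_semantic_similarity(dags, 0.5)
        assert sim.loc("d", "p") == pytest.approx(0.6)
        assert sim.loc("d", "d") == 1.0

    def test_disjoint_dags_score_zero(self):
        dags = {"a": chain_dag("a", ["pa"]), "b": chain_dag("b", ["pb"])}
        assert disease_semantic_similarity(dags).loc("a", "b") == 0.0

    def test_empty_map_rejected(self):
        with pytest.raises(InputError):
            disease_semantic_similarity({})

    def test_relabeling_permutes_rows(self):
        rng = np.random.default_rng(3)
        dags = {f"d{i}": random_dag(rng, int(rng.integers(2, 8))) for i in range(5)}
        # rebuild the same closures under permuted ids
        ids = list(dags)
        perm = [ids[k] for k in rng.permutation(len(ids))]
        sim = disease_semantic_similarity(dags, ids=ids)
        sim_p = disease_semantic_similarity(dags, ids=perm)
        lut = {d: i for i, d in enumerate(ids)}
        for a in ids:
            for b in ids:
                assert sim.values[lut[a], lut[b]] == sim_p.loc(a, b)

    def test_universe_without_dag_gets_zero_row(self):
        dags = {"d": chain_dag("d", ["p"])}
        sim = disease_semantic_similarity(dags, ids=["d", "nodag"])
        assert sim.loc("d", "nodag") == 0.0
        assert sim.loc("nodag", "nodag") == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_shared_ancestor_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        # overlapping vocabularies: draw closures over one shared node pool
        dags = {}
        for i in range(4):
            dag = random_dag(rng, int(rng.integers(2, 10)))
            renamed = {t: (t if rng.random() < 0.5 else f"{i}_{t}") for t in dag.ancestors}
            renamed[dag.term_id] = f"d{i}"
            dags[f"d{i}"] = DiseaseDAG(
                f"d{i}",
                frozenset(renamed.values()),
                frozenset((renamed[c], renamed[p]) for c, p in dag.edges),
            )
        delta = 0.5
        sim = disease_semantic_similarity(dags, delta)
        contribs = {
            d: oracles.all_paths_contribution(g.ancestors, g.edges, d, delta)
            for d, g in dags.items()
        }
        for a in dags:
            for b in dags:
                want = 1.0 if a == b else oracles.dss_value(contribs[a], contribs[b])
                assert sim.loc(a, b) == pytest.approx(want, abs=1e-12)


class TestMirnaFunctionalSimilarity:
    @staticmethod
    def dss_of(values, ids):
        return SimilarityMatrix(np.asarray(values, float), ids, "semantic")

    def test_identical_singleton_sets(self):
        dss = self.dss_of([[1.0]], ["d"])
        sim = mirna_functional_similarity({"m1": {"d"}, "m2": {"d"}}, dss)
        assert sim.loc("m1", "m2") == 1.0

    def test_two_singletons(self):
        dss = self.dss_of([[1.0, 0.6], [0.6, 1.0]], ["d1", "d2"])
        sim = mirna_functional_similarity({"m1": {"d1"}, "m2": {"d2"}}, dss)
        assert sim.loc("m1", "m2") == pytest.approx(0.6)

    def test_overlapping_sets(self):
        dss = self.dss_of([[1.0, 0.6], [0.6, 1.0]], ["d1", "d2"])
        sim = mirna_functional_similarity({"m1": {"d1"}, "m2": {"d1", "d2"}}, dss)
        assert sim.loc("m1", "m2") == pytest.approx((1.0 + 1.0 + 0.6) / 3.0)

    def test_empty_set_rejected(self):
        dss = self.dss_of([[1.0]], ["d"])
        with pytest.raises(InputError, match="empty"):
            mirna_functional_similarity({"m1": set(), "m2": {"d"}}, dss)

    def test_unknown_term_rejected(self):
        dss = self.dss_of([[1.0]], ["d"])
        with pytest.raises(InputError, match="absent"):
            mirna_functional_similarity({"m1": {"zzz"}}, dss)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n_terms, n_mirnas = 8, 6
        ids = [f"d{i}" for i in range(n_terms)]
        dss = self.dss_of(oracles.random_symmetric_similarity(rng, n_terms), ids)
        didx = dss.index()
        dtt = {
            f"m{j}": set(rng.choice(ids, size=rng.integers(1, 5), replace=False))
            for j in range(n_mirnas)
        }
        sim = mirna_functional_similarity(dtt, dss)
        for a in dtt:
            for b in dtt:
                if a == b:
                    continue
                want = oracles.mfs_value(sorted(dtt[a]), sorted(dtt[b]), dss.values, didx)
                assert sim.loc(a, b) == pytest.approx(min(want, 1.0), abs=1e-12)


class TestGipSimilarity:
    def test_identity_association_matrix(self):
        A = AssociationMatrix(np.eye(2), ["d1", "d2"], ["m1", "m2"])
        sim = gip_similarity(A, "disease")
        assert sim.loc("d1", "d2") == pytest.approx(np.exp(-2.0), abs=1e-15)
        assert sim.loc("d1", "d1") == 1.0

    def test_identical_profiles_score_one(self):
        A = AssociationMatrix(np.ones((2, 2)), ["d1", "d2"], ["m1", "m2"])
        for space in ("disease", "mirna"):
            assert np.all(gip_similarity(A, space).values == 1.0)

    def test_all_zero_matrix_rejected(self):
        A = AssociationMatrix(np.zeros((2, 2)), ["d1", "d2"], ["m1", "m2"])
        with pytest.raises(InputError, match="bandwidth"):
            gip_similarity(A, "disease")

    def test_bandwidth_scaling_raises_exponent(self):
        rng = np.random.default_rng(0)
        values = (rng.random((5, 6)) < 0.4).astype(float)
        values[0, 0] = 1.0
        A = AssociationMatrix(
            values, [f"d{i}" for i in range(5)], [f"m{j}" for j in range(6)]
        )
        base = gip_similarity(A, "mirna", gamma_prime=1.0).values
        scaled = gip_similarity(A, "mirna", gamma_prime=3.0).values
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(scaled[off], base[off] ** 3, atol=1e-12)
        assert np.all(scaled[off] <= base[off])

    @pytest.mark.parametrize("space", ["disease", "mirna"])
    def test_matches_loop_oracle(self, space):
        rng = np.random.default_rng(42)
        values = (rng.random((6, 7)) < 0.4).astype(float)
        values[0, 0] = 1.0
        A = AssociationMatrix(values, [f"d{i}" for i in range(6)], [f"m{j}" for j in range(7)])
        profiles = values if space == "disease" else values.T
        want = oracles.gip_matrix(list(profiles))
        got = gip_similarity(A, space).values
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestIntegrateSimilarity:
    @staticmethod
    def pair(rng, n):
        ids = [f"x{i}" for i in range(n)]
        primary = SimilarityMatrix(
            oracles.random_symmetric_similarity(rng, n), ids, "semantic"
        )
        gip = SimilarityMatrix(oracles.random_symmetric_similarity(rng, n), ids, "gip")
        return primary, gip

    def test_all_positive_primary_wins(self):
        rng = np.random.default_rng(1)
        primary, gip = self.pair(rng, 5)
        out = integrate_similarity(primary, gip)
        np.testing.assert_array_equal(out.values, primary.values)

    def test_zero_entry_falls_back_to_gip(self):
        ids = ["a", "b"]
        primary = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ids, "semantic")
        gip = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ids, "gip")
        assert integrate_similarity(primary, gip).loc("a", "b") == 0.4

    def test_zero_row_uses_gip_row(self):
        rng = np.random.default_rng(2)
        primary, gip = self.pair(rng, 6)
        primary.values[3, :] = 0.0
        primary.values[:, 3] = 0.0
        primary.values[3, 3] = 1.0
        out = integrate_similarity(primary, gip)
        off = [i for i in range(6) if i != 3]
        np.testing.assert_array_equal(out.values[3, off], gip.values[3, off])
        assert out.values[3, 3] == 1.0

    def test_explicit_mask_overrides_positivity(self):
        rng = np.random.default_rng(3)
        primary, gip = self.pair(rng, 4)
        out = integrate_similarity(primary, gip, mask=np.zeros((4, 4), dtype=bool))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(out.values[off], gip.values[off])

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        primary, _ = self.pair(rng, 3)
        gip = SimilarityMatrix(np.eye(3), ["q0", "q1", "q2"], "gip")
        with pytest.raises(AlignmentError):
            integrate_similarity(primary, gip)


@pytest.mark.parametrize("seed", range(5))
def test_all_similarity_layers_are_valid_similarity_matrices(seed, small_fixture):
    """Symmetry, unit diagonal and [0,1] range hold on generated studies."""
    fx = small_fixture
    for sim in (fx.DSS, fx.MFS, fx.ISD, fx.ISM):
        v = sim.values
        assert np.max(np.abs(v - v.T)) <= 1e-12
        assert np.all(np.diag(v) == 1.0)
        assert v.min() >= 0.0 and v.max() <= 1.0
    rng = np.random.default_rng(seed)
    values = (rng.random((8, 9)) < 0.3).astype(float)
    values[0, 0] = 1.0
    A = AssociationMatrix(values, [f"d{i}" for i in range(8)], [f"m{j}" for j in range(9)])
    for space in ("disease", "mirna"):
        g = gip_similarity(A, space).values
        assert np.all(g > 0.0) and np.all(g <= 1.0)
        assert np.max(np.abs(g - g.T)) <= 1e-12
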