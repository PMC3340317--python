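import numpy as np
import pytest
import scipy.sparse as sp

from semprop.fixtures import make_linear_chain, make_random_model, make_reaction_pair
from semprop.model_io import Annotation, ModelElement, NetworkModel, Reference
from semprop.propagation import (
    PropagationWeights,
    build_pair_graph,
    build_propagation_matrix,
    choose_lambda,
    feature_propagate,
    similarity_propagate,
    spectral_radius,
)
from semprop.semantic_features import build_concept_space, featurize

from tests.conftest import neumann_series


def single_reaction_model(cofactor=False):
    """a -> x -> b; optionally b is annotated as ATP (a default cofactor)."""
    m = NetworkModel("m")
    m.add_element(ModelElement("a", "species", {Annotation("demo", "A")}))
    b_ann = {Annotation("chebi", "CHEBI:15422")} if cofactor else {Annotation("demo", "B")}
    m.add_element(ModelElement("b", "species", b_ann))
    m.add_element(ModelElement("x", "reaction"))
    m.add_reference(Reference("x", "a", "reactant"))
    m.add_reference(Reference("x", "b", "product"))
    return m


class TestBuildPropagationMatrix:
    def test_one_reaction_two_species_gives_four_entries(self):
        R = build_propagation_matrix(single_reaction_model(), PropagationWeights(0.5, 0.5))
        dense = R.matrix.toarray()
        assert R.matrix.nnz == 4
        assert set(np.unique(dense[dense > 0])) == {0.5}
        idx = {eid: i for i, eid in enumerate(R.element_ids)}
        assert dense[idx["x"], idx["a"]] == 0.5  # alpha: species -> reaction
        assert dense[idx["a"], idx["x"]] == 0.5  # beta: reaction -> species

    def test_alpha_and_beta_are_directional(self):
        R = build_propagation_matrix(
            single_reaction_model(), PropagationWeights(alpha=0.25, beta=0.75)
        )
        idx = {eid: i for i, eid in enumerate(R.element_ids)}
        dense = R.matrix.toarray()
        assert dense[idx["x"], idx["a"]] == 0.25
        assert dense[idx["a"], idx["x"]] == 0.75

    def test_cofactor_species_row_and_column_are_zero(self):
        R = build_propagation_matrix(single_reaction_model(cofactor=True))
        idx = {eid: i for i, eid in enumerate(R.element_ids)}
        dense = R.matrix.toarray()
        assert not dense[idx["b"], :].any()
        assert not dense[:, idx["b"]].any()
        assert dense[idx["x"], idx["a"]] > 0  # non-cofactor edge survives

    def test_model_without_references_gives_zero_matrix(self):
        m = NetworkModel("m")
        m.add_element(ModelElement("s", "species"))
        assert build_propagation_matrix(m).matrix.nnz == 0

    def test_compartment_edges_default_to_zero_weight_but_are_configurable(self):
        chain = make_linear_chain(3)
        R0 = build_propagation_matrix(chain)
        Rc = build_propagation_matrix(chain, PropagationWeights(compartment_weight=0.1))
        idx = {eid: i for i, eid in enumerate(R0.element_ids)}
        assert R0.matrix.toarray()[idx["s1"], idx["c"]] == 0.0
        assert Rc.matrix.toarray()[idx["s1"], idx["c"]] == 0.1


class TestChooseLambda:
    def test_zero_matrix_gives_lambda_one_by_convention(self):
        assert choose_lambda(sp.csr_matrix((3, 3))) == 1.0

    def test_known_spectral_radius(self):
        R = sp.csr_matrix(np.diag([2.0, 1.0, 0.5]))
        assert choose_lambda(R, 0.5) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_lambda_times_radius_equals_fraction_against_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = sp.random(30, 30, density=0.1, random_state=rng, data_rvs=rng.random)
        lam = choose_lambda(A, 0.5)
        r_oracle = np.max(np.abs(np.linalg.eigvals(A.toarray())))
        assert lam * r_oracle == pytest.approx(0.5, abs=1e-8)

    def test_large_sparse_path_agrees_with_dense(self):
        rng = np.random.default_rng(1)
        A = sp.random(80, 80, density=0.05, random_state=rng, data_rvs=rng.random)
        r_dense = np.max(np.abs(np.linalg.eigvals(A.toarray())))
        assert spectral_radius(A) == pytest.approx(r_dense, rel=1e-6)


def random_instance(seed, n_species=12, n_reactions=9):
    model = make_random_model(n_species, n_reactions, 0.8, 15, seed=seed)
    space = build_concept_space([model])
    V = featurize(model, space)
    R = build_propagation_matrix(model)
    return model, space, V, R


class TestFeaturePropagate:
    def test_zero_transfer_matrix_keeps_direct_features(self):
        model, space, V, R = random_instance(0)
        R0 = build_propagation_matrix(
            model, PropagationWeights(alpha=0.0, beta=0.0, modifier_weight=0.0)
        )
        W = feature_propagate(V, R0)
        assert np.allclose(W.values, V.values)

    def test_isolated_elements_keep_their_direct_vectors(self):
        model, space, V, R = random_instance(3)
        W = feature_propagate(V, R)
        incoming = np.asarray(R.matrix.sum(axis=1)).ravel()
        for i in np.nonzero(incoming == 0)[0]:
            assert np.allclose(W.values[i], V.values[i])

    @pytest.mark.parametrize("seed", range(5))
    def test_solve_agrees_with_truncated_series(self, seed):
        _, _, V, R = random_instance(seed)
        lam = choose_lambda(R.matrix, 0.5)
        W = feature_propagate(V, R, lam)
        series = neumann_series(R.matrix, V.values, lam, 100)
        assert np.max(np.abs(W.values - series)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_residual_below_tolerance(self, seed):
        _, _, V, R = random_instance(seed)
        lam = choose_lambda(R.matrix, 0.5)
        W = feature_propagate(V, R, lam)
        residual = W.values - (V.values + lam * (R.matrix @ W.values))
        assert np.max(np.abs(residual)) < 1e-9

    def test_inferred_features_are_non_negative(self):
        for seed in range(5):
            _, _, V, R = random_instance(seed)
            W = feature_propagate(V, R)
            assert W.values.min() >= -1e-12

    def test_divergent_lambda_raises(self):
        _, _, V, R = random_instance(0)
        r = spectral_radius(R.matrix)
        with pytest.raises(ValueError, match="diverges"):
            feature_propagate(V, R, lam=1.5 / r)

    def test_one_directional_propagation_on_a_dag_terminates(self):
        # chain with beta = 0 propagates only species -> reaction -> nothing:
        # the series term beyond the propagation depth is identically zero
        chain = make_linear_chain(6, annotate_endpoints_only=False)
        R = build_propagation_matrix(chain, PropagationWeights(alpha=0.5, beta=0.0))
        V = featurize(chain, build_concept_space([chain]))
        dense = R.matrix.toarray()
        term = V.values.copy()
        depth = 1  # reactions sit one step from species; no further edges
        for _ in range(depth + 1):
            term = dense @ term
        assert not term.any()
        # and the exact solve equals the short series
        W = feature_propagate(V, R, lam=1.0, max_steps=depth)
        full = feature_propagate(V, R, lam=1.0)
        assert np.allclose(W.values, full.values)


class TestPairGraph:
    def test_reaction_pair_graph_nodes_and_edge_weights(self):
        m, n = make_reaction_pair()
        alpha = 0.5
        Rm = build_propagation_matrix(m, PropagationWeights(alpha, alpha))
        Rn = build_propagation_matrix(n, PropagationWeights(alpha, alpha))
        Q = build_pair_graph(Rm, Rn, m.element_types(), n.element_types())
        # 2x2 species pairs + 1 reaction pair (+ compartment pair) minus none
        pair_types = {
            (m.elements[x].element_type) for x, _ in Q.pair_ids
        }
        assert pair_types == {"species", "reaction", "compartment"}
        species_pairs = [p for p in Q.pair_ids if m.elements[p[0]].element_type == "species"]
        assert len(species_pairs) == 4
        # edges into (x, y) from (a, p) and (b, q) with weight alpha^2
        index = Q.index()
        dense = Q.matrix.toarray()
        row = index[("x", "y")]
        assert dense[row, index[("a", "p")]] == pytest.approx(alpha**2)
        assert dense[row, index[("b", "q")]] == pytest.approx(alpha**2)
        assert dense[row, index[("a", "q")]] == pytest.approx(alpha**2)
        assert dense[row, index[("b", "p")]] == pytest.approx(alpha**2)

    def test_q_entries_are_products_of_the_per_model_entries(self):
        a = make_random_model(6, 4, 1.0, 10, seed=2, model_id="A")
        b = make_random_model(5, 4, 1.0, 10, seed=5, model_id="B")
        Ra, Rb = build_propagation_matrix(a), build_propagation_matrix(b)
        Q = build_pair_graph(Ra, Rb, a.element_types(), b.element_types())
        da, db = Ra.matrix.toarray(), Rb.matrix.toarray()
        ia = {eid: i for i, eid in enumerate(Ra.element_ids)}
        ib = {eid: i for i, eid in enumerate(Rb.element_ids)}
        dense = Q.matrix.toarray()
        for r, (x, y) in enumerate(Q.pair_ids):
            for c, (u, p) in enumerate(Q.pair_ids):
                assert dense[r, c] == pytest.approx(da[ia[x], ia[u]] * db[ib[y], ib[p]])

    def test_zero_factor_matrix_gives_zero_pair_graph(self):
        m, n = make_reaction_pair()
        Rm = build_propagation_matrix(m, PropagationWeights(alpha=0.0, beta=0.0))
        Rn = build_propagation_matrix(n)
        Q = build_pair_graph(Rm, Rn, m.element_types(), n.element_types())
        assert Q.matrix.nnz == 0

    def test_cross_type_pairs_are_excluded_entirely(self):
        a = make_random_model(6, 4, 1.0, 10, seed=2, model_id="A")
        b = make_random_model(5, 4, 1.0, 10, seed=5, model_id="B")
        Q = build_pair_graph(
            build_propagation_matrix(a),
            build_propagation_matrix(b),
            a.element_types(),
            b.element_types(),
        )
        ta, tb = a.element_types(), b.element_types()
        assert all(ta[x] == tb[y] for x, y in Q.pair_ids)

    def test_pair_graph_dimension_is_product_scale(self):
        # SP cost grows with |M|x|N| pair nodes, FP only with |M| and |N|
        a = make_random_model(8, 5, 1.0, 10, seed=1, model_id="A")
        b = make_random_model(7, 5, 1.0, 10, seed=2, model_id="B")
        Ra, Rb = build_propagation_matrix(a), build_propagation_matrix(b)
        Q = build_pair_graph(Ra, Rb, a.element_types(), b.element_types())
        expected = sum(
            len(a.elements_of_type(t)) * len(b.elements_of_type(t))
            for t in ("species", "reaction", "compartment")
        )
        assert Q.n == expected
        assert Q.n > max(Ra.n, Rb.n)


class TestSimilarityPropagate:
    @staticmethod
    def sp_instance(seed):
        a = make_random_model(7, 5, 0.8, 12, seed=seed, model_id="A")
        b = make_random_model(7, 5, 0.8, 12, seed=seed + 1000, model_id="B")
        Q = build_pair_graph(
            build_propagation_matrix(a),
            build_propagation_matrix(b),
            a.element_types(),
            b.element_types(),
        )
        rng = np.random.default_rng(seed)
        sigma = rng.random(Q.n)
        return Q, sigma

    def test_zero_pair_graph_returns_sigma(self):
        Q, sigma = self.sp_instance(0)
        Q.matrix = sp.csr_matrix(Q.matrix.shape)
        assert np.allclose(similarity_propagate(sigma, Q), sigma)

    @pytest.mark.parametrize("seed", range(5))
    def test_solve_agrees_with_truncated_series(self, seed):
        Q, sigma = self.sp_instance(seed)
        lam = choose_lambda(Q.matrix, 0.5)
        psi = similarity_propagate(sigma, Q, lam)
        series = neumann_series(Q.matrix, sigma, lam, 100)
        assert np.max(np.abs(psi - series)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_stationary_point_of_the_diffusion_process(self, seed):
        # psi solves d/dt psi = sigma + lam*Q psi - psi = 0 at stationarity
        Q, sigma = self.sp_instance(seed)
        lam = choose_lambda(Q.matrix, 0.5)
        psi = similarity_propagate(sigma, Q, lam)
        residual = sigma + lam * (Q.matrix @ psi) - psi
        assert np.max(np.abs(residual)) < 1e-9

    def test_inferred_similarities_are_non_negative(self):
        for seed in range(5):
            Q, sigma = self.sp_instance(seed)
            assert similarity_propagate(sigma, Q).min() >= -1e-12

    def test_negative_sigma_rejected(self):
        Q, sigma = self.sp_instance(0)
        with pytest.raises(ValueError, match="non-negative"):
            similarity_propagate(-sigma, Q)
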