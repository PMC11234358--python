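import numpy as np
import pytest

from dtafusion import (
    DrugRecord,
    FeaturizationError,
    GINConfig,
    Invariant3DConfig,
    MolecularGraph,
    embed_1d,
    embed_3d,
    generate_conformer,
    gin_embed,
    init_3d_params,
    init_gin_params,
    load_embeddings,
    smiles_to_graph,
    tokenize_substructures,
    train_skipgram,
)
from dtafusion._util import EmbeddingSet


def _permuted(graph, perm):
    return MolecularGraph(
        graph.n_atoms,
        graph.A[np.ix_(perm, perm)],
        graph.X[perm],
        graph.E[np.ix_(perm, perm)],
        None if graph.R is None else graph.R[perm],
    )


class TestSmilesToGraph:
    def test_ethane(self):
        g = smiles_to_graph(DrugRecord("d", "CC"))
        assert g.n_atoms == 2
        assert g.A.sum() == 2  # one undirected edge
        assert np.array_equal(g.A, g.A.T)

    def test_cyclopropane_ring(self):
        g = smiles_to_graph(DrugRecord("d", "C1CC1"))
        assert g.n_atoms == 3
        assert g.A.sum() // 2 == 3

    def test_invalid_smiles_names_drug(self):
        with pytest.raises(FeaturizationError, match="baddrug"):
            smiles_to_graph(DrugRecord("baddrug", "C("))

    def test_bond_attributes_only_on_edges(self):
        g = smiles_to_graph(DrugRecord("d", "C=CC#N"))
        assert not np.any((g.E.sum(axis=2) > 0) & (g.A == 0))
        # double and triple bond channels populated
        assert g.E[..., 1].sum() > 0 and g.E[..., 2].sum() > 0


class TestTokenizer:
    def test_deterministic(self):
        d = DrugRecord("d", "OC1CCCCC1")
        assert tokenize_substructures(d) == tokenize_substructures(d)

    def test_ethane_radius0_two_identical_tokens(self):
        toks = tokenize_substructures(DrugRecord("d", "CC"), radius=0)
        assert len(toks) == 2
        assert toks[0] == toks[1]

    def test_distinct_environments_distinct_tokens(self):
        toks = tokenize_substructures(DrugRecord("d", "CO"), radius=1)
        assert len(set(toks)) > 1

    def test_invalid_smiles_raises(self):
        with pytest.raises(FeaturizationError):
            tokenize_substructures(DrugRecord("d", "xyz("))


class TestEmbed1D:
    @pytest.fixture(scope="class")
    def model(self):
        drugs = [DrugRecord(f"d{i}", s) for i, s in enumerate(["CC", "CCO", "CCC", "CO", "C1CC1"])]
        corpus = [tokenize_substructures(d) for d in drugs]
        return train_skipgram(corpus, width=16, window=3, epochs=3, seed=5)

    def test_single_token_identity(self, model):
        tok = next(iter(model.vocabulary))
        assert np.allclose(model.embed_tokens([tok]), model.vector(tok))

    def test_sum_additivity(self, model):
        toks = list(model.vocabulary)[:3]
        double = model.embed_tokens(toks + toks)
        assert np.allclose(double, 2 * model.embed_tokens(toks))

    def test_all_unknown_gives_zero_vector(self, model):
        assert np.allclose(model.embed_tokens(["nope", "nada"]), 0.0)

    def test_embed_drug(self, model):
        vec = embed_1d(DrugRecord("d", "CCO"), model)
        assert vec.shape == (16,)
        assert np.isfinite(vec).all()


class TestGIN:
    def test_permutation_invariance_many_random_graphs(self, rng):
        cfg = GINConfig(n_layers=2, hidden_width=16, output_width=24)
        params = init_gin_params(cfg, n_features=5, seed=3)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            A = (rng.random((n, n)) < 0.4).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            X = rng.normal(size=(n, 5))
            g = MolecularGraph(n, A, X, np.zeros((n, n, 4)))
            perm = rng.permutation(n)
            e1 = gin_embed(g, cfg, params)
            e2 = gin_embed(_permuted(g, perm), cfg, params)
            assert np.allclose(e1, e2, atol=1e-8)

    def test_single_node_identity_initialized(self):
        # eps=0, one layer whose MLP is identity: embedding = out-MLP(x)
        cfg = GINConfig(n_layers=1, hidden_width=3, mlp_depth=1, output_width=3)
        params = init_gin_params(cfg, n_features=3, seed=0)
        params["layers"][0] = [(np.eye(3), np.zeros(3))]
        params["out"] = [(np.eye(3), np.zeros(3))]
        x = np.array([[0.5, 1.0, 2.0]])
        g = MolecularGraph(1, np.zeros((1, 1), int), x, np.zeros((1, 1, 4)))
        assert np.allclose(gin_embed(g, cfg, params), x[0])

    def test_two_node_path_hand_computed(self):
        # width-2 features, one layer, identity MLPs, eps=0.5:
        # node state = (1+eps) x_i + x_j, readout = sum
        cfg = GINConfig(n_layers=1, hidden_width=2, mlp_depth=1, output_width=2, epsilon=0.5)
        params = init_gin_params(cfg, n_features=2, seed=0)
        params["layers"][0] = [(np.eye(2), np.zeros(2))]
        params["out"] = [(np.eye(2), np.zeros(2))]
        x = np.array([[1.0, 2.0], [3.0, 5.0]])
        A = np.array([[0, 1], [1, 0]])
        g = MolecularGraph(2, A, x, np.zeros((2, 2, 4)))
        expected = (1.5 * x[0] + x[1]) + (1.5 * x[1] + x[0])
        assert np.allclose(gin_embed(g, cfg, params), expected)

    def test_output_width_default(self):
        g = smiles_to_graph(DrugRecord("d", "c1ccccc1"))
        cfg = GINConfig()
        out = gin_embed(g, cfg, init_gin_params(cfg, seed=1))
        assert out.shape == (300,)

    def test_feature_width_mismatch(self):
        cfg = GINConfig()
        params = init_gin_params(cfg, n_features=4, seed=0)
        g = smiles_to_graph(DrugRecord("d", "CC"))
        with pytest.raises(ValueError, match="atom features"):
            gin_embed(g, cfg, params)


class TestInvariant3D:
    @pytest.fixture(scope="class")
    def setup(self):
        g = generate_conformer(smiles_to_graph(DrugRecord("d", "OC1CCCCC1")), seed=4)
        cfg = Invariant3DConfig(n_layers=2, hidden_width=16, output_width=32)
        params = init_3d_params(cfg, seed=4)
        return g, cfg, params

    def test_rigid_motion_invariance_randomized(self, setup, rng):
        from scipy.stats import ortho_group

        g, cfg, params = setup
        base = embed_3d(g, cfg, params)
        for i in range(100):
            Q = ortho_group.rvs(3, random_state=int(rng.integers(1 << 30)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1  # proper rotation only
            t = rng.normal(scale=10, size=3)
            moved = MolecularGraph(g.n_atoms, g.A, g.X, g.E, g.R @ Q.T + t)
            assert np.allclose(embed_3d(moved, cfg, params), base, atol=1e-6)

    def test_geometry_sensitivity(self, setup):
        g, cfg, params = setup
        stretched = MolecularGraph(g.n_atoms, g.A, g.X, g.E, g.R * 1.3)
        assert not np.allclose(embed_3d(stretched, cfg, params), embed_3d(g, cfg, params))

    def test_missing_coordinates_instructive_error(self):
        g = smiles_to_graph(DrugRecord("d", "CC"))
        cfg = Invariant3DConfig()
        with pytest.raises(FeaturizationError, match="generate_conformer"):
            embed_3d(g, cfg, init_3d_params(cfg, seed=0))

    def test_output_width_default(self):
        g = generate_conformer(smiles_to_graph(DrugRecord("d", "CCO")), seed=0)
        cfg = Invariant3DConfig()
        assert embed_3d(g, cfg, init_3d_params(cfg, seed=0)).shape == (512,)


class TestConformers:
    def test_ethane_sane(self):
        g = generate_conformer(smiles_to_graph(DrugRecord("d", "CC")), seed=1)
        assert g.R.shape == (2, 3)
        assert np.linalg.norm(g.R[0] - g.R[1]) > 0

    def test_seed_reproducible(self):
        base = smiles_to_graph(DrugRecord("d", "CCCO"))
        r1 = generate_conformer(base, seed=9).R
        r2 = generate_conformer(base, seed=9).R
        assert np.array_equal(r1, r2)

    def test_spring_fallback_positive_distances(self):
        # graph without a parser handle exercises the spring-layout path
        g = smiles_to_graph(DrugRecord("d", "C1CC1"))
        bare = MolecularGraph(g.n_atoms, g.A, g.X, g.E)
        out = generate_conformer(bare, seed=2)
        d01 = np.linalg.norm(out.R[0] - out.R[1])
        d02 = np.linalg.norm(out.R[0] - out.R[2])
        d12 = np.linalg.norm(out.R[1] - out.R[2])
        assert all(np.isfinite([d01, d02, d12])) and min(d01, d02, d12) > 0


class TestEmbeddingFiles:
    def test_round_trip_full_precision(self, tmp_path, rng):
        eset = EmbeddingSet("drug", "2D", 4)
        for i in range(3):
            eset.add(f"d{i}", rng.normal(size=4))
        p = tmp_path / "emb.tsv"
        eset.save(p)
        loaded = load_embeddings(p, "drug", "2D")
        assert loaded.width == 4 and len(loaded) == 3
        for i in range(3):
            assert np.array_equal(loaded[f"d{i}"], eset[f"d{i}"])

    def test_ragged_row_cites_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("d1\t1.0\t2.0\t3.0\t4.0\nd2\t1.0\t2.0\t3.0\n")
        with pytest.raises(ValueError, match="line 2"):
            load_embeddings(p, "drug", "1D")

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("d1\t1.0\nd1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_embeddings(p, "drug", "1D")

    def test_missing_id_lookup_names_id(self):
        eset = EmbeddingSet("protein", "3D", 2, {"p1": np.ones(2)})
        with pytest.raises(KeyError, match="p9"):
            eset["p9"]
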