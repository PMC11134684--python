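import numpy as np
import pandas as pd
import pytest

from pearlst.comm import (
    build_multilayer_network,
    gene_importance_perturbation,
    link_lr_to_embeddings,
    lr_score,
    mean_nn_distance,
    read_lr_pairs,
    region_interaction_strength,
)
from pearlst.warga import CriticParams, EncoderParams, TrainConfig, WargaModel


def crafted_model(n_genes, latent=3, driver_genes=(0, 1, 2), driver_dim=0):
    """Encoder whose first latent dimension reads only the driver genes."""
    W1 = np.zeros((n_genes, latent))
    for g in driver_genes:
        W1[g, driver_dim] = 1.0
    W2 = np.eye(latent)
    enc = EncoderParams(W1=W1, W2=W2, final_activation="linear")
    crit = CriticParams(W3=np.zeros((2, latent)), b1=np.zeros(2),
                        W4=np.zeros((2, 2)), b2=np.zeros(2),
                        W5=np.zeros(2), b3=0.0)
    return WargaModel(encoder=enc, critic=crit, config=TrainConfig(epochs=0))


class TestReadLrPairs:
    def test_with_and_without_header(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("ligand\treceptor\nWNT5A\tFZD1\nTGFB1\tTGFBR2\n")
        assert read_lr_pairs(str(p)) == [("WNT5A", "FZD1"), ("TGFB1", "TGFBR2")]
        p.write_text("WNT5A\tFZD1\n")
        assert read_lr_pairs(str(p)) == [("WNT5A", "FZD1")]

    def test_single_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("WNT5A\n")
        with pytest.raises(ValueError):
            read_lr_pairs(str(p))


class TestLrScore:
    def test_hand_value_single_sender_receiver(self):
        # L=3 at distance 1 with unit length scale, R=2: score = 2*3*e^-1
        X = np.array([[3.0, 0.0], [0.0, 2.0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        s = lr_score(X, coords, [True, False], [False, True],
                     [("L", "R")], ["L", "R"], length_scale=1.0)
        assert s.loc[1, "L->R"] == pytest.approx(6.0 * np.exp(-1.0))

    def test_zero_receptor_zero_score(self):
        X = np.array([[3.0, 0.0], [0.0, 0.0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        s = lr_score(X, coords, [True, False], [False, True],
                     [("L", "R")], ["L", "R"], length_scale=1.0)
        assert s.loc[1, "L->R"] == 0.0

    def test_score_decays_with_distance(self):
        gene_ids = ["L", "R"]
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        scores = []
        for d in (0.5, 1.0, 2.0, 4.0):
            coords = np.array([[0.0, 0.0], [d, 0.0]])
            s = lr_score(X, coords, [True, False], [False, True],
                         [("L", "R")], gene_ids, length_scale=1.0)
            scores.append(s.loc[1, "L->R"])
        assert all(b < a for a, b in zip(scores, scores[1:]))

    def test_rigid_motion_invariance(self, rng):
        n = 20
        X = np.abs(rng.normal(size=(n, 3)))
        coords = rng.normal(size=(n, 2))
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        mask_s = np.arange(n) < 10
        a = lr_score(X, coords, mask_s, ~mask_s, [("g0", "g1")],
                     ["g0", "g1", "g2"], length_scale=1.0)
        b = lr_score(X, coords @ R.T + 7.0, mask_s, ~mask_s, [("g0", "g1")],
                     ["g0", "g1", "g2"], length_scale=1.0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_missing_genes_skipped_empty_senders_rejected(self, rng):
        X = np.abs(rng.normal(size=(4, 2)))
        coords = rng.normal(size=(4, 2))
        s = lr_score(X, coords, [True, True, False, False],
                     [False, False, True, True],
                     [("nope", "R"), ("L", "R")], ["L", "R"])
        assert list(s.columns) == ["L->R"]
        with pytest.raises(ValueError):
            lr_score(X, coords, [False] * 4, [True] * 4, [("L", "R")], ["L", "R"])


class TestRegionInteractionStrength:
    def test_matches_brute_force(self, rng):
        n = 12
        X = np.abs(rng.normal(size=(n, 2)))
        coords = rng.normal(size=(n, 2))
        labels = np.array([0] * 6 + [1] * 6)
        pairs = [("L", "R")]
        M = region_interaction_strength(X, coords, labels, pairs, ["L", "R"],
                                        length_scale=1.0)
        # brute force for sender region 0 -> receiver region 1
        senders = np.flatnonzero(labels == 0)
        receivers = np.flatnonzero(labels == 1)
        vals = []
        for j in receivers:
            tot = 0.0
            for s in senders:
                d = np.linalg.norm(coords[s] - coords[j])
                tot += X[s, 0] * np.exp(-d)
            vals.append(X[j, 1] * tot)
        assert M.loc[0, 1] == pytest.approx(np.mean(vals))

    def test_ligand_scaling_is_linear(self, rng):
        n = 10
        X = np.abs(rng.normal(size=(n, 2)))
        coords = rng.normal(size=(n, 2))
        labels = np.array([0] * 5 + [1] * 5)
        M1 = region_interaction_strength(X, coords, labels, [("L", "R")],
                                         ["L", "R"], length_scale=1.0)
        X2 = X.copy()
        X2[:, 0] *= 3.0
        M2 = region_interaction_strength(X2, coords, labels, [("L", "R")],
                                         ["L", "R"], length_scale=1.0)
        np.testing.assert_allclose(M2.to_numpy(), 3.0 * M1.to_numpy())


class TestLinkLrToEmbeddings:
    def test_recovers_the_driving_pair(self, rng):
        n = 80
        F = np.abs(rng.normal(size=(n, 3)))
        lr_scores = pd.DataFrame(F, columns=["a->r1", "b->r2", "c->r3"])
        Z = np.column_stack([2.0 * F[:, 1] + 0.01 * rng.normal(size=n),
                             rng.normal(size=n)])
        imp = link_lr_to_embeddings(lr_scores, Z, seed=0, n_trees=100)
        assert imp["dim_0"].idxmax() == "b->r2"

    def test_constant_feature_scores_zero(self, rng):
        n = 60
        F = np.column_stack([np.full(n, 2.0), np.abs(rng.normal(size=n))])
        lr_scores = pd.DataFrame(F, columns=["a->r", "b->r"])
        Z = np.column_stack([F[:, 1] + 0.01 * rng.normal(size=n)])
        imp = link_lr_to_embeddings(lr_scores, Z, seed=0, n_trees=100)
        # permuting a constant column cannot change predictions
        assert imp.loc["a->r", "dim_0"] == 0.0
        assert imp.loc["b->r", "dim_0"] > 0.0

    def test_deterministic_and_small_n_rejected(self, rng):
        F = pd.DataFrame(np.abs(rng.normal(size=(30, 2))), columns=["a->r", "b->r"])
        Z = rng.normal(size=(30, 2))
        a = link_lr_to_embeddings(F, Z, seed=4, n_trees=50)
        b = link_lr_to_embeddings(F, Z, seed=4, n_trees=50)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            link_lr_to_embeddings(F.iloc[:5], Z[:5])


class TestGeneImportancePerturbation:
    def test_driver_genes_dominate_their_dimension(self, rng):
        n, g = 30, 8
        model = crafted_model(g, latent=3, driver_genes=(0, 1, 2))
        X = rng.normal(size=(n, g))
        imp = gene_importance_perturbation(model, X, np.eye(n),
                                           [f"g{i}" for i in range(g)], seed=1)
        top3 = set(imp["dim_0"].sort_values(ascending=False).head(3).index)
        assert top3 == {"g0", "g1", "g2"}

    def test_ignored_gene_scores_exactly_zero(self, rng):
        model = crafted_model(4, latent=2, driver_genes=(0,))
        X = rng.normal(size=(20, 4))
        imp = gene_importance_perturbation(model, X, np.eye(20),
                                           ["g0", "g1", "g2", "g3"], seed=0)
        assert imp.loc["g3", "dim_0"] == 0.0
        assert imp.loc["g3", "dim_1"] == 0.0

    def test_zero_noise_scale_all_zero(self, rng):
        model = crafted_model(3, latent=2)
        X = rng.normal(size=(15, 3))
        imp = gene_importance_perturbation(model, X, np.eye(15),
                                           ["a", "b", "c"], noise_scale=0.0)
        assert (imp.to_numpy() == 0.0).all()

    def test_deterministic_under_seed(self, rng):
        model = crafted_model(5, latent=2)
        X = rng.normal(size=(12, 5))
        ids = [f"g{i}" for i in range(5)]
        a = gene_importance_perturbation(model, X, np.eye(12), ids, seed=7)
        b = gene_importance_perturbation(model, X, np.eye(12), ids, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_untrained_model_rejected(self, rng):
        model = crafted_model(3)
        model.encoder = None
        with pytest.raises(ValueError):
            gene_importance_perturbation(model, rng.normal(size=(5, 3)),
                                         np.eye(5), ["a", "b", "c"])


class TestBuildMultilayerNetwork:
    def make_tables(self):
        lr_imp = pd.DataFrame([[0.8, 0.0], [0.0, 0.0]],
                              index=["L->R", "L2->R2"],
                              columns=["dim_0", "dim_1"])
        gene_imp = pd.DataFrame([[0.5, 0.0], [0.0, 0.3], [0.0, 0.0]],
                                index=["gA", "gB", "gC"],
                                columns=["dim_0", "dim_1"])
        return lr_imp, gene_imp

    def test_minimal_path_assembled(self):
        lr_imp, gene_imp = self.make_tables()
        net = build_multilayer_network(lr_imp, gene_imp)
        layers = {n["id"]: n["layer"] for n in net.nodes}
        assert layers == {"L": "ligand", "R": "receptor",
                          "dim_0": "embedding", "gA": "target_gene"}
        kinds = sorted(e["kind"] for e in net.edges)
        assert kinds == ["embedding-gene", "ligand-receptor",
                         "receptor-embedding"]

    def test_unused_dimension_excluded(self):
        lr_imp, gene_imp = self.make_tables()
        net = build_multilayer_network(lr_imp, gene_imp)
        ids = {n["id"] for n in net.nodes}
        assert "dim_1" not in ids and "gB" not in ids

    def test_lr_threshold_prunes_signaling_layers(self):
        lr_imp, gene_imp = self.make_tables()
        net = build_multilayer_network(lr_imp, gene_imp, lr_threshold=0.9)
        # no LR pair survives: only embedding-gene edges may remain
        assert all(e["kind"] == "embedding-gene" for e in net.edges)
        layers = {n["layer"] for n in net.nodes}
        assert "ligand" not in layers and "receptor" not in layers

    def test_gene_threshold_prunes_targets(self):
        lr_imp, gene_imp = self.make_tables()
        net = build_multilayer_network(lr_imp, gene_imp, gene_threshold=0.6)
        assert all(e["kind"] != "embedding-gene" for e in net.edges)

    def test_gene_top_q_limits_targets(self):
        lr_imp = pd.DataFrame([[1.0]], index=["L->R"], columns=["dim_0"])
        gene_imp = pd.DataFrame({"dim_0": [0.5, 0.4, 0.3, 0.2]},
                                index=["g0", "g1", "g2", "g3"])
        net = build_multilayer_network(lr_imp, gene_imp, gene_top_q=2)
        targets = {e["target"] for e in net.edges if e["kind"] == "embedding-gene"}
        assert targets == {"g0", "g1"}

    def test_json_and_graphml_round_trip(self, tmp_path):
        import json

        import networkx as nx

        lr_imp, gene_imp = self.make_tables()
        net = build_multilayer_network(lr_imp, gene_imp)
        jpath = tmp_path / "net.json"
        net.to_json(str(jpath))
        payload = json.loads(jpath.read_text())
        assert {n["id"] for n in payload["nodes"]} == {n["id"] for n in net.nodes}
        gpath = tmp_path / "net.graphml"
        net.to_graphml(str(gpath))
        g = nx.read_graphml(str(gpath))
        assert set(g.nodes) == {n["id"] for n in net.nodes}
        assert g.number_of_edges() == len(net.edges)


class TestEndToEndPlantedPathway:
    def test_planted_lr_pair_reaches_planted_targets(self, rng):
        """A crafted encoder plus mass-action scores yields the full
        ligand -> receptor -> dim -> driver-gene path."""
        n, g = 60, 6
        gene_ids = [f"g{i}" for i in range(g)]
        coords = rng.uniform(0, 10, size=(n, 2))
        X = np.abs(rng.normal(size=(n, g)))
        sender = np.arange(n) < n // 2
        X[sender, 4] += 3.0  # planted ligand g4 in senders
        X[~sender, 5] += 3.0  # planted receptor g5 in receivers
        model = crafted_model(g, latent=2, driver_genes=(0, 1))
        Z = model.embed(X, np.eye(n))
        scores = lr_score(X, coords, sender, ~sender,
                          [("g4", "g5"), ("g2", "g3")], gene_ids)
        # tie dim_0 to the planted pair for the regression step
        Zr = Z[np.flatnonzero(~sender)]
        Zr[:, 0] = scores["g4->g5"].to_numpy()
        imp_lr = link_lr_to_embeddings(scores, Zr, seed=0, n_trees=100)
        assert imp_lr["dim_0"].idxmax() == "g4->g5"
        imp_gene = gene_importance_perturbation(model, X, np.eye(n), gene_ids,
                                                seed=0)
        net = build_multilayer_network(imp_lr, imp_gene, gene_top_q=2)
        targets = {e["target"] for e in net.edges if e["kind"] == "embedding-gene"
                   and e["source"] == "dim_0"}
        assert targets == {"g0", "g1"}
        assert {"g4", "g5"} <= {node["id"] for node in net.nodes}


class TestMeanNnDistance:
    def test_unit_chain(self):
        coords = np.column_stack([np.arange(4, dtype=float), np.zeros(4)])
        assert mean_nn_distance(coords) == pytest.approx(1.0)
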