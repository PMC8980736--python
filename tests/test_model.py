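"""Surrogate architecture, training loop, splits and correlation."""

import numpy as np
import pytest

from helpers import brute_force_pearson
from surrodock import model as md
from surrodock import synthetic as sy


@pytest.fixture(scope="module")
def tiny_examples():
    examples, _ = sy.make_dataset(24, seed=5, n_iter=50)
    return examples


def small_config(**kw):
    base = dict(n_blocks=2, hidden=16, learning_rate=1e-3, epochs=3,
                batch_size=8, seed=9)
    base.update(kw)
    return md.ModelConfig(**base)


class TestBuildModel:
    def test_output_length_92(self, tiny_examples):
        net = md.build_model(small_config())
        ex = tiny_examples[0]
        out = md.predict(net, ex.pocket, ex.ligand)
        assert out.to_vector().shape == (92,)

    def test_same_seed_gives_identical_parameters(self):
        a = md.build_model(small_config())
        b = md.build_model(small_config())
        for la, lb in zip(a._all_layers(), b._all_layers()):
            np.testing.assert_array_equal(la.W, lb.W)
            np.testing.assert_array_equal(la.u, lb.u)

    def test_minimal_config_forward_finite(self):
        net = md.build_model(small_config(n_blocks=1, hidden=8))
        xp = np.zeros((1, 8000), dtype=np.float32)
        xl = np.zeros((1, 6732), dtype=np.float32)
        out = net.forward(xp, xl)
        assert out.shape == (1, 92) and np.isfinite(out).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            md.ModelConfig(n_blocks=0)
        with pytest.raises(ValueError):
            md.ModelConfig(dropout=1.0)


class TestParameterCount:
    @pytest.mark.parametrize("n,d", [(1, 8), (2, 16), (3, 12), (4, 64)])
    def test_formula_matches_enumeration(self, n, d):
        net = md.build_model(small_config(n_blocks=n, hidden=d))
        assert md.count_parameters(net) == md.parameter_count_formula(n, d)
        assert md.count_parameters(net, include_pk_head=True) == \
            md.parameter_count_formula(n, d, include_pk_head=True)

    def test_pk_head_adds_d_plus_1(self):
        n, d = 3, 32
        assert (md.parameter_count_formula(n, d, True)
                - md.parameter_count_formula(n, d)) == d + 1

    def test_strictly_increasing_in_depth_and_width(self):
        for n in range(1, 8):
            assert md.parameter_count_formula(n + 1, 64) > \
                md.parameter_count_formula(n, 64)
        for d in (16, 64, 256, 1024):
            assert md.parameter_count_formula(6, d + 1) > \
                md.parameter_count_formula(6, d)

    def test_spectral_norm_vectors_not_counted(self):
        net = md.build_model(small_config())
        total_with_aux = sum(
            layer.W.size + layer.b.size + layer.u.size + layer.v.size
            for layer in net._all_layers())
        assert md.count_parameters(net, include_pk_head=True) < total_with_aux


class TestPredict:
    def test_eval_mode_is_deterministic(self, tiny_examples):
        net = md.build_model(small_config())
        ex = tiny_examples[0]
        a = md.predict(net, ex.pocket, ex.ligand).to_vector()
        b = md.predict(net, ex.pocket, ex.ligand).to_vector()
        np.testing.assert_array_equal(a, b)

    def test_degenerate_all_padding_input_finite(self):
        from surrodock.ligand import LigandGraph, MAX_ATOMS
        from surrodock.pocket import PocketGrid
        net = md.build_model(small_config())
        grid = PocketGrid.empty((0, 0, 0))
        atom_types = np.zeros((MAX_ATOMS, 7), dtype=np.uint8)
        atom_types[:, 0] = 1
        adjacency = np.zeros((MAX_ATOMS, MAX_ATOMS, 5), dtype=np.uint8)
        adjacency[..., 0] = 1
        lig = LigandGraph(atom_types, adjacency, 0)
        out = md.predict(net, grid, lig)
        assert np.isfinite(out.to_vector()).all()

    def test_batch_of_copies_gives_identical_rows(self, tiny_examples):
        net = md.build_model(small_config())
        ex = tiny_examples[0]
        xp = np.repeat(ex.pocket.flatten()[None, :], 5, axis=0)
        xl = np.repeat(ex.ligand.flatten()[None, :], 5, axis=0)
        out = md.predict_batch(net, xp, xl)
        # rows agree to accumulation-order precision (BLAS blocks the
        # batch dimension, so bit-exact equality is not guaranteed)
        np.testing.assert_allclose(out, np.repeat(out[:1], 5, axis=0),
                                   rtol=0, atol=1e-5)

    def test_batch_matches_single_evaluation(self, tiny_examples):
        net = md.build_model(small_config())
        xp = np.stack([e.pocket.flatten() for e in tiny_examples[:4]])
        xl = np.stack([e.ligand.flatten() for e in tiny_examples[:4]])
        batched = md.predict_batch(net, xp, xl)
        singles = np.stack([
            md.predict(net, e.pocket, e.ligand).to_vector()
            for e in tiny_examples[:4]])
        np.testing.assert_allclose(batched, singles, rtol=0, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        net = md.build_model(small_config())
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 100), dtype=np.float32),
                        np.zeros((1, 6732), dtype=np.float32))


class TestTrain:
    def test_gradient_reaches_every_subnetwork(self, tiny_examples):
        net = md.build_model(small_config())
        before = {name: [layer.W.copy() for layer in layers]
                  for name, layers in net.subnetworks().items()}
        md.train(net, tiny_examples[:1],
                 small_config(epochs=1, batch_size=1, dropout=0.0))
        for name, layers in net.subnetworks().items():
            changed = any(not np.array_equal(w, layer.W)
                          for w, layer in zip(before[name], layers))
            assert changed, f"no parameter changed in {name} subnetwork"

    def test_constant_targets_are_learned(self, tiny_examples):
        # all targets identical: loss should fall steeply toward zero
        const = tiny_examples[0].targets
        examples = [md.TrainingExample(e.pocket, e.ligand, const)
                    for e in tiny_examples]
        net = md.build_model(small_config(epochs=150, dropout=0.0,
                                          learning_rate=3e-2))
        _, hist = md.train(net, examples)
        assert hist.train_loss.iloc[-1] < 0.01 * hist.train_loss.iloc[0]
        # loss decreases monotonically over the first epochs
        first = hist.train_loss.iloc[:5].to_numpy()
        assert (np.diff(first) < 0).all()

    def test_same_seed_identical_loss_history(self, tiny_examples):
        h = []
        for _ in range(2):
            net = md.build_model(small_config())
            _, hist = md.train(net, tiny_examples)
            h.append(hist.train_loss.to_numpy())
        np.testing.assert_array_equal(h[0], h[1])

    def test_default_learning_rate_is_1e_minus_6(self):
        assert md.ModelConfig().learning_rate == pytest.approx(1e-6)

    def test_early_stopping_restores_best_state(self, tiny_examples):
        cfg = small_config(epochs=30, patience=3)
        net = md.build_model(cfg)
        net, hist = md.train(net, tiny_examples[:16], cfg,
                             validation=tiny_examples[16:])
        assert "val_loss" in hist
        # restored parameters reproduce the best recorded validation loss
        xp = np.stack([e.pocket.flatten() for e in tiny_examples[16:]])
        xl = np.stack([e.ligand.flatten() for e in tiny_examples[16:]])
        y = np.stack([e.target_vector() for e in tiny_examples[16:]])
        pred = md.predict_batch(net, xp, xl)
        loss = float(np.mean(np.sum((pred - y) ** 2, axis=1)))
        assert loss == pytest.approx(hist.val_loss.min(), rel=1e-5)


class TestSplitDataset:
    def test_reference_70_30_arithmetic(self):
        items = list(range(3875))
        train, val = md.split_dataset(items, 0.7, seed=1)
        assert (len(train), len(val)) == (2712, 1163)

    def test_floor_rule_small(self):
        train, val = md.split_dataset(list(range(10)), 0.7, seed=0)
        assert (len(train), len(val)) == (7, 3)

    def test_partition_is_exact(self):
        items = list(range(101))
        train, val = md.split_dataset(items, 0.7, seed=3)
        assert sorted(train + val) == items

    def test_protein_disjoint_groups(self, tiny_examples):
        train, val = md.split_dataset(tiny_examples, 0.7, seed=2,
                                      protein_disjoint=True)
        train_ids = {e.protein_id for e in train}
        val_ids = {e.protein_id for e in val}
        assert train_ids and val_ids and not (train_ids & val_ids)
        assert len(train) + len(val) == len(tiny_examples)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            md.split_dataset(list(range(10)), 1.5)


class TestEvaluateCorrelation:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = md.evaluate_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert md.evaluate_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = md.evaluate_correlation(x, y)
        assert res.r == pytest.approx(brute_force_pearson(list(x), list(y)),
                                      abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            md.evaluate_correlation(np.ones(5), np.arange(5.0))


class TestModelResultsObjects:
    def test_fit_returns_results_with_summary(self, tiny_examples):
        results = md.DockingSurrogate(tiny_examples, small_config()).fit()
        text = results.summary()
        assert "trainable parameters" in text
        assert results.n_train == len(tiny_examples)
        assert len(results.history) == 3

    def test_checkpoint_roundtrip_bit_identical(self, tiny_examples,
                                                tmp_path):
        results = md.DockingSurrogate(tiny_examples, small_config()).fit()
        xp = np.stack([e.pocket.flatten() for e in tiny_examples[:3]])
        xl = np.stack([e.ligand.flatten() for e in tiny_examples[:3]])
        before = results.predict_batch(xp, xl)
        results.save(tmp_path / "ckpt")
        reloaded = md.SurrogateResults.load(tmp_path / "ckpt")
        after = reloaded.predict_batch(xp, xl)
        np.testing.assert_array_equal(before, after)
        assert reloaded.config == results.config
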