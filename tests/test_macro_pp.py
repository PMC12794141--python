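"""Mixture-of-experts model: gating, combination, training, checkpoints."""

import numpy as np
import pytest

from macroperm.autodiff import Parameter, Tensor
from macroperm.chemdata import Assay, Label, LabeledRecord, MoleculeRecord, canonicalize_and_key
from macroperm.macro_pp import (
    ConditionEncoding,
    MacroPPClassifier,
    MacroPPConfig,
    ModelCheckpoint,
    fit_classifier,
    fit_regressor,
    gate_weights,
    moe_combine,
)
from macroperm.nets import MPConfig

FAST = MacroPPConfig(mp=MPConfig(rounds=1, hidden_dim=8), expert_hidden=8,
                     max_epochs=3, patience=3)


class TestGateWeights:
    def test_equal_logits_uniform(self):
        g = gate_weights(Tensor(np.zeros((2, 4)))).data
        assert np.allclose(g, 0.25)

    def test_saturated_logit_wins(self):
        g = gate_weights(Tensor(np.array([[1000.0, 0.0, 0.0]]))).data
        assert g[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_two_logit_closed_form(self):
        g = gate_weights(Tensor(np.array([[1.0, 2.0]]))).data
        assert g[0, 0] == pytest.approx(np.e / (np.e + np.e**2), rel=1e-6)
        assert g[0].tolist() == pytest.approx([0.2689, 0.7311], abs=1e-4)

    def test_simplex_for_any_input(self):
        rng = np.random.default_rng(0)
        g = gate_weights(Tensor(rng.normal(scale=50, size=(20, 5)))).data
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert (g > 0).all()


class TestMoeCombine:
    def test_single_expert_identity(self):
        e = Tensor(np.array([[3.0, -2.0]]))
        out = moe_combine([e], Tensor(np.array([[1.0]])))
        assert out.data.tolist() == [[3.0, -2.0]]

    def test_half_half_mixture(self):
        e1 = Tensor(np.array([[2.0, 0.0]]))
        e2 = Tensor(np.array([[0.0, 2.0]]))
        out = moe_combine([e1, e2], Tensor(np.array([[0.5, 0.5]])))
        assert out.data.tolist() == [[1.0, 1.0]]

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        experts = [Tensor(rng.normal(size=(4, 3))) for _ in range(5)]
        g = rng.dirichlet(np.ones(5), size=4)
        out = moe_combine(experts, Tensor(g)).data
        expected = np.zeros((4, 3))
        for b in range(4):
            for i in range(5):
                expected[b] += g[b, i] * experts[i].data[b]
        assert np.abs(out - expected).max() < 1e-10

    def test_linear_in_expert_outputs(self):
        rng = np.random.default_rng(2)
        experts = [Tensor(rng.normal(size=(3, 2))) for _ in range(3)]
        scaled = [Tensor(4.0 * e.data) for e in experts]
        g = Tensor(rng.dirichlet(np.ones(3), size=3))
        assert np.allclose(moe_combine(scaled, g).data, 4.0 * moe_combine(experts, g).data)

    def test_gate_width_mismatch(self):
        with pytest.raises(ValueError):
            moe_combine([Tensor(np.ones((1, 2)))], Tensor(np.ones((1, 3))))


class TestClassifier:
    def test_same_input_same_logit_and_checkpoint_roundtrip(
        self, tiny_task_split, bundle_cache, tmp_path
    ):
        train, val = tiny_task_split
        model, ckpt = fit_classifier(train, val, FAST, seed=1, cache=bundle_cache)
        z1 = model.predict_logits(val[:5])
        z2 = model.predict_logits(val[:5])
        assert (z1 == z2).all()
        path = tmp_path / "m.ckpt.npz"
        ckpt.save(path)
        reloaded = MacroPPClassifier.from_checkpoint(ModelCheckpoint.load(path))
        assert (reloaded.predict_logits(val[:5]) == z1).all()

    def test_same_seed_reruns_identical(self, tiny_task_split, bundle_cache):
        train, val = tiny_task_split
        m1, _ = fit_classifier(train, val, FAST, seed=5, cache=bundle_cache)
        m2, _ = fit_classifier(train, val, FAST, seed=5, cache=bundle_cache)
        assert m1.training_log == m2.training_log
        for p1, p2 in zip(m1.core.parameters(), m2.core.parameters()):
            assert (p1.data == p2.data).all()

    def test_single_class_training_rejected(self, tiny_task_split, bundle_cache):
        train, val = tiny_task_split
        pos_only = [lr for lr in train if lr.label is Label.PERMEABLE]
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(pos_only, val, FAST, seed=0, cache=bundle_cache)

    def test_empty_validation_rejected(self, tiny_task_split, bundle_cache):
        train, _ = tiny_task_split
        with pytest.raises(ValueError, match="validation"):
            fit_classifier(train, [], FAST, seed=0, cache=bundle_cache)

    def test_zeroed_head_outputs_bias(self, tiny_task_split, bundle_cache):
        train, val = tiny_task_split
        model, _ = fit_classifier(train, val, FAST, seed=3, cache=bundle_cache)
        model.core.head_w.data[...] = 0.0
        model.core.head_b.data[...] = 1.5
        z = model.predict_logits(val[:8])
        assert np.allclose(z, 1.5)

    def test_separable_toy_problem_driven_to_low_bce(self, bundle_cache):
        """Labels follow molecular size exactly: training BCE falls below 0.05."""
        smis = ["C" * n for n in range(1, 13)] + ["C" * n + "O" for n in range(1, 13)]
        records = []
        for s in smis:
            can, key = canonicalize_and_key(s)
            n_heavy = len(can.replace("O", "").replace("(", "").replace(")", ""))
            value = 4.0 if n_heavy <= 6 else 8.0
            records.append(
                LabeledRecord(
                    MoleculeRecord(can, key, Assay.PAMPA, value),
                    Label.PERMEABLE if value < 6 else Label.IMPERMEABLE,
                    6.0, 0.0,
                )
            )
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=8), experts=("descriptors",),
            expert_hidden=8, max_epochs=200, patience=200, lr=5e-3, batch_size=8,
        )
        model, _ = fit_classifier(records, records, cfg, seed=0, cache=bundle_cache)
        assert model.training_log[-1]["val_loss"] < 0.05


class TestGradientCheck:
    def test_end_to_end_gradients_on_three_molecule_batch(self, bundle_cache):
        """Analytic gradients through graph + MoE match finite differences."""
        from macroperm.macro_pp import _MoECore, _Dataset, _assay_onehot
        from macroperm.featurize import Standardizer, DESCRIPTOR_NAMES, EDGE_DIM

        smis = ["CCO", "c1ccccc1", "CC(N)=O"]
        records = []
        for s in smis:
            can, key = canonicalize_and_key(s)
            records.append(
                LabeledRecord(MoleculeRecord(can, key, Assay.PAMPA, 5.0), Label.PERMEABLE, 6.0, 0.0)
            )
        desc = np.asarray([bundle_cache.get(r.record.smiles).descriptors for r in records])
        std = Standardizer().fit(desc)
        ds = _Dataset(records, bundle_cache, std, None, None, True)
        cfg = MacroPPConfig(mp=MPConfig(rounds=2, hidden_dim=4), expert_hidden=4)
        core = _MoECore(
            np.random.default_rng(0), cfg, bundle_cache.schema.dim, EDGE_DIM,
            len(DESCRIPTOR_NAMES), 5,
        )
        y = np.array([1.0, 0.0, 1.0])
        idx = np.arange(3)

        def loss_tensor():
            z = core.forward(*ds.slice(idx))
            p = z.sigmoid().clip_probs()
            yt = Tensor(y.reshape(-1, 1))
            return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()

        loss = loss_tensor()
        loss.backward()
        rng = np.random.default_rng(1)
        checked = 0
        for p in core.parameters():
            if p.grad is None or p.data.size == 0:
                continue
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for _ in range(min(3, flat.size)):
                j = int(rng.integers(flat.size))
                eps = 1e-6
                orig = flat[j]
                flat[j] = orig + eps
                fp = float(loss_tensor().data)
                flat[j] = orig - eps
                fm = float(loss_tensor().data)
                flat[j] = orig
                num = (fp - fm) / (2 * eps)
                denom = max(abs(num), abs(gflat[j]), 1e-8)
                assert abs(gflat[j] - num) / denom < 1e-4
                checked += 1
        assert checked > 20


class TestRegressor:
    def _records_with_conditions(self, bundle_cache, ph_effect=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        smis = (["C" * k for k in range(2, 12)] + ["C" * k + "O" for k in range(2, 12)]
                + ["C" * k + "N" for k in range(2, 12)] + ["C" * k + "CO" for k in range(2, 12)])
        records = []
        for i, s in enumerate(smis[:n]):
            can, key = canonicalize_and_key(s)
            mw = bundle_cache.get(can).descriptors[0]
            ph = float(rng.choice([5.0, 7.4]))
            value = 3.0 + 0.5 * (mw / 100.0) + ph_effect * (ph - 7.4)
            records.append(
                MoleculeRecord(can, key, Assay.PAMPA, value, conditions={"ph": ph, "temperature": 37.0})
            )
        return records

    def test_noiseless_linear_target_recovered(self, bundle_cache):
        from macroperm.evalx import r_squared

        records = self._records_with_conditions(bundle_cache)
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=8), experts=("descriptors",),
            expert_hidden=8, max_epochs=300, patience=300, lr=5e-3, batch_size=8,
        )
        model, _ = fit_regressor(
            records, records, ConditionEncoding("NONE"), cfg, seed=0, cache=bundle_cache
        )
        preds = model.predict(records)
        targets = [r.neg_log_papp for r in records]
        assert r_squared(targets, preds) > 0.95

    def test_condition_encoding_helps_when_target_shifts_with_ph(self, bundle_cache):
        """Planted pH effect: GLOBAL conditions beat no-conditions (median of 5 seeds)."""
        records = self._records_with_conditions(bundle_cache, ph_effect=0.4)
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=8), experts=("descriptors",),
            expert_hidden=8, max_epochs=60, patience=60, lr=5e-3, batch_size=8,
        )
        mses = {"GLOBAL": [], "NONE": []}
        for seed in range(5):
            for mode in mses:
                model, _ = fit_regressor(
                    records, records, ConditionEncoding(mode), cfg, seed=seed,
                    cache=bundle_cache,
                )
                mses[mode].append(model.training_log[-1]["val_loss"])
        assert np.median(mses["GLOBAL"]) < np.median(mses["NONE"])

    def test_same_seed_identical_parameters(self, bundle_cache):
        records = self._records_with_conditions(bundle_cache)
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=6), experts=("descriptors",),
            expert_hidden=6, max_epochs=3, patience=3,
        )
        m1, _ = fit_regressor(records, records, ConditionEncoding(), cfg, seed=2, cache=bundle_cache)
        m2, _ = fit_regressor(records, records, ConditionEncoding(), cfg, seed=2, cache=bundle_cache)
        for p1, p2 in zip(m1.core.parameters(), m2.core.parameters()):
            assert (p1.data == p2.data).all()

    def test_constant_targets_warn(self, bundle_cache):
        records = [
            MoleculeRecord(*canonicalize_and_key(s), assay=Assay.PAMPA, neg_log_papp=5.0)
            for s in ("CCO", "CCC", "CCCC")
        ]
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=4), experts=("descriptors",),
            expert_hidden=4, max_epochs=1, patience=1,
        )
        with pytest.warns(UserWarning, match="R\\^2"):
            fit_regressor(records, records, ConditionEncoding("NONE"), cfg, seed=0,
                          cache=bundle_cache)
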