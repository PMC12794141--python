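"""Geometry oracles (SASA, IMHB, RMSD) and masking-based attribution mechanics."""

import numpy as np
import pytest

from macroperm.chemdata import Label
from macroperm.interpret import (
    BONDI_RADII,
    Conformer,
    ConformerSet,
    GeometrySpec,
    channel_importance,
    detect_imhb,
    golden_spiral_points,
    kabsch_rmsd,
    polar_exposure_profile,
    select_conformers,
    shrake_rupley_sasa,
    top_confident,
)

SPEC = GeometrySpec()


class TestGoldenSpiral:
    def test_unit_norm_and_count(self):
        pts = golden_spiral_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform_centroid_near_origin(self):
        pts = golden_spiral_points(500)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        conf = Conformer(["C"], np.zeros((1, 3)), [])
        sasa = shrake_rupley_sasa(conf, SPEC)
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert sasa[0] == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(120.76, abs=0.01)

    def test_atom_buried_inside_larger_sphere_zero(self):
        conf = Conformer(["H", "I"], np.zeros((2, 3)), [(0, 1)])
        sasa = shrake_rupley_sasa(conf, SPEC)
        assert sasa[0] == 0.0

    @pytest.mark.parametrize("d", [1.0, 2.0, 4.0])
    def test_two_spheres_match_cap_formula(self, d):
        """Analytic spherical-cap oracle: each sphere loses area 2*pi*R*h, h = R - d/2."""
        conf = Conformer(["C", "C"], np.array([[0.0, 0, 0], [d, 0, 0]]), [(0, 1)])
        sasa = shrake_rupley_sasa(conf, SPEC)
        R = 1.7 + 1.4
        h = R - d / 2
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * h
        assert sasa[0] == pytest.approx(expected, rel=0.02)
        assert sasa[1] == pytest.approx(expected, rel=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=1.5, size=(5, 3))
        conf = Conformer(["C", "N", "O", "C", "S"], coords, [])
        base = shrake_rupley_sasa(conf, SPEC)
        theta = 0.83
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = Conformer(conf.elements, coords @ rot.T + np.array([3.0, -1.0, 2.0]), [])
        sasa2 = shrake_rupley_sasa(moved, SPEC)
        total1, total2 = base.sum(), sasa2.sum()
        assert abs(total1 - total2) / total1 <= 0.005

    def test_total_bounded_by_free_sphere_sum(self):
        rng = np.random.default_rng(1)
        conf = Conformer(["C", "O", "N"], rng.normal(size=(3, 3)), [])
        sasa = shrake_rupley_sasa(conf, SPEC)
        upper = sum(4 * np.pi * (BONDI_RADII[e] + 1.4) ** 2 for e in conf.elements)
        assert sasa.sum() <= upper

    def test_unknown_element_named_in_error(self):
        conf = Conformer(["C"], np.zeros((1, 3)), [])
        conf.elements = ["Zz"]
        with pytest.raises(ValueError, match="Zz"):
            shrake_rupley_sasa(conf, SPEC)


def _dha_conformer(a_pos):
    """Donor O at origin, H at (1,0,0), acceptor O at a_pos."""
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], list(a_pos)])
    return Conformer(["O", "H", "O"], coords, [(0, 1)])


class TestImhb:
    def test_collinear_within_distance_detected(self):
        conf = _dha_conformer((3.0, 0, 0))  # d(H,A) = 2.0, angle 180
        assert detect_imhb(conf, spec=SPEC) == [(0, 1, 2)]

    def test_distance_beyond_cutoff_rejected(self):
        conf = _dha_conformer((3.6, 0, 0))  # d(H,A) = 2.6 > 2.5
        assert detect_imhb(conf, spec=SPEC) == []

    def test_right_angle_rejected(self):
        conf = _dha_conformer((1.0, 2.0, 0))  # d = 2.0 but angle 90 < 120
        assert detect_imhb(conf, spec=SPEC) == []

    def test_rigid_transform_invariance(self):
        conf = _dha_conformer((2.8, 0.5, 0))
        base = detect_imhb(conf, spec=SPEC)
        theta = 1.1
        rot = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        moved = Conformer(conf.elements, conf.coords @ rot.T + 5.0, conf.bonds)
        assert detect_imhb(moved, spec=SPEC) == base

    def test_acceptor_bonded_to_hydrogen_excluded(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        conf = Conformer(["O", "H", "O"], coords, [(0, 1), (1, 2)])
        assert detect_imhb(conf, spec=SPEC) == []

    def test_missing_hydrogens_instructive_error(self):
        conf = Conformer(["O", "C"], np.array([[0.0, 0, 0], [1.5, 0, 0]]), [(0, 1)])
        with pytest.raises(ValueError, match="protonate"):
            detect_imhb(conf, spec=SPEC)


class TestKabschRmsd:
    def test_rotated_copy_zero_rmsd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        assert kabsch_rmsd(a, a @ rot.T + 2.0) == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_alignment_oracle(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)
        _, rssd = Rotation.align_vectors(b0, a0)
        assert kabsch_rmsd(a, b) == pytest.approx(rssd / np.sqrt(8), abs=1e-8)


class TestSelectConformers:
    def _conf(self, shift, energy):
        base = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.5]])
        return Conformer(["C", "C", "O"], base + shift, [(0, 1), (1, 2)], energy=energy)

    def test_duplicates_collapse(self):
        c = self._conf(0.0, 1.0)
        dup = self._conf(0.0, 2.0)  # identical geometry (translation only)
        out = select_conformers([c, dup], k=2, rmsd_min=0.3)
        assert len(out.conformers) == 1

    def test_zero_rmsd_min_keeps_lowest_energy_k(self):
        cands = [self._conf(0.0, e) for e in (3.0, 1.0, 2.0)]
        out = select_conformers(cands, k=2, rmsd_min=0.0)
        assert [c.energy for c in out.conformers] == [1.0, 2.0]

    def test_near_duplicate_skipped_in_favor_of_diverse(self):
        c1 = self._conf(0.0, 1.0)
        c2 = Conformer(  # tiny distortion of c1: below rmsd_min
            c1.elements, c1.coords + np.array([[0.05, 0, 0], [0, 0.05, 0], [0, 0, 0.05]]),
            c1.bonds, energy=2.0,
        )
        c3 = Conformer(  # genuinely different geometry (stretched internal distances)
            c1.elements, np.array([[0.0, 0, 0], [2.5, 0, 0], [5.0, 0, 2.0]]),
            c1.bonds, energy=3.0,
        )
        out = select_conformers([c1, c2, c3], k=2, rmsd_min=0.5)
        assert [c.energy for c in out.conformers] == [1.0, 3.0]

    def test_fewer_survivors_warns(self):
        c = self._conf(0.0, 1.0)
        with pytest.warns(UserWarning, match="survive"):
            out = select_conformers([c, self._conf(0.0, 2.0)], k=2, rmsd_min=0.3)
        assert len(out.conformers) == 1


class TestPolarExposure:
    def _water(self, shift=0.0):
        coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]) + shift
        return Conformer(["O", "H", "H"], coords, [(0, 1), (0, 2)])

    def test_single_conformer_equals_ensemble_of_one(self):
        conf = self._water()
        profile = polar_exposure_profile(ConformerSet("w", [conf]), SPEC)
        sasa = shrake_rupley_sasa(conf, SPEC)
        assert profile["total_hbd_sasa"] == pytest.approx(sasa[1] + sasa[2])
        assert profile["total_hba_sasa"] == pytest.approx(sasa[0])
        assert profile["per_donor_sasa"] == pytest.approx(sasa[1] + sasa[2])

    def test_zero_donor_molecule_sentinel(self):
        conf = Conformer(
            ["C", "H", "H", "H", "H"],
            np.array([[0.0, 0, 0], [1.1, 0, 0], [-1.1, 0, 0], [0, 1.1, 0], [0, -1.1, 0]]),
            [(0, 1), (0, 2), (0, 3), (0, 4)],
        )
        profile = polar_exposure_profile(ConformerSet("methane", [conf]), SPEC)
        assert profile["total_hbd_sasa"] == 0.0
        assert np.isnan(profile["per_donor_sasa"])

    def test_two_conformer_average(self):
        c1, c2 = self._water(), self._water(shift=0.0)
        c2 = Conformer(c2.elements, c2.coords * 1.2, c2.bonds)  # stretched variant
        s1 = shrake_rupley_sasa(c1, SPEC)
        s2 = shrake_rupley_sasa(c2, SPEC)
        profile = polar_exposure_profile(ConformerSet("w", [c1, c2]), SPEC)
        expected = ((s1[1] + s1[2]) + (s2[1] + s2[2])) / 2
        assert profile["total_hbd_sasa"] == pytest.approx(expected)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ConformerSet("x", [])


class TestTopConfident:
    def test_basic_ranking(self):
        top_pos, top_neg = top_confident([0.9, 0.2, 0.6], [1, 0, 1], n=1)
        assert top_pos == [0] and top_neg == [1]

    def test_ties_keep_stable_order(self):
        top_pos, top_neg = top_confident([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], n=2)
        assert top_pos == [0, 1] and top_neg == [2, 3]

    def test_n_equals_class_size_returns_all(self):
        top_pos, top_neg = top_confident([0.9, 0.1, 0.8, 0.3], [1, 0, 1, 0], n=2)
        assert sorted(top_pos) == [0, 2] and sorted(top_neg) == [1, 3]

    def test_n_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            top_confident([0.9, 0.1], [1, 0], n=2)


class TestChannelImportance:
    @pytest.fixture(scope="class")
    def trained(self, tiny_task_split, bundle_cache):
        from macroperm.macro_pp import MacroPPConfig, fit_classifier
        from macroperm.nets import MPConfig

        train, val = tiny_task_split
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=2, hidden_dim=12), experts=("graph",),
            max_epochs=6, patience=6,
        )
        model, _ = fit_classifier(train, val, cfg, seed=2, cache=bundle_cache)
        return model, val

    def test_baseline_equals_direct_bce(self, trained):
        from macroperm.evalx import bce_loss

        model, val = trained
        report = channel_importance(model, val)
        probs = model.predict_proba(val)
        y = [int(lr.label) for lr in val]
        assert report.baseline_loss == pytest.approx(bce_loss(y, probs), abs=1e-12)

    def test_ranking_is_permutation_of_schema(self, trained):
        model, val = trained
        report = channel_importance(model, val)
        assert sorted(report.ranking) == sorted(model.cache.schema.channel_names)

    def test_record_count_unchanged_by_masking(self, trained):
        model, val = trained
        n_before = len(val)
        channel_importance(model, val)
        assert len(val) == n_before

    def test_model_ignoring_graphs_has_zero_deltas(self, tiny_task_split, bundle_cache):
        from macroperm.macro_pp import MacroPPConfig, fit_classifier
        from macroperm.nets import MPConfig

        train, val = tiny_task_split
        cfg = MacroPPConfig(
            mp=MPConfig(rounds=1, hidden_dim=8), experts=("graph",),
            max_epochs=1, patience=1,
        )
        model, _ = fit_classifier(train, val, cfg, seed=0, cache=bundle_cache)
        # zero every encoder parameter: graph embedding becomes input-independent
        for p in model.core.encoder.parameters():
            p.data[...] = 0.0
        report = channel_importance(model, val)
        assert max(abs(d) for d in report.delta_loss.values()) == pytest.approx(0.0, abs=1e-12)


class TestConformerSdfIO:
    def test_round_trip_preserves_geometry_and_energy(self, tmp_path):
        from macroperm.interpret import read_conformers_sdf, write_conformers_sdf

        c1 = Conformer(["O", "H", "H"],
                       np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]),
                       [(0, 1), (0, 2)], energy=1.5)
        c2 = Conformer(c1.elements, c1.coords * 1.1, c1.bonds, energy=2.0)
        path = tmp_path / "w.sdf"
        write_conformers_sdf(ConformerSet("water", [c1, c2]), path)
        back = read_conformers_sdf(path)
        assert back.molecule_id == "water"
        assert len(back.conformers) == 2
        assert back.conformers[0].energy == 1.5
        assert np.allclose(back.conformers[1].coords, c2.coords, atol=1e-4)
        assert sorted(map(tuple, back.conformers[0].bonds)) == [(0, 1), (0, 2)]
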