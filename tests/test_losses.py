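"""Loss oracles: clamped FAPE, torsion, violation, pLDDT cross-entropy."""

import copy

import numpy as np
import pytest

from fvfold.features import RegionLabel
from fvfold.geometry.rigid import Rigid
from fvfold.losses import (
    ClampSpec,
    LossBreakdown,
    alternate_torsions,
    build_clamp_matrix,
    combine_losses,
    fape,
    plddt_loss,
    torsion_angle_loss,
    total_fape,
    violation_breakdown,
    violation_loss,
)
from fvfold.structure import TorsionSet
from tests.conftest import random_rigid

RNG = np.random.default_rng(7)


class TestClampMatrix:
    def test_rule_exhaustive(self, mini_fv):
        regions = mini_fv.regions
        spec = build_clamp_matrix(regions)
        for i, ri in enumerate(regions):
            for j, rj in enumerate(regions):
                expected = 30.0 if ri.is_cdr != rj.is_cdr else 10.0
                assert spec.matrix[i, j] == expected
        np.testing.assert_array_equal(spec.matrix, spec.matrix.T)

    def test_cdr_framework_pair_is_thirty(self):
        spec = build_clamp_matrix([RegionLabel.CDRH3, RegionLabel.FWH])
        assert spec.matrix[0, 1] == 30.0 and spec.matrix[1, 0] == 30.0

    def test_framework_pair_is_ten(self):
        spec = build_clamp_matrix([RegionLabel.FWL, RegionLabel.FWL])
        assert spec.matrix[0, 1] == 10.0


def _random_frame_batch(n):
    rots = np.stack([random_rigid(RNG).rotation for _ in range(n)])
    trans = RNG.normal(0, 5, size=(n, 3))
    return Rigid(rots, trans)


class TestFape:
    def test_zero_at_equality(self):
        frames = _random_frame_batch(5)
        pts = RNG.normal(0, 5, size=(8, 3))
        assert fape(frames, pts, frames, pts) == 0.0

    def test_hand_computed_clamped_case(self):
        frames = Rigid(np.eye(3)[None], np.zeros((1, 3)))
        pred = np.array([[40.0, 0.0, 0.0]])
        true = np.array([[0.0, 0.0, 0.0]])
        assert fape(frames, pred, frames, true, clamp=10.0, scale=10.0) == 1.0

    def test_invariance_under_independent_global_transforms(self):
        frames_p = _random_frame_batch(6)
        frames_t = _random_frame_batch(6)
        pts_p = RNG.normal(0, 5, size=(10, 3))
        pts_t = RNG.normal(0, 5, size=(10, 3))
        base = fape(frames_p, pts_p, frames_t, pts_t)
        for _ in range(50):
            gp, gt = random_rigid(RNG), random_rigid(RNG)
            moved = fape(
                Rigid(gp.rotation @ frames_p.rotation, gp.apply(frames_p.translation)),
                gp.apply(pts_p),
                Rigid(gt.rotation @ frames_t.rotation, gt.apply(frames_t.translation)),
                gt.apply(pts_t),
            )
            assert moved == pytest.approx(base, abs=1e-9)

    def test_raising_clamp_never_decreases_loss(self):
        frames = _random_frame_batch(4)
        pts_p = RNG.normal(0, 8, size=(6, 3))
        pts_t = RNG.normal(0, 8, size=(6, 3))
        lo = fape(frames, pts_p, frames, pts_t, clamp=5.0)
        hi = fape(frames, pts_p, frames, pts_t, clamp=50.0)
        unclamped = fape(frames, pts_p, frames, pts_t, clamp=np.inf)
        assert lo <= hi <= unclamped + 1e-12

    def test_count_mismatch_rejected(self):
        frames = _random_frame_batch(3)
        with pytest.raises(ValueError):
            fape(frames, np.zeros((4, 3)), frames, np.zeros((5, 3)))

    def test_tensor_route_matches_numpy_route(self):
        from fvfold.autodiff import Tensor
        from fvfold.diff_losses import fape_t

        frames_p = _random_frame_batch(5)
        frames_t = _random_frame_batch(5)
        pts_p = RNG.normal(0, 5, size=(9, 3))
        pts_t = RNG.normal(0, 5, size=(9, 3))
        clamp = RNG.choice([10.0, 30.0], size=(5, 9))
        a = fape(frames_p, pts_p, frames_t, pts_t, clamp)
        b = fape_t(
            Tensor(frames_p.rotation), Tensor(frames_p.translation), Tensor(pts_p),
            frames_t.rotation, frames_t.translation, pts_t, clamp, eps=0.0,
        )
        assert float(b.data) == pytest.approx(a, abs=1e-12)


class TestTotalFape:
    def test_perfect_trajectory_is_zero(self, mini_fv):
        clamp = build_clamp_matrix(mini_fv.regions)
        frames = mini_fv.frames()
        backbone, final = total_fape([frames] * 3, mini_fv, mini_fv, clamp)
        # frame-local backbone coords of the fixture equal the shared template
        assert backbone == pytest.approx(0.0, abs=1e-6)
        assert final == pytest.approx(0.0, abs=1e-12)

    def test_backbone_term_averages_blocks(self, mini_fv):
        from fvfold.fixtures import perturb

        clamp = build_clamp_matrix(mini_fv.regions)
        good = mini_fv.frames()
        bad = perturb(mini_fv, 2.0, seed=1).frames()
        per_block = [
            total_fape([f], mini_fv, mini_fv, clamp)[0] for f in (good, bad)
        ]
        both, _ = total_fape([good, bad], mini_fv, mini_fv, clamp)
        assert both == pytest.approx(np.mean(per_block), abs=1e-12)

    def test_worsening_one_block_increases_backbone_term(self, mini_fv):
        from fvfold.fixtures import perturb

        clamp = build_clamp_matrix(mini_fv.regions)
        good = mini_fv.frames()
        mild = perturb(mini_fv, 0.5, seed=2).frames()
        bad = perturb(mini_fv, 1.5, seed=2).frames()
        a, _ = total_fape([good, mild], mini_fv, mini_fv, clamp)
        b, _ = total_fape([good, bad], mini_fv, mini_fv, clamp)
        assert b > a

    def test_empty_trajectory_rejected(self, mini_fv):
        with pytest.raises(ValueError):
            total_fape([], mini_fv, mini_fv, build_clamp_matrix(mini_fv.regions))


def _unit_raw(angles):
    return np.stack([np.sin(angles), np.cos(angles)], axis=-1)


class TestTorsionLoss:
    def _set(self, angles, mask=None):
        angles = np.asarray(angles, dtype=float).reshape(1, 4)
        if mask is None:
            mask = np.ones((1, 4), dtype=bool)
        return TorsionSet(angles, np.asarray(mask).reshape(1, 4))

    def test_perfect_unit_prediction_is_zero(self):
        true = self._set([0.3, -1.2, 2.0, 3.0])
        assert torsion_angle_loss(_unit_raw(true.angles), true) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_pi_shift_invariant(self):
        angles = np.array([0.3, -1.2, 2.0, 3.0])
        true = self._set(angles)
        shifted = self._set(angles + 2 * np.pi)
        raw = _unit_raw(self._set([0.5, -1.0, 2.2, 2.8]).angles)
        assert torsion_angle_loss(raw, true) == pytest.approx(
            torsion_angle_loss(raw, shifted), abs=1e-12
        )

    def test_pi_symmetric_chi_scores_zero_via_alternate(self):
        angles = np.array([0.4, 0.9, -2.0, 1.1])
        true = self._set(angles)
        alt = self._set(angles + np.pi)
        raw = _unit_raw(alt.angles)  # predict the flipped branch exactly
        assert torsion_angle_loss(raw, true, alt) == pytest.approx(0.0, abs=1e-12)

    def test_norm_regularisation_term(self):
        true = self._set([0.0, 0.0, 0.0, 0.0])
        raw = _unit_raw(true.angles) * 3.0  # correct angle, norm 3
        loss = torsion_angle_loss(raw, true, norm_weight=0.02)
        assert loss == pytest.approx(0.02 * 2.0, abs=1e-9)

    def test_alternate_torsions_flip_only_symmetric_residues(self):
        angles = np.tile(np.array([0.5, 1.0, 1.5, 2.0]), (3, 1))
        mask = np.array(
            [[1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool
        )
        ts = TorsionSet(angles.copy(), mask)
        alt = alternate_torsions(ts, ["ASP", "GLU", "LYS"])
        assert alt.angles[0, 1] == pytest.approx(ts.angles[0, 1] + np.pi - 2 * np.pi)
        assert alt.angles[1, 2] == pytest.approx(ts.angles[1, 2] + np.pi - 2 * np.pi)
        np.testing.assert_array_equal(alt.angles[2], ts.angles[2])  # LYS unchanged

    def test_mask_mismatch_rejected(self):
        true = self._set([0, 0, 0, 0])
        alt = self._set([0, 0, 0, 0], mask=[1, 1, 1, 0])
        with pytest.raises(ValueError):
            torsion_angle_loss(_unit_raw(true.angles), true, alt)

    def test_tensor_route_matches_numpy(self):
        from fvfold.autodiff import Tensor
        from fvfold.diff_losses import torsion_angle_loss_t

        rng = np.random.default_rng(3)
        raw = rng.normal(0, 1.5, size=(4, 4, 2))
        angles = rng.uniform(-np.pi, np.pi, size=(4, 4))
        mask = rng.random((4, 4)) < 0.7
        mask[0] = True
        true = TorsionSet(angles, mask)
        alt = alternate_torsions(true, ["ASP", "GLU", "LYS", "PHE"])
        a = torsion_angle_loss(raw, true, alt)
        b = torsion_angle_loss_t(Tensor(raw), true, alt)
        assert float(b.data) == pytest.approx(a, abs=1e-9)


class TestViolation:
    def test_zero_on_idealized_fixture(self, mini_fv):
        parts = violation_breakdown(mini_fv)
        assert parts == {"bond": 0.0, "angle": 0.0, "clash": 0.0}

    def test_clash_at_half_radius_sum(self, mini_fv):
        rec = copy.deepcopy(mini_fv)
        # drag a light-chain CA onto a heavy-chain CA (far apart in sequence)
        target = rec.residues[2].atoms["CA"]
        rec.residues[30].atoms["CA"] = target + np.array([0.5 * 3.4 * 0.5, 0, 0])
        # distance 0.85 A << 3.4 - 1.5; penalty = limit - d
        parts = violation_breakdown(rec)
        assert parts["clash"] > 0.0

    def test_stretched_peptide_bond_isolated(self, mini_fv):
        rec = copy.deepcopy(mini_fv)
        base = violation_breakdown(rec)
        # translate everything from heavy residue 5 onward along the C->N axis
        c = rec.residues[4].atoms["C"]
        n_next = rec.residues[5].atoms["N"]
        direction = (n_next - c) / np.linalg.norm(n_next - c)
        heavy_n = len(rec.chain("H"))
        for r in rec.residues[5:heavy_n]:
            for name in r.atoms:
                r.atoms[name] = r.atoms[name] + 0.5 * direction
        parts = violation_breakdown(rec)
        assert parts["bond"] == pytest.approx(0.5 - 12 * 0.02, abs=1e-9)
        assert parts["angle"] == pytest.approx(base["angle"], abs=1e-9)

    def test_loss_is_sum_of_parts(self, mini_fv):
        assert violation_loss(mini_fv) == sum(violation_breakdown(mini_fv).values())


class TestPlddtLoss:
    def test_one_hot_correct_bin_is_zero(self):
        pred = np.zeros((3, 50))
        lddt = np.array([0.61, 0.02, 0.99])
        idx = np.minimum((lddt * 50).astype(int), 49)
        pred[np.arange(3), idx] = 1.0
        assert plddt_loss(pred, lddt) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_is_log_bins(self):
        pred = np.full((4, 50), 1 / 50)
        assert plddt_loss(pred, np.array([0.1, 0.5, 0.9, 1.0])) == pytest.approx(
            np.log(50)
        )

    def test_lddt_one_falls_in_top_bin(self):
        pred = np.zeros((1, 50))
        pred[0, 49] = 1.0
        assert plddt_loss(pred, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_lddt_rejected(self):
        with pytest.raises(ValueError):
            plddt_loss(np.full((1, 50), 1 / 50), np.array([1.2]))

    def test_cross_entropy_nonnegative(self):
        rng = np.random.default_rng(0)
        pred = rng.dirichlet(np.ones(50), size=6)
        lddt = rng.uniform(0, 1, size=6)
        assert plddt_loss(pred, lddt) > 0.0


class TestCombine:
    def test_stage1_ignores_violation(self):
        parts = LossBreakdown(backbone_fape=1.0, final_fape=0.5, torsion=0.2,
                              violation=7.0, plddt_ce=0.0)
        out = combine_losses(parts, stage=1)
        assert out.total == pytest.approx(1.7)

    def test_stage2_adds_violation(self):
        parts = LossBreakdown(backbone_fape=1.0, final_fape=0.5, torsion=0.2,
                              violation=7.0, plddt_ce=0.0)
        assert combine_losses(parts, stage=2).total == pytest.approx(8.7)

    def test_plddt_weight_is_one_percent(self):
        parts = LossBreakdown(plddt_ce=2.0)
        assert combine_losses(parts, stage=1).total == pytest.approx(0.02)

    def test_all_zero_gives_zero(self):
        assert combine_losses(LossBreakdown(), stage=2).total == 0.0

    def test_invalid_stage(self):
        with pytest.raises(ValueError):
            combine_losses(LossBreakdown(), stage=3)
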