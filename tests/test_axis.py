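import numpy as np
import pytest

import cnparcel as cn
from cnparcel.axis import DegenerateAxisError, NoCrossingError, _mask_world_coords


def synthetic_profile(angles, arc=None):
    angles = np.asarray(angles, dtype=float)
    if arc is None:
        arc = np.linspace(0.0, 44.0, len(angles))
    return cn.RadialityProfile(mean_angle=angles,
                               voxel_count=np.ones(len(angles), dtype=int),
                               arc_length=np.asarray(arc, dtype=float))


class TestFitLongitudinalSpline:
    def test_circle_geometry(self, phantom, phantom_spline):
        sp = phantom_spline
        # sampled positions on the (mean-radius) arc within half a voxel
        radii = np.linalg.norm(sp.positions[:, 1:], axis=1)
        assert np.all(np.abs(radii - radii.mean()) < 0.5)
        # tangents perpendicular to the radius vector within 2 degrees
        radial = sp.positions - sp.ac_point
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.abs(np.einsum("ij,ij->i", radial, sp.tangents))
        assert np.all(np.degrees(np.arcsin(np.clip(dots, 0, 1))) < 2.0)

    def test_45_samples_strictly_increasing_arc(self, phantom_spline):
        assert phantom_spline.n_samples == 45
        assert np.all(np.diff(phantom_spline.arc_length) > 0)
        assert np.all(np.diff(phantom_spline.params) > 0)
        norms = np.linalg.norm(phantom_spline.tangents, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_posterior_end_is_sample_zero(self, phantom, phantom_spline):
        d_post = np.linalg.norm(phantom_spline.positions[0] - phantom.arc[0])
        d_ant = np.linalg.norm(phantom_spline.positions[0] - phantom.arc[-1])
        assert d_post < d_ant

    def test_voxel_projection_distance(self, phantom, phantom_spline):
        """Brute-force nearest-point search over finely sampled positions."""
        coords = _mask_world_coords(phantom.mask, phantom.affine)
        fine_t = np.linspace(phantom_spline.params[0],
                             phantom_spline.params[-1], 500)
        fine_pos, _ = phantom_spline.evaluate(fine_t)
        d = np.min(np.linalg.norm(coords[:, None, :] - fine_pos[None, :, :],
                                  axis=2), axis=1)
        assert d.mean() <= 4.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cn.fit_longitudinal_spline(np.zeros((4, 4, 4), bool), np.eye(4),
                                       (0, 0, 0))

    def test_narrow_angular_range_raises(self):
        mask = np.zeros((3, 30, 3), bool)
        mask[1, :, 1] = True  # straight line pointing away from landmark
        with pytest.raises(DegenerateAxisError):
            cn.fit_longitudinal_spline(mask, np.eye(4), (1.0, -1000.0, 1.0))

    def test_disconnected_angular_components_raise(self, phantom):
        mask = phantom.mask.copy()
        coords = _mask_world_coords(mask, phantom.affine)
        ang = np.degrees(np.arctan2(coords[:, 2], coords[:, 1]))
        cut = (ang > 80) & (ang < 100)
        ijk = np.argwhere(mask)[cut]
        mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = False
        with pytest.raises(DegenerateAxisError, match="components"):
            cn.fit_longitudinal_spline(mask, phantom.affine, phantom.ac_point)


class TestRadialityProfile:
    def _field_with_dirs(self, phantom, dirs_fn):
        coords = _mask_world_coords(phantom.mask, phantom.affine)
        pd = np.zeros(phantom.mask.shape + (3,))
        pd[phantom.mask] = dirs_fn(coords)
        n = phantom.n_voxels
        return cn.TensorField(tensors=np.zeros((n, 6)),
                              fa=phantom.mask.astype(float),
                              principal_dir=pd,
                              eigenvalues=np.zeros((n, 3)),
                              mask=phantom.mask, affine=phantom.affine)

    def test_tangent_field_gives_zero(self, phantom, phantom_spline):
        def tangents(coords):
            th = np.arctan2(coords[:, 2], coords[:, 1])
            return np.stack([np.zeros_like(th), -np.sin(th), np.cos(th)],
                            axis=1)
        # principal dirs = spline tangents themselves -> exactly zero
        sp = phantom_spline
        t_vox = np.clip(sp.param_of(_mask_world_coords(phantom.mask,
                                                       phantom.affine)),
                        sp.params[0], sp.params[-1])
        _, deriv = sp.evaluate(t_vox)
        exact = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
        field = self._field_with_dirs(phantom, lambda c: exact)
        prof = cn.radiality_profile(field, sp)
        assert np.nanmax(prof.mean_angle) < 1e-6

    def test_perpendicular_field_gives_ninety(self, phantom, phantom_spline):
        field = self._field_with_dirs(
            phantom, lambda c: np.tile([1.0, 0.0, 0.0], (len(c), 1)))
        prof = cn.radiality_profile(field, phantom_spline)
        assert np.nanmin(prof.mean_angle) > 90.0 - 1e-6

    def test_matches_brute_force_oracle(self, noiseless_tensor_field,
                                        phantom, phantom_spline):
        prof = cn.radiality_profile(noiseless_tensor_field, phantom_spline)
        # independent per-voxel loop oracle
        sp = phantom_spline
        coords = _mask_world_coords(phantom.mask, phantom.affine)
        dirs = noiseless_tensor_field.principal_dir[phantom.mask]
        sums = np.zeros(sp.n_samples)
        counts = np.zeros(sp.n_samples, dtype=int)
        for p, v in zip(coords, dirs):
            t = float(sp.param_of(p[None])[0])
            t = min(max(t, sp.params[0]), sp.params[-1])
            i = int(np.argmin(np.abs(sp.params - t)))
            _, der = sp.evaluate(np.array([t]))
            tan = der[0] / np.linalg.norm(der[0])
            ang = np.degrees(np.arccos(min(abs(float(np.dot(v, tan))), 1.0)))
            sums[i] += ang
            counts[i] += 1
        oracle = sums / np.maximum(counts, 1)
        ok = counts > 0
        assert np.allclose(prof.mean_angle[ok], oracle[ok], atol=1e-6)
        assert np.array_equal(prof.voxel_count, counts)

    def test_voxel_counts_sum_to_mask(self, noiseless_profile, phantom):
        assert noiseless_profile.voxel_count.sum() == phantom.n_voxels

    def test_sign_flip_invariance(self, phantom, phantom_spline,
                                  noiseless_tensor_field):
        import copy
        flipped = copy.deepcopy(noiseless_tensor_field)
        flipped.principal_dir = -flipped.principal_dir
        a = cn.radiality_profile(noiseless_tensor_field, phantom_spline)
        b = cn.radiality_profile(flipped, phantom_spline)
        np.testing.assert_allclose(a.mean_angle, b.mean_angle, atol=1e-12)

    def test_bounded_0_90(self, noiseless_profile):
        ok = ~np.isnan(noiseless_profile.mean_angle)
        assert np.all(noiseless_profile.mean_angle[ok] >= 0)
        assert np.all(noiseless_profile.mean_angle[ok] <= 90)


class TestDetectGroupBoundaries:
    def test_linear_profile_midpoint_crossing(self):
        # linear 70 -> 20 degrees across the central window: the 45-degree
        # point sits exactly halfway
        arc = np.linspace(0.0, 44.0, 45)
        angles = np.interp(arc, [11.0, 28.6], [70.0, 20.0],
                           left=70.0, right=20.0)
        angles[29:] = 5.0  # head-window minimum far anterior
        prof = synthetic_profile(angles, arc)
        bs = cn.detect_group_boundaries([prof])
        assert bs.b_45 == pytest.approx((11.0 + 28.6) / 2, abs=1e-9)

    def test_v_shape_minimum_sample(self):
        arc = np.linspace(0.0, 44.0, 45)
        angles = np.full(45, 60.0)
        angles[5:25] = np.linspace(20.0, 60.0, 20)  # crossing in central win
        angles[30:39] = [50, 40, 30, 20, 10, 20, 30, 40, 50]
        prof = synthetic_profile(angles, arc)
        bs = cn.detect_group_boundaries([prof])
        assert bs.b_min == pytest.approx(arc[34])

    def test_no_crossing_raises(self):
        prof = synthetic_profile(np.full(45, 80.0))
        with pytest.raises(NoCrossingError):
            cn.detect_group_boundaries([prof])

    def test_group_level_tag(self, noiseless_profile):
        bs = cn.detect_group_boundaries([noiseless_profile])
        assert bs.level == "group"
        assert bs.b_45 < bs.b_min

    def test_phantom_13_subjects_recovery(self, phantom, phantom_spline,
                                          scheme):
        profs = []
        for s in range(13):
            dwi = cn.simulate_dwi(phantom, scheme, noise_sigma=0.05,
                                  rng_seed=100 + s)
            f = cn.fit_tensors(dwi, phantom.mask)
            profs.append(cn.radiality_profile(f, phantom_spline))
        bs = cn.detect_group_boundaries(profs)
        spacing = phantom_spline.total_arc_length / 44
        s1, s2 = phantom.planted_boundaries
        assert abs(bs.b_45 - s1) <= spacing
        assert abs(bs.b_min - s2) <= spacing


class TestRefineSubjectBoundaries:
    def test_identical_profile_keeps_boundaries(self):
        arc = np.linspace(0.0, 44.0, 45)
        angles = np.clip(np.interp(arc, [10, 30], [70, 20]), 20, 70)
        angles[35:40] = [15, 10, 5, 10, 15]
        prof = synthetic_profile(angles, arc)
        group = cn.detect_group_boundaries([prof])
        subj = cn.refine_subject_boundaries(prof, group)
        # nearest-sample quantization of the interpolated group crossing
        assert abs(subj.b_45 - group.b_45) <= arc[1] - arc[0]
        assert subj.b_min == pytest.approx(group.b_min)
        assert subj.level == "subject"

    def test_radius_limits_search(self):
        arc = np.linspace(0.0, 44.0, 45)
        angles = np.full(45, 60.0)
        angles[15] = 44.0    # near-45 inside radius of group b_45 (=15)
        angles[40] = 1.0     # better but far outside the radius
        prof = synthetic_profile(angles, arc)
        group = cn.BoundarySet(b_45=15.0, b_min=30.0, level="group")
        subj = cn.refine_subject_boundaries(prof, group, radius=5.0)
        assert subj.b_45 == pytest.approx(15.0)
        assert abs(subj.b_min - 30.0) <= 5.0

    def test_tie_goes_posterior(self):
        arc = np.linspace(0.0, 44.0, 45)
        angles = np.full(45, 60.0)
        angles[14] = 40.0
        angles[16] = 50.0  # same |angle - 45| as sample 14
        prof = synthetic_profile(angles, arc)
        group = cn.BoundarySet(b_45=15.0, b_min=30.0, level="group")
        subj = cn.refine_subject_boundaries(prof, group, radius=3.0)
        assert subj.b_45 == pytest.approx(arc[14])

    def test_window_clipping_warns(self):
        prof = synthetic_profile(np.linspace(70, 20, 45))
        group = cn.BoundarySet(b_45=2.0, b_min=42.0, level="group")
        with pytest.warns(UserWarning, match="clipped"):
            cn.refine_subject_boundaries(prof, group, radius=10.0)

    def test_requires_group_level(self):
        prof = synthetic_profile(np.linspace(70, 20, 45))
        subj = cn.BoundarySet(b_45=10.0, b_min=30.0, level="subject")
        with pytest.raises(ValueError):
            cn.refine_subject_boundaries(prof, subj)


class TestSegmentCn:
    def test_partition_property(self, phantom, phantom_spline):
        bs = cn.BoundarySet(b_45=phantom.planted_boundaries[0],
                            b_min=phantom.planted_boundaries[1],
                            level="group")
        labels = cn.segment_cn(phantom.mask, phantom.affine, phantom_spline,
                               bs)
        inside = labels[phantom.mask]
        assert np.all(np.isin(inside, (1, 2, 3)))
        assert np.all(labels[~phantom.mask] == 0)
        assert inside.size == phantom.n_voxels

    def test_thirds_give_roughly_equal_segments(self, phantom,
                                                phantom_spline):
        total = phantom_spline.total_arc_length
        bs = cn.BoundarySet(b_45=total / 3, b_min=2 * total / 3,
                            level="group")
        labels = cn.segment_cn(phantom.mask, phantom.affine, phantom_spline,
                               bs)
        counts = np.bincount(labels[phantom.mask], minlength=4)[1:]
        assert np.all(np.abs(counts / phantom.n_voxels - 1 / 3) < 0.1)

    def test_agreement_with_planted_labels(self, phantom, phantom_spline):
        bs = cn.BoundarySet(b_45=phantom.planted_boundaries[0],
                            b_min=phantom.planted_boundaries[1],
                            level="group")
        labels = cn.segment_cn(phantom.mask, phantom.affine, phantom_spline,
                               bs)
        agree = labels[phantom.mask] == phantom.segment_labels[phantom.mask]
        assert agree.mean() >= 0.95

    def test_monotone_along_arc(self, phantom, phantom_spline):
        bs = cn.BoundarySet(b_45=20.0, b_min=40.0, level="group")
        labels = cn.segment_cn(phantom.mask, phantom.affine, phantom_spline,
                               bs)
        coords = _mask_world_coords(phantom.mask, phantom.affine)
        s = phantom_spline.arc_length_of(coords)
        lab = labels[phantom.mask]
        order = np.argsort(s)
        assert np.all(np.diff(lab[order]) >= 0)

    def test_out_of_range_boundary_raises(self, phantom, phantom_spline):
        bs = cn.BoundarySet(b_45=10.0, b_min=1e4, level="group")
        with pytest.raises(ValueError):
            cn.segment_cn(phantom.mask, phantom.affine, phantom_spline, bs)


class TestChooseTypicalSubject:
    def test_row_sum_argmin(self):
        m = np.array([[0, 2, 3], [1, 0, 1], [4, 5, 0]], dtype=float)
        assert cn.choose_typical_subject(m) == 1  # row sums 5, 2, 9

    def test_all_equal_ties_to_first(self):
        assert cn.choose_typical_subject(np.ones((4, 4))) == 0

    def test_diagonal_ignored(self):
        m = np.array([[100.0, 1.0], [1.0, 0.0]])
        assert cn.choose_typical_subject(m) == 0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            m = rng.uniform(0, 10, (13, 13))
            best, best_sum = None, np.inf
            for i in range(13):
                s = sum(m[i, j] for j in range(13) if j != i)
                if s < best_sum:
                    best, best_sum = i, s
            assert cn.choose_typical_subject(m) == best

    def test_negative_costs_raise(self):
        m = np.array([[0.0, -1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            cn.choose_typical_subject(m)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            cn.choose_typical_subject(np.ones((2, 3)))


class TestScalingEquivariance:
    def test_boundaries_scale_with_phantom(self, scheme):
        """Uniform spatial scaling scales detected arc lengths."""
        results = {}
        for scale in (1.0, 1.5):
            truth = cn.make_cn_phantom(arc_radius=25.0 * scale,
                                       tube_radius=4.0 * scale,
                                       voxel_size=scale)
            dwi = cn.simulate_dwi(truth, scheme)
            f = cn.fit_tensors(dwi, truth.mask)
            sp = cn.fit_longitudinal_spline(truth.mask, truth.affine,
                                            truth.ac_point,
                                            posterior_hint=truth.arc[0])
            prof = cn.radiality_profile(f, sp)
            bs = cn.detect_group_boundaries([prof])
            results[scale] = (bs.b_45, bs.b_min, sp.total_arc_length)
        r1, r15 = results[1.0], results[1.5]
        assert r15[2] == pytest.approx(1.5 * r1[2], rel=0.02)
        assert r15[0] == pytest.approx(1.5 * r1[0], rel=0.05)
        assert r15[1] == pytest.approx(1.5 * r1[1], rel=0.05)
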