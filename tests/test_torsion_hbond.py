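import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiscan import synthetic_data as sd
from ppiscan.torsion_hbond import (
    TorsionSchedule,
    build_schedule,
    classify_hbond,
    get_atom_pos,
    hbond_geometry,
    measure_omega,
    rotate_segment,
    set_omega,
    track_scan,
    wrap_angle,
)

PAPER_LIKE = dict(start_omega=-174.0, end_omega=0.0, step=0.2, dwell=2.0)


def model_at(omega, n_residues=5, proline_index=3):
    atoms = sd._build_backbone(n_residues, proline_index, omega)
    return sd._peptide_model(atoms, n_residues, proline_index)


def all_coords(model, chain="A"):
    out = {}
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            for at in res:
                out[(res.seqid.num, at.name)] = np.array([at.pos.x, at.pos.y, at.pos.z])
    return out


class TestSchedule:
    def test_clockwise_arc_through_minus_ninety(self):
        sched = TorsionSchedule(**PAPER_LIKE, direction="clockwise")
        assert sched.n_windows == 870
        assert sched.total_time_ns == pytest.approx(1.74)
        windows = build_schedule(sched)
        assert len(windows) == 871
        centers = [c for _, c in windows]
        assert -90.0 in centers  # passes through the syn geometry

    def test_counterclockwise_complementary_arc(self):
        sched = TorsionSchedule(**PAPER_LIKE, direction="counterclockwise")
        assert sched.n_windows == 930
        assert sched.total_time_ns == pytest.approx(1.86)

    def test_syn_state_reached_at_0_84_ns(self):
        windows = build_schedule(TorsionSchedule(**PAPER_LIKE))
        (t_syn,) = [t for t, c in windows if abs(c + 90.0) < 1e-9]
        assert t_syn == pytest.approx(0.84)

    def test_degenerate_schedule(self):
        sched = TorsionSchedule(start_omega=30.0, end_omega=30.0)
        assert sched.n_windows == 0 and sched.total_time_ns == 0.0
        assert build_schedule(sched) == [(0.0, 30.0)]

    def test_indivisible_arc_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            TorsionSchedule(start_omega=0.0, end_omega=0.1, step=0.3).n_windows

    @given(st.integers(min_value=-899, max_value=900),
           st.integers(min_value=-899, max_value=900))
    @settings(max_examples=60, deadline=None)
    def test_opposite_directions_cover_the_full_circle(self, a, b):
        start, end = a * 0.2, b * 0.2
        if start == end:
            return
        cw = TorsionSchedule(start, end, direction="clockwise")
        ccw = TorsionSchedule(start, end, direction="counterclockwise")
        assert cw.arc_length + ccw.arc_length == pytest.approx(360.0)
        assert cw.n_windows * cw.step == pytest.approx(cw.arc_length)


class TestOmegaMeasurement:
    def test_planar_trans_peptide(self):
        assert measure_omega(model_at(180.0), 3) == pytest.approx(180.0, abs=1e-9)

    def test_planar_cis_peptide(self):
        assert measure_omega(model_at(0.0), 3) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_twist_recovered(self):
        assert measure_omega(model_at(-97.0), 3) == pytest.approx(-97.0, abs=1e-3)

    def test_terminal_residue_rejected(self):
        with pytest.raises(ValueError):
            measure_omega(model_at(180.0), 1)


class TestRotateSegment:
    def test_zero_rotation_is_identity(self):
        m = model_at(-174.0)
        before, after = all_coords(m), all_coords(rotate_segment(m, 3, 0.0))
        for key in before:
            assert np.allclose(before[key], after[key], atol=1e-12)

    def test_inverse_composition_restores_coordinates(self):
        m = model_at(-174.0)
        back = rotate_segment(rotate_segment(m, 3, 10.0), 3, -10.0)
        before, after = all_coords(m), all_coords(back)
        for key in before:
            assert np.allclose(before[key], after[key], atol=1e-6)

    def test_trans_to_syn_rotation(self):
        # +84 deg from -174 reaches the syn geometry at -90
        m = rotate_segment(model_at(-174.0), 3, 84.0)
        assert measure_omega(m, 3) == pytest.approx(-90.0, abs=1e-6)

    @pytest.mark.parametrize("delta", [-133.7, -30.0, 45.5, 170.0])
    def test_omega_changes_by_exactly_delta(self, delta):
        m = model_at(-174.0)
        out = rotate_segment(m, 3, delta)
        achieved = wrap_angle(measure_omega(out, 3) - (-174.0))
        assert achieved == pytest.approx(wrap_angle(delta), abs=1e-6)

    def test_isometry_within_moving_and_fixed_sets(self):
        m = model_at(-174.0)
        out = rotate_segment(m, 3, 84.0)
        before, after = all_coords(m), all_coords(out)
        moving = [k for k in before if k[0] < 3]
        fixed = [k for k in before if k[0] >= 3]
        for group in (moving, fixed):
            for i, ki in enumerate(group):
                for kj in group[i + 1:]:
                    d0 = np.linalg.norm(before[ki] - before[kj])
                    d1 = np.linalg.norm(after[ki] - after[kj])
                    assert abs(d0 - d1) < 1e-6

    def test_set_measure_roundtrip(self):
        m = model_at(-174.0)
        for target in (-174.0, -90.0, -35.4, 0.0, 121.2, 180.0):
            assert measure_omega(set_omega(m, 3, target), 3) == pytest.approx(
                target, abs=1e-3)


class TestHbondGeometry:
    def test_collinear_arrangement(self):
        d, theta = hbond_geometry([0, 0, -1.01], [0, 0, 0], [0, 0, 2.0])
        assert d == pytest.approx(2.0) and theta == pytest.approx(180.0)

    def test_right_angle_arrangement(self):
        d, theta = hbond_geometry([0, 1.01, 0], [0, 0, 0], [2.5, 0, 0])
        assert theta == pytest.approx(90.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n, h, o = np.array([0, 1.01, 0.0]), np.zeros(3), np.array([2.1, 0.5, -0.3])
        d0, t0 = hbond_geometry(n, h, o)
        # random proper rotation + translation
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-50, 50, 3)
        d1, t1 = hbond_geometry(q @ n + shift, q @ h + shift, q @ o + shift)
        assert d1 == pytest.approx(d0, abs=1e-9)
        assert t1 == pytest.approx(t0, abs=1e-9)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            hbond_geometry([0, 0, 0], [0, 0, 0], [1, 1, 1])


class TestClassifyHbond:
    @pytest.mark.parametrize("d,theta,expected", [
        (2.1, 152.0, "strong"),   # syn-state snapshot geometry
        (4.3, 134.0, "none"),     # trans-state snapshot geometry
        (2.49, 130.0, "strong"),  # boundary: inside on both criteria
        (2.51, 179.0, "none"),    # distance just outside
        (2.0, 129.9, "none"),     # angle just outside
    ])
    def test_threshold_behaviour(self, d, theta, expected):
        assert classify_hbond(d, theta) == expected


class TestTrackScan:
    def test_closest_approach_at_syn_window(self, coarse_scan, coarse_scan_spec):
        frames, summary = track_scan(
            coarse_scan, "B:1:H", "A:2:O", 3, coarse_scan_spec.schedule())
        # probe is built to meet the carbonyl O exactly at omega = -90
        assert summary["closest_approach_omega"] == pytest.approx(-90.0, abs=1e-6)
        assert summary["closest_approach_A"] == pytest.approx(2.1, abs=1e-6)
        syn = next(f for f in frames if abs(f.omega + 90.0) < 1e-6)
        assert syn.hbond_class == "strong"
        assert syn.theta_NHO == pytest.approx(180.0, abs=1e-6)
        assert summary["first_strong_ns"] is not None

    def test_far_probe_never_bonds(self, coarse_scan_spec):
        spec = sd.PeptideScanSpec(
            **{**coarse_scan_spec.__dict__,
               "acceptor_site": {"N": (50.0, 50.0, 51.01), "H": (50.0, 50.0, 50.0)}})
        st_far = sd.generate_peptide_scan(spec)
        _, summary = track_scan(st_far, "B:1:H", "A:2:O", 3, spec.schedule())
        assert summary["n_strong"] == 0 and summary["first_strong_ns"] is None

    def test_reversed_schedule_preserves_per_omega_geometry(self, coarse_scan,
                                                            coarse_scan_spec):
        probe = {"N": tuple(get_atom_pos(coarse_scan[0], "B", 1, "N")),
                 "H": tuple(get_atom_pos(coarse_scan[0], "B", 1, "H"))}
        rev_spec = sd.PeptideScanSpec(
            n_residues=5, proline_index=3, start_omega=0.0, end_omega=-174.0,
            step=2.0, dwell=2.0, direction="counterclockwise", acceptor_site=probe)
        fwd, _ = track_scan(coarse_scan, "B:1:H", "A:2:O", 3,
                            coarse_scan_spec.schedule())
        rev, _ = track_scan(sd.generate_peptide_scan(rev_spec), "B:1:H", "A:2:O", 3,
                            rev_spec.schedule())
        fwd_by_omega = {round(f.omega, 6): (f.d_HO, f.theta_NHO) for f in fwd}
        for f in rev:
            d, theta = fwd_by_omega[round(f.omega, 6)]
            assert f.d_HO == pytest.approx(d, abs=1e-6)
            assert f.theta_NHO == pytest.approx(theta, abs=1e-6)

    def test_model_count_mismatch(self, coarse_scan):
        short = TorsionSchedule(start_omega=-174.0, end_omega=-170.0, step=2.0)
        with pytest.raises(ValueError, match="models"):
            track_scan(coarse_scan, "B:1:H", "A:2:O", 3, short)
        with pytest.warns(UserWarning):
            frames, _ = track_scan(coarse_scan, "B:1:H", "A:2:O", 3, short,
                                   on_mismatch="truncate")
        assert len(frames) == 3
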