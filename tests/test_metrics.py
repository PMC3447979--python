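"""Pore radius, tilt, RMSD, kink and symmetry metrics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from msclkit import (
    CGStructure,
    FixtureParams,
    MetricError,
    detect_kink,
    domain_rmsd,
    generate_pentamer,
    helix_tilt,
    kink_fraction,
    kinked,
    pentagon_apothem,
    pore_radius,
    radial_profile,
    relative_helix_rmsd,
    segment_rmsd,
    symmetry_deviation,
)

COS36 = np.cos(np.pi / 5)


def _pentagon(R, z=0.0, phase=0.0):
    ang = 2 * np.pi * np.arange(5) / 5 + phase
    return np.stack([R * np.cos(ang), R * np.sin(ang), np.full(5, z)], axis=1)


def _rigid(coords, rotvec, shift):
    rot = Rotation.from_rotvec(rotvec)
    return rot.apply(coords) + np.asarray(shift)


class TestPentagonApothem:
    @given(R=st.floats(0.1, 50.0), phase=st.floats(0.0, 2 * np.pi))
    def test_regular_closed_form(self, R, phase):
        """apothem(regular pentagon, R) = R cos36 to 1e-12 (relative)."""
        apo = pentagon_apothem(_pentagon(R, phase=phase))
        assert apo == pytest.approx(R * COS36, rel=1e-12)

    def test_fitted_plane_handles_tilted_rings(self):
        pts = _pentagon(1.0)
        tilted = _rigid(pts, [0.4, 0.2, 0.0], [1.0, -2.0, 3.0])
        assert pentagon_apothem(tilted, plane="fit") == pytest.approx(COS36, abs=1e-9)

    def test_irregular_pentagon_against_dense_sampling(self):
        """Oracle: minimum centroid distance over 1e5 points sampled on the edges."""
        pts = _pentagon(1.0)
        pts[2, :2] *= 0.55  # pull one vertex inward
        p2 = pts[:, :2]
        centroid = p2.mean(axis=0)
        t = np.linspace(0.0, 1.0, 20001)
        best = np.inf
        for i in range(5):
            a, b = p2[i], p2[(i + 1) % 5]
            seg = a[None, :] + t[:, None] * (b - a)[None, :]
            best = min(best, np.linalg.norm(seg - centroid, axis=1).min())
        assert pentagon_apothem(pts) == pytest.approx(best, abs=1e-6)

    def test_coincident_points_rejected(self):
        pts = _pentagon(1.0)
        pts[1] = pts[0]
        with pytest.raises(MetricError):
            pentagon_apothem(pts)

    def test_self_intersection_warns_but_returns(self):
        pts = _pentagon(1.0)
        pts[[1, 3]] = pts[[3, 1]]  # bow-tie ordering
        with pytest.warns(UserWarning, match="self-intersecting"):
            val = pentagon_apothem(pts)
        assert np.isfinite(val)


class TestPoreRadius:
    def test_c5_fixture_apothems_equal_at_same_ring_radius(self):
        s = generate_pentamer(FixtureParams(tilt_tm1=0.0, tilt_tm2=0.0))
        prof = pore_radius(s)
        expected = 1.0513 * COS36
        for apo in prof.per_residue.values():
            assert apo == pytest.approx(expected, abs=1e-12)
        assert prof.gate_radius == pytest.approx(expected, abs=1e-12)

    def test_gate_radius_mean_is_tilt_independent(self, closed_structure):
        # radial tilt pivots at the gate centre, so the mean stays exact
        prof = pore_radius(closed_structure)
        assert prof.gate_radius == pytest.approx(1.0513 * COS36, abs=1e-9)

    def test_missing_residue_raises(self, closed_structure):
        with pytest.raises(Exception):
            pore_radius(closed_structure, residues=[9999])


class TestRadialProfile:
    def test_c5_symmetry_across_subunits(self, closed_structure):
        prof = radial_profile(closed_structure)
        spread = prof.groupby("residue")["r_nm"].agg(lambda v: v.max() - v.min())
        assert spread.max() < 1e-9

    def test_translation_invariance(self, closed_structure):
        rng = np.random.default_rng(7)
        shifted = closed_structure.with_coords(closed_structure.coords + rng.normal(size=3))
        a = radial_profile(closed_structure)["r_nm"].to_numpy()
        b = radial_profile(shifted)["r_nm"].to_numpy()
        assert np.abs(a - b).max() < 1e-9


class TestHelixTilt:
    def test_straight_helix_along_z(self):
        s = generate_pentamer(FixtureParams(tilt_tm1=0.0))
        for su in range(5):
            assert helix_tilt(s, "TM1", su) == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_helix_is_90_degrees(self):
        rows = [
            {"subunit": 0, "residue": 15 + i, "role": "BB", "x": 0.36 * i, "y": 1.0, "z": 2.0}
            for i in range(8)
        ]
        s = CGStructure(pd.DataFrame(rows))
        assert helix_tilt(s, "TM1", 0) == pytest.approx(90.0, abs=1e-9)

    def test_fixture_ground_truth(self, closed_structure):
        assert helix_tilt(closed_structure, "TM1") == pytest.approx(42.0, abs=1e-9)
        assert helix_tilt(closed_structure, "TM2") == pytest.approx(28.0, abs=1e-9)

    def test_too_few_beads(self, closed_structure):
        with pytest.raises(MetricError):
            helix_tilt(closed_structure, (20, 22), 0)


class TestDomainRMSD:
    def test_self_comparison_is_zero(self, closed_structure):
        assert domain_rmsd(closed_structure, closed_structure) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, closed_structure):
        moved = closed_structure.with_coords(
            _rigid(closed_structure.coords, [0.3, -0.2, 0.5], [2.0, 1.0, -3.0])
        )
        assert domain_rmsd(closed_structure, moved) == pytest.approx(0.0, abs=1e-9)
        assert domain_rmsd(closed_structure, moved, domain="TM1") == pytest.approx(0.0, abs=1e-9)

    def test_three_bead_toy_against_brute_force(self):
        """Oracle: numerical minimisation of RMSD over all rigid transforms."""
        a_pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        b_pts = np.array([[0.0, 0.2, 0], [1.1, 0, 0], [2.0, -0.1, 0.3]])

        def mk(pts):
            rows = [
                {"subunit": 0, "residue": i + 1, "role": "BB",
                 "x": p[0], "y": p[1], "z": p[2]}
                for i, p in enumerate(pts)
            ]
            return CGStructure(pd.DataFrame(rows))

        got = domain_rmsd(mk(a_pts), mk(b_pts), align="whole")

        def objective(x):
            fitted = Rotation.from_rotvec(x[:3]).apply(b_pts) + x[3:]
            return np.sqrt(np.mean(np.sum((a_pts - fitted) ** 2, axis=1)))

        starts = (np.zeros(6), np.array([0.1, -0.2, 0.3, 0.0, 0.1, 0.0]))
        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in starts
        )
        assert got == pytest.approx(best, abs=1e-6)

    def test_mismatched_beads_rejected(self, closed_structure):
        trimmed = closed_structure.select((1, 100))
        with pytest.raises(MetricError):
            domain_rmsd(closed_structure, trimmed)


class TestSegmentRMSD:
    def test_identical_structures_all_zero(self, closed_structure):
        prof = segment_rmsd(closed_structure, closed_structure, domain="TM1")
        assert (prof.values["rmsd_nm"] < 1e-12).all()

    def test_rigid_domain_motion_invisible_to_segments(self, closed_structure):
        """Rigid-body motion: segment RMSD ~0 while whole-protein RMSD is large."""
        df = closed_structure.beads.copy()
        tm1 = (df["residue"] >= 15) & (df["residue"] <= 45)
        df.loc[tm1, ["x", "y", "z"]] += [0.8, -0.5, 0.3]
        moved = CGStructure(df)
        prof = segment_rmsd(closed_structure, moved, domain="TM1")
        assert prof.values["rmsd_nm"].max() < 0.02
        assert domain_rmsd(closed_structure, moved, domain="TM1", align="whole") > 0.3

    def test_kink_elevates_only_spanning_segments(self, closed_params):
        s_kink = generate_pentamer(kinked(closed_params, 30.0, 40))
        ref = generate_pentamer(closed_params)
        prof = segment_rmsd(ref, s_kink, domain="TM1", stride=1)
        per_res = prof.per_residue()
        inside = per_res.loc[38:44]
        outside = per_res.drop(per_res.loc[38:44].index)
        assert inside.max() > 0.03  # deformation visible where windows span the kink
        assert outside.max() < 1e-9  # straight everywhere else

    def test_window_longer_than_helix(self, closed_structure):
        with pytest.raises(MetricError):
            segment_rmsd(closed_structure, closed_structure, window=50, domain="TM1")


class TestDetectKink:
    def test_reference_itself_unkinked(self, closed_structure):
        rep = detect_kink(closed_structure, closed_structure)
        assert rep.fraction == 0.0
        assert all(not r.kink_present for r in rep)

    def test_planted_kink_recovered(self, closed_params):
        s = generate_pentamer(kinked(closed_params, 30.0, 40))
        ref = generate_pentamer(closed_params)
        rep = detect_kink(s, ref)
        assert rep.fraction == 100.0
        for r in rep:
            assert r.kink_angle == pytest.approx(30.0, abs=2.0)
            assert abs(r.kink_residue - 40) <= 2
        assert sum(rep.histogram.values()) == 5
        assert all(38 <= res <= 44 for res in rep.histogram)

    def test_interval_too_short(self, closed_structure):
        with pytest.raises(MetricError):
            detect_kink(closed_structure, closed_structure, helix=(20, 26))


class TestKinkFraction:
    def test_all_straight(self, closed_structure):
        assert kink_fraction([closed_structure] * 3, closed_structure) == 0.0

    def test_mixed_ensemble_counting(self, closed_params):
        ref = generate_pentamer(closed_params)
        bent = generate_pentamer(kinked(closed_params, 30.0, 40))
        # 2 structures, 5 of 10 subunits kinked
        assert kink_fraction([ref, bent], ref) == 50.0
        # 5 structures, 2 kinked -> 40%
        assert kink_fraction([bent, bent, ref, ref, ref], ref) == 40.0

    def test_empty_list_rejected(self, closed_structure):
        with pytest.raises(MetricError):
            kink_fraction([], closed_structure)


class TestRelativeHelixRMSD:
    @pytest.mark.parametrize("pairing", ["same_subunit", "neighbour_subunit", "all_TM"])
    def test_identical_structures(self, closed_structure, pairing):
        assert relative_helix_rmsd(closed_structure, closed_structure, pairing) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rigid_pair_motion_signature(self, closed_structure):
        """Helix pairs moved as rigid units: pair RMSD ~0, all-TM RMSD large."""
        df = closed_structure.beads.copy()
        for su in range(5):
            pair = (
                (df["subunit"] == su) & (df["residue"] >= 15) & (df["residue"] <= 45)
            ) | (
                (df["subunit"] == (su + 1) % 5)
                & (df["residue"] >= 75)
                & (df["residue"] <= 107)
            )
            # radial shove of each TM1_i/TM2_{i+1} pair, different per pair
            ang = np.deg2rad(72.0 * su)
            df.loc[pair, ["x", "y"]] += 0.5 * (su + 1) / 5 * np.array(
                [np.cos(ang), np.sin(ang)]
            )
        moved = CGStructure(df)
        assert relative_helix_rmsd(closed_structure, moved, "neighbour_subunit") < 1e-9
        assert relative_helix_rmsd(closed_structure, moved, "all_TM") > 0.05

    def test_excluding_flagged_subunits(self, closed_structure):
        df = closed_structure.beads.copy()
        sel = (df["subunit"] == 2) & (df["residue"] >= 15) & (df["residue"] <= 45)
        df.loc[sel, "x"] += np.linspace(0, 1, sel.sum())  # deform subunit 2's TM1
        deformed = CGStructure(df)
        with_all = relative_helix_rmsd(closed_structure, deformed, "same_subunit")
        without = relative_helix_rmsd(
            closed_structure, deformed, "same_subunit", exclude_subunits=(2,)
        )
        assert without < with_all


class TestSymmetryDeviation:
    def test_exact_c5_is_zero(self, closed_structure):
        assert symmetry_deviation(closed_structure) == pytest.approx(0.0, abs=1e-9)

    def test_grows_with_noise(self, closed_params):
        devs = []
        for sigma in (0.01, 0.05, 0.1):
            vals = [
                symmetry_deviation(
                    generate_pentamer(
                        dataclasses.replace(closed_params, noise_sigma=sigma, seed=seed)
                    )
                )
                for seed in range(5)
            ]
            devs.append(np.mean(vals))
        assert devs[0] < devs[1] < devs[2]

    def test_single_displaced_subunit_localises(self, closed_structure):
        df = closed_structure.beads.copy()
        df.loc[df["subunit"] == 3, ["x", "y"]] += [0.6, -0.4]
        moved = CGStructure(df)
        per = symmetry_deviation(moved, per_subunit=True)
        assert max(per, key=per.get) == 3
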