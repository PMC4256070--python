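import numpy as np
import pytest

from channelkit.elastic import (
    build_kirchhoff,
    decompose,
    degenerate_groups,
    gnm_correlation,
    mode_shape,
    normalized_cross_correlation,
)
from channelkit.errors import AnalysisError, NetworkError
from channelkit.modes import (
    MotionGroup,
    associate_modes,
    compare_variants,
    detect_hinges,
    domain_correlation_summary,
    domain_rotation_angle,
    edge_conformations,
)
from channelkit.structures import delete_domain, symmetry_axis
from conftest import random_structure


class TestDetectHinges:
    def test_v_shaped_profile_single_minimum(self):
        n = 31
        profile = np.abs(np.arange(n) - 15).astype(float) + 1.0
        ranges = detect_hinges(profile, window=3, floor_quantile=0.15)
        assert len(ranges) == 1
        chain, start, end = ranges[0]
        assert start <= 16 <= end  # residue numbering is 1-based

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(0)
        profile = rng.random(50) + 0.1
        assert detect_hinges(profile) == detect_hinges(1e6 * profile)

    def test_flat_profile_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            ranges = detect_hinges(np.ones(30))
        assert ranges == []
        assert any("flat" in r.message for r in caplog.records)

    def test_c4_bundle_hinges_identical_across_chains(self, bundle, bundle_gnm):
        shape = mode_shape(bundle_gnm, 1)
        ranges = detect_hinges(
            shape, chain_ids=bundle.chain_ids, res_numbers=bundle.res_numbers
        )
        per_chain = {}
        for chain, start, end in ranges:
            per_chain.setdefault(chain, []).append((start, end))
        assert set(per_chain) == {"A", "B", "C", "D"}
        assert len({tuple(v) for v in per_chain.values()}) == 1

    def test_profile_shorter_than_window_is_error(self):
        with pytest.raises(AnalysisError, match="window"):
            detect_hinges(np.arange(4.0), window=5)


class TestAssociateModes:
    def test_identical_profiles_identity_pairing(self):
        rng = np.random.default_rng(1)
        profiles = [rng.random(40) for _ in range(4)]
        result = associate_modes(profiles, profiles)
        for k, entry in enumerate(result, start=1):
            assert entry["anm"] == k
            assert entry["score"] == pytest.approx(1.0)

    def test_small_noise_recovers_identity_pairing(self):
        rng = np.random.default_rng(42)
        profiles = [rng.random(60) for _ in range(5)]
        noisy = [p + rng.normal(0, 0.01 * np.ptp(p), len(p)) for p in profiles]
        result = associate_modes(profiles, noisy)
        assert [e["anm"] for e in result] == [1, 2, 3, 4, 5]

    def test_constant_profile_reported_missing(self):
        result = associate_modes([np.ones(10)], [np.arange(10.0)])
        assert result[0]["anm"] is None and result[0]["score"] is None

    def test_tie_breaks_toward_slower_anm_mode(self):
        p = np.arange(20.0)
        result = associate_modes([p], [p.copy(), p.copy()])
        assert result[0]["anm"] == 1

    def test_empty_inputs_are_error(self):
        with pytest.raises(AnalysisError):
            associate_modes([], [np.arange(5.0)])

    def test_bundle_slowest_gnm_matches_slow_anm_mode(self, bundle_gnm, bundle_anm):
        gshape = mode_shape(bundle_gnm, 1)
        anm_shapes = {k: mode_shape(bundle_anm, k) for k in range(1, 16)}
        entry = associate_modes({"I": gshape}, anm_shapes)[0]
        assert entry["anm"] is not None  # a genuine (non-rigid-body) slow mode
        assert entry["score"] > 0.7


class TestEdgeConformations:
    def test_zero_amplitude_returns_input(self, bundle, bundle_anm):
        edge = edge_conformations(bundle, bundle_anm, mode=1, amplitude=0.0)
        np.testing.assert_array_equal(edge.plus.coords, bundle.coords)
        np.testing.assert_array_equal(edge.minus.coords, bundle.coords)

    def test_plus_minus_symmetric_about_equilibrium(self, bundle, bundle_anm):
        edge = edge_conformations(bundle, bundle_anm, mode=2)
        np.testing.assert_allclose(
            edge.plus.coords - bundle.coords,
            -(edge.minus.coords - bundle.coords),
            atol=1e-12,
        )
        rmsd_plus = np.sqrt(np.mean((edge.plus.coords - bundle.coords) ** 2))
        rmsd_minus = np.sqrt(np.mean((edge.minus.coords - bundle.coords) ** 2))
        assert rmsd_plus == pytest.approx(rmsd_minus)

    def test_default_amplitude_caps_max_displacement(self, bundle, bundle_anm):
        edge = edge_conformations(bundle, bundle_anm, mode=1, max_displacement=2.0)
        disp = np.linalg.norm(edge.plus.coords - bundle.coords, axis=1)
        assert np.max(disp) == pytest.approx(2.0)

    def test_doubling_amplitude_doubles_displacement_collinearly(self, bundle, bundle_anm):
        e1 = edge_conformations(bundle, bundle_anm, mode=1, amplitude=0.5)
        e2 = edge_conformations(bundle, bundle_anm, mode=1, amplitude=1.0)
        np.testing.assert_allclose(
            e2.plus.coords - bundle.coords,
            2 * (e1.plus.coords - bundle.coords),
            atol=1e-12,
        )

    def test_gnm_decomposition_rejected(self, bundle, bundle_gnm):
        with pytest.raises(NetworkError, match="ANM"):
            edge_conformations(bundle, bundle_gnm, mode=1)

    def test_out_of_range_mode_is_error(self, bundle, bundle_anm):
        with pytest.raises(NetworkError):
            edge_conformations(bundle, bundle_anm, mode=0)


class TestDomainRotationAngle:
    def test_identity_gives_zero(self, bundle):
        assert domain_rotation_angle(bundle, bundle, "TM", [0, 0, 1]) == pytest.approx(0.0)

    def test_planted_rotation_recovered(self, bundle):
        theta = np.radians(5.0)
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        mask = bundle.annotation_mask("TM")
        coords = bundle.coords.copy()
        origin = bundle.coords.mean(axis=0)
        coords[mask] = (coords[mask] - origin) @ R.T + origin
        displaced = bundle.with_coords(coords)
        angle = domain_rotation_angle(bundle, displaced, "TM", [0, 0, 1])
        assert angle == pytest.approx(5.0, abs=0.1)

    def test_antisymmetric_under_swap(self, bundle, bundle_anm):
        edge = edge_conformations(bundle, bundle_anm, mode=1)
        fwd = domain_rotation_angle(bundle, edge.plus, "TM", [0, 0, 1])
        rev = domain_rotation_angle(edge.plus, bundle, "TM", [0, 0, 1])
        assert fwd == pytest.approx(-rev, abs=1e-6)

    def test_small_domain_is_error(self):
        s = random_structure(5, seed=0)
        s.annotate("tiny", {"A": [(1, 2)]})
        with pytest.raises(AnalysisError, match="fewer than 3"):
            domain_rotation_angle(s, s, "tiny", [0, 0, 1])


class TestCounterRotationPhenotype:
    """The slowest non-degenerate mode of a C4 bundle counter-rotates the
    upper (TM) and lower (cytosolic) halves about the symmetry axis."""

    def test_tm_and_cytosolic_rotate_oppositely(self, bundle, bundle_gnm, bundle_anm):
        groups = degenerate_groups(bundle_gnm, n_modes=6)
        assert len(groups[0]) == 1  # slowest mode is non-degenerate
        gshape = mode_shape(bundle_gnm, 1)
        anm_shapes = {k: mode_shape(bundle_anm, k) for k in range(1, 16)}
        anm_mode = associate_modes({"I": gshape}, anm_shapes)[0]["anm"]
        edge = edge_conformations(bundle, bundle_anm, anm_mode)
        axis = symmetry_axis(bundle)
        tm = domain_rotation_angle(bundle, edge.plus, "TM", axis)
        cyto = domain_rotation_angle(bundle, edge.plus, "cytosolic", axis)
        assert tm * cyto < 0
        assert abs(tm) > 0.01 and abs(cyto) > 0.01


class TestCompareVariants:
    def make_groups(self, shapes):
        return [
            MotionGroup(label=lab, gnm_modes=[i + 1], shape=shape)
            for i, (lab, shape) in enumerate(shapes.items())
        ]

    def test_identical_inputs_all_ones(self):
        rng = np.random.default_rng(3)
        shapes = {"I": rng.random(30), "II": rng.random(30)}
        groups = self.make_groups(shapes)
        mapping = {i: i for i in range(30)}
        report = compare_variants(groups, groups, mapping)
        assert all(v == pytest.approx(1.0) for v in report["per_motion"].values())

    def test_motion_missing_in_reduced_is_flagged(self):
        rng = np.random.default_rng(4)
        full = self.make_groups({"I": rng.random(20), "II": rng.random(20)})
        reduced = self.make_groups({"I": rng.random(20)})
        report = compare_variants(full, reduced, {i: i for i in range(20)})
        assert report["only_in_full"] == ["II"]

    def test_empty_mapping_is_error(self):
        groups = self.make_groups({"I": np.arange(10.0)})
        with pytest.raises(AnalysisError, match="empty"):
            compare_variants(groups, groups, {})

    def test_domain_deletion_keeps_slow_dynamics_but_softens_pore(self, bundle):
        """Deleting the outer (TM) half leaves the cytosolic fluctuation
        pattern correlated and increases shared-residue mobility."""
        reduced = delete_domain(bundle, "TM")
        d_full = decompose(build_kirchhoff(bundle))
        d_red = decompose(build_kirchhoff(reduced))
        full_msf = np.diag(gnm_correlation(d_full, "all"))
        red_msf = np.diag(gnm_correlation(d_red, "all"))
        shared_full = [
            i
            for i, (c, n) in enumerate(zip(bundle.chain_ids, bundle.res_numbers))
            if (c, n) in set(zip(reduced.chain_ids, reduced.res_numbers))
        ]
        # removing half the network frees the remaining residues
        assert np.mean(red_msf) > np.mean(full_msf[shared_full])


class TestDomainCorrelationSummary:
    def test_summary_over_domain_pairs(self, bundle, bundle_gnm):
        norm = normalized_cross_correlation(gnm_correlation(bundle_gnm, "all"))
        summary = domain_correlation_summary(norm, bundle, ["TM", "cytosolic"])
        assert set(summary) == {("TM", "TM"), ("TM", "cytosolic"), ("cytosolic", "cytosolic")}
        assert summary[("TM", "TM")] > summary[("TM", "cytosolic")]
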