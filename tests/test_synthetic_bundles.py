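"""Generator correctness: geometry ground truth, distortions, determinism."""

import numpy as np
import pytest

from coilmap import (
    CrickParams,
    SegmentOverride,
    assign_sequence,
    generate_crick_bundle,
    generate_family,
    generate_melt_curve,
    inject_distortion,
)
from coilmap.synthetic_bundles import PHASE_BIN


class TestCrickParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CrickParams(n_residues=5)
        with pytest.raises(ValueError):
            CrickParams(superhelix_radius=-1.0)
        with pytest.raises(ValueError):
            CrickParams(superhelix_freq=-110.0)  # |w0| >= w1

    def test_overlapping_segments_rejected(self):
        segs = (
            SegmentOverride(10, 30, superhelix_freq=0.0),
            SegmentOverride(25, 40, superhelix_freq=1.0),
        )
        with pytest.raises(ValueError, match="overlap"):
            CrickParams(n_residues=100, segments=segs)

    def test_ground_truth_register_is_heptad_periodic(self):
        reg = CrickParams(n_residues=70).ground_truth_register()
        assert reg == "abcdefg" * 10


class TestGenerateBundle:
    def test_no_supercoil_gives_straight_parallel_axes(self):
        """ω0 = 0: each chain is a straight helix at distance R0 from the
        global axis; the two chains' axis lines are 2·R0 apart."""
        p = CrickParams(n_residues=60, superhelix_freq=0.0)
        b = generate_crick_bundle(p)
        from coilmap import helix_axis_trace

        axes = [helix_axis_trace(c.ca_coords) for c in b.chains]
        pts = [t.points[t.valid] for t in axes]
        for pt in pts:
            # colinearity: residuals from the best-fit line are ~0
            centered = pt - pt.mean(axis=0)
            _, s, _ = np.linalg.svd(centered, full_matrices=False)
            assert s[1] < 0.05
            assert np.allclose(
                np.hypot(pt[:, 0], pt[:, 1]), p.superhelix_radius, atol=0.05
            )
        gap = np.linalg.norm(pts[0][:, :2] - pts[1][:, :2], axis=1)
        assert np.allclose(gap, 2 * p.superhelix_radius, atol=0.05)

    def test_sequence_length_checked(self):
        p = CrickParams(n_residues=30)
        with pytest.raises(ValueError):
            generate_crick_bundle(p, sequence="AAA")

    def test_chains_related_by_phase_offset_rotation(self):
        p = CrickParams(n_residues=40)
        b = generate_crick_bundle(p)
        ang = np.deg2rad(180.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        assert np.allclose(
            b.chains[1].ca_coords, b.chains[0].ca_coords @ rot.T, atol=1e-9
        )

    def test_rotating_all_chain_offsets_is_a_rigid_rotation(self):
        p1 = CrickParams(n_residues=40)
        p2 = CrickParams(n_residues=40, chain_phase_offsets=(30.0, 210.0))
        b1, b2 = generate_crick_bundle(p1), generate_crick_bundle(p2)
        ang = np.deg2rad(30.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        for c1, c2 in zip(b1.chains, b2.chains):
            assert np.allclose(c2.ca_coords, c1.ca_coords @ rot.T, atol=1e-9)


class TestInjectDistortion:
    def test_identity_without_call(self):
        p = CrickParams(n_residues=100)
        assert p.segments == ()

    @pytest.mark.parametrize(
        "kind,expected_jump",
        [("stutter", -PHASE_BIN), ("stammer", 4 * PHASE_BIN)],
    )
    def test_register_jump_kinds(self, kind, expected_jump):
        p = inject_distortion(CrickParams(n_residues=100), 36, kind)
        (seg,) = p.segments
        assert (seg.start, seg.end) == (36, 36)
        assert seg.phase_jump == pytest.approx(expected_jump)

    def test_planted_stutter_changes_register_by_advance_4(self):
        p = inject_distortion(CrickParams(n_residues=100), 36, "stutter")
        reg = p.ground_truth_register()
        before, after = reg[34], reg[35]  # residues 35, 36
        advance = ("abcdefg".index(after) - "abcdefg".index(before)) % 7
        assert advance == 4

    def test_segment_kinds_override_supercoil(self):
        p = inject_distortion(CrickParams(n_residues=100), 40, "unwound", length=20)
        (seg,) = p.segments
        assert (seg.start, seg.end, seg.superhelix_freq) == (40, 59, 0.0)
        p = inject_distortion(CrickParams(n_residues=100), 40, "right_handed")
        assert p.segments[0].superhelix_freq == 3.6

    def test_overlapping_injection_rejected(self):
        p = inject_distortion(CrickParams(n_residues=100), 40, "unwound")
        with pytest.raises(ValueError):
            inject_distortion(p, 45, "right_handed")

    def test_terminal_start_rejected(self):
        with pytest.raises(ValueError):
            inject_distortion(CrickParams(n_residues=100), 1, "stutter")


class TestGenerateFamily:
    def test_planted_counts_are_exact(self):
        tracks = generate_family(100, {"cc_high": 0.97}, seed=0)
        n_high = sum(t.labels["cc_high"] for t in tracks)
        n_ct = sum(t.labels["cc_cterminal"] for t in tracks)
        assert (n_high, n_ct) == (97, 97)

    def test_all_fractions_zero(self):
        (track,) = generate_family(1, {"cc_high": 0.0, "cc_cterminal": 0.0}, seed=0)
        assert track.probs.max() < 0.5

    def test_determinism(self):
        a = generate_family(20, {"cc_high": 0.8, "noncanonical": 0.5}, seed=7)
        b = generate_family(20, {"cc_high": 0.8, "noncanonical": 0.5}, seed=7)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.probs, tb.probs)
            assert ta.heptad == tb.heptad
            assert ta.labels == tb.labels

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_family(10, {"cc_high": 0.2, "cc_cterminal": 0.5}, seed=0)
        with pytest.raises(ValueError):
            generate_family(10, {"cc_high": 0.8, "cc_medium_only": 0.5}, seed=0)


class TestGenerateMeltCurve:
    def test_noiseless_curve_is_exact_logistic(self):
        c = generate_melt_curve(42.0, slope=2.0, noise_sd=0.0)
        frac = (c.signal - c.signal[0]) / (c.signal[-1] - c.signal[0])
        mid = np.interp(0.5, frac, c.temperatures)
        assert mid == pytest.approx(42.0, abs=0.1)

    def test_default_grid_matches_protocol(self):
        c = generate_melt_curve(42.0)
        assert c.temperatures[0] == 10.0 and c.temperatures[-1] == 90.0
        assert np.all(np.diff(c.temperatures) == 2.0)

    def test_tm_outside_grid_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            generate_melt_curve(150.0)

    def test_noise_determinism(self):
        a = generate_melt_curve(42.0, noise_sd=100.0, seed=3)
        b = generate_melt_curve(42.0, noise_sd=100.0, seed=3)
        assert np.array_equal(a.signal, b.signal)


class TestAssignSequence:
    def test_pure_composition_gives_poly_ala(self):
        comp = {p: {"A": 1.0} for p in "abcdefg"}
        assert assign_sequence("abcdefg" * 3, comp, seed=0) == "A" * 21

    def test_empty_register_rejected(self):
        with pytest.raises(ValueError):
            assign_sequence("", {p: {"A": 1.0} for p in "abcdefg"})

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assign_sequence("abc", {"a": {"A": 1.0}})

    def test_composition_converges(self, rng):
        comp = {p: {"L": 1.0} if p in "ad" else {"S": 1.0} for p in "abcdefg"}
        seq = assign_sequence("abcdefg" * 100, comp, seed=1)
        reg = "abcdefg" * 100
        at_core = [s for s, r in zip(seq, reg) if r in "ad"]
        assert set(at_core) == {"L"}
        assert set(seq) == {"L", "S"}
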