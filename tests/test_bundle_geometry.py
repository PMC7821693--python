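"""Measurement correctness: round trips against the analytic generator,
rigid-motion invariance, and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coilmap import (
    Bundle,
    Chain,
    CrickParams,
    bundle_axis,
    generate_crick_bundle,
    helix_axis_trace,
    inject_distortion,
    measure_bundle,
    rmsd_trace,
)
from conftest import random_canonical_params


def rigid_transform(bundle, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50, 50, 3)
    chains = [
        Chain(c.residue_ids, c.residue_names, c.ca_coords @ rot.T + shift)
        for c in bundle.chains
    ]
    return Bundle(chains=chains, parallel=bundle.parallel)


class TestHelixAxisTrace:
    def test_straight_helix_axis_is_colinear(self):
        p = CrickParams(n_residues=40, superhelix_freq=0.0)
        b = generate_crick_bundle(p)
        tr = helix_axis_trace(b.chains[0].ca_coords)
        pts = tr.points[tr.valid]
        centered = pts - pts.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        assert s[1] < 0.05

    def test_supercoiled_axis_lies_on_r0_helix(self, canonical_params,
                                               canonical_bundle):
        tr = helix_axis_trace(canonical_bundle.chains[0].ca_coords)
        pts = tr.points[tr.valid]
        radius = np.hypot(pts[:, 0], pts[:, 1])
        assert np.allclose(radius, canonical_params.superhelix_radius, atol=0.1)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            helix_axis_trace(np.zeros((6, 3)))

    def test_axis_point_spacing(self, canonical_bundle):
        tr = helix_axis_trace(canonical_bundle.chains[0].ca_coords)
        pts = tr.points[tr.valid]
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all((gaps > 0.5) & (gaps < 2.5))


class TestBundleAxis:
    def test_midpoint_symmetry(self, canonical_bundle):
        traces = [helix_axis_trace(c.ca_coords) for c in canonical_bundle.chains]
        ax = bundle_axis(traces)
        ok = ax.valid
        d0 = np.linalg.norm(ax.points[ok] - traces[0].points[ok], axis=1)
        d1 = np.linalg.norm(ax.points[ok] - traces[1].points[ok], axis=1)
        assert np.allclose(d0, d1, atol=0.1)

    def test_single_trace_rejected(self, canonical_bundle):
        tr = helix_axis_trace(canonical_bundle.chains[0].ca_coords)
        with pytest.raises(ValueError):
            bundle_axis([tr])

    def test_reproduces_generator_axis(self, canonical_bundle):
        """The measured bundle axis is the generator's z-axis (within 0.1 Å)."""
        traces = [helix_axis_trace(c.ca_coords) for c in canonical_bundle.chains]
        ax = bundle_axis(traces)
        pts = ax.points[ax.valid]
        assert np.sqrt(np.mean(pts[:, 0] ** 2 + pts[:, 1] ** 2)) < 0.1


class TestLocalSupercoil:
    @pytest.mark.parametrize("w0", [-6.0, -3.6, -3.0, -2.0, 2.0, 3.6, 6.0])
    def test_round_trip_within_tolerance(self, w0):
        p = CrickParams(n_residues=120, superhelix_freq=w0)
        m = measure_bundle(generate_crick_bundle(p))
        v = m.supercoil.values
        ok = np.isfinite(v)
        assert ok.sum() > 100
        assert np.abs(v[ok] - w0).max() < 0.2

    def test_zero_supercoil_handedness_none(self):
        p = CrickParams(n_residues=60, superhelix_freq=0.0)
        m = measure_bundle(generate_crick_bundle(p))
        h = m.supercoil.handedness
        assert set(h[h != ""]) == {"none"}

    def test_left_handed_sign_convention(self, canonical_bundle):
        m = measure_bundle(canonical_bundle)
        v = m.supercoil.values
        assert np.nanmean(v) < 0
        h = m.supercoil.handedness
        assert set(h[h != ""]) == {"left"}

    def test_right_handed_segment_called_right(self):
        p = inject_distortion(
            CrickParams(n_residues=120), 50, "right_handed", length=20
        )
        m = measure_bundle(generate_crick_bundle(p))
        h = m.supercoil.handedness
        right = {i + 1 for i, x in enumerate(h) if x == "right"}
        assert right, "no right-handed layers found"
        assert min(right) >= 48 and max(right) <= 71  # planted 50-69 (+/- 2)
        assert {i for i in range(52, 68)} <= right

    def test_periodicity_is_360_over_supercoil(self, canonical_bundle):
        m = measure_bundle(canonical_bundle)
        per = m.supercoil.periodicity
        ok = np.isfinite(per)
        assert np.allclose(per[ok], 360.0 / np.abs(m.supercoil.values[ok]))

    def test_oracle_brute_force_projection(self):
        """Per-layer angular advance equals an explicit projection onto the
        plane normal to the bundle axis, computed independently."""
        p = CrickParams(n_residues=20)
        b = generate_crick_bundle(p)
        m = measure_bundle(b)
        traces = [helix_axis_trace(c.ca_coords) for c in b.chains]
        ax = bundle_axis(traces)
        # oracle: project chain-0 axis points into the plane normal to the
        # local bundle-axis direction, take the signed angle between layers
        vals = m.chain_supercoil[0].values
        for i in range(len(vals) - 1):
            if not np.isfinite(vals[i]):
                continue
            lo = i - 1 if ax.valid[i - 1] else i
            a = ax.points[i + 1] - ax.points[lo]
            a = a / np.linalg.norm(a)
            r1 = traces[0].points[i] - ax.points[i]
            r2 = traces[0].points[i + 1] - ax.points[i + 1]
            p1 = r1 - np.dot(r1, a) * a
            p2 = r2 - np.dot(r2, a) * a
            cosang = np.dot(p1, p2) / (np.linalg.norm(p1) * np.linalg.norm(p2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            sign = np.sign(np.dot(np.cross(p1, p2), a))
            assert sign * ang == pytest.approx(vals[i], abs=1e-6)


class TestCrickPhase:
    def test_round_trip_against_generator_phase(self, canonical_params,
                                                canonical_bundle):
        m = measure_bundle(canonical_bundle)
        gt = canonical_params.minor_phase() % 360.0
        for ph in m.phases:
            ok = ph.valid
            d = (ph.values[ok] - gt[ok] + 180.0) % 360.0 - 180.0
            assert np.abs(d).max() < 5.0

    def test_phase_increment_equals_minor_helix_frequency(self, canonical_params,
                                                          canonical_bundle):
        """In the core-referenced (rotating) frame the phase advances by ω1
        per residue; the supercoil rotation is part of the frame itself."""
        m = measure_bundle(canonical_bundle)
        ph = m.phases[0].values
        ok = np.flatnonzero(np.isfinite(ph))
        inc = (np.diff(ph[ok]) + 180.0) % 360.0 - 180.0
        assert np.allclose(inc, canonical_params.helix_freq, atol=1.0)

    def test_rigid_motion_invariance(self, canonical_bundle):
        m1 = measure_bundle(canonical_bundle)
        m2 = measure_bundle(rigid_transform(canonical_bundle, seed=11))
        for p1, p2 in zip(m1.phases, m2.phases):
            ok = p1.valid & p2.valid
            d = (p1.values[ok] - p2.values[ok] + 180.0) % 360.0 - 180.0
            assert np.abs(d).max() < 1e-6


class TestInvariance:
    def test_supercoil_invariant_under_rigid_motion_and_relabeling(self, rng):
        p = random_canonical_params(rng)
        b = generate_crick_bundle(p)
        m1 = measure_bundle(b)
        moved = rigid_transform(b, seed=5)
        swapped = Bundle(chains=moved.chains[::-1], parallel=True)
        m2 = measure_bundle(swapped)
        v1, v2 = m1.supercoil.values, m2.supercoil.values
        ok = np.isfinite(v1) & np.isfinite(v2)
        assert np.abs(v1[ok] - v2[ok]).max() < 1e-6

    def test_round_trip_over_random_canonical_draws(self, rng):
        for _ in range(10):
            p = random_canonical_params(rng)
            m = measure_bundle(generate_crick_bundle(p))
            v = m.supercoil.values
            ok = np.isfinite(v)
            assert np.abs(v[ok] - p.superhelix_freq).max() < 0.2


class TestRmsdTrace:
    def test_self_rmsd_zero(self, canonical_bundle):
        assert rmsd_trace([canonical_bundle])[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_rmsd_zero(self, canonical_bundle):
        moved = rigid_transform(canonical_bundle, seed=2)
        out = rmsd_trace([canonical_bundle, moved])
        assert out[1] == pytest.approx(0.0, abs=1e-6)

    def test_topology_mismatch_rejected(self, canonical_bundle):
        other = generate_crick_bundle(CrickParams(n_residues=100))
        with pytest.raises(ValueError, match="topology"):
            rmsd_trace([canonical_bundle, other])

    def test_against_brute_force_rotation_search(self):
        """Optimal-superposition RMSD on a 5-atom toy matches direct numeric
        minimization of the superposition objective over rotation vectors,
        restarted from a coarse random grid (independent of the closed-form
        quaternion solution)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(42)
        ref = rng.normal(size=(5, 3))
        mob = ref + rng.normal(scale=0.3, size=(5, 3))
        chains = lambda xyz: [
            Chain(np.arange(1, 6), ["A"] * 5, xyz),
            Chain(np.arange(1, 6), ["A"] * 5, xyz + [0, 0, 10]),
        ]
        out = rmsd_trace([Bundle(chains(ref)), Bundle(chains(mob))])
        stack_ref = np.vstack([ref, ref + [0, 0, 10]])
        stack_mob = np.vstack([mob, mob + [0, 0, 10]])
        rc = stack_ref - stack_ref.mean(axis=0)
        mc = stack_mob - stack_mob.mean(axis=0)

        def objective(rotvec):
            d = Rotation.from_rotvec(rotvec).apply(mc) - rc
            return np.sqrt(np.mean(np.sum(d**2, axis=1)))

        best = np.inf
        starts = [np.zeros(3)] + list(rng.uniform(-np.pi, np.pi, size=(20, 3)))
        for x0 in starts:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert out[1] <= best + 1e-6
        assert out[1] == pytest.approx(best, abs=1e-4)
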