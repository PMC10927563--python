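"""Ensemble observables: gyration geometry, asphericity limits, internal
scaling, power-law fits, the Gaussian-chain null model, and replicate
summaries — including ideal-chain recovery from simulation."""

import numpy as np
import pytest

from idrpipe import ensembles as ens
from idrpipe.simulate import Trajectory
from idrpipe.seqfeatures import SequenceRecord


def _rod(n, a=1.0):
    c = np.zeros((n, 3))
    c[:, 0] = a * np.arange(n)
    return c


ISOTROPIC6 = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0],
                       [0, -1, 0], [0, 0, 1], [0, 0, -1]])


class TestChainDimensions:
    def test_two_beads(self):
        rg, re, _ = ens.chain_dimensions(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        assert rg == pytest.approx(2.0)
        assert re == pytest.approx(4.0)

    def test_coincident_beads_zero_rg(self):
        rg, re, _ = ens.chain_dimensions(np.zeros((5, 3)))
        assert rg == 0.0 and re == 0.0

    def test_five_bead_rod(self):
        # positions 0,a,2a,3a,4a: sum (x - 2a)^2 / 5 = 2 a^2
        rg, re, _ = ens.chain_dimensions(_rod(5, a=1.3))
        assert rg ** 2 == pytest.approx(2 * 1.3 ** 2)
        assert re == pytest.approx(4 * 1.3)

    def test_tensor_trace_is_rg_squared(self):
        frame = np.random.default_rng(0).normal(size=(20, 3))
        rg, _, t = ens.chain_dimensions(frame)
        assert np.trace(t) == pytest.approx(rg ** 2)
        assert np.all(np.linalg.eigvalsh(t) >= -1e-12)


class TestAsphericity:
    def test_rod_is_one(self):
        assert ens.asphericity(_rod(5)) == pytest.approx(1.0)

    def test_isotropic_six_point_is_zero(self):
        assert ens.asphericity(ISOTROPIC6) == pytest.approx(0.0, abs=1e-12)

    def test_planar_isotropic_is_quarter(self):
        # eigenvalues (lam, lam, 0): 1 - 3 lam^2 / (2 lam)^2 = 1/4
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        assert ens.asphericity(ring) == pytest.approx(0.25)

    def test_bounded_for_random_ensembles(self):
        frames = np.random.default_rng(1).normal(size=(50, 12, 3))
        d = ens.asphericity(frames)
        assert 0.0 <= d <= 1.0
        d_pf = ens.asphericity(frames, per_frame=True)
        assert 0.0 <= d_pf <= 1.0

    def test_degenerate_frames_excluded(self):
        frames = np.concatenate([np.zeros((1, 4, 3)), np.random.default_rng(2).normal(size=(3, 4, 3))])
        with pytest.warns(UserWarning, match="degenerate"):
            d = ens.asphericity(frames)
        assert 0.0 <= d <= 1.0
        with pytest.raises(ValueError):
            ens.asphericity(np.zeros((2, 4, 3)))


class TestInternalScaling:
    def test_rigid_rod_profile_linear(self):
        prof = ens.internal_scaling(_rod(10, a=2.0))
        assert np.allclose(prof.distance, 2.0 * prof.delta)

    def test_single_frame_matches_brute_force(self):
        frame = np.random.default_rng(3).normal(scale=4.0, size=(8, 3))
        prof = ens.internal_scaling(frame)
        for d in range(1, 8):
            ref = np.mean([np.linalg.norm(frame[i + d] - frame[i])
                           for i in range(8 - d)])
            assert prof.distance[d - 1] == pytest.approx(ref)

    def test_profile_bond_separation(self, ideal100_traj, params):
        prof = ens.internal_scaling(ideal100_traj)
        assert prof.distance[0] == pytest.approx(params.bond.r0, rel=0.05)


class TestFitScalingLaw:
    def test_exact_power_law_recovered(self):
        delta = np.arange(1, 101)
        prof = ens.InternalScalingProfile(delta, 3.0 * delta ** 0.5, np.ones_like(delta))
        nu, r0, resid = ens.fit_scaling_law(prof)
        assert nu == pytest.approx(0.5, abs=1e-12)
        assert r0 == pytest.approx(3.0, rel=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-10)

    def test_rigid_rod_exponent_one(self):
        prof = ens.internal_scaling(_rod(40, a=1.7))
        nu, r0, _ = ens.fit_scaling_law(prof)
        assert nu == pytest.approx(1.0, abs=1e-10)
        assert r0 == pytest.approx(1.7, rel=1e-10)

    def test_noisy_power_law_close(self):
        rng = np.random.default_rng(4)
        delta = np.arange(1, 200)
        noisy = 2.5 * delta ** 0.62 * (1 + 0.01 * rng.standard_normal(len(delta)))
        prof = ens.InternalScalingProfile(delta, noisy, np.ones_like(delta))
        nu, _, _ = ens.fit_scaling_law(prof)
        assert nu == pytest.approx(0.62, abs=0.01)

    def test_too_few_points(self):
        delta = np.arange(1, 10)
        prof = ens.InternalScalingProfile(delta, 3.0 * delta ** 0.5, np.ones_like(delta))
        with pytest.raises(ValueError):
            ens.fit_scaling_law(prof, fit_min_delta=6)


class TestAfrcReference:
    def test_gaussian_ratio_for_all_lengths(self):
        for n in (10, 50, 500):
            rg, re = ens.afrc_reference(n)
            assert re / rg == pytest.approx(np.sqrt(6.0))

    def test_loglog_exponent_is_half(self):
        ns = np.array([50, 100, 200, 300, 400, 500])
        res = np.array([ens.afrc_reference(int(n))[1] for n in ns])
        slope = np.polyfit(np.log(ns), np.log(res), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_quadrupling_doubles(self):
        assert ens.afrc_reference(400)[1] == pytest.approx(2 * ens.afrc_reference(100)[1])

    def test_sequence_input_uses_length(self):
        assert ens.afrc_reference("G" * 64) == ens.afrc_reference(64)


class TestNormalizedDimensions:
    def test_null_is_unity(self):
        rg0, re0 = ens.afrc_reference(100)
        props = ens.EnsembleProperties(rg0, re0, 0.4, 0.5, 3.8)
        assert ens.normalized_dimensions(props, "G" * 100) == (pytest.approx(1.0),
                                                              pytest.approx(1.0))

    def test_rod_like_exceeds_unity(self):
        rg, re, _ = ens.chain_dimensions(_rod(100, a=3.8))
        props = ens.EnsembleProperties(rg, re, 1.0, 1.0, 3.8)
        nrg, nre = ens.normalized_dimensions(props, "G" * 100)
        assert nrg > 1 and nre > 1

    def test_globule_toy_below_unity(self):
        n = 3000
        rg_globule = 2.0 * n ** (1 / 3)
        props = ens.EnsembleProperties(rg_globule, rg_globule * 2, 0.1, 1 / 3, 2.0)
        nrg, _ = ens.normalized_dimensions(props, "G" * n)
        assert nrg < 1


class TestEnsembleSummary:
    def _toy_traj(self, shift=0.0):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=6.0, size=(30, 40, 3)) + shift
        return Trajectory(coords, SequenceRecord("t", "G" * 40), 1.0)

    def test_identical_replicates_zero_sem(self):
        t = self._toy_traj()
        props = ens.ensemble_summary([t, self._toy_traj()])
        assert props.sem_rg == 0.0 and props.sem_re == 0.0

    def test_single_replicate_sem_undefined(self):
        props = ens.ensemble_summary([self._toy_traj()])
        assert props.sem_rg is None and props.n_replicates == 1

    def test_two_point_sem_arithmetic(self):
        # replicate means m and m + d: mean = m + d/2, sem = d / 2
        a, b = self._toy_traj(), self._toy_traj()
        props_a = ens.ensemble_summary([a])
        b.coords = b.coords * 1.2
        props_b = ens.ensemble_summary([b])
        props = ens.ensemble_summary([a, b])
        d = props_b.mean_rg - props_a.mean_rg
        assert props.mean_rg == pytest.approx((props_a.mean_rg + props_b.mean_rg) / 2)
        assert props.sem_rg == pytest.approx(abs(d) / 2)

    def test_mismatched_sequences_rejected(self):
        t = self._toy_traj()
        other = Trajectory(t.coords, SequenceRecord("u", "A" * 40), 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            ens.ensemble_summary([t, other])


class TestIdealChainRecovery:
    def test_nu_is_half(self, ideal100_traj):
        """A chain with nonbonded terms zeroed is an ideal (Gaussian) chain:
        the fitted scaling exponent must be 0.5 within 0.03."""
        nu, _, _ = ens.fit_scaling_law(ens.internal_scaling(ideal100_traj))
        assert nu == pytest.approx(0.5, abs=0.03)

    def test_mean_square_ratio_is_six(self, ideal100_traj):
        """<Re^2>/<Rg^2> = 6 N/(N+1) ~ 6 for a Gaussian chain (5% band)."""
        coords = ideal100_traj.coords
        re2 = np.sum((coords[:, -1] - coords[:, 0]) ** 2, axis=1).mean()
        rg2 = np.mean([ens.chain_dimensions(f)[0] ** 2 for f in coords])
        assert re2 / rg2 == pytest.approx(6.0, rel=0.05)

    def test_excluded_volume_raises_nu(self, ideal100_traj, params):
        """Purely repulsive nonbonded terms (like charges, no short-range
        attraction) swell the chain above the ideal exponent."""
        from idrpipe import forcefield as ff
        from idrpipe import simulate as sim

        beads = {aa: ff.BeadType(aa, b.mass, 0.5, b.sigma)
                 for aa, b in params.beads.items()}
        pairs = {k: ff.PairParams(0.0, p.sigma, p.mu, p.nu_wf)
                 for k, p in params.pairs.items()}
        rep = ff.ParameterSet("custom", beads, pairs, params.bond, params.electro)
        seq = SequenceRecord("rep60", "G" * 60)
        ideal_seq = SequenceRecord("id60", "G" * 60)
        kw = dict(production=80.0, equilibration=4.0, save_interval=0.5)
        c0 = sim.build_initial_coil(seq, rep, seed=2)
        t_rep = sim.run_langevin(c0, seq, rep, sim.desk_config(seed=5, **kw))
        t_id = sim.run_langevin(c0.copy(), ideal_seq, params,
                                sim.desk_config(seed=5, nonbonded=False, **kw))
        nu_rep, _, _ = ens.fit_scaling_law(ens.internal_scaling(t_rep))
        nu_id, _, _ = ens.fit_scaling_law(ens.internal_scaling(t_id))
        assert nu_rep > nu_id
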