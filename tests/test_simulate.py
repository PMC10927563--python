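"""Langevin engine physics: coil construction, minimization, canonical
sampling of a harmonic dimer, thermostat accuracy, free diffusion, the
near-NVE limit, and trajectory I/O."""

import math

import numpy as np
import pytest
from scipy import integrate

from idrpipe import simulate as sim
from idrpipe._kernels import KB_KCAL, KCAL_TO_MV
from idrpipe.seqfeatures import SequenceRecord


class TestInitialCoil:
    def test_dimer_bond_length(self, params):
        c = sim.build_initial_coil(SequenceRecord("d", "GS"), params, seed=0)
        assert np.linalg.norm(c[1] - c[0]) == pytest.approx(params.bond.r0)

    def test_hard_core_respected(self, params):
        seq = SequenceRecord("c", "GSTNQ" * 10)
        c = sim.build_initial_coil(seq, params, seed=4)
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        iu = np.triu_indices(len(seq), k=2)
        assert d[iu].min() >= sim.COIL_HARD_CORE - 1e-9

    def test_deterministic(self, params):
        seq = SequenceRecord("c", "GSTNQ" * 6)
        a = sim.build_initial_coil(seq, params, seed=7)
        b = sim.build_initial_coil(seq, params, seed=7)
        assert np.array_equal(a, b)


class TestMinimize:
    def test_minimal_dimer_unchanged(self, params):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [20.0, 0, 0]])   # beyond all nonbonded cutoffs
        c0[1, 0] = params.bond.r0 + 20.0
        # place at exact bond length, far from nonbonded range of each other
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        out = sim.minimize(c0, seq, params, nonbonded=False)
        assert np.allclose(out, c0)

    def test_stretched_dimer_converges(self, params):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0 + 2.0, 0, 0]])
        out = sim.minimize(c0, seq, params, nonbonded=False, ftol=1e-10,
                           max_iters=5000)
        r = np.linalg.norm(out[1] - out[0])
        assert abs(r - params.bond.r0) < 1e-4

    def test_energy_non_increasing(self, params):
        from idrpipe.forcefield import total_energy_forces

        seq = SequenceRecord("c", "MKVAYDERKGMKVAYDERKG")
        c0 = sim.build_initial_coil(seq, params, seed=3)
        e0, _ = total_energy_forces(c0, seq, params, 500.0)
        out = sim.minimize(c0, seq, params)
        e1, _ = total_energy_forces(out, seq, params, 500.0)
        assert e1 <= e0


class TestRunLangevin:
    def test_frame_count_arithmetic(self, params):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        cfg = sim.SimulationConfig(production=1.0, equilibration=0.2,
                                   save_interval=0.1, seed=1)
        traj = sim.run_langevin(c0, seq, params, cfg)
        assert traj.n_frames == 10   # production / save_interval

    def test_bitwise_seed_determinism(self, params):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        cfg = sim.SimulationConfig(production=1.0, equilibration=0.2,
                                   save_interval=0.1, seed=5)
        a = sim.run_langevin(c0.copy(), seq, params, cfg)
        b = sim.run_langevin(c0.copy(), seq, params, cfg)
        assert np.array_equal(a.coords, b.coords)

    def test_dimer_bond_statistics_canonical(self, params, dimer_traj):
        """Mean and variance of the dimer bond length match the canonical
        closed form <f(r)> = int f(r) r^2 exp(-beta k (r-r0)^2) dr / Z."""
        beta = 1.0 / (KB_KCAL * 300.0)
        k, r0 = params.bond.k, params.bond.r0
        w = lambda r: r ** 2 * math.exp(-beta * k * (r - r0) ** 2)
        z, _ = integrate.quad(w, 0, 20)
        m1, _ = integrate.quad(lambda r: r * w(r), 0, 20)
        m2, _ = integrate.quad(lambda r: r * r * w(r), 0, 20)
        mean_ref, var_ref = m1 / z, m2 / z - (m1 / z) ** 2

        r = np.linalg.norm(dimer_traj.coords[:, 1] - dimer_traj.coords[:, 0], axis=1)
        n = len(r)
        se_mean = r.std(ddof=1) / math.sqrt(n)
        assert abs(r.mean() - mean_ref) < 3 * se_mean
        se_var = r.var(ddof=1) * math.sqrt(2.0 / (n - 1))
        assert abs(r.var(ddof=1) - var_ref) < 3 * se_var

    def test_kinetic_temperature_at_target(self, chain30_traj):
        """Mean kinetic temperature of the 30-mer production run within
        three standard errors of the 300 K thermostat target."""
        t = chain30_traj.kinetic_temperature
        se = t.std(ddof=1) / math.sqrt(len(t))
        assert abs(t.mean() - 300.0) < 3 * se + 1e-12

    def test_free_bead_diffusion(self, params):
        """MSD slope of a single thermostatted bead matches 6 kB T/(m gamma)."""
        seq = SequenceRecord("free", "G")
        cfg = sim.SimulationConfig(production=50.0, equilibration=1.0,
                                   save_interval=0.01, thermostat_coupling=1.0,
                                   seed=8)
        traj = sim.run_langevin(np.zeros((1, 3)), seq, params, cfg)
        x = traj.coords[:, 0, :]
        lags = np.arange(5, 41)
        msd = np.array([np.mean(np.sum((x[l:] - x[:-l]) ** 2, axis=1)) for l in lags])
        slope = np.polyfit(lags * cfg.save_interval * 1e6, msd, 1)[0]   # A^2/fs
        mass = params.beads["G"].mass
        gamma = 1.0 / (cfg.thermostat_coupling * 1000.0)
        d_ref = KB_KCAL * 300.0 * KCAL_TO_MV / (mass * gamma)
        assert slope == pytest.approx(6.0 * d_ref, rel=0.10)

    def test_near_nve_energy_drift(self, params):
        """With the friction turned off the integrator is velocity Verlet;
        total energy drift of a dimer stays below 1e-3 kcal/mol per ns."""
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0 + 0.3, 0, 0]])
        cfg = sim.SimulationConfig(production=2.0, equilibration=0.01,
                                   save_interval=0.01,
                                   thermostat_coupling=math.inf, seed=2)
        traj = sim.run_langevin(c0, seq, params, cfg)
        n_dof = 3 * 2
        e_tot = traj.potential_energy + 0.5 * n_dof * KB_KCAL * traj.kinetic_temperature
        t_ns = np.arange(len(e_tot)) * cfg.save_interval
        drift = abs(np.polyfit(t_ns, e_tot, 1)[0])
        assert drift < 1e-3

    def test_blowup_reports_timestep(self, params):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        cfg = sim.SimulationConfig(timestep=2000.0, production=0.2,
                                   equilibration=0.02, save_interval=0.02, seed=0)
        with pytest.raises(RuntimeError, match="timestep"):
            sim.run_langevin(c0, seq, params, cfg)


class TestProtocol:
    def test_paper_production_rule(self):
        assert sim.paper_config(100).production == 6000.0
        assert sim.paper_config(300).production == 10000.0
        with pytest.warns(UserWarning, match="250"):
            cfg = sim.paper_config(250)
        assert cfg.production == 6000.0

    def test_desk_preset_values(self):
        cfg = sim.desk_config()
        assert (cfg.production, cfg.equilibration, cfg.save_interval) == (200.0, 5.0, 1.0)
        assert cfg.timestep == 20.0 and cfg.temperature == 300.0
        assert cfg.box_edge == 500.0 and cfg.thermostat_coupling == 100.0

    def test_replicates_distinct_and_deterministic(self, params):
        seq = SequenceRecord("p", "GSTNQGSTNQGS")
        kw = dict(production=2.0, equilibration=0.5, save_interval=0.5)
        a = sim.simulate_protocol(seq, params, preset="desk", seed=9,
                                  replicates=3, **kw)
        b = sim.simulate_protocol(seq, params, preset="desk", seed=9,
                                  replicates=3, **kw)
        assert len(a) == 3
        assert not np.array_equal(a[0].coords, a[1].coords)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.coords, tb.coords)


class TestTrajectoryIO:
    def test_roundtrip(self, params, tmp_path):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        cfg = sim.SimulationConfig(production=0.5, equilibration=0.1,
                                   save_interval=0.1, seed=3)
        traj = sim.run_langevin(c0, seq, params, cfg)
        sim.write_trajectory(traj, tmp_path / "t")
        back = sim.read_trajectory(tmp_path / "t")
        assert back.seq.seq == traj.seq.seq
        assert back.frame_spacing == traj.frame_spacing
        assert np.allclose(back.coords, traj.coords, atol=5e-3)   # float32 nm storage
        assert np.allclose(back.potential_energy, traj.potential_energy)

    def test_mismatched_topology_rejected(self, params, tmp_path):
        seq = SequenceRecord("d", "GS")
        c0 = np.array([[0.0, 0, 0], [params.bond.r0, 0, 0]])
        cfg = sim.SimulationConfig(production=0.5, equilibration=0.1,
                                   save_interval=0.1, seed=3)
        traj = sim.run_langevin(c0, seq, params, cfg)
        sim.write_trajectory(traj, tmp_path / "t")
        meta = (tmp_path / "t.json").read_text().replace('"GS"', '"GSG"')
        (tmp_path / "t.json").write_text(meta)
        with pytest.raises(ValueError, match="mismatch"):
            sim.read_trajectory(tmp_path / "t")
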