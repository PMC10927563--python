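"""Single-chain Langevin dynamics in the NVT ensemble.

Protocol: build a random-coil starting structure in the excluded-volume
limit, energy-minimize, equilibrate, then run production Langevin dynamics
(BAOAB splitting, friction = 1 / thermostat coupling time), discarding the
equilibration period and saving frames at a fixed interval.

Two presets:

* ``paper`` -- the full production protocol: 20 fs timestep, 300 K, 100 ps
  thermostat coupling, 500 A cubic box, frames every 2 ns, 10 ns
  equilibration, and production of 6 us for chains under 250 residues or
  10 us for longer chains (exactly 250 residues gets 6 us with a warning).
* ``desk`` -- a scaled-down protocol for desk/CI use: 200 ns production,
  5 ns equilibration, frames every 1 ns; identical physics otherwise.

Trajectories are written as DCD coordinates plus a one-CA-per-bead PDB
topology and a JSON provenance sidecar.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels
from .forcefield import ParameterSet, pack_parameters, total_energy_forces
from .seqfeatures import SequenceRecord

__all__ = [
    "SimulationConfig", "Trajectory", "desk_config", "paper_config",
    "build_initial_coil", "minimize", "run_langevin", "simulate_protocol",
    "write_trajectory", "read_trajectory",
]

KB = _kernels.KB_KCAL

#: Consecutive-bead distance beyond which the integrator aborts (A).
BLOWUP_BOND = 40.0
#: Excluded-volume floor used when building random coils (A).
COIL_HARD_CORE = 3.8


@dataclass
class SimulationConfig:
    timestep: float = 20.0            # fs
    temperature: float = 300.0        # K
    thermostat_coupling: float = 100.0  # ps
    box_edge: float = 500.0           # A
    save_interval: float = 2.0        # ns
    equilibration: float = 10.0       # ns
    production: float = 100.0         # ns
    seed: int = 0
    preset: str = "custom"
    nonbonded: bool = True

    def __post_init__(self):
        for name in ("timestep", "temperature", "thermostat_coupling",
                     "box_edge", "save_interval", "equilibration", "production"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.save_interval > self.production:
            raise ValueError("save_interval must not exceed production")


def desk_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale preset: 200 ns production / 5 ns equilibration / 1 ns saves."""
    kw = dict(production=200.0, equilibration=5.0, save_interval=1.0,
              seed=seed, preset="desk")
    kw.update(overrides)
    return SimulationConfig(**kw)


def paper_config(seq_length: int, seed: int = 0, **overrides) -> SimulationConfig:
    """Full-protocol preset; production time set by the chain-length rule."""
    if seq_length == 250:
        warnings.warn("length exactly 250: production time rule is ambiguous; using 6 us")
    production = 6000.0 if seq_length <= 250 else 10000.0
    kw = dict(production=production, equilibration=10.0, save_interval=2.0,
              seed=seed, preset="paper")
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class Trajectory:
    coords: np.ndarray                 # (frames, N, 3) A
    seq: SequenceRecord
    frame_spacing: float               # ns
    config: dict = field(default_factory=dict)
    potential_energy: np.ndarray | None = None   # kcal/mol per frame
    kinetic_temperature: np.ndarray | None = None  # K per frame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, N, 3)")
        if self.coords.shape[1] != len(self.seq):
            raise ValueError("topology/coordinate length mismatch")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------

def build_initial_coil(seq: SequenceRecord, params: ParameterSet, seed: int = 0,
                       box: float = 500.0, hard_core: float = COIL_HARD_CORE,
                       max_attempts: int = 200) -> np.ndarray:
    """Self-avoiding random-coil starting structure.

    Beads are placed sequentially at the bond length in uniformly random
    directions, rejecting placements within ``hard_core`` of any earlier
    bead, with backtracking. Deterministic given the seed.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    r0 = params.bond.r0
    n = len(seq)
    for attempt in range(max_attempts):
        coords = np.zeros((n, 3))
        i = 1
        stuck = 0
        while 0 < i < n:
            v = rng.standard_normal(3)
            v *= r0 / np.linalg.norm(v)
            cand = coords[i - 1] + v
            d = np.linalg.norm(coords[:max(i - 1, 0)] - cand, axis=1) if i > 1 else np.array([np.inf])
            if np.all(d >= hard_core) and np.all(np.abs(cand) < box / 2 - r0):
                coords[i] = cand
                i += 1
                stuck = 0
            else:
                stuck += 1
                if stuck > 100:           # backtrack one bead
                    i = max(1, i - 1)
                    stuck = 0
        if i == n:
            return coords
    raise RuntimeError(f"could not place a {n}-bead chain in the box after {max_attempts} attempts")


def minimize(coords: np.ndarray, seq: SequenceRecord, params: ParameterSet,
             max_iters: int = 1000, ftol: float = 1e-8, box: float = 500.0,
             nonbonded: bool = True) -> np.ndarray:
    """Backtracking steepest-descent minimization.

    Terminates when the maximum per-bead force norm drops below ``ftol``
    (kcal/mol/A) or after ``max_iters`` accepted steps; the energy is
    non-increasing across accepted steps.
    """
    x = np.array(coords, dtype=float)
    e, f = total_energy_forces(x, seq, params, box, nonbonded=nonbonded)
    if not math.isfinite(e):
        raise ValueError("non-finite energy at input configuration")
    step = 1e-2
    for _ in range(max_iters):
        fmax = np.max(np.linalg.norm(f, axis=1))
        if fmax < ftol:
            break
        moved = False
        while step > 1e-12:
            x_new = x + step * f / max(fmax, 1.0)
            try:
                e_new, f_new = total_energy_forces(x_new, seq, params, box,
                                                   nonbonded=nonbonded)
            except ValueError:
                step *= 0.5
                continue
            if e_new <= e:
                x, e, f = x_new, e_new, f_new
                step = min(step * 1.6, 1.0)
                moved = True
                break
            step *= 0.5
        if not moved:
            break
    return x


def _maxwell_velocities(masses: np.ndarray, temperature: float, rng) -> np.ndarray:
    kT_mv = KB * temperature * _kernels.KCAL_TO_MV
    return rng.standard_normal((len(masses), 3)) * np.sqrt(kT_mv / masses)[:, None]


def run_langevin(coords: np.ndarray, seq: SequenceRecord, params: ParameterSet,
                 config: SimulationConfig) -> Trajectory:
    """NVT Langevin production run (BAOAB splitting).

    Equilibration frames are discarded; frames are saved every
    ``save_interval``; the run is deterministic for a given seed.
    """
    coords = np.array(coords, dtype=np.float64)
    e0, f0 = total_energy_forces(coords, seq, params, config.box_edge,
                                 nonbonded=config.nonbonded)
    fmax = np.max(np.linalg.norm(f0, axis=1))
    if fmax > 100.0:
        warnings.warn(f"starting configuration looks unminimized (max force {fmax:.1f} "
                      "kcal/mol/A); consider minimize() first")

    dt = config.timestep
    save_every = int(round(config.save_interval * 1e6 / dt))
    equil_steps = int(round(config.equilibration * 1e6 / dt))
    prod_steps = int(round(config.production * 1e6 / dt))
    # align equilibration to the save cadence so production saves are exact
    equil_steps = (equil_steps // save_every) * save_every
    n_steps = equil_steps + prod_steps
    n_save = prod_steps // save_every

    pk = pack_parameters(seq, params)
    rng = np.random.default_rng(config.seed)
    vel = _maxwell_velocities(pk.masses, config.temperature, rng)
    gamma = 1.0 / (config.thermostat_coupling * 1000.0)   # 1/fs
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    frames = np.zeros((n_save, len(seq), 3))
    epot = np.zeros(n_save)
    ektemp = np.zeros(n_save)
    status, n_saved = _kernels.baoab_run(
        coords, vel, pk.masses, config.box_edge, pk.type_index, pk.wf_a,
        pk.wf_sig2, pk.wf_rc2, pk.wf_twomu, pk.wf_twonu, pk.q_pref,
        pk.dh_shift, pk.lam_inv, pk.coul_rc2, pk.bond_k, pk.bond_r0,
        config.nonbonded, dt, gamma, KB * config.temperature, n_steps,
        equil_steps, save_every, kernel_seed, BLOWUP_BOND, frames, epot, ektemp)
    if status == 2:
        raise RuntimeError(
            f"bond length exceeded {BLOWUP_BOND} A during integration: the run blew "
            f"up; reduce the timestep (currently {dt} fs)")
    if status != 0:
        raise RuntimeError(f"integration failed (status {status})")

    # box-scale sanity: the chain must never feel its periodic images
    span = frames[-1].max(axis=0) - frames[-1].min(axis=0)
    if np.any(span > config.box_edge / 2):
        warnings.warn("chain extent exceeds half the box edge; image interactions possible")

    return Trajectory(frames[:n_saved], seq, config.save_interval,
                      config=asdict(config), potential_energy=epot[:n_saved],
                      kinetic_temperature=ektemp[:n_saved])


def simulate_protocol(seq: SequenceRecord, params: ParameterSet,
                      preset: str = "desk", seed: int = 0,
                      replicates: int = 1, **overrides) -> list[Trajectory]:
    """Full protocol (coil -> minimize -> Langevin) with replicate seeds
    derived deterministically from the base seed."""
    if preset not in ("desk", "paper"):
        raise ValueError("preset must be 'desk' or 'paper'")
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=replicates)
    trajs = []
    for rs in rep_seeds:
        rs = int(rs)
        cfg = (desk_config(seed=rs, **overrides) if preset == "desk"
               else paper_config(len(seq), seed=rs, **overrides))
        coords = build_initial_coil(seq, params, seed=rs, box=cfg.box_edge)
        coords = minimize(coords, seq, params, box=cfg.box_edge,
                          nonbonded=cfg.nonbonded)
        trajs.append(run_langevin(coords, seq, params, cfg))
    return trajs


# ---------------------------------------------------------------------------
# Trajectory I/O (DCD + PDB topology + JSON sidecar, via mdtraj)

def _mdtraj_topology(seq: SequenceRecord):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    code3 = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    prev = None
    for i, aa in enumerate(seq.seq):
        res = top.add_residue(code3[aa], chain, resSeq=i + 1)
        atom = top.add_atom("CA", md.element.carbon, res)
        if prev is not None:
            top.add_bond(prev, atom)
        prev = atom
    return top


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write <path>.dcd, <path>.pdb and <path>.json (provenance sidecar)."""
    import mdtraj as md

    path = Path(path)
    top = _mdtraj_topology(traj.seq)
    mtraj = md.Trajectory(traj.coords / 10.0, top)   # A -> nm
    mtraj.save_dcd(str(path.with_suffix(".dcd")))
    mtraj[0].save_pdb(str(path.with_suffix(".pdb")))
    sidecar = {
        "id": traj.seq.id,
        "sequence": traj.seq.seq,
        "frame_spacing_ns": traj.frame_spacing,
        "config": traj.config,
        "potential_energy": None if traj.potential_energy is None
        else list(map(float, traj.potential_energy)),
        "kinetic_temperature": None if traj.kinetic_temperature is None
        else list(map(float, traj.kinetic_temperature)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    import mdtraj as md

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    mtraj = md.load(str(path.with_suffix(".dcd")), top=str(path.with_suffix(".pdb")))
    seq = SequenceRecord(meta["id"], meta["sequence"])
    coords = np.asarray(mtraj.xyz, dtype=np.float64) * 10.0   # nm -> A
    if coords.shape[1] != len(seq):
        raise ValueError("topology/coordinate length mismatch on read")
    epot = meta.get("potential_energy")
    ektemp = meta.get("kinetic_temperature")
    return Trajectory(coords, seq, meta["frame_spacing_ns"], config=meta.get("config", {}),
                      potential_energy=None if epot is None else np.asarray(epot),
                      kinetic_temperature=None if ektemp is None else np.asarray(ektemp))
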