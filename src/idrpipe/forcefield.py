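"""Residue-level coarse-grained force field.

One bead per residue. Nonbonded interactions combine a Wang--Frenkel
short-range pair potential (finite range, vanishing exactly at its cutoff)
with Debye--Hueckel screened electrostatics at implicit salt; consecutive
beads are joined by harmonic bonds. Parameter sets are pluggable: the
builtin ``"mpipi"`` set is a synthetic reconstruction in the Mpipi
functional form (see ``_ff_tables``); ``"mpipi-gg"`` is a named slot for a
user-supplied parameter file; arbitrary custom files are accepted.

Wang--Frenkel form (per pair, cutoff Rc = 3 sigma by default)::

    U(r) = eps * alpha * [(sigma/r)^(2 mu) - 1] * [(Rc/r)^(2 mu) - 1]^(2 nu)

with ``alpha`` the closed-form normalization that makes the minimum depth
exactly ``-eps``. Electrostatics::

    U(r) = C q_i q_j / (eps_r r) * exp(-r / lambda_D)

energy-shifted to zero at the Coulomb cutoff, with the Debye length
``lambda_D`` from the standard closed form at the configured ionic
strength and temperature.

Units: Angstrom, kcal/mol, Da, elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
from scipy import constants as const

from . import _ff_tables
from .seqfeatures import CANONICAL_AA, SequenceRecord

__all__ = [
    "BeadType", "PairParams", "BondParams", "ElectroParams", "ParameterSet",
    "load_parameter_set", "write_parameter_set", "builtin_parameter_set",
    "wang_frenkel_energy", "wf_alpha", "wf_rmin", "debye_huckel_energy",
    "debye_length", "bonded_energy", "total_energy_forces", "COULOMB_K",
]

#: e^2 / (4 pi eps0) in kcal * A / (mol * e^2).
COULOMB_K = 332.0637141491396

#: Beads closer than this (A) are treated as an unphysical overlap.
HARD_FLOOR = 0.8


@dataclass(frozen=True)
class BeadType:
    residue: str
    mass: float       # Da
    charge: float     # e
    sigma: float      # A

    def __post_init__(self):
        if self.sigma <= 0 or self.mass <= 0:
            raise ValueError(f"bead {self.residue}: sigma and mass must be > 0")
        if not (-1.0 <= self.charge <= 1.0):
            raise ValueError(f"bead {self.residue}: charge outside [-1, 1]")


@dataclass(frozen=True)
class PairParams:
    epsilon: float    # kcal/mol
    sigma: float      # A
    mu: float = 2.0
    nu_wf: float = 1.0
    cutoff: float | None = None   # A; default 3 sigma

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.cutoff is None:
            object.__setattr__(self, "cutoff", 3.0 * self.sigma)


@dataclass(frozen=True)
class BondParams:
    k: float     # kcal/mol/A^2
    r0: float    # A


@dataclass(frozen=True)
class ElectroParams:
    dielectric: float = 80.0
    ionic_strength: float = 0.150   # mol/L
    coulomb_cutoff: float = 35.0    # A
    temperature: float = 300.0      # K, sets the Debye length

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")


@dataclass
class ParameterSet:
    version: str
    beads: dict[str, BeadType]
    pairs: dict[tuple[str, str], PairParams]   # keys sorted residue tuples
    bond: BondParams
    electro: ElectroParams

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.version not in ("mpipi", "mpipi-gg", "custom"):
            raise ValueError(f"unknown parameter-set version {self.version!r}")
        missing_beads = sorted(set(CANONICAL_AA) - set(self.beads))
        if missing_beads:
            raise ValueError(f"missing bead types: {missing_beads}")
        want = {tuple(sorted(p)) for p in combinations_with_replacement(CANONICAL_AA, 2)}
        have = set(self.pairs)
        missing = sorted(want - have)
        if missing:
            raise ValueError(f"missing pair parameters for {len(missing)} pairs: {missing[:5]}...")

    def pair(self, a: str, b: str) -> PairParams:
        """Pair lookup, symmetric under residue swap."""
        return self.pairs[tuple(sorted((a.upper(), b.upper())))]


# ---------------------------------------------------------------------------
# Builtin set

def builtin_parameter_set(name: str = "mpipi") -> ParameterSet:
    """Construct the builtin synthetic parameter set (see ``_ff_tables``)."""
    if name != "mpipi":
        raise ValueError(
            f"no builtin parameter set {name!r}: 'mpipi-gg' must be supplied as a "
            "parameter file (load_parameter_set(path))"
        )
    t = _ff_tables
    beads = {aa: BeadType(aa, t.MASS[aa], t.CHARGE[aa], t.SIGMA[aa]) for aa in CANONICAL_AA}
    pairs = {}
    for a, b in combinations_with_replacement(CANONICAL_AA, 2):
        key = tuple(sorted((a, b)))
        sig = 0.5 * (t.SIGMA[a] + t.SIGMA[b])
        eps = t.EPS0 * 0.5 * (t.LAMBDA[a] + t.LAMBDA[b])
        pairs[key] = PairParams(epsilon=eps, sigma=sig, mu=t.MU, nu_wf=t.NU_WF)
    bond = BondParams(k=t.BOND_K, r0=t.BOND_R0)
    electro = ElectroParams(dielectric=t.DIELECTRIC, ionic_strength=t.IONIC_STRENGTH,
                            coulomb_cutoff=t.COULOMB_CUTOFF, temperature=t.TEMPERATURE)
    return ParameterSet("mpipi", beads, pairs, bond, electro)


# ---------------------------------------------------------------------------
# Parameter files: INI-like sections, strict parse, no defaults for physics.

def load_parameter_set(path_or_name: str | Path) -> ParameterSet:
    """Load a builtin set by name or a parameter file by path."""
    if str(path_or_name) in ("mpipi", "mpipi-gg"):
        return builtin_parameter_set(str(path_or_name))
    path = Path(path_or_name)
    if not path.exists():
        raise FileNotFoundError(f"parameter file {path} not found")
    sections: dict[str, list[list[str]]] = {}
    meta: dict[str, str] = {}
    current = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            sections.setdefault(current, [])
            continue
        if current is None:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip().lower()] = v.strip()
                continue
            raise ValueError(f"{path}:{ln}: data before any [section]")
        sections[current].append(line.split())

    for need in ("beads", "pairs", "bonds", "electrostatics"):
        if need not in sections:
            raise ValueError(f"{path}: missing [{need}] section")

    version = meta.get("version", "custom")
    beads = {}
    for row in sections["beads"]:
        aa, mass, charge, sigma = row[0].upper(), *map(float, row[1:4])
        if aa not in CANONICAL_AA:
            raise ValueError(f"{path}: unknown residue key {aa!r} in [beads]")
        beads[aa] = BeadType(aa, mass, charge, sigma)

    raw_pairs: dict[tuple[str, str], tuple] = {}
    for row in sections["pairs"]:
        a, b = row[0].upper(), row[1].upper()
        if a not in CANONICAL_AA or b not in CANONICAL_AA:
            raise ValueError(f"{path}: unknown residue pair ({a},{b})")
        vals = tuple(map(float, row[2:6]))  # eps sigma mu nu
        key = tuple(sorted((a, b)))
        if key in raw_pairs and not np.allclose(raw_pairs[key], vals):
            raise ValueError(f"{path}: asymmetric duplicate entries for pair {key}")
        raw_pairs[key] = vals
    pairs = {k: PairParams(*v) for k, v in raw_pairs.items()}

    brow = dict((r[0].lower(), float(r[1])) for r in sections["bonds"])
    for need in ("k", "r0"):
        if need not in brow:
            raise ValueError(f"{path}: [bonds] missing {need}")
    bond = BondParams(k=brow["k"], r0=brow["r0"])

    erow = dict((r[0].lower(), float(r[1])) for r in sections["electrostatics"])
    for need in ("dielectric", "ionic_strength", "coulomb_cutoff"):
        if need not in erow:
            raise ValueError(f"{path}: [electrostatics] missing {need}")
    electro = ElectroParams(dielectric=erow["dielectric"],
                            ionic_strength=erow["ionic_strength"],
                            coulomb_cutoff=erow["coulomb_cutoff"],
                            temperature=erow.get("temperature", 300.0))
    return ParameterSet(version, beads, pairs, bond, electro)


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    lines = [
        "# idrpipe parameter file -- units: A, kcal/mol, Da, e",
        f"version = {ps.version}",
        "", "[beads]", "# residue mass charge sigma",
    ]
    for aa in CANONICAL_AA:
        b = ps.beads[aa]
        lines.append(f"{aa} {b.mass:.4f} {b.charge:+.4f} {b.sigma:.4f}")
    lines += ["", "[pairs]", "# res_i res_j epsilon sigma mu nu_wf"]
    for key in sorted(ps.pairs):
        p = ps.pairs[key]
        lines.append(f"{key[0]} {key[1]} {p.epsilon:.6f} {p.sigma:.4f} {p.mu:g} {p.nu_wf:g}")
    lines += ["", "[bonds]", f"k {ps.bond.k:g}", f"r0 {ps.bond.r0:g}",
              "", "[electrostatics]",
              f"dielectric {ps.electro.dielectric:g}",
              f"ionic_strength {ps.electro.ionic_strength:g}",
              f"coulomb_cutoff {ps.electro.coulomb_cutoff:g}",
              f"temperature {ps.electro.temperature:g}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pair potentials

def wf_alpha(sigma: float, mu: float, nu: float, cutoff: float) -> float:
    """Closed-form Wang--Frenkel normalization making the well depth -eps."""
    x = (cutoff / sigma) ** (2.0 * mu)
    return 2.0 * nu * x * ((1.0 + 2.0 * nu) / (2.0 * nu * (x - 1.0))) ** (2.0 * nu + 1.0)


def wf_rmin(sigma: float, mu: float, nu: float, cutoff: float) -> float:
    """Location of the Wang--Frenkel minimum."""
    x = (cutoff / sigma) ** (2.0 * mu)
    return cutoff * ((1.0 + 2.0 * nu) / (1.0 + 2.0 * nu * x)) ** (1.0 / (2.0 * mu))


def wang_frenkel_energy(r, p: PairParams):
    """Wang--Frenkel pair energy at distance r (scalar or array, A)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    a = p.epsilon * wf_alpha(p.sigma, p.mu, p.nu_wf, p.cutoff)
    s = (p.sigma / r) ** (2.0 * p.mu)
    c = (p.cutoff / r) ** (2.0 * p.mu)
    u = a * (s - 1.0) * (c - 1.0) ** (2.0 * p.nu_wf)
    u = np.where(r >= p.cutoff, 0.0, u)
    return float(u) if u.ndim == 0 else u


def debye_length(ionic_strength: float, temperature: float = 300.0,
                 dielectric: float = 80.0) -> float:
    """Debye screening length (A): sqrt(eps0 eps_r kB T / (2 NA e^2 I))."""
    if ionic_strength < 0 or dielectric <= 0 or temperature <= 0:
        raise ValueError("non-physical electrostatic inputs")
    if ionic_strength == 0:
        return math.inf
    I_m3 = ionic_strength * 1000.0  # mol/L -> mol/m^3
    lam = math.sqrt(const.epsilon_0 * dielectric * const.k * temperature
                    / (2.0 * const.N_A * const.e ** 2 * I_m3))
    return lam * 1e10


def debye_huckel_energy(r, qi: float, qj: float, electro: ElectroParams):
    """Screened-Coulomb pair energy, shifted to zero at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    if qi == 0.0 or qj == 0.0:
        out = np.zeros_like(r)
        return float(out) if out.ndim == 0 else out
    lam = debye_length(electro.ionic_strength, electro.temperature, electro.dielectric)
    pref = COULOMB_K * qi * qj / electro.dielectric
    rc = electro.coulomb_cutoff
    shift = pref * math.exp(-rc / lam) / rc
    u = np.where(r >= rc, 0.0, pref * np.exp(-r / lam) / r - shift)
    return float(u) if u.ndim == 0 else u


def bonded_energy(r, bond: BondParams):
    """Harmonic bond energy U = k (r - r0)^2."""
    r = np.asarray(r, dtype=float)
    u = bond.k * (r - bond.r0) ** 2
    return float(u) if u.ndim == 0 else u


# ---------------------------------------------------------------------------
# Total energy and forces

@dataclass
class _PackedParams:
    """Flat numpy views of a ParameterSet for the numba kernels."""
    type_index: np.ndarray         # (N,) int
    masses: np.ndarray             # (N,)
    wf_a: np.ndarray               # (20,20) eps*alpha
    wf_sig2: np.ndarray            # (20,20) sigma^2
    wf_rc2: np.ndarray             # (20,20) cutoff^2
    wf_twomu: np.ndarray           # (20,20) int
    wf_twonu: np.ndarray           # (20,20) int
    q_pref: np.ndarray             # (20,20) COULOMB_K qi qj / eps_r
    dh_shift: np.ndarray           # (20,20)
    lam_inv: float
    coul_rc2: float
    bond_k: float
    bond_r0: float


def pack_parameters(seq: SequenceRecord, params: ParameterSet) -> _PackedParams:
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    tidx = np.array([aa_index[c] for c in seq.seq], dtype=np.int64)
    masses = np.array([params.beads[c].mass for c in seq.seq])
    n = len(CANONICAL_AA)
    wf_a = np.zeros((n, n)); wf_sig2 = np.zeros((n, n)); wf_rc2 = np.zeros((n, n))
    wf_twomu = np.zeros((n, n), dtype=np.int64)
    wf_twonu = np.zeros((n, n), dtype=np.int64)
    q_pref = np.zeros((n, n)); dh_shift = np.zeros((n, n))
    e = params.electro
    lam = debye_length(e.ionic_strength, e.temperature, e.dielectric)
    lam_inv = 0.0 if math.isinf(lam) else 1.0 / lam
    for a in CANONICAL_AA:
        for b in CANONICAL_AA:
            i, j = aa_index[a], aa_index[b]
            p = params.pair(a, b)
            two_mu = 2.0 * p.mu
            two_nu = 2.0 * p.nu_wf
            if abs(two_mu - round(two_mu)) > 1e-9 or abs(two_nu - round(two_nu)) > 1e-9:
                raise ValueError("kernel requires integer 2*mu and 2*nu_wf exponents")
            wf_a[i, j] = p.epsilon * wf_alpha(p.sigma, p.mu, p.nu_wf, p.cutoff)
            wf_sig2[i, j] = p.sigma ** 2
            wf_rc2[i, j] = p.cutoff ** 2
            wf_twomu[i, j] = int(round(two_mu))
            wf_twonu[i, j] = int(round(two_nu))
            qi = params.beads[a].charge
            qj = params.beads[b].charge
            pref = COULOMB_K * qi * qj / e.dielectric
            q_pref[i, j] = pref
            if pref != 0.0:
                dh_shift[i, j] = pref * math.exp(-e.coulomb_cutoff * lam_inv) / e.coulomb_cutoff
    return _PackedParams(tidx, masses, wf_a, wf_sig2, wf_rc2, wf_twomu, wf_twonu,
                         q_pref, dh_shift, lam_inv, e.coulomb_cutoff ** 2,
                         params.bond.k, params.bond.r0)


def total_energy_forces(coords: np.ndarray, seq: SequenceRecord, params: ParameterSet,
                        box: float, nonbonded: bool = True):
    """Total potential energy (kcal/mol) and analytic forces (kcal/mol/A).

    Bonds join consecutive beads; 1-2 pairs are excluded from the nonbonded
    sum (1-3 included); the minimum-image convention applies. Raises on
    unphysical overlaps (pair distance below the hard floor), which usually
    means the configuration needs re-minimization.
    """
    from ._kernels import energy_forces_kernel

    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if coords.shape[0] != len(seq):
        raise ValueError("coords/sequence length mismatch")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    max_rc = max(math.sqrt(params.pair(a, b).cutoff ** 2)
                 for a in set(seq.seq) for b in set(seq.seq))
    max_rc = max(max_rc, params.electro.coulomb_cutoff)
    if box < 2 * max_rc:
        raise ValueError(f"box ({box} A) must be >= twice the largest cutoff ({max_rc} A)")
    pk = pack_parameters(seq, params)
    forces = np.zeros_like(coords)
    energy, status = energy_forces_kernel(
        coords, box, pk.type_index, pk.wf_a, pk.wf_sig2, pk.wf_rc2,
        pk.wf_twomu, pk.wf_twonu, pk.q_pref, pk.dh_shift, pk.lam_inv,
        pk.coul_rc2, pk.bond_k, pk.bond_r0, nonbonded, HARD_FLOOR, forces)
    if status != 0:
        raise ValueError(
            f"beads closer than the hard floor ({HARD_FLOOR} A): unphysical overlap; "
            "re-minimize the configuration")
    return energy, forces
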