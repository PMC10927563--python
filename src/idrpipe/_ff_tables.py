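"""Per-residue tables for the builtin synthetic parameter set.

The builtin "mpipi" set is a synthetic reconstruction in the Mpipi-style
functional form (Wang--Frenkel pair potential + Debye--Hueckel screened
electrostatics on one bead per residue), not the published pair table:

* masses -- standard average residue masses (Da);
* charges -- scaled-charge convention: R/K = +0.75, D/E = -0.75, H = 0;
* sigma -- per-residue diameters derived from residue van der Waals
  volumes (Angstrom); pair sigma by Lorentz rule;
* epsilon -- a hand-defined per-residue stickiness lambda in [0, 1]
  (aromatics strongest, charged weakest), combined as
  eps_ij = EPS0 * (lambda_i + lambda_j) / 2.

The Wang--Frenkel exponents are mu = 2, nu = 1 for every pair, with the
cutoff at 3 sigma.
"""

MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

CHARGE = {
    "R": 0.75, "K": 0.75, "D": -0.75, "E": -0.75, "H": 0.0,
    "A": 0.0, "N": 0.0, "C": 0.0, "Q": 0.0, "G": 0.0, "I": 0.0,
    "L": 0.0, "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0,
    "W": 0.0, "Y": 0.0, "V": 0.0,
}

SIGMA = {
    "A": 5.04, "R": 6.56, "N": 5.68, "D": 5.58, "C": 5.48,
    "Q": 6.02, "E": 5.92, "G": 4.50, "H": 6.08, "I": 6.18,
    "L": 6.18, "K": 6.36, "M": 6.18, "F": 6.36, "P": 5.56,
    "S": 5.18, "T": 5.62, "W": 6.78, "Y": 6.46, "V": 5.86,
}

# Stickiness scale (dimensionless, [0, 1]): aromatics strongest, then
# aliphatics, weak for charged residues.
LAMBDA = {
    "W": 0.95, "Y": 0.90, "F": 0.85, "M": 0.65, "L": 0.60,
    "I": 0.60, "V": 0.55, "C": 0.55, "H": 0.50, "A": 0.45,
    "R": 0.45, "T": 0.40, "Q": 0.40, "G": 0.40, "N": 0.38,
    "S": 0.38, "P": 0.35, "K": 0.30, "D": 0.30, "E": 0.30,
}

#: Overall short-range energy scale (kcal/mol): eps(W,W) = EPS0 * 0.95.
EPS0 = 0.80

#: Wang--Frenkel exponents used for every builtin pair.
MU = 2.0
NU_WF = 1.0

#: Harmonic bond: U = k (r - r0)^2.
BOND_K = 9.6      # kcal/mol/A^2
BOND_R0 = 3.81    # A

#: Electrostatics.
DIELECTRIC = 80.0
IONIC_STRENGTH = 0.150    # mol/L
COULOMB_CUTOFF = 35.0     # A
TEMPERATURE = 300.0       # K (sets the builtin Debye length)
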