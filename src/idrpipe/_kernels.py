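"""Numba kernels: pairwise energy/forces and the BAOAB Langevin integrator.

All distances in Angstrom, energies in kcal/mol, masses in Da, time in fs.
``KCAL_TO_MV`` converts kcal/mol to the mass-velocity energy unit
Da * A^2 / fs^2. Exponents ``2 mu`` and ``2 nu`` enter as small integers so
the inner loop uses repeated multiplication instead of ``pow``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: kcal/mol -> Da A^2 fs^-2
KCAL_TO_MV = 4.184e-4
#: Boltzmann constant, kcal/mol/K
KB_KCAL = 0.001987204259


@njit(cache=True, inline="always")
def _ipow(x: float, n: int) -> float:
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=True)
def energy_forces_kernel(coords, box, tidx, wf_a, wf_sig2, wf_rc2, wf_twomu,
                         wf_twonu, q_pref, dh_shift, lam_inv, coul_rc2,
                         bond_k, bond_r0, nonbonded, hard_floor, forces):
    """Returns (energy, status); status 1 flags a hard-floor overlap.

    Bonds between consecutive beads; 1-2 nonbonded exclusions; minimum
    image in a cubic box. forces is written in place (zeroed here).
    """
    n = coords.shape[0]
    forces[:] = 0.0
    energy = 0.0
    status = 0
    floor2 = hard_floor * hard_floor

    # bonds
    for i in range(n - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0
        energy += bond_k * dr * dr
        if r > 0.0:
            f = -2.0 * bond_k * dr / r
            forces[i + 1, 0] += f * dx
            forces[i + 1, 1] += f * dy
            forces[i + 1, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz

    if not nonbonded:
        return energy, status

    inv_box = 1.0 / box
    for i in range(n - 2):
        ti = tidx[i]
        for j in range(i + 2, n):
            tj = tidx[j]
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            dx -= box * round(dx * inv_box)
            dy -= box * round(dy * inv_box)
            dz -= box * round(dz * inv_box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < floor2:
                status = 1
            rc2 = wf_rc2[ti, tj]
            f_over_r = 0.0
            if r2 < rc2:
                # Wang-Frenkel
                a = wf_a[ti, tj]
                twomu = wf_twomu[ti, tj]
                twonu = wf_twonu[ti, tj]
                mu = twomu // 2
                s = _ipow(wf_sig2[ti, tj] / r2, mu)
                c = _ipow(rc2 / r2, mu)
                cm1 = c - 1.0
                cm1_pow = _ipow(cm1, twonu)
                energy += a * (s - 1.0) * cm1_pow
                # dU/dr = -(2 mu A / r) [ s (c-1)^2nu + 2nu c (s-1)(c-1)^(2nu-1) ]
                cm1_pow_m1 = _ipow(cm1, twonu - 1)
                dudr_times_r = -float(twomu) * a * (
                    s * cm1_pow + float(twonu) * c * (s - 1.0) * cm1_pow_m1)
                f_over_r += -dudr_times_r / r2   # = -(dU/dr)/r
            pref = q_pref[ti, tj]
            if pref != 0.0 and r2 < coul_rc2:
                r = math.sqrt(r2)
                ex = math.exp(-r * lam_inv)
                energy += pref * ex / r - dh_shift[ti, tj]
                # dU/dr = -pref ex (lam_inv/r + 1/r^2)
                f_over_r += pref * ex * (lam_inv / r + 1.0 / r2) / r
            if f_over_r != 0.0:
                # force on j along +d means repulsion when f_over_r > 0
                forces[j, 0] += f_over_r * dx
                forces[j, 1] += f_over_r * dy
                forces[j, 2] += f_over_r * dz
                forces[i, 0] -= f_over_r * dx
                forces[i, 1] -= f_over_r * dy
                forces[i, 2] -= f_over_r * dz
    return energy, status


@njit(cache=True)
def baoab_run(coords, vel, masses, box, tidx, wf_a, wf_sig2, wf_rc2, wf_twomu,
              wf_twonu, q_pref, dh_shift, lam_inv, coul_rc2, bond_k, bond_r0,
              nonbonded, dt, gamma, kT_kcal, n_steps, equil_steps, save_every,
              seed, blowup_bond, frames, epot_out, ektemp_out):
    """BAOAB Langevin integration; fills frames/epot/ektemp for saved frames
    after the equilibration period. Returns (status, n_saved):
    status 0 ok, 1 overlap error, 2 bond blow-up, 3 non-finite energy.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    forces = np.zeros_like(coords)
    energy, status = energy_forces_kernel(
        coords, box, tidx, wf_a, wf_sig2, wf_rc2, wf_twomu, wf_twonu, q_pref,
        dh_shift, lam_inv, coul_rc2, bond_k, bond_r0, nonbonded, 0.4, forces)
    if status != 0:
        return 1, 0
    kT_mv = kT_kcal * KCAL_TO_MV
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    half_dt = 0.5 * dt
    n_saved = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            inv_m = KCAL_TO_MV / masses[i]
            vel[i, 0] += half_dt * forces[i, 0] * inv_m
            vel[i, 1] += half_dt * forces[i, 1] * inv_m
            vel[i, 2] += half_dt * forces[i, 2] * inv_m
            coords[i, 0] += half_dt * vel[i, 0]
            coords[i, 1] += half_dt * vel[i, 1]
            coords[i, 2] += half_dt * vel[i, 2]
        if gamma > 0.0:
            for i in range(n):
                sd = c2 * math.sqrt(kT_mv / masses[i])
                vel[i, 0] = c1 * vel[i, 0] + sd * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + sd * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + sd * np.random.standard_normal()
        for i in range(n):
            coords[i, 0] += half_dt * vel[i, 0]
            coords[i, 1] += half_dt * vel[i, 1]
            coords[i, 2] += half_dt * vel[i, 2]
        energy, status = energy_forces_kernel(
            coords, box, tidx, wf_a, wf_sig2, wf_rc2, wf_twomu, wf_twonu,
            q_pref, dh_shift, lam_inv, coul_rc2, bond_k, bond_r0, nonbonded,
            0.0, forces)
        for i in range(n):
            inv_m = KCAL_TO_MV / masses[i]
            vel[i, 0] += half_dt * forces[i, 0] * inv_m
            vel[i, 1] += half_dt * forces[i, 1] * inv_m
            vel[i, 2] += half_dt * forces[i, 2] * inv_m

        if step % save_every == 0:
            # stability checks at save resolution (cheap)
            if not math.isfinite(energy):
                return 3, n_saved
            for i in range(n - 1):
                dx = coords[i + 1, 0] - coords[i, 0]
                dy = coords[i + 1, 1] - coords[i, 1]
                dz = coords[i + 1, 2] - coords[i, 2]
                if dx * dx + dy * dy + dz * dz > blowup_bond * blowup_bond:
                    return 2, n_saved
            if step > equil_steps:
                ke = 0.0
                for i in range(n):
                    ke += masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                ektemp_out[n_saved] = ke / (3.0 * n * KB_KCAL * KCAL_TO_MV)
                epot_out[n_saved] = energy
                frames[n_saved] = coords
                n_saved += 1
    return 0, n_saved
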