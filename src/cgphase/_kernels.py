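"""Numba kernels: neighbor lists, pairwise forces, Langevin integration.

All kernels use the minimum-image convention in an orthorhombic periodic
box and the unit system of :mod:`cgphase.constants`.  Pair energies are
truncated and shifted to zero at their cutoffs, so the reported potential
energy is continuous in the pair distance and forces are the exact
negative gradient of the reported energy.

The nonbonded interaction per pair is the Ashbaugh-Hatch hydrophobic
term (a Lennard-Jones variant whose attractive branch is scaled by the
pair hydrophobicity lambda_ij), a Debye-Hueckel screened Coulomb term,
and an optional extra Lennard-Jones well on cation x aromatic pairs.
Per-pair constants (sigma_ij^2, lambda_ij, charge products, cutoff
shifts) are precomputed when the Verlet list is rebuilt.
"""
import numpy as np
from numba import njit

# r <= 2^(1/6) sigma  <=>  r^2 <= 2^(1/3) sigma^2
_TWO_13 = 2.0 ** (1.0 / 3.0)


@njit(cache=True, fastmath=True)
def _count_pairs(pos, box, excl_next, rc2, charged_idx, rc2_el):
    n = pos.shape[0]
    ib0 = 1.0 / box[0]
    ib1 = 1.0 / box[1]
    ib2 = 1.0 / box[2]
    n_all = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j == i + 1 and excl_next[i]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx * ib0)
            dy -= box[1] * np.rint(dy * ib1)
            dz -= box[2] * np.rint(dz * ib2)
            if dx * dx + dy * dy + dz * dz < rc2:
                n_all += 1
    n_el = 0
    m = charged_idx.size
    for a in range(m - 1):
        for b in range(a + 1, m):
            i = charged_idx[a]
            j = charged_idx[b]
            if j == i + 1 and excl_next[i]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx * ib0)
            dy -= box[1] * np.rint(dy * ib1)
            dz -= box[2] * np.rint(dz * ib2)
            if dx * dx + dy * dy + dz * dz < rc2_el:
                n_el += 1
    return n_all, n_el


@njit(cache=True, fastmath=True)
def build_pairs(
    pos,
    box,
    excl_next,
    rc2,
    charged_idx,
    rc2_el,
    sigma,
    lam,
    charge,
    catflag,
    eps,
    hscale,
    cpi_eps,
    rc_h,
    kel,
):
    """Verlet pair lists with per-pair precomputed interaction constants.

    Returns (ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref):
    a short-range list over all beads carrying sigma_ij^2, lambda_ij,
    the cation-pi well scale (cation_pi_eps/eps or 0) and the
    Lennard-Jones value at the cutoff; and an electrostatic list over
    charged beads carrying the Coulomb prefactor kel * q_i q_j.
    Bonded (i, i+1) pairs are excluded from both.
    """
    n_all, n_el = _count_pairs(pos, box, excl_next, rc2, charged_idx, rc2_el)
    ai = np.empty(n_all, dtype=np.int64)
    aj = np.empty(n_all, dtype=np.int64)
    sij2 = np.empty(n_all)
    lij = np.empty(n_all)
    cpscale = np.empty(n_all)
    ljc = np.empty(n_all)
    bi = np.empty(n_el, dtype=np.int64)
    bj = np.empty(n_el, dtype=np.int64)
    pref = np.empty(n_el)
    n = pos.shape[0]
    ib0 = 1.0 / box[0]
    ib1 = 1.0 / box[1]
    ib2 = 1.0 / box[2]
    rc_h2 = rc_h * rc_h
    cps = cpi_eps / eps if eps > 0.0 else 0.0
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j == i + 1 and excl_next[i]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx * ib0)
            dy -= box[1] * np.rint(dy * ib1)
            dz -= box[2] * np.rint(dz * ib2)
            if dx * dx + dy * dy + dz * dz < rc2:
                ai[k] = i
                aj[k] = j
                s = 0.5 * (sigma[i] + sigma[j])
                sij2[k] = s * s
                lij[k] = hscale * 0.5 * (lam[i] + lam[j])
                cpscale[k] = cps if catflag[i] * catflag[j] == 2 else 0.0
                c6 = (s * s / rc_h2) ** 3
                ljc[k] = 4.0 * eps * (c6 * c6 - c6)
                k += 1
    k = 0
    m = charged_idx.size
    for a in range(m - 1):
        for b in range(a + 1, m):
            i = charged_idx[a]
            j = charged_idx[b]
            if j == i + 1 and excl_next[i]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx * ib0)
            dy -= box[1] * np.rint(dy * ib1)
            dz -= box[2] * np.rint(dz * ib2)
            if dx * dx + dy * dy + dz * dz < rc2_el:
                bi[k] = i
                bj[k] = j
                pref[k] = kel * charge[i] * charge[j]
                k += 1
    return ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref


@njit(cache=True, fastmath=True)
def nonbonded_forces(
    pos,
    box,
    ai,
    aj,
    sij2,
    lij,
    cpscale,
    ljc,
    bi,
    bj,
    pref,
    eps,
    rc_h,
    inv_ld,
    rc_e,
    forces,
):
    """Accumulate nonbonded forces; return (e_hydro, e_elec, e_catpi, virial)."""
    e_h = 0.0
    e_cp = 0.0
    e_el = 0.0
    vir = 0.0
    ib0 = 1.0 / box[0]
    ib1 = 1.0 / box[1]
    ib2 = 1.0 / box[2]
    rc_h2 = rc_h * rc_h
    for m in range(ai.size):
        i = ai[m]
        j = aj[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx * ib0)
        dy -= box[1] * np.rint(dy * ib1)
        dz -= box[2] * np.rint(dz * ib2)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_h2 or r2 == 0.0:
            continue
        inv_r2 = 1.0 / r2
        s2 = sij2[m] * inv_r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        lj = 4.0 * eps * (s12 - s6)
        flj = 24.0 * eps * (2.0 * s12 - s6) * inv_r2
        la = lij[m]
        lc = ljc[m]
        if r2 <= _TWO_13 * sij2[m]:
            e_h += lj + (1.0 - la) * eps - la * lc
            f = flj
        else:
            e_h += la * (lj - lc)
            f = la * flj
        cs = cpscale[m]
        if cs > 0.0:
            e_cp += cs * (lj - lc)
            f += cs * flj
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
        vir += f * r2
    if bi.size > 0:
        rc_e2 = rc_e * rc_e
        cshift = np.exp(-rc_e * inv_ld) / rc_e
        for m in range(bi.size):
            i = bi[m]
            j = bj[m]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx * ib0)
            dy -= box[1] * np.rint(dy * ib1)
            dz -= box[2] * np.rint(dz * ib2)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_e2 or r2 == 0.0:
                continue
            inv_r2 = 1.0 / r2
            r = np.sqrt(r2)
            inv_r = r * inv_r2
            p = pref[m]
            sc = np.exp(-r * inv_ld)
            e_el += p * (sc * inv_r - cshift)
            f = p * sc * (inv_r2 + inv_ld * inv_r) * inv_r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
            vir += f * r2
    return e_h, e_el, e_cp, vir


@njit(cache=True, fastmath=True)
def bonded_forces(pos, box, bonds_i, bonds_j, bonds_r0, bonds_k, forces):
    """Harmonic bonds (and elastic-network springs); returns (energy, virial)."""
    e = 0.0
    vir = 0.0
    for m in range(bonds_i.size):
        i = bonds_i[m]
        j = bonds_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = r - bonds_r0[m]
        e += 0.5 * bonds_k[m] * dev * dev
        if r > 0.0:
            f = -bonds_k[m] * dev / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
            vir += f * r * r
    return e, vir


@njit(cache=True)
def energy_forces(
    pos,
    box,
    excl_next,
    chain_id,
    charged_idx,
    bonds_i,
    bonds_j,
    bonds_r0,
    bonds_k,
    sigma,
    lam,
    charge,
    catflag,
    eps,
    hscale,
    cpi_eps,
    rc_h,
    kel,
    inv_ld,
    rc_e,
):
    """One-shot energy/force evaluation with a freshly built pair list.

    Returns (forces, e_hydro, e_elec, e_catpi, e_bond, virial).
    """
    ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref = build_pairs(
        pos, box, excl_next, rc_h * rc_h, charged_idx, rc_e * rc_e,
        sigma, lam, charge, catflag, eps, hscale, cpi_eps, rc_h, kel,
    )
    forces = np.zeros_like(pos)
    e_h, e_el, e_cp, vir = nonbonded_forces(
        pos, box, ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref,
        eps, rc_h, inv_ld, rc_e, forces,
    )
    e_b, vir_b = bonded_forces(pos, box, bonds_i, bonds_j, bonds_r0, bonds_k, forces)
    return forces, e_h, e_el, e_cp, e_b, vir + vir_b


@njit(cache=True)
def _wrap(pos, box):
    for i in range(pos.shape[0]):
        for d in range(3):
            pos[i, d] -= box[d] * np.floor(pos[i, d] / box[d])


@njit(cache=True)
def relax(
    pos,
    box,
    excl_next,
    chain_id,
    charged_idx,
    bonds_i,
    bonds_j,
    bonds_r0,
    bonds_k,
    sigma,
    lam,
    charge,
    catflag,
    eps,
    hscale,
    cpi_eps,
    rc_h,
    kel,
    inv_ld,
    rc_e,
    n_iter,
    dmax,
    ftol,
):
    """Steepest-descent relaxation with a per-move displacement cap.

    Used to remove initial-placement overlaps before dynamics.  Moves
    every bead along the force direction, the largest bead by ``dmax`` nm.
    """
    for it in range(n_iter):
        out = energy_forces(
            pos, box, excl_next, chain_id, charged_idx,
            bonds_i, bonds_j, bonds_r0, bonds_k,
            sigma, lam, charge, catflag,
            eps, hscale, cpi_eps, rc_h, kel, inv_ld, rc_e,
        )
        forces = out[0]
        fmax = 0.0
        for i in range(pos.shape[0]):
            fn = np.sqrt(
                forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
            )
            if fn > fmax:
                fmax = fn
        if fmax < ftol:
            break
        scale = dmax / fmax
        for i in range(pos.shape[0]):
            for d in range(3):
                pos[i, d] += scale * forces[i, d]
        _wrap(pos, box)


@njit(cache=True, fastmath=True)
def run_langevin(
    pos,
    vel,
    box,
    mass,
    sigma,
    lam,
    charge,
    catflag,
    excl_next,
    chain_id,
    charged_idx,
    bonds_i,
    bonds_j,
    bonds_r0,
    bonds_k,
    eps,
    hscale,
    cpi_eps,
    rc_h,
    kel,
    inv_ld,
    rc_e,
    skin,
    kT,
    kB,
    gamma,
    dt,
    n_steps,
    thin,
    seed,
    frames,
    frame_times,
    elog,
    min_sigma,
    t_start,
    zero_com,
):
    """BAOAB-discretized Langevin dynamics.

    Stores a frame and an energy-log row every ``thin`` steps into the
    preallocated ``frames``/``frame_times``/``elog`` arrays.  Energy-log
    columns: step, time_ps, e_hydro, e_elec, e_catpi, e_bond, e_pot,
    e_kin, T_inst.

    Returns (status, n_frames): status 0 = ok, 1 = instability (a bead
    moved more than half the smallest bead diameter in one step),
    2 = non-finite energy.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    halfdt = 0.5 * dt
    sq = np.empty(n)
    inv_m = np.empty(n)
    for i in range(n):
        sq[i] = np.sqrt(kT / mass[i])
        inv_m[i] = 1.0 / mass[i]
    rc2 = (rc_h + skin) ** 2
    rc2_el = (rc_e + skin) ** 2
    _wrap(pos, box)
    ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref = build_pairs(
        pos, box, excl_next, rc2, charged_idx, rc2_el,
        sigma, lam, charge, catflag, eps, hscale, cpi_eps, rc_h, kel,
    )
    ref = pos.copy()
    forces = np.zeros_like(pos)
    e_h, e_el, e_cp, vir = nonbonded_forces(
        pos, box, ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref,
        eps, rc_h, inv_ld, rc_e, forces,
    )
    e_b, _ = bonded_forces(pos, box, bonds_i, bonds_j, bonds_r0, bonds_k, forces)
    nframe = 0
    trig2 = (0.5 * skin) ** 2
    dstab = 0.5 * min_sigma
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            w = halfdt * inv_m[i]
            vel[i, 0] += w * forces[i, 0]
            vel[i, 1] += w * forces[i, 1]
            vel[i, 2] += w * forces[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += halfdt * vel[i, 0]
            pos[i, 1] += halfdt * vel[i, 1]
            pos[i, 2] += halfdt * vel[i, 2]
        # O: exact Ornstein-Uhlenbeck
        v2max = 0.0
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2 * sq[i] * np.random.normal()
            vel[i, 1] = c1 * vel[i, 1] + c2 * sq[i] * np.random.normal()
            vel[i, 2] = c1 * vel[i, 2] + c2 * sq[i] * np.random.normal()
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            if v2 > v2max:
                v2max = v2
        if np.sqrt(v2max) * dt > dstab:
            return 1, nframe
        # A: half drift
        for i in range(n):
            pos[i, 0] += halfdt * vel[i, 0]
            pos[i, 1] += halfdt * vel[i, 1]
            pos[i, 2] += halfdt * vel[i, 2]
        # Verlet-list staleness check
        d2max = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > d2max:
                d2max = d2
        if d2max > trig2:
            _wrap(pos, box)
            ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref = build_pairs(
                pos, box, excl_next, rc2, charged_idx, rc2_el,
                sigma, lam, charge, catflag, eps, hscale, cpi_eps, rc_h, kel,
            )
            ref = pos.copy()
            if zero_com:
                # remove center-of-mass drift
                mtot = 0.0
                px = 0.0
                py = 0.0
                pz = 0.0
                for i in range(n):
                    mtot += mass[i]
                    px += mass[i] * vel[i, 0]
                    py += mass[i] * vel[i, 1]
                    pz += mass[i] * vel[i, 2]
                for i in range(n):
                    vel[i, 0] -= px / mtot
                    vel[i, 1] -= py / mtot
                    vel[i, 2] -= pz / mtot
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        e_h, e_el, e_cp, vir = nonbonded_forces(
            pos, box, ai, aj, sij2, lij, cpscale, ljc, bi, bj, pref,
            eps, rc_h, inv_ld, rc_e, forces,
        )
        e_b, _ = bonded_forces(pos, box, bonds_i, bonds_j, bonds_r0, bonds_k, forces)
        # B: half kick
        for i in range(n):
            w = halfdt * inv_m[i]
            vel[i, 0] += w * forces[i, 0]
            vel[i, 1] += w * forces[i, 1]
            vel[i, 2] += w * forces[i, 2]
        if (step + 1) % thin == 0:
            epot = e_h + e_el + e_cp + e_b
            if not np.isfinite(epot):
                return 2, nframe
            ekin = 0.0
            for i in range(n):
                ekin += (
                    0.5
                    * mass[i]
                    * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                )
            t_inst = 2.0 * ekin / (3.0 * n * kB)
            t = t_start + (step + 1) * dt
            for i in range(n):
                frames[nframe, i, 0] = pos[i, 0]
                frames[nframe, i, 1] = pos[i, 1]
                frames[nframe, i, 2] = pos[i, 2]
            frame_times[nframe] = t
            elog[nframe, 0] = step + 1.0
            elog[nframe, 1] = t
            elog[nframe, 2] = e_h
            elog[nframe, 3] = e_el
            elog[nframe, 4] = e_cp
            elog[nframe, 5] = e_b
            elog[nframe, 6] = epot
            elog[nframe, 7] = ekin
            elog[nframe, 8] = t_inst
            nframe += 1
    return 0, nframe
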