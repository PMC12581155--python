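"""Energy terms, forces and the per-channel energy decomposition.

Nonbonded interactions combine a screened-Coulomb (Debye-Hueckel)
term for charged beads with a Wang-Frenkel hydrophobic term using
per-residue-pair parameters.  Native contacts use a 12-10 potential

    V(r) = eps * (5 (sigma/r)^12 - 6 (sigma/r)^10)

whose minimum of depth -eps sits exactly at r = sigma, so setting
sigma to the native distance places the minimum at the reference
geometry.  All pair terms use the minimum-image convention in a cubic
periodic box.  The total energy is reported as a closed decomposition
into peptide-peptide, peptide-RNA, RNA-RNA, intramolecular-nonbonded,
bonded, and intra/inter native-contact channels; the peptide-peptide
and peptide-RNA channels contain only electrostatic + hydrophobic
cross-chain interactions, with native-contact and intramolecular
contributions excluded (they are reported in their own channels).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import cKDTree

from .units import COULOMB

_R_FLOOR = 1e-6          # numerical guard against division by zero
_OVERLAP_R = 0.05        # nm; pairs closer than this are flagged

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# ---------------------------------------------------------------------------
# scalar/vector pair kernels: each returns (V, dV/dr)
# ---------------------------------------------------------------------------


def lj1210_energy(r, epsilon, sigma):
    """12-10 native-contact potential and its radial derivative."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sr10 = (sigma / r) ** 10
    sr12 = (sigma / r) ** 12
    v = epsilon * (5.0 * sr12 - 6.0 * sr10)
    dvdr = epsilon * (-60.0 * sr12 + 60.0 * sr10) / r
    return v, dvdr


def wang_frenkel_energy(r, epsilon, sigma, mu, nu, cutoff):
    """Wang-Frenkel pair potential, zero at sigma and at the cutoff.

    V(r) = eps * alpha * ((sigma/r)^(2mu) - 1) * ((rc/r)^(2mu) - 1)^(2nu)
    with alpha chosen so the minimum depth is exactly -eps.  Vanishes
    identically for r >= cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    eps = np.asarray(epsilon, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    rc = np.asarray(cutoff, dtype=float)
    rr = np.maximum(r, _R_FLOOR)
    inside = rr < rc
    if np.all(mu == 2.0) and np.all(nu == 1.0):
        # fast integer-exponent path (the default parametrization)
        rcs = (rc / sig) ** 2
        rcs *= rcs
        alpha = 2 * rcs * (3.0 / (2.0 * (rcs - 1))) ** 3
        x = (sig / rr) ** 2
        y = (rc / rr) ** 2
        a = x * x - 1.0
        b = np.where(inside, y * y - 1.0, 0.0)
        v = eps * alpha * a * b * b
        da = -4.0 * x * x / rr
        db = -4.0 * y * y / rr
        dvdr = eps * alpha * (da * b * b + 2.0 * a * b * db)
    else:
        rcs = (rc / sig) ** (2 * mu)
        alpha = (2 * nu * rcs
                 * ((1 + 2 * nu) / (2 * nu * (rcs - 1))) ** (2 * nu + 1))
        a = (sig / rr) ** (2 * mu) - 1.0
        b = (rc / rr) ** (2 * mu) - 1.0
        b = np.where(inside, b, 0.0)
        v = eps * alpha * a * b ** (2 * nu)
        da = -2 * mu * (sig ** (2 * mu)) * rr ** (-2 * mu - 1)
        db = -2 * mu * (rc ** (2 * mu)) * rr ** (-2 * mu - 1)
        dvdr = eps * alpha * (da * b ** (2 * nu)
                              + a * 2 * nu * b ** (2 * nu - 1) * db)
    v = np.where(inside, v, 0.0)
    dvdr = np.where(inside, dvdr, 0.0)
    return v, dvdr


def wf_minimum_location(sigma, mu, nu, cutoff):
    """Radius of the Wang-Frenkel minimum (where V = -epsilon)."""
    rcs = (np.asarray(cutoff) / np.asarray(sigma)) ** (2 * np.asarray(mu))
    return cutoff * ((1 + 2 * nu) / (1 + 2 * nu * rcs)) ** (1 / (2 * mu))


def debye_huckel_energy(r, q_i, q_j, dielectric=80.0, debye_length=0.8,
                        cutoff=3.5, shifted=True):
    """Screened Coulomb interaction, energy-shifted to zero at cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    pref = COULOMB * np.asarray(q_i) * np.asarray(q_j) / dielectric
    rr = np.maximum(r, _R_FLOOR)
    v = pref * np.exp(-rr / debye_length) / rr
    shift = (pref * np.exp(-cutoff / debye_length) / cutoff) if shifted else 0.0
    dvdr = -pref * np.exp(-rr / debye_length) * (1.0 / rr + 1.0 / debye_length) / rr
    inside = rr < cutoff
    v = np.where(inside, v - shift, 0.0)
    dvdr = np.where(inside, dvdr, 0.0)
    return v, dvdr


# ---------------------------------------------------------------------------
# minimum image helpers
# ---------------------------------------------------------------------------


def minimum_image(dvec: np.ndarray, box: float) -> np.ndarray:
    return dvec - box * np.round(dvec / box)


def pair_displacements(positions, ii, jj, box):
    d = minimum_image(positions[jj] - positions[ii], box)
    r = np.sqrt((d * d).sum(axis=-1))
    return d, r


# ---------------------------------------------------------------------------
# energy decomposition container
# ---------------------------------------------------------------------------


@dataclass
class EnergyBreakdown:
    """Per-channel energies in kJ/mol; ``total`` is their exact sum."""

    V_pep_pep: float = 0.0
    V_pep_rna: float = 0.0
    V_rna_rna: float = 0.0
    V_intra: float = 0.0
    V_bonded: float = 0.0
    V_contacts_intra: float = 0.0
    V_contacts_inter: float = 0.0
    overlaps: int = 0

    CHANNELS = ("V_pep_pep", "V_pep_rna", "V_rna_rna", "V_intra",
                "V_bonded", "V_contacts_intra", "V_contacts_inter")

    @property
    def total(self) -> float:
        return float(sum(getattr(self, c) for c in self.CHANNELS))

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d


# ---------------------------------------------------------------------------
# fused pair kernels (numba fast path for the default mu=2, nu=1 table)
# ---------------------------------------------------------------------------


@_njit(fastmath=True)
def _nb_pair_kernel(ii, jj, pos, box, charge, tidx, chain_id, mol_kind,
                    native, eps_t, sig_t, wf_factor, alpha, ke, debye,
                    rc_dh, shift_unit, compute_forces, F):
    vpp = 0.0
    vpr = 0.0
    vrr = 0.0
    vin = 0.0
    n_over = 0
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < _OVERLAP_R:
            n_over += 1
        if r < _R_FLOOR:
            r = _R_FLOOR
        v = 0.0
        dv = 0.0
        if not native[k]:
            s = sig_t[tidx[i], tidx[j]]
            rc = wf_factor * s
            if r < rc:
                e = eps_t[tidx[i], tidx[j]]
                x2 = (s / r) ** 2
                x4 = x2 * x2
                y2 = (rc / r) ** 2
                y4 = y2 * y2
                a = x4 - 1.0
                b = y4 - 1.0
                v += e * alpha * a * b * b
                da = -4.0 * x4 / r
                db = -4.0 * y4 / r
                dv += e * alpha * (da * b * b + 2.0 * a * b * db)
        qq = charge[i] * charge[j]
        if qq != 0.0 and r < rc_dh:
            pref = ke * qq
            ex = np.exp(-r / debye)
            v += pref * (ex / r - shift_unit)
            dv += -pref * ex * (1.0 / r + 1.0 / debye) / r
        if chain_id[i] == chain_id[j]:
            vin += v
        else:
            ks = mol_kind[i] + mol_kind[j]
            if ks == 0:
                vpp += v
            elif ks == 1:
                vpr += v
            else:
                vrr += v
        if compute_forces:
            f = dv / r
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
    return vpp, vpr, vrr, vin, n_over


@_njit(fastmath=True)
def _nb_contact_kernel(ci, cj, pos, box, r0, eps, cls, compute_forces, F):
    v_intra = 0.0
    v_inter = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _R_FLOOR:
            r = _R_FLOOR
        sr2 = (r0[k] / r) ** 2
        sr10 = sr2 * sr2 * sr2 * sr2 * sr2
        sr12 = sr10 * sr2
        v = eps[k] * (5.0 * sr12 - 6.0 * sr10)
        dv = eps[k] * (-60.0 * sr12 + 60.0 * sr10) / r
        if cls[k] == 0:
            v_intra += v
        else:
            v_inter += v
        if compute_forces:
            f = dv / r
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
    return v_intra, v_inter


# ---------------------------------------------------------------------------
# system-level evaluation
# ---------------------------------------------------------------------------


def max_nonbonded_cutoff(system) -> float:
    wf_max = system.config.wf_cutoff_factor * system.pair_table.sigma.max()
    return max(system.config.electrostatics.cutoff, wf_max)


def nonbonded_pairs(positions, system, pairs=None):
    """Candidate nonbonded pairs within the largest cutoff.

    Uses a periodic KD-tree unless an explicit (ii, jj) pair list is
    supplied (the dynamics neighbor list path).  Exclusions (bonded
    1-2/1-3/1-4) are removed here; the returned native mask marks
    pairs whose generic WF attraction is replaced by a native contact.
    """
    box = system.box_length
    if pairs is None:
        cutoff = max_nonbonded_cutoff(system)
        tree = cKDTree(positions % box, boxsize=box)
        pr = tree.query_pairs(cutoff, output_type="ndarray")
        if pr.size == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0, dtype=bool)
        ii, jj = pr[:, 0].astype(np.int64), pr[:, 1].astype(np.int64)
    else:
        ii, jj = pairs
    keys = system.pair_key(ii, jj) if ii.size else np.zeros(0, np.int64)
    if system.exclusion_keys.size and ii.size:
        keep = ~np.isin(keys, system.exclusion_keys, assume_unique=False)
        ii, jj, keys = ii[keep], jj[keep], keys[keep]
    if system.wf_excluded_keys.size and ii.size:
        native = np.isin(keys, system.wf_excluded_keys)
    else:
        native = np.zeros(ii.size, dtype=bool)
    return ii, jj, native


def _accumulate(forces_out, idx, vec):
    n = forces_out.shape[0]
    for d in range(3):
        forces_out[:, d] += np.bincount(idx, weights=vec[:, d], minlength=n)


def energy_and_forces(positions, system, pairs=None, nlist=None,
                      compute_forces=True):
    """Evaluate every term; returns (EnergyBreakdown, forces or None).

    ``nlist`` (a dynamics NeighborList) supplies prefiltered pairs and
    the native-pair mask; otherwise pairs are found from scratch.
    """
    box = system.box_length
    n = system.n_beads
    brk = EnergyBreakdown()
    F = np.zeros((n, 3)) if compute_forces else None
    el = system.config.electrostatics

    if nlist is not None:
        ii, jj = nlist.update(positions)
        native = nlist.native_mask
    else:
        ii, jj, native = nonbonded_pairs(positions, system, pairs=pairs)

    pt = system.pair_table
    use_fast = _HAVE_NUMBA and getattr(pt, "uniform_fast", False)
    if ii.size and use_fast:
        wf_factor = system.config.wf_cutoff_factor
        rcs = wf_factor ** 4
        alpha = 2.0 * rcs * (3.0 / (2.0 * (rcs - 1.0))) ** 3
        Fbuf = F if F is not None else np.zeros((1, 3))
        vpp, vpr, vrr, vin, n_over = _nb_pair_kernel(
            ii, jj, np.ascontiguousarray(positions), box, system.charge,
            system.type_index, system.chain_id, system.mol_kind,
            native, pt.eps, pt.sigma, wf_factor, alpha,
            COULOMB / el.dielectric, el.debye_length, el.cutoff,
            np.exp(-el.cutoff / el.debye_length) / el.cutoff,
            compute_forces, Fbuf)
        brk.V_pep_pep, brk.V_pep_rna = float(vpp), float(vpr)
        brk.V_rna_rna, brk.V_intra = float(vrr), float(vin)
        brk.overlaps = int(n_over)
    elif ii.size:
        d, r = pair_displacements(positions, ii, jj, box)
        brk.overlaps = int(np.count_nonzero(r < _OVERLAP_R))
        ti, tj = system.type_index[ii], system.type_index[jj]
        pt = system.pair_table
        eps_p = pt.eps[ti, tj]
        sig_p = pt.sigma[ti, tj]
        mu_p = pt.mu[ti, tj]
        nu_p = pt.nu[ti, tj]
        rc_p = system.config.wf_cutoff_factor * sig_p
        v_wf, dv_wf = wang_frenkel_energy(r, eps_p, sig_p, mu_p, nu_p, rc_p)
        if native.any():
            v_wf = np.where(native, 0.0, v_wf)
            dv_wf = np.where(native, 0.0, dv_wf)
        qq = system.charge[ii] * system.charge[jj]
        charged = qq != 0.0
        v_dh = np.zeros_like(r)
        dv_dh = np.zeros_like(r)
        if np.any(charged):
            v_dh[charged], dv_dh[charged] = debye_huckel_energy(
                r[charged], system.charge[ii][charged],
                system.charge[jj][charged], el.dielectric,
                el.debye_length, el.cutoff)
        v = v_wf + v_dh
        dv = dv_wf + dv_dh
        same_chain = system.chain_id[ii] == system.chain_id[jj]
        kind_sum = system.mol_kind[ii] + system.mol_kind[jj]
        brk.V_intra = float(v[same_chain].sum())
        cross = ~same_chain
        brk.V_pep_pep = float(v[cross & (kind_sum == 0)].sum())
        brk.V_pep_rna = float(v[cross & (kind_sum == 1)].sum())
        brk.V_rna_rna = float(v[cross & (kind_sum == 2)].sum())
        if compute_forces:
            with np.errstate(invalid="ignore"):
                fpair = (dv / np.maximum(r, _R_FLOOR))[:, None] * d
            _accumulate(F, ii, fpair)
            _accumulate(F, jj, -fpair)

    # native contacts (explicit pair list, no distance cutoff)
    if system.contacts.shape[0]:
        ci, cj = system.contacts[:, 0], system.contacts[:, 1]
        r0 = system.contact_params[:, 0]
        eps_c = system.contact_params[:, 1]
        if _HAVE_NUMBA:
            Fbuf = F if F is not None else np.zeros((1, 3))
            vci, vce = _nb_contact_kernel(
                np.ascontiguousarray(ci), np.ascontiguousarray(cj),
                np.ascontiguousarray(positions), box,
                np.ascontiguousarray(r0), np.ascontiguousarray(eps_c),
                system.contact_class, compute_forces, Fbuf)
            brk.V_contacts_intra = float(vci)
            brk.V_contacts_inter = float(vce)
        else:
            d, r = pair_displacements(positions, ci, cj, box)
            v, dv = lj1210_energy(np.maximum(r, _R_FLOOR), eps_c, r0)
            intra_m = system.contact_class == 0
            brk.V_contacts_intra = float(v[intra_m].sum())
            brk.V_contacts_inter = float(v[~intra_m].sum())
            if compute_forces:
                fpair = (dv / np.maximum(r, _R_FLOOR))[:, None] * d
                _accumulate(F, ci, fpair)
                _accumulate(F, cj, -fpair)

    brk.V_bonded, Fb = bonded_energy_forces(positions, system,
                                            compute_forces=compute_forces)
    if compute_forces and Fb is not None:
        F += Fb
    return brk, F


def total_energy(positions, system, pairs=None) -> EnergyBreakdown:
    brk, _ = energy_and_forces(positions, system, pairs=pairs,
                               compute_forces=False)
    return brk


def forces(positions, system, pairs=None) -> np.ndarray:
    _, F = energy_and_forces(positions, system, pairs=pairs)
    return F


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------


def bonded_energy_forces(positions, system, compute_forces=True):
    box = system.box_length
    V = 0.0
    F = np.zeros_like(positions) if compute_forces else None

    if system.bonds.shape[0]:
        bi, bj = system.bonds[:, 0], system.bonds[:, 1]
        d, r = pair_displacements(positions, bi, bj, box)
        r0, k = system.bond_params[:, 0], system.bond_params[:, 1]
        V += float((k * (r - r0) ** 2).sum())
        if compute_forces:
            dvdr = 2.0 * k * (r - r0)
            fpair = (dvdr / np.maximum(r, _R_FLOOR))[:, None] * d
            _accumulate(F, bi, fpair)
            _accumulate(F, bj, -fpair)

    if system.angles.shape[0]:
        ai, aj, ak = (system.angles[:, 0], system.angles[:, 1],
                      system.angles[:, 2])
        u = minimum_image(positions[ai] - positions[aj], box)
        v = minimum_image(positions[ak] - positions[aj], box)
        nu_ = np.linalg.norm(u, axis=1)
        nv_ = np.linalg.norm(v, axis=1)
        cos_t = np.clip((u * v).sum(axis=1) / (nu_ * nv_), -1.0, 1.0)
        theta = np.arccos(cos_t)
        th0, ka = system.angle_params[:, 0], system.angle_params[:, 1]
        V += float((ka * (theta - th0) ** 2).sum())
        if compute_forces:
            dvdth = 2.0 * ka * (theta - th0)
            sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
            uh = u / nu_[:, None]
            vh = v / nv_[:, None]
            dth_di = (cos_t[:, None] * uh - vh) / (nu_ * sin_t)[:, None]
            dth_dk = (cos_t[:, None] * vh - uh) / (nv_ * sin_t)[:, None]
            fi = -dvdth[:, None] * dth_di
            fk = -dvdth[:, None] * dth_dk
            _accumulate(F, ai, fi)
            _accumulate(F, ak, fk)
            _accumulate(F, aj, -(fi + fk))

    if system.torsions.shape[0]:
        ti = system.torsions
        b1 = minimum_image(positions[ti[:, 1]] - positions[ti[:, 0]], box)
        b2 = minimum_image(positions[ti[:, 2]] - positions[ti[:, 1]], box)
        b3 = minimum_image(positions[ti[:, 3]] - positions[ti[:, 2]], box)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        phi = np.arctan2((np.cross(n1, n2) * (b2 / b2n[:, None])).sum(axis=1),
                         (n1 * n2).sum(axis=1))
        kphi = system.torsion_params[:, 0]
        mult = system.torsion_params[:, 1]
        phase = system.torsion_params[:, 2]
        V += float((kphi * (1.0 + np.cos(mult * phi - phase))).sum())
        if compute_forces:
            dvdphi = -kphi * mult * np.sin(mult * phi - phase)
            n1sq = np.maximum((n1 ** 2).sum(axis=1), 1e-12)
            n2sq = np.maximum((n2 ** 2).sum(axis=1), 1e-12)
            dphi_di = -(b2n / n1sq)[:, None] * n1
            dphi_dl = (b2n / n2sq)[:, None] * n2
            b12 = (b1 * b2).sum(axis=1) / b2n ** 2
            b32 = (b3 * b2).sum(axis=1) / b2n ** 2
            dphi_dj = -(1.0 + b12)[:, None] * dphi_di + b32[:, None] * dphi_dl
            dphi_dk = b12[:, None] * dphi_di - (1.0 + b32)[:, None] * dphi_dl
            for col, grad in ((0, dphi_di), (1, dphi_dj),
                              (2, dphi_dk), (3, dphi_dl)):
                _accumulate(F, ti[:, col], -dvdphi[:, None] * grad)

    return V, F
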