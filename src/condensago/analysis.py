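"""Condensate trajectory analysis.

Implements the order parameters and material-property estimators the
model is studied with:

* ``q_monomer`` / ``q_dimer`` — fraction of native intramolecular
  (foldedness) or intermolecular (dimerization) contacts formed, each
  in [0, 1]; a contact counts as formed when its instantaneous
  distance is within a tolerance factor (default 1.2) of the native
  distance.
* variant classification into the four groups (ordered/disordered x
  monomer/dimer) with thresholds Q_monomer > 0.35 and Q_dimer > 0.3
  (a stricter Q_dimer > 0.5 criterion is supported).
* oligomeric partner counting from pairwise interface energies under
  a negative energy cutoff.
* largest-cluster condensate membership, convex-hull density, radius
  of gyration, mean interaction energies.
* time-and-ensemble averaged MSD with a log-log fit of the diffusion
  exponent alpha and the diffusion coefficient D (MSD = 6 D t when
  diffusion is normal).
* the nematic order parameter S: the largest eigenvalue of the
  ordering matrix Q = (1/2N) sum_i (3 e_i e_i^T - I), with chain
  orientations e_i taken as the principal gyration-tensor axis.
* coexistence densities per temperature and the binodal fit that
  yields the critical temperature Tc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .potentials import lj1210_energy, minimum_image, pair_displacements
from .units import DA_PER_NM3_TO_MG_PER_ML


# ---------------------------------------------------------------------------
# native-contact order parameters
# ---------------------------------------------------------------------------


def q_fraction(positions: np.ndarray, contact_pairs: np.ndarray,
               native_distances: np.ndarray, box_length: float,
               tolerance_factor: float = 1.2) -> float:
    """Fraction of the given contacts formed in one frame."""
    contact_pairs = np.asarray(contact_pairs, dtype=np.int64)
    if contact_pairs.size == 0:
        raise ValueError("contact set must be non-empty")
    _, r = pair_displacements(positions, contact_pairs[:, 0],
                              contact_pairs[:, 1], box_length)
    formed = r <= tolerance_factor * np.asarray(native_distances)
    return float(formed.mean())


def q_monomer(positions: np.ndarray, system,
              tolerance_factor: float = 1.2) -> float:
    """Mean per-chain fraction of intramolecular native contacts."""
    mask = system.contact_class == 0
    if not mask.any():
        raise ValueError("system has no intramolecular contacts")
    pairs = system.contacts[mask]
    r0 = system.contact_params[mask, 0]
    chains = system.chain_id[pairs[:, 0]]
    _, r = pair_displacements(positions, pairs[:, 0], pairs[:, 1],
                              system.box_length)
    formed = r <= tolerance_factor * r0
    vals = [formed[chains == c].mean() for c in np.unique(chains)]
    return float(np.mean(vals))


def q_dimer(positions: np.ndarray, system,
            tolerance_factor: float = 1.2) -> float:
    """Mean best-partner fraction of interface contacts.

    Interface contacts are broadcast to every chain pair, so for each
    peptide the partner maximizing the formed-interface fraction is
    taken before averaging.
    """
    mask = system.contact_class == 1
    if not mask.any():
        return 0.0
    pairs = system.contacts[mask]
    r0 = system.contact_params[mask, 0]
    _, r = pair_displacements(positions, pairs[:, 0], pairs[:, 1],
                              system.box_length)
    formed = (r <= tolerance_factor * r0).astype(float)
    ca = system.chain_id[pairs[:, 0]]
    cb = system.chain_id[pairs[:, 1]]
    pep = system.peptide_chains()
    n = max(pep) + 1
    frac = np.zeros((n, n))
    for (a, b) in {(int(x), int(y)) for x, y in zip(ca, cb)}:
        sel = (ca == a) & (cb == b)
        frac[a, b] = frac[b, a] = formed[sel].mean()
    return float(np.mean([frac[c].max() for c in pep]))


GROUPS = ("mono_dis", "mono_ord", "dimer_dis", "dimer_ord")


def classify_variant(q_mono: float, q_dim: float,
                     q_mono_threshold: float = 0.35,
                     q_dimer_threshold: float = 0.3) -> str:
    """Four-group classification: ordered iff Q_monomer above its
    threshold, dimeric iff Q_dimer above its threshold."""
    for q in (q_mono, q_dim):
        if not (0.0 <= q <= 1.0 + 1e-9):
            raise ValueError("Q values must lie in [0, 1]")
    oligo = "dimer" if q_dim > q_dimer_threshold else "mono"
    order = "ord" if q_mono > q_mono_threshold else "dis"
    return f"{oligo}_{order}"


# ---------------------------------------------------------------------------
# oligomeric partner counting
# ---------------------------------------------------------------------------


def pairwise_interface_energies(positions: np.ndarray, system) -> dict:
    """Summed 12-10 interface-contact energy per peptide chain pair."""
    mask = system.contact_class == 1
    out: dict[tuple[int, int], float] = {}
    if not mask.any():
        return out
    pairs = system.contacts[mask]
    r0 = system.contact_params[mask, 0]
    eps = system.contact_params[mask, 1]
    _, r = pair_displacements(positions, pairs[:, 0], pairs[:, 1],
                              system.box_length)
    v, _ = lj1210_energy(np.maximum(r, 1e-6), eps, r0)
    ca = system.chain_id[pairs[:, 0]]
    cb = system.chain_id[pairs[:, 1]]
    for a, b, vv in zip(ca, cb, v):
        key = (int(min(a, b)), int(max(a, b)))
        out[key] = out.get(key, 0.0) + float(vv)
    return out


def oligomer_partners(frames: Sequence[np.ndarray], system,
                      energy_cutoff: float) -> float:
    """Mean number of interacting partners per peptide.

    A peptide pair counts as interacting when its summed interface
    energy is at or below the (negative) cutoff.  Averaged over
    peptides and frames.
    """
    if energy_cutoff >= 0:
        raise ValueError("energy cutoff must be negative (a binding energy)")
    pep = system.peptide_chains()
    if not pep:
        raise ValueError("no peptide chains")
    means = []
    for pos in frames:
        degree = dict.fromkeys(pep, 0)
        for (a, b), v in pairwise_interface_energies(pos, system).items():
            if v <= energy_cutoff:
                degree[a] += 1
                degree[b] += 1
        means.append(np.mean([degree[c] for c in pep]))
    return float(np.mean(means))


def default_partner_cutoff(contact_set) -> float:
    """25% of the full dimer-interface well depth at the current
    eps_inter scale (negative; raises in the eps_inter = 0 limit)."""
    depth = (contact_set.eps_inter * contact_set.eps0
             * len(contact_set.inter_template()))
    if depth <= 0:
        raise ValueError("interface has zero depth (eps_inter = 0)")
    return -0.25 * depth


# ---------------------------------------------------------------------------
# condensate membership, density, Rg
# ---------------------------------------------------------------------------


def _chain_graph(positions: np.ndarray, system, cluster_cutoff: float):
    box = system.box_length
    tree = cKDTree(positions % box, boxsize=box)
    pr = tree.query_pairs(cluster_cutoff, output_type="ndarray")
    nc = system.n_chains
    if pr.size:
        ca = system.chain_id[pr[:, 0]]
        cb = system.chain_id[pr[:, 1]]
        sel = ca != cb
        ca, cb = ca[sel], cb[sel]
        adj = coo_matrix((np.ones(len(ca)), (ca, cb)), shape=(nc, nc))
        adj = adj + adj.T
    else:
        adj = coo_matrix((nc, nc))
    n_comp, labels = connected_components(adj, directed=False)
    return adj.tocsr(), labels


def condensate_members(positions: np.ndarray, system,
                       cluster_cutoff: float = 1.0) -> list[int]:
    """Chains of the largest distance-linked cluster.

    Ties are broken toward the cluster containing the lowest chain
    index; deterministic for a given frame.
    """
    _, labels = _chain_graph(positions, system, cluster_cutoff)
    sizes = np.bincount(labels)
    best = sizes.max()
    for c in range(system.n_chains):          # lowest-index tie-break
        if sizes[labels[c]] == best:
            return sorted(np.flatnonzero(labels == labels[c]).tolist())
    raise AssertionError("unreachable")


def cluster_coordinates(positions: np.ndarray, system,
                        member_chains: Sequence[int],
                        cluster_cutoff: float = 1.0) -> np.ndarray:
    """Member-bead coordinates made contiguous across the periodic box.

    Each chain is first wrapped rigidly (its centroid into the box),
    then chains are stitched together by a BFS over the contact graph
    applying minimum-image shifts between neighboring chain centroids.
    """
    box = system.box_length
    adj, _ = _chain_graph(positions, system, cluster_cutoff)
    members = list(member_chains)
    chain_coords = {}
    coms = {}
    for c in members:
        idx = system.chain_atoms(c)
        xyz = positions[idx].copy()
        com = xyz.mean(axis=0)
        xyz -= box * np.floor(com / box)
        chain_coords[c] = xyz
        coms[c] = xyz.mean(axis=0)
    root = members[0]
    shift = {root: np.zeros(3)}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur].indices:
            if nb in shift or nb not in chain_coords:
                continue
            d = minimum_image(coms[nb] - (coms[cur] + shift[cur]), box)
            shift[nb] = (coms[cur] + shift[cur]) + d - coms[nb]
            queue.append(nb)
    for c in members:            # disconnected members keep rigid wrap
        shift.setdefault(c, np.zeros(3))
    return np.concatenate([chain_coords[c] + shift[c] for c in members])


def condensate_density(member_coords: np.ndarray, masses: np.ndarray,
                       bead_radius: Optional[float] = None,
                       units: str = "mg/mL") -> float:
    """Cluster mass over its convex-hull volume inflated by one bead
    radius (first-order surface correction).

    By default the inflation radius is half the mean nearest-neighbor
    spacing of the member beads, a parameter-free correction for the
    hull's finite-sampling bias; pass ``bead_radius`` to override.
    """
    member_coords = np.asarray(member_coords, dtype=float)
    if len(member_coords) < 4:
        raise ValueError("need at least 4 beads to define a hull")
    hull = ConvexHull(member_coords)
    if bead_radius is None:
        nn = cKDTree(member_coords).query(member_coords, k=2)[0][:, 1]
        bead_radius = 0.5 * float(nn.mean())
    volume = hull.volume + hull.area * bead_radius
    rho = float(np.sum(masses)) / volume          # Da / nm^3
    if units == "mg/mL":
        return rho * DA_PER_NM3_TO_MG_PER_ML
    if units == "Da/nm^3":
        return rho
    raise ValueError(f"unknown density units {units!r}")


def radius_of_gyration(coords: np.ndarray, masses: Optional[np.ndarray] = None,
                       box_length: Optional[float] = None) -> float:
    """Mass-weighted RMS distance from the centre of mass.

    The chain must be unwrapped; if ``box_length`` is given, any
    consecutive-bead distance above half the box triggers rejection.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two beads")
    if box_length is not None:
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(steps > 0.5 * box_length):
            raise ValueError("chain appears wrapped; unwrap before Rg")
    m = (np.ones(len(coords)) if masses is None
         else np.asarray(masses, dtype=float))
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum()
                         / m.sum()))


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionFit:
    D: float                    # nm^2/ps
    alpha: float
    lags: np.ndarray            # ps
    msd: np.ndarray             # nm^2
    normal_diffusion: bool


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one walker, all lags, O(n log n)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for dim in range(x.shape[1]):
        f = np.fft.rfft(x[:, dim], nfft)
        ac = np.fft.irfft(f * np.conjugate(f), nfft)[:n]
        s2 += ac
    sq = (x ** 2).sum(axis=1)
    s1 = np.zeros(n)
    ss = 2.0 * sq.sum()
    s1[0] = ss
    for m in range(1, n):
        ss -= sq[m - 1] + sq[n - m]
        s1[m] = ss
    counts = n - np.arange(n)
    return (s1 - 2.0 * s2) / counts


def msd_and_fit(times: np.ndarray, positions: np.ndarray,
                fit_window: Optional[tuple[float, float]] = None,
                dim: int = 3,
                alpha_band: tuple[float, float] = (0.9, 1.1)) -> DiffusionFit:
    """Time-and-ensemble averaged MSD with a power-law fit.

    ``positions`` is (n_frames, n_walkers, d) of unwrapped centres of
    mass.  ``alpha`` is the slope of log MSD vs log lag over the fit
    window; ``D`` comes from MSD = 2 d D t over the same window and is
    flagged as normal diffusion only when alpha falls in
    ``alpha_band``.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[:, None, :]
    n = len(times)
    if n < 4:
        raise ValueError("need at least 4 frames")
    msd = np.zeros(n)
    for w in range(positions.shape[1]):
        msd += _msd_fft(positions[:, w, :])
    msd /= positions.shape[1]
    lags = times - times[0]
    if not np.any(msd[1:] > 0):
        raise ValueError("degenerate trajectory: MSD is identically zero")
    if fit_window is None:
        fit_window = (lags[1], lags[n // 2])
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi) & (lags > 0) & (msd > 0)
    if sel.sum() < 2:
        raise ValueError("fit window outside available lag times")
    alpha, logk = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)
    D = float(np.sum(msd[sel] * lags[sel])
              / (2.0 * dim * np.sum(lags[sel] ** 2)))
    normal = alpha_band[0] <= alpha <= alpha_band[1]
    return DiffusionFit(D=D, alpha=float(alpha), lags=lags, msd=msd,
                        normal_diffusion=bool(normal))


def chain_com_series(trajectory, system, chains: Sequence[int]) -> np.ndarray:
    """(n_frames, n_chains, 3) unwrapped centre-of-mass series."""
    out = np.empty((trajectory.n_frames, len(chains), 3))
    for k, c in enumerate(chains):
        idx = system.chain_atoms(c)
        m = system.mass[idx]
        out[:, k, :] = ((m[None, :, None]
                         * trajectory.positions[:, idx, :]).sum(axis=1)
                        / m.sum())
    return out


# ---------------------------------------------------------------------------
# nematic order
# ---------------------------------------------------------------------------


def chain_orientation(coords: np.ndarray) -> Optional[np.ndarray]:
    """Principal gyration-tensor axis (unit vector, sign-irrelevant);
    None for a degenerate (point-like) chain."""
    x = coords - coords.mean(axis=0)
    gyr = x.T @ x / len(x)
    w, v = np.linalg.eigh(gyr)
    if w[-1] < 1e-12:
        return None
    return v[:, -1]


def nematic_order(orientations: np.ndarray) -> float:
    """Largest eigenvalue of Q = (1/2N) sum (3 e e^T - I)."""
    e = np.asarray(orientations, dtype=float)
    if e.ndim != 2 or len(e) < 1:
        raise ValueError("need at least one orientation vector")
    e = e / np.linalg.norm(e, axis=1)[:, None]
    q = (3.0 * np.einsum("ni,nj->ij", e, e) / len(e) - np.eye(3)) / 2.0
    q = 0.5 * (q + q.T)
    return float(np.linalg.eigvalsh(q)[-1])


def nematic_order_frame(positions: np.ndarray, system,
                        chains: Optional[Sequence[int]] = None) -> float:
    chains = list(chains) if chains is not None else system.peptide_chains()
    axes = []
    for c in chains:
        ax = chain_orientation(positions[system.chain_atoms(c)])
        if ax is None:
            warnings.warn(f"chain {c} has zero-length axis; skipped")
            continue
        axes.append(ax)
    if not axes:
        raise ValueError("no chain with a defined orientation axis")
    return nematic_order(np.array(axes))


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def energy_means(trajectory) -> tuple[float, float]:
    """Time averages of the peptide-peptide and peptide-RNA channels."""
    df = trajectory.energies
    for col in ("V_pep_pep", "V_pep_rna"):
        if col not in df.columns:
            raise ValueError(f"energy log lacks column {col}")
    return float(df["V_pep_pep"].mean()), float(df["V_pep_rna"].mean())


def helicity_proxy(positions: np.ndarray, system,
                   helix_pairs: np.ndarray, native_distances: np.ndarray,
                   tolerance_factor: float = 1.2) -> float:
    """Fraction of designated helix-region native contacts formed; a
    contact-based structural proxy, not a dihedral assignment."""
    helix_pairs = np.asarray(helix_pairs)
    if helix_pairs.size == 0:
        raise ValueError("helix contact subset must be non-empty")
    return q_fraction(positions, helix_pairs, native_distances,
                      system.box_length, tolerance_factor)


# ---------------------------------------------------------------------------
# phase behavior
# ---------------------------------------------------------------------------


@dataclass
class PhasePoint:
    temperature: float
    rho_dense: float
    rho_dilute: float
    coexists: bool

    def __post_init__(self):
        if self.coexists and self.rho_dense < self.rho_dilute:
            raise ValueError("rho_dense must be >= rho_dilute at coexistence")


def coexistence_densities(trajectory, system,
                          cluster_cutoff: float = 1.0,
                          min_cluster_fraction: float = 0.5,
                          min_persistence: float = 0.8,
                          units: str = "mg/mL") -> PhasePoint:
    """Dense/dilute densities averaged over frames.

    Coexistence requires the largest cluster to hold at least
    ``min_cluster_fraction`` of the peptide chains in at least
    ``min_persistence`` of the frames.
    """
    pep = set(system.peptide_chains())
    dense_vals, dilute_vals, big = [], [], []
    box_vol = system.box_length ** 3
    for pos in trajectory.positions:
        members = condensate_members(pos, system, cluster_cutoff)
        mem_pep = pep.intersection(members)
        big.append(len(mem_pep) >= min_cluster_fraction * max(len(pep), 1))
        midx = np.concatenate([system.chain_atoms(c) for c in members])
        if len(midx) >= 4 and len(members) > 1:
            coords = cluster_coordinates(pos, system, members,
                                         cluster_cutoff)
            hull = ConvexHull(coords)
            nn = cKDTree(coords).query(coords, k=2)[0][:, 1]
            vol = hull.volume + hull.area * 0.5 * float(nn.mean())
            dense_vals.append(system.mass[midx].sum() / vol)
        else:
            dense_vals.append(np.nan)
            vol = 0.0
        out_mask = np.ones(system.n_beads, dtype=bool)
        out_mask[midx] = False
        free_vol = max(box_vol - vol, 1e-9)
        dilute_vals.append(system.mass[out_mask].sum() / free_vol)
    conv = DA_PER_NM3_TO_MG_PER_ML if units == "mg/mL" else 1.0
    coexists = bool(np.mean(big) >= min_persistence)
    rho_d = float(np.nanmean(dense_vals)) * conv if np.any(
        np.isfinite(dense_vals)) else 0.0
    rho_l = float(np.mean(dilute_vals)) * conv
    if not coexists:
        return PhasePoint(trajectory.temperature, rho_d, rho_l, False)
    return PhasePoint(trajectory.temperature, max(rho_d, rho_l), rho_l, True)


@dataclass
class BinodalFit:
    """Critical point from a simultaneous fit of the order-parameter
    scaling law  rho_dense - rho_dilute = A (1 - T/Tc)^beta  and the
    law of rectilinear diameters."""

    Tc: float
    amplitude: float
    beta_exponent: float
    rho_c: float
    diameter_slope: float
    residual: float
    points: list = field(default_factory=list)

    def predict(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        T = np.asarray(T, dtype=float)
        t = np.maximum(1.0 - T / self.Tc, 0.0)
        delta = self.amplitude * t ** self.beta_exponent
        mean = self.rho_c + self.diameter_slope * t
        return mean + delta / 2.0, mean - delta / 2.0


def fit_tc(points: Sequence[PhasePoint], beta: float = 0.325) -> BinodalFit:
    """Fit the binodal and return the critical temperature.

    Uses only points flagged as coexisting; requires at least three.
    beta defaults to the 3D Ising value 0.325.
    """
    from scipy.optimize import least_squares

    pts = [p for p in points if p.coexists]
    if len(pts) < 3:
        raise ValueError("need at least 3 coexisting temperatures")
    T = np.array([p.temperature for p in pts])
    rd = np.array([p.rho_dense for p in pts])
    rl = np.array([p.rho_dilute for p in pts])
    order = np.argsort(T)
    if np.any(np.diff(rd[order]) > 0.15 * max(rd.max(), 1e-12)):
        warnings.warn("dense-branch densities are not monotone in T")
    delta = rd - rl
    mean = (rd + rl) / 2.0
    Tmax, Tmin = T.max(), T.min()
    Tc0 = Tmax + 0.1 * max(Tmax - Tmin, 1.0)

    def resid(p):
        Tc, A, rho_c, slope = p
        t = 1.0 - T / Tc
        t = np.maximum(t, 1e-12)
        return np.concatenate([
            delta - A * t ** beta,
            mean - (rho_c + slope * t),
        ])

    A0 = max(delta.max() / max((1 - Tmin / Tc0) ** beta, 1e-6), 1e-6)
    x0 = [Tc0, A0, float(mean.mean()), 0.0]
    res = least_squares(
        resid, x0,
        bounds=([Tmax + 1e-9, 1e-12, -np.inf, -np.inf],
                [np.inf] * 4),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    Tc, A, rho_c, slope = res.x
    return BinodalFit(Tc=float(Tc), amplitude=float(A), beta_exponent=beta,
                      rho_c=float(rho_c), diameter_slope=float(slope),
                      residual=float(np.sqrt(np.mean(res.fun ** 2))),
                      points=list(points))


def relative_stability(tc_a: float, tc_b: float) -> float:
    """Percent change of tc_a relative to tc_b: 100 (a - b) / b."""
    if tc_b <= 0:
        raise ValueError("reference Tc must be positive")
    return 100.0 * (tc_a - tc_b) / tc_b


# ---------------------------------------------------------------------------
# per-variant metric bundle
# ---------------------------------------------------------------------------


@dataclass
class CondensateMetrics:
    Q_monomer: float = np.nan
    Q_dimer: float = np.nan
    mean_partners: float = np.nan
    group: str = ""
    density: float = np.nan
    Rg_pep: float = np.nan
    Rg_rna: float = np.nan
    D: float = np.nan
    alpha: float = np.nan
    S: float = np.nan
    V_pep_pep: float = np.nan
    V_pep_rna: float = np.nan
    helicity_proxy: float = np.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(trajectory, system, contact_set=None,
                    tolerance_factor: float = 1.2,
                    partner_cutoff: Optional[float] = None,
                    cluster_cutoff: float = 1.0,
                    msd_fit_window: Optional[tuple[float, float]] = None,
                    ) -> CondensateMetrics:
    """Every summary statistic for one production trajectory."""
    m = CondensateMetrics()
    frames = trajectory.positions
    has_intra = bool((system.contact_class == 0).any())
    has_inter = bool((system.contact_class == 1).any())
    if has_intra:
        m.Q_monomer = float(np.mean(
            [q_monomer(p, system, tolerance_factor) for p in frames]))
    m.Q_dimer = (float(np.mean(
        [q_dimer(p, system, tolerance_factor) for p in frames]))
        if has_inter else 0.0)
    if has_intra:
        m.group = classify_variant(m.Q_monomer, m.Q_dimer)
    if has_inter:
        if partner_cutoff is None and contact_set is not None:
            partner_cutoff = default_partner_cutoff(contact_set)
        if partner_cutoff is not None:
            m.mean_partners = oligomer_partners(frames, system,
                                                partner_cutoff)
    else:
        m.mean_partners = 0.0

    last = frames[-1]
    members = condensate_members(last, system, cluster_cutoff)
    midx = np.concatenate([system.chain_atoms(c) for c in members])
    if len(midx) >= 4:
        coords = cluster_coordinates(last, system, members, cluster_cutoff)
        m.density = condensate_density(coords, system.mass[midx])
    pep = system.peptide_chains()
    rna = system.rna_chains()
    m.Rg_pep = float(np.mean(
        [radius_of_gyration(last[system.chain_atoms(c)],
                            system.mass[system.chain_atoms(c)])
         for c in pep])) if pep else np.nan
    m.Rg_rna = float(np.mean(
        [radius_of_gyration(last[system.chain_atoms(c)],
                            system.mass[system.chain_atoms(c)])
         for c in rna])) if rna else np.nan
    try:
        m.S = float(np.mean(
            [nematic_order_frame(p, system, pep) for p in frames]))
    except ValueError:
        pass
    if trajectory.n_frames >= 4 and pep:
        com = chain_com_series(trajectory, system, pep)
        try:
            fit = msd_and_fit(trajectory.times, com,
                              fit_window=msd_fit_window)
            m.D, m.alpha = fit.D, fit.alpha
        except ValueError:
            pass
    if len(trajectory.energies):
        m.V_pep_pep, m.V_pep_rna = energy_means(trajectory)
    return m
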