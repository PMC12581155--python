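"""Synthetic inputs with planted ground truth.

Everything the package needs to build and test itself is generated
here procedurally: a surrogate helix-hairpin-helix (HhH) dimer
reference (the real reference structure is not distributed, so an
ideal-geometry stand-in with a C2-symmetric interface is built
instead), rod frames for nematic-order checks, Brownian and
fractional-Brownian walks for diffusion-fit checks, synthetic
binodals for the critical-temperature fit, and planted two-phase
configurations for coexistence-density recovery.  Every generator is
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import PhasePoint
from .model_setup import MoleculeKind

# ideal CG helix geometry: rise per residue, turn per residue, radius
HELIX_RISE = 0.15        # nm
HELIX_TURN = np.deg2rad(100.0)
HELIX_RADIUS = 0.23      # nm


# ---------------------------------------------------------------------------
# surrogate HhH dimer reference
# ---------------------------------------------------------------------------


def make_hhh_dimer_reference(n_res: int = 26, seed: int = 0,
                             hairpin_gap: float = 0.8,
                             interface_gap: float = 0.75,
                             jitter: float = 0.0):
    """Ideal two-helix hairpin chains packed into a C2-symmetric dimer.

    Returns (coords of shape (2 n_res, 3), chain labels).  Chain B is
    chain A rotated by pi about the z axis through the interface
    midpoint, so the dimer is exactly C2-symmetric (up to optional
    seeded jitter).
    """
    if n_res < 12:
        raise ValueError("need n_res >= 12 to form two helices")
    n_half = (n_res - 2) // 2
    n_turn = n_res - 2 * n_half
    chain = np.zeros((n_res, 3))
    # helix 1 ascending +z around axis x=0, y=0
    for i in range(n_half):
        chain[i] = (HELIX_RADIUS * np.cos(HELIX_TURN * i),
                    HELIX_RADIUS * np.sin(HELIX_TURN * i),
                    HELIX_RISE * i)
    z_top = HELIX_RISE * (n_half - 1)
    # hairpin turn bridging to the second helix axis at x=hairpin_gap
    for t in range(n_turn):
        frac = (t + 1) / (n_turn + 1)
        chain[n_half + t] = (hairpin_gap * frac,
                             HELIX_RADIUS * np.sin(np.pi * frac),
                             z_top + 0.25 * np.sin(np.pi * frac))
    # helix 2 descending -z around axis x=hairpin_gap
    for j in range(n_half):
        i = n_half + n_turn + j
        chain[i] = (hairpin_gap + HELIX_RADIUS * np.cos(HELIX_TURN * j + np.pi),
                    HELIX_RADIUS * np.sin(HELIX_TURN * j + np.pi),
                    z_top - HELIX_RISE * j)
    # C2 partner: rotate pi about the z axis placed at the interface
    axis_y = -interface_gap / 2.0
    rot = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    chain_b = (chain - [0.0, axis_y, 0.0]) @ rot.T + [0.0, axis_y, 0.0]
    coords = np.concatenate([chain, chain_b])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    labels = np.repeat([0, 1], n_res)
    return coords, labels


# ---------------------------------------------------------------------------
# minimal frame container for analysis-only fixtures
# ---------------------------------------------------------------------------


@dataclass
class FrameSystem:
    """Duck-typed stand-in for a full System in analysis functions."""

    positions: np.ndarray
    chain_slices: list
    box_length: float
    mass: np.ndarray
    chain_kinds: list = field(default_factory=list)

    def __post_init__(self):
        self.n_beads = len(self.positions)
        self.chain_id = np.empty(self.n_beads, dtype=np.int64)
        for c, (a, b) in enumerate(self.chain_slices):
            self.chain_id[a:b] = c
        if not self.chain_kinds:
            self.chain_kinds = [MoleculeKind.peptide] * len(self.chain_slices)

    @property
    def n_chains(self):
        return len(self.chain_slices)

    def chain_atoms(self, chain):
        a, b = self.chain_slices[chain]
        return np.arange(a, b)

    def peptide_chains(self):
        return [c for c, k in enumerate(self.chain_kinds)
                if k is MoleculeKind.peptide]

    def rna_chains(self):
        return [c for c, k in enumerate(self.chain_kinds)
                if k is MoleculeKind.rna]


def single_frame_trajectory(positions: np.ndarray, temperature: float):
    """Wrap one frame so per-frame analysis drivers accept it."""
    return SimpleNamespace(positions=np.asarray(positions)[None, ...],
                           temperature=temperature, n_frames=1,
                           times=np.array([0.0]),
                           energies=pd.DataFrame())


# ---------------------------------------------------------------------------
# rod frames for nematic order
# ---------------------------------------------------------------------------


def make_rod_frame(n_chains: int, alignment_noise: float, seed: int = 0,
                   n_beads: int = 5, rod_length: float = 2.0,
                   box_length: float = 100.0) -> FrameSystem:
    """Rigid rods with axes drawn from a cone about z.

    ``alignment_noise`` is the cone half-angle in radians; 0 gives
    perfect alignment and any value >= pi samples the full sphere
    (isotropic).
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(seed)
    cos_min = np.cos(min(alignment_noise, np.pi))
    pos = np.empty((n_chains * n_beads, 3))
    slices = []
    t = np.linspace(-0.5, 0.5, n_beads) * rod_length
    for c in range(n_chains):
        u = rng.uniform(cos_min, 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        s = np.sqrt(max(1.0 - u * u, 0.0))
        axis = np.array([s * np.cos(phi), s * np.sin(phi), u])
        com = rng.uniform(0.25 * box_length, 0.75 * box_length, size=3)
        pos[c * n_beads:(c + 1) * n_beads] = com + t[:, None] * axis
        slices.append((c * n_beads, (c + 1) * n_beads))
    return FrameSystem(pos, slices, box_length,
                       np.full(n_chains * n_beads, 100.0))


# ---------------------------------------------------------------------------
# diffusion trajectories
# ---------------------------------------------------------------------------


def _fgn_davies_harte(n: int, hurst: float, rng) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise (circulant embedding)."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(c).real
    lam = np.maximum(lam, 0.0)          # clip tiny negative round-off
    m = len(c)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return f.real[:n]


def make_diffusion_trajectory(kind: str, n_steps: int, dt: float,
                              seed: int = 0, D: float = 1e-3,
                              hurst: float = 0.5, n_walkers: int = 1,
                              dim: int = 3):
    """Seeded random walks with known transport parameters.

    ``kind='brownian'``: Gaussian increments of variance 2 D dt per
    dimension, so MSD = 2 d D t exactly in expectation.
    ``kind='fbm'``: fractional Brownian motion with Hurst exponent H,
    so the MSD exponent alpha equals 2 H.
    Returns (times, positions) with positions (n_steps+1, n_walkers, dim).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1) * dt
    pos = np.zeros((n_steps + 1, n_walkers, dim))
    if kind == "brownian":
        incr = rng.normal(scale=np.sqrt(2.0 * D * dt),
                          size=(n_steps, n_walkers, dim))
        pos[1:] = np.cumsum(incr, axis=0)
    elif kind == "fbm":
        scale = dt ** hurst
        for w in range(n_walkers):
            for d in range(dim):
                fgn = _fgn_davies_harte(n_steps, hurst, rng)
                pos[1:, w, d] = np.cumsum(fgn) * scale
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return times, pos


# ---------------------------------------------------------------------------
# synthetic binodals and two-phase frames
# ---------------------------------------------------------------------------


def make_binodal(Tc: float, amplitude: float, T_list: Sequence[float],
                 beta: float = 0.325, rho_c: float = 300.0,
                 diameter_slope: float = 50.0, noise: float = 0.0,
                 seed: int = 0) -> list[PhasePoint]:
    """Coexistence points from the scaling law plus rectilinear
    diameter, with optional multiplicative noise."""
    if np.any(np.asarray(T_list) >= Tc):
        raise ValueError("all temperatures must be below Tc")
    rng = np.random.default_rng(seed)
    out = []
    for T in T_list:
        t = 1.0 - T / Tc
        delta = amplitude * t ** beta
        mean = rho_c + diameter_slope * t
        rho_d = mean + delta / 2.0
        rho_l = mean - delta / 2.0
        if noise > 0:
            rho_d *= 1.0 + noise * rng.standard_normal()
            rho_l *= 1.0 + noise * rng.standard_normal()
        out.append(PhasePoint(float(T), float(rho_d), float(rho_l), True))
    return out


def make_two_phase_frame(rho_dense: float, rho_dilute: float,
                         box_length: float = 12.0, seed: int = 0,
                         droplet_radius: float = 4.0,
                         bead_mass: float = 100.0,
                         units: str = "Da/nm^3") -> FrameSystem:
    """A spherical dense droplet inside a dilute gas, planted densities.

    Bead counts follow from the requested densities; each bead is its
    own single-bead chain so cluster analysis sees a chain graph.
    ``units='mg/mL'`` converts the planted values before sampling.
    """
    from .units import DA_PER_NM3_TO_MG_PER_ML

    if not rho_dense > rho_dilute >= 0:
        raise ValueError("require rho_dense > rho_dilute >= 0")
    conv = DA_PER_NM3_TO_MG_PER_ML if units == "mg/mL" else 1.0
    rho_d = rho_dense / conv            # Da/nm^3
    rho_l = rho_dilute / conv
    rng = np.random.default_rng(seed)
    center = np.full(3, box_length / 2.0)
    v_drop = 4.0 / 3.0 * np.pi * droplet_radius ** 3
    n_dense = int(round(rho_d * v_drop / bead_mass))
    n_dilute = int(round(rho_l * (box_length ** 3 - v_drop) / bead_mass))
    pts = []
    while len(pts) < n_dense:
        p = rng.uniform(-droplet_radius, droplet_radius, size=3)
        if p @ p <= droplet_radius ** 2:
            pts.append(center + p)
    gas = []
    while len(gas) < n_dilute:
        p = rng.uniform(0, box_length, size=3)
        if np.linalg.norm(p - center) > droplet_radius + 0.3:
            gas.append(p)
    pos = np.array(pts + gas) if (pts or gas) else np.zeros((0, 3))
    slices = [(i, i + 1) for i in range(len(pos))]
    return FrameSystem(pos, slices, box_length,
                       np.full(len(pos), bead_mass))
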