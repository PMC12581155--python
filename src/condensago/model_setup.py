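"""Coarse-grained topology construction and system assembly.

Peptides are represented by one bead per residue centred at the
C-alpha position; RNA nucleotides by three beads (phosphate, sugar,
base).  Bonded interactions are harmonic bonds and angles, plus soft
single-cosine torsions on runs of four successive C-alpha beads.

Charge convention: R and K carry +1e, D and E carry -1e, the RNA
phosphate bead carries -1e; every other bead is neutral.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import yaml

from .units import KB  # noqa: F401  (re-exported for convenience)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain charge at neutral pH, elementary charges
AA_CHARGE = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0}

PHOSPHATE_CODE = "p"
SUGAR_CODE = "s"
BASE_CODE = "U"
RNA_CODES = (PHOSPHATE_CODE, SUGAR_CODE, BASE_CODE)

def surrogate_pa_sequence(n_res: int = 26) -> str:
    """Synthetic PA-like sequence: arginine-rich N-terminal half,
    glutamates toward the C-terminus.

    The peptide the model was built around is not distributed with the
    package; this deterministic surrogate reproduces its charge layout
    (positive N-half, acidic C-tail) at any length and is used by
    every bundled example and test.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    half = n_res // 2
    n_half = "".join("RLARVA"[i % 6] for i in range(half))
    c_half = "".join("AELSAE"[i % 6] for i in range(n_res - half))
    return n_half + c_half


#: default surrogate for the PA peptide (synthetic sequence, length 26)
PA_SURROGATE_SEQUENCE = surrogate_pa_sequence(26)


class MoleculeKind(int, Enum):
    peptide = 0
    rna = 1


class BeadRole(int, Enum):
    calpha = 0
    phosphate = 1
    sugar = 2
    base = 3


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained interaction site."""

    index: int
    chain_id: int
    molecule_kind: MoleculeKind
    bead_role: BeadRole
    residue_code: str
    charge: float
    mass: float


@dataclass
class BondedParams:
    """Harmonic bond/angle constants and the soft torsion amplitude.

    Values are conventional CG choices (kJ/mol, nm, rad); all are
    config knobs rather than fitted quantities.
    """

    pep_bond_length: float = 0.38
    bond_k: float = 8000.0
    pep_angle_theta0: float = 2.0
    angle_k: float = 20.0
    torsion_k: float = 0.5  # soft torsions, amplitude <= 1 kJ/mol
    torsion_mult: int = 1
    torsion_phase: float = 0.0
    rna_ps_bond: float = 0.38   # phosphate-sugar, same nucleotide
    rna_sb_bond: float = 0.35   # sugar-base
    rna_sp_bond: float = 0.40   # sugar(i)-phosphate(i+1)
    rna_angle_theta0: float = 1.8
    rna_angle_k: float = 10.0


@dataclass
class Topology:
    """Bead list plus bonded terms for one molecule template.

    ``bonds`` rows are (i, j, r0, k); ``angles`` rows are
    (i, j, k, theta0, k_theta); ``torsions`` rows are
    (i, j, k, l, k_phi, multiplicity, phase).
    """

    beads: list[BeadSpec]
    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)
    torsions: list[tuple] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def total_charge(self) -> float:
        return sum(b.charge for b in self.beads)

    @property
    def residue_codes(self) -> list[str]:
        return [b.residue_code for b in self.beads]

    def validate(self) -> None:
        chains = {b.chain_id for b in self.beads}
        for i, j, *_ in self.bonds:
            if self.beads[i].chain_id != self.beads[j].chain_id:
                raise ValueError("bond joins beads of different chains")
        seen = set()
        for i, j, *_ in self.bonds:
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        for *quad, _k, _m, _p in self.torsions:
            if any(self.beads[q].molecule_kind is not MoleculeKind.peptide
                   for q in quad):
                raise ValueError("torsions are defined on peptide chains only")
        del chains

    def to_dict(self) -> dict:
        return {
            "beads": [
                {
                    "index": b.index,
                    "chain_id": b.chain_id,
                    "molecule_kind": b.molecule_kind.name,
                    "bead_role": b.bead_role.name,
                    "residue_code": b.residue_code,
                    "charge": b.charge,
                    "mass": b.mass,
                }
                for b in self.beads
            ],
            "bonds": [list(t) for t in self.bonds],
            "angles": [list(t) for t in self.angles],
            "torsions": [list(t) for t in self.torsions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        beads = [
            BeadSpec(
                index=b["index"],
                chain_id=b["chain_id"],
                molecule_kind=MoleculeKind[b["molecule_kind"]],
                bead_role=BeadRole[b["bead_role"]],
                residue_code=b["residue_code"],
                charge=b["charge"],
                mass=b["mass"],
            )
            for b in d["beads"]
        ]
        return cls(
            beads=beads,
            bonds=[tuple(t) for t in d["bonds"]],
            angles=[tuple(t) for t in d["angles"]],
            torsions=[tuple(t) for t in d["torsions"]],
        )


def residue_charge(code: str) -> float:
    if code == PHOSPHATE_CODE:
        return -1.0
    return AA_CHARGE.get(code, 0.0)


def sequence_net_charge(sequence: str) -> float:
    return float(sum(residue_charge(c) for c in sequence))


def mutate_r_to_k(sequence: str) -> str:
    """Replace every arginine by lysine (charge-preserving mutation)."""
    _check_sequence(sequence)
    return sequence.replace("R", "K")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, code in enumerate(sequence):
        if code not in AA_ALPHABET:
            raise ValueError(
                f"unknown residue code {code!r} at position {pos}"
            )


def _bond_angle_dihedral(coords: np.ndarray):
    """Native bond lengths, angles and dihedrals of a chain trace."""
    coords = np.asarray(coords, dtype=float)
    b = np.diff(coords, axis=0)
    lengths = np.linalg.norm(b, axis=1)
    u, v = b[:-1], b[1:]
    cos_t = np.clip((u * v).sum(axis=1)
                    / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)),
                    -1, 1)
    angles = np.pi - np.arccos(cos_t)
    dihedrals = []
    for i in range(len(coords) - 3):
        b1, b2, b3 = b[i], b[i + 1], b[i + 2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        dihedrals.append(np.arctan2(
            np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2))
    return lengths, angles, np.array(dihedrals)


def build_peptide_topology(
    sequence: str,
    params: Optional[BondedParams] = None,
    mass: float = 100.0,
    chain_id: int = 0,
    reference_coords: Optional[np.ndarray] = None,
) -> Topology:
    """One C-alpha bead per residue with N-1 bonds, N-2 angles and N-3
    soft torsions along the chain.

    With ``reference_coords`` the bonded equilibria (bond lengths,
    angles, torsion phases) are taken from the native chain trace, the
    structure-based convention; otherwise the generic values in
    ``params`` apply.
    """
    _check_sequence(sequence)
    params = params or BondedParams()
    beads = [
        BeadSpec(
            index=i,
            chain_id=chain_id,
            molecule_kind=MoleculeKind.peptide,
            bead_role=BeadRole.calpha,
            residue_code=code,
            charge=residue_charge(code),
            mass=mass,
        )
        for i, code in enumerate(sequence)
    ]
    n = len(sequence)
    if reference_coords is not None:
        ref = np.asarray(reference_coords, dtype=float)
        if ref.shape != (n, 3):
            raise ValueError("reference coordinates shape mismatch")
        r0s, th0s, phi0s = _bond_angle_dihedral(ref)
        bonds = [(i, i + 1, float(r0s[i]), params.bond_k)
                 for i in range(n - 1)]
        angles = [(i, i + 1, i + 2, float(th0s[i]), params.angle_k)
                  for i in range(n - 2)]
        # phase pi relative to the native dihedral puts the cosine
        # minimum exactly at the native conformation
        torsions = [
            (i, i + 1, i + 2, i + 3, params.torsion_k, 1,
             float(phi0s[i] + np.pi))
            for i in range(n - 3)
        ]
    else:
        bonds = [(i, i + 1, params.pep_bond_length, params.bond_k)
                 for i in range(n - 1)]
        angles = [(i, i + 1, i + 2, params.pep_angle_theta0, params.angle_k)
                  for i in range(n - 2)]
        torsions = [
            (i, i + 1, i + 2, i + 3,
             params.torsion_k, params.torsion_mult, params.torsion_phase)
            for i in range(n - 3)
        ]
    topo = Topology(beads=beads, bonds=bonds, angles=angles,
                    torsions=torsions)
    topo.validate()
    return topo


def build_rna_topology(
    n_nt: int,
    params: Optional[BondedParams] = None,
    mass: float = 100.0,
    chain_id: int = 0,
) -> Topology:
    """Three beads per nucleotide (phosphate, sugar, base), polyU.

    Connectivity: phosphate(i)-sugar(i), sugar(i)-base(i) within a
    nucleotide and sugar(i)-phosphate(i+1) along the backbone.
    """
    if n_nt < 1:
        raise ValueError("n_nt must be >= 1")
    params = params or BondedParams()
    beads = []
    roles = (BeadRole.phosphate, BeadRole.sugar, BeadRole.base)
    codes = RNA_CODES
    for nt in range(n_nt):
        for k in range(3):
            idx = 3 * nt + k
            beads.append(
                BeadSpec(
                    index=idx,
                    chain_id=chain_id,
                    molecule_kind=MoleculeKind.rna,
                    bead_role=roles[k],
                    residue_code=codes[k],
                    charge=residue_charge(codes[k]),
                    mass=mass,
                )
            )
    bonds = []
    angles = []
    for nt in range(n_nt):
        p, s, b = 3 * nt, 3 * nt + 1, 3 * nt + 2
        bonds.append((p, s, params.rna_ps_bond, params.bond_k))
        bonds.append((s, b, params.rna_sb_bond, params.bond_k))
        if nt + 1 < n_nt:
            p_next = 3 * (nt + 1)
            bonds.append((s, p_next, params.rna_sp_bond, params.bond_k))
            angles.append((p, s, p_next,
                           params.rna_angle_theta0, params.rna_angle_k))
            angles.append((s, p_next, 3 * (nt + 1) + 1,
                           params.rna_angle_theta0, params.rna_angle_k))
    topo = Topology(beads=beads, bonds=bonds, angles=angles, torsions=[])
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# pair table (hydrophobic Wang-Frenkel parameters)
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy, used only to shape the surrogate table
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

# approximate CG bead diameters, nm
_SIGMA = {
    "A": 0.50, "C": 0.55, "D": 0.56, "E": 0.59, "F": 0.64, "G": 0.45,
    "H": 0.61, "I": 0.62, "K": 0.64, "L": 0.62, "M": 0.62, "N": 0.57,
    "P": 0.56, "Q": 0.60, "R": 0.66, "S": 0.52, "T": 0.56, "V": 0.59,
    "W": 0.68, "Y": 0.65,
    PHOSPHATE_CODE: 0.50, SUGAR_CODE: 0.52, BASE_CODE: 0.56,
}


class PairTable:
    """Symmetric per-pair Wang-Frenkel parameters.

    Stores epsilon (kJ/mol), sigma (nm) and the shape exponents mu, nu
    for every ordered pair of residue codes.  ``surrogate()`` builds a
    synthetic table with the structure of a transferable residue-level
    parametrization: epsilon from a geometric-mean hydropathy rule with
    explicit cation-pi-like boosts for arginine/aromatics against the
    RNA base, sigma by arithmetic mixing.  It is not a published force
    field; it exists so the model runs self-contained.
    """

    def __init__(self, codes: Sequence[str], eps: np.ndarray,
                 sigma: np.ndarray, mu: np.ndarray, nu: np.ndarray):
        self.codes = list(codes)
        self.index = {c: i for i, c in enumerate(self.codes)}
        for name, arr in (("eps", eps), ("sigma", sigma),
                          ("mu", mu), ("nu", nu)):
            if not np.allclose(arr, arr.T):
                raise ValueError(f"pair table {name} must be symmetric")
        self.eps = np.asarray(eps, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        self.nu = np.asarray(nu, dtype=float)
        # the fused pair kernel handles the default exponents only
        self.uniform_fast = bool(np.all(self.mu == 2.0)
                                 and np.all(self.nu == 1.0))

    def entry(self, code_i: str, code_j: str) -> dict:
        try:
            a, b = self.index[code_i], self.index[code_j]
        except KeyError as exc:
            raise KeyError(
                f"no pair-table entry for residue pair "
                f"({code_i!r}, {code_j!r})"
            ) from exc
        return {
            "epsilon": float(self.eps[a, b]),
            "sigma": float(self.sigma[a, b]),
            "mu": float(self.mu[a, b]),
            "nu": float(self.nu[a, b]),
        }

    @classmethod
    def surrogate(cls, eps_max: float = 0.8, mu: float = 2.0,
                  nu: float = 1.0) -> "PairTable":
        codes = list(AA_ALPHABET) + list(RNA_CODES)
        n = len(codes)
        # per-residue hydrophobic strength in (0, eps_max]
        h = {}
        for c in AA_ALPHABET:
            h[c] = eps_max * ((_KD[c] + 4.5) / 9.0 * 0.9 + 0.1)
        # backbone RNA beads are nearly purely repulsive; the base bead
        # carries modest stacking-like attraction
        h[PHOSPHATE_CODE] = 0.05
        h[SUGAR_CODE] = 0.05
        h[BASE_CODE] = 0.35
        eps = np.empty((n, n))
        sig = np.empty((n, n))
        for i, ci in enumerate(codes):
            for j, cj in enumerate(codes):
                eps[i, j] = np.sqrt(h[ci] * h[cj])
                sig[i, j] = 0.5 * (_SIGMA[ci] + _SIGMA[cj])
        # cation-pi-like boosts against the base bead: arginine binds
        # polyU much more strongly than lysine; aromatics intermediate
        for c, val in (("R", 1.2), ("K", 0.30), ("F", 0.7), ("Y", 0.7),
                       ("W", 0.8)):
            i, j = codes.index(c), codes.index(BASE_CODE)
            eps[i, j] = eps[j, i] = val
        return cls(codes, eps, sig,
                   np.full((n, n), float(mu)), np.full((n, n), float(nu)))

    def to_yaml(self, path) -> None:
        d = {
            "codes": self.codes,
            "eps": self.eps.tolist(),
            "sigma": self.sigma.tolist(),
            "mu": self.mu.tolist(),
            "nu": self.nu.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PairTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["codes"], np.array(d["eps"]), np.array(d["sigma"]),
                   np.array(d["mu"]), np.array(d["nu"]))

    @classmethod
    def bundled(cls) -> "PairTable":
        """The surrogate table shipped as editable package data."""
        from importlib.resources import files

        path = files("condensago").joinpath(
            "data/pair_table_surrogate.yaml")
        return cls.from_yaml(str(path))


# ---------------------------------------------------------------------------
# system configuration and assembly
# ---------------------------------------------------------------------------


@dataclass
class Electrostatics:
    debye_length: float = 0.8   # nm, ~150 mM monovalent salt
    dielectric: float = 80.0
    cutoff: float = 3.5         # nm


@dataclass
class SystemConfig:
    """Simulation composition and run conditions.

    Defaults mirror the reference study conditions: a 30 nm cubic
    periodic box with 120 peptides and four 100-nt polyU chains,
    10 fs timestep.
    """

    box_length: float = 30.0
    n_peptides: int = 120
    n_rna: int = 4
    rna_length: int = 100
    temperature: float = 300.0
    timestep_fs: float = 10.0
    friction: float = 1.0       # 1/ps
    seed: int = 0
    electrostatics: Electrostatics = field(default_factory=Electrostatics)
    wf_cutoff_factor: float = 3.0   # WF cutoff = factor * sigma_ij
    min_separation: float = 0.35    # nm, placement rejection criterion

    def validate(self) -> None:
        if self.n_peptides < 0 or self.n_rna < 0:
            raise ValueError("counts must be >= 0")
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be > 0")
        largest_cut = max(self.electrostatics.cutoff,
                          self.wf_cutoff_factor * max(_SIGMA.values()))
        if self.box_length <= 2 * largest_cut:
            raise ValueError(
                f"box_length {self.box_length} must exceed twice the "
                f"largest cutoff ({largest_cut:.2f} nm)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        d = dict(d)
        if "electrostatics" in d and isinstance(d["electrostatics"], dict):
            d["electrostatics"] = Electrostatics(**d["electrostatics"])
        return cls(**d)


class System:
    """A fully instantiated periodic simulation system.

    Flat per-bead arrays plus instantiated bonded terms, native-contact
    lists and nonbonded exclusions; built by :func:`assemble_system`.
    """

    def __init__(self, config: SystemConfig, pair_table: PairTable):
        self.config = config
        self.pair_table = pair_table
        self.n_beads = 0
        self.positions = np.zeros((0, 3))
        self.charge = np.zeros(0)
        self.mass = np.zeros(0)
        self.chain_id = np.zeros(0, dtype=np.int64)
        self.mol_kind = np.zeros(0, dtype=np.int64)
        self.type_index = np.zeros(0, dtype=np.int64)
        self.residue_codes: list[str] = []
        self.bonds = np.zeros((0, 2), dtype=np.int64)
        self.bond_params = np.zeros((0, 2))      # r0, k
        self.angles = np.zeros((0, 3), dtype=np.int64)
        self.angle_params = np.zeros((0, 2))     # theta0, k
        self.torsions = np.zeros((0, 4), dtype=np.int64)
        self.torsion_params = np.zeros((0, 3))   # k, mult, phase
        # native contacts: columns i, j; params r0, eps; class 0=intra 1=inter
        self.contacts = np.zeros((0, 2), dtype=np.int64)
        self.contact_params = np.zeros((0, 2))
        self.contact_class = np.zeros(0, dtype=np.int64)
        self.exclusion_keys = np.zeros(0, dtype=np.int64)  # sorted i*N+j
        self.wf_excluded_keys = np.zeros(0, dtype=np.int64)
        self.chain_slices: list[tuple[int, int]] = []
        self.chain_kinds: list[MoleculeKind] = []

    # -- helpers -----------------------------------------------------------
    @property
    def box_length(self) -> float:
        return self.config.box_length

    @property
    def n_chains(self) -> int:
        return len(self.chain_slices)

    @property
    def total_charge(self) -> float:
        return float(self.charge.sum())

    def pair_key(self, i, j) -> np.ndarray:
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        return lo * np.int64(self.n_beads) + hi

    def chain_atoms(self, chain: int) -> np.ndarray:
        a, b = self.chain_slices[chain]
        return np.arange(a, b)

    def peptide_chains(self) -> list[int]:
        return [c for c, k in enumerate(self.chain_kinds)
                if k is MoleculeKind.peptide]

    def rna_chains(self) -> list[int]:
        return [c for c, k in enumerate(self.chain_kinds)
                if k is MoleculeKind.rna]


def _extended_chain_coords(topology: Topology, rng) -> np.ndarray:
    """A loose self-avoiding conformation for initial placement: beads
    follow bond connectivity as a smooth random curl."""
    n = topology.n_beads
    coords = np.zeros((n, 3))
    neighbors = {}
    for i, j, r0, _k in topology.bonds:
        neighbors.setdefault(i, []).append((j, r0))
        neighbors.setdefault(j, []).append((i, r0))
    placed = {0}
    direction = _random_unit(rng)
    # BFS over the bond graph; direction drift with steric rejection
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for (nxt, r0) in neighbors.get(cur, []):
            if nxt in placed:
                continue
            done = [p for p in placed if p != cur]
            for attempt in range(60):
                trial = direction + (0.35 + 0.15 * attempt) * rng.normal(size=3)
                trial /= np.linalg.norm(trial)
                cand = coords[cur] + r0 * trial
                if not done:
                    direction = trial
                    break
                d = np.linalg.norm(coords[done] - cand, axis=1)
                if d.min() > 0.40:
                    direction = trial
                    break
            else:
                direction = trial
            coords[nxt] = coords[cur] + r0 * direction
            placed.add(nxt)
            queue.append(nxt)
    return coords - coords.mean(axis=0)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def assemble_system(
    config: SystemConfig,
    peptide_topology: Topology,
    rna_topology: Optional[Topology] = None,
    contacts=None,
    pair_table: Optional[PairTable] = None,
    peptide_template_coords: Optional[np.ndarray] = None,
    dimer_template_coords: Optional[np.ndarray] = None,
    placement: str = "random",
    droplet_radius: Optional[float] = None,
) -> System:
    """Replicate chain templates into a periodic box.

    ``contacts`` is a :class:`~condensago.contacts.NativeContactSet`
    defined on the one- or two-chain peptide template; intermolecular
    contacts are broadcast to every peptide chain pair.  ``placement``
    is ``"random"`` (seeded random insertion with a minimum-distance
    rejection criterion) or ``"dimer"`` (peptides inserted pairwise in
    the reference dimer geometry, which requires
    ``dimer_template_coords``).
    """
    config.validate()
    if config.n_rna > 0 and rna_topology is None:
        rna_topology = build_rna_topology(config.rna_length)
    pair_table = pair_table or PairTable.surrogate()
    rng = np.random.default_rng(config.seed)
    sys_ = System(config, pair_table)

    templates: list[tuple[Topology, np.ndarray]] = []
    pep_coords = (np.asarray(peptide_template_coords, dtype=float)
                  if peptide_template_coords is not None
                  else _extended_chain_coords(peptide_topology, rng))
    if pep_coords.shape != (peptide_topology.n_beads, 3):
        raise ValueError("peptide template coordinates shape mismatch")
    for _ in range(config.n_peptides):
        templates.append((peptide_topology, pep_coords))
    if config.n_rna > 0:
        rna_coords = _extended_chain_coords(rna_topology, rng)
        for _ in range(config.n_rna):
            templates.append((rna_topology, rna_coords))

    # ---- global bead arrays ------------------------------------------
    offsets = []
    total = 0
    for topo, _ in templates:
        offsets.append(total)
        total += topo.n_beads
    sys_.n_beads = total
    sys_.charge = np.empty(total)
    sys_.mass = np.empty(total)
    sys_.chain_id = np.empty(total, dtype=np.int64)
    sys_.mol_kind = np.empty(total, dtype=np.int64)
    sys_.type_index = np.empty(total, dtype=np.int64)
    bonds, bparams = [], []
    angles, aparams = [], []
    torsions, tparams = [], []
    excl = []
    for chain, (topo, _) in enumerate(templates):
        off = offsets[chain]
        sys_.chain_slices.append((off, off + topo.n_beads))
        sys_.chain_kinds.append(topo.beads[0].molecule_kind)
        for b in topo.beads:
            g = off + b.index
            sys_.charge[g] = b.charge
            sys_.mass[g] = b.mass
            sys_.chain_id[g] = chain
            sys_.mol_kind[g] = int(b.molecule_kind)
            sys_.type_index[g] = pair_table.index[b.residue_code]
            sys_.residue_codes.append(b.residue_code)
        for i, j, r0, k in topo.bonds:
            bonds.append((off + i, off + j))
            bparams.append((r0, k))
            excl.append((off + i, off + j))
        for i, j, k3, th0, ka in topo.angles:
            angles.append((off + i, off + j, off + k3))
            aparams.append((th0, ka))
            excl.append((off + i, off + k3))  # 1-3 exclusion
        for i, j, k3, l, kphi, mult, phase in topo.torsions:
            torsions.append((off + i, off + j, off + k3, off + l))
            tparams.append((kphi, mult, phase))
            excl.append((off + i, off + l))  # 1-4 exclusion
    sys_.bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    sys_.bond_params = np.array(bparams, dtype=float).reshape(-1, 2)
    sys_.angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    sys_.angle_params = np.array(aparams, dtype=float).reshape(-1, 2)
    sys_.torsions = np.array(torsions, dtype=np.int64).reshape(-1, 4)
    sys_.torsion_params = np.array(tparams, dtype=float).reshape(-1, 3)

    # ---- native contacts --------------------------------------------
    if contacts is not None and config.n_peptides > 0:
        from .contacts import instantiate_contacts
        ci, cj, r0, eps, cls_ = instantiate_contacts(
            contacts, config.n_peptides, offsets,
            peptide_topology.n_beads)
        sys_.contacts = np.column_stack([ci, cj]).astype(np.int64)
        sys_.contact_params = np.column_stack([r0, eps])
        sys_.contact_class = cls_.astype(np.int64)
        # native pairs are excluded from the generic WF attraction so
        # their well depth is set purely by epsilon_intra/inter
        sys_.wf_excluded_keys = np.unique(sys_.pair_key(ci, cj))

    keys = sys_.pair_key([p[0] for p in excl] or [],
                         [p[1] for p in excl] or [])
    sys_.exclusion_keys = np.unique(keys) if keys.size else keys

    # ---- placement ---------------------------------------------------
    sys_.positions = _place_chains(
        sys_, templates, offsets, rng, placement, dimer_template_coords,
        droplet_radius)
    return sys_


def _place_chains(sys_: System, templates, offsets, rng, placement,
                  dimer_template_coords,
                  droplet_radius: Optional[float] = None) -> np.ndarray:
    from scipy.spatial import cKDTree

    L = sys_.box_length
    min_sep = sys_.config.min_separation
    pos = np.zeros((sys_.n_beads, 3))
    placed_pts: list[np.ndarray] = []

    def try_insert(coords_local: np.ndarray) -> Optional[np.ndarray]:
        # candidates are kept unwrapped (contiguous chains); only the
        # overlap check uses wrapped images
        for _ in range(400):
            rot = _random_rotation(rng)
            if droplet_radius is not None:
                # uniform in a sphere at the box centre (pre-assembled
                # condensate for direct-coexistence runs)
                while True:
                    p = rng.uniform(-1, 1, size=3)
                    if p @ p <= 1.0:
                        break
                com = L / 2.0 + droplet_radius * p
            else:
                com = rng.uniform(0, L, size=3)
            cand = coords_local @ rot.T + com
            if placed_pts:
                tree = cKDTree(np.concatenate(placed_pts) % L, boxsize=L)
                if tree.query(cand % L, k=1)[0].min() < min_sep:
                    continue
            return cand
        return None

    chain = 0
    n_pep = sys_.config.n_peptides
    if placement == "dimer" and n_pep >= 2:
        if dimer_template_coords is None:
            raise ValueError("dimer placement requires dimer_template_coords")
        dimer = np.asarray(dimer_template_coords, dtype=float)
        nb = templates[0][0].n_beads
        if dimer.shape != (2 * nb, 3):
            raise ValueError("dimer template must cover two peptide chains")
        dimer = dimer - dimer.mean(axis=0)
        while chain + 1 < n_pep or (n_pep % 2 == 0 and chain < n_pep):
            if chain >= n_pep - (n_pep % 2):
                break
            cand = try_insert(dimer)
            if cand is None:
                raise RuntimeError(
                    "box too small to place chains without overlap")
            pos[offsets[chain]:offsets[chain] + nb] = cand[:nb]
            pos[offsets[chain + 1]:offsets[chain + 1] + nb] = cand[nb:]
            placed_pts.append(cand)
            chain += 2
    while chain < len(templates):
        topo, coords_local = templates[chain]
        cand = try_insert(coords_local - coords_local.mean(axis=0))
        if cand is None:
            raise RuntimeError("box too small to place chains without overlap")
        pos[offsets[chain]:offsets[chain] + topo.n_beads] = cand
        placed_pts.append(cand)
        chain += 1
    return pos
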