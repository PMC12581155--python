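"""Structure-based (Go-like) native contacts.

Contacts are extracted from a two-chain reference dimer with the
shadow criterion: a pair within the distance cutoff is kept only if no
third bead, modelled as a sphere of the shadow radius, occludes the
straight segment between the two.  The resulting map is split into
intramolecular contacts (which set the foldedness of a monomer,
scaled by ``eps_intra``) and intermolecular contacts (the dimer
interface, scaled by ``eps_inter``).  Intermolecular contacts are
broadcast to every pair of peptide chains in the assembled system, so
a monomer that loses its original partner can re-dimerize, fully or
partially, with any other monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class NativeContact:
    chain_i: int
    idx_i: int          # bead index within chain_i
    chain_j: int
    idx_j: int
    native_distance: float   # nm
    contact_class: str       # "intra" | "inter"
    epsilon: float = 1.0     # kJ/mol, after scaling

    def canonical(self) -> "NativeContact":
        if (self.chain_i, self.idx_i) <= (self.chain_j, self.idx_j):
            return self
        return NativeContact(self.chain_j, self.idx_j, self.chain_i,
                             self.idx_i, self.native_distance,
                             self.contact_class, self.epsilon)


@dataclass
class NativeContactSet:
    """Template contact map plus the two tunable well-depth scales.

    ``eps_intra`` and ``eps_inter`` are dimensionless multipliers of
    the base well depth ``eps0`` (kJ/mol).  The variant grid uses
    eps_intra in {1, 2.5, 4} and eps_inter in {0, 1, 2, 3, 4};
    eps_inter = 0 removes the interface term entirely (the monomeric
    limit).
    """

    contacts: list[NativeContact]
    eps_intra: float = 1.0
    eps_inter: float = 1.0
    eps0: float = 1.0
    source_structure: str = "unknown"

    def intra(self) -> list[NativeContact]:
        return [c for c in self.contacts if c.contact_class == "intra"]

    def inter(self) -> list[NativeContact]:
        return [c for c in self.contacts if c.contact_class == "inter"]

    def with_scales(self, eps_intra: float,
                    eps_inter: float) -> "NativeContactSet":
        return NativeContactSet(self.contacts, eps_intra, eps_inter,
                                self.eps0, self.source_structure)

    # template maps keyed by within-chain indices --------------------------
    def intra_template(self) -> list[tuple[int, int, float]]:
        """Unique (i, j, r0) intra contacts, merged over template chains."""
        seen = {}
        for c in self.intra():
            key = (min(c.idx_i, c.idx_j), max(c.idx_i, c.idx_j))
            seen.setdefault(key, c.native_distance)
        return [(i, j, r0) for (i, j), r0 in sorted(seen.items())]

    def inter_template(self) -> list[tuple[int, int, float]]:
        """(i, j, r0) inter contacts with i on the first template chain."""
        out = []
        for c in self.inter():
            if c.chain_i <= c.chain_j:
                out.append((c.idx_i, c.idx_j, c.native_distance))
            else:
                out.append((c.idx_j, c.idx_i, c.native_distance))
        return sorted(out)


@dataclass(frozen=True)
class VariantSpec:
    """One point of the foldedness/oligomerization design grid."""

    eps_intra: float
    eps_inter: float
    label: str = ""

    def __post_init__(self):
        if not self.label:
            object.__setattr__(
                self, "label",
                f"intra{self.eps_intra:g}_inter{self.eps_inter:g}")


# ---------------------------------------------------------------------------
# shadow contact extraction
# ---------------------------------------------------------------------------


def _segment_point_distance(a: np.ndarray, b: np.ndarray,
                            p: np.ndarray) -> tuple[float, float]:
    """Distance from p to segment ab and the projection parameter t."""
    ab = b - a
    denom = float(ab @ ab)
    t = float((p - a) @ ab) / denom
    tc = min(1.0, max(0.0, t))
    closest = a + tc * ab
    return float(np.linalg.norm(p - closest)), t


def shadow_contacts(
    coords: np.ndarray,
    chain_labels: Sequence[int],
    cutoff: float = 0.6,
    shadow_radius: float = 0.1,
    min_seq_sep: int = 4,
) -> list[NativeContact]:
    """Shadow-criterion contact map of a reference structure.

    A pair (i, j) — inter-chain, or same-chain with sequence
    separation >= ``min_seq_sep`` — is a contact iff its distance is
    <= ``cutoff`` and no third bead of radius ``shadow_radius``
    intersects the segment between them (the minimum distance from
    the occluding bead to the segment, projection clamped to the
    segment, is below the shadow radius).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(chain_labels)
    n = len(coords)
    if n < 2:
        raise ValueError("reference needs at least two beads")
    if not (cutoff > shadow_radius > 0):
        raise ValueError("require cutoff > shadow_radius > 0")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    if dist[iu].min() < 1e-9:
        raise ValueError("degenerate reference: coincident beads")

    # within-chain residue numbering for the sequence-separation rule
    within = np.zeros(n, dtype=int)
    for lab in np.unique(labels):
        mask = labels == lab
        within[mask] = np.arange(mask.sum())

    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j] and abs(within[i] - within[j]) < min_seq_sep:
                continue
            if dist[i, j] > cutoff:
                continue
            occluded = False
            for k in range(n):
                if k == i or k == j:
                    continue
                d, _t = _segment_point_distance(coords[i], coords[j],
                                                coords[k])
                if d < shadow_radius:
                    occluded = True
                    break
            if occluded:
                continue
            cls = "intra" if labels[i] == labels[j] else "inter"
            out.append(NativeContact(int(labels[i]), int(within[i]),
                                     int(labels[j]), int(within[j]),
                                     float(dist[i, j]), cls).canonical())
    return out


def split_contacts(
    contacts: Iterable[NativeContact],
    eps_intra: float = 1.0,
    eps_inter: float = 1.0,
    eps0: float = 1.0,
) -> tuple[list[NativeContact], list[NativeContact]]:
    """Partition into (intra, inter) and assign scaled well depths."""
    intra, inter = [], []
    for c in contacts:
        if c.contact_class == "intra":
            intra.append(NativeContact(c.chain_i, c.idx_i, c.chain_j,
                                       c.idx_j, c.native_distance, "intra",
                                       eps_intra * eps0))
        else:
            inter.append(NativeContact(c.chain_i, c.idx_i, c.chain_j,
                                       c.idx_j, c.native_distance, "inter",
                                       eps_inter * eps0))
    return intra, inter


def broadcast_inter_contacts(
    inter_template: Sequence[tuple[int, int, float]],
    n_chains: int,
) -> list[tuple[int, int, int, int, float]]:
    """Instantiate template interface contacts for every chain pair.

    Returns (chain_a, idx_i, chain_b, idx_j, r0) tuples; the count is
    exactly ``len(inter_template) * n_chains * (n_chains - 1) / 2``.
    """
    if n_chains < 2:
        return []
    out = []
    for a in range(n_chains):
        for b in range(a + 1, n_chains):
            for (i, j, r0) in inter_template:
                out.append((a, i, b, j, r0))
    return out


def instantiate_contacts(contact_set: NativeContactSet, n_peptides: int,
                         chain_offsets: Sequence[int], pep_n_beads: int):
    """System-wide contact arrays for :func:`assemble_system`.

    Intra contacts are replicated per peptide chain at
    ``eps_intra * eps0``; inter contacts are broadcast to all chain
    pairs at ``eps_inter * eps0``.  A zero inter scale drops the
    interface terms entirely.
    """
    ci, cj, r0s, eps, cls_ = [], [], [], [], []
    e_intra = contact_set.eps_intra * contact_set.eps0
    e_inter = contact_set.eps_inter * contact_set.eps0
    for chain in range(n_peptides):
        off = chain_offsets[chain]
        for (i, j, r0) in contact_set.intra_template():
            if i >= pep_n_beads or j >= pep_n_beads:
                raise ValueError("contact index outside peptide template")
            ci.append(off + i)
            cj.append(off + j)
            r0s.append(r0)
            eps.append(e_intra)
            cls_.append(0)
    if e_inter > 0:
        for (a, i, b, j, r0) in broadcast_inter_contacts(
                contact_set.inter_template(), n_peptides):
            ci.append(chain_offsets[a] + i)
            cj.append(chain_offsets[b] + j)
            r0s.append(r0)
            eps.append(e_inter)
            cls_.append(1)
    return (np.array(ci, dtype=np.int64), np.array(cj, dtype=np.int64),
            np.array(r0s, dtype=float), np.array(eps, dtype=float),
            np.array(cls_, dtype=np.int64))


# ---------------------------------------------------------------------------
# plain-text contact map I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = "chain_i\ti\tchain_j\tj\tr0_nm\tclass\tepsilon"


def write_contacts_tsv(path, contacts: Iterable[NativeContact]) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for c in contacts:
            fh.write(f"{c.chain_i}\t{c.idx_i}\t{c.chain_j}\t{c.idx_j}\t"
                     f"{c.native_distance:.6f}\t{c.contact_class}\t"
                     f"{c.epsilon:.6f}\n")


def read_contacts_tsv(path) -> list[NativeContact]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _TSV_HEADER:
            raise ValueError("unrecognized contact-map header")
        for line in fh:
            f = line.split("\t")
            out.append(NativeContact(int(f[0]), int(f[1]), int(f[2]),
                                     int(f[3]), float(f[4]), f[5],
                                     float(f[6])))
    return out
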