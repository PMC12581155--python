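# Methods

## The model

`condensago` implements a hybrid coarse-grained (CG) model of a short,
arginine-rich peptide ("PA"-like) phase-separating with polyU RNA.
Each peptide residue is one bead at the C-alpha position; each RNA
nucleotide is three beads (phosphate, sugar, base).  The energy
function combines:

* **Transferable terms.**  Hydrophobicity through the Wang–Frenkel
  (WF) pair potential with per-residue-pair parameters
  (epsilon, sigma, mu, nu), and electrostatics through the
  Debye–Hückel (DH) screened Coulomb potential.  Charges are +1e for
  R/K, −1e for D/E and the RNA phosphate.
* **Structure-based (Gō-like) terms.**  Native contacts extracted
  from a two-chain reference dimer with the shadow criterion and
  modelled with a 12–10 potential
  `V(r) = eps (5 (sigma/r)^12 − 6 (sigma/r)^10)`, whose minimum of
  depth −eps sits exactly at r = sigma; sigma is set to the native
  distance so the minimum reproduces the reference geometry.
  Intramolecular contacts are scaled by `eps_intra` (foldedness dial)
  and intermolecular contacts by `eps_inter` (dimerization dial), both
  dimensionless multipliers of the base well depth `eps0`
  (default 1 kJ/mol).  Intermolecular contacts are broadcast to every
  peptide pair, so dissociated monomers can re-dimerize with any
  partner.  The design grid crosses `eps_intra ∈ {1, 2.5, 4}` with
  `eps_inter ∈ {0, 1, 2, 3, 4}` — 15 variants from disordered
  monomers to folded dimers; `eps_inter = 0` is implemented as the
  term being absent.

Bonded terms are harmonic bonds and angles plus soft single-cosine
torsions on four successive C-alpha beads (amplitude 0.5 kJ/mol by
default, ≤ 1 kJ/mol in keeping with a "soft torsion" design).  When a
reference structure is supplied, bonded equilibria (bond lengths,
angles, torsion phases) are taken from the native trace — the
structure-based convention — so the native conformation is a true
minimum of the bonded + contact energy.

### Parameter choices and units

Units are kJ/mol, nm, ps, K, elementary charges; masses are a uniform
100 Da per bead (equilibrium averages are mass-independent; transport
coefficients scale trivially).  DH defaults: dielectric 80, Debye
length 0.8 nm (≈150 mM), cutoff 3.5 nm, energy-shifted to zero at the
cutoff.  WF cutoff is 3 sigma per pair and the form vanishes there by
construction.  Nonbonded interactions are excluded for bonded 1-2,
1-3 and 1-4 pairs, and the generic WF attraction is dropped on native
pairs (their well depth must be set by eps_intra/eps_inter alone);
DH is kept on native pairs.

The WF pair table bundled with the package is a **surrogate**: the
published transferable residue-level tables are not redistributed
here, so a synthetic table with the same structure is generated
(epsilon by a geometric-mean hydropathy rule scaled to ≤0.8 kJ/mol,
sigma by arithmetic mixing of residue diameters, mu = 2, nu = 1),
with explicit cation-pi-like boosts of the arginine- and
aromatic-to-base entries so that arginine binds polyU much more
strongly than lysine — the qualitative feature the R→K perturbation
probes.  Any table with the same YAML schema can be swapped in.

### Shadow contact maps

A pair (inter-chain, or same-chain with sequence separation ≥ 4) is a
contact iff its distance is ≤ 0.6 nm and no third bead of radius
0.1 nm occludes the straight segment between them (occlusion =
perpendicular distance to the segment below the shadow radius with
the projection strictly between the endpoints).  These are
conventional shadow-map settings for CG sites.  The reference
structure is a procedurally generated, C2-symmetric helix-hairpin-
helix (HhH) dimer with ideal helix geometry (rise 0.15 nm/residue,
100°/residue, C-alpha radius 0.23 nm); it is a synthetic stand-in
whose only job is geometric plausibility: a folded monomer core and a
≥10-pair dimer interface.

## Dynamics

Langevin dynamics with the BAOAB splitting (friction 1 ps⁻¹ by
default); friction = 0 reduces the scheme exactly to velocity Verlet,
used for NVE sanity checks.  Timestep 10 fs.  Forces come from a
periodic KD-tree Verlet list (skin 0.3 nm, rebuilt when any bead has
moved half a skin).  Energy minimization is displacement-capped
steepest descent (cap 0.02 nm/step) followed by L-BFGS, with a
monotonicity guard.  A protocol run is minimize → equilibrate →
production with snapshots and a per-frame energy decomposition whose
channels (peptide–peptide, peptide–RNA, RNA–RNA, intramolecular
nonbonded, bonded, intra-/inter-contact) sum exactly to the total.
The peptide–peptide and peptide–RNA channels contain only cross-chain
electrostatic + hydrophobic terms; native-contact and intramolecular
contributions are reported separately.  Replicas differ only by seed.

## Analysis definitions

* **Q_monomer / Q_dimer** — fraction of native intra/intermolecular
  contacts formed; a contact is formed when its distance is within
  1.2× the native distance.  Q_dimer takes, per peptide, the partner
  maximizing the formed-interface fraction (contacts are broadcast to
  all pairs), then averages.  Classification: ordered iff
  Q_monomer > 0.35, dimeric iff Q_dimer > 0.3 (a stricter 0.5
  criterion is supported).
* **Oligomeric partners** — per peptide pair, the summed 12–10
  interface energy; a pair interacts when that energy is at or below
  a negative cutoff (default: 25% of the full-interface well depth at
  the current eps_inter).  The mean partner count is the average
  graph degree over peptides and frames.
* **Condensate membership** — chains linked when any bead pair is
  within 1.0 nm; the condensate is the largest connected component
  (ties broken toward the lowest chain index).  Cluster coordinates
  are made contiguous by wrapping each chain rigidly and stitching
  chains with minimum-image shifts along a BFS of the contact graph.
* **Density** — member mass over the convex-hull volume inflated by
  half the mean nearest-neighbor spacing of member beads (a
  parameter-free first-order correction for the hull's finite-
  sampling bias; on planted uniform droplets it recovers the true
  density to well under 5%, where a hull alone errs by ~10%).
* **Diffusion** — time-and-ensemble-averaged MSD of unwrapped chain
  centres of mass (FFT algorithm).  The exponent alpha is the log-log
  slope over the fit window; D comes from MSD = 2 d D t and is
  flagged as normal diffusion only for alpha in [0.9, 1.1].  For
  intra-condensate comparisons the diffusive (late-lag) window should
  be used, since short lags mix in intra-dimer rattling.
* **Nematic order** — S is the largest eigenvalue of
  Q = (1/2N) Σ (3 e eᵀ − I) over chain orientation unit vectors e,
  taken as the principal gyration-tensor axis (sign-irrelevant).
* **Phase behavior** — per temperature, the dense density from the
  condensate hull and the dilute density from everything else over
  the remaining volume; coexistence requires the largest cluster to
  hold ≥50% of peptides in ≥80% of frames.  The critical temperature
  comes from a simultaneous least-squares fit of
  (ρ_dense − ρ_dilute) = A (1 − T/Tc)^β (β fixed at 0.325, the 3D
  Ising value, config-exposed) and the law of rectilinear diameters.
  Relative stability changes are 100 (Tc_a − Tc_b)/Tc_b.

Replicate statistics are reported as the mean of replicate averages
with the standard deviation of those averages as the error.

## Synthetic fixtures and what they do (and do not) show

Every test input is generated procedurally: the HhH dimer surrogate,
rod frames with axes drawn from a cone (nematic ground truth),
Brownian walks (known D) and fractional Brownian motion via
circulant-embedding fGn (known alpha = 2H), synthetic binodals from
the scaling law (known Tc), and planted two-phase droplet frames
(known densities).  Passing these recovery tests shows the
*estimators* are correct and unbiased at the planted conditions; it
does not validate the surrogate pair table against any real peptide,
nor the quantitative condensate properties of the published
parametrization, which would require the original force-field tables
and reference structure.

## Problem sizes

The `full` preset mirrors the reference study conditions (30 nm box,
120 peptides, four 100-nt polyU chains, microsecond production, three
replicas) and is intended for cluster hardware.  The `desk` preset
(16 peptides, one 50-nt RNA, 15 nm box, ~10 ns) is a workstation
reduction.  The test-suite and the acceptance script use the `tiny`
preset — 10 peptides of 18 residues, one 20-nt polyU, 11 nm box,
30 ps equilibration + 150 ps production — chosen as the smallest
system in which the grid's qualitative regimes (disordered vs folded,
monomeric vs dimeric, condensed vs dispersed) remain distinguishable.
At this scale runs start from a pre-assembled droplet (chains placed
inside a sphere of 0.27 box lengths), the direct-coexistence
convention, because spontaneous nucleation is not reachable in
picoseconds; analyses then measure whether the condensate persists,
its internal order, and its exchange with the dilute phase.  The
reduced analysis temperature is 150 K (roughly 0.9 of the tiny
systems' apparent critical temperature); absolute temperatures are
not comparable to experiment because the surrogate table sets its own
energy scale.

## Known limitations

* The pair table and reference dimer are synthetic surrogates; all
  quantitative outputs calibrate to their energy scale.
* Hydrodynamics are absent (free-draining Langevin), so absolute
  diffusion coefficients scale as 1/N per chain.
* Tiny-preset trends are kinetic (droplet persistence over ~100 ps),
  not fully equilibrated coexistence measurements.
* The helicity proxy is a native-contact fraction over a designated
  helix subset, not a secondary-structure assignment.
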