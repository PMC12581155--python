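"""Campaign drivers: the 15-variant grid, temperature scans and the
RNA-removal / R-to-K perturbation experiments.

The design grid crosses eps_intra in {1, 2.5, 4} with eps_inter in
{0, 1, 2, 3, 4}: fifteen variants spanning the continuum from fully
disordered monomers (1, 0) to fully folded dimers (4, 4).  Reported
statistics follow a two-level scheme: the mean of replicate averages,
with the standard deviation of those averages as the error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .analysis import (BinodalFit, CondensateMetrics, PhasePoint,
                       coexistence_densities, compute_metrics, fit_tc,
                       relative_stability)
from .contacts import NativeContactSet, VariantSpec, shadow_contacts
from .dynamics import Schedule, Trajectory, run_protocol
from .fixtures import make_hhh_dimer_reference
from .model_setup import (PairTable, SystemConfig, build_peptide_topology,
                          build_rna_topology, mutate_r_to_k,
                          surrogate_pa_sequence, assemble_system)

EPS_INTRA_LEVELS = (1.0, 2.5, 4.0)
EPS_INTER_LEVELS = (0.0, 1.0, 2.0, 3.0, 4.0)


def variant_grid() -> list[VariantSpec]:
    """The full 3 x 5 design grid (15 variants)."""
    return [VariantSpec(a, b)
            for a in EPS_INTRA_LEVELS for b in EPS_INTER_LEVELS]


#: default representatives, one per group: the grid corners
REPRESENTATIVES = {
    "mono_dis": VariantSpec(1.0, 0.0),
    "mono_ord": VariantSpec(4.0, 0.0),
    "dimer_dis": VariantSpec(1.0, 4.0),
    "dimer_ord": VariantSpec(4.0, 4.0),
}


@dataclass
class ScalePreset:
    """Problem size + schedule bundle.

    ``full`` mirrors the reference study conditions (120 peptides,
    four 100-nt polyU chains, 30 nm box, microsecond production in
    three replicas).  ``desk`` is a workstation-scale reduction and
    ``tiny`` a seconds-scale preset used by the test-suite drivers.
    """

    name: str
    n_peptides: int
    n_rna: int
    rna_length: int
    box_length: float
    peptide_length: int
    equilibration_steps: int
    production_steps: int
    snapshot_interval: int
    n_replicas: int
    eps0: float = 1.0           # base contact well depth, kJ/mol
    timestep_fs: float = 10.0


PRESETS = {
    "full": ScalePreset("full", 120, 4, 100, 30.0, 26,
                        2_000_000, 100_000_000, 50_000, 3),
    "desk": ScalePreset("desk", 16, 1, 50, 15.0, 26,
                        200_000, 1_000_000, 5_000, 3),
    "tiny": ScalePreset("tiny", 10, 1, 20, 11.0, 18,
                        3_000, 15_000, 300, 1),
}

#: analysis temperature for the reduced presets, chosen once so the
#: design grid spans disordered-to-folded and monomeric-to-dimeric
#: regimes inside a persistent condensate (roughly 0.9 of the reduced
#: systems' apparent critical temperature)
STUDY_TEMPERATURE = 150.0


def build_variant_system(
    variant: VariantSpec,
    preset: ScalePreset,
    temperature: float,
    seed: int = 0,
    with_rna: bool = True,
    r_to_k: bool = False,
    sequence: Optional[str] = None,
    placement: str = "dimer",
    pair_table: Optional[PairTable] = None,
    droplet: bool = True,
):
    """Assemble one simulation system for a grid variant.

    The native-contact template comes from the surrogate HhH dimer
    reference; peptides start in the native chain conformation, placed
    pairwise in the reference dimer geometry (``placement='dimer'``)
    or individually (``'random'``).  Returns (system, contact_set).
    """
    n_res = preset.peptide_length
    ref_coords, ref_labels = make_hhh_dimer_reference(n_res)
    raw = shadow_contacts(ref_coords, ref_labels)
    contact_set = NativeContactSet(
        raw, eps_intra=variant.eps_intra, eps_inter=variant.eps_inter,
        eps0=preset.eps0, source_structure=f"surrogate_hhh_{n_res}")
    seq = sequence or surrogate_pa_sequence(n_res)
    if len(seq) != n_res:
        raise ValueError("sequence length must match the preset")
    if r_to_k:
        seq = mutate_r_to_k(seq)
    pep_topo = build_peptide_topology(seq,
                                      reference_coords=ref_coords[:n_res])
    n_rna = preset.n_rna if with_rna else 0
    rna_topo = build_rna_topology(preset.rna_length) if n_rna else None
    config = SystemConfig(
        box_length=preset.box_length,
        n_peptides=preset.n_peptides,
        n_rna=n_rna,
        rna_length=preset.rna_length,
        temperature=temperature,
        timestep_fs=preset.timestep_fs,
        seed=seed,
    )
    if placement == "dimer" and variant.eps_inter == 0:
        placement = "random"      # monomeric limit starts dissociated
    system = assemble_system(
        config, pep_topo, rna_topo, contacts=contact_set,
        pair_table=pair_table,
        peptide_template_coords=ref_coords[:n_res],
        dimer_template_coords=ref_coords if placement == "dimer" else None,
        placement=placement,
        # condensed-start (direct coexistence): chains begin inside a
        # droplet occupying ~2% of the box volume
        droplet_radius=0.27 * preset.box_length if droplet else None,
    )
    return system, contact_set


def make_schedule(preset: ScalePreset, temperature: float,
                  n_replicas: Optional[int] = None) -> Schedule:
    return Schedule(
        minimize=True,
        equilibration_steps=preset.equilibration_steps,
        production_steps=preset.production_steps,
        timestep_fs=preset.timestep_fs,
        snapshot_interval=preset.snapshot_interval,
        temperature=temperature,
        n_replicas=n_replicas or preset.n_replicas,
    )


# ---------------------------------------------------------------------------
# per-variant metric campaigns
# ---------------------------------------------------------------------------


@dataclass
class CampaignResult:
    variant: VariantSpec
    replicate_metrics: list[CondensateMetrics]
    binodal: Optional[BinodalFit] = None
    deltas: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean of replicate averages and the SD of those averages."""
        rows = [m.as_dict() for m in self.replicate_metrics]
        df = pd.DataFrame(rows).drop(columns=["group"], errors="ignore")
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def run_variant(variant: VariantSpec, preset: ScalePreset,
                temperature: float, seed: int = 0,
                with_rna: bool = True, r_to_k: bool = False,
                n_replicas: Optional[int] = None) -> CampaignResult:
    """Replicated production runs plus full metric extraction."""
    system, cset = build_variant_system(
        variant, preset, temperature, seed=seed, with_rna=with_rna,
        r_to_k=r_to_k)
    schedule = make_schedule(preset, temperature, n_replicas)
    trajs = run_protocol(system, schedule, base_seed=seed)
    metrics = [compute_metrics(t, system, contact_set=cset)
               for t in trajs]
    return CampaignResult(variant, metrics)


# ---------------------------------------------------------------------------
# temperature scans and perturbations
# ---------------------------------------------------------------------------


def temperature_scan(variant: VariantSpec, temperatures: Sequence[float],
                     preset: ScalePreset, seed: int = 0,
                     with_rna: bool = True, r_to_k: bool = False,
                     n_replicas: Optional[int] = None,
                     ) -> tuple[BinodalFit, list[PhasePoint]]:
    """Phase points over a temperature list and the fitted binodal.

    Each temperature is simulated with replicas differing only by
    seed; replicate phase points are averaged before fitting (mean of
    replicate averages).  Raises if fewer than three temperatures
    show coexistence.
    """
    if len(temperatures) < 3:
        raise ValueError("need at least 3 temperatures")
    points = []
    for it, T in enumerate(sorted(temperatures)):
        system, _ = build_variant_system(
            variant, preset, T, seed=seed + 1000 * it,
            with_rna=with_rna, r_to_k=r_to_k)
        schedule = make_schedule(preset, T, n_replicas)
        trajs = run_protocol(system, schedule, base_seed=seed + 1000 * it)
        reps = [coexistence_densities(t, system) for t in trajs]
        co = [p for p in reps if p.coexists]
        if len(co) * 2 > len(reps):
            points.append(PhasePoint(
                T, float(np.mean([p.rho_dense for p in co])),
                float(np.mean([p.rho_dilute for p in co])), True))
        else:
            points.append(PhasePoint(
                T, float(np.mean([p.rho_dense for p in reps])),
                float(np.mean([p.rho_dilute for p in reps])), False))
    n_co = sum(p.coexists for p in points)
    if n_co < 3:
        raise RuntimeError(
            f"no binodal: only {n_co} of {len(points)} temperatures show "
            "coexistence; extend the temperature range downward")
    return fit_tc(points), points


def run_perturbations(representatives: Optional[dict] = None,
                      preset: Optional[ScalePreset] = None,
                      temperatures: Optional[Sequence[float]] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Baseline vs RNA-removal vs R-to-K for one variant per group.

    Returns a tidy frame with one row per (group, condition) holding
    Tc and the mean peptide-peptide energy, plus percent deltas of
    both quantities relative to baseline.
    """
    reps = representatives or REPRESENTATIVES
    preset = preset or PRESETS["desk"]
    if temperatures is None:
        raise ValueError("temperature list required")
    rows = []
    for group, variant in reps.items():
        base_fit = None
        for cond, kw in (("baseline", {}),
                         ("no_rna", {"with_rna": False}),
                         ("r_to_k", {"r_to_k": True})):
            fit, points = temperature_scan(variant, temperatures, preset,
                                           seed=seed, **kw)
            system, cset = build_variant_system(
                variant, preset, temperatures[0], seed=seed, **kw)
            schedule = make_schedule(preset, temperatures[0])
            trajs = run_protocol(system, schedule, base_seed=seed)
            vpp = float(np.mean([analysis.energy_means(t)[0]
                                 for t in trajs]))
            row = {"group": group, "condition": cond,
                   "Tc": fit.Tc, "V_pep_pep": vpp}
            if cond == "baseline":
                base_fit = row
            else:
                row["delta_Tc_pct"] = relative_stability(
                    fit.Tc, base_fit["Tc"])
                row["delta_Vpp_pct"] = 100.0 * (
                    (vpp - base_fit["V_pep_pep"])
                    / abs(base_fit["V_pep_pep"]))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reduced-scale trend observables
# ---------------------------------------------------------------------------


def trend_observables(variant: VariantSpec, preset: ScalePreset,
                      temperature: float, seed: int,
                      with_rna: bool = True) -> dict:
    """One production run and the observables the grid trends compare.

    Returns Q parameters, mean partners, nematic order S averaged over
    frames, the late-lag diffusion coefficient of peptide centres of
    mass (the diffusive window, clear of intra-dimer rattling), and
    the mean fraction of peptides in the largest cluster (the
    coexistence-propensity proxy for condensed starts).
    """
    system, cset = build_variant_system(variant, preset, temperature,
                                        seed=seed, with_rna=with_rna)
    schedule = make_schedule(preset, temperature, n_replicas=1)
    traj = run_protocol(system, schedule, base_seed=seed)[0]
    pep = system.peptide_chains()
    pep_set = set(pep)
    out = {
        "Q_monomer": float(np.mean(
            [analysis.q_monomer(p, system) for p in traj.positions])),
        "Q_dimer": float(np.mean(
            [analysis.q_dimer(p, system) for p in traj.positions])),
        "S": float(np.mean(
            [analysis.nematic_order_frame(p, system, pep)
             for p in traj.positions])),
        "cluster_fraction": float(np.mean(
            [len(pep_set & set(analysis.condensate_members(p, system)))
             / len(pep) for p in traj.positions])),
    }
    if variant.eps_inter > 0:
        cutoff = analysis.default_partner_cutoff(cset)
        out["mean_partners"] = analysis.oligomer_partners(
            traj.positions, system, cutoff)
    else:
        out["mean_partners"] = 0.0
    com = analysis.chain_com_series(traj, system, pep)
    span = traj.times[-1] - traj.times[0]
    fit = analysis.msd_and_fit(traj.times, com,
                               fit_window=(0.2 * span, 0.5 * span))
    out["D"] = fit.D
    full = analysis.msd_and_fit(traj.times, com)
    out["alpha"] = full.alpha
    out["V_pep_pep"], out["V_pep_rna"] = analysis.energy_means(traj)
    return out


# ---------------------------------------------------------------------------
# correlation reporting
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlation_report(table: pd.DataFrame, x: str, y: str,
                       group: Optional[str] = None,
                       exclude: Optional[Sequence] = None,
                       ) -> "CorrelationReport | dict[str, CorrelationReport]":
    """Ordinary least squares of y on x with R^2.

    ``group`` stratifies by a column (e.g. monomers vs dimers);
    ``exclude`` drops labelled rows by index before fitting.
    """
    from scipy.stats import linregress

    df = table.drop(index=list(exclude)) if exclude is not None else table

    def _fit(sub: pd.DataFrame) -> CorrelationReport:
        xs = sub[x].to_numpy(dtype=float)
        ys = sub[y].to_numpy(dtype=float)
        if len(xs) < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(xs) == 0:
            raise ValueError("x has zero variance")
        if np.ptp(ys) == 0:
            return CorrelationReport(0.0, float(ys[0]), 0.0, len(xs))
        res = linregress(xs, ys)
        return CorrelationReport(float(res.slope), float(res.intercept),
                                 float(res.rvalue ** 2), len(xs))

    if group is None:
        return _fit(df)
    return {str(g): _fit(sub) for g, sub in df.groupby(group)}
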