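"""High-level compositions of the analysis stages.

These are the recipes a user would otherwise script by hand: filter →
detect rips → segment → bin → subtract → fit for pulling data, and
density → mixture fit → occupancy ladder → equilibrium force for clamp
data.  The CLI and the worked examples call these.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .clamp import (
    ClampTrace,
    equilibrium_force,
    extension_density,
    fit_two_gaussians,
    gating_energy,
)
from .fec import (
    BinnedFEC,
    ForceExtensionTrace,
    StiffnessFit,
    bin_by_force,
    boxcar_filter,
    detect_transitions,
    differential_structured_extension,
    fit_stiffness_linear,
    pool_molecules,
    segment_at_events,
)
from .io import RunConfig
from .mechanics import Constants, RigidOffset

__all__ = [
    "folded_branch_fec",
    "differential_stiffness",
    "clamp_ladder_analysis",
]


def _constants(cfg: RunConfig) -> Constants:
    return Constants(kBT=cfg.kBT, aa_rise=cfg.aa_rise, bp_rise=cfg.bp_rise)


def folded_branch_fec(
    trace: ForceExtensionTrace, cfg: RunConfig = RunConfig()
) -> tuple:
    """Filter a pulling trace, cut it at the first rip, bin the folded branch.

    Returns (binned folded branch, detected events, filtered trace).
    """
    filt = boxcar_filter(trace, cfg.boxcar_window_s)
    events = detect_transitions(filt, cfg.rip_threshold_nm, cfg.rip_max_dwell_s)
    if events:
        branch = segment_at_events(filt, events[:1])[0]
    else:
        branch = filt
    fec = bin_by_force(branch, cfg.bin_width_pN, tuple(cfg.force_range_pN))
    return fec, events, filt


def differential_stiffness(
    dna_traces: Sequence[ForceExtensionTrace],
    protein_traces: Sequence[ForceExtensionTrace],
    cfg: RunConfig = RunConfig(),
    n_disordered: float | None = None,
    nanodisc: float | None = None,
) -> dict:
    """Full differential pipeline: structured-protein extension and stiffness.

    Boxcar-filters and bins all traces, pools molecules, subtracts the
    DNA-only extension, the disordered-tail worm-like chain and the rigid
    nanodisc, and fits the folded-branch line F = k (x - x0).
    """
    c = _constants(cfg)
    n_dis = cfg.n_disordered if n_disordered is None else n_disordered
    disc = cfg.nanodisc_nm if nanodisc is None else nanodisc
    dna_fecs = []
    for tr in dna_traces:
        filt = boxcar_filter(tr, cfg.boxcar_window_s)
        dna_fecs.append(bin_by_force(filt, cfg.bin_width_pN, tuple(cfg.force_range_pN)))
    dna_pooled = pool_molecules(dna_fecs)
    protein_fecs = []
    all_events = []
    for tr in protein_traces:
        fec, events, _ = folded_branch_fec(tr, cfg)
        protein_fecs.append(fec)
        all_events.append(events)
    protein_pooled = pool_molecules(protein_fecs)
    structured = differential_structured_extension(
        protein_pooled, dna_pooled, n_dis, RigidOffset(disc), cfg.chain_P_nm, c
    )
    fit = fit_stiffness_linear(structured, tuple(cfg.stiffness_fit_range_pN))
    return {
        "stiffness": fit,
        "structured_fec": structured,
        "protein_fec": protein_pooled,
        "dna_fec": dna_pooled,
        "events": all_events,
    }


def clamp_ladder_analysis(
    traces: Sequence[ClampTrace],
    bin_width: float = 0.4,
    c: Constants = Constants(),
) -> dict:
    """Two-Gaussian occupancy per clamp and equilibrium force of the ladder.

    Each trace's extension density is fit with a two-Gaussian mixture; the
    high-extension weight is the open-state occupancy; the equilibrium
    force is the zero crossing of the occupancy log-odds versus force.
    The gating swing is taken from the clamp nearest equilibrium.
    """
    points = []
    fits = []
    for tr in traces:
        density = extension_density(tr, bin_width)
        fit = fit_two_gaussians(density)
        fits.append(fit)
        points.append((tr.mean_force, fit.weight_high))
    F_eq = equilibrium_force(points)
    nearest = int(np.argmin([abs(F - F_eq) for F, _ in points]))
    swing = fits[nearest].separation
    return {
        "F_eq": F_eq,
        "delta_x": swing,
        "occupancies": points,
        "fits": fits,
        "gating": gating_energy(F_eq, swing, c),
    }
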