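"""Synthetic dual-trap data generator with ground-truth records.

Emulates the statistical structure the analysis assumes: a protein–DNA
tether (4.5-kbp worm-like-chain DNA handles in series with an elastic-rod
protein core, unfolded-polypeptide worm-like chains and a rigid nanodisc)
pulled quasi-statically at 10 nm/s between two traps, with Gaussian
measurement noise, programmed or Bell-rate unfolding rips, and a two-state
Boltzmann gating flicker under force clamp.  Every generated trace comes
with a truth record so recovery tests can compare against the generating
parameters.  All randomness flows from a single seed through spawned
generator streams, so identical seeds give identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .clamp import ClampTrace
from .fec import ForceExtensionTrace
from .mechanics import (
    Constants,
    ElasticRod,
    RigidOffset,
    TetherModel,
    WormLikeChain,
    tether_extension,
)

__all__ = [
    "PullProtocol",
    "RipPlan",
    "SimTruth",
    "simulate_pull",
    "simulate_dna_only",
    "simulate_clamp",
    "fixture_suite",
]


@dataclass(frozen=True)
class PullProtocol:
    """Trap-motion protocol: one trap moves at constant speed, the other is fixed."""

    speed: float = 10.0  # nm/s
    trap_stiffness: float = 0.3  # pN/nm per trap
    sampling_rate: float = 1000.0  # Hz raw acquisition
    force_range: tuple = (0.5, 20.0)  # pN, start and stop force of the ramp
    phase: str = "pull"  # pull | relax

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.trap_stiffness <= 0 or self.sampling_rate <= 0:
            raise ValueError("speed, trap_stiffness, sampling_rate must be > 0")
        if self.force_range[1] <= self.force_range[0]:
            raise ValueError("force_range must be increasing")


@dataclass(frozen=True)
class RipPlan:
    """One unfolding/extension event in the simulation plan.

    Either a fixed ``trigger_force`` or Bell-rate kinetics (``k0`` at zero
    force, barrier distance ``x_dagger``) fires the event; it releases
    ``delta_residues`` of polypeptide into the unfolded chain and shifts
    the rod intrinsic length by ``delta_x0`` (negative models an
    insertion-type extension drop).
    """

    delta_residues: float = 0.0
    delta_x0: float = 0.0
    trigger_force: float | None = None
    k0: float | None = None
    x_dagger: float | None = None

    def __post_init__(self) -> None:
        stochastic = self.k0 is not None and self.x_dagger is not None
        if (self.trigger_force is None) == (not stochastic):
            raise ValueError("specify either trigger_force or (k0, x_dagger)")


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of one tether, serialized alongside every trace."""

    dna_bp: float = 4520.0
    dna_P: float = 40.0
    rod: ElasticRod | None = ElasticRod(20.0, 0.7)
    n_disordered: float = 123.0
    chain_P: float = 0.6
    nanodisc: float = 5.0
    rips: tuple = ()
    noise_ext: float = 2.0  # nm per raw sample
    noise_F: float = 0.2  # pN per raw sample
    seed: int = 0

    def max_residues(self, residues_per_AR: int = 33, n_AR: int = 29) -> float:
        return n_AR * residues_per_AR

    def tether(self, state: int = 0, c: Constants = Constants()) -> TetherModel:
        """Series tether after the first ``state`` planned events have fired."""
        residues = self.n_disordered
        x0_shift = 0.0
        for rip in self.rips[:state]:
            residues += rip.delta_residues
            x0_shift += rip.delta_x0
        elements = [WormLikeChain.from_basepairs(self.dna_bp, self.dna_P, c)]
        if self.rod is not None:
            elements.append(
                ElasticRod(max(self.rod.intrinsic_length + x0_shift, 0.0),
                           self.rod.stiffness)
            )
        if residues > 0:
            elements.append(WormLikeChain.from_residues(residues, self.chain_P, c))
        if self.nanodisc > 0:
            elements.append(RigidOffset(self.nanodisc))
        return TetherModel(tuple(elements))

    def truth_record(self) -> dict:
        rec = {
            "dna_bp": self.dna_bp,
            "dna_P": self.dna_P,
            "rod_x0": None if self.rod is None else self.rod.intrinsic_length,
            "rod_k": None if self.rod is None else self.rod.stiffness,
            "n_disordered": self.n_disordered,
            "chain_P": self.chain_P,
            "nanodisc": self.nanodisc,
            "noise_ext": self.noise_ext,
            "noise_F": self.noise_F,
            "seed": self.seed,
            "rips": [
                {
                    "delta_residues": r.delta_residues,
                    "delta_x0": r.delta_x0,
                    "trigger_force": r.trigger_force,
                    "k0": r.k0,
                    "x_dagger": r.x_dagger,
                }
                for r in self.rips
            ],
        }
        return rec


# ---------------------------------------------------------------------------


def _force_table(tether: TetherModel, c: Constants, f_max: float) -> tuple:
    """Monotone (force, extension) lookup for fast separation -> force maps."""
    grid = np.concatenate(([0.0], np.geomspace(1e-4, max(f_max * 1.3, 1.0), 1200)))
    ext = np.array([tether_extension(F, tether, c) for F in grid])
    return grid, ext


def simulate_pull(
    truth: SimTruth,
    protocol: PullProtocol = PullProtocol(),
    c: Constants = Constants(),
    rng: np.random.Generator | None = None,
    label: str = "pull",
) -> tuple:
    """Quasi-static pulling (or relaxation) trace plus its truth sidecar.

    At each trap separation the tension balances the tether in series with
    the two trap springs; planned rips switch the tether state when their
    fixed force is reached or their Bell-rate hazard fires, and i.i.d.
    Gaussian noise is added to the recorded force and extension.
    """
    total_residues = truth.n_disordered + sum(r.delta_residues for r in truth.rips)
    if truth.rips and total_residues - truth.n_disordered > truth.max_residues():
        raise ValueError("rip plan releases more residues than the ARD contains")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_states = len(truth.rips) + 1
    f_lo, f_hi = protocol.force_range
    tables = [_force_table(truth.tether(s, c), c, f_hi) for s in range(n_states)]
    trap_compliance = 2.0 / protocol.trap_stiffness

    def sep_of_force(state: int, F) -> np.ndarray:
        Fg, ext = tables[state]
        return np.interp(F, Fg, ext) + np.asarray(F) * trap_compliance

    def force_of_sep(state: int, S) -> np.ndarray:
        Fg, ext = tables[state]
        return np.interp(S, ext + Fg * trap_compliance, Fg)

    pull = protocol.phase == "pull"
    start_state = 0 if pull else n_states - 1
    S_start = float(sep_of_force(start_state, f_lo if pull else f_hi))
    S_stop = float(sep_of_force(n_states - 1 if pull else 0, f_hi if pull else f_lo))
    direction = 1.0 if S_stop >= S_start else -1.0
    n_samples = int(abs(S_stop - S_start) / protocol.speed * protocol.sampling_rate) + 1
    t = np.arange(n_samples) / protocol.sampling_rate
    S = S_start + direction * protocol.speed * t

    state = start_state
    F = np.empty(n_samples)
    events = []
    i = 0
    dt = 1.0 / protocol.sampling_rate
    while i < n_samples:
        F_seg = force_of_sep(state, S[i:])
        fire_at = None
        if pull and state < n_states - 1:
            rip = truth.rips[state]
            if rip.trigger_force is not None:
                hits = np.nonzero(F_seg >= rip.trigger_force)[0]
                if hits.size:
                    fire_at = int(hits[0])
            else:
                hazard = rip.k0 * np.exp(F_seg * rip.x_dagger / c.kBT) * dt
                cum = np.cumsum(hazard)
                draw = rng.exponential()
                hits = np.nonzero(cum >= draw)[0]
                if hits.size:
                    fire_at = int(hits[0])
        if fire_at is None:
            F[i:] = F_seg
            break
        F[i : i + fire_at + 1] = F_seg[: fire_at + 1]
        i += fire_at + 1
        state += 1
        if i < n_samples:
            events.append(
                {
                    "time_s": float(t[i]),
                    "force_pN": float(F_seg[fire_at]),
                    "state": state,
                    "delta_residues": truth.rips[state - 1].delta_residues,
                    "delta_x0": truth.rips[state - 1].delta_x0,
                }
            )
    X = S - F * trap_compliance  # true tether extension
    F_meas = F + rng.normal(0.0, truth.noise_F, n_samples)
    X_meas = X + rng.normal(0.0, truth.noise_ext, n_samples)
    trace = ForceExtensionTrace(
        t, F_meas, X_meas, trap_sep=S, label=label, phase=protocol.phase,
        sampling_rate=protocol.sampling_rate,
    )
    sidecar = {
        "truth": truth.truth_record(),
        "protocol": {
            "speed": protocol.speed,
            "trap_stiffness": protocol.trap_stiffness,
            "sampling_rate": protocol.sampling_rate,
            "force_range": list(protocol.force_range),
            "phase": protocol.phase,
        },
        "events": events,
        "final_state": state,
    }
    return trace, sidecar


def simulate_dna_only(
    truth: SimTruth | None = None,
    protocol: PullProtocol = PullProtocol(),
    c: Constants = Constants(),
    rng: np.random.Generator | None = None,
    label: str = "dna",
) -> tuple:
    """DNA-handles-only pull: the same generator with a bare-handle tether."""
    if truth is None:
        truth = SimTruth()
    bare = replace(truth, rod=None, n_disordered=0.0, nanodisc=0.0, rips=())
    return simulate_pull(bare, protocol, c, rng=rng, label=label)


def simulate_clamp(
    delta_x: float = 4.7,
    F_eq: float = 6.9,
    clamp_force: float = 6.9,
    duration: float = 60.0,
    noise_sd: float = 1.5,
    k0: float = 1.0,
    sampling_rate: float = 200.0,
    baseline: float = 0.0,
    seed: int = 0,
    c: Constants = Constants(),
    rng: np.random.Generator | None = None,
) -> tuple:
    """Two-state gating flicker at a constant mean force.

    A continuous-time Markov chain with rates
    k_open = k0 exp(+(F - F_eq) dx / 2 kBT), k_close = k0 exp(-...),
    whose stationary high-state occupancy follows the Boltzmann relation
    P = 1/(1 + exp((F_eq - F) dx / kBT)); dwells are sampled exactly and
    the recorded extension adds Gaussian noise.  The symmetric rate scale
    k0 gives roughly 2 k0 * duration transitions at equilibrium.
    """
    if delta_x <= 0 or duration <= 0 or sampling_rate <= 0:
        raise ValueError("delta_x, duration, sampling_rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    bias = (clamp_force - F_eq) * delta_x / (2.0 * c.kBT)
    k_open = k0 * math.exp(bias)
    k_close = k0 * math.exp(-bias)
    # start from the stationary distribution
    p_high = k_open / (k_open + k_close)
    state = 1 if rng.random() < p_high else 0
    t = 0.0
    switch_times = []
    states = [state]
    n_transitions = 0
    while t < duration:
        rate = k_close if state else k_open
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        switch_times.append(t)
        state = 1 - state
        states.append(state)
        n_transitions += 1
    times = np.arange(int(duration * sampling_rate)) / sampling_rate
    state_at = np.asarray(states)[np.searchsorted(switch_times, times, side="right")]
    ext = baseline + state_at * delta_x + rng.normal(0.0, noise_sd, times.size)
    trace = ClampTrace(times, ext, mean_force=clamp_force, sampling_rate=sampling_rate)
    sidecar = {
        "truth": {
            "delta_x": delta_x,
            "F_eq": F_eq,
            "clamp_force": clamp_force,
            "noise_sd": noise_sd,
            "k0": k0,
            "baseline": baseline,
            "seed": seed,
            "occupancy_high": p_high,
        },
        "n_transitions": n_transitions,
    }
    return trace, sidecar


# ---------------------------------------------------------------------------
# canonical cohort


#: Truth stiffness (pN/nm), intrinsic length (nm), tail residues, nanodisc
#: offset (nm), mean initial unfolding force (pN) and residues released by
#: the first rip for the three constructs the cohort emulates.
CONSTRUCTS = {
    "wt": dict(k=0.7, x0=20.0, n_disordered=123.0, nanodisc=5.0,
               unfold_F=7.1, rip_residues=330.0),
    "d12": dict(k=0.26, x0=16.0, n_disordered=123.0, nanodisc=5.0,
                unfold_F=5.1, rip_residues=330.0),
    "ankb": dict(k=0.12, x0=8.0, n_disordered=30.0, nanodisc=0.0,
                 unfold_F=5.5, rip_residues=132.0),
}

#: Clamp-ladder forces (pN) spanning the gating equilibrium.
CLAMP_LADDER = (5.5, 6.25, 6.9, 7.55, 8.3)


def construct_truth(name: str, seed: int = 0, with_rips: bool = True) -> SimTruth:
    """Canonical SimTruth for one construct of the study cohort."""
    params = CONSTRUCTS[name]
    rips = ()
    if with_rips:
        rips = (
            RipPlan(delta_residues=params["rip_residues"],
                    trigger_force=params["unfold_F"]),
        )
    return SimTruth(
        rod=ElasticRod(params["x0"], params["k"]),
        n_disordered=params["n_disordered"],
        nanodisc=params["nanodisc"],
        rips=rips,
        seed=seed,
    )


def fixture_suite(out_dir, seed: int = 0, n_molecules: int = 3) -> list:
    """Write the canonical synthetic cohort to ``out_dir``.

    DNA-only plus WT, Δ12-type and AnkB-type pulls (with truth sidecars)
    and a constant-force clamp ladder; idempotent for a given seed.
    Returns the list of written trace paths.
    """
    from .io import write_report, write_trace  # local import: io depends on types here

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    paths = []

    def emit(name, trace, sidecar):
        p = out / f"{name}.tsv"
        write_trace(trace, p)
        write_report(sidecar, out / f"{name}.tsv.truth.json", seed=seed)
        paths.append(p)

    streams = root.spawn(1 + len(CONSTRUCTS) * n_molecules + len(CLAMP_LADDER))
    si = 0
    trace, sidecar = simulate_dna_only(rng=np.random.default_rng(streams[si]))
    emit("dna", trace, sidecar)
    si += 1
    for name in CONSTRUCTS:
        for m in range(n_molecules):
            truth = construct_truth(name, seed=seed)
            trace, sidecar = simulate_pull(
                truth, rng=np.random.default_rng(streams[si]), label=f"{name}_{m:02d}"
            )
            emit(f"{name}_{m:02d}", trace, sidecar)
            si += 1
    for j, F in enumerate(CLAMP_LADDER):
        trace, sidecar = simulate_clamp(
            clamp_force=F, rng=np.random.default_rng(streams[si])
        )
        emit(f"clamp_{j}_{F:.2f}pN".replace(".", "p"), trace, sidecar)
        si += 1
    return paths
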