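"""Gating-spring model of a tethered mechanosensitive channel.

Physical picture: the four ankyrin-repeat domains (ARDs) of the tetramer
are joined at an N-terminal contact site into a coupled spring whose
effective stiffness depends on how many subunits are pulled
(:func:`effective_stiffness`).  The structured gating spring is an elastic
rod in series with a parallel bundle of disordered polypeptide tails; the
channel gate adds a fixed gating swing to the rod's intrinsic length and a
gate energy V when open.  Channel opening at quasi-static loading follows
the Boltzmann distribution of the open/closed state energies at fixed
end-to-end extension; :func:`gating_curves` tabulates tension, stiffness
and open probability versus extension, and :func:`midpoint_force` locates
the half-open point.  A generic Bell–Evans module covers
non-equilibrium rupture under a constant loading rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .mechanics import (
    Constants,
    ElasticRod,
    ParallelBundle,
    TetherModel,
    WormLikeChain,
    rod_extension,
    tether_force,
    tether_stiffness,
    wlc_energy,
    wlc_extension,
)

__all__ = [
    "SpringNetwork",
    "GatingConfig",
    "StimulusSpec",
    "BellKinetics",
    "effective_stiffness",
    "state_energy",
    "open_probability",
    "gating_curves",
    "midpoint_force",
    "loading_rate",
    "round_to_one_sig_fig",
    "bell_rupture_distribution",
]


@dataclass(frozen=True)
class SpringNetwork:
    """Coupled-ARD spring network linked at the N-terminal contact site.

    Each isolated ARD of ``n_AR`` repeats has stiffness ``ka`` and uniform
    elasticity, so an m-repeat segment has stiffness n_AR*ka/m (compliance
    proportional to length).  The contact site splits each ARD into
    ``split_N`` repeats toward the pulled N terminus and ``split_C``
    repeats toward the channel; all ``n_subunits`` C-segments act in
    parallel, while only the pulled subunits' N-segments carry load.
    """

    ka: float = 0.7 * 14.0 / 29.0  # calibrated so one pulled subunit gives 0.7 pN/nm
    n_AR: int = 29
    split_N: int = 9
    split_C: int = 20
    n_subunits: int = 4

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if self.split_N + self.split_C != self.n_AR:
            raise ValueError("split_N + split_C must equal n_AR")

    @classmethod
    def from_single_subunit_stiffness(
        cls, k_single: float, n_AR: int = 29, split_N: int = 9, split_C: int = 20,
        n_subunits: int = 4,
    ) -> "SpringNetwork":
        """Calibrate ``ka`` so that pulling one subunit gives ``k_single``."""
        proto = cls(1.0, n_AR, split_N, split_C, n_subunits)
        ka = k_single / effective_stiffness(proto, 1)
        return replace(proto, ka=ka)


def effective_stiffness(net: SpringNetwork, n_pulled: int) -> float:
    """Overall tetramer stiffness with ``n_pulled`` subunits under load.

    Series combination of the parallel pulled N-segments,
    kN = n_pulled * (n_AR/split_N) * ka, with the parallel anchored
    C-segments, kC = n_subunits * (n_AR/split_C) * ka.
    """
    if not 1 <= n_pulled <= net.n_subunits:
        raise ValueError(
            f"n_pulled={n_pulled} outside [1, {net.n_subunits}]"
        )
    kN = n_pulled * net.n_AR * net.ka / net.split_N
    kC = net.n_subunits * net.n_AR * net.ka / net.split_C
    return kN * kC / (kN + kC)


@dataclass(frozen=True)
class GatingConfig:
    """Parameters of the tetramer gating model.

    The closed-channel rod has intrinsic length ``x0_closed_folded``
    (fully folded ARDs) or ``x0_closed_partial`` (partially unfolded);
    opening adds ``gating_swing`` to the intrinsic length and costs
    ``V_open`` (in kBT).  Each of the ``n_tethered`` subunits contributes
    a disordered tail whose residue count depends on the folding state;
    the tails share the tension equally as a parallel bundle.
    """

    k_fold: float = 1.4  # pN/nm, folded-rod stiffness (all four subunits loaded)
    x0_closed_folded: float = 20.0  # nm
    x0_closed_partial: float = 14.5  # nm
    gating_swing: float = 4.6  # nm
    V_open: float = 8.0  # kBT
    disordered_residues_folded: int = 123  # per subunit
    disordered_residues_partial: int = 442  # per subunit
    n_tethered: int = 4
    chain_P: float = 0.6  # nm

    def x0(self, open_: bool, partial: bool) -> float:
        base = self.x0_closed_partial if partial else self.x0_closed_folded
        return base + (self.gating_swing if open_ else 0.0)

    def chain(self, partial: bool, c: Constants = Constants()) -> WormLikeChain | None:
        n = self.disordered_residues_partial if partial else self.disordered_residues_folded
        if n == 0:
            return None
        return WormLikeChain.from_residues(n, self.chain_P, c)

    def tether(self, open_: bool, partial: bool, c: Constants = Constants()) -> TetherModel:
        """Series rod + parallel bundle of disordered tails for one state."""
        elements = [ElasticRod(self.x0(open_, partial), self.k_fold)]
        chain = self.chain(partial, c)
        if chain is not None:
            elements.append(ParallelBundle(chain, self.n_tethered))
        return TetherModel(tuple(elements))


@dataclass(frozen=True)
class StimulusSpec:
    """Oscillatory stimulus: frequency (Hz) and peak gating-spring extension change (nm)."""

    frequency: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.amplitude <= 0:
            raise ValueError("frequency and amplitude must be > 0")


# ---------------------------------------------------------------------------
# state energies and open probability


def _solve_state_tension(x: float, open_: bool, partial: bool, cfg: GatingConfig,
                         c: Constants) -> float:
    """Tension of one channel state at end-to-end extension x.

    Below the state's zero-force length the disordered tails are slack and
    the rod carries linear compression (F < 0), keeping the energy surface
    continuous for the Boltzmann comparison of states.
    """
    if x < 0:
        raise ValueError(f"extension x={x} nm must be >= 0")
    tether = cfg.tether(open_, partial, c)
    if x >= tether.zero_force_length():
        return tether_force(x, tether, c)
    rod = ElasticRod(cfg.x0(open_, partial), cfg.k_fold)
    return cfg.k_fold * (x - rod.intrinsic_length)


def state_energy(
    x: float,
    open_: bool,
    partial: bool,
    cfg: GatingConfig = GatingConfig(),
    c: Constants = Constants(),
) -> tuple[float, float]:
    """Total energy (pN·nm) and tension (pN) of one state at extension ``x``.

    E = F^2/(2 k_fold) + Eu + V, with Eu the summed entropic energy of the
    stretched disordered tails (each at tension F/n) and V the gate energy
    (0 closed, V_open*kBT open).
    """
    F = _solve_state_tension(x, open_, partial, cfg, c)
    E = F * F / (2.0 * cfg.k_fold)
    chain = cfg.chain(partial, c)
    if F > 0 and chain is not None:
        xu = wlc_extension(F / cfg.n_tethered, chain, c)
        E += cfg.n_tethered * wlc_energy(xu, chain, c)
    if open_:
        E += cfg.V_open * c.kBT
    return E, F


def open_probability(
    x: float,
    partial: bool = False,
    cfg: GatingConfig = GatingConfig(),
    c: Constants = Constants(),
) -> float:
    """Boltzmann open probability P = 1/(1 + exp(dE/kBT)) at extension ``x``."""
    E_open, _ = state_energy(x, True, partial, cfg, c)
    E_closed, _ = state_energy(x, False, partial, cfg, c)
    dE = E_open - E_closed
    return 1.0 / (1.0 + math.exp(min(dE / c.kBT, 700.0)))


def gating_curves(
    x_grid,
    cfg: GatingConfig = GatingConfig(),
    c: Constants = Constants(),
    partial: bool = False,
) -> pd.DataFrame:
    """Tension, stiffness and open probability along an extension grid.

    Returns a DataFrame with columns ``ext_nm, F_closed_pN, F_open_pN,
    F_avg_pN, stiffness_pN_per_nm, p_open``; the average tension weighs
    the branch tensions by the Boltzmann occupancies and the stiffness is
    the same occupancy-weighted mix of branch stiffnesses.
    """
    rows = []
    for x in np.asarray(x_grid, dtype=float):
        E_c, F_c = state_energy(x, False, partial, cfg, c)
        E_o, F_o = state_energy(x, True, partial, cfg, c)
        p = 1.0 / (1.0 + math.exp(min((E_o - E_c) / c.kBT, 700.0)))
        ks = []
        for open_, F in ((False, F_c), (True, F_o)):
            if F > 0:
                ks.append(tether_stiffness(F, cfg.tether(open_, partial, c), c))
            else:
                ks.append(cfg.k_fold)  # slack chains: rod alone
        rows.append(
            (x, F_c, F_o, p * F_o + (1 - p) * F_c, p * ks[1] + (1 - p) * ks[0], p)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ext_nm",
            "F_closed_pN",
            "F_open_pN",
            "F_avg_pN",
            "stiffness_pN_per_nm",
            "p_open",
        ],
    )


def midpoint_force(
    cfg: GatingConfig = GatingConfig(),
    c: Constants = Constants(),
    partial: bool = False,
) -> dict:
    """Gating force: tensions at the extension where open and closed states
    are equally probable.

    Root-solves dE(x*) = 0 and returns the average tension there together
    with both branch tensions and x* itself.
    """

    def dE(x: float) -> float:
        return state_energy(x, True, partial, cfg, c)[0] - state_energy(
            x, False, partial, cfg, c
        )[0]

    lo = cfg.x0(False, partial)
    hi = lo + 200.0
    if dE(lo) <= 0 or dE(hi) >= 0:
        raise ValueError("no open/closed equal-energy point in the search domain")
    x_star = brentq(dE, lo, hi, xtol=1e-12, rtol=1e-12)
    _, F_closed = state_energy(x_star, False, partial, cfg, c)
    _, F_open = state_energy(x_star, True, partial, cfg, c)
    return {
        "x_star_nm": x_star,
        "F_closed_pN": F_closed,
        "F_open_pN": F_open,
        "F_avg_pN": 0.5 * (F_closed + F_open),
    }


# ---------------------------------------------------------------------------
# stimulus loading rate


def loading_rate(stim: StimulusSpec, stiffness: float, peak: bool = False) -> float:
    """Force loading rate (pN/s) of an oscillatory stimulus on a spring.

    Default convention: the amplitude is traversed once per half period,
    giving rate = stiffness * amplitude * 2 * frequency.  With
    ``peak=True`` the instantaneous sinusoidal maximum 2*pi*f*A*k is
    returned instead.
    """
    if stiffness < 0:
        raise ValueError("stiffness must be >= 0")
    factor = 2.0 * math.pi if peak else 2.0
    return stiffness * stim.amplitude * factor * stim.frequency


def round_to_one_sig_fig(value: float) -> float:
    """Round to one significant figure (3 × 10^3 style reporting)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    scale = 10.0**exponent
    return round(value / scale) * scale


# ---------------------------------------------------------------------------
# Bell–Evans rupture kinetics


@dataclass(frozen=True)
class BellKinetics:
    """Bell rate law k(F) = k0 exp(F x_dagger / kBT)."""

    k0: float = 1e-3  # 1/s at zero force
    x_dagger: float = 2.0  # nm, distance to the transition state

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.x_dagger <= 0:
            raise ValueError("k0 and x_dagger must be > 0")

    def rate(self, F, c: Constants = Constants()):
        return self.k0 * np.exp(np.asarray(F, dtype=float) * self.x_dagger / c.kBT)


def bell_rupture_distribution(
    kin: BellKinetics, loading_rate: float, c: Constants = Constants()
) -> dict:
    """Rupture-force distribution at constant loading rate r.

    Survival S(F) = exp[-(k0 kBT)/(r x‡) (exp(F x‡/kBT) - 1)], density
    p(F) = k(F) S(F)/r, analytic mode F* = (kBT/x‡) ln(r x‡/(k0 kBT)),
    mean by quadrature.  Returns callables and summary scalars.
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be > 0")
    a = kin.x_dagger / c.kBT
    b = kin.k0 * c.kBT / (loading_rate * kin.x_dagger)

    def survival(F):
        F = np.asarray(F, dtype=float)
        return np.exp(-b * (np.exp(np.clip(a * F, None, 700.0)) - 1.0))

    def density(F):
        F = np.asarray(F, dtype=float)
        return kin.k0 * np.exp(np.clip(a * F, None, 700.0)) / loading_rate * survival(F)

    mode = max((c.kBT / kin.x_dagger) * math.log(1.0 / b), 0.0)
    upper = mode + 20.0 * c.kBT / kin.x_dagger + 10.0
    mean = quad(lambda F: F * density(F), 0.0, upper, limit=200)[0]
    return {
        "survival": survival,
        "density": density,
        "mode_pN": mode,
        "mean_pN": mean,
        "upper_support_pN": upper,
    }
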