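"""Closed-form polymer and rod mechanics for bead-tether force spectroscopy.

The mechanical vocabulary of a dual-trap pulling experiment on a
membrane-protein tether: worm-like chains (DNA handles, unfolded
polypeptide), elastic rods (folded protein domains), rigid offsets
(nanodisc) and parallel bundles of identical elements (several disordered
tails sharing the load).  Elements compose in series into a
:class:`TetherModel` that shares one tension and sums extensions; its
force–extension relation is inverted by bracketed root finding.

Units throughout: length nm, force pN, energy pN·nm, stiffness pN/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Constants",
    "WormLikeChain",
    "ElasticRod",
    "RigidOffset",
    "ParallelBundle",
    "TetherModel",
    "wlc_force",
    "wlc_extension",
    "wlc_energy",
    "rod_extension",
    "tether_extension",
    "tether_force",
    "tether_stiffness",
]

#: Contour length per base pair of B-form DNA, nm.
BP_RISE = 0.338
#: Contour length per amino acid of unfolded polypeptide, nm.
AA_RISE = 0.365

_REL_TOL = 1e-9


@dataclass(frozen=True)
class Constants:
    """Physical constants of the experiment.

    kBT is the thermal energy at room temperature; aa_rise and bp_rise
    convert residue / base-pair counts to contour length.
    """

    kBT: float = 4.1  # pN·nm
    aa_rise: float = AA_RISE  # nm per residue
    bp_rise: float = BP_RISE  # nm per base pair

    def __post_init__(self) -> None:
        if self.kBT <= 0 or self.aa_rise <= 0 or self.bp_rise <= 0:
            raise ValueError("all constants must be strictly positive")


@dataclass(frozen=True)
class WormLikeChain:
    """Semi-flexible polymer with contour length L and persistence length P (nm)."""

    contour_length: float
    persistence_length: float

    def __post_init__(self) -> None:
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.persistence_length <= 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )

    @classmethod
    def from_residues(
        cls, n_residues: float, persistence_length: float = 0.6, c: Constants = Constants()
    ) -> "WormLikeChain":
        """Unfolded polypeptide of ``n_residues`` amino acids."""
        return cls(n_residues * c.aa_rise, persistence_length)

    @classmethod
    def from_basepairs(
        cls, n_bp: float, persistence_length: float = 40.0, c: Constants = Constants()
    ) -> "WormLikeChain":
        """Double-stranded DNA handle of ``n_bp`` base pairs."""
        return cls(n_bp * c.bp_rise, persistence_length)


@dataclass(frozen=True)
class ElasticRod:
    """Linear spring with intrinsic (zero-force) length x0 and stiffness k."""

    intrinsic_length: float
    stiffness: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError(f"stiffness must be > 0, got {self.stiffness}")
        if self.intrinsic_length < 0:
            raise ValueError(f"intrinsic_length must be >= 0, got {self.intrinsic_length}")


@dataclass(frozen=True)
class RigidOffset:
    """Force-independent length (e.g. the nanodisc, ~5 nm)."""

    length: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"length must be >= 0, got {self.length}")


@dataclass(frozen=True)
class ParallelBundle:
    """``multiplicity`` identical elements in parallel at a common extension.

    The bundle carries force F by loading each member with F/n, so the
    bundle extension equals the member extension at F/n and the bundle
    compliance is the member compliance divided by n.
    """

    element: object
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


@dataclass(frozen=True)
class TetherModel:
    """Ordered series of mechanical elements sharing one tension."""

    elements: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))

    def zero_force_length(self) -> float:
        """Summed extension at F = 0 (rigid parts and rod intrinsic lengths)."""
        total = 0.0
        for el in self.elements:
            if isinstance(el, ParallelBundle):
                el = el.element
            if isinstance(el, ElasticRod):
                total += el.intrinsic_length
            elif isinstance(el, RigidOffset):
                total += el.length
        return total

    def max_extension(self) -> float:
        """Supremum of attainable extension (inf when a rod is present)."""
        total = 0.0
        for el in self.elements:
            inner = el.element if isinstance(el, ParallelBundle) else el
            if isinstance(inner, WormLikeChain):
                total += inner.contour_length
            elif isinstance(inner, ElasticRod):
                return np.inf
            elif isinstance(inner, RigidOffset):
                total += inner.length
        return total


# ---------------------------------------------------------------------------
# worm-like chain


def wlc_force(x: float, chain: WormLikeChain, c: Constants = Constants()) -> float:
    """Tension of a worm-like chain at extension ``x`` (interpolation formula).

    F = (kBT/P) [ 1/(4 (1 - x/L)^2) + x/L - 1/4 ], diverging as x -> L.
    """
    L, P = chain.contour_length, chain.persistence_length
    x = float(x)
    if x < 0 or x >= L:
        raise ValueError(f"extension x={x} nm outside [0, L={L} nm)")
    r = x / L
    return (c.kBT / P) * (0.25 / (1.0 - r) ** 2 + r - 0.25)


def wlc_extension(F: float, chain: WormLikeChain, c: Constants = Constants()) -> float:
    """Inverse of :func:`wlc_force`: unique extension in [0, L) at tension F."""
    F = float(F)
    if F < 0:
        raise ValueError(f"force F={F} pN must be >= 0")
    if F == 0.0:
        return 0.0
    L = chain.contour_length

    def g(r: float) -> float:
        return (0.25 / (1.0 - r) ** 2 + r - 0.25) - F * chain.persistence_length / c.kBT

    # g is strictly increasing on [0, 1); bracket the root away from r = 1
    hi = 1.0 - 1e-14
    r = brentq(g, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    return r * L


def wlc_energy(x: float, chain: WormLikeChain, c: Constants = Constants()) -> float:
    """Entropic stretching energy of a worm-like chain at extension ``x``.

    E = (kBT/P) (L/4) [3 (x/L)^2 - 2 (x/L)^3] / (1 - x/L); the exact
    integral of :func:`wlc_force` from 0 to x.
    """
    L, P = chain.contour_length, chain.persistence_length
    x = float(x)
    if x < 0 or x >= L:
        raise ValueError(f"extension x={x} nm outside [0, L={L} nm)")
    r = x / L
    return (c.kBT / P) * (L / 4.0) * (3.0 * r**2 - 2.0 * r**3) / (1.0 - r)


def _wlc_compliance(F: float, chain: WormLikeChain, c: Constants) -> float:
    """dx/dF of a worm-like chain at tension F (analytic)."""
    x = wlc_extension(F, chain, c)
    r = x / chain.contour_length
    dFdx = (c.kBT / chain.persistence_length / chain.contour_length) * (
        0.5 / (1.0 - r) ** 3 + 1.0
    )
    return 1.0 / dFdx


# ---------------------------------------------------------------------------
# rods and composites


def rod_extension(F: float, rod: ElasticRod) -> float:
    """Extension of an elastic rod: x0 + F/k (F < 0 means compression)."""
    return rod.intrinsic_length + float(F) / rod.stiffness


def _element_extension(F: float, el, c: Constants) -> float:
    if isinstance(el, ParallelBundle):
        return _element_extension(F / el.multiplicity, el.element, c)
    if isinstance(el, WormLikeChain):
        return wlc_extension(F, el, c)
    if isinstance(el, ElasticRod):
        return rod_extension(F, el)
    if isinstance(el, RigidOffset):
        return el.length
    raise TypeError(f"unknown mechanical element {type(el).__name__}")


def _element_compliance(F: float, el, c: Constants) -> float:
    if isinstance(el, ParallelBundle):
        return _element_compliance(F / el.multiplicity, el.element, c) / el.multiplicity
    if isinstance(el, WormLikeChain):
        return _wlc_compliance(F, el, c)
    if isinstance(el, ElasticRod):
        return 1.0 / el.stiffness
    if isinstance(el, RigidOffset):
        return 0.0
    raise TypeError(f"unknown mechanical element {type(el).__name__}")


def tether_extension(F: float, tether: TetherModel, c: Constants = Constants()) -> float:
    """Total extension of a series tether at common tension F (sum over elements)."""
    F = float(F)
    if F < 0:
        raise ValueError(f"force F={F} pN must be >= 0")
    return sum(_element_extension(F, el, c) for el in tether.elements)


def tether_force(X: float, tether: TetherModel, c: Constants = Constants()) -> float:
    """Tension at which the tether's total extension equals ``X``.

    Bracketed (bisection-secured) root of ``tether_extension(F) = X``; the
    bracket is expanded geometrically until it straddles the target.
    """
    X = float(X)
    x0 = tether.zero_force_length()
    if X < x0:
        raise ValueError(
            f"extension X={X} nm below zero-force length {x0} nm of the tether"
        )
    if X == x0 and tether_extension(0.0, tether, c) == X:
        return 0.0
    xmax = tether.max_extension()
    if np.isfinite(xmax) and X >= xmax:
        raise ValueError(f"extension X={X} nm at or beyond contour limit {xmax} nm")

    def h(F: float) -> float:
        return tether_extension(F, tether, c) - X

    lo, hi = 0.0, 1.0
    while h(hi) < 0:
        lo, hi = hi, hi * 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for physical tethers
            raise RuntimeError("failed to bracket tether tension")
    F = brentq(h, lo, hi, xtol=1e-12, rtol=_REL_TOL)
    return F


def tether_stiffness(F: float, tether: TetherModel, c: Constants = Constants()) -> float:
    """Stiffness dF/dX of the tether at tension F (series compliances add)."""
    F = float(F)
    if F <= 0:
        raise ValueError(f"force F={F} pN must be > 0 for a defined WLC compliance")
    compliance = sum(_element_compliance(F, el, c) for el in tether.elements)
    return 1.0 / compliance
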