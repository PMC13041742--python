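"""Constant-force (force-clamp) two-state analysis of the gating transition.

At a clamped mean force near equilibrium the extension flickers between
two levels (closed and open channel).  The extension histogram is fit by
a sum of two Gaussians; the high-extension weight gives the open-state
occupancy, a log-odds interpolation across a clamp ladder gives the
equilibrium force, and the gating energy is the reversible work
F_eq × Δx converted to kBT and kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .mechanics import Constants

__all__ = [
    "ClampTrace",
    "TwoGaussianFit",
    "GatingEstimate",
    "KCAL_PER_MOL_IN_PN_NM",
    "extension_density",
    "TwoGaussianMixtureModel",
    "fit_two_gaussians",
    "equilibrium_force",
    "gating_energy",
    "gating_energy_per_transition",
]

#: 1 kcal/mol expressed in pN·nm per molecule (kBT = 4.1 pN·nm ~ 0.593 kcal/mol).
KCAL_PER_MOL_IN_PN_NM = 6.9477


@dataclass
class ClampTrace:
    """Extension-time trajectory at a constant mean force."""

    time: np.ndarray
    extension: np.ndarray
    mean_force: float
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.size != self.extension.size:
            raise ValueError("time and extension must have equal length")
        if self.mean_force <= 0:
            raise ValueError("mean_force must be > 0")
        if self.sampling_rate is None and self.time.size >= 2:
            self.sampling_rate = 1.0 / float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) > 1 else 0.0


@dataclass
class TwoGaussianFit:
    """Two-Gaussian mixture of the clamp extension density.

    Canonicalized so mu_high > mu_low; ``weight_high`` is the mass of the
    high-extension (open-state) component.
    """

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    weight_high: float
    converged: bool = True
    degenerate: bool = False
    redchi: float = np.nan

    @property
    def separation(self) -> float:
        return self.mu_high - self.mu_low

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-Gaussian clamp mixture fit",
                "------------------------------",
                f"mu_low / mu_high   : {self.mu_low:.3f} / {self.mu_high:.3f} nm",
                f"separation (swing) : {self.separation:.3f} nm",
                f"sigma_low / high   : {self.sigma_low:.3f} / {self.sigma_high:.3f} nm",
                f"open-state weight  : {self.weight_high:.3f}",
                f"converged / degenerate : {self.converged} / {self.degenerate}",
            ]
        )


@dataclass
class GatingEstimate:
    """Gating work F_eq × Δx with unit conversions."""

    F_eq: float
    delta_x: float
    energy_pN_nm: float
    energy_kBT: float
    energy_kcal_per_mol: float
    n_transitions: int = 0
    mode: str = "from_means"

    def summary(self) -> str:
        return "\n".join(
            [
                "Gating-transition energy",
                "------------------------",
                f"equilibrium force : {self.F_eq:.2f} pN",
                f"gating swing      : {self.delta_x:.2f} nm",
                f"work              : {self.energy_pN_nm:.2f} pN nm"
                f" = {self.energy_kBT:.2f} kBT"
                f" = {self.energy_kcal_per_mol:.2f} kcal/mol",
                f"mode              : {self.mode} (n={self.n_transitions})",
            ]
        )


# ---------------------------------------------------------------------------


def extension_density(trace: ClampTrace, bin_width: float = 0.5) -> dict:
    """Normalized histogram density of the clamp extension (integrates to 1)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(trace) == 0:
        raise ValueError("empty clamp trace")
    x = trace.extension
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + 1.5 * bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"extension": centers, "density": density, "bin_width": bin_width}


def _two_gauss(x, mu1, mu2, s1, s2, w):
    g1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return (1.0 - w) * g1 + w * g2


class TwoGaussianMixtureModel:
    """Weighted least-squares two-Gaussian fit of an extension density.

    Initialized from the two most prominent well-separated modes of the
    density; results are canonicalized so the high-extension component is
    second.
    """

    def __init__(self, density: dict):
        self.x = np.asarray(density["extension"], dtype=float)
        self.y = np.asarray(density["density"], dtype=float)
        self.bin_width = float(density["bin_width"])
        if np.count_nonzero(self.y > 0) < 10:
            raise ValueError("need a density with at least 10 occupied bins")

    def _initial_modes(self) -> tuple:
        order = np.argsort(self.y)[::-1]
        m1 = self.x[order[0]]
        for idx in order[1:]:
            if abs(self.x[idx] - m1) > 1.5 * self.bin_width:
                return (min(m1, self.x[idx]), max(m1, self.x[idx]))
        return (m1, m1)  # degenerate: single mode

    def fit(self) -> TwoGaussianFit:
        mu1, mu2 = self._initial_modes()
        degenerate = (mu2 - mu1) <= self.bin_width
        mean = np.average(self.x, weights=self.y)
        sd = np.sqrt(np.average((self.x - mean) ** 2, weights=self.y))

        def resid(p):
            v = p.valuesdict()
            return _two_gauss(self.x, v["mu1"], v["mu2"], v["s1"], v["s2"], v["w"]) - self.y

        # the mixture objective has degenerate local minima when the modes
        # overlap, so try several moment-based starts and keep the best
        starts = []
        if not degenerate:
            starts.append((mu1, mu2, 0.5))
        for sep in (sd, 1.5 * sd, 2.0 * sd):
            for w in (0.25, 0.5, 0.75):
                starts.append((mean - w * sep, mean + (1.0 - w) * sep, w))
        best = None
        for m1, m2, w0 in starts:
            params = lmfit.Parameters()
            params.add("mu1", value=m1)
            params.add("delta", value=max(m2 - m1, self.bin_width),
                       min=0.5 * self.bin_width, max=10.0 * sd + self.bin_width)
            params.add("mu2", expr="mu1 + delta")
            s0 = float(np.clip(np.sqrt(max(sd**2 - ((m2 - m1) / 2) ** 2, 0.0)) or sd / 2,
                               0.3 * self.bin_width, 3.0 * sd))
            params.add("s1", value=s0, min=0.25 * self.bin_width, max=4.0 * sd)
            params.add("s2", value=s0, min=0.25 * self.bin_width, max=4.0 * sd)
            params.add("w", value=w0, min=1e-3, max=1.0 - 1e-3)
            try:
                cand = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if best is None or cand.redchi < best.redchi:
                best = cand
        if best is None:
            raise RuntimeError("two-Gaussian mixture fit failed from every start")
        res = best
        v = res.params.valuesdict()
        mu_l, mu_h = v["mu1"], v["mu2"]
        s_l, s_h = abs(v["s1"]), abs(v["s2"])
        w_h = v["w"]
        if mu_l > mu_h:  # canonical order: high-extension component second
            mu_l, mu_h = mu_h, mu_l
            s_l, s_h = s_h, s_l
            w_h = 1.0 - w_h
        return TwoGaussianFit(
            mu_low=float(mu_l),
            mu_high=float(mu_h),
            sigma_low=float(s_l),
            sigma_high=float(s_h),
            weight_high=float(w_h),
            converged=bool(res.success),
            degenerate=degenerate,
            redchi=float(res.redchi),
        )


def fit_two_gaussians(density: dict) -> TwoGaussianFit:
    """Functional wrapper around :class:`TwoGaussianMixtureModel`."""
    return TwoGaussianMixtureModel(density).fit()


def equilibrium_force(clamps) -> float:
    """Force of equal open/closed occupancy from a clamp ladder.

    ``clamps`` are (mean_force, occupancy_high) pairs; the zero crossing
    of log(p/(1-p)) versus force is located by linear interpolation, which
    is exact for a two-state system with a constant gating swing.
    """
    pts = sorted((float(F), float(p)) for F, p in clamps)
    if len(pts) < 2:
        raise ValueError("need at least two clamp points")
    F = np.array([p[0] for p in pts])
    occ = np.array([p[1] for p in pts])
    if np.any((occ <= 0) | (occ >= 1)):
        raise ValueError("occupancies must lie strictly in (0, 1)")
    logodds = np.log(occ / (1.0 - occ))
    exact = np.isclose(logodds, 0.0, atol=1e-12)
    if exact.any():
        return float(F[np.argmax(exact)])
    sign = np.sign(logodds)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise ValueError("clamp ladder does not straddle occupancy 0.5")
    # least-squares line through all points is exact for the two-state model
    # and averages noise; fall back to local interpolation if it misbehaves
    slope, intercept = np.polyfit(F, logodds, 1)
    if slope != 0:
        F_eq = -intercept / slope
        if F[0] <= F_eq <= F[-1]:
            return float(F_eq)
    i = crossings[0]
    return float(
        F[i] - logodds[i] * (F[i + 1] - F[i]) / (logodds[i + 1] - logodds[i])
    )


def gating_energy(F_eq: float, delta_x: float, c: Constants = Constants()) -> GatingEstimate:
    """Gating work from the mean equilibrium force and gating swing."""
    if F_eq < 0 or delta_x < 0:
        raise ValueError("F_eq and delta_x must be >= 0")
    work = F_eq * delta_x
    return GatingEstimate(
        F_eq=F_eq,
        delta_x=delta_x,
        energy_pN_nm=work,
        energy_kBT=work / c.kBT,
        energy_kcal_per_mol=work / KCAL_PER_MOL_IN_PN_NM,
        n_transitions=0,
        mode="from_means",
    )


def gating_energy_per_transition(pairs, c: Constants = Constants()) -> GatingEstimate:
    """Gating work averaged over per-transition (force, extension change) pairs."""
    pairs = [(float(F), float(dx)) for F, dx in pairs]
    if not pairs:
        raise ValueError("need at least one transition")
    works = np.array([F * dx for F, dx in pairs])
    work = float(np.mean(works))
    return GatingEstimate(
        F_eq=float(np.mean([F for F, _ in pairs])),
        delta_x=float(np.mean([dx for _, dx in pairs])),
        energy_pN_nm=work,
        energy_kBT=work / c.kBT,
        energy_kcal_per_mol=work / KCAL_PER_MOL_IN_PN_NM,
        n_transitions=len(pairs),
        mode="per_transition",
    )
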