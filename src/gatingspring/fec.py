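"""Force–extension curve (FEC) analysis for the differential tether assay.

The experiment pulls the same DNA tether twice — once bare, once with the
protein inserted by strand displacement — so the protein's absolute
extension is the difference of the two force-binned FECs after further
subtracting the disordered-tail worm-like chain and the rigid nanodisc.
This module covers that pipeline end to end: boxcar filtering, force
binning, differential subtraction, molecule pooling, the linear stiffness
fit of the folded branch, a global worm-like-chain fit of DNA-only and
protein–DNA FECs, rip (unfolding/refolding/insertion) detection,
contour-length state assignment to ankyrin-repeat counts, rupture-force
statistics, state occurrence profiles and refolding classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import lmfit
import numpy as np

from .mechanics import Constants, RigidOffset, WormLikeChain, wlc_extension

__all__ = [
    "ForceExtensionTrace",
    "BinnedFEC",
    "RipEvent",
    "StateAssignment",
    "StiffnessFit",
    "boxcar_filter",
    "bin_by_force",
    "differential_structured_extension",
    "pool_molecules",
    "LinearStiffnessModel",
    "fit_stiffness_linear",
    "GlobalFECModel",
    "GlobalFECResults",
    "fit_fec_global",
    "detect_transitions",
    "segment_at_events",
    "assign_states",
    "unfolding_force_stats",
    "state_occurrence_profile",
    "classify_refolding",
]

RESIDUES_PER_AR = 33


@dataclass
class ForceExtensionTrace:
    """Uniformly sampled pulling trajectory (time s, force pN, extension nm)."""

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    trap_sep: np.ndarray | None = None
    label: str = ""
    phase: str = "pull"  # pull | relax
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.trap_sep is not None:
            self.trap_sep = np.asarray(self.trap_sep, dtype=float)
        n = self.time.size
        if self.force.size != n or self.extension.size != n:
            raise ValueError("time, force, extension must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if dt.min() < 0.99 * dt.max() or dt.max() > 1.01 * dt.min():
                raise ValueError("sampling must be uniform within 1%")
            if self.sampling_rate is None:
                self.sampling_rate = 1.0 / float(np.mean(dt))
        if self.phase not in ("pull", "relax"):
            raise ValueError(f"phase must be 'pull' or 'relax', got {self.phase!r}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) > 1 else 0.0

    def slice(self, start: int, stop: int) -> "ForceExtensionTrace":
        return ForceExtensionTrace(
            self.time[start:stop],
            self.force[start:stop],
            self.extension[start:stop],
            None if self.trap_sep is None else self.trap_sep[start:stop],
            self.label,
            self.phase,
            self.sampling_rate,
        )


@dataclass
class BinnedFEC:
    """Force-binned FEC: per-bin mean extension, spread and sample count.

    ``mean_force`` is the average measured force of the samples in each
    bin; downstream fits evaluate models there rather than at the
    geometric bin center, which matters where the tether compliance is
    large compared to the bin width.
    """

    force_center: np.ndarray
    mean_ext: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    bin_width: float = np.nan
    n_molecules: int = 1
    mean_force: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force_center = np.asarray(self.force_center, dtype=float)
        self.mean_ext = np.asarray(self.mean_ext, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.mean_force is None:
            self.mean_force = self.force_center.copy()
        else:
            self.mean_force = np.asarray(self.mean_force, dtype=float)
        if np.any(np.diff(self.force_center) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("reported bins must contain at least one sample")

    def __len__(self) -> int:
        return self.force_center.size

    def restrict(self, lo: float, hi: float) -> "BinnedFEC":
        m = (self.force_center >= lo) & (self.force_center <= hi)
        return replace(
            self,
            force_center=self.force_center[m],
            mean_ext=self.mean_ext[m],
            sd=self.sd[m],
            n=self.n[m],
            mean_force=self.mean_force[m],
        )


@dataclass(frozen=True)
class RipEvent:
    """Abrupt extension change: an unfolding rip, a refolding step or a
    strand-displacement insertion."""

    time: float
    force_at_rip: float
    extension_jump: float
    direction: str  # unfolding | refolding | insertion
    index: int = -1


@dataclass(frozen=True)
class StateAssignment:
    """FEC branch mapped to unfolded residue / ankyrin-repeat counts."""

    contour_gain: float
    unfolded_residues: int
    unfolded_ARs: int
    state_label: str


@dataclass
class StiffnessFit:
    """Result of the linear folded-branch fit F = k (x - x0)."""

    k: float
    x0: float
    k_sem: float
    x0_sem: float
    force_range: tuple
    n_molecules: int = 1
    n_bins: int = 0
    converged: bool = True

    def summary(self) -> str:
        lines = [
            "Linear gating-spring stiffness fit",
            "----------------------------------",
            f"force range        : {self.force_range[0]:.2f} - {self.force_range[1]:.2f} pN",
            f"bins / molecules   : {self.n_bins} / {self.n_molecules}",
            f"stiffness k        : {self.k:.4g} +/- {self.k_sem:.2g} pN/nm",
            f"intrinsic length x0: {self.x0:.4g} +/- {self.x0_sem:.2g} nm",
            f"converged          : {self.converged}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# filtering and binning


def boxcar_filter(trace: ForceExtensionTrace, window: float) -> ForceExtensionTrace:
    """Centered moving average of force and extension over ``window`` seconds.

    Edges without full support are dropped, so the output is shorter by one
    window's worth of samples.
    """
    if window <= 0 or window > trace.duration:
        raise ValueError(f"window {window}s outside (0, {trace.duration}s]")
    m = int(round(window * trace.sampling_rate))
    if m < 2:
        raise ValueError(f"window {window}s covers fewer than 2 samples")
    kernel = np.full(m, 1.0 / m)
    out = ForceExtensionTrace(
        np.convolve(trace.time, kernel, mode="valid"),
        np.convolve(trace.force, kernel, mode="valid"),
        np.convolve(trace.extension, kernel, mode="valid"),
        None
        if trace.trap_sep is None
        else np.convolve(trace.trap_sep, kernel, mode="valid"),
        trace.label,
        trace.phase,
        trace.sampling_rate,
    )
    return out


def bin_by_force(
    trace: ForceExtensionTrace,
    bin_width: float = 0.2,
    force_range: tuple = (0.5, 20.0),
) -> BinnedFEC:
    """Discretize a trace into uniform force bins of the extension statistics.

    Per-bin spread is the population SD of the extensions in the bin; bins
    with no samples are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = force_range
    if hi <= lo:
        raise ValueError(f"empty force range {force_range}")
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    idx = np.floor((trace.force - lo) / bin_width).astype(int)
    valid = (trace.force >= lo) & (trace.force < edges[-1]) & (idx >= 0)
    idx = idx[valid]
    ext = trace.extension[valid]
    if ext.size == 0:
        return BinnedFEC(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=int), bin_width
        )
    nbins = edges.size - 1
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=ext, minlength=nbins)
    sq = np.bincount(idx, weights=ext**2, minlength=nbins)
    fsums = np.bincount(idx, weights=trace.force[valid], minlength=nbins)
    occupied = counts > 0
    mean = sums[occupied] / counts[occupied]
    var = np.maximum(sq[occupied] / counts[occupied] - mean**2, 0.0)
    centers = (edges[:-1] + 0.5 * bin_width)[occupied]
    return BinnedFEC(
        centers,
        mean,
        np.sqrt(var),
        counts[occupied],
        bin_width,
        mean_force=fsums[occupied] / counts[occupied],
    )


def _shared_bins(a: BinnedFEC, b: BinnedFEC) -> tuple:
    tol = 1e-6 * max(1.0, a.bin_width if np.isfinite(a.bin_width) else 1.0)
    ia, ib = [], []
    j = 0
    for i, fc in enumerate(a.force_center):
        while j < len(b) and b.force_center[j] < fc - tol:
            j += 1
        if j < len(b) and abs(b.force_center[j] - fc) <= tol:
            ia.append(i)
            ib.append(j)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def differential_structured_extension(
    protein_fec: BinnedFEC,
    dna_fec: BinnedFEC,
    n_disordered: float = 123,
    nanodisc: RigidOffset = RigidOffset(5.0),
    chain_P: float = 0.6,
    c: Constants = Constants(),
) -> BinnedFEC:
    """Structured-protein extension by differential subtraction.

    Per shared force bin: protein-tether mean minus DNA-only mean, minus
    the worm-like-chain extension of the ``n_disordered``-residue tail and
    the rigid nanodisc length; spreads propagate in quadrature.
    """
    ia, ib = _shared_bins(protein_fec, dna_fec)
    if ia.size == 0:
        raise ValueError("protein and DNA FECs share no force bins")
    F = protein_fec.mean_force[ia]
    # evaluate the DNA handle extension at the protein bins' mean force:
    # a first-order slope correction removes the bias from the two ramps
    # sampling each force bin slightly differently
    x_dna = dna_fec.mean_ext[ib]
    if ib.size >= 2:
        slope = np.gradient(dna_fec.mean_ext[ib], dna_fec.mean_force[ib])
        x_dna = x_dna + slope * (F - dna_fec.mean_force[ib])
    if n_disordered > 0:
        chain = WormLikeChain.from_residues(n_disordered, chain_P, c)
        xu = np.array([wlc_extension(f, chain, c) for f in F])
    else:
        xu = np.zeros_like(F)
    mean = protein_fec.mean_ext[ia] - x_dna - xu - nanodisc.length
    sd = np.sqrt(protein_fec.sd[ia] ** 2 + dna_fec.sd[ib] ** 2)
    n = np.minimum(protein_fec.n[ia], dna_fec.n[ib])
    return BinnedFEC(
        protein_fec.force_center[ia],
        mean,
        sd,
        n,
        protein_fec.bin_width,
        protein_fec.n_molecules,
        mean_force=F,
        meta={"n_disordered": n_disordered, "nanodisc_nm": nanodisc.length},
    )


def pool_molecules(fecs: Sequence[BinnedFEC]) -> BinnedFEC:
    """Pool binned FECs of several molecules into common force bins.

    Pooled mean and population SD are computed over all samples of all
    molecules (moment combination weighted by per-bin counts).
    """
    if len(fecs) == 0:
        raise ValueError("need at least one binned FEC")
    if len(fecs) == 1:
        out = replace(fecs[0])
        out.meta = dict(out.meta, sd_convention="population")
        return out
    centers = sorted({round(float(fc), 9) for fec in fecs for fc in fec.force_center})
    centers = np.asarray(centers)
    n_tot = np.zeros(centers.size)
    s1 = np.zeros(centers.size)
    s2 = np.zeros(centers.size)
    sF = np.zeros(centers.size)
    for fec in fecs:
        pos = np.searchsorted(centers, fec.force_center)
        n_tot[pos] += fec.n
        s1[pos] += fec.n * fec.mean_ext
        s2[pos] += fec.n * (fec.sd**2 + fec.mean_ext**2)
        sF[pos] += fec.n * fec.mean_force
    occupied = n_tot > 0
    mean = s1[occupied] / n_tot[occupied]
    var = np.maximum(s2[occupied] / n_tot[occupied] - mean**2, 0.0)
    return BinnedFEC(
        centers[occupied],
        mean,
        np.sqrt(var),
        n_tot[occupied].astype(int),
        fecs[0].bin_width,
        n_molecules=sum(f.n_molecules for f in fecs),
        mean_force=sF[occupied] / n_tot[occupied],
        meta={"sd_convention": "population"},
    )


# ---------------------------------------------------------------------------
# stiffness fit (Model/Results)


class LinearStiffnessModel:
    """Linear model F = k (x - x0) of the folded-branch structured extension.

    statsmodels-style: construct from a :class:`BinnedFEC`, call
    :meth:`fit`, read the :class:`StiffnessFit` results object.
    """

    def __init__(self, fec: BinnedFEC, force_range: tuple = (1.0, 7.0)):
        self.fec = fec
        self.force_range = tuple(force_range)

    def fit(self) -> StiffnessFit:
        sub = self.fec.restrict(*self.force_range)
        if len(sub) < 3:
            raise ValueError(
                f"need >=3 bins in force range {self.force_range}, got {len(sub)}"
            )
        # regress extension on force, x = x0 + F/k, weighted by the per-bin
        # standard error (low-force bins carry large handle-compliance spread)
        F, x = sub.mean_force, sub.mean_ext
        sem = sub.sd / np.sqrt(sub.n)
        w = np.where(sem > 1e-12, 1.0 / np.maximum(sem, 1e-12), 1.0)
        if not np.all(sem > 1e-12):
            w = np.ones_like(F)  # noiseless input: ordinary least squares
        A = (np.vstack([np.ones_like(F), F]) * w).T
        coef, res, *_ = np.linalg.lstsq(A, x * w, rcond=None)
        x0, slope = coef
        dof = len(sub) - 2
        rss = float(res[0]) if res.size else float(np.sum((x * w - A @ coef) ** 2))
        s2 = rss / dof if dof > 0 else np.nan
        cov = s2 * np.linalg.inv(A.T @ A)
        slope_sem = np.sqrt(cov[1, 1])
        x0_sem = np.sqrt(cov[0, 0])
        converged = slope > 0
        k = 1.0 / slope if converged else np.nan
        k_sem = slope_sem / slope**2 if converged else np.nan
        return StiffnessFit(
            k=k,
            x0=x0,
            k_sem=k_sem,
            x0_sem=x0_sem,
            force_range=self.force_range,
            n_molecules=sub.n_molecules,
            n_bins=len(sub),
            converged=converged,
        )


def fit_stiffness_linear(fec: BinnedFEC, force_range: tuple = (1.0, 7.0)) -> StiffnessFit:
    """Functional wrapper around :class:`LinearStiffnessModel`."""
    return LinearStiffnessModel(fec, force_range).fit()


# ---------------------------------------------------------------------------
# global FEC fit (Model/Results)


@dataclass
class GlobalFECResults:
    """Estimates from the simultaneous DNA-only / protein–DNA FEC fit."""

    params: dict
    stderr: dict
    contour_gains: list
    unfolded_residues: list
    redchi: float
    success: bool
    message: str
    lmfit_result: object = None

    def summary(self) -> str:
        lines = ["Global FEC fit", "--------------"]
        for name, val in self.params.items():
            err = self.stderr.get(name)
            err_s = f" +/- {err:.3g}" if err is not None and np.isfinite(err) else ""
            lines.append(f"{name:>12s} : {val:.6g}{err_s}")
        for j, (g, r) in enumerate(zip(self.contour_gains, self.unfolded_residues)):
            lines.append(f"branch {j}: contour gain {g:.2f} nm -> {r} residues")
        lines.append(f"reduced chi^2 : {self.redchi:.4g}")
        lines.append(f"success       : {self.success} ({self.message})")
        return "\n".join(lines)


class GlobalFECModel:
    """Simultaneous worm-like-chain fit of DNA-only and protein–DNA FECs.

    The DNA-only FEC constrains the handle persistence length; each
    protein–DNA branch adds the protein rod (x0, k), the fixed-length
    disordered tail, the rigid nanodisc and a free per-branch contour gain
    of unfolded polypeptide.  Free parameters: P_dna, P_chain, x0, k and
    one gain per branch (gains may be fixed at zero for the folded branch).
    """

    def __init__(
        self,
        dna_fec: BinnedFEC,
        branches: Sequence[BinnedFEC],
        dna_contour: float,
        n_disordered: float = 123,
        nanodisc: RigidOffset = RigidOffset(5.0),
        fit_gain: Sequence[bool] | None = None,
        gain_guess: float = 100.0,
        c: Constants = Constants(),
    ):
        self.dna_fec = dna_fec
        self.branches = list(branches)
        self.dna_contour = dna_contour
        self.n_disordered = n_disordered
        self.nanodisc = nanodisc
        self.fit_gain = list(fit_gain) if fit_gain is not None else [True] * len(branches)
        self.gain_guess = gain_guess
        self.c = c

    def _predict_dna(self, F: np.ndarray, P_dna: float) -> np.ndarray:
        chain = WormLikeChain(self.dna_contour, P_dna)
        return np.array([wlc_extension(f, chain, self.c) for f in F])

    def _predict_branch(
        self, F: np.ndarray, P_dna: float, P_chain: float, x0: float, k: float, gain: float
    ) -> np.ndarray:
        xd = self._predict_dna(F, P_dna)
        L_u = self.n_disordered * self.c.aa_rise + gain
        if L_u > 0:
            chain = WormLikeChain(L_u, P_chain)
            xu = np.array([wlc_extension(f, chain, self.c) for f in F])
        else:
            xu = np.zeros_like(F)
        return xd + x0 + F / k + xu + self.nanodisc.length

    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        out = []
        for fec, pred in [(self.dna_fec, None)] + [
            (b, j) for j, b in enumerate(self.branches)
        ]:
            F = fec.mean_force
            if pred is None:
                model = self._predict_dna(F, v["P_dna"])
            else:
                model = self._predict_branch(
                    F, v["P_dna"], v["P_chain"], v["x0"], v["k"], v[f"gain_{pred}"]
                )
            sem = fec.sd / np.sqrt(fec.n)
            sem = np.where(sem > 1e-12, sem, 1.0)
            out.append((fec.mean_ext - model) / sem)
        return np.concatenate(out)

    def fit(self, fix: Sequence[str] = (), **start) -> GlobalFECResults:
        """Fit; parameters named in ``fix`` are held at their start values."""
        params = lmfit.Parameters()
        params.add("P_dna", value=start.get("P_dna", 40.0), min=10.0, max=80.0)
        params.add("P_chain", value=start.get("P_chain", 0.6), min=0.3, max=1.5)
        params.add("x0", value=start.get("x0", 20.0), min=0.0, max=100.0)
        params.add("k", value=start.get("k", 1.0), min=1e-3, max=100.0)
        for name in fix:
            params[name].vary = False
        for j, free in enumerate(self.fit_gain):
            params.add(
                f"gain_{j}",
                value=start.get(f"gain_{j}", self.gain_guess if free else 0.0),
                min=0.0,
                max=2000.0,
                vary=free,
            )
        result = lmfit.minimize(self._residuals, params, method="leastsq")
        if not result.success:
            raise RuntimeError(
                "global FEC fit did not converge: "
                f"{result.message}; last residual norm "
                f"{np.linalg.norm(result.residual):.4g}"
            )
        vals = {n: float(p.value) for n, p in result.params.items()}
        errs = {
            n: (float(p.stderr) if p.stderr is not None else np.nan)
            for n, p in result.params.items()
        }
        gains = [vals[f"gain_{j}"] for j in range(len(self.branches))]
        residues = [int(round(g / self.c.aa_rise)) for g in gains]
        return GlobalFECResults(
            params=vals,
            stderr=errs,
            contour_gains=gains,
            unfolded_residues=residues,
            redchi=float(result.redchi),
            success=bool(result.success),
            message=str(result.message),
            lmfit_result=result,
        )


def fit_fec_global(
    dna_fec: BinnedFEC, tether_fec: BinnedFEC | Sequence[BinnedFEC], dna_contour: float,
    **kwargs,
) -> GlobalFECResults:
    """Functional wrapper around :class:`GlobalFECModel`."""
    branches = [tether_fec] if isinstance(tether_fec, BinnedFEC) else list(tether_fec)
    return GlobalFECModel(dna_fec, branches, dna_contour, **kwargs).fit()


# ---------------------------------------------------------------------------
# transitions


def detect_transitions(
    trace: ForceExtensionTrace,
    jump_threshold: float = 3.0,
    max_dwell: float = 0.02,
) -> list:
    """Detect abrupt extension jumps (rips) in a filtered trace.

    An event is a change of at least ``jump_threshold`` nm completing
    within ``max_dwell`` seconds while the trap moves negligibly.  The
    jump size is measured between medians of short flanking windows and
    the direction classified from its sign and the pulling phase:
    positive on pull = unfolding; negative on pull = insertion; negative
    on relax = refolding.
    """
    n = len(trace)
    g = max(int(round(max_dwell * trace.sampling_rate)), 1)
    if n < 8 * g + 2:
        return []
    x = trace.extension
    d = x[g:] - x[:-g]  # change over the dwell window, length n-g
    # candidate regions at half threshold (a boxcar-smeared jump spreads its
    # change over the filter width); the decisive jump size is re-measured
    # from medians of windows flanking the whole candidate run
    hot = np.abs(d) >= 0.5 * jump_threshold
    events: list[RipEvent] = []
    i = 0
    while i < d.size:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < d.size and hot[j + 1] and np.sign(d[j + 1]) == np.sign(d[i]):
            j += 1
        # run [i, j] in d-space covers samples [i, j + g] of the trace
        lo, hi = i, min(j + g + 1, n)
        pre = x[max(lo - 3 * g, 0) : lo]
        post = x[hi : hi + 3 * g]
        centre = (lo + hi) // 2
        if pre.size >= g and post.size >= g:
            jump = float(np.median(post) - np.median(pre))
            if abs(jump) >= jump_threshold:
                force = float(np.median(trace.force[max(lo - 3 * g, 0) : lo]))
                if jump > 0:
                    direction = "unfolding"
                else:
                    direction = "insertion" if trace.phase == "pull" else "refolding"
                events.append(
                    RipEvent(
                        time=float(trace.time[centre]),
                        force_at_rip=force,
                        extension_jump=jump,
                        direction=direction,
                        index=centre,
                    )
                )
        i = j + 1 + 3 * g  # skip past this event's support
    return events


def segment_at_events(
    trace: ForceExtensionTrace, events: Sequence[RipEvent], guard: float = 0.2
) -> list:
    """Split a trace into branches between detected events.

    ``guard`` seconds around each event are discarded on both sides so
    branch statistics are not contaminated by the jump itself.
    """
    gi = int(round(guard * trace.sampling_rate))
    cuts = [0]
    for ev in sorted(events, key=lambda e: e.time):
        cuts.append(max(ev.index - gi, cuts[-1]))
        cuts.append(min(ev.index + gi, len(trace)))
    cuts.append(len(trace))
    branches = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        if b - a > 2:
            branches.append(trace.slice(a, b))
    return branches


# ---------------------------------------------------------------------------
# state assignment and statistics


def _round_half_even(v: float) -> int:
    return int(round(v))  # Python 3 banker's rounding


def assign_states(
    contour_gains: Iterable[float],
    c: Constants = Constants(),
    residues_per_AR: int = RESIDUES_PER_AR,
    ar_tolerance: int = 2,
) -> list:
    """Map contour-length gains to unfolded residue / ankyrin-repeat counts.

    Canonical intermediate labels: I1 (~10 ARs), I2 (~20), I3 (29, fully
    unfolded ARD), matched within ``ar_tolerance`` repeats; zero gain is
    the folded state F_A.
    """
    out = []
    for gain in contour_gains:
        if gain < 0:
            raise ValueError(f"contour gain {gain} nm must be >= 0")
        residues = _round_half_even(gain / c.aa_rise)
        ars = _round_half_even(residues / residues_per_AR)
        if ars == 0:
            label = "F_A"
        elif abs(ars - 10) <= ar_tolerance:
            label = "I1"
        elif abs(ars - 20) <= ar_tolerance:
            label = "I2"
        elif abs(ars - 29) <= ar_tolerance:
            label = "I3"
        else:
            label = "custom"
        out.append(StateAssignment(float(gain), residues, ars, label))
    return out


def unfolding_force_stats(
    events_per_molecule: Sequence[Sequence[RipEvent]],
    which: str = "first",
    bin_width: float = 0.5,
) -> dict:
    """Mean/SD (sample convention) and histogram of unfolding rip forces.

    ``which='first'`` takes the first unfolding event of each molecule
    (the initial ARD rip); ``which='all'`` pools every unfolding event.
    """
    forces = []
    for events in events_per_molecule:
        unf = [e.force_at_rip for e in events if e.direction == "unfolding"]
        if which == "first":
            if not unf:
                raise ValueError("a molecule has no unfolding event (which='first')")
            forces.append(unf[0])
        elif which == "all":
            forces.extend(unf)
        else:
            raise ValueError("which must be 'first' or 'all'")
    if not forces:
        raise ValueError("no unfolding events supplied")
    forces = np.asarray(forces, dtype=float)
    mean = float(np.mean(forces))
    sd = float(np.std(forces, ddof=1)) if forces.size > 1 else np.nan
    lo = np.floor(forces.min() / bin_width) * bin_width
    hi = np.ceil(forces.max() / bin_width) * bin_width + 0.5 * bin_width
    counts, edges = np.histogram(forces, bins=np.arange(lo, hi + bin_width, bin_width))
    return {
        "mean": mean,
        "sd": sd,
        "n": int(forces.size),
        "sd_convention": "sample" if forces.size > 1 else "undefined",
        "histogram": {"edges": edges, "counts": counts},
        "forces": forces,
    }


def state_occurrence_profile(
    gains_per_molecule: Sequence[Sequence[float]],
    grid_width: float = 10.0,
    grid_max: float | None = None,
) -> dict:
    """Occurrence probability of visited contour gains over molecules.

    Each branch visit of each molecule contributes one count to a uniform
    contour-gain grid; the profile is normalized to unit total mass.
    """
    if len(gains_per_molecule) == 0:
        raise ValueError("need at least one analyzed FEC")
    gains = np.asarray(
        [g for mol in gains_per_molecule for g in mol], dtype=float
    )
    if gains.size == 0:
        raise ValueError("no branch contour gains supplied")
    if grid_max is None:
        grid_max = (np.floor(gains.max() / grid_width) + 1) * grid_width
    edges = np.arange(0.0, grid_max + 0.5 * grid_width, grid_width)
    counts, edges = np.histogram(gains, bins=edges)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"contour_gain": centers, "probability": prob, "n_visits": int(gains.size)}


def classify_refolding(
    first_pull: BinnedFEC,
    repull: BinnedFEC,
    criterion_range: tuple = (2.0, 6.0),
    tol: float = 2.0,
) -> str:
    """Classify a repull as 'refolded' or 'misfolded'.

    Refolded iff the RMS extension deviation from the first pull over the
    criterion force range is at most ``tol`` nm.
    """
    a = first_pull.restrict(*criterion_range)
    b = repull.restrict(*criterion_range)
    ia, ib = _shared_bins(a, b)
    if ia.size == 0:
        raise ValueError(f"no shared bins in criterion range {criterion_range}")
    rms = float(np.sqrt(np.mean((a.mean_ext[ia] - b.mean_ext[ib]) ** 2)))
    return "refolded" if rms <= tol else "misfolded"
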