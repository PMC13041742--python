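"""Differential FEC pipeline: filtering, binning, subtraction, fits, rips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gatingspring.fec import (
    BinnedFEC,
    ForceExtensionTrace,
    GlobalFECModel,
    assign_states,
    bin_by_force,
    boxcar_filter,
    classify_refolding,
    detect_transitions,
    differential_structured_extension,
    fit_stiffness_linear,
    pool_molecules,
    state_occurrence_profile,
    unfolding_force_stats,
    RipEvent,
)
from gatingspring.mechanics import (
    Constants,
    ElasticRod,
    RigidOffset,
    WormLikeChain,
    rod_extension,
    wlc_extension,
)

C = Constants()


def make_trace(force, extension, rate=1000.0, phase="pull"):
    n = len(force)
    return ForceExtensionTrace(
        np.arange(n) / rate, np.asarray(force), np.asarray(extension), phase=phase
    )


def model_bins(F, rod=None, n_res=0.0, disc=0.0, dna=None, sd=1.0, n=100):
    """BinnedFEC evaluated exactly on the mechanical model at forces F."""
    F = np.asarray(F, dtype=float)
    x = np.zeros_like(F)
    if dna is not None:
        x += np.array([wlc_extension(f, dna, C) for f in F])
    if rod is not None:
        x += rod.intrinsic_length + F / rod.stiffness
    if n_res > 0:
        chain = WormLikeChain.from_residues(n_res, 0.6, C)
        x += np.array([wlc_extension(f, chain, C) for f in F])
    x += disc
    return BinnedFEC(F, x, np.full_like(F, sd), np.full(F.size, n), float(F[1] - F[0]))


class TestBoxcar:
    def test_constant_trace_unchanged(self):
        tr = make_trace(np.full(1000, 5.0), np.full(1000, 100.0))
        out = boxcar_filter(tr, 0.05)
        assert np.allclose(out.force, 5.0)
        assert np.allclose(out.extension, 100.0)
        assert len(out) == len(tr) - 49

    def test_white_noise_variance_reduction(self, rng):
        sigma = 2.0
        tr = make_trace(np.full(20000, 5.0), rng.normal(0, sigma, 20000))
        m = 100
        out = boxcar_filter(tr, m / tr.sampling_rate)
        # decimate to independent windows before estimating the sd
        sub = out.extension[::m]
        assert np.std(sub) == pytest.approx(sigma / np.sqrt(m), rel=0.10)

    def test_impulse_response_is_plateau(self):
        ext = np.zeros(500)
        ext[250] = 7.0
        tr = make_trace(np.full(500, 5.0), ext)
        out = boxcar_filter(tr, 0.05)  # 50 samples
        assert out.extension.max() == pytest.approx(7.0 / 50, rel=1e-9)
        assert np.count_nonzero(out.extension > 1e-12) == 50

    def test_window_shorter_than_two_samples_rejected(self):
        tr = make_trace(np.full(100, 5.0), np.zeros(100))
        with pytest.raises(ValueError):
            boxcar_filter(tr, 0.001)


class TestBinning:
    def test_single_force_single_bin(self):
        tr = make_trace(np.full(50, 3.05), np.linspace(10, 12, 50))
        fec = bin_by_force(tr, 0.2, (0.5, 20.0))
        assert len(fec) == 1
        assert fec.mean_ext[0] == pytest.approx(11.0)
        assert fec.n[0] == 50

    def test_noiseless_rod_ramp_lies_on_line(self):
        F = np.linspace(0.6, 9.9, 4000)
        tr = make_trace(F, 20.0 + F / 0.7)
        fec = bin_by_force(tr, 0.2, (0.5, 10.0))
        assert np.allclose(fec.mean_ext, 20.0 + fec.mean_force / 0.7, atol=1e-9)

    def test_pooled_counts_add(self):
        F = np.linspace(1.0, 5.0, 1000)
        a = bin_by_force(make_trace(F, F * 2), 0.5, (0.5, 6.0))
        b = bin_by_force(make_trace(F, F * 2), 0.5, (0.5, 6.0))
        pooled = pool_molecules([a, b])
        assert np.array_equal(pooled.n, a.n + b.n)

    def test_empty_range_rejected(self):
        tr = make_trace(np.full(10, 3.0), np.zeros(10))
        with pytest.raises(ValueError):
            bin_by_force(tr, 0.2, (5.0, 5.0))


class TestDifferential:
    FORCES = np.arange(0.6, 7.01, 0.2)
    DNA = WormLikeChain(1527.8, 40.0)

    def test_recovers_rod_law_on_noiseless_pair(self):
        rod = ElasticRod(20.0, 0.7)
        protein = model_bins(self.FORCES, rod=rod, n_res=123, disc=5.0, dna=self.DNA)
        dna = model_bins(self.FORCES, dna=self.DNA)
        out = differential_structured_extension(
            protein, dna, 123, RigidOffset(5.0), 0.6, C
        )
        assert np.allclose(out.mean_ext, 20.0 + out.mean_force / 0.7, atol=1e-6)

    def test_plain_difference_without_corrections(self):
        a = model_bins(self.FORCES, rod=ElasticRod(10.0, 1.0))
        b = model_bins(self.FORCES, rod=ElasticRod(4.0, 1.0))
        out = differential_structured_extension(a, b, 0, RigidOffset(0.0), 0.6, C)
        assert np.allclose(out.mean_ext, 6.0, atol=1e-9)

    def test_identical_inputs_give_zero(self):
        a = model_bins(self.FORCES, dna=self.DNA)
        out = differential_structured_extension(a, a, 0, RigidOffset(0.0), 0.6, C)
        assert np.allclose(out.mean_ext, 0.0, atol=1e-9)

    def test_disjoint_bins_rejected(self):
        a = model_bins(np.array([1.0, 1.2]), rod=ElasticRod(10.0, 1.0))
        b = model_bins(np.array([5.0, 5.2]), rod=ElasticRod(10.0, 1.0))
        with pytest.raises(ValueError):
            differential_structured_extension(a, b, 0, RigidOffset(0.0), 0.6, C)

    def test_sd_propagates_in_quadrature(self):
        a = model_bins(self.FORCES, rod=ElasticRod(10.0, 1.0), sd=3.0)
        b = model_bins(self.FORCES, rod=ElasticRod(4.0, 1.0), sd=4.0)
        out = differential_structured_extension(a, b, 0, RigidOffset(0.0), 0.6, C)
        assert np.allclose(out.sd, 5.0)


class TestPooling:
    def test_single_input_unchanged(self):
        fec = model_bins(np.array([1.0, 1.2, 1.4]), rod=ElasticRod(10.0, 1.0))
        pooled = pool_molecules([fec])
        assert np.allclose(pooled.mean_ext, fec.mean_ext)

    def test_identical_molecules_have_zero_spread(self):
        F = np.array([1.0, 1.2, 1.4])
        a = model_bins(F, rod=ElasticRod(10.0, 1.0), sd=0.0)
        pooled = pool_molecules([a, a])
        assert np.allclose(pooled.sd, 0.0)
        assert pooled.n_molecules == 2

    def test_offset_molecules_pool_to_midpoint(self):
        F = np.array([1.0, 1.2, 1.4])
        base = model_bins(F, rod=ElasticRod(10.0, 1.0), sd=0.0)
        up = BinnedFEC(F, base.mean_ext + 3.0, base.sd, base.n, 0.2)
        down = BinnedFEC(F, base.mean_ext - 3.0, base.sd, base.n, 0.2)
        pooled = pool_molecules([up, down])
        assert np.allclose(pooled.mean_ext, base.mean_ext)
        # population convention: SD equals the half-spread d
        assert np.allclose(pooled.sd, 3.0)
        assert pooled.meta["sd_convention"] == "population"


class TestStiffnessFit:
    def test_exact_line_recovered(self):
        F = np.arange(1.1, 7.0, 0.2)
        fec = model_bins(F, rod=ElasticRod(20.0, 0.7), sd=0.0)
        fit = fit_stiffness_linear(fec, (1.0, 7.0))
        assert fit.k == pytest.approx(0.7, abs=1e-9)
        assert fit.x0 == pytest.approx(20.0, abs=1e-9)
        assert fit.converged

    def test_too_few_bins_rejected(self):
        fec = model_bins(np.array([2.0, 3.0]), rod=ElasticRod(20.0, 0.7))
        with pytest.raises(ValueError):
            fit_stiffness_linear(fec, (1.0, 7.0))

    def test_negative_slope_flagged_not_clamped(self):
        F = np.arange(1.1, 7.0, 0.5)
        fec = BinnedFEC(F, 30.0 - F, np.ones_like(F), np.full(F.size, 10), 0.5)
        fit = fit_stiffness_linear(fec, (1.0, 7.0))
        assert not fit.converged
        assert np.isnan(fit.k)


class TestGlobalFit:
    FORCES = np.arange(0.6, 15.01, 0.2)
    DNA = WormLikeChain(4520 * 0.338, 40.0)

    def _noiseless_inputs(self, gain=0.0):
        rod = ElasticRod(20.0, 0.7)
        dna = model_bins(self.FORCES, dna=self.DNA, sd=0.0)
        protein = model_bins(
            self.FORCES, rod=rod, n_res=123 + gain / C.aa_rise, disc=5.0, dna=self.DNA,
            sd=0.0,
        )
        return dna, protein

    def test_noiseless_self_consistency(self):
        dna, protein = self._noiseless_inputs()
        res = GlobalFECModel(dna, [protein], self.DNA.contour_length,
                             fit_gain=[False]).fit()
        assert res.params["P_dna"] == pytest.approx(40.0, rel=1e-6)
        assert res.params["P_chain"] == pytest.approx(0.6, rel=1e-6)
        assert res.params["x0"] == pytest.approx(20.0, rel=1e-6)
        assert res.params["k"] == pytest.approx(0.7, rel=1e-6)

    def test_branch_contour_gain_maps_to_residues(self):
        dna, protein = self._noiseless_inputs(gain=349.305)  # 957 residues
        res = GlobalFECModel(dna, [protein], self.DNA.contour_length,
                             gain_guess=300.0).fit()
        assert res.contour_gains[0] == pytest.approx(349.305, rel=1e-4)
        assert res.unfolded_residues[0] == 957

    def test_noisy_estimates_within_three_stderr(self):
        """Error calibration: truth inside 3 SE for >=95% of seeded fits."""
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            dna, protein = self._noiseless_inputs()
            noisy_dna = BinnedFEC(
                dna.force_center, dna.mean_ext + rng.normal(0, 2.0, len(dna)),
                np.full(len(dna), 2.0), np.ones(len(dna), dtype=int), 0.2,
            )
            noisy_prot = BinnedFEC(
                protein.force_center,
                protein.mean_ext + rng.normal(0, 2.0, len(protein)),
                np.full(len(protein), 2.0), np.ones(len(protein), dtype=int), 0.2,
            )
            res = GlobalFECModel(noisy_dna, [noisy_prot], self.DNA.contour_length,
                                 fit_gain=[False]).fit()
            truth = {"P_dna": 40.0, "P_chain": 0.6, "x0": 20.0, "k": 0.7}
            if all(
                abs(res.params[p] - v) <= 3 * res.stderr[p] for p, v in truth.items()
            ):
                ok += 1
        assert ok >= 95


class TestTransitionDetection:
    def _ramp_with_steps(self, steps, rate=1000.0, noise=0.15, seed=0):
        """Linear ramp with instantaneous extension steps at known times."""
        rng = np.random.default_rng(seed)
        n = 20000
        t = np.arange(n) / rate
        F = 1.0 + 0.4 * t
        x = 100.0 + 5.0 * t + rng.normal(0, noise, n)
        for at, size in steps:
            x[int(at * rate):] += size
        return make_trace(F, x, rate)

    def test_no_events_on_clean_ramp(self):
        tr = self._ramp_with_steps([], noise=0.0)
        assert detect_transitions(tr) == []

    def test_programmed_rips_recovered(self):
        steps = [(5.0, 8.0), (10.0, 12.0), (15.0, 20.0)]
        tr = self._ramp_with_steps(steps)
        events = detect_transitions(tr)
        assert len(events) == 3
        for ev, (at, size) in zip(events, steps):
            assert ev.direction == "unfolding"
            assert ev.extension_jump == pytest.approx(size, abs=1.0)
            assert ev.force_at_rip == pytest.approx(1.0 + 0.4 * at, abs=0.2)

    def test_extension_drop_is_insertion(self):
        tr = self._ramp_with_steps([(8.0, -10.0)])
        events = detect_transitions(tr)
        assert len(events) == 1
        assert events[0].direction == "insertion"
        assert events[0].extension_jump == pytest.approx(-10.0, abs=1.0)

    def test_drop_during_relaxation_is_refolding(self):
        tr = self._ramp_with_steps([(8.0, -10.0)])
        tr.phase = "relax"
        events = detect_transitions(tr)
        assert events[0].direction == "refolding"

    def test_no_false_positives_on_noise(self):
        for seed in range(100):
            tr = self._ramp_with_steps([], noise=0.2, seed=seed)
            assert detect_transitions(tr) == []

    def test_full_recall_at_twice_threshold(self):
        for seed in range(20):
            tr = self._ramp_with_steps([(9.0, 6.0)], seed=seed)
            events = detect_transitions(tr, jump_threshold=3.0)
            assert len(events) == 1


class TestStateAssignment:
    @pytest.mark.parametrize(
        "gain, residues, ars, label",
        [
            (349.3, 957, 29, "I3"),
            (120.5, 330, 10, "I1"),
            (241.0, 660, 20, "I2"),
            (0.0, 0, 0, "F_A"),
        ],
    )
    def test_canonical_assignments(self, gain, residues, ars, label):
        (a,) = assign_states([gain])
        assert (a.unfolded_residues, a.unfolded_ARs, a.state_label) == (
            residues,
            ars,
            label,
        )

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            assign_states([-1.0])

    @given(st.integers(0, 1200))
    def test_roundtrip_on_integer_residues(self, residues):
        gain = residues * C.aa_rise
        (a,) = assign_states([gain])
        assert a.unfolded_residues == residues


class TestRuptureStats:
    @staticmethod
    def _events(forces):
        return [
            [RipEvent(time=0.0, force_at_rip=f, extension_jump=10.0,
                      direction="unfolding")]
            for f in forces
        ]

    def test_mean_and_sample_sd(self):
        out = unfolding_force_stats(self._events([5.0, 7.0, 9.0]))
        assert out["mean"] == pytest.approx(7.0)
        assert out["sd"] == pytest.approx(2.0)
        assert out["sd_convention"] == "sample"

    def test_single_event_sd_flagged(self):
        out = unfolding_force_stats(self._events([6.5]))
        assert out["mean"] == pytest.approx(6.5)
        assert np.isnan(out["sd"])
        assert out["sd_convention"] == "undefined"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            unfolding_force_stats([])


class TestOccurrenceProfile:
    def test_single_state_is_delta(self):
        out = state_occurrence_profile([[349.3]] * 5, grid_width=10.0)
        assert out["probability"].sum() == pytest.approx(1.0)
        assert np.count_nonzero(out["probability"]) == 1

    def test_three_programmed_states_give_three_peaks(self):
        gains = [[120.5, 241.0, 349.3] for _ in range(10)]
        out = state_occurrence_profile(gains, grid_width=10.0)
        peaks = np.nonzero(out["probability"] > 0)[0]
        assert peaks.size == 3
        centers = out["contour_gain"][peaks]
        assert np.allclose(sorted(centers), [125.0, 245.0, 345.0], atol=5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            state_occurrence_profile([])


class TestRefoldingClassifier:
    F = np.arange(1.1, 7.0, 0.2)

    def test_identical_repull_is_refolded(self):
        fec = model_bins(self.F, rod=ElasticRod(20.0, 0.7))
        assert classify_refolding(fec, fec) == "refolded"

    def test_shifted_repull_is_misfolded(self):
        fec = model_bins(self.F, rod=ElasticRod(20.0, 0.7))
        shifted = BinnedFEC(self.F, fec.mean_ext + 20.0, fec.sd, fec.n, 0.2)
        assert classify_refolding(fec, shifted) == "misfolded"

    def test_no_overlap_rejected(self):
        fec = model_bins(np.array([1.0, 1.2, 1.4]), rod=ElasticRod(20.0, 0.7))
        high = model_bins(np.array([10.0, 10.2]), rod=ElasticRod(20.0, 0.7))
        with pytest.raises(ValueError):
            classify_refolding(fec, high, criterion_range=(2.0, 6.0))
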