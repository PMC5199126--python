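"""Deterministic batch-competition model: growth, cycle ends, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batchevol.deterministic import (
    BatchProtocol,
    GrowthLaw,
    analytic_selection_coefficient,
    cycle_end_time,
    doubling_time_term,
    lag_term,
    regress_selection_coefficient,
    run_deterministic_competition,
    subpopulation_size,
)

from conftest import ASK10, FPS1, WT


class TestSubpopulationSize:
    @pytest.mark.parametrize(
        "law, t, expected",
        [
            (GrowthLaw(804.8, 162.3, 1e5), 804.8, 1e5),  # end of lag
            (GrowthLaw(276.6, 130.2, 1.0), 276.6 + 5 * 130.2, 32.0),  # 5 doublings
            (GrowthLaw(100.0, 60.0, 777.0), 0.0, 777.0),  # identity at start
        ],
    )
    def test_growth_law(self, law, t, expected):
        assert subpopulation_size(law, t) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_lag(self):
        law = GrowthLaw(500.0, 120.0, 1e4)
        eps = 1e-9
        assert subpopulation_size(law, 500.0 + eps) == pytest.approx(1e4, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            subpopulation_size(GrowthLaw(10, 10, 1), -1.0)

    def test_invalid_laws_rejected(self):
        with pytest.raises(ValueError):
            GrowthLaw(-1.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            GrowthLaw(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            GrowthLaw(0.0, 100.0, -5.0)


class TestCycleEndTime:
    def test_single_law_closed_form(self):
        proto = BatchProtocol(100_000, 5)
        law = GrowthLaw(804.8, 162.3, 100_000)
        assert cycle_end_time([law], proto) == pytest.approx(
            804.8 + 5 * 162.3, abs=1e-6
        )

    def test_identical_laws_match_single(self):
        proto = BatchProtocol(100_000, 5)
        pair = [GrowthLaw(804.8, 162.3, 60_000), GrowthLaw(804.8, 162.3, 40_000)]
        single = [GrowthLaw(804.8, 162.3, 100_000)]
        assert cycle_end_time(pair, proto) == pytest.approx(
            cycle_end_time(single, proto), abs=1e-6
        )

    def test_fast_minority_advances_cycle_end(self):
        """A faster mutant shortens the cycle vs the WT-only closed form;
        cross-checked against a naive bisection oracle."""
        proto = BatchProtocol(100_000, 5)
        laws = [
            GrowthLaw(WT["lag"], WT["doubling"], 99_999),
            GrowthLaw(FPS1["lag"], FPS1["doubling"], 1),
        ]
        t_end = cycle_end_time(laws, proto)
        wt_only = WT["lag"] + 5 * WT["doubling"]
        assert t_end < wt_only

        def total(t):
            return sum(subpopulation_size(law, t) for law in laws)

        lo, hi = 0.0, 5000.0
        for _ in range(80):  # bisection oracle on the monotone total
            mid = (lo + hi) / 2
            if total(mid) < 2**5 * 100_000:
                lo = mid
            else:
                hi = mid
        assert t_end == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            cycle_end_time([GrowthLaw(1, 1, 0.0)], BatchProtocol(10, 2))


class TestCompetitionTrajectory:
    def test_neutral_ratio_conserved(self, protocol):
        wt = GrowthLaw(WT["lag"], WT["doubling"], 99_999)
        mut = GrowthLaw(WT["lag"], WT["doubling"], 1)
        traj = run_deterministic_competition(wt, mut, protocol)
        assert np.allclose(traj.ratios, traj.ratios[0], rtol=1e-9)

    def test_disadvantaged_mutant_declines(self, protocol):
        wt = GrowthLaw(WT["lag"], WT["doubling"], 99_999)
        mut = GrowthLaw(WT["lag"] + 120, WT["doubling"] + 20, 1)
        traj = run_deterministic_competition(wt, mut, protocol)
        assert np.all(np.diff(traj.ratios) < 0)

    def test_frequencies_follow_ratios(self, protocol, wt_law, fps1_law):
        traj = run_deterministic_competition(wt_law, fps1_law, protocol)
        np.testing.assert_allclose(
            traj.frequencies, traj.ratios / (1 + traj.ratios), rtol=1e-9
        )
        assert np.all(np.diff(traj.generations) == protocol.doublings_per_cycle)

    def test_fps1_fixes_by_generation_25(self, protocol, wt_law, fps1_law):
        traj = run_deterministic_competition(wt_law, fps1_law, protocol)
        assert traj.fixation_generation(0.99) == 25.0

    def test_initial_counts_must_match_bottleneck(self, protocol, wt_law):
        with pytest.raises(ValueError):
            run_deterministic_competition(wt_law, GrowthLaw(300, 130, 2), protocol)

    def test_export_round_trip(self, protocol, wt_law, fps1_law, tmp_path):
        import pandas as pd

        traj = run_deterministic_competition(wt_law, fps1_law, protocol)
        path = tmp_path / "traj.tsv"
        traj.write(path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == [
            "cycle", "t_end_min", "generations", "ln_ratio", "mutant_frequency",
        ]
        assert len(frame) == protocol.n_cycles + 1
        np.testing.assert_allclose(
            frame["mutant_frequency"].to_numpy(), traj.frequencies, rtol=1e-6
        )


class TestAnalyticSelectionCoefficient:
    def test_identical_genotypes_neutral(self):
        assert analytic_selection_coefficient(500, 150, 500, 150, 5) == 0.0

    def test_doubling_only_value(self):
        # hand evaluation of ln2 * (162.3/130.2 - 1)
        s = analytic_selection_coefficient(804.8, 162.3, 804.8, 130.2, 5)
        assert s == pytest.approx(0.1709, abs=2e-4)

    def test_full_fps1_value(self):
        s = analytic_selection_coefficient(804.8, 162.3, 276.6, 130.2, 5)
        assert s == pytest.approx(0.7333, abs=2e-4)

    @given(
        lam1=st.floats(0, 1000),
        dlam=st.floats(0, 500),
        tau1=st.floats(50, 400),
        tau2=st.floats(50, 400),
        m=st.integers(1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_terms_exactly_additive(self, lam1, dlam, tau1, tau2, m):
        lam2 = lam1 - dlam if lam1 >= dlam else 0.0
        full = analytic_selection_coefficient(lam1, tau1, lam2, tau2, m)
        parts = doubling_time_term(tau1, tau2) + lag_term(lam1, lam2, tau2, m)
        assert full == parts  # identical floating-point expression

    def test_lag_term_decays_with_m_and_tau(self):
        base = lag_term(804.8, 276.6, 130.2, 5)
        assert lag_term(804.8, 276.6, 130.2, 6) < base
        assert lag_term(804.8, 276.6, 140.0, 5) < base

    def test_longer_mutant_lag_warns(self):
        with pytest.warns(UserWarning):
            analytic_selection_coefficient(300, 150, 400, 150, 5)

    def test_first_cycle_increment_matches_analytic(self, protocol, wt_law, fps1_law):
        """While the mutant is rare the WT sets the cycle end, so the
        per-generation ln-ratio increment equals the closed form."""
        traj = run_deterministic_competition(wt_law, fps1_law, protocol)
        lnr = np.log(traj.ratios)
        increment = (lnr[1] - lnr[0]) / protocol.doublings_per_cycle
        s_analytic = analytic_selection_coefficient(
            WT["lag"], WT["doubling"], FPS1["lag"], FPS1["doubling"], 5
        )
        assert increment == pytest.approx(s_analytic, abs=1e-3)


class TestRegressedSelectionCoefficient:
    def test_exact_linear_recovery(self):
        from batchevol.deterministic import CompetitionTrajectory

        gens = 5.0 * np.arange(11)
        traj = CompetitionTrajectory(
            cycle_end_times=np.arange(1, 11, dtype=float),
            ratios=np.exp(0.5 * gens - 10.0),
            generations=gens,
            frequencies=np.zeros(11),
            wt_counts=np.full(11, 1e4),
            mutant_counts=np.zeros(11),
        )
        assert regress_selection_coefficient(traj) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "mutant, expected",
        [(FPS1, 0.64), (ASK10, 0.41), ({"lag": 630.4, "doubling": 122.8}, 0.36)],
        ids=["FPS1", "ASK10", "ACR3"],
    )
    def test_empirical_selection_coefficients(self, protocol, wt_law, mutant, expected):
        traj = run_deterministic_competition(
            wt_law, GrowthLaw(mutant["lag"], mutant["doubling"], 1), protocol
        )
        s = regress_selection_coefficient(traj)
        assert s == pytest.approx(expected, abs=0.02)
        assert traj.selection_coefficient == s

    def test_too_few_points_rejected(self):
        from batchevol.deterministic import CompetitionTrajectory

        traj = CompetitionTrajectory(
            cycle_end_times=np.array([1.0]),
            ratios=np.array([1.0, 2.0]),
            generations=np.array([0.0, 5.0]),
            frequencies=np.zeros(2),
            wt_counts=np.full(2, 10.0),
            mutant_counts=np.zeros(2),
        )
        with pytest.raises(ValueError):
            regress_selection_coefficient(traj)
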