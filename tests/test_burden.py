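import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoburden.binding import BindingCall
from neoburden.burden import (
    BurdenParams,
    SampleBurden,
    burdens_to_frame,
    count_binders,
    count_predicted_neoantigens,
    expected_authentic,
    min_neoantigens_for_likelihood,
    percent_likelihood,
    prob_at_least_one,
    scale_loci,
    summarize_cohort,
)
from neoburden.errors import CoverageError, ParameterError
from neoburden.peptidome import PeptideWindow


class TestExpectedAuthentic:
    @pytest.mark.parametrize(
        "N, expected", [(6, 0.48), (27, 2.16), (0, 0.0)]
    )
    def test_median_burden_estimates(self, N, expected):
        assert expected_authentic(N, 0.08) == pytest.approx(expected, abs=1e-12)

    def test_linear_in_N(self):
        a = 0.08
        assert expected_authentic(6 + 27, a) == pytest.approx(
            expected_authentic(6, a) + expected_authentic(27, a)
        )

    def test_rate_domain(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                expected_authentic(5, bad)


class TestProbAtLeastOne:
    def test_median_burden_percentages(self):
        assert percent_likelihood(prob_at_least_one(6, 0.08)) == 39
        assert percent_likelihood(prob_at_least_one(27, 0.08)) == 89

    def test_zero_count_gives_zero(self):
        for a in (0.01, 0.08, 0.99):
            assert prob_at_least_one(0, a) == 0.0

    def test_matches_exponential_form(self):
        for N in (0.5, 3, 18.0, 100):
            assert prob_at_least_one(N, 0.08) == pytest.approx(
                1 - math.exp(N * math.log1p(-0.08)), abs=1e-14
            )

    def test_accepts_fractional_scaled_counts(self):
        assert 0 < prob_at_least_one(7.5, 0.08) < 1

    @given(
        st.floats(0.0, 200.0), st.floats(0.0, 200.0), st.floats(0.01, 0.5)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_increasing_in_N(self, n1, n2, a):
        lo, hi = sorted((n1, n2))
        p_lo, p_hi = prob_at_least_one(lo, a), prob_at_least_one(hi, a)
        assert p_hi >= p_lo
        # strict until floating point saturates at either end
        if hi - lo > 1e-6 and p_lo < 1.0:
            assert p_hi > p_lo

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            prob_at_least_one(-1, 0.08)


class TestRounding:
    @pytest.mark.parametrize(
        "p, pct", [(0.3936, 39), (0.8948, 89), (0.895, 90), (0.005, 1), (0.0, 0)]
    )
    def test_half_up(self, p, pct):
        assert percent_likelihood(p) == pct


class TestThreshold:
    def test_matches_brute_force_over_grid(self):
        for a in (0.02, 0.08, 0.2, 0.5):
            for cutoff in (0.5, 0.9, 0.95):
                brute = next(
                    n for n in range(0, 1000)
                    if prob_at_least_one(n, a) >= cutoff
                )
                assert min_neoantigens_for_likelihood(a, cutoff) == brute

    def test_default_parameters(self):
        assert min_neoantigens_for_likelihood() == 28


class TestScaleLoci:
    @pytest.mark.parametrize(
        "args, expected", [((9, 1, 3), 27.0), ((9, 3, 3), 9.0), ((5, 2, 3), 7.5)]
    )
    def test_extrapolation(self, args, expected):
        assert scale_loci(*args) == expected

    def test_domain(self):
        with pytest.raises(ParameterError):
            scale_loci(9, 0, 3)
        with pytest.raises(ParameterError):
            scale_loci(9, 4, 3)
        with pytest.raises(ParameterError):
            scale_loci(-1, 1, 3)


class TestCounting:
    def test_definitional_modes(self):
        windows = [
            [PeptideWindow(f"PEP{i:02d}AAA", i + 1, 8) for i in range(38)]
        ]
        calls = {
            (w.sequence, "HLA-A*02:01"): 5000.0 for w in windows[0]
        }
        calls[(windows[0][3].sequence, "HLA-A*02:01")] = 50.0
        calls[(windows[0][9].sequence, "HLA-A*02:01")] = 80.0
        counts = count_binders(windows, calls, ["HLA-A*02:01"], 100.0)
        assert counts.per_peptide == 2
        assert counts.per_mutation == 1

    def test_no_binders(self):
        windows = [[PeptideWindow("AAAAAAAA", 1, 8)]]
        calls = {("AAAAAAAA", "X"): 200.0}
        counts = count_binders(windows, calls, ["X"], 100.0)
        assert counts == type(counts)(0, 0)

    def test_planted_fixture_counts_both_modes(self):
        # 10 mutations; binders planted in 3 of them, one carrying 4
        # sub-threshold windows (4 + 1 + 1 = 6 binder peptides).
        rng = np.random.default_rng(0)
        windows, calls = [], {}
        planted = {0: 4, 5: 1, 9: 1}
        for m in range(10):
            ws = []
            for i in range(6):
                seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9))
                ws.append(PeptideWindow(seq, i + 1, 9))
                calls[(seq, "A1")] = 30.0 if i < planted.get(m, 0) else 900.0
            windows.append(ws)
        counts = count_binders(windows, calls, ["A1"], 100.0)
        # brute-force recount straight from the call table
        brute_peptides = {
            w.sequence
            for ws in windows
            for w in ws
            if calls[(w.sequence, "A1")] < 100.0
        }
        assert counts.per_peptide == len(brute_peptides) == 6
        assert counts.per_mutation == 3
        assert counts.per_peptide >= counts.per_mutation

    def test_min_over_alleles(self):
        windows = [[PeptideWindow("AAAAAAAA", 1, 8)]]
        calls = {("AAAAAAAA", "X"): 200.0, ("AAAAAAAA", "Y"): 50.0}
        assert count_binders(windows, calls, ["X", "Y"], 100.0).per_peptide == 1

    def test_coverage_gap_raises(self):
        windows = [[PeptideWindow("AAAAAAAA", 1, 8)]]
        with pytest.raises(CoverageError):
            count_binders(windows, {}, ["X"], 100.0)

    def test_count_predicted_neoantigens_dispatches_on_mode(self):
        windows = [[PeptideWindow("AAAAAAAA", 1, 8), PeptideWindow("CCCCCCCC", 2, 8)]]
        calls = {("AAAAAAAA", "X"): 10.0, ("CCCCCCCC", "X"): 20.0}
        muts = [object()]
        per_pep = count_predicted_neoantigens(
            muts, windows, calls, ["X"], BurdenParams(counting_mode="per_peptide")
        )
        per_mut = count_predicted_neoantigens(
            muts, windows, calls, ["X"], BurdenParams(counting_mode="per_mutation")
        )
        assert (per_pep, per_mut) == (2, 1)


def _burden(sample_id, N, n_total=40, a=0.08):
    raw = int(N // 3)
    return SampleBurden(
        sample_id=sample_id,
        n_total=n_total,
        n_transcribed=n_total // 2,
        n_predicted_raw=raw,
        N=N,
        E=a * N,
        P=prob_at_least_one(N, a),
    )


class TestCohortSummary:
    def test_three_sample_example(self):
        burdens = [_burden("a", 0), _burden("b", 6), _burden("c", 27)]
        summary = summarize_cohort(burdens)
        assert summary.median_N == 6
        # N = 27 gives P = 0.8948 < 0.90 (the threshold N is 28), so no
        # sample reaches the cutoff.
        assert summary.frac_above_cutoff == 0.0

    def test_single_sample(self):
        summary = summarize_cohort([_burden("solo", 90)])
        assert summary.median_N == 90
        assert summary.frac_above_cutoff == 1.0

    def test_even_cohort_median_is_midpoint(self):
        burdens = [_burden(s, N) for s, N in zip("abcd", (0, 6, 12, 27))]
        assert summarize_cohort(burdens).median_N == 9.0

    def test_rank_order_descending_with_id_ties(self):
        burdens = [
            _burden("b", 6, n_total=40),
            _burden("a", 0, n_total=40),
            _burden("c", 27, n_total=99),
        ]
        summary = summarize_cohort(burdens)
        assert [b.sample_id for b in summary.samples] == ["c", "a", "b"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            summarize_cohort([])

    def test_two_route_frac_agreement(self):
        # counting P >= cutoff must equal counting N >= N* exactly
        rng = np.random.default_rng(12)
        n_star = min_neoantigens_for_likelihood(0.08, 0.90)
        for _ in range(50):
            Ns = rng.integers(0, 60, size=rng.integers(1, 40))
            burdens = [_burden(f"s{i}", int(N) * 3) for i, N in enumerate(Ns)]
            summary = summarize_cohort(burdens)
            frac_by_threshold = np.mean([b.N >= n_star for b in burdens])
            assert summary.frac_above_cutoff == frac_by_threshold

    def test_table_reports_rounded_percentages(self):
        frame = burdens_to_frame([_burden("hgsc", 6), _burden("lung", 27)])
        assert list(frame["P_pct"]) == [39, 89]


class TestBurdenParams:
    def test_domain_checks(self):
        with pytest.raises(ParameterError):
            BurdenParams(authenticity_rate=0.0)
        with pytest.raises(ParameterError):
            BurdenParams(threshold_nM=0.0)
        with pytest.raises(ParameterError):
            BurdenParams(counting_mode="per_sample")
        with pytest.raises(ParameterError):
            BurdenParams(likelihood_cutoff=1.0)
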