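"""Transition-matrix assembly, normalization, mass weighting, modulation."""

import io
import math

import numpy as np
import pytest
from scipy import stats

from cellhydro import (
    ArrheniusSign,
    DomainError,
    NormalizationError,
    ProcessConditions,
    apply_modulation,
    breaking_probability,
    build_matrix,
    diag_from_column,
    frequencies_from_matrix,
    load_printed_n10_matrix,
    mass_weight,
    modulation,
    raw_breaking_sum,
    scale_breaking,
)
from cellhydro.ladder import MassClassLadder, TerminalScheme
from cellhydro.transition import (
    ModulationFactors,
    TransitionFrequencies,
    matrix_from_csv,
    matrix_to_csv,
)


def oracle_entry(N, j, i, distribution, convention):
    """Independent branch-logic evaluation of one matrix entry.

    Re-derives the construction rules directly with scipy densities, no
    shared code with the implementation.
    """
    if i == j == N:
        return 1.0
    if j < i or (j == i == 0):
        # strict corner handled separately by the caller
        return 0.0 if j < i else None
    x = i if convention == "source_class" else j - i
    k = N + 1 - x
    mu, var = k / 2, (k * k - 1) / 12
    if distribution == "gauss":
        def f(d):
            if var == 0:
                return 1.0 if d == mu else 0.0
            return stats.norm.pdf(d, loc=mu, scale=math.sqrt(var))
    else:
        lam, beta = 1.4 + mu / N, 0.95 + var / N
        def f(d):
            return stats.weibull_min.pdf(d, beta, scale=lam)
    if j > i:
        return float(f(j - i))
    # diagonal 0 < i < N: 1 - sum of the column's off-diagonals
    total = 0.0
    for jj in range(i + 1, N + 1):
        xx = i if convention == "source_class" else jj - i
        kk = N + 1 - xx
        mm, vv = kk / 2, (kk * kk - 1) / 12
        if distribution == "gauss":
            total += float(stats.norm.pdf(jj - i, loc=mm, scale=math.sqrt(vv)))
        else:
            total += float(
                stats.weibull_min.pdf(jj - i, 0.95 + vv / N, scale=1.4 + mm / N)
            )
    return 1.0 - total


class TestBuildMatrix:
    @pytest.mark.parametrize("dist", ["gauss", "weibull"])
    def test_absorbing_terminal_class(self, dist):
        P = build_matrix(10, dist)
        np.testing.assert_array_equal(P.P[:, 10], np.eye(11)[10])

    def test_strict_gauss_corner(self):
        P = build_matrix(10, "gauss", normalization_mode="strict_paper")
        assert P.P[0, 0] == pytest.approx(1 / 11)
        assert P.column0_defect != 0.0

    def test_strict_weibull_corner(self):
        P = build_matrix(10, "weibull", normalization_mode="strict_paper")
        assert P.P[0, 0] == pytest.approx(3.5 / 11)

    @pytest.mark.parametrize("dist", ["gauss", "weibull"])
    @pytest.mark.parametrize("conv", ["source_class", "jump_distance"])
    @pytest.mark.parametrize("N", [2, 3, 5, 10, 17])
    def test_structure_and_normalization(self, N, dist, conv):
        """Lower-triangular, entries in [0,1], stochastic columns."""
        P = build_matrix(N, dist, conv).P
        assert np.all(np.triu(P, k=1) == 0.0)
        assert np.all(P >= 0) and np.all(P <= 1)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("dist", ["gauss", "weibull"])
    @pytest.mark.parametrize("conv", ["source_class", "jump_distance"])
    @pytest.mark.parametrize("N", [2, 3, 4, 5, 6])
    def test_entries_match_independent_oracle(self, N, dist, conv):
        P = build_matrix(N, dist, conv).P
        for i in range(N + 1):
            for j in range(N + 1):
                expected = oracle_entry(N, j, i, dist, conv)
                if expected is None:  # conservative (0,0): 1 - column sum
                    expected = 1.0 - P[1:, 0].sum()
                assert P[j, i] == pytest.approx(expected, abs=1e-13)

    def test_weibull_large_n_column_overflow_is_an_error(self):
        """Sharply peaked Weibull shapes at large N put the raw density sum
        above 1, which is rejected with the offending column named."""
        with pytest.raises(NormalizationError, match="column 0"):
            build_matrix(100, "weibull")
        assert raw_breaking_sum(100, "weibull") > 1

    def test_breaking_scale_restores_normalizability(self):
        s = 0.5 / raw_breaking_sum(100, "weibull")
        P = build_matrix(100, "weibull", breaking_scale=s)
        np.testing.assert_allclose(P.P.sum(axis=0), 1.0, atol=1e-12)
        assert breaking_probability(P, 0) == pytest.approx(0.5)

    def test_hmf_channel_row_structure(self):
        """Chains feed glucose only; the single HMF entry sits at (N, N-1)."""
        P = build_matrix(10, "gauss", hmf_channel=True)
        assert np.all(P.P[10, :9] == 0.0)
        assert P.P[10, 9] > 0.0
        np.testing.assert_allclose(P.P.sum(axis=0), 1.0, atol=1e-12)

    def test_invalid_n(self):
        with pytest.raises(DomainError):
            build_matrix(0)


class TestDiagAndBreaking:
    def test_printed_matrix_diagonals_consistent(self):
        """Re-deriving the printed diagonals from the printed off-diagonal
        columns reproduces them within transcription rounding."""
        P = load_printed_n10_matrix()
        col1 = P[2:, 1]
        assert diag_from_column(col1) == pytest.approx(0.353, abs=5e-4)
        assert abs(diag_from_column(col1) - P[1, 1]) <= 0.002
        col4 = P[5:, 4]
        assert diag_from_column(col4) == pytest.approx(0.358, abs=5e-4)
        assert abs(diag_from_column(col4) - P[4, 4]) <= 0.002

    def test_empty_column_survives(self):
        assert diag_from_column([]) == 1.0

    def test_oversum_rejected(self):
        with pytest.raises(NormalizationError):
            diag_from_column([0.7, 0.4])

    def test_breaking_probability_complements_diagonal(self, gauss10):
        for i in range(11):
            assert breaking_probability(gauss10, i) == pytest.approx(
                1.0 - gauss10.P[i, i], abs=1e-12
            )

    def test_absorbing_class_never_breaks(self, gauss10):
        assert breaking_probability(gauss10, 10) == 0.0


class TestFrequencies:
    def test_offdiagonal_rate_conversion(self, gauss10):
        freq = frequencies_from_matrix(gauss10)
        off = np.tril(np.ones((11, 11), dtype=bool), k=-1)
        np.testing.assert_allclose(
            freq.alpha[off] * 100.0, gauss10.P[off], atol=1e-15
        )
        assert np.all(np.diag(freq.alpha) == 0.0)

    def test_example_value(self):
        # P = 0.036 over 100 s -> 3.6e-4 1/s
        assert 0.036 / 100.0 == pytest.approx(3.6e-4)

    def test_bad_dt(self, gauss10):
        with pytest.raises(DomainError):
            frequencies_from_matrix(gauss10, dt=0.0)


class TestMassWeight:
    def _toy(self, masses, alpha_col0, dt):
        N = len(masses) - 1
        alpha = np.zeros((N + 1, N + 1))
        alpha[1:, 0] = alpha_col0
        lad = MassClassLadder(
            n_units=N,
            masses=tuple(masses),
            labels=tuple(str(m) for m in masses),
            terminal_scheme=TerminalScheme.GLUCOSE_TERMINAL,
        )
        return TransitionFrequencies(alpha=alpha, N=N, dt=dt), lad

    def test_worked_three_class_example(self):
        """M = (3,2,1), unit rates, p0 = 0.2: off-diagonals split 2:1."""
        freq, lad = self._toy([3, 2, 1], [1.0, 1.0], dt=0.1)
        Pm = mass_weight(freq, lad)
        assert Pm.P[1, 0] == pytest.approx(0.2 * 2 / 3)
        assert Pm.P[2, 0] == pytest.approx(0.2 * 1 / 3)
        assert Pm.P[0, 0] == pytest.approx(0.8)

    def test_uniform_masses_change_nothing(self, gauss10):
        """With equal destination masses the weights cancel."""
        flat = MassClassLadder(
            n_units=10,
            masses=tuple([500] * 11),
            labels=tuple("c" for _ in range(11)),
            terminal_scheme=TerminalScheme.GLUCOSE_TERMINAL,
        )
        Pm = mass_weight(frequencies_from_matrix(gauss10), flat)
        np.testing.assert_allclose(Pm.P, gauss10.P, atol=1e-14)

    def test_column_sums_preserved(self, gauss10, ladder10):
        Pm = mass_weight(frequencies_from_matrix(gauss10), ladder10)
        np.testing.assert_allclose(Pm.P.sum(axis=0), 1.0, atol=1e-12)
        for i in range(11):
            assert breaking_probability(Pm, i) == pytest.approx(
                breaking_probability(gauss10, i), abs=1e-12
            )

    def test_mass_weighting_favors_heavy_destinations(self, gauss10, ladder10):
        Pm = mass_weight(frequencies_from_matrix(gauss10), ladder10)
        # relative to the unweighted column, the heaviest destination gains
        col, colm = gauss10.P[1:, 0], Pm.P[1:, 0]
        assert colm[0] / col[0] > colm[-1] / col[-1]


class TestModulation:
    def test_identity_at_reference(self):
        cond = ProcessConditions(T=453, T_ref=453, c_a=1, c_a_ref=1, E_Am=1.7e5)
        f = modulation(cond)
        assert f.g == 1.0 and f.h_bulk == 1.0 and f.h_G == 1.0

    def test_acid_factor(self):
        cond = ProcessConditions(T=453, T_ref=453, c_a=4, c_a_ref=1, acid_order=1)
        assert modulation(cond).g == pytest.approx(4.0)

    def test_printed_sign_slows_with_heat(self):
        """The as-printed exponent decreases rates at T > T_ref (an
        anti-Arrhenius artefact of the printed formula); the physical
        switch restores the usual behaviour."""
        kw = dict(T=483, T_ref=453, c_a=1, c_a_ref=1, E_Am=1.7e5, E_AG=1.3e5)
        printed = modulation(ProcessConditions(**kw))
        assert printed.h_bulk < 1.0
        physical = modulation(
            ProcessConditions(**kw, arrhenius_sign=ArrheniusSign.PHYSICAL)
        )
        assert physical.h_bulk > 1.0
        assert physical.h_bulk == pytest.approx(1 / printed.h_bulk)

    def test_invalid_conditions(self):
        with pytest.raises(DomainError):
            ProcessConditions(T=-1, T_ref=453, c_a=1, c_a_ref=1)


class TestApplyModulation:
    def test_identity_factors_leave_matrix_unchanged(self, gauss10):
        out = apply_modulation(gauss10, ModulationFactors(g=1, h_bulk=1, h_G=1))
        np.testing.assert_array_equal(out.P, gauss10.P)

    def test_doubling_g_doubles_offdiagonals(self):
        P = build_matrix(10, "gauss", breaking_scale=0.3)
        out = apply_modulation(P, ModulationFactors(g=2, h_bulk=1, h_G=1))
        off = np.tril(np.ones((11, 11), dtype=bool), k=-1)
        np.testing.assert_allclose(out.P[off], 2 * P.P[off], atol=1e-15)
        np.testing.assert_allclose(out.P.sum(axis=0), 1.0, atol=1e-12)

    def test_hG_touches_only_terminal_entry(self, gauss10):
        out = apply_modulation(gauss10, ModulationFactors(g=1, h_bulk=1, h_G=0.5))
        assert out.P[10, 9] == pytest.approx(0.5 * gauss10.P[10, 9])
        off = np.tril(np.ones((11, 11), dtype=bool), k=-1)
        off[10, 9] = False
        np.testing.assert_allclose(out.P[off], gauss10.P[off], atol=1e-15)

    def test_overflow_suggests_smaller_step(self, gauss10):
        with pytest.raises(NormalizationError, match="smaller time step"):
            apply_modulation(gauss10, ModulationFactors(g=5, h_bulk=1, h_G=1))

    def test_modulated_construction_equals_post_modulation(self):
        """Applying factors during construction and after it agree."""
        f = ModulationFactors(g=0.8, h_bulk=0.5, h_G=0.3)
        built = build_matrix(10, "gauss", factors=f)
        post = apply_modulation(build_matrix(10, "gauss"), f)
        np.testing.assert_allclose(built.P, post.P, atol=1e-14)

    def test_scale_breaking_roundtrip(self, gauss10):
        out = scale_breaking(scale_breaking(gauss10, 0.5), 2.0)
        np.testing.assert_allclose(out.P, gauss10.P, atol=1e-14)


class TestCsvRoundTrip:
    def test_matrix_roundtrip_exact(self, gauss10):
        buf = io.StringIO()
        matrix_to_csv(gauss10, buf)
        buf.seek(0)
        back = matrix_from_csv(buf)
        np.testing.assert_array_equal(back.P, gauss10.P)
        assert back.N == gauss10.N
        assert back.distribution == gauss10.distribution
        assert back.dt == gauss10.dt
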