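"""Column-pair score terms: closed forms, windowing, weighting, ablations."""

import io
import math

import numpy as np
import pytest
from dataclasses import replace

from alignhush import (
    ScoringParams,
    column_match_score,
    conservation_score,
    default_ss_table,
    hydrophobic_score,
    match_score_matrix,
    ss_score,
    uniform_background,
    windowed_term,
)
from alignhush.errors import ContractViolation, FormatError
from alignhush.hmm_io import MatchState
from alignhush.scoring import LOG_FLOOR

from conftest import make_random_profile


def state_from_probs(p, bg=None):
    bg = bg or uniform_background()
    return MatchState(
        odds=np.asarray(p) / np.sqrt(bg.b),
        hydrophobicity=0.0,
        ss_freq=np.full(3, 1 / 3),
        trans=np.array([0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5]),
    )


class TestConservation:
    def test_background_vs_background_is_zero(self):
        bg = uniform_background()
        st = state_from_probs(bg.b, bg)
        assert conservation_score(st, st) == pytest.approx(0.0, abs=1e-12)

    def test_same_point_mass_uniform_background(self):
        p = np.zeros(20)
        p[4] = 1.0
        st = state_from_probs(p)
        assert conservation_score(st, st) == pytest.approx(math.log2(20))

    def test_disjoint_point_masses_hit_floor(self):
        p, q = np.zeros(20), np.zeros(20)
        p[0], q[1] = 1.0, 1.0
        assert conservation_score(state_from_probs(p), state_from_probs(q)) == LOG_FLOOR


class TestHydrophobic:
    def test_equal_hydropathies_give_offset(self):
        assert hydrophobic_score(2.0, 2.0, 1.5) == 1.5

    def test_zero_crossing_at_offset(self):
        assert hydrophobic_score(3.0, 1.5, 1.5) == pytest.approx(0.0)

    def test_symmetric(self):
        assert hydrophobic_score(-2.0, 3.1, 1.5) == hydrophobic_score(3.1, -2.0, 1.5)


class TestSSScore:
    def test_point_masses_pick_table_entry(self):
        table = default_ss_table()
        fx = np.array([1.0, 0, 0])
        assert ss_score(fx, fx, table) == pytest.approx(table.L[0, 0])

    def test_uniform_gives_table_mean(self):
        table = default_ss_table()
        u = np.full(3, 1 / 3)
        assert ss_score(u, u, table) == pytest.approx(table.L.mean())

    def test_swap_invariant(self):
        table = default_ss_table()
        fx, fy = np.array([0.7, 0.2, 0.1]), np.array([0.1, 0.3, 0.6])
        assert ss_score(fx, fy, table) == pytest.approx(ss_score(fy, fx, table))

    def test_bilinear_in_first_argument(self):
        table = default_ss_table()
        rng = np.random.default_rng(0)
        f1, f2, g = rng.dirichlet(np.ones(3), size=3)
        a = 0.3
        assert ss_score(a * f1 + (1 - a) * f2, g, table) == pytest.approx(
            a * ss_score(f1, g, table) + (1 - a) * ss_score(f2, g, table)
        )


class TestWindow:
    def constant_profiles(self, n, m):
        rng = np.random.default_rng(1)
        return make_random_profile(rng, n), make_random_profile(rng, m)

    def test_width_one_is_raw_term(self):
        P, Q = self.constant_profiles(4, 4)
        raw = lambda P, Q, i, j: float(i * 10 + j)
        assert windowed_term(raw, P, Q, 2, 3, 1) == 23.0

    def test_constant_field_interior_sums_five(self):
        P, Q = self.constant_profiles(7, 7)
        const = lambda *a: 2.5
        assert windowed_term(const, P, Q, 4, 4, 5) == pytest.approx(5 * 2.5)

    def test_corner_truncates_to_three(self):
        P, Q = self.constant_profiles(5, 5)
        const = lambda *a: 2.5
        assert windowed_term(const, P, Q, 1, 1, 5) == pytest.approx(3 * 2.5)

    def test_out_of_range_centre_rejected(self):
        P, Q = self.constant_profiles(3, 3)
        with pytest.raises(ContractViolation):
            windowed_term(lambda *a: 0.0, P, Q, 4, 1, 1)


class TestColumnMatchScore:
    def test_conservation_only_with_unit_window(self):
        rng = np.random.default_rng(2)
        P, Q = make_random_profile(rng, 5), make_random_profile(rng, 5)
        params = ScoringParams(Wc=2.0, Wh=0, Ws=0, win_c=1)
        got = column_match_score(P, Q, 3, 2, params)
        assert got == pytest.approx(
            2.0 * conservation_score(P.states[2], Q.states[1])
        )

    def test_all_weights_zero_annihilate(self):
        rng = np.random.default_rng(3)
        P, Q = make_random_profile(rng, 4), make_random_profile(rng, 4)
        params = ScoringParams(Wc=0, Wh=0, Ws=0)
        assert column_match_score(P, Q, 2, 2, params) == 0.0

    def test_matrix_matches_per_cell_computation(self):
        # dense vectorised matrix vs the scalar per-cell path
        rng = np.random.default_rng(4)
        P, Q = make_random_profile(rng, 6), make_random_profile(rng, 8)
        params = ScoringParams()
        M = match_score_matrix(P, Q, params)
        for i in range(1, 7):
            for j in range(1, 9):
                assert M[i - 1, j - 1] == pytest.approx(
                    column_match_score(P, Q, i, j, params), abs=1e-12
                )

    def test_term_by_term_oracle(self):
        # independent summation of the three windowed terms
        rng = np.random.default_rng(5)
        P, Q = make_random_profile(rng, 6), make_random_profile(rng, 6)
        params = ScoringParams()
        i, j = 3, 4
        cons = windowed_term(
            lambda P, Q, a, b: conservation_score(P.states[a - 1], Q.states[b - 1]),
            P, Q, i, j, params.win_c,
        )
        hyd = windowed_term(
            lambda P, Q, a, b: hydrophobic_score(
                P.states[a - 1].hydrophobicity,
                Q.states[b - 1].hydrophobicity,
                params.hydro_offset,
            ),
            P, Q, i, j, params.win_h,
        )
        ss = windowed_term(
            lambda P, Q, a, b: ss_score(
                P.states[a - 1].ss_freq, Q.states[b - 1].ss_freq, params.ss_table
            ),
            P, Q, i, j, params.win_s,
        )
        expected = params.Wc * cons + params.Wh * hyd + params.Ws * ss
        assert column_match_score(P, Q, i, j, params) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unannotated_ss_contributes_zero(self):
        rng = np.random.default_rng(6)
        P = make_random_profile(rng, 5, annotated=False)
        Q = make_random_profile(rng, 5)
        full = ScoringParams()
        no_ss = replace(full, Ws=0.0)
        for i, j in [(1, 1), (3, 3), (5, 2)]:
            assert column_match_score(P, Q, i, j, full) == pytest.approx(
                column_match_score(P, Q, i, j, no_ss)
            )

    def test_symmetry_under_profile_swap(self):
        rng = np.random.default_rng(7)
        P, Q = make_random_profile(rng, 5), make_random_profile(rng, 7)
        params = ScoringParams()
        Mpq = match_score_matrix(P, Q, params)
        Mqp = match_score_matrix(Q, P, params)
        np.testing.assert_allclose(Mpq, Mqp.T, atol=1e-12)


class TestConfig:
    def test_roundtrip(self):
        params = ScoringParams(Wc=0.8, Wh=0.1, win_c=3)
        buf = io.StringIO()
        params.to_config(buf)
        again = ScoringParams.from_config(buf.getvalue())
        assert again.Wc == 0.8 and again.Wh == 0.1 and again.win_c == 3

    def test_unknown_key_rejected(self):
        with pytest.raises(FormatError):
            ScoringParams.from_config("bogus = 3\n")

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(win_c=4)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(Wh=-0.1)
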