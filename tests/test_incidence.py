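"""Degrees of grey incidence: worked examples, invariances, oracle parity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from greyrank import (
    DomainError,
    GreyConfig,
    Sequence,
    absolute_degree,
    deng_degree,
    grey_coefficients,
    rank_factors,
    relative_degree,
    run_all_models,
    sdgra,
    ssgra,
)
from ._bruteforce import absolute_bf, deng_bf, relative_bf
from .conftest import make_seq

small_int_seq = st.lists(st.integers(min_value=1, max_value=9), min_size=3, max_size=6)


class TestGreyCoefficients:
    def test_identical_sequences_all_one(self):
        s = make_seq([3.0, 1.0, 4.0, 1.5])
        np.testing.assert_allclose(grey_coefficients(s, s), 1.0)

    def test_hand_worked_reversed_sequence(self):
        # mean images (0.5,1,1.5) vs (1.5,1,0.5): |delta|=(1,0,1), eps=0.5
        coeffs = grey_coefficients(make_seq([1, 2, 3]), make_seq([3, 2, 1], "r"))
        np.testing.assert_allclose(coeffs, [1 / 3, 1.0, 1 / 3], atol=1e-15)

    def test_proportional_comparison_all_one(self):
        coeffs = grey_coefficients(make_seq([1, 2, 3]), make_seq([2, 4, 6], "p"))
        np.testing.assert_allclose(coeffs, 1.0)

    def test_unit_where_deviation_attains_minimum(self):
        ref = make_seq([1.0, 2.0, 3.0, 5.0])
        comp = make_seq([1.2, 1.8, 3.3, 4.0], "c")
        coeffs = grey_coefficients(ref, comp)
        deltas = np.abs(
            ref.values / ref.values.mean() - comp.values / comp.values.mean()
        )
        assert np.argmax(coeffs) == np.argmin(deltas)
        assert coeffs.max() <= 1.0 and coeffs.min() > 0.0


class TestDengDegree:
    def test_identical_is_one(self):
        s = make_seq([4.0, 2.0, 7.0])
        assert deng_degree(s, s) == 1.0

    def test_hand_worked_value(self):
        got = deng_degree(make_seq([1, 2, 3]), make_seq([3, 2, 1], "r"))
        assert got == pytest.approx(5 / 9, abs=1e-15)

    @given(small_int_seq, st.floats(min_value=0.05, max_value=20.0))
    def test_scale_invariance(self, values, a):
        ref = make_seq([1.0, 3.0, 2.0, 5.0, 4.0, 6.0][: len(values)])
        comp = make_seq(values, "c")
        scaled = make_seq(a * comp.values, "c2")
        assert deng_degree(ref, comp) == pytest.approx(
            deng_degree(ref, scaled), abs=1e-9
        )

    @given(small_int_seq)
    def test_monotone_in_resolution_coefficient(self, values):
        ref = make_seq(list(range(1, len(values) + 1)))
        comp = make_seq(values, "c")
        degrees = [
            deng_degree(ref, comp, GreyConfig(epsilon=e))
            for e in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(b - a >= -1e-12 for a, b in zip(degrees, degrees[1:]))


class TestAreaDegrees:
    def test_absolute_equal_shifted_curves(self):
        # zero-start images coincide -> area signatures equal -> degree 1
        assert absolute_degree(make_seq([1, 2, 3]), make_seq([2, 3, 4], "c")) == 1.0

    def test_absolute_flat_comparison(self):
        # s0 = 1 + 2/2 = 2, si = 0 -> (1+2)/(1+2+2)
        got = absolute_degree(make_seq([1, 2, 3]), make_seq([5, 5, 5], "c"))
        assert got == pytest.approx(0.6, abs=1e-15)

    def test_absolute_self_is_one(self):
        s = make_seq([3.0, 1.0, 4.0, 1.0, 5.0])
        assert absolute_degree(s, s) == 1.0

    def test_absolute_not_scale_invariant(self):
        ref = make_seq([1, 2, 3])
        assert absolute_degree(ref, make_seq([10, 20, 30], "c")) < absolute_degree(
            ref, make_seq([1, 2, 3], "c")
        )

    def test_relative_proportional_is_one(self):
        assert relative_degree(make_seq([2, 4, 6]), make_seq([1, 2, 3], "c")) == 1.0

    def test_relative_flat_comparison(self):
        got = relative_degree(make_seq([1, 2, 3]), make_seq([1, 1, 1], "c"))
        assert got == pytest.approx(0.6, abs=1e-15)

    @given(small_int_seq, st.floats(min_value=0.05, max_value=20.0))
    def test_relative_scale_invariance(self, values, a):
        ref = make_seq([2.0, 1.0, 4.0, 3.0, 6.0, 5.0][: len(values)])
        comp = make_seq(values, "c")
        scaled = make_seq(a * comp.values, "c2")
        assert relative_degree(ref, comp) == pytest.approx(
            relative_degree(ref, scaled), abs=1e-9
        )


class TestSyntheticDegrees:
    @pytest.mark.parametrize(
        "absolute,relative,expected",
        [(0.599, 0.893, 0.746), (0.500, 0.524, 0.512), (0.7, 0.7, 0.7)],
    )
    def test_sdgra_values(self, absolute, relative, expected):
        assert round(sdgra(absolute, relative, 0.5), 3) == expected

    @pytest.mark.parametrize(
        "deng,absolute,expected",
        [(0.941, 0.599, 0.770), (0.967, 0.695, 0.831), (1.0, 1.0, 1.0)],
    )
    def test_ssgra_values(self, deng, absolute, expected):
        assert round(ssgra(deng, absolute), 3) == expected

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_out_of_range_degree_rejected(self, bad):
        with pytest.raises(DomainError):
            sdgra(bad, 0.5)
        with pytest.raises(DomainError):
            ssgra(0.5, bad)


class TestRanking:
    def test_descending_order(self):
        ranks = rank_factors({"income": 0.566, "physician": 0.859, "smoking": 0.941})
        assert ranks == {"smoking": "1", "physician": "2", "income": "3"}

    def test_tied_pair_shares_notation(self):
        ranks = rank_factors(
            {"a": 0.9001, "b": 0.8002, "c": 0.6431, "d": 0.6429, "e": 0.5}
        )
        assert ranks["c"] == "3(4)" and ranks["d"] == "3(4)"
        assert ranks["a"] == "1" and ranks["e"] == "5"

    def test_single_factor(self):
        assert rank_factors({"only": 0.4}) == {"only": "1"}

    @given(
        st.dictionaries(
            st.sampled_from(list("abcdefg")),
            st.floats(min_value=0.01, max_value=1.0),
            min_size=1,
            max_size=7,
        )
    )
    def test_positions_cover_one_to_n(self, degrees):
        ranks = rank_factors(degrees)
        first_positions = sorted(int(r.split("(")[0]) for r in ranks.values())
        assert first_positions[0] == 1
        assert len(ranks) == len(degrees)


class TestRunAllModels:
    def test_identical_single_comparison(self):
        s = make_seq([40.0, 42.0, 44.0, 43.0])
        table = run_all_models(s, [s.with_values(s.values, suffix="_c")])
        assert np.allclose(table.degrees.to_numpy(), 1.0)
        assert set(table.ranks.iloc[0]) == {"1"}

    def test_proportional_factor_tops_deng_and_relative(self):
        years = np.arange(2001, 2011)
        rng = np.random.default_rng(7)
        ref = Sequence("m", years, 40 + np.linspace(0, 8, 10) + rng.normal(0, 1, 10))
        prop = Sequence("prop", years, 0.3 * ref.values)
        others = [
            Sequence("flat", years, np.full(10, 30.0)),
            Sequence("noise", years, 30 + rng.normal(0, 5, 10)),
        ]
        table = run_all_models(ref, [prop, *others])
        assert table.ranks.loc["prop", "deng"] == "1"
        assert table.ranks.loc["prop", "relative"] == "1"
        assert table.degrees.loc["prop", "deng"] == pytest.approx(1.0)

    def test_synthetic_degree_identities_exact(self, default_panel):
        sub = default_panel.frame[default_panel.frame.group == "female"]
        ref = Sequence("mortality", sub.year.to_numpy(), sub.mortality.to_numpy())
        comps = [
            Sequence(c, sub.year.to_numpy(), sub[c].to_numpy())
            for c in ("income", "physician", "smoking")
        ]
        table = run_all_models(ref, comps)
        d = table.degrees
        np.testing.assert_allclose(
            d["sdgra"], 0.5 * d["absolute"] + 0.5 * d["relative"], atol=1e-15
        )
        np.testing.assert_allclose(
            d["ssgra"], 0.5 * (d["deng"] + d["absolute"]), atol=1e-15
        )

    def test_lagged_run_drops_first_year(self, default_panel):
        sub = default_panel.frame[default_panel.frame.group == "male"]
        ref = Sequence("mortality", sub.year.to_numpy(), sub.mortality.to_numpy())
        comps = [Sequence("smoking", sub.year.to_numpy(), sub.smoking.to_numpy())]
        t0 = run_all_models(ref, comps, lag=0)
        t1 = run_all_models(ref, comps, lag=1)
        assert t0.lag == 0 and t1.lag == 1
        assert not np.allclose(
            t0.degrees.loc["smoking", "deng"], t1.degrees.loc["smoking", "deng"]
        )


class TestBruteForceParity:
    """Vectorized degrees agree with a literal loop transcription."""

    def test_random_small_integer_sequences(self):
        rng = np.random.default_rng(20230303)
        config = GreyConfig()
        for _ in range(200):
            m = int(rng.integers(3, 7))
            ref = make_seq(rng.integers(1, 10, size=m).astype(float))
            comps = [
                make_seq(rng.integers(1, 10, size=m).astype(float), name=f"c{j}")
                for j in range(int(rng.integers(1, 4)))
            ]
            for j, comp in enumerate(comps):
                deng = deng_degree(ref, comp, config, pool=comps)
                assert deng == pytest.approx(
                    deng_bf(
                        list(ref.values), [list(c.values) for c in comps], j
                    ),
                    abs=1e-12,
                )
                assert absolute_degree(ref, comp) == pytest.approx(
                    absolute_bf(list(ref.values), list(comp.values)), abs=1e-12
                )
                assert relative_degree(ref, comp) == pytest.approx(
                    relative_bf(list(ref.values), list(comp.values)), abs=1e-12
                )
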