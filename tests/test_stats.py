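"""Disproportionality statistics: closed forms, oracles, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal import (
    BcpnnPrior,
    Thresholds,
    UndefinedResultError,
    bcpnn,
    classify,
    compute_signal,
    compute_signals,
    ebgm,
    prr_chisq,
    ror,
)
from pvsignal.stats import format_signals, rank_signals, yates_chisq

TOY = (10, 20, 30, 240)


class TestClosedForms:
    def test_ror_point_and_interval(self):
        est, lo, hi = ror(*TOY)
        assert est == pytest.approx(4.0)
        # SE = sqrt(1/10+1/20+1/30+1/240) = sqrt(0.1875)
        assert lo == pytest.approx(4.0 * math.exp(-1.96 * math.sqrt(0.1875)))
        assert (lo, hi) == (pytest.approx(1.712, abs=1e-3),
                            pytest.approx(9.347, abs=1e-3))

    def test_prr_point_and_yates_chisq(self):
        est, lo, hi, chi = prr_chisq(*TOY)
        assert est == pytest.approx(3.0)
        assert lo < est < hi
        # N(|ad-bc|-N/2)^2 / ((a+b)(c+d)(a+c)(b+d)) by hand = 9.6955
        assert chi == pytest.approx(9.70, abs=0.01)

    def test_ebgm_point_and_lower_bound(self):
        est, lo, _ = ebgm(*TOY)
        assert est == pytest.approx(2.5)
        assert lo == pytest.approx(1.070, abs=5e-4)

    def test_bcpnn_raw_and_posterior(self):
        res = bcpnn(*TOY)
        assert res.ic_raw == pytest.approx(math.log2(2.5), abs=1e-9)
        assert res.e_ic == pytest.approx(1.086, abs=5e-4)
        assert res.ic025 < res.e_ic

    def test_balanced_table_is_null(self):
        assert ror(5, 5, 5, 5)[0] == pytest.approx(1.0)
        lo, hi = ror(5, 5, 5, 5)[1:]
        assert lo < 1.0 < hi
        est, _, _, chi = prr_chisq(5, 5, 5, 5)
        assert est == pytest.approx(1.0)
        assert chi == 0.0
        assert ebgm(5, 5, 5, 5)[0] == pytest.approx(1.0)
        # default prior makes the posterior expectation exactly zero here
        assert bcpnn(5, 5, 5, 5).e_ic == 0.0

    def test_yates_floor_at_zero(self):
        assert yates_chisq(5, 5, 5, 5) == 0.0
        assert yates_chisq(6, 5, 5, 5) == 0.0  # |ad-bc| < N/2


class TestDegenerateTables:
    @pytest.mark.parametrize("cells,name", [
        ((0, 5, 5, 5), "a"), ((5, 0, 5, 5), "b"),
        ((5, 5, 0, 5), "c"), ((5, 5, 5, 0), "d"),
    ])
    def test_zero_cell_raises_naming_cell(self, cells, name):
        with pytest.raises(UndefinedResultError, match=f"cell {name}"):
            ror(*cells)

    def test_haldane_correction_enables_zero_cells(self):
        est, lo, hi = ror(0, 5, 5, 5, correction=True)
        assert est == (0.5 * 5.5) / (5.5 * 5.5)
        assert lo < est < hi

    def test_bcpnn_requires_positive_margins(self):
        with pytest.raises(UndefinedResultError):
            bcpnn(0, 0, 5, 5)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ror(-1, 2, 3, 4)


class TestClassify:
    def test_all_criteria_met(self):
        flags = classify(_make({}), Thresholds())
        assert flags == (True, True, True, True, True)

    def test_min_case_rule_blocks_frequentist_flags(self):
        flags = classify(_make({"a": 2, "ror_lo": 50.0}), Thresholds())
        assert not flags.ror_pos and not flags.prr_pos
        assert not flags.consensus

    def test_strict_inequalities(self):
        assert not classify(_make({"ic025": 0.0})).bcpnn_pos
        assert not classify(_make({"ebgm05": 2.0})).ebgm_pos
        assert not classify(_make({"ror_lo": 1.0})).ror_pos

    def test_alternative_prr_rule(self):
        t = Thresholds(prr_rule="prr2_chi4")
        assert classify(_make({"prr": 2.5, "chisq": 5.0, "prr_lo": 0.5}), t).prr_pos
        assert not classify(_make({"prr": 2.5, "chisq": 3.0}), t).prr_pos
        assert not classify(_make({"prr": 1.5, "chisq": 50.0}), t).prr_pos

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(prr_rule="bogus")


def _make(overrides):
    from pvsignal.stats import SignalResult

    base = dict(drug="x", a=10, ror=5.0, ror_lo=2.0, ror_hi=12.0, prr=5.0,
                prr_lo=2.0, prr_hi=12.0, chisq=30.0, ic=2.0, ic025=1.0,
                ebgm=5.0, ebgm05=3.0, ebgm95=8.0)
    base.update(overrides)
    return SignalResult(**base)


def _random_tables(rng, n, lo=1, hi=500):
    return [(int(rng.integers(lo, hi)), int(rng.integers(lo, hi)),
             int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
            for _ in range(n)]


class TestOracleEquivalence:
    def test_ror_matches_statsmodels_on_random_tables(self):
        """Cross-check against an independent 2x2 odds-ratio routine."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(42)
        for a, b, c, d in _random_tables(rng, 1000):
            est, lo, hi = ror(a, b, c, d)
            t22 = sm.Table2x2(np.array([[a, b], [c, d]]))
            assert est == pytest.approx(t22.oddsratio, rel=1e-12)
            o_lo, o_hi = t22.oddsratio_confint(0.05)
            assert lo == pytest.approx(o_lo, rel=1e-3)
            assert hi == pytest.approx(o_hi, rel=1e-3)


class TestInvariants:
    def test_monotone_in_a_for_ror_and_prr(self):
        rng = np.random.default_rng(0)
        for a, b, c, d in _random_tables(rng, 200):
            assert ror(a + 1, b, c, d)[0] > ror(a, b, c, d)[0]
            assert prr_chisq(a + 1, b, c, d)[0] > prr_chisq(a, b, c, d)[0]

    def test_monotone_in_a_for_rrr_in_surveillance_regime(self):
        """aN/((a+b)(a+c)) rises with a while margins stay small vs N."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = int(rng.integers(1, 30))
            b = int(rng.integers(500, 5000))
            c = int(rng.integers(500, 5000))
            d = int(rng.integers(100_000, 1_000_000))
            assert ebgm(a + 1, b, c, d)[0] > ebgm(a, b, c, d)[0]
            assert bcpnn(a + 1, b, c, d).ic_raw > bcpnn(a, b, c, d).ic_raw

    def test_null_calibration_under_independence(self):
        """Product tables (a,b,c,d) = (rs, rt, us, ut) are exactly null."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            r, s, t, u = (int(rng.integers(1, 40)) for _ in range(4))
            a, b, c, d = r * s, r * t, u * s, u * t
            assert ror(a, b, c, d)[0] == pytest.approx(1.0)
            assert prr_chisq(a, b, c, d)[0] == pytest.approx(1.0)
            assert ebgm(a, b, c, d)[0] == pytest.approx(1.0)
            assert bcpnn(a, b, c, d).ic_raw == pytest.approx(0.0, abs=1e-12)

    def test_bcpnn_shrinks_toward_zero_and_converges(self):
        """Posterior IC shrinks toward 0 in the sparse regime the method
        targets (margins small relative to N); the prior can offset the
        posterior by a few thousandths at most there.  Under proportional
        cell scaling the posterior converges to the raw IC."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = int(rng.integers(1, 50))
            b = int(rng.integers(50, 2000))
            c = int(rng.integers(50, 2000))
            d = int(rng.integers(20_000, 500_000))
            res = bcpnn(a, b, c, d)
            assert abs(res.e_ic) <= abs(res.ic_raw) + 0.01
        for a, b, c, d in _random_tables(rng, 200, lo=1, hi=300):
            res = bcpnn(a, b, c, d)
            big = bcpnn(100 * a, 100 * b, 100 * c, 100 * d)
            assert abs(big.e_ic - big.ic_raw) < abs(res.e_ic - res.ic_raw) + 1e-9
            assert abs(big.e_ic - big.ic_raw) < 0.02

    def test_ror_dominates_prr_on_positive_association(self):
        rng = np.random.default_rng(4)
        checked = 0
        for a, b, c, d in _random_tables(rng, 500):
            if a * d < b * c:
                continue
            checked += 1
            r = ror(a, b, c, d)[0]
            p = prr_chisq(a, b, c, d)[0]
            assert r >= p - 1e-12
            if a * d > b * c:
                assert p > 1.0 or b / (b + d) >= 1.0
        assert checked > 50


class TestTableInterface:
    def test_compute_signals_frame(self):
        tables = pd.DataFrame(
            {"drug": ["x", "y"], "a": [10, 3], "b": [20, 10], "c": [30, 37],
             "d": [240, 250], "N": [300, 300]}
        )
        out = compute_signals(tables)
        assert list(out["drug"]) == ["x", "y"]
        assert out.loc[0, "ror"] == pytest.approx(4.0)
        assert out.loc[0, "consensus"] in (True, False)

    def test_rank_by_ror_with_tie_rules(self):
        sig = pd.DataFrame({
            "drug": ["b", "a", "c"], "a": [5, 9, 9],
            "ror": [4.0, 4.0, 4.0],
        })
        ranked = rank_signals(sig)
        assert list(ranked["drug"]) == ["a", "c", "b"]

    def test_rank_by_cases(self):
        sig = pd.DataFrame({"drug": ["a", "b"], "a": [3, 9], "ror": [9.0, 2.0]})
        assert list(rank_signals(sig, by="cases")["drug"]) == ["b", "a"]

    def test_format_rounds_half_up(self):
        sig = pd.DataFrame({"drug": ["x"], "a": [3], "ror": [1.005],
                            "ic": [-1.005]})
        out = format_signals(sig)
        assert out.loc[0, "ror"] == 1.01
        assert out.loc[0, "ic"] == -1.01


class TestPriorSensitivity:
    def test_custom_prior_changes_shrinkage(self):
        default = bcpnn(*TOY)
        flat = bcpnn(*TOY, prior=BcpnnPrior(gamma11=0.5, alpha1=0.5, beta1=0.5,
                                            alpha=1.0, beta=1.0))
        assert default.ic_raw == flat.ic_raw
        assert default.e_ic != flat.e_ic
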