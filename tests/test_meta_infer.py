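"""Fixed-effects meta-analysis, Cochran's Q, BH correction, DMS calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dmscall.meta_infer import (
    bh_adjust,
    call_dms,
    fixed_effects_meta,
    heterogeneity_filter,
    meta_analyze_table,
)


class TestFixedEffectsMeta:
    def test_identical_studies_pool_as_sqrt2(self):
        m = fixed_effects_meta([1.0, 1.0], [0.4, 0.4])
        assert m.beta_meta == pytest.approx(1.0)
        assert m.se_meta == pytest.approx(0.4 / np.sqrt(2), abs=1e-12)
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert m.p_Q == pytest.approx(1.0)

    def test_single_study_returns_input(self):
        m = fixed_effects_meta([0.7], [0.2])
        assert m.beta_meta == pytest.approx(0.7)
        assert m.se_meta == pytest.approx(0.2)
        assert m.k == 1 and m.Q == 0.0 and m.p_Q == 1.0

    def test_worked_two_study_example(self):
        # w = (4, 16): beta = 0.36, se = 1/sqrt(20), Q = 2.048
        m = fixed_effects_meta([1.0, 0.2], [0.5, 0.25])
        assert m.beta_meta == pytest.approx(0.36, abs=1e-12)
        assert m.se_meta == pytest.approx(1 / np.sqrt(20), abs=1e-12)
        assert m.Q == pytest.approx(2.048, abs=1e-12)
        assert m.p_Q == pytest.approx(stats.chi2.sf(2.048, 1), abs=1e-12)

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([], [])
        with pytest.raises(ValueError):
            fixed_effects_meta([1.0], [np.inf])
        with pytest.raises(ValueError):
            fixed_effects_meta([1.0], [0.0])

    def test_se_meta_never_exceeds_smallest_input_se(self, rng):
        for _ in range(50):
            k = rng.integers(1, 6)
            b = rng.normal(0, 1, k)
            s = rng.uniform(0.05, 2.0, k)
            m = fixed_effects_meta(b, s)
            assert m.se_meta <= s.min() + 1e-12
            if k == 1:
                assert m.se_meta == pytest.approx(s.min())

    def test_negligible_study_leaves_pool_unchanged(self):
        base = fixed_effects_meta([1.0, 0.2], [0.5, 0.25])
        padded = fixed_effects_meta([1.0, 0.2, 50.0], [0.5, 0.25, 1e6])
        assert padded.beta_meta == pytest.approx(base.beta_meta, abs=1e-8)
        assert padded.se_meta == pytest.approx(base.se_meta, abs=1e-8)

    @given(st.floats(min_value=-5, max_value=5))
    def test_q_invariant_under_common_shift(self, shift):
        b = np.array([0.3, -0.2, 1.1])
        s = np.array([0.2, 0.4, 0.3])
        assert fixed_effects_meta(b + shift, s).Q == pytest.approx(
            fixed_effects_meta(b, s).Q, abs=1e-9
        )


class TestHeterogeneity:
    def test_opposite_large_effects_flagged(self):
        m = fixed_effects_meta([2.0, -2.0], [0.1, 0.1])
        assert m.Q == pytest.approx(800.0, abs=1e-9)
        assert m.heterogeneous

    def test_identical_effects_retained(self):
        assert not fixed_effects_meta([1.0, 1.0], [0.3, 0.3]).heterogeneous

    def test_single_study_never_flagged(self):
        df = pd.DataFrame({"k": [1], "p_Q": [0.001]})
        assert not heterogeneity_filter(df)["heterogeneous"].iloc[0]


class TestBhAdjust:
    def test_step_up_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_is_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # m=2, not 3
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02], atol=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 1, 200)
        np.testing.assert_allclose(
            bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_bounds_and_monotonicity(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _fit_row(ref, line, beta, se, tested=True, converged=True, pruned=False):
    return {
        "reference": ref,
        "start": 0,
        "end": 1,
        "strand": "+",
        "mod_code": "a",
        "cell_line": line,
        "beta1": beta,
        "se1": se,
        "tested": tested,
        "converged": converged,
        "pruned": pruned,
    }


class TestCallDms:
    def test_pruned_site_enters_with_k1(self):
        fits = pd.DataFrame(
            [
                _fit_row("tx1", "A", 1.0, 0.2, pruned=True),
                _fit_row("tx1", "B", 1.1, 0.2),
            ]
        )
        dms = call_dms(fits)
        assert len(dms) == 1
        assert dms["k"].iloc[0] == 1
        assert dms["beta_meta"].iloc[0] == pytest.approx(1.1)

    def test_both_lines_only_drops_k1_sites(self):
        fits = pd.DataFrame(
            [
                _fit_row("tx1", "A", 1.0, 0.2),
                _fit_row("tx1", "B", 1.1, 0.2),
                _fit_row("tx2", "A", 0.5, 0.2),
            ]
        )
        assert len(call_dms(fits)) == 2
        both = call_dms(fits, both_lines_only=True)
        assert both["reference"].tolist() == ["tx1"]

    def test_heterogeneous_site_excluded_from_bh_pool(self):
        rows = [
            _fit_row("tx1", "A", 2.0, 0.1),
            _fit_row("tx1", "B", -2.0, 0.1),
            _fit_row("tx2", "A", 1.5, 0.2),
            _fit_row("tx2", "B", 1.4, 0.2),
        ]
        dms = call_dms(pd.DataFrame(rows))
        het = dms[dms["reference"] == "tx1"].iloc[0]
        assert het["heterogeneous"] and not het["is_dms"]
        assert np.isnan(het["q_value"])
        clean = dms[dms["reference"] == "tx2"].iloc[0]
        # q equals p: the heterogeneous site does not count toward m
        assert clean["q_value"] == pytest.approx(clean["p"])

    def test_empty_input_gives_empty_table(self):
        fits = pd.DataFrame([_fit_row("tx1", "A", 1.0, 0.2, tested=False)])
        assert call_dms(fits).empty

    def test_meta_analyze_table_matches_scalar_path(self, rng):
        rows = []
        for i in range(30):
            for line in ("A", "B"):
                rows.append(
                    _fit_row(f"tx{i}", line, rng.normal(), rng.uniform(0.1, 0.5))
                )
        fits = pd.DataFrame(rows)
        table = meta_analyze_table(
            fits, ["reference", "start", "end", "strand", "mod_code"]
        ).set_index("reference")
        for ref, sub in fits.groupby("reference"):
            m = fixed_effects_meta(sub["beta1"], sub["se1"])
            assert table.loc[ref, "beta_meta"] == pytest.approx(m.beta_meta)
            assert table.loc[ref, "se_meta"] == pytest.approx(m.se_meta)
            assert table.loc[ref, "Q"] == pytest.approx(m.Q, abs=1e-9)
            assert table.loc[ref, "p_Q"] == pytest.approx(m.p_Q, abs=1e-9)
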