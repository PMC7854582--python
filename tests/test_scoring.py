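"""Pearson scoring against codes and lineage-identity classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hoxcode as hx
from hoxcode.codes import HoxCodeTable
from hoxcode.io import ValidationError
from hoxcode.scoring import calls_to_frame


def brute_pearson(x, y):
    """Textbook formula, pure Python, fsum accumulation."""
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    num = math.fsum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        math.fsum((a - mx) ** 2 for a in x) * math.fsum((b - my) ** 2 for b in y)
    )
    return num / den if den else float("nan")


class TestPearson:
    def test_identity_and_reversal(self):
        assert hx.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert hx.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x, y = [1, 2, 3, 4], [2, 4, 4, 8]
        assert hx.pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-15)

    def test_zero_variance_gives_missing(self):
        assert math.isnan(hx.pearson([5, 5, 5], [1, 2, 3]))

    @pytest.mark.parametrize("x,y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])])
    def test_short_or_mismatched_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            hx.pearson(x, y)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hx.pearson([1, 2, np.nan], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=20),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_positive_affine_maps(self, xs, a, b):
        rng = np.random.default_rng(11)
        ys = rng.normal(size=len(xs))
        r0 = hx.pearson(xs, ys)
        if math.isnan(r0):
            return
        r_pos = hx.pearson([a * v + b for v in xs], ys)
        r_neg = hx.pearson([-a * v + b for v in xs], ys)
        assert r_pos == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert hx.pearson(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


def small_codes():
    genes = ["HOXA1", "HOXB2", "HOXC4", "HOXD8", "HOXB13"]
    codes = pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0, 0.0], [1.0, 0.0, 5.0, 0.0, 1.0]],
        index=pd.Index(["lung", "prostate", "skin"], name="tissue"),
        columns=genes,
    )
    return HoxCodeTable(codes=codes, transform="none")


class TestScoreSamples:
    def test_sample_equal_to_code_scores_one(self):
        codes = small_codes()
        m = pd.DataFrame(
            {"s1": codes.codes.loc["prostate"].to_numpy()},
            index=pd.Index(codes.gene_ids, name="gene"),
        )
        scores = hx.score_samples(m, codes)
        assert scores.loc["s1", "prostate"] == pytest.approx(1.0, abs=1e-12)

    def test_codes_as_pseudo_samples_give_unit_diagonal(self):
        codes = small_codes()
        m = codes.codes.T.copy()
        scores = hx.score_samples(m, codes)
        np.testing.assert_allclose(np.diag(scores.to_numpy()), 1.0, atol=1e-12)

    def test_flat_sample_gets_missing_row(self, caplog):
        codes = small_codes()
        m = pd.DataFrame(
            {"flat": [2.0] * 5, "ok": [0, 1, 2, 3, 4.0]},
            index=pd.Index(codes.gene_ids, name="gene"),
        )
        with caplog.at_level("WARNING"):
            scores = hx.score_samples(m, codes)
        assert scores.loc["flat"].isna().all()
        assert not scores.loc["ok"].isna().any()

    def test_gene_mismatch_rejected(self):
        codes = small_codes()
        m = pd.DataFrame({"s1": [1, 2, 3.0]},
                         index=pd.Index(codes.gene_ids[:3], name="gene"))
        with pytest.raises(ValidationError):
            hx.score_samples(m, codes)

    def test_generated_samples_argmax_their_tissue(self, default_cohort):
        m, meta, truth = default_cohort
        sub = hx.subset_to_gene_set(m, hx.hox_gene_set(), "strict")
        codes = hx.build_codes(sub, meta)
        scores = hx.score_samples(sub, codes)
        argmax = scores.idxmax(axis=1)
        agree = (argmax == meta.loc[scores.index]).mean()
        assert agree >= 0.99


def scores_fixture():
    return pd.DataFrame(
        {
            "lung": [0.1, 0.2, 0.5, np.nan],
            "prostate": [0.85, 0.10, 0.25, np.nan],
            "skin": [0.0, 0.25, 0.6, np.nan],
        },
        index=pd.Index(["keep", "lost", "moved", "flat"], name="sample_id"),
    )


class TestClassify:
    def test_home_calls(self):
        scores = scores_fixture()
        meta = pd.Series("prostate", index=scores.index)
        calls = {c.sample_id: c for c in hx.classify(scores, meta)}
        assert calls["keep"].call == "kept"
        assert calls["lost"].call == "switched_no_identity"
        assert calls["moved"].call == "switched_to_other"
        assert calls["moved"].best_tissue == "skin"
        assert calls["flat"].call == "undefined"

    def test_boundary_score_is_switched(self):
        scores = pd.DataFrame({"prostate": [0.3], "lung": [0.0]},
                              index=pd.Index(["s"], name="sample_id"))
        meta = pd.Series("prostate", index=scores.index)
        (call,) = hx.classify(scores, meta, threshold=0.3)
        assert call.call == "switched_no_identity"

    def test_no_home_semantics(self):
        scores = pd.DataFrame(
            {"lung": [0.6, 0.5, 0.1], "prostate": [0.1, 0.4, 0.2]},
            index=pd.Index(["one_hit", "two_hits", "no_hit"], name="sample_id"),
        )
        calls = {c.sample_id: c for c in hx.classify(scores, None)}
        assert calls["one_hit"].call == "kept"
        assert calls["one_hit"].best_tissue == "lung"
        assert calls["two_hits"].call == "ambiguous"
        assert calls["no_hit"].call == "switched_no_identity"

    def test_best_tissue_tie_breaks_lexicographically(self):
        scores = pd.DataFrame({"zebra": [0.9], "apple": [0.9]},
                              index=pd.Index(["s"], name="sample_id"))
        (call,) = hx.classify(scores, None)
        assert call.best_tissue == "apple"

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hx.classify(scores_fixture(), None, threshold=1.0)

    def test_unknown_home_tissue_rejected(self):
        scores = scores_fixture()
        meta = pd.Series("kidney", index=scores.index)
        with pytest.raises(ValidationError, match="kidney"):
            hx.classify(scores, meta)

    def test_output_invariant_to_sample_order(self):
        scores = scores_fixture()
        meta = pd.Series("prostate", index=scores.index)
        fwd = calls_to_frame(hx.classify(scores, meta))
        rev = calls_to_frame(hx.classify(scores.iloc[::-1], meta))
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())

    def test_scores_invariant_to_tissue_column_order(self):
        scores = scores_fixture()
        meta = pd.Series("prostate", index=scores.index)
        fwd = calls_to_frame(hx.classify(scores, meta))
        shuf = calls_to_frame(hx.classify(scores[["skin", "lung", "prostate"]], meta))
        pd.testing.assert_frame_equal(fwd, shuf)


class TestSummarizeCalls:
    def test_fraction_kept_shape(self):
        scores = pd.DataFrame(
            {"prostate": [0.8] * 2 + [0.1] * 13, "lung": [0.0] * 15},
            index=pd.Index([f"n{i}" for i in range(15)], name="sample_id"),
        )
        meta = pd.Series("prostate", index=scores.index)
        groups = pd.Series("NEPCa", index=scores.index)
        summary = hx.summarize_calls(hx.classify(scores, meta), groups)
        assert summary.loc["NEPCa", "kept"] == 2
        assert summary.loc["NEPCa", "switched_no_identity"] == 13
        assert summary.loc["NEPCa", "fraction_kept"] == pytest.approx(2 / 15)

    def test_all_kept_gives_fraction_one(self):
        scores = pd.DataFrame({"prostate": [0.9, 0.8]},
                              index=pd.Index(["a", "b"], name="sample_id"))
        meta = pd.Series("prostate", index=scores.index)
        summary = hx.summarize_calls(hx.classify(scores, meta), meta)
        assert summary["fraction_kept"].tolist() == [1.0]

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            hx.summarize_calls([], pd.Series(dtype=object))

    def test_sample_missing_from_groups_rejected(self):
        scores = pd.DataFrame({"prostate": [0.9]},
                              index=pd.Index(["a"], name="sample_id"))
        calls = hx.classify(scores, None)
        with pytest.raises(ValidationError):
            hx.summarize_calls(calls, pd.Series({"other": "g"}))
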