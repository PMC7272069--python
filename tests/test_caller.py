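"""Dual negative-binomial methylation calling: filters, normalization,
exact and GLM tests, BH, grid evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from msdart import caller
from msdart.caller import (
    CallerParams,
    call_methylation,
    estimate_normalization,
    evaluate_parameter_grid,
    exact_nb_pvalue,
    filter_tags,
)
from msdart.caller import test_exact as nb_exact_test
from msdart.caller import test_glm as nb_glm_test
from msdart.stats_base import bh_adjust
from msdart.tagbuilder import MSDTag

from conftest import draw_nb


def _df(rows, columns, index=None):
    return pd.DataFrame(
        np.asarray(rows), columns=columns,
        index=index or [f"tag{i}" for i in range(len(rows))],
    )


def _two_tissue_columns():
    return pd.MultiIndex.from_tuples(
        [
            (t, f"rep{r}", lib)
            for t in ("t1", "t2")
            for lib in ("MspI", "HpaII")
            for r in (1, 2)
        ],
        names=["tissue", "replicate", "library"],
    )


class TestFilterTags:
    def test_missing_in_one_tissue(self):
        cols = _two_tissue_columns()
        df = _df([[0, 0, 5, 5, 9, 9, 5, 5]], cols)
        _, status = filter_tags(df, CallerParams())
        assert status["tag0"] == "filtered_missing"

    def test_min_count_tissue_total(self):
        cols = _two_tissue_columns()
        df = _df([[1, 1, 5, 5, 9, 9, 5, 5]], cols)  # t1 MspI total 2 < 3
        _, status = filter_tags(df, CallerParams())
        assert status["tag0"] == "filtered_min_count"

    def test_all_passing_unchanged(self):
        cols = _two_tissue_columns()
        df = _df([[4, 4, 5, 5, 9, 9, 5, 5], [9, 9, 1, 1, 8, 8, 2, 2]], cols)
        out, status = filter_tags(df, CallerParams())
        assert out.equals(df)
        assert set(status.values()) == {"pass"}

    def test_per_replicate_scope(self):
        cols = _two_tissue_columns()
        df = _df([[2, 9, 5, 5, 9, 9, 5, 5]], cols)
        _, status = filter_tags(
            df, CallerParams(min_count=3, min_count_scope="per_replicate")
        )
        assert status["tag0"] == "filtered_min_count"

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CallerParams(fdr_max=0).validate()
        with pytest.raises(ValueError):
            CallerParams(direction="sideways").validate()


class TestNormalization:
    def test_identical_columns(self, tissue_columns):
        df = _df(np.tile([[5, 5, 5, 5, 5, 5]], (10, 1)), tissue_columns)
        assert np.allclose(estimate_normalization(df).values, 1.0)

    def test_proportional_columns(self, tissue_columns):
        rng = np.random.default_rng(30)
        base = rng.integers(1, 100, size=50).astype(float)
        df = _df(np.column_stack([base, base, base, 2 * base, 2 * base, 2 * base]),
                 tissue_columns)
        f = estimate_normalization(df).values
        assert np.allclose(f[3:] / f[:3], 2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_median_of_ratios_oracle(self, tissue_columns):
        rng = np.random.default_rng(31)
        y = rng.integers(0, 60, size=(80, 6)).astype(float)
        df = _df(y, tissue_columns)
        got = estimate_normalization(df).values
        # direct formula replay on zero-free tags
        zf = y[(y > 0).all(axis=1)]
        gm = np.exp(np.mean(np.log(zf), axis=1))
        oracle = np.array([np.median(zf[:, j] / gm) for j in range(6)])
        oracle /= np.exp(np.mean(np.log(oracle)))
        assert np.allclose(got, oracle)

    def test_all_zero_containing_falls_back_with_warning(self, tissue_columns):
        y = np.eye(6)
        df = _df(y, tissue_columns)
        with pytest.warns(UserWarning, match="zero-free"):
            f = estimate_normalization(df)
        assert (f.values > 0).all()


class TestExactTest:
    def test_strong_signal_small_p(self, tissue_columns):
        df = _df([[30, 28, 32, 0, 1, 0]], tissue_columns)
        res = nb_exact_test(df, pd.Series(1.0, index=tissue_columns), "t1")
        assert res["p"].iloc[0] < 1e-4

    def test_identical_groups_p_one(self, tissue_columns):
        df = _df([[10, 10, 10, 10, 10, 10]], tissue_columns)
        res = nb_exact_test(df, pd.Series(1.0, index=tissue_columns), "t1")
        assert res["p"].iloc[0] == 1.0

    def test_all_zero_tag_p_one(self, tissue_columns):
        df = _df([[0, 0, 0, 0, 0, 0]], tissue_columns)
        res = nb_exact_test(df, pd.Series(1.0, index=tissue_columns), "t1")
        assert res["p"].iloc[0] == 1.0

    def test_zero_dispersion_limit_is_binomial_split(self):
        for z_a, z_b in [(40, 20), (10, 10), (25, 3)]:
            z = z_a + z_b
            p_nb = exact_nb_pvalue(z_a, z_b, 3, 3, 1e-9)
            p_bin = min(1.0, 2 * min(binom.cdf(z_a, z, 0.5), binom.sf(z_a - 1, z, 0.5)))
            assert p_nb == pytest.approx(p_bin, rel=1e-5)

    def test_conditional_matches_monte_carlo_nb_oracle(self):
        # oracle: conditional law of z_a given z via NB simulation
        rng = np.random.default_rng(32)
        phi, n_a, n_b, mu = 0.1, 3, 3, 10.0
        r = 1.0 / phi
        za = rng.negative_binomial(n_a * r, (n_a * r) / (n_a * r + n_a * mu), 200_000)
        zb = rng.negative_binomial(n_b * r, (n_b * r) / (n_b * r + n_b * mu), 200_000)
        z_obs, za_obs = 60, 45
        sel = za[za + zb == z_obs]
        mc_high = (sel >= za_obs).mean()
        mc_low = (sel <= za_obs).mean()
        mc_p = min(1.0, 2 * min(mc_low, mc_high))
        p = exact_nb_pvalue(za_obs, z_obs - za_obs, n_a, n_b, phi)
        assert p == pytest.approx(mc_p, abs=0.02)

    def test_replicate_relabeling_invariance(self, tissue_columns):
        rng = np.random.default_rng(33)
        y = rng.integers(0, 40, size=(30, 6))
        df = _df(y, tissue_columns)
        perm = y[:, [2, 0, 1, 4, 5, 3]]  # permute reps within each library
        df2 = _df(perm, tissue_columns)
        f = pd.Series(1.0, index=tissue_columns)
        assert np.allclose(
            nb_exact_test(df, f, "t1")["p"], nb_exact_test(df2, f, "t1")["p"]
        )


class TestGlmTest:
    def test_strong_signal(self, tissue_columns):
        df = _df([[30, 28, 32, 0, 1, 0]], tissue_columns)
        res = nb_glm_test(df, pd.Series(1.0, index=tissue_columns), "t1")
        assert res["log2fc"].iloc[0] >= 4
        assert res["p"].iloc[0] < 1e-4

    def test_null_symmetry(self, tissue_columns):
        df = _df([[10, 10, 10, 10, 10, 10]], tissue_columns)
        res = nb_glm_test(df, pd.Series(1.0, index=tissue_columns), "t1")
        assert abs(res["log2fc"].iloc[0]) < 0.1
        assert res["p"].iloc[0] > 0.5

    def test_scale_equivariance_of_log2fc(self, tissue_columns):
        rng = np.random.default_rng(34)
        y = rng.integers(1, 60, size=(100, 6))
        f = pd.Series(1.0, index=tissue_columns)
        r1 = nb_glm_test(_df(y, tissue_columns), f, "t1")
        r2 = nb_glm_test(_df(2 * y, tissue_columns), f, "t1")
        assert np.allclose(r1["log2fc"], r2["log2fc"], atol=1e-6)

    def test_wald_p_consistent_with_parametric_bootstrap(self, tissue_columns):
        # null tags at the fitted parameters: p should be roughly uniform
        rng = np.random.default_rng(35)
        y = draw_nb(rng, 30.0, 0.05, (400, 6))
        res = nb_glm_test(_df(y, tissue_columns), pd.Series(1.0, index=tissue_columns), "t1")
        assert (res["p"] < 0.05).mean() < 0.12  # not badly anti-conservative


class TestBH:
    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(36)
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            got = bh_adjust(p)
            # step-up oracle
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, p[i] * m / rank)
                adj[i] = val
                prev = val
            assert np.allclose(got, adj)


class TestCallMethylation:
    def test_fold_change_gate(self, tissue_columns):
        # a minority of tags with a strong but sub-2-fold MspI excess:
        # significant p-values, yet the FC gate must keep them uncalled
        rng = np.random.default_rng(37)
        shifted = np.arange(400) < 80
        ym = rng.poisson(300, size=(400, 3))
        yh = rng.poisson(np.where(shifted, 180, 300)[:, None], size=(400, 3))
        df = _df(np.hstack([ym, yh]), tissue_columns)
        calls = call_methylation(df, CallerParams(), "t1")
        frame = caller.calls_to_frame(calls)
        sig = (frame.fdr_exact <= 0.05) & (frame.fdr_glm <= 0.05)
        assert sig[shifted].mean() > 0.5  # significance is there...
        assert not (frame.status == "methylated").any()  # ...but the FC gate holds

    def test_dual_test_never_calls_more_than_single_test(self, tissue_columns):
        rng = np.random.default_rng(38)
        meth = rng.random(300) < 0.2
        ym = draw_nb(rng, 30.0, 0.05, (300, 3))
        yh = draw_nb(rng, np.where(meth, 2.0, 30.0)[:, None], 0.05, (300, 3))
        df = _df(np.hstack([ym, yh]), tissue_columns)
        calls = call_methylation(df, CallerParams(), "t1")
        frame = caller.calls_to_frame(calls)
        called = frame.status == "methylated"
        one_test = (frame.fdr_exact <= 0.05) & (
            frame.log2_fold_change >= 1
        )
        assert called.sum() <= one_test.sum()
        assert (called <= one_test).all()

    def test_reverse_direction_labels(self, tissue_columns):
        df = _df([[0, 1, 0, 30, 28, 32]], tissue_columns)
        params = CallerParams(direction="HpaII_over_MspI")
        calls = call_methylation(
            df, params, "t1", factors=pd.Series(1.0, index=tissue_columns)
        )
        assert calls[0].status == "reverse_significant"

    def test_single_replicate_rejected(self):
        cols = pd.MultiIndex.from_tuples(
            [("t1", "rep1", "MspI"), ("t1", "rep1", "HpaII")],
            names=["tissue", "replicate", "library"],
        )
        df = _df([[5, 5]], cols)
        with pytest.raises(ValueError, match="replicates"):
            call_methylation(df, CallerParams(), "t1")


class TestParameterGrid:
    def _tags(self, index):
        return [
            MSDTag(t, "c1", "+", 101 + i * 500, 200 + i * 500, 100 + i * 500,
                   f"c1:{199 + i * 500}")
            for i, t in enumerate(index)
        ]

    def test_grid_cardinality(self, tissue_columns):
        rng = np.random.default_rng(39)
        y = draw_nb(rng, 30.0, 0.05, (60, 6))
        df = _df(y, tissue_columns)
        tags = self._tags(df.index)
        states = {t.msd_site_id: "unmethylated" for t in tags}
        rows, _ = evaluate_parameter_grid(df, tags, states, "t1")
        assert len(rows) == 18

    def test_single_combination_selected(self, tissue_columns):
        rng = np.random.default_rng(40)
        meth = np.arange(60) < 10
        ym = draw_nb(rng, 30.0, 0.05, (60, 3))
        yh = draw_nb(rng, np.where(meth, 2.0, 30.0)[:, None], 0.05, (60, 3))
        df = _df(np.hstack([ym, yh]), tissue_columns)
        tags = self._tags(df.index)
        states = {
            t.msd_site_id: ("fully_methylated" if m else "unmethylated")
            for t, m in zip(tags, meth)
        }
        rows, sel = evaluate_parameter_grid(
            df, tags, states, "t1",
            fdr_values=(0.05,), fc_values=(2.0,), min_count_values=(3,),
        )
        assert len(rows) == 1
        assert (sel.fdr_max, sel.min_count) == (0.05, 3)

    def test_loose_fc_adding_false_positives_is_not_selected(self, tissue_columns):
        # planted truth where FC>=2 separates cleanly; FC>=1 admits a block of
        # highly significant sub-2-fold shifts that are not methylated
        rng = np.random.default_rng(41)
        n = 300
        meth = np.arange(n) < 30
        shifted = (~meth) & (np.arange(n) < 90)
        mean_h = np.where(meth, 300 / 16, np.where(shifted, 180.0, 300.0))
        ym = draw_nb(rng, 300.0, 0.01, (n, 3))
        yh = draw_nb(rng, mean_h[:, None], 0.01, (n, 3))
        df = _df(np.hstack([ym, yh]), tissue_columns)
        tags = self._tags(df.index)
        states = {
            t.msd_site_id: ("fully_methylated" if m else "unmethylated")
            for t, m in zip(tags, meth)
        }
        rows, sel = evaluate_parameter_grid(
            df, tags, states, "t1", fdr_values=(0.05,), fc_values=(1.0, 2.0),
            min_count_values=(3,),
        )
        assert sel.min_log2_fold_change == pytest.approx(1.0)

    def test_row_invariants(self, tissue_columns):
        rng = np.random.default_rng(42)
        y = draw_nb(rng, 30.0, 0.05, (60, 6))
        df = _df(y, tissue_columns)
        tags = self._tags(df.index)
        states = {t.msd_site_id: "fully_methylated" for t in tags[:30]}
        rows, _ = evaluate_parameter_grid(df, tags, states, "t1")
        for r in rows:
            assert r.n_confirmed <= r.n_covered_by_wgbs <= r.n_called
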