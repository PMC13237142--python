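"""Moderated differential testing, imputation, three-way ANOVA, clustering."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kdprof.differential import (
    IntensityMatrix,
    build_intensity_matrix,
    cluster_heatmap_input,
    dynamic_cutoff,
    estimate_prior,
    filter_min_replicates,
    median_normalize,
    minprob_impute,
    moderated_test,
    squeeze_variances,
    three_way_anova,
    trigamma_inverse,
)


def _matrix(values, probes, fractions=None, metals=None):
    """Assemble an IntensityMatrix from an array and per-sample labels."""
    n = values.shape[1]
    fractions = fractions or ["nuclear"] * n
    metals = metals or ["Mg"] * n
    reps = []
    seen = {}
    for key in zip(probes, fractions, metals):
        seen[key] = seen.get(key, 0) + 1
        reps.append(seen[key])
    labels = [f"{p}_{f}-{m}_rep{r}" for p, f, m, r in zip(probes, fractions, metals, reps)]
    samples = pd.DataFrame(
        {"probe": probes, "fraction": fractions, "metal": metals, "replicate": reps},
        index=pd.Index(labels, name="sample"),
    )
    values = pd.DataFrame(
        values, index=[f"P{i}" for i in range(values.shape[0])], columns=labels
    )
    return IntensityMatrix(values, samples)


def _two_group(values):
    n = values.shape[1] // 2
    return _matrix(values, ["A"] * n + ["B"] * (values.shape[1] - n))


class TestMedianNormalize:
    def test_sample_medians_are_equalized(self, rng):
        m = _two_group(rng.normal(0, 1, (40, 6)) + np.arange(6))
        out = median_normalize(m)
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_idempotent_when_already_equal(self, rng):
        m = _two_group(rng.normal(0, 1, (40, 6)))
        once = median_normalize(m)
        twice = median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_degenerate_column_passes_through_with_warning(self, rng):
        values = rng.normal(0, 1, (10, 4))
        values[:, 0] = np.nan
        m = _two_group(values)
        with pytest.warns(UserWarning, match="left unshifted"):
            out = median_normalize(m)
        assert out.values.iloc[:, 0].isna().all()


class TestModeratedTest:
    def test_equal_variances_reduce_to_ordinary_t(self, rng):
        # identical residual pattern per protein -> identical variances ->
        # complete pooling to that same variance is a no-op
        base = rng.normal(0, 1, 6)
        base -= base[:3].mean() * np.r_[1, 1, 1, 0, 0, 0] + base[3:].mean() * np.r_[0, 0, 0, 1, 1, 1]
        deltas = rng.normal(0, 2, (30, 1)) * np.r_[1, 1, 1, 0, 0, 0][None, :]
        m = _two_group(base[None, :] + deltas)
        res = moderated_test(m, ("A", "B"))
        A, B = m.values.iloc[:, :3].to_numpy(), m.values.iloc[:, 3:].to_numpy()
        t_ref, _ = stats.ttest_ind(A, B, axis=1)
        np.testing.assert_allclose(res["moderated_t"], t_ref, rtol=1e-8)

    def test_zero_fold_change_gives_p_one(self):
        values = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (5, 1))
        values += np.random.default_rng(0).normal(0, 0.1, values.shape)
        values[0, 3:] = values[0, :3]  # exactly equal groups
        res = moderated_test(_two_group(values), ("A", "B")).set_index("protein_id")
        assert res.loc["P0", "moderated_t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["P0", "p_value"] == pytest.approx(1.0)

    def test_global_null_is_calibrated(self, rng):
        m = _two_group(rng.normal(0, 1, (2000, 6)))
        res = moderated_test(m, ("A", "B"))
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_unknown_contrast_level_rejected(self, rng):
        m = _two_group(rng.normal(0, 1, (5, 6)))
        with pytest.raises(ValueError, match="not found"):
            moderated_test(m, ("A", "Z"))

    def test_matches_limma_oracle(self, rng, tmp_path):
        """Independent cross-check against the reference R implementation."""
        data = rng.normal(0, 1, (60, 6)) * rng.uniform(0.5, 2.0, (60, 1))
        data[:10, :3] += 2.0
        mat_path = tmp_path / "mat.csv"
        pd.DataFrame(data, index=[f"P{i}" for i in range(60)]).to_csv(mat_path)
        script = tmp_path / "oracle.R"
        out_path = tmp_path / "out.csv"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'm <- as.matrix(read.csv("{mat_path}", row.names=1))\n'
            "design <- cbind(Intercept=1, A=c(1,1,1,0,0,0))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            'out <- data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"])\n'
            f'write.csv(out, "{out_path}")\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"R/limma oracle unavailable: {proc.stderr[:200]}")
        oracle = pd.read_csv(out_path, index_col=0)
        res = moderated_test(_two_group(data), ("A", "B")).set_index("protein_id")
        np.testing.assert_allclose(res["moderated_t"], oracle["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p_value"], oracle["p"], rtol=1e-8)


class TestModerationLimits:
    def test_d0_zero_recovers_ordinary_variance(self, rng):
        s2 = rng.uniform(0.5, 2.0, 50)
        df = np.full(50, 4.0)
        np.testing.assert_allclose(squeeze_variances(s2, df, 1e-12, 1.0), s2, rtol=1e-10)

    def test_d0_infinite_pools_completely(self, rng):
        s2 = rng.uniform(0.5, 2.0, 50)
        df = np.full(50, 4.0)
        assert (squeeze_variances(s2, df, np.inf, 0.7) == 0.7).all()

    def test_homogeneous_variances_give_infinite_prior_df(self):
        d0, s0 = estimate_prior(np.full(100, 1.3), np.full(100, 4.0))
        assert np.isinf(d0)
        assert s0 == pytest.approx(1.3, rel=1e-9)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-8)


class TestDynamicCutoff:
    def test_symmetric_null_gives_symmetric_thresholds(self, rng):
        x = rng.normal(0, 1, 500)
        x = np.concatenate([x, -x])
        lo, hi, fallback = dynamic_cutoff(x)
        assert not fallback
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_zero_mad_falls_back_to_static(self):
        with pytest.warns(UserWarning, match="MAD"):
            _, _, fallback = dynamic_cutoff(np.zeros(100))
        assert fallback

    def test_too_few_results_fall_back(self):
        with pytest.warns(UserWarning, match="too few"):
            _, _, fallback = dynamic_cutoff(np.arange(10.0))
        assert fallback

    def test_strong_responders_exceed_threshold(self, rng):
        null = rng.normal(0, 0.3, 950)
        responders = rng.normal(4.0, 0.3, 50)
        lo, hi, fallback = dynamic_cutoff(np.concatenate([null, responders]))
        assert not fallback
        assert (responders > hi).all()


class TestMinProbImputation:
    def test_complete_matrix_returned_unchanged(self, rng):
        m = _two_group(rng.normal(20, 1, (30, 6)))
        out = minprob_impute(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_seeded_and_reproducible(self, rng):
        values = rng.normal(20, 1, (50, 6))
        values[rng.random(values.shape) < 0.2] = np.nan
        m = _two_group(values)
        out1 = minprob_impute(m, seed=11)
        out2 = minprob_impute(m, seed=11)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert not out1.values.isna().any().any()

    def test_imputed_values_center_on_low_quantile(self, rng):
        values = rng.normal(20, 2, (4000, 6))
        mask = rng.random(values.shape) < 0.15
        m = _two_group(np.where(mask, np.nan, values))
        out = minprob_impute(m, q=0.01, tune_sigma=1.0, seed=3)
        imputed = out.values.to_numpy()[mask]
        col_q = np.nanquantile(np.where(mask, np.nan, values), 0.01, axis=0)
        sigma = out.values.to_numpy()[~mask].std()
        assert imputed.mean() == pytest.approx(
            col_q.mean(), abs=3 * sigma / np.sqrt(mask.sum())
        )

    def test_all_missing_sample_is_an_error(self, rng):
        values = rng.normal(20, 1, (10, 6))
        values[:, 2] = np.nan
        with pytest.raises(ValueError, match="rep3|sample"):
            minprob_impute(_two_group(values), seed=0)


def _full_factorial(n_proteins, rng, effect=None):
    """4 compounds x 2 fractions x 2 metals x 3 reps = 48 samples."""
    probes, fractions, metals = [], [], []
    for p in ("c1", "c2", "c3", "c4"):
        for f in ("cytosolic", "nuclear"):
            for m in ("EDTA", "Mg"):
                for _ in range(3):
                    probes.append(p)
                    fractions.append(f)
                    metals.append(m)
    values = rng.normal(0, 1, (n_proteins, len(probes)))
    if effect == "compound":
        values[:, np.array(probes) == "c1"] += 5.0
    elif effect == "metal":
        values[:, np.array(metals) == "Mg"] += 5.0
    return _matrix(values, probes, fractions, metals)


class TestThreeWayAnova:
    def test_compound_only_effect_is_compound_specific(self, rng):
        m = _full_factorial(20, rng, effect="compound")
        res = three_way_anova(m)
        assert res["compound_specific"].all()
        assert (res["q_fraction"] >= 0.05).all()

    def test_metal_responder_is_not_compound_specific(self, rng):
        m = _full_factorial(20, rng, effect="metal")
        res = three_way_anova(m)
        assert not res["compound_specific"].any()

    def test_null_per_factor_p_is_calibrated(self, rng):
        res = three_way_anova(_full_factorial(2000, rng))
        for factor in ("compound", "fraction", "treatment"):
            assert (res[f"p_{factor}"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        m = _full_factorial(5, rng)
        res = three_way_anova(m)
        for i in range(5):
            df = m.samples.copy()
            df["y"] = m.values.iloc[i].to_numpy()
            fit = smf.ols("y ~ C(probe) + C(fraction) + C(metal)", data=df).fit()
            tab = anova_lm(fit, typ=2)
            assert res.loc[i, "F_compound"] == pytest.approx(tab.loc["C(probe)", "F"])
            assert res.loc[i, "p_fraction"] == pytest.approx(tab.loc["C(fraction)", "PR(>F)"])
            assert res.loc[i, "F_treatment"] == pytest.approx(tab.loc["C(metal)", "F"])

    def test_incomplete_matrix_rejected(self, rng):
        m = _full_factorial(5, rng)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            three_way_anova(m)

    def test_missing_factor_level_rejected(self, rng):
        m = _two_group(rng.normal(0, 1, (5, 6)))
        with pytest.raises(ValueError, match="missing level"):
            three_way_anova(m)


class TestClustering:
    def test_row_z_scores(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 6.0]], index=["a", "b"])
        res = cluster_heatmap_input(values)
        np.testing.assert_allclose(res.zscores.loc["a"], [-1, 0, 1])
        assert abs(res.zscores.loc["a"].mean()) < 1e-12
        assert abs(res.zscores.loc["a"].std(ddof=1) - 1) < 1e-12

    def test_identical_rows_merge_at_height_zero(self, rng):
        base = rng.normal(0, 1, 5)
        values = pd.DataFrame([base, base, base + rng.normal(0, 5, 5)])
        res = cluster_heatmap_input(values)
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_complete_linkage_matches_hand_computation(self):
        # 1-D points 0, 1, 4, 10 in a single column (plus a zero column so
        # z-scoring is bypassed by passing pre-standardized data directly)
        from scipy.cluster import hierarchy

        pts = np.array([[0.0], [1.0], [4.0], [10.0]])
        link = hierarchy.linkage(pts, method="complete", metric="euclidean")
        # merges: {0,1}@1, then with {4}@4, then with {10}@10
        np.testing.assert_allclose(link[:, 2], [1.0, 4.0, 10.0])

    def test_zero_variance_row_excluded(self, rng):
        values = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        values.iloc[2] = 7.0
        res = cluster_heatmap_input(values)
        assert res.excluded == [2]
        assert 2 not in res.row_order

    def test_needs_two_rows_and_columns(self):
        with pytest.raises(ValueError):
            cluster_heatmap_input(pd.DataFrame([[1.0, 2.0]]))


class TestMatrixConstruction:
    def test_extracts_single_concentration_channel(self, noisy_dataset, single_probe_design):
        table, _ = noisy_dataset
        m = build_intensity_matrix(table)
        channel = single_probe_design.n_channels - 2  # 33.3 uM is one step down
        expected = np.log2(
            table.data[channel]
            .unstack(["probe", "fraction", "metal", "replicate"])
            .to_numpy()
        )
        np.testing.assert_allclose(m.values.to_numpy(), expected)

    def test_two_of_three_replicate_gate(self, rng):
        values = rng.normal(20, 1, (3, 6))
        values[0, :] = np.nan  # never quantified
        values[1, [0, 1, 3, 4]] = np.nan  # 1 of 3 in A, 1 of 3 in B -> drop
        values[2, [0, 5]] = np.nan  # 2 of 3 in A -> keep
        m = filter_min_replicates(_two_group(values))
        assert list(m.values.index) == ["P2"]
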