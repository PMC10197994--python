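import numpy as np
import pandas as pd
import pytest

from cdpksurvey import expression as ex


def _mat(values, samples=None, genes=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"0H_r{i+1}" for i in range(values.shape[1])]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFpkm:
    def test_closed_form_ten(self):
        counts = _mat([[10]])
        out = ex.fpkm(counts, pd.Series({"g0": 1000}),
                      pd.Series({"0H_r1": 1_000_000.0}))
        assert out.values.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_counts_give_zero(self):
        out = ex.fpkm(_mat([[0]]), pd.Series({"g0": 500}),
                      pd.Series({"0H_r1": 2e6}))
        assert out.values.iloc[0, 0] == 0.0

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(0)
        counts = _mat(rng.integers(0, 1000, size=(6, 4)))
        lengths = pd.Series(rng.integers(300, 3000, size=6).astype(float),
                            index=counts.index)
        libs = pd.Series(rng.uniform(5e5, 2e6, size=4), index=counts.columns)
        out = ex.fpkm(counts, lengths, libs)
        for g in counts.index:
            for s in counts.columns:
                expected = 1e9 * counts.loc[g, s] / (libs[s] * lengths[g])
                assert out.values.loc[g, s] == pytest.approx(expected)

    def test_linear_in_counts_inverse_in_length(self):
        counts = _mat([[100]])
        libs = pd.Series({"0H_r1": 1e6})
        a = ex.fpkm(counts, pd.Series({"g0": 1000}), libs).values.iloc[0, 0]
        b = ex.fpkm(counts * 3, pd.Series({"g0": 1000}), libs).values.iloc[0, 0]
        c = ex.fpkm(counts, pd.Series({"g0": 2000}), libs).values.iloc[0, 0]
        assert b == pytest.approx(3 * a)
        assert c == pytest.approx(a / 2)

    def test_zero_library_size_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            ex.fpkm(_mat([[1]]), pd.Series({"g0": 100}),
                    pd.Series({"0H_r1": 0.0}))


class TestFilter:
    def _fpkm(self, values, **kw):
        return ex.ExpressionMatrix(_mat(values, **kw), "FPKM")

    def test_exactly_one_everywhere_is_dropped(self):
        mat = self._fpkm([[1.0, 1.0, 1.0]])
        assert ex.filter_expressed(mat) == []

    def test_single_sample_above_threshold_keeps_gene(self):
        mat = self._fpkm([[0.0, 5.0, 0.2]])
        assert ex.filter_expressed(mat) == ["g0"]

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(1)
        mat = self._fpkm(rng.uniform(0, 10, size=(20, 5)))
        prev = None
        for t in (0.5, 1.0, 2.0, 5.0):
            kept = set(ex.filter_expressed(mat, t))
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_synthetic_expressed_set_matches_manifest(self, bundle):
        mat = ex.fpkm(
            ex.read_counts(bundle.counts_path),
            ex.read_lengths(bundle.lengths_path),
            ex.read_library_sizes(bundle.library_sizes_path),
        )
        assert set(ex.filter_expressed(mat)) == set(
            bundle.manifest.expressed_genes
        )


class TestTransform:
    def test_constant_gene_becomes_zero_row_with_warning(self):
        mat = ex.ExpressionMatrix(_mat([[5.0, 5.0, 5.0], [1, 2, 4]]), "FPKM")
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ex.log2_center_scale(mat)
        assert (out.iloc[0] == 0).all()

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        mat = ex.ExpressionMatrix(_mat(rng.uniform(0, 50, (10, 8))), "FPKM")
        out = ex.log2_center_scale(mat)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, (5, 6))
        mat = ex.ExpressionMatrix(_mat(vals), "FPKM")
        out = ex.log2_center_scale(mat)
        for i in range(5):
            row = np.log2(vals[i] + 1)
            mean = row.sum() / len(row)
            sd = (((row - mean) ** 2).sum() / (len(row) - 1)) ** 0.5
            assert np.allclose(out.iloc[i], (row - mean) / sd)


class TestCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 10, 6)
        vals = np.vstack([base, base, rng.uniform(0, 10, 6)])
        order, z = ex.cluster_genes(_mat(vals))
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(map(int, z[0, :2])) == {0, 1}

    def test_anticorrelated_blocks_split_at_top(self):
        rng = np.random.default_rng(5)
        up = np.linspace(0, 1, 8)
        vals = [up + rng.normal(0, 0.01, 8) for _ in range(4)]
        vals += [up[::-1] + rng.normal(0, 0.01, 8) for _ in range(4)]
        order, z = ex.cluster_genes(_mat(np.array(vals)))
        block = {order.index(f"g{i}") < 4 for i in range(4)}
        assert len(block) == 1  # first block contiguous in leaf order

    def test_row_permutation_gives_same_merge_heights(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 10, (8, 5))
        _, z1 = ex.cluster_genes(_mat(vals))
        perm = rng.permutation(8)
        _, z2 = ex.cluster_genes(
            _mat(vals[perm], genes=[f"g{i}" for i in perm])
        )
        assert np.allclose(sorted(z1[:, 2]), sorted(z2[:, 2]))


class TestCalls:
    def test_identical_means_are_flat(self):
        mean = pd.DataFrame({"0H": [10.0], "30M": [10.0]}, index=["g0"])
        (call,) = ex.call_responses(mean)
        assert call.direction == ex.FLAT

    def test_fourfold_induction_closed_form(self):
        mean = pd.DataFrame({"0H": [10.0], "30M": [40.0]}, index=["g0"])
        (call,) = ex.call_responses(mean)
        assert call.log2_fold_change == pytest.approx(np.log2(41 / 11))
        assert call.direction == ex.UP

    def test_missing_control_is_error(self):
        mean = pd.DataFrame({"30M": [1.0]}, index=["g0"])
        with pytest.raises(ValueError, match="control"):
            ex.call_responses(mean)


class TestDeltaDeltaCt:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "timepoint", "replicate", "ct_target",
                     "ct_reference"],
        )

    def test_zero_ddct_gives_fold_one(self):
        t = self._table(
            [["g", "0H", 1, 25.0, 18.0], ["g", "30M", 1, 25.0, 18.0]]
        )
        folds = ex.delta_delta_ct(t)
        assert folds.loc["g", "30M"] == pytest.approx(1.0)

    def test_minus_five_ddct_gives_fold_thirty_two(self):
        t = self._table(
            [["g", "0H", 1, 25.0, 18.0], ["g", "30M", 1, 20.0, 18.0]]
        )
        folds = ex.delta_delta_ct(t)
        assert folds.loc["g", "30M"] == pytest.approx(32.0)

    def test_control_column_is_exactly_one(self, bundle):
        folds = ex.delta_delta_ct(ex.read_ct_table(bundle.ct_path))
        assert (folds["0H"] == 1.0).all()

    def test_missing_control_rows_name_the_gene(self):
        t = self._table([["gX", "30M", 1, 20.0, 18.0],
                         ["gY", "0H", 1, 25.0, 18.0],
                         ["gY", "30M", 1, 24.0, 18.0]])
        with pytest.raises(ValueError, match="gX"):
            ex.delta_delta_ct(t)

    def test_noisy_recovery_consistent_with_monte_carlo_propagation(
        self, bundle
    ):
        # oracle: simulate Gaussian Ct noise through the 2^-ddCt estimator
        # to predict the fraction of fold estimates within 20% of truth
        cfg = bundle.config
        rng = np.random.default_rng(0)
        sd, reps, n_mc = cfg.ct_noise_sd, cfg.replicates, 20_000
        dct_t = rng.normal(0, sd, (n_mc, reps)).mean(1) - rng.normal(
            0, sd, (n_mc, reps)
        ).mean(1)
        dct_c = rng.normal(0, sd, (n_mc, reps)).mean(1) - rng.normal(
            0, sd, (n_mc, reps)
        ).mean(1)
        err = 2.0 ** -(dct_t - dct_c)
        predicted = np.mean(np.abs(err - 1) <= 0.2)

        folds = ex.delta_delta_ct(ex.read_ct_table(bundle.ct_path))
        hits = total = 0
        for gene, per_tp in bundle.manifest.planted_ddct.items():
            for tp, ddct in per_tp.items():
                if tp == "0H":
                    continue
                total += 1
                truth = 2.0 ** -ddct
                hits += abs(folds.loc[gene, tp] - truth) <= 0.2 * truth
        # binomial slack around the Monte-Carlo prediction at this sample size
        assert hits / total >= predicted - 0.15
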