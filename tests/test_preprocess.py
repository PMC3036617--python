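import numpy as np
import pandas as pd
import pytest

from conftest import make_expression
from zdimorph.preprocess import (
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    sample_qc,
)
from zdimorph.data_model import ArrayDesign, SampleSheet


def polish_oracle(x, tol=1e-10, max_iter=500):
    """Independent, naive median polish (same sweep order, run to convergence)."""
    x = np.asarray(x, dtype=float)
    nr, nc = x.shape
    r = x.copy()
    row = np.zeros(nr)
    col = np.zeros(nc)
    for it in range(max_iter):
        biggest = 0.0
        for j in range(nc):
            m = float(np.median([r[i][j] for i in range(nr)]))
            col[j] += m
            for i in range(nr):
                r[i][j] -= m
            biggest = max(biggest, abs(m))
        for i in range(nr):
            m = float(np.median([r[i][j] for j in range(nc)]))
            row[i] += m
            for j in range(nc):
                r[i][j] -= m
            biggest = max(biggest, abs(m))
        if it > 0 and biggest < tol:
            break
    overall = float(np.median(row))
    return overall, row - overall, col, r


def tiny_design(probe_lists):
    return ArrayDesign(
        pd.DataFrame(
            {
                "probe_ids": [tuple(p) for p in probe_lists],
                "gene_id": [None] * len(probe_lists),
                "chromosome": ["none"] * len(probe_lists),
                "evalue": [np.nan] * len(probe_lists),
            },
            index=pd.Index([f"e{i}" for i in range(len(probe_lists))], name="est_id"),
        )
    )


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        m = make_expression(np.tile([[1.0], [5.0], [2.0]], (1, 4)))
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_two_point_symmetric_case(self):
        m = make_expression([[1.0, 3.0], [2.0, 4.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), [[2.0, 2.0], [3.0, 3.0]])

    def test_defining_property_on_random_matrix(self, rng):
        m = make_expression(rng.gamma(3.0, 2.0, size=(50, 4)))
        out = quantile_normalize(m)
        target = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        for j in range(4):
            np.testing.assert_allclose(np.sort(out.to_numpy()[:, j]), target)
        assert np.isclose(out.to_numpy().sum(), m.to_numpy().sum())

    def test_idempotent(self, rng):
        m = make_expression(rng.lognormal(3, 1, size=(80, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9, rtol=0)

    def test_ties_share_mean_of_target_values(self):
        # column 0 has a tie at its two lowest entries
        m = make_expression([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(m)
        target = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        np.testing.assert_allclose(out.iloc[0, 0], (target[0] + target[1]) / 2)
        np.testing.assert_allclose(out.iloc[1, 0], (target[0] + target[1]) / 2)

    def test_single_column_is_identity_with_warning(self):
        m = make_expression([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single column"):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestMedianPolish:
    def test_single_probe_table_passes_through(self):
        # the additive model collapses when there is only one probe row
        y = np.array([[2.0, 4.0, 8.0]])
        overall, row, col, resid = median_polish(y[None, :, :])
        np.testing.assert_allclose(overall[:, None] + col, y)
        np.testing.assert_allclose(resid, 0.0)

    def test_constant_matrix_gives_log2_constant(self):
        design = tiny_design([[f"p{i}" for i in range(8)]])
        m = pd.DataFrame(
            np.full((8, 3), 16.0),
            index=[f"p{i}" for i in range(8)],
            columns=["s0", "s1", "s2"],
        )
        expr = median_polish_summarize(m, design)
        np.testing.assert_allclose(expr.to_numpy(), 4.0)

    def test_matches_independent_oracle_on_toy_tables(self, rng):
        for _ in range(10):
            y = rng.normal(8, 1, size=(3, 3))
            overall, row, col, resid = median_polish(y[None], tol=1e-10, max_iter=500)
            o_overall, o_row, o_col, o_resid = polish_oracle(y)
            np.testing.assert_allclose(overall[0] + col[0], o_overall + o_col, atol=1e-8)

    def test_residual_medians_small_at_convergence(self, rng):
        y = rng.normal(0, 1, size=(5, 11, 12))
        _, _, _, resid = median_polish(y, tol=0.01, max_iter=10)
        assert np.abs(np.median(resid, axis=1)).max() <= 0.01 + 1e-12
        assert np.abs(np.median(resid, axis=2)).max() <= 0.01 + 1e-12

    def test_summarization_equivariant_under_per_sample_shift(self, small_experiment):
        sp = small_experiment.config.species_labels[0]
        m = small_experiment.probes[sp]
        expr = median_polish_summarize(m, small_experiment.design)
        shifted = m.copy()
        c = 1.75
        shifted[shifted.columns[2]] *= 2.0**c  # +c on the log2 scale
        expr_shift = median_polish_summarize(shifted, small_experiment.design)
        delta = (expr_shift - expr).to_numpy()
        np.testing.assert_allclose(delta[:, 2], c, atol=1e-9)
        np.testing.assert_allclose(np.delete(delta, 2, axis=1), 0.0, atol=1e-9)

    def test_reconstruction_identity(self, rng):
        y = rng.normal(0, 1, size=(4, 9, 6))
        overall, row, col, resid = median_polish(y)
        fit = overall[:, None, None] + row[:, :, None] + col[:, None, :] + resid
        np.testing.assert_allclose(fit, y, atol=1e-12)


class TestSampleQC:
    def _sheet(self, ids, species="sp"):
        return SampleSheet(
            pd.DataFrame(
                {
                    "species": species,
                    "sex": ["male", "female"] * (len(ids) // 2) + ["male"] * (len(ids) % 2),
                    "population": "",
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )

    def test_duplicated_columns_have_correlation_one_and_no_flags(self, rng):
        base = rng.normal(8, 1, size=200)
        m = make_expression(np.column_stack([base, base, base]), samples=["a", "b", "c"])
        report = sample_qc(m, self._sheet(["a", "b", "c"]))
        assert report.flagged == []
        corr = report.correlations["sp"].to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_noise_sample_flagged(self, rng):
        # enough good replicates that one bad sample cannot drag their own
        # mean replicate correlation below the threshold
        base = rng.normal(8, 1, size=500)
        ids = [f"g{i}" for i in range(12)]
        cols = [base + rng.normal(0, 0.05, 500) for _ in ids]
        cols.append(rng.normal(8, 1, size=500))  # unrelated sample
        ids.append("bad")
        m = make_expression(np.column_stack(cols), samples=ids)
        report = sample_qc(m, self._sheet(ids), threshold=0.9)
        assert report.flagged == ["bad"]

    def test_zero_threshold_never_flags(self, rng):
        m = make_expression(rng.normal(0, 1, size=(50, 4)), samples=list("abcd"))
        report = sample_qc(m, self._sheet(list("abcd")), threshold=0.0)
        assert report.flagged == []
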