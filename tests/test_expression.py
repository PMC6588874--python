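import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncweave.expression import (
    CountMatrix,
    DEThresholds,
    bh_adjust,
    call_de,
    estimate_dispersion,
    fpkm,
    nb_exact_test,
    tmm_factors,
)
from lncweave.synthetic import GroundTruth, SyntheticConfig, gen_counts, standard_comparisons


def make_cm(counts, groups=None, lengths=None):
    df = pd.DataFrame(counts)
    groups = groups or {c: c.split("_")[0] for c in df.columns}
    lengths = lengths if lengths is not None else pd.Series(1000.0, index=df.index)
    return CountMatrix(df, groups, lengths)


class TestFPKM:
    def test_formula_worked_example(self):
        """count 10, length 1000 bp, library 1e6 -> FPKM 10."""
        cm = make_cm(
            {"A_1": [10, 1_000_000 - 10], "B_1": [10, 1_000_000 - 10]},
            lengths=pd.Series([1000.0, 500.0]),
        )
        out = fpkm(cm)
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_all_zero_gene_is_zero_everywhere(self):
        cm = make_cm({"A_1": [0, 5], "B_1": [0, 7]})
        assert (fpkm(cm).iloc[0] == 0).all()

    def test_library_scale_invariance(self):
        cm1 = make_cm({"A_1": [10, 90], "B_1": [20, 80]})
        cm2 = make_cm({"A_1": [20, 180], "B_1": [20, 80]})
        pd.testing.assert_frame_equal(fpkm(cm1), fpkm(cm2))

    def test_zero_total_sample_errors_naming_sample(self):
        cm = make_cm({"A_1": [0, 0], "B_1": [1, 1]})
        with pytest.raises(ValueError, match="A_1"):
            fpkm(cm)

    def test_aggregate_identity(self):
        """Sum_g FPKM * length / 1e9 * total == total (formula algebra)."""
        rng = np.random.default_rng(0)
        cm = make_cm(
            {"A_1": rng.integers(0, 500, 50), "B_1": rng.integers(0, 500, 50)},
            lengths=pd.Series(rng.integers(200, 5000, 50).astype(float)),
        )
        out = fpkm(cm)
        totals = cm.counts.sum(axis=0)
        recon = out.mul(cm.lengths, axis=0).mul(totals, axis=1) / 1e9
        pd.testing.assert_frame_equal(recon, cm.counts.astype(float))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 1000, 200)
        f = tmm_factors(pd.DataFrame({"a": col, "b": col}))
        assert np.allclose(f, 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 1000, (500, 6)))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_pure_scaling_absorbed_by_library_size(self):
        """A 2x scaled copy has all M-values 0, so the factor ratio is 1."""
        rng = np.random.default_rng(3)
        col = rng.integers(1, 1000, 300)
        f = tmm_factors(pd.DataFrame({"a": col, "b": 2 * col}))
        assert f["a"] == pytest.approx(f["b"], rel=1e-9)


class TestDispersion:
    def _sim_cm(self, phi, seed, n=2000):
        rng = np.random.default_rng(seed)
        mu = np.maximum(np.exp(rng.normal(5, 1, n)), 10)
        if phi == 0:
            y = rng.poisson(mu[:, None], size=(n, 6))
        else:
            r = 1 / phi
            y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 6))
        return make_cm(pd.DataFrame(
            y.astype(float), columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
        ))

    def test_poisson_data_yields_near_zero_dispersion(self):
        cm = self._sim_cm(0.0, seed=4)
        assert float(estimate_dispersion(cm).median()) <= 0.05

    def test_nb_dispersion_recovered(self):
        cm = self._sim_cm(0.2, seed=5)
        assert 0.1 <= float(estimate_dispersion(cm).median()) <= 0.3

    def test_moment_estimate_floors_at_zero(self):
        """Var < mean in both groups floors the raw moment estimate at 0."""
        cm = make_cm({
            "A_1": [100.0], "A_2": [101.0], "A_3": [99.0],
            "B_1": [100.0], "B_2": [101.0], "B_3": [99.0],
        })
        assert float(estimate_dispersion(cm, n0=0.0, method="moments").iloc[0]) == 0.0


class TestExactTest:
    def test_identical_group_sums_give_p_one(self):
        lib = np.array([1e6] * 3)
        p = nb_exact_test([10, 10, 10], [10, 10, 10], lib, lib, 0.1)
        assert p == 1.0

    def test_reduces_to_conditional_binomial_at_phi_zero(self):
        """Small totals: enumerate the conditional binomial exactly."""
        lib = np.array([1.0])
        rng = np.random.default_rng(6)
        for _ in range(50):
            sa, sb = int(rng.integers(0, 16)), int(rng.integers(0, 16))
            if sa + sb == 0:
                continue
            t = sa + sb
            pmf = stats.binom.pmf(np.arange(t + 1), t, 0.5)
            want = pmf[pmf <= pmf[sa] * (1 + 1e-12)].sum()
            got = nb_exact_test([sa], [sb], lib, lib, 0.0)
            assert got == pytest.approx(min(1.0, want), rel=1e-9)

    def test_symmetric_under_group_swap(self):
        lib = np.array([1e6, 1.1e6, 0.9e6])
        a, b = [30, 45, 12], [99, 120, 80]
        assert nb_exact_test(a, b, lib, lib, 0.2) == pytest.approx(
            nb_exact_test(b, a, lib, lib, 0.2)
        )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], np.array([1.0]), np.array([1.0]), -0.1)

    def test_null_type_one_error_calibrated(self):
        """NB null (phi=0.1, 3v3): fraction of p <= 0.05 near nominal."""
        rng = np.random.default_rng(7)
        n = 800
        mu = np.maximum(np.exp(rng.normal(5, 1, n)), 10)
        r = 10.0
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 6))
        lib = y.sum(axis=0).astype(float)
        ps = np.array([
            nb_exact_test(y[i, :3], y[i, 3:], lib[:3], lib[3:], 0.1) for i in range(n)
        ])
        assert 0.02 <= (ps <= 0.05).mean() <= 0.08


class TestBH:
    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDE:
    def test_identical_counts_called_ns(self):
        cm = make_cm({
            "A_1": [50.0, 500], "A_2": [50.0, 500], "A_3": [50.0, 500],
            "B_1": [50.0, 500], "B_2": [50.0, 500], "B_3": [50.0, 500],
        })
        recs = call_de(cm, [("A", "B")])["A_vs_B"]
        assert all(r.call == "ns" for r in recs)

    def test_unknown_group_errors(self):
        cm = make_cm({"A_1": [1.0], "A_2": [2.0], "B_1": [1.0], "B_2": [2.0]})
        with pytest.raises(ValueError):
            call_de(cm, [("A", "Z")])

    def test_null_matrix_yields_almost_no_calls(self):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1000)],
            "length": 1000, "kind": "coding",
        })
        cfg = SyntheticConfig(seed=9, de_fraction=0.0, n_trans_pairs=0)
        cm, _ = gen_counts(cfg, genes, GroundTruth())
        recs = call_de(cm, [("BS", "WS")])["BS_vs_WS"]
        n_called = sum(r.call != "ns" for r in recs)
        assert n_called <= 0.01 * len(recs)

    def test_planted_de_recovered(self):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(800)],
            "length": 1000, "kind": "coding",
        })
        cfg = SyntheticConfig(seed=10, de_fraction=0.1, de_log2fc=2.0,
                              nb_dispersion=0.1, n_trans_pairs=0)
        truth = GroundTruth()
        cm, _ = gen_counts(cfg, genes, truth)
        de = call_de(cm, standard_comparisons(cfg.groups))
        for comp, recs in de.items():
            planted = truth.de_ids_by_comparison[comp]
            called = {r.gene_id: r.call for r in recs if r.call != "ns"}
            tp = sum(1 for g, d in called.items() if planted.get(g) == d)
            assert tp / len(planted) >= 0.8

    def test_log2fc_sign_negated_under_swap(self):
        cm = make_cm({
            "A_1": [200.0, 500], "A_2": [210.0, 500], "A_3": [190.0, 500],
            "B_1": [50.0, 500], "B_2": [55.0, 500], "B_3": [45.0, 500],
        })
        ab = call_de(cm, [("A", "B")])["A_vs_B"][0]
        ba = call_de(cm, [("B", "A")])["B_vs_A"][0]
        assert ab.log2fc == pytest.approx(-ba.log2fc)
        assert ab.p == pytest.approx(ba.p)
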