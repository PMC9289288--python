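import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gravirebound import diffexpr as D


def _oracle_size_factors(mat: np.ndarray) -> np.ndarray:
    """Independent re-implementation of median-of-ratios."""
    keep = (mat > 0).all(axis=1)
    ref = np.exp(np.mean(np.log(mat[keep]), axis=1))
    return np.array([np.median(mat[keep, j] / ref) for j in range(mat.shape[1])])


def _oracle_bh(p: np.ndarray) -> np.ndarray:
    """Brute-force BH from the definition fdr_i = min_{k: p_k >= p_i} m p_k / rank_k."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [m * p[k] / rank[k] for k in range(m) if p[k] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


def _sim_counts(rng, n_genes, means, disp, n_per_group=4):
    m = np.broadcast_to(np.asarray(means, dtype=float)[:, None], (n_genes, 2 * n_per_group))
    size = 1.0 / disp
    return pd.DataFrame(
        rng.negative_binomial(size, size / (size + m)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)],
    )


@pytest.fixture
def groups():
    return pd.Series(
        {f"A{i}": "A" for i in range(4)} | {f"B{i}": "B" for i in range(4)},
        name="condition",
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [5]], (1, 4)))
        sf = D.size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_doubles_its_factor(self):
        base = np.array([[10.0, 10, 10], [50, 50, 50], [7, 7, 7]])
        base[:, 2] *= 2
        sf = D.size_factors(pd.DataFrame(base))
        assert sf.iloc[2] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_independent_oracle(self, rng):
        mat = rng.integers(1, 500, size=(50, 6)).astype(float)
        sf = D.size_factors(pd.DataFrame(mat))
        assert np.allclose(sf.to_numpy(), _oracle_size_factors(mat))

    def test_no_always_positive_gene_is_error(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            D.size_factors(counts)


class TestDispersion:
    def test_poisson_data_gives_near_zero(self, rng, groups):
        counts = pd.DataFrame(
            rng.poisson(100, size=(500, 8)), columns=groups.index
        )
        sf = pd.Series(1.0, index=groups.index)
        d = D.estimate_dispersion(counts, sf, groups)
        assert d.median() < 0.01

    def test_recovers_simulated_dispersion(self, rng, groups):
        counts = _sim_counts(rng, 2000, np.full(2000, 200.0), 0.1)
        sf = pd.Series(1.0, index=groups.index)
        d = D.estimate_dispersion(counts, sf, groups)
        assert 0.05 <= d.median() <= 0.2

    def test_single_gene_skips_trend(self, rng, groups):
        counts = _sim_counts(rng, 1, [150.0], 0.05)
        sf = pd.Series(1.0, index=groups.index)
        d = D.estimate_dispersion(counts, sf, groups)
        assert len(d) == 1 and d.iloc[0] >= D.DISPERSION_FLOOR


class TestWaldContrast:
    def test_twofold_difference_gives_lfc_one(self, rng, groups):
        means = np.concatenate([np.full((300, 4), 200.0), np.full((300, 4), 100.0)], axis=1)
        size = 1 / 0.01
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + means)), columns=groups.index
        )
        sf = pd.Series(1.0, index=groups.index)
        disp = pd.Series(0.01, index=counts.index)
        res = D.nb_wald_contrast(counts, sf, disp, list(groups.index[:4]), list(groups.index[4:]))
        assert res["lfc"].mean() == pytest.approx(1.0, abs=0.05)
        assert (res["fdr"] < 0.05).mean() > 0.95

    def test_antisymmetry_is_exact(self, rng, groups):
        counts = _sim_counts(rng, 200, rng.uniform(20, 500, 200), 0.05)
        sf = D.size_factors(counts)
        disp = D.estimate_dispersion(counts, sf, groups)
        a = list(groups.index[:4])
        b = list(groups.index[4:])
        ab = D.nb_wald_contrast(counts, sf, disp, a, b)
        ba = D.nb_wald_contrast(counts, sf, disp, b, a)
        assert np.array_equal(ab["lfc"].to_numpy(), -ba["lfc"].to_numpy())
        assert np.array_equal(ab["p"].to_numpy(), ba["p"].to_numpy(), equal_nan=True)
        assert np.array_equal(ab["fdr"].to_numpy(), ba["fdr"].to_numpy(), equal_nan=True)

    def test_scaling_sample_with_its_size_factor_changes_nothing(self, rng, groups):
        counts = _sim_counts(rng, 200, rng.uniform(20, 500, 200), 0.05)
        sf = D.size_factors(counts)
        disp = D.estimate_dispersion(counts, sf, groups)
        a, b = list(groups.index[:4]), list(groups.index[4:])
        res = D.nb_wald_contrast(counts, sf, disp, a, b)
        scaled = counts.copy()
        scaled["A0"] = scaled["A0"] * 4  # power of two: bit-exact normalized counts
        sf2 = sf.copy()
        sf2["A0"] *= 4
        res2 = D.nb_wald_contrast(scaled, sf2, disp, a, b)
        for col in ("base_mean", "lfc", "stat", "p", "fdr"):
            assert np.array_equal(
                res[col].to_numpy(), res2[col].to_numpy(), equal_nan=True
            )

    def test_all_zero_gene_is_non_observable(self, rng, groups):
        counts = _sim_counts(rng, 5, np.full(5, 100.0), 0.05)
        counts.iloc[0] = 0
        sf = pd.Series(1.0, index=groups.index)
        disp = pd.Series(0.05, index=counts.index)
        res = D.nb_wald_contrast(counts, sf, disp, list(groups.index[:4]), list(groups.index[4:]))
        assert not res["observable"].iloc[0]
        assert np.isnan(res["fdr"].iloc[0])


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(D.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert D.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            assert np.allclose(D.bh_adjust(p), _oracle_bh(p))

    def test_nan_propagates(self):
        out = D.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], _oracle_bh(np.array([0.01, 0.5])))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_range_and_order_preservation(self, pvals):
        p = np.array(pvals)
        out = D.bh_adjust(p)
        assert ((out >= 0) & (out <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()
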