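import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirdeq.diffexp import (
    DERecord,
    fold_change,
    holm_adjust,
    make_de_records,
    select_clustering_set,
    select_signature,
    two_group_ttest,
    ttest_table,
)
from mirdeq.examples import SIGNATURE_FAMILY_SIZE, SIGNATURE_PVALUES


def holm_oracle(p, m):
    """Brute-force running-maximum step-down adjustment."""
    order = np.argsort(p, kind="stable")
    out = np.empty(len(p))
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        out[idx] = min(1.0, running)
    return out


class TestTTest:
    def test_identical_groups(self):
        t, p = two_group_ttest([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(ValueError, match="zero variance, unequal means"):
            two_group_ttest([0, 0, 0, 0], [1, 1, 1, 1])

    def test_constant_equal_groups(self):
        assert two_group_ttest([2, 2], [2, 2]) == (0.0, 1.0)

    def test_group_too_small(self):
        with pytest.raises(ValueError, match=">= 2"):
            two_group_ttest([1.0], [1.0, 2.0])

    def test_textbook_formula_oracle(self):
        a = np.array([2.0, 2.1, 1.9])
        b = np.array([1.0, 1.1, 0.9])
        t, p = two_group_ttest(a, b)
        # independent evaluation of the pooled-variance formula
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        p_ref = 2 * stats.t.sf(abs(t_ref), 4)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            t, p = two_group_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(scale=3.0, size=5)
        t, p = two_group_ttest(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_table_matches_scalar(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 10))
        mask = np.array([True] * 6 + [False] * 4)
        t_vec, p_vec = ttest_table(values, mask)
        for i in range(30):
            t, p = two_group_ttest(values[i, mask], values[i, ~mask])
            assert t_vec[i] == pytest.approx(t, abs=1e-12)
            assert p_vec[i] == pytest.approx(p, abs=1e-12)


class TestHolm:
    def test_single_p_identity(self):
        assert holm_adjust([0.5], m=1).tolist() == [0.5]

    def test_cap_at_one(self):
        assert holm_adjust([0.5, 0.9], m=2).tolist() == [1.0, 1.0]

    def test_family_too_small(self):
        with pytest.raises(ValueError, match="family size"):
            holm_adjust([0.1, 0.2], m=1)

    def test_invalid_p(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_adjust([1.5], m=2)

    def test_published_rank10(self):
        p = [x for _, x, _ in SIGNATURE_PVALUES]
        adj = holm_adjust(p, m=SIGNATURE_FAMILY_SIZE)
        assert f"{adj[9]:.2E}" == "1.04E-02"

    def test_published_rank18_running_maximum(self):
        p = [x for _, x, _ in SIGNATURE_PVALUES]
        adj = holm_adjust(p, m=SIGNATURE_FAMILY_SIZE)
        # naive product at rank 18 is 128 * 1.59e-4 = 2.04e-2, overridden by
        # the rank-17 running maximum 129 * 1.59e-4 = 2.05e-2
        assert f"{adj[17]:.2E}" == "2.05E-02"
        assert adj[17] == adj[16]

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=15)
        adj = holm_adjust(p, m=40)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= 0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        assert np.allclose(holm_adjust(p)[perm], holm_adjust(p[perm]))

    def test_statsmodels_crosscheck(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        ours = holm_adjust(p)  # m = len(p): the statsmodels convention
        theirs = multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        st.integers(min_value=0, max_value=180),
    )
    def test_oracle_property(self, p, extra):
        p = np.array(p)
        m = len(p) + extra
        assert np.allclose(holm_adjust(p, m), holm_oracle(p, m))


class TestFoldChange:
    @pytest.mark.parametrize(
        "mean_t,mean_n,direction,rounded",
        [
            (3729.0, 1352.0, "up", 2.8),
            (1980.0, 6520.0, "down", 3.3),
            (323.0, 89.0, "up", 3.6),
        ],
    )
    def test_published_examples(self, mean_t, mean_n, direction, rounded):
        d, fold = fold_change(mean_t, mean_n)
        assert d == direction
        assert round(fold, 1) == rounded

    def test_undefined_when_denominator_zero(self):
        assert fold_change(182.0, 0.0) == ("up", None)

    def test_tie_convention(self):
        assert fold_change(7.0, 7.0) == ("up", 1.0)

    def test_negative_mean_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            fold_change(-1.0, 2.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
    )
    def test_swap_symmetry(self, a, b):
        d_ab, f_ab = fold_change(a, b)
        d_ba, f_ba = fold_change(b, a)
        assert f_ab == f_ba
        if a != b and f_ab is not None:
            assert {d_ab, d_ba} == {"up", "down"}


def _record(mirna_id="m", p_raw=0.5, p_adj=0.5, fold=2.5, diff=200.0):
    return DERecord(mirna_id, 100.0, 40.0, 1.0, p_raw, p_adj, "up", fold, diff)


class TestSelection:
    def test_published_signature_count(self):
        p = np.array([x for _, x, _ in SIGNATURE_PVALUES])
        adj = holm_adjust(p, m=SIGNATURE_FAMILY_SIZE)
        records = [
            _record(mirna_id=name, p_raw=raw, p_adj=a)
            for (name, raw, _), a in zip(SIGNATURE_PVALUES, adj)
        ]
        assert len(select_signature(records, alpha=0.05)) == 25

    def test_strict_alpha(self):
        assert select_signature([_record(p_adj=0.05)], alpha=0.05) == []

    def test_empty(self):
        assert select_signature([]) == []

    def test_sorted_by_raw_p_then_id(self):
        records = [
            _record("b", p_raw=0.01, p_adj=0.02),
            _record("a", p_raw=0.01, p_adj=0.02),
            _record("c", p_raw=0.001, p_adj=0.002),
        ]
        assert [r.mirna_id for r in select_signature(records)] == ["c", "a", "b"]

    def test_clustering_set_strict_fold(self):
        assert select_clustering_set([_record(fold=2.0, diff=500.0)]) == []

    def test_clustering_set_included(self):
        rec = _record(fold=2.758, diff=2377.0)
        assert select_clustering_set([rec]) == [rec]

    def test_clustering_set_undefined_fold_excluded(self):
        assert select_clustering_set([_record(fold=None, diff=182.0)]) == []


class TestMakeRecords:
    def test_small_pipeline(self):
        from tests.conftest import make_sample_table
        from mirdeq.normalization import NormalizedMatrix, log10_transform

        rng = np.random.default_rng(7)
        values = rng.uniform(1, 100, size=(12, 8))
        linear = NormalizedMatrix(
            [f"m{i}" for i in range(12)],
            [f"t{j}" for j in range(4)] + [f"n{j}" for j in range(4)],
            values,
            "linear",
        )
        logged = log10_transform(linear)
        table = make_sample_table(
            [f"t{j}" for j in range(4)], [f"n{j}" for j in range(4)]
        )
        records = make_de_records(linear, logged, table)
        assert len(records) == 12
        for r in records:
            assert 0 <= r.p_raw <= r.p_adj <= 1
            if r.mean_tumor > r.mean_normal:
                assert r.direction == "up"
            if r.fold_change is not None:
                assert r.fold_change >= 1.0
            assert r.mean_diff == pytest.approx(
                abs(r.mean_tumor - r.mean_normal)
            )

    def test_missing_sample_error(self, two_group_samples):
        from mirdeq.normalization import NormalizedMatrix, log10_transform

        linear = NormalizedMatrix(
            ["m"], ["s1", "sX"], np.array([[1.0, 2.0]]), "linear"
        )
        with pytest.raises(ValueError, match="sX"):
            make_de_records(
                linear, log10_transform(linear), two_group_samples
            )
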