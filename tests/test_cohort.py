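import math

import numpy as np
import pandas as pd
import pytest

from dsrt.cohort import (differential_sensitivity, hierarchical_clustering,
                         moderated_ttest, one_way_anova,
                         pairwise_subtype_correlation, pca_projection, sem,
                         subtype_group_stats, welch_t)
from dsrt.dss import ScreenMatrix


# ---------------------------------------------------------------------------
# closed-form oracles, implemented independently of scipy/statsmodels
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


def anova_oracle(*groups):
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    from scipy.stats import f as fdist
    return F, fdist.sf(F, df_b, df_w)


def spearman_oracle(x, y):
    def rank_avg(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = rank_avg(x), rank_avg(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def bh_oracle(pvals):
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = m - rank_from_end  # 1-based rank
        prev = min(prev, p[idx] * m / i)
        q[idx] = prev
    return q


def make_matrix(values, subtypes, drug_prefix="D"):
    values = np.asarray(values, float)
    n, d = values.shape
    sample_ids = [f"S{i}" for i in range(n)]
    dss = pd.DataFrame(values, index=sample_ids,
                       columns=[f"{drug_prefix}{j}" for j in range(d)])
    samples = pd.DataFrame({"patient_id": sample_ids, "subtype": subtypes,
                            "serial_index": 1}, index=sample_ids)
    drugs = pd.DataFrame({"class": "targeted", "mechanism_tags": "X"},
                         index=dss.columns)
    return ScreenMatrix(dss=dss, samples=samples, drugs=drugs)


class TestPrimitives:
    def test_sem_formula(self):
        assert sem([10, 20, 30]) == pytest.approx(10 / math.sqrt(3))
        assert sem([10, 20, 30]) == pytest.approx(5.7735, abs=1e-4)

    def test_welch_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_matches_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 2, rng.integers(3, 10))
            t1, p1 = welch_t(a, b)
            t2, p2 = welch_oracle(a, b)
            assert t1 == pytest.approx(t2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_welch_separated_groups(self, rng):
        a = np.array([0.0, 0.0, 0.0]) + rng.normal(0, 1e-3, 3)
        b = np.array([10.0, 10.0, 10.0]) + rng.normal(0, 1e-3, 3)
        _, p = welch_t(a, b)
        assert p < 0.01

    def test_welch_small_group_undefined(self):
        t, p = welch_t([1.0], [1.0, 2.0])
        assert math.isnan(t) and math.isnan(p)

    def test_anova_matches_oracle(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        F1, p1 = one_way_anova(*groups)
        F2, p2 = anova_oracle(*groups)
        assert F1 == pytest.approx(F2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestGroupStats:
    def test_class_level_fractions(self, small_matrix):
        out = subtype_group_stats(small_matrix, level="class")
        assert set(out["unit"]) == {"all", "chemotherapy", "targeted"}
        for g in ("HGSOC", "LGSOC", "MUCOC"):
            assert f"mean_{g}" in out.columns
            assert f"sem_{g}" in out.columns
        assert "anova_p" in out.columns
        assert "welch_p_HGSOC_vs_LGSOC" in out.columns

    def test_identical_groups_p_one(self):
        vals = np.tile([[5.0, 6.0], [7.0, 8.0]], (2, 1))
        m = make_matrix(vals, ["HGSOC", "HGSOC", "LGSOC", "LGSOC"])
        out = subtype_group_stats(m, level="drug")
        assert np.allclose(out["welch_p_HGSOC_vs_LGSOC"], 1.0)

    def test_undefined_stats_for_tiny_group(self):
        m = make_matrix([[1.0], [2.0], [3.0]], ["HGSOC", "HGSOC", "LGSOC"])
        out = subtype_group_stats(m, level="drug")
        assert math.isnan(out["welch_p_HGSOC_vs_LGSOC"].iloc[0])
        assert math.isnan(out["sem_LGSOC"].iloc[0])


class TestCorrelation:
    def test_identical_vectors_rho_one(self):
        vals = np.vstack([np.arange(10.0)] * 4)
        m = make_matrix(vals, ["HGSOC", "HGSOC", "LGSOC", "LGSOC"])
        out = pairwise_subtype_correlation(m)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        up = np.arange(10.0)
        vals = np.vstack([up, up, up[::-1], up[::-1]])
        m = make_matrix(vals, ["HGSOC", "HGSOC", "LGSOC", "LGSOC"])
        out = pairwise_subtype_correlation(m)
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        vals = rng.uniform(0, 30, (4, 100))
        m = make_matrix(vals, ["HGSOC", "HGSOC", "LGSOC", "LGSOC"])
        out = pairwise_subtype_correlation(m)
        mean_h = vals[:2].mean(axis=0)
        mean_l = vals[2:].mean(axis=0)
        assert out["rho"].iloc[0] == pytest.approx(
            spearman_oracle(mean_h, mean_l), abs=1e-12)

    def test_constant_vector_flagged(self):
        vals = np.vstack([np.ones(5), np.ones(5), np.arange(5.0),
                          np.arange(5.0)])
        m = make_matrix(vals, ["HGSOC", "HGSOC", "LGSOC", "LGSOC"])
        out = pairwise_subtype_correlation(m)
        assert out["flag"].iloc[0] == "constant_vector"
        assert math.isnan(out["rho"].iloc[0])


class TestClustering:
    def test_duplicates_merge_first(self, rng):
        vals = rng.uniform(0, 30, (4, 20))
        vals[1] = vals[0]
        m = make_matrix(vals, ["HGSOC"] * 4)
        res = hierarchical_clustering(m)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_single_sample_trivial_tree(self):
        m = make_matrix([[1.0, 2.0]], ["HGSOC"])
        res = hierarchical_clustering(m)
        assert res.linkage_matrix.shape[0] == 0
        assert res.leaf_order == ["S0"]

    def test_planted_subtypes_recovered_zero_noise(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 5, 30)
        rows, labels = [], []
        for i, sub in enumerate(["HGSOC", "LGSOC", "MUCOC"]):
            shift = np.zeros(30)
            shift[i * 10:(i + 1) * 10] = 25.0
            for _ in range(3):
                rows.append(base + shift)
                labels.append(sub)
        m = make_matrix(np.array(rows), labels)
        res = hierarchical_clustering(m, k=3)
        from sklearn.metrics import adjusted_rand_score
        codes = pd.Categorical(labels).codes
        assert adjusted_rand_score(codes, res.labels) == 1.0

    def test_missing_values_error(self):
        vals = np.ones((3, 4))
        vals[0, 0] = np.nan
        m = make_matrix(vals, ["HGSOC"] * 3)
        with pytest.raises(ValueError, match="missing"):
            hierarchical_clustering(m)


class TestPCA:
    def test_duplicated_samples_identical_scores(self, rng):
        vals = rng.uniform(0, 30, (5, 20))
        vals[1] = vals[0]
        m = make_matrix(vals, ["HGSOC"] * 5)
        res = pca_projection(m)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1], atol=1e-9)

    def test_explained_nonincreasing_and_bounded(self, rng):
        vals = rng.uniform(0, 30, (6, 15))
        m = make_matrix(vals, ["HGSOC"] * 6)
        res = pca_projection(m, n_components=2)
        assert res.explained_fraction[0] >= res.explained_fraction[1]
        assert res.explained_fraction.sum() <= 1.0 + 1e-12

    def test_zero_variance_columns_dropped(self, rng):
        vals = rng.uniform(0, 30, (5, 10))
        vals[:, 3] = 7.0
        m = make_matrix(vals, ["HGSOC"] * 5)
        res = pca_projection(m)
        assert res.dropped_columns == ["D3"]

    def test_requires_three_samples(self):
        m = make_matrix(np.ones((2, 4)), ["HGSOC", "LGSOC"])
        with pytest.raises(ValueError, match=">=3 samples"):
            pca_projection(m)

    def test_planted_subtype_separates(self):
        rng = np.random.default_rng(9)
        rows, labels = [], []
        for sub, shift in (("LGSOC", 20.0), ("HGSOC", 0.0), ("MUCOC", 0.0)):
            for _ in range(4):
                v = rng.uniform(0, 5, 40)
                v[:15] += shift
                rows.append(v)
                labels.append(sub)
        m = make_matrix(np.array(rows), labels)
        res = pca_projection(m)
        from sklearn.metrics import silhouette_samples
        lab = np.array([s == "LGSOC" for s in labels])
        sil = silhouette_samples(res.scores.to_numpy(), lab)
        assert sil[lab].mean() > 0


class TestDifferential:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(12.0, 20.0), (6, 1))
        m = make_matrix(vals, ["HGSOC"] * 6)
        out = differential_sensitivity(m, ["S0", "S1", "S2"],
                                       ["S3", "S4", "S5"])
        assert np.allclose(out["effect"], 0.0)
        assert np.allclose(out["q"], 1.0)

    def test_planted_shift_ranks_top(self, rng):
        vals = rng.normal(15, 2, (10, 50))
        vals[:5, 7] += 20.0  # drug D7 shifted in group A
        m = make_matrix(vals, ["HGSOC"] * 10)
        out = differential_sensitivity(m, [f"S{i}" for i in range(5)],
                                       [f"S{i}" for i in range(5, 10)])
        top3 = out.reindex(out["t_mod"].abs().sort_values(
            ascending=False).index)["drug_id"].head(3)
        assert "D7" in set(top3)

    def test_bh_oracle(self):
        p = [0.01, 0.02, 0.03, 0.5]
        q = bh_oracle(p)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])
        from statsmodels.stats.multitest import multipletests
        assert np.allclose(multipletests(p, method="fdr_bh")[1], q)

    def test_inclusion_filter(self, rng):
        vals = np.full((4, 3), 2.0)
        vals[:, 1] = 20.0  # only D1 ever reaches the threshold
        vals += rng.normal(0, 0.1, vals.shape)
        m = make_matrix(vals, ["HGSOC"] * 4)
        out = differential_sensitivity(m, ["S0", "S1"], ["S2", "S3"])
        assert list(out["drug_id"]) == ["D1"]

    def test_filter_removes_everything(self):
        m = make_matrix(np.ones((4, 3)), ["HGSOC"] * 4)
        out = differential_sensitivity(m, ["S0", "S1"], ["S2", "S3"])
        assert len(out) == 0

    def test_moderated_t_matches_closed_form_textbook(self, rng):
        # balanced 2-group data with the prior forced flat: the moderated t
        # reduces to the pooled-variance t up to variance shrinkage; check the
        # pieces against hand computation
        A = rng.normal(0, 1, (4, 30))
        B = rng.normal(0, 1, (4, 30))
        out = moderated_ttest(A, B)
        d = 6
        s2 = (((A - A.mean(0)) ** 2).sum(0) + ((B - B.mean(0)) ** 2).sum(0)) / d
        assert np.allclose(out["s2"], s2, atol=1e-12)
        assert np.allclose(out["effect"], A.mean(0) - B.mean(0), atol=1e-12)
        # shrunken variances lie between the prior and the raw variance
        lo = np.minimum(s2, out["s2_post"])
        hi = np.maximum(s2, out["s2_post"])
        assert ((out["s2_post"] >= np.minimum(lo, hi) - 1e-12).all())
        # monotone: ordering of |t| matches ordering of |effect|/sqrt(s2_post)
        manual = np.abs(out["effect"]) / np.sqrt(out["s2_post"] * (1 / 4 + 1 / 4))
        assert np.allclose(np.abs(out["t_mod"]), manual, atol=1e-10)
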