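"""Layer statistics, FDR adjustment, PAM clustering and group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hippodti.analysis import (
    adjusted_rand_index,
    bhy_adjust,
    compare_layers,
    eae_compare,
    misclassification_count,
    pam_cluster,
    reconstruct_standard_datasets,
    standard_dataset_masks,
    voi_means_from_maps,
)


def _bhy_brute_force(p):
    """Independent step-up implementation of the Benjamini–Yekutieli rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    ranked = p[order]
    adj = ranked * m * c_m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHY:
    def test_single_p_scaled_by_c1(self):
        # m = 1: c(1) = 1, so the value is unchanged
        assert bhy_adjust([0.03]) == pytest.approx([0.03])

    def test_all_ones_stay_one(self):
        assert bhy_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_matches_independent_step_up(self, ps):
        assert bhy_adjust(ps) == pytest.approx(_bhy_brute_force(ps), abs=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_dominates_plain_bh(self, ps):
        from statsmodels.stats.multitest import multipletests

        by = bhy_adjust(ps)
        bh = multipletests(ps, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)

    def test_adjusted_at_least_raw(self):
        ps = [0.01, 0.02, 0.9]
        assert np.all(bhy_adjust(ps) >= np.asarray(ps))


def _ari_brute_force(a, b):
    """Pair-counting ARI: agreements over all item pairs, chance-corrected."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        ss += sa and sb
        sd += sa and not sb
        ds += (not sa) and sb
        dd += (not sa) and (not sb)
    expected = (ss + sd) * (ss + ds) / (n * (n - 1) / 2)
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == 1.0

    def test_label_permutation_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [2, 2, 0, 0, 1, 1]
        assert adjusted_rand_index(a, b) == 1.0

    def test_crossed_contingency_matches_pair_counting(self):
        # contingency [[2,1],[1,2]] on 6 items
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 0, 1, 1]
        assert adjusted_rand_index(a, b) == pytest.approx(_ari_brute_force(a, b))

    @given(
        st.lists(st.integers(0, 2), min_size=4, max_size=12),
        st.lists(st.integers(0, 2), min_size=4, max_size=12),
    )
    def test_matches_brute_force_generally(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert adjusted_rand_index(a, b) == pytest.approx(
            _ari_brute_force(a, b), abs=1e-12
        )


class TestMisclassification:
    def test_perfect_clustering(self):
        truth = ["SR"] * 5 + ["SLM"] * 5 + ["ML"] * 5
        assign = [0] * 5 + [1] * 5 + [2] * 5
        assert misclassification_count(assign, truth) == 0

    def test_one_swapped_item(self):
        truth = np.repeat(["SR", "SLM", "ML"], 15)
        assign = np.repeat([0, 1, 2], 15)
        assign[0] = 1
        assert misclassification_count(assign, truth) == 1

    def test_crossed_majorities_brute_force(self):
        # 2 clusters / 2 classes; optimal matching found by trying both
        truth = np.array([0, 0, 0, 1, 1])
        assign = np.array([1, 1, 0, 0, 0])
        best = min(
            sum(int(m[c] != t) for c, t in zip(assign, truth))
            for m in ({0: 0, 1: 1}, {0: 1, 1: 0})
        )
        assert misclassification_count(assign, truth) == best


class TestPAM:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([rng.normal(c, 1.0, (20, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 20)
        res = pam_cluster(X, k=3, truth=truth)
        assert res.ari == 1.0
        assert res.n_misclassified == 0

    def test_identical_points_degenerate(self):
        X = np.zeros((10, 3))
        res = pam_cluster(X, k=3, truth=np.repeat([0, 1, 2], [4, 3, 3]))
        assert res.ari <= 0.0

    def test_objective_monotone_over_swaps(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 3))
        res = pam_cluster(X, k=3)
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_history, res.cost_history[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((2, 2)), k=3)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 4))
        a = pam_cluster(X, k=3)
        b = pam_cluster(X, k=3)
        assert np.array_equal(a.assignments, b.assignments)


def _layer_table(effects, n=15, sd=1.0, seed=0, dataset="B2700-43Dir", metric="MD"):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n):
        for layer, mu in zip(("SR", "SLM", "ML"), effects):
            rows.append(
                {
                    "animal_id": f"a{a}",
                    "group": "control",
                    "dataset_label": dataset,
                    "layer": layer,
                    metric: rng.normal(mu, sd),
                }
            )
    return pd.DataFrame(rows)


class TestCompareLayers:
    def test_null_effect_gives_large_p_small_effect_size(self):
        table = _layer_table([0.5, 0.5, 0.5], sd=0.02, seed=3)
        omnibus, posthoc = compare_layers(table, "MD", "B2700-43Dir")
        assert omnibus.p_raw > 0.05
        assert omnibus.effect_size < 0.14
        assert all(t.p_adjusted >= t.p_raw for t in posthoc)

    def test_huge_separation_detected_everywhere(self):
        # three layers offset by 10 sd
        table = _layer_table([0.0, 10.0, 20.0], sd=1.0, seed=4)
        omnibus, posthoc = compare_layers(table, "MD", "B2700-43Dir")
        assert omnibus.p_raw < 1e-6
        assert omnibus.effect_size_category == "large"
        assert all(t.p_adjusted < 0.001 for t in posthoc)

    def test_friedman_used_for_non_normal_cells(self):
        rng = np.random.default_rng(5)
        rows = []
        for a in range(15):
            for i, layer in enumerate(("SR", "SLM", "ML")):
                # heavy-tailed, strongly skewed cell distributions
                rows.append(
                    {
                        "animal_id": f"a{a}",
                        "group": "control",
                        "dataset_label": "d",
                        "layer": layer,
                        "MD": float(i + rng.lognormal(0, 1.5)),
                    }
                )
        omnibus, _ = compare_layers(pd.DataFrame(rows), "MD", "d")
        assert omnibus.method == "Friedman"
        assert omnibus.effect_size_name == "W"

    def test_unbalanced_rows_rejected(self):
        table = _layer_table([0, 0, 0]).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|missing"):
            compare_layers(table, "MD", "B2700-43Dir")


def _group_table(delta, n_ctl=15, n_eae=16, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n, mu in (("control", n_ctl, 0.0), ("EAE", n_eae, delta)):
        for a in range(n):
            rows.append(
                {
                    "animal_id": f"{g}{a}",
                    "group": g,
                    "dataset_label": "B2700-43Dir",
                    "layer": "ML",
                    "MD": rng.normal(mu, sd),
                }
            )
    return pd.DataFrame(rows)


class TestEAECompare:
    def test_identical_groups_not_significant(self):
        t = eae_compare(_group_table(0.0, seed=6), "MD", "B2700-43Dir")
        assert t.p_raw > 0.05
        assert t.p_adjusted is None  # no adjustment by design

    def test_two_sd_effect_power(self):
        hits = sum(
            eae_compare(_group_table(2.0, seed=s), "MD", "B2700-43Dir").p_raw < 0.05
            for s in range(200)
        )
        assert hits >= 190  # >= 95% power at a 2-pooled-sd shift

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            eae_compare(_group_table(0.0, n_ctl=2, n_eae=2), "MD", "B2700-43Dir")


class TestVOIExtraction:
    def test_uniform_map_mean(self):
        from hippodti.phantom import build_label_map

        lm = build_label_map((24, 24, 3))
        maps = {"MD": np.full(lm.shape, 0.5)}
        df = voi_means_from_maps(maps, lm)
        assert np.allclose(df["MD"], 0.5)

    def test_empty_voi_rejected(self):
        lm = np.zeros((4, 4, 2), dtype=np.int16)
        with pytest.raises(ValueError, match="no voxels"):
            voi_means_from_maps({"MD": np.zeros(lm.shape)}, lm)


class TestDatasetReconstruction:
    def test_five_standard_datasets(self, small_noisy_cohort):
        cohort, _ = small_noisy_cohort
        subs = reconstruct_standard_datasets(cohort[0])
        assert set(subs) == {
            "B1000-12Dir", "B1000-22Dir", "B2700-12Dir", "B2700-22Dir", "B2700-43Dir",
        }
        for label, ds in subs.items():
            b = float(label.split("-")[0][1:])
            n = int(label.split("-")[1][:-3])
            assert np.count_nonzero(ds.scheme.bvals == b) == n
            assert ds.scheme.n_b0 == 2  # each keeps its shell's b=0 pair

    def test_masks_are_subsets_of_their_shell(self, small_noisy_cohort):
        cohort, _ = small_noisy_cohort
        scheme = cohort[0].scheme
        masks = standard_dataset_masks(scheme)
        small = masks["B2700-12Dir"] & (scheme.bvals > 0)
        big = masks["B2700-43Dir"] & (scheme.bvals > 0)
        assert np.all(big[small])
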