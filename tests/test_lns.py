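import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lnskit as lk
from lnskit.io import DataError
from lnskit.lns import FLAG_CONSTANT, count_diverged

from conftest import make_dataset


def hand_pearson(a, b):
    """Explicit sum-based Pearson, independent of numpy.corrcoef."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    return (da * db).sum() / np.sqrt((da ** 2).sum() * (db ** 2).sum())


def brute_force_lns(ZA, ZB):
    """Per-pair loop oracle: drop index i from both rows, hand Pearson."""
    n = ZA.shape[0]
    out = np.empty(n)
    for i in range(n):
        a = np.delete(ZA[i], i)
        b = np.delete(ZB[i], i)
        out[i] = hand_pearson(a, b)
    return out


class TestLnsPair:
    def test_identical_and_negated_vectors(self):
        w = np.array([0.3, -1.0, 2.0, 0.1])
        assert lk.lns_pair(w, w) == pytest.approx(1.0)
        assert lk.lns_pair(w, -w) == pytest.approx(-1.0)

    def test_four_point_hand_oracle(self):
        wa = np.array([0.1, -0.2, 0.3, 0.0])
        wb = np.array([0.2, -0.1, 0.2, 0.1])
        assert lk.lns_pair(wa, wb) == pytest.approx(hand_pearson(wa, wb), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(lk.lns_pair(np.ones(5), np.arange(5.0)))

    def test_pairwise_complete_masking(self):
        wa = np.array([1.0, np.nan, 2.0, 3.0, 0.0])
        wb = np.array([0.5, 7.0, 1.0, 2.0, 0.1])
        m = np.isfinite(wa)
        assert lk.lns_pair(wa, wb) == pytest.approx(hand_pearson(wa[m], wb[m]))

    @settings(deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=12),
           st.integers(0, 2 ** 31 - 1))
    def test_bounded_and_symmetric(self, vals, seed):
        a = np.array(vals)
        b = np.random.default_rng(seed).normal(size=a.size)
        r = lk.lns_pair(a, b)
        if np.isfinite(r):
            assert -1.0 <= r <= 1.0
            assert lk.lns_pair(b, a) == pytest.approx(r, abs=1e-12)


def small_networks(seed=0, n=20):
    """Two standardized connection matrices plus an ortholog map."""
    rng = np.random.default_rng(seed)
    za = rng.normal(size=(n, n))
    zb = 0.6 * za + 0.8 * rng.normal(size=(n, n))
    za, zb = (za + za.T) / 2, (zb + zb.T) / 2
    genes_a = [f"gA{i:02d}" for i in range(n)]
    genes_b = [f"gB{i:02d}" for i in range(n)]
    conn_a = lk.standardize(za, genes_a)
    conn_b = lk.standardize(zb, genes_b)
    om = lk.OrthologMap(list(zip(genes_a, genes_b)))
    return conn_a, conn_b, om


class TestGlobalLns:
    def test_self_comparison_is_identity(self):
        conn_a, _, _ = small_networks()
        om = lk.OrthologMap.identity(conn_a.gene_ids)
        table = lk.global_lns(conn_a, conn_a, om)
        assert np.allclose(table["lns"], 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        conn_a, conn_b, om = small_networks(seed=3, n=30)
        table = lk.global_lns(conn_a, conn_b, om)
        oracle = brute_force_lns(conn_a.z, conn_b.z)
        # the oracle row excludes index i, where the implementation holds NaN
        assert np.allclose(table["lns"].to_numpy(), oracle, atol=1e-10)

    def test_species_argument_swap_is_symmetric(self):
        conn_a, conn_b, om = small_networks(seed=4)
        fwd = lk.global_lns(conn_a, conn_b, om)["lns"].to_numpy()
        swapped = lk.OrthologMap([(b, a) for a, b in om.pairs])
        rev = lk.global_lns(conn_b, conn_a, swapped)["lns"].to_numpy()
        assert np.allclose(fwd, rev, atol=1e-12)

    def test_permuted_orthology_centers_near_zero(self, networks):
        conn_a, conn_b, om, _ = networks
        rng = np.random.default_rng(5)
        perm = rng.permutation(om.N)
        shuffled = lk.OrthologMap(
            [(om.pairs[i][0], om.pairs[perm[i]][1]) for i in range(om.N)]
        )
        vals = lk.global_lns(conn_a, conn_b, shuffled)["lns"]
        assert abs(vals.mean()) < 0.1
        # in contrast the true matching is strongly positive
        true_vals = lk.global_lns(conn_a, conn_b, om)["lns"]
        assert true_vals.median() > 0.3

    def test_missing_gene_flagged(self):
        conn_a, conn_b, om = small_networks(seed=6)
        extended = lk.OrthologMap(om.pairs + [("gA_absent", "gB_absent")])
        table = lk.global_lns(conn_a, conn_b, extended)
        last = table.iloc[-1]
        assert last["flag"] == "missing_gene"
        assert np.isnan(last["lns"])


class TestConditionLns:
    def test_matched_structure_gives_positive_median(self):
        spec = lk.SyntheticSpec(n_genes=80, n_datasets=1, missing_rate=0.0,
                                divergent_fraction=0.0, seed=8)
        ds_a, ds_b, om, _ = lk.generate_compendium(spec)
        table = lk.condition_lns(ds_a[0], ds_b[0], om)
        assert table["lns"].median() > 0

    def test_invariant_to_common_array_reordering(self):
        spec = lk.SyntheticSpec(n_genes=40, n_datasets=1, missing_rate=0.0,
                                seed=9)
        ds_a, ds_b, om, _ = lk.generate_compendium(spec)
        base = lk.condition_lns(ds_a[0], ds_b[0], om)["lns"].to_numpy()
        rng = np.random.default_rng(1)
        cols = list(ds_b[0].values.columns[rng.permutation(ds_b[0].n_arrays)])
        shuffled = lk.ExpressionDataset(ds_b[0].dataset_id,
                                        ds_b[0].values[cols])
        again = lk.condition_lns(ds_a[0], shuffled, om)["lns"].to_numpy()
        assert np.allclose(base, again, atol=1e-10)

    def test_planted_divergence_scores_lower(self):
        spec = lk.SyntheticSpec(n_genes=120, n_datasets=1, missing_rate=0.0,
                                divergent_fraction=0.25, seed=10)
        ds_a, ds_b, om, truth = lk.generate_compendium(spec)
        table = lk.condition_lns(ds_a[0], ds_b[0], om)
        div = table["gene_a"].isin(set(truth.divergent))
        assert table.loc[div, "lns"].mean() < table.loc[~div, "lns"].mean()


class TestRandomizedNull:
    def test_seed_determinism(self, networks):
        conn_a, conn_b, om, _ = networks
        a = lk.randomized_null(conn_a, conn_b, om, n_permutations=3, seed=99)
        b = lk.randomized_null(conn_a, conn_b, om, n_permutations=3, seed=99)
        assert np.array_equal(a.samples, b.samples)

    def test_single_permutation_equals_shuffle_oracle(self):
        conn_a, conn_b, om = small_networks(seed=12, n=10)
        null = lk.randomized_null(conn_a, conn_b, om, n_permutations=1, seed=7)
        perm = np.random.default_rng(7).permutation(10)
        zb = conn_b.z[np.ix_(perm, perm)]
        oracle = brute_force_lns(conn_a.z, zb)
        assert np.allclose(np.sort(null.samples), np.sort(oracle), atol=1e-10)

    def test_bounded_in_unit_interval(self, pooled_null):
        assert np.all(pooled_null.samples >= -1.0)
        assert np.all(pooled_null.samples <= 1.0)


class TestCountDiverged:
    def test_null_self_comparison_counts_about_half(self, networks, pooled_null):
        conn_a, conn_b, om, _ = networks
        import pandas as pd

        rng = np.random.default_rng(0)
        fake = pd.DataFrame({
            "gene_a": [f"x{i}" for i in range(2000)],
            "gene_b": [f"y{i}" for i in range(2000)],
            "context": "null-check",
            "lns": rng.choice(pooled_null.samples, size=2000, replace=False),
            "flag": "ok",
        })
        res = count_diverged(fake, pooled_null)
        assert 0.4 < res.count / 2000 < 0.6
        assert res.p_value > 0.01

    def test_all_ones_count_zero(self, pooled_null):
        import pandas as pd

        table = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"],
                              "context": "x", "lns": [1.0], "flag": "ok"})
        assert count_diverged(table, pooled_null).count == 0

    def test_planted_divergence_drives_the_count(self):
        # a fully diverged ortholog's LNS is itself a null draw, so roughly
        # half the planted genes land below the null mean -- but the genes
        # that do land below should be (almost) exclusively planted ones
        spec = lk.SyntheticSpec(n_genes=120, n_datasets=2, missing_rate=0.0,
                                divergent_fraction=0.25, seed=13)
        ds_a, ds_b, om, truth = lk.generate_compendium(spec)
        conn_a = lk.build_global_network([lk.preprocess(d) for d in ds_a])
        conn_b = lk.build_global_network([lk.preprocess(d) for d in ds_b])
        table = lk.global_lns(conn_a, conn_b, om)
        null = lk.randomized_null(conn_a, conn_b, om, n_permutations=20, seed=2)
        res = count_diverged(table, null)
        div = table["gene_a"].isin(set(truth.divergent))
        below = table["lns"] < res.cutoff
        assert res.count >= 0.4 * len(truth.divergent)
        assert (div & below).sum() >= 0.9 * res.count
        assert res.p_value < 1e-6  # real distribution strongly shifted

    def test_empty_table_is_error(self, pooled_null):
        import pandas as pd

        with pytest.raises(DataError):
            count_diverged(pd.DataFrame(columns=["lns"]), pooled_null)


class TestWithinSpecies:
    def test_duplicated_dataset_gives_lns_one(self):
        # two copies of the same dataset: whatever the split, each half is
        # that dataset's own network, so every gene matches itself exactly
        spec = lk.SyntheticSpec(n_genes=50, n_datasets=1, missing_rate=0.0,
                                seed=14)
        ds_a, _, _, _ = lk.generate_compendium(spec)
        table = lk.within_species_lns(ds_a + ds_a, split_seed=3)
        ok = table[table["flag"] == "ok"]
        assert np.allclose(ok["lns"], 1.0, atol=1e-10)

    def test_independent_noise_centers_near_zero(self):
        rng = np.random.default_rng(15)
        datasets = [make_dataset(rng.normal(size=(60, 10)),
                                 dataset_id=f"noise{i}") for i in range(4)]
        table = lk.within_species_lns(datasets, split_seed=1)
        assert abs(table["lns"].mean()) < 0.15

    def test_within_exceeds_between_at_matched_depth(self):
        # compare at equal dataset counts (3 vs 3) so the contrast isolates
        # the planted divergence rather than aggregation depth
        ds_a, ds_b, om, _ = lk.generate_compendium(lk.SyntheticSpec())
        pre_a = [lk.preprocess(d) for d in ds_a]
        pre_b = [lk.preprocess(d) for d in ds_b]
        within = lk.within_species_lns(pre_a, split_seed=2)
        conn_a = lk.build_global_network(pre_a[:3])
        conn_b = lk.build_global_network(pre_b[:3])
        between = lk.global_lns(conn_a, conn_b, om)
        assert within["lns"].median() > between["lns"].median()

    def test_fewer_than_two_datasets_is_error(self):
        with pytest.raises(DataError):
            lk.within_species_lns([make_dataset(np.eye(4))])


def test_constant_connection_vector_flagged():
    n = 8
    za = np.zeros((n, n))
    zb = np.random.default_rng(0).normal(size=(n, n))
    zb = (zb + zb.T) / 2
    genes = [f"g{i}" for i in range(n)]
    # bypass standardize for A (it would reject the degenerate matrix) to
    # exercise the per-pair constant-vector flag
    conn_a = lk.ConnectionMatrix(genes, np.where(np.eye(n, dtype=bool), np.nan, za))
    conn_b = lk.standardize(zb, genes)
    table = lk.global_lns(conn_a, conn_b, lk.OrthologMap.identity(genes))
    assert (table["flag"] == FLAG_CONSTANT).all()
    assert table["lns"].isna().all()
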