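"""Running sum, enrichment score, permutation null and the nes grid."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temponet.gsea import (
    RankedGeneList,
    enrichment_score,
    nes_matrix,
    normalize_and_pvalue,
    permutation_null,
    rank_genes,
    running_sum,
    read_nes_long,
    write_nes_long,
)
from temponet.genesets import GeneSet

from conftest import make_sets


def naive_enrichment_score(weights, hit_genes, genes):
    """Independent double-loop reference implementation of the statistic."""
    n = len(genes)
    hits = [g in hit_genes for g in genes]
    n_h = sum(hits)
    n_r = sum(abs(w) for w, h in zip(weights, hits) if h)
    best_max, best_min = -np.inf, np.inf
    p_hit = p_miss = 0.0
    for i in range(n):
        if hits[i]:
            p_hit += abs(weights[i]) / n_r
        else:
            p_miss += 1.0 / (n - n_h)
        v = p_hit - p_miss
        best_max = max(best_max, v)
        best_min = min(best_min, v)
    return best_max + best_min


def ranked(values: dict[str, float]) -> RankedGeneList:
    df = pd.DataFrame({"t": values})
    return rank_genes(df, "t")


class TestRankGenes:
    def test_orders_by_absolute_value_descending(self):
        r = ranked({"a": -3.0, "b": 2.0, "c": 0.5})
        assert list(r.genes) == ["a", "b", "c"]
        assert list(r.weights) == [-3.0, 2.0, 0.5]

    def test_ties_break_alphabetically(self):
        r = ranked({"zed": 1.0, "ant": -1.0, "mid": 2.0})
        assert list(r.genes) == ["mid", "ant", "zed"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(size=100))}
        r = ranked(vals)
        expected = sorted(vals, key=lambda g: (-abs(vals[g]), g))
        assert list(r.genes) == expected

    def test_unknown_timepoint_raises(self):
        df = pd.DataFrame({"t": {"a": 1.0}})
        with pytest.raises(ValueError, match="unknown"):
            rank_genes(df, "nope")


class TestRunningSum:
    def test_equal_weights_hits_on_top(self):
        r = RankedGeneList(
            genes=np.array(["a", "b", "c", "d"], dtype=object),
            weights=np.array([1.0, 1.0, 1.0, 1.0]),
        )
        np.testing.assert_allclose(running_sum(r, {"a", "b"}), [0.5, 1.0, 0.5, 0.0])

    def test_equal_weights_hits_on_bottom(self):
        r = RankedGeneList(
            genes=np.array(["a", "b", "c", "d"], dtype=object),
            weights=np.array([1.0, 1.0, 1.0, 1.0]),
        )
        np.testing.assert_allclose(running_sum(r, {"c", "d"}), [-0.5, -1.0, -0.5, 0.0])

    def test_final_element_is_zero(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        r = ranked(vals)
        hit = set(rng.choice(sorted(vals), 7, replace=False))
        assert running_sum(r, hit)[-1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_or_full_hit_set_raises(self):
        r = ranked({"a": 2.0, "b": 1.0})
        with pytest.raises(ValueError):
            running_sum(r, {"zz"})
        with pytest.raises(ValueError):
            running_sum(r, {"a", "b"})


class TestEnrichmentScore:
    def test_perfect_top_enrichment_scores_one(self):
        r = RankedGeneList(
            genes=np.array(list("abcdef"), dtype=object), weights=np.ones(6)
        )
        assert enrichment_score(r, {"a", "b"}) == pytest.approx(1.0)

    def test_perfect_bottom_enrichment_scores_minus_one(self):
        r = RankedGeneList(
            genes=np.array(list("abcdef"), dtype=object), weights=np.ones(6)
        )
        assert enrichment_score(r, {"e", "f"}) == pytest.approx(-1.0)

    def test_worked_example_max_plus_min(self):
        # |r| = (5,4,3,2,1), hits at ranks 1, 3, 5:
        # running sum (0.5556, 0.0556, 0.3889, -0.1111, 0) -> es 0.4444
        r = RankedGeneList(
            genes=np.array(list("abcde"), dtype=object),
            weights=np.array([5.0, 4.0, 3.0, 2.0, 1.0]),
        )
        rs = running_sum(r, {"a", "c", "e"})
        np.testing.assert_allclose(rs, [5 / 9, 5 / 9 - 0.5, 8 / 9 - 0.5, 8 / 9 - 1.0, 0.0], atol=1e-12)
        assert enrichment_score(r, {"a", "c", "e"}) == pytest.approx(4 / 9, abs=1e-12)

    def test_matches_naive_double_loop_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(10, 80))
            vals = {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(size=n) * 3)}
            r = ranked(vals)
            k = int(rng.integers(1, n))
            hit = set(rng.choice(sorted(vals), k, replace=False))
            es = enrichment_score(r, hit)
            oracle = naive_enrichment_score(list(r.weights), hit, list(r.genes))
            assert es == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 17.0])
    def test_invariant_to_positive_rescaling_of_weights(self, c):
        rng = np.random.default_rng(9)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        hit = set(rng.choice(sorted(vals), 6, replace=False))
        es1 = enrichment_score(ranked(vals), hit)
        es2 = enrichment_score(ranked({g: c * v for g, v in vals.items()}), hit)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_max_deviation_statistic_available(self):
        r = RankedGeneList(
            genes=np.array(list("abcd"), dtype=object), weights=np.ones(4)
        )
        assert enrichment_score(r, {"c", "d"}, statistic="max_deviation") == pytest.approx(-1.0)


class TestPermutationNull:
    def test_deterministic_under_seed(self):
        r = ranked({f"g{i}": float(i + 1) for i in range(30)})
        a = permutation_null(r, set_size=5, n_perm=50, seed=3)
        b = permutation_null(r, set_size=5, n_perm=50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_single_permutation(self):
        r = ranked({f"g{i}": 1.0 for i in range(10)})
        assert permutation_null(r, set_size=3, n_perm=1, seed=0).shape == (1,)

    def test_equal_weight_null_is_centred(self):
        # under equal weights the statistic is symmetric around 0
        r = ranked({f"g{i:04d}": 1.0 for i in range(1000)})
        null = permutation_null(r, set_size=50, n_perm=2000, seed=1)
        assert abs(null.mean()) < 0.05

    def test_invalid_args(self):
        r = ranked({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            permutation_null(r, set_size=1, n_perm=0)
        with pytest.raises(ValueError):
            permutation_null(r, set_size=2, n_perm=10)


class TestNormalizeAndPvalue:
    def test_printed_rule_example(self):
        nes, p = normalize_and_pvalue(0.5, np.array([0.25, 0.25, -0.3]))
        assert nes == pytest.approx(2.0)
        assert p == 0.0

    def test_ties_counted_in_pvalue(self):
        nes, p = normalize_and_pvalue(0.4, np.array([0.4, 0.4, 0.4]))
        assert p == 1.0

    def test_zero_es_degenerate(self):
        assert normalize_and_pvalue(0.0, np.array([0.1, -0.1])) == (0.0, 1.0)

    def test_negative_side_mirror(self):
        nes, p = normalize_and_pvalue(-0.5, np.array([-0.25, 0.3, -0.25]))
        assert nes == pytest.approx(-2.0)
        assert p == 0.0

    def test_empty_sign_portion_floors_pvalue(self):
        nes, p = normalize_and_pvalue(0.5, np.array([-0.1, -0.2, -0.3, -0.4]))
        assert np.isnan(nes)
        assert p == pytest.approx(0.25)


class TestNesMatrix:
    def _grid(self, seed=0, n_perm=100):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(60)]
        matrix = pd.DataFrame(
            rng.normal(size=(60, 3)), index=genes, columns=["Day 1", "Day 6", "Day 10"]
        )
        lib = make_sets(
            {f"S{j}": set(rng.choice(genes, 8, replace=False)) for j in range(5)}
        )
        return matrix, lib

    def test_shape_contract(self):
        matrix, lib = self._grid()
        nm = nes_matrix(matrix, lib, n_perm=100, seed=5)
        assert nm.es.shape == (5, 3)
        assert nm.nes.shape == (5, 3)
        assert nm.pvalue.shape == (5, 3)
        assert set(nm.sizes.index) == {f"S{j}" for j in range(5)}

    def test_column_order_independence(self):
        matrix, lib = self._grid()
        nm1 = nes_matrix(matrix, lib, n_perm=100, seed=5)
        shuffled = matrix[["Day 10", "Day 1", "Day 6"]]
        nm2 = nes_matrix(shuffled, lib, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(nm1.nes, nm2.nes[["Day 1", "Day 6", "Day 10"]])

    def test_planted_process_tops_its_column(self, small_study):
        library, matrix, probes, truth, nm, G = small_study
        for proc, tp in truth.planted_cells:
            col = nm.nes[tp]
            assert col.idxmax() == proc

    def test_high_nes_implies_low_pvalue(self, small_study):
        *_, nm, _ = small_study
        nes = nm.nes.to_numpy().ravel()
        p = nm.pvalue.to_numpy().ravel()
        keep = np.isfinite(nes) & np.isfinite(p) & (nes > 0)
        rho = stats.spearmanr(nes[keep], p[keep]).statistic
        assert rho < -0.2

    def test_mean_abs_fold_change_tracks_nes(self, small_study):
        library, matrix, _, _, nm, _ = small_study
        tp = nm.timepoints[0]
        mean_fc, nes_vals = [], []
        for s in library:
            genes = [g for g in s.genes if g in matrix.index]
            v = nm.nes.at[s.name, tp]
            if genes and np.isfinite(v):
                mean_fc.append(matrix.loc[genes, tp].abs().mean())
                nes_vals.append(v)
        rho = stats.spearmanr(nes_vals, mean_fc).statistic
        assert rho > 0.3

    def test_long_format_round_trip(self, tmp_path):
        matrix, lib = self._grid()
        nm = nes_matrix(matrix, lib, n_perm=50, seed=2)
        p = tmp_path / "nes.tsv"
        write_nes_long(nm, p)
        back = read_nes_long(p)
        pd.testing.assert_frame_equal(back.nes, nm.nes)
        pd.testing.assert_frame_equal(back.es, nm.es)
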