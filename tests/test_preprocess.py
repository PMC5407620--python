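"""Probe-table preprocessing: fill rules, time-point merge, never-perturbed drop."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from temponet.preprocess import (
    DUMMY,
    ProbeTable,
    day_number,
    default_mapping,
    drop_never_perturbed,
    merge_timepoints,
    preprocess_pipeline,
    read_fc_matrix,
    read_probe_table,
    secondary_fill,
    step1_primary_fill,
    step23_secondary_fill,
    write_fc_matrix,
)
from temponet.synthetic import SyntheticSpec, simulate


def probes_from(records, timepoints):
    """records: list of (probe_id, gene, {tp: (r1, r2, r3, p)})."""
    n, t = len(records), len(timepoints)
    reps = np.zeros((n, t, 3))
    pvals = np.full((n, t), 0.5)
    for i, (_, _, per_tp) in enumerate(records):
        for j, tp in enumerate(timepoints):
            if tp in per_tp:
                *r, p = per_tp[tp]
                reps[i, j, :] = r
                pvals[i, j] = p
    return ProbeTable(
        probe_ids=np.array([r[0] for r in records], dtype=object),
        gene_symbols=np.array([r[1] for r in records], dtype=object),
        timepoints=list(timepoints),
        replicates=reps,
        pvalues=pvals,
    )


class TestDayNumber:
    @pytest.mark.parametrize(
        "label,expected",
        [("Day 1", 1), ("Day 14", 14), ("Week 0", 14), ("Week 3", 35), ("Week 18", 140)],
    )
    def test_week_conversion_adds_14_days(self, label, expected):
        assert day_number(label) == expected

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            day_number("Month 2")


class TestStep1:
    def test_qualifying_triplet_gets_replicate_mean(self):
        probes = probes_from([("p1", "GA", {"Day 1": (1.5, 2.0, 1.2, 0.01)})], ["Day 1"])
        m = step1_primary_fill(probes)
        assert m.at["GA", "Day 1"] == pytest.approx(1.5667, abs=1e-4)

    def test_one_replicate_inside_band_disqualifies(self):
        probes = probes_from(
            [
                ("p1", "GA", {"Day 1": (1.5, 0.9, 2.0, 0.01), "Day 6": (1.5, 1.4, 1.3, 0.01)}),
            ],
            ["Day 1", "Day 6"],
        )
        m = step1_primary_fill(probes)
        assert np.isnan(m.at["GA", "Day 1"])
        assert m.at["GA", "Day 6"] == pytest.approx(1.4)

    def test_minimum_pvalue_probe_wins(self):
        probes = probes_from(
            [
                ("pA", "GA", {"Day 1": (1.5, 1.5, 1.5, 0.04)}),
                ("pB", "GA", {"Day 1": (2.5, 2.5, 2.5, 0.01)}),
            ],
            ["Day 1"],
        )
        m = step1_primary_fill(probes)
        assert m.at["GA", "Day 1"] == pytest.approx(2.5)

    def test_pvalue_tie_breaks_on_probe_id(self):
        probes = probes_from(
            [
                ("pB", "GA", {"Day 1": (2.5, 2.5, 2.5, 0.01)}),
                ("pA", "GA", {"Day 1": (1.5, 1.5, 1.5, 0.01)}),
            ],
            ["Day 1"],
        )
        m = step1_primary_fill(probes)
        assert m.at["GA", "Day 1"] == pytest.approx(1.5)  # pA < pB


class TestStep23:
    # hand-oracle over the branch structure of the secondary fill
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            # two outside [-1,1], no common sign across all three, same-sign
            # pair (1.4, 1.1) -> mean 1.25, outside the dummy band
            ((1.4, 1.1, -0.2), 1.25),
            # all inside, same sign, mean 0.2 in (-0.8, 0.8) -> dummy
            ((0.3, 0.2, 0.1), DUMMY),
            # all inside, same sign, mean 0.8167 >= 0.8 -> kept
            ((0.9, 0.85, 0.7), 0.8167),
            # negative mirror of the pair rule
            ((-1.4, -1.1, 0.2), -1.25),
            # exactly -0.8 is kept (band is open)
            ((-0.8, -0.8, -0.8), -0.8),
            # zero breaks same-sign: pair (1.5, 1.2) -> 1.35
            ((1.5, 1.2, 0.0), 1.35),
            # no same-sign pair at all -> dummy
            ((1.5, -1.2, 0.0), DUMMY),
        ],
    )
    def test_single_probe_branches(self, triplet, expected):
        probes = probes_from([("p1", "GA", {"Day 1": (*triplet, 0.1)})], ["Day 1"])
        v = step23_secondary_fill(probes, "GA", "Day 1")
        assert v == pytest.approx(expected, abs=1e-4)

    def test_two_outside_candidates_preferred_over_all_inside(self):
        probes = probes_from(
            [
                ("pA", "GA", {"Day 1": (0.9, 0.9, 0.9, 0.001)}),  # group B, tiny p
                ("pB", "GA", {"Day 1": (1.4, 1.2, -0.5, 0.9)}),  # group A, big p
            ],
            ["Day 1"],
        )
        # group A exists, so the all-inside probe is never considered
        assert step23_secondary_fill(probes, "GA", "Day 1") == pytest.approx(1.3)

    def test_three_same_sign_preferred_over_pair(self):
        # both probes sit in group A (two replicates outside the band);
        # the all-same-sign probe wins regardless of p-value
        probes = probes_from(
            [
                ("pA", "GA", {"Day 1": (1.4, 1.2, -0.5, 0.001)}),  # same-sign pair only
                ("pB", "GA", {"Day 1": (1.3, 1.2, 0.4, 0.9)}),  # all three same sign
            ],
            ["Day 1"],
        )
        assert step23_secondary_fill(probes, "GA", "Day 1") == pytest.approx((1.3 + 1.2 + 0.4) / 3)

    def test_group_a_without_usable_sign_falls_to_dummy_not_group_b(self):
        probes = probes_from(
            [
                ("pA", "GA", {"Day 1": (1.5, -1.2, 0.0, 0.01)}),  # group A, no pair
                ("pB", "GA", {"Day 1": (0.9, 0.9, 0.9, 0.01)}),  # group B, clean
            ],
            ["Day 1"],
        )
        assert step23_secondary_fill(probes, "GA", "Day 1") == DUMMY


class TestMerge:
    def _matrix(self, a, b):
        return pd.DataFrame({"Day 14": [a], "Week 0": [b]}, index=["GA"])

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1.6, 2.0, 1.8),  # same direction -> mean
            (1.6, -1.4, DUMMY),  # opposite directions -> dummy
            (1.6, 0.3, 1.6),  # only first perturbed
            (0.3, 1.6, 1.6),  # only second perturbed
            (0.3, 0.9, 0.3),  # neither perturbed -> Day 14 value
            (-1.5, -2.5, -2.0),  # negative same direction
        ],
    )
    def test_merge_rules(self, a, b, expected):
        out = merge_timepoints(self._matrix(a, b))
        assert list(out.columns) == ["Day 14"]
        assert out.at["GA", "Day 14"] == pytest.approx(expected)

    def test_missing_label_raises(self):
        m = pd.DataFrame({"Day 14": [1.0]}, index=["GA"])
        with pytest.raises(ValueError, match="Week 0"):
            merge_timepoints(m)

    def test_merged_column_keeps_day_order(self):
        m = pd.DataFrame(
            {"Day 1": [0.1], "Day 14": [1.5], "Week 0": [1.7], "Week 3": [0.2]},
            index=["GA"],
        )
        out = merge_timepoints(m)
        assert list(out.columns) == ["Day 1", "Day 14", "Week 3"]


class TestDrop:
    def test_rows_below_threshold_removed(self):
        m = pd.DataFrame(
            {"Day 1": [DUMMY, DUMMY], "Day 6": [0.5, 1.1], "Day 10": [0.9, 0.2]},
            index=["drop_me", "keep_me"],
        )
        out = drop_never_perturbed(m)
        assert list(out.index) == ["keep_me"]

    def test_all_dropped_is_an_error(self):
        m = pd.DataFrame({"Day 1": [0.5]}, index=["GA"])
        with pytest.raises(ValueError, match="degenerate"):
            drop_never_perturbed(m)


class TestPipeline:
    def test_every_cell_is_rule_mean_or_dummy_and_step1_never_overwritten(self):
        probes = probes_from(
            [
                ("p1", "GA", {"Day 1": (1.5, 2.0, 1.2, 0.01), "Day 6": (0.3, 0.2, 0.1, 0.5)}),
                ("p2", "GB", {"Day 1": (0.2, 0.1, 0.0, 0.5), "Day 6": (-1.5, -1.4, -1.6, 0.02)}),
            ],
            ["Day 1", "Day 6"],
        )
        step1 = step1_primary_fill(probes)
        final = preprocess_pipeline(probes, merge_pair=None)
        # step-1 cells survive untouched
        for g in final.index:
            for c in final.columns:
                if not np.isnan(step1.at[g, c]):
                    assert final.at[g, c] == step1.at[g, c]
        assert final.at["GA", "Day 6"] == DUMMY
        assert final.at["GB", "Day 1"] == DUMMY
        assert not final.isna().any().any()

    def test_zero_replicate_noise_round_trips_step1_cells(self):
        spec = SyntheticSpec(
            n_genes=300, n_processes=20, t_points=4, path_length=4,
            replicate_noise=0.0, extra_probe_rate=0.0, seed=1,
        )
        _, matrix, probes, _ = simulate(spec)
        final = preprocess_pipeline(probes, merge_pair=None)
        for g in final.index:
            for c in final.columns:
                v = matrix.at[g, c]
                if abs(v) > 1:
                    assert final.at[g, c] == pytest.approx(v, abs=1e-12)

    def test_planted_genes_survive_drop(self):
        spec = SyntheticSpec(n_genes=400, n_processes=25, t_points=4, path_length=4, seed=2)
        library, matrix, probes, truth = simulate(spec)
        final = preprocess_pipeline(probes, merge_pair=None)
        for proc, genes in truth.planted_genes.items():
            for g in genes:
                assert g in final.index


class TestIO:
    def test_fc_matrix_round_trip(self, tmp_path):
        m = pd.DataFrame(
            {"Day 1": [1.5, -0.2], "Day 6": [DUMMY, 2.0]}, index=["GA", "GB"]
        )
        m.index.name = "gene"
        p = tmp_path / "fc.tsv"
        write_fc_matrix(m, p)
        back = read_fc_matrix(p)
        pd.testing.assert_frame_equal(back, m)

    def test_probe_table_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_genes=50, n_processes=5, t_points=3, path_length=3, seed=3)
        _, _, probes, _ = simulate(spec)
        df = probes.to_frame()
        path = tmp_path / "probes.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_probe_table(path, default_mapping(probes.timepoints))
        assert list(back.probe_ids) == list(probes.probe_ids)
        np.testing.assert_allclose(back.replicates, probes.replicates)
        np.testing.assert_allclose(back.pvalues, probes.pvalues)
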