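"""Plot-data builders and rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import peparray as pa
from peparray.arrayio import ArrayValidationError, TargetingRecord, TargetingTable

from conftest import make_matrix
from test_arrayio import small_synoptic


def targeting(rows):
    return TargetingTable([TargetingRecord("V", p, s, e, sid) for p, s, e, sid in rows])


@pytest.fixture()
def tiled_table():
    """Synoptic table over 4 overlapping 15-mers (starts 1,5,9,13), 2+2 samples."""
    rng = np.random.default_rng(0)
    m = make_matrix(
        rng.uniform(10, 100, (4, 4)),
        ["control", "control", "treatment", "treatment"],
        peptide_ids=["P1", "P2", "P3", "P4"],
    )
    table = pa.build_synoptic_table(m)
    targets = targeting(
        [("S", 1, 15, "P1"), ("S", 5, 19, "P2"), ("S", 9, 23, "P3"), ("S", 13, 27, "P4")]
    )
    return table, targets


class TestDistributionSummaries:
    def test_quartiles_linear_interpolation(self):
        m = make_matrix(
            np.array([[1.0, 9.0], [2.0, 9.0], [3.0, 9.0], [4.0, 9.0], [5.0, 9.0]]),
            ["control", "treatment"],
        )
        box = pa.build_distribution_summaries(m).boxplots[0]
        assert (box.q1, box.median, box.q3) == (2, 3, 4)
        assert box.whisker_low == 1 and box.whisker_high == 5
        assert box.outliers.size == 0

    def test_constant_sample_degenerate_box(self):
        m = make_matrix(np.full((6, 2), 7.0), ["control", "treatment"])
        box = pa.build_distribution_summaries(m).boxplots[0]
        assert box.q1 == box.median == box.q3 == 7.0
        assert box.outliers.size == 0

    def test_outliers_beyond_tukey_fences(self):
        vals = np.array([1.0, 2, 3, 4, 5, 100.0])
        m = make_matrix(np.column_stack([vals, vals]), ["control", "treatment"])
        box = pa.build_distribution_summaries(m).boxplots[0]
        assert box.outliers.tolist() == [100.0]
        assert box.whisker_high == 5.0

    def test_homoscedastic_null_has_no_mean_variance_trend(self, null_experiment):
        # after variance stabilization the per-peptide variance must not
        # track the mean (|spearman rho| < 0.1 over 2,000 peptides)
        _, _, _, matrix = null_experiment
        out, _ = pa.vsn_normalize(matrix)
        mv = pa.build_distribution_summaries(out).mean_variance["control"]
        rho = spearmanr(mv["mean"], mv["variance"]).statistic
        assert abs(rho) < 0.1

    def test_cohort_styling_labels(self, null_experiment):
        _, _, _, matrix = null_experiment
        summaries = pa.build_distribution_summaries(matrix)
        assert [b.cohort for b in summaries.boxplots] == ["control"] * 10 + ["treatment"] * 10


class TestPositionalHeatmap:
    def test_rows_sorted_n_to_c(self):
        rng = np.random.default_rng(1)
        m = make_matrix(
            rng.uniform(0, 1, (3, 2)), ["control", "treatment"],
            peptide_ids=["A", "B", "C"],
        )
        table = pa.build_synoptic_table(m)
        t = targeting([("S", 9, 23, "A"), ("S", 1, 15, "B"), ("S", 5, 19, "C")])
        hm = pa.build_positional_heatmap(table, t)
        assert hm.starts == [1, 5, 9]
        assert hm.spot_ids == ["B", "C", "A"]

    def test_cells_equal_synoptic_values(self, tiled_table):
        table, targets = tiled_table
        hm = pa.build_positional_heatmap(table, targets)
        expected = table.sample_values().loc[hm.spot_ids].to_numpy()
        assert np.array_equal(hm.values, expected)

    def test_unknown_spot_id_named(self, tiled_table):
        table, _ = tiled_table
        bad = targeting([("S", 1, 15, "P1"), ("S", 5, 19, "missing_spot")])
        with pytest.raises(ArrayValidationError, match="missing_spot"):
            pa.build_positional_heatmap(table, bad)

    def test_subset_variant_ordered_by_rank(self, tiled_table):
        table, _ = tiled_table
        hm = pa.build_subset_heatmap(table, ["P3", "P1"])
        assert hm.spot_ids == ["P3", "P1"]
        assert np.array_equal(hm.values, table.sample_values().loc[["P3", "P1"]].to_numpy())


class TestBandProfile:
    def test_center_and_band_arithmetic(self):
        m = make_matrix(
            np.array([[2.0, 4.0, 5.0, 5.0]]),
            ["control", "control", "treatment", "treatment"],
            peptide_ids=["P1"],
        )
        table = pa.build_synoptic_table(m)
        bp = pa.build_band_profile(table, targeting([("S", 1, 15, "P1")]))
        sd = np.sqrt(2)  # n-1 SD of (2, 4)
        assert bp.center["control"][0] == pytest.approx(3.0)
        assert bp.lower["control"][0] == pytest.approx(3.0 - sd)
        assert bp.upper["control"][0] == pytest.approx(3.0 + sd)

    def test_identical_cohorts_zero_effect(self):
        X = np.tile(np.array([[3.0], [9.0]]), (1, 4))
        m = make_matrix(X, ["control", "control", "treatment", "treatment"],
                        peptide_ids=["P1", "P2"])
        table = pa.build_synoptic_table(m)
        bp = pa.build_band_profile(
            table, targeting([("S", 1, 15, "P1"), ("S", 5, 19, "P2")])
        )
        assert np.allclose(bp.effect, 0.0)

    def test_effect_equals_delta_rfu(self, tiled_table):
        table, targets = tiled_table
        bp = pa.build_band_profile(table, targets)
        deltas = table.data.set_index("spot_id")["delta_rfu"]
        assert np.allclose(bp.effect, deltas.loc[bp.spot_ids].to_numpy())
        assert (bp.lower["control"] <= bp.center["control"]).all()
        assert (bp.center["control"] <= bp.upper["control"]).all()


class TestStripData:
    def test_fixed_sample_order_across_strips(self, tiled_table):
        table, targets = tiled_table
        strip = pa.build_strip_data(table, targeting=targets)
        orders = [[s for s, _, _ in strip.dots[p]] for p in strip.peptides]
        assert all(o == strip.sample_ids for o in orders)
        assert strip.cohorts == ["control", "control", "treatment", "treatment"]

    def test_single_sample_single_dot(self):
        m = make_matrix(np.array([[1.0, 2.0]]), ["control", "treatment"], peptide_ids=["P1"])
        table = pa.build_synoptic_table(m)
        strip = pa.build_strip_data(table, peptides=["P1"])
        assert len(strip.dots["P1"]) == 2

    def test_order_invariant_to_table_row_shuffle(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            rng.uniform(0, 1, (5, 5)),
            ["control"] * 3 + ["treatment"] * 2,
            peptide_ids=list("ABCDE"),
        )
        table = pa.build_synoptic_table(m)
        shuffled = pa.SynopticTable(
            data=table.data.sample(frac=1, random_state=1).reset_index(drop=True),
            control_samples=table.control_samples,
            treatment_samples=table.treatment_samples,
        )
        a = pa.build_strip_data(table, peptides=["B", "D"])
        b = pa.build_strip_data(shuffled, peptides=["B", "D"])
        assert a.dots == b.dots

    def test_multi_protein_rejected(self, tiled_table):
        table, _ = tiled_table
        bad = targeting([("S", 1, 15, "P1"), ("N", 1, 15, "P2")])
        with pytest.raises(ArrayValidationError, match="one protein"):
            pa.build_strip_data(table, targeting=bad)


class TestEpitopeMap:
    def test_tiling_needs_four_lanes(self, tiled_table):
        # each 15-mer with 11-residue overlap overlaps its next 3
        # neighbours, so 4 consecutive peptides need 4 lanes
        table, targets = tiled_table
        em = pa.build_epitope_map(table, targets)
        lanes = [seg[3] for seg in em.segments]
        assert sorted(lanes) == [0, 1, 2, 3]
        assert em.index_range == (1, 27)

    def test_color_values_are_deltas_with_symmetric_scale(self, tiled_table):
        table, targets = tiled_table
        em = pa.build_epitope_map(table, targets)
        deltas = table.data.set_index("spot_id")["delta_rfu"]
        for spot_id, _, _, _, colorv in em.segments:
            assert colorv == deltas[spot_id]
        assert em.color_limit == pytest.approx(deltas.abs().max())

    def test_negating_deltas_mirrors_colors(self, tiled_table):
        table, targets = tiled_table
        flipped = pa.SynopticTable(
            data=table.data.assign(delta_rfu=-table.data["delta_rfu"]),
            control_samples=table.control_samples,
            treatment_samples=table.treatment_samples,
        )
        a = pa.build_epitope_map(table, targets)
        b = pa.build_epitope_map(flipped, targets)
        assert a.color_limit == b.color_limit
        for sa, sb in zip(a.segments, b.segments):
            assert sa[4] == -sb[4]

    def test_nonoverlapping_single_lane(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.uniform(0, 1, (2, 2)), ["control", "treatment"],
                        peptide_ids=["P1", "P2"])
        table = pa.build_synoptic_table(m)
        em = pa.build_epitope_map(
            table, targeting([("S", 1, 15, "P1"), ("S", 16, 30, "P2")])
        )
        assert [seg[3] for seg in em.segments] == [0, 0]


class TestRender:
    def test_band_profile_smoke(self, tiled_table, tmp_path):
        table, targets = tiled_table
        bp = pa.build_band_profile(table, targets)
        out = pa.render(bp, tmp_path / "line.png")
        assert out.exists() and out.stat().st_size > 0

    def test_svg_deterministic(self, tiled_table, tmp_path):
        table, targets = tiled_table
        strip = pa.build_strip_data(table, targeting=targets)
        p1 = pa.render(strip, tmp_path / "a.svg", seed=4)
        p2 = pa.render(strip, tmp_path / "b.svg", seed=4)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_format_rejected(self, tiled_table, tmp_path):
        table, targets = tiled_table
        bp = pa.build_band_profile(table, targets)
        with pytest.raises(ValueError, match="format"):
            pa.render(bp, tmp_path / "x.bmp")

    def test_rendering_does_not_mutate_data(self, tiled_table, tmp_path):
        table, targets = tiled_table
        hm = pa.build_positional_heatmap(table, targets)
        before = hm.values.copy()
        pa.render(hm, tmp_path / "hm.png")
        assert np.array_equal(hm.values, before)

    def test_export_json(self, tiled_table, tmp_path):
        import json

        table, targets = tiled_table
        em = pa.build_epitope_map(table, targets)
        path = tmp_path / "em.json"
        pa.export_plot_data(em, path)
        payload = json.loads(path.read_text())
        assert len(payload["segments"]) == 4
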