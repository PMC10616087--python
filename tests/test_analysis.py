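"""Growth curves, AUC/GI, Bliss synergy, spherical layers, exports."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hybridboss.analysis import (GrowthCurve, SnapshotTable, auc,
                                 bliss_reference, combination_index,
                                 effect_from_growth, growth_curve,
                                 growth_index, layer_decompose, per_layer_gi,
                                 per_layer_growth, povray_export, read_csv,
                                 to_csv)

DATA = Path(__file__).parent / "data"


def frame(records):
    return pd.DataFrame(records,
                        columns=["time", "id", "x", "y", "z", "radius",
                                 "phase", "layer"])


def snapshot_of(counts_by_phase_per_time):
    """Build a SnapshotTable from {time: {phase: n}} with cells at origin."""
    rows = []
    cid = 0
    for t, phases in counts_by_phase_per_time.items():
        for phase, n in phases.items():
            for _ in range(n):
                rows.append([t, cid, 0.0, 0.0, 0.0, 8.0, phase, ""])
                cid += 1
    return SnapshotTable(frame(rows))


class TestGrowthCurve:
    def test_single_snapshot_counts(self):
        table = snapshot_of({0.0: {"cycling": 10}})
        curve = growth_curve(table)
        assert curve.alive.tolist() == [10]
        assert curve.dead.tolist() == [0]

    def test_all_apoptotic_counts_as_dead(self):
        curve = growth_curve(snapshot_of({0.0: {"apoptotic": 7}}))
        assert curve.alive.tolist() == [0]
        assert curve.dead.tolist() == [7]

    def test_removed_cells_excluded(self):
        curve = growth_curve(snapshot_of({0.0: {"cycling": 3, "removed": 4}}))
        assert curve.alive.tolist() == [3]
        assert curve.dead.tolist() == [0]

    def test_three_snapshot_hand_count(self):
        table = snapshot_of({
            0.0: {"cycling": 5},
            10.0: {"cycling": 6, "apoptotic": 1},
            20.0: {"cycling": 4, "apoptotic": 2, "necrotic": 1},
        })
        curve = growth_curve(table)
        assert curve.times.tolist() == [0.0, 10.0, 20.0]
        assert curve.alive.tolist() == [5, 6, 4]
        assert curve.dead.tolist() == [0, 1, 3]

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phases"):
            SnapshotTable(frame([[0.0, 0, 0, 0, 0, 8.0, "zombie", ""]]))


class TestAUC:
    def test_rectangle(self):
        curve = GrowthCurve([0.0, 1000.0], [100, 100])
        assert auc(curve) == 100_000.0

    def test_triangle(self):
        curve = GrowthCurve([0.0, 100.0], [0, 100])
        assert auc(curve) == 5_000.0

    def test_exact_for_piecewise_linear_input(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 100, 12))
        counts = rng.integers(0, 50, 12)
        coarse = auc(GrowthCurve(times, counts))
        # refine each segment: trapezoid is exact for piecewise-linear data
        fine_t = [times[0]]
        fine_c = [counts[0]]
        for (t0, t1), (c0, c1) in zip(zip(times, times[1:]), zip(counts, counts[1:])):
            for s in np.linspace(0, 1, 20)[1:]:
                fine_t.append(t0 + s * (t1 - t0))
                fine_c.append(c0 + s * (c1 - c0))
        assert auc(GrowthCurve(fine_t, fine_c)) == pytest.approx(coarse, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc(GrowthCurve([0.0], [10]))


class TestGrowthIndex:
    def test_equal_aucs_give_zero(self):
        assert growth_index(1234.5, 1234.5) == 0.0

    @pytest.mark.parametrize("ratio, gi", [(2.0, 1.0), (0.5, -1.0)])
    def test_log2_of_ratio(self, ratio, gi):
        assert growth_index(ratio * 100.0, 100.0) == pytest.approx(gi)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.uniform(10, 1000, 2)
            assert growth_index(a, b) == pytest.approx(-growth_index(b, a))

    def test_nonpositive_auc_rejected(self):
        with pytest.raises(ValueError):
            growth_index(0.0, 10.0)


class TestBliss:
    def test_null_drug_is_identity(self):
        assert bliss_reference(0.0, 0.6) == 0.6

    def test_saturated_drug_dominates(self):
        assert bliss_reference(1.0, 0.3) == 1.0

    def test_half_half(self):
        assert bliss_reference(0.5, 0.5) == 0.75

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.random(2)
            assert bliss_reference(x, y) == pytest.approx(bliss_reference(y, x))
            assert 0.0 <= bliss_reference(x, y) <= 1.0

    def test_out_of_range_effects_rejected(self):
        with pytest.raises(ValueError):
            bliss_reference(-0.1, 0.5)
        with pytest.raises(ValueError):
            bliss_reference(0.5, 1.2)


class TestCombinationIndex:
    def test_additivity_point_is_one(self):
        e_hat = bliss_reference(0.3, 0.4)
        assert combination_index(e_hat, e_hat) == 1.0

    def test_synergy_below_one(self):
        assert combination_index(0.4, 0.8) == 0.5

    def test_antagonism_above_one(self):
        assert combination_index(0.8, 0.4) == 2.0

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            combination_index(0.5, 0.0)


class TestEffectFromGrowth:
    def test_no_change_is_zero(self):
        assert effect_from_growth(100.0, 100.0) == 0.0

    def test_halved_auc_is_half(self):
        assert effect_from_growth(50.0, 100.0) == 0.5

    def test_growth_promotion_clamped_to_zero(self):
        assert effect_from_growth(150.0, 100.0) == 0.0


class TestLayers:
    def test_centre_is_layer_one(self):
        assert layer_decompose([[0.0, 0.0, 0.0]])[0] == 1

    def test_225_micron_is_layer_five(self):
        assert layer_decompose([[225.0, 0.0, 0.0]])[0] == 5

    def test_boundary_goes_to_outer_layer(self):
        assert layer_decompose([[50.0, 0.0, 0.0]])[0] == 2

    def test_partition_of_population(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-240, 240, (500, 3))
        layers = layer_decompose(pos)
        assert layers.shape == (500,)
        dist = np.linalg.norm(pos, axis=1)
        assert ((dist >= (layers - 1) * 50.0) & (dist < layers * 50.0)).all()

    def test_per_layer_hand_counts(self):
        rows = []
        for i, r in enumerate([10.0, 30.0, 60.0, 80.0, 120.0]):
            rows.append([0.0, i, r, 0.0, 0.0, 8.0, "cycling", ""])
        table = SnapshotTable(frame(rows))
        curves = per_layer_growth(table)
        assert curves[1].alive.tolist() == [2]
        assert curves[2].alive.tolist() == [2]
        assert curves[3].alive.tolist() == [1]

    def test_whole_population_auc_equals_layer_sum(self):
        rng = np.random.default_rng(4)
        rows = []
        cid = 0
        for t in (0.0, 100.0, 200.0):
            for _ in range(rng.integers(20, 40)):
                x, y, z = rng.uniform(-120, 120, 3)
                rows.append([t, cid, x, y, z, 8.0, "cycling", ""])
                cid += 1
        table = SnapshotTable(frame(rows))
        total = auc(growth_curve(table))
        layered = sum(auc(c) for c in per_layer_growth(table).values())
        assert layered == pytest.approx(total, rel=1e-12)

    def test_identical_snapshots_give_zero_gi_everywhere(self):
        rows = [[t, i, 30.0 * i, 0.0, 0.0, 8.0, "cycling", ""]
                for t in (0.0, 100.0) for i in range(4)]
        table = SnapshotTable(frame(rows))
        gis = per_layer_gi(table, table)
        assert all(v == 0.0 for v in gis.values() if v is not None)
        assert any(v is not None for v in gis.values())

    def test_empty_layer_reported_missing(self):
        near = SnapshotTable(frame(
            [[t, 0, 10.0, 0.0, 0.0, 8.0, "cycling", ""] for t in (0.0, 100.0)]))
        far = SnapshotTable(frame(
            [[t, 0, 80.0, 0.0, 0.0, 8.0, "cycling", ""] for t in (0.0, 100.0)]))
        gis = per_layer_gi(near, far)
        assert gis[1] is None and gis[2] is None


class TestPovray:
    def golden_frame(self):
        return pd.DataFrame({
            "time": [0.0] * 5, "id": range(5),
            "x": [0.0, 20.0, -20.0, 0.0, 10.0],
            "y": [0.0, 0.0, 10.0, -15.0, 25.0],
            "z": [0.0, 5.0, 0.0, 10.0, -10.0],
            "radius": [8.4, 8.4, 6.0, 8.4, 5.0],
            "phase": ["cycling", "cycling", "apoptotic", "necrotic", "removed"],
            "layer": [""] * 5,
        })

    def test_single_living_cell_is_one_blue_sphere(self):
        scene = povray_export(self.golden_frame().iloc[:1])
        assert scene.count("sphere {") == 1
        assert "<0.20, 0.40, 1.00>" in scene

    def test_sphere_count_excludes_removed(self):
        scene = povray_export(self.golden_frame())
        assert scene.count("sphere {") == 4

    def test_apoptotic_cells_are_red(self):
        scene = povray_export(self.golden_frame())
        assert "<1.00, 0.15, 0.15>" in scene

    def test_golden_file_byte_identical(self):
        scene = povray_export(self.golden_frame())
        assert scene == (DATA / "golden_scene.pov").read_text()

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            povray_export(self.golden_frame().iloc[0:0])


class TestCsvRoundTrip:
    def test_write_read_write_idempotent(self, tmp_path):
        table = snapshot_of({0.0: {"cycling": 5}, 240.0: {"cycling": 6,
                                                          "apoptotic": 1}})
        cells_path, counts_path = to_csv(table, tmp_path / "a")
        again = read_csv(cells_path)
        cells2, counts2 = to_csv(again, tmp_path / "b")
        assert cells_path.read_text() == cells2.read_text()
        assert counts_path.read_text() == counts2.read_text()

    def test_counts_rows_equal_snapshot_count(self, tmp_path):
        table = snapshot_of({0.0: {"cycling": 2}, 240.0: {"cycling": 3},
                             480.0: {"cycling": 4}})
        _, counts_path = to_csv(table, tmp_path)
        counts = pd.read_csv(counts_path)
        assert len(counts) == 3
        assert counts["alive"].tolist() == [2, 3, 4]

    def test_empty_population_writes_header_only(self, tmp_path):
        table = SnapshotTable(frame([]))
        cells_path, counts_path = to_csv(table, tmp_path)
        assert pd.read_csv(cells_path).empty
        assert pd.read_csv(counts_path).empty
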