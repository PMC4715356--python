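import numpy as np
import pandas as pd
import pytest

from retlam.binning import (append_additional_region,
                            compute_manual_boundaries,
                            compute_uniform_boundaries)
from retlam.errors import NormalizationError
from retlam.profiles import IntensityProfile
from retlam.quantify import (RESULT_COLUMNS, assemble_results, assign_layers,
                             intensity_percent, layer_mean_intensity,
                             normalized_intensity, quantify_channel,
                             subtract_background, write_results)


def random_boundary_set(rng, max_interior=6):
    k = rng.integers(0, max_interior + 1)
    pos = np.sort(rng.uniform(0.05, 0.95, k))
    pos = pos[np.concatenate([[True], np.diff(pos) > 1e-3])] if k else pos
    return compute_manual_boundaries(pos)


class TestLayerMeans:
    def test_constant_profile(self):
        prof = IntensityProfile(np.full(100, 5.0))
        means = layer_mean_intensity(prof, compute_uniform_boundaries(4))
        np.testing.assert_allclose(means, 5.0)

    def test_step_function_split_at_half(self):
        values = np.where(np.arange(100) < 50, 1.0, 3.0)
        means = layer_mean_intensity(IntensityProfile(values),
                                     compute_manual_boundaries([0.5]))
        np.testing.assert_allclose(means, [1.0, 3.0])

    def test_matches_bruteforce_interval_assignment(self, rng):
        for _ in range(50):
            n = int(rng.integers(40, 200))
            values = rng.uniform(0, 255, n)
            bs = random_boundary_set(rng)
            means = layer_mean_intensity(IntensityProfile(values), bs)
            b = bs.boundaries
            for k in range(bs.n_layers):
                members = [values[i] for i in range(n)
                           if (b[k] <= (i + 0.5) / n < b[k + 1])
                           or (k == bs.n_layers - 1 and (i + 0.5) / n == b[-1])]
                expected = np.mean(members) if members else 0.0
                assert means[k] == pytest.approx(expected)

    def test_every_pixel_in_exactly_one_layer(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 300))
            bs = random_boundary_set(rng)
            idx = assign_layers(n, bs, float(n))
            assert np.all(idx >= 0)
            counts = np.bincount(idx, minlength=bs.n_layers)
            assert counts.sum() == n

    def test_profile_shorter_than_outer_boundary_raises(self):
        bs = append_additional_region(compute_uniform_boundaries(5), 1.5)
        with pytest.raises(ValueError, match="cover"):
            layer_mean_intensity(IntensityProfile(np.ones(100)), bs, 100.0)

    def test_empty_layer_gets_zero_and_warning(self, caplog):
        bs = compute_manual_boundaries([0.001, 0.002])
        with caplog.at_level("WARNING"):
            means = layer_mean_intensity(IntensityProfile(np.ones(100)), bs)
        assert means[1] == 0.0
        assert any("no pixel centers" in r.message for r in caplog.records)


class TestIntensityStatistics:
    def test_normalization_formula(self):
        np.testing.assert_allclose(normalized_intensity([10, 20, 30]),
                                   [0.1, 10.1, 20.1])

    def test_zero_layer_goes_negative_unclamped(self):
        np.testing.assert_allclose(normalized_intensity([0, 10]), [-9.9, 0.1])

    def test_uniform_means(self):
        np.testing.assert_allclose(normalized_intensity([4.0, 4.0, 4.0]),
                                   0.01 * 4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(NormalizationError):
            normalized_intensity([0.0, 0.0])

    def test_rank_order_preserved(self, rng):
        means = rng.uniform(0, 50, 10)
        assert list(np.argsort(normalized_intensity(means))) == \
               list(np.argsort(means))

    def test_background_subtraction(self):
        np.testing.assert_allclose(subtract_background([5, 10], 0), [5, 10])
        np.testing.assert_allclose(subtract_background([5, 10], 5), [0, 5])
        np.testing.assert_allclose(subtract_background([3], 5), [-2])

    def test_percent_shares(self):
        np.testing.assert_allclose(intensity_percent([20, 30, 50]),
                                   [20, 30, 50])
        np.testing.assert_allclose(intensity_percent([0, 7, 0]), [0, 100, 0])

    def test_percent_sums_to_hundred(self, rng):
        means = rng.uniform(0.1, 9, 12)
        assert intensity_percent(means).sum() == pytest.approx(100, abs=1e-6)

    def test_percent_of_all_zero_rejected(self):
        with pytest.raises(ValueError):
            intensity_percent([0.0, 0.0])


class TestAssembly:
    def make_tables(self, images=("img1",), channels=("c0", "c1", "c2")):
        bs = append_additional_region(compute_uniform_boundaries(10), 1.2)
        tables = {}
        rng = np.random.default_rng(1)
        for im in images:
            for ch in channels:
                prof = IntensityProfile(rng.uniform(1, 9, 120))
                tables[(im, ch)] = quantify_channel(prof, bs, 100.0)
        return tables

    def test_record_count_with_additional_region(self):
        results = assemble_results(self.make_tables())
        assert len(results) == 11 * 3  # (10 IPL + additional) x 3 channels

    def test_background_column_blank_when_disabled(self, tmp_path):
        results = assemble_results(self.make_tables(), with_background=False)
        assert results["intensity_minus_background"].isna().all()
        path = tmp_path / "results.tsv"
        write_results(results, path)
        table = pd.read_csv(path, sep="\t")
        assert list(table.columns) == RESULT_COLUMNS
        assert table["intensity_minus_background"].isna().all()

    def test_combined_rows_are_cross_image_means(self):
        tables = self.make_tables(images=("a", "b"))
        results = assemble_results(tables)
        combined = results[results["image"] == "combined"]
        assert len(combined) == 11 * 3
        for (ch, layer), row in combined.set_index(
                ["channel", "layer_number"]).iterrows():
            expected = np.mean([
                tables[(im, ch)].set_index("layer_number")
                .loc[layer, "intensity"] for im in ("a", "b")])
            assert row["intensity"] == pytest.approx(expected)

    def test_inconsistent_layer_counts_rejected(self):
        tables = self.make_tables()
        prof = IntensityProfile(np.ones(50))
        tables[("img1", "odd")] = quantify_channel(
            prof, compute_uniform_boundaries(5))
        with pytest.raises(ValueError, match="layer counts"):
            assemble_results(tables)

    def test_written_numbers_have_six_significant_digits(self, tmp_path):
        results = assemble_results(self.make_tables())
        path = tmp_path / "r.tsv"
        write_results(results, path)
        body = path.read_text().splitlines()[1]
        cell = body.split("\t")[5]  # an intensity value
        assert len(cell.replace(".", "").replace("-", "").lstrip("0")) <= 6
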