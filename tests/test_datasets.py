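"""Synthetic generator closed forms, determinism and bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csarray import datasets
from csarray.datasets import (
    AnalyteFingerprint,
    NoiseSpec,
    generate_adulteration,
    generate_class_population,
    generate_mixture_grid,
    generate_single_analyte,
    mixture_expected_response,
)

QUIET = NoiseSpec(replicate_sd=0.0, seed=0)


def simple_fp(amp=None, k=1.0, s=1.0, name="toy"):
    amp = np.arange(1.0, 13.0) if amp is None else np.asarray(amp, float)
    return AnalyteFingerprint(name, amp, k, s)


class TestFingerprint:
    def test_zero_concentration_gives_zero_response(self):
        d = generate_single_analyte(simple_fp(), [0.0], 3, QUIET)
        assert np.all(d.features == 0.0)

    def test_saturation_limit_approaches_max_response(self):
        fp = simple_fp(k=0.5, s=1.2)
        row = fp.expected_response(1e6)
        assert np.allclose(row, fp.max_response, rtol=1e-2)

    def test_half_saturation_point_is_half_the_maximum(self):
        fp = simple_fp(k=1.0, s=1.0)
        assert np.allclose(fp.expected_response(1.0), fp.max_response / 2.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simple_fp(k=0.0)
        with pytest.raises(ValueError):
            simple_fp(s=-1.0)
        with pytest.raises(ValueError, match="12"):
            AnalyteFingerprint("bad", np.ones(5), 1.0, 1.0)

    def test_per_channel_parameters_broadcast(self):
        fp = AnalyteFingerprint("v", np.ones(12), np.linspace(1, 4, 12), 1.0)
        r = fp.expected_response(2.0)
        assert np.allclose(r, 2.0 / (np.linspace(1, 4, 12) + 2.0))

    @given(st.floats(0.001, 10.0), st.floats(1.2, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_magnitude_monotone_in_concentration(self, c, factor):
        fp = simple_fp(amp=[-5, 3, 8, -2, 1, 6, -7, 4, 9, -1, 2, 5], k=0.7, s=0.6)
        lo, hi = np.abs(fp.expected_response(c)), np.abs(fp.expected_response(c * factor))
        assert np.all(hi >= lo - 1e-12)


class TestSingleAnalyte:
    def test_row_count_is_conditions_times_replicates(self):
        d = generate_single_analyte(simple_fp(), [0.1, 1, 10], 24, QUIET)
        assert len(d) == 72
        assert list(d.labels["concentration"].unique()) == [0.1, 1, 10]

    def test_negative_concentration_rejected_naming_value(self):
        with pytest.raises(ValueError, match="-0.5"):
            generate_single_analyte(simple_fp(), [1.0, -0.5], 2, QUIET)

    def test_noise_free_rows_equal_expected_response(self):
        fp = simple_fp(k=2.0, s=0.8)
        d = generate_single_analyte(fp, [0.5, 5.0], 2, QUIET)
        assert np.allclose(d.features[0], fp.expected_response(0.5))
        assert np.allclose(d.features[2], fp.expected_response(5.0))

    def test_seeded_determinism(self):
        noise = NoiseSpec(replicate_sd=2.0, seed=11)
        a = generate_single_analyte(simple_fp(), [1, 2], 5, noise)
        b = generate_single_analyte(simple_fp(), [1, 2], 5, noise)
        assert np.array_equal(a.features, b.features)


class TestMixtureGrid:
    def grid_set(self, fingerprints, **kw):
        fps = [fingerprints["acetic"], fingerprints["hexanoic"], fingerprints["butyric"]]
        return generate_mixture_grid(fps, 6.0, datasets.MIXTURE_GRID, 4, QUIET, **kw)

    def test_five_point_grid_gives_25_distinct_classes(self, fingerprints):
        d = self.grid_set(fingerprints)
        counts = d.labels["label"].value_counts()
        assert len(counts) == 25 and set(counts) == {4}
        assert counts.index[0] == "h1" and "h25" in counts.index

    def test_zero_variable_acids_reduce_to_fixed_component(self, fingerprints):
        fps = [fingerprints["acetic"], fingerprints["hexanoic"], fingerprints["butyric"]]
        d = generate_mixture_grid(fps, 6.0, [0.0], 1, QUIET)
        assert np.allclose(d.features[0], fps[0].expected_response(6.0))

    def test_interaction_offset_deterministic_and_distinct(self, fingerprints):
        fps = [fingerprints["acetic"], fingerprints["hexanoic"], fingerprints["butyric"]]
        a = mixture_expected_response(fps, (6.0, 1.0, 3.0))
        b = mixture_expected_response(fps, (6.0, 1.0, 3.0))
        c = mixture_expected_response(fps, (6.0, 3.0, 1.0))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_additivity_when_interaction_disabled(self, fingerprints):
        fps = [fingerprints["acetic"], fingerprints["hexanoic"], fingerprints["butyric"]]
        got = mixture_expected_response(fps, (6.0, 1.0, 3.0), interaction_strength=0.0)
        expected = (
            fps[0].expected_response(6.0)
            + fps[1].expected_response(1.0)
            + fps[2].expected_response(3.0)
        )
        assert np.allclose(got, np.clip(expected, -255, 255))

    def test_identical_noisespec_gives_identical_matrices(self, fingerprints):
        fps = [fingerprints["acetic"], fingerprints["hexanoic"], fingerprints["butyric"]]
        noise = NoiseSpec(replicate_sd=3.0, seed=5)
        a = generate_mixture_grid(fps, 6.0, [0.1, 1.0], 3, noise)
        b = generate_mixture_grid(fps, 6.0, [0.1, 1.0], 3, noise)
        assert np.array_equal(a.features, b.features)

    def test_fewer_than_three_fingerprints_rejected(self, fingerprints):
        with pytest.raises(ValueError, match="3 fingerprints"):
            generate_mixture_grid([fingerprints["acetic"]], 6.0, [1.0], 2, QUIET)


class TestClassPopulation:
    def test_noise_free_rows_equal_centroids(self):
        cents = np.vstack([np.zeros(12), np.ones(12)])
        d = generate_class_population(cents, 3, QUIET)
        assert np.array_equal(d.features[:3], np.zeros((3, 12)))
        assert np.array_equal(d.features[3:], np.ones((3, 12)))

    def test_12_classes_24_replicates_bookkeeping(self):
        cents = datasets.draw_class_centroids(12, seed=0)
        d = generate_class_population(cents, 24, QUIET)
        assert len(d) == 288
        assert list(d.labels["label"].unique()) == [f"f{i}" for i in range(1, 13)]

    def test_duplicate_centroids_rejected(self):
        cents = np.vstack([np.ones(12), np.ones(12)])
        with pytest.raises(ValueError, match="duplicate"):
            generate_class_population(cents, 2, QUIET)

    def test_nearest_centroid_recovers_labels_at_high_separation(self):
        cents = datasets.draw_class_centroids(6, seed=3)
        sd = datasets.min_separation(cents) / 10.0
        d = generate_class_population(cents, 24, NoiseSpec(replicate_sd=sd, seed=2))
        # brute-force nearest-centroid assignment
        dist = ((d.features[:, None, :] - cents[None]) ** 2).sum(axis=2)
        assigned = dist.argmin(axis=1)
        truth = np.repeat(np.arange(6), 24)
        assert np.array_equal(assigned, truth)


class TestAdulteration:
    def test_blend_endpoints(self):
        pure, adult = np.full(12, 10.0), np.full(12, -20.0)
        d = generate_adulteration(pure, adult, [0.0, 1.0], 1, QUIET)
        assert np.allclose(d.features[0], pure)
        assert np.allclose(d.features[1], adult)

    def test_blends_lie_on_segment(self):
        pure, adult = np.zeros(12), np.full(12, 100.0)
        fr = [0.5, 0.6, 0.7, 0.8, 0.9]
        d = generate_adulteration(pure, adult, fr, 1, QUIET)
        assert np.allclose(d.features, np.outer(fr, adult))
        assert len(np.unique(d.features[:, 0])) == 5

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="1.5"):
            generate_adulteration(np.zeros(12), np.ones(12), [1.5], 1, QUIET)


class TestIO:
    def test_csv_roundtrip_with_metadata(self, tmp_path, fingerprints):
        d = generate_single_analyte(
            fingerprints["acetic"], [0.1, 1.0], 3, NoiseSpec(replicate_sd=1.0, seed=9)
        )
        path = tmp_path / "set.csv"
        datasets.write_response_set(path, d)
        back = datasets.read_response_set(path)
        assert np.allclose(back.features, d.features)
        pd.testing.assert_frame_equal(back.labels, d.labels.reset_index(drop=True))
        assert back.metadata["seed"] == 9

    def test_metadata_regenerates_set_exactly(self, fingerprints):
        d = generate_single_analyte(
            fingerprints["lactic"], [0.5, 5.0], 4, NoiseSpec(replicate_sd=2.0, seed=3)
        )
        meta = d.metadata
        again = generate_single_analyte(
            AnalyteFingerprint.from_dict(meta["fingerprint"]),
            meta["concentrations"],
            meta["n_rep"],
            NoiseSpec(meta["replicate_sd"], meta["seed"]),
        )
        assert np.array_equal(d.features, again.features)


def test_default_library_has_nine_distinct_acids(fingerprints):
    assert set(fingerprints) == set(datasets.MOLAR_MASS_G_PER_MOL)
    dirs = np.array([fp.max_response / np.linalg.norm(fp.max_response) for fp in fingerprints.values()])
    cos = dirs @ dirs.T
    np.fill_diagonal(cos, 0.0)
    assert np.abs(cos).max() < 0.9  # pairwise-distinct directions
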