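"""Generator properties: determinism, ground-truth self-consistency, gate fidelity."""

import numpy as np
import pytest

from conftest import brute_force_golgi_features
from phenogate.errors import ParameterError
from phenogate.gates import GateConfig, Morphotype, classify_golgi_morphotype
from phenogate.synth import (
    ColocSpec,
    NotochordSpec,
    SpotFieldSpec,
    SyntheticCellSpec,
    TARGET_BOXES,
    generate_cell_image,
    generate_coloc_pair,
    generate_notochord_trace,
    generate_population,
    generate_spot_image,
    sample_targets,
)


class TestCellGeneration:
    def test_realized_features_match_brute_force_oracle(self, compact_cell):
        """Sidecar (A, MI) equal independent pixel counting on the true masks."""
        stack, truth = compact_cell
        a, mi = brute_force_golgi_features(
            truth.cell_mask, truth.golgi_mask, stack["golgi"])
        assert truth.realized_a == pytest.approx(a, abs=1e-9)
        assert truth.realized_mi == pytest.approx(mi, abs=1e-9)

    def test_compact_cell_lands_in_compact_gate(self, compact_cell):
        _, truth = compact_cell
        label = classify_golgi_morphotype(truth.realized_a, truth.realized_mi)
        assert label is Morphotype.COMPACT

    def test_dispersed_cell_exceeds_printed_gate_bounds(self):
        """A > 12 and MI < 0.8 for a totally dispersed target, as the gate demands."""
        spec = SyntheticCellSpec("totally_dispersed", target_a=20.0,
                                 target_mi=0.4, seed=7)
        _, truth = generate_cell_image(spec)
        assert truth.realized_a > 12
        assert truth.realized_mi < 0.8
        assert truth.true_label is Morphotype.TOTALLY_DISPERSED

    def test_realized_a_within_half_pixel_of_target(self, dispersed_cell):
        _, truth = dispersed_cell
        half_pixel_pct = 100.0 * 0.5 / truth.cell_mask.sum()
        assert abs(truth.realized_a - 15.0) <= half_pixel_pct
        assert truth.realized_mi == pytest.approx(0.4, abs=1e-12)

    def test_noiseless_unblurred_golgi_channel_is_mask_times_constant(self):
        spec = SyntheticCellSpec("compact", target_a=2.0, target_mi=1.8,
                                 n_golgi_objects=1, psf_sigma=0.0, noise_sd=0.0,
                                 seed=4)
        stack, truth = generate_cell_image(spec)
        expected = truth.golgi_mask * (1.8 * 100.0)
        assert np.array_equal(stack["golgi"], expected)

    def test_identical_spec_is_bit_identical(self):
        spec = SyntheticCellSpec("partially_dispersed", target_a=6.0,
                                 target_mi=0.5, noise_sd=3.0, seed=42)
        s1, t1 = generate_cell_image(spec)
        s2, t2 = generate_cell_image(spec)
        for name in s1.channels:
            assert np.array_equal(s1[name], s2[name])
        assert np.array_equal(t1.golgi_mask, t2.golgi_mask)

    def test_masks_nest(self, dispersed_cell):
        _, truth = dispersed_cell
        assert not (truth.nucleus_mask & ~truth.cell_mask).any()
        assert not (truth.golgi_mask & ~truth.cell_mask).any()
        assert not (truth.golgi_mask & truth.nucleus_mask).any()

    @pytest.mark.parametrize("kwargs", [
        dict(target_a=0.0), dict(target_a=100.0), dict(target_a=95.0),
        dict(nucleus_radius=120.0), dict(noise_sd=-1.0),
    ])
    def test_invalid_specs_raise(self, kwargs):
        base = dict(morphotype="compact", target_a=1.5, target_mi=2.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            spec = SyntheticCellSpec(**base)
            generate_cell_image(spec)


class TestPopulation:
    def test_counts_and_determinism(self):
        counts = {m.value: 3 for m in TARGET_BOXES}
        pop1 = generate_population(counts, seed=3)
        pop2 = generate_population(counts, seed=3)
        assert len(pop1) == 12
        labels = [t.true_label for _, t in pop1]
        for m in TARGET_BOXES:
            assert labels.count(m) == 3
        for (s1, t1), (s2, t2) in zip(pop1, pop2):
            assert np.array_equal(s1["golgi"], s2["golgi"])
            assert t1.realized_a == t2.realized_a

    def test_empty_request_gives_empty_dataset(self):
        assert generate_population({"compact": 0}, seed=1) == []

    def test_margin_keeps_targets_away_from_gate_boundaries(self):
        """With margin m, sampled targets sit >= m * box-width from each finite edge."""
        rng = np.random.default_rng(0)
        for label, ((a_lo, a_hi), (mi_lo, mi_hi)) in TARGET_BOXES.items():
            pts = sample_targets(label, 200, rng, margin=0.2)
            da, dmi = a_hi - a_lo, mi_hi - mi_lo
            assert np.all(pts[:, 0] >= a_lo + 0.2 * da)
            assert np.all(pts[:, 0] <= a_hi - 0.2 * da)
            assert np.all(pts[:, 1] >= mi_lo + 0.2 * dmi)
            assert np.all(pts[:, 1] <= mi_hi - 0.2 * dmi)

    def test_gate_fidelity_at_zero_noise(self):
        """Every generated cell's realized features classify as its true label."""
        counts = {m.value: 4 for m in TARGET_BOXES}
        for _, truth in generate_population(counts, seed=9, margin=0.1):
            label = classify_golgi_morphotype(truth.realized_a, truth.realized_mi)
            assert label is truth.true_label


class TestColocPairs:
    def test_identical_channels_give_exactly_one(self):
        stack, truth = generate_coloc_pair(ColocSpec(true_m1=1.0, true_m2=1.0, seed=2))
        assert np.array_equal(stack["ch_a"], stack["ch_b"])
        assert truth.realized_m1 == 1.0 and truth.realized_m2 == 1.0

    def test_disjoint_supports_give_exactly_zero(self):
        stack, truth = generate_coloc_pair(ColocSpec(true_m1=0.0, true_m2=0.0, seed=2))
        assert not (truth.mask_a & truth.mask_b).any()
        assert truth.realized_m1 == 0.0 and truth.realized_m2 == 0.0

    @pytest.mark.parametrize("m1,m2", [(0.5, 0.5), (0.3, 0.8), (0.7, 0.25)])
    def test_targets_hit_within_tolerance(self, m1, m2):
        _, truth = generate_coloc_pair(ColocSpec(true_m1=m1, true_m2=m2, seed=5))
        assert truth.realized_m1 == pytest.approx(m1, abs=0.02)
        assert truth.realized_m2 == pytest.approx(m2, abs=0.02)

    def test_unreachable_targets_raise(self):
        with pytest.raises(ParameterError):
            ColocSpec(true_m1=0.5, true_m2=0.5, n_objects=0)
        with pytest.raises(ParameterError):
            ColocSpec(true_m1=0.0, true_m2=0.5)  # empty overlap forces M2 = 0


class TestNotochordTraces:
    def test_single_180_gives_collinear_trace(self):
        trace = generate_notochord_trace(NotochordSpec(vertex_angles=(180.0,)))
        assert trace.shape == (3, 2)
        v1, v2 = trace[1] - trace[0], trace[2] - trace[1]
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        assert cross == pytest.approx(0.0, abs=1e-9)

    def test_no_angles_gives_straight_two_segment_trace(self):
        trace = generate_notochord_trace(NotochordSpec())
        assert trace.shape == (3, 2)

    def test_jitter_free_trace_is_seed_independent(self):
        spec_a = NotochordSpec(vertex_angles=(120.0, 100.0), jitter_sd=0.0, seed=1)
        spec_b = NotochordSpec(vertex_angles=(120.0, 100.0), jitter_sd=0.0, seed=999)
        assert np.array_equal(generate_notochord_trace(spec_a),
                              generate_notochord_trace(spec_b))

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ParameterError):
            NotochordSpec(vertex_angles=(0.0,))
        with pytest.raises(ParameterError):
            NotochordSpec(vertex_angles=(181.0,))


class TestSpotFields:
    def test_zero_spots_gives_empty_coordinates(self):
        img, coords = generate_spot_image(SpotFieldSpec(n_spots=0, seed=1))
        assert coords.shape == (0, 2)
        assert img.max() == 0.0  # noiseless empty field is blank

    def test_noiseless_field_has_exactly_n_local_maxima(self):
        """Exhaustive 8-neighbour scan finds one strict maximum per spot."""
        img, coords = generate_spot_image(SpotFieldSpec(n_spots=7, seed=3))
        h, w = img.shape
        maxima = []
        for i in range(1, h - 1):
            for j in range(1, w - 1):
                v = img[i, j]
                if v > 0.5 * img.max():
                    patch = img[i - 1:i + 2, j - 1:j + 2].copy()
                    patch[1, 1] = -np.inf
                    if v > patch.max():
                        maxima.append((i, j))
        assert len(maxima) == 7
        assert sorted(maxima) == sorted(map(tuple, coords.astype(int)))

    def test_determinism_and_min_separation(self):
        spec = SpotFieldSpec(n_spots=9, min_separation=12.0, seed=8)
        img1, c1 = generate_spot_image(spec)
        img2, c2 = generate_spot_image(spec)
        assert np.array_equal(c1, c2) and np.array_equal(img1, img2)
        d = np.linalg.norm(c1[:, None] - c1[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0

    def test_infeasible_packing_raises(self):
        with pytest.raises(ParameterError):
            generate_spot_image(SpotFieldSpec(n_spots=200, min_separation=20.0,
                                              image_shape=(64, 64), seed=0))
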