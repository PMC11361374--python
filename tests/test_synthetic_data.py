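import numpy as np
import pytest

import nepheno as ne
from nepheno.synthetic_data import frap_model, sample_count, PlacementError


class TestNucleusImages:
    def test_no_planted_objects(self):
        spec = ne.NucleusImageSpec(image_size=(200, 200), n_nuclei=1, noise_sd=0,
                                   blur_sigma=0, seed=0)
        _, _, truth = ne.make_nucleus_image(spec)
        assert truth.n_nuclei == 1
        assert len(truth.bleb_to_nucleus) == 0

    def test_planted_blebs_disjoint_from_ring(self, small_nucleus_spec):
        dapi, lamin, truth = ne.make_nucleus_image(small_nucleus_spec)
        assert len(truth.bleb_to_nucleus) == 3
        # lamin signal sits only on the ring: bleb truth pixels carry background
        bleb_px = truth.bleb_labels > 0
        assert np.all(lamin.pixels[bleb_px] == small_nucleus_spec.background_level)
        # blebs are outside the nucleus ellipse
        assert np.all(truth.nucleus_labels[bleb_px] == 0)

    def test_determinism_bit_identical(self, small_nucleus_spec):
        d1, l1, t1 = ne.make_nucleus_image(small_nucleus_spec)
        d2, l2, t2 = ne.make_nucleus_image(small_nucleus_spec)
        assert np.array_equal(d1.pixels, d2.pixels)
        assert np.array_equal(l1.pixels, l2.pixels)
        assert np.array_equal(t1.nucleus_labels, t2.nucleus_labels)

    def test_geometric_soundness_threshold_recovers_truth(self, clean_pair):
        dapi, _, truth = clean_pair
        fg = dapi.pixels > 100.0  # background_level
        assert np.array_equal(fg, (truth.nucleus_labels > 0) | (truth.bleb_labels > 0))

    def test_nuclei_disjoint_and_inside_frame(self):
        spec = ne.NucleusImageSpec(image_size=(400, 400), n_nuclei=6, noise_sd=0,
                                   blur_sigma=0, blebs_per_nucleus=1, seed=3)
        _, _, truth = ne.make_nucleus_image(spec)
        assert sorted(truth.border_touching) == list(range(1, 7))
        assert not any(truth.border_touching.values())

    def test_placement_failure_signaled(self):
        spec = ne.NucleusImageSpec(image_size=(200, 200), n_nuclei=40,
                                   radius_range=(25.0, 30.0), max_place_retries=20, seed=0)
        with pytest.raises((PlacementError, ValueError)):
            ne.make_nucleus_image(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="ring_width"):
            ne.NucleusImageSpec(radius_range=(2.0, 5.0), ring_width=3.0).validate()
        with pytest.raises(ValueError):
            ne.NucleusImageSpec(eccentricity_range=(0.2, 1.0)).validate()

    def test_truth_json_roundtrip(self, clean_pair, tmp_path):
        import json
        _, _, truth = clean_pair
        p = truth.to_json(tmp_path / "truth.json")
        data = json.loads(p.read_text())
        assert len(data["nuclei"]) == 3
        assert len(data["bleb_to_nucleus"]) == 3


class TestFociImages:
    def test_planted_counts_and_centroids_inside(self):
        spec = ne.NucleusImageSpec(image_size=(400, 400), n_nuclei=4, foci_per_nucleus=5,
                                   focus_amplitude=100.0, noise_sd=10.0, seed=5)
        marker, dapi, truth = ne.make_foci_image(spec)
        for lab, pts in truth.foci.items():
            assert len(pts) == 5
            for r, c in pts:
                assert truth.nucleus_labels[int(round(r)), int(round(c))] == lab

    def test_zero_foci_gives_background_only(self):
        spec = ne.NucleusImageSpec(image_size=(200, 200), n_nuclei=2, foci_per_nucleus=0,
                                   noise_sd=0, blur_sigma=0, seed=6)
        marker, _, _ = ne.make_foci_image(spec)
        assert np.all(marker.pixels == spec.background_level)

    def test_count_distributions(self, rng):
        assert sample_count(3, rng) == 3
        draws = [sample_count(("bernoulli", 0.5), rng) for _ in range(200)]
        assert set(draws) <= {0, 1} and 0 < sum(draws) < 200
        lam_draws = [sample_count(("poisson", 3.0), rng) for _ in range(500)]
        assert abs(np.mean(lam_draws) - 3.0) < 3 * np.sqrt(3.0 / 500)
        with pytest.raises(ValueError):
            sample_count(("weird", 1.0), rng)


class TestFrapSimulation:
    def test_protocol_93_frames_spanning_93s(self):
        trace = ne.simulate_frap(ne.FrapSimSpec())
        assert len(trace.t) == 93
        assert trace.n_prebleach == 3
        assert trace.t[0] == 0.0 and trace.t[-1] == 92.0  # 93 frames at 1 s

    def test_noiseless_matches_model_exactly(self):
        spec = ne.FrapSimSpec(y0=0.2, a=0.7, b=0.1, noise_sd=0.0, reference_decay_rate=0.0)
        trace = ne.simulate_frap(spec)
        x = trace.t[3:] - trace.t[3]
        assert np.allclose(trace.roi[3:], frap_model(x, 0.2, 0.7, 0.1), atol=0)
        assert np.all(trace.roi[:3] == 1.0)

    def test_flat_trace_when_y0_equals_a(self):
        spec = ne.FrapSimSpec(y0=0.5, a=0.5, b=0.1, noise_sd=0.0, reference_decay_rate=0.0)
        trace = ne.simulate_frap(spec)
        assert np.allclose(trace.roi[3:], 0.5)

    def test_half_time_closed_form(self):
        # noiseless trace evaluated at x = ln2/b sits exactly halfway
        y = frap_model(np.log(2) / 0.13, 0.1, 0.9, 0.13)
        assert y == pytest.approx((0.1 + 0.9) / 2, abs=1e-15)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ne.FrapSimSpec(b=-1.0).validate()
        with pytest.raises(ValueError):
            ne.FrapSimSpec(y0=0.9, a=0.5).validate()


class TestCountSimulation:
    def test_no_de_when_fraction_zero(self):
        sim = ne.simulate_counts(ne.CountSimSpec(n_genes=100, de_fraction=0.0, seed=0))
        assert sim.truth["is_de"].sum() == 0

    def test_determinism(self):
        spec = ne.CountSimSpec(n_genes=200, seed=9)
        a = ne.simulate_counts(spec).counts
        b = ne.simulate_counts(spec).counts
        assert a.equals(b)

    def test_counts_nonnegative_integers(self):
        sim = ne.simulate_counts(ne.CountSimSpec(n_genes=300, dispersion=0.5, seed=1))
        arr = sim.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()

    def test_low_dispersion_recovers_planted_log2fc(self):
        # law of large numbers at n = 50 samples/group, near-Poisson counts
        spec = ne.CountSimSpec(n_genes=200, n_samples_per_group=50, dispersion=1e-15,
                               mean_log=7.0, sd_log=0.3, de_fraction=0.5,
                               planted_log2fc=2.0, seed=11)
        sim = ne.simulate_counts(spec)
        de = sim.truth["is_de"].to_numpy()
        m1 = sim.counts.loc[:, sim.groups == "g1"].mean(axis=1).to_numpy()
        m2 = sim.counts.loc[:, sim.groups == "g2"].mean(axis=1).to_numpy()
        ratio = np.log2(m2[de] / m1[de])
        assert np.abs(ratio - 2.0).max() < 0.15
        assert np.abs(np.log2(m2[~de] / m1[~de])).max() < 0.15
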