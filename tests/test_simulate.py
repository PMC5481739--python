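"""Cohort generator: allelic-signal model, determinism and marginal rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tscpipe.config import GENE_LOCI, CohortConfig, ConfigError
from tscpipe.simulate import (
    draw_deletion_sizes,
    expected_allelic_signal,
    generate_cohort,
    make_reference_profiles,
    sample_truth,
    simulate_track,
)


class TestExpectedAllelicSignal:
    @pytest.mark.parametrize("purity", [0.1, 0.5, 1.0])
    def test_diploid_identity(self, purity):
        (b1, b2), lrr = expected_allelic_signal((1, 1), purity)
        assert b1 == b2 == pytest.approx(0.5)
        assert lrr == pytest.approx(0.0)

    def test_cnloh_pure_tumour(self):
        (b1, b2), lrr = expected_allelic_signal((2, 0), 1.0)
        assert sorted([b1, b2]) == [0.0, 1.0]
        assert lrr == pytest.approx(0.0)

    def test_cnloh_half_purity(self):
        (b1, b2), lrr = expected_allelic_signal((2, 0), 0.5)
        assert sorted([b1, b2]) == pytest.approx([0.25, 0.75])
        assert lrr == pytest.approx(0.0)

    def test_deletion_lrr(self):
        _, lrr = expected_allelic_signal((1, 0), 0.8)
        assert lrr == pytest.approx(math.log2(1.2 / 2), abs=1e-9)

    @pytest.mark.parametrize("purity", [0.0, -0.2, 1.01])
    def test_purity_domain_error(self, purity):
        with pytest.raises(ValueError):
            expected_allelic_signal((1, 1), purity)

    def test_homozygous_deletion_pure_tumour_rejected(self):
        with pytest.raises(ValueError):
            expected_allelic_signal((0, 0), 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        na=st.integers(0, 4), nb=st.integers(0, 4),
        purity=st.floats(0.01, 1.0, allow_nan=False),
    )
    def test_mirror_alternatives_sum_to_one(self, na, nb, purity):
        if na == 0 and nb == 0 and purity == 1.0:
            return
        (b1, b2), _ = expected_allelic_signal((na, nb), purity)
        assert b1 + b2 == pytest.approx(1.0)
        assert 0.0 <= b1 <= 1.0


class TestConfig:
    def test_bad_proportions_name_field(self):
        with pytest.raises(ConfigError, match="gene_split"):
            CohortConfig(gene_split={"TSC2": 0.9, "TSC1": 0.2, "none": 0.03})

    def test_bad_purity_range(self):
        with pytest.raises(ConfigError, match="purity_range"):
            CohortConfig(purity_range=(0.0, 0.9))

    def test_roundtrip(self, tmp_path):
        from tscpipe.config import read_config, write_config

        cfg = CohortConfig(n_patients=7, seed=3, somatic_rate_per_mb=0.5)
        path = tmp_path / "cfg.txt"
        write_config(cfg, path)
        back = read_config(path)
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_key_rejected(self, tmp_path):
        from tscpipe.config import read_config

        p = tmp_path / "bad.txt"
        p.write_text("not_a_field = 3\n")
        with pytest.raises(ConfigError, match="not_a_field"):
            read_config(p)


class TestCohortGeneration:
    def test_seed_determinism_byte_identical(self):
        cfg = CohortConfig(n_patients=6, seed=42)
        t1, b1 = generate_cohort(cfg)
        t2, b2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(b1.variants, b2.variants)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        pd.testing.assert_frame_equal(b1.betas, b2.betas)
        assert t1.to_json_dict() == t2.to_json_dict()
        trk1 = b1.tracks["P001-" + t1.lesions[0]["type"] + "1"]["chr16"]
        trk2 = b2.tracks["P001-" + t2.lesions[0]["type"] + "1"]["chr16"]
        np.testing.assert_array_equal(trk1.baf, trk2.baf)

    def test_zero_second_hit_prob_gives_single_hits(self):
        cfg = CohortConfig(
            n_patients=30, seed=1,
            second_hit_prob={t: 0.0 for t in ("RA", "TUB", "SEN_SEGA", "CRM", "SK")},
        )
        truth = sample_truth(cfg)
        assert all(les["second_hit"] is None for les in truth.lesions)

    def test_gene_split_converges(self):
        cfg = CohortConfig(n_patients=500, seed=7)
        truth = sample_truth(cfg)
        frac = np.mean([p["gene"] == "TSC2" for p in truth.patients])
        se = math.sqrt(0.849 * 0.151 / 500)
        assert abs(frac - 0.849) <= 3 * se

    def test_second_hit_rate_within_binomial_ci(self):
        cfg = CohortConfig(
            n_patients=600, seed=9,
            lesion_mix={"RA": 0.0, "TUB": 1.0, "SEN_SEGA": 0.0, "CRM": 0.0, "SK": 0.0},
        )
        truth = sample_truth(cfg)
        tubers = [
            les for les in truth.lesions
            if {p["patient"]: p for p in truth.patients}[les["patient"]]["gene"]
        ]
        assert len(tubers) >= 200
        rate = np.mean([les["second_hit"] is not None for les in tubers])
        se = math.sqrt(0.35 * 0.65 / len(tubers))
        assert abs(rate - 0.35) <= 1.96 * se

    def test_deletion_size_median_and_truncation(self, rng):
        cfg = CohortConfig()
        sizes = draw_deletion_sizes(rng, 500, cfg)
        assert sizes.min() >= 462 and sizes.max() <= 4.8e6
        assert abs(np.median(sizes) - 48_600) / 48_600 <= 0.20


class TestLayers:
    def test_germline_depth_vaf_mean(self, rng):
        # binomial allele-depth layer: germline het in normal tissue -> ~0.5
        from tscpipe.simulate import _draw_depth_alt

        vafs = []
        for _ in range(400):
            dp, alt = _draw_depth_alt(rng, 100.0, 0.5)
            vafs.append(alt / dp)
        assert np.mean(vafs) == pytest.approx(0.5, abs=0.01)

    def test_somatic_vaf_tracks_purity(self, rng):
        # clonal somatic het at purity 0.26 on a diploid locus -> VAF ~0.13
        from tscpipe.simulate import _draw_depth_alt

        vafs = [alt / dp for dp, alt in
                (_draw_depth_alt(rng, 100.0, 0.26 / 2) for _ in range(600))]
        assert np.mean(vafs) == pytest.approx(0.13, abs=0.01)

    def test_track_positions_and_baf_bounds(self, small_cohort):
        truth, bundle = small_cohort
        for chrom_tracks in bundle.tracks.values():
            for track in chrom_tracks.values():
                assert np.all(np.diff(track.positions) > 0)
                assert track.baf.min() >= 0 and track.baf.max() <= 1

    def test_cnloh_track_shows_divergent_baf_stable_lrr(self, rng):
        track = simulate_track(
            "chr16", 4_000_000, [(0, 2_000_000, (1, 1), (2, 0))], 0.6, rng
        )
        het = track.het_mask
        inside = (track.positions < 2_000_000) & het
        outside = (track.positions >= 2_000_000) & het
        inside_dev = np.abs(track.baf[inside] - 0.5).mean()
        outside_dev = np.abs(track.baf[outside] - 0.5).mean()
        assert inside_dev > 0.15 > outside_dev
        assert abs(track.lrr[track.positions < 2_000_000].mean()) < 0.05

    def test_degenerate_mixture_counts_proportional_to_signature(self):
        cfg = CohortConfig(n_patients=4, seed=2, nb_dispersion=0.0)
        truth = sample_truth(cfg)
        rng = np.random.default_rng(0)
        profiles, _ = make_reference_profiles(truth, cfg, rng)
        sample = next(iter(truth.fractions))
        truth.fractions[sample] = [1.0] + [0.0] * (len(truth.cell_types) - 1)
        mu = profiles.to_numpy() @ np.asarray(truth.fractions[sample])
        # Poisson(mu) means are proportional to the pure type's column
        ratio = mu / profiles.iloc[:, 0].to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_variant_table_vaf_consistency(self, small_cohort):
        _, bundle = small_cohort
        v = bundle.variants
        assert ((v["AD_REF"] + v["AD_ALT"]) == v["DP"]).all()
        assert (v["AD_ALT"] >= 0).all() and (v["AD_ALT"] <= v["DP"]).all()

    def test_germline_hit_position_inside_gene(self, small_cohort):
        truth, _ = small_cohort
        for pat in truth.patients:
            germ = pat["germline"]
            if germ is None or "pos" not in germ:
                continue
            chrom, start, end = GENE_LOCI[pat["gene"]]
            assert germ["chrom"] == chrom and start <= germ["pos"] < end
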