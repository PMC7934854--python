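"""Generators: determinism, planted-truth consistency, validation."""

import numpy as np
import pytest

import retmosaic as rm
from retmosaic.errors import ValidationError
from retmosaic.synthetic import generate_cluster_mosaic


class TestFlatMount:
    def test_same_seed_bit_identical(self):
        spec = rm.FlatMountSpec(
            seed=7, image_height_px=256, image_width_px=256, retina_radius_px=120, n_cones=150
        )
        a, b = rm.generate_flatmount(spec), rm.generate_flatmount(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.crater_mask, b.crater_mask)

    def test_empty_mosaic_is_constant_background(self):
        spec = rm.FlatMountSpec(
            seed=1,
            image_height_px=128,
            image_width_px=128,
            retina_radius_px=60,
            n_cones=0,
            noise_sd=0.0,
            shot_noise=False,
        )
        t = rm.generate_flatmount(spec)
        assert t.n_true == 0 and len(t.centroids) == 0
        assert np.all(t.image == spec.background_level)

    def test_centroids_avoid_craters_and_stay_in_retina(self):
        spec0 = rm.FlatMountSpec(
            seed=3, image_height_px=512, image_width_px=512, retina_radius_px=240, n_cones=500
        )
        craters = rm.sample_craters(spec0, 4, 0.10, seed=3)
        spec = rm.FlatMountSpec(
            seed=3,
            image_height_px=512,
            image_width_px=512,
            retina_radius_px=240,
            n_cones=500,
            craters=craters,
        )
        t = rm.generate_flatmount(spec)
        ci = np.round(t.centroids).astype(int)
        assert t.n_true == 500
        assert not t.crater_mask[ci[:, 0], ci[:, 1]].any()
        assert t.retina_mask[ci[:, 0], ci[:, 1]].all()
        realized = t.crater_mask.sum() / t.retina_mask.sum()
        assert realized == pytest.approx(0.10, abs=0.01)

    @pytest.mark.parametrize(
        "kw",
        [
            {"image_height_px": -5},
            {"dim_fraction": 1.5},
            {"dim_amplitude": 3000.0},  # >= bright
            {"nucleus_sigma_px": 0.0},
            {"craters": ((10.0, 10.0, 50.0),)},  # escapes the retina disc
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValidationError):
            rm.generate_flatmount(rm.FlatMountSpec(seed=0, **kw))

    def test_mask_consistency_over_random_specs(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(20, 120))
            spec0 = rm.FlatMountSpec(
                seed=int(rng.integers(0, 2**31)),
                image_height_px=192,
                image_width_px=192,
                retina_radius_px=85.0,
                n_cones=n,
                dim_fraction=float(rng.uniform(0, 1)),
                cluster_fraction=float(rng.uniform(0, 0.3)),
            )
            from dataclasses import replace

            craters = rm.sample_craters(spec0, 1, float(rng.uniform(0.02, 0.08)), seed=1)
            spec = replace(spec0, craters=craters)
            t = rm.generate_flatmount(spec)
            ci = np.round(t.centroids).astype(int)
            assert not t.crater_mask[ci[:, 0], ci[:, 1]].any()
            assert t.retina_mask[ci[:, 0], ci[:, 1]].all()
            assert t.n_true == len(t.centroids) == n

    def test_cluster_mosaic_planted_geometry(self):
        truth, clusters = generate_cluster_mosaic(
            rm.FlatMountSpec(seed=2), n_singletons=100, kmer_counts={2: 10, 3: 10}
        )
        assert truth.n_true == 100 + 2 * 10 + 3 * 10
        sig = truth.spec.nucleus_sigma_px
        for cl in clusters:
            steps = np.hypot(*(np.diff(cl, axis=0).T))
            assert np.all(steps <= 2.0 * sig + 1e-9)


class TestEMField:
    def test_fractions_realized_and_masks_tile(self, em_field):
        spec, image, masks, fractions = em_field
        total = np.zeros(image.shape, dtype=int)
        for m in masks.values():
            total += m.astype(int)
        assert np.all(total == 1)  # disjoint and tiling
        assert fractions["microvilli"] == pytest.approx(0.6, abs=0.02)
        assert fractions["none"] == pytest.approx(0.3, abs=0.02)
        assert fractions["dead"] == pytest.approx(0.1, abs=0.02)

    def test_degenerate_single_class(self):
        spec = rm.EMFieldSpec(frac_microvilli=1.0, frac_none=0.0, frac_dead=0.0, seed=1)
        image, masks, fractions = rm.generate_em_field(spec)
        assert fractions["microvilli"] == 1.0
        assert masks["microvilli"].all()

    def test_determinism(self):
        spec = rm.EMFieldSpec(seed=10)
        a, _, _ = rm.generate_em_field(spec)
        b, _, _ = rm.generate_em_field(spec)
        assert np.array_equal(a, b)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            rm.generate_em_field(rm.EMFieldSpec(frac_microvilli=0.5, frac_none=0.5, frac_dead=0.1))


class TestDETables:
    def test_planted_counts_and_signs(self, de_bundle):
        spec, a, b, term_map, planted = de_bundle
        m = a.merge(b, on="gene", suffixes=("_a", "_b"))
        sig = (m["padj_a"] < spec.alpha) & (m["padj_b"] < spec.alpha)
        disc = m.loc[sig & (np.sign(m["log2fc_a"]) == -np.sign(m["log2fc_b"]))]
        conc = m.loc[sig & (np.sign(m["log2fc_a"]) == np.sign(m["log2fc_b"]))]
        assert len(disc) == spec.n_sig_discordant
        assert len(conc) == spec.n_sig_concordant
        planted_set = set(planted["discordant_up_in_a"]) | set(planted["discordant_down_in_a"])
        assert set(disc["gene"]) == planted_set

    def test_determinism(self):
        spec = rm.DETableSpec(seed=5, n_genes=400, n_sig_discordant=4, n_sig_concordant=6)
        a1, b1, t1, p1 = rm.generate_de_tables(spec)
        a2, b2, t2, p2 = rm.generate_de_tables(spec)
        assert a1.equals(a2) and b1.equals(b2) and t1.equals(t2) and p1 == p2

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValidationError):
            rm.generate_de_tables(
                rm.DETableSpec(n_genes=10, n_sig_discordant=8, n_sig_concordant=8)
            )

    def test_null_planting_gives_empty_discordance(self):
        spec = rm.DETableSpec(seed=3, n_genes=500, n_sig_discordant=0, n_sig_concordant=5)
        a, b, _, _ = rm.generate_de_tables(spec)
        res = rm.discordant_genes(a, b, alpha=spec.alpha)
        assert not res.discordant
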