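"""Ground-truth fidelity and determinism of the synthetic-data generator."""

import math

import numpy as np
import pytest

from earmorph import audiometry as aud
from earmorph import geometry as geo
from earmorph import synthetic as syn
from earmorph.phylo import bm_covariance


class TestSimulateTree:
    def test_three_tips(self):
        phy = syn.simulate_tree(3, seed=0)
        assert phy.n_tips == 3
        depths = set(round(d, 9) for d in phy.tip_depths().values())
        assert len(depths) == 1
        assert phy.is_ultrametric

    def test_deterministic_per_seed(self):
        a = syn.simulate_tree(10, seed=4).as_newick()
        b = syn.simulate_tree(10, seed=4).as_newick()
        assert a == b
        assert a != syn.simulate_tree(10, seed=5).as_newick()

    def test_33_tips_at_stated_root_age(self):
        phy = syn.simulate_tree(33, seed=1, root_age=75.0)
        assert phy.n_tips == 33
        assert max(phy.tip_depths().values()) == pytest.approx(75.0)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_tree(2)


class TestEvolveTraits:
    def test_zero_rates_give_root_everywhere(self, archetype):
        phy = syn.simulate_tree(8, seed=2)
        rates = {f: 0.0 for f in syn.default_bm_rates()}
        out = syn.evolve_traits(phy, archetype, rates, seed=0)
        for arch in out.values():
            assert arch.turns == archetype.turns
            assert arch.basal_radius == pytest.approx(archetype.basal_radius)

    def test_unknown_clade_rejected(self, archetype):
        phy = syn.simulate_tree(6, seed=3)
        with pytest.raises(ValueError, match="unknown clade"):
            syn.evolve_traits(phy, archetype, {}, {"nope": {"turns": 1.0}},
                              {"real": phy.tip_labels[:2]}, seed=0)

    def test_tip_covariance_matches_bm(self, archetype):
        # Monte-Carlo check of the additive-scale field against rate * C
        phy = syn.simulate_tree(5, seed=6, root_age=10.0)
        rate = 0.01
        reps = 5000
        vals = np.empty((5, reps))
        for r in range(reps):
            out = syn.evolve_traits(phy, archetype, {"turns": rate}, seed=r)
            vals[:, r] = [out[sp].turns for sp in phy.tip_labels]
        emp = np.cov(vals)
        C = rate * bm_covariance(phy).matrix
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / reps)
        assert np.all(np.abs(emp - C) < 3.5 * se)

    def test_clade_shift_mean_difference(self, archetype):
        phy = syn.simulate_tree(8, seed=7, root_age=10.0)
        clade = [lf.taxon.label for lf in
                 phy.tree.seed_node.child_nodes()[0].leaf_iter()]
        rest = [sp for sp in phy.tip_labels if sp not in clade]
        shift = 0.9
        diffs = []
        for r in range(300):
            out = syn.evolve_traits(phy, archetype, {"turns": 0.005},
                                    {"c": {"turns": shift}}, {"c": clade},
                                    seed=10_000 + r)
            diffs.append(np.mean([out[s].turns for s in clade])
                         - np.mean([out[s].turns for s in rest]))
        assert np.mean(diffs) == pytest.approx(shift, abs=0.1)


class TestRenderCochlea:
    def test_winding_equals_construction(self, archetype):
        curve, rw, areas, ow = syn.render_cochlea(archetype, 400, 0.0, 0)
        w = geo.winding_angle(curve)
        # basal-turn undulation biases the winding estimate by ~2e-3 turns
        assert abs(w) == pytest.approx(2 * np.pi * archetype.turns, abs=0.02)
        assert geo.number_of_turns(curve) == 2.5

    def test_tube_area_at_base(self, archetype):
        _, _, areas, _ = syn.render_cochlea(archetype, 100, 0.0, 0)
        assert areas[0] == pytest.approx(np.pi * archetype.tube_radius0**2)

    def test_arc_length_quadrature_oracle(self, archetype):
        curve, *_ = syn.render_cochlea(archetype, 4000, 0.0, 0)
        measured = geo.curve_length(curve)
        assert measured == pytest.approx(syn.analytic_arc_length(archetype),
                                         rel=1e-3)

    def test_oval_window_area_truth(self, archetype):
        _, _, _, ow = syn.render_cochlea(archetype, 100, 0.0, 0)
        a, b = syn.oval_window_semi_axes(archetype)
        # a 24-gon inscribed in the ellipse carries a ~1.1% area deficit
        assert geo.oval_window_area(ow) == pytest.approx(np.pi * a * b, rel=0.02)

    def test_deterministic_per_seed(self, archetype):
        c1, *_ = syn.render_cochlea(archetype, 100, 0.05, 9)
        c2, *_ = syn.render_cochlea(archetype, 100, 0.05, 9)
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_points_rejected(self, archetype):
        with pytest.raises(ValueError):
            syn.render_cochlea(archetype, 10, 0.0, 0)


class TestGenerateAudiogram:
    def test_noiseless_v_recovery(self):
        rec, truth = syn.generate_audiogram("X", 0.35, 40.0, spl1_true=28.0,
                                            shape="V", noise_sd=0.0, seed=0)
        lfc = aud.frequency_cutoff(rec, "low")
        hfc = aud.frequency_cutoff(rec, "high")
        assert abs(math.log2(lfc / truth["LFC"])) < 0.06
        assert abs(math.log2(hfc / truth["HFC"])) < 0.06

    def test_w_construction_and_extraction(self):
        # two dips, the higher-frequency one 5 dB deeper
        rec, truth = syn.generate_audiogram("X", 0.25, 50.0, shape="W",
                                            noise_sd=0.0, seed=0,
                                            peak_sensitivity=18.0)
        ps, cf1, cf2 = aud.peak_and_characteristic(rec)
        assert cf1 < cf2
        assert abs(math.log2(cf1 / truth["CF1"])) < 0.3
        assert abs(math.log2(cf2 / truth["CF2"])) < 0.3
        assert ps == pytest.approx(truth["PS"], abs=1.0)

    def test_restricted_grid_gives_missing_lfc(self):
        rec, truth = syn.generate_audiogram(
            "X", 0.5, 32.0, shape="V", noise_sd=0.0, seed=0,
            frequency_grid=np.exp2(np.arange(1.0, 5.5, 0.5)))
        # tested grid starts at 2 kHz >= 2 * LFC_true; terminal < 45 dB
        assert rec.frequencies_khz[0] >= 2 * truth["LFC"]
        assert rec.thresholds_db[0] < 45.0
        assert aud.frequency_cutoff(rec, "low") is None

    def test_infeasible_anchoring_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_audiogram("X", 2.0, 0.5)

    def test_interpolated_cutoff_threshold_is_criterion(self):
        rec, _ = syn.generate_audiogram("X", 0.3, 45.0, shape="V",
                                        noise_sd=0.0, seed=0)
        f = aud.frequency_cutoff(rec, "low")
        assert aud.interpolate_threshold(rec, f) == pytest.approx(60.0, abs=1e-9)


class TestABRVariant:
    def test_zero_offset_zero_noise(self):
        rec, _ = syn.generate_audiogram("X", 0.3, 45.0, noise_sd=0.0, seed=0)
        abr = syn.make_abr_variant(rec, offset_profile=lambda f: 0.0)
        np.testing.assert_array_equal(abr.thresholds_db, rec.thresholds_db)
        assert abr.method == "ABR"

    def test_offsets_positive_and_larger_below_2khz(self):
        rec, _ = syn.generate_audiogram("X", 0.3, 45.0, noise_sd=0.0, seed=0)
        abr = syn.make_abr_variant(rec)
        offs = abr.thresholds_db - rec.thresholds_db
        assert np.all(offs > 0)
        low = offs[rec.frequencies_khz < 2.0].mean()
        high = offs[rec.frequencies_khz > 8.0].mean()
        assert low > high

    def test_constant_offset_cancels_exactly(self):
        rec, _ = syn.generate_audiogram("X", 0.3, 45.0, noise_sd=0.0, seed=0)
        other, _ = syn.generate_audiogram("Y", 0.4, 38.0, noise_sd=0.0, seed=1)
        prof = lambda f: 10.0
        abr1 = syn.make_abr_variant(rec, offset_profile=prof)
        abr2 = syn.make_abr_variant(other, offset_profile=prof)
        cf = aud.compute_correction_factors(rec, abr1, other, abr2)
        out = aud.apply_correction(abr1, cf)
        np.testing.assert_allclose(out.thresholds_db, rec.thresholds_db,
                                   atol=1e-9)


@pytest.fixture(scope="module")
def world():
    return syn.generate_world(seed=7)


class TestGenerateWorld:
    def test_default_study_conditions(self, world):
        assert world.phylogeny.n_tips == 33
        assert len(world.specimens) == 66
        species_with_specimens = {s.species for s in world.specimens}
        assert species_with_specimens == set(world.phylogeny.tip_labels)

    def test_exactly_one_behavioral_audiogram_per_species(self, world):
        assert sorted(world.behavioral) == world.phylogeny.tip_labels
        for sp, rec in world.behavioral.items():
            assert rec.method == "BA-S"

    def test_configurations_have_130_points(self, world):
        spm = world.specimens[0]
        pts = spm.cochlea.points
        if spm.side == "left":
            pts = geo.mirror_configuration(pts)
        config = geo.build_configuration(pts[1:], pts[:2])
        assert config.shape == (130, 3)
        semis = geo.resample_equidistant(pts[1:], 127)
        assert semis.shape == (127, 3)

    def test_regeneration_bit_identical(self, world):
        again = syn.generate_world(seed=7)
        assert world.phylogeny.as_newick() == again.phylogeny.as_newick()
        for a, b in zip(world.specimens, again.specimens):
            np.testing.assert_array_equal(a.cochlea.points, b.cochlea.points)
        assert world.truth.equals(again.truth)
        assert world.traits.equals(again.traits)

    def test_written_directory_bit_identical(self, world, tmp_path):
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        syn.write_world(world, d1)
        syn.write_world(syn.generate_world(seed=7), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_truth_ledger_covers_metrics_and_hearing(self, world):
        expected = {"CL", "CW", "NT", "OWA", "true_LFC", "true_HFC",
                    "true_PS", "true_CF1", "true_CF2", "true_SPL1"}
        assert expected <= set(world.truth.columns)

    def test_abr_records_present_for_references(self, world):
        methods = {}
        for rec in world.audiograms:
            methods.setdefault(rec.species, set()).add(rec.method)
        for sp in world.reference_species:
            assert methods[sp] == {"BA-S", "ABR"}
        n_abr_only = sum(1 for m in methods.values() if m == {"ABR"})
        assert n_abr_only == world.config.n_abr_only
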