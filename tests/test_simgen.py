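"""Generator determinism and truth consistency."""

import numpy as np
import pytest
from scipy import stats

from gliaquant import simgen
from gliaquant.morphometry import score_scene
from gliaquant.neurogenesis import laminar_counts, linear_density
from gliaquant.plaques import (
    default_background,
    detect_plaques,
    exclude_overlaps,
    halo_intensity,
    regress_intensity_on_area,
)
from gliaquant.signatures import filter_by_fold, filter_scores, intersect_sets


class TestMicroglia:
    def test_seed_determinism(self):
        spec = simgen.MicrogliaSpec()
        a, _ = simgen.generate_microglia_scene(spec, seed=3)
        b, _ = simgen.generate_microglia_scene(spec, seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self):
        spec = simgen.MicrogliaSpec()
        a, _ = simgen.generate_microglia_scene(spec, seed=3)
        b, _ = simgen.generate_microglia_scene(spec, seed=4)
        assert (a.pixels != b.pixels).any()

    def test_cell_count_recovered_by_segmentation(self):
        spec = simgen.MicrogliaSpec(n_cells=5)
        plane, truth = simgen.generate_microglia_scene(spec, seed=8)
        records = score_scene(plane, "g")
        assert len(records) == len(truth) == 5

    def test_soma_only_cells_are_compact(self):
        plane, truth = simgen.generate_microglia_scene(
            simgen.MicrogliaSpec(n_branches=0), seed=9
        )
        records = score_scene(plane, "g")
        assert all(r.form_factor >= 0.95 for r in records)
        assert all(t.solidity_class == "amoeboid" for t in truth)

    def test_branch_ladder_strictly_decreases_form_factor(self):
        lengths = (10.0, 30.0, 60.0)
        means = []
        for length in lengths:
            vals = []
            for seed in (21, 22):
                plane, _ = simgen.generate_microglia_scene(
                    simgen.MicrogliaSpec(branch_length_um=length, n_cells=3, image_size_px=900),
                    seed,
                )
                vals += [r.form_factor for r in score_scene(plane, "g")]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        rho = stats.spearmanr(lengths, means).statistic
        assert rho < -0.9

    def test_infeasible_packing_raises(self):
        with pytest.raises(simgen.PackingError):
            simgen.generate_microglia_scene(
                simgen.MicrogliaSpec(n_cells=100, image_size_px=256), seed=1
            )

    def test_truth_pixels_match_scene(self):
        plane, truth = simgen.generate_microglia_scene(simgen.MicrogliaSpec(), seed=5)
        assert sum(t.n_pixels for t in truth) == int((plane.pixels > 0).sum())


class TestPlaqueScene:
    def test_seed_determinism(self):
        spec = simgen.PlaqueSpec()
        a1, g1, _ = simgen.generate_plaque_scene(spec, seed=6)
        a2, g2, _ = simgen.generate_plaque_scene(spec, seed=6)
        np.testing.assert_array_equal(a1.pixels, a2.pixels)
        np.testing.assert_array_equal(g1.pixels, g2.pixels)

    def test_noiseless_recovery_under_3pct(self):
        spec = simgen.PlaqueSpec(sigma=0.0)
        plaque, glial, truth = simgen.generate_plaque_scene(spec, seed=13)
        records = detect_plaques(plaque)
        exclude_overlaps(records)
        bg = default_background(glial, records)
        for r in records:
            halo_intensity(glial, r, bg)
        fit = regress_intensity_on_area(records)
        assert fit.slope == pytest.approx(spec.beta1, rel=0.03)
        assert fit.intercept == pytest.approx(spec.beta0, rel=0.03)

    def test_forced_overlap_is_flagged(self):
        spec = simgen.PlaqueSpec(n_plaques=4, allow_overlap=True, image_size_px=300)
        plaque, _, _ = simgen.generate_plaque_scene(spec, seed=19)
        records = detect_plaques(plaque)
        exclude_overlaps(records)
        assert any(r.excluded for r in records)

    def test_zero_slope_ci_covers_zero(self):
        # beta1 = 0: fitted slope CI should cover 0 at ~95%.
        spec = simgen.PlaqueSpec(beta1=0.0, beta0=2e5, sigma=3e4)
        hits = reps = 0
        for rep in range(200):
            pts = simgen.sample_halo_records(spec, seed=5000 + rep, n=40)
            fit = regress_intensity_on_area(pts)
            reps += 1
            hits += int(fit.slope_ci[0] <= 0.0 <= fit.slope_ci[1])
        assert 0.90 <= hits / reps <= 0.99

    def test_sigma_for_r2_calibration(self):
        rng = np.random.default_rng(2)
        areas = rng.uniform(50, 400, 5000)
        sigma = simgen.sigma_for_r2(633.8, areas, 0.6)
        y = 633.8 * areas + 276179 + rng.normal(0, sigma, areas.size)
        fit = regress_intensity_on_area(np.column_stack([areas, y]))
        assert fit.r_squared == pytest.approx(0.6, abs=0.05)


class TestSgz:
    def test_exact_laminar_truth(self):
        spec = simgen.SgzSpec(n_somata=12, primaries_per_soma=1, secondaries_per_primary=2,
                              frac_secondary_crossing=0.75)
        scene, truth, _ = simgen.generate_sgz_scene(spec, seed=3)
        counts = laminar_counts(scene)
        assert (counts.a, counts.b, counts.c) == (truth.a, truth.b, truth.c) == (12, 12, 18)

    def test_partial_crossing_fractions(self):
        spec = simgen.SgzSpec(n_somata=10, frac_primary_crossing=0.6, secondaries_per_primary=1)
        scene, truth, _ = simgen.generate_sgz_scene(spec, seed=4)
        counts = laminar_counts(scene)
        assert counts.b == truth.b == 6

    def test_zero_dendrites(self):
        spec = simgen.SgzSpec(primaries_per_soma=0)
        scene, truth, _ = simgen.generate_sgz_scene(spec, seed=5)
        counts = laminar_counts(scene)
        assert (counts.b, counts.c) == (0, 0) == (truth.b, truth.c)

    def test_density_matches_spec(self):
        spec = simgen.SgzSpec(n_somata=10, length_um=2000.0, wobble_um=0.0)
        scene, truth, _ = simgen.generate_sgz_scene(spec, seed=6)
        d = linear_density(scene.soma_positions["DCX"], scene.sgz_polyline, 20, 1.0)
        assert d == pytest.approx(5.0, rel=0.01)
        assert truth.density_per_mm == pytest.approx(5.0, rel=0.01)

    def test_qc_image_rendered_on_request(self):
        _, _, qc = simgen.generate_sgz_scene(simgen.SgzSpec(qc_image=True), seed=7)
        assert qc is not None and qc.pixels.max() == 255


class TestSignatureTables:
    def test_designed_venn_recovered(self):
        genes, _, truth = simgen.generate_signature_tables(simgen.SignatureSpec(), seed=11)
        up, down = filter_by_fold(genes)
        up_venn = intersect_sets(up)
        down_venn = intersect_sets(down)
        for region, members in truth["up_regions"].items():
            assert up_venn.count(*region) == len(members)
        for region, members in truth["down_regions"].items():
            assert down_venn.count(*region) == len(members)

    def test_all_folds_inside_band_yield_empty_sets(self):
        spec = simgen.SignatureSpec(up_regions={}, down_regions={}, n_unchanged=40)
        genes, _, _ = simgen.generate_signature_tables(spec, seed=12)
        up, down = filter_by_fold(genes)
        assert all(not s for s in up.values()) and all(not s for s in down.values())

    def test_score_counts_match_truth_and_monotone(self):
        _, scores, truth = simgen.generate_signature_tables(simgen.SignatureSpec(), seed=13)
        n80 = len(filter_scores(scores, 80.0)[0])
        n90 = len(filter_scores(scores, 90.0)[0])
        assert n80 == truth["score_counts_above"][80.0]
        assert n90 == truth["score_counts_above"][90.0]
        assert n90 <= n80


class TestMetabolicCohort:
    def test_seed_determinism(self):
        a, _ = simgen.generate_metabolic_cohort(simgen.MetabolicSpec(), seed=3)
        b, _ = simgen.generate_metabolic_cohort(simgen.MetabolicSpec(), seed=3)
        assert a.equals(b)

    def test_impaired_group_stays_at_peak(self):
        spec = simgen.MetabolicSpec(ogtt_noise_sd=0.0)
        df, truth = simgen.generate_metabolic_cohort(spec, seed=4)
        hf = df[df["group"] == "HFSTZ"]
        assert (hf["ogtt_120"] > 0.9 * truth["HFSTZ"]["ogtt_peak"]).all()
        ncd = df[df["group"] == "NCD"]
        assert (ncd["ogtt_120"] < 0.6 * truth["NCD"]["ogtt_peak"]).all()

    def test_cohort_homa_near_truth(self):
        spec = simgen.MetabolicSpec(n_per_group=40)
        df, truth = simgen.generate_metabolic_cohort(spec, seed=5)
        from gliaquant.metabolic import summarize_cohort

        out = summarize_cohort(df).set_index("group")
        for gname in truth:
            mean = out.loc[gname, "homa_ir_mean"]
            sem = out.loc[gname, "homa_ir_sem"]
            # sample mean of products has extra spread vs product of means
            assert abs(mean - truth[gname]["homa_ir_expected"]) < 4 * sem + 1.0
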