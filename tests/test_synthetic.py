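"""Tests of the synthetic microscopy generator against its own ground
truth and the documented hierarchical structure."""

import numpy as np
import pytest

from phenoscreen import synthetic as sy


class TestRenderField:
    def test_nc_ratio_recovered_from_masks(self):
        params = sy.PhenotypeParams(rbp_nc_ratio=3.0, noise_sd=0.0)
        spec = sy.CultureSpec("control", "CTRL1", "EXP1", params, seed=3)
        fs, gt = sy.render_field(spec, size=(512, 512), n_z=3)
        assert abs(sy.measured_nc_ratio(fs, gt) / 3.0 - 1.0) < 0.05

    def test_unperturbed_nuclei_are_near_circular(self):
        params = sy.PhenotypeParams(nuclear_irregularity=0.0, noise_sd=0.0)
        spec = sy.CultureSpec("control", "CTRL1", "EXP1", params, seed=4)
        _, gt = sy.render_field(spec, size=(512, 512), n_z=3)
        assert sy.nucleus_boundary_radial_std(gt.nucleus_mask) < 1.0

    def test_fragmentation_strictly_shortens_skeleton(self):
        base = dict(noise_sd=0.0)
        spec0 = sy.CultureSpec("control", "C", "E",
                               sy.PhenotypeParams(neurite_fragmentation=0.0, **base), seed=5)
        spec1 = sy.CultureSpec("control", "C", "E",
                               sy.PhenotypeParams(neurite_fragmentation=0.5, **base), seed=5)
        _, gt0 = sy.render_field(spec0, size=(512, 512), n_z=3)
        _, gt1 = sy.render_field(spec1, size=(512, 512), n_z=3)
        assert sy.skeleton_length(gt1) < sy.skeleton_length(gt0)

    def test_masks_align_with_channels(self, noiseless_field):
        fs, gt = noiseless_field
        dapi = fs.channels["DAPI"][fs.n_z // 2].astype(float)
        assert dapi[gt.nucleus_mask].mean() > dapi[~gt.nucleus_mask].mean()
        biii = fs.channels["BIII"][fs.n_z // 2].astype(float)
        assert biii[gt.soma_mask].mean() > biii[~(gt.soma_mask | gt.neurite_skeleton)].mean()

    def test_mip_approximates_in_focus_plane(self, noiseless_field):
        fs, _ = noiseless_field
        from phenoscreen.preprocessing import max_intensity_projection
        mip = max_intensity_projection(fs.channels["DAPI"]).astype(float)
        focus = fs.channels["DAPI"][fs.n_z // 2].astype(float)
        assert np.abs(mip - focus).mean() / focus.mean() < 0.15

    def test_determinism(self):
        params = sy.PhenotypeParams()
        spec = sy.CultureSpec("control", "CTRL1", "EXP1", params, seed=11)
        fs1, _ = sy.render_field(spec, size=(256, 256), n_z=3)
        fs2, _ = sy.render_field(spec, size=(256, 256), n_z=3)
        for m in fs1.channels:
            assert np.array_equal(fs1.channels[m], fs2.channels[m])

    def test_degenerate_size_rejected(self):
        spec = sy.CultureSpec("control", "C", "E", sy.PhenotypeParams(), seed=0)
        with pytest.raises(ValueError):
            sy.render_field(spec, size=(100, 100))

    @pytest.mark.parametrize("param,values,measure", [
        ("nuclear_irregularity", [0.0, 0.08, 0.16],
         lambda fs, gt: sy.nucleus_boundary_radial_std(gt.nucleus_mask)),
        ("rbp_nc_ratio", [1.5, 3.0, 6.0], sy.measured_nc_ratio),
    ])
    def test_parameter_monotonicity(self, param, values, measure):
        """Increasing a phenotype parameter increases the image statistic
        it controls, measured on ground truth."""
        measured = []
        for v in values:
            params = sy.PhenotypeParams(noise_sd=0.0, **{param: v})
            spec = sy.CultureSpec("control", "C", "E", params, seed=21)
            fs, gt = sy.render_field(spec, size=(512, 512), n_z=3)
            measured.append(measure(fs, gt))
        assert measured[0] < measured[1] < measured[2]


class TestPhenotypeParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            sy.PhenotypeParams(rbp_nc_ratio=0.0)
        with pytest.raises(ValueError):
            sy.PhenotypeParams(neurite_fragmentation=1.5)
        with pytest.raises(ValueError):
            sy.PhenotypeParams(nuclear_radius_px=-1.0)

    def test_condition_shift_applies_documented_deltas(self):
        cfg = sy.PhenotypeConfig(line_jitter=0.0, experiment_jitter=0.0)
        p = sy.apply_condition(cfg, "heat", "CTRL1", "EXP1", master_seed=0)
        base = cfg.base
        for name, delta in sy.CONDITION_EFFECTS["heat"].items():
            assert getattr(p, name) == pytest.approx(getattr(base, name) + delta)

    def test_recovery_attenuates_shift(self):
        cfg = sy.PhenotypeConfig(line_jitter=0.0, experiment_jitter=0.0,
                                 recovery_halflife_h=1.0)
        p0 = sy.apply_condition(cfg, "heat", "CTRL1", "EXP1", 0, recovery_h=0.0)
        p2 = sy.apply_condition(cfg, "heat", "CTRL1", "EXP1", 0, recovery_h=2.0)
        base = cfg.base.nuclear_irregularity
        full = sy.CONDITION_EFFECTS["heat"]["nuclear_irregularity"]
        assert p0.nuclear_irregularity == pytest.approx(base + full)
        assert p2.nuclear_irregularity == pytest.approx(base + full / 4)

    def test_unknown_condition_named_in_error(self):
        cfg = sy.PhenotypeConfig()
        with pytest.raises(ValueError, match="frozen"):
            sy.apply_condition(cfg, "frozen", "CTRL1", "EXP1", 0)


class TestGeneratePlate:
    def test_layout_counts(self, tiny_plate):
        fields, manifest = tiny_plate
        # 1 experiment x 2 lines x 2 conditions x 1 well x 4 fields
        assert len(fields) == 16
        # one manifest row per (field, marker, z-plane)
        assert len(manifest) == 16 * 3 * 3
        assert set(manifest["condition"]) == {"control", "heat"}

    def test_manifest_schema(self, tiny_plate):
        _, manifest = tiny_plate
        assert list(manifest.columns) == ["experiment", "plate", "well", "cell_line",
                                          "condition", "marker", "field", "z", "path"]
        assert set(manifest["marker"]) == {"DAPI", "BIII", "FUS"}

    def test_determinism(self):
        layout = sy.PlateLayout(cell_lines=("CTRL1",), conditions=("control",))
        f1, m1 = sy.generate_plate(layout, seed=8, size=(256, 256),
                                   fields_per_well=1, n_z=3)
        f2, m2 = sy.generate_plate(layout, seed=8, size=(256, 256),
                                   fields_per_well=1, n_z=3)
        assert m1.equals(m2)
        for (a, _), (b, _) in zip(f1, f2):
            for m in a.channels:
                assert np.array_equal(a.channels[m], b.channels[m])

    def test_fields_and_planes_sampled_in_documented_ranges(self):
        layout = sy.PlateLayout(cell_lines=("CTRL1", "CTRL2", "CTRL3"),
                                conditions=("control", "heat"),
                                experiments=("EXP1", "EXP2"))
        fields, manifest = sy.generate_plate(layout, seed=13, size=(256, 256))
        per_well = manifest.groupby("well")["field"].nunique()
        assert per_well.between(10, 12).all()
        per_field = manifest.groupby(["well", "marker", "field"])["z"].nunique()
        assert per_field.between(3, 5).all()
        assert per_well.nunique() > 1  # the range is actually exercised

    def test_unknown_condition_rejected(self):
        layout = sy.PlateLayout(conditions=("control", "vortexed"))
        with pytest.raises(ValueError, match="vortexed"):
            sy.generate_plate(layout, seed=0, size=(256, 256), fields_per_well=1)


class TestSimulatePredictionTable:
    def test_degenerate_model_is_constant(self):
        tab = sy.simulate_prediction_table(0.3, 0.0, 0.0, 0.0, 0.0,
                                           n_lines=2, n_experiments=2,
                                           n_cultures=3, seed=0)
        assert np.allclose(tab["prediction"], 0.3)

    def test_effect_recovered_at_large_n(self):
        """Law of large numbers: the condition group-mean difference
        approaches beta1."""
        tab = sy.simulate_prediction_table(0.3, 0.4, 0.05, 0.05, 0.1,
                                           n_lines=10, n_experiments=10,
                                           n_cultures=50, seed=1)
        assert len(tab) == 10 * 10 * 2 * 50
        diff = (tab[tab.condition == 1].prediction.mean()
                - tab[tab.condition == 0].prediction.mean())
        assert abs(diff - 0.4) < 0.01

    def test_determinism_and_negative_sd_rejection(self):
        t1 = sy.simulate_prediction_table(0.2, 0.1, 0.05, 0.05, 0.1, seed=3)
        t2 = sy.simulate_prediction_table(0.2, 0.1, 0.05, 0.05, 0.1, seed=3)
        assert t1.equals(t2)
        with pytest.raises(ValueError):
            sy.simulate_prediction_table(0.2, 0.1, -0.05, 0.05, 0.1)

    def test_variance_decomposition_recovers_hierarchy(self):
        """The mixed model recovers the generator's variance components
        (averaged over replicates of 5,000 cultures to control the
        level-sampling noise of the random-effect draws)."""
        from phenoscreen.inference import fit_random_intercept_lmm
        targets = {"var_line": 0.05 ** 2, "var_experiment": 0.04 ** 2,
                   "var_resid": 0.1 ** 2}
        acc = {k: [] for k in targets}
        for rep in range(6):
            tab = sy.simulate_prediction_table(0.3, 0.2, 0.05, 0.04, 0.1,
                                               n_lines=50, n_experiments=50,
                                               n_cultures=1, seed=100 + rep)
            assert len(tab) == 5000
            est = fit_random_intercept_lmm(tab)
            for k in targets:
                acc[k].append(getattr(est, k))
        for k, target in targets.items():
            assert abs(np.mean(acc[k]) / target - 1.0) < 0.2, k
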