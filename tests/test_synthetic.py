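"""Ground-truth contracts of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gcquant import synthetic as syn


class TestPlates:
    def test_noise_free_anchors(self):
        cfg = syn.PlateSimConfig(n_compounds=5, concentrations=(5.0,),
                                 well_noise_sd=0.0, seed=0)
        plates, truth = syn.gen_plates(cfg)
        pos = plates.loc[plates["role"] == "pos_ctrl", "value"]
        neg = plates.loc[plates["role"] == "neg_ctrl", "value"]
        assert (pos == cfg.kill_floor).all()
        assert (neg == cfg.baseline_viability).all()
        # a compound with viability v maps exactly to v after NPI
        from gcquant.screen import npi_normalize

        norm = npi_normalize(plates)
        wells = norm[norm["role"] == "compound"]
        merged = wells.merge(truth, on="compound")
        np.testing.assert_allclose(merged["value"], merged["viability"],
                                   atol=1e-12)

    def test_control_layout(self):
        cfg = syn.PlateSimConfig(n_compounds=5, seed=1)
        plates, _ = syn.gen_plates(cfg)
        controls = plates[plates["role"].isin(["pos_ctrl", "neg_ctrl"])]
        assert set(controls["column"].unique()) == {2, 23}
        per_plate = controls.groupby(["plate", "role"]).size()
        assert (per_plate >= 8).all()
        # alternating down the column: odd rows positive, even rows negative
        col2 = controls[controls["column"] == 2]
        assert (col2.loc[col2["row"] % 2 == 1, "role"] == "pos_ctrl").all()
        assert (col2.loc[col2["row"] % 2 == 0, "role"] == "neg_ctrl").all()

    def test_interaction_shift_applied_in_treated_arm_only(self):
        cfg = syn.PlateSimConfig(
            n_compounds=3, concentrations=(5.0,), well_noise_sd=0.0,
            interaction_set={"cmpd_0000": -0.4}, seed=2,
        )
        plates, truth = syn.gen_plates(cfg)
        wells = plates[plates["compound"] == "cmpd_0000"]
        v = truth.set_index("compound").loc["cmpd_0000", "viability"]
        span = cfg.baseline_viability - cfg.kill_floor
        veh = wells.loc[wells["arm"] == "vehicle", "value"].unique()
        trt = wells.loc[wells["arm"] == "pretreat", "value"].unique()
        assert veh == pytest.approx(cfg.kill_floor + v * span)
        assert trt == pytest.approx(cfg.kill_floor + (v - 0.4) * span)

    def test_deterministic(self):
        cfg = syn.PlateSimConfig(n_compounds=8, well_noise_sd=0.05, seed=3)
        p1, t1 = syn.gen_plates(cfg)
        p2, t2 = syn.gen_plates(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_interaction_compound_rejected(self):
        cfg = syn.PlateSimConfig(n_compounds=2,
                                 interaction_set={"nope": -0.5})
        with pytest.raises(ValueError):
            syn.gen_plates(cfg)


class TestCohort:
    def test_null_linkage_spearman_centred(self):
        rhos = []
        for seed in range(200):
            cfg = syn.CohortSimConfig(
                n_samples=30, n_signature_genes=5, n_background_enhancers=5,
                linkage_effect=0.0, seed=seed,
            )
            data, _ = syn.gen_cohort(cfg)
            rhos.append(
                spearmanr(data.accessibility.loc["CERES"],
                          data.expression.loc["CDKN1C"]).statistic
            )
        assert abs(np.mean(rhos)) <= 0.05

    def test_zero_loading_null_signature(self):
        data, truth = syn.gen_cohort(
            syn.CohortSimConfig(signature_loading=0.0, seed=1)
        )
        sig = data.expression.loc[truth.attrs["signature_genes"]]
        rho = spearmanr(sig.mean(axis=0), truth["latent_activity"]).statistic
        assert abs(rho) < 0.2

    def test_noise_free_signature_affine_in_latent(self):
        data, truth = syn.gen_cohort(
            syn.CohortSimConfig(noise_sd=0.0, signature_loading=1.0, seed=2)
        )
        sig = data.expression.loc[truth.attrs["signature_genes"]]
        np.testing.assert_allclose(
            sig.to_numpy(), np.tile(truth["latent_activity"], (len(sig), 1)),
            atol=1e-12,
        )

    def test_background_independent_of_target(self):
        data, _ = syn.gen_cohort(syn.CohortSimConfig(seed=3))
        bg = data.accessibility.drop(index="CERES")
        target = data.expression.loc["CDKN1C"]
        rhos = [spearmanr(bg.iloc[i], target).statistic
                for i in range(0, len(bg), 10)]
        assert max(np.abs(rhos)) < 0.3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_cohort(syn.CohortSimConfig(n_samples=3))

    def test_bed_matches_accessibility(self):
        data, _ = syn.gen_cohort(syn.CohortSimConfig(seed=4))
        assert list(data.enhancer_bed["name"]) == list(data.accessibility.index)
        assert (data.enhancer_bed["start"] < data.enhancer_bed["end"]).all()


class TestFourC:
    def test_no_effect_zero_dispersion_identical(self):
        cfg = syn.FourCSimConfig(dispersion=0.0, seed=0)
        profile, _ = syn.gen_fourc(cfg)
        wide = profile.pivot_table(index=["start", "end", "replicate"],
                                   columns="condition", values="signal")
        np.testing.assert_allclose(wide.iloc[:, 0], wide.iloc[:, 1])

    def test_effect_region_doubled(self):
        region = (2_773_921, 2_812_270, 2.0)
        cfg = syn.FourCSimConfig(dispersion=0.0, seed=1,
                                 effect_regions=(region,))
        profile, truth = syn.gen_fourc(cfg)
        wide = profile[profile["replicate"] == 1].pivot_table(
            index=["start", "end"], columns="condition", values="signal"
        ).reset_index()
        mid = 0.5 * (wide["start"] + wide["end"])
        inside = (mid >= region[0]) & (mid <= region[1])
        ratio = wide["GC"] / wide["vehicle"]
        np.testing.assert_allclose(ratio[inside], 2.0)
        np.testing.assert_allclose(ratio[~inside], 1.0)
        assert set(truth.loc[truth["fold"] == 2.0].index) == set(
            np.flatnonzero(inside)
        )

    def test_fragments_sorted_nonoverlapping(self):
        profile, _ = syn.gen_fourc(syn.FourCSimConfig(seed=2))
        frags = profile[["start", "end"]].drop_duplicates().sort_values("start")
        assert (frags["start"].to_numpy()[1:] > frags["end"].to_numpy()[:-1]).all()

    def test_effect_outside_span_rejected(self):
        cfg = syn.FourCSimConfig(effect_regions=((1, 100, 2.0),))
        with pytest.raises(ValueError, match="outside"):
            syn.gen_fourc(cfg)

    def test_deterministic(self):
        cfg = syn.FourCSimConfig(seed=5, dispersion=0.3)
        p1, _ = syn.gen_fourc(cfg)
        p2, _ = syn.gen_fourc(cfg)
        pd.testing.assert_frame_equal(p1, p2)


class TestLFQ:
    def test_deterministic(self):
        cfg = syn.LFQSimConfig(n_proteins=50, seed=6)
        m1, g1, t1 = syn.gen_lfq(cfg)
        m2, _, _ = syn.gen_lfq(cfg)
        pd.testing.assert_frame_equal(m1, m2)

    def test_group_labels(self):
        _, groups, _ = syn.gen_lfq(syn.LFQSimConfig(n_proteins=10, seed=0))
        assert groups["group"].value_counts().to_dict() == {"vehicle": 3,
                                                            "GC": 3}


class TestImages:
    def test_empty_field(self):
        cfg = syn.ImageSimConfig(n_nuclei=0, seed=0, shape=(64, 64))
        nuclear, marker, truth = syn.gen_image(cfg)
        assert truth.labels.max() == 0
        assert truth.centers.shape == (0, 2)

    def test_component_count_without_touching(self):
        from scipy import ndimage as ndi

        cfg = syn.ImageSimConfig(n_nuclei=20, touching_fraction=0.0, seed=1)
        _, _, truth = syn.gen_image(cfg)
        _, n = ndi.label(truth.labels > 0)
        assert n == 20

    def test_deterministic_positive_assignment(self):
        cfg = syn.ImageSimConfig(n_nuclei=40, marker_positive_fraction=0.5,
                                 seed=2)
        _, _, truth = syn.gen_image(cfg)
        assert truth.positive.sum() == 20

    def test_deterministic(self):
        cfg = syn.ImageSimConfig(seed=3, shape=(128, 128), n_nuclei=5)
        n1, m1, t1 = syn.gen_image(cfg)
        n2, m2, t2 = syn.gen_image(cfg)
        np.testing.assert_array_equal(n1, n2)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(t1.labels, t2.labels)
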