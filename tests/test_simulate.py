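"""Synthetic-data generators: anchors, inversions, determinism."""

import numpy as np
import pandas as pd
import pytest

from beeqmp.errors import ConfigError
from beeqmp.permstats import spearman
from beeqmp.profiles import (
    SEVEN_PHYLOTYPES,
    BeeTypeProfile,
    TaxonProfile,
    colonization_anchors,
    default_curves,
    paper_anchors,
)
from beeqmp.qpcr import quantify, summed_load
from beeqmp.simulate import (
    ge_matrix,
    gen_amplicon,
    gen_colonization,
    gen_cq,
    gen_hive,
    gen_standards,
    pool_bees,
    truth_long,
)


def binom_3se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestGenHive:
    def test_firm4_detectability_anchor(self):
        bees = gen_hive(n_per_type=1000, seed=101)
        foragers = bees[bees["bee_type"] == "forager"]
        frac = (foragers["lactobacillus_firm4"] > 0).mean()
        assert abs(frac - 0.984) < binom_3se(0.984, 1000)

    def test_winter_forager_total_load_ratio(self):
        bees = gen_hive(n_per_type=1000, seed=102)
        total = ge_matrix(bees)[SEVEN_PHYLOTYPES].sum(axis=1)
        ratio = (
            total[bees["bee_type"] == "winter"].mean()
            / total[bees["bee_type"] == "forager"].mean()
        )
        assert ratio == pytest.approx(10.0, rel=0.10)

    def test_zero_detectability_means_absent(self):
        profile = BeeTypeProfile(
            "x", {"gilliamella": TaxonProfile(6.0, 0.3, 0.0)}
        )
        bees = gen_hive({"x": profile}, n_per_type=50, seed=1)
        assert (bees["gilliamella"] == 0).all()

    def test_determinism(self):
        a = gen_hive(n_per_type=10, seed=7)
        b = gen_hive(n_per_type=10, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n_rejected(self):
        with pytest.raises(ConfigError):
            gen_hive(n_per_type=0, seed=1)


class TestGenCq:
    def test_noiseless_chain_recovers_truth_exactly(self):
        bees = gen_hive(n_per_type=5, seed=21)
        cq = gen_cq(bees, sigma_cq=0.0, seed=22, n_replicates=1)
        out = quantify(cq, default_curves())
        wide = out.pivot(index="sample_id", columns="target_id", values="n_ge")
        truth = ge_matrix(bees)
        for t in SEVEN_PHYLOTYPES:
            true = truth.loc[wide.index, t]
            detected = true > 0
            np.testing.assert_allclose(
                wide.loc[detected, t], true[detected], rtol=1e-6
            )

    def test_true_zero_emitted_undetected(self):
        profile = BeeTypeProfile("x", {"gilliamella": TaxonProfile(6.0, 0.3, 0.0)})
        bees = gen_hive({"x": profile}, n_per_type=3, seed=2)
        cq = gen_cq(bees, sigma_cq=0.0, seed=3, targets=["gilliamella"])
        gil = cq[cq["target_id"] == "gilliamella"]
        assert gil["cq"].isna().all()

    def test_noise_propagation_delta_method(self):
        # sd of log10(recovered copies) is sigma_cq / |slope|
        curve = default_curves()["gilliamella"]
        rng = np.random.default_rng(30)
        sigma = 0.2
        cqs = curve.cq_of(1e5) + rng.normal(0, sigma, size=4000)
        logs = (curve.intercept - cqs) * np.log10(curve.efficiency)
        assert logs.mean() == pytest.approx(5.0, abs=0.02)
        assert logs.std(ddof=1) == pytest.approx(sigma / abs(curve.slope), rel=0.1)

    def test_universal_assay_reports_total_16s(self):
        bees = gen_hive(n_per_type=4, seed=31)
        cq = gen_cq(bees, sigma_cq=0.0, seed=32, n_replicates=1)
        out = quantify(cq, default_curves())
        uni = out[out["target_id"] == "universal_16s"].set_index("sample_id")
        truth = ge_matrix(bees)
        from beeqmp.profiles import RRNA_LOCI

        expected = sum(truth[t] * RRNA_LOCI[t] for t in truth.columns)
        np.testing.assert_allclose(
            uni["n_ge"], expected.loc[uni.index], rtol=1e-6
        )
        # universal assay reports n_abs (16S copies), not genome equivalents
        np.testing.assert_allclose(uni["n_ge"], uni["n_abs"], rtol=1e-12)

    def test_missing_curve_rejected(self):
        bees = gen_hive(n_per_type=2, seed=1)
        with pytest.raises(ConfigError):
            gen_cq(bees, curves={}, targets=["gilliamella"])


class TestGenAmplicon:
    def test_copy_number_weighting(self):
        # equal GE, 4 vs 2 operons -> expected read ratio 2:1
        profile = BeeTypeProfile(
            "x",
            {"gilliamella": TaxonProfile(6.0, 0.0, 1.0),
             "bartonella": TaxonProfile(6.0, 0.0, 1.0)},
        )
        bees = gen_hive({"x": profile}, n_per_type=1, seed=3)
        amp = gen_amplicon(bees, depth=1_000_000, seed=4, split_asvs=False,
                           offtarget_frac=0.0, spurious_rate=0.0)
        counts = amp.counts.iloc[:, 0]
        ratio = counts["asv_gilliamella_1"] / counts["asv_bartonella_1"]
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_large_depth_proportions_converge_to_weights(self):
        bees = gen_hive(n_per_type=1, seed=5)
        amp = gen_amplicon(bees, depth=1_000_000, seed=6, split_asvs=False,
                           offtarget_frac=0.0, spurious_rate=0.0)
        bee = bees.iloc[0]
        from beeqmp.profiles import RRNA_LOCI

        taxa = ge_matrix(bees).columns
        w = np.array([bee[t] * RRNA_LOCI[t] for t in taxa])
        w = w / w.sum()
        obs = np.array(
            [amp.counts.loc[f"asv_{t}_1"].iloc[0] for t in taxa], dtype=float
        )
        obs /= obs.sum()
        big = w > 1e-4
        np.testing.assert_allclose(obs[big], w[big], rtol=0.05)

    def test_total_16s_is_copy_sum(self):
        bees = gen_hive(n_per_type=3, seed=7)
        amp = gen_amplicon(bees, depth=1000, seed=8)
        from beeqmp.profiles import RRNA_LOCI

        truth = ge_matrix(bees)
        expected = sum(truth[t] * RRNA_LOCI[t] for t in truth.columns)
        np.testing.assert_allclose(amp.total_16s, expected, rtol=1e-12)

    def test_offtarget_and_spurious_rows_present(self):
        bees = gen_hive(n_per_type=3, seed=9)
        amp = gen_amplicon(bees, depth=20_000, seed=10)
        assert (amp.taxonomy["category"] == "excluded").sum() == 2
        mito = amp.counts.loc["asv_host_mito"].sum()
        assert mito > 0
        spurious = amp.counts.loc[amp.counts.index.str.startswith("asv_spurious")]
        assert spurious.to_numpy().sum() < 10 * 2  # stays under the filter

    def test_determinism(self):
        bees = gen_hive(n_per_type=3, seed=11)
        a = gen_amplicon(bees, depth=5000, seed=12)
        b = gen_amplicon(bees, depth=5000, seed=12)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestPooling:
    def test_equal_mass_average(self):
        bees = gen_hive(n_per_type=40, seed=13)
        pooled = pool_bees(bees, guts_per_pool=20, by=("bee_type",))
        assert len(pooled) == 6  # 3 types x 2 pools
        forager = bees[bees["bee_type"] == "forager"]
        first = pooled.loc["forager_pool01"]
        np.testing.assert_allclose(
            first["gilliamella"], forager.iloc[:20]["gilliamella"].mean(), rtol=1e-12
        )


class TestColonization:
    def test_sw_prevalence_anchors(self):
        col = gen_colonization(n_per_arm=200, seed=41)
        sw = col[col["treatment"] == "SW"]
        bart = (sw["bartonella"] > 0).mean()
        fri = (sw["frischella"] > 0).mean()
        assert abs(bart - 0.75) < binom_3se(0.75, 200)
        assert fri < 0.5 + binom_3se(0.45, 200)
        swp = col[col["treatment"] == "SW+P"]
        assert (swp["frischella"] > 0).all()

    def test_gut_weight_ratio_anchor(self):
        col = gen_colonization(n_per_arm=500, seed=42)
        means = col.groupby("treatment")["gut_weight_mg"].mean()
        assert means["SW+P"] / means["SW"] == pytest.approx(2.0, rel=0.1)

    def test_weight_load_correlation_switch(self):
        off = gen_colonization(colonization_anchors(0.0), n_per_arm=300, seed=43)
        sw = off[off["treatment"] == "SW"]
        rho0 = spearman(sw["gut_weight_mg"], ge_matrix(sw).sum(axis=1))
        assert abs(rho0) < 0.15
        on = gen_colonization(colonization_anchors(0.7), n_per_arm=300, seed=43)
        sw = on[on["treatment"] == "SW"]
        rho = spearman(sw["gut_weight_mg"], ge_matrix(sw).sum(axis=1))
        assert 0.5 < rho < 0.95

    def test_determinism(self):
        a = gen_colonization(n_per_arm=10, seed=44)
        b = gen_colonization(n_per_arm=10, seed=44)
        pd.testing.assert_frame_equal(a, b)


class TestStandardsAndTruth:
    def test_standards_refit_recovers_panel(self):
        from beeqmp.io import fit_curves_from_standards

        curves = default_curves()
        standards = gen_standards(curves, sigma_cq=0.0, seed=51)
        refit = fit_curves_from_standards(standards)
        for tid, c in curves.items():
            assert refit[tid].slope == pytest.approx(c.slope, abs=1e-9)
            assert refit[tid].intercept == pytest.approx(c.intercept, abs=1e-9)
            assert refit[tid].lod_copies == c.lod_copies

    def test_truth_long_round_trip(self):
        bees = gen_hive(n_per_type=2, seed=52)
        long = truth_long(bees)
        assert len(long) == len(bees) * len(ge_matrix(bees).columns)
        wide = long.pivot(index="sample_id", columns="taxon", values="true_ge")
        pd.testing.assert_frame_equal(
            wide.loc[bees.index, ge_matrix(bees).columns],
            ge_matrix(bees),
            check_names=False,
        )
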