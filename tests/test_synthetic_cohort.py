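"""Generator checks: allele frequencies, block LD, phenotype architecture,
catalog ground truth and the exclusion fixture."""

import numpy as np
import pandas as pd
import pytest

from adiposcore.synthetic_cohort import (ArchitectureSpec, ArchitectureError,
                                         VariantSpec, default_architecture,
                                         load_architecture, make_exclusion_fixture,
                                         save_architecture, simulate_catalog,
                                         simulate_genotypes, simulate_phenotypes)
from adiposcore.io_and_qc import apply_sample_exclusions


def simple_spec(variants, effects, n_samples, seed=0, n_families=1,
                family_sd=0.0, residual_sd=None, loadings=None):
    P = 6
    eff = np.zeros((len(variants), P))
    eff[:, 0] = effects  # load on BMI only
    return ArchitectureSpec(
        n_samples=n_samples, n_families=n_families, family_sd=family_sd,
        variants=variants, effects=eff,
        factor_loadings=np.zeros((0, P)) if loadings is None else loadings,
        residual_sd=np.ones(P) if residual_sd is None else residual_sd,
        seed=seed)


def bmi_z(ct: pd.DataFrame) -> np.ndarray:
    v2 = ct[ct["visit"] == 2]
    return ((v2["BMI"] - 32.2) / 7.2).to_numpy()


class TestGenotypes:
    def test_maf_converges(self):
        spec = simple_spec([VariantSpec(maf=0.5, block_id="b0")], [0.0], 10_000, seed=7)
        gm = simulate_genotypes(spec)
        assert abs(gm.dosages.mean() / 2 - 0.5) < 0.02  # 4 binomial s.e.

    def test_zero_target_r2_gives_independence(self):
        spec = simple_spec(
            [VariantSpec(maf=0.3, block_id="b0"), VariantSpec(maf=0.3, block_id="b0")],
            [0.0, 0.0], 50_000, seed=3)
        gm = simulate_genotypes(spec)
        r = np.corrcoef(gm.dosages.T)[0, 1]
        assert r * r < 0.01

    def test_block_r2_hits_target(self):
        vs = [VariantSpec(maf=0.4, block_id="b0", target_r2=0.8) for _ in range(3)]
        spec = simple_spec(vs, [0.0] * 3, 50_000, seed=11)
        gm = simulate_genotypes(spec)
        C = np.corrcoef(gm.dosages.T)
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(C[a, b] ** 2 - 0.8) < 0.05

    def test_cross_block_independent(self):
        vs = [VariantSpec(maf=0.3, block_id="b0", target_r2=0.9),
              VariantSpec(maf=0.3, block_id="b0", target_r2=0.9),
              VariantSpec(maf=0.3, block_id="b1")]
        spec = simple_spec(vs, [0.0] * 3, 30_000, seed=5)
        gm = simulate_genotypes(spec)
        C = np.corrcoef(gm.dosages.T)
        assert C[0, 1] ** 2 > 0.8
        assert C[0, 2] ** 2 < 0.01

    def test_deterministic_under_seed(self):
        spec = default_architecture(n_samples=300, seed=42, n_backbone=10)
        gm1, gm2 = simulate_genotypes(spec), simulate_genotypes(spec)
        assert np.array_equal(gm1.dosages, gm2.dosages)
        ct1 = simulate_phenotypes(gm1, spec)
        ct2 = simulate_phenotypes(gm2, spec)
        pd.testing.assert_frame_equal(ct1, ct2)

    @pytest.mark.parametrize("bad", [
        VariantSpec(maf=0.0, block_id="b"), VariantSpec(maf=1.0, block_id="b"),
        VariantSpec(maf=0.3, block_id="b", target_r2=1.0)])
    def test_invalid_variant_rejected(self, bad):
        with pytest.raises(ArchitectureError):
            simple_spec([bad], [0.0], 10)

    def test_unattainable_r2_for_divergent_mafs_rejected(self):
        vs = [VariantSpec(maf=0.02, block_id="b0", target_r2=0.95),
              VariantSpec(maf=0.5, block_id="b0", target_r2=0.95)]
        spec = simple_spec(vs, [0.0, 0.0], 100)
        with pytest.raises(ArchitectureError):
            simulate_genotypes(spec)


class TestPhenotypes:
    def test_null_architecture_no_genetic_slope(self):
        vs = [VariantSpec(maf=0.3, block_id=f"b{j}") for j in range(5)]
        spec = simple_spec(vs, [0.0] * 5, 5_000, seed=1)
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        s = gm.dosages.sum(axis=1)
        y = bmi_z(ct)
        slope = np.polyfit(s, y, 1)[0]
        se = np.std(y) / (np.std(s) * np.sqrt(len(y)))
        assert abs(slope / se) < 3

    def test_single_causal_effect_recovered(self):
        maf, effect = 0.3, 0.3
        resid = np.sqrt(1 - 2 * maf * (1 - maf) * effect**2)
        spec = simple_spec([VariantSpec(maf=maf, block_id="b0")], [effect], 5_000,
                           seed=2, residual_sd=np.full(6, resid))
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        g = gm.dosages[:, 0]
        y = bmi_z(ct)
        slope = np.polyfit(g, y, 1)[0]
        se = resid / (np.std(g) * np.sqrt(len(y)))
        assert abs(slope - effect) < 3 * se

    def test_family_intraclass_correlation(self):
        spec = simple_spec([VariantSpec(maf=0.3, block_id="b0")], [0.0], 2_500,
                           seed=4, n_families=500, family_sd=0.5)
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        v2 = ct[ct["visit"] == 2]
        y = bmi_z(ct)
        df = pd.DataFrame({"fam": v2["family_id"].to_numpy(), "y": y})
        k = 5
        grand = df["y"].mean()
        groups = df.groupby("fam")["y"]
        msb = k * ((groups.mean() - grand) ** 2).sum() / (groups.ngroups - 1)
        msw = groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum() / (len(df) - groups.ngroups)
        icc = (msb - msw) / (msb + (k - 1) * msw)
        assert abs(icc - 0.25 / 1.25) < 0.05

    def test_genetic_variance_decomposition(self):
        vs = [VariantSpec(maf=f, block_id=f"b{j}") for j, f in enumerate((0.2, 0.35, 0.5))]
        effects = np.array([0.3, 0.25, 0.2])
        spec = simple_spec(vs, effects, 30_000, seed=9)
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        y = bmi_z(ct)
        freqs = np.array([0.2, 0.35, 0.5])
        expected_genetic = float(np.sum(2 * freqs * (1 - freqs) * effects**2))
        genetic_part = (gm.dosages - 2 * freqs) @ effects
        assert abs(np.var(genetic_part) - expected_genetic) < 0.01
        assert abs(np.var(y) - (expected_genetic + 1.0)) < 0.05

    def test_whr_is_wc_over_hc(self):
        spec = default_architecture(n_samples=200, seed=0, n_backbone=5)
        gm = simulate_genotypes(spec)
        ct = simulate_phenotypes(gm, spec)
        np.testing.assert_allclose(ct["WHR"], ct["WC"] / ct["HC"], rtol=1e-12)
        assert (ct["SAT"].dropna() >= 0).all()
        assert (ct["VAT"].dropna() >= 0).all()

    def test_dimension_mismatch_rejected(self):
        spec = simple_spec([VariantSpec(maf=0.3, block_id="b0")], [0.1], 100)
        other = simple_spec([VariantSpec(maf=0.3, block_id="b0")], [0.1], 50)
        gm = simulate_genotypes(other)
        with pytest.raises(ArchitectureError):
            simulate_phenotypes(gm, spec)


class TestCatalog:
    def test_counts_and_ground_truth(self):
        spec = default_architecture(n_samples=100, seed=1, n_backbone=0)
        gm = simulate_genotypes(spec)
        cat0 = simulate_catalog(gm, spec, n_false=0, seed=1)
        assert all(e.is_causal for e in cat0)
        cat = simulate_catalog(gm, spec, n_false=5, seed=1)
        assert len(cat) == len(cat0) + 5
        assert sum(not e.is_causal for e in cat) == 5

    def test_reported_p_at_genomewide_significance(self):
        spec = default_architecture(n_samples=100, seed=2, n_backbone=0)
        gm = simulate_genotypes(spec)
        cat = simulate_catalog(gm, spec, n_false=8, seed=2)
        assert all(e.reported_p <= 5e-8 for e in cat)

    def test_n_false_exceeding_nulls_rejected(self):
        spec = default_architecture(n_samples=50, seed=3, n_backbone=0)
        gm = simulate_genotypes(spec)
        with pytest.raises(ArchitectureError):
            simulate_catalog(gm, spec, n_false=1000, seed=3)


class TestExclusionFixture:
    def test_no_flags(self):
        ct = make_exclusion_fixture(100, 0, 0, seed=0)
        assert not ct["pregnancy_excluded"].any()
        assert not ct["missing_implausible"].any()

    def test_flag_arithmetic(self):
        ct = make_exclusion_fixture(100, 10, 20, seed=0)
        assert ct["pregnancy_excluded"].sum() == 10
        assert ct["missing_implausible"].sum() == 20
        assert not (ct["pregnancy_excluded"] & ct["missing_implausible"]).any()
        assert len(apply_sample_exclusions(ct)) == 70

    def test_pregnancy_flags_on_females_only(self):
        ct = make_exclusion_fixture(200, 15, 0, seed=1)
        assert (ct.loc[ct["pregnancy_excluded"], "sex"] == "female").all()

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            make_exclusion_fixture(10, 6, 5, seed=0)


def test_architecture_save_load_roundtrip(tmp_path):
    spec = default_architecture(n_samples=120, seed=5, n_backbone=3)
    path = tmp_path / "arch.cfg"
    save_architecture(spec, str(path))
    back = load_architecture(str(path))
    assert back.n_samples == spec.n_samples
    assert back.variants == spec.variants
    np.testing.assert_allclose(back.effects, spec.effects, rtol=1e-9)
    np.testing.assert_allclose(back.factor_loadings, spec.factor_loadings, rtol=1e-9)
    gm1, gm2 = simulate_genotypes(spec), simulate_genotypes(back)
    assert np.array_equal(gm1.dosages, gm2.dosages)
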