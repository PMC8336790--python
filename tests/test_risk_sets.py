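"""LD computation, greedy sentinel pruning (against a brute-force oracle) and
the three nested filtering approaches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adiposcore.internal_gwas import GwasResult
from adiposcore.io_and_qc import QcConfig
from adiposcore.risk_sets import (CatalogEntry, LdUndefinedError, build_risk_set,
                                  compute_ld_r2, prune_by_ld)
from adiposcore.synthetic_cohort import VariantSpec, simulate_genotypes

from conftest import make_gm
from test_synthetic_cohort import simple_spec


def entry(key, p=1e-9, year=2015, n=100_000, allele=None, trait="BMI"):
    alt = key.split(":")[3]
    return CatalogEntry(key=key, effect_allele=allele or alt, trait=trait,
                        reported_p=p, study_year=year, study_n=n)


def greedy_oracle(entries, gm, ld_r2):
    """Independent re-statement of the pruning rule: walk in priority order,
    keep iff pairwise r^2 with every kept entry is < threshold (constant
    columns treated unlinked)."""
    idx = {v.key: j for j, v in enumerate(gm.variants)}
    kept = []
    for e in sorted(entries, key=lambda e: (e.reported_p, -e.study_n,
                                            -e.study_year, e.key)):
        if e.key not in idx:
            continue
        x = gm.dosages[:, idx[e.key]]
        ok = True
        for k in kept:
            y = gm.dosages[:, idx[k.key]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 >= ld_r2:
                ok = False
                break
        if ok:
            kept.append(e)
    return [e.key for e in kept]


class TestLdR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 1, 0], dtype=float)
        assert compute_ld_r2(x, x) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # cov = 1/3, var = 2/3 each -> r = 0.5, r^2 = 0.25
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0, 1, 0, 2, 1, 2], dtype=float)
        assert compute_ld_r2(x, y) == pytest.approx(0.25, abs=1e-12)
        assert compute_ld_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_independent_variants_near_zero(self, rng):
        x = rng.binomial(2, 0.3, 50_000).astype(float)
        y = rng.binomial(2, 0.4, 50_000).astype(float)
        assert compute_ld_r2(x, y) < 0.01

    def test_pairwise_complete_handling(self):
        x = np.array([0, 1, 2, np.nan, 2], dtype=float)
        y = np.array([0, 1, 2, 2, np.nan], dtype=float)
        assert compute_ld_r2(x, y) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(LdUndefinedError):
            compute_ld_r2(np.ones(10), np.arange(10, dtype=float))


class TestPrune:
    def test_unlinked_all_kept(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(2_000, 4)).astype(float))
        entries = [entry(v.key, p=10.0**-(9 + j)) for j, v in enumerate(gm.variants)]
        rs = prune_by_ld(entries, gm)
        assert len(rs.entries) == 4

    def test_sentinel_has_lowest_p(self, rng):
        d = rng.binomial(2, 0.4, size=(500, 1)).astype(float)
        gm = make_gm(np.column_stack([d, d]))  # perfect LD pair
        keys = [v.key for v in gm.variants]
        entries = [entry(keys[0], p=1e-9), entry(keys[1], p=1e-30)]
        rs = prune_by_ld(entries, gm)
        assert rs.keys == [keys[1]]
        dropped = rs.audit[rs.audit["status"] == "dropped"]
        assert dropped.iloc[0]["sentinel_of"] == keys[1]

    def test_tie_breaks_study_size_then_year(self, rng):
        d = rng.binomial(2, 0.4, size=(500, 1)).astype(float)
        gm = make_gm(np.column_stack([d, d, d]))
        keys = [v.key for v in gm.variants]
        entries = [entry(keys[0], p=1e-9, n=50_000, year=2020),
                   entry(keys[1], p=1e-9, n=500_000, year=2010),
                   entry(keys[2], p=1e-9, n=500_000, year=2018)]
        rs = prune_by_ld(entries, gm)
        assert rs.keys == [keys[2]]  # largest study, most recent

    def test_matches_brute_force_oracle(self, rng):
        for draw in range(20):
            k = int(rng.integers(3, 9))
            blocks = rng.integers(0, 3, size=k)
            r2s = rng.uniform(0.0, 0.9, size=3)
            block_maf = rng.uniform(0.1, 0.5, size=3)  # shared maf keeps any r2 attainable
            vs = [VariantSpec(maf=float(block_maf[blocks[j]]),
                              block_id=f"b{blocks[j]}",
                              target_r2=float(r2s[blocks[j]])) for j in range(k)]
            spec = simple_spec(vs, [0.0] * k, 400, seed=draw)
            gm = simulate_genotypes(spec)
            entries = [entry(v.key, p=10.0 ** -rng.uniform(8, 30),
                             n=int(rng.integers(1e4, 1e6)),
                             year=int(rng.integers(2008, 2021)))
                       for v in gm.variants]
            rs = prune_by_ld(entries, gm)
            assert rs.keys == greedy_oracle(entries, gm, 0.1)

    def test_input_order_invariance(self, rng):
        vs = [VariantSpec(maf=0.3, block_id="b0", target_r2=0.6) for _ in range(4)]
        spec = simple_spec(vs, [0.0] * 4, 500, seed=3)
        gm = simulate_genotypes(spec)
        entries = [entry(v.key, p=10.0**-(9 + j)) for j, v in enumerate(gm.variants)]
        rs1 = prune_by_ld(entries, gm)
        rs2 = prune_by_ld(entries[::-1], gm)
        assert rs1.keys == rs2.keys

    def test_missing_variant_skipped_with_audit(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(100, 1)).astype(float))
        entries = [entry(gm.variants[0].key), entry("9:999:A:G")]
        rs = prune_by_ld(entries, gm)
        assert rs.keys == [gm.variants[0].key]
        assert (rs.audit["status"] == "skipped").sum() == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_output_always_pairwise_unlinked(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        block_maf = rng.uniform(0.1, 0.5, size=3)
        block_r2 = rng.uniform(0, 0.9, size=3)
        which = rng.integers(0, 3, size=k)
        vs = [VariantSpec(maf=float(block_maf[b]), block_id=f"b{b}",
                          target_r2=float(block_r2[b])) for b in which]
        spec = simple_spec(vs, [0.0] * k, 300, seed=seed)
        gm = simulate_genotypes(spec)
        entries = [entry(v.key, p=10.0 ** -rng.uniform(8, 30)) for v in gm.variants]
        rs = prune_by_ld(entries, gm)
        idx = gm.variant_index
        for a in range(len(rs.entries)):
            for b in range(a + 1, len(rs.entries)):
                r2 = compute_ld_r2(gm.dosages[:, idx[rs.keys[a]]],
                                   gm.dosages[:, idx[rs.keys[b]]])
                assert r2 < 0.1


class TestApproaches:
    def make_inputs(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(2_000, 5)).astype(float))
        keys = [v.key for v in gm.variants]
        catalog = [entry(k, p=10.0**-(9 + j)) for j, k in enumerate(keys)]
        betas = [0.2, 0.1, 0.05, -0.1, -0.2]
        ps = [0.001, 0.01, 0.50, 0.001, 0.60]
        internal = [GwasResult(key=k, trait="BMI", beta=b, se=0.05, p=p, n_used=2000)
                    for k, b, p in zip(keys, betas, ps)]
        return gm, catalog, internal

    def test_nested_sizes_5_3_2(self, rng):
        gm, catalog, internal = self.make_inputs(rng)
        sizes = [len(build_risk_set(catalog, internal, a, gm, trait="BMI").entries)
                 for a in (1, 2, 3)]
        assert sizes == [5, 3, 2]

    def test_nesting_property(self, rng):
        gm, catalog, internal = self.make_inputs(rng)
        s1, s2, s3 = (set(build_risk_set(catalog, internal, a, gm, trait="BMI").keys)
                      for a in (1, 2, 3))
        assert s3 <= s2 <= s1

    def test_effect_allele_orientation_in_replication(self, rng):
        # a ref-effect-allele entry with negative alt-oriented beta replicates
        gm = make_gm(rng.binomial(2, 0.4, size=(500, 1)).astype(float))
        v = gm.variants[0]
        catalog = [entry(v.key, allele=v.ref)]
        internal = [GwasResult(key=v.key, trait="BMI", beta=-0.2, se=0.05,
                               p=0.001, n_used=500)]
        assert len(build_risk_set(catalog, internal, 3, gm, trait="BMI").entries) == 1

    def test_nominal_threshold_is_exclusive(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(500, 1)).astype(float))
        k = gm.variants[0].key
        internal = [GwasResult(key=k, trait="BMI", beta=0.1, se=0.05, p=0.05,
                               n_used=500)]
        rs = build_risk_set([entry(k)], internal, 3, gm, trait="BMI")
        assert len(rs.entries) == 0  # p must be strictly below 0.05

    def test_approach_2_requires_internal(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(100, 1)).astype(float))
        with pytest.raises(ValueError):
            build_risk_set([entry(gm.variants[0].key)], None, 2, gm, trait="BMI")

    def test_admission_requires_genomewide_significance(self, rng):
        gm = make_gm(rng.binomial(2, 0.4, size=(100, 2)).astype(float))
        keys = [v.key for v in gm.variants]
        catalog = [entry(keys[0], p=4e-8), entry(keys[1], p=6e-8)]
        rs = build_risk_set(catalog, None, 1, gm, trait="BMI")
        assert rs.keys == [keys[0]]


def test_catalog_entry_validation():
    with pytest.raises(ValueError):
        CatalogEntry(key="1:1:A:G", effect_allele="G", trait="nope",
                     reported_p=1e-9, study_year=2020, study_n=1000)
    with pytest.raises(ValueError):
        CatalogEntry(key="1:1:A:G", effect_allele="G", trait="BMI",
                     reported_p=0.0, study_year=2020, study_n=1000)
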