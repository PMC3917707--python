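"""Cohort ingestion, genotype coding, HWE, standardisation, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mriv import (
    CohortData,
    FixtureConfig,
    GenotypeCounts,
    MissingnessPolicy,
    apply_missingness_policy,
    generate_fixture,
    genotype_counts,
    hwe_chisq,
    read_cohort_table,
    standardize_trait,
    vcf_to_dosage,
    write_cohort_table,
)
from mriv.data import SchemaError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCohortTable:
    SCHEMA = {"outcome": "y", "exposure": "x",
              "genotypes": {"FTO": {"effect_allele": "A"}}}

    def test_allele_pair_counting(self, tmp_path):
        p = _write(tmp_path, "c.csv",
                   "y,x,FTO\n1,2,TT\n2,3,TA\n3,4,AA\n4,5,TA\n5,6,TT\n")
        data = read_cohort_table(p, self.SCHEMA)
        assert data.frame["FTO"].tolist() == [0, 1, 2, 1, 0]
        assert data.n == 5

    def test_out_of_range_dosage_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "c.csv", "y,x,g\n1,2,0\n2,3,3\n")
        with pytest.raises(SchemaError, match=r"'g'.*row 1.*'3'"):
            read_cohort_table(p, {"outcome": "y", "exposure": "x",
                                  "genotypes": {"g": None}})

    def test_unknown_schema_column(self, tmp_path):
        p = _write(tmp_path, "c.csv", "y,x\n1,2\n")
        with pytest.raises(SchemaError, match="nope"):
            read_cohort_table(p, {"outcome": "y", "exposure": "nope"})

    def test_non_numeric_outcome(self, tmp_path):
        p = _write(tmp_path, "c.csv", "y,x,g\nhigh,2,0\n")
        with pytest.raises(SchemaError, match="'y'"):
            read_cohort_table(p, {"outcome": "y", "exposure": "x",
                                  "genotypes": {"g": None}})

    def test_missing_codes_preserved_not_dropped(self, tmp_path):
        p = _write(tmp_path, "c.csv", "y,x,g\n1,2,NA\n2,3,1\n3,4,./.\n")
        data = read_cohort_table(p, {"outcome": "y", "exposure": "x",
                                     "genotypes": {"g": None}})
        assert data.n == 3
        assert data.missing_mask()["g"].tolist() == [True, False, True]

    def test_round_trip(self, tmp_path):
        fix = generate_fixture(dataclasses.replace(FixtureConfig(), n=200), seed=3)
        out = tmp_path / "rt.csv"
        write_cohort_table(fix, out)
        schema = {"outcome": "bmd", "exposure": "fat_mass", "id": "id",
                  "covariates": ["height"],
                  "genotypes": {g: None for g in fix.genotypes}}
        back = read_cohort_table(out, schema)
        np.testing.assert_array_equal(back.genotype_matrix(), fix.genotype_matrix())
        pd.testing.assert_frame_equal(back.missing_mask(), fix.missing_mask())


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


class TestVcfToDosage:
    def _vcf(self, tmp_path, body):
        return _write(tmp_path, "toy.vcf", VCF_HEADER + body)

    def test_effect_alt_and_ref_coding(self, tmp_path):
        p = self._vcf(tmp_path,
                      "1\t100\trs1\tT\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
                      "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t1/1\t0/1\t./.\n")
        mat, samples = vcf_to_dosage(p, ["rs1", "rs2"], {"rs1": "A", "rs2": "C"})
        assert samples == ["S1", "S2", "S3"]
        assert mat["rs1"].tolist() == [1.0, 2.0, 0.0]
        # rs2 counted toward REF: 1/1 -> 0, 0/1 -> 1, ./. -> missing
        assert mat["rs2"].tolist()[:2] == [0.0, 1.0]
        assert np.isnan(mat["rs2"].iloc[2])

    def test_absent_variant(self, tmp_path):
        p = self._vcf(tmp_path, "1\t100\trs1\tT\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n")
        with pytest.raises(ValueError, match="rs9"):
            vcf_to_dosage(p, ["rs9"], {"rs9": "A"})

    def test_multiallelic_rejected(self, tmp_path):
        p = self._vcf(tmp_path, "1\t100\trs1\tT\tA,G\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n")
        with pytest.raises(ValueError, match="multiallelic"):
            vcf_to_dosage(p, ["rs1"], {"rs1": "A"})

    def test_foreign_effect_allele(self, tmp_path):
        p = self._vcf(tmp_path, "1\t100\trs1\tT\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n")
        with pytest.raises(ValueError, match="neither REF"):
            vcf_to_dosage(p, ["rs1"], {"rs1": "G"})

    def test_fixture_round_trip_against_generator_truth(self, tmp_path, rng):
        truth = rng.integers(0, 3, size=(3, 2)).astype(float)
        lines = []
        for v in range(2):
            gts = []
            for s in range(3):
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(truth[s, v])])
            lines.append(f"1\t{100 + v}\trs{v}\tT\tA\t.\tPASS\t.\tGT\t" + "\t".join(gts))
        p = self._vcf(tmp_path, "\n".join(lines) + "\n")
        mat, _ = vcf_to_dosage(p, ["rs0", "rs1"], {"rs0": "A", "rs1": "A"})
        np.testing.assert_array_equal(mat.to_numpy(), truth)


class TestHWE:
    @pytest.mark.parametrize("counts,expected_p", [
        ((3115, 2017, 280), 0.04),
        ((3705, 1465, 153), 0.57),
        ((1731, 2604, 968), 0.84),
    ])
    def test_cohort_genotype_tables(self, counts, expected_p):
        res = hwe_chisq(GenotypeCounts(*counts))
        assert round(res.p, 2) == expected_p
        assert res.df == 1

    def test_perfect_hwe_fit(self):
        res = hwe_chisq(GenotypeCounts(2500, 5000, 2500))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        res = hwe_chisq(GenotypeCounts(100, 0, 0))
        assert res.monomorphic and res.p == 1.0 and res.chi2 == 0.0

    @given(st.integers(0, 5000), st.integers(0, 5000), st.integers(0, 5000))
    def test_homozygote_label_swap_invariance(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        a = hwe_chisq(GenotypeCounts(n0, n1, n2))
        b = hwe_chisq(GenotypeCounts(n2, n1, n0))
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12, abs=1e-12)

    def test_counts_from_dosage_vector(self):
        c = genotype_counts([0, 1, 2, 1, np.nan, 0])
        assert (c.n0, c.n1, c.n2) == (2, 2, 1)


class TestStandardizeTrait:
    def test_mean_zero_sd_one(self, rng):
        v = rng.lognormal(1.0, 0.4, 500)
        z = standardize_trait(v, log_first=True,
                              age=rng.normal(10, 1, 500), sex=rng.binomial(1, 0.5, 500))
        assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=0) - 1) < 1e-10

    def test_constant_adjusters_reduce_to_zscore(self, rng):
        v = rng.lognormal(0.0, 1.0, 100)
        z = standardize_trait(v, log_first=True, age=np.full(100, 9.9))
        lv = np.log(v)
        np.testing.assert_allclose(z, (lv - lv.mean()) / lv.std(ddof=0), atol=1e-10)

    def test_residual_orthogonal_to_age(self, rng):
        age = rng.normal(10, 1, 400)
        v = 3.0 + 0.7 * age + rng.normal(0, 1, 400)
        z = standardize_trait(v, age=age)
        assert abs((z * (age - age.mean())).sum()) < 1e-8

    def test_log_requires_positive(self):
        with pytest.raises(ValueError, match="non-positive"):
            standardize_trait([1.0, -2.0], log_first=True)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero residual variance"):
            standardize_trait([2.0, 2.0, 2.0])

    def test_affine_invariance_without_log(self, rng):
        v = rng.normal(5, 2, 300)
        np.testing.assert_allclose(standardize_trait(v),
                                   standardize_trait(3.0 * v - 7.0), atol=1e-10)

    def test_missing_stays_missing(self):
        z = standardize_trait([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3]]).any()


class TestMissingnessPolicy:
    def _cohort(self, frame, genos):
        return CohortData(frame=frame, outcome="y", exposure="x", genotypes=genos)

    def test_disjoint_missingness_counts(self):
        n = 1000
        frame = pd.DataFrame({"y": np.zeros(n), "x": np.ones(n)})
        for j in range(4):
            g = np.ones(n)
            g[j * 50:(j + 1) * 50] = np.nan  # disjoint 5% blocks
            frame[f"G{j + 1}"] = g
        data = self._cohort(frame, [f"G{j + 1}" for j in range(4)])
        sub, acct = apply_missingness_policy(
            data, MissingnessPolicy("complete_case_all_instruments"), data.genotypes)
        per_snp = acct.set_index("column")["n"]
        assert all(per_snp[g] == 950 for g in data.genotypes)
        assert per_snp["all_instruments"] == 800 == sub.n

    def test_no_missingness_identity(self):
        frame = pd.DataFrame({"y": [1.0, 2.0], "x": [3.0, 4.0], "g": [0.0, 1.0]})
        data = self._cohort(frame, ["g"])
        sub, acct = apply_missingness_policy(data, MissingnessPolicy(), ["g"])
        pd.testing.assert_frame_equal(sub.frame, data.frame)

    def test_per_model_mode_defers(self):
        frame = pd.DataFrame({"y": [1.0, 2.0], "x": [3.0, 4.0], "g": [np.nan, 1.0]})
        data = self._cohort(frame, ["g"])
        sub, _ = apply_missingness_policy(
            data, MissingnessPolicy("complete_case_per_model"), ["g"])
        assert sub.n == 2  # filtering deferred to each fit

    def test_all_instruments_n_bounded_by_min_per_snp(self):
        fix = generate_fixture(seed=11)
        sub, acct = apply_missingness_policy(fix, MissingnessPolicy(), fix.genotypes)
        per_snp = acct.set_index("column")["n"]
        assert per_snp["all_instruments"] <= per_snp[fix.genotypes].min()

    def test_joint_sample_narrows_like_real_cohorts(self):
        # per-SNP retention in the 92-98% range, joint complete case well below
        fix = generate_fixture(seed=5)
        _, acct = apply_missingness_policy(fix, MissingnessPolicy(), fix.genotypes)
        fr = acct.set_index("column")["fraction"]
        assert all(0.90 < fr[g] < 0.99 for g in fix.genotypes)
        assert fr["all_instruments"] < fr[fix.genotypes].min() - 0.02

    def test_empty_instruments_rejected(self):
        fix = generate_fixture(seed=1)
        with pytest.raises(ValueError, match="empty instrument set"):
            apply_missingness_policy(fix, MissingnessPolicy(), [])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown policy mode"):
            MissingnessPolicy("impute")


class TestGenerateFixture:
    def test_genotypes_in_hwe(self):
        cfg = dataclasses.replace(
            FixtureConfig(), n=100_000,
            snps={"SNP": (0.4, 0.0)}, missingness={})
        fix = generate_fixture(cfg, seed=8)
        res = hwe_chisq(genotype_counts(fix.frame["SNP"]))
        assert res.p > 0.001

    def test_zero_missingness_complete_mask(self):
        cfg = dataclasses.replace(FixtureConfig(), n=500, missingness={})
        fix = generate_fixture(cfg, seed=2)
        assert not fix.missing_mask().any().any()

    def test_no_confounding_recovers_causal_slope(self):
        cfg = dataclasses.replace(
            FixtureConfig(), n=20_000, confounder_sd=0.0,
            snps={k: (f, 0.0) for k, (f, _) in FixtureConfig().snps.items()},
            missingness={})
        fix = generate_fixture(cfg, seed=7)
        ly = np.log(fix.frame["bmd"])
        lx = np.log(fix.frame["fat_mass"])
        X = np.column_stack([np.ones(cfg.n), fix.frame["age"], fix.frame["sex"], lx])
        slope = np.linalg.lstsq(X, ly, rcond=None)[0][-1]
        assert slope == pytest.approx(cfg.causal_effect, abs=0.03)

    def test_reproducible_under_seed(self):
        a = generate_fixture(seed=13)
        b = generate_fixture(seed=13)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FixtureConfig(n=-5)
        with pytest.raises(ValueError):
            FixtureConfig(snps={"g": (1.5, 0.1)})
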