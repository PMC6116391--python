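"""Trio transmission imputation, HWE testing and allele coding."""

import numpy as np
import pandas as pd
import pytest

from lipidpoe import trio as tr
from lipidpoe.trio import (TrioGenotypes, encode_alleles, hwe_test,
                           impute_transmissions, impute_transmissions_frame,
                           infer_transmission, maternal_untransmitted,
                           parse_genotype, read_trios, snp_qc,
                           write_transmissions)

from conftest import all_trio_configs, brute_force_transmission


def make_trio(f, m, c):
    return TrioGenotypes("snp", "fam", f, m, c)


class TestInferTransmission:
    @pytest.mark.parametrize("f,m,c", all_trio_configs())
    def test_matches_brute_force_oracle(self, f, m, c):
        """Table-based imputation agrees with gamete-pair enumeration on all
        27 configurations."""
        pat, mat, consistent = brute_force_transmission(f, m, c)
        res = infer_transmission(make_trio(f, m, c))
        assert res.consistent is consistent
        if consistent:
            assert (res.paternal_allele, res.maternal_allele) == (pat, mat)
        else:
            assert res.paternal_allele == res.maternal_allele == "unknown"

    def test_consistency_census(self):
        """15 Mendelian-consistent configurations, exactly one uninformative."""
        results = [infer_transmission(make_trio(*cfg))
                   for cfg in all_trio_configs()]
        assert sum(r.consistent for r in results) == 15
        uninf = [r for r in results if r.paternal_allele == "uninformative"]
        assert len(uninf) == 1
        assert uninf[0].maternal_allele == "uninformative"

    @pytest.mark.parametrize("f,m,c,pat,mat", [
        (1, 0, 1, "a", "A"),   # het father, hom-major mother, het child
        (1, 1, 1, "uninformative", "uninformative"),
        (0, 0, 0, "A", "A"),
    ])
    def test_published_imputation_rows(self, f, m, c, pat, mat):
        res = infer_transmission(make_trio(f, m, c))
        assert (res.paternal_allele, res.maternal_allele) == (pat, mat)

    def test_mendelian_impossible(self):
        res = infer_transmission(make_trio(0, 0, 2))
        assert res.consistent is False

    def test_missing_member_unknown(self):
        res = infer_transmission(make_trio(None, 0, 0))
        assert res.consistent is None
        assert res.paternal_allele == "unknown"

    def test_malformed_genotype_names_field(self):
        with pytest.raises(ValueError, match="father"):
            TrioGenotypes.from_strings("s", "f", "A/X", "A/A", "A/A")


class TestMaternalUntransmitted:
    def test_homozygous_mother(self):
        assert maternal_untransmitted(make_trio(0, 2, 1)) == "a"
        assert maternal_untransmitted(make_trio(0, 0, 0)) == "A"

    def test_triple_heterozygote_unknown(self):
        assert maternal_untransmitted(make_trio(1, 1, 1)) == "unknown"

    @pytest.mark.parametrize("f,m,c", all_trio_configs())
    def test_transmitted_untransmitted_partition_mother(self, f, m, c):
        """Transmitted + untransmitted alleles permute the mother's genotype
        whenever both are known."""
        res = infer_transmission(make_trio(f, m, c))
        pair = (res.maternal_allele, res.maternal_untransmitted)
        if all(x in ("A", "a") for x in pair):
            assert sorted(pair).count("a") == m


class TestHwe:
    def test_exact_equilibrium(self):
        chi2, p, degenerate = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert not degenerate

    def test_mild_departure(self):
        # expected counts 49/42/9 at p_hat = 0.7 -> chi2 = 1/49 + 4/42 + 1/9
        chi2, p, _ = hwe_test(50, 40, 10)
        assert chi2 == pytest.approx(1 / 49 + 4 / 42 + 1 / 9, rel=1e-12)
        assert p == pytest.approx(0.6339, abs=2e-4)

    def test_strong_departure_rejected(self):
        _, p, _ = hwe_test(90, 0, 10)
        assert p < 0.05

    def test_monomorphic_degenerate(self):
        chi2, p, degenerate = hwe_test(100, 0, 0)
        assert (chi2, p, degenerate) == (0.0, 1.0, True)

    def test_rejection_rate_under_null(self):
        """Under HWE sampling, the chi-square test rejects at ~alpha for any
        MAF, within binomial error over 2000 replicates."""
        rng = np.random.default_rng(5)
        for maf in (0.1, 0.3, 0.5):
            rejections = 0
            reps = 2000
            geno = rng.binomial(2, maf, size=(reps, 300))
            for row in geno:
                counts = np.bincount(row, minlength=3)
                _, p, degenerate = hwe_test(*counts)
                rejections += (not degenerate) and p < 0.05
            rate = rejections / reps
            # 3 binomial SEs around 0.05 (chi2 approximation adds a little)
            assert abs(rate - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / reps)


class TestEncoding:
    @pytest.fixture()
    def imputed(self):
        trios = [make_trio(1, 0, 1), make_trio(1, 1, 1), make_trio(0, 2, 1)]
        df = impute_transmissions(trios)
        df["transmitted_allele"] = df["paternal_allele"]
        return df

    def test_transmitted_binary(self, imputed):
        coded = encode_alleles(imputed, "transmitted-binary")
        assert coded.iloc[0] == 1.0            # paternal 'a'
        assert np.isnan(coded.iloc[1])          # uninformative -> masked
        assert coded.iloc[2] == 0.0

    def test_additive_schemes(self, imputed):
        assert list(encode_alleles(imputed, "genotype-additive")) == [1, 1, 1]
        assert list(encode_alleles(imputed, "maternal-genotype-additive")) == \
            [0, 1, 2]

    def test_untransmitted_binary(self, imputed):
        coded = encode_alleles(imputed, "untransmitted-binary")
        assert coded.iloc[2] == 1.0  # a/a mother -> untransmitted 'a'

    def test_unknown_scheme(self, imputed):
        with pytest.raises(ValueError, match="scheme"):
            encode_alleles(imputed, "dominant")


def test_frame_imputation_equals_loop():
    """The vectorized merge-based imputation reproduces the per-trio loop,
    including missing and Mendelian-inconsistent rows."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(200):
        f, m, c = rng.integers(0, 3, size=3)
        if rng.random() < 0.1:
            f = None
        rows.append({"family_id": f"F{i}", "snp_id": "s1",
                     "father_gt": tr.format_genotype(f),
                     "mother_gt": tr.format_genotype(int(m)),
                     "child_gt": tr.format_genotype(int(c))})
    df = pd.DataFrame(rows)
    fast = impute_transmissions_frame(df)
    slow = impute_transmissions(
        [TrioGenotypes.from_strings(r.snp_id, r.family_id, r.father_gt,
                                    r.mother_gt, r.child_gt)
         for r in df.itertuples()])
    for col in ("paternal_allele", "maternal_allele",
                "maternal_untransmitted"):
        assert list(fast[col]) == list(slow[col])
    assert list(fast["consistent"].fillna("NA")) == \
        list(slow["consistent"].fillna("NA"))


def test_snp_qc_pass_rule():
    rng = np.random.default_rng(1)
    trios = [make_trio(int(f), int(m), None)
             for f, m in rng.binomial(2, 0.3, size=(200, 2))]
    rep = snp_qc(trios)
    assert rep.hwe_p > 0.05 and rep.passed
    assert sum(rep.founder_counts) == 400
    rep2 = snp_qc(trios, discordancy_rate=0.02)
    assert not rep2.passed  # discordancy above 1 %


def test_read_write_roundtrip(tmp_path):
    df = pd.DataFrame({
        "family_id": ["F1", "F2"], "snp_id": ["s", "s"],
        "father_gt": ["A/a", "A/A"], "mother_gt": ["a/a", "A/a"],
        "child_gt": ["A/a", "./."],
    })
    path = tmp_path / "trios.tsv"
    df.to_csv(path, sep="\t", index=False)
    trios = read_trios(path)
    assert trios[0].father == 1 and trios[1].child is None
    out = impute_transmissions(trios)
    write_transmissions(out, tmp_path / "tx.tsv")
    back = pd.read_csv(tmp_path / "tx.tsv", sep="\t")
    assert back.loc[0, "paternal_allele"] == "A"
    assert back.loc[0, "maternal_allele"] == "a"


def test_parse_genotype_dialects():
    assert parse_genotype("Aa") == 1
    assert parse_genotype(2) == 2
    assert parse_genotype("") is None
    assert parse_genotype("G/T", {"G": "A", "T": "a"}) == 1
    with pytest.raises(ValueError):
        parse_genotype("A/a/a")
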