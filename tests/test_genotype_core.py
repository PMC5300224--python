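"""PLINK I/O round-trips, panel merging with allele reconciliation, and the
QC cascade against hand-counted toy panels."""

import numpy as np
import pytest

from introgress import genotype_core as gc
from introgress import synthetic_data as sd
from introgress.errors import FormatError, MergeConflictError

from conftest import make_matrix


def test_handwritten_ped_map_parses_with_one_missing(tmp_path):
    (tmp_path / "t.map").write_text(
        "1 rs1 0 100\n1 rs2 0 200\n1 rs3 0 300\n"
    )
    (tmp_path / "t.ped").write_text(
        "FAM1 s1 0 0 0 -9 A A A G G G\n"
        "FAM2 s2 0 0 0 -9 A G 0 0 G G\n"
    )
    g = gc.read_plink(tmp_path / "t", dialect="text")
    assert g.n_samples == 2 and g.n_snps == 3
    assert int((g.dosage == gc.MISSING).sum()) == 1
    # rs1: alleles A(3) G(1) -> minor G; dosages count G: s1=0, s2=1
    assert list(g.dosage[:, 0]) == [0, 1]
    # rs3 monomorphic G -> zero copies of the (absent) alternative
    assert set(g.dosage[:, 2]) == {0}


def test_ped_with_wrong_field_count_raises(tmp_path):
    (tmp_path / "t.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
    (tmp_path / "t.ped").write_text("F s1 0 0 0 -9 A A\n")
    with pytest.raises(FormatError):
        gc.read_plink(tmp_path / "t", dialect="text")


def test_bed_magic_byte_mismatch_raises(tmp_path):
    (tmp_path / "t.fam").write_text("F s1 0 0 0 -9\n")
    (tmp_path / "t.bim").write_text("1\trs1\t0\t100\tA\tG\n")
    (tmp_path / "t.bed").write_bytes(b"\x00\x00\x00\x00")
    with pytest.raises(FormatError):
        gc.read_plink(tmp_path / "t", dialect="binary")


@pytest.mark.parametrize("dialect", ["text", "binary"])
@pytest.mark.parametrize("n_samples", [4, 255])  # 255 hits the 2-bit padding edge
def test_roundtrip_is_exact(tmp_path, dialect, n_samples):
    fr = sd.simulate_breed_frequencies(40, 2, 0.1, seed=1)
    q = np.tile([0.5, 0.5], (n_samples, 1))
    g, _ = sd.simulate_admixed_cohort(fr, q, missing_rate=0.05, seed=2)
    g = gc.recode_minor(g)
    gc.write_plink(g, tmp_path / "t", dialect=dialect)
    back = gc.read_plink(tmp_path / "t", dialect=dialect)
    assert np.array_equal(g.dosage, back.dosage)
    assert list(back.samples["iid"]) == list(g.samples["iid"])
    assert list(back.snps["snp_id"]) == list(g.snps["snp_id"])


def test_text_and_binary_dialects_agree(tmp_path):
    fr = sd.simulate_breed_frequencies(60, 2, 0.1, seed=3)
    g, _ = sd.simulate_admixed_cohort(
        fr, np.tile([0.3, 0.7], (9, 1)), missing_rate=0.1, seed=4
    )
    g = gc.recode_minor(g)
    gc.write_plink(g, tmp_path / "t", dialect="text")
    gc.write_plink(g, tmp_path / "b", dialect="binary")
    gt = gc.read_plink(tmp_path / "t", dialect="text")
    gb = gc.read_plink(tmp_path / "b", dialect="binary")
    assert np.array_equal(gt.dosage, gb.dosage)


def test_write_is_byte_stable(tmp_path):
    fr = sd.simulate_breed_frequencies(30, 2, 0.1, seed=5)
    g, _ = sd.simulate_admixed_cohort(fr, np.tile([0.5, 0.5], (7, 1)), seed=6)
    gc.write_plink(g, tmp_path / "a", dialect="binary")
    gc.write_plink(g, tmp_path / "b", dialect="binary")
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


def test_zero_snp_matrix_roundtrips(tmp_path):
    g = make_matrix(np.zeros((3, 0)))
    for dialect in ("text", "binary"):
        gc.write_plink(g, tmp_path / dialect / "t", dialect=dialect)
        back = gc.read_plink(tmp_path / dialect / "t", dialect=dialect)
        assert back.n_snps == 0 and back.n_samples == 3


def test_minor_allele_coding_invariant(tmp_path):
    fr = sd.simulate_breed_frequencies(200, 2, 0.1, seed=7)
    g, _ = sd.simulate_admixed_cohort(fr, np.tile([0.5, 0.5], (60, 1)), seed=8)
    gc.write_plink(g, tmp_path / "t", dialect="binary")
    back = gc.read_plink(tmp_path / "t", dialect="binary")
    f = gc.allele1_frequency(back.dosage)
    assert np.nanmax(f) <= 0.5 + 1e-12


def test_minor_coding_tie_keeps_lexicographic_allele():
    g = make_matrix([[2], [0]], alleles=[("B", "A")])  # freq exactly 0.5
    rec = gc.recode_minor(g)
    assert rec.snps["allele1"].iat[0] == "A"
    assert list(rec.dosage[:, 0]) == [0, 2]


class TestMerge:
    def test_disjoint_samples_identical_maps(self):
        a = make_matrix([[0, 1], [2, 1]], groups=["A", "A"])
        b = make_matrix([[1, 1], [0, 2]], groups=["B", "B"])
        m = gc.merge_panels([a, b])
        assert m.n_samples == 4 and m.n_snps == 2

    def test_swapped_alleles_are_reconciled(self):
        a = make_matrix([[0, 1], [2, 1]], alleles=[("A", "B"), ("A", "B")])
        b = make_matrix(
            [[2, 1], [0, 1]], alleles=[("B", "A"), ("A", "B")]
        )  # first SNP coded from the other allele
        m = gc.merge_panels([a, b])
        # after flipping onto a common coding the allele-1 counts agree
        f = gc.allele1_frequency(m.dosage)
        assert np.allclose(f, gc.allele1_frequency(np.array([[0, 1], [2, 1], [0, 1], [2, 1]])))

    def test_partial_snp_overlap_keeps_intersection(self):
        fr = sd.simulate_breed_frequencies(10, 2, 0.1, seed=9)
        g, _ = sd.simulate_admixed_cohort(fr, np.tile([0.5, 0.5], (4, 1)), seed=10)
        a = g.take_snps(range(0, 6))
        b = g.take_snps(range(4, 10))
        m = gc.merge_panels([a, b])
        assert m.n_snps == 2  # snps 4,5

    def test_irreconcilable_alleles_raise(self):
        a = make_matrix([[0], [2]], alleles=[("A", "B")])
        b = make_matrix([[0], [2]], alleles=[("C", "T")])
        with pytest.raises(MergeConflictError):
            gc.merge_panels([a, b])

    def test_merge_is_order_insensitive_up_to_sample_order(self):
        fr = sd.simulate_breed_frequencies(30, 2, 0.1, seed=11)
        g, _ = sd.simulate_admixed_cohort(fr, np.tile([0.5, 0.5], (6, 1)), seed=12)
        a, b = g.take_samples(range(0, 3)), g.take_samples(range(3, 6))
        m1 = gc.merge_panels([a, b])
        m2 = gc.merge_panels([b, a])
        assert list(m1.snps["snp_id"]) == list(m2.snps["snp_id"])
        order = [list(m2.samples["iid"]).index(i) for i in m1.samples["iid"]]
        assert np.array_equal(m1.dosage, m2.dosage[order])


class TestExtract:
    def test_all_ids_is_identity(self, recovery_cohort):
        g, _ = recovery_cohort
        sub = gc.extract_snp_subset(g, list(g.snps["snp_id"]))
        assert np.array_equal(sub.dosage, g.dosage)

    def test_disjoint_ids_give_empty_matrix(self, recovery_cohort):
        g, _ = recovery_cohort
        assert gc.extract_snp_subset(g, ["nope"]).n_snps == 0

    def test_half_subset_has_exact_count(self, recovery_cohort):
        g, _ = recovery_cohort
        keep = list(g.snps["snp_id"])[::2]
        assert gc.extract_snp_subset(g, keep).n_snps == len(keep)


class TestQcFilter:
    def _toy(self):
        # 12 SNPs: 2 on chromosome 30; one autosomal SNP at 8% missing
        # (spread over 8 samples that each end at exactly 10% missing, under
        # the mind threshold); one autosomal SNP violating HWE hard.
        rng = np.random.default_rng(0)
        n = 100
        dosage = rng.binomial(2, 0.4, size=(n, 12)).astype(np.int8)
        dosage[:8, 2] = gc.MISSING  # 8% missing SNP
        dosage[:, 3] = 1  # every genotype heterozygous: HWE p ~ 1e-29
        return make_matrix(dosage, chrom=[30, 30] + [1] * 10)

    def test_hand_counted_cascade(self):
        g = self._toy()
        filt, report = gc.qc_filter(g, mind=0.10, geno=0.05, hwe_p=1e-5)
        assert report.n_samples_removed == 0
        reasons = dict(
            zip(report.snps_removed["snp_id"], report.snps_removed["reason"])
        )
        assert reasons == {
            "snp0": "chromosome",
            "snp1": "chromosome",
            "snp2": "SNP call rate",
            "snp3": "HWE",
        }
        assert filt.n_snps == 8

    def test_low_call_rate_sample_removed_with_reason(self):
        dosage = np.ones((4, 20), dtype=np.int8)
        dosage[0, :3] = gc.MISSING  # call rate 0.85
        dosage[:, -1] = [0, 1, 2, 1]  # keep some variation
        g = make_matrix(dosage)
        _, report = gc.qc_filter(g, hwe_p=None)
        assert list(report.samples_removed["iid"]) == ["s0"]
        assert report.samples_removed["reason"].iat[0] == "sample call rate"
        assert report.samples_removed["call_rate"].iat[0] == pytest.approx(0.85)

    def test_clean_snp_retained(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.binomial(2, 0.3, size=(200, 1)).astype(np.int8))
        filt, report = gc.qc_filter(g, maf=0.05)
        assert filt.n_snps == 1 and report.n_snps_removed == 0

    def test_maf_filter_removes_rare_snp(self):
        dosage = np.zeros((100, 2), dtype=np.int8)
        dosage[:40, 0] = 1  # MAF 0.2
        dosage[0, 1] = 1  # MAF 0.005
        g = make_matrix(dosage)
        filt, report = gc.qc_filter(g, hwe_p=None, maf=0.05)
        assert list(report.snps_removed["snp_id"]) == ["snp1"]
        assert list(report.snps_removed["reason"]) == ["MAF"]

    def test_filter_is_idempotent(self, recovery_cohort):
        g, _ = recovery_cohort
        once, _ = gc.qc_filter(g, maf=0.05)
        twice, report = gc.qc_filter(once, maf=0.05)
        assert report.n_snps_removed == 0 and report.n_samples_removed == 0
        assert np.array_equal(once.dosage, twice.dosage)


class TestAlleleFrequencies:
    def test_direct_count(self):
        g = make_matrix([[0], [1], [2]])
        assert gc.allele_frequencies(g).freqs[0, 0] == pytest.approx(0.5)

    def test_all_missing_snp_is_undefined_not_zero(self):
        g = make_matrix([[gc.MISSING], [gc.MISSING]])
        assert np.isnan(gc.allele_frequencies(g).freqs[0, 0])

    def test_per_group_frequencies_recover_generator(self, two_breed_freqs):
        q = np.vstack([np.tile([1.0, 0.0], (300, 1)), np.tile([0.0, 1.0], (300, 1))])
        g, _ = sd.simulate_admixed_cohort(
            two_breed_freqs, q, seed=20, group_labels=["ZB"] * 300 + ["CH"] * 300
        )
        est = gc.allele_frequencies(g, by_group=True)
        for b, name in enumerate(["ZB", "CH"]):
            f_true = two_breed_freqs.freqs[b]
            f_est = est.freqs[est.populations.index(name)]
            se = np.sqrt(f_true * (1 - f_true) / (2 * 300))
            assert np.mean(np.abs(f_est - f_true) > 3 * se + 1e-9) < 0.01
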