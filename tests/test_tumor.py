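"""Tumor compartment analysis: microhomology, classification, Eq.-style
pooling, bootstrap z-scores and Stouffer combination."""

import numpy as np
import pandas as pd
import pytest

import breakbalance as bb
from breakbalance.indel_quant import ConfigurationError, ValidationError
from breakbalance.synthetic import tumor_lad_index
from breakbalance.tumor_ccd import (
    COUNT_COLS,
    aggregate_counts,
    annotate_deletions,
    eligible_gois,
    sample_count_matrix,
)


class TestMicrohomology:
    def test_right_flank_homology(self):
        ref = {"c": "TAGCAGCTT"}
        # deletion [1,4) removes "AGC"; downstream flank starts "AGC..."
        assert bb.compute_microhomology(ref, "c", 1, 4) == 3

    def test_no_shared_bases_gives_zero(self):
        ref = {"c": "AAATTTCCC"}
        assert bb.compute_microhomology(ref, "c", 3, 6) == 0

    def test_tandem_copy_deletion_has_full_homology(self):
        ref = {"c": "GGATCGATCGG"}
        # deleting one "GATC" copy: homology equals the deletion length
        assert bb.compute_microhomology(ref, "c", 2, 6) == 4

    def test_left_flank_homology_counts_too(self):
        ref = {"c": "TTAGCAGCTT"}
        # deletion [5,8) removes "GCT"? use a clean left-homology case:
        ref = {"c": "AAGCGCTT"}
        # deletion [4,6) removes "GC"; upstream flank ends "GC"
        assert bb.compute_microhomology(ref, "c", 4, 6) == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bb.compute_microhomology({"c": "ACGT"}, "c", 2, 8)


class TestClassifyDeletion:
    @pytest.mark.parametrize(
        "length, mh, expected",
        [
            (7, 3, "MMEJ_sig"),
            (6, 0, "NHEJ_sig"),
            (5, 2, "unclassified"),   # the >5 bp boundary
            (8, 1, "unclassified"),   # 1 bp microhomology is ambiguous
            (3, 0, "unclassified"),
        ],
    )
    def test_signature_rules(self, length, mh, expected):
        assert bb.classify_deletion(length, mh) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bb.classify_deletion(0, 0)


class TestCompartmentAssignment:
    def test_full_containment_required(self, lad_index):
        assert lad_index.assign("chr1", 100, 150) == "Het"
        assert lad_index.assign("chr1", 1100, 1150) == "Eu"
        assert lad_index.assign("chr1", 950, 1050) == "neither"  # spans boundary
        assert lad_index.assign("chr1", 4500, 4600) == "neither"
        assert lad_index.assign("chr2", 100, 150) == "neither"

    def test_bed_parse_error_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t100\tcLAD\nchr1\tx\t200\tciLAD\n")
        with pytest.raises(ValidationError, match="line 2"):
            bb.LadIndex.from_bed(bed)

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "lads.bed"
        bed.write_text("chr1\t0\t1000\tcLAD\nchr1\t1000\t2000\tciLAD\n")
        idx = bb.LadIndex.from_bed(bed)
        assert idx.assign("chr1", 10, 20) == "Het"
        assert idx.assign("chr1", 1500, 1600) == "Eu"


def meta_row(sample_id, lof="", anyd=None, deficiency=False, signature=False, n_subs=1000,
             subtype="A", dataset="d1"):
    return {
        "sample_id": sample_id,
        "cancer_subtype": subtype,
        "dataset": dataset,
        "driver_lof_genes": lof,
        "driver_genes": anyd if anyd is not None else lof,
        "other_repair_deficiency": deficiency,
        "mutagenic_signature": signature,
        "n_substitutions": n_subs,
    }


class TestFilterSamples:
    def test_clean_single_goi_lof_is_case(self):
        meta = pd.DataFrame([meta_row("s1", lof="ATM")])
        assert bb.filter_samples(meta, "ATM")["role"].iloc[0] == "case"

    def test_low_substitution_count_excluded(self):
        meta = pd.DataFrame([meta_row("s1", lof="ATM", n_subs=400)])
        assert bb.filter_samples(meta, "ATM")["role"].iloc[0] == "excluded"

    def test_two_goi_drivers_excluded_as_case(self):
        meta = pd.DataFrame([meta_row("s1", lof="ATM,BLM")])
        assert bb.filter_samples(meta, "ATM")["role"].iloc[0] == "excluded"

    def test_control_needs_no_goi_driver_of_any_kind(self):
        meta = pd.DataFrame(
            [
                meta_row("clean"),
                meta_row("non_lof_driver", lof="", anyd="ATM"),
                meta_row("flagged", deficiency=True),
            ]
        )
        roles = bb.filter_samples(meta, "ATM").set_index("sample_id")["role"]
        assert roles["clean"] == "control"
        assert roles["non_lof_driver"] == "excluded"
        assert roles["flagged"] == "excluded"

    def test_gene_selection_rule(self):
        rows = [meta_row(f"c{i}", lof="ATM", subtype="A") for i in range(3)]
        rows += [meta_row(f"d{i}", lof="ATM", subtype=chr(66 + i)) for i in range(2)]
        rows += [meta_row(f"e{i}", lof="BLM", subtype=chr(66 + i)) for i in range(5)]
        meta = pd.DataFrame(rows)
        # ATM: 5 cases, 3 in subtype A -> eligible; BLM: 5 cases all in
        # different subtypes -> not eligible
        assert eligible_gois(meta, ("ATM", "BLM")) == ["ATM"]


class TestCountsAndStat:
    def annotated(self, lad_index):
        dels = pd.DataFrame(
            {
                "sample_id": ["s1"] * 5 + ["s2"] * 2,
                "chrom": "chr1",
                "start": [10, 40, 80, 1100, 2100, 120, 1200],
                "end": [20, 50, 90, 1110, 2110, 130, 1210],
                "mh_len": [3, 2, 0, 0, 2, 2, 0],
            }
        )
        return annotate_deletions(dels, lad_index)

    def test_single_sample_pooling(self, lad_index):
        ann = self.annotated(lad_index)
        counts = sample_count_matrix(ann, ["s1"])
        # s1: two MMEJ in Het, one NHEJ in Het, one NHEJ in Eu, one MMEJ in Het (2100)
        assert counts.loc["s1", "mmej_het"] == 3
        assert counts.loc["s1", "nhej_het"] == 1
        assert counts.loc["s1", "nhej_eu"] == 1

    def test_pooling_equals_per_sample_sum(self, lad_index):
        ann = self.annotated(lad_index)
        both = sample_count_matrix(ann, ["s1", "s2"])
        total = aggregate_counts(both)
        manual = sample_count_matrix(ann, ["s1"]).iloc[0] + sample_count_matrix(ann, ["s2"]).iloc[0]
        assert (total == manual.to_numpy()).all()

    def test_empty_group_is_zero(self, lad_index):
        ann = self.annotated(lad_index)
        counts = sample_count_matrix(ann, ["missing_sample"])
        assert (counts.to_numpy() == 0).all()

    def test_het_eu_arithmetic(self):
        val, corrected = bb.het_eu_stat([40, 10, 20, 40])
        assert val == pytest.approx(3.0) and not corrected

    def test_het_eu_scale_invariance_and_antisymmetry(self):
        v1, _ = bb.het_eu_stat([40, 10, 20, 40])
        v2, _ = bb.het_eu_stat([400, 100, 200, 400])
        assert v1 == pytest.approx(v2)
        swapped, _ = bb.het_eu_stat([20, 40, 40, 10])
        assert swapped == pytest.approx(-v1)

    def test_zero_count_continuity_correction_flagged(self):
        val, corrected = bb.het_eu_stat([0, 10, 20, 40])
        assert corrected
        expected = np.log2(0.5 / 10.5) - np.log2(20.5 / 40.5)
        assert val == pytest.approx(expected)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            bb.het_eu_stat([0, 0, 0, 0])


class TestBootstrapZ:
    def counts(self, rng, n, scale=30):
        lam = np.array([scale, scale / 2, scale / 2, scale])
        return pd.DataFrame(rng.poisson(lam, size=(n, 4)), columns=COUNT_COLS)

    def test_null_cases_yield_moderate_z(self, rng):
        zs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            ctrl = self.counts(r, 30)
            case = self.counts(r, 8)
            st = bb.bootstrap_z(case, ctrl, n_boot=300, seed=seed)
            zs.append(st.z_case)
        assert np.mean(np.abs(np.array(zs)) < 3) >= 0.9

    def test_identical_controls_are_degenerate(self):
        ctrl = pd.DataFrame([[10, 5, 5, 10]] * 6, columns=COUNT_COLS)
        case = pd.DataFrame([[10, 5, 5, 10]] * 3, columns=COUNT_COLS)
        with pytest.raises(ValidationError):
            bb.bootstrap_z(case, ctrl, n_boot=100, seed=0)

    def test_too_few_controls_rejected(self, rng):
        ctrl = self.counts(rng, 4)
        case = self.counts(rng, 3)
        with pytest.raises(ConfigurationError):
            bb.bootstrap_z(case, ctrl)

    def test_planted_het_shift_detected(self, rng):
        ctrl = self.counts(rng, 30, scale=60)
        case = self.counts(rng, 10, scale=60)
        case["mmej_het"] = rng.poisson(30, size=10)  # halved MMEJ in Het
        st = bb.bootstrap_z(case, ctrl, n_boot=500, seed=1)
        assert st.z_case < -3


class TestStouffer:
    def test_identity_at_k_one(self):
        Z, p = bb.stouffer([1.7])
        assert Z == pytest.approx(1.7)

    def test_hand_computed_combination(self):
        Z, _ = bb.stouffer([1.2, -0.4, 2.0])
        assert Z == pytest.approx(2.8 / np.sqrt(3))

    def test_equal_inputs_closed_form(self):
        Z, _ = bb.stouffer([0.9] * 4)
        assert Z == pytest.approx(0.9 * 2)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            bb.stouffer([])

    def test_standard_normal_under_null(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        zs = [bb.stouffer(rng.normal(size=rng.integers(1, 6)))[0] for _ in range(1000)]
        assert stats.kstest(zs, "norm").pvalue > 0.01


class TestCohortAnalysis:
    def test_planted_het_mmej_reduction_detected(self):
        truth = bb.TumorTruth(
            seed=21, n_cases=12, n_controls=40, case_effect={("Het", "MMEJ"): 0.5}
        )
        dels, meta, lads = bb.sim_tumors(truth)
        strata, gois = bb.analyze_cohort(
            dels, meta, tumor_lad_index(lads), n_boot=500, seed=4
        )
        assert gois.loc[0, "goi"] == "ATM"
        assert gois.loc[0, "significant"]
        assert strata["z_case"].iloc[0] < 0

    def test_null_cohort_not_significant(self):
        truth = bb.TumorTruth(seed=22, n_cases=12, n_controls=40)
        dels, meta, lads = bb.sim_tumors(truth)
        _, gois = bb.analyze_cohort(dels, meta, tumor_lad_index(lads), n_boot=500, seed=4)
        assert abs(gois.loc[0, "Z"]) < 4


class TestLongMhDeletions:
    def make_cohort(self, rng, n_samples, het_rate, eu_rate, prefix):
        rows = []
        for i in range(n_samples):
            sid = f"{prefix}{i}"
            for comp, rate, base in (("het", het_rate, 0), ("eu", eu_rate, 1_000_000)):
                for _ in range(rng.poisson(rate)):
                    start = base + int(rng.integers(0, 900_000))
                    rows.append((sid, "chr1", start, start + 2000, 3))
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "mh_len"])

    def lads(self):
        return bb.LadIndex(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 1_000_000],
                    "end": [1_000_000, 2_000_000],
                    "label": ["cLAD", "ciLAD"],
                }
            )
        )

    def test_size_bounds_respected(self):
        lads = self.lads()
        sv = pd.DataFrame(
            {
                "sample_id": ["a", "a", "a"],
                "chrom": "chr1",
                "start": [100, 200_000, 500_000],
                "end": [100 + 1399, 200_000 + 2000, 500_000 + 3000],
                "mh_len": [3, 3, 1],
            }
        )
        ctrl = self.make_cohort(np.random.default_rng(0), 6, 5, 5, "c")
        sv = pd.concat([sv, ctrl], ignore_index=True)
        res = bb.long_mh_deletions(sv, lads, ["a"], ctrl["sample_id"].unique(), seed=0)
        # the 1399 bp deletion is below the 1.4 kb bound; mh 1 is excluded
        assert res["case_het"] + res["case_eu"] == 1

    def test_identical_rates_give_moderate_z(self):
        rng = np.random.default_rng(3)
        lads = self.lads()
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            case = self.make_cohort(r, 8, 10, 10, "case")
            ctrl = self.make_cohort(r, 20, 10, 10, "ctrl")
            sv = pd.concat([case, ctrl], ignore_index=True)
            res = bb.long_mh_deletions(
                sv, lads, case["sample_id"].unique(), ctrl["sample_id"].unique(), seed=seed
            )
            ok += abs(res["z_case"]) < 3
        assert ok >= 9

    def test_planted_compartment_shift_detected(self):
        rng = np.random.default_rng(9)
        lads = self.lads()
        case = self.make_cohort(rng, 10, 2, 20, "case")   # shifted toward Eu
        ctrl = self.make_cohort(rng, 20, 10, 10, "ctrl")
        sv = pd.concat([case, ctrl], ignore_index=True)
        res = bb.long_mh_deletions(
            sv, lads, case["sample_id"].unique(), ctrl["sample_id"].unique(), seed=1
        )
        assert res["z_case"] < -3


def test_vcf_deletion_coordinates(tmp_path):
    vcf = tmp_path / "dels.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=1000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t5\t.\tGACGT\tG\t.\t.\t.\n"
    )
    from breakbalance.tumor_ccd import read_deletions_vcf

    df = read_deletions_vcf(vcf, sample_id="s1")
    # POS 5, REF GACGT -> deletion of ACGT at 0-based [5, 9)
    assert df.iloc[0][["start", "end"]].tolist() == [5, 9]
    assert df.iloc[0]["sample_id"] == "s1"
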