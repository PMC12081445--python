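"""Cohort analytics: prevalence, recurrence, co-occurrence, biomarkers."""

import numpy as np
import pandas as pd
import pytest

from trkfusion.classifier import LIKELY_ONCOGENIC, ONCOGENIC, VUS
from trkfusion.cohort import (
    AnalysisConfig,
    biomarker_comparison,
    cooccurrence_summary,
    format_alterations,
    msi_proportions,
    partner_novelty_summary,
    prevalence_table,
    proportion_pct,
    read_cohort,
    recurrence_table,
    round_half_up,
    specimen_positivity,
)

CFG = AnalysisConfig()


def classified_frame(rows):
    """rows: (specimen, fusion_name, verdict)"""
    records = []
    for specimen, fusion, verdict in rows:
        gene_5p, ntrk = fusion.rsplit("-", 1)
        records.append(
            dict(specimen_id=specimen, fusion_name=fusion, gene_5p=gene_5p,
                 gene_3p=ntrk, ntrk_gene=ntrk, verdict=verdict)
        )
    return pd.DataFrame(records)


def cohort_frame(n, types=None, alterations=None, **overrides):
    df = pd.DataFrame(
        {
            "specimen_id": [f"S{i}" for i in range(1, n + 1)],
            "tumor_type": types if types is not None else ["NSCLC"] * n,
            "age": 60, "sex": "F", "stage": "unknown",
            "tmb": 5.0, "pdl1_score": 10.0, "pdl1_score_type": "TPS",
            "msi": "MSS",
            "alterations": alterations if alterations is not None else [()] * n,
        }
    )
    for key, values in overrides.items():
        df[key] = values
    return df


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, nd, expected",
        [
            (3, 157, 2, 1.91),
            (9, 1423, 2, 0.63),
            (69, 19531, 2, 0.35),
            (5, 69, 2, 7.25),
            (2, 69, 2, 2.90),
            (3, 19591, 3, 0.015),
            (35, 69, 1, 50.7),
            (59, 69, 0, 86.0),
        ],
    )
    def test_half_up_percentages(self, num, den, nd, expected):
        assert proportion_pct(num, den, nd) == expected

    def test_half_up_at_tie(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.5, 0) == 3.0


class TestPositivityAndPrevalence:
    def test_specimen_dedup_and_vus_exclusion(self):
        classified = classified_frame(
            [
                ("A", "LMNA-NTRK1", ONCOGENIC),
                ("A", "ETV6-NTRK3", ONCOGENIC),  # same specimen counted once
                ("B", "HMCN1-NTRK1", LIKELY_ONCOGENIC),
                ("C", "XYZ-NTRK2", VUS),  # VUS-only specimen is negative
            ]
        )
        pos = specimen_positivity(classified)
        assert pos["positive_specimens"] == {"A", "B"}
        assert pos["n_qualifying_fusions"] == 3
        assert pos["n_positive_specimens"] == 2

    def test_prevalence_counts_and_sums(self):
        cohort = cohort_frame(10, types=["NSCLC"] * 6 + ["breast"] * 4)
        table = prevalence_table(cohort, {"S1", "S7"}, CFG).set_index("tumor_type")
        assert table.loc["NSCLC", "n_positive"] == 1
        assert table.loc["breast", "percent"] == 25.0
        named = table.drop(index="ALL")
        assert named["n_positive"].sum() == table.loc["ALL", "n_positive"]
        assert named["n_total"].sum() == table.loc["ALL", "n_total"]

    def test_zero_positive_type_is_zero_percent(self):
        cohort = cohort_frame(4, types=["uterine"] * 4)
        table = prevalence_table(cohort, set(), CFG)
        assert (table["percent"] == 0.0).all()

    def test_unknown_specimen_flag_errors(self):
        with pytest.raises(ValueError, match="not in cohort"):
            prevalence_table(cohort_frame(2), {"NOPE"}, CFG)


class TestRecurrence:
    def test_counts_and_sorting(self):
        classified = classified_frame(
            [("A", "ETV6-NTRK3", ONCOGENIC), ("B", "ETV6-NTRK3", ONCOGENIC),
             ("C", "LMNA-NTRK1", ONCOGENIC), ("D", "AAA-NTRK2", LIKELY_ONCOGENIC)]
        )
        cohort = cohort_frame(4, types=["breast", "NSCLC", "NSCLC", "other"])
        cohort["specimen_id"] = ["A", "B", "C", "D"]
        table = recurrence_table(classified, cohort, 1000, CFG)
        assert list(table["fusion_name"][:1]) == ["ETV6-NTRK3"]
        top = table.iloc[0]
        assert top["n_specimens"] == 2
        assert top["fusion_pct"] == proportion_pct(2, 4, 2)
        assert top["cohort_pct"] == proportion_pct(2, 1000, 3)
        # singletons tie-broken by name
        assert list(table["fusion_name"][1:]) == ["AAA-NTRK2", "LMNA-NTRK1"]

    def test_duplicate_call_in_one_specimen_counts_once(self):
        classified = classified_frame(
            [("A", "PRKACA-NTRK2", LIKELY_ONCOGENIC)] * 2
        )
        table = recurrence_table(classified, None, 100, CFG)
        assert table.loc[0, "n_specimens"] == 1

    def test_cohort_total_smaller_than_positives_errors(self):
        classified = classified_frame([("A", "ETV6-NTRK3", ONCOGENIC)])
        with pytest.raises(ValueError):
            recurrence_table(classified, None, 0, CFG)


class TestNovelty:
    def test_pair_level_counting(self, kb):
        classified = classified_frame(
            [
                ("A", "EML4-NTRK1", ONCOGENIC),
                ("B", "EML4-NTRK3", ONCOGENIC),  # same partner, second pair
                ("C", "EML4-NTRK3", ONCOGENIC),  # duplicate pair, not re-counted
                ("D", "HMCN1-NTRK1", LIKELY_ONCOGENIC),
                ("E", "XYZ-NTRK2", VUS),  # VUS excluded
            ]
        )
        assert partner_novelty_summary(classified, kb) == (2, 1)

    def test_empty(self, kb):
        empty = classified_frame([]).reindex(
            columns=["specimen_id", "fusion_name", "gene_5p", "gene_3p",
                     "ntrk_gene", "verdict"]
        )
        assert partner_novelty_summary(empty, kb) == (0, 0)


class TestCooccurrence:
    def test_frequencies_and_dedup(self):
        alts = [()] * 10
        alts[0] = (("TP53", "snv_indel", True), ("TP53", "cnv_loss", True))
        alts[1] = (("TP53", "snv_indel", True),)
        alts[2] = (("KRAS", "snv_indel", False),)  # not pathogenic: ignored
        cohort = cohort_frame(10, alterations=alts)
        flags = {f"S{i}" for i in range(1, 11)}
        out = cooccurrence_summary(cohort, flags, CFG)
        gene = out["gene_freq"].set_index("gene")
        # dual-class TP53 specimen counted once for the gene frequency
        assert gene.loc["TP53", "n_specimens"] == 2
        assert gene.loc["TP53", "percent"] == 20.0
        assert "KRAS" not in gene.index
        assert out["matrix"].loc["TP53", "S1"] == "cnv_loss+snv_indel"
        assert out["class_freq"]["n_snv_indel"] == 2
        assert out["class_freq"]["n_cnv"] == 1

    def test_min_freq_boundary_inclusive(self):
        alts = [()] * 100
        for i in range(3):
            alts[i] = (("GENE3", "snv_indel", True),)
        for i in range(3, 5):
            alts[i] = (("GENE2", "snv_indel", True),)
        cohort = cohort_frame(100, alterations=alts)
        flags = {f"S{i}" for i in range(1, 101)}
        out = cooccurrence_summary(cohort, flags, CFG)
        assert "GENE3" in out["matrix"].index  # exactly 3.0%: retained
        assert "GENE2" not in out["matrix"].index  # 2.0%: dropped

    def test_matrix_columns_are_positive_specimens(self):
        cohort = cohort_frame(6)
        flags = {"S1", "S2", "S3"}
        out = cooccurrence_summary(cohort, flags, CFG)
        assert list(out["matrix"].columns) == ["S1", "S2", "S3"] or out["matrix"].empty

    def test_removing_filter_only_adds_rows(self):
        alts = [()] * 50
        for i in range(5):
            alts[i] = (("BIG", "snv_indel", True),)
        alts[5] = (("SMALL", "snv_indel", True),)
        cohort = cohort_frame(50, alterations=alts)
        flags = {f"S{i}" for i in range(1, 51)}
        strict = cooccurrence_summary(cohort, flags, CFG)
        loose = cooccurrence_summary(
            cohort, flags, AnalysisConfig(oncoprint_min_freq=1.0)
        )
        assert set(strict["matrix"].index) <= set(loose["matrix"].index)
        for gene in strict["matrix"].index:
            assert (
                loose["matrix"].loc[gene] == strict["matrix"].loc[gene]
            ).all()


class TestBiomarkers:
    def test_identical_distributions_null_case(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1.5, 0.5, size=400)
        cohort = cohort_frame(400, tmb=values)
        flags = {f"S{i}" for i in range(1, 201)}
        out = biomarker_comparison(cohort, flags, "tmb")
        assert out["p_value"] > 0.05
        # both groups drawn from one distribution: medians close
        assert abs(out["median_positive"] - out["median_negative"]) < 1.5

    def test_shifted_positive_group_detected(self):
        """Generated with the NTRK+ TMB shift: positive median lower, small p."""
        rng = np.random.default_rng(1)
        n_pos, n_neg = 60, 400
        pos_tmb = np.exp(rng.normal(np.log(2.1), 0.8, n_pos)) - 1
        neg_tmb = np.exp(rng.normal(np.log(6.4), 0.8, n_neg)) - 1
        cohort = cohort_frame(
            n_pos + n_neg,
            types=["head_and_neck"] * (n_pos + n_neg),
            tmb=np.clip(np.concatenate([pos_tmb, neg_tmb]), 0, None),
        )
        flags = {f"S{i}" for i in range(1, n_pos + 1)}
        out = biomarker_comparison(cohort, flags, "tmb", ["head_and_neck"])
        assert out["median_positive"] < out["median_negative"]
        assert out["p_value"] < 1e-4

    def test_rank_sum_invariant_to_log_transform(self):
        """The rank-sum p on log(TMB+1) equals the p on raw TMB (monotone
        transform) — an implementation check of the transform plumbing."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        values = rng.lognormal(1.5, 0.8, size=100)
        cohort = cohort_frame(100, tmb=values)
        flags = {f"S{i}" for i in range(1, 41)}
        out = biomarker_comparison(cohort, flags, "tmb")
        pos = values[:40]
        neg = values[40:]
        raw_p = mannwhitneyu(pos, neg, alternative="two-sided").pvalue
        assert out["p_value"] == pytest.approx(raw_p, rel=1e-12)

    def test_pdl1_requires_score_type_and_never_pools(self):
        cohort = cohort_frame(
            6,
            pdl1_score=[0, 10, 80, 5, 50, 20],
            pdl1_score_type=["TPS", "TPS", "TPS", "CPS", "CPS", "CPS"],
        )
        flags = {"S1", "S4"}
        with pytest.raises(ValueError, match="score_type"):
            biomarker_comparison(cohort, flags, "pdl1")
        out = biomarker_comparison(cohort, flags, "pdl1", score_type="TPS")
        assert out["n_positive"] + out["n_negative"] == 3

    def test_empty_group_skipped_with_warning(self):
        cohort = cohort_frame(4)
        with pytest.warns(UserWarning, match="skipped"):
            assert biomarker_comparison(cohort, set(), "tmb") is None

    def test_missing_values_dropped_and_counted(self):
        cohort = cohort_frame(6, tmb=[1.0, 2.0, None, 4.0, None, 6.0])
        out = biomarker_comparison(cohort, {"S1", "S2"}, "tmb")
        assert out["n_missing_dropped"] == 2
        assert out["n_positive"] == 2 and out["n_negative"] == 2


class TestMsi:
    @pytest.mark.parametrize(
        "msi_pos, expected",
        [(["MSI-H"] * 6 + ["MSS"] * 6, 50.0),
         (["MSS"] * 12, 0.0),
         (["MSI-H"] * 12, 100.0)],
    )
    def test_proportions_no_test(self, msi_pos, expected):
        cohort = cohort_frame(
            24, types=["colorectal"] * 24, msi=msi_pos + ["MSS"] * 12
        )
        flags = {f"S{i}" for i in range(1, 13)}
        out = msi_proportions(cohort, flags, ["colorectal"])
        assert out["positive"]["pct_msi_h"] == expected
        assert out["positive"]["n"] == 12
        assert "p_value" not in out


class TestCohortIO:
    def test_roundtrip_alterations(self, tmp_path):
        alts = (("TP53", "snv_indel", True), ("MDM2", "cnv_amp", False))
        df = cohort_frame(2)
        df.loc[0, "alterations"] = format_alterations(alts)
        df.loc[1, "alterations"] = ""
        path = tmp_path / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_cohort(path)
        assert back.loc[0, "alterations"] == alts
        assert back.loc[1, "alterations"] == ()

    def test_duplicate_specimens_rejected(self, tmp_path):
        df = cohort_frame(2)
        df["specimen_id"] = ["S1", "S1"]
        path = tmp_path / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path)
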