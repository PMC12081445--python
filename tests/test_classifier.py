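"""The oncogenicity decision procedure and frame-preservation logic."""

import numpy as np
import pytest

from trkfusion.classifier import (
    IN_FRAME,
    INDETERMINATE,
    LIKELY_ONCOGENIC,
    ONCOGENIC,
    OUT_OF_FRAME,
    VUS,
    classified_to_frame,
    classify_batch,
    classify_fusion,
    frame_preserved,
)
from trkfusion.fusion_ingest import FusionCall, annotate_fusion, write_fusion_calls
from trkfusion.knowledge_base import PartnerEvidence
from trkfusion.simulate import _FusionFactory
from trkfusion.transcript_model import BreakpointDescriptor as BP


def make(models, g5, bp5, g3, bp3, reads=12, specimen="S1"):
    return annotate_fusion(FusionCall(specimen, g5, g3, bp5, bp3, reads), models)


class TestWorkedExamples:
    def test_known_partner_intronic_fusion_is_oncogenic(self, models, kb):
        fusion = make(models, "LMNA", BP("", "intron", 3), "NTRK1", BP("", "intron", 11))
        result = classify_fusion(fusion, kb, models)
        assert result.verdict == ONCOGENIC
        assert ("partner_status", "known(canonical)") in result.reasons

    def test_canonical_gnaq_ntrk2_intron15(self, models, kb):
        fusion = make(models, "GNAQ", BP("", "intron", 1), "NTRK2", BP("", "intron", 15))
        assert classify_fusion(fusion, kb, models).verdict == ONCOGENIC

    def test_novel_in_frame_is_likely_oncogenic(self, models, kb):
        factory = _FusionFactory(np.random.default_rng(5), models, kb, 0.8)
        made = factory.qualifying("S1", want_known=False)
        assert made is not None
        call, truth = made
        fusion = annotate_fusion(call, models)
        result = classify_fusion(fusion, kb, models)
        assert result.verdict == LIKELY_ONCOGENIC
        assert ("frame_status", IN_FRAME) in result.reasons

    def test_ntrk_5prime_orientation_is_vus(self, models, kb):
        fusion = make(models, "NTRK2", BP("", "intron", 15), "LMNA", BP("", "intron", 3))
        result = classify_fusion(fusion, kb, models)
        assert result.verdict == VUS
        assert result.reasons[0] == ("orientation", "ntrk_role=5prime")

    def test_tkd_lost_is_vus_even_for_known_partner(self, models, kb):
        fusion = make(models, "LMNA", BP("", "intron", 3), "NTRK1", BP("", "intron", 14))
        result = classify_fusion(fusion, kb, models)
        assert result.verdict == VUS
        assert ("tkd_retained", "false") in result.reasons

    def test_known_partner_precedes_frame_test(self, models, kb):
        """A curated partner is ONCOGENIC even when the junction frame is
        indeterminate (promoter-swap style: no coding retained on 5' side)."""
        # LMNA exon 1 breakpoint inside the 5' UTR -> no retained CDS
        utr_offset = models["LMNA"].exon(1).coding_start_offset
        assert utr_offset > 0
        fusion = make(models, "LMNA", BP("", "exon", 1, utr_offset), "NTRK1",
                      BP("", "intron", 10))
        status = frame_preserved(fusion, models)
        assert status.value == INDETERMINATE
        assert classify_fusion(fusion, kb, models).verdict == ONCOGENIC

    def test_novel_indeterminate_is_vus(self, models, kb):
        noncoding_first = next(
            g for g, m in models.items()
            if m.exon(1).coding_length == 0 and g.startswith("NVP")
        )
        fusion = make(models, noncoding_first, BP("", "intron", 1), "NTRK1",
                      BP("", "intron", 10))
        assert frame_preserved(fusion, models).value == INDETERMINATE
        assert classify_fusion(fusion, kb, models).verdict == VUS


class TestFramePhases:
    def test_matched_zero_phases_in_frame(self, models):
        """A 5' segment whose CDS length is a codon multiple joined to a
        phase-0 3' exon is in frame."""
        lmna = models["LMNA"]
        ntrk1 = models["NTRK1"]
        # find an intron after which LMNA's retained CDS is a multiple of 3
        for i in range(1, lmna.n_exons):
            retained = sum(e.coding_length for e in lmna.exons[:i])
            if retained > 0 and retained % 3 == 0:
                break
        else:
            pytest.skip("no codon-aligned intron in this geometry")
        for j in range(1, ntrk1.n_exons):
            lost = sum(e.coding_length for e in ntrk1.exons[:j])
            if lost % 3 == 0:
                fusion = make(models, "LMNA", BP("", "intron", i), "NTRK1",
                              BP("", "intron", j))
                status = frame_preserved(fusion, models)
                assert (status.end_phase_5p, status.start_phase_3p) == (0, 0)
                assert status.value == IN_FRAME
                return
        pytest.skip("no phase-0 NTRK1 intron in this geometry")

    def test_phase_mismatch_out_of_frame(self, models):
        lmna, ntrk1 = models["LMNA"], models["NTRK1"]
        phases5 = {
            sum(e.coding_length for e in lmna.exons[:i]) % 3: i
            for i in range(1, lmna.n_exons)
            if sum(e.coding_length for e in lmna.exons[:i]) > 0
        }
        phases3 = {
            sum(e.coding_length for e in ntrk1.exons[:j]) % 3: j
            for j in range(1, 11)
        }
        for p5, i in phases5.items():
            for p3, j in phases3.items():
                if p5 != p3:
                    fusion = make(models, "LMNA", BP("", "intron", i), "NTRK1",
                                  BP("", "intron", j))
                    assert frame_preserved(fusion, models).value == OUT_OF_FRAME
                    return
        pytest.skip("geometry offers no mismatched pair")

    def test_agrees_with_translate_and_scan_oracle(self, models, kb, frame_oracle):
        """Phase arithmetic must agree with sequence-level translation on
        hundreds of generated junctions, including exonic mid-codon joins."""
        rng = np.random.default_rng(123)
        factory = _FusionFactory(rng, models, kb, frac_intronic=0.6)
        n_checked = 0
        disagreements = []
        while n_checked < 500:
            kind = ["known", "novel", "oof"][int(rng.integers(3))]
            if kind == "oof":
                made = factory.decoy("S", "out_of_frame")
            else:
                made = factory.qualifying("S", want_known=(kind == "known"))
            if made is None:
                continue
            call, truth = made
            fusion = annotate_fusion(call, models)
            got = frame_preserved(fusion, models).value
            want = frame_oracle.frame_of(
                fusion.gene_5p, fusion.breakpoint_5p,
                fusion.gene_3p, fusion.breakpoint_3p,
            )
            if got != want:
                disagreements.append((call.name, got, want))
            n_checked += 1
        assert not disagreements, disagreements[:10]


class TestDecisionProperties:
    def _random_fusions(self, models, kb, n, seed):
        rng = np.random.default_rng(seed)
        factory = _FusionFactory(rng, models, kb, 0.7)
        out = []
        while len(out) < n:
            roll = rng.random()
            if roll < 0.5:
                made = factory.qualifying("S", want_known=roll < 0.2)
            else:
                kind = ["out_of_frame", "ntrk_5prime", "tkd_lost"][int(rng.integers(3))]
                made = factory.decoy("S", kind)
            if made is not None:
                out.append(annotate_fusion(made[0], models))
        return out

    def test_verdict_partition(self, models, kb):
        fusions = self._random_fusions(models, kb, 120, seed=9)
        verdicts = [classify_fusion(f, kb, models).verdict for f in fusions]
        assert all(v in (ONCOGENIC, LIKELY_ONCOGENIC, VUS) for v in verdicts)
        assert len(verdicts) == 120

    def test_kb_upgrade_never_demotes(self, models, kb):
        """Adding a partner pair to the registry can only move verdicts
        upward (LIKELY->ONCOGENIC or VUS->{VUS, ONCOGENIC})."""
        rank = {VUS: 0, LIKELY_ONCOGENIC: 1, ONCOGENIC: 2}
        fusions = self._random_fusions(models, kb, 120, seed=10)
        for fusion in fusions:
            before = classify_fusion(fusion, kb, models).verdict
            upgraded = kb.with_entry(
                PartnerEvidence(fusion.gene_5p, fusion.gene_3p
                                if fusion.ntrk_role == "3prime" else "NTRK1",
                                "clinical_validity")
            )
            after = classify_fusion(fusion, upgraded, models).verdict
            assert rank[after] >= rank[before]
            assert before != LIKELY_ONCOGENIC or after == ONCOGENIC

    def test_classification_is_idempotent(self, models, kb):
        for fusion in self._random_fusions(models, kb, 40, seed=11):
            once = classify_fusion(fusion, kb, models)
            twice = classify_fusion(once.fusion, kb, models)
            assert twice.verdict == once.verdict
            assert twice.reasons == once.reasons


class TestBatch:
    def test_pipeline_counts_reconcile(self, tmp_path, models, kb):
        calls = [
            FusionCall("S2", "LMNA", "NTRK1", "intron3", "intron11", 12),
            FusionCall("S1", "ETV6", "NTRK3", "intron4", "intron14", 7),
            FusionCall("S3", "TPM3", "NTRK1", "intron2", "intron9", 4),  # filtered
        ]
        # go through the canonical TSV to exercise the full pipeline
        path = tmp_path / "calls.tsv"
        write_fusion_calls(
            [
                FusionCall(c.specimen_id, c.gene_5p, c.gene_3p,
                           c.breakpoint_5p, c.breakpoint_3p, c.unique_reads)
                for c in calls
            ],
            path,
        )
        classified, qc = classify_batch(path, models, kb, min_reads=5)
        assert qc["n_parsed"] == 3
        assert qc["n_filtered_low_reads"] == 1
        assert qc["n_classified"] == 2
        assert (
            qc["n_parsed"]
            == qc["n_classified"] + qc["n_filtered_low_reads"] + qc["n_annotation_failed"]
        )
        # deterministic ordering: by specimen, then input order
        assert [c.fusion.specimen_id for c in classified] == ["S1", "S2"]
        assert "S3" not in set(classified_to_frame(classified)["specimen_id"])

    def test_empty_input(self, tmp_path, models, kb):
        path = tmp_path / "empty.tsv"
        write_fusion_calls([], path)
        classified, qc = classify_batch(path, models, kb)
        assert classified == []
        assert qc["n_parsed"] == 0 and qc["n_classified"] == 0

    def test_annotation_failure_counted_not_fatal(self, models, kb):
        calls = [
            FusionCall("S1", "LMNA", "NTRK1", "intron3", "intron11", 9),
            FusionCall("S2", "LMNA", "NTRK1", "chr1:1", "intron11", 9),  # off-gene
        ]
        classified, qc = classify_batch(calls, models, kb)
        assert qc["n_annotation_failed"] == 1
        assert qc["n_classified"] == 1
        assert len(qc["annotation_errors"]) == 1
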