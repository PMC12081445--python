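"""Rule-based oncogenicity classification of NTRK fusions.

A detected fusion is classified by a fixed decision procedure derived from
the ClinGen-style somatic curation rules for TRK fusions:

1. the NTRK gene must be the 3' component of the fusion, else VUS;
2. the 3' segment must retain the tyrosine-kinase domain, else VUS;
3. if the 5' partner is a known partner of that NTRK gene -> ONCOGENIC;
4. else, if the junction preserves the reading frame -> LIKELY_ONCOGENIC;
5. else -> VUS (variant of unknown significance).

The known-partner test deliberately precedes the frame test: a curated
partner yields ONCOGENIC even when the frame is indeterminate (promoter
swap style breakpoints in 5' UTR/intron 1), because the frame condition
applies only to novel partners.  Frame preservation is decided by exon
phase arithmetic (see :mod:`trkfusion.transcript_model`): the cumulative
coding length retained on the 5' side mod 3 must equal the phase at which
the 3' segment resumes.

Every verdict carries an ordered, machine-readable evidence trail and the
knowledge-base version, so classifications are auditable and reproducible
as curation evolves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .fusion_ingest import (
    DEFAULT_MIN_READS,
    AnnotatedFusion,
    FusionCall,
    IngestQC,
    annotate_batch,
    filter_read_support,
    read_fusion_calls,
)
from .knowledge_base import KnowledgeBase, is_known, partner_status
from .transcript_model import (
    NON_CODING,
    BreakpointDescriptor,
    TranscriptModel,
    cumulative_cds_before,
    exon_phase,
    tkd_retained,
)

ONCOGENIC = "ONCOGENIC"
LIKELY_ONCOGENIC = "LIKELY_ONCOGENIC"
VUS = "VUS"
VERDICTS = (ONCOGENIC, LIKELY_ONCOGENIC, VUS)

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FrameStatus:
    """Reading-frame verdict for a fusion junction.

    ``end_phase_5p`` is the cumulative retained 5' coding length mod 3;
    ``start_phase_3p`` is the phase at which the 3' gene's CDS resumes.
    ``None`` marks an undefined phase (no coding sequence on that side).
    The junction is in frame iff both phases are defined and equal.
    """

    value: str
    end_phase_5p: Optional[int]
    start_phase_3p: Optional[int]


@dataclass(frozen=True)
class ClassifiedFusion:
    fusion: AnnotatedFusion
    verdict: str
    reasons: tuple[tuple[str, str], ...]
    kb_version: str

    @property
    def name(self) -> str:
        return self.fusion.name


def _retained_cds_5p(transcript: TranscriptModel, bp: BreakpointDescriptor) -> int:
    """Coding length retained upstream of (and including) the breakpoint."""
    if bp.kind == "intron":
        return sum(e.coding_length for e in transcript.exons[: bp.ordinal])
    exon = transcript.exon(bp.ordinal)
    upstream = cumulative_cds_before(transcript, bp.ordinal)
    # retained bases of the broken exon: 1..offset (0-based half-open [0, offset))
    within = max(
        0, min(exon.coding_end_offset, bp.exon_offset) - exon.coding_start_offset
    )
    return upstream + within


def _lost_cds_3p(transcript: TranscriptModel, bp: BreakpointDescriptor) -> int:
    """Coding length lost upstream of the breakpoint on the 3' side."""
    if bp.kind == "intron":
        return sum(e.coding_length for e in transcript.exons[: bp.ordinal])
    exon = transcript.exon(bp.ordinal)
    upstream = cumulative_cds_before(transcript, bp.ordinal)
    # the 3' segment retains bases offset..length; bases [0, offset) of the
    # exon minus the retained base itself are lost: lost = [0, offset-1)
    within = max(
        0, min(exon.coding_end_offset, bp.exon_offset - 1) - exon.coding_start_offset
    )
    return upstream + within


def frame_preserved(
    fusion: AnnotatedFusion, transcripts: Mapping[str, TranscriptModel]
) -> FrameStatus:
    """Exon-phase test of reading-frame preservation across the junction.

    Intronic breakpoints use whole-exon phase arithmetic; exonic breakpoints
    are scored at the exact coding offset (mid-codon joins included).  The
    status is ``indeterminate`` when the retained 5' portion contains no
    coding sequence or the 3' phase is undefined.
    """
    t5 = transcripts[fusion.gene_5p]
    t3 = transcripts[fusion.gene_3p]
    retained_5p = _retained_cds_5p(t5, fusion.breakpoint_5p)
    end_phase: Optional[int] = retained_5p % 3 if retained_5p > 0 else None

    bp3 = fusion.breakpoint_3p
    if bp3.kind == "intron":
        phase = exon_phase(t3, bp3.ordinal + 1)
        start_phase: Optional[int] = None if phase == NON_CODING else int(phase)
    else:
        exon = t3.exon(bp3.ordinal)
        if exon.coding_length == 0 and cumulative_cds_before(t3, bp3.ordinal) == 0:
            start_phase = None
        else:
            start_phase = _lost_cds_3p(t3, bp3) % 3

    if end_phase is None or start_phase is None:
        value = INDETERMINATE
    elif end_phase == start_phase:
        value = IN_FRAME
    else:
        value = OUT_OF_FRAME
    return FrameStatus(value, end_phase, start_phase)


def classify_fusion(
    fusion: AnnotatedFusion,
    kb: KnowledgeBase,
    transcripts: Mapping[str, TranscriptModel],
) -> ClassifiedFusion:
    """Apply the five-step decision procedure to one annotated fusion."""
    reasons: list[tuple[str, str]] = []

    if fusion.ntrk_role != "3prime":
        reasons.append(("orientation", f"ntrk_role={fusion.ntrk_role}"))
        return ClassifiedFusion(fusion, VUS, tuple(reasons), kb.version)
    reasons.append(("orientation", "ntrk_3prime"))

    ntrk = fusion.ntrk_gene
    assert ntrk is not None
    retained = tkd_retained(
        transcripts[ntrk], fusion.breakpoint_3p, "3prime", kb.tkd_regions
    )
    reasons.append(("tkd_retained", str(retained).lower()))
    if not retained:
        return ClassifiedFusion(fusion, VUS, tuple(reasons), kb.version)

    status = partner_status(kb, fusion.gene_5p, ntrk)
    reasons.append(("partner_status", status))
    if is_known(status):
        return ClassifiedFusion(fusion, ONCOGENIC, tuple(reasons), kb.version)

    frame = frame_preserved(fusion, transcripts)
    reasons.append(("frame_status", frame.value))
    if frame.value == IN_FRAME:
        return ClassifiedFusion(fusion, LIKELY_ONCOGENIC, tuple(reasons), kb.version)
    return ClassifiedFusion(fusion, VUS, tuple(reasons), kb.version)


def classify_batch(
    calls: Union[str, Path, Sequence[FusionCall]],
    transcripts: Mapping[str, TranscriptModel],
    kb: KnowledgeBase,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[list[ClassifiedFusion], dict]:
    """Full pipeline: read -> read-support filter -> annotate -> classify.

    Returns the classified fusions (ordered by specimen, then input row
    order) and a QC report whose totals reconcile:
    ``n_parsed == n_classified + n_filtered_low_reads + n_annotation_failed``.
    """
    if isinstance(calls, (str, Path)):
        calls = read_fusion_calls(calls)
    qc = IngestQC(n_parsed=len(calls))
    kept, removed = filter_read_support(calls, min_reads)
    qc.n_filtered_low_reads = len(removed)
    annotated, qc = annotate_batch(kept, transcripts, qc)
    indexed = sorted(
        enumerate(annotated), key=lambda pair: (pair[1].specimen_id, pair[0])
    )
    classified = [classify_fusion(f, kb, transcripts) for _, f in indexed]
    report = qc.as_dict()
    report["n_classified"] = len(classified)
    report["kb_version"] = kb.version
    report["min_reads"] = min_reads
    report["verdict_counts"] = {
        v: sum(1 for c in classified if c.verdict == v) for v in VERDICTS
    }
    return classified, report


def classified_to_frame(classified: Sequence[ClassifiedFusion]) -> pd.DataFrame:
    """Tabular view of classifications (one row per fusion)."""
    rows = []
    for c in classified:
        rows.append(
            {
                "specimen_id": c.fusion.specimen_id,
                "fusion_name": c.name,
                "gene_5p": c.fusion.gene_5p,
                "gene_3p": c.fusion.gene_3p,
                "ntrk_gene": c.fusion.ntrk_gene or "",
                "verdict": c.verdict,
                "reasons": ";".join(f"{k}={v}" for k, v in c.reasons),
                "kb_version": c.kb_version,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "fusion_name",
            "gene_5p",
            "gene_3p",
            "ntrk_gene",
            "verdict",
            "reasons",
            "kb_version",
        ],
    )
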