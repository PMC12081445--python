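"""Reading candidate fusion calls and annotating their breakpoints.

Candidate fusions arrive as a tab-separated table (one row per call,
annotated as [5' gene]-[3' gene]) or, from structural-variant callers, as
VCF breakend (BND) records.  This module parses them, applies the unique
supporting-read filter (default >= 5 reads per fusion event), and resolves
both breakpoints against transcript models.  Parsing and filtering are
deliberately separate steps: sub-threshold rows are parsed, retained, and
only dropped by :func:`filter_read_support` so QC totals reconcile.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .transcript_model import (
    NTRK_GENES,
    BreakpointDescriptor,
    TranscriptError,
    TranscriptModel,
    locate_breakpoint,
)

FUSION_TSV_COLUMNS = (
    "specimen_id",
    "gene_5p",
    "bp_5p",
    "gene_3p",
    "bp_3p",
    "unique_reads",
)

DEFAULT_MIN_READS = 5

_BP_PATTERNS = (
    re.compile(r"^(?P<chrom>chr[\w.]+):(?P<pos>\d+)$"),
    re.compile(r"^intron(?P<intron>\d+)$"),
    re.compile(r"^exon(?P<exon>\d+)(?:\+(?P<offset>\d+))?$"),
)


class FusionParseError(ValueError):
    """Malformed fusion table or breakpoint string."""


@dataclass(frozen=True)
class FusionCall:
    """A candidate fusion before breakpoint annotation.

    Breakpoints may be raw genomic positions (``"chrN:pos"``) or already
    transcript-relative (``"intronK"`` / ``"exonK+offset"``); both are kept
    verbatim until :func:`annotate_fusion` resolves them.
    """

    specimen_id: str
    gene_5p: str
    gene_3p: str
    breakpoint_5p: Union[str, BreakpointDescriptor]
    breakpoint_3p: Union[str, BreakpointDescriptor]
    unique_reads: int
    caller_tag: str = ""

    def __post_init__(self) -> None:
        if not self.gene_5p or not self.gene_3p:
            raise FusionParseError("fusion call requires both gene symbols")
        if self.unique_reads < 0:
            raise FusionParseError("unique_reads must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.gene_5p}-{self.gene_3p}"


@dataclass(frozen=True)
class AnnotatedFusion:
    """A fusion call with both breakpoints resolved to descriptors."""

    specimen_id: str
    gene_5p: str
    gene_3p: str
    breakpoint_5p: BreakpointDescriptor
    breakpoint_3p: BreakpointDescriptor
    unique_reads: int
    caller_tag: str = ""
    ntrk_role: str = "none"  # none | 5prime | 3prime
    ntrk_gene: Optional[str] = None

    @property
    def name(self) -> str:
        return f"{self.gene_5p}-{self.gene_3p}"


@dataclass
class IngestQC:
    """Bookkeeping for one ingestion run; totals must reconcile."""

    n_parsed: int = 0
    n_filtered_low_reads: int = 0
    n_annotation_failed: int = 0
    annotation_errors: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_parsed": self.n_parsed,
            "n_filtered_low_reads": self.n_filtered_low_reads,
            "n_annotation_failed": self.n_annotation_failed,
            "annotation_errors": list(self.annotation_errors),
        }


def parse_breakpoint_string(text: str) -> Union[str, BreakpointDescriptor]:
    """Parse a breakpoint cell: genomic strings pass through for later
    resolution, transcript-relative strings become descriptors (the gene is
    attached by the caller)."""
    text = text.strip()
    for pattern in _BP_PATTERNS:
        m = pattern.match(text)
        if not m:
            continue
        groups = m.groupdict()
        if "pos" in groups:
            return text  # genomic; resolved against the transcript later
        if "intron" in groups and groups.get("intron"):
            return BreakpointDescriptor("", "intron", int(groups["intron"]))
        return BreakpointDescriptor(
            "", "exon", int(groups["exon"]), int(groups.get("offset") or 1)
        )
    raise FusionParseError(f"unparseable breakpoint string: {text!r}")


def read_fusion_calls(path: Union[str, Path]) -> list[FusionCall]:
    """Read the canonical fusion TSV; row order is preserved.

    Raises :class:`FusionParseError` on a missing column immediately; row
    level problems are collected and reported together with line numbers.
    """
    calls: list[FusionCall] = []
    errors: list[str] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(FUSION_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FusionParseError(
                f"{path}: missing required columns: {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                calls.append(
                    FusionCall(
                        specimen_id=row["specimen_id"].strip(),
                        gene_5p=row["gene_5p"].strip(),
                        gene_3p=row["gene_3p"].strip(),
                        breakpoint_5p=parse_breakpoint_string(row["bp_5p"]),
                        breakpoint_3p=parse_breakpoint_string(row["bp_3p"]),
                        unique_reads=int(row["unique_reads"]),
                        caller_tag=(row.get("caller_tag") or "").strip(),
                    )
                )
            except (FusionParseError, ValueError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    if errors:
        raise FusionParseError("; ".join(errors))
    return calls


def write_fusion_calls(calls: Sequence[FusionCall], path: Union[str, Path]) -> None:
    """Inverse of :func:`read_fusion_calls` for well-formed records."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(FUSION_TSV_COLUMNS + ("caller_tag",))
        for call in calls:
            writer.writerow(
                [
                    call.specimen_id,
                    call.gene_5p,
                    _format_breakpoint(call.breakpoint_5p),
                    call.gene_3p,
                    _format_breakpoint(call.breakpoint_3p),
                    call.unique_reads,
                    call.caller_tag,
                ]
            )


def _format_breakpoint(bp: Union[str, BreakpointDescriptor]) -> str:
    if isinstance(bp, str):
        return bp
    if bp.kind == "intron":
        return f"intron{bp.ordinal}"
    return f"exon{bp.ordinal}+{bp.exon_offset}"


def filter_read_support(
    calls: Sequence[FusionCall], min_reads: int = DEFAULT_MIN_READS
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Partition calls into (kept, removed) by unique supporting reads.

    A call is kept iff ``unique_reads >= min_reads``; both lists preserve
    input order and together partition the input exactly.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    kept = [c for c in calls if c.unique_reads >= min_reads]
    removed = [c for c in calls if c.unique_reads < min_reads]
    return kept, removed


def annotate_fusion(
    call: FusionCall, transcripts: Mapping[str, TranscriptModel]
) -> AnnotatedFusion:
    """Resolve both breakpoints and assign the NTRK role.

    A fusion with NTRK on both sides is treated as 3'-NTRK (the
    classification rules key off the 3' component; the 5' NTRK acts as an
    ordinary partner gene).
    """
    missing = [g for g in (call.gene_5p, call.gene_3p) if g not in transcripts]
    if missing:
        raise TranscriptError(f"gene(s) not in transcript models: {missing}")
    bp5 = _resolve(call.breakpoint_5p, transcripts[call.gene_5p])
    bp3 = _resolve(call.breakpoint_3p, transcripts[call.gene_3p])
    if call.gene_3p in NTRK_GENES:
        role, gene = "3prime", call.gene_3p
    elif call.gene_5p in NTRK_GENES:
        role, gene = "5prime", call.gene_5p
    else:
        role, gene = "none", None
    return AnnotatedFusion(
        specimen_id=call.specimen_id,
        gene_5p=call.gene_5p,
        gene_3p=call.gene_3p,
        breakpoint_5p=bp5,
        breakpoint_3p=bp3,
        unique_reads=call.unique_reads,
        caller_tag=call.caller_tag,
        ntrk_role=role,
        ntrk_gene=gene,
    )


def _resolve(
    bp: Union[str, BreakpointDescriptor], transcript: TranscriptModel
) -> BreakpointDescriptor:
    if isinstance(bp, str) and ":" not in bp:
        bp = parse_breakpoint_string(bp)
    if isinstance(bp, BreakpointDescriptor):
        descr = replace(bp, gene_symbol=transcript.gene_symbol)
        if descr.kind == "intron" and not descr.ordinal <= transcript.n_exons - 1:
            raise TranscriptError(
                f"{transcript.gene_symbol}: no intron {descr.ordinal}"
            )
        if descr.kind == "exon":
            exon = transcript.exon(descr.ordinal)
            if not 1 <= descr.exon_offset <= exon.length:
                raise TranscriptError(
                    f"{transcript.gene_symbol}: offset {descr.exon_offset} "
                    f"outside exon {descr.ordinal}"
                )
        return descr
    chrom, pos = bp.split(":")
    if chrom != transcript.chromosome:
        raise TranscriptError(
            f"breakpoint {bp} on wrong chromosome for {transcript.gene_symbol} "
            f"({transcript.chromosome})"
        )
    return locate_breakpoint(transcript, int(pos))


def annotate_batch(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
    qc: Optional[IngestQC] = None,
) -> tuple[list[AnnotatedFusion], IngestQC]:
    """Annotate calls; records failing annotation are excluded and counted."""
    qc = qc or IngestQC()
    out: list[AnnotatedFusion] = []
    for call in calls:
        try:
            out.append(annotate_fusion(call, transcripts))
        except TranscriptError as exc:
            qc.n_annotation_failed += 1
            qc.annotation_errors.append(f"{call.specimen_id} {call.name}: {exc}")
    return out, qc


# ---------------------------------------------------------------------------
# VCF breakend adapter
# ---------------------------------------------------------------------------

_BND_ALT = re.compile(r"[\[\]](?P<chrom>[\w.]+):(?P<pos>\d+)[\[\]]")


def read_fusion_vcf(path: Union[str, Path]) -> tuple[list[FusionCall], list[str]]:
    """Thin adapter mapping paired BND records to one FusionCall each.

    Requires ``SVTYPE=BND`` records with ``MATEID``; the 5'/3' genes are
    taken from a ``GENE`` INFO key and supporting reads from ``SR``.  The
    record whose gene is not an NTRK gene is taken as the 5' side; unpaired
    BNDs are returned as QC flags, not errors.  The TSV remains the
    canonical internal format — this exists because real-world calls arrive
    as VCF.
    """
    import pysam

    records: dict[str, dict] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "BND":
                continue
            mate = rec.info.get("MATEID")
            if isinstance(mate, tuple):
                mate = mate[0]
            records[rec.id] = {
                "id": rec.id,
                "mate": mate,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "gene": rec.info.get("GENE"),
                "sr": int(rec.info.get("SR", 0)),
                "specimen": rec.info.get("SPECIMEN", ""),
            }

    calls: list[FusionCall] = []
    flags: list[str] = []
    seen: set[str] = set()
    for rid, rec in records.items():
        if rid in seen:
            continue
        mate = records.get(rec["mate"] or "")
        if mate is None:
            flags.append(f"unpaired BND record: {rid}")
            continue
        seen.update({rid, mate["id"]})
        # orient: NTRK side is 3' when present, else keep file order
        first, second = rec, mate
        if first["gene"] in NTRK_GENES and second["gene"] not in NTRK_GENES:
            first, second = second, first
        calls.append(
            FusionCall(
                specimen_id=first["specimen"] or second["specimen"],
                gene_5p=first["gene"],
                gene_3p=second["gene"],
                breakpoint_5p=f"{_chr(first['chrom'])}:{first['pos']}",
                breakpoint_3p=f"{_chr(second['chrom'])}:{second['pos']}",
                unique_reads=max(first["sr"], second["sr"]),
                caller_tag="vcf-bnd",
            )
        )
    return calls, flags


def _chr(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else f"chr{chrom}"
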