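"""Transcript models and breakpoint coordinate primitives.

Everything downstream of fusion calling — locating breakpoints, deciding
whether the tyrosine-kinase domain (TKD) survives in the 3' segment, and
testing reading-frame preservation at the junction — reduces to interval
arithmetic over exon structures.  This module provides that substrate:

* :class:`Exon` / :class:`TranscriptModel` — one canonical transcript per
  gene, exons numbered in transcription order (exon 1 = 5'-most in mRNA),
  with the coding portion of each exon tracked explicitly.
* :func:`exon_phase` — cumulative coding length upstream of an exon mod 3,
  the quantity whose equality across a fusion junction implies the
  downstream reading frame is preserved.
* :func:`locate_breakpoint` — strand-aware mapping of a genomic position to
  an intron ordinal or an exon ordinal plus offset.
* :func:`tkd_retained` — does the 3' NTRK segment keep the kinase domain?

Coordinates are 1-based, fully closed intervals throughout, matching GTF
convention.  No genome sequence is touched here; frame logic is pure
interval arithmetic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Union

logger = logging.getLogger(__name__)

NTRK_GENES = ("NTRK1", "NTRK2", "NTRK3")

#: Exons encoding the TRK tyrosine-kinase domain, per gene (annotation).
TKD_EXONS: dict[str, tuple[int, int]] = {
    "NTRK1": (9, 17),
    "NTRK2": (16, 20),
    "NTRK3": (15, 19),
}

#: Breakpoint-compatible kinase region used by the retention test: a 3'
#: breakpoint strictly upstream of ``first_exon`` keeps a functional kinase
#: fold.  This is deliberately a data table, not a rule derived from
#: TKD_EXONS: curated fusion diagrams show NTRK1 fusions with intron-11
#: breakpoints acting as oncogenic drivers even though the annotated domain
#: begins at exon 9, so the operational region for NTRK1 starts at exon 12.
#: Override via the ``tkd_regions`` argument of :func:`tkd_retained` (the
#: knowledge-base loader can carry a replacement table).
DEFAULT_TKD_RETENTION: dict[str, tuple[int, int]] = {
    "NTRK1": (12, 17),
    "NTRK2": (16, 20),
    "NTRK3": (15, 19),
}

NON_CODING = "non-coding"


class TranscriptError(ValueError):
    """Invalid transcript structure or out-of-range query."""


@dataclass(frozen=True)
class TkdRange:
    """Exon span encoding the tyrosine-kinase domain of one NTRK gene."""

    ntrk_gene: str
    first_exon: int
    last_exon: int

    def __post_init__(self) -> None:
        if self.ntrk_gene not in NTRK_GENES:
            raise TranscriptError(f"not an NTRK gene: {self.ntrk_gene}")
        if not 1 <= self.first_exon <= self.last_exon:
            raise TranscriptError("invalid TKD exon range")


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript.

    ``coding_start_offset``/``coding_end_offset`` delimit the CDS portion of
    the exon as a 0-based half-open interval in transcript orientation
    (offset 0 = the exon's 5'-most base in the mRNA).  An empty interval
    (start == end) marks a fully untranslated exon.
    """

    number: int
    genomic_start: int
    genomic_end: int
    coding_start_offset: int = 0
    coding_end_offset: int = 0

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise TranscriptError(
                f"exon {self.number}: genomic_start > genomic_end"
            )
        if not 0 <= self.coding_start_offset <= self.coding_end_offset <= self.length:
            raise TranscriptError(
                f"exon {self.number}: coding interval outside exon"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    @property
    def coding_length(self) -> int:
        return self.coding_end_offset - self.coding_start_offset


@dataclass(frozen=True)
class BreakpointDescriptor:
    """A breakpoint expressed in transcript coordinates.

    ``kind='intron'``, ordinal i: the break lies between exon i and exon
    i+1.  ``kind='exon'``, ordinal j with ``exon_offset`` k (1-based, in
    transcript orientation): the break falls at base k of exon j — a 5'
    segment retains bases 1..k of that exon, a 3' segment retains bases
    k..length.
    """

    gene_symbol: str
    kind: Literal["intron", "exon"]
    ordinal: int
    exon_offset: int = 0
    genomic_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("intron", "exon"):
            raise TranscriptError(f"bad breakpoint kind: {self.kind}")
        if self.ordinal < 1:
            raise TranscriptError("breakpoint ordinal must be >= 1")
        if self.kind == "intron" and self.exon_offset != 0:
            raise TranscriptError("intron breakpoints carry no exon offset")


@dataclass
class TranscriptModel:
    """Canonical transcript for one gene: ordered exons plus domain spans."""

    gene_symbol: str
    chromosome: str
    strand: Literal["+", "-"]
    exons: list[Exon]
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"{self.gene_symbol}: bad strand {self.strand!r}")
        if not self.exons:
            raise TranscriptError(f"{self.gene_symbol}: transcript has no exons")
        numbers = [e.number for e in self.exons]
        if numbers != list(range(1, len(self.exons) + 1)):
            raise TranscriptError(
                f"{self.gene_symbol}: exon numbers must be 1..n consecutive"
            )
        # transcription order: genomic order on +, reverse-genomic on -
        starts = [e.genomic_start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise TranscriptError(
                f"{self.gene_symbol}: exons not in transcription order"
            )
        spans = sorted((e.genomic_start, e.genomic_end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise TranscriptError(f"{self.gene_symbol}: overlapping exons")
        for name, first, last in self.domains:
            if not 1 <= first <= last <= len(self.exons):
                raise TranscriptError(
                    f"{self.gene_symbol}: domain {name} exon range out of bounds"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (
            min(e.genomic_start for e in self.exons),
            max(e.genomic_end for e in self.exons),
        )

    @property
    def cds_length(self) -> int:
        return sum(e.coding_length for e in self.exons)

    def exon(self, number: int) -> Exon:
        if not 1 <= number <= self.n_exons:
            raise TranscriptError(
                f"{self.gene_symbol}: no exon {number} (transcript has {self.n_exons})"
            )
        return self.exons[number - 1]

    def domain_range(self, name: str) -> Optional[tuple[int, int]]:
        for dname, first, last in self.domains:
            if dname == name:
                return (first, last)
        return None


# ---------------------------------------------------------------------------
# phase / breakpoint / domain primitives
# ---------------------------------------------------------------------------


def cumulative_cds_before(transcript: TranscriptModel, exon_number: int) -> int:
    """Total coding length of exons strictly upstream of ``exon_number``."""
    transcript.exon(exon_number)
    return sum(e.coding_length for e in transcript.exons[: exon_number - 1])


def exon_phase(transcript: TranscriptModel, exon_number: int) -> Union[int, str]:
    """Reading-frame phase of an exon: upstream coding length mod 3.

    Returns ``"non-coding"`` when the exon carries no CDS and no upstream
    exon does either (the phase is undefined, not zero).  Equal phases on
    the two sides of a fusion junction imply the downstream frame is
    preserved.
    """
    upstream = cumulative_cds_before(transcript, exon_number)
    if transcript.exon(exon_number).coding_length == 0 and upstream == 0:
        return NON_CODING
    return upstream % 3


def locate_breakpoint(
    transcript: TranscriptModel, genomic_position: int, flank: int = 0
) -> BreakpointDescriptor:
    """Map a genomic position to an intron or exon breakpoint descriptor.

    Strand-aware: intron i always means "between exon i and exon i+1 in
    transcript order", whatever the genomic layout.  Positions outside the
    transcript span (± ``flank``) raise :class:`TranscriptError`; with a
    positive flank, near-terminal positions snap to the first/last base of
    the terminal exon.
    """
    lo, hi = transcript.genomic_span
    if not lo - flank <= genomic_position <= hi + flank:
        raise TranscriptError(
            f"position {genomic_position} outside {transcript.gene_symbol} "
            f"span {lo}-{hi} (flank={flank})"
        )
    pos = min(max(genomic_position, lo), hi)
    for exon in transcript.exons:
        if exon.genomic_start <= pos <= exon.genomic_end:
            if transcript.strand == "+":
                offset = pos - exon.genomic_start + 1
            else:
                offset = exon.genomic_end - pos + 1
            return BreakpointDescriptor(
                transcript.gene_symbol, "exon", exon.number, offset, genomic_position
            )
    # between two adjacent exons in transcript order
    for i in range(transcript.n_exons - 1):
        a, b = transcript.exons[i], transcript.exons[i + 1]
        gap_lo = min(a.genomic_end, b.genomic_end) + 1
        gap_hi = max(a.genomic_start, b.genomic_start) - 1
        if gap_lo <= pos <= gap_hi:
            return BreakpointDescriptor(
                transcript.gene_symbol, "intron", a.number, 0, genomic_position
            )
    raise TranscriptError(  # pragma: no cover - spans are gap-free by construction
        f"position {genomic_position} unmapped in {transcript.gene_symbol}"
    )


def breakpoint_to_genomic(
    transcript: TranscriptModel, breakpoint: BreakpointDescriptor
) -> int:
    """Inverse of :func:`locate_breakpoint` (intron breakpoints map to the
    first intronic base in transcript orientation)."""
    if breakpoint.kind == "exon":
        exon = transcript.exon(breakpoint.ordinal)
        if not 1 <= breakpoint.exon_offset <= exon.length:
            raise TranscriptError(
                f"offset {breakpoint.exon_offset} outside exon {exon.number}"
            )
        if transcript.strand == "+":
            return exon.genomic_start + breakpoint.exon_offset - 1
        return exon.genomic_end - breakpoint.exon_offset + 1
    if not 1 <= breakpoint.ordinal <= transcript.n_exons - 1:
        raise TranscriptError(
            f"{transcript.gene_symbol}: no intron {breakpoint.ordinal}"
        )
    exon = transcript.exon(breakpoint.ordinal)
    return exon.genomic_end + 1 if transcript.strand == "+" else exon.genomic_start - 1


def tkd_retained(
    transcript: TranscriptModel,
    breakpoint: BreakpointDescriptor,
    role: str = "3prime",
    tkd_regions: Optional[Mapping[str, tuple[int, int]]] = None,
) -> bool:
    """Does the 3' segment downstream of ``breakpoint`` retain the kinase domain?

    The test is driven by a per-gene breakpoint-compatible region table
    (default :data:`DEFAULT_TKD_RETENTION`): retention holds iff every exon
    of the region lies fully downstream of the breakpoint, i.e. an intron
    breakpoint with ordinal < first region exon, or an exon breakpoint
    strictly upstream of the region's first exon.  An exonic breakpoint
    inside the region counts as not retained — partial domain loss is never
    assumed functional.
    """
    if role != "3prime":
        raise TranscriptError("TKD retention is defined for the 3' fusion segment")
    regions = tkd_regions if tkd_regions is not None else DEFAULT_TKD_RETENTION
    gene = transcript.gene_symbol
    if gene not in regions:
        raise TranscriptError(f"{gene} has no kinase-domain region; not an NTRK gene?")
    first_exon = regions[gene][0]
    return breakpoint.ordinal < first_exon


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "gene",
    "chrom",
    "strand",
    "exon_number",
    "start",
    "end",
    "cds_start",
    "cds_end",
    "domain",
)


def load_transcripts(path: Union[str, Path]) -> dict[str, TranscriptModel]:
    """Load one canonical transcript per gene from GTF or simplified exon TSV.

    The two readers produce identical :class:`TranscriptModel` content for
    equivalent input.  When a GTF holds several transcripts of a gene the
    one with the longest CDS wins (logged).  NTRK genes are always annotated
    with their TKD exon span when the input does not provide one.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        models = _load_gtf(path)
    else:
        models = _load_exon_tsv(path)
    for gene, model in models.items():
        if gene in TKD_EXONS and model.domain_range("TKD") is None:
            first, last = TKD_EXONS[gene]
            if last <= model.n_exons:
                model.domains.append(("TKD", first, last))
                model.validate()
    return models


def _load_exon_tsv(path: Path) -> dict[str, TranscriptModel]:
    rows_by_gene: dict[str, list[dict]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(TSV_COLUMNS[:-1]) - set(reader.fieldnames or ())
        if missing:
            raise TranscriptError(
                f"{path}: missing required columns: {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                parsed = {
                    "gene": row["gene"],
                    "chrom": row["chrom"],
                    "strand": row["strand"],
                    "exon_number": int(row["exon_number"]),
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "cds_start": _opt_int(row["cds_start"]),
                    "cds_end": _opt_int(row["cds_end"]),
                    "domain": (row.get("domain") or "").strip(),
                }
            except (KeyError, ValueError) as exc:
                raise TranscriptError(f"{path}:{lineno}: malformed record ({exc})")
            rows_by_gene.setdefault(parsed["gene"], []).append(parsed)

    models: dict[str, TranscriptModel] = {}
    for gene, rows in rows_by_gene.items():
        rows.sort(key=lambda r: r["exon_number"])
        strand = rows[0]["strand"]
        exons = [
            _exon_from_genomic(
                r["exon_number"], r["start"], r["end"], r["cds_start"], r["cds_end"], strand
            )
            for r in rows
        ]
        domains = _domains_from_rows(rows)
        models[gene] = TranscriptModel(gene, rows[0]["chrom"], strand, exons, domains)
    if not models:
        raise TranscriptError(f"{path}: no transcripts found")
    return models


def _opt_int(value: Optional[str]) -> Optional[int]:
    value = (value or "").strip()
    return None if value in ("", ".", "NA") else int(value)


def _exon_from_genomic(
    number: int,
    start: int,
    end: int,
    cds_start: Optional[int],
    cds_end: Optional[int],
    strand: str,
) -> Exon:
    """Convert genomic CDS coordinates to transcript-orientation offsets."""
    if cds_start is None or cds_end is None:
        return Exon(number, start, end, 0, 0)
    if not start <= cds_start <= cds_end <= end:
        raise TranscriptError(f"exon {number}: CDS {cds_start}-{cds_end} outside exon")
    if strand == "+":
        lo, hi = cds_start - start, cds_end - start + 1
    else:
        lo, hi = end - cds_end, end - cds_start + 1
    return Exon(number, start, end, lo, hi)


def _domains_from_rows(rows: list[dict]) -> list[tuple[str, int, int]]:
    spans: dict[str, list[int]] = {}
    for r in rows:
        if r["domain"]:
            spans.setdefault(r["domain"], []).append(r["exon_number"])
    return [(name, min(nums), max(nums)) for name, nums in spans.items()]


def _load_gtf(path: Path) -> dict[str, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # group exon/CDS features per transcript, then pick longest CDS per gene
    per_transcript: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gene = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gene is None:
            raise TranscriptError(
                f"{path}: {feat.featuretype} record without gene_id/transcript_id"
            )
        entry = per_transcript.setdefault(
            tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                  "exons": [], "cds": []}
        )
        entry[("exons" if feat.featuretype == "exon" else "cds")].append(
            (feat.start, feat.end)
        )

    best: dict[str, dict] = {}
    for tid, entry in per_transcript.items():
        if not entry["exons"]:
            raise TranscriptError(f"{path}: transcript {tid} has no exons")
        cds_len = sum(e - s + 1 for s, e in entry["cds"])
        entry["tid"], entry["cds_len"] = tid, cds_len
        prev = best.get(entry["gene"])
        if prev is None or cds_len > prev["cds_len"]:
            if prev is not None:
                logger.info(
                    "gene %s: selected transcript %s (CDS %d nt) over %s",
                    entry["gene"], tid, cds_len, prev["tid"],
                )
            best[entry["gene"]] = entry

    models: dict[str, TranscriptModel] = {}
    for gene, entry in best.items():
        strand = entry["strand"]
        exon_spans = sorted(entry["exons"], reverse=(strand == "-"))
        cds_spans = entry["cds"]
        exons = []
        for i, (start, end) in enumerate(exon_spans, start=1):
            overlap = [
                (max(start, cs), min(end, ce))
                for cs, ce in cds_spans
                if cs <= end and ce >= start
            ]
            if overlap:
                cs = min(s for s, _ in overlap)
                ce = max(e for _, e in overlap)
                exons.append(_exon_from_genomic(i, start, end, cs, ce, strand))
            else:
                exons.append(Exon(i, start, end, 0, 0))
        models[gene] = TranscriptModel(gene, entry["chrom"], strand, exons, [])
    if not models:
        raise TranscriptError(f"{path}: no transcripts found")
    return models


def write_exon_tsv(
    models: Iterable[TranscriptModel], path: Union[str, Path]
) -> None:
    """Serialize transcript models to the simplified exon TSV dialect."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for model in models:
            for exon in model.exons:
                if exon.coding_length > 0:
                    if model.strand == "+":
                        cds_start = exon.genomic_start + exon.coding_start_offset
                        cds_end = exon.genomic_start + exon.coding_end_offset - 1
                    else:
                        cds_end = exon.genomic_end - exon.coding_start_offset
                        cds_start = exon.genomic_end - exon.coding_end_offset + 1
                    cds = (str(cds_start), str(cds_end))
                else:
                    cds = (".", ".")
                domain = ""
                for name, first, last in model.domains:
                    if first <= exon.number <= last:
                        domain = name
                        break
                writer.writerow(
                    [
                        model.gene_symbol,
                        model.chromosome,
                        model.strand,
                        exon.number,
                        exon.genomic_start,
                        exon.genomic_end,
                        *cds,
                        domain,
                    ]
                )
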