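"""Registry of known NTRK fusion partner genes.

The oncogenic rule of the classifier hinges on whether the 5' partner of a
fusion is a *known* partner of that particular NTRK gene.  Knownness is
pair-level — (partner, NTRK gene) — not partner-global: EML4 is curated for
both NTRK1 and NTRK3, and a partner curated only for NTRK1 counts as novel
when fused to NTRK2.  Two evidence classes exist:

* ``canonical`` — curated in COSMIC/GENIE or reported in >3 studies;
* ``clinical_validity`` — identified in the clinical trials supporting the
  TRK-inhibitor approvals.

The default registry ships as versioned data (``data/partner_kb.tsv``), not
code; classification reports always carry the KB version, because the
oncogenic / likely-oncogenic boundary moves as curation grows.  The same
file may carry per-gene kinase-region overrides for the domain-retention
test (``#tkd_region`` directive lines).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .transcript_model import DEFAULT_TKD_RETENTION, NTRK_GENES

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("canonical", "clinical_validity")

KB_COLUMNS = ("partner_gene", "ntrk_gene", "evidence_class", "source_tags")


class KnowledgeBaseError(ValueError):
    """Malformed knowledge-base table."""


@dataclass(frozen=True)
class PartnerEvidence:
    partner_gene: str
    ntrk_gene: str
    evidence_class: str
    source_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ntrk_gene not in NTRK_GENES:
            raise KnowledgeBaseError(f"not an NTRK gene: {self.ntrk_gene}")
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise KnowledgeBaseError(
                f"invalid evidence_class {self.evidence_class!r}; "
                f"expected one of {EVIDENCE_CLASSES}"
            )


@dataclass
class KnowledgeBase:
    """Deduplicated (partner, NTRK gene) registry with a version tag."""

    entries: dict[tuple[str, str], PartnerEvidence]
    version: str = "unversioned"
    tkd_regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TKD_RETENTION)
    )

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, partner_gene: str, ntrk_gene: str) -> Optional[PartnerEvidence]:
        return self.entries.get((partner_gene, ntrk_gene))

    def with_entry(self, entry: PartnerEvidence) -> "KnowledgeBase":
        """A copy with one additional pair (used for curation what-ifs)."""
        entries = dict(self.entries)
        entries[(entry.partner_gene, entry.ntrk_gene)] = entry
        return KnowledgeBase(entries, version=f"{self.version}+1", tkd_regions=dict(self.tkd_regions))


def partner_status(kb: KnowledgeBase, partner_gene: str, ntrk_gene: str) -> str:
    """``known(canonical)`` / ``known(clinical_validity)`` / ``novel``.

    Exact pair match required: a partner curated for a different NTRK gene
    returns ``novel``.  Pure and total — unknown genes are simply novel.
    """
    if ntrk_gene not in NTRK_GENES:
        raise KnowledgeBaseError(f"not an NTRK gene: {ntrk_gene}")
    entry = kb.lookup(partner_gene, ntrk_gene)
    if entry is None:
        return "novel"
    return f"known({entry.evidence_class})"


def is_known(status: str) -> bool:
    return status.startswith("known(")


def load_kb(path: Union[str, Path], version: Optional[str] = None) -> KnowledgeBase:
    """Load a partner registry from TSV, deduplicating exact pairs.

    Directive lines ``#tkd_region<TAB>GENE<TAB>first<TAB>last`` override the
    default breakpoint-compatible kinase region used by the retention test.
    Duplicate (partner, NTRK) rows collapse to one entry with a warning.
    """
    path = Path(path)
    entries: dict[tuple[str, str], PartnerEvidence] = {}
    tkd_regions = dict(DEFAULT_TKD_RETENTION)
    file_version = version
    with open(path, newline="") as handle:
        header: Optional[list[str]] = None
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if row[0].startswith("#"):
                directive = row[0].lstrip("#").strip()
                if directive == "version" and len(row) >= 2:
                    file_version = file_version or row[1].strip()
                elif directive == "tkd_region" and len(row) >= 4:
                    tkd_regions[row[1].strip()] = (int(row[2]), int(row[3]))
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = set(KB_COLUMNS) - set(header)
                if missing:
                    raise KnowledgeBaseError(
                        f"{path}: missing required columns: {sorted(missing)}"
                    )
                continue
            record = dict(zip(header, row))
            entry = PartnerEvidence(
                partner_gene=record["partner_gene"].strip(),
                ntrk_gene=record["ntrk_gene"].strip(),
                evidence_class=record["evidence_class"].strip(),
                source_tags=tuple(
                    t.strip() for t in record.get("source_tags", "").split(",") if t.strip()
                ),
            )
            key = (entry.partner_gene, entry.ntrk_gene)
            if key in entries:
                warnings.warn(
                    f"{path}:{lineno}: duplicate KB row for {key}; keeping first",
                    stacklevel=2,
                )
                continue
            entries[key] = entry
    if header is None:
        raise KnowledgeBaseError(f"{path}: no header row found")
    return KnowledgeBase(
        entries,
        version=file_version or path.stem,
        tkd_regions=tkd_regions,
    )


def default_kb() -> KnowledgeBase:
    """The registry shipped with the package."""
    with resources.as_file(
        resources.files("trkfusion.data").joinpath("partner_kb.tsv")
    ) as path:
        return load_kb(path)
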