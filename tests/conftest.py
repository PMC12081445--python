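"""Shared fixtures: simulated transcriptomes and a sequence-level oracle.

The frame oracle is deliberately independent of the package's exon-phase
arithmetic: it synthesizes actual nucleotide sequences over the transcript
models (codons drawn from a stop-free alphabet), splices the fused mRNA at
the breakpoints, translates from the 5' gene's start codon, and scans the
protein for a marker peptide encoded by the 3' gene's terminal codons.  A
junction preserves the reading frame iff the marker survives translation.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from trkfusion.knowledge_base import default_kb
from trkfusion.simulate import simulate_transcriptome
from trkfusion.transcript_model import BreakpointDescriptor, TranscriptModel

# codons of the form C-x-x can never spell a stop codon in any reading
# frame of their concatenation (every position = 0 mod 3 is a C, and stops
# all start with T), so frameshifted translation runs through uninterrupted
SAFE_CODONS = [f"C{a}{b}" for a in "ACGT" for b in "ACGT"]


@pytest.fixture(scope="session")
def models():
    return simulate_transcriptome(30, seed=11)


@pytest.fixture(scope="session")
def kb():
    return default_kb()


def gene_mrna(model: TranscriptModel, rng: np.random.Generator) -> list[str]:
    """Per-exon mRNA sequences: CDS positions carry stop-free codon stream,
    UTR positions are 'A' filler."""
    total_cds = model.cds_length
    n_codons = -(-total_cds // 3)
    stream = "".join(
        SAFE_CODONS[i] for i in rng.integers(0, len(SAFE_CODONS), size=n_codons)
    )[:total_cds]
    out = []
    consumed = 0
    for exon in model.exons:
        seq = ["A"] * exon.length
        for k in range(exon.coding_start_offset, exon.coding_end_offset):
            seq[k] = stream[consumed]
            consumed += 1
        out.append("".join(seq))
    return out


class SequenceFrameOracle:
    """Translate-and-scan check of frame preservation for fused transcripts."""

    def __init__(self, models: dict, seed: int = 7, marker_codons: int = 10):
        self.models = models
        self.marker_codons = marker_codons
        self.exon_seqs: dict[str, list[str]] = {}
        self.cds: dict[str, str] = {}
        for gene in sorted(models):
            rng = np.random.default_rng(seed + sum(map(ord, gene)))
            seqs = gene_mrna(models[gene], rng)
            self.exon_seqs[gene] = seqs
            cds = []
            for exon, seq in zip(models[gene].exons, seqs):
                cds.append(seq[exon.coding_start_offset: exon.coding_end_offset])
            self.cds[gene] = "".join(cds)

    def _retained_5p(self, gene: str, bp: BreakpointDescriptor) -> str:
        seqs = self.exon_seqs[gene]
        if bp.kind == "intron":
            return "".join(seqs[: bp.ordinal])
        return "".join(seqs[: bp.ordinal - 1]) + seqs[bp.ordinal - 1][: bp.exon_offset]

    def _retained_3p(self, gene: str, bp: BreakpointDescriptor) -> str:
        seqs = self.exon_seqs[gene]
        if bp.kind == "intron":
            return "".join(seqs[bp.ordinal:])
        return seqs[bp.ordinal - 1][bp.exon_offset - 1:] + "".join(seqs[bp.ordinal:])

    def _cds_start_in_retained(self, gene: str, bp: BreakpointDescriptor):
        """mRNA offset of the first coding base within the retained 5' part."""
        model = self.models[gene]
        mrna_offset = 0
        for exon in model.exons:
            limit = exon.length
            if bp.kind == "exon" and exon.number == bp.ordinal:
                limit = bp.exon_offset
            if exon.coding_length > 0 and exon.coding_start_offset < limit:
                return mrna_offset + exon.coding_start_offset
            mrna_offset += limit
            if bp.kind == "exon" and exon.number == bp.ordinal:
                break
            if bp.kind == "intron" and exon.number == bp.ordinal:
                break
        return None

    def frame_of(self, gene_5p, bp5, gene_3p, bp3) -> str:
        """'in_frame' | 'out_of_frame' | 'indeterminate' by translation."""
        fused = self._retained_5p(gene_5p, bp5) + self._retained_3p(gene_3p, bp3)
        start = self._cds_start_in_retained(gene_5p, bp5)
        if start is None:
            return "indeterminate"
        marker_nt = self.cds[gene_3p][-3 * self.marker_codons:]
        if len(marker_nt) < 3 * self.marker_codons:
            return "indeterminate"
        marker = str(Seq(marker_nt).translate())
        coding = fused[start:]
        coding = coding[: len(coding) - len(coding) % 3]
        protein = str(Seq(coding).translate())
        return "in_frame" if marker in protein else "out_of_frame"


@pytest.fixture(scope="session")
def frame_oracle(models):
    return SequenceFrameOracle(models)
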