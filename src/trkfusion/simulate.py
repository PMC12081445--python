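"""Synthetic transcriptomes and tumor cohorts with known ground truth.

No case-level data from real fusion-screening cohorts are public, so every
pipeline stage is exercised on simulated inputs whose truth is recorded at
generation time.  The generator emulates the structure of a real-world
pan-tumor screening cohort: per-tumor-type fusion prevalences on the order
of 0.2-2%, a mix of known and novel 5' partners with intronic and exonic
breakpoints, unique-read support straddling the >=5 filter, co-alteration
frequencies (TP53 in roughly half of fusion-positive tumors), log-normal
TMB with group shifts on the log scale, zero-inflated PD-L1 scores, and
MSI-H enrichment in colorectal/small-intestine tumors.

Fusions are constructed *verdict-first*: the generator decides the intended
verdict (oncogenic via a known partner, likely oncogenic via a novel
in-frame partner, or one of several VUS/filtered decoy kinds) and then
searches the simulated transcript geometry for breakpoints that realize it.
This guarantees label balance for classifier testing regardless of the
random gene shapes.  All randomness flows from a single mandatory seed;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .classifier import (
    IN_FRAME,
    INDETERMINATE,
    LIKELY_ONCOGENIC,
    ONCOGENIC,
    OUT_OF_FRAME,
    VUS,
    _lost_cds_3p,
    _retained_cds_5p,
)
from .cohort import COHORT_COLUMNS, format_alterations
from .fusion_ingest import FusionCall, write_fusion_calls
from .knowledge_base import KnowledgeBase, default_kb
from .transcript_model import (
    DEFAULT_TKD_RETENTION,
    NON_CODING,
    NTRK_GENES,
    TKD_EXONS,
    BreakpointDescriptor,
    Exon,
    TranscriptModel,
    breakpoint_to_genomic,
    exon_phase,
    write_exon_tsv,
)

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: Tumor-type composition resembling a large real-world solid-tumor cohort
#: (NSCLC ~39%, the rest spread over the common solid types).
DEFAULT_TUMOR_TYPE_WEIGHTS = {
    "NSCLC": 0.3895,
    "breast": 0.0726,
    "colorectal": 0.10,
    "head_and_neck": 0.0216,
    "glioblastoma": 0.0080,
    "small_intestine": 0.0039,
    "uterine": 0.0262,
    "ovarian": 0.0600,
    "prostate": 0.0500,
    "sarcoma": 0.0500,
    "thyroid": 0.0300,
    "pancreatic": 0.0600,
    "other": 0.1282,
}

#: Per-type probability that a specimen carries a qualifying (oncogenic or
#: likely oncogenic) NTRK fusion; overall prevalence works out near 0.35%.
DEFAULT_FUSION_PREVALENCE = {
    "NSCLC": 0.0024,
    "breast": 0.0063,
    "colorectal": 0.0050,
    "head_and_neck": 0.0095,
    "glioblastoma": 0.0191,
    "small_intestine": 0.0132,
    "uterine": 0.0019,
    "ovarian": 0.0040,
    "prostate": 0.0030,
    "sarcoma": 0.0040,
    "thyroid": 0.0040,
    "pancreatic": 0.0020,
    "other": 0.0043,
}

#: gene -> (alteration class, P(carry | NTRK+), P(carry | NTRK-)); values
#: mirror reported co-alteration frequencies (TP53 ~50.7% among positives).
DEFAULT_CO_ALTERATION = {
    "TP53": ("snv_indel", 0.507, 0.45),
    "ARID1A": ("snv_indel", 0.13, 0.10),
    "KRAS": ("snv_indel", 0.13, 0.15),
    "NOTCH1": ("snv_indel", 0.101, 0.05),
    "EGFR": ("snv_indel", 0.06, 0.08),
    "MDM2": ("cnv_amp", 0.04, 0.03),
    "PTEN": ("cnv_loss", 0.04, 0.03),
}

#: log(TMB+1) mean shift for NTRK+ specimens, per tumor type (log scale,
#: matching the analysis transform); medians mimic reported group medians
#: (head & neck 1.1 vs 5.4, colorectal 7.8 vs 6.2 mutations/Mb).
_HN_SHIFT = float(np.log(2.1) - np.log(6.4))
_CRC_SHIFT = float(np.log(8.8) - np.log(7.2))
DEFAULT_TMB = {
    "default": {"mu": float(np.log(7.0)), "sigma": 0.8, "shift": 0.0},
    "head_and_neck": {"mu": float(np.log(6.4)), "sigma": 0.8, "shift": _HN_SHIFT},
    "colorectal": {"mu": float(np.log(7.2)), "sigma": 0.8, "shift": _CRC_SHIFT},
}

#: zero-inflated PD-L1 mixture (P(score 0), P(1-49), P(50-100)) per status.
DEFAULT_PDL1 = {
    "default": {"pos": (0.45, 0.40, 0.15), "neg": (0.45, 0.40, 0.15)},
    "head_and_neck": {"pos": (0.65, 0.25, 0.10), "neg": (0.30, 0.50, 0.20)},
    "colorectal": {"pos": (0.20, 0.60, 0.20), "neg": (0.60, 0.30, 0.10)},
    "NSCLC": {"pos": (0.34, 0.33, 0.33), "neg": (0.40, 0.40, 0.20)},
}

DEFAULT_MSI = {
    "default": {"pos": 0.00, "neg": 0.01},
    "colorectal": {"pos": 0.50, "neg": 0.066},
    "small_intestine": {"pos": 0.50, "neg": 0.066},
}

DECOY_KINDS = ("out_of_frame", "ntrk_5prime", "tkd_lost", "subthreshold")


@dataclass
class SimulationParams:
    """Generator settings; the defaults are the study conditions."""

    n_specimens: int = 2000
    seed: int = 0
    n_partner_genes: int = 30
    tumor_type_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_TYPE_WEIGHTS)
    )
    fusion_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_FUSION_PREVALENCE)
    )
    known_partner_frac: float = 0.35  # qualifying fusions with a known partner
    second_fusion_prob: float = 0.06  # positives carrying a 2nd qualifying fusion
    frac_intronic: float = 0.8  # breakpoints placed in introns vs exons
    decoy_rate: float = 0.0015  # per-specimen rate of non-qualifying fusion rows
    co_alteration: dict = field(default_factory=lambda: dict(DEFAULT_CO_ALTERATION))
    tmb: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TMB.items()})
    pdl1: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PDL1.items()})
    msi: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MSI.items()})

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        total = sum(self.tumor_type_weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"tumor_type_weights sum to {total}, expected 1")
        for t, p in self.fusion_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {t} outside [0, 1]: {p}")
        for p in (self.known_partner_frac, self.frac_intronic, self.decoy_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fusion_truths: list  # one dict per emitted fusion row
    specimen_status: dict  # specimen_id -> True if NTRK+ (qualifying fusion)
    seed: int

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "seed": self.seed,
                    "specimen_status": self.specimen_status,
                    "fusion_truths": self.fusion_truths,
                },
                handle,
                indent=1,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# transcriptome simulation
# ---------------------------------------------------------------------------

_KNOWN_PARTNER_POOL = (
    "LMNA", "PEAR1", "RABGAP1L", "TP53", "EML4", "TPM3", "LGR6", "TPR",
    "IRF2BP2", "GKAP1", "SQSTM1", "GNAQ", "SASH1", "ETV6", "ARNT2", "TARSL2",
)

#: literature partners absent from the curated registry (hence novel)
_NAMED_NOVEL_POOL = ("HMCN1", "PRKACA", "ERBB2", "KANK1", "ASTN2", "FAM174B")


def _build_gene(
    rng: np.random.Generator,
    name: str,
    chrom: str,
    base: int,
    n_exons: int,
    strand: str,
    noncoding_first_exon: bool = False,
    first_exon_cds_mod: Optional[int] = None,
    domains: Optional[list] = None,
) -> TranscriptModel:
    """Assemble one transcript with UTRs trimmed so the CDS is a multiple of 3."""
    lengths = rng.integers(60, 301, size=n_exons)
    introns = rng.integers(500, 5001, size=n_exons - 1) if n_exons > 1 else []
    utr5 = int(rng.integers(5, min(50, lengths[0] - 6)))
    utr3 = int(rng.integers(5, min(50, lengths[-1] - 6)))
    if noncoding_first_exon:
        utr5 = int(lengths[0])
    elif first_exon_cds_mod is not None:
        # pin the first exon's coding length mod 3 (phase anchors)
        while (lengths[0] - utr5) % 3 != first_exon_cds_mod:
            utr5 += 1
    coding = [int(l) for l in lengths]
    coding[0] = int(lengths[0]) - utr5
    coding[-1] = int(lengths[-1]) - utr3
    if n_exons == 1:
        coding[0] = int(lengths[0]) - utr5 - utr3
    rem = sum(coding) % 3
    utr3 += rem
    coding[-1] -= rem
    if coding[-1] < 3:  # keep a sane terminal coding stretch
        utr3 -= 3
        coding[-1] += 3

    # transcript-order relative layout, then strand-aware genomic placement
    rel = []
    cursor = 0
    for i, length in enumerate(lengths):
        rel.append((cursor, cursor + int(length) - 1))
        cursor += int(length) + (int(introns[i]) if i < n_exons - 1 else 0)
    span = cursor if n_exons == 1 else rel[-1][1] + 1

    exons = []
    for i, (s, e) in enumerate(rel):
        if strand == "+":
            gstart, gend = base + s, base + e
        else:
            gstart, gend = base + (span - 1 - e), base + (span - 1 - s)
        length = int(lengths[i])
        if i == 0:
            lo, hi = utr5, utr5 + max(coding[0], 0)
        elif i == n_exons - 1:
            lo, hi = 0, max(coding[-1], 0)
        else:
            lo, hi = 0, length
        if hi < lo:
            lo = hi = 0
        exons.append(Exon(i + 1, gstart, gend, lo, hi))
    return TranscriptModel(name, chrom, strand, exons, list(domains or []))


def simulate_transcriptome(
    n_partner_genes: int, seed: int
) -> dict[str, TranscriptModel]:
    """NTRK1/2/3-like models plus partner genes of varied shape.

    The NTRK models carry their TKD exon ranges (9-17 / 16-20 / 15-19).
    Partners include every gene in the default knowledge base (so known
    pair fusions can be constructed), novel partners with first-exon coding
    phases pinned to 0, 1 and 2, and one gene with a fully non-coding first
    exon to exercise indeterminate frame calls.
    """
    if n_partner_genes < 1:
        raise ValueError("n_partner_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models: dict[str, TranscriptModel] = {}
    ntrk_specs = [
        ("NTRK1", 17, "+", "chr1"),
        ("NTRK2", 20, "+", "chr9"),
        ("NTRK3", 20, "-", "chr15"),
    ]
    base = 1_000_000
    for name, n_exons, strand, chrom in ntrk_specs:
        first, last = TKD_EXONS[name]
        models[name] = _build_gene(
            rng, name, chrom, base, n_exons, strand, domains=[("TKD", first, last)]
        )
        base += 2_000_000

    partner_names = list(_KNOWN_PARTNER_POOL) + list(_NAMED_NOVEL_POOL)
    n_novel = max(n_partner_genes - len(partner_names), 3)
    partner_names += [f"NVP{i:02d}" for i in range(1, n_novel + 1)]
    chroms = [f"chr{c}" for c in list(range(1, 23))]
    for idx, name in enumerate(partner_names):
        # curated partners get enough exons for their literature breakpoints
        # (e.g. LMNA intron 3); novel genes may be short
        lo = 6 if name in _KNOWN_PARTNER_POOL else 3
        n_exons = int(rng.integers(lo, 13))
        strand = "+" if rng.random() < 0.5 else "-"
        is_novel = name.startswith("NVP")
        novel_idx = int(name[3:]) - 1 if is_novel else -1
        models[name] = _build_gene(
            rng,
            name,
            chroms[idx % len(chroms)],
            base,
            n_exons,
            strand,
            noncoding_first_exon=(is_novel and novel_idx == n_novel - 1),
            first_exon_cds_mod=(novel_idx if 0 <= novel_idx <= 2 else None),
        )
        base += 2_000_000
    return models


def write_gtf(models: dict[str, TranscriptModel], path: Union[str, Path]) -> None:
    """Emit the models as an ensembl-dialect GTF (exon + CDS features)."""
    lines = []
    for gene in sorted(models):
        model = models[gene]
        tid = f"{gene}-T1"
        for exon in model.exons:
            attrs = (
                f'gene_id "{gene}"; transcript_id "{tid}"; '
                f'exon_number "{exon.number}";'
            )
            lines.append(
                "\t".join(
                    [
                        model.chromosome, "sim", "exon",
                        str(exon.genomic_start), str(exon.genomic_end),
                        ".", model.strand, ".", attrs,
                    ]
                )
            )
            if exon.coding_length > 0:
                if model.strand == "+":
                    cs = exon.genomic_start + exon.coding_start_offset
                    ce = exon.genomic_start + exon.coding_end_offset - 1
                else:
                    ce = exon.genomic_end - exon.coding_start_offset
                    cs = exon.genomic_end - exon.coding_end_offset + 1
                lines.append(
                    "\t".join(
                        [
                            model.chromosome, "sim", "CDS",
                            str(cs), str(ce), ".", model.strand, "0", attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# breakpoint construction (verdict-first)
# ---------------------------------------------------------------------------


def _intron_genomic_range(model: TranscriptModel, ordinal: int) -> tuple[int, int]:
    a, b = model.exon(ordinal), model.exon(ordinal + 1)
    lo = min(a.genomic_end, b.genomic_end) + 1
    hi = max(a.genomic_start, b.genomic_start) - 1
    return lo, hi


def _candidates_5p(model: TranscriptModel) -> list[tuple[BreakpointDescriptor, Optional[int]]]:
    """5' breakpoint candidates with the phase of the retained segment."""
    out = []
    for i in range(1, model.n_exons):  # introns
        bp = BreakpointDescriptor(model.gene_symbol, "intron", i)
        retained = _retained_cds_5p(model, bp)
        out.append((bp, retained % 3 if retained > 0 else None))
    last_coding = max(
        (e.number for e in model.exons if e.coding_length > 0), default=0
    )
    for exon in model.exons:  # a few exonic offsets per exon
        for offset in (exon.length // 3, (2 * exon.length) // 3):
            if not 1 <= offset <= exon.length:
                continue
            # breakpoints past the stop codon never yield a read-through
            # fusion protein; keep candidates within the coding body
            if exon.number > last_coding or (
                exon.number == last_coding and offset > exon.coding_end_offset
            ):
                continue
            bp = BreakpointDescriptor(model.gene_symbol, "exon", exon.number, offset)
            retained = _retained_cds_5p(model, bp)
            out.append((bp, retained % 3 if retained > 0 else None))
    return out


def _candidates_3p(model: TranscriptModel, compatible_only: bool = True):
    """3' NTRK breakpoint candidates with their resume phase; optionally
    restricted to the kinase-retaining region."""
    first = DEFAULT_TKD_RETENTION[model.gene_symbol][0]
    out = []
    for i in range(1, model.n_exons):
        if compatible_only and not i < first:
            continue
        if not compatible_only and i < first:
            continue
        phase = exon_phase(model, i + 1)
        out.append(
            (
                BreakpointDescriptor(model.gene_symbol, "intron", i),
                None if phase == NON_CODING else int(phase),
            )
        )
    for exon in model.exons:
        ok = exon.number < first
        if compatible_only != ok:
            continue
        offset = max(exon.length // 2, 1)
        bp = BreakpointDescriptor(model.gene_symbol, "exon", exon.number, offset)
        if exon.coding_length == 0 and sum(
            e.coding_length for e in model.exons[: exon.number - 1]
        ) == 0:
            phase3: Optional[int] = None
        else:
            phase3 = _lost_cds_3p(model, bp) % 3
        out.append((bp, phase3))
    return out


def _genomic_string(
    rng: np.random.Generator, model: TranscriptModel, bp: BreakpointDescriptor
) -> str:
    """Random concrete genomic position realizing the descriptor."""
    if bp.kind == "exon":
        pos = breakpoint_to_genomic(model, bp)
    else:
        lo, hi = _intron_genomic_range(model, bp.ordinal)
        pos = int(rng.integers(lo, hi + 1))
    return f"{model.chromosome}:{pos}"


def _bp_dict(bp: BreakpointDescriptor) -> dict:
    return {"kind": bp.kind, "ordinal": bp.ordinal, "exon_offset": bp.exon_offset}


class _FusionFactory:
    """Draws fusion rows realizing an intended verdict against the models."""

    def __init__(
        self,
        rng: np.random.Generator,
        models: dict[str, TranscriptModel],
        kb: KnowledgeBase,
        frac_intronic: float,
    ):
        self.rng = rng
        self.models = models
        self.kb = kb
        self.frac_intronic = frac_intronic
        self.known_pairs = [
            (p, n) for (p, n) in kb.entries if p in models and n in models
        ]
        self.novel_partners = [
            g for g in models
            if g not in NTRK_GENES
            and all((g, n) not in kb.entries for n in NTRK_GENES)
        ]
        self._c5 = {g: _candidates_5p(m) for g, m in models.items() if g not in NTRK_GENES}
        self._c3_ok = {g: _candidates_3p(self.models[g], True) for g in NTRK_GENES}
        self._c3_bad = {g: _candidates_3p(self.models[g], False) for g in NTRK_GENES}

    def _pick(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def _pick_5p(self, partner: str, want_phase, prefer_intronic=True):
        """A 5' breakpoint whose retained-segment phase satisfies ``want_phase``
        (an int to match, ``"mismatch:k"`` to avoid k, or None for any)."""
        cands = self._c5[partner]

        def ok(phase):
            if want_phase is None:
                return True
            if isinstance(want_phase, str):
                k = int(want_phase.split(":")[1])
                return phase is not None and phase != k
            return phase == want_phase

        pool = [(bp, ph) for bp, ph in cands if ok(ph)]
        if prefer_intronic and self.rng.random() < self.frac_intronic:
            intronic = [(bp, ph) for bp, ph in pool if bp.kind == "intron"]
            if intronic:
                pool = intronic
        return self._pick(pool) if pool else None

    def qualifying(self, specimen_id: str, want_known: bool) -> Optional[tuple[FusionCall, dict]]:
        """One oncogenic (known partner) or likely-oncogenic (novel, in-frame)
        fusion; returns None when the geometry offers no realization."""
        ntrk = self._pick(NTRK_GENES)
        pool = self._c3_ok[ntrk]
        if self.rng.random() < self.frac_intronic:
            intronic = [(bp, ph) for bp, ph in pool if bp.kind == "intron"]
            pool = intronic or pool
        bp3, phase3 = self._pick(pool)

        if want_known:
            pairs = [(p, n) for p, n in self.known_pairs if n == ntrk]
            if not pairs:
                return None
            partner = self._pick(pairs)[0]
            chosen = self._pick_5p(partner, None)
            verdict, frame = ONCOGENIC, None
        else:
            partner = self._pick(self.novel_partners)
            if phase3 is None:
                return None
            chosen = self._pick_5p(partner, phase3)
            verdict, frame = LIKELY_ONCOGENIC, IN_FRAME
        if chosen is None:
            return None
        bp5, phase5 = chosen
        if frame is None:
            frame = (
                IN_FRAME
                if phase5 is not None and phase5 == phase3
                else (INDETERMINATE if phase5 is None or phase3 is None else OUT_OF_FRAME)
            )
        reads = 5 + int(self.rng.poisson(12))
        call = FusionCall(
            specimen_id, partner, ntrk,
            _genomic_string(self.rng, self.models[partner], bp5),
            _genomic_string(self.rng, self.models[ntrk], bp3),
            reads, caller_tag="sim",
        )
        truth = {
            "specimen_id": specimen_id,
            "name": call.name,
            "kind": "known_partner" if want_known else "novel_in_frame",
            "verdict": verdict,
            "frame": frame,
            "bp_5p": _bp_dict(bp5),
            "bp_3p": _bp_dict(bp3),
            "unique_reads": reads,
            "passes_read_filter": True,
        }
        return call, truth

    def decoy(self, specimen_id: str, kind: str) -> Optional[tuple[FusionCall, dict]]:
        """A non-qualifying fusion row of the requested failure kind."""
        ntrk = self._pick(NTRK_GENES)
        if kind == "ntrk_5prime":
            partner = self._pick(self.novel_partners)
            bp5, _ = self._pick(self._c5[partner])
            bp3, _ = self._pick(self._c3_ok[ntrk])
            reads = 5 + int(self.rng.poisson(8))
            call = FusionCall(
                specimen_id, ntrk, partner,
                _genomic_string(self.rng, self.models[ntrk], bp3),
                _genomic_string(self.rng, self.models[partner], bp5),
                reads, caller_tag="sim",
            )
            verdict, frame, passes = VUS, None, True
            bp5_out, bp3_out = bp3, bp5
        elif kind == "tkd_lost":
            partner = self._pick(self.novel_partners)
            chosen5 = self._pick(self._c5[partner])
            bp3, _ = self._pick(self._c3_bad[ntrk])
            reads = 5 + int(self.rng.poisson(8))
            call = FusionCall(
                specimen_id, partner, ntrk,
                _genomic_string(self.rng, self.models[partner], chosen5[0]),
                _genomic_string(self.rng, self.models[ntrk], bp3),
                reads, caller_tag="sim",
            )
            verdict, frame, passes = VUS, None, True
            bp5_out, bp3_out = chosen5[0], bp3
        elif kind == "out_of_frame":
            partner = self._pick(self.novel_partners)
            pool = [(bp, ph) for bp, ph in self._c3_ok[ntrk] if ph is not None]
            bp3, phase3 = self._pick(pool)
            chosen = self._pick_5p(partner, f"mismatch:{phase3}")
            if chosen is None:
                return None
            reads = 5 + int(self.rng.poisson(8))
            call = FusionCall(
                specimen_id, partner, ntrk,
                _genomic_string(self.rng, self.models[partner], chosen[0]),
                _genomic_string(self.rng, self.models[ntrk], bp3),
                reads, caller_tag="sim",
            )
            verdict, frame, passes = VUS, OUT_OF_FRAME, True
            bp5_out, bp3_out = chosen[0], bp3
        elif kind == "subthreshold":
            made = self.qualifying(specimen_id, want_known=bool(self.rng.integers(2)))
            if made is None:
                return None
            call, truth = made
            reads = int(self.rng.integers(1, 5))
            call = FusionCall(
                call.specimen_id, call.gene_5p, call.gene_3p,
                call.breakpoint_5p, call.breakpoint_3p, reads, call.caller_tag,
            )
            truth.update(
                {"kind": "subthreshold", "unique_reads": reads,
                 "passes_read_filter": False}
            )
            return call, truth
        else:
            raise ValueError(f"unknown decoy kind: {kind}")
        truth = {
            "specimen_id": specimen_id,
            "name": call.name,
            "kind": kind,
            "verdict": verdict,
            "frame": frame,
            "bp_5p": _bp_dict(bp5_out),
            "bp_3p": _bp_dict(bp3_out),
            "unique_reads": reads,
            "passes_read_filter": passes,
        }
        return call, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    params: SimulationParams
    models: dict
    fusion_calls: list
    cohort: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write fusion TSV, cohort TSV, annotation (both dialects), truth
        JSON and a params echo; paths returned by name."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fusions": out / "fusions.tsv",
            "cohort": out / "cohort.tsv",
            "transcripts_tsv": out / "transcripts.tsv",
            "transcripts_gtf": out / "transcripts.gtf",
            "truth": out / "truth.json",
            "params": out / "params.yaml",
        }
        write_fusion_calls(self.fusion_calls, paths["fusions"])
        serializable = self.cohort.assign(
            alterations=self.cohort["alterations"].map(format_alterations)
        )
        serializable.to_csv(paths["cohort"], sep="\t", index=False)
        write_exon_tsv(
            [self.models[g] for g in sorted(self.models)], paths["transcripts_tsv"]
        )
        write_gtf(self.models, paths["transcripts_gtf"])
        self.truth.to_json(paths["truth"])
        import yaml

        with open(paths["params"], "w") as handle:
            yaml.safe_dump(asdict(self.params), handle, sort_keys=True)
        return paths


def _sample_pdl1(rng: np.random.Generator, mix: tuple[float, float, float]) -> float:
    u = rng.random()
    if u < mix[0]:
        return 0.0
    if u < mix[0] + mix[1]:
        return float(rng.integers(1, 50))
    return float(rng.integers(50, 101))


def simulate_cohort(
    params: SimulationParams,
    models: Optional[dict[str, TranscriptModel]] = None,
    kb: Optional[KnowledgeBase] = None,
) -> SimulatedCohort:
    """Generate fusion calls + specimen metadata with recorded ground truth.

    NTRK+ specimens receive at least one fusion constructed to match their
    intended verdict; decoys (wrong orientation, kinase domain lost, out of
    frame, sub-threshold reads) are sprinkled over the whole cohort.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    kb = kb or default_kb()
    if models is None:
        models = simulate_transcriptome(params.n_partner_genes, params.seed)
    factory = _FusionFactory(rng, models, kb, params.frac_intronic)

    n = params.n_specimens
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    types = sorted(params.tumor_type_weights)
    weights = np.array([params.tumor_type_weights[t] for t in types])
    tumor_type = rng.choice(types, size=n, p=weights / weights.sum())
    prevalence = np.array(
        [params.fusion_prevalence.get(t, 0.0) for t in tumor_type]
    )
    positive = rng.random(n) < prevalence

    # --- fusions -----------------------------------------------------------
    calls: list[FusionCall] = []
    truths: list[dict] = []
    for i in np.flatnonzero(positive):
        n_fusions = 1 + int(rng.random() < params.second_fusion_prob)
        made_any = False
        for _ in range(n_fusions):
            want_known = rng.random() < params.known_partner_frac
            made = factory.qualifying(ids[i], want_known)
            if made is None:  # retry once with the other partner class
                made = factory.qualifying(ids[i], not want_known)
            if made is not None:
                calls.append(made[0])
                truths.append(made[1])
                made_any = True
        if not made_any:  # geometry never realizes a verdict -> flip truth
            positive[i] = False
    decoy_mask = rng.random(n) < params.decoy_rate
    for i in np.flatnonzero(decoy_mask):
        kind = DECOY_KINDS[int(rng.integers(len(DECOY_KINDS)))]
        made = factory.decoy(ids[i], kind)
        if made is not None:
            calls.append(made[0])
            truths.append(made[1])

    # --- clinical covariates ----------------------------------------------
    age = np.clip(np.round(rng.normal(66, 12, size=n)), 26, 89).astype(int)
    sex = np.where(rng.random(n) < 0.57, "F", "M")
    stage = rng.choice(
        ["unknown", "IV", "<=III"], size=n, p=[0.57, 0.36, 0.07]
    )
    log_tmb = np.empty(n)
    pdl1 = np.empty(n)
    pdl1_type = np.empty(n, dtype=object)
    msi = np.empty(n, dtype=object)
    for i in range(n):
        t = tumor_type[i]
        cfg = params.tmb.get(t, params.tmb["default"])
        log_tmb[i] = rng.normal(
            cfg["mu"] + (cfg["shift"] if positive[i] else 0.0), cfg["sigma"]
        )
        mix_cfg = params.pdl1.get(t, params.pdl1["default"])
        pdl1[i] = _sample_pdl1(rng, mix_cfg["pos" if positive[i] else "neg"])
        pdl1_type[i] = "TPS" if t == "NSCLC" else "CPS"
        msi_cfg = params.msi.get(t, params.msi["default"])
        p_h = msi_cfg["pos" if positive[i] else "neg"]
        msi[i] = "MSI-H" if rng.random() < p_h else "MSS"
    tmb = np.round(np.maximum(np.exp(log_tmb) - 1.0, 0.0), 1)
    pdl1_missing = rng.random(n) < 0.15
    msi_missing = rng.random(n) < 0.05

    alterations = [[] for _ in range(n)]
    for gene in sorted(params.co_alteration):
        klass, p_pos, p_neg = params.co_alteration[gene]
        p = np.where(positive, p_pos, p_neg)
        carry = rng.random(n) < p
        pathogenic = rng.random(n) < 0.9  # a few benign records exercise filtering
        for i in np.flatnonzero(carry):
            alterations[i].append((gene, klass, bool(pathogenic[i])))

    cohort = pd.DataFrame(
        {
            "specimen_id": ids,
            "tumor_type": tumor_type,
            "age": age,
            "sex": sex,
            "stage": stage,
            "tmb": tmb,
            "pdl1_score": [
                "" if pdl1_missing[i] else pdl1[i] for i in range(n)
            ],
            "pdl1_score_type": pdl1_type,
            "msi": ["" if msi_missing[i] else msi[i] for i in range(n)],
            "alterations": [tuple(a) for a in alterations],
        },
        columns=list(COHORT_COLUMNS),
    )
    truth = GroundTruth(
        fusion_truths=truths,
        specimen_status={ids[i]: bool(positive[i]) for i in range(n)},
        seed=params.seed,
    )
    return SimulatedCohort(params, models, calls, cohort, truth)
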