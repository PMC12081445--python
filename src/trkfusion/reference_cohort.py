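"""Reference cohort counts from a published pan-tumor NTRK fusion screen.

Case-level data from the large real-world screening cohort this package
characterizes (19,591 FFPE solid-tumor specimens, 73 oncogenic or likely
oncogenic NTRK fusions in 69 specimens) are not public; only the printed
summary tables are.  This module transcribes those printed numerators and
denominators and expands them into concrete, SYNTHETIC case-level inputs —
a specimen table and a classified-fusion table whose marginal counts equal
the printed ones — so the cohort analytics operate on real inputs rather
than on pre-computed percentages.  Every attribute that the printed tables
do not constrain (which specimen carries which alteration, exact ages, ...)
is an arbitrary deterministic choice and carries no evidential weight.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .classifier import LIKELY_ONCOGENIC, ONCOGENIC

#: Printed counts (numerator, denominator or plain N) from the reference
#: screen; the single source for the expansion below.
REFERENCE_COUNTS = {
    "total_specimens": 19_591,          # submitted for profiling
    "passed_rna_specimens": 19_531,     # NSCLC 7,630 + other solid 11,901
    "positive_specimens": 69,
    "qualifying_fusions": 73,
    "nsclc": (18, 7_630),
    "other_solid": (51, 11_901),
    "per_type": {
        "glioblastoma": (3, 157),
        "small_intestine": (1, 76),
        "head_and_neck": (4, 423),
        "uterine": (1, 514),
        "breast": (9, 1_423),
    },
    "recurrent_fusions": {
        # fusion -> (n_specimens, verdict)
        "ETV6-NTRK3": (5, ONCOGENIC),
        "TPM3-NTRK1": (3, ONCOGENIC),
        "LMNA-NTRK1": (3, ONCOGENIC),
        "EML4-NTRK3": (2, ONCOGENIC),
        "TPR-NTRK1": (2, ONCOGENIC),
        "PEAR1-NTRK1": (2, ONCOGENIC),
        "IRF2BP2-NTRK1": (2, ONCOGENIC),
        "KANK1-NTRK3": (2, LIKELY_ONCOGENIC),
    },
    "cooccurring_genes": {"TP53": 35, "ARID1A": 9, "KRAS": 9, "NOTCH1": 7},
    "cooccurring_classes": {"snv_indel": 59, "cnv": 20, "fusion": 18},
    "driver_cooccurrence": (20, 69),
    "nsclc_driver_cooccurrence": (11, 18),
    "msi_h_crc_small_intestine_positive": (6, 12),
    "partner_pairs": {"known": 18, "novel": 41},
    "stage_of_staged": {"IV": 25, "<=III": 4},
}


@lru_cache(maxsize=1)
def reference_counts() -> dict:
    return REFERENCE_COUNTS


# ---------------------------------------------------------------------------
# prevalence inputs: one row per profiled specimen, flags for positives
# ---------------------------------------------------------------------------


def reference_prevalence_inputs() -> tuple[pd.DataFrame, set[str]]:
    """A 19,531-row specimen frame (the RNA-pass denominator) whose per-type
    and overall positive counts equal the printed ones."""
    counts = reference_counts()
    groups = [("NSCLC", *counts["nsclc"])]
    named_total = named_pos = 0
    for t, (n_pos, n_tot) in counts["per_type"].items():
        groups.append((t, n_pos, n_tot))
        named_pos += n_pos
        named_total += n_tot
    other_pos = counts["other_solid"][0] - named_pos
    other_tot = counts["other_solid"][1] - named_total
    groups.append(("other_solid", other_pos, other_tot))

    types, flags, ids = [], [], []
    i = 0
    for tumor_type, n_pos, n_tot in groups:
        for j in range(n_tot):
            i += 1
            ids.append(f"R{i:05d}")
            types.append(tumor_type)
            flags.append(j < n_pos)
    cohort = pd.DataFrame({"specimen_id": ids, "tumor_type": types})
    positives = {sid for sid, f in zip(ids, flags) if f}
    assert len(cohort) == counts["passed_rna_specimens"]
    assert len(positives) == counts["positive_specimens"]
    return cohort, positives


# ---------------------------------------------------------------------------
# the 69 fusion-positive specimens, expanded to case level
# ---------------------------------------------------------------------------

_POSITIVE_TYPES = (
    [("NSCLC", 18)] + [("colorectal", 11)] + [("small_intestine", 1)]
    + [("head_and_neck", 4)] + [("glioblastoma", 3)] + [("breast", 9)]
    + [("uterine", 1)] + [("ovarian", 2)] + [("prostate", 2)]
    + [("sarcoma", 2)] + [("thyroid", 1)] + [("pancreatic", 1)]
    + [("esophageal", 1)] + [("unknown_primary", 1)] + [("other", 12)]
)

def _pid(i: int) -> str:
    return f"P{i:02d}"


def _positive_specimen_table() -> pd.DataFrame:
    rows = []
    i = 0
    for tumor_type, n in _POSITIVE_TYPES:
        for _ in range(n):
            i += 1
            rows.append({"specimen_id": _pid(i), "tumor_type": tumor_type})
    assert i == 69
    return pd.DataFrame(rows)


# alteration layout chosen so every printed marginal count is met at once:
# snv carriers are specimens 1-59, cnv carriers 20 distinct specimens,
# fusion-class carriers 18, driver-gene carriers 20 overall / 11 in NSCLC.
_ALTERATIONS = {
    "TP53": ("snv_indel", list(range(1, 36))),
    "ARID1A": ("snv_indel", list(range(36, 45))),
    "KRAS": ("snv_indel", [1, 2, 19, 45, 46, 47, 48, 49, 50]),
    "NOTCH1": ("snv_indel", [35, 51, 52, 53, 54, 55, 56]),
    "EGFR": ("snv_indel", [3, 4, 5, 6]),
    "BRAF": ("snv_indel", [8, 11]),
    "MET": ("snv_indel", [9]),
    "ERBB2": ("snv_indel", [10]),
    "PIK3CA": ("snv_indel", [38, 47, 48]),
    "POLD1": ("snv_indel", [19, 30]),
    "KMT2D": ("snv_indel", [57, 58, 59]),
    "MDM2": ("cnv_amp", [12, 13, 14]),
    "PTEN": ("cnv_loss", [15, 16, 30]),
    "CDKN2A": ("cnv_loss", [17, 18, 20, 21, 22]),
    "MYC": ("cnv_amp", [23, 24, 25, 26]),
    "RB1": ("cnv_loss", [27, 28, 29, 31, 32]),
    "ALK": ("fusion", [7, 60]),
    "RET": ("fusion", [19]),
    "FGFR2": ("fusion", [20, 21, 22, 23, 24]),
    "FGFR3": ("fusion", list(range(61, 70))),
}
_ERBB2_FUSION_SPECIMEN = 38  # breast specimen also carrying the ERBB2 fusion
_BENIGN = [("MUC16", "snv_indel", 61)]  # known_pathogenic=False, filtered out

_MSI_H = {19, 20, 21, 22, 23, 30}  # 6 of the 12 colorectal/small-intestine

_TMB = {19: 91.6, 30: 80.0, 31: 1.1, 32: 0.8, 33: 1.5, 34: 1.1}
_CRC_TMB = [7.8, 6.5, 9.0, 5.0, 8.5, 10.0, 7.0, 8.0, 3.0, 7.8]  # specimens 20-29

_NSCLC_TPS = [0, 0, 0, 0, 0, 0, 10, 20, 30, 40, 45, 25, 50, 60, 70, 80, 90, 55]
_CRC_CPS = {19: 80, 20: 20, 21: 25, 22: 10, 23: 30, 24: 0, 25: 20, 26: 15,
            27: 20, 28: 35, 29: 5, 30: 10}
_HN_CPS = {31: 0, 32: 0, 33: 0, 34: 5}


def reference_positive_cohort() -> tuple[pd.DataFrame, set[str]]:
    """The 69 fusion-positive specimens as a full specimen table."""
    base = _positive_specimen_table()
    n = len(base)

    alterations: dict[int, list] = {i: [] for i in range(1, n + 1)}
    for gene, (klass, specimens) in _ALTERATIONS.items():
        for s in specimens:
            alterations[s].append((gene, klass, True))
    alterations[_ERBB2_FUSION_SPECIMEN].append(("ERBB2", "fusion", True))
    for gene, klass, s in _BENIGN:
        alterations[s].append((gene, klass, False))

    # ages: spread 26..89 with median 66 (the printed median/range)
    ages = (
        list(np.linspace(26, 65, 34).round().astype(int))
        + [66]
        + list(np.linspace(67, 89, 34).round().astype(int))
    )
    # sex: NSCLC 8 M / 10 F; other 20 M / 31 F
    sex = ["M"] * 8 + ["F"] * 10 + ["M"] * 20 + ["F"] * 31
    # stage: NSCLC <=III 1 / IV 5 / unknown 12; other 3 / 20 / 28
    stage = {}
    for s in range(1, 70):
        stage[s] = "unknown"
    for s in (1, 2, 3, 4, 5):
        stage[s] = "IV"
    stage[18] = "<=III"
    for s in (19, 20, 21):
        stage[s] = "<=III"
    for s in range(22, 42):
        stage[s] = "IV"

    tmb, pdl1, pdl1_type, msi = [], [], [], []
    crc_iter = iter(_CRC_TMB)
    for s, tumor_type in enumerate(base["tumor_type"], start=1):
        if s in _TMB:
            tmb.append(_TMB[s])
        elif tumor_type == "colorectal":
            tmb.append(next(crc_iter))
        else:
            tmb.append(round(4.0 + (s % 7), 1))
        if tumor_type == "NSCLC":
            pdl1.append(float(_NSCLC_TPS[s - 1]))
            pdl1_type.append("TPS")
        elif s in _CRC_CPS:
            pdl1.append(float(_CRC_CPS[s]))
            pdl1_type.append("CPS")
        elif s in _HN_CPS:
            pdl1.append(float(_HN_CPS[s]))
            pdl1_type.append("CPS")
        elif tumor_type == "glioblastoma":
            pdl1.append(None)
            pdl1_type.append("CPS")
        else:
            pdl1.append(float((s * 3) % 40))
            pdl1_type.append("CPS")
        msi.append("MSI-H" if s in _MSI_H else "MSS")

    cohort = base.assign(
        age=ages,
        sex=sex,
        stage=[stage[s] for s in range(1, n + 1)],
        tmb=tmb,
        pdl1_score=pdl1,
        pdl1_score_type=pdl1_type,
        msi=msi,
        alterations=[tuple(alterations[s]) for s in range(1, n + 1)],
    )
    return cohort, set(cohort["specimen_id"])


# ---------------------------------------------------------------------------
# the 73 qualifying fusions as a classified table
# ---------------------------------------------------------------------------

# recurrent fusions with the printed tumor-type breakdown
_RECURRENT_CARRIERS = {
    "ETV6-NTRK3": [31, 32, 33, 34, 54],       # head & neck x4, thyroid
    "TPM3-NTRK1": [39, 30, 57],               # breast, small intestine, CUP
    "LMNA-NTRK1": [25, 26, 12],               # colorectal x2, NSCLC
    "EML4-NTRK3": [27, 52],                   # colorectal, sarcoma
    "TPR-NTRK1": [28, 29],                    # colorectal x2
    "PEAR1-NTRK1": [50, 53],                  # prostate, sarcoma
    "IRF2BP2-NTRK1": [40, 13],                # breast, NSCLC
    "KANK1-NTRK3": [48, 49],                  # ovarian x2
}

# the 11 known partner pairs seen in exactly one specimen each
_KNOWN_SINGLETONS = {
    "RABGAP1L-NTRK1": 1, "TP53-NTRK1": 2, "EML4-NTRK1": 3, "LGR6-NTRK1": 4,
    "GKAP1-NTRK2": 5, "SQSTM1-NTRK2": 6, "GNAQ-NTRK2": 56,  # esophageal
    "SASH1-NTRK3": 7, "ARNT2-NTRK3": 8, "SQSTM1-NTRK3": 9, "TARSL2-NTRK3": 10,
}

_NOVEL_NTRK1 = ["HMCN1", "LRRC16A", "FAM227B", "MKKS", "DST"]
_NOVEL_NTRK2 = [
    "ASTN2", "MSANTD3", "PRKACA", "SLC6A6", "KRT5", "HMSD", "SERPINB8",
    "ZNF98", "CTSA", "DYRK1A", "AGBL4", "NAV2", "TLE4", "CPEB4", "RBMS3",
    "DNER", "SOX5", "TCF4", "LSAMP", "CDH18", "MAGI2",
]
_NOVEL_NTRK3 = [
    "ERBB2", "FAM174B", "PIAS1", "SETD5", "SND1", "MDM2", "INTS2", "FHOD3",
    "AKAP13", "SPECC1", "RBFOX1", "CTNNA2", "PTPRD", "UNC13C",
]
# one singleton pair was called twice in the same specimen (73 fusion rows
# over 69 specimens means some specimens carry two calls); pinned so the
# pair still counts as "detected in one tumor specimen"
_DUPLICATED_SINGLETON = ("PRKACA-NTRK2", 14)


def reference_classified() -> pd.DataFrame:
    """Classified-fusion table (73 qualifying rows) matching every printed
    recurrence, novelty and positivity count."""
    rows: list[tuple[int, str, str]] = []  # (specimen index, fusion, verdict)
    counts = reference_counts()
    for fusion, carriers in _RECURRENT_CARRIERS.items():
        verdict = counts["recurrent_fusions"][fusion][1]
        rows.extend((s, fusion, verdict) for s in carriers)
    rows.extend((s, f, ONCOGENIC) for f, s in _KNOWN_SINGLETONS.items())
    rows.append((_ERBB2_FUSION_SPECIMEN, "ERBB2-NTRK3", LIKELY_ONCOGENIC))

    dup_fusion, dup_specimen = _DUPLICATED_SINGLETON
    rows.append((dup_specimen, dup_fusion, LIKELY_ONCOGENIC))
    rows.append((dup_specimen, dup_fusion, LIKELY_ONCOGENIC))

    novel_pairs = (
        [f"{p}-NTRK1" for p in _NOVEL_NTRK1]
        + [f"{p}-NTRK2" for p in _NOVEL_NTRK2 if f"{p}-NTRK2" != dup_fusion]
        + [f"{p}-NTRK3" for p in _NOVEL_NTRK3 if p != "ERBB2"]
    )
    used = {s for s, _, _ in rows}
    free = [s for s in range(1, 70) if s not in used]
    for i, fusion in enumerate(novel_pairs):
        rows.append((free[i % len(free)], fusion, LIKELY_ONCOGENIC))

    types = dict(
        zip(range(1, 70), _positive_specimen_table()["tumor_type"])
    )
    records = []
    for s, fusion, verdict in rows:
        gene_5p, ntrk = fusion.rsplit("-", 1)
        records.append(
            {
                "specimen_id": _pid(s),
                "fusion_name": fusion,
                "gene_5p": gene_5p,
                "gene_3p": ntrk,
                "ntrk_gene": ntrk,
                "verdict": verdict,
                "tumor_type": types[s],
            }
        )
    table = pd.DataFrame(records)
    assert len(table) == counts["qualifying_fusions"]
    assert table["specimen_id"].nunique() == counts["positive_specimens"]
    return table
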