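"""Cohort-level analytics over classified fusions and specimen metadata.

Given the classifier's output and a clinical/biomarker table (one row per
tumor specimen), these operations derive the standard characterization
tables for a fusion-screening cohort:

* per-tumor-type prevalence of fusion-positive specimens;
* recurrence of individual fusions (fusion% of positives, % of cohort);
* known vs novel partner-pair bookkeeping;
* co-occurring pathogenic alteration frequencies and an oncoprint matrix;
* immunotherapy biomarker comparisons (TMB, PD-L1, MSI) between
  fusion-positive and fusion-negative specimens.

Percentages are rounded half-up at the precision conventional for each
table (see :class:`AnalysisConfig`), so printed tables are reproducible
arithmetic, not formatting accidents.  TMB comparisons are rank-sum tests
on log(TMB + 1); PD-L1 TPS and CPS are never pooled in one test.  P-values
are reported uncorrected and flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import LIKELY_ONCOGENIC, ONCOGENIC
from .knowledge_base import KnowledgeBase, is_known, partner_status
from .transcript_model import NTRK_GENES

QUALIFYING_VERDICTS = (ONCOGENIC, LIKELY_ONCOGENIC)

ALTERATION_CLASSES = ("snv_indel", "cnv_amp", "cnv_loss", "fusion")

#: Genes counted as co-occurring oncogenic drivers; configurable because
#: published summaries name examples, not an exhaustive list.
DEFAULT_DRIVER_GENES = (
    "ALK",
    "KRAS",
    "BRAF",
    "EGFR",
    "RET",
    "ROS1",
    "MET",
    "ERBB2",
    "PIK3CA",
)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def proportion_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage with half-up rounding; the arithmetic behind every table."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and rounding conventions for the cohort tables."""

    tmb_high_threshold: float = 10.0  # mutations/Mb
    pdl1_low_min: float = 1.0  # negative <1, low 1-49, high >=50
    pdl1_high_min: float = 50.0
    oncoprint_min_freq: float = 3.0  # percent, boundary inclusive
    min_reads: int = 5
    prevalence_decimals: int = 2
    fusion_pct_decimals: int = 2
    cohort_pct_decimals: int = 3
    gene_freq_decimals: int = 1
    class_freq_decimals: int = 0
    driver_genes: tuple[str, ...] = DEFAULT_DRIVER_GENES

    def __post_init__(self) -> None:
        if self.tmb_high_threshold <= 0 or self.oncoprint_min_freq <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class SpecimenRecord:
    """Clinical + biomarker + alteration state for one tumor specimen."""

    specimen_id: str
    tumor_type: str
    age: Optional[float] = None
    sex: Optional[str] = None
    stage: str = "unknown"  # "<=III" | "IV" | "unknown"
    tmb: Optional[float] = None
    pdl1_score: Optional[float] = None
    pdl1_score_type: Optional[str] = None  # TPS | CPS
    msi: Optional[str] = None  # MSI-H | MSS
    alterations: tuple[tuple[str, str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.tmb is not None and self.tmb < 0:
            raise ValueError("tmb must be >= 0")
        if self.pdl1_score is not None and not 0 <= self.pdl1_score <= 100:
            raise ValueError("pdl1_score must be in [0, 100]")
        for _, klass, _ in self.alterations:
            if klass not in ALTERATION_CLASSES:
                raise ValueError(f"unknown alteration class {klass!r}")


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "specimen_id",
    "tumor_type",
    "age",
    "sex",
    "stage",
    "tmb",
    "pdl1_score",
    "pdl1_score_type",
    "msi",
    "alterations",
)


def _parse_alterations(cell: str) -> tuple[tuple[str, str, bool], ...]:
    """Decode ``GENE:class:1|GENE:class:0`` cells (1 = known pathogenic)."""
    cell = (cell or "").strip()
    if not cell:
        return ()
    out = []
    for item in cell.split("|"):
        gene, klass, flag = item.split(":")
        out.append((gene, klass, flag == "1"))
    return tuple(out)


def format_alterations(alterations: Iterable[tuple[str, str, bool]]) -> str:
    return "|".join(f"{g}:{k}:{int(p)}" for g, k, p in alterations)


def read_cohort(path) -> pd.DataFrame:
    """Load the specimen table; alterations stay encoded as tuples."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns: {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate specimen_id values")
    df["alterations"] = df["alterations"].fillna("").map(_parse_alterations)
    return df


# ---------------------------------------------------------------------------
# positivity, prevalence, recurrence
# ---------------------------------------------------------------------------


def specimen_positivity(classified: pd.DataFrame) -> dict:
    """Collapse fusion-level verdicts to per-specimen positivity.

    A specimen is positive iff it carries at least one ONCOGENIC or
    LIKELY_ONCOGENIC fusion; a specimen with several qualifying fusions is
    counted once (fusion-level and specimen-level counts are both reported).
    """
    qualifying = classified[classified["verdict"].isin(QUALIFYING_VERDICTS)]
    positive = set(qualifying["specimen_id"])
    return {
        "positive_specimens": positive,
        "n_qualifying_fusions": int(len(qualifying)),
        "n_positive_specimens": len(positive),
    }


def prevalence_table(
    cohort: pd.DataFrame,
    positive_specimens: Iterable[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-tumor-type and overall fusion prevalence.

    percent = 100 * n_positive / n_total, half-up rounded; the overall row
    is labeled ``ALL`` and its counts equal the column sums of the others.
    """
    positive = set(positive_specimens)
    known = set(cohort["specimen_id"])
    stray = positive - known
    if stray:
        raise ValueError(f"positive specimens not in cohort: {sorted(stray)[:5]}")
    flagged = cohort.assign(positive=cohort["specimen_id"].isin(positive))
    rows = []
    for tumor_type, group in flagged.groupby("tumor_type", sort=True):
        rows.append(
            {
                "tumor_type": tumor_type,
                "n_positive": int(group["positive"].sum()),
                "n_total": int(len(group)),
            }
        )
    rows.append(
        {
            "tumor_type": "ALL",
            "n_positive": int(flagged["positive"].sum()),
            "n_total": int(len(flagged)),
        }
    )
    table = pd.DataFrame(rows)
    table["percent"] = [
        proportion_pct(r.n_positive, r.n_total, config.prevalence_decimals)
        for r in table.itertuples()
    ]
    return table


def recurrence_table(
    classified: pd.DataFrame,
    cohort: Optional[pd.DataFrame],
    n_cohort_total: int,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-fusion recurrence among qualifying (oncogenic/likely) fusions.

    fusion% uses the number of positive specimens as denominator; cohort%
    uses the full cohort size.  Sorted by specimen count descending, then
    fusion name.
    """
    pos = specimen_positivity(classified)
    n_positive = pos["n_positive_specimens"]
    if n_cohort_total < n_positive:
        raise ValueError("n_cohort_total smaller than number of positive specimens")
    qualifying = classified[classified["verdict"].isin(QUALIFYING_VERDICTS)]
    type_of = (
        dict(zip(cohort["specimen_id"], cohort["tumor_type"]))
        if cohort is not None
        else {}
    )
    rows = []
    for name, group in qualifying.groupby("fusion_name"):
        specimens = sorted(set(group["specimen_id"]))
        types = pd.Series(
            [type_of.get(s, "unknown") for s in specimens]
        ).value_counts()
        rows.append(
            {
                "fusion_name": name,
                "n_specimens": len(specimens),
                "fusion_pct": proportion_pct(
                    len(specimens), n_positive, config.fusion_pct_decimals
                ),
                "cohort_pct": proportion_pct(
                    len(specimens), n_cohort_total, config.cohort_pct_decimals
                ),
                "verdict": group["verdict"].iloc[0],
                "tumor_types": ", ".join(
                    f"{t} ({n})" for t, n in types.items()
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "fusion_name",
            "n_specimens",
            "fusion_pct",
            "cohort_pct",
            "verdict",
            "tumor_types",
        ],
    )
    return table.sort_values(
        ["n_specimens", "fusion_name"], ascending=[False, True]
    ).reset_index(drop=True)


def partner_novelty_summary(
    classified: pd.DataFrame, kb: KnowledgeBase
) -> tuple[int, int]:
    """(n_known_pairs, n_novel_pairs) over distinct (partner, NTRK) pairs
    among qualifying fusions; the same partner with two NTRK genes is two
    pairs."""
    qualifying = classified[classified["verdict"].isin(QUALIFYING_VERDICTS)]
    pairs = set(zip(qualifying["gene_5p"], qualifying["ntrk_gene"]))
    n_known = sum(1 for p, n in pairs if is_known(partner_status(kb, p, n)))
    return n_known, len(pairs) - n_known


# ---------------------------------------------------------------------------
# co-occurring alterations
# ---------------------------------------------------------------------------


def _pathogenic_alterations(row_alterations) -> list[tuple[str, str]]:
    return [(g, k) for g, k, pathogenic in row_alterations if pathogenic]


def cooccurrence_summary(
    cohort: pd.DataFrame,
    positive_specimens: Iterable[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Per-gene alteration frequencies and oncoprint matrix among positives.

    Only known-pathogenic alterations count.  A specimen with several
    alteration classes in one gene counts once toward that gene's frequency
    but every class appears in the matrix cell.  Genes at or above
    ``oncoprint_min_freq`` percent (boundary inclusive, tested on the exact
    fraction) form the matrix rows; matrix columns are exactly the positive
    specimens.
    """
    positive = sorted(set(positive_specimens))
    subset = cohort[cohort["specimen_id"].isin(positive)]
    n_pos = len(positive)
    if n_pos == 0:
        return {
            "gene_freq": pd.DataFrame(columns=["gene", "n_specimens", "percent"]),
            "matrix": pd.DataFrame(),
            "class_freq": {},
        }

    per_gene: dict[str, set[str]] = {}
    cells: dict[tuple[str, str], set[str]] = {}
    class_hits: dict[str, set[str]] = {"snv_indel": set(), "cnv": set(), "fusion": set()}
    for row in subset.itertuples():
        for gene, klass in _pathogenic_alterations(row.alterations):
            per_gene.setdefault(gene, set()).add(row.specimen_id)
            cells.setdefault((gene, row.specimen_id), set()).add(klass)
            if klass == "snv_indel":
                class_hits["snv_indel"].add(row.specimen_id)
            elif klass in ("cnv_amp", "cnv_loss"):
                class_hits["cnv"].add(row.specimen_id)
            elif klass == "fusion" and gene not in NTRK_GENES:
                class_hits["fusion"].add(row.specimen_id)

    gene_rows = [
        {
            "gene": gene,
            "n_specimens": len(specimens),
            "percent": proportion_pct(
                len(specimens), n_pos, config.gene_freq_decimals
            ),
        }
        for gene, specimens in per_gene.items()
    ]
    gene_freq = (
        pd.DataFrame(gene_rows, columns=["gene", "n_specimens", "percent"])
        .sort_values(["n_specimens", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )

    # boundary-inclusive filter on the exact (unrounded) frequency
    retained = [
        r["gene"]
        for r in gene_rows
        if 100.0 * r["n_specimens"] / n_pos >= config.oncoprint_min_freq - 1e-9
    ]
    retained = [g for g in gene_freq["gene"] if g in set(retained)]
    matrix = pd.DataFrame(
        [
            ["+".join(sorted(cells.get((gene, s), ()))) for s in positive]
            for gene in retained
        ],
        index=retained,
        columns=positive,
    )

    class_freq = {
        f"any_{name}": proportion_pct(len(hits), n_pos, config.class_freq_decimals)
        for name, hits in class_hits.items()
    }
    class_counts = {f"n_{name}": len(hits) for name, hits in class_hits.items()}
    return {
        "gene_freq": gene_freq,
        "matrix": matrix,
        "class_freq": {**class_freq, **class_counts, "n_positive": n_pos},
    }


def driver_cooccurrence(
    cohort: pd.DataFrame,
    positive_specimens: Iterable[str],
    config: AnalysisConfig = AnalysisConfig(),
    tumor_type: Optional[str] = None,
) -> dict:
    """Fraction of positive specimens carrying >=1 pathogenic alteration in
    a configured driver gene (optionally within one tumor type)."""
    positive = set(positive_specimens)
    subset = cohort[cohort["specimen_id"].isin(positive)]
    if tumor_type is not None:
        subset = subset[subset["tumor_type"] == tumor_type]
    drivers = set(config.driver_genes)
    n = len(subset)
    hits = sum(
        1
        for row in subset.itertuples()
        if any(g in drivers for g, _ in _pathogenic_alterations(row.alterations))
    )
    return {
        "n_with_driver": hits,
        "n_positive": n,
        "percent": proportion_pct(hits, n, 0) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# immunotherapy biomarkers
# ---------------------------------------------------------------------------


def biomarker_comparison(
    cohort: pd.DataFrame,
    positive_specimens: Iterable[str],
    biomarker: str,
    tumor_types: Optional[Sequence[str]] = None,
    score_type: Optional[str] = None,
) -> Optional[dict]:
    """Wilcoxon rank-sum comparison of TMB or PD-L1 between NTRK+ and NTRK-.

    TMB is tested on log(TMB + 1) but medians are reported on the original
    mutations/Mb scale (the rank-sum statistic is invariant to the monotone
    transform; the transform matches plotting convention).  PD-L1 is tested
    on the raw 0-100 score, restricted to a single score type — TPS and CPS
    are never pooled.  Missing values are dropped with counts reported.
    Returns ``None`` (with a warning) when either group is empty.
    """
    if biomarker not in ("tmb", "pdl1"):
        raise ValueError("biomarker must be 'tmb' or 'pdl1'")
    subset = cohort
    if tumor_types is not None:
        subset = subset[subset["tumor_type"].isin(tumor_types)]
    if biomarker == "pdl1":
        if score_type is None:
            raise ValueError("PD-L1 comparison requires an explicit score_type")
        subset = subset[subset["pdl1_score_type"] == score_type]
        values = pd.to_numeric(subset["pdl1_score"], errors="coerce")
    else:
        values = pd.to_numeric(subset["tmb"], errors="coerce")

    positive = subset["specimen_id"].isin(set(positive_specimens))
    n_missing = int(values.isna().sum())
    keep = values.notna()
    values, positive = values[keep], positive[keep]
    pos_vals = values[positive].to_numpy(float)
    neg_vals = values[~positive].to_numpy(float)
    if len(pos_vals) == 0 or len(neg_vals) == 0:
        warnings.warn(
            f"{biomarker} stratum skipped: empty group after missing-value removal",
            stacklevel=2,
        )
        return None

    if biomarker == "tmb":
        stat, p = stats.mannwhitneyu(
            np.log(pos_vals + 1.0), np.log(neg_vals + 1.0), alternative="two-sided"
        )
    else:
        stat, p = stats.mannwhitneyu(pos_vals, neg_vals, alternative="two-sided")
    return {
        "biomarker": biomarker,
        "score_type": score_type,
        "median_positive": float(np.median(pos_vals)),
        "median_negative": float(np.median(neg_vals)),
        "n_positive": int(len(pos_vals)),
        "n_negative": int(len(neg_vals)),
        "n_missing_dropped": n_missing,
        "statistic": float(stat),
        "p_value": float(p),
        "p_value_correction": "uncorrected",
    }


def msi_proportions(
    cohort: pd.DataFrame,
    positive_specimens: Iterable[str],
    tumor_types: Optional[Sequence[str]] = None,
) -> dict:
    """MSI-H fraction among NTRK+ and NTRK- separately (no hypothesis test:
    MSI-H group sizes are typically too small)."""
    subset = cohort[cohort["msi"].isin(["MSI-H", "MSS"])]
    if tumor_types is not None:
        subset = subset[subset["tumor_type"].isin(tumor_types)]
    positive = subset["specimen_id"].isin(set(positive_specimens))
    out = {}
    for label, group in (("positive", subset[positive]), ("negative", subset[~positive])):
        n = len(group)
        n_h = int((group["msi"] == "MSI-H").sum())
        out[label] = {
            "n": n,
            "n_msi_h": n_h,
            "pct_msi_h": proportion_pct(n_h, n, 1) if n else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# patient characteristics (age/sex/stage); only exercisable on case-level data
# ---------------------------------------------------------------------------


def patient_characteristics(
    cohort: pd.DataFrame, positive_specimens: Iterable[str]
) -> dict:
    """Age/sex/stage summary of fusion-positive specimens."""
    pos = cohort[cohort["specimen_id"].isin(set(positive_specimens))]
    ages = pd.to_numeric(pos["age"], errors="coerce").dropna()
    stages = pos["stage"].fillna("unknown")
    staged = stages[stages != "unknown"]
    return {
        "n": len(pos),
        "age_median": float(ages.median()) if len(ages) else float("nan"),
        "age_range": (
            (float(ages.min()), float(ages.max())) if len(ages) else (None, None)
        ),
        "sex_counts": pos["sex"].value_counts().to_dict(),
        "stage_counts": stages.value_counts().to_dict(),
        "pct_stage_iv_of_staged": (
            proportion_pct(int((staged == "IV").sum()), len(staged), 0)
            if len(staged)
            else float("nan")
        ),
    }
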