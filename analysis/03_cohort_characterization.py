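#!/usr/bin/env python
"""Step 3 — cohort-level characterization of the simulated screen.

Derives the standard tables from the classified fusions plus specimen
metadata: per-type prevalence, fusion recurrence, partner novelty,
co-occurring pathogenic alterations (oncoprint), and immunotherapy
biomarker comparisons (TMB on log(TMB+1), PD-L1 by score type, MSI-H
proportions).  Writes everything under results/cohort/.
"""

import json
from pathlib import Path

import pandas as pd

from trkfusion.cohort import (
    AnalysisConfig,
    biomarker_comparison,
    cooccurrence_summary,
    msi_proportions,
    partner_novelty_summary,
    prevalence_table,
    read_cohort,
    recurrence_table,
    specimen_positivity,
)
from trkfusion.knowledge_base import default_kb

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    config = AnalysisConfig()
    classified = pd.read_csv(RESULTS / "classified.tsv", sep="\t",
                             dtype={"specimen_id": str})
    cohort = read_cohort(RESULTS / "simulated" / "cohort.tsv")
    pos = specimen_positivity(classified)
    flags = pos["positive_specimens"]

    prevalence = prevalence_table(cohort, flags, config)
    prevalence.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    overall = prevalence.set_index("tumor_type").loc["ALL"]
    print(f"{pos['n_qualifying_fusions']} qualifying fusions in "
          f"{pos['n_positive_specimens']} specimens "
          f"(overall prevalence {overall['percent']}%)")

    recurrence = recurrence_table(classified, cohort, len(cohort), config)
    recurrence.to_csv(out / "recurrence.tsv", sep="\t", index=False)
    recurrent = recurrence[recurrence["n_specimens"] > 1]
    print(f"recurrent fusions (>1 specimen): {len(recurrent)}")

    known, novel = partner_novelty_summary(classified, default_kb())
    print(f"distinct partner pairs: {known} known, {novel} novel")

    co = cooccurrence_summary(cohort, flags, config)
    co["gene_freq"].to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    co["matrix"].to_csv(out / "oncoprint_matrix.tsv", sep="\t")
    top = co["gene_freq"].head(1)
    if len(top):
        print(f"most co-altered gene: {top.iloc[0]['gene']} "
              f"({top.iloc[0]['percent']}% of positives)")

    biomarkers = {}
    for stratum, types, score_type in [
        ("all", None, None),
        ("head_and_neck", ["head_and_neck"], "CPS"),
        ("colorectal", ["colorectal"], "CPS"),
    ]:
        tmb = biomarker_comparison(cohort, flags, "tmb", types)
        pdl1 = (
            biomarker_comparison(cohort, flags, "pdl1", types, score_type)
            if score_type
            else None
        )
        biomarkers[stratum] = {"tmb": tmb, "pdl1": pdl1}
        if tmb:
            print(f"TMB {stratum}: median {tmb['median_positive']} (NTRK+) vs "
                  f"{tmb['median_negative']} (NTRK-), p={tmb['p_value']:.3g} "
                  f"(uncorrected)")
    biomarkers["msi_gi"] = msi_proportions(
        cohort, flags, ["colorectal", "small_intestine"]
    )
    (out / "biomarkers.json").write_text(
        json.dumps(biomarkers, indent=1, sort_keys=True, default=float)
    )
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
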