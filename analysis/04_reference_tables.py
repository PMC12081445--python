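#!/usr/bin/env python
"""Step 4 — reproduce the reference screen's printed tables.

Feeds the transcribed count tables of the published 19,591-specimen
pan-tumor screen through the same analytics operations used in step 3 and
writes the reproduced prevalence/recurrence/co-occurrence tables under
results/reference/.  The printed percentages must re-emerge from the raw
numerators and denominators under the configured half-up rounding.
"""

from pathlib import Path

import trkfusion as tk
from trkfusion.cohort import AnalysisConfig, driver_cooccurrence

RESULTS = Path(__file__).resolve().parents[1] / "results" / "reference"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    config = AnalysisConfig()
    counts = tk.reference_counts()

    cohort, flags = tk.reference_prevalence_inputs()
    prevalence = tk.prevalence_table(cohort, flags, config)
    prevalence.to_csv(RESULTS / "prevalence.tsv", sep="\t", index=False)
    overall = prevalence.set_index("tumor_type").loc["ALL"]
    print(f"overall prevalence: {int(overall['n_positive'])}/"
          f"{int(overall['n_total'])} = {overall['percent']}%")

    classified = tk.reference_classified()
    recurrence = tk.recurrence_table(
        classified, None, counts["total_specimens"], config
    )
    recurrence[recurrence["n_specimens"] > 1].to_csv(
        RESULTS / "recurrence.tsv", sep="\t", index=False
    )
    top = recurrence.iloc[0]
    print(f"most recurrent fusion: {top['fusion_name']} "
          f"(N={top['n_specimens']}, {top['fusion_pct']}% of positives)")

    known, novel = tk.partner_novelty_summary(classified, tk.default_kb())
    print(f"partner pairs: {known} known, {novel} novel")

    pos_cohort, pos_flags = tk.reference_positive_cohort()
    co = tk.cooccurrence_summary(pos_cohort, pos_flags, config)
    co["gene_freq"].to_csv(RESULTS / "cooccurrence.tsv", sep="\t", index=False)
    co["matrix"].to_csv(RESULTS / "oncoprint_matrix.tsv", sep="\t")
    gene = co["gene_freq"].set_index("gene")
    print(f"TP53 co-altered in {gene.loc['TP53', 'percent']}% of positives; "
          f"class frequencies: snv {co['class_freq']['any_snv_indel']}%, "
          f"cnv {co['class_freq']['any_cnv']}%, "
          f"fusion {co['class_freq']['any_fusion']}%")
    drivers = driver_cooccurrence(pos_cohort, pos_flags, config)
    print(f"co-occurring driver in {drivers['percent']}% of positives")
    msi = tk.msi_proportions(pos_cohort, pos_flags,
                             ["colorectal", "small_intestine"])
    print(f"MSI-H among NTRK+ colorectal/small-intestine: "
          f"{msi['positive']['n_msi_h']}/{msi['positive']['n']} "
          f"({msi['positive']['pct_msi_h']}%)")


if __name__ == "__main__":
    main()
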