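#!/usr/bin/env python
"""Step 2 — classify the candidate fusions.

Runs the full classification pipeline (parse -> read-support filter ->
breakpoint annotation -> oncogenicity rules) over the simulated calls from
step 1, writes results/classified.tsv and results/qc.json, and checks the
verdicts against the generator's ground truth.
"""

import json
from pathlib import Path

from trkfusion.classifier import classified_to_frame, classify_batch
from trkfusion.knowledge_base import default_kb
from trkfusion.transcript_model import load_transcripts

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    transcripts = load_transcripts(RESULTS / "simulated" / "transcripts.tsv")
    kb = default_kb()
    classified, qc = classify_batch(
        RESULTS / "simulated" / "fusions.tsv", transcripts, kb, min_reads=5
    )
    frame = classified_to_frame(classified)
    frame.to_csv(RESULTS / "classified.tsv", sep="\t", index=False)
    (RESULTS / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))

    truth = json.loads((RESULTS / "simulated" / "truth.json").read_text())
    expected = {}
    for t in truth["fusion_truths"]:
        if t["passes_read_filter"]:
            expected.setdefault((t["specimen_id"], t["name"]), []).append(t["verdict"])
    got = {}
    for row in frame.itertuples():
        got.setdefault((row.specimen_id, row.fusion_name), []).append(row.verdict)
    agree = sum(
        sorted(got.get(k, [])) == sorted(v) for k, v in expected.items()
    )
    print(f"classified {qc['n_classified']} fusions with KB {qc['kb_version']}")
    print(f"  verdicts: {qc['verdict_counts']}")
    print(f"  filtered for <5 reads: {qc['n_filtered_low_reads']}; "
          f"annotation failures: {qc['n_annotation_failed']}")
    print(f"  ground-truth agreement: {agree}/{len(expected)} fusion events")


if __name__ == "__main__":
    main()
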