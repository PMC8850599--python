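#!/usr/bin/env python
"""Comparative-CT expression analysis of the six candidate markers.

Reads the Ct table and sample metadata from ``results/data/qpcr/``,
collapses technical replicates, computes relative quantities (2^-ddCt),
runs the adaptive group comparisons (control vs PD; control/early/late
with post hocs) and per-marker ROC, and writes:

* ``results/marker_comparisons.tsv`` — the flattened comparison table
* ``results/marker_roc.json``        — AUC, flip flag and curve points
* ``results/relative_expression.tsv``
"""

import json
from pathlib import Path

import pandas as pd

from triadscreen.qpcr import (
    collapse_replicates,
    marker_report,
    relative_expression,
    report_to_frame,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    ct = pd.read_csv(RESULTS / "data" / "qpcr" / "ct_long.tsv", sep="\t")
    meta = pd.read_csv(RESULTS / "data" / "qpcr" / "samples.tsv", sep="\t")

    rel = relative_expression(collapse_replicates(ct), meta)
    rel.to_csv(RESULTS / "relative_expression.tsv", sep="\t", index=False)

    report = marker_report(rel, meta)
    frame = report_to_frame(report)
    frame.to_csv(RESULTS / "marker_comparisons.tsv", sep="\t", index=False)

    roc_out = {}
    for marker, entry in report.items():
        roc = entry["roc"]
        roc_out[marker] = {
            "auc": roc.auc,
            "flipped": roc.flipped,
            "fpr": list(roc.fpr),
            "tpr": list(roc.tpr),
        }
        ctl_pd = next(c for c in entry["comparisons"]
                      if c.comparison == "Controls vs. PD")
        print(f"{marker:16s} direction={entry['direction']:4s} "
              f"AUC={roc.auc:.4f}  {ctl_pd.test_name}: "
              f"p={ctl_pd.p_value:.2e} effect={ctl_pd.effect:+.3f}")
    (RESULTS / "marker_roc.json").write_text(
        json.dumps(roc_out, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
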