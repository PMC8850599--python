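#!/usr/bin/env python
"""Dual-luciferase reporter analysis and seed-site verification.

Reads the plate from ``results/data/reporter/`` and the WT/MT/miRNA
sequences from ``results/data/sequences/``, then writes:

* ``results/reporter_comparisons.tsv`` — percent activity change and
  Bonferroni-corrected p-values per construct versus the negative control
* ``results/seed_sites.json`` — sites found on WT and MT and the
  disruption verdict
"""

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from triadscreen.reporter_seed import (
    compare_reporter_conditions,
    find_seed_sites,
    normalize_reporter,
    verify_mutant_disruption,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def read_single_fasta(path: Path) -> str:
    (record,) = SeqIO.parse(path, "fasta")
    return str(record.seq)


def main() -> None:
    plate = pd.read_csv(RESULTS / "data" / "reporter" / "plate.csv")
    table = compare_reporter_conditions(normalize_reporter(plate))
    table.to_csv(RESULTS / "reporter_comparisons.tsv", sep="\t", index=False)
    for _, row in table.iterrows():
        if row["condition"] == "NC":
            continue
        print(f"{row['condition']}: {row['percent_change']:+.1f}% change, "
              f"p={row['p_value']:.2e}")

    seq_dir = RESULTS / "data" / "sequences"
    wt = read_single_fasta(seq_dir / "wt.fa")
    mt = read_single_fasta(seq_dir / "mt.fa")
    mirna = read_single_fasta(seq_dir / "mirna.fa")
    verdict = verify_mutant_disruption(wt, mt, mirna)
    out = {
        "wt_sites": [
            {"start": s.start, "end": s.end, "class": s.site_class}
            for s in find_seed_sites(mirna, wt)
        ],
        "mt_sites": [
            {"start": s.start, "end": s.end, "class": s.site_class}
            for s in find_seed_sites(mirna, mt)
        ],
        "disrupted": verdict.disrupted,
    }
    (RESULTS / "seed_sites.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )
    print("WT sites:", out["wt_sites"])
    print("mutant disrupts the site:", verdict.disrupted)


if __name__ == "__main__":
    main()
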