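#!/usr/bin/env python
"""Generate every synthetic input for the downstream analysis steps.

Writes, under ``results/data/``:

* ``kb/``         — seven-table knowledge base with planted triads, decoys
                    and ground-truth manifest
* ``qpcr/``       — long-format Ct table and sample metadata at the study
                    design (20 controls, 38 patients)
* ``reporter/``   — dual-luciferase plate
* ``sequences/``  — WT/MT reporter inserts and the miRNA (FASTA)
"""

from pathlib import Path

from triadscreen.simulate import (
    SynthConfig,
    generate_ct_dataset,
    generate_knowledge_base,
    generate_reporter_plate,
    generate_sequences,
)

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
CONFIG = SynthConfig(seed=0)


def main() -> None:
    kb, kb_manifest = generate_knowledge_base(CONFIG, DATA / "kb")
    print(f"knowledge base: {len(kb.mirnas)} miRNAs, "
          f"{len(kb.mirna_lncrna)} miRNA-lncRNA interactions, "
          f"{len(kb_manifest.planted_triads)} planted triads, "
          f"{len(kb_manifest.decoy_stages)} decoys")

    ct, meta, _ = generate_ct_dataset(CONFIG, DATA / "qpcr")
    print(f"qPCR: {len(meta)} samples "
          f"({(meta['group'] == 'control').sum()} control, "
          f"{(meta['group'] == 'PD').sum()} PD), {len(ct)} Ct wells")

    plate, plate_manifest = generate_reporter_plate(CONFIG, DATA / "reporter")
    print(f"reporter: {len(plate)} wells, "
          f"planted inhibition {plate_manifest.inhibition}")

    wt, mt, mirna, seq_manifest = generate_sequences(CONFIG,
                                                     DATA / "sequences")
    print(f"sequences: insert length {len(wt)}, miRNA length {len(mirna)}, "
          f"{seq_manifest.site_class} site at "
          f"[{seq_manifest.site_start}, {seq_manifest.site_end})")


if __name__ == "__main__":
    main()
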