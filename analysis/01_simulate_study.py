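#!/usr/bin/env python
"""Generate the synthetic microcosm study used by the downstream analyses.

Emulates the experimental design: 3 freezing pretreatments (+4 / -20 /
-80 degC) x 3 replicate microcosms, each sequenced before (day 0) and
after (day 7) incubation at +50 degC, at 45,000 reads per library, with
20 thermospore OTUs hidden in a 300-OTU background community. Writes the
count table, sample metadata and ground truth under results/synthetic/.
"""

import json
from pathlib import Path

from thermotrace import tables_io
from thermotrace.synthetic_community import CommunitySimConfig, generate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20190503


def main() -> None:
    cfg = CommunitySimConfig(seed=SEED)
    table, meta, truth = generate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    tables_io.write_otu_table(table, OUT / "otu_counts.tsv")
    tables_io.write_metadata(meta, OUT / "sample_metadata.tsv")
    (OUT / "study_truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "otu_ids": truth.otu_ids,
                "thermospore_ids": truth.thermospore_ids,
                "class_labels": [l for l in truth.class_labels if l],
                "growth_factor": dict(
                    zip(truth.thermospore_ids,
                        truth.growth_factor[truth.is_thermospore].round(1).tolist())
                ),
                "survived": {
                    mc_id: dict(zip(truth.thermospore_ids, mc.survived.tolist()))
                    for mc_id, mc in truth.microcosms.items()
                },
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )

    n_surv = {mc_id: int(mc.survived.sum()) for mc_id, mc in truth.microcosms.items()}
    print(f"simulated {table.n_otus} OTUs x {table.n_samples} samples (seed {SEED})")
    print(f"thermospores surviving per microcosm: {n_surv}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
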