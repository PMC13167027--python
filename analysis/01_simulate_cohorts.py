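#!/usr/bin/env python
"""Generate the truth-labelled datasets every later stage consumes.

Writes under results/data/:
  metagenome/  reference.fasta, genes.bed, one SAM per sample, samples.tsv,
               truth.json  — 8 luna-dominant + 8 lotti-dominant samples over
               200 genes with 12 planted luna-specific genes, at the
               study's depth regimes (50x vs 5x core, 0x specific in
               lotti-dominant samples)
  amplicon/    gill_*.tsv and env_*.tsv ASV tables for 130 hosts and four
               seagrass-habitat compartments, truth.json
"""

import argparse
from pathlib import Path

from symprof import simulate as sim


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out_dir / "data"
    reference, genes, truth = sim.simulate_reference(
        n_genes=200, n_specific=12, gene_length=300, seed=args.seed
    )
    _, metadata, truth = sim.simulate_cohort(
        8, 8, reference, genes, truth, sim.ReadSimParams(),
        seed=args.seed + 1, out_dir=data / "metagenome",
    )
    print(
        f"metagenome cohort: {len(metadata)} samples over {len(genes)} genes "
        f"({len(truth.specific_genes)} planted luna-specific) -> {data / 'metagenome'}"
    )

    amp = data / "amplicon"
    amp.mkdir(parents=True, exist_ok=True)
    gill, env, asv_truth = sim.simulate_asv_dataset(
        sim.ASVSimParams(n_hosts=130), seed=args.seed + 2
    )
    gill.write(amp, prefix="gill")
    env.write(amp, prefix="env")
    asv_truth.write(amp / "truth.json")
    print(
        f"amplicon dataset: {len(gill.sample_ids)} gill + {len(env.sample_ids)} "
        f"environment samples, shared ASVs planted: "
        f"{sorted(asv_truth.shared_asv_ids)} -> {amp}"
    )


if __name__ == "__main__":
    main()
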