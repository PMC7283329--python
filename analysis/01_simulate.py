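#!/usr/bin/env python
"""Generate the synthetic study used by the rest of the analysis.

Writes genotypes (VCF), grain-quality traits (TSV), a synthetic gene
annotation (GFF3), ground truth (JSON) and a rendered hyperspectral scene
(ENVI cubes + sample map) to results/data/. Everything downstream reads only
these files.
"""

import json
from pathlib import Path

from grainspec.synthetic import SimConfig, write_dataset

OUT = Path("results/data")


def main() -> None:
    cfg = SimConfig(seed=1)
    paths = write_dataset(OUT, cfg)
    print(f"simulated {cfg.n_samples} samples, {cfg.n_snps} SNPs, "
          f"{cfg.n_causal} causal chalk loci (effects {cfg.causal_effects})")
    truth = json.loads(Path(paths["truth"]).read_text())
    print(f"causal marker indices: {truth['causal_snp_indices']}")
    print("wrote:", json.dumps(paths, indent=1))


if __name__ == "__main__":
    main()
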