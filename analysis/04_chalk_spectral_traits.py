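#!/usr/bin/env python
"""Relate spectral variation to percent chalk.

Groups wavelengths into five contiguous ranges by K-means on their
across-sample profiles, scores the first principal component of each group
per sample, regresses chalk on each group PC1, and writes the heatmap
clustering order. The PC1 of the 702-922 nm range is saved as the GWAS trait.
"""

import numpy as np
import pandas as pd

from grainspec import chemometrics as chem
from grainspec.imaging import SpectraTable


def main() -> None:
    spectra = SpectraTable.from_tsv("results/spectra.tsv")
    traits = pd.read_csv("results/data/traits.tsv", sep="\t", index_col=0).loc[spectra.sample_ids]
    chalk = traits["chalk"].to_numpy()

    groups = chem.group_wavelengths(spectra, k=5, seed=1)
    rows = []
    for g in range(5):
        pc1 = chem.spectral_trait_pc1(spectra, groups.band_indices(g))
        reg = chem.regress_trait(chalk, pc1.scores)
        rows.append({
            "group": g + 1, "lo_nm": groups.ranges[g][0], "hi_nm": groups.ranges[g][1],
            "pc1_variance_pct": 100 * pc1.variance_proportion,
            "r2_chalk": reg["r2"], "p": reg["p"], "stars": reg["stars"],
        })
    table = pd.DataFrame(rows)
    table.to_csv("results/group_regressions.tsv", sep="\t", index=False)
    best = table.loc[table["r2_chalk"].idxmax()]
    print(table.to_string(index=False))
    print(f"strongest chalk association: group {int(best.group)} "
          f"({best.lo_nm:.0f}-{best.hi_nm:.0f} nm), R^2 = {best.r2_chalk:.2f}")

    wl = spectra.wavelengths
    idx = np.flatnonzero((wl >= 702) & (wl <= 922))
    gwas_trait = chem.spectral_trait_pc1(spectra, idx)
    pd.Series(gwas_trait.scores, index=pd.Index(spectra.sample_ids, name="sample_id"),
              name="pc1_702_922").to_frame().to_csv("results/gwas_trait.tsv", sep="\t")
    print(f"saved 702-922 nm PC1 ({100 * gwas_trait.variance_proportion:.1f}% of "
          f"in-band variance) as the GWAS trait")

    heat = chem.cluster_heatmap(spectra, trait=chalk, metric="pearson", normalize01=True)
    pd.DataFrame({"row": [heat.row_labels[i] for i in heat.leaf_order]}).to_csv(
        "results/heatmap_leaf_order.tsv", sep="\t", index=False)
    print("wrote results/group_regressions.tsv, results/gwas_trait.tsv, "
          "results/heatmap_leaf_order.tsv")


if __name__ == "__main__":
    main()
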