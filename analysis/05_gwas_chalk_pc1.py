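#!/usr/bin/env python
"""Mixed-model GWAS of the 702-922 nm spectral PC1.

QC filters the VCF (missing > 20%, MAF < 0.05), builds 3 structure PCs and a
VanRaden kinship matrix, runs the per-marker REML scan on the non-pigmented
bran subset, attaches Storey q-values, and flags markers at p <= 1e-6.
Writes the per-marker table and Manhattan/QQ data to results/.
"""

import json

import pandas as pd

from grainspec import association as A
from grainspec.pipeline import NON_PIGMENTED


def main() -> None:
    geno = A.read_vcf("results/data/genotypes.vcf")
    trait = pd.read_csv("results/gwas_trait.tsv", sep="\t", index_col=0).iloc[:, 0]
    traits = pd.read_csv("results/data/traits.tsv", sep="\t", index_col=0)
    keep = [s for s in geno.sample_ids if traits.loc[s, "bran_color"] in NON_PIGMENTED]
    idx = [geno.sample_ids.index(s) for s in keep]
    geno = A.GenotypeData(geno.matrix[idx], geno.chrom, geno.pos, geno.ids, keep)

    geno, qc = A.filter_genotypes(geno, max_missing=0.20, min_maf=0.05)
    print(f"QC: kept {qc['n_kept']}/{qc['n_input']} markers "
          f"({qc['dropped_missing']} over missing cap, {qc['dropped_maf']} under MAF)")
    pcs = A.structure_covariates(geno, 3)
    k = A.kinship(geno)
    result = A.mlm_scan(trait, geno, pcs, k)
    result = A.fdr_threshold(result, p_cutoff=1e-6)
    result.table.to_csv("results/association.tsv", sep="\t", index=False)

    plot = A.manhattan_qq_data(result)
    plot["manhattan"][["chrom", "pos", "cum_pos", "neglog10p"]].to_csv(
        "results/manhattan.tsv", sep="\t", index=False)
    plot["qq"].to_csv("results/qq.tsv", sep="\t", index=False)
    n_sig = int(result.table["significant"].sum())
    print(f"{n_sig} markers significant at p <= 1e-6; "
          f"lambda_GC = {plot['lambda_gc']:.3f}")
    top = result.table.nsmallest(5, "p")[["chrom", "pos", "id", "beta", "p", "r2"]]
    print("top markers:")
    print(top.to_string(index=False))
    with open("results/gwas_summary.json", "w") as fh:
        json.dump({"qc": qc, "n_samples": geno.n_samples,
                   "lambda_gc": plot["lambda_gc"], "n_significant": n_sig}, fh, indent=1)


if __name__ == "__main__":
    main()
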