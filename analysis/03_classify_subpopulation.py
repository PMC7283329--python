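#!/usr/bin/env python
"""Classify sub-population (and environment) from the grain spectra.

Fits PLS-DA against binary membership coding with a stratified 10% holdback,
scores per-wavelength importance (VIP), selects wavelengths at the 0.8
threshold, and validates an LDA classifier on the selected bands. Writes
beta/VIP per wavelength and a JSON summary to results/.
"""

import json

import numpy as np
import pandas as pd

from grainspec import chemometrics as chem
from grainspec.imaging import SpectraTable


def classify(spectra, traits, target, seed=1):
    coding = chem.ClassCoding.from_labels(traits[target].to_numpy())
    plsda = chem.fit_plsda(spectra, coding, holdback_fraction=0.10, seed=seed)
    vip = chem.vip(plsda.model)
    selected = chem.select_wavelengths(plsda.model, vip_threshold=0.8)
    lda = chem.fit_lda(
        spectra.subset_bands(np.flatnonzero(np.isin(spectra.wavelengths, selected))),
        coding.labels, plsda.train_idx, plsda.test_idx,
    )
    return coding, plsda, vip, selected, lda


def main() -> None:
    spectra = SpectraTable.from_tsv("results/spectra.tsv")
    traits = pd.read_csv("results/data/traits.tsv", sep="\t", index_col=0).loc[spectra.sample_ids]

    summary = {}
    for target in ("subpop", "environment"):
        coding, plsda, vip, selected, lda = classify(spectra, traits, target)
        summary[target] = {
            "n_components": plsda.model.n_components,
            "pve_per_class_pct": plsda.pve_per_class,
            "plsda_holdback_accuracy": plsda.holdback_accuracy,
            "n_selected_wavelengths": int(selected.size),
            "lda_train_accuracy": lda.train_accuracy,
            "lda_holdback_accuracy": lda.holdback_accuracy,
            "lda_per_class_holdback": lda.per_class_holdback,
        }
        if target == "subpop":
            pd.DataFrame({
                "wavelength_nm": spectra.wavelengths,
                "vip": vip.scores,
                **{f"beta_{c}": plsda.model.beta[:, j] for j, c in enumerate(coding.classes)},
            }).to_csv("results/beta_vip_subpop.tsv", sep="\t", index=False)
        print(f"{target}: LDA holdback accuracy "
              f"{lda.holdback_accuracy:.1%} on {selected.size} selected wavelengths "
              f"({plsda.model.n_components} PLS components)")
    with open("results/classification.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print("wrote results/classification.json, results/beta_vip_subpop.tsv")


if __name__ == "__main__":
    main()
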