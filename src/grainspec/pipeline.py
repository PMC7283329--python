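"""End-to-end orchestration from a single YAML config.

Stage order: (simulate) -> calibrate -> segment -> extract -> preprocess ->
classify and/or trait-spectra -> gwas -> segments -> genes. Every stage
writes plain-text artifacts (TSV/JSON) into the output directory and the run
ends with a manifest recording inputs, parameters, the seed, and a sha256
checksum per artifact; re-running the same config reproduces identical
checksums. A stage failure aborts the run with the failing stage named and a
FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import association as assoc
from . import segments as segs
from .envi import read_envi
from .errors import ConfigurationError, GrainspecError
from .imaging import GrainMask, ReferenceImages, SpectraTable, calibrate, extract_spectra, segment_grains
from .preprocess import apply_chain, parse_chain
from .synthetic import SimConfig, write_dataset

NON_PIGMENTED = {"white", "light_brown", "brown"}

# thresholds the study states once; logged with every run
DEFAULTS = {
    "roi_nm": 750.0,
    "min_area": 50,
    "vip_threshold": 0.8,
    "holdback_fraction": 0.10,
    "n_groups": 5,
    "trait_band_lo": 702.0,
    "trait_band_hi": 922.0,
    "max_missing": 0.20,
    "min_maf": 0.05,
    "n_pcs": 3,
    "p_cutoff": 1e-6,
    "flank_kb": 100,
    "radius_kb": 150,
}


@dataclass
class PipelineConfig:
    """Validated run configuration (see DEFAULTS for the analysis thresholds)."""

    outdir: str
    seed: int = 0
    simulate: bool = False
    sim: dict = field(default_factory=dict)
    # input paths (ignored for stages that are off or simulated)
    raw: str | None = None
    white: str | None = None
    dark: str | None = None
    sample_map: str | None = None
    sample_labels: str | None = None
    traits: str | None = None
    vcf: str | None = None
    gff3: str | None = None
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "extract": True,
            "classify": True,
            "trait_spectra": True,
            "gwas": True,
            "segments": True,
            "genes": False,
        }
    )
    preprocess: str = "none"
    classify_target: str = "subpop"  # or "environment"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged
        if not 0 < self.params["p_cutoff"] < 1:
            raise ConfigurationError("p_cutoff must be in (0, 1)")
        if self.params["flank_kb"] <= 0 or self.params["radius_kb"] <= 0:
            raise ConfigurationError("flank and radius must be positive")
        if self.classify_target not in ("subpop", "environment"):
            raise ConfigurationError("classify_target must be subpop|environment")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        """Check that every enabled stage has its inputs before running."""
        if self.simulate:
            return
        needed = []
        if self.stages.get("extract"):
            needed += [("raw", self.raw), ("white", self.white), ("dark", self.dark)]
        if self.stages.get("classify") or self.stages.get("trait_spectra"):
            needed.append(("traits", self.traits))
        if self.stages.get("gwas"):
            needed.append(("vcf", self.vcf))
        if self.stages.get("genes"):
            needed.append(("gff3", self.gff3))
        missing = [name for name, p in needed if not p or not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing inputs for enabled stages: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also written
    to ``<outdir>/manifest.json``)."""
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": dict(cfg.params),
        "preprocess": cfg.preprocess,
        "stages": {},
        "artifacts": {},
    }
    current = "setup"
    try:
        if cfg.simulate:
            current = "simulate"
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
            paths = write_dataset(outdir / "inputs", sim_cfg)
            cfg.raw = paths.get("raw")
            cfg.white = paths.get("white")
            cfg.dark = paths.get("dark")
            cfg.sample_map = paths.get("sample_map")
            cfg.sample_labels = paths.get("sample_labels")
            cfg.traits = paths["traits"]
            cfg.vcf = paths["vcf"]
            if not cfg.gff3:
                cfg.gff3 = paths.get("gff3")
            manifest["stages"]["simulate"] = "completed"

        spectra = None
        if cfg.stages.get("extract"):
            current = "extract"
            raw, wl = read_envi(cfg.raw)
            white, _ = read_envi(cfg.white)
            dark, _ = read_envi(cfg.dark)
            cube = calibrate(raw, ReferenceImages(white=white, dark=dark), wl)
            sample_map = (
                np.loadtxt(cfg.sample_map, dtype=int) if cfg.sample_map else None
            )
            mask = segment_grains(
                cube,
                roi_wavelength=cfg.params["roi_nm"],
                min_area=cfg.params["min_area"],
                sample_map=sample_map,
            )
            labels = None
            if cfg.sample_labels:
                labels = {
                    int(k): v
                    for k, v in json.loads(Path(cfg.sample_labels).read_text()).items()
                }
            spectra = extract_spectra(cube, mask, labels)
            spectra = apply_chain(spectra, parse_chain(cfg.preprocess))
            spectra.to_tsv(outdir / "spectra.tsv")
            manifest["stages"]["extract"] = "completed"

        traits = None
        if cfg.traits:
            traits = pd.read_csv(cfg.traits, sep="\t", index_col=0)
        if spectra is None and (
            cfg.stages.get("classify") or cfg.stages.get("trait_spectra")
        ):
            spectra = SpectraTable.from_tsv(outdir / "spectra.tsv")
        if spectra is not None and traits is not None:
            traits = traits.loc[spectra.sample_ids]

        if cfg.stages.get("classify"):
            current = "classify"
            target = "subpop" if cfg.classify_target == "subpop" else "environment"
            coding = chem.ClassCoding.from_labels(traits[target].to_numpy())
            plsda = chem.fit_plsda(
                spectra,
                coding,
                holdback_fraction=cfg.params["holdback_fraction"],
                seed=cfg.seed,
            )
            vip_scores = chem.vip(plsda.model)
            selected = chem.select_wavelengths(
                plsda.model, vip_threshold=cfg.params["vip_threshold"]
            )
            sel_idx = np.isin(spectra.wavelengths, selected)
            lda = chem.fit_lda(
                spectra.subset_bands(np.flatnonzero(sel_idx)),
                coding.labels,
                plsda.train_idx,
                plsda.test_idx,
            )
            pd.DataFrame(
                {
                    "wavelength_nm": spectra.wavelengths,
                    "vip": vip_scores.scores,
                    **{
                        f"beta_{c}": plsda.model.beta[:, j]
                        for j, c in enumerate(coding.classes)
                    },
                }
            ).to_csv(outdir / "beta_vip.tsv", sep="\t", index=False)
            pd.DataFrame({"selected_nm": selected}).to_csv(
                outdir / "selected_wavelengths.tsv", sep="\t", index=False
            )
            summary = {
                "target": target,
                "n_components": plsda.model.n_components,
                "plsda_train_accuracy": plsda.train_accuracy,
                "plsda_holdback_accuracy": plsda.holdback_accuracy,
                "pve_per_class": plsda.pve_per_class,
                "n_selected_wavelengths": int(sel_idx.sum()),
                "lda_train_accuracy": lda.train_accuracy,
                "lda_holdback_accuracy": lda.holdback_accuracy,
                "lda_per_class_holdback": lda.per_class_holdback,
            }
            (outdir / "classification.json").write_text(json.dumps(summary, indent=1))
            manifest["stages"]["classify"] = "completed"

        trait_pc1 = None
        if cfg.stages.get("trait_spectra"):
            current = "trait_spectra"
            groups = chem.group_wavelengths(
                spectra, k=cfg.params["n_groups"], seed=cfg.seed
            )
            rows = []
            pc1_cols = {}
            for g in range(cfg.params["n_groups"]):
                trait_g = chem.spectral_trait_pc1(spectra, groups.band_indices(g))
                pc1_cols[f"group{g + 1}_pc1"] = trait_g.scores
                reg = chem.regress_trait(traits["chalk"].to_numpy(), trait_g.scores)
                rows.append(
                    {
                        "group": g + 1,
                        "lo_nm": groups.ranges[g][0],
                        "hi_nm": groups.ranges[g][1],
                        "variance_proportion": trait_g.variance_proportion,
                        "r2_chalk": reg["r2"],
                        "p_chalk": reg["p"],
                        "stars": reg["stars"],
                    }
                )
            # the GWAS trait: PC1 of the configured chalk-associated range
            lo, hi = cfg.params["trait_band_lo"], cfg.params["trait_band_hi"]
            band_idx = np.flatnonzero(
                (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
            )
            gwas_trait = chem.spectral_trait_pc1(spectra, band_idx)
            trait_pc1 = pd.Series(
                gwas_trait.scores, index=spectra.sample_ids, name="pc1_trait_band"
            )
            pc1 = pd.DataFrame(pc1_cols, index=pd.Index(spectra.sample_ids, name="sample_id"))
            pc1["pc1_trait_band"] = trait_pc1
            pc1.to_csv(outdir / "pc1_traits.tsv", sep="\t")
            pd.DataFrame(rows).to_csv(outdir / "group_regressions.tsv", sep="\t", index=False)
            manifest["stages"]["trait_spectra"] = "completed"

        result = None
        geno = None
        if cfg.stages.get("gwas"):
            current = "gwas"
            geno = assoc.read_vcf(cfg.vcf)
            if trait_pc1 is None:
                pc1 = pd.read_csv(outdir / "pc1_traits.tsv", sep="\t", index_col=0)
                trait_pc1 = pc1["pc1_trait_band"]
            # only non-pigmented bran samples enter the scan
            if traits is not None and "bran_color" in traits:
                keep_ids = [
                    s
                    for s in geno.sample_ids
                    if s in traits.index and traits.loc[s, "bran_color"] in NON_PIGMENTED
                ]
                keep = [geno.sample_ids.index(s) for s in keep_ids]
                geno = assoc.GenotypeData(
                    geno.matrix[keep], geno.chrom, geno.pos, geno.ids, keep_ids
                )
            geno, qc_report = assoc.filter_genotypes(
                geno, cfg.params["max_missing"], cfg.params["min_maf"]
            )
            pcs = assoc.structure_covariates(geno, cfg.params["n_pcs"])
            k = assoc.kinship(geno)
            np.savetxt(outdir / "kinship.tsv", k.values, delimiter="\t")
            result = assoc.mlm_scan(trait_pc1, geno, pcs, k)
            result = assoc.fdr_threshold(result, p_cutoff=cfg.params["p_cutoff"])
            result.table.to_csv(outdir / "association.tsv", sep="\t", index=False)
            plot = assoc.manhattan_qq_data(result)
            plot["manhattan"].to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
            plot["qq"].to_csv(outdir / "qq.tsv", sep="\t", index=False)
            (outdir / "gwas_summary.json").write_text(
                json.dumps(
                    {
                        "qc": qc_report,
                        "n_samples": geno.n_samples,
                        "lambda_gc": plot["lambda_gc"],
                        "n_significant": int(result.table["significant"].sum()),
                    },
                    indent=1,
                )
            )
            manifest["stages"]["gwas"] = "completed"

        segments = None
        if cfg.stages.get("segments"):
            current = "segments"
            if result is None:
                table = pd.read_csv(outdir / "association.tsv", sep="\t")
                result = assoc.AssociationResult(table, cfg.params["p_cutoff"])
            sig = result.significant().sort_values(["chrom", "pos"])
            chrom_lengths = None
            if geno is not None:
                chrom_lengths = {
                    str(c): int(geno.pos[geno.chrom == c].max()) + cfg.params["flank_kb"] * 1000
                    for c in pd.unique(geno.chrom)
                }
            segments = segs.define_segments(
                sig[["chrom", "pos", "p"]].itertuples(index=False),
                flank=cfg.params["flank_kb"] * 1000,
                chrom_lengths=chrom_lengths,
            )
            segs.segments_to_frame(segments).to_csv(
                outdir / "segments.tsv", sep="\t", index=False
            )
            manifest["stages"]["segments"] = "completed"

        if cfg.stages.get("genes"):
            current = "genes"
            genes = segs.read_gff3_genes(cfg.gff3)
            hits = segs.candidate_genes(
                segments, genes, radius=cfg.params["radius_kb"] * 1000
            )
            pd.DataFrame(
                [
                    {
                        "chrom": h.segment.chrom,
                        "peak_pos": h.segment.peak_pos,
                        "gene_id": h.gene_id,
                        "distance_bp": h.distance,
                        "description": h.description,
                    }
                    for h in hits
                ]
            ).to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
            manifest["stages"]["genes"] = "completed"

    except GrainspecError as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise GrainspecError(f"stage {current!r} failed: {exc}") from exc

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
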