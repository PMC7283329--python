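"""Synthetic rice-grain study generator.

Emulates the statistical structure of a multi-environment diversity-panel
grain-quality study so every pipeline stage is testable without external
data:

* **Genotypes** — biallelic SNPs on several chromosomes for a panel split
  into sub-populations. Sub-population allele frequencies are drawn around a
  shared ancestral frequency by the Balding-Nichols model, with divergence
  controlled by a single Fst parameter; a few designated causal loci carry
  additive effects on grain chalk. Missing calls are injected completely at
  random.
* **Traits** — percent chalk is the clipped sum of the causal additive
  effects, sub-population and environment shifts, and Gaussian noise;
  secondary grain traits (amylose, ASV, kernel dimensions) are generated with
  configurable correlation to chalk.
* **Scenes** — grains are rendered as non-overlapping ellipses on a dark
  background, one grid cell of grains per sample. A pixel's spectrum is the
  sample's bran-class baseline, plus a chalk-proportional loading supported
  only on the chalk band (690-920 nm by default), plus environment-specific
  band offsets and sub-population visible-range offsets, plus noise. Raw
  camera counts are constructed so that white/dark calibration recovers the
  designed reflectance exactly when noise is zero.

All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .association import MISSING, GenotypeData, write_vcf
from .envi import write_envi
from .errors import CapacityError, ConfigurationError
from .imaging import ReferenceImages, SpectraTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "Scene",
    "default_wavelengths",
    "simulate_genotypes",
    "simulate_traits",
    "render_scene",
    "write_scene",
    "write_truth",
]


def default_wavelengths() -> np.ndarray:
    """400-1004 nm at 4 nm spacing (152 bands)."""
    return np.arange(400.0, 1004.0 + 1e-9, 4.0)


# default bran baselines: (visible-plateau, NIR-plateau) reflectance.
# Non-pigmented bran classes differ chiefly in the visible range and converge
# in the NIR, where chalk is the dominant source of variation.
_DEFAULT_PALETTE = {
    "white": (0.46, 0.60),
    "light_brown": (0.40, 0.60),
    "brown": (0.33, 0.60),
}

# default environment offsets: env -> list of ((lo_nm, hi_nm), reflectance offset)
_DEFAULT_ENV_OFFSETS = {
    "TX08": [((400.0, 460.0), 0.030), ((930.0, 1004.0), 0.008)],
    "AR09": [((740.0, 960.0), 0.004)],
    "AR10": [((745.0, 900.0), -0.004)],
}

_DEFAULT_SUBPOPS = ("IND", "TEJ", "TRJ")

# bran-class frequencies differ by sub-population (the visible-range signal
# that lets spectra discriminate sub-populations)
_DEFAULT_BRAN_PROBS = {
    "IND": {"white": 0.70, "light_brown": 0.20, "brown": 0.10},
    "TEJ": {"white": 0.30, "light_brown": 0.50, "brown": 0.20},
    "TRJ": {"white": 0.15, "light_brown": 0.30, "brown": 0.55},
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the desk-scale shape of a three-sub-population,
    three-environment panel: 132 samples (the size of a non-pigmented-bran
    GWAS subset), moderate divergence (Fst 0.15), three causal chalk loci
    whose additive effects dominate the chalk variance, a chalk-proportional
    reflectance loading on 690-920 nm, and ~4 nm band spacing over
    400-1004 nm.
    """

    n_samples: int = 132
    n_subpops: int = 3
    subpop_names: tuple = _DEFAULT_SUBPOPS
    fst: float = 0.15
    n_snps: int = 3000
    n_chromosomes: int = 5
    chrom_length: int = 30_000_000
    n_causal: int = 3
    causal_effects: tuple = (8.0, 6.0, 5.0)  # chalk % per alt allele
    missing_rate: float = 0.02
    chalk_baseline: float = 10.0
    chalk_noise_sd: float = 3.0
    subpop_chalk_shift: dict = field(
        default_factory=lambda: {"IND": 2.0, "TEJ": 0.0, "TRJ": 1.0}
    )
    env_names: tuple = ("TX08", "AR09", "AR10")
    env_chalk_shift: dict = field(
        default_factory=lambda: {"TX08": 4.0, "AR09": 0.0, "AR10": 2.0}
    )
    chalk_band_lo: float = 690.0
    chalk_band_hi: float = 920.0
    chalk_loading: float = 0.004  # peak reflectance per chalk %
    env_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_ENV_OFFSETS))
    bran_palette: dict = field(default_factory=lambda: dict(_DEFAULT_PALETTE))
    bran_probs_by_subpop: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_BRAN_PROBS.items()}
    )
    subpop_vis_offset: dict = field(
        default_factory=lambda: {"IND": 0.012, "TEJ": 0.0, "TRJ": -0.012}
    )
    trait_corr_amylose: float = 0.55
    noise_sd: float = 0.01  # per-pixel reflectance noise
    grains_per_sample: int = 5
    cell_px: int = 44
    # semi-axis range keeps every grain above the 50 px noise-removal floor
    grain_semiaxes: tuple = (4.2, 6.5)
    background_reflectance: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ConfigurationError("fst must be in (0, 1)")
        if self.n_causal > self.n_snps:
            raise ConfigurationError("n_causal must be <= n_snps")
        if len(self.causal_effects) != self.n_causal:
            raise ConfigurationError("causal_effects length must equal n_causal")
        if self.chalk_band_lo >= self.chalk_band_hi:
            raise ConfigurationError("chalk_band_lo must be < chalk_band_hi")
        if self.noise_sd < 0 or self.chalk_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if self.n_subpops != len(self.subpop_names):
            raise ConfigurationError("subpop_names length must equal n_subpops")
        if self.n_samples < self.n_subpops:
            raise ConfigurationError("need at least one sample per sub-population")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelengths()

    def chalk_band_mask(self) -> np.ndarray:
        wl = self.wavelengths
        return (wl >= self.chalk_band_lo) & (wl <= self.chalk_band_hi)


@dataclass
class SimTruth:
    """Ground truth carried alongside the generated artifacts."""

    causal_snp_indices: np.ndarray
    causal_effects: np.ndarray
    causal_dosages: np.ndarray  # pristine (pre-missingness) dosages, n x n_causal
    subpop: np.ndarray
    environment: np.ndarray
    bran_class: np.ndarray
    chalk: np.ndarray | None = None
    discriminative_bands: np.ndarray | None = None  # per-wavelength flags

    def validate(self, n_snps: int) -> None:
        if np.any(self.causal_snp_indices >= n_snps):
            raise ConfigurationError("causal index beyond n_snps")
        if self.chalk is not None and (
            self.chalk.min() < 0 or self.chalk.max() > 100
        ):
            raise ConfigurationError("chalk outside [0, 100]")


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeData, SimTruth]:
    """Structured genotypes under the Balding-Nichols model.

    Per SNP, an ancestral frequency p0 ~ U(0.1, 0.9) is perturbed per
    sub-population by Beta(p0 (1-F)/F, (1-p0)(1-F)/F); dosages are
    Binomial(2, p_subpop). Causal loci are drawn among markers that are
    clearly polymorphic overall so they survive MAF filtering.
    """
    rng = _rng(cfg, 0)
    n, m = cfg.n_samples, cfg.n_snps
    f = cfg.fst

    sizes = np.full(cfg.n_subpops, n // cfg.n_subpops)
    sizes[: n % cfg.n_subpops] += 1
    subpop = np.repeat(np.asarray(cfg.subpop_names, dtype=object), sizes)

    p0 = rng.uniform(0.1, 0.9, size=m)
    a = p0 * (1 - f) / f
    b = (1 - p0) * (1 - f) / f
    pk = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpops, m))
    sub_idx = np.searchsorted(np.cumsum(sizes), np.arange(n), side="right")
    dosage = rng.binomial(2, pk[sub_idx, :]).astype(np.int8)

    # marker map: even split over chromosomes, sorted unique positions
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chroms, poss = [], []
    for c, cnt in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length + 1), size=cnt, replace=False))
        chroms.append(np.full(cnt, f"chr{c}", dtype=object))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    ids = np.array([f"SNP-{c}-{p}" for c, p in zip(chrom, pos)], dtype=object)

    overall = dosage.mean(axis=0) / 2.0
    eligible = np.flatnonzero((overall >= 0.15) & (overall <= 0.85))
    if eligible.size < cfg.n_causal:
        raise ConfigurationError("too few polymorphic markers for causal loci")
    causal = np.sort(rng.choice(eligible, size=cfg.n_causal, replace=False))
    causal_dosages = dosage[:, causal].astype(float)

    matrix = dosage.copy()
    if cfg.missing_rate > 0:
        miss = rng.random(matrix.shape) < cfg.missing_rate
        matrix[miss] = MISSING

    env = np.asarray(
        [cfg.env_names[i % len(cfg.env_names)] for i in range(n)], dtype=object
    )
    classes = np.asarray(sorted(cfg.bran_palette), dtype=object)
    bran = np.empty(n, dtype=object)
    for i, sp in enumerate(subpop):
        probs = cfg.bran_probs_by_subpop.get(sp)
        if probs:
            pvec = np.array([probs.get(c, 0.0) for c in classes])
            pvec = pvec / pvec.sum()
        else:
            pvec = np.full(classes.size, 1.0 / classes.size)
        bran[i] = rng.choice(classes, p=pvec)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    geno = GenotypeData(matrix, chrom, pos, ids, sample_ids)
    truth = SimTruth(
        causal_snp_indices=causal,
        causal_effects=np.asarray(cfg.causal_effects, dtype=float),
        causal_dosages=causal_dosages,
        subpop=subpop,
        environment=env,
        bran_class=bran,
        discriminative_bands=cfg.chalk_band_mask(),
    )
    truth.validate(m)
    return geno, truth


def simulate_traits(
    geno: GenotypeData, truth: SimTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Per-sample grain-quality traits; chalk is the association target.

    chalk = baseline + sum(causal effects x dosage) + sub-population shift
    + environment shift + N(0, chalk_noise_sd), clipped to [0, 100].
    Amylose is generated with configurable correlation to chalk; kernel
    dimensions and ASV are weakly structured fillers.
    """
    rng = _rng(cfg, 1)
    n = geno.n_samples
    genetic = truth.causal_dosages @ truth.causal_effects
    sub_shift = np.array([cfg.subpop_chalk_shift.get(s, 0.0) for s in truth.subpop])
    env_shift = np.array([cfg.env_chalk_shift.get(e, 0.0) for e in truth.environment])
    chalk = (
        cfg.chalk_baseline
        + genetic
        + sub_shift
        + env_shift
        + rng.normal(0, cfg.chalk_noise_sd, size=n)
    )
    chalk = np.clip(chalk, 0.0, 100.0)
    truth.chalk = chalk
    truth.validate(geno.n_markers)

    rho = cfg.trait_corr_amylose
    z = (chalk - chalk.mean()) / (chalk.std() or 1.0)
    amylose = 20.0 + 3.0 * (rho * z + np.sqrt(max(1 - rho**2, 0)) * rng.normal(size=n))
    asv = np.clip(np.round(4.0 + rng.normal(0, 1.2, size=n)), 1, 7)
    length = 7.0 + 0.3 * rng.normal(size=n) - 0.1 * rho * z
    width = 2.2 + 0.12 * rng.normal(size=n) + 0.05 * rho * z
    thickness = 1.8 + 0.08 * rng.normal(size=n)
    return pd.DataFrame(
        {
            "chalk": chalk,
            "amylose": amylose,
            "asv": asv,
            "length_mm": length,
            "width_mm": width,
            "thickness_mm": thickness,
            "bran_color": truth.bran_class,
            "subpop": truth.subpop,
            "environment": truth.environment,
        },
        index=pd.Index(geno.sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# scene rendering


@dataclass
class Scene:
    """A rendered acquisition: raw counts + references + ground truth."""

    raw: np.ndarray
    refs: ReferenceImages
    wavelengths: np.ndarray
    sample_map: np.ndarray  # per-pixel sample index (1-based), 0 = background
    truth_mask: np.ndarray  # boolean grain mask
    designed_spectra: SpectraTable  # noise-free per-sample reflectance
    sample_labels: dict  # label int -> sample_id


def _bran_baseline(cfg: SimConfig, bran_class: str) -> np.ndarray:
    vis, nir = cfg.bran_palette[bran_class]
    wl = cfg.wavelengths
    ramp = 1.0 / (1.0 + np.exp(-(wl - 620.0) / 45.0))  # smooth vis->NIR transition
    return vis + (nir - vis) * ramp


def designed_spectrum(
    cfg: SimConfig, bran_class: str, chalk: float, environment: str, subpop: str
) -> np.ndarray:
    """Noise-free reflectance for one sample."""
    wl = cfg.wavelengths
    spec = _bran_baseline(cfg, bran_class).copy()
    band = cfg.chalk_band_mask()
    if band.any():
        lo, hi = cfg.chalk_band_lo, cfg.chalk_band_hi
        bump = np.sin(np.pi * (wl[band] - lo) / (hi - lo))
        spec[band] += cfg.chalk_loading * chalk * bump
    for (lo, hi), off in cfg.env_offsets.get(environment, []):
        spec[(wl >= lo) & (wl <= hi)] += off
    vis = wl <= 700.0
    spec[vis] += cfg.subpop_vis_offset.get(subpop, 0.0)
    return spec


def render_scene(traits: pd.DataFrame, cfg: SimConfig) -> Scene:
    """Render one scene with a grid cell of grain ellipses per sample.

    Raw counts are D + I (W - D) for a smoothly varying white reference W and
    constant dark current D, so calibration recovers the designed
    reflectance exactly at noise_sd = 0.
    """
    missing = [b for b in pd.unique(traits["bran_color"]) if b not in cfg.bran_palette]
    if missing:
        raise ConfigurationError(f"bran classes without palette entry: {missing}")
    rng = _rng(cfg, 2)
    n = len(traits)
    wl = cfg.wavelengths
    n_bands = wl.size

    n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    cell = cfg.cell_px
    rows_px, cols_px = n_rows * cell, n_cols * cell

    lab = np.zeros((rows_px, cols_px), dtype=int)
    r_min, r_max = cfg.grain_semiaxes
    if 2 * r_max >= cell:
        raise CapacityError("cell too small for the configured grain size")
    yy, xx = np.mgrid[0:cell, 0:cell]
    for i in range(n):
        cr, cc = divmod(i, n_cols)
        cell_mask = np.zeros((cell, cell), dtype=bool)
        placed = 0
        attempts = 0
        while placed < cfg.grains_per_sample:
            attempts += 1
            if attempts > 200 * cfg.grains_per_sample:
                raise CapacityError(
                    f"could not place {cfg.grains_per_sample} grains in a "
                    f"{cell}x{cell} px cell"
                )
            ra = rng.uniform(r_min, r_max)
            rb = rng.uniform(r_min, r_max)
            cy = rng.uniform(r_max + 1, cell - r_max - 1)
            cx = rng.uniform(r_max + 1, cell - r_max - 1)
            ell = ((yy - cy) / ra) ** 2 + ((xx - cx) / rb) ** 2 <= 1.0
            if (ell & cell_mask).any():
                continue
            cell_mask |= ell
            placed += 1
        lab[cr * cell : (cr + 1) * cell, cc * cell : (cc + 1) * cell][cell_mask] = i + 1

    spectra = np.empty((n, n_bands))
    for i, (sid, row) in enumerate(traits.iterrows()):
        spectra[i] = designed_spectrum(
            cfg, row["bran_color"], float(row["chalk"]), row["environment"], row["subpop"]
        )
    background = np.full(n_bands, cfg.background_reflectance)
    lookup = np.vstack([background, spectra])  # index 0 = background
    reflect = lookup[lab]
    if cfg.noise_sd > 0:
        reflect = reflect + rng.normal(0, cfg.noise_sd, size=reflect.shape)

    # references: smooth spatial/spectral variation in W, constant dark
    col_profile = 1.0 + 0.05 * np.sin(np.linspace(0, np.pi, cols_px))
    band_profile = 3200.0 + 600.0 * np.sin(np.linspace(0.3, 2.6, n_bands))
    white = col_profile[None, :, None] * band_profile[None, None, :]
    white = np.broadcast_to(white, reflect.shape).copy()
    dark = np.full_like(white, 120.0)
    raw = dark + reflect * (white - dark)

    designed = SpectraTable(
        sample_ids=list(traits.index), spectra=spectra, wavelengths=wl
    )
    return Scene(
        raw=raw,
        refs=ReferenceImages(white=white, dark=dark),
        wavelengths=wl,
        sample_map=lab,
        truth_mask=lab > 0,
        designed_spectra=designed,
        sample_labels={i + 1: sid for i, sid in enumerate(traits.index)},
    )


# ---------------------------------------------------------------------------
# serialization


def write_scene(scene: Scene, outdir: str | Path, stem: str = "scene") -> dict:
    """Write the scene as ENVI cubes plus a plain-text sample map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": str(outdir / f"{stem}_raw.hdr"),
        "white": str(outdir / f"{stem}_white.hdr"),
        "dark": str(outdir / f"{stem}_dark.hdr"),
        "sample_map": str(outdir / f"{stem}_sample_map.txt"),
        "sample_labels": str(outdir / f"{stem}_sample_labels.json"),
    }
    write_envi(paths["raw"], scene.raw, scene.wavelengths)
    write_envi(paths["white"], scene.refs.white, scene.wavelengths)
    write_envi(paths["dark"], scene.refs.dark, scene.wavelengths)
    np.savetxt(paths["sample_map"], scene.sample_map, fmt="%d")
    Path(paths["sample_labels"]).write_text(
        json.dumps({str(k): v for k, v in scene.sample_labels.items()}, indent=1)
    )
    return paths


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "causal_snp_indices": truth.causal_snp_indices.tolist(),
        "causal_effects": truth.causal_effects.tolist(),
        "subpop": truth.subpop.tolist(),
        "environment": truth.environment.tolist(),
        "bran_class": truth.bran_class.tolist(),
        "chalk": None if truth.chalk is None else truth.chalk.tolist(),
        "discriminative_bands": (
            None
            if truth.discriminative_bands is None
            else truth.discriminative_bands.astype(int).tolist()
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_annotation(
    geno: GenotypeData,
    truth: SimTruth,
    path: str | Path,
    genes_per_chrom: int = 40,
    causal_gene_offset: int = 20_000,
) -> None:
    """Write a synthetic GFF3 gene annotation for the simulated genome.

    Random gene spans tile each chromosome, plus one named gene placed within
    ``causal_gene_offset`` bp of every causal SNP so the candidate-gene search
    has planted hits. Synthetic stand-in for a real genome annotation.
    """
    rng = np.random.default_rng(geno.n_markers)
    lines = ["##gff-version 3"]
    counter = 0
    for c in pd.unique(geno.chrom):
        length = int(geno.pos[geno.chrom == c].max()) + 100_000
        starts = np.sort(rng.choice(np.arange(1, length, 5_000), genes_per_chrom, replace=False))
        for s in starts:
            counter += 1
            stop = int(min(s + rng.integers(1_000, 8_000), length))
            lines.append(
                f"{c}\tsynthetic\tgene\t{int(s)}\t{stop}\t.\t+\t.\t"
                f"ID=SYNG_{counter:04d};description=synthetic gene"
            )
    for k, idx in enumerate(truth.causal_snp_indices):
        c, p = geno.chrom[idx], int(geno.pos[idx])
        start = max(1, p + causal_gene_offset)
        lines.append(
            f"{c}\tsynthetic\tgene\t{start}\t{start + 3_000}\t.\t-\t.\t"
            f"ID=CAUSAL_NEIGHBOR_{k + 1};description=planted near causal locus"
        )
    body = sorted(lines[1:], key=lambda l: (l.split("\t")[0], int(l.split("\t")[3])))
    Path(path).write_text("\n".join([lines[0], *body]) + "\n")


def write_dataset(outdir: str | Path, cfg: SimConfig, render: bool = True) -> dict:
    """Generate and serialize a full synthetic study (genotypes, traits,
    optional scene). Returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, truth = simulate_genotypes(cfg)
    traits = simulate_traits(geno, truth, cfg)
    paths = {
        "vcf": str(outdir / "genotypes.vcf"),
        "traits": str(outdir / "traits.tsv"),
        "truth": str(outdir / "truth.json"),
        "gff3": str(outdir / "annotation.gff3"),
    }
    write_vcf(geno, paths["vcf"])
    traits.to_csv(paths["traits"], sep="\t")
    write_truth(truth, paths["truth"])
    write_annotation(geno, truth, paths["gff3"])
    if render:
        scene = render_scene(traits, cfg)
        paths.update(write_scene(scene, outdir))
    return paths
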