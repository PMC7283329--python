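"""Mixed-linear-model association scan on spectral traits.

Genotypes are biallelic SNPs coded 0/1/2 (alt-allele dosage, -1 missing).
QC drops markers with missing rate > 20% or minor allele frequency < 0.05.
Population structure enters the model twice: as fixed covariates (top
principal components of the standardized genotype matrix) and as a random
polygenic term with VanRaden kinship covariance.

For each marker the model is

    y = mu + C g + x_m b + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

Variance components are re-estimated for every marker ("each marker",
no-compression) by REML over the ratio d = se^2/sg^2, using the
eigendecomposition K = U S U' computed once: rotating by U' makes the
covariance diagonal, so each candidate d costs one weighted least squares
solve. The marker test is a Wald t-test on b with n - q residual degrees of
freedom, which collapses exactly to the ordinary single-coefficient F-test
when K = I. Missing calls are excluded marker-wise (the sub-panel kinship is
re-eigendecomposed per missingness pattern, cached).

Genome-wide significance uses a fixed p cutoff (default 1e-6) chosen via FDR
analysis; q-values are Storey's estimator with a smoother for pi0 (pi0 = 1
reduces to Benjamini-Hochberg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from scipy.optimize import minimize_scalar

from .errors import (
    AlignmentError,
    DimensionError,
    EmptyPanelError,
    KinshipError,
)

MISSING = -1

__all__ = [
    "GenotypeData",
    "KinshipMatrix",
    "AssociationResult",
    "read_vcf",
    "write_vcf",
    "filter_genotypes",
    "structure_covariates",
    "kinship",
    "mlm_scan",
    "fdr_threshold",
    "manhattan_qq_data",
]


@dataclass
class GenotypeData:
    """SNP dosage matrix (samples x markers) with marker metadata."""

    matrix: np.ndarray  # int8, 0/1/2, MISSING=-1
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if self.matrix.shape != (len(self.sample_ids), self.pos.size):
            raise ValueError("matrix shape does not match sample/marker counts")
        valid = np.isin(self.matrix, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.pos.size

    def take_markers(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.matrix[:, index], self.chrom[index], self.pos[index],
            self.ids[index], self.sample_ids,
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        m = self.matrix.astype(float)
        obs = m != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(m == MISSING, 0, m).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def imputed(self) -> np.ndarray:
        """Float matrix with missing calls replaced by the marker mean (2p)."""
        x = self.matrix.astype(float)
        p = self.allele_freq()
        miss = x == MISSING
        return np.where(miss, (2.0 * p)[None, :], x)


def read_vcf(path: str | Path) -> GenotypeData:
    """Read GT dosages from a (plain or bgzipped) VCF; multi-allelic sites
    are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, chroms, poss, ids = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = var.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic site(s)")
    matrix = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeData(matrix, np.array(chroms), np.array(poss), np.array(ids), samples)


def write_vcf(geno: GenotypeData, path: str | Path) -> None:
    """Write dosages as a minimal diploid GT-only VCF (ref A, alt T)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.chrom):
            maxpos = int(geno.pos[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={maxpos}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in geno.sample_ids) + "\n")
        for j in range(geno.n_markers):
            calls = "\t".join(gt_str[int(g)] for g in geno.matrix[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# QC and structure


def filter_genotypes(
    geno: GenotypeData, max_missing: float = 0.20, min_maf: float = 0.05
) -> tuple[GenotypeData, dict]:
    """Drop markers failing the missing-rate or MAF filter.

    MAF is computed over non-missing calls. Returns the filtered panel and a
    report with counts dropped per rule.
    """
    miss_rate = (geno.matrix == MISSING).mean(axis=0)
    p = geno.allele_freq()
    maf = np.minimum(p, 1 - p)
    bad_miss = miss_rate > max_missing
    bad_maf = (maf < min_maf) | ~np.isfinite(maf)
    keep = ~(bad_miss | bad_maf)
    if not keep.any():
        raise EmptyPanelError("all markers removed by QC")
    report = {
        "n_input": geno.n_markers,
        "n_kept": int(keep.sum()),
        "dropped_missing": int(bad_miss.sum()),
        "dropped_maf": int((bad_maf & ~bad_miss).sum()),
    }
    return geno.take_markers(np.flatnonzero(keep)), report


def _standardized(geno: GenotypeData) -> np.ndarray:
    """Mean-imputed, centered, sqrt(2pq)-scaled genotype matrix."""
    x = geno.imputed()
    p = geno.allele_freq()
    denom = np.sqrt(2.0 * p * (1 - p))
    denom = np.where(denom == 0, 1.0, denom)
    return (x - 2.0 * p) / denom


def structure_covariates(geno: GenotypeData, n_pcs: int = 3) -> np.ndarray:
    """Top principal-component scores of the standardized genotype matrix.

    Returns an (n_samples, n_pcs) matrix; n_pcs = 0 gives a 0-column matrix
    (intercept-only model downstream).
    """
    if n_pcs >= geno.n_samples:
        raise DimensionError("n_pcs must be smaller than the sample count")
    if n_pcs == 0:
        return np.empty((geno.n_samples, 0))
    z = _standardized(geno)
    zc = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix."""

    values: np.ndarray
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise KinshipError("kinship matrix not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise KinshipError("kinship matrix not positive semi-definite")


def kinship(geno: GenotypeData) -> KinshipMatrix:
    """Centered cross-product kinship: K = ZZ' / (2 sum p(1-p))."""
    x = geno.imputed()
    p = geno.allele_freq()
    z = x - 2.0 * p
    denom = float(2.0 * (p * (1 - p)).sum())
    if denom == 0:
        raise EmptyPanelError("no polymorphic marker for kinship")
    k = z @ z.T / denom
    k = (k + k.T) / 2.0
    return KinshipMatrix(values=k, sample_ids=list(geno.sample_ids))


# ---------------------------------------------------------------------------
# mixed model scan


@dataclass
class AssociationResult:
    """Per-marker statistics plus trait-level significance calls."""

    table: pd.DataFrame  # chrom, pos, id, beta, se, p, r2 (+ q, significant)
    p_cutoff: float | None = None

    def significant(self) -> pd.DataFrame:
        if "significant" not in self.table:
            raise ValueError("run fdr_threshold first")
        return self.table[self.table["significant"]]


def _reml_crit(delta: float, s: np.ndarray, xr: np.ndarray, yr: np.ndarray) -> tuple:
    """Negative REML criterion (up to constants) and the WLS pieces at delta."""
    w = 1.0 / (s + delta)
    a = (xr * w[:, None]).T @ xr
    b = (xr * w[:, None]).T @ yr
    ywy = float(yr @ (w * yr))
    try:
        coef = np.linalg.solve(a, b)
        sign, logdet_a = np.linalg.slogdet(a)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    if sign <= 0:
        return np.inf, None, None, None
    ypy = ywy - float(b @ coef)
    if ypy <= 0:
        return np.inf, None, None, None
    nq = yr.size - xr.shape[1]
    crit = nq * np.log(ypy) + np.log(s + delta).sum() + logdet_a
    return crit, coef, a, ypy


def _grid_crits(grid, s, xr, yr) -> np.ndarray:
    """REML criterion on the whole delta grid at once (batched WLS)."""
    w = 1.0 / (s[None, :] + grid[:, None])  # d x n
    a = np.einsum("dn,ni,nj->dij", w, xr, xr)
    b = np.einsum("dn,ni->di", w * yr[None, :], xr)
    ywy = w @ (yr * yr)
    sign, logdet_a = np.linalg.slogdet(a)
    with np.errstate(all="ignore"):
        coef = np.linalg.solve(a, b[..., None])[..., 0]
        ypy = ywy - np.einsum("di,di->d", b, coef)
        nq = yr.size - xr.shape[1]
        crit = nq * np.log(ypy) + np.log(s[None, :] + grid[:, None]).sum(axis=1) + logdet_a
    crit[(sign <= 0) | ~np.isfinite(crit) | (ypy <= 0)] = np.inf
    return crit


def _fit_marker(s, xr, yr, grid) -> tuple:
    """REML over delta = se^2/sg^2: log-grid then golden-section refinement."""
    crits = _grid_crits(grid, s, xr, yr)
    i = int(np.argmin(crits))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda ld: _reml_crit(10.0**ld, s, xr, yr)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    delta = float(10.0**res.x)
    crit, coef, a, ypy = _reml_crit(delta, s, xr, yr)
    if coef is None:
        delta = float(grid[i])
        crit, coef, a, ypy = _reml_crit(delta, s, xr, yr)
    return delta, coef, a, ypy


def mlm_scan(
    trait,
    geno: GenotypeData,
    covariates: np.ndarray | None,
    k: KinshipMatrix,
    delta_grid: np.ndarray | None = None,
) -> AssociationResult:
    """Per-marker mixed-model scan with marker-wise REML.

    ``trait`` may be an array aligned to ``geno.sample_ids`` or a pandas
    Series indexed by sample id (realigned; missing ids raise
    :class:`AlignmentError`). Returns effect, standard error, Wald p-value
    and incremental R^2 per marker.
    """
    if isinstance(trait, pd.Series):
        missing = [sid for sid in geno.sample_ids if sid not in trait.index]
        if missing:
            raise AlignmentError(f"trait missing sample ids: {missing[:5]}")
        y = trait.reindex(geno.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.size != geno.n_samples:
            raise AlignmentError("trait length does not match sample count")
    if covariates is None:
        covariates = np.empty((geno.n_samples, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != geno.n_samples:
        raise AlignmentError("covariate rows do not match sample count")
    if delta_grid is None:
        delta_grid = np.logspace(-5, 5, 61)

    n = geno.n_samples
    kv = k.values
    s_full, u_full = np.linalg.eigh(kv)
    s_full = np.clip(s_full, 0, None)
    base = np.column_stack([np.ones(n), covariates])
    # cache rotations per missingness pattern
    cache: dict = {(): (s_full, u_full.T @ base, u_full.T @ y, u_full)}

    out = np.full((geno.n_markers, 4), np.nan)  # beta, se, p, r2
    gmat = geno.matrix
    for j in range(geno.n_markers):
        col = gmat[:, j].astype(float)
        obs = col != MISSING
        key = tuple(np.flatnonzero(~obs).tolist())
        if key not in cache:
            sub = np.flatnonzero(obs)
            s_sub, u_sub = np.linalg.eigh(kv[np.ix_(sub, sub)])
            s_sub = np.clip(s_sub, 0, None)
            cache[key] = (s_sub, u_sub.T @ base[sub], u_sub.T @ y[sub], u_sub)
        s, base_r, yr, u = cache[key]
        x = col[obs]
        if np.ptp(x) == 0:
            continue
        xr = np.column_stack([base_r, u.T @ x])
        delta, coef, a, ypy = _fit_marker(s, xr, yr, delta_grid)
        if coef is None:
            continue
        nq = yr.size - xr.shape[1]
        sg2 = ypy / nq
        ainv_mm = float(np.linalg.inv(a)[-1, -1])
        beta = float(coef[-1])
        se = float(np.sqrt(sg2 * ainv_mm))
        tstat = beta / se if se > 0 else 0.0
        p = float(2.0 * stats.t.sf(abs(tstat), nq))
        # incremental R^2: null model at the same delta
        _, _, _, ypy0 = _reml_crit(delta, s, base_r, yr)
        r2 = float(1.0 - ypy / ypy0) if ypy0 and ypy0 > 0 else np.nan
        out[j] = (beta, se, max(p, np.nextafter(0, 1)), r2)

    table = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "pos": geno.pos,
            "id": geno.ids,
            "beta": out[:, 0],
            "se": out[:, 1],
            "p": out[:, 2],
            "r2": out[:, 3],
        }
    )
    return AssociationResult(table=table)


# ---------------------------------------------------------------------------
# FDR


def storey_qvalues(pvalues: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; pi0 estimated by a cubic-spline smoother over a
    lambda grid (0.05..0.95), with pi0 = 1 (Benjamini-Hochberg) as fallback."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
        try:
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam.max()))
        except Exception:
            pi0 = 1.0
        if not np.isfinite(pi0) or pi0 <= 0:
            pi0 = 1.0
        pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def fdr_threshold(
    result: AssociationResult, p_cutoff: float = 1e-6, pi0: float | None = None
) -> AssociationResult:
    """Attach Storey q-values and flag markers at the genome-wide p cutoff."""
    mask = np.isfinite(result.table["p"].to_numpy())
    q = np.full(mask.size, np.nan)
    q[mask] = storey_qvalues(result.table.loc[mask, "p"].to_numpy(), pi0=pi0)
    table = result.table.copy()
    table["q"] = q
    table["significant"] = table["p"] <= p_cutoff
    return AssociationResult(table=table, p_cutoff=p_cutoff)


# ---------------------------------------------------------------------------
# plot-ready data


def manhattan_qq_data(result: AssociationResult) -> dict:
    """Cumulative-coordinate Manhattan table, QQ quantiles and lambda_GC."""
    t = result.table.dropna(subset=["p"]).copy()
    if t.empty:
        raise ValueError("no finite p-values")
    offset = 0
    cum = np.empty(len(t), dtype=np.int64)
    offsets = {}
    for c in pd.unique(t["chrom"]):
        sel = t["chrom"] == c
        offsets[c] = offset
        cum[sel.to_numpy()] = t.loc[sel, "pos"].to_numpy() + offset
        offset += int(t.loc[sel, "pos"].max())
    t["cum_pos"] = cum
    t["neglog10p"] = -np.log10(t["p"])
    p = np.sort(t["p"].to_numpy())
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    chi2_obs = stats.chi2.isf(p, df=1)
    lambda_gc = float(np.median(chi2_obs) / stats.chi2.isf(0.5, df=1))
    qq = pd.DataFrame(
        {"expected_neglog10p": -np.log10(expected), "observed_neglog10p": -np.log10(p)}
    )
    return {"manhattan": t, "qq": qq, "lambda_gc": lambda_gc, "chrom_offsets": offsets}
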