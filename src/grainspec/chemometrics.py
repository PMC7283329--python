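"""Chemometrics: PLS-DA, VIP wavelength selection, LDA, and spectral traits.

The discrimination chain mirrors standard Vis/NIR practice:

1. Class membership is coded as a binary indicator matrix Y (one column per
   class, 1 for membership). A partial least squares model regresses Y on the
   centered-and-scaled spectra X, extracting components by the iterative
   bilinear (NIPALS) algorithm with X- and Y-deflation.
2. Per-wavelength influence is scored by VIP (variable importance in
   projection), whose squares average to 1 by construction; wavelengths with
   VIP >= 0.8 (optionally intersected with local extrema of the PLS beta
   coefficients) are retained.
3. The selected wavelengths feed a Fisher linear discriminant model, with
   classification by nearest class mean in canonical space and a stratified
   10% holdback set for validation.

For quantitative traits, wavelengths are grouped by K-means on their
across-sample profiles (post-processed into contiguous nm ranges), the first
principal component of each group becomes a per-sample spectral trait, and
that trait is regressed on the measured grain trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import average as hc_average
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .errors import (
    ClassSizeError,
    ClusteringError,
    DegenerateModelError,
    SelectionError,
)
from .imaging import SpectraTable

__all__ = [
    "ClassCoding",
    "PLSModel",
    "PLSDAResult",
    "VIPScores",
    "WavelengthGroups",
    "SpectralTrait",
    "LDAResult",
    "HeatmapResult",
    "fit_pls",
    "fit_plsda",
    "vip",
    "select_wavelengths",
    "fit_lda",
    "group_wavelengths",
    "spectral_trait_pc1",
    "regress_trait",
    "cluster_heatmap",
]


# ---------------------------------------------------------------------------
# class coding


@dataclass
class ClassCoding:
    """Binary membership coding: indicator[i, c] = 1 iff sample i is in class c."""

    classes: list
    indicator: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_labels(cls, labels) -> "ClassCoding":
        labels = np.asarray(labels)
        classes = sorted(set(labels.tolist()))
        indicator = np.zeros((labels.size, len(classes)))
        for c, name in enumerate(classes):
            indicator[labels == name, c] = 1.0
        return cls(classes=classes, indicator=indicator, labels=labels)


# ---------------------------------------------------------------------------
# PLS core (NIPALS)


@dataclass
class PLSModel:
    """NIPALS PLS2 model on centered/scaled X and centered Y.

    ``beta`` maps standardized X to centered Y; :meth:`predict` handles the
    centering/scaling state so callers work in raw units.
    """

    n_components: int
    weights: np.ndarray  # p x A, unit columns
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # r x A
    scores: np.ndarray  # n x A
    beta: np.ndarray  # p x r
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    wavelengths: np.ndarray | None = None
    classes: list | None = None

    @property
    def ssy(self) -> np.ndarray:
        """Y-variance captured per component: (t_a't_a)(q_a'q_a)."""
        tt = np.einsum("ia,ia->a", self.scores, self.scores)
        qq = np.einsum("ra,ra->a", self.y_loadings, self.y_loadings)
        return tt * qq

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (np.atleast_2d(x) - self.x_mean) / self.x_sd
        return xs @ self.beta + self.y_mean

    def predict_class(self, x: np.ndarray) -> np.ndarray:
        if self.classes is None:
            raise ValueError("model was not fitted against a class coding")
        yhat = self.predict(x)
        return np.asarray(self.classes, dtype=object)[np.argmax(yhat, axis=1)]


def fit_pls(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSModel:
    """Fit PLS by NIPALS with X- and Y-deflation.

    X is centered and scaled to unit (n-1) variance per column; Y is centered.
    Score vectors come out mutually orthogonal because each component is
    extracted from the deflated X.
    """
    x = np.asarray(x, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != x.shape[0]:
        y = y.T
    n, p = x.shape
    if not 1 <= n_components < min(n, p) + 1:
        raise ValueError("n_components must be in [1, min(n, p)]")

    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0, ddof=1)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean = y.mean(axis=0)
    e = (x - x_mean) / x_sd
    f = y - y_mean

    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_components):
        # start from the Y column with the largest remaining variance
        u = f[:, np.argmax(f.var(axis=0))].copy()
        if np.allclose(f, 0) or np.allclose(e, 0):
            break
        t_old = None
        for _ in range(max_iter):
            w = e.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t = e @ w
            tt = t @ t
            if tt == 0:
                break
            q = f.T @ t / tt
            qq = q @ q
            if qq == 0:
                break
            u = f @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        if tt == 0:
            break
        pvec = e.T @ t / tt
        e = e - np.outer(t, pvec)
        f = f - np.outer(t, q)
        ws.append(w)
        ps.append(pvec)
        qs.append(q)
        ts.append(t)

    if not ws:
        raise DegenerateModelError("no PLS component could be extracted")
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_mat = np.column_stack(qs)
    t_mat = np.column_stack(ts)
    # beta on the standardized-X / centered-Y scale
    beta = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_mat.T)
    return PLSModel(
        n_components=w_mat.shape[1],
        weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_mat,
        scores=t_mat,
        beta=beta,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
    )


def _stratified_holdback(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class random split; at least one holdback sample per class when
    fraction > 0 and the class has > 2 members."""
    test_idx = []
    for name in np.unique(labels):
        idx = np.flatnonzero(labels == name)
        n_hold = int(round(fraction * idx.size))
        if fraction > 0 and n_hold == 0 and idx.size > 2:
            n_hold = 1
        test_idx.extend(rng.permutation(idx)[:n_hold].tolist())
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


def _cv_n_components(x, y, max_comp: int, seed: int, n_folds: int = 5) -> int:
    """Pick the component count minimizing 5-fold prediction MSE."""
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    errs = np.zeros(max_comp)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        for a in range(1, max_comp + 1):
            try:
                m = fit_pls(x[mask], y[mask], a)
            except DegenerateModelError:
                errs[a - 1] += np.inf
                continue
            resid = y[fold] - m.predict(x[fold])
            errs[a - 1] += float((resid**2).sum())
    return int(np.argmin(errs)) + 1


@dataclass
class PLSDAResult:
    model: PLSModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_accuracy: float
    holdback_accuracy: float
    pve_per_class: dict
    predicted_holdback: np.ndarray


def fit_plsda(
    spectra: SpectraTable,
    coding: ClassCoding,
    n_components: int | None = None,
    holdback_fraction: float = 0.10,
    seed: int = 0,
    max_components: int = 10,
) -> PLSDAResult:
    """PLS-DA with a stratified holdback validation split.

    The holdback rows are excluded from fitting; when ``n_components`` is not
    fixed it is chosen by 5-fold cross-validated prediction error on the
    training rows. Per-class percent variance explained (PVE) is reported on
    the training fit; predicted class is the argmax of the predicted
    indicator row.
    """
    if len(coding.classes) < 2:
        raise ClassSizeError("need at least 2 classes")
    x = spectra.spectra
    y = coding.indicator
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_holdback(coding.labels, holdback_fraction, rng)
    counts = {
        c: int((coding.labels[train_idx] == c).sum()) for c in coding.classes
    }
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise ClassSizeError(f"classes with < 2 training samples: {small}")

    xt, yt = x[train_idx], y[train_idx]
    cap = min(max_components, min(xt.shape) - 1)
    if n_components is None:
        n_components = _cv_n_components(xt, yt, cap, seed)
    model = fit_pls(xt, yt, n_components)
    model.wavelengths = spectra.wavelengths
    model.classes = coding.classes

    yhat_t = model.predict(xt)
    sse = ((yt - yhat_t) ** 2).sum(axis=0)
    sst = ((yt - yt.mean(axis=0)) ** 2).sum(axis=0)
    pve = {
        c: float(100.0 * (1 - sse[j] / sst[j])) if sst[j] > 0 else 0.0
        for j, c in enumerate(coding.classes)
    }
    pred_t = model.predict_class(xt)
    train_acc = float(np.mean(pred_t == coding.labels[train_idx]))
    if test_idx.size:
        pred_h = model.predict_class(x[test_idx])
        hold_acc = float(np.mean(pred_h == coding.labels[test_idx]))
    else:
        pred_h = np.array([], dtype=object)
        hold_acc = float("nan")
    return PLSDAResult(
        model=model,
        train_idx=train_idx,
        test_idx=test_idx,
        train_accuracy=train_acc,
        holdback_accuracy=hold_acc,
        pve_per_class=pve,
        predicted_holdback=pred_h,
    )


# ---------------------------------------------------------------------------
# VIP and wavelength selection


@dataclass
class VIPScores:
    scores: np.ndarray
    wavelengths: np.ndarray | None = None


def vip(model: PLSModel) -> VIPScores:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the Y-variance explained by component a. With unit-norm
    weights the squares of the scores average to exactly 1 over wavelengths.
    """
    ssy = model.ssy
    total = ssy.sum()
    if total <= 0:
        raise DegenerateModelError("model explains no Y variance")
    p = model.weights.shape[0]
    w2 = model.weights**2  # columns already unit norm
    scores = np.sqrt(p * (w2 @ ssy) / total)
    return VIPScores(scores=scores, wavelengths=model.wavelengths)


def _local_extrema(values: np.ndarray) -> np.ndarray:
    """Boolean mask of local maxima of |values| (plateau-tolerant, ends count)."""
    v = np.abs(values)
    left = np.r_[-np.inf, v[:-1]]
    right = np.r_[v[1:], -np.inf]
    return (v >= left) & (v >= right)


def select_wavelengths(
    model: PLSModel,
    vip_threshold: float = 0.8,
    use_beta_peaks: bool = False,
) -> np.ndarray:
    """Wavelengths with VIP >= threshold, optionally restricted to |beta| peaks.

    Returns the selected wavelengths in nm (band indices if the model has no
    wavelength axis). Raises :class:`SelectionError` when nothing survives.
    """
    scores = vip(model).scores
    keep = scores >= vip_threshold
    if use_beta_peaks:
        peak_any = np.zeros_like(keep)
        for r in range(model.beta.shape[1]):
            peak_any |= _local_extrema(model.beta[:, r])
        keep &= peak_any
    if not keep.any():
        raise SelectionError(
            f"no wavelength reaches VIP {vip_threshold}; lower the threshold"
        )
    if model.wavelengths is not None:
        return model.wavelengths[keep]
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LDAResult:
    axes: np.ndarray  # p x (C-1) canonical directions
    class_means_canonical: np.ndarray
    grand_mean: np.ndarray
    classes: list
    train_scores: np.ndarray
    holdback_scores: np.ndarray
    train_accuracy: float
    holdback_accuracy: float
    per_class_holdback: dict

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.grand_mean) @ self.axes

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self.transform(x)
        d = ((z[:, None, :] - self.class_means_canonical[None]) ** 2).sum(axis=2)
        return np.asarray(self.classes, dtype=object)[np.argmin(d, axis=1)]


def fit_lda(
    spectra: SpectraTable,
    labels,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    ridge: float = 1e-6,
) -> LDAResult:
    """Fisher discriminant analysis with equal priors.

    Canonical axes are the leading eigenvectors of Sw^-1 Sb (at most C-1);
    classification is nearest class mean in canonical space. The pooled
    within-class covariance gets a small ridge (relative to its mean diagonal)
    when bands outnumber samples.
    """
    labels = np.asarray(labels)
    x = spectra.spectra
    xt, yt = x[train_idx], labels[train_idx]
    classes = sorted(set(yt.tolist()))
    if len(classes) < 2:
        raise ClassSizeError("LDA needs >= 2 classes in training data")
    p = xt.shape[1]
    grand = xt.mean(axis=0)
    means = np.vstack([xt[yt == c].mean(axis=0) for c in classes])
    sw = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = xt[yt == c] - mu
        sw += d.T @ d
    dof = max(xt.shape[0] - len(classes), 1)
    sw /= dof
    sw += ridge * (np.trace(sw) / p + 1.0) * np.eye(p)
    sb = np.zeros((p, p))
    for mu in means:  # equal priors: unweighted between-class scatter
        d = (mu - grand)[:, None]
        sb += d @ d.T
    sb /= len(classes)

    evals, evecs = np.linalg.eig(np.linalg.solve(sw, sb))
    order = np.argsort(evals.real)[::-1]
    n_axes = min(len(classes) - 1, p)
    axes = evecs[:, order[:n_axes]].real
    # normalize axes to unit within-class variance
    for j in range(axes.shape[1]):
        scale = float(axes[:, j] @ sw @ axes[:, j])
        if scale > 0:
            axes[:, j] /= np.sqrt(scale)

    result = LDAResult(
        axes=axes,
        class_means_canonical=(means - grand) @ axes,
        grand_mean=grand,
        classes=classes,
        train_scores=(xt - grand) @ axes,
        holdback_scores=(x[test_idx] - grand) @ axes,
        train_accuracy=0.0,
        holdback_accuracy=float("nan"),
        per_class_holdback={},
    )
    result.train_accuracy = float(np.mean(result.predict(xt) == yt))
    if test_idx.size:
        pred = result.predict(x[test_idx])
        truth = labels[test_idx]
        result.holdback_accuracy = float(np.mean(pred == truth))
        result.per_class_holdback = {
            c: float(np.mean(pred[truth == c] == c))
            for c in classes
            if np.any(truth == c)
        }
    return result


# ---------------------------------------------------------------------------
# wavelength grouping and spectral traits


@dataclass
class WavelengthGroups:
    """Partition of the band axis into contiguous nm ranges."""

    group_of_band: np.ndarray  # group index per band, 0..k-1 in nm order
    ranges: list  # [(lo_nm, hi_nm), ...] per group
    wavelengths: np.ndarray

    def band_indices(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.group_of_band == group)


def _contiguous_partition(labels: np.ndarray, k: int) -> np.ndarray:
    """Partition positions 0..p-1 into k contiguous blocks maximizing agreement
    with the given cluster labels, blocks taking clusters in order of their
    mean position. Dynamic program, O(k p^2)."""
    p = labels.size
    clusters = np.unique(labels)
    order = sorted(clusters, key=lambda c: np.flatnonzero(labels == c).mean())
    # gain[j][i0][i1): matches of cluster order[j] in [i0, i1)
    onehot = np.stack([(labels == c).astype(int) for c in order])  # k x p
    csum = np.concatenate([np.zeros((k, 1), dtype=int), np.cumsum(onehot, axis=1)], axis=1)

    NEG = -(10**9)
    best = np.full((k + 1, p + 1), NEG)
    back = np.zeros((k + 1, p + 1), dtype=int)
    best[0, 0] = 0
    for j in range(1, k + 1):
        for i1 in range(j, p - (k - j) + 1):
            scores = best[j - 1, j - 1 : i1] + (
                csum[j - 1, i1] - csum[j - 1, j - 1 : i1]
            )
            arg = int(np.argmax(scores))
            best[j, i1] = scores[arg]
            back[j, i1] = arg + (j - 1)
    cuts = [p]
    i1 = p
    for j in range(k, 0, -1):
        i1 = back[j, i1]
        cuts.append(i1)
    cuts = cuts[::-1]
    out = np.empty(p, dtype=int)
    for j in range(k):
        out[cuts[j] : cuts[j + 1]] = j
    return out


def group_wavelengths(
    spectra: SpectraTable,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 20,
) -> WavelengthGroups:
    """Cluster bands into k contiguous nm ranges.

    Each band is a point in sample space (its across-sample profile,
    standardized); K-means with ``n_restarts`` keeps the best within-cluster
    sum of squares, then a dynamic program snaps the labels to k contiguous
    blocks along the wavelength axis by majority assignment.
    """
    p = spectra.spectra.shape[1]
    if k >= p:
        raise ValueError("k must be smaller than the number of bands")
    if k == 1:
        return WavelengthGroups(
            group_of_band=np.zeros(p, dtype=int),
            ranges=[(float(spectra.wavelengths[0]), float(spectra.wavelengths[-1]))],
            wavelengths=spectra.wavelengths,
        )
    profiles = spectra.spectra.T  # band x sample
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (profiles - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(z)
    labels = km.labels_
    if np.unique(labels).size < k:
        raise ClusteringError("K-means left an empty cluster after restarts")
    group = _contiguous_partition(labels, k)
    wl = spectra.wavelengths
    ranges = [
        (float(wl[group == j].min()), float(wl[group == j].max())) for j in range(k)
    ]
    return WavelengthGroups(group_of_band=group, ranges=ranges, wavelengths=wl)


@dataclass
class SpectralTrait:
    """PC1 of a wavelength group: one score per sample plus its variance share."""

    scores: np.ndarray
    variance_proportion: float
    group_range: tuple


def spectral_trait_pc1(
    spectra: SpectraTable, band_index: np.ndarray, group_range: tuple | None = None
) -> SpectralTrait:
    """First principal component of the given bands, scored per sample.

    Columns are centered; the sign is fixed so that PC1 correlates positively
    with the in-group mean reflectance.
    """
    band_index = np.asarray(band_index)
    if band_index.size < 2:
        raise ValueError("group must contain at least 2 bands")
    x = spectra.spectra[:, band_index]
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise DegenerateModelError("zero-variance wavelength group")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    mean_ref = x.mean(axis=1)
    if np.corrcoef(scores, mean_ref)[0, 1] < 0:
        scores = -scores
    var_prop = float(s[0] ** 2 / (s**2).sum())
    if group_range is None:
        wl = spectra.wavelengths[band_index]
        group_range = (float(wl.min()), float(wl.max()))
    return SpectralTrait(scores=scores, variance_proportion=var_prop, group_range=group_range)


def regress_trait(y: np.ndarray, x: np.ndarray) -> dict:
    """Simple linear regression of a grain trait on a spectral predictor.

    Returns R^2, the F-test p-value (identical to the slope t-test for one
    predictor), and a significance label: ``**`` p < 0.01, ``*`` p < 0.05,
    ``ns`` otherwise. Pairs with missing values are dropped.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise DegenerateModelError("constant predictor")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    p = float(fit.pvalue)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "ns")
    return {"r2": r2, "p": p, "slope": float(fit.slope), "intercept": float(fit.intercept), "stars": stars, "n": int(y.size)}


# ---------------------------------------------------------------------------
# heatmap clustering


@dataclass
class HeatmapResult:
    linkage: np.ndarray
    leaf_order: np.ndarray
    matrix: np.ndarray  # rows as clustered (normalized if requested)
    row_labels: list


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo = m.min(axis=1, keepdims=True)
    hi = m.max(axis=1, keepdims=True)
    rng = np.where(hi - lo == 0, 1.0, hi - lo)
    return (m - lo) / rng


def cluster_heatmap(
    spectra: SpectraTable,
    trait: np.ndarray | None = None,
    metric: str = "pearson",
    normalize01: bool = True,
    axis: str = "bands",
) -> HeatmapResult:
    """One-way hierarchical clustering for the reflectance/chalk heatmap.

    ``axis='bands'`` clusters wavelengths by their across-sample profiles
    (optionally appending the trait as an extra row, as in a spectra-vs-chalk
    heatmap); ``axis='samples'`` clusters individuals. Distance is
    1 - Pearson r or Euclidean; linkage is average.
    """
    if axis == "bands":
        m = spectra.spectra.T.copy()
        labels = [f"{w:g}" for w in spectra.wavelengths]
        if trait is not None:
            m = np.vstack([m, np.asarray(trait, dtype=float)])
            labels.append("trait")
    elif axis == "samples":
        m = spectra.spectra.copy()
        labels = list(spectra.sample_ids)
        if trait is not None:
            m = np.hstack([m, np.asarray(trait, dtype=float)[:, None]])
    else:
        raise ValueError("axis must be 'bands' or 'samples'")
    if normalize01:
        m = _normalize01(m)
    if metric == "pearson":
        if np.any(m.std(axis=1) == 0):
            raise DegenerateModelError("constant row under Pearson distance")
        d = pdist(m, metric="correlation")
    elif metric == "euclidean":
        d = pdist(m, metric="euclidean")
    else:
        raise ValueError("metric must be 'pearson' or 'euclidean'")
    z = hc_average(d)
    return HeatmapResult(linkage=z, leaf_order=leaves_list(z), matrix=m, row_labels=labels)
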