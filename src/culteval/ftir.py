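"""FT-IR spectral preprocessing, covariance PCA, Fisher LDA and cross-validation.

Preprocessing follows the two-step pipeline standard for ATR FT-IR
microbial fingerprinting:

1. *Baseline correction* — subtract the straight line through the first and
   last point of the spectrum.  With slope ``(a_n - a_1)/(w_n - w_1)`` and
   offset ``a_1 - slope * w_1``, the corrected spectrum is
   ``a'_k = a_k - (w_k * slope + offset)``; both endpoints become exactly 0.
2. *Vector normalization* — centre the corrected spectrum
   (``a''_k = a'_k - mean(a')``) and divide by its Euclidean norm
   (``a'''_k = a''_k / sqrt(sum a''^2)``) so the squared components sum to 1.

The combination makes the analytical spectrum invariant to any added linear
ramp and to positive intensity scaling.  Classification operates on the
fingerprint (900-1800 cm^-1) and CH-stretching (2800-3000 cm^-1) regions via
covariance PCA and multi-class Fisher LDA with stratified k-fold
cross-validation (k = 5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

logger = logging.getLogger("culteval")

#: Analysis regions, cm^-1 (inclusive bounds).
FINGERPRINT: tuple[float, float] = (900.0, 1800.0)
CH_STRETCH: tuple[float, float] = (2800.0, 3000.0)

REGIONS = {"fingerprint": FINGERPRINT, "ch": CH_STRETCH}

STAGES = ("raw", "baseline_corrected", "normalized")


@dataclass
class Spectrum:
    """A single wavenumber-indexed absorbance vector."""

    w: np.ndarray
    a: np.ndarray
    stage: str = "raw"
    label: str | None = None
    name: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.w.shape != self.a.shape or self.w.ndim != 1:
            raise ValueError("wavenumber and absorbance vectors must align")
        if self.w.size < 3:
            raise ValueError("spectrum needs at least 3 points")
        dw = np.diff(self.w)
        if not ((dw > 0).all() or (dw < 0).all()):
            raise ValueError("wavenumber grid must be strictly monotone")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n(self) -> int:
        return self.w.size


@dataclass
class SpectrumSet:
    """Spectra on a common grid with class labels."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            w0 = self.spectra[0].w
            for s in self.spectra[1:]:
                if s.w.shape != w0.shape or not np.allclose(s.w, w0):
                    raise ValueError("spectra must share a common grid")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].w

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.spectra]

    @property
    def classes(self) -> list[str]:
        return sorted({s.label for s in self.spectra if s.label is not None})

    def matrix(self) -> np.ndarray:
        """Spectra x points absorbance matrix."""
        return np.vstack([s.a for s in self.spectra])

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet(spectra=[fn(s) for s in self.spectra])


# -- preprocessing (the stated two-step pipeline) ---------------------------


def baseline_correct(s: Spectrum) -> Spectrum:
    """Subtract the endpoint-to-endpoint line; endpoints map to exactly 0."""
    if s.stage != "raw":
        raise ValueError(f"baseline_correct expects a raw spectrum, got {s.stage}")
    if s.w[-1] == s.w[0]:
        raise ValueError("degenerate grid: first and last wavenumber coincide")
    slope = (s.a[-1] - s.a[0]) / (s.w[-1] - s.w[0])
    offset = s.a[0] - slope * s.w[0]
    corrected = s.a - (s.w * slope + offset)
    return replace(s, a=corrected, stage="baseline_corrected")


def vector_normalize(s: Spectrum) -> Spectrum:
    """Centre then scale to unit Euclidean norm (sum of squares = 1)."""
    if s.stage != "baseline_corrected":
        raise ValueError(
            f"vector_normalize expects a baseline-corrected spectrum, got {s.stage}"
        )
    centered = s.a - s.a.mean()
    norm = np.sqrt((centered**2).sum())
    if norm == 0:
        raise ValueError(f"constant spectrum {s.name!r}: zero norm after centering")
    return replace(s, a=centered / norm, stage="normalized")


def preprocess(s: Spectrum) -> Spectrum:
    """Baseline correction followed by vector normalization."""
    return vector_normalize(baseline_correct(s))


def slice_region(
    obj: Spectrum | SpectrumSet,
    region: str | tuple[float, float],
) -> Spectrum | SpectrumSet:
    """Inclusive wavenumber slice; named regions: 'fingerprint', 'ch'."""
    if isinstance(obj, SpectrumSet):
        return SpectrumSet(spectra=[slice_region(s, region) for s in obj.spectra])
    if isinstance(region, str):
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}; valid: {sorted(REGIONS)}")
        lo, hi = REGIONS[region]
        tag = region
    else:
        lo, hi = region
        tag = f"{lo:g}-{hi:g}"
    mask = (obj.w >= lo) & (obj.w <= hi)
    if mask.sum() < 3:
        raise ValueError(f"region [{lo}, {hi}] intersects the grid in < 3 points")
    return replace(obj, w=obj.w[mask], a=obj.a[mask], region=tag)


def analysis_matrix(sset: SpectrumSet, preprocess_spectra: bool = True) -> np.ndarray:
    """Concatenated fingerprint + CH-stretch features after preprocessing.

    Each region is preprocessed independently (the endpoint baseline and the
    vector norm are region-local quantities).
    """
    blocks = []
    for region in ("fingerprint", "ch"):
        sub = slice_region(sset, region)
        if preprocess_spectra:
            sub = sub.map(preprocess)
        blocks.append(sub.matrix())
    return np.hstack(blocks)


# -- I/O ---------------------------------------------------------------------


def read_spectrum(path, label: str | None = None, name: str | None = None) -> Spectrum:
    """Two-column text: wavenumber, absorbance (optional header)."""
    df = pd.read_csv(
        path, sep=None, engine="python", comment="#", header=None,
        skip_blank_lines=True,
    )
    if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        try:
            [float(x) for x in df.iloc[0]]
        except (TypeError, ValueError):
            df = df.iloc[1:]
    arr = df.astype(float).to_numpy()
    return Spectrum(w=arr[:, 0], a=arr[:, 1], label=label, name=name)


def read_spectrum_set(path, labels_path=None) -> SpectrumSet:
    """Wide TSV: first column wavenumber, one column per spectrum.

    `labels_path` is a TSV with columns ``name\tlabel``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    labels: dict[str, str] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", comment="#")
        labels = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
    spectra = [
        Spectrum(w=w, a=df[c].to_numpy(dtype=float), name=str(c),
                 label=labels.get(str(c)))
        for c in df.columns[1:]
    ]
    return SpectrumSet(spectra=spectra)


def write_spectrum_set(sset: SpectrumSet, path, labels_path=None) -> None:
    df = pd.DataFrame({"wavenumber": sset.grid})
    for i, s in enumerate(sset.spectra):
        df[s.name or f"spectrum_{i:03d}"] = s.a
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if labels_path is not None:
        pd.DataFrame(
            {
                "name": [s.name or f"spectrum_{i:03d}" for i, s in enumerate(sset.spectra)],
                "label": [s.label for s in sset.spectra],
            }
        ).to_csv(labels_path, sep="\t", index=False)


# -- covariance PCA ----------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray          # spectra x components
    loadings: np.ndarray        # points x components, orthonormal columns
    explained_variance: np.ndarray
    explained_fraction: np.ndarray
    mean: np.ndarray


def pca(X: np.ndarray | SpectrumSet, n_components: int | None = None) -> PCAResult:
    """Covariance-matrix PCA via SVD of the centred data (no scaling)."""
    if isinstance(X, SpectrumSet):
        X = X.matrix()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (n - 1)
    total = ((Xc**2).sum()) / (n - 1)
    k = n_components
    return PCAResult(
        scores=(U * S)[:, :k],
        loadings=Vt[:k].T,
        explained_variance=eigvals[:k],
        explained_fraction=eigvals[:k] / total if total > 0 else eigvals[:k] * 0,
        mean=mean,
    )


# -- Fisher LDA ---------------------------------------------------------------


@dataclass
class LDAModel:
    """Multi-class Fisher discriminant with nearest-class-mean assignment."""

    axes: np.ndarray            # features x (c-1) discriminant directions
    eigenvalues: np.ndarray
    class_means: dict[str, np.ndarray]   # in discriminant space
    classes: list[str]
    mean: np.ndarray
    projection: np.ndarray | None = None  # optional PCA pre-projection

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.projection is not None:
            X = (X - self.mean) @ self.projection
        else:
            X = X - self.mean
        return X @ self.axes

    def predict(self, X: np.ndarray) -> list[str]:
        Z = self.transform(X)
        means = np.vstack([self.class_means[c] for c in self.classes])
        d2 = ((Z[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        return [self.classes[i] for i in d2.argmin(axis=1)]


def fit_lda(
    X: np.ndarray | SpectrumSet,
    labels: list[str] | None = None,
    regularization: str = "pca_reduce",
    variance_kept: float = 0.99,
    ridge: float = 1e-6,
) -> LDAModel:
    """Fisher LDA maximizing the between/within generalized Rayleigh quotient.

    ``regularization='pca_reduce'`` first projects onto the principal
    components explaining >= `variance_kept` of the variance (the usual cure
    when points outnumber spectra); ``'ridge'`` adds `ridge` to the
    within-scatter diagonal; ``'none'`` errors on a singular within-scatter.
    """
    if isinstance(X, SpectrumSet):
        if labels is None:
            labels = [s.label for s in X.spectra]
        X = X.matrix()
    X = np.asarray(X, dtype=float)
    if labels is None:
        raise ValueError("labels required")
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"class {c!r} needs >= 2 training spectra")

    grand_mean = X.mean(axis=0)
    projection = None
    if regularization == "pca_reduce":
        res = pca(X)
        cum = np.cumsum(res.explained_fraction)
        k = int(np.searchsorted(cum, variance_kept) + 1)
        # keep the within-class scatter nonsingular: rank(Sw) <= n - c
        k = max(1, min(k, res.loadings.shape[1], X.shape[0] - len(classes)))
        projection = res.loadings[:, :k]
        Xw = (X - grand_mean) @ projection
    elif regularization in ("ridge", "none"):
        Xw = X - grand_mean
    else:
        raise ValueError(f"unknown regularization {regularization!r}")

    p = Xw.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        idx = [i for i, l in enumerate(labels) if l == c]
        Xc = Xw[idx]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        Sb += len(idx) * np.outer(mu, mu)
    if regularization == "ridge":
        Sw = Sw + ridge * np.eye(p)
    elif regularization == "none":
        if np.linalg.matrix_rank(Sw) < p:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; choose regularization="
                "'pca_reduce' or 'ridge'"
            )
    # generalized symmetric eigenproblem Sb v = lambda Sw v
    try:
        eigvals, eigvecs = eigh(Sb, Sw)
    except np.linalg.LinAlgError:
        if regularization == "none":
            raise
        jitter = 1e-10 * max(np.trace(Sw) / p, 1.0)
        eigvals, eigvecs = eigh(Sb, Sw + jitter * np.eye(p))
    order = np.argsort(eigvals)[::-1]
    n_axes = len(classes) - 1
    eigvals = np.clip(eigvals[order][:n_axes], 0.0, None)
    axes = eigvecs[:, order][:, :n_axes]

    model = LDAModel(
        axes=axes,
        eigenvalues=eigvals,
        class_means={},
        classes=classes,
        mean=grand_mean,
        projection=projection,
    )
    Z = model.transform(X)
    for c in classes:
        idx = [i for i, l in enumerate(labels) if l == c]
        model.class_means[c] = Z[idx].mean(axis=0)
    return model


# -- cross-validated classification -------------------------------------------


@dataclass
class ClassifierReport:
    accuracy: float
    ci_lower: float
    ci_upper: float
    confusion: pd.DataFrame          # true x predicted counts
    predictions: pd.DataFrame        # name, true, predicted, fold
    discriminants: np.ndarray        # out-of-fold LD coordinates per spectrum


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        raise ValueError("empty sample")
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def _stratified_folds(
    labels: list[str], k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment; warns when a class has < k members."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == c])
        if idx.size < k:
            logger.warning("class %s has %d < k=%d members; folds stay stratified "
                           "but this class misses some folds", c, idx.size, k)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def cross_validate(
    sset: SpectrumSet,
    scheme: str = "kfold",
    k: int = 5,
    seed: int = 0,
    regularization: str = "pca_reduce",
    preprocess_spectra: bool = True,
) -> ClassifierReport:
    """Stratified k-fold (or leave-one-out) Fisher-LDA classification.

    Spectra are preprocessed and restricted to the fingerprint + CH-stretch
    regions before fitting.  The report pools out-of-fold predictions; the
    95% CI on the accuracy is the Wilson score interval.
    """
    labels = [s.label for s in sset.spectra]
    if any(l is None for l in labels):
        raise ValueError("every spectrum needs a class label")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("classification needs >= 2 classes")
    X = analysis_matrix(sset, preprocess_spectra=preprocess_spectra)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if scheme == "kfold":
        folds = _stratified_folds(labels, k, rng)
    elif scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    predicted: list[str | None] = [None] * n
    fold_of = np.full(n, -1)
    n_axes = len(classes) - 1
    discriminants = np.zeros((n, n_axes))
    for f, test_idx in enumerate(folds):
        if test_idx.size == 0:
            continue
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit_lda(
            X[train_idx], [labels[i] for i in train_idx],
            regularization=regularization,
        )
        preds = model.predict(X[test_idx])
        Z = model.transform(X[test_idx])
        for j, i in enumerate(test_idx):
            predicted[i] = preds[j]
            fold_of[i] = f
            discriminants[i, : Z.shape[1]] = Z[j]

    correct = sum(p == t for p, t in zip(predicted, labels))
    accuracy = correct / n
    lo, hi = wilson_interval(correct, n)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(labels, predicted):
        confusion.loc[t, p] += 1
    predictions = pd.DataFrame(
        {
            "name": [s.name or f"spectrum_{i:03d}" for i, s in enumerate(sset.spectra)],
            "true": labels,
            "predicted": predicted,
            "fold": fold_of,
        }
    )
    return ClassifierReport(
        accuracy=accuracy, ci_lower=lo, ci_upper=hi,
        confusion=confusion, predictions=predictions,
        discriminants=discriminants,
    )
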