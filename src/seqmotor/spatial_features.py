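"""Spatial-filter feature bank: DCPM, TRCA and one-vs-rest FBCSP.

Feature epochs cover [-0.5, 1.5) s around the first keystroke at 200 Hz
(400 samples, spanning both keystrokes at ~1 s spacing).  Two filtered
variants feed the bank:

* ``mrcp_branch`` (1-8 Hz): DCPM — per-class discriminative spatial
  patterns (DSP, top 2 generalized eigenvectors of between- over
  within-class scatter), a projected class template, and per-epoch
  similarity to the template measured both by per-dimension Pearson
  correlation and by canonical correlation (CCA alignment) — and TRCA,
  whose filters maximize inter-trial covariance of the time-locked
  response (top 3 components per class, template correlation features).
* ``band_branch`` (theta 4-8, alpha 8-13, beta 13-30 Hz): one-vs-rest CSP
  per band and class, top 3 filters, normalized log-variance features.

With 4 classes this yields 16 DCPM + 4 TRCA + 36 FBCSP = 56 features per
trial.  All scatter/covariance matrices receive scalar convex shrinkage
toward a scaled identity; eigenvector signs are fixed by making the
largest-magnitude coefficient positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core_io import TASKS, ContinuousRecording, EpochSet, extract_epochs
from .preprocess import butterworth_filter, resample

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((4.0, 8.0), (8.0, 13.0),
                                                  (13.0, 30.0))
BAND_NAMES = {(4.0, 8.0): "theta", (8.0, 13.0): "alpha", (13.0, 30.0): "beta"}


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class FeatureEpochSet:
    """Filtered epoch variants feeding the spatial-filter bank."""

    mrcp_branch: EpochSet                      # 1-8 Hz
    band_branch: dict[tuple[float, float], EpochSet]
    labels: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.mrcp_branch.n_trials

    def subset(self, idx) -> "FeatureEpochSet":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(int)
        return FeatureEpochSet(
            mrcp_branch=self.mrcp_branch.copy_with(
                data=self.mrcp_branch.data[idx],
                labels=self.mrcp_branch.labels[idx], dropped=[]),
            band_branch={b: e.copy_with(data=e.data[idx],
                                        labels=e.labels[idx], dropped=[])
                         for b, e in self.band_branch.items()},
            labels=self.labels[idx],
        )

    def with_labels(self, labels) -> "FeatureEpochSet":
        """Same epochs with replaced per-trial labels (e.g. permutation)."""
        labels = np.asarray(labels, dtype=object)
        if len(labels) != self.n_trials:
            raise ValueError("label count must match trial count")
        return FeatureEpochSet(
            mrcp_branch=self.mrcp_branch.copy_with(labels=labels.copy()),
            band_branch={b: e.copy_with(labels=labels.copy())
                         for b, e in self.band_branch.items()},
            labels=labels.copy(),
        )


@dataclass
class DcpmModel:
    classes: tuple[str, ...]
    filters: dict[str, np.ndarray]     # class -> n_dsp x channels
    templates: dict[str, np.ndarray]   # class -> n_dsp x samples


@dataclass
class TrcaModel:
    classes: tuple[str, ...]
    filters: dict[str, np.ndarray]     # class -> n_comp x channels
    templates: dict[str, np.ndarray]   # class -> n_comp x samples


@dataclass
class CspModel:
    classes: tuple[str, ...]
    bands: tuple[tuple[float, float], ...]
    filters: dict[tuple[tuple[float, float], str], np.ndarray]
    eigenvalues: dict[tuple[tuple[float, float], str], np.ndarray]


@dataclass
class SpatialFilterModel:
    """The fitted DCPM + TRCA + FBCSP bank."""

    dcpm: DcpmModel
    trca: TrcaModel
    csp: CspModel
    band_defs: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    regularization: float = 0.05


@dataclass
class FeatureMatrix:
    """Trials x 56 feature values with stable names (16 DCPM | 4 TRCA | 36 FBCSP)."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match matrix width")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")


# --------------------------------------------------------------------------
# numerics
# --------------------------------------------------------------------------

def shrink(cov: np.ndarray, intensity: float) -> np.ndarray:
    """Convex shrinkage toward tr(C)/n * I."""
    n = cov.shape[0]
    target = (np.trace(cov) / n) * np.eye(n)
    return (1.0 - intensity) * cov + intensity * target


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coefficient of each column positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def generalized_eig_descending(a: np.ndarray, b: np.ndarray,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Solve A v = lambda B v for symmetric A, SPD B; eigenvalues descending,
    eigenvector signs deterministic."""
    if np.linalg.cond(b) > 1e12:
        raise np.linalg.LinAlgError(
            "singular scatter/covariance matrix; increase the shrinkage "
            "regularization"
        )
    w, v = scipy.linalg.eigh(a, b)
    order = np.argsort(w)[::-1]
    return w[order], _fix_signs(v[:, order])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    return float(x @ y / denom) if denom > 0 else 0.0


def canonical_correlations(x: np.ndarray, y: np.ndarray,
                           reg: float = 1e-10) -> np.ndarray:
    """Canonical correlations between two d x n multichannel signals,
    descending, clipped to [0, 1]."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    n = x.shape[1]
    cxx = xc @ xc.T / n + reg * np.eye(x.shape[0])
    cyy = yc @ yc.T / n + reg * np.eye(y.shape[0])
    cxy = xc @ yc.T / n

    def inv_sqrt(c):
        w, v = np.linalg.eigh(c)
        w = np.maximum(w, reg)
        return v @ np.diag(1.0 / np.sqrt(w)) @ v.T

    k = inv_sqrt(cxx) @ cxy @ inv_sqrt(cyy)
    rho = np.linalg.svd(k, compute_uv=False)
    return np.clip(rho, 0.0, 1.0)


# --------------------------------------------------------------------------
# epoch preparation
# --------------------------------------------------------------------------

def prepare_feature_epochs(rec: ContinuousRecording,
                           target_rate: float = 200.0,
                           tmin: float = -0.5, tmax: float = 1.5,
                           mrcp_band: tuple[float, float] = (1.0, 8.0),
                           bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                           ) -> FeatureEpochSet:
    """Resample to 200 Hz, band-filter the continuous signal per branch and
    epoch [-0.5, 1.5) s around the first keystroke (400 samples)."""
    base = resample(rec, target_rate)
    mrcp = extract_epochs(
        butterworth_filter(base, low=mrcp_band[0], high=mrcp_band[1]),
        tmin, tmax)
    band_branch = {}
    for band in bands:
        band_branch[tuple(band)] = extract_epochs(
            butterworth_filter(base, low=band[0], high=band[1]), tmin, tmax)
    return FeatureEpochSet(mrcp, band_branch, mrcp.labels.copy())


# --------------------------------------------------------------------------
# DCPM
# --------------------------------------------------------------------------

def fit_dcpm(epochs: EpochSet, n_dsp: int = 2,
             shrinkage: float = 0.05,
             classes: tuple[str, ...] | None = None) -> DcpmModel:
    """Per-class one-vs-rest discriminative spatial patterns + templates.

    DSP filters are the top generalized eigenvectors of the between-class
    scatter (class mean vs rest mean) over the within-class scatter of
    trials around their class means.
    """
    labels = epochs.labels
    classes = classes or tuple(t for t in TASKS if t in set(labels))
    if len(classes) < 2:
        raise ValueError("DCPM needs at least 2 classes")
    X = epochs.data
    Xc = X - X.mean(axis=2, keepdims=True)       # remove per-channel DC
    filters, templates = {}, {}
    for cls in classes:
        sel = labels == cls
        if sel.sum() < 2 or (~sel).sum() < 2:
            raise ValueError(f"need >= 2 trials per class, class {cls}")
        m_cls = Xc[sel].mean(axis=0)
        m_rest = Xc[~sel].mean(axis=0)
        diff = m_cls - m_rest
        sb = diff @ diff.T / diff.shape[1]
        centered = Xc.copy()
        centered[sel] -= m_cls
        centered[~sel] -= m_rest
        sw = np.einsum("ict,idt->cd", centered, centered) / (
            centered.shape[0] * centered.shape[2])
        if shrinkage == 0 and np.linalg.cond(sw) > 1e12:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; set shrinkage > 0")
        _, vecs = generalized_eig_descending(sb, shrink(sw, shrinkage))
        w = vecs[:, :n_dsp].T                     # n_dsp x channels
        filters[cls] = w
        templates[cls] = w @ m_cls
    return DcpmModel(tuple(classes), filters, templates)


def dcpm_transform(model: DcpmModel, epoch: np.ndarray) -> np.ndarray:
    """16 DCPM features for one epoch (channels x samples).

    Per class: Pearson correlation of each projected dimension with the
    class template, followed by the canonical correlations of the
    projected epoch with the template (CCA alignment) — 4 values per class.
    """
    feats = []
    for cls in model.classes:
        w = model.filters[cls]
        t = model.templates[cls]
        if epoch.shape[1] != t.shape[1]:
            raise ValueError("epoch length does not match the model grid")
        p = w @ (epoch - epoch.mean(axis=1, keepdims=True))
        for d in range(w.shape[0]):
            feats.append(_pearson(p[d], t[d]))
        rho = canonical_correlations(p, t)
        feats.extend(rho[: w.shape[0]].tolist())
    return np.asarray(feats)


def dcpm_feature_names(model: DcpmModel) -> list[str]:
    names = []
    for cls in model.classes:
        n_dsp = model.filters[cls].shape[0]
        names += [f"dcpm/{cls}/d{d + 1}/corr" for d in range(n_dsp)]
        names += [f"dcpm/{cls}/d{d + 1}/cca" for d in range(n_dsp)]
    return names


# --------------------------------------------------------------------------
# TRCA
# --------------------------------------------------------------------------

def fit_trca(epochs: EpochSet, n_comp: int = 3, shrinkage: float = 0.05,
             classes: tuple[str, ...] | None = None) -> TrcaModel:
    """Per-class task-related component analysis.

    Maximizes the summed inter-trial covariance of the time-locked
    response over the total covariance; the top ``n_comp`` generalized
    eigenvectors are kept and the class template is the projected trial
    average.
    """
    labels = epochs.labels
    classes = classes or tuple(t for t in TASKS if t in set(labels))
    filters, templates = {}, {}
    for cls in classes:
        X = epochs.data[labels == cls]
        if X.shape[0] < 2:
            raise ValueError(f"TRCA needs >= 2 trials per class, class {cls}")
        Xc = X - X.mean(axis=2, keepdims=True)
        n_tr, _, n_t = Xc.shape
        summed = Xc.sum(axis=0)
        q = np.einsum("ict,idt->cd", Xc, Xc) / (n_tr * n_t)
        s = (summed @ summed.T / n_t - q * n_tr) / max(n_tr * (n_tr - 1), 1)
        if shrinkage == 0 and np.linalg.cond(q) > 1e12:
            raise np.linalg.LinAlgError(
                "rank-deficient covariance; set shrinkage > 0")
        _, vecs = generalized_eig_descending(s, shrink(q, shrinkage))
        w = vecs[:, :n_comp].T
        filters[cls] = w
        templates[cls] = w @ Xc.mean(axis=0)
    return TrcaModel(tuple(classes), filters, templates)


def trca_transform(model: TrcaModel, epoch: np.ndarray) -> np.ndarray:
    """4 TRCA features: per class, the Pearson correlation between the
    projected epoch and the projected class template, components
    concatenated."""
    feats = []
    for cls in model.classes:
        w = model.filters[cls]
        t = model.templates[cls]
        if epoch.shape[1] != t.shape[1]:
            raise ValueError("epoch length does not match the model grid")
        p = w @ (epoch - epoch.mean(axis=1, keepdims=True))
        feats.append(_pearson(p.ravel(), t.ravel()))
    return np.asarray(feats)


def trca_feature_names(model: TrcaModel) -> list[str]:
    return [f"trca/{cls}" for cls in model.classes]


# --------------------------------------------------------------------------
# FBCSP
# --------------------------------------------------------------------------

def fit_fbcsp(band_epochs: dict[tuple[float, float], EpochSet],
              n_filters: int = 3, shrinkage: float = 0.05,
              normalize_trace: bool = True,
              classes: tuple[str, ...] | None = None) -> CspModel:
    """One-vs-rest CSP per band and class.

    Per band and class the filters are the top ``n_filters`` generalized
    eigenvectors of (class covariance, class + rest covariance); the
    eigenvalues lie in (0, 1).  Trial covariances are trace-normalized by
    default (``normalize_trace=False`` uses raw covariances).
    """
    some = next(iter(band_epochs.values()))
    labels = some.labels
    classes = classes or tuple(t for t in TASKS if t in set(labels))
    filters, eigenvalues = {}, {}
    for band, epochs in band_epochs.items():
        X = epochs.data - epochs.data.mean(axis=2, keepdims=True)
        covs = np.einsum("ict,idt->icd", X, X) / X.shape[2]
        if normalize_trace:
            traces = np.trace(covs, axis1=1, axis2=2)
            covs = covs / traces[:, None, None]
        for cls in classes:
            sel = epochs.labels == cls
            if sel.sum() < 2 or (~sel).sum() < 2:
                raise ValueError(
                    f"CSP needs >= 2 trials per class per band, class {cls}")
            c_cls = covs[sel].mean(axis=0)
            c_rest = covs[~sel].mean(axis=0)
            composite = c_cls + c_rest
            if shrinkage == 0 and np.linalg.cond(composite) > 1e12:
                raise np.linalg.LinAlgError(
                    "singular composite covariance; set shrinkage > 0")
            vals, vecs = generalized_eig_descending(
                c_cls, shrink(composite, shrinkage))
            filters[(band, cls)] = vecs[:, :n_filters].T
            eigenvalues[(band, cls)] = vals[:n_filters]
    return CspModel(tuple(classes), tuple(band_epochs.keys()), filters,
                    eigenvalues)


def fbcsp_transform(model: CspModel,
                    band_epoch: dict[tuple[float, float], np.ndarray],
                    ) -> np.ndarray:
    """36 FBCSP features: per band x class x filter, the log of the
    projected-signal variance normalized by the sum over that projection
    block (scale invariant)."""
    feats = []
    for band in model.bands:
        epoch = band_epoch[band]
        for cls in model.classes:
            w = model.filters[(band, cls)]
            p = w @ (epoch - epoch.mean(axis=1, keepdims=True))
            v = p.var(axis=1)
            if np.any(v <= 0):
                bad = [f"fbcsp/{BAND_NAMES.get(band, band)}/{cls}/f{i + 1}"
                       for i in np.flatnonzero(v <= 0)]
                raise ValueError(f"zero-variance projection for {bad}")
            feats.extend(np.log(v / v.sum()).tolist())
    return np.asarray(feats)


def fbcsp_feature_names(model: CspModel) -> list[str]:
    names = []
    for band in model.bands:
        bname = BAND_NAMES.get(band, f"{band[0]:g}-{band[1]:g}Hz")
        for cls in model.classes:
            n_f = model.filters[(band, cls)].shape[0]
            names += [f"fbcsp/{bname}/{cls}/f{i + 1}" for i in range(n_f)]
    return names


# --------------------------------------------------------------------------
# assembled bank
# --------------------------------------------------------------------------

def fit_spatial_models(train: FeatureEpochSet, n_dsp: int = 2,
                       n_trca: int = 3, n_csp: int = 3,
                       shrinkage: float = 0.05,
                       classes: tuple[str, ...] | None = None,
                       ) -> SpatialFilterModel:
    """Fit DCPM, TRCA and FBCSP on training trials only."""
    dcpm = fit_dcpm(train.mrcp_branch, n_dsp=n_dsp, shrinkage=shrinkage,
                    classes=classes)
    trca = fit_trca(train.mrcp_branch, n_comp=n_trca, shrinkage=shrinkage,
                    classes=classes)
    csp = fit_fbcsp(train.band_branch, n_filters=n_csp, shrinkage=shrinkage,
                    classes=classes)
    return SpatialFilterModel(dcpm, trca, csp,
                              band_defs=tuple(train.band_branch.keys()),
                              regularization=shrinkage)


def extract_features(models: SpatialFilterModel,
                     epochs: FeatureEpochSet) -> FeatureMatrix:
    """Concatenate [16 DCPM | 4 TRCA | 36 FBCSP] per trial."""
    if models.dcpm is None or models.trca is None or models.csp is None:
        raise ValueError("all three spatial-filter branches must be fitted")
    rows = []
    for i in range(epochs.n_trials):
        mrcp_ep = epochs.mrcp_branch.data[i]
        band_ep = {b: e.data[i] for b, e in epochs.band_branch.items()}
        rows.append(np.concatenate([
            dcpm_transform(models.dcpm, mrcp_ep),
            trca_transform(models.trca, mrcp_ep),
            fbcsp_transform(models.csp, band_ep),
        ]))
    names = (dcpm_feature_names(models.dcpm)
             + trca_feature_names(models.trca)
             + fbcsp_feature_names(models.csp))
    values = np.asarray(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(values, epochs.labels.copy(), tuple(names))
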