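"""Voxel-wise and tract-wise lesion analytics.

Covers the lesion-analysis suite: the 10% coverage filter, lesion-size
residualization, sparse canonical-correlation lesion-symptom mapping
(LSM) with k-fold cross-validated significance, streamline disconnection
maps, tract lesion-load percentages, anatomical labelling of weight
maps, and the AIC-based predictive validity comparison (PVC) of two
behaviour maps.

All analyses operate in voxel space on a verified-identical grid; voxel
indices are 0-based and flat (C-order) unless stated.  NIfTI affines are
carried through I/O but never interpreted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .stats import pearson

__all__ = [
    "LesionVolume",
    "CohortLesions",
    "TractAtlas",
    "StreamlineSet",
    "LSMResult",
    "PVCResult",
    "SpaceError",
    "voxel_coverage_filter",
    "regress_out",
    "tract_lesion_percentage",
    "disconnection_map",
    "sparse_cca_lsm",
    "permutation_p",
    "pvc",
    "pvc_verdict",
    "label_weights",
    "lesion_matrix",
    "load_lesion_nifti",
    "save_volume_nifti",
]


class SpaceError(ValueError):
    """Grids or template spaces do not match."""


@dataclass(frozen=True)
class LesionVolume:
    data: np.ndarray
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    space_tag: str = "synthetic"

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("lesion data must be 3-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("lesion mask must be binary")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "data", arr.astype(np.uint8))

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def size_cc(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_cc


@dataclass(frozen=True)
class CohortLesions:
    subjects: tuple
    volumes: tuple

    def __post_init__(self):
        vols = tuple(self.volumes)
        if len(vols) != len(self.subjects):
            raise ValueError("subjects and volumes must align")
        if vols:
            shape = vols[0].data.shape
            tag = vols[0].space_tag
            for v in vols[1:]:
                if v.data.shape != shape or v.space_tag != tag:
                    raise SpaceError("all lesions must share one grid and space")
        object.__setattr__(self, "volumes", vols)

    @property
    def grid_shape(self):
        return self.volumes[0].data.shape if self.volumes else None

    @property
    def lesion_size_cc(self) -> np.ndarray:
        return np.array([v.size_cc for v in self.volumes])

    def __len__(self):
        return len(self.subjects)


@dataclass(frozen=True)
class TractAtlas:
    tracts: dict  # name -> (m, 3) int array of voxel indices
    grid_shape: tuple = None

    def __post_init__(self):
        tr = {}
        for name, vox in self.tracts.items():
            arr = np.asarray(vox, dtype=int).reshape(-1, 3)
            if arr.shape[0] == 0:
                raise ValueError(f"tract {name!r} is empty")
            tr[name] = arr
        if len(tr) != len(self.tracts):
            raise ValueError("tract names must be unique")
        object.__setattr__(self, "tracts", tr)


@dataclass(frozen=True)
class StreamlineSet:
    streamlines: tuple  # each an (L, 3) int array of voxel indices
    grid_shape: tuple

    def __post_init__(self):
        paths = []
        shape = np.asarray(self.grid_shape, int)
        for p in self.streamlines:
            arr = np.asarray(p, dtype=int).reshape(-1, 3)
            if arr.shape[0] == 0:
                raise ValueError("streamline paths must be non-empty")
            if (arr < 0).any() or (arr >= shape[None, :]).any():
                raise ValueError("streamline voxel outside grid")
            paths.append(arr)
        object.__setattr__(self, "streamlines", tuple(paths))


@dataclass(frozen=True)
class LSMResult:
    weights: np.ndarray          # aligned with `voxels`
    voxels: np.ndarray           # flat voxel indices the model was fit on
    grid_shape: tuple
    cv_correlation: float
    p: float
    sparseness: float
    folds: int
    seed: int
    displayed_voxels: frozenset = field(default_factory=frozenset)

    def weight_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape)
        vol.flat[self.voxels] = self.weights
        return vol


@dataclass(frozen=True)
class PVCResult:
    aic_single: float
    aic_two: float
    aic_difference: float
    verdict: str  # "single_map" | "two_maps"


# ---------------------------------------------------------------------------

def lesion_matrix(cohort: CohortLesions, voxels=None):
    """Stack cohort masks into a subjects x voxels binary matrix; columns
    restricted to ``voxels`` (flat indices) when given."""
    flat = np.stack([v.data.ravel() for v in cohort.volumes]).astype(float)
    if voxels is not None:
        flat = flat[:, np.asarray(voxels, int)]
    return flat


def voxel_coverage_filter(cohort: CohortLesions, min_fraction: float = 0.10) -> np.ndarray:
    """Flat indices of voxels lesioned in at least ``min_fraction`` of
    subjects (inclusive: count/n >= min_fraction)."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    counts = np.sum([v.data.ravel() for v in cohort.volumes], axis=0)
    n = len(cohort)
    return np.flatnonzero(counts / n >= min_fraction - 1e-12)


def regress_out(behavior, covariate) -> np.ndarray:
    """Residuals of an intercept+slope OLS of behavior on the covariate
    (e.g. total lesion size); residuals have zero mean."""
    y = np.asarray(behavior, float).ravel()
    z = np.asarray(covariate, float).ravel()
    if y.size != z.size:
        raise ValueError("behavior and covariate must align")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("behavior is constant")
    X = np.column_stack([np.ones(y.size), z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def tract_lesion_percentage(lesion: LesionVolume, atlas: TractAtlas) -> dict:
    """Per tract, |lesion ∩ tract| / |tract| in [0, 1]."""
    if atlas.grid_shape is not None and tuple(atlas.grid_shape) != lesion.data.shape:
        raise SpaceError("atlas and lesion grids differ")
    out = {}
    for name, vox in atlas.tracts.items():
        if (vox >= np.array(lesion.data.shape)[None, :]).any():
            raise SpaceError(f"tract {name!r} exceeds the lesion grid")
        hit = lesion.data[vox[:, 0], vox[:, 1], vox[:, 2]].sum()
        out[name] = float(hit) / vox.shape[0]
    return out


def disconnection_map(lesion: LesionVolume, streamlines: StreamlineSet,
                      binarize_threshold: float = 0.5):
    """Voxel-wise disconnection: per traversed voxel, the fraction of
    template streamlines through it that intersect the lesion, plus the
    binarized (fraction >= threshold) map.

    A streamline is disconnected iff any of its voxels is lesioned;
    untraversed voxels are 0 in both outputs.
    """
    if not (0.0 < binarize_threshold <= 1.0):
        raise ValueError("binarize_threshold must be in (0, 1]")
    shape = tuple(streamlines.grid_shape)
    if shape != lesion.data.shape:
        raise SpaceError("streamlines and lesion grids differ")
    total = np.zeros(int(np.prod(shape)))
    disc = np.zeros_like(total)
    lesion_flat = lesion.data.ravel()
    for path in streamlines.streamlines:
        uniq = np.unique(np.ravel_multi_index((path[:, 0], path[:, 1], path[:, 2]), shape))
        total[uniq] += 1.0
        if lesion_flat[uniq].any():
            disc[uniq] += 1.0
    frac = np.where(total > 0, disc / np.maximum(total, 1.0), 0.0).reshape(shape)
    binary = (frac >= binarize_threshold).astype(np.uint8)
    return frac, binary


# ---------------------------------------------------------------------------
# Sparse CCA LSM

def _retained_count(m: int, sparseness: float) -> int:
    return max(1, int(round(abs(sparseness) * m)))


def _fit_sparse_weights(X, y, keep: int, nonneg: bool, n_iter: int = 150):
    """Iterative hard thresholding on ||y_std - Xc w||^2 with the top
    ``keep`` |weights| retained per step; the final vector is returned
    unit-norm (correlation with Xw is scale invariant)."""
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    ys = (y - y.mean())
    sd = ys.std()
    if sd == 0:
        raise ValueError("behavior is constant")
    ys = ys / sd
    # deterministic Lipschitz bound via power iteration
    v = np.ones(m) / np.sqrt(m)
    for _ in range(30):
        v = Xc.T @ (Xc @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    L = max(np.linalg.norm(Xc @ v) ** 2, 1e-12)
    step = 1.0 / L
    w = np.zeros(m)
    for _ in range(n_iter):
        grad = Xc.T @ (ys - Xc @ w)
        w = w + step * grad
        if nonneg:
            w = np.maximum(w, 0.0)
        if keep < m:
            cut = np.partition(np.abs(w), m - keep)[m - keep]
            w[np.abs(w) < cut] = 0.0
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _fold_indices(n: int, folds: int, seed: int):
    order = np.random.default_rng(seed).permutation(n)
    return np.array_split(order, folds)


def sparse_cca_lsm(X, behavior, sparseness: float = -0.3, folds: int = 4,
                   seed: int = 0, voxels=None, grid_shape=None,
                   display_cut: float = 0.1) -> LSMResult:
    """Sparse canonical-correlation lesion-symptom mapping.

    Finds a unit-norm weight vector w maximizing corr(Xw, behavior)
    subject to retaining the top |sparseness| fraction of |w| (signs
    unconstrained when sparseness < 0, non-negative otherwise).
    Significance is the one-tailed correlation between pooled held-out
    predictions Xw and the behavior over k folds.  ``displayed_voxels``
    are negative-weight voxels whose |weight|/max|weight| exceeds the
    display cut (negative weights mark damage that predicts worse
    scores).
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("lesion matrix must be 2-D with at least one voxel")
    y = np.asarray(behavior, float).ravel()
    n, m = X.shape
    if y.size != n:
        raise ValueError("behavior must align with lesion-matrix rows")
    if np.ptp(y) == 0:
        raise ValueError("behavior is constant")
    voxels = np.arange(m) if voxels is None else np.asarray(voxels, int)
    keep = _retained_count(m, sparseness)
    nonneg = sparseness > 0

    w = _fit_sparse_weights(X, y, keep, nonneg)

    preds = np.empty(n)
    for test_idx in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test_idx)
        w_tr = _fit_sparse_weights(X[train], y[train], keep, nonneg)
        preds[test_idx] = X[test_idx] @ w_tr
    if np.ptp(preds) == 0:
        cv_r, p = 0.0, 1.0
    else:
        res = pearson(preds, y, alternative="greater")
        cv_r, p = res.r, res.p
    wmax = np.max(np.abs(w))
    if wmax > 0:
        disp = voxels[(w < 0) & (np.abs(w) / wmax > display_cut)]
    else:
        disp = np.array([], int)
    return LSMResult(weights=w, voxels=voxels,
                     grid_shape=tuple(grid_shape) if grid_shape else (m,),
                     cv_correlation=float(cv_r), p=float(p),
                     sparseness=sparseness, folds=folds, seed=seed,
                     displayed_voxels=frozenset(int(v) for v in disp))


def permutation_p(X, behavior, n_perm: int = 100, sparseness: float = -0.3,
                  folds: int = 4, seed: int = 0) -> float:
    """Permutation calibration of the cross-validated correlation."""
    base = sparse_cca_lsm(X, behavior, sparseness, folds, seed).cv_correlation
    rng = np.random.default_rng(seed)
    y = np.asarray(behavior, float).ravel()
    count = 0
    for i in range(n_perm):
        yp = rng.permutation(y)
        r = sparse_cca_lsm(X, yp, sparseness, folds, seed=seed + 1 + i).cv_correlation
        if r >= base:
            count += 1
    return (1 + count) / (n_perm + 1)


def pvc_verdict(aic_difference: float) -> str:
    """Two distinct maps only when the single-map AIC exceeds the
    two-map AIC by strictly more than 100."""
    return "two_maps" if aic_difference > 100.0 else "single_map"


def _cv_rss(X, y, keep, nonneg, folds, seed):
    """Residual sum of squares of cross-validated predictions, with a
    per-fold linear calibration (train-set intercept+slope of y on Xw)
    so residuals live on the behaviour scale."""
    n = X.shape[0]
    preds = np.empty(n)
    for test_idx in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test_idx)
        w = _fit_sparse_weights(X[train], y[train], keep, nonneg)
        s_tr = X[train] @ w
        A = np.column_stack([np.ones(train.size), s_tr])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        preds[test_idx] = coef[0] + coef[1] * (X[test_idx] @ w)
    return float(np.sum((y - preds) ** 2))


def pvc(X, behavior_1, behavior_2, sparseness: float = -0.3, folds: int = 4,
        seed: int = 0) -> PVCResult:
    """Predictive validity comparison of two behaviour maps.

    The single-map model fits one weight map on the stacked data (both
    behaviours, shared weights); the two-map model fits each behaviour
    separately.  Per model, AIC = sum over behaviours of n*ln(RSS/n)
    plus 2k with k = number of maps x retained-voxel count, residuals
    taken from cross-validated predictions.  A difference
    (single - two) > 100 indicates reliably distinct maps.
    """
    X = np.asarray(X, float)
    y1 = np.asarray(behavior_1, float).ravel()
    y2 = np.asarray(behavior_2, float).ravel()
    n, m = X.shape
    if y1.size != n or y2.size != n:
        raise ValueError("behaviours must align with the lesion matrix rows")
    # defensive standardization (both behaviours should arrive residualized)
    y1 = (y1 - y1.mean()) / (y1.std() or 1.0)
    y2 = (y2 - y2.mean()) / (y2.std() or 1.0)
    keep = _retained_count(m, sparseness)
    nonneg = sparseness > 0

    rss1 = _cv_rss(X, y1, keep, nonneg, folds, seed)
    rss2 = _cv_rss(X, y2, keep, nonneg, folds, seed)
    aic_two = n * np.log(rss1 / n) + n * np.log(rss2 / n) + 2 * (2 * keep)

    # single map: shared weights from stacked data, fold split on subjects
    preds1 = np.empty(n)
    preds2 = np.empty(n)
    for test_idx in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test_idx)
        Xs = np.vstack([X[train], X[train]])
        ys = np.concatenate([y1[train], y2[train]])
        w = _fit_sparse_weights(Xs, ys, keep, nonneg)
        s_tr = X[train] @ w
        for y, preds in ((y1, preds1), (y2, preds2)):
            A = np.column_stack([np.ones(train.size), s_tr])
            coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
            preds[test_idx] = coef[0] + coef[1] * (X[test_idx] @ w)
    rss1s = float(np.sum((y1 - preds1) ** 2))
    rss2s = float(np.sum((y2 - preds2) ** 2))
    aic_single = n * np.log(rss1s / n) + n * np.log(rss2s / n) + 2 * keep

    diff = float(aic_single - aic_two)
    return PVCResult(aic_single=float(aic_single), aic_two=float(aic_two),
                     aic_difference=diff, verdict=pvc_verdict(diff))


def label_weights(result: LSMResult, atlas: TractAtlas, min_share: float = 0.10):
    """Share of |weight| mass per atlas region, filtered at > min_share.

    Shares over all regions plus the unlabelled remainder sum to 1.
    Returns a DataFrame (region, share) sorted by share, and includes an
    ``unlabelled`` row only when it clears the filter.
    """
    import pandas as pd

    total = float(np.sum(np.abs(result.weights)))
    if total == 0.0:
        return pd.DataFrame(columns=["region", "share"])
    grid = result.grid_shape
    wvol = np.zeros(int(np.prod(grid)))
    wvol[result.voxels] = np.abs(result.weights)
    labelled = np.zeros_like(wvol, dtype=bool)
    rows = []
    for name, vox in atlas.tracts.items():
        flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), grid)
        rows.append((name, float(wvol[flat].sum()) / total))
        labelled[flat] = True
    rows.append(("unlabelled", float(wvol[~labelled].sum()) / total))
    df = pd.DataFrame(rows, columns=["region", "share"])
    df = df[df["share"] > min_share].sort_values("share", ascending=False)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# NIfTI / JSON I/O

def load_lesion_nifti(path, space_tag: str = "user") -> LesionVolume:
    img = nib.load(str(path))
    data = (np.asanyarray(img.dataobj) > 0.5).astype(np.uint8)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionVolume(data=data, voxel_size_mm=zooms, space_tag=space_tag)


def save_volume_nifti(data, path, voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_streamlines_json(path) -> StreamlineSet:
    payload = json.loads(open(path).read())
    return StreamlineSet(streamlines=tuple(np.asarray(p, int) for p in payload["streamlines"]),
                         grid_shape=tuple(payload["grid_shape"]))


def save_streamlines_json(streamlines: StreamlineSet, path) -> None:
    payload = {
        "grid_shape": list(streamlines.grid_shape),
        "streamlines": [p.tolist() for p in streamlines.streamlines],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def load_tract_atlas(path, grid_shape=None) -> TractAtlas:
    """Tract atlas from JSON voxel sets ({name: [[i,j,k], ...]}) or a
    NIfTI label volume (integer labels; names are 'region_<label>')."""
    path = str(path)
    if path.endswith(".json"):
        payload = json.loads(open(path).read())
        grid = tuple(payload.get("grid_shape", grid_shape or ()))
        return TractAtlas(tracts={k: np.asarray(v, int) for k, v in payload["tracts"].items()},
                          grid_shape=grid or None)
    img = nib.load(path)
    lab = np.asanyarray(img.dataobj).astype(int)
    tracts = {}
    for val in np.unique(lab):
        if val == 0:
            continue
        tracts[f"region_{val}"] = np.argwhere(lab == val)
    return TractAtlas(tracts=tracts, grid_shape=lab.shape)


def save_tract_atlas_json(atlas: TractAtlas, path) -> None:
    payload = {
        "grid_shape": list(atlas.grid_shape) if atlas.grid_shape else None,
        "tracts": {k: v.tolist() for k, v in sorted(atlas.tracts.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")
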