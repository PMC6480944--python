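"""Group ICA for multi-subject fMRI.

The three stages of temporal-concatenation group ICA: (1) data reduction —
per-run PCA to ``k1`` dimensions followed by a group PCA of the concatenated
reduced data to the model order; (2) Infomax ICA on the group-reduced data;
(3) back-reconstruction of per-subject-run spatial maps and time courses by
partitioning the group mixing matrix (GICA back-projection). The model order
can be estimated by a modified minimum-description-length criterion whose
effective sample size is corrected for spatial smoothness by voxel
subsampling.

Conventions: a data matrix is timepoints x in-mask voxels with every voxel
time series mean-centred; component sign is canonicalized so the voxel of
maximal absolute group-map value is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import SubjectScan

logger = logging.getLogger(__name__)


@dataclass
class DataMatrix:
    """Timepoints x voxels matrix for one subject-run, in-mask voxels only.

    ``mask`` maps matrix columns back to the 3-D grid (boolean volume); it may
    be omitted when the spatial layout is irrelevant (then the effective
    sample size for MDL falls back to a count-based stride correction).
    """

    values: np.ndarray
    mask: np.ndarray | None = None

    @classmethod
    def from_scan(cls, scan: SubjectScan, mask: np.ndarray) -> "DataMatrix":
        x = scan.data.reshape(-1, scan.data.shape[-1])[mask.reshape(-1)].T
        x = np.asarray(x, dtype=np.float64)
        x -= x.mean(axis=0, keepdims=True)  # centre each voxel time series
        return cls(values=x, mask=mask)


@dataclass
class GicaConfig:
    """Tunables for group ICA.

    ``k1`` is the per-run PCA order (default ``min(2 * n_components,
    timepoints)``, leaving headroom for the group reduction). MDL uses
    ``subsample_stride`` voxels per axis for the effective sample size.
    Infomax halves the learning rate and restarts on divergence, up to
    ``max_anneal`` retries.
    """

    k1: int | None = None
    max_order: int = 30
    subsample_stride: int = 2
    learning_rate: float = 0.05
    max_iter: int = 2048
    tol: float = 1e-6
    max_anneal: int = 5
    normalize_voxels: bool = False
    seed: int = 0


@dataclass
class GicaResult:
    """Group ICA output: group maps, mixing, per-subject maps and time courses."""

    n_components: int
    group_maps: np.ndarray                      # (k, voxels)
    group_mixing: np.ndarray                    # (n_runs * k1, k)
    subject_maps: dict[str, np.ndarray]         # subject -> (k, voxels), run-averaged
    subject_timecourses: dict[tuple[str, int], np.ndarray]  # (subject, run) -> (T, k)
    mask: np.ndarray | None
    affine: np.ndarray | None
    converged: bool

    def map_volume(self, maps_row: np.ndarray) -> np.ndarray:
        """Embed one spatial map (length = n in-mask voxels) into the 3-D grid."""
        if self.mask is None:
            raise ValueError("no mask recorded; cannot rebuild volumes")
        vol = np.zeros(self.mask.shape, dtype=float)
        vol[self.mask] = maps_row
        return vol

    def subject_map_volumes(self, subject_id: str) -> list[np.ndarray]:
        return [self.map_volume(row) for row in self.subject_maps[subject_id]]


# ---------------------------------------------------------------------------
# model order: modified MDL
# ---------------------------------------------------------------------------

def _effective_samples(mask: np.ndarray | None, n_voxels: int, stride: int) -> int:
    """Effective i.i.d. sample count after an every-stride-th-voxel subsample.

    fMRI voxels are spatially smoothed, so treating all of them as independent
    samples overstates the evidence; subsampling at ``stride`` per axis keeps
    roughly one voxel per smoothness kernel.
    """
    if stride <= 1:
        return n_voxels
    if mask is not None:
        coords = np.argwhere(mask)
        keep = np.all(coords % stride == 0, axis=1)
        n_eff = int(keep.sum())
    else:
        n_eff = n_voxels // stride**3
    return max(n_eff, 2)


def mdl_criterion(eigenvalues: np.ndarray, n_eff: int, max_order: int) -> np.ndarray:
    """MDL(k) for k = 1..max_order from descending sample-covariance eigenvalues.

    MDL(k) = -N' (p - k) log(g_k / a_k) + 0.5 k (2p - k + 1) log N', where
    g_k and a_k are the geometric and arithmetic means of the p - k smallest
    eigenvalues and N' the effective sample size.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = lam.size
    out = np.empty(max_order)
    log_lam = np.log(lam)
    for k in range(1, max_order + 1):
        tail = lam[k:]
        log_g = log_lam[k:].mean()
        a = tail.mean()
        out[k - 1] = -n_eff * (p - k) * (log_g - np.log(a)) \
            + 0.5 * k * (2 * p - k + 1) * np.log(n_eff)
    return out


def estimate_n_components_mdl(
    data: DataMatrix, max_order: int = 30, subsample_stride: int = 2
) -> int:
    """Estimate the ICA model order by the modified MDL criterion.

    Eigenvalues come from the temporal sample covariance (voxels as samples);
    the "modified" element is the spatial-correlation-corrected effective
    sample size N' obtained by voxel subsampling at ``subsample_stride``.
    Returns the argmin of MDL(k) over k in [1, max_order].
    """
    x = np.asarray(data.values, dtype=float)
    t, n_vox = x.shape
    if max_order >= min(t, n_vox):
        raise ValueError(
            f"max_order={max_order} must be < min(timepoints, voxels)={min(t, n_vox)}"
        )
    x = x - x.mean(axis=0, keepdims=True)
    cov = x @ x.T / n_vox
    lam = np.linalg.eigvalsh(cov)[::-1]
    tol = lam[0] * 1e-12 if lam[0] > 0 else 0.0
    p = int((lam > tol).sum())
    if p <= max_order:
        raise ValueError(
            f"only {p} positive eigenvalues after centering (need > max_order="
            f"{max_order}); data may be rank deficient"
        )
    lam = lam[:p]
    n_eff = _effective_samples(data.mask, n_vox, subsample_stride)
    crit = mdl_criterion(lam, n_eff, max_order)
    return int(np.argmin(crit)) + 1


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def pca_reduce(data, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce a timepoints x voxels matrix to its top-k temporal PCs.

    Returns ``(reduced, basis, eigenvalues)`` with ``reduced = basis.T @ X``
    of shape (k, voxels), ``basis`` the (timepoints, k) orthonormal
    eigenvectors of X X^T, and all eigenvalues in non-increasing order.
    Discarded variance equals the sum of the trailing eigenvalues.
    """
    x = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    t = x.shape[0]
    if k > t:
        raise ValueError(f"k={k} exceeds timepoints={t}")
    cov = x @ x.T
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    basis = vec[:, :k]
    reduced = basis.T @ x
    return reduced, basis, lam


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------

@dataclass
class InfomaxResult:
    unmixing: np.ndarray   # (k, k), includes whitening
    sources: np.ndarray    # (k, voxels)
    converged: bool
    n_iter: int


def infomax_ica(
    reduced: np.ndarray,
    learning_rate: float = 0.05,
    max_iter: int = 2048,
    tol: float = 1e-6,
    seed: int = 0,
    max_anneal: int = 5,
) -> InfomaxResult:
    """Infomax ICA by full-batch natural-gradient ascent.

    Whitens the k x voxels input, then iterates the natural-gradient update
    ``dW = eta (I + (1 - 2 y) u^T / n) W`` with the logistic nonlinearity
    ``y = 1 / (1 + exp(-u))`` until the weight-change Frobenius norm drops
    below ``tol`` or ``max_iter`` is reached. The step size anneals by a
    factor 0.9 whenever the update direction swings by more than 60 degrees
    (the classic oscillation heuristic), which is what drives the final
    convergence. On divergence (non-finite or exploding weights) the initial
    learning rate is halved and the run restarted, up to ``max_anneal``
    times; persistent divergence raises.
    """
    y0 = np.asarray(reduced, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise ValueError("non-finite values in input to infomax_ica")
    k, n = y0.shape
    y0 = y0 - y0.mean(axis=1, keepdims=True)
    cov = y0 @ y0.T / n
    lam, vec = np.linalg.eigh(cov)
    lam = np.clip(lam, 1e-12 * max(lam.max(), 1e-300), None)
    whiten = (vec / np.sqrt(lam)) @ vec.T  # symmetric whitening, (k, k)
    z = whiten @ y0

    eye = np.eye(k)
    cos60 = np.cos(np.radians(60.0))
    for attempt in range(max_anneal + 1):
        eta = learning_rate * 0.5**attempt
        rng = np.random.default_rng([int(seed), 17, attempt])
        w = np.linalg.qr(rng.normal(size=(k, k)))[0]
        converged = False
        diverged = False
        it = 0
        old_dw = None
        for it in range(1, max_iter + 1):
            u = w @ z
            y = 1.0 / (1.0 + np.exp(-u))
            grad = eye + (1.0 - 2.0 * y) @ u.T / n
            dw = eta * grad @ w
            w = w + dw
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e8:
                diverged = True
                break
            dw_norm = np.linalg.norm(dw)
            if old_dw is not None:
                cos_ang = float((dw * old_dw).sum()) / (
                    dw_norm * np.linalg.norm(old_dw) + 1e-300
                )
                if cos_ang < cos60:
                    eta *= 0.9
            old_dw = dw
            if dw_norm < tol:
                converged = True
                break
        if diverged:
            logger.warning(
                "infomax diverged; halving learning rate (retry %d)", attempt + 1
            )
            continue
        unmixing = w @ whiten
        return InfomaxResult(
            unmixing=unmixing,
            sources=unmixing @ np.asarray(reduced, dtype=float),
            converged=converged,
            n_iter=it,
        )
    raise RuntimeError(
        "infomax ICA diverged after annealing retries; reduce the learning rate"
    )


def amari_index(w_est: np.ndarray, a_true: np.ndarray) -> float:
    """Permutation/scale-invariant separation error in [0, 1]; 0 is perfect.

    Scores ``P = w_est @ a_true`` against a scaled permutation matrix.
    """
    p = np.abs(w_est @ a_true)
    k = p.shape[0]
    row = (p.sum(axis=1) / p.max(axis=1) - 1.0).sum()
    col = (p.sum(axis=0) / p.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * k * (k - 1)))


# ---------------------------------------------------------------------------
# full group ICA with back-reconstruction
# ---------------------------------------------------------------------------

def _canonical_signs(group_maps: np.ndarray) -> np.ndarray:
    """Per-component sign flips making the max-|value| voxel positive."""
    idx = np.argmax(np.abs(group_maps), axis=1)
    vals = group_maps[np.arange(group_maps.shape[0]), idx]
    signs = np.where(vals < 0, -1.0, 1.0)
    return signs


def run_group_ica(
    scans: list[SubjectScan],
    n_components: int | str = "auto",
    config: GicaConfig | None = None,
    mask: np.ndarray | None = None,
) -> GicaResult:
    """Run temporal-concatenation group ICA over all subject-runs.

    Each run is PCA-reduced to ``k1`` components; the reduced runs are
    concatenated along the (reduced) time axis, group-PCA-reduced to the model
    order, and Infomax-unmixed. Per-subject-run spatial maps are recovered by
    GICA back-projection (pseudo-inverse of each run's block of the group
    mixing matrix applied to that run's reduced data) and averaged over each
    subject's runs. With ``n_components="auto"`` the order is the median of
    per-run modified-MDL estimates.

    Amplitude convention: the map/time-course scale split is arbitrary per
    subject-run and component, so each component's time course is normalized
    to unit standard deviation and the amplitude moved into the spatial map.
    Without this, per-subject amplitude differences (the effect of interest
    in a two-group comparison) are absorbed by the mixing blocks and vanish
    from the maps. Group maps are scaled by the RMS of the per-run scales,
    which keeps the single-subject-single-run case an exact identity between
    subject and group maps.
    """
    if not scans:
        raise ValueError("no scans given")
    cfg = config or GicaConfig()
    shape = scans[0].data.shape
    for s in scans:
        if s.data.shape != shape:
            raise ValueError(
                f"inconsistent grids: {s.subject_id} run {s.run} has "
                f"{s.data.shape}, expected {shape}"
            )
    if mask is None:
        # voxels with any temporal variance in the first scan
        first = scans[0].data
        mask = first.std(axis=-1) > 0
    matrices = [DataMatrix.from_scan(s, mask) for s in scans]
    if cfg.normalize_voxels:
        for dm in matrices:
            sd = dm.values.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            dm.values /= sd

    if n_components == "auto":
        orders = [
            estimate_n_components_mdl(dm, cfg.max_order, cfg.subsample_stride)
            for dm in matrices
        ]
        k = int(round(float(np.median(orders))))
        logger.info("MDL model order: median %d over %d runs", k, len(orders))
    else:
        k = int(n_components)

    t = matrices[0].values.shape[0]
    k1 = cfg.k1 if cfg.k1 is not None else min(2 * k, t)
    if k1 < k:
        raise ValueError(f"k1={k1} must be >= n_components={k}")

    bases = []
    reduced_runs = []
    for dm in matrices:
        red, basis, _ = pca_reduce(dm, k1)
        bases.append(basis)
        reduced_runs.append(red)
    z = np.vstack(reduced_runs)  # (R * k1, voxels)

    group_red, group_basis, _ = pca_reduce(z, k)  # basis: (R*k1, k)
    ica = infomax_ica(
        group_red,
        learning_rate=cfg.learning_rate,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        seed=cfg.seed,
        max_anneal=cfg.max_anneal,
    )
    group_maps = ica.sources  # (k, voxels)
    # group mixing: stacked reduced data ~ mixing @ group_maps
    mixing = group_basis @ np.linalg.inv(ica.unmixing)  # (R*k1, k)

    per_subject: dict[str, list[np.ndarray]] = {}
    timecourses: dict[tuple[str, int], np.ndarray] = {}
    run_scales = np.empty((len(scans), k))
    for i, scan in enumerate(scans):
        block = mixing[i * k1:(i + 1) * k1, :]       # (k1, k)
        maps_i = np.linalg.pinv(block) @ reduced_runs[i]  # (k, voxels)
        tc_i = bases[i] @ block                       # (T, k)
        # unit-variance time courses; amplitude lives in the maps
        scale = tc_i.std(axis=0)
        scale[scale == 0] = 1.0
        run_scales[i] = scale
        maps_i *= scale[:, None]
        tc_i = tc_i / scale[None, :]
        per_subject.setdefault(scan.subject_id, []).append(maps_i)
        timecourses[(scan.subject_id, scan.run)] = tc_i
    group_maps = group_maps * np.sqrt((run_scales**2).mean(axis=0))[:, None]

    signs = _canonical_signs(group_maps)
    group_maps = group_maps * signs[:, None]
    mixing = mixing * signs[None, :]
    for key in timecourses:
        timecourses[key] = timecourses[key] * signs[None, :]
    for sid in per_subject:
        per_subject[sid] = [m * signs[:, None] for m in per_subject[sid]]
    subject_maps = {sid: np.mean(m, axis=0) for sid, m in per_subject.items()}

    return GicaResult(
        n_components=k,
        group_maps=group_maps,
        group_mixing=mixing,
        subject_maps=subject_maps,
        subject_timecourses=timecourses,
        mask=mask,
        affine=scans[0].affine,
        converged=ica.converged,
    )
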