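"""Seeded synthetic multi-subject task-fMRI cohorts.

Generates everything the downstream analysis consumes — an atlas
parcellation, block-design time courses, and 4-D subject-run volumes — with
the statistical structure the group-ICA pipeline assumes: spatially
independent source networks with region-shaped supports, mixed into voxel
time series by task-locked time courses, plus additive noise. A designated
set of atlas regions carries a group amplitude difference so that parameter
recovery by the full pipeline is a meaningful check.

The emulated study: two groups (healthy vs. schizophrenia, 34 subjects each),
three runs per subject, a Sternberg item-recognition block design with memory
loads of 1, 3 and 5 digits (two blocks per load per run, alternating with
fixation), TR 2 s, 180 volumes per 6-minute run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .atlas_assets import AAL_116_NAMES, AtlasParcellation, write_atlas

LOAD_CONDITIONS = ("load1", "load3", "load5")
#: group coding: +1 = schizophrenia (positive class), -1 = healthy
GROUP_PATIENT = 1
GROUP_HEALTHY = -1


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid: voxel counts, voxel size, run length and TR.

    The full-study grid is 53 x 63 x 46 voxels at 3 mm with 180 volumes at
    TR 2 s (a 6-minute run); tests use a reduced grid.
    """

    nx: int = 53
    ny: int = 63
    nz: int = 46
    voxel_size_mm: float = 3.0
    n_timepoints: int = 180
    tr_s: float = 2.0

    def __post_init__(self):
        for name in ("nx", "ny", "nz", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"GridSpec.{name} must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    @classmethod
    def reduced(cls, n_timepoints: int = 180) -> "GridSpec":
        """Reduced grid for tests and simulations on a single CPU."""
        return cls(nx=20, ny=22, nz=18, n_timepoints=n_timepoints)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: group sizes, planted sources, effect and noise.

    ``effect_regions`` are atlas labels whose source amplitude is multiplied
    by ``(1 + effect_size)`` in the patient group. ``subject_gain_sd`` is the
    standard deviation of the per-subject, per-region multiplicative gain
    (mean 1) — the between-subject regional amplitude variability against
    which the group effect competes. With the defaults (gain sd 0.1, effect
    0.22) the planted regional feature separates the groups at a Cohen's d
    near 2.
    """

    n_healthy: int = 34
    n_patient: int = 34
    n_runs: int = 3
    n_sources: int = 13
    effect_regions: tuple[int, ...] = (1,)
    effect_size: float = 0.22
    noise_sd: float = 0.5
    subject_gain_sd: float = 0.1
    ar_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 2 or self.n_patient < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")


@dataclass
class BlockDesign:
    """Per-timepoint condition labels plus boxcar and HRF-convolved regressors."""

    conditions: np.ndarray            # length T array of condition names
    boxcars: dict[str, np.ndarray]    # per load condition, 0/1 over T
    regressors: dict[str, np.ndarray]  # HRF-convolved boxcars
    tr_s: float


@dataclass
class SubjectScan:
    """One subject-run 4-D volume with grid metadata and group label."""

    subject_id: str
    run: int
    group: int                 # +1 patient, -1 healthy
    data: np.ndarray           # (nx, ny, nz, T) float32
    affine: np.ndarray
    tr_s: float


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def ellipsoid_mask(grid: GridSpec) -> np.ndarray:
    """Axis-aligned ellipsoidal brain mask centred in the grid."""
    ii, jj, kk = np.meshgrid(
        np.arange(grid.nx), np.arange(grid.ny), np.arange(grid.nz), indexing="ij"
    )
    cx, cy, cz = (grid.nx - 1) / 2, (grid.ny - 1) / 2, (grid.nz - 1) / 2
    rx, ry, rz = 0.45 * grid.nx, 0.45 * grid.ny, 0.45 * grid.nz
    r2 = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2
    return r2 <= 1.0


def make_atlas(grid: GridSpec, n_regions: int, seed: int) -> AtlasParcellation:
    """Partition an ellipsoidal brain mask into seeded Voronoi regions.

    Exactly ``n_regions`` non-empty cells labelled 1..n_regions; background 0.
    For 116 regions, names follow the embedded AAL table in AAL order.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = ellipsoid_mask(grid)
    coords = np.argwhere(mask)  # (M, 3)
    m = coords.shape[0]
    if n_regions > m:
        raise ValueError(
            f"n_regions={n_regions} exceeds the {m} in-mask voxels of grid {grid.shape}"
        )
    rng = np.random.default_rng([int(seed), 101])
    seed_idx = rng.choice(m, size=n_regions, replace=False)
    seed_pts = coords[seed_idx].astype(float)
    # nearest seed point; ties resolved toward the lowest seed index
    d2 = ((coords[:, None, :] - seed_pts[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[tuple(coords.T)] = assign
    if n_regions == 116:
        names = AAL_116_NAMES
    else:
        names = tuple(f"Region_{i:03d}" for i in range(1, n_regions + 1))
    return AtlasParcellation(labels=labels, names=names, affine=grid.affine)


# ---------------------------------------------------------------------------
# block design
# ---------------------------------------------------------------------------

def double_gamma_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Peak near 6 s, undershoot near 16 s with 1:6 amplitude ratio; normalized
    to unit peak.
    """
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    h = gamma_dist.pdf(t, a=6.0) - gamma_dist.pdf(t, a=16.0) / 6.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def convolve_hrf(boxcar: np.ndarray, tr_s: float) -> np.ndarray:
    """Convolve a regressor with the canonical HRF, truncated to run length."""
    h = double_gamma_hrf(tr_s)
    return np.convolve(np.asarray(boxcar, dtype=float), h)[: len(boxcar)]


def make_block_design(
    grid: GridSpec, seed: int, fixation_timepoints: int = 6
) -> BlockDesign:
    """Pseudorandom Sternberg block design for one run.

    Two blocks of each memory-load condition (1, 3 and 5 digits) alternate
    with seven fixation epochs; block order is a seeded permutation. Fixation
    epochs default to 6 TRs (12 s) — the source protocol fixes the block
    structure but not the fixation duration.
    """
    t_total = grid.n_timepoints
    n_blocks = 2 * len(LOAD_CONDITIONS)
    block_len = (t_total - (n_blocks + 1) * fixation_timepoints) // n_blocks
    if block_len < 1:
        raise ValueError(
            f"n_timepoints={t_total} too short for {n_blocks} task blocks plus "
            f"{n_blocks + 1} fixation epochs of {fixation_timepoints} timepoints"
        )
    rng = np.random.default_rng([int(seed), 202])
    order = rng.permutation(np.repeat(LOAD_CONDITIONS, 2))
    conditions = []
    for cond in order:
        conditions.extend(["fixation"] * fixation_timepoints)
        conditions.extend([cond] * block_len)
    conditions.extend(["fixation"] * (t_total - len(conditions)))
    conditions = np.array(conditions)
    boxcars = {c: (conditions == c).astype(float) for c in LOAD_CONDITIONS}
    regressors = {c: convolve_hrf(b, grid.tr_s) for c, b in boxcars.items()}
    return BlockDesign(
        conditions=conditions, boxcars=boxcars, regressors=regressors, tr_s=grid.tr_s
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def plan_source_supports(
    atlas: AtlasParcellation, n_sources: int, seed: int
) -> list[tuple[int, ...]]:
    """Deterministic partition of atlas labels into per-source support sets.

    Region labels are shuffled under the cohort seed and dealt round-robin to
    the sources, so supports are disjoint (spatial independence of the planted
    maps) and every region belongs to exactly one source.
    """
    labels = atlas.region_labels
    rng = np.random.default_rng([int(seed), 303])
    shuffled = rng.permutation(labels)
    supports: list[list[int]] = [[] for _ in range(n_sources)]
    for i, lab in enumerate(shuffled):
        supports[i % n_sources].append(int(lab))
    return [tuple(sorted(s)) for s in supports]


def _source_maps(
    atlas: AtlasParcellation,
    mask_flat: np.ndarray,
    supports: list[tuple[int, ...]],
    seed: int,
) -> np.ndarray:
    """Planted spatial sources: zero-mean Laplace loadings on disjoint supports."""
    labels_flat = atlas.labels.reshape(-1)[mask_flat]
    rng = np.random.default_rng([int(seed), 404])
    maps = np.zeros((len(supports), labels_flat.size))
    for k, sup in enumerate(supports):
        in_sup = np.isin(labels_flat, sup)
        maps[k, in_sup] = rng.laplace(0.0, 1.0, size=int(in_sup.sum()))
    return maps


def _ar1_noise(rng: np.random.Generator, shape: tuple, rho: float, sd: float) -> np.ndarray:
    white = rng.normal(0.0, sd, size=shape)
    if rho == 0.0:
        return white
    out = np.empty_like(white)
    out[0] = white[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + scale * white[t]
    return out


def simulate_cohort(
    cohort: CohortSpec, atlas: AtlasParcellation, grid: GridSpec
) -> tuple[list[SubjectScan], pd.DataFrame]:
    """Simulate all subject-run volumes for a two-group cohort.

    Each volume is ``sum_k a_k(t) * g_sr * m_v * s_k(v) + noise`` where the
    ``s_k`` are disjoint region-supported Laplace source maps, ``a_k(t)`` mixes
    one HRF-convolved load regressor with a slow drift and white innovation
    (standardized to unit variance), ``g_sr`` is the subject's gain for the
    region containing voxel v (independent across subjects and regions), and
    ``m_v`` is ``1 + effect_size`` over ``effect_regions`` for patients and 1
    otherwise. Returns the scans and a subject-level manifest (one row per
    subject: subject_id, group).
    """
    if atlas.labels.shape != grid.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match {grid.shape}"
        )
    missing = sorted(set(cohort.effect_regions) - set(atlas.region_labels.tolist()))
    if missing:
        raise ValueError(f"effect_regions not in atlas: {missing}")

    mask = ellipsoid_mask(grid)
    mask_flat = mask.reshape(-1)
    labels_flat = atlas.labels.reshape(-1)[mask_flat]
    supports = plan_source_supports(atlas, cohort.n_sources, cohort.seed)
    smaps = _source_maps(atlas, mask_flat, supports, cohort.seed)
    in_effect = np.isin(labels_flat, list(cohort.effect_regions))

    n_sub = cohort.n_healthy + cohort.n_patient
    groups = [GROUP_HEALTHY] * cohort.n_healthy + [GROUP_PATIENT] * cohort.n_patient
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_sub)]

    master = np.random.default_rng([int(cohort.seed), 505])
    region_labels = atlas.region_labels
    gains = 1.0 + cohort.subject_gain_sd * master.normal(
        size=(n_sub, region_labels.size)
    )
    # per-voxel index into the region-gain vector (0 for unlabeled voxels)
    label_pos = np.searchsorted(region_labels, labels_flat)
    labeled = np.isin(labels_flat, region_labels)

    t_total = grid.n_timepoints
    scans: list[SubjectScan] = []
    for s_idx, (sid, grp) in enumerate(zip(subject_ids, groups)):
        # patient amplitude modulation over the effect regions
        eff = 1.0 + (cohort.effect_size if grp == GROUP_PATIENT else 0.0)
        gain_vox = np.ones(labels_flat.size)
        gain_vox[labeled] = gains[s_idx][label_pos[labeled]]
        subj_maps = smaps.copy()
        subj_maps[:, in_effect] *= eff
        subj_maps *= gain_vox[None, :]
        for run in range(1, cohort.n_runs + 1):
            rng = np.random.default_rng([int(cohort.seed), 606, s_idx, run])
            design = make_block_design(
                grid, seed=int(rng.integers(2**31 - 1))
            )
            tcs = np.empty((t_total, cohort.n_sources))
            tt = np.arange(t_total)
            for k in range(cohort.n_sources):
                reg = design.regressors[LOAD_CONDITIONS[k % 3]]
                drift = np.cos(
                    2 * np.pi * rng.uniform(0.5, 2.0) * tt / t_total
                    + rng.uniform(0, 2 * np.pi)
                )
                a = reg + 0.4 * drift + 0.9 * rng.normal(size=t_total)
                a = a - a.mean()
                sd = a.std()
                tcs[:, k] = a / sd if sd > 0 else a
            signal = tcs @ subj_maps  # (T, M)
            noise = _ar1_noise(
                rng, signal.shape, cohort.ar_rho, cohort.noise_sd
            )
            vol = np.zeros((np.prod(grid.shape), t_total), dtype=np.float32)
            vol[mask_flat] = (signal + noise).T.astype(np.float32)
            data = vol.reshape(grid.shape + (t_total,))
            scans.append(
                SubjectScan(
                    subject_id=sid,
                    run=run,
                    group=grp,
                    data=data,
                    affine=grid.affine,
                    tr_s=grid.tr_s,
                )
            )
    manifest = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    return scans, manifest


def write_cohort(
    scans: list[SubjectScan],
    manifest: pd.DataFrame,
    out_dir,
    atlas: AtlasParcellation | None = None,
    provenance: dict | None = None,
) -> dict:
    """Write a simulated cohort to disk.

    One 4-D NIfTI-1 file per subject-run, the atlas volume (if given), a TSV
    run manifest (subject_id, group, run, path) and a JSON provenance record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    for scan in scans:
        path = out / f"{scan.subject_id}_run-{scan.run}.nii"
        nib.save(nib.Nifti1Image(scan.data, scan.affine), str(path))
        rows.append(
            {
                "subject_id": scan.subject_id,
                "group": group_of[scan.subject_id],
                "run": scan.run,
                "path": str(path),
            }
        )
    run_manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.tsv"
    run_manifest.to_csv(manifest_path, sep="\t", index=False)
    paths = {"manifest": str(manifest_path), "volumes": [r["path"] for r in rows]}
    if atlas is not None:
        paths["atlas"] = write_atlas(atlas, out / "atlas.nii")
    if provenance is not None:
        prov_path = out / "provenance.json"
        prov_path.write_text(json.dumps(provenance, indent=2, default=str))
        paths["provenance"] = str(prov_path)
    return paths


def cohort_provenance(cohort: CohortSpec, grid: GridSpec) -> dict:
    """JSON-serializable record of the generating configuration."""
    return {
        "cohort": dataclasses.asdict(cohort),
        "grid": dataclasses.asdict(grid),
    }
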