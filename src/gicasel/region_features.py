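"""Atlas segmentation of component maps and regional statistics.

Each subject's spatial map for one independent component is segmented by an
integer-labelled parcellation and summarized per region by five statistics of
the voxel values V_r = [v_1 .. v_N]:

    mean      mu = sum(v_i) / N
    std       sigma = sqrt(sum((v_i - mu)^2) / N)          (population form)
    skewness  S = sum((v_i - mu)^3) / (N sigma^3)
    kurtosis  K = sum((v_i - mu)^4) / (N sigma^4)           (raw, Normal -> 3)
    entropy   E = -sum_i P_i log2 P_i, P_i from an equal-width histogram

With a 116-region parcellation a subject is described by 580 = 116 x 5
features per component. Columns are region-major in ascending label order
with the statistic order above.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_assets import AtlasParcellation

logger = logging.getLogger(__name__)

STAT_NAMES = ("mean", "std", "skewness", "kurtosis", "entropy")


@dataclass
class RegionVoxelSet:
    """Voxel intensities of one atlas region from one subject's component map."""

    region_label: int
    region_name: str
    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class FeatureMatrix:
    """Subjects x (regions * 5 statistics) feature table for one component."""

    values: np.ndarray                         # (n_subjects, n_regions * 5)
    column_descriptors: list[tuple[str, str]]  # (region_name, statistic)
    subject_ids: list[str]
    group_labels: np.ndarray                   # +1 patient / -1 healthy

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, region_name: str, statistic: str) -> int:
        return self.column_descriptors.index((region_name, statistic))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{r}|{s}" for r, s in self.column_descriptors]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.group_labels)
        return df

    def write_tsv(self, path) -> str:
        self.to_frame().to_csv(str(path), sep="\t", index=False, float_format="%.12g")
        return str(path)

    def write_descriptors(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(
                [{"region": r, "statistic": s} for r, s in self.column_descriptors],
                fh,
                indent=2,
            )
        return str(path)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(str(path), sep="\t")
        desc = [tuple(c.rsplit("|", 1)) for c in df.columns[2:]]
        return cls(
            values=df.iloc[:, 2:].to_numpy(float),
            column_descriptors=desc,
            subject_ids=df["subject_id"].tolist(),
            group_labels=df["group"].to_numpy(int),
        )


def segment_map(
    component_map: np.ndarray, atlas: AtlasParcellation, strict: bool = True
) -> list[RegionVoxelSet]:
    """Split a 3-D component map into per-region voxel sets.

    One set per declared atlas label (1..len(names)) in ascending order;
    background (label 0) voxels are excluded. In strict mode an empty region
    raises; otherwise it yields an empty set (whose statistics are zero).
    """
    if component_map.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: map {component_map.shape} vs atlas {atlas.labels.shape}"
        )
    out = []
    for label in range(1, len(atlas.names) + 1):
        vals = component_map[atlas.labels == label]
        if vals.size == 0 and strict:
            raise ValueError(f"region {atlas.name_of(label)} (label {label}) is empty")
        out.append(
            RegionVoxelSet(
                region_label=int(label),
                region_name=atlas.name_of(int(label)),
                values=np.asarray(vals, dtype=float),
            )
        )
    return out


def region_statistics(region: RegionVoxelSet, histogram_bins: int = 256) -> np.ndarray:
    """Five-vector (mean, std, skewness, kurtosis, entropy) for one region.

    Moments use the population (divide-by-N) convention; kurtosis is raw (a
    Normal sample gives ~3). Entropy uses a normalized equal-width histogram
    over [min, max] with zero-probability bins skipped. Degenerate regions
    (constant values or a single voxel) report 0 for the shape statistics
    with a logged warning.
    """
    if histogram_bins < 2:
        raise ValueError("histogram_bins must be >= 2")
    v = np.asarray(region.values, dtype=float)
    n = v.size
    if n == 0:
        logger.warning("empty region %s: all five features set to 0", region.region_name)
        return np.zeros(5)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"non-finite voxel values in region {region.region_name}")
    mu = v.sum() / n
    dev = v - mu
    sigma = np.sqrt((dev**2).sum() / n)
    if sigma > 0:
        skew = (dev**3).sum() / (n * sigma**3)
        kurt = (dev**4).sum() / (n * sigma**4)
    else:
        logger.warning(
            "constant region %s (N=%d): skewness/kurtosis reported as 0",
            region.region_name, n,
        )
        skew = 0.0
        kurt = 0.0
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        counts, _ = np.histogram(v, bins=histogram_bins, range=(vmin, vmax))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    return np.array([mu, sigma, skew, kurt, entropy])


def build_feature_matrix(
    subject_maps: dict[str, np.ndarray],
    atlas: AtlasParcellation,
    manifest: pd.DataFrame,
    histogram_bins: int = 256,
    strict: bool = True,
    zscore_maps: bool = False,
) -> FeatureMatrix:
    """Feature matrix for one component: a row per subject in manifest order.

    ``subject_maps`` maps subject id to that subject's 3-D component map.
    With ``zscore_maps`` each map is standardized over its nonbackground
    voxels before segmentation. Missing subjects raise. With a 116-region
    atlas the result has 580 columns.
    """
    rows = []
    descriptors: list[tuple[str, str]] | None = None
    for sid in manifest["subject_id"]:
        if sid not in subject_maps:
            raise KeyError(f"missing component map for subject {sid}")
        cmap = subject_maps[sid]
        if zscore_maps:
            inb = atlas.labels > 0
            mu, sd = cmap[inb].mean(), cmap[inb].std()
            cmap = (cmap - mu) / (sd if sd > 0 else 1.0)
        regions = segment_map(cmap, atlas, strict=strict)
        if descriptors is None:
            descriptors = [
                (r.region_name, s) for r in regions for s in STAT_NAMES
            ]
        feats = np.concatenate(
            [region_statistics(r, histogram_bins) for r in regions]
        )
        rows.append(feats)
    values = np.vstack(rows)
    if strict and not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        r, c = bad[0]
        raise ValueError(
            f"non-finite feature at subject {manifest['subject_id'].iloc[r]}, "
            f"column {descriptors[c]}"
        )
    return FeatureMatrix(
        values=values,
        column_descriptors=descriptors,
        subject_ids=list(manifest["subject_id"]),
        group_labels=manifest["group"].to_numpy(int),
    )
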