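"""Backtracking selected features to named brain regions.

Selected feature columns are mapped back through the column descriptors to
(region, statistic) pairs, de-duplicated into a per-component region list
with fold-selection frequencies, coalesced across components into a
cross-component frequency table, and exported as TSV tables plus a NIfTI
label mask of the frequently occurring regions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_assets import AtlasParcellation, write_atlas


@dataclass
class IcRegionList:
    """Regions selected for one component, with statistics and frequencies."""

    regions: list[str]                       # de-duplicated, by descending frequency
    statistics: dict[str, set[str]]          # region -> statistics involved
    fold_frequency: dict[str, int]           # region -> folds (x repeats) selecting it
    n_folds: int


@dataclass
class RegionReport:
    """Cross-component coalesced region report."""

    per_ic: list[IcRegionList]
    cross_ic_frequency: dict[str, int]       # region -> number of components
    frequent_regions: list[str]              # at the stated threshold
    min_ic_count: int


def backtrack_features(
    chosen_subsets: list[tuple[int, ...]],
    column_descriptors: list[tuple[str, str]],
    min_fold_frac: float = 0.0,
) -> IcRegionList:
    """Map per-fold chosen feature columns of one component to named regions.

    A region is included when it is selected in more than ``min_fold_frac``
    of the folds (default: any fold). Frequencies count folds, not columns —
    choosing all five statistics of a region in one fold counts once.
    """
    n_cols = len(column_descriptors)
    freq: Counter = Counter()
    stats: dict[str, set[str]] = {}
    for subset in chosen_subsets:
        fold_regions = set()
        for col in subset:
            if not 0 <= col < n_cols:
                raise IndexError(
                    f"column index {col} outside descriptor table of {n_cols} columns"
                )
            region, stat = column_descriptors[col]
            fold_regions.add(region)
            stats.setdefault(region, set()).add(stat)
        freq.update(fold_regions)
    n_folds = len(chosen_subsets)
    threshold = min_fold_frac * n_folds
    kept = [r for r, c in freq.items() if c > threshold or (threshold == 0 and c >= 1)]
    kept.sort(key=lambda r: (-freq[r], r))
    return IcRegionList(
        regions=kept,
        statistics={r: stats[r] for r in kept},
        fold_frequency={r: int(freq[r]) for r in kept},
        n_folds=n_folds,
    )


def coalesce_regions(
    per_ic: list[IcRegionList], min_ic_count: int | None = None
) -> RegionReport:
    """Coalesce per-component region lists into a cross-component report.

    ``min_ic_count`` defaults to half the components (rounded up): a region
    is "frequently occurring" when at least that many components select it.
    The frequent set is sorted by descending frequency, then name.
    """
    if not per_ic:
        raise ValueError("need at least one per-component region list")
    n_ics = len(per_ic)
    if min_ic_count is None:
        min_ic_count = ceil(n_ics / 2)
    counts: Counter = Counter()
    for ic in per_ic:
        counts.update(set(ic.regions))
    frequent = [r for r, c in counts.items() if c >= min_ic_count]
    frequent.sort(key=lambda r: (-counts[r], r))
    return RegionReport(
        per_ic=per_ic,
        cross_ic_frequency=dict(counts),
        frequent_regions=frequent,
        min_ic_count=min_ic_count,
    )


def write_region_mask(
    frequent_regions: list[str], atlas: AtlasParcellation, path
) -> str:
    """NIfTI label volume keeping atlas labels of the frequent regions only."""
    name_to_label = {atlas.name_of(int(l)): int(l) for l in atlas.region_labels}
    unknown = [r for r in frequent_regions if r not in name_to_label]
    if unknown:
        raise ValueError(f"regions not in atlas: {unknown}")
    keep = {name_to_label[r] for r in frequent_regions}
    masked = np.where(np.isin(atlas.labels, list(keep)), atlas.labels, 0)
    out = AtlasParcellation(
        labels=masked.astype(atlas.labels.dtype), names=atlas.names, affine=atlas.affine
    )
    return write_atlas(out, path)


def per_ic_frame(ic: IcRegionList) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": ic.regions,
            "statistics": [
                ",".join(sorted(ic.statistics[r])) for r in ic.regions
            ],
            "fold_frequency": [ic.fold_frequency[r] for r in ic.regions],
            "n_folds": ic.n_folds,
        }
    )


def write_report(report: RegionReport, atlas: AtlasParcellation, out_dir) -> dict:
    """Write per-IC TSVs, the cross-IC frequency TSV, mask and summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"per_ic": []}
    for i, ic in enumerate(report.per_ic, start=1):
        p = out / f"ic-{i:02d}_regions.tsv"
        per_ic_frame(ic).to_csv(p, sep="\t", index=False)
        paths["per_ic"].append(str(p))
    cross = pd.DataFrame(
        sorted(
            report.cross_ic_frequency.items(), key=lambda kv: (-kv[1], kv[0])
        ),
        columns=["region", "n_components"],
    )
    cross_path = out / "cross_ic_frequency.tsv"
    cross.to_csv(cross_path, sep="\t", index=False)
    paths["cross_ic"] = str(cross_path)
    paths["mask"] = write_region_mask(
        report.frequent_regions, atlas, out / "frequent_regions_mask.nii"
    )
    lines = [
        "# Region report",
        "",
        f"Components: {len(report.per_ic)}",
        f"Frequent-region threshold: >= {report.min_ic_count} components",
        "",
        "## Frequently occurring regions",
        "",
    ]
    for r in report.frequent_regions:
        lines.append(f"- {r} ({report.cross_ic_frequency[r]} components)")
    summary = out / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    paths["summary"] = str(summary)
    return paths
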