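"""Embedded AAL region-name table and atlas I/O.

The Automated Anatomical Labeling (AAL) parcellation divides the MNI-space
brain volume into 116 named regions (90 cerebral, 26 cerebellar/vermian).
Only the public label *name* table is embedded here; the label *volume* is
not redistributed — users supply their own atlas NIfTI on the analysis grid,
and the synthetic atlas generator stands in for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import pandas as pd

#: AAL label names in canonical order; integer label i maps to AAL_116_NAMES[i-1].
AAL_116_NAMES: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
    "Cerebelum_Crus1_L", "Cerebelum_Crus1_R",
    "Cerebelum_Crus2_L", "Cerebelum_Crus2_R",
    "Cerebelum_3_L", "Cerebelum_3_R",
    "Cerebelum_4_5_L", "Cerebelum_4_5_R",
    "Cerebelum_6_L", "Cerebelum_6_R",
    "Cerebelum_7b_L", "Cerebelum_7b_R",
    "Cerebelum_8_L", "Cerebelum_8_R",
    "Cerebelum_9_L", "Cerebelum_9_R",
    "Cerebelum_10_L", "Cerebelum_10_R",
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6",
    "Vermis_7", "Vermis_8", "Vermis_9", "Vermis_10",
)


@dataclass(frozen=True)
class AalLabelTable:
    """Ordered (label, name) table for a 116-region AAL-style parcellation."""

    labels: tuple[int, ...]
    names: tuple[str, ...]

    def name_of(self, label: int) -> str:
        return self.names[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "name": self.names})


@dataclass
class AtlasParcellation:
    """Integer label volume plus an ordered region-name table.

    ``labels`` is a 3-D integer array; 0 is background, positive values are
    region labels. ``names`` maps label ``l`` to ``names[l - 1]``. ``affine``
    carries the voxel-to-world transform of the grid.
    """

    labels: np.ndarray
    names: tuple[str, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def region_labels(self) -> np.ndarray:
        """Sorted unique non-zero labels present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.size)

    def name_of(self, label: int) -> str:
        return self.names[label - 1]


def load_label_table() -> AalLabelTable:
    """Return the embedded 116-entry AAL label table (stable across calls)."""
    return AalLabelTable(labels=tuple(range(1, 117)), names=AAL_116_NAMES)


def load_atlas(path, names: tuple[str, ...] | None = None) -> AtlasParcellation:
    """Load an integer-labelled parcellation volume from a NIfTI-1 file.

    Parameters
    ----------
    path : str or Path
        NIfTI-1 file containing a 3-D integer label volume.
    names : tuple of str, optional
        Region names; label ``l`` maps to ``names[l-1]``. When omitted and the
        volume carries exactly the labels 1..116, the embedded AAL table is
        used; otherwise generic ``Region_###`` names are generated.

    Raises
    ------
    ValueError
        If the volume is not integer-valued, or if AAL naming is implied but
        labels fall outside 0..116.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"atlas volume {path} is not integer-valued")
    labels = np.round(data).astype(np.int32)
    max_label = int(labels.max(initial=0))
    if names is None:
        if max_label == 116:
            offenders = sorted(set(np.unique(labels)) - set(range(0, 117)))
            if offenders:
                raise ValueError(
                    f"labels outside 0..116 with AAL naming requested: {offenders}"
                )
            names = AAL_116_NAMES
        else:
            names = tuple(f"Region_{i:03d}" for i in range(1, max_label + 1))
    return AtlasParcellation(labels=labels, names=tuple(names), affine=img.affine)


def write_atlas(atlas: AtlasParcellation, path) -> str:
    """Write a parcellation to NIfTI-1, preserving labels and affine exactly."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(path))
    return str(path)


def write_label_table(atlas: AtlasParcellation, path) -> str:
    """Export the (label, name) table as TSV."""
    df = pd.DataFrame(
        {
            "label": np.arange(1, len(atlas.names) + 1),
            "name": list(atlas.names),
        }
    )
    df.to_csv(str(path), sep="\t", index=False)
    return str(path)
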