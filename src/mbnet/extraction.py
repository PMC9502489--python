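"""Region feature extraction from a voxelwise feature image and an atlas.

The real-data entry point: a gray-matter feature image (e.g. smoothed
modulated GM intensity, 3-D, or 4-D with a trailing feature axis) and an
integer atlas label image of the same spatial shape are turned into one
vertex-by-feature matrix per mapped region. Only label membership matters:
voxel coordinates are discarded, since the similarity computation treats a
region's features as a multiset. Background label 0 is always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mbnet.cohort import RegionFeatureSet

__all__ = ["AtlasLabelImage", "extract_region_features", "load_nifti", "read_label_map"]


@dataclass
class AtlasLabelImage:
    """3-D integer label array plus a label -> region-name map.

    Labels are non-negative; 0 is background. ``missing_labels`` lists any
    mapped label absent from the array (flagged at construction, fatal at
    extraction time).
    """

    labels: np.ndarray
    names: dict
    missing_labels: list = field(init=False, default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative (0 = background)")
        present = set(np.unique(self.labels).tolist())
        self.missing_labels = sorted(int(l) for l in self.names if int(l) != 0 and int(l) not in present)


def extract_region_features(feature_image, atlas: AtlasLabelImage, mask_nonfinite: bool = False) -> list:
    """One :class:`RegionFeatureSet` per mapped atlas label.

    ``feature_image`` is a 3-D array (single feature) or 4-D with features
    on the last axis; its spatial shape must match the atlas. Non-finite
    voxels inside a region are an error unless ``mask_nonfinite`` drops
    them. A mapped label with no voxels is an error naming the label.
    """
    img = np.asarray(getattr(feature_image, "dataobj", feature_image), dtype=float)
    if img.ndim == 3:
        img = img[..., None]
    if img.ndim != 4:
        raise ValueError(f"feature image must be 3-D or 4-D, got shape {img.shape}")
    if img.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"feature image spatial shape {img.shape[:3]} != atlas shape {atlas.labels.shape}"
        )
    if atlas.missing_labels:
        raise ValueError(f"mapped labels absent from atlas image: {atlas.missing_labels}")

    out = []
    for label, name in sorted(atlas.names.items(), key=lambda kv: int(kv[0])):
        label = int(label)
        if label == 0:
            continue
        vals = img[atlas.labels == label]  # (n_voxels, d)
        finite = np.all(np.isfinite(vals), axis=1)
        if not finite.all():
            if mask_nonfinite:
                vals = vals[finite]
            else:
                raise ValueError(
                    f"region label {label} ({name}): {int((~finite).sum())} non-finite voxel(s); "
                    "set mask_nonfinite=True to drop them"
                )
        if vals.shape[0] == 0:
            raise ValueError(f"region label {label} ({name}): no usable voxels")
        out.append(RegionFeatureSet(region_id=label, name=str(name), values=vals))
    return out


def load_nifti(path):
    """Load a NIfTI image, returning (data array, nibabel image)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img


def read_label_map(path) -> dict:
    """Two-column TSV (label, name) -> {label: name}; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label map needs two columns (label, name)")
    first = df.iloc[0, 0]
    try:
        int(first)
    except ValueError:
        df = df.iloc[1:]  # header row
    return {int(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}


def features_to_long_tsv(subject_id: str, regions, path) -> None:
    """Write extracted regions in the long-form feature TSV of the cohort module."""
    frames = []
    for reg in regions:
        n, d = reg.values.shape
        df = pd.DataFrame(reg.values, columns=[f"f{i + 1}" for i in range(d)])
        df.insert(0, "vertex_index", np.arange(n))
        df.insert(0, "region_id", reg.region_id)
        df.insert(0, "subject_id", subject_id)
        frames.append(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")
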