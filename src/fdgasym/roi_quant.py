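"""Regional SUVmean extraction against a left/right-paired parcellation.

Mirrors the static-PET processing chain: the label volume is resampled
(nearest neighbor, through world coordinates) onto the PET grid, then
the arithmetic mean of the SUV image is taken over each region.  Labels
are always brought to the PET grid, never the reverse, so intensities
are never interpolated before averaging.  Background (label 0) is never
included in any mean.  The epileptogenic-zone ROI may be a single
region or a union of regions; a union's SUVmean is voxel-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .phantom import LabelVolume, SUVVolume

__all__ = ["ROIStats", "RegionPair", "resample_labels", "extract_suvmean", "paired_suvmeans"]


@dataclass(frozen=True)
class ROIStats:
    """SUVmean of one region (or union) at one acquisition time."""

    label: Union[int, tuple]
    name: str
    n_voxels: int
    suvmean: float
    t_min: float


@dataclass(frozen=True)
class RegionPair:
    """EZ-side and contralateral SUVmeans at one time point."""

    ez_label: Union[int, tuple]
    ez_suvmean: float
    contra_label: Union[int, tuple]
    contra_suvmean: float
    timepoint: str  # "early" | "delayed"


def _check_affine(affine: np.ndarray) -> None:
    if abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")


def resample_labels(labels: LabelVolume, target_affine: np.ndarray, target_shape) -> LabelVolume:
    """Nearest-neighbor resampling of integer labels onto a target grid.

    Each target voxel is mapped through world coordinates into the
    source grid and takes the label of the nearest source voxel; ties
    at exact half-voxel boundaries resolve toward the lower index.
    Voxels mapping outside the source grid become background.  The
    pairing table and names carry over unchanged.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    _check_affine(labels.affine)
    _check_affine(target_affine)
    if tuple(target_shape) == labels.data.shape and np.allclose(target_affine, labels.affine):
        return LabelVolume(labels.data.copy(), labels.affine.copy(), dict(labels.pairs), dict(labels.names))

    idx = np.indices(tuple(target_shape)).reshape(3, -1).astype(float)
    src_vox = np.linalg.inv(labels.affine) @ target_affine
    coords = src_vox[:3, :3] @ idx + src_vox[:3, 3:4]
    # round half toward the lower index: ceil(x - 1/2)
    nearest = np.ceil(coords - 0.5).astype(np.int64)
    inside = np.all((nearest >= 0) & (nearest < np.array(labels.data.shape)[:, None]), axis=0)
    out = np.zeros(idx.shape[1], dtype=labels.data.dtype)
    ni = nearest[:, inside]
    out[inside] = labels.data[ni[0], ni[1], ni[2]]
    return LabelVolume(
        data=out.reshape(tuple(target_shape)),
        affine=target_affine.copy(),
        pairs=dict(labels.pairs),
        names=dict(labels.names),
    )


def _resolve(labels: LabelVolume, label) -> tuple:
    """Normalize a label spec (id, name, or iterable thereof) to label ids."""
    if isinstance(label, str):
        return (labels.label_for_name(label),)
    if isinstance(label, (int, np.integer)):
        return (int(label),)
    if isinstance(label, Iterable):
        out = []
        for item in label:
            out.extend(_resolve(labels, item))
        return tuple(out)
    raise TypeError(f"cannot interpret region spec {label!r}")


def _require_same_grid(image: SUVVolume, labels: LabelVolume) -> None:
    if image.data.shape != labels.data.shape or not np.allclose(image.affine, labels.affine):
        raise ValueError(
            "image and label grids differ; resample the labels onto the PET grid "
            "with resample_labels() first"
        )


def extract_suvmean(image: SUVVolume, labels: LabelVolume, label) -> ROIStats:
    """Arithmetic mean of the SUV image over one region or union of regions."""
    _require_same_grid(image, labels)
    ids = _resolve(labels, label)
    present = set(int(l) for l in labels.labels())
    absent = [i for i in ids if i not in present]
    if absent:
        raise KeyError(f"label(s) {absent} absent from parcellation; available: {sorted(present)}")
    mask = np.isin(labels.data, ids)
    n = int(mask.sum())
    name = "+".join(labels.names.get(i, str(i)) for i in ids)
    return ROIStats(
        label=ids[0] if len(ids) == 1 else ids,
        name=name,
        n_voxels=n,
        suvmean=float(image.data[mask].mean()),
        t_min=image.t_min,
    )


def paired_suvmeans(image: SUVVolume, labels: LabelVolume, ez_label, timepoint: str = "") -> RegionPair:
    """SUVmean of the EZ region (or union) and its mirror partner."""
    ids = _resolve(labels, ez_label)
    try:
        partners = tuple(labels.partner(i) for i in ids)
    except KeyError as exc:
        raise KeyError(f"EZ region has no mirror partner: {exc}") from exc
    ez = extract_suvmean(image, labels, ids)
    contra = extract_suvmean(image, labels, partners)
    return RegionPair(
        ez_label=ez.label,
        ez_suvmean=ez.suvmean,
        contra_label=contra.label,
        contra_suvmean=contra.suvmean,
        timepoint=timepoint,
    )
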