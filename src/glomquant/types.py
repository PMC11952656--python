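"""Core domain types shared across the imaging pipeline.

Axis convention is ``(z, y, x)`` with 0-based voxel indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import EmptyRegionError


@dataclass(frozen=True)
class VoxelStack:
    """A single-channel 3D intensity grid.

    Parameters
    ----------
    data
        3D array, axis order ``(z, y, x)``. Values must be finite and
        non-negative; integer and floating dtypes are both accepted.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"VoxelStack requires a 3D array, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError(f"VoxelStack requires a numeric dtype, got {arr.dtype}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("VoxelStack values must be finite")
        if arr.min() < 0:
            raise ValueError("VoxelStack values must be non-negative")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass(frozen=True)
class GlomerulusAtlas:
    """Labeled integer volume mapping voxels to named glomeruli.

    ``labels`` uses 0 for background; ``name_table`` maps each nonzero
    label to a unique glomerulus name. A name may map to a label absent
    from the volume (tolerated at load time with a warning); using such a
    region raises :class:`~glomquant.errors.EmptyRegionError`.
    """

    labels: np.ndarray
    name_table: Dict[int, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"atlas labels must be integer-typed, got {arr.dtype}")
        names = list(self.name_table.values())
        if len(names) != len(set(names)):
            raise ValueError("glomerulus names must be unique")
        if 0 in self.name_table:
            raise ValueError("label 0 is reserved for background")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def names(self) -> List[str]:
        return list(self.name_table.values())

    def label_of(self, name: str) -> int:
        for label, nm in self.name_table.items():
            if nm == name:
                return label
        raise KeyError(f"glomerulus {name!r} not in atlas")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the named glomerulus; raises if it has no voxels."""
        m = self.labels == self.label_of(name)
        if not m.any():
            raise EmptyRegionError(f"glomerulus {name!r} has no voxels")
        return m

    def voxel_count(self, name: str) -> int:
        return int(self.mask(name).sum())


@dataclass
class DensityRecord:
    """Per-glomerulus mean fluorescence density (intensity sum / voxel count)."""

    densities: Dict[str, float]
    voxel_counts: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "densities": {k: float(v) for k, v in self.densities.items()},
            "voxel_counts": {k: int(v) for k, v in self.voxel_counts.items()},
        }


@dataclass
class TargetingMask:
    """Boolean targeting-area mask with the parameters that produced it."""

    mask: np.ndarray
    threshold_used: float
    blur_radius: float

    def __post_init__(self) -> None:
        if self.mask.ndim != 3 or self.mask.dtype != bool:
            raise ValueError("TargetingMask.mask must be a 3D boolean array")


@dataclass
class MistargetRecord:
    """Per-glomerulus targeting volumes and off-target/reference ratios."""

    volumes: Dict[str, int]
    reference: str
    ratios: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "volumes": {k: int(v) for k, v in self.volumes.items()},
            "reference": self.reference,
            "ratios": {k: float(v) for k, v in self.ratios.items()},
        }


@dataclass
class PhenotypeCall:
    """Mistargeting phenotype call by a minimum-evidence-volume rule."""

    positive: bool
    evidence_voxels: int
    min_voxels: int
    target: str

    def __post_init__(self) -> None:
        assert self.positive == (self.evidence_voxels >= self.min_voxels)

    def to_dict(self) -> dict:
        return {
            "positive": bool(self.positive),
            "evidence_voxels": int(self.evidence_voxels),
            "min_voxels": int(self.min_voxels),
            "target": self.target,
        }


@dataclass
class QuantRecord:
    """All per-sample quantification outputs."""

    sample_id: str
    density: DensityRecord
    preference_index: Optional[float]
    mistarget: MistargetRecord
    phenotype: PhenotypeCall
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "density": self.density.to_dict(),
            "preference_index": (
                None if self.preference_index is None else float(self.preference_index)
            ),
            "mistarget": self.mistarget.to_dict(),
            "phenotype": self.phenotype.to_dict(),
            "params": self.params,
        }
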