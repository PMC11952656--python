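"""Imaging quantification: blur, Otsu segmentation, masked densities,
preference indices, mistargeting ratios, and phenotype calls.

The segmentation path mirrors the standard interactive workflow: per-slice
2D Gaussian smoothing followed by a global Otsu threshold; foreground is
strictly greater than the threshold. Densities are always measured on the
raw (unblurred) channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    UndefinedIndexError,
    ZeroReferenceVolumeError,
)
from .types import (
    DensityRecord,
    GlomerulusAtlas,
    MistargetRecord,
    PhenotypeCall,
    QuantRecord,
    TargetingMask,
    VoxelStack,
)

DEFAULT_BLUR_RADIUS = 1.0
DEFAULT_NBINS = 256
DEFAULT_MIN_VOXELS = 10
# kernel support in sigmas; 6 keeps truncation error below 1e-8 relative
GAUSSIAN_TRUNCATE = 6.0


def gaussian_blur(stack: VoxelStack, radius: float) -> VoxelStack:
    """Per-slice 2D Gaussian smoothing with sigma = ``radius`` pixels.

    Reflective border padding; depth (z) is never mixed across slices.
    """
    if radius <= 0:
        raise ValueError(f"blur radius must be > 0, got {radius}")
    blurred = ndimage.gaussian_filter(
        stack.data.astype(np.float64),
        sigma=(0.0, radius, radius),
        mode="reflect",
        truncate=GAUSSIAN_TRUNCATE,
    )
    # smoothing of non-negative data is non-negative up to rounding
    np.clip(blurred, 0.0, None, out=blurred)
    return VoxelStack(blurred)


def otsu_threshold(stack: VoxelStack, nbins: int = DEFAULT_NBINS) -> float:
    """Threshold maximizing between-class variance on a global histogram.

    The histogram has ``nbins`` equal-width bins spanning [min, max] of all
    voxels. Candidate thresholds are the bin centers; the returned value is
    the center of the last background bin, so ``value > threshold`` selects
    the foreground class. Ties are broken toward the lowest threshold.
    """
    data = stack.data.ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise DegenerateHistogramError("stack is constant; no threshold exists")
    counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0

    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)                     # weight of class {bins <= t}
    w1 = w0[-1] - w0
    s0 = np.cumsum(counts * centers)           # first moments
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(s0[-1] - s0, w1, out=np.zeros_like(s0), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2       # between-class variance, unnormalized

    valid = (w0 > 0) & (w1 > 0)
    sigma_b[~valid] = -np.inf
    best = int(np.argmax(sigma_b))             # argmax takes the first (lowest) tie
    return float(centers[best])


def segment_targeting(
    stack: VoxelStack,
    radius: float = DEFAULT_BLUR_RADIUS,
    nbins: int = DEFAULT_NBINS,
) -> TargetingMask:
    """Define the targeting area: blur then Otsu; foreground is > threshold."""
    blurred = gaussian_blur(stack, radius)
    thr = otsu_threshold(blurred, nbins=nbins)
    return TargetingMask(mask=blurred.data > thr, threshold_used=thr, blur_radius=radius)


def mean_density(stack: VoxelStack, atlas: GlomerulusAtlas, name: str) -> float:
    """Mean fluorescent density: total intensity in the region / its volume."""
    region = atlas.mask(name)  # KeyError if unknown, EmptyRegionError if empty
    return float(stack.data[region].mean())


def preference_index(i_a: float, i_b: float) -> float:
    """Normalized difference (a - b) / (a + b), in [-1, 1].

    Positive means the first input is larger. Undefined (both zero) is an
    error rather than 0: returning 0 would fabricate "no preference".
    """
    if i_a < 0 or i_b < 0:
        raise ValueError("densities must be non-negative")
    total = i_a + i_b
    if total == 0:
        raise UndefinedIndexError("preference index undefined for (0, 0)")
    return float((i_a - i_b) / total)


def mistargeting_ratio(
    mask: TargetingMask,
    atlas: GlomerulusAtlas,
    reference: str,
    others: Sequence[str],
) -> MistargetRecord:
    """Targeting volume per glomerulus and each off-target/reference ratio."""
    volumes: Dict[str, int] = {}
    for name in [reference, *others]:
        volumes[name] = int(np.count_nonzero(mask.mask & atlas.mask(name)))
    v_ref = volumes[reference]
    if v_ref == 0:
        raise ZeroReferenceVolumeError(
            f"reference {reference!r} has zero targeting volume"
        )
    ratios = {name: volumes[name] / v_ref for name in others}
    return MistargetRecord(volumes=volumes, reference=reference, ratios=ratios)


def call_phenotype(
    record: MistargetRecord, target: str, min_voxels: int = DEFAULT_MIN_VOXELS
) -> PhenotypeCall:
    """Mistargeting-positive iff the target's volume is >= ``min_voxels``."""
    if target not in record.volumes:
        raise KeyError(f"target {target!r} not in mistarget record")
    v = record.volumes[target]
    return PhenotypeCall(
        positive=v >= min_voxels,
        evidence_voxels=v,
        min_voxels=min_voxels,
        target=target,
    )


@dataclass(frozen=True)
class QuantConfig:
    """Parameters for :func:`quantify_sample`."""

    reference: str = "VA1d"
    others: Sequence[str] = ("VA1v",)
    protein_pair: Sequence[str] = ("VA1d", "VA1v")
    phenotype_target: Optional[str] = None  # default: first off-target
    blur_radius: float = DEFAULT_BLUR_RADIUS
    nbins: int = DEFAULT_NBINS
    min_voxels: int = DEFAULT_MIN_VOXELS

    def target(self) -> str:
        return self.phenotype_target or self.others[0]


def quantify_sample(
    channels: Mapping[str, VoxelStack],
    atlas: GlomerulusAtlas,
    config: QuantConfig = QuantConfig(),
    sample_id: str = "sample",
) -> QuantRecord:
    """Full per-sample quantification.

    Densities and the preference index come from the raw ``protein``
    channel; segmentation, targeting volumes, mistargeting ratios, and the
    phenotype call come from the blurred+thresholded ``label`` channel.
    """
    for key in ("label", "protein"):
        if key not in channels:
            raise KeyError(f"sample {sample_id!r}: missing channel {key!r}")
        if channels[key].shape != atlas.shape:
            raise ValueError(
                f"sample {sample_id!r}: channel {key!r} shape "
                f"{channels[key].shape} != atlas shape {atlas.shape}"
            )
    try:
        protein = channels["protein"]
        names = list(dict.fromkeys([*config.protein_pair, config.reference, *config.others]))
        densities = {nm: mean_density(protein, atlas, nm) for nm in names}
        counts = {nm: atlas.voxel_count(nm) for nm in names}
        density = DensityRecord(densities=densities, voxel_counts=counts)
        a, b = config.protein_pair
        try:
            pi = preference_index(densities[a], densities[b])
        except UndefinedIndexError:
            pi = None

        mask = segment_targeting(
            channels["label"], radius=config.blur_radius, nbins=config.nbins
        )
        mistarget = mistargeting_ratio(mask, atlas, config.reference, config.others)
        phenotype = call_phenotype(mistarget, config.target(), config.min_voxels)
    except Exception as exc:
        raise type(exc)(f"sample {sample_id!r}: {exc}") from exc

    params = {
        "blur_radius": config.blur_radius,
        "nbins": config.nbins,
        "min_voxels": config.min_voxels,
        "threshold_used": float(mask.threshold_used),
        "reference": config.reference,
        "others": list(config.others),
        "protein_pair": list(config.protein_pair),
        "phenotype_target": config.target(),
    }
    return QuantRecord(
        sample_id=sample_id,
        density=density,
        preference_index=pi,
        mistarget=mistarget,
        phenotype=phenotype,
        params=params,
    )
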