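"""Synthetic ground-truth generators.

Emulates the study's raw inputs — multi-channel confocal stacks of labeled
neurites over an atlas of glomeruli, and genes x cell-types count tables —
with every planted parameter recorded in a manifest, so the whole pipeline
is testable without any external data.

Conventions: axis order ``(z, y, x)``, 0-based voxel indices; a voxel
belongs to an ellipsoid iff its center satisfies the ellipsoid inequality.
One global integer seed; per-sample seeds are ``seed + sample_index``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import BoundsError, OverlapError
from .types import GlomerulusAtlas, VoxelStack

# ---------------------------------------------------------------------------
# atlas


@dataclass(frozen=True)
class EllipsoidSpec:
    """One glomerulus: an axis-aligned ellipsoid in voxel coordinates."""

    name: str
    center: Tuple[float, float, float]  # (z, y, x)
    radii: Tuple[float, float, float]   # (rz, ry, rx)


@dataclass(frozen=True)
class AtlasSpec:
    stack_shape: Tuple[int, int, int]
    glomeruli: Tuple[EllipsoidSpec, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.glomeruli]
        if len(names) != len(set(names)):
            raise ValueError("glomerulus names must be unique")
        object.__setattr__(self, "glomeruli", tuple(self.glomeruli))


def _ellipsoid_mask(shape: Tuple[int, int, int], g: EllipsoidSpec) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = g.center
    rz, ry, rx = g.radii
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def build_atlas(spec: AtlasSpec) -> GlomerulusAtlas:
    """Render the spec's ellipsoids into an integer label volume.

    Labels are 1-based in declaration order; 0 is background. Overlapping
    ellipsoids raise :class:`OverlapError`; an ellipsoid whose bounding box
    leaves the stack raises :class:`BoundsError`.
    """
    labels = np.zeros(spec.stack_shape, dtype=np.uint16)
    name_table: Dict[int, str] = {}
    for i, g in enumerate(spec.glomeruli, start=1):
        for axis in range(3):
            if g.center[axis] - g.radii[axis] < 0 or (
                g.center[axis] + g.radii[axis] > spec.stack_shape[axis] - 1
            ):
                raise BoundsError(
                    f"glomerulus {g.name!r} extends outside the stack on axis {axis}"
                )
        mask = _ellipsoid_mask(spec.stack_shape, g)
        if not mask.any():
            raise ValueError(f"glomerulus {g.name!r} renders to zero voxels")
        if (labels[mask] != 0).any():
            raise OverlapError(f"glomerulus {g.name!r} overlaps an earlier region")
        labels[mask] = i
        name_table[i] = g.name
    return GlomerulusAtlas(labels=labels, name_table=name_table)


# ---------------------------------------------------------------------------
# image samples


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated sample (or a cohort template).

    ``mistarget_fraction`` maps each off-target glomerulus to the fraction
    of its voxels occupied by mistargeted label signal. ``protein_mean``
    holds the planted per-glomerulus mean protein intensity (pre-noise).
    """

    seed: int
    reference: str = "VA1d"
    mistarget_fraction: Dict[str, float] = field(default_factory=dict)
    label_intensity: float = 200.0
    protein_mean: Dict[str, float] = field(default_factory=dict)
    gaussian_sd: float = 0.0
    poisson: bool = False
    psf_sigma: float = 0.0
    phenotype_prob: float = 1.0

    def __post_init__(self) -> None:
        for name, m in self.mistarget_fraction.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mistarget_fraction[{name!r}]={m} not in [0,1]")
        if not 0.0 <= self.phenotype_prob <= 1.0:
            raise ValueError("phenotype_prob must be in [0,1]")
        if self.label_intensity < 0 or self.gaussian_sd < 0 or self.psf_sigma < 0:
            raise ValueError("intensities and noise scales must be >= 0")
        if any(v < 0 for v in self.protein_mean.values()):
            raise ValueError("protein_mean values must be >= 0")


@dataclass
class SampleManifest:
    """Exactly what was planted in one rendered sample."""

    seed: int
    reference: str
    mistarget_fraction: Dict[str, float]
    planted_volumes: Dict[str, int]       # rendered foreground voxels per glomerulus
    planted_proportions: Dict[str, float]  # planted_volumes[g] / planted_volumes[ref]
    label_intensity: float
    protein_mean: Dict[str, float]
    noise: dict
    positive: bool

    def to_dict(self) -> dict:
        return asdict(self)


NEUROPIL_INTENSITY = 120.0
NEUROPIL_BACKGROUND = 8.0


def _contiguous_subregion(
    region: np.ndarray, n_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """A contiguous blob of exactly ``n_voxels`` voxels inside ``region``.

    Grown by Euclidean distance from a randomly chosen seed voxel, with a
    deterministic (z, y, x) tie-break so equal seeds give equal blobs.
    """
    coords = np.argwhere(region)
    seed_voxel = coords[rng.integers(len(coords))]
    d2 = ((coords - seed_voxel) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    chosen = coords[order[:n_voxels]]
    out = np.zeros_like(region)
    out[tuple(chosen.T)] = True
    return out


def simulate_sample(
    spec: AtlasSpec, truth: SimTruth
) -> Tuple[Dict[str, VoxelStack], GlomerulusAtlas, SampleManifest]:
    """Render one sample: neuropil, label, and protein channels plus manifest.

    The label channel fills the reference glomerulus at ``label_intensity``
    and, for each off-target g with fraction m_g > 0, a contiguous random
    sub-region covering m_g of g's voxels. The protein channel is constant
    ``protein_mean[g]`` inside each glomerulus. Degradation order: PSF blur,
    then Poisson resampling (if enabled), then additive Gaussian noise
    (clipped at zero).
    """
    total_m = sum(truth.mistarget_fraction.values())
    if total_m > 1.0:
        raise ValueError(f"sum of mistarget fractions {total_m} exceeds 1")
    atlas = build_atlas(spec)
    rng = np.random.default_rng(truth.seed)

    label = np.zeros(spec.stack_shape, dtype=np.float64)
    ref_mask = atlas.mask(truth.reference)
    label[ref_mask] = truth.label_intensity
    planted_volumes = {truth.reference: int(ref_mask.sum())}
    for name, m in truth.mistarget_fraction.items():
        region = atlas.mask(name)
        n_sub = max(1, round(m * int(region.sum()))) if m > 0 else 0
        if n_sub > 0:
            sub = _contiguous_subregion(region, n_sub, rng)
            label[sub] = truth.label_intensity
        planted_volumes[name] = n_sub

    protein = np.zeros(spec.stack_shape, dtype=np.float64)
    for name, mean in truth.protein_mean.items():
        protein[atlas.mask(name)] = mean

    neuropil = np.full(spec.stack_shape, NEUROPIL_BACKGROUND, dtype=np.float64)
    neuropil[atlas.labels > 0] = NEUROPIL_INTENSITY

    channels: Dict[str, VoxelStack] = {}
    for key, img in (("neuropil", neuropil), ("label", label), ("protein", protein)):
        if truth.psf_sigma > 0:
            from scipy import ndimage

            img = ndimage.gaussian_filter(img, sigma=truth.psf_sigma, mode="reflect")
        if truth.poisson:
            img = rng.poisson(img).astype(np.float64)
        if truth.gaussian_sd > 0:
            img = img + rng.normal(0.0, truth.gaussian_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
        channels[key] = VoxelStack(img)

    ref_vol = planted_volumes[truth.reference]
    manifest = SampleManifest(
        seed=truth.seed,
        reference=truth.reference,
        mistarget_fraction=dict(truth.mistarget_fraction),
        planted_volumes=planted_volumes,
        planted_proportions={
            g: v / ref_vol for g, v in planted_volumes.items() if g != truth.reference
        },
        label_intensity=truth.label_intensity,
        protein_mean=dict(truth.protein_mean),
        noise={
            "gaussian_sd": truth.gaussian_sd,
            "poisson": truth.poisson,
            "psf_sigma": truth.psf_sigma,
        },
        positive=any(m > 0 for m in truth.mistarget_fraction.values()),
    )
    return channels, atlas, manifest


def simulate_cohort(
    spec: AtlasSpec,
    truth: SimTruth,
    n_samples: int,
    seed: int,
    render: bool = True,
) -> Tuple[List[Tuple[Dict[str, VoxelStack], GlomerulusAtlas, SampleManifest]], List[dict]]:
    """Draw ``n_samples`` independent samples.

    Each sample is mistargeting-positive (the template's fractions planted)
    with probability ``truth.phenotype_prob``, otherwise all fractions are
    zeroed. Sample i uses seed ``seed + i``. With ``render=False`` the
    channels/atlas are omitted (``None``) — useful for fast cohort-level
    statistics on the manifest alone.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    samples = []
    manifest: List[dict] = []
    for i in range(n_samples):
        positive = bool(np.random.default_rng([seed, i]).random() < truth.phenotype_prob)
        fractions = dict(truth.mistarget_fraction) if positive else {
            k: 0.0 for k in truth.mistarget_fraction
        }
        sample_truth = replace(truth, seed=seed + i, mistarget_fraction=fractions)
        if render:
            channels, atlas, sm = simulate_sample(spec, sample_truth)
            samples.append((channels, atlas, sm))
        else:
            sm = SampleManifest(
                seed=seed + i,
                reference=truth.reference,
                mistarget_fraction=fractions,
                planted_volumes={},
                planted_proportions={},
                label_intensity=truth.label_intensity,
                protein_mean=dict(truth.protein_mean),
                noise={
                    "gaussian_sd": truth.gaussian_sd,
                    "poisson": truth.poisson,
                    "psf_sigma": truth.psf_sigma,
                },
                positive=positive,
            )
            samples.append((None, None, sm))
        manifest.append(sm.to_dict())
    return samples, manifest


def default_atlas_spec(
    stack_shape: Tuple[int, int, int] = (32, 128, 128)
) -> AtlasSpec:
    """A five-glomerulus atlas with equal-sized reference and main off-target."""
    z, y, x = stack_shape
    r = (z * 0.22, y * 0.11, x * 0.11)
    return AtlasSpec(
        stack_shape=stack_shape,
        glomeruli=(
            EllipsoidSpec("VA1d", (z * 0.5, y * 0.30, x * 0.35), r),
            EllipsoidSpec("VA1v", (z * 0.5, y * 0.62, x * 0.35), r),
            EllipsoidSpec("DA1", (z * 0.5, y * 0.30, x * 0.70), r),
            EllipsoidSpec("DA4l", (z * 0.5, y * 0.62, x * 0.70), r),
        ),
    )


# ---------------------------------------------------------------------------
# expression tables


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    cls: str  # "ORN" or "PN"
    glomerulus: str

    def __post_init__(self) -> None:
        if self.cls not in ("ORN", "PN"):
            raise ValueError(f"class must be ORN or PN, got {self.cls!r}")


@dataclass(frozen=True)
class PlantedPair:
    """An inverse ligand-receptor pair to plant in the simulated table."""

    ligand: str
    receptor: str
    sender_hi: str
    sender_lo: str
    receiver_hi: str
    receiver_lo: str
    log2_effect: float

    def __post_init__(self) -> None:
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be >= 0")


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_genes: int
    cell_types: Tuple[CellTypeSpec, ...]
    planted_pairs: Tuple[PlantedPair, ...] = ()
    nb_dispersion: float = 2.0  # NB size parameter; larger -> closer to Poisson
    library_size: int = 1_000_000
    cells_per_type: int = 30

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "planted_pairs", tuple(self.planted_pairs))
        by_name = {t.name: t for t in self.cell_types}
        gene_names = set(self._gene_names())
        for p in self.planted_pairs:
            for g in (p.ligand, p.receptor):
                if g not in gene_names:
                    raise ValueError(f"planted gene {g!r} outside gene universe")
            for t in (p.sender_hi, p.sender_lo, p.receiver_hi, p.receiver_lo):
                if t not in by_name:
                    raise ValueError(f"planted cell type {t!r} does not exist")
            if by_name[p.sender_hi].cls != by_name[p.sender_lo].cls:
                raise ValueError("sender pair must share a class")
            if by_name[p.receiver_hi].cls != by_name[p.receiver_lo].cls:
                raise ValueError("receiver pair must share a class")
            if by_name[p.sender_hi].cls == by_name[p.receiver_hi].cls:
                raise ValueError("sender and receiver pairs must have opposite classes")

    def _gene_names(self) -> List[str]:
        planted = []
        for p in self.planted_pairs:
            for g in (p.ligand, p.receptor):
                if g not in planted:
                    planted.append(g)
        decoys = [f"gene{i:04d}" for i in range(self.n_genes)]
        return planted + decoys


def simulate_expression(spec: ExpressionSimSpec, seed: int):
    """Negative-binomial genes x cell-types counts with planted inverse pairs.

    Per-type counts are the sum of ``cells_per_type`` i.i.d. per-cell NB
    draws (drawn in closed form as a single NB with scaled size), each cell
    sequenced to ~``library_size`` reads. Planted effects multiply the
    ligand's mean in ``sender_hi`` and the receptor's mean in
    ``receiver_hi`` by ``2**log2_effect``.

    Returns an :class:`~glomquant.screen.ExpressionTable` of raw counts and
    a truth dict listing the planted pairs.
    """
    from .screen import ExpressionTable

    rng = np.random.default_rng(seed)
    genes = spec._gene_names()
    types = [t.name for t in spec.cell_types]
    n_g, n_t = len(genes), len(types)

    base = rng.lognormal(mean=2.0, sigma=1.2, size=n_g)
    mu = np.tile(base[:, None], (1, n_t))
    gidx = {g: i for i, g in enumerate(genes)}
    tidx = {t: i for i, t in enumerate(types)}
    for p in spec.planted_pairs:
        mu[gidx[p.ligand], tidx[p.sender_hi]] *= 2.0 ** p.log2_effect
        mu[gidx[p.receptor], tidx[p.receiver_hi]] *= 2.0 ** p.log2_effect

    # per-cell means scaled to the library size, then summed over cells
    mu_cell = mu / mu.sum(axis=0, keepdims=True) * spec.library_size
    r_type = spec.nb_dispersion * spec.cells_per_type
    mean_type = mu_cell * spec.cells_per_type
    p_nb = r_type / (r_type + mean_type)
    counts = rng.negative_binomial(r_type, p_nb)

    values = pd.DataFrame(counts, index=genes, columns=types)
    meta = pd.DataFrame(
        {
            "cell_type": types,
            "class": [t.cls for t in spec.cell_types],
            "glomerulus": [t.glomerulus for t in spec.cell_types],
        }
    ).set_index("cell_type")
    table = ExpressionTable(values=values, meta=meta, is_cpm=False)
    truth = {
        "seed": seed,
        "planted_pairs": [asdict(p) for p in spec.planted_pairs],
    }
    return table, truth
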