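"""Property-based benchmark computations for the acceptance suite.

Each function recomputes one calibration/recovery quantity from scratch by
running the package on freshly generated synthetic data. All randomness is
driven by an explicit seed.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path
from typing import Dict, Sequence

import numpy as np

from .quant import QuantConfig, otsu_threshold, quantify_sample
from .screen import cpm_normalize, rank_candidates
from .stats import penetrance
from .synthetic import (
    AtlasSpec,
    CellTypeSpec,
    EllipsoidSpec,
    ExpressionSimSpec,
    PlantedPair,
    SimTruth,
    default_atlas_spec,
    simulate_expression,
    simulate_sample,
)
from .types import VoxelStack


def _brute_force_otsu(data: np.ndarray, nbins: int = 256) -> float:
    """Independent exhaustive between-class-variance scan (reporting oracle)."""
    lo, hi = float(data.min()), float(data.max())
    counts, edges = np.histogram(data.ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = counts.sum()
    best_t, best_var = None, -1.0
    for t in range(nbins):
        w0 = counts[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(centers[best_t])


def otsu_agreement(n_stacks: int = 50, seed: int = 0) -> Dict[str, float]:
    """Fraction of random 8-bit stacks where the fast implementation equals
    the exhaustive scan."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_stacks):
        data = rng.integers(0, 256, size=(4, 24, 24)).astype(np.float64)
        if data.min() == data.max():
            continue
        total += 1
        fast = otsu_threshold(VoxelStack(data))
        agree += np.isclose(fast, _brute_force_otsu(data))
    return {"agreement": agree / total, "n": total}


def _small_spec() -> AtlasSpec:
    return AtlasSpec(
        stack_shape=(16, 48, 48),
        glomeruli=(
            EllipsoidSpec("VA1d", (8, 14, 24), (4, 7, 7)),
            EllipsoidSpec("VA1v", (8, 32, 24), (4, 7, 7)),
        ),
    )


def pi_recovery(
    ratios: Sequence[float] = (1.0, 2.0, 3.0), n_seeds: int = 20, seed: int = 0
) -> Dict[float, float]:
    """Max |estimated PI - (r-1)/(r+1)| per planted ratio, at <= 10% noise."""
    spec = default_atlas_spec((24, 72, 72))
    errors: Dict[float, float] = {}
    for r in ratios:
        target = (r - 1) / (r + 1)
        worst = 0.0
        for i in range(n_seeds):
            truth = SimTruth(
                seed=seed + i,
                mistarget_fraction={"VA1v": 0.1},
                protein_mean={"VA1d": 50.0 * r, "VA1v": 50.0},
                gaussian_sd=5.0,  # 10% of the lower planted mean
                psf_sigma=0.5,
            )
            channels, atlas, _ = simulate_sample(spec, truth)
            rec = quantify_sample(channels, atlas, QuantConfig(), f"pi_{r}_{i}")
            worst = max(worst, abs(rec.preference_index - target))
        errors[r] = worst
    return errors


def mistarget_recovery(
    fractions: Sequence[float] = (0.05, 0.1, 0.2), n_seeds: int = 20, seed: int = 0
) -> Dict[float, float]:
    """Max relative error of the recovered mistargeting ratio per planted m."""
    spec = default_atlas_spec()  # full size: boundary bias well below 15%
    errors: Dict[float, float] = {}
    for m in fractions:
        worst = 0.0
        for i in range(n_seeds):
            truth = SimTruth(
                seed=seed + i,
                mistarget_fraction={"VA1v": m},
                protein_mean={"VA1d": 100.0, "VA1v": 100.0},
                gaussian_sd=10.0,
                psf_sigma=0.5,
            )
            channels, atlas, manifest = simulate_sample(spec, truth)
            rec = quantify_sample(channels, atlas, QuantConfig(), f"m_{m}_{i}")
            planted = manifest.planted_proportions["VA1v"]
            worst = max(worst, abs(rec.mistarget.ratios["VA1v"] / planted - 1.0))
        errors[m] = worst
    return errors


def phenotype_calibration(
    n_samples: int = 100, m_positive: float = 0.1, seed: int = 0
) -> Dict[str, float]:
    """False-positive rate on m=0 noisy samples and true-positive rate at
    the given planted fraction, under the default phenotype rule."""
    spec = _small_spec()
    config = QuantConfig()
    fp = tp = 0
    for i in range(n_samples):
        base = dict(
            protein_mean={"VA1d": 100.0, "VA1v": 100.0},
            gaussian_sd=20.0,  # 10% of label_intensity
            poisson=True,
            psf_sigma=0.5,
        )
        truth_neg = SimTruth(seed=seed + i, mistarget_fraction={"VA1v": 0.0}, **base)
        channels, atlas, _ = simulate_sample(spec, truth_neg)
        fp += quantify_sample(channels, atlas, config, f"neg{i}").phenotype.positive

        truth_pos = SimTruth(
            seed=seed + n_samples + i, mistarget_fraction={"VA1v": m_positive}, **base
        )
        channels, atlas, _ = simulate_sample(spec, truth_pos)
        tp += quantify_sample(channels, atlas, config, f"pos{i}").phenotype.positive
    return {
        "false_positive_rate": fp / n_samples,
        "true_positive_rate": tp / n_samples,
        "n": n_samples,
    }


def clopper_pearson_coverage(
    n_sim: int = 2000, n: int = 12, probs: Sequence[float] = (0.1, 0.3, 0.5),
    seed: int = 0,
) -> Dict[float, float]:
    """Empirical CI coverage of the exact binomial interval per true p."""
    rng = np.random.default_rng(seed)
    coverage: Dict[float, float] = {}
    for p in probs:
        ks = rng.binomial(n, p, size=n_sim)
        covered = 0
        for k in np.bincount(ks, minlength=n + 1).nonzero()[0]:
            res = penetrance(int(k), n)
            if res.ci_low <= 100 * p <= res.ci_high:
                covered += int((ks == k).sum())
        coverage[p] = covered / n_sim
    return coverage


def type_i_error(n_rep: int = 2000, seed: int = 0) -> Dict[str, float]:
    """Null rejection rates at alpha=0.05 for the t and Kruskal-Wallis tests."""
    from .stats import kruskal_wallis, one_sample_t

    rng = np.random.default_rng(seed)
    t_rej = 0
    for row in rng.normal(0, 1, size=(n_rep, 10)):
        _, _, p = one_sample_t(row)
        t_rej += p < 0.05
    kw_rej = 0
    for _ in range(n_rep):
        groups = [rng.normal(0, 1, 15) for _ in range(3)]
        _, _, p = kruskal_wallis(groups)
        kw_rej += p < 0.05
    return {"t_test": t_rej / n_rep, "kruskal_wallis": kw_rej / n_rep, "n": n_rep}


def _screen_spec(n_decoys: int = 200, effect: float = 3.0) -> ExpressionSimSpec:
    types = (
        CellTypeSpec("VA1d-ORN", "ORN", "VA1d"),
        CellTypeSpec("VA1v-ORN", "ORN", "VA1v"),
        CellTypeSpec("VA1d-PN", "PN", "VA1d"),
        CellTypeSpec("VA1v-PN", "PN", "VA1v"),
    )
    # alternating orientations keep cross combinations of planted genes from
    # flooding the top ranks
    orientations = [
        ("VA1v-ORN", "VA1d-ORN", "VA1d-PN", "VA1v-PN"),
        ("VA1d-ORN", "VA1v-ORN", "VA1v-PN", "VA1d-PN"),
        ("VA1v-ORN", "VA1d-ORN", "VA1d-PN", "VA1v-PN"),
    ]
    pairs = tuple(
        PlantedPair(f"lig{i}", f"rec{i}", s_hi, s_lo, r_hi, r_lo, effect)
        for i, (s_hi, s_lo, r_hi, r_lo) in enumerate(orientations)
    )
    # type-level profiles average enough cells that chance decoy asymmetry
    # stays below the planted effect
    return ExpressionSimSpec(
        n_genes=n_decoys,
        cell_types=types,
        planted_pairs=pairs,
        nb_dispersion=0.5,
        cells_per_type=60,
    )


def screen_recovery(n_seeds: int = 100, seed: int = 0) -> Dict[str, float]:
    """Planted-pair recovery: top-5 rate under default filters and mean
    AUROC (planted pairs vs decoy-decoy pairs, unfiltered scores)."""
    spec = _screen_spec()
    planted = {("lig0", "rec0"), ("lig1", "rec1"), ("lig2", "rec2")}
    ligands = ["lig0", "lig1", "lig2"] + [f"gene{i:04d}" for i in range(100)]
    receptors = ["rec0", "rec1", "rec2"] + [f"gene{i:04d}" for i in range(100, 200)]
    sender = ("VA1v-ORN", "VA1d-ORN")
    receiver = ("VA1v-PN", "VA1d-PN")

    top5_hits = 0
    aurocs = []
    for i in range(n_seeds):
        table, _ = simulate_expression(spec, seed=seed + i)
        cpm = cpm_normalize(table)
        ranked = rank_candidates(cpm, ligands, receptors, sender, receiver)
        top5 = {(c.ligand, c.receptor) for c in ranked[:5]}
        top5_hits += planted <= top5

        full = rank_candidates(
            cpm, ligands, receptors, sender, receiver, min_cpm=0.0, min_abs_pi=0.0
        )
        pos, neg = [], []
        for c in full:
            if (c.ligand, c.receptor) in planted:
                pos.append(c.score)
            elif c.ligand.startswith("gene") and c.receptor.startswith("gene"):
                neg.append(c.score)
        pos_arr, neg_arr = np.asarray(pos), np.asarray(neg)
        wins = (pos_arr[:, None] > neg_arr[None, :]).sum()
        ties = (pos_arr[:, None] == neg_arr[None, :]).sum()
        aurocs.append((wins + 0.5 * ties) / (len(pos) * len(neg)))
    return {
        "top5_rate": top5_hits / n_seeds,
        "auroc": float(np.mean(aurocs)),
        "n": n_seeds,
    }


def determinism_check(seed: int = 0) -> bool:
    """Two pipeline runs with identical (config, seed) produce byte-identical
    artifacts."""
    from .pipeline import run_pipeline

    config = {
        "simulate": {
            "stack_shape": [16, 48, 48],
            "mistarget_fraction": {"VA1v": 0.2},
            "protein_mean": {"VA1d": 150, "VA1v": 50},
            "gaussian_sd": 10.0,
            "poisson": True,
            "glomeruli": [
                {"name": "VA1d", "center": [8, 14, 24], "radii": [4, 7, 7]},
                {"name": "VA1v", "center": [8, 32, 24], "radii": [4, 7, 7]},
            ],
        }
    }
    with tempfile.TemporaryDirectory() as tmp:
        a, b = Path(tmp) / "a", Path(tmp) / "b"
        run_pipeline(config, a, seed, n_samples=4)
        run_pipeline(config, b, seed, n_samples=4)
        names = ["results.jsonl", "summary.json", "penetrance.tsv", "manifest.json"]
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        return len(match) == len(names) and not mismatch and not errors
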