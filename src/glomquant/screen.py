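"""Transcriptome screening: CPM normalization, expression preference
indices, inverse-expression candidate scoring, and cue-coverage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError

DEFAULT_MIN_CPM = 10.0
DEFAULT_MIN_ABS_PI = 0.2
DEFAULT_COVERAGE_TAU = 2.0  # on log2(CPM+1) values


@dataclass(frozen=True)
class ExpressionTable:
    """Genes x cell-types expression matrix with cell-type metadata.

    ``values``: DataFrame indexed by gene, columns are cell-type names.
    ``meta``: DataFrame indexed by cell type with columns ``class``
    (ORN or PN) and ``glomerulus``. ``is_cpm`` flags whether values are
    CPM-normalized (False means raw counts).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    is_cpm: bool = True

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and cell-type names must be unique")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"cell types without metadata: {sorted(missing)}")
        bad = set(self.meta["class"]) - {"ORN", "PN"}
        if bad:
            raise ValueError(f"unknown cell-type classes: {sorted(bad)}")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self.values.columns)

    def class_of(self, cell_type: str) -> str:
        return str(self.meta.loc[cell_type, "class"])

    def value(self, gene: str, cell_type: str) -> float:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in table")
        if cell_type not in self.values.columns:
            raise KeyError(f"cell type {cell_type!r} not in table")
        return float(self.values.loc[gene, cell_type])


@dataclass(frozen=True)
class CandidatePairScore:
    ligand: str
    receptor: str
    sender_class: str
    pi_ligand: float
    pi_receptor: float
    score: float
    inverse: bool

    def to_dict(self) -> dict:
        return {
            "ligand": self.ligand,
            "receptor": self.receptor,
            "sender_class": self.sender_class,
            "pi_ligand": self.pi_ligand,
            "pi_receptor": self.pi_receptor,
            "score": self.score,
            "inverse": self.inverse,
        }


@dataclass
class CoverageSummary:
    cue_counts: Dict[str, int]  # PN type -> number of cues above tau (0..3)
    tau: float
    fraction_at_least_one: float
    fraction_all_three: float

    def to_dict(self) -> dict:
        return {
            "cue_counts": {k: int(v) for k, v in self.cue_counts.items()},
            "tau": float(self.tau),
            "fraction_at_least_one": float(self.fraction_at_least_one),
            "fraction_all_three": float(self.fraction_all_three),
        }


def cpm_normalize(table: ExpressionTable) -> ExpressionTable:
    """Counts-per-million: each column scaled so it sums to 10^6."""
    totals = table.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"cell type(s) with zero total counts: {list(zero.index)}"
        )
    cpm = table.values / totals * 1e6
    return ExpressionTable(values=cpm, meta=table.meta, is_cpm=True)


def log_transform(table: ExpressionTable) -> ExpressionTable:
    """Elementwise log2(value + 1); monotone and zero-preserving."""
    return ExpressionTable(
        values=np.log2(table.values + 1.0), meta=table.meta, is_cpm=table.is_cpm
    )


def expression_preference_index(
    table: ExpressionTable, gene: str, type_a: str, type_b: str
) -> float:
    """(v_a - v_b) / (v_a + v_b) for one gene between two cell types."""
    v_a = table.value(gene, type_a)
    v_b = table.value(gene, type_b)
    if v_a + v_b == 0:
        raise UndefinedIndexError(
            f"gene {gene!r} has zero expression in both {type_a!r} and {type_b!r}"
        )
    return (v_a - v_b) / (v_a + v_b)


def _check_pair_classes(
    table: ExpressionTable,
    sender_pair: Sequence[str],
    receiver_pair: Sequence[str],
) -> Tuple[str, str]:
    s_cls = {table.class_of(t) for t in sender_pair}
    r_cls = {table.class_of(t) for t in receiver_pair}
    if len(s_cls) != 1 or len(r_cls) != 1:
        raise ValueError("each pair must contain cell types of a single class")
    (s,) = s_cls
    (r,) = r_cls
    if s == r:
        raise ValueError(
            f"sender and receiver pairs must come from opposite classes (both {s})"
        )
    return s, r


def inverse_pair_score(
    table: ExpressionTable,
    ligand: str,
    receptor: str,
    sender_pair: Sequence[str],
    receiver_pair: Sequence[str],
) -> CandidatePairScore:
    """Score = -PI_ligand * PI_receptor with both pairs oriented alike.

    Positive score means the ligand and receptor are preferentially
    expressed on opposite sides (inverse expression); the magnitude rewards
    strong two-sided asymmetry.
    """
    sender_class, _ = _check_pair_classes(table, sender_pair, receiver_pair)
    pi_l = expression_preference_index(table, ligand, sender_pair[0], sender_pair[1])
    pi_r = expression_preference_index(table, receptor, receiver_pair[0], receiver_pair[1])
    score = -pi_l * pi_r
    return CandidatePairScore(
        ligand=ligand,
        receptor=receptor,
        sender_class=sender_class,
        pi_ligand=pi_l,
        pi_receptor=pi_r,
        score=score,
        inverse=score > 0,
    )


def rank_candidates(
    table: ExpressionTable,
    ligand_genes: Sequence[str],
    receptor_genes: Sequence[str],
    sender_pair: Sequence[str],
    receiver_pair: Sequence[str],
    min_cpm: float = DEFAULT_MIN_CPM,
    min_abs_pi: float = DEFAULT_MIN_ABS_PI,
) -> List[CandidatePairScore]:
    """Score all ligand x receptor combinations and rank by inverse score.

    A pair is kept only if, on each side, the higher-expressing type of the
    pair reaches ``min_cpm`` and |PI| >= ``min_abs_pi``. Sorted by
    descending score, ties broken lexicographically by (ligand, receptor).
    """
    if not ligand_genes or not receptor_genes:
        raise ValueError("gene sets must be non-empty")
    sender_class, _ = _check_pair_classes(table, sender_pair, receiver_pair)

    def _side(genes: Sequence[str], pair: Sequence[str]):
        sub = table.values.loc[list(genes), list(pair)].to_numpy(dtype=np.float64)
        v_a, v_b = sub[:, 0], sub[:, 1]
        total = v_a + v_b
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(total > 0, (v_a - v_b) / np.where(total > 0, total, 1), np.nan)
        keep = (np.maximum(v_a, v_b) >= min_cpm) & (np.abs(pi) >= min_abs_pi)
        keep &= ~np.isnan(pi)
        return pi, keep

    pi_l, keep_l = _side(ligand_genes, sender_pair)
    pi_r, keep_r = _side(receptor_genes, receiver_pair)

    results: List[CandidatePairScore] = []
    for i, lig in enumerate(ligand_genes):
        if not keep_l[i]:
            continue
        for j, rec in enumerate(receptor_genes):
            if not keep_r[j]:
                continue
            score = float(-pi_l[i] * pi_r[j])
            results.append(
                CandidatePairScore(
                    ligand=lig,
                    receptor=rec,
                    sender_class=sender_class,
                    pi_ligand=float(pi_l[i]),
                    pi_receptor=float(pi_r[j]),
                    score=score,
                    inverse=score > 0,
                )
            )
    results.sort(key=lambda c: (-c.score, c.ligand, c.receptor))
    return results


def cue_coverage(
    table: ExpressionTable,
    cue_spec: Mapping[str, Union[str, Tuple[str, str]]],
    pn_types: Sequence[str],
    tau: float = DEFAULT_COVERAGE_TAU,
) -> CoverageSummary:
    """Count, per PN type, how many of three cues exceed ``tau``.

    ``cue_spec`` maps each cue name to either a single gene or a pair of
    genes combined by elementwise maximum. Exactly three cues are expected.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if len(cue_spec) != 3:
        raise ValueError(f"expected exactly 3 cues, got {len(cue_spec)}")
    cue_values: Dict[str, np.ndarray] = {}
    for cue, genes in cue_spec.items():
        if isinstance(genes, str):
            genes = (genes,)
        rows = []
        for g in genes:
            if g not in table.values.index:
                raise KeyError(f"cue gene {g!r} not in table")
            rows.append(table.values.loc[g, list(pn_types)].to_numpy(dtype=np.float64))
        cue_values[cue] = np.max(np.vstack(rows), axis=0)

    stacked = np.vstack([cue_values[c] for c in cue_spec])  # 3 x n_types
    counts = (stacked > tau).sum(axis=0)
    cue_counts = {t: int(c) for t, c in zip(pn_types, counts)}
    n = len(pn_types)
    return CoverageSummary(
        cue_counts=cue_counts,
        tau=tau,
        fraction_at_least_one=float((counts >= 1).sum() / n) if n else 0.0,
        fraction_all_three=float((counts == 3).sum() / n) if n else 0.0,
    )
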