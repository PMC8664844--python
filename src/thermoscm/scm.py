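"""Scoring card construction and use.

A scoring card assigns each of the 400 g-gap dipeptides a propensity score in
[0, 1000] expressing how strongly the dipeptide is associated with the
thermophilic (positive) class.  A protein is scored by the weighted sum
``S(P) = sum_d w_d * PS_d`` with weights given by its dipeptide composition,
and classified as positive when the score reaches the card's threshold.

Initial scores are estimated statistically: the per-class mean composition
difference of each dipeptide, min-max rescaled onto [0, 1000].  A genetic
algorithm (see :mod:`thermoscm.ga`) then refines the card.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DIPEPTIDES, N_DIPEPTIDES, gdc_compose, gdc_matrix
from .io import POSITIVE, NEGATIVE, STANDARD_AA, LabeledDataset

SCORE_MIN = 0.0
SCORE_MAX = 1000.0

INITIAL = "initial"
OPTIMIZED = "optimized"


class ThresholdUnsetError(RuntimeError):
    """Classification attempted before a decision threshold was chosen."""


class EmptyClassError(ValueError):
    """An operation that needs both classes received an empty one."""


@dataclass
class PropensityTable:
    """400 dipeptide propensity scores plus gap size and decision threshold.

    ``values`` is ordered as :data:`thermoscm.features.DIPEPTIDES`; the
    mapping view :attr:`scores` keys by two-letter dipeptide so the internal
    ordering is never observable externally.
    """

    g: int
    values: np.ndarray  # (400,) floats in [0, 1000]
    threshold: float | None = None
    provenance: str = INITIAL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DIPEPTIDES,):
            raise ValueError(f"expected 400 scores, got shape {self.values.shape}")
        if self.values.min() < SCORE_MIN - 1e-9 or self.values.max() > SCORE_MAX + 1e-9:
            raise ValueError("propensity scores must lie within [0, 1000]")
        if self.threshold is not None and not (
            self.values.min() <= self.threshold <= self.values.max()
        ):
            raise ValueError("threshold must lie within [min(scores), max(scores)]")

    @property
    def scores(self) -> dict[str, float]:
        return dict(zip(DIPEPTIDES, self.values.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dipeptide": DIPEPTIDES, "score": self.values})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "g": self.g,
            "threshold": self.threshold,
            "provenance": self.provenance,
            "metadata": self.metadata,
            "scores": self.scores,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PropensityTable":
        payload = json.loads(Path(path).read_text())
        values = np.array([payload["scores"][d] for d in DIPEPTIDES])
        return cls(
            g=payload["g"],
            values=values,
            threshold=payload["threshold"],
            provenance=payload.get("provenance", OPTIMIZED),
            metadata=payload.get("metadata", {}),
        )


@dataclass(frozen=True)
class AminoAcidPropensity:
    """Per-residue propensity derived by averaging a dipeptide scoring card."""

    scores: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[a] for a in STANDARD_AA])


def rescale_minmax(diffs: np.ndarray) -> np.ndarray:
    """Min-max rescale onto [0, 1000]; an all-equal input maps to 500."""
    lo, hi = diffs.min(), diffs.max()
    if hi == lo:
        return np.full_like(diffs, 500.0)
    return (diffs - lo) / (hi - lo) * SCORE_MAX


def class_mean_composition(dataset: LabeledDataset, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-sequence GDC fractions for (positives, negatives)."""
    if not dataset.positives or not dataset.negatives:
        raise EmptyClassError("both classes must be non-empty")
    pos = gdc_matrix([r.sequence for r in dataset.positives], g).mean(axis=0)
    neg = gdc_matrix([r.sequence for r in dataset.negatives], g).mean(axis=0)
    return pos, neg


def estimate_initial(train: LabeledDataset, g: int) -> PropensityTable:
    """Statistical (pre-optimization) scoring card at gap *g*.

    Each dipeptide's raw propensity is the difference of its class-mean
    compositions (positives minus negatives, sequences weighted equally);
    the 400 differences are min-max rescaled onto [0, 1000], so the most
    positive-class-biased dipeptide scores 1000 and the most
    negative-class-biased scores 0.  The decision threshold is left unset.
    """
    pos, neg = class_mean_composition(train, g)
    return PropensityTable(g=g, values=rescale_minmax(pos - neg), provenance=INITIAL)


def score_protein(seq: str, table: PropensityTable, mode: str = "fraction") -> float:
    """Weighted-sum score of one protein under a scoring card.

    With ``mode="fraction"`` (default) the weights are the normalized g-gap
    composition, so the score is a convex combination of the 400 propensity
    scores and is independent of sequence length.  ``mode="count"`` uses raw
    dipeptide counts instead, making the score scale with length.
    """
    vec = gdc_compose(seq, table.g)
    if mode == "fraction":
        weights = vec.values
    elif mode == "count":
        weights = vec.values * (len(seq) - table.g - 1)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return float(weights @ table.values)


def score_dataset(
    sequences: Sequence[str], table: PropensityTable, mode: str = "fraction"
) -> np.ndarray:
    """Vectorized :func:`score_protein` over several sequences."""
    mat = gdc_matrix(sequences, table.g)
    if mode == "count":
        lengths = np.array([len(s) - table.g - 1 for s in sequences])
        mat = mat * lengths[:, None]
    return mat @ table.values


def classify(score: float, threshold: float | None) -> str:
    """Positive iff score >= threshold (ties classify as positive)."""
    if threshold is None:
        raise ThresholdUnsetError("no decision threshold has been set on this table")
    return POSITIVE if score >= threshold else NEGATIVE


def aa_propensity(table: PropensityTable) -> AminoAcidPropensity:
    """Per-residue propensity: mean score of the 40 dipeptides containing it.

    For residue ``a`` this averages the 20 scores with ``a`` first and the 20
    with ``a`` second, so the homodipeptide ``aa`` contributes twice.
    """
    grid = table.values.reshape(20, 20)
    per_aa = (grid.sum(axis=1) + grid.sum(axis=0)) / 40.0
    return AminoAcidPropensity(scores=dict(zip(STANDARD_AA, per_aa.tolist())))


def rank_proteins(
    dataset: LabeledDataset, table: PropensityTable, k: int
) -> list[tuple[str, float]]:
    """Top-k (id, score) pairs, highest score first; ties break by id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [
        (rec.id, score_protein(rec.sequence, table)) for rec in dataset.records
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return scored[:k]
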