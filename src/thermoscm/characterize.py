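"""Interpretation of a trained scoring card.

The per-residue propensities derived from a card can be correlated against
per-residue physicochemical scales from the AAindex database to identify
which properties (surface composition, hydrophobicity, charge, ...) the
card has implicitly learned to track; the card itself ranks dipeptides by
their association with the thermophilic class, and score histograms show
how well the two classes separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .features import DIPEPTIDES
from .io import STANDARD_AA, LabeledDataset
from .scm import AminoAcidPropensity, PropensityTable, score_dataset

#: Residue order of the two value rows of an AAindex1 'I' block.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWVY"


class AAindexParseError(ValueError):
    """Malformed AAindex1 record (names the offending accession if known)."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or too few residues)."""


@dataclass
class AAindexProperty:
    """One physicochemical property: accession, title, per-residue values.

    ``values`` may omit residues recorded as NA in the database.
    """

    accession: str
    title: str = ""
    values: dict[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        self.values = dict(self.values or {})
        unknown = set(self.values) - set(STANDARD_AA)
        if unknown:
            raise ValueError(f"unknown residues in property values: {sorted(unknown)}")


def parse_aaindex1(path: str | Path) -> list[AAindexProperty]:
    """Parse an AAindex1 flat file (records start 'H ', values under 'I ').

    The value block is the canonical two-row, ten-column layout; 'NA'
    entries are recorded as missing.  Raises :class:`AAindexParseError` on a
    malformed record, naming its accession.
    """
    properties: list[AAindexProperty] = []
    accession: str | None = None
    title_parts: list[str] = []
    value_tokens: list[str] = []
    in_values = False

    def flush() -> None:
        nonlocal accession, title_parts, value_tokens, in_values
        if accession is None:
            return
        if len(value_tokens) != 20:
            raise AAindexParseError(
                f"record {accession}: expected 20 value entries, got {len(value_tokens)}"
            )
        values: dict[str, float] = {}
        for aa, token in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, value_tokens):
            if token.upper() == "NA":
                continue
            try:
                values[aa] = float(token)
            except ValueError:
                raise AAindexParseError(
                    f"record {accession}: bad value {token!r} for residue {aa}"
                ) from None
        properties.append(
            AAindexProperty(accession=accession, title=" ".join(title_parts), values=values)
        )
        accession, title_parts, value_tokens, in_values = None, [], [], False

    for line in Path(path).read_text().splitlines():
        if line.startswith("H "):
            if accession is not None:
                raise AAindexParseError(
                    f"record {accession}: new header before terminating '//'"
                )
            accession = line[2:].strip()
        elif line.startswith("D ") and accession is not None:
            title_parts.append(line[2:].strip())
        elif line.startswith("I ") and accession is not None:
            in_values = True
        elif line.startswith("//"):
            flush()
        elif in_values and line[:1].isspace():
            value_tokens.extend(line.split())
        elif line[:1].isalpha():
            in_values = False
    if accession is not None:
        raise AAindexParseError(f"record {accession}: missing terminating '//'")
    return properties


def correlate_property(aa: AminoAcidPropensity, prop: AAindexProperty) -> float:
    """Pearson R between per-residue propensities and one property scale.

    Computed over the residues present in both inputs (pairwise deletion of
    NA entries); raises :class:`UndefinedCorrelationError` below 3 shared
    residues or on zero variance.
    """
    shared = [a for a in STANDARD_AA if a in prop.values and a in aa.scores]
    if len(shared) < 3:
        raise UndefinedCorrelationError(
            f"{prop.accession}: only {len(shared)} residues shared"
        )
    x = np.array([aa.scores[a] for a in shared])
    y = np.array([prop.values[a] for a in shared])
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(f"{prop.accession}: zero variance")
    return float(pearsonr(x, y)[0])


def rank_properties(
    aa: AminoAcidPropensity, props: Sequence[AAindexProperty], k: int
) -> tuple[list[tuple[AAindexProperty, float]], list[tuple[AAindexProperty, float]], list[str]]:
    """Most and least propensity-correlated properties.

    Returns ``(top, bottom, excluded)``: the k properties with the highest
    signed R, the k with the lowest, and the accessions of properties whose
    correlation is undefined.
    """
    if not props:
        raise ValueError("props must be non-empty")
    scored: list[tuple[AAindexProperty, float]] = []
    excluded: list[str] = []
    for prop in props:
        try:
            scored.append((prop, correlate_property(aa, prop)))
        except UndefinedCorrelationError:
            excluded.append(prop.accession)
    scored.sort(key=lambda item: (-item[1], item[0].accession))
    return scored[:k], scored[::-1][:k], excluded


def top_dipeptides(
    table: PropensityTable, k: int
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """(highest, lowest) k dipeptides by propensity score; ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = sorted(zip(DIPEPTIDES, table.values.tolist()))
    by_desc = sorted(pairs, key=lambda it: (-it[1], it[0]))
    by_asc = sorted(pairs, key=lambda it: (it[1], it[0]))
    return by_desc[:k], by_asc[:k]


@dataclass(frozen=True)
class ScoreHistogram:
    """Per-class score histogram on shared bin edges, with class moments."""

    edges: np.ndarray
    positive_counts: np.ndarray
    negative_counts: np.ndarray
    positive_mean: float
    positive_sd: float
    negative_mean: float
    negative_sd: float


def score_histogram(
    dataset: LabeledDataset, table: PropensityTable, bins: int
) -> ScoreHistogram:
    """Histogram protein scores per class over the pooled score range."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if not dataset.positives or not dataset.negatives:
        raise ValueError("both classes must be non-empty")
    pos = score_dataset([r.sequence for r in dataset.positives], table)
    neg = score_dataset([r.sequence for r in dataset.negatives], table)
    pooled = np.concatenate([pos, neg])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    pos_counts, _ = np.histogram(pos, bins=edges)
    neg_counts, _ = np.histogram(neg, bins=edges)

    def sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    return ScoreHistogram(
        edges=edges,
        positive_counts=pos_counts,
        negative_counts=neg_counts,
        positive_mean=float(pos.mean()),
        positive_sd=sd(pos),
        negative_mean=float(neg.mean()),
        negative_sd=sd(neg),
    )
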