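"""g-gap dipeptide composition (GDC) encoding.

A g-gap dipeptide is an ordered residue pair separated by ``g`` intervening
residues, so a pair spans sequence positions ``(p, p + g + 1)`` and ``g = 0``
recovers classic dipeptide composition.  A sequence of length ``L >= g + 2``
yields ``L - g - 1`` pairs; the GDC vector is the 400-dimensional vector of
pair fractions, which sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import STANDARD_AA

#: Residue -> rank in the alphabetical one-letter ordering.
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: The 400 ordered dipeptides, row-major in (first residue, second residue).
DIPEPTIDES = [a + b for a in STANDARD_AA for b in STANDARD_AA]

N_DIPEPTIDES = 400

_CODE = np.full(128, -1, dtype=np.int64)
for _aa, _i in AA_INDEX.items():
    _CODE[ord(_aa)] = _i


class SequenceLengthError(ValueError):
    """Sequence too short to contain a single g-gap dipeptide."""


class NonStandardResidueError(ValueError):
    """Residue outside the 20 standard one-letter codes."""


@dataclass(frozen=True)
class DipeptideCounts:
    """Raw g-gap dipeptide counts of one sequence (sums to L - g - 1)."""

    g: int
    counts: np.ndarray  # (400,) non-negative integers


@dataclass(frozen=True)
class GdcVector:
    """Normalized g-gap dipeptide composition of one sequence (sums to 1)."""

    g: int
    values: np.ndarray  # (400,) fractions


def dipeptide_index(first: str, second: str) -> int:
    """Row-major index of the ordered dipeptide: 20 * rank(first) + rank(second)."""
    try:
        return 20 * AA_INDEX[first] + AA_INDEX[second]
    except KeyError as exc:
        raise NonStandardResidueError(f"non-standard residue: {exc.args[0]!r}") from None


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to integer residue ranks, validating residues."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise NonStandardResidueError(f"non-standard residue: {bad!r}")
    return codes


def count_dipeptides(seq: str, g: int) -> DipeptideCounts:
    """Count all ordered pairs (seq[p], seq[p + g + 1]).

    Raises SequenceLengthError if ``len(seq) < g + 2``.
    """
    if g < 0:
        raise ValueError(f"gap size must be non-negative, got {g}")
    if len(seq) < g + 2:
        raise SequenceLengthError(
            f"sequence of length {len(seq)} has no dipeptide at gap {g} "
            f"(needs length >= {g + 2})"
        )
    codes = encode_sequence(seq)
    idx = 20 * codes[: len(seq) - g - 1] + codes[g + 1 :]
    counts = np.bincount(idx, minlength=N_DIPEPTIDES)
    return DipeptideCounts(g=g, counts=counts)


def gdc_compose(seq: str, g: int) -> GdcVector:
    """The GDC(g) vector of one sequence: counts / (L - g - 1)."""
    counted = count_dipeptides(seq, g)
    return GdcVector(g=g, values=counted.counts / counted.counts.sum())


def gdc_matrix(sequences: Sequence[str], g: int) -> np.ndarray:
    """Stack GDC(g) vectors of several sequences into an (n, 400) matrix."""
    return np.array([gdc_compose(s, g).values for s in sequences])


def gdc_frame(ids: Sequence[str], sequences: Sequence[str], g: int) -> pd.DataFrame:
    """GDC feature matrix as a DataFrame (rows = ids, 400 dipeptide columns)."""
    return pd.DataFrame(gdc_matrix(sequences, g), index=list(ids), columns=DIPEPTIDES)
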