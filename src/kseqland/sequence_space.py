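"""Sequence representation, distances, and mutant-neighborhood enumeration.

The pools analysed here are fixed-length DNA 21-mers (the central variable
region of the ribozyme construct, read out by sequencing).  RNA input is
normalised to DNA (U -> T) at I/O boundaries; everything internal works on
uppercase ACGT strings.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import edlib

DNA_ALPHABET = "ACGT"
VARIABLE_REGION_LENGTH = 21


class SequenceLengthError(ValueError):
    """Raised when equal-length sequences are required but not supplied."""


class NeighborhoodDepthError(ValueError):
    """Raised when a mutant neighborhood beyond double mutants is requested."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.strip().upper().replace("U", "T")


def is_valid_sequence(seq: str, length: int | None = None) -> bool:
    """True iff ``seq`` is over {A,C,G,T} and, if given, of the required length."""
    if length is not None and len(seq) != length:
        return False
    return bool(seq) and all(b in DNA_ALPHABET for b in seq)


def hamming_distance(a: str, b: str) -> int:
    """Number of substitution differences between two equal-length sequences.

    Raises
    ------
    SequenceLengthError
        If ``a`` and ``b`` differ in length.
    """
    if len(a) != len(b):
        raise SequenceLengthError(
            f"hamming_distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def levenshtein_distance(a: str, b: str) -> int:
    """Minimal number of substitutions, insertions, or deletions between two strings."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def enumerate_mutants(center: str, max_distance: int) -> set[str]:
    """All sequences within Hamming distance ``max_distance`` of ``center``.

    Only depths 0-2 are supported: the mutant pools assayed here consist of a
    wild type plus its complete single- and double-substitution neighborhood
    (1 + 3L + 9*L*(L-1)/2 sequences; 1954 for L = 21).

    Raises
    ------
    NeighborhoodDepthError
        If ``max_distance`` > 2.
    ValueError
        If ``center`` contains non-ACGT characters.
    """
    if max_distance > 2:
        raise NeighborhoodDepthError(
            f"neighborhoods beyond double mutants are not supported (got {max_distance})"
        )
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    if not is_valid_sequence(center):
        raise ValueError(f"center contains characters outside {DNA_ALPHABET}")

    members = {center}
    L = len(center)
    if max_distance >= 1:
        for i in range(L):
            for base in DNA_ALPHABET:
                if base != center[i]:
                    members.add(center[:i] + base + center[i + 1 :])
    if max_distance >= 2:
        for i, j in combinations(range(L), 2):
            for bi in DNA_ALPHABET:
                if bi == center[i]:
                    continue
                for bj in DNA_ALPHABET:
                    if bj == center[j]:
                        continue
                    members.add(center[:i] + bi + center[i + 1 : j] + bj + center[j + 1 :])
    return members


def neighborhood_size(length: int, max_distance: int) -> int:
    """Closed-form size of a substitution neighborhood over a 4-letter alphabet."""
    if max_distance == 0:
        return 1
    if max_distance == 1:
        return 1 + 3 * length
    if max_distance == 2:
        return 1 + 3 * length + 9 * length * (length - 1) // 2
    raise NeighborhoodDepthError("only depths 0-2 have precomputed sizes")


def assign_to_centers(
    sequences: Iterable[str], centers: Sequence[str], max_distance: int = 2
) -> dict[str, str | None]:
    """Assign each sequence to its nearest center within ``max_distance``.

    A sequence within range of several centers goes to the nearest one; exact
    distance ties go to the center listed first.  Sequences out of range of
    every center map to ``None``.
    """
    out: dict[str, str | None] = {}
    for seq in sequences:
        best: str | None = None
        best_d = max_distance + 1
        for center in centers:
            if len(center) != len(seq):
                continue
            d = hamming_distance(seq, center)
            if d < best_d:
                best, best_d = center, d
        out[seq] = best
    return out


def mutation_label(center: str, variant: str) -> str:
    """Compact edit label for a variant, e.g. ``5G|12T`` (1-based positions)."""
    if len(center) != len(variant):
        raise SequenceLengthError("mutation_label requires equal lengths")
    edits = [f"{i + 1}{b}" for i, (a, b) in enumerate(zip(center, variant)) if a != b]
    return "|".join(edits) if edits else "wt"
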