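"""Kimura two-parameter (K2P) distances from an aligned nucleotide FASTA.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T) and transversions (all other changes):

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the per-site proportions of transition- and
transversion-differing sites among the comparable positions of a pair.
Sites where either sequence carries a gap or any non-ACGT symbol (N,
IUPAC ambiguity codes) are excluded pair by pair (pairwise deletion);
ambiguity codes are treated as missing rather than fractionally matched.
No among-site rate correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .cross_data import DistanceMatrix

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence at or beyond saturation."""


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, too few sequences, no usable sites)."""


@dataclass(frozen=True)
class AlignedSequences:
    """A set of equal-length nucleotide sequences with labels."""

    ids: tuple[str, ...]
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "residues", tuple(s.upper() for s in self.residues))
        if len(self.ids) != len(self.residues):
            raise AlignmentError("ids and residues differ in number")
        if len(self.ids) < 2:
            raise AlignmentError("need at least two sequences")
        lengths = {len(s) for s in self.residues}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences are not aligned: lengths {sorted(lengths)}")
        if lengths == {0}:
            raise AlignmentError("alignment has zero length")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedSequences":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=tuple(r.id for r in recs), residues=tuple(str(r.seq) for r in recs))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.residues):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class SitePartition:
    """Pairwise site classification: usable sites and P/Q proportions."""

    usable_sites: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.usable_sites < 1:
            raise AlignmentError("no comparable positions between the pair")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("P and Q must be non-negative with P + Q <= 1")


def classify_pair(seq_a: str, seq_b: str) -> SitePartition:
    """Classify the sites of an aligned pair into transitions/transversions.

    Pairwise deletion: a site counts only if both residues are in
    {A, C, G, T}.  Among usable sites, A<->G and C<->T mismatches are
    transitions, all other mismatches transversions.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences have unequal lengths")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    usable = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    n_use = int(usable.sum())
    if n_use == 0:
        raise AlignmentError("zero usable sites: no comparable positions")
    au, bu = a[usable], b[usable]
    diff = au != bu
    purine_a = (au == b"A") | (au == b"G")
    purine_b = (bu == b"A") | (bu == b"G")
    ts = diff & (purine_a == purine_b)  # same class, different base
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return SitePartition(usable_sites=n_use, P=n_ts / n_use, Q=n_tv / n_use)


def k2p_distance(part: SitePartition) -> float:
    """K2P distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    Raises :class:`SaturationError` when either logarithm argument is
    non-positive (observed divergence too high for the correction).
    """
    w1 = 1.0 - 2.0 * part.P - part.Q
    w2 = 1.0 - 2.0 * part.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated divergence (P={part.P:.4g}, Q={part.Q:.4g}): "
            "1-2P-Q and 1-2Q must both be positive"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_k2p(seq_a: str, seq_b: str) -> float:
    """Convenience: classify a pair and return its K2P distance."""
    return k2p_distance(classify_pair(seq_a, seq_b))


def distance_matrix(
    aln: AlignedSequences, pop_map: Mapping[str, str] | None = None
) -> DistanceMatrix:
    """All-pairs K2P distance matrix from an alignment.

    ``pop_map`` maps sequence ids to population labels (one representative
    sequence per population); by default the sequence ids themselves label
    the matrix.  Saturation or zero-usable-site errors are re-raised naming
    the offending pair.
    """
    if pop_map is None:
        labels = aln.ids
    else:
        labels = tuple(pop_map[i] for i in aln.ids)
        if len(set(labels)) != len(labels):
            raise AlignmentError("pop_map must give one sequence per population")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = pairwise_k2p(aln.residues[i], aln.residues[j])
            except (SaturationError, AlignmentError) as exc:
                raise type(exc)(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
    return DistanceMatrix(labels=labels, d=d)


def format_distance(d: float) -> str:
    """Outputs report distances to 3 decimals (full precision kept internally)."""
    return f"{d:.3f}"
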