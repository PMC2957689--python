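"""Protein similarity backends for the within-group reciprocal-best-hit step.

Two interchangeable backends implement the ``score_pairs`` contract:

* :class:`BuiltinAligner` — Smith–Waterman local alignment (BLOSUM62,
  affine gaps, open 11 / extend 1) via Biopython's PairwiseAligner, with
  bit scores from Karlin–Altschul scaling (λ = 0.267, K = 0.041, the
  standard gapped BLOSUM62 11/1 parameters) and E-values from the bit
  score and the two sequence lengths. This keeps the pipeline free of any
  external search binary.
* :class:`TabularBackend` — looks pairs up in a precomputed 12-column
  tabular similarity file (e.g. from an external all-vs-all protein
  search); pairs absent from the file are treated as no-hit.

Both are deterministic for fixed inputs and score symmetrically. Residue
characters outside the BLOSUM62 alphabet are aligned as ``X`` (scored as
a near-neutral mismatch); the stored sequences are never modified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import ProteinRecord, TabularHit, read_tabular_hits

KARLIN_ALTSCHUL_LAMBDA = 0.267
KARLIN_ALTSCHUL_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1


@dataclass(frozen=True)
class SimilarityHit:
    """A scored protein pair: higher bit score means more similar."""

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float


class SimilarityBackend(Protocol):
    def score_pairs(
        self, queries: Sequence[ProteinRecord], subjects: Sequence[ProteinRecord]
    ) -> list[SimilarityHit]:
        """Score every query×subject pair; omit pairs with no detectable similarity."""
        ...


def bits_from_raw(raw_score: float) -> float:
    """Karlin–Altschul normalization of a raw local-alignment score."""
    return (KARLIN_ALTSCHUL_LAMBDA * raw_score - math.log(KARLIN_ALTSCHUL_K)) / math.log(2)


def evalue_from_bits(bit_score: float, len_query: int, len_subject: int) -> float:
    """E-value for a single pairwise comparison: m·n·2^(−bits)."""
    return len_query * len_subject * 2.0 ** (-bit_score)


class BuiltinAligner:
    """Smith–Waterman local alignment backend (no external binary needed).

    Gap convention follows Biopython's PairwiseAligner: a gap of length L
    costs open + (L−1)·extend. Only positive-scoring pairs are reported;
    a threshold on the bit score can be set to discard weak pairs.
    """

    def __init__(self, min_bit_score: float | None = None) -> None:
        matrix = substitution_matrices.load("BLOSUM62")
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -GAP_OPEN
        aligner.extend_gap_score = -GAP_EXTEND
        self._aligner = aligner
        self._alphabet = set(str(matrix.alphabet))
        self.min_bit_score = min_bit_score
        self._cache: dict[tuple[str, str], float] = {}

    def _sanitize(self, sequence: str) -> str:
        seq = sequence.upper()
        if all(c in self._alphabet for c in seq):
            return seq
        return "".join(c if c in self._alphabet else "X" for c in seq)

    def raw_score(self, seq_a: str, seq_b: str) -> float:
        """Raw Smith–Waterman score of the best local alignment (≥ 0)."""
        if not seq_a or not seq_b:
            raise ValueError("cannot align an empty sequence")
        return float(self._aligner.score(self._sanitize(seq_a), self._sanitize(seq_b)))

    def align(self, a: ProteinRecord, b: ProteinRecord) -> SimilarityHit:
        key = (a.sequence, b.sequence) if a.sequence <= b.sequence else (b.sequence, a.sequence)
        raw = self._cache.get(key)
        if raw is None:
            raw = self.raw_score(a.sequence, b.sequence)
            self._cache[key] = raw
        bits = bits_from_raw(raw)
        return SimilarityHit(
            query_id=a.protein_id,
            subject_id=b.protein_id,
            bit_score=bits,
            evalue=evalue_from_bits(bits, a.length, b.length),
        )

    def score_pairs(
        self, queries: Sequence[ProteinRecord], subjects: Sequence[ProteinRecord]
    ) -> list[SimilarityHit]:
        hits: list[SimilarityHit] = []
        for q in queries:
            for s in subjects:
                if q.protein_id == s.protein_id:
                    continue
                hit = self.align(q, s)
                key = (q.sequence, s.sequence) if q.sequence <= s.sequence else (s.sequence, q.sequence)
                if self._cache[key] <= 0:
                    continue  # no positive-scoring local alignment
                if self.min_bit_score is not None and hit.bit_score < self.min_bit_score:
                    continue
                hits.append(hit)
        return hits


def builtin_align(a: ProteinRecord, b: ProteinRecord) -> SimilarityHit:
    """One-shot convenience wrapper around :class:`BuiltinAligner`."""
    return BuiltinAligner().align(a, b)


class TabularBackend:
    """Similarity backend over a precomputed pairwise tabular hit file.

    Hits are stored per unordered pair, keeping the best row (highest bit
    score, then lowest E-value) so that scoring is available in both
    directions. Pairs with no row are no-hits.
    """

    def __init__(self, hits: Iterable[TabularHit]) -> None:
        self._pairs: dict[frozenset[str], tuple[float, float]] = {}
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            key = frozenset((h.query_id, h.subject_id))
            best = self._pairs.get(key)
            cand = (h.bit_score, h.evalue)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                self._pairs[key] = cand

    @classmethod
    def from_file(cls, path: str | Path) -> "TabularBackend":
        return cls(read_tabular_hits(path))

    def score_pairs(
        self, queries: Sequence[ProteinRecord], subjects: Sequence[ProteinRecord]
    ) -> list[SimilarityHit]:
        hits: list[SimilarityHit] = []
        for q in queries:
            for s in subjects:
                if q.protein_id == s.protein_id:
                    continue
                found = self._pairs.get(frozenset((q.protein_id, s.protein_id)))
                if found is None:
                    continue
                bit, ev = found
                hits.append(
                    SimilarityHit(
                        query_id=q.protein_id, subject_id=s.protein_id, bit_score=bit, evalue=ev
                    )
                )
        return hits


class MatrixBackend:
    """In-memory score-matrix backend, mainly for tests and oracles."""

    def __init__(self, scores: dict[tuple[str, str], tuple[float, float]]) -> None:
        # scores[(a, b)] = (bit_score, evalue); symmetrized on construction
        self._scores: dict[tuple[str, str], tuple[float, float]] = {}
        for (a, b), v in scores.items():
            self._scores[(a, b)] = v
            self._scores.setdefault((b, a), v)

    def score_pairs(
        self, queries: Sequence[ProteinRecord], subjects: Sequence[ProteinRecord]
    ) -> list[SimilarityHit]:
        hits = []
        for q in queries:
            for s in subjects:
                if q.protein_id == s.protein_id:
                    continue
                v = self._scores.get((q.protein_id, s.protein_id))
                if v is None:
                    continue
                hits.append(
                    SimilarityHit(
                        query_id=q.protein_id, subject_id=s.protein_id, bit_score=v[0], evalue=v[1]
                    )
                )
        return hits
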