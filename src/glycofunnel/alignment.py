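"""Deterministic global pairwise alignment with affine gaps.

This is the in-package replacement for an external multiple-sequence
alignment step: each ortholog is aligned globally to the human reference
(Needleman–Wunsch with Gotoh affine-gap states) and site coordinates are
mapped through the alignment.  A gap run of length ``L`` costs
``gap_open + (L - 1) * gap_extend``.  Traceback tie-breaking is fixed
(prefer diagonal, then up, then left) so that the chosen alignment — and
therefore every mapped site coordinate — is reproducible across platforms.

Direct switches between the two gap states are permitted at gap-open cost,
so the optimum agrees with an unrestricted enumeration over all gapped
alignments; with protein matrices and realistic penalties such columns never
appear in an optimal path.

Precomputed alignments (aligned FASTA or Clustal) can be ingested instead
via :func:`pairwise_from_msa`, and take precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .model import GlycoFunnelError

NEG_INF = -1e30
_TOL = 1e-9

#: Marker returned by :func:`map_position` when the reference residue is
#: aligned against a gap in the other sequence.
GAP = None


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    #: Optional explicit matrix mapping (a, b) -> score; overrides
    #: ``matrix_name`` (used for reduced-alphabet tests).
    matrix: Optional[Mapping[tuple[str, str], float]] = None

    def lookup(self) -> Mapping[tuple[str, str], float]:
        if self.matrix is not None:
            return self.matrix
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str) -> dict[tuple[str, str], float]:
    arr = substitution_matrices.load(name)
    letters = arr.alphabet
    return {
        (a, b): float(arr[a, b]) for a in letters for b in letters
    }


@dataclass(frozen=True)
class PairAlignment:
    """A global alignment of two sequences as equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise GlycoFunnelError("bad_alignment", "aligned strings differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise GlycoFunnelError("bad_alignment", "gap-gap column in alignment")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


def _encode(seq: str, alphabet: dict[str, int]) -> np.ndarray:
    return np.fromiter((alphabet[c] for c in seq), dtype=np.intp, count=len(seq))


def align_pair(
    seq_a: str, seq_b: str, params: ScoringParams | None = None
) -> PairAlignment:
    """Optimal global alignment of ``seq_a`` and ``seq_b``.

    Dynamic programming over three states per cell (match, gap-in-b "up",
    gap-in-a "left"); rows are numpy-vectorised, the within-row horizontal
    gap state is resolved with a running-maximum scan.
    """
    if params is None:
        params = ScoringParams()
    if not seq_a or not seq_b:
        raise GlycoFunnelError("empty_sequence", "cannot align an empty sequence")
    table = params.lookup()
    letters = sorted({c for pair in table for c in pair} | set(seq_a) | set(seq_b))
    alphabet = {c: i for i, c in enumerate(letters)}
    k = len(letters)
    S = np.full((k, k), NEG_INF)
    for (x, y), v in table.items():
        S[alphabet[x], alphabet[y]] = v
    missing = [c for c in set(seq_a) | set(seq_b) if (c, c) not in table]
    if missing:
        raise GlycoFunnelError(
            "unscored_letter",
            f"letters not covered by matrix {params.matrix_name}: {sorted(missing)}",
        )

    a = _encode(seq_a, alphabet)
    b = _encode(seq_b, alphabet)
    n, m = len(a), len(b)
    go, ge = float(params.gap_open), float(params.gap_extend)

    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in b, consumes a ("up")
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in a, consumes b ("left")
    M[0, 0] = 0.0
    if n:
        Ix[1:, 0] = -go - ge * np.arange(n)
    if m:
        Iy[0, 1:] = -go - ge * np.arange(m)

    js = np.arange(m)
    for i in range(1, n + 1):
        sub = S[a[i - 1], b]  # scores of a_i against every b_j
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        Ix[i, :] = np.maximum(
            np.maximum(M[i - 1], Iy[i - 1]) - go, Ix[i - 1] - ge
        )
        Ix[i, 0] = -go - ge * (i - 1)
        # Iy[i, j] = max_{k<j} max(M[i,k], Ix[i,k]) - go - (j-1-k)*ge
        P = np.maximum(M[i, :m], Ix[i, :m])
        run = np.maximum.accumulate(P + ge * js)
        Iy[i, 1:] = run - go - ge * js
        Iy[i, 0] = NEG_INF

    # Traceback with fixed preference: diagonal (M) > up (Ix) > left (Iy).
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax([v + _TOL * (2 - idx) for idx, v in enumerate(finals)]))
    # argmax with tiny bias keeps preference order on exact ties
    score = float(max(finals))
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M: consumed a_i and b_j
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            target = M[i, j] - S[a[i - 1], b[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, val in ((0, M[i, j]), (1, Ix[i, j]), (2, Iy[i, j])):
                if abs(val - target) <= _TOL:
                    state = cand
                    break
        elif state == 1:  # Ix: consumed a_i, gap in b
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            target = Ix[i, j]
            i -= 1
            if abs(M[i, j] - go - target) <= _TOL:
                state = 0
            elif abs(Ix[i, j] - ge - target) <= _TOL:
                state = 1
            else:
                state = 2
        else:  # Iy: consumed b_j, gap in a
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            target = Iy[i, j]
            j -= 1
            if abs(M[i, j] - go - target) <= _TOL:
                state = 0
            elif abs(Ix[i, j] - go - target) <= _TOL:
                state = 1
            else:
                state = 2
    return PairAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=score,
        params=params,
    )


def map_position(alignment: PairAlignment, pos_in_a: int) -> Optional[int]:
    """Map a 1-based position in sequence A to its aligned 1-based position
    in sequence B, or :data:`GAP` when the column carries a gap in B."""
    seq_a_len = len(alignment.seq_a)
    if not 1 <= pos_in_a <= seq_a_len:
        raise GlycoFunnelError(
            "out_of_range", f"position {pos_in_a} outside 1..{seq_a_len}"
        )
    count_a = 0
    count_b = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if cb != "-":
            count_b += 1
        if ca != "-":
            count_a += 1
            if count_a == pos_in_a:
                return count_b if cb != "-" else GAP
    raise AssertionError("unreachable: position not found in alignment")


def pairwise_from_msa(msa, id_a: str, id_b: str) -> PairAlignment:
    """Project a precomputed multiple alignment onto a sequence pair.

    ``msa`` is a Biopython ``MultipleSeqAlignment`` (read with ``AlignIO``
    from aligned FASTA or Clustal format).  Columns gapped in both chosen
    rows are dropped; the score is not recomputed (set to ``nan``) because
    the external aligner's objective is unknown.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    for rid in (id_a, id_b):
        if rid not in rows:
            raise GlycoFunnelError("missing_msa_row", f"{rid!r} not in alignment")
    kept_a, kept_b = [], []
    for x, y in zip(rows[id_a], rows[id_b]):
        if x == "-" and y == "-":
            continue
        kept_a.append(x)
        kept_b.append(y)
    return PairAlignment(
        aligned_a="".join(kept_a),
        aligned_b="".join(kept_b),
        score=float("nan"),
    )
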