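"""Global pairwise alignment and master–slave stacking of TE family copies.

Each copy retained for age estimation (strictly longer than 100 bp) is
globally aligned to its family consensus with the Needleman–Wunsch
algorithm under affine gap costs (Gotoh three-state recursion).  The
pairwise alignments are then stacked into a master–slave multiple
alignment: columns are consensus positions, characters a copy aligns to a
master gap (slave-only insertions) are dropped from the matrix but counted
in a per-copy insertion log, and consensus positions outside a truncated
copy read '-'.

Affine gaps (a gap of length k costs ``gap_open + k * gap_extend``) are
used because TE copies accumulate long internal deletions that a linear
gap cost over-penalizes.  'N' is scored 0 against any base and never
counts as a match or mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NEG_INF = -1.0e30
_EPS = 1e-4


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class PairwiseAlignment:
    master_aligned: str
    slave_aligned: str
    score: float
    slave_id: str = ""

    def __post_init__(self):
        if len(self.master_aligned) != len(self.slave_aligned):
            raise ValueError("gapped sequences differ in length")


def filter_copies_by_length(copies: Sequence, min_length: int = 100) -> list:
    """Keep copies strictly longer than ``min_length`` (default 100 bp).

    Accepts anything exposing ``copy_length`` (TECopy) or ``len()``.
    """
    def _length(c):
        return c.copy_length if hasattr(c, "copy_length") else len(c)

    return [c for c in copies if _length(c) > min_length]


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)  # 4 = N / ambiguous
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _fill_numpy(a: np.ndarray, b: np.ndarray, match: float, mismatch: float,
                go: float, ge: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-vectorized Gotoh fill; the horizontal state is computed with a
    prefix-max scan (a gap of span j-k costs go + (j-k)*ge from the best
    non-horizontal state at column k)."""
    n, m = a.size, b.size
    sub_all = np.where((a[:, None] == 4) | (b[None, :] == 4), 0.0,
                       np.where(a[:, None] == b[None, :],
                                match, mismatch)).astype(np.float32)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)  # gap in slave (vertical)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)  # gap in master (horizontal)
    M[0, 0] = 0.0
    X[1:, 0] = go + ge * np.arange(1, n + 1)
    Y[0, 1:] = go + ge * np.arange(1, m + 1)

    ge_j = (ge * np.arange(m)).astype(np.float32)
    ge_j1 = (go + ge * np.arange(1, m + 1)).astype(np.float32)
    goge = np.float32(go + ge)
    ge32 = np.float32(ge)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        np.add(prev_best[:-1], sub_all[i - 1], out=M[i, 1:])
        np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + goge,
                   X[i - 1, 1:] + ge32, out=X[i, 1:])
        X[i, 0] = go + ge * i
        B = np.maximum(M[i, :m], X[i, :m])
        run = np.maximum.accumulate(B - ge_j)
        np.add(ge_j1, run, out=Y[i, 1:])
    return M, X, Y


try:  # cell-wise fill, much faster when numba is present
    from numba import njit

    @njit(cache=True)
    def _fill_numba(a, b, match, mismatch, go, ge):  # pragma: no cover - numba
        n, m = a.size, b.size
        M = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
        X = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
        Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = go + ge * i
        for j in range(1, m + 1):
            Y[0, j] = go + ge * j
        for i in range(1, n + 1):
            ai = a[i - 1]
            for j in range(1, m + 1):
                bj = b[j - 1]
                if ai == 4 or bj == 4:
                    s = 0.0
                elif ai == bj:
                    s = match
                else:
                    s = mismatch
                p = M[i - 1, j - 1]
                if X[i - 1, j - 1] > p:
                    p = X[i - 1, j - 1]
                if Y[i - 1, j - 1] > p:
                    p = Y[i - 1, j - 1]
                M[i, j] = p + s
                x = M[i - 1, j] + go + ge
                if Y[i - 1, j] + go + ge > x:
                    x = Y[i - 1, j] + go + ge
                if X[i - 1, j] + ge > x:
                    x = X[i - 1, j] + ge
                X[i, j] = x
                y = M[i, j - 1] + go + ge
                if X[i, j - 1] + go + ge > y:
                    y = X[i, j - 1] + go + ge
                if Y[i, j - 1] + ge > y:
                    y = Y[i, j - 1] + ge
                Y[i, j] = y
        return M, X, Y

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def global_align(master: str, slave: str,
                 scoring: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap scoring.

    Traceback ties are broken deterministically: prefer the diagonal move,
    then the vertical (gap in slave), then the horizontal (gap in master).
    """
    if not master or not slave:
        raise ValueError("sequences must be non-empty")
    a = _encode(master)
    b = _encode(slave)
    n, m = a.size, b.size
    go, ge = scoring.gap_open, scoring.gap_extend

    fill = _fill_numba if _HAVE_NUMBA else _fill_numpy
    M, X, Y = fill(a, b, float(scoring.match), float(scoring.mismatch),
                   float(go), float(ge))

    # --- traceback -------------------------------------------------------
    i, j = n, m
    scores = (M[n, m], X[n, m], Y[n, m])
    best = max(scores)
    state = int(np.argmax([s >= best - _EPS for s in scores]))  # M > X > Y
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            out_a.append(master[i - 1])
            out_b.append(slave[j - 1])
            target = M[i, j]
            i, j = i - 1, j - 1
            cands = (M[i, j], X[i, j], Y[i, j])
            # predecessor contributed target - sub; pick by M > X > Y preference
            ref = max(cands)
            state = next(k for k, v in enumerate(cands) if v >= ref - _EPS)
        elif state == 1:  # vertical: consume master, gap in slave
            out_a.append(master[i - 1])
            out_b.append("-")
            prev = (M[i - 1, j] + go + ge, X[i - 1, j] + ge, Y[i - 1, j] + go + ge)
            i -= 1
            ref = X[i + 1, j]
            state = next(k for k, v in enumerate(prev) if v >= ref - _EPS)
        else:  # horizontal: gap in master, consume slave
            out_a.append("-")
            out_b.append(slave[j - 1])
            prev = (M[i, j - 1] + go + ge, X[i, j - 1] + go + ge, Y[i, j - 1] + ge)
            j -= 1
            ref = Y[i, j + 1]
            state = next(k for k, v in enumerate(prev) if v >= ref - _EPS)
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(best))


@dataclass
class MasterSlaveMSA:
    """Consensus-column-indexed alignment of a family's copies.

    ``rows`` maps copy id to a string of exactly ``len(consensus)``
    characters over {A, C, G, T, N, -}; ``insertions`` counts the
    slave-only inserted bases dropped per copy.
    """

    consensus_id: str
    consensus: str
    rows: dict[str, str] = field(default_factory=dict)
    insertions: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def row_ids(self) -> list[str]:
        return list(self.rows)

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        records = [(self.consensus_id, self.consensus)]
        records += list(self.rows.items())
        write_fasta(records, path)


def stack_alignments(consensus_id: str, consensus: str,
                     alignments: Sequence[PairwiseAlignment]) -> MasterSlaveMSA:
    """Stack master-referenced pairwise alignments into a master–slave MSA."""
    msa = MasterSlaveMSA(consensus_id, consensus.upper())
    for k, aln in enumerate(alignments):
        row_id = aln.slave_id or f"row{k + 1}"
        degapped = aln.master_aligned.replace("-", "").upper()
        if degapped != msa.consensus:
            raise ValueError(
                f"{row_id}: master side of the alignment does not degap to the consensus"
            )
        chars: list[str] = []
        inserted = 0
        for mc, sc in zip(aln.master_aligned.upper(), aln.slave_aligned.upper()):
            if mc == "-":
                inserted += sc != "-"
                continue
            chars.append(sc)
        msa.rows[row_id] = "".join(chars)
        msa.insertions[row_id] = inserted
    return msa
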