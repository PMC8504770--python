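"""Structural discovery of MITE-like elements.

MITEs (miniature inverted-repeat transposable elements) are short
non-autonomous class II elements recognizable purely from structure: a
pair of terminal inverted repeats (TIRs) and a target-site duplication
(TSD) in the immediately flanking host sequence.  This module scans raw
sequence for candidate intervals with inverted terminal repeats, validates
the TSD in the flanks, clusters candidate sequences into families by
greedy centroid clustering on global-alignment identity, and assigns
superfamilies from an ordered TSD/TIR signature table.

The TIR rule is explicit and re-checkable: an interval [i, j] (inclusive
ends) has TIR length t when t is the largest value not exceeding
``max_tir`` nor half the element length such that at most ``max_mismatch``
of the base pairs (i+k, j-k), k < t, fail to be complementary ('N'
complements nothing).  Candidates require t >= ``min_tir``; overlapping
candidates are resolved longest-TIR-first, then leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .alignment import ScoringScheme, global_align

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass
class MITECandidate:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    tir_length: int
    tir_mismatches: int
    sequence: str = ""
    tsd: str = ""
    rejection: str = ""

    @property
    def element_length(self) -> int:
        return self.end - self.start


def _scan_antidiagonals(s: np.ndarray, comp: np.ndarray, min_tir: int,
                        max_tir: int, min_len: int, max_len: int,
                        max_mismatch: int) -> list[tuple[int, int, int, int]]:
    """Vectorized raw scan along anti-diagonals of the self-complementarity
    matrix; returns (start, end, tir_length, mismatches) tuples."""
    n = s.size
    raw: list[tuple[int, int, int, int]] = []
    for d in range(min_len - 1, 2 * n - min_len):
        # starts i with element [i, d - i] of length L = d - 2i + 1
        i_lo = max(0, d - (n - 1), -((max_len - 1 - d) // 2))  # ceil((d-max_len+1)/2)
        i_hi = (d - min_len + 1) // 2
        if i_hi < i_lo:
            continue
        # inward pair at offset k from start a: positions (a+k, d-a-k);
        # valid while a+k < d-a-k, i.e. index < d/2 (strictly inside)
        top = min(i_hi + max_tir, (d - 1) // 2 if d % 2 else d // 2 - 1)
        idx = np.arange(i_lo, top + 1)
        if idx.size == 0:
            continue
        v = (s[idx] != 4) & (s[idx] == comp[d - idx])
        c = np.concatenate([[0], np.cumsum(~v)])
        starts = np.arange(i_lo, i_hi + 1)
        r = starts - i_lo
        t_raw = np.searchsorted(c, c[r] + max_mismatch, side="right") - 1 - r
        L = d - 2 * starts + 1
        t_cap = np.minimum(np.minimum(max_tir, L // 2), idx.size - r)
        t = np.minimum(t_raw, t_cap)
        ok = np.nonzero(t >= min_tir)[0]
        for k in ok:
            a = int(starts[k])
            tk = int(t[k])
            raw.append((a, d - a + 1, tk, int(c[r[k] + tk] - c[r[k]])))
    return raw


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _scan_cells(s, comp, min_tir, max_tir, min_len, max_len,
                    max_mismatch):  # pragma: no cover - numba
        n = s.size
        cap_out = 1024
        out = np.empty((cap_out, 4), dtype=np.int64)
        m = 0
        for i in range(n):
            j_top = min(i + max_len, n)
            for j in range(i + min_len, j_top + 1):  # j = end (exclusive)
                L = j - i
                cap = min(max_tir, L // 2)
                mism = 0
                best_t = 0
                best_m = 0
                for k in range(cap):
                    a = s[i + k]
                    b = s[j - 1 - k]
                    if a == 4 or b == 4 or comp[i + k] != b:
                        mism += 1
                        if mism > max_mismatch:
                            break
                    best_t = k + 1
                    best_m = mism
                if best_t >= min_tir:
                    if m == cap_out:
                        bigger = np.empty((cap_out * 2, 4), dtype=np.int64)
                        bigger[:cap_out] = out
                        out = bigger
                        cap_out *= 2
                    out[m, 0] = i
                    out[m, 1] = j
                    out[m, 2] = best_t
                    out[m, 3] = best_m
                    m += 1
        return out[:m]

    _HAVE_NUMBA_SCAN = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA_SCAN = False


def find_inverted_repeats(sequence: str, seq_id: str = "seq", *,
                          min_tir: int = 10, max_tir: int = 200,
                          min_len: int = 50, max_len: int = 800,
                          max_mismatch: int = 2) -> list[MITECandidate]:
    """Scan one sequence for TIR-bearing candidate elements.

    A TIR at interval ends (i, j) is a run of complementary base pairs
    moving inward along the anti-diagonal i + j of the (implicit)
    self-complementarity matrix.  Overlapping raw hits are resolved
    longest-TIR-first, then leftmost.  The TIR structure is
    strand-symmetric, so elements are found regardless of the strand they
    inserted on.
    """
    s = _ENCODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    comp = _COMPLEMENT[s]
    if _HAVE_NUMBA_SCAN:
        hits = _scan_cells(s, comp, min_tir, max_tir, min_len, max_len,
                           max_mismatch)
        raw = [(int(a), int(e), int(t), int(mm)) for a, e, t, mm in hits]
    else:
        raw = _scan_antidiagonals(s, comp, min_tir, max_tir, min_len,
                                  max_len, max_mismatch)
    candidates = [MITECandidate(seq_id, a, e, t, mm) for a, e, t, mm in raw]
    # overlap resolution: longest TIR first, then leftmost
    candidates.sort(key=lambda m: (-m.tir_length, m.start, m.end))
    kept: list[MITECandidate] = []
    taken = IntervalTree()
    for cand in candidates:
        if not taken.overlap(cand.start, cand.end):
            taken.addi(cand.start, cand.end)
            cand.sequence = sequence[cand.start:cand.end].upper()
            kept.append(cand)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept


def validate_tsd(candidate: MITECandidate, sequence: str,
                 k_range: tuple[int, int] = (2, 10),
                 strict: bool = True) -> MITECandidate | None:
    """Record the target-site duplication of a candidate, or reject it.

    The TSD is the largest k in ``k_range`` for which the k bases
    immediately left of the element equal the k bases immediately right of
    it.  Candidates too close to the sequence edge for the longest flank
    are rejected ("flank unavailable"); candidates with no duplicated
    flank of length >= min(k_range) are rejected when ``strict``.
    """
    k_min, k_max = k_range
    seq = sequence.upper()
    if candidate.start < k_max or candidate.end + k_max > len(seq):
        candidate.rejection = "flank unavailable"
        return None
    for k in range(k_max, k_min - 1, -1):
        left = seq[candidate.start - k:candidate.start]
        right = seq[candidate.end:candidate.end + k]
        if left == right and "N" not in left:
            candidate.tsd = left
            return candidate
    if strict:
        candidate.rejection = "no target site duplication"
        return None
    return candidate


def _tir_stats(seq: str, start: int, end: int, max_tir: int,
               max_mismatch: int) -> tuple[int, int]:
    """Recompute (tir_length, mismatches) for an interval by scanning inward."""
    L = end - start
    cap = min(max_tir, L // 2)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    mism = 0
    best_t = 0
    best_m = 0
    for k in range(cap):
        a, b = seq[start + k], seq[end - 1 - k]
        if comp.get(a) != b:
            mism += 1
            if mism > max_mismatch:
                break
        best_t, best_m = k + 1, mism
    return best_t, best_m


def refine_candidate(candidate: MITECandidate, sequence: str, *,
                     k_range: tuple[int, int] = (2, 10), min_tir: int = 10,
                     min_len: int = 50, max_tir: int = 200,
                     max_mismatch: int = 2, max_shift: int = 10,
                     table: Sequence["SignatureRule"] = None,
                     strict: bool = True) -> MITECandidate | None:
    """TSD-guided boundary refinement of a raw TIR candidate.

    The inverted-repeat run of a genuine element often overshoots its true
    boundaries: a palindromic TSD (e.g. the TA target of Tc1/mariner
    elements) is its own reverse complement and is absorbed into the run,
    and chance complementarity of the flanking host bases extends the run
    symmetrically.  The true element therefore sits at
    ``[start + a, end - a)`` for some small shift a >= 0.  Each shift is
    tested for a duplicated flanking k-mer; per shift the longest
    duplication consistent with a signature-table rule is kept (plus the
    longest overall when no rule matches), and among validating
    hypotheses one is chosen by (1) TSD consistent with a signature rule,
    (2) smallest shift, (3) longest TSD.  The residual ambiguity of
    palindromic targets is inherent to single-element structural evidence
    and is documented rather than hidden: a chance flank duplication can
    still shift a boundary by a few bases.

    Returns the refined candidate (TIR statistics recomputed at the new
    boundaries) or None when no shift validates and ``strict`` is set.
    """
    if table is None:
        table = DEFAULT_SIGNATURE_TABLE
    k_min, k_max = k_range
    seq = sequence.upper()
    n = len(seq)
    hypotheses = []
    max_a = min(max_shift, candidate.tir_length - min_tir)
    for a in range(0, max_a + 1):
        p, q = candidate.start + a, candidate.end - a
        if q - p < min_len or p < k_max or q + k_max > n:
            continue
        tir_start = seq[p:p + 8]
        have_nonsig = False
        for k in range(k_max, k_min - 1, -1):
            left = seq[p - k:p]
            if "N" in left or left != seq[q:q + k]:
                continue
            sig = any(r.matches(left, tir_start) for r in table)
            if sig:
                hypotheses.append((0, a, -k, p, q, left))
                break  # longest signature-consistent duplication at this shift
            if not have_nonsig:
                hypotheses.append((1, a, -k, p, q, left))
                have_nonsig = True
    if not hypotheses:
        if strict:
            candidate.rejection = "no target site duplication"
            return None
        candidate.sequence = seq[candidate.start:candidate.end]
        return candidate
    _, a, _, p, q, tsd = min(hypotheses)
    t, m = _tir_stats(seq, p, q, max_tir, max_mismatch)
    if t < min_tir:
        if strict:
            candidate.rejection = "refined TIR below minimum"
            return None
        return candidate
    refined = MITECandidate(candidate.seq_id, p, q, t, m, seq[p:q], tsd)
    return refined


def alignment_identity(a: str, b: str,
                       scoring: ScoringScheme = ScoringScheme()) -> float:
    """Fraction of identical columns in the global alignment of a and b."""
    aln = global_align(a, b, scoring)
    matches = sum(x == y and x != "-" for x, y in zip(aln.master_aligned,
                                                     aln.slave_aligned))
    return matches / len(aln.master_aligned)


try:
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None


def _identity_possible(a: str, b: str, threshold: float) -> bool:
    """Cheap necessary condition for alignment identity >= threshold.

    For any global alignment with identity M/C >= threshold, the edit
    distance is at most C - M <= (1 - threshold) * (len(a) + len(b)), so a
    larger edit distance rules the pair out without running the scored
    alignment.
    """
    if _edlib is None:
        return True
    bound = int((1.0 - threshold) * (len(a) + len(b)))
    res = _edlib.align(a, b, mode="NW", task="distance", k=bound)
    return res["editDistance"] != -1


@dataclass
class MITEFamily:
    family_id: str
    centroid: MITECandidate
    members: list[MITECandidate] = field(default_factory=list)
    identity_threshold: float = 0.80
    superfamily: str = "unclassified"

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_mites(candidates: Sequence[MITECandidate],
                  identity_threshold: float = 0.80) -> list[MITEFamily]:
    """Greedy centroid clustering of candidate sequences.

    Candidates are processed by decreasing length (ties keep input order);
    each joins the first existing centroid it matches at
    ``identity_threshold`` global-alignment identity on either strand
    (elements insert on both strands), otherwise it founds a new family.
    Deterministic given the input order.
    """
    from .io import revcomp

    ordered = sorted(candidates, key=lambda m: -len(m.sequence))
    families: list[MITEFamily] = []
    for cand in ordered:
        rc = revcomp(cand.sequence)
        for fam in families:
            lc, lf = len(cand.sequence), len(fam.centroid.sequence)
            # identity = matches/columns <= min(lc, lf)/max(lc, lf): skip
            # alignments that cannot possibly reach the threshold
            if min(lc, lf) < identity_threshold * max(lc, lf):
                continue
            centroid = fam.centroid.sequence
            hit = False
            for query in (cand.sequence, rc):
                if not _identity_possible(centroid, query, identity_threshold):
                    continue
                if alignment_identity(centroid, query) >= identity_threshold:
                    hit = True
                    break
            if hit:
                fam.members.append(cand)
                break
        else:
            families.append(MITEFamily(f"MF{len(families) + 1}", cand, [cand],
                                       identity_threshold))
    return families


@dataclass(frozen=True)
class SignatureRule:
    """One ordered rule of the superfamily signature table."""

    label: str
    tsd_motifs: tuple[str, ...] = ()    # acceptable exact TSD sequences
    tsd_lengths: tuple[int, ...] = ()   # acceptable TSD lengths
    tir_prefix: str | None = None       # required TIR terminal motif

    def matches(self, tsd: str, tir_start: str) -> bool:
        if not tsd:
            return False
        if self.tsd_motifs and tsd not in self.tsd_motifs:
            return False
        if self.tsd_lengths and len(tsd) not in self.tsd_lengths:
            return False
        if self.tir_prefix is not None and not tir_start.startswith(self.tir_prefix):
            return False
        return True


#: Conventional TSD/TIR signatures of the six MITE-relevant superfamilies.
#: TA targets mark Tc1/mariner, TTAA marks PiggyBac, 8-bp TSDs mark hAT
#: (CAG-initial TIRs) and P elements, 3-bp TAA/TTA targets mark
#: Pif-Harbinger, and CACT-initial TIRs with short TSDs mark CACTA.
DEFAULT_SIGNATURE_TABLE: tuple[SignatureRule, ...] = (
    SignatureRule("Tc1/mariner", tsd_motifs=("TA",)),
    SignatureRule("PiggyBac", tsd_motifs=("TTAA",)),
    SignatureRule("hAT", tsd_lengths=(8,), tir_prefix="CAG"),
    SignatureRule("P", tsd_lengths=(8,)),
    SignatureRule("Pif-Harbinger", tsd_motifs=("TAA", "TTA")),
    SignatureRule("CACTA", tsd_lengths=(2, 3, 4), tir_prefix="CACT"),
)


def assign_superfamily(candidate: MITECandidate,
                       table: Sequence[SignatureRule] = DEFAULT_SIGNATURE_TABLE
                       ) -> str:
    """Label a candidate (or family centroid) from the signature table.

    Rules are evaluated in order; the first match wins and candidates
    matching no rule are "unclassified".
    """
    tir_start = candidate.sequence[:candidate.tir_length] if candidate.sequence else ""
    for rule in table:
        if rule.matches(candidate.tsd, tir_start):
            return rule.label
    return "unclassified"


def scan_genome(genome: dict[str, str], *, min_tir: int = 10, max_tir: int = 200,
                min_len: int = 50, max_len: int = 800, max_mismatch: int = 2,
                tsd_range: tuple[int, int] = (2, 10), strict_tsd: bool = True,
                refine_boundaries: bool = True,
                exclude: Iterable[tuple[str, int, int]] = (),
                identity_threshold: float = 0.80,
                table: Sequence[SignatureRule] = DEFAULT_SIGNATURE_TABLE,
                ) -> tuple[list[MITECandidate], list[MITEFamily]]:
    """Full structural MITE scan over a genome.

    ``exclude`` suppresses candidates overlapping the given (seq_id,
    start, end) intervals — typically annotated full-length autonomous
    class II copies, whose own TIRs would otherwise be re-reported.
    ``refine_boundaries`` applies TSD-guided boundary refinement (see
    :func:`refine_candidate`); with it off, candidates keep their raw
    maximal-TIR boundaries and are validated by a plain flank comparison.
    Returns validated candidates and their clustered, labelled families.
    """
    excluded = {}
    for seq_id, start, end in exclude:
        excluded.setdefault(seq_id, IntervalTree()).addi(start, end)
    validated: list[MITECandidate] = []
    for seq_id in genome:
        seq = genome[seq_id]
        for cand in find_inverted_repeats(seq, seq_id, min_tir=min_tir,
                                          max_tir=max_tir, min_len=min_len,
                                          max_len=max_len,
                                          max_mismatch=max_mismatch):
            if seq_id in excluded and excluded[seq_id].overlap(cand.start, cand.end):
                continue
            if refine_boundaries:
                got = refine_candidate(cand, seq, k_range=tsd_range,
                                       min_tir=min_tir, min_len=min_len,
                                       max_tir=max_tir,
                                       max_mismatch=max_mismatch,
                                       table=table, strict=strict_tsd)
            else:
                got = validate_tsd(cand, seq, tsd_range, strict_tsd)
            if got is not None:
                validated.append(got)
    families = cluster_mites(validated, identity_threshold)
    for fam in families:
        fam.superfamily = assign_superfamily(fam.centroid, table)
    return validated, families
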