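"""Copy-age estimation from master–slave alignments and family trees.

The age of a TE copy is expressed as raw substitutions per base pair
(p-distance).  Two statistics are produced per family:

* the divergence of each copy from its consensus (the putative ancestral
  sequence) — the per-copy age plotted in repeat landscapes;
* the divergence between the two copies of every *terminal fork* (cherry)
  of the family tree — the age of the most recent transposition events.

Trees are inferred by neighbor joining on p-distances.  Only cherry
membership feeds the age statistic, and NJ cherries agree with
maximum-likelihood cherries on well-separated data, so a full ML search is
not performed; an HKY85-style distance correction (which reduces to the
Kimura two-parameter form under the uniform base frequencies used
throughout) is available behind a flag.

Transposition bursts appear as modes of the age distribution; they are
detected as local maxima of a lightly smoothed histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .alignment import MasterSlaveMSA


@dataclass
class DistanceMatrix:
    """Pairwise p-distances with compared-site counts.

    An entry is *defined* only when the two rows share at least
    ``min_sites`` compared columns; undefined entries are NaN.
    """

    ids: list[str]
    values: np.ndarray  # (n, n) float, NaN where undefined
    sites: np.ndarray   # (n, n) int, compared columns per pair
    min_sites: int = 50

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


@dataclass(frozen=True)
class CherryAge:
    """A terminal-fork copy pair and its substitutions-per-bp age."""

    family_id: str
    copy_a: str
    copy_b: str
    age: float
    sites: int


def _row_array(row: str) -> np.ndarray:
    return np.frombuffer(row.encode(), dtype=np.uint8)


def _compare(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(mismatches, compared sites) excluding columns with '-' or 'N'."""
    bad = (a == ord("-")) | (b == ord("-")) | (a == ord("N")) | (b == ord("N"))
    ok = ~bad
    sites = int(ok.sum())
    mism = int(((a != b) & ok).sum())
    return mism, sites


def p_distance(msa: MasterSlaveMSA, row_i: str, row_j: str,
               min_sites: int = 50) -> tuple[float, int]:
    """Raw substitutions per compared base pair between two MSA rows.

    Columns carrying a gap or an N in either row are excluded.  When fewer
    than ``min_sites`` columns remain the pair is uncomparable and the
    distance is NaN.
    """
    mism, sites = _compare(_row_array(msa.rows[row_i]), _row_array(msa.rows[row_j]))
    if sites < min_sites:
        return float("nan"), sites
    return mism / sites, sites


def _k2p_correct(p: float, q: float) -> float:
    """Kimura two-parameter distance from transition (p) and transversion
    (q) proportions; this is the HKY85 distance under uniform base
    frequencies."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_TRANSITIONS = {(ord("A"), ord("G")), (ord("G"), ord("A")),
                (ord("C"), ord("T")), (ord("T"), ord("C"))}


def pairwise_distances(msa: MasterSlaveMSA, min_sites: int = 50,
                       correction: str = "none") -> DistanceMatrix:
    """All-pairs distance matrix over the MSA rows.

    ``correction='hky'`` applies the HKY85/K2P multiple-hit correction;
    the default is the raw p-distance the age statistic is defined on.
    """
    if correction not in {"none", "hky"}:
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(msa.rows)
    arrays = [_row_array(msa.rows[i]) for i in ids]
    n = len(ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int(((arrays[i] != ord("-")) & (arrays[i] != ord("N"))).sum())
        for j in range(i + 1, n):
            a, b = arrays[i], arrays[j]
            bad = (a == ord("-")) | (b == ord("-")) | (a == ord("N")) | (b == ord("N"))
            ok = ~bad
            ns = int(ok.sum())
            sites[i, j] = sites[j, i] = ns
            if ns < min_sites:
                values[i, j] = values[j, i] = float("nan")
                continue
            diff = (a != b) & ok
            if correction == "hky":
                ts = sum(1 for x, y in zip(a[diff], b[diff])
                         if (int(x), int(y)) in _TRANSITIONS)
                tv = int(diff.sum()) - ts
                d = _k2p_correct(ts / ns, tv / ns)
            else:
                d = int(diff.sum()) / ns
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, sites, min_sites)


def comparable_ids(dm: DistanceMatrix) -> list[str]:
    """Largest usable subset of rows: iteratively drop the row with the
    most undefined pairwise entries until none remain."""
    values = dm.values.copy()
    keep = list(range(len(dm.ids)))
    while True:
        sub = values[np.ix_(keep, keep)]
        undef = np.isnan(sub).sum(axis=1)
        if not undef.any():
            return [dm.ids[k] for k in keep]
        keep.pop(int(np.argmax(undef)))


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree over the comparable rows of the matrix.

    Negative NJ branch lengths are clamped to zero.  A two-copy family
    yields a single edge whose total length equals the pair's distance.
    Raises ``ValueError`` when fewer than two comparable copies remain.
    """
    ids = comparable_ids(dm)
    if len(ids) < 2:
        raise ValueError(
            f"need at least 2 comparable copies, got {len(ids)}"
        )
    if len(ids) == 2:
        d = dm[ids[0], ids[1]]
        a = TreeNode(name=ids[0], length=d / 2.0)
        b = TreeNode(name=ids[1], length=d / 2.0)
        return TreeNode(children=[a, b])
    index = [dm.ids.index(i) for i in ids]
    sub = dm.values[np.ix_(index, index)]
    tree = nj(_SkbioDM(sub, ids), neg_as_zero=True)
    return tree


def terminal_fork_pairs(tree: TreeNode) -> list[tuple[str, str]]:
    """All cherries: leaf pairs whose connecting path crosses exactly one
    internal node.

    For the degenerate three-leaf star every pair qualifies under the path
    definition; only the pair with the smallest summed branch lengths is
    returned so that the number of cherries never exceeds n/2.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        return []
    if len(tips) == 2:
        return [tuple(sorted(t.name for t in tips))]

    # the path between two leaves contains exactly one internal node iff
    # they share a parent, so cherries are parents with two leaf children
    # (three only at the star root of a three-leaf tree)
    pairs: list[tuple[str, str]] = []
    for node in tree.non_tips(include_self=True):
        tips_here = [c for c in node.children if c.is_tip()]
        if len(tips_here) == 2:
            pairs.append(tuple(sorted(t.name for t in tips_here)))
        elif len(tips_here) == 3:  # three-leaf star
            best = min(
                ((x, y) for i, x in enumerate(tips_here) for y in tips_here[i + 1:]),
                key=lambda p: ((p[0].length or 0) + (p[1].length or 0),
                               tuple(sorted((p[0].name, p[1].name)))),
            )
            pairs.append(tuple(sorted(t.name for t in best)))
    return sorted(pairs)


def family_ages(msa: MasterSlaveMSA, dm: DistanceMatrix,
                tree: TreeNode, family_id: str = "",
                method: str = "pairwise") -> tuple[list[CherryAge], list[str]]:
    """One age per terminal fork of the family tree.

    ``method='pairwise'`` (default) takes the raw p-distance between the
    two cherry copies; ``method='branch_sum'`` takes the sum of their two
    terminal branch lengths instead.  Returns the ages plus a log of
    cherries dropped as uncomparable.
    """
    if method not in {"pairwise", "branch_sum"}:
        raise ValueError(f"unknown method {method!r}")
    ages: list[CherryAge] = []
    dropped: list[str] = []
    tip_index = {t.name: t for t in tree.tips()} if method == "branch_sum" else {}
    for a, b in terminal_fork_pairs(tree):
        i, j = dm.ids.index(a), dm.ids.index(b)
        sites = int(dm.sites[i, j])
        if sites < dm.min_sites or np.isnan(dm.values[i, j]):
            dropped.append(f"{a}/{b}: only {sites} compared sites")
            continue
        if method == "branch_sum":
            age = (tip_index[a].length or 0.0) + (tip_index[b].length or 0.0)
        else:
            age = float(dm.values[i, j])
        ages.append(CherryAge(family_id, a, b, age, sites))
    return ages, dropped


def copy_consensus_divergence(msa: MasterSlaveMSA,
                              min_sites: int = 50) -> dict[str, tuple[float, int]]:
    """p-distance of every row against the consensus (ancestral) sequence.

    Same column-exclusion rule as :func:`p_distance`; rows with fewer than
    ``min_sites`` comparable columns get NaN.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    cons = _row_array(msa.consensus)
    out: dict[str, tuple[float, int]] = {}
    for row_id, row in msa.rows.items():
        mism, sites = _compare(cons, _row_array(row))
        out[row_id] = (mism / sites if sites >= min_sites else float("nan"), sites)
    return out


@dataclass
class AgeHistogram:
    """Half-open binning of ages: bin k covers [k*w, (k+1)*w)."""

    bin_width: float
    counts: np.ndarray
    strata: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width


def burst_histogram(ages: Sequence[float], bin_width: float = 0.01,
                    labels: Sequence[str] | None = None,
                    n_bins: int | None = None) -> AgeHistogram:
    """Histogram of ages on half-open divergence bins, optionally
    stratified by superfamily label."""
    ages = np.asarray(list(ages), dtype=float)
    if ages.size and ((ages < 0) | (ages > 1)).any():
        raise ValueError("ages must lie in [0, 1]")
    if n_bins is None:
        top = float(ages.max()) if ages.size else 0.0
        n_bins = max(1, int(np.floor(top / bin_width)) + 1)
    idx = np.minimum(np.floor(ages / bin_width).astype(int), n_bins - 1) \
        if ages.size else np.array([], dtype=int)
    counts = np.bincount(idx, minlength=n_bins)
    hist = AgeHistogram(bin_width, counts)
    if labels is not None:
        labels = list(labels)
        if len(labels) != ages.size:
            raise ValueError("one label per age required")
        for lab in sorted(set(labels)):
            sel = [i for i, l in enumerate(labels) if l == lab]
            hist.strata[lab] = np.bincount(idx[sel], minlength=n_bins)
    return hist


def detect_bursts(hist: AgeHistogram, min_prominence_fraction: float = 0.1,
                  smooth_window: int = 3) -> list[float]:
    """Detect transposition bursts as modes of the age distribution.

    The counts are smoothed with a centered moving average
    (``smooth_window`` bins, zero-padded at the edges); a burst is a
    maximal plateau of the smoothed profile that is strictly higher than
    both neighbours and reaches at least ``min_prominence_fraction`` of
    the global smoothed maximum.  Each plateau reports the raw-count
    argmax bin within it.  Bin centers are returned sorted by recency
    (lowest divergence first).
    """
    counts = hist.counts.astype(float)
    if counts.sum() == 0:
        return []
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(counts, kernel, mode="same")
    threshold = min_prominence_fraction * smooth.max()

    peaks: list[int] = []
    n = smooth.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[j + 1] if j + 1 < n else -np.inf
        if smooth[i] > left and smooth[i] > right and smooth[i] >= threshold:
            segment = counts[i:j + 1]
            peaks.append(i + int(np.argmax(segment)))
        i = j + 1
    return [float((k + 0.5) * hist.bin_width) for k in sorted(peaks)]
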