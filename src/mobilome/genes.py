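"""TE insertion context relative to genes: nearest features, positional
categories, orientation bias tests and the recent-insertion summary.

Each TE copy is related to its nearest gene (minimal edge-to-edge gap,
zero on overlap) and classified into one primary positional category,
evaluated in this order: gene contained in the TE; TE contained in the
gene (sub-typed exonic/intronic); TE overlapping the transcription start
(5') or end (3') coordinate; exact boundary coincidence (one feature
starting exactly where the other ends); "next to" the gene when the gap is
below a threshold (2 kb by default); none otherwise.  5'/3' are
strand-aware: the 5' side is the transcription start side of the gene.

Orientation is sense when TE and gene are annotated on the same strand.
The orientation bias test reports, per category, a Pearson goodness-of-fit
chi-square against a 50:50 sense/antisense split (df 1) and, across
categories, a Pearson independence test on the categories x 2 table
(df = categories - 1).  No multiple-testing correction is applied; the
omnibus test is reported alongside the per-category ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inventory import TECopy
from .io import read_gff

#: primary positional categories, in evaluation order
CATEGORIES = (
    "gene_inside_te",
    "te_inside_gene_exonic",
    "te_inside_gene_intronic",
    "overlap_5prime",
    "overlap_3prime",
    "boundary_gene_start_eq_te_end",
    "boundary_gene_end_eq_te_start",
    "next_to_gene",
    "none",
)


@dataclass
class GeneFeature:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval")
        last = self.start
        for a, b in self.exons:
            if a < self.start or b > self.end or a < last or b <= a:
                raise ValueError(f"{self.gene_id}: exons must be sorted, "
                                 "non-overlapping and inside the gene")
            last = b


def read_gene_gff(path: str | Path) -> list[GeneFeature]:
    """Read gene and Parent-linked exon features from GFF3."""
    genes: dict[str, GeneFeature] = {}
    exons: list[tuple[str, int, int]] = []
    for feat in read_gff(path):
        if feat.type == "gene":
            gid = feat.attributes.get("ID", f"gene@{feat.seq_id}:{feat.start}")
            genes[gid] = GeneFeature(feat.seq_id, feat.start, feat.end,
                                     feat.strand, gid)
        elif feat.type == "exon":
            parent = feat.attributes.get("Parent", "")
            exons.append((parent, feat.start, feat.end))
    for parent, a, b in exons:
        if parent in genes:
            genes[parent].exons.append((a, b))
    out = list(genes.values())
    for g in out:
        g.exons.sort()
        g.validate()
    return out


def _gap(te_start: int, te_end: int, g_start: int, g_end: int) -> int:
    """Unsigned edge-to-edge distance; 0 when the intervals overlap or abut."""
    if te_end <= g_start:
        return g_start - te_end
    if g_end <= te_start:
        return te_start - g_end
    return 0


def nearest_gene(te: TECopy, genes: Sequence[GeneFeature]
                 ) -> list[tuple[GeneFeature, int]]:
    """Nearest gene(s) on the TE's sequence by edge-to-edge gap.

    Returns every gene achieving the minimal gap (ties on both sides are
    all reported); empty when no gene shares the sequence.
    """
    best: list[tuple[GeneFeature, int]] = []
    best_gap: int | None = None
    for g in genes:
        if g.seq_id != te.seq_id:
            continue
        gap = _gap(te.start, te.end, g.start, g.end)
        if best_gap is None or gap < best_gap:
            best, best_gap = [(g, gap)], gap
        elif gap == best_gap:
            best.append((g, gap))
    return best


@dataclass
class InsertionContext:
    te_copy_id: str
    gene_id: str | None
    category: str
    orientation: str  # sense / antisense / undetermined
    gap_distance: int
    recent: bool = False
    excluded: bool = False  # gene-inside-TE cases are flagged, not dropped


def classify_insertion(te: TECopy, gene: GeneFeature | None,
                       near_threshold: int = 2000) -> InsertionContext:
    """Classify one TE-gene relation into its primary positional category."""
    if gene is None:
        return InsertionContext(te.copy_id, None, "none", "undetermined", -1)
    if gene.seq_id != te.seq_id:
        raise ValueError(f"{te.copy_id} and {gene.gene_id} lie on different sequences")
    if te.strand == ".":
        orientation = "undetermined"
    elif gene.strand not in {"+", "-"}:
        orientation = "undetermined"
    else:
        orientation = "sense" if te.strand == gene.strand else "antisense"
    gap = _gap(te.start, te.end, gene.start, gene.end)

    if gene.start >= te.start and gene.end <= te.end:
        # the annotated "TE" swallows the gene whole; kept but flagged for
        # exclusion from orientation statistics
        return InsertionContext(te.copy_id, gene.gene_id, "gene_inside_te",
                                orientation, 0, excluded=True)
    if te.start >= gene.start and te.end <= gene.end:
        exonic = any(te.start < b and a < te.end for a, b in gene.exons)
        cat = "te_inside_gene_exonic" if exonic else "te_inside_gene_intronic"
        return InsertionContext(te.copy_id, gene.gene_id, cat, orientation, 0)
    if te.start < gene.end and gene.start < te.end:  # partial overlap
        tss = gene.start if gene.strand == "+" else gene.end - 1
        tes = gene.end - 1 if gene.strand == "+" else gene.start
        if te.start <= tss < te.end:
            cat = "overlap_5prime"
        elif te.start <= tes < te.end:
            cat = "overlap_3prime"
        else:  # pragma: no cover - unreachable: a partial overlap spans an end
            raise AssertionError("partial overlap covers neither gene end")
        return InsertionContext(te.copy_id, gene.gene_id, cat, orientation, 0)
    if te.end == gene.start:
        return InsertionContext(te.copy_id, gene.gene_id,
                                "boundary_gene_start_eq_te_end", orientation, 0)
    if gene.end == te.start:
        return InsertionContext(te.copy_id, gene.gene_id,
                                "boundary_gene_end_eq_te_start", orientation, 0)
    if 0 < gap < near_threshold:
        return InsertionContext(te.copy_id, gene.gene_id, "next_to_gene",
                                orientation, gap)
    return InsertionContext(te.copy_id, gene.gene_id, "none", orientation, gap)


def classify_all(tes: Sequence[TECopy], genes: Sequence[GeneFeature],
                 near_threshold: int = 2000) -> list[InsertionContext]:
    """Contexts for every TE copy against its nearest gene.

    Nearest-gene ties are broken deterministically towards the gene with
    the smaller start coordinate.
    """
    by_seq: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for lst in by_seq.values():
        lst.sort(key=lambda g: (g.start, g.end))
    out = []
    for te in tes:
        hits = nearest_gene(te, by_seq.get(te.seq_id, []))
        gene = min(hits, key=lambda h: (h[0].start, h[0].gene_id))[0] if hits else None
        out.append(classify_insertion(te, gene, near_threshold))
    return out


@dataclass
class OrientationTest:
    per_category: dict[str, tuple[float, float]]  # category -> (chi2, p), df 1
    omnibus_statistic: float
    omnibus_df: int
    omnibus_p: float
    excluded: list[str] = field(default_factory=list)


def orientation_chi_square(counts: Mapping[str, tuple[int, int]]) -> OrientationTest:
    """Sense/antisense orientation bias tests.

    ``counts`` maps category -> (sense, antisense).  Zero-total categories
    are excluded (and logged).  Per-category: Pearson goodness of fit
    against 50:50, df 1, no continuity correction.  Omnibus: Pearson
    independence test on the k x 2 table, df k-1.
    """
    per: dict[str, tuple[float, float]] = {}
    rows = []
    excluded = []
    for cat, (sense, anti) in counts.items():
        if sense < 0 or anti < 0:
            raise ValueError(f"{cat}: negative count")
        if sense + anti == 0:
            excluded.append(cat)
            continue
        chi2, p = stats.chisquare([sense, anti])
        per[cat] = (float(chi2), float(p))
        rows.append([sense, anti])
    table = np.asarray(rows) if rows else np.empty((0, 2))
    if len(rows) >= 2 and (table.sum(axis=0) > 0).all():
        res = stats.chi2_contingency(table, correction=False)
        omnibus, df, p = float(res.statistic), int(res.dof), float(res.pvalue)
    else:
        omnibus, df, p = float("nan"), 0, float("nan")
    return OrientationTest(per, omnibus, df, p, excluded)


#: mapping of primary categories to the four recent-insertion site groups
_SITE_GROUPS = {
    "next_to_gene": "next_to_genes",
    "te_inside_gene_exonic": "inside_gene_exonic",
    "te_inside_gene_intronic": "inside_gene_intronic",
    "overlap_5prime": "five_prime",
    "overlap_3prime": "three_prime",
}


def recent_insertion_report(contexts: Iterable[InsertionContext],
                            divergences: Mapping[str, float],
                            superfamily_of: Mapping[str, str] | None = None,
                            max_divergence: float = 0.02
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary of recently transposed copies near or inside genes.

    Keeps contexts whose copy diverges strictly less than
    ``max_divergence`` from its family consensus (a copy at exactly the
    threshold is excluded), groups them by superfamily x site category,
    and tabulates sense/antisense totals per site group.  Returns
    (per-superfamily table with a total row, orientation table).
    """
    superfamily_of = superfamily_of or {}
    site_cols = ["next_to_genes", "inside_gene_exonic", "inside_gene_intronic",
                 "five_prime", "three_prime"]
    rows: dict[str, dict[str, int]] = {}
    orient: dict[str, dict[str, int]] = {}
    for ctx in contexts:
        d = divergences.get(ctx.te_copy_id)
        if d is None or not (d < max_divergence):
            continue
        group = _SITE_GROUPS.get(ctx.category)
        if group is None:
            continue
        ctx = InsertionContext(**{**vars(ctx), "recent": True})
        sf = superfamily_of.get(ctx.te_copy_id, "unknown")
        row = rows.setdefault(sf, {c: 0 for c in site_cols} | {"n_sites": 0})
        row[group] += 1
        row["n_sites"] += 1
        o = orient.setdefault(group, {"sense": 0, "antisense": 0})
        if ctx.orientation in o:
            o[ctx.orientation] += 1
    table = pd.DataFrame(
        [{"superfamily": sf, **row} for sf, row in sorted(rows.items())],
        columns=["superfamily", "n_sites"] + site_cols,
    )
    if len(table):
        total = {"superfamily": "total",
                 **{c: int(table[c].sum()) for c in ["n_sites"] + site_cols}}
    else:
        total = {"superfamily": "total", "n_sites": 0,
                 **{c: 0 for c in site_cols}}
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    orientation = pd.DataFrame(
        [{"site": site, **counts} for site, counts in sorted(orient.items())],
        columns=["site", "sense", "antisense"],
    )
    return table, orientation
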