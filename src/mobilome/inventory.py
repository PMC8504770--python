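"""TE copy inventory: annotation parsing, library filters and coverage tables.

Implements the accounting conventions of a REPET-style annotation survey:

* a *full-length copy* (FLC) covers strictly more than 95% of its family
  consensus;
* the filtered consensus library drops SSR consensuses, unclassified
  ("noCat") consensuses built from fewer than 10 copies, and any consensus
  without at least one FLC;
* genome coverage of a group of copies is the length of the *union* of
  their intervals (overlapping fragments counted once), divided by the
  total assembly length (including N runs) for percentages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence


import pandas as pd

from .io import GFFFeature, read_gff, write_gff
from .simulate import CLASS_I_CODES, CLASS_II_CODES

#: classification values that are not TE orders
NON_TE_CLASSIFICATIONS = {"SSR", "noCat", "PHG"}


@dataclass
class TECopy:
    """One annotated TE insertion (0-based half-open interval)."""

    seq_id: str
    start: int
    end: int
    strand: str
    family_id: str
    wicker_code: str
    copy_id: str = ""

    @property
    def copy_length(self) -> int:
        return self.end - self.start


@dataclass
class TEConsensus:
    """Family reference sequence with its classification and copy census."""

    family_id: str
    sequence: str
    classification: str
    copy_count: int = 0
    flc_count: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def te_class(code: str) -> str:
    """Map a Wicker-style order code to 'I', 'II' or 'other'."""
    if code in CLASS_I_CODES or code.startswith("R"):
        return "I"
    if code in CLASS_II_CODES or code.startswith("D") or code.upper().startswith("MITE"):
        return "II"
    return "other"


def read_te_gff(path: str | Path) -> tuple[list[TECopy], list[str]]:
    """Read TE copies from GFF3.

    Returns the copies plus a log of skipped features (those lacking a
    family attribute).  Coordinates are converted from GFF3's 1-based
    inclusive convention to 0-based half-open.
    """
    copies: list[TECopy] = []
    skipped: list[str] = []
    for feat in read_gff(path):
        family = feat.attributes.get("Target", feat.attributes.get("family", ""))
        if family:
            family = family.split()[0]  # GFF3 Target may carry coordinates
        if not family:
            skipped.append(
                f"{feat.seq_id}:{feat.start + 1}-{feat.end}: no family attribute"
            )
            continue
        code = feat.attributes.get("class", feat.attributes.get("classification", ""))
        copies.append(TECopy(feat.seq_id, feat.start, feat.end, feat.strand,
                             family, code, feat.attributes.get("ID", "")))
    return copies, skipped


def write_te_gff(copies: Iterable[TECopy], path: str | Path) -> None:
    feats = [
        GFFFeature(c.seq_id, "mobilome", "match", c.start, c.end, ".",
                   c.strand, ".",
                   {"ID": c.copy_id or f"copy{i + 1}", "Target": c.family_id,
                    "class": c.wicker_code})
        for i, c in enumerate(copies)
    ]
    write_gff(feats, path)


def read_consensus_fasta(path: str | Path) -> list[TEConsensus]:
    """Read a consensus library whose headers carry ``wicker=CODE``."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"wicker=(\S+)", rec.description)
        code = m.group(1) if m else "noCat"
        out.append(TEConsensus(rec.id, str(rec.seq).upper(), code))
    return out


def flag_full_length(copies: Sequence[TECopy],
                     consensus_lengths: Mapping[str, int],
                     threshold: float = 0.95) -> list[bool]:
    """Flag copies covering strictly more than ``threshold`` of their consensus.

    The comparison is exact (no floating-point slack): a copy at exactly
    95% of the consensus length is *not* full length.
    """
    unknown = sorted({c.family_id for c in copies} - set(consensus_lengths))
    if unknown:
        raise KeyError(f"copies reference families with no consensus length: {unknown}")
    frac = Fraction(threshold).limit_denominator(10**6)
    return [
        c.copy_length * frac.denominator > frac.numerator * consensus_lengths[c.family_id]
        for c in copies
    ]


def census(consensuses: Iterable[TEConsensus], copies: Sequence[TECopy],
           threshold: float = 0.95) -> None:
    """Fill copy_count / flc_count on each consensus from the copy table."""
    cons = {c.family_id: c for c in consensuses}
    lengths = {fid: c.length for fid, c in cons.items()}
    known = [c for c in copies if c.family_id in lengths]
    flags = flag_full_length(known, lengths, threshold)
    for c in cons.values():
        c.copy_count = 0
        c.flc_count = 0
    for copy, is_flc in zip(known, flags):
        cons[copy.family_id].copy_count += 1
        cons[copy.family_id].flc_count += int(is_flc)


def filter_consensus_library(
    consensuses: Sequence[TEConsensus],
    min_nocat_copies: int = 10,
) -> tuple[list[TEConsensus], dict[str, list[str]]]:
    """Apply the library filters; returns (kept, per-rule removal log).

    Rules, in order: drop SSR consensuses; drop noCat consensuses generated
    from fewer than ``min_nocat_copies`` copies; drop any consensus without
    a single full-length copy.
    """
    kept: list[TEConsensus] = []
    log: dict[str, list[str]] = {"ssr": [], "nocat_low_copy": [], "no_flc": []}
    for cons in consensuses:
        if cons.classification == "SSR":
            log["ssr"].append(cons.family_id)
        elif cons.classification == "noCat" and cons.copy_count < min_nocat_copies:
            log["nocat_low_copy"].append(cons.family_id)
        elif cons.flc_count == 0:
            log["no_flc"].append(cons.family_id)
        else:
            kept.append(cons)
    return kept, log


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length covered by the union of half-open intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start)


def _group_key(copy: TECopy, group_by: str, anchored: set[str]) -> str:
    if group_by == "class":
        return te_class(copy.wicker_code)
    if group_by == "order":
        return copy.wicker_code or "noCat"
    if group_by == "family":
        return copy.family_id
    if group_by == "chromosome":
        return copy.seq_id if copy.seq_id in anchored else "Un"
    raise ValueError(f"unknown group_by {group_by!r}")


def coverage_table(copies: Sequence[TECopy], genome_lengths: Mapping[str, int],
                   group_by: str = "order", *, union: bool = True,
                   anchored: set[str] | None = None) -> pd.DataFrame:
    """Per-group genome coverage (union bp and percent of assembly).

    ``group_by`` is one of class / order / family / chromosome.  For the
    chromosome grouping, sequences outside ``anchored`` (default: ids not
    starting with "chr") are pooled into an "Un" pseudo-chromosome, the
    usual treatment of scaffolds not anchored to chromosomes.  With
    ``union=False`` raw fragment lengths are summed instead of union-merged.
    """
    unknown = sorted({c.seq_id for c in copies} - set(genome_lengths))
    if unknown:
        raise KeyError(f"copies placed on unknown sequences: {unknown}")
    if anchored is None:
        anchored = {s for s in genome_lengths if s.lower().startswith("chr")}
    genome_size = sum(genome_lengths.values())

    by_group: dict[str, dict[str, list[tuple[int, int]]]] = {}
    n_copies: dict[str, int] = {}
    families: dict[str, set[str]] = {}
    for copy in copies:
        key = _group_key(copy, group_by, anchored)
        by_group.setdefault(key, {}).setdefault(copy.seq_id, []).append(
            (copy.start, copy.end))
        n_copies[key] = n_copies.get(key, 0) + 1
        families.setdefault(key, set()).add(copy.family_id)

    rows = []
    for key in sorted(by_group):
        if union:
            bp = sum(_union_length(iv) for iv in by_group[key].values())
        else:
            bp = sum(e - s for iv in by_group[key].values() for s, e in iv)
        rows.append({
            group_by: key,
            "n_copies": n_copies[key],
            "n_families": len(families[key]),
            "coverage_bp": bp,
            "coverage_percent": 100.0 * bp / genome_size if genome_size else 0.0,
        })
    return pd.DataFrame(rows, columns=[group_by, "n_copies", "n_families",
                                       "coverage_bp", "coverage_percent"])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for report display."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_inventory(per_order: pd.DataFrame,
                        genome_length: int | None = None) -> pd.DataFrame:
    """Aggregate a per-order inventory table into class totals and a grand total.

    ``per_order`` needs columns ``code`` (Wicker order code, or SSR / noCat
    / PHG), ``consensus_count``, ``percent`` and ``bp``; extra columns are
    ignored.  Class percents are recomputed from bp when ``genome_length``
    is given, otherwise summed from the printed per-row percents.
    """
    df = per_order.copy()
    df["te_class"] = [
        "other" if code in NON_TE_CLASSIFICATIONS else te_class(code)
        for code in df["code"]
    ]
    out_rows = []
    for klass in ("I", "II"):
        sub = df[df["te_class"] == klass]
        if sub.empty:
            out_rows.append({"row": f"total_class_{klass}", "consensus_count": 0,
                             "percent": 0.0, "bp": 0})
            continue
        bp = int(sub["bp"].sum())
        if genome_length:
            percent = 100.0 * bp / genome_length
        else:
            percent = float(sub["percent"].sum())
        out_rows.append({"row": f"total_class_{klass}",
                         "consensus_count": int(sub["consensus_count"].sum()),
                         "percent": round_half_up(percent, 2), "bp": bp})
    bp = int(df["bp"].sum())
    if genome_length:
        percent = 100.0 * bp / genome_length
    else:
        percent = float(df["percent"].sum())
    out_rows.append({"row": "total", "consensus_count": int(df["consensus_count"].sum()),
                     "percent": round_half_up(percent, 2), "bp": bp})
    return pd.DataFrame(out_rows, columns=["row", "consensus_count", "percent", "bp"])


def inventory_report(copies: Sequence[TECopy], genome_lengths: Mapping[str, int],
                     consensuses: Sequence[TEConsensus] | None = None
                     ) -> dict[str, pd.DataFrame]:
    """Standard report bundle: per-order, per-class and per-chromosome tables."""
    report = {
        "by_order": coverage_table(copies, genome_lengths, "order"),
        "by_class": coverage_table(copies, genome_lengths, "class"),
        "by_chromosome": coverage_table(copies, genome_lengths, "chromosome"),
        "by_family": coverage_table(copies, genome_lengths, "family"),
    }
    if consensuses is not None:
        per_order = report["by_order"].rename(columns={"order": "code"})
        n_cons = {}
        for cons in consensuses:
            n_cons[cons.classification] = n_cons.get(cons.classification, 0) + 1
        per_order["consensus_count"] = [
            n_cons.get(code, per_order.loc[i, "n_families"])
            for i, code in enumerate(per_order["code"])
        ]
        per_order = per_order.rename(columns={"coverage_percent": "percent",
                                              "coverage_bp": "bp"})
        report["totals"] = aggregate_inventory(
            per_order[["code", "consensus_count", "percent", "bp"]],
            genome_length=sum(genome_lengths.values()),
        )
    return report
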