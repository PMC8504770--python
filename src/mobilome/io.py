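"""FASTA and GFF3 helpers shared by the pipeline stages.

Coordinates are stored internally as 0-based half-open intervals and
converted to/from the 1-based inclusive convention of GFF3 at the file
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_HEADER = "##gff-version 3"


class GFFParseError(ValueError):
    """Raised on a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class GFFFeature:
    seq_id: str
    source: str
    type: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path: str | Path) -> list[GFFFeature]:
    """Parse a GFF3 file into features with 0-based half-open coordinates."""
    features: list[GFFFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            seq_id, source, ftype, start_s, end_s, score, strand, phase, attr_s = fields
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError:
                raise GFFParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise GFFParseError(lineno, f"invalid interval {start}..{end}")
            if strand not in {"+", "-", "."}:
                raise GFFParseError(lineno, f"invalid strand {strand!r}")
            features.append(
                GFFFeature(seq_id, source, ftype, start - 1, end, score, strand, phase,
                           _parse_attributes(attr_s))
            )
    return features


def format_gff_line(feature: GFFFeature) -> str:
    attrs = ";".join(f"{k}={v}" for k, v in feature.attributes.items())
    return "\t".join([
        feature.seq_id, feature.source, feature.type,
        str(feature.start + 1), str(feature.end),
        feature.score, feature.strand, feature.phase, attrs or ".",
    ])


def write_gff(features: Iterable[GFFFeature], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(GFF_HEADER + "\n")
        for feature in features:
            handle.write(format_gff_line(feature) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_records(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, *, wrap: int = 60,
                descriptions: dict[str, str] | None = None) -> None:
    """Write sequences as wrapped FASTA (60 columns by default)."""
    items: Iterator[tuple[str, str]]
    items = sequences.items() if isinstance(sequences, dict) else iter(sequences)
    descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name, seq in items:
            desc = descriptions.get(name, "")
            header = f">{name} {desc}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(seq), wrap):
                handle.write(seq[i:i + wrap] + "\n")


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())
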