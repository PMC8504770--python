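"""Synthetic mobilome generator with known ground truth.

Emulates the layout of a fragmented insect genome assembly: a few
chromosomes plus unplaced scaffolds, transposable-element families of both
classes planted at controlled divergences (so that transposition "bursts"
appear at known positions of the age distribution), internal deletions and
terminal truncations, target-site duplications flanking class II
insertions, short MITE-like elements with terminal inverted repeats, and
genes with exon/intron structure placed at controlled distances and
positions relative to TE copies.

The substitution process is single-hit per site: each consensus position is
substituted at most once, with probability equal to the target divergence,
so the realized proportion of substituted sites is an unbiased estimate of
the target.  This calibrates the generator to the raw
substitutions-per-base-pair statistic used downstream for copy ages, not to
evolutionary time.  Transition/transversion weighting follows HKY85 with
uniform base frequencies (default kappa = 2.0).

All randomness flows from explicit integer seeds; identical specs and seed
produce byte-identical output bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GFFFeature, revcomp, write_fasta, write_gff

WICKER_CODES = {
    # Class I (retrotransposons)
    "RLX",   # LTR retrotransposons
    "RIX",   # LINEs
    "RSX",   # SINEs
    "RPX",   # Penelope-like elements
    "RXX",   # other retrotransposons (e.g. TRIMs)
    # Class II (DNA transposons)
    "DTX",   # TIR elements
    "MITE",  # miniature inverted-repeat elements
    "DHX",   # Helitrons
    "DMX",   # Mavericks
    "DXX",   # other class II
}

CLASS_I_CODES = {"RLX", "RIX", "RSX", "RPX", "RXX"}
CLASS_II_CODES = {"DTX", "MITE", "DHX", "DMX", "DXX"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Positional categories the gene/TE context planner understands.
CONTEXT_CATEGORIES = (
    "next_to_gene",
    "te_inside_gene_exonic",
    "te_inside_gene_intronic",
    "gene_inside_te",
    "overlap_5prime",
    "overlap_3prime",
    "boundary_gene_start_eq_te_end",
    "boundary_gene_end_eq_te_start",
    "none",
)


class SpecError(ValueError):
    """A family/burst/genome specification violates one of its invariants."""


@dataclass(frozen=True)
class FamilySpec:
    """Structural description of one TE family.

    ``tir_length`` > 0 imposes terminal inverted repeats on the consensus
    (class II / MITE anatomy); ``tsd_length`` > 0 makes every planted copy
    of the family flanked by a target-site duplication of that length.
    ``tsd_motif`` fixes the duplicated motif (e.g. ``"TA"`` for
    Tc1/mariner-like targets); if None, each insertion draws a random k-mer.
    """

    family_id: str
    wicker_code: str
    consensus_length: int
    tir_length: int = 0
    tsd_length: int = 0
    tsd_motif: str | None = None

    def validate(self) -> None:
        if self.wicker_code not in WICKER_CODES:
            raise SpecError(f"{self.family_id}: unknown classification code {self.wicker_code!r}")
        if self.consensus_length < 2 * self.tir_length:
            raise SpecError(
                f"{self.family_id}: consensus_length {self.consensus_length} < "
                f"2*tir_length {2 * self.tir_length}"
            )
        if self.tir_length < 0:
            raise SpecError(f"{self.family_id}: negative tir_length")
        if not (0 <= self.tsd_length <= 10):
            raise SpecError(f"{self.family_id}: tsd_length {self.tsd_length} outside [0, 10]")
        if self.tsd_motif is not None and len(self.tsd_motif) != self.tsd_length:
            raise SpecError(f"{self.family_id}: tsd_motif length != tsd_length")
        if self.wicker_code in CLASS_I_CODES and self.tir_length:
            raise SpecError(f"{self.family_id}: class I families carry no TIRs")


@dataclass(frozen=True)
class BurstSpec:
    """One wave of insertions of a family at a common target divergence."""

    family_id: str
    n_copies: int
    target_divergence: float
    deletion_prob: float = 0.0
    deletion_fraction_range: tuple[float, float] = (0.1, 0.5)
    truncation_prob: float = 0.0

    def validate(self) -> None:
        if self.n_copies < 1:
            raise SpecError(f"{self.family_id}: n_copies must be >= 1")
        if not (0.0 <= self.target_divergence < 0.75):
            raise SpecError(
                f"{self.family_id}: target_divergence {self.target_divergence} outside "
                "[0, 0.75) (saturated)"
            )
        lo, hi = self.deletion_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise SpecError(f"{self.family_id}: deletion fractions must lie in (0, 1)")
        for name, p in (("deletion_prob", self.deletion_prob),
                        ("truncation_prob", self.truncation_prob)):
            if not (0.0 <= p <= 1.0):
                raise SpecError(f"{self.family_id}: {name} outside [0, 1]")


@dataclass
class GenomeSpec:
    """Layout of the synthetic assembly.

    ``chromosome_lengths`` defines the anchored chromosomes;
    ``scaffold_lengths`` adds unplaced scaffolds (grouped as the "Un"
    pseudo-chromosome by the inventory stage).  ``te_gene_distance_plan``
    lists ``(category, count)`` pairs of TE-vs-gene placements to plant with
    known context category; remaining copies are placed far (>
    ``far_distance``) from every gene.
    """

    chromosome_lengths: Sequence[int]
    gene_count: int = 0
    exons_per_gene: tuple[int, int] = (1, 4)
    te_gene_distance_plan: Sequence[tuple[str, int]] = ()
    seed: int = 0
    scaffold_lengths: Sequence[int] = ()
    gene_length_range: tuple[int, int] = (600, 2400)
    near_distance: int = 2000
    far_distance: int = 3000
    placement_margin: int | None = None  # default: far_distance
    n_gap_runs: int = 0
    gap_run_length: int = 100

    def validate(self) -> None:
        if not self.chromosome_lengths:
            raise SpecError("at least one chromosome is required")
        for length in list(self.chromosome_lengths) + list(self.scaffold_lengths):
            if length <= 0:
                raise SpecError("all sequence lengths must be positive")
        if self.gene_count < 0:
            raise SpecError("gene_count must be non-negative")
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise SpecError("exons_per_gene range invalid")
        planned = sum(c for _, c in self.te_gene_distance_plan)
        for cat, count in self.te_gene_distance_plan:
            if cat not in CONTEXT_CATEGORIES:
                raise SpecError(f"unknown context category {cat!r}")
            if count < 0:
                raise SpecError("context counts must be non-negative")
        if planned > self.gene_count and any(
            cat != "none" for cat, c in self.te_gene_distance_plan if c
        ):
            raise SpecError("te_gene_distance_plan needs one gene per planted context")


@dataclass
class CopyTruth:
    copy_id: str
    family_id: str
    wicker_code: str
    seq_id: str | None
    start: int | None
    end: int | None
    strand: str | None
    substitutions: int
    true_divergence: float
    deletion_applied: bool
    deletion_length: int
    truncation_applied: bool
    tsd: str
    context_category: str | None = None


@dataclass
class MobilomeBundle:
    """In-memory result of :func:`build_genome`, writable as a file bundle."""

    genome: dict[str, str]
    consensus: dict[str, str]
    families: dict[str, FamilySpec]
    te_features: list[GFFFeature]
    gene_features: list[GFFFeature]
    truth_copies: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_contexts: pd.DataFrame

    def te_copies(self) -> list:
        """The planted copies as inventory TECopy records (no file I/O)."""
        from .inventory import TECopy

        return [TECopy(f.seq_id, f.start, f.end, f.strand,
                       f.attributes["Target"], f.attributes["class"],
                       f.attributes["ID"])
                for f in self.te_features]

    def consensus_records(self) -> list:
        """The family consensuses as inventory TEConsensus records."""
        from .inventory import TEConsensus

        return [TEConsensus(fid, seq, self.families[fid].wicker_code)
                for fid, seq in self.consensus.items()]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "consensus": outdir / "consensus.fa",
            "te_gff": outdir / "te.gff3",
            "gene_gff": outdir / "genes.gff3",
            "truth_copies": outdir / "truth_copies.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_contexts": outdir / "truth_contexts.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_fasta(
            self.consensus, paths["consensus"],
            descriptions={fid: f"wicker={spec.wicker_code}"
                          for fid, spec in self.families.items()},
        )
        write_gff(self.te_features, paths["te_gff"])
        write_gff(self.gene_features, paths["gene_gff"])
        self.truth_copies.to_csv(paths["truth_copies"], sep="\t", index=False)
        self.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth_contexts.to_csv(paths["truth_contexts"], sep="\t", index=False)
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_consensus(spec: FamilySpec, rng_seed: int) -> str:
    """Draw a random consensus sequence honouring the family's TIR anatomy.

    The last ``tir_length`` bases are the reverse complement of the first
    ``tir_length`` bases; the interior is i.i.d. uniform over ACGT.
    """
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    seq = _random_sequence(rng, spec.consensus_length)
    if spec.tir_length > 0:
        t = spec.tir_length
        seq = seq[: spec.consensus_length - t] + revcomp(seq[:t])
    return seq


def evolve_copy(consensus: str, burst: BurstSpec, kappa: float = 2.0,
                rng_seed: int = 0) -> tuple[str, CopyTruth]:
    """Derive one copy from the consensus under the burst's parameters.

    Each site is substituted independently with probability
    ``target_divergence`` (single hit); given a substitution, a transition
    is chosen with probability kappa/(kappa+2) and each transversion with
    probability 1/(kappa+2).  The realized substitution count is recorded
    before any deletion or truncation is applied, so the truth divergence
    refers to the full-length copy.
    """
    if not consensus:
        raise SpecError("consensus must be non-empty")
    if kappa <= 0:
        raise SpecError("kappa must be positive")
    burst.validate()
    rng = np.random.default_rng(rng_seed)
    codes = np.array([_BASE_INDEX[b] for b in consensus], dtype=np.int8)
    L = codes.size

    hit = rng.random(L) < burst.target_divergence
    n_sub = int(hit.sum())
    u = rng.random(L)  # consumed for every site to keep the stream layout fixed
    p_transition = kappa / (kappa + 2.0)
    transition = codes ^ 2  # A<->G, C<->T under the 0..3 = ACGT encoding
    # The two transversion partners of base b are the complements pair.
    tv1 = codes ^ 1
    tv2 = codes ^ 3
    new = np.where(u < p_transition, transition,
                   np.where(u < (1.0 + p_transition) / 2.0, tv1, tv2))
    evolved = np.where(hit, new, codes).astype(np.uint8)
    seq = bytes(_BASES[evolved]).decode()

    deletion_applied = False
    deletion_length = 0
    if burst.deletion_prob and rng.random() < burst.deletion_prob:
        lo, hi = burst.deletion_fraction_range
        frac = rng.uniform(lo, hi)
        deletion_length = int(frac * L)
        if 0 < deletion_length < len(seq):
            start = int(rng.integers(1, len(seq) - deletion_length))
            seq = seq[:start] + seq[start + deletion_length:]
            deletion_applied = True
        else:
            deletion_length = 0
    truncation_applied = False
    if burst.truncation_prob and rng.random() < burst.truncation_prob:
        lo, hi = burst.deletion_fraction_range
        cut = int(rng.uniform(lo, hi) * len(seq))
        if 0 < cut < len(seq):
            seq = seq[cut:] if rng.random() < 0.5 else seq[:-cut]
            truncation_applied = True

    truth = CopyTruth(
        copy_id="", family_id=burst.family_id, wicker_code="",
        seq_id=None, start=None, end=None, strand=None,
        substitutions=n_sub, true_divergence=n_sub / L,
        deletion_applied=deletion_applied, deletion_length=deletion_length,
        truncation_applied=truncation_applied, tsd="",
    )
    return seq, truth


class PlacementError(RuntimeError):
    """No free slot could be found on any sequence after bounded retries."""


class _Placer:
    """Rejection-samples non-overlapping intervals over the assembly."""

    def __init__(self, seq_lengths: dict[str, int], rng: np.random.Generator,
                 margin: int = 1, max_tries: int = 500):
        self.seq_lengths = seq_lengths
        self.rng = rng
        self.margin = margin
        self.max_tries = max_tries
        self.occupied = {name: IntervalTree() for name in seq_lengths}

    def reserve(self, length: int, *, on: str | None = None) -> tuple[str, int]:
        names = [on] if on else list(self.seq_lengths)
        for _ in range(self.max_tries):
            name = names[int(self.rng.integers(0, len(names)))]
            limit = self.seq_lengths[name] - length
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            if not self.occupied[name].overlap(start - self.margin, start + length + self.margin):
                self.occupied[name].addi(start, start + length)
                return name, start
        where = on or "+".join(self.seq_lengths)
        raise PlacementError(
            f"could not place a {length} bp interval on {where} after "
            f"{self.max_tries} tries"
        )


def _layout_exons(rng: np.random.Generator, gene_len: int, n_exons: int) -> list[tuple[int, int]]:
    """Split [0, gene_len) into n_exons exons separated by introns."""
    if n_exons == 1:
        return [(0, gene_len)]
    # 2*n_exons - 1 alternating blocks, each at least 30 bp (or as fits).
    blocks = 2 * n_exons - 1
    min_block = max(10, min(30, gene_len // (2 * blocks)))
    free = gene_len - blocks * min_block
    cuts = np.sort(rng.integers(0, free + 1, size=blocks - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [free]])) + min_block
    exons = []
    pos = 0
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(size)))
        pos += int(size)
    return exons


def build_genome(gspec: GenomeSpec, families: Sequence[FamilySpec],
                 bursts: Sequence[BurstSpec]) -> MobilomeBundle:
    """Assemble the full synthetic bundle from the three spec layers.

    Returns genome, consensus library, TE and gene annotations, and a
    ground-truth record for every emitted feature.  Deterministic: the same
    (specs, seed) yield a byte-identical bundle.
    """
    gspec.validate()
    fam_by_id = {}
    for fam in families:
        fam.validate()
        if fam.family_id in fam_by_id:
            raise SpecError(f"duplicate family id {fam.family_id}")
        fam_by_id[fam.family_id] = fam
    for burst in bursts:
        burst.validate()
        if burst.family_id not in fam_by_id:
            raise SpecError(f"burst references unknown family {burst.family_id}")

    rng = np.random.default_rng(gspec.seed)

    # --- sequences -------------------------------------------------------
    seq_names = [f"chr{i + 1}" for i in range(len(gspec.chromosome_lengths))]
    seq_names += [f"scaffold{i + 1}" for i in range(len(gspec.scaffold_lengths))]
    seq_lengths = dict(zip(seq_names, list(gspec.chromosome_lengths) + list(gspec.scaffold_lengths)))
    genome = {name: np.frombuffer(_random_sequence(rng, n).encode(), dtype=np.uint8).copy()
              for name, n in seq_lengths.items()}

    consensus = {fam.family_id: make_consensus(fam, int(rng.integers(0, 2**31 - 1)))
                 for fam in families}

    # --- evolve copies ---------------------------------------------------
    copies: list[tuple[str, str, CopyTruth]] = []  # (copy_id, sequence, truth)
    counter = 0
    for burst in bursts:
        fam = fam_by_id[burst.family_id]
        for _ in range(burst.n_copies):
            counter += 1
            copy_id = f"{burst.family_id}_c{counter}"
            seq, truth = evolve_copy(consensus[burst.family_id], burst,
                                     rng_seed=int(rng.integers(0, 2**31 - 1)))
            truth.copy_id = copy_id
            truth.wicker_code = fam.wicker_code
            copies.append((copy_id, seq, truth))

    margin = (gspec.placement_margin if gspec.placement_margin is not None
              else gspec.far_distance)
    placer = _Placer(seq_lengths, rng, margin=margin)

    # --- genes -----------------------------------------------------------
    gene_records: list[dict] = []
    gene_features: list[GFFFeature] = []

    def _new_gene(seq_id: str, start: int, length: int) -> dict:
        idx = len(gene_records) + 1
        gene_id = f"gene{idx}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(gspec.exons_per_gene[0], gspec.exons_per_gene[1] + 1))
        exons = [(start + a, start + b) for a, b in _layout_exons(rng, length, n_exons)]
        rec = {"gene_id": gene_id, "seq_id": seq_id, "start": start,
               "end": start + length, "strand": strand, "exons": exons}
        gene_records.append(rec)
        return rec

    def _emit_gene(rec: dict) -> None:
        gene_features.append(GFFFeature(rec["seq_id"], "mobilome_sim", "gene",
                                        rec["start"], rec["end"], ".", rec["strand"], ".",
                                        {"ID": rec["gene_id"]}))
        for i, (a, b) in enumerate(rec["exons"], start=1):
            gene_features.append(GFFFeature(rec["seq_id"], "mobilome_sim", "exon",
                                            a, b, ".", rec["strand"], ".",
                                            {"ID": f"{rec['gene_id']}.e{i}",
                                             "Parent": rec["gene_id"]}))

    # --- planned TE/gene contexts ---------------------------------------
    te_features: list[GFFFeature] = []
    context_rows: list[dict] = []
    plan: list[str] = []
    for cat, count in gspec.te_gene_distance_plan:
        plan.extend([cat] * count)
    if len(plan) > len(copies):
        raise SpecError("te_gene_distance_plan needs one TE copy per planted context")

    def _plant_copy(copy_id: str, seq: str, truth: CopyTruth, seq_id: str,
                    start: int, strand: str, fam: FamilySpec) -> None:
        arr = genome[seq_id]
        planted = revcomp(seq) if strand == "-" else seq
        arr[start:start + len(seq)] = np.frombuffer(planted.encode(), dtype=np.uint8)
        tsd = ""
        if fam.tsd_length > 0:
            tsd = fam.tsd_motif or _random_sequence(rng, fam.tsd_length)
            t = np.frombuffer(tsd.encode(), dtype=np.uint8)
            arr[start - fam.tsd_length:start] = t
            arr[start + len(seq):start + len(seq) + fam.tsd_length] = t
        truth.seq_id = seq_id
        truth.start = start
        truth.end = start + len(seq)
        truth.strand = strand
        truth.tsd = tsd
        te_features.append(GFFFeature(seq_id, "mobilome_sim", "match",
                                      start, start + len(seq), ".", strand, ".",
                                      {"ID": copy_id, "Target": truth.family_id,
                                       "class": truth.wicker_code}))

    gene_len_lo, gene_len_hi = gspec.gene_length_range
    for i, cat in enumerate(plan):
        copy_id, seq, truth = copies[i]
        fam = fam_by_id[truth.family_id]
        te_len = len(seq)
        pad = fam.tsd_length + 2
        gene_len = int(rng.integers(gene_len_lo, gene_len_hi + 1))
        te_strand = "+" if rng.random() < 0.5 else "-"

        if cat == "gene_inside_te":
            gene_len = min(gene_len, max(te_len // 3, 30))
            if te_len < gene_len + 10:
                raise PlacementError(
                    f"{copy_id}: copy too short ({te_len} bp) to contain a gene"
                )
        elif cat in ("te_inside_gene_exonic", "te_inside_gene_intronic"):
            gene_len = max(gene_len, te_len + 200)
        elif cat in ("overlap_5prime", "overlap_3prime"):
            gene_len = max(gene_len, te_len + 120)
        region = gene_len + te_len + gspec.far_distance + 2 * pad + 120
        seq_id, base = placer.reserve(region)
        gstart = base + pad + 60
        if cat == "next_to_gene":
            gap = int(rng.integers(1, gspec.near_distance))
            te_start = gstart + gene_len + gap
            rec = _new_gene(seq_id, gstart, gene_len)
        elif cat == "none":
            te_start = gstart + gene_len + gspec.far_distance
            rec = _new_gene(seq_id, gstart, gene_len)
        elif cat == "te_inside_gene_exonic":
            rec = _new_gene(seq_id, gstart, gene_len)
            rec["exons"] = [(gstart, gstart + gene_len)]  # single-exon gene
            te_start = gstart + int(rng.integers(1, gene_len - te_len - 1))
        elif cat == "te_inside_gene_intronic":
            rec = _new_gene(seq_id, gstart, gene_len)
            # two exons around one intron wide enough for the copy
            half = (gene_len - te_len - 40) // 2
            m1, m2 = gstart + half, gstart + half + te_len + 40
            rec["exons"] = [(gstart, m1), (m2, gstart + gene_len)]
            te_start = m1 + int(rng.integers(1, 40))
        elif cat == "gene_inside_te":
            te_start = gstart
            inner = te_start + int(rng.integers(1, te_len - gene_len - 1))
            rec = _new_gene(seq_id, inner, gene_len)
        elif cat in ("overlap_5prime", "overlap_3prime"):
            rec = _new_gene(seq_id, gstart, gene_len)
            # strand-aware transcription start/end coordinate
            if (cat == "overlap_5prime") == (rec["strand"] == "+"):
                anchor = rec["start"]
                # TE starts left of the gene, covers the start coordinate
                off = int(rng.integers(1, min(te_len - 1, 50)))
                te_start = anchor - off
            else:
                anchor = rec["end"] - 1
                # TE covers the end coordinate and runs past the gene
                off = int(rng.integers(1, min(te_len - 1, 50)))
                te_start = anchor - te_len + 1 + off
        elif cat == "boundary_gene_start_eq_te_end":
            rec = _new_gene(seq_id, gstart + te_len, gene_len)
            te_start = gstart
        elif cat == "boundary_gene_end_eq_te_start":
            rec = _new_gene(seq_id, gstart, gene_len)
            te_start = gstart + gene_len
        else:  # pragma: no cover
            raise SpecError(f"unhandled category {cat}")
        _emit_gene(rec)
        _plant_copy(copy_id, seq, truth, seq_id, te_start, te_strand, fam)
        truth.context_category = cat
        context_rows.append({"copy_id": copy_id, "gene_id": rec["gene_id"],
                             "category": cat})

    # --- free genes ------------------------------------------------------
    for _ in range(gspec.gene_count - len(gene_records)):
        length = int(rng.integers(gene_len_lo, gene_len_hi + 1))
        seq_id, start = placer.reserve(length)
        rec = _new_gene(seq_id, start, length)
        _emit_gene(rec)

    # --- unplanned copies, away from genes -------------------------------
    for copy_id, seq, truth in copies[len(plan):]:
        fam = fam_by_id[truth.family_id]
        pad = fam.tsd_length + 2
        strand = "+" if rng.random() < 0.5 else "-"
        seq_id, base = placer.reserve(len(seq) + 2 * pad)
        _plant_copy(copy_id, seq, truth, seq_id, base + pad, strand, fam)

    # --- optional assembly gaps (runs of N) ------------------------------
    for _ in range(gspec.n_gap_runs):
        seq_id, start = placer.reserve(gspec.gap_run_length)
        genome[seq_id][start:start + gspec.gap_run_length] = ord("N")

    te_features.sort(key=lambda f: (f.seq_id, f.start, f.end))
    gene_features.sort(key=lambda f: (f.seq_id, f.start, f.end, f.type != "gene"))

    truth_copies = pd.DataFrame(
        [{k: v for k, v in vars(t).items() if k != "context_category"}
         for _, _, t in copies]
    )
    truth_genes = pd.DataFrame(
        [{"gene_id": r["gene_id"], "seq_id": r["seq_id"], "start": r["start"],
          "end": r["end"], "strand": r["strand"],
          "exons": ";".join(f"{a}-{b}" for a, b in r["exons"])}
         for r in gene_records]
    )
    truth_contexts = pd.DataFrame(context_rows, columns=["copy_id", "gene_id", "category"])

    return MobilomeBundle(
        genome={name: bytes(arr).decode() for name, arr in genome.items()},
        consensus=consensus,
        families=fam_by_id,
        te_features=te_features,
        gene_features=gene_features,
        truth_copies=truth_copies,
        truth_genes=truth_genes,
        truth_contexts=truth_contexts,
    )
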