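"""End-to-end orchestration of the mobilome analysis stages.

Each stage is re-runnable from the previous stage's files; ``run_pipeline``
chains them and writes the full report bundle.  Every report carries the
hash of the configuration that produced it, and reruns with identical
inputs and configuration are byte-identical (the analysis stages consume
no randomness; only the synthetic generator is seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path


import pandas as pd

from . import ages as ages_mod
from . import genes as genes_mod
from . import inventory as inv_mod
from . import mites as mites_mod
from .alignment import ScoringScheme, filter_copies_by_length, global_align, stack_alignments
from .io import read_fasta, revcomp

log = logging.getLogger("mobilome")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the pipeline.

    The defaults are the survey's printed thresholds: full-length copies
    cover more than 95% of their consensus, only copies longer than 100 bp
    are aligned for age estimation, ages are binned at 1% divergence,
    copies under 2% divergence count as recent, and "near" a gene means
    within 2 kb.
    """

    genome: str = ""
    te_gff: str = ""
    gene_gff: str = ""
    consensus: str = ""
    outdir: str = "mobilome_out"
    flc_threshold: float = 0.95
    min_copy_length: int = 100
    min_sites: int = 50
    age_bin_width: float = 0.01
    recency_threshold: float = 0.02
    near_threshold: int = 2000
    min_nocat_copies: int = 10
    mite_min_tir: int = 10
    mite_max_tir: int = 200
    mite_min_len: int = 50
    mite_max_len: int = 800
    mite_max_mismatch: int = 2
    mite_strict_tsd: bool = True
    scoring: tuple[float, float, float, float] = (1.0, -1.0, -4.0, -1.0)
    seed: int = 0

    def config_hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# mobilome-config: {config_hash}\n")
        df.to_csv(handle, sep="\t", index=False)


def _write_json(obj, path: Path, config_hash: str) -> None:
    with open(path, "w") as handle:
        json.dump({"config": config_hash, **obj}, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _load_inputs(config: PipelineConfig):
    try:
        genome = read_fasta(config.genome)
    except (OSError, ValueError) as exc:
        raise StageError("inputs", f"cannot read genome FASTA: {exc}") from exc
    try:
        copies, skipped = inv_mod.read_te_gff(config.te_gff)
    except (OSError, ValueError) as exc:
        raise StageError("inputs", f"cannot read TE GFF3: {exc}") from exc
    consensuses = None
    if config.consensus:
        try:
            consensuses = inv_mod.read_consensus_fasta(config.consensus)
        except (OSError, ValueError) as exc:
            raise StageError("inputs", f"cannot read consensus FASTA: {exc}") from exc
    genes = None
    if config.gene_gff:
        try:
            genes = genes_mod.read_gene_gff(config.gene_gff)
        except (OSError, ValueError) as exc:
            raise StageError("inputs", f"cannot read gene GFF3: {exc}") from exc
    return genome, copies, skipped, consensuses, genes


def stage_inventory(copies, genome, consensuses, config: PipelineConfig):
    try:
        report = inv_mod.inventory_report(
            copies, {k: len(v) for k, v in genome.items()}, consensuses)
    except KeyError as exc:
        raise StageError("te_inventory", str(exc)) from exc
    filter_log = {}
    if consensuses is not None:
        inv_mod.census(consensuses, copies, config.flc_threshold)
        kept, removal_log = inv_mod.filter_consensus_library(
            consensuses, config.min_nocat_copies)
        filter_log = {"kept": [c.family_id for c in kept], **removal_log}
    return report, filter_log


def stage_ages(copies, genome, consensuses, config: PipelineConfig):
    """Align each family's copies to its consensus and estimate ages."""
    scoring = ScoringScheme(*config.scoring)
    by_family: dict[str, list] = {}
    for copy in copies:
        by_family.setdefault(copy.family_id, []).append(copy)
    cons_by_id = {c.family_id: c for c in (consensuses or [])}

    cherry_rows, div_rows, skip_log = [], [], []
    for family_id in sorted(by_family):
        cons = cons_by_id.get(family_id)
        if cons is None:
            skip_log.append(f"{family_id}: no consensus sequence")
            continue
        kept = filter_copies_by_length(by_family[family_id], config.min_copy_length)
        if not kept:
            skip_log.append(f"{family_id}: no copies above "
                            f"{config.min_copy_length} bp")
            continue
        alignments = []
        for copy in kept:
            seq = genome[copy.seq_id][copy.start:copy.end]
            if copy.strand == "-":
                seq = revcomp(seq)
            aln = global_align(cons.sequence, seq, scoring)
            aln.slave_id = copy.copy_id or f"{family_id}@{copy.seq_id}:{copy.start}"
            alignments.append(aln)
        msa = stack_alignments(family_id, cons.sequence, alignments)
        for copy_id, (div, sites) in ages_mod.copy_consensus_divergence(
                msa, config.min_sites).items():
            div_rows.append({"copy_id": copy_id, "family_id": family_id,
                             "wicker_code": cons.classification,
                             "divergence": div, "sites": sites})
        dm = ages_mod.pairwise_distances(msa, config.min_sites)
        try:
            tree = ages_mod.build_tree(dm)
        except ValueError as exc:
            skip_log.append(f"{family_id}: {exc}")
            continue
        cherry_ages, dropped = ages_mod.family_ages(msa, dm, tree, family_id)
        skip_log.extend(f"{family_id}: {d}" for d in dropped)
        for ca in cherry_ages:
            cherry_rows.append({"family_id": ca.family_id, "copy_a": ca.copy_a,
                                "copy_b": ca.copy_b, "age": ca.age,
                                "sites": ca.sites,
                                "wicker_code": cons.classification})

    cherry_df = pd.DataFrame(cherry_rows, columns=["family_id", "copy_a", "copy_b",
                                                   "age", "sites", "wicker_code"])
    div_df = pd.DataFrame(div_rows, columns=["copy_id", "family_id", "wicker_code",
                                             "divergence", "sites"])
    usable = div_df.dropna(subset=["divergence"])
    hist = ages_mod.burst_histogram(usable["divergence"].to_numpy(),
                                    config.age_bin_width,
                                    labels=usable["wicker_code"].tolist())
    peaks = {
        "consensus_divergence_peaks": ages_mod.detect_bursts(hist),
        "cherry_age_peaks": ages_mod.detect_bursts(
            ages_mod.burst_histogram(cherry_df["age"].dropna().to_numpy(),
                                     config.age_bin_width)),
    }
    return cherry_df, div_df, hist, peaks, skip_log


def stage_mites(genome, config: PipelineConfig, exclude=()):
    candidates, families = mites_mod.scan_genome(
        genome, min_tir=config.mite_min_tir, max_tir=config.mite_max_tir,
        min_len=config.mite_min_len, max_len=config.mite_max_len,
        max_mismatch=config.mite_max_mismatch,
        strict_tsd=config.mite_strict_tsd, exclude=exclude)
    return candidates, families


#: Table-2-style grouping of primary categories for orientation testing
ORIENTATION_GROUPS = {
    "next_to_gene": "next_to_gene",
    "te_inside_gene_exonic": "te_inside_gene",
    "te_inside_gene_intronic": "te_inside_gene",
    "gene_inside_te": "gene_inside_te",
    "overlap_5prime": "five_prime_region",
    "overlap_3prime": "three_prime_region",
}


def orientation_counts_from_contexts(contexts) -> dict[str, tuple[int, int]]:
    counts: dict[str, list[int]] = {}
    for ctx in contexts:
        group = ORIENTATION_GROUPS.get(ctx.category)
        if group is None or ctx.orientation == "undetermined":
            continue
        pair = counts.setdefault(group, [0, 0])
        pair[0 if ctx.orientation == "sense" else 1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def stage_gene_context(copies, genes, div_df, config: PipelineConfig):
    contexts = genes_mod.classify_all(copies, genes, config.near_threshold)
    counts = orientation_counts_from_contexts(contexts)
    test = genes_mod.orientation_chi_square(counts) if len(counts) >= 2 else None
    divergences = {r.copy_id: r.divergence for r in div_df.itertuples()
                   if pd.notna(r.divergence)}
    superfamily = {r.copy_id: r.wicker_code for r in div_df.itertuples()}
    recent, recent_orient = genes_mod.recent_insertion_report(
        contexts, divergences, superfamily, config.recency_threshold)
    return contexts, counts, test, recent, recent_orient


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every applicable stage and write the report bundle."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    outputs: dict[str, Path] = {}

    genome, copies, skipped, consensuses, genes = _load_inputs(config)
    log.info("inputs loaded in %.1fs (%d sequences, %d TE copies)",
             time.time() - t0, len(genome), len(copies))

    t = time.time()
    report, filter_log = stage_inventory(copies, genome, consensuses, config)
    for name, df in report.items():
        path = outdir / f"inventory_{name}.tsv"
        _write_tsv(df, path, h)
        outputs[f"inventory_{name}"] = path
    _write_json({"skipped_features": skipped, "library_filter": filter_log},
                outdir / "inventory_log.json", h)
    outputs["inventory_log"] = outdir / "inventory_log.json"
    log.info("te_inventory done in %.1fs", time.time() - t)

    if consensuses is not None:
        t = time.time()
        cherry_df, div_df, hist, peaks, skip_log = stage_ages(
            copies, genome, consensuses, config)
        _write_tsv(cherry_df, outdir / "cherry_ages.tsv", h)
        _write_tsv(div_df, outdir / "consensus_divergence.tsv", h)
        hist_df = pd.DataFrame({
            "bin_start": hist.edges[:-1], "bin_end": hist.edges[1:],
            "count": hist.counts,
            **{f"count_{lab}": c for lab, c in hist.strata.items()},
        })
        _write_tsv(hist_df, outdir / "age_histogram.tsv", h)
        _write_json({**peaks, "skipped": skip_log},
                    outdir / "burst_peaks.json", h)
        outputs.update({
            "cherry_ages": outdir / "cherry_ages.tsv",
            "consensus_divergence": outdir / "consensus_divergence.tsv",
            "age_histogram": outdir / "age_histogram.tsv",
            "burst_peaks": outdir / "burst_peaks.json",
        })
        log.info("age_estimation done in %.1fs", time.time() - t)
    else:
        div_df = pd.DataFrame(columns=["copy_id", "family_id", "wicker_code",
                                       "divergence", "sites"])

    t = time.time()
    candidates, mite_families = stage_mites(genome, config)
    cand_df = pd.DataFrame(
        [{"seq_id": c.seq_id, "start": c.start, "end": c.end,
          "tir_length": c.tir_length, "tir_mismatches": c.tir_mismatches,
          "tsd": c.tsd} for c in candidates])
    fam_df = pd.DataFrame(
        [{"family_id": f.family_id, "size": f.size,
          "superfamily": f.superfamily, "tsd": f.centroid.tsd,
          "tir_length": f.centroid.tir_length} for f in mite_families])
    _write_tsv(cand_df, outdir / "mite_candidates.tsv", h)
    _write_tsv(fam_df, outdir / "mite_families.tsv", h)
    outputs["mite_candidates"] = outdir / "mite_candidates.tsv"
    outputs["mite_families"] = outdir / "mite_families.tsv"
    log.info("mite_finder done in %.1fs (%d candidates, %d families)",
             time.time() - t, len(candidates), len(mite_families))

    if genes is not None:
        t = time.time()
        contexts, counts, test, recent, recent_orient = stage_gene_context(
            copies, genes, div_df, config)
        ctx_df = pd.DataFrame([vars(c) for c in contexts])
        _write_tsv(ctx_df, outdir / "insertion_contexts.tsv", h)
        payload = {"counts": {k: list(v) for k, v in counts.items()}}
        if test is not None:
            payload["per_category"] = {k: list(v)
                                       for k, v in test.per_category.items()}
            payload["omnibus"] = {"statistic": test.omnibus_statistic,
                                  "df": test.omnibus_df, "p": test.omnibus_p}
        _write_json(payload, outdir / "orientation_tests.json", h)
        _write_tsv(recent, outdir / "recent_insertions.tsv", h)
        _write_tsv(recent_orient, outdir / "recent_orientation.tsv", h)
        outputs.update({
            "insertion_contexts": outdir / "insertion_contexts.tsv",
            "orientation_tests": outdir / "orientation_tests.json",
            "recent_insertions": outdir / "recent_insertions.tsv",
            "recent_orientation": outdir / "recent_orientation.tsv",
        })
        log.info("gene_context done in %.1fs", time.time() - t)

    log.info("pipeline complete in %.1fs", time.time() - t0)
    return outputs
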