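"""Canonical synthetic study designs.

These presets freeze the simulation conditions used throughout the test
suite and the reproduction script, so that every consumer runs the same
experiment:

* ``two_burst_mobilome`` — the burst-dating design: TE families whose
  copies were planted in two transposition waves, a recent one at 2%
  divergence and an ancient one at 20%, mirroring the two activity peaks
  reported for the Hessian fly mobilome.
* ``mite_recall_genome`` — perfect MITE plants (intact TIRs, clean TSDs)
  for scanner recall measurements: Tc1/mariner-like elements with TA
  targets and P/hAT-like elements with 8-bp targets.
* ``context_plan_genome`` — genes plus TE copies planted at controlled
  positions relative to them, one per positional category.
"""

from __future__ import annotations

from .simulate import BurstSpec, FamilySpec, GenomeSpec

#: the two activity waves, as substitutions per bp from the consensus
RECENT_BURST = 0.02
ANCIENT_BURST = 0.20


def two_burst_mobilome(seed: int, n_families: int = 10,
                       copies_per_family: int = 30,
                       consensus_length: int = 1000,
                       divergences: tuple[float, float] = (RECENT_BURST,
                                                           ANCIENT_BURST),
                       ) -> tuple[GenomeSpec, list[FamilySpec], list[BurstSpec]]:
    """Families split between a recent and an ancient transposition wave.

    Each family contributes half its copies to each wave.  Class I and
    class II families alternate (class II carrying TA target-site
    duplications); copies are full length so that every copy's realized
    divergence estimates its wave's age.
    """
    families: list[FamilySpec] = []
    bursts: list[BurstSpec] = []
    half = copies_per_family // 2
    for i in range(n_families):
        if i % 2 == 0:
            fam = FamilySpec(f"fam{i + 1}", "DTX", consensus_length,
                             tir_length=25, tsd_length=2, tsd_motif="TA")
        else:
            fam = FamilySpec(f"fam{i + 1}", "RLX", consensus_length)
        families.append(fam)
        bursts.append(BurstSpec(fam.family_id, half, divergences[0]))
        bursts.append(BurstSpec(fam.family_id, copies_per_family - half,
                                divergences[1]))
    n_copies = n_families * copies_per_family
    # room for every copy plus spacing; placement margin kept small since
    # no gene-context guarantees are needed here
    genome_bp = int(n_copies * consensus_length * 2.5)
    gspec = GenomeSpec(
        chromosome_lengths=[genome_bp // 2, genome_bp // 2],
        gene_count=0, seed=seed, placement_margin=20,
    )
    return gspec, families, bursts


def mite_recall_genome(seed: int, n_ta: int = 3, n_8mer: int = 2,
                       ) -> tuple[GenomeSpec, list[FamilySpec], list[BurstSpec]]:
    """One genome of the MITE recall sweep: perfect plants only.

    Plants are spaced beyond the scanner's maximum element length so that
    two identical copies can never be bridged by a single spurious
    inverted repeat.
    """
    families = [
        FamilySpec("mite_ta", "MITE", 300, tir_length=20, tsd_length=2,
                   tsd_motif="TA"),
        FamilySpec("mite_p", "MITE", 400, tir_length=25, tsd_length=8),
    ]
    bursts = [BurstSpec("mite_ta", n_ta, 0.0), BurstSpec("mite_p", n_8mer, 0.0)]
    gspec = GenomeSpec(chromosome_lengths=[15000, 15000], seed=seed,
                       placement_margin=900)
    return gspec, families, bursts


def context_plan_genome(seed: int, per_category: int = 1,
                        ) -> tuple[GenomeSpec, list[FamilySpec], list[BurstSpec]]:
    """Genes with TE copies planted at every positional category."""
    from .simulate import CONTEXT_CATEGORIES

    plan = [(cat, per_category) for cat in CONTEXT_CATEGORIES]
    n = len(CONTEXT_CATEGORIES) * per_category
    families = [
        FamilySpec("ctxA", "DTX", 500, tir_length=20, tsd_length=2,
                   tsd_motif="TA"),
        FamilySpec("ctxB", "RLX", 700),
    ]
    bursts = [BurstSpec("ctxA", (n + 1) // 2, 0.01),
              BurstSpec("ctxB", n // 2, 0.05)]
    gspec = GenomeSpec(
        chromosome_lengths=[140000 * per_category, 140000 * per_category],
        gene_count=n + 4, te_gene_distance_plan=plan, seed=seed,
        scaffold_lengths=[40000],
    )
    return gspec, families, bursts
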