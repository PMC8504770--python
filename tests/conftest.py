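"""Shared fixtures: small synthetic bundles built once per session."""

from __future__ import annotations

import pytest

from mobilome.presets import context_plan_genome, mite_recall_genome
from mobilome.simulate import (BurstSpec, FamilySpec, GenomeSpec,
                               build_genome)


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small mixed bundle: three TE families, a handful of genes and a
    few planted gene contexts, on two chromosomes plus one scaffold."""
    families = [
        FamilySpec("dtxA", "DTX", 800, tir_length=20, tsd_length=2,
                   tsd_motif="TA"),
        FamilySpec("rlxA", "RLX", 1200),
        FamilySpec("miteA", "MITE", 300, tir_length=18, tsd_length=8),
    ]
    bursts = [
        BurstSpec("dtxA", 6, 0.02),
        BurstSpec("rlxA", 5, 0.10, deletion_prob=0.4),
        BurstSpec("miteA", 5, 0.05),
    ]
    gspec = GenomeSpec(
        chromosome_lengths=[60000, 60000],
        scaffold_lengths=[15000],
        gene_count=6,
        te_gene_distance_plan=[("next_to_gene", 1),
                               ("te_inside_gene_exonic", 1),
                               ("none", 1)],
        seed=42,
    )
    return build_genome(gspec, families, bursts)


@pytest.fixture(scope="session")
def tiny_bundle_dir(tiny_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = tiny_bundle.write(outdir)
    return paths


@pytest.fixture(scope="session")
def context_bundle():
    """One TE copy planted at every positional category, with free genes."""
    gspec, families, bursts = context_plan_genome(seed=3)
    return build_genome(gspec, families, bursts)


@pytest.fixture(scope="session")
def recall_bundles():
    """Ten genomes of perfect MITE plants (the scanner recall sweep)."""
    bundles = []
    for seed in range(10):
        gspec, families, bursts = mite_recall_genome(seed)
        bundles.append(build_genome(gspec, families, bursts))
    return bundles
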