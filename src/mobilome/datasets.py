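"""Bundled reference tables from the published Hessian fly mobilome survey.

These are the printed summary tables of the *Mayetiola destructor* genome
annotation (global TE inventory over the two annotation rounds, TE-vs-gene
orientation counts, and recent-insertion counts per superfamily).  They are
inputs for arithmetic checks and worked examples, not outputs of this
package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("mobilome.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def te_inventory_table() -> pd.DataFrame:
    """Per-order TE inventory of the M. destructor assembly.

    Columns: round ('all' = every copy, 'flc' = full-length-copy library),
    code (Wicker order code or SSR/noCat/PHG), order, consensus_count,
    percent (of the 153 Mb assembly), bp.
    """
    return _load("mdes_te_inventory.tsv")


def orientation_counts() -> pd.DataFrame:
    """Sense/antisense TE insertion counts per gene-relative position."""
    return _load("mdes_orientation_counts.tsv")


def recent_insertion_counts() -> pd.DataFrame:
    """Insertion-site counts per superfamily for copies < 2% diverged."""
    return _load("mdes_recent_insertions.tsv")
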