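"""Packaged example data: the 14-lineage thrush statistics table and a tree.

The statistics table carries the published per-lineage PSMC summaries
for 8 seasonally migratory and 6 resident thrush lineages and is the
canonical input for table-mode runs.  The accompanying 14-taxon tree is
a SYNTHETIC stand-in: the study clade's published topology is not
redistributable here, so the tree encodes only the structural
constraints known for the group (the two within-species lineage pairs,
C. occidentalis sister to C. guttatus, Hylocichla sister to the rest)
and is suitable for exercising the phylogenetic-signal screen, not for
inference about the real clade.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

from paleopop.psmc_io import parse_newick


def _data_text(name: str) -> str:
    return (resources.files("paleopop") / "data" / name).read_text(encoding="utf-8")


def load_thrush_stats() -> pd.DataFrame:
    """The per-lineage statistics table (Ne columns in units of 1e4)."""
    import io

    return pd.read_csv(io.StringIO(_data_text("thrush_stats.tsv")), sep="\t", comment="#")


def load_thrush_tree() -> dendropy.Tree:
    """Synthetic stand-in topology over the 14 packaged lineages."""
    return parse_newick(_data_text("thrush_tree_synthetic.nwk"))
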