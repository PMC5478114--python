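"""Bundled signature definitions.

Ships the 17-gene HTICS prognostic signature for HER2+:ERα− breast
cancer (8 up-regulated and 9 down-regulated genes across five
pathways), the Core1/Core2/Core subsets extracted from its
sub-signature combination analysis, the five-gene HER2 amplicon list,
and a table of documented substitute genes.  The substitute table is
partial: it contains only pairs with a published annotation, so it does
not cover all 17 genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import GeneSignature, read_signature


def _data_path(name: str):
    return resources.files("sigcore").joinpath("data", name)


def _load_signature(name: str, label: str) -> GeneSignature:
    with resources.as_file(_data_path(name)) as p:
        return read_signature(p, name=label)


def load_htics() -> GeneSignature:
    """The 17-gene HTICS signature (8 up, 9 down, 5 pathways)."""
    return _load_signature("htics.tsv", "HTICS")


def load_core1() -> GeneSignature:
    """Core1: 8 genes extracted from all significant sub-signatures."""
    return _load_signature("core1.tsv", "Core1")


def load_core2() -> GeneSignature:
    """Core2: 8 genes extracted from the top-performing sub-signatures."""
    return _load_signature("core2.tsv", "Core2")


def load_core() -> GeneSignature:
    """The 6-gene Core (= Core1 ∩ Core2)."""
    return _load_signature("core.tsv", "Core")


def load_amplicon_genes() -> list[str]:
    """The five co-amplified HER2 amplicon genes."""
    with resources.as_file(_data_path("amplicon_genes.tsv")) as p:
        return list(pd.read_csv(p, sep="\t")["gene"])


def load_substitutes() -> pd.DataFrame:
    """Documented substitute pairs (partial; see module docstring).

    Columns: gene, substitute, substitute_pathway, same_pathway (0/1),
    role (``ffpe_backup`` for the four FFPE replacements,
    ``same_pathway`` / ``top_correlate`` otherwise).
    """
    with resources.as_file(_data_path("substitutes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def htics_m() -> GeneSignature:
    """HTICSm: HTICS with its four weak-FFPE genes replaced.

    Npy→Spink5, Ccr2→Ctss, CD180→Aim2, CD72→CD48; substitutes inherit
    the replaced gene's direction.
    """
    from .substitution import apply_substitution, substitution_map_from_table

    subs = load_substitutes()
    subs = subs[subs["role"] == "ffpe_backup"]
    return apply_substitution(
        load_htics(),
        substitution_map_from_table(subs),
        genes_to_replace=list(subs["gene"]),
        name="HTICSm",
    )
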