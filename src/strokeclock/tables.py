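"""Loaders for the transcribed published candidate tables shipped with
the package (literature biomarker list, the surgery/anesthesia up/down
lists, the human->rat mapping, and the top-20 time-responsive genes)."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_RANKINGS = {
    "literature": "candidate_ranking_literature.tsv",
    "stroke_up": "candidate_ranking_stroke_up.tsv",
    "stroke_down": "candidate_ranking_stroke_down.tsv",
}


def _path(name: str):
    return resources.files("strokeclock.data").joinpath(name)


def load_candidate_biomarkers() -> pd.DataFrame:
    """Literature stroke-biomarker candidates (human nomenclature).

    The source table prints 74 entries of which two (BNP and Nt-proBNP)
    resolve to the same gene (NPPB); downstream alias resolution
    deduplicates to the 73 distinct candidates.
    """
    with _path("candidate_biomarkers.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


def load_mapping() -> pd.DataFrame:
    """Static human-candidate-name -> rat-gene mapping table."""
    with _path("human_rat_mapping.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_candidate_ranking(which: str = "literature") -> pd.DataFrame:
    """A transcribed printed ranking: columns gene, p, rank, probe_id.

    'NS' / blank p entries come back as NaN (not significant). Returned
    indexed by gene name, suitable for ``locate_in_ranking``.
    """
    if which not in _RANKINGS:
        raise KeyError(f"unknown ranking {which!r}; choose from {sorted(_RANKINGS)}")
    with _path(_RANKINGS[which]).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df["p"] = pd.to_numeric(df["p"].replace("NS", np.nan), errors="coerce")
    df["rank"] = pd.to_numeric(df["rank"], errors="coerce")
    return df.set_index("gene")


def load_top20() -> pd.DataFrame:
    """The 20 most time-responsive genes with their printed p-values."""
    with _path("top20_time_responsive.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"p": float, "probe_id": str, "gene": str})
    return df.set_index("gene")
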