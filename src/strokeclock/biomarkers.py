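"""Cross-ranking of external candidate biomarker lists.

Locates literature candidate genes (human nomenclature) inside the
pipeline's moderated-F ranking via a static human->rat mapping table,
counts how many clear the significance cutoff, and computes the
condition-specificity set partition (Venn logic) between two
up/down-regulated gene list pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UserInputError

DEFAULT_ALPHA = 5e-7


def _norm(name: str) -> str:
    return str(name).strip().casefold()


def resolve_aliases(candidates: pd.DataFrame) -> pd.DataFrame:
    """Resolve each candidate to its current name and drop duplicates.

    ``candidates`` columns: name, alt_name (optional), plus any carried
    metadata. The resolved name is alt_name when given, else name.
    Entries resolving to the same name are merged (first row wins, source
    tags concatenated when a ``source`` column exists).
    """
    out = candidates.copy()
    alt = out.get("alt_name")
    if alt is None:
        out["resolved"] = out["name"]
    else:
        out["resolved"] = np.where(alt.fillna("").astype(str).str.strip() != "",
                                   alt, out["name"])
    out["_key"] = out["resolved"].map(_norm)
    if "source" in out.columns:
        merged_src = out.groupby("_key", sort=False)["source"].agg(
            lambda s: ";".join(dict.fromkeys(str(v) for v in s if pd.notna(v)))
        )
        out = out.drop_duplicates("_key", keep="first")
        out["source"] = out["_key"].map(merged_src)
    else:
        out = out.drop_duplicates("_key", keep="first")
    return out.drop(columns="_key").reset_index(drop=True)


def map_candidates(
    candidates: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate candidates to internal (rat) gene IDs via the mapping table.

    Name comparison is case-insensitive and runs on the alias-resolved
    name. One candidate may map to several internal genes (one output
    row each, provenance kept). Returns (mapped, unmatched).
    """
    cand = resolve_aliases(candidates)
    if mapping.empty and not cand.empty:
        import warnings
        warnings.warn("empty mapping table: all candidates unmatched", stacklevel=2)
        return cand.iloc[0:0].assign(internal=[], kind=[]), cand
    mp = mapping.copy()
    mp["_key"] = mp["external"].map(_norm)
    if mp.duplicated(["_key", "internal"]).any():
        dup = mp[mp.duplicated(["_key", "internal"], keep=False)]
        raise UserInputError(
            f"mapping table has duplicate rows for {sorted(set(dup['external']))[:3]}"
        )
    cand["_key"] = cand["resolved"].map(_norm)
    joined = cand.merge(mp[["_key", "internal", "kind"]], on="_key", how="left")
    mapped = joined[joined["internal"].notna()].drop(columns="_key").reset_index(drop=True)
    unmatched = (
        joined[joined["internal"].isna()]
        .drop(columns=["_key", "internal", "kind"])
        .reset_index(drop=True)
    )
    return mapped, unmatched


def locate_in_ranking(mapped: pd.DataFrame, ranking: pd.DataFrame) -> pd.DataFrame:
    """Annotate mapped candidates with their rank and p in the ranking.

    ``ranking`` is indexed by gene with ``p`` and (optionally) ``rank``
    columns; internal IDs absent from it are flagged not-significant
    style (p = NaN, ``in_ranking`` False) rather than dropped.
    """
    rk = ranking.copy()
    rk.index = rk.index.map(_norm)
    if "rank" not in rk.columns:
        rk = rk.iloc[np.lexsort((rk.index.astype(str), rk["p"].to_numpy()))]
        rk["rank"] = np.arange(1, len(rk) + 1)
    out = mapped.copy()
    keys = out["internal"].map(_norm)
    out["p"] = keys.map(rk["p"]).astype(float)
    out["rank"] = keys.map(rk["rank"])
    out["in_ranking"] = keys.isin(rk.index)
    return out


def count_significant(rank_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> int:
    """Rows with p < alpha; entries without a p (NS) count as p = 1."""
    if not (0 < alpha < 1):
        raise UserInputError("alpha must be in (0, 1)")
    p = pd.to_numeric(rank_table["p"], errors="coerce").fillna(1.0)
    return int((p < alpha).sum())


@dataclass(frozen=True)
class VennPartition:
    """Two-list set partition per direction (condition1 vs condition2)."""

    up_only_1: frozenset
    up_only_2: frozenset
    up_shared: frozenset
    down_only_1: frozenset
    down_only_2: frozenset
    down_shared: frozenset

    def counts(self) -> dict[str, int]:
        return {
            "up_only_1": len(self.up_only_1),
            "up_only_2": len(self.up_only_2),
            "up_shared": len(self.up_shared),
            "down_only_1": len(self.down_only_1),
            "down_only_2": len(self.down_only_2),
            "down_shared": len(self.down_shared),
        }


def venn_partition(up1: Iterable, down1: Iterable, up2: Iterable, down2: Iterable) -> VennPartition:
    """Exclusive/shared partition of two up-lists and two down-lists."""
    u1, u2 = {_norm(g) for g in up1}, {_norm(g) for g in up2}
    d1, d2 = {_norm(g) for g in down1}, {_norm(g) for g in down2}
    return VennPartition(
        up_only_1=frozenset(u1 - u2), up_only_2=frozenset(u2 - u1),
        up_shared=frozenset(u1 & u2),
        down_only_1=frozenset(d1 - d2), down_only_2=frozenset(d2 - d1),
        down_shared=frozenset(d1 & d2),
    )


def heatmap_matrix(
    profiles: pd.DataFrame,
    gene_subset: Sequence[str],
    ordering: str = "as_given",
    pvalues: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Centered averaged profiles for a gene subset, ready for rendering.

    ``ordering``: "as_given" keeps the subset order, "by_p" sorts by the
    supplied p-values (ascending). Subset members absent from the
    profiles are excluded and returned in the sidecar list.
    """
    if len(gene_subset) == 0:
        raise UserInputError("empty gene subset")
    lookup = {_norm(g): g for g in profiles.index}
    present, absent = [], []
    for g in gene_subset:
        hit = lookup.get(_norm(g))
        (present if hit is not None else absent).append(hit or str(g))
    if not present:
        raise UserInputError("no subset gene found in the profile matrix")
    mat = profiles.loc[present]
    mat = mat.sub(mat.mean(axis=1), axis=0)
    if ordering == "by_p":
        if pvalues is None:
            raise UserInputError("ordering='by_p' requires pvalues")
        pv = pd.Series({g: float(pvalues.get(g, np.inf)) for g in present})
        mat = mat.loc[pv.sort_values(kind="mergesort").index]
    elif ordering != "as_given":
        raise UserInputError(f"unknown ordering {ordering!r}")
    return mat, absent
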