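"""Consensus vote-counting screen for resistance-gene candidates.

A gene is a *candidate* when it is significantly up-regulated
(log2FC >= up_lfc and p <= up_p) in at least ``min_support`` resistant
cohorts and never drops below ``floor_lfc`` in the remaining cohorts.
Candidates are ranked by their support count (number of up-regulated
cohorts); those whose support strictly exceeds ``min_support`` are the
resistance-related genes (PRGs) the pipeline carries forward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the screen and the downstream synergy/network stages.

    Defaults are the study conventions: up-regulation log2FC >= 1 at
    p <= 0.05 in >= 3 cohorts, a -0.2 log2FC floor elsewhere, synergy DE at
    log2FC >= 0.6 / p <= 0.05, and interaction confidence > 0.7.
    """

    up_lfc: float = 1.0
    up_p: float = 0.05
    floor_lfc: float = -0.2
    min_support: int = 3
    synergy_lfc: float = 0.6
    synergy_p: float = 0.05
    ppi_score: float = 0.7

    def __post_init__(self) -> None:
        if not (self.up_lfc > 0 > self.floor_lfc):
            raise ValueError("need up_lfc > 0 > floor_lfc")
        for name in ("up_p", "synergy_p"):
            p = getattr(self, name)
            if not (0 < p < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0 <= self.ppi_score <= 1):
            raise ValueError("ppi_score must lie in [0, 1]")


def _pivot(de: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = de.pivot(index="gene", columns="cohort", values=column)
    return wide.sort_index()


def cohort_up_flags(de: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Genes x cohorts boolean frame: True where log2fc >= up_lfc and
    p <= up_p (thresholds inclusive).  NA where the gene is not measured in
    that cohort.  Genes measured in fewer than half the cohorts are dropped
    with a warning."""
    lfc = _pivot(de, "log2fc")
    pval = _pivot(de, "p")
    n_cohorts = lfc.shape[1]
    measured = lfc.notna()
    min_measured = math.ceil(n_cohorts / 2)
    too_sparse = measured.sum(axis=1) < min_measured
    if too_sparse.any():
        warnings.warn(
            f"{int(too_sparse.sum())} gene(s) measured in fewer than "
            f"{min_measured}/{n_cohorts} cohorts; excluded from the screen"
        )
        lfc, pval, measured = (
            x.loc[~too_sparse] for x in (lfc, pval, measured)
        )
    flags = (lfc >= config.up_lfc) & (pval <= config.up_p)
    return flags.where(measured)  # NA where unmeasured


def candidate_screen(de: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Build the candidate table from a long DETable.

    Columns: per-cohort flag columns ``flag_<cohort>``, ``support``,
    ``floor_ok``, ``is_candidate`` (support >= min_support AND floor_ok,
    the floor applying only to measured cohorts without an up-flag).
    """
    flags = cohort_up_flags(de, config)
    lfc = _pivot(de, "log2fc").loc[flags.index]
    measured = flags.notna()
    up = flags.fillna(False).astype(bool)
    support = up.sum(axis=1).astype(int)
    floor_cohorts = measured & ~up
    floor_ok = (~((lfc < config.floor_lfc) & floor_cohorts)).all(axis=1)
    table = pd.DataFrame(index=flags.index)
    for cohort in flags.columns:
        table[f"flag_{cohort}"] = up[cohort]
    table["support"] = support
    table["floor_ok"] = floor_ok
    table["is_candidate"] = (support >= config.min_support) & floor_ok
    table["is_prg"] = False
    table["rank"] = 0
    return table


def rank_and_select_prgs(
    candidates: pd.DataFrame, config: ScreenConfig
) -> pd.DataFrame:
    """Rank candidates by support (descending, ties lexicographic by gene)
    and flag PRGs: candidates with support strictly above ``min_support``."""
    table = candidates.copy()
    cand = table[table["is_candidate"]]
    if cand.empty:
        warnings.warn("no candidate genes; PRG set is empty")
        return table
    order = cand.iloc[
        np.lexsort((cand.index.to_numpy(), -cand["support"].to_numpy()))
    ]
    table.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    table["is_prg"] = table["is_candidate"] & (
        table["support"] > config.min_support
    )
    if not table["is_prg"].any():
        warnings.warn(
            "no candidate exceeds min_support; PRG set is empty"
        )
    return table


def screen_summary(table: pd.DataFrame) -> dict:
    cands = table[table["is_candidate"]].sort_values("rank")
    return {
        "n_genes": int(len(table)),
        "n_candidates": int(table["is_candidate"].sum()),
        "n_prgs": int(table["is_prg"].sum()),
        "candidates": list(cands.index),
        "prgs": list(cands[cands["is_prg"]].index),
        "supports": {g: int(s) for g, s in cands["support"].items()},
    }


def write_candidate_table(table: pd.DataFrame, path) -> None:
    """TSV: gene, support, is_candidate, is_prg, rank, flags as a 0/1 string."""
    flag_cols = [c for c in table.columns if c.startswith("flag_")]
    out = pd.DataFrame(
        {
            "gene": table.index,
            "support": table["support"].to_numpy(),
            "is_candidate": table["is_candidate"].astype(int).to_numpy(),
            "is_prg": table["is_prg"].astype(int).to_numpy(),
            "rank": table["rank"].to_numpy(),
            "flags": [
                "".join(str(int(v)) for v in row)
                for row in table[flag_cols].to_numpy()
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)
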