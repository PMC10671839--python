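"""Synergy-gene discovery around an anchor gene.

Pipeline: split patients at the median expression of the anchor (the top
screen hit, CPT1A in the motivating study); find genes co-upregulated in
the high-anchor group; intersect with the lipid-metabolism and oncological
gene sets; keep only genes with a high-confidence direct interaction edge
to the anchor; finally intersect with a literature list of lipid-metabolism
drug-resistance genes (LRG selection).

Gene symbols are uppercased and whitespace-stripped at every set boundary;
no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .consensus_screen import ScreenConfig
from .diffexpr import de_table_for_cohorts
from .expression_core import CohortPair, ExpressionMatrix
from .patient_stats import median_split

LITERATURE_GMT = "literature_lrg.gmt"


def norm_gene(g: str) -> str:
    return str(g).strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed); the synergy stage requires the
    ``lipid_metabolism`` and ``oncological`` sets."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> set[str]:
        if name not in self.sets:
            raise KeyError(f"gene set {name!r} not loaded")
        return self.sets[name]

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        self.sets[name] = {norm_gene(g) for g in genes}
        self.descriptions[name] = description

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        """Parse a GMT file: one set per line, tab-separated
        ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
        coll = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        "and >=1 gene"
                    )
                coll.add(parts[0], parts[2:], parts[1])
        return coll

    def write_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


class InteractionTable:
    """Undirected scored interaction edges with scores in [0, 1].

    Duplicate undirected edges collapse keeping the maximum score;
    self-loops are dropped.  STRING-style integer scores (0-1000) are
    auto-detected (any score > 1) and divided by 1000.
    """

    def __init__(self, edges: pd.DataFrame):
        required = ["gene_a", "gene_b", "score"]
        missing = [c for c in required if c not in edges.columns]
        if missing:
            raise ValueError(f"edge table missing column(s) {missing}")
        df = edges[required].copy()
        df["gene_a"] = df["gene_a"].map(norm_gene)
        df["gene_b"] = df["gene_b"].map(norm_gene)
        df["score"] = df["score"].astype(float)
        if (df["score"] > 1.0).any():
            df["score"] /= 1000.0
        if (df["score"] < 0).any() or (df["score"] > 1).any():
            raise ValueError("scores must lie in [0, 1] (or STRING 0-1000)")
        df = df[df["gene_a"] != df["gene_b"]]
        if df.empty:
            self.edges = pd.DataFrame(columns=required)
            return
        lo = np.minimum(df["gene_a"], df["gene_b"])
        hi = np.maximum(df["gene_a"], df["gene_b"])
        df = pd.DataFrame({"gene_a": lo, "gene_b": hi, "score": df["score"]})
        df = (
            df.groupby(["gene_a", "gene_b"], as_index=False)["score"]
            .max()
            .sort_values(["gene_a", "gene_b"])
        )
        self.edges = df.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.4g")

    def neighbors_above(self, gene: str, threshold: float) -> set[str]:
        """Genes with a direct edge to ``gene`` scoring strictly above
        ``threshold``."""
        g = norm_gene(gene)
        df = self.edges
        hit = df[(df["score"] > threshold)]
        out = set(hit.loc[hit["gene_a"] == g, "gene_b"])
        out |= set(hit.loc[hit["gene_b"] == g, "gene_a"])
        return out


def co_upregulated_genes(
    patient_matrix: ExpressionMatrix, anchor: str, config: ScreenConfig
) -> set[str]:
    """Genes up-regulated (log2FC >= synergy_lfc, p <= synergy_p, moderated
    t) in high-anchor vs low-anchor patients under a median split."""
    anchor = norm_gene(anchor)
    genes_norm = [norm_gene(g) for g in patient_matrix.gene_ids]
    if anchor not in genes_norm:
        raise KeyError(f"anchor gene {anchor!r} absent from patient matrix")
    anchor_row = patient_matrix.data.iloc[genes_norm.index(anchor)]
    groups = median_split(anchor_row)
    pair = CohortPair(
        cohort_id="patients",
        sensitive_samples=tuple(groups.index[groups == "low"]),
        resistant_samples=tuple(groups.index[groups == "high"]),
    )
    de = de_table_for_cohorts(patient_matrix, [pair])
    hits = de[(de["log2fc"] >= config.synergy_lfc) & (de["p"] <= config.synergy_p)]
    return {norm_gene(g) for g in hits["gene"]}


def triple_intersection(co_up: set, sets: GeneSetCollection) -> set[str]:
    """Genes in the co-upregulated set, the lipid-metabolism set and the
    oncological set simultaneously."""
    lipid = sets["lipid_metabolism"]
    onco = sets["oncological"]
    return {norm_gene(g) for g in co_up} & lipid & onco


def ppi_core_filter(
    synergy: set, anchor: str, edges: InteractionTable, config: ScreenConfig
) -> set[str]:
    """The anchor plus synergy genes tied to it by an interaction edge with
    score strictly above ``config.ppi_score``."""
    anchor = norm_gene(anchor)
    partners = edges.neighbors_above(anchor, config.ppi_score)
    synergy = {norm_gene(g) for g in synergy}
    return {anchor} | (partners & synergy)


def lrg_select(core: set, anchor: str, literature) -> set[str]:
    """Core partners that the literature flags as lipid-metabolism
    drug-resistance genes, the anchor excluded."""
    if not literature:
        raise ValueError("literature gene list is empty")
    lit = {norm_gene(g) for g in literature}
    return ({norm_gene(g) for g in core} & lit) - {norm_gene(anchor)}


def load_literature_list() -> list[str]:
    """The packaged literature list of lipid-metabolism enzymes implicated
    in cancer drug resistance (editable; ships as a GMT resource)."""
    ref = resources.files("prgscreen").joinpath("data", LITERATURE_GMT)
    with resources.as_file(ref) as path:
        coll = GeneSetCollection.read_gmt(path)
    return sorted(coll["lipid_drug_resistance_literature"])


@dataclass
class SynergyResult:
    anchor: str
    co_up: set[str]
    synergy: set[str]
    core_partners: set[str]
    lrgs: set[str]

    def summary(self) -> dict:
        return {
            "anchor": self.anchor,
            "n_co_up": len(self.co_up),
            "n_synergy": len(self.synergy),
            "n_core": len(self.core_partners),
            "core_partners": sorted(self.core_partners),
            "lrgs": sorted(self.lrgs),
        }


def run_synergy_analysis(
    patient_matrix: ExpressionMatrix,
    anchor: str,
    gene_sets: GeneSetCollection,
    edges: InteractionTable,
    config: ScreenConfig,
    literature=None,
) -> SynergyResult:
    """Full synergy pass: co-up DE -> triple intersection -> interaction
    core -> LRG selection."""
    if literature is None:
        literature = load_literature_list()
    co_up = co_upregulated_genes(patient_matrix, anchor, config)
    synergy = triple_intersection(co_up, gene_sets)
    core = ppi_core_filter(synergy, anchor, edges, config)
    lrgs = lrg_select(core, anchor, literature)
    return SynergyResult(norm_gene(anchor), co_up, synergy, core, lrgs)
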