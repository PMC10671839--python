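"""Synthetic inputs with the statistical structure the screen assumes.

Three generator families cover every file the pipeline consumes:

* cell-line panels — paired sensitive/resistant cohorts with cohort batch
  shifts, per-sample array offsets, and resistance genes planted up-regulated
  in chosen cohort subsets;
* patient cohorts — log2 expression where chosen genes track an anchor gene
  with a target correlation, plus exponential survival whose hazard depends
  on chosen driver genes, with censoring calibrated to a target rate;
* scored interaction tables and 4PL viability curves.

A deterministic *reference fixture* wires all of these together so the full
pipeline (candidate screen -> PRGs -> synergy -> interaction core -> LRGs)
has a known, exactly reproducible answer: 19 candidate genes with supports
7/4/4 for the top three, a 19-node interaction core around CPT1A, and LRGs
{ACACA, CPT2, FASN, SCD}.

All generators are pure functions of their spec (seed included); randomness
flows through a single explicitly seeded numpy Generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .assay_stats import DoseResponseData, four_pl
from .consensus_screen import ScreenConfig
from .expression_core import ExpressionMatrix, SampleSheet
from .synergy_network import GeneSetCollection, InteractionTable

# ---------------------------------------------------------------- cell lines


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    effect_log2fc: float
    cohorts: tuple[int, ...]  # 0-based cohort indices carrying the effect


@dataclass
class PanelSpec:
    """Multi-cohort sensitive/resistant panel specification.

    Defaults emulate the study layout: 7 cohort pairs, 3 replicates per arm,
    cohort batch shifts of sd 0.5 and per-sample array offsets of sd 0.3 on
    top of within-arm noise.
    """

    n_genes: int = 1000
    n_cohorts: int = 7
    reps_per_arm: int = 3
    planted: list[PlantedEffect] = field(default_factory=list)
    batch_scale_sd: float = 0.5
    sample_shift_sd: float = 0.3
    noise_sd: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_arm < 1:
            raise ValueError("reps_per_arm must be >= 1")
        for eff in self.planted:
            bad = [c for c in eff.cohorts if not 0 <= c < self.n_cohorts]
            if bad:
                raise ValueError(
                    f"planted gene {eff.gene}: cohort indices {bad} out of range"
                )


def _gene_universe(n_genes: int, named: list[str]) -> list[str]:
    named = list(dict.fromkeys(named))
    if len(named) > n_genes:
        raise ValueError("more named genes than n_genes")
    fillers = [f"G{i:05d}" for i in range(n_genes - len(named))]
    return named + fillers


def gen_cellline_panel(spec: PanelSpec):
    """Simulate the panel; returns (ExpressionMatrix, SampleSheet, pairs)."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec.n_genes, [p.gene for p in spec.planted])
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)

    columns, rows_cohort, rows_cond = [], [], []
    for c in range(spec.n_cohorts):
        cid = f"C{c + 1}"
        for arm, tag in (("sensitive", "sen"), ("resistant", "res")):
            for r in range(spec.reps_per_arm):
                columns.append(f"{cid}_{tag}{r + 1}")
                rows_cohort.append(cid)
                rows_cond.append(arm)
    n_samples = len(columns)

    batch = rng.normal(0.0, spec.batch_scale_sd, spec.n_cohorts)
    shifts = rng.normal(0.0, spec.sample_shift_sd, n_samples)
    vals = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, n_samples))
    cohort_of = np.repeat(np.arange(spec.n_cohorts), 2 * spec.reps_per_arm)
    resistant = np.array([c == "resistant" for c in rows_cond])
    vals += batch[cohort_of][None, :] + shifts[None, :]

    gene_index = {g: i for i, g in enumerate(genes)}
    for eff in spec.planted:
        gi = gene_index[eff.gene]
        mask = resistant & np.isin(cohort_of, eff.cohorts)
        vals[gi, mask] += eff.effect_log2fc

    matrix = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=columns))
    sheet = SampleSheet(
        pd.DataFrame(
            {"sample_id": columns, "cohort_id": rows_cohort, "condition": rows_cond}
        )
    )
    return matrix, sheet, sheet.cohort_pairs()


# ------------------------------------------------------------------ patients


@dataclass
class PatientSpec:
    """Patient cohort with anchor-correlated genes and gene-driven hazard.

    ``synergy_genes`` maps gene -> target Pearson correlation with the
    anchor; ``hazard_beta`` maps gene -> log-hazard-ratio per SD of its
    expression.  Defaults mirror the study's cohort size (368) and a 40%
    censoring fraction typical of an ovarian-cancer registry cut.
    """

    n_patients: int = 368
    n_genes: int = 1000
    anchor: str = "CPT1A"
    synergy_genes: dict[str, float] = field(default_factory=dict)
    hazard_beta: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.4
    baseline_hazard: float = 1.0 / 1000.0  # per day
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, r in self.synergy_genes.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation for {g} must lie in (-1, 1)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


def gen_patient_cohort(spec: PatientSpec):
    """Simulate expression + survival; returns (ExpressionMatrix, DataFrame).

    The survival frame has columns patient_id, time_days, event (1 = death).
    Censoring is independent exponential with its rate solved numerically so
    the expected censored fraction equals ``censoring_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    named = [spec.anchor] + [g for g in spec.synergy_genes if g != spec.anchor]
    named += [g for g in spec.hazard_beta if g not in named]
    genes = _gene_universe(spec.n_genes, named)
    n = spec.n_patients

    z_anchor = rng.standard_normal(n)
    z = rng.standard_normal((spec.n_genes, n))
    expr = spec.baseline_mean + z
    gene_index = {g: i for i, g in enumerate(genes)}
    expr[gene_index[spec.anchor]] = spec.baseline_mean + z_anchor
    for g, r in spec.synergy_genes.items():
        gi = gene_index[g]
        expr[gi] = spec.baseline_mean + r * z_anchor + np.sqrt(1 - r * r) * z[gi]

    matrix = ExpressionMatrix(
        pd.DataFrame(
            expr, index=genes, columns=[f"P{i + 1:04d}" for i in range(n)]
        )
    )

    lp = np.zeros(n)
    for g, beta in spec.hazard_beta.items():
        row = expr[gene_index[g]]
        lp += beta * (row - row.mean()) / row.std(ddof=0)
    rate = spec.baseline_hazard * np.exp(lp)
    t_death = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        # solve mean(hc / (hc + rate_i)) = censoring_rate for the censor rate
        target = spec.censoring_rate

        def gap(log_hc):
            hc = np.exp(log_hc)
            return float(np.mean(hc / (hc + rate))) - target

        log_hc = optimize.brentq(gap, -30.0, 10.0)
        t_cens = rng.exponential(np.exp(-log_hc), n)
        time = np.minimum(t_death, t_cens)
        event = (t_death <= t_cens).astype(int)
    else:
        time, event = t_death, np.ones(n, dtype=int)
    survival = pd.DataFrame(
        {
            "patient_id": matrix.sample_ids,
            "time_days": np.maximum(time, 1e-3),
            "event": event,
        }
    )
    return matrix, survival


# ------------------------------------------------------------- interactions


def gen_interaction_table(
    nodes, anchor: str, true_partners, decoy_density: float = 0.02, seed: int = 0
) -> InteractionTable:
    """Scored edge table: anchor-partner edges score Uniform(0.75, 0.99),
    decoy edges Uniform(0.10, 0.69) sprinkled at ``decoy_density``."""
    rng = np.random.default_rng(seed)
    nodes = list(dict.fromkeys(nodes))
    partners = list(dict.fromkeys(true_partners))
    missing = [p for p in partners if p not in nodes]
    if missing:
        raise ValueError(f"partners not in node universe: {missing}")
    rows = [
        (anchor, p, rng.uniform(0.75, 0.99)) for p in partners if p != anchor
    ]
    others = [x for x in nodes if x != anchor]
    for i, a in enumerate(others):
        for b in others[i + 1 :]:
            if rng.random() < decoy_density:
                rows.append((a, b, rng.uniform(0.10, 0.69)))
        if a not in partners and rng.random() < decoy_density:
            rows.append((anchor, a, rng.uniform(0.10, 0.69)))
    return InteractionTable(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    )


# ------------------------------------------------------------ dose response


def gen_dose_response(
    bottom: float,
    top: float,
    hill: float,
    ic50: float,
    doses=None,
    reps: int = 3,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> DoseResponseData:
    """Viability replicates from a 4PL curve plus Gaussian noise.

    The default dose ladder is a 3-fold dilution series (0 to 9000 nM),
    matching a standard 96-well IC50 layout.
    """
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = [0.0, 12.3, 37.0, 111.0, 333.0, 1000.0, 3000.0, 9000.0]
    doses = np.asarray(doses, float)
    clean = four_pl(np.where(doses == 0, 1e-9, doses), bottom, top, hill, ic50)
    clean = np.where(doses == 0, top, clean)
    responses = [
        c + rng.normal(0.0, noise_sd, reps) for c in clean
    ]
    return DoseResponseData(doses, responses)


# ----------------------------------------------------------------- fixture

# the 19-gene candidate list the deterministic fixture reproduces
FIXTURE_CANDIDATES_3 = [
    "ACSS1", "AK5", "ALCAM", "CHRD", "CLDN1", "CLDN16", "GALNT10", "HERC5",
    "LAMB1", "NFE2L3", "OSTF1", "PGM2", "PODXL", "PRKD3", "SLC4A8", "THBS1",
]
FIXTURE_CANDIDATES_4 = ["CPT1A", "ATP1B1"]
FIXTURE_CANDIDATE_7 = "ABCB1"

# 18 interaction partners wired to the anchor in the fixture network
FIXTURE_CORE_PARTNERS = [
    "ACACA", "ACADM", "ACADVL", "ACSL1", "ACSL3", "CHKB", "RORA", "EP300",
    "SCD", "HADHB", "SREBF2", "PPARG", "FASN", "HADHA", "SREBF1", "PPARA",
    "SLC25A20", "CPT2",
]

# decoys exercising each rejection rule of the screen
FIXTURE_DECOYS = {
    "TUBB3": "floor",  # up in 3 cohorts but down (-0.5) in a fourth
    "MAPT": "weak",  # log2fc 0.5 everywhere: never significant at >= 1
    "BCL2": "support",  # up in only 2 cohorts
}


@dataclass
class PaperFixture:
    """Deterministic full-input bundle with known pipeline output."""

    cell_matrix: ExpressionMatrix
    sheet: SampleSheet
    pairs: list
    patient_matrix: ExpressionMatrix
    survival: pd.DataFrame
    gene_sets: GeneSetCollection
    interactions: InteractionTable
    literature: list[str]
    dose_response: dict[str, DoseResponseData]
    config: ScreenConfig
    anchor: str = "CPT1A"


def build_paper_fixture(seed: int = 0) -> PaperFixture:
    """Build the deterministic reference bundle.

    Planted structure (within-arm sd 0.05, so every planted effect is
    detected and every null is flat, for any seed):

    * ABCB1 up (log2FC 3) in all 7 cohorts; CPT1A and ATP1B1 in 4; the 16
      remaining candidates in rotating 3-cohort subsets -> exactly 19
      candidates with supports 7, 4, 4, 3 x 16;
    * three decoys: a floor violator, a sub-threshold shift, a 2-cohort hit;
    * a patient cohort where the 18 fixture partners track CPT1A (r = 0.9),
      ATP1B1 tracks it weakly (r = 0.32), CPT1A raises the death hazard and
      ATP1B1 lowers it;
    * gene sets and a scored interaction table such that the synergy stage
      returns a 19-node core and LRGs {ACACA, CPT2, FASN, SCD};
    * paired paclitaxel viability curves with IC50s 1574 / 299.7 nM.
    """
    planted = [PlantedEffect(FIXTURE_CANDIDATE_7, 3.0, tuple(range(7)))]
    planted += [
        PlantedEffect(g, 3.0, (0, 1, 2, 3)) for g in FIXTURE_CANDIDATES_4
    ]
    for i, g in enumerate(FIXTURE_CANDIDATES_3):
        planted.append(PlantedEffect(g, 3.0, (i % 7, (i + 1) % 7, (i + 2) % 7)))
    planted.append(PlantedEffect("TUBB3", 3.0, (0, 1, 2)))
    planted.append(PlantedEffect("TUBB3", -0.5, (3,)))  # floor violation
    planted.append(PlantedEffect("MAPT", 0.5, tuple(range(7))))
    planted.append(PlantedEffect("BCL2", 3.0, (4, 5)))

    panel_spec = PanelSpec(
        n_genes=1000,
        n_cohorts=7,
        reps_per_arm=3,
        planted=planted,
        batch_scale_sd=0.5,
        sample_shift_sd=0.3,
        noise_sd=0.05,
        seed=seed,
    )
    cell_matrix, sheet, pairs = gen_cellline_panel(panel_spec)

    partners_r = {g: 0.9 for g in FIXTURE_CORE_PARTNERS}
    partners_r["ACLY"] = 0.9  # co-up and in both sets, but no strong edge
    partners_r["ATP1B1"] = 0.32
    patient_spec = PatientSpec(
        n_patients=368,
        n_genes=1000,
        anchor="CPT1A",
        synergy_genes=partners_r,
        hazard_beta={"CPT1A": 0.7, "ATP1B1": -0.5},
        censoring_rate=0.4,
        seed=seed + 1,
    )
    patient_matrix, survival = gen_patient_cohort(patient_spec)

    gene_sets = GeneSetCollection()
    lipid_extra = ["PLIN1", "DGAT1", "LPL"]  # in sets but not co-upregulated
    onco_extra = ["MYC", "TP53", "KRAS"]
    gene_sets.add(
        "lipid_metabolism",
        FIXTURE_CORE_PARTNERS + ["ACLY", "CPT1A"] + lipid_extra,
        "fixture lipid-metabolism set",
    )
    gene_sets.add(
        "oncological",
        FIXTURE_CORE_PARTNERS + ["ACLY", "CPT1A"] + onco_extra,
        "fixture oncological set",
    )

    interactions = gen_interaction_table(
        nodes=patient_matrix.gene_ids,
        anchor="CPT1A",
        true_partners=FIXTURE_CORE_PARTNERS,
        decoy_density=0.0,
        seed=seed + 2,
    )
    # explicit sub-threshold decoy edges, ACLY among them
    decoy_rows = pd.DataFrame(
        {
            "gene_a": ["CPT1A", "CPT1A", "CPT1A"],
            "gene_b": ["ACLY", "MYC", "PLIN1"],
            "score": [0.5, 0.4, 0.3],
        }
    )
    interactions = InteractionTable(
        pd.concat([interactions.edges, decoy_rows], ignore_index=True)
    )

    from .synergy_network import load_literature_list

    literature = load_literature_list()

    dose_response = {
        "A2780_PTX": gen_dose_response(
            5.0, 100.0, 1.2, 1574.0, noise_sd=3.0, seed=seed + 3
        ),
        "A2780": gen_dose_response(
            5.0, 100.0, 1.2, 299.7, noise_sd=3.0, seed=seed + 4
        ),
    }

    return PaperFixture(
        cell_matrix=cell_matrix,
        sheet=sheet,
        pairs=pairs,
        patient_matrix=patient_matrix,
        survival=survival,
        gene_sets=gene_sets,
        interactions=interactions,
        literature=literature,
        dose_response=dose_response,
        config=ScreenConfig(),
    )


def write_bundle(fixture: PaperFixture, out_dir, seed: int | None = None) -> dict:
    """Write every pipeline input of a fixture bundle to ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) naming each
    file; the resulting directory is directly consumable by the CLI stages.
    """
    import json
    from pathlib import Path

    from .expression_core import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "dose_response").mkdir(exist_ok=True)

    write_expression(fixture.cell_matrix, out / "cellline_expression.tsv")
    fixture.sheet.write(out / "cellline_sheet.tsv")
    write_expression(fixture.patient_matrix, out / "patient_expression.tsv")
    fixture.survival.to_csv(
        out / "survival.tsv", sep="\t", index=False, float_format="%.6g"
    )
    fixture.gene_sets.write_gmt(out / "gene_sets.gmt")
    fixture.interactions.write_tsv(out / "interactions.tsv")
    lit = GeneSetCollection()
    lit.add(
        "lipid_drug_resistance_literature", fixture.literature, "literature list"
    )
    lit.write_gmt(out / "literature.gmt")
    for name, data in fixture.dose_response.items():
        n_reps = max(len(r) for r in data.responses)
        frame = pd.DataFrame(
            [
                [c, *r, *([np.nan] * (n_reps - len(r)))]
                for c, r in zip(data.concentrations, data.responses)
            ],
            columns=["concentration_nM"] + [f"rep{i + 1}" for i in range(n_reps)],
        )
        frame.to_csv(out / "dose_response" / f"{name}.csv", index=False)

    manifest = {
        "generator": "prgscreen.synthetic_data",
        "seed": seed,
        "anchor": fixture.anchor,
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
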