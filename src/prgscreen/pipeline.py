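"""Configuration-driven orchestration of the analysis stages.

Each stage reads its inputs from paths named in a YAML config, runs the
library functions, and writes machine-readable outputs (TSV tables + a JSON
summary) plus a manifest recording the config hash, seed, package version
and per-file checksums, so identical configs yield byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay_stats import DoseResponseData, FitError, fit_4pl, resistance_index
from .consensus_screen import (
    ScreenConfig,
    candidate_screen,
    rank_and_select_prgs,
    screen_summary,
    write_candidate_table,
)
from .diffexpr import de_table_for_cohorts, write_de_table
from .expression_core import quantile_normalize, read_expression
from .patient_stats import km_estimate, load_survival, log_rank_test, median_split, write_curve
from .synergy_network import (
    GeneSetCollection,
    InteractionTable,
    run_synergy_analysis,
)

log = logging.getLogger("prgscreen")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed, schema version 1)."""

    schema_version: int = 1
    seed: int = 0
    anchor: str = "CPT1A"
    # input paths (stage-dependent; validated by the stage that needs them)
    cellline_matrix: str | None = None
    cellline_sheet: str | None = None
    patient_matrix: str | None = None
    patient_linear_counts: bool = False
    survival: str | None = None
    gene_sets_gmt: str | None = None
    interactions: str | None = None
    dose_response_dir: str | None = None
    resistant_label: str = "resistant"
    sensitive_label: str = "sensitive"
    normalize: bool = True
    stages: list[str] = field(
        default_factory=lambda: ["screen", "synergy", "assay"]
    )
    screen: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.schema_version != 1:
            raise ConfigError(f"unsupported schema_version {cfg.schema_version}")
        screen_known = {f.name for f in fields(ScreenConfig)}
        bad = set(cfg.screen) - screen_known
        if bad:
            raise ConfigError(f"unknown screen threshold key(s): {sorted(bad)}")
        return cfg

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(**self.screen)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigError(f"config missing required path(s): {missing}")
        for n in names:
            p = Path(getattr(self, n))
            if not p.exists():
                raise ConfigError(f"{n}: no such file or directory: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, stage: str, outputs) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_dir(out_dir, stage: str) -> Path:
    d = Path(out_dir) / stage
    if d.exists():
        shutil.rmtree(d)  # stale partial outputs never survive a rerun
    d.mkdir(parents=True)
    return d


def run_screen(config: RunConfig, out_dir) -> dict:
    """Normalization -> per-cohort moderated-t DE -> consensus screen."""
    config.require("cellline_matrix", "cellline_sheet")
    out = _stage_dir(out_dir, "screen")
    log.info("screen: loading expression matrix")
    matrix, sheet = read_expression(
        config.cellline_matrix, config.cellline_sheet, collapse=True
    )
    scfg = config.screen_config()
    pairs = sheet.cohort_pairs()
    tables = []
    for pair in pairs:
        cols = list(pair.sensitive_samples) + list(pair.resistant_samples)
        sub = matrix.subset_samples(cols)
        if config.normalize:
            sub = quantile_normalize(sub)
        tables.append(de_table_for_cohorts(sub, [pair]))
        log.info("screen: cohort %s analysed (%d genes)", pair.cohort_id, len(sub.gene_ids))
    de = pd.concat(tables, ignore_index=True)
    table = rank_and_select_prgs(candidate_screen(de, scfg), scfg)
    summary = screen_summary(table)
    summary["thresholds"] = asdict(scfg)

    de_path = out / "de_table.tsv"
    cand_path = out / "candidates.tsv"
    sum_path = out / "screen_summary.json"
    write_de_table(de, de_path)
    write_candidate_table(table, cand_path)
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest(out, config, "screen", [de_path, cand_path, sum_path])
    log.info(
        "screen: %d candidates, %d PRGs", summary["n_candidates"], summary["n_prgs"]
    )
    return summary


def run_synergy(config: RunConfig, out_dir) -> dict:
    """Median split -> co-up DE -> set intersection -> PPI core -> LRGs,
    plus KM curves and log-rank p for the anchor and each LRG."""
    config.require("patient_matrix", "survival", "gene_sets_gmt", "interactions")
    out = _stage_dir(out_dir, "synergy")
    matrix = read_expression(
        config.patient_matrix, collapse=True,
        linear_counts=config.patient_linear_counts,
    )
    survival = load_survival(config.survival)
    gene_sets = GeneSetCollection.read_gmt(config.gene_sets_gmt)
    edges = InteractionTable.read_tsv(config.interactions)
    scfg = config.screen_config()

    result = run_synergy_analysis(matrix, config.anchor, gene_sets, edges, scfg)
    summary = result.summary()

    surv = survival.set_index("patient_id")
    outputs = []
    km_stats = {}
    genes_norm = {g.strip().upper(): g for g in matrix.gene_ids}
    for gene in [result.anchor, *sorted(result.lrgs)]:
        row_name = genes_norm.get(gene)
        if row_name is None:
            continue
        expr = matrix.data.loc[row_name, surv.index]
        groups = median_split(expr)
        rec = {
            lab: surv.loc[groups[groups == lab].index] for lab in ("low", "high")
        }
        lr = log_rank_test(
            rec["low"]["time_days"], rec["low"]["event"],
            rec["high"]["time_days"], rec["high"]["event"],
        )
        km_stats[gene] = {"log_rank_chi_sq": lr.chi_sq, "log_rank_p": lr.p}
        for lab in ("low", "high"):
            curve = km_estimate(rec[lab]["time_days"], rec[lab]["event"])
            path = out / f"km_{gene}_{lab}.tsv"
            write_curve(curve, path)
            outputs.append(path)
    summary["survival"] = km_stats

    sum_path = out / "synergy_summary.json"
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    outputs.append(sum_path)
    _write_manifest(out, config, "synergy", outputs)
    log.info("synergy: core=%d LRGs=%s", summary["n_core"], summary["lrgs"])
    return summary


def run_assay(config: RunConfig, out_dir) -> dict:
    """4PL fits + IC50 table for every dose-response CSV; RI for the
    labeled resistant/sensitive pair when both fit."""
    config.require("dose_response_dir")
    out = _stage_dir(out_dir, "assay")
    csvs = sorted(Path(config.dose_response_dir).glob("*.csv"))
    if not csvs:
        raise ConfigError(f"no dose-response CSVs in {config.dose_response_dir}")
    fits, failures = {}, {}
    for path in csvs:
        name = path.stem
        try:
            fit = fit_4pl(DoseResponseData.read_csv(path))
            fits[name] = {
                "bottom": fit.bottom, "top": fit.top, "hill": fit.hill,
                "ic50_nM": fit.ic50, "rss": fit.rss,
            }
        except (FitError, ValueError) as exc:
            failures[name] = str(exc)
            log.warning("assay: fit failed for %s: %s", name, exc)
    summary: dict = {"fits": fits, "failures": failures}
    res = [n for n in fits if config.resistant_label in n.lower() or "ptx" in n.lower()]
    sen = [n for n in fits if n not in res]
    if len(res) == 1 and len(sen) == 1:
        ri = resistance_index(fits[res[0]]["ic50_nM"], fits[sen[0]]["ic50_nM"])
        summary["resistance_index"] = {
            "resistant": res[0], "sensitive": sen[0], "ri": ri.ri,
        }
    sum_path = out / "assay_summary.json"
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest(out, config, "assay", [sum_path])
    return summary


def run_all(config: RunConfig, out_dir) -> dict:
    results = {}
    runners = {"screen": run_screen, "synergy": run_synergy, "assay": run_assay}
    for stage in ["screen", "synergy", "assay"]:
        if stage not in config.stages:
            results[stage] = {"skipped": True}
            log.info("%s: skipped by config", stage)
            continue
        results[stage] = runners[stage](config, out_dir)
    with open(Path(out_dir) / "run_summary.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
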