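"""End-to-end orchestration: simulate -> quantify -> assemble -> test -> enrich.

`run_pipeline` executes the whole analysis from a single RunConfig, writes
every stage's TSV outputs into an output directory and returns (and writes)
a machine-readable JSON run report whose counts match the files.  Stage
failures are re-raised as PipelineError carrying the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assemble, calibrate, differential, enrich, quantify, synthetic
from .errors import ConfigurationError, PipelineError

log = logging.getLogger("plexde")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``synthetic`` is set the cohort is simulated; otherwise
    ``peptide_table``, ``design_table`` and ``gene_sets`` paths must point
    to existing inputs (peptide TSV, design TSV, GMT).
    """

    out_dir: str = "plexde_out"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    peptide_table: str | None = None
    design_table: str | None = None
    gene_sets: str | None = None
    # synthetic gene-set generation (used only when simulating)
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (10, 30)
    enrichment_fraction: float = 0.9
    n_enriched_sets: int = 5
    # analysis parameters
    q_threshold: float = 0.05
    alpha: float = 0.05
    neglog_threshold: float = 1.3
    variance_floor: float = 1e-6
    test_variant: str = "pooled"
    storey_lambda: float = 0.5
    filter_rules: assemble.FilterRules = field(default_factory=assemble.FilterRules)

    def validate(self) -> None:
        for name, value, lo, hi in (
            ("q_threshold", self.q_threshold, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("storey_lambda", self.storey_lambda, 0.0, 1.0),
        ):
            if not lo < value < hi:
                raise ConfigurationError(f"{name} must lie in ({lo}, {hi})")
        if self.neglog_threshold < 0:
            raise ConfigurationError("neglog_threshold must be >= 0")
        if self.variance_floor <= 0:
            raise ConfigurationError("variance_floor must be > 0")
        if self.synthetic is None:
            for name in ("peptide_table", "design_table", "gene_sets"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(
                        f"{name} must point to an existing file when not simulating"
                    )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        syn = raw.pop("synthetic", None)
        rules = raw.pop("filter_rules", None)
        if rules is not None:
            for key in ("contaminant_accessions", "depletion_targets", "manual_exclusions"):
                if key in rules:
                    rules[key] = frozenset(rules[key])
            raw["filter_rules"] = assemble.FilterRules(**rules)
        cfg = cls(**raw)
        if syn is not None:
            if "gis_channels" in syn:
                syn["gis_channels"] = tuple(syn["gis_channels"])
            if "peptides_per_protein_range" in syn:
                syn["peptides_per_protein_range"] = tuple(syn["peptides_per_protein_range"])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if "gene_set_size_range" in raw:
            cfg.gene_set_size_range = tuple(raw["gene_set_size_range"])
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_rules"] = {
            "decoy_prefix": self.filter_rules.decoy_prefix,
            "contaminant_accessions": sorted(self.filter_rules.contaminant_accessions),
            "depletion_targets": sorted(self.filter_rules.depletion_targets),
            "manual_exclusions": sorted(self.filter_rules.manual_exclusions),
        }
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: RunConfig, out: Path):
    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    log.info("simulate: seed=%d", syn.seed)
    designs, tables, truth = synthetic.generate_cohort(syn)
    sets = synthetic.generate_genesets(
        truth,
        n_sets=config.n_gene_sets,
        set_size_range=config.gene_set_size_range,
        enrichment_fraction=config.enrichment_fraction,
        seed=config.seed + 1,
        n_enriched=config.n_enriched_sets,
    )
    assemble.write_designs(designs, out / "design.tsv")
    quantify.write_peptide_table(pd.concat(tables, ignore_index=True), out / "peptides.tsv")
    enrich.write_gmt(sets, out / "gene_sets.gmt")
    return designs, tables, sets, truth


@_stage("load")
def _load(config: RunConfig):
    designs = assemble.read_designs(config.design_table)
    peptides = quantify.read_peptide_table(config.peptide_table)
    by_exp = quantify.split_experiments(peptides)
    tables = [by_exp[d.experiment_id] for d in designs]
    sets = enrich.read_gmt(config.gene_sets)
    return designs, tables, sets, None


@_stage("quantify")
def _quantify(designs, tables, out: Path):
    records = {"low": {}, "high": {}}
    for design, table in zip(designs, tables):
        for choice in ("low", "high"):
            ref = design.reference_channel(choice)
            recs = quantify.rollup_experiment(table, ref)
            records[choice][design.experiment_id] = recs
    for choice in ("low", "high"):
        combined = pd.concat(records[choice].values(), ignore_index=True)
        quantify.write_ratio_table(combined, out / f"ratios_{choice}.tsv")
    return records


@_stage("calibrate")
def _calibrate(records_low, designs, alpha, out: Path):
    reports = [
        calibrate.gis_false_positive_count(records_low[d.experiment_id], d, alpha=alpha)
        for d in designs
    ]
    calibrate.write_calibration_table(reports, out / "calibration.tsv")
    return reports


@_stage("assemble")
def _assemble(records, designs, config: RunConfig, out: Path):
    accessions = sorted(
        {a for recs in records["low"].values() for a in recs["accession"].unique()}
    )
    retained, removed = assemble.apply_filters(accessions, config.filter_rules)
    removed.to_csv(out / "removed_proteins.tsv", sep="\t", index=False)
    keep = set(retained)
    masters = {}
    for choice in ("low", "high"):
        filtered = {
            e: r.loc[r["accession"].isin(keep)].reset_index(drop=True)
            for e, r in records[choice].items()
        }
        master = assemble.build_master_table(
            filtered, designs, reference_choice=choice, variance_floor=config.variance_floor
        )
        assemble.write_master_table(master, out / f"master_{choice}.tsv")
        masters[choice] = master
    return masters, retained, removed


@_stage("test")
def _test(masters, config: RunConfig, out: Path):
    diff = differential.run_differential(
        masters["low"],
        masters["high"],
        q_threshold=config.q_threshold,
        variant=config.test_variant,
        lam=config.storey_lambda,
    )
    differential.write_differential_table(diff, out / "differential.tsv")
    return diff


@_stage("enrich")
def _enrich(diff, sets, config: RunConfig, out: Path):
    result = enrich.run_enrichment(
        diff, sets, q_threshold=config.q_threshold, neglog_threshold=config.neglog_threshold
    )
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    fractions = enrich.direction_fractions(diff, sets)
    fractions.to_csv(out / "pathway_fractions.tsv", sep="\t", index=False)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        designs, tables, sets, truth = _simulate(config, out)
    else:
        designs, tables, sets, truth = _load(config)

    records = _quantify(designs, tables, out)
    reports = _calibrate(records["low"], designs, config.alpha, out)
    masters, retained, removed = _assemble(records, designs, config, out)
    diff = _test(masters, config, out)
    enr = _enrich(diff, sets, config, out)

    report = {
        "seed": config.seed,
        "n_experiments": len(designs),
        "n_samples": sum(len(d.samples()) for d in designs),
        "peptide_rows": int(sum(len(t) for t in tables)),
        "proteins_quantified": len(retained),
        "proteins_removed_by_filters": int(len(removed)),
        "calibration": [r.to_dict() for r in reports],
        "master_rows": {c: int(len(masters[c].lfc)) for c in ("low", "high")},
        "dropped_insufficient_replication": {
            c: int(len(masters[c].dropped)) for c in ("low", "high")
        },
        "n_tested": int(diff["p_low"].notna().sum()),
        "significant_low": int(diff["significant_low"].sum()),
        "significant_high": int(diff["significant_high"].sum()),
        "consensus": int(diff["consensus"].sum()),
        "gene_sets": len(sets),
        "enriched_pathways": int(enr["significant"].sum()) if len(enr) else 0,
        "config": config.echo(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
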