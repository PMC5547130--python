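import numpy as np
import pandas as pd
import pytest

from plexde.assemble import build_master_table
from plexde.differential import run_differential
from plexde.quantify import rollup_experiment
from plexde.synthetic import SyntheticConfig, generate_cohort


def small_config(**overrides) -> SyntheticConfig:
    """Two-plex cohort (12 subjects, 7/5) small enough for unit tests."""
    defaults = dict(
        n_experiments=2,
        n_survivors=7,
        n_nonsurvivors=5,
        n_proteins=120,
        n_de=12,
        detect_prob=1.0,
        seed=11,
    )
    defaults.update(overrides)
    if "n_de" not in overrides:
        defaults["n_de"] = min(defaults["n_de"], defaults["n_proteins"] // 4)
    return SyntheticConfig(**defaults)


def analyze_cohort(config: SyntheticConfig):
    """Run quantify -> assemble -> differential on a generated cohort."""
    designs, tables, truth = generate_cohort(config)
    records = {"low": {}, "high": {}}
    for design, table in zip(designs, tables):
        for choice in ("low", "high"):
            ref = design.reference_channel(choice)
            records[choice][design.experiment_id] = rollup_experiment(table, ref)
    masters = {
        choice: build_master_table(records[choice], designs, reference_choice=choice)
        for choice in ("low", "high")
    }
    diff = run_differential(masters["low"], masters["high"])
    return designs, tables, truth, records, masters, diff


def peptide_table(log_ratios, ref_channel="113", target_channel="118",
                  accession="P0001", experiment_id="EXP1", base=1e5) -> pd.DataFrame:
    """One protein's peptide table with prescribed target/reference log10 ratios."""
    from plexde.channels import ITRAQ8, intensity_column

    rows = []
    for j, r in enumerate(log_ratios, start=1):
        row = {
            "experiment_id": experiment_id,
            "accession": accession,
            "peptide_id": f"{accession}_pep{j}",
        }
        for ch in ITRAQ8:
            row[intensity_column(ch)] = base
        row[intensity_column(target_channel)] = base * 10.0 ** r
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def planted_run():
    """A small planted cohort analysed end to end (shared across tests)."""
    cfg = small_config(effect_size_delta=1.2, seed=7)
    return analyze_cohort(cfg)
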