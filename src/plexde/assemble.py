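"""Cross-experiment alignment into a master protein x sample table.

Each multiplexed experiment yields protein ratios versus its pooled global
internal standard (GIS).  Because the same GIS pool is present in every
plex, log10 fold changes versus the GIS are comparable across experiments
and can be aligned into a single protein x sample matrix.  Each cell also
carries a variance derived from the roll-up error factor (EF):

    SE  = log10(EF) / 1.96          var = max(variance_floor, SE**2)

Proteins are retained only when quantified with a defined EF in at least
two experiments; the rest are dropped (and listed) as insufficiently
replicated.  Accession lists are filtered beforehand for decoys,
contaminants, depletion-column targets and manual exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import GIS_MARKER, ITRAQ8
from .errors import DesignError

SURVIVOR = "survivor"
NONSURVIVOR = "nonsurvivor"

#: 95% two-sided normal multiplier used to convert an EF into a standard error.
_Z95 = 1.96


@dataclass(frozen=True)
class ExperimentDesign:
    """Channel layout of one eightplex: which channel holds which subject.

    ``channel_map`` maps every channel label to a sample ID or the GIS
    marker; ``gis_channels`` orders the two reference channels as
    (low_reference, high_reference); ``group_map`` labels each sample
    survivor or nonsurvivor.
    """

    experiment_id: str
    channel_map: Mapping[str, str]
    gis_channels: tuple[str, str]
    group_map: Mapping[str, str]

    def validate(self) -> None:
        channels = set(self.channel_map)
        if not set(self.gis_channels) <= channels:
            raise DesignError(
                f"{self.experiment_id}: GIS channels {self.gis_channels} not in channel map"
            )
        gis = [c for c, s in self.channel_map.items() if s == GIS_MARKER]
        if sorted(gis) != sorted(self.gis_channels) or len(self.gis_channels) != 2:
            raise DesignError(
                f"{self.experiment_id}: exactly two GIS channels required, got {gis}"
            )
        samples = self.samples()
        if len(samples) != len(channels) - 2:
            raise DesignError(f"{self.experiment_id}: duplicate sample within experiment")
        unknown = set(samples) - set(self.group_map)
        if unknown:
            raise DesignError(f"{self.experiment_id}: samples without group label: {sorted(unknown)}")

    def samples(self) -> list[str]:
        return sorted(s for s in self.channel_map.values() if s != GIS_MARKER)

    def sample_channels(self) -> dict[str, str]:
        """channel -> sample ID for the six subject channels."""
        return {c: s for c, s in self.channel_map.items() if s != GIS_MARKER}

    def reference_channel(self, choice: str) -> str:
        if choice == "low":
            return self.gis_channels[0]
        if choice == "high":
            return self.gis_channels[1]
        raise DesignError(f"unknown reference choice {choice!r} (expected 'low' or 'high')")


# A deliberately generic default rule set: the study-specific manual list is
# not public, so these cover the common cases (decoy prefix, cRAP-style
# contaminants, immunoglobulin chains left by antibody-based depletion).
DEFAULT_CONTAMINANTS = frozenset({"P02769", "P00761", "P02662", "P02663", "P02666"})
DEFAULT_DEPLETION_TARGETS = frozenset({"P01857", "P01859", "P01834", "P01871", "P01876"})


@dataclass(frozen=True)
class FilterRules:
    """Accession-level exclusion rules applied before alignment."""

    decoy_prefix: str = "REV_"
    contaminant_accessions: frozenset[str] = DEFAULT_CONTAMINANTS
    depletion_targets: frozenset[str] = DEFAULT_DEPLETION_TARGETS
    manual_exclusions: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "contaminant_accessions", frozenset(a.upper() for a in self.contaminant_accessions))
        object.__setattr__(self, "depletion_targets", frozenset(a.upper() for a in self.depletion_targets))
        object.__setattr__(self, "manual_exclusions", frozenset(a.upper() for a in self.manual_exclusions))
        overlap = (
            (self.contaminant_accessions & self.depletion_targets)
            | (self.contaminant_accessions & self.manual_exclusions)
            | (self.depletion_targets & self.manual_exclusions)
        )
        if overlap:
            raise DesignError(f"filter rule sets overlap on {sorted(overlap)}")


def apply_filters(
    accessions: Iterable[str], rules: FilterRules
) -> tuple[list[str], pd.DataFrame]:
    """Partition accessions into retained and removed (with one reason each).

    Reason precedence: decoy, contaminant, depletion_target, manual.
    """
    retained: list[str] = []
    removed: list[tuple[str, str]] = []
    for acc in accessions:
        norm = acc.upper()
        if rules.decoy_prefix and norm.startswith(rules.decoy_prefix.upper()):
            removed.append((acc, "decoy"))
        elif norm in rules.contaminant_accessions:
            removed.append((acc, "contaminant"))
        elif norm in rules.depletion_targets:
            removed.append((acc, "depletion_target"))
        elif norm in rules.manual_exclusions:
            removed.append((acc, "manual"))
        else:
            retained.append(acc)
    removed_df = pd.DataFrame(removed, columns=["accession", "reason"])
    return retained, removed_df


@dataclass
class MasterQuantTable:
    """Aligned log10 fold changes vs one GIS reference, with per-cell variances.

    ``lfc`` and ``var`` are protein x sample DataFrames with identical shape
    and missingness; ``groups`` maps sample -> outcome group;
    ``n_experiments`` counts contributing experiments per protein;
    ``dropped`` lists excluded proteins with a reason.
    """

    lfc: pd.DataFrame
    var: pd.DataFrame
    groups: pd.Series
    n_experiments: pd.Series
    reference_used: str
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["accession", "reason"]))

    @property
    def samples(self) -> list[str]:
        return list(self.lfc.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


def build_master_table(
    records_by_experiment: Mapping[str, pd.DataFrame],
    designs: Sequence[ExperimentDesign],
    reference_choice: str = "low",
    variance_floor: float = 1e-6,
) -> MasterQuantTable:
    """Align per-experiment ratio records into one master table.

    Every experiment's records must already be expressed against the GIS
    channel selected by *reference_choice*.  Cells without a defined error
    factor (single-peptide ratios) are treated as missing; proteins with
    fewer than two contributing experiments are dropped with reason
    ``insufficient replication``.
    """
    if variance_floor <= 0:
        raise ValueError("variance_floor must be positive")
    design_map = {d.experiment_id: d for d in designs}
    seen_samples: dict[str, str] = {}
    for d in designs:
        d.validate()
        for s in d.samples():
            if s in seen_samples:
                raise DesignError(f"sample {s!r} appears in {seen_samples[s]} and {d.experiment_id}")
            seen_samples[s] = d.experiment_id

    cell_frames: list[pd.DataFrame] = []
    all_accessions: set[str] = set()
    exp_of_cells: list[pd.DataFrame] = []
    for exp_id, records in records_by_experiment.items():
        if exp_id not in design_map:
            raise DesignError(f"records for unknown experiment {exp_id!r}")
        design = design_map[exp_id]
        ref = design.reference_channel(reference_choice)
        all_accessions.update(records["accession"].unique())
        wrong = records.loc[records["reference_channel"] != ref]
        if len(wrong):
            raise DesignError(
                f"{exp_id}: records use reference {wrong['reference_channel'].iloc[0]!r}, "
                f"expected {reference_choice!r} GIS channel {ref!r}"
            )
        ch2s = design.sample_channels()
        sub = records.loc[records["target_channel"].isin(ch2s)].copy()
        sub = sub.loc[np.isfinite(sub["error_factor"].to_numpy(float))]
        if not len(sub):
            continue
        sub["sample_id"] = sub["target_channel"].map(ch2s)
        se = np.log10(sub["error_factor"].to_numpy(float)) / _Z95
        sub["lfc"] = np.log10(sub["ratio"].to_numpy(float))
        sub["var"] = np.maximum(variance_floor, se**2)
        cell_frames.append(sub[["accession", "sample_id", "lfc", "var"]])
        exp_of_cells.append(pd.DataFrame({"accession": sub["accession"].unique(), "experiment_id": exp_id}))

    sample_order = [s for d in designs for s in sorted(d.sample_channels().values())]
    groups = pd.Series({s: design_map[e].group_map[s] for s, e in seen_samples.items()}).reindex(sample_order)

    if cell_frames:
        cells = pd.concat(cell_frames, ignore_index=True)
        lfc = cells.pivot(index="accession", columns="sample_id", values="lfc").reindex(columns=sample_order)
        var = cells.pivot(index="accession", columns="sample_id", values="var").reindex(columns=sample_order)
        n_exp = (
            pd.concat(exp_of_cells, ignore_index=True)
            .groupby("accession")["experiment_id"]
            .nunique()
            .reindex(lfc.index)
        )
    else:
        lfc = pd.DataFrame(columns=sample_order)
        var = pd.DataFrame(columns=sample_order)
        n_exp = pd.Series(dtype=int)

    keep = n_exp[n_exp >= 2].index
    dropped_accs = sorted(all_accessions - set(keep))
    dropped = pd.DataFrame({"accession": dropped_accs, "reason": "insufficient replication"})
    lfc = lfc.loc[keep].sort_index()
    var = var.loc[keep].sort_index()
    n_exp = n_exp.loc[lfc.index].astype(int)
    n_exp.name = "n_experiments"
    return MasterQuantTable(
        lfc=lfc,
        var=var,
        groups=groups,
        n_experiments=n_exp,
        reference_used=reference_choice,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_designs(designs: Sequence[ExperimentDesign], path) -> None:
    rows = []
    for d in designs:
        for channel in sorted(d.channel_map, key=ITRAQ8.index):
            sample = d.channel_map[channel]
            group = d.group_map.get(sample, "") if sample != GIS_MARKER else ""
            rows.append((d.experiment_id, channel, sample, group))
    pd.DataFrame(rows, columns=["experiment_id", "channel", "sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_designs(path) -> list[ExperimentDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    designs = []
    for exp_id, grp in df.groupby("experiment_id", sort=True):
        channel_map = dict(zip(grp["channel"], grp["sample_id"]))
        gis = [c for c in sorted(channel_map, key=ITRAQ8.index) if channel_map[c] == GIS_MARKER]
        if len(gis) != 2:
            raise DesignError(f"{exp_id}: design file must mark exactly two GIS channels")
        group_map = {
            s: g for s, g in zip(grp["sample_id"], grp["group"]) if s != GIS_MARKER
        }
        d = ExperimentDesign(
            experiment_id=str(exp_id),
            channel_map=channel_map,
            gis_channels=(gis[0], gis[1]),
            group_map=group_map,
        )
        d.validate()
        designs.append(d)
    return designs


def write_master_table(master: MasterQuantTable, path) -> None:
    out = pd.DataFrame(index=master.lfc.index)
    for s in master.samples:
        out[f"lfc_{s}"] = master.lfc[s]
        out[f"var_{s}"] = master.var[s]
    out["n_experiments"] = master.n_experiments
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_master_table(path, designs: Sequence[ExperimentDesign], reference_used: str) -> MasterQuantTable:
    df = pd.read_csv(path, sep="\t", index_col="accession")
    samples = [c[4:] for c in df.columns if c.startswith("lfc_")]
    lfc = df[[f"lfc_{s}" for s in samples]].copy()
    lfc.columns = samples
    var = df[[f"var_{s}" for s in samples]].copy()
    var.columns = samples
    group_map = {s: g for d in designs for s, g in d.group_map.items()}
    groups = pd.Series({s: group_map[s] for s in samples}).reindex(samples)
    return MasterQuantTable(
        lfc=lfc,
        var=var,
        groups=groups,
        n_experiments=df["n_experiments"].astype(int),
        reference_used=reference_used,
    )
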