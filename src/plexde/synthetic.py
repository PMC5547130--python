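"""Synthetic multiplexed cohorts with planted ground truth.

Emulates the design of a multi-plex isobaric-labeling outcome study: six
eightplex experiments, each carrying the pooled global internal standard
(GIS) in two fixed reporter channels and six individual subjects in the
remaining channels; 36 subjects split 20 survivors / 16 non-survivors,
randomly placed across plexes and channels.

The generative model is deliberately minimal so that every downstream
stage has an analytically known truth:

    I[protein p, peptide j, channel c] = base_p * 10 ** (effect_{p,c} + eps)
    eps ~ Normal(0, peptide_sigma)   i.i.d. per peptide x channel  (log10)

The channel effect of a subject sample is a per-protein-per-subject
biological deviation (SD ``subject_sigma``) plus, for planted proteins,
a group offset: survivors carry +sign*delta/2 and non-survivors
-sign*delta/2 on the log10 scale, so the planted survivor-minus-
nonsurvivor difference is sign*delta.  GIS channels have effect 0 by
construction (the pool is the same material in every plex).  Detection is
Bernoulli per protein x experiment; peptide counts are uniform over a
configurable range; base abundances are log-uniform over three decades.

Subjects are allocated to plexes in group-balanced blocks and then placed
on channels uniformly at random within each plex, mirroring the stated
within-experiment channel randomization while keeping outcome groups
unconfounded with plex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemble import NONSURVIVOR, SURVIVOR, ExperimentDesign
from .channels import GIS_MARKER, ITRAQ8, intensity_column
from .enrich import GeneSet, GeneSetCollection
from .errors import ConfigurationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the emulated study layout: 6 eightplexes, GIS in the
    first and last channel of every plex, 20 survivors and 16 non-survivors.
    ``effect_size_delta`` is the planted between-group difference in log10
    fold change; ``peptide_sigma`` the SD of peptide-level log10 noise.
    """

    n_experiments: int = 6
    channels_per_experiment: int = 8
    gis_channels: tuple[str, str] = (ITRAQ8[0], ITRAQ8[-1])
    n_survivors: int = 20
    n_nonsurvivors: int = 16
    n_proteins: int = 1000
    n_de: int = 50
    effect_size_delta: float = 0.8
    subject_sigma: float = 0.4
    peptide_sigma: float = 0.1
    peptides_per_protein_range: tuple[int, int] = (15, 45)
    detect_prob: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.channels_per_experiment != 8:
            raise ConfigurationError("channels_per_experiment must be 8 (eightplex labeling)")
        expected = self.n_experiments * (self.channels_per_experiment - 2)
        if self.n_survivors + self.n_nonsurvivors != expected:
            raise ConfigurationError(
                "n_survivors + n_nonsurvivors must equal "
                "n_experiments * (channels_per_experiment - 2): "
                f"{self.n_survivors} + {self.n_nonsurvivors} != {expected}"
            )
        if not 0 <= self.n_de <= self.n_proteins:
            raise ConfigurationError("n_de must satisfy 0 <= n_de <= n_proteins")
        if not 0 < self.detect_prob <= 1:
            raise ConfigurationError("detect_prob must lie in (0, 1]")
        if self.peptide_sigma < 0:
            raise ConfigurationError("peptide_sigma must be >= 0")
        if self.subject_sigma < 0:
            raise ConfigurationError("subject_sigma must be >= 0")
        lo, hi = self.peptides_per_protein_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("peptides_per_protein_range must satisfy 1 <= lo <= hi")
        if len(set(self.gis_channels)) != 2 or not set(self.gis_channels) <= set(ITRAQ8):
            raise ConfigurationError(f"gis_channels must be two distinct labels from {ITRAQ8}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``de_accessions`` maps each planted protein to its signed planted
    log10 group difference (survivor minus non-survivor).
    """

    de_accessions: dict[str, float]
    channel_assignment: dict[tuple[str, str], str]
    accessions: list[str]
    group_map: dict[str, str]
    enriched_set_names: list[str] = field(default_factory=list)

    def de_direction(self, accession: str) -> int:
        return int(np.sign(self.de_accessions[accession]))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ExperimentDesign], list[pd.DataFrame], SyntheticTruth]:
    """Generate designs, per-experiment peptide tables, and the truth object.

    Identical configs (including seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    width = len(str(max(n_p, 1)))
    accessions = [f"P{i:0{width}d}" for i in range(1, n_p + 1)]

    base = 10.0 ** rng.uniform(4.0, 7.0, n_p)  # 3 decades of abundance
    de_idx = rng.choice(n_p, size=config.n_de, replace=False)
    de_signs = rng.choice([-1.0, 1.0], size=config.n_de)
    de_accessions = {
        accessions[i]: float(s * config.effect_size_delta)
        for i, s in sorted(zip(de_idx.tolist(), de_signs.tolist()))
    }
    # per-protein half-offsets applied to survivors (+) and non-survivors (-)
    half = np.zeros(n_p)
    half[de_idx] = de_signs * config.effect_size_delta / 2.0

    survivors = [f"S{i:02d}" for i in range(1, config.n_survivors + 1)]
    nonsurvivors = [f"N{i:02d}" for i in range(1, config.n_nonsurvivors + 1)]
    group_map = {s: SURVIVOR for s in survivors} | {s: NONSURVIVOR for s in nonsurvivors}

    sample_channels = [c for c in ITRAQ8 if c not in config.gis_channels]
    n_sample_ch = len(sample_channels)
    lo, hi = config.peptides_per_protein_range

    # Group-balanced block allocation of subjects to plexes (so outcome is not
    # confounded with plex), then random channel placement within each plex.
    n_exp = config.n_experiments
    surv_counts = np.full(n_exp, config.n_survivors // n_exp)
    extra = rng.choice(n_exp, size=config.n_survivors % n_exp, replace=False)
    surv_counts[extra] += 1
    surv_pool = list(rng.permutation(np.array(survivors, dtype=object)))
    nons_pool = list(rng.permutation(np.array(nonsurvivors, dtype=object)))
    blocks = []
    for e in range(n_exp):
        take_s = int(surv_counts[e])
        block = surv_pool[:take_s] + nons_pool[: n_sample_ch - take_s]
        del surv_pool[:take_s], nons_pool[: n_sample_ch - take_s]
        blocks.append(np.array(block, dtype=object))

    designs: list[ExperimentDesign] = []
    tables: list[pd.DataFrame] = []
    channel_assignment: dict[tuple[str, str], str] = {}
    for e in range(config.n_experiments):
        exp_id = f"EXP{e + 1}"
        chunk = blocks[e][rng.permutation(n_sample_ch)]  # random channel placement
        channel_map = {c: GIS_MARKER for c in config.gis_channels}
        channel_map.update({c: str(s) for c, s in zip(sample_channels, chunk)})
        channel_map = {c: channel_map[c] for c in ITRAQ8}
        design = ExperimentDesign(
            experiment_id=exp_id,
            channel_map=channel_map,
            gis_channels=config.gis_channels,
            group_map={str(s): group_map[str(s)] for s in chunk},
        )
        designs.append(design)
        channel_assignment.update({(exp_id, c): s for c, s in channel_map.items()})

        detected = np.flatnonzero(rng.random(n_p) < config.detect_prob)
        k = rng.integers(lo, hi + 1, size=detected.size)
        prot_rows = np.repeat(detected, k)
        pep_within = np.concatenate([np.arange(1, kk + 1) for kk in k]) if detected.size else np.array([], int)

        # log10 channel effects per protein x channel: group offset plus a
        # per-subject biological deviation; the pooled GIS stays at 0
        subject_dev = rng.normal(0.0, config.subject_sigma, size=(n_p, n_sample_ch)) if config.subject_sigma > 0 else np.zeros((n_p, n_sample_ch))
        effect = np.zeros((prot_rows.size, len(ITRAQ8)))
        si = 0
        for ci, ch in enumerate(ITRAQ8):
            who = channel_map[ch]
            if who == GIS_MARKER:
                continue
            sign = 1.0 if group_map[who] == SURVIVOR else -1.0
            effect[:, ci] = sign * half[prot_rows] + subject_dev[prot_rows, si]
            si += 1
        noise = rng.normal(0.0, config.peptide_sigma, size=effect.shape) if config.peptide_sigma > 0 else np.zeros(effect.shape)
        intensities = base[prot_rows, None] * 10.0 ** (effect + noise)

        table = pd.DataFrame(
            {
                "experiment_id": exp_id,
                "accession": [accessions[i] for i in prot_rows],
                "peptide_id": [f"{accessions[i]}_pep{j}" for i, j in zip(prot_rows, pep_within)],
            }
        )
        for ci, ch in enumerate(ITRAQ8):
            table[intensity_column(ch)] = intensities[:, ci]
        tables.append(table)

    truth = SyntheticTruth(
        de_accessions=de_accessions,
        channel_assignment=channel_assignment,
        accessions=accessions,
        group_map=group_map,
    )
    return designs, tables, truth


def generate_genesets(
    truth: SyntheticTruth,
    n_sets: int,
    set_size_range: tuple[int, int],
    enrichment_fraction: float,
    seed: int,
    n_enriched: int | None = None,
) -> GeneSetCollection:
    """Gene sets over the synthetic proteins, some enriched for planted effects.

    The first ``n_enriched`` sets (default ``n_sets // 4``) draw
    ``enrichment_fraction`` of their members from the planted differential
    proteins, annotated with the planted sign as the expected direction;
    all other members are drawn uniformly from the protein universe with
    direction 0.  Enriched set names are recorded on *truth*.
    """
    lo, hi = set_size_range
    n_prot = len(truth.accessions)
    if not 1 <= lo <= hi:
        raise ConfigurationError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > n_prot:
        raise ConfigurationError(
            f"set_size_range upper bound {hi} exceeds protein count {n_prot}"
        )
    if not 0 <= enrichment_fraction <= 1:
        raise ConfigurationError("enrichment_fraction must lie in [0, 1]")
    if n_enriched is None:
        n_enriched = n_sets // 4
    if n_enriched > n_sets:
        raise ConfigurationError("n_enriched cannot exceed n_sets")

    rng = np.random.default_rng(seed)
    de_accs = list(truth.de_accessions)
    universe = np.array(truth.accessions, dtype=object)
    sets: list[GeneSet] = []
    enriched_names: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members: dict[str, int] = {}
        if i < n_enriched:
            name = f"ENRSET{i + 1:02d}"
            enriched_names.append(name)
            n_from_de = min(round(enrichment_fraction * size), len(de_accs))
            picked = rng.choice(len(de_accs), size=n_from_de, replace=False)
            for j in sorted(picked.tolist()):
                members[de_accs[j]] = truth.de_direction(de_accs[j])
        else:
            name = f"RANDSET{i + 1:02d}"
        while len(members) < size:
            extra = rng.choice(n_prot, size=size - len(members), replace=False)
            for j in extra.tolist():
                acc = str(universe[j])
                members.setdefault(acc, 0)
        sets.append(GeneSet(name=name, members=members))
    truth.enriched_set_names = enriched_names
    return GeneSetCollection(sets=sets)
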