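"""Generate a synthetic multiplexed cohort with planted truth.

Six eightplex experiments, two pooled-reference (GIS) channels each, 36
subjects (20 survivors / 16 non-survivors), 1,000 proteins of which 50
carry a planted log10 group difference of +-0.8.
"""

from plexde import SyntheticConfig, generate_cohort

config = SyntheticConfig(seed=1)
designs, peptide_tables, truth = generate_cohort(config)

print(f"experiments : {len(designs)}")
print(f"subjects    : {sum(len(d.samples()) for d in designs)} "
      f"({sum(1 for g in truth.group_map.values() if g == 'survivor')} survivors)")
print(f"peptide rows: {sum(len(t) for t in peptide_tables)}")
print(f"planted DE  : {len(truth.de_accessions)} proteins, e.g. "
      f"{list(truth.de_accessions.items())[:3]}")
d = designs[0]
print(f"{d.experiment_id} channel map: {dict(d.channel_map)}")
# each experiment carries the GIS pool in channels 113 and 121; the planted
# effects (signed log10 survivor-minus-nonsurvivor differences) are the
# ground truth every downstream stage is scored against.
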