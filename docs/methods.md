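# Methods

## The analysis model

The pipeline targets multi-plex isobaric-labeling studies in which a pooled
global internal standard (GIS) occupies two reporter channels of every plex
and the remaining channels hold individual subjects from two outcome groups.
All quantification is ratio-based against the GIS, which makes log10 fold
changes comparable across plexes; the duplicated GIS channel provides both a
built-in false-positive diagnostic (its self-ratio is exactly 1) and a
second, independent reference against which the whole differential analysis
can be repeated.

### Protein roll-up

For one protein in one plex, peptides with strictly positive intensity in
both channels contribute r_j = log10(I_target,j / I_ref,j). The protein
ratio is 10^mean(r), the p-value a two-sided one-sample t-test of {r_j}
against 0 (df = k−1), and the error factor EF = 10^(t_{0.975,k−1}·sd(r)/√k).
Zero intensities are treated as missing — no pseudo-counts — so a protein
without a usable peptide pair is simply absent from that plex. With a single
usable peptide the ratio is reported but p and EF are undefined; such cells
never enter downstream variance weighting. Proprietary vendor corrections
(bias/background) are deliberately not reproduced: the roll-up is the
documented, testable geometric-mean form, and equivalence with vendor output
is not claimed.

Degenerate cases: zero peptide spread with a zero mean yields (ratio 1,
p = 1, EF = 1); zero spread with a nonzero mean yields p = 0, EF = 1; a
target equal to the reference is the exact identity record.

### Master-table assembly

Cells carry lfc = log10(ratio) and var = max(floor, (log10 EF / 1.96)²).
The normal multiplier is used because ratio tables in the wild (vendor
exports) do not reliably carry peptide counts; the EF already encodes the
t-quantile, so this conversion *inflates* the variance of low-peptide-count
cells relative to a plain SE², a mild and welcome regularization of their
weights. The variance floor (default 1e-6 on the log10² scale) exists only
to prevent infinite weights from degenerate EF = 1 cells. Proteins are kept
when they appear with a defined EF in at least two plexes; dropped proteins
are listed with a reason so that row count + dropped count always equals the
number of quantified accessions (a conservation law the tests enforce).
Accession matching is exact-string; isoform collapsing is out of scope.

### Weighted differential testing

Per protein, groups are compared with the inverse-variance-weighted
two-sample t-test (pooled variant by default, matching a weighted
PROC-TTEST-style analysis; Welch with Satterthwaite df is available).
Samples missing a protein are dropped from that protein's test; a group
with fewer than two observations yields no test. Storey q-values use a
single fixed λ = 0.5 with π0 clamped to [1/m, 1]; one correction is applied
per GIS reference, and the consensus flag requires q ≤ 0.05 under both
references. Two-sided tests throughout; direction is reported as the sign
of the survivor-minus-nonsurvivor weighted mean, not via one-sided testing.

**Calibration caveat (our own measurement).** With weights estimated from
peptide-level spread, the weighted t is mildly anti-conservative: across
seeded null cohorts at the default settings the empirical type-I error at
p < 0.05 is about 0.06–0.085 (mean ≈ 0.074) rather than 0.05. The cause is
dispersion of the estimated weights — a protein-by-protein lottery in which
cells with accidentally small variance estimates dominate their group mean.
With oracle (true-variance) weights the same statistic is exactly
calibrated, which isolates weight estimation as the sole source. This is a
property of the method class, not of the implementation. The dual-reference
consensus absorbs most of the excess: on null cohorts the consensus count at
q ≤ 0.05 is 0–1 per 1,000 proteins even when per-reference counts are
inflated. Interpret single-reference p-values near 0.05 with caution;
consensus calls are the intended output.

### Duplicate-GIS calibration

Per plex, proteins whose GIS-high vs GIS-low ratio has p < α (default 0.05)
are counted as quantification false positives; single-peptide ratios are
excluded from the tested denominator. The report is diagnostic only — no
correction is derived from it. On null synthetic cohorts the counts sit in
the Binomial(n, α) band, and the fraction converges to α as the protein
count grows.

### Pathway over-representation and activation z

The differential list for enrichment is the consensus set. The universe
defaults to all quantified gene symbols (the defensible analogue of a
knowledge-base universe, which is not reconstructable); union-of-sets and
explicit universes are supported. Each set gets the right-tailed Fisher
exact p — the hypergeometric tail P(X ≥ k) — with one Benjamini–Hochberg
correction across sets and a significance flag at −log10(adjusted p) ≥ 1.3,
algebraically identical to adjusted p ≤ 0.05. Direction-annotated members
contribute to the unweighted activation z-score
(n_con − n_dis)/√(n_con + n_dis); a set with no annotated overlap gets no
z-score. When several proteins map to one symbol the observed direction is
the majority sign, ties unannotated. Note that the step-up adjustment is
order-invariant and monotone but *not* idempotent: re-adjusting already
adjusted values generally raises them, so adjusted p-values must never be
fed back through the correction.

## The synthetic cohort generator

The generator emulates the study design end to end: 6 eightplexes with the
GIS fixed in channels 113 and 121, 36 subjects (20 survivors / 16
non-survivors) allocated to plexes in group-balanced blocks and placed on
channels uniformly at random within each plex. Balanced allocation keeps
outcome unconfounded with plex — with fully random allocation, a plex that
happens to hold five survivors and one non-survivor couples the shared
reference-channel noise into the group contrast and the null behaviour of
the downstream test becomes a per-cohort lottery.

Channel intensities follow
`base_p · 10^(group offset + subject deviation + peptide noise)`:

| parameter | default | meaning / why |
| --- | --- | --- |
| `n_proteins` | 1000 | order of the retained-protein count in a depleted BALF experiment |
| `n_de` | 50 | planted differential subset |
| `effect_size_delta` | 0.8 | planted log10 survivor−nonsurvivor difference; strong but below the 1.5–2.4 range of the most extreme reported fold changes |
| `subject_sigma` | 0.4 | SD of per-subject per-protein biological deviation (log10); chosen so group SEs at n≈13–20 land in the 0.05–0.2 range reported for weighted fold changes |
| `peptide_sigma` | 0.1 | SD of i.i.d. log10 reporter noise per peptide × channel |
| `peptides_per_protein_range` | (15, 45) | quantifiable measurements per protein per run, matching ~25–44 spectra/protein in the emulated study's search summary |
| `detect_prob` | 0.8 | per-protein per-plex detection, producing realistic cross-plex missingness |

Base abundances are log-uniform over three decades so roll-up tests span
intensity ranges; abundance cancels in ratios. GIS channels carry effect 0:
the pool is identical material in every plex (pooling proportions among its
donors are not modelled — it is treated as one homogeneous reference).
Identical configs produce bit-identical output.

What the generator does **not** model: spectra, m/z, isotopic impurity,
retention time, peptide-specific ionization bias, shared-peptide protein
inference, or heavy-tailed peptide-count distributions (real cohorts have
many one-peptide proteins and a long right tail; the uniform range
understates weight dispersion, so real-data type-I inflation of the
single-reference weighted test is plausibly larger than the simulated
0.06–0.085). Passing tests therefore demonstrate correctness of the
statistical machinery and honest behaviour under a realistic-but-idealized
noise model, not performance on any particular real dataset.

Gene sets are drawn over the synthetic proteins; designated enriched sets
take a configurable fraction of members from the planted proteins,
annotated with the planted sign as the expected direction, remaining
members uniform with direction 0. The direction-annotated GMT dialect
appends `:+1` / `:-1` to member symbols; plain GMT reads back with all
directions 0.

## Numerical and design decisions

- Log base 10 throughout, the reporting convention for iTRAQ ratios.
- Re-referencing between the two GIS channels recomputes from peptide level
  rather than dividing ratios, so p and EF are exact for the new reference;
  on full-coverage data the chained-ratio identity and the A→B→A round trip
  hold to 1e-9 and are asserted in tests.
- π0 at a single fixed λ rather than the λ-grid smoother: reproducible and
  adequate at m ≈ 1000; forcing π0 = 1 reproduces Benjamini–Hochberg
  exactly, which the tests exploit as an oracle.
- Filter rules ship with generic defaults (decoy prefix `REV_`, a small
  cRAP-style contaminant list, immunoglobulin chains as depletion targets);
  a study-specific manual exclusion list is the caller's responsibility.
  Each removed accession carries exactly one reason, with precedence
  decoy → contaminant → depletion target → manual.
- Reported problem sizes in tests: unit tests run two-plex cohorts of ~120
  proteins; cohort-level checks use the full 6-plex design at 1,000
  proteins, with the recovery/false-discovery battery averaged over 20
  seeded replicates.

## Known limitations

- Single-reference p-values are anti-conservative by roughly half their
  nominal level at p ≈ 0.05 (see the calibration caveat); the consensus set
  is the calibrated deliverable.
- EF and p-value computation is this package's documented form; numerical
  equivalence with proprietary search-engine output is not claimed.
- No protein inference, isotope-impurity correction, or loading
  normalization beyond the reference ratio itself.
- The enrichment universe is a modelling choice; conclusions can shift with
  it, which is why the policy is explicit and configurable.
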