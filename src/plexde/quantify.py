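"""Peptide-to-protein roll-up of reporter-ion intensities.

Quantification in isobaric-label experiments is ratio based: every peptide
contributes a reporter-ion intensity per channel, and a protein's abundance
in a target channel relative to a reference channel is summarised from the
per-peptide log10 ratios.  The roll-up here is the geometric mean of the
peptide ratios, with a one-sample t-test of the log ratios against 0 and a
multiplicative 95% confidence half-width, the *error factor* (EF):

    ratio = 10 ** mean(r_j)          r_j = log10(I_target,j / I_ref,j)
    p     = two-sided t-test of {r_j} vs 0, df = k - 1
    EF    = 10 ** (t_{0.975, k-1} * sd(r) / sqrt(k))

so the 95% CI of the ratio is [ratio / EF, ratio * EF].  With a single
usable peptide the ratio is reported but p and EF are undefined (NaN).
Zero intensities mark missing reporter ions and the peptide is dropped for
that channel pair; no pseudo-counts are added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .channels import ITRAQ8, intensity_column
from .errors import DesignError

#: Columns of a protein-ratio table (also the on-disk TSV schema).
RATIO_COLUMNS = (
    "experiment_id",
    "accession",
    "reference_channel",
    "target_channel",
    "ratio",
    "p_value",
    "error_factor",
    "n_peptides",
)

#: Columns of a peptide-quant table.
PEPTIDE_COLUMNS = ("experiment_id", "accession", "peptide_id") + tuple(
    intensity_column(c) for c in ITRAQ8
)


@dataclass(frozen=True)
class ProteinRatioRecord:
    """One protein x one target channel x one reference channel.

    ``p_value`` and ``error_factor`` are NaN when only one usable peptide
    supported the ratio.
    """

    experiment_id: str
    accession: str
    reference_channel: str
    target_channel: str
    ratio: float
    p_value: float
    error_factor: float
    n_peptides: int


def _summarise_log_ratios(r: np.ndarray) -> tuple[float, float, float]:
    """(ratio, p, EF) from a vector of per-peptide log10 ratios."""
    k = r.size
    mean = float(np.mean(r))
    ratio = float(10.0 ** mean)
    if k < 2:
        return ratio, float("nan"), float("nan")
    sd = float(np.std(r, ddof=1))
    if sd == 0.0:
        # degenerate spread: the ratio is measured without dispersion
        return ratio, (1.0 if mean == 0.0 else 0.0), 1.0
    se = sd / np.sqrt(k)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), k - 1))
    ef = float(10.0 ** (stats.t.ppf(0.975, k - 1) * se))
    return ratio, p, ef


def protein_rollup(
    peptides: pd.DataFrame,
    reference_channel: str,
    target_channel: str,
) -> ProteinRatioRecord | None:
    """Roll one protein's peptides (one experiment) up to a ratio record.

    *peptides* must contain rows for exactly one (experiment, accession)
    pair.  Returns ``None`` when no peptide has strictly positive intensity
    in both channels (a missing-record signal).
    """
    acc = peptides["accession"].unique()
    exp = peptides["experiment_id"].unique()
    if len(acc) != 1 or len(exp) != 1:
        raise ValueError("protein_rollup expects one protein in one experiment")
    ref_col = intensity_column(reference_channel)
    tgt_col = intensity_column(target_channel)
    ok = (peptides[ref_col].to_numpy() > 0) & (peptides[tgt_col].to_numpy() > 0)
    k = int(ok.sum())
    if k == 0:
        return None
    if target_channel == reference_channel:
        ratio, p, ef = 1.0, 1.0, 1.0
    else:
        r = np.log10(
            peptides.loc[ok, tgt_col].to_numpy() / peptides.loc[ok, ref_col].to_numpy()
        )
        ratio, p, ef = _summarise_log_ratios(r)
    return ProteinRatioRecord(
        experiment_id=str(exp[0]),
        accession=str(acc[0]),
        reference_channel=reference_channel,
        target_channel=target_channel,
        ratio=ratio,
        p_value=p,
        error_factor=ef,
        n_peptides=k,
    )


def rollup_experiment(
    peptides: pd.DataFrame,
    reference_channel: str,
    target_channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Roll every protein in one experiment's peptide table up against a reference.

    Vectorised equivalent of calling :func:`protein_rollup` per protein and
    target channel.  Proteins without any usable peptide pair for a target
    are simply absent from that target's rows.
    """
    channels = [c for c in ITRAQ8 if intensity_column(c) in peptides.columns]
    if reference_channel not in channels:
        raise DesignError(f"reference channel {reference_channel!r} not in table")
    if target_channels is None:
        target_channels = [c for c in channels if c != reference_channel]
    exp_ids = peptides["experiment_id"].unique()
    if len(exp_ids) != 1:
        raise ValueError("rollup_experiment expects a single experiment")
    exp_id = str(exp_ids[0])

    ref = peptides[intensity_column(reference_channel)].to_numpy(float)
    acc = peptides["accession"].to_numpy()
    frames: list[pd.DataFrame] = []
    for tgt in target_channels:
        tgt_arr = peptides[intensity_column(tgt)].to_numpy(float)
        ok = (ref > 0) & (tgt_arr > 0)
        if not ok.any():
            continue
        sub_acc = acc[ok]
        if tgt == reference_channel:
            counts = pd.Series(sub_acc).value_counts().sort_index()
            frame = pd.DataFrame(
                {
                    "accession": counts.index,
                    "ratio": 1.0,
                    "p_value": 1.0,
                    "error_factor": 1.0,
                    "n_peptides": counts.to_numpy(),
                }
            )
        else:
            r = np.log10(tgt_arr[ok] / ref[ok])
            g = pd.Series(r).groupby(sub_acc)
            k = g.size().to_numpy()
            mean = g.mean().to_numpy()
            sd = g.std(ddof=1).to_numpy()  # NaN where k == 1
            ratio = 10.0 ** mean
            p = np.full(mean.shape, np.nan)
            ef = np.full(mean.shape, np.nan)
            multi = k >= 2
            zero_sd = multi & (sd == 0.0)
            pos_sd = multi & (sd > 0.0)
            se = np.where(pos_sd, sd / np.sqrt(k), np.nan)
            with np.errstate(invalid="ignore"):
                tstat = np.where(pos_sd, mean / se, np.nan)
            p[pos_sd] = 2.0 * stats.t.sf(np.abs(tstat[pos_sd]), k[pos_sd] - 1)
            ef[pos_sd] = 10.0 ** (stats.t.ppf(0.975, k[pos_sd] - 1) * se[pos_sd])
            p[zero_sd] = np.where(mean[zero_sd] == 0.0, 1.0, 0.0)
            ef[zero_sd] = 1.0
            frame = pd.DataFrame(
                {
                    "accession": g.size().index,
                    "ratio": ratio,
                    "p_value": p,
                    "error_factor": ef,
                    "n_peptides": k,
                }
            )
        frame.insert(0, "experiment_id", exp_id)
        frame.insert(2, "reference_channel", reference_channel)
        frame.insert(3, "target_channel", tgt)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=list(RATIO_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["target_channel", "accession"], ignore_index=True)


def rereference(
    records: pd.DataFrame,
    peptides: pd.DataFrame,
    new_reference: str,
) -> pd.DataFrame:
    """Recompute ratio records against a different reference channel.

    Ratios are re-derived from the peptide level (not by dividing existing
    ratios) so the p-value and error factor are exact for the new reference.
    The returned table covers the union of the old records' target channels
    and their old reference, so chained ratios remain available.
    """
    channels = [c for c in ITRAQ8 if intensity_column(c) in peptides.columns]
    if new_reference not in channels:
        raise DesignError(f"channel {new_reference!r} not in the experiment design")
    targets = sorted(
        set(records["target_channel"]) | set(records["reference_channel"]),
        key=ITRAQ8.index,
    )
    return rollup_experiment(peptides, new_reference, target_channels=targets)


def write_ratio_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=list(RATIO_COLUMNS))


def read_ratio_table(path) -> pd.DataFrame:
    """Read a protein-ratio TSV (also the ingestion point for vendor exports)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "experiment_id": str,
            "accession": str,
            "reference_channel": str,
            "target_channel": str,
        },
    )
    missing = set(RATIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratio table missing columns: {sorted(missing)}")
    return df


def write_peptide_table(peptides: pd.DataFrame, path) -> None:
    peptides.to_csv(path, sep="\t", index=False, columns=list(PEPTIDE_COLUMNS))


def read_peptide_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "accession": str, "peptide_id": str})
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def split_experiments(peptides: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a concatenated peptide table into per-experiment tables."""
    return {
        str(exp): grp.reset_index(drop=True)
        for exp, grp in peptides.groupby("experiment_id", sort=True)
    }
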