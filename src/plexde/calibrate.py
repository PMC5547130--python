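"""Duplicate-reference false-positive calibration.

The pooled global internal standard (GIS) occupies two reporter channels
of every plex, so the GIS-vs-GIS protein ratio has a true value of exactly
1.  Any protein whose GIS-high vs GIS-low ratio differs significantly
from 1 is therefore an empirical quantification false positive, and the
per-experiment count is a direct diagnostic of quantitative quality.  The
calibration is diagnostic only; no correction is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .assemble import ExperimentDesign
from .errors import DesignError


@dataclass(frozen=True)
class CalibrationReport:
    experiment_id: str
    n_proteins_tested: int
    alpha: float
    n_false_positive: int

    @property
    def fraction(self) -> float:
        if self.n_proteins_tested == 0:
            return float("nan")
        return self.n_false_positive / self.n_proteins_tested

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction"] = self.fraction
        return d


def gis_false_positive_count(
    records: pd.DataFrame,
    design: ExperimentDesign,
    alpha: float = 0.05,
) -> CalibrationReport:
    """Count proteins whose GIS-vs-GIS ratio is significantly different from 1.

    *records* are one experiment's ratio records referenced to the low GIS
    channel; the rows tested are those targeting the high GIS channel.
    Proteins without a defined p-value (single-peptide ratios) are excluded
    from the tested count.  Significance is p < alpha.
    """
    design.validate()
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    gis_low, gis_high = design.gis_channels
    sub = records.loc[
        (records["experiment_id"] == design.experiment_id)
        & (records["reference_channel"] == gis_low)
        & (records["target_channel"] == gis_high)
    ]
    if not len(sub):
        raise DesignError(
            f"{design.experiment_id}: no GIS-vs-GIS records "
            f"(target {gis_high} vs reference {gis_low})"
        )
    p = sub["p_value"].to_numpy(float)
    tested = np.isfinite(p)
    n_fp = int((p[tested] < alpha).sum())
    return CalibrationReport(
        experiment_id=design.experiment_id,
        n_proteins_tested=int(tested.sum()),
        alpha=alpha,
        n_false_positive=n_fp,
    )


def write_calibration_table(reports, path) -> None:
    pd.DataFrame([r.to_dict() for r in reports])[
        ["experiment_id", "n_proteins_tested", "alpha", "n_false_positive", "fraction"]
    ].to_csv(path, sep="\t", index=False)
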