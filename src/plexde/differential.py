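"""Inverse-variance-weighted differential expression with Storey FDR.

Per protein, the two outcome groups' log10 fold changes (vs the GIS) are
compared with a weighted two-sample t-test whose weights are the inverse
of each cell's roll-up variance:

    w_i   = 1 / v_i
    xbar  = sum(w_i x_i) / sum(w_i)
    s2_w  = sum(w_i (x_i - xbar)^2) / (n - 1)

pooled variant (default, the SAS-style weighted t):
    s2_p = ((n1-1) s2_w1 + (n2-1) s2_w2) / (n1 + n2 - 2)
    t    = (xbar1 - xbar2) / sqrt(s2_p (1/sum(w1) + 1/sum(w2)))
    df   = n1 + n2 - 2

welch variant: per-group Var_g = s2_wg / sum(w_g) with Satterthwaite df.

Multiple testing uses Storey's q-value with a fixed tuning parameter:
    pi0   = clamp(#{p_i > lambda} / (m (1 - lambda)), 1/m, 1)
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j          (p sorted ascending)

The analysis is run once per GIS reference (low and high channel); a
protein is a *consensus* call when q <= threshold under both references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assemble import NONSURVIVOR, SURVIVOR, MasterQuantTable


@dataclass(frozen=True)
class GroupSummary:
    n: int
    weighted_mean: float
    se: float
    sum_weights: float
    weighted_variance: float


@dataclass(frozen=True)
class WeightedTestResult:
    group1: GroupSummary
    group2: GroupSummary
    t: float
    df: float
    p: float
    variant: str


def _group_summary(x: np.ndarray, v: np.ndarray) -> GroupSummary:
    w = 1.0 / v
    sw = float(w.sum())
    xbar = float((w * x).sum() / sw)
    n = x.size
    s2w = float((w * (x - xbar) ** 2).sum() / (n - 1))
    se = float(np.sqrt(s2w / sw))
    return GroupSummary(n=n, weighted_mean=xbar, se=se, sum_weights=sw, weighted_variance=s2w)


def weighted_two_sample_t(
    x1, v1, x2, v2, variant: str = "pooled"
) -> WeightedTestResult:
    """Weighted two-sample t-test with inverse-variance weights.

    With unit weights the pooled variant reduces exactly to the classical
    equal-variance two-sample t-test.  Each group needs at least two
    observations; all variances must be strictly positive.
    """
    x1 = np.asarray(x1, float)
    v1 = np.asarray(v1, float)
    x2 = np.asarray(x2, float)
    v2 = np.asarray(v2, float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs n >= 2 observations")
    if (v1 <= 0).any() or (v2 <= 0).any():
        raise ValueError("variances must be strictly positive")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    g1 = _group_summary(x1, v1)
    g2 = _group_summary(x2, v2)
    diff = g1.weighted_mean - g2.weighted_mean
    if variant == "pooled":
        df = g1.n + g2.n - 2
        s2p = ((g1.n - 1) * g1.weighted_variance + (g2.n - 1) * g2.weighted_variance) / df
        denom = np.sqrt(s2p * (1.0 / g1.sum_weights + 1.0 / g2.sum_weights))
    else:
        var1 = g1.weighted_variance / g1.sum_weights
        var2 = g2.weighted_variance / g2.sum_weights
        denom = np.sqrt(var1 + var2)
        df = (var1 + var2) ** 2 / (var1**2 / (g1.n - 1) + var2**2 / (g2.n - 1))
    if denom == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / denom
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WeightedTestResult(group1=g1, group2=g2, t=float(t), df=float(df), p=p, variant=variant)


@dataclass(frozen=True)
class QValueResult:
    p: np.ndarray
    pi0: float
    lam: float
    q: np.ndarray


def storey_qvalues(p, lam: float = 0.5, pi0: float | None = None) -> QValueResult:
    """Storey q-values with a single fixed lambda.

    ``pi0`` may be supplied to override the estimate (``pi0=1`` reproduces
    the Benjamini-Hochberg adjustment exactly).
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return QValueResult(p=p, pi0=1.0, lam=lam, q=p.copy())
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    m = p.size
    if pi0 is None:
        pi0 = float(np.clip((p > lam).sum() / (m * (1.0 - lam)), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p=p, pi0=pi0, lam=lam, q=q)


def _reference_tests(master: MasterQuantTable, variant: str) -> pd.DataFrame:
    surv = master.group_samples(SURVIVOR)
    nons = master.group_samples(NONSURVIVOR)
    rows = []
    lfc_s = master.lfc[surv].to_numpy(float)
    var_s = master.var[surv].to_numpy(float)
    lfc_n = master.lfc[nons].to_numpy(float)
    var_n = master.var[nons].to_numpy(float)
    for i, acc in enumerate(master.lfc.index):
        ok_s = ~np.isnan(lfc_s[i])
        ok_n = ~np.isnan(lfc_n[i])
        if ok_s.sum() < 2 or ok_n.sum() < 2:
            rows.append((acc, int(ok_s.sum()), np.nan, np.nan, int(ok_n.sum()), np.nan, np.nan, np.nan, np.nan))
            continue
        res = weighted_two_sample_t(
            lfc_s[i, ok_s], var_s[i, ok_s], lfc_n[i, ok_n], var_n[i, ok_n], variant
        )
        rows.append(
            (
                acc,
                res.group1.n,
                res.group1.weighted_mean,
                res.group1.se,
                res.group2.n,
                res.group2.weighted_mean,
                res.group2.se,
                res.t,
                res.p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "n_survivor",
            "mean_survivor",
            "se_survivor",
            "n_nonsurvivor",
            "mean_nonsurvivor",
            "se_nonsurvivor",
            "t",
            "p",
        ],
    ).set_index("accession")


def run_differential(
    master_low: MasterQuantTable,
    master_high: MasterQuantTable,
    q_threshold: float = 0.05,
    variant: str = "pooled",
    lam: float = 0.5,
) -> pd.DataFrame:
    """Dual-reference differential analysis with consensus calls.

    Returns one row per protein present in either master table, with the
    weighted test, Storey q and significance flag under each GIS reference
    (one Storey correction per reference), a ``consensus`` flag (q below
    threshold under both), and ``direction`` = sign(survivor - nonsurvivor
    weighted mean) for downstream pathway analysis.
    """
    if set(master_low.samples) != set(master_high.samples):
        raise ValueError("the two master tables must cover the same samples")
    pieces = {}
    for name, master in (("low", master_low), ("high", master_high)):
        tests = _reference_tests(master, variant)
        valid = tests["p"].notna()
        q = np.full(len(tests), np.nan)
        if valid.any():
            q[valid.to_numpy()] = storey_qvalues(tests.loc[valid, "p"].to_numpy(), lam=lam).q
        tests["q"] = q
        tests["significant"] = tests["q"] <= q_threshold
        pieces[name] = tests.add_suffix(f"_{name}")
    out = pieces["low"].join(pieces["high"], how="outer")
    for col in ("significant_low", "significant_high"):
        out[col] = out[col].astype("boolean").fillna(False).astype(bool)
    out["consensus"] = out["significant_low"] & out["significant_high"]
    delta = out["mean_survivor_low"] - out["mean_nonsurvivor_low"]
    fallback = out["mean_survivor_high"] - out["mean_nonsurvivor_high"]
    delta = delta.fillna(fallback)
    out["direction"] = np.sign(delta).fillna(0).astype(int)
    return out.sort_index()


def write_differential_table(diff: pd.DataFrame, path) -> None:
    out = diff.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_differential_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="accession")
    for col in ("significant_low", "significant_high", "consensus"):
        df[col] = df[col].astype(bool)
    return df
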