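"""Direction-aware gene-set over-representation analysis.

Given the consensus differential proteins and a fixed gene-set collection
(GMT), each set is scored by the right-tailed Fisher exact test — the
hypergeometric tail probability of drawing at least k set members among
the n differential genes from a universe of N — followed by a single
Benjamini-Hochberg correction across sets and a significance call at
-log10(adjusted p) >= 1.3 (equivalently adjusted p <= 0.05).

Sets may annotate members with an expected direction (+1 activation-
consistent, -1 inhibition-consistent, 0 unannotated).  The activation
z-score summarises net concordance of the observed fold-change directions
with those annotations:

    z = (n_concordant - n_discordant) / sqrt(n_concordant + n_discordant)

and is undefined (NaN) when no overlapping gene carries an annotation.
A positive z predicts activation in survivors (observed direction is the
sign of the survivor-minus-nonsurvivor weighted mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; members map symbol -> expected direction in {+1,-1,0}."""

    name: str
    members: Mapping[str, int]
    description: str = ""

    def __post_init__(self):
        bad = {d for d in self.members.values() if d not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"{self.name}: directions must be -1, 0 or +1, got {bad}")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe_policy: str = "all_quantified"

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the one-sided Fisher p."""
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def fisher_enrichment(
    de_genes: set[str], gene_set: Iterable[str], universe: set[str]
) -> tuple[int, int, int, int, float]:
    """Right-tailed Fisher exact test of set over-representation.

    Returns (k, K, n, N): overlap, set size in universe, DE genes in
    universe, universe size — and the hypergeometric right-tail
    P(X >= k).
    """
    if not universe:
        raise ValueError("universe is empty")
    members = set(gene_set) & universe
    de = set(de_genes) & universe
    N = len(universe)
    K = len(members)
    n = len(de)
    k = len(de & members)
    return k, K, n, N, fisher_right_tail(k, K, n, N)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def activation_zscore(
    overlap_genes: Sequence[tuple[int, int]],
) -> tuple[float, int, int]:
    """Net concordance z over direction-annotated overlap genes.

    *overlap_genes* holds (observed_direction, expected_direction) pairs;
    genes with expected direction 0 do not contribute.  Returns
    (z, n_concordant, n_discordant); z is NaN with no annotated genes.
    """
    n_con = n_dis = 0
    for obs, exp in overlap_genes:
        if exp == 0 or obs == 0:
            continue
        if obs * exp == 1:
            n_con += 1
        else:
            n_dis += 1
    if n_con + n_dis == 0:
        return float("nan"), 0, 0
    return (n_con - n_dis) / math.sqrt(n_con + n_dis), n_con, n_dis


def run_enrichment(
    diff: pd.DataFrame,
    sets: GeneSetCollection,
    q_threshold: float = 0.05,
    neglog_threshold: float = 1.3,
    universe: set[str] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Score every gene set against the consensus differential proteins.

    *diff* is the differential table (indexed by accession, with
    ``consensus`` and ``direction`` columns).  Accessions map to gene
    symbols through *symbol_map* (identity by default, case-normalised).
    The universe follows the collection's policy: all quantified genes
    (default), the union of set members, or an explicit set.  One B-H
    correction is applied across all sets; results are sorted by
    -log10(adjusted p), descending.
    """
    if symbol_map is None:
        to_symbol = {acc: str(acc).upper() for acc in diff.index}
    else:
        to_symbol = {acc: symbol_map[acc].upper() for acc in diff.index if acc in symbol_map}

    direction = {}
    de_genes: set[str] = set()
    quantified: set[str] = set()
    for acc, sym in to_symbol.items():
        quantified.add(sym)
        row = diff.loc[acc]
        if bool(row["consensus"]):
            de_genes.add(sym)
            # majority sign across proteins sharing a symbol; ties unannotate
            direction[sym] = direction.get(sym, 0) + int(row["direction"])

    if universe is not None:
        uni = {g.upper() for g in universe}
    elif sets.universe_policy == "union_of_sets":
        uni = {g.upper() for s in sets for g in s.members}
    elif sets.universe_policy == "all_quantified":
        uni = quantified
    else:
        raise ValueError(
            f"universe_policy {sets.universe_policy!r} requires an explicit universe"
        )
    de_genes &= uni

    rows = []
    for s in sets:
        members = {g.upper(): d for g, d in s.members.items()}
        k, K, n, N, p = fisher_enrichment(de_genes, members, uni)
        overlap = sorted(de_genes & set(members) & uni)
        pairs = [(int(np.sign(direction.get(g, 0))), members[g]) for g in overlap]
        z, n_con, n_dis = activation_zscore(pairs)
        rows.append((s.name, k, K, n, N, p, z, n_con, n_dis, ",".join(overlap)))
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "k", "K", "n", "N", "p_fisher",
            "z", "n_concordant", "n_discordant", "overlap_genes",
        ],
    )
    if len(out) and out["K"].sum() == 0:
        warnings.warn("no overlap between universe and any gene set")
        return out.iloc[0:0]
    if len(out):
        out["p_bh"] = bh_adjust(out["p_fisher"].to_numpy())
        with np.errstate(divide="ignore"):
            out["neg_log10_bh"] = -np.log10(out["p_bh"])
        out["significant"] = out["neg_log10_bh"] >= neglog_threshold
        out = out.sort_values(
            ["neg_log10_bh", "set_name"], ascending=[False, True], ignore_index=True
        )
    return out


def direction_fractions(
    diff: pd.DataFrame,
    sets: GeneSetCollection,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pathway fractions of members up / down in survivors or absent.

    Stacked-bar-ready: for each set, the fraction of members that are
    consensus-differential with positive direction (up in survivors),
    negative direction (down), or not in the differential list (absent).
    """
    if symbol_map is None:
        to_symbol = {acc: str(acc).upper() for acc in diff.index}
    else:
        to_symbol = {acc: symbol_map[acc].upper() for acc in diff.index if acc in symbol_map}
    sign_of: dict[str, int] = {}
    for acc, sym in to_symbol.items():
        row = diff.loc[acc]
        if bool(row["consensus"]):
            sign_of[sym] = int(row["direction"])
    rows = []
    for s in sets:
        members = [g.upper() for g in s.members]
        size = len(members)
        up = sum(1 for g in members if sign_of.get(g, 0) > 0)
        down = sum(1 for g in members if sign_of.get(g, 0) < 0)
        absent = size - up - down
        rows.append((s.name, size, up / size, down / size, absent / size))
    return pd.DataFrame(
        rows, columns=["set_name", "set_size", "frac_up", "frac_down", "frac_absent"]
    )


# ---------------------------------------------------------------------------
# GMT I/O (direction-annotated dialect: member suffix ":+1" / ":-1")


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            toks = []
            for g, d in s.members.items():
                toks.append(f"{g}:{d:+d}" if d else g)
            desc = s.description or "na"
            fh.write("\t".join([s.name, desc] + toks) + "\n")


def read_gmt(path, universe_policy: str = "all_quantified") -> GeneSetCollection:
    """Read plain or direction-annotated GMT (members may end in ':+1'/':-1')."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, raw = toks[0], toks[1], toks[2:]
            members: dict[str, int] = {}
            for tok in raw:
                if tok.endswith(":+1") or tok.endswith(":-1"):
                    members[tok[:-3]] = int(tok[-2:])
                elif tok:
                    members[tok] = 0
            sets.append(GeneSet(name=name, members=members, description=desc))
    return GeneSetCollection(sets=sets, universe_policy=universe_policy)
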