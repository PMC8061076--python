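"""CpX-resolution enrichment of region sets in genomic features.

Enrichment is computed at the level of individual cytosines (CpGs for
CG-DMR/VMR sets, CpAs/CpTs for CH sets) rather than regions or base pairs:
this accounts for the non-uniform genomic distribution of CpXs and avoids
double-counting regions straddling a feature boundary.  For each feature a
2x2 table is formed::

    n11 = CpXs in regions, inside the feature
    n12 = CpXs in regions, outside the feature
    n21 = CpXs not in regions, inside the feature
    n22 = CpXs not in regions, outside the feature

with log2(OR) = log2(n11) + log2(n22) - log2(n12) - log2(n21), standard
error sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22), an approximate 95% CI of
log2(OR) -/+ 2*se, and a two-sided Fisher exact p-value for the null of
independence.  No continuity correction is applied: any zero cell flags the
result undefined (a Haldane-corrected variant exists behind an explicit
flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicFeatureSet, RegionSet


@dataclass(frozen=True)
class ContingencyTable:
    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


@dataclass
class EnrichmentResult:
    region_set: str
    feature: str
    table: ContingencyTable
    log2_or: float
    se: float
    ci95: tuple[float, float]
    fisher_p: float = float("nan")
    undefined: bool = False
    significant: bool | None = None


def _membership(chrom: np.ndarray, pos0: np.ndarray, intervals) -> np.ndarray:
    """Point-in-interval membership for 0-based positions against merged
    per-chromosome half-open intervals."""
    ch_i, st_i, en_i = intervals
    flags = np.zeros(len(pos0), dtype=bool)
    for c in np.unique(ch_i.astype(str)):
        sel = ch_i.astype(str) == c
        starts, ends = np.sort(st_i[sel]), en_i[sel][np.argsort(st_i[sel])]
        # merge overlapping intervals so searchsorted parity works
        m_starts, m_ends = [], []
        for s0, e0 in zip(starts, ends):
            if m_ends and s0 <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e0)
            else:
                m_starts.append(s0)
                m_ends.append(e0)
        m_starts, m_ends = np.array(m_starts), np.array(m_ends)
        here = chrom.astype(str) == c
        p = pos0[here]
        j = np.searchsorted(m_starts, p, side="right") - 1
        ok = (j >= 0) & (p < m_ends[np.clip(j, 0, len(m_ends) - 1)])
        flags[here] = ok
    return flags


def build_contingency(
    loci: pd.DataFrame, regions: RegionSet, feature: GenomicFeatureSet
) -> ContingencyTable:
    """Classify every locus by region-set and feature membership.

    Membership is by the locus point coordinate (the C position, converted
    to 0-based), consistent with CpX counting.  ``loci`` must already be
    restricted to the relevant context.
    """
    chrom = loci["chrom"].to_numpy()
    pos0 = loci["pos"].to_numpy(np.int64) - 1
    in_region = _membership(chrom, pos0, regions.intervals0())
    in_feature = _membership(chrom, pos0, (feature.chroms, feature.starts, feature.ends))
    n11 = int((in_region & in_feature).sum())
    n12 = int((in_region & ~in_feature).sum())
    n21 = int((~in_region & in_feature).sum())
    n22 = int((~in_region & ~in_feature).sum())
    return ContingencyTable(n11, n12, n21, n22)


def log2_odds_ratio(
    t: ContingencyTable,
    region_set: str = "",
    feature: str = "",
    haldane: bool = False,
) -> EnrichmentResult:
    """Closed-form log2 odds ratio with SE and approximate 95% CI.

    Any zero cell yields an undefined result (NaN estimates, flagged)
    unless ``haldane=True`` adds 0.5 to every cell.
    """
    cells = np.array([t.n11, t.n12, t.n21, t.n22], dtype=float)
    if haldane:
        cells = cells + 0.5
    if (cells == 0).any():
        return EnrichmentResult(
            region_set, feature, t,
            log2_or=float("nan"), se=float("nan"),
            ci95=(float("nan"), float("nan")), undefined=True,
        )
    a, b, c, d = cells
    log2_or = float(np.log2(a) + np.log2(d) - np.log2(b) - np.log2(c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return EnrichmentResult(
        region_set, feature, t, log2_or=log2_or, se=se,
        ci95=(log2_or - 2 * se, log2_or + 2 * se),
    )


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for independence of the 2x2 table."""
    return float(scipy.stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def enrich_batch(
    loci: pd.DataFrame,
    regions: RegionSet,
    features: list[GenomicFeatureSet],
    averaging_groups: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    haldane: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """One enrichment per (region set, feature), long-format.

    Significance is Benjamini-Hochberg adjusted across features within the
    region set at level ``alpha``.  When ``averaging_groups`` maps a group
    name to feature names (e.g. one chromHMM state measured in several
    tissues), the arithmetic mean of log2(OR) within each group is also
    reported; significance is never averaged.
    """
    results: list[EnrichmentResult] = []
    for feat in features:
        table = build_contingency(loci, regions, feat)
        res = log2_odds_ratio(table, regions.kind, feat.name, haldane=haldane)
        res.fisher_p = fisher_exact(table)
        results.append(res)

    pvals = np.array([r.fisher_p for r in results])
    if len(pvals):
        rejected = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        for r, rej in zip(results, rejected):
            r.significant = bool(rej)

    df = pd.DataFrame(
        [
            {
                "region_set": r.region_set, "feature": r.feature,
                "n11": r.table.n11, "n12": r.table.n12,
                "n21": r.table.n21, "n22": r.table.n22,
                "log2_or": r.log2_or, "se": r.se,
                "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "fisher_p": r.fisher_p, "significant": r.significant,
                "undefined": r.undefined,
            }
            for r in results
        ]
    )
    means = None
    if averaging_groups:
        rows = []
        for gname, members in averaging_groups.items():
            vals = df.loc[df["feature"].isin(members), "log2_or"]
            rows.append({"group": gname, "mean_log2_or": float(vals.mean()), "n_features": len(vals)})
        means = pd.DataFrame(rows)
    return df, means
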