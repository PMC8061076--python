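"""Differentially methylated region (DMR) calling on smoothed data.

Per-locus one-way ANOVA F statistics (signed t for two groups) are computed
on smoothed methylation fractions, thresholded at a scale-free cutoff (the
genome-wide 99th percentile by default), and maximal qualifying runs are
segmented into candidate regions scored by ``areaStat`` (sum of locus
statistics) and ``maxStat``.  Family-wise error control is by permutation of
group labels: the full statistic + segmentation pipeline is re-run on each
permuted labelling and the maximum |areaStat| per permutation forms the null
(maxT-style), giving each observed region an add-one permutation p-value
``(1 + #{perm maxima >= |areaStat|}) / (B + 1)``.

Non-CpG (CH) DMRs are the same operations run separately per
dinucleotide/strand stratum — CpA and CpT are not palindromic — with the
``ch`` smoothing preset; the union of the per-stratum region sets is
reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MethregionsError, Region, RegionSet, SampleTable, SmoothedDataset
from . import smoothing as _smoothing

# candidate-entry cutoff: the extreme 5% of the locus statistic, the
# BSmooth-family convention (qcutoff (0.025, 0.975) on two-sided t)
DEFAULT_CUTOFF_QUANTILE = 0.95
DEFAULT_MAX_GAP = {"cg_small": 300, "cg_block": 10_000, "ch": 1_000}
DEFAULT_MIN_LOCI = 3


@dataclass
class LocusStats:
    """Per-locus test statistics with positional context.

    ``stat`` is the ANOVA F (NaN where any group has < 2 non-missing
    samples); for exactly two groups ``t`` additionally carries the signed
    pooled-variance t statistic with ``F = t**2``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    stat: np.ndarray
    group_means: np.ndarray  # (L, k)
    groups: list[str]
    t: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.stat)


def _group_indicator(codes: np.ndarray, k: int) -> np.ndarray:
    G = np.zeros((len(codes), k))
    G[np.arange(len(codes)), codes] = 1.0
    return G


class _FstatWorkspace:
    """Label-independent pieces of the per-locus ANOVA, shared across
    permutations of the group labels."""

    def __init__(self, beta: np.ndarray):
        self.valid = np.isfinite(beta)
        self.b0 = np.where(self.valid, beta, 0.0)
        self.n_tot = self.valid.sum(axis=1)
        self.s_tot = self.b0.sum(axis=1)
        self.sq_tot = (self.b0**2 * self.valid).sum(axis=1)


def _fstat_matrix(beta: np.ndarray, codes: np.ndarray, k: int, ws: _FstatWorkspace | None = None):
    """Vectorized one-way ANOVA across loci with NaN exclusion.

    Returns (F, group_means, t_signed_or_None).
    """
    if ws is None:
        ws = _FstatWorkspace(beta)
    valid, b0 = ws.valid, ws.b0
    G = _group_indicator(codes, k)
    n_g = valid @ G  # (L, k)
    s_g = b0 @ G
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_g = np.where(n_g > 0, s_g / np.maximum(n_g, 1), np.nan)
    n_tot, s_tot = ws.n_tot, ws.s_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = s_tot / n_tot
        ss_tot = ws.sq_tot - n_tot * grand**2
        ssb = (n_g * (np.nan_to_num(mean_g) - grand[:, None]) ** 2 * (n_g > 0)).sum(axis=1)
    ssw = np.maximum(ss_tot - ssb, 0.0)

    df1 = k - 1
    df2 = n_tot - k
    # relative tolerance for detecting an exactly-constant-within-groups locus
    tol = 1e-12 * np.maximum(ss_tot, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / df1) / (ssw / np.maximum(df2, 1))
    zero_both = (ssb <= tol) & (ssw <= tol)
    F = np.where(zero_both, 0.0, F)
    F = np.where((ssw <= tol) & ~zero_both, np.inf, F)
    F = np.where((df2 < 1) | (np.min(n_g, axis=1) < 2), np.nan, F)

    t = None
    if k == 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            sp2 = ssw / np.maximum(df2, 1)
            se = np.sqrt(sp2 * (1.0 / np.maximum(n_g[:, 0], 1) + 1.0 / np.maximum(n_g[:, 1], 1)))
            diff = mean_g[:, 0] - mean_g[:, 1]
            t = diff / se
        t = np.where(np.isnan(F), np.nan, t)
        t = np.where(np.isinf(F), np.sign(diff) * np.inf, t)
        t = np.where(F == 0, 0.0, t)
    return F, mean_g, t


def locus_fstat(s: SmoothedDataset, groups: SampleTable | None = None) -> LocusStats:
    """One-way ANOVA F per locus on smoothed values (signed t for 2 groups)."""
    samples = groups if groups is not None else s.samples
    codes, labels = samples.group_codes()
    k = len(labels)
    if k < 2:
        raise MethregionsError("locus_fstat requires >= 2 groups")
    counts = np.bincount(codes, minlength=k)
    if (counts < 2).any():
        raise MethregionsError("every group needs >= 2 samples")
    F, mean_g, t = _fstat_matrix(s.beta, codes, k)
    return LocusStats(
        chrom=s.loci["chrom"].to_numpy(),
        pos=s.loci["pos"].to_numpy(np.int64),
        stat=F,
        group_means=mean_g,
        groups=labels,
        t=t,
    )


def _cap_infinite(stat: np.ndarray) -> np.ndarray:
    """Cap infinite locus statistics at the finite maximum (keeps areaStat finite)."""
    finite = stat[np.isfinite(stat)]
    cap = finite.max() if finite.size else 0.0
    out = stat.copy()
    out[np.isposinf(out)] = cap
    out[np.isneginf(out)] = -cap
    return out


def _segment(
    score: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    cutoff: float,
    max_gap_bp: int,
    sign: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of loci with score >= cutoff, split at chromosome changes,
    gaps > max_gap_bp, and (two-group mode) sign changes.  Returns [i0, i1)."""
    mask = np.where(np.isfinite(score), score, -np.inf) >= cutoff
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = (
        (np.diff(idx) > 1)
        | (chrom[idx[1:]] != chrom[idx[:-1]])
        | ((pos[idx[1:]] - pos[idx[:-1]]) > max_gap_bp)
    )
    if sign is not None:
        brk |= sign[idx[1:]] != sign[idx[:-1]]
    starts = np.concatenate([[0], np.flatnonzero(brk) + 1])
    ends = np.concatenate([np.flatnonzero(brk), [idx.size - 1]])
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def call_candidates(
    stats: LocusStats,
    cutoff: float,
    max_gap_bp: int = 300,
    min_loci: int = DEFAULT_MIN_LOCI,
    stratum: str = "",
) -> list[Region]:
    """Segment locus statistics into scored candidate regions.

    In two-group mode the run criterion is |t| >= cutoff with constant sign
    and areaStat is the sum of signed t (so |areaStat| = sum |t|); otherwise
    the criterion is F >= cutoff and areaStat the sum of F.  Runs shorter
    than ``min_loci`` are discarded.  Infinite locus statistics are capped at
    the finite maximum before segmentation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if stats.t is not None:
        base = _cap_infinite(stats.t)
        score = np.abs(base)
        sign = np.sign(base)
    else:
        base = _cap_infinite(stats.stat)
        score = base
        sign = None

    regions = []
    for i0, i1 in _segment(score, stats.chrom, stats.pos, cutoff, max_gap_bp, sign):
        if i1 - i0 < min_loci:
            continue
        seg = base[i0:i1]
        gm = np.nanmean(stats.group_means[i0:i1], axis=0)
        finite_gm = gm[np.isfinite(gm)]
        max_diff = float(finite_gm.max() - finite_gm.min()) if finite_gm.size else float("nan")
        regions.append(
            Region(
                chrom=str(stats.chrom[i0]),
                start=int(stats.pos[i0]),
                end=int(stats.pos[i1 - 1]),
                n_loci=i1 - i0,
                area_stat=float(seg.sum()),
                max_stat=float(np.abs(seg).max()),
                group_means={g: float(m) for g, m in zip(stats.groups, gm)},
                max_group_diff=max_diff,
                locus_slice=(i0, i1),
                stratum=stratum,
            )
        )
    return regions


def _resolve_cutoff(stat: np.ndarray, cutoff: float | None, quantile: float) -> float:
    if cutoff is not None:
        return float(cutoff)
    finite = stat[np.isfinite(stat)]
    if finite.size == 0:
        return np.inf
    return float(np.quantile(finite, quantile))


def _perm_max_area(
    beta, codes, k, chrom, pos, cutoff, quantile, max_gap_bp, min_loci, ws=None
) -> float:
    """Maximum |areaStat| over candidate regions for one labelling (0 if none)."""
    F, _, t = _fstat_matrix(beta, codes, k, ws)
    if t is not None:
        base = _cap_infinite(t)
        score, sign = np.abs(base), np.sign(base)
    else:
        base = _cap_infinite(F)
        score, sign = base, None
    cut = _resolve_cutoff(score if t is not None else base, cutoff, quantile)
    best = 0.0
    for i0, i1 in _segment(score, chrom, pos, cut, max_gap_bp, sign):
        if i1 - i0 < min_loci:
            continue
        best = max(best, abs(float(base[i0:i1].sum())))
    return best


def _distinct_assignments(codes: np.ndarray) -> list[np.ndarray]:
    seen = set()
    out = []
    for perm in itertools.permutations(range(len(codes))):
        assign = tuple(codes[list(perm)])
        if assign not in seen:
            seen.add(assign)
            out.append(np.array(assign, dtype=codes.dtype))
    return out


def permutation_fwer(
    s: SmoothedDataset,
    groups: SampleTable | None = None,
    cutoff: float | None = None,
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
    max_gap_bp: int = 300,
    min_loci: int = DEFAULT_MIN_LOCI,
    B: int = 100,
    seed: int | None = 0,
    alpha: float = 0.05,
    exhaustive: bool = False,
    kind: str = "cg_dmr",
    stratum: str = "",
) -> RegionSet:
    """Call candidate regions and attach permutation FWER p-values.

    ``cutoff=None`` uses the genome-wide ``cutoff_quantile`` of the observed
    locus statistic, re-derived within each permutation so that the identical
    procedure is applied to permuted data.  ``exhaustive=True`` replaces the
    B random permutations by all distinct non-identity label assignments
    (only sensible for very small designs).
    """
    samples = groups if groups is not None else s.samples
    codes, labels = samples.group_codes()
    k = len(labels)
    if k < 2:
        raise MethregionsError("permutation test requires >= 2 groups")

    stats = locus_fstat(s, samples)
    obs_score = np.abs(_cap_infinite(stats.t)) if stats.t is not None else _cap_infinite(stats.stat)
    cut = _resolve_cutoff(obs_score, cutoff, cutoff_quantile)
    regions = call_candidates(stats, cut, max_gap_bp, min_loci, stratum=stratum)

    chrom, pos = stats.chrom, stats.pos
    if exhaustive:
        assignments = [a for a in _distinct_assignments(codes) if not np.array_equal(a, codes)]
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(codes) for _ in range(B)]
    ws = _FstatWorkspace(s.beta)
    null_max = np.array(
        [
            _perm_max_area(
                s.beta, a, k, chrom, pos, cutoff, cutoff_quantile, max_gap_bp, min_loci, ws
            )
            for a in assignments
        ]
    )

    n_eff = len(assignments)
    for r in regions:
        k_ge = int((null_max >= abs(r.area_stat) - 1e-12).sum())
        r.fwer_p = (1 + k_ge) / (n_eff + 1)
        r.significant = r.fwer_p <= alpha

    provenance = {
        "kind": kind,
        "cutoff": cut,
        "cutoff_quantile": None if cutoff is not None else cutoff_quantile,
        "max_gap_bp": max_gap_bp,
        "min_loci": min_loci,
        "B": n_eff,
        "seed": seed,
        "alpha": alpha,
        "groups": labels,
        "stratum": stratum,
        "smoothing": getattr(s.config, "name", None),
        "source": s.source_fingerprint,
    }
    return RegionSet(regions, kind=kind, provenance=provenance)


# ---------------------------------------------------------------------------
# annotation and selection
# ---------------------------------------------------------------------------


def region_sample_means(r: Region, s: SmoothedDataset) -> np.ndarray:
    """Per-sample mean smoothed methylation over the region's member loci."""
    if r.locus_slice is not None:
        i0, i1 = r.locus_slice
        block = s.beta[i0:i1]
    else:
        sel = (
            (s.loci["chrom"].to_numpy() == r.chrom)
            & (s.loci["pos"].to_numpy() >= r.start)
            & (s.loci["pos"].to_numpy() <= r.end)
        )
        block = s.beta[sel]
    if block.shape[0] == 0:
        raise MethregionsError("region has no member loci in this dataset")
    with np.errstate(invalid="ignore"):
        return np.nanmean(block, axis=0)


def annotate_pairwise(
    r: Region, s: SmoothedDataset, groups: SampleTable | None = None, delta_min: float = 0.1
) -> frozenset:
    """Annotate a region with the group pairs whose region-mean methylation
    differs by at least ``delta_min`` (stored on the region)."""
    samples = groups if groups is not None else s.samples
    codes, labels = samples.group_codes()
    y = region_sample_means(r, s)
    means = {}
    for gi, g in enumerate(labels):
        vals = y[codes == gi]
        vals = vals[np.isfinite(vals)]
        means[g] = float(vals.mean()) if vals.size else float("nan")
    pairs = set()
    for g1, g2 in itertools.combinations(labels, 2):
        if np.isfinite(means[g1]) and np.isfinite(means[g2]) and abs(means[g1] - means[g2]) >= delta_min:
            pairs.add((g1, g2))
    r.annotation = frozenset(pairs)
    r.group_means = means
    return r.annotation


def select_discriminatory(
    regions: RegionSet,
    groups: list[str] | None = None,
    caps: dict[str, int] | None = None,
) -> dict[str, RegionSet]:
    """Per-group discriminatory regions: every annotated pair contains the group.

    A region whose annotation is e.g. {(A,B), (A,C), (A,D)} separates A from
    the rest and is discriminatory for A.  Within each group the output is
    sorted by maxStat descending and truncated to ``caps[group]`` when given.
    """
    if groups is None:
        groups = sorted({g for r in regions for p in r.annotation for g in p})
    out: dict[str, list[Region]] = {g: [] for g in groups}
    for r in regions:
        if not r.annotation:
            continue
        common = set.intersection(*(set(p) for p in r.annotation))
        for g in common:
            if g in out:
                out[g].append(r)
    result = {}
    for g, lst in out.items():
        lst = sorted(lst, key=lambda r: -r.max_stat)
        if caps and g in caps:
            lst = lst[: caps[g]]
        result[g] = RegionSet(lst, kind=regions.kind, provenance={**regions.provenance, "discriminatory_for": g})
    return result


def region_methylation_matrix(r: RegionSet, s: SmoothedDataset) -> pd.DataFrame:
    """Regions x samples matrix of mean smoothed methylation (missing-aware)."""
    rows = [region_sample_means(reg, s) for reg in r]
    index = [f"{reg.chrom}:{reg.start}-{reg.end}" for reg in r]
    return pd.DataFrame(rows, index=index, columns=s.samples.sample_ids)


# ---------------------------------------------------------------------------
# CH (non-CpG) strata
# ---------------------------------------------------------------------------


def ch_dmr_analysis(
    strata: dict[str, "MethylationDataset"],
    groups: SampleTable | None = None,
    config: "_smoothing.SmoothingConfig | None" = None,
    **permutation_kwargs,
) -> RegionSet:
    """Run the DMR pipeline per dinucleotide/strand stratum and report the union.

    ``strata`` maps a stratum label (e.g. ``CA+``, ``CA-``, ``CT+``, ``CT-``)
    to its per-strand dataset.  Each stratum is smoothed with the ``ch``
    preset and analysed independently; the reported set is the concatenation
    of per-stratum region sets, each region tagged with its stratum.
    """
    cfg = config or _smoothing.preset("ch")
    all_regions: list[Region] = []
    prov: dict = {"strata": sorted(strata)}
    for label in sorted(strata):
        sm = _smoothing.smooth(strata[label], cfg)
        rs = permutation_fwer(sm, groups, kind="ch_dmr", stratum=label, **permutation_kwargs)
        all_regions.extend(rs.regions)
        prov[label] = rs.provenance
    return RegionSet(all_regions, kind="ch_dmr", provenance=prov)
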