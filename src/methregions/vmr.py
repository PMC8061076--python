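"""Variably methylated region (VMR) detection and cross-tissue sharing.

A VMR is an interval of high inter-individual methylation variance within
one tissue (not a between-tissue difference).  The procedure:

1. keep CpGs with sequencing coverage > ``min_cov`` reads in > ``min_samples``
   samples (strict inequalities);
2. per tissue, compute the per-locus sample standard deviation (n-1
   denominator) of smoothed methylation;
3. take the 99th percentile of each tissue's SD distribution and use the
   minimum across tissues as a single genome-wide cutoff — the same cutoff
   for every tissue lets more-variable tissues yield more VMRs;
4. call maximal runs of loci with SD above the cutoff, keep runs with more
   than 10 CpGs;
5. drop VMRs driven by a single outlier sample, flagged by a maximum Cook's
   distance > 0.7 from an intercept-only fit of per-sample region means;
6. effect size = range of the per-sample, across-region average methylation;
7. classify merged cross-tissue intervals as tissue-specific, shared, or
   ubiquitous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethregionsError, MethylationDataset, Region, RegionSet, SmoothedDataset

DEFAULT_SD_QUANTILE = 0.99
DEFAULT_MIN_CPGS = 11  # "> 10 CpGs"
DEFAULT_COOKS_THRESHOLD = 0.7
DEFAULT_MAX_GAP = 300


def methylation_span(sd_cutoff: float) -> float:
    """Methylation difference spanned by +/- 2 SD at the cutoff (= 4 x cutoff).

    An SD cutoff of 0.095 therefore corresponds to a 0.38 (38%) methylation
    span, the scale at which at least 99% of a normal methylation
    distribution falls within +/- 2 SD.
    """
    return 4.0 * sd_cutoff


@dataclass
class VMR:
    """One variably methylated region in one tissue."""

    chrom: str
    start: int  # 1-based inclusive first/last member CpG
    end: int
    n_cpgs: int
    tissue: str
    max_sd: float
    mean_sd: float
    effect_size: float = float("nan")
    cooks_max: float = float("nan")
    retained: bool = True
    note: str = ""
    locus_slice: tuple[int, int] | None = None

    def as_record(self) -> dict:
        return {
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "n_cpgs": self.n_cpgs, "tissue": self.tissue,
            "max_sd": self.max_sd, "mean_sd": self.mean_sd,
            "effect_size": self.effect_size, "cooks_max": self.cooks_max,
            "retained": self.retained, "note": self.note,
        }


@dataclass
class VMRSharing:
    """A merged cross-tissue VMR interval and its sharing class."""

    chrom: str
    start: int
    end: int
    tissues: frozenset
    sharing_class: str  # tissue_specific | shared | ubiquitous


# ---------------------------------------------------------------------------
# filters and statistics
# ---------------------------------------------------------------------------


def coverage_filter(d: MethylationDataset, min_cov: int, min_samples: int) -> np.ndarray:
    """Locus mask: kept iff #{samples with Cov > min_cov} > min_samples."""
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if min_samples > d.samples.n:
        raise ValueError("min_samples exceeds the number of samples")
    return (d.Cov > min_cov).sum(axis=1) > min_samples


def per_tissue_sd(s: SmoothedDataset, tissue: str) -> np.ndarray:
    """Per-locus sample SD (ddof=1) of smoothed values across one tissue's samples.

    NaN where fewer than two non-missing samples remain at a locus.
    """
    mask = s.samples.tissue_mask(tissue)
    if mask.sum() < 3:
        raise MethregionsError(f"tissue {tissue!r} has fewer than 3 samples")
    block = s.beta[:, mask]
    n = np.isfinite(block).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(block, axis=1, ddof=1)
    sd[n < 2] = np.nan
    return sd


def select_cutoff(per_tissue_sds: dict[str, np.ndarray], q: float = DEFAULT_SD_QUANTILE) -> float:
    """Single genome-wide SD cutoff: the minimum across tissues of each
    tissue's q-th SD quantile (type-7 linear interpolation)."""
    if not per_tissue_sds:
        raise MethregionsError("select_cutoff needs at least one tissue")
    cuts = []
    for tissue, sd in per_tissue_sds.items():
        vals = np.asarray(sd, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise MethregionsError(f"tissue {tissue!r} has an empty SD distribution")
        cuts.append(float(np.quantile(vals, q)))  # numpy default = type 7
    return min(cuts)


def call_vmrs(
    sd: np.ndarray,
    loci: pd.DataFrame,
    cutoff: float,
    tissue: str,
    max_gap_bp: int = DEFAULT_MAX_GAP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> list[VMR]:
    """Maximal runs of loci with SD strictly above the cutoff.

    Runs split at chromosome changes and inter-locus gaps > ``max_gap_bp``;
    runs with fewer than ``min_cpgs`` CpGs are dropped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sd = np.asarray(sd, dtype=float)
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy(np.int64)
    mask = np.where(np.isfinite(sd), sd, -np.inf) > cutoff
    idx = np.flatnonzero(mask)
    out: list[VMR] = []
    if idx.size == 0:
        return out
    brk = (
        (np.diff(idx) > 1)
        | (chrom[idx[1:]] != chrom[idx[:-1]])
        | ((pos[idx[1:]] - pos[idx[:-1]]) > max_gap_bp)
    )
    starts = np.concatenate([[0], np.flatnonzero(brk) + 1])
    ends = np.concatenate([np.flatnonzero(brk), [idx.size - 1]])
    for a, b in zip(starts, ends):
        i0, i1 = int(idx[a]), int(idx[b]) + 1
        if i1 - i0 < min_cpgs:
            continue
        seg = sd[i0:i1]
        out.append(
            VMR(
                chrom=str(chrom[i0]),
                start=int(pos[i0]),
                end=int(pos[i1 - 1]),
                n_cpgs=i1 - i0,
                tissue=tissue,
                max_sd=float(np.nanmax(seg)),
                mean_sd=float(np.nanmean(seg)),
                locus_slice=(i0, i1),
            )
        )
    return out


def _region_sample_means(v: VMR, s: SmoothedDataset, tissue: str) -> np.ndarray:
    mask = s.samples.tissue_mask(tissue)
    if v.locus_slice is not None:
        i0, i1 = v.locus_slice
        block = s.beta[i0:i1][:, mask]
    else:
        sel = (
            (s.loci["chrom"].to_numpy() == v.chrom)
            & (s.loci["pos"].to_numpy() >= v.start)
            & (s.loci["pos"].to_numpy() <= v.end)
        )
        block = s.beta[sel][:, mask]
    with np.errstate(invalid="ignore"):
        y = np.nanmean(block, axis=0)
    return y[np.isfinite(y)]


def cooks_filter(
    v: VMR, s: SmoothedDataset, tissue: str | None = None, threshold: float = DEFAULT_COOKS_THRESHOLD
) -> tuple[float, bool]:
    """Maximum Cook's distance of per-sample region means; retain if <= threshold.

    The model is an intercept-only regression of the per-sample region-mean
    methylation (the minimal model for "this sample is an outlier relative
    to the tissue mean"): with leverage h = 1/n and p = 1 parameter,
    ``D_i = e_i^2 * h / (p * s^2 * (1 - h)^2)`` where ``s^2`` is the residual
    mean square.  All-equal means give D = 0 (retained); fewer than 3 usable
    samples is a degenerate design and the VMR is rejected with a note.
    Updates and returns ``(cooks_max, retained)``.
    """
    y = _region_sample_means(v, s, tissue or v.tissue)
    n = y.size
    if n < 3:
        v.cooks_max, v.retained, v.note = float("nan"), False, "insufficient samples"
        return v.cooks_max, v.retained
    e = y - y.mean()
    s2 = float((e**2).sum() / (n - 1))
    if s2 == 0.0:
        v.cooks_max, v.retained = 0.0, True
        return v.cooks_max, v.retained
    h = 1.0 / n
    D = e**2 * h / (1 * s2 * (1 - h) ** 2)
    v.cooks_max = float(D.max())
    v.retained = v.cooks_max <= threshold
    if not v.retained:
        v.note = "outlier-driven (Cook's distance)"
    return v.cooks_max, v.retained


def effect_size(v: VMR, s: SmoothedDataset, tissue: str | None = None) -> float:
    """Range (max - min) of the per-sample, across-region average methylation."""
    y = _region_sample_means(v, s, tissue or v.tissue)
    v.effect_size = float(y.max() - y.min()) if y.size else float("nan")
    return v.effect_size


# ---------------------------------------------------------------------------
# sharing classification
# ---------------------------------------------------------------------------


def classify_sharing(
    per_tissue_vmrs: dict[str, list[VMR]], all_tissues: list[str] | None = None
) -> list[VMRSharing]:
    """Union-merge retained VMRs across tissues and classify each merged interval.

    Overlap is >= 1 shared bp with transitive closure.  A merged interval is
    ``tissue_specific`` with exactly one member tissue, ``ubiquitous`` when
    every configured tissue contributes an overlapping VMR, otherwise
    ``shared``.  The classes partition the merged intervals.
    """
    if all_tissues is None:
        all_tissues = sorted(per_tissue_vmrs)
    entries = []
    for tissue, vmrs in per_tissue_vmrs.items():
        for v in vmrs:
            if v.retained:
                entries.append((v.chrom, v.start, v.end, tissue))
    if not entries:
        return []
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    merged: list[VMRSharing] = []
    cur_chrom, cur_start, cur_end, cur_tissues = entries[0][0], entries[0][1], entries[0][2], {entries[0][3]}
    full = set(all_tissues)

    def _emit():
        if cur_tissues == full:
            cls = "ubiquitous"
        elif len(cur_tissues) == 1:
            cls = "tissue_specific"
        else:
            cls = "shared"
        merged.append(VMRSharing(cur_chrom, cur_start, cur_end, frozenset(cur_tissues), cls))

    for chrom, start, end, tissue in entries[1:]:
        if chrom == cur_chrom and start <= cur_end:  # >= 1 shared bp (1-based inclusive)
            cur_end = max(cur_end, end)
            cur_tissues.add(tissue)
        else:
            _emit()
            cur_chrom, cur_start, cur_end, cur_tissues = chrom, start, end, {tissue}
    _emit()
    return merged


def sharing_table(sharing: list[VMRSharing]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": m.chrom, "start": m.start, "end": m.end,
                "tissues": ",".join(sorted(m.tissues)), "n_tissues": len(m.tissues),
                "class": m.sharing_class,
            }
            for m in sharing
        ],
        columns=["chrom", "start", "end", "tissues", "n_tissues", "class"],
    )


# ---------------------------------------------------------------------------
# end-to-end per-tissue analysis
# ---------------------------------------------------------------------------


@dataclass
class VMRAnalysis:
    """Result bundle of a multi-tissue VMR analysis."""

    cutoff: float
    per_tissue: dict[str, list[VMR]]
    sharing: list[VMRSharing]
    kept_loci: np.ndarray = field(default=None)  # mask over the input loci

    def table(self) -> pd.DataFrame:
        rows = [v.as_record() for vmrs in self.per_tissue.values() for v in vmrs]
        cols = ["chrom", "start", "end", "n_cpgs", "tissue", "max_sd", "mean_sd",
                "effect_size", "cooks_max", "retained", "note"]
        return pd.DataFrame(rows, columns=cols)

    def region_set(self, tissue: str) -> RegionSet:
        regions = [
            Region(
                chrom=v.chrom, start=v.start, end=v.end, n_loci=v.n_cpgs,
                area_stat=float("nan"), max_stat=v.max_sd, stratum=tissue,
            )
            for v in self.per_tissue.get(tissue, [])
            if v.retained
        ]
        return RegionSet(regions, kind="vmr", provenance={"tissue": tissue, "cutoff": self.cutoff})


def vmr_analysis(
    raw: MethylationDataset,
    smoothed: SmoothedDataset,
    tissues: list[str] | None = None,
    min_cov: int = 5,
    min_samples: int | None = None,
    q: float = DEFAULT_SD_QUANTILE,
    max_gap_bp: int = DEFAULT_MAX_GAP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    cooks_threshold: float = DEFAULT_COOKS_THRESHOLD,
) -> VMRAnalysis:
    """Run the full VMR procedure across tissues.

    ``min_samples`` defaults to just over half the cohort, scaling the
    study's coverage filter to the design at hand.
    """
    if tissues is None:
        tissues = smoothed.samples.tissues
    if min_samples is None:
        min_samples = raw.samples.n // 2
    keep = coverage_filter(raw, min_cov, min_samples)
    sm = smoothed.subset_loci(keep)

    sds = {t: per_tissue_sd(sm, t) for t in tissues}
    cutoff = select_cutoff(sds, q)

    per_tissue: dict[str, list[VMR]] = {}
    for t in tissues:
        vmrs = call_vmrs(sds[t], sm.loci, cutoff, t, max_gap_bp, min_cpgs)
        for v in vmrs:
            cooks_filter(v, sm, t, cooks_threshold)
            if v.retained:
                effect_size(v, sm, t)
        per_tissue[t] = vmrs
    sharing = classify_sharing(
        {t: [v for v in vs if v.retained] for t, vs in per_tissue.items()}, tissues
    )
    return VMRAnalysis(cutoff=cutoff, per_tissue=per_tissue, sharing=sharing, kept_loci=keep)
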