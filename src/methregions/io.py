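"""Readers/writers for the standard formats touched by the pipeline and
genomic-interval primitives.

Formats: Bismark-style per-cytosine reports (tab-separated ``chrom  pos
strand  count_methylated  count_unmethylated  context  [trinucleotide]``,
optionally gzipped), delimited sample sheets, and BED3/BED4+ feature files.

Coordinate conventions: loci are 1-based (as in cytosine reports); all
interval sets are normalized to 0-based half-open internally and BED is
emitted 0-based half-open.  A 1-based inclusive locus span ``[s..e]`` maps
to the half-open interval ``[s-1, e)`` and back, exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CONTEXTS,
    GenomicFeatureSet,
    MethylationDataset,
    ParseError,
    RegionSet,
    SampleTable,
    SmoothedDataset,
)

REPORT_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context", "tri"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------


def read_cytosine_report(
    path,
    context_filter: set[str] | None = None,
    strand_filter: str | None = None,
    sample_id: str = "sample",
) -> MethylationDataset:
    """Read a single-sample per-cytosine report.

    Returns a single-sample :class:`MethylationDataset` with
    ``M = count_methylated`` and ``Cov = count_methylated + count_unmethylated``.
    Zero-coverage loci are retained.  Malformed lines raise :class:`ParseError`
    naming the offending line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 columns, got {len(parts)}")
            chrom, pos_s, strand, m_s, u_s, context = parts[:6]
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer pos/counts") from None
            if pos < 1:
                raise ParseError(f"{path}: line {lineno}: position {pos} < 1")
            if m < 0 or u < 0:
                raise ParseError(f"{path}: line {lineno}: negative counts")
            if context not in CONTEXTS:
                raise ParseError(f"{path}: line {lineno}: unknown context {context!r}")
            if strand not in ("+", "-", "both"):
                raise ParseError(f"{path}: line {lineno}: unknown strand {strand!r}")
            if context_filter is not None and context not in context_filter:
                continue
            if strand_filter is not None and strand != strand_filter:
                continue
            rows.append((chrom, pos, strand, m, u, context))

    samples = SampleTable(
        pd.DataFrame(
            [[sample_id, sample_id, "unknown", "unknown", "brain"]],
            columns=["sample_id", "donor_id", "tissue", "group", "tissue_class"],
        )
    )
    if not rows:
        loci = pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
        loci["pos"] = loci["pos"].astype(np.int64)
        return MethylationDataset(loci, np.zeros((0, 1), np.int64), np.zeros((0, 1), np.int64), samples)

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_m", "count_u", "context"])
    df = df.sort_values(["chrom", "pos", "strand", "context"], kind="mergesort").reset_index(drop=True)
    loci = df[["chrom", "pos", "strand", "context"]].copy()
    M = df["count_m"].to_numpy(np.int64)[:, None]
    Cov = (df["count_m"] + df["count_u"]).to_numpy(np.int64)[:, None]
    return MethylationDataset(loci, M, Cov, samples)


def write_cytosine_report(d: MethylationDataset, path, sample: int | str = 0) -> None:
    """Write one sample of a dataset back to cytosine-report format."""
    if isinstance(sample, str):
        sample = d.samples.sample_ids.index(sample)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        m = d.M[:, sample]
        u = d.Cov[:, sample] - m
        for (chrom, pos, strand, context), mi, ui in zip(
            d.loci.itertuples(index=False), m, u
        ):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{mi}\t{ui}\t{context}\n")


def read_cytosine_reports(
    paths: Mapping[str, "str | Path"],
    samples: SampleTable,
    context_filter: set[str] | None = None,
    strand_filter: str | None = None,
) -> MethylationDataset:
    """Assemble a multi-sample dataset from per-sample report files.

    ``paths`` maps sample_id -> file.  Loci are aligned on the union across
    samples; a sample missing a locus gets Cov = 0 there.
    """
    per_sample = {}
    for sid in samples.sample_ids:
        if sid not in paths:
            raise ParseError(f"no report file given for sample {sid!r}")
        per_sample[sid] = read_cytosine_report(
            paths[sid], context_filter=context_filter, strand_filter=strand_filter, sample_id=sid
        )

    frames = []
    for sid, d in per_sample.items():
        f = d.loci.copy()
        f["M"] = d.M[:, 0]
        f["Cov"] = d.Cov[:, 0]
        f["sample_id"] = sid
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True)
    key = ["chrom", "pos", "strand", "context"]
    wide_m = merged.pivot_table(index=key, columns="sample_id", values="M", fill_value=0, sort=False)
    wide_c = merged.pivot_table(index=key, columns="sample_id", values="Cov", fill_value=0, sort=False)
    idx = wide_m.index.to_frame(index=False).sort_values(
        ["chrom", "pos", "strand", "context"], kind="mergesort"
    )
    order = idx.index.to_numpy()
    loci = idx.reset_index(drop=True)
    sample_ids = samples.sample_ids
    M = wide_m.reindex(columns=sample_ids).to_numpy(np.int64)[order]
    Cov = wide_c.reindex(columns=sample_ids).to_numpy(np.int64)[order]
    return MethylationDataset(loci, M, Cov, samples)


def read_sample_sheet(path, sep: str = "\t") -> SampleTable:
    return SampleTable.from_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# CpG strand collapsing
# ---------------------------------------------------------------------------


def collapse_cpg_strands(d: MethylationDataset) -> MethylationDataset:
    """Combine +/− strand counts of each CpG into one locus.

    CpG dinucleotides are palindromic: the cytosine at ``(chrom, p, +)``
    pairs with the one at ``(chrom, p+1, -)``.  The collapsed locus sits at
    the + strand C position with ``strand='both'`` and summed counts.
    Unpaired loci pass through with their own counts.  Total M and Cov are
    conserved.
    """
    loci = d.loci
    if len(loci) and (loci["context"] != "CG").any():
        raise ValueError("collapse_cpg_strands requires a CG-context dataset")
    if len(loci) == 0:
        return d

    chrom = loci["chrom"].to_numpy(object)
    pos = loci["pos"].to_numpy(np.int64)
    strand = loci["strand"].to_numpy(object)

    plus = np.flatnonzero(strand == "+")
    minus = np.flatnonzero(strand == "-")
    # match (chrom, p, +) with (chrom, p+1, -)
    minus_key = pd.MultiIndex.from_arrays([chrom[minus], pos[minus] - 1])
    plus_key = pd.MultiIndex.from_arrays([chrom[plus], pos[plus]])
    match = minus_key.get_indexer(plus_key)  # index into `minus` arrays, -1 if unpaired

    paired_plus = plus[match >= 0]
    paired_minus = minus[match[match >= 0]]
    unpaired = np.setdiff1d(
        np.arange(len(loci)), np.concatenate([paired_plus, paired_minus]), assume_unique=False
    )

    out_chrom = np.concatenate([chrom[paired_plus], chrom[unpaired]])
    out_pos = np.concatenate([pos[paired_plus], pos[unpaired]])
    out_strand = np.concatenate(
        [np.full(len(paired_plus), "both", object), strand[unpaired]]
    )
    out_M = np.concatenate([d.M[paired_plus] + d.M[paired_minus], d.M[unpaired]])
    out_Cov = np.concatenate([d.Cov[paired_plus] + d.Cov[paired_minus], d.Cov[unpaired]])

    order = np.lexsort((out_pos, out_chrom.astype(str)))
    new_loci = pd.DataFrame(
        {
            "chrom": out_chrom[order],
            "pos": out_pos[order],
            "strand": out_strand[order],
            "context": "CG",
        }
    )
    return MethylationDataset(new_loci, out_M[order], out_Cov[order], d.samples)


# ---------------------------------------------------------------------------
# binning / promoters / overlaps
# ---------------------------------------------------------------------------


def bin_methylation(s: SmoothedDataset, bin_bp: int) -> pd.DataFrame:
    """Mean smoothed methylation per (chrom, bin) per sample.

    Bin ``b`` covers the 0-based half-open interval ``[b*bin_bp, (b+1)*bin_bp)``;
    a 1-based locus at ``pos`` falls in bin ``(pos-1) // bin_bp``.  Bins with
    no loci are dropped.  The per-bin value is the unweighted mean of smoothed
    fractions (NaN-aware).
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    bins = (s.loci["pos"].to_numpy(np.int64) - 1) // bin_bp
    key = pd.MultiIndex.from_arrays([s.loci["chrom"], bins], names=["chrom", "bin"])
    df = pd.DataFrame(s.beta, columns=s.samples.sample_ids, index=key)
    return df.groupby(level=["chrom", "bin"], sort=True).mean()


def make_promoters(
    tss_table: Sequence[tuple[str, int, str, str]], flank_bp: int
) -> GenomicFeatureSet:
    """Promoter windows centered on each TSS (strand-symmetric).

    A 1-based TSS at ``t`` yields the 0-based half-open interval
    ``[t-1-flank_bp, t-1+flank_bp)``, clipped at 0; ``flank_bp=2000`` gives
    the conventional 4-kb promoter window.
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    intervals, labels = [], []
    for chrom, tss, _strand, gene in tss_table:
        start = max(0, tss - 1 - flank_bp)
        end = tss - 1 + flank_bp
        intervals.append((chrom, start, end))
        labels.append(gene)
    return GenomicFeatureSet.from_intervals("promoters", intervals, labels)


def _region_intervals0(a) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(a, RegionSet):
        return a.intervals0()
    if isinstance(a, GenomicFeatureSet):
        return a.chroms, a.starts, a.ends
    raise TypeError(f"expected RegionSet or GenomicFeatureSet, got {type(a)}")


def overlap_regions(a, b: GenomicFeatureSet, mode: str = "any_bp"):
    """Flag regions of ``a`` overlapping features of ``b``.

    ``mode='any_bp'`` flags regions sharing at least one base with any
    feature; ``mode='contained'`` flags regions lying entirely inside a
    single feature interval.  Returns ``(flags, pairs)`` where ``pairs`` is a
    list of (region index, feature index) with any-bp overlap.
    """
    if mode not in ("any_bp", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    ch_a, st_a, en_a = _region_intervals0(a)

    trees: dict[str, IntervalTree] = {}
    for j in range(len(b)):
        trees.setdefault(str(b.chroms[j]), IntervalTree()).addi(
            int(b.starts[j]), int(b.ends[j]), j
        )

    flags = np.zeros(len(st_a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in range(len(st_a)):
        tree = trees.get(str(ch_a[i]))
        if tree is None:
            continue
        hits = tree.overlap(int(st_a[i]), int(en_a[i]))
        for h in sorted(hits, key=lambda h: h.data):
            pairs.append((i, h.data))
        if mode == "any_bp":
            flags[i] = bool(hits)
        else:
            flags[i] = any(h.begin <= st_a[i] and h.end >= en_a[i] for h in hits)
    return flags, pairs


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_regions_bed(r: RegionSet, path) -> None:
    """Write a region set as BED (0-based half-open) with name and score.

    The name column carries ``<kind>_<ordinal>``; the score column carries
    the region's max statistic.
    """
    with open(path, "wt") as fh:
        fh.write(f"# methregions {r.kind}; score=max_stat; provenance={r.provenance_json()}\n")
        for i, reg in enumerate(r.regions):
            fh.write(
                f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\t{r.kind}_{i}\t{reg.max_stat:.6g}\n"
            )


def read_bed(path, name: str | None = None) -> GenomicFeatureSet:
    """Read BED3/BED4+ into a feature set (0-based half-open)."""
    intervals, labels, have_labels = [], [], False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            intervals.append((parts[0], start, end))
            if len(parts) >= 4:
                have_labels = True
                labels.append(parts[3])
            else:
                labels.append("")
    return GenomicFeatureSet.from_intervals(
        name or Path(path).stem, intervals, labels if have_labels else None
    )


def write_bed(f: GenomicFeatureSet, path) -> None:
    with open(path, "wt") as fh:
        for j in range(len(f)):
            label = "" if f.labels is None else f"\t{f.labels[j]}"
            fh.write(f"{f.chroms[j]}\t{f.starts[j]}\t{f.ends[j]}{label}\n")
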