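"""Core in-memory containers shared by every stage of the pipeline.

The analysis currency is a matrix of per-cytosine methylated / total read
counts across samples (:class:`MethylationDataset`), its locally smoothed
counterpart (:class:`SmoothedDataset`), and scored genomic intervals
(:class:`Region` / :class:`RegionSet`).  Loci are stored 1-based (the native
convention of per-cytosine report files); interval sets destined for BED
interchange are 0-based half-open (:class:`GenomicFeatureSet`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CA", "CT", "CC")
STRANDS = ("+", "-", "both")
TISSUE_CLASSES = ("brain", "non_brain")

SAMPLE_SHEET_COLUMNS = ["sample_id", "donor_id", "tissue", "group", "tissue_class"]


class MethregionsError(Exception):
    """Base class for package errors."""


class ParseError(MethregionsError):
    """Malformed input file."""


class ConfigError(MethregionsError):
    """Invalid run configuration (detected before compute starts)."""


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleTable:
    """Sample metadata: sample -> donor -> tissue -> analysis group.

    ``group`` is the label differential analyses compare (e.g. the 5-group
    scheme that pools cortical and basal-ganglia tissues); ``tissue`` is the
    label variability (VMR) analyses stratify by.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"sample table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConfigError(f"duplicate sample_id values: {dup}")
        for col in ("tissue", "group"):
            if (df[col].astype(str).str.len() == 0).any() or df[col].isna().any():
                raise ConfigError(f"sample table has empty values in '{col}'")
        bad = set(df["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ConfigError(f"unknown tissue_class values: {sorted(bad)}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def tissues(self) -> list[str]:
        return sorted(self.frame["tissue"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def group_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer group code per sample plus the sorted group label list."""
        labels = self.groups
        lut = {g: i for i, g in enumerate(labels)}
        codes = np.array([lut[g] for g in self.frame["group"]], dtype=np.intp)
        return codes, labels

    def tissue_mask(self, tissue: str) -> np.ndarray:
        if tissue not in set(self.frame["tissue"]):
            raise ConfigError(f"unknown tissue {tissue!r}")
        return (self.frame["tissue"] == tissue).to_numpy()

    def with_groups(self, tissue_to_group: Mapping[str, str]) -> "SampleTable":
        """Re-derive ``group`` deterministically from a tissue->group map."""
        unknown = set(tissue_to_group) - set(self.frame["tissue"])
        if unknown:
            raise ConfigError(f"grouping references unknown tissues: {sorted(unknown)}")
        df = self.frame.copy()
        df["group"] = [tissue_to_group.get(t, t) for t in df["tissue"]]
        return SampleTable(df)

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, sep: str = "\t") -> "SampleTable":
        return cls(pd.read_csv(path, sep=sep, dtype=str))

    def to_csv(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# count and smoothed matrices
# ---------------------------------------------------------------------------

LOCI_COLUMNS = ["chrom", "pos", "strand", "context"]


def _check_loci(loci: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCI_COLUMNS if c not in loci.columns]
    if missing:
        raise MethregionsError(f"loci frame missing columns: {missing}")
    if len(loci) and (loci["pos"] < 1).any():
        raise MethregionsError("locus positions must be >= 1 (1-based)")
    # sorted within chromosome; ties only across distinct strand/context
    # (a single-stratum dataset is therefore strictly sorted)
    by_chrom = loci.groupby("chrom", sort=False)["pos"]
    if len(loci) and not all(g.is_monotonic_increasing for _, g in by_chrom):
        raise MethregionsError("loci must be sorted by position within chromosome")
    if len(loci) and loci.duplicated(subset=["chrom", "pos", "strand", "context"]).any():
        raise MethregionsError("duplicate loci (same chrom/pos/strand/context)")
    return loci.reset_index(drop=True)


@dataclass
class MethylationDataset:
    """Per-locus methylated (``M``) and total (``Cov``) read counts.

    ``M`` and ``Cov`` are ``(n_loci, n_samples)`` integer matrices aligned to
    ``loci`` rows and ``samples`` rows.  Zero-coverage loci are retained;
    coverage filtering is an explicit downstream step.
    """

    loci: pd.DataFrame
    M: np.ndarray
    Cov: np.ndarray
    samples: SampleTable

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.M = np.asarray(self.M)
        self.Cov = np.asarray(self.Cov)
        if self.M.shape != self.Cov.shape or self.M.shape != (len(self.loci), self.samples.n):
            raise MethregionsError(
                f"count matrix shape {self.M.shape} does not match "
                f"{len(self.loci)} loci x {self.samples.n} samples"
            )
        if self.M.size and ((self.M < 0).any() or (self.M > self.Cov).any()):
            raise MethregionsError("counts must satisfy 0 <= M <= Cov")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def fractions(self) -> np.ndarray:
        """Raw methylation fractions M/Cov with NaN where coverage is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.Cov > 0, self.M / np.maximum(self.Cov, 1), np.nan)

    def subset_loci(self, mask: np.ndarray) -> "MethylationDataset":
        mask = np.asarray(mask)
        return MethylationDataset(
            self.loci.loc[mask].reset_index(drop=True), self.M[mask], self.Cov[mask], self.samples
        )

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.loci, index=False).values.tobytes())
        h.update(np.ascontiguousarray(self.M))
        h.update(np.ascontiguousarray(self.Cov))
        h.update(",".join(self.samples.sample_ids).encode())
        return h.hexdigest()[:16]


@dataclass
class SmoothedDataset:
    """Per-locus, per-sample smoothed methylation fractions in [0, 1].

    ``beta`` is NaN where a sample had no covered locus anywhere in the
    smoothing window.  Locus order matches the source dataset.
    """

    loci: pd.DataFrame
    beta: np.ndarray
    samples: SampleTable
    config: "object" = None  # SmoothingConfig; untyped to avoid cycle
    source_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.loci = _check_loci(self.loci)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.loci), self.samples.n):
            raise MethregionsError("beta shape does not match loci x samples")
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise MethregionsError("smoothed values must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "SmoothedDataset":
        mask = np.asarray(mask)
        return SmoothedDataset(
            self.loci.loc[mask].reset_index(drop=True),
            self.beta[mask],
            self.samples,
            self.config,
            self.source_fingerprint,
        )


# ---------------------------------------------------------------------------
# scored regions
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """A scored genomic interval (DMR, block, or VMR).

    ``start``/``end`` are the 1-based inclusive positions of the first and
    last member locus.  ``area_stat`` is the sum and ``max_stat`` the maximum
    of the per-locus statistic over member loci.
    """

    chrom: str
    start: int
    end: int
    n_loci: int
    area_stat: float
    max_stat: float
    group_means: dict[str, float] = field(default_factory=dict)
    max_group_diff: float = float("nan")
    fwer_p: float = float("nan")
    significant: bool | None = None
    annotation: frozenset = frozenset()
    locus_slice: tuple[int, int] | None = None  # [i0, i1) indexes into source loci
    stratum: str = ""

    def as_record(self) -> dict:
        rec = {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "n_loci": self.n_loci,
            "area_stat": self.area_stat,
            "max_stat": self.max_stat,
            "max_group_diff": self.max_group_diff,
            "fwer_p": self.fwer_p,
            "significant": self.significant,
            "annotation": ";".join(sorted("|".join(p) for p in self.annotation)),
            "stratum": self.stratum,
        }
        for g, m in self.group_means.items():
            rec[f"mean_{g}"] = m
        return rec


@dataclass
class RegionSet:
    """An ordered collection of regions of one kind with its provenance."""

    regions: list[Region]
    kind: str  # cg_dmr | cg_block | ch_dmr | vmr
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.regions:
            return pd.DataFrame(
                columns=["chrom", "start", "end", "n_loci", "area_stat", "max_stat",
                         "max_group_diff", "fwer_p", "significant", "annotation", "stratum"]
            )
        return pd.DataFrame([r.as_record() for r in self.regions])

    def intervals0(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Regions as (chroms, starts, ends) in 0-based half-open coordinates."""
        chroms = np.array([r.chrom for r in self.regions], dtype=object)
        starts = np.array([r.start - 1 for r in self.regions], dtype=np.int64)
        ends = np.array([r.end for r in self.regions], dtype=np.int64)
        return chroms, starts, ends

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# feature sets (0-based half-open)
# ---------------------------------------------------------------------------


@dataclass
class GenomicFeatureSet:
    """A named set of genomic intervals in 0-based half-open coordinates.

    Intervals may overlap within a set; multi-state annotations (e.g.
    chromHMM) are represented as one set per state.
    """

    name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise MethregionsError("feature arrays must have equal length")
        if len(self.starts) and (self.starts >= self.ends).any():
            raise MethregionsError("feature intervals require start < end")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.starts):
                raise MethregionsError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Sequence[tuple[str, int, int]], labels=None
    ) -> "GenomicFeatureSet":
        if len(intervals) == 0:
            return cls(name, np.empty(0, object), np.empty(0, np.int64), np.empty(0, np.int64),
                       None if labels is None else np.empty(0, object))
        ch, st, en = zip(*intervals)
        return cls(name, np.array(ch, object), np.array(st, np.int64), np.array(en, np.int64),
                   None if labels is None else np.array(labels, object))

    def sorted(self) -> "GenomicFeatureSet":
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        return GenomicFeatureSet(
            self.name, self.chroms[order], self.starts[order], self.ends[order],
            None if self.labels is None else self.labels[order],
        )
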