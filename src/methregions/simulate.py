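"""Seeded generator of multi-tissue, multi-donor WGBS count data.

The generator emulates the statistical structure of a multi-tissue
bisulfite study: clustered CpG positions (dense hypomethylated islands in a
high-methylation open sea), Poisson sequencing coverage, beta-binomial
methylation counts with ambient biological overdispersion, and planted
signal of four kinds:

* **DMRs** — group-level mean shifts over short CpG runs;
* **blocks** — long intervals with small group shifts;
* **VMRs** — per-sample methylation level shifts drawn once per
  (sample, region), i.e. regional inter-individual variability; optionally
  genotype-driven (a biallelic SNP per donor producing trimodal means);
* **outlier VMRs** — a shift in a single designated sample, the kind of
  pseudo-VMR the Cook's-distance filter is meant to remove.

Non-CpG (CA) strata are simulated sparsely with a low baseline, reflecting
mCH levels in neurons.  All outputs are reproducible bit-for-bit from the
seed, and every planted region is emitted in a machine-readable truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MethylationDataset, MethregionsError, SampleTable

BRAIN_TISSUES = ("cortical", "basal_ganglia", "hippocampus", "hypothalamus", "amygdala")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and emission parameters of the generator.

    Defaults describe the standard desk-scale configuration: 5 tissue groups
    x 8 donors, two 2-Mb chromosomes (~40,000 CpGs), mean coverage 12x,
    ambient beta-binomial dispersion 0.02, DMR shifts of 0.3-0.5 over 12-30
    CpGs, long low-magnitude blocks, VMR level-shift SD 0.15 over 15-30
    CpGs.
    """

    seed: int
    tissues: tuple[str, ...] = BRAIN_TISSUES
    samples_per_tissue: int = 8
    non_brain: tuple[str, ...] = ()
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    # CpG placement: open-sea mean spacing + dense islands
    opensea_spacing: float = 110.0
    island_spacing: float = 15.0
    island_size_mean: float = 30.0
    islands_per_mb: float = 25.0
    # baseline methylation landscape
    baseline_opensea: float = 0.85
    baseline_island: float = 0.10
    baseline_jitter_sd: float = 0.03
    # emission
    coverage_lambda: float = 12.0
    dispersion: float = 0.02
    # planted regions
    planted_max_gap_bp: int = 250  # planted DMR/VMR runs avoid larger internal gaps
    n_dmrs: int = 20
    dmr_n_loci: tuple[int, int] = (12, 30)
    dmr_delta: tuple[float, float] = (0.3, 0.5)
    n_blocks: int = 4
    block_n_loci: tuple[int, int] = (300, 600)
    block_delta: tuple[float, float] = (0.08, 0.12)
    n_vmrs: int = 20
    vmr_n_loci: tuple[int, int] = (15, 30)
    vmr_sigma: float = 0.15
    # VMRs occupy intermediately methylated sequence, so per-sample level
    # shifts stay inside [0, 1] instead of piling up at a boundary
    vmr_base_range: tuple[float, float] = (0.35, 0.65)
    n_snp_vmrs: int = 2
    snp_maf: float = 0.3
    snp_effect: float = 0.35
    n_outlier_vmrs: int = 0
    outlier_shift: float = 0.6
    # non-CpG strata
    ch_contexts: tuple[str, ...] = ("CA",)
    ch_fraction: float = 0.25  # CH locus density relative to CpG sites
    ch_baseline: float = 0.03
    ch_jitter_sd: float = 0.01
    n_ch_dmrs: int = 4
    ch_dmr_n_loci: tuple[int, int] = (60, 120)
    ch_delta: tuple[float, float] = (0.08, 0.12)

    def null(self) -> "SimulationConfig":
        """The same design with no planted regions of any kind."""
        return replace(
            self, n_dmrs=0, n_blocks=0, n_vmrs=0, n_snp_vmrs=0, n_outlier_vmrs=0, n_ch_dmrs=0
        )


@dataclass
class TruthSet:
    """Planted-region ground truth: one row per region.

    Columns: kind (dmr | block | vmr | snp_vmr | outlier_vmr | ch_dmr),
    chrom, start, end (1-based
    inclusive first/last planted cytosine), n_loci, context, tissues
    (comma-joined affected tissues or groups), effect (delta for mean
    shifts; sigma for VMR level shifts), detail (free-form, e.g. SNP
    genotypes or the outlier sample).
    """

    regions: pd.DataFrame

    COLUMNS = ["kind", "chrom", "start", "end", "n_loci", "context", "tissues", "effect", "detail"]

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.regions[self.regions["kind"] == kind].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.regions)

    def write(self, path) -> None:
        self.regions.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthSet":
        return cls(
            pd.read_csv(
                path, sep="\t", keep_default_na=False,
                dtype={"chrom": str, "kind": str, "tissues": str, "detail": str},
            )
        )

    def to_bed_frame(self) -> pd.DataFrame:
        """Truth intervals in BED (0-based half-open) coordinates."""
        df = self.regions
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"] - 1,
                "end": df["end"],
                "name": [f"{k}_{i}" for i, k in enumerate(df["kind"])],
            }
        )


@dataclass
class SimulationResult:
    datasets: dict[str, MethylationDataset]  # "CG" (per-strand) + CH strata like "CA+"
    samples: SampleTable
    truth: TruthSet
    config: SimulationConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _make_sample_table(cfg: SimulationConfig) -> SampleTable:
    rows = []
    tissues = tuple(cfg.tissues) + tuple(cfg.non_brain)
    for tissue in tissues:
        for d in range(cfg.samples_per_tissue):
            donor = f"d{d + 1:02d}"
            rows.append(
                [f"{tissue}_{donor}", donor, tissue, tissue,
                 "non_brain" if tissue in cfg.non_brain else "brain"]
            )
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "donor_id", "tissue", "group", "tissue_class"])
    )


def _cpg_positions(rng: np.random.Generator, length: int, cfg: SimulationConfig):
    """Clustered CpG site positions (of the + strand C) and island flags."""
    open_sea = np.cumsum(rng.exponential(cfg.opensea_spacing, int(2 * length / cfg.opensea_spacing)) + 2.0)
    open_sea = open_sea[open_sea < length - 2]
    n_islands = max(0, int(np.round(cfg.islands_per_mb * length / 1e6)))
    island_pos = []
    for center in np.sort(rng.uniform(0, length, n_islands)):
        n_cpg = max(3, int(rng.poisson(cfg.island_size_mean)))
        offs = np.cumsum(rng.exponential(cfg.island_spacing, n_cpg) + 2.0)
        island_pos.append(center + offs - offs.mean())
    island = np.concatenate(island_pos) if island_pos else np.empty(0)
    island = island[(island > 1) & (island < length - 2)]

    pos = np.concatenate([open_sea, island]).astype(np.int64)
    flag = np.concatenate([np.zeros(len(open_sea), bool), np.ones(len(island), bool)])
    order = np.argsort(pos, kind="stable")
    pos, flag = pos[order], flag[order]
    keep = np.concatenate([[True], np.diff(pos) >= 2])  # room for the - strand C
    return np.maximum(pos[keep], 1), flag[keep]


def _pick_runs(
    rng: np.random.Generator,
    n_loci_per_chrom: dict[str, int],
    used: dict[str, np.ndarray],
    n_regions: int,
    size_range: tuple[int, int],
    positions: dict[str, np.ndarray] | None = None,
    max_internal_gap: int | None = None,
) -> list[tuple[str, int, int]]:
    """Choose non-overlapping runs of consecutive loci; returns (chrom, i0, i1).

    With ``max_internal_gap`` set, candidate runs containing a larger
    inter-locus gap are rejected: planted regulatory-scale regions live in
    locally CpG-dense sequence, mirroring the density of real DMRs/VMRs.
    """
    chroms = list(n_loci_per_chrom)
    out = []
    attempts = 0
    while len(out) < n_regions and attempts < 500 * max(1, n_regions):
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        L = n_loci_per_chrom[chrom]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if size >= L:
            continue
        i0 = int(rng.integers(0, L - size))
        if used[chrom][i0 : i0 + size].any():
            continue
        if max_internal_gap is not None and positions is not None:
            gaps = np.diff(positions[chrom][i0 : i0 + size])
            if len(gaps) and gaps.max() > max_internal_gap:
                continue
        used[chrom][i0 : i0 + size] = True
        out.append((chrom, i0, i0 + size))
    if len(out) < n_regions:
        raise MethregionsError("could not place all planted regions; genome too small")
    return out


def _betabinom_counts(rng, cov: np.ndarray, pi: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draws; the Beta draw happens once per (locus, sample)."""
    if rho <= 1e-9:
        p = pi
    else:
        a = pi * (1 - rho) / rho
        b = (1 - pi) * (1 - rho) / rho
        p = rng.beta(a, b)
    return rng.binomial(cov, p)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate count datasets, a sample table, and the planted-region truth set."""
    rng = np.random.default_rng(cfg.seed)
    samples = _make_sample_table(cfg)
    S = samples.n
    tissue_arr = samples.frame["tissue"].to_numpy()
    donor_arr = samples.frame["donor_id"].to_numpy()
    all_tissues = list(dict.fromkeys(tissue_arr))

    # --- CpG landscape ----------------------------------------------------
    chrom_pos: dict[str, np.ndarray] = {}
    chrom_island: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        pos, flag = _cpg_positions(rng, length, cfg)
        chrom_pos[chrom] = pos
        chrom_island[chrom] = flag
    n_per_chrom = {c: len(p) for c, p in chrom_pos.items()}

    baseline = {}
    for chrom in chrom_pos:
        base = np.where(chrom_island[chrom], cfg.baseline_island, cfg.baseline_opensea)
        baseline[chrom] = np.clip(base + rng.normal(0, cfg.baseline_jitter_sd, len(base)), 0.01, 0.99)

    # --- plant regions ----------------------------------------------------
    used = {c: np.zeros(n, bool) for c, n in n_per_chrom.items()}
    truth_rows: list[dict] = []
    # per-chromosome additive effect per (locus, sample)
    effect = {c: np.zeros((n, S)) for c, n in n_per_chrom.items()}

    def _signed(delta: float, base_mean: float) -> float:
        return -delta if base_mean > 0.5 else delta

    dense = dict(positions=chrom_pos, max_internal_gap=cfg.planted_max_gap_bp)

    for chrom, i0, i1 in _pick_runs(rng, n_per_chrom, used, cfg.n_dmrs, cfg.dmr_n_loci, **dense):
        group = all_tissues[rng.integers(len(cfg.tissues))]
        delta = float(rng.uniform(*cfg.dmr_delta))
        d = _signed(delta, float(baseline[chrom][i0:i1].mean()))
        effect[chrom][i0:i1, tissue_arr == group] += d
        truth_rows.append(dict(kind="dmr", chrom=chrom, start=int(chrom_pos[chrom][i0]),
                               end=int(chrom_pos[chrom][i1 - 1]), n_loci=i1 - i0, context="CG",
                               tissues=group, effect=d, detail=""))

    for chrom, i0, i1 in _pick_runs(rng, n_per_chrom, used, cfg.n_blocks, cfg.block_n_loci):
        group = all_tissues[rng.integers(len(cfg.tissues))]
        delta = float(rng.uniform(*cfg.block_delta))
        d = _signed(delta, float(baseline[chrom][i0:i1].mean()))
        effect[chrom][i0:i1, tissue_arr == group] += d
        truth_rows.append(dict(kind="block", chrom=chrom, start=int(chrom_pos[chrom][i0]),
                               end=int(chrom_pos[chrom][i1 - 1]), n_loci=i1 - i0, context="CG",
                               tissues=group, effect=d, detail=""))

    def _rebase_mid(chrom: str, i0: int, i1: int) -> None:
        base = rng.uniform(*cfg.vmr_base_range)
        baseline[chrom][i0:i1] = np.clip(
            base + rng.normal(0, cfg.baseline_jitter_sd, i1 - i0), 0.01, 0.99
        )

    for chrom, i0, i1 in _pick_runs(rng, n_per_chrom, used, cfg.n_vmrs, cfg.vmr_n_loci, **dense):
        _rebase_mid(chrom, i0, i1)
        u = rng.uniform()
        if u < 0.4:
            affected = [all_tissues[rng.integers(len(all_tissues))]]
        elif u < 0.7:
            affected = list(all_tissues)
        else:
            k = int(rng.integers(2, max(3, len(all_tissues))))
            affected = list(rng.choice(all_tissues, size=min(k, len(all_tissues)), replace=False))
        mask = np.isin(tissue_arr, affected)
        shifts = rng.normal(0, cfg.vmr_sigma, S) * mask
        effect[chrom][i0:i1, :] += shifts[None, :]
        truth_rows.append(dict(kind="vmr", chrom=chrom, start=int(chrom_pos[chrom][i0]),
                               end=int(chrom_pos[chrom][i1 - 1]), n_loci=i1 - i0, context="CG",
                               tissues=",".join(sorted(affected)), effect=cfg.vmr_sigma, detail=""))

    for chrom, i0, i1 in _pick_runs(rng, n_per_chrom, used, cfg.n_snp_vmrs, cfg.vmr_n_loci, **dense):
        _rebase_mid(chrom, i0, i1)
        donors = sorted(set(donor_arr))
        geno = {d: int(rng.binomial(2, cfg.snp_maf)) for d in donors}
        shifts = np.array([(geno[d] - 1) * cfg.snp_effect for d in donor_arr])
        effect[chrom][i0:i1, :] += shifts[None, :]
        snp_pos = int(chrom_pos[chrom][(i0 + i1) // 2])
        detail = "snp_pos=%d;genotypes=%s" % (snp_pos, ",".join(f"{d}:{geno[d]}" for d in donors))
        truth_rows.append(dict(kind="snp_vmr", chrom=chrom, start=int(chrom_pos[chrom][i0]),
                               end=int(chrom_pos[chrom][i1 - 1]), n_loci=i1 - i0, context="CG",
                               tissues=",".join(sorted(all_tissues)), effect=cfg.snp_effect,
                               detail=detail))

    for chrom, i0, i1 in _pick_runs(rng, n_per_chrom, used, cfg.n_outlier_vmrs, cfg.vmr_n_loci, **dense):
        _rebase_mid(chrom, i0, i1)
        tissue = all_tissues[rng.integers(len(all_tissues))]
        members = np.flatnonzero(tissue_arr == tissue)
        victim = int(members[rng.integers(len(members))])
        d = _signed(cfg.outlier_shift, float(baseline[chrom][i0:i1].mean()))
        effect[chrom][i0:i1, victim] += d
        truth_rows.append(dict(kind="outlier_vmr", chrom=chrom, start=int(chrom_pos[chrom][i0]),
                               end=int(chrom_pos[chrom][i1 - 1]), n_loci=i1 - i0, context="CG",
                               tissues=tissue, effect=d,
                               detail=f"sample={samples.sample_ids[victim]}"))

    # --- CpG counts (per strand; both strands share the site-level Beta draw)
    half = cfg.coverage_lambda / 2.0
    loci_frames, M_parts, C_parts = [], [], []
    for chrom in cfg.chrom_lengths:
        pos = chrom_pos[chrom]
        pi = np.clip(baseline[chrom][:, None] + effect[chrom], 0.003, 0.997)
        if cfg.dispersion > 1e-9:
            a = pi * (1 - cfg.dispersion) / cfg.dispersion
            b = (1 - pi) * (1 - cfg.dispersion) / cfg.dispersion
            p = rng.beta(a, b)
        else:
            p = pi
        cov_p = rng.poisson(half, size=p.shape)
        cov_m = rng.poisson(half, size=p.shape)
        m_p = rng.binomial(cov_p, p)
        m_m = rng.binomial(cov_m, p)
        n = len(pos)
        frame = pd.DataFrame(
            {
                "chrom": np.repeat(chrom, 2 * n),
                "pos": np.empty(2 * n, np.int64),
                "strand": np.empty(2 * n, object),
                "context": "CG",
            }
        )
        frame.loc[0::2, "pos"] = pos
        frame.loc[1::2, "pos"] = pos + 1
        frame.loc[0::2, "strand"] = "+"
        frame.loc[1::2, "strand"] = "-"
        M2 = np.empty((2 * n, S), np.int64)
        C2 = np.empty((2 * n, S), np.int64)
        M2[0::2], M2[1::2] = m_p, m_m
        C2[0::2], C2[1::2] = cov_p, cov_m
        loci_frames.append(frame)
        M_parts.append(M2)
        C_parts.append(C2)
    cg = MethylationDataset(
        pd.concat(loci_frames, ignore_index=True),
        np.concatenate(M_parts),
        np.concatenate(C_parts),
        samples,
    )
    datasets = {"CG": cg}

    # --- CH strata --------------------------------------------------------
    # keep every (chrom, strand, pos) unique across strata
    occupied: dict[tuple[str, str], set] = {}
    for chrom in cfg.chrom_lengths:
        occupied[(chrom, "+")] = set(chrom_pos[chrom].tolist())
        occupied[(chrom, "-")] = set((chrom_pos[chrom] + 1).tolist())
    for context in cfg.ch_contexts:
        for strand in ("+", "-"):
            datasets[f"{context}{strand}"] = _simulate_ch_stratum(
                rng, cfg, samples, context, strand, tissue_arr, all_tissues, truth_rows, occupied
            )

    truth = TruthSet(pd.DataFrame(truth_rows, columns=TruthSet.COLUMNS))
    return SimulationResult(datasets=datasets, samples=samples, truth=truth, config=cfg)


def _simulate_ch_stratum(
    rng, cfg, samples, context, strand, tissue_arr, all_tissues, truth_rows, occupied
):
    S = samples.n
    loci_frames, M_parts, C_parts = [], [], []
    for chrom, length in cfg.chrom_lengths.items():
        spacing = cfg.opensea_spacing / max(cfg.ch_fraction, 1e-6)
        pos = np.cumsum(rng.exponential(spacing, int(2 * length / spacing)) + 1.0)
        pos = pos[pos < length].astype(np.int64)
        pos = np.maximum(pos, 1)
        pos = pos[np.concatenate([[True], np.diff(pos) >= 1])]
        taken = occupied.setdefault((chrom, strand), set())
        pos = np.array([p for p in pos.tolist() if p not in taken], dtype=np.int64)
        taken.update(pos.tolist())
        n = len(pos)
        base = np.clip(rng.normal(cfg.ch_baseline, cfg.ch_jitter_sd, n), 0.003, 0.5)
        eff = np.zeros((n, S))
        n_regions = cfg.n_ch_dmrs // (2 * max(len(cfg.ch_contexts), 1) * len(cfg.chrom_lengths))
        n_regions = max(n_regions, 1) if cfg.n_ch_dmrs > 0 else 0
        used = {chrom: np.zeros(n, bool)}
        if n_regions:
            for c, i0, i1 in _pick_runs(rng, {chrom: n}, used, n_regions, cfg.ch_dmr_n_loci):
                group = all_tissues[rng.integers(len(cfg.tissues))]
                delta = float(rng.uniform(*cfg.ch_delta))
                eff[i0:i1, tissue_arr == group] += delta
                truth_rows.append(dict(kind="ch_dmr", chrom=chrom, start=int(pos[i0]),
                                       end=int(pos[i1 - 1]), n_loci=i1 - i0,
                                       context=f"{context}{strand}", tissues=group,
                                       effect=delta, detail=""))
        pi = np.clip(base[:, None] + eff, 0.003, 0.997)
        cov = rng.poisson(cfg.coverage_lambda, size=pi.shape)
        m = _betabinom_counts(rng, cov, pi, cfg.dispersion)
        loci_frames.append(
            pd.DataFrame({"chrom": np.repeat(chrom, n), "pos": pos, "strand": strand, "context": context})
        )
        M_parts.append(m)
        C_parts.append(cov)
    return MethylationDataset(
        pd.concat(loci_frames, ignore_index=True),
        np.concatenate(M_parts),
        np.concatenate(C_parts),
        samples,
    )


def simulate_null(cfg: SimulationConfig) -> SimulationResult:
    """The same design with no planted regions (exchangeable group labels)."""
    return simulate(cfg.null())


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------


def write_fixture(sim: SimulationResult, out_dir, gzip_reports: bool = False) -> dict:
    """Write per-sample cytosine reports, the sample sheet, and the truth set.

    Each sample's report merges every context stratum, sorted by (chrom,
    pos).  Returns a manifest mapping sample_id -> report path plus the
    sheet/truth paths; files round-trip through the readers to equal
    matrices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".txt.gz" if gzip_reports else ".txt"

    merged_loci, merged_M, merged_C = [], [], []
    for name in sorted(sim.datasets):
        d = sim.datasets[name]
        merged_loci.append(d.loci)
        merged_M.append(d.M)
        merged_C.append(d.Cov)
    loci = pd.concat(merged_loci, ignore_index=True)
    M = np.concatenate(merged_M)
    Cov = np.concatenate(merged_C)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy().astype(str)))
    loci = loci.iloc[order].reset_index(drop=True)
    M, Cov = M[order], Cov[order]

    manifest = {"reports": {}, "sample_sheet": str(out_dir / "sample_sheet.tsv"),
                "truth": str(out_dir / "truth.tsv"), "truth_bed": str(out_dir / "truth.bed")}
    for si, sid in enumerate(sim.samples.sample_ids):
        path = out_dir / f"{sid}.cytosine_report{suffix}"
        report = loci[["chrom", "pos", "strand"]].copy()
        report["count_m"] = M[:, si]
        report["count_u"] = Cov[:, si] - M[:, si]
        report["context"] = loci["context"]
        report.to_csv(path, sep="\t", header=False, index=False)
        manifest["reports"][sid] = str(path)

    sim.samples.to_csv(manifest["sample_sheet"])
    sim.truth.write(manifest["truth"])
    bed = sim.truth.to_bed_frame()
    bed.to_csv(manifest["truth_bed"], sep="\t", index=False, header=False)
    return manifest
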