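"""End-to-end orchestration: configuration, staging, provenance.

A :class:`RunConfig` (built in code or loaded from YAML) names the inputs
(either a simulation block or per-sample cytosine reports plus a sample
sheet), the grouping scheme, the smoothing preset, and the DMR/VMR/
enrichment parameters.  :func:`run` validates the configuration before any
compute starts, executes the requested stages, writes delimited region
tables and BED files, and records a machine-readable provenance manifest.
All stochastic stages consume the configured seed; re-running an identical
configuration reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import dmr as _dmr
from . import enrich as _enrich
from . import io as _io
from . import smoothing as _smoothing
from . import vmr as _vmr
from .core import ConfigError, MethylationDataset, RegionSet
from .simulate import SimulationConfig, simulate as _simulate

logger = logging.getLogger("methregions")


@dataclass
class RunConfig:
    output_dir: str
    seed: int
    analyses: tuple[str, ...] = ("dmr", "vmr")  # any of: dmr, block, ch_dmr, vmr, enrich
    # input: exactly one of `simulation` (kwargs for SimulationConfig) or
    # `reports` (+ sample_sheet)
    simulation: dict | None = None
    reports: dict[str, str] | None = None
    sample_sheet: str | None = None
    grouping: dict[str, str] | None = None  # tissue -> group
    smoothing_preset: str = "cg_small"
    dmr_params: dict = field(default_factory=dict)  # cutoff_quantile, max_gap_bp, min_loci, B, alpha
    vmr_params: dict = field(default_factory=dict)  # min_cov, min_samples, q, cooks_threshold, min_cpgs
    feature_beds: dict[str, str] = field(default_factory=dict)  # name -> BED path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        known = {"dmr", "block", "ch_dmr", "vmr", "enrich"}
        bad = set(self.analyses) - known
        if bad:
            raise ConfigError(f"unknown analyses: {sorted(bad)}")
        if (self.simulation is None) == (self.reports is None):
            raise ConfigError("configure exactly one of 'simulation' or 'reports'")
        if self.reports is not None and self.sample_sheet is None:
            raise ConfigError("'reports' input requires 'sample_sheet'")
        if self.smoothing_preset not in ("cg_small", "cg_block", "ch"):
            raise ConfigError(f"unknown smoothing preset {self.smoothing_preset!r}")
        for name, path in self.feature_beds.items():
            if not Path(path).exists():
                raise ConfigError(f"feature BED {name!r} not found: {path}")


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = _simulate(SimulationConfig(**sim_kwargs))
        return sim.datasets, sim.samples, sim.truth
    samples = _io.read_sample_sheet(cfg.sample_sheet)
    missing = [s for s in samples.sample_ids if s not in cfg.reports]
    if missing:
        raise ConfigError(f"no report configured for samples: {missing}")
    cg = _io.read_cytosine_reports(cfg.reports, samples, context_filter={"CG"})
    datasets = {"CG": cg}
    for context in ("CA", "CT", "CC"):
        for strand in ("+", "-"):
            stratum = _io.read_cytosine_reports(
                cfg.reports, samples, context_filter={context}, strand_filter=strand
            )
            if stratum.n_loci:
                datasets[f"{context}{strand}"] = stratum
    return datasets, samples, None


def _timed(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
    return out


def run(cfg: RunConfig) -> dict:
    """Execute the configured analyses; returns the provenance manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(cfg), "seed": cfg.seed, "outputs": {}}

    try:
        datasets, samples, truth = _timed("load", _load_inputs, cfg)
        if cfg.grouping:
            samples = samples.with_groups(cfg.grouping)

        cg = _timed("collapse", _io.collapse_cpg_strands, datasets["CG"])
        cg = MethylationDataset(cg.loci, cg.M, cg.Cov, samples)

        smoothed = None
        region_sets: dict[str, RegionSet] = {}

        if {"dmr", "block", "vmr", "enrich"} & set(cfg.analyses):
            smoothed = _timed(
                "smooth", _smoothing.smooth, cg, _smoothing.preset(cfg.smoothing_preset)
            )

        if "dmr" in cfg.analyses:
            rs = _timed(
                "dmr", _dmr.permutation_fwer, smoothed,
                seed=cfg.seed, **{"B": 50, **cfg.dmr_params},
            )
            for r in rs:
                _dmr.annotate_pairwise(r, smoothed)
            region_sets["cg_dmr"] = rs
            _write_region_set(rs, out, "cg_dmr", manifest)

        if "block" in cfg.analyses:
            block_smoothed = _timed(
                "smooth_block", _smoothing.smooth, cg, _smoothing.preset("cg_block")
            )
            rs = _timed(
                "block", _dmr.permutation_fwer, block_smoothed,
                seed=cfg.seed, kind="cg_block",
                **{"B": 50, "max_gap_bp": _dmr.DEFAULT_MAX_GAP["cg_block"], **cfg.dmr_params},
            )
            region_sets["cg_block"] = rs
            _write_region_set(rs, out, "cg_block", manifest)

        if "ch_dmr" in cfg.analyses:
            strata = {k: v for k, v in datasets.items() if k != "CG"}
            if strata:
                rs = _timed(
                    "ch_dmr", _dmr.ch_dmr_analysis, strata, samples,
                    seed=cfg.seed,
                    **{"B": 50, "max_gap_bp": _dmr.DEFAULT_MAX_GAP["ch"], **cfg.dmr_params},
                )
                region_sets["ch_dmr"] = rs
                _write_region_set(rs, out, "ch_dmr", manifest)

        if "vmr" in cfg.analyses:
            res = _timed("vmr", _vmr.vmr_analysis, cg, smoothed, **cfg.vmr_params)
            table = res.table()
            table.to_csv(out / "vmr_regions.tsv", sep="\t", index=False)
            _vmr.sharing_table(res.sharing).to_csv(out / "vmr_sharing.tsv", sep="\t", index=False)
            manifest["outputs"]["vmr_regions"] = "vmr_regions.tsv"
            manifest["outputs"]["vmr_sharing"] = "vmr_sharing.tsv"
            manifest["vmr_cutoff"] = res.cutoff
            for tissue in res.per_tissue:
                region_sets[f"vmr_{tissue}"] = res.region_set(tissue)

        if "enrich" in cfg.analyses and cfg.feature_beds:
            features = [_io.read_bed(path, name) for name, path in cfg.feature_beds.items()]
            frames = []
            for name, rs in region_sets.items():
                df, _ = _enrich.enrich_batch(cg.loci, rs, features)
                df.insert(0, "analysis", name)
                frames.append(df)
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )
                manifest["outputs"]["enrichment"] = "enrichment.tsv"

        if truth is not None:
            truth.write(out / "truth.tsv")
            manifest["outputs"]["truth"] = "truth.tsv"

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_region_set(rs: RegionSet, out: Path, name: str, manifest: dict) -> None:
    rs.to_dataframe().to_csv(out / f"{name}_regions.tsv", sep="\t", index=False)
    _io.write_regions_bed(rs, out / f"{name}_regions.bed")
    manifest["outputs"][name] = f"{name}_regions.tsv"
    manifest["outputs"][f"{name}_bed"] = f"{name}_regions.bed"
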