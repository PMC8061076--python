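"""Reusable simulation experiments: FWER calibration and recovery rates.

These drive both the test suite and the reproduction script.  Every
experiment takes an explicit seed and derives per-replicate seeds from it,
so results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import dmr as _dmr
from . import io as _io
from . import smoothing as _smoothing
from . import vmr as _vmr
from .simulate import SimulationConfig, simulate, simulate_null

_SEED_MOD = 2**31 - 1


def _sub_seed(seed: int, i: int, salt: int) -> int:
    return (seed * 1_000_003 + salt * 7919 + i) % _SEED_MOD


def null_fwer_calibration(
    n_replicates: int = 200,
    B: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    samples_per_tissue: int = 5,
    progress: bool = False,
) -> dict:
    """Family-wise error rate of the CG-DMR caller on null simulations.

    Each replicate simulates the 5-group design with exchangeable labels and
    no planted regions (~40,000 CpGs), runs strand collapsing, smoothing,
    F-statistic segmentation, and permutation FWER control, and records
    whether any region reaches significance at ``alpha``.  Returns the
    observed family-wise error fraction and its Monte-Carlo standard error.
    """
    hits = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=_sub_seed(seed, i, 1),
            samples_per_tissue=samples_per_tissue,
            ch_contexts=(),
        )
        sim = simulate_null(cfg)
        cg = _io.collapse_cpg_strands(sim.datasets["CG"])
        sm = _smoothing.smooth(cg, _smoothing.preset("cg_small"))
        rs = _dmr.permutation_fwer(sm, B=B, seed=_sub_seed(seed, i, 2), alpha=alpha)
        if any(r.significant for r in rs):
            hits += 1
        if progress and (i + 1) % 20 == 0:
            print(f"  null replicate {i + 1}/{n_replicates}: fwer so far {hits / (i + 1):.3f}")
    frac = hits / n_replicates
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {"fwer": frac, "n_replicates": n_replicates, "B": B, "alpha": alpha, "mc_se": mc_se}


def _overlaps(chrom, start, end, items) -> bool:
    return any(c == chrom and s <= end and start <= e for c, s, e in items)


def dmr_recovery(n_replicates: int = 3, B: int = 50, seed: int = 0) -> dict:
    """Sensitivity of permutation-significant CG-DMRs against planted truth
    (>= 1 bp overlap) on the standard synthetic configuration."""
    tp = n = 0
    for i in range(n_replicates):
        sim = simulate(SimulationConfig(seed=_sub_seed(seed, i, 3), ch_contexts=()))
        cg = _io.collapse_cpg_strands(sim.datasets["CG"])
        sm = _smoothing.smooth(cg, _smoothing.preset("cg_small"))
        rs = _dmr.permutation_fwer(sm, B=B, seed=_sub_seed(seed, i, 4))
        sig = [(r.chrom, r.start, r.end) for r in rs if r.significant]
        truth = sim.truth.of_kind("dmr")
        tp += sum(_overlaps(t.chrom, t.start, t.end, sig) for _, t in truth.iterrows())
        n += len(truth)
    return {"sensitivity": tp / n, "n_planted": n, "n_replicates": n_replicates}


def vmr_recovery(n_replicates: int = 3, seed: int = 0) -> dict:
    """Sensitivity and truth-FDR of retained VMRs on the standard synthetic
    configuration.

    Sensitivity counts planted level-shift VMRs recovered by a retained VMR
    (>= 1 bp overlap); the false-discovery fraction counts retained VMRs
    overlapping no planted variability region of any kind.
    """
    tp = n = fp = ret_n = 0
    for i in range(n_replicates):
        sim = simulate(SimulationConfig(seed=_sub_seed(seed, i, 5), ch_contexts=()))
        cg = _io.collapse_cpg_strands(sim.datasets["CG"])
        sm = _smoothing.smooth(cg, _smoothing.preset("cg_small"))
        res = _vmr.vmr_analysis(cg, sm)
        retained = [
            (v.chrom, v.start, v.end)
            for vs in res.per_tissue.values()
            for v in vs
            if v.retained
        ]
        truth_sigma = sim.truth.of_kind("vmr")
        truth_any = sim.truth.regions[
            sim.truth.regions["kind"].isin(["vmr", "snp_vmr", "outlier_vmr"])
        ]
        any_items = [(t.chrom, t.start, t.end) for _, t in truth_any.iterrows()]
        tp += sum(_overlaps(t.chrom, t.start, t.end, retained) for _, t in truth_sigma.iterrows())
        n += len(truth_sigma)
        fp += sum(not _overlaps(c, s, e, any_items) for c, s, e in retained)
        ret_n += len(retained)
    return {
        "sensitivity": tp / n,
        "fdr": fp / max(ret_n, 1),
        "n_planted": n,
        "n_retained": ret_n,
        "n_replicates": n_replicates,
    }


def outlier_removal_rate(n_replicates: int = 40, seed: int = 0) -> dict:
    """Fraction of replicates whose outlier-driven pseudo-VMRs are removed.

    Each replicate plants VMR-sized regions whose variability comes solely
    from a single shifted sample; the Cook's-distance filter should leave no
    retained VMR over such a region.
    """
    removed = total = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=_sub_seed(seed, i, 6),
            chrom_lengths={"chr1": 600_000},
            n_dmrs=0,
            n_blocks=0,
            n_vmrs=6,
            n_snp_vmrs=0,
            n_outlier_vmrs=3,
            ch_contexts=(),
        )
        sim = simulate(cfg)
        cg = _io.collapse_cpg_strands(sim.datasets["CG"])
        sm = _smoothing.smooth(cg, _smoothing.preset("cg_small"))
        res = _vmr.vmr_analysis(cg, sm)
        retained = [
            (v.chrom, v.start, v.end)
            for vs in res.per_tissue.values()
            for v in vs
            if v.retained
        ]
        for _, t in sim.truth.of_kind("outlier_vmr").iterrows():
            total += 1
            if not _overlaps(t.chrom, t.start, t.end, retained):
                removed += 1
    return {"removal_rate": removed / max(total, 1), "n_planted": total, "n_replicates": n_replicates}


def enrichment_null_center(n_replicates: int = 200, seed: int = 0) -> dict:
    """Mean log2 odds ratio when regions are placed uniformly at random.

    With no association between regions and features the enrichment log2 OR
    is centered at zero; returns the mean across replicates and its
    Monte-Carlo standard error.
    """
    from .core import GenomicFeatureSet, Region, RegionSet
    from .enrich import build_contingency, log2_odds_ratio
    import pandas as pd

    rng = np.random.default_rng(seed)
    length = 1_000_000
    # cell counts are kept in the hundreds so the log-OR estimator's
    # small-count skew is negligible relative to the Monte-Carlo error
    pos = np.sort(rng.choice(np.arange(1, length), size=20_000, replace=False))
    loci = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "both", "context": "CG"})
    feat_starts = np.sort(rng.choice(length - 3000, size=80, replace=False))
    feature = GenomicFeatureSet("feat", np.repeat("chr1", 80), feat_starts, feat_starts + 2500)

    vals = []
    for _ in range(n_replicates):
        starts = rng.integers(1, length - 4000, size=40)
        regions = RegionSet(
            [Region("chr1", int(s), int(s + 3000), 1, 0.0, 0.0) for s in np.sort(starts)],
            kind="cg_dmr",
        )
        res = log2_odds_ratio(build_contingency(loci, regions, feature))
        if not res.undefined:
            vals.append(res.log2_or)
    vals = np.array(vals)
    return {
        "mean_log2_or": float(vals.mean()),
        "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "n": int(len(vals)),
    }
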