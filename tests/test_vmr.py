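import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methregions as mr
from methregions.vmr import VMR, call_vmrs, methylation_span

from conftest import make_dataset, make_samples, make_smoothed


# ---------------------------------------------------------------------------
# coverage filter and SD machinery
# ---------------------------------------------------------------------------


def test_coverage_filter_strict_inequalities():
    samples = make_samples({"t": 4})
    cov = np.array([[5, 5, 5, 5], [6, 6, 6, 0], [6, 6, 6, 6]])
    d = make_dataset([10, 20, 30], np.zeros_like(cov), cov, samples)
    mask = mr.coverage_filter(d, min_cov=5, min_samples=2)
    # row 0: Cov == min_cov everywhere -> dropped (strict >)
    # row 1: 3 samples with Cov > 5 and 3 > 2 -> kept
    assert mask.tolist() == [False, True, True]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_coverage_filter_matches_count_oracle(seed):
    rng = np.random.default_rng(seed)
    n, s = int(rng.integers(1, 40)), int(rng.integers(1, 8))
    cov = rng.poisson(6, (n, s))
    d = make_dataset(
        np.arange(1, n + 1) * 5, np.zeros_like(cov), cov, make_samples({"t": s})
    )
    min_cov, min_samples = int(rng.integers(0, 10)), int(rng.integers(0, s))
    mask = mr.coverage_filter(d, min_cov, min_samples)
    expected = [(row > min_cov).sum() > min_samples for row in cov]
    assert mask.tolist() == expected


def test_per_tissue_sd_closed_forms():
    samples = make_samples({"t": 3})
    beta = np.array([[0.4, 0.4, 0.4], [0.0, 1.0, np.nan]])
    s = make_smoothed([10, 20], beta, samples)
    sd = mr.per_tissue_sd(s, "t")
    assert sd[0] == pytest.approx(0.0, abs=1e-12)
    assert sd[1] == pytest.approx(np.sqrt(0.5), abs=1e-12)  # {0, 1}: SD = 0.7071


def test_per_tissue_sd_matches_textbook_formula():
    rng = np.random.default_rng(9)
    samples = make_samples({"t": 6})
    beta = rng.uniform(size=(40, 6))
    s = make_smoothed(np.arange(1, 41) * 7, beta, samples)
    sd = mr.per_tissue_sd(s, "t")
    mean = beta.mean(axis=1, keepdims=True)
    expected = np.sqrt(((beta - mean) ** 2).sum(axis=1) / 5)
    assert np.allclose(sd, expected)


def test_per_tissue_sd_needs_three_samples():
    s = make_smoothed([10], np.array([[0.1, 0.2]]), make_samples({"t": 2}))
    with pytest.raises(mr.MethregionsError):
        mr.per_tissue_sd(s, "t")


def test_select_cutoff_minimum_across_tissues():
    sds = {
        "a": np.full(200, 0.12), "b": np.full(200, 0.095), "c": np.full(200, 0.11),
    }
    assert mr.select_cutoff(sds) == pytest.approx(0.095)
    assert mr.select_cutoff({"only": np.linspace(0, 1, 101)}) == pytest.approx(
        np.quantile(np.linspace(0, 1, 101), 0.99)
    )
    with pytest.raises(mr.MethregionsError):
        mr.select_cutoff({"bad": np.array([np.nan])})


def test_methylation_span_of_cutoff():
    # +/- 2 SD at the cutoff spans 4 x cutoff on the methylation scale
    assert methylation_span(0.095) == pytest.approx(0.38)


# ---------------------------------------------------------------------------
# VMR calling
# ---------------------------------------------------------------------------


def _loci(pos, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, np.int64), "strand": "both", "context": "CG"}
    )


def test_call_vmrs_examples():
    pos = (np.arange(15) + 1) * 10
    sd = np.full(15, 0.01)
    assert call_vmrs(sd, _loci(pos), cutoff=0.05, tissue="t") == []
    sd11 = np.concatenate([np.full(11, 0.2), np.full(4, 0.01)])
    out = call_vmrs(sd11, _loci(pos), cutoff=0.05, tissue="t")
    assert len(out) == 1 and out[0].n_cpgs == 11 and out[0].tissue == "t"
    # 10 qualifying loci only -> dropped ("> 10 CpGs")
    sd10 = np.concatenate([np.full(10, 0.2), np.full(5, 0.01)])
    assert call_vmrs(sd10, _loci(pos), cutoff=0.05, tissue="t") == []


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_call_vmrs_matches_run_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 80))
    pos = np.sort(rng.choice(np.arange(1, 4000), n, replace=False))
    sd = rng.uniform(0, 0.2, n)
    cutoff, max_gap, min_cpgs = 0.1, 300, 3
    out = call_vmrs(sd, _loci(pos), cutoff, "t", max_gap, min_cpgs)
    runs, cur = [], []
    for i in range(n):
        if sd[i] > cutoff and (not cur or pos[i] - pos[cur[-1]] <= max_gap):
            cur.append(i)
        else:
            if len(cur) >= min_cpgs:
                runs.append(cur)
            cur = [i] if sd[i] > cutoff else []
    if len(cur) >= min_cpgs:
        runs.append(cur)
    assert [(v.start, v.end, v.n_cpgs) for v in out] == [
        (pos[r[0]], pos[r[-1]], len(r)) for r in runs
    ]
    for v, r in zip(out, runs):
        assert v.max_sd == pytest.approx(sd[r].max())


def test_raising_cutoff_is_monotone():
    rng = np.random.default_rng(4)
    pos = np.sort(rng.choice(10_000, 300, replace=False)) + 1
    sd = rng.uniform(0, 0.3, 300)
    counts = [
        len(call_vmrs(sd, _loci(pos), c, "t", min_cpgs=3)) for c in (0.05, 0.1, 0.15, 0.2)
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# Cook's filter and effect size
# ---------------------------------------------------------------------------


def _region_for(beta, samples):
    s = make_smoothed(np.arange(1, beta.shape[0] + 1) * 10, beta, samples)
    v = VMR("chr1", 10, beta.shape[0] * 10, beta.shape[0], samples.tissues[0],
            0.2, 0.2, locus_slice=(0, beta.shape[0]))
    return v, s


def test_cooks_all_equal_retained():
    samples = make_samples({"t": 5})
    v, s = _region_for(np.full((12, 5), 0.4), samples)
    cooks, retained = mr.cooks_filter(v, s)
    assert cooks == 0.0 and retained


def test_cooks_two_samples_degenerate_rejected():
    samples = make_samples({"t": 2})
    v, s = _region_for(np.tile([0.2, 0.8], (12, 1)), samples)
    cooks, retained = mr.cooks_filter(v, s)
    assert not retained and v.note == "insufficient samples"


def test_cooks_outlier_matches_closed_form_and_statsmodels():
    """n = 10, nine values 0.2 and one 0.9: max Cook's distance matches both
    the closed form and statsmodels' influence diagnostics, and exceeds 0.7."""
    import statsmodels.api as sm_api

    y = np.array([0.2] * 9 + [0.9])
    samples = make_samples({"t": 10})
    v, s = _region_for(np.tile(y, (12, 1)), samples)
    cooks, retained = mr.cooks_filter(v, s)
    n = 10
    e = y - y.mean()
    s2 = (e**2).sum() / (n - 1)
    h = 1 / n
    expected = (e**2 * h / (s2 * (1 - h) ** 2)).max()
    assert cooks == pytest.approx(expected, rel=1e-12)
    ols = sm_api.OLS(y, np.ones((n, 1))).fit()
    sm_cooks = ols.get_influence().cooks_distance[0]
    assert cooks == pytest.approx(sm_cooks.max(), rel=1e-9)
    assert cooks > 0.7 and not retained


def test_effect_size_is_range_of_sample_means():
    samples = make_samples({"t": 3})
    beta = np.tile([0.2, 0.5, 0.7], (12, 1))
    v, s = _region_for(beta, samples)
    assert mr.effect_size(v, s) == pytest.approx(0.5)
    v2, s2 = _region_for(np.full((12, 3), 0.4), samples)
    assert mr.effect_size(v2, s2) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# sharing classification
# ---------------------------------------------------------------------------


def _vmr(chrom, start, end, tissue):
    return VMR(chrom, start, end, 11, tissue, 0.2, 0.15)


def test_classify_sharing_examples():
    per_tissue = {
        "a": [_vmr("chr1", 100, 200, "a")],
        "b": [_vmr("chr1", 150, 260, "b"), _vmr("chr2", 50, 80, "b")],
        "c": [_vmr("chr1", 250, 320, "c")],
    }
    merged = mr.classify_sharing(per_tissue, ["a", "b", "c"])
    classes = {(m.chrom, m.start, m.end): m.sharing_class for m in merged}
    # chained overlap a-b-c merges transitively into one ubiquitous interval
    assert classes[("chr1", 100, 320)] == "ubiquitous"
    assert classes[("chr2", 50, 80)] == "tissue_specific"


def test_classify_sharing_shared_class_and_partition():
    per_tissue = {
        "a": [_vmr("chr1", 10, 50, "a"), _vmr("chr1", 500, 600, "a")],
        "b": [_vmr("chr1", 40, 90, "b")],
        "c": [],
    }
    merged = mr.classify_sharing(per_tissue, ["a", "b", "c"])
    by_class = {}
    for m in merged:
        by_class.setdefault(m.sharing_class, []).append(m)
    assert len(by_class.get("shared", [])) == 1
    assert len(by_class.get("tissue_specific", [])) == 1
    # classes partition the merged intervals
    assert sum(len(v) for v in by_class.values()) == len(merged)


def test_classify_sharing_ignores_unretained():
    v = _vmr("chr1", 10, 50, "a")
    v.retained = False
    assert mr.classify_sharing({"a": [v]}, ["a"]) == []


# ---------------------------------------------------------------------------
# end-to-end analysis bundle
# ---------------------------------------------------------------------------


def test_vmr_analysis_on_planted_simulation(small_sim):
    cg = mr.collapse_cpg_strands(small_sim.datasets["CG"])
    sm = mr.smooth(cg, mr.preset("cg_small"))
    res = mr.vmr_analysis(cg, sm)
    assert res.cutoff > 0
    table = res.table()
    assert set(table.columns) >= {"chrom", "start", "end", "n_cpgs", "tissue", "retained"}
    retained = table[table["retained"]]
    assert len(retained) > 0
    assert (retained["n_cpgs"] > 10).all()
    assert retained["effect_size"].between(0, 1).all()
    # at least half of the planted level-shift VMRs are recovered here
    vt = small_sim.truth.of_kind("vmr")
    hits = sum(
        ((retained["chrom"] == t.chrom) & (retained["start"] <= t.end)
         & (retained["end"] >= t.start)).any()
        for _, t in vt.iterrows()
    )
    assert hits >= len(vt) / 2
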