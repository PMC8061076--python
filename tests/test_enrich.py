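import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methregions as mr
from methregions.enrich import ContingencyTable

from conftest import make_samples


def _loci(pos, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, np.int64), "strand": "both", "context": "CG"}
    )


def _regions(intervals):
    return mr.RegionSet(
        [mr.Region(c, s, e, 1, 0.0, 0.0) for c, s, e in intervals], kind="cg_dmr"
    )


def test_contingency_no_regions():
    t = mr.build_contingency(
        _loci([10, 20, 30]), _regions([]), mr.GenomicFeatureSet.from_intervals("f", [("chr1", 0, 25)])
    )
    assert (t.n11, t.n12) == (0, 0) and t.n21 == 2 and t.n22 == 1


def test_contingency_feature_covers_everything():
    t = mr.build_contingency(
        _loci([10, 20, 30]),
        _regions([("chr1", 5, 15)]),
        mr.GenomicFeatureSet.from_intervals("f", [("chr1", 0, 1000)]),
    )
    assert t.n12 == 0 and t.n22 == 0 and t.total == 3


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_contingency_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 500), size=int(rng.integers(1, 60)), replace=False))
    r_iv = [("chr1", int(s), int(s + rng.integers(1, 40))) for s in rng.integers(1, 450, 4)]
    f_iv = [("chr1", int(s), int(s + rng.integers(1, 40))) for s in rng.integers(0, 450, 4)]
    t = mr.build_contingency(
        _loci(pos), _regions(r_iv), mr.GenomicFeatureSet.from_intervals("f", f_iv)
    )
    in_r = [any(s <= p <= e for _, s, e in r_iv) for p in pos]  # 1-based inclusive span
    in_f = [any(fs <= p - 1 < fe for _, fs, fe in f_iv) for p in pos]  # 0-based half-open
    assert t.n11 == sum(a and b for a, b in zip(in_r, in_f))
    assert t.n12 == sum(a and not b for a, b in zip(in_r, in_f))
    assert t.n21 == sum(b and not a for a, b in zip(in_r, in_f))
    assert t.n22 == sum(not a and not b for a, b in zip(in_r, in_f))


def test_log2_or_proportional_table_is_zero():
    res = mr.log2_odds_ratio(ContingencyTable(10, 90, 100, 900))
    assert res.log2_or == pytest.approx(0.0)
    assert not res.undefined


def test_log2_or_closed_form():
    t = ContingencyTable(30, 70, 70, 330)
    res = mr.log2_odds_ratio(t)
    assert res.log2_or == pytest.approx(math.log2((30 * 330) / (70 * 70)))
    se = math.sqrt(1 / 30 + 1 / 70 + 1 / 70 + 1 / 330)
    assert res.se == pytest.approx(se)
    assert res.ci95 == pytest.approx((res.log2_or - 2 * se, res.log2_or + 2 * se))


def test_log2_or_zero_cell_undefined_unless_haldane():
    t = ContingencyTable(0, 10, 10, 10)
    res = mr.log2_odds_ratio(t)
    assert res.undefined and math.isnan(res.log2_or)
    res_h = mr.log2_odds_ratio(t, haldane=True)
    assert not res_h.undefined and math.isfinite(res_h.log2_or)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(1, 200)] * 4))
def test_log2_or_antisymmetric_under_row_swap(cells):
    a, b, c, d = cells
    r1 = mr.log2_odds_ratio(ContingencyTable(a, b, c, d))
    r2 = mr.log2_odds_ratio(ContingencyTable(c, d, a, b))
    assert r1.log2_or == pytest.approx(-r2.log2_or)
    assert r1.se == pytest.approx(r2.se)


def _fisher_enum_oracle(a, b, c, d):
    """Exact two-sided Fisher p by full hypergeometric enumeration with
    integer-exact probabilities (math.comb)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return total / denom


def test_fisher_exact_examples():
    assert mr.fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)
    assert mr.fisher_exact(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / math.comb(10, 5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 15)] * 4))
def test_fisher_matches_enumeration_for_small_margins(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    assert mr.fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
        _fisher_enum_oracle(a, b, c, d), rel=1e-9, abs=1e-12
    )


def test_enrich_batch_matches_single_calls_and_averages():
    rng = np.random.default_rng(1)
    pos = np.sort(rng.choice(5000, 400, replace=False)) + 1
    loci = _loci(pos)
    regions = _regions([("chr1", 100, 600), ("chr1", 2000, 2600)])
    feats = [
        mr.GenomicFeatureSet.from_intervals("f1", [("chr1", 0, 800)]),
        mr.GenomicFeatureSet.from_intervals("f2", [("chr1", 3000, 4000)]),
    ]
    df, means = mr.enrich_batch(loci, regions, feats, averaging_groups={"g": ["f1", "f2"]})
    for _, row in df.iterrows():
        feat = feats[0] if row["feature"] == "f1" else feats[1]
        t = mr.build_contingency(loci, regions, feat)
        single = mr.log2_odds_ratio(t, regions.kind, feat.name)
        assert row["log2_or"] == pytest.approx(single.log2_or, nan_ok=True)
        assert row["fisher_p"] == pytest.approx(mr.fisher_exact(t))
    assert means.iloc[0]["mean_log2_or"] == pytest.approx(df["log2_or"].mean())
    # significance flags are BH-adjusted booleans
    assert df["significant"].isin([True, False]).all()


def test_enrichment_null_center_experiment():
    from methregions.experiments import enrichment_null_center

    r = enrichment_null_center(n_replicates=200, seed=0)
    assert abs(r["mean_log2_or"]) <= 2 * r["mc_se"]
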