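import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methregions as mr
from methregions.dmr import LocusStats, _cap_infinite

from conftest import make_samples, make_smoothed


def _anova_oracle(groups_vals):
    """Hand-coded one-way ANOVA from sums of squares."""
    all_vals = np.concatenate(groups_vals)
    k, n = len(groups_vals), len(all_vals)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups_vals)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))


def test_fstat_three_group_toy_matches_oracle():
    vals = [[0.1, 0.2], [0.5, 0.6], [0.9, 1.0]]
    samples = make_samples({"a": 2, "b": 2, "c": 2})
    beta = np.array([np.concatenate(vals)])
    s = make_smoothed([100], beta, samples)
    stats = mr.locus_fstat(s)
    assert stats.stat[0] == pytest.approx(_anova_oracle(vals), rel=1e-12)
    assert stats.groups == ["a", "b", "c"]


def test_fstat_identical_values_zero():
    samples = make_samples({"a": 2, "b": 2})
    s = make_smoothed([10], np.full((1, 4), 0.3), samples)
    stats = mr.locus_fstat(s)
    assert stats.stat[0] == 0.0 and stats.t[0] == 0.0


def test_fstat_ssw_zero_gives_inf():
    samples = make_samples({"a": 2, "b": 2})
    s = make_smoothed([10], np.array([[0.2, 0.2, 0.8, 0.8]]), samples)
    stats = mr.locus_fstat(s)
    assert np.isposinf(stats.stat[0])


def test_two_group_f_equals_t_squared():
    rng = np.random.default_rng(7)
    samples = make_samples({"a": 4, "b": 5})
    beta = rng.uniform(size=(50, 9))
    stats = mr.locus_fstat(make_smoothed(np.arange(1, 51) * 10, beta, samples))
    finite = np.isfinite(stats.stat)
    assert np.allclose(stats.stat[finite], stats.t[finite] ** 2, rtol=1e-9)
    # signed t against scipy's pooled-variance t
    import scipy.stats

    t_ref = scipy.stats.ttest_ind(beta[:, :4], beta[:, 4:], axis=1).statistic
    assert np.allclose(stats.t[finite], t_ref[finite], rtol=1e-9)


def test_fstat_missing_group_rule():
    samples = make_samples({"a": 2, "b": 2})
    beta = np.array([[0.1, np.nan, 0.5, 0.6]])  # group a has < 2 non-missing
    stats = mr.locus_fstat(make_smoothed([10], beta, samples))
    assert np.isnan(stats.stat[0])


def _stats_from(stat, pos=None, chrom=None, groups=("a", "b", "c")):
    stat = np.asarray(stat, dtype=float)
    n = len(stat)
    return LocusStats(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n, dtype=object),
        pos=np.asarray(pos if pos is not None else (np.arange(n) + 1) * 10, dtype=np.int64),
        stat=stat,
        group_means=np.tile(stat[:, None], (1, len(groups))) * 0.0,
        groups=list(groups),
    )


def test_call_candidates_none_above_cutoff():
    assert mr.call_candidates(_stats_from([1, 2, 3]), cutoff=5, min_loci=1) == []


def test_call_candidates_single_spanning_region():
    regions = mr.call_candidates(_stats_from([5, 6, 7, 8]), cutoff=4, max_gap_bp=100, min_loci=2)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.n_loci) == (10, 40, 4)
    assert r.area_stat == 26 and r.max_stat == 8


def test_call_candidates_gap_and_chrom_splits():
    stats = _stats_from(
        [5, 5, 5, 5], pos=[10, 20, 1000, 1010], chrom=["chr1", "chr1", "chr1", "chr2"]
    )
    regions = mr.call_candidates(stats, cutoff=4, max_gap_bp=300, min_loci=1)
    assert [(r.chrom, r.start, r.end) for r in regions] == [
        ("chr1", 10, 20), ("chr1", 1000, 1000), ("chr2", 1010, 1010)
    ]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_call_candidates_matches_run_length_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 60))
    stat = rng.uniform(0, 10, n)
    pos = np.sort(rng.choice(np.arange(1, 5000), n, replace=False))
    cutoff, max_gap, min_loci = 5.0, 300, int(rng.integers(1, 4))
    regions = mr.call_candidates(_stats_from(stat, pos=pos), cutoff, max_gap, min_loci)
    # direct scan oracle
    runs, cur = [], []
    for i in range(n):
        if stat[i] >= cutoff and (not cur or pos[i] - pos[cur[-1]] <= max_gap):
            cur.append(i)
        else:
            if len(cur) >= min_loci:
                runs.append(cur)
            cur = [i] if stat[i] >= cutoff else []
    if len(cur) >= min_loci:
        runs.append(cur)
    assert len(regions) == len(runs)
    for r, run in zip(regions, runs):
        assert (r.start, r.end, r.n_loci) == (pos[run[0]], pos[run[-1]], len(run))
        assert r.area_stat == pytest.approx(stat[run].sum())


def test_cap_infinite():
    capped = _cap_infinite(np.array([1.0, np.inf, 3.0, -np.inf]))
    assert capped.tolist() == [1.0, 3.0, 3.0, -3.0]


# ---------------------------------------------------------------------------
# permutation FWER
# ---------------------------------------------------------------------------


def _two_group_toy(seed=0, delta=0.5):
    rng = np.random.default_rng(seed)
    pos = (np.arange(30) + 1) * 50
    beta = np.clip(rng.normal(0.5, 0.02, size=(30, 4)), 0, 1)
    beta[10:20, :2] += delta  # group a shifted over a 10-locus region
    beta = np.clip(beta, 0, 1)
    return make_smoothed(pos, beta, make_samples({"a": 2, "b": 2}))


def test_exhaustive_permutation_matches_enumeration_oracle():
    """n = 4 with groups of 2: the permutation p-value over all distinct
    label assignments equals exhaustive enumeration."""
    import scipy.stats

    s = _two_group_toy()
    rs = mr.permutation_fwer(s, cutoff=2.0, max_gap_bp=200, min_loci=3, exhaustive=True)
    assert len(rs) >= 1
    top = max(rs, key=lambda r: abs(r.area_stat))

    def max_area(codes):
        codes = np.asarray(codes)
        a, b = s.beta[:, codes == 0], s.beta[:, codes == 1]
        t = scipy.stats.ttest_ind(a, b, axis=1).statistic
        finite = t[np.isfinite(t)]
        cap = np.abs(finite).max() if finite.size else 0.0
        t = np.nan_to_num(np.clip(t, -cap, cap))
        best, cur, cur_sign = 0.0, [], 0
        for i in range(len(t)):
            qual = abs(t[i]) >= 2.0
            sign = np.sign(t[i])
            if qual and (not cur or sign == cur_sign):
                cur.append(t[i])
                cur_sign = sign
            else:
                if len(cur) >= 3:
                    best = max(best, abs(sum(cur)))
                cur, cur_sign = ([t[i]], sign) if qual else ([], 0)
        if len(cur) >= 3:
            best = max(best, abs(sum(cur)))
        return best

    obs_codes = (0, 0, 1, 1)
    assignments = sorted({p for p in itertools.permutations(obs_codes)})
    others = [a for a in assignments if a != obs_codes]
    k = sum(max_area(a) >= abs(top.area_stat) - 1e-12 for a in others)
    assert top.fwer_p == pytest.approx((1 + k) / (len(others) + 1))


def test_fwer_p_floor_and_ceiling():
    s = _two_group_toy(delta=0.8)
    rs = mr.permutation_fwer(s, cutoff=2.0, min_loci=3, B=20, seed=5)
    top = max(rs, key=lambda r: abs(r.area_stat))
    assert top.fwer_p >= 1 / 21  # add-one floor
    flat = make_smoothed(
        (np.arange(30) + 1) * 50,
        np.full((30, 4), 0.5) + np.random.default_rng(1).normal(0, 1e-3, (30, 4)),
        make_samples({"a": 2, "b": 2}),
    )
    rs_flat = mr.permutation_fwer(flat, min_loci=1, B=20, seed=5)
    for r in rs_flat:
        assert 0 < r.fwer_p <= 1


def test_single_group_errors():
    s = make_smoothed([10, 20], np.full((2, 3), 0.5), make_samples({"a": 3}))
    with pytest.raises(mr.MethregionsError):
        mr.permutation_fwer(s, B=2, seed=0)


# ---------------------------------------------------------------------------
# annotation / selection / matrices
# ---------------------------------------------------------------------------


def _annotated_region(means, delta_min=0.1):
    samples = make_samples({g: 2 for g in means})
    beta = np.array([[m for g, m in means.items() for m in (means[g], means[g])]])
    s = make_smoothed([10], beta, samples)
    r = mr.Region("chr1", 10, 10, 1, 1.0, 1.0, locus_slice=(0, 1))
    mr.annotate_pairwise(r, s, delta_min=delta_min)
    return r


def test_annotate_pairwise_examples():
    assert _annotated_region({"a": 0.5, "b": 0.5, "c": 0.5}).annotation == frozenset()
    r = _annotated_region({"a": 0.2, "b": 0.2, "c": 0.8})
    assert r.annotation == frozenset({("a", "c"), ("b", "c")})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_annotate_pairwise_matches_threshold_oracle(seed):
    rng = np.random.default_rng(seed)
    groups = ["a", "b", "c", "d"]
    means = {g: float(rng.uniform()) for g in groups}
    r = _annotated_region(means)
    expected = {
        (g1, g2)
        for g1, g2 in itertools.combinations(groups, 2)
        if abs(means[g1] - means[g2]) >= 0.1
    }
    assert r.annotation == frozenset(expected)


def _region_with_annotation(pairs, max_stat):
    r = mr.Region("chr1", 1, 2, 3, max_stat, max_stat)
    r.annotation = frozenset(pairs)
    return r


def test_select_discriminatory_rules():
    regions = mr.RegionSet(
        [
            _region_with_annotation({("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")}, 5.0),
            _region_with_annotation({("a", "b"), ("b", "c")}, 4.0),
            _region_with_annotation({("a", "b"), ("c", "d")}, 3.0),
        ],
        kind="cg_dmr",
    )
    out = mr.select_discriminatory(regions, groups=["a", "b", "c", "d", "e"])
    assert len(out["a"]) == 1 and out["a"].regions[0].max_stat == 5.0
    assert [r.max_stat for r in out["b"].regions] == [4.0]
    assert len(out["c"]) == 0  # {(a,b),(c,d)} shares no common group


def test_select_discriminatory_caps_by_max_stat():
    regions = mr.RegionSet(
        [_region_with_annotation({("a", "b")}, s) for s in (9, 7, 5, 3, 1)], kind="cg_dmr"
    )
    out = mr.select_discriminatory(regions, groups=["a", "b"], caps={"a": 2})
    assert [r.max_stat for r in out["a"].regions] == [9, 7]


def test_region_methylation_matrix():
    samples = make_samples({"a": 2})
    beta = np.array([[0.2, 0.4], [0.4, 0.6], [0.9, 0.1]])
    s = make_smoothed([10, 20, 30], beta, samples)
    regions = mr.RegionSet(
        [mr.Region("chr1", 10, 20, 2, 1, 1, locus_slice=(0, 2)),
         mr.Region("chr1", 30, 30, 1, 1, 1, locus_slice=(2, 3))],
        kind="cg_dmr",
    )
    mat = mr.region_methylation_matrix(regions, s)
    assert np.allclose(mat.iloc[0], [0.3, 0.5])
    assert np.allclose(mat.iloc[1], beta[2])


def test_region_matrix_empty_region_errors():
    samples = make_samples({"a": 2})
    s = make_smoothed([10], np.array([[0.5, 0.5]]), samples)
    bad = mr.RegionSet([mr.Region("chr2", 5, 6, 0, 0, 0)], kind="cg_dmr")
    with pytest.raises(mr.MethregionsError):
        mr.region_methylation_matrix(bad, s)


def test_ch_analysis_reports_union_of_strata():
    cfg = mr.SimulationConfig(
        seed=7, chrom_lengths={"chr1": 500_000}, n_dmrs=0, n_blocks=0, n_vmrs=0,
        n_snp_vmrs=0, ch_contexts=("CA",), n_ch_dmrs=2,
    )
    sim = mr.simulate(cfg)
    strata = {k: v for k, v in sim.datasets.items() if k.startswith("CA")}
    rs = mr.ch_dmr_analysis(strata, B=30, seed=3, min_loci=3, max_gap_bp=1000)
    assert rs.kind == "ch_dmr"
    assert set(r.stratum for r in rs) <= {"CA+", "CA-"}
    truth = sim.truth.of_kind("ch_dmr")
    sig = [r for r in rs if r.significant]
    hits = sum(
        any(r.chrom == t.chrom and r.start <= t.end and t.start <= r.end and
            r.stratum == t.context for r in sig)
        for _, t in truth.iterrows()
    )
    assert hits >= len(truth) // 2
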