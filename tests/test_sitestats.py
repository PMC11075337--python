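"""Per-site statistics: hard filter, MAF/het/missing/depth, W&C Fst against an
independent transcription of the 1984 variance components, and the exact HWE
test against full enumeration."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from snppanel.matrix import MISSING, GenotypeMatrix, PopulationSpec
from snppanel.sitestats import (
    SiteStats,
    fst_screen,
    hard_filter,
    high_poly_screen,
    hwe_exact_p,
    maf,
    mean_depth,
    missing_rate,
    obs_het,
    wc_fst,
    wc_fst_sites,
)

# ---------------------------------------------------------------- hard filter

PASSING = {"FS": 0.0, "MQ": 60.0, "QD": 30.0, "ReadPosRankSum": 0.0,
           "MQRankSum": 0.0, "HaplotypeScore": 0.0}


@pytest.mark.parametrize(
    "overrides, expect_pass, reason",
    [
        ({}, True, None),
        # every bound is attained inclusively except MQRankSum (strict >)
        ({"FS": 60.0, "HaplotypeScore": 13.0, "MQ": 40.0, "QD": 2.0,
          "ReadPosRankSum": -8.0, "MQRankSum": -12.4}, True, None),
        ({"MQRankSum": -12.5}, False, "MQRankSum"),
        ({"FS": 60.01}, False, "FS"),
        ({"MQ": 39.9}, False, "MQ"),
        ({"QD": 1.99}, False, "QD"),
        ({"ReadPosRankSum": -8.01}, False, "ReadPosRankSum"),
        ({"HaplotypeScore": 13.1}, False, "HaplotypeScore"),
    ],
)
def test_hard_filter_boundaries(overrides, expect_pass, reason):
    ann = {**PASSING, **overrides}
    passed, why = hard_filter(ann)
    assert passed is expect_pass
    assert why == reason


def test_hard_filter_absent_fields_lenient_vs_strict():
    # rank-sum annotations are legitimately absent at hom-only sites
    assert hard_filter({"FS": 10.0, "MQ": 50.0})[0]
    assert not hard_filter({"FS": 10.0, "MQ": 50.0}, strict=True)[0]
    assert hard_filter({})[0]  # total function, lenient default


# ------------------------------------------------------- elementary statistics


@pytest.mark.parametrize(
    "codes, expected",
    [
        ([1, 1, 1], 0.5),          # all het
        ([0, 0, 1], 1 / 6),        # 1 alt allele of 6
        ([2, 2], 0.0),             # monomorphic alt
        ([0, MISSING, 1], 0.25),   # missing excluded from denominator
    ],
)
def test_maf(codes, expected):
    assert maf(codes) == pytest.approx(expected)


def test_maf_all_missing_is_undefined():
    assert math.isnan(maf([MISSING, MISSING]))


def test_obs_het_missing_rate_mean_depth():
    assert obs_het([1, 1, 0, 2]) == 0.5
    assert missing_rate([0, MISSING, MISSING, 2]) == 0.5
    assert mean_depth([0, 10, 20]) == 10.0
    assert mean_depth([0, 10, 20], codes=[MISSING, 0, 1], called_only=True) == 15.0


# ---------------------------------------------------------------- W&C Fst


def wc_oracle(codes1, codes2):
    """Literal scalar transcription of the Weir & Cockerham (1984) two-population
    single-site theta (a, b, c variance components), kept independent of the
    vectorised implementation."""
    pops = []
    for codes in (codes1, codes2):
        called = [c for c in codes if c != MISSING]
        n = len(called)
        if n == 0:
            return float("nan")
        p = sum(called) / (2 * n)
        h = sum(1 for c in called if c == 1) / n
        pops.append((n, p, h))
    r = 2
    (n1, p1, h1), (n2, p2, h2) = pops
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return float("nan")
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def test_wc_fst_fixed_difference_is_one():
    masks = [np.r_[np.ones(10, bool), np.zeros(10, bool)],
             np.r_[np.zeros(10, bool), np.ones(10, bool)]]
    codes = np.r_[np.zeros(10, int), np.full(10, 2)]
    assert wc_fst(codes, masks=masks) == pytest.approx(1.0)


def test_wc_fst_monomorphic_is_undefined():
    masks = [np.array([True, True, False, False]),
             np.array([False, False, True, True])]
    assert math.isnan(wc_fst(np.zeros(4, int), masks=masks))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    codes1=hst.lists(hst.sampled_from([0, 1, 2, MISSING]), min_size=2, max_size=12),
    codes2=hst.lists(hst.sampled_from([0, 1, 2, MISSING]), min_size=2, max_size=12),
)
def test_wc_fst_matches_independent_transcription(codes1, codes2):
    n1, n2 = len(codes1), len(codes2)
    masks = [np.r_[np.ones(n1, bool), np.zeros(n2, bool)],
             np.r_[np.zeros(n1, bool), np.ones(n2, bool)]]
    codes = np.array(codes1 + codes2)
    got = wc_fst(codes, masks=masks)
    want = wc_oracle(codes1, codes2)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    codes1=hst.lists(hst.sampled_from([0, 1, 2]), min_size=2, max_size=10),
    codes2=hst.lists(hst.sampled_from([0, 1, 2]), min_size=2, max_size=10),
)
def test_wc_fst_symmetries(codes1, codes2):
    """Invariant under swapping population labels and under ref/alt recoding."""
    n1, n2 = len(codes1), len(codes2)
    m1 = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
    m2 = ~m1
    codes = np.array(codes1 + codes2)
    f = wc_fst(codes, masks=[m1, m2])
    f_swapped = wc_fst(codes, masks=[m2, m1])
    f_recoded = wc_fst(2 - codes, masks=[m1, m2])
    if math.isnan(f):
        assert math.isnan(f_swapped) and math.isnan(f_recoded)
    else:
        assert f == pytest.approx(f_swapped, abs=1e-12)
        assert f == pytest.approx(f_recoded, abs=1e-12)


def test_wc_fst_sites_agrees_with_scalar(sim_study):
    _, _, matrix, pops = sim_study
    sub = matrix.subset_sites(np.arange(50))
    masks = list(pops.masks(sub).values())
    vec = wc_fst_sites(sub, pops)
    for j in range(50):
        scalar = wc_fst(sub.codes[:, j], masks=masks)
        if math.isnan(scalar):
            assert math.isnan(vec[j])
        else:
            assert vec[j] == pytest.approx(scalar, abs=1e-12)


# ---------------------------------------------------------------- screens


def test_high_poly_screen_boundaries():
    at_bounds = SiteStats(maf=0.05, missing_rate=0.1, obs_het=0.3, mean_depth=2)
    assert high_poly_screen(at_bounds, mode="candidate")  # inclusive bounds
    assert not high_poly_screen(at_bounds, mode="panel")  # MAF must exceed 0.1
    assert not high_poly_screen(
        SiteStats(maf=0.1, missing_rate=0.05, obs_het=0.2, mean_depth=10), mode="panel"
    )  # strict >
    good = SiteStats(maf=0.4, missing_rate=0.0, obs_het=0.1, mean_depth=30)
    assert high_poly_screen(good, mode="candidate")
    assert high_poly_screen(good, mode="panel")
    assert not high_poly_screen(good, mode="panel", biallelic_snp=False)


def test_fst_screen_strict_threshold():
    assert fst_screen(SiteStats(0.3, 0, 0.2, 10, fst=0.51))
    assert not fst_screen(SiteStats(0.3, 0, 0.2, 10, fst=0.5))
    assert not fst_screen(SiteStats(0.3, 0, 0.2, 10, fst=float("nan")))


# ---------------------------------------------------------------- HWE exact test


def hwe_enumeration_oracle(n_homref, n_het, n_homalt):
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_homref + n_het + n_homalt
    n_alt = n_het + 2 * n_homalt
    probs = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_ref < 0:
            continue
        # P(h | allele counts) ∝ n! 2^h / (hom_ref! h! hom_alt!)
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_ref) * math.factorial(h) * math.factorial(hom_alt),
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


@pytest.mark.parametrize(
    "counts",
    [(5, 0, 0), (0, 0, 7), (1, 1, 1), (3, 5, 2), (20, 10, 20), (0, 50, 0),
     (57, 14, 50), (100, 57, 43), (2, 1, 0)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), rel=1e-10
    )


def test_hwe_monomorphic_and_het_excess():
    assert hwe_exact_p(17, 0, 0) == 1.0
    assert hwe_exact_p(0, 100, 0) < 1e-6  # extreme het excess


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    a=hst.integers(0, 60), b=hst.integers(0, 60), c=hst.integers(0, 60)
)
def test_hwe_exact_property(a, b, c):
    if a + b + c == 0:
        return
    p = hwe_exact_p(a, b, c)
    assert 0 < p <= 1
    assert p == pytest.approx(hwe_enumeration_oracle(a, b, c), rel=1e-9)


def test_hwe_null_calibration():
    """Under true HWE sampling the exact p-value is (super-)uniform: the
    fraction of sites with p < 0.05 stays at or below ~nominal."""
    rng = np.random.default_rng(99)
    n, n_sites = 60, 5000
    p_alt = rng.uniform(0.05, 0.95, n_sites)
    codes = rng.binomial(2, p_alt, size=(n, n_sites))
    frac = np.mean([
        hwe_exact_p(*(np.bincount(codes[:, j], minlength=3))) < 0.05
        for j in range(n_sites)
    ])
    assert frac <= 0.07
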