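"""The presence model: enumeration, likelihood, prior, posterior, selection.

The fast configuration-table path is checked against an independent naive
oracle that performs the nested sums and the explicit marginalization over
hidden missing bases.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplocal.loci import SnvLocus
from haplocal.model import (
    LocalHaplotypeModel,
    ModelParams,
    brute_force_posterior,
    call_segment,
    config_logprior,
    decimal_index,
    enumerate_haplotypes,
    fdr_select,
    fragment_loglik,
    index_set,
    joint_config_table,
    lambdas_from_index,
    posterior_presence,
    prior_presence_prob,
)
from haplocal.reads import FragmentObservation, PatternCounts, expand_patterns
from haplocal.segments import SegmentDef
from haplocal.simulate import scenario_fixture

from .conftest import make_segment


def obs(calls, e=0.001):
    return FragmentObservation("x", calls, errors=(e,) * len(calls))


# --- enumeration and indexing ----------------------------------------------


def test_enumeration_order_r2():
    seg = make_segment([(100, "G", "A"), (197, "A", "C")])
    assert [h.seq for h in enumerate_haplotypes(seg)] == ["GA", "GC", "AA", "AC"]


def test_enumeration_r3_and_refusal():
    seg3 = make_segment([(100, "A", "G"), (160, "A", "C"), (220, "A", "T")])
    assert len(enumerate_haplotypes(seg3)) == 8
    seg4 = SegmentDef(
        "chr1",
        tuple(SnvLocus("chr1", 100 + 10 * i, "A", "G") for i in range(4)),
        analyzed=True,
    )
    with pytest.raises(ValueError, match="not-analyzed"):
        enumerate_haplotypes(seg4)


def test_decimal_index_msb_first():
    assert decimal_index((1, 1, 0, 1)) == 13
    for l in range(16):
        assert decimal_index(lambdas_from_index(l, 4)) == l


def test_printed_index_sets():
    assert index_set(2, 1, 4) == frozenset({4, 5, 6, 7, 12, 13, 14, 15})
    assert index_set(3, 0, 4) == frozenset({0, 1, 4, 5, 8, 9, 12, 13})


@pytest.mark.parametrize("L", [2, 4, 8])
def test_index_set_partition(L):
    for j in range(1, L + 1):
        v1, v0 = index_set(j, 1, L), index_set(j, 0, L)
        assert len(v1) == len(v0) == 2 ** (L - 1)
        assert v1 | v0 == frozenset(range(2**L)) and not v1 & v0


# --- likelihood and prior ---------------------------------------------------


@pytest.mark.parametrize(
    "calls, hap, expected",
    [
        ("GA", "GA", math.log(0.999**2)),
        ("GM", "GA", math.log(0.999)),
        ("GC", "GA", math.log(0.999 * 0.001 / 3)),
    ],
)
def test_fragment_loglik(calls, hap, expected):
    assert fragment_loglik(obs(calls), hap) == pytest.approx(expected, abs=1e-12)


def test_prior_presence_prob():
    assert prior_presence_prob(0.05, 1.0) == pytest.approx(0.05 / 1.05, abs=1e-12)
    assert prior_presence_prob(0.3, 0.3) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        prior_presence_prob(-1.0, 1.0)


def test_config_logprior_independence():
    params = ModelParams()
    p = 0.05 / 1.05
    assert config_logprior((0, 0, 0, 0), params) == pytest.approx(
        4 * math.log1p(-p), abs=1e-12
    )
    assert config_logprior((1, 0, 1, 0), params) == pytest.approx(
        2 * math.log(p) + 2 * math.log1p(-p), abs=1e-12
    )


# --- joint table and posteriors ---------------------------------------------


@pytest.fixture
def seg_ga():
    return make_segment([(100, "G", "A"), (197, "A", "C")])


def test_single_fragment_favors_its_haplotype(seg_ga):
    haps = enumerate_haplotypes(seg_ga)
    joint = joint_config_table(PatternCounts({"GA": 1}), haps, ModelParams())
    assert joint.sum() == pytest.approx(1.0, abs=1e-12)
    assert joint[0] == 0.0  # all-absent configuration is impossible
    # {GA only present} = lambda (1,0,0,0) = index 8
    assert int(np.argmax(joint)) == 8


def test_two_fragments_favor_pair_config(seg_ga):
    haps = enumerate_haplotypes(seg_ga)
    joint = joint_config_table(PatternCounts({"GA": 1, "GC": 1}), haps, ModelParams())
    pair = joint[decimal_index((1, 1, 0, 0))]
    singles = [joint[decimal_index(lam)] for lam in
               ((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1))]
    assert pair > max(singles)


def test_posterior_partition(seg_ga):
    haps = enumerate_haplotypes(seg_ga)
    joint = joint_config_table(
        PatternCounts({"GA": 3, "GC": 2, "MC": 1}), haps, ModelParams()
    )
    xi = posterior_presence(joint, 4)
    for j in range(1, 5):
        idx0 = np.fromiter(index_set(j, 0, 4), dtype=int)
        assert xi[j - 1] + joint[idx0].sum() == pytest.approx(1.0, abs=1e-12)


def test_uniform_joint_gives_half():
    joint = np.full(16, 1 / 16)
    assert posterior_presence(joint, 4) == pytest.approx(np.full(4, 0.5), abs=1e-12)


def test_zero_fragments_reported_empty(seg_ga):
    results = call_segment(seg_ga, [], ModelParams())
    assert results.n_significant == 0 and not results.is_lhv
    with pytest.raises(ValueError, match="at least one fragment"):
        joint_config_table(PatternCounts({}), enumerate_haplotypes(seg_ga), ModelParams())


# --- FDR selection -----------------------------------------------------------


@pytest.mark.parametrize(
    "xi, f0, expected",
    [
        ([1.0, 0.995, 0.992, 0.30], 0.01, [1, 2, 3]),
        ([0.5, 0.5, 0.5, 0.5], 0.01, []),
        ([1.0, 1.0], 0.01, [1, 2]),
        ([0.999, 0.2, 0.995, 0.1], 0.01, [1, 3]),
    ],
)
def test_fdr_select(xi, f0, expected):
    assert fdr_select(np.array(xi), f0) == expected


def test_fdr_select_bad_threshold():
    with pytest.raises(ValueError):
        fdr_select(np.array([0.5]), 1.5)


def test_fdr_tie_break_deterministic():
    # ties keep enumeration order; the top-t rule must be reproducible
    xi = np.array([0.9, 0.995, 0.995, 0.995])
    assert fdr_select(xi, 0.01) == [2, 3, 4]


# --- oracle equivalence ------------------------------------------------------


def test_missing_base_marginalization_shortcut():
    """Explicit sum over the hidden base equals the drop-the-term shortcut."""
    from haplocal.model import _explicit_marginal_lik

    val = _explicit_marginal_lik("GM", (0.001, 0.001), "GA", 0.001)
    assert val == pytest.approx(0.999, abs=1e-12)
    full = _explicit_marginal_lik("GA", (0.001, 0.001), "GA", 0.001)
    assert full == pytest.approx(0.999**2, abs=1e-15)


def _random_instance(rng):
    R = int(rng.integers(2, 4))
    segment = make_segment(
        [(100 + 60 * r, "A", "G") for r in range(R)]
    )
    e = float(rng.choice([0.001, 0.01, 0.1]))
    N = int(rng.integers(1, 11))
    observations = []
    for i in range(N):
        while True:
            calls = "".join(
                rng.choice(["A", "G", "M"], p=[0.4, 0.4, 0.2]) for _ in range(R)
            )
            if set(calls) != {"M"}:
                break
        observations.append(FragmentObservation(f"f{i}", calls, errors=(e,) * R))
    return segment, observations, ModelParams(e_const=e)


def test_oracle_equivalence_random_instances():
    """Fast configuration-table posteriors match the naive nested-sum oracle."""
    rng = np.random.default_rng(20240917)
    worst = 0.0
    for _ in range(100):
        segment, observations, params = _random_instance(rng)
        fast = call_segment(segment, observations, params).xi
        slow = brute_force_posterior(observations, segment, params)
        worst = max(worst, float(np.max(np.abs(fast - slow))))
    assert worst < 1e-10


def test_oracle_equivalence_on_scenarios():
    for n in range(1, 9):
        segment, patterns = scenario_fixture(n)
        observations = expand_patterns(patterns)
        fast = call_segment(segment, observations).xi
        slow = brute_force_posterior(observations, segment)
        assert np.max(np.abs(fast - slow)) < 1e-10


# --- published scenario calls -----------------------------------------------


SCENARIO_CALLS = {
    1: {"GA", "GC", "AC"},
    2: set(),
    3: {"AGA", "AGC", "GAC"},
    4: set(),
    5: {"AAA", "AAT", "ACA"},
    6: {"GA", "GC", "AC"},
    7: {"GG", "GC", "AG"},
    8: {"TT", "CG", "CT"},
}


@pytest.mark.parametrize("n", range(1, 9))
def test_scenario_calls(n):
    segment, patterns = scenario_fixture(n)
    results = LocalHaplotypeModel(segment, patterns).fit()
    assert set(results.selected_sequences) == SCENARIO_CALLS[n]
    assert results.is_lhv == (len(SCENARIO_CALLS[n]) >= 3)
    if SCENARIO_CALLS[n]:
        assert min(results.xi_for(s) for s in SCENARIO_CALLS[n]) > 0.99


# --- model invariants --------------------------------------------------------


def test_fragment_order_invariance(seg_ga):
    observations = [obs(c) for c in ["GA", "GC", "AC", "GA", "MC", "GM"]]
    xi1 = call_segment(seg_ga, observations).xi
    xi2 = call_segment(seg_ga, observations[::-1]).xi
    assert np.array_equal(xi1, xi2)


def test_allele_relabel_equivariance():
    """Swapping which allele is ref/alt at SNV 1 permutes xi accordingly."""
    seg = make_segment([(100, "G", "A"), (197, "A", "C")])
    seg_swapped = make_segment([(100, "A", "G"), (197, "A", "C")])
    observations = [obs(c) for c in ["GA", "GA", "GC", "AC", "AC"]]
    xi = call_segment(seg, observations).xi
    xi_sw = call_segment(seg_swapped, observations).xi
    seqs = [h.seq for h in enumerate_haplotypes(seg)]
    seqs_sw = [h.seq for h in enumerate_haplotypes(seg_swapped)]
    for s, x in zip(seqs, xi):
        assert x == pytest.approx(xi_sw[seqs_sw.index(s)], abs=1e-12)


@pytest.mark.parametrize("n", range(1, 9))
def test_doubling_fragments_never_decreases_max_xi(n):
    segment, patterns = scenario_fixture(n)
    doubled = PatternCounts({p: 2 * c for p, c in patterns.counts.items()})
    xi1 = LocalHaplotypeModel(segment, patterns).fit().xi
    xi2 = LocalHaplotypeModel(segment, doubled).fit().xi
    assert xi2.max() >= xi1.max() - 1e-12


def test_scenario4_to_5_flip():
    """Adding reads for three haplotypes flips the call from none to those 3."""
    seg4, pat4 = scenario_fixture(4)
    assert LocalHaplotypeModel(seg4, pat4).fit().selected_sequences == ()
    boosted = dict(pat4.counts)
    for p in ("AAA", "AAT", "ACA"):
        boosted[p] += 4
    results = LocalHaplotypeModel(seg4, PatternCounts(boosted)).fit()
    assert set(results.selected_sequences) == {"AAA", "AAT", "ACA"}
    assert all(round(results.xi_for(s), 2) == 1.00 for s in ("AAA", "AAT", "ACA"))


@pytest.mark.parametrize("n", range(1, 9))
def test_higher_error_shrinks_selection(n):
    """Raising e_ir can only lose confidence: selection at e=0.2 is a subset."""
    segment, patterns = scenario_fixture(n)
    low = LocalHaplotypeModel(segment, patterns, ModelParams(e_const=0.001)).fit()
    high = LocalHaplotypeModel(segment, patterns, ModelParams(e_const=0.2)).fit()
    assert set(high.selected_sequences) <= set(low.selected_sequences)


@given(
    counts=st.dictionaries(
        st.sampled_from(["GA", "GC", "AA", "AC", "GM", "MA", "MC", "AM", "MG"]),
        st.integers(min_value=1, max_value=30),
        min_size=1,
        max_size=6,
    ),
    e=st.sampled_from([0.001, 0.01, 0.1]),
)
@settings(deadline=None, max_examples=60)
def test_posterior_normalization_property(counts, e):
    seg = make_segment([(100, "G", "A"), (197, "A", "C")])
    model = LocalHaplotypeModel(seg, PatternCounts(counts), ModelParams(e_const=e))
    results = model.fit()
    assert results.joint.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all((results.xi >= 0) & (results.xi <= 1))


def test_summary_table(seg_ga):
    results = call_segment(seg_ga, [obs("GA")] * 10)
    table = results.summary()
    assert list(table.columns) == ["haplotype", "xi", "significant"]
    assert table["significant"].sum() == results.n_significant
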