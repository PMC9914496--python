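import itertools

import numpy as np
import pytest

import tcrhla as t
from tcrhla import synthetic_data as sd
from tcrhla.evaluation import (
    AmbiguousExample,
    association_recall_test,
    ga_null_curve,
    shared_tcr_associations,
)
from tcrhla.io_preprocess import DonorRepertoire, RecordError, TCRBeta

H = [t.HLAAllele("A", f"{i+1:02d}", "01") for i in range(32)] + \
    [t.HLAAllele("B", f"{i+1:02d}", "01") for i in range(32)]


def _brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_roc_auc_endpoints():
    assert t.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    with pytest.raises(RecordError) as e:
        t.roc_auc([0.1, 0.2], [1, 1])
    assert e.value.reason == "degenerate_labels"


def test_roc_auc_matches_pairwise_oracle():
    """Exact agreement with exhaustive pairwise Mann-Whitney counting,
    including ties, on small random inputs."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert t.roc_auc(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels), abs=1e-12)


def test_roc_auc_hand_listed_four_pairs():
    scores = [0.9, 0.4, 0.6, 0.3]
    labels = [1, 1, 0, 0]
    assert t.roc_auc(scores, labels) == pytest.approx(
        _brute_force_auc(scores, labels), abs=1e-12)


def test_roc_auc_null():
    rng = np.random.default_rng(1)
    scores = rng.random(10_000)
    labels = rng.integers(0, 2, size=10_000)
    assert abs(t.roc_auc(scores, labels) - 0.5) < 0.02


def _random_examples(rng, n, m=4):
    out = []
    for _ in range(n):
        a = rng.choice(32, size=m // 2, replace=False)
        b = 32 + rng.choice(32, size=m - m // 2, replace=False)
        out.append(AmbiguousExample(
            tcr=TCRBeta("C" + "".join(rng.choice(list("ASDFGHKL"), size=8)),
                        "V01-01", "J01"),
            candidates=frozenset(H[i] for i in np.concatenate([a, b]))))
    return out


def _random_scorer(seed):
    rng = np.random.default_rng(seed)

    def fn(tcrs, uni):
        return rng.random((len(tcrs), len(uni)))

    return fn


def _candidate_oracle(examples):
    lookup = {id(e.tcr): e.candidates for e in examples}

    def fn(tcrs, uni):
        out = np.zeros((len(tcrs), len(uni)))
        for i, tc in enumerate(tcrs):
            for j, h in enumerate(uni):
                if h in lookup[id(tc)]:
                    out[i, j] = 1.0
        return out

    return fn


def test_group_accuracy_oracle_is_one():
    rng = np.random.default_rng(2)
    ex = _random_examples(rng, 200)
    assert t.group_accuracy(_candidate_oracle(ex), ex, H).ga == 1.0


def test_group_accuracy_random_scorer_binomial_rate():
    """Uniform-random scores, m=4 candidates, universe 64: GA ~ 4/64."""
    rng = np.random.default_rng(3)
    ex = _random_examples(rng, 10_000)
    ga = t.group_accuracy(_random_scorer(4), ex, H)
    assert abs(ga.ga - 4 / 64) < 0.01
    assert ga.n_tcrs == 10_000


def test_group_accuracy_single_miss_is_zero():
    ex = [AmbiguousExample(tcr=TCRBeta("CASSA", "V01-01", "J01"),
                           candidates=frozenset([H[0]]))]

    def anti(tcrs, uni):
        return np.array([[0.0 if h == H[0] else 1.0 for h in uni]])

    assert t.group_accuracy(anti, ex, H).ga == 0.0


def test_ga_null_curve_matches_random_rate():
    rng = np.random.default_rng(5)
    ex = _random_examples(rng, 2000)
    nc = ga_null_curve(_candidate_oracle(ex), ex, fractions=[1.0], R=10, seed=0)
    assert abs(nc.means[0] - 4 / 64) < 0.02
    assert nc.standard_errors[0] < 0.01


def test_ga_null_curve_se_shrinks_with_fraction():
    rng = np.random.default_rng(6)
    ex = _random_examples(rng, 3000)
    neg_rho = 0
    for run in range(10):
        nc = ga_null_curve(_candidate_oracle(ex), ex,
                           fractions=[0.05, 0.2, 0.5, 1.0], R=10, seed=run)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(nc.fractions, nc.standard_errors)
        neg_rho += rho < 0
    assert neg_rho >= 8


def test_ga_null_curve_r_bounds():
    rng = np.random.default_rng(7)
    ex = _random_examples(rng, 50)
    nc = ga_null_curve(_candidate_oracle(ex), ex, fractions=[1.0], R=2, seed=0)
    assert nc.R == 2 and len(nc.means) == 1
    with pytest.raises(RecordError):
        ga_null_curve(_candidate_oracle(ex), ex, fractions=[1.0], R=1, seed=0)


@pytest.mark.parametrize("m,expected", [(1, 1.0), (2, 0.75), (4, 0.625)])
def test_max_auc_bound_closed_form(m, expected):
    assert t.max_auc_bound(m) == pytest.approx(expected)


def test_max_auc_bound_invalid():
    with pytest.raises(RecordError):
        t.max_auc_bound(0)
    with pytest.raises(RecordError):
        t.max_auc_bound(10, universe_size=5)


def test_simulated_ceiling_matches_closed_form_m2():
    auc = t.simulate_ambiguity_auc(n_tcrs=20_000, m=2, universe_size=64, seed=0)
    assert auc == pytest.approx(0.75, abs=0.01)


def test_any_scorer_respects_ceiling():
    """Empirical AUC of a perfect oracle on ambiguous labels stays below
    (m+1)/(2m) + 0.02 (the ceiling is an upper bound, not just a target)."""
    auc = t.simulate_ambiguity_auc(n_tcrs=20_000, m=4, universe_size=64, seed=1)
    assert auc <= t.max_auc_bound(4) + 0.02


def _donor(idx, alleles, tcrs):
    return DonorRepertoire(f"d{idx}", frozenset(alleles), tcrs)


def test_shared_tcr_hand_arithmetic():
    """10 carrier donors; h1 in 8 (pop 0.4), h2 in 4 (pop 0.2), h3 in 2
    (pop 0.4) -> ratios 2.0, 2.0, 0.5 -> normalized 0.444/0.444/0.111,
    no call at r1=0.5."""
    h1, h2, h3 = H[0], H[1], H[2]
    shared = TCRBeta("CASSSHARED", "V01-01", "J01")
    donors = []
    for i in range(10):
        alleles = set()
        if i < 8:
            alleles.add(h1)
        if i in (0, 1, 8, 9):
            alleles.add(h2)
        if i in (8, 9):
            alleles.add(h3)
        donors.append(_donor(i, alleles, [shared]))
    pop = {h1: 0.4, h2: 0.2, h3: 0.4}
    out = shared_tcr_associations(donors, population_hla_freq=pop, T1=10, r1=0.5)
    assert len(out) == 1
    a = out[0]
    assert a.ratios[h1] == pytest.approx(4 / 9)
    assert a.ratios[h2] == pytest.approx(4 / 9)
    assert a.ratios[h3] == pytest.approx(1 / 9)
    assert sum(a.ratios.values()) == pytest.approx(1.0, abs=1e-9)
    assert a.called is None  # max normalized ratio 0.444 < 0.5


def test_shared_tcr_pure_association_called():
    """An allele carried by every carrier donor but rare in the population
    gets a dominant normalized ratio and is called."""
    shared = TCRBeta("CASSSHARED", "V01-01", "J01")
    donors = [_donor(i, {H[0], H[1 + i]}, [shared]) for i in range(6)]
    pop = {H[0]: 0.2}
    pop.update({H[1 + i]: 0.8 for i in range(6)})
    out = shared_tcr_associations(donors, population_hla_freq=pop, T1=5, r1=0.5)
    # ratios: h0 = 1.0/0.2 = 5; each other = (1/6)/0.8 -> normalized h0 = 0.8
    assert out[0].called == H[0]
    assert out[0].ratios[H[0]] == pytest.approx(5 / 6.25)


def test_shared_tcr_threshold_presets():
    shared = TCRBeta("CASSSHARED", "V01-01", "J01")
    donors = [_donor(i, {H[0], H[1]}, [shared]) for i in range(20)]
    for T1, r1 in ((15, 0.5), (5, 0.25)):
        out = shared_tcr_associations(donors, T1=T1, r1=r1)
        assert out and out[0].T1 == T1 and out[0].r1 == r1


def test_shared_tcr_below_t1_excluded():
    shared = TCRBeta("CASSSHARED", "V01-01", "J01")
    donors = [_donor(i, {H[0], H[1]}, [shared]) for i in range(4)]
    assert shared_tcr_associations(donors, T1=5, r1=0.1) == []


def _associations(n, hla):
    rng = np.random.default_rng(8)
    out = []
    for i in range(n):
        tcr = TCRBeta("C" + "".join(rng.choice(list("ASDFGHKL"), size=8)),
                      "V01-01", "J01")
        out.append(t.evaluation.SharedTCRAssociation(
            tcr=tcr, n_donors=10, ratios={hla: 1.0}, called=hla, T1=5, r1=0.25))
    return out


def test_association_recall_perfect_oracle_significant():
    hla = H[0]
    assoc = _associations(40, hla)

    def oracle(tcrs, uni):
        return np.array([[1.0 if h == hla else 0.0 for h in uni]] * len(tcrs))

    out = association_recall_test(oracle, assoc, H)
    assert len(out) == 1
    assert out[0].recall == 1.0
    assert out[0].p_value < 0.001 and out[0].stars == "***"


def test_association_recall_random_scorer_non_significant():
    """A random scorer's recall ~ 1/|universe|; chi-squared is
    non-significant at alpha=0.05 in >= 9 of 10 seeded runs."""
    hla = H[0]
    assoc = _associations(40, hla)
    nonsig = 0
    for run in range(10):
        out = association_recall_test(_random_scorer(100 + run), assoc, H)
        nonsig += out[0].p_value > 0.05
    assert nonsig >= 9


def test_association_recall_requires_calls():
    with pytest.raises(RecordError):
        association_recall_test(_random_scorer(0), [], H)


def test_star_thresholds():
    from tcrhla.evaluation import _stars
    assert _stars(0.0005) == "***"
    assert _stars(0.005) == "**"
    assert _stars(0.03) == "*"
    assert _stars(0.2) == ""
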