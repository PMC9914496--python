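import numpy as np
import pytest
from scipy.stats import chi2_contingency

import tcrhla as t
from tcrhla import synthetic_data as sd
from tcrhla.io_preprocess import RecordError


def test_generate_pth_recovers_planted_conditional():
    """Empirical P(v1|h1) matches the planted 0.9 at n=10000."""
    pool = sd.default_hla_pool(1, 1)
    a = np.array([[0.9, 0.1], [0.1, 0.9]])
    spec = sd.GeneratorSpec(n_tcrs=10_000, hla_pool=pool,
                            v_pool=["V01-01", "V02-01"], association=a, seed=7)
    pairs = sd.generate_pth(spec)
    h1 = pool[0]
    n_h1 = sum(1 for p in pairs if p.hla == h1)
    n_v1h1 = sum(1 for p in pairs if p.hla == h1 and p.tcr.v_gene == "V01-01")
    assert abs(n_v1h1 / n_h1 - 0.9) < 0.02


def test_generate_pth_no_motif_cdr3_independent_of_hla():
    """Without a motif map the first CDR3 letter is independent of the HLA
    (chi-square non-significant at alpha=0.01 in >= 18 of 20 seeded runs)."""
    pool = sd.default_hla_pool(2, 2)
    nonsig = 0
    for run in range(20):
        spec = sd.GeneratorSpec(n_tcrs=800, hla_pool=pool,
                                v_pool=sd.default_v_pool(4),
                                association=sd.uniform_association(4, 4),
                                seed=100 + run)
        pairs = sd.generate_pth(spec)
        letters = sorted({p.tcr.cdr3b[0] for p in pairs})
        table = np.zeros((len(pool), len(letters)))
        li = {c: i for i, c in enumerate(letters)}
        hi = {h: i for i, h in enumerate(pool)}
        for p in pairs:
            table[hi[p.hla], li[p.tcr.cdr3b[0]]] += 1
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = chi2_contingency(table)
        nonsig += pval > 0.01
    assert nonsig >= 18


def test_generate_pth_degenerate_and_invalid():
    spec = sd.GeneratorSpec(n_tcrs=0, hla_pool=sd.default_hla_pool(1, 1),
                            v_pool=["V01-01"])
    assert sd.generate_pth(spec) == []
    bad = sd.GeneratorSpec(n_tcrs=5, hla_pool=sd.default_hla_pool(1, 1),
                           v_pool=["V01-01", "V02-01"],
                           association=np.array([[0.5, 0.2], [0.5, 0.5]]))
    with pytest.raises(RecordError) as e:
        sd.generate_pth(bad)
    assert e.value.reason == "invalid_spec"


def test_generate_bse_truth_in_candidates():
    spec = sd.GeneratorSpec(hla_pool=sd.default_hla_pool(8, 8),
                            v_pool=sd.default_v_pool(8), seed=1)
    donors, truth = sd.generate_bse(spec, n_donors=50, tcrs_per_donor=20)
    for d in donors:
        assert {h.locus for h in d.hla_set} == {"A", "B"}
        for i in range(len(d.tcrs)):
            assert truth[(d.donor_id, i)] in d.hla_set


def test_generate_bse_truth_uniform_within_donor():
    """Each of a donor's m alleles receives ~1/m of its TCRs."""
    spec = sd.GeneratorSpec(hla_pool=sd.default_hla_pool(8, 8),
                            v_pool=sd.default_v_pool(8), seed=3)
    donors, truth = sd.generate_bse(spec, n_donors=20, tcrs_per_donor=400)
    for d in donors[:5]:
        m = len(d.hla_set)
        for h in d.hla_set:
            frac = np.mean([truth[(d.donor_id, i)] == h
                            for i in range(len(d.tcrs))])
            assert abs(frac - 1 / m) < 4 * np.sqrt((1 / m) * (1 - 1 / m) / 400)


def test_generate_bse_unambiguous_oracle_ga_is_one():
    spec = sd.GeneratorSpec(hla_pool=sd.default_hla_pool(4, 4),
                            v_pool=sd.default_v_pool(4), seed=2)
    donors, truth = sd.generate_bse(spec, n_donors=10, tcrs_per_donor=10,
                                    alleles_per_donor=1)
    universe = sorted(frozenset().union(*(d.hla_set for d in donors)))
    examples, truths = [], []
    for d in donors:
        for i, tc in enumerate(d.tcrs):
            examples.append(t.AmbiguousExample(tcr=tc, candidates=d.hla_set))
            truths.append(truth[(d.donor_id, i)])
    lookup = {id(e.tcr): tr for e, tr in zip(examples, truths)}

    def oracle(tcrs, uni):
        out = np.zeros((len(tcrs), len(uni)))
        for i, tc in enumerate(tcrs):
            out[i, uni.index(lookup[id(tc)])] = 1.0
        return out

    assert t.group_accuracy(oracle, examples, universe).ga == 1.0


def test_generate_bse_insufficient_pool():
    spec = sd.GeneratorSpec(hla_pool=sd.default_hla_pool(1, 1),
                            v_pool=sd.default_v_pool(2), seed=0)
    with pytest.raises(RecordError) as e:
        sd.generate_bse(spec, n_donors=2, tcrs_per_donor=5)
    assert e.value.reason == "invalid_spec"


def test_uniform_association_gives_null_naive_bayes_auc():
    """No planted signal -> NB AUC vs non-candidate negatives ~ 0.5."""
    pool = sd.default_hla_pool(8, 8)
    spec = sd.GeneratorSpec(hla_pool=pool, v_pool=sd.default_v_pool(8),
                            association=sd.uniform_association(16, 8), seed=9)
    donors, truth = sd.generate_bse(spec, n_donors=80, tcrs_per_donor=60)
    def pairs_of(ds):
        return [t.PairExample(tcr=tc, hla=truth[(d.donor_id, i)], label=1)
                for d in ds for i, tc in enumerate(d.tcrs)]
    res = t.VGeneNaiveBayes(pairs_of(donors[:40])).fit(smoothing_alpha=1.0)
    test_pos = pairs_of(donors[40:])
    negatives = t.sample_negatives(test_pos, ratio=1.0, seed=0)
    scores = np.concatenate([res.score_pairs(test_pos), res.score_pairs(negatives)])
    labels = [1] * len(test_pos) + [0] * len(negatives)
    assert abs(t.roc_auc(scores, labels) - 0.5) < 0.03


def test_make_noisy_pth_candidate_sets(counts_8228_pairs):
    pool = sd.default_hla_pool(4, 4)
    spec = sd.GeneratorSpec(n_tcrs=500, hla_pool=pool,
                            v_pool=sd.default_v_pool(4), seed=5)
    pairs = sd.generate_pth(spec)
    noisy = sd.make_noisy_pth(pairs, k_extra=3, seed=1)
    assert all(len(c) == 4 for _, c in noisy)
    assert all(p.hla in c for p, (_, c) in zip(pairs, noisy))
    # k_extra=0 is the identity
    ident = sd.make_noisy_pth(pairs, k_extra=0, seed=1)
    assert all(c == frozenset([p.hla]) for p, (_, c) in zip(pairs, ident))
    # too few distinct alleles
    with pytest.raises(RecordError) as e:
        sd.make_noisy_pth(counts_8228_pairs, k_extra=3)
    assert e.value.reason == "insufficient_alleles"


def test_make_noisy_pth_extra_alleles_match_table_distribution():
    """Sampled extras track the table's empirical HLA distribution (TV < 0.03)."""
    pool = sd.default_hla_pool(8, 8)
    freqs = np.array([3.0 + i for i in range(16)])  # mild skew: extras'
    freqs /= freqs.sum()  # per-row truth-exclusion bias stays within the band
    spec = sd.GeneratorSpec(n_tcrs=10_000, hla_pool=pool, hla_freqs=freqs,
                            v_pool=sd.default_v_pool(4), seed=11)
    pairs = sd.generate_pth(spec)
    noisy = sd.make_noisy_pth(pairs, k_extra=3, seed=2)
    table_freq = {h: sum(1 for p in pairs if p.hla == h) / len(pairs) for h in pool}
    extra_counts = {h: 0 for h in pool}
    n_extra = 0
    for p, (_, cand) in zip(pairs, noisy):
        for h in cand - {p.hla}:
            extra_counts[h] += 1
            n_extra += 1
    tv = 0.5 * sum(abs(extra_counts[h] / n_extra - table_freq[h]) for h in pool)
    assert tv < 0.03


def test_generators_deterministic_under_seed():
    spec = sd.GeneratorSpec(n_tcrs=50, hla_pool=sd.default_hla_pool(4, 4),
                            v_pool=sd.default_v_pool(4), seed=21)
    a = sd.generate_pth(spec)
    b = sd.generate_pth(spec)
    assert [(p.key, p.label) for p in a] == [(p.key, p.label) for p in b]
    d1, t1 = sd.generate_bse(spec, n_donors=5, tcrs_per_donor=10)
    d2, t2 = sd.generate_bse(spec, n_donors=5, tcrs_per_donor=10)
    assert t1 == t2
    assert [(d.donor_id, d.hla_set, [x.key for x in d.tcrs]) for d in d1] == \
           [(d.donor_id, d.hla_set, [x.key for x in d.tcrs]) for d in d2]


def test_generate_cd4cd8_motif_enrichment():
    spec = sd.GeneratorSpec(n_tcrs=2000, hla_pool=sd.default_hla_pool(2, 2),
                            v_pool=sd.default_v_pool(4), cd8_motif="WQKF",
                            motif_strength=0.7, seed=4)
    tcrs = sd.generate_cd4cd8(spec)
    cd8 = [x for x in tcrs if x.compartment == "CD8"]
    cd4 = [x for x in tcrs if x.compartment == "CD4"]
    f8 = np.mean(["WQKF" in x.cdr3b for x in cd8])
    f4 = np.mean(["WQKF" in x.cdr3b for x in cd4])
    assert f8 > 0.6 and f4 < 0.05
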