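import numpy as np
import pytest

import tcrhla as t
from tcrhla import synthetic_data as sd
from tcrhla.binding_model import donor_aware_split, sample_negatives
from tcrhla.io_preprocess import RecordError


def _pair(cdr3, v, hla, label=1, donor=None):
    return t.PairExample(tcr=t.TCRBeta(cdr3, v, "J01"), hla=hla, label=label,
                         donor=donor)


H = [t.HLAAllele("A", f"{i+1:02d}", "01") for i in range(8)]


def test_sample_negatives_exhausts_2x2_diagonal():
    """2 TCRs x 2 HLAs with positives on the diagonal: by enumeration of all
    4 pairs the only possible negatives are the 2 off-diagonal pairs."""
    pos = [_pair("CASSA", "V01-01", H[0]), _pair("CASSD", "V02-01", H[1])]
    neg = sample_negatives(pos, ratio=1.0, seed=0)
    assert len(neg) == 2
    assert {(p.tcr.cdr3b, p.hla) for p in neg} == {("CASSA", H[1]), ("CASSD", H[0])}
    assert all(p.label == 0 for p in neg)


def test_sample_negatives_matches_hla_marginal():
    """Negatives' HLA frequencies match the positives' (TV < 0.03 at n=10k)."""
    rng = np.random.default_rng(0)
    # mild skew: per-TCR rejection of the one positive pair systematically
    # tilts the negative marginal by ~f_h^2, which stays within the band here
    freqs = np.array([2, 2, 2.5, 2.5, 3, 3, 3.5, 3.5])
    freqs /= freqs.sum()
    pos = []
    for i in range(10_000):
        cdr3 = "C" + "".join(rng.choice(list("ASDFGHKLMNPQRSTVWY"), size=10))
        pos.append(_pair(cdr3, "V01-01", H[rng.choice(8, p=freqs)]))
    neg = sample_negatives(pos, ratio=1.0, seed=1)
    assert len(neg) == len(pos)
    fp = np.array([sum(1 for p in pos if p.hla == h) for h in H]) / len(pos)
    fn = np.array([sum(1 for p in neg if p.hla == h) for h in H]) / len(neg)
    assert 0.5 * np.abs(fp - fn).sum() < 0.03
    # TCR marginal preserved exactly (multiset reuse)
    assert sorted(p.tcr.key for p in neg) == sorted(p.tcr.key for p in pos)


def test_sample_negatives_ratio_zero_and_disjointness():
    pos = [_pair(f"CASS{aa}", "V01-01", H[i % 3]) for i, aa in enumerate("ADEFG")]
    assert sample_negatives(pos, ratio=0, seed=0) == []
    neg = sample_negatives(pos, ratio=2.0, seed=0)
    assert len(neg) == 2 * len(pos)
    assert {p.key for p in neg}.isdisjoint({p.key for p in pos})


def test_sample_negatives_dense_space_exhausted():
    # every (TCR, HLA) combination is positive: no negative space at all
    pos = [_pair(c, "V01-01", h) for c in ("CASSA", "CASSD") for h in H[:2]]
    with pytest.raises(RecordError) as e:
        sample_negatives(pos, ratio=1.0, seed=0, max_tries_factor=10)
    assert e.value.reason == "negative_space_exhausted"


def test_donor_aware_split_disjoint():
    pairs = [_pair(f"CASS{a}{b}", "V01-01", H[0], donor=f"d{i % 7}")
             for i, (a, b) in enumerate((x, y) for x in "ACDEF" for y in "ACDEF")]
    tr, te = donor_aware_split(pairs, 0.3, seed=1)
    assert len(tr) + len(te) == len(pairs)
    assert {pairs[i].donor for i in tr}.isdisjoint({pairs[i].donor for i in te})


def test_donor_aware_split_single_donor_fails():
    pairs = [_pair("CASSA", "V01-01", H[0], donor="d0")] * 5
    with pytest.raises(RecordError) as e:
        donor_aware_split(pairs, 0.2, seed=0)
    assert e.value.reason == "cannot_split"


def test_early_stopping_patience_one_constant_val_auc():
    """With patience=1 and a constant validation AUC, training stops after
    the second epoch.  Every donor carries a single class, so whichever
    donor forms the validation slice its AUC is degenerate (constant 0.5)."""
    rng = np.random.default_rng(3)
    pos, neg = [], []
    for d in range(6):
        for _ in range(30):
            cdr3 = "C" + "".join(rng.choice(list("ASDFGHKL"), size=7))
            if d < 3:
                pos.append(_pair(cdr3, "V01-01", H[d], donor=f"p{d}"))
            else:
                neg.append(_pair(cdr3, "V01-01", H[d], label=0, donor=f"n{d}"))
    cfg = t.BindingModelConfig(max_epochs=30, patience=1, ae_epochs=2,
                               ae_hidden=32, max_len=21, seed=5)
    res = t.BindingModel(pos, neg, config=cfg).fit()
    assert all(h["val_auc"] == 0.5 for h in res.history)
    assert len(res.history) == 2


def test_fit_invariants(tiny_trained_binding):
    res, pairs = tiny_trained_binding
    # early-stopping correctness: restored epoch has the max validation AUC
    aucs = [h["val_auc"] for h in res.history]
    assert res.history[res.best_epoch]["val_auc"] == max(aucs)
    assert len(res.history) <= res.model.config.max_epochs
    # negatives never collide with positives
    assert {p.key for p in res.model.negatives}.isdisjoint(
        {p.key for p in res.model.positives})


def test_predict_contract(tiny_trained_binding):
    res, pairs = tiny_trained_binding
    scores = res.predict(pairs[:50])
    assert np.all((scores >= 0) & (scores <= 1))
    # duplicates in a batch score identically; repeat calls are deterministic
    dup = [pairs[0], pairs[1], pairs[0]]
    s = res.predict(dup)
    assert s[0] == s[2]
    assert np.array_equal(res.predict(dup), s)


def test_planted_signal_mean_score_separation(tiny_trained_binding):
    res, pairs = tiny_trained_binding
    neg = sample_negatives(pairs, ratio=1.0, seed=9)
    assert res.predict(pairs[:400]).mean() > res.predict(neg[:400]).mean()


def test_score_all_hla_contract(tiny_trained_binding):
    res, pairs = tiny_trained_binding
    tcr = pairs[0].tcr
    ranked = res.score_all_hla(tcr)
    scores = [s for _, s in ranked]
    assert scores == sorted(scores, reverse=True)
    # consistency with pairwise predict
    direct = res.predict([t.PairExample(tcr=tcr, hla=h, label=0)
                          for h, _ in ranked])
    assert np.allclose(direct, scores)
    # universe of one
    only = res.score_all_hla(tcr, hla_universe=[H[0]])
    assert only[0][0] == H[0]


def test_planted_truth_ranks_high(tiny_trained_binding, small_planted_spec):
    """On planted data the true allele lands in the top 4 of the universe
    more often than the 4/|universe| chance rate."""
    res, pairs = tiny_trained_binding
    uni = sorted(small_planted_spec.hla_pool)
    s, uni_sorted = res.score_matrix([p.tcr for p in pairs[:300]], uni)
    ranks = np.argsort(-s, axis=1)
    hit = 0
    for i, p in enumerate(pairs[:300]):
        top4 = [uni_sorted[j] for j in ranks[i, :4]]
        hit += p.hla in top4
    assert hit / 300 > 4 / len(uni)
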