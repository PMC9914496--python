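"""Metrics and statistical checks for ambiguous-label HLA prediction.

Repertoire data attaches a *set* of candidate alleles to each TCR rather
than a single label, which breaks ordinary accuracy and caps the attainable
ROC AUC.  This module provides:

* plain ROC AUC (delegating to scikit-learn) with the degenerate-input
  contract the rest of the package relies on;
* **Group Accuracy (GA)** — the fraction of TCRs whose top-ranked allele over
  the whole universe falls inside their candidate set;
* the scrambled-label GA **null curve** (mean +/- standard error over R
  scrambling realizations per sample-size fraction);
* the **ambiguity AUC ceiling**: with m candidate alleles of which exactly
  one is truly restricting, even a perfect scorer labels m-1 of its
  "positives" with noise scores, so AUC <= (m+1)/(2m) in the large-universe
  limit (0.625 at m=4); a Monte-Carlo perfect-oracle simulation is provided
  for finite universes;
* donor co-occurrence cross-validation: TCRs shared by many donors are
  assigned an HLA from normalized co-occurrence ratios, and a model's recall
  on those associations is compared with a random scorer by chi-squared test.

Scorers follow a batched protocol ``score_fn(tcrs, universe) -> (n, U)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score

from .io_preprocess import DonorRepertoire, HLAAllele, RecordError, TCRBeta

ScoreFn = Callable[[Sequence[TCRBeta], Sequence[HLAAllele]], np.ndarray]


@dataclass
class AmbiguousExample:
    """A TCR with its candidate allele set (and implied non-candidates)."""

    tcr: TCRBeta
    candidates: frozenset
    donor: Optional[str] = None

    def __post_init__(self):
        if not self.candidates:
            raise RecordError("invalid_spec", "empty candidate set")

    def non_candidates(self, universe: Sequence[HLAAllele]) -> frozenset:
        return frozenset(universe) - self.candidates


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC; equals the Mann-Whitney P(score_pos > score_neg) + tie/2."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise RecordError("degenerate_labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Group accuracy


@dataclass
class GAResult:
    ga: float
    n_tcrs: int
    hits: np.ndarray  # per-TCR hit indicator

    def __post_init__(self):
        assert np.isclose(self.ga, self.hits.mean())


def _top_alleles(score_fn: ScoreFn, examples: Sequence[AmbiguousExample],
                 universe: Sequence[HLAAllele], batch_size: int = 2048) -> list[HLAAllele]:
    """Argmax allele per TCR over the whole universe, ties broken by
    canonical allele-name order (the universe is scored in sorted order and
    the first maximum wins)."""
    uni = sorted(universe)
    tops: list[HLAAllele] = []
    for start in range(0, len(examples), batch_size):
        chunk = [e.tcr for e in examples[start:start + batch_size]]
        s = np.asarray(score_fn(chunk, uni))
        tops.extend(uni[j] for j in s.argmax(axis=1))
    return tops


def group_accuracy(score_fn: ScoreFn, examples: Sequence[AmbiguousExample],
                   universe: Sequence[HLAAllele]) -> GAResult:
    """Fraction of TCRs whose universe-wide argmax is in their candidate set."""
    if not frozenset().union(*(e.candidates for e in examples)) <= set(universe):
        raise RecordError("invalid_spec", "universe must cover all candidate sets")
    tops = _top_alleles(score_fn, examples, universe)
    hits = np.array([t in e.candidates for t, e in zip(tops, examples)], dtype=float)
    return GAResult(ga=float(hits.mean()), n_tcrs=len(examples), hits=hits)


@dataclass
class NullCurve:
    fractions: list[float]
    means: list[float]
    standard_errors: list[float]
    R: int


def ga_null_curve(score_fn: ScoreFn, examples: Sequence[AmbiguousExample],
                  fractions: Sequence[float], R: int = 10, seed: int = 0) -> NullCurve:
    """Expected GA when candidate sets are scrambled across TCRs.

    For each sample-size fraction, R realizations each subsample that share
    of TCRs and permute the candidate-set assignment across the subsample;
    reported is the mean GA +/- standard error over realizations.
    """
    if R < 2:
        raise RecordError("invalid_spec", "R >= 2 required")
    universe = sorted(frozenset().union(*(e.candidates for e in examples)))
    tops = _top_alleles(score_fn, examples, universe)
    rng = np.random.default_rng(seed)
    out_f, out_m, out_se = [], [], []
    for frac in fractions:
        n_sub = int(round(frac * len(examples)))
        if n_sub < 2:
            continue
        gas = []
        for _ in range(R):
            idx = rng.choice(len(examples), size=n_sub, replace=False)
            perm = rng.permutation(idx)  # scrambled candidate-set assignment
            hits = [tops[i] in examples[j].candidates for i, j in zip(idx, perm)]
            gas.append(float(np.mean(hits)))
        gas = np.array(gas)
        out_f.append(float(frac))
        out_m.append(float(gas.mean()))
        out_se.append(float(gas.std(ddof=1) / np.sqrt(R)))
    return NullCurve(fractions=out_f, means=out_m, standard_errors=out_se, R=R)


# ---------------------------------------------------------------------------
# Ambiguity AUC ceiling


def max_auc_bound(m: int, universe_size: Optional[int] = None) -> float:
    """AUC ceiling of a perfect scorer under m-candidate ambiguity.

    One of the m labelled positives per TCR is truly positive; the other
    m-1 carry noise scores indistinguishable from negatives, so even a
    perfect scorer attains AUC = 1/m * 1 + (m-1)/m * 1/2 = (m+1)/(2m) in the
    large-universe limit (~0.625 at m=4, 1 at m=1).
    """
    if m < 1:
        raise RecordError("invalid_m")
    if universe_size is not None and m > universe_size:
        raise RecordError("invalid_m", "m exceeds universe size")
    return (m + 1) / (2 * m)


def simulate_ambiguity_auc(
    n_tcrs: int = 20_000, m: int = 4, universe_size: int = 64, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the ceiling with a perfect oracle.

    Each simulated TCR gets m candidate alleles (2 per locus when m=4, one
    hidden truth).  The oracle scores the true pair above everything; all
    other pairs draw from a common noise distribution.  AUC is computed with
    positives = candidate pairs and negatives = an equal number of sampled
    non-candidate pairs.
    """
    if m < 1 or m > universe_size:
        raise RecordError("invalid_m")
    rng = np.random.default_rng(seed)
    scores, labels = [], []
    for _ in range(n_tcrs):
        cand = rng.choice(universe_size, size=m, replace=False)
        true = cand[0]  # candidate order is random, so this is uniform
        non_cand = np.setdiff1d(np.arange(universe_size), cand)
        neg = rng.choice(non_cand, size=min(m, len(non_cand)), replace=False)
        for h in cand:
            scores.append(2.0 if h == true else rng.random())
            labels.append(1)
        for _h in neg:
            scores.append(rng.random())
            labels.append(0)
    return roc_auc(scores, labels)


# ---------------------------------------------------------------------------
# Donor co-occurrence cross-validation


@dataclass
class SharedTCRAssociation:
    tcr: TCRBeta
    n_donors: int
    ratios: dict            # HLAAllele -> normalized ratio (sums to 1)
    called: Optional[HLAAllele]
    T1: int
    r1: float


def shared_tcr_associations(
    repertoires: Sequence[DonorRepertoire],
    population_hla_freq: Optional[dict] = None,
    T1: int = 15,
    r1: float = 0.5,
) -> list[SharedTCRAssociation]:
    """HLA associations of TCRs shared by at least T1 donors.

    For each shared TCR, the fraction of its carrier donors typed with each
    allele is divided by that allele's population frequency; the resulting
    ratio vector is renormalized to sum to 1 and an association is called
    when its maximum exceeds r1.  Population frequencies default to the
    fraction of input donors carrying each allele.
    """
    universe = sorted(frozenset().union(*(d.binding_hlas for d in repertoires)))
    if population_hla_freq is None:
        population_hla_freq = {
            h: sum(1 for d in repertoires if h in d.hla_set) / len(repertoires)
            for h in universe
        }
    if any(population_hla_freq.get(h, 0.0) <= 0 for h in universe):
        raise RecordError("invalid_spec", "population frequency must be > 0")
    carriers: dict[tuple, list[DonorRepertoire]] = {}
    tcr_of: dict[tuple, TCRBeta] = {}
    for d in repertoires:  # a donor counts once per distinct TCR
        seen = set()
        for t in d.tcrs:
            if t.key in seen:
                continue
            seen.add(t.key)
            carriers.setdefault(t.key, []).append(d)
            tcr_of.setdefault(t.key, t)
    out: list[SharedTCRAssociation] = []
    for key, ds in sorted(carriers.items()):
        if len(ds) < T1:
            continue
        raw = np.array([
            sum(1 for d in ds if h in d.hla_set) / len(ds) for h in universe
        ])
        ratio = raw / np.array([population_hla_freq[h] for h in universe])
        total = ratio.sum()
        if total == 0:
            continue
        norm = ratio / total
        j = int(norm.argmax())
        called = universe[j] if norm[j] > r1 else None
        out.append(SharedTCRAssociation(
            tcr=tcr_of[key], n_donors=len(ds),
            ratios={h: float(v) for h, v in zip(universe, norm)},
            called=called, T1=T1, r1=r1))
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssociationRecall:
    hla: HLAAllele
    n_tcrs: int
    recall: float
    random_recall: float
    chi2: float
    p_value: float
    stars: str = field(init=False)

    def __post_init__(self):
        self.stars = _stars(self.p_value)


def association_recall_test(
    score_fn: ScoreFn,
    associations: Sequence[SharedTCRAssociation],
    universe: Sequence[HLAAllele],
) -> list[AssociationRecall]:
    """Per-HLA recall of co-occurrence-called associations, vs random.

    Recall is the fraction of a HLA's associated TCRs for which the scorer
    ranks that HLA first over the universe; a chi-squared test (1 df,
    continuity-corrected 2x2 table of hits/misses) compares it to the random
    expectation of 1/|universe| per TCR.
    """
    called = [a for a in associations if a.called is not None]
    if not called:
        raise RecordError("invalid_spec", "no called associations")
    uni = sorted(universe)
    tops = _top_alleles(
        score_fn,
        [AmbiguousExample(tcr=a.tcr, candidates=frozenset([a.called])) for a in called],
        uni,
    )
    by_hla: dict[HLAAllele, list[bool]] = {}
    for a, top in zip(called, tops):
        by_hla.setdefault(a.called, []).append(top == a.called)
    p_random = 1.0 / len(uni)
    out = []
    for h in sorted(by_hla):
        hits = by_hla[h]
        n = len(hits)
        k = sum(hits)
        exp_hit = n * p_random
        table = np.array([[k, n - k], [exp_hit, n - exp_hit]])
        if table[0].min() < 0 or n == 0:
            continue
        chi2, p = _chi2_2x2(table)
        out.append(AssociationRecall(hla=h, n_tcrs=n, recall=k / n,
                                     random_recall=p_random, chi2=chi2, p_value=p))
    return out


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    try:
        chi2, p, _, _ = chi2_contingency(table, correction=True)
    except ValueError:  # a zero marginal
        return 0.0, 1.0
    return float(chi2), float(p)
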