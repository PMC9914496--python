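"""Two-stage training for repertoires with ambiguous HLA labels.

Bulk-sequenced repertoires attach each TCR to the donor's full candidate
set rather than a single allele.  The two-stage scheme trains through the
ambiguity:

* **Stage 1** treats every (TCR, candidate) pair as positive; negatives are
  (TCR, non-candidate) pairs sampled to the configured ratio with the same
  marginal-matching rule used for paired data.
* **Stage 2** relabels: for each TCR only the candidate that scored highest
  under the stage-1 model stays positive; the remaining candidates become
  negatives (topped up with non-candidate negatives to preserve the ratio),
  and the model is retrained.  Further rounds repeat the relabeling.

With singleton candidate sets the procedure reduces exactly to ordinary
supervised training for any number of rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binding_model import (
    BindingModel,
    BindingModelConfig,
    BindingResults,
    donor_aware_split,
    make_scorer,
)
from .evaluation import AmbiguousExample, GAResult, group_accuracy, roc_auc
from .io_preprocess import DonorRepertoire, HLAAllele, PairExample, RecordError


def examples_from_repertoires(donors: Sequence[DonorRepertoire]) -> list[AmbiguousExample]:
    """One ambiguous example per TCR, candidates = the donor's A/B alleles."""
    out = []
    for d in donors:
        cand = d.binding_hlas
        for t in d.tcrs:
            out.append(AmbiguousExample(tcr=t, candidates=cand, donor=d.donor_id))
    return out


def stage1_pairs(
    examples: Sequence[AmbiguousExample],
    universe: Sequence[HLAAllele],
    ratio: float = 1.0,
    seed: int = 0,
) -> tuple[list[PairExample], list[PairExample]]:
    """All (TCR, candidate) pairs as positives; non-candidate negatives.

    Negatives reuse each TCR and draw alleles from the empirical candidate
    allele distribution restricted to that TCR's non-candidates, giving
    ``ratio`` negatives per positive.
    """
    uni = sorted(universe)
    positives: list[PairExample] = []
    for e in examples:
        for h in sorted(e.candidates):
            positives.append(PairExample(tcr=e.tcr, hla=h, label=1, donor=e.donor))
    negatives = _non_candidate_negatives(examples, uni, n_per_example=[
        int(round(ratio * len(e.candidates))) for e in examples], seed=seed)
    return positives, negatives


def _non_candidate_negatives(
    examples: Sequence[AmbiguousExample],
    universe: Sequence[HLAAllele],
    n_per_example: Sequence[int],
    seed: int,
) -> list[PairExample]:
    """Sample non-candidate alleles per TCR, weighted by the candidate-allele
    empirical distribution so the negative HLA marginal tracks the positive."""
    uni = sorted(universe)
    hidx = {h: i for i, h in enumerate(uni)}
    weights = np.zeros(len(uni))
    for e in examples:
        for h in e.candidates:
            weights[hidx[h]] += 1
    if weights.sum() == 0:
        weights[:] = 1.0
    rng = np.random.default_rng(seed)
    negatives: list[PairExample] = []
    for e, n_neg in zip(examples, n_per_example):
        mask = np.ones(len(uni), dtype=bool)
        for h in e.candidates:
            mask[hidx[h]] = False
        if not mask.any():
            raise RecordError("no_negative_candidates", e.tcr.cdr3b)
        w = np.where(mask, weights, 0.0)
        if w.sum() == 0:
            w = mask.astype(float)
        p = w / w.sum()
        k = min(n_neg, int(mask.sum()))
        for j in rng.choice(len(uni), size=k, replace=False, p=p):
            negatives.append(PairExample(tcr=e.tcr, hla=uni[j], label=0, donor=e.donor))
    return negatives


def stage2_relabel(
    results: BindingResults,
    examples: Sequence[AmbiguousExample],
    universe: Sequence[HLAAllele],
    ratio: float = 1.0,
    seed: int = 0,
) -> tuple[list[PairExample], list[PairExample], dict]:
    """Keep each TCR's top-scoring candidate positive, the rest negative.

    The argmax is over the TCR's own candidates, ties broken by canonical
    allele-name order.  Non-candidate negatives are added so the per-TCR
    negative count reaches ``ratio * |candidates|`` as in stage 1.
    Returns (positives, negatives, info) with a tie count in ``info``.
    """
    positives: list[PairExample] = []
    negatives: list[PairExample] = []
    n_ties = 0
    cand_lists = [sorted(e.candidates) for e in examples]
    flat = [PairExample(tcr=e.tcr, hla=h, label=0)
            for e, cands in zip(examples, cand_lists) for h in cands]
    flat_scores = results.predict(flat)
    off = 0
    for e, cands in zip(examples, cand_lists):
        scores = flat_scores[off:off + len(cands)]
        off += len(cands)
        best = int(np.argmax(scores))  # first max = lexicographic tie-break
        if np.sum(scores == scores[best]) > 1:
            n_ties += 1
        positives.append(PairExample(tcr=e.tcr, hla=cands[best], label=1,
                                     donor=e.donor))
        for j, h in enumerate(cands):
            if j != best:
                negatives.append(PairExample(tcr=e.tcr, hla=h, label=0,
                                             donor=e.donor))
    # top up with non-candidate negatives to preserve the stage-1 class ratio
    deficit = [max(0, int(round(ratio * len(e.candidates))) - (len(e.candidates) - 1))
               for e in examples]
    if any(deficit):
        negatives += _non_candidate_negatives(examples, sorted(universe),
                                              n_per_example=deficit, seed=seed)
    return positives, negatives, {"n_ties": n_ties}


@dataclass
class RoundMetrics:
    round: int
    ga: GAResult
    auc: float
    validation_auc: float
    truth_recovery: Optional[float] = None


@dataclass
class TwoStageResults:
    """Final model plus per-round held-out evaluation."""

    results: BindingResults
    rounds: list = field(default_factory=list)
    relabel_info: list = field(default_factory=list)
    train_idx: Optional[np.ndarray] = None
    test_idx: Optional[np.ndarray] = None

    def summary(self) -> str:
        lines = ["Two-stage ambiguous-label training"]
        for r in self.rounds:
            lines.append(
                f"  round {r.round}: held-out GA={r.ga.ga:.3f}  AUC={r.auc:.3f}"
                + (f"  truth recovery={r.truth_recovery:.3f}"
                   if r.truth_recovery is not None else "")
            )
        return "\n".join(lines)


def _heldout_metrics(results: BindingResults, test: Sequence[AmbiguousExample],
                     universe: Sequence[HLAAllele], seed: int) -> tuple[GAResult, float]:
    ga = group_accuracy(make_scorer(results), test, universe)
    pos, neg = stage1_pairs(test, universe, ratio=1.0, seed=seed)
    scores = np.concatenate([results.predict(pos), results.predict(neg)])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return ga, roc_auc(scores, labels)


def run_two_stage(
    examples: Sequence[AmbiguousExample],
    config: Optional[BindingModelConfig] = None,
    n_rounds: int = 2,
    universe: Optional[Sequence[HLAAllele]] = None,
    truth: Optional[Sequence[HLAAllele]] = None,
    warm_start: bool = True,
) -> TwoStageResults:
    """Train through the candidate-set ambiguity for ``n_rounds`` rounds.

    Round 1 trains on all candidate pairs; each later round retrains on the
    previous model's relabeling.  Held-out GA and AUC (donor-aware 80/20)
    are reported per round; when the generator's ``truth`` (true allele per
    example, aligned with ``examples``) is given, the fraction of training
    TCRs whose stage-2 positive equals the truth is reported too.
    """
    if n_rounds < 1:
        raise RecordError("invalid_spec", "n_rounds >= 1")
    cfg = config or BindingModelConfig()
    if universe is None:
        universe = sorted(frozenset().union(*(e.candidates for e in examples)))
    uni = sorted(universe)
    # donor-aware 80/20 on the examples themselves
    marker = [PairExample(tcr=e.tcr, hla=next(iter(e.candidates)), label=1,
                          donor=e.donor) for e in examples]
    train_idx, test_idx = donor_aware_split(marker, cfg.test_fraction, cfg.seed + 3)
    train = [examples[i] for i in train_idx]
    test = [examples[i] for i in test_idx]
    truth_train = [truth[i] for i in train_idx] if truth is not None else None

    pos, neg = stage1_pairs(train, uni, ratio=cfg.negative_ratio, seed=cfg.seed)
    model = BindingModel(pos, neg, config=cfg, hla_universe=uni)
    results = model.fit()
    out = TwoStageResults(results=results, train_idx=train_idx, test_idx=test_idx)
    ga, auc = _heldout_metrics(results, test, uni, seed=cfg.seed + 11)
    out.rounds.append(RoundMetrics(round=1, ga=ga, auc=auc,
                                   validation_auc=results.validation_auc))
    ae = results.tcr_encoder.ae  # reuse the pretrained autoencoder across rounds
    for r in range(2, n_rounds + 1):
        pos, neg, info = stage2_relabel(results, train, uni,
                                        ratio=cfg.negative_ratio, seed=cfg.seed + r)
        out.relabel_info.append(info)
        recovery = None
        if truth_train is not None:
            recovery = float(np.mean([p.hla == t for p, t in zip(pos, truth_train)]))
        model = BindingModel(pos, neg, config=cfg, hla_universe=uni, autoencoder=ae)
        results = model.fit(warm_start_from=results if warm_start else None)
        ga, auc = _heldout_metrics(results, test, uni, seed=cfg.seed + 11 + r)
        out.rounds.append(RoundMetrics(round=r, ga=ga, auc=auc,
                                       validation_auc=results.validation_auc,
                                       truth_recovery=recovery))
    out.results = results
    return out
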