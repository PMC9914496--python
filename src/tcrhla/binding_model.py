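"""TCR-HLA binding predictor.

A binary network scoring whether a TCR and a Class I HLA allele bind,
peptide-agnostic.  The TCR encoding ``E_t`` (autoencoded CDR3 + V/J gene
embeddings) is concatenated with the HLA encoding ``E_h`` (character CNN)
into ``E_th``, which feeds an MLP with one hidden layer of half the input
dimension (Leaky ReLU, dropout 0.1) and a sigmoid output.

Training follows the repertoire-study protocol: negatives are sampled so
their TCR and HLA marginals match the positives', splits are donor-aware
(a donor is never on both sides), and early stopping monitors the AUC of an
internal validation slice with a fixed patience.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .encoders import CDR3Autoencoder, GeneVocab, HLAEncoder, TCREncoder
from .io_preprocess import HLAAllele, PairExample, RecordError, TCRBeta


@dataclass
class BindingModelConfig:
    learning_rate: float = 0.007
    weight_decay: float = 0.001
    dropout: float = 0.1
    patience: int = 20
    batch_size: int = 512
    max_epochs: int = 200
    ae_embed_dim: int = 30
    ae_hidden: int = 300
    ae_epochs: int = 300
    ae_pretrain_max: int = 20_000   # cap on the pretraining corpus size
    max_len: int = 25
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    negative_ratio: float = 1.0
    finetune_ae: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.patience < 1:
            raise RecordError("invalid_config")


def sample_negatives(
    positives: Sequence[PairExample],
    ratio: float = 1.0,
    seed: int = 0,
    hla_universe: Optional[Sequence[HLAAllele]] = None,
    max_tries_factor: int = 1000,
) -> list[PairExample]:
    """Negatives absent from the positive set with matched feature marginals.

    TCRs are reused as-is (every positive TCR contributes ``ratio`` negatives)
    and HLAs are drawn from the positives' empirical HLA distribution, with
    rejection of pairs present in the positive set.
    """
    if ratio <= 0:
        return []
    tcr_keys = {p.tcr.key for p in positives}
    hla_set = {p.hla for p in positives}
    if len(tcr_keys) < 2 or len(hla_set) < 2:
        raise RecordError("negative_space_exhausted", "need >=2 TCRs and >=2 HLAs")
    pos_keys = {p.key for p in positives}
    if hla_universe is None:
        hlas = sorted(hla_set)
        counts = np.zeros(len(hlas))
        hidx = {h: i for i, h in enumerate(hlas)}
        for p in positives:
            counts[hidx[p.hla]] += 1
        probs = counts / counts.sum()
    else:
        hlas = sorted(hla_universe)
        probs = np.full(len(hlas), 1.0 / len(hlas))
    rng = np.random.default_rng(seed)
    n_target = int(round(ratio * len(positives)))
    # repeat the positive TCR multiset to preserve its marginal exactly
    pool = [positives[i % len(positives)] for i in range(n_target)]
    negatives: list[PairExample] = []
    tries = 0
    limit = max_tries_factor * max(n_target, 1)
    for p in pool:
        while True:
            tries += 1
            if tries > limit:
                raise RecordError("negative_space_exhausted")
            h = hlas[int(rng.choice(len(hlas), p=probs))]
            if (*p.tcr.key, h.name) not in pos_keys:
                negatives.append(PairExample(tcr=p.tcr, hla=h, label=0, donor=p.donor))
                break
    return negatives


def donor_aware_split(
    pairs: Sequence[PairExample], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split where no donor appears on both sides.

    Pairs without donor provenance are split at random. Donors are shuffled
    and assigned to the test side until it holds ``test_fraction`` of pairs.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    donors = [p.donor for p in pairs]
    if all(d is None for d in donors):
        order = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        return np.sort(order[n_test:]), np.sort(order[:n_test])
    uniq = sorted({d for d in donors if d is not None})
    if len(uniq) < 2:
        raise RecordError("cannot_split", "need >=2 donors for a donor-aware split")
    rng.shuffle(uniq)
    target = test_fraction * n
    test_donors: set = set()
    covered = 0
    for d in uniq:
        if covered >= target:
            break
        test_donors.add(d)
        covered += sum(1 for x in donors if x == d)
    if len(test_donors) == len(uniq):
        test_donors.discard(next(iter(test_donors)))
    test_idx = np.array([i for i, d in enumerate(donors) if d in test_donors])
    train_idx = np.array([i for i, d in enumerate(donors) if d not in test_donors])
    return train_idx, test_idx


class BindingModel:
    """Model object; ``fit`` trains the network and returns results.

    Parameters
    ----------
    positives, negatives
        Labelled pairs. When ``negatives`` is None they are sampled with
        :func:`sample_negatives` at ``config.negative_ratio``.
    hla_universe
        Alleles that must be scorable at inference (defaults to those seen
        in the pairs).
    autoencoder
        Optional pre-pretrained CDR3 autoencoder to reuse across fits.
    """

    def __init__(
        self,
        positives: Sequence[PairExample],
        negatives: Optional[Sequence[PairExample]] = None,
        config: Optional[BindingModelConfig] = None,
        hla_universe: Optional[Sequence[HLAAllele]] = None,
        autoencoder: Optional[CDR3Autoencoder] = None,
    ):
        if not positives:
            raise RecordError("empty_training")
        self.config = config or BindingModelConfig()
        self.positives = list(positives)
        if negatives is None:
            negatives = sample_negatives(
                positives, ratio=self.config.negative_ratio, seed=self.config.seed)
        self.negatives = list(negatives)
        self.hla_universe = sorted(hla_universe) if hla_universe is not None else \
            sorted({p.hla for p in self.positives})
        self._given_ae = autoencoder

    # -- component construction ---------------------------------------------
    def _build(self, warm: Optional["BindingResults"] = None):
        cfg = self.config
        pairs = self.positives + self.negatives
        if warm is not None:
            ae = warm.tcr_encoder.ae
            tcr_enc, hla_enc, mlp = warm.tcr_encoder, warm.hla_encoder, warm.mlp
            return tcr_enc, hla_enc, mlp
        rng = np.random.default_rng(cfg.seed)
        if self._given_ae is not None:
            ae = self._given_ae
        else:
            corpus = sorted({p.tcr.cdr3b for p in pairs})
            if len(corpus) > cfg.ae_pretrain_max:
                sub = np.random.default_rng(cfg.seed).choice(
                    len(corpus), size=cfg.ae_pretrain_max, replace=False)
                corpus = [corpus[i] for i in sub]
            ae = CDR3Autoencoder(max_len=cfg.max_len, embed_dim=cfg.ae_embed_dim,
                                 hidden=cfg.ae_hidden, seed=cfg.seed)
            ae.pretrain(corpus, epochs=cfg.ae_epochs, seed=cfg.seed)
        v_vocab = GeneVocab([p.tcr.v_gene for p in pairs])
        j_vocab = GeneVocab([p.tcr.j_gene for p in pairs])
        tcr_enc = TCREncoder(ae, v_vocab, j_vocab, seed=cfg.seed,
                             finetune_ae=cfg.finetune_ae)
        hla_enc = HLAEncoder(seed=cfg.seed + 1, dropout=cfg.dropout)
        d_in = tcr_enc.dim + hla_enc.dim
        mlp = nn.Sequential(
            nn.Linear(d_in, d_in // 2, rng),
            nn.LeakyReLU(),
            nn.Dropout(cfg.dropout, rng),
            nn.Linear(d_in // 2, 1, rng),
        )
        return tcr_enc, hla_enc, mlp

    # -- training -------------------------------------------------------------
    def fit(self, warm_start_from: Optional["BindingResults"] = None) -> "BindingResults":
        cfg = self.config
        tcr_enc, hla_enc, mlp = self._build(warm_start_from)
        pairs = self.positives + self.negatives
        train_idx, val_idx = donor_aware_split(pairs, cfg.val_fraction, cfg.seed + 7)
        params = tcr_enc.params() + hla_enc.params() + mlp.params()
        opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 13)
        y = np.array([p.label for p in pairs], dtype=float)
        val_pairs = [pairs[i] for i in val_idx]
        y_val = y[val_idx]

        def forward_batch(batch: list[PairExample], train: bool) -> np.ndarray:
            et = tcr_enc.forward([p.tcr for p in batch], train=train)
            eh = hla_enc.forward([p.hla for p in batch], train=train)
            self._split_at = et.shape[1]
            self._eth = np.concatenate([et, eh], axis=1)
            return mlp.forward(self._eth, train=train)

        def backward_batch(grad_logits: np.ndarray) -> None:
            g = mlp.backward(grad_logits[:, None])
            tcr_enc.backward(g[:, : self._split_at])
            hla_enc.backward(g[:, self._split_at:])

        history: list[dict] = []
        best_auc, best_state, best_epoch = -np.inf, None, -1
        epochs_since_best = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [pairs[i] for i in idx]
                opt.zero_grad()
                logits = forward_batch(batch, train=True).reshape(-1)
                loss, grad = nn.bce_with_logits(logits, y[idx])
                backward_batch(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            val_scores = _predict_components(tcr_enc, hla_enc, mlp, val_pairs,
                                             cfg.batch_size)
            val_auc = roc_auc_score(y_val, val_scores) if len(set(y_val)) > 1 else 0.5
            history.append({"epoch": epoch, "loss": epoch_loss / len(order),
                            "val_auc": float(val_auc)})
            if val_auc > best_auc:
                best_auc, best_epoch = val_auc, epoch
                best_state = nn.clone_state(nn.get_state(params))
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= cfg.patience:
                    break
        if best_state is not None:
            nn.set_state(params, best_state)
        return BindingResults(
            model=self, tcr_encoder=tcr_enc, hla_encoder=hla_enc, mlp=mlp,
            history=history, best_epoch=best_epoch,
            split={"train_idx": train_idx, "val_idx": val_idx,
                   "train_donors": sorted({pairs[i].donor for i in train_idx} - {None}),
                   "val_donors": sorted({pairs[i].donor for i in val_idx} - {None})},
        )


def _predict_components(tcr_enc, hla_enc, mlp, pairs, batch_size) -> np.ndarray:
    out = np.empty(len(pairs))
    for start in range(0, len(pairs), batch_size):
        batch = pairs[start:start + batch_size]
        et = tcr_enc.forward([p.tcr for p in batch], train=False)
        eh = hla_enc.forward([p.hla for p in batch], train=False)
        logits = mlp.forward(np.concatenate([et, eh], axis=1), train=False)
        out[start:start + batch_size] = nn.sigmoid(logits.reshape(-1))
    return out


@dataclass
class BindingResults:
    """Trained binding predictor: weights, history and scoring interface."""

    model: BindingModel
    tcr_encoder: TCREncoder
    hla_encoder: HLAEncoder
    mlp: nn.Sequential
    history: list = dc_field(default_factory=list)
    best_epoch: int = -1
    split: dict = dc_field(default_factory=dict)

    def predict(self, pairs: Sequence[PairExample]) -> np.ndarray:
        """Binding probability in [0, 1] per pair; deterministic at inference."""
        return _predict_components(self.tcr_encoder, self.hla_encoder, self.mlp,
                                   list(pairs), self.model.config.batch_size)

    def score_all_hla(
        self, tcr: TCRBeta, hla_universe: Optional[Sequence[HLAAllele]] = None
    ) -> list[tuple[HLAAllele, float]]:
        """All alleles ranked by score, ties broken by canonical name order."""
        universe = sorted(hla_universe if hla_universe is not None
                          else self.model.hla_universe)
        if not universe:
            raise RecordError("empty_universe")
        scores = self.predict([PairExample(tcr=tcr, hla=h, label=0) for h in universe])
        order = sorted(range(len(universe)), key=lambda i: (-scores[i], universe[i].name))
        return [(universe[i], float(scores[i])) for i in order]

    def score_matrix(self, tcrs: Sequence[TCRBeta],
                     hla_universe: Optional[Sequence[HLAAllele]] = None) -> tuple:
        """(n_tcr, n_hla) score grid in canonical allele order (batched)."""
        universe = sorted(hla_universe if hla_universe is not None
                          else self.model.hla_universe)
        pairs = [PairExample(tcr=t, hla=h, label=0) for t in tcrs for h in universe]
        s = self.predict(pairs).reshape(len(tcrs), len(universe))
        return s, universe

    @property
    def validation_auc(self) -> float:
        return self.history[self.best_epoch]["val_auc"] if self.history else float("nan")

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "TCR-HLA binding predictor",
            f"  positives / negatives : {len(self.model.positives)} / {len(self.model.negatives)}",
            f"  HLA universe          : {len(self.model.hla_universe)} alleles",
            f"  E_t dim / E_h dim     : {self.tcr_encoder.dim} / {self.hla_encoder.dim}",
            f"  epochs run (best)     : {len(self.history)} ({self.best_epoch})",
            f"  validation AUC        : {self.validation_auc:.4f}",
            f"  lr / weight decay     : {cfg.learning_rate} / {cfg.weight_decay}",
        ]
        return "\n".join(lines)


def make_scorer(results: BindingResults) -> Callable:
    """Adapter to the evaluation module's batched scorer protocol:
    ``score_fn(tcrs, universe) -> (n_tcr, n_hla) score matrix``."""

    def score_fn(tcrs: Sequence[TCRBeta], universe: Sequence[HLAAllele]) -> np.ndarray:
        s, _ = results.score_matrix(tcrs, universe)
        return s

    return score_fn
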