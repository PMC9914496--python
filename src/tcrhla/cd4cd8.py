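"""CD4/CD8 compartment classifier for unsorted repertoires.

Class I binding prediction only makes sense for CD8 T cells, so mixed
(whole-blood) repertoires are filtered first: a binary network on the TCR
encoding ``E_t`` predicts 1 for CD8 and 0 for CD4, and the highest-scoring
fraction of TCRs is kept.

Sensible values for that fraction span orders of magnitude — a few percent
of a pre-sorted repertoire down to 0.01% of a large mixed cohort — so
``filter_top_cd8`` takes it as a required argument with no default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .binding_model import donor_aware_split
from .encoders import CDR3Autoencoder, GeneVocab, TCREncoder
from .io_preprocess import PairExample, RecordError, TCRBeta


@dataclass
class CD4CD8Config:
    learning_rate: float = 0.0005
    weight_decay: float = 0.0005
    dropout: float = 0.1
    patience: int = 20
    batch_size: int = 512
    max_epochs: int = 200
    ae_embed_dim: int = 30
    ae_hidden: int = 300
    ae_epochs: int = 300
    ae_pretrain_max: int = 20_000
    max_len: int = 25
    val_fraction: float = 0.1
    finetune_ae: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise RecordError("invalid_config")


class CD4CD8Model:
    """Model object over compartment-labelled TCRs; ``fit`` returns results."""

    def __init__(self, tcrs: Sequence[TCRBeta], config: Optional[CD4CD8Config] = None,
                 donors: Optional[Sequence[Optional[str]]] = None,
                 autoencoder: Optional[CDR3Autoencoder] = None):
        labelled = [t for t in tcrs if t.compartment in ("CD4", "CD8")]
        classes = {t.compartment for t in labelled}
        if len(classes) < 2:
            raise RecordError("single_class")
        self.tcrs = labelled
        self.donors = list(donors) if donors is not None else [None] * len(labelled)
        self.config = config or CD4CD8Config()
        self._given_ae = autoencoder

    def fit(self) -> "CD4CD8Results":
        cfg = self.config
        y = np.array([1.0 if t.compartment == "CD8" else 0.0 for t in self.tcrs])
        if self._given_ae is not None:
            ae = self._given_ae
        else:
            corpus = sorted({t.cdr3b for t in self.tcrs})
            if len(corpus) > cfg.ae_pretrain_max:
                sub = np.random.default_rng(cfg.seed).choice(
                    len(corpus), size=cfg.ae_pretrain_max, replace=False)
                corpus = [corpus[i] for i in sub]
            ae = CDR3Autoencoder(max_len=cfg.max_len, embed_dim=cfg.ae_embed_dim,
                                 hidden=cfg.ae_hidden, seed=cfg.seed)
            ae.pretrain(corpus, epochs=cfg.ae_epochs, seed=cfg.seed)
        v_vocab = GeneVocab([t.v_gene for t in self.tcrs])
        j_vocab = GeneVocab([t.j_gene for t in self.tcrs])
        enc = TCREncoder(ae, v_vocab, j_vocab, seed=cfg.seed,
                         finetune_ae=cfg.finetune_ae)
        rng = np.random.default_rng(cfg.seed + 5)
        # one hidden linear layer of half the input dimension, ReLU, sigmoid out
        mlp = nn.Sequential(
            nn.Linear(enc.dim, enc.dim // 2, rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, rng),
            nn.Linear(enc.dim // 2, 1, rng),
        )
        # donor-aware internal validation split (random when donors unknown)
        marker = [PairExample(tcr=t, hla=_DUMMY_HLA, label=1, donor=d)
                  for t, d in zip(self.tcrs, self.donors)]
        train_idx, val_idx = donor_aware_split(marker, cfg.val_fraction, cfg.seed + 7)
        params = enc.params() + mlp.params()
        opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng2 = np.random.default_rng(cfg.seed + 13)
        history: list[dict] = []
        best_auc, best_state, best_epoch = -np.inf, None, -1
        since_best = 0
        val_tcrs = [self.tcrs[i] for i in val_idx]
        y_val = y[val_idx]
        for epoch in range(cfg.max_epochs):
            order = rng2.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                et = enc.forward([self.tcrs[i] for i in idx], train=True)
                logits = mlp.forward(et, train=True).reshape(-1)
                loss, grad = nn.bce_with_logits(logits, y[idx])
                enc.backward(mlp.backward(grad[:, None]))
                opt.step()
                epoch_loss += loss * len(idx)
            val_scores = _score(enc, mlp, val_tcrs, cfg.batch_size)
            val_auc = roc_auc_score(y_val, val_scores) if len(set(y_val)) > 1 else 0.5
            history.append({"epoch": epoch, "loss": epoch_loss / len(order),
                            "val_auc": float(val_auc)})
            if val_auc > best_auc:
                best_auc, best_epoch = val_auc, epoch
                best_state = nn.clone_state(nn.get_state(params))
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_state is not None:
            nn.set_state(params, best_state)
        return CD4CD8Results(model=self, encoder=enc, mlp=mlp, history=history,
                             best_epoch=best_epoch,
                             split={"train_idx": train_idx, "val_idx": val_idx})


# placeholder allele for reusing the donor-aware split helper on bare TCRs
from .io_preprocess import HLAAllele as _HLA  # noqa: E402

_DUMMY_HLA = _HLA("A", "01", "01")


def _score(enc: TCREncoder, mlp: nn.Sequential, tcrs: Sequence[TCRBeta],
           batch_size: int) -> np.ndarray:
    out = np.empty(len(tcrs))
    for start in range(0, len(tcrs), batch_size):
        batch = tcrs[start:start + batch_size]
        logits = mlp.forward(enc.forward(batch, train=False), train=False)
        out[start:start + batch_size] = nn.sigmoid(logits.reshape(-1))
    return out


@dataclass
class CD4CD8Results:
    model: CD4CD8Model
    encoder: TCREncoder
    mlp: nn.Sequential
    history: list = dc_field(default_factory=list)
    best_epoch: int = -1
    split: dict = dc_field(default_factory=dict)

    def predict(self, tcrs: Sequence[TCRBeta]) -> np.ndarray:
        """P(CD8) per TCR, in [0, 1]."""
        return _score(self.encoder, self.mlp, list(tcrs),
                      self.model.config.batch_size)

    @property
    def validation_auc(self) -> float:
        return self.history[self.best_epoch]["val_auc"] if self.history else float("nan")

    def summary(self) -> str:
        n8 = sum(1 for t in self.model.tcrs if t.compartment == "CD8")
        return "\n".join([
            "CD4/CD8 compartment classifier",
            f"  TCRs (CD8 / CD4)  : {n8} / {len(self.model.tcrs) - n8}",
            f"  epochs run (best) : {len(self.history)} ({self.best_epoch})",
            f"  validation AUC    : {self.validation_auc:.4f}",
        ])


def filter_top_cd8(results: CD4CD8Results, tcrs: Sequence[TCRBeta],
                   top_fraction: float) -> list[TCRBeta]:
    """The ceil(top_fraction * n) TCRs most likely to be CD8.

    ``top_fraction`` is deliberately required (no default).  Ordering is by
    descending score with ties broken by input order (stable sort).
    """
    if not 0 < top_fraction <= 1:
        raise RecordError("invalid_spec", "0 < top_fraction <= 1")
    tcrs = list(tcrs)
    if not tcrs:
        return []
    scores = results.predict(tcrs)
    k = int(np.ceil(top_fraction * len(tcrs)))
    order = np.argsort(-scores, kind="stable")[:k]
    return [tcrs[i] for i in sorted(order.tolist())]
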