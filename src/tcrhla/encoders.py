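"""Fixed-length vector encodings for TCRs and HLA alleles.

* CDR3 sequences: 21-symbol one-hot (20 amino acids + a stop symbol marking
  the end of the sequence, then zero padding), compressed by an autoencoder
  pretrained on sequences alone — no HLA information is consumed.
* V/J genes: learned 50-dimensional categorical embeddings with a reserved
  unknown token for genes unseen at training time.
* HLA alleles: the characters of the canonical allele name ("A*02:01") are
  embedded in 14 dimensions and passed through a two-layer character CNN
  (ReLU + max-pooling each) and two linear layers with dropout, giving a
  100-dimensional encoding.  A pluggable interface: any object with the same
  ``forward``/``backward``/``params`` surface (e.g. one consuming protein
  pseudo-sequences) can be swapped in.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import nn
from .io_preprocess import AMINO_ACIDS, HLAAllele, RecordError, TCRBeta

STOP = "$"
CDR3_ALPHABET = AMINO_ACIDS + STOP          # 21 symbols
_AA_INDEX = {a: i for i, a in enumerate(CDR3_ALPHABET)}
STOP_IDX = _AA_INDEX[STOP]

DEFAULT_MAX_LEN = 25


def one_hot(cdr3: str, max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """(max_len, 21) one-hot matrix: residues, one stop row, zero padding."""
    if len(cdr3) + 1 > max_len:
        raise RecordError("cdr3_too_long", cdr3)
    m = np.zeros((max_len, len(CDR3_ALPHABET)))
    for i, aa in enumerate(cdr3):
        if aa not in _AA_INDEX or aa == STOP:
            raise RecordError("invalid_residue", aa)
        m[i, _AA_INDEX[aa]] = 1.0
    m[len(cdr3), STOP_IDX] = 1.0
    return m


def decode_one_hot(m: np.ndarray) -> str:
    """Inverse of :func:`one_hot` on its image (reads rows up to the stop)."""
    out = []
    for row in m:
        if row.sum() == 0:
            break
        idx = int(row.argmax())
        if idx == STOP_IDX:
            break
        out.append(CDR3_ALPHABET[idx])
    return "".join(out)


def _class_targets(cdr3s: Sequence[str], max_len: int) -> np.ndarray:
    """Integer class per position; trailing padding is trained toward stop."""
    t = np.full((len(cdr3s), max_len), STOP_IDX, dtype=int)
    for n, s in enumerate(cdr3s):
        for i, aa in enumerate(s):
            t[n, i] = _AA_INDEX[aa]
    return t


def _one_hot_batch(cdr3s: Sequence[str], max_len: int) -> np.ndarray:
    return np.stack([one_hot(s, max_len) for s in cdr3s]).astype(np.float32)


class CDR3Autoencoder:
    """Sequence autoencoder over one-hot CDR3 matrices.

    The encoder (flatten -> dense -> ReLU -> dense) maps to a ``embed_dim``
    latent vector; the mirrored decoder emits per-position residue logits and
    training minimizes per-position cross-entropy.  Pretraining sees only
    sequences; the pretrained encoder later initializes (and is fine-tuned
    inside) the downstream classifiers.
    """

    def __init__(self, max_len: int = DEFAULT_MAX_LEN, embed_dim: int = 30,
                 hidden: int = 300, seed: int = 0):
        self.max_len = max_len
        self.embed_dim = embed_dim
        rng = np.random.default_rng(seed)
        d_in = max_len * len(CDR3_ALPHABET)
        self.encoder = nn.Sequential(
            nn.Flatten(),
            nn.Linear(d_in, hidden, rng),
            nn.ReLU(),
            nn.Linear(hidden, embed_dim, rng),
        )
        self.decoder = nn.Sequential(
            nn.Linear(embed_dim, hidden, rng),
            nn.ReLU(),
            nn.Linear(hidden, d_in, rng),
        )
        self.loss_history: list[float] = []

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def pretrain(self, cdr3s: Sequence[str], epochs: int = 300, lr: float = 1e-3,
                 batch_size: int = 512, seed: int = 0) -> "CDR3Autoencoder":
        """Minimize reconstruction cross-entropy on a sequence corpus."""
        if not cdr3s:
            raise RecordError("empty_training")
        uniq = sorted(set(cdr3s))
        x = _one_hot_batch(uniq, self.max_len)
        targets = _class_targets(uniq, self.max_len)
        opt = nn.Adam(self.params(), lr=lr)
        rng = np.random.default_rng(seed)
        n = len(uniq)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                opt.zero_grad()
                z = self.encoder.forward(x[idx], train=True)
                logits = self.decoder.forward(z, train=True).reshape(
                    len(idx), self.max_len, -1)
                loss, grad = nn.softmax_cross_entropy(logits, targets[idx])
                g = self.decoder.backward(grad.reshape(len(idx), -1))
                self.encoder.backward(g)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history.append(epoch_loss / n)
        return self

    def encode(self, cdr3s: Sequence[str]) -> np.ndarray:
        """Latent embedding, deterministic at inference."""
        return self.encoder.forward(_one_hot_batch(cdr3s, self.max_len), train=False)

    def reconstruct(self, cdr3s: Sequence[str]) -> list[str]:
        z = self.encode(cdr3s)
        logits = self.decoder.forward(z, train=False).reshape(
            len(cdr3s), self.max_len, -1)
        out = []
        for row in logits.argmax(axis=-1):
            seq = []
            for idx in row:
                if idx == STOP_IDX:
                    break
                seq.append(CDR3_ALPHABET[idx])
            out.append("".join(seq))
        return out

    def reconstruction_accuracy(self, cdr3s: Sequence[str]) -> float:
        """Per-position argmax accuracy over residues plus the stop row."""
        z = self.encode(cdr3s)
        logits = self.decoder.forward(z, train=False).reshape(
            len(cdr3s), self.max_len, -1)
        pred = logits.argmax(axis=-1)
        targets = _class_targets(cdr3s, self.max_len)
        hits = total = 0
        for n, s in enumerate(cdr3s):
            upto = len(s) + 1   # residues + stop
            hits += int((pred[n, :upto] == targets[n, :upto]).sum())
            total += upto
        return hits / total


UNK = "<unk>"


class GeneVocab:
    """Gene-name to embedding-row index, with a reserved unknown token."""

    def __init__(self, genes: Sequence[str]):
        self.index = {UNK: 0}
        for g in sorted(set(genes)):
            self.index.setdefault(g, len(self.index))
        self.n_unknown_hits = 0

    def __len__(self):
        return len(self.index)

    def __contains__(self, gene):
        return gene in self.index

    def encode(self, gene: str) -> int:
        if gene not in self.index:
            self.n_unknown_hits += 1
            return 0
        return self.index[gene]


class TCREncoder:
    """Builds ``E_t = [AE(cdr3b) | Emb_V(v) | Emb_J(j)]`` (alpha analogues optional).

    The autoencoder's encoder half is part of the graph: gradients flow into
    it when ``finetune_ae`` (its pretrained weights are the initialization),
    otherwise latent vectors are treated as fixed features.
    """

    GENE_EMB_DIM = 50

    def __init__(self, autoencoder: CDR3Autoencoder, v_vocab: GeneVocab,
                 j_vocab: GeneVocab, seed: int = 0, finetune_ae: bool = True,
                 use_alpha: bool = False,
                 va_vocab: Optional[GeneVocab] = None,
                 ja_vocab: Optional[GeneVocab] = None):
        rng = np.random.default_rng(seed)
        self.ae = autoencoder
        self.finetune_ae = finetune_ae
        self.v_vocab, self.j_vocab = v_vocab, j_vocab
        self.emb_v = nn.Embedding(len(v_vocab), self.GENE_EMB_DIM, rng)
        self.emb_j = nn.Embedding(len(j_vocab), self.GENE_EMB_DIM, rng)
        self.use_alpha = use_alpha
        if use_alpha:
            self.va_vocab, self.ja_vocab = va_vocab, ja_vocab
            self.emb_va = nn.Embedding(len(va_vocab), self.GENE_EMB_DIM, rng)
            self.emb_ja = nn.Embedding(len(ja_vocab), self.GENE_EMB_DIM, rng)
        self._cache: dict[str, np.ndarray] = {}

    @property
    def dim(self) -> int:
        d = self.ae.embed_dim + 2 * self.GENE_EMB_DIM
        if self.use_alpha:
            d += self.ae.embed_dim + 2 * self.GENE_EMB_DIM
        return d

    def params(self):
        out = [*self.emb_v.params(), *self.emb_j.params()]
        if self.use_alpha:
            out += [*self.emb_va.params(), *self.emb_ja.params()]
        if self.finetune_ae:
            out += self.ae.encoder.params()
        return out

    def _onehots(self, cdr3s: Sequence[str]) -> np.ndarray:
        rows = []
        for s in cdr3s:
            if s not in self._cache:
                self._cache[s] = one_hot(s, self.ae.max_len).astype(np.float32)
            rows.append(self._cache[s])
        return np.stack(rows)

    def forward(self, tcrs: Sequence[TCRBeta], train: bool = False) -> np.ndarray:
        cdr3s = [t.cdr3b for t in tcrs]
        if self.finetune_ae:
            z = self.ae.encoder.forward(self._onehots(cdr3s), train=train)
        else:
            z = self.ae.encode(cdr3s)
        ev = self.emb_v.forward([self.v_vocab.encode(t.v_gene) for t in tcrs], train=train)
        ej = self.emb_j.forward([self.j_vocab.encode(t.j_gene) for t in tcrs], train=train)
        parts = [z, ev, ej]
        if self.use_alpha:
            za = self.ae.encode([t.cdr3a or "" for t in tcrs])
            eva = self.emb_va.forward(
                [self.va_vocab.encode(t.v_gene_a or UNK) for t in tcrs], train=train)
            eja = self.emb_ja.forward(
                [self.ja_vocab.encode(t.j_gene_a or UNK) for t in tcrs], train=train)
            parts += [za, eva, eja]
        return np.concatenate(parts, axis=1)

    def backward(self, grad: np.ndarray) -> None:
        d_ae, d_g = self.ae.embed_dim, self.GENE_EMB_DIM
        off = 0
        g_ae = grad[:, off:off + d_ae]; off += d_ae
        g_v = grad[:, off:off + d_g]; off += d_g
        g_j = grad[:, off:off + d_g]; off += d_g
        if self.finetune_ae:
            self.ae.encoder.backward(g_ae)
        self.emb_v.backward(g_v)
        self.emb_j.backward(g_j)
        if self.use_alpha:
            off += d_ae  # frozen alpha AE features
            self.emb_va.backward(grad[:, off:off + d_g]); off += d_g
            self.emb_ja.backward(grad[:, off:off + d_g])


#: characters appearing in canonical allele names, index 0 reserved for padding
HLA_CHAR_VOCAB = "\0*:0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_HLA_CHAR_INDEX = {c: i for i, c in enumerate(HLA_CHAR_VOCAB)}
HLA_NAME_LEN = 10


def hla_char_indices(hla: HLAAllele, max_len: int = HLA_NAME_LEN) -> np.ndarray:
    """Canonical allele name as padded character indices."""
    name = hla.name[:max_len]
    idx = np.zeros(max_len, dtype=int)
    for i, c in enumerate(name):
        idx[i] = _HLA_CHAR_INDEX.get(c, 0)
    return idx


class HLAEncoder:
    """Character CNN over the allele name producing a 100-dim encoding ``E_h``.

    14-dim character embedding, two (conv -> ReLU -> max-pool) blocks, then
    two linear layers with dropout 0.1.
    """

    CHAR_EMB_DIM = 14
    OUT_DIM = 100

    def __init__(self, seed: int = 0, dropout: float = 0.1):
        rng = np.random.default_rng(seed)
        self.emb = nn.Embedding(len(HLA_CHAR_VOCAB), self.CHAR_EMB_DIM, rng)
        # name length 10 -> conv3: 8 -> pool2: 4 -> conv2: 3 -> pool2: 1
        self.cnn = nn.Sequential(
            nn.Conv1d(self.CHAR_EMB_DIM, 32, 3, rng),
            nn.ReLU(),
            nn.MaxPool1d(2),
            nn.Conv1d(32, 64, 2, rng),
            nn.ReLU(),
            nn.MaxPool1d(2),
            nn.Flatten(),
            nn.Linear(64, 64, rng),
            nn.ReLU(),
            nn.Dropout(dropout, rng),
            nn.Linear(64, self.OUT_DIM, rng),
        )

    @property
    def dim(self) -> int:
        return self.OUT_DIM

    def params(self):
        return self.emb.params() + self.cnn.params()

    def forward(self, hlas: Sequence[HLAAllele], train: bool = False) -> np.ndarray:
        idx = np.stack([hla_char_indices(h) for h in hlas])
        x = self.emb.forward(idx, train=train)
        return self.cnn.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.cnn.backward(grad)
        self.emb.backward(g)
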