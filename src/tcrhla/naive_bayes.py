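"""Naive Bayes V-beta-gene association model for HLA restriction.

The CDR1 and CDR2 loops that contact the MHC alpha-helices are fully
determined by the V gene, so a first-order predictor of which HLA a TCR is
restricted by can be read off V-gene usage alone.  From positive (TCR, HLA)
pairs we estimate

* ``P(h_i)`` — probability a random TCR in the table binds HLA ``h_i``,
* ``P(v_j)`` — probability a random TCR uses V gene ``v_j``,
* ``P(v_j | h_i)`` — V-gene usage conditioned on the bound HLA,

and score any (h, v) pair with Bayes' rule::

    s_ij = P(h_i | v_j) = P(h_i) P(v_j | h_i) / P(v_j)

With no smoothing this is exactly ``count(h_i, v_j) / count(v_j)``.  An
optional Laplace pseudo-count keeps scores finite on (h, v) combinations
unseen in training, which otherwise crash cross-dataset transfer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io_preprocess import HLAAllele, PairExample, RecordError


class VGeneNaiveBayes:
    """Model object; ``fit`` estimates the probability tables.

    Parameters
    ----------
    pairs
        Positive (label=1) training pairs, already normalized.
    """

    def __init__(self, pairs: Sequence[PairExample]):
        pos = [p for p in pairs if p.label == 1]
        if not pos:
            raise RecordError("empty_training")
        self.pairs = pos
        self.hlas: list[HLAAllele] = sorted({p.hla for p in pos})
        self.v_genes: list[str] = sorted({p.tcr.v_gene for p in pos})

    def fit(self, smoothing_alpha: float = 0.0) -> "NaiveBayesResults":
        """Estimate the (optionally pseudo-count smoothed) frequency tables."""
        n = len(self.pairs)
        H, V = len(self.hlas), len(self.v_genes)
        h_idx = {h: i for i, h in enumerate(self.hlas)}
        v_idx = {v: j for j, v in enumerate(self.v_genes)}
        joint = np.zeros((H, V))
        for p in self.pairs:
            joint[h_idx[p.hla], v_idx[p.tcr.v_gene]] += 1
        a = float(smoothing_alpha)
        p_h = (joint.sum(axis=1) + a * V) / (n + a * H * V)
        p_v_given_h = (joint + a) / (joint.sum(axis=1, keepdims=True) + a * V)
        # marginalising keeps per-v scores summing to 1 for any alpha;
        # for alpha=0 this equals the empirical count(v)/n
        p_v = p_h @ p_v_given_h
        return NaiveBayesResults(self, p_h, p_v, p_v_given_h, a)


@dataclass
class NaiveBayesResults:
    """Fitted probability tables plus the Bayes-rule scorer."""

    model: VGeneNaiveBayes
    p_h_arr: np.ndarray
    p_v_arr: np.ndarray
    p_v_given_h_arr: np.ndarray
    smoothing_alpha: float

    def __post_init__(self):
        self._h_idx = {h: i for i, h in enumerate(self.model.hlas)}
        self._v_idx = {v: j for j, v in enumerate(self.model.v_genes)}

    # -- dict-style views of the tables -------------------------------------
    @property
    def p_h(self) -> dict:
        return {h: float(self.p_h_arr[i]) for h, i in self._h_idx.items()}

    @property
    def p_v(self) -> dict:
        return {v: float(self.p_v_arr[j]) for v, j in self._v_idx.items()}

    @property
    def p_v_given_h(self) -> dict:
        return {
            (h, v): float(self.p_v_given_h_arr[i, j])
            for h, i in self._h_idx.items()
            for v, j in self._v_idx.items()
        }

    # -- scoring -------------------------------------------------------------
    def score(self, v_gene: str) -> dict:
        """Posterior ``P(h | v)`` over every HLA for one V gene."""
        if v_gene not in self._v_idx:
            if self.smoothing_alpha > 0:
                # unseen gene: conditioning is uninformative, posterior = prior
                return {h: float(self.p_h_arr[i]) for h, i in self._h_idx.items()}
            raise RecordError("unseen_v_gene", v_gene)
        j = self._v_idx[v_gene]
        if self.p_v_arr[j] == 0:
            raise RecordError("unseen_v_gene", v_gene)
        s = self.p_h_arr * self.p_v_given_h_arr[:, j] / self.p_v_arr[j]
        return {h: float(s[i]) for h, i in self._h_idx.items()}

    def score_pairs(self, pairs: Sequence[PairExample]) -> np.ndarray:
        """``P(h | v)`` for each pair's own (h, v); vectorised convenience."""
        return np.array([self.score(p.tcr.v_gene).get(p.hla, 0.0) for p in pairs])

    def score_matrix(self) -> np.ndarray:
        """Full (n_hla, n_v) matrix of posteriors ``s_ij = P(h_i | v_j)``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            s = self.p_h_arr[:, None] * self.p_v_given_h_arr / self.p_v_arr[None, :]
        return np.nan_to_num(s)

    def log_matrix(self, epsilon: float = 1e-5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``log(s_ij + eps)`` plus single-link leaf orderings of rows/columns.

        The leaf orders reproduce the usual two-dimensional clustered-heatmap
        layout (single linkage, Euclidean distance on the log rows/columns).
        """
        m = np.log(self.score_matrix() + epsilon)
        row_order = _single_link_order(m)
        col_order = _single_link_order(m.T)
        return m, row_order, col_order

    # -- reporting -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flat table of (h, v, P(h), P(v), P(v|h)) for serialization."""
        rows = []
        for h, i in self._h_idx.items():
            for v, j in self._v_idx.items():
                rows.append((h.name, v, self.p_h_arr[i], self.p_v_arr[j],
                             self.p_v_given_h_arr[i, j]))
        return pd.DataFrame(rows, columns=["hla", "v_gene", "p_h", "p_v", "p_v_given_h"])

    def summary(self) -> str:
        top = Counter()
        for p in self.model.pairs:
            top[p.hla.name] += 1
        lines = [
            "V-gene Naive Bayes association model",
            f"  training pairs : {len(self.model.pairs)}",
            f"  HLA alleles    : {len(self.model.hlas)}",
            f"  V genes        : {len(self.model.v_genes)}",
            f"  smoothing alpha: {self.smoothing_alpha}",
            "  most frequent HLAs: "
            + ", ".join(f"{h} ({c})" for h, c in top.most_common(3)),
        ]
        return "\n".join(lines)


def _single_link_order(rows: np.ndarray) -> np.ndarray:
    if rows.shape[0] <= 1:
        return np.arange(rows.shape[0])
    return leaves_list(linkage(rows, method="single", metric="euclidean"))
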