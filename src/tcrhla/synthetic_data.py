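"""Synthetic repertoires with planted TCR-HLA structure.

Three kinds of data are generated, mirroring the study designs the package
targets, with known ground truth for parameter-recovery tests:

* **Paired tables** — (TCR, HLA) positives where the V-beta gene is drawn
  from a planted conditional distribution ``A[h, v] = P(v | h)``, optionally
  with an HLA-specific CDR3 k-mer motif inserted.
* **Bulk repertoires** — donors carry 2 A + 2 B alleles drawn from population
  frequencies; each TCR's true restricting allele is hidden among the donor's
  candidates (uniform within donor) and returned separately as a truth map.
* **CD4/CD8 repertoires** — CDR3s with a k-mer enriched in CD8 cells.

A labelled paired table can also be degraded into the ambiguous
bulk-sequencing form by attaching extra candidate alleles sampled from the
table's empirical HLA distribution (``make_noisy_pth``).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_preprocess import (
    AMINO_ACIDS,
    DonorRepertoire,
    HLAAllele,
    PairExample,
    RecordError,
    TCRBeta,
)

# CDR3 length support: 8..20 with a peak near 14, a coarse match to observed
# beta-chain length distributions.
CDR3_LENGTHS = np.arange(8, 21)
_raw = np.exp(-0.5 * ((CDR3_LENGTHS - 14) / 2.2) ** 2)
DEFAULT_LENGTH_PMF = _raw / _raw.sum()


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic repertoire generator.

    ``association`` is a (n_hla, n_v) row-stochastic matrix: row i is the
    V-gene distribution of TCRs restricted by ``hla_pool[i]``. ``motif_map``
    plants an HLA-specific CDR3 k-mer with probability ``motif_strength``;
    ``cd8_motif`` plants a compartment signal the same way.
    """

    n_tcrs: int = 10_000
    hla_pool: Sequence[HLAAllele] = field(default_factory=list)
    hla_freqs: Optional[np.ndarray] = None
    v_pool: Sequence[str] = field(default_factory=list)
    v_freqs: Optional[np.ndarray] = None
    association: Optional[np.ndarray] = None
    cdr3_length_pmf: np.ndarray = field(default_factory=lambda: DEFAULT_LENGTH_PMF.copy())
    motif_map: dict = field(default_factory=dict)
    motif_strength: float = 0.0
    cd8_motif: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.association is not None:
            a = np.asarray(self.association, dtype=float)
            if a.shape != (len(self.hla_pool), len(self.v_pool)):
                raise RecordError("invalid_spec", "association shape mismatch")
            if not np.allclose(a.sum(axis=1), 1.0, atol=1e-8):
                raise RecordError("invalid_spec", "association rows must sum to 1")
        for freqs, pool in ((self.hla_freqs, self.hla_pool), (self.v_freqs, self.v_pool)):
            if freqs is not None:
                f = np.asarray(freqs, dtype=float)
                if len(f) != len(pool) or not np.isclose(f.sum(), 1.0, atol=1e-8):
                    raise RecordError("invalid_spec", "pool frequencies must sum to 1")

    def _hla_freqs(self) -> np.ndarray:
        if self.hla_freqs is not None:
            return np.asarray(self.hla_freqs, dtype=float)
        return np.full(len(self.hla_pool), 1.0 / len(self.hla_pool))

    def _v_freqs(self) -> np.ndarray:
        if self.v_freqs is not None:
            return np.asarray(self.v_freqs, dtype=float)
        return np.full(len(self.v_pool), 1.0 / len(self.v_pool))


def default_hla_pool(n_a: int = 32, n_b: int = 32) -> list[HLAAllele]:
    """A universe of n_a A-locus + n_b B-locus two-field alleles."""
    pool = [HLAAllele("A", f"{i + 1:02d}", "01") for i in range(n_a)]
    pool += [HLAAllele("B", f"{i + 1:02d}", "01") for i in range(n_b)]
    return pool


def default_v_pool(n: int = 30) -> list[str]:
    return [f"V{i + 1:02d}-01" for i in range(n)]


def planted_association(n_hla: int, n_v: int, strength: float = 0.9) -> np.ndarray:
    """Row-stochastic matrix where HLA i concentrates mass on V gene i mod n_v.

    ``strength`` goes to the preferred V gene, the remainder spread uniformly
    over the others; ``strength = 1/n_v`` would be uniform (no signal).
    """
    a = np.full((n_hla, n_v), (1.0 - strength) / (n_v - 1))
    for i in range(n_hla):
        a[i, i % n_v] = strength
    return a


def uniform_association(n_hla: int, n_v: int) -> np.ndarray:
    return np.full((n_hla, n_v), 1.0 / n_v)


def _draw_cdr3(rng: np.random.Generator, spec: GeneratorSpec, motif: Optional[str]) -> str:
    length = int(rng.choice(CDR3_LENGTHS, p=spec.cdr3_length_pmf))
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    seq = "".join(letters)
    if motif is not None and rng.random() < spec.motif_strength:
        k = len(motif)
        if k <= length:
            pos = int(rng.integers(0, length - k + 1))
            seq = seq[:pos] + motif + seq[pos + k:]
    return seq


def _draw_tcr(
    rng: np.random.Generator, spec: GeneratorSpec, h_idx: int, compartment: str = "unknown"
) -> TCRBeta:
    if spec.association is not None:
        v_probs = np.asarray(spec.association, dtype=float)[h_idx]
    else:
        v_probs = spec._v_freqs()
    v = spec.v_pool[int(rng.choice(len(spec.v_pool), p=v_probs))]
    motif = spec.motif_map.get(spec.hla_pool[h_idx])
    j = f"J{int(rng.integers(1, 3)):02d}"
    return TCRBeta(cdr3b=_draw_cdr3(rng, spec, motif), v_gene=v, j_gene=j, compartment=compartment)


def generate_pth(spec: GeneratorSpec) -> list[PairExample]:
    """Paired positives: h from the pool frequencies, v from ``A[h, .]``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hf = spec._hla_freqs()
    pairs = []
    for _ in range(spec.n_tcrs):
        hi = int(rng.choice(len(spec.hla_pool), p=hf))
        pairs.append(PairExample(tcr=_draw_tcr(rng, spec, hi), hla=spec.hla_pool[hi], label=1))
    return pairs


def generate_bse(
    spec: GeneratorSpec,
    n_donors: int,
    tcrs_per_donor: int = 200,
    alleles_per_donor: int = 4,
) -> tuple[list[DonorRepertoire], dict]:
    """Bulk repertoires where each TCR's true allele is hidden among candidates.

    Each donor draws ``alleles_per_donor`` alleles — half from the A locus and
    half from the B locus, without replacement within a locus — from the pool
    frequencies. Each TCR picks its TRUE allele uniformly from the donor's
    set, then V gene and CDR3 exactly as in :func:`generate_pth`.

    Returns ``(donors, truth)`` with ``truth[(donor_id, i)]`` the true allele
    of ``donors[..].tcrs[i]`` — for parameter-recovery tests only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hf = spec._hla_freqs()
    by_locus: dict[str, list[int]] = {}
    for i, h in enumerate(spec.hla_pool):
        by_locus.setdefault(h.locus, []).append(i)
    per_locus = alleles_per_donor // 2
    for locus in ("A", "B"):
        if len(by_locus.get(locus, [])) < per_locus:
            raise RecordError("invalid_spec", f"need >= {per_locus} alleles at locus {locus}")
    donors: list[DonorRepertoire] = []
    truth: dict = {}
    for d in range(n_donors):
        chosen: list[int] = []
        for locus in ("A", "B"):
            idx = np.array(by_locus[locus])
            p = hf[idx] / hf[idx].sum()
            take = per_locus if locus == "A" else alleles_per_donor - per_locus
            chosen.extend(rng.choice(idx, size=take, replace=False, p=p).tolist())
        if alleles_per_donor == 1:  # degenerate, ambiguity-free case
            chosen = [chosen[0]]
        donor_id = f"donor{d:04d}"
        hla_set = frozenset(spec.hla_pool[i] for i in chosen)
        tcrs = []
        for i in range(tcrs_per_donor):
            hi = int(rng.choice(chosen))
            tcrs.append(_draw_tcr(rng, spec, hi))
            truth[(donor_id, i)] = spec.hla_pool[hi]
        donors.append(DonorRepertoire(donor_id=donor_id, hla_set=hla_set, tcrs=tcrs))
    return donors, truth


def generate_cd4cd8(
    spec: GeneratorSpec, n_tcrs: Optional[int] = None, cd8_fraction: float = 0.5
) -> list[TCRBeta]:
    """Compartment-labelled TCRs with the CD8 k-mer planted via motif_strength."""
    spec.validate()
    if spec.cd8_motif is None:
        raise RecordError("invalid_spec", "cd8_motif required")
    n = spec.n_tcrs if n_tcrs is None else n_tcrs
    rng = np.random.default_rng(spec.seed)
    vf = spec._v_freqs()
    out = []
    for _ in range(n):
        is_cd8 = rng.random() < cd8_fraction
        v = spec.v_pool[int(rng.choice(len(spec.v_pool), p=vf))]
        seq = _draw_cdr3(rng, spec, spec.cd8_motif if is_cd8 else None)
        j = f"J{int(rng.integers(1, 3)):02d}"
        out.append(TCRBeta(cdr3b=seq, v_gene=v, j_gene=j,
                           compartment="CD8" if is_cd8 else "CD4"))
    return out


def make_noisy_pth(
    pairs: Sequence[PairExample], k_extra: int = 3, seed: int = 0
) -> list[tuple[TCRBeta, frozenset]]:
    """Degrade a labelled paired table into the ambiguous bulk form.

    Each TCR's candidate set is its true allele plus ``k_extra`` distinct
    alleles sampled (excluding the truth, without replacement) from the
    empirical HLA distribution of the input table, so every candidate set has
    exactly ``k_extra + 1`` alleles and contains the truth.
    """
    alleles = sorted({p.hla for p in pairs})
    if len(alleles) < k_extra + 1:
        raise RecordError("insufficient_alleles", f"{len(alleles)} distinct alleles")
    rng = np.random.default_rng(seed)
    counts = np.array([sum(1 for p in pairs if p.hla == a) for a in alleles], dtype=float)
    out = []
    for p in pairs:
        ti = alleles.index(p.hla)
        w = counts.copy()
        w[ti] = 0.0
        extra_idx = rng.choice(len(alleles), size=k_extra, replace=False, p=w / w.sum()) \
            if k_extra else np.array([], dtype=int)
        cand = frozenset([p.hla] + [alleles[i] for i in extra_idx])
        out.append((p.tcr, cand))
    return out
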