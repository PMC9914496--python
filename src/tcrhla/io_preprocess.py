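"""Reading, normalization and filtering of TCR and HLA records.

Paired TCR-HLA tables (curated-database style CSVs) and per-donor bulk
repertoires (AIRR-style TSVs plus an HLA typing table) are normalized to a
single canonical representation:

* HLA alleles as two-field Class I labels, e.g. ``A*02:01``.  Inputs with
  only the two-digit allele group (``HLA-A*02``, serological ``A2``) are
  completed to the most frequent full allele of that group, taken from a
  :class:`FrequencyCatalog`.
* V-beta genes as two-field labels ``V<dd>-<dd>``: dataset prefixes
  (``TRBV``/``TCRBV``/``V``) are stripped, allele suffixes (``:01``/``*01``)
  removed, slash-separated multi-option names collapsed to the first option,
  single-field names completed via the catalog.
* J-beta genes as one-field family labels ``J<dd>``.

All downstream modules consume only the canonical records defined here.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

CLASS_I_BINDING_LOCI = ("A", "B")


class RecordError(ValueError):
    """A record that cannot be normalized; carries a machine-readable reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True, order=True)
class HLAAllele:
    """Two-field HLA allele label, e.g. ``A*02:01``.

    Loci other than A and B are storable (e.g. C, DRB1 appearing as labels in
    curated tables) but are outside the Class I A/B binding-prediction scope.
    """

    locus: str
    field1: str
    field2: str

    def __post_init__(self):
        if not re.fullmatch(r"[A-Z]+[0-9]*", self.locus):
            raise RecordError("unparseable_hla", f"bad locus {self.locus!r}")
        if not (self.field1.isdigit() and self.field2.isdigit()):
            raise RecordError("unparseable_hla", "non-numeric allele fields")

    @property
    def name(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}"

    @property
    def group(self) -> str:
        return f"{self.locus}*{self.field1}"

    @property
    def in_binding_scope(self) -> bool:
        return self.locus in CLASS_I_BINDING_LOCI

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class TCRBeta:
    """One receptor record: CDR3-beta sequence plus normalized gene labels."""

    cdr3b: str
    v_gene: str
    j_gene: str
    cdr3a: Optional[str] = None
    v_gene_a: Optional[str] = None
    j_gene_a: Optional[str] = None
    compartment: str = "unknown"  # {CD4, CD8, unknown}

    def __post_init__(self):
        if not self.cdr3b or not set(self.cdr3b) <= _AA_SET:
            raise RecordError("invalid_residue", self.cdr3b)
        if not re.fullmatch(r"V\d{2}-\d{2}", self.v_gene):
            raise RecordError("unparseable_v_gene", self.v_gene)
        if not re.fullmatch(r"J\d{2}", self.j_gene):
            raise RecordError("unparseable_j_gene", self.j_gene)
        if self.compartment not in ("CD4", "CD8", "unknown"):
            raise RecordError("invalid_compartment", self.compartment)

    @property
    def key(self) -> tuple:
        return (self.cdr3b, self.v_gene, self.j_gene)


@dataclass
class PairExample:
    """A (TCR, HLA, label) training/evaluation instance.

    ``donor`` is optional provenance used for donor-aware train/test splits.
    """

    tcr: TCRBeta
    hla: HLAAllele
    label: int
    donor: Optional[str] = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise RecordError("invalid_label", str(self.label))

    @property
    def key(self) -> tuple:
        return (*self.tcr.key, self.hla.name)


@dataclass
class DonorRepertoire:
    """A donor's candidate HLA alleles and sequenced TCRs.

    ``hla_set`` has set semantics: a homozygous donor keeps one copy of the
    duplicated allele, so the candidate count may be below 4.
    """

    donor_id: str
    hla_set: frozenset = field(default_factory=frozenset)
    tcrs: list = field(default_factory=list)

    @property
    def binding_hlas(self) -> frozenset:
        return frozenset(h for h in self.hla_set if h.in_binding_scope)


# ---------------------------------------------------------------------------
# Frequency catalog and normalization


@dataclass
class FrequencyCatalog:
    """Most-frequent completions for HLA groups and single-field V genes.

    Built by counting full labels in a reference table; each group maps to
    exactly one completion (ties broken by canonical string order).
    """

    hla_completions: dict = field(default_factory=dict)   # "A*02" -> "A*02:01"
    v_completions: dict = field(default_factory=dict)     # "V05"  -> "V05-01"

    @classmethod
    def from_counts(cls, hla_names: Iterable[str], v_names: Iterable[str]) -> "FrequencyCatalog":
        """Count already-canonical full names and keep the modal completion per group."""
        hla_groups: dict[str, Counter] = {}
        for name in hla_names:
            m = re.fullmatch(r"([A-Z]+\d*)\*(\d{2}):(\d{2})", name)
            if not m:
                continue
            hla_groups.setdefault(f"{m.group(1)}*{m.group(2)}", Counter())[name] += 1
        v_groups: dict[str, Counter] = {}
        for name in v_names:
            m = re.fullmatch(r"(V\d{2})-(\d{2})", name)
            if not m:
                continue
            v_groups.setdefault(m.group(1), Counter())[name] += 1

        def modal(counter: Counter) -> str:
            top = max(counter.values())
            return min(n for n, c in counter.items() if c == top)

        return cls(
            hla_completions={g: modal(c) for g, c in hla_groups.items()},
            v_completions={g: modal(c) for g, c in v_groups.items()},
        )


_HLA_RE = re.compile(
    r"""^(?:HLA[-_ ]?)?          # optional HLA- prefix
        ([A-Z]+\d*)              # locus (A, B, C, DRB1, ...)
        (?:\*|\s|-)?             # separator
        (\d+)                    # allele group
        (?::(\d+))?              # optional protein field
        """,
    re.VERBOSE,
)


def normalize_hla(raw: str, catalog: Optional[FrequencyCatalog] = None) -> HLAAllele:
    """Normalize an HLA designation in any common dialect to two fields.

    Accepts ``HLA-A*02:01``, ``A*02:01``, ``HLA-A*02``, serological ``A2``.
    Two-digit-only inputs are completed using the catalog's most frequent
    allele of that group.

    Raises
    ------
    RecordError
        ``unparseable_hla`` for strings no dialect matches; ``unknown_group``
        when a group-only input has no catalog completion.
    """
    if not raw or not isinstance(raw, str):
        raise RecordError("unparseable_hla", repr(raw))
    s = raw.strip().upper().replace("’", "'")
    m = _HLA_RE.match(s)
    if not m:
        raise RecordError("unparseable_hla", raw)
    locus, f1, f2 = m.group(1), m.group(2), m.group(3)
    f1 = f1.zfill(2)
    if f2 is not None:
        return HLAAllele(locus, f1, f2.zfill(2))
    group = f"{locus}*{f1}"
    if catalog is None or group not in catalog.hla_completions:
        raise RecordError("unknown_group", group)
    full = catalog.hla_completions[group]
    locus2, f1b, f2b = re.fullmatch(r"([A-Z]+\d*)\*(\d{2}):(\d{2})", full).groups()
    return HLAAllele(locus2, f1b, f2b)


_V_PREFIX_RE = re.compile(r"^(?:TCRB?V|TRBV|TCRBV|V)", re.IGNORECASE)


def normalize_v_gene(raw: str, catalog: Optional[FrequencyCatalog] = None) -> str:
    """Normalize a V-beta designation to the two-field form ``V<dd>-<dd>``.

    Allele suffixes are stripped (``V01-02:01`` -> ``V01-02``), slash lists
    collapse to the first option (``V13-01/3/4`` -> ``V13-01``) and
    single-field names are completed via the catalog (``V05`` -> ``V05-01``).
    """
    if not raw or not isinstance(raw, str):
        raise RecordError("unparseable_v_gene", repr(raw))
    s = raw.strip().upper()
    s = s.split("/")[0]                      # multi-option: first one chosen
    s = re.split(r"[:*]", s, maxsplit=1)[0]  # drop allele suffix
    s = _V_PREFIX_RE.sub("", s, count=1)
    m = re.fullmatch(r"0*(\d+)(?:-0*(\d+))?", s)
    if not m:
        raise RecordError("unparseable_v_gene", raw)
    fam = m.group(1).zfill(2)
    if m.group(2) is not None:
        return f"V{fam}-{m.group(2).zfill(2)}"
    key = f"V{fam}"
    if catalog is None or key not in catalog.v_completions:
        raise RecordError("unknown_group", key)
    return catalog.v_completions[key]


_J_PREFIX_RE = re.compile(r"^(?:TCRB?J|TRBJ|TCRBJ|J)", re.IGNORECASE)


def normalize_j_gene(raw: str) -> str:
    """Normalize a J-beta designation to the one-field family form ``J<dd>``."""
    if not raw or not isinstance(raw, str):
        raise RecordError("unparseable_j_gene", repr(raw))
    s = raw.strip().upper().split("/")[0]
    s = re.split(r"[:*]", s, maxsplit=1)[0]
    s = _J_PREFIX_RE.sub("", s, count=1)
    m = re.fullmatch(r"0*(\d+)(?:-0*\d+)?", s)
    if not m:
        raise RecordError("unparseable_j_gene", raw)
    return f"J{m.group(1).zfill(2)}"


# ---------------------------------------------------------------------------
# PTH table filtering

#: column synonyms for curated paired tables
PTH_COLUMNS = {
    "species": ("species", "Species"),
    "cdr3b": ("cdr3b", "CDR3.beta.aa", "cdr3_beta", "junction_aa"),
    "v_gene": ("v_gene", "TRBV", "v_call", "vb"),
    "j_gene": ("j_gene", "TRBJ", "j_call", "jb"),
    "hla": ("hla", "MHC", "mhc", "HLA"),
    "cdr3a": ("cdr3a", "CDR3.alpha.aa"),
    "v_gene_a": ("v_gene_a", "TRAV"),
    "j_gene_a": ("j_gene_a", "TRAJ"),
    "compartment": ("compartment", "T.Cell.Type", "cell_type"),
}


def _pick(row: dict, logical: str):
    for c in PTH_COLUMNS[logical]:
        if c in row and row[c] is not None and not pd.isna(row[c]) and str(row[c]).strip():
            return str(row[c]).strip()
    return None


def build_catalog(rows: pd.DataFrame) -> FrequencyCatalog:
    """Frequency catalog estimated from the full labels in a raw PTH table."""
    hla_names, v_names = [], []
    for _, row in rows.iterrows():
        r = row.to_dict()
        raw_hla = _pick(r, "hla")
        if raw_hla and "," not in raw_hla:
            try:
                hla_names.append(normalize_hla(raw_hla).name)
            except RecordError:
                pass
        raw_v = _pick(r, "v_gene")
        if raw_v:
            try:
                v_names.append(normalize_v_gene(raw_v))
            except RecordError:
                pass
    return FrequencyCatalog.from_counts(hla_names, v_names)


def filter_pth_records(
    rows: pd.DataFrame,
    catalog: Optional[FrequencyCatalog] = None,
    species: str = "Human",
    deduplicate: bool = True,
) -> tuple[list[PairExample], dict[str, int]]:
    """Apply the curated-table filters and return clean positive pairs.

    Dropped, in order of precedence: non-human rows, rows with missing HLA,
    rows listing two or more HLA alleles, rows with missing CDR3-beta, rows
    whose fields fail normalization, exact duplicate (TCR, HLA) pairs.

    Returns ``(kept, audit)`` where the audit counts every drop reason;
    ``kept + dropped`` always equals the input row count.
    """
    if catalog is None:
        catalog = build_catalog(rows)
    kept: list[PairExample] = []
    audit: Counter = Counter()
    seen: set[tuple] = set()
    for _, row in rows.iterrows():
        r = row.to_dict()
        sp = _pick(r, "species")
        if sp is not None and sp.lower() != species.lower():
            audit["non_human"] += 1
            continue
        raw_hla = _pick(r, "hla")
        if raw_hla is None:
            audit["missing_hla"] += 1
            continue
        if len([a for a in re.split(r"[,;]", raw_hla) if a.strip()]) >= 2:
            audit["multiple_hla"] += 1
            continue
        cdr3 = _pick(r, "cdr3b")
        if cdr3 is None:
            audit["missing_cdr3"] += 1
            continue
        try:
            hla = normalize_hla(raw_hla, catalog)
            raw_v = _pick(r, "v_gene")
            raw_j = _pick(r, "j_gene")
            if raw_v is None or raw_j is None:
                raise RecordError("missing_gene")
            comp = _pick(r, "compartment") or "unknown"
            if comp.upper() not in ("CD4", "CD8"):
                comp = "unknown"
            else:
                comp = comp.upper()
            tcr = TCRBeta(
                cdr3b=cdr3.upper(),
                v_gene=normalize_v_gene(raw_v, catalog),
                j_gene=normalize_j_gene(raw_j),
                cdr3a=_pick(r, "cdr3a"),
                v_gene_a=_pick(r, "v_gene_a"),
                j_gene_a=_pick(r, "j_gene_a"),
                compartment=comp,
            )
        except RecordError as e:
            audit[e.reason] += 1
            continue
        pair = PairExample(tcr=tcr, hla=hla, label=1)
        if deduplicate:
            if pair.key in seen:
                audit["duplicate_pair"] += 1
                continue
            seen.add(pair.key)
        kept.append(pair)
    return kept, dict(audit)


# ---------------------------------------------------------------------------
# Repertoire I/O

#: AIRR Rearrangement names and an immunoSEQ-style alternative
AIRR_COLUMN_MAP = {"cdr3b": "junction_aa", "v_gene": "v_call", "j_gene": "j_call"}
IMMUNOSEQ_COLUMN_MAP = {"cdr3b": "amino_acid", "v_gene": "v_gene", "j_gene": "j_gene"}


def read_typing_table(path) -> dict[str, frozenset]:
    """Donor HLA typing from a 2-column TSV (donor_id, comma-separated alleles).

    C-locus (and any non-A/B) alleles are discarded with a logged count.
    """
    typing: dict[str, frozenset] = {}
    n_dropped = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "donor_id":
                continue
            donor, alleles_raw = row[0], row[1]
            alleles = set()
            for tok in alleles_raw.split(","):
                tok = tok.strip()
                if not tok:
                    continue
                allele = normalize_hla(tok)
                if allele.in_binding_scope:
                    alleles.add(allele)
                else:
                    n_dropped += 1
            typing[donor] = frozenset(alleles)
    if n_dropped:
        logger.warning("discarded %d non-A/B alleles from typing table", n_dropped)
    return typing


def read_repertoire(
    path,
    hla_typing_path,
    column_map: Optional[dict] = None,
    donor_column: str = "repertoire_id",
    catalog: Optional[FrequencyCatalog] = None,
) -> list[DonorRepertoire]:
    """Read an AIRR-style rearrangement TSV grouped per donor.

    ``column_map`` maps the logical names {cdr3b, v_gene, j_gene} to the file's
    columns (default AIRR names). Every donor in the rearrangement file must
    appear in the typing table, else ``RecordError("missing_typing")``.
    """
    cmap = dict(AIRR_COLUMN_MAP if column_map is None else column_map)
    typing = read_typing_table(hla_typing_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    donors: dict[str, DonorRepertoire] = {}
    n_bad = 0
    for _, row in df.iterrows():
        donor_id = row[donor_column]
        if donor_id not in typing:
            raise RecordError("missing_typing", donor_id)
        if donor_id not in donors:
            donors[donor_id] = DonorRepertoire(donor_id=donor_id, hla_set=typing[donor_id])
        try:
            comp = str(row["compartment"]).upper() if "compartment" in df.columns else "unknown"
            if comp not in ("CD4", "CD8"):
                comp = "unknown"
            tcr = TCRBeta(
                cdr3b=str(row[cmap["cdr3b"]]).strip().upper(),
                v_gene=normalize_v_gene(str(row[cmap["v_gene"]]), catalog),
                j_gene=normalize_j_gene(str(row[cmap["j_gene"]])),
                compartment=comp,
            )
        except RecordError:
            n_bad += 1
            continue
        donors[donor_id].tcrs.append(tcr)
    if n_bad:
        logger.warning("dropped %d unparseable rearrangement rows", n_bad)
    return list(donors.values())


def write_repertoire(donors: Sequence[DonorRepertoire], path, typing_path) -> None:
    """Write donors back to the AIRR-style TSV + typing-table pair."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["repertoire_id", "junction_aa", "v_call", "j_call", "compartment"])
        for d in donors:
            for t in d.tcrs:
                w.writerow([d.donor_id, t.cdr3b, t.v_gene, t.j_gene, t.compartment])
    with open(typing_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["donor_id", "alleles"])
        for d in donors:
            w.writerow([d.donor_id, ",".join(sorted(h.name for h in d.hla_set))])


def write_pairs(pairs: Sequence[PairExample], path) -> None:
    """Canonical pair CSV consumed by all other modules."""
    pd.DataFrame(
        {
            "cdr3b": [p.tcr.cdr3b for p in pairs],
            "v_gene": [p.tcr.v_gene for p in pairs],
            "j_gene": [p.tcr.j_gene for p in pairs],
            "hla": [p.hla.name for p in pairs],
            "label": [p.label for p in pairs],
            "donor": [p.donor or "" for p in pairs],
        }
    ).to_csv(path, index=False)


def read_pairs(path) -> list[PairExample]:
    """Read the canonical pair CSV back into PairExample records."""
    df = pd.read_csv(path, dtype={"label": int}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            PairExample(
                tcr=TCRBeta(cdr3b=row["cdr3b"], v_gene=row["v_gene"], j_gene=row["j_gene"]),
                hla=normalize_hla(row["hla"]),
                label=int(row["label"]),
                donor=row["donor"] or None,
            )
        )
    return out
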