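"""Parsing of variant and alignment inputs and projection onto domain models.

Somatic variants are observed in protein coordinates (one gene, one
residue); the statistical model operates in domain-model coordinates, where
the aligned positions of every gene carrying the same domain family are
pooled.  This module reads TCGA-dialect MAF tables, protein FASTA, and
protein-to-domain-model alignments, chooses one representative protein per
gene, and projects each variant onto 1-based match-state positions of the
domain model.  Variants falling on insert (gap) columns are assigned to the
last match state before the gap.
"""

from __future__ import annotations

import gzip
import re
import warnings
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Classification",
    "Validation",
    "Source",
    "ProteinRecord",
    "VariantRecord",
    "DomainHit",
    "DomainProjection",
    "PositionCounts",
    "SkipReport",
    "MafFormatError",
    "read_fasta",
    "read_maf",
    "read_dat",
    "write_dat",
    "stockholm_to_dat",
    "select_representatives",
    "project_variant",
    "build_position_counts",
    "POOLED",
]

POOLED = "POOLED"

DEFAULT_EVALUE_MAX = 0.001

# Amino-acid alphabet; 'X' (unknown) and 'U' (selenocysteine) tolerated on input.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = set(AA20) | {"X", "U"}


class Classification(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    silent = "silent"
    other = "other"


class Validation(str, Enum):
    validated = "validated"
    unvalidated = "unvalidated"
    unknown = "unknown"


class Source(str, Enum):
    swissprot = "swissprot"
    refseq = "refseq"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    source: Source
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: unexpected residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    gene_id: str
    patient_id: str
    cancer_type: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    classification: Classification
    validation: Validation
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")


#: marker for an alignment column that consumes a protein residue but no
#: model position (an insert state)
INSERT = None


@dataclass(frozen=True)
class DomainHit:
    """One protein-to-domain-model alignment.

    The per-residue structure is carried by ``state_string``, a string over
    {M, I, D} read left to right: M consumes one protein residue and one
    model position, I consumes one protein residue only, D consumes one
    model position only.
    """

    protein_id: str
    domain_acc: str
    model_length: int
    evalue: float
    protein_start: int
    model_start: int
    state_string: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if set(self.state_string) - set("MID"):
            raise ValueError("state_string must be over {M, I, D}")
        if self.model_start < 1 or self.protein_start < 1:
            raise ValueError("protein_start and model_start are 1-based")
        m_end = self.model_start - 1 + sum(c != "I" for c in self.state_string)
        if m_end > self.model_length:
            raise ValueError(
                f"alignment consumes model positions up to {m_end} "
                f"but model_length is {self.model_length}"
            )

    @property
    def columns(self) -> list[tuple[int, int | None]]:
        """Ordered (protein_pos, model_pos-or-INSERT) pairs, residue-consuming
        columns only (D states consume no residue and emit no column)."""
        out: list[tuple[int, int | None]] = []
        p = self.protein_start
        m = self.model_start
        for c in self.state_string:
            if c == "M":
                out.append((p, m))
                p += 1
                m += 1
            elif c == "I":
                out.append((p, INSERT))
                p += 1
            else:  # D
                m += 1
        return out

    @property
    def protein_end(self) -> int:
        """Last protein residue consumed by the alignment (closed interval)."""
        return self.protein_start - 1 + sum(c != "D" for c in self.state_string)

    def match_map(self) -> dict[int, int]:
        """model_pos -> protein_pos for match states only."""
        return {m: p for p, m in self.columns if m is not INSERT}


@dataclass(frozen=True)
class DomainProjection:
    variant: VariantRecord
    domain_acc: str
    model_pos: int
    via_gap: bool


@dataclass
class PositionCounts:
    """Aggregated mutation counts per model position for one (family, cancer type)."""

    domain_acc: str
    cancer_type: str
    counts: np.ndarray  # length model_length, dtype int

    @property
    def model_length(self) -> int:
        return len(self.counts)

    @property
    def histogram(self) -> dict[int, int]:
        """n_j: number of model positions carrying exactly j variants."""
        bc = np.bincount(self.counts)
        return {j: int(n) for j, n in enumerate(bc) if n > 0}


@dataclass
class SkipReport:
    """Row/variant accounting for one read or projection pass."""

    rows_read: int = 0
    failed_validation: int = 0
    class_filtered: int = 0
    no_position: int = 0
    duplicates: int = 0
    retained: int = 0
    # projection-stage tallies
    not_representative: int = 0
    outside_hits: int = 0
    before_first_match: int = 0
    projected: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


class MafFormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# FASTA


def _default_header_parser(header: str) -> tuple[str, Source, str]:
    """Parse ``protein_id|source|gene_id`` headers (the package's fixture
    dialect) plus common Swiss-Prot (``sp|ACC|NAME GN=GENE``) and RefSeq
    (``NP_...``) styles."""
    parts = header.split("|")
    if len(parts) == 3 and parts[1] in ("swissprot", "refseq"):
        return parts[0], Source(parts[1]), parts[2]
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        gene = parts[2].split()[0]
        m = re.search(r"GN=(\S+)", header)
        if m:
            gene = m.group(1)
        return parts[1], Source.swissprot, gene
    first = header.split()[0]
    if re.match(r"[NXY]P_\d+", first):
        m = re.search(r"GN=(\S+)", header)
        gene = m.group(1) if m else first
        return first, Source.refseq, gene
    raise ValueError(f"cannot parse FASTA header: {header!r}")


def read_fasta(path, header_parser=_default_header_parser) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid, source, gene = header_parser(rec.description)
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    gene_id=gene,
                    source=source,
                    sequence=str(rec.seq).upper(),
                )
            )
    return records


# --------------------------------------------------------------------------
# MAF

# column aliases resolved case-insensitively; first present alias wins
MAF_ALIASES: dict[str, tuple[str, ...]] = {
    "gene": ("hugo_symbol", "gene", "gene_symbol"),
    "patient": ("tumor_sample_barcode", "patient_id", "sample_barcode"),
    "classification": ("variant_classification",),
    "validation": ("validation_status",),
    "protein_change": ("protein_change", "hgvsp_short", "amino_acid_change"),
    "protein_pos": ("protein_position", "amino_acid_position"),
    "cancer_type": ("cancer_type", "tumor_type", "study"),
}

_CLASS_MAP = {
    "missense_mutation": Classification.missense,
    "missense": Classification.missense,
    "nonsense_mutation": Classification.nonsense,
    "nonsense": Classification.nonsense,
    "nonstop_mutation": Classification.other,
    "silent": Classification.silent,
    "synonymous": Classification.silent,
}

_HGVSP_RE = re.compile(r"^p\.\(?([A-Za-z*]{1,3})(\d+)([A-Za-z*]{1,3})\)?$")

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}


def parse_protein_change(change: str) -> tuple[int, str, str] | None:
    """Parse an HGVS-p short- or long-form substitution like ``p.V600E`` or
    ``p.Val600Glu`` into (protein_pos, ref_aa, alt_aa); None if unparseable."""
    if not isinstance(change, str):
        return None
    m = _HGVSP_RE.match(change.strip())
    if not m:
        return None
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if len(ref) == 3:
        ref = _AA3TO1.get(ref, "")
    if len(alt) == 3:
        alt = _AA3TO1.get(alt, "")
    if len(ref) != 1 or len(alt) != 1:
        return None
    return pos, ref.upper(), alt.upper()


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for key, aliases in MAF_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
    return resolved


def read_maf(
    path,
    require_validated: bool = True,
    classes: set[Classification] | None = None,
    cancer_type: str | None = None,
) -> tuple[list[VariantRecord], SkipReport]:
    """Read a tab-separated MAF, filter, parse protein positions, deduplicate.

    Only variants whose classification is in ``classes`` (default: missense
    only) are retained; with ``require_validated`` only rows whose validation
    status is Valid/Validated pass.  Duplicate events (same gene, patient,
    protein position and alternate residue) collapse to one.  ``cancer_type``
    supplies the study code when the MAF carries no such column.
    """
    if classes is None:
        classes = {Classification.missense}
    report = SkipReport()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)
    for mandatory in ("gene", "patient", "classification", "validation"):
        if mandatory not in cols:
            raise MafFormatError(
                f"{path}: no column found for {mandatory!r} "
                f"(aliases tried: {MAF_ALIASES[mandatory]})"
            )
    if "protein_change" not in cols and "protein_pos" not in cols:
        raise MafFormatError(
            f"{path}: no protein-change or protein-position column found"
        )

    report.rows_read = len(df)
    records: list[VariantRecord] = []
    seen: set[tuple[str, str, int, str]] = set()
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        vstat = row_d[cols["validation"]].strip().lower()
        validation = (
            Validation.validated
            if vstat in ("valid", "validated")
            else Validation.unknown
            if vstat in ("unknown", "")
            else Validation.unvalidated
        )
        if require_validated and validation is not Validation.validated:
            report.failed_validation += 1
            continue
        cls = _CLASS_MAP.get(
            row_d[cols["classification"]].strip().lower(), Classification.other
        )
        if cls not in classes:
            report.class_filtered += 1
            continue
        pos = ref = alt = None
        if "protein_change" in cols:
            parsed = parse_protein_change(row_d[cols["protein_change"]])
            if parsed:
                pos, ref, alt = parsed
        if pos is None and "protein_pos" in cols:
            raw = row_d[cols["protein_pos"]].strip()
            if raw.isdigit() and int(raw) >= 1:
                pos, ref, alt = int(raw), "X", "X"
        if pos is None:
            report.no_position += 1
            continue
        gene = row_d[cols["gene"]].strip()
        patient = row_d[cols["patient"]].strip()
        ctype = (
            row_d[cols["cancer_type"]].strip()
            if "cancer_type" in cols
            else (cancer_type or "UNKNOWN")
        )
        key = (gene, patient, pos, alt)
        if key in seen:
            report.duplicates += 1
            continue
        seen.add(key)
        records.append(
            VariantRecord(
                gene_id=gene,
                patient_id=patient,
                cancer_type=ctype,
                protein_pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                classification=cls,
                validation=validation,
            )
        )
    report.retained = len(records)
    if report.rows_read > 0 and not records:
        warnings.warn(f"{path}: no variants retained after filtering")
    return records, report


# --------------------------------------------------------------------------
# Alignments: DAT (canonical) and Stockholm conversion

DAT_COLUMNS = [
    "protein_id",
    "domain_acc",
    "model_length",
    "evalue",
    "protein_start",
    "model_start",
    "state_string",
]


def read_dat(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(DAT_COLUMNS) - set(df.columns)
    if missing:
        raise MafFormatError(f"{path}: DAT table missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        hits.append(
            DomainHit(
                protein_id=d["protein_id"],
                domain_acc=d["domain_acc"],
                model_length=int(d["model_length"]),
                evalue=float(d["evalue"]),
                protein_start=int(d["protein_start"]),
                model_start=int(d["model_start"]),
                state_string=d["state_string"],
            )
        )
    return hits


def write_dat(hits: Iterable[DomainHit], path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "domain_acc": h.domain_acc,
            "model_length": h.model_length,
            "evalue": f"{h.evalue:.3g}",
            "protein_start": h.protein_start,
            "model_start": h.model_start,
            "state_string": h.state_string,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=DAT_COLUMNS).to_csv(path, sep="\t", index=False)


def stockholm_to_dat(
    path, domain_acc: str, evalue: float = 0.0, model_length: int | None = None
) -> list[DomainHit]:
    """Convert a Stockholm alignment with an ``#=GC RF`` reference line into
    DomainHit records.

    Match columns are the RF positions that carry a non-gap character
    (HMMER writes ``x`` for match states and ``.`` for insert columns;
    Pfam RF lines may carry consensus letters instead).  Sequence names of
    the form ``id/start-end`` supply the protein start coordinate;
    otherwise the alignment is assumed to begin at residue 1.
    """
    from Bio import AlignIO

    aln = AlignIO.read(path, "stockholm")
    rf = aln.column_annotations.get("reference_annotation")
    if rf is None:
        raise MafFormatError(f"{path}: Stockholm file lacks a #=GC RF line")
    is_match = [c not in ".-~" for c in rf]
    n_match = sum(is_match)
    if model_length is None:
        model_length = n_match
    hits = []
    for rec in aln:
        name = rec.id
        protein_start = 1
        m = re.match(r"(.+)/(\d+)-(\d+)$", name)
        if m:
            name, protein_start = m.group(1), int(m.group(2))
        states = []
        for col, match in zip(str(rec.seq), is_match):
            gap = col in ".-"
            if match:
                states.append("D" if gap else "M")
            elif not gap:
                states.append("I")
        state_string = "".join(states).strip("I") or "M"
        # inserts outside the first/last match state are not part of the hit
        hits.append(
            DomainHit(
                protein_id=name,
                domain_acc=domain_acc,
                model_length=model_length,
                evalue=evalue,
                protein_start=protein_start,
                model_start=1,
                state_string=state_string,
            )
        )
    return hits


# --------------------------------------------------------------------------
# Representative selection and projection


def select_representatives(
    proteins: Sequence[ProteinRecord],
) -> dict[str, str]:
    """One representative protein per gene: any Swiss-Prot entry beats any
    RefSeq entry; within a source the longest wins (protein_id breaks ties
    deterministically)."""
    best: dict[str, ProteinRecord] = {}
    for p in proteins:
        cur = best.get(p.gene_id)
        if cur is None:
            best[p.gene_id] = p
            continue
        rank = (p.source is Source.swissprot, p.length, p.protein_id)
        cur_rank = (cur.source is Source.swissprot, cur.length, cur.protein_id)
        if rank > cur_rank:
            best[p.gene_id] = p
    return {g: p.protein_id for g, p in best.items()}


def project_variant(
    variant: VariantRecord,
    hit: DomainHit,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> DomainProjection | None:
    """Project a protein-coordinate variant onto the hit's model coordinates.

    A residue on a match column maps to that model position; a residue on an
    insert column maps to the last match state before the gap (via_gap=True);
    a residue before the first match column, or outside the hit's residue
    span, does not project (returns None).
    """
    if hit.evalue > evalue_max:
        return None
    if variant.protein_id is not None and variant.protein_id != hit.protein_id:
        raise ValueError("variant and hit refer to different proteins")
    pos = variant.protein_pos
    if pos < hit.protein_start or pos > hit.protein_end:
        return None
    match_pp: list[int] = []  # protein positions of match columns, ascending
    match_mp: list[int] = []
    p = hit.protein_start
    m = hit.model_start
    for c in hit.state_string:
        if c == "M":
            match_pp.append(p)
            match_mp.append(m)
            p += 1
            m += 1
        elif c == "I":
            p += 1
        else:
            m += 1
    i = bisect_right(match_pp, pos) - 1
    if i < 0:
        return None  # insert run before the first match state
    if match_pp[i] == pos:
        return DomainProjection(variant, hit.domain_acc, match_mp[i], via_gap=False)
    return DomainProjection(variant, hit.domain_acc, match_mp[i], via_gap=True)


def build_position_counts(
    variants: Sequence[VariantRecord],
    hits: Sequence[DomainHit],
    representatives: Mapping[str, str],
    group_by_cancer: bool = True,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[dict[tuple[str, str], PositionCounts], SkipReport]:
    """Aggregate variants into per-(family, cancer type) count vectors.

    Each variant contributes once to every domain *family* whose alignment
    covers it; overlapping hits of the same family on one protein are
    resolved to the single hit with the smallest E-value (ties: leftmost
    envelope start) so no event is double counted within a family.
    """
    report = SkipReport()
    report.rows_read = len(variants)
    gene_of_protein = {pid: g for g, pid in representatives.items()}
    hits_by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    model_len: dict[str, int] = {}
    for h in hits:
        if h.evalue > evalue_max:
            continue
        hits_by_protein[h.protein_id].append(h)
        prev = model_len.setdefault(h.domain_acc, h.model_length)
        if prev != h.model_length:
            raise ValueError(
                f"inconsistent model_length for {h.domain_acc}: {prev} vs {h.model_length}"
            )

    counts: dict[tuple[str, str], np.ndarray] = {}
    for v in variants:
        rep = representatives.get(v.gene_id)
        if rep is None or (v.protein_id is not None and v.protein_id != rep):
            report.not_representative += 1
            continue
        v_resolved = v if v.protein_id == rep else VariantRecord(
            gene_id=v.gene_id,
            patient_id=v.patient_id,
            cancer_type=v.cancer_type,
            protein_pos=v.protein_pos,
            ref_aa=v.ref_aa,
            alt_aa=v.alt_aa,
            classification=v.classification,
            validation=v.validation,
            protein_id=rep,
        )
        covering: dict[str, list[DomainHit]] = defaultdict(list)
        for h in hits_by_protein.get(rep, ()):
            if h.protein_start <= v.protein_pos <= h.protein_end:
                covering[h.domain_acc].append(h)
        if not covering:
            report.outside_hits += 1
            continue
        landed = False
        for acc, fam_hits in covering.items():
            best = min(fam_hits, key=lambda h: (h.evalue, h.protein_start))
            proj = project_variant(v_resolved, best, evalue_max)
            if proj is None:
                continue
            ctype = v.cancer_type if group_by_cancer else POOLED
            key = (acc, ctype)
            if key not in counts:
                counts[key] = np.zeros(model_len[acc], dtype=int)
            counts[key][proj.model_pos - 1] += 1
            landed = True
        if landed:
            report.projected += 1
        else:
            report.before_first_match += 1
    report.retained = report.projected
    out = {
        key: PositionCounts(domain_acc=key[0], cancer_type=key[1], counts=vec)
        for key, vec in sorted(counts.items())
    }
    return out, report
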