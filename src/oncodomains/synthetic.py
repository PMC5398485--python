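"""Seeded synthetic domain families, alignments, and MAFs with planted hotspots.

Every stage of the pipeline is testable without controlled-access tumor data:
``make_family`` emits a protein family with known insert/delete structure
(FASTA + alignment table), and ``plant_variants`` draws per-position
mutation counts from the null Zero-Inflated Poisson at background positions
and from an elevated-rate Poisson at designated signal positions, then
scatters the events over member genes and synthetic patients and writes MAF
rows whose protein coordinates invert the alignment map exactly.  A truth
table records the planted signal positions.

The defaults mirror the background regime the statistical model assumes for
aggregated per-position counts: zero-inflation 0.3, null rate 0.5, signal
rate 8 — sparse counts at almost all positions with a handful of strongly
recurrent ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_mapping import AA20, DomainHit, ProteinRecord, Source

__all__ = [
    "FamilySpec",
    "PlantSpec",
    "make_family",
    "plant_variants",
    "write_family",
    "write_maf",
    "write_truth",
]

MAF_HEADER = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Cancer_Type",
    "Variant_Classification",
    "Validation_Status",
    "Protein_Change",
]


@dataclass(frozen=True)
class FamilySpec:
    domain_acc: str = "synd00001"
    model_length: int = 200
    n_genes: int = 4
    envelope_offsets: tuple[int, ...] | None = None  # N-terminal flank per gene
    insert_rate: float = 0.02
    delete_rate: float = 0.02
    substitution_rate: float = 0.3  # divergence from the family consensus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_length < 1 or self.n_genes < 1:
            raise ValueError("model_length and n_genes must be >= 1")
        if self.envelope_offsets is not None and len(self.envelope_offsets) != self.n_genes:
            raise ValueError("envelope_offsets must list one offset per gene")


@dataclass(frozen=True)
class PlantSpec:
    pi_zero: float = 0.3
    lam0: float = 0.5
    signal_positions: frozenset[int] = frozenset()
    lam1: float = 8.0
    min_signal_count: int = 0  # condition signal draws on >= this count
    n_patients: int = 200
    cancer_type: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lam1 > self.lam0:
            raise ValueError("signal rate lam1 must exceed null rate lam0")
        if not 0 <= self.pi_zero <= 1:
            raise ValueError("pi_zero must be in [0, 1]")


def make_family(spec: FamilySpec) -> tuple[list[ProteinRecord], list[DomainHit]]:
    """Generate a seeded protein family with per-gene insert/delete structure.

    Sequences diverge from a common consensus at ``substitution_rate``;
    deletions drop a match column (D), inserts add residues between match
    columns (I).  Regeneration from the same spec is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AA20))
    consensus = rng.choice(aa, size=spec.model_length)
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    for g in range(spec.n_genes):
        gene_id = f"{spec.domain_acc.upper()}G{g + 1:02d}"
        protein_id = f"SYNP_{spec.domain_acc}_{g + 1:02d}"
        source = Source.swissprot if g % 2 == 0 else Source.refseq
        offset = (
            spec.envelope_offsets[g]
            if spec.envelope_offsets is not None
            else int(rng.integers(0, 21))
        )
        states: list[str] = []
        residues: list[str] = []
        for m in range(spec.model_length):
            if rng.random() < spec.delete_rate:
                states.append("D")
                continue
            states.append("M")
            if rng.random() < spec.substitution_rate:
                residues.append(str(rng.choice(aa)))
            else:
                residues.append(str(consensus[m]))
            if m < spec.model_length - 1 and rng.random() < spec.insert_rate:
                for _ in range(int(rng.geometric(0.5))):
                    states.append("I")
                    residues.append(str(rng.choice(aa)))
        if "M" not in states:
            raise ValueError(
                f"spec produced an empty alignment for gene {gene_id}; lower delete_rate"
            )
        flank_n = "".join(rng.choice(aa, size=offset))
        sequence = flank_n + "".join(residues)
        evalue = float(10.0 ** rng.uniform(-12, -4))
        proteins.append(
            ProteinRecord(
                protein_id=protein_id, gene_id=gene_id, source=source, sequence=sequence
            )
        )
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_acc=spec.domain_acc,
                model_length=spec.model_length,
                evalue=evalue,
                protein_start=offset + 1,
                model_start=1,
                state_string="".join(states),
            )
        )
    return proteins, hits


def plant_variants(
    proteins: list[ProteinRecord],
    hits: list[DomainHit],
    plant: PlantSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-position counts from the null/signal mixture and emit MAF rows.

    Null positions draw from ZIP(pi_zero, lam0), signal positions from
    Poisson(lam1).  Each event picks a uniformly random member gene whose
    alignment has the position as a match state, a random patient, and an
    alternate residue; (gene, patient, position, alt) tuples are kept unique
    so MAF deduplication preserves every planted event.  Returns the MAF
    frame and a truth frame (domain_acc, model_pos, is_signal).
    """
    if not hits:
        raise ValueError("family has no alignments")
    acc = hits[0].domain_acc
    L = hits[0].model_length
    bad_signal = [p for p in plant.signal_positions if not 1 <= p <= L]
    if bad_signal:
        raise ValueError(f"signal positions outside [1, {L}]: {sorted(bad_signal)}")
    seq_of = {p.protein_id: p for p in proteins}
    # model_pos -> list of (gene_id, protein_pos, ref_aa)
    reachable: dict[int, list[tuple[str, int, str]]] = {m: [] for m in range(1, L + 1)}
    for h in hits:
        prot = seq_of[h.protein_id]
        for m, p in h.match_map().items():
            reachable[m].append((prot.gene_id, p, prot.sequence[p - 1]))
    dead_signal = sorted(p for p in plant.signal_positions if not reachable[p])
    if dead_signal:
        raise ValueError(
            f"signal positions deleted in every member gene: {dead_signal}"
        )

    rng = np.random.default_rng(plant.seed)
    alphabet = list(AA20)
    rows = []
    used: set[tuple[str, str, int, str]] = set()
    for m in range(1, L + 1):
        if m in plant.signal_positions:
            # truncated Poisson: exact-recovery fixtures require planted
            # positions to carry unambiguously elevated counts
            k = int(rng.poisson(plant.lam1))
            while k < plant.min_signal_count:
                k = int(rng.poisson(plant.lam1))
        elif rng.random() < plant.pi_zero:
            k = 0
        else:
            k = int(rng.poisson(plant.lam0))
        if k == 0 or not reachable[m]:
            continue
        options = reachable[m]
        for _ in range(k):
            gene, ppos, ref = options[int(rng.integers(len(options)))]
            alts = [a for a in alphabet if a != ref]
            # keep the dedup key unique so every event survives MAF reading
            for _attempt in range(10 * plant.n_patients):
                patient = f"SYN-{plant.cancer_type}-{int(rng.integers(plant.n_patients)) + 1:04d}"
                alt = alts[int(rng.integers(len(alts)))]
                key = (gene, patient, ppos, alt)
                if key not in used:
                    used.add(key)
                    break
            else:
                raise RuntimeError("could not place event without duplicating; raise n_patients")
            rows.append(
                {
                    "Hugo_Symbol": gene,
                    "Tumor_Sample_Barcode": patient,
                    "Cancer_Type": plant.cancer_type,
                    "Variant_Classification": "Missense_Mutation",
                    "Validation_Status": "Valid",
                    "Protein_Change": f"p.{ref}{ppos}{alt}",
                }
            )
    maf = pd.DataFrame(rows, columns=MAF_HEADER)
    truth = pd.DataFrame(
        {
            "domain_acc": acc,
            "model_pos": np.arange(1, L + 1),
            "is_signal": [int(m in plant.signal_positions) for m in range(1, L + 1)],
        }
    )
    return maf, truth


# --------------------------------------------------------------------------
# Writers (bit-deterministic, 60-column FASTA)


def write_family(
    proteins: list[ProteinRecord], hits: list[DomainHit], fasta_path, dat_path
) -> None:
    from .domain_mapping import write_dat

    with open(fasta_path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}|{p.source.value}|{p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    write_dat(hits, dat_path)


def write_maf(maf: pd.DataFrame, path) -> None:
    maf.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
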