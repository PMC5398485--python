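"""Alignment-column conservation scoring and hotspot overlap/enrichment tests.

Conservation of a domain-model position is measured by the Shannon entropy
of the amino-acid frequencies in that alignment column,

    H_j = - sum_i p(a_i, j) ln p(a_i, j),

gaps excluded.  A position is flagged conserved when its conservation score
C_j = -H_j is at least one standard deviation above the domain's mean score
(equivalently H_j <= mean(H) - sd(H)).  Overlap between hotspot positions
and conserved or annotated positions is assessed by Fisher's exact test
with Bonferroni correction, plus a Pearson (point-biserial) correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain_mapping import (
    AA20,
    Classification,
    DomainHit,
    ProteinRecord,
    Validation,
    VariantRecord,
    project_variant,
)

__all__ = [
    "ColumnProfile",
    "ConservationProfile",
    "ContingencyTable",
    "build_column_profiles",
    "column_entropy",
    "flag_conserved",
    "conservation_profile",
    "fisher_overlap",
    "bonferroni",
    "point_biserial",
    "term_enrichment",
    "read_feature_table",
    "project_features",
]


@dataclass
class ColumnProfile:
    model_pos: int
    aa_freq: dict[str, float]
    n_residues: int


@dataclass
class ConservationProfile:
    """Per-position entropy H_j, score C_j = -H_j, and conserved flags for
    one domain family.  Positions with fewer than two observed residues have
    undefined entropy (NaN) and are excluded from the mean/sd."""

    domain_acc: str
    entropy: np.ndarray  # NaN where undefined
    conserved: np.ndarray  # bool

    @property
    def score(self) -> np.ndarray:
        return -self.entropy


def build_column_profiles(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    domain_acc: str,
) -> list[ColumnProfile]:
    """Stack the match-state residues of every hit of one family into
    per-model-position amino-acid frequency profiles (gaps excluded)."""
    seq_of = {p.protein_id: p.sequence for p in proteins}
    model_length = None
    tallies: dict[int, dict[str, int]] = {}
    for h in hits:
        if h.domain_acc != domain_acc or h.protein_id not in seq_of:
            continue
        model_length = h.model_length
        seq = seq_of[h.protein_id]
        for m, p in h.match_map().items():
            aa = seq[p - 1].upper()
            if aa not in AA20:
                continue  # X/U carry no conservation information
            tallies.setdefault(m, {})[aa] = tallies.setdefault(m, {}).get(aa, 0) + 1
    if model_length is None:
        return []
    profiles = []
    for m in range(1, model_length + 1):
        tally = tallies.get(m, {})
        n = sum(tally.values())
        freq = {aa: c / n for aa, c in tally.items()} if n else {}
        profiles.append(ColumnProfile(model_pos=m, aa_freq=freq, n_residues=n))
    return profiles


def column_entropy(profile: ColumnProfile) -> float:
    """Shannon entropy of one alignment column; 0*ln(0) is taken as 0.
    Result lies in [0, ln 20]. Raises on an empty column."""
    if profile.n_residues < 1:
        raise ValueError(f"column {profile.model_pos} has no observed residues")
    h = -sum(p * math.log(p) for p in profile.aa_freq.values() if p > 0)
    return max(h, 0.0)  # clip -0.0 from rounding


def flag_conserved(entropies: Sequence[float] | np.ndarray) -> np.ndarray:
    """Conserved flags from per-position entropies (NaN = undefined column).

    Score C_j = -H_j; flag iff C_j >= mean(C) + sd(C) over defined columns
    (ties at the threshold are conserved).  Degenerate domains with sd = 0
    flag nothing — there every position would trivially pass — and warn.
    """
    h = np.asarray(entropies, dtype=float)
    flags = np.zeros(h.shape, dtype=bool)
    defined = np.isfinite(h)
    if defined.sum() < 2:
        warnings.warn("fewer than 2 defined columns; no conservation flags")
        return flags
    c = -h[defined]
    sd = float(c.std(ddof=0))
    if sd == 0.0:
        warnings.warn("all defined columns share one entropy; no position flagged")
        return flags
    threshold = float(c.mean()) + sd
    flags[defined] = c >= threshold
    return flags


def conservation_profile(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    domain_acc: str,
) -> ConservationProfile:
    profiles = build_column_profiles(proteins, hits, domain_acc)
    h = np.array(
        [
            column_entropy(p) if p.n_residues >= 2 else np.nan
            for p in profiles
        ]
    )
    return ConservationProfile(
        domain_acc=domain_acc, entropy=h, conserved=flag_conserved(h)
    )


@dataclass
class ContingencyTable:
    """2x2 table (hit yes/no x annotated yes/no) with Fisher's exact test.

    The odds ratio uses the Haldane-Anscombe +0.5 correction when any cell
    is zero (for reporting only; the exact test uses the raw counts)."""

    table: np.ndarray
    odds_ratio: float
    p_raw: float
    p_adjusted: float = float("nan")


def fisher_overlap(x: Sequence[int], y: Sequence[int]) -> ContingencyTable:
    """Two-sided Fisher's exact test of association between two equal-length
    binary vectors over the same position universe.  Zero-margin tables
    return p = 1 by convention."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must share one position universe")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    table = np.array([[a, b], [c, d]])
    if min(a + b, c + d, a + c, b + d) == 0:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    if 0 in (a, b, c, d):
        oa, ob, oc, od = (v + 0.5 for v in (a, b, c, d))
    else:
        oa, ob, oc, od = a, b, c, d
    return ContingencyTable(
        table=table, odds_ratio=(oa * od) / (ob * oc), p_raw=float(p)
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, m*p); m defaults to the number of tests
    and must not be smaller than it."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of tests ({p.size})")
    return np.minimum(1.0, m * p)


def point_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between a binary indicator and a
    second (binary or real) vector; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def term_enrichment(
    member_sets: Mapping[str, Iterable[str]],
    hit_set: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-term Fisher enrichment of the hit set within the universe,
    Bonferroni-corrected over the number of terms actually tested.

    Terms with no member inside the universe are skipped.  Returns a frame
    sorted by adjusted p: term, n_term, n_hit_term, odds_ratio, p_raw,
    p_adjusted.
    """
    universe = set(universe)
    hit_set = set(hit_set)
    if not hit_set <= universe:
        raise ValueError("hit_set must be a subset of the universe")
    order = sorted(universe)
    in_hit = np.array([g in hit_set for g in order])
    rows = []
    for term in sorted(member_sets):
        members = set(member_sets[term]) & universe
        if not members:
            continue
        in_term = np.array([g in members for g in order])
        ct = fisher_overlap(in_hit, in_term)
        rows.append(
            {
                "term": term,
                "n_term": len(members),
                "n_hit_term": int((in_hit & in_term).sum()),
                "odds_ratio": ct.odds_ratio,
                "p_raw": ct.p_raw,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "n_term", "n_hit_term", "odds_ratio", "p_raw"]
    )
    if len(df):
        df["p_adjusted"] = bonferroni(df["p_raw"].to_numpy(), len(df))
        df = df.sort_values(["p_adjusted", "term"], kind="stable").reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


# --------------------------------------------------------------------------
# Per-residue feature annotations


def read_feature_table(path) -> pd.DataFrame:
    """Feature annotation TSV: protein_id, residue_pos (1-based), feature_name."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"residue_pos": int})
    missing = {"protein_id", "residue_pos", "feature_name"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    return df


def project_features(
    features: pd.DataFrame,
    hits: Sequence[DomainHit],
    domain_acc: str,
    evalue_max: float = 0.001,
) -> dict[str, np.ndarray]:
    """Project per-protein-residue features onto model positions through the
    alignment (same gap rule as variants).  A model position is annotated
    with a feature when ANY member protein carries that feature at a residue
    aligning there.  Returns feature_name -> boolean vector of length L."""
    fam_hits = [h for h in hits if h.domain_acc == domain_acc]
    if not fam_hits:
        return {}
    model_length = fam_hits[0].model_length
    by_protein: dict[str, list[DomainHit]] = {}
    for h in fam_hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, np.ndarray] = {}
    for row in features.itertuples(index=False):
        for h in by_protein.get(row.protein_id, ()):
            probe = VariantRecord(
                gene_id="", patient_id="", cancer_type="",
                protein_pos=int(row.residue_pos), ref_aa="X", alt_aa="X",
                classification=Classification.other, validation=Validation.unknown,
                protein_id=row.protein_id,
            )
            proj = project_variant(probe, h, evalue_max)
            if proj is not None:
                vec = out.setdefault(
                    row.feature_name, np.zeros(model_length, dtype=bool)
                )
                vec[proj.model_pos - 1] = True
    return out
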