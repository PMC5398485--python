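"""End-to-end orchestration: read inputs, count, fit, call, score, report.

``run_pipeline`` wires the stages together for one run configuration and
writes TSV outputs (hotspot calls, per-cancer-type summaries, fit
diagnostics, conservation profiles, enrichment tables) plus a
machine-readable JSON run report.  Every output file starts with one
``#``-prefixed header line carrying the package version, the seed, and a
hash of the configuration, and reruns with the same configuration are
byte-identical.  ``bootstrap`` measures call stability by subsampling a
fraction of patients (or of variant events) without replacement and
repeating the count/fit/call stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domain_mapping import (
    Classification,
    PositionCounts,
    VariantRecord,
    build_position_counts,
    read_dat,
    read_fasta,
    read_maf,
    select_representatives,
)
from .hotspot_stats import (
    FitConfig,
    HotspotCall,
    call_hotspots,
    fit_null_mixture,
    summarize,
    summary_frame,
)
from .conservation import (
    bonferroni,
    conservation_profile,
    fisher_overlap,
    project_features,
    read_feature_table,
    term_enrichment,
)

log = logging.getLogger("oncodomains")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "bootstrap"]


@dataclass
class RunConfig:
    maf: list[str] = field(default_factory=list)
    fasta: str | None = None
    alignments: str | None = None  # DAT table
    features: str | None = None  # per-residue feature annotation TSV
    terms: str | None = None  # term_id, term_name, member_id TSV
    outdir: str = "oncodomains_out"
    evalue_max: float = 0.001
    cutoffs: tuple[float, ...] = (0.05, 0.01)
    classes: tuple[str, ...] = ("missense",)
    require_validated: bool = True
    min_positions: int = 10
    pooled: bool = False
    bootstrap_fractions: tuple[float, ...] = (0.75, 0.5)
    bootstrap_unit: str = "patients"  # or "variants"
    bootstrap_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.maf, str):
            self.maf = [self.maf]
        for c in self.cutoffs:
            if not 0 < c < 1:
                raise ValueError(f"cutoff {c} outside (0, 1)")
        for f in self.bootstrap_fractions:
            if not 0 < f <= 1:
                raise ValueError(f"bootstrap fraction {f} outside (0, 1]")
        if self.bootstrap_unit not in ("patients", "variants"):
            raise ValueError("bootstrap_unit must be 'patients' or 'variants'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("cutoffs", "classes", "bootstrap_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    hotspots: pd.DataFrame
    summary: pd.DataFrame
    diagnostics: pd.DataFrame
    conservation: pd.DataFrame
    calls: list[HotspotCall]
    report: dict


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# oncodomains v{__version__} seed={config.seed} config={config.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_inputs(config: RunConfig):
    variants: list[VariantRecord] = []
    reads = {}
    classes = {Classification(c) for c in config.classes}
    for path in config.maf:
        recs, rep = read_maf(
            path, require_validated=config.require_validated, classes=classes
        )
        variants.extend(recs)
        reads[str(path)] = rep.as_dict()
    proteins = read_fasta(config.fasta) if config.fasta else []
    hits = read_dat(config.alignments) if config.alignments else []
    return variants, proteins, hits, reads


def _fit_and_call(
    counts_by_key: dict[tuple[str, str], PositionCounts],
    config: RunConfig,
) -> tuple[list[HotspotCall], pd.DataFrame, list[tuple[str, str]]]:
    fit_cfg = FitConfig(min_positions=config.min_positions)
    primary = max(config.cutoffs)
    calls: list[HotspotCall] = []
    diag_rows = []
    skipped = []
    for key in sorted(counts_by_key):
        pc = counts_by_key[key]
        if pc.model_length < config.min_positions or not (pc.counts > 0).any():
            skipped.append(key)
            continue
        fit = fit_null_mixture(pc, fit_cfg)
        if fit is None:
            skipped.append(key)
            continue
        calls.extend(call_hotspots(pc, fit, cutoff=primary, include_all=True))
        diag_rows.append(
            {
                "domain_acc": pc.domain_acc,
                "cancer_type": pc.cancer_type,
                "pi_zero": fit.pi_zero,
                "lam0": fit.lam0,
                "lam1": fit.lam1,
                "p0": fit.p0,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "degenerate": fit.degenerate,
            }
        )
    return calls, pd.DataFrame(diag_rows), skipped


def _hotspot_frame(calls: Sequence[HotspotCall], cutoffs) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "domain_acc": c.domain_acc,
            "cancer_type": c.cancer_type,
            "model_pos": c.model_pos,
            "count": c.count,
            "fdr_local": c.fdr_local,
            "fdr_tail": c.fdr_tail,
        }
        for cut in sorted(cutoffs, reverse=True):
            row[f"significant_at_{cut}"] = int(c.count >= 1 and c.fdr_local < cut)
        rows.append(row)
    cols = ["domain_acc", "cancer_type", "model_pos", "count", "fdr_local", "fdr_tail"]
    cols += [f"significant_at_{cut}" for cut in sorted(cutoffs, reverse=True)]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run map → fit → call → conserve → enrich and write all outputs."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, proteins, hits, reads = _load_inputs(config)
    log.info("read %d variants, %d proteins, %d alignments", len(variants), len(proteins), len(hits))

    representatives = select_representatives(proteins)
    counts_by_key, proj_report = build_position_counts(
        variants,
        hits,
        representatives,
        group_by_cancer=not config.pooled,
        evalue_max=config.evalue_max,
    )
    log.info("projection: %s", proj_report.as_dict())

    calls, diagnostics, skipped = _fit_and_call(counts_by_key, config)
    hotspots = _hotspot_frame(calls, config.cutoffs)
    summary = summary_frame(summarize(calls, config.cutoffs))
    log.info("called %d significant positions across %d families",
             int(sum(c.significant for c in calls)), len(counts_by_key))

    accs = sorted({acc for acc, _ in counts_by_key})
    cons_rows = []
    for acc in accs:
        prof = conservation_profile(proteins, hits, acc)
        for i, (h, flag) in enumerate(zip(prof.entropy, prof.conserved), start=1):
            cons_rows.append(
                {
                    "domain_acc": acc,
                    "model_pos": i,
                    "entropy": h,
                    "conserved": int(flag),
                }
            )
    conservation = pd.DataFrame(
        cons_rows, columns=["domain_acc", "model_pos", "entropy", "conserved"]
    )

    primary = max(config.cutoffs)
    enrichment_tables = _enrichment(
        config, hits, counts_by_key, calls, conservation, primary
    )

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "maf_reads": reads,
        "projection": proj_report.as_dict(),
        "n_families_analyzed": len(counts_by_key) - len(skipped),
        "n_families_skipped": len(skipped),
        "n_significant": int(sum(c.significant for c in calls)),
    }

    _write_tsv(hotspots, outdir / "hotspots.tsv", config)
    _write_tsv(summary, outdir / "summary.tsv", config)
    _write_tsv(diagnostics, outdir / "fit_diagnostics.tsv", config)
    _write_tsv(conservation, outdir / "conservation.tsv", config)
    for name, table in enrichment_tables.items():
        _write_tsv(table, outdir / f"{name}.tsv", config)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return RunResult(
        hotspots=hotspots,
        summary=summary,
        diagnostics=diagnostics,
        conservation=conservation,
        calls=calls,
        report=report,
    )


def _enrichment(config, hits, counts_by_key, calls, conservation, cutoff):
    """Pooled overlap tests: positions of all analyzed domains form one
    universe; hotspot indicator vs conserved indicator and vs each feature."""
    tables: dict[str, pd.DataFrame] = {}
    sig = {
        (c.domain_acc, c.model_pos)
        for c in calls
        if c.count >= 1 and c.fdr_local < cutoff
    }
    if len(conservation):
        hot_vec = [
            (r.domain_acc, r.model_pos) in sig for r in conservation.itertuples()
        ]
        cons_vec = conservation["conserved"].astype(bool).to_numpy()
        ct = fisher_overlap(hot_vec, cons_vec)
        tables["conservation_overlap"] = pd.DataFrame(
            [
                {
                    "test": "hotspot_vs_conserved",
                    "n_hot_cons": ct.table[0, 0],
                    "odds_ratio": ct.odds_ratio,
                    "p_raw": ct.p_raw,
                }
            ]
        )
    if config.features:
        features = read_feature_table(config.features)
        accs = sorted({acc for acc, _ in counts_by_key})
        rows = []
        hot_all: list[bool] = []
        feat_all: dict[str, list[bool]] = {}
        for acc in accs:
            proj = project_features(features, hits, acc, config.evalue_max)
            L = next(h.model_length for h in hits if h.domain_acc == acc)
            hot = [(acc, m) in sig for m in range(1, L + 1)]
            hot_all.extend(hot)
            for fname in sorted(
                {f for f in features["feature_name"].unique()}
            ):
                vec = proj.get(fname, np.zeros(L, dtype=bool))
                feat_all.setdefault(fname, []).extend(bool(v) for v in vec)
        for fname in sorted(feat_all):
            ct = fisher_overlap(hot_all, feat_all[fname])
            rows.append(
                {
                    "feature_name": fname,
                    "n_annotated": int(np.sum(feat_all[fname])),
                    "odds_ratio": ct.odds_ratio,
                    "p_raw": ct.p_raw,
                }
            )
        df = pd.DataFrame(
            rows, columns=["feature_name", "n_annotated", "odds_ratio", "p_raw"]
        )
        if len(df):
            df["p_adjusted"] = bonferroni(df["p_raw"].to_numpy(), len(df))
            df = df.sort_values(["p_adjusted", "feature_name"], kind="stable").reset_index(drop=True)
        tables["feature_enrichment"] = df
    if config.terms:
        terms = pd.read_csv(config.terms, sep="\t", comment="#", dtype=str)
        member_sets = {
            t: set(g["member_id"]) for t, g in terms.groupby("term_id")
        }
        universe = {acc for acc, _ in counts_by_key}
        hit_set = {acc for acc, _ in sig}
        tables["term_enrichment"] = term_enrichment(
            member_sets, hit_set & universe, universe
        )
    return tables


def bootstrap(config: RunConfig) -> pd.DataFrame:
    """Stability analysis: subsample patients (or variant events) WITHOUT
    replacement at each configured fraction, repeat count/fit/call, and
    tabulate oncodomain and hotspot counts per replicate at the primary
    cutoff.  Deterministic given config.seed."""
    variants, proteins, hits, _ = _load_inputs(config)
    representatives = select_representatives(proteins)
    primary = max(config.cutoffs)
    rows = []
    for fraction in config.bootstrap_fractions:
        for rep in range(config.bootstrap_reps):
            rng = np.random.default_rng([config.seed, rep, int(fraction * 10000)])
            if config.bootstrap_unit == "patients":
                patients = sorted({v.patient_id for v in variants})
                k = int(round(fraction * len(patients)))
                if k == 0:
                    log.warning("fraction %s yields 0 patients; replicate %d skipped", fraction, rep)
                    continue
                keep = set(rng.choice(patients, size=k, replace=False))
                sub = [v for v in variants if v.patient_id in keep]
            else:
                k = int(round(fraction * len(variants)))
                if k == 0:
                    log.warning("fraction %s yields 0 variants; replicate %d skipped", fraction, rep)
                    continue
                idx = rng.choice(len(variants), size=k, replace=False)
                sub = [variants[i] for i in sorted(idx)]
            counts_by_key, _ = build_position_counts(
                sub,
                hits,
                representatives,
                group_by_cancer=not config.pooled,
                evalue_max=config.evalue_max,
            )
            calls, _, _ = _fit_and_call(counts_by_key, config)
            sig = [c for c in calls if c.significant]
            rows.append(
                {
                    "fraction": fraction,
                    "unit": config.bootstrap_unit,
                    "replicate": rep,
                    "n_oncodomains": len({(c.domain_acc, c.cancer_type) for c in sig}),
                    "n_hotspots": len(sig),
                }
            )
    df = pd.DataFrame(
        rows, columns=["fraction", "unit", "replicate", "n_oncodomains", "n_hotspots"]
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, outdir / "bootstrap.tsv", config)
    return df
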