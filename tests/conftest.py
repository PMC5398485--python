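import numpy as np
import pytest

from oncodomains import FamilySpec, PlantSpec, make_family, plant_variants
from oncodomains.synthetic import write_family, write_maf, write_truth


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory):
    """Five synthetic families (L=200), three strong signal positions each
    (lam1=8 over a ZIP(0.3, 0.5) background), written to disk as one MAF +
    FASTA + alignment table with a combined truth table."""
    root = tmp_path_factory.mktemp("planted")
    import pandas as pd

    mafs, truths = [], []
    all_proteins, all_hits = [], []
    signal = {}
    for k in range(5):
        acc = f"synd{k + 1:05d}"
        spec = FamilySpec(
            domain_acc=acc, model_length=200, n_genes=4,
            insert_rate=0.02, delete_rate=0.02, seed=100 + k,
        )
        proteins, hits = make_family(spec)
        positions = frozenset({40 + k, 90 + k, 160 + k})
        plant = PlantSpec(
            pi_zero=0.3, lam0=0.5, signal_positions=positions, lam1=8.0,
            min_signal_count=8, n_patients=300, cancer_type="SYN", seed=200 + k,
        )
        maf, truth = plant_variants(proteins, hits, plant)
        mafs.append(maf)
        truths.append(truth)
        all_proteins.extend(proteins)
        all_hits.extend(hits)
        signal[acc] = positions
    maf = pd.concat(mafs, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    write_family(all_proteins, all_hits, root / "family.fasta", root / "family.dat.tsv")
    write_maf(maf, root / "variants.maf")
    write_truth(truth, root / "truth.tsv")
    return {
        "root": root,
        "maf": root / "variants.maf",
        "fasta": root / "family.fasta",
        "dat": root / "family.dat.tsv",
        "truth": truth,
        "signal": signal,
        "proteins": all_proteins,
        "hits": all_hits,
    }


def draw_mixture_counts(rng, n, pi=0.3, lam0=0.5, signal_frac=0.05, lam1=6.0):
    """Per-position counts from signal_frac*Poisson(lam1) + rest ZIP(pi, lam0);
    returns (counts, is_signal)."""
    is_signal = rng.random(n) < signal_frac
    null = np.where(rng.random(n) < pi, 0, rng.poisson(lam0, n))
    return np.where(is_signal, rng.poisson(lam1, n), null), is_signal
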