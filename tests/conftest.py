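"""Shared fixtures: small deterministic genomes and synthetic cohorts.

Heavy synthetic constructions are session-scoped so several tests can score
different statistics against the same planted ground truth.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from damagemap import synthetic as syn
from damagemap.core_io import FeatureTrack, GenomicInterval

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def sites_from_truth(truth: syn.SyntheticTruth, sample: str = "truth") -> pd.DataFrame:
    """Planted sites as a called-site table with unit read support."""
    df = truth.df[["contig", "pos", "strand"]].copy()
    df["base"] = "G"
    df["sample"] = sample
    df["read_support"] = 1
    return df


def wor_inclusion_probs(weights: np.ndarray, n: int) -> np.ndarray:
    """Exact per-item inclusion probabilities for sequential weighted
    sampling without replacement (the exponential-race model): pi_i =
    1 - exp(-theta w_i) with theta chosen so the probabilities sum to n.

    At a non-negligible sampling fraction this differs measurably from the
    naive n * w_i / sum(w): high-weight items are depleted early, which
    flattens their realized frequencies.  Tests that score planted-site
    compositions use this as the sampling oracle.
    """
    from scipy.optimize import brentq

    w = np.asarray(weights, dtype=float)

    def excess(theta):
        return np.sum(1.0 - np.exp(-theta * w)) - n

    hi = 1.0
    while excess(hi) < 0:
        hi *= 2.0
    theta = brentq(excess, 0.0, hi, xtol=1e-15)
    return 1.0 - np.exp(-theta * w)


@pytest.fixture(scope="session")
def uniform_genome():
    return syn.make_genome(100_000, seed=7)


@pytest.fixture(scope="session")
def humanlike_genome():
    """1 Mb, GC 0.41 with isochore-like 10 kb GC blocks."""
    return syn.make_genome(1_000_000, gc=0.41, gc_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def chromatin_cohort(humanlike_genome):
    """Planted damage with open-chromatin depletion plus an nDNA landscape.

    50 randomly placed 4 kb open regions; cell damage survives there with
    probability 0.3 while the nDNA landscape ignores chromatin entirely.
    """
    genome = humanlike_genome
    open_ivs = syn._random_disjoint_intervals(
        genome.lengths, 50, 4_000, np.random.default_rng(100)
    )
    open_track = FeatureTrack("open_chromatin", open_ivs)
    cell_model = syn.DamageModel(open_region_survival=0.3)
    ndna_model = syn.DamageModel()
    cell_truth = syn.plant_damage(
        genome, cell_model, 25_000, open_regions=open_track,
        rng=np.random.default_rng(101),
    )
    ndna_truth = syn.plant_damage(
        genome, ndna_model, 25_000, rng=np.random.default_rng(102)
    )
    return {
        "genome": genome,
        "open_track": open_track,
        "cell_sites": sites_from_truth(cell_truth, "cell"),
        "ndna_sites": sites_from_truth(ndna_truth, "nDNA"),
        "cell_truth": cell_truth,
        "ndna_truth": ndna_truth,
    }


@pytest.fixture(scope="session")
def strand_bias_cohort(humanlike_genome):
    """2,000 dense genes and damage planted with ts_survival = 0.5.

    Also returns the exact expected TS/NTS count ratio derived from the
    candidate-position weights (the sampling oracle), so tests can draw a
    proper 3-sigma band.
    """
    genome = humanlike_genome
    rng = np.random.default_rng(55)
    starts = np.arange(0, 1_000_000, 500)[:2_000]
    genes = pd.DataFrame(
        {
            "contig": "chr1",
            "start": starts + 50,
            "end": starts + 450,
            "name": [f"g{i}" for i in range(2_000)],
            "strand": rng.choice(["+", "-"], size=2_000),
        }
    )
    s = 0.5
    model = syn.DamageModel(ts_survival=s)
    truth = syn.plant_damage(
        genome, model, 30_000, genes=genes, rng=np.random.default_rng(56)
    )
    # sampling oracle: without-replacement inclusion probabilities over the
    # effective per-candidate weights (context weight x ts survival)
    cand = syn._candidate_sites(genome)
    w = model.normalized_weights[cand["triad_idx"].to_numpy()]
    ts_mask = syn._transcribed_strand_mask(cand, genes)
    w_eff = np.where(ts_mask, w * s, w)
    pi = wor_inclusion_probs(w_eff / w_eff.sum(), 30_000)
    body = FeatureTrack(
        "bodies",
        [GenomicInterval(r.contig, r.start, r.end) for r in genes.itertuples()],
    )
    in_gene = body.points_in("chr1", cand["pos"].to_numpy())
    e_ts = float(pi[in_gene & ts_mask].sum())
    e_nts = float(pi[in_gene & ~ts_mask].sum())
    expected_ratio = e_ts / e_nts
    expected_n_in_gene = e_ts + e_nts
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "sites": sites_from_truth(truth),
        "ts_survival": s,
        "expected_ratio": expected_ratio,
        "expected_n_in_gene": expected_n_in_gene,
    }


@pytest.fixture(scope="session")
def dose_cohort():
    """Full read-level cohort driven by two processes (background + one
    damage preference): untreated, four doses, nDNA."""
    from damagemap import experiments

    return experiments.rank_selection_experiment(seed=1)
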