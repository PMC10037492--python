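"""Strand-aware single-base damage calling from read 5' ends.

A polymerase replicating an immunoprecipitated fragment stalls immediately
before a bulky adduct, so the adduct sits one base 5' of the read start on
the read's strand: a + read with 5' end at p implies a lesion at p - 1 on
the + strand, and a - read with 5' end at p implies a lesion at p + 1 on
the - strand (whose base is the complement of the reference).  Calls are
recorded regardless of the reference base — non-G calls constitute the
background signal in the base-composition diagnostic — and G-restriction
happens only downstream in signature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import BASE_INDEX, FeatureTrack, GenomeIndex, attach_five_prime

__all__ = [
    "DamageSiteSet",
    "CallStats",
    "call_damage_sites",
    "composition_at_offsets",
    "simulate_random_reads",
]

_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G in index space


@dataclass
class CallStats:
    n_reads: int
    n_out_of_bounds: int
    n_blacklisted: int
    n_sites: int
    collision_rate: float  # fraction of reads sharing a 5' end with another


class DamageSiteSet:
    """Aggregated single-base damage calls.

    ``df`` columns: contig, pos (0-based), strand, base (damaged-strand
    reference base), sample, read_support.  One row per distinct
    (contig, pos, strand, sample).
    """

    def __init__(self, df: pd.DataFrame, stats: "CallStats | None" = None):
        required = {"contig", "pos", "strand", "base", "sample", "read_support"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        self.stats = stats

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def for_sample(self, sample: str) -> "DamageSiteSet":
        return DamageSiteSet(self.df[self.df["sample"] == sample].reset_index(drop=True))

    def total_support(self) -> int:
        return int(self.df["read_support"].sum())

    def positions(self) -> set[tuple[str, int, str]]:
        return set(zip(self.df["contig"], self.df["pos"].astype(int), self.df["strand"]))

    def write_bed(self, path: "str | Path") -> None:
        """BED6: name = damaged-strand base, score = read support."""
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.contig}\t{row.pos}\t{row.pos + 1}\t{row.base}"
                    f"\t{row.read_support}\t{row.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: "str | Path", sample: str = "sample") -> "DamageSiteSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]), f[5], f[3], sample, int(f[4])))
        return cls(
            pd.DataFrame(
                rows,
                columns=["contig", "pos", "strand", "base", "sample", "read_support"],
            )
        )

    @classmethod
    def concat(cls, parts: "list[DamageSiteSet]") -> "DamageSiteSet":
        return cls(pd.concat([p.df for p in parts], ignore_index=True))


def call_damage_sites(
    reads: pd.DataFrame,
    genome: GenomeIndex,
    blacklist: "FeatureTrack | None" = None,
) -> DamageSiteSet:
    """Convert aligned reads into aggregated damage calls.

    Reads whose inferred lesion position falls outside its contig or inside
    the blacklist are dropped and counted in the returned stats.
    """
    if "five_prime" not in reads.columns:
        reads = attach_five_prime(reads)
    unknown = set(reads["contig"].unique()) - set(genome.contigs)
    if unknown:
        raise ValueError(f"reads on contigs absent from genome: {sorted(unknown)}")
    bad_strand = ~reads["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError("reads must have strand + or -")

    n_reads = len(reads)
    strand = reads["strand"].to_numpy()
    five = reads["five_prime"].to_numpy()
    pos = np.where(strand == "+", five - 1, five + 1)
    contigs = reads["contig"].to_numpy()
    lengths = genome.lengths
    clen = np.array([lengths[c] for c in contigs], dtype=np.int64)
    in_bounds = (pos >= 0) & (pos < clen)
    n_oob = int((~in_bounds).sum())

    df = pd.DataFrame(
        {
            "contig": contigs[in_bounds],
            "pos": pos[in_bounds],
            "strand": strand[in_bounds],
            "sample": reads["sample"].to_numpy()[in_bounds],
        }
    )
    n_blacklisted = 0
    if blacklist is not None and len(blacklist) and len(df):
        keep = np.ones(len(df), dtype=bool)
        carr = df["contig"].to_numpy()
        parr = df["pos"].to_numpy()
        for contig in pd.unique(df["contig"]):
            sel = np.flatnonzero(carr == contig)
            keep[sel] = ~blacklist.points_in(contig, parr[sel])
        n_blacklisted = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)

    if len(df):
        base_idx = np.empty(len(df), dtype=np.int8)
        carr = df["contig"].to_numpy()
        parr = df["pos"].to_numpy()
        for contig in pd.unique(df["contig"]):
            sel = np.flatnonzero(carr == contig)
            idx = BASE_INDEX[genome.array(contig)[parr[sel]]]
            base_idx[sel] = idx
        minus = df["strand"].to_numpy() == "-"
        valid = base_idx >= 0
        base_idx = np.where(minus & valid, _COMP_IDX[np.clip(base_idx, 0, 3)], base_idx)
        df["base"] = np.where(valid, np.array(list("ACGT"))[np.clip(base_idx, 0, 3)], "N")
        agg = (
            df.groupby(["contig", "pos", "strand", "base", "sample"], sort=True)
            .size()
            .rename("read_support")
            .reset_index()
        )
    else:
        agg = pd.DataFrame(
            columns=["contig", "pos", "strand", "base", "sample", "read_support"]
        )

    kept = n_reads - n_oob - n_blacklisted
    collision_rate = 0.0 if kept == 0 else 1.0 - len(agg) / kept
    stats = CallStats(
        n_reads=n_reads,
        n_out_of_bounds=n_oob,
        n_blacklisted=n_blacklisted,
        n_sites=len(agg),
        collision_rate=collision_rate,
    )
    return DamageSiteSet(agg, stats)


def composition_at_offsets(
    sites: "DamageSiteSet | pd.DataFrame",
    genome: GenomeIndex,
    offsets: "tuple[int, ...] | range" = range(-3, 4),
) -> pd.DataFrame:
    """Read-support-weighted base fractions around called positions.

    Offsets run 5'->3' on the damaged strand (offset 0 is the call itself;
    -1 is one base 5' of it, where damage would sit if the polymerase had
    stalled prematurely).  Per offset, positions leaving the contig or
    hitting N are excluded.  Returns a DataFrame indexed by offset with
    columns A, C, G, T whose rows each sum to 1.
    """
    df = sites.df if isinstance(sites, DamageSiteSet) else sites
    if len(df) == 0:
        raise ValueError("empty site set")
    if "read_support" not in df.columns:
        df = df.assign(read_support=1)
    offsets = list(offsets)
    pos = df["pos"].to_numpy()
    minus = df["strand"].to_numpy() == "-"
    weights = df["read_support"].to_numpy().astype(np.float64)
    contigs = df["contig"].to_numpy()
    lengths = genome.lengths
    clen = np.array([lengths[c] for c in contigs], dtype=np.int64)

    out = np.zeros((len(offsets), 4), dtype=np.float64)
    base_at = np.full(len(df), -1, dtype=np.int8)
    for i, off in enumerate(offsets):
        gpos = np.where(minus, pos - off, pos + off)
        ok = (gpos >= 0) & (gpos < clen)
        base_at[:] = -1
        for contig in pd.unique(df["contig"]):
            sel = np.flatnonzero((contigs == contig) & ok)
            base_at[sel] = BASE_INDEX[genome.array(contig)[gpos[sel]]]
        base_at[minus & (base_at >= 0)] = _COMP_IDX[
            np.clip(base_at[minus & (base_at >= 0)], 0, 3)
        ]
        usable = base_at >= 0
        if not usable.any():
            continue
        out[i] = np.bincount(
            base_at[usable], weights=weights[usable], minlength=4
        )
        out[i] /= out[i].sum()
    return pd.DataFrame(out, index=pd.Index(offsets, name="offset"), columns=list("ACGT"))


def simulate_random_reads(
    genome: GenomeIndex,
    n: int,
    read_length: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform random 5'-end reads over both strands (the random baseline
    used to establish the natural base composition at called positions)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = genome.contigs
    lengths = genome.lengths
    # valid + starts: [0, L - rl]; valid - 5' ends: [rl - 1, L - 1]; both ranges
    # have L - rl + 1 choices, so weight contigs by that.
    sizes = np.array([max(lengths[c] - read_length + 1, 0) for c in names])
    if sizes.sum() == 0:
        raise ValueError("no contig long enough for the read length")
    contig_idx = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    offset = rng.integers(0, sizes[contig_idx])
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    plus = strand == "+"
    start = np.where(plus, offset, offset)
    end = start + read_length
    reads = pd.DataFrame(
        {
            "contig": np.array(names, dtype=object)[contig_idx],
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": strand,
            "sample": "random",
        }
    )
    return attach_five_prime(reads)
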