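"""Synthetic damage-seq data with known ground truth.

Generates a toy genome, plants guanine adducts according to a parameterized
damage model, and emits damage-seq-like reads: a fraction ``purity`` of
reads start one base 3' of a planted adduct on the adduct's strand (a
polymerase that stalls immediately before the lesion), a minor fraction of
those start one base early (premature stall, -2), and the remainder are
background reads whose -1 base is a G with probability ``background_g_bias``
(mimicking residual polymerase stalling at unmodified G in untreated
libraries).  A cohort mixes untreated, dose-series cell samples and a
chromatin-free naked-DNA (nDNA) sample.

Every planted site is recorded in a truth ledger so downstream calling,
distribution and signature analyses can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    BASE_INDEX,
    FeatureTrack,
    GenomeIndex,
    GenomicInterval,
    attach_five_prime,
    genes_to_bed,
    reads_to_bed,
)

__all__ = [
    "G16_CONTEXTS",
    "DamageModel",
    "SyntheticTruth",
    "default_context_weights",
    "make_genome",
    "plant_damage",
    "emit_reads",
    "CohortConfig",
    "Cohort",
    "make_cohort",
]

#: The 16 guanine-centered trinucleotide contexts, ordered lexicographically
#: by (5' flank, 3' flank).
G16_CONTEXTS: list[str] = [f + "G" + t for f in "ACGT" for t in "ACGT"]

_G16_INDEX = {t: i for i, t in enumerate(G16_CONTEXTS)}


def default_context_weights() -> dict[str, float]:
    """A fixed, non-uniform guanine context preference.

    Encodes a CpG-flavoured reactivity profile (bulky aromatic adducts form
    preferentially at 5'-CG dinucleotides, with a milder boost from a 3' G);
    used as the generator default so planted damage carries a recoverable,
    non-trivial signature.
    """
    weights = {}
    for f in "ACGT":
        for t in "ACGT":
            w = 1.0
            if f == "C":
                w *= 3.0
            elif f == "T":
                w *= 0.6
            if t == "G":
                w *= 1.8
            elif t == "T":
                w *= 0.7
            weights[f + "G" + t] = w
    return weights


@dataclass
class DamageModel:
    """Parameters of the generative damage process.

    context_weights
        Relative sampling weight per guanine trinucleotide context (16 NGN
        entries); normalized to 1 before sampling.
    open_region_survival
        Multiplier in (0, 1] on damage weight inside designated open-chromatin
        intervals (values < 1 deplete damage there, emulating faster repair
        of accessible DNA).
    ts_survival
        Multiplier in (0, 1] on damage weight on the transcribed (template)
        strand of designated genes (transcription-coupled repair analog).
    purity
        Fraction of emitted reads that are adduct-derived.
    premature_stall_fraction
        Fraction of adduct reads starting two bases 3' of the adduct
        instead of one (minor early polymerase stop).
    background_g_bias
        Probability that a background read has G at its -1 position.
    """

    context_weights: Mapping[str, float] = field(default_factory=default_context_weights)
    open_region_survival: float = 1.0
    ts_survival: float = 1.0
    purity: float = 1.0
    premature_stall_fraction: float = 0.05
    background_g_bias: float = 0.30

    def __post_init__(self):
        unknown = set(self.context_weights) - set(G16_CONTEXTS)
        if unknown:
            raise ValueError(f"unknown context keys: {sorted(unknown)}")
        w = np.array([self.context_weights.get(t, 0.0) for t in G16_CONTEXTS])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("context weights must be non-negative with positive sum")
        if not (0.0 < self.open_region_survival <= 1.0):
            raise ValueError("open_region_survival must be in (0, 1]")
        if not (0.0 <= self.ts_survival <= 1.0):
            raise ValueError("ts_survival must be in [0, 1]")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        if not (0.0 <= self.premature_stall_fraction <= 1.0):
            raise ValueError("premature_stall_fraction must be in [0, 1]")
        if not (0.0 <= self.background_g_bias <= 1.0):
            raise ValueError("background_g_bias must be in [0, 1]")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.array([self.context_weights.get(t, 0.0) for t in G16_CONTEXTS], dtype=float)
        return w / w.sum()

    def replace(self, **kwargs) -> "DamageModel":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ledger of planted sites: contig, pos, strand, triad, process."""

    df: pd.DataFrame
    condition: str = "damage"

    def __post_init__(self):
        required = {"contig", "pos", "strand", "triad", "process"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"truth ledger missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> set[tuple[str, int, str]]:
        return set(
            zip(self.df["contig"], self.df["pos"].astype(int), self.df["strand"])
        )

    def triad_histogram(self) -> pd.Series:
        counts = self.df["triad"].value_counts()
        return counts.reindex(G16_CONTEXTS, fill_value=0).astype(int)

    def to_tsv(self, path: "str | Path") -> None:
        out = self.df.copy()
        out.insert(0, "condition", self.condition)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t")
        condition = df["condition"].iloc[0] if "condition" in df and len(df) else "damage"
        return cls(df.drop(columns=["condition"], errors="ignore"), condition)


# --- genome -----------------------------------------------------------------


def make_genome(
    lengths: "int | Mapping[str, int]",
    composition: "Mapping[str, float] | None" = None,
    gc: "float | None" = None,
    gc_sd: float = 0.0,
    block: int = 10_000,
    seed: int = 0,
    path: "str | Path | None" = None,
) -> GenomeIndex:
    """Sample a random genome with controlled base composition.

    Either ``composition`` (dict over ACGT summing to 1 within 1e-9) or
    ``gc`` may be given; default is uniform.  When ``gc_sd > 0`` the GC
    fraction varies between ``block``-sized segments (isochore-like GC
    heterogeneity), drawn from a clipped normal around the requested mean.
    Deterministic for a fixed seed.  Optionally writes a FASTA.
    """
    if isinstance(lengths, int):
        lengths = {"chr1": lengths}
    for name, n in lengths.items():
        if n < 1000:
            raise ValueError(f"contig {name!r} shorter than 1 kb")
    if composition is not None and gc is not None:
        raise ValueError("give composition or gc, not both")
    if composition is None:
        g = 0.25 if gc is None else gc / 2.0
        composition = {"A": 0.5 - g, "C": g, "G": g, "T": 0.5 - g}
    p = np.array([composition.get(b, 0.0) for b in "ACGT"], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {p.sum()!r}, expected 1")
    if (p < 0).any():
        raise ValueError("composition must be non-negative")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    gc_mean = p[1] + p[2]
    sequences: dict[str, np.ndarray] = {}
    for name, n in lengths.items():
        if gc_sd <= 0:
            seq = rng.choice(alphabet, size=n, p=p)
        else:
            parts = []
            for start in range(0, n, block):
                m = min(block, n - start)
                gc_b = float(np.clip(rng.normal(gc_mean, gc_sd), 0.02, 0.98))
                scale_gc = gc_b / gc_mean if gc_mean > 0 else 0.0
                scale_at = (1 - gc_b) / (1 - gc_mean) if gc_mean < 1 else 0.0
                pb = p * np.array([scale_at, scale_gc, scale_gc, scale_at])
                pb = pb / pb.sum()
                parts.append(rng.choice(alphabet, size=m, p=pb))
            seq = np.concatenate(parts)
        sequences[name] = seq
    genome = GenomeIndex(sequences)
    if path is not None:
        genome.write_fasta(path)
    return genome


# --- candidate guanine positions -------------------------------------------


def _candidate_sites(genome: GenomeIndex) -> pd.DataFrame:
    """All G positions on both strands with their damaged-strand triads.

    Excludes contig-edge positions and triads touching N.  The triad is read
    5'->3' on the damaged strand: the reverse complement of the reference
    window for minus-strand sites (a minus-strand G is a reference C).
    """
    frames = []
    for contig in genome.contigs:
        arr = genome.array(contig)
        idx = BASE_INDEX[arr].astype(np.int64)  # A0 C1 G2 T3, N=-1
        n = arr.size
        center = idx[1 : n - 1]
        left = idx[: n - 2]
        right = idx[2:]
        valid_flanks = (left >= 0) & (right >= 0)
        # plus strand: reference G; triad = left, G, right
        plus = np.flatnonzero((center == 2) & valid_flanks) + 1
        plus_tri = left[plus - 1] * 4 + right[plus - 1]
        # minus strand: reference C; damaged-strand triad = comp(right), G, comp(left)
        minus = np.flatnonzero((center == 1) & valid_flanks) + 1
        comp = 3 - idx  # A<->T, C<->G in index space (N becomes 4, filtered already)
        minus_tri = comp[minus + 1] * 4 + comp[minus - 1]
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": np.concatenate([plus, minus]),
                    "strand": ["+"] * plus.size + ["-"] * minus.size,
                    "triad_idx": np.concatenate([plus_tri, minus_tri]).astype(np.int16),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _transcribed_strand_mask(cand: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """True where a candidate site lies on the transcribed (template) strand
    of a gene body: the - strand for + genes and vice versa."""
    mask = np.zeros(len(cand), dtype=bool)
    contigs = cand["contig"].to_numpy()
    pos = cand["pos"].to_numpy()
    strand = cand["strand"].to_numpy()
    for gene_strand, template in (("+", "-"), ("-", "+")):
        sub = genes[genes["strand"] == gene_strand]
        if sub.empty:
            continue
        track = FeatureTrack(
            "genes",
            [GenomicInterval(r.contig, r.start, r.end) for r in sub.itertuples()],
        )
        cand_sel = np.flatnonzero(strand == template)
        for contig in np.unique(contigs[cand_sel]):
            sel = cand_sel[contigs[cand_sel] == contig]
            mask[sel] |= track.points_in(contig, pos[sel])
    return mask


def plant_damage(
    genome: GenomeIndex,
    model: DamageModel,
    n_sites: int,
    open_regions: "FeatureTrack | None" = None,
    genes: "pd.DataFrame | None" = None,
    seed: "int | None" = 0,
    rng: "np.random.Generator | None" = None,
) -> SyntheticTruth:
    """Sample ``n_sites`` distinct damage positions over both strands.

    The sampling probability of each eligible G position is proportional to
    ``context_weight(triad) x open_region_survival (if inside an open
    region) x ts_survival (if on the transcribed strand of a gene)``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    cand = _candidate_sites(genome)
    if cand.empty:
        raise ValueError("genome has no eligible G positions")
    w = model.normalized_weights[cand["triad_idx"].to_numpy()]
    if open_regions is not None and model.open_region_survival < 1.0:
        contigs = cand["contig"].to_numpy()
        pos = cand["pos"].to_numpy()
        inside = np.zeros(len(cand), dtype=bool)
        for contig in np.unique(contigs):
            sel = np.flatnonzero(contigs == contig)
            inside[sel] = open_regions.points_in(contig, pos[sel])
        w = np.where(inside, w * model.open_region_survival, w)
    if genes is not None and model.ts_survival < 1.0:
        ts = _transcribed_strand_mask(cand, genes)
        w = np.where(ts, w * model.ts_survival, w)
    eligible = int((w > 0).sum())
    if eligible == 0:
        raise ValueError("no eligible G positions with positive weight")
    if n_sites > eligible:
        raise ValueError(f"n_sites={n_sites} exceeds {eligible} eligible positions")
    p = w / w.sum()
    chosen = rng.choice(len(cand), size=n_sites, replace=False, p=p)
    chosen.sort()
    sites = cand.iloc[chosen].reset_index(drop=True)
    triads = [G16_CONTEXTS[i] for i in sites["triad_idx"]]
    truth = pd.DataFrame(
        {
            "contig": sites["contig"],
            "pos": sites["pos"].astype(np.int64),
            "strand": sites["strand"],
            "triad": triads,
            "process": "damage",
        }
    )
    return SyntheticTruth(truth)


# --- reads ------------------------------------------------------------------


def _background_pools(genome: GenomeIndex, read_length: int):
    """Valid background 5'-end positions split by (strand, G at -1)."""
    pools = {}
    for contig in genome.contigs:
        arr = genome.array(contig)
        n = arr.size
        # + strand: read [q, q+L); -1 base is arr[q-1]; need q >= 1 for -1 to exist
        q = np.arange(1, max(n - read_length + 1, 1), dtype=np.int64)
        if q.size:
            is_g = arr[q - 1] == ord("G")
            pools.setdefault(("+", True), []).append((contig, q[is_g]))
            pools.setdefault(("+", False), []).append((contig, q[~is_g]))
        # - strand: 5' end q, read [q-L+1, q+1); -1 base is comp(arr[q+1])
        q = np.arange(read_length - 1, n - 1, dtype=np.int64)
        if q.size:
            is_g = arr[q + 1] == ord("C")
            pools.setdefault(("-", True), []).append((contig, q[is_g]))
            pools.setdefault(("-", False), []).append((contig, q[~is_g]))
    flat = {}
    for key, parts in pools.items():
        contigs = np.concatenate(
            [np.full(qs.size, i, dtype=np.int64) for i, (_, qs) in enumerate(parts)]
        )
        names = [c for c, _ in parts]
        positions = np.concatenate([qs for _, qs in parts])
        flat[key] = (names, contigs, positions)
    return flat


def emit_reads(
    truth: SyntheticTruth,
    model: DamageModel,
    genome: GenomeIndex,
    n_reads: int,
    read_length: int = 50,
    sample: str = "sample",
    seed: "int | None" = 0,
    rng: "np.random.Generator | None" = None,
) -> pd.DataFrame:
    """Emit BED6-style reads for one sample.

    Adduct reads are allocated over planted sites as evenly as possible
    (every site receives ``floor(n_adduct / n_sites)`` reads and a random
    subset one extra), so with enough reads every planted site is covered.
    Reads that would leave the contig are re-drawn.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lengths = genome.lengths
    n_adduct = int(rng.binomial(n_reads, model.purity)) if n_reads else 0
    rows = []

    if n_adduct and len(truth):
        n_sites = len(truth)
        base_mult = n_adduct // n_sites
        extra = n_adduct % n_sites
        mult = np.full(n_sites, base_mult, dtype=np.int64)
        if extra:
            mult[rng.choice(n_sites, size=extra, replace=False)] += 1
        site_idx = np.repeat(np.arange(n_sites), mult)
        rng.shuffle(site_idx)
        tdf = truth.df
        pos = tdf["pos"].to_numpy()[site_idx]
        strand = tdf["strand"].to_numpy()[site_idx]
        contig = tdf["contig"].to_numpy()[site_idx]
        offset = np.where(
            rng.random(site_idx.size) < model.premature_stall_fraction, 2, 1
        )
        plus = strand == "+"
        five = np.where(plus, pos + offset, pos - offset)
        clen = np.array([lengths[c] for c in contig])
        ok = (five >= 0) & (five < clen)
        # a read whose 5' end leaves the contig is discarded and resampled
        # from another site; fragments merely overhanging the contig end are
        # truncated so edge sites remain observable
        for _ in range(100):
            bad = np.flatnonzero(~ok)
            if bad.size == 0:
                break
            redraw = rng.integers(0, n_sites, size=bad.size)
            pos[bad] = tdf["pos"].to_numpy()[redraw]
            strand[bad] = tdf["strand"].to_numpy()[redraw]
            contig[bad] = tdf["contig"].to_numpy()[redraw]
            offset_b = np.where(
                rng.random(bad.size) < model.premature_stall_fraction, 2, 1
            )
            plus_b = strand[bad] == "+"
            five[bad] = np.where(plus_b, pos[bad] + offset_b, pos[bad] - offset_b)
            clen[bad] = np.array([lengths[c] for c in contig[bad]])
            ok[bad] = (five[bad] >= 0) & (five[bad] < clen[bad])
        plus = strand == "+"
        start = np.where(plus, five, np.maximum(five - read_length + 1, 0))
        end = np.where(plus, np.minimum(five + read_length, clen), five + 1)
        keep = np.flatnonzero(ok)
        rows.append(
            pd.DataFrame(
                {
                    "contig": contig[keep],
                    "start": start[keep],
                    "end": end[keep],
                    "strand": strand[keep],
                }
            )
        )

    n_bg = n_reads - (len(rows[0]) if rows else 0)
    if n_bg > 0:
        pools = _background_pools(genome, read_length)
        strand_choice = np.where(rng.random(n_bg) < 0.5, "+", "-")
        g_choice = rng.random(n_bg) < model.background_g_bias
        parts = []
        for s in ("+", "-"):
            for g in (True, False):
                count = int(((strand_choice == s) & (g_choice == g)).sum())
                if count == 0:
                    continue
                names, contig_ids, positions = pools[(s, g)]
                pick = rng.integers(0, positions.size, size=count)
                q = positions[pick]
                c = np.array(names, dtype=object)[contig_ids[pick]]
                if s == "+":
                    st, en = q, q + read_length
                else:
                    st, en = q - read_length + 1, q + 1
                parts.append(
                    pd.DataFrame({"contig": c, "start": st, "end": en, "strand": s})
                )
        rows.extend(parts)

    if rows:
        reads = pd.concat(rows, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=["contig", "start", "end", "strand"])
    reads["sample"] = sample
    reads = attach_five_prime(reads)
    # deterministic order for byte-identical output
    reads = reads.sort_values(
        ["contig", "start", "end", "strand"], kind="mergesort"
    ).reset_index(drop=True)
    return reads


# --- cohort -----------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Doses map to read purity (the planted lesion landscape is shared across
    cell samples; only the adduct-derived read fraction grows with dose,
    emulating a monotone dose response).  The nDNA sample gets its own
    landscape planted with chromatin and transcription effects switched off.
    """

    genome_length: "int | Mapping[str, int]" = 1_000_000
    gc: float = 0.41
    gc_sd: float = 0.05
    gc_block: int = 10_000
    n_sites: int = 20_000
    doses: "Sequence[tuple[str, float]]" = (
        ("0.25uM", 0.40),
        ("0.5uM", 0.55),
        ("1uM", 0.70),
        ("2uM", 0.80),
    )
    ndna_purity: float = 0.90
    n_replicates: int = 1
    n_reads: int = 60_000
    read_length: int = 50
    n_open_regions: int = 150
    open_region_length: int = 2_000
    n_genes: int = 300
    gene_length: int = 1_500
    open_region_survival: float = 0.4
    ts_survival: float = 0.6
    premature_stall_fraction: float = 0.05
    background_g_bias: float = 0.30
    context_weights: "Mapping[str, float] | None" = None
    seed: int = 0


@dataclass
class Cohort:
    genome: GenomeIndex
    open_regions: FeatureTrack
    genes: pd.DataFrame
    truths: dict[str, SyntheticTruth]
    reads: dict[str, pd.DataFrame]  # sample -> reads table
    manifest: pd.DataFrame  # sample, condition, replicate, purity, n_reads
    config: CohortConfig

    def write(self, outdir: "str | Path") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fasta = outdir / "genome.fa"
        self.genome.write_fasta(fasta)
        paths["genome"] = fasta
        self.open_regions.to_bed(outdir / "open_regions.bed")
        paths["open_regions"] = outdir / "open_regions.bed"
        genes_to_bed(self.genes, outdir / "genes.bed")
        paths["genes"] = outdir / "genes.bed"
        for condition, truth in self.truths.items():
            p = outdir / f"truth_{condition}.tsv"
            truth.to_tsv(p)
            paths[f"truth_{condition}"] = p
        manifest = self.manifest.copy()
        bed_paths = []
        for sample in manifest["sample"]:
            p = outdir / f"reads_{sample}.bed"
            reads_to_bed(self.reads[sample], p)
            bed_paths.append(p.name)  # relative to the manifest's directory
            paths[f"reads_{sample}"] = p
        manifest["path"] = bed_paths
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        paths["manifest"] = outdir / "manifest.tsv"
        return paths


def _random_disjoint_intervals(
    lengths: Mapping[str, int],
    n: int,
    size: int,
    rng: np.random.Generator,
    stranded: bool = False,
) -> list[GenomicInterval]:
    """n non-overlapping fixed-size intervals spread over the genome."""
    total = sum(lengths.values())
    out: list[GenomicInterval] = []
    names = list(lengths)
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        contig = names[int(rng.choice(len(names), p=weights))]
        clen = lengths[contig]
        if clen <= size + 2:
            continue
        start = int(rng.integers(1, clen - size - 1))
        end = start + size
        if any(start < e and s < end for s, e in occupied[contig]):
            continue
        occupied[contig].append((start, end))
        strand = "." if not stranded else ("+" if rng.random() < 0.5 else "-")
        out.append(GenomicInterval(contig, start, end, strand))
    if len(out) < n:
        raise ValueError(f"could not place {n} disjoint intervals of size {size}")
    return out


def make_cohort(config: CohortConfig, outdir: "str | Path | None" = None) -> Cohort:
    """Generate genome, annotations, truth ledgers and per-sample reads."""
    ss = np.random.SeedSequence(config.seed)
    (genome_seed, region_seed, plant_seed, ndna_seed, *sample_seeds) = ss.spawn(
        4 + (1 + len(config.doses) * config.n_replicates + 1)
    )
    genome = make_genome(
        config.genome_length,
        gc=config.gc,
        gc_sd=config.gc_sd,
        block=config.gc_block,
        seed=genome_seed,
    )
    lengths = genome.lengths
    region_rng = np.random.default_rng(region_seed)
    open_ivs = _random_disjoint_intervals(
        lengths, config.n_open_regions, config.open_region_length, region_rng
    )
    open_regions = FeatureTrack("open_chromatin", open_ivs)
    gene_ivs = _random_disjoint_intervals(
        lengths, config.n_genes, config.gene_length, region_rng, stranded=True
    )
    genes = pd.DataFrame(
        {
            "contig": [iv.contig for iv in gene_ivs],
            "start": [iv.start for iv in gene_ivs],
            "end": [iv.end for iv in gene_ivs],
            "name": [f"gene{i}" for i in range(len(gene_ivs))],
            "strand": [iv.strand for iv in gene_ivs],
        }
    )

    weights = (
        dict(config.context_weights)
        if config.context_weights is not None
        else default_context_weights()
    )
    cell_model = DamageModel(
        context_weights=weights,
        open_region_survival=config.open_region_survival,
        ts_survival=config.ts_survival,
        premature_stall_fraction=config.premature_stall_fraction,
        background_g_bias=config.background_g_bias,
    )
    ndna_model = cell_model.replace(open_region_survival=1.0, ts_survival=1.0)

    cell_truth = plant_damage(
        genome,
        cell_model,
        config.n_sites,
        open_regions=open_regions,
        genes=genes,
        rng=np.random.default_rng(plant_seed),
    )
    cell_truth.condition = "cell"
    ndna_truth = plant_damage(
        genome, ndna_model, config.n_sites, rng=np.random.default_rng(ndna_seed)
    )
    ndna_truth.condition = "nDNA"

    reads: dict[str, pd.DataFrame] = {}
    rows = []
    seeds = iter(sample_seeds)

    def emit(sample, condition, replicate, truth, model, purity):
        m = model.replace(purity=purity)
        reads[sample] = emit_reads(
            truth,
            m,
            genome,
            config.n_reads,
            read_length=config.read_length,
            sample=sample,
            rng=np.random.default_rng(next(seeds)),
        )
        rows.append(
            {
                "sample": sample,
                "condition": condition,
                "replicate": replicate,
                "purity": purity,
                "n_reads": len(reads[sample]),
            }
        )

    emit("untreated", "untreated", 1, cell_truth, cell_model, 0.0)
    for label, purity in config.doses:
        for rep in range(1, config.n_replicates + 1):
            emit(f"{label}_r{rep}", label, rep, cell_truth, cell_model, purity)
    emit("nDNA", "nDNA", 1, ndna_truth, ndna_model, config.ndna_purity)

    cohort = Cohort(
        genome=genome,
        open_regions=open_regions,
        genes=genes,
        truths={"cell": cell_truth, "nDNA": ndna_truth},
        reads=reads,
        manifest=pd.DataFrame(rows),
        config=config,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
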