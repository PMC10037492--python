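"""Bin-level genomic distribution statistics for damage maps.

Covers: fixed-width binning of called sites, per-bin GC and feature
coverage, relative abundance (log2 cell/nDNA) against a naked-DNA
reference, Spearman correlations with genomic features, AIC-guided bin-size
evaluation, hot/cold-spot extraction, metagene profiles around TSS/TES,
transcribed- vs non-transcribed-strand bias, and LOESS smoothing for
presentation.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import FeatureTrack, GenomeIndex, GenomicInterval

__all__ = [
    "GenomePartition",
    "BinTrack",
    "RelativeAbundanceTrack",
    "CorrelationResult",
    "BinSizeEvaluation",
    "ProfileMatrix",
    "StrandBiasResult",
    "bin_counts",
    "relative_abundance",
    "correlate",
    "evaluate_bin_sizes",
    "hot_cold_spots",
    "fraction_negative_per_contig",
    "metagene_profile",
    "ts_nts_profile",
    "ts_nts_bias",
    "loess_smooth",
]


class GenomePartition:
    """Fixed-width bins tiling each contig left to right.

    The last, possibly shorter, bin of each contig is retained and flagged
    ``partial``.
    """

    def __init__(self, lengths: Mapping[str, int], width: int):
        if width < 1:
            raise ValueError("bin width must be >= 1")
        self.lengths = dict(lengths)
        self.width = int(width)
        frames = []
        offset = 0
        self._offsets: dict[str, int] = {}
        for contig, n in self.lengths.items():
            nbins = (n + width - 1) // width
            starts = np.arange(nbins, dtype=np.int64) * width
            ends = np.minimum(starts + width, n)
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "start": starts,
                        "end": ends,
                        "partial": ends - starts < width,
                    }
                )
            )
            self._offsets[contig] = offset
            offset += nbins
        self.bins = pd.concat(frames, ignore_index=True)

    @classmethod
    def from_genome(cls, genome: GenomeIndex, width: int) -> "GenomePartition":
        return cls(genome.lengths, width)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomePartition)
            and self.width == other.width
            and self.lengths == other.lengths
        )

    def bin_ids(self, contigs: np.ndarray, positions: np.ndarray) -> np.ndarray:
        ids = np.empty(len(positions), dtype=np.int64)
        contigs = np.asarray(contigs)
        positions = np.asarray(positions)
        for contig in pd.unique(pd.Series(contigs)):
            if contig not in self._offsets:
                raise KeyError(f"contig {contig!r} not in partition")
            sel = np.flatnonzero(contigs == contig)
            ids[sel] = self._offsets[contig] + positions[sel] // self.width
        return ids


@dataclass
class BinTrack:
    """Per-bin damage statistics on a fixed genome partition.

    ``df`` carries contig/start/end/partial plus ``count`` (summed read
    support) and ``rate`` (counts per million called sites).  Optional
    columns (``gc``, feature coverages) are attached by the helpers below.
    """

    partition: GenomePartition
    df: pd.DataFrame

    @property
    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy()

    @property
    def rates(self) -> np.ndarray:
        return self.df["rate"].to_numpy()

    def add_gc(self, genome: GenomeIndex) -> "BinTrack":
        gc = np.empty(self.partition.n_bins)
        i = 0
        for contig, n in self.partition.lengths.items():
            arr = genome.array(contig)
            is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
            is_acgt = (arr != ord("N")).astype(np.int64)
            cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
            cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
            sub = self.df[self.df["contig"] == contig]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            denom = cum_ok[e] - cum_ok[s]
            with np.errstate(invalid="ignore"):
                gc[i : i + len(sub)] = np.where(
                    denom > 0, (cum_gc[e] - cum_gc[s]) / denom, np.nan
                )
            i += len(sub)
        self.df["gc"] = gc
        return self

    def add_feature_coverage(self, feature: FeatureTrack, name: "str | None" = None) -> "BinTrack":
        """Fraction of each bin covered by the (merged) feature intervals."""
        name = name or feature.name
        cov = np.zeros(self.partition.n_bins)
        i = 0
        for contig in self.partition.lengths:
            sub = self.df[self.df["contig"] == contig]
            starts, ends = feature.merged(contig)
            if starts.size:
                lens = ends - starts
                cum = np.concatenate([[0], np.cumsum(lens)])

                def covered_up_to(x):
                    j = np.searchsorted(starts, x, side="left")
                    c = cum[j].astype(np.float64)
                    has_prev = j > 0
                    prev = j[has_prev] - 1
                    overhang = np.maximum(ends[prev] - x[has_prev], 0)
                    c[has_prev] -= overhang
                    return c

                s = sub["start"].to_numpy()
                e = sub["end"].to_numpy()
                cov[i : i + len(sub)] = (covered_up_to(e) - covered_up_to(s)) / (e - s)
            i += len(sub)
        self.df[name] = cov
        return self


@dataclass
class RelativeAbundanceTrack:
    """Per-bin log2((cell rate + eps) / (nDNA rate + eps)).

    Bins empty in both samples are missing (NaN), not 0.  Positive values
    mark cellular accumulation relative to naked DNA, negative values
    depletion.
    """

    partition: GenomePartition
    df: pd.DataFrame  # contig/start/end/partial/value (+ carried covariates)
    epsilon: float

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()


def bin_counts(sites, partition: GenomePartition) -> BinTrack:
    """Sum read support per bin; rate = count x 1e6 / total support."""
    df = getattr(sites, "df", sites)
    out = partition.bins.copy()
    counts = np.zeros(partition.n_bins, dtype=np.int64)
    if len(df):
        ids = partition.bin_ids(df["contig"].to_numpy(), df["pos"].to_numpy())
        counts = np.bincount(
            ids, weights=df["read_support"].to_numpy(), minlength=partition.n_bins
        ).astype(np.int64)
    total = counts.sum()
    out["count"] = counts
    out["rate"] = counts * 1e6 / total if total > 0 else 0.0
    return BinTrack(partition, out)


def relative_abundance(
    cell: BinTrack, ndna: BinTrack, epsilon: float = 1.0
) -> RelativeAbundanceTrack:
    """log2 ratio of normalized damage rates, cell over naked DNA."""
    if cell.partition != ndna.partition:
        raise ValueError("cell and nDNA tracks are on different partitions")
    rc, rn = cell.rates.astype(float), ndna.rates.astype(float)
    value = np.log2((rc + epsilon) / (rn + epsilon))
    missing = (cell.counts == 0) & (ndna.counts == 0)
    value = np.where(missing, np.nan, value)
    df = cell.partition.bins.copy()
    df["value"] = value
    for extra in ("gc",):
        if extra in cell.df.columns:
            df[extra] = cell.df[extra].to_numpy()
    return RelativeAbundanceTrack(cell.partition, df, epsilon)


@dataclass
class CorrelationResult:
    coefficient: float
    n: int
    pvalue: "float | None" = None
    coefficient_sd: "float | None" = None  # across replicates, when supplied

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def correlate(signal, feature, method: str = "spearman") -> CorrelationResult:
    """Rank correlation between a per-bin signal and a feature vector.

    ``signal`` may be one vector or a list of replicate vectors; replicates
    report the mean +/- SD of per-replicate coefficients.  Pairs with
    missing values are dropped; fewer than 3 usable pairs is an error.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    feature = np.asarray(feature, dtype=float)

    def one(vec) -> CorrelationResult:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != feature.shape:
            raise ValueError("signal and feature lengths differ")
        ok = ~(np.isnan(vec) | np.isnan(feature))
        if ok.sum() < 3:
            raise ValueError("fewer than 3 usable bins")
        if method == "spearman":
            rho, p = sps.spearmanr(vec[ok], feature[ok])
        else:
            rho, p = sps.pearsonr(vec[ok], feature[ok])
        return CorrelationResult(float(rho), int(ok.sum()), float(p))

    if isinstance(signal, (list, tuple)):
        results = [one(v) for v in signal]
        coefs = np.array([r.coefficient for r in results])
        return CorrelationResult(
            float(coefs.mean()),
            int(np.mean([r.n for r in results])),
            None,
            float(coefs.std(ddof=1)) if len(coefs) > 1 else 0.0,
        )
    return one(signal)


@dataclass
class BinSizeEvaluation:
    """AIC per candidate bin width for the smoothed-Poisson count model."""

    table: pd.DataFrame  # width, n_bins, loglik, eff_params, aic
    selected_widths: list[int]
    best_width: int


def evaluate_bin_sizes(
    sites,
    lengths: Mapping[str, int],
    widths: Sequence[int],
    tolerance: float = 0.05,
    base_width: "int | None" = None,
) -> BinSizeEvaluation:
    """Score candidate bin widths by the AIC of a block-smoothed Poisson
    count model.

    Counts at a common base resolution (default: the gcd of the candidate
    widths) are modelled as Poisson observations of a latent rate that is
    constant within each candidate bin — i.e. the candidate binning acts as
    a block-average smoother of the base-resolution signal.  AIC =
    -2 log L + 2 x effective parameters, where the effective parameters
    equal the trace of the block smoother (= the number of candidate
    bins).  Small bins overfit sampling noise and pay the parameter
    penalty; bins much wider than the genuine rate structure underfit it
    and pay in likelihood, so the AIC minimum tracks the scale of real
    signal variation.

    Widths within ``tolerance`` of the minimum (as a fraction of the
    observed AIC range) are flagged as the selected range.  Widths
    exceeding the longest contig are skipped with a warning.
    """
    if len(widths) < 2:
        raise ValueError("need at least 2 candidate widths")
    longest = max(lengths.values())
    usable = []
    for width in widths:
        if width > longest:
            warnings.warn(f"bin width {width} exceeds longest contig; skipped")
        else:
            usable.append(int(width))
    if not usable:
        raise ValueError("no usable bin widths")
    if base_width is None:
        base_width = int(np.gcd.reduce(usable))
    base_part = GenomePartition(lengths, base_width)
    base = bin_counts(sites, base_part).df
    c = base["count"].to_numpy(dtype=float)
    base_len = (base["end"] - base["start"]).to_numpy(dtype=float)
    base_contig = base["contig"].to_numpy()
    base_start = base["start"].to_numpy()

    rows = []
    for width in dict.fromkeys(usable):
        part = GenomePartition(lengths, width)
        ids = part.bin_ids(base_contig, base_start)
        block_counts = np.bincount(ids, weights=c, minlength=part.n_bins)
        block_len = np.bincount(ids, weights=base_len, minlength=part.n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate_bp = np.where(block_len > 0, block_counts / block_len, 0.0)
        lam = rate_bp[ids] * base_len
        loglik = float(sps.poisson.logpmf(c, np.maximum(lam, 1e-300)).sum())
        eff_params = float(part.n_bins)  # trace of the block-average smoother
        rows.append(
            {
                "width": width,
                "n_bins": part.n_bins,
                "loglik": loglik,
                "eff_params": eff_params,
                "aic": -2.0 * loglik + 2.0 * eff_params,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no usable bin widths")
    aic = table["aic"].to_numpy()
    span = aic.max() - aic.min()
    cutoff = aic.min() + tolerance * span if span > 0 else aic.min()
    selected = table.loc[aic <= cutoff, "width"].astype(int).tolist()
    best = int(table.loc[aic.argmin(), "width"])
    return BinSizeEvaluation(table, selected, best)


def hot_cold_spots(
    track: RelativeAbundanceTrack,
    hot_percentile: float = 99.99,
    cold_percentile: float = 0.01,
    min_bins: int = 10_000,
) -> tuple[FeatureTrack, FeatureTrack]:
    """Bins above/below extreme relative-abundance percentiles.

    Strict inequalities, so a constant track yields empty sets.  With fewer
    than ``min_bins`` usable bins the default thresholds would select
    nothing meaningful, so they are scaled to 1/n tails with a warning.
    """
    df = track.df
    ok = ~df["value"].isna()
    values = df.loc[ok, "value"].to_numpy()
    if values.size == 0:
        raise ValueError("all bins missing")
    if values.size < min_bins and (hot_percentile >= 99.99 or cold_percentile <= 0.01):
        hot_percentile = min(hot_percentile, 100.0 * (1.0 - 1.0 / values.size))
        cold_percentile = max(cold_percentile, 100.0 / values.size)
        warnings.warn(
            f"only {values.size} usable bins; percentile thresholds scaled to "
            f"{cold_percentile:.4g}/{hot_percentile:.6g}"
        )
    hot_thr = np.percentile(values, hot_percentile)
    cold_thr = np.percentile(values, cold_percentile)
    sub = df.loc[ok]
    hot = sub[sub["value"] > hot_thr]
    cold = sub[sub["value"] < cold_thr]

    def to_track(name, d):
        return FeatureTrack(
            name,
            [GenomicInterval(r.contig, r.start, r.end) for r in d.itertuples()],
            scores=list(d["value"]),
        )

    return to_track("hot_spots", hot), to_track("cold_spots", cold)


def fraction_negative_per_contig(track: RelativeAbundanceTrack) -> pd.Series:
    """Per-contig fraction of non-missing bins with negative relative
    abundance (depleted relative to naked DNA)."""
    df = track.df
    if len(df) == 0:
        raise ValueError("empty track")
    ok = df[~df["value"].isna()]
    return ok.groupby("contig", sort=False)["value"].apply(lambda v: float((v < 0).mean()))


@dataclass
class ProfileMatrix:
    """Per-gene, per-bin damage counts over an anchored, oriented window."""

    anchor: str
    flank: int
    binsize: int
    offsets: np.ndarray  # left edge of each bin relative to the anchor
    matrix: np.ndarray  # genes x bins, read-support counts
    gene_names: list[str]
    total_support: int  # sample-wide support, for CPM scaling

    @property
    def mean_profile(self) -> np.ndarray:
        """Mean per-gene damage rate per bin (counts per million called
        sites), the aggregate metagene curve."""
        scale = 1e6 / self.total_support if self.total_support else 0.0
        return self.matrix.mean(axis=0) * scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_rate": self.mean_profile}
        )


def _anchor_positions(genes: pd.DataFrame, anchor: str) -> np.ndarray:
    plus = genes["strand"].to_numpy() == "+"
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    if anchor == "TSS":
        return np.where(plus, start, end - 1)
    if anchor == "TES":
        return np.where(plus, end - 1, start)
    raise ValueError("anchor must be 'TSS' or 'TES'")


def _profile_counts(
    sites_df: pd.DataFrame,
    genes: pd.DataFrame,
    anchor: str,
    flank: int,
    binsize: int,
    site_strand_filter=None,
) -> tuple[np.ndarray, np.ndarray]:
    nbins = 2 * flank // binsize
    matrix = np.zeros((len(genes), nbins))
    anchors = _anchor_positions(genes, anchor)
    offsets = np.arange(-flank, flank, binsize)
    by_contig = {
        contig: sub.sort_values("pos") for contig, sub in sites_df.groupby("contig")
    }
    gene_strands = genes["strand"].to_numpy()
    gene_contigs = genes["contig"].to_numpy()
    for gi in range(len(genes)):
        sub = by_contig.get(gene_contigs[gi])
        if sub is None:
            continue
        a = anchors[gi]
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [a - flank, a + flank])
        if lo == hi:
            continue
        window = sub.iloc[lo:hi]
        p = window["pos"].to_numpy()
        w = window["read_support"].to_numpy().astype(float)
        if site_strand_filter is not None:
            keep = site_strand_filter(gene_strands[gi], window["strand"].to_numpy())
            p, w = p[keep], w[keep]
        if p.size == 0:
            continue
        o = p - a if gene_strands[gi] == "+" else a - p
        keep = (o >= -flank) & (o < flank)
        b = (o[keep] + flank) // binsize
        matrix[gi] += np.bincount(b.astype(int), weights=w[keep], minlength=nbins)
    return offsets, matrix


def metagene_profile(
    sites,
    genes: pd.DataFrame,
    anchor: str = "TSS",
    flank: int = 2_000,
    binsize: int = 25,
) -> ProfileMatrix:
    """Damage profile around gene anchors, oriented 5'->3' of each gene
    (upstream on the left), pooling damage from both strands."""
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of the bin size")
    df = getattr(sites, "df", sites)
    offsets, matrix = _profile_counts(df, genes, anchor, flank, binsize)
    return ProfileMatrix(
        anchor,
        flank,
        binsize,
        offsets,
        matrix,
        list(genes["name"]),
        int(df["read_support"].sum()),
    )


def ts_nts_profile(
    sites,
    genes: pd.DataFrame,
    anchor: str = "TSS",
    flank: int = 2_000,
    binsize: int = 25,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Strand-resolved metagene profiles: (transcribed, non-transcribed).

    The transcribed strand is the template: the - strand for a + gene."""
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of the bin size")
    df = getattr(sites, "df", sites)
    total = int(df["read_support"].sum())

    def ts_filter(gene_strand, site_strands):
        return site_strands != gene_strand

    def nts_filter(gene_strand, site_strands):
        return site_strands == gene_strand

    out = []
    for f in (ts_filter, nts_filter):
        offsets, matrix = _profile_counts(df, genes, anchor, flank, binsize, f)
        out.append(
            ProfileMatrix(anchor, flank, binsize, offsets, matrix, list(genes["name"]), total)
        )
    return out[0], out[1]


@dataclass
class StrandBiasResult:
    per_gene: pd.DataFrame  # name, ts, nts
    ratio: float  # pooled TS / NTS
    pvalue: float  # two-sided Wilcoxon signed-rank across genes
    n_genes: int


def ts_nts_bias(sites, genes: pd.DataFrame) -> StrandBiasResult:
    """Damage counts on transcribed vs non-transcribed strands of gene
    bodies, with a paired Wilcoxon signed-rank test across genes.

    For a gene transcribed from the + strand, the transcribed (template)
    strand is the - strand, so TS = minus-strand sites in the body.
    """
    df = getattr(sites, "df", sites)
    ts = np.zeros(len(genes))
    nts = np.zeros(len(genes))
    by_contig = {
        contig: sub.sort_values("pos") for contig, sub in df.groupby("contig")
    }
    for gi, gene in enumerate(genes.itertuples(index=False)):
        sub = by_contig.get(gene.contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [gene.start, gene.end])
        if lo == hi:
            continue
        window = sub.iloc[lo:hi]
        support = window["read_support"].to_numpy().astype(float)
        template = window["strand"].to_numpy() != gene.strand
        ts[gi] = support[template].sum()
        nts[gi] = support[~template].sum()
    per_gene = pd.DataFrame({"name": genes["name"], "ts": ts, "nts": nts})
    any_damage = (ts + nts) > 0
    if not any_damage.any():
        raise ValueError("no gene contains any damage")
    total_nts = nts.sum()
    ratio = float(ts.sum() / total_nts) if total_nts > 0 else np.inf
    diffs = ts[any_damage] - nts[any_damage]
    if np.all(diffs == 0):
        pvalue = 1.0
    else:
        try:
            pvalue = float(sps.wilcoxon(ts[any_damage], nts[any_damage]).pvalue)
        except ValueError:
            pvalue = 1.0
    return StrandBiasResult(per_gene, ratio, pvalue, int(any_damage.sum()))


def loess_smooth(values, span: float = 0.3, x=None) -> np.ndarray:
    """LOESS-smoothed copy of a signal (presentation only, never feeds
    statistics downstream).  NaNs are ignored during fitting and returned
    as NaN."""
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    if x is None:
        x = np.arange(values.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 10:
        raise ValueError("need at least 10 points")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(values[ok], x[ok], frac=span, return_sorted=False)
    out = np.full(values.shape, np.nan)
    out[ok] = fitted
    return out
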