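"""Trinucleotide damage signatures: context profiling, NMF extraction, and
comparison with 96-class substitution signatures.

A guanine monoadduct has 16 possible trinucleotide contexts (NGN); cancer
substitution signatures live in 96 classes (6 pyrimidine-centered base
changes x 16 flank pairs).  The damage profile over the 16 G-contexts is
compared to the 16 bars of a chosen substitution channel (e.g. C>A) by
mapping each G-centered triad onto the reverse complement C-centered triad
and taking the cosine of the unit-sum 16-vectors.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import BASES, GenomeIndex, revcomp
from .synthetic import G16_CONTEXTS

__all__ = [
    "ALL64_CONTEXTS",
    "G16_CONTEXTS",
    "SUBSTITUTION_CHANNELS",
    "SUBSTITUTION_CLASSES",
    "ContextProfile",
    "ReferenceSignature",
    "SignatureDecomposition",
    "context_counts",
    "genome_context_frequencies",
    "enrich_against_background",
    "context_matrix",
    "nmf_extract",
    "select_rank",
    "cosine_similarity",
    "compare_to_reference",
    "read_reference_signatures",
]

#: All 64 trinucleotide contexts, grouped by center base then ordered
#: lexicographically by (5' flank, 3' flank); the 16 G-centered contexts are
#: therefore contiguous.
ALL64_CONTEXTS: list[str] = [
    f + c + t for c in BASES for f in BASES for t in BASES
]

#: The six pyrimidine-centered substitution channels.
SUBSTITUTION_CHANNELS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 substitution classes, channel-major, flanks lexicographic.
SUBSTITUTION_CLASSES: list[str] = [
    f"{f}[{ch}]{t}" for ch in SUBSTITUTION_CHANNELS for f in BASES for t in BASES
]

_CTX_INDEX = {c: i for i, c in enumerate(ALL64_CONTEXTS)}


@dataclass
class ContextProfile:
    """Non-negative values over trinucleotide contexts.

    representation: 'all64' (damage at any center base) or 'g16' (guanine
    contexts only).  normalization: 'counts', 'frequency' (unit-sum) or
    'enrichment' (background-corrected, unit-sum).
    """

    values: pd.Series
    representation: str = "all64"
    normalization: str = "counts"

    def __post_init__(self):
        expected = ALL64_CONTEXTS if self.representation == "all64" else G16_CONTEXTS
        if self.representation not in ("all64", "g16"):
            raise ValueError(f"unknown representation {self.representation!r}")
        self.values = self.values.reindex(expected).fillna(0.0).astype(float)
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        if self.normalization in ("frequency", "enrichment"):
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("unit-sum profile does not sum to 1")

    def unit_sum(self) -> "ContextProfile":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        norm = "enrichment" if self.normalization == "enrichment" else "frequency"
        return ContextProfile(self.values / total, self.representation, norm)

    def g16(self) -> "ContextProfile":
        """Restrict to the 16 guanine-centered contexts."""
        if self.representation == "g16":
            return self
        vals = self.values.loc[G16_CONTEXTS]
        norm = self.normalization
        if norm in ("frequency", "enrichment") and abs(vals.sum() - 1.0) > 1e-9:
            norm = "counts"  # a subset of a unit-sum profile is no longer unit-sum
        return ContextProfile(vals, "g16", norm)

    def to_tsv(self, path: "str | Path") -> None:
        self.values.rename_axis("context").rename("value").to_csv(path, sep="\t")


def _triads_for_sites(df: pd.DataFrame, genome: GenomeIndex):
    """Damaged-strand triad index (into ALL64) per site; -1 where excluded
    (contig edge or N in the window)."""
    idx = np.full(len(df), -1, dtype=np.int64)
    contigs = df["contig"].to_numpy()
    pos = df["pos"].to_numpy()
    minus = df["strand"].to_numpy() == "-"
    from .core_io import BASE_INDEX

    for contig in pd.unique(df["contig"]):
        arr = genome.array(contig)
        b = BASE_INDEX[arr].astype(np.int64)
        n = arr.size
        sel = np.flatnonzero(contigs == contig)
        p = pos[sel]
        interior = (p >= 1) & (p <= n - 2)
        si = sel[interior]
        pi = p[interior]
        left, center, right = b[pi - 1], b[pi], b[pi + 1]
        ok = (left >= 0) & (center >= 0) & (right >= 0)
        f, c, t = left[ok], center[ok], right[ok]
        m = minus[si][ok]
        # minus strand: triad on the damaged strand = revcomp of the window
        f2 = np.where(m, 3 - t, f)
        c2 = np.where(m, 3 - c, c)
        t2 = np.where(m, 3 - f, t)
        idx[si[ok]] = c2 * 16 + f2 * 4 + t2
    return idx


def context_counts(
    sites, genome: GenomeIndex, representation: str = "all64"
) -> ContextProfile:
    """Read-support-weighted triad counts at called sites.

    Triads are read 5'->3' on the damaged strand (minus-strand windows are
    reverse-complemented); sites at contig edges or with N in the window
    are excluded.  'g16' keeps only sites whose called base is G.
    """
    df = getattr(sites, "df", sites)
    if len(df) == 0:
        raise ValueError("empty site set")
    idx = _triads_for_sites(df, genome)
    ok = idx >= 0
    if not ok.any():
        raise ValueError("no usable sites (all at edges or in N context)")
    weights = df["read_support"].to_numpy().astype(float) if "read_support" in df else np.ones(len(df))
    counts = np.bincount(idx[ok], weights=weights[ok], minlength=64)
    series = pd.Series(counts, index=ALL64_CONTEXTS)
    profile = ContextProfile(series, "all64", "counts")
    return profile.g16() if representation == "g16" else profile


def genome_context_frequencies(
    genome: GenomeIndex, representation: str = "all64"
) -> ContextProfile:
    """Triad frequencies over every genomic position on both strands (the
    availability background for enrichment correction)."""
    from .core_io import BASE_INDEX

    counts = np.zeros(64)
    for contig in genome.contigs:
        b = BASE_INDEX[genome.array(contig)].astype(np.int64)
        f, c, t = b[:-2], b[1:-1], b[2:]
        ok = (f >= 0) & (c >= 0) & (t >= 0)
        fwd = c[ok] * 16 + f[ok] * 4 + t[ok]
        counts += np.bincount(fwd, minlength=64)
        rev = (3 - c[ok]) * 16 + (3 - t[ok]) * 4 + (3 - f[ok])
        counts += np.bincount(rev, minlength=64)
    series = pd.Series(counts, index=ALL64_CONTEXTS)
    profile = ContextProfile(series, "all64", "counts")
    if representation == "g16":
        profile = profile.g16()
    return profile.unit_sum()


def enrich_against_background(
    raw: ContextProfile, background: ContextProfile
) -> ContextProfile:
    """Observed triad frequency divided by availability, renormalized.

    value_t = (count_t / sum counts) / (background_t / sum background),
    then unit-sum.  Observed triads with zero background frequency are an
    error.
    """
    if raw.representation != background.representation:
        raise ValueError("profile and background representations differ")
    obs = raw.values / raw.values.sum()
    bg = background.values / background.values.sum()
    observed = obs > 0
    if (bg[observed] <= 0).any():
        zero = list(obs.index[observed & (bg <= 0)])
        raise ValueError(f"observed triads absent from background: {zero}")
    enr = np.where(bg > 0, obs / bg.replace(0, np.nan), 0.0)
    enr = pd.Series(np.nan_to_num(enr), index=obs.index)
    enr = enr / enr.sum()
    return ContextProfile(enr, raw.representation, "enrichment")


def context_matrix(
    sites,
    genome: GenomeIndex,
    representation: str = "g16",
    correct_background: bool = True,
) -> pd.DataFrame:
    """Per-sample context profiles as a contexts x samples matrix.

    Default: background-corrected unit-sum G16 profiles, the input used for
    signature extraction.
    """
    df = getattr(sites, "df", sites)
    background = (
        genome_context_frequencies(genome, representation) if correct_background else None
    )
    cols = {}
    for sample, sub in df.groupby("sample", sort=False):
        profile = context_counts(sub, genome, representation)
        if correct_background:
            profile = enrich_against_background(profile, background)
        else:
            profile = profile.unit_sum()
        cols[sample] = profile.values
    return pd.DataFrame(cols)


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (|a| |b|) for non-negative profiles; in [0, 1]."""
    a = np.asarray(getattr(a, "values", a), dtype=float).ravel()
    b = np.asarray(getattr(b, "values", b), dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SignatureDecomposition:
    """NMF factor pair over a sample cohort.

    W: contexts x k signatures (columns unit-sum); H: k x samples relative
    contributions (columns unit-sum).  Signatures are ordered by their
    contribution in the background (untreated) sample, descending, so the
    background-like signature comes first and the damage-like signature
    last.
    """

    W: pd.DataFrame
    H: pd.DataFrame
    reconstruction_error: float
    k: int
    seed: int
    background_sample: "str | None" = None
    rank_table: "pd.DataFrame | None" = None

    def __post_init__(self):
        if (self.W.to_numpy() < -1e-12).any() or (self.H.to_numpy() < -1e-12).any():
            raise ValueError("NMF factors must be non-negative")

    @property
    def background_signature(self) -> pd.Series:
        return self.W.iloc[:, 0]

    @property
    def damage_signature(self) -> pd.Series:
        return self.W.iloc[:, -1]


def _nmf_once(V: np.ndarray, k: int, seed: int, max_iter: int):
    from sklearn.decomposition import NMF

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(
            n_components=k,
            init="random",
            random_state=seed,
            max_iter=max_iter,
            tol=1e-10,
        )
        W = model.fit_transform(V)
        H = model.components_
    err = float(np.linalg.norm(V - W @ H))
    return W, H, err


def nmf_extract(
    profiles: pd.DataFrame,
    k: "int | None" = 2,
    k_range: "Sequence[int] | None" = None,
    n_restarts: int = 50,
    seed: int = 0,
    background_sample: "str | None" = None,
    max_iter: int = 2000,
) -> SignatureDecomposition:
    """Factorize a contexts x samples profile matrix into k signatures.

    Runs ``n_restarts`` randomly initialized fits (Frobenius objective) and
    keeps the lowest reconstruction error; restart ties break toward the
    lowest restart seed.  With ``k_range``, the rank is chosen by restart
    stability (mean silhouette of clustered restart signatures) combined
    with the reconstruction-error elbow (see :func:`select_rank`).
    """
    V = profiles.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("profile matrix must be non-negative")
    n_contexts, n_samples = V.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rank_table = None
    if k_range is not None:
        k, rank_table = select_rank(
            profiles, k_range, n_restarts=n_restarts, seed=seed
        )
    if k is None:
        raise ValueError("give k or k_range")
    if k >= min(n_contexts, n_samples):
        raise ValueError(
            f"k={k} must be < min(contexts, samples) = {min(n_contexts, n_samples)}"
        )
    best = None
    for r in range(n_restarts):
        W, H, err = _nmf_once(V, k, seed + r, max_iter)
        if best is None or err < best[2] - 1e-15:
            best = (W, H, err, seed + r)
    W, H, err, used_seed = best

    # scale-normalize: signatures to unit sum, contributions to unit column sum
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    hsum = H.sum(axis=0)
    hsum[hsum == 0] = 1.0
    H = H / hsum

    samples = list(profiles.columns)
    if background_sample is None:
        guesses = [s for s in samples if "untreated" in str(s).lower()]
        background_sample = guesses[0] if guesses else samples[0]
    if background_sample not in samples:
        raise ValueError(f"background sample {background_sample!r} not in cohort")
    bg_idx = samples.index(background_sample)
    order = np.argsort(-H[:, bg_idx], kind="stable")
    W, H = W[:, order], H[order]

    names = [f"S{i + 1}" for i in range(k)]
    return SignatureDecomposition(
        W=pd.DataFrame(W, index=profiles.index, columns=names),
        H=pd.DataFrame(H, index=names, columns=samples),
        reconstruction_error=err,
        k=k,
        seed=used_seed,
        background_sample=background_sample,
        rank_table=rank_table,
    )


def select_rank(
    profiles: pd.DataFrame,
    k_range: Sequence[int],
    n_restarts: int = 30,
    seed: int = 0,
    stability_min: float = 0.8,
    elbow_fraction: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Choose the NMF rank by restart stability plus the error elbow.

    For each k, restart signatures are pooled, clustered into k groups
    (k-means on unit-normalized columns) and scored by the mean cosine
    silhouette; the error drop from k-1 to k is measured against the
    norm of the data.  Selected: the largest k that is stable
    (silhouette >= ``stability_min``; k=1 counts as stable) and still buys
    a substantial error reduction (drop >= ``elbow_fraction`` x |V|).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    V = profiles.to_numpy(dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 for k in ks):
        raise ValueError("ranks must be >= 1")
    if max(ks) >= min(V.shape):
        raise ValueError("max rank must be < min(contexts, samples)")
    norm_v = float(np.linalg.norm(V))
    rows = []
    prev_err = norm_v  # error of the empty (k=0) model
    for k in ks:
        errs = []
        sigs = []
        for r in range(n_restarts):
            W, _, err = _nmf_once(V, k, seed + 1000 * k + r, max_iter=1000)
            errs.append(err)
            norms = np.linalg.norm(W, axis=0)
            norms[norms == 0] = 1.0
            sigs.append(W / norms)
        best_err = float(min(errs))
        if k == 1:
            stability = 1.0
        else:
            X = np.concatenate([s.T for s in sigs], axis=0)
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            stability = float(silhouette_score(X, km.labels_, metric="cosine"))
        rows.append(
            {
                "k": k,
                "error": best_err,
                "error_drop": prev_err - best_err,
                "stability": stability,
            }
        )
        prev_err = best_err
    table = pd.DataFrame(rows)
    eligible = table[
        (table["stability"] >= stability_min)
        & (table["error_drop"] >= elbow_fraction * norm_v)
    ]
    if len(eligible):
        selected = int(eligible["k"].max())
    else:
        selected = int(table.loc[table["stability"].idxmax(), "k"])
    return selected, table


# --- reference signatures ---------------------------------------------------


@dataclass
class ReferenceSignature:
    """A 96-class substitution signature (pyrimidine-centered convention)."""

    label: str
    values: pd.Series  # indexed by SUBSTITUTION_CLASSES, sums to 1

    def __post_init__(self):
        if len(self.values) != 96:
            raise ValueError(f"reference {self.label!r} must have 96 classes")
        self.values = self.values.reindex(SUBSTITUTION_CLASSES)
        if self.values.isna().any():
            raise ValueError(f"reference {self.label!r} has missing classes")
        total = self.values.sum()
        if total <= 0:
            raise ValueError("reference must have positive mass")
        self.values = self.values / total

    def channel(self, channel: str) -> pd.Series:
        """The 16 bars of one substitution channel, indexed by flank pair
        (5' base, 3' base) lexicographically."""
        if channel not in SUBSTITUTION_CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        keys = [f"{f}[{channel}]{t}" for f in BASES for t in BASES]
        out = self.values.loc[keys]
        out.index = [f + t for f in BASES for t in BASES]
        return out


def damage_to_channel_order(damage_g16: pd.Series) -> pd.Series:
    """Map a G-centered 16-context damage profile onto C-centered channel
    order via reverse complement: triad 5'f-G-t3' pairs with the mutation
    context revcomp(f G t) = comp(t)-C-comp(f)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    values = {}
    for triad, v in damage_g16.items():
        f, t = triad[0], triad[2]
        values[comp[t] + comp[f]] = float(v)
    keys = [f + t for f in BASES for t in BASES]
    return pd.Series([values[k] for k in keys], index=keys)


def compare_to_reference(
    damage_g16,
    references: "ReferenceSignature | Sequence[ReferenceSignature]",
    channels: Sequence[str] = SUBSTITUTION_CHANNELS,
) -> pd.DataFrame:
    """Cosine similarity of the damage profile against reference channels.

    The 16 G-context damage values are re-keyed into C-centered flank-pair
    order by reverse complement, unit-summed, and compared with each
    reference's unit-sum channel vector.  Returns a tidy frame
    (reference, channel, cosine), sorted by cosine descending.
    """
    if isinstance(damage_g16, ContextProfile):
        if damage_g16.representation != "g16":
            damage_g16 = damage_g16.g16()
        damage_g16 = damage_g16.values
    if isinstance(references, ReferenceSignature):
        references = [references]
    mapped = damage_to_channel_order(damage_g16)
    if mapped.sum() <= 0:
        raise ValueError("damage profile has no mass")
    mapped = mapped / mapped.sum()
    rows = []
    for ref in references:
        for ch in channels:
            bars = ref.channel(ch)
            if bars.sum() <= 0:
                continue
            bars = bars / bars.sum()
            rows.append(
                {
                    "reference": ref.label,
                    "channel": ch,
                    "cosine": cosine_similarity(mapped.to_numpy(), bars.to_numpy()),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values("cosine", ascending=False)
        .reset_index(drop=True)
    )


def read_reference_signatures(path: "str | Path") -> list[ReferenceSignature]:
    """Read 96-class signatures from TSV.

    Two dialects: (a) COSMIC-style with Type (e.g. C>A) and Subtype (e.g.
    ACA) columns plus one column per signature; (b) a plain table whose
    first column holds class labels like A[C>A]A with one column per
    signature.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "type" in cols and "subtype" in cols:
        classes = [
            f"{sub[0]}[{typ}]{sub[2]}"
            for typ, sub in zip(df[cols["type"]], df[cols["subtype"]])
        ]
        value_cols = [c for c in df.columns if c not in (cols["type"], cols["subtype"])]
    else:
        first = df.columns[0]
        classes = list(df[first])
        value_cols = list(df.columns[1:])
    out = []
    for c in value_cols:
        out.append(ReferenceSignature(c, pd.Series(list(df[c]), index=classes)))
    return out
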