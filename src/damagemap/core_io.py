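"""Genomic primitives and readers/writers for the formats the pipeline touches.

Coordinates are 0-based half-open (BED-native) everywhere in memory; 1-based
coordinates appear only in human-readable reports and in mutation-catalog
input files, which are converted on read.  Sequence is normalized to
uppercase A/C/G/T/N on load; anything else becomes N.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIndex",
    "GenomicInterval",
    "ReadRecord",
    "FeatureTrack",
    "BedParseError",
    "read_bed",
    "reads_from_bed",
    "reads_to_bed",
    "write_bedgraph",
    "read_bedgraph",
    "apply_blacklist",
    "load_genes",
    "revcomp",
]

# --- sequence normalization tables -----------------------------------------

_NORM = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGTN":
    _NORM[_b] = _b
    _NORM[_b + 32] = _b  # lowercase

_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y

# byte -> base index (A=0, C=1, G=2, T=3, N/other=-1)
BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    BASE_INDEX[_b] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC A/C/G/T/N string."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode("ascii")


def complement_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


class GenomeIndex:
    """Random-access reference sequence keyed by contig.

    Holds each contig as a normalized uint8 array in memory, which keeps
    per-site context extraction fully vectorized.  Construct from an
    in-memory mapping (synthetic genomes) or from a FASTA file.
    """

    def __init__(self, sequences: Mapping[str, "str | bytes | np.ndarray"]):
        self._arrays: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if isinstance(seq, str):
                raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            elif isinstance(seq, (bytes, bytearray)):
                raw = np.frombuffer(bytes(seq), dtype=np.uint8)
            else:
                raw = np.asarray(seq, dtype=np.uint8)
            if raw.size == 0:
                raise ValueError(f"contig {name!r} has length 0")
            arr = _NORM[raw]
            arr.setflags(write=False)
            self._arrays[name] = arr

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> list[str]:
        return list(self._arrays)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: arr.size for name, arr in self._arrays.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._arrays

    def length(self, contig: str) -> int:
        return self.array(contig).size

    def array(self, contig: str) -> np.ndarray:
        try:
            return self._arrays[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} not in genome") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the [start, end) sequence, uppercase A/C/G/T/N."""
        arr = self.array(contig)
        if not (0 <= start < end <= arr.size):
            raise ValueError(
                f"window {contig}:{start}-{end} outside contig of length {arr.size}"
            )
        return arr[start:end].tobytes().decode("ascii")

    def write_fasta(self, path: "str | Path", width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, arr in self._arrays.items():
                fh.write(f">{name}\n")
                seq = arr.tobytes().decode("ascii")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval with optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned fragment; the 5' end carries the damage information."""

    interval: GenomicInterval
    sample: str = "sample"

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError("reads must be stranded")

    @property
    def five_prime(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


class BedParseError(ValueError):
    pass


def read_bed(path: "str | Path") -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals (strand '.' when the column is absent).

    Malformed lines raise :class:`BedParseError` carrying the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1:3]}"
                ) from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return out


def reads_from_bed(path: "str | Path", sample: str = "sample") -> pd.DataFrame:
    """Load BED6 aligned fragments as a reads table.

    Columns: contig, start, end, strand, sample, five_prime.  A read's 5'
    end is ``start`` on the + strand and ``end - 1`` on the - strand.
    """
    ivs = read_bed(path)
    if any(iv.strand not in ("+", "-") for iv in ivs):
        raise BedParseError(f"{path}: reads require a strand column")
    df = pd.DataFrame(
        {
            "contig": [iv.contig for iv in ivs],
            "start": np.array([iv.start for iv in ivs], dtype=np.int64),
            "end": np.array([iv.end for iv in ivs], dtype=np.int64),
            "strand": [iv.strand for iv in ivs],
        }
    )
    df["sample"] = sample
    return attach_five_prime(df)


def attach_five_prime(reads: pd.DataFrame) -> pd.DataFrame:
    reads = reads.copy()
    reads["five_prime"] = np.where(
        reads["strand"].to_numpy() == "+",
        reads["start"].to_numpy(),
        reads["end"].to_numpy() - 1,
    )
    return reads


def reads_to_bed(reads: pd.DataFrame, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.sample}\t0\t{row.strand}\n"
            )


@dataclass
class FeatureTrack:
    """A named set of intervals (peaks, repeats, blacklist regions, ...).

    Intervals are sorted on construction; a merged per-contig representation
    backs all overlap queries.
    """

    name: str
    intervals: Sequence[GenomicInterval]
    scores: "Sequence[float] | None" = None
    _merged: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise ValueError("scores length must match intervals")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].contig,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        self.intervals = [self.intervals[i] for i in order]
        if self.scores is not None:
            self.scores = [self.scores[i] for i in order]
        self._merged = {}

    @classmethod
    def from_bed(cls, path: "str | Path", name: "str | None" = None) -> "FeatureTrack":
        return cls(name or Path(path).stem, read_bed(path))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_bp(self) -> int:
        total = 0
        for contig in {iv.contig for iv in self.intervals}:
            starts, ends = self.merged(contig)
            total += int((ends - starts).sum())
        return total

    def merged(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted, merged (starts, ends) arrays for one contig."""
        if contig not in self._merged:
            ivs = [iv for iv in self.intervals if iv.contig == contig]
            starts, ends = [], []
            for iv in ivs:  # already sorted
                if starts and iv.start <= ends[-1]:
                    ends[-1] = max(ends[-1], iv.end)
                else:
                    starts.append(iv.start)
                    ends.append(iv.end)
            self._merged[contig] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
        return self._merged[contig]

    def points_in(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each 0-based position fall inside the track?"""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends = self.merged(contig)
        if starts.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        hit = idx >= 0
        hit[hit] = positions[hit] < ends[idx[hit]]
        return hit

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        starts, ends = self.merged(iv.contig)
        if starts.size == 0:
            return False
        i = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return i >= 0 and ends[i] > iv.start

    def to_bed(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            for i, iv in enumerate(self.intervals):
                score = 0.0 if self.scores is None else self.scores[i]
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{self.name}\t{score:g}\t{iv.strand}\n"
                )


def apply_blacklist(items, blacklist: "FeatureTrack | None"):
    """Drop items overlapping a blacklist track.

    ``items`` may be a list of :class:`GenomicInterval` or a DataFrame with
    ``contig``/``pos`` columns (single-base sites).  Returns
    ``(kept, n_removed)``, preserving order.
    """
    if blacklist is None or len(blacklist) == 0:
        return items, 0
    if isinstance(items, pd.DataFrame):
        items = items.reset_index(drop=True)
        keep = np.ones(len(items), dtype=bool)
        contigs = items["contig"].to_numpy()
        pos = items["pos"].to_numpy()
        for contig in pd.unique(items["contig"]):
            sel = np.flatnonzero(contigs == contig)
            keep[sel] = ~blacklist.points_in(contig, pos[sel])
        return items.loc[keep].reset_index(drop=True), int((~keep).sum())
    kept_list = [iv for iv in items if not blacklist.overlaps_interval(iv)]
    return kept_list, len(items) - len(kept_list)


# --- bedGraph ---------------------------------------------------------------


def write_bedgraph(
    track,
    path: "str | Path",
    value_col: str = "rate",
    lengths: "Mapping[str, int] | None" = None,
) -> None:
    """Write one line per non-missing bin: contig, start, end, value.

    ``track`` is a BinTrack-like object exposing ``.df`` or a DataFrame with
    contig/start/end plus the value column.  NaN values (missing bins) are
    skipped.  Values are written with 6 decimals so a read/write round trip
    preserves them to that precision.
    """
    df = getattr(track, "df", track)
    if lengths is not None:
        unknown = set(df["contig"]) - set(lengths)
        if unknown:
            raise ValueError(f"unknown contigs in track: {sorted(unknown)}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            value = getattr(row, value_col)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{value:.6f}\n")


def read_bedgraph(path: "str | Path") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            rows.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


# --- gene models ------------------------------------------------------------


def load_genes(path: "str | Path") -> pd.DataFrame:
    """Load gene bodies with strand from BED6/BED12 or a headered TSV.

    The TSV dialect needs columns contig, tss, tes, strand (tss/tes are
    1-based positions of the first/last transcribed base; name optional).
    Returns a DataFrame with contig, start, end, name, strand where
    [start, end) is the 0-based gene body oriented genomically.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header = first.rstrip("\n").split("\t")
    if "tss" in [h.lower() for h in header]:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        for col in ("contig", "tss", "tes", "strand"):
            if col not in df.columns:
                raise ValueError(f"gene TSV missing column {col!r}")
        plus = df["strand"] == "+"
        start = np.where(plus, df["tss"] - 1, df["tes"] - 1)
        end = np.where(plus, df["tes"], df["tss"])
        out = pd.DataFrame(
            {
                "contig": df["contig"],
                "start": start.astype(np.int64),
                "end": end.astype(np.int64),
                "name": df.get("name", pd.Series([f"gene{i}" for i in range(len(df))])),
                "strand": df["strand"],
            }
        )
    else:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise BedParseError(
                        f"{path}:{lineno}: gene BED needs >= 6 columns"
                    )
                rows.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
        out = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand"])
    bad = ~out["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("genes must be stranded (+/-)")
    if (out["start"] >= out["end"]).any():
        raise ValueError("gene with start >= end")
    return out.reset_index(drop=True)


def genes_to_bed(genes: pd.DataFrame, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")
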