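"""Single-nucleotide intersection of damage calls with mutation catalogs.

A mutation record is strand-agnostic while a guanine adduct is strand
aware, so matching uses the G:C pair rule: damage on either strand at the
mutation's coordinate counts (a minus-strand G adduct corresponds to a
C-position mutation record on the reference strand).  Replication support
is summarized per exposure condition: replicate read support is summed,
and a match is flagged ``multi_condition`` when damage appears in at least
two conditions and ``multi_read`` when at least one condition accumulates
two or more reads across its replicates.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_mutations", "match_sites", "recurrence_rank"]

_VALID_BASES = set("ACGT")


def read_mutations(path: "str | Path") -> pd.DataFrame:
    """Load a mutation catalog from TSV or minimal VCF.

    TSV dialect (headered): chrom, pos (1-based), ref, alt, patients, gene.
    Positions are converted to the internal 0-based convention on read.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##") or first.startswith("#CHROM"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]) - 1, f[3], f[4], 1, "."))
        df = pd.DataFrame(
            rows, columns=["contig", "pos", "ref", "alt", "recurrence", "gene"]
        )
    else:
        raw = pd.read_csv(path, sep="\t")
        raw.columns = [c.lower() for c in raw.columns]
        chrom = "chrom" if "chrom" in raw.columns else "contig"
        df = pd.DataFrame(
            {
                "contig": raw[chrom],
                "pos": raw["pos"].astype(np.int64) - 1,
                "ref": raw["ref"].str.upper(),
                "alt": raw["alt"].str.upper(),
                "recurrence": raw.get("patients", pd.Series(np.ones(len(raw)))).astype(int),
                "gene": raw.get("gene", pd.Series(["."] * len(raw))),
            }
        )
    bad = (df["ref"] == df["alt"]) | ~df["ref"].isin(_VALID_BASES) | ~df["alt"].isin(_VALID_BASES)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} invalid mutation records (ref/alt)")
    return df.reset_index(drop=True)


def match_sites(
    sites,
    mutations: pd.DataFrame,
    sample_conditions: "Mapping[str, str] | None" = None,
    contigs: "list[str] | None" = None,
) -> pd.DataFrame:
    """Aggregate damage support at each mutation position.

    ``sites`` is a DamageSiteSet or site table with a ``sample`` column;
    ``sample_conditions`` maps sample labels to exposure conditions
    (replicates of one condition share a value; default: each sample is
    its own condition).  Returns one row per mutation with per-condition
    support columns, sorted by (multi_read, multi_condition, total
    support) descending.
    """
    df = getattr(sites, "df", sites)
    if sample_conditions is None:
        sample_conditions = {s: s for s in df["sample"].unique()}
    universe = set(contigs) if contigs is not None else set(df["contig"].unique())
    stray = set(mutations["contig"].unique()) - universe
    if stray:
        raise ValueError(
            "mutation catalog contigs not present in the damage data: "
            f"{sorted(stray)} (known: {sorted(universe)})"
        )
    damage = df.copy()
    damage["condition"] = damage["sample"].map(lambda s: sample_conditions.get(s, s))
    # G:C pair rule: collapse strands at each coordinate
    support = (
        damage.groupby(["contig", "pos", "condition"], sort=False)["read_support"]
        .sum()
        .reset_index()
    )
    conditions = sorted(set(sample_conditions.values()))
    wide = (
        support.pivot_table(
            index=["contig", "pos"],
            columns="condition",
            values="read_support",
            fill_value=0,
        )
        .reindex(columns=conditions, fill_value=0)
        .astype(int)
    )
    merged = mutations.merge(
        wide, how="left", left_on=["contig", "pos"], right_index=True
    )
    cond_cols = [c for c in conditions]
    merged[cond_cols] = merged[cond_cols].fillna(0).astype(int)
    support_mat = merged[cond_cols].to_numpy()
    merged["n_conditions"] = (support_mat > 0).sum(axis=1)
    merged["total_support"] = support_mat.sum(axis=1)
    merged["multi_condition"] = merged["n_conditions"] >= 2
    merged["multi_read"] = (support_mat >= 2).any(axis=1)
    merged = merged.rename(columns={c: f"support:{c}" for c in cond_cols})
    return merged.sort_values(
        ["multi_read", "multi_condition", "total_support"],
        ascending=False,
        kind="mergesort",
    ).reset_index(drop=True)


def recurrence_rank(matches: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Annotate each match with its recurrence percentile in the catalog.

    Percentile = 100 x fraction of catalog records with recurrence <= the
    match's recurrence, so the most recurrent site scores 100.
    """
    cat = np.sort(catalog["recurrence"].to_numpy())
    out = matches.copy()
    ranks = np.searchsorted(cat, out["recurrence"].to_numpy(), side="right")
    out["recurrence_percentile"] = 100.0 * ranks / len(cat)
    return out
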