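"""End-to-end orchestration: simulate -> call -> distribution -> signatures
-> match, from a single validated config, with a checksummed output
manifest and per-stage logging of every filtering step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import calling, distribution, matching, signatures, synthetic
from .core_io import FeatureTrack, GenomeIndex, load_genes, reads_from_bed, write_bedgraph

log = logging.getLogger("damagemap")

__all__ = ["RunConfig", "SimulateConfig", "run_all", "load_config"]


class SimulateConfig(BaseModel):
    genome_length: int = 1_000_000
    gc: float = 0.41
    gc_sd: float = 0.05
    n_sites: int = 20_000
    doses: dict[str, float] = Field(
        default_factory=lambda: {"0.25uM": 0.4, "0.5uM": 0.55, "1uM": 0.7, "2uM": 0.8}
    )
    ndna_purity: float = 0.9
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

    def to_cohort_config(self, seed: int) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(
            genome_length=self.genome_length,
            gc=self.gc,
            gc_sd=self.gc_sd,
            n_sites=self.n_sites,
            doses=tuple(self.doses.items()),
            ndna_purity=self.ndna_purity,
            n_replicates=self.n_replicates,
            n_reads=self.n_reads,
            read_length=self.read_length,
            n_open_regions=self.n_open_regions,
            open_region_length=self.open_region_length,
            n_genes=self.n_genes,
            gene_length=self.gene_length,
            open_region_survival=self.open_region_survival,
            ts_survival=self.ts_survival,
            premature_stall_fraction=self.premature_stall_fraction,
            background_g_bias=self.background_g_bias,
            seed=seed,
        )

    @property
    def n_samples(self) -> int:
        return 1 + len(self.doses) * self.n_replicates + 1  # untreated + doses + nDNA


class RunConfig(BaseModel):
    """Validated run configuration; every default is echoed into the run
    manifest so each output is reproducible from the manifest alone."""

    seed: int = 0
    simulate: Optional[SimulateConfig] = SimulateConfig()
    genome_fasta: Optional[str] = None
    reads: dict[str, str] = Field(default_factory=dict)  # sample -> BED6 path
    sample_conditions: dict[str, str] = Field(default_factory=dict)
    blacklist: Optional[str] = None
    features: dict[str, str] = Field(default_factory=dict)  # name -> BED path
    genes: Optional[str] = None
    mutations: Optional[str] = None
    references: Optional[str] = None

    bin_width: int = 10_000
    candidate_bin_widths: list[int] = Field(
        default_factory=lambda: [5_000, 10_000, 20_000, 50_000, 100_000]
    )
    epsilon: float = 1.0
    hot_percentile: float = 99.99
    cold_percentile: float = 0.01
    flank: int = 2_000
    profile_bin: int = 25
    nmf_k: Optional[int] = 2
    nmf_k_range: Optional[list[int]] = None
    nmf_restarts: int = 50

    @model_validator(mode="after")
    def _check(self):
        if self.simulate is None and not self.reads:
            raise ValueError("config needs either a simulate section or reads paths")
        if self.simulate is None and self.genome_fasta is None:
            raise ValueError("reads input requires genome_fasta")
        if self.flank % self.profile_bin != 0:
            raise ValueError("flank must be a multiple of profile_bin")
        n_samples = (
            self.simulate.n_samples if self.simulate is not None else len(self.reads)
        )
        if self.nmf_k is not None and self.nmf_k >= n_samples:
            raise ValueError(
                f"nmf_k={self.nmf_k} must be < number of samples ({n_samples})"
            )
        if self.nmf_k_range is not None and max(self.nmf_k_range) >= n_samples:
            raise ValueError("max of nmf_k_range must be < number of samples")
        return self


def load_config(path: "str | Path") -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: RunConfig,
    out_dir: "str | Path",
    seed: "int | None" = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every configured stage; returns the output manifest.

    Deterministic for a fixed (config, seed).  With ``resume=True`` a stage
    whose outputs already exist is skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed

    # fail before stage 1 on missing inputs, aggregated
    missing = []
    for label, path in [
        ("genome_fasta", config.genome_fasta),
        ("blacklist", config.blacklist),
        ("genes", config.genes),
        ("mutations", config.mutations),
        ("references", config.references),
        *[(f"reads:{s}", p) for s, p in config.reads.items()],
        *[(f"feature:{n}", p) for n, p in config.features.items()],
    ]:
        if path is not None and not Path(path).exists():
            missing.append(f"{label}: {path}")
    if missing:
        raise FileNotFoundError("missing inputs:\n  " + "\n  ".join(missing))

    outputs: list[Path] = []

    def record(path: Path) -> Path:
        outputs.append(path)
        return path

    # --- stage 1: simulate or load ----------------------------------------
    sim_dir = out / "simulated"
    if config.simulate is not None:
        if resume and (sim_dir / "manifest.tsv").exists():
            log.info("simulate: resume, reusing %s", sim_dir)
            cohort = None
            genome = GenomeIndex.from_fasta(sim_dir / "genome.fa")
            manifest = pd.read_csv(sim_dir / "manifest.tsv", sep="\t")
            reads = {
                row["sample"]: reads_from_bed(sim_dir / row["path"], row["sample"])
                for _, row in manifest.iterrows()
            }
            open_regions = FeatureTrack.from_bed(sim_dir / "open_regions.bed", "open_chromatin")
            genes = load_genes(sim_dir / "genes.bed")
            conditions = dict(zip(manifest["sample"], manifest["condition"]))
        else:
            cohort = synthetic.make_cohort(
                config.simulate.to_cohort_config(seed), outdir=sim_dir
            )
            genome = cohort.genome
            reads = cohort.reads
            open_regions = cohort.open_regions
            genes = cohort.genes
            conditions = dict(
                zip(cohort.manifest["sample"], cohort.manifest["condition"])
            )
            log.info(
                "simulate: %d samples, %d planted sites",
                len(reads),
                len(cohort.truths["cell"]),
            )
        for p in sorted(sim_dir.glob("*")):
            record(p)
        features = {"open_chromatin": open_regions}
    else:
        genome = GenomeIndex.from_fasta(config.genome_fasta)
        reads = {s: reads_from_bed(p, s) for s, p in config.reads.items()}
        genes = load_genes(config.genes) if config.genes else None
        features = {}
        conditions = {s: config.sample_conditions.get(s, s) for s in reads}
    for name, path in config.features.items():
        features[name] = FeatureTrack.from_bed(path, name)
    blacklist = (
        FeatureTrack.from_bed(config.blacklist, "blacklist")
        if config.blacklist
        else None
    )

    # --- stage 2: damage calling ------------------------------------------
    call_dir = out / "sites"
    call_dir.mkdir(exist_ok=True)
    site_sets: dict[str, calling.DamageSiteSet] = {}
    for sample, rd in reads.items():
        sites = calling.call_damage_sites(rd, genome, blacklist)
        site_sets[sample] = sites
        st = sites.stats
        log.info(
            "call[%s]: %d reads -> %d sites (%d out of bounds, %d blacklisted, "
            "collision rate %.3f)",
            sample, st.n_reads, st.n_sites, st.n_out_of_bounds,
            st.n_blacklisted, st.collision_rate,
        )
        sites.write_bed(record(call_dir / f"{sample}.bed"))
        comp = calling.composition_at_offsets(sites, genome)
        comp.to_csv(record(call_dir / f"{sample}.composition.tsv"), sep="\t")

    # --- stage 3: distribution --------------------------------------------
    dist_dir = out / "distribution"
    dist_dir.mkdir(exist_ok=True)
    samples = list(site_sets)
    ndna_samples = [s for s in samples if conditions.get(s) == "nDNA"]
    cell_samples = [
        s for s in samples
        if conditions.get(s) not in ("nDNA", "untreated")
    ]
    if ndna_samples and cell_samples:
        part = distribution.GenomePartition.from_genome(genome, config.bin_width)
        ndna_track = distribution.bin_counts(site_sets[ndna_samples[0]], part)
        # highest-support exposed sample as the headline cell condition
        cell_sample = max(cell_samples, key=lambda s: site_sets[s].total_support())
        cell_track = distribution.bin_counts(site_sets[cell_sample], part).add_gc(genome)
        for name, feat in features.items():
            cell_track.add_feature_coverage(feat, name)
        ra = distribution.relative_abundance(cell_track, ndna_track, config.epsilon)
        write_bedgraph(cell_track, record(dist_dir / "cell_rate.bedgraph"), "rate")
        write_bedgraph(ndna_track, record(dist_dir / "ndna_rate.bedgraph"), "rate")
        write_bedgraph(ra, record(dist_dir / "relative_abundance.bedgraph"), "value")
        corr_rows = []
        for name in ["gc", *features.keys()]:
            res = distribution.correlate(ra.df["value"], cell_track.df[name])
            corr_rows.append(
                {"feature": name, "rho": res.coefficient, "n": res.n, "p": res.pvalue}
            )
        pd.DataFrame(corr_rows).to_csv(
            record(dist_dir / "correlations.tsv"), sep="\t", index=False
        )
        ev = distribution.evaluate_bin_sizes(
            site_sets[cell_sample], genome.lengths, config.candidate_bin_widths
        )
        ev.table.to_csv(record(dist_dir / "bin_size_aic.tsv"), sep="\t", index=False)
        hot, cold = distribution.hot_cold_spots(
            ra, config.hot_percentile, config.cold_percentile
        )
        hot.to_bed(record(dist_dir / "hot_spots.bed"))
        cold.to_bed(record(dist_dir / "cold_spots.bed"))
        distribution.fraction_negative_per_contig(ra).rename("fraction_negative").to_csv(
            record(dist_dir / "fraction_negative.tsv"), sep="\t"
        )
        if genes is not None and len(genes):
            prof = distribution.metagene_profile(
                site_sets[cell_sample], genes, "TSS", config.flank, config.profile_bin
            )
            prof.to_frame().to_csv(
                record(dist_dir / "metagene_tss.tsv"), sep="\t", index=False
            )
            ts_prof, nts_prof = distribution.ts_nts_profile(
                site_sets[cell_sample], genes, "TSS", config.flank, config.profile_bin
            )
            pd.DataFrame(
                {
                    "offset": ts_prof.offsets,
                    "ts_rate": ts_prof.mean_profile,
                    "nts_rate": nts_prof.mean_profile,
                }
            ).to_csv(record(dist_dir / "ts_nts_profile.tsv"), sep="\t", index=False)
            bias = distribution.ts_nts_bias(site_sets[cell_sample], genes)
            pd.DataFrame(
                [{"ratio": bias.ratio, "pvalue": bias.pvalue, "n_genes": bias.n_genes}]
            ).to_csv(record(dist_dir / "ts_nts_bias.tsv"), sep="\t", index=False)
            log.info(
                "distribution: TS/NTS ratio %.3f (p=%.2e, %d genes)",
                bias.ratio, bias.pvalue, bias.n_genes,
            )

    # --- stage 4: signatures ------------------------------------------------
    sig_dir = out / "signatures"
    sig_dir.mkdir(exist_ok=True)
    all_sites = calling.DamageSiteSet.concat(list(site_sets.values()))
    profiles = signatures.context_matrix(all_sites, genome, "g16")
    profiles.rename_axis("context").to_csv(record(sig_dir / "profiles_g16.tsv"), sep="\t")
    background_sample = next(
        (s for s in samples if conditions.get(s) == "untreated"), samples[0]
    )
    decomp = signatures.nmf_extract(
        profiles,
        k=config.nmf_k,
        k_range=config.nmf_k_range,
        n_restarts=config.nmf_restarts,
        seed=seed,
        background_sample=background_sample,
    )
    decomp.W.rename_axis("context").to_csv(record(sig_dir / "signatures.tsv"), sep="\t")
    decomp.H.rename_axis("signature").to_csv(
        record(sig_dir / "contributions.tsv"), sep="\t"
    )
    meta = {
        "k": decomp.k,
        "reconstruction_error": decomp.reconstruction_error,
        "seed": decomp.seed,
        "background_sample": decomp.background_sample,
    }
    (sig_dir / "nmf_meta.json").write_text(json.dumps(meta, indent=2))
    record(sig_dir / "nmf_meta.json")
    log.info("signatures: k=%d, reconstruction error %.4g", decomp.k, decomp.reconstruction_error)
    if config.references:
        refs = signatures.read_reference_signatures(config.references)
        report = signatures.compare_to_reference(decomp.damage_signature, refs)
        report.to_csv(record(sig_dir / "reference_cosine.tsv"), sep="\t", index=False)

    # --- stage 5: matching ---------------------------------------------------
    if config.mutations:
        muts = matching.read_mutations(config.mutations)
        matches = matching.match_sites(
            all_sites, muts, conditions, contigs=genome.contigs
        )
        matches = matching.recurrence_rank(matches, muts)
        match_dir = out / "matches"
        match_dir.mkdir(exist_ok=True)
        matches.to_csv(record(match_dir / "damage_mutation_matches.tsv"), sep="\t", index=False)
        log.info(
            "match: %d/%d mutation sites with damage support",
            int((matches["total_support"] > 0).sum()), len(matches),
        )

    # --- manifest -------------------------------------------------------------
    manifest = pd.DataFrame(
        {
            "file": [str(p.relative_to(out)) for p in outputs],
            "sha256": [_sha256(p) for p in outputs],
        }
    ).sort_values("file", kind="mergesort").reset_index(drop=True)
    config_echo = out / "run_config.json"
    config_echo.write_text(
        json.dumps({"seed": seed, **json.loads(config.model_dump_json())}, indent=2)
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
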