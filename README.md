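# damagemap

Strand-aware analysis of **damage-seq** experiments: sequencing libraries in
which a high-fidelity polymerase stalls at a bulky DNA adduct (e.g. the
benzo[a]pyrene metabolite adduct *N*²-BPDE-dG on guanine), so that the
lesion sits at the **−1 position relative to each read start** on the read's
strand. From aligned read 5′ ends, `damagemap`:

- calls single-base, strand-resolved damage sites and reports
  base-composition diagnostics around them (including the −2 premature-stall
  check);
- quantifies the genomic distribution of damage in fixed-width bins against
  an exposed naked-DNA (nDNA) reference via the **relative abundance**
  log₂(cell/nDNA), with Spearman correlations to GC content and feature
  tracks (open chromatin, histone marks, repeats), AIC-guided bin-size
  evaluation, hot/cold-spot extraction at extreme percentiles, 25 bp
  metagene profiles, and transcribed- vs non-transcribed-strand (TS/NTS)
  bias with a paired Wilcoxon test;
- builds **trinucleotide damage signatures**: a guanine monoadduct has 16
  possible NGN contexts; per-sample context frequencies are corrected for
  genomic triad availability and decomposed by non-negative matrix
  factorization (NMF) into a library-background signature and a damage
  signature, whose 16 bars can be compared (cosine similarity, after
  reverse-complement mapping G-centered triads onto C-centered ones) with
  any channel of a 96-class substitution signature;
- matches damage sites to mutation catalogs at single-nucleotide
  resolution under a G:C-pair rule with replication-support flags;
- ships a **synthetic-data generator** that plants adducts with a
  configurable context preference, open-chromatin depletion, transcribed-
  strand depletion, read purity, background G bias and a premature-stall
  fraction — and records every planted site in a truth ledger, so the whole
  pipeline is testable against known ground truth.

## The model in brief

For a read on the + strand with 5′ end at *p*, the lesion is called at
*p* − 1 on +; for a − strand read with 5′ end at *p*, at *p* + 1 on −, with
the damaged-strand base being the complement of the reference. Per-bin
damage rates are counts per million called sites; the relative abundance in
bin *i* is

```
RA_i = log2( (cell_rate_i + ε) / (nDNA_rate_i + ε) ),   ε = 1 by default
```

(positive = cellular accumulation, negative = depletion relative to naked
DNA). The damage signature is the unit-sum vector over the 16 NGN contexts
of (observed triad frequency) / (genomic triad frequency), and cohorts are
decomposed as `V ≈ W·H` with non-negative `W` (contexts × k signatures) and
`H` (k × samples contributions), `k` fixed or chosen by restart stability
plus the reconstruction-error elbow.

## Worked example

```python
from damagemap import calling, signatures, synthetic

cfg = synthetic.CohortConfig(
    genome_length=500_000, n_sites=10_000,
    doses=(("0.5uM", 0.5), ("2uM", 0.8)), n_reads=30_000,
    n_open_regions=40, n_genes=100, seed=42,
)
cohort = synthetic.make_cohort(cfg)

for sample in ["untreated", "0.5uM_r1", "2uM_r1", "nDNA"]:
    sites = calling.call_damage_sites(cohort.reads[sample], cohort.genome)
    comp = calling.composition_at_offsets(sites, cohort.genome, offsets=[0])
    print(f"{sample:10s}  sites={len(sites):6d}  G at damage position = {comp.loc[0,'G']:.3f}")

all_sites = calling.DamageSiteSet.concat(
    [calling.call_damage_sites(r, cohort.genome) for r in cohort.reads.values()]
)
profiles = signatures.context_matrix(all_sites, cohort.genome, "g16")
decomp = signatures.nmf_extract(profiles, k=2, seed=0, background_sample="untreated")
print(decomp.H.round(3).to_string())
```

prints

```
untreated   sites= 29532  G at damage position = 0.298
0.5uM_r1    sites= 25086  G at damage position = 0.637
2uM_r1      sites= 17089  G at damage position = 0.831
nDNA        sites= 14201  G at damage position = 0.902

    untreated  0.5uM_r1  2uM_r1   nDNA
S1      0.812     0.331   0.232  0.218
S2      0.188     0.669   0.768  0.782
```

The untreated library shows the ~30% background G bias at the called
position; the G fraction climbs with exposure dose and is highest in naked
DNA, where neither chromatin nor repair shapes the landscape. The NMF
contribution matrix `H` shows signature S1 (background) dominating the
untreated sample and the damage signature S2 growing monotonically with
dose — its top contexts here are CGG/CGA/CGC, the planted CpG-flavoured
preference.

## Command line

```bash
damagemap --seed 7 --out-dir demo_out run-all --config configs/demo.yaml
damagemap call --reads reads.bed --genome genome.fa --blacklist bl.bed --out sites.bed
damagemap signature --sites cell=sites.bed --genome genome.fa --refs cosmic.tsv --k 2
```

`run-all` executes simulate → call → distribution → signature → match from
one YAML config and writes a checksummed manifest; reruns with the same
config and seed are byte-identical.

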