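# replidamage

Where does replication-stress DNA damage land on the genome? When the
histone methyltransferase PR-Set7 (Set8) is depleted, Drosophila cells
lose H4K20 monomethylation and accumulate DNA damage marked by
phosphorylated H2A.v (γ-H2A.v, the fly γ-H2AX). `replidamage` is a
pipeline for the genomic side of that question: it quantifies
ChIP-seq/BrdU-seq signal over genomic bins, contrasts conditions, calls
broad damage domains, and asks whether those domains sit in
late-replicating chromatin.

It is written for genomicists who have aligned reads (as BED intervals),
a replication-timing profile, and annotations, and who want a tested,
deterministic implementation of this analysis chain:

1. **coverage** — bin the genome (sliding 10 kb/1 kb or non-overlapping
   5 kb windows), count reads by fragment midpoint, normalize to RPKM
   (reads per kilobase of bin per million mapped reads), average
   replicates, compute replicate/condition Pearson correlations;
2. **diffsignal** — scale samples on the top 5% of bins and compute the
   per-bin differential
   `d_i = log2(treatment RPKM_i + 1) − log2(control RPKM_i + 1)`;
3. **hmm** — segment `d` with a two-state hidden Markov model with
   Gaussian emissions `N(μ_k, σ_k²)`, trained by Baum–Welch over all
   chromosomes jointly and decoded with Viterbi into discrete
   positive/negative domains (with BIC model selection against a
   one-state null so pure noise yields no domains);
4. **domains** — reciprocal overlap counts against late-replicating
   domains, the per-5 kb-bin Pearson correlation between `d` and
   replication timing, and a metadomain profile (each domain rescaled to
   50 inner bins plus 25 equal-width flanks per side);
5. **profiles** — strand-aware aggregate profiles around TSS or origin
   anchors, and a genic/intergenic signal partition with a rank-sum
   test;
6. **synthetic** — a generator of small genomes with planted timing
   domains, TSS, origins, and simulated reads from a piecewise-constant
   enrichment intensity, so the whole pipeline runs and is tested
   without any external data.

See `docs/methods.md` for the model details, parameter defaults, and
limitations.

## Worked example

Simulate the standard fixture (two 10 Mb chromosomes, five 200–400 kb
late-replicating domains each, γ-H2A.v duplicates with 4-fold
enrichment inside late domains after depletion) and run the damage arm:

```python
from replidamage.synthetic import default_fixture
from replidamage.pipeline import PipelineConfig, run_damage_analysis

genome, files = default_fixture("demo_fixture", seed=11)
cfg = PipelineConfig(
    chrom_sizes=files["chrom_sizes"],
    reads={
        "control": [files["reads:gh2av_control_rep1"],
                    files["reads:gh2av_control_rep2"]],
        "treatment": [files["reads:gh2av_depleted_rep1"],
                      files["reads:gh2av_depleted_rep2"]],
    },
    timing_bedgraph=files["timing"],
    timing_domains_bed=files["timing_domains"],
    out_dir="demo_results",
)
manifest = run_damage_analysis(cfg)
print("positive domains:", manifest["n_positive_domains"])
print("late domains hit:", manifest["late_domain_overlap"])
print("timing correlation:", round(manifest["timing_correlation"]["r"], 3))
print("state means:", [round(m, 2) for m in manifest["hmm"]["means"]])
```

prints

```
positive domains: 10
late domains hit: {'n_query': 10, 'n_reference': 10, 'n_query_hit': 10, 'n_reference_hit': 10}
timing correlation: -0.952
state means: [-0.52, 1.44]
```

All ten planted late-replicating domains are recovered as γ-H2A.v-type
positive domains (and every called domain overlaps a late domain); the
log2-difference track is strongly anticorrelated with replication timing
(damage goes where replication is late); and the fitted emission means
separate the background state (−0.52 — negative because per-million
normalization pushes the treatment background down when late domains
soak up reads) from the damage state (+1.44 ≈ the planted 4-fold
enrichment after renormalization). `demo_results/` contains the RPKM and
log2-difference bedGraphs, the domain BED, the metadomain table, and a
JSON manifest with parameters, replicate correlations and output
checksums.

The same thing from the shell:

```sh
replidamage simulate --out-dir demo_fixture --seed 11
replidamage run-damage --config run.yaml --out demo_results
```

plus `run-h4k20me1` (early/late S-phase scaling, TSS aggregate,
genic/intergenic partition) and `run-origins` (BrdU condition
correlation matrix, origin-anchored profile), and the single-stage
subcommands `coverage`, `diff`, `segment`, `profile`.

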