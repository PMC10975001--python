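# hausflow

Analysis pipeline for information exchange between a root hemiparasite and
its host, built around a four-compartment design: intact parasite root
(`TH`), parasite-side chimera (`THC`), host-side chimera (`PC`) and intact
host root (`P`), with biological replicates per compartment.

Stages:

- **dam_screen** — differential-metabolite screening: group-mean log2 fold
  change plus OPLS-DA variable-importance-in-projection (VIP) scores;
  a feature is differential when VIP ≥ 1 and |log2FC| ≥ 1. Also PCA quality
  checks, cross-comparison co-regulation classes, exact hypergeometric
  enrichment, and a Welch-test upregulation predicate.
- **origin_assign** — unigene-to-genome assignment from tabular alignment
  hits (best bitscore per genome, e-value ≤ 1e-10) or a built-in canonical
  k-mer containment classifier.
- **mobility** — direction-classified transferred metabolites (undetected in
  exactly one intact compartment, detected in the other three) and mobile
  genes (FPKM < 3 in one intact compartment, ≥ 3 in the other three).
- **haustoria_network** — haustoria-formation gene selection (upregulated in
  both chimeras, intact-root FPKM < 0.3) and the gene–metabolite Pearson
  network (|r| > 0.80, p < 0.05, both strict).
- **synthetic_data** — four-compartment experiment generator with planted,
  exactly recoverable ground truth (mobile genes, transferred metabolites,
  haustoria genes, differential metabolites, correlated pairs, genomes and
  unigene sequences).
- **io_formats / pipeline / cli** — TSV feature tables (missing-cell
  dialects, thousands separators), 12-column alignment tables, FASTA,
  SIF/TSV edge export, YAML-configured end-to-end runs.

Bundled under `hausflow/data/` are small published summary tables (one
aggregate value per compartment) used as desk-scale fixtures: the
five-compound transferred-metabolite intensities, the 50 mobile-gene FPKM
rows, the 44 chimera-induced genes and the 56 co-regulated metabolites.

## CLI

```bash
# generate a synthetic experiment with ground truth
hausflow simulate --seed 1 --out sim/

# full pipeline from a YAML config (see PipelineConfig for keys)
hausflow all --config pipeline.yaml --out results/

# individual stages
hausflow dam --metabolites m.tsv --samples map.tsv --compare TH:THC --compare P:PC --out dams/
hausflow assign --unigenes u.fasta --genome-a parasite.fa --genome-b host.fa --out origins.tsv
hausflow mobility --genes g.tsv --metabolites m.tsv --samples map.tsv --out calls/
hausflow network --genes g.tsv --metabolites m.tsv --samples map.tsv --out net/
```

Sample-to-compartment maps are two-column TSV (`sample_id<TAB>compartment`);
alternatively sample ids of the form `TH_1`, `PC2` are parsed directly.

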