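# clcfam

Analysis toolkit for the CLC anion channel/transporter gene family:

* **family_identification** — read proteomes (FASTA), locate Voltage_CLC and
  CBS domains either by ingesting HMMER3 per-domain tables (`domtblout`) or
  with a built-in log-odds profile scanner (Gumbel-calibrated E-values), and
  filter candidates at an E-value cutoff (default `1e-10`). Isoforms collapse
  to the longest sequence per locus.
* **protein_properties** — length, molecular weight (average residue masses),
  isoelectric point (Henderson–Hasselbalch net charge, Bjellqvist pKa set,
  bisection), GRAVY (Kyte–Doolittle), and a documented hydropathy-window
  transmembrane-segment heuristic (window 19, threshold 1.6 — descriptive
  output, not an HMM predictor).
* **motif_classification** — locates the conserved regions `GxGIPE` (I),
  `GKxGPxxH` (II) and `PxxGxLF` (III); the region-I wildcard residue calls
  anion selectivity (P → NO3⁻, S → Cl⁻), and the gating glutamate (region II)
  plus proton glutamate (4 residues past region III) call antiporter vs
  channel. A column-anchored alignment mode is available.
* **phylo_reconciliation** — Newick I/O, a simplified conserved-block
  alignment filter, p/Poisson distances, neighbor joining (midpoint-rooted),
  LCA gene-tree/species-tree reconciliation with duplication and loss
  calling, clade-absence reports and ortholog-based gene naming.
* **expression_anion_stats** — 2^−ΔΔCT fold changes from Ct tables (technical
  replicates averaged before biological statistics), classical one-way ANOVA,
  Tukey HSD with compact letter display, treatment-vs-control ratios, and
  Pearson correlation matrices with significance stars.
* **synthetic_data** — generators for planted-signal proteomes,
  duplication–loss gene histories inside a species tree, and Ct/measurement
  tables; every fixture ships with a ground-truth manifest.
* **pipeline / cli** — YAML-config orchestration of all stages with
  provenance (parameters, seed, input checksums).

All residue coordinates are 1-based inclusive.

## CLI

```sh
clcfam identify  --fasta proteome.fasta --e-cutoff 1e-10 --out outdir/
clcfam properties --fasta candidates.fasta --out properties.tsv
clcfam classify  --fasta candidates.fasta --out classification.tsv
clcfam blockfilter --aln aln.fasta --out blocks.fasta
clcfam reconcile --gene-tree g.nwk --species-tree s.nwk --map leafmap.tsv --out outdir/
clcfam expression --ct ct.csv --ref PgActin --out outdir/
clcfam anova --table measurements.csv --out outdir/
clcfam correlate --table samples.csv --out outdir/
clcfam simulate proteome --seed 1 --n-true 7 --n-decoy 20 --out fixture/
clcfam run --config pipeline.yaml
```

A pipeline config is a YAML file with `outdir`, an `inputs` mapping
(`proteome_fasta`, optional `domtbl`, `gene_tree`/`species_tree`/`leaf_map`,
`ct_table`, `measurement_table`, ...), and optional parameter overrides
(`e_cutoff`, `alpha`, `proton_offset`, `block_filter`, `seed`, ...). Stages
with missing optional inputs are skipped with a logged notice.

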