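# mitocub

Codon usage bias analysis for mitochondrial and nuclear genomes:

- **RSCU** (relative synonymous codon usage) per gene or per genome, with a
  configurable family policy (sixfold families split into fourfold + twofold
  sub-families by default; single-codon families excluded).
- **ENc–GC3 neutrality analysis**: Wright's effective number of codons per
  gene, synonymous-sites GC3, the neutral expectation
  `g(s) = 2 + s + 29/(s² + (1−s)²)`, the relative deviation
  `(expected − observed)/expected`, and the R² fit of a gene cloud against
  the curve.
- **Correspondence analysis** of gene-level RSCU matrices (eigenvalues,
  percent inertia, row/column principal coordinates and contributions) and
  **hierarchical clustering** of genome-level RSCU profiles with Newick
  output.
- **tRNA adaptation**: per-codon relative adaptiveness `wi` from tRNA gene
  copy numbers under wobble constraints, gene-level tAI, the
  translational-selection **S statistic** (correlation of tAI with ENc
  deviation) and its **permutation test** (wi values shuffled over codons;
  top-5% significance rule), plus an optional hill-climbing optimizer for
  the wobble constraint vector.
- **tRNAome decodability** under explicit wobble rules (strict / crick /
  extended-with-inosine) and a wobble-versatility check per codon family.
- **Synthetic data generators** for gene sets with controlled per-gene GC3,
  tunable selection strength toward a supplied tRNA pool, and tRNAomes with
  full or sparse decoding coverage — used for calibration and testing.

Mitochondrial genes default to NCBI translation table 4 (`mold_mito`,
UGA = Trp), nuclear genes to table 1 (`standard`); both are configurable,
and custom 64-codon tables can be loaded from plain-text files. Reported
"mean RSCU" values are unweighted means over gene-level vectors.

## CLI

```bash
mitocub rscu genes.fasta --code mold_mito --out rscu.tsv
mitocub enc genes.fasta --out enc.tsv
mitocub ca genes.fasta --out-prefix ca
mitocub cluster genomeA.fasta genomeB.fasta genomeC.fasta --out dendro.nwk
mitocub stest genes.fasta --trna trna.tsv --n-perm 100 --seed 42
mitocub decode --trna trna.tsv --code mold_mito --rules crick
mitocub simulate --scenario selected --out-fasta genes.fasta --out-trna trna.tsv
mitocub run --config run.yaml --out results/
```

`mitocub run` executes the whole battery per genome from a YAML config
(CDS FASTA or GenBank input, tRNA counts as TSV `anticodon  amino_acid
copy_number` or from GenBank tRNA features) and writes a bundle of TSVs,
a Newick dendrogram and a `manifest.json` carrying the seed and config
hash; identical config + inputs give byte-identical bundles. Exit codes:
0 ok, 2 config error, 3 data error.

Example `run.yaml`:

```yaml
genomes:
  - id: genomeA
    organelle: mito
    genbank: genomeA.gb        # or cds_fasta: + trna_tsv:
codes: {mito: mold_mito, nuclear: standard}
n_perm: 100
seed: 42
out_dir: results
```

## Layout

```
src/mitocub/
  codon_core.py      genetic codes, synonymous families, codon counting
  sequence_io.py     FASTA / GenBank / tRNA-TSV / result-table IO
  cub_metrics.py     RSCU, GC/GC3, ENc, neutral curve, deviation
  multivariate.py    correspondence analysis, hierarchical clustering
  trna_selection.py  wi, tAI, S statistic, permutation test, optimizer
  wobble.py          wobble rules, decodability, versatility check
  synthetic_data.py  gene-set and tRNAome simulators, packaged scenarios
  pipeline.py        config validation and the end-to-end report bundle
  cli.py             click-based command line
  data/              default wobble constraint values (editable TSV)
```
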