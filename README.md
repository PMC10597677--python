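# pufascreen

Tools for detecting long-chain polyunsaturated fatty acid (LC-PUFA)
biosynthesis genes of bdelloid-rotifer origin in crustacean transcriptome
assemblies, and for characterizing what those genes can do.

The package covers six analysis stages plus a synthetic-data generator:

| module | what it does |
| --- | --- |
| `pufascreen.fattyacids` | Fatty-acid shorthand (`20:5n-3`), Δ-position derivation, and a desaturation/elongation reaction network with reachability ("can this enzyme set make EPA?") |
| `pufascreen.motifs` | Six-frame ORF extraction and classification of translations into enzyme families (front-end desaturase, methyl-end desaturase, elongase) by diagnostic histidine-box / HPGG motif rules |
| `pufascreen.cox1` | cox1 DNA-barcode contamination screen: k-mer read recruitment, local-alignment identity against a reference panel, strict >75% positivity rule |
| `pufascreen.identity` | Deterministic global percent-identity and per-gene identity matrices between samples |
| `pufascreen.genestructure` | Exon–intron organization from GFF3, GT–AG splice-site checks, polypyrimidine tracts, introner-like classification |
| `pufascreen.conversion` | GC-FID peak-area conversion arithmetic for single-enzyme yeast assays |
| `pufascreen.simulate` | Seeded synthetic samples and genome fixtures with exact truth files |

## CLI

Everything is under one entry point:

```bash
# synthetic fixtures (FASTA + truth JSON)
pufascreen simulate sample --profile freshwater --seed 7 --out fw/
pufascreen simulate genome --seed 1 --out gen/

# gene screen: candidates FASTA, evidence + per-family summary TSV, JSON report
pufascreen screen-genes --in fw/sample.fasta --min-codons 100 --out-prefix out/fw

# cox1 contamination screen (bundled synthetic panel used when --panel omitted)
pufascreen screen-cox1 --contigs fw/sample.fasta --threshold 75 --min-len 100

# per-gene identity between two samples
pufascreen identity --set A=a.fasta --set B=b.fasta --pair A,B

# exon-intron organization and intron features
pufascreen structure --genome gen/genome.fasta --gff gen/annotation.gff3

# pathway reachability with a reaction path (exit 0 iff reachable)
pufascreen pathway --activities bdelloid_characterized --precursor 18:1n-9 --target 20:5n-3

# conversion percentages from a (fatty_acid, area) TSV
pufascreen conversion --areas run.tsv --enzyme elovl25

# orchestrated run over several samples
pufascreen full --sample fw=fw/sample.fasta --sample ma=ma/sample.fasta --out-dir results/
```

Activity presets (`bdelloid_characterized`, `elovl25`, `fed_d5`, `fed_d6`,
`wx`) ship in `pufascreen/data/activity_presets.json`; `--activities` also
accepts a JSON file with the same layout.

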