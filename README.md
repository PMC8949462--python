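# acaryopan

Toolkit for comparative analysis of small collections of closely related
bacterial genomes (built around *Acaryochloris*-like study designs): reference
pan-genome construction from reciprocal homology searches, core-genome
phylogeny, topology-congruence tests for horizontal gene transfer, binary
trait reconstruction, functional-profile clustering with multiscale-bootstrap
support, and growth-rate comparison across treatments. A seeded synthetic-data
generator with full ground truth drives an end-to-end, byte-reproducible
pipeline.

## Components

| module | contents |
|---|---|
| `acaryopan.alignment` | affine-gap Smith–Waterman (numba), k-mer seeding, Karlin–Altschul E-values |
| `acaryopan.homology` | gene-vs-genome (blastn-style) and protein-vs-six-frame-reference (tblastn-style) searches |
| `acaryopan.pangenome` | two-direction presence calls, core / strict-core / unique-core sets, Venn partition |
| `acaryopan.phylo` | neighbor joining, GTR+Γ(+I) pruning likelihood, branch-length optimization, bootstrap |
| `acaryopan.congruence` | Shimodaira–Hasegawa test via RELL resampling, HGT verdicts |
| `acaryopan.traits` | Hartigan (Fitch) and Dollo parsimony, trait covariation |
| `acaryopan.profiles` | Euclidean average-linkage clustering with multiscale-bootstrap AU support |
| `acaryopan.growth` | exponential-window growth rates, 3-doublings rule, Welch tests with BH correction |
| `acaryopan.synthetic` | seeded genome-collection generator with known gene gains/losses, HGT cassette, trait events, OD curves |
| `acaryopan.pipeline` / `acaryopan.cli` | staged pipeline with config + checksummed manifest; `acaryopan` CLI |

## Worked example

Run the whole pipeline on a small simulated collection (4 ingroup strains
`T01..T04`, 2 outgroups):

```bash
cat > config.json <<'EOF'
{"seed": 3, "sim_n_ingroup": 4, "sim_n_outgroup": 2, "sim_n_genes": 16,
 "sim_mean_gene_len": 600, "bootstrap_B": 200, "au_B_per_scale": 40}
EOF
acaryopan run --config config.json --out out/
```

This writes one directory per stage (`simulate/`, `search/`, `pangenome/`,
`tree/`, `shtest/`, `traits/`, `ironclust/`, `growth/`) plus a
`manifest.json` with the config hash and a SHA-256 checksum of every output
file. Reruns with the same config are byte-identical.

Selected actual outputs from the run above:

`out/pangenome/core_summary.json` — core genes present in ≥ n−1 ingroup
strains, strict core in all, unique core absent from both outgroups:

```json
{
  "n_core": 11,
  "n_strict_core": 10,
  "n_unique_core": 6
}
```

`out/tree/species_tree.nwk` — core-genome NJ tree with bootstrap support:

```
(T04:1,(T03:0,(T01:0,T02:0)100:0)100:1)100;
```

`out/shtest/shtest.json` — the transferred cassette (genes
`hgt0000,hgt0001,hgt0002`) rejects the species topology:

```json
{
  "delta_lnl_species": 10.04,
  "gene": "hgt0000,hgt0001,hgt0002",
  "p_species": 0.015,
  "verdict": "incongruent (consistent with HGT)"
}
```

`out/traits/trait_events.tsv` — parsimony gain/loss placements:

```
trait          method  branch        event
plasmid_block  fitch   T04           gain
plasmid_block  dollo   T01|T02|T03   loss
```

Individual stages are also exposed as subcommands, e.g.:

```bash
acaryopan search --direction nt --reference out/simulate/T01 \
    --target out/simulate/T02            # 12-column tabular hits on stdout
acaryopan tree --alignment out/tree/core_alignment.fasta
acaryopan shtest --species sp.fasta --gene gene.fasta -B 1000
acaryopan growth --od out/simulate/od.tsv --out growth/
```

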