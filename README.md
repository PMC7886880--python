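# indelmark

Development of agarose-resolvable InDel markers from whole-genome
re-sequencing of two breeding parents.

## The problem

Cultivated cucumber (and many other crops) has a narrow genetic base, so
distinguishing breeding lines, verifying F1 hybrid seed lots and building
phylogenies need cheap, co-dominant DNA markers. Insertion/deletion (InDel)
polymorphisms between the two parents of a hybrid variety are ideal raw
material: a PCR primer pair flanking an InDel amplifies a different-sized
product from each parent, a true F1 shows **both** bands, and when the two
alleles differ by more than 30 bp the bands separate on a plain 2% agarose
gel — no polyacrylamide equipment required.

`indelmark` turns two parent-versus-reference InDel call sets (VCF or TSV)
plus the reference genome (FASTA) into a table of designed markers, and
provides the downstream analyses a breeding program needs:

- **discovery** — left-aligned, parsimonious InDel normalization; derivation
  of the InDels polymorphic *between* the parents (present in exactly one of
  them); per-chromosome density (InDels/Mb) and size-class accounting
  (small 1–10 bp, medium 11–20 / 21–30 bp, large >30 bp);
- **design** — 150 bp flank extraction, exhaustive primer scan under the
  marker-development constraints (primer 18–28 bp, Tm 57–63 °C by the
  SantaLucia nearest-neighbor model, product 80–300 bp on the reference
  allele), in-silico PCR per parental allele, agarose/polyacrylamide gel
  classification at the 30 bp cutoff;
- **genotyping statistics** — allele frequencies, gene diversity
  `1 − Σp_i²`, Botstein's PIC `1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`, observed
  heterozygosity, Nei's minimum genetic distance
  `mean_loci[(J_X + J_Y)/2 − J_XY]`, and UPGMA dendrograms (Newick out);
- **hybrid-seed purity** — per-seedling classification
  (true hybrid / selfed / off-type / missing) from co-dominant band calls
  and the batch purity percentage;
- **simulation** — reference genomes, parents with planted InDels (with
  ground-truth tables), genotype panels with group structure, and F1 seed
  lots with contaminants, so every stage can be validated against known
  truth.

## Worked example

Simulate two parents, then run the full report chain:

```sh
indelmark simulate --seed 7 --n-a-only 40 --n-b-only 20 --n-shared 10 --outdir demo
indelmark report --reference demo/reference.fasta \
    --calls-a demo/parentA.vcf --calls-b demo/parentB.vcf --outdir demo/report
```

The log ends with

```
report complete: 60 loci, 59 with primers
```

60 loci is exactly the planted 40 + 20 parent-unique events (the 10 shared
InDels are invisible between the parents and correctly excluded).
`demo/report/discovery_summary.tsv` starts

```
section	name	count	density_or_percent
chromosome	Chr1	13	130.0
chromosome	Chr2	9	90.0
```

i.e. 13 cross-parent InDels on the 100 kb Chr1 = 130.0 InDels/Mb. A designed
agarose-class row of `demo/report/markers.tsv` looks like

```
InDel002  Chr1  15223  47  large  agarose  CAGGAATTGTAGATTCGTGTATTCGCGT  GGGAGAGCTTATCTCGTTTCCTACGA  60.11  60.05  269  222
```

a 47 bp insertion carried by parent A: the primer pair (Tm 60.11/60.05 °C)
amplifies 269 bp from parent A and 222 bp from parent B — the sizes differ
by exactly the planted 47 bp, well above the 30 bp agarose threshold, so a
true hybrid shows the 222 + 269 double band.

The same analyses are importable as a library
(`indelmark.derive_cross_parent`, `indelmark.design_markers`,
`indelmark.panel_summary`, `indelmark.upgma`, `indelmark.batch_purity`, ...);
see `docs/methods.md` for the underlying models and choices.

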