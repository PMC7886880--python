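# Methods

## Scope and data flow

The pipeline starts *after* variant calling: its inputs are a reference
genome and two parent-versus-reference InDel call sets (VCF 4.x subset —
CHROM/POS/REF/ALT only — or a four-column TSV). Read mapping, duplicate
marking and caller-level filtering are upstream concerns; the package trusts
the calls it is given. Coordinates are 1-based with the VCF anchor-base
convention throughout; only pure InDels (one allele a strict prefix of the
other) are retained, and SNVs or complex substitutions are skipped with a
logged count.

## Cross-parent InDel discovery

Two call sets against the same reference are compared on the canonical
representation of each event: left-aligned through any repeat context and
trimmed to a single anchor base (the standard parsimony/left-alignment
normalization; `bcftools norm` is used as an independent oracle in the test
suite). An InDel whose canonical key appears in exactly one parent is
polymorphic between the parents — at that position the other parent matches
the reference — and becomes a marker candidate with that parent as carrier.
Identical keys in both parents are shared ancestral variation and are
excluded. When the parents carry two *different* alleles at the same
canonical anchor the locus is kept (`both_distinct`) with
`allele_size_diff = |length_A − length_B|`, because the two products remain
distinguishable by size; if the two alleles happen to have equal lengths the
locus is sequence- but not length-polymorphic and is dropped with a log
message — a PCR band cannot resolve it.

Size classes partition |length|: small 1–10 bp, medium 11–20 and 21–30 bp,
large >30 bp. Density is `count / length_Mb` reported to one decimal, both
per chromosome and in total. Output ordering is deterministic:
(chromosome, position, carrier, alt allele).

## Marker design

**Template.** 150 bases of reference sequence upstream of the anchor, the
reference allele, and 150 bases downstream (flanks shortened with a warning
at chromosome ends; for `both_distinct` loci the centre spans the longer
reference allele).

**Melting temperature.** Unified nearest-neighbor thermodynamics
(SantaLucia 1998 ΔH/ΔS table), duplex of the primer with its exact
complement, primer in excess: `Tm = 1000·ΔH / (ΔS_salt + R·ln(CT/4)) −
273.15` with `ΔS_salt = ΔS + 0.368·(N−1)·ln[Na+]`, at fixed 50 mM
monovalent salt and 500 nM total primer, no divalent correction. These
conditions are frozen so designs are reproducible and testable; the test
suite cross-checks against an independent NN implementation to <0.1 °C.

**Primer selection.** Exhaustive scan: every 18–28-mer of the upstream flank
(forward) and every reverse complement of a downstream-flank 18–28-mer
(reverse), both therefore strictly outside the InDel allele so that both
parental alleles amplify. Pairs must satisfy Tm 57–63 °C and a
reference-allele product of 80–300 bp (product = end-to-end span including
both primers). Among surviving pairs the score
`|Tm_f − 60| + |Tm_r − 60| + |Tm_f − Tm_r| + GC-penalty + homopolymer-penalty`
is minimized, where the GC penalty is 1 per primer outside 40–60% GC and the
homopolymer penalty 1 per single-base run ≥5 within a primer. Ties break by
(smaller product, leftmost forward start, lexicographic sequences), making
the design a pure function of (template, constraints). Loci with no
qualifying pair return no primers (logged) and still appear in the marker
table with empty primer fields.

**In-silico PCR.** Exact string match of the forward primer and of the
reverse primer's reverse complement against each parental allele sequence;
a product is reported only when each primer has exactly one binding site in
the searched region (no single clean band otherwise). By construction
`|product_A − product_B|` equals the allele size difference; the alternate
allele's product may leave the 80–300 bp window (large insertions exceed
it, large deletions undershoot it) — the window is a constraint on the
reference allele only, matching how templates are screened before any
genotype is known.

**Gel class.** Agarose iff the allele size difference exceeds 30 bp, else
polyacrylamide. Primer uniqueness is checked within the template only;
genome-wide specificity screening is out of scope (empirical PCR validation
plays that role in practice).

## Panel statistics and phylogenetics

For each marker, allele frequencies count allele copies (homozygote 2,
heterozygote 1 + 1; missing excluded from the denominator). Gene diversity
is `1 − Σp_i²` with no small-sample correction; PIC is Botstein's
`1 − Σp_i² − Σ_{i<j} 2 p_i² p_j²` (always ≤ gene diversity — property
tested); observed heterozygosity is the fraction of non-missing lines with
two bands. Panel means are plain arithmetic means.

Nei's *minimum* genetic distance between lines X and Y is the mean over
shared non-missing loci of `(J_X + J_Y)/2 − J_XY`, with J the sums of
within-line allele-frequency products and within-line frequencies 1 (or
0.5/0.5 for a heterozygote). For fully inbred panels this reduces to the
simple mismatch proportion across loci, which the tests exploit as a
closed-form limit. The distance formula and the 0.5/0.5 heterozygote
weighting are the package's frozen reading of "Nei's minimum distance";
PowerMarker's exact conventions are not documented publicly, so this is the
single largest interpretive choice in the package.

UPGMA merges the closest pair of clusters, placing the merge node at height
d/2 and updating distances by the size-weighted arithmetic average; ties
break on the lexicographically smallest pair of member-label tuples, so the
tree is invariant to input order. The output (a scikit-bio `TreeNode`,
serialized as Newick) is ultrametric by construction; tests verify
ultrametry to 1e-9 and agreement of cophenetic distances with SciPy's
average-linkage clustering on random matrices.

The 0/1 allele-presence transform (one column per marker×band, heterozygote
scoring 1 in both of its marker's columns) is provided for interoperability
with qualitative-coding tools and round-trips losslessly.

## Hybrid-seed purity

Given the two parental band sizes at a co-dominant marker, a seedling is a
true hybrid if it shows both bands (within a configurable size tolerance,
default 0 bp — exact for in-silico sizes, widen for gel-estimated ones),
selfed-female/male if it shows only one parent's band, off-type if any band
matches neither parent, and missing with no call. The marker is rejected as
unusable when the parental bands are closer than twice the tolerance. Batch
purity = true hybrids / classified individuals × 100, with missing
individuals reported separately. Multi-marker batches combine conservatively
(hybrid only if hybrid at every informative marker; conflicting selfed calls
at different markers mark an individual off-type).

## Synthetic data

The generator emulates the two-re-sequenced-parents study design with full
ground truth. Reference chromosomes are i.i.d. bases at a configured GC
fraction (default 0.35, a cucumber-like composition). Planted events default
to the empirically observed mixture of a cucumber parent-vs-reference call
set: size classes 53.9% / 26.1% / 8.9% / 11.1% (small / 11–20 / 21–30 /
large, uniform within class, large on 31–60 bp) and 49.4% insertions.
Events are placed with ≥200 bp spacing between footprints and a 300 bp
margin from chromosome ends so that flank extraction and primer design
never straddle two events; infeasible packings raise an error rather than
degrade silently. A configurable fraction (default 10%) of events is
planted inside generated homopolymer tracts and *exported* anchored at a
random offset within the tract while the truth table records the canonical
form — exercising normalization exactly where real callers disagree about
anchors. `plant_indels` returns its own copy of the reference (the tracts
are written into it); downstream steps must use that copy.

Genotype panels draw fully inbred (homozygous) lines by default, with an
optional per-call heterozygosity rate and an optional two-group structure in
which the first k markers are fixed for alternate alleles between groups —
the configuration used to verify that group-diagnostic markers split a
UPGMA tree into the two expected clades. F1 seed lots allocate class counts
exactly (largest-remainder rounding of the configured fractions) and
shuffle individuals, so a 90%-hybrid batch of 100 scores exactly 90.0%.

What the simulations do **not** model: sequencing error and coverage (calls
are exact), linkage between loci, realistic repeat landscapes beyond
homopolymers, primer–template mismatch hybridization, and gel sizing error
(unless a tolerance is set). Passing tests therefore demonstrate correctness
of the algorithms under clean calls, not robustness to caller noise.

## Problem sizes and numerical choices

The validation suite runs discovery on a 7 × 100 kb genome with 175 planted
events (100 A-only, 50 B-only, 25 shared), the design audit on ~120
large-InDel templates, phylogenetics on panels of ≤20 lines × ≤25 markers,
and purity on 100-seedling batches — sizes chosen so the whole suite
completes in seconds while every check remains exact rather than
approximate. Floating-point comparisons use 1e-9 tolerances for tree
heights and exact equality for counts and band sizes. Densities and
percentages are rounded to one decimal at the reporting boundary only;
internal computation is unrounded.

## Known limitations

- Published full-scale results that depend on unreleased raw reads or
  supplementary genotype tables (genome-wide call counts, the 48-line
  cluster memberships, the parental Nei distance of 0.96) are documented
  but cannot be recomputed here.
- Primer specificity is local to the design template; no genome-wide
  e-PCR with mismatches, secondary-structure or dimer screening.
- The cost-driven "arbitrary selection" of a marker subset for wet-lab
  validation is exposed only as an explicit seeded subsample operation,
  never applied by default.
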