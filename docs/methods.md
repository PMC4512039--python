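# Methods

## The analysis model

`famprio` assumes called, unphased genotypes for a nuclear family with
one or more affected siblings and both parents (the canonical design is
a quad: two affected brothers, father, mother).  The pipeline starts
from genotypes: alignment, duplicate removal, recalibration and variant
calling are upstream concerns and out of scope.  All coordinates are
1-based as in VCF; multiallelic records are split into biallelic sites
on load (allele *k* maps to 1 at the *k*-th derived site, every other
allele to 0), so downstream logic only ever sees alternate index 1.
Male X genotypes are normalized to hemizygous even when the VCF encodes
them as diploid homozygotes; a diploid-het male X call is treated as
impossible and removed by the Mendelian filter.

### The reduction cascade

Stages run in a fixed order (QC/missingness → Mendelian →
shared-by-affected → consequence → classification → prioritization) and
each logs input/output counts to the filter trace.  The site-level
stages before classification are pure set filters, so permuting them
changes only the trace counts, never the surviving set; a test asserts
this commutativity.

* **Missing data.** The default policy is strict: a missing call in any
  required member fails the site, because the workflow removes rather
  than imputes.  A lenient mode (missing passes QC and the Mendelian
  check as unknown) is available; a missing affected-sib call always
  fails the sharing test.
* **Mendelian consistency** is decided by gamete enumeration: a child
  genotype is consistent iff it can be formed from one allele of each
  parent (autosomes), or iff the hemizygous allele is transmissible by
  the mother (male X).  Y and mitochondrial sites are rejected as
  unsupported.  The implementation is cross-checked against an
  independent brute-force oracle over all 27 autosomal and 18 male-X
  trio combinations.
* **Sharing** defaults to genotype identity across affected sibs (the
  source data print a single sibship genotype column); a looser
  any-carrier mode is a configuration switch.
* **Parental origin** of a shared het allele is resolved by carrier
  status: paternal if only the father carries it, maternal if only the
  mother, ambiguous if both, inconsistent if neither.  No read-backed
  phasing is attempted.  A gene with ≥ 2 shared het variants is
  `compound_het` only when both a paternal and a maternal origin
  resolve; if ambiguity blocks resolution it is
  `compound_het_ambiguous` (reported, flagged); two variants with the
  same resolved origin are never called compound het.  The worked
  example's *PDE4DIP* (one maternal variant, one with both parents
  carrying) is the ambiguous case; it still counts toward the
  compound-het section of the candidate table.

### Rarity and consensus

Heterozygous candidates use the maximum MAF across the population
databases that report one (conservative: rare in every population
reported).  The pair rule for compound hets — at least one member at
MAF ≤ `rare_maf` (default 10⁻³), every member at ≤ `common_cap`
(default 0.10) — encodes the recessive-model view that the *pair*
frequency must be small, and deliberately admits a moderately common
partner allele such as the worked example's rs79842542 (MAF 0.06/0.07).
Homozygous candidates are judged on the ESP homozygote frequency q²
(default cap 0.05) rather than the allele frequency.  A variant absent
from every database is treated as rare: absence from large population
catalogues is itself evidence of rarity, the same logic that defines
"private" de novo candidates.  q² is *not* constrained to be ≤ MAF —
database values can depart from Hardy-Weinberg expectations and one
worked-example row does.

Tool thresholds are the tools' published operating points: Sift ≤ 0.05
and Polyphen2 ≥ 0.957 inclusive, Fathmm < −1.5 strict.  A prioritized
candidate must pass its class's rarity rule and have its defining
variants "putatively damaging" (≥ 1 damaging vote, or no tool able to
score — benefit of the doubt, mirroring the missing-frequency rule; for
compound hets both members of some trans pair must qualify).  SiPhy
conservation (default reporting threshold 10) never filters; it is
annotation only.

One known tension in the source material: the *GEN1* homozygote is
described as damaging by all three tools, but its printed scores
(0.03 / 0.81 / −0.45) pass only the Sift threshold.  The package follows
the printed thresholds and scores; the verdict is one damaging vote.

### De novo and X screens

A de novo candidate must be carried by every affected sib, absent from
all supplied frequency tables, and show zero alternate-supporting reads
in both parents with parental coverage ≥ `min_parent_depth` (default
8×).  Parents lacking depth information exclude the site and are
counted in the trace as insufficient coverage.  Database absence is
evaluated against supplied tables only; there are no live queries.  The
X screen requires every affected male sib hemizygous-alt with a carrier
mother; a non-carrier mother marks the site transmission-inconsistent.

### Panels, cohorts, karyotypes

The built-in panel is the 17 Fanconi anemia complementation groups with
an alias table (SLX4↔FANCP, BRCA2↔FANCD1, BRIP1↔FANCJ, PALB2↔FANCN,
RAD51C↔FANCO, XPF/ERCC4↔FANCQ, BRCA1↔FANCS); comparisons are
case-insensitive and composite symbols ("FANCP/SLX4") resolve through
either part.  Carrier counting treats missing genotypes as
non-carriers, so denominators include incompletely covered samples;
modes are any-alt (≥ 1 queried site), hom-alt at every queried site,
and het at every queried site (the double-heterozygote lookup).
Cohort size is 3 × trios + singletons.

Karyotype parsing covers the ISCN numeric-prefix form with
whole-chromosome gains/losses only; structural tokens (inv, t, del)
are carried verbatim as notes, never interpreted.  A declared modal
number that disagrees with 46 + gains − losses is flagged, never
silently corrected.  Ploidy bands (hypodiploid < 46, diploid 46, low
hyperdiploid 47–50, high hyperdiploid 51–67, near-triploid+ > 67)
follow cytogenetic convention and are configurable; they are not
derived from any single dataset.

## The simulator

`famprio.simulate` draws background sites from a two-component MAF
mixture (by default 30 % "extremely rare" sites with MAF log-uniform on
[10⁻⁵, 10⁻³], the rest uniform on [0.01, 0.5]; 5 % of sites on X),
assigns genes (never spanning chromosomes), consequence labels and
benign scores (background variants draw damaging scores with
configurable probability, default 0).  Parental genotypes are
Hardy-Weinberg draws at the true MAF; each sib receives one uniformly
chosen allele per parent, maternal-only on male X.  Siblings are
independent given the parents — no linkage — so sib-sharing
probabilities are exactly computable, and tests compare observed
sharing against that analytic oracle.  Read depths are Poisson (28.1×
sibs, 19.4× parents, a realistic design with shallower parents);
alternate-allele depths are binomial given the called genotype.
Genotyping error is a per-call channel: with probability ε a diploid
genotype is replaced by one of the other two genotypes uniformly (a
hemizygous allele flips).  The observed Mendelian-inconsistency rate
under ε is checked against an exact enumeration of the error channel
composed with Hardy-Weinberg and transmission.

Spiked disease configurations are written as dedicated extra sites with
deterministic positions and genes, genotype patterns set directly
(error-free by construction), rare/damaging annotations (Sift 0,
Polyphen2 1, Fathmm −3; the homozygous scenario gets q² = 0.0025; the
de novo scenario gets no database record and parents forced to ≥ 8×
coverage with zero alternate reads), and are recorded in a truth set.
Everything is deterministic given the seed, and fixture files (VCF,
PED, TSV, truth JSON) are byte-stable.

What the simulator does **not** emulate: linkage disequilibrium and
within-gene haplotype structure, population stratification, indel
realignment artifacts, strand or capture biases, related cohort
individuals, and correlated (batch) genotyping errors.  Passing the
recovery tests therefore demonstrates the *logic* of the cascade —
classification, phasing, thresholds — not robustness to every artifact
of real exome data.

## Problem sizes and numerics

The recovery experiment uses 200 simulated quads of 1,000 sites each
(50 per spiked scenario, ε = 0): recall of spiked candidates is 1.0 and
the false-candidate count 0 under default thresholds with benign
backgrounds.  The error-model check uses 10 quads of 2,000 autosomal
sites at ε ∈ {0.001, 0.01}, comparing inconsistency counts to the
analytic expectation within three Monte-Carlo standard errors.  These
sizes give stable statistics while keeping the full suite fast.  There
is no unseeded randomness anywhere in the pipeline proper; re-running a
configuration byte-reproduces the report.

## Data normalization notes

The worked-example table is reconstructed from a published clinical
report.  One homozygous-section row (CA9 rs2071676) prints the sibs'
genotype as a pair of reference letters; the fixture normalizes that
row's ref/alt orientation so the sibship is homozygous for the
alternate allele, matching its section.  Susceptibility-locus and
FANCA positions were not printed; they carry synthetic placeholder
coordinates and are addressed by rsid only.

## Known limitations

* Phasing is transmission-based only; a compound het with both parents
  het at both sites stays ambiguous (reported, not resolved).
* Indels pass through the same types with left-alignment assumed
  upstream; complex MNVs and structural variants are out of scope.
* The ISCN grammar covers numeric-prefix whole-chromosome records only.
* The de novo screen depends on parental AD/DP fields; VCFs without
  depth information yield no de novo candidates (by design, with the
  exclusions counted in the trace).
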