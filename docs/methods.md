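# Methods

## Problem and pipeline

The package quantifies the genomic association between phosphoenolpyruvate
mutase (Ppm, the C–P-bond-forming enzyme of phosphonate biosynthesis) and
nucleotidyltransferases, and characterizes the kinetics of the
phosphonyl-tailoring cytidylyltransferases (PntC) found in those clusters.
The genomic analysis runs in a fixed stage order:

1. **Genome dereplication** by trinucleotide signature (one representative
   per species-like group), so multiply-deposited strains do not dominate
   distance statistics.
2. **Hit-quality filtering** of per-domain profile-HMM matches: Pfam
   gathering-threshold membership and ≥60% model coverage, then greedy
   highest-score resolution of overlapping domains per protein.
3. **Motif screening**: PF13714 matches are genuine PEP mutases only if they
   carry the catalytic motif EDKXXXXXNS.
4. **Deduplication and fusion inventory** over the motif-positive,
   non-redundant Ppm set.
5. **Gene-distance statistics**: per genome, the single nearest
   ppm↔nucleotidyltransferase pair, as a histogram with cumulative
   fractions.

## Models and rules

**Coverage.** A hit's coverage is `(hmm_to − hmm_from + 1) / model_length`
— the fraction of the *model* covered, not of the query protein, because
the retrieval rule demands alignment to the HMM. The 60% bound is
inclusive. Coverage is assessed per domain; a config switch
(`sum_split_domains`, off by default) is deliberately not offered because
summing split domains changes hit identity — instead callers may merge rows
upstream.

**Gathering thresholds.** Searches run with `--cut_ga` emit only passing
rows, so `meets_ga` defaults to true at parse time; a per-family GA table
can be supplied for tables produced without curated cutoffs.

**Overlap resolution.** Greedy by descending per-domain bit score (ties:
smaller alignment start, then input order); a candidate is kept iff it
shares no residue with an already-kept hit (a configurable overlap
tolerance, default 0, relaxes this). The kept set is pairwise disjoint and
deterministic.

**Motif.** The default pattern `EDKx{5}NS` is compiled into an
overlap-aware regular expression. `X` (an ambiguous residue) matches the
five wildcard positions but never a literal anchor, so ambiguity cannot
create a motif call. The scan covers the whole protein rather than the
PF13714 envelope: the motif is diagnostic wherever it occurs, and
restricting it would make calls sensitive to alignment endpoint jitter.

**Fusion categories.** Partner accessions are the non-PF13714 accessions
among a protein's resolved hits: none → ALONE; PF12804 → NTP_TRANSF_3;
PF01467 → CTP_TRANSF_LIKE; both → TRIPLE; anything else → OTHER. When a
named partner co-occurs with an unrelated extra domain the named partner
wins by default (`named_partners_take_precedence=False` reverses this).
Percentages are reported over the motif-positive non-redundant count (the
"all Ppm proteins" denominator); the fused share of all non-redundant
family matches is additionally reported over the pre-motif denominator.
Both rounded (1 decimal, half-away-from-zero) and unrounded values are kept
because published roundings of the same quantity can disagree in the last
digit.

**Gene distance.** Genes are ordered by ascending start coordinate within
each replicon (strand ignored) and distance is the absolute ordinal
difference: adjacent genes are 1 apart, a fusion is 0. Distances are only
defined within a replicon (the default; circular replicons use the shorter
arc behind a flag), and per genome only the minimum over all PPM×NTF pairs
is tabulated, so a genome with a fused Ppm always records 0 regardless of
additional nearby nucleotidyltransferases.

**Trinucleotide signatures.** The 64-vector of relative frequencies of all
overlapping 3-mers counted over every replicon *and its reverse
complement* (strand-symmetric by construction); windows containing
non-ACGT characters are skipped for determinism. Distance is the mean
absolute component difference scaled ×100, so the species-level cutoff
operates at delta = 0.03. Dereplication is greedy leader clustering with
genomes visited by descending total length (ties by id): a genome joins
the first representative within delta, else founds a new one. The exact
signature distance used in prior genome-signature work is not fully
specified in the literature this emulates; the mean-|Δ| form and the
greedy rule are this package's explicit, configurable choices, validated
by the contract that mutated copies of a genome cluster together while
compositionally independent genomes stay apart.

**Kinetics.** Initial-rate tables (S in mM, v in M/s) are fit by bounded
trust-region least squares to `v = kcat·E0·S/(KM + S)` or the
substrate-inhibition law `v = kcat·E0·S/(KM + S(1 + S/KS))`. The
substrate-inhibition algebraic form is the standard uncompetitive
single-site form; self-consistency between the generator and the fitter is
the tested contract. Fitting is performed on `v/E0` (turnover scale, s⁻¹)
because raw velocities of ~1e-7 M/s put gradients below feasible stopping
tolerances; the residual sum of squares is rescaled back to velocity
units. Initialization: kcat₀ = max(v)/E0, KM₀ = S nearest half-max,
KS₀ = max(S). Standard errors are asymptotic (from the SVD of the Jacobian
at the optimum), matching routine non-linear-regression reporting; no
bootstrap. A fitted KS above 100× the largest assayed S flags "inhibition
not identifiable". Specificity constants convert KM from mM to M;
fold-preference ratios are rounded half-away-from-zero to 2 significant
figures, the convention used when reporting, e.g., a 200-fold preference.

## Synthetic data: what it emulates, what it does not

The generator stands in for a large reference genome collection. Each
genome spec plants, with exact ground truth: Ppm-like proteins with or
without the motif, fusion architectures (hit rows on non-overlapping
alignment coordinates), PF13714 coverage values (below-threshold values
make negative controls), separate nucleotidyltransferase genes at exact
gene distances (distance 0 is always realized as a fusion on the Ppm
protein itself), exact-duplicate sequence groups, and per-genome
nucleotide composition.

Choices and their rationale:

- **Background proteins** are i.i.d. uniform over the 20 amino acids
  (length 250), so an accidental motif has probability ≈ L·(1/20)⁵ per
  protein — negligible, and additionally excluded by rejection sampling so
  planted flags are exact.
- **Nucleotide composition** per genome is drawn from Dirichlet(10,10,10,10).
  Uniform-composition genomes would all converge to the same trinucleotide
  signature regardless of length, making species-level dereplication
  untestable; compositional draws emulate the GC/skew variation that makes
  real signatures species-specific.
- **Within-species replicates** are point-mutated copies at 1%
  substitution. With ~3% of 3-mer windows perturbed, the expected scaled
  signature distance on ≥50 kb genomes stays well under the 0.03 cutoff,
  while independent compositions sit ~10× above it.
- **Gene layout**: 1 gene per kb, 900 bp CDS rows in ascending coordinate
  order, one protein per gene.
- **Hit scores** are drawn from fixed uniform ranges; they order overlap
  resolution but carry no biophysical meaning.

Not emulated: codon structure (proteins and genome nucleotides are
independent), realistic HMM score/E-value distributions, indels,
multi-domain architectures beyond the three modeled families, plasmid
copy-number effects. Passing round-trip tests therefore demonstrates the
correctness of the bookkeeping and rules on clean inputs, not robustness
to noisy annotation or fragmented assemblies.

**Kinetic data** are generated from the substrate-inhibition law (KS = ∞
gives Michaelis–Menten) with multiplicative Gaussian noise of given
relative SD at 50 nM enzyme, the published assay concentration; negative
noisy velocities are clamped to 0 and flagged.

## Problem sizes used by tests and the acceptance script

Synthetic suites use 20 genomes of 12–25 genes each (exercising every
fusion category, motif negatives, a below-coverage control, distances 1–6,
duplicates, and two-replicon genomes); dereplication uses 3 planted
clusters × 4 copies of 50 kb genomes; oracle-equivalence checks run 100
random instances per operation; kinetic Monte Carlo uses 200 replicates at
5% noise. These sizes keep the whole suite in a few seconds while leaving
every rule load-bearing.

## Known limitations

- The dereplication distance is a package choice (see above); absolute
  delta values are comparable only within this implementation.
- Percentages derived from published funnel counts reproduce printed
  values under 1-decimal half-away-from-zero rounding; where a source
  prints two different roundings of the same quantity, both the rounded
  and unrounded values are exposed and no reconciliation is attempted.
- `nearest_distance_per_genome` does not compare loci across replicons of
  one genome (no meaningful gene-order metric exists between replicons).
- Asymptotic standard errors understate uncertainty for poorly identified
  KS; the identifiability warning is the guard, not the error bar.
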