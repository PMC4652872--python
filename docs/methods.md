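# Methods

## The genetic model

The package models a two-line pedigree: a homozygous-resistant founder
line (r/r at the trait locus) and a susceptible line (s/s), crossed to an
F1, with either a backcross to the resistant line or an F1 × F1
intercross producing the mapped progeny.  Two meiosis models apply:

* **Female meiosis is achiasmatic**: one of the two homologs is
  transmitted intact with probability 1/2, never a mosaic.  This is the
  rule in female Lepidoptera and is what makes whole-chromosome trait
  assignment possible from dominant markers.
* **Male meiosis follows the Haldane (no-interference) model**: the
  starting homolog is chosen with probability 1/2 and the source homolog
  switches independently between adjacent loci i, i+1 with probability
  r_i.  Recombination fractions are interval properties in marker order;
  non-adjacent fractions compose as r₁₃ = r₁₂ + r₂₃ − 2·r₁₂·r₂₃.
  Interference is not identifiable from the pairwise fractions this
  design yields, so no interference model is offered.

The trait is fully recessive by default: discriminating-dose survival
probabilities (rr, rs, ss) = (1, 0, 0).  Bioassay misclassification is
supported through false-negative/false-positive rates (default 0, used
only for robustness exercises): the effective survival probability is
p(1−fn) + (1−p)·fp.

### Marker models

* **Dominant (AFLP-style)** markers score band presence/absence.  An
  informative marker is band-heterozygous in the informative F1 parent
  with the band on exactly one grandparental homolog, while the other
  parent is band-absent; a progeny's band state therefore reads out which
  maternal homolog it inherited.
* **Codominant (EPIC-style)** markers score an unordered fragment-size
  pair (e.g. `272/282`).  The resistant line is fixed for one size, the
  F1 heterozygous.

## Stage 1 — co-segregation grouping

Under error-free achiasmatic segregation, same-chromosome dominant
markers show identical or exactly complementary patterns over progeny.
Grouping is single-linkage clustering: markers link iff their patterns
agree at ≥ (n_compared − max_mismatch) jointly scored progeny, directly
or after complementing one side (phase).  Defaults: `max_mismatch = 0`,
markers with > 20 % missing progeny calls excluded, ≥ 20 progeny
required.  Groups are numbered by descending size then smallest member
id so output is stable; each group's reference pattern is its
smallest-id member, and phases are reported relative to it.  With a
nonzero tolerance a marker can sit within tolerance of two otherwise
unlinked clusters; such articulation markers are reported *unresolved*
and assigned to neither rather than silently merging chromosomes.

## Stage 2 — signed interaction χ²

Per linkage group, each progeny's maternal homolog class (resistant- vs
susceptible-grandparent) is called by majority vote over phase-adjusted
marker calls; ties and zero-information individuals are ambiguous and
excluded listwise per group.  Band→homolog orientation is anchored on
the grandparent genotypes (the band should appear in exactly one
grandparent); markers without a discriminating grandparent call inherit
the orientation of their anchored group mates via the grouping phase.

The statistic on the 2×2 table (a, b; c, d) = (survivors × homolog
class; controls × homolog class) is N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
N = a+b+c+d, signed by (ad−bc), with the p-value from χ²₁ on the
magnitude.  No Yates continuity correction is applied — the statistic is
the plain Pearson interaction form (the suite cross-checks it against an
independent generic 2×2 implementation).  Tables with a zero margin are
undefined, flagged, and excluded from the multiple-testing count m;
significance flags use Bonferroni thresholds α/m for α ∈
{0.05, 0.005, 0.001}.

## Stage 3 — recombination mapping

Only the paternal meiosis is informative in the male-informative
families: survivors of the discriminating dose are r/r, so their
maternal allele at every linked codominant marker is the resistant-line
allele.  Hence:

* trait–marker: recombinant iff heterozygous; r̂ = heterozygote
  fraction, SE = √(r̂(1−r̂)/n).  This holds identically for
  backcross-to-resistant and F2 designs (each selected offspring
  contributes exactly one paternal meiosis), which is also why families
  of both designs pool by simple summed counts.
* marker–marker: paternal alleles are recovered by subtracting the known
  maternal allele (a homozygote whose shared allele is the maternal one
  resolves to that allele); an offspring is recombinant iff its paternal
  alleles derive from different F1 homologs.  The F1 phase must be
  supplied (known from grandparents); phase inference from progeny is
  out of scope.
* Genotypes carrying alleles absent from the parents are pedigree
  inconsistencies: flagged by individual id and excluded.
* r̂ > 0.5 is reported as-is with an `unlinked` flag, never truncated.

**Ordering** minimizes the sum of adjacent r̂ over permutations,
exhaustively for ≤ 8 loci (orientation canonicalized to the
lexicographically smaller terminal locus).  Ties break first by the
expected double-recombinant load Σ r_i·r_{i+1} over adjacent interval
pairs, then lexicographically; beyond 8 loci a greedy seriation grows
the chain from the tightest pair.  This is a deliberate design choice:
ordering loci by synteny with a reference genome such as *Bombyx mori*
is an annotation input, not an algorithm, so it is left to the user.  Map
rendering prints fractions to 2 dp (`A–(0.16)–B–…`); distances use
Haldane's d = −50 ln(1−2r) cM with r ≥ 0.5 mapping to infinity.

## Stage 4 — CDS consequence annotation

Coordinates are 1-based inclusive on the CDS.  Edit kinds: deletion of a
closed interval; insertion after a position; replacement (deletion plus
insert at the site); duplication, whose stated interval is interpreted
as the *post-duplication coordinates of the inserted copy* (the
alternative reading — the template interval — shifts the edited sequence
by one repeat unit but not the first affected codon).  Translation is
the standard genetic code, frame 1, reported up to the first stop
(Biopython's translator underneath).

The **frame shift** is reported as (deleted − inserted) mod 3 — the
phase by which the ribosome's downstream frame leads the reference — so
a 5-nt deletion is a shift of 2 and a 5-nt duplication a shift of 1.  A
stop is *premature* when its codon index is below the reference stop's.
Classification: frameshift-truncation (shift ≠ 0), nonsense (in-frame
with a new stop), in-frame-indel, or silent-boundary (empty edit).  A
feature is lost *wholly* when it starts at/after the premature stop and
*partly* when the stop falls inside it; "truncated before NBF2" means
stop codon < NBF2 start.

### The synthetic reference

`make_synthetic_abca2_cds()` builds a 1,742-codon + TAA reference
(5,229 nt) of random non-stop codons, with the documented local
sequences planted at the three mutation sites: the 73-bp segment at nt
2,889–2,961, `ACAAG` at nt 3,127–3,131, and the `GAATA` duplication
template at nt 4,099–4,103.  Planting makes the R01 replacement
reproduce its documented local outcome exactly (Gly at codon 964
followed by a stop at 965) and keeps the R03 duplication's template
check meaningful.  Everything outside those windows is synthetic:
residue identities, downstream stop positions for R02, and feature
intervals are *not* those of the real gene.  The feature table honours
the published topology (ECD2 spanning codons 964 and 1,043, TM XII
ending just before 1,368, NBF2 downstream of all three stops) with
approximate synthetic boundaries; a real CDS FASTA and feature TSV drop
in without code change.

## What the simulator does and does not emulate

Emulated: cross topologies (female-/male-informative backcross, F2),
achiasmatic female meiosis, Haldane male meiosis, dominant and
codominant marker scoring conventions, recessive discriminating-dose
selection with optional misclassification, cohort structure
(treated-survivor / treated-dead / control / parent).

Not emulated: genotyping error and band-intensity artefacts of real
AFLP gels, segregating variation within founder lines beyond the
band-presence model, mutation genesis, multi-generation pedigrees,
linkage disequilibrium in field populations.  Passing tests therefore
demonstrate correctness of the estimators and clustering under the
stated model, not robustness to assay artefacts — the `max_mismatch`
tolerance and bioassay error rates exist precisely so such robustness
can be explored.

## Reproducibility and problem sizes

Every simulation consumes one `numpy` generator seeded per family; draws
occur in a documented fixed order (treated progeny before controls;
groups in sorted order; maternal gamete, paternal gamete, bioassay), so
a seed pins the genotype matrix bit-for-bit.  The study-scale analyses
use: 161 markers / 31 chromosomes / 29 + 30 progeny for grouping and
association; three mapping families totalling 72 selected meioses for
the preliminary map; 200 replicates × 500 selected progeny for the
estimator-recovery checks (Monte-Carlo SE ≈ 0.001 on r̂); 1,000
null-simulation replicates for family-wise error control; these sizes
keep the full suite and the acceptance script in the low minutes on one
core.

## Known limitations

* Grouping assumes the female-informative design; it will mis-group
  markers scored in a recombining parent (by design — recombination-aware
  grouping is a non-goal).
* The ordering criterion is a heuristic consistent with, but not
  equivalent to, multipoint maximum likelihood; for the ≤ 8-locus maps
  this pipeline targets it is exhaustive and exact under its criterion.
* Homolog-class anchoring requires grandparent rows in the genotype
  matrix; without any discriminating grandparent call a group's sign is
  arbitrary (magnitude and p are unaffected).
* The bioassay error-rate defaults (0) reflect the idealized design;
  real screens may misclassify, which biases r̂ upward through spurious
  "survivors".
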