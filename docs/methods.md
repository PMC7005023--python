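# Methods

`oligocoi` implements a high-throughput DNA-barcoding workflow for single
aquatic oligochaete specimens and the downstream sediment-quality
diagnostics, together with a ground-truth simulator that makes every stage
testable without external data. This note records the model, the defaults
and the design choices that were genuinely open.

## Pipeline model

Each specimen is PCR-amplified with a 313-bp mitochondrial COI fragment
using primers that carry an 8-nt tag at each 5′ end; the (forward, reverse)
tag combination uniquely identifies the specimen within one site library.
The processing contract per site is:

1. **Quality filter.** A read pair is kept iff both mates have mean Phred
   quality ≥ 30 and contain no ambiguous base. The threshold is read
   inclusively (mean exactly 30.0 keeps the pair).
2. **Demultiplex.** A pair is assigned to specimen *s* iff the forward read
   begins exactly with `fwd_tag(s) + fwd_primer` and the reverse read with
   `rev_tag(s) + rev_primer` — zero mismatches, no tag-error correction.
   Tag and primer bases are trimmed; everything else is rejected and
   counted. Combination uniqueness guarantees at most one match.
3. **Merge.** The reverse mate is reverse-complemented and the pair merged
   by a quality-weighted ungapped overlap consensus: candidate overlaps
   ≥ 20 nt are scored by Σ ±min(q_f, q_r) (positive for agreement), overlaps
   with more than 10% mismatches are discarded, disagreements resolve to the
   higher-quality base, and the merged quality is the per-position maximum.
   This is deliberately a re-specification of Bayesian pair-mergers as a
   transparent consensus rule: the tested contract is exact template
   reconstruction under low error, not any particular posterior model.
4. **Barcode distillation.** Merged reads are dereplicated (descending
   count, ties lexicographic); chimeras are removed by a de-novo two-parent
   test (a query is chimeric if some split point matches the prefix of one
   ≥2×-more-abundant sequence and the suffix of a different one, each
   within 1 mismatch, while the query is ≥ 3 mismatches from both parents);
   survivors are clustered into OTUs by greedy abundance-ordered centroid
   clustering at 97% identity; the barcode is the representative of the
   most abundant OTU, requiring ≥ 10 supporting reads (otherwise the
   specimen is counted as failed). Clustering is per specimen, not
   library-wide: the unit of analysis is the tagged specimen.
5. **Assignment.** Kimura 2-parameter distance to every reference,

       d = −½·ln((1 − 2P − Q)·√(1 − 2Q)),

   with P and Q the transition and transversion proportions over compared
   sites (N positions excluded, ≥ 100 sites required; unequal lengths are
   end-trimmed at the best ungapped offset). A barcode is assigned to the
   nearest reference when the distance is below that reference's threshold:
   10% by default, 8% genus-wide in *Nais* and *Uncinais*. A non-positive
   logarithm argument marks the pair *saturated*, treated as above any
   threshold. Unassigned barcodes fall through to an optional secondary
   database in the same format (the stand-in for a public-repository
   search), then are single-linkage clustered into labelled new lineages
   under the same conspecificity rule. A new lineage can be placed to
   family/subfamily level on a neighbour-joining tree (Q-criterion,
   Studier–Keppler branch lengths, deterministic label-order tie-breaks)
   with column-bootstrap supports (1,000 replicates by default): the
   placement is the smallest single-family reference group containing the
   query whose subtending edge reaches 70% support, else *incertae sedis*.
   Manual morphological identifications of preserved anterior parts can be
   merged afterwards as overrides (route `morphology`).

## Indices

Streams are scored with IOBS = 10·S/T, where S is the number of taxa among
the identified specimens and T is the percentage — over *all* identified
specimens — of the dominant tubificid group (with vs without hair setae).
Lakes are scored with the percentage of specimens belonging to
pollution-sensitive taxa; the sensitivity list is a database column, not a
constant, so species can be added to it. Both metrics are blind to whether
counts came from morphological or genetic identification.

Two conventions close gaps the printed class scales leave open:

* IOBS bands are half-open: [6,∞) very good, [3,6) good, [2,3) medium,
  [1,2) poor, [0,1) bad. Lake bands: (50,100] very good, (20,50] good,
  (10,20] medium, (5,10] poor, [0,5] bad.
* T = 0 (no tubificids) yields an explicitly undefined IOBS and class
  rather than a special-cased value; such sites are excluded from the
  agreement counts but retained in the per-site tables.
* New lineages without a hair-setae group count toward S and the
  denominator of T but never toward T's numerator (their group cannot be
  read off a barcode).

## Concordance layer

For each metric the genetic value *y* is regressed on the morphological
value *x* by OLS (y = a·x + b), reporting a, b, R² (squared Pearson
correlation) and the two-sided Pearson-test p-value from
t = r·√((n−2)/(1−r²)) on n−2 df. IOBS series are log-linearized before
regression — natural log of *both* series, with non-positive or undefined
pairs dropped (warned, listed). The natural-log-both-variables reading is a
documented choice; the transform applies only to IOBS, not to the
percentage metrics. Quality-class agreement is tabulated per site on the
ordered scale bad < poor < medium < good < very_good as
identical / genetic-higher / genetic-lower.

## Synthetic data generator

The generator emulates the study design with known truth:

* **Reference lineages.** A random 313-bp root sequence is mutated
  independently per lineage so that all pairwise K2P distances exceed
  `min_sep` (default 0.15, enforced by rejection sampling; infeasible
  settings raise). Designated *cryptic pairs* add a transitions-only
  partner at ~0.12 K2P sharing the original's taxon name — species a
  barcode separates but a morphologist lumps. Traits follow a fixed
  scheme: groups cycle through the six family/subfamily groups; tubificids
  are non-sensitive, the other families sensitive.
* **Communities.** Each site has a degradation level g ∈ [0,1]; tolerant
  (tubificid) lineages get weight ∝ g, sensitive taxa ∝ 1−g, with
  lognormal heterogeneity. Specimens are drawn sequentially i.i.d. from the
  normalized weights, so a 66-specimen draw contains the 33-specimen draw
  at the same seed as its prefix (nested subsampling).
* **Reads.** Depth per specimen is Poisson(mean 50) floored at one pair,
  with an optional dropout probability (default 0). Substitutions are
  i.i.d. per base; Phred qualities come from a two-tier high/low mixture
  (Q40/Q20) whose expected error equals the configured rate, so the Q30
  mean filter is exercised meaningfully. A configured fraction of pairs
  (default 1%) are two-parent chimeras spliced at a uniform breakpoint,
  keeping the focal specimen's tags. Indels are not simulated
  (substitution-dominated short-read errors; merging stays
  alignment-free); an `indel_rate` field is reserved but fixed at 0.
* **Tags.** Latin-square style: each 8-mer is reused across specimens but
  every combination is unique; tags are pairwise ≥ 3 mismatches apart so a
  single sequencing error in a tag can never produce another valid
  combination.
* **Morphological observer.** Cryptic-pair members collapse onto their
  shared name; a configured fraction of specimens (default 10%) is demoted
  to a family/subfamily label that keeps the hair-setae group (visible on
  immature tubificids) but loses species-level sensitivity information.
  Counts are conserved.

The per-base error (0.001) and chimera (0.01) defaults are simulation
choices, not measured values. Specimen barcodes equal their lineage's
reference sequence (no intraspecific variation); with cryptic pairs and
demotion switched off and noise at zero, the pipeline therefore recovers
the true community exactly — an identity property the tests assert. What
passing tests consequently do **not** show: robustness to indels, tag
jumping between libraries, PCR abundance bias, primer-site variation, or
intraspecific sequence variation in real populations.

## Numerical and reproducibility choices

* Deterministic tie-breaks everywhere (lexicographic sequence/label order):
  dereplication, dominant OTU, nearest-reference ties (preferring a record
  whose threshold admits the match), NJ pair selection, new-lineage labels.
* Saturated K2P distances enter NJ matrices as the cap value 5.0
  substitutions/site — far above any real COI distance — rather than
  infinity, keeping the agglomeration finite.
* One master seed derives every per-site, per-stage seed as
  SHA-256(master:site:stage) mod 2³¹, so sites are independent and reruns
  are byte-identical; every output table carries the configuration hash
  and master seed in a comment line.
* Study scale in the shipped drivers and acceptance script: 20 sites
  (13 stream, 7 lake), 33 or 66 specimens per site, 14 reference lineages
  with 2 cryptic pairs, depth 50. The NJ bootstrap default stays at 1,000
  replicates; tests use fewer where only determinism or support logic is
  at stake.

## Known limitations

* The 8% threshold is applied genus-wide in *Nais*/*Uncinais*, a
  simplification of "some species within" those genera.
* The chimera test needs both parents abundant in the same read set; PCR
  chimeras whose second parent comes from another specimen are instead
  neutralized by OTU clustering and the dominant-OTU rule within the
  specimen.
* Family-level placement trusts bootstrap monophyly; paraphyletic
  reference families will yield *incertae sedis* rather than a forced call.
* The IOBL index (lake metabolic potential) is out of scope, as is any
  fuzzy tag matching or gapped alignment.
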