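# Methods

## Data model

An SSR fingerprint is, per sample, a map from marker to a **set** of allele
fragment lengths (AFLs, integers in bp). Sets — not multisets — because
fragment sizing cannot observe copy number: a single peak may be a
homozygote, a locus with a null allele, or an unmeasured second allele, so
`221:221` and `221:0` both normalize to `{221}`. The empty set encodes a
null call (`0` in tables). AFLs outside [50, 600] bp are rejected as data
errors: capillary sizing against 500-size ladders cannot produce them.

The default panel is the 17-marker ECPGR *Malus/Pyrus* set in its standard
order (CH01h01 … GD147). Hi02c07 and CH04e05 are flagged multi-locus, GD12
unknown; primer sequences are carried as metadata only.

## Distance and grouping

The pairwise distance is one minus the Dice–Sørensen allele-sharing
coefficient, summed over markers, with tolerance-aware matching:

- **Matching, not binning.** An allele x of one profile may be paired with
  at most one allele y of the other, with |x−y| ≤ tolerance (default 1 bp).
  The count of common alleles is the maximum such matching, computed
  greedily over the sorted allele lists — provably optimal for an interval
  tolerance, and verified against exhaustive enumeration in the tests.
  Transitive binning would let a chain 100/101/102 count as mutual matches;
  matching does not.
- **Null handling.** A marker null in both profiles is dropped from
  numerator and denominator (so d(p, p) = 0 even for partially null p); a
  marker null in one profile contributes that profile's allele count to the
  denominator only, so amplification dropout pushes profiles apart rather
  than silently matching. Two entirely null profiles have no defined
  distance; the matrix routine flags such pairs at 1.0 with a warning
  instead of failing.
- **Linkage.** Groups are connected components of the graph with an edge
  wherever d ≤ cutoff (default 0.25), i.e. single linkage, inclusive at the
  cutoff. This matches the operational behaviour of pooling campaigns —
  adding data can merge previously distinct groups, never silently split
  them — and makes the group count monotone non-increasing in the cutoff.
  Chaining of closely related di-/triploid cultivars is the known failure
  mode; it is handled by explicit `split_group` directives, not by a
  different linkage.
- **Identifiers.** Groups are numbered `MD_0001, MD_0002, …` by first
  appearance of their earliest member in input order, so a run is
  deterministic given the input file. Historical group numbers from any
  earlier campaign are not reproduced; splits allocate fresh numbers and the
  audit log records the old → new mapping.
- **Scale.** Replicate samples with identical profiles are deduplicated
  before the quadratic distance pass. On genebank-shaped data (thousands of
  samples, many replicates) this cuts the work severalfold; 2,000 samples
  cluster in a few seconds on one CPU.

## Harmonization

- **Shift correction.** One marker (CH02g09 by default) shows a systematic
  2 bp inter-cohort sizing offset, predominantly at 122–140 bp. Correction
  requires within-group evidence: an affected-cohort AFL a in the window is
  raised to a+2 only when a group mate from the other cohort shows a+2 at
  that marker *and* no other-cohort mate shows a itself. The corroboration
  clause makes the operation idempotent and prevents blanket shifting of
  every in-window value. The window is configurable because the offset was
  only *predominantly* confined to it.
- **Directives.** Manual curation — removing failed or swapped samples,
  reassigning samples to their correct group, splitting over-merged groups,
  widening the artefact-removal window for a specific group/marker — is
  expressed as a YAML list of `{verb, target, args}` replayed identically on
  every run. Unknown targets and non-partitioning splits are hard errors;
  every mutation is appended to an ordered audit log. Samples whose
  pomological determination matches an exclusion vocabulary (rootstocks,
  crab apples, wild apples) get auto-generated removal directives.

## Consensus rules

Per group and marker, calls are tallied exactly (the null call is its own
category) and resolved in a fixed order:

1. **Modal call**, with ties resolved deterministically: tied calls that are
   within-tolerance variants of each other collapse to the variant with the
   smaller AFLs (treating the pair as a sizing artefact); otherwise the
   first-seen call is kept. Both cases are flagged `unresolved` — curation
   that a human performed "by personal evaluation" is here deterministic
   and visible.
2. **Fill rule**: if the modal call is null but any sample shows alleles,
   the most frequent non-null call wins (`missing-filled`).
3. **Heterozygous preference**: a minority call that is a strict superset of
   the current call wins when every extra allele differs from every current
   allele by more than the tolerance (`heterozygous-preference`). The
   superset requirement means a disjoint minority call can never overwrite
   the majority; the rule iterates so chained supersets resolve fully. Fill
   runs before promotion, and both flags are kept when both fire.
4. **Ploidy-aware artefact removal**: for diploid genotypes at single-locus
   markers with more than two consensus alleles, an allele carried by *no
   other consensus genotype* (census over consensus genotypes, not samples)
   and lying within a window (default 1 bp; per-group directive override,
   e.g. 2 bp) of a widespread allele in the same call is removed, smallest
   first, until two remain (`ploidy-adjusted`). If removal cannot resolve
   the excess the call is left intact and flagged. Multi-locus markers are
   exempt, and ploidy is metadata only — never inferred from allele counts,
   so triploid three-allele calls are untouched.

Cultivar naming precedence: modal pomological determination → modal
holder-supplied name → the group id itself. Group trueness aggregates the
member codes: R→1; any of {1, 5, 2} wins in that order; else the most
common of {3, 4} (tie → 3, the weaker claim); 0 (deceased) is dominated by
any other code. Aggregation is order-invariant and idempotent.

**Validation.** The reciprocal match compares each consensus genotype
against every individual profile with *exact* set equality at all markers —
no tolerance, since the question is whether the consensus can be anchored to
a physically existing accession or is a synthetic optimum.

## Synthetic data

The generator emulates the inventory campaign the package was built for:
per-cultivar true genotypes drawn from per-marker allele pools (8–25
alleles in 90–260 bp), 90% diploid / 10% triploid, 1–73 replicate samples
per cultivar, a 37/63 split between an early and a late sampling cohort,
and mutant/sport cultivars (5%) that share their parent's genotype under a
distinct name. Non-mutant genotypes are kept pairwise above the 0.25
distance cutoff by rejection sampling so a noise-free run is perfectly
recoverable (ARI 1.0).

Noise model and defaults, chosen as realistic post-reference-alignment
error levels for capillary SSR sizing: per-allele ±1 bp jitter at 2%,
per-marker amplification dropout at 2%, whole-profile sample swaps at 0.5%,
and the 2 bp cohort offset at CH02g09 applied to in-window alleles of the
early cohort. Every injected error is a ledger entry (jitter and shift as
single substitutions, dropout as the whole dropped call, swaps as sample
pairs); replaying the ledger in reverse restores the noise-free dataset
exactly, which the tests assert. A jitter/shift substitution whose target
value already exists in the call is skipped so every entry stays
invertible. All randomness flows through one seeded NumPy generator with
integer-only allele arithmetic, so output is reproducible across platforms.

What the generator does **not** emulate: realistic per-locus allele
frequency spectra, pedigree/relatedness structure between cultivars, PCR
stutter ladders, or the pomologists' error process (labels are correct
except for injected swaps). Passing recovery tests therefore demonstrates
the pipeline's behaviour under the stated noise mechanisms, not performance
on any particular real collection.

### Recovery behaviour and its limits

With the default conditions (50 cultivars, 1–73 replicates) the pipeline
recovers the partition at ARI ≥ 0.99 and ≥ 95% of molecular classes get an
exactly true consensus; the residual failures are singleton cultivars with
a dropped-out marker, which no consensus rule can repair.

Exact consensus recovery degrades sharply when replicate counts are small
and per-allele jitter is high, and this is structural rather than an
implementation defect. A sample's call at one marker is exactly correct
with probability q ≈ (1−j)² (1−δ) for jitter rate j and dropout rate δ; a
cultivar with k replicates needs the true call to win the tally at all 17
markers. At j = 0.10, δ = 0.05: q ≈ 0.77, so a singleton is essentially
never exact (0.77¹⁷ ≈ 0.01), k = 2 fails on ties about half the time, and
only k ≥ 6 reaches per-marker reliability above 0.995. Averaged over 1–10
replicates per cultivar the expected exact-recovery fraction is ≈ 0.65 —
the measured value — while clustering stays perfect (tolerance matching
absorbs ±1 bp jitter, so ARI = 1.0). The corresponding stress test in the
acceptance suite documents this ceiling; the dropout-only mechanisms (fill
rule, heterozygous preference) do rescue k ≥ 2 cultivars, which is why the
default-conditions test passes.

## Numerical and engineering choices

- Distances are plain float64; comparisons against the cutoff are
  inclusive (d ≤ 0.25). All allele arithmetic is integer.
- The clustering cutoff grid, seeds and problem sizes used in the test
  suite are fixed in the tests themselves; simulations are sized (tens of
  cultivars, ≤ 2,000 samples) to keep the whole suite in single-digit
  seconds while still exercising the deduplicated quadratic path.
- Stage outputs are plain CSV/JSON; reruns with identical inputs,
  parameters and seed are byte-identical, and the run manifest (input
  SHA-256, directive hash, parameter hash, seed, package version) suffices
  to re-execute a run exactly.
- The `pipeline`/`cli` layer is a thin orchestration over the library; every
  scientific operation is importable and individually tested.

## Known limitations

- Mutant/sport cultivars cannot be separated from their parent by SSR
  profile; they are reported as one molecular group (the generator models
  this, and evaluation treats parent + mutants as one class).
- Swapped samples are *placed* with their DNA donor's group but not
  automatically diagnosed as swaps; diagnosis needs the pomological context
  and stays a manual (directive) decision.
- Single-linkage chaining can merge genuinely distinct, closely related
  cultivars near the cutoff; the remedy is a split directive informed by
  pomology, not a tighter global cutoff.
- The reciprocal match is exact by design; a consensus one jitter step away
  from a real sample counts as synthetic.
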