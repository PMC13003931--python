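# Methods

## The quantification problem

Pseudouridine (Ψ) is a mass-silent uridine isomer, so targeted sequencing
assays detect it indirectly through a chemical signature introduced during
reverse transcription: after CMC treatment (or bisulfite treatment in the
BID-seq protocol), a Ψ residue causes the reverse transcriptase to skip the
base, leaving a 1-nt deletion in the cDNA at the modified position. The raw
deletion rate at a site is therefore a *downward-biased* readout of the true
Ψ stoichiometry θ — the chemistry converts only a fraction `p_del_psi` of
modified molecules into deletions. The pipeline's central correction is
normalization to a 100 % ΨTP standard: an in-vitro transcript of the same
sequence context made with ΨTP fully substituting UTP, run through identical
chemistry. Its deletion rate estimates `p_del_psi` directly, and

```
effective_psi = deletion_rate(sample) / deletion_rate(standard)
```

is a consistent estimator of θ when the background deletion rate of
unmodified U is negligible.

## CMC amplicon procedure

Reads are processed in a fixed order:

1. **UMI extraction.** Each read carries a 10-mer unique molecular
   identifier; by default it is the read prefix (`umi_offset = 0`,
   configurable). The UMI is sliced out and the remainder is the payload.
2. **UMI collapse.** For each distinct UMI string, exactly the
   first-encountered read is kept, in original file order. Matching is by
   exact string identity with no mismatch tolerance; the operation is
   idempotent and removes PCR-duplicate weighting.
3. **Anchor matching.** The payload must contain the leftmost exact
   occurrence of the 8-mer upstream anchor followed by the leftmost exact
   occurrence of the 8-mer downstream anchor; any substitution disqualifies
   an occurrence. If the sense strand fails, the reverse complement is
   tried, and the gap sequence is reported back in sense orientation. The
   gap between the anchors must not exceed `max_gap` (default 10).
4. **Classification.** Gap 2 → deletion signature; gap 3 with T at the
   central gap base → retained unmodified; gap 3 with non-T middle →
   retained-mutated; any other admissible gap stays in the denominator but
   in no numerator. The four buckets partition the anchor-matched reads —
   an invariant checked at run time on every input.
5. **Rates.** `deletion_rate = n_del / n_anchor_matched`;
   `mutation_rate = n_ret_nonT / n_anchor_matched`. A locus with zero
   anchor-matched reads is an explicit error naming the locus, never a
   silent zero; no pseudocounts are used.
6. **Normalization.** `effective_psi = deletion_rate / standard_deletion_rate`.
   Values above 1 are reported as-is with a warning so calibration bias
   stays visible; capping at 1 is opt-in (`clamp`).

Design choices where the procedure was genuinely open:

* **Both anchors are required.** Gap lengths are only defined between two
  matches, so "upstream or downstream" is read conjunctively. A permissive
  `single_anchor` mode (off by default) accepts one perfect anchor and
  infers the gap from the best Hamming placement of the other, ties broken
  toward the smaller gap.
* **Denominator.** "Total sequences at a locus" is all reads with both
  perfect anchors at gap ≤ `max_gap`; reads at other gaps dilute the rates
  rather than being discarded — the conservative reading.
* **Headline statistic.** `effective_psi` uses the deletion rate only
  (consistent with the BID-seq normalization); the mutation rate is always
  reported alongside.
* **Collapse before matching.** UMI collapse precedes anchor matching, so
  a duplicate whose anchors were corrupted by sequencing error can shadow
  a clean copy under the same UMI. This matches the stated processing
  order and costs only sequencing-error-sized losses.
* **No quality filtering by default.**

## BID-seq procedure

Input is a pre-extracted per-read record stream (read_id, position,
covered, deleted) rather than BAM, keeping the module testable without an
aligner. Records aggregate into a per-position pileup; the deletion rate is
deletions/coverage, *undefined* (NaN) rather than 0 at zero coverage. Site
calls require `min_coverage` (default 100) in both sample and standard —
below it the site is a no-call, not a 0. Site-level effective Ψ shares the
exact normalization contract of the CMC module: identical rate pairs give
identical values.

## Assay statistics

* **Relative expression** assumes perfect amplification efficiency
  (doubling per cycle): `2^(mean Cq_control − mean Cq_target)`, replicates
  averaged on the Cq scale before exponentiation (per-replicate ratio
  averaging is available behind a flag). Nuclear-to-cytosolic enrichment is
  the ratio of the control-normalized expressions of the two fractions;
  per-fraction dilution factors shift every Cq in a fraction by a constant
  and cancel exactly. Dual-housekeeping designs are computed as separate
  single-control results reported side by side, not a geometric mean.
* **Gel PSI**: band intensity from intercalating dyes scales with mass, so
  molar amount = intensity / length_bp and
  PSI = molar_included / (molar_included + molar_excluded). dPSI between
  conditions is PSI_treated − PSI_control.
* **Sanger A>I editing**: inosine base-pairs like guanosine, so the editing
  fraction at the targeted adenosine is g / (a + g) of the peak heights.
  The module consumes a peak-height table; chromatogram parsing is out of
  scope. g/(a+g) is the field-standard estimator, adopted here as an
  explicit assumption.
* **Luciferase**: per-well FLuc/RLuc with per-condition means.
* **Performance correlation**: per-gene ratio of mean editing efficiencies
  (U7smOPT snRNA construct over cadRNA construct), Pearson-correlated
  against a covariate such as exon count. `pearson_with_p` implements the
  product-moment formula directly with the two-sided p-value from
  t = r·√((n−2)/(1−r²)) on n−2 df; the direct formula returns exactly ±1
  on colinear integer-representable data, which library implementations do
  not guarantee.

## Synthetic-data model

The generator produces every input above with known truth. Per molecule:
Ψ with probability θ; if Ψ, deletion with `p_del_psi`, else non-T
misincorporation with `p_mut_psi`; if unmodified U, deletion with `p_del_u`.
Each molecule gets a uniform random UMI (4^10 space; ~0.5 % collision mass
at 10,000 molecules — collisions are kept, as in real libraries), a
geometric number of PCR duplicates (mean `dup_mean`, the simplest
memoryless amplification model), and per-base substitution sequencing error
applied *after* duplication so duplicates can disagree and anchors can be
corrupted — such reads realistically fail matching downstream. The 100 %
ΨTP standard generator is the same model with θ forced to 1 (byte-identical
to a θ=1 sample at the same seed). BID-seq reads tile the reference
deterministically with per-read, per-site stochastic deletion. Cq tables
follow Cq = 20 − log2(abundance) + N(0, σ); the baseline 20 is arbitrary
and documented since only differences matter. Performance tables plant a
chosen Pearson correlation between the ratio and an integer exon count via
the standard bivariate construction, with uncorrelated decoy covariates.

What the generator does **not** emulate: full-length transcriptome reads,
paired-end insert-size structure, alignment artifacts, UMI sequencing
errors creating phantom molecules, PCR jackpotting beyond the geometric
model, or CMC/bisulfite side reactions beyond the deletion/mutation
signature. Passing recovery tests therefore shows the estimators invert
the stated generative model, not that they are robust to every artifact of
real libraries.

## Numerical and testing choices

* Probabilities validated to [0,1] at construction; degenerate inputs
  (zero matched reads, zero standard rate, zero coverage, zero A+G signal)
  raise named errors rather than returning 0.
* All randomness flows through `numpy.random.default_rng(seed)`; seeds are
  mandatory arguments and recorded in JSON provenance sidecars, from which
  a demo run is reproducible byte-for-byte (output paths are excluded from
  provenance as non-scientific).
* Statistical tests run at 10,000 molecules / 10,000× coverage, where the
  binomial standard error of the normalized ratio is ≲0.014 in the worst
  grid cell; recovery assertions at ±0.02 are therefore sharp rather than
  generous, and tests use fixed seeds.
* The end-to-end demo quantifies a θ grid {0, 0.25, 0.5, 0.75, 1} against
  one shared 100 % standard and writes a plot-ready recovery TSV.

## Known limitations

* Only 1-nt deletions of the central base are modeled and classified;
  multi-nt deletion signatures fall into `n_other_gap`.
* The effective-Ψ estimator is biased upward by
  (1−θ)·p_del_u/p_del_psi under nonzero background — measured and matched
  by the bias test; no background subtraction is attempted.
* UMI collapse trusts UMIs literally: sequencing errors inside a UMI
  create phantom molecules (not simulated, not corrected).
* The single-anchor permissive mode uses a heuristic Hamming placement and
  is intended for diagnostics, not headline rates.
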