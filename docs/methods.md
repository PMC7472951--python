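# Methods

This note records the models, conventions and numerical choices behind
`repdiv`, and what the simulator does and does not emulate.

## Generative model of a sample

A sample (one animal's sorted B-cell mRNA) is modelled as:

1. **Naive clones.** `n_naive_clones` activated naive B-cell ancestors,
   each built as a random germline V segment, a non-templated junction
   insert, and a random germline J segment. Synthetic V segments are
   285–300 nt, in frame, stop-free, ending three codons after the
   conserved 2nd-CYS anchor; J segments are 45–60 nt with 2–4
   CDR3-templated codons before the conserved J-TRP anchor. Junction
   inserts are 0–12 nt with 90% of the mass on multiples of three,
   weighted to peak at 6–9 nt: TdT N-additions average a handful of
   nucleotides and empty junctions are uncommon, while frame-preserving
   lengths dominate because out-of-frame rearrangements are re-drawn by
   the productivity retry loop (ancestors are productive by
   construction; the loop aborts with the seed after a bounded number of
   failures). Resulting CDR3s are 4–10 aa — shorter than the murine
   CDR-H3 average because the synthetic V/J carry minimal CDR3 template,
   which matters for none of the statistics tested.
2. **Clone sizes.** `n_molecules` mRNA molecules are apportioned to
   clones by a uniform, geometric (default, ratio 0.98) or power-law
   weight vector using largest-remainder rounding, with every clone
   guaranteed at least one molecule. The geometric default gives the
   mild dominance structure expected of an immunized plasma-cell
   compartment; the law is configurable because the true clone-size
   distribution of such samples is not established.
3. **Somatic hypermutation.** Each molecule is its ancestor with
   independent per-base substitutions at `shm_rate` (no indels, no
   hot-spot motifs). Defaults: 1.5%/base for IgG, 0.3%/base for IgM,
   reflecting the much heavier mutational load of class-switched
   transcripts. Ground truth records every mutated position.
4. **Reads.** Every molecule receives a distinct random 14-nt UMI
   (collisions redrawn and logged); `reads_per_molecule` single-end reads
   cover UMI + full variable region. Sequencing errors are independent
   per-base substitutions at `seq_error_rate` (default 0.001) applied to
   the sequence region; per-base Phred values are drawn around the
   quality corresponding to that rate (cap Q40, jitter σ=2). The UMI
   field itself is emitted error-free: exact-match UMI grouping is the
   documented contract of the consensus stage, and UMI-error network
   merging is deliberately out of scope.

**What this does not emulate.** Paired-end 250 bp chemistry and read
merging (reads are single-end over the full region); SHM lineage
structure *within* a clone — every molecule mutates independently from
the naive ancestor rather than descending through an expanding tree.
Two consequences to keep in mind when transferring conclusions to real
data: (a) nucleotide-identical expanded clones are common in real
plasma-cell data (transcripts of one cell share one genome) but arise
here only when `shm_rate` is low, so IgG-level simulations have
`n_large_clones ≈ 0` at desk depth while IgM-level ones behave
realistically; (b) intra-clone CDR3 variants sit at most one mutation
step from the ancestor rather than forming longer chains. Neither
affects the validity of the boundary, refinement, recovery or
calibration checks, which is what the simulator exists for.

## Consensus stage

Reads are grouped by exact UMI match. Groups below `min_reads_per_umi`
(default 2, a MIGEC-like floor) are rejected and counted. Within a
group, reads whose length differs from the modal length are excluded
from voting (ties on the modal length go to the shorter length); the
consensus base per column is the majority vote, ties broken by higher
summed Phred, then alphabetically — a fully deterministic rule.
`mean_phred` averages the qualities of consensus-supporting bases, and
the quality filter keeps consensuses with mean Phred strictly over 20
("over 20" is read as a strict inequality; 20.0 is rejected, 20.01
kept). Consensus construction is permutation-invariant in read order.

## Annotation

V and J segments are assigned by semi-global ("infix") alignment of each
full germline segment against the query using edlib's bit-vector edit
distance: the reference must align end-to-end, query overhangs are free,
and the lowest-distance reference wins with ties broken by name order.
Unit edit costs order candidates identically to a match/mismatch scoring
scheme on the substitution-only data this pipeline models, and run two
orders of magnitude faster, which is what makes annotating every
molecule at acceptance scale practical. Identity is
matches / aligned-reference-columns computed from the alignment path;
queries whose best distance exceeds `max_dist_frac` (default 0.35) of
the reference length are unassigned, excluded and counted. The J search
is restricted downstream of the V alignment end, mirroring the physical
layout. The CDR3 is the nucleotide stretch strictly between the V-Cys
and J-Trp anchor codons (both excluded — IMGT's CDR3, two codons
narrower than the junction; the classic off-by-two trap is covered by
tests). Productivity = CDR3 length divisible by three and a stop-free
translation of the variable region. Coordinates are 0-based half-open
internally.

Two caveats inherent to alignment-based mutation counting: a
substitution in the terminal 1–3 bases of a templated segment, or two
substitutions within a few bases of each other, can be explained by an
equally cheap shifted/indel path, so mutation counts are exact for
isolated interior substitutions and may differ by ±1 otherwise (IMGT
output has the same ambiguity). Internal consistency — identity 1.0 if
and only if zero counted mutations — holds unconditionally.

## Diversity measures

Clone definitions nest (nucleotide ⊂ CDR3VJ ⊂ CDR3), so richness obeys
`n_cdr3 ≤ n_cdr3vj ≤ n_distinct_nt` on any input; this is asserted
property-style across seeded samples. Abundance is counted in
UMI-collapsed molecules, never raw reads — the UMI stage exists to make
that the meaningful currency. Large-clone counting uses a strict
threshold (frequency > 0.5%), expanded-vertex flagging in the network an
inclusive one (≥ 0.5%); both boundary conventions are deliberate,
distinct, and pinned by tests at exactly 5/1000. VJ100 counts distinct
nucleotide sequences with 100% V and J identity; the non-templated
junction may vary freely, since an unmutated naive-derived molecule can
carry any junction. Shannon uses the natural log (ecology convention);
`inverse_simpson ≤ exp(shannon) ≤ richness` (Hill-number ordering, with
equality exactly for uniform abundances) is enforced on random
probability vectors. Richness is reported raw, matching standard
practice at matched depth; a rarefaction helper exists but is an
explicitly labelled extension, off by default.

The CDR3 length spectrum's normality test defaults to Shapiro–Wilk and
is reported not-applicable for degenerate input. Shapiro–Wilk is
oversensitive to the integer discreteness of length data: on
integer-rounded normal samples it rejects almost always by n ≈ 200 even
though the underlying distribution is normal. For samples deeper than a
few hundred molecules the D'Agostino option (`test="normaltest"`), which
is robust to this granularity, is the better choice; the choice is
config-exposed and recorded in the output.

## Similarity network

Vertices are distinct nucleotide sequences (weight = molecule count;
clonotype-level vertices by option); edges connect equal-length CDR3
keys at Hamming distance ≤ 1 — amino-acid keys by default, nucleotide
keys by flag, and every report names the rule used. Substitution-only
matching (no indel tolerance) keeps the edge relation exactly checkable
against a brute-force transitive-closure oracle, which the tests do for
hundreds of random inputs. Edges are found by neighborhood hashing
(each key filed under all single-position masks), which is exact and
near-linear. Graphs are built per sample, never pooled across animals.
Cluster counts undercount true naive-lineage numbers slightly when two
clones draw CDR3s within one step of each other — a property of the
statistic itself, visible here as a few-percent compression of
between-group fold changes.

## Spectratype

Peak tables (`length_bp,area` CSV) merge duplicate lengths by summing
area and drop peaks at or below a configurable noise floor (default 0).
Area is the abundance proxy (pass height data in the area column to use
height). Lengths are assumed integer after peak-caller rounding; a
binning tolerance is available for fractional input. Group comparisons
pool each group by union of peak lengths; `unique + common = pooled
richness` holds by construction and is asserted. Index computations
reuse the clonotype implementations on area proportions.

## Group statistics

Unpaired two-sided Student's t-test by default (the conventional default
of desk statistics packages; Welch by flag, Mann–Whitney for
distribution-free comparisons), fold change = mean(B)/mean(A), SEM =
SD(n−1)/√n, stars at 0.05/0.01/0.001. No multiple-comparison correction
is applied by default; Benjamini–Hochberg is available as an explicit
opt-in. Comparisons of constant identical groups (e.g. all-zero
large-clone counts) are flagged degenerate with p = 1 rather than
producing spurious statistics. The statistics path is calibrated: under
the null (identical group configurations) the t-test on cluster counts
rejects at ~5% at α = 0.05 across 200 simulated replicates.

## Reproducibility and problem sizes

Every stochastic stage receives a sub-seed derived by SHA-256 hashing of
(master seed, sample id, stage name), truncated below 2³¹ and recorded
in the run manifest; reruns are byte-identical. Scenario presets mirror
classic immunized-mouse designs (2–6 animals per group, CD138⁺ plasma
cells or antigen-specific CD19⁺ cells, IgG or IgM), with the
transgenic-like group of immunized presets carrying 1.16–1.7× as many
activated naive clones. The package's standard problem sizes are 800
molecules per sample (600 in replicate studies) at 3 reads per molecule,
200-replicate null calibrations, and 10–20 replicate contrast-recovery
studies; these sizes give stable statistics while keeping any study a
matter of minutes on a single CPU.

## Known limitations

- No D-segment assignment or allele-level calls (none of the computed
  measures use them); no indel SHM; no light chains.
- The annotator is a minimal stand-in for full IMGT/HighV-QUEST
  annotation; for real data the table readers accept IMGT or AIRR
  output directly and are the recommended route.
- Spectratype analysis starts from peak tables; raw electropherogram
  processing and fragment-size calibration are out of scope.
- Simulator realism limits are described above; in particular, absolute
  values of `n_large_clones` and `n_vj100` under IgG-level SHM are
  small by construction and should not be compared to deep-sequencing
  values from real repertoires.
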