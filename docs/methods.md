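# Methods

## Scope and model

`pyroprof` analyses amplicon reads of antibody variable domains (FV)
against *known* references — the setting of a control experiment in which
molecules of Sanger-verified sequence are pyrosequenced and every
difference between a read and its reference is, by construction, a
sequencing error. All statistics are therefore conditional on the correct
reference being supplied; the package does not search a germline V-allele
database, and "functionality" is called against the supplied reference's
frame and conserved residues rather than by junction analysis.

## Reference model

A reference is a contiguous tiling of the six FV regions (FR1, CDR1, FR2,
CDR2, FR3, CDR3) read in one frame with no internal stop codon, carrying
conserved framework anchors (Cys at the end of FR1, Trp at the start of
FR2, Cys at the end of FR3). `generate_reference` builds such sequences
codon-by-codon (stop codons rejected), writes the conserved codons, and
plants polyG runs of 2–4 nt, at least one inside CDR1 — the hotspot where
pyrosequencing run-miscounts concentrate. Default layout: 78/24/51/30/114/33
nt = 330 nt, all parameters exposed. Generation retries deterministically
under a fixed seed until every invariant holds.

## Coordinate convention

One convention binds the whole package: an insertion occurs *before* a
0-based reference position; deletions and substitutions occupy half-open
reference intervals. Indels are left-normalized — shifted to the leftmost
alignment-equivalent placement, rotating inserted strings as needed — so an
indel inside a homopolymer run always reports the run's leftmost
coordinate. Simulator truth logs, aligner events and recurrence signatures
are directly comparable because all three use the canonical form.
Same-type events that land on one canonical position (insertions) or
become adjacent (deletions) merge into a single multi-base event, so two
single-G insertions in one 2-G run report as one length-2 event
("4G in place of 2").

## Alignment

Scoring is match +2, mismatch −1, gap −1 per base. The BLAST-style gap
parameters this mirrors state no separate extension cost, so gaps are
linear; affine scoring is deliberately not implemented. The aligner
computes the maximal-scoring *contiguous* alignment with free end-gaps on
both sequences (the deterministic equivalent of a single local HSP):
unaligned read overhangs are free, and uncovered reference ends mean
truncation. Linear gap costs admit an O(nm) row-wise prefix-max recurrence
(each row is a vectorized running maximum), which keeps a 330×330 problem
under ~1 ms. Traceback is deterministic: diagonal over deletion over
insertion, ties at the optimum broken towards the largest aligned spans;
optimal local alignments necessarily start and end on match columns. `N`
(and the pad `n`) mismatch every base, so an ambiguous base can never
create a spurious match.

The full-length filter retains a read only if its aligned span covers the
whole reference, mirroring the study design of keeping only reads spanning
the complete FV.

**Boundary behaviour.** A consequence of any reference-bounded comparison
is that events at the reference boundary are unobservable: an insertion
extending a terminal homopolymer run is alignment-equivalent to a longer
read overhang, and a deletion of the final base is indistinguishable from
1-nt truncation. The simulator therefore plants events only at interior
canonical positions (and never extends runs touching the 3′ end), which is
also the realistic regime — amplicon primers flank the domain, so
biological errors of interest are interior. A truncated erroneous read
whose tail coincidentally matches shifted reference positions can still be
scored as covering the reference (the gap is then reported as an interior
deletion); this ambiguity is inherent, not an implementation artifact.

## Read simulation

Each read independently draws a category from a six-way mixture whose
defaults encode the observed 454 error spectrum: 60% accurate, 12% single
1-nt insertion, 8% multi-insertion (2–3 insertions), 5% single deletion,
5% single substitution, 10% mixed. The published spectrum reports
"deletion and single substitution together" at 10% without a split; the
package defaults to an even 5/5 split, configurable. "Mixed" is simulated
as 2–4 single-nt events spanning at least two event types.

Indels are placed inside a homopolymer run (length ≥ 2) with probability
`homopolymer_bias` (default 0.8 — the published account says "mostly" at
runs without quantifying; the parameter is exposed and never asserted).
Run-extending insertions draw their base from `insertion_base_probs`
(default G 0.55, A 0.20, C 0.20, T 0.05, encoding ">50% G" with the rest
ordered C ≈ A ≫ T) and then a run of that base, optionally weighted by
hotspot triples (position, base, weight); random-site insertions draw
position uniformly and base from the same distribution. Deletion runs are
chosen uniformly (the spectrum does not constrain deleted-base
composition). Multi-event reads enforce a ≥10-nt canonical separation so
events cannot coalesce into a different alignment explanation; this is what
makes "classifier category == planted category" essentially deterministic,
leaving only binomial mixture noise — the property the replica tests rely
on. Reads are built by replaying the planted events, so the truth log
reproduces each read exactly by construction.

## Classification

Categories partition all full-length reads: no events → accurate;
insertion-only events → single_insertion (1 nt total) or multi_insertion
(≥2 nt total, whether one longer run-miscount or several sites); exactly
one 1-nt deletion or substitution → the corresponding single category;
everything else (≥2 distinct types, or one non-insertion event of ≥2 nt)
→ mixed. Pure multi-insertions stay in the insertion class, keeping the
"~12% single vs ~20% combined insertion" distinction computable.
`frameshift` is (inserted − deleted) mod 3 ≠ 0; `premature_stop` scans
complete codons of the read from the reference frame offset.

Insertions are localized to the region whose half-open interval contains
their canonical position; a boundary insertion belongs to the region
starting there (its bases precede that region's first base). CDR3 events
are labelled like any other region.

## Composition deltas and recurrence

The composition-difference vector (dA, dG, dT, dC) is the read-minus-
reference base count; its components sum to the length difference. A
recurrence signature is the delta vector refined by canonical event
positions (default), which separates a hotspot insertion from equal-
composition insertions elsewhere; composition-only grouping is available as
an option since a delta-only view is also informative. Signatures are
reported when they recur in ≥ 0.5% of erroneous reads (configurable).

## Correction and functionality

Correction is two-pass: pass 1 aligns the read and takes its indel events;
insertions are excised from the read and deletions padded with lowercase
`n` at the deleted coordinates, restoring reference length and numbering;
pass 2 re-aligns the edited read and re-calls functionality. Substitutions
are never modified. A codon containing `n` translates as `X`: never a stop,
and breaking a conserved-residue check only when the conserved codon itself
is padded. Verdicts: productive = in frame and stop-free; stop_codon = any
internal stop; unproductive = frameshifted without a stop; no_alignment =
coverage-weighted identity (column identity × covered reference fraction)
below 60%, a configurable floor operationalizing "no rearrangement" — the
weighting prevents a short accidental local hit from counting as identity.
`recovered` means not-productive before and productive after. Recovery is
reported against both denominators (all reads, erroneous reads) since
either convention is defensible.

Correction is idempotent (a corrected read re-aligns with no indels), never
touches match or substitution columns, and makes every indel-only
simulated read productive. Substitution-only reads that stay in frame and
stop-free pass through untouched and productive — the mechanism behind a
residual, uncorrectable error fraction equal to the substitution rate.

## Numerical and testing choices

- All randomness flows through explicitly seeded numpy `Generator`
  streams; one stream per simulation call, no global state. Pipelines are
  byte-identical across reruns with a fixed seed.
- Category percentages are reported to 0.1%.
- Stochastic tests compare observed shares to configured probabilities
  within 3 binomial standard errors at their sample size.
- The aligner is validated against an independent recursive exhaustive
  scorer on all short pairs over a two-letter alphabet plus seeded random
  pairs up to 12 nt (the exhaustive-pair space at 12 nt is astronomically
  large, so random pairs stand in beyond length 3), and cross-checked
  against unit-cost edit distances from `edlib` on single-edit reads.
  Round-trip and normalization idempotence run on 10,000 random cases.
- Replica problem sizes: n = 5000 reads for mixture-recovery checks
  (3 SE of a 12% share is ±1.4 points), n = 3000 for the substitution
  residual, smaller batches for per-read properties.

## What the simulator does and does not emulate

It emulates the *category mixture*, homopolymer concentration, G-dominance
and hotspot recurrence of 454 antibody reads — the features the analysis
stages consume. It does not emulate flowgram-level signal, quality scores,
chimeras, primer sequences, read-length variation or carry-forward/
incomplete-extension artifacts. Passing replica tests therefore show that
the pipeline recovers a known error structure of this shape from raw
sequences; they do not certify performance on real flowgram data, where
error rates vary with run length and position in ways this model holds
fixed.

## Known limitations

- Single-run design: substitutions that stay in frame cannot be detected,
  and nothing here replaces repeated sequencing for them.
- Events at reference boundaries are unobservable (see above).
- Each read must come with its known reference; there is no multi-
  reference assignment or germline database search.
- Affine gap costs and quality-aware alignment are out of scope.
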