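# Methods

## The screening model

The package implements a staged funnel for identifying candidate
micropeptide-encoding lincRNAs in a tumor context. Each stage consumes the
survivors of the previous one; promoter chromatin annotation is computed
alongside but deliberately never filters, because open chromatin explains
tumor-specific expression rather than defining it, and real screens retain
candidates whose accessibility data are simply missing or negative.

**Exclusivity.** Expression state is a three-way classification of FPKM:
*on* at or above τ_on, *off* at or below τ_off, *ambiguous* in between. A
transcript is exclusive iff on in the tumor sample and off in every normal
sample. Ambiguity in a normal sample disqualifies: a candidate with
low-but-nonzero normal signal is not tissue-exclusive, and treating the gray
zone as failure is the conservative choice. Defaults τ_on = 1.0 FPKM (the
conventional "expressed" floor for bulk RNA-seq) and τ_off = 0.0 (strict
silence; the worked-example table prints exactly 0 in liver, and its
smallest retained tumor value is 13.7 FPKM, far above any plausible floor).
Both are configuration-exposed. The screen is monotone: raising τ_on or
lowering τ_off can only shrink the exclusive set, a property the test suite
checks directly.

**Replicate confirmation** re-applies the *on* test in an independent tumor
dataset. Transcripts absent from the replicate are dropped and logged rather
than silently passed: absence of evidence is treated as failure to confirm.

**Promoter annotation.** The proximal promoter is a strand-aware window of
1000 bp upstream and 500 bp downstream of the TSS — a conventional proximal
definition, since "proximal promoter" has no single canonical size; both
extents are configurable. Overlap counting uses ≥ 1 shared base under
0-based half-open semantics and ignores strand (DNase accessibility is
unstranded). *Differentially open* = at least one tumor DNase peak and zero
normal peaks in the window; the boolean is invariant to duplicated peaks by
construction. CAGE support means a CAGE cluster within ±100 bp of the
annotated TSS (cap sites scatter a few tens of bp around annotated starts;
the slack is configurable). TF/histone ChIP tracks are counted generically
by name with no per-factor logic.

**ORF model.** Only the three sense-strand frames are scanned — the
transcript itself is the molecule being translated, so antisense frames are
irrelevant. An ORF runs from the 5′-most ATG to its first in-frame stop;
there is one ORF per (frame, stop) pair, which keeps ORF counts well-defined
(downstream in-frame ATGs are alternative starts of the same ORF, not new
ORFs). ORFs lacking an in-frame stop before the transcript end are discarded
(no read-through assumption). The length filter is strict — "longer than
50 aa" admits 51 and rejects 50. Codons containing N match neither ATG nor a
stop, and translate to X. Kozak scoring uses the two context positions with
dominant effect on initiation (purine at −3, G at +4); positions beyond the
sequence ends count as failing, so a transcript-initial ATG can be at most
adequate. Peptide masses are sums of *average* residue masses plus one water
(18.02 Da), matching kDa-scale gel estimates rather than mass-spec
monoisotopic values.

**Export.** Cytoplasmic fraction = cyt/(cyt + nuc) from compartment FPKMs.
The default export threshold is 0.2: the biological requirement is clear
cytoplasmic presence, not cytoplasmic dominance, so the floor is low;
a transcript detected in neither compartment is reported as not expressed
and excluded rather than scored. With threshold 0 every expressed transcript
is exported (degenerate-configuration sanity check in the suite).

**Polysome quantification.** qPCR amplifies exponentially, so template
abundance in fraction *i* is proportional to E^(−ct_i) with per-cycle
efficiency E ∈ (1, 2]; normalizing across fractions gives the RNA
distribution p. This makes p invariant to any global CT offset — only
relative cycle differences carry information — and the implementation
subtracts the minimum CT before exponentiating so late CTs cannot underflow.
Missing CT (no amplification) is zero abundance, not an imputed
limit-of-detection value: simpler and conservative. Efficiency is fixed at
2.0 (perfect doubling) unless configured; per-assay efficiencies are an
input, not estimated. Polysomal fractions default to the bottom 40% of the
gradient (heavy, multi-ribosome material sediments deepest); which fractions
are truly polysomal comes from the absorbance trace in practice, so the set
is configuration-declared. The translated call uses a 0.5 polysomal-mass
cutoff: a majority of the transcript on polysomes. The qPCR positive control
(e.g. Actin) is carried through the CT table but not used for normalization
by default — the shift-invariance of p makes a spiked-control correction a
no-op for within-transcript distributions.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
the sequence content of any real genome:

- **Expression.** Planted exclusive transcripts draw tumor FPKM as
  τ_on + LogNormal(ln 30, 0.5) — median ≈ 31 FPKM, matching the 13.7–105
  FPKM range of the worked example — and are exactly zero in all normals.
  A leakage probability flips individual normal cells to small positive
  values, the realistic failure mode of tissue exclusivity. Background
  transcripts are expressed in 1–4 random normal tissues and half of them in
  the tumor as well. The replicate redraws tumor values and zeroes the
  planted-but-unconfirmed ids.
- **Default cohort size.** 500 transcripts, a 17-tissue normal panel
  (liver + 16 body tissues), truth counts 12 exclusive / 9 confirmed /
  6 ORF-bearing / 5 exported / 3 translated, 7 open promoters — the funnel
  shape of the motivating screen. These are the default study conditions;
  all counts are arguments.
- **Sequences.** ORFs are planted as cassettes (engineered −3/+4 context,
  ATG, random non-stop codons, stop) in random background on a toy
  chromosome, 900 nt per transcript by default. Planting is
  *scanner-verified*: each sequence is re-scanned with `find_orfs` and
  resampled until its qualifying-ORF content equals the request, with a
  bounded retry budget (default 100) and a hard error after that — explicit
  rather than silently biased. Transcripts are single-exon models; splice
  complexity is out of scope.
- **Tracks.** Open-promoter ids get a tumor DNase peak, a cCRE and a CAGE
  cluster at the TSS; decoy normal peaks land at non-candidate promoters.
- **CT tables.** Built by inverting the fraction-distribution formula from a
  target mass vector (translated: 75% polysomal; others: 15%) around a
  20-cycle offset, then adding Gaussian CT noise of configurable sd.

What the generator does **not** emulate: real genomic coordinates, GC
composition or codon usage, splice isoforms, FPKM estimation noise,
replicate-level qPCR variance structure, or cross-contamination between
gradient fractions. Passing tests therefore demonstrate that the pipeline's
logic recovers planted signal under its own model assumptions — they do not
validate FPKM quantification or peak calling, which are upstream of this
package by design.

## Numerical and design notes

- Coordinates are 0-based half-open everywhere internally (BED convention);
  1-based conversion helpers are provided and round-trip exactly.
- Tie-breaks: exclusive calls sort by descending tumor FPKM, then id.
- The worked-example check cannot be extended to the real flagship
  transcript's nucleotide sequence, which lives in an external lncRNA
  database; the acceptance path instead scans a synthetic stand-in planted
  with the same published ORF layout (52 aa weak + 68 aa strong Kozak) and
  is labelled synthetic wherever it appears.
- Mass bounds: any n-residue peptide lies between all-glycine
  (57.05 n + 18.02) and all-tryptophan (186.08 n + 18.02) Da; property tests
  use these extremes.
- Problem sizes in the default test and acceptance runs (500-transcript
  cohorts, 300 random sequences for scanner-oracle equivalence, 1000 random
  interval cases, 20 seeds per CT-noise level) were chosen as the smallest
  sizes at which the checked properties are non-trivial; everything runs in
  seconds.

## Known limitations

- Non-AUG starts, ribosome-profiling-based ORF calling and coding-potential
  classifiers are out of scope; the ORF stage is a pure sequence scan.
- FPKM tables are consumed as given — no normalization or differential
  expression; upstream quantification choices propagate untouched.
- The polysome stage models one gradient, one efficiency value, and no
  replicate variance; disagreeing replicates must be reconciled upstream.
- Promoter annotation consumes called peaks; peak calling from coverage is
  explicitly not implemented.
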