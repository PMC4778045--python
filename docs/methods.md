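# Methods

`dropscreen` simulates a droplet in-vitro two-hybrid peptide screen and
implements the deep-sequencing analysis used to read one out. This note
records the model, the parameters that matter, the numerical choices,
and what the synthetic data do and do not capture.

## Library model

A `LibraryDesign` is a scaffold peptide with degenerate codons at chosen
1-based positions. The default randomizes positions 3, 7 and 10 of
`TSFAEYWNLLSP` (the hydrophobic triad F/W/L critical for MDM2 binding;
chosen to mirror p53's F19/W23/L26) with NNK codons. NNK expands to
4×4×2 = 32 codons covering all 20 amino acids and exactly one stop
(amber TAG); enumeration excludes stop-containing combinations at the
peptide level, yielding 20³ = 8000 variants over 31³ = 29 791 stop-free
codon triples, and groups synonymous combinations ("genotypes") per
peptide — `FWL` has 3 (F×1, W×1, L×3). Antisense schemes (MNN) are
reverse-complemented to the sense frame before expansion, so MNN ≡ NNK.

The flank sequences (T7 promoter context upstream, a 100-nt
DNA-binding-domain fusion stub downstream) are synthetic placeholders of
realistic length, since only their roles, not their sequences, are fixed
by the construct design; both are configurable. Scaffold codons are
common E. coli codons; any synonymous choice gives the same peptide
space.

`expected_variant_frequency` reports the uniform-codon-synthesis null
(genotype multiplicity over stop-free triples; `FWL` → 3/29 791 ≈
1.01×10⁻⁴). Measured input libraries typically deviate from this null
(synthesis and amplification bias); the package reports the null but
does not fit the bias.

## Drop loading

Templates per drop are Poisson(λ); identities are drawn with replacement
from per-variant weights. Two weightings are built in:

- `uniform` (default): every peptide variant at 1/N. This is the
  equimolar-library idealization that the standard screening arithmetic
  assumes — expected binder drops N_drop·λ/N_library, e.g. 37.5 ≈ 38
  for 3×10⁶ drops over 8000 variants at λ = 0.1, or 12.5 per 10⁶ drops.
- `genotype`: weights proportional to genotype multiplicity, as
  uniform-codon NNK synthesis would produce (binder rate 3/29 791,
  ~10.1 binder drops per 10⁶). Explicit per-variant abundances override
  both.

Leaked transcripts — mRNAs made by the polymerase in the bulk mix before
encapsulation — are loaded independently at `leakage_rate` (default 0.2
per drop) from the same weights. They carry genotype information into
downstream sequencing but never produce fluorescence; they are the
mechanism by which non-binder sequences appear in bright-pool reads.

`plan_screen` exposes the design arithmetic: drops required =
coverage·N/λ, with warnings above λ = 0.1 (doublet false positives:
P(2) = 3.9% at λ = 0.33) and below it (empty-drop throughput cost).
Reports carry the closed-form doublet fraction and the formula value of
drops-per-binder-drop (N/λ = 8.0×10⁴ for the default screen); informal
roundings of these quantities in circulation (3%; 1.2–1.3×10⁵) are not
reproduced.

## Fluorescence and sorting

A drop holding k high-affinity templates has mean normalized
fluorescence `baseline + increment·k^cooperativity`; defaults (1, 1,
1.35) put the empty-drop peak at 1.0, one template at 2.0 and two at
≈3.55, matching the observed bimodal histogram shape and the >3.5
multi-template signals. The exponent is the package's choice of
functional form; nothing deeper than "reconcile 2.0 at k=1 with >3.5 at
k=2" constrains it. Low-affinity templates and leaked transcripts
contribute nothing; affinity is a binary label (the screen demonstrates
only signal-positive ~3 nM and signal-negative ~46 nM endpoints).

Peak noise is Gaussian (σ = 0.10) truncated at ±3σ and at zero. The
truncation is deliberate: measured drop histograms show compact,
well-separated peaks, and a heavy Gaussian tail on the 90%-mass
empty-drop peak would put Φ(−3) ≈ 0.13% of empty drops above a 1.3
gate — thousands of false-positive bright drops per million, orders of
magnitude more than a real sorter records. With truncation the
empty-drop support is [0.7, 1.3] and the bright count of a binder-free
screen is exactly zero, so bright counts are driven by binder occupancy
(Poisson) alone. Sampling uses the inverse-CDF on one uniform per drop.

Sorting partitions drops at the threshold (default 1.3, over
width-gate-passing drops); the pulse-width gate excludes a Bernoulli 1%
of drops independent of content, standing in for merged/split-drop
rejection. Normalization is implicit: fluorescence is generated directly
on the normalized scale, avoiding an arbitrary raw-intensity unit.

## Read simulation

RT and PCR are collapsed into one bias stage: pool abundance per variant
∝ (template count × `transcripts_per_template` + leaked count) ×
LogNormal(0, `efficiency_sd`). `transcripts_per_template` (default 300)
encodes that an expressed drop contributes on the order of hundreds of
mRNA copies per DNA template, versus one molecule per leaked transcript;
the exact ratio is not identifiable from available data and is
configurable. `efficiency_sd` defaults to 0.5 — a typical 2–3-fold
amplicon bias; at 1.0 (exercised in tests) per-genotype biases exceeding
5-fold are common enough to distort small pools noticeably.

Reads are 56-bp windows of the template, centered on the span of the
variable codons so all three plus constant anchors fit in one read
(window offset configurable). Substitution errors are i.i.d. per base
(default 10⁻³); no indels or chimeras. Qualities are flat at Q35 with an
exponential 3′ decay (start 40, rate 0.15 per base, SD 3) whose tail
falls below Q20, so quality trimming has real work. Output is Phred+33
FASTQ, deterministic under a seed.

## Sequencing analysis

Trimming removes a configurable 3′ adapter first (suffix match,
including partial prefixes, with configurable mismatches), then applies
the running-sum quality trim: subtract the cutoff (Q20) from each Phred
score and cut at the position minimizing the partial sum from the 3′
end. Unlike "cut at first base < Q20", this tolerates isolated bad bases
inside a good read; it is idempotent and never lengthens a read. A
vectorized batch version (`trim_batch`, and `extract_batch` below) is
used for pools and is tested for equivalence against the scalar
reference.

Codon extraction scans every alignment start of the fixed anchor/slot
layout (anchors derived from the design and read window); each anchor
may mismatch in ≤1 position (substitutions only — the platform's error
profile is substitution-dominated), the trailing anchor may be truncated
but must match over its covered prefix, and a read must extend through
the last codon slot. Reads with no valid placement are rejected
`anchor_mismatch`, short reads `truncated`, and reads with multiple
valid placements `ambiguous`; rejection reasons partition the rejected
reads. Reads are processed in sequencing orientation only (amplicon
orientation is fixed by the primers).

Tabulation translates codon tuples, counts stop-containing tuples
separately (expected under NNK via TAG) and excludes them from peptide
frequencies, and records joint frequencies, per-position marginals, and
genotype-per-peptide diversity. Enrichment is bright frequency over
input frequency per peptide, ranked descending; peptides absent from the
input are flagged rather than divided. Significance, where wanted, is a
percentile bootstrap CI on the frequency ratio (binomial resampling of
both pools, default 2000 draws), flagging enrichment when the 95% CI
excludes 1 — chosen over a named parametric test because none is
canonical for ratios of small pool frequencies.

## Pipeline, determinism, problem sizes

`run_pipeline` chains design → encapsulation → fluorescence → sorting →
amplification → reads → analysis → report, with one
`numpy.random.Generator` seeded from the config driving every stage;
identical config + seed gives byte-identical TSV/FASTQ outputs. The
report carries predicted vs realized occupancy, bright counts, and the
top enriched peptides.

Default problem sizes were chosen so each stage is statistically
meaningful at interactive runtimes: the full 8000-member screen at 10⁶
drops (the scale at which the expected binder-drop count is 12.5 and
per-replicate bright counts are informative) runs in a few seconds;
read depths of 10⁴ (sorted pools) and 2×10⁵ (input library) keep the
binder's input frequency measurable — at shallower input depth the
binder's expected read count approaches 1 and fold-enrichment becomes
undefined for unlucky replicates, which is a property of depth, not of
the screen. Unit tests use a 20-member single-position library where a
few thousand drops suffice.

## What the synthetic data do not capture

- Absolute template concentration error: real screens can observe
  bright fractions well below the Poisson prediction (e.g. 4.9% vs the
  predicted 9.5% for a pure-binder sample) because the input DNA
  concentration is uncertain; the simulator takes λ as exact.
- Microfluidic physics: drop coalescence/splitting beyond the Bernoulli
  width-gate flag, detector pulse shapes, sorting errors.
- Sequencing realism: indels, adapter read-through beyond a single
  configurable suffix, paired ends, chimeras, per-cycle error profiles.
- Library synthesis bias: measured input frequencies can exceed the
  uniform null several-fold; the package reports the null and measured
  values side by side but does not model the bias.
- Affinity is binary; intermediate K_d behavior (partial reporter
  activation) is not modeled.

Passing tests therefore demonstrate the statistical machinery of the
screen — occupancy, gating, enrichment arithmetic, extraction — under an
idealized instrument, not instrument-level fidelity.
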