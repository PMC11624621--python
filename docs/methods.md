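# Methods

## Load model

The unit of "harm" is a per-variant mutation-impact score: a
nonnegative, dimensionless, CADD-style weight supplied as input (this
package never computes impact scores). An individual's genotype at a
site is its deleterious-allele dosage (0/1/2 diploid, 0/1 hemizygous);
allele strings are abstracted away, and the optional VCF importer maps
ALT dosage to deleterious dosage only when the deleterious allele is
declared per site.

Dominance is a single coefficient `h ∈ [0, 1]` applied uniformly to
all variants. The default `h = 0` treats every deleterious variant as
fully recessive, which is the usual working assumption for the strongly
deleterious variants that dominate load calculations; `h` is exposed
because partially dominant variants shift load from the masked to the
realised component (realised heterozygous contribution `h·s`, masked
`(1−h)·s`). For `h = 0` the two components exactly partition the
carried load — every carried variant is counted once, in one component
— which is enforced as a property test.

Hemizygosity is opt-in: a variant is marked `sex_linked` and an
individual `heterogametic` (female, in birds). The defaults are
all-autosomal and sex-unknown, because typical input tables carry no
sex-chromosome annotation. Missing genotypes contribute zero to every
sum (with a logged warning) rather than aborting; an individual with
no genotypes at all is an error, since its "load" would be a
meaningless zero.

Profiles are aggregated per scaffold in lexicographic scaffold-name
order — an arbitrary but stable convention that keeps all outputs of a
dataset comparable note-for-note. The scaffold universe can be fixed
explicitly (e.g. "the 100 largest scaffolds") so that scaffolds
carrying no variant still appear with load 0 and always claim their
note in the sonification.

## Cross engine

Virtual crosses are all ordered parent pairs including selfing: n
founders give n² crosses (six give 36, matching the shape of the data
this tool is designed to read). The symmetric duplicates are retained
deliberately — results are symmetric, and the n² enumeration matches
the deposited-table convention. Selfing crosses model extreme
inbreeding for pedagogical contrast, not a biological proposal.

The primary output is the *expectation* of the offspring realised load
under Mendelian segregation, computed in closed form per locus
(transmission probability 0, ½ or 1 by parental dosage) and summed per
scaffold. Loci segregate independently: linkage is ignored, which is
exact for expectations (linearity) and only affects the variance of
sampled offspring. A seeded Monte-Carlo sampler (`sample_offspring`)
exists for validation and teaching; tests check its mean against the
closed form at N = 10,000 within three standard errors, and the closed
form itself against brute-force gamete-pair enumeration to 1e-12.

Sex-linked sites are treated as autosomal unless an offspring-sex mode
is requested, in which case the heterogametic offspring expresses the
homogametic parent's transmitted allele hemizygously and the two
offspring sexes are mixed 50/50 (or fixed). This is off by default
since unannotated data cannot use it.

All randomness flows from one integer seed per call
(`numpy.random.default_rng`); there is no global random state.

## Sonification

The mapping from a per-scaffold load score to a pitch-bend value is
`scale · round_to_quantum(score)` with `quantum = 5` and
`scale = −20`, clamped to the −8192 floor of the signed 14-bit bend
range. Rounding first (ties away from zero, a fixed deterministic
choice) means loads below 2.5 leave the note exactly in tune; scaling
by −20 then spreads the useful range of the data across most of the
downward bend range. Note the order matters at the top of the range:
the maximum observed per-scaffold load of 376 gives
−20 · 375 = −7500 through the production path, while scaling the
unrounded maximum gives −20 · 376 = −7520; the latter is the
conventional statement of the output range (0 to −7520) and is what
the acceptance script reports as the bend floor.

Bends are inserted with zero time delta immediately before each note
onset (a `note_on` with velocity > 0; velocity-0 `note_on` is the
note-release dialect and is never detuned), so each note is off-key
but steady while it sounds — no glissando. The first `skip_prefix = 4`
onsets are left entirely untouched (no value-0 bend is inserted) to
give the listener an in-tune reference; a profile longer than the
remaining onsets is an error rather than a silent truncation, because
a partially rendered genome would misrepresent the data. Pitch-bend is
channel-wide, so polyphonic overlap is rejected outright.

No bend-range RPN setup is emitted by default; the ±2-semitone General
MIDI default is assumed. `emit_rpn=True` (or `--emit-rpn`) prepends
RPN 0 messages pinning the range for strict synthesizers.

MIDI I/O is a built-in minimal Standard-MIDI-File module (format 0 and
single-melody-track format 1, running status and velocity-0 releases
normalised on interpretation, events preserved verbatim for lossless
round trips). Audio rendering to .wav is out of scope.

## Game evaluation

Candidate offspring are ranked by total expected realised load,
ascending, with lexicographic tie-breaks for determinism. A survey
respondent names the most and the least optimal of k sonified
offspring; naming both correctly by uniform guessing (two distinct
picks) succeeds with probability 1/k · 1/(k−1) = 1/6 for k = 3, the
null of the exact one-sided binomial test. The tail probability is
computed via `scipy.stats.binom.logsf`, so p-values far below 1e-20
remain exact in log space; tests verify it against direct pmf
summation for all n ≤ 30. For the published three-offspring survey
counts (62 of 98 respondents correct on both), the exact tail at
π₀ = 1/6 is ≈ 7.3e-25 — overwhelming evidence against guessing,
though note that quoted significance bounds computed with a normal
approximation can be several orders of magnitude smaller than the
exact tail this package reports.

Percentages in survey summaries are reported to one decimal place.
Responses naming unknown offspring are rejected and counted, not
silently dropped.

## Synthetic data

The generator emulates the study conditions end to end: 6 diploid
founders, 658 SNPs spread uniformly over 100 scaffolds
(`scaffold_001` … `scaffold_100`, lexicographic by construction),
fully genotyped. Deleterious-allele frequencies are Beta(0.5, 2)
(mean 0.2 — rare-skewed, but with the inflated frequencies drift
produces in a bottlenecked captive population) and impact scores are
Gamma(shape 3, scale 15) (mean 45, coefficient of variation ≈ 0.58,
resembling the high per-site scores of SNPs at ultra-conserved
elements). Founder genotypes are Hardy–Weinberg draws at each
variant's frequency — the simplest neutral stand-in. These
distributions are this package's modelling choices; the real study's
are unpublished. Under them the expected outcross total is
≈ 658 · 45 · E[q²] ≈ 2.5k and the expected selfing total ≈ 4.2k,
landing synthetic cross totals in the regime of real published
per-cross sums, with per-scaffold maxima comfortably inside the
calibration ceiling of 376. Generation fails loudly
(`CalibrationError`) in the rare seeds (≲0.1%) whose expected
per-scaffold loads exceed that ceiling.

What the generator does **not** emulate: linkage (sites are
independent), missing genotypes, sex chromosomes, realistic scaffold
size variation, or any demographic history. Tests passing on this
synthetic population therefore validate the arithmetic and the
pipeline contracts, not the population-genetic realism of any
particular dataset.

The melody generator produces a strictly monophonic single-channel
random walk on the A-minor scale in even quarter notes (default 104
onsets, 120 bpm) — a stand-in for a transcribed familiar melody; the
detuning algorithm is melody-agnostic. The response generator draws
each respondent's two answers with stated per-question success
probabilities, errors uniform over the wrong options and the two
answers always distinct; with p_most = 1/3 and p_least = 1/2 it
reduces exactly to uniform guessing (both-correct rate 1/6).

## Numerical and scale choices

Expectation-vs-oracle agreement is asserted at 1e-12 (pure floating
sums, no iterative numerics). Stochastic checks use fixed seeds and
3-standard-error bands. The multi-seed ecological property (selfing
crosses carry more expected load than outcrosses, and per-scaffold
loads stay within 0–376) is run over 50 seeds of the full
658-variant population, which completes in a few seconds; Monte-Carlo
convergence uses 10,000 offspring of a small hand-built cross. The
test suite and the acceptance script each run in well under a minute.

## Known limitations

- Dominance is one global `h`, not per-variant.
- No kinship/pedigree accounting (founder-genome equivalents, Ballou &
  Lacy mean kinship) — ranking is purely load-based.
- Linkage is ignored; sampled offspring variance is therefore
  understated relative to a physical genome.
- The SMF module covers the melody-manipulation subset of MIDI, not
  SMPTE divisions or multi-melody arrangements.
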