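# loadtune

Sonification of the realised genetic load of virtual offspring in
captive-bred populations.

Small zoo populations of endangered species — the motivating system is
the pink pigeon (*Nesoenas mayeri*) — inevitably accumulate recessive
deleterious variants. Genomics-informed breeding can avoid crosses
between parents that carry the same harmful variants and would
otherwise produce homozygous, inbreeding-depressed offspring. To make
this audible to non-specialists (zoo visitors, survey participants),
`loadtune` turns the genome of each candidate offspring into a
detuned rendition of a familiar melody: every scaffold of the assembly
maps to one note, and the realised load on that scaffold bends the
note flat. The least detuned offspring is the best mate-pair choice.

## The model

For a variant $v$ with mutation-impact score $s_v$ (CADD-like,
dimensionless, $s_v \ge 0$) and deleterious-allele dosage $d \in
\{0,1,2\}$, the load components of a carrier with dominance
coefficient $h \in [0,1]$ (default $h=0$, fully recessive) are

- realised: $s_v$ if $d=2$, $h\,s_v$ if $d=1$ (the full $s_v$ for a
  hemizygous carrier of the heterogametic sex at a sex-linked site);
- masked: $(1-h)\,s_v$ if $d=1$, else 0.

A virtual cross of parents A and B transmits each parental allele with
Mendelian probability $p = d/2$ independently per locus, so the
expected realised load contributed by variant $v$ to the offspring is

$$E[\ell_v] = s_v\,\bigl(p_A p_B + h\,(p_A(1-p_B) + p_B(1-p_A))\bigr).$$

All $n^2$ ordered crosses of $n$ founders, selfing included, are
enumerated (6 founders → 36 crosses). Loads are summed per scaffold in
lexicographic scaffold order; the shared load of a parent pair — the
sum of $s_v$ where both carry at least one copy — predicts offspring
homozygosity risk.

Sonification maps a per-scaffold profile to MIDI pitch-bend: each
score is rounded to the nearest multiple of 5 (ties away from zero, so
small loads leave the note in tune) and multiplied by −20, giving a
non-positive 14-bit bend value clamped at −8192 (≈ two semitones flat
under the General MIDI default bend range). One bend is inserted
immediately before each note onset, skipping the first four notes so
the listener hears an in-tune reference. Survey responses naming the
most and least optimal of $k$ sonified offspring are scored against
the load ranking and tested against the guessing null
$\pi_0 = 1/(k(k-1))$ with an exact one-sided binomial test computed in
log space.

## Worked example

```
loadtune simulate --seed 42 --out-dir fx
loadtune cross-loads --variants fx/variants.csv --genotypes fx/genotypes.csv \
    --out cross_loads.csv --shared-out shared.csv
loadtune rank --loads cross_loads.csv
```

prints the 36 crosses in ascending expected offspring realised load
(sum of impact scores over the 100 scaffolds):

```
PP1xPP5 2171.5
PP5xPP1 2171.5
PP1xPP3 2241.2
...
most optimal: PP1xPP5
least optimal: PP4xPP4
```

so for this synthetic population the pairing PP1 × PP5 minimises the
expected realised load (2171.5) while the selfing cross PP4 × PP4
maximises it (4648.7). Sonify any cross and simulate a listener survey:

```
loadtune sonify --melody fx/melody.mid --loads cross_loads.csv \
    --cross PP2xPP6 --out offspring.mid
loadtune responses --loads cross_loads.csv --crosses PP2xPP3,PP1xPP1,PP2xPP6 \
    --n 98 --p-most 0.745 --p-least 0.867 --seed 1 --out responses.csv
loadtune survey --responses responses.csv --loads cross_loads.csv \
    --crosses PP2xPP3,PP1xPP1,PP2xPP6
```

```
correct most: 72  correct least: 71  both: 61
exact binomial upper-tail p = 6.138e-24
```

`offspring.mid` contains exactly 100 pitch-bend events, one per
scaffold, all in [−8192, 0]; 61 of 98 simulated listeners identified
both extremes, vastly better than the 1/6 guessing null.

The same workflow is available as a library: `generate_population` →
`all_cross_results` → `detune_melody` / `evaluate_survey`; see the
module docstrings.

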