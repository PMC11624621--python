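"""Synthetic fixtures for the whole pipeline: founder population, melody
and survey responses.

The generated population emulates the study system: six diploid
founders genotyped at ~658 SNPs with CADD-like impact scores spread
over the 100 largest scaffolds of a draft assembly, with per-scaffold
offspring realised loads calibrated to lie in the observed 0-376 range.
Deleterious-allele frequencies are drawn from Beta(0.5, 2) (rare-skewed
but with the inflated frequencies a bottlenecked captive population
accumulates) and impact scores from Gamma(shape=3, scale=15) (mean 45,
matching the high per-site CADD scores of SNPs at ultra-conserved
elements). Founder genotypes are Hardy-Weinberg draws at each variant's
frequency. These distributions are modelling choices of this package;
the real study's are unpublished.

The melody generator stands in for a 104-note transcription of a
familiar tune: a seeded random walk on the A-minor scale, strictly
monophonic on a single channel. The response generator simulates
listeners who answer each question correctly with a stated probability,
erring uniformly over the wrong options.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .load_model import Individual, Population, Variant
from .cross_engine import all_cross_results
from .game_eval import Ranking
from .midi import MidiEvent, end_of_track, tempo_event
from .sonifier import MelodyTrack


class CalibrationError(ValueError):
    """Generated loads fall outside the target range; adjust the spec."""


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the synthetic founder population."""

    n_individuals: int = 6
    n_scaffolds: int = 100
    n_variants: int = 658
    allele_freq_beta: Tuple[float, float] = (0.5, 2.0)
    impact_gamma: Tuple[float, float] = (3.0, 15.0)  # (shape, scale)
    max_scaffold_load: float = 376.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_scaffolds < 1 or self.n_variants < 0:
            raise ValueError("counts must be positive (n_variants may be 0)")


@dataclass(frozen=True)
class MelodySpec:
    """Parameters of the synthetic monophonic melody."""

    n_notes: int = 104
    tempo_bpm: float = 120.0
    ticks_per_beat: int = 480
    channel: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 5:
            raise ValueError("melody needs at least 5 notes (4-note prefix + 1 detunable)")


def _scaffold_names(n: int) -> List[str]:
    width = max(3, len(str(n)))
    return [f"scaffold_{i:0{width}d}" for i in range(1, n + 1)]


def generate_population(spec: PopulationSpec = PopulationSpec()) -> Population:
    """Draw a founder population; deterministic for a given seed.

    Raises :class:`CalibrationError` when any expected per-scaffold
    offspring load over all virtual crosses exceeds ``max_scaffold_load``
    (rare under the defaults; lower the Gamma scale or the frequencies
    to fix a custom spec).
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = _scaffold_names(spec.n_scaffolds)
    a, b = spec.allele_freq_beta
    shape, scale = spec.impact_gamma

    variants: List[Variant] = []
    used_sites = set()
    for i in range(spec.n_variants):
        scaffold = scaffolds[rng.integers(spec.n_scaffolds)]
        position = int(rng.integers(1, 5_000_000))
        while (scaffold, position) in used_sites:
            position = int(rng.integers(1, 5_000_000))
        used_sites.add((scaffold, position))
        variants.append(
            Variant(
                variant_id=f"var{i + 1:04d}",
                scaffold=scaffold,
                position=position,
                impact_score=float(rng.gamma(shape, scale)),
            )
        )

    freqs = rng.beta(a, b, size=spec.n_variants)
    ids = [f"PP{i + 1}" for i in range(spec.n_individuals)]
    dosages = rng.binomial(2, freqs[:, None], size=(spec.n_variants, spec.n_individuals))
    individuals = [
        Individual(
            individual_id=ids[j],
            genotypes={v.variant_id: int(dosages[i, j]) for i, v in enumerate(variants)},
        )
        for j in range(spec.n_individuals)
    ]
    population = Population(variants=variants, individuals=individuals,
                            scaffolds=scaffolds)

    if spec.n_variants:
        worst = max(float(r.profile.scores.max()) for r in all_cross_results(population))
        if worst > spec.max_scaffold_load:
            raise CalibrationError(
                f"maximum expected per-scaffold offspring load {worst:.1f} exceeds "
                f"{spec.max_scaffold_load}; reduce impact_gamma scale or allele "
                "frequencies (or use another seed)"
            )
    return population


# A-minor scale over two octaves around A4
_SCALE = (57, 59, 60, 62, 64, 65, 67, 69, 71, 72, 74, 76, 77, 79, 81)


def generate_melody(spec: MelodySpec = MelodySpec()) -> MelodyTrack:
    """A strictly monophonic single-channel melody with ``n_notes`` onsets:
    a bounded random walk on the A-minor scale in even quarter notes."""
    rng = np.random.default_rng(spec.seed)
    events: List[MidiEvent] = [tempo_event(int(round(60_000_000 / spec.tempo_bpm)))]
    degree = len(_SCALE) // 2
    duration = spec.ticks_per_beat
    for _ in range(spec.n_notes):
        step = int(rng.integers(-2, 3))
        degree = min(max(degree + step, 0), len(_SCALE) - 1)
        note = _SCALE[degree]
        velocity = int(rng.integers(70, 100))
        events.append(MidiEvent(delta=0, type="note_on", channel=spec.channel,
                                note=note, velocity=velocity))
        events.append(MidiEvent(delta=duration, type="note_on", channel=spec.channel,
                                note=note, velocity=0))
    events.append(end_of_track())
    return MelodyTrack(tracks=[events], melody_index=0,
                       ticks_per_beat=spec.ticks_per_beat, fmt=0)


def generate_responses(
    truth: Ranking,
    n: int,
    p_most: float,
    p_least: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n`` respondents naming the most and least optimal offspring.

    Each respondent independently answers the most-optimal question
    correctly with probability ``p_most`` (errors uniform over the other
    options) and then the least-optimal question correctly with
    probability ``p_least`` when the true answer is still available
    (i.e. was not already named as most optimal); errors are uniform
    over the remaining wrong options. The two answers are always
    distinct.
    """
    if not (0.0 <= p_most <= 1.0 and 0.0 <= p_least <= 1.0):
        raise ValueError("success probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    options = list(truth.cross_ids)
    if len(options) < 2:
        raise ValueError("need at least 2 offspring options")
    rows = []
    for r in range(n):
        if rng.random() < p_most:
            most = truth.most_optimal
        else:
            wrong = [o for o in options if o != truth.most_optimal]
            most = wrong[rng.integers(len(wrong))]
        least_available = [o for o in options if o != most]
        if truth.least_optimal in least_available and rng.random() < p_least:
            least = truth.least_optimal
        else:
            wrong = [o for o in least_available if o != truth.least_optimal]
            least = wrong[rng.integers(len(wrong))]
        rows.append((f"resp{r + 1:03d}", most, least))
    return pd.DataFrame(rows, columns=["respondent_id", "most_optimal", "least_optimal"])
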