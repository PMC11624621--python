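"""Virtual Mendelian crosses and offspring realised-load expectations.

Every ordered parent pair of a population — selfing included — defines a
virtual cross (n individuals give n² crosses; the six sequenced founders
give 36). Under Mendelian segregation each diploid parent transmits its
deleterious allele with probability 0, ½ or 1 according to its dosage,
independently across variants (linkage is ignored). The primary output
is the *expected* realised load of the offspring per scaffold:

    E[load_v] = s_v · (pA·pB + h·(pA·(1-pB) + pB·(1-pA)))

where pA, pB are the parental transmission probabilities and h the
dominance coefficient. A seeded Monte-Carlo offspring sampler is
provided for validation. The shared load of a parent pair — the sum of
impact scores at sites where both carry the deleterious allele —
predicts the risk of homozygous offspring and hence of inbreeding
depression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .load_model import (
    DominanceModel,
    Individual,
    Population,
    ScaffoldLoadProfile,
    Sex,
    Variant,
    scaffold_order,
)

_TRANSMISSION = {0: 0.0, 1: 0.5, 2: 1.0}


@dataclass(frozen=True)
class CrossSpec:
    """An ordered parent pair; equal ids denote a selfing cross."""

    parent_a: str
    parent_b: str

    @property
    def cross_id(self) -> str:
        return f"{self.parent_a}x{self.parent_b}"

    @property
    def is_selfing(self) -> bool:
        return self.parent_a == self.parent_b


@dataclass
class CrossResult:
    """Expected realised load of a cross's offspring, per scaffold and total."""

    cross: CrossSpec
    profile: ScaffoldLoadProfile

    @property
    def total(self) -> float:
        return self.profile.total

    @property
    def cross_id(self) -> str:
        return self.cross.cross_id


def transmission_prob(dosage: int) -> float:
    """Probability that a diploid parent transmits the deleterious allele."""
    try:
        return _TRANSMISSION[dosage]
    except KeyError:
        raise ValueError(f"invalid diploid dosage {dosage}") from None


def enumerate_crosses(population: Population | Sequence[str]) -> List[CrossSpec]:
    """All ordered parent pairs including selfing, in lexicographic order
    (outer parent_a, inner parent_b)."""
    if isinstance(population, Population):
        ids = population.individual_ids
    else:
        ids = list(population)
    if not ids:
        raise ValueError("population is empty")
    ids = sorted(ids)
    return [CrossSpec(a, b) for a in ids for b in ids]


def _expected_variant_contribution(
    variant: Variant,
    parent_a: Individual,
    parent_b: Individual,
    model: DominanceModel,
    offspring_sex: Optional[Sex],
) -> float:
    da = parent_a.dosage(variant.variant_id)
    db = parent_b.dosage(variant.variant_id)
    if da is None or db is None:
        return 0.0
    s, h = variant.impact_score, model.h

    if variant.sex_linked and offspring_sex is not None:
        # Z-linked site in a bird-like ZW system: the homogametic parent
        # contributes a Z gamete with probability dosage/2; the
        # heterogametic parent carries a single Z (dosage 0/1) and passes
        # it only to homogametic offspring.
        if parent_a.sex == Sex.HOMOGAMETIC and parent_b.sex == Sex.HETEROGAMETIC:
            hom, het = parent_a, parent_b
        elif parent_b.sex == Sex.HOMOGAMETIC and parent_a.sex == Sex.HETEROGAMETIC:
            hom, het = parent_b, parent_a
        else:
            raise ValueError(
                "sex-linked expectation needs one homogametic and one "
                f"heterogametic parent for variant {variant.variant_id}"
            )
        p_hom = transmission_prob(hom.dosage(variant.variant_id))
        d_het = het.dosage(variant.variant_id)
        if d_het not in (0, 1):
            raise ValueError(f"heterogametic parent must be hemizygous at {variant.variant_id}")
        # heterogametic offspring: hemizygous, expresses its single Z allele
        e_heterogametic = s * p_hom
        # homogametic offspring: diploid on Z
        p_het = float(d_het)
        e_homogametic = s * (p_hom * p_het + h * (p_hom * (1 - p_het) + p_het * (1 - p_hom)))
        if offspring_sex == Sex.HETEROGAMETIC:
            return e_heterogametic
        if offspring_sex == Sex.HOMOGAMETIC:
            return e_homogametic
        return 0.5 * (e_heterogametic + e_homogametic)

    pa = transmission_prob(da)
    pb = transmission_prob(db)
    return s * (pa * pb + h * (pa * (1 - pb) + pb * (1 - pa)))


def expected_offspring_profile(
    cross: CrossSpec,
    population: Population,
    model: DominanceModel = DominanceModel(),
    offspring_sex: Optional[Sex] = None,
) -> CrossResult:
    """Expected per-scaffold realised load of the cross's offspring.

    Sex-linked variants are treated as autosomal unless ``offspring_sex``
    is given (``Sex.UNKNOWN`` averages the two offspring sexes 50/50).
    Variants with a missing parental genotype contribute 0.
    """
    parent_a = population.individual(cross.parent_a)
    parent_b = population.individual(cross.parent_b)
    scaffolds = population.scaffold_names()
    index = {name: i for i, name in enumerate(scaffolds)}
    scores = np.zeros(len(scaffolds))
    for variant in population.variants:
        scores[index[variant.scaffold]] += _expected_variant_contribution(
            variant, parent_a, parent_b, model, offspring_sex
        )
    return CrossResult(cross=cross, profile=ScaffoldLoadProfile(scaffolds, scores))


def all_cross_results(
    population: Population,
    model: DominanceModel = DominanceModel(),
) -> List[CrossResult]:
    """Expected offspring profiles for every ordered cross (incl. selfing)."""
    return [expected_offspring_profile(c, population, model)
            for c in enumerate_crosses(population)]


def sample_offspring(
    cross: CrossSpec,
    population: Population,
    seed: int,
    offspring_id: Optional[str] = None,
) -> Individual:
    """Draw one Mendelian offspring: per variant, dosage is the sum of one
    Bernoulli(p) draw per parent, independent across variants."""
    rng = np.random.default_rng(seed)
    parent_a = population.individual(cross.parent_a)
    parent_b = population.individual(cross.parent_b)
    genotypes = {}
    for variant in population.variants:
        da = parent_a.dosage(variant.variant_id)
        db = parent_b.dosage(variant.variant_id)
        if da is None or db is None:
            genotypes[variant.variant_id] = None
            continue
        pa = transmission_prob(da)
        pb = transmission_prob(db)
        genotypes[variant.variant_id] = int(rng.random() < pa) + int(rng.random() < pb)
    return Individual(
        individual_id=offspring_id or f"{cross.cross_id}_offspring",
        genotypes=genotypes,
    )


def shared_load(a: Individual, b: Individual, variants: Sequence[Variant]) -> float:
    """Sum of impact scores over variants where both individuals carry at
    least one copy of the deleterious allele."""
    total = 0.0
    for variant in variants:
        da = a.dosage(variant.variant_id) or 0
        db = b.dosage(variant.variant_id) or 0
        if da >= 1 and db >= 1:
            total += variant.impact_score
    return total


def shared_load_matrix(population: Population) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared load; the diagonal is each
    individual's own carried load sum."""
    ids = sorted(population.individual_ids)
    values = np.zeros((len(ids), len(ids)))
    for i, ida in enumerate(ids):
        for j, idb in enumerate(ids[i:], start=i):
            value = shared_load(population.individual(ida),
                                population.individual(idb),
                                population.variants)
            values[i, j] = values[j, i] = value
    return pd.DataFrame(values, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# tabular output in the deposited-data shape

def cross_loads_frame(results: Sequence[CrossResult]) -> pd.DataFrame:
    """Long-format table: cross_id, scaffold, realised_load (one row per
    cross per scaffold, scaffolds lexicographic)."""
    rows = []
    for result in results:
        for scaffold, score in zip(result.profile.scaffolds, result.profile.scores):
            rows.append((result.cross_id, scaffold, float(score)))
    return pd.DataFrame(rows, columns=["cross_id", "scaffold", "realised_load"])


def write_cross_loads(path, results: Sequence[CrossResult]) -> None:
    cross_loads_frame(results).to_csv(path, index=False)


def read_cross_loads(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"cross_id", "scaffold", "realised_load"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cross-loads table missing columns: {sorted(missing)}")
    return frame


def profile_from_cross_loads(frame: pd.DataFrame, cross_id: str) -> ScaffoldLoadProfile:
    """Extract one cross's per-scaffold profile, enforcing lexicographic
    scaffold order."""
    sub = frame[frame["cross_id"] == cross_id].sort_values("scaffold")
    if sub.empty:
        known = sorted(frame["cross_id"].unique())
        raise KeyError(f"cross {cross_id!r} not in table (known: {known[:8]}...)")
    return ScaffoldLoadProfile(
        scaffolds=list(sub["scaffold"]),
        scores=sub["realised_load"].to_numpy(),
    )


def write_shared_load_matrix(path, population: Population) -> None:
    matrix = shared_load_matrix(population)
    matrix.index.name = "individual"
    matrix.to_csv(path)
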