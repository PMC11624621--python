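"""Genetic-load model: variants, genotypes and per-scaffold load profiles.

The genetic load of an individual is quantified as a sum of per-variant
mutation-impact scores (CADD-style, PHRED-scaled, dimensionless),
partitioned into two components:

* **realised load** — expressed in the carrier: homozygous deleterious
  variants, heterozygous variants weighted by the dominance coefficient
  ``h``, and hemizygous deleterious variants on the sex chromosomes of
  the heterogametic sex (females in birds).
* **masked load** — hidden by (partial) recessivity: heterozygous
  variants weighted by ``1 - h``. It costs the carrier nothing but is
  converted into realised load in inbred descendants.

Loads are aggregated per scaffold (the draft-assembly unit), yielding an
alphabetically ordered profile with one nonnegative score per scaffold.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIPLOID_DOSAGES = (0, 1, 2)
HEMIZYGOUS_DOSAGES = (0, 1)


class InvalidGenotypeError(ValueError):
    """A dosage outside the valid set for the site's ploidy."""


class Sex(enum.Enum):
    """Sex of an individual in terms of sex-chromosome constitution.

    In birds females are the heterogametic sex (ZW) and are hemizygous
    for Z-linked loci; males (ZZ) carry two copies.
    """

    HOMOGAMETIC = "homogametic"
    HETEROGAMETIC = "heterogametic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Variant:
    """One genomic site carrying a deleterious allele.

    ``impact_score`` is a nonnegative CADD-like weight; ``position`` is
    1-based. ``sex_linked`` marks sites hemizygous in the heterogametic
    sex.
    """

    variant_id: str
    scaffold: str
    position: int
    impact_score: float
    sex_linked: bool = False

    def __post_init__(self) -> None:
        if self.impact_score < 0:
            raise ValueError(f"impact_score must be >= 0, got {self.impact_score}")
        if self.position < 1:
            raise ValueError(f"position is 1-based, got {self.position}")


@dataclass(frozen=True)
class DominanceModel:
    """Expression coefficient ``h`` of a heterozygous deleterious allele.

    ``h = 0`` is full recessivity (the default): heterozygotes express
    nothing and the whole heterozygous load is masked. ``h = 1`` is full
    dominance.
    """

    h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"dominance coefficient h must be in [0, 1], got {self.h}")


@dataclass
class Individual:
    """A genotyped individual: deleterious-allele dosage per variant.

    ``genotypes`` maps variant_id to dosage (0/1/2 diploid, 0/1
    hemizygous) or ``None`` for an explicit missing call.
    """

    individual_id: str
    genotypes: Dict[str, Optional[int]] = field(default_factory=dict)
    sex: Sex = Sex.UNKNOWN

    def dosage(self, variant_id: str) -> Optional[int]:
        return self.genotypes.get(variant_id)


@dataclass
class ScaffoldLoadProfile:
    """Per-scaffold load scores in a fixed lexicographic scaffold order."""

    scaffolds: List[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scaffolds) != len(self.scores):
            raise ValueError("scaffolds and scores must have equal length")
        if list(self.scaffolds) != sorted(self.scaffolds):
            raise ValueError("scaffolds must be sorted lexicographically")
        if np.any(self.scores < 0):
            raise ValueError("load scores must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.scores.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.scaffolds, name="scaffold"))


def _is_hemizygous(variant: Variant, carrier_sex: Sex) -> bool:
    return variant.sex_linked and carrier_sex == Sex.HETEROGAMETIC


def _check_dosage(variant: Variant, dosage: int, carrier_sex: Sex) -> None:
    valid = HEMIZYGOUS_DOSAGES if _is_hemizygous(variant, carrier_sex) else DIPLOID_DOSAGES
    if dosage not in valid:
        raise InvalidGenotypeError(
            f"dosage {dosage} invalid at {variant.variant_id} "
            f"({'hemizygous' if _is_hemizygous(variant, carrier_sex) else 'diploid'} site)"
        )


def realised_contribution(
    variant: Variant,
    dosage: int,
    model: DominanceModel = DominanceModel(),
    carrier_sex: Sex = Sex.UNKNOWN,
) -> float:
    """Realised-load contribution of one genotype.

    Homozygotes express the full impact score, heterozygotes a fraction
    ``h``, and hemizygous carriers of the heterogametic sex the full
    score from their single copy.
    """
    _check_dosage(variant, dosage, carrier_sex)
    if _is_hemizygous(variant, carrier_sex):
        return variant.impact_score if dosage == 1 else 0.0
    if dosage == 2:
        return variant.impact_score
    if dosage == 1:
        return model.h * variant.impact_score
    return 0.0


def masked_contribution(
    variant: Variant,
    dosage: int,
    model: DominanceModel = DominanceModel(),
) -> float:
    """Masked-load contribution: the recessive share ``(1 - h)`` of a
    heterozygous deleterious allele; zero otherwise."""
    _check_dosage(variant, dosage, Sex.UNKNOWN)
    if dosage == 1:
        return (1.0 - model.h) * variant.impact_score
    return 0.0


def scaffold_order(
    variants: Sequence[Variant],
    scaffolds: Optional[Sequence[str]] = None,
) -> List[str]:
    """Lexicographically sorted scaffold names.

    By default the names observed in the variant table; an explicit
    ``scaffolds`` universe may add variant-free scaffolds (which then
    appear in profiles with score 0) but must cover every variant.
    """
    observed = {v.scaffold for v in variants}
    if scaffolds is None:
        return sorted(observed)
    universe = set(scaffolds)
    stray = observed - universe
    if stray:
        raise ValueError(f"variants on scaffolds outside the universe: {sorted(stray)[:5]}")
    return sorted(universe)


def per_scaffold_load(
    individual: Individual,
    variants: Sequence[Variant],
    model: DominanceModel = DominanceModel(),
    component: str = "realised",
    scaffolds: Optional[Sequence[str]] = None,
) -> ScaffoldLoadProfile:
    """Aggregate one load component over each scaffold of the variant table.

    Scaffolds with no contributing variants appear with score 0; missing
    genotypes contribute 0 (logged); an individual missing every
    genotype is an error.
    """
    if not variants:
        raise ValueError("variant table is empty")
    if component not in ("realised", "masked"):
        raise ValueError(f"component must be 'realised' or 'masked', got {component!r}")
    scaffolds = scaffold_order(variants, scaffolds)
    index = {name: i for i, name in enumerate(scaffolds)}
    scores = np.zeros(len(scaffolds))
    n_missing = 0
    for variant in variants:
        dosage = individual.dosage(variant.variant_id)
        if dosage is None:
            n_missing += 1
            continue
        if component == "realised":
            value = realised_contribution(variant, dosage, model, individual.sex)
        else:
            value = masked_contribution(variant, dosage, model)
        scores[index[variant.scaffold]] += value
    if n_missing == len(variants):
        raise ValueError(f"all genotypes missing for individual {individual.individual_id}")
    if n_missing:
        logger.warning(
            "individual %s: %d/%d genotypes missing, contributing 0",
            individual.individual_id, n_missing, len(variants),
        )
    return ScaffoldLoadProfile(scaffolds=scaffolds, scores=scores)


# ---------------------------------------------------------------------------
# population container and tabular IO

@dataclass
class Population:
    """A variant table plus the individuals genotyped at it.

    ``scaffolds`` optionally fixes the scaffold universe (e.g. the 100
    largest assembly scaffolds) so variant-free scaffolds still appear
    in load profiles with score 0.
    """

    variants: List[Variant]
    individuals: List[Individual]
    scaffolds: Optional[List[str]] = None

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            key = (v.scaffold, v.position)
            if key in seen:
                raise ValueError(f"duplicate variant site {key}")
            seen.add(key)
        if self.scaffolds is not None:
            scaffold_order(self.variants, self.scaffolds)  # validates coverage

    def scaffold_names(self) -> List[str]:
        return scaffold_order(self.variants, self.scaffolds)

    @property
    def individual_ids(self) -> List[str]:
        return [ind.individual_id for ind in self.individuals]

    def individual(self, individual_id: str) -> Individual:
        for ind in self.individuals:
            if ind.individual_id == individual_id:
                return ind
        raise KeyError(f"unknown individual {individual_id!r}")

    def dosage_matrix(self) -> pd.DataFrame:
        """Variants x individuals dosage matrix (NaN = missing)."""
        data = {
            ind.individual_id: [
                np.nan if ind.dosage(v.variant_id) is None else ind.dosage(v.variant_id)
                for v in self.variants
            ]
            for ind in self.individuals
        }
        return pd.DataFrame(data, index=[v.variant_id for v in self.variants])

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "scaffold": [v.scaffold for v in self.variants],
                "position": [v.position for v in self.variants],
                "impact_score": [v.impact_score for v in self.variants],
                "sex_linked": [v.sex_linked for v in self.variants],
            }
        )


def variants_from_frame(frame: pd.DataFrame) -> List[Variant]:
    required = {"variant_id", "scaffold", "position", "impact_score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    sex_linked = frame["sex_linked"] if "sex_linked" in frame.columns else False
    frame = frame.assign(sex_linked=sex_linked)
    return [
        Variant(
            variant_id=str(row.variant_id),
            scaffold=str(row.scaffold),
            position=int(row.position),
            impact_score=float(row.impact_score),
            sex_linked=bool(row.sex_linked),
        )
        for row in frame.itertuples()
    ]


def read_variant_table(path) -> List[Variant]:
    """Read a CSV/TSV variant table (columns variant_id, scaffold,
    position, impact_score, optional sex_linked)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    return variants_from_frame(frame)


def read_genotype_matrix(path, variants: Sequence[Variant]) -> List[Individual]:
    """Read a CSV/TSV genotype matrix: rows variants, columns individuals,
    values in {0, 1, 2, NA}."""
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    known = {v.variant_id for v in variants}
    unknown = [vid for vid in frame.index if str(vid) not in known]
    if unknown:
        raise ValueError(f"genotype matrix contains unknown variants: {unknown[:5]}")
    individuals = []
    for column in frame.columns:
        genotypes: Dict[str, Optional[int]] = {}
        for vid, value in frame[column].items():
            genotypes[str(vid)] = None if pd.isna(value) else int(value)
        individuals.append(Individual(individual_id=str(column), genotypes=genotypes))
    return individuals


def write_genotype_matrix(path, population: Population) -> None:
    matrix = population.dosage_matrix()
    matrix.index.name = "variant_id"
    matrix.to_csv(path)


def read_vcf(path, deleterious_alleles: Mapping[str, str]) -> Population:
    """Import a sites+GT VCF as a population.

    ``deleterious_alleles`` maps ``"scaffold:position"`` to the declared
    deleterious allele; only declared sites are imported, and ALT dosage
    is converted to deleterious-allele dosage (flipped when REF is the
    deleterious allele). Impact scores are read from a ``CADD`` INFO
    field, defaulting to 0 when absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: List[Variant] = []
    genotypes: Dict[str, List[Optional[int]]] = {s: [] for s in samples}
    for record in vcf:
        key = f"{record.CHROM}:{record.POS}"
        if key not in deleterious_alleles:
            continue
        allele = deleterious_alleles[key]
        if record.ALT and allele == record.ALT[0]:
            flip = False
        elif allele == record.REF:
            flip = True
        else:
            raise ValueError(f"declared deleterious allele {allele!r} not present at {key}")
        score = float(record.INFO.get("CADD", 0.0))
        vid = f"{record.CHROM}_{record.POS}"
        variants.append(Variant(vid, record.CHROM, record.POS, score))
        alt_dosage = record.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt in zip(samples, alt_dosage):
            if gt == 2:
                dosage: Optional[int] = None
            else:
                d = {0: 0, 1: 1, 3: 2}[gt]
                dosage = 2 - d if flip else d
            genotypes[sample].append(dosage)
    individuals = [
        Individual(individual_id=s,
                   genotypes={v.variant_id: g for v, g in zip(variants, genotypes[s])})
        for s in samples
    ]
    return Population(variants=variants, individuals=individuals)
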