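"""Mendelian models of sex-chromosome crosses in terrestrial isopods.

Terrestrial isopods (Oniscidea) carry either male-heterogametic (XY/XX) or
female-heterogametic (ZW/ZZ) sex chromosomes. Because sexual differentiation
is hormonally controlled, a genetic female can be reversed into a functional
phenotypic male ("neomale") by androgenic-gland implantation. Crossing a
neomale with its sisters amounts to crossing two individuals with identical
sex-chromosome genotypes, and the F1 sex ratio then diagnoses the system:

* ZW neomale x ZW female -> 25% ZZ males, 50% ZW + 25% WW females if the WW
  genotype is viable; 33% males, 67% females if WW dies.
* XX neomale x XX female -> 100% XX females.

This module implements those predictions as exact gamete-union arithmetic,
plus the cytoplasmic alternative: feminizing *Wolbachia* endosymbionts, which
after loss of the W chromosome turn ZZ genetic males into phenotypic females
at the maternal transmission rate (~90% in *Armadillidium vulgare*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

__all__ = [
    "Genotype",
    "ViabilityConfig",
    "CrossPrediction",
    "InvalidCrossError",
    "cross",
    "wolbachia_progeny",
    "XX",
    "XY",
    "ZZ",
    "ZW",
    "WW",
    "YY",
]

_ALLELE_ORDER = {"X": 0, "Y": 1, "Z": 2, "W": 3}
_VALID_PAIRS = frozenset({"XX", "XY", "ZZ", "ZW", "WW", "YY"})
# Phenotypic sex implied by the genotype (WW/YY assume the carrier is viable).
_SEX = {"XX": "female", "XY": "male", "ZZ": "male", "ZW": "female",
        "WW": "female", "YY": "male"}


class InvalidCrossError(ValueError):
    """Raised when a cross is not realizable (e.g. two phenotypic males)."""


class Genotype:
    """An unordered pair of sex-chromosome alleles.

    Only the six biologically meaningful pairs are constructible:
    XX, XY, ZZ, ZW, WW and YY. The phenotypic sex is derived from the
    genotype (XX female, XY male, ZZ male, ZW female, WW female, YY male);
    experimental sex reversal is expressed at cross time, not here.
    """

    __slots__ = ("alleles",)

    def __init__(self, alleles: Iterable[str] | str):
        pair = tuple(alleles)
        if len(pair) != 2:
            raise ValueError(f"a genotype holds exactly two alleles, got {pair!r}")
        for a in pair:
            if a not in _ALLELE_ORDER:
                raise ValueError(f"unknown sex-chromosome allele {a!r}")
        canonical = "".join(sorted(pair, key=_ALLELE_ORDER.__getitem__))
        if canonical not in _VALID_PAIRS:
            raise ValueError(
                f"genotype {canonical!r} is not constructible; "
                f"valid pairs are {sorted(_VALID_PAIRS)}"
            )
        object.__setattr__(self, "alleles", canonical)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("Genotype is immutable")

    @property
    def sex(self) -> str:
        """Phenotypic sex implied by the genotype ('male' or 'female')."""
        return _SEX[self.alleles]

    @property
    def system(self) -> str:
        """'XY' for X/Y-allele genotypes, 'ZW' for Z/W-allele genotypes."""
        return "XY" if self.alleles[0] in "XY" else "ZW"

    def __eq__(self, other):
        return isinstance(other, Genotype) and self.alleles == other.alleles

    def __hash__(self):
        return hash(self.alleles)

    def __repr__(self):
        return f"Genotype({self.alleles!r})"

    def __str__(self):
        return self.alleles


XX = Genotype("XX")
XY = Genotype("XY")
ZZ = Genotype("ZZ")
ZW = Genotype("ZW")
WW = Genotype("WW")
YY = Genotype("YY")


@dataclass(frozen=True)
class ViabilityConfig:
    """Viability of the sex-limited-chromosome homozygotes.

    WW viability is the diagnostic quantity in ZW neomale crosses; YY
    viability defaults to viable (it never affects the neomale crosses, which
    produce no YY offspring, but matters for XY male x XY-carrier designs).
    """

    ww_viable: bool = True
    yy_viable: bool = True

    def is_viable(self, genotype: Genotype) -> bool:
        if genotype == WW:
            return self.ww_viable
        if genotype == YY:
            return self.yy_viable
        return True


@dataclass(frozen=True)
class CrossPrediction:
    """Expected F1 composition of a cross.

    ``genotype_freqs`` sums to 1 after inviable classes are removed and the
    remainder renormalized; ``male_prop + female_prop == 1``.
    """

    genotype_freqs: dict[Genotype, float]
    male_prop: float
    female_prop: float

    def as_dict(self) -> dict:
        """JSON-serializable form with string genotype keys."""
        return {
            "genotype_freqs": {str(g): f for g, f in self.genotype_freqs.items()},
            "male_prop": self.male_prop,
            "female_prop": self.female_prop,
        }


def _effective_sex(genotype: Genotype, reversed_: bool) -> str:
    if not reversed_:
        return genotype.sex
    return "male" if genotype.sex == "female" else "female"


def cross(
    parent1: Genotype,
    parent2: Genotype,
    viability: ViabilityConfig | None = None,
    *,
    parent1_reversed: bool = False,
    parent2_reversed: bool = False,
) -> CrossPrediction:
    """Predict the F1 of a cross between two sex-chromosome genotypes.

    Gametes are drawn with equal probability from each parent's two alleles
    and united; offspring classes that are inviable under ``viability`` are
    removed and the remaining frequencies renormalized. Sex is assigned from
    the offspring genotype.

    ``parent*_reversed`` flags an experimentally sex-reversed parent: a
    neomale is a female genotype with ``reversed=True``, a *Wolbachia*-
    feminized ZZ female is a male genotype with ``reversed=True``. The cross
    validates on phenotype: exactly one functional male and one functional
    female are required.

    Raises
    ------
    InvalidCrossError
        If the two parents have the same functional sex, or carry
        chromosomes from different systems (X/Y vs Z/W).
    """
    viability = viability if viability is not None else ViabilityConfig()
    sexes = {
        _effective_sex(parent1, parent1_reversed),
        _effective_sex(parent2, parent2_reversed),
    }
    if sexes != {"male", "female"}:
        raise InvalidCrossError(
            "a cross requires one functional male and one functional female "
            f"(got two {sexes.pop()}s); use the reversal flags for neomales "
            "or feminized individuals"
        )
    if parent1.system != parent2.system:
        raise InvalidCrossError(
            f"parents carry incompatible sex-chromosome systems "
            f"({parent1.system} x {parent2.system})"
        )

    freqs: dict[Genotype, Fraction] = {}
    quarter = Fraction(1, 4)
    for a in parent1.alleles:
        for b in parent2.alleles:
            g = Genotype((a, b))
            freqs[g] = freqs.get(g, Fraction(0)) + quarter

    viable = {g: f for g, f in freqs.items() if viability.is_viable(g)}
    if not viable:
        raise InvalidCrossError("no viable offspring class under this viability config")
    total = sum(viable.values())
    viable = {g: f / total for g, f in viable.items()}

    male = sum(f for g, f in viable.items() if g.sex == "male")
    return CrossPrediction(
        genotype_freqs={g: float(f) for g, f in viable.items()},
        male_prop=float(male),
        female_prop=float(1 - male),
    )


def wolbachia_progeny(transmission_rate: float) -> CrossPrediction:
    """Expected brood composition under cytoplasmic (Wolbachia) feminization.

    Models a population in which the W chromosome has been lost: every
    individual is a ZZ genetic male, and an offspring develops as a female
    exactly when it inherits the maternally transmitted *Wolbachia*
    (probability ``transmission_rate``, ~0.9 in *A. vulgare*). Feminization
    is a Bernoulli event per offspring; all genotypes are ZZ.
    """
    if not 0.0 <= transmission_rate <= 1.0:
        raise ValueError(
            f"transmission_rate must be in [0, 1], got {transmission_rate}"
        )
    return CrossPrediction(
        genotype_freqs={ZZ: 1.0},
        male_prop=1.0 - transmission_rate,
        female_prop=float(transmission_rate),
    )
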