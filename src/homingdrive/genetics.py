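"""Alleles, genotypes and germline transmission for a homing suppression drive.

The drive construct (T) sits inside a haplosufficient gene required for
survival to adulthood.  In the germline of W/T heterozygotes the Cas9/gRNA
cassette cuts the wild-type (W) allele; homology-directed repair copies the
drive across ("homing"), while end joining leaves a mutated target site that
is either a non-functional resistant allele (R) or, with probability ``p``,
a functional resistant allele (r).  All rates are parameterised from the
measured transmission rate ``d`` — the fraction of progeny of a W/T parent
that inherit T — via ``e = 2d - 1``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Tuple


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Allele(enum.Enum):
    """The four target-site alleles.

    W  wild type: functional, cleavable.
    T  transgenic drive insertion: non-functional, not cleavable.
    R  end-joining product that destroys gene function: not cleavable.
    r  end-joining product that preserves gene function: not cleavable.
    """

    W = ("W", True, True)
    T = ("T", False, False)
    R = ("R", False, False)
    r = ("r", True, False)

    def __init__(self, symbol: str, functional: bool, cleavable: bool):
        self.symbol = symbol
        self.functional = functional
        self.cleavable = cleavable

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Allele.{self.symbol}"


#: Canonical allele order used by every vectorised representation.
ALLELES: Tuple[Allele, ...] = (Allele.W, Allele.T, Allele.R, Allele.r)
ALLELE_INDEX: Dict[Allele, int] = {a: i for i, a in enumerate(ALLELES)}


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered pair of alleles; stored in canonical allele order."""

    first: Allele
    second: Allele

    @staticmethod
    def of(a: Allele, b: Allele) -> "Genotype":
        if ALLELE_INDEX[a] <= ALLELE_INDEX[b]:
            return Genotype(a, b)
        return Genotype(b, a)

    @property
    def alleles(self) -> Tuple[Allele, Allele]:
        return (self.first, self.second)

    @property
    def is_viable(self) -> bool:
        """True iff at least one allele retains gene function.

        The target gene is haplosufficient but required for survival to
        adulthood, so T/T, T/R and R/R individuals die before eclosion.
        """
        return self.first.functional or self.second.functional

    @property
    def is_carrier(self) -> bool:
        """True iff the individual carries the drive allele (marker positive)."""
        return Allele.T in self.alleles

    @property
    def is_het_carrier(self) -> bool:
        """Viable drive carrier (necessarily heterozygous, W/T or T/r)."""
        return self.is_carrier and self.is_viable

    @property
    def label(self) -> str:
        return f"{self.first.symbol}/{self.second.symbol}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The ten unordered genotypes, canonical order.
GENOTYPES: Tuple[Genotype, ...] = tuple(
    Genotype.of(a, b)
    for a, b in itertools.combinations_with_replacement(ALLELES, 2)
)
GENOTYPE_INDEX: Dict[Genotype, int] = {g: i for i, g in enumerate(GENOTYPES)}
GENOTYPE_BY_LABEL: Dict[str, Genotype] = {g.label: g for g in GENOTYPES}

WW = GENOTYPE_BY_LABEL["W/W"]
WT = GENOTYPE_BY_LABEL["W/T"]


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value!r} must lie in [0, 1]")


@dataclass(frozen=True)
class DriveRates:
    """Sex-specific homing parameters derived from measured transmission.

    d_f, d_m : transmission of T from a W/T parent
    e_f, e_m : germline conversion (homing) probability of a W allele, 2d-1
    u        : probability a non-converted cleaved W carries an end-joining
               mutation (shared between sexes; measured once on pooled larvae)
    p        : probability an end-joining product is functional (r) not R
    c_f, c_m : total cleavage probability, e + (1-e)u
    j_f, j_m : end-joining share among cleaved alleles, (1-e)u / c
    """

    d_f: float
    d_m: float
    e_f: float
    e_m: float
    u: float
    p: float
    c_f: float
    c_m: float
    j_f: float
    j_m: float

    def d(self, sex: Sex) -> float:
        return self.d_f if sex is Sex.FEMALE else self.d_m

    def e(self, sex: Sex) -> float:
        return self.e_f if sex is Sex.FEMALE else self.e_m

    def with_p(self, p: float) -> "DriveRates":
        """Same measured rates with a different functional-repair fraction."""
        return derive_rates(self.d_f, self.d_m, self.u, p)

    def report(self) -> Dict[str, Dict[str, float]]:
        """Raw and 3-decimal values for every derived quantity."""
        out: Dict[str, Dict[str, float]] = {}
        for name in ("d_f", "d_m", "e_f", "e_m", "u", "p", "c_f", "c_m", "j_f", "j_m"):
            value = getattr(self, name)
            out[name] = {"raw": value, "rounded": round3(value)}
        return out


def round3(x: float) -> float:
    """Round to 3 decimal places, halves away from zero (printed convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def derive_rates(d_f: float, d_m: float, u: float, p: float = 0.0) -> DriveRates:
    """Derive cleavage and end-joining rates from measured transmission.

    With transmission d >= 1/2 the conversion probability is e = 2d - 1,
    total cleavage c = e + (1-e)u and the end-joining share among cleaved
    alleles j = (1-e)u / c (defined as 0 when nothing is cleaved).
    """
    for name, d in (("d_f", d_f), ("d_m", d_m)):
        _check_unit(name, d)
        if d < 0.5:
            raise ValueError(
                f"{name}={d!r} is below 0.5: the conversion rate e = 2d - 1 "
                "would be negative"
            )
    _check_unit("u", u)
    _check_unit("p", p)

    def _per_sex(d: float) -> Tuple[float, float, float]:
        e = 2.0 * d - 1.0
        c = e + (1.0 - e) * u
        j = (1.0 - e) * u / c if c > 0.0 else 0.0
        return e, c, j

    e_f, c_f, j_f = _per_sex(d_f)
    e_m, c_m, j_m = _per_sex(d_m)
    return DriveRates(
        d_f=d_f, d_m=d_m, e_f=e_f, e_m=e_m, u=u, p=p,
        c_f=c_f, c_m=c_m, j_f=j_f, j_m=j_m,
    )


def mendelian_rates() -> DriveRates:
    """Null model: no homing, no cleavage (the non-driving control allele)."""
    return derive_rates(0.5, 0.5, 0.0, 0.0)


@dataclass(frozen=True)
class GameteDistribution:
    """Probability of each allele among the gametes of one parent."""

    probs: Tuple[float, float, float, float]  # ordered as ALLELES

    def __post_init__(self) -> None:
        total = sum(self.probs)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"gamete probabilities sum to {total!r}, not 1")
        if any(q < 0.0 for q in self.probs):
            raise ValueError("gamete probabilities must be non-negative")

    def p(self, allele: Allele) -> float:
        return self.probs[ALLELE_INDEX[allele]]

    def as_dict(self) -> Dict[Allele, float]:
        return dict(zip(ALLELES, self.probs))


def gamete_distribution(parent: Genotype, sex: Sex, rates: DriveRates) -> GameteDistribution:
    """Germline output of one parent.

    Homing acts only in W/T individuals: the drive cuts the W allele with
    total probability c, converting it to T (HDR) or to R/r (end joining).
    Written in terms of the transmission rate d, a W/T parent passes on
    T with probability d = (1+e)/2.  Every other genotype — including W/R,
    W/r, T/r and T/R — segregates Mendelian 1/2:1/2, because cleavage needs
    both a T allele (the nuclease source) and a cleavable partner (W).
    """
    if not parent.is_viable:
        raise ValueError(f"inviable genotype {parent.label} never reproduces")
    probs = [0.0, 0.0, 0.0, 0.0]
    if parent == WT:
        e = rates.e(sex)
        u, p = rates.u, rates.p
        probs[ALLELE_INDEX[Allele.T]] = (1.0 + e) / 2.0
        probs[ALLELE_INDEX[Allele.W]] = (1.0 - e) * (1.0 - u) / 2.0
        probs[ALLELE_INDEX[Allele.r]] = (1.0 - e) * u * p / 2.0
        probs[ALLELE_INDEX[Allele.R]] = (1.0 - e) * u * (1.0 - p) / 2.0
    else:
        for allele in parent.alleles:
            probs[ALLELE_INDEX[allele]] += 0.5
    return GameteDistribution(tuple(probs))


def cross_zygote_distribution(
    mother: Genotype, father: Genotype, rates: DriveRates
) -> Dict[Genotype, float]:
    """Zygote genotype distribution from a single cross.

    Outer product of the maternal and paternal gamete distributions,
    collapsed over allele order.
    """
    gm = gamete_distribution(mother, Sex.FEMALE, rates)
    gp = gamete_distribution(father, Sex.MALE, rates)
    out: Dict[Genotype, float] = {g: 0.0 for g in GENOTYPES}
    for a in ALLELES:
        for b in ALLELES:
            out[Genotype.of(a, b)] += gm.p(a) * gp.p(b)
    return out


def genotype_frequencies_to_alleles(freqs: Mapping[Genotype, float]) -> Dict[Allele, float]:
    """Collapse genotype frequencies to allele frequencies."""
    out = {a: 0.0 for a in ALLELES}
    for g, f in freqs.items():
        out[g.first] += 0.5 * f
        out[g.second] += 0.5 * f
    return out


def carrier_frequency(freqs: Mapping[Genotype, float]) -> float:
    """Frequency of drive-marker-positive individuals."""
    return sum(f for g, f in freqs.items() if g.is_carrier)


def iter_viable() -> Iterable[Genotype]:
    return (g for g in GENOTYPES if g.is_viable)
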