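"""Haploid porcine sperm karyotype and the Robertsonian-fusion segregation model.

The boar (*Sus scrofa*) haploid sperm karyotype carries 18 autosomes plus one
gonosome (X or Y), i.e. 19 chromosomes and 38 telomeres.  Two centromeric
satellite families are distinguishable by FISH probes: the AC6 family marks
the six acrocentric autosomes (SSC13--SSC18) and the SSCRS2A family marks the
(sub)metacentric chromosomes SSC2--SSC11 and the gonosome (11 centromeres);
SSC1 and SSC12 are labeled by neither probe.

A Robertsonian translocation t(13;17) fuses SSC13 and SSC17 at their
centromeres into a single chromosome, reducing the haploid set to 18
chromosomes and 36 telomeres.  The fusion product is modeled with a single
AC6-class centromere, because the fused centromere yields one FISH signal.

A heterozygous carrier produces (to a good approximation, ignoring the rare
unbalanced gametes) half translocated and half normal balanced sperm; the
segregation model below turns that Mendelian ratio into expected proportions
of nuclei whose SSC13/SSC17 territories are proximal (colocalized or
adjacent) versus distant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "CentromereClass",
    "Chromosome",
    "Karyotype",
    "SegregationParams",
    "build_haploid_karyotype",
    "labeled_centromere_count",
    "expected_category_proportions",
]


class CentromereClass(str, Enum):
    """Centromeric satellite family recognized by the two probes."""

    ACROCENTRIC = "acrocentric"  # AC6 probe target
    SUBMETA_OR_METACENTRIC = "submeta_or_metacentric"  # SSCRS2A probe target
    UNLABELED = "unlabeled"  # SSC1 and SSC12: neither probe binds

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: probe name -> centromere class it labels
PROBE_CLASSES = {
    "AC6": CentromereClass.ACROCENTRIC,
    "SSCRS2A": CentromereClass.SUBMETA_OR_METACENTRIC,
}

#: acrocentric autosomes of the pig
ACROCENTRIC_AUTOSOMES = ("SSC13", "SSC14", "SSC15", "SSC16", "SSC17", "SSC18")

#: autosomes whose centromeres are not labeled by either probe
UNLABELED_AUTOSOMES = ("SSC1", "SSC12")

#: single gonosome slot; X-vs-Y identity is a per-nucleus attribute, not a
#: separate chromosome (a haploid sperm carries exactly one of the two)
GONOSOME_NAME = "SSCX/Y"

#: name of the fusion product of the Robertsonian translocation
FUSED_NAME = "SSC13;17"


@dataclass(frozen=True)
class Chromosome:
    """One haploid chromosome with its centromeric probe class.

    Every chromosome, fused or not, carries exactly two telomeres: the
    Robertsonian fusion joins two acrocentrics at their centromeric ends, so
    the two p-terminal telomeres are lost with the satellite arms and the
    product keeps one telomere per remaining arm.
    """

    name: str
    centromere_class: CentromereClass
    telomere_count: int = 2

    def __post_init__(self) -> None:
        if self.telomere_count != 2:
            raise ValueError("every chromosome carries exactly 2 telomeres")


@dataclass(frozen=True)
class Karyotype:
    """An ordered haploid chromosome set, optionally carrying the 13;17 fusion."""

    chromosomes: tuple[Chromosome, ...]
    is_fused_13_17: bool = False

    def __post_init__(self) -> None:
        expected_n = 18 if self.is_fused_13_17 else 19
        if len(self.chromosomes) != expected_n:
            raise ValueError(
                f"karyotype with is_fused_13_17={self.is_fused_13_17} must have "
                f"{expected_n} chromosomes, got {len(self.chromosomes)}"
            )

    @property
    def chromosome_count(self) -> int:
        return len(self.chromosomes)

    @property
    def telomere_count(self) -> int:
        return sum(c.telomere_count for c in self.chromosomes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "is_fused_13_17": self.is_fused_13_17,
                "chromosomes": [
                    {
                        "name": c.name,
                        "centromere_class": c.centromere_class.value,
                        "telomere_count": c.telomere_count,
                    }
                    for c in self.chromosomes
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Karyotype":
        doc = json.loads(text)
        chroms = tuple(
            Chromosome(
                name=c["name"],
                centromere_class=CentromereClass(c["centromere_class"]),
                telomere_count=c.get("telomere_count", 2),
            )
            for c in doc["chromosomes"]
        )
        return cls(chromosomes=chroms, is_fused_13_17=bool(doc["is_fused_13_17"]))


def _autosome_class(name: str) -> CentromereClass:
    if name in UNLABELED_AUTOSOMES:
        return CentromereClass.UNLABELED
    if name in ACROCENTRIC_AUTOSOMES:
        return CentromereClass.ACROCENTRIC
    return CentromereClass.SUBMETA_OR_METACENTRIC


def build_haploid_karyotype(fused: bool = False) -> Karyotype:
    """Build the haploid boar sperm karyotype.

    Parameters
    ----------
    fused:
        If True, SSC13 and SSC17 are replaced by the single Robertsonian
        fusion product ``SSC13;17`` (modeled with one acrocentric-class
        centromere), giving 18 chromosomes and 36 telomeres instead of
        19 and 38.
    """
    chroms: list[Chromosome] = []
    for i in range(1, 19):
        name = f"SSC{i}"
        if fused and name in ("SSC13", "SSC17"):
            continue
        chroms.append(Chromosome(name, _autosome_class(name)))
    if fused:
        chroms.append(Chromosome(FUSED_NAME, CentromereClass.ACROCENTRIC))
    chroms.append(Chromosome(GONOSOME_NAME, CentromereClass.SUBMETA_OR_METACENTRIC))
    return Karyotype(chromosomes=tuple(chroms), is_fused_13_17=fused)


def labeled_centromere_count(karyotype: Karyotype, probe: str) -> int:
    """Number of centromeres in ``karyotype`` labeled by ``probe``.

    ``AC6`` labels acrocentric centromeres (6 in a control sperm, 5 in a
    translocated one, since the fusion merges two centromeric signals into
    one); ``SSCRS2A`` labels the (sub)metacentric centromeres except SSC1 and
    SSC12 (11 in either karyotype).
    """
    try:
        target = PROBE_CLASSES[probe]
    except KeyError:
        raise ValueError(
            f"unknown probe {probe!r}; expected one of {sorted(PROBE_CLASSES)}"
        ) from None
    return sum(1 for c in karyotype.chromosomes if c.centromere_class is target)


@dataclass(frozen=True)
class SegregationParams:
    """Parameters of the carrier segregation model.

    carrier_gamete_fusion_fraction:
        Probability that a balanced gamete from the carrier bears the fused
        chromosome; 0.5 for a heterozygous carrier.
    baseline_proximal_fraction:
        Fraction of control (non-translocated) nuclei whose SSC13 and SSC17
        territories are colocalized or adjacent.  Defaults to 0.5 (the
        rounded control proximity); the observed control value 0.48 can be
        passed instead.
    """

    carrier_gamete_fusion_fraction: float = 0.5
    baseline_proximal_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("carrier_gamete_fusion_fraction", "baseline_proximal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def expected_category_proportions(params: SegregationParams) -> tuple[float, float]:
    """Expected (proximal, distant) fractions of SSC13/SSC17 territory pairs.

    A gamete carrying the fusion has its two territories merged, hence always
    proximal (colocalized or adjacent); a non-carrier gamete is proximal with
    the baseline probability.  With fusion fraction ``f`` and baseline ``b``::

        proximal = f + (1 - f) * b
        distant  = 1 - proximal

    For a heterozygous carrier (f = 0.5) and a control proximity of one half
    (b = 0.5), this gives (0.75, 0.25).
    """
    f = params.carrier_gamete_fusion_fraction
    b = params.baseline_proximal_fraction
    proximal = f + (1.0 - f) * b
    return proximal, 1.0 - proximal
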