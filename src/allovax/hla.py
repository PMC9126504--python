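"""HLA class I alleles and six-allele haplotypes.

Alleles are modeled at two-field ("4-digit") resolution, e.g. ``HLA-A*02:01``.
Only the classical class I loci (A, B, C) are represented. Each individual
carries two alleles per locus, so a haplotype holds six allele slots of which
three to six are distinct (homozygosity at any locus is allowed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

LOCI = ("A", "B", "C")

_ALLELE_RE = re.compile(r"^HLA-([ABC])\*(\d{2,4}):(\d{2,4})$")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A class I allele at two-field resolution, e.g. ``HLA-B*07:02``."""

    name: str

    def __post_init__(self) -> None:
        if not _ALLELE_RE.match(self.name):
            raise ValueError(
                f"not a two-field HLA class I allele name: {self.name!r} "
                "(expected 'HLA-<A|B|C>*<group>:<protein>')"
            )

    @property
    def locus(self) -> str:
        return _ALLELE_RE.match(self.name).group(1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class Haplotype:
    """Six class I allele slots: two per locus in A, A, B, B, C, C order."""

    alleles: tuple[HLAAllele, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != 6:
            raise ValueError(f"haplotype needs 6 allele slots, got {len(self.alleles)}")
        for i, locus in enumerate(LOCI):
            pair = self.alleles[2 * i : 2 * i + 2]
            bad = [a.name for a in pair if a.locus != locus]
            if bad:
                raise ValueError(f"slots {2*i}-{2*i+1} must be locus {locus}, got {bad}")

    @property
    def allele_set(self) -> frozenset[HLAAllele]:
        """The deduplicated allele set (size 3-6)."""
        return frozenset(self.alleles)

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)
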