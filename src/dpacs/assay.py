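"""In-silico PCR-RFLP: amplicon assembly, genotype band patterns, gel resolvability.

A dPACS amplicon is fully determined by its primers: forward primer, the
uncovered diagnostic base(s), then the reverse complement of the reverse
primer.  Heterozygote lanes carry both alleles' digestion products, so the
het band pattern is the multiset union of the two homozygote patterns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

from .enzymes import Enzyme, digest
from .seqcore import clean, revcomp

Genotype = Literal["hom_wild", "het", "hom_mutant"]

GENOTYPES: tuple[Genotype, ...] = ("hom_wild", "het", "hom_mutant")


@dataclass(frozen=True)
class Amplicon:
    """A per-allele PCR product."""

    allele: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BandPattern:
    """Predicted gel bands for one genotype.

    ``bands`` is the full multiset of fragment lengths; ``display_bands``
    collapses duplicates (co-migrating identical lengths appear once on a
    gel).
    """

    genotype: Genotype
    bands: tuple[int, ...]

    @property
    def display_bands(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.bands), reverse=True))


def build_amplicon(
    fw_primer: str, diagnostic_bases: str, rv_primer: str, allele: str = ""
) -> Amplicon:
    """Assemble fw_primer + diagnostic bases + revcomp(rv_primer).

    ``diagnostic_bases`` may be empty (a pure-deletion allele).
    """
    fw = clean(fw_primer)
    diag = clean(diagnostic_bases) if diagnostic_bases else ""
    return Amplicon(allele=allele, sequence=fw + diag + revcomp(rv_primer))


def genotype_bands(
    enzyme: Enzyme,
    wild_amplicon: Amplicon | str,
    mutant_amplicon: Amplicon | str,
    genotype: Genotype,
) -> BandPattern:
    """Predicted band pattern for a genotype under one enzyme.

    Homozygotes show the digestion fragments of their own allele's
    amplicon; a heterozygote shows the union of both.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    wseq = wild_amplicon.sequence if isinstance(wild_amplicon, Amplicon) else wild_amplicon
    mseq = mutant_amplicon.sequence if isinstance(mutant_amplicon, Amplicon) else mutant_amplicon
    if genotype == "hom_wild":
        bands = digest(enzyme, wseq).fragments
    elif genotype == "hom_mutant":
        bands = digest(enzyme, mseq).fragments
    else:
        bands = digest(enzyme, wseq).fragments + digest(enzyme, mseq).fragments
    return BandPattern(genotype=genotype, bands=tuple(sorted(bands, reverse=True)))


def resolvable(
    pattern_a: BandPattern, pattern_b: BandPattern, min_delta: int = 15
) -> bool:
    """Can a gel distinguish the two patterns?

    True iff the band multisets differ and every band present in exactly
    one pattern sits at least ``min_delta`` nt away from every band of the
    other pattern — closer bands are treated as co-migrating.  Bands within
    one pattern are never required to separate from each other: the
    diagnostic contrast is cut-vs-uncut, and e.g. a 42/40 doublet reads as
    one thick band harmlessly.
    """
    if min_delta < 1:
        raise ValueError("min_delta must be >= 1")
    a, b = Counter(pattern_a.bands), Counter(pattern_b.bands)
    if a == b:
        return False
    only_a = list((a - b).elements())
    only_b = list((b - a).elements())
    for band in only_a:
        if any(abs(band - other) < min_delta for other in b):
            return False
    for band in only_b:
        if any(abs(band - other) < min_delta for other in a):
            return False
    return True
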