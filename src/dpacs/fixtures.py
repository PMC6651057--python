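"""Packaged worked-assay fixtures.

Three published dPACS assays are shipped as fixtures, reconstructed from
their printed primer sequences and diagnostic dinucleotides:

* ``psbA_S264`` — photosystem II D1 protein, serine264 (wild ``AG``) vs the
  triazine-resistance glycine variant (``GG``); PleI cuts the wild allele.
* ``ACCase_I2041`` — acetyl-CoA carboxylase isoleucine2041 (wild ``AT``)
  vs the asparagine variant (``AA``); EcoRI cuts the wild allele.
* ``EPSPS_P106`` — EPSP synthase proline106 (``CC``) and its serine
  (``TC``), threonine (``AC``) and alanine (``GC``) glyphosate-resistance
  variants; a four-enzyme panel (XcmI/XmnI/RsaI/Cac8I) detects one allele
  each from a single PCR product.

For the psbA assay the underlying wild/mutant templates are reconstructed
by reverting the two described forced mutations in the printed primers
(thymine->guanine at the forward primer's 3' terminus; adenine->guanine at
the penultimate 3' base of the reverse primer), so the full design search
can be replayed against it.  For the other two assays the templates are
not fully recoverable from the published record, so those fixtures are
amplicon-level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .assay import build_amplicon
from .enzymes import Enzyme, parse_enzyme_table
from .seqcore import AllelePair, make_allele_pair, revcomp

PSBA_FW = "TGCTTCATGGTTACTTTGGTCGATTGATCTTCCAATATGCG"
PSBA_RV = "AAGCAGCTAAGAAAAAGTGTAAAGAACGAGAGTTGTTGAGA"
ACCASE_FW = "GCTTCTCTGGTGGGCAAAGAGACCTTTTTGAAGGA"
ACCASE_RV = "GGCAGGCAGATTATATGTCCTAAGGTTCTCAACAATTGTTGATCCAGCCTGCAGA"
EPSPS_FW = "GGTGCAGCTCTTCTTGGGGAATGCTGGAACTGGAATGCGT"
EPSPS_RV = "AGTTGCATTTCCTCCAGCAGCAGTTACCCATGCTGTCAAT"

PLE_I = Enzyme("PleI", "GAGTC", 4, 5)
ECO_RI = Enzyme("EcoRI", "GAATTC", -5, -1)
XMN_I = Enzyme("XmnI", "GAANNNNTTC", -5, -5)
RSA_I = Enzyme("RsaI", "GTAC", -2, -2)
CAC8_I = Enzyme("Cac8I", "GCNNGC", -3, -3)
XCM_I = Enzyme("XcmI", "CCANNNNNNNNNTGG", -7, -8)


@dataclass(frozen=True)
class FixtureAssay:
    """A published assay: primers, per-allele diagnostic bases, enzyme panel."""

    name: str
    fw_primer: str
    rv_primer: str
    #: allele label -> uncovered diagnostic bases
    diagnostic: dict[str, str]
    #: allele label -> the panel enzyme that cuts that allele's amplicon
    enzyme_for: dict[str, Enzyme]
    #: stated primer lengths where the published text and printed sequence
    #: disagree (psbA forward: stated 40 nt, printed 41 characters)
    stated_fw_len: Optional[int] = None
    pair: Optional[AllelePair] = field(default=None, repr=False)

    @property
    def enzymes(self) -> list[Enzyme]:
        return list(self.enzyme_for.values())

    @property
    def alleles(self) -> list[str]:
        return list(self.diagnostic)

    def amplicon(self, allele: str) -> str:
        return build_amplicon(
            self.fw_primer, self.diagnostic[allele], self.rv_primer, allele
        ).sequence

    @property
    def amplicons(self) -> dict[str, str]:
        return {a: self.amplicon(a) for a in self.diagnostic}


def _reconstruct_psba_pair() -> AllelePair:
    # revert the forced mutations described for the published primers:
    # fw 3'-terminal T->G and rv penultimate A->G
    fw_template = PSBA_FW[:-1] + "T"
    rv_template = PSBA_RV[:-2] + "A" + PSBA_RV[-1]
    wild = fw_template + "AG" + revcomp(rv_template)
    mutant = fw_template + "GG" + revcomp(rv_template)
    return make_allele_pair(wild, mutant)


_FIXTURES: dict[str, FixtureAssay] = {}


def _build() -> None:
    _FIXTURES["psbA_S264"] = FixtureAssay(
        name="psbA_S264",
        fw_primer=PSBA_FW,
        rv_primer=PSBA_RV,
        diagnostic={"wild": "AG", "mutant": "GG"},
        enzyme_for={"wild": PLE_I},
        stated_fw_len=40,
        pair=_reconstruct_psba_pair(),
    )
    _FIXTURES["ACCase_I2041"] = FixtureAssay(
        name="ACCase_I2041",
        fw_primer=ACCASE_FW,
        rv_primer=ACCASE_RV,
        diagnostic={"wild": "AT", "mutant": "AA"},
        enzyme_for={"wild": ECO_RI},
    )
    _FIXTURES["EPSPS_P106"] = FixtureAssay(
        name="EPSPS_P106",
        fw_primer=EPSPS_FW,
        rv_primer=EPSPS_RV,
        diagnostic={"P": "CC", "S": "TC", "T": "AC", "A": "GC"},
        enzyme_for={"P": XCM_I, "S": XMN_I, "T": RSA_I, "A": CAC8_I},
    )


_build()

FIXTURE_NAMES = tuple(_FIXTURES)


def load_fixture(name: str) -> FixtureAssay:
    """Load a packaged assay fixture by name.

    Raises KeyError with the known names for an unknown fixture.
    """
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        ) from None


def mini_enzyme_table_text() -> str:
    """The packaged mini enzyme table (six assay enzymes plus decoys)."""
    return (
        resources.files("dpacs.data").joinpath("mini_rebase.txt").read_text()
    )


def mini_enzyme_db() -> list[Enzyme]:
    return parse_enzyme_table(mini_enzyme_table_text().splitlines())
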