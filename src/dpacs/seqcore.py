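"""IUPAC nucleotide alphabet, degenerate pattern scanning and allele pairs.

Sequences are plain upper-case strings over the 15-letter IUPAC alphabet,
with ``-`` permitted only in aligned context (indel columns).  All public
coordinates are 1-based inclusive, matching molecular-biology convention;
internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Base sets for every IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Concrete base encoding each base set, for turning a set back into a code.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}


class AlphabetError(ValueError):
    """A character outside the IUPAC alphabet (or a gap out of context)."""


class PairValidationError(ValueError):
    """An aligned wild/mutant pair violating the input contract."""


def clean(seq: str, allow_gaps: bool = False) -> str:
    """Normalise raw input: upper-case, map U->T, validate the alphabet.

    Parameters
    ----------
    seq:
        Raw nucleotide string.
    allow_gaps:
        Permit ``-`` (aligned context only).

    Raises
    ------
    AlphabetError
        On any character outside the IUPAC alphabet.
    """
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch in IUPAC_SETS:
            continue
        if ch == GAP and allow_gaps:
            continue
        raise AlphabetError(
            f"invalid nucleotide {ch!r} at position {i + 1}"
            + ("" if allow_gaps else " (gaps not allowed here)")
        )
    return out


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet.

    Ambiguity codes map to their complementary codes (R<->Y, K<->M,
    B<->V, D<->H; S, W and N are self-complementary).  Gap characters are
    rejected: primers and amplicons are ungapped.
    """
    s = clean(seq, allow_gaps=False)
    return s.translate(_COMPLEMENT)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True if the pattern equals its own reverse complement (e.g. GAATTC)."""
    return clean(pattern) == revcomp(pattern)


def iupac_compatible(pattern_code: str, base_code: str) -> bool:
    """Subset test: does ``pattern_code`` accept every base of ``base_code``?

    ``N`` accepts everything; a concrete pattern base accepts only itself.
    The test is directional: ``iupac_compatible('A', 'N')`` is False.
    """
    try:
        pat = IUPAC_SETS[pattern_code]
        base = IUPAC_SETS[base_code]
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC code {exc.args[0]!r}") from None
    return base <= pat


def codes_intersect(code_a: str, code_b: str) -> bool:
    """True if the two codes share at least one concrete base."""
    try:
        return bool(IUPAC_SETS[code_a] & IUPAC_SETS[code_b])
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC code {exc.args[0]!r}") from None


@dataclass(frozen=True, order=True)
class SiteHit:
    """A pattern occurrence: 1-based start on the plus strand, and strand."""

    position: int
    strand: str  # '+' or '-'


def _matches_at(pattern: str, seq: str, start0: int) -> bool:
    return all(
        iupac_compatible(p, seq[start0 + j]) for j, p in enumerate(pattern)
    )


def scan(pattern: str, seq: str, both_strands: bool = True) -> list[SiteHit]:
    """Find all degenerate-pattern matches in an ungapped sequence.

    Minus-strand hits are matches of ``revcomp(pattern)``, reported by their
    plus-strand start coordinate.  Self-reverse-complementary patterns are
    reported once per location, as '+'.  A pattern longer than the sequence
    yields no hits.
    """
    pattern = clean(pattern)
    seq = clean(seq)
    hits: list[SiteHit] = []
    n, m = len(seq), len(pattern)
    if m == 0 or m > n:
        return hits
    for i in range(n - m + 1):
        if _matches_at(pattern, seq, i):
            hits.append(SiteHit(i + 1, "+"))
    if both_strands and not is_palindromic(pattern):
        rc = revcomp(pattern)
        for i in range(n - m + 1):
            if _matches_at(rc, seq, i):
                hits.append(SiteHit(i + 1, "-"))
    hits.sort()
    return hits


@dataclass(frozen=True)
class AllelePair:
    """An aligned wild/mutant sequence pair with derived diagnostics.

    ``diagnostic_columns`` are the 1-based alignment columns where the two
    alleles differ by IUPAC base-set inequality (gap vs base counts as a
    difference; an ambiguity superset vs its subset also counts — the
    ambiguity may hide the other allele).  ``column_maps`` take an aligned
    column to the 1-based ungapped position in each allele (gap columns
    absent).
    """

    wild_aligned: str
    mutant_aligned: str
    diagnostic_columns: tuple[int, ...]
    wild_seq: str = field(repr=False)
    mutant_seq: str = field(repr=False)
    wild_column_map: dict[int, int] = field(repr=False)
    mutant_column_map: dict[int, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.wild_aligned)

    def swapped(self) -> "AllelePair":
        """The same pair with the wild/mutant labels exchanged."""
        return make_allele_pair(self.mutant_aligned, self.wild_aligned)


def _column_map(aligned: str) -> dict[int, int]:
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aligned, start=1):
        if ch != GAP:
            pos += 1
            out[col] = pos
    return out


def _columns_differ(a: str, b: str) -> bool:
    if a == GAP or b == GAP:
        return a != b
    return IUPAC_SETS[a] != IUPAC_SETS[b]


def make_allele_pair(wild_aligned: str, mutant_aligned: str) -> AllelePair:
    """Validate an aligned pair and derive its diagnostic columns.

    Raises
    ------
    PairValidationError
        On length mismatch, zero differing columns, or a column gapped in
        both alleles.
    """
    w = clean(wild_aligned, allow_gaps=True)
    m = clean(mutant_aligned, allow_gaps=True)
    if len(w) != len(m):
        raise PairValidationError(
            f"aligned lengths differ: {len(w)} vs {len(m)}"
        )
    if not w:
        raise PairValidationError("empty alignment")
    diag: list[int] = []
    for col, (cw, cm) in enumerate(zip(w, m), start=1):
        if cw == GAP and cm == GAP:
            raise PairValidationError(f"column {col} is a gap in both alleles")
        if _columns_differ(cw, cm):
            diag.append(col)
    if not diag:
        raise PairValidationError("alleles are identical: no diagnostic column")
    return AllelePair(
        wild_aligned=w,
        mutant_aligned=m,
        diagnostic_columns=tuple(diag),
        wild_seq=ungap(w),
        mutant_seq=ungap(m),
        wild_column_map=_column_map(w),
        mutant_column_map=_column_map(m),
    )
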