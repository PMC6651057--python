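"""Restriction-enzyme model, table parsing and in-silico digestion.

Cut offsets follow the REBASE trailing-offset convention: ``cut_top`` and
``cut_bottom`` count nucleotides 3' of the recognition site's last base, so
``GAGTC(4/5)`` has ``cut_top=4``; zero or negative values place the cut
inside (or 5' of the end of) the site, so caret notation ``G^AATTC``
normalises to ``cut_top=-5``.  Fragment lengths are always reported from
TOP-strand cut positions: this reproduces published digest sizes for the
blunt and staggered cutters alike, and resolves single-base overhang
ambiguity (e.g. a 4/5 offset cutter) consistently.

Only enzymes with exactly one cleavage position per strand are modelled;
double-cutting and nicking enzymes are rejected at parse time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, TextIO

from .seqcore import (
    SiteHit,
    clean,
    is_palindromic,
    revcomp,
    scan,
)

log = logging.getLogger(__name__)


class EnzymeParseError(ValueError):
    """An enzyme-table line that cannot be interpreted."""


@dataclass(frozen=True)
class Enzyme:
    """A Type II restriction enzyme with a single cut per strand."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    commercial: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", clean(self.recognition))
        if not self.recognition:
            raise EnzymeParseError(f"{self.name}: empty recognition site")

    @property
    def site_len(self) -> int:
        return len(self.recognition)

    @property
    def top_cut_from_start(self) -> int:
        """Top-strand cut coordinate relative to site start (bases 5' of cut)."""
        return self.site_len + self.cut_top

    @property
    def bottom_cut_from_start(self) -> int:
        """Bottom-strand cut, in top-strand local coordinates from site start."""
        return self.site_len + self.cut_bottom

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.recognition)

    def caret_notation(self) -> str:
        """Human-readable site, caret form when the cut is inside the site."""
        t = self.top_cut_from_start
        if 0 <= t <= self.site_len:
            return self.recognition[:t] + "^" + self.recognition[t:]
        return f"{self.recognition}({self.cut_top}/{self.cut_bottom})"


@dataclass(frozen=True)
class EnzymeHit:
    """A recognition-site occurrence with its top-strand cut coordinate.

    ``position`` is the 1-based plus-strand start of the matched site;
    ``cut_after`` is the 1-based index i such that the top strand is cut
    between bases i and i+1.  ``cutting`` is False when that coordinate
    falls outside [1, len(seq)-1] — the enzyme binds but cannot produce two
    fragments (offset cutters near an amplicon end).
    """

    position: int
    strand: str
    cut_after: int
    cutting: bool


@dataclass(frozen=True)
class DigestResult:
    """Top-strand fragment lengths (sorted descending) and cut positions."""

    fragments: tuple[int, ...]
    cut_positions: tuple[int, ...]


_PAREN_RE = re.compile(
    r"^(?P<site>[A-Za-z]+)\((?P<t>-?\d+)/(?P<b>-?\d+)\)$"
)
_DOUBLE_CUT_RE = re.compile(r"\(-?\d+/-?\d+\).*\(-?\d+/-?\d+\)")


def parse_site(site: str) -> tuple[str, int, int]:
    """Parse a single site string in caret or trailing-offset dialect.

    ``G^AATTC`` places the top cut after base 1 with the symmetric bottom
    cut (palindromic caret convention); ``GAGTC(4/5)`` gives explicit
    top/bottom offsets 3' of the site.

    Returns (recognition, cut_top, cut_bottom).
    """
    site = site.strip()
    if _DOUBLE_CUT_RE.search(site):
        raise EnzymeParseError(
            f"two cleavage positions per strand not supported: {site!r}"
        )
    if "^" in site:
        if site.count("^") != 1:
            raise EnzymeParseError(f"multiple carets in {site!r}")
        left, right = site.split("^")
        rec = clean(left + right)
        t_from_start = len(left)
        # caret dialect implies a symmetric (palindromic-style) bottom cut
        b_from_start = len(rec) - t_from_start
        return rec, t_from_start - len(rec), b_from_start - len(rec)
    m = _PAREN_RE.match(site)
    if m:
        rec = clean(m.group("site"))
        return rec, int(m.group("t")), int(m.group("b"))
    raise EnzymeParseError(f"unparsable site string {site!r}")


def parse_enzyme_table(stream: Iterable[str] | TextIO) -> list[Enzyme]:
    """Parse a "NAME<ws>SITE[<ws>FLAG]" enzyme table.

    Both dialects are auto-detected per line.  Comment lines (``#``) and
    blanks are skipped.  An optional third field marks availability: ``-``
    flags a non-commercial enzyme; anything else (e.g. supplier codes) or
    absence means commercially available.  A record with two cleavage
    positions per strand is skipped with a logged warning; any other
    unparsable line raises, naming the line.
    """
    out: list[Enzyme] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise EnzymeParseError(f"line {lineno}: expected 'NAME SITE', got {line!r}")
        name, site = fields[0], fields[1]
        commercial = not (len(fields) > 2 and fields[2] == "-")
        try:
            rec, cut_top, cut_bottom = parse_site(site)
        except EnzymeParseError as exc:
            if _DOUBLE_CUT_RE.search(site):
                log.warning("line %d: skipping %s (%s)", lineno, name, exc)
                continue
            raise EnzymeParseError(f"line {lineno}: {exc}") from None
        out.append(Enzyme(name, rec, cut_top, cut_bottom, commercial))
    return out


def dedupe_isoschizomers(enzymes: Iterable[Enzyme]) -> list[Enzyme]:
    """Collapse enzymes sharing (recognition, cut_top, cut_bottom).

    The prototype kept is the commercially available one when any is, then
    the alphabetically first name — deterministic regardless of input order.
    """
    groups: dict[tuple[str, int, int], list[Enzyme]] = {}
    order: list[tuple[str, int, int]] = []
    for e in enzymes:
        key = (e.recognition, e.cut_top, e.cut_bottom)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(e)
    return [
        min(groups[k], key=lambda e: (not e.commercial, e.name)) for k in order
    ]


def _top_cut_coordinate(enzyme: Enzyme, hit: SiteHit) -> int:
    """1-based "cut after base i" index on the plus strand for a site hit."""
    start0 = hit.position - 1
    if hit.strand == "+":
        return start0 + enzyme.top_cut_from_start
    # Minus-strand site: the enzyme reads the bottom strand, so its
    # bottom-strand cut lands on the amplicon's top strand.
    return start0 + enzyme.site_len - enzyme.bottom_cut_from_start


def find_sites(enzyme: Enzyme, seq: str) -> list[EnzymeHit]:
    """All recognition-site occurrences on both strands, with cut status."""
    seq = clean(seq)
    hits = []
    for h in scan(enzyme.recognition, seq, both_strands=True):
        cut = _top_cut_coordinate(enzyme, h)
        hits.append(
            EnzymeHit(h.position, h.strand, cut, 1 <= cut <= len(seq) - 1)
        )
    return hits


def digest(enzyme: Enzyme, seq: str) -> DigestResult:
    """In-silico digestion of a linear sequence.

    Fragment lengths derive from the top-strand cut coordinates of all
    cutting site hits; with no (cutting) hits the result is one full-length
    fragment.
    """
    seq = clean(seq)
    cuts = sorted({h.cut_after for h in find_sites(enzyme, seq) if h.cutting})
    frags = []
    prev = 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(seq) - prev)
    return DigestResult(
        fragments=tuple(sorted(frags, reverse=True)),
        cut_positions=tuple(cuts),
    )
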