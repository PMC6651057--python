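"""The dPACS search engine.

Given an aligned wild/mutant pair, find (primer pair, enzyme, forced
mismatch) combinations in which mismatches deliberately written into one or
both long primers create a restriction site that cuts exactly one allele of
the short amplicon.

Geometry
--------
The submitted region decomposes into three parts shared coordinate-wise by
both alleles: a left flank ``F`` (identical in both alleles), the
diagnostic window (the columns between the first and last differing
alignment column inclusive, left uncovered by the primers), and a right
flank ``R``.  The forward primer is a 3'-anchored suffix of ``F``; the
reverse primer is the reverse complement of a prefix of ``R``; the amplicon
of an allele is ``fw + window_bases(allele) + revcomp(rv)``.  Because
non-differing columns are never gapped, ``F`` and ``R`` are gap-free and
identical across alleles; indels live entirely inside the window.

A candidate assay is built by placing an enzyme's recognition pattern over
the window (either strand), computing the minimal set of flank positions
that must be rewritten in a primer so that the pattern matches the target
allele — and verifying the other allele cannot match even through its
ambiguity codes — then choosing the shortest primers that cover every
rewritten position, and finally detecting and eliminating any additional
(off-target) sites of the same enzyme in either allele's amplicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

from .enzymes import (
    DigestResult,
    Enzyme,
    EnzymeHit,
    dedupe_isoschizomers,
    digest,
    find_sites,
)
from .seqcore import (
    GAP,
    IUPAC_SETS,
    AllelePair,
    codes_intersect,
    iupac_compatible,
    revcomp,
    ungap,
)

log = logging.getLogger(__name__)

Allele = Literal["wild", "mutant"]
Side = Literal["forward", "reverse"]


def other_allele(allele: Allele) -> Allele:
    return "mutant" if allele == "wild" else "wild"


# ---------------------------------------------------------------------------
# parameters and result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignParams:
    """Tunable search parameters.

    Primer lengths default to the 35–55 nt window: at least 35 nt so the
    restricted fragments stay well separated from the uncut amplicon, at
    most 55 nt to avoid the extra purification cost of longer synthesis.
    Budgets cap deliberate mismatches per primer (``per_primer``) or summed
    over both (``total``); off-target fixes are tallied separately under
    ``extra_budget``.  ``min_resolvability`` is the minimum gap in nt
    between the uncut amplicon and the largest digestion fragment for a
    candidate to count as gel-resolvable.
    """

    primer_len_min: int = 35
    primer_len_max: int = 55
    budget_fw: int = 2
    budget_rv: int = 2
    budget_mode: Literal["per_primer", "total"] = "per_primer"
    min_resolvability: int = 15
    require_commercial: bool = True
    detect_allele: Literal["wild", "mutant", "both"] = "wild"
    extra_budget: int = 2

    def __post_init__(self) -> None:
        if self.budget_fw < 0 or self.budget_rv < 0 or self.extra_budget < 0:
            raise ValueError("mismatch budgets must be >= 0")
        if not 1 <= self.primer_len_min <= self.primer_len_max:
            raise ValueError("need 1 <= primer_len_min <= primer_len_max")


@dataclass(frozen=True, order=True)
class Placement:
    """A recognition-pattern placement on the target allele's region.

    ``start`` is 1-based on the target allele's ungapped sequence; a '-'
    strand placement means the reverse complement of the pattern occupies
    these plus-strand positions.
    """

    start: int
    strand: str


@dataclass(frozen=True)
class ForcedMutation:
    """A deliberate primer/template mismatch, in primer sense.

    ``position_from_3prime`` is 1-based: 1 is the primer's 3'-terminal
    base.  Bases are given in primer reading sense (so a reverse-side
    mutation reports the complement of the template top strand).
    Instantiating an ambiguous template code to one of its own bases is not
    a forced mutation and is recorded separately.
    """

    primer_side: Side
    position_from_3prime: int
    template_base: str
    primer_base: str
    off_target_fix: bool = False

    def brief(self) -> str:
        tag = "F" if self.primer_side == "forward" else "R"
        return f"{tag}:-{self.position_from_3prime} {self.template_base}>{self.primer_base}"


@dataclass(frozen=True)
class Instantiation:
    """An ambiguous template code pinned to one of its own bases by a primer."""

    primer_side: Side
    position_from_3prime: int
    template_code: str
    primer_base: str


@dataclass
class OffTarget:
    """A non-engineered cutting site of the candidate's enzyme."""

    allele: Allele
    hit: EnzymeHit
    fixable: bool


@dataclass
class AssayCandidate:
    """A designed assay: primer pair, enzyme, and per-allele predictions."""

    enzyme: Enzyme
    cut_allele: Allele
    placement: Placement
    fw_primer: str
    rv_primer: str
    forced_mutations: list[ForcedMutation]
    instantiations: list[Instantiation]
    diagnostic_bases: dict[Allele, str]
    amplicons: dict[Allele, str]
    digests: dict[Allele, DigestResult] = field(default_factory=dict)
    offtargets: list[OffTarget] = field(default_factory=list)
    rejection: Optional[str] = None

    @property
    def discriminating_mutations(self) -> list[ForcedMutation]:
        return [m for m in self.forced_mutations if not m.off_target_fix]

    @property
    def offtarget_fixes(self) -> list[ForcedMutation]:
        return [m for m in self.forced_mutations if m.off_target_fix]

    @property
    def n_forced(self) -> int:
        return len(self.forced_mutations)

    @property
    def min_distance_from_3prime(self) -> float:
        if not self.forced_mutations:
            return float("inf")
        return min(m.position_from_3prime - 1 for m in self.forced_mutations)

    @property
    def resolvability_gap(self) -> int:
        """Uncut length of the non-target allele minus its largest cut fragment."""
        uncut = len(self.amplicons[other_allele(self.cut_allele)])
        largest_cut = max(self.digests[self.cut_allele].fragments)
        return uncut - largest_cut

    @property
    def score(self) -> tuple:
        return (
            self.n_forced,
            -self.min_distance_from_3prime,
            not self.enzyme.commercial,
            -self.resolvability_gap,
            self.enzyme.name,
        )

    def mutation_key(self) -> frozenset[tuple[str, int, str]]:
        """Canonical identity of the discriminating mutation set."""
        return frozenset(
            (m.primer_side, m.position_from_3prime, m.primer_base)
            for m in self.discriminating_mutations
        )

    def triple(self) -> tuple[str, tuple[int, str], frozenset]:
        return (self.enzyme.name, (self.placement.start, self.placement.strand),
                self.mutation_key())


# ---------------------------------------------------------------------------
# region decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """Flanks and per-allele diagnostic-window bases of an AllelePair."""

    F: str
    R: str
    window: dict[Allele, str]
    diag_positions: dict[Allele, frozenset[int]]  # 0-based, region coords

    def seq(self, allele: Allele) -> str:
        return self.F + self.window[allele] + self.R

    def window_span(self, allele: Allele) -> tuple[int, int]:
        """0-based half-open span of the window in this allele's region."""
        return len(self.F), len(self.F) + len(self.window[allele])


def decompose(pair: AllelePair) -> Region:
    first, last = pair.diagnostic_columns[0], pair.diagnostic_columns[-1]
    F = pair.wild_aligned[: first - 1]
    R = pair.wild_aligned[last:]
    assert GAP not in F and GAP not in R  # guaranteed by pair validation
    window = {
        "wild": ungap(pair.wild_aligned[first - 1 : last]),
        "mutant": ungap(pair.mutant_aligned[first - 1 : last]),
    }
    diag_positions: dict[Allele, frozenset[int]] = {}
    for allele, aligned, cmap in (
        ("wild", pair.wild_aligned, pair.wild_column_map),
        ("mutant", pair.mutant_aligned, pair.mutant_column_map),
    ):
        diag_positions[allele] = frozenset(
            cmap[c] - 1 for c in pair.diagnostic_columns if aligned[c - 1] != GAP
        )
    return Region(F=F, R=R, window=window, diag_positions=diag_positions)


# ---------------------------------------------------------------------------
# placement enumeration and mismatch derivation
# ---------------------------------------------------------------------------


def _oriented_pattern(enzyme: Enzyme, strand: str) -> str:
    return enzyme.recognition if strand == "+" else revcomp(enzyme.recognition)


def enumerate_placements(
    enzyme: Enzyme, pair: AllelePair, params: DesignParams,
    target: Allele = "wild",
) -> list[Placement]:
    """All placements of the recognition pattern over the diagnostic region.

    A placement must lie fully inside the target allele's region and
    overlap at least one diagnostic position (for a pure-deletion target
    allele: straddle the deletion junction).  Palindromic patterns are
    enumerated once per location.
    """
    region = decompose(pair)
    return _enumerate_placements(enzyme, region, target)


def _enumerate_placements(
    enzyme: Enzyme, region: Region, target: Allele
) -> list[Placement]:
    seq = region.seq(target)
    L = enzyme.site_len
    diag = region.diag_positions[target]
    wstart, wend = region.window_span(target)
    strands = ["+"] if enzyme.palindromic else ["+", "-"]
    out = []
    for strand in strands:
        for s0 in range(0, len(seq) - L + 1):
            span = range(s0, s0 + L)
            if diag:
                if not any(p in diag for p in span):
                    continue
            else:
                # target allele carries a deletion: anchor on the junction
                if not (s0 < wstart < s0 + L):
                    continue
            out.append(Placement(start=s0 + 1, strand=strand))
    out.sort()
    return out


@dataclass(frozen=True)
class _Change:
    """Internal: a rewritten flank position (region coordinates)."""

    side: Side
    flank_pos: int  # 0-based within F (forward) or R (reverse)
    new_code: str
    template_code: str
    forced: bool
    off_target_fix: bool = False

    def position_from_3prime(self, region: Region) -> int:
        if self.side == "forward":
            return len(region.F) - self.flank_pos
        return self.flank_pos + 1

    def primer_sense(self, code: str) -> str:
        return code if self.side == "forward" else revcomp(code)


class Infeasible(Exception):
    """A placement that cannot be engineered; carries the reason."""


def _classify(region: Region, target: Allele, pos0: int) -> tuple[str, int]:
    """Classify a region position: ('forward'|'window'|'reverse', flank index)."""
    wstart, wend = region.window_span(target)
    if pos0 < wstart:
        return "forward", pos0
    if pos0 < wend:
        return "window", pos0 - wstart
    return "reverse", pos0 - wend


def required_mismatches(
    placement: Placement,
    enzyme: Enzyme,
    pair: AllelePair,
    target_allele: Allele = "wild",
) -> list[ForcedMutation]:
    """Minimal forced-mutation set for a placement, or raise Infeasible.

    Returns the canonical (alphabetically first) base assignment over the
    minimal support; the full search additionally falls back to later
    assignments when a base choice fails downstream verification.
    """
    region = decompose(pair)
    inst, slots = _required_slots(placement, enzyme, region, target_allele)
    for changes in _assignments(inst, slots, region):
        if not _other_allele_can_match(
            placement,
            _oriented_pattern(enzyme, placement.strand),
            region,
            target_allele,
            changes,
        ):
            return [_to_forced(c, region) for c in changes if c.forced]
    raise Infeasible("no discrimination: other allele can also match")


def _to_forced(c: _Change, region: Region) -> ForcedMutation:
    return ForcedMutation(
        primer_side=c.side,
        position_from_3prime=c.position_from_3prime(region),
        template_base=c.primer_sense(c.template_code),
        primer_base=c.primer_sense(c.new_code),
        off_target_fix=c.off_target_fix,
    )


#: a forced-mutation slot: (side, flank index, template code, allowed bases)
_Slot = tuple[Side, int, str, tuple[str, ...]]


def _required_slots(
    placement: Placement, enzyme: Enzyme, region: Region, target: Allele
) -> tuple[list[_Change], list[_Slot]]:
    """Derive the minimal support of flank rewrites for a placement.

    Window positions are not primer-coverable: the pattern code must accept
    every base the (possibly ambiguous) template allows there, else the
    placement is infeasible.  Flank positions already accepted are left as
    template; ambiguous flank codes that merely intersect the pattern are
    instantiated (pinned, not forced); disjoint codes become forced-mutation
    slots whose allowed bases are those the pattern accepts.  Returns
    (instantiations, forced slots).
    """
    pat = _oriented_pattern(enzyme, placement.strand)
    s0 = placement.start - 1
    seq_t = region.seq(target)
    if s0 < 0 or s0 + len(pat) > len(seq_t):
        raise Infeasible("placement outside region")
    inst: list[_Change] = []
    slots: list[_Slot] = []
    for j, p in enumerate(pat):
        pos0 = s0 + j
        kind, idx = _classify(region, target, pos0)
        c = seq_t[pos0]
        if kind == "window":
            if not iupac_compatible(p, c):
                raise Infeasible(
                    f"required change at diagnostic-window position {pos0 + 1}"
                )
            continue
        if iupac_compatible(p, c):
            continue
        if codes_intersect(p, c):
            base = min(IUPAC_SETS[p] & IUPAC_SETS[c])
            inst.append(_Change(kind, idx, base, c, forced=False))
        else:
            slots.append((kind, idx, c, tuple(sorted(IUPAC_SETS[p]))))
    return inst, slots


def _assignments(
    inst: list[_Change], slots: list[_Slot], region: Region
) -> Iterable[list[_Change]]:
    """All base assignments over the forced slots, canonically ordered.

    Assignments are yielded sorted by the canonical mutation-set key
    (sorted (side, position-from-3', base) tuples), so the first assignment
    surviving downstream verification is the one a brute-force enumerator
    would select as minimal.
    """
    from itertools import product

    if not slots:
        yield list(inst)
        return
    options = []
    for combo in product(*(bases for *_x, bases in slots)):
        forced = [
            _Change(side, idx, base, tmpl, forced=True)
            for (side, idx, tmpl, _bases), base in zip(slots, combo)
        ]
        key = tuple(
            sorted(
                (c.side, c.position_from_3prime(region), c.primer_sense(c.new_code))
                for c in forced
            )
        )
        options.append((key, forced))
    options.sort(key=lambda t: t[0])
    for _key, forced in options:
        yield inst + forced


def _apply_changes(region: Region, allele: Allele, changes: Iterable[_Change]) -> str:
    F = list(region.F)
    R = list(region.R)
    for c in changes:
        (F if c.side == "forward" else R)[c.flank_pos] = c.new_code
    return "".join(F) + region.window[allele] + "".join(R)


def _other_allele_can_match(
    placement: Placement, pat: str, region: Region, target: Allele,
    changes: list[_Change],
) -> bool:
    """Can the non-target allele match the pattern at this placement?

    "Can match" uses base-set intersection at every position: an ambiguity
    code in the other allele may hide a cuttable base, so possibility of a
    match is enough to void discrimination.  With an indel the placement is
    checked under both the left-anchored and right-anchored alignment of
    the window shift.
    """
    other = other_allele(target)
    seq_o = _apply_changes(region, other, changes)
    s0 = placement.start - 1
    shift = len(region.window[other]) - len(region.window[target])
    for anchor in {s0, s0 + shift}:
        if anchor < 0 or anchor + len(pat) > len(seq_o):
            continue
        if all(codes_intersect(p, seq_o[anchor + j]) for j, p in enumerate(pat)):
            return True
    return False


# ---------------------------------------------------------------------------
# primer construction
# ---------------------------------------------------------------------------


def _coverage_requirements(
    placement: Placement, enzyme: Enzyme, region: Region, target: Allele,
    changes: list[_Change],
) -> tuple[int, int]:
    """Minimum primer reach (fw, rv) in nt so the amplicon keeps the whole
    engineered site, its top-strand cut point, and every rewritten position."""
    s0 = placement.start - 1
    L = enzyme.site_len
    wstart, wend = region.window_span(target)
    need_f = max(0, wstart - s0)
    need_r = max(0, (s0 + L) - wend)
    # the cut coordinate needs >=1 amplicon base on each side
    if placement.strand == "+":
        cut = s0 + enzyme.top_cut_from_start
    else:
        cut = s0 + L - enzyme.bottom_cut_from_start
    if cut <= wstart:
        need_f = max(need_f, wstart - cut + 1)
    if cut >= wend:
        need_r = max(need_r, cut - wend + 1)
    for c in changes:
        if c.side == "forward":
            need_f = max(need_f, len(region.F) - c.flank_pos)
        else:
            need_r = max(need_r, c.flank_pos + 1)
    return need_f, need_r


def build_primers(
    region: Region,
    changes: list[_Change],
    params: DesignParams,
    need_f: int = 0,
    need_r: int = 0,
) -> tuple[str, str]:
    """Choose primer lengths and emit the primer sequences.

    Each primer takes the minimum length within the allowed window that
    covers every required position; it grows beyond ``primer_len_min`` only
    as needed.  Raises Infeasible when the required coverage exceeds
    ``primer_len_max`` or the available flank.
    """
    for c in changes:
        if c.side == "forward":
            need_f = max(need_f, len(region.F) - c.flank_pos)
        else:
            need_r = max(need_r, c.flank_pos + 1)
    k_f = max(params.primer_len_min, need_f)
    k_r = max(params.primer_len_min, need_r)
    if k_f > params.primer_len_max or k_r > params.primer_len_max:
        raise Infeasible("required primer coverage exceeds primer_len_max")
    if k_f > len(region.F) or k_r > len(region.R):
        raise Infeasible("required primer length exceeds available flank")
    F_mod = list(region.F)
    R_mod = list(region.R)
    for c in changes:
        (F_mod if c.side == "forward" else R_mod)[c.flank_pos] = c.new_code
    fw = "".join(F_mod[len(region.F) - k_f :])
    rv = revcomp("".join(R_mod[:k_r]))
    return fw, rv


def _assemble(
    enzyme: Enzyme,
    placement: Placement,
    region: Region,
    target: Allele,
    changes: list[_Change],
    params: DesignParams,
) -> AssayCandidate:
    need_f, need_r = _coverage_requirements(placement, enzyme, region, target, changes)
    fw, rv = build_primers(region, changes, params, need_f, need_r)
    amplicons: dict[Allele, str] = {
        a: fw + region.window[a] + revcomp(rv) for a in ("wild", "mutant")
    }
    cand = AssayCandidate(
        enzyme=enzyme,
        cut_allele=target,
        placement=placement,
        fw_primer=fw,
        rv_primer=rv,
        forced_mutations=[_to_forced(c, region) for c in changes if c.forced],
        instantiations=[
            Instantiation(
                primer_side=c.side,
                position_from_3prime=c.position_from_3prime(region),
                template_code=c.primer_sense(c.template_code),
                primer_base=c.primer_sense(c.new_code),
            )
            for c in changes
            if not c.forced
        ],
        diagnostic_bases=dict(region.window),
        amplicons=amplicons,
    )
    cand.digests = {a: digest(enzyme, amplicons[a]) for a in amplicons}
    return cand


# ---------------------------------------------------------------------------
# off-target detection and elimination
# ---------------------------------------------------------------------------


def _engineered_hit_coords(
    cand: AssayCandidate, region: Region
) -> tuple[int, str]:
    """(1-based amplicon position, strand) of the engineered site in the cut allele."""
    offset = len(region.F) - _fw_reach(cand, region)
    return cand.placement.start - offset, cand.placement.strand


def _fw_reach(cand: AssayCandidate, region: Region) -> int:
    return len(cand.fw_primer)


def find_offtargets(cand: AssayCandidate, region: Region) -> list[OffTarget]:
    """All cutting sites of the enzyme other than the engineered one.

    Sites overlapping only the diagnostic window cannot be broken by a
    primer and are reported as unfixable.
    """
    eng_pos, eng_strand = _engineered_hit_coords(cand, region)
    out: list[OffTarget] = []
    for allele in ("wild", "mutant"):
        amp = cand.amplicons[allele]
        wstart = len(cand.fw_primer)
        wend = wstart + len(cand.diagnostic_bases[allele])
        for h in find_sites(cand.enzyme, amp):
            if not h.cutting:
                continue
            if allele == cand.cut_allele and (h.position, h.strand) == (
                eng_pos,
                eng_strand,
            ):
                continue
            span = range(h.position - 1, h.position - 1 + cand.enzyme.site_len)
            fixable = any(p < wstart or p >= wend for p in span)
            out.append(OffTarget(allele=allele, hit=h, fixable=fixable))
    out.sort(key=lambda o: (o.allele != cand.cut_allele, o.hit.position, o.hit.strand))
    return out


def _amp_pos_to_change_slot(
    cand: AssayCandidate, allele: Allele, pos0: int, region: Region
) -> Optional[tuple[Side, int, int]]:
    """Map a 0-based amplicon position to (side, flank index, dist from 3').

    Returns None for window positions (not primer-coverable).
    """
    wstart = len(cand.fw_primer)
    wend = wstart + len(cand.diagnostic_bases[allele])
    if pos0 < wstart:
        flank_pos = len(region.F) - wstart + pos0
        return "forward", flank_pos, wstart - 1 - pos0
    if pos0 < wend:
        return None
    flank_pos = pos0 - wend
    return "reverse", flank_pos, flank_pos


def eliminate_offtargets(
    cand: AssayCandidate,
    region: Region,
    changes: list[_Change],
    params: DesignParams,
    extra_budget: Optional[int] = None,
) -> tuple[AssayCandidate, list[_Change]]:
    """Greedily break off-target sites with additional primer mismatches.

    For each off-target in turn, try the single primer-coverable base
    change farthest from its primer's 3' end that (a) certainly breaks the
    site, (b) does not touch the engineered site or the window, and (c)
    creates no new cutting site for the enzyme anywhere in either amplicon;
    re-scan after each fix.  Fix mutations are tallied separately from the
    discriminating budget, capped by ``extra_budget``.  Raises Infeasible
    when an off-target survives every in-budget fix.
    """
    if extra_budget is None:
        extra_budget = params.extra_budget
    fixes_used = 0
    current = cand
    cur_changes = list(changes)
    while True:
        offs = find_offtargets(current, region)
        current.offtargets = offs
        if not offs:
            return current, cur_changes
        if fixes_used >= extra_budget:
            raise Infeasible(
                f"{len(offs)} off-target site(s) remain with fix budget exhausted"
            )
        off = offs[0]
        if not off.fixable:
            raise Infeasible("off-target overlaps only diagnostic bases: unfixable")
        fixed = _try_fix(current, off, region, cur_changes, params)
        if fixed is None:
            raise Infeasible("no single-base change breaks the off-target site")
        current, cur_changes = fixed
        fixes_used += 1


def _try_fix(
    cand: AssayCandidate,
    off: OffTarget,
    region: Region,
    changes: list[_Change],
    params: DesignParams,
) -> Optional[tuple[AssayCandidate, list[_Change]]]:
    enzyme = cand.enzyme
    pat = _oriented_pattern(enzyme, off.hit.strand)
    eng_pos, _ = _engineered_hit_coords(cand, region)
    eng_span_cut = set(range(eng_pos - 1, eng_pos - 1 + enzyme.site_len))
    baseline = {
        a: {
            (h.position, h.strand)
            for h in find_sites(enzyme, cand.amplicons[a])
            if h.cutting
        }
        for a in ("wild", "mutant")
    }
    slots = []
    for j in range(enzyme.site_len):
        pos0 = off.hit.position - 1 + j
        slot = _amp_pos_to_change_slot(cand, off.allele, pos0, region)
        if slot is None:
            continue
        side, flank_pos, dist3 = slot
        # a fix inside the cut allele's engineered site would destroy it;
        # flank coordinates are shared between alleles, so check via slot
        cut_amp_pos0 = (
            flank_pos - (len(region.F) - len(cand.fw_primer))
            if side == "forward"
            else len(cand.fw_primer)
            + len(cand.diagnostic_bases[cand.cut_allele])
            + flank_pos
        )
        if cut_amp_pos0 in eng_span_cut:
            continue
        slots.append((dist3, side, flank_pos, j))
    # farthest from the 3' end first; deterministic tie-break
    slots.sort(key=lambda t: (-t[0], t[1], t[2]))
    for dist3, side, flank_pos, j in slots:
        flank = region.F if side == "forward" else region.R
        current_code = flank[flank_pos]
        for c in changes:
            if c.side == side and c.flank_pos == flank_pos:
                current_code = c.new_code
        breaking = sorted(set("ACGT") - IUPAC_SETS[pat[j]] - {current_code})
        for base in breaking:
            trial = [
                c for c in changes if not (c.side == side and c.flank_pos == flank_pos)
            ]
            trial.append(
                _Change(side, flank_pos, base, current_code, forced=True,
                        off_target_fix=True)
            )
            try:
                trial_cand = _assemble(
                    enzyme, cand.placement, region, cand.cut_allele, trial, params
                )
            except Infeasible:
                continue
            after = {
                a: {
                    (h.position, h.strand)
                    for h in find_sites(enzyme, trial_cand.amplicons[a])
                    if h.cutting
                }
                for a in ("wild", "mutant")
            }
            removed_target = (off.hit.position, off.hit.strand) not in after[off.allele]
            no_new = all(after[a] <= baseline[a] for a in after)
            eng_intact = (eng_pos, cand.placement.strand) in after[cand.cut_allele]
            if removed_target and no_new and eng_intact:
                return trial_cand, trial
    return None


# ---------------------------------------------------------------------------
# verification, ranking, search
# ---------------------------------------------------------------------------


def verify(cand: AssayCandidate, params: DesignParams) -> Optional[str]:
    """Recompute the candidate's digestion behaviour from scratch.

    Returns None when valid, else a rejection reason: the enzyme must cut
    the target allele's amplicon (>= 2 fragments), leave the other allele
    whole, and the cut-vs-uncut contrast must meet the resolvability gap.
    """
    cut = digest(cand.enzyme, cand.amplicons[cand.cut_allele])
    uncut = digest(cand.enzyme, cand.amplicons[other_allele(cand.cut_allele)])
    cand.digests = {
        cand.cut_allele: cut,
        other_allele(cand.cut_allele): uncut,
    }
    if len(cut.fragments) < 2:
        return "enzyme does not cut the target allele amplicon"
    if len(uncut.fragments) != 1:
        return "enzyme cuts the non-target allele amplicon"
    if cand.resolvability_gap < params.min_resolvability:
        return (
            f"resolvability gap {cand.resolvability_gap} nt below "
            f"{params.min_resolvability} nt"
        )
    return None


def rank(candidates: list[AssayCandidate]) -> list[AssayCandidate]:
    """Deterministic ranking: fewest forced mismatches first, then the set
    whose nearest mismatch sits farthest from a 3' end, commercial enzymes
    before flagged ones, larger cut-vs-uncut gap, enzyme name."""
    return sorted(
        candidates,
        key=lambda c: c.score
        + (
            c.cut_allele,
            (c.placement.start, c.placement.strand),
            tuple(sorted(c.mutation_key())),
        ),
    )


def _slots_within_budget(slots: list[_Slot], params: DesignParams) -> bool:
    n_fw = sum(1 for s in slots if s[0] == "forward")
    n_rv = sum(1 for s in slots if s[0] == "reverse")
    if params.budget_mode == "total":
        return n_fw + n_rv <= params.budget_fw + params.budget_rv
    return n_fw <= params.budget_fw and n_rv <= params.budget_rv


def search(
    pair: AllelePair,
    db: Iterable[Enzyme],
    params: DesignParams = DesignParams(),
) -> list[AssayCandidate]:
    """Full dPACS search: ranked assay candidates for the requested allele(s).

    Pipeline per enzyme and placement: derive the minimal discriminating
    mismatch set, check budgets, build minimal-length primers, eliminate
    off-target sites, verify digestion from scratch, then rank.  Output
    order is deterministic; an empty list is a valid outcome.
    """
    enzymes = dedupe_isoschizomers(db)
    if params.require_commercial:
        enzymes = [e for e in enzymes if e.commercial]
    enzymes = sorted(enzymes, key=lambda e: e.name)
    region = decompose(pair)
    targets: list[Allele]
    if params.detect_allele == "both":
        targets = ["wild", "mutant"]
    else:
        targets = [params.detect_allele]
    results: list[AssayCandidate] = []
    stats = {"placements": 0, "feasible": 0, "verified": 0}
    for target in targets:
        for enzyme in enzymes:
            pat = _oriented_pattern(enzyme, "+")
            for placement in _enumerate_placements(enzyme, region, target):
                stats["placements"] += 1
                try:
                    inst, slots = _required_slots(placement, enzyme, region, target)
                except Infeasible:
                    continue
                if not _slots_within_budget(slots, params):
                    continue
                stats["feasible"] += 1
                oriented = _oriented_pattern(enzyme, placement.strand)
                for changes in _assignments(inst, slots, region):
                    if _other_allele_can_match(
                        placement, oriented, region, target, changes
                    ):
                        continue
                    try:
                        cand = _assemble(
                            enzyme, placement, region, target, changes, params
                        )
                        cand, changes2 = eliminate_offtargets(
                            cand, region, changes, params
                        )
                    except Infeasible as exc:
                        log.debug(
                            "%s %s: rejected (%s)", enzyme.name, placement, exc
                        )
                        continue
                    reason = verify(cand, params)
                    if reason is not None:
                        log.debug(
                            "%s %s: rejected (%s)", enzyme.name, placement, reason
                        )
                        continue
                    stats["verified"] += 1
                    results.append(cand)
                    break  # first (canonical) surviving assignment only
    log.info(
        "search: %d enzymes, budgets fw=%d rv=%d; placements=%d feasible=%d "
        "verified=%d",
        len(enzymes), params.budget_fw, params.budget_rv,
        stats["placements"], stats["feasible"], stats["verified"],
    )
    return rank(results)


# ---------------------------------------------------------------------------
# two-enzyme panels on a single PCR product
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayPanel:
    """A wild-detecting and a mutant-detecting assay sharing one primer pair.

    The merged primers carry the union of both candidates' mismatches; each
    enzyme must still cut only its own target allele's amplicon, so the two
    digests can be run from a single PCR product in separate reactions.
    """

    fw_primer: str
    rv_primer: str
    wild_candidate: AssayCandidate
    mutant_candidate: AssayCandidate


def pair_panels(
    pair: AllelePair,
    wild_cands: list[AssayCandidate],
    mutant_cands: list[AssayCandidate],
    params: DesignParams = DesignParams(),
    limit: int = 10,
) -> list[AssayPanel]:
    """Pair non-interfering candidates into single-PCR panels.

    For each (wild-detecting, mutant-detecting) combination, merge the
    primer rewrites; a merge fails on conflicting bases at the same flank
    position, and the merged amplicons are re-verified for both enzymes
    (each cuts exactly its own target, no off-targets for either).
    """
    region = decompose(pair)
    panels: list[AssayPanel] = []
    for wc in wild_cands:
        for mc in mutant_cands:
            merged = _merge_panel(region, wc, mc, params)
            if merged is not None:
                panels.append(merged)
            if len(panels) >= limit:
                return panels
    return panels


def _primer_changes(cand: AssayCandidate, region: Region) -> dict[tuple[str, int], str]:
    """Rewritten flank positions of a candidate versus the template flanks."""
    out: dict[tuple[str, int], str] = {}
    off_f = len(region.F) - len(cand.fw_primer)
    for i, base in enumerate(cand.fw_primer):
        if region.F[off_f + i] != base:
            out[("forward", off_f + i)] = base
    rv_top = revcomp(cand.rv_primer)
    for i, base in enumerate(rv_top):
        if region.R[i] != base:
            out[("reverse", i)] = base
    return out


def _merge_panel(
    region: Region,
    wc: AssayCandidate,
    mc: AssayCandidate,
    params: DesignParams,
) -> Optional[AssayPanel]:
    ch_w = _primer_changes(wc, region)
    ch_m = _primer_changes(mc, region)
    for key in ch_w.keys() & ch_m.keys():
        if ch_w[key] != ch_m[key]:
            return None
    merged = {**ch_w, **ch_m}
    k_f = max(len(wc.fw_primer), len(mc.fw_primer))
    k_r = max(len(wc.rv_primer), len(mc.rv_primer))
    F_mod = list(region.F)
    R_mod = list(region.R)
    for (side, pos), base in merged.items():
        (F_mod if side == "forward" else R_mod)[pos] = base
    fw = "".join(F_mod[len(region.F) - k_f :])
    rv = revcomp("".join(R_mod[:k_r]))
    amp = {a: fw + region.window[a] + revcomp(rv) for a in ("wild", "mutant")}
    for cand, target in ((wc, "wild"), (mc, "mutant")):
        cut = digest(cand.enzyme, amp[target])
        uncut = digest(cand.enzyme, amp[other_allele(target)])
        if len(cut.fragments) < 2 or len(uncut.fragments) != 1:
            return None
        if len(amp[other_allele(target)]) - max(cut.fragments) < params.min_resolvability:
            return None
    return AssayPanel(fw_primer=fw, rv_primer=rv, wild_candidate=wc, mutant_candidate=mc)
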