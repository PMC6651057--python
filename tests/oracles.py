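"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — naive
per-position matching, local complement tables, exhaustive enumeration of
mismatch subsets — so it shares no code path with the package internals it
checks (the in-silico digest of assembled amplicons is also recomputed
locally from the cut-offset definition).
"""

from __future__ import annotations

from itertools import product

_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def certain_match(pattern: str, seq: str, i: int) -> bool:
    return all(
        set(_SETS[seq[i + j]]) <= set(_SETS[p]) for j, p in enumerate(pattern)
    )


def naive_scan(pattern: str, seq: str) -> list[tuple[int, str]]:
    """Sliding-window scan, both strands, palindromes reported once as '+'."""
    hits = []
    pats = [("+", pattern)]
    if rc(pattern) != pattern:
        pats.append(("-", rc(pattern)))
    for strand, pat in pats:
        for i in range(len(seq) - len(pat) + 1):
            if certain_match(pat, seq, i):
                hits.append((i + 1, strand))
    return sorted(hits)


def naive_cut_coords(enzyme, seq: str) -> list[tuple[int, str, int]]:
    """(pos1, strand, top-strand cut coordinate) for every site occurrence."""
    L = len(enzyme.recognition)
    out = []
    for pos1, strand in naive_scan(enzyme.recognition, seq):
        i = pos1 - 1
        cut = i + L + enzyme.cut_top if strand == "+" else i - enzyme.cut_bottom
        out.append((pos1, strand, cut))
    return out


def naive_digest(enzyme, seq: str) -> list[int]:
    """Fragment lengths (descending) from first-principles cut arithmetic."""
    cuts = sorted(
        {c for _p, _s, c in naive_cut_coords(enzyme, seq) if 1 <= c <= len(seq) - 1}
    )
    frags = []
    prev = 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(seq) - prev)
    return sorted(frags, reverse=True)


def _decompose(pair):
    """Region split computed directly from the aligned strings."""
    w, m = pair.wild_aligned, pair.mutant_aligned
    diff = [
        i
        for i, (a, b) in enumerate(zip(w, m))
        if ("-" in (a, b) and a != b)
        or ("-" not in (a, b) and set(_SETS[a]) != set(_SETS[b]))
    ]
    first, last = diff[0], diff[-1]
    F = w[:first]
    R = w[last + 1 :]
    win = {
        "wild": w[first : last + 1].replace("-", ""),
        "mutant": m[first : last + 1].replace("-", ""),
    }
    diag_pos = {}
    for allele, aligned in (("wild", w), ("mutant", m)):
        pos = []
        ungapped = 0
        for i, ch in enumerate(aligned):
            if ch != "-":
                if i in diff:
                    pos.append(ungapped)
                ungapped += 1
        diag_pos[allele] = set(pos)
    return F, R, win, diag_pos


def brute_force_search(pair, db, params, target="wild"):
    """Exhaustive enumeration of (enzyme, placement, forced-mutation set).

    For every placement of every enzyme's pattern (both strands) over the
    diagnostic region, every substitution assignment over the flank
    positions inside the recognition span is tried; a triple is valid when
    the target allele's amplicon certainly carries the site, the other
    allele cannot carry it even through ambiguity codes, per-side budgets
    and primer-length coverage hold, the assembled amplicons digest to
    >= 2 / exactly 1 fragments with no off-target site anywhere (the
    zero-extra-budget setting this oracle models), and the cut-vs-uncut
    gap meets the resolvability threshold.  Per (enzyme, placement) the
    minimal valid set under (size, canonical order) is kept — the set the
    package search is specified to construct.  Substitutions outside the
    recognition span cannot contribute to site creation and are not
    enumerated.
    """
    F, R, win, diag_pos = _decompose(pair)
    other = "mutant" if target == "wild" else "wild"
    seq_t = F + win[target] + R
    wstart, wend = len(F), len(F) + len(win[target])
    shift = len(win[other]) - len(win[target])
    best: dict[tuple, frozenset] = {}
    seen = set()
    for enzyme in db:
        key_e = (enzyme.recognition, enzyme.cut_top, enzyme.cut_bottom)
        if key_e in seen:
            continue
        seen.add(key_e)
        if params.require_commercial and not enzyme.commercial:
            continue
        L = len(enzyme.recognition)
        strands = ["+"] if rc(enzyme.recognition) == enzyme.recognition else ["+", "-"]
        for strand in strands:
            pat = enzyme.recognition if strand == "+" else rc(enzyme.recognition)
            for s0 in range(0, len(seq_t) - L + 1):
                span = range(s0, s0 + L)
                if diag_pos[target]:
                    if not any(p in diag_pos[target] for p in span):
                        continue
                elif not (s0 < wstart < s0 + L):
                    continue
                ok = True
                support = []  # (region pos, allowed bases)
                for j in range(L):
                    pos = s0 + j
                    base = seq_t[pos]
                    allowed = set(_SETS[pat[j]])
                    if wstart <= pos < wend:
                        if not set(_SETS[base]) <= allowed:
                            ok = False
                            break
                    elif base not in allowed:
                        assert base in "ACGT", "oracle expects concrete flanks"
                        support.append((pos, sorted(allowed)))
                if not ok:
                    continue
                n_fw = sum(1 for p, _ in support if p < wstart)
                n_rv = len(support) - n_fw
                if params.budget_mode == "total":
                    if n_fw + n_rv > params.budget_fw + params.budget_rv:
                        continue
                elif n_fw > params.budget_fw or n_rv > params.budget_rv:
                    continue
                cut = (
                    s0 + L + enzyme.cut_top
                    if strand == "+"
                    else s0 - enzyme.cut_bottom
                )
                need_f = max(0, wstart - s0)
                need_r = max(0, s0 + L - wend)
                if cut <= wstart:
                    need_f = max(need_f, wstart - cut + 1)
                if cut >= wend:
                    need_r = max(need_r, cut - wend + 1)
                for p, _ in support:
                    if p < wstart:
                        need_f = max(need_f, wstart - p)
                    else:
                        need_r = max(need_r, p - wend + 1)
                k_f = max(params.primer_len_min, need_f)
                k_r = max(params.primer_len_min, need_r)
                if (
                    k_f > params.primer_len_max
                    or k_r > params.primer_len_max
                    or k_f > len(F)
                    or k_r > len(R)
                ):
                    continue
                for combo in product(*(bases for _p, bases in support)):
                    seq_mod = list(seq_t)
                    for (p, _), b in zip(support, combo):
                        seq_mod[p] = b
                    F_mod = "".join(seq_mod[:wstart])
                    R_mod = "".join(seq_mod[wend:])
                    # other allele must not possibly match at the placement
                    seq_o = F_mod + win[other] + R_mod
                    clash = False
                    for anchor in {s0, s0 + shift}:
                        if 0 <= anchor <= len(seq_o) - L and all(
                            set(_SETS[seq_o[anchor + j]]) & set(_SETS[pat[j]])
                            for j in range(L)
                        ):
                            clash = True
                            break
                    if clash:
                        continue
                    amp_t = F_mod[len(F) - k_f :] + win[target] + R_mod[:k_r]
                    amp_o = F_mod[len(F) - k_f :] + win[other] + R_mod[:k_r]
                    eng = (s0 - (len(F) - k_f) + 1, strand)
                    hits_t = {
                        (p, s)
                        for p, s, c in naive_cut_coords(enzyme, amp_t)
                        if 1 <= c <= len(amp_t) - 1
                    }
                    hits_o = {
                        (p, s)
                        for p, s, c in naive_cut_coords(enzyme, amp_o)
                        if 1 <= c <= len(amp_o) - 1
                    }
                    if hits_t != {eng} or hits_o:
                        continue
                    frags_t = naive_digest(enzyme, amp_t)
                    frags_o = naive_digest(enzyme, amp_o)
                    if len(frags_t) < 2 or len(frags_o) != 1:
                        continue
                    if len(amp_o) - max(frags_t) < params.min_resolvability:
                        continue
                    muts = []
                    for (p, _), b in zip(support, combo):
                        if p < wstart:
                            muts.append(("forward", wstart - p, b))
                        else:
                            muts.append(("reverse", p - wend + 1, _COMP[b]))
                    key = (enzyme.name, (s0 + 1, strand))
                    cand = frozenset(muts)
                    rank_key = (len(cand), tuple(sorted(cand)))
                    if key not in best or rank_key < (
                        len(best[key]),
                        tuple(sorted(best[key])),
                    ):
                        best[key] = cand
    return {(name, plc, muts) for (name, plc), muts in best.items()}
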