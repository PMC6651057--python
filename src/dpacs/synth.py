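"""Seeded synthetic allele-pair generator for search and oracle testing.

Generation is a pure function of a :class:`SyntheticPairSpec`: the same
spec (including its seed) always yields a byte-identical pair.  Optionally
a recognition site for a chosen enzyme is planted so that it spans the
diagnostic region of one allele and certainly cannot form in the other —
re-verified by scanning before the pair is returned.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .enzymes import Enzyme
from .seqcore import (
    GAP,
    IUPAC_SETS,
    AllelePair,
    make_allele_pair,
    revcomp,
    scan,
    ungap,
)


class GenerationError(RuntimeError):
    """Planting was impossible for the requested spec."""


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Parameters of one synthetic aligned wild/mutant pair.

    ``n_diff`` counts substitution (SNP) columns; ``indel_len`` adds that
    many insertion columns to the mutant allele (0 = pure SNP pair).
    ``planted_enzyme`` plants its recognition site across the diagnostic
    region of ``planted_allele`` only.
    """

    seed: int
    flank_len: int = 20
    n_diff: int = 1
    indel_len: int = 0
    planted_enzyme: Optional[Enzyme] = None
    planted_allele: str = "wild"

    def __post_init__(self) -> None:
        if self.n_diff < 1:
            raise ValueError("n_diff must be >= 1")
        if self.flank_len < 1 or self.indel_len < 0:
            raise ValueError("flank_len >= 1 and indel_len >= 0 required")
        if self.planted_allele not in ("wild", "mutant"):
            raise ValueError("planted_allele must be 'wild' or 'mutant'")


def _random_flanks(rng: random.Random, n: int) -> tuple[str, str]:
    return (
        "".join(rng.choice("ACGT") for _ in range(n)),
        "".join(rng.choice("ACGT") for _ in range(n)),
    )


def _random_windows(rng: random.Random, spec: SyntheticPairSpec) -> tuple[str, str]:
    wild = []
    mut = []
    for _ in range(spec.n_diff):
        b = rng.choice("ACGT")
        wild.append(b)
        mut.append(rng.choice(sorted(set("ACGT") - {b})))
    wild_win = "".join(wild) + GAP * spec.indel_len
    mut_win = "".join(mut) + "".join(
        rng.choice("ACGT") for _ in range(spec.indel_len)
    )
    return wild_win, mut_win


def _plant(
    rng: random.Random,
    left: str,
    right: str,
    wild_win: str,
    mut_win: str,
    spec: SyntheticPairSpec,
) -> Optional[tuple[str, str, str, str]]:
    """Overwrite the junction so the pattern spans the planted allele's window.

    The site is written with one pattern position over the first window
    column; the other allele gets a window base outside that pattern
    code's set, guaranteeing it cannot match there.
    """
    enz = spec.planted_enzyme
    assert enz is not None
    pat = enz.recognition
    L = len(pat)
    planted_win, other_win = (
        (wild_win, mut_win) if spec.planted_allele == "wild" else (mut_win, wild_win)
    )
    # position of the first window column within the site, i.e. how many
    # pattern bases fall on the left flank
    for k in range(1, L):
        if k > len(left):
            continue
        win_cols = min(len(ungap(planted_win)), L - k)
        tail = L - k - win_cols
        if tail > len(right):
            continue
        diag_code = pat[k]
        blockers = sorted(set("ACGT") - IUPAC_SETS[diag_code])
        if not blockers:
            continue  # pattern accepts everything here; try the next offset
        new_left = left[: len(left) - k] + "".join(
            rng.choice(sorted(IUPAC_SETS[c])) for c in pat[:k]
        )
        p_bases = [rng.choice(sorted(IUPAC_SETS[c])) for c in pat[k : k + win_cols]]
        new_planted = "".join(p_bases) + ungap(planted_win)[win_cols:]
        new_other = rng.choice(blockers) + ungap(other_win)[1:]
        new_right = (
            "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in pat[k + win_cols :])
            + right[tail:]
        )
        # restore alignment gaps
        def regap(template: str, bases: str) -> str:
            out = []
            it = iter(bases)
            for ch in template:
                out.append(GAP if ch == GAP else next(it))
            return "".join(out)

        if spec.planted_allele == "wild":
            w_win, m_win = regap(wild_win, new_planted), regap(mut_win, new_other)
        else:
            w_win, m_win = regap(wild_win, new_other), regap(mut_win, new_planted)
        return new_left, new_right, w_win, m_win
    return None


def _verify_plant(pair: AllelePair, spec: SyntheticPairSpec) -> bool:
    enz = spec.planted_enzyme
    assert enz is not None
    planted_seq = pair.wild_seq if spec.planted_allele == "wild" else pair.mutant_seq
    other_seq = pair.mutant_seq if spec.planted_allele == "wild" else pair.wild_seq
    return bool(scan(enz.recognition, planted_seq)) and not scan(
        enz.recognition, other_seq
    )


def generate_pair(spec: SyntheticPairSpec, max_attempts: int = 200) -> AllelePair:
    """Generate a validated aligned pair from the spec, deterministically.

    With a planted enzyme the result is re-scanned: the recognition site
    must occur in the planted allele and nowhere in the other allele;
    random flanks that spoil this are redrawn.  Raises GenerationError when
    no attempt satisfies the plant.
    """
    rng = random.Random(spec.seed)
    for _ in range(max_attempts):
        left, right = _random_flanks(rng, spec.flank_len)
        wild_win, mut_win = _random_windows(rng, spec)
        if spec.planted_enzyme is not None:
            planted = _plant(rng, left, right, wild_win, mut_win, spec)
            if planted is None:
                raise GenerationError(
                    f"cannot plant {spec.planted_enzyme.name} site with "
                    f"flank_len={spec.flank_len}, n_diff={spec.n_diff}"
                )
            left, right, wild_win, mut_win = planted
        pair = make_allele_pair(left + wild_win + right, left + mut_win + right)
        if spec.planted_enzyme is None or _verify_plant(pair, spec):
            return pair
    raise GenerationError(
        f"no successful plant of {spec.planted_enzyme.name} in "
        f"{max_attempts} attempts (seed {spec.seed})"
    )
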