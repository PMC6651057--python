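"""File I/O: aligned FASTA ingest, enzyme tables, candidate reports."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path
from typing import IO, Iterable, Optional, TextIO, Union

from Bio import SeqIO

from . import __version__
from .design import AssayCandidate, DesignParams
from .enzymes import Enzyme, parse_enzyme_table
from .seqcore import AllelePair, PairValidationError, make_allele_pair

TSV_COLUMNS = [
    "rank",
    "enzyme",
    "recognition",
    "cut_allele",
    "fw_primer",
    "rv_primer",
    "forced_mutations",
    "amplicon_len_wild",
    "amplicon_len_mutant",
    "digest_wild",
    "digest_mutant",
    "offtarget_fixes",
]


def read_allele_pair_fasta(source: Union[str, Path, TextIO]) -> AllelePair:
    """Read an aligned wild/mutant pair from FASTA.

    Exactly two records are required.  By convention the first record is
    the wild allele; records whose IDs are ``wild``/``mutant`` (any case)
    override the ordering.  Gap hyphens are accepted within sequence
    lines.
    """
    records = list(SeqIO.parse(source, "fasta"))
    if len(records) != 2:
        raise PairValidationError(
            f"expected exactly 2 FASTA records, found {len(records)}"
        )
    ids = [r.id.lower() for r in records]
    if "wild" in ids and "mutant" in ids:
        wild = records[ids.index("wild")]
        mutant = records[ids.index("mutant")]
    else:
        wild, mutant = records
    return make_allele_pair(str(wild.seq), str(mutant.seq))


def load_enzyme_table(source: Union[str, Path, TextIO]) -> list[Enzyme]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_enzyme_table(fh)
    return parse_enzyme_table(source)


def _digest_str(cand: AssayCandidate, allele: str) -> str:
    return "/".join(str(f) for f in cand.digests[allele].fragments)


def candidate_record(cand: AssayCandidate, rank: int) -> dict:
    """A flat, serialisable summary of one candidate."""
    return {
        "rank": rank,
        "enzyme": cand.enzyme.name,
        "recognition": cand.enzyme.caret_notation(),
        "commercial": cand.enzyme.commercial,
        "cut_allele": cand.cut_allele,
        "fw_primer": cand.fw_primer,
        "rv_primer": cand.rv_primer,
        "forced_mutations": "; ".join(
            m.brief() for m in cand.discriminating_mutations
        ),
        "offtarget_fixes": "; ".join(m.brief() for m in cand.offtarget_fixes),
        "instantiations": "; ".join(
            f"{'F' if i.primer_side == 'forward' else 'R'}:"
            f"-{i.position_from_3prime} {i.template_code}={i.primer_base}"
            for i in cand.instantiations
        ),
        "amplicon_len_wild": len(cand.amplicons["wild"]),
        "amplicon_len_mutant": len(cand.amplicons["mutant"]),
        "digest_wild": _digest_str(cand, "wild"),
        "digest_mutant": _digest_str(cand, "mutant"),
        "resolvability_gap": cand.resolvability_gap,
        "note": (
            "low levels of undigested background can occur in PCR-RFLP and "
            "should not be read as heterozygosity"
        ),
    }


def write_report(
    candidates: list[AssayCandidate],
    out: TextIO = sys.stdout,
    fmt: str = "tsv",
    params: Optional[DesignParams] = None,
) -> None:
    """Serialise ranked candidates as TSV (default) or JSON.

    The TSV carries a header comment echoing the package version and the
    search parameters; an empty candidate list yields a header-only table.
    """
    records = [candidate_record(c, i + 1) for i, c in enumerate(candidates)]
    if fmt == "json":
        payload = {
            "version": __version__,
            "params": asdict(params) if params is not None else None,
            "candidates": records,
        }
        json.dump(payload, out, indent=2)
        out.write("\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r}")
    out.write(f"# dpacs {__version__}\n")
    if params is not None:
        out.write(f"# params: {asdict(params)}\n")
    out.write("\t".join(TSV_COLUMNS) + "\n")
    for rec in records:
        out.write("\t".join(str(rec[c]) for c in TSV_COLUMNS) + "\n")


def read_report_json(source: Union[str, Path, IO[str]]) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return json.load(fh)
    return json.load(source)
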