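# Methods

## The dPACS design model

A dPACS assay genotypes a known SNP or deletion–insertion polymorphism by
amplifying a short product whose two long primers cover everything except
the diagnostic base(s), then digesting with an enzyme whose recognition
site — engineered through deliberate primer/template mismatches — forms in
exactly one allele. Because the primers tile the whole amplicon, every
non-diagnostic position can be rewritten: both to create the
discriminating site and to erase incidental sites of the same enzyme.

### Region geometry

The input is an aligned wild/mutant pair (equal aligned length, hyphens
for indel columns). Diagnostic columns are those where the two alleles'
IUPAC base *sets* differ; a gap opposite a base counts, and an ambiguity
code differing from its subset (wild `Y` vs mutant `T`) also counts — the
ambiguity may hide the other allele, so the conservative reading treats it
as a difference. The *diagnostic window* is the contiguous column range
from the first to the last diagnostic column; columns inside it that
happen to be equal remain uncovered by primers along with the differing
ones. Validation guarantees non-window columns are never gapped, so the
flanks `F` (left) and `R` (right) are gap-free and identical across
alleles, and an allele's full region reads `F + window(allele) + R`.

Note one consequence: when a codon's two "diagnostic dinucleotide" bases
differ at only one position (psbA `AG`/`GG`, EPSPS `CC`/`TC`), the window
is a single column and the flanking primer reaches one base further than a
design that always excludes both codon bases. The search then reproduces
the published mismatch patterns; amplicon coordinates shift by one base
relative to the published primers, which is why the fixture-level
digestion checks are run on amplicons assembled from the printed primer
strings themselves.

### Candidate construction

For each enzyme (isoschizomers collapsed to one prototype) and each strand
orientation of its recognition pattern, every placement that fits inside
the region and overlaps ≥ 1 diagnostic position is considered (for a
pure-deletion target allele, placements straddling the deletion junction).
Per placement:

1. **Minimal mismatch support.** Window positions are immutable: the
   pattern code must accept *every* base the template allows there, else
   the placement is infeasible. Flank positions already accepted by the
   pattern are left alone; a flank code that merely intersects the pattern
   (e.g. template `Y` under pattern `T`) is *instantiated* — the primer
   pins it to one of the template's own bases, which is not counted as a
   forced mutation; a disjoint code forces a mutation, with the allowed
   bases being those the pattern accepts. Base assignments over the
   support are tried in canonical (alphabetical) order and the first one
   surviving all downstream checks is kept, so the output is exactly what
   exhaustive enumeration would select as minimal.
2. **Discrimination.** With the mismatches written into the shared
   flanks, the *other* allele must not be able to match the pattern at
   this placement under any reading of its ambiguity codes (base-set
   intersection at every position). For indel pairs the placement is
   checked under both the left- and right-anchored alignment of the
   window shift. Mismatches are capped per primer (or jointly, in
   `total` budget mode).
3. **Primer lengths.** Each primer takes the minimum length within
   [`primer_len_min`, `primer_len_max`] that covers the engineered site's
   extent into its flank, the top-strand cut coordinate (one amplicon base
   must remain on each side of the cut), and every rewritten position;
   it grows beyond the minimum only as needed. Insufficient flank or
   required coverage beyond the maximum rejects the candidate.
4. **Off-target elimination.** Both alleles' amplicons are rescanned; any
   cutting site other than the engineered one is an off-target. A greedy
   loop breaks each one with the single primer-coverable base change
   farthest from that primer's 3' end that certainly destroys the site,
   does not touch the diagnostic window or the engineered site, and
   creates no new site for the enzyme in either amplicon (verified by
   rescan after each fix). These fix mutations are tallied separately
   from the discriminating budget under `extra_budget`. An off-target
   overlapping only the window is unfixable and rejects the candidate.
5. **Verification.** Digestion is recomputed from scratch: the target
   amplicon must yield ≥ 2 fragments, the other allele exactly one, and
   the gap between the uncut length and the largest cut fragment must
   reach `min_resolvability`.

### Ranking

Candidates sort by: total forced mismatches (fixes included); then the
nearest mismatch as far as possible from its primer's 3' end (protecting
PCR efficiency); commercially available enzymes before flagged ones; then
the larger cut-vs-uncut gap; then enzyme name, placement and mutation set
as deterministic tie-breaks.

### Digestion conventions

Cut offsets follow REBASE's trailing-offset convention (`GAGTC(4/5)`:
top-strand cut 4 nt past the site); caret notation normalises to the same
form with a symmetric bottom cut. Fragment lengths are always measured
between *top-strand* cut coordinates — this reproduces the published
fragment sizes for blunt, 5'-overhang and offset cutters alike and
resolves the one-base ambiguity of staggered cuts consistently. A site
whose cut coordinate falls outside the open interval of the sequence binds
but does not cut (flagged, excluded from digestion). Digestion is linear
only — PCR products are linear. Site scanning uses subset semantics (a
sequence code matches a pattern code when its base set is contained in the
pattern's), palindromic sites are reported once per location, and
minus-strand sites cut the top strand at the enzyme's bottom-strand
offset.

Heterozygote band patterns are the multiset union of the two homozygote
digests. Two patterns are gel-resolvable when they differ and every band
unique to one pattern lies ≥ `min_delta` nt (default 15) from every band
of the other; bands within one pattern are never required to separate —
the diagnostic contrast on these small high-resolution gels is
cut-versus-uncut, and an internal 42/40 doublet co-migrates harmlessly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `primer_len_min` / `primer_len_max` | 35 / 55 nt | primer-length window: ≥ 35 nt keeps the restricted fragments well clear of the uncut band; ≤ 55 nt avoids extra synthesis-purification cost |
| `budget_fw`, `budget_rv` | 2, 2 | forced-mismatch caps per primer (`budget_mode="total"` pools them) |
| `extra_budget` | 2 | additional mismatches reserved for off-target elimination, tallied separately because elimination is a subsequent step, not part of the discriminating design |
| `min_resolvability` | 15 nt | minimum uncut-vs-largest-fragment gap; no published numeric rule exists for 4% high-resolution agarose, so this is an explicit, overridable default |
| `require_commercial` | true | drop enzymes with no commercial supplier (otherwise retained but ranked below) |
| `detect_allele` | `wild` | which allele the enzyme should cut; `both` runs two searches and can pair non-interfering candidates into single-PCR two-enzyme panels (merged primers re-verified for all four allele × enzyme digests) |

The window-length choice for submissions (how much flank to provide) is
the caller's: the packaged psbA fixture uses the flanks recoverable from
the published primers, and the synthetic generator takes `flank_len` as an
explicit parameter.

## Packaged fixtures

The three published assays ship as fixtures: psbA S264 (PleI cuts the
wild serine allele), ACCase I2041 (EcoRI cuts wild isoleucine) and the
EPSPS P106 four-allele panel (XcmI/XmnI/RsaI/Cac8I for P/S/T/A). Their
amplicons are assembled from the printed primer strings and diagnostic
dinucleotides through the generic builder, and the digestion tests check
the printed fragment sizes with no special-casing. Two in-source
inconsistencies in the published record are handled explicitly:

- the printed psbA forward primer is 41 characters where the text states
  40 bp; fixtures store the printed string verbatim and expose the stated
  length as metadata, and tests avoid the quantities sensitive to that one
  base (full amplicon length and the larger PleI fragment), keeping the
  robust smaller fragment (35 bp);
- the printed XcmI digest (47/35) matches bottom-strand arithmetic on the
  printed primers, while this package's uniform top-strand convention
  gives 48/34; XcmI is therefore covered by the cut-only-its-own-allele
  specificity checks rather than exact fragment sizes.

For psbA the underlying templates are additionally reconstructed by
reverting the two described forced mutations in the printed primers, so
the full search can be replayed end-to-end; for the other two assays the
templates are not fully recoverable and the fixtures are amplicon-level.

## Synthetic generator

`dpacs.synth.generate_pair` emulates a submission: uniform-random concrete
flanks of a chosen length, `n_diff` substitution columns whose alleles are
guaranteed to differ, an optional mutant-side insertion of `indel_len`
bases, and optionally a planted recognition site written across the
junction of one allele with the first diagnostic base of the other allele
set outside the pattern's base set. Generation is a pure function of the
spec (seed included); planted instances are re-scanned before return and
redrawn if the random flanks spoil allele-exclusivity. The generator does
not emulate real templates' base composition, homopolymers, ambiguity
codes or flanking-sequence conservation — passing searches on synthetic
pairs demonstrate combinatorial correctness of the search, not wet-lab
performance of the resulting primers (no melting-temperature, hairpin or
dimer modelling anywhere in the package).

## Verification strategy and problem sizes

Beyond unit tests, the search is checked against an independent
brute-force enumerator that re-derives the region split from the aligned
strings, tries every placement and every substitution assignment over the
recognition span, and filters by first-principles re-implementations of
the match, coverage, digestion and resolvability rules. Equivalence is
asserted as set equality of (enzyme, placement, mutation-set) triples on
randomized instances with 8–16 nt flanks, 1–2 diagnostic columns,
optional 3 nt insertions and per-primer budgets up to 2, against a
four-enzyme table — 200 seeded cases in the acceptance suite (the
enumerator is exponential in budget × span, so small instances are the
honest regime for it; the search itself runs full-size inputs in well
under a second). Substitutions outside the recognition span are not
enumerated by the oracle: they cannot contribute to creating the site, and
off-target elimination — where out-of-span rewrites do act — is exercised
by dedicated planted-site tests with its own single-fix brute-force check.

## Known limitations

- Off-target scanning uses certain-match semantics; a site that is merely
  *possible* through ambiguity codes in a flank is not flagged. (At the
  engineered placement itself the conservative possible-match test is
  used, so discrimination never relies on an ambiguous read.)
- With indels, discrimination is checked at the placement's two natural
  anchorings only; a pattern match arising at a shifted position in the
  other allele surfaces later as an off-target of the verification digest
  rather than at mismatch-derivation time.
- Primer thermodynamics, multiplex design and probe-based assays are out
  of scope; residual undigested background seen in real PCR-RFLP is noted
  in reports but not modelled quantitatively.
- Enzymes with two cleavage positions per strand and nicking enzymes are
  rejected at parse time; methylation sensitivity and buffer
  compatibility are not modelled.
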