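# dpacs

Design of **dPACS** (derived Polymorphic Amplified Cleaved Sequence)
PCR-RFLP genotyping assays for known SNPs and small indels.

## The problem

Genotyping a known point mutation by PCR-RFLP requires a restriction site
that distinguishes the two alleles. When no natural site exists, the
classical dCAPS trick engineers one with mismatches in a primer adjacent
to the SNP — but only one primer is available, and off-target sites
elsewhere in the amplicon cannot be removed. The dPACS strategy instead
amplifies a short (~80–100 bp) product with **two long primers (35–55 nt)
that together cover the entire amplicon except the diagnostic base(s)**.
Every non-diagnostic position is therefore primer-writable: mismatches can
be forced on either or both primers to create an allele-specific site, and
any unwanted site of the same enzyme can be erased the same way. The
approach was developed for herbicide-resistance surveillance in weeds
(psbA S264G, ACCase I2041N, EPSPS P106S/T/A), where flanking sequence is
too variable across species for probe-based assays.

This package implements the full design search as a library and CLI:

- IUPAC-aware degenerate pattern scanning and reverse complement
  (`dpacs.seqcore`);
- a restriction-enzyme model with REBASE-style table parsing (caret
  `G^AATTC` and trailing-offset `GAGTC(4/5)` dialects) and in-silico
  digestion of linear amplicons (`dpacs.enzymes`);
- the search itself — placement enumeration over the diagnostic window,
  minimal forced-mismatch derivation, shortest-covering primer
  construction, off-target detection/elimination, independent verification
  and deterministic ranking (`dpacs.design`);
- genotype band-pattern prediction including heterozygotes, and a gel
  resolvability check (`dpacs.assay`);
- packaged fixtures for the three published assays, a seeded synthetic
  pair generator, and TSV/JSON reports (`dpacs.fixtures`, `dpacs.synth`,
  `dpacs.io`, `dpacs.cli`).

## Model

For an aligned allele pair, let `F` and `R` be the flanks left and right
of the diagnostic window (the columns between the first and last differing
alignment column). The amplicon of allele *a* is

```
amplicon(a) = fw + window(a) + revcomp(rv)
```

where `fw` is a 3'-anchored suffix of `F` and `rv` the reverse complement
of a prefix of `R`, both possibly carrying forced mismatches. A candidate
assay is a triple (enzyme *E*, placement, mismatch set *M*) such that,
writing *M* into the primers, `digest(E, amplicon(target))` yields ≥ 2
fragments through a site overlapping the diagnostic bases, while the other
allele's amplicon stays whole — even under the most cut-favourable reading
of its IUPAC ambiguity codes. Fragment lengths are computed from
top-strand cut positions. Candidates are ranked by (fewest forced
mismatches, mismatches farthest from the 3' ends, commercial enzyme,
largest cut-vs-uncut gap, name).

## Worked example

Replay the published psbA serine-264 design (wild `AG` vs mutant `GG`
diagnostic bases) against the packaged mini enzyme table, with one allowed
mismatch per primer and the published primer lengths:

```
$ dpacs design --alleles pair.fasta --budget-fw 1 --budget-rv 1 \
      --min-primer 41 --max-primer 41 --detect wild
```

Among the eight candidates returned is the enzyme the original assay
chose:

```
rank  enzyme  recognition  cut_allele  forced_mutations    digest_wild  digest_mutant
7     PleI    GAGTC(4/5)   wild        F:-1 T>G; R:-3 A>G  49/34        83
```

PleI needs exactly one forced mutation on each primer — a T→G at the
forward primer's 3'-terminal base and an A→G near the reverse primer's 3'
end — to create its GAGTC site across the junction in the serine allele
only: the wild 83 bp amplicon digests into two fragments while the mutant
allele stays uncut, so homozygotes and heterozygotes separate cleanly on a
high-resolution gel. (Rank 1 goes to SpeI, which manages with a single
mismatch on the forward primer only.)

Digestion and band-pattern prediction are also exposed directly:

```
$ dpacs digest --amplicon <83bp-sequence> --enzyme PleI
84      PleI    49/35
$ dpacs bands --fixture ACCase_I2041 --genotype het
ACCase_I2041    EcoRI   het     92/58/34
```

The heterozygote lane shows the union of the uncut 92 bp fragment and the
wild-allele 58/34 digestion products.

## Documentation

See `docs/methods.md` for the model details, parameter semantics, the
synthetic-data generator, and known limitations.
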