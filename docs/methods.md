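# Methods notes

## Model and assumptions

The package implements duplex-consensus error correction over aligned
paired-end reads. Its central assumption is mechanistic: a *true* mutation
exists in the fragment before any amplification or sequencing, so every
read of the fragment on either strand carries it; a *platform error* is
introduced per read per strand and is (approximately) independent across
reads. Consensus over reads within one strand removes most single-read
errors; requiring agreement *between* the two strand consensuses removes
errors that happened to dominate one strand. The residual error rate of a
dsDCS base therefore scales like the product of per-strand error
probabilities and is far below any per-read rate.

Fragment identity is defined purely by mapped coordinates: all read pairs
with identical (contig, start, end) form one same-position group (SP-G).
Two distinct source fragments with identical endpoints are
indistinguishable and merge; if they disagree at a site the unanimity rule
masks it to N, which costs a little sensitivity and no specificity. No
unique molecular identifiers are modelled.

### Consensus rules

- **Single-strand consensus (default `unanimity`):** a position keeps a
  base only if every *covering* read pair observed that base. Uncovered
  positions and literal `N` base calls are treated as absent observations
  — they do not veto the reads that do cover the position; zero coverage
  gives N. A within-pair conflict (the two mates of one pair overlap
  mid-fragment and disagree) is a positive contradiction and always forces
  N. A `majority` variant (strict plurality, ties → N) is available as a
  config switch.
- **Duplex rule:** both orientation subgroups must have ≥
  `min_pairs_per_strand` members (default 1 — the both-orientations
  requirement itself); the duplex base is the common strand-consensus base
  where both strands agree on a real base, else N.
- Consensus coordinates are inherited from the SP-G key rather than
  re-aligned: simulated reads are born aligned, and re-mapping consensus
  reads is an external-tool concern, not part of the algorithm.

### Counting conventions

Read-base accounting throughout: every non-N dsDCS base at an unmasked
position adds 1 to the denominator of its reference class (G:C or A:T),
and each family covering a site contributes independently. Frequencies are
per 10⁶ base pairs; the overall mutation (OM) frequency is pooled counts
over pooled denominators, not a mean of class frequencies. Sites called in
more than `recurrence_k` (default 2) families are flagged as possible
clonal expansions but never collapsed. Masked positions (BED intervals
expanded half-open; VCF POS converted to 0-based) contribute to neither
numerator nor denominator.

The 96-channel spectrum uses COSMIC conventions: pyrimidine-centred
substitution blocks C>A, C>G, C>T, T>A, T>C, T>G, flanks alphabetical.
Channel denominators are dsDCS read bases whose reference trinucleotide
(strand-folded, 32 bins) matches the channel context; contig-edge bases
lack a context and are excluded from trinucleotide denominators only.
Cosine similarity defaults to per-channel frequencies (a counts option
exists); whether published cross-platform similarities used counts or
frequencies is generally unstated, and for spectra with similar
denominators the two agree closely.

### Signature decomposition

Greedy forward selection: normalise the spectrum to sum 1, repeatedly add
the signature whose inclusion (with a full non-negative least-squares
refit) most reduces residual SSE, stop when the relative improvement drops
below `tol` (1e-3), zero out weights below `weight_cutoff` (0.06), refit
once. This mirrors the published deconstructSigs defaults but is an
independent implementation; numeric parity with that package is not
claimed. NNLS does not itself bound the total weight; when the
unconstrained optimum exceeds 1 the constrained optimum lies on the
boundary, so the fit is repeated with a heavy penalty row enforcing
Σw = 1. Tests verify the result against an exhaustive 0.01-resolution grid
search over the weight simplex for K ≤ 3.

The packaged signature matrix (`data/signatures_synthetic.tsv`) is
synthetic: three constructed columns for mixture tests plus two columns
typed loosely after well-known processes (a C>A "smoking-like" and an
NpCpG C>T "deamination-like" profile). They are stand-ins, not COSMIC
data, and are labelled as such in the file.

## What the simulator emulates — and what it does not

Emulated: normal fragment lengths around a sonication peak; families of
multiple read pairs per strand; single-orientation families; 2×`read_length`
mate geometry with an uncovered inner gap when the fragment is longer than
both reads and overlapping mates (with independent errors, hence possible
conflicts) when shorter; per-substitution per-strand error rates applied in
strand-local coordinates, so strand-asymmetric miscalls (e.g. the elevated
C→G of two-colour chemistry) appear as C→G on one strand's reads and G→C
on the other's; true mutations at per-base-pair class rates, optionally
redistributed over trinucleotide contexts (a site of context c carries
16·w_c times the class rate, so uniform weights reproduce the plain rate).

Not emulated: indels and soft-clips, quality-score variation (a constant
high quality is written), PCR duplicate-structure beyond the configured
reads-per-strand distribution, chimeras, coverage biases, or flowcell
artefacts. A green simulation test therefore establishes the *logic* of
consensus, counting and spectra — not performance on the pathologies of
real libraries.

## Parameter defaults and rationale

| parameter | default | why |
|---|---|---|
| fragment length mean | 350 bp | stated sonication peak of the emulated protocol |
| fragment length sd | 50 bp | typical Covaris spread; not stated anywhere, chosen once |
| read length | 150 bp (100 for the HiSeq-like preset) | 2×150 / 2×100 run formats |
| reads per strand | geometric, mean 2 (min 1) | family-size distributions are unpublished; exposed in config |
| both-strand probability | 0.8 | unpublished; gives a realistic minority of single-orientation families |
| preset error rates | ~1e-4 per substitution per strand (total ~3e-4–1e-3/bp) | the reported raw-platform band of 1e-3–1e-4/bp; NextSeq-like preset carries strand-local C→G at 6e-4 |
| min pairs per strand | 1 | the both-orientations requirement only; higher values in config |
| decomposition tol / cutoff | 1e-3 / 0.06 | the cited package's documented defaults |
| dose-response background | 0.2e-6 per G:C bp | low end of the stated background band (0.2–0.5e-6) |

## Numerical choices

- Sequences are uint8 ASCII arrays; consensus is vectorised per SP-G
  (unanimity via a masked max + equality reduction, with the `?` conflict
  sentinel sorting below 'A' so it can never win and always breaks
  agreement).
- Coordinates are 0-based half-open everywhere; SAM's 1-based POS exists
  only at the pysam boundary. TLEN is signed by leftmost-mate convention
  (read 1 positive on ties).
- Published worked-example statistics are computed in `decimal.Decimal`
  from the printed strings: three of the published 2-dp means sit exactly
  on .5 boundaries (0.225, 0.465, 0.265) where binary floats misround.
  Reported tables round half to even at 2 decimals, the only convention
  reproducing all printed means simultaneously. The cross-platform CV uses
  the sample (n−1) SD over the four per-platform means — verified by
  reproduction of the printed value.
- The t-test is the pooled-variance two-sided Student test with no
  multiplicity correction; zero pooled variance with unequal means raises
  rather than returning an infinite statistic.
- Degenerate frequency cells: zero denominator with a nonzero count is an
  error; zero over zero is reported as 0 with a warning.
- All randomness flows from one `numpy` Generator per simulation; a fixed
  seed fixes every output byte. Run-config hashes exclude the output
  directory, so runs differing only in destination produce identical
  tables.

## Known limitations

- Coordinate-only family identity undercounts when distinct fragments
  collide on endpoints (noticeable on small simulated genomes, negligible
  at mammalian genome scale).
- The caller is the consensus itself: no VAF model, no germline
  genotyping, no indels.
- Published per-platform frequencies come from undeposited sequencing
  data; the package reproduces the statistics derivable from the printed
  tables exactly and validates everything else on synthetic data, so
  platform-specific absolute backgrounds are illustrative presets, not
  calibrated measurements.
- The 300 mg/kg Max−Min range printed in the benchmark study (0.150) is
  not derivable from any combination of its printed per-sample values (the
  printed 300 mg/kg values give 0.36); only the controls range (0.163) is
  reproduced and asserted.
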