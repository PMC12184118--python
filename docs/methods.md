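# Methods

This note documents the models and conventions behind `mampipe`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices that affect results.

## Coordinates and alphabet

All residue coordinates are 1-based with inclusive spans, matching the
field's notation for peptide positions (G53…I65) and cleavage sites
(G20-G21). Sequences use the strict 20-letter alphabet; ambiguity codes
(B, J, O, U, X, Z) are rejected on read unless explicitly allowed, because
motif semantics must be unambiguous (an X can never satisfy a literal).
Delimited tables are auto-detected as tab or comma only; any other dialect
must be named explicitly — silently misparsing a peptide table is worse
than failing.

## Motif engine

Patterns follow the Fuzzpro/PROSITE style: residue literals, alternations
`[T/L]`, wildcard `x`, fixed gaps `x(m)` and variable gaps `x(m,n)`. A
match is a fully resolved alignment — a start position plus one length per
gap element — so the span identity
`end − start + 1 = #literals + Σ gap_lengths` holds by construction.
`scan(mode="all")` enumerates every start and gap assignment (overlaps
included); `mode="canonical"` returns the leftmost start and, within it,
the lexicographically smallest gap vector (shortest gaps first). The
tie-break is a convention: the reference implementation of such scanners
does not define which expansion to report, and shortest-leftmost is
deterministic; for the MAM leader the gap of 11 is forced anyway, because
the V literal only aligns with Val18. The scanner is validated against a
brute-force oracle that expands every gap assignment into a
wildcard-string and tests every offset (tractable for ≤ 3 gap elements and
total gap span ≤ 5; 1000 random sequences in the suite).

One enclosing bracket pair around a whole pattern (`[MMMPANx(8,11)VxGG]`,
the common way these motifs are quoted) is stripped, except where the
content would itself be a plain alternation like `[T/L]`.

## Leader annotation

PCAT substrates are cleaved after a Gly-Gly dipeptide; positions are
counted backwards from the cleavage site, −1 being the last leader residue
(the second G). `annotate_leader` requires the signature motif to match
with its terminal GG ending at or before `max_leader_len` (default 40,
generous against known leader lengths of ~15–25 residues), verifies the
anchored dipeptide really is GG, and evaluates the positional consensus
{−12: I/V/L, −8: E, −7: M/L, −4: V, −2: G, −1: G}. The −12 and −7 sets are
unions over the described Ile/Val and Met/Leu variants of Gram-positive
PCAT substrates; all sets are configurable. When the motif matches at
several starts within range, the leftmost wins and a warning is logged.
Splitting at the site gives leader = 1..gg_start+1 and cargo =
gg_start+2..L, so leader + cargo always reconstructs the input; for MAM
the mature cargo is residues 22–135 (114 aa; a hexamer of it holds 684).

## Peptidomics

Peptides are mapped by exact substring search; every occurrence of a
multi-locus peptide counts toward coverage (coverage is a union statement,
and short repeated words are rare at protein scale). Ile/Leu equivalence
(isobaric residues) is off by default — the MAM peptide set maps exactly
without it — and can only add matches. Coverage presence is the union of
spans; depth additionally sums spectral counts per residue; the
uncovered-prefix length (maximal run of unsupported residues from position
1) is the peptidomic signature of a leader peptide. "Peptides per sample"
means distinct peptide sequences — the unit in which the growth-phase
counts are reported — while spectral counts are used for depth and
ranking only. Identification filtering is two-stage with strict
inequalities: peptide E-value < 0.01, then ≥ 2 distinct peptide sequences
per protein, then protein E-value < 1e-4 when available.

Phase summaries report mean and sample SD (ddof = 1; the convention is not
otherwise pinned down) of replicate counts, per-OD values computed per
replicate before averaging, and each series scaled by its own maximum
(so scaled maxima are exactly 1.0, for plotting counts and OD on one
axis).

## NSAF abundance

`NSAF_ij = (c_ij/L_i) / Σ_k (c_kj/L_k)` per sample; zero-count proteins
keep NSAF 0 and are not dropped (preserves table shape for joins); an
all-zero sample is an error. Fraction-level abundance is the mean NSAF over
that fraction's replicate samples, computed before ranking (mean-then-rank);
proteome percentage is 100 × mean NSAF; ties rank by protein id. Enrichment
between fractions is Welch's unequal-variance two-sided t-test on
per-replicate NSAF values, applied unconditionally rather than gating a
pooled test on a preliminary variance test — the two-step procedure is
unstable at n = 4 and the Welch test is valid under equal variances too.
Shared-peptide (protein-inference) corrections are out of scope.

## Physicochemistry

Average masses come from the standard average residue-mass table plus one
water per chain; cysteines are treated as free. Charged-residue counts are
Asp+Glu and Arg+Lys (His excluded, matching the ProtParam report
convention). The theoretical pI solves Q(pH) = 0 where Q sums
Henderson–Hasselbalch terms over all side chains plus one N-terminal and
one C-terminal group **per chain**; bisection on [0, 14] runs to
floating-point convergence (well past the 0.001 pH tolerance), and the
suite checks |Q(pI)| < 1e-3 against a dense grid scan. Q is strictly
decreasing in pH, so the root is unique. The Bjellqvist pKa set
(ProtParam's, with residue-specific terminal values) is the default; the
EMBOSS set is selectable. Reported pI values are rounded to 2 decimals.
An n-chain homo-oligomer is modelled as disjoint chains: mass and charge
counts scale by n, and because every group count scales uniformly the
oligomer pI equals the monomer pI (asserted to 0.01 in the suite).

## Synthetic generators

All generators draw from a single numpy `default_rng(seed)` in a fixed,
documented order, so identical configs give byte-identical outputs.

**Peptidome.** Emulates nonspecific extracellular degradation of a secreted
protein: no cleavage-site preference is modelled (the simplest model
consistent with the observed randomness of peptide boundaries). Lengths
follow a discrete triangular law on 5–29 with a flat peak at 12–13;
starts are uniform over positions strictly after the protected prefix
(default 21, the leader, which the peptidomics never observes); spectral
counts are 1 + negative-binomial (mean 3, dispersion 1 — small, skewed
counts with occasional high-abundance peptides). Per-replicate expected
distinct-peptide yields default to {6 h: 1.25, 9 h: 2.75, 18 h: 41.25,
25 h: 66.5} with four replicates — the reported growth-phase means — with
realised numbers Poisson around them. The OD curve uses the measured
18-h value (1.6406) and otherwise a typical anaerobe growth curve
(0.05, 0.35, 1.6406, 1.75); published per-OD normalised values depend on
unprinted per-replicate ODs and are therefore never asserted. The
uncovered-prefix estimator is exact as soon as one peptide starts at the
first unprotected residue; at ~500 peptides on a 135-residue substrate
that start is drawn ~5 times in expectation, so the estimate can
occasionally overshoot by a residue or two (about 1 draw in 100) — the
recovery tests use multiple seeds at this scale.

**Count table.** 20 proteins × 2 fractions × 4 replicates by default.
Expected counts scale with protein length — the sampling bias NSAF exists
to undo — times a per-protein lognormal abundance factor (σ = 0.4, a
modest spread among a panel of comparably abundant proteins) times the
baseline mean (30). Counts are negative-binomial with dispersion 10
(≈ 33% replicate CV, typical spectral-count reproducibility). One
designated protein's expectation is multiplied by the enrichment fold
(default 5) in the designated fraction, emulating an envelope-enriched
protein; at these settings the planted protein is the top-ranked NSAF
protein in the enriched fraction in 98/100 seeds and Welch-significant in
96/100.

**Genomes.** Each genome gets background proteins drawn i.i.d. uniform
over the residue alphabet and, with probability `p_both`, one planted
leader-motif protein and one PCAT-motif protein (planted ids recorded as
ground truth). For exactness guarantees the background alphabet can be
restricted (e.g. G-free), making accidental motif hits impossible;
otherwise the planted bookkeeping defines truth. Taxon labels are drawn
per genome with configurable weights (the screen driver uses a 95:5
*Faecalibacterium*:other split to mirror the strong taxon concentration of
leader-motif proteins).

What the generators deliberately do **not** emulate: mass spectra,
retention times, identification error and FDR structure, shared peptides
between proteins, modification variants, or any cleavage-site preference.
Passing the planted-recovery tests therefore shows the estimators are
correct under the stated sampling model, not that real spectra would be
identified correctly upstream.

## Reference inputs and the UniProt-gated targets

The 42-residue N-terminal peptide, the two signature motifs, the consensus
sets and the chain-length bookkeeping are embedded as published constants
and drive the worked examples and acceptance targets. Composition-dependent
values of the full-length protein (hexamer mass 86.9 kDa, mature-hexamer pI
9.35, Asp+Glu 54/42, Arg+Lys 54) require the actual UniProt C7H4X2 record;
`load_reference_protein` reads a cached `data/reference/C7H4X2.fasta` or
fetches it when the network allows. Where the record is unavailable the
corresponding test fails rather than silently passing, and the analysis
driver substitutes a clearly labelled synthetic stand-in for which only
chain/residue bookkeeping is meaningful.

## Problem sizes in the default suite

The test suite runs scanner/oracle equivalence on 1000 random sequences
(≤ 50 aa, ≤ 3 gap elements, total gap span ≤ 5), peptidome recovery at
~500 peptides × 4 protected-prefix values × 5 seeds, length-law GOF at
10,000 draws, and enrichment recovery over 100 seeded tables — a few
seconds in total on one CPU.

## Known limitations

* The motif engine enumerates gap assignments; patterns with many long
  variable gaps grow combinatorially (fine for signature motifs, not for
  profile-scale searches). No PSSM/HMM models.
* NSAF uses raw counts with no protein-inference or shared-peptide
  handling.
* pI/mass treat chains as unmodified and disulfide-free; no
  structure-based electrostatics.
* The co-occurrence screen is desk-scale; it reproduces the logic, not the
  scale, of database-wide searches.
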