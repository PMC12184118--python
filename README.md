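# mampipe

Sequence-level analysis toolkit for the **MAM/PCAT secretion system** of
*Faecalibacterium duncaniae*.

MAM (Microbial Anti-inflammatory Molecule, UniProt C7H4X2) is a 135-residue
protein whose N-terminal 21 residues form a **double-glycine leader
peptide**: the cognate ABC transporter PCAT (UniProt C7H4X1) carries a C39
cysteine peptidase that cleaves immediately after the Gly-Gly dipeptide
(G20-G21) and exports the mature cargo (residues 22-135). `mampipe`
implements the computational analyses by which this system is localised and
characterised from sequence data alone, for proteomics/peptidomics
practitioners:

* **Peptidomics** — map identified peptides onto a reference protein
  (exact search, optional Ile/Leu equivalence), per-residue coverage and
  spectral-count depth, the uncovered-prefix statistic (the leader shows up
  as a run of residues with no peptide evidence), peptide length
  distributions, two-stage identification filtering (peptide E-value < 0.01,
  ≥ 2 distinct peptides per protein, protein E-value < 1e-4), and
  growth-phase summaries (per-replicate distinct-peptide counts, per-OD600
  normalisation, max-scaling).
* **Abundance** — Normalized Spectral Abundance Factor,
  `NSAF_ij = (c_ij / L_i) / Σ_k (c_kj / L_k)`
  for spectral count `c` and protein length `L`, proteome-percentage
  ranking per cell fraction, and Welch-t enrichment tests between fractions
  (e.g. envelope vs cytoplasm).
* **Motif scanning** — a PROSITE/Fuzzpro-style pattern engine (literals,
  alternations `[T/L]`, wildcards `x`, variable gaps `x(8,11)`) that reports
  every start *and* every gap-length assignment; leader annotation anchored
  on the signature motif `MMMPANx(8,11)VxGG` with positional consensus
  scoring (−12 ∈ {I,V,L}, −8 = E, −7 ∈ {M,L}, −4 = V, −2/−1 = GG, counting
  back from the cleavage site); leader/cargo splitting; and a genome
  co-occurrence screen for the MAM and PCAT motifs (`GIE[T/L][V/I]K`).
* **Physicochemistry** — ProtParam-compatible average mass, Asp+Glu /
  Arg+Lys counts and theoretical pI (Bjellqvist or EMBOSS pKa sets,
  bisection on the Henderson–Hasselbalch net charge) for single chains and
  n-chain oligomers, e.g. the putative MAM hexamer.
* **Synthetic data** — generators for degradation peptidomes (protected
  leader prefix, triangular 5–29 length law peaking at 12–13, growth-phase
  yields), fractionation count tables with a planted enriched protein, and
  genome sets with planted motif co-occurrence — every pipeline stage is
  testable against known ground truth without downloads.

## Worked example

The published 42-residue N-terminal peptide of MAM
(`MMMPANYSVIAENEMTYVNGGANFIDAIGAVTAPIWTLDNVK`, identified by LC-MS/MS in
the envelope fraction) is built in, and `reproduce-paper` chains the
desk-scale analyses on it:

```bash
$ mampipe reproduce-paper
{
  "leader_motif": "MMMPANx(8,11)VxGG",
  "gg_start": 20,
  "leader_length": 21,
  "leader": "MMMPANYSVIAENEMTYVNGG",
  "consensus_score": 6,
  "leader_asp_glu_arg_lys": [2, 0],
  "coverage_tiling_22_135": 0.8444,
  "hexamer_fl_residues": 810,
  "hexamer_dlp_residues": 684
}
```

Reading: the leader motif matches once, with the forced gap assignment
(11, 1), placing the Gly-Gly at positions 20–21; the leader is therefore
21 residues and scores 6/6 on the PCAT-substrate consensus. Peptides
tiling the cargo (22–135) cover 114/135 = 84.4% of the protein, leaving
exactly the leader uncovered. Hexamers of the full-length and mature
chains contain 6×135 = 810 and 6×114 = 684 residues.

The `analysis/` drivers run the same operations as a narrative pipeline on
synthetic data (each prints what it found and writes tables under
`results/`):

```bash
$ python analysis/01_simulate_peptidome.py --seed 1   # growth-phase peptidome
$ python analysis/02_coverage_and_phases.py
coverage: 83.7% of 135 residues; uncovered prefix = 22 aa (the leader)
peptide lengths 6-28, modal length(s) [13]
distinct peptides per phase (mean, scaled):
        mean_peptides  scaled_peptides
time_h
6.0               1.5            0.022
9.0               4.5            0.066
18.0             43.0            0.628
25.0             68.5            1.000
$ python analysis/03_abundance_nsaf.py --seed 1       # NSAF + enrichment
$ python analysis/04_motif_screen.py --seed 1         # leader + genome screen
$ python analysis/05_physchem_hexamers.py             # hexamer profiles
```

(At this seed the ~480-peptide draw happens to leave position 22 uncovered
too, so the uncovered-prefix estimate overshoots the planted 21 by one —
the estimator is exact once a peptide starts at the first cargo residue,
which is the typical case; see `docs/methods.md`.)

Every subcommand is also available directly (`mampipe scan`,
`annotate-leader`, `screen`, `map-peptides`, `coverage`, `phase-summary`,
`nsaf`, `enrich`, `physchem`, `simulate ...`); run `mampipe --help`.

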