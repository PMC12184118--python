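"""Published reference inputs for the MAM/PCAT system of *F. duncaniae*.

MAM (Microbial Anti-inflammatory Molecule, UniProt C7H4X2) is a 135-residue
protein whose first 21 residues form a double-glycine leader peptide; its
cognate exporter PCAT (UniProt C7H4X1) is an ABC transporter fused to a C39
cysteine peptidase that cleaves after the Gly-Gly site. The constants here
are sequence-level facts usable without any download: the LC-MS/MS-identified
42-residue N-terminal peptide, the two signature motifs, and the positional
consensus of Gram-positive PCAT leader peptides.
"""

from __future__ import annotations

#: UniProt accessions for the two reference proteins.
MAM_ACCESSION = "C7H4X2"
PCAT_ACCESSION = "C7H4X1"

#: The 42-residue N-terminal peptide of MAM identified in the envelope
#: fraction (one spectrum, E-value 4.5e-9). Residues 1-21 are the leader
#: (ending in G20 G21), residues 22-42 the start of the cargo.
MAM_NTERM_42 = "MMMPANYSVIAENEMTYVNGGANFIDAIGAVTAPIWTLDNVK"

#: Signature motif of the MAM leader peptide (PROSITE-style text).
LEADER_MOTIF_TEXT = "MMMPANx(8,11)VxGG"

#: Signature motif of the PCAT peptidase domain.
PCAT_MOTIF_TEXT = "GIE[T/L][V/I]K"

#: Full-length and mature (leader-excised) chain lengths, residues.
MAM_LENGTH = 135
MAM_LEADER_LENGTH = 21
MAM_CARGO_LENGTH = MAM_LENGTH - MAM_LEADER_LENGTH  # 114
#: 1-based span of the mature cargo on the full-length chain.
MAM_CARGO_SPAN = (22, 135)

#: Positional consensus of PCAT-substrate leader peptides, indexed from the
#: cleavage site: -1 is the last leader residue (the second glycine).
#: -12 admits Ile/Val/Leu and -7 Met/Leu, covering the described variants.
LEADER_CONSENSUS: dict[int, frozenset[str]] = {
    -12: frozenset("IVL"),
    -8: frozenset("E"),
    -7: frozenset("ML"),
    -4: frozenset("V"),
    -2: frozenset("G"),
    -1: frozenset("G"),
}

#: Highest-abundance supernatant peptides with their 1-based spans on MAM
#: and summed spectral counts (from the growth-phase peptidomics).
TOP_SUPERNATANT_PEPTIDES = (
    ("GNTFLQSTINRTI", 53, 65, 28),
    ("AAVYNLGVAPTKNTVKETEVKFTV", 112, 135, 25),
    ("VGNTFLQSTINRTI", 52, 65, 20),
)

#: Mean +/- SD distinct supernatant peptides per growth time point
#: (four biological replicates; exponential 6/9 h, stationary 18/25 h).
PHASE_PEPTIDE_MEANS = {6.0: 1.25, 9.0: 2.75, 18.0: 41.25, 25.0: 66.5}
PHASE_PEPTIDE_SDS = {6.0: 0.96, 9.0: 0.50, 18.0: 3.50, 25.0: 2.38}

#: Culture density at early stationary phase (18 h), OD600.
OD600_18H = 1.6406
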