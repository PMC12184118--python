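"""Double-glycine leader-peptide annotation and leader/cargo splitting.

PCAT substrates carry an N-terminal leader peptide that ends in a Gly-Gly
dipeptide; the C39 peptidase of the transporter cleaves immediately after
the second glycine, so positions are counted backwards from the cleavage
site: -1 is the last leader residue (the second G), -2 the first G, and so
on. Annotation anchors on the leader signature motif, verifies the GG, and
scores the positional consensus of Gram-positive PCAT substrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from . import reference
from .io_formats import ProteinRecord
from .motifs import Gap, MotifMatch, SequenceMotif, parse_pattern, scan

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeaderAnnotation:
    """A located leader peptide on a protein.

    ``gg_start`` is the 1-based position of the first glycine of the GG
    dipeptide; the leader spans residues 1..gg_start+1 and the cargo starts
    at gg_start+2. ``consensus_checks`` maps each consensus position (-12,
    -8, -7, -4, -2, -1; -1 = last leader residue) to whether the residue
    there belongs to the expected set.
    """

    protein_id: str
    gg_start: int
    leader_span: tuple[int, int]
    cargo_span: tuple[int, int]
    consensus_checks: dict[int, bool]
    motif_match: MotifMatch

    @property
    def leader_length(self) -> int:
        return self.leader_span[1]

    @property
    def consensus_score(self) -> int:
        return sum(self.consensus_checks.values())


def default_leader_motif() -> SequenceMotif:
    """The MAM leader signature motif, MMMPANx(8,11)VxGG."""
    return parse_pattern(reference.LEADER_MOTIF_TEXT)


def annotate_leader(
    protein: ProteinRecord,
    motif: SequenceMotif | None = None,
    max_leader_len: int = 40,
    consensus: Mapping[int, frozenset[str]] = reference.LEADER_CONSENSUS,
) -> LeaderAnnotation | None:
    """Annotate the double-glycine leader of ``protein``, if present.

    The leader motif must match with its terminal GG ending at a position
    <= ``max_leader_len``; among qualifying matches the leftmost start wins
    and, within it, the shortest gap assignment. Returns None when the motif
    does not match in range or the anchored dipeptide is not Gly-Gly.
    """
    if max_leader_len < 4:
        raise ValueError("max_leader_len must be >= 4")
    motif = motif or default_leader_motif()
    candidates = [m for m in scan(motif, protein, mode="all")
                  if m.end <= max_leader_len]
    if not candidates:
        return None
    best = min(candidates, key=lambda m: (m.start, m.gap_lengths))
    if len({m.start for m in candidates}) > 1:
        log.warning(
            "%s: leader motif matches at %d starts within the first %d "
            "residues; using leftmost", protein.id,
            len({m.start for m in candidates}), max_leader_len)
    gg_start = best.end - 1
    seq = protein.sequence
    if seq[gg_start - 1] != "G" or seq[gg_start] != "G":
        return None
    leader_end = gg_start + 1
    checks = {
        pos: (leader_end + pos >= 0
              and seq[leader_end + pos] in allowed)
        for pos, allowed in sorted(consensus.items())
    }
    return LeaderAnnotation(
        protein_id=protein.id,
        gg_start=gg_start,
        leader_span=(1, leader_end),
        cargo_span=(leader_end + 1, len(seq)),
        consensus_checks=checks,
        motif_match=best,
    )


def split_leader_cargo(
    protein: ProteinRecord, annotation: LeaderAnnotation
) -> tuple[str, str]:
    """Split the sequence into (leader, cargo) at the annotated GG site.

    The concatenation of the two parts always reproduces the input; the
    cargo is empty when the protein ends at its leader.
    """
    seq = protein.sequence
    end = annotation.leader_span[1]
    if end > len(seq) or seq[annotation.gg_start - 1:end] != "GG":
        raise ValueError(
            f"annotation (GG at {annotation.gg_start}) inconsistent with "
            f"sequence of {protein.id!r}")
    return seq[:end], seq[end:]
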