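"""Genome co-occurrence screen for the MAM and PCAT signature motifs.

Given protein sets grouped by genome, flags each genome for presence of a
leader-motif (MAM-like) protein and a PCAT-motif protein, and summarises
how motif-positive proteins distribute over taxa — the desk-scale analogue
of screening a sequence database for genomes that carry both partners.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

from .io_formats import ProteinRecord
from .motifs import SequenceMotif, scan


@dataclass(frozen=True)
class GenomeFlags:
    genome_id: str
    has_mam_motif: bool
    has_pcat_motif: bool

    @property
    def has_both(self) -> bool:
        return self.has_mam_motif and self.has_pcat_motif


@dataclass(frozen=True)
class CooccurrenceReport:
    """Per-genome motif flags plus the headline counts of the screen."""

    genomes: tuple[GenomeFlags, ...]
    n_mam_proteins: int
    n_pcat_proteins: int
    n_genomes_with_both: int
    #: fraction of MAM-motif-positive proteins per taxon (sums to 1 when any)
    taxon_fraction: dict[str, float]
    mam_positive_ids: tuple[str, ...]
    pcat_positive_ids: tuple[str, ...]

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


def cooccurrence_screen(
    proteins: Iterable[ProteinRecord],
    mam_motif: SequenceMotif,
    pcat_motif: SequenceMotif,
) -> CooccurrenceReport:
    """Screen genome-grouped proteins for co-occurrence of the two motifs.

    A protein counts once however many times a motif matches it. Proteins
    without a taxon label are pooled under "unassigned". Raises ValueError
    on empty input.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein set")
    missing = [p.id for p in proteins if p.genome_id is None]
    if missing:
        raise ValueError(
            f"proteins without genome_id: {missing[:3]}{'...' if len(missing) > 3 else ''}")

    by_genome: dict[str, list[ProteinRecord]] = defaultdict(list)
    for p in proteins:
        by_genome[p.genome_id].append(p)

    mam_ids: list[str] = []
    pcat_ids: list[str] = []
    flags: list[GenomeFlags] = []
    taxon_counts: Counter[str] = Counter()
    for genome_id in sorted(by_genome):
        has_mam = has_pcat = False
        for p in by_genome[genome_id]:
            if scan(mam_motif, p, mode="canonical"):
                has_mam = True
                mam_ids.append(p.id)
                taxon_counts[p.taxon or "unassigned"] += 1
            if scan(pcat_motif, p, mode="canonical"):
                has_pcat = True
                pcat_ids.append(p.id)
        flags.append(GenomeFlags(genome_id, has_mam, has_pcat))

    total_mam = len(mam_ids)
    taxon_fraction = {t: c / total_mam for t, c in sorted(taxon_counts.items())} \
        if total_mam else {}
    return CooccurrenceReport(
        genomes=tuple(flags),
        n_mam_proteins=total_mam,
        n_pcat_proteins=len(pcat_ids),
        n_genomes_with_both=sum(f.has_both for f in flags),
        taxon_fraction=taxon_fraction,
        mam_positive_ids=tuple(mam_ids),
        pcat_positive_ids=tuple(pcat_ids),
    )
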