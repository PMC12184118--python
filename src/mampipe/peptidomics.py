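"""Peptide-to-protein mapping, coverage and growth-phase summaries.

Identified peptides (nonspecific degradation products here, not tryptic
digests) are mapped back onto a reference protein by exact substring search,
optionally treating Ile and Leu as indistinguishable, as they are by mass.
Coverage is a union-of-spans statement per residue; depth additionally
weights residues by spectral counts. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeptideObservation, ProteinRecord, SampleMetadata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideMatch:
    """One exact occurrence of an identified peptide on a protein."""

    peptide: str
    start: int
    end: int
    spectral_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"span {self.start}..{self.end} does not fit peptide of "
                f"length {len(self.peptide)}")


@dataclass
class CoverageMap:
    """Per-residue evidence over one protein.

    ``presence[i]`` is True when residue i+1 lies in at least one mapped
    peptide; ``depth[i]`` sums spectral counts of all peptides covering it.
    """

    protein_id: str
    length: int
    depth: np.ndarray
    presence: np.ndarray

    @property
    def covered_fraction(self) -> float:
        return float(self.presence.sum()) / self.length

    @property
    def uncovered_prefix_len(self) -> int:
        covered = np.flatnonzero(self.presence)
        return int(covered[0]) if covered.size else self.length


def apply_identification_filters(
    observations_by_protein: Mapping[str, Sequence[PeptideObservation]],
    peptide_evalue_max: float = 0.01,
    min_peptides: int = 2,
    protein_evalue_max: float | None = 1e-4,
    protein_evalues: Mapping[str, float] | None = None,
) -> dict[str, list[PeptideObservation]]:
    """Apply the two-stage identification filter.

    Peptides with E-value >= ``peptide_evalue_max`` are removed (strict <);
    proteins left with fewer than ``min_peptides`` distinct peptide
    sequences are dropped entirely; when per-protein E-values are supplied,
    proteins at or above ``protein_evalue_max`` are dropped too.
    """
    out: dict[str, list[PeptideObservation]] = {}
    for protein_id, obs in observations_by_protein.items():
        if protein_evalues is not None and protein_evalue_max is not None:
            pe = protein_evalues.get(protein_id)
            if pe is None:
                raise ValueError(f"no protein E-value for {protein_id!r}")
            if not pe < protein_evalue_max:
                continue
        kept = []
        for o in obs:
            if o.evalue is None:
                raise ValueError(
                    f"peptide {o.peptide!r} of {protein_id!r} has no E-value; "
                    "cannot apply the peptide E-value filter")
            if o.evalue < peptide_evalue_max:
                kept.append(o)
        if len({o.peptide for o in kept}) >= min_peptides:
            out[protein_id] = kept
    return out


def _il_fold(seq: str) -> str:
    return seq.replace("I", "L")


def find_occurrences(peptide: str, protein_seq: str, il_equivalent: bool = False) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence."""
    hay = _il_fold(protein_seq) if il_equivalent else protein_seq
    needle = _il_fold(peptide) if il_equivalent else peptide
    starts, i = [], hay.find(needle)
    while i != -1:
        starts.append(i + 1)
        i = hay.find(needle, i + 1)
    return starts


def map_peptides(
    peptides: Iterable[PeptideObservation],
    protein: ProteinRecord,
    il_equivalent: bool = False,
) -> tuple[list[PeptideMatch], list[PeptideObservation]]:
    """Map observations onto ``protein`` by exact (overlap-allowing) search.

    Returns (matches, unmapped). Every occurrence of a multi-locus peptide
    is reported; with ``il_equivalent`` Ile and Leu are interchangeable
    during matching (the reported peptide keeps its observed sequence).
    """
    matches: list[PeptideMatch] = []
    unmapped: list[PeptideObservation] = []
    for obs in peptides:
        starts = find_occurrences(obs.peptide, protein.sequence, il_equivalent)
        if not starts:
            unmapped.append(obs)
            continue
        for s in starts:
            matches.append(PeptideMatch(
                peptide=obs.peptide, start=s, end=s + len(obs.peptide) - 1,
                spectral_count=obs.spectral_count, sample_id=obs.sample_id,
            ))
    if unmapped:
        log.warning("%d peptide observation(s) did not map onto %s",
                    len(unmapped), protein.id)
    return matches, unmapped


def coverage(matches: Iterable[PeptideMatch], protein: ProteinRecord) -> CoverageMap:
    """Per-residue presence and spectral-count-weighted depth."""
    L = len(protein)
    depth = np.zeros(L, dtype=np.int64)
    presence = np.zeros(L, dtype=bool)
    for m in matches:
        if m.start < 1 or m.end > L:
            raise ValueError(
                f"match {m.peptide!r} at {m.start}..{m.end} out of bounds "
                f"for {protein.id!r} (length {L})")
        depth[m.start - 1:m.end] += m.spectral_count
        presence[m.start - 1:m.end] = True
    return CoverageMap(protein_id=protein.id, length=L,
                       depth=depth, presence=presence)


def length_distribution(
    peptides: Iterable[str | PeptideObservation],
) -> tuple[dict[int, int], int, int, list[int]]:
    """Length histogram over distinct peptide sequences.

    Returns (counts per length, min, max, modes); all tied modal lengths
    are reported. Raises ValueError on empty input.
    """
    seqs = {p.peptide if isinstance(p, PeptideObservation) else p
            for p in peptides}
    if not seqs:
        raise ValueError("no peptides")
    hist = Counter(len(s) for s in seqs)
    top = max(hist.values())
    modes = sorted(l for l, c in hist.items() if c == top)
    return dict(sorted(hist.items())), min(hist), max(hist), modes


def top_peptides(
    observations: Iterable[PeptideObservation], k: int = 10
) -> list[tuple[str, int]]:
    """Distinct peptides ranked by total spectral count over all samples.

    Ties are broken by lexicographic sequence order so the ranking is
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals: Counter[str] = Counter()
    for o in observations:
        totals[o.peptide] += o.spectral_count
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def peptides_per_sample(
    observations: Iterable[PeptideObservation],
) -> dict[str, int]:
    """Distinct peptide sequences per sample (the per-sample 'peptide count')."""
    seen: dict[str, set[str]] = defaultdict(set)
    for o in observations:
        seen[o.sample_id].add(o.peptide)
    return {s: len(v) for s, v in seen.items()}


def phase_summary(
    sample_counts: Mapping[str, int],
    metadata: Sequence[SampleMetadata],
    per_od: bool = True,
) -> pd.DataFrame:
    """Growth-phase summary of per-sample distinct-peptide counts.

    For each time point: mean and sample SD (n-1) of the replicate counts,
    the same for counts divided per-replicate by OD600 (when ``per_od``),
    and max-scaled series (each series divided by its own maximum, so the
    scaled maxima are exactly 1). Samples missing from ``sample_counts``
    count as 0 peptides. Returns a DataFrame indexed by time_h.
    """
    by_time: dict[float, list[SampleMetadata]] = defaultdict(list)
    for m in metadata:
        by_time[m.time_h].append(m)

    rows = []
    for t in sorted(by_time):
        reps = by_time[t]
        counts = np.array([sample_counts.get(m.sample_id, 0) for m in reps],
                          dtype=float)
        row = {
            "time_h": t,
            "n_replicates": len(reps),
            "mean_peptides": counts.mean(),
            "sd_peptides": counts.std(ddof=1) if len(reps) > 1 else 0.0,
            "mean_od": np.mean([m.od600 for m in reps]),
        }
        if per_od:
            ratios = np.array([sample_counts.get(m.sample_id, 0) / m.od600
                               for m in reps])
            row["per_od_mean"] = ratios.mean()
            row["per_od_sd"] = ratios.std(ddof=1) if len(reps) > 1 else 0.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("time_h")
    for col in ("mean_peptides", "mean_od") + (("per_od_mean",) if per_od else ()):
        peak = df[col].max()
        df[f"scaled_{col.replace('mean_', '').replace('_mean', '')}"] = (
            df[col] / peak if peak > 0 else 0.0)
    return df
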