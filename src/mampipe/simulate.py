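"""Synthetic peptidomes, spectral-count tables and genome sets.

Every generator mirrors a feature of the study system so downstream
operations can be tested against planted ground truth:

* ``simulate_peptidome`` — nonspecific degradation of a secreted protein:
  peptide lengths 5-29 with modal lengths 12-13 (triangular law), starts
  uniform over the cargo region (the leader prefix is never sampled),
  spectral counts negative-binomial, and per-replicate peptide yields that
  rise from exponential to stationary phase.
* ``simulate_count_table`` — protein x sample spectral counts over two or
  more cell fractions with one designated envelope-enriched protein.
* ``simulate_genomes`` — background protein sets in which a fraction of
  genomes carries both a leader-motif protein and a PCAT-motif protein.

All sampling comes from a single numpy Generator seeded per call, drawn in
a fixed documented order, so identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, PeptideObservation, ProteinRecord, \
    SampleMetadata, SpectralCountTable
import pandas as pd

_ALPHABET = "".join(sorted(AMINO_ACIDS))

#: Expected distinct peptides per replicate at each sampling time (h),
#: rising from exponential (6, 9 h) to late stationary phase (25 h).
DEFAULT_PHASE_YIELD: dict[float, float] = {6.0: 1.25, 9.0: 2.75,
                                           18.0: 41.25, 25.0: 66.5}

#: Culture OD600 at each sampling time. 18 h is the measured early
#: stationary value; the others follow a typical anaerobe growth curve.
DEFAULT_OD_CURVE: dict[float, float] = {6.0: 0.05, 9.0: 0.35,
                                        18.0: 1.6406, 25.0: 1.75}


def triangular_length_law(
    len_min: int = 5, len_max: int = 29,
    mode_lo: int = 12, mode_hi: int = 13,
) -> dict[int, float]:
    """Discrete triangular length distribution with a flat two-length peak.

    Weights rise linearly from ``len_min`` to ``mode_lo``, stay equal over
    the modal lengths, and fall linearly to ``len_max``; normalised to 1.
    """
    if not len_min <= mode_lo <= mode_hi <= len_max:
        raise ValueError("need len_min <= mode_lo <= mode_hi <= len_max")
    peak = float(mode_lo - len_min + 1)
    w: dict[int, float] = {}
    for l in range(len_min, len_max + 1):
        if l < mode_lo:
            w[l] = l - len_min + 1
        elif l <= mode_hi:
            w[l] = peak
        else:
            w[l] = peak * (len_max - l + 1) / (len_max - mode_hi + 1)
    total = sum(w.values())
    return {l: v / total for l, v in w.items()}


@dataclass
class PeptidomeConfig:
    """Conditions for one synthetic degradation-peptidome experiment."""

    protein: ProteinRecord
    protected_prefix_len: int = 21
    n_peptides: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_YIELD))
    length_law: Mapping[int, float] = field(
        default_factory=triangular_length_law)
    count_mean: float = 3.0
    count_dispersion: float = 1.0
    od_curve: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_OD_CURVE))
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.protein.sequence)
        if not 0 <= self.protected_prefix_len < L:
            raise ValueError("protected_prefix_len must be in [0, protein length)")
        if min(self.length_law) < 1:
            raise ValueError("peptide lengths must be >= 1")
        if abs(sum(self.length_law.values()) - 1.0) > 1e-9:
            raise ValueError("length_law probabilities must sum to 1")
        if min(self.length_law) > L - self.protected_prefix_len:
            raise ValueError(
                "minimum peptide length exceeds the unprotected region")
        missing = set(self.n_peptides) - set(self.od_curve)
        if missing:
            raise ValueError(f"od_curve missing time points {sorted(missing)}")


@dataclass(frozen=True)
class PeptidomeGroundTruth:
    protected_prefix_len: int
    length_law: dict[int, float]
    expected_yield: dict[float, float]
    realized_counts: dict[tuple[float, str], int]  # (time_h, replicate) -> n


def simulate_peptidome(
    config: PeptidomeConfig,
) -> tuple[list[PeptideObservation], list[SampleMetadata], PeptidomeGroundTruth]:
    """Draw a degradation peptidome with a protected leader prefix.

    For each (time, replicate) the number of draws is Poisson with the
    configured per-replicate yield. Each draw samples a length from the
    length law (resampling lengths infeasible for the unprotected region),
    then a start uniform over {protected_prefix_len+1, ..., L-length+1},
    then a spectral count 1 + NB(dispersion, mean-1). No peptide ever
    overlaps the protected prefix.
    """
    rng = np.random.default_rng(config.seed)
    seq = config.protein.sequence
    L = len(seq)
    lengths = np.array(sorted(config.length_law))
    probs = np.array([config.length_law[l] for l in lengths])
    feasible = lengths <= L - config.protected_prefix_len

    observations: list[PeptideObservation] = []
    metadata: list[SampleMetadata] = []
    realized: dict[tuple[float, str], int] = {}
    for t in sorted(config.n_peptides):
        for r in range(1, config.n_replicates + 1):
            rep = f"r{r}"
            sample_id = f"t{t:g}_{rep}"
            metadata.append(SampleMetadata(
                sample_id=sample_id, time_h=t, od600=config.od_curve[t],
                replicate=rep, fraction="supernatant"))
            n = int(rng.poisson(config.n_peptides[t]))
            realized[(t, rep)] = n
            for _ in range(n):
                while True:
                    length = int(rng.choice(lengths, p=probs))
                    if feasible[np.searchsorted(lengths, length)]:
                        break
                start = int(rng.integers(config.protected_prefix_len + 1,
                                         L - length + 2))
                count = 1 + _negative_binomial(
                    rng, max(config.count_mean - 1.0, 1e-9),
                    config.count_dispersion)
                observations.append(PeptideObservation(
                    peptide=seq[start - 1:start + length - 1],
                    spectral_count=count, sample_id=sample_id, time_h=t,
                    replicate=rep, fraction="supernatant",
                    protein_id=config.protein.id,
                ))
    truth = PeptidomeGroundTruth(
        protected_prefix_len=config.protected_prefix_len,
        length_law=dict(config.length_law),
        expected_yield=dict(config.n_peptides),
        realized_counts=realized,
    )
    return observations, metadata, truth


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """NB draw parameterised by mean and dispersion r (variance = m + m^2/r)."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


@dataclass
class CountTableConfig:
    """Conditions for a synthetic fractionation spectral-count table."""

    n_proteins: int = 20
    length_range: tuple[int, int] = (100, 600)
    enriched_protein_index: int = 0
    enrichment_fold: float = 5.0
    enriched_fraction: str = "envelope"
    fractions: Sequence[str] = ("envelope", "cytoplasm")
    n_replicates: int = 4
    baseline_mean: float = 30.0
    dispersion: float = 10.0
    abundance_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.enriched_protein_index < self.n_proteins:
            raise ValueError("enriched_protein_index out of range")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.enriched_fraction not in self.fractions:
            raise ValueError("enriched_fraction not among fractions")


@dataclass(frozen=True)
class CountTableGroundTruth:
    enriched_protein_id: str
    enriched_fraction: str
    enrichment_fold: float
    baseline_abundance: dict[str, float]


def simulate_count_table(
    config: CountTableConfig,
) -> tuple[SpectralCountTable, CountTableGroundTruth]:
    """Draw a protein x sample count table with one enriched protein.

    Sampling order: protein lengths, per-protein lognormal abundance
    factors, then counts protein-major / sample-minor. Expected counts
    scale with protein length (longer proteins yield more peptide spectra
    — the sampling bias NSAF exists to undo), so a protein's expected NSAF
    reflects its abundance factor alone. The designated protein's expected
    count is multiplied by ``enrichment_fold`` in the enriched fraction
    only.
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"P{i:03d}" for i in range(config.n_proteins)]
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1,
                           size=config.n_proteins)
    abund = np.exp(rng.normal(0.0, config.abundance_sigma,
                              size=config.n_proteins))
    mean_length = 0.5 * (config.length_range[0] + config.length_range[1])
    samples = [f"{f}_r{j}" for f in config.fractions
               for j in range(1, config.n_replicates + 1)]
    fractions = {s: s.rsplit("_", 1)[0] for s in samples}
    counts = np.zeros((config.n_proteins, len(samples)), dtype=int)
    for i in range(config.n_proteins):
        for j, s in enumerate(samples):
            mean = config.baseline_mean * abund[i] * lengths[i] / mean_length
            if (i == config.enriched_protein_index
                    and fractions[s] == config.enriched_fraction):
                mean *= config.enrichment_fold
            counts[i, j] = _negative_binomial(rng, mean, config.dispersion)
    table = SpectralCountTable(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="protein_id"),
                            columns=samples),
        lengths=pd.Series(lengths, index=pd.Index(ids, name="protein_id"),
                          name="length"),
        fractions=fractions,
    )
    truth = CountTableGroundTruth(
        enriched_protein_id=ids[config.enriched_protein_index],
        enriched_fraction=config.enriched_fraction,
        enrichment_fold=config.enrichment_fold,
        baseline_abundance=dict(zip(ids, abund.tolist())),
    )
    return table, truth


@dataclass(frozen=True)
class GenomeGroundTruth:
    #: genome_id -> (planted MAM-like protein id, planted PCAT protein id)
    planted: dict[str, tuple[str, str]]
    taxa: dict[str, str]


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def simulate_genomes(
    n_genomes: int,
    p_both: float = 0.5,
    taxon_labels: Sequence[str] = ("Faecalibacterium", "other"),
    seed: int = 0,
    *,
    taxon_weights: Sequence[float] | None = None,
    n_background: int = 5,
    background_length: tuple[int, int] = (80, 300),
    background_alphabet: str = _ALPHABET,
) -> tuple[list[ProteinRecord], GenomeGroundTruth]:
    """Generate genome protein sets with planted motif co-occurrence.

    Each genome receives ``n_background`` random background proteins and,
    with probability ``p_both``, one planted protein matching the MAM
    leader motif plus one matching the PCAT motif. Use a restricted
    ``background_alphabet`` (e.g. without G) to make accidental background
    matches impossible when a p_both=0 guarantee is needed.
    """
    if not 0 <= p_both <= 1:
        raise ValueError("p_both must be in [0, 1]")
    rng = np.random.default_rng(seed)
    weights = (np.full(len(taxon_labels), 1.0 / len(taxon_labels))
               if taxon_weights is None
               else np.asarray(taxon_weights, dtype=float) / np.sum(taxon_weights))
    proteins: list[ProteinRecord] = []
    planted: dict[str, tuple[str, str]] = {}
    taxa: dict[str, str] = {}
    lo, hi = background_length
    for g in range(n_genomes):
        genome_id = f"genome{g:03d}"
        taxon = str(rng.choice(list(taxon_labels), p=weights))
        taxa[genome_id] = taxon
        for b in range(n_background):
            proteins.append(ProteinRecord(
                id=f"{genome_id}_bg{b}",
                sequence=_random_seq(rng, int(rng.integers(lo, hi + 1)),
                                     background_alphabet),
                genome_id=genome_id, taxon=taxon))
        if rng.random() < p_both:
            gap = int(rng.integers(8, 12))
            mam_seq = ("MMMPAN" + _random_seq(rng, gap, _ALPHABET)
                       + "V" + _random_seq(rng, 1, _ALPHABET) + "GG"
                       + _random_seq(rng, 100, _ALPHABET))
            pcat_core = ("GIE" + str(rng.choice(["T", "L"]))
                         + str(rng.choice(["V", "I"])) + "K")
            flank_n = int(rng.integers(50, 150))
            pcat_seq = (_random_seq(rng, flank_n, _ALPHABET) + pcat_core
                        + _random_seq(rng, 100, _ALPHABET))
            mam_id = f"{genome_id}_mam"
            pcat_id = f"{genome_id}_pcat"
            proteins.append(ProteinRecord(id=mam_id, sequence=mam_seq,
                                          genome_id=genome_id, taxon=taxon))
            proteins.append(ProteinRecord(id=pcat_id, sequence=pcat_seq,
                                          genome_id=genome_id, taxon=taxon))
            planted[genome_id] = (mam_id, pcat_id)
    return proteins, GenomeGroundTruth(planted=planted, taxa=taxa)
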