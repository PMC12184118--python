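"""Readers and writers for the external formats the pipeline touches.

Sequences travel as FASTA (via Biopython), peptide/count/metadata tables as
tab- or comma-delimited text (via pandas), run configuration as YAML or JSON.
Every reader validates on ingest and raises :class:`FormatError` with a
record- or row-addressed message, so malformed inputs fail loudly instead of
propagating silently into downstream statistics.
"""

from __future__ import annotations

import io
import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The strict 20-letter amino-acid alphabet accepted by default.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/non-standard codes tolerated only with ``allow_ambiguous``.
AMBIGUOUS_CODES = frozenset("BJOUXZ")

#: Recognised subcellular fractions for sample labelling.
FRACTIONS = ("supernatant", "cytoplasm", "envelope", "licl")


class FormatError(ValueError):
    """A malformed input file, with a record/row-addressed message."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional genome/taxon provenance.

    Residues are numbered 1-based throughout the package, matching the
    field's convention for leader-peptide positions (e.g. G20G21).
    """

    id: str
    sequence: str
    genome_id: str | None = None
    taxon: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide with its spectral count and sample context."""

    peptide: str
    spectral_count: int
    sample_id: str
    time_h: float | None = None
    replicate: str | None = None
    fraction: str | None = None
    evalue: float | None = None
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError("empty peptide sequence")
        if self.spectral_count < 0:
            raise FormatError(
                f"peptide {self.peptide!r}: negative spectral count"
            )
        if self.evalue is not None and self.evalue <= 0:
            raise FormatError(f"peptide {self.peptide!r}: E-value must be > 0")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample culture context: collection time, OD600 and replicate."""

    sample_id: str
    time_h: float
    od600: float
    replicate: str
    fraction: str | None = None

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise FormatError(f"sample {self.sample_id!r}: od600 must be > 0")


@dataclass
class SpectralCountTable:
    """Protein-by-sample spectral counts with protein lengths.

    ``counts`` is a DataFrame indexed by protein_id with one column per
    sample; ``lengths`` a Series of residue counts on the same index;
    ``fractions`` maps each sample to its subcellular fraction label.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    fractions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise FormatError("count matrix and length vector indices differ")
        if (self.lengths < 1).any():
            bad = self.lengths.index[self.lengths < 1][0]
            raise FormatError(f"protein {bad!r}: length must be >= 1")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative spectral count in table")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _check_alphabet(seq: str, record_id: str, allow_ambiguous: bool) -> None:
    allowed = AMINO_ACIDS | (AMBIGUOUS_CODES if allow_ambiguous else frozenset())
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise FormatError(
                f"record {record_id!r}: invalid residue {ch!r} at position {i}"
            )


def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; the header token before the first whitespace
    becomes the id and the remainder the description. Rejects an empty file
    ("no records") and any residue outside the 20-letter alphabet unless
    ``allow_ambiguous`` is set.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _check_alphabet(seq, rec.id, allow_ambiguous)
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (canonical 60-column lines)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def _sniff_sep(path: Path, sep: str | None) -> str:
    """Detect tab vs comma from the header line; anything else must be explicit."""
    if sep is not None:
        return sep
    header = path.open().readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise FormatError(
        f"{path}: cannot detect delimiter (tab or comma); pass sep explicitly"
    )


#: Canonical column names for peptide tables; a dialect maps source -> these.
PEPTIDE_COLUMNS = ("peptide", "spectral_count", "sample_id")
OPTIONAL_PEPTIDE_COLUMNS = ("time_h", "replicate", "fraction", "evalue", "protein_id")


def read_peptide_table(
    path: str | Path,
    *,
    sep: str | None = None,
    dialect: Mapping[str, str] | None = None,
) -> list[PeptideObservation]:
    """Read an identified-peptide table into typed observations.

    ``dialect`` renames source columns to the canonical names (for mapping
    supplementary-table layouts at read time). Required columns: peptide,
    spectral_count, sample_id. Optional: time_h, replicate, fraction,
    evalue, protein_id. Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if dialect:
        df = df.rename(columns=dict(dialect))
    for col in PEPTIDE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: list[PeptideObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        count = int(d["spectral_count"])
        if count < 0:
            raise FormatError(f"{path}: row {i}: negative spectral_count")
        peptide = str(d["peptide"]).upper()
        _check_alphabet(peptide, f"row {i}", allow_ambiguous=False)
        kwargs = {}
        for col in OPTIONAL_PEPTIDE_COLUMNS:
            if col in d and pd.notna(d[col]):
                kwargs[col] = d[col]
        if "time_h" in kwargs:
            kwargs["time_h"] = float(kwargs["time_h"])
        if "evalue" in kwargs:
            kwargs["evalue"] = float(kwargs["evalue"])
        if "fraction" in kwargs and kwargs["fraction"] not in FRACTIONS:
            raise FormatError(
                f"{path}: row {i}: unknown fraction {kwargs['fraction']!r}"
            )
        out.append(
            PeptideObservation(
                peptide=peptide, spectral_count=count,
                sample_id=str(d["sample_id"]), **kwargs,
            )
        )
    return out


def write_peptide_table(observations: Sequence[PeptideObservation], path: str | Path) -> None:
    """Write observations as TSV with canonical column names."""
    rows = []
    for o in observations:
        rows.append({
            "peptide": o.peptide, "spectral_count": o.spectral_count,
            "sample_id": o.sample_id, "time_h": o.time_h,
            "replicate": o.replicate, "fraction": o.fraction,
            "evalue": o.evalue, "protein_id": o.protein_id,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path, *, sep: str | None = None) -> list[SampleMetadata]:
    """Read per-sample metadata (sample_id, time_h, od600, replicate[, fraction])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    for col in ("sample_id", "time_h", "od600", "replicate"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        frac = d.get("fraction")
        out.append(SampleMetadata(
            sample_id=str(d["sample_id"]), time_h=float(d["time_h"]),
            od600=float(d["od600"]), replicate=str(d["replicate"]),
            fraction=None if frac is None or pd.isna(frac) else str(frac),
        ))
    return out


def read_count_table(
    path: str | Path,
    *,
    sep: str | None = None,
    fractions: Mapping[str, str] | None = None,
) -> SpectralCountTable:
    """Read a protein x sample spectral-count table.

    Layout: first column protein_id, second column length (residues),
    remaining columns one per sample. Fraction labels come from the
    ``fractions`` mapping when given, else from the sample-name convention
    ``<fraction>_<replicate>`` (prefix before the last underscore).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need protein_id, length and >= 1 sample column")
    pid_col, len_col = df.columns[0], df.columns[1]
    if df[pid_col].duplicated().any():
        dup = df[pid_col][df[pid_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate protein_id {dup!r}")
    sample_cols = list(df.columns[2:])
    counts = df[sample_cols].copy()
    for col in sample_cols:
        vals = counts[col]
        if not (vals == vals.astype(int)).all():
            raise FormatError(f"{path}: non-integer count in sample {col!r}")
    counts = counts.astype(int)
    counts.index = pd.Index(df[pid_col].astype(str), name="protein_id")
    lengths = pd.Series(df[len_col].astype(int).to_numpy(), index=counts.index,
                        name="length")
    if fractions is None:
        fractions = {s: s.rsplit("_", 1)[0] for s in sample_cols}
    return SpectralCountTable(counts=counts, lengths=lengths,
                              fractions=dict(fractions))


def write_count_table(table: SpectralCountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "length", table.lengths)
    df.to_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_run_summary(path: str | Path, command: str, config: Mapping) -> None:
    """Persist a replayable JSON run summary (resolved config + version)."""
    from . import __version__

    payload = {"tool": "mampipe", "version": __version__,
               "command": command, "config": dict(config)}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot_fasta(accession: str, *, timeout: float = 30.0) -> ProteinRecord:
    """Fetch one UniProtKB record as FASTA over REST (requires network)."""
    url = UNIPROT_FASTA_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not recs:
        raise FormatError(f"UniProt {accession}: no records returned")
    rec = recs[0]
    return ProteinRecord(id=accession, sequence=str(rec.seq).upper(),
                         description=rec.description)


def load_reference_protein(
    accession: str,
    search_dirs: Sequence[str | Path] = ("data/reference",),
    *,
    allow_fetch: bool = True,
) -> ProteinRecord:
    """Load a reference UniProt record from disk, falling back to a fetch.

    Looks for ``<accession>.fasta`` in ``search_dirs`` first so analyses are
    reproducible offline once the record has been cached; otherwise fetches
    from UniProt when ``allow_fetch`` is true.
    """
    for d in search_dirs:
        p = Path(d) / f"{accession}.fasta"
        if p.exists():
            return read_fasta(p)[0]
    if allow_fetch:
        log.info("fetching %s from UniProt", accession)
        return fetch_uniprot_fasta(accession)
    raise FileNotFoundError(
        f"reference record {accession} not found under {list(search_dirs)} "
        "and fetching is disabled"
    )
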