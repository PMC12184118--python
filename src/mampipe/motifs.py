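"""PROSITE-style sequence-motif parsing and scanning.

The pattern grammar mirrors the Fuzzpro notation used for the MAM and PCAT
signature motifs:

* a residue letter matches itself (``M``),
* ``[A/B/...]`` matches any listed residue (slashes optional),
* ``x`` matches any residue, ``x(m)`` exactly m residues, ``x(m,n)`` between
  m and n residues (a variable gap).

Scanning reports every start position and, for variable gaps, every feasible
gap-length assignment, so a match is a fully resolved alignment of the
pattern onto the protein rather than just a span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Union

from .io_formats import AMINO_ACIDS, ProteinRecord


class PatternError(ValueError):
    """A malformed motif pattern; message carries the character offset."""


@dataclass(frozen=True)
class LiteralSet:
    """One pattern position matching any residue in ``residues``."""

    residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise PatternError("empty residue set")

    def matches(self, ch: str) -> bool:
        return ch in self.residues


@dataclass(frozen=True)
class Gap:
    """A run of ``min_len`` to ``max_len`` arbitrary residues."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len < 0 or self.max_len < self.min_len:
            raise PatternError(
                f"invalid gap bounds ({self.min_len},{self.max_len})"
            )


Element = Union[LiteralSet, Gap]


@dataclass(frozen=True)
class SequenceMotif:
    """A parsed motif: an ordered list of literal sets and gaps."""

    elements: tuple[Element, ...]
    source_text: str

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError("motif has no elements")

    @property
    def n_gaps(self) -> int:
        return sum(isinstance(e, Gap) for e in self.elements)

    @property
    def n_literals(self) -> int:
        return sum(isinstance(e, LiteralSet) for e in self.elements)

    @property
    def min_span(self) -> int:
        return self.n_literals + sum(
            e.min_len for e in self.elements if isinstance(e, Gap))

    @property
    def max_span(self) -> int:
        return self.n_literals + sum(
            e.max_len for e in self.elements if isinstance(e, Gap))


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence with resolved gap lengths.

    ``start``/``end`` are 1-based inclusive; ``gap_lengths`` holds the chosen
    length for each Gap element in pattern order, so the span arithmetic
    ``end - start + 1 == n_literals + sum(gap_lengths)`` always holds.
    """

    protein_id: str
    start: int
    end: int
    gap_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span {self.start}..{self.end}")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


_GAP_RE = re.compile(r"\((\d+)(?:,(\d+))?\)")


def parse_pattern(text: str) -> SequenceMotif:
    """Parse motif ``text`` into a :class:`SequenceMotif`.

    A single pair of brackets enclosing the entire pattern (the common way
    these motifs are quoted, e.g. ``[MMMPANx(8,11)VxGG]``) is stripped when
    the content would not itself be a bare alternation.
    """
    stripped = _strip_enclosing_brackets(text)
    elements: list[Element] = []
    i = 0
    s = stripped
    while i < len(s):
        ch = s[i]
        if ch == "x":
            m = _GAP_RE.match(s, i + 1)
            if m:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if hi < lo:
                    raise PatternError(
                        f"offset {i}: gap upper bound {hi} < lower bound {lo}")
                elements.append(Gap(lo, hi))
                i = m.end()
            else:
                elements.append(Gap(1, 1))
                i += 1
        elif ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise PatternError(f"offset {i}: unbalanced '['")
            inner = s[i + 1:j].replace("/", "")
            if not inner:
                raise PatternError(f"offset {i}: empty alternation")
            bad = [c for c in inner if c not in AMINO_ACIDS]
            if bad:
                raise PatternError(f"offset {i}: invalid residue {bad[0]!r}")
            elements.append(LiteralSet(frozenset(inner)))
            i = j + 1
        elif ch == "]":
            raise PatternError(f"offset {i}: unbalanced ']'")
        elif ch in AMINO_ACIDS:
            elements.append(LiteralSet(frozenset(ch)))
            i += 1
        else:
            raise PatternError(f"offset {i}: unexpected character {ch!r}")
    if not elements:
        raise PatternError("empty pattern")
    return SequenceMotif(elements=tuple(elements), source_text=text)


def _strip_enclosing_brackets(text: str) -> str:
    """Strip one wrapping bracket pair unless it is a bare alternation."""
    if not (text.startswith("[") and text.endswith("]")):
        return text
    inner = text[1:-1]
    # The wrapper's ']' must be the one opened at offset 0: reject "[A][B]".
    depth = 0
    for i, ch in enumerate(text):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth == 0 and i != len(text) - 1:
                return text
    # "[T/L]" is an alternation, not a wrapper: keep it if the content is
    # letters/slashes only and contains structure characters otherwise.
    if all(c in AMINO_ACIDS or c == "/" for c in inner):
        return text
    return inner


def _assignments(
    seq: str, pos: int, elements: tuple[Element, ...], idx: int,
    gaps: list[int],
) -> Iterator[tuple[int, tuple[int, ...]]]:
    """Yield (end_pos_exclusive_0based, gap_lengths) for matches at ``pos``."""
    if idx == len(elements):
        yield pos, tuple(gaps)
        return
    el = elements[idx]
    if isinstance(el, LiteralSet):
        if pos < len(seq) and el.matches(seq[pos]):
            yield from _assignments(seq, pos + 1, elements, idx + 1, gaps)
    else:
        for g in range(el.min_len, el.max_len + 1):
            if pos + g > len(seq):
                break
            gaps.append(g)
            yield from _assignments(seq, pos + g, elements, idx + 1, gaps)
            gaps.pop()


def scan(
    motif: SequenceMotif,
    protein: ProteinRecord | str,
    mode: Literal["all", "canonical"] = "all",
) -> list[MotifMatch]:
    """Scan ``protein`` with ``motif``.

    mode="all" returns every (start, gap-assignment) pair whose expansion
    matches, sorted by start, then total span length, then gap lengths.
    mode="canonical" returns at most one match: the leftmost start and,
    among its assignments, the lexicographically smallest gap_lengths
    (shortest gaps first). Overlapping occurrences are all reported.
    """
    if isinstance(protein, str):
        protein = ProteinRecord(id="seq", sequence=protein)
    seq = protein.sequence
    matches: list[MotifMatch] = []
    for start0 in range(0, len(seq) - motif.min_span + 1):
        found_here: list[MotifMatch] = []
        for end0, gaps in _assignments(seq, start0, motif.elements, 0, []):
            found_here.append(MotifMatch(
                protein_id=protein.id, start=start0 + 1, end=end0,
                gap_lengths=gaps,
            ))
        if not found_here:
            continue
        if mode == "canonical":
            return [min(found_here, key=lambda m: m.gap_lengths)]
        matches.extend(found_here)
    matches.sort(key=lambda m: (m.start, m.span_length, m.gap_lengths))
    return matches
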