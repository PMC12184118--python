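"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-derive results by exhaustive enumeration (expand a
motif into every fixed-length wildcard string and test every offset; take
literal set unions for coverage) and stay independent of the library code
they check.
"""

from itertools import product

from mampipe.motifs import Gap, LiteralSet, SequenceMotif

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(motif: SequenceMotif, seq: str) -> set[tuple[int, tuple[int, ...]]]:
    """All (1-based start, gap_lengths) pairs by exhaustive expansion.

    Expands every combination of gap lengths into a list of per-position
    allowed-residue sets (wildcards = full alphabet) and slides it over
    every offset of ``seq``.
    """
    gap_ranges = [range(e.min_len, e.max_len + 1)
                  for e in motif.elements if isinstance(e, Gap)]
    hits: set[tuple[int, tuple[int, ...]]] = set()
    for gaps in product(*gap_ranges):
        pattern: list[set[str]] = []
        gi = 0
        for e in motif.elements:
            if isinstance(e, LiteralSet):
                pattern.append(set(e.residues))
            else:
                pattern.extend([set(AA)] * gaps[gi])
                gi += 1
        n = len(pattern)
        for off in range(len(seq) - n + 1):
            if all(seq[off + k] in pattern[k] for k in range(n)):
                hits.add((off + 1, tuple(gaps)))
    return hits


def random_motif(rng, max_gap_elements=3, max_gap_span=5) -> SequenceMotif:
    """A small random motif within the oracle's tractable regime."""
    elements = []
    text_parts = []
    n_gaps = 0
    gap_budget = max_gap_span
    for _ in range(int(rng.integers(2, 7))):
        kind = rng.random()
        if kind < 0.3 and n_gaps < max_gap_elements and gap_budget > 0:
            lo = int(rng.integers(0, min(2, gap_budget) + 1))
            hi = int(rng.integers(lo, gap_budget + 1))
            gap_budget -= hi
            n_gaps += 1
            elements.append(Gap(lo, hi))
            text_parts.append(f"x({lo},{hi})")
        elif kind < 0.5:
            k = int(rng.integers(2, 4))
            residues = rng.choice(list(AA), size=k, replace=False)
            elements.append(LiteralSet(frozenset(residues)))
            text_parts.append("[" + "/".join(residues) + "]")
        else:
            ch = str(rng.choice(list(AA)))
            elements.append(LiteralSet(frozenset(ch)))
            text_parts.append(ch)
    if not any(isinstance(e, LiteralSet) for e in elements):
        ch = str(rng.choice(list(AA)))
        elements.append(LiteralSet(frozenset(ch)))
        text_parts.append(ch)
    return SequenceMotif(elements=tuple(elements),
                         source_text="".join(text_parts))


def welch_t(a, b):
    """Textbook Welch t statistic and Welch-Satterthwaite df."""
    import math

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
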