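"""NSAF spectral-count abundance and between-fraction enrichment.

The Normalized Spectral Abundance Factor of protein i in sample j is

    SAF_ij  = count_ij / length_i
    NSAF_ij = SAF_ij / sum_k SAF_kj

so NSAF sums to 1 over proteins within each sample, corrects spectral
counts for protein length, and is invariant to uniform rescaling of a
sample's counts. Proteome percentage is 100 x mean NSAF over a fraction's
replicate samples; enrichment between fractions is tested with Welch's
unequal-variance two-sided t-test on per-replicate NSAF values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SpectralCountTable


@dataclass
class NSAFResult:
    """Per-(protein, sample) NSAF plus per-fraction means and ranks."""

    saf: pd.DataFrame
    nsaf: pd.DataFrame
    fractions: dict[str, str]
    #: mean NSAF per protein (rows) per fraction (columns)
    mean_by_fraction: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.nsaf.index)


def nsaf(table: SpectralCountTable) -> NSAFResult:
    """Compute NSAF for every protein and sample of ``table``.

    Zero-count proteins keep NSAF 0 (they are not dropped). A sample whose
    counts are all zero has no defined normalization and raises ValueError.
    """
    saf = table.counts.div(table.lengths, axis=0)
    totals = saf.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        raise ValueError(f"sample {dead[0]!r} has all-zero counts")
    nsaf_df = saf.div(totals, axis=1)

    fracs = sorted(set(table.fractions.values()))
    means = pd.DataFrame(index=nsaf_df.index, columns=fracs, dtype=float)
    for f in fracs:
        cols = [s for s in nsaf_df.columns if table.fractions.get(s) == f]
        means[f] = nsaf_df[cols].mean(axis=1)
    return NSAFResult(saf=saf, nsaf=nsaf_df, fractions=dict(table.fractions),
                      mean_by_fraction=means)


def rank_and_percent(result: NSAFResult, fraction: str) -> pd.DataFrame:
    """Rank proteins by mean NSAF within ``fraction`` (mean-then-rank).

    Returns a DataFrame ordered by descending mean NSAF (ties broken by
    protein_id) with columns mean_nsaf, proteome_percent (= 100 x mean
    NSAF) and rank (1 = most abundant).
    """
    if fraction not in result.mean_by_fraction.columns:
        raise ValueError(f"unknown fraction {fraction!r}")
    df = result.mean_by_fraction[[fraction]].rename(columns={fraction: "mean_nsaf"})
    df = df.sort_index(kind="stable").sort_values(
        "mean_nsaf", ascending=False, kind="stable")
    df["proteome_percent"] = 100.0 * df["mean_nsaf"]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass(frozen=True)
class EnrichmentResult:
    protein_id: str
    fraction_a: str
    fraction_b: str
    mean_a: float
    mean_b: float
    ratio: float
    t: float
    p: float
    n_a: int
    n_b: int


def fraction_enrichment(
    result: NSAFResult,
    protein_id: str,
    fraction_a: str,
    fraction_b: str,
) -> EnrichmentResult:
    """Welch two-sided t-test of a protein's NSAF between two fractions.

    Uses per-replicate NSAF values; requires >= 2 replicate samples per
    fraction. ratio = mean_a / mean_b (inf when mean_b is 0). Two groups
    with identical values give t = 0, p = 1.
    """
    if protein_id not in result.nsaf.index:
        raise ValueError(f"unknown protein {protein_id!r}")
    groups = {}
    for name in (fraction_a, fraction_b):
        cols = [s for s in result.nsaf.columns
                if result.fractions.get(s) == name]
        if len(cols) < 2:
            raise ValueError(
                f"fraction {name!r} has {len(cols)} replicate(s); need >= 2")
        groups[name] = result.nsaf.loc[protein_id, cols].to_numpy(dtype=float)
    a, b = groups[fraction_a], groups[fraction_b]
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = float(mean_a / mean_b) if mean_b != 0 else float("inf")
    return EnrichmentResult(
        protein_id=protein_id, fraction_a=fraction_a, fraction_b=fraction_b,
        mean_a=mean_a, mean_b=mean_b, ratio=ratio,
        t=float(t), p=float(p), n_a=len(a), n_b=len(b),
    )
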