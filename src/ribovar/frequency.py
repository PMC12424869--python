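"""From perfect-hit sets to per-participant nucleotide-variant frequencies.

Per participant and region, perfect hits are resolved into per-allele read
counts under a configurable multi-mapper policy, then converted through
the lookup table into nucleotide-variant counts and divided by the total
reads mapped to the region.  Also provides cohort depth statistics with
the low-depth flag, population-variability ranking, the read-fraction
rDNA copy-number proxy, and cross-platform concordance QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas, LookupTable
from .mapper import PerfectHitSet

LOW_DEPTH_THRESHOLD = 5000  # mean mapped reads per variant across the cohort

POLICIES = ("fractional", "unique_only", "all_hits")


@dataclass
class AlleleCounts:
    """Per-region allele read counts for one participant.

    Counts may be fractional (a read split among k tied alleles adds 1/k
    to each under the fractional policy).
    """

    participant_id: str
    counts: dict[str, dict[str, float]] = field(default_factory=dict)

    def region_total(self, region_id: str) -> float:
        return float(sum(self.counts.get(region_id, {}).values()))

    def add(self, region_id: str, allele_id: str, weight: float) -> None:
        region = self.counts.setdefault(region_id, {})
        region[allele_id] = region.get(allele_id, 0.0) + weight


def count_alleles(
    hitsets: Iterable[PerfectHitSet],
    participant_id: str,
    policy: str = "fractional",
) -> AlleleCounts:
    """Resolve one participant's hit sets into per-allele counts.

    fractional   a read hitting k alleles adds 1/k to each (read count is
                 conserved: totals equal the number of mapped reads);
    unique_only  only reads hitting exactly one allele are counted;
    all_hits     every hit allele gets a full count (an all-alignments
                 aligner tally; not count-conserving).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown counting policy {policy!r}")
    out = AlleleCounts(participant_id=participant_id)
    for hs in hitsets:
        alleles = hs.alleles
        k = len(alleles)
        if k == 0:
            continue
        if policy == "unique_only" and k > 1:
            continue
        weight = 1.0 / k if policy == "fractional" else 1.0
        for region_id, allele_id in alleles:
            out.add(region_id, allele_id, weight)
    return out


def counts_to_variant_frequencies(
    counts: AlleleCounts, lookup: LookupTable
) -> tuple[dict[str, float], dict[str, float]]:
    """Convert allele counts to nucleotide-variant relative frequencies.

    freq(v) = sum of counts of alleles carrying v / total counts in the
    region.  Returns (variant frequencies, per-region totals); regions
    with zero total contribute no frequencies (missing, not zero).
    """
    freqs: dict[str, float] = {}
    totals: dict[str, float] = {}
    for region_id, allele_counts in counts.counts.items():
        if region_id not in lookup:
            raise ValueError(f"region {region_id!r} missing from lookup table")
        entry = lookup[region_id]
        unknown = set(allele_counts) - set(entry)
        if unknown:
            raise ValueError(
                f"alleles {sorted(unknown)} of region {region_id!r} absent "
                f"from lookup table"
            )
        total = sum(allele_counts.values())
        totals[region_id] = total
        if total == 0:
            continue
        variant_counts: dict[str, float] = {}
        for allele_id, c in allele_counts.items():
            for key in entry[allele_id]:
                variant_counts[key] = variant_counts.get(key, 0.0) + c
        # variants of the region absent from every counted allele are 0
        for allele_id, keys in entry.items():
            for key in keys:
                variant_counts.setdefault(key, 0.0)
        for key, c in variant_counts.items():
            freqs[key] = c / total
    return freqs, totals


def cohort_frequency_table(
    per_participant: Mapping[str, AlleleCounts], lookup: LookupTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-participant frequencies into participants x variants.

    Returns (frequency table with NaN for unobserved regions, per-region
    read-total table).
    """
    all_keys = sorted(
        {k for entry in lookup.values() for keys in entry.values() for k in keys}
    )
    regions = sorted(lookup)
    freq_rows, total_rows = {}, {}
    for pid, counts in per_participant.items():
        freqs, totals = counts_to_variant_frequencies(counts, lookup)
        freq_rows[pid] = freqs
        total_rows[pid] = totals
    pids = list(per_participant)
    freq = pd.DataFrame.from_dict(freq_rows, orient="index").reindex(
        index=pids, columns=all_keys
    )
    totals = (
        pd.DataFrame.from_dict(total_rows, orient="index")
        .reindex(index=pids, columns=regions)
        .fillna(0.0)
    )
    freq.index.name = totals.index.name = "participant_id"
    return freq.sort_index(), totals.sort_index()


def variant_depths(
    per_participant: Mapping[str, AlleleCounts], lookup: LookupTable
) -> pd.DataFrame:
    """Participants x variants table of reads supporting each variant.

    Depth of a variant for a participant = summed counts of the region's
    alleles that carry the variant.
    """
    rows = {}
    for pid, counts in per_participant.items():
        row: dict[str, float] = {}
        for region_id, allele_counts in counts.counts.items():
            entry = lookup[region_id]
            for allele_id, keys in entry.items():
                c = allele_counts.get(allele_id, 0.0)
                for key in keys:
                    row[key] = row.get(key, 0.0) + c
        rows[pid] = row
    all_keys = sorted(
        {k for entry in lookup.values() for keys in entry.values() for k in keys}
    )
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=all_keys)
    out.index.name = "participant_id"
    return out.fillna(0.0).sort_index()


def depth_statistics(
    depths: pd.DataFrame, threshold: float = LOW_DEPTH_THRESHOLD
) -> pd.DataFrame:
    """Per-variant mean depth across the cohort with the low-depth flag.

    A variant is flagged when its mean mapped-read count is strictly below
    ``threshold`` (default 5000).
    """
    mean_depth = depths.mean(axis=0)
    return pd.DataFrame(
        {
            "mean_depth": mean_depth,
            "low_depth": mean_depth < threshold,
        }
    ).rename_axis("variant")


def rank_population_variability(freq: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Rank variants by variance of frequency across participants.

    Ties break by variant key.  Requires >= 2 participants.  Returns the
    ``top_k`` most variable variants with variance and observed range.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if len(freq) < 2:
        raise ValueError("need at least two participants to rank variability")
    var = freq.var(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "variance": var,
            "min_freq": freq.min(axis=0),
            "max_freq": freq.max(axis=0),
        }
    ).rename_axis("variant")
    out = out.sort_values(
        ["variance", "variant"], ascending=[False, True], kind="mergesort"
    )
    return out.head(top_k)


@dataclass(frozen=True)
class CopyNumberEstimate:
    """rDNA copy number proxied by the fraction of reads mapping to rDNA."""

    participant_id: str
    rdna_read_fraction: float
    c45s: float


def estimate_rdna_copy_number(
    participant_id: str,
    n_rdna_reads: float,
    n_total_reads: float,
    scale_constant: float,
) -> CopyNumberEstimate:
    """c45S = (rDNA reads / total reads) x scale constant.

    The scale constant converts a read fraction into copy units; it is a
    calibration input (e.g. locus length vs genome length x known mean
    copy number), not estimated here.
    """
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    if not (0 <= n_rdna_reads <= n_total_reads):
        raise ValueError("n_rdna_reads must lie in [0, n_total_reads]")
    frac = n_rdna_reads / n_total_reads
    return CopyNumberEstimate(
        participant_id=participant_id,
        rdna_read_fraction=frac,
        c45s=frac * scale_constant,
    )


def concordance(
    freq_a: Mapping[str, float] | pd.Series,
    freq_b: Mapping[str, float] | pd.Series,
    discordance_threshold: float = 0.2,
    depth_flags: Mapping[str, bool] | None = None,
) -> dict:
    """Compare two variant-frequency profiles (e.g. short- vs long-read).

    Returns Pearson and Spearman correlations over shared non-missing
    variants plus the list of variants whose absolute frequency difference
    exceeds ``discordance_threshold``, annotated with low-depth flags when
    provided.
    """
    a = pd.Series(freq_a, dtype=float).dropna()
    b = pd.Series(freq_b, dtype=float).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared variants for concordance, got {len(shared)}"
        )
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    delta = np.abs(x - y)
    discordant = [
        {
            "variant": v,
            "freq_a": float(xi),
            "freq_b": float(yi),
            "abs_diff": float(d),
            "low_depth": bool(depth_flags.get(v, False)) if depth_flags else None,
        }
        for v, xi, yi, d in zip(shared, x, y, delta)
        if d > discordance_threshold
    ]
    return {
        "n_shared": int(len(shared)),
        "pearson": float(pearson),
        "spearman": float(spearman),
        "discordant": discordant,
    }
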