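"""Twin-based heritability of variant frequencies.

Monozygotic (MZ) twin pairs are identified from pairwise kinship
coefficients (kinship > 0.4); parent-offspring pairs from kinship in
[0.17, 0.35] with birth years more than 18 years apart, and trios are
assembled from them.  Heritability of a variant is estimated directly as
the Spearman correlation of its frequency across twin pairs; variants
above a threshold (default R > 0.8) are classified heritable, the rest
presumed predominantly somatic.  Additional diagnostics: the correlation
between twin-correlation and sequencing depth (the GC-coverage confound),
the pairwise linkage matrix of heritable variants, and per-variant
correlation with rDNA copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MZ_KINSHIP_THRESHOLD = 0.4
PO_KINSHIP_RANGE = (0.17, 0.35)
PO_MIN_YEAR_GAP = 18
HERITABLE_THRESHOLD = 0.8
DEPTH_FILTER_THRESHOLD = 5000.0


@dataclass(frozen=True)
class KinshipRecord:
    id_a: str
    id_b: str
    kinship: float
    birth_year_a: float | None = None
    birth_year_b: float | None = None


def identify_twins(
    records: Iterable[KinshipRecord],
    threshold: float = MZ_KINSHIP_THRESHOLD,
) -> list[tuple[str, str]]:
    """MZ pairs: kinship strictly > threshold, one pair per participant.

    Relatedness tables can list a participant in several pairs; pairs are
    accepted greedily by descending kinship so each participant appears at
    most once.
    """
    candidates = sorted(
        (r for r in records if r.kinship > threshold),
        key=lambda r: (-r.kinship, r.id_a, r.id_b),
    )
    used: set[str] = set()
    pairs = []
    for r in candidates:
        if r.id_a in used or r.id_b in used or r.id_a == r.id_b:
            continue
        pairs.append((r.id_a, r.id_b))
        used.update((r.id_a, r.id_b))
    return pairs


def identify_parent_offspring_and_trios(
    records: Iterable[KinshipRecord],
    kinship_range: tuple[float, float] = PO_KINSHIP_RANGE,
    min_year_gap: float = PO_MIN_YEAR_GAP,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Parent-offspring pairs and (child, parent, parent) trios.

    A pair is parent-offspring (PO) when kinship lies within
    ``kinship_range`` (inclusive) and birth years differ by more than
    ``min_year_gap``; the younger participant is the offspring.  A trio is
    a child with two distinct parents that are not PO with each other.
    Pairs with missing birth years are skipped (logged).
    """
    lo, hi = kinship_range
    po_pairs: list[tuple[str, str]] = []  # (parent, child)
    po_set: set[frozenset[str]] = set()
    for r in records:
        if not (lo <= r.kinship <= hi):
            continue
        if r.birth_year_a is None or r.birth_year_b is None:
            logger.warning(
                "kinship pair (%s, %s) skipped: missing birth year", r.id_a, r.id_b
            )
            continue
        if abs(r.birth_year_a - r.birth_year_b) <= min_year_gap:
            continue
        if r.birth_year_a < r.birth_year_b:
            parent, child = r.id_a, r.id_b
        else:
            parent, child = r.id_b, r.id_a
        po_pairs.append((parent, child))
        po_set.add(frozenset((r.id_a, r.id_b)))
    parents_by_child: dict[str, list[str]] = {}
    for parent, child in po_pairs:
        parents_by_child.setdefault(child, []).append(parent)
    trios = []
    for child, parents in sorted(parents_by_child.items()):
        for i in range(len(parents)):
            for j in range(i + 1, len(parents)):
                pa, pb = sorted((parents[i], parents[j]))
                if frozenset((pa, pb)) in po_set:
                    continue  # grandparent chain, not a mating pair
                trios.append((child, pa, pb))
    return po_pairs, trios


def twin_variant_correlation(
    freq: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    heritable_threshold: float = HERITABLE_THRESHOLD,
    mean_depth: Mapping[str, float] | pd.Series | None = None,
    min_pairs: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variant Spearman correlation of frequencies across twin pairs.

    Each pair's orientation (which twin is x and which is y) is
    randomized once under ``seed`` so that input ordering cannot create
    artefacts; Spearman R is symmetric in expectation either way.
    Variants with fewer than ``min_pairs`` informative pairs get NaN.
    Columns: twin_spearman, n_pairs, mean_depth, heritable (strict >).
    """
    rng = np.random.default_rng(seed)
    oriented = [
        (b, a) if rng.random() < 0.5 else (a, b)
        for a, b in pairs
        if a in freq.index and b in freq.index
    ]
    logger.info("twin correlation over %d pairs (seed=%d)", len(oriented), seed)
    if not oriented:
        raise ValueError("no twin pair has frequency data")
    x = freq.loc[[a for a, _ in oriented]].to_numpy(dtype=float)
    y = freq.loc[[b for _, b in oriented]].to_numpy(dtype=float)
    rows = []
    depth = pd.Series(mean_depth, dtype=float) if mean_depth is not None else None
    for k, variant in enumerate(freq.columns):
        ok = ~(np.isnan(x[:, k]) | np.isnan(y[:, k]))
        n = int(ok.sum())
        if n >= min_pairs:
            r = stats.spearmanr(x[ok, k], y[ok, k]).statistic
        else:
            r = np.nan
        rows.append(
            {
                "variant": variant,
                "twin_spearman": r,
                "n_pairs": n,
                "mean_depth": (
                    float(depth.get(variant, np.nan)) if depth is not None else np.nan
                ),
                "heritable": bool(r > heritable_threshold)
                if not np.isnan(r)
                else False,
            }
        )
    return pd.DataFrame(rows).set_index("variant")


def depth_confound(
    records: pd.DataFrame,
    depth_threshold: float = DEPTH_FILTER_THRESHOLD,
) -> dict:
    """Correlation of twin-correlation with mean variant read depth.

    Returns Pearson R over all variants and over the subset with mean
    depth >= ``depth_threshold`` — low-depth variants suffer
    coverage-driven noise that deflates twin correlation, so the filtered
    correlation should shrink when depth is the confounder.  Strata with
    < 3 variants give NaN rather than raising.
    """
    df = records.dropna(subset=["twin_spearman", "mean_depth"])

    def _corr(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            return float("nan")
        if sub["mean_depth"].std() == 0 or sub["twin_spearman"].std() == 0:
            return float("nan")
        return float(
            stats.pearsonr(sub["mean_depth"], sub["twin_spearman"]).statistic
        )

    filtered = df[df["mean_depth"] >= depth_threshold]
    return {
        "r_all": _corr(df),
        "n_all": int(len(df)),
        "r_filtered": _corr(filtered),
        "n_filtered": int(len(filtered)),
        "n_low_depth": int((df["mean_depth"] < depth_threshold).sum()),
    }


def heritable_linkage(
    freq: pd.DataFrame,
    heritable_keys: Sequence[str],
    region_of_variant: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation matrix of heritable variants.

    Computed over participants with pairwise-complete observations.
    Returns (matrix, hierarchical-clustering leaf order for plotting);
    constant columns yield NaN entries (logged).  When region annotations
    are given they are attached as a 'region' attribute on the matrix.
    """
    keys = [k for k in heritable_keys if k in freq.columns]
    if len(keys) < 2:
        raise ValueError("need >= 2 heritable variants for a linkage matrix")
    sub = freq[keys]
    if len(sub) < 3:
        raise ValueError("need >= 3 participants for a linkage matrix")
    constant = [k for k in keys if sub[k].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant heritable columns (NaN rows): %s", constant)
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    finite = corr.fillna(0.0)
    if len(keys) > 2:
        dist = squareform((1.0 - finite.to_numpy()), checks=False)
        order = hierarchy.leaves_list(
            hierarchy.average(np.clip(dist, 0.0, None))
        )
        leaf_order = [keys[i] for i in order]
    else:
        leaf_order = list(keys)
    if region_of_variant is not None:
        corr.attrs["region"] = {k: region_of_variant.get(k) for k in keys}
    return corr, leaf_order


def copy_number_correlation(
    freq: pd.DataFrame,
    c45s: pd.Series,
    heritable_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-variant Pearson correlation of frequency with rDNA copy number.

    Constant inputs give NaN.  When heritable flags are supplied a
    stratified mean |R| summary is attached via DataFrame.attrs, matching
    the expectation that abundant heritable variants decouple from copy
    number while somatic variants may track it.
    """
    shared = freq.index.intersection(c45s.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 participants")
    cn = c45s.loc[shared].to_numpy(dtype=float)
    rows = []
    for variant in freq.columns:
        v = freq.loc[shared, variant].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 3 or np.nanstd(v[ok]) == 0 or np.std(cn[ok]) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(v[ok], cn[ok]).statistic)
        rows.append({"variant": variant, "cn_pearson": r})
    out = pd.DataFrame(rows).set_index("variant")
    if heritable_flags is not None:
        flags = heritable_flags.reindex(out.index).fillna(False).astype(bool)
        out.attrs["summary"] = {
            "mean_abs_r_heritable": float(
                out.loc[flags, "cn_pearson"].abs().mean()
            ),
            "mean_abs_r_non_heritable": float(
                out.loc[~flags, "cn_pearson"].abs().mean()
            ),
        }
    return out
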