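"""Per-region rare-variant burden from unique-mapper allele counts.

The segment-level algorithm, applied independently per region:

1. count unique mappers u_ap per allele and participant;
2. keep the resolvable set  A-bar = {a : sum_p u_ap >= min_support}
   (cohort-wide support, default 2); collapse the remaining
   indistinguishable alleles onto their single most atlas-abundant
   representative, giving A-bar+;
3. recount: reads whose hits all fall outside A-bar become unique
   mappers credited to the representative, giving u+;
4. depth QC: exclude regions whose cohort median depth is < 30;
5. pi = u+ / sum(u+); allele copy numbers c = pi x c45S; entries below
   one copy are zeroed (treated as somatic noise in low-frequency
   clones); renormalize to pi*;
6. per participant and region, MAF = max_a pi*_a (the frequency of the
   region's most common resolved allele) and burden = 1 - MAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas
from .frequency import CopyNumberEstimate
from .mapper import PerfectHitSet

MIN_COHORT_SUPPORT = 2
MEDIAN_DEPTH_THRESHOLD = 30.0
COPY_ZERO_THRESHOLD = 1.0


@dataclass
class ResolvableAlleleSet:
    """Per-region cohort-supported alleles and the collapse representative.

    ``supported`` is A-bar; ``representative`` is the most atlas-abundant
    excluded allele (kept so reads from indistinguishable rare alleles
    still land somewhere); ``resolvable`` is A-bar+.
    """

    region_id: str
    supported: frozenset[str]
    representative: str | None
    flagged_no_support: bool = False

    @property
    def resolvable(self) -> frozenset[str]:
        if self.representative is None:
            return self.supported
        return self.supported | {self.representative}


def unique_counts(
    hitsets: Iterable[PerfectHitSet], region_ids: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Plain unique-mapper count vectors u_p: region -> allele -> count."""
    out: dict[str, dict[str, float]] = {r: {} for r in region_ids}
    for hs in hitsets:
        if hs.n_alleles != 1:
            continue
        region_id, allele_id = next(iter(hs.alleles))
        region = out.setdefault(region_id, {})
        region[allele_id] = region.get(allele_id, 0.0) + 1.0
    return out


def cohort_allele_support(
    per_participant_u: Mapping[str, Mapping[str, Mapping[str, float]]],
    atlas: Atlas,
    min_support: float = MIN_COHORT_SUPPORT,
) -> dict[str, ResolvableAlleleSet]:
    """A-bar and A-bar+ per region from cohort-wide unique-mapper sums.

    An allele is supported when its unique mappers summed over the whole
    cohort reach ``min_support``.  Among the excluded alleles the one with
    the highest atlas abundance (ties by allele_id) is retained as the
    collapse representative; when every allele is supported there is
    nothing to collapse.
    """
    out: dict[str, ResolvableAlleleSet] = {}
    for region in atlas.regions:
        rid = region.region_id
        alleles = atlas.region_alleles(rid)
        sums = {a.allele_id: 0.0 for a in alleles}
        for u in per_participant_u.values():
            for allele_id, c in u.get(rid, {}).items():
                sums[allele_id] = sums.get(allele_id, 0.0) + c
        supported = frozenset(a for a, s in sums.items() if s >= min_support)
        excluded = [a for a in alleles if a.allele_id not in supported]
        representative = None
        if excluded:
            representative = min(
                excluded, key=lambda a: (-a.atlas_abundance, a.allele_id)
            ).allele_id
        out[rid] = ResolvableAlleleSet(
            region_id=rid,
            supported=supported,
            representative=representative,
            flagged_no_support=sum(sums.values()) == 0,
        )
    return out


def recount_with_collapsed_alleles(
    hitsets: Iterable[PerfectHitSet],
    support: Mapping[str, ResolvableAlleleSet],
) -> dict[str, dict[str, float]]:
    """Updated unique-mapper counts u+ over the resolvable sets A-bar+.

    A read becomes a unique mapper when either (a) it hits exactly one
    allele overall and that allele is resolvable, or (b) all of its hits
    fall outside A-bar of a single region — the hit alleles are mutually
    indistinguishable, so the read is credited to the region's collapse
    representative.  Reads mixing a supported allele with excluded ones
    stay multi-mappers (conservative).  Collapsing can only add unique
    mappers, never remove them.
    """
    out: dict[str, dict[str, float]] = {s: {} for s in support}

    def credit(region_id: str, allele_id: str) -> None:
        region = out.setdefault(region_id, {})
        region[allele_id] = region.get(allele_id, 0.0) + 1.0

    for hs in hitsets:
        alleles = hs.alleles
        if not alleles:
            continue
        regions = {r for r, _ in alleles}
        if len(regions) > 1:
            continue  # cross-region multi-mapper
        (region_id,) = regions
        spec = support.get(region_id)
        if spec is None:
            continue
        hit_ids = {a for _, a in alleles}
        in_supported = hit_ids & spec.supported
        if len(hit_ids) == 1 and hit_ids <= spec.resolvable:
            credit(region_id, next(iter(hit_ids)))
        elif not in_supported and spec.representative is not None:
            # all hit alleles were collapsed: the read is unique in A-bar+
            credit(region_id, spec.representative)
    return out


@dataclass
class SegmentDepth:
    """Per (participant, region) depth plus the cohort-level QC verdict."""

    participant_id: str
    region_id: str
    depth: float
    cohort_median: float | None = None
    pass_qc: bool | None = None


def segment_depth(
    u_plus: Mapping[str, Mapping[str, float]],
    region_lengths: Mapping[str, float],
    participant_id: str,
    read_length: int = 150,
    mode: str = "per_base",
) -> dict[str, SegmentDepth]:
    """Segment read depth d_ps from collapsed unique counts.

    per_base (default): d = sum(u+) x read_length / L_s, i.e. mean
    per-base coverage.  count_per_base: d = sum(u+) / L_s, the literal
    reads-over-length ratio, kept as an alternative convention.
    """
    if mode not in ("per_base", "count_per_base"):
        raise ValueError(f"unknown depth mode {mode!r}")
    out = {}
    for region_id, length in region_lengths.items():
        if length <= 0:
            raise ValueError(f"region {region_id!r}: non-positive length")
        total = sum(u_plus.get(region_id, {}).values())
        d = total * read_length / length if mode == "per_base" else total / length
        out[region_id] = SegmentDepth(
            participant_id=participant_id, region_id=region_id, depth=d
        )
    return out


def apply_depth_qc(
    depths: Mapping[str, Mapping[str, SegmentDepth]],
    threshold: float = MEDIAN_DEPTH_THRESHOLD,
) -> dict[str, bool]:
    """Cohort-median depth QC per region: pass iff median >= threshold."""
    verdicts: dict[str, bool] = {}
    regions = {r for per in depths.values() for r in per}
    for region_id in regions:
        values = [per[region_id].depth for per in depths.values() if region_id in per]
        median = float(np.median(values)) if values else 0.0
        ok = median >= threshold
        verdicts[region_id] = ok
        for per in depths.values():
            if region_id in per:
                per[region_id].cohort_median = median
                per[region_id].pass_qc = ok
    return verdicts


@dataclass
class BurdenResult:
    """Resolved allele frequencies and burden for one (participant, region)."""

    participant_id: str
    region_id: str
    allele_ids: tuple[str, ...]
    pi: np.ndarray  # raw u+ frequencies
    copy: np.ndarray  # pi x c45S
    copy_star: np.ndarray  # copies < zero_threshold set to 0
    pi_star: np.ndarray  # renormalized
    maf: float
    burden: float
    unresolved: bool = False


def resolve_frequencies(
    u_plus_region: Mapping[str, float],
    c45s: CopyNumberEstimate | float,
    participant_id: str,
    region_id: str,
    zero_threshold: float = COPY_ZERO_THRESHOLD,
) -> BurdenResult | None:
    """Copy-number-scaled zeroing and renormalization for one region.

    Alleles whose estimated copy number pi x c45S falls below
    ``zero_threshold`` (default one copy) are treated as somatic noise and
    zeroed before renormalizing.  Returns None when the region has no
    unique mappers; a result with ``unresolved=True`` when every allele is
    zeroed.
    """
    total = float(sum(u_plus_region.values()))
    if total <= 0:
        return None
    cn = c45s.c45s if isinstance(c45s, CopyNumberEstimate) else float(c45s)
    if cn < 0:
        raise ValueError("c45S must be non-negative")
    allele_ids = tuple(sorted(u_plus_region))
    u = np.array([u_plus_region[a] for a in allele_ids], dtype=float)
    pi = u / total
    copy = pi * cn
    copy_star = np.where(copy < zero_threshold, 0.0, copy)
    star_total = copy_star.sum()
    if star_total > 0:
        pi_star = copy_star / star_total
        maf = float(pi_star.max())
        return BurdenResult(
            participant_id=participant_id,
            region_id=region_id,
            allele_ids=allele_ids,
            pi=pi,
            copy=copy,
            copy_star=copy_star,
            pi_star=pi_star,
            maf=maf,
            burden=1.0 - maf,
        )
    return BurdenResult(
        participant_id=participant_id,
        region_id=region_id,
        allele_ids=allele_ids,
        pi=pi,
        copy=copy,
        copy_star=copy_star,
        pi_star=np.full_like(pi, np.nan),
        maf=float("nan"),
        burden=float("nan"),
        unresolved=True,
    )


def region_burden_table(
    results: Iterable[BurdenResult | None],
    qc_verdicts: Mapping[str, bool] | None = None,
    region_classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format cohort table of per (participant, region) burden.

    Rows for regions failing depth QC are masked to NA (kept, flagged);
    unresolved results are NA as well.  ``region_class`` annotates ES vs
    non-ES when provided.
    """
    rows = []
    for res in results:
        if res is None:
            continue
        qc_ok = True if qc_verdicts is None else qc_verdicts.get(res.region_id, False)
        masked = (not qc_ok) or res.unresolved
        rows.append(
            {
                "participant_id": res.participant_id,
                "region_id": res.region_id,
                "region_class": (
                    region_classes.get(res.region_id) if region_classes else None
                ),
                "maf": np.nan if masked else res.maf,
                "burden": np.nan if masked else res.burden,
                "pass_depth_qc": qc_ok,
                "unresolved": res.unresolved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "region_id",
            "region_class",
            "maf",
            "burden",
            "pass_depth_qc",
            "unresolved",
        ],
    )


def burden_matrix(table: pd.DataFrame, value: str = "burden") -> pd.DataFrame:
    """Pivot the long burden table into participants x regions."""
    return table.pivot(index="participant_id", columns="region_id", values=value)
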