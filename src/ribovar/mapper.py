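"""Perfect-match read mapping against extended atlas alleles.

Downstream counting only ever uses alignments with no mismatches and no
gaps, so mapping reduces to exact substring search over the extended
allele sequences; an external gapped aligner is not needed.  Two modes:

``full``
    the entire read must match verbatim;
``quality_masked``
    read positions with base quality <= ``min_base_quality`` (default 20)
    act as wildcards, every other position must match, and no gaps are
    allowed — mirrors counting only gapless CIGARs with all high-quality
    bases agreeing.

Both strands are searched.  A read is a *unique mapper* when its perfect
hits touch exactly one allele across all regions, a *multi-mapper* with
two or more alleles, otherwise unmapped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .atlas import Atlas, AtlasAllele

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_BASE_QUALITY = 20


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


Hit = tuple[str, str, int, str]  # (region_id, allele_id, offset, strand)


@dataclass
class PerfectHitSet:
    """All perfect alignments of one read."""

    read_id: str
    hits: frozenset[Hit] = frozenset()

    @property
    def alleles(self) -> frozenset[tuple[str, str]]:
        """Distinct (region_id, allele_id) pairs hit by the read."""
        return frozenset((h[0], h[1]) for h in self.hits)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class ReadClassification:
    """Partition of a read set into unmapped / unique / multi-mappers."""

    unique: dict[str, tuple[str, str]] = field(default_factory=dict)
    multimapper: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unique": len(self.unique),
            "multimapper": len(self.multimapper),
            "unmapped": len(self.unmapped),
        }


class PerfectMatchIndex:
    """k-mer seed-and-verify exact substring index over extended alleles.

    Seeds are k-mers (default k=31) of the forward extended sequences;
    queries are verified by direct string comparison, so results are exact.
    Reads shorter than k fall back to a linear scan.
    """

    def __init__(self, atlas: Atlas, k: int = 31):
        if not atlas.alleles:
            raise ValueError("cannot index an empty atlas")
        self.k = k
        self.alleles: list[AtlasAllele] = list(atlas.alleles)
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate (region, allele) ids in atlas")
        for a in self.alleles:
            if not a.extended_sequence:
                raise ValueError(
                    f"allele {a.name} has no extended sequence; call "
                    f"Atlas.extend_all() first"
                )
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for ai, a in enumerate(self.alleles):
            seq = a.extended_sequence
            for off in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[off : off + k], []).append((ai, off))

    # -- full mode ---------------------------------------------------------

    def _find_exact(self, query: str) -> Iterator[tuple[int, int]]:
        """Yield (allele_index, offset) of verbatim occurrences of query."""
        if len(query) >= self.k:
            seed = query[: self.k]
            for ai, off in self._seeds.get(seed, ()):
                seq = self.alleles[ai].extended_sequence
                if seq[off : off + len(query)] == query:
                    yield ai, off
        else:
            for ai, a in enumerate(self.alleles):
                start = 0
                while (off := a.extended_sequence.find(query, start)) != -1:
                    yield ai, off
                    start = off + 1

    # -- quality-masked mode ----------------------------------------------

    def _find_masked(
        self, query: str, qualities: Sequence[int], min_q: int
    ) -> Iterator[tuple[int, int]]:
        """Occurrences where positions with quality > min_q match exactly."""
        high = [q > min_q for q in qualities]
        if all(high):
            yield from self._find_exact(query)
            return
        # seed on a clean high-quality k-mer when one exists
        seed_at = next(
            (
                i
                for i in range(len(query) - self.k + 1)
                if all(high[i : i + self.k])
            ),
            None,
        )
        if seed_at is not None:
            seen: set[tuple[int, int]] = set()
            for ai, off in self._seeds.get(query[seed_at : seed_at + self.k], ()):
                start = off - seed_at
                if start < 0:
                    continue
                key = (ai, start)
                if key in seen:
                    continue
                seen.add(key)
                seq = self.alleles[ai].extended_sequence
                if start + len(query) > len(seq):
                    continue
                if all(
                    not high[i] or seq[start + i] == query[i]
                    for i in range(len(query))
                ):
                    yield ai, start
        else:
            # no clean seed: regex scan with wildcards at low-quality bases
            pattern = re.compile(
                "".join(c if h else "." for c, h in zip(query, high))
            )
            for ai, a in enumerate(self.alleles):
                start = 0
                while (m := pattern.search(a.extended_sequence, start)) is not None:
                    yield ai, m.start()
                    start = m.start() + 1

    # -- public API --------------------------------------------------------

    def map_read(
        self,
        read: ReadRecord,
        mode: str = "full",
        min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    ) -> PerfectHitSet:
        """Perfect hits of a read on both strands.

        Empty reads yield an empty hit set (logged, not raised).  A read
        hitting one allele at several offsets still counts that allele once
        downstream; all offsets are reported here.
        """
        if mode not in ("full", "quality_masked"):
            raise ValueError(f"unknown mapping mode {mode!r}")
        if not read.sequence:
            logger.warning("empty read %s skipped", read.read_id)
            return PerfectHitSet(read_id=read.read_id)
        hits: set[Hit] = set()
        for strand, seq, quals in (
            ("+", read.sequence, read.qualities),
            ("-", reverse_complement(read.sequence), read.qualities[::-1]),
        ):
            if mode == "full":
                found = self._find_exact(seq)
            else:
                found = self._find_masked(seq, quals, min_base_quality)
            for ai, off in found:
                a = self.alleles[ai]
                hits.add((a.region_id, a.allele_id, off, strand))
        return PerfectHitSet(read_id=read.read_id, hits=frozenset(hits))

    def map_reads(
        self,
        reads: Iterable[ReadRecord],
        mode: str = "full",
        min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    ) -> list[PerfectHitSet]:
        return [self.map_read(r, mode, min_base_quality) for r in reads]


def brute_force_map(
    read: ReadRecord,
    alleles: Sequence[AtlasAllele],
    mode: str = "full",
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> PerfectHitSet:
    """Reference sliding-window scan, independent of the k-mer index.

    O(reads x alleles x positions); used as the oracle the index is
    checked against.
    """
    hits: set[Hit] = set()
    for strand, seq, quals in (
        ("+", read.sequence, read.qualities),
        ("-", reverse_complement(read.sequence), read.qualities[::-1]),
    ):
        if not seq:
            continue
        for a in alleles:
            target = a.extended_sequence
            for off in range(len(target) - len(seq) + 1):
                window = target[off : off + len(seq)]
                if mode == "full":
                    ok = window == seq
                else:
                    ok = all(
                        q <= min_base_quality or w == c
                        for w, c, q in zip(window, seq, quals)
                    )
                if ok:
                    hits.add((a.region_id, a.allele_id, off, strand))
    return PerfectHitSet(read_id=read.read_id, hits=frozenset(hits))


def classify_reads(hitsets: Iterable[PerfectHitSet]) -> ReadClassification:
    """Partition reads into unique mappers, multi-mappers and unmapped.

    Uniqueness is global: a read hitting alleles in two different regions
    is a multi-mapper.
    """
    out = ReadClassification()
    for hs in hitsets:
        n = hs.n_alleles
        if n == 0:
            out.unmapped.append(hs.read_id)
        elif n == 1:
            out.unique[hs.read_id] = next(iter(hs.alleles))
        else:
            out.multimapper.append(hs.read_id)
    return out


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

def write_sam(
    path,
    hitsets: Iterable[PerfectHitSet],
    reads: dict[str, ReadRecord],
    atlas: Atlas,
) -> None:
    """Write hits as a SAM file with '<region>|<allele>' reference names.

    The first alignment of a read is primary; the rest are marked
    secondary (mirrors an aligner reporting all alignments).
    """
    import pysam

    alleles = list(atlas.alleles)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": a.name, "LN": len(a.extended_sequence)} for a in alleles
        ],
    }
    name_to_tid = {a.name: i for i, a in enumerate(alleles)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for hs in hitsets:
            read = reads[hs.read_id]
            for i, (region_id, allele_id, off, strand) in enumerate(
                sorted(hs.hits)
            ):
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = hs.read_id
                rec.reference_id = name_to_tid[f"{region_id}|{allele_id}"]
                rec.reference_start = off
                rec.cigarstring = f"{len(read.sequence)}M"
                rec.mapping_quality = 255
                rec.is_secondary = i > 0
                rec.is_reverse = strand == "-"
                if strand == "-":
                    rec.query_sequence = reverse_complement(read.sequence)
                    rec.query_qualities = list(read.qualities[::-1])
                else:
                    rec.query_sequence = read.sequence
                    rec.query_qualities = list(read.qualities)
                fh.write(rec)


def ingest_sam(
    path,
    atlas: Atlas,
    mode: str = "full",
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[PerfectHitSet]:
    """Read alignments from SAM, keeping only re-verified perfect hits.

    Secondary and supplementary alignments are retained.  Every alignment
    is re-checked against the extended allele sequence (trust-but-verify):
    gapped CIGARs are dropped; in full mode any mismatch drops the hit; in
    quality_masked mode only mismatches at positions with quality >
    ``min_base_quality`` do.
    """
    import pysam

    by_name = {a.name: a for a in atlas.alleles}
    hits_by_read: dict[str, set[Hit]] = {}
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                hits_by_read.setdefault(rec.query_name, set())
                continue
            rname = rec.reference_name
            if rname not in by_name:
                unknown.add(rname)
                continue
            hits_by_read.setdefault(rec.query_name, set())
            # gapless means a single M/=/X run (soft-clips not accepted in
            # full mode; in masked mode clipped bases would be unverified,
            # so they are rejected there too)
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] not in (0, 7, 8):
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None:
                continue
            allele = by_name[rname]
            target = allele.extended_sequence
            off = rec.reference_start
            if off + len(seq) > len(target):
                continue
            window = target[off : off + len(seq)]
            if mode == "full":
                ok = window == seq
            else:
                if quals is None:
                    ok = window == seq
                else:
                    ok = all(
                        q <= min_base_quality or w == c
                        for w, c, q in zip(window, seq, quals)
                    )
            if ok:
                strand = "-" if rec.is_reverse else "+"
                hits_by_read[rec.query_name].add(
                    (allele.region_id, allele.allele_id, off, strand)
                )
    if unknown:
        raise ValueError(
            f"SAM references not in atlas: {', '.join(sorted(unknown))}"
        )
    return [
        PerfectHitSet(read_id=rid, hits=frozenset(h))
        for rid, h in hits_by_read.items()
    ]
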