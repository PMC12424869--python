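"""Atlas model: subunit references, region annotations, alleles, lookup tables.

The atlas describes each 18S/28S subunit as a tiling of expansion-segment
(ES) and non-ES regions.  Every region carries a set of observed *alleles*
(combinations of nucleotide variants spanning the region).  For short-read
mapping each allele sequence is extended with up to 150 bases of
non-variant reference flank on both sides, and a per-region lookup table
maps each allele to the single-nucleotide variants it carries — the bridge
from allele-resolution read counts to nucleotide-resolution frequencies.

Coordinates are 1-based inclusive on the subunit.  Indels are VCF-style:
left-anchored with one shared reference base ("2177:G:GTG" inserts TG
after the G at 2177).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align

_ALPHABET = set("ACGT")
_KEY_RE = re.compile(r"^(\d+):([ACGT]+):([ACGT]+)$")


class AtlasError(ValueError):
    """Inconsistent atlas content (coordinates, sequences or variant sets)."""


@dataclass(frozen=True)
class SubunitReference:
    """Reference sequence of one rRNA subunit (18S or 28S)."""

    subunit_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AtlasError(f"empty reference for subunit {self.subunit_id!r}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise AtlasError(
                f"subunit {self.subunit_id!r}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Substring for 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise AtlasError(
                f"coordinates {start}-{end} outside subunit "
                f"{self.subunit_id!r} of length {self.length}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class RegionAnnotation:
    """One ES or non-ES region on a subunit, 1-based inclusive coordinates."""

    region_id: str
    subunit_id: str
    region_class: str  # "ES" or "non-ES"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.region_class not in ("ES", "non-ES"):
            raise AtlasError(
                f"region {self.region_id!r}: class must be ES or non-ES, "
                f"got {self.region_class!r}"
            )
        if not (1 <= self.start <= self.end):
            raise AtlasError(
                f"region {self.region_id!r}: invalid coordinates "
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, order=True)
class NucleotideVariant:
    """A single nucleotide variant on a subunit.

    SNVs have len(ref) == len(alt) == 1; indels share one left-anchor
    reference base, so an insertion is e.g. ref="G", alt="GTG" and a
    deletion ref="GTG", alt="G".
    """

    subunit_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise AtlasError(f"variant at {self.position}: ref == alt ({self.ref})")
        for s in (self.ref, self.alt):
            if not s or set(s) - _ALPHABET:
                raise AtlasError(
                    f"variant at {self.position}: bad allele string {s!r}"
                )

    @property
    def key(self) -> str:
        return f"{self.position}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def parse_variant_key(key: str, subunit_id: str) -> NucleotideVariant:
    """Parse a canonical "position:ref:alt" key (e.g. "4913:C:T")."""
    m = _KEY_RE.match(key)
    if m is None:
        raise AtlasError(f"malformed variant key {key!r}")
    return NucleotideVariant(
        subunit_id=subunit_id,
        position=int(m.group(1)),
        ref=m.group(2),
        alt=m.group(3),
    )


@dataclass(frozen=True)
class AtlasAllele:
    """One observed allele (variant combination) of a region.

    ``core_sequence`` spans exactly the region; ``extended_sequence`` adds
    non-variant reference flanks (possibly truncated at subunit ends) so
    that full-length short reads can align.  ``variants`` is the ordered
    tuple of nucleotide variants the allele carries; the reference allele
    carries none.
    """

    region_id: str
    allele_id: str
    core_sequence: str
    variants: tuple[NucleotideVariant, ...] = ()
    extended_sequence: str = ""
    atlas_abundance: float = 0.0

    @property
    def name(self) -> str:
        """FASTA/SAM reference name, '<region>|<allele>'."""
        return f"{self.region_id}|{self.allele_id}"

    @property
    def is_reference(self) -> bool:
        return not self.variants


def apply_variants(
    region_ref: str,
    variants: Iterable[NucleotideVariant],
    region_start: int,
) -> str:
    """Apply variants (subunit coordinates) to a region reference sequence.

    Used both to validate declared variant sets against allele sequences
    and by the simulator to construct allele cores.
    """
    out: list[str] = []
    cursor = 0  # 0-based within region_ref
    for v in sorted(variants, key=lambda v: v.position):
        off = v.position - region_start
        if off < cursor or off + len(v.ref) > len(region_ref):
            raise AtlasError(
                f"variant {v.key} outside region or overlapping a previous one"
            )
        if region_ref[off : off + len(v.ref)] != v.ref:
            raise AtlasError(
                f"variant {v.key}: reference is "
                f"{region_ref[off : off + len(v.ref)]!r}, not {v.ref!r}"
            )
        out.append(region_ref[cursor:off])
        out.append(v.alt)
        cursor = off + len(v.ref)
    out.append(region_ref[cursor:])
    return "".join(out)


def extend_allele(
    allele: AtlasAllele,
    subunit_ref: SubunitReference,
    region: RegionAnnotation,
    flank_len: int = 150,
) -> AtlasAllele:
    """Attach up to ``flank_len`` bases of reference flank on each side.

    Flanks are reference sequence (identical for all alleles of a region)
    and are truncated at subunit boundaries.
    """
    if flank_len < 0:
        raise AtlasError("flank_len must be non-negative")
    if region.end > subunit_ref.length:
        raise AtlasError(
            f"region {region.region_id!r} end {region.end} beyond subunit "
            f"length {subunit_ref.length}"
        )
    f5 = min(flank_len, region.start - 1)
    f3 = min(flank_len, subunit_ref.length - region.end)
    left = subunit_ref.slice(region.start - f5, region.start - 1) if f5 else ""
    right = subunit_ref.slice(region.end + 1, region.end + f3) if f3 else ""
    return replace(allele, extended_sequence=left + allele.core_sequence + right)


# ---------------------------------------------------------------------------
# Variant derivation by global alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def normalize_variant(
    position: int, ref: str, alt: str, subunit_seq: str
) -> tuple[int, str, str]:
    """Left-align and minimalize an indel/substitution against the subunit.

    Standard VCF normalization: trim shared trailing bases (extending left
    with the preceding reference base when one allele empties), then trim
    shared leading bases while both alleles keep >= 2 bases.  Position is
    1-based on the subunit.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (not ref or not alt or (len(ref) != len(alt) and ref[-1] == alt[-1])) \
                and position > 1:
            prev = subunit_seq[position - 2]
            if ref and alt and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            ref, alt = prev + ref, prev + alt
            position -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, position = ref[1:], alt[1:], position + 1
    return position, ref, alt


def derive_variants(
    core_sequence: str,
    subunit_ref: SubunitReference,
    region: RegionAnnotation,
) -> tuple[NucleotideVariant, ...]:
    """Infer the variant set of an allele by global alignment to the region.

    Needleman-Wunsch alignment of the allele core against the region
    reference, with VCF-style left-shift normalization of indels.
    Substitution runs are split into individual SNVs; each gap run becomes
    one left-anchored indel.
    """
    region_ref = subunit_ref.slice(region.start, region.end)
    if core_sequence == region_ref:
        return ()
    aln = _make_aligner().align(region_ref, core_sequence)[0]
    ref_aln, alt_aln = _gapped_strings(aln)
    raw: list[tuple[int, str, str]] = []  # (0-based region offset, ref, alt)
    ref_pos = 0
    i = 0
    n = len(ref_aln)
    while i < n:
        if ref_aln[i] == alt_aln[i]:
            ref_pos += 1
            i += 1
            continue
        if ref_aln[i] != "-" and alt_aln[i] != "-":
            raw.append((ref_pos, ref_aln[i], alt_aln[i]))  # SNV column
            ref_pos += 1
            i += 1
            continue
        # gap run: collect maximal stretch with a gap in either row
        j = i
        r, a = [], []
        while j < n and ("-" in (ref_aln[j], alt_aln[j])):
            if ref_aln[j] != "-":
                r.append(ref_aln[j])
            if alt_aln[j] != "-":
                a.append(alt_aln[j])
            j += 1
        anchor_off = ref_pos - 1
        if anchor_off >= 0:
            # anchor on the preceding reference base (VCF convention)
            anchor = region_ref[anchor_off]
            raw.append((anchor_off, anchor + "".join(r), anchor + "".join(a)))
        else:
            # indel at the very start of the region: anchor on the first
            # reference base following the event instead
            anchor = region_ref[len(r)]
            raw.append((0, "".join(r) + anchor, "".join(a) + anchor))
        ref_pos += len(r)
        i = j
    out = []
    for off, ref, alt in raw:
        pos, ref, alt = normalize_variant(
            region.start + off, ref, alt, subunit_ref.sequence
        )
        out.append(
            NucleotideVariant(
                subunit_id=region.subunit_id, position=pos, ref=ref, alt=alt
            )
        )
    return tuple(sorted(out, key=lambda v: (v.position, v.key)))


def _gapped_strings(aln) -> tuple[str, str]:
    """Gapped target/query rows of a Bio.Align alignment."""
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# Atlas container and lookup table
# ---------------------------------------------------------------------------

LookupTable = dict[str, dict[str, list[str]]]  # region -> allele -> variant keys


@dataclass
class Atlas:
    """An rRNA variant atlas: subunits, region tiling, and region alleles."""

    subunits: dict[str, SubunitReference]
    regions: list[RegionAnnotation]
    alleles: list[AtlasAllele] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate_tiling()
        seen: set[tuple[str, str]] = set()
        for a in self.alleles:
            if (a.region_id, a.allele_id) in seen:
                raise AtlasError(f"duplicate allele {a.name}")
            seen.add((a.region_id, a.allele_id))

    def validate_tiling(self) -> None:
        """Regions of each subunit must be non-overlapping and tile it."""
        by_subunit: dict[str, list[RegionAnnotation]] = {}
        for r in self.regions:
            if r.subunit_id not in self.subunits:
                raise AtlasError(f"region {r.region_id!r}: unknown subunit")
            by_subunit.setdefault(r.subunit_id, []).append(r)
        for sid, regs in by_subunit.items():
            regs = sorted(regs, key=lambda r: r.start)
            expect = 1
            for r in regs:
                if r.start != expect:
                    raise AtlasError(
                        f"subunit {sid}: regions do not tile (gap/overlap at "
                        f"{r.region_id!r}, expected start {expect})"
                    )
                expect = r.end + 1
            if expect != self.subunits[sid].length + 1:
                raise AtlasError(f"subunit {sid}: regions do not reach the end")

    def region(self, region_id: str) -> RegionAnnotation:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def region_alleles(self, region_id: str) -> list[AtlasAllele]:
        return [a for a in self.alleles if a.region_id == region_id]

    def allele(self, region_id: str, allele_id: str) -> AtlasAllele:
        for a in self.alleles:
            if a.region_id == region_id and a.allele_id == allele_id:
                return a
        raise KeyError(f"{region_id}|{allele_id}")

    def region_class(self, region_id: str) -> str:
        return self.region(region_id).region_class

    def validate_alleles(self) -> None:
        """Check every declared variant set reconstructs its core sequence."""
        for a in self.alleles:
            region = self.region(a.region_id)
            ref = self.subunits[region.subunit_id].slice(region.start, region.end)
            rebuilt = apply_variants(ref, a.variants, region.start)
            if rebuilt != a.core_sequence:
                raise AtlasError(
                    f"allele {a.name}: declared variants do not reproduce "
                    f"its core sequence"
                )

    def extend_all(self, flank_len: int = 150) -> "Atlas":
        """Return a copy with extended sequences attached to every allele."""
        extended = []
        for a in self.alleles:
            region = self.region(a.region_id)
            extended.append(
                extend_allele(a, self.subunits[region.subunit_id], region, flank_len)
            )
        return Atlas(subunits=self.subunits, regions=self.regions, alleles=extended)


def build_lookup_table(atlas: Atlas, derive_missing: bool = True) -> LookupTable:
    """Map every allele of every region to its nucleotide-variant keys.

    Variant sets declared in the atlas are validated against the allele
    sequence; alleles without a declared set have theirs derived by global
    alignment when ``derive_missing`` is true.  Lists are ordered by
    ascending position; the reference allele maps to [].
    """
    table: LookupTable = {}
    for region in atlas.regions:
        subunit = atlas.subunits[region.subunit_id]
        region_ref = subunit.slice(region.start, region.end)
        entry: dict[str, list[str]] = {}
        for a in atlas.region_alleles(region.region_id):
            variants = a.variants
            if not variants and a.core_sequence != region_ref:
                if not derive_missing:
                    raise AtlasError(f"allele {a.name}: no variant list")
                variants = derive_variants(a.core_sequence, subunit, region)
            else:
                rebuilt = apply_variants(region_ref, variants, region.start)
                if rebuilt != a.core_sequence:
                    raise AtlasError(
                        f"allele {a.name}: stated variants not reconstructible "
                        f"from core_sequence"
                    )
            for v in variants:
                if not (region.start <= v.position <= region.end):
                    raise AtlasError(
                        f"allele {a.name}: variant {v.key} outside region"
                    )
            entry[a.allele_id] = [
                v.key for v in sorted(variants, key=lambda v: (v.position, v.key))
            ]
        table[region.region_id] = entry
    return table


def variant_region_map(atlas: Atlas, lookup: LookupTable) -> dict[str, str]:
    """Map each variant key to the region that contains it."""
    out: dict[str, str] = {}
    for region_id, entry in lookup.items():
        for keys in entry.values():
            for k in keys:
                out[k] = region_id
    return out
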