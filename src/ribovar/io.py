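"""Readers and writers for the interchange formats.

FASTA for subunit references and extended allele sequences (record id
'<region>|<allele>'), a sidecar TSV describing alleles (variant keys,
atlas abundance), BED for region annotations (0-based half-open on disk,
1-based inclusive in memory), FASTQ for reads (gzip-transparent), and
commented TSV for all tabular outputs.  Subunit coordinates are 1-based
inclusive everywhere inside the package; every TSV written here carries a
header comment stating the tool version and that convention.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .atlas import (
    Atlas,
    AtlasAllele,
    RegionAnnotation,
    SubunitReference,
    apply_variants,
    extend_allele,
    parse_variant_key,
    AtlasError,
)
from .mapper import ReadRecord
from .twins import KinshipRecord

_HEADER = (
    f"# ribovar {__version__}; coordinates: 1-based inclusive on subunit; "
    "missing value: NA"
)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def write_atlas(atlas: Atlas, directory) -> dict[str, Path]:
    """Write an atlas as subunits.fasta, regions.bed, alleles.fasta
    (extended sequences) and alleles.tsv (sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "subunits": directory / "subunits.fasta",
        "regions": directory / "regions.bed",
        "alleles": directory / "alleles.fasta",
        "sidecar": directory / "alleles.tsv",
    }
    SeqIO.write(
        [
            SeqRecord(Seq(s.sequence), id=sid, description="")
            for sid, s in sorted(atlas.subunits.items())
        ],
        str(paths["subunits"]),
        "fasta",
    )
    with open(paths["regions"], "w") as fh:
        fh.write("# BED 0-based half-open; name=region_id; extra col=class\n")
        for r in sorted(atlas.regions, key=lambda r: (r.subunit_id, r.start)):
            fh.write(
                f"{r.subunit_id}\t{r.start - 1}\t{r.end}\t{r.region_id}\t0\t+"
                f"\t{r.region_class}\n"
            )
    SeqIO.write(
        [
            SeqRecord(Seq(a.extended_sequence), id=a.name, description="")
            for a in atlas.alleles
        ],
        str(paths["alleles"]),
        "fasta",
    )
    rows = [
        {
            "region_id": a.region_id,
            "allele_id": a.allele_id,
            "variant_keys": ",".join(v.key for v in a.variants),
            "atlas_abundance": a.atlas_abundance,
        }
        for a in atlas.alleles
    ]
    write_tsv(pd.DataFrame(rows), paths["sidecar"])
    return paths


def read_regions_bed(path) -> list[RegionAnnotation]:
    """Parse a region BED (0-based half-open on disk) to 1-based regions."""
    regions = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AtlasError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AtlasError(f"{path}:{lineno}: bad coordinates") from exc
            region_class = fields[6] if len(fields) >= 7 else "non-ES"
            regions.append(
                RegionAnnotation(
                    region_id=fields[3],
                    subunit_id=fields[0],
                    region_class=region_class,
                    start=start0 + 1,
                    end=end,
                )
            )
    return regions


def read_atlas(directory, flank_len: int = 150) -> Atlas:
    """Rebuild an atlas from the files written by :func:`write_atlas`.

    Core sequences are reconstructed by applying each allele's declared
    variants to the region reference and are verified against the
    extended sequences in alleles.fasta.
    """
    directory = Path(directory)
    subunits = {
        rec.id: SubunitReference(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(directory / "subunits.fasta"), "fasta")
    }
    regions = read_regions_bed(directory / "regions.bed")
    sidecar = read_tsv(directory / "alleles.tsv").fillna({"variant_keys": ""})
    extended = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(directory / "alleles.fasta"), "fasta")
    }
    region_by_id = {r.region_id: r for r in regions}
    alleles = []
    for _, row in sidecar.iterrows():
        region = region_by_id[row["region_id"]]
        subunit = subunits[region.subunit_id]
        keys = [k for k in str(row["variant_keys"]).split(",") if k]
        variants = tuple(parse_variant_key(k, region.subunit_id) for k in keys)
        core = apply_variants(
            subunit.slice(region.start, region.end), variants, region.start
        )
        allele = extend_allele(
            AtlasAllele(
                region_id=region.region_id,
                allele_id=str(row["allele_id"]),
                core_sequence=core,
                variants=variants,
                atlas_abundance=float(row["atlas_abundance"]),
            ),
            subunit,
            region,
            flank_len,
        )
        name = allele.name
        if name in extended and extended[name] != allele.extended_sequence:
            raise AtlasError(
                f"allele {name}: FASTA sequence disagrees with variants+reference"
            )
        alleles.append(allele)
    return Atlas(subunits=subunits, regions=regions, alleles=alleles)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")


def read_fastq(path) -> list[ReadRecord]:
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(
                ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """TSV with a provenance/convention header comment; NaN -> NA."""
    with _open_text(path, "wt") as fh:
        fh.write(_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], index_col=index_col
    )


def read_kinship(path) -> list[KinshipRecord]:
    df = read_tsv(path)
    required = {"id_a", "id_b", "kinship"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinship table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            KinshipRecord(
                id_a=str(row["id_a"]),
                id_b=str(row["id_b"]),
                kinship=float(row["kinship"]),
                birth_year_a=(
                    float(row["birth_year_a"])
                    if "birth_year_a" in df.columns and pd.notna(row["birth_year_a"])
                    else None
                ),
                birth_year_b=(
                    float(row["birth_year_b"])
                    if "birth_year_b" in df.columns and pd.notna(row["birth_year_b"])
                    else None
                ),
            )
        )
    return records
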