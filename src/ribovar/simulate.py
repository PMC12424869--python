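"""Synthetic rDNA cohorts: atlas, genomes, reads and phenotypes.

Emulates the structure of the real study system: a multi-copy 45S locus
(hundreds of tandem copies per individual) whose 18S/28S subunits are
tiled by ES / non-ES regions, each with a small set of observed alleles;
germline allele compositions shared exactly within monozygotic twin
pairs; low-frequency somatic mutations injected per copy and per
individual; per-participant copy numbers; GC-aware 150-bp reads with
two-state base qualities; and phenotypes driven linearly (traits) or
logistically (diseases) by variant frequencies and region burden.

Everything is driven by one integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .atlas import (
    Atlas,
    AtlasAllele,
    NucleotideVariant,
    RegionAnnotation,
    SubunitReference,
    apply_variants,
    normalize_variant,
)
from .mapper import ReadRecord

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Copy numbers centre on 400 (the locus is present in hundreds of
    copies); reads are 150 bp; regions are a few hundred bases so a read
    can span a whole region plus flank.  ``depth`` is reads per region
    per participant.  ``somatic_rate`` is the per-copy probability that a
    region copy carries a somatic conversion to the region's somatic-only
    allele.  ``gc_bias_strength`` > 0 down-weights sampling of GC-rich
    reads through a logistic acceptance function.
    """

    seed: int = 0
    subunit_id: str = "28S"
    n_regions: int = 3
    region_length: tuple[int, int] = (220, 320)
    alleles_per_region: int = 4  # incl. reference, excl. somatic-only
    somatic_alleles_per_region: int = 1
    max_variants_per_allele: int = 2
    germline_concentration: float = 8.0
    n_participants: int = 20
    n_twin_pairs: int = 5
    somatic_rate: float = 0.004
    cn_somatic_coupling: float = 0.0
    copy_number_mean: float = 400.0
    copy_number_sd: float = 40.0
    read_length: int = 150
    depth: int = 2000
    error_rate: float = 0.0005  # per high-quality base
    low_quality_rate: float = 0.02  # fraction of bases at the low Q state
    low_quality_error_rate: float = 0.1  # per low-quality base
    quality_high: int = 37
    quality_low: int = 10
    gc_bias_strength: float = 0.0
    n_pcs: int = 20
    n_batches: int = 3

    def __post_init__(self) -> None:
        if self.alleles_per_region < 1:
            raise ValueError("alleles_per_region must be >= 1")
        if 2 * self.n_twin_pairs > self.n_participants:
            raise ValueError("more twins than participants")
        for rate in (
            self.somatic_rate,
            self.error_rate,
            self.low_quality_rate,
            self.low_quality_error_rate,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Atlas simulation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


def _random_variant(
    rng: np.random.Generator,
    subunit_seq: str,
    region: RegionAnnotation,
    taken: set[int],
) -> NucleotideVariant | None:
    """One random SNV or short indel inside the region, canonical form.

    Positions keep a margin from region edges and from other variants of
    the same allele so that left-shift normalization cannot move a
    variant out of its region or merge events.
    """
    for _ in range(50):
        pos = int(rng.integers(region.start + 15, region.end - 15))
        if any(abs(pos - t) < 12 for t in taken):
            continue
        ref_base = subunit_seq[pos - 1]
        kind = rng.choice(["snv", "ins", "del"], p=[0.4, 0.3, 0.3])
        if kind == "snv":
            alt = rng.choice([b for b in BASES if b != ref_base])
            v = (pos, ref_base, str(alt))
        elif kind == "ins":
            ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
            v = (pos, ref_base, ref_base + ins)
        else:
            dlen = int(rng.integers(1, 4))
            v = (pos, subunit_seq[pos - 1 : pos + dlen], ref_base)
        npos, nref, nalt = normalize_variant(*v, subunit_seq)
        if not (region.start + 2 <= npos <= region.end - 6):
            continue
        if any(abs(npos - t) < 12 for t in taken):
            continue
        taken.add(npos)
        return NucleotideVariant(region.subunit_id, npos, nref, nalt)
    return None


def simulate_atlas(config: SimulationConfig, flank_len: int = 150) -> Atlas:
    """Generate a subunit reference, region tiling and region alleles.

    Regions alternate ES / non-ES.  Each region gets a reference allele,
    ``alleles_per_region - 1`` germline alleles with positive atlas
    abundance, and ``somatic_alleles_per_region`` somatic-only alleles
    (abundance 0, reachable only by somatic injection).  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    lengths = [
        int(rng.integers(*config.region_length)) for _ in range(config.n_regions)
    ]
    seq = _random_sequence(rng, sum(lengths), gc=0.55)
    subunit = SubunitReference(config.subunit_id, seq)
    regions, alleles = [], []
    start = 1
    for i, length in enumerate(lengths):
        region = RegionAnnotation(
            region_id=f"r{i + 1:02d}",
            subunit_id=config.subunit_id,
            region_class="ES" if i % 2 == 0 else "non-ES",
            start=start,
            end=start + length - 1,
        )
        regions.append(region)
        start = region.end + 1
    for region in regions:
        region_ref = subunit.slice(region.start, region.end)
        n_alt = config.alleles_per_region - 1 + config.somatic_alleles_per_region
        variant_sets: list[tuple[NucleotideVariant, ...]] = [()]
        cores = {region_ref}
        attempts = 0
        while len(variant_sets) < n_alt + 1 and attempts < 200:
            attempts += 1
            taken: set[int] = set()
            k = int(rng.integers(1, config.max_variants_per_allele + 1))
            vs = []
            for _ in range(k):
                v = _random_variant(rng, seq, region, taken)
                if v is not None:
                    vs.append(v)
            if not vs:
                continue
            vs = tuple(sorted(vs, key=lambda v: v.position))
            core = apply_variants(region_ref, vs, region.start)
            if core in cores:
                continue
            cores.add(core)
            variant_sets.append(vs)
        n_germline = config.alleles_per_region  # incl. reference
        abundances = rng.dirichlet(np.full(n_germline, 2.0))
        abundances = np.concatenate(
            [abundances, np.zeros(len(variant_sets) - n_germline)]
        )
        for j, vs in enumerate(variant_sets):
            somatic_only = j >= n_germline
            allele_id = (
                "ref"
                if j == 0
                else (f"som{j - n_germline + 1}" if somatic_only else f"alt{j}")
            )
            alleles.append(
                AtlasAllele(
                    region_id=region.region_id,
                    allele_id=allele_id,
                    core_sequence=apply_variants(region_ref, vs, region.start),
                    variants=vs,
                    atlas_abundance=float(abundances[j]),
                )
            )
    atlas = Atlas(subunits={subunit.subunit_id: subunit}, regions=regions,
                  alleles=alleles)
    atlas.validate_alleles()
    return atlas.extend_all(flank_len)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class ParticipantTruth:
    """Ground truth for one simulated participant."""

    participant_id: str
    family_id: str
    c45s: int
    copy_composition: dict[str, dict[str, int]]  # region -> allele -> copies
    true_frequencies: dict[str, float]  # variant key -> copy fraction
    true_burden: dict[str, float]  # region -> 1 - major-allele copy fraction
    covariates: dict[str, object] = field(default_factory=dict)


def _truth_from_composition(
    atlas: Atlas, composition: dict[str, dict[str, int]]
) -> tuple[dict[str, float], dict[str, float]]:
    freqs: dict[str, float] = {}
    burden: dict[str, float] = {}
    for region in atlas.regions:
        rid = region.region_id
        counts = composition[rid]
        total = sum(counts.values())
        by_variant: dict[str, float] = {}
        for a in atlas.region_alleles(rid):
            c = counts.get(a.allele_id, 0)
            for v in a.variants:
                by_variant[v.key] = by_variant.get(v.key, 0.0) + c
        for a in atlas.region_alleles(rid):
            for v in a.variants:
                by_variant.setdefault(v.key, 0.0)
        for key, c in by_variant.items():
            freqs[key] = c / total if total else float("nan")
        burden[rid] = 1.0 - (max(counts.values()) / total if total else float("nan"))
    return freqs, burden


def simulate_cohort(
    atlas: Atlas, config: SimulationConfig
) -> list[ParticipantTruth]:
    """Draw per-participant 45S copy compositions, twins first.

    Twin pairs share the germline copy composition and copy number
    exactly; somatic conversions are then injected independently per
    individual: each copy switches to one of the region's somatic-only
    alleles with probability ``somatic_rate`` (optionally scaled by the
    participant's copy-number deviation via ``cn_somatic_coupling``).
    """
    rng = np.random.default_rng(config.seed + 1)
    germline_abund = {
        r.region_id: np.array(
            [
                a.atlas_abundance
                for a in atlas.region_alleles(r.region_id)
                if a.atlas_abundance > 0 or a.is_reference
            ]
        )
        for r in atlas.regions
    }
    germline_ids = {
        r.region_id: [
            a.allele_id
            for a in atlas.region_alleles(r.region_id)
            if a.atlas_abundance > 0 or a.is_reference
        ]
        for r in atlas.regions
    }
    somatic_ids = {
        r.region_id: [
            a.allele_id
            for a in atlas.region_alleles(r.region_id)
            if a.atlas_abundance == 0 and not a.is_reference
        ]
        for r in atlas.regions
    }

    def germline_genome() -> tuple[int, dict[str, dict[str, int]]]:
        cn = max(50, int(round(rng.normal(config.copy_number_mean,
                                          config.copy_number_sd))))
        comp: dict[str, dict[str, int]] = {}
        for region in atlas.regions:
            rid = region.region_id
            base = germline_abund[rid]
            probs = base / base.sum() if base.sum() > 0 else np.full(
                len(base), 1.0 / len(base)
            )
            indiv = rng.dirichlet(probs * config.germline_concentration + 1e-3)
            counts = rng.multinomial(cn, indiv)
            comp[rid] = {
                aid: int(c) for aid, c in zip(germline_ids[rid], counts)
            }
        return cn, comp

    def inject_somatic(
        cn: int, comp: dict[str, dict[str, int]]
    ) -> dict[str, dict[str, int]]:
        rate = config.somatic_rate
        if config.cn_somatic_coupling:
            z = (cn - config.copy_number_mean) / max(config.copy_number_sd, 1e-9)
            rate = float(np.clip(rate * (1.0 + config.cn_somatic_coupling * z),
                                 0.0, 1.0))
        out: dict[str, dict[str, int]] = {}
        for rid, counts in comp.items():
            new = dict(counts)
            sinks = somatic_ids[rid]
            if sinks and rate > 0:
                for aid in list(new):
                    n_mut = rng.binomial(new[aid], rate)
                    if n_mut:
                        new[aid] -= n_mut
                        for _ in range(n_mut):
                            sink = sinks[int(rng.integers(len(sinks)))]
                            new[sink] = new.get(sink, 0) + 1
            for sink in sinks:
                new.setdefault(sink, 0)
            out[rid] = new
        return out

    truths: list[ParticipantTruth] = []
    pid = 0

    def covariates() -> dict[str, object]:
        cov = {
            "age": float(rng.uniform(40, 70)),
            "sex": int(rng.integers(0, 2)),
            "batch": f"B{int(rng.integers(1, config.n_batches + 1))}",
        }
        for i in range(1, config.n_pcs + 1):
            cov[f"pc{i}"] = float(rng.normal())
        return cov

    for fam in range(config.n_twin_pairs):
        cn, germ = germline_genome()
        for _ in range(2):
            pid += 1
            comp = inject_somatic(cn, germ)
            freqs, burden = _truth_from_composition(atlas, comp)
            cov = covariates()
            cov["rdna_cn"] = float(cn)
            truths.append(
                ParticipantTruth(
                    participant_id=f"P{pid:04d}",
                    family_id=f"F{fam + 1:03d}",
                    c45s=cn,
                    copy_composition=comp,
                    true_frequencies=freqs,
                    true_burden=burden,
                    covariates=cov,
                )
            )
    while pid < config.n_participants:
        pid += 1
        cn, germ = germline_genome()
        comp = inject_somatic(cn, germ)
        freqs, burden = _truth_from_composition(atlas, comp)
        cov = covariates()
        cov["rdna_cn"] = float(cn)
        truths.append(
            ParticipantTruth(
                participant_id=f"P{pid:04d}",
                family_id=f"S{pid:04d}",
                c45s=cn,
                copy_composition=comp,
                true_frequencies=freqs,
                true_burden=burden,
                covariates=cov,
            )
        )
    return truths


def twin_pairs_of(truths: Sequence[ParticipantTruth]) -> list[tuple[str, str]]:
    by_family: dict[str, list[str]] = {}
    for t in truths:
        if t.family_id.startswith("F"):
            by_family.setdefault(t.family_id, []).append(t.participant_id)
    return [tuple(sorted(v)) for _, v in sorted(by_family.items()) if len(v) == 2]


def kinship_table(
    truths: Sequence[ParticipantTruth],
    config: SimulationConfig,
    n_unrelated_pairs: int = 20,
) -> pd.DataFrame:
    """Kinship records: MZ twins near 0.5, random unrelated pairs near 0."""
    rng = np.random.default_rng(config.seed + 2)
    birth_year = {
        t.participant_id: int(2024 - round(t.covariates["age"])) for t in truths
    }
    rows = []
    for a, b in twin_pairs_of(truths):
        rows.append(
            {
                "id_a": a,
                "id_b": b,
                "kinship": float(np.clip(rng.normal(0.5, 0.02), 0.0, 0.6)),
                "birth_year_a": birth_year[a],
                "birth_year_b": birth_year[b],
            }
        )
        birth_year[b] = birth_year[a]  # twins share a birth year
    ids = [t.participant_id for t in truths]
    twin_ids = {x for pair in twin_pairs_of(truths) for x in pair}
    for _ in range(n_unrelated_pairs):
        a, b = rng.choice(ids, size=2, replace=False)
        if a in twin_ids and b in twin_ids:
            continue
        rows.append(
            {
                "id_a": str(a),
                "id_b": str(b),
                "kinship": float(rng.uniform(0.0, 0.08)),
                "birth_year_a": birth_year[str(a)],
                "birth_year_b": birth_year[str(b)],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def simulate_reads(
    truth: ParticipantTruth,
    atlas: Atlas,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Error-prone 150-bp reads from a participant's allele copies.

    Source alleles are sampled proportionally to copy number times the
    number of valid start positions on the extended sequence; start
    positions are uniform; strands are random.  Base qualities are
    two-state (high/low); sequencing errors occur at state-specific
    rates.  With ``gc_bias_strength`` g > 0, a candidate read with GC
    fraction x is accepted with probability sigmoid(-g * (x - 0.5)),
    which down-weights GC-rich windows (at g = 0 acceptance is uniform).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    L = config.read_length
    sources: list[tuple[AtlasAllele, int]] = []
    weights = []
    for region in atlas.regions:
        for a in atlas.region_alleles(region.region_id):
            copies = truth.copy_composition[region.region_id].get(a.allele_id, 0)
            n_pos = len(a.extended_sequence) - L + 1
            if copies > 0 and n_pos > 0:
                sources.append((a, n_pos))
                weights.append(copies * n_pos)
    if not sources:
        return []
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    n_target = config.depth * len(atlas.regions)
    reads: list[ReadRecord] = []
    i = 0
    while len(reads) < n_target:
        i += 1
        allele, n_pos = sources[int(rng.choice(len(sources), p=w))]
        start = int(rng.integers(n_pos))
        frag = allele.extended_sequence[start : start + L]
        if config.gc_bias_strength > 0:
            accept = expit(-config.gc_bias_strength * (_gc_fraction(frag) - 0.5))
        else:
            accept = 0.5
        if rng.random() > accept:
            continue
        if rng.random() < 0.5:
            frag = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        low = rng.random(L) < config.low_quality_rate
        quals = np.where(low, config.quality_low, config.quality_high)
        err_p = np.where(low, config.low_quality_error_rate, config.error_rate)
        errs = rng.random(L) < err_p
        if errs.any():
            bases = list(frag)
            for j in np.flatnonzero(errs):
                bases[j] = rng.choice([b for b in BASES if b != bases[j]])
            frag = "".join(bases)
        # provenance is embedded in the read id so downstream tests can
        # compare calls against the true source allele
        reads.append(
            ReadRecord(
                read_id=(
                    f"{truth.participant_id}:{len(reads):07d}"
                    f"|{allele.region_id}|{allele.allele_id}|{start}"
                ),
                sequence=frag,
                qualities=tuple(int(q) for q in quals),
            )
        )
    return reads


def read_provenance(read_id: str) -> tuple[str, str, int] | None:
    """(region_id, allele_id, start) encoded in a simulated read id."""
    parts = read_id.split("|")
    if len(parts) != 4:
        return None
    return parts[1], parts[2], int(parts[3])


# ---------------------------------------------------------------------------
# Count-level frequency sampling (fast path for cohort-scale statistics)
# ---------------------------------------------------------------------------

def sample_observed_frequencies(
    truths: Sequence[ParticipantTruth],
    depth: float | Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Binomial read-sampling noise on true variant frequencies.

    Observed frequency = Binomial(depth_v, pi) / depth_v per participant
    and variant — the sampling distribution the full read pipeline
    converges to when reads are error-free and span their region.
    ``depth`` may be a scalar or a per-variant-key mapping.
    """
    rng = np.random.default_rng(seed)
    keys = sorted(truths[0].true_frequencies)
    depths = (
        {k: float(depth) for k in keys}
        if np.isscalar(depth)
        else {k: float(depth[k]) for k in keys}
    )
    rows = {}
    for t in truths:
        rows[t.participant_id] = {
            k: rng.binomial(int(depths[k]), t.true_frequencies[k]) / depths[k]
            for k in keys
        }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=keys)
    out.index.name = "participant_id"
    return out


def simulate_twin_frequency_study(
    n_pairs: int,
    n_germline: int,
    n_somatic: int,
    depth: float | Sequence[float],
    seed: int,
    germline_beta: tuple[float, float] = (2.0, 4.0),
    somatic_mean: float = 0.01,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.Series, pd.Series]:
    """Direct count-level twin study with labelled variant classes.

    Germline variants: one true frequency per pair drawn from
    Beta(*germline_beta*), shared by both twins.  Somatic variants: an
    independent per-individual frequency with mean ``somatic_mean``
    (Gamma-distributed, clipped to [0, 1]) — no twin resemblance at all.
    Observed values add Binomial(depth) sampling noise.  Returns
    (frequency table, pairs, class labels 'germline'/'somatic' per
    variant, per-variant depth).
    """
    rng = np.random.default_rng(seed)
    keys = [f"g{i:04d}" for i in range(n_germline)] + [
        f"s{i:04d}" for i in range(n_somatic)
    ]
    labels = pd.Series(
        ["germline"] * n_germline + ["somatic"] * n_somatic, index=keys,
        name="class",
    )
    if np.isscalar(depth):
        depth_per_variant = pd.Series(float(depth), index=keys, name="depth")
    else:
        depth_per_variant = pd.Series(
            np.asarray(depth, dtype=float), index=keys, name="depth"
        )
    ids = []
    pairs = []
    rows = []
    for p in range(n_pairs):
        a, b = f"T{p:04d}a", f"T{p:04d}b"
        pairs.append((a, b))
        ids.extend([a, b])
        germ = rng.beta(*germline_beta, size=n_germline)
        for _ in range(2):
            som = np.clip(
                rng.gamma(shape=1.0, scale=somatic_mean, size=n_somatic), 0, 1
            )
            rows.append(np.concatenate([germ, som]))
    true = np.vstack(rows)
    d = depth_per_variant.to_numpy()
    observed = rng.binomial(d.astype(int)[None, :].repeat(len(ids), 0), true) / d
    freq = pd.DataFrame(observed, index=ids, columns=keys)
    freq.index.name = "participant_id"
    return freq, pairs, labels, depth_per_variant


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def covariate_table(truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    out = pd.DataFrame(
        {t.participant_id: t.covariates for t in truths}
    ).T.infer_objects()
    out.index.name = "participant_id"
    return out


def simulate_phenotypes(
    truths: Sequence[ParticipantTruth],
    trait_effects: Mapping[str, Mapping[str, float]],
    seed: int,
    noise_sd: float = 1.0,
    disease_effects: Mapping[str, Mapping[str, float]] | None = None,
    disease_prevalence: float = 0.1,
    covariate_effects: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Traits and disease indicators driven by true variant frequencies.

    ``trait_effects`` maps trait name -> {variant key: beta}; each trait
    is sum(beta x true frequency) + covariate effects + N(0, noise_sd).
    ``disease_effects`` maps disease name -> {region id: log-odds per
    burden unit}; the logistic intercept is set so the expected
    prevalence matches ``disease_prevalence``.  All draws are seeded.
    """
    rng = np.random.default_rng(seed)
    cov_eff = dict(covariate_effects or {"age": 0.01, "sex": 0.2})
    ids = [t.participant_id for t in truths]
    cov = covariate_table(truths)
    known_keys = set(truths[0].true_frequencies)
    traits = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    for name, effects in trait_effects.items():
        unknown = set(effects) - known_keys
        if unknown:
            raise ValueError(f"trait {name!r}: unknown variant keys {sorted(unknown)}")
        vals = []
        for t in truths:
            v = sum(b * t.true_frequencies[k] for k, b in effects.items())
            v += sum(c * float(cov.loc[t.participant_id, col])
                     for col, c in cov_eff.items())
            vals.append(v)
        traits[name] = np.asarray(vals) + rng.normal(0, noise_sd, size=len(ids))
    diseases = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    for name, effects in (disease_effects or {}).items():
        lp = np.array(
            [
                sum(b * t.true_burden[r] for r, b in effects.items())
                + sum(
                    c * float(cov.loc[t.participant_id, col])
                    for col, c in cov_eff.items()
                )
                for t in truths
            ]
        )
        intercept = np.log(disease_prevalence / (1 - disease_prevalence)) - lp.mean()
        diseases[name] = rng.binomial(1, expit(intercept + lp))
    return traits, diseases
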