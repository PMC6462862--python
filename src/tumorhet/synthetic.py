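"""Synthetic multi-region cohort generator with known ground truth.

Emulates the data shape of a multi-region tumor WGS study — several sampled
regions per patient, cellularity-scaled read counts at ~150x, a large truncal
mutation load with smaller private branches, per-branch signature mixtures,
CNV/LOH segments, and germline DNA-repair variants whose presence raises the
trunk's tobacco-signature exposure (the gene-by-environment effect the
statistics stage is meant to recover).

Everything is seeded and deterministic.  The generator does not simulate
reads (no FASTQ/BAM), structural variants, or realistic indels (indels are
1-bp insertions, present for counting only).  Somatic SNV read counts assume
a diploid heterozygous state regardless of the simulated CNV segments; only
germline-het sites feel the LOH segments, which is the part the allelic
stage consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .signatures import (
    BASES,
    SUBSTITUTIONS,
    SignatureCatalog,
    revcomp,
)
from .types import AnnotatedVariant, CNVSegment, Cohort, Patient, RegionSample
from . import vcfio

_PYRIMIDINES = "CT"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GermlineConfig:
    """Germline repair-variant injection and its coupling to tobacco exposure.

    A patient is germline-mutant with probability ``p_mutant``; mutant
    patients draw their truncal tobacco fraction from
    N(tobacco_fraction_mutant, sd), wild-type from N(tobacco_fraction_wt, sd)
    (clipped to a proper proportion).  ``n_benign_decoys`` germline records
    that fail the repair filter are added per patient so the filter has
    something to reject.
    """

    p_mutant: float = 0.5
    tobacco_fraction_mutant: float = 0.5
    tobacco_fraction_wt: float = 0.2
    tobacco_fraction_sd: float = 0.1
    n_benign_decoys: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mutant <= 1.0:
            raise ConfigError("p_mutant must be in [0, 1]")
        for name in ("tobacco_fraction_mutant", "tobacco_fraction_wt"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.tobacco_fraction_sd < 0:
            raise ConfigError("tobacco_fraction_sd must be non-negative")


@dataclass
class SimConfig:
    """Study-condition parameters for the cohort generator.

    Defaults mirror the emulated study design at desk scale: three regions
    per patient at 150x mean depth, cellularity uniform on (0.4, 0.9), a
    dominantly truncal architecture (80% truncal), 10-60 pack-years, and a
    0.001 per-base error rate for absent-site noise.
    """

    n_patients: int = 4
    regions_per_patient: int = 3
    n_somatic: int = 1000
    truncal_fraction: float = 0.8
    branch_exposures: Optional[dict[str, dict[str, float]]] = None
    cellularity: float | tuple[float, float] = (0.4, 0.9)
    mean_depth: float = 150.0
    sequencing_error: float = 0.001
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    pack_years_range: tuple[float, float] = (10.0, 60.0)
    callable_mb: float = 100.0
    reference_length: int = 100_000
    gc_fraction: float = 0.41
    n_germline_hets: int = 60
    indel_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.germline, dict):
            self.germline = GermlineConfig(**self.germline)
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.regions_per_patient < 1:
            raise ConfigError("regions_per_patient must be >= 1")
        if self.n_somatic < 0:
            raise ConfigError("n_somatic must be >= 0")
        if not 0.0 <= self.truncal_fraction <= 1.0:
            raise ConfigError("truncal_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if not 0.0 <= self.sequencing_error <= 1.0:
            raise ConfigError("sequencing_error must be in [0, 1]")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0, 1]")
        if self.callable_mb <= 0:
            raise ConfigError("callable_mb must be positive")
        if self.reference_length < 3:
            raise ConfigError("reference_length must be >= 3")
        lo, hi = self._cellularity_range()
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("cellularity must lie in (0, 1]")
        if self.branch_exposures is not None:
            expected = {"truncal"} | {f"R{i+1}" for i in range(self.regions_per_patient)}
            if set(self.branch_exposures) != expected:
                raise ConfigError(
                    f"branch_exposures labels {sorted(self.branch_exposures)} do not "
                    f"match required labels {sorted(expected)}"
                )
            for label, mixture in self.branch_exposures.items():
                total = sum(mixture.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(f"branch {label!r} exposures sum to {total}, not 1")
                if any(v < 0 for v in mixture.values()):
                    raise ConfigError(f"branch {label!r} has negative exposure")

    def _cellularity_range(self) -> tuple[float, float]:
        if isinstance(self.cellularity, (tuple, list)):
            lo, hi = self.cellularity
            return float(lo), float(hi)
        return float(self.cellularity), float(self.cellularity)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cellularity"] = list(self._cellularity_range())
        d["pack_years_range"] = list(self.pack_years_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "cellularity" in d and isinstance(d["cellularity"], list):
            d["cellularity"] = tuple(d["cellularity"])
        if "pack_years_range" in d and isinstance(d["pack_years_range"], list):
            d["pack_years_range"] = tuple(d["pack_years_range"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a key/value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class GroundTruth:
    """Per-variant, per-branch, per-segment and per-patient truth tables."""

    variants: pd.DataFrame
    exposures: pd.DataFrame
    cnv: pd.DataFrame
    patients: pd.DataFrame

    _FILES = {
        "variants": "truth_variants.tsv",
        "exposures": "truth_exposures.tsv",
        "cnv": "truth_cnv.tsv",
        "patients": "truth_patients.tsv",
    }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for attr, filename in self._FILES.items():
            getattr(self, attr).to_csv(out_dir / filename, sep="\t", index=False)

    @classmethod
    def read(cls, out_dir: str | Path) -> "GroundTruth":
        out_dir = Path(out_dir)
        frames = {}
        for attr, filename in cls._FILES.items():
            path = out_dir / filename
            if not path.exists():
                raise FileNotFoundError(f"missing ground-truth table {path}")
            frames[attr] = pd.read_csv(path, sep="\t")
        return cls(**frames)


# ---------------------------------------------------------------------------
# Reference sequence and trinucleotide-context index
# ---------------------------------------------------------------------------

def generate_reference(length_bp: int, gc_fraction: float, seed: int) -> str:
    """Random reference sequence with the requested GC content."""
    if length_bp < 3:
        raise ValueError("length_bp must be >= 3")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list("ACGT"), size=length_bp, p=[at, gc, gc, at])
    return "".join(bases)


class ReferenceContextIndex:
    """Positions of each pyrimidine-centered trinucleotide in a reference.

    Supports sampling variant positions without replacement so one reference
    can host several branches' mutations with no positional collisions.
    Positions are 0-based internally; emitted variants are 1-based.
    """

    def __init__(self, sequence: str, chrom: str = "chr1"):
        self.sequence = sequence.upper()
        self.chrom = chrom
        self._avail: dict[str, list[int]] = {}
        self._used = np.zeros(len(sequence), dtype=bool)
        for pos0 in range(1, len(self.sequence) - 1):
            tri = self.sequence[pos0 - 1 : pos0 + 2]
            if any(b not in "ACGT" for b in tri):
                continue
            key = tri if tri[1] in _PYRIMIDINES else revcomp(tri)
            self._avail.setdefault(key, []).append(pos0)

    def n_available(self, context: str) -> int:
        return len(self._avail.get(context, []))

    def sample_channels(
        self, channel_counts: Sequence[int], rng: np.random.Generator
    ) -> list[tuple[int, str, str]]:
        """Draw (pos0, ref, alt) for the requested per-channel counts."""
        draws: list[tuple[int, str, str]] = []
        for channel_idx, count in enumerate(channel_counts):
            if count == 0:
                continue
            sub = SUBSTITUTIONS[channel_idx // 16]
            five = BASES[(channel_idx % 16) // 4]
            three = BASES[channel_idx % 4]
            context = five + sub[0] + three
            avail = self._avail.get(context, [])
            if count > len(avail):
                raise ValueError(
                    f"reference exhausted for context {context}: "
                    f"need {count}, have {len(avail)}"
                )
            chosen_idx = rng.choice(len(avail), size=count, replace=False)
            chosen = [avail[i] for i in chosen_idx]
            for i in sorted(chosen_idx, reverse=True):
                avail.pop(i)
            for pos0 in chosen:
                self._used[pos0] = True
                if self.sequence[pos0] in _PYRIMIDINES:
                    ref, alt = sub[0], sub[2]
                else:
                    ref, alt = revcomp(sub[0]), revcomp(sub[2])
                draws.append((pos0, ref, alt))
        return draws

    def take_unused_position(self, rng: np.random.Generator) -> int:
        """Random interior position not yet holding a variant (0-based)."""
        upper = len(self.sequence) - 1
        for _ in range(10_000):
            pos0 = int(rng.integers(1, upper))
            if not self._used[pos0]:
                self._used[pos0] = True
                return pos0
        raise ValueError("reference exhausted: no unused interior positions left")


def draw_mutations(
    n: int,
    exposures: Sequence[float],
    catalog: SignatureCatalog,
    reference: str,
    seed: Optional[int] = None,
    chrom: str = "chr1",
    rng: Optional[np.random.Generator] = None,
    index: Optional[ReferenceContextIndex] = None,
) -> list[AnnotatedVariant]:
    """Draw SNVs whose 96-channel spectrum follows catalog^T . exposures.

    Channels are drawn multinomially from the mixture distribution; each
    mutation lands on a reference position whose trinucleotide context
    matches its channel (reverse-complemented for purine-reference sites).
    """
    if n == 0:
        return []
    if catalog.n_signatures == 0:
        raise ValueError("cannot draw mutations from an empty catalog")
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (catalog.n_signatures,):
        raise ValueError("exposures length must equal the number of catalog signatures")
    if abs(exposures.sum() - 1.0) > 1e-9:
        raise ValueError("exposures must sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if index is None:
        index = ReferenceContextIndex(reference, chrom)
    probs = exposures @ catalog.matrix
    probs = probs / probs.sum()
    channel_counts = rng.multinomial(n, probs)
    variants = []
    for pos0, ref, alt in index.sample_channels(channel_counts, rng):
        variants.append(AnnotatedVariant(chrom=index.chrom, pos=pos0 + 1, ref=ref, alt=alt))
    return variants


def assign_read_counts(
    present: bool,
    depth_mean: float,
    cellularity: float,
    tumor_alt_copies: int,
    tumor_total_copies: int,
    error_rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    germline_alt_copies: int = 0,
) -> tuple[int, int]:
    """Simulate (alt_reads, total_reads) for one site in one region.

    Total depth is Poisson around ``depth_mean``; alt reads are binomial at
    the expected VAF of the mixture (error-adjusted), or at ``error_rate``
    alone when the variant is absent.  Zero drawn depth returns (0, 0) — the
    VAF is undefined there and downstream calls treat it as missing.
    """
    from .allelic import expected_vaf

    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = int(rng.poisson(depth_mean))
    if total == 0:
        return (0, 0)
    if present:
        vaf = expected_vaf(cellularity, germline_alt_copies, tumor_alt_copies, tumor_total_copies)
        if math.isnan(vaf):
            vaf = 0.0
        p = vaf * (1.0 - error_rate) + (1.0 - vaf) * error_rate
    else:
        p = error_rate
    alt = int(rng.binomial(total, p))
    return (alt, total)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_HISTOTYPES = ("LUAD", "LUSC", "SCLC")
_HISTOTYPE_PROBS = (0.5, 0.3, 0.2)

# non-tobacco remainder of the truncal mixture, renormalized to (1 - tobacco)
_TRUNK_REMAINDER = {
    "clock-like": 0.45,
    "apobec-like": 0.20,
    "hrd-like": 0.10,
    "poleta-like": 0.05,
    "background": 0.20,
}

_PRIVATE_DOMINANT_CHOICES = ("clock-like", "apobec-like", "hrd-like", "poleta-like")


def _trunk_mixture(tobacco_fraction: float) -> dict[str, float]:
    mixture = {"tobacco-like": tobacco_fraction}
    for name, weight in _TRUNK_REMAINDER.items():
        mixture[name] = weight * (1.0 - tobacco_fraction)
    return mixture


def _private_mixture(dominant: str) -> dict[str, float]:
    mixture = {name: 0.0 for name in ["tobacco-like", *_TRUNK_REMAINDER]}
    mixture[dominant] = 0.7
    others = [n for n in mixture if n != dominant]
    for name in others:
        mixture[name] += 0.3 / len(others)
    return mixture


def _mixture_vector(mixture: Mapping[str, float], catalog: SignatureCatalog) -> np.ndarray:
    vec = np.zeros(catalog.n_signatures)
    for name, weight in mixture.items():
        if name not in catalog.names:
            raise ConfigError(f"exposure references unknown signature {name!r}")
        vec[catalog.names.index(name)] = weight
    return vec


def _segment_template(length: int) -> list[tuple[int, int]]:
    """Fixed 4-segment layout (1-based inclusive) over the reference."""
    bounds = [0, int(0.3 * length), int(0.55 * length), int(0.8 * length), length]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(4)]


def _simulate_patient_cnv(
    rng: np.random.Generator, regions: list[str], length: int
) -> dict[str, list[CNVSegment]]:
    """Per-region CNV profiles: one candidate-event slot, one LOH slot."""
    template = _segment_template(length)
    states: dict[str, list[tuple[int, Optional[int]]]] = {r: [] for r in regions}

    # slot 0 and 3: neutral everywhere
    # slot 1: candidate high/zero CN event
    event_cn: Optional[int] = None
    if rng.random() < 0.7:
        event_cn = int(rng.choice([0, 7, 8]))
    event_regions = set()
    if event_cn is not None:
        if rng.random() < 0.5:
            event_regions = set(regions)
        else:
            event_regions = {regions[int(rng.integers(len(regions)))]}

    # slot 2: LOH event (hemizygous loss or copy-neutral)
    loh_state: Optional[tuple[int, int]] = None
    if rng.random() < 0.6:
        loh_state = (1, 0) if rng.random() < 0.5 else (2, 0)
    loh_regions = set()
    if loh_state is not None:
        if rng.random() < 0.5:
            loh_regions = set(regions)
        else:
            loh_regions = {regions[int(rng.integers(len(regions)))]}

    for region in regions:
        for slot, (start, end) in enumerate(template):
            cn, minor = 2, 1
            if slot == 1 and region in event_regions and event_cn is not None:
                cn, minor = event_cn, 0 if event_cn == 0 else min(1, event_cn)
            if slot == 2 and region in loh_regions and loh_state is not None:
                cn, minor = loh_state
            states[region].append((cn, minor))

    profiles = {}
    for region in regions:
        profiles[region] = [
            CNVSegment("chr1", start, end, cn, minor)
            for (start, end), (cn, minor) in zip(template, states[region])
        ]
    return profiles


def _segment_state_at(
    profile: Sequence[CNVSegment], pos: int
) -> tuple[int, Optional[int]]:
    for seg in profile:
        if seg.overlaps(pos):
            return seg.copy_number, seg.minor_cn
    return 2, 1


def truncal_private_split(
    n_somatic: int, truncal_fraction: float, regions: Sequence[str]
) -> dict[str, int]:
    """Exact branch-count partition: half-up-rounded truncal count, private
    remainder spread as evenly as possible in region order."""
    if len(regions) == 1:
        return {"truncal": n_somatic}
    counts = {"truncal": _round_half_up(truncal_fraction * n_somatic)}
    n_private = n_somatic - counts["truncal"]
    base, rem = divmod(n_private, len(regions))
    for i, region in enumerate(regions):
        counts[region] = base + (1 if i < rem else 0)
    return counts


def simulate_cohort(
    config: SimConfig,
    catalog: Optional[SignatureCatalog] = None,
) -> tuple[Cohort, GroundTruth, dict[str, str]]:
    """Generate a full synthetic cohort and its ground truth.

    Returns the in-memory cohort, the truth tables, and the reference as a
    chrom->sequence mapping.  Use :func:`write_cohort` to serialize.
    """
    if catalog is None:
        catalog = vcfio.default_catalog()
    seed_seq = np.random.SeedSequence(config.seed)
    ref_seed, *patient_seeds = seed_seq.spawn(config.n_patients + 1)
    reference = generate_reference(
        config.reference_length, config.gc_fraction, np.random.default_rng(ref_seed).integers(2**31)
    )
    refmap = {"chr1": reference}
    repair_genes = sorted(vcfio.default_gene_list("repair"))
    driver_genes = sorted(vcfio.default_gene_list("drivers"))

    cohort = Cohort()
    truth_variant_rows: list[dict] = []
    truth_exposure_rows: list[dict] = []
    truth_cnv_rows: list[dict] = []
    truth_patient_rows: list[dict] = []

    lo_cell, hi_cell = config._cellularity_range()
    region_labels = [f"R{i+1}" for i in range(config.regions_per_patient)]

    for p_idx in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[p_idx])
        pid = f"P{p_idx+1:02d}"
        cellularities = {
            r: float(rng.uniform(lo_cell, hi_cell)) if hi_cell > lo_cell else lo_cell
            for r in region_labels
        }
        regions = [RegionSample(r, cellularities[r]) for r in region_labels]
        pack_years = float(rng.uniform(*config.pack_years_range))
        smoking_status = "current" if rng.random() < 0.3 else "former"
        histotype = str(rng.choice(_HISTOTYPES, p=_HISTOTYPE_PROBS))
        germline_mutant = bool(rng.random() < config.germline.p_mutant)

        # branch exposure mixtures
        if config.branch_exposures is not None:
            mixtures = {k: dict(v) for k, v in config.branch_exposures.items()}
            tobacco_fraction = mixtures["truncal"].get("tobacco-like", 0.0)
        else:
            mean = (
                config.germline.tobacco_fraction_mutant
                if germline_mutant
                else config.germline.tobacco_fraction_wt
            )
            tobacco_fraction = float(
                np.clip(rng.normal(mean, config.germline.tobacco_fraction_sd), 0.02, 0.95)
            )
            mixtures = {"truncal": _trunk_mixture(tobacco_fraction)}
            for region in region_labels:
                dominant = str(rng.choice(_PRIVATE_DOMINANT_CHOICES))
                mixtures[region] = _private_mixture(dominant)

        branch_counts = truncal_private_split(
            config.n_somatic, config.truncal_fraction, region_labels
        )

        index = ReferenceContextIndex(reference)
        patient = Patient(
            patient_id=pid,
            regions=regions,
            histotype=histotype,
            smoking_status=smoking_status,
            pack_years=pack_years,
        )

        # CNV profiles first so germline-het read counts can honor LOH state
        patient.cnv = _simulate_patient_cnv(rng, region_labels, config.reference_length)
        for region, profile in patient.cnv.items():
            for seg in profile:
                truth_cnv_rows.append(
                    {
                        "patient_id": pid,
                        "region_id": region,
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "copy_number": seg.copy_number,
                        "minor_cn": seg.minor_cn,
                        "loh": bool(seg.minor_cn == 0 and seg.copy_number > 0),
                    }
                )

        # somatic variants per branch
        for branch, count in branch_counts.items():
            mixture = mixtures.get(branch) if len(region_labels) > 1 else mixtures["truncal"]
            exposure_vec = _mixture_vector(mixture, catalog)
            n_indel = _round_half_up(config.indel_fraction * count)
            n_snv = count - n_indel
            branch_variants = draw_mutations(
                n_snv, exposure_vec, catalog, reference, rng=rng, index=index
            )
            for _ in range(n_indel):
                pos0 = index.take_unused_position(rng)
                base = reference[pos0]
                branch_variants.append(
                    AnnotatedVariant(chrom="chr1", pos=pos0 + 1, ref=base, alt=base + "A")
                )
            for v in branch_variants:
                v.qss = float(np.round(rng.uniform(16, 60), 1))
                if rng.random() < 0.05:  # a tail of low-quality calls
                    v.qss = float(np.round(rng.uniform(2, 15), 1))
                present_regions = (
                    set(region_labels) if branch == "truncal" else {branch}
                )
                for region in region_labels:
                    v.per_region_support[region] = assign_read_counts(
                        present=region in present_regions,
                        depth_mean=config.mean_depth,
                        cellularity=cellularities[region],
                        tumor_alt_copies=1,
                        tumor_total_copies=2,
                        error_rate=config.sequencing_error,
                        rng=rng,
                    )
                truth_variant_rows.append(
                    {
                        "patient_id": pid,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "vtype": v.vtype,
                        "branch": branch,
                    }
                )
            patient.somatic.extend(branch_variants)
            for name, weight in mixtures[
                branch if len(region_labels) > 1 else "truncal"
            ].items():
                truth_exposure_rows.append(
                    {
                        "patient_id": pid,
                        "branch": branch,
                        "signature": name,
                        "fraction": weight,
                    }
                )

        # driver annotations on a couple of truncal variants
        truncal_snvs = [
            v for v in patient.somatic[: branch_counts["truncal"]] if v.is_snv
        ]
        for v in truncal_snvs[:2]:
            v.gene = str(rng.choice(driver_genes))
            v.impact = str(rng.choice(["HIGH", "MODERATE"]))
            v.cadd = float(np.round(rng.uniform(10, 35), 2))
            v.qss = float(np.round(rng.uniform(20, 60), 1))
            v.pop_af = 1e-4

        # germline repair variant (mutant patients) + decoys + het SNP panel
        def _germline_support(
            pos: int, loh_aware: bool
        ) -> dict[str, tuple[int, int]]:
            support = {
                "germline": assign_read_counts(
                    True, 35.0, 0.0, 1, 2, config.sequencing_error,
                    rng=rng, germline_alt_copies=1,
                )
            }
            lost_alt = bool(rng.random() < 0.5)
            for region in region_labels:
                c_alt, c_tot = 1, 2
                if loh_aware:
                    cn, minor = _segment_state_at(patient.cnv[region], pos)
                    if minor == 0 and cn > 0:  # LOH in this region
                        c_tot = cn
                        c_alt = 0 if lost_alt else cn
                    elif cn == 0:
                        c_alt, c_tot = 0, 0
                support[region] = assign_read_counts(
                    True,
                    config.mean_depth,
                    cellularities[region],
                    c_alt,
                    c_tot,
                    config.sequencing_error,
                    rng=rng,
                    germline_alt_copies=1,
                )
            return support

        if germline_mutant:
            pos0 = index.take_unused_position(rng)
            evidence = int(rng.integers(3))
            variant = AnnotatedVariant(
                chrom="chr1",
                pos=pos0 + 1,
                ref=reference[pos0],
                alt="A" if reference[pos0] != "A" else "G",
                gene=str(rng.choice(repair_genes)),
                impact="MODERATE",
                pop_af=float(np.round(rng.uniform(0.0001, 0.019), 5)),
                clinvar="pathogenic" if evidence == 0 else "none",
                pfam_domain=evidence == 1,
                predictor_calls=(
                    {"SIFT": "damaging"}
                    if evidence == 1
                    else {"PROVEAN": "damaging", "PolyPhen": "damaging"}
                    if evidence == 2
                    else {}
                ),
                per_region_support=_germline_support(pos0 + 1, loh_aware=True),
            )
            patient.germline.append(variant)

        decoy_kinds = ["benign_predictors", "common_af", "non_repair_gene"]
        for d in range(config.germline.n_benign_decoys):
            pos0 = index.take_unused_position(rng)
            kind = decoy_kinds[d % len(decoy_kinds)]
            patient.germline.append(
                AnnotatedVariant(
                    chrom="chr1",
                    pos=pos0 + 1,
                    ref=reference[pos0],
                    alt="C" if reference[pos0] != "C" else "T",
                    gene=(
                        str(rng.choice(repair_genes))
                        if kind != "non_repair_gene"
                        else "OR2T1"
                    ),
                    impact="MODERATE",
                    pop_af=(
                        0.05 if kind == "common_af"
                        else float(np.round(rng.uniform(0.0001, 0.019), 5))
                    ),
                    clinvar="pathogenic" if kind == "non_repair_gene" else "none",
                    pfam_domain=False,
                    predictor_calls={"SIFT": "benign", "PROVEAN": "benign"},
                    per_region_support=_germline_support(pos0 + 1, loh_aware=False),
                )
            )

        for _ in range(config.n_germline_hets):
            pos0 = index.take_unused_position(rng)
            patient.germline_hets.append(
                AnnotatedVariant(
                    chrom="chr1",
                    pos=pos0 + 1,
                    ref=reference[pos0],
                    alt="T" if reference[pos0] != "T" else "G",
                    pop_af=float(np.round(rng.uniform(0.05, 0.5), 4)),
                    per_region_support=_germline_support(pos0 + 1, loh_aware=True),
                )
            )

        truth_patient_rows.append(
            {
                "patient_id": pid,
                "germline_mutant": germline_mutant,
                "tobacco_fraction": tobacco_fraction,
                "pack_years": pack_years,
                "smoking_status": smoking_status,
                "histotype": histotype,
            }
        )
        cohort.patients.append(patient)

    truth = GroundTruth(
        variants=pd.DataFrame(
            truth_variant_rows,
            columns=["patient_id", "chrom", "pos", "ref", "alt", "vtype", "branch"],
        ),
        exposures=pd.DataFrame(
            truth_exposure_rows,
            columns=["patient_id", "branch", "signature", "fraction"],
        ),
        cnv=pd.DataFrame(
            truth_cnv_rows,
            columns=[
                "patient_id", "region_id", "chrom", "start", "end",
                "copy_number", "minor_cn", "loh",
            ],
        ),
        patients=pd.DataFrame(
            truth_patient_rows,
            columns=[
                "patient_id", "germline_mutant", "tobacco_fraction",
                "pack_years", "smoking_status", "histotype",
            ],
        ),
    )
    return cohort, truth, refmap


def write_cohort(
    cohort: Cohort,
    truth: GroundTruth,
    refmap: Mapping[str, str],
    config: SimConfig,
    out_dir: str | Path,
) -> dict:
    """Serialize a simulated cohort: FASTA + VCFs + TSV metadata + truth.

    Returns a small manifest of per-patient record counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcfio.write_fasta(refmap, out_dir / "reference.fa")
    config.to_yaml(out_dir / "config.yaml")
    truth.write(out_dir / "truth")

    metadata_rows = []
    counts = {}
    for patient in cohort:
        pdir = out_dir / "patients" / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        vcfio.write_vcf(patient.somatic, pdir / "somatic.vcf", patient.region_ids)
        germline_all = patient.germline + patient.germline_hets
        vcfio.write_vcf(
            germline_all, pdir / "germline.vcf", ["germline", *patient.region_ids]
        )
        for region, profile in patient.cnv.items():
            vcfio.write_segments(profile, pdir / f"cnv_{region}.tsv")
        for region in patient.regions:
            metadata_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "region_id": region.region_id,
                    "cellularity": round(region.cellularity, 6),
                    "histotype": patient.histotype,
                    "smoking_status": patient.smoking_status,
                    "pack_years": round(patient.pack_years, 3),
                }
            )
        counts[patient.patient_id] = {
            "somatic": len(patient.somatic),
            "germline": len(germline_all),
            "regions": len(patient.regions),
        }
    pd.DataFrame(
        metadata_rows,
        columns=[
            "patient_id", "region_id", "cellularity",
            "histotype", "smoking_status", "pack_years",
        ],
    ).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return counts


def simulate_association_cohort(
    n_mutant: int = 10,
    n_wildtype: int = 10,
    mutant_mean: float = 0.5,
    wildtype_mean: float = 0.2,
    sd: float = 0.1,
    seed: int = 0,
    pack_years_range: tuple[float, float] = (10.0, 60.0),
    n_mutations_range: tuple[int, int] = (1000, 40000),
) -> pd.DataFrame:
    """Patient-metric table with a known germline->tobacco effect.

    A lightweight generator for calibrating the association statistics:
    smoking fractions are drawn per group from clipped normals, and burden /
    per-pack-year metrics derived from drawn mutation totals.  This skips
    read-level simulation entirely; the full generator exercises that path.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_mutant + n_wildtype):
        mutant = i < n_mutant
        mean = mutant_mean if mutant else wildtype_mean
        fraction = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
        n_mutations = int(rng.integers(*n_mutations_range))
        pack_years = float(rng.uniform(*pack_years_range))
        smoking_count = _round_half_up(fraction * n_mutations)
        rows.append(
            {
                "patient_id": f"S{i+1:03d}",
                "germline_mutant": mutant,
                "smoking_fraction": fraction,
                "n_mutations": n_mutations,
                "pack_years": pack_years,
                "burden_per_mb": n_mutations / 2800.0,
                "smoking_variants_per_py": smoking_count / pack_years,
            }
        )
    return pd.DataFrame(rows)
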