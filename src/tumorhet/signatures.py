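"""Mutational-signature analysis on the 96-channel substitution spectrum.

Single-base substitutions are classified by the pyrimidine-centered change
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 5' and 3' flanking bases,
giving 96 channels.  Observed spectra are decomposed against a fixed catalog
of reference signatures by non-negative least squares (supervised fitting,
not de novo extraction), and exposures are attributed per clone-tree branch.
The fraction assigned to the tobacco signature drives the smoking metrics
(signature fraction, smoking-variant count, smoking variants per pack-year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .exceptions import UndefinedFitError
from .types import AnnotatedVariant

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: Canonical channel order: substitution class major, then 5' base, then 3'
#: base, each lexicographic over A,C,G,T.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_name(five: str, ref: str, alt: str, three: str) -> str:
    """Channel for a substitution given its immediate context.

    Purine-reference changes are reverse-complemented onto the
    pyrimidine-centered strand.
    """
    if ref in "AG":
        five, ref, alt, three = (
            three.translate(_COMPLEMENT),
            ref.translate(_COMPLEMENT),
            alt.translate(_COMPLEMENT),
            five.translate(_COMPLEMENT),
        )
    return f"{five}[{ref}>{alt}]{three}"


def trinucleotide_context(
    reference: Mapping[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> Optional[int]:
    """Map an SNV to its 96-channel index, or None when not applicable.

    Indels and variants at the first/last base of the contig (no full
    trinucleotide context) return None and are excluded from spectra.
    Raises ValueError when the reference base at ``pos`` does not match
    ``ref`` (1-based coordinates).
    """
    if len(ref) != 1 or len(alt) != 1:
        return None
    seq = reference[chrom]
    if pos < 2 or pos > len(seq) - 1:
        return None
    ref = ref.upper()
    alt = alt.upper()
    base = seq[pos - 1].upper()
    if base != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: sequence has {base}, variant ref is {ref}"
        )
    five = seq[pos - 2].upper()
    three = seq[pos].upper()
    name = channel_name(five, ref, alt, three)
    idx = _CHANNEL_INDEX.get(name)
    if idx is None:  # ambiguous bases (N) in context
        return None
    return idx


@dataclass
class SignatureCatalog:
    """Reference signatures: S rows of 96 channel probabilities each."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError(f"catalog matrix must be S x 96 (got {self.matrix.shape})")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("number of names does not match number of rows")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names in catalog")
        if np.any(self.matrix < 0):
            raise ValueError("catalog probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.names[i] for i in np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]]
            raise ValueError(f"catalog rows must sum to 1 (bad rows: {bad})")
        # renormalize away float noise within tolerance
        self.matrix = self.matrix / sums[:, None]

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[0]

    @property
    def tobacco_index(self) -> int:
        """Index of the signature designated as the tobacco/smoking process."""
        for i, name in enumerate(self.names):
            if "tobacco" in name.lower() or "smoking" in name.lower():
                return i
        raise ValueError("catalog has no signature labeled as tobacco/smoking")

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(list(names), self.matrix[idx])


@dataclass
class MutationSpectrum:
    """96-channel SNV counts plus the number of excluded (non-SNV/edge) calls."""

    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExposureFit:
    """Non-negative exposures of catalog signatures fitted to one spectrum.

    ``exposures`` are on the mutation-count scale; ``fractions`` sum to 1.
    ``low_confidence`` marks fits on spectra below the branch SNV minimum.
    """

    signature_names: list[str]
    exposures: np.ndarray
    fractions: np.ndarray
    residual_norm: float
    n_mutations: int
    low_confidence: bool = False

    def fraction_of(self, name: str) -> float:
        return float(self.fractions[self.signature_names.index(name)])


@dataclass
class SmokingMetrics:
    smoking_fraction: float
    smoking_variant_count: int
    smoking_variants_per_py: Optional[float]


def build_spectrum(
    variants: Sequence[AnnotatedVariant], reference: Mapping[str, str]
) -> MutationSpectrum:
    """Bin SNVs into the 96 channels; indels and edge positions are tallied
    as excluded, never counted."""
    counts = np.zeros(96, dtype=np.int64)
    n_excluded = 0
    for v in variants:
        idx = trinucleotide_context(reference, v.chrom, v.pos, v.ref, v.alt)
        if idx is None:
            n_excluded += 1
        else:
            counts[idx] += 1
    return MutationSpectrum(counts, n_excluded)


def fit_exposures(spectrum: MutationSpectrum, catalog: SignatureCatalog) -> ExposureFit:
    """Supervised signature fit by non-negative least squares.

    Minimizes ``|| spectrum/total - catalog^T e ||_2`` over e >= 0 using the
    Lawson–Hanson active-set algorithm, then rescales exposures to the
    mutation-count scale.
    """
    total = spectrum.total
    if total == 0:
        raise UndefinedFitError("cannot fit exposures to an empty spectrum")
    target = spectrum.counts / total
    weights, residual = nnls(catalog.matrix.T, target)
    weight_sum = weights.sum()
    if weight_sum > 0:
        fractions = weights / weight_sum
    else:
        fractions = np.zeros_like(weights)
    return ExposureFit(
        signature_names=list(catalog.names),
        exposures=weights * total,
        fractions=fractions,
        residual_norm=float(residual),
        n_mutations=total,
    )


def branch_signatures(
    tree,
    reference: Mapping[str, str],
    catalog: SignatureCatalog,
    min_snvs: int = 50,
) -> dict[str, Optional[ExposureFit]]:
    """One exposure fit per clone-tree branch, on that branch's SNVs only.

    Branches with fewer than ``min_snvs`` SNVs are still fitted but flagged
    ``low_confidence``; branches with zero SNVs map to None (undefined fit).
    """
    fits: dict[str, Optional[ExposureFit]] = {}
    for node in tree.iter_nodes():
        if node.label == "germline":
            continue
        spectrum = build_spectrum(node.variants, reference)
        if spectrum.total == 0:
            fits[node.label] = None
            continue
        fit = fit_exposures(spectrum, catalog)
        fit.low_confidence = spectrum.total < min_snvs
        fits[node.label] = fit
    return fits


def smoking_metrics(
    fit: ExposureFit,
    pack_years: Optional[float],
    tobacco_name: Optional[str] = None,
) -> SmokingMetrics:
    """Smoking-attributable fraction, variant count and per-pack-year rate.

    ``smoking_variants_per_py`` is undefined (None) for never-smokers
    (pack_years 0 or missing); the signature fraction is still reported.
    """
    if pack_years is not None and pack_years < 0:
        raise ValueError("pack_years must be non-negative")
    if tobacco_name is None:
        idx = [i for i, n in enumerate(fit.signature_names) if "tobacco" in n.lower()]
        if not idx:
            raise ValueError("fit has no tobacco-labeled signature")
        tobacco_idx = idx[0]
    else:
        tobacco_idx = fit.signature_names.index(tobacco_name)
    fraction = float(fit.fractions[tobacco_idx])
    count = int(np.floor(fraction * fit.n_mutations + 0.5))
    if pack_years is None or pack_years == 0:
        per_py = None
    else:
        per_py = count / pack_years
    return SmokingMetrics(fraction, count, per_py)


# ---------------------------------------------------------------------------
# Bundled synthetic catalog
# ---------------------------------------------------------------------------

def _context_block(sub: str) -> np.ndarray:
    """Boolean mask over the 96 channels for one substitution class."""
    mask = np.zeros(96, dtype=bool)
    start = SUBSTITUTIONS.index(sub) * 16
    mask[start : start + 16] = True
    return mask


def make_synthetic_catalog() -> SignatureCatalog:
    """Construct the bundled synthetic signature catalog.

    Six signatures with the qualitative shapes of well-known mutational
    processes, built from scratch (they are NOT the COSMIC references and
    carry a `synthetic` label for that reason):

    - ``tobacco-like``:  all mass on C>A channels with a mild context tilt
      (benzo[a]pyrene-adduct style transversions);
    - ``clock-like``:    C>T concentrated at NpCpG (5-methyl-cytosine
      deamination, the age/clock process);
    - ``apobec-like``:   C>T and C>G restricted to TpC contexts;
    - ``hrd-like``:      broad, near-featureless spread over all classes
      (homologous-recombination-deficiency style);
    - ``poleta-like``:   T>G with some T>C at A/T 5' contexts
      (polymerase-eta somatic hypermutation style);
    - ``background``:    exactly uniform over the 96 channels.
    """
    rows = []

    # tobacco-like: C>A only, context weights product of 5' and 3' factors
    w5 = {"A": 1.0, "C": 1.5, "G": 0.8, "T": 1.2}
    w3 = {"A": 1.2, "C": 1.5, "G": 0.8, "T": 1.0}
    tobacco = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        if ch[2:5] == "C>A":
            tobacco[i] = w5[ch[0]] * w3[ch[6]]
    rows.append(tobacco / tobacco.sum())

    # clock-like: 90% of mass at N[C>T]G, 10% spread over remaining C>T
    clock = np.zeros(96)
    cpg = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "C>T" and ch[6] == "G"]
    rest = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "C>T" and ch[6] != "G"]
    clock[cpg] = 0.9 / len(cpg)
    clock[rest] = 0.1 / len(rest)
    rows.append(clock)

    # apobec-like: T[C>T]{A,T} and T[C>G]{A,T}
    apobec = np.zeros(96)
    targets = ["T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T"]
    for name in targets:
        apobec[_CHANNEL_INDEX[name]] = 0.25
    rows.append(apobec)

    # hrd-like: broad with per-class tilts, uniform within class
    hrd = np.zeros(96)
    class_mass = {"C>A": 0.18, "C>G": 0.17, "C>T": 0.12, "T>A": 0.19, "T>C": 0.20, "T>G": 0.14}
    for sub, mass in class_mass.items():
        hrd[_context_block(sub)] = mass / 16.0
    rows.append(hrd)

    # poleta-like: T>G (80%) and T>C (20%) at 5' A or T
    poleta = np.zeros(96)
    tg = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "T>G" and ch[0] in "AT"]
    tc = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "T>C" and ch[0] in "AT"]
    poleta[tg] = 0.8 / len(tg)
    poleta[tc] = 0.2 / len(tc)
    rows.append(poleta)

    # flat background
    rows.append(np.full(96, 1.0 / 96.0))

    names = ["tobacco-like", "clock-like", "apobec-like", "hrd-like", "poleta-like", "background"]
    return SignatureCatalog(names, np.vstack(rows))
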