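"""Seeded generative models for mosaic founders, assay signals and clone draws.

The generator emulates the study system end to end: a founder animal carries
1-5 distinct alleles at the target locus (mosaicism from post-zygotic editing)
with Dirichlet-distributed fractions; allele categories span the full taxonomy
(wt, HDR, partial_HDR, deletion, insertion, point_mutation, mixed).  From an
allele population it renders triplicate multiplex qPCR plates with
probe-binding-dependent drop-off, ~20,000-partition dPCR chips with Poisson
copy loading, amplicon clone draws for sequencing, and endpoint-fluorescence
samples for competitive genotyping.  All generators are bit-reproducible given
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .allele_classify import HdrComponent, HdrTemplate, default_window
from .dpcr_quant import DpcrChip
from .endpoint_genotype import EndpointSample
from .errors import GenerationError, InputError
from .qpcr_quant import (
    CHANNEL_REFERENCE,
    CHANNEL_TARGET,
    FLAG_NO_AMPLIFICATION,
    QpcrWell,
)
from .thermo import BufferConditions, mismatch_discrimination

CATEGORIES = ("wt", "HDR", "partial_HDR", "deletion", "insertion", "point_mutation", "mixed")

# Default founder category mix: loosely shaped like the published aggregate
# distribution of clone-sequenced alleles (deletions dominate NHEJ outcomes,
# full HDR is rare, partial HDR is a sizeable fraction of HDR-related events).
DEFAULT_CATEGORY_PROBS = {
    "wt": 0.25,
    "HDR": 0.07,
    "partial_HDR": 0.10,
    "deletion": 0.33,
    "insertion": 0.10,
    "point_mutation": 0.05,
    "mixed": 0.10,
}

BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_default_locus(length: int = 476, seed: int = 20_170_831):
    """Deterministic synthetic target locus: (reference, cut_site, HdrTemplate).

    The reference carries an NGG PAM 3 nt downstream of the cut and a
    near-EcoRI site; the donor template encodes a codon change 6 nt upstream of
    the cut, a PAM-breaking substitution, and the silent substitution that
    completes the GAATTC restriction site.
    """
    rng = np.random.default_rng(seed)
    ref = list(rng.choice(BASES, size=length))
    cut = length // 2
    ref[cut + 3 : cut + 6] = list("TGG")       # PAM (NGG)
    ref[cut + 10 : cut + 16] = list("GAGTTC")  # one substitution away from GAATTC
    reference = "".join(ref)

    codon_ref = reference[cut - 6]
    codon_alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[codon_ref]
    hdr = HdrTemplate(
        components=(
            HdrComponent("target_codon", cut - 6, codon_ref, codon_alt),
            HdrComponent("pam_mutation", cut + 4, "G", "T"),
            HdrComponent("silent_restriction_site", cut + 12, "G", "A"),
        )
    )
    return reference, cut, hdr


@dataclass(frozen=True)
class Allele:
    window_seq: str
    category: str
    fraction: float


@dataclass(frozen=True)
class AllelePopulation:
    alleles: tuple[Allele, ...]
    reference: str
    cut_site: int
    hdr: HdrTemplate
    window: tuple[int, int]

    def __post_init__(self):
        total = sum(a.fraction for a in self.alleles)
        if not self.alleles or abs(total - 1.0) > 1e-9:
            raise InputError("allele fractions must be positive and sum to 1")
        if any(a.fraction <= 0 for a in self.alleles):
            raise InputError("allele fractions must be positive")

    @property
    def wt_fraction(self) -> float:
        """True unedited fraction (percent)."""
        return 100.0 * sum(a.fraction for a in self.alleles if a.category == "wt")

    def full_sequence(self, allele: Allele) -> str:
        w0, w1 = self.window
        return self.reference[:w0] + allele.window_seq + self.reference[w1:]


@dataclass(frozen=True)
class FounderConfig:
    category_probs: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    allele_count_range: tuple[int, int] = (1, 5)
    deletion_size_range: tuple[int, int] = (1, 12)
    insertion_size_range: tuple[int, int] = (1, 6)
    dirichlet_alpha: float = 1.0
    window_width: int = 70

    def __post_init__(self):
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError("category probabilities must sum to 1")


def _apply_substitution(seq: str, pos: int, alt: str) -> str:
    return seq[:pos] + alt + seq[pos + len(alt):]


def _make_allele_window(
    category: str,
    ref_window: str,
    cut_local: int,
    hdr_local: list[HdrComponent],
    cfg: FounderConfig,
    rng: np.random.Generator,
) -> str:
    """Concrete window sequence realizing ``category``; edits stay >= 3 nt from
    the window edges so the classifier sees them unambiguously."""
    n = len(ref_window)
    margin = 3
    comp_positions = {p for c in hdr_local for p in range(c.start, c.start + len(c.ref))}

    def random_sub(exclude: set[int]) -> tuple[int, str]:
        choices = [
            p for p in range(margin, n - margin)
            if p not in comp_positions and p not in exclude
        ]
        pos = int(rng.choice(choices))
        alt = str(rng.choice([b for b in "ACGT" if b != ref_window[pos]]))
        return pos, alt

    if category == "wt":
        return ref_window
    if category in ("HDR", "partial_HDR"):
        comps = list(hdr_local)
        if category == "partial_HDR":
            k = int(rng.integers(1, len(comps)))  # nonempty proper subset
            idx = rng.choice(len(comps), size=k, replace=False)
            comps = [comps[i] for i in sorted(idx)]
        seq = ref_window
        for c in comps:
            seq = _apply_substitution(seq, c.start, c.alt)
        return seq
    if category == "deletion":
        k = int(rng.integers(cfg.deletion_size_range[0], cfg.deletion_size_range[1] + 1))
        lo = max(cut_local - k, margin)
        hi = min(cut_local, n - margin - k)
        if hi < lo:
            raise GenerationError("deletion does not fit in the analysis window")
        start = int(rng.integers(lo, hi + 1))
        return ref_window[:start] + ref_window[start + k:]
    if category == "insertion":
        k = int(rng.integers(cfg.insertion_size_range[0], cfg.insertion_size_range[1] + 1))
        ins = "".join(rng.choice(BASES, size=k))
        return ref_window[:cut_local] + ins + ref_window[cut_local:]
    if category == "point_mutation":
        pos, alt = random_sub(set())
        return _apply_substitution(ref_window, pos, alt)
    if category == "mixed":
        # small deletion at the cut plus a well-separated substitution
        k = int(rng.integers(1, 4))
        start = max(min(cut_local - k // 2, n - margin - k), margin)
        exclude = set(range(start - 6, start + k + 6))
        pos, alt = random_sub(exclude)
        seq = _apply_substitution(ref_window, pos, alt)
        return seq[:start] + seq[start + k:]
    raise InputError(f"unknown category {category!r}")


def simulate_founder(
    config: FounderConfig | None = None,
    seed=0,
    reference: str | None = None,
    cut_site: int | None = None,
    hdr: HdrTemplate | None = None,
) -> AllelePopulation:
    """One mosaic founder: 1-5 distinct alleles with Dirichlet fractions."""
    cfg = config or FounderConfig()
    rng = _rng(seed)
    if reference is None:
        reference, cut_site, hdr = make_default_locus()
    window = default_window(cut_site, cfg.window_width)
    w0, w1 = window
    ref_window = reference[w0:w1]
    cut_local = cut_site - w0
    hdr_local = [replace(c, start=c.start - w0) for c in hdr.components]

    cats = list(cfg.category_probs)
    probs = np.array([cfg.category_probs[c] for c in cats])
    n_alleles = int(rng.integers(cfg.allele_count_range[0], cfg.allele_count_range[1] + 1))

    alleles: list[tuple[str, str]] = []
    seen: set[str] = set()
    attempts = 0
    while len(alleles) < n_alleles:
        attempts += 1
        if attempts > 200:
            raise GenerationError("could not generate the requested number of distinct alleles")
        cat = str(rng.choice(cats, p=probs))
        if cat in ("wt", "HDR") and any(c == cat for _, c in alleles):
            continue  # wt and full HDR are unique sequences
        seq = _make_allele_window(cat, ref_window, cut_local, hdr_local, cfg, rng)
        if seq in seen:
            continue
        seen.add(seq)
        alleles.append((seq, cat))

    fractions = rng.dirichlet([cfg.dirichlet_alpha] * n_alleles)
    # guard against degenerate tiny fractions
    fractions = np.clip(fractions, 0.01, None)
    fractions = fractions / fractions.sum()
    return AllelePopulation(
        alleles=tuple(
            Allele(seq, cat, float(f)) for (seq, cat), f in zip(alleles, fractions)
        ),
        reference=reference,
        cut_site=cut_site,
        hdr=hdr,
        window=window,
    )


def population_from_wt_fraction(
    wt_fraction_percent: float,
    edited_category: str = "deletion",
    seed=0,
    config: FounderConfig | None = None,
) -> AllelePopulation:
    """Two-allele population with an exact wt fraction (for recovery studies)."""
    cfg = config or FounderConfig()
    rng = _rng(seed)
    reference, cut, hdr = make_default_locus()
    window = default_window(cut, cfg.window_width)
    w0, _ = window
    ref_window = reference[w0 : window[1]]
    hdr_local = [replace(c, start=c.start - w0) for c in hdr.components]
    f = wt_fraction_percent / 100.0
    if not 0.0 <= f <= 1.0:
        raise InputError("wt fraction must be in [0, 100] percent")
    alleles = []
    if f > 0:
        alleles.append(Allele(ref_window, "wt", f))
    if f < 1:
        seq = _make_allele_window(edited_category, ref_window, cut - w0, hdr_local, cfg, rng)
        alleles.append(Allele(seq, edited_category, 1.0 - f))
    return AllelePopulation(tuple(alleles), reference, cut, hdr, window)


# --- assay physics --------------------------------------------------------------------


@dataclass(frozen=True)
class AssayPhysics:
    """Per-allele probe binding and signal-noise model.

    ``binding_table`` maps category -> (target_binding, reference_binding) in
    [0, 1]; if None, binding is derived from the thermodynamic bound fraction
    of each probe against each allele (requires ``assay`` at call time).
    """

    binding_table: dict | None = None
    pcr_efficiency: float = 2.0
    cq_noise_sd: float = 0.1
    baseline_cq: float = 24.0

    def __post_init__(self):
        if self.binding_table is not None:
            for cat, (bt, br) in self.binding_table.items():
                if not (0 <= bt <= 1 and 0 <= br <= 1):
                    raise InputError(f"binding efficiencies for {cat!r} must be in [0,1]")
        if self.cq_noise_sd < 0:
            raise InputError("cq_noise_sd must be >= 0")


def lna_binding() -> dict:
    """Ideal LNA target probe: binds wt only; reference probe unaffected."""
    table = {cat: (0.0, 1.0) for cat in CATEGORIES}
    table["wt"] = (1.0, 1.0)
    return table


def oligo_binding(partial: float = 0.5) -> dict:
    """Unmodified oligo target probe: single-base changes and 1-nt insertions
    are still moderately bound (``partial``); larger disruptions are not."""
    table = lna_binding()
    for cat in ("HDR", "partial_HDR", "point_mutation", "insertion"):
        table[cat] = (partial, 1.0)
    return table


def uniform_edited_binding(efficiency: float) -> dict:
    """Every edited allele bound at ``efficiency`` by the target probe."""
    table = {cat: (float(efficiency), 1.0) for cat in CATEGORIES}
    table["wt"] = (1.0, 1.0)
    return table


def _binding_for(population: AllelePopulation, physics: AssayPhysics, assay=None,
                 cond: BufferConditions | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(target, reference) binding efficiency per allele."""
    if physics.binding_table is not None:
        bt = np.array([physics.binding_table[a.category][0] for a in population.alleles])
        br = np.array([physics.binding_table[a.category][1] for a in population.alleles])
        return bt, br
    if assay is None:
        raise InputError("thermo-derived binding requires an assay")
    cond = cond or BufferConditions()
    wt_full = population.reference
    bt, br = [], []
    for a in population.alleles:
        full = population.full_sequence(a)
        effs = []
        for probe in (assay.target_probe, assay.reference_probe):
            if full == wt_full:
                effs.append(1.0)
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = mismatch_discrimination(probe, wt_full, full, cond)
            wt_bound = md.wt.bound_fraction_at_anneal
            eff = md.variant.bound_fraction_at_anneal / wt_bound if wt_bound > 0 else 0.0
            effs.append(float(np.clip(eff, 0.0, 1.0)))
        bt.append(effs[0])
        br.append(effs[1])
    return np.array(bt), np.array(br)


def simulate_qpcr(
    population: AllelePopulation,
    physics: AssayPhysics | None = None,
    replicates: int = 3,
    seed=0,
    sample_id: str = "sample",
    assay=None,
) -> list[QpcrWell]:
    """Triplicate two-channel wells for one sample.

    Effective channel signal is the binding-weighted allele mass; with
    efficiency E, Cq = baseline - log_E(signal) + Gaussian noise per replicate.
    A target signal of zero emits no-amplification flags.
    """
    physics = physics or AssayPhysics(binding_table=lna_binding())
    rng = _rng(seed)
    fr = np.array([a.fraction for a in population.alleles])
    bt, br = _binding_for(population, physics, assay)
    signal_t = float(np.dot(fr, bt))
    signal_r = float(np.dot(fr, br))
    log_e = math.log(physics.pcr_efficiency)

    wells: list[QpcrWell] = []
    for channel, signal in ((CHANNEL_TARGET, signal_t), (CHANNEL_REFERENCE, signal_r)):
        for rep in range(1, replicates + 1):
            if signal <= 0:
                wells.append(QpcrWell(sample_id, channel, rep, None,
                                      frozenset({FLAG_NO_AMPLIFICATION})))
                continue
            cq = physics.baseline_cq - math.log(signal) / log_e
            cq += float(rng.normal(0.0, physics.cq_noise_sd))
            wells.append(QpcrWell(sample_id, channel, rep, cq))
    return wells


@dataclass(frozen=True)
class FluorescenceClusters:
    negative_mean: float = 0.5
    negative_sd: float = 0.08
    positive_mean: float = 2.0
    positive_sd: float = 0.15


def simulate_dpcr_chip(
    population: AllelePopulation,
    n_partitions: int = 20_000,
    mean_copies_per_partition: float = 0.6,
    physics: AssayPhysics | None = None,
    seed=0,
    assay=None,
    render_fluorescence: bool = False,
    clusters: FluorescenceClusters | None = None,
) -> DpcrChip:
    """Poisson-loaded two-channel chip; each copy binds each probe Bernoulli."""
    if n_partitions < 100:
        raise InputError("n_partitions must be >= 100")
    if mean_copies_per_partition <= 0:
        raise InputError("mean copies per partition must be > 0")
    physics = physics or AssayPhysics(binding_table=lna_binding())
    rng = _rng(seed)
    fr = np.array([a.fraction for a in population.alleles])
    bt, br = _binding_for(population, physics, assay)
    q_t = float(np.clip(np.dot(fr, bt), 0.0, 1.0))
    q_r = float(np.clip(np.dot(fr, br), 0.0, 1.0))

    counts = rng.poisson(mean_copies_per_partition, size=n_partitions)
    n_t = rng.binomial(counts, q_t) if q_t > 0 else np.zeros_like(counts)
    n_r = rng.binomial(counts, q_r) if q_r > 0 else np.zeros_like(counts)
    calls = np.column_stack([(n_r > 0), (n_t > 0)])

    fluor = None
    if render_fluorescence:
        cl = clusters or FluorescenceClusters()
        fluor = np.empty((n_partitions, 2))
        for col in (0, 1):
            pos = calls[:, col]
            fluor[:, col] = np.where(
                pos,
                rng.normal(cl.positive_mean, cl.positive_sd, size=n_partitions),
                rng.normal(cl.negative_mean, cl.negative_sd, size=n_partitions),
            )
        fluor = np.clip(fluor, 0.0, None)
    return DpcrChip(calls=calls, fluorescence=fluor)


def simulate_clones(
    population: AllelePopulation,
    n_clones: int = 15,
    seed=0,
    animal_id: str = "animal1",
) -> list[tuple[str, str]]:
    """Multinomial clone draw; returns (clone_id, full amplicon sequence) pairs
    with IDs in the ``animalID.cloneN`` convention."""
    if n_clones < 1:
        raise InputError("n_clones must be >= 1")
    rng = _rng(seed)
    fr = np.array([a.fraction for a in population.alleles])
    draws = rng.choice(len(fr), size=n_clones, p=fr)
    return [
        (f"{animal_id}.clone{i + 1}", population.full_sequence(population.alleles[k]))
        for i, k in enumerate(draws)
    ]


@dataclass(frozen=True)
class EndpointClusterParams:
    wt_centroid: tuple[float, float] = (2.0, 0.3)    # (wt channel, mut channel)
    homo_centroid: tuple[float, float] = (0.3, 2.0)
    ntc_level: tuple[float, float] = (0.15, 0.15)
    cluster_sd: float = 0.06
    ntc_sd: float = 0.02

    @property
    def het_centroid(self) -> tuple[float, float]:
        return (
            (self.wt_centroid[0] + self.homo_centroid[0]) / 2.0,
            (self.wt_centroid[1] + self.homo_centroid[1]) / 2.0,
        )


def simulate_endpoint(
    genotype,
    params: EndpointClusterParams | None = None,
    seed=0,
    sample_id: str = "sample",
    role: str = "unknown",
) -> EndpointSample:
    """Two-channel endpoint draw around the genotype centroid.

    ``genotype`` is one of "WT", "HET", "HOMO", "NTC" or ("mosaic", fraction)
    with the mosaic centroid interpolated between WT and HOMO by the mutant
    fraction.
    """
    params = params or EndpointClusterParams()
    rng = _rng(seed)
    if isinstance(genotype, tuple) and genotype[0] == "mosaic":
        f = float(genotype[1])
        if not 0 <= f <= 1:
            raise InputError("mosaic fraction must be in [0, 1]")
        cx = params.wt_centroid[0] + f * (params.homo_centroid[0] - params.wt_centroid[0])
        cy = params.wt_centroid[1] + f * (params.homo_centroid[1] - params.wt_centroid[1])
        sd = params.cluster_sd
    elif genotype == "NTC":
        cx, cy = params.ntc_level
        sd = params.ntc_sd
    elif genotype in ("WT", "HET", "HOMO"):
        cx, cy = {
            "WT": params.wt_centroid,
            "HET": params.het_centroid,
            "HOMO": params.homo_centroid,
        }[genotype]
        sd = params.cluster_sd
    else:
        raise InputError(f"unknown genotype {genotype!r}")
    wt = max(float(rng.normal(cx, sd)), 0.0)
    mut = max(float(rng.normal(cy, sd)), 0.0)
    return EndpointSample(sample_id, wt, mut, role)
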