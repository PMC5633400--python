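"""Construction of drop-off assays and competitive allele-specific probe pairs.

A drop-off assay is a single amplicon carrying two hydrolysis probes on
different fluorophore channels: an LNA "target" probe spanning the Cas9 cut
site (binding is abolished by editing) and an internal "reference" probe distal
to the cut site (binding survives editing and normalizes input).  Placement and
melting-temperature constraints follow standard multiplex probe-assay practice:
both probes melt 3-6 C above the primers so they are bound before extension,
the two probes melt within a small tolerance of each other, and neither probe
overlaps the primers or the other probe.

The Cas9 cut-site convention is the blunt double-strand break 3 nt 5' of the
PAM (between protospacer positions 17 and 18), stored as a 0-based inter-base
coordinate on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DesignError, InputError
from .thermo import (
    BufferConditions,
    Duplex,
    ThermoResult,
    _check_sequence,
    melting_temperature,
    revcomp,
)

CHANNELS = ("FAM", "VIC")
ROLES = ("target", "internal_reference", "external_reference", "allele_wt", "allele_mut")


@dataclass(frozen=True)
class ProbeDesign:
    """An oligonucleotide probe with locked positions and a channel assignment.

    ``sequence`` is 5'->3' on the strand given by ``strand`` (+ means the probe
    sequence equals the reference over ``footprint`` and hybridizes to the
    antisense strand).  ``footprint`` is a half-open 0-based interval on the
    reference.
    """

    name: str
    sequence: str
    lna_positions: frozenset[int]
    channel: str
    role: str
    tm_C: float
    footprint: tuple[int, int]
    strand: str = "+"

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "probe sequence"))
        object.__setattr__(self, "lna_positions", frozenset(self.lna_positions))
        if self.channel not in CHANNELS:
            raise InputError(f"channel must be one of {CHANNELS}")
        if self.role not in ROLES:
            raise InputError(f"role must be one of {ROLES}")
        if self.strand not in "+-":
            raise InputError("strand must be '+' or '-'")
        if self.footprint[1] - self.footprint[0] != len(self.sequence):
            raise InputError("footprint width must equal probe length")

    def display_sequence(self) -> str:
        """Sequence with locked bases in the '+N' prefix dialect (e.g. A+C+G+TT)."""
        return "".join(
            ("+" + b) if i in self.lna_positions else b for i, b in enumerate(self.sequence)
        )


@dataclass(frozen=True)
class PrimerDesign:
    name: str
    sequence: str
    footprint: tuple[int, int]
    strand: str
    tm_C: float


@dataclass(frozen=True)
class DropOffAssay:
    reference_id: str
    fw_primer: PrimerDesign
    rv_primer: PrimerDesign
    target_probe: ProbeDesign
    reference_probe: ProbeDesign
    amplicon: tuple[int, int]
    cut_site: int
    penalty: float = 0.0


@dataclass(frozen=True)
class DesignConstraints:
    """Placement and Tm windows for drop-off assay design.

    The amplicon-length window is centered on the conventional 134 bp; probes
    must melt ``probe_primer_tm_offset`` (default [3, 6] C) above the hottest
    primer and within ``probe_tm_tolerance`` of each other.
    """

    amplicon_length_range: tuple[int, int] = (110, 160)
    amplicon_length_target: int = 134
    primer_length_range: tuple[int, int] = (18, 28)
    probe_length_range: tuple[int, int] = (16, 32)
    probe_primer_tm_offset: tuple[float, float] = (3.0, 6.0)
    probe_tm_tolerance: float = 2.0
    min_ref_probe_cut_distance: int = 8
    primer_gc_range: tuple[float, float] = (0.30, 0.70)
    max_homopolymer: int = 4
    max_candidates: int = 5

    def __post_init__(self):
        for lo, hi in (
            self.amplicon_length_range,
            self.primer_length_range,
            self.probe_length_range,
            self.probe_primer_tm_offset,
        ):
            if lo > hi:
                raise InputError("constraint range is empty")


@dataclass(frozen=True)
class ConstraintCheck:
    constraint: str
    passed: bool
    measured: object


@dataclass
class DesignResult:
    assays: list[DropOffAssay]
    failures: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.assays)

    def __len__(self):
        return len(self.assays)


def _gc_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _probe_tm(seq: str, lna: frozenset[int], cond: BufferConditions) -> ThermoResult:
    return melting_temperature(Duplex(seq, revcomp(seq), lna), cond)


def _oligo_tm(seq: str, cond: BufferConditions) -> float:
    return _probe_tm(seq, frozenset(), cond).tm_C


def _lna_triplet(probe_seq: str, cut_in_probe: int) -> frozenset[int]:
    """Three consecutive locked positions centered on the inter-base cut.

    Default covers the two bases 5' and one base 3' of the scissile phosphate;
    shifted minimally if the triplet would sit inside a >=4-long G run.
    """
    n = len(probe_seq)
    for shift in (0, 1, -1, 2, -2):
        start = cut_in_probe - 2 + shift
        if start < 1 or start + 3 > n - 1:
            continue
        window = probe_seq[max(start - 1, 0) : start + 4]
        if "GGGG" in window:
            continue
        return frozenset(range(start, start + 3))
    start = min(max(cut_in_probe - 2, 1), n - 4)
    return frozenset(range(start, start + 3))


def design_dropoff_assay(
    reference_seq: str,
    cut_site: int,
    constraints: DesignConstraints | None = None,
    cond: BufferConditions | None = None,
    reference_id: str = "reference",
) -> DesignResult:
    """Enumerate and rank drop-off assays around ``cut_site``.

    Deterministic: candidates are enumerated in a fixed order and ranked by a
    composite penalty (probe/primer Tm deviations from window centers, GC
    extremes, homopolymer runs, amplicon-length deviation from the target).
    Returns a :class:`DesignResult`; when no candidate satisfies the
    constraints its ``failures`` dict reports which constraint eliminated how
    many candidates.
    """
    constraints = constraints or DesignConstraints()
    cond = cond or BufferConditions()
    reference_seq = _check_sequence(reference_seq, "reference_seq")
    c = constraints
    min_amp, max_amp = c.amplicon_length_range
    if len(reference_seq) < max_amp:
        raise InputError("reference shorter than the maximum amplicon length")
    if cut_site < min_amp // 2 or cut_site > len(reference_seq) - min_amp // 2:
        raise InputError(
            "cut_site must be at least half an amplicon length from both reference ends"
        )

    failures: dict[str, int] = {}

    def fail(name: str):
        failures[name] = failures.get(name, 0) + 1

    lengths = sorted(range(min_amp, max_amp + 1), key=lambda L: (abs(L - c.amplicon_length_target), L))
    assays: list[DropOffAssay] = []

    for amp_len in lengths:
        if len(assays) >= c.max_candidates:
            break
        # amplicon placements: cut roughly 1/3 from one end so the reference
        # probe has room on the distal side; try a few shifts
        base_start = cut_site - amp_len // 3
        for shift in (0, -6, 6, -12, 12):
            start = base_start + shift
            end = start + amp_len
            if start < 0 or end > len(reference_seq):
                continue
            if not (start + c.primer_length_range[0] + 4 < cut_site < end - c.primer_length_range[0] - 4):
                fail("cut_site_inside_amplicon")
                continue
            amplicon = reference_seq[start:end]
            assay = _design_on_amplicon(
                reference_seq, reference_id, start, amp_len, cut_site, c, cond, fail
            )
            if assay is not None:
                assays.append(assay)
            if len(assays) >= c.max_candidates:
                break

    assays.sort(key=lambda a: (a.penalty, a.amplicon))
    return DesignResult(assays=assays, failures=failures)


def _design_on_amplicon(ref, ref_id, start, amp_len, cut_site, c, cond, fail):
    end = start + amp_len
    amplicon = ref[start:end]

    # primers: choose lengths minimizing Tm mismatch between the pair
    primer_cands_f = []
    primer_cands_r = []
    for k in range(c.primer_length_range[0], c.primer_length_range[1] + 1):
        fw = amplicon[:k]
        rv = revcomp(amplicon[-k:])
        for seq, store, strand in ((fw, primer_cands_f, "+"), (rv, primer_cands_r, "-")):
            if _max_homopolymer(seq) > c.max_homopolymer + 1:
                fail("primer_homopolymer")
                continue
            store.append((seq, k, _oligo_tm(seq, cond), strand))
    if not primer_cands_f or not primer_cands_r:
        return None

    pairs = sorted(
        ((f, r) for f in primer_cands_f for r in primer_cands_r),
        key=lambda fr: abs(fr[0][2] - fr[1][2]),
    )[:8]

    lo_off, hi_off = c.probe_primer_tm_offset
    for fwc, rvc in pairs:
        primer_tm_max = max(fwc[2], rvc[2])
        tm_lo = primer_tm_max + lo_off
        tm_hi = primer_tm_max + hi_off

        tgt = _find_target_probe(ref, start, end, cut_site, fwc[1], rvc[1], c, cond, tm_lo, tm_hi, fail)
        if tgt is None:
            continue
        refp = _find_reference_probe(
            ref, start, end, cut_site, fwc[1], rvc[1], tgt, c, cond, tm_lo, tm_hi, fail
        )
        if refp is None:
            continue

        fw = PrimerDesign("fw_primer", fwc[0], (start, start + fwc[1]), "+", fwc[2])
        rv = PrimerDesign("rv_primer", rvc[0], (end - rvc[1], end), "-", rvc[2])
        penalty = (
            abs(amp_len - c.amplicon_length_target) * 0.05
            + abs(fwc[2] - rvc[2]) * 0.5
            + abs(tgt.tm_C - refp.tm_C) * 0.5
            + abs(_gc_fraction(tgt.sequence) - 0.5)
            + abs(_gc_fraction(refp.sequence) - 0.5)
            + max(_max_homopolymer(tgt.sequence) - c.max_homopolymer, 0)
            + max(_max_homopolymer(refp.sequence) - c.max_homopolymer, 0)
        )
        return DropOffAssay(
            reference_id=ref_id,
            fw_primer=fw,
            rv_primer=rv,
            target_probe=tgt,
            reference_probe=refp,
            amplicon=(start, end),
            cut_site=cut_site,
            penalty=round(penalty, 6),
        )
    return None


def _find_target_probe(ref, start, end, cut_site, fw_len, rv_len, c, cond, tm_lo, tm_hi, fail):
    """LNA probe spanning the cut site, Tm inside [tm_lo, tm_hi]."""
    best = None
    for plen in range(c.probe_length_range[0], c.probe_length_range[1] + 1):
        # center the probe on the cut, allow small slides
        for slide in (0, -2, 2, -4, 4):
            p0 = cut_site - plen // 2 + slide
            p1 = p0 + plen
            if p0 < start + fw_len or p1 > end - rv_len:
                fail("target_probe_overlaps_primer")
                continue
            if not (p0 < cut_site < p1):
                continue
            cut_in_probe = cut_site - p0
            if cut_in_probe < 3 or plen - cut_in_probe < 3:
                continue
            seq = ref[p0:p1]
            lna = _lna_triplet(seq, cut_in_probe)
            tm = _probe_tm(seq, lna, cond).tm_C
            if not tm_lo <= tm <= tm_hi:
                fail("target_probe_tm_window")
                continue
            cand = ProbeDesign(
                "target_probe", seq, lna, "FAM", "target", round(tm, 3), (p0, p1), "+"
            )
            score = abs(tm - (tm_lo + tm_hi) / 2)
            if best is None or score < best[0]:
                best = (score, cand)
    return best[1] if best else None


def _find_reference_probe(ref, start, end, cut_site, fw_len, rv_len, target, c, cond, tm_lo, tm_hi, fail):
    """Unmodified probe distal to the cut site, Tm near the target probe's."""
    best = None
    lo = start + fw_len
    hi = end - rv_len
    for plen in range(c.probe_length_range[0], c.probe_length_range[1] + 1):
        for p0 in range(lo, hi - plen + 1):
            p1 = p0 + plen
            if p0 <= cut_site < p1 or (p0 < cut_site < p1):
                fail("reference_probe_contains_cut")
                continue
            if min(abs(p0 - cut_site), abs(p1 - cut_site)) < c.min_ref_probe_cut_distance:
                fail("reference_probe_too_close_to_cut")
                continue
            if p0 < target.footprint[1] and target.footprint[0] < p1:
                fail("probe_overlap")
                continue
            seq = ref[p0:p1]
            tm = _oligo_tm(seq, cond)
            if not tm_lo <= tm <= tm_hi:
                fail("reference_probe_tm_window")
                continue
            if abs(tm - target.tm_C) > c.probe_tm_tolerance:
                fail("probe_probe_tm_tolerance")
                continue
            cand = ProbeDesign(
                "reference_probe", seq, frozenset(), "VIC", "internal_reference",
                round(tm, 3), (p0, p1), "+",
            )
            score = abs(tm - target.tm_C)
            if best is None or score < best[0]:
                best = (score, cand)
        if best is not None and best[0] < 0.5:
            break
    return best[1] if best else None


def design_allele_probes(
    reference_seq: str,
    variant: tuple[int, str, str] | dict,
    site: int | None = None,
    probe_length: int = 24,
    cond: BufferConditions | None = None,
) -> tuple[ProbeDesign, ProbeDesign]:
    """Competitive allele-specific probe pair for a substitution.

    ``variant`` is ``(site, ref_base(s), alt_base(s))`` (or a dict with those
    keys); both probes share one footprint centered on the site, differ only at
    the variant position(s), carry a locked doublet covering the discriminating
    site, and sit on different channels (wt -> VIC, mut -> FAM).
    """
    cond = cond or BufferConditions()
    reference_seq = _check_sequence(reference_seq, "reference_seq")
    if isinstance(variant, dict):
        site0, ref_b, alt_b = variant["site"], variant["ref"], variant["alt"]
    else:
        site0, ref_b, alt_b = variant
    if site is not None:
        site0 = site
    ref_b = _check_sequence(ref_b, "variant ref")
    alt_b = _check_sequence(alt_b, "variant alt")
    if len(ref_b) != len(alt_b):
        raise InputError("allele probes support substitutions only (len(ref) == len(alt))")
    if reference_seq[site0 : site0 + len(ref_b)] != ref_b:
        raise InputError("variant ref bases do not match the reference at the given site")

    p0 = site0 - (probe_length - len(ref_b)) // 2
    p1 = p0 + probe_length
    if p0 < 0 or p1 > len(reference_seq):
        raise DesignError("probe footprint falls off the reference")
    pos_in_probe = site0 - p0
    if pos_in_probe < 2 or pos_in_probe + len(ref_b) > probe_length - 2:
        raise DesignError(
            "discriminating site within 2 nt of the probe end: no terminal discrimination"
        )

    wt_seq = reference_seq[p0:p1]
    mut_seq = wt_seq[:pos_in_probe] + alt_b + wt_seq[pos_in_probe + len(ref_b):]
    # locked doublet covering the discriminating site
    lna = frozenset({pos_in_probe, pos_in_probe + 1})
    wt_tm = _probe_tm(wt_seq, lna, cond).tm_C
    mut_tm = _probe_tm(mut_seq, lna, cond).tm_C
    wt = ProbeDesign("allele_wt_probe", wt_seq, lna, "VIC", "allele_wt",
                     round(wt_tm, 3), (p0, p1), "+")
    mut = ProbeDesign("allele_mut_probe", mut_seq, lna, "FAM", "allele_mut",
                      round(mut_tm, 3), (p0, p1), "+")
    return wt, mut


def validate_assay(
    assay: DropOffAssay,
    cond: BufferConditions | None = None,
    constraints: DesignConstraints | None = None,
) -> list[ConstraintCheck]:
    """Re-measure every drop-off invariant; empty failure list iff all hold."""
    cond = cond or BufferConditions()
    c = constraints or DesignConstraints()
    checks: list[ConstraintCheck] = []
    a0, a1 = assay.amplicon

    def add(name, passed, measured):
        checks.append(ConstraintCheck(name, bool(passed), measured))

    for probe in (assay.target_probe, assay.reference_probe):
        f0, f1 = probe.footprint
        inside = a0 < f0 and f1 < a1
        clear_fw = f0 >= assay.fw_primer.footprint[1]
        clear_rv = f1 <= assay.rv_primer.footprint[0]
        add(f"{probe.name}_inside_amplicon", inside and clear_fw and clear_rv, (f0, f1))

    t0, t1 = assay.target_probe.footprint
    r0, r1 = assay.reference_probe.footprint
    add("probes_do_not_overlap", t1 <= r0 or r1 <= t0, (assay.target_probe.footprint, assay.reference_probe.footprint))
    add("target_probe_contains_cut", t0 < assay.cut_site < t1, assay.cut_site)
    lna = sorted(assay.target_probe.lna_positions)
    consec = any(
        lna[i + 2] - lna[i] == 2 for i in range(len(lna) - 2)
    ) if len(lna) >= 3 else False
    cut_in_probe = assay.cut_site - t0
    triplet_near_cut = consec and any(
        abs(p - cut_in_probe) <= 3 for p in lna
    )
    add("target_probe_lna_triplet_at_cut", triplet_near_cut, lna)
    add("reference_probe_distal_to_cut", not (r0 < assay.cut_site < r1) and not (r0 <= assay.cut_site < r1), assay.cut_site)
    add("channels_differ", assay.target_probe.channel != assay.reference_probe.channel,
        (assay.target_probe.channel, assay.reference_probe.channel))

    tgt_tm = _probe_tm(assay.target_probe.sequence, assay.target_probe.lna_positions, cond).tm_C
    ref_tm = _probe_tm(assay.reference_probe.sequence, assay.reference_probe.lna_positions, cond).tm_C
    fw_tm = _oligo_tm(assay.fw_primer.sequence, cond)
    rv_tm = _oligo_tm(assay.rv_primer.sequence, cond)
    offset = min(tgt_tm, ref_tm) - max(fw_tm, rv_tm)
    lo, hi = c.probe_primer_tm_offset
    add("probe_primer_tm_offset_in_window", lo - 1e-9 <= offset <= hi + 1e-9, round(offset, 3))
    add("probe_probe_tm_tolerance", abs(tgt_tm - ref_tm) <= c.probe_tm_tolerance + 1e-9,
        round(abs(tgt_tm - ref_tm), 3))
    add("amplicon_length_in_range",
        c.amplicon_length_range[0] <= a1 - a0 <= c.amplicon_length_range[1], a1 - a0)
    return checks


def assay_failures(checks: list[ConstraintCheck]) -> list[ConstraintCheck]:
    return [c for c in checks if not c.passed]
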