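"""Nearest-neighbor hybridization thermodynamics for DNA probes with LNA substitutions.

Two-state duplex model: enthalpy/entropy are summed over nearest-neighbor stacks
(unified DNA/DNA parameter set, with the published single-internal-mismatch and
terminal-mismatch tables), locked-nucleic-acid residues contribute per-base
stabilization increments, and the melting temperature is corrected for divalent
cations (Owczarzy-style Mg2+ correction with free Mg2+ = Mg2+ - dNTP, since dNTPs
chelate magnesium stoichiometrically).  The equilibrium bound fraction at the
annealing temperature follows from the two-state mass-action law, so that
bound_fraction = 0.5 exactly when the annealing temperature equals Tm at the
reference strand concentration.

The NN/mismatch parameter *tables* are published data and are imported from
Bio.SeqUtils.MeltingTemp; all summation, LNA, bulge and salt-correction logic
lives here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.SeqUtils import MeltingTemp as _mt

from .errors import AlignmentError, InputError

R_GAS = 1.987  # cal / (mol K)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

# Per-locked-base stabilization increments (dH kcal/mol, dS cal/mol/K).
# Condensed per-base form of published LNA duplex-stabilization data
# (ddG37 of roughly -0.9 to -1.3 kcal/mol per internal locked residue).
LNA_BASE_INCREMENT = {
    "A": (-3.3, -7.74),
    "C": (-4.5, -10.48),
    "G": (-4.0, -9.35),
    "T": (-3.5, -8.22),
}
# Extra destabilization when the locked residue itself is mismatched/bulged,
# and when a mismatch sits immediately adjacent to a locked residue.  LNA
# sharpens discrimination: a mismatch under or next to a lock costs more
# than the same mismatch in an unmodified probe.
LNA_MISMATCH_PENALTY = (3.0, 1.6)   # ddG37 ~ +2.5 kcal/mol
LNA_ADJACENT_PENALTY = (1.5, 0.97)  # ddG37 ~ +1.2 kcal/mol
# Fixed destabilization per bulged (unpaired) base; no complete NN table for
# bulges exists, and only relative discrimination is consumed downstream.
DEFAULT_BULGE_PENALTY = (3.5, 2.26)  # ddG37 ~ +2.8 kcal/mol


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise InputError(f"cannot complement non-ACGT base {base!r}")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _check_sequence(seq: str, what: str, strict_acgt: bool = True) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise InputError(f"{what} contains non-IUPAC characters: {sorted(bad)}")
    if strict_acgt and (set(seq) - set("ACGT")):
        raise InputError(
            f"{what} contains ambiguity codes; thermodynamics require unambiguous ACGT"
        )
    return seq


@dataclass(frozen=True)
class BufferConditions:
    """Solution conditions of the hybridization reaction.

    Defaults mirror standard multiplex qPCR chemistry: 50 mM monovalent,
    3.0 mM Mg2+, 0.8 mM total dNTPs, 250 nM total probe strand, 60 C anneal.
    """

    monovalent_mM: float = 50.0
    mg_mM: float = 3.0
    dntp_mM: float = 0.8
    strand_conc_nM: float = 250.0
    anneal_temp_C: float = 60.0

    def __post_init__(self):
        for name in ("monovalent_mM", "mg_mM", "dntp_mM", "strand_conc_nM"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.strand_conc_nM == 0:
            raise InputError("strand_conc_nM must be > 0")

    @property
    def free_mg_M(self) -> float:
        """Free Mg2+ (mol/L) after stoichiometric dNTP chelation."""
        return max(self.mg_mM - self.dntp_mM, 0.0) * 1e-3


@dataclass(frozen=True)
class Duplex:
    """A probe bound to a template strand at a fixed offset (gapless pairing).

    ``template_sequence`` is the strand the probe hybridizes to, written 5'->3';
    the probe pairs antiparallel with template[offset : offset + len(probe)],
    so a perfect-match probe equals the reverse complement of that site.
    """

    probe_sequence: str
    template_sequence: str
    lna_positions: frozenset[int] = field(default_factory=frozenset)
    alignment_offset: int = 0

    def __post_init__(self):
        probe = _check_sequence(self.probe_sequence, "probe_sequence")
        template = _check_sequence(self.template_sequence, "template_sequence")
        object.__setattr__(self, "probe_sequence", probe)
        object.__setattr__(self, "template_sequence", template)
        object.__setattr__(self, "lna_positions", frozenset(self.lna_positions))
        if not 8 <= len(probe) <= 60:
            raise InputError("probe length must be in [8, 60]")
        if any(p < 0 or p >= len(probe) for p in self.lna_positions):
            raise InputError("every lna_position must index into the probe")
        if self.alignment_offset < 0 or self.alignment_offset + len(probe) > len(template):
            raise AlignmentError(
                "probe does not fit on the template at the given alignment_offset"
            )

    @property
    def site(self) -> str:
        """Template region under the probe, 5'->3'."""
        o = self.alignment_offset
        return self.template_sequence[o : o + len(self.probe_sequence)]

    def pairing(self) -> list[tuple[str | None, str | None, int | None]]:
        """Per-position pairing events along the probe 5'->3'.

        Each event is (probe_base|None, template_base|None, probe_index|None);
        template bases are reported in 3'->5' order (antiparallel partner).
        """
        site_3to5 = self.site[::-1]
        return [
            (p, t, i)
            for i, (p, t) in enumerate(zip(self.probe_sequence, site_3to5))
        ]

    def mismatch_positions(self) -> list[int]:
        return [
            i
            for p, t, i in self.pairing()
            if p is not None and t is not None and _COMPLEMENT[p] != t
        ]


@dataclass(frozen=True)
class ThermoResult:
    dH: float  # kcal/mol
    dS: float  # cal/(mol K), at 1 M monovalent before salt correction
    tm_C: float
    bound_fraction_at_anneal: float


@dataclass(frozen=True)
class MismatchDiscrimination:
    delta_tm_C: float
    delta_bound_fraction: float
    wt: ThermoResult
    variant: ThermoResult


def _table_lookup(table: dict, key: str):
    """NN-table lookup with the 180-degree-rotation fallback (reversed key)."""
    if key in table:
        return table[key]
    rkey = key[::-1]
    return table.get(rkey)


def _pairing_thermo(
    events: list[tuple[str | None, str | None, int | None]],
    lna_positions: frozenset[int],
    bulge_penalty: tuple[float, float] = DEFAULT_BULGE_PENALTY,
) -> tuple[float, float, int]:
    """Sum dH (kcal/mol) / dS (cal/mol/K) over a pairing-event list.

    Events: (probe_base|None, template_base(3'->5')|None, probe_index|None);
    None on one side marks a bulged base.  Stacks spanning a bulge contribute
    nothing; each bulged base adds a fixed penalty.  Returns (dH, dS, n_pairs).
    """
    dH = 0.0
    dS = 0.0

    def is_pair(e):
        return e[0] is not None and e[1] is not None

    def is_match(e):
        return is_pair(e) and _COMPLEMENT[e[0]] == e[1]

    pairs = [e for e in events if is_pair(e)]
    if len(pairs) < 2:
        raise AlignmentError("fewer than two paired positions; no duplex forms")

    # initiation at each matched terminus
    for term in (pairs[0], pairs[-1]):
        if is_match(term):
            key = "init_A/T" if term[0] in "AT" else "init_G/C"
            h, s = _mt.DNA_NN3[key]
            dH += h
            dS += s

    for a, b in zip(events, events[1:]):
        if not (is_pair(a) and is_pair(b)):
            continue  # stack broken by a bulge
        key = f"{a[0]}{b[0]}/{a[1]}{b[1]}"
        ma, mb = is_match(a), is_match(b)
        if ma and mb:
            val = _table_lookup(_mt.DNA_NN3, key)
        elif ma or mb:
            internal = a is not events[0] and b is not events[-1]
            val = _table_lookup(_mt.DNA_IMM1 if internal else _mt.DNA_TMM, key)
        else:
            val = None  # tandem mismatch: no stack credit
        if val is not None:
            dH += val[0]
            dS += val[1]

    # bulges
    n_bulged = sum(1 for e in events if not is_pair(e))
    dH += bulge_penalty[0] * n_bulged
    dS += bulge_penalty[1] * n_bulged

    # LNA terms
    mismatched_idx = {e[2] for e in events if is_pair(e) and not is_match(e)}
    bulged_probe_idx = {e[2] for e in events if e[2] is not None and e[1] is None}
    for i in sorted(lna_positions):
        if i in bulged_probe_idx or i in mismatched_idx:
            dH += LNA_MISMATCH_PENALTY[0]
            dS += LNA_MISMATCH_PENALTY[1]
            continue
        # locked residue is paired and matched: stabilization
        base = next((e[0] for e in events if e[2] == i), None)
        if base is None:
            continue
        h, s = LNA_BASE_INCREMENT[base]
        dH += h
        dS += s
        for j in (i - 1, i + 1):
            if j in mismatched_idx:
                dH += LNA_ADJACENT_PENALTY[0]
                dS += LNA_ADJACENT_PENALTY[1]

    return dH, dS, len(pairs)


def _owczarzy_mg_inverse_tm_shift(fgc: float, nbp: int, mon_M: float, mg_M: float) -> float:
    """Additive correction to 1/Tm (K^-1) for divalent/monovalent salt."""
    a, b, c, d = 3.92e-5, -9.11e-6, 6.26e-5, 1.42e-5
    e, f, g = -4.82e-4, 5.25e-4, 8.31e-5
    if mg_M <= 0 and mon_M <= 0:
        return 0.0
    if mg_M <= 0:
        # monovalent-only correction
        ln_m = math.log(mon_M)
        return (4.29 * fgc - 3.95) * 1e-5 * ln_m + 9.40e-6 * ln_m ** 2
    if mon_M > 0:
        ratio = math.sqrt(mg_M) / mon_M
        if ratio < 0.22:
            ln_m = math.log(mon_M)
            return (4.29 * fgc - 3.95) * 1e-5 * ln_m + 9.40e-6 * ln_m ** 2
        if ratio < 6.0:
            ln_m = math.log(mon_M)
            a = 3.92e-5 * (0.843 - 0.352 * math.sqrt(mon_M) * ln_m)
            d = 1.42e-5 * (1.279 - 4.03e-3 * ln_m - 8.03e-3 * ln_m ** 2)
            g = 8.31e-5 * (0.486 - 0.258 * ln_m + 5.25e-3 * ln_m ** 3)
    ln_mg = math.log(mg_M)
    return (
        a
        + b * ln_mg
        + fgc * (c + d * ln_mg)
        + (1.0 / (2.0 * (nbp - 1))) * (e + f * ln_mg + g * ln_mg ** 2)
    )


def _two_state_bound_fraction(dH: float, dS_eff: float, temp_C: float, ct_M: float) -> float:
    """Fraction of probe strands in duplex at temp_C (equal strand concentrations)."""
    t_K = temp_C + 273.15
    exponent = -(dH * 1000.0 - t_K * dS_eff) / (R_GAS * t_K)
    exponent = min(exponent, 500.0)
    k_eq = math.exp(exponent)
    c0 = ct_M / 2.0
    x = k_eq * c0
    if x < 1e-12:
        return x  # dilute limit
    disc = (2 * x + 1) ** 2 - 4 * x * x
    return (2 * x + 1 - math.sqrt(disc)) / (2 * x)


def duplex_thermo(
    events: list[tuple[str | None, str | None, int | None]],
    lna_positions: frozenset[int],
    cond: BufferConditions,
    bulge_penalty: tuple[float, float] = DEFAULT_BULGE_PENALTY,
) -> ThermoResult:
    """Two-state thermodynamics for an arbitrary pairing-event list."""
    dH, dS, n_pairs = _pairing_thermo(events, lna_positions, bulge_penalty)
    ct = cond.strand_conc_nM * 1e-9
    denom = dS + R_GAS * math.log(ct / 4.0)
    tm_1m_K = dH * 1000.0 / denom if denom != 0 else float("nan")

    paired = [e for e in events if e[0] is not None and e[1] is not None]
    fgc = sum(1 for e in paired if e[0] in "GC") / max(len(paired), 1)
    shift = _owczarzy_mg_inverse_tm_shift(
        fgc, max(n_pairs, 2), cond.monovalent_mM * 1e-3, cond.free_mg_M
    )
    tm_K = 1.0 / (1.0 / tm_1m_K + shift) if tm_1m_K > 0 else tm_1m_K
    # entropy consistent with the salt-corrected Tm, so bound_fraction(Tm) = 0.5
    dS_eff = dH * 1000.0 / tm_K - R_GAS * math.log(ct / 4.0)
    bound = _two_state_bound_fraction(dH, dS_eff, cond.anneal_temp_C, ct)
    return ThermoResult(dH=dH, dS=dS, tm_C=tm_K - 273.15, bound_fraction_at_anneal=bound)


def melting_temperature(duplex: Duplex, cond: BufferConditions | None = None) -> ThermoResult:
    """Tm and annealing-temperature bound fraction for a gapless probe/template duplex.

    Up to 30% of probe positions may be mismatched; more indicates the probe is
    being evaluated against the wrong site and raises :class:`AlignmentError`.
    """
    cond = cond or BufferConditions()
    n_mm = len(duplex.mismatch_positions())
    if n_mm > 0.30 * len(duplex.probe_sequence):
        raise AlignmentError(
            f"{n_mm} mismatched positions exceed 30% of probe length; "
            "sequences cannot be paired at this offset"
        )
    return duplex_thermo(duplex.pairing(), duplex.lna_positions, cond)


# --- mismatch / indel discrimination -------------------------------------------------

_PROBE_ALIGNER = Align.PairwiseAligner()
_PROBE_ALIGNER.mode = "local"
_PROBE_ALIGNER.match_score = 1
_PROBE_ALIGNER.mismatch_score = -1
_PROBE_ALIGNER.open_gap_score = -3
_PROBE_ALIGNER.extend_gap_score = -1


def _gapless_match_count(probe: str, template: str, offset: int) -> int:
    site_rc = revcomp(template[offset : offset + len(probe)])
    return sum(1 for a, b in zip(probe, site_rc) if a == b)


def _best_gapless_offset(probe: str, template: str) -> tuple[int, int]:
    best = (-1, -1)
    for o in range(len(template) - len(probe) + 1):
        m = _gapless_match_count(probe, template, o)
        if m > best[1]:
            best = (o, m)
    if best[0] < 0:
        raise AlignmentError("probe longer than template")
    return best


def _events_from_alignment(probe: str, template: str) -> list:
    """Pairing events for a probe on a template allowing indels under the footprint.

    The probe's reverse complement is template-sense, so it is aligned to the
    template directly; aligned columns become base pairs, gaps become bulges.
    """
    probe_rc = revcomp(probe)
    aln = _PROBE_ALIGNER.align(probe_rc, template)[0]
    events: list[tuple[str | None, str | None, int | None]] = []
    blocks_q, blocks_t = aln.aligned  # (probe_rc blocks, template blocks)
    prev_q = prev_t = None
    for (q0, q1), (t0, t1) in zip(blocks_q, blocks_t):
        if prev_q is not None:
            for q in range(prev_q, q0):  # probe-side bulge
                i = len(probe) - 1 - q
                events.append((probe[i], None, i))
            for t in range(prev_t, t0):  # template-side bulge
                events.append((None, template[t], None))
        for q, t in zip(range(q0, q1), range(t0, t1)):
            i = len(probe) - 1 - q  # probe_rc runs 3'->5' along the probe
            events.append((probe[i], template[t], i))
        prev_q, prev_t = q1, t1
    # events were built along the probe 3'->5'; reverse so they run 5'->3'
    # along the probe, leaving template partners in 3'->5' order as the NN
    # key convention requires.
    events.reverse()
    return events


def mismatch_discrimination(
    probe,
    wt_template: str,
    variant_template: str,
    cond: BufferConditions | None = None,
) -> MismatchDiscrimination:
    """Tm and bound-fraction penalty of a variant duplex relative to wild type.

    ``probe`` is anything with ``sequence`` and ``lna_positions`` attributes (a
    :class:`~lnadrop.assay_design.ProbeDesign`) or a plain ``(sequence,
    lna_positions)`` tuple.  Templates may be supplied on either strand; the
    orientation is auto-detected from the wild-type placement.  A variant
    identical to wild type under the probe footprint yields dTm = 0 with a
    no-discrimination warning.
    """
    cond = cond or BufferConditions()
    if isinstance(probe, tuple):
        seq, lna = probe
    else:
        seq, lna = probe.sequence, probe.lna_positions
    seq = _check_sequence(seq, "probe")
    lna = frozenset(lna)
    wt_template = _check_sequence(wt_template, "wt_template")
    variant_template = _check_sequence(variant_template, "variant_template")

    # orientation: the probe should bind one strand of the wt template nearly
    # perfectly; test both and keep the better.
    off_f, m_f = _best_gapless_offset(seq, wt_template)
    wt_rc = revcomp(wt_template)
    off_r, m_r = _best_gapless_offset(seq, wt_rc)
    if m_r > m_f:
        wt_template, variant_template = wt_rc, revcomp(variant_template)
        off_f = off_r
    wt_res = melting_temperature(
        Duplex(seq, wt_template, lna, off_f), cond
    )

    # footprint comparison for the no-discrimination warning
    wt_site = wt_template[off_f : off_f + len(seq)]
    off_v, m_v = _best_gapless_offset(seq, variant_template)
    var_site = variant_template[off_v : off_v + len(seq)]
    if wt_site == var_site and len(wt_template) == len(variant_template):
        warnings.warn(
            "variant is identical to wild type under the probe footprint; "
            "no discrimination (dTm = 0)",
            stacklevel=2,
        )
        return MismatchDiscrimination(0.0, 0.0, wt_res, wt_res)

    if m_v == len(seq):
        var_res = melting_temperature(Duplex(seq, variant_template, lna, off_v), cond)
    else:
        events = _events_from_alignment(seq, variant_template)
        var_res = duplex_thermo(events, lna, cond)

    return MismatchDiscrimination(
        delta_tm_C=wt_res.tm_C - var_res.tm_C,
        delta_bound_fraction=wt_res.bound_fraction_at_anneal - var_res.bound_fraction_at_anneal,
        wt=wt_res,
        variant=var_res,
    )
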