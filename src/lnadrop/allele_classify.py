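"""Clone-sequence alignment, variant calling and allele taxonomy.

Each Sanger/plasmid clone of the target amplicon is globally aligned to the
reference (affine gaps: match +1, mismatch -2, open -5, extend -1 — weights
that favor parsimonious indel calls at amplicon scale), variants are extracted
and indels left-shifted within repeat context, and the allele is classified
inside a fixed analysis window (default 70 nt centered on the cut site) into:

    wt, HDR, partial_HDR, deletion, insertion, point_mutation, mixed

HDR is defined by a donor template with named components (target codon change,
PAM mutation, silent restriction site): an allele is HDR iff all components are
present and nothing else is altered in the window; partial_HDR iff a nonempty
proper subset of components is present and nothing else; alleles combining two
or more variant classes (ins/del, del/mut, mut/ins, ...) are mixed.  Variants
outside the window are recorded separately and do not affect the category.

All coordinates are 0-based half-open internally; reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .errors import IncompleteCloneError, InputError, UnalignableCloneError
from .thermo import _check_sequence, revcomp

CATEGORIES = ("wt", "HDR", "partial_HDR", "deletion", "insertion", "point_mutation", "mixed")

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5   # cost of the first base of a gap
GAP_EXTEND = -1

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = MATCH_SCORE
_ALIGNER.mismatch_score = MISMATCH_SCORE
_ALIGNER.open_gap_score = GAP_OPEN
_ALIGNER.extend_gap_score = GAP_EXTEND


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized difference against the reference.

    substitution: pos, ref base(s) -> alt base(s) (always length 1 here);
    insertion: alt inserted before reference position pos (ref == "");
    deletion: ref bases removed starting at pos (alt == "").
    """

    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "substitution"
        return "insertion" if self.alt else "deletion"

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    def one_based(self) -> str:
        return f"{self.pos + 1}:{self.ref or '-'}>{self.alt or '-'}"


@dataclass(frozen=True)
class HdrComponent:
    name: str  # target_codon | pam_mutation | silent_restriction_site
    start: int
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != len(self.alt) or not self.ref:
            raise InputError("HDR components must be same-length substitutions")


@dataclass(frozen=True)
class HdrTemplate:
    components: tuple[HdrComponent, ...]
    restriction_site: str = "GAATTC"  # EcoRI by convention

    def __post_init__(self):
        spans = sorted((c.start, c.start + len(c.ref)) for c in self.components)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise InputError("HDR components must not overlap")

    @property
    def component_names(self) -> frozenset[str]:
        return frozenset(c.name for c in self.components)

    def footprint(self) -> set[int]:
        pos: set[int] = set()
        for c in self.components:
            pos.update(range(c.start, c.start + len(c.ref)))
        return pos


@dataclass(frozen=True)
class CloneAlignment:
    clone_id: str
    reference: str
    clone_seq: str          # orientation-normalized (reference strand)
    orientation: str        # '+' if input was already reference-strand
    score: float
    identity: float
    columns: tuple[tuple[int | None, str | None, str | None], ...]
    # columns: (ref_pos|None, ref_base|None, clone_base|None); None marks a gap


@dataclass(frozen=True)
class AlleleRecord:
    clone_id: str
    category: str
    variants_in_window: tuple[Variant, ...]
    variants_outside_window: tuple[Variant, ...]
    hdr_components_present: frozenset[str]
    identity: float
    orientation: str

    @property
    def variant_key(self) -> tuple[Variant, ...]:
        """Exact-identity key used to count distinct alleles."""
        return tuple(sorted(self.variants_in_window + self.variants_outside_window))


@dataclass(frozen=True)
class FounderSummary:
    animal_id: str
    n_clones: int
    distinct_alleles: int
    category_fractions: dict[str, float]
    wt_percent: float
    n_variants_outside_window: int


def default_window(cut_site: int, width: int = 70) -> tuple[int, int]:
    """Analysis window of ``width`` nt centered on the inter-base cut coordinate."""
    return (cut_site - width // 2, cut_site + (width + 1) // 2)


def align_to_reference(
    clone_seq: str,
    reference: str,
    clone_id: str = "clone",
    min_identity: float = 0.60,
) -> CloneAlignment:
    """Global affine-gap alignment with orientation auto-detection.

    The reverse complement is tried as well and the better-scoring orientation
    kept, so classification is invariant to clone orientation.  Clones below
    ``min_identity`` raise :class:`UnalignableCloneError` (off-target amplicon
    or vector sequence).
    """
    clone_seq = _check_sequence(clone_seq, "clone_seq")
    reference = _check_sequence(reference, "reference")
    if not 0.5 * len(reference) <= len(clone_seq) <= 1.5 * len(reference):
        raise InputError("clone length outside 0.5-1.5x the reference length")

    fwd = _ALIGNER.align(reference, clone_seq)
    rev = _ALIGNER.align(reference, revcomp(clone_seq))
    if fwd.score >= rev.score:
        aln, seq, orientation = fwd[0], clone_seq, "+"
        score = fwd.score
    else:
        aln, seq, orientation = rev[0], revcomp(clone_seq), "-"
        score = rev.score

    columns: list[tuple[int | None, str | None, str | None]] = []
    blocks_r, blocks_q = aln.aligned
    prev_r = prev_q = 0
    matches = 0
    for (r0, r1), (q0, q1) in zip(blocks_r, blocks_q):
        for r in range(prev_r, r0):   # deletion in clone
            columns.append((r, reference[r], None))
        for q in range(prev_q, q0):   # insertion in clone, before ref pos r0
            columns.append((r0, None, seq[q]))
        for r, q in zip(range(r0, r1), range(q0, q1)):
            columns.append((r, reference[r], seq[q]))
            if reference[r] == seq[q]:
                matches += 1
        prev_r, prev_q = r1, q1
    for r in range(prev_r, len(reference)):
        columns.append((r, reference[r], None))
    for q in range(prev_q, len(seq)):
        columns.append((len(reference), None, seq[q]))

    # identity over the shorter sequence: a cleanly truncated clone is not
    # "unalignable" (it fails the window-coverage check instead)
    identity = matches / min(len(reference), len(seq))
    if identity < min_identity:
        raise UnalignableCloneError(
            f"{clone_id}: identity {identity:.2f} below floor {min_identity:.2f}"
        )
    return CloneAlignment(clone_id, reference, seq, orientation, float(score),
                          identity, tuple(columns))


def _left_shift(pos: int, seq: str, reference: str) -> tuple[int, str]:
    """Shift an indel leftward through identical context (homopolymers/repeats)."""
    while pos > 0 and seq and reference[pos - 1] == seq[-1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_variants(alignment: CloneAlignment) -> tuple[Variant, ...]:
    """Normalized variant list from an alignment (indels left-shifted)."""
    reference = alignment.reference
    variants: list[Variant] = []
    run_kind: str | None = None
    run_pos = 0
    run_seq: list[str] = []

    def flush():
        nonlocal run_kind, run_seq
        if run_kind == "del":
            pos, seq = _left_shift(run_pos, "".join(run_seq), reference)
            variants.append(Variant(pos, seq, ""))
        elif run_kind == "ins":
            pos, seq = _left_shift(run_pos, "".join(run_seq), reference)
            variants.append(Variant(pos, "", seq))
        run_kind, run_seq = None, []

    for ref_pos, ref_base, clone_base in alignment.columns:
        if ref_base is not None and clone_base is not None:
            flush()
            if ref_base != clone_base:
                variants.append(Variant(ref_pos, ref_base, clone_base))
        elif clone_base is None:  # deletion column
            if run_kind != "del" or ref_pos != run_pos + len(run_seq):
                flush()
                run_kind, run_pos = "del", ref_pos
            run_seq.append(ref_base)
        else:  # insertion column
            if run_kind != "ins" or ref_pos != run_pos:
                flush()
                run_kind, run_pos = "ins", ref_pos
            run_seq.append(clone_base)
    flush()
    return tuple(sorted(variants))


def _variant_in_window(v: Variant, window: tuple[int, int]) -> bool:
    w0, w1 = window
    if v.kind == "insertion":
        return w0 < v.pos < w1
    return v.pos < w1 and v.end > w0


def classify_allele(
    alignment: CloneAlignment,
    hdr: HdrTemplate,
    window: tuple[int, int],
) -> AlleleRecord:
    """Category call for one aligned clone against the HDR template.

    Raises :class:`IncompleteCloneError` when the clone does not span the
    analysis window.
    """
    aligned_ref = [c[0] for c in alignment.columns if c[1] is not None and c[2] is not None]
    # the clone must reach both window boundaries (an in-window deletion is
    # fine; a truncated clone that starts or ends inside the window is not)
    if not aligned_ref or aligned_ref[0] > window[0] or aligned_ref[-1] < window[1] - 1:
        raise IncompleteCloneError(
            f"{alignment.clone_id}: alignment does not cover the analysis window"
        )

    variants = call_variants(alignment)
    in_win = tuple(v for v in variants if _variant_in_window(v, window))
    out_win = tuple(v for v in variants if not _variant_in_window(v, window))

    # component presence: clone base(s) aligned to the component coordinates
    clone_at: dict[int, str | None] = {}
    for ref_pos, ref_base, clone_base in alignment.columns:
        if ref_base is not None:
            clone_at[ref_pos] = clone_base
    present: set[str] = set()
    for comp in hdr.components:
        observed = [clone_at.get(p) for p in range(comp.start, comp.start + len(comp.ref))]
        if None not in observed and "".join(observed) == comp.alt:
            present.add(comp.name)

    footprint = hdr.footprint()
    hdr_subs = {
        v for v in in_win
        if v.kind == "substitution" and v.pos in footprint
    }
    other = [v for v in in_win if v not in hdr_subs]

    if not in_win:
        category = "wt"
    elif present == set(hdr.component_names) and not other:
        category = "HDR"
    elif present and not other:
        category = "partial_HDR"
    else:
        kinds = {v.kind for v in in_win}
        if len(kinds) >= 2:
            category = "mixed"
        else:
            category = {
                "substitution": "point_mutation",
                "deletion": "deletion",
                "insertion": "insertion",
            }[kinds.pop()]

    return AlleleRecord(
        clone_id=alignment.clone_id,
        category=category,
        variants_in_window=in_win,
        variants_outside_window=out_win,
        hdr_components_present=frozenset(present),
        identity=alignment.identity,
        orientation=alignment.orientation,
    )


def summarize_founder(
    records: list[AlleleRecord],
    animal_id: str | None = None,
    collapse_singleton_substitutions: bool = False,
) -> FounderSummary:
    """Per-animal mosaicism summary: category fractions and allele diversity.

    Distinct alleles are counted by exact variant-set identity after gap
    normalization.  ``collapse_singleton_substitutions`` optionally merges an
    allele seen once that differs from a more abundant allele by exactly one
    extra substitution (a concession to sequencing error; off by default since
    plasmid clones are high-quality).
    """
    if not records:
        raise InputError("at least one classified record required")
    if animal_id is None:
        animal_id = records[0].clone_id.split(".")[0]

    keys: dict[tuple, int] = {}
    for r in records:
        keys[r.variant_key] = keys.get(r.variant_key, 0) + 1

    if collapse_singleton_substitutions:
        singletons = [k for k, n in keys.items() if n == 1]
        for k in singletons:
            kset = set(k)
            for other, n_other in sorted(keys.items(), key=lambda kv: -kv[1]):
                if other == k or n_other < 2:
                    continue
                diff = kset.symmetric_difference(other)
                if len(diff) == 1 and next(iter(diff)).kind == "substitution":
                    keys[other] += keys.pop(k)
                    break

    n = len(records)
    counts = {cat: 0 for cat in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    fractions = {cat: c / n for cat, c in counts.items()}
    return FounderSummary(
        animal_id=animal_id,
        n_clones=n,
        distinct_alleles=len(keys),
        category_fractions=fractions,
        wt_percent=100.0 * fractions["wt"],
        n_variants_outside_window=sum(len(r.variants_outside_window) for r in records),
    )


def hdr_component_venn(
    records: list[AlleleRecord],
    hdr: HdrTemplate,
) -> dict[frozenset[str], int]:
    """Counts of clones per nonempty HDR-component subset (Venn cells).

    Every one of the 2^k - 1 nonempty subsets appears as a key, zero-filled;
    a clone contributes to the cell matching exactly its present components.
    """
    names = sorted(hdr.component_names)
    cells: dict[frozenset[str], int] = {}
    for mask in range(1, 2 ** len(names)):
        subset = frozenset(n for i, n in enumerate(names) if mask >> i & 1)
        cells[subset] = 0
    for r in records:
        if r.hdr_components_present:
            cells[frozenset(r.hdr_components_present)] += 1
    return cells
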