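"""Alignment, variant normalization and the seven-category allele taxonomy."""

import numpy as np
import pytest

from lnadrop import simulate as sim
from lnadrop.allele_classify import (
    Variant,
    align_to_reference,
    call_variants,
    classify_allele,
    default_window,
    hdr_component_venn,
    summarize_founder,
)
from lnadrop.errors import IncompleteCloneError, InputError, UnalignableCloneError

from oracles import gotoh_all_optimal


@pytest.fixture(scope="module")
def window(locus):
    return default_window(locus[1])


def apply_hdr(reference, hdr, names=None):
    seq = list(reference)
    for c in hdr.components:
        if names is None or c.name in names:
            seq[c.start : c.start + len(c.ref)] = list(c.alt)
    return "".join(seq)


def test_identical_clone_is_wt(locus, window):
    reference, cut, hdr = locus
    aln = align_to_reference(reference, reference)
    assert aln.identity == 1.0
    assert call_variants(aln) == ()
    rec = classify_allele(aln, hdr, window)
    assert rec.category == "wt"
    assert rec.hdr_components_present == frozenset()


def test_unique_deletion_called_at_exact_coordinates(locus):
    reference = locus[0]
    # pick a deletion inside a locally unique context
    pos, k = 150, 4
    clone = reference[:pos] + reference[pos + k:]
    variants = call_variants(align_to_reference(clone, reference))
    score, oracle_sets = gotoh_all_optimal(reference[:300], clone[:300 - k])
    assert len(variants) == 1
    v = variants[0]
    assert v.kind == "deletion" and len(v.ref) == k
    assert (v.pos, v.ref, v.alt) in {vs[0] for vs in oracle_sets if len(vs) == 1}


def test_deletion_in_homopolymer_is_left_shifted(locus):
    reference = locus[0]
    run = reference.find("AAA")
    assert run > 0
    clone = reference[: run + 2] + reference[run + 3:]  # delete last A of the run
    variants = call_variants(align_to_reference(clone, reference))
    dels = [v for v in variants if v.kind == "deletion"]
    assert len(dels) == 1
    start = run
    while start > 0 and reference[start - 1] == "A":
        start -= 1
    assert dels[0].pos == start  # leftmost placement


def test_hdr_and_partial_hdr_categories(locus, window):
    reference, cut, hdr = locus
    full = apply_hdr(reference, hdr)
    rec = classify_allele(align_to_reference(full, reference), hdr, window)
    assert rec.category == "HDR"
    assert rec.hdr_components_present == hdr.component_names

    partial = apply_hdr(reference, hdr, {"pam_mutation", "silent_restriction_site"})
    rec2 = classify_allele(align_to_reference(partial, reference), hdr, window)
    assert rec2.category == "partial_HDR"
    assert rec2.hdr_components_present == frozenset({"pam_mutation", "silent_restriction_site"})


def test_deletion_plus_substitution_is_mixed(locus, window):
    reference, cut, hdr = locus
    clone = list(reference)
    del clone[cut : cut + 2]
    sub = cut - 20
    clone[sub] = "A" if reference[sub] != "A" else "G"
    rec = classify_allele(align_to_reference("".join(clone), reference), hdr, window)
    assert rec.category == "mixed"


def test_orientation_invariance(locus, window):
    reference, cut, hdr = locus
    clone = reference[:cut] + "TTACG" + reference[cut:]  # 5-nt insertion
    fwd = classify_allele(align_to_reference(clone, reference), hdr, window)
    from lnadrop.thermo import revcomp

    rev = classify_allele(align_to_reference(revcomp(clone), reference), hdr, window)
    assert rev.category == fwd.category == "insertion"
    assert rev.variants_in_window == fwd.variants_in_window
    assert rev.orientation == "-"


def test_truncated_clone_is_incomplete(locus, window):
    reference, cut, hdr = locus
    half = reference[: cut + 20]  # stops inside the window
    with pytest.raises(IncompleteCloneError):
        classify_allele(align_to_reference(half, reference), hdr, window)


def test_unalignable_clone_rejected(locus):
    reference = locus[0]
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=len(reference)))
    with pytest.raises(UnalignableCloneError):
        align_to_reference(junk, reference)


def test_clone_length_bounds(locus):
    reference = locus[0]
    with pytest.raises(InputError):
        align_to_reference(reference[:100], reference)


def test_founder_summary_counts(locus, window):
    reference, cut, hdr = locus
    wt_recs = [
        classify_allele(align_to_reference(reference, reference, f"m1.clone{i}"), hdr, window)
        for i in range(15)
    ]
    s = summarize_founder(wt_recs)
    assert s.distinct_alleles == 1
    assert s.wt_percent == 100.0
    assert s.animal_id == "m1"
    assert sum(s.category_fractions.values()) == pytest.approx(1.0)

    # five structurally different alleles -> five distinct
    clones = [
        reference,
        apply_hdr(reference, hdr),
        reference[:cut] + reference[cut + 3:],
        reference[:cut] + "ACGTA" + reference[cut:],
        reference[:cut - 15] + ("A" if reference[cut - 15] != "A" else "C") + reference[cut - 14:],
    ]
    recs = [
        classify_allele(align_to_reference(c, reference, f"m2.clone{i}"), hdr, window)
        for i, c in enumerate(clones)
    ]
    s2 = summarize_founder(recs)
    assert s2.distinct_alleles == 5
    assert len({r.category for r in recs}) == 5


def test_hdr_component_venn_counts(locus, window):
    reference, cut, hdr = locus
    all_wt = [
        classify_allele(align_to_reference(reference, reference, f"m.c{i}"), hdr, window)
        for i in range(4)
    ]
    cells = hdr_component_venn(all_wt, hdr)
    assert len(cells) == 7 and all(n == 0 for n in cells.values())

    recs = [
        classify_allele(align_to_reference(apply_hdr(reference, hdr), reference, f"m.f{i}"),
                        hdr, window)
        for i in range(2)
    ] + [
        classify_allele(align_to_reference(apply_hdr(reference, hdr, {"pam_mutation"}),
                                           reference, f"m.p{i}"), hdr, window)
        for i in range(3)
    ]
    cells2 = hdr_component_venn(recs, hdr)
    assert cells2[hdr.component_names] == 2
    assert cells2[frozenset({"pam_mutation"})] == 3
    assert sum(cells2.values()) == 5


def test_venn_counts_equal_brute_force_recount(locus, window):
    """Generator-driven records recounted by direct enumeration."""
    reference, cut, hdr = locus
    rng = np.random.default_rng(21)
    records = []
    for a in range(40):
        pop = sim.simulate_founder(seed=rng, reference=reference, cut_site=cut, hdr=hdr)
        for cid, seq in sim.simulate_clones(pop, 5, seed=rng, animal_id=f"x{a}"):
            records.append(classify_allele(align_to_reference(seq, reference, cid), hdr, window))
    cells = hdr_component_venn(records, hdr)
    brute = {}
    for r in records:
        if r.hdr_components_present:
            brute[frozenset(r.hdr_components_present)] = \
                brute.get(frozenset(r.hdr_components_present), 0) + 1
    for subset, n in cells.items():
        assert n == brute.get(subset, 0)


def test_founder_fractions_within_multinomial_bounds(locus, window):
    """Clone draws from a known two-allele population land inside 3-SE bounds."""
    reference, cut, hdr = locus
    pop = sim.population_from_wt_fraction(50.0, seed=1)
    n = 600
    clones = sim.simulate_clones(pop, n, seed=123, animal_id="big")
    recs = [classify_allele(align_to_reference(s, reference, c), hdr, window)
            for c, s in clones]
    s = summarize_founder(recs)
    se = 100 * np.sqrt(0.25 / n)
    assert abs(s.wt_percent - 50.0) < 3 * se


def test_variant_one_based_rendering():
    assert Variant(9, "A", "G").one_based() == "10:A>G"
    assert Variant(9, "AC", "").one_based() == "10:AC>-"
    assert Variant(9, "", "TT").one_based() == "10:->TT"
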