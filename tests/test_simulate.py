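"""Generator determinism, distributional correctness, generator/analyzer adjointness."""

import numpy as np
import pytest

from lnadrop import simulate as sim
from lnadrop.dpcr_quant import classify_partitions, wt_fraction_dpcr
from lnadrop.errors import InputError
from lnadrop.qpcr_quant import ddcq_wt_fraction


def test_pure_wt_config_yields_single_wt_allele():
    cfg = sim.FounderConfig(category_probs={"wt": 1.0}, allele_count_range=(1, 1))
    pop = sim.simulate_founder(cfg, seed=4)
    assert len(pop.alleles) == 1
    assert pop.alleles[0].category == "wt"
    assert pop.alleles[0].fraction == pytest.approx(1.0)
    assert pop.wt_fraction == pytest.approx(100.0)


def test_generators_are_bit_reproducible():
    a = sim.simulate_founder(seed=99)
    b = sim.simulate_founder(seed=99)
    assert a == b
    assert sim.simulate_clones(a, 10, seed=5) == sim.simulate_clones(b, 10, seed=5)
    ca = sim.simulate_dpcr_chip(a, n_partitions=500, seed=7)
    cb = sim.simulate_dpcr_chip(b, n_partitions=500, seed=7)
    assert np.array_equal(ca.calls, cb.calls)
    wa = sim.simulate_qpcr(a, seed=3)
    wb = sim.simulate_qpcr(b, seed=3)
    assert wa == wb


def test_category_frequencies_match_configured_probabilities():
    """Single-allele animals: category draw is exactly categorical(p)."""
    cfg = sim.FounderConfig(allele_count_range=(1, 1))
    rng = np.random.default_rng(2)
    n = 4000
    counts = {c: 0 for c in sim.CATEGORIES}
    for _ in range(n):
        pop = sim.simulate_founder(cfg, seed=rng)
        counts[pop.alleles[0].category] += 1
    for cat, p in cfg.category_probs.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[cat] / n - p) < 3 * se, cat


def test_allele_count_range_and_distinctness():
    rng = np.random.default_rng(6)
    seen_counts = set()
    for _ in range(60):
        pop = sim.simulate_founder(seed=rng)
        seen_counts.add(len(pop.alleles))
        seqs = [a.window_seq for a in pop.alleles]
        assert len(set(seqs)) == len(seqs)
        assert sum(a.fraction for a in pop.alleles) == pytest.approx(1.0)
    assert seen_counts == {1, 2, 3, 4, 5}


def test_qpcr_simulation_closed_forms():
    noiseless = sim.AssayPhysics(binding_table=sim.lna_binding(), cq_noise_sd=0.0)
    wt = sim.population_from_wt_fraction(100.0, seed=1)
    wells = sim.simulate_qpcr(wt, noiseless, seed=1, sample_id="cal")
    quarter = sim.population_from_wt_fraction(25.0, seed=2)
    wells_q = sim.simulate_qpcr(quarter, noiseless, seed=2, sample_id="s")
    # 25% wt with full drop-off: target Cq shifts by log2(4) = 2 cycles
    cq_t = [w.cq for w in wells_q if w.channel == "target"][0]
    cq_r = [w.cq for w in wells_q if w.channel == "reference"][0]
    assert cq_t - cq_r == pytest.approx(2.0)
    res = {r.sample_id: r for r in ddcq_wt_fraction(wells + wells_q, "cal")}
    assert res["cal"].delta_delta_cq == 0.0
    assert res["s"].wt_fraction == pytest.approx(25.0)


def test_qpcr_partial_binding_closed_form():
    """25% wt plus a 75% variant bound at 0.5 reads out as 62.5% 'wt'."""
    pop = sim.population_from_wt_fraction(25.0, edited_category="point_mutation", seed=3)
    physics = sim.AssayPhysics(binding_table=sim.uniform_edited_binding(0.5), cq_noise_sd=0.0)
    cal = sim.population_from_wt_fraction(100.0, seed=4)
    wells = sim.simulate_qpcr(cal, physics, seed=1, sample_id="cal")
    wells += sim.simulate_qpcr(pop, physics, seed=2, sample_id="s")
    res = {r.sample_id: r for r in ddcq_wt_fraction(wells, "cal")}
    assert res["s"].wt_fraction == pytest.approx(100 * (0.25 + 0.5 * 0.75), abs=1e-9)


def test_fully_edited_sample_emits_no_amplification():
    pop = sim.population_from_wt_fraction(0.0, seed=5)
    wells = sim.simulate_qpcr(pop, sim.AssayPhysics(binding_table=sim.lna_binding()), seed=1)
    target = [w for w in wells if w.channel == "target"]
    assert all(w.no_amplification for w in target)


def test_dpcr_chip_poisson_occupancy():
    pop = sim.population_from_wt_fraction(100.0, seed=1)
    chip = sim.simulate_dpcr_chip(pop, n_partitions=20000,
                                  mean_copies_per_partition=0.6, seed=8)
    frac_ref = chip.calls[:, 0].mean()
    expected = 1 - np.exp(-0.6)
    assert abs(frac_ref - expected) < 4 * np.sqrt(expected * (1 - expected) / 20000)
    # 100% wt: target-positive set equals reference-positive set
    assert np.array_equal(chip.calls[:, 0], chip.calls[:, 1])


def test_dpcr_zero_wt_population_has_no_target_positives():
    pop = sim.population_from_wt_fraction(0.0, seed=2)
    chip = sim.simulate_dpcr_chip(pop, n_partitions=1000, seed=3)
    assert chip.calls[:, 1].sum() == 0


def test_dpcr_round_trip_recovers_fraction():
    rng = np.random.default_rng(9)
    for true in (5.0, 25.0, 50.0, 75.0, 95.0):
        pop = sim.population_from_wt_fraction(true, seed=11)
        chip = sim.simulate_dpcr_chip(pop, n_partitions=20000, seed=rng)
        est = wt_fraction_dpcr(classify_partitions(chip))
        assert est.ci95[0] - 0.5 <= true <= est.ci95[1] + 0.5


def test_clone_draws_follow_binomial_law():
    pop = sim.population_from_wt_fraction(50.0, seed=1)
    rng = np.random.default_rng(14)
    wt_counts = []
    wt_seq = pop.full_sequence(pop.alleles[0])
    for _ in range(1000):
        clones = sim.simulate_clones(pop, 15, seed=rng)
        wt_counts.append(sum(1 for _, s in clones if s == wt_seq))
    wt_counts = np.array(wt_counts)
    assert abs(wt_counts.mean() - 7.5) < 3 * np.sqrt(15 * 0.25 / 1000)
    assert abs(wt_counts.var(ddof=1) - 15 * 0.25) < 0.5


def test_single_allele_population_yields_identical_clones():
    pop = sim.population_from_wt_fraction(100.0, seed=1)
    clones = sim.simulate_clones(pop, 8, seed=2)
    assert len({s for _, s in clones}) == 1
    assert [cid.split(".")[0] for cid, _ in clones] == ["animal1"] * 8


def test_endpoint_centroids_and_ntc():
    params = sim.EndpointClusterParams()
    ntc = sim.simulate_endpoint("NTC", params, seed=1)
    assert ntc.fluor_wt < 0.3 and ntc.fluor_mut < 0.3
    # HET centroid is the WT/HOMO midpoint by construction
    assert params.het_centroid == (
        pytest.approx((params.wt_centroid[0] + params.homo_centroid[0]) / 2),
        pytest.approx((params.wt_centroid[1] + params.homo_centroid[1]) / 2),
    )
    with pytest.raises(InputError):
        sim.simulate_endpoint("XX", params, seed=1)
    with pytest.raises(InputError):
        sim.simulate_endpoint(("mosaic", 1.5), params, seed=1)


def test_invalid_configs_rejected():
    with pytest.raises(InputError):
        sim.FounderConfig(category_probs={"wt": 0.5})
    with pytest.raises(InputError):
        sim.AssayPhysics(binding_table={"wt": (1.2, 1.0)})
    with pytest.raises(InputError):
        sim.simulate_dpcr_chip(sim.population_from_wt_fraction(50.0, seed=1),
                               n_partitions=10, seed=1)
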