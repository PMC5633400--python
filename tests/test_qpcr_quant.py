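"""ddCq arithmetic, replicate handling, calibration slope, estimator behaviour."""

import numpy as np
import pytest

from lnadrop import simulate as sim
from lnadrop.errors import InputError
from lnadrop.qpcr_quant import (
    DilutionSeries,
    QpcrWell,
    calibration_slope,
    ddcq_wt_fraction,
    summarize_replicates,
)

from oracles import ols_slope_intercept


def wells_for(sample, target_cq, ref_cq, reps=3):
    out = []
    for r in range(1, reps + 1):
        out.append(QpcrWell(sample, "target", r, target_cq))
        out.append(QpcrWell(sample, "reference", r, ref_cq))
    return out


def test_ddcq_halving_example():
    """One extra target cycle relative to the calibrator means 50% wt."""
    plate = wells_for("cal", 24.0, 24.0) + wells_for("s", 25.0, 24.0)
    res = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}
    assert res["s"].delta_delta_cq == pytest.approx(1.0)
    assert res["s"].wt_fraction == pytest.approx(50.0)


def test_ddcq_equal_dcq_is_100_percent():
    plate = wells_for("cal", 24.0, 23.0) + wells_for("s", 26.0, 25.0)
    res = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}
    assert res["s"].wt_fraction == pytest.approx(100.0)
    assert res["cal"].wt_fraction == 100.0  # calibrator is 100% by construction


def test_recovery_of_simulated_true_fraction():
    """Noise-free plates recover the exact truth; noisy plates within 3 points
    in the mean (50 plates, sigma = 0.1)."""
    pop = sim.population_from_wt_fraction(30.0, seed=5)
    cal = sim.population_from_wt_fraction(100.0, seed=6)
    noiseless = sim.AssayPhysics(binding_table=sim.lna_binding(), cq_noise_sd=0.0)
    plate = sim.simulate_qpcr(cal, noiseless, seed=1, sample_id="cal")
    plate += sim.simulate_qpcr(pop, noiseless, seed=2, sample_id="s")
    res = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}
    assert res["s"].wt_fraction == pytest.approx(30.0, abs=1e-9)

    noisy = sim.AssayPhysics(binding_table=sim.lna_binding(), cq_noise_sd=0.1)
    rng = np.random.default_rng(12)
    ests = []
    for _ in range(50):
        plate = sim.simulate_qpcr(cal, noisy, seed=rng, sample_id="cal")
        plate += sim.simulate_qpcr(pop, noisy, seed=rng, sample_id="s")
        ests.append({r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}["s"].wt_fraction)
    assert abs(np.mean(ests) - 30.0) < 3.0


def test_oligo_probe_bias_direction():
    """Partial binding of edited alleles inflates the apparent wt fraction —
    the characteristic failure mode of unmodified oligo target probes."""
    cal = sim.population_from_wt_fraction(100.0, seed=6)
    noiseless_oligo = sim.AssayPhysics(binding_table=sim.uniform_edited_binding(0.5),
                                       cq_noise_sd=0.0)
    for true in (5.0, 30.0, 70.0, 95.0):
        pop = sim.population_from_wt_fraction(true, seed=5)
        plate = sim.simulate_qpcr(cal, noiseless_oligo, seed=1, sample_id="cal")
        plate += sim.simulate_qpcr(pop, noiseless_oligo, seed=2, sample_id="s")
        est = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}["s"].wt_fraction
        assert est > true
        assert est == pytest.approx(true + 0.5 * (100.0 - true), abs=1e-9)


def test_plate_invariances():
    """wt estimate is invariant to a constant Cq offset and strictly decreasing
    in the target Cq."""
    base = wells_for("cal", 24.0, 23.5) + wells_for("s", 25.0, 23.5)
    est0 = {r.sample_id: r for r in ddcq_wt_fraction(base, "cal")}["s"].wt_fraction
    shifted = [QpcrWell(w.sample_id, w.channel, w.replicate, w.cq + 3.0) for w in base]
    est1 = {r.sample_id: r for r in ddcq_wt_fraction(shifted, "cal")}["s"].wt_fraction
    assert est1 == pytest.approx(est0)
    higher_target = wells_for("cal", 24.0, 23.5) + wells_for("s", 25.4, 23.5)
    est2 = {r.sample_id: r for r in ddcq_wt_fraction(higher_target, "cal")}["s"].wt_fraction
    assert est2 < est0


def test_missing_channel_and_below_detection():
    plate = wells_for("cal", 24.0, 24.0)
    plate += [QpcrWell("noref", "target", 1, 25.0)]
    plate += [
        QpcrWell("edited", "target", r, None, frozenset({"noamp"})) for r in (1, 2, 3)
    ] + [QpcrWell("edited", "reference", r, 24.0) for r in (1, 2, 3)]
    res = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}
    assert res["noref"].error == "missing channel: reference"
    assert res["edited"].wt_fraction == 0.0
    assert "below_detection" in res["edited"].flags


def test_values_above_100_clip_with_raw_retained():
    plate = wells_for("cal", 24.0, 24.0) + wells_for("s", 23.5, 24.0)
    res = {r.sample_id: r for r in ddcq_wt_fraction(plate, "cal")}
    assert res["s"].wt_fraction == 100.0
    assert res["s"].wt_fraction_raw > 100.0
    assert "clipped" in res["s"].flags


def test_summarize_replicates_outlier_rule():
    s = summarize_replicates([QpcrWell("a", "target", r, cq) for r, cq in
                              enumerate((24.0, 24.0, 24.0), 1)])
    assert s.mean_cq == 24.0 and s.sd == 0.0
    s2 = summarize_replicates([QpcrWell("a", "target", r, cq) for r, cq in
                               enumerate((24.0, 24.1, 27.0), 1)])
    assert s2.outlier_replicates == (3,)
    assert s2.mean_cq == pytest.approx(24.05)


def test_summarize_replicates_matches_formulas():
    rng = np.random.default_rng(3)
    for _ in range(20):
        cqs = rng.normal(25, 0.5, size=3)
        med = np.median(cqs)
        cqs = np.clip(cqs, med - 0.4, med + 0.4)  # keep inside the outlier rule
        s = summarize_replicates([QpcrWell("a", "target", r + 1, c)
                                  for r, c in enumerate(cqs)])
        assert s.mean_cq == pytest.approx(np.mean(cqs))
        assert s.sem == pytest.approx(np.std(cqs, ddof=1) / np.sqrt(3))


def _series(dcqs):
    levels = []
    for i, d in enumerate(dcqs):
        wells = [QpcrWell("lvl", "target", r, 24.0 + d) for r in (1, 2, 3)]
        wells += [QpcrWell("lvl", "reference", r, 24.0) for r in (1, 2, 3)]
        levels.append((float(i), tuple(wells)))
    return DilutionSeries(tuple(levels))


def test_calibration_slope_pass_and_fail():
    flat = calibration_slope(_series([0.4] * 5))
    assert flat.slope == pytest.approx(0.0, abs=1e-12) and flat.passed
    rising = calibration_slope(_series([0.0, 0.15, 0.30, 0.45, 0.60]))
    assert rising.slope == pytest.approx(0.15)
    assert not rising.passed


def test_calibration_slope_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    dcqs = list(rng.normal(0.2, 0.3, size=6))
    res = calibration_slope(_series(dcqs))
    slope, intercept = ols_slope_intercept(list(range(6)), dcqs)
    assert res.slope == pytest.approx(slope, abs=1e-9)
    assert res.intercept == pytest.approx(intercept, abs=1e-9)


def test_calibration_needs_three_levels():
    with pytest.raises(InputError):
        _series([0.1, 0.2])


def test_well_validation():
    with pytest.raises(InputError):
        QpcrWell("a", "target", 1, -1.0)
    with pytest.raises(InputError):
        QpcrWell("a", "blue", 1, 24.0)
    # flagged no-amplification wells may omit cq
    w = QpcrWell("a", "target", 1, None, frozenset({"noamp"}))
    assert w.no_amplification
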