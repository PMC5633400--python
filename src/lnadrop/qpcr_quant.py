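"""Unedited-allele (wt) fraction from multiplex qPCR Cq data by the ddCq method.

For each sample, dCq = mean Cq(target) - mean Cq(reference); ddCq is referenced
to a designated unedited calibrator sample; wt fraction = 100 * 2^(-ddCq).
Both the drop-off configuration (internal reference probe in the same wells)
and the trans-multiplex configuration (external reference assay) reduce to the
same arithmetic here; the mode is recorded and validated but the estimator is
shared.  Amplification efficiency is assumed to be 2.0 on both channels; the
calibration-slope check (dCq regressed on log10 input) is the guard for that
assumption, with the conventional |slope| <= 0.1 pass rule.

SEM is propagated to first order from replicate Cq variability:
sd(ddCq)^2 = sem_t^2 + sem_r^2 + sem_t,cal^2 + sem_r,cal^2 and
sem(wt%) = wt% * ln(2) * sd(ddCq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

CHANNEL_TARGET = "target"
CHANNEL_REFERENCE = "reference"
FLAG_NO_AMPLIFICATION = "noamp"
FLAG_OUTLIER = "outlier"
DEFAULT_OUTLIER_CYCLES = 0.5


@dataclass(frozen=True)
class QpcrWell:
    sample_id: str
    channel: str
    replicate: int
    cq: float | None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.channel not in (CHANNEL_TARGET, CHANNEL_REFERENCE):
            raise InputError(f"channel must be '{CHANNEL_TARGET}' or '{CHANNEL_REFERENCE}'")
        if FLAG_NO_AMPLIFICATION not in self.flags:
            if self.cq is None or not (self.cq > 0):
                raise InputError("cq must be > 0 unless the well is flagged no-amplification")

    @property
    def no_amplification(self) -> bool:
        return FLAG_NO_AMPLIFICATION in self.flags


@dataclass(frozen=True)
class ReplicateSummary:
    sample_id: str
    channel: str
    n: int
    mean_cq: float | None
    sd: float | None
    sem: float | None
    outlier_replicates: tuple[int, ...] = ()
    no_amplification: bool = False


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    delta_cq: float | None
    delta_delta_cq: float | None
    wt_fraction: float | None  # percent, clipped to [0, 100]
    wt_fraction_raw: float | None  # percent, unclipped
    sem: float | None  # percent
    flags: tuple[str, ...] = ()
    error: str | None = None


@dataclass(frozen=True)
class DilutionSeries:
    """(log10 input amount, wells) pairs for the dCq-slope compatibility check."""

    levels: tuple[tuple[float, tuple[QpcrWell, ...]], ...]

    def __post_init__(self):
        if len({lvl for lvl, _ in self.levels}) < 3:
            raise InputError("a dilution series needs >= 3 distinct input levels")


def summarize_replicates(
    wells: list[QpcrWell],
    outlier_cycles: float = DEFAULT_OUTLIER_CYCLES,
) -> ReplicateSummary:
    """Mean/SD/SEM over non-flagged replicates of one (sample, channel) group.

    With >= 3 usable replicates, a replicate further than ``outlier_cycles``
    from the group median is flagged and excluded from the mean.
    """
    if not wells:
        raise InputError("at least one replicate required")
    ids = {(w.sample_id, w.channel) for w in wells}
    if len(ids) != 1:
        raise InputError("wells from multiple (sample, channel) groups passed together")
    sample_id, channel = next(iter(ids))

    usable = [w for w in wells if not w.no_amplification]
    if not usable:
        return ReplicateSummary(sample_id, channel, 0, None, None, None, (), True)

    cqs = np.array([w.cq for w in usable], dtype=float)
    outliers: tuple[int, ...] = ()
    if len(cqs) >= 3:
        med = float(np.median(cqs))
        keep = np.abs(cqs - med) <= outlier_cycles
        if not keep.all():
            outliers = tuple(w.replicate for w, k in zip(usable, keep) if not k)
            cqs = cqs[keep]
    mean = float(np.mean(cqs))
    sd = float(np.std(cqs, ddof=1)) if len(cqs) > 1 else 0.0
    sem = sd / math.sqrt(len(cqs))
    return ReplicateSummary(sample_id, channel, len(cqs), mean, sd, sem, outliers, False)


def _group_wells(plate: list[QpcrWell]) -> dict[tuple[str, str], list[QpcrWell]]:
    groups: dict[tuple[str, str], list[QpcrWell]] = {}
    for w in plate:
        groups.setdefault((w.sample_id, w.channel), []).append(w)
    return groups


def ddcq_wt_fraction(
    plate: list[QpcrWell],
    calibrator_id: str,
    mode: str = "dropoff",
    outlier_cycles: float = DEFAULT_OUTLIER_CYCLES,
) -> list[QuantResult]:
    """Per-sample wt percentage by the ddCq method, referenced to ``calibrator_id``.

    Samples missing a channel yield a per-sample error record; a sample whose
    target channel never amplified is reported as 0% wt with a
    ``below_detection`` flag.  Results above 100% are clipped with the raw
    value retained.
    """
    if mode not in ("dropoff", "trans_multiplex"):
        raise InputError("mode must be 'dropoff' or 'trans_multiplex'")
    groups = _group_wells(plate)
    samples = sorted({sid for sid, _ in groups})
    if (calibrator_id, CHANNEL_TARGET) not in groups or (calibrator_id, CHANNEL_REFERENCE) not in groups:
        raise InputError(f"calibrator {calibrator_id!r} must have both channels on the plate")

    cal_t = summarize_replicates(groups[(calibrator_id, CHANNEL_TARGET)], outlier_cycles)
    cal_r = summarize_replicates(groups[(calibrator_id, CHANNEL_REFERENCE)], outlier_cycles)
    if cal_t.no_amplification or cal_r.no_amplification:
        raise InputError("calibrator sample failed to amplify")
    cal_dcq = cal_t.mean_cq - cal_r.mean_cq
    cal_var = cal_t.sem ** 2 + cal_r.sem ** 2

    results: list[QuantResult] = []
    for sid in samples:
        tgt_wells = groups.get((sid, CHANNEL_TARGET))
        ref_wells = groups.get((sid, CHANNEL_REFERENCE))
        if tgt_wells is None or ref_wells is None:
            missing = CHANNEL_TARGET if tgt_wells is None else CHANNEL_REFERENCE
            results.append(QuantResult(sid, None, None, None, None, None,
                                       error=f"missing channel: {missing}"))
            continue
        t = summarize_replicates(tgt_wells, outlier_cycles)
        r = summarize_replicates(ref_wells, outlier_cycles)
        if r.no_amplification:
            results.append(QuantResult(sid, None, None, None, None, None,
                                       error="reference channel did not amplify"))
            continue
        if t.no_amplification:
            results.append(QuantResult(sid, None, None, 0.0, 0.0, 0.0,
                                       flags=("below_detection",)))
            continue
        if sid == calibrator_id:
            # 100% by construction
            sem = 100.0 * math.log(2) * math.sqrt(cal_var)
            results.append(QuantResult(sid, cal_dcq, 0.0, 100.0, 100.0, sem))
            continue
        dcq = t.mean_cq - r.mean_cq
        ddcq = dcq - cal_dcq
        raw = 100.0 * 2.0 ** (-ddcq)
        sd_ddcq = math.sqrt(t.sem ** 2 + r.sem ** 2 + cal_var)
        sem = raw * math.log(2) * sd_ddcq
        flags = ("clipped",) if raw > 100.0 else ()
        results.append(QuantResult(sid, dcq, ddcq, min(raw, 100.0), raw, sem, flags=flags))
    return results


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    passed: bool
    threshold: float
    n_levels: int


def calibration_slope(series: DilutionSeries, threshold: float = 0.1) -> CalibrationResult:
    """OLS fit of dCq against log10 input; pass iff |slope| <= threshold.

    A flat dCq across input levels means both channels amplify with matching
    efficiency, the precondition of the ddCq method.
    """
    xs, ys = [], []
    for log_amount, wells in series.levels:
        t = summarize_replicates([w for w in wells if w.channel == CHANNEL_TARGET])
        r = summarize_replicates([w for w in wells if w.channel == CHANNEL_REFERENCE])
        if t.no_amplification or r.no_amplification:
            raise InputError(f"level {log_amount}: a channel failed to amplify")
        xs.append(log_amount)
        ys.append(t.mean_cq - r.mean_cq)
    slope, intercept = np.polyfit(np.asarray(xs, float), np.asarray(ys, float), 1)
    return CalibrationResult(float(slope), float(intercept), bool(abs(slope) <= threshold),
                             threshold, len(xs))
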