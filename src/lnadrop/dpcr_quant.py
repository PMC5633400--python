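"""Digital PCR partition classification and Poisson occupancy estimation.

Each chip partition is scored positive/negative on the reference and target
channels.  Template loading follows Poisson occupancy, so the mean copies per
partition on a channel is lambda = -ln(1 - positive fraction).  Because both
probe sites sit on one short amplicon, their occupancies are perfectly linked
and the unedited fraction is a ratio of lambdas:

    wt% = 100 * lambda_target / lambda_reference

Confidence intervals: Wilson intervals on single-channel positive proportions
(well-behaved near 0 and 1) transformed through -ln(1-p); for the wt-fraction
ratio, first-order (delta-method) propagation of the joint multinomial
covariance of the two positive proportions — the two channels share partitions
and are strongly positively correlated, which a naive independent-channel
propagation would ignore, overstating the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, NoTemplateError, SaturatedChipError, ThresholdError


@dataclass(frozen=True)
class PartitionCounts:
    double_pos: int
    ref_only: int
    target_only: int
    double_neg: int

    @property
    def n_total(self) -> int:
        return self.double_pos + self.ref_only + self.target_only + self.double_neg

    @property
    def ref_positive(self) -> int:
        return self.double_pos + self.ref_only

    @property
    def target_positive(self) -> int:
        return self.double_pos + self.target_only


@dataclass(frozen=True)
class DpcrChip:
    """Per-partition two-channel data: boolean calls and/or raw fluorescence."""

    calls: np.ndarray | None = None       # shape (n, 2) bool: [:,0]=reference, [:,1]=target
    fluorescence: np.ndarray | None = None  # shape (n, 2) float, same column order
    quality: float = 1.0                  # fraction of readable partitions

    def __post_init__(self):
        if self.calls is None and self.fluorescence is None:
            raise InputError("chip needs boolean calls or raw fluorescence")
        for arr in (self.calls, self.fluorescence):
            if arr is not None and (arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1):
                raise InputError("partition arrays must have shape (n >= 1, 2)")

    @property
    def n_total(self) -> int:
        arr = self.calls if self.calls is not None else self.fluorescence
        return arr.shape[0]


@dataclass(frozen=True)
class LambdaEstimate:
    lam: float
    ci95: tuple[float, float]
    positives: int
    total: int


@dataclass(frozen=True)
class DpcrEstimate:
    lambda_reference: float
    lambda_target: float
    wt_fraction: float          # percent, clipped to [0, 100]
    wt_fraction_raw: float      # percent, unclipped
    ci95: tuple[float, float]   # percent
    counts: PartitionCounts
    flags: tuple[str, ...] = ()


def _valley_threshold(values: np.ndarray, bins: int = 64) -> float:
    """Threshold at the histogram valley between the two largest modes."""
    hist, edges = np.histogram(values, bins=bins)
    # light smoothing keeps shot noise from splitting modes
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    peaks = [
        i for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    # collapse plateau peaks and keep the two tallest
    peaks = sorted(peaks, key=lambda i: -smooth[i])
    distinct = []
    for p in peaks:
        if all(abs(p - q) > 3 for q in distinct):
            distinct.append(p)
        if len(distinct) == 2:
            break
    if len(distinct) < 2:
        raise ThresholdError("channel histogram is unimodal; set thresholds manually")
    lo, hi = sorted(distinct)
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    # a genuine two-mode split has a deep valley; shot-noise wiggles on one
    # mode do not
    if smooth[valley] > 0.3 * min(smooth[lo], smooth[hi]):
        raise ThresholdError("channel histogram is unimodal; set thresholds manually")
    return float((edges[valley] + edges[valley + 1]) / 2.0)


def classify_partitions(
    chip: DpcrChip,
    thresholds: tuple[float, float] | None = None,
) -> PartitionCounts:
    """Assign each partition to one of four classes by two-channel positivity.

    ``thresholds`` is (reference, target) on raw fluorescence; if omitted and
    the chip carries fluorescence, each channel is thresholded automatically at
    the valley between the two modes of its histogram.  Target-only partitions
    are biologically anomalous and surface through ``PartitionCounts``.
    """
    if chip.calls is not None and thresholds is None and chip.fluorescence is None:
        calls = chip.calls.astype(bool)
    else:
        if chip.fluorescence is None:
            raise InputError("thresholds given but chip has no raw fluorescence")
        if chip.n_total < 100:
            raise InputError("need >= 100 readable partitions to classify")
        fl = chip.fluorescence
        if thresholds is None:
            thresholds = (_valley_threshold(fl[:, 0]), _valley_threshold(fl[:, 1]))
        calls = fl > np.asarray(thresholds)[None, :]
    ref_pos = calls[:, 0]
    tgt_pos = calls[:, 1]
    return PartitionCounts(
        double_pos=int(np.sum(ref_pos & tgt_pos)),
        ref_only=int(np.sum(ref_pos & ~tgt_pos)),
        target_only=int(np.sum(~ref_pos & tgt_pos)),
        double_neg=int(np.sum(~ref_pos & ~tgt_pos)),
    )


def poisson_lambda(positives: int, total: int, alpha: float = 0.05) -> LambdaEstimate:
    """Mean copies/partition with a Wilson-interval-backed 95% CI.

    lambda = -ln(1 - positives/total); the binomial CI on the positive
    proportion is pushed through the same transform.
    """
    if not 0 <= positives <= total or total < 1:
        raise InputError("need 0 <= positives <= total, total >= 1")
    if positives == total:
        raise SaturatedChipError(
            "every partition is positive; lambda is unbounded (dilute and rerun)"
        )
    p = positives / total
    lam = -math.log1p(-p)
    lo, hi = proportion_confint(positives, total, alpha=alpha, method="wilson")
    hi = min(float(hi), 1.0 - 1e-12)
    lo = max(float(lo), 0.0)
    return LambdaEstimate(lam, (-math.log1p(-lo), -math.log1p(-hi)), positives, total)


def wt_fraction_dpcr(counts: PartitionCounts) -> DpcrEstimate:
    """Unedited fraction as 100 * lambda_target / lambda_reference with 95% CI.

    Target-positive = double_pos + target_only (target-only partitions are
    counted but flagged); reference-positive = double_pos + ref_only.
    """
    n = counts.n_total
    if n < 1:
        raise InputError("empty chip")
    if counts.ref_positive == 0:
        raise NoTemplateError("no reference-positive partitions: no template loaded")
    if counts.ref_positive == n:
        raise SaturatedChipError("reference channel saturated; lambda unbounded")

    p_r = counts.ref_positive / n
    p_t = counts.target_positive / n
    lam_r = -math.log1p(-p_r)
    lam_t = -math.log1p(-p_t)
    raw = 100.0 * lam_t / lam_r

    # delta-method variance with the multinomial covariance of (p_t, p_r)
    p_both = counts.double_pos / n
    var_pt = p_t * (1 - p_t) / n
    var_pr = p_r * (1 - p_r) / n
    cov_ptr = (p_both - p_t * p_r) / n
    # d lambda / d p = 1 / (1 - p)
    var_lt = var_pt / (1 - p_t) ** 2
    var_lr = var_pr / (1 - p_r) ** 2
    cov_l = cov_ptr / ((1 - p_t) * (1 - p_r))
    if lam_t > 0:
        rel_var = var_lt / lam_t ** 2 + var_lr / lam_r ** 2 - 2 * cov_l / (lam_t * lam_r)
        sd = raw * math.sqrt(max(rel_var, 0.0))
    else:
        sd = 100.0 * math.sqrt(var_lt) / lam_r
    ci = (max(raw - 1.96 * sd, 0.0), raw + 1.96 * sd)

    flags = []
    if counts.target_only > 0:
        flags.append("target_only_partitions")
    if lam_t > lam_r:
        flags.append("lambda_target_exceeds_reference")
    return DpcrEstimate(
        lambda_reference=lam_r,
        lambda_target=lam_t,
        wt_fraction=float(np.clip(raw, 0.0, 100.0)),
        wt_fraction_raw=raw,
        ci95=ci,
        counts=counts,
        flags=tuple(flags),
    )
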