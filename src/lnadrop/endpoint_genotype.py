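"""Genotype calls from competitive allele-specific probe endpoint fluorescence.

Two differentially-labeled LNA probes (wild-type vs mutant allele) compete for
the same site; after amplification the terminal fluorescence of each channel is
read and samples are placed in the two-channel allele-discrimination plane.
Calls are control-anchored: channels are normalized against NTC-subtracted
control maxima, control centroids are computed in (signal angle, amplitude)
space, and unknowns take the nearest centroid's genotype.  Samples with real
signal that sit far from every control cluster are flagged as founder-mosaic
candidates (mosaic founders carry allele mixtures at non-Mendelian ratios and
fall off the WT/HET/HOMO clusters); samples at NTC level are indeterminate.
Normalization makes calls invariant to common-mode gain changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

ROLES = ("unknown", "control_WT", "control_HET", "control_HOMO", "NTC")
GENOTYPES = ("WT", "HET", "HOMO")


@dataclass(frozen=True)
class EndpointSample:
    sample_id: str
    fluor_wt: float
    fluor_mut: float
    role: str = "unknown"

    def __post_init__(self):
        if self.fluor_wt < 0 or self.fluor_mut < 0:
            raise InputError("fluorescence must be >= 0")
        if self.role not in ROLES:
            raise InputError(f"role must be one of {ROLES}")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str  # WT | HET | HOMO | indeterminate | founder_mosaic_candidate
    distance: float | None = None          # to the nearest control centroid
    nearest_control: str | None = None
    amplitude: float | None = None
    angle_deg: float | None = None


@dataclass(frozen=True)
class GenotypeConfig:
    mosaic_distance_sd: float = 3.0   # centroid-distance cutoff, in within-control SDs
    min_control_sd: float = 0.04      # floor when controls have single members
    noise_margin: float = 3.0         # amplitude must exceed this many NTC SDs
    min_ntc_sd_rel: float = 0.01      # NTC-noise floor, relative to control maxima


def _polar(wt: float, mut: float) -> tuple[float, float]:
    return math.atan2(mut, wt), math.hypot(wt, mut)


def call_genotypes(
    samples: list[EndpointSample],
    config: GenotypeConfig | None = None,
) -> list[GenotypeCall]:
    """Nearest-control-centroid genotype calls in the discrimination plane.

    Requires at least one control of each of WT/HET/HOMO.  NTC samples never
    receive a genotype (they are reported indeterminate).
    """
    config = config or GenotypeConfig()
    by_role: dict[str, list[EndpointSample]] = {r: [] for r in ROLES}
    for s in samples:
        by_role[s.role].append(s)
    for ctl in ("control_WT", "control_HET", "control_HOMO"):
        if not by_role[ctl]:
            raise ConfigurationError(f"missing required control class: {ctl}")

    ntc = by_role["NTC"]
    if ntc:
        ntc_wt = float(np.mean([s.fluor_wt for s in ntc]))
        ntc_mut = float(np.mean([s.fluor_mut for s in ntc]))
        ntc_sd_obs = float(np.std(
            [_polar(s.fluor_wt - ntc_wt, s.fluor_mut - ntc_mut)[1] for s in ntc]
        ))
    else:
        ntc_wt = ntc_mut = 0.0
        ntc_sd_obs = 0.0

    # per-channel normalization by NTC-subtracted control maxima
    ctl_samples = by_role["control_WT"] + by_role["control_HET"] + by_role["control_HOMO"]
    max_wt = max(s.fluor_wt - ntc_wt for s in ctl_samples)
    max_mut = max(s.fluor_mut - ntc_mut for s in ctl_samples)
    if max_wt <= 0 or max_mut <= 0:
        raise ConfigurationError("controls do not rise above NTC level on both channels")
    # the floor is relative to signal scale so calls survive gain changes
    ntc_sd = max(ntc_sd_obs, config.min_ntc_sd_rel * max(max_wt, max_mut))

    def norm(s: EndpointSample) -> tuple[float, float]:
        return (
            max((s.fluor_wt - ntc_wt) / max_wt, 0.0),
            max((s.fluor_mut - ntc_mut) / max_mut, 0.0),
        )

    # chord distance in the (angle, amplitude) plane (law of cosines): the
    # exact discrimination-plane separation, expressed in polar coordinates
    def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
        d2 = a[1] ** 2 + b[1] ** 2 - 2 * a[1] * b[1] * math.cos(a[0] - b[0])
        return math.sqrt(max(d2, 0.0))

    centroids: dict[str, tuple[float, float]] = {}
    class_spreads: list[float] = []
    for geno, ctl in zip(GENOTYPES, ("control_WT", "control_HET", "control_HOMO")):
        pts = [_polar(*norm(s)) for s in by_role[ctl]]
        ang = float(np.mean([p[0] for p in pts]))
        amp = float(np.mean([p[1] for p in pts]))
        centroids[geno] = (ang, amp)
        if len(pts) > 1:
            class_spreads.append(math.sqrt(float(np.mean(
                [_dist(p, (ang, amp)) ** 2 for p in pts]
            ))))
    # widest per-class RMS radial spread: the mosaic cutoff must cover the
    # loosest control cluster
    control_sd = max(
        max(class_spreads) if class_spreads else 0.0, config.min_control_sd
    )

    noise_floor = config.noise_margin * ntc_sd / max(max_wt, max_mut)

    calls: list[GenotypeCall] = []
    for s in samples:
        if s.role == "NTC":
            calls.append(GenotypeCall(s.sample_id, "indeterminate"))
            continue
        ang, amp = _polar(*norm(s))
        dists = {g: _dist((ang, amp), c) for g, c in centroids.items()}
        nearest = min(dists, key=dists.get)
        d = dists[nearest]
        if amp < noise_floor:
            call = "indeterminate"
        elif d > config.mosaic_distance_sd * control_sd:
            call = "founder_mosaic_candidate"
        else:
            call = nearest
        calls.append(GenotypeCall(s.sample_id, call, d, nearest, amp, math.degrees(ang)))
    return calls


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    passed: bool


def linearity_check(
    dose_series: list[tuple[float, EndpointSample]],
    r2_threshold: float = 0.98,
) -> LinearityResult:
    """Dose-response linearity of the mutant channel against known mutant fraction.

    Least-squares fit of the mutant-channel signal (normalized to its maximum)
    against the known fraction; passes iff r^2 >= threshold.
    """
    if len(dose_series) < 3:
        raise InputError("linearity check needs >= 3 known fractions")
    x = np.array([f for f, _ in dose_series], dtype=float)
    y = np.array([s.fluor_mut for _, s in dose_series], dtype=float)
    ymax = y.max()
    if ymax > 0:
        y = y / ymax
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearityResult(float(slope), float(intercept), r2, bool(r2 >= r2_threshold))
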