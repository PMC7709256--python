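"""Ks distributions, WGD peak detection, clock calibration, and event dating.

Peaks are located with a Gaussian mixture on log-Ks (component count chosen
by minimum BIC), reported back on the Ks scale.  The synonymous clock follows
r = Ks / (2 T): a median ortholog Ks between two genomes of known divergence
time calibrates r, and a WGD peak Ks is then dated as T = Ks / (2 r).  Ages
are displayed rounded to the nearest million years, half up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "KsDistribution",
    "KsPeak",
    "RateCalibration",
    "WgdEvent",
    "fit_peaks",
    "calibrate_rate",
    "date_event",
    "round_my",
    "compare_distributions",
    "orthologous_ks_window",
]

DEFAULT_KS_MAX = 3.0  # JC correction diverges toward saturation; larger Ks excluded
DEFAULT_MAX_COMPONENTS = 4
MIN_FIT_VALUES = 20


@dataclass
class KsDistribution:
    """A filtered set of Ks values (block medians or pairwise estimates)."""

    label: str
    values: list[float]
    kind: str = "paralog"  # 'paralog' (within-genome) | 'ortholog' (between)
    ks_max: float = DEFAULT_KS_MAX
    peaks: list["KsPeak"] | None = None

    def __post_init__(self) -> None:
        self.values = [v for v in self.values if v is not None and 0.0 < v <= self.ks_max]
        if not self.values:
            raise ValueError(f"distribution {self.label!r}: no usable Ks values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class KsPeak:
    """One mixture component on the Ks scale."""

    location: float  # exp(mean of the log-Ks component)
    width: float  # component sd mapped to the Ks scale (delta method)
    weight: float
    members: list[int] = field(default_factory=list)  # indices of assigned values


@dataclass(frozen=True)
class RateCalibration:
    """r = median_ks / (2 * divergence_time) in substitutions/site/year."""

    median_ks: float
    divergence_time_my: float
    r: float


@dataclass
class WgdEvent:
    """A dated WGD: a Ks peak converted to an age through the clock."""

    name: str
    peak_ks: float
    age_my: float

    @property
    def display_age(self) -> int:
        return round_my(self.age_my)


def fit_peaks(
    distribution: KsDistribution,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    seed: int = 0,
) -> list[KsPeak]:
    """Fit a BIC-selected Gaussian mixture on log-Ks; peaks sorted ascending."""
    values = np.asarray(distribution.values, dtype=float)
    if len(values) < MIN_FIT_VALUES:
        raise ValueError(
            f"distribution {distribution.label!r}: need >= {MIN_FIT_VALUES} values, "
            f"got {len(values)}"
        )
    logv = np.log(values).reshape(-1, 1)
    if np.ptp(logv) == 0.0:  # zero-variance limit: one degenerate component
        peaks = [KsPeak(float(values[0]), 0.0, 1.0, list(range(len(values))))]
        distribution.peaks = peaks
        return peaks
    best = None
    best_bic = math.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=3, random_state=seed)
        gm.fit(logv)
        bic = gm.bic(logv)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    assert best is not None
    means = best.means_.ravel()
    sigmas = np.sqrt(best.covariances_.reshape(-1))
    weights = best.weights_.ravel()
    resp = best.predict(logv)
    order = np.argsort(means)
    peaks = []
    for rank, ci in enumerate(order):
        loc = float(np.exp(means[ci]))
        peaks.append(
            KsPeak(
                location=loc,
                width=float(loc * sigmas[ci]),
                weight=float(weights[ci]),
                members=[i for i in range(len(values)) if resp[i] == ci],
            )
        )
    distribution.peaks = peaks
    return peaks


def calibrate_rate(median_ks: float, divergence_time_my: float) -> RateCalibration:
    """Synonymous substitutions per site per year from an ortholog median Ks
    and a known divergence time (r = Ks / 2T)."""
    if median_ks <= 0 or divergence_time_my <= 0:
        raise ValueError("median_ks and divergence_time_my must be positive")
    r = median_ks / (2.0 * divergence_time_my * 1e6)
    return RateCalibration(median_ks, divergence_time_my, r)


def date_event(peak_ks: float, calibration: RateCalibration | float) -> float:
    """Age of a WGD peak in million years (T = Ks / 2r).

    ``calibration`` is a :class:`RateCalibration` or a bare rate r in
    substitutions/site/year (e.g. a published rounded value)."""
    if peak_ks <= 0:
        raise ValueError("peak_ks must be positive")
    r = calibration.r if isinstance(calibration, RateCalibration) else float(calibration)
    if r <= 0:
        raise ValueError("calibration rate must be positive")
    return peak_ks / (2.0 * r) / 1e6


def round_my(age_my: float) -> int:
    """Nearest-MY display rounding, half up (53.5 -> 54)."""
    return int(math.floor(age_my + 0.5))


def compare_distributions(
    dists: Sequence[KsDistribution],
    ortholog_label: str | None = None,
) -> pd.DataFrame:
    """Ordered table of fitted peak locations across distributions.

    Paralog (WGD) peaks smaller than the reference ortholog-divergence peak
    are flagged post-divergence — under the clock assumption the duplication
    happened after the speciation, i.e. it is lineage-specific."""
    rows = []
    ref_peak = None
    if ortholog_label is None:
        ortho = [d for d in dists if d.kind == "ortholog"]
        if ortho:
            ortholog_label = ortho[0].label
    for d in dists:
        if d.peaks is None:
            raise ValueError(f"distribution {d.label!r} has no fitted peaks")
        if d.label == ortholog_label:
            ref_peak = min(p.location for p in d.peaks)
    for d in dists:
        for p in d.peaks:
            if d.label == ortholog_label:
                flag = "ortholog_reference"
            elif ref_peak is None:
                flag = ""
            else:
                flag = "post-divergence" if p.location < ref_peak else "pre-divergence"
            rows.append(
                {"label": d.label, "kind": d.kind, "peak_ks": p.location,
                 "width": p.width, "weight": p.weight, "n": d.n, "flag": flag}
            )
    return pd.DataFrame(rows).sort_values(["label", "peak_ks"]).reset_index(drop=True)


def orthologous_ks_window(
    medians: Sequence[float],
    seed: int = 0,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> tuple[float, float]:
    """[0, m + 2w] where m, w are the location and width of the lowest-Ks
    mixture component of cross-genome block median Ks — the window that keeps
    speciation-age (orthologous) blocks and drops older duplication-age ones."""
    dist = KsDistribution("ortholog-medians", list(medians), kind="ortholog")
    peaks = fit_peaks(dist, max_components=max_components, seed=seed)
    lowest = peaks[0]
    return 0.0, lowest.location + 2.0 * lowest.width
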