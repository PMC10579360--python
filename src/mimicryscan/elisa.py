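"""ELISA cross-reactivity analysis against a background-derived cutoff.

The assay applies an antibody raised against the microbial target protein
to a panel of human tissue antigens and reads optical densities (OD,
405 nm). Most antigens cluster near the plate background; the reactivity
cutoff is defined as that background cluster's mean plus ``cutoff_k``
standard deviations (the published analysis uses one SD: 0.16 + 0.12 =
0.28 for the polyclonal antibody, 0.15 + 0.09 = 0.24 for the monoclonal).
An antigen is called reactive when its mean OD exceeds the cutoff.

Background membership is circular as stated (the cutoff defines the
background that defines the cutoff). It is resolved here by iterative
outlier trimming: starting from all antigens, any antigen whose mean OD
exceeds ``mean + trim_k * SD`` of the current set is dropped, and the
statistics are recomputed until membership stabilizes. The trimming
multiplier ``trim_k`` (default 2) is deliberately larger than ``cutoff_k``:
trimming at one SD has no stable fixed point on a roughly normal cluster
(each round removes the top ~16% until almost nothing is left), whereas
two-SD trimming removes only clear off-cluster antigens. An explicit
background list bypasses the iteration entirely.

The per-antigen p-value is the upper tail of a normal distribution fitted
to the background cluster (one-sided z). It is a stand-in for whatever
unnamed test produced the published per-antigen p-values, and preserves the
published monotonicity: the higher the OD above the cutoff, the smaller
the p-value. Reproducing the published p-values is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .types import ELISAMeasurement

__all__ = [
    "ReactivityResult",
    "determine_background",
    "determine_cutoff",
    "classify_antigens",
    "duplicate_cv_check",
    "analyze_panel",
]


@dataclass(frozen=True)
class ReactivityResult:
    """Per-antigen classification against the background-derived cutoff."""

    antigen: str
    antibody: str
    mean_od: float
    cv_percent: float | None
    cutoff: float
    reactive: bool
    p_value: float
    background_member: bool


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def determine_background(
    measurements: Sequence[ELISAMeasurement],
    trim_k: float = 2.0,
    background_antigens: Iterable[str] | None = None,
) -> tuple[set[str], float, float]:
    """Identify the near-background antigen cluster and its mean/SD.

    Iteratively trims antigens whose mean OD exceeds ``mean + trim_k * SD``
    of the current set until membership stabilizes (membership only
    shrinks, so convergence is guaranteed). Passing ``background_antigens``
    bypasses the iteration and computes the statistics on the given set.

    Returns ``(background antigen names, mean OD, SD)``. SD is the sample
    standard deviation, at full precision (rounding is a display concern).
    Requires at least 3 antigens. Note the limitation: when reactive ODs
    overlap the background cluster, trimming keeps borderline antigens in
    the background and the estimates are biased accordingly.
    """
    if len(measurements) < 3:
        raise ValueError("background determination requires >= 3 antigens")
    by_name = {m.antigen: m.mean_od for m in measurements}
    if background_antigens is not None:
        names = set(background_antigens)
        missing = names - by_name.keys()
        if missing:
            raise ValueError(f"unknown background antigens: {sorted(missing)}")
        mean, sd = _mean_sd([by_name[n] for n in names])
        return names, mean, sd
    current = list(by_name)
    for _ in range(100):
        mean, sd = _mean_sd([by_name[n] for n in current])
        ceiling = mean + trim_k * sd
        kept = [n for n in current if by_name[n] <= ceiling]
        if len(kept) == len(current):
            return set(current), mean, sd
        current = kept
    raise AssertionError("background trimming failed to converge")  # pragma: no cover


def determine_cutoff(mean: float, sd: float, k: float = 1.0) -> float:
    """Reactivity cutoff: background mean plus ``k`` standard deviations."""
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    if k <= 0:
        raise ValueError("k must be positive")
    return mean + k * sd


def classify_antigens(
    measurements: Sequence[ELISAMeasurement],
    cutoff: float,
    background_mean: float,
    background_sd: float,
    background_members: Iterable[str] = (),
) -> list[ReactivityResult]:
    """Classify every antigen against the cutoff, sorted by descending OD.

    ``reactive`` iff mean OD > cutoff. The p-value is the one-sided upper
    tail of Normal(background mean, background SD^2) at the antigen's mean
    OD (see module docstring); it decreases strictly as OD increases.
    """
    bg = set(background_members)
    results = []
    for m in measurements:
        od = m.mean_od
        if background_sd > 0:
            p = float(sps.norm.sf(od, loc=background_mean, scale=background_sd))
            p = max(p, np.finfo(float).tiny)
        else:
            p = 1.0 if od <= background_mean else float(np.finfo(float).tiny)
        results.append(
            ReactivityResult(
                antigen=m.antigen,
                antibody=m.antibody,
                mean_od=od,
                cv_percent=m.cv_percent,
                cutoff=cutoff,
                reactive=od > cutoff,
                p_value=p,
                background_member=m.antigen in bg,
            )
        )
    results.sort(key=lambda r: (-r.mean_od, r.antigen))
    return results


def duplicate_cv_check(
    measurements: Sequence[ELISAMeasurement],
    max_cv_percent: float = 7.0,
) -> list[tuple[str, float | None, bool | None]]:
    """Duplicate-well quality control.

    Returns ``(antigen, cv_percent, passed)`` per antigen, where the CV of
    duplicates is 100*|od1-od2|/mean and ``passed`` is ``cv <
    max_cv_percent``. Single-replicate antigens are flagged not-assessable
    (``None``), not failed.
    """
    out = []
    for m in measurements:
        cv = m.cv_percent
        out.append((m.antigen, cv, None if cv is None else cv < max_cv_percent))
    return out


def analyze_panel(
    measurements: Sequence[ELISAMeasurement],
    cutoff_k: float = 1.0,
    trim_k: float = 2.0,
    background_antigens: Iterable[str] | None = None,
) -> tuple[list[ReactivityResult], float, float, float]:
    """Full panel analysis: background, cutoff, classification.

    Returns ``(results, background mean, background SD, cutoff)``.
    """
    bg, mean, sd = determine_background(
        measurements, trim_k=trim_k, background_antigens=background_antigens
    )
    cutoff = determine_cutoff(mean, sd, cutoff_k)
    results = classify_antigens(measurements, cutoff, mean, sd, bg)
    return results, mean, sd, cutoff
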