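"""Quantifying localized dilations from skeleton radius profiles.

A skeletonized capillary branch yields a profile of lumen radius r(s)
versus centreline arclength s.  A localized dilation (sinusoid) shows up
as a dominant interior maximum.  Two endpoint conventions are supported:

* ``local_minima`` — the dilation spans the two local minima flanking the
  global maximum, and the undilated radius R0 is the branch minimum;
* ``average_crossing`` — R0 is the arclength-weighted branch mean radius,
  and the dilation spans the two crossings of r(s) through R0 nearest the
  global maximum.

Raw skeleton radii are noisy (voxel quantization), so endpoint detection
runs on a moving-average smoothed profile; R0 and R_max are always taken
from the unsmoothed data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .shape import DilationShape, bump_shape

__all__ = [
    "DilationMeasurement",
    "RadiusProfile",
    "measure_dilation",
    "profile_to_shape",
    "read_profile",
    "write_profile",
]

Definition = Literal["local_minima", "average_crossing"]


@dataclass
class RadiusProfile:
    """Radius-vs-arclength samples of one capillary branch (um)."""

    s: np.ndarray
    r: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.s.shape != self.r.shape or self.s.ndim != 1 or len(self.s) < 3:
            raise ValueError("s and r must be equal-length 1-D arrays with >= 3 samples")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arclength samples must be strictly increasing")
        if np.any(self.r <= 0):
            raise ValueError("radii must be positive")

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])


@dataclass
class DilationMeasurement:
    """Measured dilation geometry under one endpoint definition."""

    definition: Definition
    detected: bool
    lam: float | None = None
    R0: float | None = None
    R_max: float | None = None
    s_start: float | None = None
    s_end: float | None = None
    smoothing_window: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _moving_average(r: np.ndarray, s: np.ndarray, window: float) -> np.ndarray:
    """Arclength-window moving average (window in um; 0 = no smoothing)."""
    if window <= 0:
        return r.copy()
    out = np.empty_like(r)
    half = window / 2.0
    for i, si in enumerate(s):
        mask = (s >= si - half) & (s <= si + half)
        out[i] = r[mask].mean()
    return out


def measure_dilation(
    profile: RadiusProfile,
    definition: Definition = "average_crossing",
    smoothing_window: float = 3.0,
) -> DilationMeasurement:
    """Measure the dominant dilation of a branch under one definition.

    Returns a measurement with ``detected=False`` (not an exception) when
    the profile has no interior maximum or no flanking minima/crossings.
    """
    if definition not in ("local_minima", "average_crossing"):
        raise ValueError(f"unknown definition {definition!r}")
    if smoothing_window < 0:
        raise ValueError("smoothing_window must be >= 0")
    s, r = profile.s, profile.r
    rs = _moving_average(r, s, smoothing_window)

    i_max = int(np.argmax(rs))
    no_dilation = DilationMeasurement(
        definition=definition, detected=False, smoothing_window=smoothing_window
    )
    if i_max == 0 or i_max == len(s) - 1:
        return no_dilation
    if np.ptp(rs) < 1e-12 * max(1.0, float(np.max(rs))):
        return no_dilation  # constant profile

    if definition == "local_minima":
        r0 = float(np.min(r))
        # local minima of the smoothed profile on each side of the maximum
        interior = np.nonzero((rs[1:-1] <= rs[:-2]) & (rs[1:-1] <= rs[2:]))[0] + 1
        left = interior[interior < i_max]
        right = interior[interior > i_max]
        if len(left) == 0 or len(right) == 0:
            return no_dilation
        i_lo, i_hi = int(left[-1]), int(right[0])
        s_lo, s_hi = float(s[i_lo]), float(s[i_hi])
        in_window = slice(i_lo, i_hi + 1)
    else:
        r0 = float(np.trapezoid(r, s) / (s[-1] - s[0]))
        dev = rs - r0
        if dev[i_max] <= 0:
            return no_dilation
        sign_change = np.nonzero(dev[:-1] * dev[1:] <= 0)[0]
        left = sign_change[sign_change < i_max]
        right = sign_change[sign_change >= i_max]
        if len(left) == 0 or len(right) == 0:
            return no_dilation

        def interp_cross(i: int) -> float:
            d0, d1 = dev[i], dev[i + 1]
            if d1 == d0:
                return float(s[i])
            t = -d0 / (d1 - d0)
            return float(s[i] + t * (s[i + 1] - s[i]))

        s_lo = interp_cross(int(left[-1]))
        s_hi = interp_cross(int(right[0]))
        in_window = (s >= s_lo) & (s <= s_hi)

    window_vals = np.atleast_1d(r[in_window])
    r_max = float(np.max(window_vals)) if window_vals.size else float(r[i_max])
    r_max = max(r_max, r0)
    return DilationMeasurement(
        definition=definition,
        detected=True,
        lam=s_hi - s_lo,
        R0=r0,
        R_max=r_max,
        s_start=s_lo,
        s_end=s_hi,
        smoothing_window=smoothing_window,
    )


def profile_to_shape(measurement: DilationMeasurement, L: float) -> DilationShape:
    """One-DOF cosine-bump shape with the measured (R0, R_max, lam), centred in L."""
    if not measurement.detected:
        raise ValueError("cannot build a shape from a 'no dilation detected' measurement")
    return bump_shape(measurement.R0, measurement.R_max, measurement.lam, L)


def read_profile(path: str | Path, provenance: str = "") -> RadiusProfile:
    """Read a two-column delimited profile with header ``s_um,r_um``."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    return RadiusProfile(
        s=np.asarray(data["s_um"], dtype=float),
        r=np.asarray(data["r_um"], dtype=float),
        provenance=provenance or str(path),
    )


def write_profile(profile: RadiusProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("s_um,r_um\n")
        for si, ri in zip(profile.s, profile.r):
            fh.write(f"{si:.10g},{ri:.10g}\n")
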