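"""Deterministic generators for test inputs and the packaged reference data.

Everything here is a pure function of its arguments (plus an explicit
seed where noise is involved), so regenerating any fixture is
bit-reproducible.  The packaged morphometry table ships the measured
geometric and computed flow properties of three confocal 3D images of
terminal-villus capillaries; the synthetic generators emulate the
associated skeleton radius profiles and idealized annulus geometries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import TransportParameters
from .profiles import RadiusProfile
from .reduced import CapillarySummary, annular_diffusion_bound
from .shape import bump_shape

__all__ = [
    "AnnulusCase",
    "make_annulus_case",
    "make_bump_profile",
    "morphometry_table",
    "reference_capillaries",
    "write_fixture_files",
]

_DATA_FILE = "capillary_morphometry.csv"


def morphometry_table() -> pd.DataFrame:
    """The packaged per-image morphometry table as a DataFrame."""
    with resources.files("fetocap.data").joinpath(_DATA_FILE).open("r") as fh:
        return pd.read_csv(fh)


def reference_capillaries() -> list[CapillarySummary]:
    """The three reference capillaries as :class:`CapillarySummary` rows.

    Capillary volume and surface area are derived from the villous totals
    and the tabulated fractions; the numerically computed diffusion bound
    (from the full 3D solution) is attached as ``N_max_numeric``.
    """
    df = morphometry_table()
    out = []
    for _, row in df.iterrows():
        out.append(
            CapillarySummary(
                label=row["label"],
                L=float(row["L_um"]),
                L_path=float(row["L_path_um"]),
                V_cap=float(row["villous_volume_um3"]) * float(row["cap_volume_fraction"]),
                A=float(row["villous_area_um2"]) * float(row["cap_area_fraction"]),
                d=float(row["d_um"]),
                R_resistance=float(row["R_resistance_Pa_s_per_um3"]),
                N_max_numeric=float(row["N_max_numeric_ug_per_s"]),
            )
        )
    return out


def make_bump_profile(
    R0: float,
    R_max: float,
    lam: float,
    L: float,
    ds: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> RadiusProfile:
    """Sample the 1-DOF cosine bump as a skeleton-style radius profile.

    Adds seeded additive Gaussian radius noise (emulating voxel
    quantization scatter) and floors radii at 0.1 um.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sigma > 0")
    shape = bump_shape(R0, R_max, lam, L)
    s = np.arange(0.0, L + ds / 2.0, ds)
    r = np.asarray(shape.radius(s), dtype=float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sigma, size=r.shape)
    r = np.maximum(r, 0.1)
    note = f"synthetic bump R0={R0} R_max={R_max} lam={lam} L={L} ds={ds} sigma={noise_sigma} seed={seed}"
    return RadiusProfile(s=s, r=r, provenance=note)


@dataclass
class AnnulusCase:
    """Concentric-annulus diffusion test case with its closed-form flux.

    A capillary of radius R0 (perfectly absorbing, c = 0) sits inside a
    villous cylinder of radius R0 + d whose surface is held at c_mat; both
    have length L.  The analytic radial-diffusion transfer rate is
    N = 2*pi*L*D*c_mat / ln(1 + d/R0) = D*A*c_mat/(R0*ln(1+d/R0)).
    """

    R0: float
    d: float
    L: float
    inner_area: float
    N_analytic: float  # ug/s


def make_annulus_case(
    R0: float, d: float, L: float, params: TransportParameters | None = None
) -> AnnulusCase:
    if params is None:
        params = TransportParameters()
    if R0 <= 0 or d <= 0 or L <= 0:
        raise ValueError("R0, d and L must be positive")
    area = 2.0 * np.pi * R0 * L
    n = annular_diffusion_bound(params, area, R0, d)
    return AnnulusCase(R0=R0, d=d, L=L, inner_area=area, N_analytic=n)


def write_fixture_files(out_dir: str | Path, seed: int = 0) -> dict:
    """Materialize the standard fixtures to ``out_dir`` with a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    df = morphometry_table()
    p = out / "capillary_morphometry.csv"
    df.to_csv(p, index=False)
    files[p.name] = _sha256(p)

    prof = make_bump_profile(4.7, 6.8, 31.0, 76.0, ds=0.5, noise_sigma=0.1, seed=seed)
    p = out / "bump_profile_noisy.csv"
    from .profiles import write_profile

    write_profile(prof, p)
    files[p.name] = _sha256(p)

    shp = bump_shape(4.7, 6.8, 31.0, 76.0)
    p = out / "bump_shape.json"
    shp.to_json(p)
    files[p.name] = _sha256(p)

    manifest = out / "MANIFEST.json"
    manifest.write_text(json.dumps({"seed": seed, "sha256": files}, indent=1), encoding="utf-8")
    return files


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
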