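"""Validation metrics: curve comparison at equal volume, RMSE summaries.

Experimental and computational inflation runs are compared "at equal
volume": both P-V and d-V curves are linearly interpolated onto a common
uniform volume grid spanning the overlap of their volume ranges, and the
root-mean-square errors

    RMSE_P = sqrt(mean((P_exp - P_comp)^2))
    RMSE_d = sqrt(mean((d_exp - d_comp)^2))

are reported, together with RMSE_P as a percentage of the maximum
experimental pressure and a flag comparing RMSE_d with the 0.5 mm
fluoroscopy image resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class InflationCurve:
    """Paired (time, volume, pressure, central diameter) inflation samples."""

    time_s: np.ndarray
    volume_ml: np.ndarray
    pressure_mmhg: np.ndarray
    diameter_mm: np.ndarray
    provenance: str = "synthetic"  # experimental | computational | synthetic

    def __post_init__(self):
        arrays = {}
        for name in ("time_s", "volume_ml", "pressure_mmhg", "diameter_mm"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["volume_ml"].size
        if any(a.shape != (n,) for a in arrays.values()) or n < 1:
            raise InvalidInputError("curve columns must be 1-D arrays of equal length")
        if n > 1 and np.any(np.diff(arrays["volume_ml"]) <= 0.0):
            raise InvalidInputError("volume must be strictly increasing")
        if np.any(arrays["pressure_mmhg"] < -1e-9):
            raise InvalidInputError("pressure must be >= 0")

    def __len__(self) -> int:
        return self.volume_ml.size

    @property
    def max_pressure_mmhg(self) -> float:
        return float(np.max(self.pressure_mmhg))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "volume_ml": self.volume_ml,
                "pressure_mmHg": self.pressure_mmhg,
                "diameter_mm": self.diameter_mm,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "experimental") -> "InflationCurve":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        def col(name):
            if name.lower() not in cols:
                raise InvalidInputError(f"curve file {path} lacks column {name!r}")
            return df[cols[name.lower()]].to_numpy(dtype=float)
        return cls(
            time_s=col("time_s"),
            volume_ml=col("volume_ml"),
            pressure_mmhg=col("pressure_mmHg"),
            diameter_mm=col("diameter_mm"),
            provenance=provenance,
        )


def resample_at_equal_volume(
    a: InflationCurve, b: InflationCurve, n_grid: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate both curves onto a uniform volume grid over their overlap.

    Returns (grid, P_a, P_b, d_a, d_b).  Errors if the volume ranges do
    not overlap.
    """
    lo = max(a.volume_ml[0], b.volume_ml[0])
    hi = min(a.volume_ml[-1], b.volume_ml[-1])
    if hi <= lo:
        raise InvalidInputError(
            f"volume ranges do not overlap: [{a.volume_ml[0]:g}, {a.volume_ml[-1]:g}] vs "
            f"[{b.volume_ml[0]:g}, {b.volume_ml[-1]:g}]"
        )
    if n_grid < 2:
        raise InvalidInputError("n_grid must be >= 2")
    grid = np.linspace(lo, hi, n_grid)
    pa = np.interp(grid, a.volume_ml, a.pressure_mmhg)
    pb = np.interp(grid, b.volume_ml, b.pressure_mmhg)
    da = np.interp(grid, a.volume_ml, a.diameter_mm)
    db = np.interp(grid, b.volume_ml, b.diameter_mm)
    return grid, pa, pb, da, db


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference sqrt(mean((a - b)^2)) of paired samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise InvalidInputError("rmse needs >= 1 pair of equal-shape samples")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_percent_of_max(rmse_value: float, experimental) -> float:
    """RMSE as a percentage of the maximum experimental pressure.

    ``experimental`` may be an :class:`InflationCurve` or the maximum
    pressure itself.
    """
    if isinstance(experimental, InflationCurve):
        p_max = experimental.max_pressure_mmhg
    else:
        p_max = float(experimental)
    if p_max <= 0.0:
        raise InvalidInputError("maximum experimental pressure must be > 0")
    return 100.0 * rmse_value / p_max


@dataclass(frozen=True)
class CurveComparison:
    """Full comparison of an experimental and a computational curve."""

    volume_grid_ml: np.ndarray
    pressure_exp_mmhg: np.ndarray
    pressure_comp_mmhg: np.ndarray
    diameter_exp_mm: np.ndarray
    diameter_comp_mm: np.ndarray
    rmse_pressure_mmhg: float
    rmse_diameter_mm: float
    rmse_pressure_pct_of_max: float
    diameter_resolution_mm: float
    rmse_diameter_within_resolution: bool

    def report(self) -> dict:
        return {
            "rmse_pressure_mmHg": self.rmse_pressure_mmhg,
            "rmse_diameter_mm": self.rmse_diameter_mm,
            "rmse_pressure_pct_of_max": self.rmse_pressure_pct_of_max,
            "diameter_resolution_mm": self.diameter_resolution_mm,
            "rmse_diameter_within_resolution": self.rmse_diameter_within_resolution,
            "n_grid": int(self.volume_grid_ml.size),
            "volume_overlap_ml": [
                float(self.volume_grid_ml[0]),
                float(self.volume_grid_ml[-1]),
            ],
        }


def compare_curves(
    exp: InflationCurve,
    comp: InflationCurve,
    n_grid: int = 200,
    diameter_resolution_mm: float = 0.5,
) -> CurveComparison:
    """Compare curves at equal volume and summarise RMSEs.

    The RMSE_d flag marks whether the diameter error is below the
    acquisition-system (fluoroscopy) resolution, the natural noise floor
    of the bench diameter measurement.
    """
    grid, pe, pc, de, dc = resample_at_equal_volume(exp, comp, n_grid)
    rp = rmse(pe, pc)
    rd = rmse(de, dc)
    return CurveComparison(
        volume_grid_ml=grid,
        pressure_exp_mmhg=pe,
        pressure_comp_mmhg=pc,
        diameter_exp_mm=de,
        diameter_comp_mm=dc,
        rmse_pressure_mmhg=rp,
        rmse_diameter_mm=rd,
        rmse_pressure_pct_of_max=rmse_percent_of_max(rp, exp),
        diameter_resolution_mm=diameter_resolution_mm,
        rmse_diameter_within_resolution=bool(rd < diameter_resolution_mm),
    )
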