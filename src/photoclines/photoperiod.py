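"""Day length as a function of latitude and season.

Populations at the equator see ~12 h of daylight year-round; with increasing
|latitude| the annual range between the shortest and longest day widens, up to
the 0 h / 24 h extremes past the polar circles.  The difference between the
annual maximum and minimum day length (Δphotoperiod, hours) is the
environmental covariate of the selection scan: it is zero at the equator and a
monotone function of |latitude|, so any rank-based association with it is
insensitive to the fine details of the day-length formula.

Day length follows the standard sunrise equation with the CBM solar
declination approximation and a geometric horizon (no atmospheric refraction
or twilight correction):

    δ(d)  = −23.44° · cos(360° · (d + 10) / 365)
    cos ω = −tan(lat) · tan(δ)
    L     = 2ω / 15  hours

clamped to 0 h (polar night, cos ω > 1) and 24 h (polar day, cos ω < −1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentTable",
    "day_length",
    "annual_photoperiod_extremes",
    "delta_photoperiod",
    "environment_for_latitudes",
]

_AXIAL_TILT = 23.44  # degrees
_DAYS = np.arange(1, 366)


def day_length(latitude: float, day_of_year: int) -> float:
    """Hours of daylight at ``latitude`` on ``day_of_year`` (1-365).

    Parameters
    ----------
    latitude : float
        Degrees, in [-90, 90].
    day_of_year : int
        1-based day of a 365-day year.

    Returns
    -------
    float
        Day length in hours, in [0, 24].
    """
    if abs(latitude) > 90:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    decl = -_AXIAL_TILT * np.cos(np.deg2rad(360.0 * (day_of_year + 10) / 365.0))
    cos_omega = -np.tan(np.deg2rad(latitude)) * np.tan(np.deg2rad(decl))
    if cos_omega > 1.0:
        return 0.0
    if cos_omega < -1.0:
        return 24.0
    omega = np.rad2deg(np.arccos(cos_omega))
    return float(2.0 * omega / 15.0)


def _day_lengths_all_year(latitude: float) -> np.ndarray:
    decl = -_AXIAL_TILT * np.cos(np.deg2rad(360.0 * (_DAYS + 10) / 365.0))
    cos_omega = -np.tan(np.deg2rad(latitude)) * np.tan(np.deg2rad(decl))
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_omega)) / 15.0


def annual_photoperiod_extremes(latitude: float) -> tuple[float, float]:
    """Annual minimum and maximum day length (hours) at ``latitude``."""
    if abs(latitude) > 90:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    lengths = _day_lengths_all_year(latitude)
    return float(lengths.min()), float(lengths.max())


def delta_photoperiod(latitude: float) -> float:
    """Annual day-length range (max − min, hours); zero at the equator."""
    lo, hi = annual_photoperiod_extremes(latitude)
    return hi - lo


@dataclass
class EnvironmentTable:
    """Per-population environmental covariates.

    ``variables`` maps variable name -> {population_id -> value}.  The three
    photoperiod variables are always present once built from latitudes;
    arbitrary user-supplied variables (temperature, radiation flux, ...) are
    carried as opaque extra columns.
    """

    population_ids: list[str]
    variables: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValueError("duplicate population ids")
        for name, mapping in self.variables.items():
            missing = set(self.population_ids) - set(mapping)
            if missing:
                raise ValueError(f"variable {name!r} missing populations {sorted(missing)}")
        self._validate_photoperiod()

    def _validate_photoperiod(self) -> None:
        v = self.variables
        if not {"min_photoperiod", "max_photoperiod"} <= set(v):
            return
        for pid in self.population_ids:
            lo, hi = v["min_photoperiod"][pid], v["max_photoperiod"][pid]
            if not (0.0 <= lo <= hi <= 24.0):
                raise ValueError(f"photoperiod extremes out of order for {pid}: {lo}, {hi}")

    def values(self, variable: str) -> pd.Series:
        if variable not in self.variables:
            raise KeyError(f"variable {variable!r} not in environment table")
        return pd.Series(
            [self.variables[variable][p] for p in self.population_ids],
            index=self.population_ids,
            name=variable,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.values(name) for name in self.variables},
            index=self.population_ids,
        ).rename_axis("population_id")

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "EnvironmentTable":
        df = pd.read_csv(path, sep="\t", index_col="population_id")
        return cls(
            population_ids=[str(i) for i in df.index],
            variables={c: {str(i): float(v) for i, v in df[c].items()} for c in df.columns},
        )


def environment_for_latitudes(
    population_ids: list[str],
    latitudes: list[float],
    extra: dict[str, dict[str, float]] | None = None,
) -> EnvironmentTable:
    """Build an EnvironmentTable with the three photoperiod variables."""
    mins, maxs, deltas = {}, {}, {}
    for pid, lat in zip(population_ids, latitudes, strict=True):
        lo, hi = annual_photoperiod_extremes(lat)
        mins[pid], maxs[pid], deltas[pid] = lo, hi, hi - lo
    variables = {
        "min_photoperiod": mins,
        "max_photoperiod": maxs,
        "delta_photoperiod": deltas,
    }
    if extra:
        variables.update(extra)
    return EnvironmentTable(population_ids=list(population_ids), variables=variables)
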