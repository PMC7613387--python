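"""Goodness-of-fit statistics, leaf-to-canopy upscaling, and relative uncertainty."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "goodness_of_fit",
    "upscale_to_canopy",
    "coefficient_of_variation",
    "CV_UNDEFINED",
]

#: Sentinel for "maximal uncertainty": CV where the mean is (near) zero.
CV_UNDEFINED = np.inf

#: leaf-trait unit conversion so that leaf value x LAI lands in g/m^2
_UPSCALE_FACTOR = {
    "Cab": 1e-2,  # ug/cm^2 -> g/m^2
    "Cw": 1e4,    # cm EWT (= g/cm^2 of water) -> g/m^2
    "Cm": 1e4,    # g/cm^2 -> g/m^2
}


@dataclass(frozen=True)
class ValidationReport:
    """RMSE (trait units), NRMSE (% of observed range), and R^2."""

    RMSE: float
    NRMSE: float
    R2: float
    n: int
    trait: str = ""
    units: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "trait": self.trait, "units": self.units, "n": self.n,
            "RMSE": self.RMSE, "NRMSE_percent": self.NRMSE, "R2": self.R2,
        }])


def goodness_of_fit(observed, estimated, trait: str = "",
                    units: str = "") -> ValidationReport:
    """Validation statistics of estimates against observations.

    NRMSE is the RMSE divided by the observed range, in percent.  R^2 is the
    coefficient of determination 1 - SS_res / SS_tot (against the 1:1 line,
    so it can be negative), not a squared correlation.
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.shape != est.shape:
        raise ValueError("observed and estimated lengths differ")
    if obs.size < 2:
        raise ValueError("at least two pairs required")
    rng = float(np.ptp(obs))
    if rng == 0.0:
        raise ValueError("zero observed range: NRMSE undefined")
    res = obs - est
    rmse = float(np.sqrt(np.mean(res**2)))
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return ValidationReport(
        RMSE=rmse,
        NRMSE=100.0 * rmse / rng,
        R2=1.0 - ss_res / ss_tot,
        n=obs.size,
        trait=trait,
        units=units,
    )


def upscale_to_canopy(leaf_value, lai, trait: str):
    """Canopy-level trait (g/m^2) as leaf value x LAI with unit conversion.

    ``trait`` selects the conversion: Cab in ug/cm^2 (x 1e-2), Cw in cm EWT
    (x 1e4), Cm in g/cm^2 (x 1e4).
    """
    if trait not in _UPSCALE_FACTOR:
        raise ValueError(f"no canopy upscaling defined for trait {trait!r}")
    leaf = np.asarray(leaf_value, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(leaf < 0) or np.any(lai < 0):
        raise ValueError("leaf value and LAI must be non-negative")
    out = leaf * lai * _UPSCALE_FACTOR[trait]
    return float(out) if out.ndim == 0 else out


def coefficient_of_variation(mean, sd, eps: float = 1e-12):
    """Relative uncertainty CV = 100 * SD / mean, in percent.

    Where the mean is <= ``eps`` the ratio is undefined and the maximal-
    uncertainty sentinel (inf) is returned, which downstream masking treats
    as "always masked".
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > eps, 100.0 * sd / np.maximum(mean, eps), CV_UNDEFINED)
    cv = np.where((sd == 0) & (mean > eps), 0.0, cv)
    return float(cv) if cv.ndim == 0 else cv
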