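"""Physical corrections linking column AOD and dry PM2.5 to surface optics.

Satellite AOD integrates extinction over the whole column while PM2.5 is
measured at the surface, so AOD is normalised by the planetary boundary
layer height (km) into a per-km extinction proxy.  Station PM2.5 is
measured dry, while ambient particles swell with relative humidity; the
hygroscopic correction inflates the dry mass by (1 - RH/100)^-1.  Both
corrections are exact algebraic maps with exact inverses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["revise_aod", "revise_pm25", "dry_pm25"]


def _as_array_or_scalar(x):
    arr = np.asarray(x, dtype=float)
    return arr


def revise_aod(aod, pblh_km):
    """PBLH-normalised AOD: ``aod / pblh_km`` (per-km extinction proxy).

    Homogeneous of degree +1 in ``aod`` and -1 in ``pblh_km``.
    """
    aod = _as_array_or_scalar(aod)
    pblh = _as_array_or_scalar(pblh_km)
    if np.any(pblh <= 0):
        raise ValueError("pblh_km must be positive")
    if np.any(aod < 0):
        raise ValueError("aod must be >= 0")
    out = aod / pblh
    return float(out) if out.ndim == 0 else out


def _check_rh(rh_pct, rh_cap):
    rh = _as_array_or_scalar(rh_pct)
    if np.any(rh < 0) or np.any(rh >= 100):
        raise ValueError("rh_pct must be in [0, 100)")
    if rh_cap is not None and np.any(rh > rh_cap):
        raise ValueError(f"rh_pct exceeds rh_cap={rh_cap}")
    return rh


def revise_pm25(pm25, rh_pct, rh_cap: float | None = None):
    """Hygroscopic correction: ``pm25 * (1 - rh_pct/100)**-1``.

    Strictly increasing in RH for positive mass; identity at RH = 0.
    Diverges as RH -> 100, hence the optional cap.
    """
    pm = _as_array_or_scalar(pm25)
    if np.any(pm < 0):
        raise ValueError("pm25 must be >= 0")
    rh = _check_rh(rh_pct, rh_cap)
    out = pm / (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


def dry_pm25(revised_pm25, rh_pct, rh_cap: float | None = None):
    """Inverse hygroscopic correction: back to the measured (dry) scale."""
    rev = _as_array_or_scalar(revised_pm25)
    rh = _check_rh(rh_pct, rh_cap)
    out = rev * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out
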