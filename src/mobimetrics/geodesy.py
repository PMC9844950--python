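"""Geodesic distance on the WGS84 ellipsoid.

Distances between consecutive trajectory fixes are geodesic (ellipsoidal),
not great-circle: at the sub-kilometre scales gated by positional
uncertainty the ~0.3% flattening error of a spherical formula would be the
same order as the quantity of interest.

The inverse problem is solved with Vincenty's iterative method, vectorised
over numpy arrays. Vincenty converges for all point pairs except nearly
antipodal ones (within ~0.5 degrees of the antipode), which cannot occur
between consecutive fixes of a real trajectory; those pairs fall back to
the last iterate, accurate to a few metres at worst.
"""

from __future__ import annotations

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

_MAX_ITER = 200
_TOL = 1e-12


def geodesic_distance(lat1, lon1, lat2, lon2):
    """Geodesic distance in metres between WGS84 points.

    Accepts scalars or equal-shaped arrays of latitude/longitude in
    degrees; returns metres with the same shape (scalar in, scalar out).
    Symmetric and zero for coincident points.
    """
    lat1a, lon1a, lat2a, lon2a = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    )
    scalar = lat1a.ndim == 0
    lat1a, lon1a, lat2a, lon2a = (np.atleast_1d(a) for a in (lat1a, lon1a, lat2a, lon2a))

    phi1 = np.radians(lat1a)
    phi2 = np.radians(lat2a)
    L = np.radians(lon2a - lon1a)

    U1 = np.arctan((1 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(_MAX_ITER):
        if not active.any():
            break
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        ss = np.hypot(t1, t2)
        cs = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss > 0, cosU1 * cosU2 * sin_lam / np.where(ss == 0, 1, ss), 0.0)
        csa = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(csa > 0, cs - 2 * sinU1 * sinU2 / np.where(csa == 0, 1, csa), 0.0)
        C = WGS84_F / 16 * csa * (4 + WGS84_F * (4 - 3 * csa))
        lam_new = L + (1 - C) * WGS84_F * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1 + 2 * c2sm**2))
        )

        upd = active
        sin_sigma = np.where(upd, ss, sin_sigma)
        cos_sigma = np.where(upd, cs, cos_sigma)
        sigma = np.where(upd, sig, sigma)
        cos_sq_alpha = np.where(upd, csa, cos_sq_alpha)
        cos2sm = np.where(upd, c2sm, cos2sm)
        converged = np.abs(lam_new - lam) < _TOL
        lam = np.where(upd, lam_new, lam)
        active = active & ~converged

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    B = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos2sm
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos2sm**2)
                - B / 6 * cos2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos2sm**2)
            )
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma)

    # coincident points never enter the series expansion cleanly; force 0
    same = (lat1a == lat2a) & ((lon1a - lon2a) % 360.0 == 0.0)
    dist = np.where(same, 0.0, dist)

    if scalar:
        return float(dist[0])
    return dist
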