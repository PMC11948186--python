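"""Circular statistics kernel.

Descriptive statistics (mean angle, resultant length) and the three
hypothesis tests used on entrainment angles: the Rayleigh test of
uniformity, the Watson-Williams test for equality of mean directions, and
the two-sample Kuiper test for equality of angular distributions.

The API surface is in degrees; all internal computation is in radians, with
the single conversion point in :func:`_to_radians`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import wrap_degrees

__all__ = [
    "circular_mean_resultant",
    "rayleigh_test",
    "watson_williams_test",
    "kuiper_test",
    "WatsonWilliamsResult",
    "KuiperResult",
]

_RESULTANT_EPS = 1e-12


def _to_radians(angles_deg):
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size < 1:
        raise ValueError("need at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.radians(a)


def circular_mean_resultant(angles_deg, weights=None):
    """Mean direction and resultant length of a sample of angles.

    The mean resultant vector is ``R e^{i theta} = (1/n) sum_k e^{i theta_k}``.
    ``R`` is 1 for perfectly concentrated angles and 0 for balanced ones; when
    ``R`` is numerically zero (e.g. antipodal pairs) the mean direction is
    undefined and NaN is returned.

    Returns
    -------
    (mean_angle_deg, R) : tuple of float
        Mean angle in degrees in [-180, 180); NaN if undefined.
    """
    rad = _to_radians(angles_deg)
    if weights is None:
        z = np.exp(1j * rad).mean()
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != rad.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, matching length")
        z = (w * np.exp(1j * rad)).sum() / w.sum()
    r = float(np.abs(z))
    if r < _RESULTANT_EPS:
        return float("nan"), 0.0
    return float(wrap_degrees(np.degrees(np.angle(z)))), r


def rayleigh_test(angles_deg):
    """Rayleigh test of circular uniformity.

    Z = n R^2; the p-value uses the standard small-sample corrected
    approximation, clipped into (0, 1].
    """
    rad = _to_radians(angles_deg)
    n = rad.size
    r = float(np.abs(np.exp(1j * rad).mean()))
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
        / (288.0 * n * n)
    )
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _a1inv(r):
    """Inverse of A1(kappa) = I1(kappa)/I0(kappa) (Fisher's approximation)."""
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


@dataclass
class WatsonWilliamsResult:
    F: float
    p: float
    df_between: int
    df_within: int
    kappa: float
    assumptions_ok: bool
    warnings: tuple = ()


def watson_williams_test(*samples_deg):
    """Watson-Williams test for equality of mean directions across groups.

    The circular analogue of one-way ANOVA: assumes von Mises samples with a
    shared, adequately large concentration.  Samples with fewer than 10
    angles or pooled mean resultant length below 0.45 violate the guideline
    assumptions; the test still runs but is flagged.
    """
    if len(samples_deg) == 1 and isinstance(samples_deg[0], (list, tuple)) \
            and not np.isscalar(samples_deg[0][0]):
        samples_deg = tuple(samples_deg[0])
    if len(samples_deg) < 2:
        raise ValueError("need at least two samples")
    groups = [_to_radians(s) for s in samples_deg]
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    k = len(groups)
    if n_total <= k:
        raise ValueError("too few angles for the Watson-Williams test")

    resultants = np.array(
        [np.abs(np.exp(1j * g).sum()) for g in groups]
    )  # group resultant lengths (not normalized)
    pooled = np.concatenate(groups)
    r_all = float(np.abs(np.exp(1j * pooled).sum()))
    rw = float(resultants.sum() / n_total)  # weighted mean resultant length

    warnings = []
    if np.any(ns < 10):
        warnings.append("group with n < 10")
    if rw < 0.45:
        warnings.append("pooled resultant length < 0.45; low concentration")

    kappa = _a1inv(min(rw, 1.0 - 1e-12))
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    sum_r = float(resultants.sum())
    denom = n_total - sum_r
    if denom <= 0:  # all angles identical in every group
        return WatsonWilliamsResult(0.0, 1.0, k - 1, n_total - k, kappa,
                                    not warnings, tuple(warnings))
    f_stat = correction * ((sum_r - r_all) / (k - 1)) / (denom / (n_total - k))
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, k - 1, n_total - k))
    return WatsonWilliamsResult(
        float(f_stat), p, k - 1, n_total - k, kappa, not warnings,
        tuple(warnings),
    )


@dataclass
class KuiperResult:
    V: float
    p: float
    n_effective: float


def _kuiper_p(v, n_eff):
    """Asymptotic Kuiper tail probability with Stephens' finite-n factor."""
    lam = (np.sqrt(n_eff) + 0.155 + 0.24 / np.sqrt(n_eff)) * v
    if lam < 0.4:
        return 1.0
    p = 0.0
    for j in range(1, 200):
        term = 2.0 * (4.0 * j * j * lam * lam - 1.0) * np.exp(
            -2.0 * j * j * lam * lam
        )
        p += term
        if abs(term) < 1e-10:
            break
    return float(min(max(p, 0.0), 1.0))


def kuiper_test(sample_a_deg, sample_b_deg):
    """Two-sample Kuiper test for equality of circular distributions.

    V = D+ + D- on the circular ECDFs, which makes the statistic invariant
    to a common rotation of both samples (unlike Kolmogorov-Smirnov).
    """
    a = np.sort(_to_radians(sample_a_deg))
    b = np.sort(_to_radians(sample_b_deg))
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    # ECDF difference evaluated at every pooled point
    fa = np.searchsorted(a, pooled, side="right") / na
    fb = np.searchsorted(b, pooled, side="right") / nb
    d = fa - fb
    v = float(d.max() - min(d.min(), 0.0)) if na and nb else 0.0
    # D- must also account for the difference just before each jump
    fa_lo = np.searchsorted(a, pooled, side="left") / na
    fb_lo = np.searchsorted(b, pooled, side="left") / nb
    d_lo = fa_lo - fb_lo
    d_plus = max(d.max(), d_lo.max(), 0.0)
    d_minus = max((-d).max(), (-d_lo).max(), 0.0)
    v = float(d_plus + d_minus)
    n_eff = na * nb / (na + nb)
    return KuiperResult(v, _kuiper_p(v, n_eff), n_eff)
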