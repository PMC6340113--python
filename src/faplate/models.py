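"""Forward models for fluorescence-anisotropy (FA) titrations.

A TAMRA-labelled peptide P at fixed total concentration is titrated with a
protein (CaM or an isolated CaM domain).  Binding follows simple 1:1 mass
action, PCaM <=> P + CaM with K_D = [P][CaM]/[PCaM].  Because the peptide
is held at ~50 nM while K_D values reach down to ~1 nM, ligand depletion is
substantial and the exact quadratic isotherm must be used: the fractional
saturation Y of peptide with protein is the physical root of

    Y**2 - Y * (K_D + P_tot + C_tot) / P_tot + C_tot / P_tot = 0.

The measured anisotropy is a mole-fraction-weighted mixture of the free and
bound peptide signals, FA = FA_P * (1 - Y) + FA_PCaM * Y.  The same affine
mixture maps the Hill saturation of a preformed complex with Ca²⁺ onto the
column-wise FA response.

``equilibrium_oracle`` solves the same 1:1 equilibrium by bracketed
bisection on free protein; it exists as an independent cross-check of the
closed-form isotherm and is deliberately free of shared code with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EquilibriumState",
    "one_site_saturation",
    "two_mode_saturation",
    "fa_mixture",
    "hill_saturation",
    "equilibrium_oracle",
]


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (molar) of one 1:1 binding equilibrium."""

    p_free: float
    cam_free: float
    complex: float


def _check_nonneg(**vals: float) -> None:
    for name, v in vals.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be >= 0")


def one_site_saturation(kd, p_tot, cam_tot):
    """Fractional saturation Y of peptide for the 1:1 depletion isotherm.

    Parameters are molar; ``cam_tot`` may be an array.  The smaller root of
    the binding quadratic is evaluated in the Citardauq form

        [PC] = 2 * P_tot * C_tot / (b + sqrt(b**2 - 4 * P_tot * C_tot)),
        b = K_D + P_tot + C_tot,

    which avoids the catastrophic cancellation the textbook formula
    suffers when K_D << P_tot (tight binding).
    """
    kd = np.asarray(kd, dtype=float)
    cam_tot = np.asarray(cam_tot, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be > 0")
    if not p_tot > 0:
        raise ValueError("p_tot must be > 0")
    _check_nonneg(cam_tot=cam_tot)
    b = kd + p_tot + cam_tot
    disc = b * b - 4.0 * p_tot * cam_tot
    complex_conc = 2.0 * p_tot * cam_tot / (b + np.sqrt(disc))
    y = complex_conc / p_tot
    return y if y.ndim else float(y)


def two_mode_saturation(kd_i, kd_ii, cam_tot):
    """Sum-of-two-hyperbolas saturation for two independent binding modes.

    Valid in low-affinity regimes where free protein ~ total protein.  The
    two modes contribute additively, so Y ranges over [0, 2); downstream
    the bound-state FA amplitude is treated as effective, not per-site.
    """
    cam_tot = np.asarray(cam_tot, dtype=float)
    if np.any(np.asarray(kd_i) <= 0) or np.any(np.asarray(kd_ii) <= 0):
        raise ValueError("kd_i and kd_ii must be > 0")
    _check_nonneg(cam_tot=cam_tot)
    y = cam_tot / (kd_i + cam_tot) + cam_tot / (kd_ii + cam_tot)
    return y if y.ndim else float(y)


def fa_mixture(y, fa_lo, fa_hi):
    """Affine mixture of the free- and bound-state anisotropy signals."""
    if not (np.all(np.isfinite(fa_lo)) and np.all(np.isfinite(fa_hi))):
        raise ValueError("FA endpoints must be finite")
    y = np.asarray(y, dtype=float)
    out = fa_lo * (1.0 - y) + fa_hi * y
    return out if out.ndim else float(out)


def hill_saturation(app_kd, n, ca):
    """Hill saturation Y = 1 / ((appK_D/[Ca²⁺])**n + 1).

    ``app_kd`` is the free Ca²⁺ at half-saturation; ``n`` the empirical
    cooperativity exponent.  Y(0) = 0 by continuity.
    """
    if not app_kd > 0:
        raise ValueError("app_kd must be > 0")
    if not n > 0:
        raise ValueError("n must be > 0")
    ca = np.asarray(ca, dtype=float)
    _check_nonneg(ca=ca)
    with np.errstate(divide="ignore", over="ignore"):
        y = np.where(ca > 0, 1.0 / ((app_kd / np.maximum(ca, 1e-300)) ** n + 1.0), 0.0)
    return y if y.ndim else float(y)


def equilibrium_oracle(kd: float, p_tot: float, cam_tot: float) -> EquilibriumState:
    """Solve the 1:1 equilibrium by bisection on free protein.

    Independent of the closed-form isotherm: brackets free CaM in
    [0, cam_tot] and drives the protein mass balance
    cam_free + P_tot * cam_free / (K_D + cam_free) - cam_tot to zero.
    """
    if kd <= 0 and not np.isinf(kd):
        raise ValueError("kd must be > 0")
    if p_tot <= 0:
        raise ValueError("p_tot must be > 0")
    _check_nonneg(cam_tot=cam_tot)
    if cam_tot == 0.0:
        return EquilibriumState(p_free=p_tot, cam_free=0.0, complex=0.0)
    if np.isinf(kd):
        return EquilibriumState(p_free=p_tot, cam_free=cam_tot, complex=0.0)

    def balance(cam_free: float) -> float:
        return cam_free + p_tot * cam_free / (kd + cam_free) - cam_tot

    cam_free = brentq(balance, 0.0, cam_tot, xtol=1e-30, rtol=8.9e-16, maxiter=300)
    complex_conc = p_tot * cam_free / (kd + cam_free)
    return EquilibriumState(
        p_free=p_tot - complex_conc,
        cam_free=cam_free,
        complex=complex_conc,
    )
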