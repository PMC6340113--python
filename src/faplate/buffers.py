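"""Chelator-buffered free Ca²⁺ ("pCa buffer") calculations.

A pCa buffer clamps the free Ca²⁺ concentration of a solution with one or
more chelators (typically EGTA for the nanomolar range and NTA for the
micromolar range).  At a working pH well below the chelators' pKa values a
large fraction of the ligand is protonated and unavailable for Ca²⁺, so the
absolute stability constant must be corrected for proton competition
(Schwarzenbach's conditional-constant formalism):

    alpha_H = 1 + sum_i 10**(pKa_1 + ... + pKa_i - i * pH)
    K_D,cond = alpha_H / 10**logK_abs        (molar dissociation constant)

Free Ca²⁺ then follows from the total-Ca mass balance over all chelators,

    Ca_tot = f + sum_j  L_j,tot * f / (K_Dj + f),

which is strictly monotone in the free concentration f and is solved by
bracketed root-finding on [0, Ca_tot].

A two-stock mixing design produces a gradient of free Ca²⁺: a chelator
buffer without added Ca²⁺ and the same buffer brought to 3 mM total Ca²⁺
are mixed in fractions f ∈ [0, 1], giving Ca_tot = f * 3 mM per row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ChelatorSpec",
    "PCaBuffer",
    "EGTA",
    "NTA",
    "conditional_kd",
    "solve_free_calcium",
    "design_mixing_series",
    "default_pca_series",
]

#: Total Ca²⁺ of the high-Ca mixing stock (molar).
CA_TOTAL_STOCK = 3.0e-3


@dataclass(frozen=True)
class ChelatorSpec:
    """One Ca²⁺ chelator: total concentration and stability constants.

    ``abs_logK_ca`` is the log10 absolute (pH-independent) Ca²⁺ association
    constant; ``pka_list`` holds the proton pKa values relevant at the
    working pH, sorted descending.  Constants refer to ~0.15 M ionic
    strength, 25 °C.
    """

    name: str
    total_conc: float
    abs_logK_ca: float
    pka_list: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not math.isfinite(self.total_conc) or self.total_conc < 0:
            raise ValueError(f"{self.name}: total_conc must be finite and >= 0")
        if not math.isfinite(self.abs_logK_ca) or self.abs_logK_ca <= 0:
            raise ValueError(f"{self.name}: abs_logK_ca must be finite and > 0")
        if any(not math.isfinite(p) for p in self.pka_list):
            raise ValueError(f"{self.name}: non-finite pKa")
        if list(self.pka_list) != sorted(self.pka_list, reverse=True):
            raise ValueError(f"{self.name}: pka_list must be sorted descending")

    def with_total(self, total_conc: float) -> "ChelatorSpec":
        return ChelatorSpec(self.name, total_conc, self.abs_logK_ca, self.pka_list)


# Default constants (NIST-style, I ~ 0.15 M, 25 °C).  Only the two most
# acid-relevant protonations are carried; configurable via ChelatorSpec.
EGTA = ChelatorSpec("EGTA", 0.5e-3, 10.86, (9.40, 8.79))
NTA = ChelatorSpec("NTA", 2.0e-3, 6.41, (9.73,))


@dataclass(frozen=True)
class PCaBuffer:
    """A chelator-buffered solution with solved free Ca²⁺."""

    chelators: tuple[ChelatorSpec, ...]
    ph: float
    ca_total: float
    ca_free: float
    mix_fraction: float | None = None
    ionic_strength: float = 0.15
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ca_free <= self.ca_total or
                math.isclose(self.ca_free, self.ca_total, rel_tol=1e-9)):
            raise ValueError("ca_free must lie in [0, ca_total]")


def conditional_kd(chelator: ChelatorSpec, ph: float) -> float:
    """pH-corrected (conditional) Ca²⁺ dissociation constant, molar.

    Applies the proton side-reaction coefficient alpha_H to the absolute
    association constant.  Strictly increasing in [H⁺]: more acidic
    solutions bind Ca²⁺ more weakly.
    """
    if not (5.0 <= ph <= 9.0):
        raise ValueError(f"pH {ph} outside supported range [5, 9]")
    alpha_h = 1.0
    cum_pka = 0.0
    for i, pka in enumerate(chelator.pka_list, start=1):
        cum_pka += pka
        alpha_h += 10.0 ** (cum_pka - i * ph)
    kd = alpha_h / 10.0 ** chelator.abs_logK_ca
    if not math.isfinite(kd):
        raise ValueError(f"{chelator.name}: non-finite conditional K_D")
    return kd


def _mass_balance(f: float, ca_total: float,
                  totals: np.ndarray, kds: np.ndarray) -> float:
    return f + float(np.sum(totals * f / (kds + f))) - ca_total


def solve_free_calcium(
    ca_total: float,
    chelators: list[ChelatorSpec] | tuple[ChelatorSpec, ...],
    ph: float = 7.2,
) -> float:
    """Free Ca²⁺ (molar) for a given total Ca²⁺ over a chelator mixture.

    The unique nonnegative root of the Ca mass balance, found by Brent's
    method on [0, ca_total] and polished with Newton steps so the relative
    mass-balance residual is at machine precision.
    """
    if ca_total < 0:
        raise ValueError("ca_total must be >= 0")
    if ca_total == 0.0:
        return 0.0
    if not chelators:
        return float(ca_total)
    kds = np.array([conditional_kd(c, ph) for c in chelators])
    totals = np.array([c.total_conc for c in chelators])
    if np.any(kds <= 0):
        raise ValueError("conditional K_D must be > 0")
    f = brentq(
        _mass_balance, 0.0, ca_total, args=(ca_total, totals, kds),
        xtol=1e-24, rtol=8.9e-16, maxiter=200,
    )
    # Newton polish: the residual slope 1 + sum(L*K/(K+f)^2) is analytic.
    for _ in range(3):
        resid = _mass_balance(f, ca_total, totals, kds)
        slope = 1.0 + float(np.sum(totals * kds / (kds + f) ** 2))
        step = resid / slope
        if f - step < 0:
            break
        f -= step
        if abs(step) < 1e-18 * max(f, 1e-30):
            break
    return float(min(max(f, 0.0), ca_total))


def design_mixing_series(
    chelators: list[ChelatorSpec] | tuple[ChelatorSpec, ...] = (EGTA, NTA),
    *,
    fractions: list[float] | None = None,
    targets: list[float] | None = None,
    ph: float = 7.2,
    ca_total_stock: float = CA_TOTAL_STOCK,
) -> list[PCaBuffer]:
    """Design the two-stock mixing series that sets each row's free Ca²⁺.

    Forward mode (``fractions``): each entry f gives ca_total = f * stock
    with the free concentration solved.  Inverse mode (``targets``): for
    each desired free Ca²⁺ the mixing fraction is found by root-finding.
    Exactly one of the two keyword lists must be given.
    """
    if (fractions is None) == (targets is None):
        raise ValueError("give exactly one of fractions= or targets=")
    chelators = tuple(chelators)

    if fractions is not None:
        out = []
        for f in fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mixing fraction {f} outside [0, 1]")
            ca_tot = f * ca_total_stock
            out.append(PCaBuffer(chelators, ph, ca_tot,
                                 solve_free_calcium(ca_tot, chelators, ph), f))
        return out

    hi = solve_free_calcium(ca_total_stock, chelators, ph)
    out = []
    for target in targets:
        if not 0.0 <= target <= hi * (1 + 1e-12):
            raise ValueError(
                f"target free Ca {target:.3g} M outside achievable interval "
                f"[0, {hi:.3g}] M for this chelator mix"
            )
        if target == 0.0:
            out.append(PCaBuffer(chelators, ph, 0.0, 0.0, 0.0))
            continue
        f = brentq(
            lambda x: solve_free_calcium(x * ca_total_stock, chelators, ph) - target,
            0.0, 1.0, xtol=1e-18, rtol=8.9e-16, maxiter=200,
        )
        ca_tot = f * ca_total_stock
        out.append(PCaBuffer(chelators, ph, ca_tot,
                             solve_free_calcium(ca_tot, chelators, ph), f))
    return out


def default_pca_series(
    n_rows: int = 16,
    ca_free_min: float = 0.3e-9,
    ca_free_max: float = 400e-6,
    chelators: tuple[ChelatorSpec, ...] = (EGTA, NTA),
    ph: float = 7.2,
) -> list[PCaBuffer]:
    """The default 16-row gradient: log-spaced free Ca²⁺ 0.3 nM – 400 µM."""
    targets = list(np.geomspace(ca_free_min, ca_free_max, n_rows))
    return design_mixing_series(chelators, targets=targets, ph=ph)
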