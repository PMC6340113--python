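"""Column-wise Ca²⁺ response analysis: apparent Ca²⁺ affinities.

Reading one plate column down the 16 pCa rows gives the anisotropy of a
protein/peptide mixture at a fixed protein:peptide ratio as a function of
free Ca²⁺.  With the protein in excess the complex is formed throughout,
and the rise in FA with Ca²⁺ reports Ca²⁺ loading of the complex.  The
curve is fitted with an empirical Hill model on the raw FA signal,

    FA = FA_lowCa * (1 - Y) + FA_highCa * Y,
    Y  = 1 / ((appK_D / [Ca²⁺])**n + 1),

where appK_D is the free Ca²⁺ at half-saturation and n the Hill
coefficient.  appK_D is fitted on the log10 scale; n is free within
[0.5, 4].  The bound-endpoint is parameterized as FA_lowCa plus a
nonnegative amplitude, so a fitted response is increasing by
construction and Ca²⁺-unresponsive (or decreasing) columns surface as a
"no Ca²⁺ response" flag rather than an inverted fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .models import fa_mixture, hill_saturation

__all__ = [
    "CalciumResponseCurve",
    "HillFitResult",
    "extract_ca_response",
    "fit_hill",
    "normalize_response",
]

_LOG_APPKD_BOUNDS = (-12.0, -2.0)
_HILL_N_BOUNDS = (0.5, 4.0)
_FA_LO_BOUNDS = (0.0, 500.0)
_AMP_BOUNDS = (0.0, 500.0)
_MIN_POINTS = 8
_SPAN_NOISE_FACTOR = 3.0


@dataclass(frozen=True)
class CalciumResponseCurve:
    """One extracted column: FA versus free Ca²⁺ at fixed protein:peptide ratio."""

    ca_free: np.ndarray
    fa: np.ndarray
    ratio: float
    column_index: int = 0
    construct: str = ""

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca_free, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        if ca.shape != fa.shape:
            raise ValueError("ca_free and fa must have equal length")
        order = np.argsort(ca)
        ca, fa = ca[order], fa[order]
        if np.any(np.diff(ca) <= 0):
            raise ValueError("ca_free values must be distinct")
        object.__setattr__(self, "ca_free", ca)
        object.__setattr__(self, "fa", fa)

    def __len__(self) -> int:
        return len(self.fa)


@dataclass(frozen=True)
class HillFitResult:
    """Fitted apparent Ca²⁺ affinity of a protein/peptide complex."""

    app_kd: float | None
    n: float
    fa_low_ca: float
    fa_high_ca: float
    ci95: dict[str, tuple[float, float]]
    rss: float
    sigma: float
    converged: bool
    n_points: int
    flags: tuple[str, ...] = ()
    ratio: float | None = None
    construct: str = ""


def extract_ca_response(
    plate: pd.DataFrame,
    target_ratio: float,
    column: int | None = None,
    construct: str = "",
) -> CalciumResponseCurve:
    """Extract the column whose protein:peptide ratio is nearest the target.

    Nearness is judged in log space over the nominal per-column ratios.
    ``column`` overrides the automatic choice.  All plate rows must be
    present.  A ratio <= 1 (no protein excess) is allowed but warned
    about, since the Hill readout presumes the complex is formed
    throughout the Ca²⁺ series.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be > 0")
    n_rows = plate["row"].nunique()
    expected_rows = set(range(1, n_rows + 1))
    present = set(plate["row"].unique())
    missing = sorted(expected_rows - present)
    if missing:
        raise ValueError(f"plate is missing rows: {missing}")

    per_col = plate.groupby("col").agg(
        cam=("cam_tot_M", "median"), pep=("peptide_conc_M", "median")
    )
    ratios = per_col["cam"] / per_col["pep"]
    if column is None:
        column = int((np.log(ratios) - math.log(target_ratio)).abs().idxmin())
    ratio = float(ratios.loc[column])
    if ratio <= 1.0:
        warnings.warn(
            f"column {column} has protein:peptide ratio {ratio:.2g} <= 1; "
            "the Ca²⁺ response presumes excess protein", stacklevel=2,
        )
    sub = plate[plate["col"] == column].sort_values("ca_free_M")
    if sub["row"].nunique() != n_rows:
        raise ValueError(f"column {column} does not cover all {n_rows} rows")
    return CalciumResponseCurve(
        ca_free=sub["ca_free_M"].to_numpy(),
        fa=sub["fa"].to_numpy(),
        ratio=ratio,
        column_index=column,
        construct=construct,
    )


def _estimate_noise(fa: np.ndarray) -> float:
    d = np.diff(fa)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def fit_hill(curve: CalciumResponseCurve) -> HillFitResult:
    """Fit the Hill model to one Ca²⁺ response curve (raw FA signal)."""
    if len(curve) < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {len(curve)}")
    ca, fa = curve.ca_free, curve.fa

    def predict(theta: np.ndarray) -> np.ndarray:
        log_kd, n, fa_lo, amp = theta
        y = hill_saturation(10.0 ** log_kd, n, ca)
        return fa_mixture(y, fa_lo, fa_lo + amp)

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - fa

    # midpoint guess: free Ca where the signal crosses half its range
    half_fa = 0.5 * (np.min(fa) + np.max(fa))
    idx = int(np.argmin(np.abs(fa - half_fa)))
    kd0 = float(np.clip(ca[idx], 10.0 ** _LOG_APPKD_BOUNDS[0],
                        10.0 ** _LOG_APPKD_BOUNDS[1]))
    amp0 = max(float(np.max(fa) - np.min(fa)), 1.0)
    x0 = [math.log10(kd0), 1.5, float(np.min(fa)), amp0]
    res = least_squares(
        resid, x0,
        bounds=([_LOG_APPKD_BOUNDS[0], _HILL_N_BOUNDS[0],
                 _FA_LO_BOUNDS[0], _AMP_BOUNDS[0]],
                [_LOG_APPKD_BOUNDS[1], _HILL_N_BOUNDS[1],
                 _FA_LO_BOUNDS[1], _AMP_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    n_pts, n_par = len(curve), 4
    dof = max(n_pts - n_par, 1)
    rss = float(2.0 * res.cost)
    sigma = math.sqrt(rss / dof)
    cov = (rss / dof) * np.linalg.pinv(res.jac.T @ res.jac)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(0.975, dof)
    log_kd, n_hill, fa_lo, amp = res.x
    ci = {
        "app_kd": (10.0 ** (log_kd - tq * se[0]), 10.0 ** (log_kd + tq * se[0])),
        "n": (n_hill - tq * se[1], n_hill + tq * se[1]),
        "fa_low_ca": (fa_lo - tq * se[2], fa_lo + tq * se[2]),
        "fa_high_ca": (fa_lo + amp - tq * (se[2] + se[3]),
                       fa_lo + amp + tq * (se[2] + se[3])),
    }
    fitted = predict(res.x)
    span = float(np.max(fitted) - np.min(fitted))
    noise = max(sigma, _estimate_noise(fa))
    flags: list[str] = []
    converged = bool(res.success)
    app_kd: float | None = 10.0 ** log_kd
    if span < _SPAN_NOISE_FACTOR * noise or amp <= 0.0:
        flags.append("no Ca2+ response")
        converged = False
        app_kd = None
    return HillFitResult(
        app_kd=app_kd, n=float(n_hill), fa_low_ca=float(fa_lo),
        fa_high_ca=float(fa_lo + amp), ci95=ci, rss=rss, sigma=sigma,
        converged=converged, n_points=n_pts, flags=tuple(flags),
        ratio=curve.ratio, construct=curve.construct,
    )


def normalize_response(
    curve: CalciumResponseCurve, fit: HillFitResult
) -> np.ndarray:
    """Map raw FA onto fractional saturation with the fitted endpoints.

    Y_i = (FA_i - FA_lowCa) / (FA_highCa - FA_lowCa); the fitted curve
    then passes through 0.5 at [Ca²⁺] = appK_D.
    """
    if not fit.converged:
        raise ValueError("cannot normalize a non-converged fit")
    span = fit.fa_high_ca - fit.fa_low_ca
    if span <= 0:
        raise ValueError("degenerate FA endpoints")
    return (curve.fa - fit.fa_low_ca) / span
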