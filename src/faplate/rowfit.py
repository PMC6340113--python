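"""Row-wise titration-curve fitting: K_D versus free Ca²⁺.

Each plate row yields one curve of raw anisotropy against total protein at
a fixed free Ca²⁺.  The one-site fit estimates (K_D, FA_P, FA_PCaM) by
unweighted nonlinear least squares on the raw FA signal, with K_D fitted
on the log10 scale (the titration spans >5 decades and the sampling is
geometric, so the log parameterization is both better conditioned and the
natural scale for the confidence interval).  The two-mode variant fits a
sum of two hyperbolas (K_DI, K_DII = r * K_DI with r >= 1) for rows where
the single-site depletion isotherm misfits; the extra mode is only
accepted when an F-test on the residual sum of squares supports it and the
fitted K_D ratio is at least 5.

Confidence intervals are asymptotic: from the Jacobian at the optimum with
a Student-t quantile on n - p degrees of freedom, matching what standard
curve-fitting software reports.  Fits are flagged unreliable outside the
~1 nM – 5 µM window the assay can resolve (below, the curve is
stoichiometric and K_D barely enters; above, the top of the dilution
series no longer saturates).  Rows whose fitted dynamic range is within
noise are flagged "no-binding" and carry no K_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .models import fa_mixture, one_site_saturation, two_mode_saturation

__all__ = [
    "TitrationCurve",
    "BindingFitResult",
    "AffinityProfile",
    "fit_one_site",
    "fit_two_mode",
    "select_model",
    "build_affinity_profile",
    "curves_from_plate",
    "RELIABLE_KD_WINDOW",
]

#: Affinity window (molar) the assay resolves reliably.
RELIABLE_KD_WINDOW = (1e-9, 5e-6)

_LOGKD_BOUNDS = (-12.0, -3.0)
_FA_BOUNDS = (0.0, 500.0)
_MIN_POINTS = 6
#: fitted FA dynamic range must exceed this multiple of the noise estimate
_SPAN_NOISE_FACTOR = 3.0


@dataclass(frozen=True)
class TitrationCurve:
    """One plate row: raw FA versus total protein at fixed free Ca²⁺."""

    ca_free: float
    cam_tot: np.ndarray
    fa: np.ndarray
    peptide_conc: float
    peptide_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        cam = np.asarray(self.cam_tot, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        object.__setattr__(self, "cam_tot", cam)
        object.__setattr__(self, "fa", fa)
        if cam.shape != fa.shape:
            raise ValueError("cam_tot and fa must have equal length")
        if np.any(np.diff(cam) >= 0):
            raise ValueError("cam_tot must be strictly decreasing")
        if not self.peptide_conc > 0:
            raise ValueError("peptide_conc must be > 0")

    def __len__(self) -> int:
        return len(self.fa)


@dataclass(frozen=True)
class BindingFitResult:
    """Fitted binding parameters for one titration curve."""

    model: str                      # "one_site" | "two_mode"
    kd: float | None                # headline K_D (K_DI for two_mode), molar
    fa_p: float
    fa_pcam: float
    ci95: dict[str, tuple[float, float]]
    rss: float
    sigma: float                    # residual noise estimate
    converged: bool
    reliable: bool
    n_points: int
    flags: tuple[str, ...] = ()
    kd_ii: float | None = None      # two_mode only
    kd_ratio: float | None = None   # K_DII / K_DI
    ca_free: float | None = None
    peptide_id: str = ""
    replicate: int = 1

    @property
    def kd_ci(self) -> tuple[float, float] | None:
        return self.ci95.get("kd")


def _estimate_noise(fa: np.ndarray) -> float:
    """Robust read-noise estimate from first differences of the signal."""
    d = np.diff(fa)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def _asymptotic_ci(res, n: int, n_par: int) -> tuple[np.ndarray, float]:
    """95% half-widths per parameter from the Jacobian at the optimum."""
    dof = max(n - n_par, 1)
    rss = float(2.0 * res.cost)
    sigma2 = rss / dof
    jtj = res.jac.T @ res.jac
    cov = sigma2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(0.975, dof)
    return tq * se, math.sqrt(sigma2)


def _finish(curve, res, model, names, predict, headline_kd, extras):
    n = len(curve)
    n_par = len(res.x)
    half, sigma = _asymptotic_ci(res, n, n_par)
    ci = {}
    for name, x, h in zip(names, res.x, half):
        if name.startswith("log10_"):
            ci[name.removeprefix("log10_")] = (
                10.0 ** max(x - h, -300.0), 10.0 ** min(x + h, 300.0))
        else:
            ci[name] = (x - h, x + h)
    rss = float(2.0 * res.cost)
    fitted = predict(res.x)
    span = float(np.max(fitted) - np.min(fitted))
    noise = max(sigma, _estimate_noise(curve.fa))
    flags = list(extras.pop("flags", ()))
    converged = bool(res.success)
    kd = headline_kd
    if span < _SPAN_NOISE_FACTOR * noise:
        flags.append("no-binding/unresolvable")
        converged = False
        kd = None
    fa_p = extras.pop("fa_p")
    fa_pcam = extras.pop("fa_pcam")
    if kd is not None and fa_pcam <= fa_p:
        flags.append("inverted-endpoints")
        converged = False
        kd = None
    reliable = (
        kd is not None
        and converged
        and RELIABLE_KD_WINDOW[0] <= kd <= RELIABLE_KD_WINDOW[1]
    )
    return BindingFitResult(
        model=model, kd=kd, fa_p=fa_p, fa_pcam=fa_pcam, ci95=ci,
        rss=rss, sigma=sigma, converged=converged, reliable=reliable,
        n_points=n, flags=tuple(flags),
        ca_free=curve.ca_free, peptide_id=curve.peptide_id,
        replicate=curve.replicate, **extras,
    )


def _init_endpoints(fa: np.ndarray) -> tuple[float, float]:
    lo = float(np.clip(np.min(fa), *_FA_BOUNDS))
    hi = float(np.clip(np.max(fa), *_FA_BOUNDS))
    if hi - lo < 1.0:
        hi = min(lo + 1.0, _FA_BOUNDS[1])
    return lo, hi


def fit_one_site(curve: TitrationCurve) -> BindingFitResult:
    """Fit the 1:1 ligand-depletion isotherm to one titration curve."""
    if len(curve) < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {len(curve)}")
    cam, fa, p_tot = curve.cam_tot, curve.fa, curve.peptide_conc

    def predict(theta: np.ndarray) -> np.ndarray:
        logkd, fa_p, fa_pcam = theta
        y = one_site_saturation(10.0 ** logkd, p_tot, cam)
        return fa_mixture(y, fa_p, fa_pcam)

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - fa

    kd0 = float(np.exp(np.mean(np.log(cam[cam > 0]))))
    lo0, hi0 = _init_endpoints(fa)
    x0 = [np.clip(math.log10(kd0), *_LOGKD_BOUNDS), lo0, hi0]
    res = least_squares(
        resid, x0,
        bounds=([_LOGKD_BOUNDS[0], _FA_BOUNDS[0], _FA_BOUNDS[0]],
                [_LOGKD_BOUNDS[1], _FA_BOUNDS[1], _FA_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return _finish(
        curve, res, "one_site", ("log10_kd", "fa_p", "fa_pcam"), predict,
        headline_kd=10.0 ** res.x[0],
        extras={"fa_p": float(res.x[1]), "fa_pcam": float(res.x[2])},
    )


def fit_two_mode(curve: TitrationCurve) -> BindingFitResult:
    """Fit the two-mode (sum of hyperbolas) model to one titration curve.

    Intended for low-affinity rows where free ~ total protein.  K_DII is
    parameterized as r * K_DI with log10 r in [0, 3], so the ordering
    K_DI <= K_DII holds by construction; the headline affinity is K_DI.
    An identifiability flag is raised when the ratio collapses to 1 or
    the K_DII interval spans more than four decades.
    """
    if len(curve) < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} points, got {len(curve)}")
    cam, fa = curve.cam_tot, curve.fa

    def predict(theta: np.ndarray) -> np.ndarray:
        logkd, logr, fa_p, fa_pcam = theta
        kd_i = 10.0 ** logkd
        y = two_mode_saturation(kd_i, kd_i * 10.0 ** logr, cam)
        return fa_mixture(y, fa_p, fa_pcam)

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - fa

    kd0 = float(np.exp(np.mean(np.log(cam[cam > 0]))))
    lo0, hi0 = _init_endpoints(fa)
    x0 = [np.clip(math.log10(kd0), *_LOGKD_BOUNDS), 1.0, lo0, hi0]
    res = least_squares(
        resid, x0,
        bounds=([_LOGKD_BOUNDS[0], 0.0, _FA_BOUNDS[0], _FA_BOUNDS[0]],
                [_LOGKD_BOUNDS[1], 3.0, _FA_BOUNDS[1], _FA_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    kd_i = 10.0 ** res.x[0]
    ratio = 10.0 ** res.x[1]
    # width of the 95% interval on log10 K_DII from the full covariance:
    # var(log kd_ii) = var(log kd_i) + var(log r) + 2 cov
    dof = max(len(curve) - 4, 1)
    cov = (2.0 * res.cost / dof) * np.linalg.pinv(res.jac.T @ res.jac)
    var_kdii = max(cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1], 0.0)
    kdii_log_width = 2.0 * stats.t.ppf(0.975, dof) * math.sqrt(var_kdii)
    flags = []
    if ratio < 1.05 or kdii_log_width > 4.0:
        flags.append("two-mode-unsupported")
    return _finish(
        curve, res, "two_mode",
        ("log10_kd", "log10_kd_ratio", "fa_p", "fa_pcam"), predict,
        headline_kd=kd_i,
        extras={
            "fa_p": float(res.x[2]), "fa_pcam": float(res.x[3]),
            "kd_ii": kd_i * ratio, "kd_ratio": ratio, "flags": flags,
        },
    )


def select_model(
    one_site: BindingFitResult,
    two_mode: BindingFitResult,
    alpha: float = 0.05,
) -> BindingFitResult:
    """Choose between the one-site and two-mode fit of the same curve.

    The extra mode must earn its parameter: accepted only if the F-test on
    the RSS reduction is significant at ``alpha`` AND the fitted
    K_DII/K_DI ratio is at least 5 (well-separated modes).  Ties and
    everything ambiguous fall back to the one-site fit (parsimony).
    """
    if not one_site.converged:
        return one_site if not two_mode.converged else two_mode
    if not two_mode.converged:
        return one_site
    n = one_site.n_points
    dof2 = n - 4
    if dof2 <= 0 or two_mode.rss <= 0:
        return one_site
    f_stat = (one_site.rss - two_mode.rss) / (two_mode.rss / dof2)
    if f_stat <= 0:
        return one_site
    p_val = float(stats.f.sf(f_stat, 1, dof2))
    if p_val < alpha and (two_mode.kd_ratio or 0.0) >= 5.0:
        return two_mode
    return one_site


@dataclass(frozen=True)
class AffinityProfile:
    """K_D as a function of free Ca²⁺, with across-replicate summaries."""

    peptide_id: str
    construct: str
    points: tuple[BindingFitResult, ...]
    summary: pd.DataFrame = field(repr=False)
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.summary.copy()


def build_affinity_profile(
    fits: list[BindingFitResult],
    construct: str = "full-length CaM",
) -> AffinityProfile:
    """Group per-row fits by free Ca²⁺ and summarize across replicates.

    The per-condition summary is the geometric-mean K_D with a t-based
    95% CI on log10 K_D (replicate-to-replicate variation); a single
    replicate passes through its own asymptotic CI.  Non-converged or
    unreliable fits are excluded and counted.
    """
    if not fits:
        raise ValueError("no fits given")
    usable = [f for f in fits if f.converged and f.reliable and f.kd is not None]
    n_excluded = len(fits) - len(usable)
    if not usable:
        raise ValueError("no converged, reliable fits to summarize")
    peptide_id = usable[0].peptide_id
    groups: dict[float, list[BindingFitResult]] = {}
    for f in sorted(usable, key=lambda f: f.ca_free):
        groups.setdefault(f.ca_free, []).append(f)
    rows = []
    for ca, grp in groups.items():
        logs = np.log10([f.kd for f in grp])
        gmean = 10.0 ** float(np.mean(logs))
        n_rep = len(grp)
        if n_rep == 1:
            lo, hi = grp[0].kd_ci if grp[0].kd_ci else (np.nan, np.nan)
        else:
            sd = float(np.std(logs, ddof=1))
            h = stats.t.ppf(0.975, n_rep - 1) * sd / math.sqrt(n_rep)
            lo, hi = 10.0 ** (np.mean(logs) - h), 10.0 ** (np.mean(logs) + h)
        rows.append({
            "ca_free_M": ca, "kd_M": gmean, "ci_lo_M": lo, "ci_hi_M": hi,
            "model": grp[0].model, "reliable": True, "n_replicates": n_rep,
        })
    summary = pd.DataFrame(rows).sort_values("ca_free_M", ignore_index=True)
    return AffinityProfile(
        peptide_id=peptide_id, construct=construct,
        points=tuple(sorted(usable, key=lambda f: (f.ca_free, f.replicate))),
        summary=summary, n_excluded=n_excluded,
    )


def curves_from_plate(plate: pd.DataFrame) -> list[TitrationCurve]:
    """Split a long-format plate table into per-row titration curves."""
    required = {"row", "ca_free_M", "cam_tot_M", "fa", "peptide_conc_M"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    curves = []
    keys = ["replicate", "row"] if "replicate" in plate.columns else ["row"]
    for _, grp in plate.groupby(keys, sort=True):
        grp = grp.sort_values("cam_tot_M", ascending=False)
        curves.append(TitrationCurve(
            ca_free=float(grp["ca_free_M"].iloc[0]),
            cam_tot=grp["cam_tot_M"].to_numpy(),
            fa=grp["fa"].to_numpy(),
            peptide_conc=float(grp["peptide_conc_M"].iloc[0]),
            peptide_id=str(grp["peptide_id"].iloc[0]) if "peptide_id" in grp else "",
            replicate=int(grp["replicate"].iloc[0]) if "replicate" in grp else 1,
        ))
    return curves
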