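"""Headline numbers, comparisons, and the end-to-end pipeline driver.

Affinity differences are summarized as fold changes (always >= 1, rounded
to two significant figures for reporting) and judged by the conservative
rule of nonoverlapping 95% confidence intervals: two estimates differ only
when their intervals are disjoint, with shared endpoints counting as
overlap.
"""

from __future__ import annotations

import json
import math
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .buffers import EGTA, NTA, design_mixing_series, default_pca_series
from .hill import extract_ca_response, fit_hill
from .peptides import get_peptide
from .plate import PlateDesign, SimulationTruth, simulate_plate
from .rowfit import (
    build_affinity_profile,
    curves_from_plate,
    fit_one_site,
    fit_two_mode,
    select_model,
)

__all__ = [
    "ComparisonResult",
    "fold_change",
    "round_sig",
    "compare_nonoverlapping_ci",
    "run_pipeline",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def fold_change(kd_a: float, kd_b: float) -> float:
    """Ratio of the weaker to the tighter affinity; symmetric and >= 1."""
    if not (kd_a > 0 and kd_b > 0):
        raise ValueError("dissociation constants must be > 0")
    return max(kd_a, kd_b) / min(kd_a, kd_b)


@dataclass(frozen=True)
class ComparisonResult:
    a_label: str
    b_label: str
    estimate_a: float
    estimate_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    fold: float
    significant: bool


def compare_nonoverlapping_ci(
    estimate_a: float,
    ci_a: tuple[float, float],
    estimate_b: float,
    ci_b: tuple[float, float],
    a_label: str = "A",
    b_label: str = "B",
    converged_a: bool = True,
    converged_b: bool = True,
) -> ComparisonResult:
    """Conservative significance call: disjoint 95% CIs.

    Shared endpoints count as overlap (not significant).  Refuses
    non-converged inputs.
    """
    if not (converged_a and converged_b):
        raise ValueError("comparison refused: non-converged fit(s)")
    for ci in (ci_a, ci_b):
        if not all(math.isfinite(v) for v in ci):
            raise ValueError("confidence intervals must be finite")
    significant = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
    return ComparisonResult(
        a_label=a_label, b_label=b_label,
        estimate_a=estimate_a, estimate_b=estimate_b,
        ci_a=tuple(ci_a), ci_b=tuple(ci_b),
        fold=fold_change(estimate_a, estimate_b),
        significant=significant,
    )


# ---------------------------------------------------------------- pipeline

_DEFAULT_CONFIG = {
    "seed": 0,
    "design": {},       # PlateDesign overrides (peptide_id, stock_conc, ...)
    "truth": {},        # SimulationTruth overrides
    "analysis": {"model": "auto", "alpha": 0.05, "ratio": 4.0},
}


def _build_design(cfg: dict) -> PlateDesign:
    kw = dict(cfg)
    peptide_id = kw.pop("peptide_id", "CaMBD2")
    n_rows = kw.pop("n_rows", 16)
    ca_lo = kw.pop("ca_free_min", 0.3e-9)
    ca_hi = kw.pop("ca_free_max", 400e-6)
    buffers = tuple(default_pca_series(n_rows, ca_lo, ca_hi))
    return PlateDesign(row_buffers=buffers, peptide=get_peptide(peptide_id), **kw)


def _fit_rows(plate: pd.DataFrame, model: str, alpha: float):
    results = []
    for curve in curves_from_plate(plate):
        if model == "one-site":
            results.append(fit_one_site(curve))
        elif model == "two-mode":
            results.append(fit_two_mode(curve))
        else:
            results.append(select_model(fit_one_site(curve),
                                        fit_two_mode(curve), alpha))
    return results


def _fit_json(fit) -> dict:
    d = asdict(fit)
    d["flags"] = list(fit.flags)
    d["ci95"] = {k: list(v) for k, v in fit.ci95.items()}
    return d


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """simulate -> fit rows -> fit Ca²⁺ response -> report.

    ``config`` is a dict or path to a YAML file with optional ``seed``,
    ``design``, ``truth``, and ``analysis`` sections; every artifact lands
    in ``outdir``.  Deterministic given the seed.  Returns a manifest of
    the written files plus the headline numbers.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**_DEFAULT_CONFIG, **config}
    cfg["analysis"] = {**_DEFAULT_CONFIG["analysis"], **cfg.get("analysis", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = _build_design(cfg.get("design") or {})
    truth = SimulationTruth(**{**(cfg.get("truth") or {}), "seed": cfg["seed"]})
    plate = simulate_plate(design, truth)
    plate.to_csv(outdir / "plate.csv", index=False)

    fits = _fit_rows(plate, cfg["analysis"]["model"], cfg["analysis"]["alpha"])
    (outdir / "fits.json").write_text(
        json.dumps([_fit_json(f) for f in fits], indent=1, default=float)
    )
    profile = build_affinity_profile(fits)
    profile.to_frame().to_csv(outdir / "profile.csv", index=False)

    curve = extract_ca_response(plate, cfg["analysis"]["ratio"])
    hill = fit_hill(curve)
    (outdir / "hill.json").write_text(
        json.dumps({
            "app_kd_M": hill.app_kd, "n": hill.n,
            "fa_low_ca": hill.fa_low_ca, "fa_high_ca": hill.fa_high_ca,
            "ci95": {k: list(v) for k, v in hill.ci95.items()},
            "converged": hill.converged, "flags": list(hill.flags),
            "column": curve.column_index, "ratio": curve.ratio,
        }, indent=1, default=float)
    )

    kds = profile.summary
    headline = {
        "kd_lowest_ca_M": float(kds["kd_M"].iloc[0]),
        "kd_highest_ca_M": float(kds["kd_M"].iloc[-1]),
        "kd_fold_change": round_sig(
            fold_change(kds["kd_M"].iloc[0], kds["kd_M"].iloc[-1])),
        "app_kd_M": hill.app_kd,
        "hill_n": hill.n,
    }
    meta = {
        "faplate_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg["seed"],
        "chelator_constants": {
            c.name: {"total_M": c.total_conc, "logK_Ca": c.abs_logK_ca,
                     "pKa": list(c.pka_list)}
            for c in (EGTA, NTA)
        },
        "design": {
            "peptide": design.peptide.id,
            "peptide_conc_M": design.peptide_conc,
            "stock_conc_M": design.stock_conc,
            "n_rows": design.n_rows, "n_cols": design.n_cols,
        },
        "truth": asdict(truth),
        "headline": headline,
    }
    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=1, default=float))
    return {
        "outdir": str(outdir),
        "files": ["plate.csv", "fits.json", "profile.csv", "hill.json",
                  "run_metadata.json"],
        **headline,
    }
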