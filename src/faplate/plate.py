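"""Synthetic 384-well two-dimensional titration plates.

The assay layout: a 16-row x 24-column plate.  Each row is one pCa buffer
condition (one free Ca²⁺, spanning 0.3 nM – 400 µM down the plate); across
each row the protein (CaM) is serially diluted while the labelled peptide
stays fixed at ~50 nM.  Column 1 receives 3 µl protein stock into 65 µl of
buffer, then 38 µl is transferred stepwise into 30 µl wells, a 38:68
dilution per column, giving 24 protein concentrations spanning more than
five orders of magnitude.

The generator draws each well's anisotropy from the 1:1 ligand-depletion
isotherm with a Ca²⁺-dependent generating K_D (a smooth, monotone
log-logistic profile between an apo and a Ca²⁺-saturated affinity) plus
additive Gaussian read noise, and optionally compounds a multiplicative
per-transfer pipetting error down the dilution series.  Anisotropy is
treated as a pure mole-fraction-weighted signal; intensity-enhancement
effects of binding on the probe are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .buffers import PCaBuffer, default_pca_series
from .models import fa_mixture, one_site_saturation
from .peptides import Peptide, get_peptide

__all__ = [
    "PlateDesign",
    "SimulationTruth",
    "dilution_series",
    "kd_linkage_profile",
    "simulate_titration_row",
    "simulate_plate",
    "conc_from_absorbance",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = [
    "plate_id", "replicate", "row", "col",
    "ca_free_M", "cam_tot_M", "peptide_id", "peptide_conc_M", "fa",
]


@dataclass(frozen=True)
class PlateDesign:
    """Geometry and contents of one titration plate.

    Volumes are in µl; concentrations molar.  Defaults reproduce the
    standard layout: 680 µM protein stock (3 µl into 65 µl buffer gives a
    30 µM top concentration), 50 nM peptide, 38:68 serial dilution.
    """

    row_buffers: tuple[PCaBuffer, ...] = ()
    peptide: Peptide = field(default_factory=lambda: get_peptide("CaMBD2"))
    peptide_conc: float = 50e-9
    stock_conc: float = 680e-6
    v_stock: float = 3.0
    v_first: float = 65.0
    v_well: float = 30.0
    v_transfer: float = 38.0
    n_cols: int = 24

    def __post_init__(self) -> None:
        for v in (self.v_stock, self.v_first, self.v_well, self.v_transfer):
            if not v > 0:
                raise ValueError("all volumes must be > 0")
        if not (self.stock_conc > 0 and self.peptide_conc > 0):
            raise ValueError("concentrations must be > 0")
        if self.n_cols < 2:
            raise ValueError("need at least 2 columns")
        if not self.row_buffers:
            object.__setattr__(self, "row_buffers", tuple(default_pca_series()))

    @property
    def n_rows(self) -> int:
        return len(self.row_buffers)

    @property
    def dilution_factor(self) -> float:
        return self.v_transfer / (self.v_transfer + self.v_well)

    @property
    def top_conc(self) -> float:
        return self.stock_conc * self.v_stock / (self.v_stock + self.v_first)


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters for one synthetic plate.

    ``kd_apo``/``kd_sat`` anchor the Ca²⁺-dependent K_D profile at zero
    and saturating Ca²⁺ (kd_sat <= kd_apo: affinity increases with Ca²⁺);
    ``pca_mid``/``slope`` place and sharpen the log-logistic transition.
    FA baselines default to 150 (free peptide) and 250 (bound plateau);
    read noise sigma 3 anisotropy units; pipetting CV 2% per transfer.
    """

    kd_apo: float = 390e-9
    kd_sat: float = 1e-9
    pca_mid: float = 60e-9
    slope: float = 2.0
    fa_free: float = 150.0
    fa_bound: float = 250.0
    noise_sd: float = 3.0
    pipette_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_sat > self.kd_apo:
            raise ValueError("kd_sat must be <= kd_apo")
        if self.noise_sd < 0 or self.pipette_cv < 0:
            raise ValueError("noise_sd and pipette_cv must be >= 0")
        if not (self.pca_mid > 0 and self.slope > 0):
            raise ValueError("pca_mid and slope must be > 0")

    @classmethod
    def no_binding(cls, **kw) -> "SimulationTruth":
        """Truth for the free-dye control: flat rows at the free baseline."""
        return cls(kd_apo=math.inf, kd_sat=math.inf, **kw)


def dilution_series(design: PlateDesign) -> np.ndarray:
    """Nominal total protein concentration per column (molar), decreasing."""
    d = design.dilution_factor
    return design.top_conc * d ** np.arange(design.n_cols)


def kd_linkage_profile(truth: SimulationTruth, ca) -> np.ndarray | float:
    """Generating K_D at free Ca²⁺ ``ca``: log-logistic between the anchors.

    log10 K_D(ca) = log10 kd_sat + (log10 kd_apo - log10 kd_sat) /
                    (1 + (ca / pca_mid)**slope)
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be >= 0")
    if math.isinf(truth.kd_apo) or math.isinf(truth.kd_sat):
        out = np.full(ca.shape, np.inf)
        return out if out.ndim else float(out)
    lo, hi = math.log10(truth.kd_sat), math.log10(truth.kd_apo)
    logkd = lo + (hi - lo) / (1.0 + (ca / truth.pca_mid) ** truth.slope)
    out = 10.0 ** logkd
    return out if out.ndim else float(out)


def _noisy_series(design: PlateDesign, cv: float, rng: np.random.Generator) -> np.ndarray:
    """One row's realized concentrations with compounding transfer errors."""
    nominal_top = design.top_conc
    if cv == 0:
        return dilution_series(design)
    top = nominal_top * (1.0 + cv * rng.standard_normal())
    factors = design.dilution_factor * (1.0 + cv * rng.standard_normal(design.n_cols - 1))
    return top * np.concatenate([[1.0], np.cumprod(factors)])


def simulate_titration_row(
    cam_tot: np.ndarray,
    kd: float,
    peptide_conc: float,
    fa_free: float,
    fa_bound: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """FA readings for one titration row at a single K_D."""
    if math.isinf(kd):
        fa = np.full(len(cam_tot), float(fa_free))
    else:
        y = one_site_saturation(kd, peptide_conc, cam_tot)
        fa = fa_mixture(y, fa_free, fa_bound)
    if noise_sd > 0:
        fa = fa + noise_sd * rng.standard_normal(len(cam_tot))
    return np.asarray(fa, dtype=float)


def simulate_plate(
    design: PlateDesign,
    truth: SimulationTruth,
    plate_id: str = "synthetic",
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a full plate; returns a long-format measurement table.

    One seeded generator drives the whole plate, so an identical seed
    yields a bit-identical table.  Pipetting errors are drawn per transfer
    and compound down each row, as in a real serial dilution.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    binds = design.peptide.binds
    records = []
    for r, buf in enumerate(design.row_buffers, start=1):
        cam = _noisy_series(design, truth.pipette_cv, rng)
        kd = kd_linkage_profile(truth, buf.ca_free) if binds else math.inf
        fa = simulate_titration_row(
            cam, kd, design.peptide_conc,
            truth.fa_free, truth.fa_bound, truth.noise_sd, rng,
        )
        for c in range(design.n_cols):
            records.append((plate_id, replicate, r, c + 1, buf.ca_free,
                            cam[c], design.peptide.id, design.peptide_conc,
                            fa[c]))
    return pd.DataFrame.from_records(records, columns=PLATE_COLUMNS)


def conc_from_absorbance(a: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer–Lambert concentration, c = A / (epsilon * l), in molar."""
    if a < 0:
        raise ValueError("absorbance must be >= 0")
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    if not path_cm > 0:
        raise ValueError("path length must be > 0")
    return a / (epsilon * path_cm)
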