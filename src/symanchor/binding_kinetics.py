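"""Dose-response blocking model, Kd estimation and mutant-cycle energetics.

The unblocked current fraction of a channel population exposed to a
pore-blocking toxin follows a 1:1 binding isotherm with a fixed residual
floor:

    I/Imax = floor + amplitude * (1 + [toxin]/Kd)^-1

with floor = 0.1 and amplitude = 0.9 by default.  The floor absorbs the
~10% of channels inserted facing the wrong way in a planar bilayer, which
the extracellular toxin cannot block; at zero concentration the fraction is
exactly floor + amplitude = 1.  Concentrations and Kd are in nM throughout.

Double-mutant-cycle coupling energies use the standard log cross-ratio of
the four dissociation constants, in kT units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BlockingModel",
    "DoseResponseData",
    "CouplingResult",
    "unblocked_fraction",
    "fit_kd",
    "affinity_fold_change",
    "coupling_energy",
]

KCAL_PER_KT_298 = 0.5925  # kcal/mol per kT at 298 K


@dataclass
class BlockingModel:
    kd: float                 # nM
    floor: float = 0.1
    amplitude: float = 0.9

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        if abs(self.floor + self.amplitude - 1.0) > 1e-9:
            raise ValueError("floor + amplitude must equal 1 (zero-concentration normalization)")


@dataclass
class DoseResponseData:
    concentrations: np.ndarray   # nM
    fractions: np.ndarray        # I/Imax
    sem: np.ndarray | None = None
    n_replicates: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.concentrations.shape != self.fractions.shape:
            raise ValueError("concentrations and fractions differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.fractions.shape:
                raise ValueError("sem length mismatch")


@dataclass
class CouplingResult:
    delta_delta_g_kt: float
    kds_nM: tuple[float, float, float, float]

    def in_kcal_per_mol(self, temperature_k: float = 298.0) -> float:
        return self.delta_delta_g_kt * KCAL_PER_KT_298 * temperature_k / 298.0


def unblocked_fraction(conc, model: BlockingModel):
    """I/Imax at toxin concentration `conc` (nM); vectorized."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    out = model.floor + model.amplitude / (1.0 + conc / model.kd)
    return float(out) if out.ndim == 0 else out


@dataclass
class KdFit:
    kd: float
    kd_se: float
    residuals: np.ndarray
    model: BlockingModel


def fit_kd(data: DoseResponseData, floor: float = 0.1, amplitude: float = 0.9,
           weighted: bool = False) -> KdFit:
    """Least-squares Kd with floor and amplitude held fixed.

    The search runs on log(Kd), which makes the optimization scale-free
    across the nM-uM range.  The asymptotic standard error comes from the
    Jacobian at the optimum.  With `weighted`, residuals are divided by the
    per-point SEM (data must carry one).
    """
    pos = data.concentrations > 0
    if np.unique(data.concentrations[pos]).size < 3:
        raise ValueError("need >= 3 distinct positive concentrations to identify Kd")
    if np.all(data.fractions >= 0.99):
        raise ValueError("no block observed (all fractions >= 0.99): Kd not identifiable")
    if weighted:
        if data.sem is None:
            raise ValueError("weighted fit requires per-point SEM")
        w = 1.0 / np.where(data.sem > 0, data.sem, np.nanmin(data.sem[data.sem > 0]))
    else:
        w = np.ones_like(data.fractions)

    conc, frac = data.concentrations, data.fractions

    def resid(log_kd):
        model = floor + amplitude / (1.0 + conc / np.exp(log_kd[0]))
        return w * (model - frac)

    # start from the concentration closest to half-block
    half = floor + amplitude / 2.0
    k0 = conc[pos][np.argmin(np.abs(frac[pos] - half))]
    sol = least_squares(resid, x0=[np.log(max(k0, 1e-6))], method="lm")
    if not sol.success:
        raise RuntimeError(f"Kd fit did not converge: {sol.message}")
    kd = float(np.exp(sol.x[0]))
    # asymptotic SE on log kd -> delta-method SE on kd
    dof = max(len(frac) - 1, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    JtJ = float((sol.jac.T @ sol.jac)[0, 0])
    se_log = np.sqrt(s2 / JtJ) if JtJ > 0 else np.inf
    return KdFit(kd, kd * se_log, sol.fun / w, BlockingModel(kd, floor, amplitude))


def affinity_fold_change(kd_a: float, kd_b: float) -> float:
    """Fold change kd_b / kd_a (e.g. ~10-fold weakened binding in Cs+ vs K+)."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_b / kd_a


def coupling_energy(kd_ww: float, kd_mw: float, kd_wm: float,
                    kd_mm: float) -> CouplingResult:
    """Double-mutant-cycle coupling energy in kT.

    ddG = ln[(kd_mm * kd_ww) / (kd_mw * kd_wm)]: zero when the two mutations
    act independently, positive when the double mutant is weaker than the
    product of the singles predicts.  Symmetric under exchange of the two
    single mutants.
    """
    kds = (kd_ww, kd_mw, kd_wm, kd_mm)
    if any(k <= 0 for k in kds):
        raise ValueError("all four dissociation constants must be positive")
    return CouplingResult(float(np.log((kd_mm * kd_ww) / (kd_mw * kd_wm))), kds)
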