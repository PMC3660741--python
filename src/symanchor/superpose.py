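"""Least-squares rigid-body superposition restricted to proper rotations.

The Kabsch algorithm gives the closed-form minimizer of the weighted sum of
squared distances between paired point sets over rotations with det = +1.
Reflections are forbidden because a physical ligand cannot be mirrored; when
the optimal orthogonal map would be a reflection, the sign of the smallest
singular vector is flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_structures import RigidTransform, Structure

__all__ = ["SuperpositionResult", "kabsch", "superpose_structures", "UnderDeterminedWarning"]


class UnderDeterminedWarning(UserWarning):
    """Fewer than 3 points, or (near-)collinear points: rotation not unique."""


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    per_point_residuals: np.ndarray
    n_points: int
    #: literal mean of distances (the alternative reading of a
    #: "minimize the sum of distances" objective) — diagnostic only
    mean_distance: float = 0.0
    under_determined: bool = False

    @property
    def sum_distances(self) -> float:
        return float(np.sum(self.per_point_residuals))


def _collinear(points: np.ndarray, tol_deg: float = 1.0) -> bool:
    if len(points) < 3:
        return True
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] == 0:
        return True
    return s[1] / s[0] < np.sin(np.deg2rad(tol_deg))


def kabsch(moving, fixed, weights=None) -> SuperpositionResult:
    """Optimal proper rigid transform mapping `moving` onto `fixed`.

    Points are paired by index.  With 3 non-collinear points (the anchor
    placement case: three heavy-atom markers) the rotation is unique; fewer
    or collinear points return a minimizer flagged under-determined.
    """
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if moving.shape != fixed.shape:
        raise ValueError(f"point sets differ in shape: {moving.shape} vs {fixed.shape}")
    n = len(moving)
    if n == 0:
        raise ValueError("empty point sets")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be a non-negative length-n vector")
        if w.sum() == 0:
            raise ValueError("weights sum to zero")
    wn = w / w.sum()

    mu_m = wn @ moving
    mu_f = wn @ fixed
    A = (fixed - mu_f).T @ ((moving - mu_m) * wn[:, None])
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = mu_f - R @ mu_m
    transform = RigidTransform(R, t)

    resid = np.linalg.norm(transform.apply(moving) - fixed, axis=1)
    rmsd = float(np.sqrt(np.sum(wn * resid**2)))
    under = n < 3 or _collinear(moving)
    if under:
        warnings.warn(f"superposition with n={n} points is under-determined",
                      UnderDeterminedWarning)
    return SuperpositionResult(transform, rmsd, resid, n,
                               mean_distance=float(np.mean(resid)),
                               under_determined=under)


def superpose_structures(moving: Structure, fixed: Structure,
                         chain_id: str | None = None,
                         res_range: tuple[int, int] | None = None,
                         atom_names: set[str] | None = None,
                         ) -> SuperpositionResult:
    """Superpose two structures over an explicit selection.

    The selection (chain, author residue range, atom-name set — e.g. the
    main-chain atoms of the pore domain, residues 321-414) must resolve to
    the same ordered atom pairing in both structures; unpaired atoms raise
    a pairing error listing the offenders.
    """
    sel_m = moving.select(chain_id, res_range, atom_names)
    sel_f = fixed.select(chain_id, res_range, atom_names)
    keys_m = [(r.chain_id, r.seq_number, r.insertion_code, a.name)
              for r in sel_m.residues for a in r.atoms]
    keys_f = [(r.chain_id, r.seq_number, r.insertion_code, a.name)
              for r in sel_f.residues for a in r.atoms]
    if keys_m != keys_f:
        only_m = sorted(set(keys_m) - set(keys_f))
        only_f = sorted(set(keys_f) - set(keys_m))
        raise ValueError(
            "selection does not pair: "
            f"only in moving: {only_m[:5]}; only in fixed: {only_f[:5]}")
    if not keys_m:
        raise ValueError("selection resolves to zero atoms")
    return kabsch(sel_m.coords(), sel_f.coords())
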