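"""Anchor-constrained placement of an asymmetric rigid ligand into a
Cn-symmetric receptor.

An asymmetric ligand bound to an n-fold symmetric receptor occupies n
statistically distinguishable but energetically equivalent orientations,
each at occupancy 1/n.  A marker atom on the ligand therefore appears as n
symmetry-related peaks (e.g. in an anomalous difference map).  Given sparse
marker observations, the placement problem is: choose one peak image per
marker (an assignment) and the rigid pose that best fits the chosen images.

Two modes are provided:
  * ``exhaustive`` — enumerate every assignment over candidate peak images
    and keep the one with minimal marker RMSD;
  * ``seeded`` — use an approximate initial pose to pick, for each marker,
    the nearest candidate image (the disambiguation used when a rough
    density-based placement is already available), then fit once.

Both the RMS and the literal sum-of-distances objectives are reported; the
minimizer is chosen by RMS, which has the Kabsch closed form.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_structures import RigidTransform, Structure, SymmetryGroup, apply_transform
from .superpose import kabsch

__all__ = [
    "MarkerSelector",
    "AnchorProblem",
    "PlacementResult",
    "filter_axis_peaks",
    "expand_peaks",
    "place_ligand",
    "cross_validate_copy",
]

DEFAULT_MIN_AXIS_DISTANCE = 2.0  # A; on-axis peaks are symmetry-reinforced noise
DEDUP_TOL = 0.5  # A; orbit-image deduplication against observed peaks


@dataclass(frozen=True)
class MarkerSelector:
    """Names one marker atom on the ligand: (id, chain, residue number, atom name)."""

    marker_id: str
    chain_id: str
    seq_number: int
    atom_name: str

    def resolve(self, ligand: Structure) -> np.ndarray:
        res = ligand.residue(self.chain_id, self.seq_number)
        return res.atom(self.atom_name).xyz


@dataclass
class AnchorProblem:
    ligand_model: Structure
    markers: list[MarkerSelector]
    peaks: list[np.ndarray]          # per-marker arrays of observed peak positions
    symmetry: SymmetryGroup
    peak_heights: list[np.ndarray] | None = None
    initial_pose: RigidTransform | None = None

    def __post_init__(self):
        if not self.markers:
            raise ValueError("at least one marker is required")
        if len(self.peaks) != len(self.markers):
            raise ValueError("one peak set per marker required")
        self.peaks = [np.atleast_2d(np.asarray(p, dtype=float)) for p in self.peaks]
        for m in self.markers:
            m.resolve(self.ligand_model)  # must resolve to exactly one atom

    def marker_positions(self) -> np.ndarray:
        return np.array([m.resolve(self.ligand_model) for m in self.markers])


@dataclass
class PlacementResult:
    best_assignment: list[int]
    pose: RigidTransform
    rmsd_markers: float
    sum_distances: float
    per_marker_residuals: np.ndarray
    equivalent_poses: list[RigidTransform]
    occupancy_per_pose: float
    diagnostics: dict = field(default_factory=dict)

    def apply(self, ligand: Structure, pose_index: int = 0) -> Structure:
        """Ligand model moved into the receptor frame by one equivalent pose."""
        return apply_transform(ligand, self.equivalent_poses[pose_index])


def filter_axis_peaks(peaks, symmetry: SymmetryGroup,
                      min_axis_distance: float = DEFAULT_MIN_AXIS_DISTANCE):
    """Drop peaks closer than min_axis_distance to the symmetry axis.

    Peaks on the axis of a cyclic map arise from n-fold reinforcement of
    noise (every noise feature near the axis is stacked onto itself by the
    symmetry) and must not be used as anchors.  Removal is reported, never
    silent: returns (kept, removed) arrays.
    """
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    d = symmetry.axis_distance(peaks)
    keep = d >= min_axis_distance
    kept, removed = peaks[keep], peaks[~keep]
    if len(kept) == 0 and len(peaks) > 0:
        warnings.warn("axis filter removed every peak")
    return kept, removed


def expand_peaks(peaks_per_marker, symmetry: SymmetryGroup,
                 dedup_tol: float = DEDUP_TOL):
    """Expand each observed peak to its full symmetry orbit.

    A single detected peak per marker still yields n candidate images, so
    the assignment search covers all orientations even when only one of the
    n symmetry-related peaks was observed.  Candidates = union of the orbits
    of all observed peaks, deduplicated within dedup_tol.
    """
    out = []
    for peaks in peaks_per_marker:
        peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
        candidates: list[np.ndarray] = []
        for p in peaks:
            for g in symmetry.elements:
                img = g.apply(p)
                if not any(np.linalg.norm(img - c) <= dedup_tol for c in candidates):
                    candidates.append(img)
        out.append(np.array(candidates))
    return out


def _fit_assignment(marker_xyz: np.ndarray, candidates, assignment) -> tuple:
    targets = np.array([candidates[i][j] for i, j in enumerate(assignment)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = kabsch(marker_xyz, targets)
    return res.rmsd, res


def place_ligand(problem: AnchorProblem, mode: str = "exhaustive",
                 min_axis_distance: float = DEFAULT_MIN_AXIS_DISTANCE,
                 filter_axis: bool = True) -> PlacementResult:
    """Fit the ligand pose from symmetry-ambiguous marker peaks.

    Exhaustive mode enumerates every per-marker choice of candidate image
    (product space) and returns the assignment with minimal marker RMSD.
    Seeded mode requires an initial pose and picks, per marker, the candidate
    image nearest the pose-predicted marker position, then fits once.  The
    result always carries all n symmetry-equivalent poses, each at occupancy
    1/n.
    """
    if mode not in ("exhaustive", "seeded"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "seeded" and problem.initial_pose is None:
        raise ValueError("seeded mode requires an initial_pose")
    n_markers = len(problem.markers)
    if n_markers < 3:
        warnings.warn(f"{n_markers} markers: pose is under-determined")

    diagnostics: dict = {"filtered_peaks": []}
    filtered = []
    for m, peaks in zip(problem.markers, problem.peaks):
        if filter_axis:
            kept, removed = filter_axis_peaks(peaks, problem.symmetry, min_axis_distance)
            if len(removed):
                diagnostics["filtered_peaks"].append(
                    {"marker": m.marker_id, "removed": removed.tolist()})
        else:
            kept = peaks
        if len(kept) == 0:
            raise ValueError(f"marker {m.marker_id!r}: no peaks remain after axis filtering")
        filtered.append(kept)

    candidates = expand_peaks(filtered, problem.symmetry)
    marker_xyz = problem.marker_positions()

    if mode == "exhaustive":
        best = None
        for assignment in itertools.product(*(range(len(c)) for c in candidates)):
            rmsd, res = _fit_assignment(marker_xyz, candidates, assignment)
            if best is None or rmsd < best[0]:
                best = (rmsd, list(assignment), res)
        rmsd, assignment, fit = best
        diagnostics["n_assignments"] = int(np.prod([len(c) for c in candidates]))
    else:
        predicted = problem.initial_pose.apply(marker_xyz)
        assignment = []
        for i, cand in enumerate(candidates):
            d = np.linalg.norm(cand - predicted[i], axis=1)
            j = int(np.argmin(d))
            ties = np.flatnonzero(np.isclose(d, d[j], atol=1e-9))
            if len(ties) > 1:
                warnings.warn(
                    f"marker {problem.markers[i].marker_id!r}: nearest-image tie, "
                    "taking lowest index")
                j = int(ties[0])
            assignment.append(j)
        rmsd, fit = _fit_assignment(marker_xyz, candidates, assignment)
        diagnostics["n_assignments"] = 1

    pose = fit.transform
    equivalent = [g.compose(pose) for g in problem.symmetry.elements]
    return PlacementResult(
        best_assignment=assignment,
        pose=pose,
        rmsd_markers=rmsd,
        sum_distances=float(np.sum(fit.per_point_residuals)),
        per_marker_residuals=fit.per_point_residuals,
        equivalent_poses=equivalent,
        occupancy_per_pose=1.0 / problem.symmetry.order,
        diagnostics=diagnostics,
    )


def cross_validate_copy(placed: PlacementResult, ligand: Structure,
                        copy_transform: RigidTransform,
                        probe: MarkerSelector, observed_peaks_copy,
                        symmetry: SymmetryGroup | None = None) -> dict:
    """Cross-validate a placement against an independent receptor copy.

    When the crystal contains two independent copies of the receptor, the
    pose fitted on copy A predicts where a probe atom (e.g. the sulfur of a
    marker methionine) should sit on copy B.  ``copy_transform`` maps copy A
    onto copy B; the report gives the distance from the predicted probe
    position to the nearest observed peak of copy B.  A small distance
    validates the placement; the threshold is left to the caller.
    """
    observed = np.atleast_2d(np.asarray(observed_peaks_copy, dtype=float))
    if len(observed) == 0:
        raise ValueError("no observed peaks for the receptor copy")
    probe_xyz = placed.pose.apply(probe.resolve(ligand))
    predicted = copy_transform.apply(probe_xyz)
    if symmetry is not None and symmetry.axis_distance(predicted) < 1e-6:
        warnings.warn("probe lies on the symmetry axis: all images coincide")
    d = np.linalg.norm(observed - predicted, axis=1)
    i = int(np.argmin(d))
    return {
        "predicted_position": predicted,
        "nearest_peak_index": i,
        "nearest_peak": observed[i],
        "distance": float(d[i]),
        "all_distances": d,
    }
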