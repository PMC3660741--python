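"""Selectivity-filter ion-site geometry and occupancy classification.

A K+ channel selectivity filter presents four stacked ion-binding cages,
S1 (most extracellular) through S4, each defined by two adjacent layers of
four backbone carbonyl oxygens (one per subunit).  The site center is the
midpoint of the two layer centroids.  Occupancy here is purely geometric —
an ion within a capture radius of a site center — never density-based.

The blocking toxin projects a lysine ammonium group toward S1: within
hydrogen-bonding range of all four oxygens of S1's extracellular half-cage,
it competes with a permeant ion for the site.  ``s1_competition_report``
summarizes that competition for the three study conditions: wild-type toxin
in K+ (S1 empty), Lys27Met in K+ (S1 partially occupied), wild-type in Cs+
(S1 occupied despite the toxin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_structures import SymmetryGroup

__all__ = [
    "Ion",
    "IonSiteModel",
    "OccupancyPattern",
    "build_sites",
    "classify_occupancy",
    "probe_coordination",
    "s1_competition_report",
    "CAPTURE_RADIUS",
    "HBOND_MAX",
]

CAPTURE_RADIUS = 1.5   # A, half the ~3 A inter-site spacing
HBOND_MAX = 3.5        # A


@dataclass
class Ion:
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)


@dataclass
class IonSiteModel:
    """S1-S4 site centers (S1 most extracellular) and their defining layers."""

    site_centers: np.ndarray        # (4, 3), ordered S1 -> S4
    layer_centroids: np.ndarray     # (5, 3), extracellular -> intracellular
    layer_oxygens: list[np.ndarray]  # per layer, (4, 3) subunit oxygens
    axis_direction: np.ndarray      # unit vector pointing extracellular

    def site_center(self, site: int) -> np.ndarray:
        """Center of site S<site>, site in 1..4."""
        if not 1 <= site <= 4:
            raise ValueError(f"site index {site} outside 1..4")
        return self.site_centers[site - 1]


@dataclass
class OccupancyPattern:
    occupied: list[bool]            # S1..S4
    ions_per_site: list[list[Ion]]  # assigned ions per site
    unassigned: list[Ion]

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return tuple(self.occupied)


def build_sites(layer_oxygens: list[np.ndarray],
                symmetry: SymmetryGroup) -> IonSiteModel:
    """Ion-site model from five carbonyl-oxygen layers of a C4 filter.

    Each layer must contain 4 symmetry-related oxygens (one per subunit).
    Layers may be supplied in any order; they are sorted by axial coordinate
    with the extracellular side (larger projection on the axis direction)
    first, so S1 is always the most extracellular cage.
    """
    if len(layer_oxygens) != 5:
        raise ValueError(f"expected 5 oxygen layers, got {len(layer_oxygens)}")
    layers = [np.atleast_2d(np.asarray(L, dtype=float)) for L in layer_oxygens]
    for i, L in enumerate(layers):
        if L.shape != (4, 3):
            raise ValueError(f"layer {i} has {L.shape[0]} oxygens, expected 4")
    u = symmetry.axis_direction
    centroids = np.array([L.mean(axis=0) for L in layers])
    z = centroids @ u
    order = np.argsort(-z)  # extracellular (high projection) first
    zs = z[order]
    if np.any(np.diff(zs) >= 0):
        raise ValueError("oxygen layers are not strictly ordered along the axis")
    layers = [layers[i] for i in order]
    centroids = centroids[order]
    centers = 0.5 * (centroids[:-1] + centroids[1:])
    return IonSiteModel(centers, centroids, layers, u)


def classify_occupancy(sites: IonSiteModel, ions: list[Ion],
                       capture_radius: float = CAPTURE_RADIUS) -> OccupancyPattern:
    """Assign each ion to its nearest site; occupied if within capture_radius.

    An ion is assigned to at most one site.  Two ions captured by the same
    site are both reported with a multiplicity warning.
    """
    if capture_radius < 0:
        raise ValueError("capture_radius must be non-negative")
    per_site: list[list[Ion]] = [[] for _ in range(4)]
    unassigned: list[Ion] = []
    for ion in ions:
        d = np.linalg.norm(sites.site_centers - ion.xyz, axis=1)
        k = int(np.argmin(d))
        if d[k] <= capture_radius:
            per_site[k].append(ion)
        else:
            unassigned.append(ion)
    for k, lst in enumerate(per_site):
        if len(lst) > 1:
            warnings.warn(f"site S{k+1} captured {len(lst)} ions")
    return OccupancyPattern([bool(lst) for lst in per_site], per_site, unassigned)


def probe_coordination(probe_xyz, sites: IonSiteModel, site: int,
                       hbond_max: float = HBOND_MAX) -> dict:
    """Distances from a probe atom to the extracellular half-cage of a site.

    Reports the four distances from the probe to the oxygens of the layer on
    the site's extracellular side (for S1, the oxygens that would form the
    top half of the coordination cage of an ion at S1) and how many fall
    within hbond_max.
    """
    if not 1 <= site <= 4:
        raise ValueError(f"site index {site} outside 1..4")
    if hbond_max < 0:
        raise ValueError("hbond_max must be non-negative")
    probe_xyz = np.asarray(probe_xyz, dtype=float)
    top_layer = sites.layer_oxygens[site - 1]  # layer on the extracellular side
    d = np.linalg.norm(top_layer - probe_xyz, axis=1)
    return {
        "distances": d,
        "n_within": int(np.sum((d <= hbond_max) & (hbond_max > 0))),
        "hbond_max": hbond_max,
    }


def s1_competition_report(probe_xyz, sites: IonSiteModel,
                          occupancy: OccupancyPattern,
                          hbond_max: float = HBOND_MAX) -> dict:
    """Side-by-side view of the probe (toxin lysine) and the S1 ion state.

    Flags the three study scenarios: a coordinating probe with S1 empty
    (wild-type toxin in K+), S1 partially occupied (Lys27Met, the S1 ion
    carrying a fractional occupancy), and S1 occupied despite the probe
    (Cs+, which out-competes the lysine for S1).
    """
    report: dict = {"occupancy": list(occupancy.flags)}
    s1_ions = occupancy.ions_per_site[0]
    s1_occ = max((i.occupancy for i in s1_ions), default=0.0)
    if probe_xyz is None:
        report["scenario"] = "free filter (no probe)"
        report["probe"] = None
        return report
    probe_xyz = np.asarray(probe_xyz, dtype=float)
    d_s1 = float(np.linalg.norm(probe_xyz - sites.site_center(1)))
    if d_s1 > 50.0:
        raise ValueError(f"probe is {d_s1:.0f} A from the filter: frame mismatch")
    coord = probe_coordination(probe_xyz, sites, 1, hbond_max)
    report["probe"] = {
        "distance_to_s1": d_s1,
        "coordination_count": coord["n_within"],
        "oxygen_distances": coord["distances"].tolist(),
    }
    coordinated = coord["n_within"] >= 3
    if not occupancy.flags[0]:
        report["scenario"] = ("S1 empty, probe coordinated" if coordinated
                              else "S1 empty, probe distant")
    elif s1_occ < 1.0:
        report["scenario"] = "S1 partially occupied"
    else:
        report["scenario"] = "S1 occupied despite probe"
    report["s1_ion_occupancy"] = s1_occ
    return report
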