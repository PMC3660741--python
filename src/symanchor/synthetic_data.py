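"""Generators emulating the inputs of the toxin-channel analysis chain.

Every generator is a pure function of (spec, seed) and produces the same
statistical/geometric structure as the experimental inputs — a C4 pore with
five carbonyl-oxygen layers defining sites S1-S4, a rigid 37-residue
toxin-like body carrying three marker atoms and a protruding lysine probe,
symmetry-ambiguous anchor peaks (each marker observed as its C4 orbit with
positional noise, optionally plus a spurious on-axis peak), ion-placement
scenarios for the three study conditions, and dose-response data drawn from
the blocking equation.  No sequence realism or real coordinates are
attempted; geometry only.

Noise conventions: ``noise_sd`` on peaks is the per-coordinate standard
deviation of isotropic Gaussian noise; ``noise_sd`` on structures is the
RMS atomic displacement (per-coordinate sd = noise_sd / sqrt(3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_kinetics import BlockingModel, DoseResponseData, unblocked_fraction
from .core_structures import (Atom, Residue, RigidTransform, Structure,
                              SymmetryGroup, apply_transform, make_cn_group)
from .pore_ions import Ion, IonSiteModel, build_sites
from .sequences import CTX_SEQUENCE
from .symmetric_placement import AnchorProblem, MarkerSelector

__all__ = [
    "ChannelSpec",
    "ToxinSpec",
    "ScenarioSpec",
    "gen_c4_channel",
    "gen_toxin",
    "gen_placement_problem",
    "gen_scenario",
    "gen_dose_response",
    "default_true_pose",
]

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# filter residue numbers carrying the five oxygen layers, most
# extracellular first (the channel's TVGYG-like run, author numbering)
_FILTER_RESIDUES = [(374, "GLY"), (373, "TYR"), (372, "GLY"), (371, "VAL"), (370, "THR")]
_LANDMARKS = {353: "GLN", 359: "ASP", 375: "ASP", 377: "VAL"}


@dataclass
class ChannelSpec:
    order: int = 4
    filter_ring_radius: float = 1.35     # A; K+-channel-like fixture constant
    filter_layer_z: tuple = (12.4, 9.3, 6.2, 3.1, 0.0)  # extracellular first
    shell_radius: float = 11.0
    n_shell_atoms: int = 80
    noise_sd: float = 0.0                # RMS atomic displacement, A

    def __post_init__(self):
        if self.order < 3:
            raise ValueError("channel symmetry order must be >= 3")
        if len(self.filter_layer_z) != 5:
            raise ValueError("exactly 5 filter oxygen layers required")
        z = list(self.filter_layer_z)
        if sorted(z, reverse=True) != z or len(set(z)) != 5:
            raise ValueError("filter layers must be strictly ordered, extracellular first")


@dataclass
class ToxinSpec:
    n_residues: int = 37
    marker_residues: tuple = (7, 14, 29)
    marker_atoms: tuple = ("SE", "I1", "SD")
    #: marker positions in the toxin local frame, A: ~16 A triangle with
    #: azimuths ~120 deg apart, which is maximally incompatible with the
    #: receptor's 90 deg rotations — no mixed set of C4 images of the three
    #: markers is near-congruent to the true triangle (worst-case image-swap
    #: fit leaves > 3 A RMSD), keeping the assignment search well conditioned.
    marker_positions: tuple = ((-8.0, -5.1, 1.0), (8.3, -4.3, 1.5), (-0.4, 9.2, 2.4))
    probe_residue: int = 27
    body_radius: float = 7.0
    probe_protrusion: float = 6.0        # NZ beyond the body surface, A
    sequence: str = CTX_SEQUENCE


@dataclass
class ScenarioSpec:
    scenario: str = "wt_K"               # wt_K | K27M_K | wt_Cs
    s1_fractional_occupancy: float = 0.3  # fixture value for K27M_K (arbitrary)

    def __post_init__(self):
        if self.scenario not in ("wt_K", "K27M_K", "wt_Cs"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi * i), r * np.sin(phi * i), z])


def gen_c4_channel(spec: ChannelSpec = ChannelSpec(), seed: int = 0,
                   ) -> tuple[Structure, SymmetryGroup, IonSiteModel]:
    """Cn-symmetric channel fixture: one protomer replicated by the group.

    The protomer carries five filter backbone oxygens (one per layer), named
    landmark residues on the extracellular turret, and a shell of CA atoms.
    Returns the structure, the construction symmetry group (axis = z through
    the origin) and the ground-truth ion-site model built from the noiseless
    layer positions.
    """
    rng = np.random.default_rng(seed)
    group = make_cn_group([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], spec.order)

    protomer: list[Residue] = []
    for (num, res_name), z in zip(_FILTER_RESIDUES, spec.filter_layer_z):
        xyz = np.array([spec.filter_ring_radius, 0.0, z])
        atoms = [Atom("O", "O", xyz),
                 Atom("CA", "C", xyz + np.array([2.5, 0.6, 0.0]))]
        protomer.append(Residue("A", num, res_name, atoms))

    turret_z = {353: 15.0, 359: 16.5, 375: 12.0, 377: 10.5}
    turret_r = {353: 13.0, 359: 15.5, 375: 6.5, 377: 5.0}
    side_atoms = {"GLN": [("NE2", "N"), ("OE1", "O")],
                  "ASP": [("OD1", "O"), ("OD2", "O")],
                  "VAL": [("CG1", "C")]}
    for num, res_name in sorted(_LANDMARKS.items()):
        r, z = turret_r[num], turret_z[num]
        base = np.array([r * np.cos(np.deg2rad(15 * (num % 4))),
                         r * np.sin(np.deg2rad(15 * (num % 4))), z])
        atoms = [Atom("CA", "C", base)]
        for i, (aname, el) in enumerate(side_atoms[res_name]):
            atoms.append(Atom(aname, el, base + np.array([0.8 * (i + 1), 0.5 * i, 0.9])))
        protomer.append(Residue("A", num, res_name, atoms))

    used = {n for n, _ in _FILTER_RESIDUES} | set(_LANDMARKS)
    shell_numbers = [n for n in range(321, 415) if n not in used][: spec.n_shell_atoms]
    t = np.linspace(0, 1, len(shell_numbers))
    theta = np.deg2rad(-40 + 80 * t) + 0.6 * np.sin(6 * np.pi * t)
    radius = spec.shell_radius + 2.5 * np.cos(4 * np.pi * t)
    zz = -4.0 + 18.0 * t
    for num, th, r, z in zip(shell_numbers, theta, radius, zz):
        protomer.append(Residue("A", num, "ALA",
                                [Atom("CA", "C", np.array([r * np.cos(th),
                                                           r * np.sin(th), z]))]))
    protomer.sort(key=lambda r: r.seq_number)

    residues: list[Residue] = []
    for ci, g in enumerate(group.elements):
        chain = chr(ord("A") + ci)
        for r in protomer:
            atoms = []
            for a in r.atoms:
                xyz = g.apply(a.xyz)
                if spec.noise_sd > 0:
                    xyz = xyz + rng.normal(0.0, spec.noise_sd / np.sqrt(3.0), 3)
                atoms.append(Atom(a.name, a.element, xyz))
            residues.append(Residue(chain, r.seq_number, r.res_name, atoms))
    channel = Structure(residues, id=f"c{spec.order}_channel")

    # ground-truth sites from the noiseless construction layers
    layers = []
    for z in spec.filter_layer_z:
        p0 = np.array([spec.filter_ring_radius, 0.0, z])
        layers.append(np.array([g.apply(p0) for g in group.elements[:4]])
                      if spec.order >= 4 else
                      np.array([g.apply(p0) for g in group.elements]))
    sites = build_sites(layers[:5], group) if spec.order == 4 else None
    return channel, group, sites


def gen_toxin(spec: ToxinSpec = ToxinSpec(), seed: int = 0) -> Structure:
    """Rigid toxin-like body: 37 CA atoms on a compact shell, three marker
    atoms, a cysteine-like scaffold and a probe lysine with protruding NZ.

    The geometry is deterministic given the spec; the seed only jitters the
    CA shell slightly so distinct toxin instances are distinguishable.
    Marker positions are seed-independent (reproducible marker triangle).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    mpos = np.asarray(spec.marker_positions, dtype=float)
    if len(mpos) >= 3:
        s = np.linalg.svd(mpos - mpos.mean(axis=0), compute_uv=False)
        if s[1] < 1e-6 * max(s[0], 1.0):
            raise ValueError("marker positions are collinear")
    ca = _fibonacci_sphere(n, spec.body_radius)
    # rotate so the probe residue's CA sits at the -z pole (pore-facing)
    probe_idx = spec.probe_residue - 1
    v = ca[probe_idx] / np.linalg.norm(ca[probe_idx])
    target = np.array([0.0, 0.0, -1.0])
    axis = np.cross(v, target)
    s, cth = np.linalg.norm(axis), float(v @ target)
    if s > 1e-12:
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]]) / s
        R = np.eye(3) + s * K + (1 - cth) * (K @ K)
        ca = ca @ R.T

    residues = []
    markers = dict(zip(spec.marker_residues, spec.marker_atoms))
    for i in range(n):
        num = i + 1
        aa = spec.sequence[i] if i < len(spec.sequence) else "A"
        res_name = _AA3.get(aa, "ALA")
        if num == spec.probe_residue and spec.sequence[i] != "K":
            res_name = _AA3.get(spec.sequence[i], "MET")
        xyz = ca[i] + rng.normal(0.0, 0.05, 3)
        atoms = [Atom("CA", "C", xyz)]
        if num in markers:
            # fixed, seed-independent marker position (reproducible triangle)
            midx = spec.marker_residues.index(num)
            el = {"SE": "SE", "I1": "I", "SD": "S"}.get(markers[num], "C")
            atoms.append(Atom(markers[num], el,
                              np.array(spec.marker_positions[midx], dtype=float)))
        if num == spec.probe_residue:
            tip = ca[i] + np.array([0.0, 0.0, -spec.probe_protrusion])
            atoms.append(Atom("NZ", "N", tip))
        residues.append(Residue("T", num, res_name, atoms))
    return Structure(residues, id="toxin")


def default_true_pose(channel_spec: ChannelSpec = ChannelSpec(),
                      toxin_spec: ToxinSpec = ToxinSpec(),
                      azimuth_deg: float = 25.0, tilt_deg: float = 5.0,
                      probe_height: float = 2.0) -> RigidTransform:
    """Pose placing the toxin at the pore mouth, probe NZ over the filter.

    The NZ tip ends up on the axis, `probe_height` A extracellular of the
    top oxygen layer; the body is rotated about the pore axis by
    `azimuth_deg` (the binding orientation is arbitrary) and tilted by
    `tilt_deg` so nothing is accidentally axial.
    """
    z_top = channel_spec.filter_layer_z[0]
    nz_local = np.array([0.0, 0.0, -(toxin_spec.body_radius + toxin_spec.probe_protrusion)])
    a, t = np.deg2rad(azimuth_deg), np.deg2rad(tilt_deg)
    Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    R = Rz @ Rx
    target_nz = np.array([0.0, 0.0, z_top + probe_height])
    trans = target_nz - R @ nz_local
    return RigidTransform(R, trans)


def gen_placement_problem(channel_spec: ChannelSpec = ChannelSpec(),
                          toxin_spec: ToxinSpec = ToxinSpec(),
                          true_pose: RigidTransform | None = None,
                          noise_sd: float = 0.0,
                          spurious_axis_peak: bool = False,
                          peaks_per_marker: str = "orbit",
                          seed: int = 0) -> tuple[AnchorProblem, dict]:
    """Symmetry-ambiguous anchor problem with known ground truth.

    Peaks = the full C4 orbit of each true (posed) marker position, plus
    isotropic Gaussian noise of per-coordinate sd `noise_sd` on every peak,
    plus (optionally) one spurious peak on the symmetry axis — the
    reinforced-noise artifact.  Returns the problem and a ground-truth dict
    with the generating pose and noiseless marker positions.

    ``peaks_per_marker="single"`` records only one randomly chosen member of
    each marker's orbit (the disambiguated-peak situation); the placement
    search then recovers the other orientations by orbit expansion, giving
    exactly n candidate images per marker.  This is the configuration under
    which marker-RMSD statistics are calibrated: with the full noisy orbit
    observed, the exhaustive minimum can mix independently noisy images of
    different peaks and its RMSD is biased low.
    """
    if peaks_per_marker not in ("orbit", "single"):
        raise ValueError(f"unknown peaks_per_marker {peaks_per_marker!r}")
    rng = np.random.default_rng(seed)
    channel, group, _ = gen_c4_channel(channel_spec, seed=seed)
    toxin = gen_toxin(toxin_spec, seed=seed)
    if true_pose is None:
        true_pose = default_true_pose(channel_spec, toxin_spec,
                                      azimuth_deg=float(rng.uniform(0, 360)))
    posed = apply_transform(toxin, true_pose)
    # pore-mouth sanity: probe tip must sit extracellular of the filter top
    nz = posed.residue("T", toxin_spec.probe_residue).atom("NZ").xyz
    z_top = channel_spec.filter_layer_z[0]
    if nz[2] < z_top - 1.0 or group.axis_distance(nz) > 10.0:
        raise ValueError("pose does not place the toxin at the pore mouth")
    # clash check against the receptor body
    ch_xyz = channel.coords()
    tx_xyz = posed.coords()
    dmin = np.sqrt(((tx_xyz[:, None, :] - ch_xyz[None, :, :]) ** 2).sum(-1)).min()
    if dmin < 1.0:
        raise ValueError(f"pose clashes with the receptor (min distance {dmin:.2f} A)")

    markers = [MarkerSelector(f"m{num}", "T", num, atom)
               for num, atom in zip(toxin_spec.marker_residues, toxin_spec.marker_atoms)]
    true_marker_xyz = np.array([m.resolve(posed) for m in markers])
    peaks = []
    for xyz in true_marker_xyz:
        images = np.array([g.apply(xyz) for g in group.elements])
        if noise_sd > 0:
            images = images + rng.normal(0.0, noise_sd, images.shape)
        if peaks_per_marker == "single":
            images = images[rng.integers(0, len(images)):][:1]
        if spurious_axis_peak:
            images = np.vstack([images, [0.0, 0.0, z_top + rng.uniform(2.0, 6.0)]])
        peaks.append(images)

    problem = AnchorProblem(gen_toxin(toxin_spec, seed=seed), markers, peaks, group)
    truth = {
        "pose": true_pose,
        "marker_positions": true_marker_xyz,
        "n_spurious": int(spurious_axis_peak) * len(markers),
        "channel": channel,
        "group": group,
    }
    return problem, truth


def gen_scenario(spec: ScenarioSpec = ScenarioSpec(), seed: int = 0) -> dict:
    """One of the three study conditions, with expected occupancy pattern.

    wt_K:    toxin probe coordinating S1's top layer; K+ at S2, S3, S4.
    K27M_K:  shortened probe (methionine-like); K+ at all four sites, the
             S1 ion carrying the fixture fractional occupancy.
    wt_Cs:   toxin probe present; three Cs+ ions at S1, S3, S4.
    """
    channel_spec = ChannelSpec()
    channel, group, sites = gen_c4_channel(channel_spec, seed=seed)
    toxin_spec = ToxinSpec()
    if spec.scenario == "K27M_K":
        # methionine side chain is ~2 A shorter than lysine: probe retracts
        toxin_spec = ToxinSpec(probe_protrusion=4.0)
    toxin = gen_toxin(toxin_spec, seed=seed)
    pose = default_true_pose(channel_spec, toxin_spec)
    posed = apply_transform(toxin, pose)

    if spec.scenario == "wt_K":
        ions = [Ion("K", sites.site_center(k)) for k in (2, 3, 4)]
        expected = (False, True, True, True)
    elif spec.scenario == "K27M_K":
        ions = [Ion("K", sites.site_center(1), occupancy=spec.s1_fractional_occupancy)]
        ions += [Ion("K", sites.site_center(k)) for k in (2, 3, 4)]
        expected = (True, True, True, True)
    else:  # wt_Cs
        ions = [Ion("CS", sites.site_center(k)) for k in (1, 3, 4)]
        expected = (True, False, True, True)
    return {
        "channel": channel,
        "group": group,
        "sites": sites,
        "toxin": posed,
        "probe_xyz": posed.residue("T", toxin_spec.probe_residue).atom("NZ").xyz,
        "ions": ions,
        "expected_pattern": expected,
        "scenario": spec.scenario,
    }


def gen_dose_response(true_kd: float, concentrations, noise_sd: float = 0.02,
                      n_replicates: int = 3, seed: int = 0) -> DoseResponseData:
    """Dose-response observations drawn from the blocking equation.

    Per-replicate fractions = model value + Gaussian noise (sd in fraction
    units), truncated to > 0; the returned data carry replicate means and
    SEMs.  Bit-for-bit reproducible for a given seed.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("need at least one concentration")
    if true_kd <= 0:
        raise ValueError("true Kd must be positive")
    rng = np.random.default_rng(seed)
    model = BlockingModel(true_kd)
    clean = unblocked_fraction(concentrations, model)
    reps = clean[:, None] + rng.normal(0.0, noise_sd, (len(concentrations), n_replicates))
    reps = np.maximum(reps, 1e-6)
    means = reps.mean(axis=1)
    sem = reps.std(axis=1, ddof=1) / np.sqrt(n_replicates) if n_replicates > 1 else None
    return DoseResponseData(concentrations, means, sem,
                            np.full(len(concentrations), n_replicates))
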