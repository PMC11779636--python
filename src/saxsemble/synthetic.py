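"""Ground-truth-known synthetic data emulating a heterogeneous RNA ensemble.

The generators produce the inputs every other module consumes, at the
physical scale of a large two-domain RNA: multi-class conformer ensembles
with a rigid core and flexible peripheral arms whose inter-domain opening
differs by class (radius of gyration spread ≈ 46–58 Å), noisy mixture SAXS
curves with known volume fractions, rank-controlled single-mode ensembles
for exercising PCA, and multiple alignments whose per-column conservation
is statistically coupled to per-residue flexibility.

Every generator is deterministic given its seed and returns the ground
truth needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import MultipleAlignment
from .structures import Conformer, ConformerEnsemble

__all__ = [
    "SyntheticEnsembleSpec",
    "default_study_spec",
    "generate_hinge_ensemble",
    "synthesize_mixture_profile",
    "generate_mode_ensemble",
    "generate_coupled_msa",
]

_BASES = np.array(["A", "C", "G", "U"])


@dataclass(frozen=True)
class ClassParams:
    """Hinge geometry of one conformer class."""

    hinge_mean_deg: float
    hinge_sd_deg: float
    arm_jitter: float  # isotropic Cartesian jitter on arm beads, Å


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Blueprint of a two-domain hinge ensemble.

    ``core_range`` residues form the rigid body (identical across members);
    each arm is a residue interval hinged at an attachment residue inside
    the core.  Classes differ in mean hinge opening of the first arm.
    """

    n_residues: int = 400
    core_range: tuple[int, int] = (131, 270)
    arm_definitions: tuple[tuple[tuple[int, int], int], ...] = (
        ((1, 130), 131),
        ((271, 400), 270),
    )
    class_params: tuple[ClassParams, ...] = (
        ClassParams(0.0, 4.0, 1.0),      # compact, Rg ≈ 48 Å
        ClassParams(-65.0, 4.0, 1.0),    # partially open, Rg ≈ 53 Å
        ClassParams(-140.0, 4.0, 1.0),   # extended, Rg ≈ 57 Å
    )
    class_counts: tuple[int, ...] = (32, 118, 8)
    bead_spacing: float = 5.9
    arm_helix_radius: float = 9.0
    arm_helix_pitch: float = 8.2
    core_helix_radius: float = 13.0
    core_helix_pitch: float = 3.0
    #: unit-ish direction each arm leaves the core along in the closed state
    arm_directions: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.3),
        (0.6, 0.8, -0.2),
        (0.0, 1.0, 0.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        intervals = [self.core_range] + [iv for iv, _ in self.arm_definitions]
        covered: set[int] = set()
        for lo, hi in intervals:
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"interval {lo}..{hi} outside 1..{self.n_residues}")
            block = set(range(lo, hi + 1))
            if covered & block:
                raise ValueError("residue intervals overlap")
            covered |= block
        if len(self.class_params) != len(self.class_counts):
            raise ValueError("one parameter set per class count required")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be nonnegative")
        for p in self.class_params:
            if p.hinge_sd_deg < 0 or p.arm_jitter < 0:
                raise ValueError("sd and jitter must be nonnegative")


def default_study_spec(seed: int = 0) -> SyntheticEnsembleSpec:
    """The study-scale default: 158 conformers in 3 classes (32/118/8)."""
    return SyntheticEnsembleSpec(seed=seed)


def _helix_points(n: int, radius: float, pitch: float, spacing: float) -> np.ndarray:
    """n beads on a helix along +z with the given bead-to-bead contour spacing."""
    circumference_term = np.sqrt((2 * np.pi * radius) ** 2 + pitch**2)
    dtheta = 2 * np.pi * spacing / circumference_term
    theta = np.arange(n) * dtheta
    z = theta / (2 * np.pi) * pitch
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _base_structure(spec: SyntheticEnsembleSpec) -> tuple[np.ndarray, dict]:
    """Deterministic base coordinates (closed state, hinge angle 0) plus layout."""
    coords = np.zeros((spec.n_residues, 3))
    lo, hi = spec.core_range
    n_core = hi - lo + 1
    core = _helix_points(n_core, spec.core_helix_radius, spec.core_helix_pitch, spec.bead_spacing)
    core -= core.mean(axis=0)
    coords[lo - 1 : hi] = core

    layout = {"arms": []}
    directions = [np.array(d, dtype=float) for d in spec.arm_directions]
    for a, ((alo, ahi), attach) in enumerate(spec.arm_definitions):
        n_arm = ahi - alo + 1
        arm_local = _helix_points(n_arm, spec.arm_helix_radius, spec.arm_helix_pitch, spec.bead_spacing)
        # orient the helix axis (+z) along the arm direction and root it at
        # the attachment bead, offset by one spacing
        d = directions[a % len(directions)]
        d = d / np.linalg.norm(d)
        zhat = np.array([0.0, 0.0, 1.0])
        v = np.cross(zhat, d)
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3) if d @ zhat > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            rot = _rotation_about_axis(v, np.arccos(np.clip(zhat @ d, -1, 1)))
        attach_xyz = coords[attach - 1]
        arm = (arm_local - arm_local[0]) @ rot.T + attach_xyz + d * spec.bead_spacing
        # residues in an arm run toward the core terminus: order beads so the
        # bead adjacent to the attachment is the interval end nearest it
        if abs(alo - attach) > abs(ahi - attach):
            arm = arm[::-1]
        coords[alo - 1 : ahi] = arm
        # hinge axis: perpendicular to both the arm direction and z
        axis = np.cross(d, zhat)
        if np.linalg.norm(axis) < 1e-12:
            axis = np.array([1.0, 0.0, 0.0])
        layout["arms"].append(
            {"interval": (alo, ahi), "attach_xyz": attach_xyz, "hinge_axis": axis}
        )
    return coords, layout


def generate_hinge_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[ConformerEnsemble, dict]:
    """Generate a multi-class two-domain hinge ensemble with known truth.

    Core beads are identical across members; the first arm is rotated about
    its attachment point by a class-specific hinge angle (mean ± sd per
    member), remaining arms get only jitter.  Returns the ensemble and a
    truth dict with per-member class labels, core residues, and per-member
    hinge angles.
    """
    rng = np.random.default_rng(spec.seed)
    base, layout = _base_structure(spec)
    lo, hi = spec.core_range
    core_residues = np.arange(lo, hi + 1)
    resnums = np.arange(1, spec.n_residues + 1)

    members: list[Conformer] = []
    labels: list[int] = []
    angles: list[float] = []
    idx = 0
    for ci, (params, count) in enumerate(zip(spec.class_params, spec.class_counts)):
        for _ in range(count):
            coords = base.copy()
            angle = np.deg2rad(params.hinge_mean_deg + params.hinge_sd_deg * rng.standard_normal())
            if layout["arms"]:
                arm0 = layout["arms"][0]
                alo, ahi = arm0["interval"]
                rot = _rotation_about_axis(arm0["hinge_axis"], angle)
                pivot = arm0["attach_xyz"]
                coords[alo - 1 : ahi] = (coords[alo - 1 : ahi] - pivot) @ rot.T + pivot
            if params.arm_jitter > 0:
                for arm in layout["arms"]:
                    alo, ahi = arm["interval"]
                    coords[alo - 1 : ahi] += params.arm_jitter * rng.standard_normal(
                        (ahi - alo + 1, 3)
                    )
            members.append(
                Conformer(id=f"S{idx + 1:03d}", residue_numbers=resnums, coords=coords)
            )
            labels.append(ci)
            angles.append(float(np.rad2deg(angle)))
            idx += 1
    if len(members) < 2:
        raise ValueError("class counts must produce at least 2 members")
    ensemble = ConformerEnsemble(members)
    truth = {
        "class_labels": np.array(labels),
        "core_residues": core_residues,
        "hinge_angles_deg": np.array(angles),
        "seed": spec.seed,
    }
    return ensemble, truth


def synthesize_mixture_profile(
    component_profiles: Sequence,
    fractions: Sequence[float],
    noise_fraction: float = 0.01,
    seed: int = 0,
    label: str = "mixture",
):
    """Noisy mixture curve: I = Σ f_i·I_i with multiplicative Gaussian noise.

    The σ column is set to the true noise level (noise_fraction · I).  The
    inverse of the volume-fraction model, used to create experiments with
    known ground truth.
    """
    from .saxs import ScatteringProfile  # local import avoids a cycle

    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {fractions.sum()})")
    if len(fractions) != len(component_profiles):
        raise ValueError("one fraction per component required")
    q = component_profiles[0].q
    for p in component_profiles[1:]:
        if not np.array_equal(p.q, q):
            raise ValueError("component profiles must share one q grid")
    ideal = np.sum([f * p.intensity for f, p in zip(fractions, component_profiles)], axis=0)
    rng = np.random.default_rng(seed)
    noisy = ideal * (1.0 + noise_fraction * rng.standard_normal(len(q)))
    sigma = np.maximum(noise_fraction * np.abs(ideal), 1e-12)
    return ScatteringProfile(q=q, intensity=noisy, sigma=sigma, label=label)


def generate_mode_ensemble(
    base: Conformer,
    mode_vector: np.ndarray,
    amplitudes: Sequence[float],
    jitter: float = 0.0,
    seed: int = 0,
) -> ConformerEnsemble:
    """Ensemble displaced along one fixed 3N mode with optional isotropic jitter.

    member_m = base + amplitude_m · mode (+ N(0, jitter²) per coordinate).
    With zero jitter the ensemble is exactly rank one, so its first
    principal component is the mode.
    """
    mode = np.asarray(mode_vector, dtype=float)
    n = base.n_residues
    if mode.shape not in {(3 * n,), (n, 3)}:
        raise ValueError(f"mode vector must have 3N = {3 * n} entries")
    mode = mode.reshape(n, 3)
    rng = np.random.default_rng(seed)
    members = []
    for m, amp in enumerate(amplitudes):
        coords = base.coords + amp * mode
        if jitter > 0:
            coords = coords + jitter * rng.standard_normal((n, 3))
        members.append(
            Conformer(id=f"mode{m:03d}", residue_numbers=base.residue_numbers, coords=coords)
        )
    return ConformerEnsemble(members)


def generate_coupled_msa(
    flex_profile: np.ndarray,
    n_sequences: int = 100,
    coupling: float = -1.0,
    seed: int = 0,
    max_substitution: float = 0.75,
    planted_anticorrelated: Sequence[int] = (),
) -> tuple[MultipleAlignment, dict]:
    """Alignment whose column variability is coupled to per-residue flexibility.

    ``coupling`` in [−1, 1] sets the induced correlation between sequence
    conservation and flexibility: −1 makes the most flexible residues the
    most variable (so conservation tracks rigidity and SCS correlates
    positively with 3DCS), +1 the reverse, 0 uniform variability.
    Residue indices in ``planted_anticorrelated`` (0-based positions into
    ``flex_profile``) are forced fully conserved regardless of flexibility —
    planted high-SCS/low-3DCS outliers.  Returns the alignment plus ground
    truth (per-column substitution probability and consensus).
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    flex = np.asarray(flex_profile, dtype=float)
    if flex.size < 1 or n_sequences < 2:
        raise ValueError("need a flexibility profile and at least 2 sequences")
    span = np.ptp(flex)
    f = (flex - flex.min()) / span if span > 0 else np.full_like(flex, 0.5)
    # mutation level in [0, 1]: coupling −1 → level = f (flexible mutate more)
    level = 0.5 - 0.5 * coupling * (2.0 * f - 1.0)
    sub_prob = max_substitution * level
    planted = np.asarray(list(planted_anticorrelated), dtype=int)
    if planted.size:
        sub_prob[planted] = 0.0

    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=flex.size)
    rows = np.tile(consensus, (n_sequences, 1))
    mutate = rng.random((n_sequences, flex.size)) < sub_prob[None, :]
    random_bases = rng.integers(0, 4, size=rows.shape)
    rows = np.where(mutate, random_bases, rows)
    seqs = tuple("".join(_BASES[r]) for r in rows)
    ids = tuple(f"seq{i + 1:03d}" for i in range(n_sequences))
    msa = MultipleAlignment(ids=ids, rows=seqs)
    truth = {
        "substitution_probability": sub_prob,
        "consensus": "".join(_BASES[consensus]),
        "planted_anticorrelated": planted,
        "seed": seed,
    }
    return msa, truth
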