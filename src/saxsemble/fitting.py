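"""Volume-fraction deconvolution of an experimental SAXS curve.

The experimental intensity is modelled as a linear combination of conformer
profiles,

    I_total(q) = Σ_i ν_i · I_i(q),   0 ≤ ν_i ≤ 1,  Σ ν_i = 1,

with one global scale absorbing units.  The weights are found by bounded
least squares (trust-region reflective) against the error-weighted
experimental curve.  On top of the single fit sit: cosine-distance
classification of conformer profiles against labelled references, the
randomized combination χ² study (repeated fits of k random members per
class), a compact genetic-algorithm subensemble selector, and population
tracking across a titration series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .saxs import ScatteringProfile, reduced_chi2

__all__ = [
    "VolumeFractionFit",
    "ClassAssignment",
    "CombinationStudyResult",
    "fit_volume_fractions",
    "classify_by_cosine",
    "combination_chi2_study",
    "ga_subensemble_select",
    "titration_population_series",
]


@dataclass(frozen=True)
class VolumeFractionFit:
    """Result of one volume-fraction deconvolution.

    ``nu`` are the normalized volume fractions (sum to 1), ``scale`` the
    global intensity scale, ``chi2`` the reduced χ² of the fitted total
    curve against the experimental one, ``identifiable`` is False when the
    candidate profiles are numerically rank-deficient (e.g. duplicates), in
    which case only sums of fractions over degenerate groups are meaningful.
    """

    member_ids: tuple[str, ...]
    nu: np.ndarray
    scale: float
    chi2: float
    fitted_total: ScatteringProfile
    identifiable: bool = True

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float)
        object.__setattr__(self, "nu", nu)
        if len(nu) != len(self.member_ids):
            raise ValueError("one fraction per member id required")
        if abs(nu.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if self.chi2 < 0:
            raise ValueError("chi2 must be nonnegative")

    def as_dict(self) -> dict:
        return {
            "member_ids": list(self.member_ids),
            "nu": [float(v) for v in self.nu],
            "scale": self.scale,
            "chi2": self.chi2,
            "identifiable": self.identifiable,
        }


@dataclass(frozen=True)
class ClassAssignment:
    """Per-conformer class labels from nearest-reference cosine distance."""

    member_ids: tuple[str, ...]
    labels: tuple[str, ...]
    distances: pd.DataFrame  # rows: members, columns: reference labels
    threshold: float

    def members_of(self, label: str) -> list[str]:
        return [m for m, l in zip(self.member_ids, self.labels) if l == label]

    @property
    def class_labels(self) -> list[str]:
        return list(self.distances.columns)


@dataclass(frozen=True)
class CombinationStudyResult:
    """χ² samples of randomized k-per-class combination fits.

    ``samples`` maps k → array of χ² values (one per round); ``summary`` is
    a table of mean µ, s.d. σ and minimum per k.
    """

    samples: dict[int, np.ndarray]
    summary: pd.DataFrame
    rounds: int
    seed: int


def _common_grid_matrix(
    profiles: Sequence[ScatteringProfile], experimental: ScatteringProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate candidates onto the experimental grid over the q overlap."""
    qlo = max(p.q.min() for p in profiles)
    qhi = min(p.q.max() for p in profiles)
    mask = (experimental.q >= qlo - 1e-12) & (experimental.q <= qhi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("no usable q overlap between candidates and experimental curve")
    q = experimental.q[mask]
    a = np.column_stack([np.interp(q, p.q, p.intensity) for p in profiles])
    return q, a, experimental.intensity[mask], experimental.effective_sigma()[mask]


def fit_volume_fractions(
    candidate_profiles: Sequence[ScatteringProfile],
    experimental: ScatteringProfile,
) -> VolumeFractionFit:
    """Fit experimental SAXS as a bounded linear combination of candidates.

    Solves min_w || (I_exp − Σ w_i I_i)/σ ||² with w_i ∈ [0, 1] by the
    trust-region reflective bounded least-squares solver; the reported
    fractions are ν_i = w_i / Σ w_i and the global scale is Σ w_i.
    Deterministic given inputs.
    """
    if len(candidate_profiles) < 1:
        raise ValueError("need at least one candidate profile")
    q, a, i_exp, sig = _common_grid_matrix(candidate_profiles, experimental)
    aw = a / sig[:, None]
    bw = i_exp / sig
    res = lsq_linear(aw, bw, bounds=(0.0, np.inf), method="trf", tol=1e-12)
    w = res.x
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("degenerate fit: all weights zero (is the experimental curve zero?)")
    # rank deficiency => fraction split within a degenerate group is arbitrary
    identifiable = np.linalg.matrix_rank(aw, tol=1e-8 * np.linalg.norm(aw)) == a.shape[1]
    nu = w / total_w
    fitted = ScatteringProfile(q=q, intensity=a @ w, label="I_total")
    k = len(q)
    chi2 = float(np.sum(((i_exp - a @ w) / sig) ** 2) / (k - 1))
    return VolumeFractionFit(
        member_ids=tuple(p.label for p in candidate_profiles),
        nu=nu,
        scale=float(total_w),
        chi2=chi2,
        fitted_total=fitted,
        identifiable=bool(identifiable),
    )


def classify_by_cosine(
    candidate_profiles: Sequence[ScatteringProfile],
    reference_profiles: Sequence[ScatteringProfile],
    threshold: float = 0.1,
) -> ClassAssignment:
    """Assign each candidate to its nearest reference by cosine distance.

    Distance is 1 − cosine similarity of the raw intensity vectors over the
    reference q grid, so the assignment is invariant to per-profile positive
    scaling.  Candidates farther than ``threshold`` from every reference are
    labelled ``"unassigned"``.  Ties break in reference order.
    """
    if not reference_profiles:
        raise ValueError("need at least one reference profile")
    q = reference_profiles[0].q
    ref_vecs = []
    for r in reference_profiles:
        v = r.interpolated_to(q).intensity if not np.array_equal(r.q, q) else r.intensity
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"reference {r.label!r} has zero-norm intensity")
        ref_vecs.append(v / norm)
    ref_mat = np.array(ref_vecs)

    labels, rows = [], []
    for c in candidate_profiles:
        v = c.interpolated_to(q).intensity if not np.array_equal(c.q, q) else c.intensity
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"candidate {c.label!r} has zero-norm intensity")
        dist = 1.0 - ref_mat @ (v / norm)
        rows.append(dist)
        best = int(np.argmin(dist))
        labels.append(reference_profiles[best].label if dist[best] <= threshold else "unassigned")
    frame = pd.DataFrame(
        rows,
        index=[c.label for c in candidate_profiles],
        columns=[r.label for r in reference_profiles],
    )
    return ClassAssignment(
        member_ids=tuple(c.label for c in candidate_profiles),
        labels=tuple(labels),
        distances=frame,
        threshold=threshold,
    )


def combination_chi2_study(
    assignment: ClassAssignment,
    profiles: dict[str, ScatteringProfile],
    experimental: ScatteringProfile,
    counts_per_class: Sequence[int] = (1, 2, 3, 5, 10, 20, 50),
    rounds: int = 10_000,
    seed: int = 0,
) -> CombinationStudyResult:
    """Randomized combination χ² study.

    For each k in ``counts_per_class`` and each of ``rounds`` rounds, draw k
    members per class uniformly without replacement (classes smaller than k
    contribute all their members), fit volume fractions for the drawn
    subset, and record the reduced χ².  Fully reproducible from ``seed``.
    """
    by_class = {
        label: assignment.members_of(label) for label in assignment.class_labels
    }
    for label, ids in by_class.items():
        if not ids:
            raise ValueError(f"class {label!r} is empty")
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    for k in counts_per_class:
        chi2s = np.empty(rounds)
        for r in range(rounds):
            chosen: list[str] = []
            for ids in by_class.values():
                if len(ids) <= k:
                    chosen.extend(ids)
                else:
                    idx = rng.choice(len(ids), size=k, replace=False)
                    chosen.extend(ids[i] for i in idx)
            fit = fit_volume_fractions([profiles[i] for i in chosen], experimental)
            chi2s[r] = fit.chi2
        samples[int(k)] = chi2s
    summary = pd.DataFrame(
        {
            "k": list(samples),
            "mean": [s.mean() for s in samples.values()],
            "sd": [s.std(ddof=1) if len(s) > 1 else 0.0 for s in samples.values()],
            "min": [s.min() for s in samples.values()],
        }
    ).set_index("k")
    return CombinationStudyResult(samples=samples, summary=summary, rounds=rounds, seed=seed)


def ga_subensemble_select(
    pool_profiles: Sequence[ScatteringProfile],
    experimental: ScatteringProfile,
    generations: int = 100,
    ensembles_per_generation: int = 50,
    max_per_ensemble: int = 50,
    seed: int = 0,
    rg_by_id: dict[str, float] | None = None,
) -> dict:
    """Genetic-algorithm subensemble selection (compact EOM-style search).

    Chromosomes are membership bitmasks over the pool (1–``max_per_ensemble``
    members); fitness is the reduced χ² of the volume-fraction fit of the
    selected subset.  Tournament selection (size 2), single-point crossover
    and per-gene mutation at rate 1/L.  Seeded and reproducible; the best
    subensemble's χ² can never exceed the best single-candidate χ² because
    all singletons are seeded into the initial population.
    """
    if len(pool_profiles) < 2:
        raise ValueError("pool must hold at least 2 profiles")
    rng = np.random.default_rng(seed)
    L = len(pool_profiles)
    cache: dict[bytes, float] = {}

    def score(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            subset = [p for p, m in zip(pool_profiles, mask) if m]
            cache[key] = fit_volume_fractions(subset, experimental).chi2
        return cache[key]

    def clip(mask: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(mask)
        if len(on) == 0:
            mask = mask.copy()
            mask[rng.integers(L)] = True
        elif len(on) > max_per_ensemble:
            off = rng.choice(on, size=len(on) - max_per_ensemble, replace=False)
            mask = mask.copy()
            mask[off] = False
        return mask

    # initial population: all singletons plus random masks
    pop: list[np.ndarray] = []
    for i in range(min(L, ensembles_per_generation)):
        m = np.zeros(L, dtype=bool)
        m[i] = True
        pop.append(m)
    while len(pop) < ensembles_per_generation:
        pop.append(clip(rng.random(L) < min(0.5, max_per_ensemble / L)))

    best_mask, best_chi2 = None, np.inf
    for _ in range(generations):
        fitness = np.array([score(m) for m in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_chi2:
            best_chi2 = float(fitness[gen_best])
            best_mask = pop[gen_best].copy()
        children = [best_mask.copy()]  # elitism
        while len(children) < ensembles_per_generation:
            # tournament selection, size 2
            parents = []
            for _ in range(2):
                a, b = rng.integers(len(pop), size=2)
                parents.append(pop[a] if fitness[a] <= fitness[b] else pop[b])
            point = rng.integers(1, L)
            child = np.concatenate([parents[0][:point], parents[1][point:]])
            flip = rng.random(L) < 1.0 / L
            child = clip(child ^ flip)
            children.append(child)
        pop = children
    fitness = np.array([score(m) for m in pop])
    gen_best = int(np.argmin(fitness))
    if fitness[gen_best] < best_chi2:
        best_chi2 = float(fitness[gen_best])
        best_mask = pop[gen_best].copy()

    selected = [p.label for p, m in zip(pool_profiles, best_mask) if m]
    rgs = None
    if rg_by_id is not None:
        rgs = [rg_by_id[i] for i in selected if i in rg_by_id]
    return {"selected_ids": selected, "chi2": best_chi2, "rg_selected": rgs, "seed": seed}


def titration_population_series(
    experimental_series: Sequence[ScatteringProfile],
    reference_profiles: Sequence[ScatteringProfile],
) -> pd.DataFrame:
    """Per-condition class populations across a titration series.

    Each experimental curve is deconvolved against the reference profiles;
    the row holds the resulting volume fractions (summing to 1) plus the
    reduced χ² of the fit.
    """
    rows = []
    for prof in experimental_series:
        fit = fit_volume_fractions(reference_profiles, prof)
        row = {rid: float(v) for rid, v in zip(fit.member_ids, fit.nu)}
        row["chi2"] = fit.chi2
        rows.append(row)
    return pd.DataFrame(rows, index=[p.label for p in experimental_series])
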