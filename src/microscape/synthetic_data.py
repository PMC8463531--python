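"""Synthetic abundance tables with known attractor structure.

The generators emulate the three kinds of datasets the landscape
analysis is designed for, with ground truth attached:

* cross-sectional mixtures of K archetypal functional profiles with
  compositional (Dirichlet) noise — the metastability setting;
* multi-generation cohorts whose lineages persist on, or drift away
  from, their archetype — the functional-persistence setting;
* longitudinal trajectories that start from distinct compositions
  (e.g. two birth modes) and converge to shared target archetypes —
  the ecological-succession setting.

Archetypes are built from disjoint dominant-feature blocks blended
toward the uniform composition as ``separation`` decreases, which gives
a direct handle on between-archetype Jensen–Shannon divergence.
Generators emit proportions; ``to_counts`` adds an optional multinomial
sampling step for count-based statistics such as the Morisita index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import CommunityTable, SampleMetadata

__all__ = [
    "SyntheticSpec",
    "make_archetypes",
    "sample_cross_sectional",
    "sample_trajectories",
    "sample_generational",
    "to_counts",
]

# tiny Dirichlet floor keeping zero-block features strictly positive
_ALPHA_FLOOR = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for the generators.

    Parameters
    ----------
    K : int
        Number of archetypal profiles (planted attractors).
    F : int
        Number of features (predicted functions).
    separation : float in [0, 1]
        Blend between disjoint dominant blocks (1) and the uniform
        composition (0); controls between-archetype divergence.
    concentration : float
        Dirichlet concentration of the compositional noise; higher is
        tighter around the archetype.
    n_per_group : int
        Samples per archetype (cross-sectional) or lineages per
        archetype (generational).
    generations, timepoints : int
        Depth of the generational / longitudinal designs.
    start_modes : int
        Number of distinct initial compositions (e.g. 2 birth modes).
    convergence_rate : float in (0, 1]
        Per-step pull toward the target archetype along a trajectory.
    drift : float in [0, 1]
        Per-generation probability that a lineage switches archetype.
    seed : int
    """

    K: int = 3
    F: int = 100
    separation: float = 1.0
    concentration: float = 300.0
    n_per_group: int = 30
    generations: int = 3
    timepoints: int = 8
    start_modes: int = 2
    convergence_rate: float = 0.4
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.F < 2:
            raise ValueError("F must be >= 2")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not (0.0 < self.convergence_rate <= 1.0):
            raise ValueError("convergence_rate must be in (0, 1]")
        if not (0.0 <= self.separation <= 1.0):
            raise ValueError("separation must be in [0, 1]")
        if not (0.0 <= self.drift <= 1.0):
            raise ValueError("drift must be in [0, 1]")


def make_archetypes(spec: SyntheticSpec) -> np.ndarray:
    """K archetypal compositions over F features, shape (K, F).

    Archetype k concentrates its mass on the k-th of K disjoint feature
    blocks; ``separation`` linearly blends block profiles toward the
    uniform composition (separation 0 → all archetypes uniform).
    """
    if spec.K > spec.F:
        raise ValueError(f"cannot build {spec.K} disjoint blocks from {spec.F} features")
    uniform = np.full(spec.F, 1.0 / spec.F)
    bounds = np.linspace(0, spec.F, spec.K + 1).astype(int)
    archetypes = np.empty((spec.K, spec.F))
    for k in range(spec.K):
        block = np.zeros(spec.F)
        block[bounds[k] : bounds[k + 1]] = 1.0 / (bounds[k + 1] - bounds[k])
        archetypes[k] = spec.separation * block + (1.0 - spec.separation) * uniform
    return archetypes


def _dirichlet_around(center: np.ndarray, concentration: float, rng) -> np.ndarray:
    return rng.dirichlet(concentration * center + _ALPHA_FLOOR)


def sample_cross_sectional(spec: SyntheticSpec) -> tuple[CommunityTable, np.ndarray]:
    """n_per_group Dirichlet draws around each archetype.

    Returns the table (relative abundances) and the integer archetype
    label per sample.
    """
    rng = np.random.default_rng(spec.seed)
    archetypes = make_archetypes(spec)
    rows, labels, ids = [], [], []
    for k in range(spec.K):
        for i in range(spec.n_per_group):
            rows.append(_dirichlet_around(archetypes[k], spec.concentration, rng))
            labels.append(k)
            ids.append(f"s{k}_{i:03d}")
    table = CommunityTable(
        sample_ids=ids,
        feature_ids=[f"f{j}" for j in range(spec.F)],
        values=np.array(rows),
        is_relative=True,
    )
    return table, np.array(labels)


def sample_trajectories(
    spec: SyntheticSpec, noise: bool = True, shared_target: bool = True
) -> tuple[CommunityTable, SampleMetadata, np.ndarray]:
    """Longitudinal subjects converging from distinct starts to archetypes.

    Each subject starts at a start-mode-specific composition (far from
    every archetype) and moves a fraction ``convergence_rate`` of the
    way to its target archetype per timepoint; observed samples add
    Dirichlet noise unless ``noise`` is off.  With ``shared_target``
    all subjects converge to archetype 0 regardless of start mode —
    the succession-independent-of-birth-mode structure; otherwise
    targets rotate over archetypes.

    Returns the table, metadata (subject, timepoint, start_mode) and
    the target label per sample.
    """
    if spec.start_modes < 1:
        raise ValueError("start_modes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    archetypes = make_archetypes(spec)
    # start compositions: random sparse profiles, one per mode
    starts = rng.dirichlet(np.full(spec.F, 0.3), size=spec.start_modes)
    rows, ids, meta_rows, targets = [], [], [], []
    subject = 0
    for mode in range(spec.start_modes):
        for i in range(spec.n_per_group):
            target_k = 0 if shared_target else subject % spec.K
            target = archetypes[target_k]
            p = starts[mode].copy()
            for t in range(spec.timepoints):
                p = (1.0 - spec.convergence_rate) * p + spec.convergence_rate * target
                p = p / p.sum()
                observed = (
                    _dirichlet_around(p, spec.concentration, rng) if noise else p
                )
                rows.append(observed)
                ids.append(f"subj{subject:03d}_t{t:02d}")
                meta_rows.append(
                    {"sample_id": f"subj{subject:03d}_t{t:02d}",
                     "subject": f"subj{subject:03d}",
                     "timepoint": t,
                     "start_mode": f"mode{mode}"}
                )
                targets.append(target_k)
            subject += 1
    table = CommunityTable(
        sample_ids=ids,
        feature_ids=[f"f{j}" for j in range(spec.F)],
        values=np.array(rows),
        is_relative=True,
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta, np.array(targets)


def sample_generational(
    spec: SyntheticSpec, n_treatments: int = 2
) -> tuple[CommunityTable, SampleMetadata, np.ndarray]:
    """Multi-generation lineages that persist on or drift off archetypes.

    Each lineage starts on an archetype; each generation it keeps its
    archetype or, with probability ``drift``, switches to a uniformly
    chosen different one.  Drift 0 models perfect functional
    persistence across generations; drift > 0 models divergence.

    Returns the table, metadata (generation, treatment, lineage) and
    the true archetype label per sample.
    """
    if spec.generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(spec.seed)
    archetypes = make_archetypes(spec)
    rows, ids, meta_rows, labels = [], [], [], []
    lineage = 0
    for k0 in range(spec.K):
        for i in range(spec.n_per_group):
            k = k0
            treatment = f"trt{lineage % n_treatments}"
            for g in range(spec.generations):
                if g > 0 and spec.K > 1 and rng.random() < spec.drift:
                    others = [j for j in range(spec.K) if j != k]
                    k = int(rng.choice(others))
                sid = f"lin{lineage:03d}_g{g}"
                rows.append(_dirichlet_around(archetypes[k], spec.concentration, rng))
                ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "generation": g, "treatment": treatment,
                     "lineage": f"lin{lineage:03d}"}
                )
                labels.append(k)
            lineage += 1
    table = CommunityTable(
        sample_ids=ids,
        feature_ids=[f"f{j}" for j in range(spec.F)],
        values=np.array(rows),
        is_relative=True,
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta, np.array(labels)


def to_counts(table: CommunityTable, depth: int = 10_000, seed=None) -> CommunityTable:
    """Multinomial resampling of each row to integer counts at ``depth``."""
    rng = np.random.default_rng(seed)
    counts = np.vstack([rng.multinomial(depth, row / row.sum()) for row in table.values])
    return CommunityTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        values=counts.astype(float),
        is_relative=False,
    )
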