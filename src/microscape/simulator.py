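"""Individual-based stochastic community simulation.

Two models over a fixed pool of ``I`` sites (hosts/microhabitats) and a
metacommunity of ``S`` species:

* **Hubbell** — zero-sum neutral dynamics: every timestep a batch of
  individuals dies and each is immediately replaced either by an
  immigrant (drawn in proportion to per-species migration
  probabilities) or by the offspring of a surviving local individual.
  Total occupancy stays at ``I`` throughout.

* **SOI** (self-organized instability) — three phases per timestep, in
  fixed order: (1) immigration of each species into one empty site with
  its migration probability; (2) ``I`` pairwise events, each drawing an
  occupied site and another site uniformly: reproduction into an empty
  site with probability ``growth_prob``, or displacement driven by the
  interaction asymmetry Δ = A[i, j] − A[j, i] (the winner overwrites
  the loser with probability min(1, |Δ|)); (3) independent per-site
  extinction.

Connectivity — the fraction of non-zero off-diagonal interaction
entries — is the knob that separates the models: connectivity 0
dispatches to the neutral Hubbell dynamics.

All replicates of a parameter combination share one interaction
matrix, one set of initially fixed individuals and one migration
vector; randomness is managed through a single experiment seed with
counter-based derivation (no global state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "SimConfig",
    "CommunityState",
    "SimulationResult",
    "random_interaction_matrix",
    "initial_state",
    "simulate_soi",
    "simulate_hubbell",
    "run_experiment",
    "results_to_dataframe",
]

EMPTY = -1


@dataclass(frozen=True)
class InteractionMatrix:
    """Pairwise interaction strengths; A[i, j] = effect of j on i."""

    S: int
    A: np.ndarray
    connectivity: float
    positive_edge_fraction: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.shape != (self.S, self.S):
            raise ValueError(f"interaction matrix shape {A.shape} != ({self.S}, {self.S})")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults are the study conditions: 50 metacommunity species, 500
    individuals (sites), 600 timesteps, 450 replicates per parameter
    combination, migration probabilities drawn from U(0, 1).
    Death and growth rates are model conventions of this package.
    """

    S: int = 50
    I: int = 500
    timesteps: int = 600
    replicates: int = 450
    n_fixed: int = 0
    extinction_prob: float = 0.1
    growth_prob: float = 0.5
    migration_probs: np.ndarray | None = None
    self_limitation: float = -0.5
    value_range: float = 1.0
    max_pep: float = 0.3
    keep_trajectory: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_fixed <= self.I):
            raise ValueError(f"n_fixed must be in [0, {self.I}]")
        for name in ("extinction_prob", "growth_prob", "max_pep"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.migration_probs is not None:
            m = np.asarray(self.migration_probs, dtype=float)
            if m.shape != (self.S,):
                raise ValueError(f"migration_probs must have length S={self.S}")
            if np.any((m < 0) | (m > 1)):
                raise ValueError("migration_probs must lie in [0, 1]")
            object.__setattr__(self, "migration_probs", m)


@dataclass(frozen=True)
class CommunityState:
    """Site-occupancy vector; each entry a species id in 0..S-1 or EMPTY."""

    sites: np.ndarray
    S: int

    def __post_init__(self) -> None:
        sites = np.asarray(self.sites, dtype=np.int64)
        object.__setattr__(self, "sites", sites)
        occupied = sites[sites != EMPTY]
        if occupied.size and (occupied.min() < 0 or occupied.max() >= self.S):
            raise ValueError("species ids out of range")

    @property
    def I(self) -> int:
        return self.sites.size

    def abundances(self) -> np.ndarray:
        return np.bincount(self.sites[self.sites != EMPTY], minlength=self.S)


@dataclass(frozen=True)
class SimulationResult:
    """Final state of one replicate."""

    replicate: int
    connectivity: float
    n_fixed: int
    seed: int
    abundances: np.ndarray
    trajectory: np.ndarray | None = None


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def random_interaction_matrix(
    S: int,
    connectivity: float,
    max_pep: float = 0.3,
    value_range: float = 1.0,
    self_limitation: float = -0.5,
    seed=None,
) -> InteractionMatrix:
    """Draw a random interaction matrix at the given connectivity.

    Exactly round(connectivity·S·(S−1)) off-diagonal entries are
    non-zero, placed uniformly without replacement, with values uniform
    on (−value_range, value_range) excluding 0.  While the fraction of
    positive non-zero entries exceeds ``max_pep``, the sign of a
    uniformly chosen positive entry is switched.  The diagonal holds
    the self-limitation constant.
    """
    if not (0.0 <= connectivity <= 1.0):
        raise ValueError(f"connectivity must be in [0, 1], got {connectivity}")
    if not (0.0 <= max_pep <= 1.0):
        raise ValueError(f"max_pep must be in [0, 1], got {max_pep}")
    rng = np.random.default_rng(seed)
    A = np.zeros((S, S))
    n_offdiag = S * (S - 1)
    n_nonzero = int(round(connectivity * n_offdiag))
    if n_nonzero:
        offdiag = [(i, j) for i in range(S) for j in range(S) if i != j]
        chosen = rng.choice(n_offdiag, size=n_nonzero, replace=False)
        values = rng.uniform(-value_range, value_range, size=n_nonzero)
        while np.any(values == 0.0):  # pragma: no cover - measure zero
            zeros = values == 0.0
            values[zeros] = rng.uniform(-value_range, value_range, size=zeros.sum())
        for idx, val in zip(chosen, values):
            i, j = offdiag[idx]
            A[i, j] = val
        while (A > 0).sum() / n_nonzero > max_pep:
            pos = np.argwhere(A > 0)
            i, j = pos[rng.integers(len(pos))]
            A[i, j] = -A[i, j]
    np.fill_diagonal(A, self_limitation)
    mask = ~np.eye(S, dtype=bool)
    nz = A[mask] != 0
    pep = float((A[mask][nz] > 0).mean()) if nz.any() else 0.0
    return InteractionMatrix(S=S, A=A, connectivity=connectivity, positive_edge_fraction=pep)


def initial_state(config: SimConfig, fixed_individuals, seed=None) -> CommunityState:
    """Fully occupied starting community.

    The first ``n_fixed`` sites hold the shared fixed individuals
    (identical across replicates of a combination); the remaining
    sites are drawn uniformly over species per replicate.
    """
    fixed = np.asarray(fixed_individuals, dtype=np.int64)
    if fixed.size != config.n_fixed:
        raise ValueError(
            f"fixed_individuals has length {fixed.size}, expected n_fixed={config.n_fixed}"
        )
    if config.n_fixed > config.I:
        raise ValueError("n_fixed exceeds the number of sites")
    rng = np.random.default_rng(seed)
    sites = np.empty(config.I, dtype=np.int64)
    sites[: config.n_fixed] = fixed
    sites[config.n_fixed :] = rng.integers(0, config.S, size=config.I - config.n_fixed)
    return CommunityState(sites=sites, S=config.S)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def simulate_soi(
    config: SimConfig,
    interactions: InteractionMatrix,
    init: CommunityState,
    seed=None,
    replicate: int = 0,
) -> SimulationResult:
    """Run the SOI model: immigration, pairwise events, extinction."""
    rng = np.random.default_rng(seed)
    S, I, A = config.S, config.I, interactions.A
    m = config.migration_probs
    if m is None:
        m = np.full(S, 0.5)
    sites = init.sites.copy()
    occupied = [int(i) for i in np.flatnonzero(sites != EMPTY)]
    growth = config.growth_prob
    traj = np.zeros((config.timesteps, S), dtype=np.int64) if config.keep_trajectory else None

    def occupy(site: int, species: int) -> None:
        sites[site] = species
        occupied.append(site)

    for t in range(config.timesteps):
        # phase 1: immigration — one empty site per migrating species
        migrants = np.flatnonzero(rng.random(S) < m)
        for s in migrants:
            n_empty = I - len(occupied)
            if n_empty == 0:
                break
            empties = np.flatnonzero(sites == EMPTY)
            occupy(int(empties[rng.integers(n_empty)]), int(s))

        # phase 2: I pairwise interaction/growth events
        if occupied:
            u_a = rng.random(I)
            u_b = rng.integers(0, I - 1, size=I)
            u_p = rng.random(I)
            for e in range(I):
                n_occ = len(occupied)
                if n_occ == 0:
                    break
                a = occupied[int(u_a[e] * n_occ)]
                b = int(u_b[e])
                if b >= a:
                    b += 1
                i = sites[a]
                j = sites[b]
                if j == EMPTY:
                    if u_p[e] < growth:
                        occupy(b, int(i))
                elif j != i:
                    delta = A[i, j] - A[j, i]
                    if delta > 0:
                        if u_p[e] < delta:
                            sites[b] = i
                    elif delta < 0:
                        if u_p[e] < -delta:
                            sites[a] = j

        # phase 3: independent extinction of occupied sites
        if config.extinction_prob > 0 and occupied:
            occ_arr = np.array(occupied)
            dead = occ_arr[rng.random(len(occ_arr)) < config.extinction_prob]
            if dead.size:
                sites[dead] = EMPTY
                occupied = [int(i) for i in np.flatnonzero(sites != EMPTY)]
        if traj is not None:
            traj[t] = np.bincount(sites[sites != EMPTY], minlength=S)

    final = np.bincount(sites[sites != EMPTY], minlength=S)
    return SimulationResult(
        replicate=replicate,
        connectivity=interactions.connectivity,
        n_fixed=config.n_fixed,
        seed=_seed_int(seed),
        abundances=final,
        trajectory=traj,
    )


def simulate_hubbell(
    config: SimConfig,
    init: CommunityState,
    seed=None,
    replicate: int = 0,
) -> SimulationResult:
    """Run the zero-sum neutral model.

    Each timestep, d = max(1, round(extinction_prob·I)) distinct
    individuals die; each is immediately replaced by an immigrant with
    probability m̄ = mean(migration_probs) — species drawn proportional
    to the migration probabilities — or by the offspring of a uniformly
    chosen surviving local individual.
    """
    if np.any(init.sites == EMPTY):
        raise ValueError("Hubbell model requires a fully occupied initial state")
    rng = np.random.default_rng(seed)
    S, I = config.S, config.I
    m = config.migration_probs
    if m is None:
        m = np.full(S, 0.5)
    m_bar = float(np.mean(m))
    m_total = float(np.sum(m))
    immigrant_p = m / m_total if m_total > 0 else None
    sites = init.sites.copy()
    d = max(1, int(round(config.extinction_prob * I)))
    traj = np.zeros((config.timesteps, S), dtype=np.int64) if config.keep_trajectory else None

    for t in range(config.timesteps):
        dying = rng.choice(I, size=d, replace=False)
        for site in dying:
            if immigrant_p is not None and rng.random() < m_bar:
                sites[site] = rng.choice(S, p=immigrant_p)
            else:
                parent = rng.integers(I - 1)
                if parent >= site:
                    parent += 1
                sites[site] = sites[parent]
        if traj is not None:
            traj[t] = np.bincount(sites, minlength=S)

    return SimulationResult(
        replicate=replicate,
        connectivity=0.0,
        n_fixed=config.n_fixed,
        seed=_seed_int(seed),
        abundances=np.bincount(sites, minlength=S),
        trajectory=traj,
    )


def _seed_int(seed) -> int:
    if seed is None:
        return -1
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(seed) % (2**31)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


def run_experiment(
    connectivity_grid,
    n_fixed_grid,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[SimulationResult]:
    """Simulate the full connectivity × n_fixed grid.

    For each combination, one interaction matrix, one fixed-individual
    list and one migration vector are drawn; ``config.replicates``
    replicates then run with distinct per-replicate seeds derived from
    the experiment seed (connectivity 0 dispatches to the Hubbell
    model).  Deterministic: the same experiment seed reproduces every
    abundance bit for bit.
    """
    root = np.random.SeedSequence(seed)
    results: list[SimulationResult] = []
    combos = [(c, f) for c in connectivity_grid for f in n_fixed_grid]
    combo_seeds = root.spawn(len(combos))
    for (conn, n_fixed), combo_seq in zip(combos, combo_seeds):
        setup_seq, *rep_seqs = combo_seq.spawn(config.replicates + 1)
        setup_rng = np.random.default_rng(setup_seq)
        combo_config = replace(
            config,
            n_fixed=n_fixed,
            migration_probs=setup_rng.uniform(0.0, 1.0, size=config.S),
        )
        interactions = random_interaction_matrix(
            S=config.S,
            connectivity=conn,
            max_pep=config.max_pep,
            value_range=config.value_range,
            self_limitation=config.self_limitation,
            seed=setup_rng,
        )
        fixed = setup_rng.integers(0, config.S, size=n_fixed)
        for rep, rep_seq in enumerate(rep_seqs):
            init_seq, dyn_seq = rep_seq.spawn(2)
            init = initial_state(combo_config, fixed, seed=init_seq)
            if conn == 0:
                res = simulate_hubbell(combo_config, init, seed=dyn_seq, replicate=rep)
            else:
                res = simulate_soi(combo_config, interactions, init, seed=dyn_seq, replicate=rep)
            results.append(replace(res, connectivity=conn))
    return results


def results_to_dataframe(results: list[SimulationResult]) -> pd.DataFrame:
    """Long table: connectivity, n_fixed, replicate, seed, one column per species."""
    S = results[0].abundances.size
    rows = []
    for r in results:
        row = {
            "connectivity": r.connectivity,
            "n_fixed": r.n_fixed,
            "replicate": r.replicate,
            "seed": r.seed,
        }
        row.update({f"sp{k}": int(r.abundances[k]) for k in range(S)})
        rows.append(row)
    return pd.DataFrame(rows)
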