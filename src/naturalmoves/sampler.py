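"""Metropolis Monte Carlo over a natural-move set, with optional parallel
tempering and burn-in step-size tuning.

One iteration: draw a generator (by weight), apply its proposal, restore
chain connectivity through the flanking molten zones, evaluate the energy
difference incrementally, and accept with the Metropolis probability
min(1, exp(-dE / kB T)).  A closure that cannot bridge its anchors makes the
proposal infeasible and the move is rejected outright, which preserves
detailed balance (the reverse move from an intact state into a broken one
has zero probability).

Parallel tempering advances independent replicas on a temperature ladder and
attempts deterministic even/odd neighbour swaps every ``exchange_interval``
iterations with probability min(1, exp[(beta_i - beta_j)(E_i - E_j)]).
Observables are read from the lowest (canonical) temperature's trajectory.

Reproducibility: one master seed spawns independent per-replica streams, so
identical (seed, config) pairs give bit-identical trajectories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .closure import ClosureInfeasible, close_chain
from .energy import KB, EnergyModel, delta_energy, total_energy
from .moves import MoveGenerator, MoveSet, propose_rigid, propose_torsion
from .structure import Conformation, Trajectory

__all__ = [
    "SamplerConfig",
    "RunStats",
    "metropolis_accept",
    "run_mc",
    "run_parallel_tempering",
    "tune_step_sizes",
]

#: replica ladder used by the protein case study (Kelvin)
DEFAULT_LADDER = (300.0, 336.0, 376.0, 421.0, 472.0, 529.0)


@dataclass
class SamplerConfig:
    """Sampling schedule.  Defaults mirror the six-replica ladder of the
    protein study, with desk-scale iteration counts (production runs used
    1e6-5e6 iterations and 15-30 repeats; raise ``iterations`` for that)."""

    temperatures: tuple[float, ...] = DEFAULT_LADDER
    iterations: int = 10_000
    seed: int = 0
    exchange_interval: int = 100
    sample_interval: int = 100
    closure_tol: float = 1e-3
    closure_max_iter: int = 200
    min_acceptance: float = 0.25  # tuning / health-check targets
    min_exchange: float = 0.10

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        temps = tuple(self.temperatures)
        if not temps or any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = temps


@dataclass
class RunStats:
    proposed: dict[str, int] = field(default_factory=dict)
    accepted: dict[str, int] = field(default_factory=dict)
    closure_failures: int = 0
    per_replica_acceptance: list[float] = field(default_factory=list)
    exchange_attempted: int = 0
    exchange_accepted: int = 0

    def generator_rate(self, label: str) -> float:
        p = self.proposed.get(label, 0)
        return self.accepted.get(label, 0) / p if p else 0.0

    @property
    def acceptance_rate(self) -> float:
        p = sum(self.proposed.values())
        return sum(self.accepted.values()) / p if p else 0.0

    @property
    def exchange_rate(self) -> float:
        return self.exchange_accepted / self.exchange_attempted if self.exchange_attempted else 0.0


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/(kB T))); non-finite dE rejects."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if not math.isfinite(delta_E):
        return False
    if delta_E <= 0.0:
        return True
    return rng.random() < math.exp(-delta_E / (KB * T))


class _Walker:
    """A single replica: coordinates, energy bookkeeping and counters."""

    def __init__(
        self,
        conf: Conformation,
        moveset: MoveSet,
        model: EnergyModel,
        temperature: float,
        rng: np.random.Generator,
        config: SamplerConfig,
    ) -> None:
        self.coords = conf.coords.copy()
        self.moveset = moveset
        self.model = model
        self.T = temperature
        self.rng = rng
        self.config = config
        self.energy = total_energy(self.coords, model)
        self.stats = RunStats()
        w = moveset.weights
        self._cumw = np.cumsum(w / w.sum())
        self._moved = [g.moved_atoms() for g in moveset.generators]

    def step(self) -> None:
        gens = self.moveset.generators
        gi = int(np.searchsorted(self._cumw, self.rng.random()))
        gi = min(gi, len(gens) - 1)
        g = gens[gi]
        self.stats.proposed[g.label] = self.stats.proposed.get(g.label, 0) + 1

        trial = self.coords.copy()
        try:
            if g.kind == "rigid":
                propose_rigid(trial, g.atoms, self.rng, g.max_trans, g.max_rot)
                for problem in g.closures:
                    close_chain(
                        trial,
                        problem,
                        tol=self.config.closure_tol,
                        max_iter=self.config.closure_max_iter,
                    )
            elif g.kind == "torsion":
                propose_torsion(trial, g.atoms, g.axis, self.rng, g.max_rot)
            else:
                raise ValueError(f"unknown generator kind {g.kind!r}")
        except ClosureInfeasible:
            self.stats.closure_failures += 1
            return

        dE = delta_energy(trial, self.coords, self._moved[gi], self.model)
        if metropolis_accept(dE, self.T, self.rng):
            self.coords = trial
            self.energy += dE
            self.stats.accepted[g.label] = self.stats.accepted.get(g.label, 0) + 1

    def resync_energy(self) -> None:
        self.energy = total_energy(self.coords, self.model)


def run_mc(
    conf: Conformation,
    moveset: MoveSet,
    model: EnergyModel,
    config: SamplerConfig,
    temperature: float | None = None,
) -> tuple[Trajectory, RunStats]:
    """Single-temperature Metropolis run.  The trajectory records the initial
    conformation and one frame every ``sample_interval`` iterations."""
    T = temperature if temperature is not None else config.temperatures[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    walker = _Walker(conf, moveset, model, T, rng, config)

    traj = Trajectory(
        topology=conf.copy(),
        frames=[walker.coords.copy()],
        energies=[walker.energy],
        metadata={"temperature": T, "seed": config.seed},
    )
    for it in range(1, config.iterations + 1):
        walker.step()
        if it % config.sample_interval == 0:
            walker.resync_energy()
            traj.frames.append(walker.coords.copy())
            traj.energies.append(walker.energy)
    walker.stats.per_replica_acceptance = [walker.stats.acceptance_rate]
    return traj, walker.stats


def run_parallel_tempering(
    conf: Conformation,
    moveset: MoveSet,
    model: EnergyModel,
    config: SamplerConfig,
) -> tuple[list[Trajectory], RunStats]:
    """Replica-exchange run over ``config.temperatures``.

    Returns one trajectory per ladder temperature (index 0, the canonical
    temperature, is the primary output) plus combined statistics.  With a
    single temperature this degenerates to :func:`run_mc`.
    """
    temps = config.temperatures
    if len(temps) == 1:
        traj, stats = run_mc(conf, moveset, model, config)
        return [traj], stats

    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(len(temps) + 1)
    exchange_rng = np.random.default_rng(children[-1])
    walkers = [
        _Walker(conf, moveset, model, T, np.random.default_rng(children[i]), config)
        for i, T in enumerate(temps)
    ]
    trajs = [
        Trajectory(
            topology=conf.copy(),
            frames=[w.coords.copy()],
            energies=[w.energy],
            metadata={"temperature": w.T, "seed": config.seed, "replica": i},
        )
        for i, w in enumerate(walkers)
    ]

    stats = RunStats()
    sweep = 0
    for it in range(1, config.iterations + 1):
        for w in walkers:
            w.step()
        if it % config.exchange_interval == 0:
            start = sweep % 2
            sweep += 1
            for i in range(start, len(walkers) - 1, 2):
                wi, wj = walkers[i], walkers[i + 1]
                stats.exchange_attempted += 1
                beta_i, beta_j = 1.0 / (KB * wi.T), 1.0 / (KB * wj.T)
                log_p = (beta_i - beta_j) * (wi.energy - wj.energy)
                if log_p >= 0 or exchange_rng.random() < math.exp(log_p):
                    wi.coords, wj.coords = wj.coords, wi.coords
                    wi.energy, wj.energy = wj.energy, wi.energy
                    stats.exchange_accepted += 1
        if it % config.sample_interval == 0:
            for w, traj in zip(walkers, trajs):
                w.resync_energy()
                traj.frames.append(w.coords.copy())
                traj.energies.append(w.energy)

    for w in walkers:
        stats.per_replica_acceptance.append(w.stats.acceptance_rate)
        for label in w.stats.proposed:
            stats.proposed[label] = stats.proposed.get(label, 0) + w.stats.proposed[label]
            stats.accepted[label] = stats.accepted.get(label, 0) + w.stats.accepted.get(label, 0)
        stats.closure_failures += w.stats.closure_failures
    return trajs, stats


def tune_step_sizes(
    conf: Conformation,
    moveset: MoveSet,
    model: EnergyModel,
    T: float,
    target_rate: float = 0.25,
    budget: int = 5000,
    chunk: int = 250,
    seed: int = 0,
) -> MoveSet:
    """Multiplicative step-size adaptation during a burn-in budget.

    Per-generator acceptance is measured over chunks; generators below the
    target shrink their steps (x0.7), generators far above it grow (x1.3).
    The returned move set is frozen -- adaptation never continues into the
    production run, which would break detailed balance.  If the target is
    unattainable within the budget a warning is raised and the best-effort
    steps are returned.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    tuned = moveset.copy()
    config = SamplerConfig(temperatures=(T,), iterations=0, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    walker = _Walker(conf, tuned, model, T, rng, config)

    grow_above = min(0.95, target_rate + 0.30)
    done = 0
    meas_p: dict[str, int] = {}
    meas_a: dict[str, int] = {}
    while done < budget:
        n = min(chunk, budget - done)
        walker.stats = RunStats()
        for _ in range(n):
            walker.step()
        done += n
        for g in tuned.generators:
            p = walker.stats.proposed.get(g.label, 0)
            if p == 0:
                continue
            a = walker.stats.accepted.get(g.label, 0)
            if done > budget // 2:  # per-chunk rates are noisy; judge on the tail
                meas_p[g.label] = meas_p.get(g.label, 0) + p
                meas_a[g.label] = meas_a.get(g.label, 0) + a
            rate = a / p
            factor = 0.7 if rate < target_rate else (1.3 if rate > grow_above else 1.0)
            if factor != 1.0:
                g.max_trans = float(np.clip(g.max_trans * factor, 0.0, 100.0))
                if g.max_trans:
                    g.max_trans = max(g.max_trans, 1e-4)
                g.max_rot = float(np.clip(g.max_rot * factor, 0.0, 360.0))
                if g.max_rot:
                    g.max_rot = max(g.max_rot, 1e-4)
        walker.resync_energy()

    low = [lbl for lbl, p in meas_p.items() if meas_a.get(lbl, 0) / p < target_rate]
    if low:
        warnings.warn(
            f"step-size tuning could not reach acceptance {target_rate} for: {', '.join(low)}",
            stacklevel=2,
        )
    return tuned
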