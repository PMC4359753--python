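"""Neutral Wright--Fisher null for inversion-frequency trajectories.

An inversion is treated as an allele ``A`` segregating in a closed
population of effective size N. Each generation the allele frequency is
resampled binomially over the population's chromosome copies:

    p_{t+1} = X / n_copies,   X ~ Binomial(n_copies, p_t),

with absorption at 0 and 1. By default N is read as a diploid effective
size, so n_copies = 2N chromosome copies are resampled; a haploid reading
(n_copies = N) is available behind a flag.

The empirical p-value for an observed set of replicate frequency changes is
the fraction of simulated experiments in which *every* replicate's polarized
frequency change (signed in the direction observed for that replicate)
strictly exceeds the observed one. Replicates are simulated independently
from their observed starting frequencies for their own generation counts;
a replicate with zero observed change has no polarity, is flagged, and its
exceedance condition degrades to |simulated change| > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class WFSimConfig:
    """Configuration of the neutral drift simulation.

    N
        Effective population size (default 200).
    diploid
        If true (default), n_copies = 2N chromosome copies are binomially
        resampled each generation; otherwise n_copies = N.
    p0
        Initial inversion frequency per replicate.
    generations
        Generations simulated per replicate (may differ, e.g. 60 for a hot
        regime and 34 for a cold regime).
    iterations
        Number of simulated experiments (default 100 000).
    """

    N: int = 200
    p0: tuple[float, ...] = (0.1,)
    generations: tuple[int, ...] = (34,)
    iterations: int = 100_000
    seed: int | None = None
    diploid: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if len(self.p0) != len(self.generations):
            raise ValueError("p0 and generations must have one entry per replicate")
        for p in self.p0:
            if not 0.0 <= p <= 1.0:
                raise ValueError("p0 must lie in [0, 1]")
        for g in self.generations:
            if g < 0:
                raise ValueError("generations must be >= 0")

    @property
    def n_copies(self) -> int:
        return 2 * self.N if self.diploid else self.N

    @property
    def n_replicates(self) -> int:
        return len(self.p0)


def simulate_trajectory(
    cfg: WFSimConfig, replicate: int = 0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One frequency trajectory, generations 0..T inclusive."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_copies
    p = cfg.p0[replicate]
    traj = np.empty(cfg.generations[replicate] + 1)
    traj[0] = p
    for t in range(1, traj.size):
        p = rng.binomial(n, p) / n
        traj[t] = p
    return traj


def simulate_final_frequencies(
    n_copies: int,
    p0: float,
    generations: int,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized endpoint frequencies of ``iterations`` independent
    trajectories started at ``p0`` and drifted for ``generations``."""
    p = np.full(iterations, p0)
    for _ in range(generations):
        p = rng.binomial(n_copies, p) / n_copies
    return p


@dataclass
class EmpiricalPResult:
    """Outcome of the neutral-drift exceedance test.

    ``p_value`` has resolution 1/iterations; when no simulated experiment
    exceeds the observation it is reported as 0 with ``upper_bound``
    = 1/iterations (read: p < 1/iterations).
    """

    p_value: float
    exceedances: int
    iterations: int
    observed_change: tuple[float, ...]
    zero_change_replicates: tuple[int, ...] = field(default_factory=tuple)

    @property
    def upper_bound(self) -> float:
        return max(self.p_value, 1.0 / self.iterations)

    def __str__(self) -> str:
        if self.exceedances == 0:
            return f"p < {1.0 / self.iterations:g}"
        return f"p = {self.p_value:g}"


def empirical_p(
    observed_start: Sequence[float],
    observed_end: Sequence[float],
    cfg: WFSimConfig,
) -> EmpiricalPResult:
    """Empirical p-value of observed replicate changes under neutral drift.

    Each replicate is simulated from ``observed_start[r]`` (which should
    also equal ``cfg.p0[r]``) for its configured generation count. An
    iteration counts as an exceedance iff, in every replicate, the simulated
    polarized change strictly exceeds the observed polarized change, where
    polarity is the sign of that replicate's observed change.
    """
    start = np.asarray(observed_start, dtype=float)
    end = np.asarray(observed_end, dtype=float)
    if start.shape != end.shape or start.size != cfg.n_replicates:
        raise ValueError("need one observed start/end pair per replicate")
    rng = np.random.default_rng(cfg.seed)
    obs_change = end - start
    zero_reps = tuple(int(i) for i in np.where(obs_change == 0)[0])

    exceed = np.ones(cfg.iterations, dtype=bool)
    for r in range(cfg.n_replicates):
        final = simulate_final_frequencies(
            cfg.n_copies, start[r], cfg.generations[r], cfg.iterations, rng
        )
        sim_change = final - start[r]
        if obs_change[r] == 0:
            exceed &= np.abs(sim_change) > 0
        else:
            sign = np.sign(obs_change[r])
            exceed &= sign * sim_change > sign * obs_change[r]
    n_exceed = int(exceed.sum())
    return EmpiricalPResult(
        p_value=n_exceed / cfg.iterations,
        exceedances=n_exceed,
        iterations=cfg.iterations,
        observed_change=tuple(float(c) for c in obs_change),
        zero_change_replicates=zero_reps,
    )
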