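"""Age-from-stage demography: survivorship/fertility schedules and lifespan.

A stage-structured survival matrix ``U`` defines an absorbing Markov chain
(death is the absorbing state).  From it we derive the age-indexed
survivorship ``lx`` and fertility ``mx`` of a birth cohort, and the mean and
variance of lifespan via the fundamental matrix ``N = (I - U)^-1``.

Age is counted in projection intervals with age 0 at the first census; an
individual certain to die before the second census has lifespan 1 (it lived
one interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

XMAX_DEFAULT = 1000
LX_CUTOFF = 1e-7


class SingularChainError(ValueError):
    """(I - U) is singular: some stage retains individuals forever."""


@dataclass(frozen=True)
class FundamentalMatrix:
    """N = (I - U)^-1: expected intervals spent in each stage before death,
    by starting stage (columns index the starting stage)."""

    N: np.ndarray


@dataclass(frozen=True)
class AgeSchedule:
    """Age-indexed survivorship and fertility of a cohort.

    ``lx[x]`` is the proportion of the cohort alive at age ``x``
    (``lx[0] == 1``); ``mx[x]`` is per-capita fertility at age ``x``
    conditional on being alive, NaN where the cohort is extinct.
    """

    lx: np.ndarray
    mx: np.ndarray
    start_distribution: np.ndarray

    @property
    def xmax(self) -> int:
        return len(self.lx) - 1


def default_start_distribution(F: np.ndarray) -> np.ndarray:
    """Cohort entry distribution: all mass on the stage receiving the most
    reproduction inflow (largest row sum of F; ties broken by stage order).

    Offspring enter the life cycle through the rows of ``F``; with no
    reproduction at all, the first stage is used.
    """
    F = np.asarray(F, dtype=float)
    c = np.zeros(F.shape[0])
    inflow = F.sum(axis=1)
    c[int(np.argmax(inflow))] = 1.0
    return c


def fundamental_matrix(U: np.ndarray) -> FundamentalMatrix:
    """Return N = (I - U)^-1 for a survival matrix with spectral radius < 1.

    Raises
    ------
    SingularChainError
        When some stage (or cycle of stages) has survival outflow summing to
        one, i.e. individuals never die; the message names the stage.
    """
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    rho = np.max(np.abs(np.linalg.eigvals(U))) if n else 0.0
    if rho >= 1 - 1e-12:
        closed = np.nonzero(U.sum(axis=0) >= 1 - 1e-9)[0]
        where = (
            f"stage(s) {', '.join(str(i + 1) for i in closed)}"
            if closed.size
            else "a stage cycle"
        )
        raise SingularChainError(
            f"immortal chain: survival mass of {where} sums to 1 "
            f"(spectral radius {rho:.6g})"
        )
    N = np.linalg.solve(np.eye(n) - U, np.eye(n))
    return FundamentalMatrix(N=N)


def survivorship_schedule(
    U: np.ndarray,
    start_distribution: np.ndarray,
    xmax: int = XMAX_DEFAULT,
    cutoff: float = LX_CUTOFF,
) -> np.ndarray:
    """Survivorship curve lx[x] = 1' U^x c for x = 0..xmax.

    Iteration stops early once ``lx`` falls below ``cutoff`` (the remaining
    tail is demographically negligible and would only add noise to the
    shape metrics).
    """
    U = np.asarray(U, dtype=float)
    c = np.asarray(start_distribution, dtype=float)
    lx = [1.0]
    v = c.copy()
    for _ in range(xmax):
        v = U @ v
        s = float(v.sum())
        lx.append(s)
        if s < cutoff:
            break
    return np.array(lx)


def fertility_schedule(
    U: np.ndarray,
    F: np.ndarray,
    start_distribution: np.ndarray,
    xmax: int = XMAX_DEFAULT,
    cutoff: float = LX_CUTOFF,
) -> AgeSchedule:
    """Joint lx/mx schedule of a cohort.

    ``mx[x] = (1' F U^x c) / (1' U^x c)``: expected offspring per survivor
    at age x.  Ages where the cohort is extinct carry ``mx = NaN``.
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    c = np.asarray(start_distribution, dtype=float)
    lx, mx = [1.0], []
    v = c.copy()
    mx.append(float(F.sum(axis=0) @ v))  # lx[0] = 1
    for _ in range(xmax):
        v = U @ v
        s = float(v.sum())
        lx.append(s)
        mx.append(float(F.sum(axis=0) @ v) / s if s > 0 else np.nan)
        if s < cutoff:
            break
    return AgeSchedule(
        lx=np.array(lx), mx=np.array(mx), start_distribution=c
    )


def lifespan_moments(
    U: np.ndarray, start_distribution: np.ndarray
) -> tuple[float, float]:
    """Mean and variance of cohort lifespan from the absorbing chain.

    eta_e = 1' N c  (mean intervals lived, counting the first),
    var    = 1'(2N - I) N c - eta_e^2.
    """
    c = np.asarray(start_distribution, dtype=float)
    N = fundamental_matrix(U).N
    ones = np.ones(N.shape[0])
    eta = float(ones @ N @ c)
    second = float(ones @ (2.0 * N - np.eye(N.shape[0])) @ N @ c)
    return eta, second - eta**2


def simulate_cohort_counts(
    U: np.ndarray,
    start_distribution: np.ndarray,
    n_individuals: int,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo cohort: number of deaths at each age.

    Tracks stage-occupancy counts and draws multinomial transitions
    (stages..., dead) per stage per step — distributionally identical to
    individual-level simulation but vectorized.  Returns ``deaths`` where
    ``deaths[x]`` individuals lived exactly ``x + 1`` intervals.  This is the
    independent stochastic oracle for :func:`lifespan_moments`.
    """
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    counts = rng.multinomial(n_individuals, np.asarray(start_distribution, float))
    probs = [np.append(U[:, j], max(0.0, 1.0 - U[:, j].sum())) for j in range(n)]
    deaths = []
    for _ in range(max_steps):
        nxt = np.zeros(n, dtype=np.int64)
        dead = 0
        for j in range(n):
            if counts[j] == 0:
                continue
            draw = rng.multinomial(counts[j], probs[j])
            nxt += draw[:n]
            dead += draw[n]
        deaths.append(dead)
        counts = nxt
        if counts.sum() == 0:
            break
    return np.array(deaths, dtype=np.int64)
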