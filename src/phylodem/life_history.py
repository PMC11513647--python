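"""The eleven life-history traits derived from one matrix population model.

Traits (annual units unless noted):

====================  =====================================================
T                     generation time, log(R0)/log(lambda) by default
R0                    net reproductive output per newborn
eta_e, var_eta_e      mean / variance of cohort life expectancy
L_max                 age by which 99% of a cohort has died
L_alpha               mean age at first reproduction (conditional on maturing)
L_alpha_omega         mean remaining life expectancy at first reproduction
p_R                   probability of reproducing before dying
s_lx, s_mx            shape of survivorship / reproduction over age, in
                      [-0.5, +0.5]; 0 = constant with age, > 0 = declining
S                     degree of parity: entropy of the age distribution of
                      reproduction; 0 = semelparity
====================  =====================================================

Traits whose preconditions fail (e.g. no reproduction) come back as NaN
rather than raising, so downstream tables carry explicit missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .age_from_stage import (
    default_start_distribution,
    fertility_schedule,
    fundamental_matrix,
    lifespan_moments,
    survivorship_schedule,
)
from .mpm import MatrixPopulationModel

TRAIT_NAMES = (
    "T",
    "R0",
    "eta_e",
    "var_eta_e",
    "L_max",
    "L_alpha",
    "L_alpha_omega",
    "p_R",
    "s_lx",
    "s_mx",
    "S",
)


@dataclass(frozen=True)
class LifeHistoryTraits:
    T: float
    R0: float
    eta_e: float
    var_eta_e: float
    L_max: float
    L_alpha: float
    L_alpha_omega: float
    p_R: float
    s_lx: float
    s_mx: float
    S: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Rates and timings
# ---------------------------------------------------------------------------


def net_reproductive_rate(U: np.ndarray, F: np.ndarray) -> float:
    """R0: dominant eigenvalue of F (I - U)^-1 — lifetime offspring per
    newborn of the average individual."""
    F = np.asarray(F, dtype=float)
    if not np.any(F):
        return 0.0
    N = fundamental_matrix(U).N
    vals = np.linalg.eigvals(F @ N)
    return float(np.max(vals.real))


def generation_time(
    U: np.ndarray, F: np.ndarray, method: str = "r0", A: np.ndarray | None = None
) -> float:
    """Generation time T.

    ``method='r0'`` (default): T = log(R0)/log(lambda), the time for the
    population to grow by its net reproductive rate.  ``method='abar'``:
    mean age of mothers at the stable stage structure,
    T = lambda v'w / (v' F w).  Returns NaN when both lambda and R0 are 1
    (0/0) or when either is nonpositive.
    """
    from .perturbation import eigen_structure  # local import, avoids cycle

    A_full = (np.asarray(U, float) + np.asarray(F, float)) if A is None else A
    es = eigen_structure(A_full, check=False)
    lam = es.lam
    if method == "abar":
        denom = float(es.v @ np.asarray(F, float) @ es.w)
        if denom <= 0:
            return float("nan")
        return float(lam * (es.v @ es.w) / denom)
    if method != "r0":
        raise ValueError(f"unknown generation-time method {method!r}")
    R0 = net_reproductive_rate(U, F)
    if R0 <= 0 or lam <= 0:
        return float("nan")
    if abs(np.log(lam)) < 1e-12:
        return float("nan") if abs(np.log(R0)) < 1e-12 else float("inf")
    return float(np.log(R0) / np.log(lam))


def max_longevity(
    U: np.ndarray, start_distribution: np.ndarray, xmax: int = 10_000
) -> int:
    """L_max: smallest age x at which survivorship drops strictly below 1%
    (more than 99% of the cohort has died)."""
    lx = survivorship_schedule(U, start_distribution, xmax=xmax, cutoff=0.0)
    below = np.nonzero(lx < 0.01)[0]
    if not below.size:
        raise ValueError(
            f"survivorship still >= 1% at age {xmax}; increase xmax"
        )
    return int(below[0])


# ---------------------------------------------------------------------------
# Maturation: absorbing chain with reproductive stages made absorbing
# ---------------------------------------------------------------------------


def reproductive_stages(F: np.ndarray) -> np.ndarray:
    """Indices of reproductive stages: columns of F with positive sum."""
    return np.nonzero(np.asarray(F, float).sum(axis=0) > 0)[0]


def _maturation_chain(U: np.ndarray, F: np.ndarray):
    """Split U into transient (pre-reproductive) and reproductive blocks."""
    U = np.asarray(U, dtype=float)
    repro = reproductive_stages(F)
    if repro.size == 0:
        raise ValueError("no reproductive stage: every column of F is zero")
    mask = np.zeros(U.shape[0], dtype=bool)
    mask[repro] = True
    B = U[np.ix_(~mask, ~mask)]  # transient -> transient
    R = U[np.ix_(mask, ~mask)]  # transient -> reproductive
    return mask, B, R


def maturity_probability(
    U: np.ndarray, F: np.ndarray, start_distribution: np.ndarray
) -> float:
    """p_R: probability of entering a reproductive stage before death."""
    c = np.asarray(start_distribution, dtype=float)
    mask, B, R = _maturation_chain(U, F)
    p = float(c[mask].sum())  # mass born mature
    if (~mask).any():
        ct = c[~mask]
        nt = np.linalg.solve(np.eye(B.shape[0]) - B, ct)
        p += float(R.sum(axis=0) @ nt)
    return min(p, 1.0)


def age_at_maturity(
    U: np.ndarray, F: np.ndarray, start_distribution: np.ndarray
) -> float:
    """L_alpha: mean age at first entry into a reproductive stage, over the
    individuals that mature (mean absorption time of the conditioned chain).

    Mass starting in a reproductive stage matures at age 0.
    """
    c = np.asarray(start_distribution, dtype=float)
    mask, B, R = _maturation_chain(U, F)
    p_direct = float(c[mask].sum())
    if not (~mask).any():
        return 0.0
    ct = c[~mask]
    k = B.shape[0]
    # a_j: absorption probability from transient stage j
    a = np.linalg.solve((np.eye(k) - B).T, R.sum(axis=0))
    p_mature = p_direct + float(a @ ct)
    if p_mature <= 0:
        raise ValueError("maturity probability is zero")
    # Doob transform: chain conditioned on eventual maturation
    pos = a > 0
    Bc = B[np.ix_(pos, pos)] * (a[pos][:, None] / a[pos][None, :])
    m = np.linalg.solve((np.eye(int(pos.sum())) - Bc).T, np.ones(int(pos.sum())))
    mean_t = np.zeros(k)
    mean_t[pos] = m
    # directly-mature starting mass (p_direct) contributes age 0
    return float((a * ct) @ mean_t) / p_mature


def reproductive_window(
    U: np.ndarray, F: np.ndarray, start_distribution: np.ndarray
) -> float:
    """L_alpha_omega: mean remaining life expectancy at the moment of first
    entry into a reproductive stage (the average span over which an
    individual can reproduce)."""
    c = np.asarray(start_distribution, dtype=float)
    mask, B, R = _maturation_chain(U, F)
    n = U.shape[0]
    # entry distribution over reproductive stages
    entry = np.array(c[mask], dtype=float)
    if (~mask).any():
        ct = c[~mask]
        nt = np.linalg.solve(np.eye(B.shape[0]) - B, ct)
        entry = entry + R @ nt
    total = float(entry.sum())
    if total <= 0:
        raise ValueError("maturity probability is zero")
    entry /= total
    N = fundamental_matrix(U).N
    eta_by_stage = np.ones(n) @ N  # remaining expectancy per starting stage
    return float(entry @ eta_by_stage[mask])


# ---------------------------------------------------------------------------
# Shape statistics and parity
# ---------------------------------------------------------------------------


def shape_survivorship(lx: np.ndarray) -> float:
    """s_lx: shape of the survivorship curve, in [-0.5, +0.5].

    Ages with lx > 0 are standardized to [0, 1] and log-survivorship to
    g = log lx / log lx_last; s_lx = 0.5 minus the trapezoid area under g.
    Constant per-step survival (exponential lx) gives exactly 0; survival
    falling with age (senescence) gives s_lx > 0.  NaN when the retained
    curve shows no mortality at all.
    """
    lx = np.asarray(lx, dtype=float)
    keep = lx > 0
    lx = lx[keep]
    if len(lx) < 3:
        raise ValueError("need at least 3 ages with lx > 0")
    if lx[-1] >= 1.0:
        return float("nan")
    x = np.arange(len(lx), dtype=float)
    xs = x / x[-1]
    g = np.log(lx) / np.log(lx[-1])
    return float(0.5 - np.trapezoid(g, xs))


def shape_reproduction(lx: np.ndarray, mx: np.ndarray) -> float:
    """s_mx: shape of reproduction over age, in [-0.5, +0.5].

    The cumulative reproduction M(x) over the ages with lx > 0 is
    standardized to [0, 1] against a time axis on which age-x reproduction
    has accrued by the end of interval x (the curve starts at (0, 0)); s_mx
    is the area under the standardized curve minus 0.5.  Constant mx gives
    exactly 0; early-concentrated reproduction gives s_mx > 0.
    """
    lx = np.asarray(lx, dtype=float)
    mx = np.asarray(mx, dtype=float)
    keep = (lx > 0) & np.isfinite(mx)
    mx = mx[keep]
    if len(mx) < 3:
        raise ValueError("need at least 3 ages with defined mx")
    M = np.cumsum(mx)
    if M[-1] <= 0:
        raise ValueError("total reproduction is zero")
    k = len(mx)
    t = np.concatenate([[0.0], (np.arange(k) + 1.0) / k])
    h = np.concatenate([[0.0], M / M[-1]])
    return float(np.trapezoid(h, t) - 0.5)


def degree_of_parity(lx: np.ndarray, mx: np.ndarray) -> float:
    """S: Shannon entropy (natural log) of the age distribution of
    reproduction p_x = lx mx / sum(lx mx); 0 = strict semelparity."""
    lx = np.asarray(lx, dtype=float)
    mx = np.asarray(mx, dtype=float)
    keep = (lx > 0) & np.isfinite(mx)
    r = lx[keep] * mx[keep]
    total = r.sum()
    if total <= 0:
        raise ValueError("total reproduction is zero")
    p = r[r > 0] / total
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalizes -0.0


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def compute_all_traits(
    mpm: MatrixPopulationModel,
    start_distribution: np.ndarray | None = None,
    generation_time_method: str = "r0",
) -> LifeHistoryTraits:
    """All eleven traits for one (annualized) MPM.

    Components whose preconditions fail (no reproduction, undefined shapes)
    are returned as NaN; these propagate downstream as missing values and
    feed the imputation step.  Shape statistics and parity are computed on
    schedules truncated at L_max, so late-life plateaus supported by a
    vanishing fraction of the cohort cannot distort them.
    """
    U, F = mpm.U, mpm.F
    c = default_start_distribution(F) if start_distribution is None else np.asarray(
        start_distribution, dtype=float
    )
    nan = float("nan")
    out = {k: nan for k in TRAIT_NAMES}

    try:
        out["eta_e"], out["var_eta_e"] = lifespan_moments(U, c)
    except Exception:
        pass
    try:
        out["L_max"] = float(max_longevity(U, c))
    except Exception:
        pass
    try:
        out["R0"] = net_reproductive_rate(U, F)
    except Exception:
        pass
    try:
        out["T"] = generation_time(U, F, method=generation_time_method, A=mpm.A)
    except Exception:
        pass
    has_repro = reproductive_stages(F).size > 0
    if has_repro:
        try:
            out["p_R"] = maturity_probability(U, F, c)
            out["L_alpha"] = age_at_maturity(U, F, c)
            out["L_alpha_omega"] = reproductive_window(U, F, c)
        except Exception:
            pass

    sched = fertility_schedule(U, F, c)
    lx, mx = sched.lx, sched.mx
    if np.isfinite(out["L_max"]):
        stop = int(out["L_max"]) + 1
        lx, mx = lx[:stop], mx[:stop]
    try:
        out["s_lx"] = shape_survivorship(lx)
    except Exception:
        pass
    if has_repro:
        try:
            out["s_mx"] = shape_reproduction(lx, mx)
        except Exception:
            pass
        try:
            out["S"] = degree_of_parity(lx, mx)
        except Exception:
            pass
    return LifeHistoryTraits(**out)
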