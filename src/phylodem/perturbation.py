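"""Asymptotic structure, mean vital rates, elasticities and transients.

Everything here presumes the ergodicity gate: the matrix must be
irreducible, primitive and ergodic so that a single real dominant
eigenvalue exists and the asymptotic quantities are well defined.  Gate
failures raise :class:`GateError`; :func:`summarize` converts them into a
row of NaNs with a ``gate_reason``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .mpm import MatrixPopulationModel, check_ergodicity


class GateError(ValueError):
    """The matrix fails the irreducible/primitive/ergodic gate."""


@dataclass(frozen=True)
class EigenStructure:
    """Dominant eigen-structure of a projection matrix.

    ``lam``: dominant eigenvalue (asymptotic growth rate);
    ``w``: stable stage distribution (right eigenvector, sums to 1);
    ``v``: reproductive values (left eigenvector, scaled so v'w = 1);
    ``lam2``: subdominant eigenvalue (possibly complex; drives transients).
    """

    lam: float
    w: np.ndarray
    v: np.ndarray
    lam2: complex


def _gate_reason(A: np.ndarray) -> str | None:
    flags = check_ergodicity(A)
    if not flags["irreducible"]:
        return "reducible"
    if not flags["primitive"]:
        return "imprimitive"
    if not flags["ergodic"]:
        return "non-ergodic"
    return None


def eigen_structure(A: np.ndarray, check: bool = True) -> EigenStructure:
    """Dominant eigenvalue and left/right eigenvectors of ``A``.

    With ``check=True`` (default) the ergodicity gate is enforced first.
    """
    A = np.asarray(A, dtype=float)
    if check:
        reason = _gate_reason(A)
        if reason is not None:
            raise GateError(f"matrix fails the ergodicity gate: {reason}")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    k = order[0]
    lam = float(vals[k].real)
    w = vecs[:, k].real
    w = np.abs(w) / np.abs(w).sum()

    lvals, lvecs = np.linalg.eig(A.T)
    kl = int(np.argmax(np.abs(lvals)))
    v = lvecs[:, kl].real
    v = np.abs(v)
    vw = float(v @ w)
    if vw > 0:
        v = v / vw

    # subdominant eigenvalue: second-largest modulus; of a conjugate pair,
    # report the member with positive imaginary part
    lam2 = complex(vals[order[1]]) if len(vals) > 1 else complex(0.0)
    ties = vals[np.isclose(np.abs(vals), abs(lam2), rtol=1e-12)]
    with_pos = ties[ties.imag > 0]
    if with_pos.size:
        lam2 = complex(with_pos[0])
    return EigenStructure(lam=lam, w=w, v=v, lam2=lam2)


def deviance_from_equilibrium(lam: float) -> float:
    """|1 - lambda|: distance of the growth rate from demographic
    equilibrium (the quantity the social-buffering hypothesis expects to
    shrink with sociality)."""
    return abs(1.0 - lam)


# ---------------------------------------------------------------------------
# Vital rates
# ---------------------------------------------------------------------------


def stage_vital_rates(U: np.ndarray, F: np.ndarray):
    """Per-stage vital rates from the U/F split.

    sigma_j: survival (column sum of U); gamma_j / rho_j: probability of
    growing (below-diagonal mass) / shrinking (above-diagonal mass)
    conditional on survival; phi_j: per-capita reproduction (column sum of
    F).  Stages with sigma_j = 0 get gamma = rho = 0.
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    sigma = U.sum(axis=0)
    lower = np.tril(U, -1).sum(axis=0)
    upper = np.triu(U, 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(sigma > 0, lower / np.where(sigma > 0, sigma, 1), 0.0)
        rho = np.where(sigma > 0, upper / np.where(sigma > 0, sigma, 1), 0.0)
    phi = F.sum(axis=0)
    return sigma, gamma, rho, phi


def mean_vital_rates(
    U: np.ndarray, F: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float]:
    """Stable-structure-weighted mean vital rates (sigma, gamma, rho, phi).

    sigma and phi average over all stages with weights ``w``; gamma and rho
    are conditional on survival, so they average only over stages with
    sigma_j > 0, with the weights renormalized over those stages.
    """
    sigma, gamma, rho, phi = stage_vital_rates(U, F)
    w = np.asarray(w, dtype=float)
    sigma_bar = float(w @ sigma)
    phi_bar = float(w @ phi)
    alive = sigma > 0
    if alive.any() and w[alive].sum() > 0:
        wa = w[alive] / w[alive].sum()
        gamma_bar = float(wa @ gamma[alive])
        rho_bar = float(wa @ rho[alive])
    else:
        gamma_bar = rho_bar = 0.0
    return sigma_bar, gamma_bar, rho_bar, phi_bar


# ---------------------------------------------------------------------------
# Elasticities
# ---------------------------------------------------------------------------


def element_elasticities(A: np.ndarray, es: EigenStructure | None = None) -> np.ndarray:
    """Element-level elasticities e_ij = a_ij v_i w_j / (lambda v'w).

    They sum to one: lambda is homogeneous of degree one in the a_ij.
    """
    A = np.asarray(A, dtype=float)
    es = eigen_structure(A) if es is None else es
    S = np.outer(es.v, es.w) / float(es.v @ es.w)  # sensitivities
    return A * S / es.lam


def elasticities(
    A: np.ndarray, U: np.ndarray, F: np.ndarray
) -> tuple[float, float, float, float]:
    """Elasticities of lambda to the four vital rates (E_sigma, E_gamma,
    E_rho, E_phi).

    Each column j of U is parameterized as sigma_j times a conditional
    transition distribution split into growth (below diagonal), shrinkage
    (above diagonal) and stasis (diagonal).  A survival perturbation scales
    the whole column of U; growth/shrinkage perturbations scale the
    respective conditional mass, compensated from stasis; a reproduction
    perturbation scales the column of F.  Summing the chain rule over
    stages gives:

        E_sigma = sum of U-element elasticities
        E_phi   = sum of F-element elasticities
        E_gamma = sum of below-diagonal U elasticities
                  - sum_j (below-diag mass_j) * s_jj / lambda
        E_rho   = likewise with the above-diagonal mass

    where s_ij = v_i w_j / v'w is the sensitivity of lambda.
    """
    A = np.asarray(A, dtype=float)
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    es = eigen_structure(A)
    S = np.outer(es.v, es.w) / float(es.v @ es.w)
    eU = U * S / es.lam
    eF = F * S / es.lam
    E_sigma = float(eU.sum())
    E_phi = float(eF.sum())
    s_diag = np.diag(S)
    lower_mass = np.tril(U, -1).sum(axis=0)
    upper_mass = np.triu(U, 1).sum(axis=0)
    E_gamma = float(np.tril(eU, -1).sum() - (lower_mass * s_diag).sum() / es.lam)
    E_rho = float(np.triu(eU, 1).sum() - (upper_mass * s_diag).sum() / es.lam)
    return E_sigma, E_gamma, E_rho, E_phi


def perturbed_matrices(
    U: np.ndarray, F: np.ndarray, rate: str, eps: float
) -> np.ndarray:
    """Rebuild A after a relative perturbation (1 + eps) of one vital rate
    applied simultaneously in every stage.

    The finite-difference oracle for :func:`elasticities`: the central
    difference of log(lambda) over log(1 + eps) equals the summed
    elasticity of that rate.
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    if rate == "phi":
        return U + F * (1 + eps)
    if rate == "sigma":
        return U * (1 + eps) + F
    lower = np.tril(U, -1)
    upper = np.triu(U, 1)
    diag = np.diag(np.diag(U))
    if rate == "gamma":
        # scale growth mass, compensate from stasis to hold survival fixed
        newdiag = np.diag(np.diag(diag) - eps * lower.sum(axis=0))
        return lower * (1 + eps) + upper + newdiag + F
    if rate == "rho":
        newdiag = np.diag(np.diag(diag) - eps * upper.sum(axis=0))
        return lower + upper * (1 + eps) + newdiag + F
    raise ValueError(f"unknown vital rate {rate!r}")


# ---------------------------------------------------------------------------
# Transients
# ---------------------------------------------------------------------------


def transient_metrics(
    A: np.ndarray, es: EigenStructure | None = None
) -> tuple[float, float, float, float]:
    """(zeta, Pi, reactivity, attenuation).

    zeta = lambda/|lambda_2|: damping ratio, the asymptotic rate of decay
    of deviations from the stable structure (>= 1).  Pi = 2*pi/|arg
    lambda_2|: period of the transient oscillation (infinite when lambda_2
    is real positive).  Reactivity and first-step attenuation are the
    largest and smallest one-step amplifications of total population size
    in the lambda-standardized model A/lambda, i.e. its max and min column
    sums; they straddle 1.
    """
    A = np.asarray(A, dtype=float)
    es = eigen_structure(A) if es is None else es
    lam2 = es.lam2
    zeta = es.lam / abs(lam2) if abs(lam2) > 0 else float("inf")
    theta = abs(np.angle(lam2))
    Pi = float(2 * np.pi / theta) if theta > 1e-12 else float("inf")
    Ahat = A / es.lam
    colsums = Ahat.sum(axis=0)
    return float(zeta), Pi, float(colsums.max()), float(colsums.min())


# ---------------------------------------------------------------------------
# Summary assembly
# ---------------------------------------------------------------------------

SUMMARY_FIELDS = (
    "lam",
    "deviance",
    "sigma_bar",
    "gamma_bar",
    "rho_bar",
    "phi_bar",
    "E_sigma",
    "E_gamma",
    "E_rho",
    "E_phi",
    "zeta",
    "Pi",
    "reactivity",
    "attenuation",
)


@dataclass(frozen=True)
class DemographicSummary:
    lam: float
    deviance: float
    sigma_bar: float
    gamma_bar: float
    rho_bar: float
    phi_bar: float
    E_sigma: float
    E_gamma: float
    E_rho: float
    E_phi: float
    zeta: float
    Pi: float
    reactivity: float
    attenuation: float
    gate_reason: str | None = None

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d


def summarize(mpm: MatrixPopulationModel) -> DemographicSummary:
    """Full asymptotic/elasticity/transient summary for one MPM.

    Matrices failing the ergodicity gate yield NaNs plus the gate reason
    (reducible / imprimitive / non-ergodic); life-history traits are
    unaffected by the gate and live in :mod:`phylodem.life_history`.
    """
    A, U, F = mpm.A, mpm.U, mpm.F
    reason = _gate_reason(A)
    nan = float("nan")
    if reason is not None:
        return DemographicSummary(
            *([nan] * len(SUMMARY_FIELDS)), gate_reason=reason
        )
    es = eigen_structure(A, check=False)
    sigma_bar, gamma_bar, rho_bar, phi_bar = mean_vital_rates(U, F, es.w)
    E_sigma, E_gamma, E_rho, E_phi = elasticities(A, U, F)
    zeta, Pi, reactivity, attenuation = transient_metrics(A, es)
    return DemographicSummary(
        lam=es.lam,
        deviance=deviance_from_equilibrium(es.lam),
        sigma_bar=sigma_bar,
        gamma_bar=gamma_bar,
        rho_bar=rho_bar,
        phi_bar=phi_bar,
        E_sigma=E_sigma,
        E_gamma=E_gamma,
        E_rho=E_rho,
        E_phi=E_phi,
        zeta=zeta,
        Pi=Pi,
        reactivity=reactivity,
        attenuation=attenuation,
        gate_reason=None,
    )
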