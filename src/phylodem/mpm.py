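"""Matrix population model (MPM) container, validation and selection.

An MPM projects a stage-structured population over one time step:
``n(t+1) = A n(t)`` with ``A = U + F``, where ``U`` holds stage-specific
survival/transition rates and ``F`` per-capita reproduction.  Columns index
the source stage and rows the destination stage, so ``A[i, j]`` is the
per-capita contribution of stage ``j`` to stage ``i`` over one projection
interval (the COMADRE orientation; every downstream formula assumes it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

#: tolerance for the A = U + F identity and column-survival checks;
#: published MPMs rarely carry more than six significant digits.
DECOMPOSITION_TOL = 1e-9


class MPMValidationError(ValueError):
    """Raised when matrices violate the structural invariants of an MPM."""


@dataclass(frozen=True)
class MatrixPopulationModel:
    """One matrix population model plus the study metadata used for selection.

    Parameters
    ----------
    A, U, F
        Square nonnegative matrices of identical dimension with
        ``A = U + F``.
    stage_labels
        Ordered stage names; order encodes development (later = more
        developed), which defines growth vs shrinkage downstream.
    interval
        Projection interval ``P`` in years.
    species_id
        Species identifier (ties the model to trees and trait tables).
    wild, unmanipulated, extant
        Study metadata used by :func:`select_mpms`.
    """

    A: np.ndarray
    U: np.ndarray
    F: np.ndarray
    stage_labels: tuple[str, ...] = ()
    interval: float = 1.0
    species_id: str = ""
    wild: bool = True
    unmanipulated: bool = True
    extant: bool = True

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "U", np.asarray(self.U, dtype=float))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if not self.stage_labels:
            n = self.A.shape[0] if self.A.ndim == 2 else 0
            object.__setattr__(
                self, "stage_labels", tuple(f"stage_{k + 1}" for k in range(n))
            )
        else:
            object.__setattr__(self, "stage_labels", tuple(self.stage_labels))

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    @property
    def has_split(self) -> bool:
        """Whether a U/F decomposition is available (F not degenerate)."""
        return self.U is not None and self.F is not None

    def survival_column_sums(self) -> np.ndarray:
        return self.U.sum(axis=0)


def validate_mpm(
    A: np.ndarray,
    U: np.ndarray,
    F: np.ndarray,
    P: float = 1.0,
    *,
    stage_labels: Sequence[str] | None = None,
    species_id: str = "",
    **metadata,
) -> MatrixPopulationModel:
    """Validate matrices and return a :class:`MatrixPopulationModel`.

    Enforces: square matrices of one common dimension, nonnegative entries,
    ``A = U + F`` within :data:`DECOMPOSITION_TOL`, column survival sums of
    ``U`` at most 1 (survival above 1 inflates longevity estimates), and
    ``P > 0``.

    Raises
    ------
    MPMValidationError
        On any violated invariant, with a message naming the offending check.
    """
    A = np.asarray(A, dtype=float)
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    for name, M in (("A", A), ("U", U), ("F", F)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise MPMValidationError(f"matrix {name} is not square: shape {M.shape}")
    if not (A.shape == U.shape == F.shape):
        raise MPMValidationError(
            f"dimension mismatch: A {A.shape}, U {U.shape}, F {F.shape}"
        )
    for name, M in (("A", A), ("U", U), ("F", F)):
        if not np.all(np.isfinite(M)):
            raise MPMValidationError(f"matrix {name} has non-finite entries")
        if np.any(M < 0):
            raise MPMValidationError(f"matrix {name} has negative entries")
    if not P > 0:
        raise MPMValidationError(f"projection interval must be positive, got {P}")
    gap = np.max(np.abs(A - (U + F))) if A.size else 0.0
    if gap > DECOMPOSITION_TOL:
        raise MPMValidationError(
            f"A differs from U + F by up to {gap:.3g} (> {DECOMPOSITION_TOL:g})"
        )
    colsums = U.sum(axis=0)
    bad = np.nonzero(colsums > 1 + DECOMPOSITION_TOL)[0]
    if bad.size:
        labels = list(stage_labels) if stage_labels else None
        which = labels[bad[0]] if labels else f"column {bad[0]}"
        raise MPMValidationError(
            f"survival exceeds 1 in {which} (column sum {colsums[bad[0]]:.6g})"
        )
    if stage_labels is not None and len(stage_labels) != A.shape[0]:
        raise MPMValidationError(
            f"{len(stage_labels)} stage labels for dimension {A.shape[0]}"
        )
    return MatrixPopulationModel(
        A=A,
        U=U,
        F=F,
        stage_labels=tuple(stage_labels) if stage_labels else (),
        interval=float(P),
        species_id=species_id,
        **metadata,
    )


# ---------------------------------------------------------------------------
# Study selection
# ---------------------------------------------------------------------------

#: selection criteria in the order they are reported for rejected records
CRITERIA = ("wild/unmanipulated", "dimension", "split", "survival", "extant")


def _first_violation(m: MatrixPopulationModel, min_dim: int) -> str | None:
    if not (m.wild and m.unmanipulated):
        return "wild/unmanipulated"
    if m.dim < min_dim:
        return "dimension"
    if not m.has_split or (m.U.size and not np.any(m.U + m.F)):
        return "split"
    if np.any(m.survival_column_sums() > 1 + DECOMPOSITION_TOL):
        return "survival"
    if not m.extant:
        return "extant"
    return None


def select_mpms(
    records: Sequence, min_dim: int = 4
) -> tuple[list, list[tuple[str, str]]]:
    """Filter records by the study-inclusion criteria.

    Retains only models that are (i) from wild, unmanipulated populations,
    (ii) of dimension >= ``min_dim`` (enough stages to resolve age-specific
    patterns), (iii) with a U/F split, (iv) with stage survival column sums
    <= 1, and (v) from extant species.  Records failing more than one
    criterion are logged with the first violated criterion only, in the
    order of :data:`CRITERIA`.

    Accepts either :class:`MatrixPopulationModel` objects or any object with
    an ``mpm`` attribute (e.g. :class:`~phylodem.synthetic.SpeciesRecord`).

    Returns
    -------
    (retained, rejection_log)
        ``retained`` preserves input order; ``rejection_log`` is a list of
        ``(species_id, reason)`` pairs.
    """
    retained, log = [], []
    for rec in records:
        m = rec.mpm if hasattr(rec, "mpm") else rec
        reason = _first_violation(m, min_dim)
        if reason is None:
            retained.append(rec)
        else:
            log.append((m.species_id, reason))
    return retained, log


# ---------------------------------------------------------------------------
# Annualization and averaging
# ---------------------------------------------------------------------------


def rescale_to_annual(mpm: MatrixPopulationModel) -> MatrixPopulationModel:
    """Rescale an MPM to an annual projection interval.

    Every element ``a_ij`` is replaced by ``a_ij ** (1/P)``; the resulting
    interval is 1 year.  Idempotent once ``P == 1``.
    """
    P = mpm.interval
    if P == 1.0:
        return mpm
    e = 1.0 / P
    return replace(mpm, A=mpm.A**e, U=mpm.U**e, F=mpm.F**e, interval=1.0)


def grand_mean(mpms: Sequence[MatrixPopulationModel]) -> MatrixPopulationModel:
    """Element-by-element arithmetic mean of several MPMs for one species.

    All models must share dimension and stage labels.  Metadata are taken
    from the first model; the result is re-validated.
    """
    if not mpms:
        raise ValueError("grand_mean needs at least one MPM")
    first = mpms[0]
    for m in mpms[1:]:
        if m.dim != first.dim:
            raise MPMValidationError(
                f"grand_mean dimension mismatch: {m.dim} vs {first.dim}"
            )
        if m.stage_labels != first.stage_labels:
            raise MPMValidationError("grand_mean stage-label mismatch")
        if m.interval != first.interval:
            raise MPMValidationError("grand_mean projection-interval mismatch")
    A = np.mean([m.A for m in mpms], axis=0)
    U = np.mean([m.U for m in mpms], axis=0)
    F = np.mean([m.F for m in mpms], axis=0)
    return validate_mpm(
        A,
        U,
        F,
        first.interval,
        stage_labels=first.stage_labels,
        species_id=first.species_id,
        wild=first.wild,
        unmanipulated=first.unmanipulated,
        extant=first.extant,
    )


def choose_representative(mpms: Sequence[MatrixPopulationModel]) -> MatrixPopulationModel:
    """Pick the single most representative model among several studies.

    Cross-study tie-break used when one species has several candidate
    studies: prefer the greatest matrix dimension, then the first in input
    order.  This is a helper for callers that curate multi-study species;
    :func:`grand_mean` itself averages whatever it is given.
    """
    return max(mpms, key=lambda m: m.dim)


# ---------------------------------------------------------------------------
# Ergodicity gate
# ---------------------------------------------------------------------------


def check_ergodicity(A: np.ndarray, tol: float = 1e-12) -> dict[str, bool]:
    """Classify a nonnegative matrix as irreducible / primitive / ergodic.

    * irreducible: the digraph of positive entries is strongly connected;
    * primitive: irreducible and aperiodic (gcd of cycle lengths 1), so a
      single dominant eigenvalue strictly exceeds all others in modulus;
    * ergodic: the stage structure converges to the same stable form from
      any starting condition — operationally, the left eigenvector of the
      dominant eigenvalue is strictly positive.

    Asymptotic, elasticity and transient metrics are only meaningful when
    all three hold (the gate used by :mod:`phylodem.perturbation`).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    src, dst = np.nonzero(A.T > tol)  # A[i, j]: j -> i
    G.add_edges_from(zip(src, dst))
    irreducible = nx.is_strongly_connected(G)
    primitive = irreducible and nx.is_aperiodic(G)

    # left eigenvector of the modulus-dominant eigenvalue
    vals, vecs = np.linalg.eig(A.T)
    k = int(np.argmax(np.abs(vals)))
    v = vecs[:, k]
    v = np.real(v * np.sign(v[np.argmax(np.abs(v))].real or 1.0))
    vmax = np.max(np.abs(v))
    ergodic = bool(vmax > 0 and np.all(v / vmax > 1e-10))
    return {"irreducible": irreducible, "primitive": primitive, "ergodic": ergodic}


def passes_gate(A: np.ndarray) -> bool:
    """True when A is irreducible, primitive and ergodic."""
    flags = check_ergodicity(A)
    return flags["irreducible"] and flags["primitive"] and flags["ergodic"]
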