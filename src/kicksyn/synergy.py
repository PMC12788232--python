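"""Non-negative matrix factorization of muscle activity and VAF order selection.

The activation matrix D (muscles x time) is decomposed as D ~ W·C with
non-negative synergy weights W (muscles x k, unit-norm columns) and
activation coefficients C (k x time).  The solver is Lee-Seung multiplicative
updates for the squared Frobenius loss, restarted from several seeded random
initializations with the best fit kept.  Model order is the smallest synergy
count whose variance accounted for,

    VAF = 1 - SSE / SST,   SSE = sum (D - WC)^2,   SST = sum D^2,

reaches the configured threshold (default 90 %).  SST is uncentered, the
usual convention for non-negative envelope data; a mean-centered variant is
available by flag.  Within a fitted model, synergies are numbered by
ascending coefficient peak time (SYN1 peaks first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import ActivationMatrix

__all__ = [
    "VafReport",
    "SynergyModel",
    "SynergyMatch",
    "OrderSelectionError",
    "compute_vaf",
    "nmf_fit",
    "vaf_curve",
    "select_order",
    "match_synergies",
]

_EPS = 1e-12


@dataclass(frozen=True)
class VafReport:
    sse: float
    sst: float
    vaf: float

    @property
    def vaf_percent(self) -> float:
        return 100.0 * self.vaf


@dataclass(frozen=True)
class SynergyModel:
    """Fitted factorization with unit-norm weight columns."""

    weights: np.ndarray        # muscles x order
    coefficients: np.ndarray   # order x n_points
    order: int
    vaf: VafReport
    restarts_used: int = 1
    converged: bool = True
    muscle_labels: tuple[str, ...] | None = None
    #: VAF at each order tried during selection (order -> VAF fraction)
    vaf_curve: dict[int, float] = field(default_factory=dict)

    def reconstruction(self) -> np.ndarray:
        return self.weights @ self.coefficients

    def peak_times(self) -> np.ndarray:
        """Coefficient peak positions on the normalized 0-100 timeline."""
        n = self.coefficients.shape[1]
        t = np.linspace(0.0, 100.0, n)
        return t[np.argmax(self.coefficients, axis=1)]


@dataclass(frozen=True)
class SynergyMatch:
    """Bijection mapping synergies of one model onto a reference model.

    ``permutation[i]`` is the index of the other model's synergy matched to
    reference synergy ``i``; ``similarities[i]`` is the cosine similarity of
    the matched weight columns.
    """

    permutation: np.ndarray
    similarities: np.ndarray

    def __post_init__(self) -> None:
        if sorted(self.permutation.tolist()) != list(range(len(
                self.permutation))):
            raise ValueError("permutation must be a bijection")


class OrderSelectionError(RuntimeError):
    """Raised when no order up to ``max_order`` reaches the VAF threshold."""

    def __init__(self, message: str, vaf_curve: dict[int, float]):
        super().__init__(message)
        self.vaf_curve = vaf_curve


def _values(D) -> np.ndarray:
    arr = D.values if isinstance(D, ActivationMatrix) else np.asarray(
        D, dtype=float)
    if arr.ndim != 2:
        raise ValueError("D must be a 2-D matrix")
    return arr


def compute_vaf(D, reconstruction: np.ndarray,
                centered: bool = False) -> VafReport:
    """Variance accounted for by a reconstruction of D.

    Uncentered by default: SST is the sum of squared entries of D, so a zero
    reconstruction scores VAF = 0 and a perfect one VAF = 1.
    """
    Dv = _values(D)
    R = np.asarray(reconstruction, dtype=float)
    if R.shape != Dv.shape:
        raise ValueError(f"shape mismatch: D {Dv.shape} vs R {R.shape}")
    sse = float(np.sum((Dv - R) ** 2))
    sst = float(np.sum((Dv - Dv.mean()) ** 2) if centered
                else np.sum(Dv ** 2))
    if sst <= 0:
        raise ValueError("SST is zero: D carries no variance to account for")
    return VafReport(sse=sse, sst=sst, vaf=1.0 - sse / sst)


def _multiplicative_updates(D: np.ndarray, W: np.ndarray, C: np.ndarray,
                            max_iter: int, tol: float) -> tuple[
                                np.ndarray, np.ndarray, bool]:
    """Lee-Seung updates for min ||D - WC||_F^2; stops on relative change."""
    prev = np.sum((D - W @ C) ** 2)
    converged = False
    for _ in range(max_iter):
        C *= (W.T @ D) / (W.T @ W @ C + _EPS)
        W *= (D @ C.T) / (W @ (C @ C.T) + _EPS)
        err = np.sum((D - W @ C) ** 2)
        if prev > 0 and abs(prev - err) / prev < tol:
            converged = True
            break
        prev = err
    return W, C, converged


def _normalize_and_sort(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray,
                                                               np.ndarray]:
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    W = W / safe
    C = C * safe[:, None]
    # number synergies by ascending coefficient peak time
    order = np.argsort(np.argmax(C, axis=1), kind="stable")
    return W[:, order], C[order]


def nmf_fit(D, order: int, *, max_iter: int = 1000, tol: float = 1e-6,
            seed: int = 0, restarts: int = 20,
            inits: list[tuple[np.ndarray, np.ndarray]] | None = None,
            ) -> SynergyModel:
    """Fit a fixed-order factorization, keeping the best of seeded restarts.

    Each restart starts from uniform random factors in (0, 1]; optional
    explicit ``inits`` (e.g. warm starts from a lower-order solution) are
    tried in addition.  The returned model has unit-norm weight columns, with
    the scale carried by the coefficients.
    """
    Dv = _values(D)
    if (Dv < 0).any():
        raise ValueError("D must be non-negative")
    m, n = Dv.shape
    if not 1 <= order <= min(m, n):
        raise ValueError(f"order must be in [1, {min(m, n)}], got {order}")
    if Dv.max() == 0:
        raise ValueError("D is identically zero")

    rng = np.random.default_rng(seed)
    candidates: list[tuple[np.ndarray, np.ndarray]] = list(inits or [])
    scale = np.sqrt(Dv.mean() / order)
    for _ in range(restarts):
        W0 = scale * (1.0 - rng.random((m, order)))   # uniform in (0, 1]
        C0 = scale * (1.0 - rng.random((order, n)))
        candidates.append((W0, C0))

    best = None
    for W0, C0 in candidates:
        W, C, conv = _multiplicative_updates(Dv, W0.copy(), C0.copy(),
                                             max_iter, tol)
        sse = np.sum((Dv - W @ C) ** 2)
        if best is None or sse < best[0]:
            best = (sse, W, C, conv)

    _, W, C, conv = best
    W, C = _normalize_and_sort(W, C)
    report = compute_vaf(Dv, W @ C)
    labels = D.muscle_labels if isinstance(D, ActivationMatrix) else None
    return SynergyModel(weights=W, coefficients=C, order=order, vaf=report,
                        restarts_used=len(candidates), converged=conv,
                        muscle_labels=labels)


def _iter_models(D, cap: int, *, max_iter: int, tol: float, seed: int,
                 restarts: int, warm_start: bool):
    """Yield (order, model) for orders 1..cap, warm-starting each order.

    With ``warm_start`` each order adds one initialization built from the
    previous order's solution padded with a small random extra synergy, so a
    higher order can never fit worse than a lower one (up to solver
    tolerance) and the best-of-restarts VAF curve is monotone.
    """
    Dv = _values(D)
    rng = np.random.default_rng(seed)
    prev: SynergyModel | None = None
    for order in range(1, cap + 1):
        inits = None
        if warm_start and prev is not None:
            scale = 0.01 * np.sqrt(Dv.mean() / order)
            W0 = np.column_stack([prev.weights * prev.coefficients.max(),
                                  scale * rng.random(Dv.shape[0])])
            C0 = np.vstack([prev.coefficients / max(
                prev.coefficients.max(), _EPS),
                scale * rng.random(Dv.shape[1])])
            inits = [(W0, C0)]
        model = nmf_fit(D, order, max_iter=max_iter, tol=tol,
                        seed=seed + order, restarts=restarts, inits=inits)
        yield order, model
        prev = model


def vaf_curve(D, max_order: int | None = None, *, max_iter: int = 1000,
              tol: float = 1e-6, seed: int = 0, restarts: int = 20,
              warm_start: bool = True) -> dict[int, SynergyModel]:
    """Best-of-restarts model at every order from 1 to ``max_order``."""
    Dv = _values(D)
    cap = min(Dv.shape) if max_order is None else min(max_order,
                                                      min(Dv.shape))
    return dict(_iter_models(D, cap, max_iter=max_iter, tol=tol, seed=seed,
                             restarts=restarts, warm_start=warm_start))


def select_order(D, threshold: float = 0.90, max_order: int | None = None,
                 *, max_iter: int = 1000, tol: float = 1e-6, seed: int = 0,
                 restarts: int = 20, warm_start: bool = True) -> SynergyModel:
    """Smallest-order model whose VAF reaches ``threshold``.

    Orders are tried in ascending sequence with warm starts (see
    :func:`vaf_curve`).  The VAF-vs-order curve up to the selected order is
    retained on the returned model; failure to reach the threshold raises
    :class:`OrderSelectionError` carrying the curve.
    """
    Dv = _values(D)
    cap = min(Dv.shape) if max_order is None else min(max_order,
                                                      min(Dv.shape))
    curve: dict[int, float] = {}
    for order, model in _iter_models(D, cap, max_iter=max_iter, tol=tol,
                                     seed=seed, restarts=restarts,
                                     warm_start=warm_start):
        curve[order] = model.vaf.vaf
        if model.vaf.vaf >= threshold:
            return SynergyModel(
                weights=model.weights, coefficients=model.coefficients,
                order=order, vaf=model.vaf,
                restarts_used=model.restarts_used, converged=model.converged,
                muscle_labels=model.muscle_labels, vaf_curve=dict(curve))
    raise OrderSelectionError(
        f"VAF threshold {threshold} not reached by order {cap} "
        f"(best {max(curve.values()):.4f})", curve)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (A.T @ B) / denom
    return np.where(denom > 0, cos, 0.0)


def match_synergies(reference: SynergyModel,
                    other: SynergyModel) -> SynergyMatch:
    """Optimal pairing of two models' synergies by weight-column cosine.

    Solved as a linear assignment maximizing total cosine similarity; with
    non-negative weights all similarities lie in [0, 1].  Tied assignments
    resolve deterministically (earlier coefficient peak first, following the
    models' peak-time ordering).
    """
    if reference.order != other.order:
        raise ValueError(
            f"orders differ: {reference.order} vs {other.order}")
    cos = _cosine_matrix(reference.weights, other.weights)
    rows, cols = linear_sum_assignment(-cos)
    perm = np.empty(reference.order, dtype=int)
    perm[rows] = cols
    return SynergyMatch(permutation=perm,
                        similarities=cos[rows, perm[rows]])
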