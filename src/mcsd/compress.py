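"""Learning the sparse compress matrix by row-wise l1-minimization.

Given the normalized training matrix ``S`` (N probes x c samples) and a
target matrix ``Y`` (M x c) whose rows are the selected informative rows of
``S``, the compress matrix ``Phi`` (M x N) is learned one row at a time as a
basis-pursuit problem::

    min ||phi||_1   subject to   S^T phi = y_row

The linear system has c equations and N unknowns, so for N >> c it is heavily
underdetermined and the minimum-l1 solution is sparse. Because each target
row is itself a row of ``S``, the unit selector vector (1 at the target row,
0 elsewhere) is always feasible, so every learned row has l1 norm <= 1 up to
solver tolerance; the solver finds either that selector or a cheaper sparse
combination of correlated rows.

Two solvers are provided:

* ``"lp"`` (default) — basis pursuit as a linear program via the standard
  positive/negative-part split, solved with HiGHS. Exact and deterministic.
* ``"lars"`` — the homotopy / least-angle-regression path of the lasso driven
  to (near-)zero penalty, which converges to the basis-pursuit solution for
  consistent systems. Much faster for large N; used for large simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from sklearn.linear_model import lars_path

from .data_io import ExpressionMatrix
from .errors import InfeasibleError

__all__ = ["CompressMatrix", "build_target", "solve_row", "solve_compress_matrix", "project"]

#: entries below this magnitude are truncated to exact zeros for sparsity
_ZERO_TRUNC = 1e-12

SOLVERS = ("lp", "lars")


@dataclass
class RowReport:
    """Per-row solver diagnostics."""

    residual: float
    l1_norm: float
    iterations: int
    solver: str


@dataclass
class CompressMatrix:
    """Sparse M x N projection from the original to the compressed space."""

    matrix: sp.csr_matrix
    solver_report: list[RowReport] = field(default_factory=list)
    tol: float = 1e-6
    solver: str = "lp"

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def row_l1_norms(self) -> np.ndarray:
        return np.asarray(np.abs(self.matrix).sum(axis=1)).ravel()

    @classmethod
    def identity(cls, n: int) -> "CompressMatrix":
        return cls(sp.identity(n, format="csr"), [], 0.0, "identity")

    @classmethod
    def selector(cls, selected: np.ndarray, n: int) -> "CompressMatrix":
        """Rows = unit vectors at ``selected``; the uncompressed restriction."""
        selected = np.asarray(selected, dtype=int)
        m = selected.size
        mat = sp.csr_matrix(
            (np.ones(m), (np.arange(m), selected)), shape=(m, n)
        )
        return cls(mat, [], 0.0, "selector")


def _values(S) -> np.ndarray:
    if isinstance(S, ExpressionMatrix):
        return S.values
    return np.asarray(S, dtype=np.float64)


def build_target(S, selected) -> np.ndarray:
    """Target matrix Y: the selected rows of S, in selection order."""
    Sv = _values(S)
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selection is empty")
    if selected.min() < 0 or selected.max() >= Sv.shape[0]:
        raise ValueError(
            f"selected index out of range [0, {Sv.shape[0]}): "
            f"{selected.min()}..{selected.max()}"
        )
    return Sv[selected].copy()


def solve_row(
    S, y_row: np.ndarray, tol: float = 1e-6, solver: str = "lp"
) -> tuple[np.ndarray, RowReport]:
    """Minimum-l1 solution of ``S^T phi = y_row``.

    Returns the length-N coefficient vector (tiny entries truncated to 0)
    and a :class:`RowReport`. Raises :class:`InfeasibleError` when the
    constraint residual cannot be brought below ``tol``.
    """
    Sv = _values(S)
    n, c = Sv.shape
    y = np.asarray(y_row, dtype=np.float64).ravel()
    if y.size != c:
        raise ValueError(f"y_row has length {y.size}, expected {c}")
    if c >= n:
        warnings.warn(
            f"system has {c} equations for {n} unknowns; no compression benefit",
            stacklevel=2,
        )
    if np.all(y == 0.0):
        return np.zeros(n), RowReport(0.0, 0.0, 0, solver)

    A = Sv.T  # c x n
    used = solver
    if solver == "lars":
        # homotopy fast path; rare path degeneracies fall back to the LP
        try:
            _, _, coefs = lars_path(A, y, method="lasso", alpha_min=0.0)
            phi = coefs[:, -1]
            iters = coefs.shape[1]
        except Exception:
            phi, iters = None, 0
        if phi is None or float(np.linalg.norm(A @ phi - y)) > tol:
            used = "lars+lp"
            phi, iters = _solve_lp(A, y)
    elif solver == "lp":
        phi, iters = _solve_lp(A, y)
    else:
        raise ValueError(f"unknown solver {solver!r}; choose from {SOLVERS}")

    residual = float(np.linalg.norm(A @ phi - y))
    if residual > tol:
        raise InfeasibleError(
            f"constraint residual {residual:.3e} exceeds tol {tol:.3e}"
        )
    phi[np.abs(phi) < _ZERO_TRUNC] = 0.0
    return phi, RowReport(residual, float(np.abs(phi).sum()), iters, used)


def _solve_lp(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Basis pursuit as a linear program (positive/negative split, HiGHS)."""
    n = A.shape[1]
    res = linprog(
        np.ones(2 * n),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=(0, None),
        method="highs",
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleError(f"LP failed (status {res.status}): {res.message}")
    return res.x[:n] - res.x[n:], int(getattr(res, "nit", 0))


def solve_compress_matrix(
    S, Y, tol: float = 1e-6, solver: str = "lp"
) -> CompressMatrix:
    """Solve every row of ``Phi S = Y`` independently.

    Row independence implies that permuting the rows of ``Y`` permutes the
    rows of ``Phi`` identically.
    """
    Sv = _values(S)
    Yv = np.asarray(Y, dtype=np.float64)
    if Yv.ndim != 2 or Yv.shape[1] != Sv.shape[1]:
        raise ValueError(
            f"Y has shape {Yv.shape}; expected (M, {Sv.shape[1]})"
        )
    rows = []
    reports = []
    for j in range(Yv.shape[0]):
        try:
            phi, rep = solve_row(Sv, Yv[j], tol=tol, solver=solver)
        except InfeasibleError as exc:
            raise InfeasibleError(f"row {j}: {exc}") from exc
        rows.append(sp.csr_matrix(phi))
        reports.append(rep)
    mat = sp.vstack(rows, format="csr")
    return CompressMatrix(mat, reports, tol, solver)


def project(phi: CompressMatrix | sp.spmatrix | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply the compress matrix: an M x N linear map on vectors or columns."""
    mat = phi.matrix if isinstance(phi, CompressMatrix) else phi
    x = np.asarray(x, dtype=np.float64)
    n = mat.shape[1]
    if x.shape[0] != n:
        raise ValueError(f"input has leading dimension {x.shape[0]}, expected {n}")
    return np.asarray(mat @ x)
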