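"""Ideal-observer Bayesian classification in the compressed space.

The model assumes expression profiles are isotropic Gaussian around a class
mean in the original (normalized) feature space: an observation ``x`` from
class ``k`` has density N(s_k, sigma^2 I_N). After projection with the
compress matrix ``Phi`` the compressed observation ``y = Phi x`` is still
Gaussian, with mean ``Phi s_k`` and covariance ``sigma^2 Phi Phi^T`` — an
M-dimensional density, so its normalizer uses the compressed dimension M.

Decisions follow the ideal observer: decide class ``l`` maximizing the
expected utility

    EU(l) = sum_k U[l, k] * P_k * p(y | class k)

where ``U[i, j]`` is the utility of deciding class ``i`` when the truth is
``j`` and ``P_k`` are the class priors. With the identity (Kronecker-delta)
utility and equal priors this reduces to maximum likelihood. All likelihood
arithmetic is carried out in log space with a shared log-sum-exp shift;
argmax ties break toward the lowest class index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy.integrate import quad
from scipy.stats import norm

from . import compress as _compress
from . import feature_selection as _fs
from .data_io import (
    AlignmentError,
    ExpressionMatrix,
    LabeledDataset,
    RowStats,
    apply_row_stats,
    normalize_rows,
)
from .compress import CompressMatrix, build_target, project, solve_compress_matrix
from .errors import InputError, SingularCovarianceError

__all__ = [
    "MCSDModel",
    "logdensity_original",
    "logdensity_compressed",
    "bayes_risk_two_class",
    "gaussian_bayes_risk",
    "identity_utility",
    "estimate_utility",
    "classify",
    "expected_utilities",
    "fit",
    "predict",
    "accuracy",
    "format_percent",
    "stability_experiment",
    "save_model",
    "load_model",
]

#: relative ridge applied to the compressed covariance when ill-conditioned
_RIDGE_EPS = 1e-10
#: condition number beyond which the covariance is declared singular
_COND_LIMIT = 1e12
#: floor on the estimated noise scale (degenerate zero-noise training data)
_SIGMA_FLOOR = 1e-8

UTILITY_METHODS = ("identity", "pairwise_br", "mc_multiclass")
SIGMA_MODES = ("pooled", "per_class")
DETECTORS = ("mcsd", "noncompressed")


# ---------------------------------------------------------------------------
# densities


def logdensity_original(y_hat: np.ndarray, s: np.ndarray, sigma: float) -> float:
    """Log of the isotropic Gaussian density N(s, sigma^2 I) at ``y_hat``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    s = np.asarray(s, dtype=np.float64).ravel()
    if y_hat.size != s.size:
        raise ValueError("dimension mismatch between observation and mean")
    n = y_hat.size
    r = y_hat - s
    return float(-0.5 * n * np.log(2 * np.pi * sigma**2) - (r @ r) / (2 * sigma**2))


def _covariance_factor(gram: np.ndarray, sigma: float):
    """Cholesky factor and log-determinant of ``sigma^2 * gram``.

    Adds a relative ridge only when the matrix is ill-conditioned, so that a
    well-conditioned covariance is factored exactly.
    """
    m = gram.shape[0]
    cov = sigma**2 * gram
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 0 or eig[-1] / max(eig[0], np.finfo(float).tiny) > _COND_LIMIT:
        tr = np.trace(cov)
        ridge = _RIDGE_EPS * (tr / m if tr > 0 else 1.0)
        cov = cov + ridge * np.eye(m)
        eig = eig + ridge
        if eig[0] <= 0 or eig[-1] / eig[0] > _COND_LIMIT:
            raise SingularCovarianceError(
                f"compressed covariance condition number {eig[-1] / max(eig[0], 0):.3e} "
                f"exceeds {_COND_LIMIT:.0e} after conditioning"
            )
    c, low = scipy.linalg.cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return (c, low), float(logdet)


def logdensity_compressed(
    y: np.ndarray,
    phi: CompressMatrix | np.ndarray,
    s: np.ndarray,
    sigma: float,
) -> float:
    """Log-density of the compressed Gaussian N(Phi s, sigma^2 Phi Phi^T).

    Computed via a symmetric (Cholesky) factorization; the normalizer uses
    the compressed dimension M so the density integrates to one on R^M.
    Reduces to :func:`logdensity_original` when Phi is the identity.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    mat = phi.matrix if isinstance(phi, CompressMatrix) else np.asarray(phi)
    y = np.asarray(y, dtype=np.float64).ravel()
    s = np.asarray(s, dtype=np.float64).ravel()
    mu = np.asarray(mat @ s, dtype=np.float64).ravel()
    m = mat.shape[0]
    if y.size != m:
        raise ValueError(f"observation has length {y.size}, expected {m}")
    gram = np.asarray((mat @ mat.T).toarray() if sp.issparse(mat) else mat @ mat.T)
    factor, logdet = _covariance_factor(gram, sigma)
    r = y - mu
    maha = float(r @ scipy.linalg.cho_solve(factor, r))
    return float(-0.5 * (m * np.log(2 * np.pi) + logdet + maha))


# ---------------------------------------------------------------------------
# Bayes risk and utility


def bayes_risk_two_class(p1_prior, p2_prior, p1, p2, y0: float) -> float:
    """Two-class one-dimensional Bayes risk by numerical quadrature.

    ``p1``/``p2`` are density callables; class 1 occupies the region below
    the decision boundary ``y0`` and class 2 the region above, so the risk is
    the class-2 mass below ``y0`` plus the class-1 mass above it, weighted by
    the priors.
    """
    if abs(p1_prior + p2_prior - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    lower = _tail_quad(p2, y0, side="left")
    upper = _tail_quad(p1, y0, side="right")
    return float(p2_prior * lower + p1_prior * upper)


def _tail_quad(p, y0: float, side: str) -> float:
    """Integrate a density over (-inf, y0] or [y0, inf).

    A single adaptive pass over a semi-infinite interval can miss a narrow
    mode far from the boundary, so the interval is cut into a geometric
    ladder of finite segments plus a far-field remainder.
    """
    sign = -1.0 if side == "left" else 1.0
    edges = y0 + sign * 2.0 ** np.arange(0, 61, dtype=np.float64)
    total, _ = quad(p, min(y0, edges[0]), max(y0, edges[0]))
    for a, b in zip(edges[:-1], edges[1:]):
        seg, _ = quad(p, min(a, b), max(a, b))
        total += seg
    far, _ = quad(p, -np.inf, edges[-1]) if side == "left" else quad(p, edges[-1], np.inf)
    return total + far


def gaussian_bayes_risk(
    p1_prior, p2_prior, mu1, sigma1, mu2, sigma2, y0: float
) -> float:
    """Closed form of :func:`bayes_risk_two_class` for Gaussian densities."""
    if abs(p1_prior + p2_prior - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    return float(
        p2_prior * norm.cdf(y0, loc=mu2, scale=sigma2)
        + p1_prior * norm.sf(y0, loc=mu1, scale=sigma1)
    )


def identity_utility(n: int) -> np.ndarray:
    """The Kronecker-delta utility of the ideal detector."""
    return np.eye(n)


def estimate_utility(
    means_compressed: np.ndarray,
    gram: np.ndarray,
    sigma: float | np.ndarray,
    priors: np.ndarray,
    method: str = "identity",
    n_mc: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Utility matrix U[i, j]: payoff for deciding class i when truth is j.

    identity
        Kronecker delta (ideal detector); reduces the decision rule to
        maximum likelihood under equal priors.
    pairwise_br
        U[i, j] = 1 - BR(i, j) off the diagonal, where BR(i, j) is the
        two-class Bayes risk between the compressed class Gaussians along
        their Fisher discriminant direction (closed form, equal pair priors,
        midpoint boundary); diagonal 1. Coincident means give BR = 1/2.
    mc_multiclass
        Monte-Carlo estimate of the decision-probability matrix
        P(decide i | truth j) under maximum-likelihood decisions: diagonal
        1 - (class-conditional error), off-diagonal the confusion mass into
        the wrong region. Approaches the identity for well-separated classes.
    """
    mu = np.asarray(means_compressed, dtype=np.float64)
    n = mu.shape[0]
    sig = float(np.mean(sigma))
    if method == "identity":
        return identity_utility(n)
    cov = sig**2 * np.asarray(gram, dtype=np.float64)
    if method == "pairwise_br":
        u = np.eye(n)
        factor, _ = _covariance_factor(np.asarray(gram), sig)
        for i in range(n):
            for j in range(i + 1, n):
                d = mu[i] - mu[j]
                if np.linalg.norm(d) < 1e-12:
                    br = 0.5
                else:
                    w = scipy.linalg.cho_solve(factor, d)
                    gap = float(w @ d)
                    sd = float(np.sqrt(w @ cov @ w))
                    # midpoint boundary between the 1-D projected means
                    br = gaussian_bayes_risk(
                        0.5, 0.5, gap / 2.0, sd, -gap / 2.0, sd, 0.0
                    )
                u[i, j] = u[j, i] = 1.0 - br
        return u
    if method == "mc_multiclass":
        if n_mc < 1000:
            raise ValueError("mc_multiclass requires n_mc >= 1000")
        if seed is None:
            raise ValueError("mc_multiclass requires an explicit seed")
        rng = np.random.default_rng(seed)
        factor, logdet = _covariance_factor(np.asarray(gram), sig)
        chol = np.linalg.cholesky(cov + _RIDGE_EPS * np.trace(cov) / n * np.eye(cov.shape[0]))
        conf = np.zeros((n, n))
        for j in range(n):
            draws = mu[j] + rng.standard_normal((n_mc, cov.shape[0])) @ chol.T
            # max-likelihood labeling (shared covariance: linear scores)
            scores = np.empty((n_mc, n))
            for k in range(n):
                r = draws - mu[k]
                scores[:, k] = -0.5 * np.einsum(
                    "ij,ij->i", r, scipy.linalg.cho_solve(factor, r.T).T
                ) + np.log(priors[k])
            decided = np.argmax(scores, axis=1)
            conf[:, j] = np.bincount(decided, minlength=n) / n_mc
        return conf
    raise ValueError(f"unknown utility method {method!r}; choose from {UTILITY_METHODS}")


# ---------------------------------------------------------------------------
# the model


@dataclass
class MCSDModel:
    """A fitted multi-class compressed-sensing detector."""

    phi: CompressMatrix
    class_means: np.ndarray  # n_classes x N, in the normalized original space
    class_means_compressed: np.ndarray  # n_classes x M
    sigma: np.ndarray  # scalar-like (pooled) or per-class, shape (n,) always
    priors: np.ndarray
    utility: np.ndarray
    class_names: list[str]
    row_stats: RowStats | None = None
    selected: np.ndarray | None = None
    probe_ids: list[str] | None = None
    config: dict = field(default_factory=dict)
    _factors: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=np.float64)
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=np.float64))
        if self.sigma.size == 1:
            self.sigma = np.full(len(self.class_names), float(self.sigma[0]))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if abs(self.priors.sum() - 1.0) > 1e-9 or np.any(self.priors < 0):
            raise ValueError("priors must be non-negative and sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def m(self) -> int:
        return self.phi.m

    def _gram(self) -> np.ndarray:
        if "gram" not in self._factors:
            mat = self.phi.matrix
            g = mat @ mat.T
            self._factors["gram"] = np.asarray(g.toarray() if sp.issparse(g) else g)
        return self._factors["gram"]

    def _class_factor(self, k: int):
        key = ("chol", k)
        if key not in self._factors:
            self._factors[key] = _covariance_factor(self._gram(), float(self.sigma[k]))
        return self._factors[key]

    def log_likelihoods(self, y: np.ndarray) -> np.ndarray:
        """Per-class compressed Gaussian log-densities at ``y``."""
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != self.m:
            raise ValueError(f"observation has length {y.size}, expected {self.m}")
        out = np.empty(self.n_classes)
        for k in range(self.n_classes):
            factor, logdet = self._class_factor(k)
            r = y - self.class_means_compressed[k]
            maha = float(r @ scipy.linalg.cho_solve(factor, r))
            out[k] = -0.5 * (self.m * np.log(2 * np.pi) + logdet + maha)
        return out


def expected_utilities(y: np.ndarray, model: MCSDModel) -> np.ndarray:
    """Per-class expected utilities, normalized by the evidence.

    EU(l) = sum_k U[l,k] P_k p_k(y) / sum_k P_k p_k(y); the normalization is
    positive and common to all candidates, so the argmax is unchanged while
    the values stay in a readable range.
    """
    logp = model.log_likelihoods(y)
    shift = logp.max()
    w = model.priors * np.exp(logp - shift)
    evidence = w.sum()
    if evidence == 0:
        return np.full(model.n_classes, np.nan)
    return (model.utility @ w) / evidence


def classify(y: np.ndarray, model: MCSDModel) -> int:
    """Maximum-expected-utility class for one compressed observation.

    Ties break toward the lowest class index.
    """
    eu = expected_utilities(y, model)
    if np.any(np.isnan(eu)):
        return 0
    return int(np.argmax(eu))


# ---------------------------------------------------------------------------
# fitting and prediction


def _pooled_sigma(X_sel: np.ndarray, y: np.ndarray, n_classes: int, mode: str) -> np.ndarray:
    """Noise scale from within-class dispersion of the selected features.

    pooled: one scale shared by all classes — the square root of the average
    (over selected features) pooled within-class variance. per_class: the
    same quantity computed class by class.
    """
    if mode == "pooled":
        ss = 0.0
        dof = 0
        for k in range(n_classes):
            Xk = X_sel[:, y == k]
            ss += ((Xk - Xk.mean(axis=1, keepdims=True)) ** 2).sum()
            dof += Xk.shape[0] * (Xk.shape[1] - 1)
        sig = np.sqrt(ss / dof) if dof > 0 else 0.0
        return np.full(n_classes, max(float(sig), _SIGMA_FLOOR))
    if mode == "per_class":
        out = np.empty(n_classes)
        for k in range(n_classes):
            Xk = X_sel[:, y == k]
            v = ((Xk - Xk.mean(axis=1, keepdims=True)) ** 2).sum() / (
                Xk.shape[0] * (Xk.shape[1] - 1)
            )
            out[k] = max(float(np.sqrt(v)), _SIGMA_FLOOR)
        return out
    raise ValueError(f"unknown sigma mode {mode!r}; choose from {SIGMA_MODES}")


def fit(
    train: LabeledDataset,
    m: int | None = None,
    *,
    solver: str = "lp",
    utility_method: str = "identity",
    sigma_mode: str = "pooled",
    priors: str = "equal",
    detector: str = "mcsd",
    tol: float = 1e-6,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> MCSDModel:
    """Fit the full detector pipeline on labeled training data.

    Steps: min-max normalize rows (training statistics retained), score and
    select the ``m`` most informative features, learn the compress matrix on
    the normalized training matrix with the selected rows as targets, then
    estimate per-class compressed means, the noise scale (pooled within-class
    standard deviation over selected features), priors and the utility matrix.

    ``detector="noncompressed"`` replaces the learned compress matrix with
    the plain selector of the chosen features (covariance sigma^2 I): the
    baseline detector operating on uncompressed selected features. With
    ``m=None`` it uses all features.
    """
    counts = train.class_counts()
    if np.any(counts < 2):
        bad = [train.class_names[k] for k in np.flatnonzero(counts < 2)]
        raise InputError(f"fit requires >=2 training samples per class; short: {bad}")
    c = train.matrix.n_samples
    n_feat = train.matrix.n_probes
    if detector not in DETECTORS:
        raise ValueError(f"unknown detector {detector!r}; choose from {DETECTORS}")
    if m is None:
        if detector == "mcsd":
            raise ValueError("the compressed detector requires an explicit m")
        m = n_feat
    if detector == "mcsd" and m > c:
        raise ValueError(
            f"compressed dimension m={m} exceeds the number of training samples "
            f"c={c}; each compress-matrix row solves a {c}-equation system, so "
            f"m <= c is required"
        )

    train_n, _, row_stats = normalize_rows(train.matrix)
    labeled_n = LabeledDataset(train_n, dict(train.labels), list(train.class_names))

    if m < n_feat:
        profiles = _fs.normalize_profile(_fs.feature_profile(labeled_n))
        selected = _fs.select_features(profiles, m)
    else:
        selected = np.arange(n_feat)

    S = train_n.values
    if detector == "mcsd":
        Y = build_target(S, selected)
        phi = solve_compress_matrix(S, Y, tol=tol, solver=solver)
    else:
        phi = CompressMatrix.selector(selected, n_feat)

    y = labeled_n.y
    n_classes = train.n_classes
    class_means = np.vstack([S[:, y == k].mean(axis=1) for k in range(n_classes)])
    means_compressed = np.vstack([project(phi, class_means[k]) for k in range(n_classes)])
    sigma = _pooled_sigma(S[selected], y, n_classes, sigma_mode)

    if priors == "equal":
        pri = np.full(n_classes, 1.0 / n_classes)
    elif priors == "empirical":
        pri = counts / counts.sum()
    else:
        raise ValueError(f"unknown priors {priors!r}")

    gram = phi.matrix @ phi.matrix.T
    gram = np.asarray(gram.toarray() if sp.issparse(gram) else gram)
    utility = estimate_utility(
        means_compressed, gram, float(np.mean(sigma)), pri,
        method=utility_method, n_mc=n_mc, seed=seed,
    )

    config = {
        "m": int(m),
        "solver": solver,
        "utility_method": utility_method,
        "sigma_mode": sigma_mode,
        "priors": priors,
        "detector": detector,
        "tol": tol,
        "n_mc": int(n_mc),
        "seed": seed,
    }
    return MCSDModel(
        phi=phi,
        class_means=class_means,
        class_means_compressed=means_compressed,
        sigma=sigma,
        priors=pri,
        utility=utility,
        class_names=list(train.class_names),
        row_stats=row_stats,
        selected=np.asarray(selected, dtype=int),
        probe_ids=list(train.matrix.probe_ids),
        config=config,
    )


def predict(model: MCSDModel, test: ExpressionMatrix) -> np.ndarray:
    """Class indices for every column of a test matrix.

    Test rows are normalized with the stored training row statistics
    (clipping into [0, 1]), projected with the learned compress matrix, and
    classified independently.
    """
    if model.probe_ids is not None and list(test.probe_ids) != list(model.probe_ids):
        raise AlignmentError("test probe ids differ from the training probes")
    test_n = apply_row_stats(test, model.row_stats) if model.row_stats else test
    Y = project(model.phi, test_n.values)  # M x n_samples
    return np.array([classify(Y[:, j], model) for j in range(Y.shape[1])], dtype=int)


def predict_table(model: MCSDModel, test: ExpressionMatrix) -> pd.DataFrame:
    """Predictions plus per-class expected utilities, one row per sample."""
    if model.probe_ids is not None and list(test.probe_ids) != list(model.probe_ids):
        raise AlignmentError("test probe ids differ from the training probes")
    test_n = apply_row_stats(test, model.row_stats) if model.row_stats else test
    Y = project(model.phi, test_n.values)
    rows = []
    for j, sid in enumerate(test.sample_ids):
        eu = expected_utilities(Y[:, j], model)
        k = int(np.argmax(eu))
        rows.append(
            {"sample_id": sid, "predicted_class": model.class_names[k]}
            | {f"EU_{c}": eu[i] for i, c in enumerate(model.class_names)}
        )
    return pd.DataFrame(rows)


def accuracy(predicted, truth) -> float:
    """Fraction of correctly labeled samples."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.size == 0:
        raise ValueError("empty label arrays")
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(p == t))


def format_percent(a: float) -> str:
    """An accuracy ratio as a percentage with one decimal, e.g. '90.9'."""
    return f"{100.0 * a:.1f}"


# ---------------------------------------------------------------------------
# stability


@dataclass
class StabilityResult:
    mean_accuracy: float
    std_accuracy: float
    accuracies: list[float]


def stability_experiment(
    data: LabeledDataset,
    n_repeats: int,
    per_class_train: int,
    seed: int,
    m: int,
    **fit_kwargs,
) -> StabilityResult:
    """Repeated balanced random resplits: fit, predict, aggregate accuracy.

    Each repeat draws ``per_class_train`` training samples per class
    uniformly at random (seeded), fits on them and evaluates on the
    remainder. The standard deviation is the sample (ddof=1) deviation.
    """
    from .synthetic import split_balanced  # local import to avoid a cycle

    counts = data.class_counts()
    if np.any(counts < per_class_train + 1):
        raise ValueError(
            f"every class needs > {per_class_train} samples; counts {counts.tolist()}"
        )
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        tr, te = split_balanced(data, per_class_train, split_seed)
        model = fit(tr, m, **fit_kwargs)
        pred = predict(model, te.matrix)
        accs.append(accuracy(pred, te.y))
    mean = float(np.mean(accs))
    std = float(np.std(accs, ddof=1)) if n_repeats > 1 else 0.0
    return StabilityResult(mean, std, accs)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: MCSDModel, path) -> None:
    """Serialize a model to a directory of plain-text artifacts.

    model.json holds sigma, priors, class names, utility, means and config;
    phi.tsv the sparse triplets of the compress matrix; row_stats.tsv the
    per-probe normalization statistics; selected.tsv the selected features.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = model.phi.matrix.tocoo()
    with open(path / "phi.tsv", "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c_, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c_}\t{float(v)!r}\n")
    meta = {
        "format": "mcsd-model/1",
        "m": model.m,
        "n": model.phi.n,
        "class_names": model.class_names,
        "sigma": [float(s) for s in model.sigma],
        "priors": [float(p) for p in model.priors],
        "utility": [[float(v) for v in row] for row in model.utility],
        "class_means": [[float(v) for v in row] for row in model.class_means],
        "class_means_compressed": [
            [float(v) for v in row] for row in model.class_means_compressed
        ],
        "config": model.config,
        "phi_solver": model.phi.solver,
        "phi_tol": model.phi.tol,
    }
    with open(path / "model.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if model.row_stats is not None:
        with open(path / "row_stats.tsv", "w") as fh:
            fh.write("probe_id\tmin\tmax\n")
            probes = model.probe_ids or [str(i) for i in range(model.row_stats.mins.size)]
            for pid, lo, hi in zip(probes, model.row_stats.mins, model.row_stats.maxs):
                fh.write(f"{pid}\t{float(lo)!r}\t{float(hi)!r}\n")
    if model.selected is not None:
        with open(path / "selected.tsv", "w") as fh:
            fh.write("rank\tfeature_index\tprobe_id\n")
            for rank, idx in enumerate(model.selected):
                pid = model.probe_ids[idx] if model.probe_ids else str(idx)
                fh.write(f"{rank}\t{int(idx)}\t{pid}\n")


def load_model(path) -> MCSDModel:
    path = Path(path)
    with open(path / "model.json") as fh:
        meta = json.load(fh)
    tri = pd.read_csv(path / "phi.tsv", sep="\t")
    mat = sp.csr_matrix(
        (tri["value"], (tri["row"], tri["col"])), shape=(meta["m"], meta["n"])
    )
    phi = CompressMatrix(mat, [], meta.get("phi_tol", 1e-6), meta.get("phi_solver", "lp"))
    row_stats = None
    probe_ids = None
    rs_path = path / "row_stats.tsv"
    if rs_path.exists():
        rs = pd.read_csv(rs_path, sep="\t", dtype={"probe_id": str})
        row_stats = RowStats(rs["min"].to_numpy(), rs["max"].to_numpy())
        probe_ids = [str(p) for p in rs["probe_id"]]
    selected = None
    sel_path = path / "selected.tsv"
    if sel_path.exists():
        selected = pd.read_csv(sel_path, sep="\t")["feature_index"].to_numpy()
    return MCSDModel(
        phi=phi,
        class_means=np.asarray(meta["class_means"], dtype=np.float64),
        class_means_compressed=np.asarray(
            meta["class_means_compressed"], dtype=np.float64
        ),
        sigma=np.asarray(meta["sigma"], dtype=np.float64),
        priors=np.asarray(meta["priors"], dtype=np.float64),
        utility=np.asarray(meta["utility"], dtype=np.float64),
        class_names=list(meta["class_names"]),
        row_stats=row_stats,
        selected=selected,
        probe_ids=probe_ids,
        config=dict(meta.get("config", {})),
    )
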