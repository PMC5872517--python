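"""Gaussian simultaneous-equation models and their graph semantics.

A simultaneous-equation model (SEM) ``Y = A Y + B X + E`` couples a vector of
endogenous variables Y (cycles and feedback loops allowed through A) to
exogenous variables X.  Under the standard conditions — joint Gaussianity,
E ⊥ X, invertible I−A, diagonal Cov(E), block-diagonal Ψ = Cov(X) with full
blocks — the joint law of (Y, X) is global Markov with respect to the SEM's
*path diagram*: directed edges at the nonzero entries of A and B, undirected
edges at the nonzero off-diagonal entries of Ψ.  :func:`gaussian_ci` is the
algebraic side of that equivalence (vanishing partial covariance), used to
cross-check the graphical side (``global_markov_query``).

The integrative three-level model stacks two such SEMs::

    Y = A Y + B X + E_Y      (gene expression given copy number/methylation)
    Z = C Z + D Y + E_Z      (protein expression given gene expression)

with diagonal error covariances Σ_Y = diag(σ), Σ_Z = diag(λ), so that
p(Y, Z | X) = p(Z | Y) · p(Y | X) with

    Y | X ~ N((I−A)⁻¹ B X,  (I−A)⁻¹ Σ_Y (I−A)⁻ᵀ)
    Z | Y ~ N((I−C)⁻¹ D Y,  (I−C)⁻¹ Σ_Z (I−C)⁻ᵀ).

X interleaves copy number and methylation per gene: in 1-based terms column
2i−1 of B multiplies the copy number of gene i and column 2i its methylation
(0-based rows 2i and 2i+1 of the X block).  The *cis* restriction zeroes
every entry of B outside those two columns of its own row: DNA-level
measurements of gene i may affect only gene i's expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import ReciprocalGraph

__all__ = [
    "GeneralSEM",
    "IntegrativeSEMParams",
    "OmicsDataset",
    "cis_mask",
    "path_diagram",
    "joint_gaussian",
    "gaussian_ci",
    "conditional_moments",
    "loglik",
    "save_params",
    "load_params",
]

#: reject I−A / I−C as numerically singular below this reciprocal condition number
RCOND_MIN = 1e-10


def _rcond(m: np.ndarray) -> float:
    sv = np.linalg.svd(m, compute_uv=False)
    return 0.0 if sv[0] == 0 else float(sv[-1] / sv[0])


def _check_invertible(m: np.ndarray, name: str) -> None:
    if _rcond(m) < RCOND_MIN:
        raise ValueError(f"{name} is numerically singular (rcond < {RCOND_MIN:g})")


def cis_mask(p: int) -> np.ndarray:
    """Boolean (p, 2p) mask of the structurally free entries of B: row i may
    load only on columns 2i, 2i+1 (0-based; copy number then methylation)."""
    m = np.zeros((p, 2 * p), dtype=bool)
    idx = np.arange(p)
    m[idx, 2 * idx] = True
    m[idx, 2 * idx + 1] = True
    return m


@dataclass
class GeneralSEM:
    """One-layer SEM ``Y = A Y + B X + E`` under the five Gaussian-RG
    conditions.

    Attributes
    ----------
    A : (p, p) array, zero diagonal
    B : (p, q) array
    Psi : (q, q) symmetric positive-definite covariance of X
    err_var : (p,) positive error variances (diagonal Cov(E))
    """

    A: np.ndarray
    B: np.ndarray
    Psi: np.ndarray
    err_var: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        self.err_var = np.asarray(self.err_var, dtype=float)
        p, q = self.B.shape
        if self.A.shape != (p, p):
            raise ValueError("A must be p x p with p = B.shape[0]")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have a zero diagonal")
        if self.Psi.shape != (q, q):
            raise ValueError("Psi must be q x q with q = B.shape[1]")
        if not np.allclose(self.Psi, self.Psi.T):
            raise ValueError("Psi must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Psi) <= 0):
            raise ValueError("Psi must be positive definite")
        if self.err_var.shape != (p,) or np.any(self.err_var <= 0):
            raise ValueError("err_var must be p positive variances")
        _check_invertible(np.eye(p) - self.A, "I - A")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def q(self) -> int:
        return self.B.shape[1]


def path_diagram(sem: GeneralSEM, y_labels=None, x_labels=None) -> ReciprocalGraph:
    """Path diagram of a one-layer SEM.

    Nodes Y1..Yp, X1..Xq (or the given labels); directed edge j→i for every
    nonzero a_ij (j a Y node) or b_ij (j an X node); undirected edge X_i−X_j
    for every nonzero off-diagonal Ψ entry.
    """
    p, q = sem.p, sem.q
    ylab = list(y_labels) if y_labels is not None else [f"Y{i + 1}" for i in range(p)]
    xlab = list(x_labels) if x_labels is not None else [f"X{j + 1}" for j in range(q)]
    if len(ylab) != p or len(xlab) != q:
        raise ValueError("label lengths must match p and q")
    directed = []
    for i in range(p):
        for j in range(p):
            if sem.A[i, j] != 0:
                directed.append((ylab[j], ylab[i]))
        for j in range(q):
            if sem.B[i, j] != 0:
                directed.append((xlab[j], ylab[i]))
    undirected = [
        (xlab[i], xlab[j])
        for i in range(q)
        for j in range(i + 1, q)
        if sem.Psi[i, j] != 0
    ]
    return ReciprocalGraph(ylab + xlab, directed, undirected)


def joint_gaussian(sem: GeneralSEM) -> np.ndarray:
    """Implied (p+q) x (p+q) covariance of the stacked vector (Y, X).

    Σ_YY = (I−A)⁻¹ (B Ψ Bᵀ + diag(err_var)) (I−A)⁻ᵀ,
    Σ_YX = (I−A)⁻¹ B Ψ,  Σ_XX = Ψ.
    """
    p = sem.p
    inv = np.linalg.inv(np.eye(p) - sem.A)
    bp = sem.B @ sem.Psi
    syy = inv @ (bp @ sem.B.T + np.diag(sem.err_var)) @ inv.T
    syx = inv @ bp
    top = np.hstack([syy, syx])
    bot = np.hstack([syx.T, sem.Psi])
    cov = np.vstack([top, bot])
    return 0.5 * (cov + cov.T)


def gaussian_ci(cov: np.ndarray, a, b, c, tol: float = 1e-8) -> bool:
    """Gaussian conditional independence Z_a ⊥ Z_b | Z_c read off a covariance.

    True iff every entry of the partial covariance of (a, b) given c — the
    Schur complement Σ_ab − Σ_ac Σ_cc⁻¹ Σ_cb, computed on correlation-
    standardized variables — is below ``tol`` in absolute value.
    """
    cov = np.asarray(cov, dtype=float)
    a, b, c = (np.asarray(sorted(s), dtype=int) for s in (set(a), set(b), set(c)))
    if set(a) & set(b) or set(a) & set(c) or set(b) & set(c):
        raise ValueError("index sets must be pairwise disjoint")
    if a.size == 0 or b.size == 0:
        raise ValueError("a and b must be nonempty")
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("covariance must be positive definite")
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    sab = corr[np.ix_(a, b)]
    if c.size:
        scc = corr[np.ix_(c, c)]
        sac = corr[np.ix_(a, c)]
        scb = corr[np.ix_(c, b)]
        sab = sab - sac @ np.linalg.solve(scc, scb)
    return bool(np.max(np.abs(sab)) < tol)


@dataclass
class IntegrativeSEMParams:
    """Parameters (A, B, C, D, σ, λ) of the two-layer integrative SEM.

    ``sigma`` and ``lam`` are error *variances* (the diagonals of Σ_Y, Σ_Z).
    ``B`` is stored dense (p, 2p); with ``cis_only`` (the default) every
    entry outside the cis mask must be exactly zero.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    cis_only: bool = True
    gene_labels: Optional[list] = None

    def __post_init__(self):
        for name in ("A", "B", "C", "D", "sigma", "lam"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        p = self.A.shape[0]
        if self.A.shape != (p, p) or self.C.shape != (p, p):
            raise ValueError("A and C must be p x p")
        if np.any(np.diag(self.A) != 0) or np.any(np.diag(self.C) != 0):
            raise ValueError("A and C must have zero diagonals")
        if self.B.shape != (p, 2 * p):
            raise ValueError("B must be p x 2p")
        if self.D.shape != (p, p):
            raise ValueError("D must be p x p")
        if self.cis_only and np.any(self.B[~cis_mask(p)] != 0):
            raise ValueError("cis_only: B entries outside columns 2i-1, 2i must be 0")
        for name, v in (("sigma", self.sigma), ("lam", self.lam)):
            if v.shape != (p,) or np.any(v <= 0):
                raise ValueError(f"{name} must be p positive variances")
        _check_invertible(np.eye(p) - self.A, "I - A")
        _check_invertible(np.eye(p) - self.C, "I - C")
        if self.gene_labels is None:
            self.gene_labels = [f"gene{i + 1}" for i in range(p)]
        elif len(self.gene_labels) != p:
            raise ValueError("gene_labels must have length p")

    @property
    def p(self) -> int:
        return self.A.shape[0]


@dataclass
class OmicsDataset:
    """Aligned observation blocks for p genes over n samples.

    X : (2p, n) copy number and methylation, interleaved per gene (row 2i =
        copy number of gene i, row 2i+1 = its methylation, 0-based);
    Y : (p, n) gene expression;  Z : (p, n) protein expression.
    """

    gene_labels: list
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    sample_labels: Optional[list] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        p = len(self.gene_labels)
        if len(set(self.gene_labels)) != p:
            raise ValueError("duplicate gene labels")
        n = self.Y.shape[1] if self.Y.ndim == 2 else -1
        if self.X.shape != (2 * p, n) or self.Y.shape != (p, n) or self.Z.shape != (p, n):
            raise ValueError(
                "blocks must have matching sample counts and shapes "
                "(2p x n, p x n, p x n)"
            )
        for name, blk in (("X", self.X), ("Y", self.Y), ("Z", self.Z)):
            if not np.all(np.isfinite(blk)):
                raise ValueError(f"non-finite values in block {name}")
        if self.sample_labels is not None and len(self.sample_labels) != n:
            raise ValueError("sample_labels must have length n")

    @property
    def p(self) -> int:
        return len(self.gene_labels)

    @property
    def n(self) -> int:
        return self.Y.shape[1]

    def standardize(self) -> "OmicsDataset":
        """Center every row and scale it to unit sample variance."""

        def std(m):
            m = m - m.mean(axis=1, keepdims=True)
            s = m.std(axis=1, ddof=1, keepdims=True)
            s[s == 0] = 1.0
            return m / s

        return OmicsDataset(
            list(self.gene_labels), std(self.X), std(self.Y), std(self.Z),
            None if self.sample_labels is None else list(self.sample_labels),
        )


def conditional_moments(params: IntegrativeSEMParams, layer: str, predictors: np.ndarray):
    """Mean and covariance of one layer of the factored model.

    ``layer="Y|X"``: mean (I−A)⁻¹ B X, cov (I−A)⁻¹ Σ_Y (I−A)⁻ᵀ, with
    ``predictors`` the (2p, n) X block.  ``layer="Z|Y"``: analogous with C,
    D, Σ_Z and the (p, n) Y block.
    """
    p = params.p
    predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
    if layer == "Y|X":
        coef, load, var, nrows = params.A, params.B, params.sigma, 2 * p
    elif layer == "Z|Y":
        coef, load, var, nrows = params.C, params.D, params.lam, p
    else:
        raise ValueError("layer must be 'Y|X' or 'Z|Y'")
    if predictors.shape[0] != nrows:
        raise ValueError(f"predictor block for layer {layer} must have {nrows} rows")
    m = np.eye(p) - coef
    try:
        _check_invertible(m, "I - A" if layer == "Y|X" else "I - C")
    except ValueError as err:
        raise ValueError(f"layer {layer}: {err}") from None
    inv = np.linalg.inv(m)
    mean = inv @ load @ predictors
    cov = inv @ np.diag(var) @ inv.T
    return mean, 0.5 * (cov + cov.T)


def _layer_loglik(coef, load, var, resp, pred) -> float:
    # log N(resp | (I-coef)^-1 load pred, (I-coef)^-1 diag(var) (I-coef)^-T)
    # evaluated in residual form: R = (I-coef) resp - load pred
    p, n = resp.shape
    m = np.eye(p) - coef
    sign, logdet = np.linalg.slogdet(m)
    if sign == 0:
        raise ValueError("singular structural matrix")
    r = m @ resp - load @ pred
    rss = np.sum(r * r, axis=1)
    return float(
        n * logdet
        - 0.5 * n * np.sum(np.log(2 * np.pi * var))
        - 0.5 * np.sum(rss / var)
    )


def loglik(params: IntegrativeSEMParams, data: OmicsDataset) -> float:
    """Log density log p(Y, Z | X) = log p(Z | Y) + log p(Y | X)."""
    if data.p != params.p:
        raise ValueError("params and data disagree on the number of genes")
    _check_invertible(np.eye(params.p) - params.A, "I - A")
    _check_invertible(np.eye(params.p) - params.C, "I - C")
    ll_y = _layer_loglik(params.A, params.B, params.sigma, data.Y, data.X)
    ll_z = _layer_loglik(params.C, params.D, params.lam, data.Z, data.Y)
    return ll_y + ll_z


# -- parameter-bundle serialization ---------------------------------------


def save_params(params: IntegrativeSEMParams, path) -> None:
    """Serialize a parameter bundle as JSON with named arrays, sorted keys."""
    doc = {
        "A": params.A.tolist(),
        "B": params.B.tolist(),
        "C": params.C.tolist(),
        "D": params.D.tolist(),
        "cis_only": params.cis_only,
        "gene_labels": list(params.gene_labels),
        "lambda": params.lam.tolist(),
        "sigma": params.sigma.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_params(path) -> IntegrativeSEMParams:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return IntegrativeSEMParams(
        A=np.array(doc["A"]),
        B=np.array(doc["B"]),
        C=np.array(doc["C"]),
        D=np.array(doc["D"]),
        sigma=np.array(doc["sigma"]),
        lam=np.array(doc["lambda"]),
        cis_only=bool(doc["cis_only"]),
        gene_labels=list(doc["gene_labels"]),
    )
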