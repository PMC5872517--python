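"""Ground-truth parameter generation and forward simulation.

The generator emulates the data-generating class the integrative SEM
assumes: sparse gene–gene (A), protein–protein (C) and gene–protein (D)
coefficient matrices, cis-only DNA→RNA loadings (B), diagonal Gaussian
errors, and exogenous copy-number/methylation pairs drawn per gene from a
bivariate Gaussian with a fixed within-gene correlation.  Feedback loops
(reciprocal pairs a_ij, a_ji both nonzero) can be forced to exercise the
cyclic capability that separates this model class from DAGs.

The default scenario — ``p=5, n=300, sparsity=0.15, effects in [0.8, 1.2],
error SD 0.5, x_corr=0.3`` — is the package's fixed recovery-test setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sem import IntegrativeSEMParams, OmicsDataset, cis_mask

__all__ = ["SimulationConfig", "generate_params", "simulate_dataset"]

#: probability that each cis entry of B (copy number / methylation -> own gene)
#: is nonzero in generated ground truth
CIS_PROB = 0.9

#: minimum reciprocal condition number of I-A, I-C accepted at generation
GEN_RCOND_MIN = 1e-6

_MAX_RESAMPLE = 1000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic recovery scenario.

    ``sparsity`` is the expected fraction of structurally free A/C/D entries
    that are nonzero; nonzero magnitudes are uniform on
    [effect_low, effect_high] with random sign.  ``error_sd_Y``/``error_sd_Z``
    are error standard deviations (variances σ = sd²).  ``x_corr`` is the
    within-gene copy-number/methylation correlation.
    """

    p: int = 5
    n: int = 300
    sparsity: float = 0.15
    effect_low: float = 0.8
    effect_high: float = 1.2
    error_sd_Y: float = 0.5
    error_sd_Z: float = 0.5
    x_corr: float = 0.3
    allow_feedback: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.p < 2 or self.n < 1:
            raise ValueError("require p >= 2 and n >= 1")
        if not 0 <= self.sparsity <= 1:
            raise ValueError("sparsity must be in [0, 1]")
        if not 0 < self.effect_low <= self.effect_high:
            raise ValueError("require 0 < effect_low <= effect_high")
        if not abs(self.x_corr) < 1:
            raise ValueError("|x_corr| must be < 1")
        if self.error_sd_Y <= 0 or self.error_sd_Z <= 0:
            raise ValueError("error SDs must be positive")


def _rcond(m: np.ndarray) -> float:
    sv = np.linalg.svd(m, compute_uv=False)
    return 0.0 if sv[0] == 0 else float(sv[-1] / sv[0])


def _effects(rng: np.random.Generator, mask: np.ndarray, lo: float, hi: float):
    mag = rng.uniform(lo, hi, size=mask.shape)
    sign = rng.choice([-1.0, 1.0], size=mask.shape)
    return np.where(mask, mag * sign, 0.0)


def generate_params(cfg: SimulationConfig) -> IntegrativeSEMParams:
    """Draw ground-truth parameters; deterministic per ``cfg.seed``.

    Free positions of A, C, D are included independently at rate
    ``sparsity`` (cis entries of B at rate ``CIS_PROB``); when
    ``allow_feedback`` one reciprocal pair a_ij, a_ji is forced nonzero.
    Draws are rejected until I−A and I−C are well conditioned.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    offdiag = ~np.eye(p, dtype=bool)
    eye = np.eye(p)
    for _ in range(_MAX_RESAMPLE):
        a_mask = (rng.random((p, p)) < cfg.sparsity) & offdiag
        if cfg.allow_feedback:
            i, j = rng.choice(p, size=2, replace=False)
            a_mask[i, j] = a_mask[j, i] = True
        c_mask = (rng.random((p, p)) < cfg.sparsity) & offdiag
        d_mask = rng.random((p, p)) < cfg.sparsity
        b_mask = cis_mask(p) & (rng.random((p, 2 * p)) < CIS_PROB)
        A = _effects(rng, a_mask, cfg.effect_low, cfg.effect_high)
        C = _effects(rng, c_mask, cfg.effect_low, cfg.effect_high)
        D = _effects(rng, d_mask, cfg.effect_low, cfg.effect_high)
        B = _effects(rng, b_mask, cfg.effect_low, cfg.effect_high)
        if _rcond(eye - A) > GEN_RCOND_MIN and _rcond(eye - C) > GEN_RCOND_MIN:
            return IntegrativeSEMParams(
                A=A, B=B, C=C, D=D,
                sigma=np.full(p, cfg.error_sd_Y**2),
                lam=np.full(p, cfg.error_sd_Z**2),
            )
    raise RuntimeError(
        "could not generate well-conditioned structural matrices; "
        "lower sparsity or effect sizes"
    )


def true_edge_masks(params: IntegrativeSEMParams) -> dict:
    """Boolean nonzero masks of the ground-truth coefficient blocks."""
    return {
        "A": params.A != 0,
        "B": params.B != 0,
        "C": params.C != 0,
        "D": params.D != 0,
    }


def simulate_dataset(
    params: IntegrativeSEMParams, cfg: SimulationConfig, seed=None
) -> OmicsDataset:
    """Forward-simulate an aligned multi-omics dataset.

    Per sample: the (copy number, methylation) pair of each gene is drawn
    from a bivariate standard Gaussian with correlation ``x_corr``; then
    Y = (I−A)⁻¹ (B X + E_Y) and Z = (I−C)⁻¹ (D Y + E_Z).
    Reproducible per seed (defaults to ``cfg.seed + 1``).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    p, n = params.p, cfg.n
    chol = np.linalg.cholesky(
        np.array([[1.0, cfg.x_corr], [cfg.x_corr, 1.0]])
    )
    X = np.empty((2 * p, n))
    for i in range(p):
        X[2 * i: 2 * i + 2] = chol @ rng.standard_normal((2, n))
    ey = cfg.error_sd_Y * rng.standard_normal((p, n))
    ez = cfg.error_sd_Z * rng.standard_normal((p, n))
    Y = np.linalg.solve(np.eye(p) - params.A, params.B @ X + ey)
    Z = np.linalg.solve(np.eye(p) - params.C, params.D @ Y + ez)
    labels = list(params.gene_labels)
    samples = [f"s{k + 1}" for k in range(n)]
    return OmicsDataset(labels, X, Y, Z, samples)
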