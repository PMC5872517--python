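"""Thresholded priors and the Metropolis-within-Gibbs sampler.

Prior.  Each free coefficient has a latent Gaussian value and appears in the
model only when its magnitude clears a row-level threshold::

    a_ij = ã_ij · 1(|ã_ij| > tY_i),   ã_ij ~ N(0, τ_ij),
    τ_ij ~ IG(α_τ, β_τ),              t_i ~ Uniform(0, t0),

and the same construction for B (cis entries, sharing the row threshold
tY_i), C and D (sharing tZ_i).  The threshold induces exact zeros — edge
exclusion — and controls the minimum effect size of an included edge.
Error variances get conjugate inverse-gamma priors σ_j, λ_j ~ IG(a, b).

Sampler.  One sweep cycles (i) Metropolis updates of every free latent
coefficient — by default an independence proposal mixing a uniform draw on
the spike (−t_i, t_i) with the Gaussian formed by the row likelihood and
the N(0, τ) prior, which jumps directly between edge exclusion and the
conditional slab mode; symmetric random walks and prior draws are
selectable alternatives — plus involutive direction-swap and joint
reciprocal-pair moves that cross between nearly likelihood-equivalent
network orientations; (ii) an exact Gibbs draw of each row threshold from
its piecewise-constant full conditional; (iii) Gibbs draws of the scales
τ | ã ~ IG(α_τ + ½, β_τ + ã²/2); and (iv) Gibbs draws of the variances
σ_i | · ~ IG(a + n/2, b + RSS_i/2), where RSS_i is the residual sum of
squares of row i of (I−A)Y − BX (λ analogous for the protein layer).
Burn-in optionally anneals the likelihood over melt/freeze cycles and
restarts the sampling phase from the best-scoring visited state; retained
draws always come from the untempered kernel.  The numerical core lives in
:mod:`rgsem._kernels`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .sem import OmicsDataset, RCOND_MIN, cis_mask

__all__ = [
    "PriorHyperparams",
    "MCMCState",
    "Trace",
    "init_state",
    "update_coefficients",
    "update_thresholds",
    "update_scales",
    "update_variances",
    "run_mcmc",
]

_INIT_RETRIES = 200


@dataclass
class PriorHyperparams:
    """Hyperparameters of the thresholded prior and the proposal kernel.

    t0 : upper bound of the uniform threshold prior (default 1, sensible on
        standardized data where included effects rarely exceed 1).
    alpha_tau, beta_tau : IG shape/scale of the coefficient-scale hyperprior.
    a_var, b_var : IG shape/scale for the error variances (weakly
        informative by default).
    proposal_sd_coef : random-walk SD for latent coefficients.
    proposal_sd_thresh : random-walk SD for thresholds; ``None`` means
        0.05·t0.
    """

    t0: float = 1.0
    alpha_tau: float = 1.0
    beta_tau: float = 1.0
    a_var: float = 0.01
    b_var: float = 0.01
    proposal_sd_coef: float = 0.1
    proposal_sd_thresh: Optional[float] = None

    def __post_init__(self):
        vals = [self.t0, self.alpha_tau, self.beta_tau, self.a_var,
                self.b_var, self.proposal_sd_coef]
        if self.proposal_sd_thresh is not None:
            vals.append(self.proposal_sd_thresh)
        if any(v <= 0 for v in vals):
            raise ValueError("all hyperparameters must be strictly positive")

    @property
    def sd_thresh(self) -> float:
        return 0.05 * self.t0 if self.proposal_sd_thresh is None else self.proposal_sd_thresh


@dataclass
class MCMCState:
    """Latent coefficients, thresholds, scales and variances of one sweep.

    Latent arrays are dense; boolean masks mark the structurally free
    positions (off-diagonal for A and C, the cis columns for B, all of D).
    Effective coefficients are the row-thresholded latents.
    """

    Alat: np.ndarray
    Blat: np.ndarray
    Clat: np.ndarray
    Dlat: np.ndarray
    tY: np.ndarray
    tZ: np.ndarray
    tauA: np.ndarray
    tauB: np.ndarray
    tauC: np.ndarray
    tauD: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    Amask: np.ndarray
    Bmask: np.ndarray
    Cmask: np.ndarray
    Dmask: np.ndarray

    @property
    def p(self) -> int:
        return self.Alat.shape[0]

    def effective(self, block: str) -> np.ndarray:
        """Thresholded coefficient matrix for block in {'A','B','C','D'}."""
        lat = getattr(self, block + "lat")
        mask = getattr(self, block + "mask")
        t = self.tY if block in ("A", "B") else self.tZ
        return np.where(mask & (np.abs(lat) > t[:, None]), lat, 0.0)

    def copy(self) -> "MCMCState":
        return MCMCState(**{
            k: getattr(self, k).copy()
            for k in ("Alat", "Blat", "Clat", "Dlat", "tY", "tZ",
                      "tauA", "tauB", "tauC", "tauD", "sigma", "lam",
                      "Amask", "Bmask", "Cmask", "Dmask")
        })

    def validate(self, t0: float) -> None:
        if np.any((self.tY <= 0) | (self.tY >= t0) | (self.tZ <= 0) | (self.tZ >= t0)):
            raise ValueError("thresholds must lie in (0, t0)")
        for nm in ("tauA", "tauB", "tauC", "tauD", "sigma", "lam"):
            if np.any(getattr(self, nm) <= 0):
                raise ValueError(f"{nm} must be strictly positive")
        for blk in ("A", "C"):
            m = np.eye(self.p) - self.effective(blk)
            sv = np.linalg.svd(m, compute_uv=False)
            if sv[-1] / sv[0] < RCOND_MIN:
                raise ValueError(f"I - {blk} is numerically singular")


@dataclass
class Trace:
    """Retained posterior draws of the effective (thresholded) parameters."""

    A: np.ndarray          # (L, p, p)
    B: np.ndarray          # (L, p, 2p)
    C: np.ndarray          # (L, p, p)
    D: np.ndarray          # (L, p, p)
    sigma: np.ndarray      # (L, p)
    lam: np.ndarray        # (L, p)
    tY: np.ndarray         # (L, p)
    tZ: np.ndarray         # (L, p)
    meta: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        p = self.p
        cols = {}
        for name, arr in (("A", self.A), ("B", self.B), ("C", self.C), ("D", self.D)):
            for i in range(arr.shape[1]):
                for j in range(arr.shape[2]):
                    cols[f"{name}[{i},{j}]"] = arr[:, i, j]
        for name, arr in (("sigma", self.sigma), ("lambda", self.lam),
                          ("tY", self.tY), ("tZ", self.tZ)):
            for i in range(p):
                cols[f"{name}[{i}]"] = arr[:, i]
        return pd.DataFrame(cols)

    def save(self, draws_path, meta_path) -> None:
        """Columnar TSV of draws plus a JSON sidecar of run metadata."""
        self.to_dataframe().to_csv(draws_path, sep="\t", index=False,
                                   float_format="%.17g")
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump({"meta": self.meta, "acceptance": self.acceptance,
                       "p": self.p, "n_draws": self.n_draws},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, draws_path, meta_path) -> "Trace":
        df = pd.read_csv(draws_path, sep="\t", float_precision="round_trip")
        with open(meta_path, encoding="utf-8") as fh:
            side = json.load(fh)
        p = side["p"]
        L = len(df)

        def block(name, ncol):
            out = np.empty((L, p, ncol))
            for i in range(p):
                for j in range(ncol):
                    out[:, i, j] = df[f"{name}[{i},{j}]"].to_numpy()
            return out

        def vec(name):
            return np.column_stack([df[f"{name}[{i}]"].to_numpy() for i in range(p)])

        return cls(
            A=block("A", p), B=block("B", 2 * p), C=block("C", p), D=block("D", p),
            sigma=vec("sigma"), lam=vec("lambda"), tY=vec("tY"), tZ=vec("tZ"),
            meta=side.get("meta", {}), acceptance=side.get("acceptance", {}),
        )


def default_masks(p: int) -> dict:
    off = ~np.eye(p, dtype=bool)
    return {"Amask": off.copy(), "Bmask": cis_mask(p),
            "Cmask": off.copy(), "Dmask": np.ones((p, p), dtype=bool)}


def _suff_stats(data: OmicsDataset):
    X, Y, Z = data.X, data.Y, data.Z
    return (Y @ Y.T, Y @ X.T, X @ X.T, Z @ Z.T, Z @ Y.T)


def _ridge_rows(resp, endo, exo, exo_mask, penalty=1.0):
    """Per-row ridge warm start: regress each response row on the other
    endogenous rows and its free exogenous rows."""
    p, n = resp.shape
    q = exo.shape[0]
    coef_endo = np.zeros((p, p))
    coef_exo = np.zeros((p, q))
    for i in range(p):
        pred_idx = [j for j in range(p) if j != i]
        exo_idx = [k for k in range(q) if exo_mask[i, k]]
        preds = np.vstack([endo[pred_idx], exo[exo_idx]]) if exo_idx else endo[pred_idx]
        gram = preds @ preds.T + penalty * np.eye(preds.shape[0])
        beta = np.linalg.solve(gram, preds @ resp[i])
        coef_endo[i, pred_idx] = beta[: len(pred_idx)]
        if exo_idx:
            coef_exo[i, exo_idx] = beta[len(pred_idx):]
    return coef_endo, coef_exo


def init_state(
    data: OmicsDataset,
    hyper: PriorHyperparams,
    seed: int,
    strategy: str = "empty",
) -> MCMCState:
    """Build a starting state for the sampler; deterministic per seed.

    ``strategy``:

    - ``"empty"`` (default): scales, thresholds and variances are drawn
      from their priors, then all latent coefficients are zeroed (every
      edge starts excluded) and the error variances are set to the marginal
      data row variances.  Starting from the empty network and letting the
      likelihood recruit edges avoids the variance-inflation trap of a
      dense random start, where large random coefficients blow up the
      residuals, the Gibbs variance update inflates σ, and the flat
      likelihood lets an arbitrary dense web consolidate.
    - ``"prior"``: all blocks drawn from their priors (resampled, bounded
      retries, until I−A and I−C are invertible).
    - ``"ridge"``: per-row ridge-regression warm start for the latent
      coefficients; priors for everything else.
    """
    if strategy not in ("empty", "prior", "ridge"):
        raise ValueError("strategy must be 'empty', 'prior' or 'ridge'")
    rng = np.random.default_rng(seed)
    p = data.p
    masks = default_masks(p)

    def ig(shape_arr, a, b):
        return b / rng.gamma(a, size=shape_arr)

    for _ in range(_INIT_RETRIES):
        tau = {k: ig(v.shape, hyper.alpha_tau, hyper.beta_tau)
               for k, v in (("A", masks["Amask"]), ("B", masks["Bmask"]),
                            ("C", masks["Cmask"]), ("D", masks["Dmask"]))}
        lat = {k: np.where(masks[k + "mask"],
                           rng.normal(0.0, np.sqrt(tau[k])), 0.0)
               for k in ("A", "B", "C", "D")}
        if strategy == "ridge":
            lat["A"], lat["B"] = _ridge_rows(data.Y, data.Y, data.X, masks["Bmask"])
            lat["C"], lat["D"] = _ridge_rows(data.Z, data.Z, data.Y, masks["Dmask"])
            lat["A"] *= masks["Amask"]
            lat["C"] *= masks["Cmask"]
        state = MCMCState(
            Alat=lat["A"], Blat=lat["B"], Clat=lat["C"], Dlat=lat["D"],
            tY=rng.uniform(0.0, hyper.t0, p), tZ=rng.uniform(0.0, hyper.t0, p),
            tauA=tau["A"], tauB=tau["B"], tauC=tau["C"], tauD=tau["D"],
            sigma=ig(p, hyper.a_var, hyper.b_var),
            lam=ig(p, hyper.a_var, hyper.b_var),
            **masks,
        )
        try:
            state.validate(hyper.t0)
        except ValueError:
            if strategy == "ridge":
                # shrink the warm start rather than resampling forever
                strategy = "prior"
            continue
        if strategy == "empty":
            for nm in ("Alat", "Blat", "Clat", "Dlat"):
                getattr(state, nm)[:] = 0.0
            if data.n > 1:
                state.sigma[:] = data.Y.var(axis=1)
                state.lam[:] = data.Z.var(axis=1)
        return state
    raise RuntimeError(
        "could not initialize an invertible state; try smaller initial "
        "coefficients (e.g. larger alpha_tau / smaller beta_tau)"
    )


def _kernel_seed(seed: int) -> int:
    return int((seed * 2654435761 + 1) % (2**31 - 1))


def _run(state, data, hyper, seed, n_iter, burnin, thin, *,
         proposal="conditional", adapt=False, anneal=2, sample_coef=True,
         sample_thresh=True, sample_scales=True, sample_vars=True):
    syy, syx, sxx, szz, szy = _suff_stats(data)
    out = _kernels.run_chain(
        _kernel_seed(seed), n_iter, burnin, thin,
        state.Alat, state.Amask, state.tauA,
        state.Blat, state.Bmask, state.tauB,
        state.Clat, state.Cmask, state.tauC,
        state.Dlat, state.Dmask, state.tauD,
        state.tY, state.tZ, state.sigma, state.lam,
        syy, syx, sxx, szz, szy,
        data.n, hyper.t0, hyper.alpha_tau, hyper.beta_tau,
        hyper.a_var, hyper.b_var,
        hyper.proposal_sd_coef, hyper.sd_thresh,
        {"rw": 0, "prior": 1, "conditional": 2}[proposal], RCOND_MIN,
        sample_coef, sample_thresh, sample_scales, sample_vars, adapt,
        anneal,
    )
    return out


def _single_update(state, data, hyper, seed, **flags):
    opts = dict(sample_coef=False, sample_thresh=False,
                sample_scales=False, sample_vars=False)
    opts.update(flags)
    new = state.copy()
    _run(new, data, hyper, seed, n_iter=1, burnin=0, thin=1, **opts)
    return new


def update_coefficients(state, data, hyper, seed, proposal="conditional") -> MCMCState:
    """One Metropolis pass over all free latent coefficients."""
    return _single_update(state, data, hyper, seed,
                          sample_coef=True, proposal=proposal)


def update_thresholds(state, data, hyper, seed) -> MCMCState:
    """One Metropolis pass over the row thresholds."""
    return _single_update(state, data, hyper, seed, sample_thresh=True)


def update_scales(state, data, hyper, seed) -> MCMCState:
    """Gibbs draw of every coefficient-scale τ | ã ~ IG(α+½, β+ã²/2)."""
    return _single_update(state, data, hyper, seed, sample_scales=True)


def update_variances(state, data, hyper, seed) -> MCMCState:
    """Gibbs draw of σ, λ from their inverse-gamma full conditionals."""
    return _single_update(state, data, hyper, seed, sample_vars=True)


def run_mcmc(
    data: OmicsDataset,
    hyper: Optional[PriorHyperparams] = None,
    n_iter: int = 20000,
    burnin: int = 5000,
    thin: int = 10,
    seed: int = 0,
    *,
    init_strategy: str = "empty",
    adapt: bool = False,
    anneal: int = 2,
    proposal: str = "conditional",
    init: Optional[MCMCState] = None,
    sample_coef: bool = True,
    sample_thresh: bool = True,
    sample_scales: bool = True,
    sample_vars: bool = True,
) -> Trace:
    """Run the full sampler and return the retained draws.

    Sweeps cycle coefficients → thresholds → scales → variances; every
    ``thin``-th post-burn-in state is retained
    (⌊(n_iter − burnin)/thin⌋ draws).  Fully reproducible per seed.
    """
    if hyper is None:
        hyper = PriorHyperparams()
    if not n_iter > burnin >= 0:
        raise ValueError("require n_iter > burnin >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if proposal not in ("rw", "prior", "conditional"):
        raise ValueError("proposal must be 'rw', 'prior' or 'conditional'")
    state = (init_state(data, hyper, seed, init_strategy)
             if init is None else init.copy())
    (a, b, c, d, sigma, lam, ty, tz, acc, tot, sds) = _run(
        state, data, hyper, seed, n_iter, burnin, thin,
        proposal=proposal, adapt=adapt, anneal=anneal,
        sample_coef=sample_coef, sample_thresh=sample_thresh,
        sample_scales=sample_scales, sample_vars=sample_vars,
    )
    names = ["coefficients_Y", "coefficients_Z", "thresholds_Y",
             "thresholds_Z", "swaps_Y", "swaps_Z"]
    acceptance = {
        nm: {"accepted": int(acc[k]), "proposed": int(tot[k]),
             "rate": float(acc[k] / tot[k]) if tot[k] else float("nan")}
        for k, nm in enumerate(names)
    }
    meta = {
        "n_iter": n_iter, "burnin": burnin, "thin": thin, "seed": seed,
        "proposal": proposal, "adapt": adapt, "anneal": anneal,
        "init_strategy": init_strategy if init is None else "custom",
        "p": data.p, "n": data.n,
        "hyper": {
            "t0": hyper.t0, "alpha_tau": hyper.alpha_tau,
            "beta_tau": hyper.beta_tau, "a_var": hyper.a_var,
            "b_var": hyper.b_var,
            "proposal_sd_coef": hyper.proposal_sd_coef,
            "proposal_sd_thresh": hyper.sd_thresh,
        },
        "final_proposal_sds": [float(s) for s in sds],
        "gene_labels": list(data.gene_labels),
    }
    return Trace(A=a, B=b, C=c, D=d, sigma=sigma, lam=lam, tY=ty, tZ=tz,
                 meta=meta, acceptance=acceptance)
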