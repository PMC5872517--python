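"""JIT-compiled Metropolis-within-Gibbs kernel for the thresholded-prior SEM.

All likelihood evaluations run on Gram-matrix sufficient statistics
(S_yy = Y Yᵀ etc.), so a single-coefficient proposal costs O(p²) plus one
small log-determinant, independent of the sample count n.  For one layer
with structural matrix M = I − A_eff and loading row w_i,

    log p(resp | pred) = n·log|det M| − (n/2) Σ_i log(2π σ_i)
                         − (1/2) Σ_i RSS_i / σ_i,
    RSS_i = m_i S_rr m_iᵀ − 2 m_i S_rp w_iᵀ + w_i S_pp w_iᵀ.

Effective coefficients are the thresholded latents, a_ij = ã_ij·1(|ã_ij|>t_i)
with the row threshold shared by the endogenous and exogenous blocks of the
layer.  A single seeded RNG stream drives the whole chain; the update order
is fixed (coefficients → thresholds → scales → variances, Y layer before Z,
row-major within a block), which makes traces bit-reproducible per seed.
"""

import math

import numpy as np
from numba import njit

__all__ = ["run_chain", "seed_rng"]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _thresh_mat(lat, mask, t):
    p, q = lat.shape
    out = np.zeros((p, q))
    for i in range(p):
        for j in range(q):
            if mask[i, j] and abs(lat[i, j]) > t[i]:
                out[i, j] = lat[i, j]
    return out


@njit(cache=True)
def _row_rss(mrow, wrow, srr, srp, spp):
    p = mrow.shape[0]
    q = wrow.shape[0]
    s = 0.0
    for j in range(p):
        mj = mrow[j]
        if mj != 0.0:
            for k in range(p):
                if mrow[k] != 0.0:
                    s += mj * mrow[k] * srr[j, k]
            acc = 0.0
            for k in range(q):
                if wrow[k] != 0.0:
                    acc += srp[j, k] * wrow[k]
            s -= 2.0 * mj * acc
    for j in range(q):
        wj = wrow[j]
        if wj != 0.0:
            for k in range(q):
                if wrow[k] != 0.0:
                    s += wj * wrow[k] * spp[j, k]
    return s


@njit(cache=True)
def _rcond(m):
    sv = np.linalg.svd(m)[1]
    if sv[0] == 0.0:
        return 0.0
    return sv[-1] / sv[0]


_LOG_HALF = -0.6931471805599453
_LOG_SQRT_2PI = 0.9189385332046727


@njit(cache=True)
def _logq_mix(x, t, mu, s):
    """Log density of the mixture proposal ½·U(−t, t) + ½·N(μ, s²)."""
    a = _LOG_HALF - _LOG_SQRT_2PI - np.log(s) - 0.5 * ((x - mu) / s) ** 2
    if abs(x) < t:
        b = _LOG_HALF - np.log(2.0 * t)
        hi = a if a > b else b
        return hi + np.log(np.exp(a - hi) + np.exp(b - hi))
    return a


@njit(cache=True)
def _cond_endo(i, j, m, weff, srr, srp, var_i, tau_ij, beta):
    """Gaussian (μ, sd) of the RSS×prior conditional for endogenous entry
    (i, j); the log-determinant factor is left to the acceptance ratio."""
    p = m.shape[0]
    q = weff.shape[1]
    blin = 0.0
    for kk in range(p):
        mv = m[i, kk] if kk != j else (1.0 if kk == i else 0.0)
        if mv != 0.0:
            blin += srr[j, kk] * mv
    for kk in range(q):
        if weff[i, kk] != 0.0:
            blin -= srp[j, kk] * weff[i, kk]
    prec = beta * srr[j, j] / var_i + 1.0 / tau_ij
    return beta * (blin / var_i) / prec, 1.0 / np.sqrt(prec)


@njit(cache=True)
def _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp):
    p = elat.shape[0]
    eeff = _thresh_mat(elat, emask, t)
    weff = _thresh_mat(wlat, wmask, t)
    m = np.eye(p) - eeff
    sign, ld = np.linalg.slogdet(m)
    rss = np.empty(p)
    for i in range(p):
        rss[i] = _row_rss(m[i], weff[i], srr, srp, spp)
    return eeff, weff, m, ld, rss


@njit(cache=True)
def _update_layer_coeffs(
    elat, emask, tau_e, wlat, wmask, tau_w, t, var,
    srr, srp, spp, n, sd, prop_kind, rcond_min, beta,
):
    """Metropolis sweep over every free latent coefficient of one layer.

    ``prop_kind`` selects the proposal: 0 = symmetric Gaussian random walk,
    1 = independence draw from the prior, 2 = conditional-conjugate
    independence proposal q = N(μ, 1/P) with P = γ/σ_i + 1/τ and
    μ = (β/σ_i)/P, where RSS_i(v) = const − 2βv + γv² is the exact
    quadratic dependence of the row residual sum of squares on the
    coefficient value.  For exogenous entries the conditional proposal is
    the exact full conditional (acceptance 1 up to thresholding); for
    endogenous entries the log-determinant term enters the ratio.  The
    conditional proposal jumps directly between the spike (|v| ≤ t_i,
    coefficient excluded) and the slab, which is what lets the sampler add
    and delete edges efficiently.  Mutates elat/wlat in place; returns
    (accepted, proposed)."""
    p = elat.shape[0]
    q = wlat.shape[1]
    acc = 0
    tot = 0
    eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp)

    for i in range(p):
        for j in range(p):
            if not emask[i, j]:
                continue
            tot += 1
            cur = elat[i, j]
            tau = tau_e[i, j]
            if prop_kind == 0:
                prop = cur + sd * np.random.standard_normal()
                logr = (cur * cur - prop * prop) / (2.0 * tau)
            elif prop_kind == 1:
                prop = np.sqrt(tau) * np.random.standard_normal()
                logr = 0.0
            else:
                # quadratic RSS_i(v): u = structural row with entry j removed
                blin = 0.0
                for kk in range(p):
                    mv = m[i, kk] if kk != j else (1.0 if kk == i else 0.0)
                    if mv != 0.0:
                        blin += srr[j, kk] * mv
                for kk in range(q):
                    if weff[i, kk] != 0.0:
                        blin -= srp[j, kk] * weff[i, kk]
                gam = srr[j, j]
                prec = beta * gam / var[i] + 1.0 / tau
                mu = beta * (blin / var[i]) / prec
                sq = 1.0 / np.sqrt(prec)
                if np.random.random() < 0.5:
                    prop = np.random.uniform(-t[i], t[i])
                else:
                    prop = mu + sq * np.random.standard_normal()
                logr = ((cur * cur - prop * prop) / (2.0 * tau)
                        + _logq_mix(cur, t[i], mu, sq)
                        - _logq_mix(prop, t[i], mu, sq))
            cur_eff = cur if abs(cur) > t[i] else 0.0
            prop_eff = prop if abs(prop) > t[i] else 0.0
            changed = prop_eff != cur_eff
            ld2 = ld
            rss2 = rss[i]
            if changed:
                mnew = m.copy()
                mnew[i, j] = -prop_eff
                if _rcond(mnew) < rcond_min:
                    continue
                sign2, ld2 = np.linalg.slogdet(mnew)
                if sign2 == 0.0:
                    continue
                rss2 = _row_rss(mnew[i], weff[i], srr, srp, spp)
                logr += beta * (n * (ld2 - ld) - 0.5 * (rss2 - rss[i]) / var[i])
            if np.log(np.random.random()) < logr:
                elat[i, j] = prop
                if changed:
                    m[i, j] = -prop_eff
                    eeff[i, j] = prop_eff
                    ld = ld2
                    rss[i] = rss2
                acc += 1

    for i in range(p):
        for k in range(q):
            if not wmask[i, k]:
                continue
            tot += 1
            cur = wlat[i, k]
            tau = tau_w[i, k]
            if prop_kind == 0:
                prop = cur + sd * np.random.standard_normal()
                logr = (cur * cur - prop * prop) / (2.0 * tau)
            elif prop_kind == 1:
                prop = np.sqrt(tau) * np.random.standard_normal()
                logr = 0.0
            else:
                blin = 0.0
                for kk in range(p):
                    if m[i, kk] != 0.0:
                        blin += srp[kk, k] * m[i, kk]
                for kk in range(q):
                    if kk != k and weff[i, kk] != 0.0:
                        blin -= spp[k, kk] * weff[i, kk]
                gam = spp[k, k]
                prec = beta * gam / var[i] + 1.0 / tau
                mu = beta * (blin / var[i]) / prec
                sq = 1.0 / np.sqrt(prec)
                if np.random.random() < 0.5:
                    prop = np.random.uniform(-t[i], t[i])
                else:
                    prop = mu + sq * np.random.standard_normal()
                logr = ((cur * cur - prop * prop) / (2.0 * tau)
                        + _logq_mix(cur, t[i], mu, sq)
                        - _logq_mix(prop, t[i], mu, sq))
            cur_eff = cur if abs(cur) > t[i] else 0.0
            prop_eff = prop if abs(prop) > t[i] else 0.0
            changed = prop_eff != cur_eff
            rss2 = rss[i]
            if changed:
                wrow = weff[i].copy()
                wrow[k] = prop_eff
                rss2 = _row_rss(m[i], wrow, srr, srp, spp)
                logr += -0.5 * beta * (rss2 - rss[i]) / var[i]
            if np.log(np.random.random()) < logr:
                wlat[i, k] = prop
                if changed:
                    weff[i, k] = prop_eff
                    rss[i] = rss2
                acc += 1
    return acc, tot


@njit(cache=True)
def _swap_moves(
    elat, emask, tau_e, wlat, wmask, tau_w, t, var,
    srr, srp, spp, n, rcond_min, cross, beta,
):
    """Involutive exchange moves that jump between near-equivalent modes.

    Direction swaps exchange the latent values of a reciprocal pair
    (ã_ij, ã_ji) — the two orientations of an edge between endogenous
    variables are often nearly likelihood-equivalent, and single-site
    updates cannot cross between them.  When ``cross`` is set (protein
    layer, where the exogenous block indexes the same genes), the move also
    swaps ã_ij with the exogenous latent w̃_ij, exchanging "protein j
    regulates protein i" against "gene j regulates protein i".  Proposals
    are involutions, so the Hastings ratio is the posterior ratio alone."""
    p = elat.shape[0]
    acc = 0
    tot = 0
    eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp)

    for i in range(p):
        for j in range(i + 1, p):
            if not (emask[i, j] and emask[j, i]):
                continue
            vij = elat[i, j]
            vji = elat[j, i]
            if vij == vji:
                continue
            tot += 1
            new_ij = vji if abs(vji) > t[i] else 0.0
            new_ji = vij if abs(vij) > t[j] else 0.0
            mnew = m.copy()
            mnew[i, j] = -new_ij
            mnew[j, i] = -new_ji
            if _rcond(mnew) < rcond_min:
                continue
            sign2, ld2 = np.linalg.slogdet(mnew)
            if sign2 == 0.0:
                continue
            rss_i = _row_rss(mnew[i], weff[i], srr, srp, spp)
            rss_j = _row_rss(mnew[j], weff[j], srr, srp, spp)
            logr = (beta * (n * (ld2 - ld)
                            - 0.5 * (rss_i - rss[i]) / var[i]
                            - 0.5 * (rss_j - rss[j]) / var[j])
                    + (vij * vij - vji * vji) / (2.0 * tau_e[i, j])
                    + (vji * vji - vij * vij) / (2.0 * tau_e[j, i]))
            if np.log(np.random.random()) < logr:
                elat[i, j] = vji
                elat[j, i] = vij
                eeff[i, j] = new_ij
                eeff[j, i] = new_ji
                m[i, j] = -new_ij
                m[j, i] = -new_ji
                ld = ld2
                rss[i] = rss_i
                rss[j] = rss_j
                acc += 1

    # joint conditional proposal for both directions of a reciprocal pair.
    # A feedback loop with gain a_ij·a_ji near 1 trades a large log|det|
    # penalty against small residuals, so the two coefficients must be born
    # together; single-site moves essentially never cross into that basin.
    for i in range(p):
        for j in range(i + 1, p):
            if not (emask[i, j] and emask[j, i]):
                continue
            tot += 1
            v1 = elat[i, j]
            v2 = elat[j, i]
            mu1, s1 = _cond_endo(i, j, m, weff, srr, srp, var[i],
                                 tau_e[i, j], beta)
            mu2, s2 = _cond_endo(j, i, m, weff, srr, srp, var[j],
                                 tau_e[j, i], beta)
            if np.random.random() < 0.5:
                p1 = np.random.uniform(-t[i], t[i])
            else:
                p1 = mu1 + s1 * np.random.standard_normal()
            if np.random.random() < 0.5:
                p2 = np.random.uniform(-t[j], t[j])
            else:
                p2 = mu2 + s2 * np.random.standard_normal()
            new_1 = p1 if abs(p1) > t[i] else 0.0
            new_2 = p2 if abs(p2) > t[j] else 0.0
            mnew = m.copy()
            mnew[i, j] = -new_1
            mnew[j, i] = -new_2
            if _rcond(mnew) < rcond_min:
                continue
            sign2, ld2 = np.linalg.slogdet(mnew)
            if sign2 == 0.0:
                continue
            rss_i = _row_rss(mnew[i], weff[i], srr, srp, spp)
            rss_j = _row_rss(mnew[j], weff[j], srr, srp, spp)
            logr = (beta * (n * (ld2 - ld)
                            - 0.5 * (rss_i - rss[i]) / var[i]
                            - 0.5 * (rss_j - rss[j]) / var[j])
                    + (v1 * v1 - p1 * p1) / (2.0 * tau_e[i, j])
                    + (v2 * v2 - p2 * p2) / (2.0 * tau_e[j, i])
                    + _logq_mix(v1, t[i], mu1, s1)
                    + _logq_mix(v2, t[j], mu2, s2)
                    - _logq_mix(p1, t[i], mu1, s1)
                    - _logq_mix(p2, t[j], mu2, s2))
            if np.log(np.random.random()) < logr:
                elat[i, j] = p1
                elat[j, i] = p2
                eeff[i, j] = new_1
                eeff[j, i] = new_2
                m[i, j] = -new_1
                m[j, i] = -new_2
                ld = ld2
                rss[i] = rss_i
                rss[j] = rss_j
                acc += 1

    if cross and wlat.shape[1] == p:
        for i in range(p):
            for j in range(p):
                if not (emask[i, j] and wmask[i, j]):
                    continue
                ve = elat[i, j]
                vw = wlat[i, j]
                if ve == vw:
                    continue
                tot += 1
                new_e = vw if abs(vw) > t[i] else 0.0
                new_w = ve if abs(ve) > t[i] else 0.0
                mnew = m.copy()
                mnew[i, j] = -new_e
                if _rcond(mnew) < rcond_min:
                    continue
                sign2, ld2 = np.linalg.slogdet(mnew)
                if sign2 == 0.0:
                    continue
                wrow = weff[i].copy()
                wrow[j] = new_w
                rss_i = _row_rss(mnew[i], wrow, srr, srp, spp)
                logr = (beta * (n * (ld2 - ld)
                                - 0.5 * (rss_i - rss[i]) / var[i])
                        + (ve * ve - vw * vw) / (2.0 * tau_e[i, j])
                        + (vw * vw - ve * ve) / (2.0 * tau_w[i, j]))
                if np.log(np.random.random()) < logr:
                    elat[i, j] = vw
                    wlat[i, j] = ve
                    eeff[i, j] = new_e
                    weff[i, j] = new_w
                    m[i, j] = -new_e
                    ld = ld2
                    rss[i] = rss_i
                    acc += 1
    return acc, tot


@njit(cache=True)
def _update_layer_thresholds(
    elat, emask, wlat, wmask, t, var,
    srr, srp, spp, n, sd_t, t0, rcond_min, beta,
):
    """Random-walk Metropolis on the row thresholds of one layer; proposals
    outside (0, t0) are rejected, keeping the kernel symmetric on the
    constrained support."""
    p = elat.shape[0]
    q = wlat.shape[1]
    acc = 0
    tot = 0
    eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp)
    for i in range(p):
        tot += 1
        prop = t[i] + sd_t * np.random.standard_normal()
        if prop <= 0.0 or prop >= t0:
            continue
        erow = np.zeros(p)
        wrow = np.zeros(q)
        for j in range(p):
            if emask[i, j] and abs(elat[i, j]) > prop:
                erow[j] = elat[i, j]
        for k in range(q):
            if wmask[i, k] and abs(wlat[i, k]) > prop:
                wrow[k] = wlat[i, k]
        same = True
        for j in range(p):
            if erow[j] != eeff[i, j]:
                same = False
                break
        if same:
            for k in range(q):
                if wrow[k] != weff[i, k]:
                    same = False
                    break
        if same:
            # identical effective coefficients: flat likelihood, uniform prior
            t[i] = prop
            acc += 1
            continue
        mnew = m.copy()
        for j in range(p):
            mnew[i, j] = (1.0 if j == i else 0.0) - erow[j]
        if _rcond(mnew) < rcond_min:
            continue
        sign2, ld2 = np.linalg.slogdet(mnew)
        if sign2 == 0.0:
            continue
        rss2 = _row_rss(mnew[i], wrow, srr, srp, spp)
        logr = beta * (n * (ld2 - ld) - 0.5 * (rss2 - rss[i]) / var[i])
        if np.log(np.random.random()) < logr:
            t[i] = prop
            for j in range(p):
                eeff[i, j] = erow[j]
                m[i, j] = mnew[i, j]
            for k in range(q):
                weff[i, k] = wrow[k]
            ld = ld2
            rss[i] = rss2
            acc += 1
    return acc, tot


@njit(cache=True)
def _gibbs_layer_thresholds(
    elat, emask, wlat, wmask, t, var,
    srr, srp, spp, n, t0, rcond_min, beta,
):
    """Exact Gibbs draw of each row threshold t_i from its full conditional.

    Given the latents, the likelihood is piecewise constant in t_i with
    breakpoints at the latent magnitudes below t0 (crossing a breakpoint
    flips one coefficient's inclusion).  Each segment's mass is its prior
    length times the tempered layer likelihood of the implied active set,
    so t_i can be drawn exactly: pick a segment by weight, then uniformly
    within it.  This teleports the threshold across inclusion regimes that
    a random walk would take thousands of proposals to cross."""
    p = elat.shape[0]
    q = wlat.shape[1]
    eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp)
    moved = 0
    for i in range(p):
        # collect breakpoints: latent magnitudes in (0, t0) of row i
        bps = np.empty(p + q + 2)
        nb = 0
        bps[nb] = 0.0
        nb += 1
        for j in range(p):
            if emask[i, j]:
                a = abs(elat[i, j])
                if 0.0 < a < t0:
                    bps[nb] = a
                    nb += 1
        for k in range(q):
            if wmask[i, k]:
                a = abs(wlat[i, k])
                if 0.0 < a < t0:
                    bps[nb] = a
                    nb += 1
        bps[nb] = t0
        nb += 1
        seg = np.sort(bps[:nb])
        nseg = nb - 1
        logw = np.full(nseg, -np.inf)
        mrow_best = np.zeros((nseg, p))
        wrow_best = np.zeros((nseg, q))
        ld_seg = np.zeros(nseg)
        rss_seg = np.zeros(nseg)
        for k in range(nseg):
            lo = seg[k]
            hi = seg[k + 1]
            if hi - lo <= 0.0:
                continue
            tm = 0.5 * (lo + hi)
            mnew = m.copy()
            for j in range(p):
                ev = elat[i, j] if (emask[i, j] and abs(elat[i, j]) > tm) else 0.0
                mnew[i, j] = (1.0 if j == i else 0.0) - ev
                mrow_best[k, j] = mnew[i, j]
            for kk in range(q):
                wrow_best[k, kk] = (wlat[i, kk]
                                    if (wmask[i, kk] and abs(wlat[i, kk]) > tm)
                                    else 0.0)
            if _rcond(mnew) < rcond_min:
                continue
            sgn, ldk = np.linalg.slogdet(mnew)
            if sgn == 0.0:
                continue
            rssk = _row_rss(mnew[i], wrow_best[k], srr, srp, spp)
            ld_seg[k] = ldk
            rss_seg[k] = rssk
            logw[k] = (beta * (n * ldk - 0.5 * rssk / var[i])
                       + np.log(hi - lo))
        hi_w = np.max(logw)
        if hi_w == -np.inf:
            continue
        wsum = 0.0
        for k in range(nseg):
            if logw[k] > -np.inf:
                wsum += np.exp(logw[k] - hi_w)
        u = np.random.random() * wsum
        pick = nseg - 1
        csum = 0.0
        for k in range(nseg):
            if logw[k] > -np.inf:
                csum += np.exp(logw[k] - hi_w)
                if u <= csum:
                    pick = k
                    break
        t[i] = seg[pick] + np.random.random() * (seg[pick + 1] - seg[pick])
        for j in range(p):
            m[i, j] = mrow_best[pick, j]
            eeff[i, j] = (1.0 if j == i else 0.0) - m[i, j]
        for kk in range(q):
            weff[i, kk] = wrow_best[pick, kk]
        ld = ld_seg[pick]
        rss[i] = rss_seg[pick]
        moved += 1
    return moved, p


@njit(cache=True)
def _gibbs_scales(lat, mask, tau, alpha_tau, beta_tau):
    p, q = lat.shape
    for i in range(p):
        for j in range(q):
            if mask[i, j]:
                scale = beta_tau + 0.5 * lat[i, j] * lat[i, j]
                tau[i, j] = scale / np.random.gamma(alpha_tau + 0.5, 1.0)


@njit(cache=True)
def _gibbs_layer_variances(
    elat, emask, wlat, wmask, t, var, srr, srp, spp, n, a_var, b_var, beta
):
    p = elat.shape[0]
    eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t, srr, srp, spp)
    for i in range(p):
        rssi = rss[i] if rss[i] > 0.0 else 0.0
        scale = b_var + 0.5 * beta * rssi
        var[i] = scale / np.random.gamma(a_var + 0.5 * beta * n, 1.0)


@njit(cache=True)
def _log_ig(x, a, b):
    return a * np.log(b) - math.lgamma(a) - (a + 1.0) * np.log(x) - b / x


@njit(cache=True)
def _log_joint(
    alat, amask, tau_a, blat, bmask, tau_b,
    clat, cmask, tau_c, dlat, dmask, tau_d,
    t_y, t_z, sigma, lam,
    syy, syx, sxx, szz, szy,
    n, alpha_tau, beta_tau, a_var, b_var,
):
    """Unnormalized log joint density (likelihood × priors) of a state;
    used to pick the best burn-in cycle snapshot."""
    p = alat.shape[0]
    total = 0.0
    for layer in range(2):
        if layer == 0:
            elat, emask, tau_e = alat, amask, tau_a
            wlat, wmask, tau_w = blat, bmask, tau_b
            t, var, srr, srp, spp = t_y, sigma, syy, syx, sxx
        else:
            elat, emask, tau_e = clat, cmask, tau_c
            wlat, wmask, tau_w = dlat, dmask, tau_d
            t, var, srr, srp, spp = t_z, lam, szz, szy, syy
        eeff, weff, m, ld, rss = _layer_state(elat, emask, wlat, wmask, t,
                                              srr, srp, spp)
        total += n * ld
        for i in range(p):
            total += (-0.5 * n * np.log(2.0 * np.pi * var[i])
                      - 0.5 * max(rss[i], 0.0) / var[i])
            total += _log_ig(var[i], a_var, b_var)
        for i in range(p):
            for j in range(elat.shape[1]):
                if emask[i, j]:
                    total += (-0.5 * elat[i, j] ** 2 / tau_e[i, j]
                              - 0.5 * np.log(2.0 * np.pi * tau_e[i, j])
                              + _log_ig(tau_e[i, j], alpha_tau, beta_tau))
            for j in range(wlat.shape[1]):
                if wmask[i, j]:
                    total += (-0.5 * wlat[i, j] ** 2 / tau_w[i, j]
                              - 0.5 * np.log(2.0 * np.pi * tau_w[i, j])
                              + _log_ig(tau_w[i, j], alpha_tau, beta_tau))
    return total


@njit(cache=True)
def run_chain(
    seed, n_iter, burnin, thin,
    alat, amask, tau_a, blat, bmask, tau_b,
    clat, cmask, tau_c, dlat, dmask, tau_d,
    t_y, t_z, sigma, lam,
    syy, syx, sxx, szz, szy,
    n, t0, alpha_tau, beta_tau, a_var, b_var,
    sd_coef, sd_t, prop_kind, rcond_min,
    sample_coef, sample_thresh, sample_scales, sample_vars, adapt, anneal,
):
    """Full sweep loop.  Mutates the state arrays in place and returns the
    retained effective-coefficient draws plus acceptance counters and the
    (possibly adapted) proposal SDs."""
    np.random.seed(seed)
    p = alat.shape[0]
    q = blat.shape[1]
    n_keep = (n_iter - burnin) // thin

    out_a = np.zeros((n_keep, p, p))
    out_b = np.zeros((n_keep, p, q))
    out_c = np.zeros((n_keep, p, p))
    out_d = np.zeros((n_keep, p, p))
    out_sigma = np.zeros((n_keep, p))
    out_lam = np.zeros((n_keep, p))
    out_ty = np.zeros((n_keep, p))
    out_tz = np.zeros((n_keep, p))

    # coef Y, coef Z, thresh Y, thresh Z, swap Y, swap Z
    acc = np.zeros(6, dtype=np.int64)
    tot = np.zeros(6, dtype=np.int64)
    win_acc = np.zeros(4, dtype=np.int64)
    win_tot = np.zeros(4, dtype=np.int64)
    sds = np.array([sd_coef, sd_coef, sd_t, sd_t])

    kept = 0
    # annealed burn-in: `anneal` melt/freeze cycles of likelihood
    # tempering.  Each cycle ramps the inverse temperature from 0.05 to 1
    # over 80% of the cycle, then holds at 1; at the end of every cycle the
    # state is scored by its (untempered) log joint density, and the best
    # snapshot is restored when burn-in ends.  Burn-in draws are discarded,
    # so this only chooses the starting point of the exact-posterior phase.
    n_cycles = anneal if burnin > 0 else 0
    cycle_len = burnin // n_cycles if n_cycles > 0 else 0
    best_score = -np.inf
    b_alat = alat.copy()
    b_blat = blat.copy()
    b_clat = clat.copy()
    b_dlat = dlat.copy()
    b_ty = t_y.copy()
    b_tz = t_z.copy()
    b_sigma = sigma.copy()
    b_lam = lam.copy()
    b_tau_a = tau_a.copy()
    b_tau_b = tau_b.copy()
    b_tau_c = tau_c.copy()
    b_tau_d = tau_d.copy()
    for it in range(n_iter):
        beta = 1.0
        if n_cycles > 0 and it < burnin:
            cyc = min(it // cycle_len, n_cycles - 1)
            pos = it - cyc * cycle_len
            span = 0.8 * cycle_len
            if pos < span:
                beta = 0.05 + 0.95 * pos / span
        # several coefficient/swap/threshold passes per sweep: these moves
        # are cheap on Gram statistics, and extra passes buy mixing without
        # extra likelihood data passes
        n_inner = 1
        for _inner in range(n_inner):
            if sample_coef:
                a1, t1 = _update_layer_coeffs(
                    alat, amask, tau_a, blat, bmask, tau_b, t_y, sigma,
                    syy, syx, sxx, n, sds[0], prop_kind, rcond_min, beta)
                a2, t2 = _update_layer_coeffs(
                    clat, cmask, tau_c, dlat, dmask, tau_d, t_z, lam,
                    szz, szy, syy, n, sds[1], prop_kind, rcond_min, beta)
                acc[0] += a1
                tot[0] += t1
                acc[1] += a2
                tot[1] += t2
                win_acc[0] += a1
                win_tot[0] += t1
                win_acc[1] += a2
                win_tot[1] += t2
                for _rep in range(2):
                    a5, t5 = _swap_moves(
                        alat, amask, tau_a, blat, bmask, tau_b, t_y, sigma,
                        syy, syx, sxx, n, rcond_min, False, beta)
                    a6, t6 = _swap_moves(
                        clat, cmask, tau_c, dlat, dmask, tau_d, t_z, lam,
                        szz, szy, syy, n, rcond_min, True, beta)
                    acc[4] += a5
                    tot[4] += t5
                    acc[5] += a6
                    tot[5] += t6
            if sample_thresh:
                if prop_kind == 0:
                    a3, t3 = _update_layer_thresholds(
                        alat, amask, blat, bmask, t_y, sigma,
                        syy, syx, sxx, n, sds[2], t0, rcond_min, beta)
                    a4, t4 = _update_layer_thresholds(
                        clat, cmask, dlat, dmask, t_z, lam,
                        szz, szy, syy, n, sds[3], t0, rcond_min, beta)
                else:
                    a3, t3 = _gibbs_layer_thresholds(
                        alat, amask, blat, bmask, t_y, sigma,
                        syy, syx, sxx, n, t0, rcond_min, beta)
                    a4, t4 = _gibbs_layer_thresholds(
                        clat, cmask, dlat, dmask, t_z, lam,
                        szz, szy, syy, n, t0, rcond_min, beta)
                acc[2] += a3
                tot[2] += t3
                acc[3] += a4
                tot[3] += t4
                win_acc[2] += a3
                win_tot[2] += t3
                win_acc[3] += a4
                win_tot[3] += t4
        if sample_scales:
            _gibbs_scales(alat, amask, tau_a, alpha_tau, beta_tau)
            _gibbs_scales(blat, bmask, tau_b, alpha_tau, beta_tau)
            _gibbs_scales(clat, cmask, tau_c, alpha_tau, beta_tau)
            _gibbs_scales(dlat, dmask, tau_d, alpha_tau, beta_tau)
        if sample_vars:
            _gibbs_layer_variances(
                alat, amask, blat, bmask, t_y, sigma, syy, syx, sxx,
                n, a_var, b_var, beta)
            _gibbs_layer_variances(
                clat, cmask, dlat, dmask, t_z, lam, szz, szy, syy,
                n, a_var, b_var, beta)

        # optional proposal-SD adaptation toward 20-40% acceptance, burn-in only
        if adapt and prop_kind == 0 and it < burnin and (it + 1) % 200 == 0:
            for k in range(4):
                if win_tot[k] > 0:
                    rate = win_acc[k] / win_tot[k]
                    if rate > 0.4:
                        sds[k] *= 1.3
                    elif rate < 0.2:
                        sds[k] *= 0.7
                win_acc[k] = 0
                win_tot[k] = 0

        if n_cycles > 0 and it < burnin and (
                (beta == 1.0 and (it + 1) % 100 == 0) or it == burnin - 1):
            score = _log_joint(
                alat, amask, tau_a, blat, bmask, tau_b,
                clat, cmask, tau_c, dlat, dmask, tau_d,
                t_y, t_z, sigma, lam, syy, syx, sxx, szz, szy,
                n, alpha_tau, beta_tau, a_var, b_var)
            if score > best_score:
                best_score = score
                b_alat[:] = alat
                b_blat[:] = blat
                b_clat[:] = clat
                b_dlat[:] = dlat
                b_ty[:] = t_y
                b_tz[:] = t_z
                b_sigma[:] = sigma
                b_lam[:] = lam
                b_tau_a[:] = tau_a
                b_tau_b[:] = tau_b
                b_tau_c[:] = tau_c
                b_tau_d[:] = tau_d
            if it == burnin - 1 and best_score > -np.inf:
                alat[:] = b_alat
                blat[:] = b_blat
                clat[:] = b_clat
                dlat[:] = b_dlat
                t_y[:] = b_ty
                t_z[:] = b_tz
                sigma[:] = b_sigma
                lam[:] = b_lam
                tau_a[:] = b_tau_a
                tau_b[:] = b_tau_b
                tau_c[:] = b_tau_c
                tau_d[:] = b_tau_d

        if it >= burnin and (it - burnin + 1) % thin == 0 and kept < n_keep:
            out_a[kept] = _thresh_mat(alat, amask, t_y)
            out_b[kept] = _thresh_mat(blat, bmask, t_y)
            out_c[kept] = _thresh_mat(clat, cmask, t_z)
            out_d[kept] = _thresh_mat(dlat, dmask, t_z)
            out_sigma[kept] = sigma
            out_lam[kept] = lam
            out_ty[kept] = t_y
            out_tz[kept] = t_z
            kept += 1

    return (out_a, out_b, out_c, out_d, out_sigma, out_lam, out_ty, out_tz,
            acc, tot, sds)
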