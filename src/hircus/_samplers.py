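"""Numba Gibbs-sampler kernels for the animal models.

The kernels combine three kinds of moves:

* per-level Gaussian updates of location effects (fixed cells, maternal and
  common-environment levels) from their full conditionals, the standard
  animal-model Gibbs scheme;
* joint per-animal updates of the additive and permanent-environment pair
  (they share incidence rows, so they are one 4-dimensional block);
* a partially collapsed update of the covariance pairs that per-level
  conditioning cannot mix.  Additive and permanent-environment (growth), or
  additive and residual (survival, one record per animal), are separated
  only by pedigree structure; conditioning variances on the current effect
  split traps the chain.  Instead, the summed effect u = a + p is rotated
  into the eigenbasis of the relationship matrix A = Q diag(lam) Q', where
  its blocks are independent with covariance lam_i G0 + P0; (G0, P0) are
  drawn jointly from this collapsed density by a short random-walk
  Metropolis sweep, and the split is then redrawn exactly from its Gaussian
  conditional given u.  Every animal carries a (latent) permanent effect so
  the rotation is exact; levels without records are pure augmentation.

Remaining covariances (maternal, common-environment, residual in the growth
model) keep conjugate inverse-Wishart draws.  All randomness uses numba's
internal RNG, seeded at kernel entry, so chains are bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _chol2(a11, a12, a22):
    l11 = math.sqrt(max(a11, 1e-300))
    l21 = a12 / l11
    l22 = math.sqrt(max(a22 - l21 * l21, 1e-300))
    return l11, l21, l22


@njit(cache=True, inline="always")
def _sample_gauss2(la11, la12, la22, r1, r2):
    """Draw from N(Lambda^-1 r, Lambda^-1) for a 2x2 precision Lambda."""
    l11, l21, l22 = _chol2(la11, la12, la22)
    u1 = r1 / l11
    u2 = (r2 - l21 * u1) / l22
    mean2 = u2 / l22
    mean1 = (u1 - l21 * mean2) / l11
    z1 = np.random.standard_normal()
    z2 = np.random.standard_normal()
    w2 = z2 / l22
    w1 = (z1 - l21 * w2) / l11
    return mean1 + w1, mean2 + w2


@njit(cache=True, inline="always")
def _inv2(a11, a12, a22):
    det = a11 * a22 - a12 * a12
    if det <= 0.0:
        det = 1e-300
    return a22 / det, -a12 / det, a11 / det


@njit(cache=True, inline="always")
def _draw_invwishart2(df, s11, s12, s22):
    """One draw from InvWishart(df, S) for a 2x2 scale matrix S."""
    v11, v12, v22 = _inv2(s11, s12, s22)
    l11, l21, l22 = _chol2(v11, v12, v22)
    t11 = math.sqrt(np.random.chisquare(df))
    t21 = np.random.standard_normal()
    t22 = math.sqrt(np.random.chisquare(df - 1.0))
    x11 = l11 * t11
    x21 = l21 * t11 + l22 * t21
    x22 = l22 * t22
    w11 = x11 * x11
    w12 = x11 * x21
    w22 = x21 * x21 + x22 * x22
    return _inv2(w11, w12, w22)


@njit(cache=True, inline="always")
def _draw_invwishart1(df, s):
    return s / np.random.chisquare(df)


@njit(cache=True, inline="always")
def _chol_solve_sample4(M, rhs, xout):
    """In place: draw xout ~ N(M^-1 rhs, M^-1) for a 4x4 precision M (lower)."""
    for i in range(4):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= M[i, k] * M[j, k]
            if i == j:
                M[i, i] = math.sqrt(max(s, 1e-300))
            else:
                M[i, j] = s / M[j, j]
    for i in range(4):
        s = rhs[i]
        for k in range(i):
            s -= M[i, k] * xout[k]
        xout[i] = s / M[i, i]
    for i in range(3, -1, -1):
        s = xout[i]
        for k in range(i + 1, 4):
            s -= M[k, i] * rhs[k]
        rhs[i] = s / M[i, i]
    for i in range(3, -1, -1):
        s = np.random.standard_normal()
        for k in range(i + 1, 4):
            s -= M[k, i] * xout[k]
        xout[i] = s / M[i, i]
    for i in range(4):
        xout[i] += rhs[i]


@njit(cache=True, inline="always")
def _tnorm_above(mu, sd, lo):
    """Draw from N(mu, sd^2) truncated to (lo, inf)."""
    alpha = (lo - mu) / sd
    if alpha < 0.3:
        while True:
            z = np.random.standard_normal()
            if z > alpha:
                return mu + sd * z
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + np.random.exponential(1.0) / lam
        diff = z - lam
        if np.random.random() < math.exp(-0.5 * diff * diff):
            return mu + sd * z


@njit(cache=True, inline="always")
def _logpost_pair2(lam, ut1, ut2, g11, g12, g22, p11, p12, p22,
                   nu_g, sg11, sg12, sg22, nu_p, sp11, sp12, sp22):
    """Collapsed log density of (G0, P0) given rotated sums u~ (bivariate).

    sum_i log N2(u~_i; 0, lam_i G0 + P0) plus the inverse-Wishart log priors.
    """
    q = lam.shape[0]
    ll = 0.0
    for i in range(q):
        s11 = lam[i] * g11 + p11
        s12 = lam[i] * g12 + p12
        s22 = lam[i] * g22 + p22
        det = s11 * s22 - s12 * s12
        if det <= 0.0 or s11 <= 0.0:
            return -1e300
        i11 = s22 / det
        i12 = -s12 / det
        i22 = s11 / det
        quad = (ut1[i] * ut1[i] * i11 + 2.0 * ut1[i] * ut2[i] * i12
                + ut2[i] * ut2[i] * i22)
        ll += -0.5 * math.log(det) - 0.5 * quad
    for rep in range(2):
        if rep == 0:
            a11, a12, a22, nu, s11, s12, s22 = g11, g12, g22, nu_g, sg11, sg12, sg22
        else:
            a11, a12, a22, nu, s11, s12, s22 = p11, p12, p22, nu_p, sp11, sp12, sp22
        det = a11 * a22 - a12 * a12
        if det <= 0.0:
            return -1e300
        i11, i12, i22 = _inv2(a11, a12, a22)
        tr = s11 * i11 + 2.0 * s12 * i12 + s22 * i22
        ll += -0.5 * (nu + 3.0) * math.log(det) - 0.5 * tr
    return ll


@njit(cache=True, inline="always")
def _theta_to_cov(t1, t2, t3):
    v1 = math.exp(t1)
    v2 = math.exp(t2)
    rho = math.tanh(t3)
    return v1, rho * math.sqrt(v1 * v2), v2


@njit(cache=True, inline="always")
def _logdet2(a11, a12, a22):
    det = a11 * a22 - a12 * a12
    if det <= 0.0:
        return -1e300
    return math.log(det)


@njit(cache=True, inline="always")
def _draw_mvn2(c11, c12, c22):
    """Draw from N(0, C) for a 2x2 covariance C (PSD, possibly singular)."""
    l11, l21, l22 = _chol2(max(c11, 0.0), c12, max(c22, 0.0))
    z1 = np.random.standard_normal()
    z2 = np.random.standard_normal()
    return l11 * z1, l21 * z1 + l22 * z2


# ---------------------------------------------------------------------------
# bivariate growth model: generic kernel (arbitrary pedigrees)
# ---------------------------------------------------------------------------


@njit(cache=True)
def growth_gibbs_kernel(
    y1, y2, miss,
    cellx, animx, damx, herdx,
    cell_ptr, cell_idx,
    anim_ptr, anim_idx,
    dam_ptr, dam_idx,
    herd_ptr, herd_idx,
    Ainv, Q, lam,
    use_m, use_p, use_c,
    prior_df, prior_s,          # (5,), (5,3): order a, m, p, c, e
    n_iter, burn_in, thin, seed,
    mh_steps, mh_scale,
):
    """Gibbs chain for the bivariate repeatability-maternal animal model.

    miss codes: 0 both traits observed, 1 trait 2 missing, 2 trait 1 missing;
    missing-trait residuals are re-imputed from their Gaussian conditional at
    the top of every scan.  The additive and permanent-environment effects of
    an animal share incidence rows and are sampled as one 4-dimensional
    block; their covariance pair (G0, P0) is drawn from the collapsed
    conditional given u = a + p in the eigenbasis of A (per-level
    conditioning cannot mix that split).  Maternal, common-environment and
    residual covariances use conjugate inverse-Wishart draws.  Returns
    (n_keep, 15) covariance samples ordered (a11,a12,a22, m.., p.., c.., e..).
    """
    np.random.seed(seed)
    n = y1.shape[0]
    ncell = cell_ptr.shape[0] - 1
    q = Ainv.shape[0]
    ndam = dam_ptr.shape[0] - 1
    nherd = herd_ptr.shape[0] - 1

    beta1 = np.zeros(ncell)
    beta2 = np.zeros(ncell)
    a1 = np.zeros(q)
    a2 = np.zeros(q)
    p1 = np.zeros(q)    # every animal carries a latent permanent effect
    p2 = np.zeros(q)
    m1 = np.zeros(ndam)
    m2 = np.zeros(ndam)
    c1 = np.zeros(nherd)
    c2 = np.zeros(nherd)
    e1 = np.zeros(n)
    e2 = np.zeros(n)

    # start values: cell means for fixed effects, moment-based covariances
    tot2 = 0.0
    cnt2 = 0.0
    for j in range(n):
        if miss[j] != 1:
            tot2 += y2[j]
            cnt2 += 1.0
    glob2 = tot2 / cnt2 if cnt2 > 0 else 0.0
    for k in range(ncell):
        s1 = 0.0
        s2 = 0.0
        c2n = 0.0
        nk = cell_ptr[k + 1] - cell_ptr[k]
        for jj in range(cell_ptr[k], cell_ptr[k + 1]):
            j = cell_idx[jj]
            if miss[j] != 2:
                s1 += y1[j]
            if miss[j] != 1:
                s2 += y2[j]
                c2n += 1.0
        beta1[k] = s1 / nk if nk > 0 else 0.0
        beta2[k] = s2 / c2n if c2n > 0 else glob2
    v1 = 0.0
    v2 = 0.0
    for j in range(n):
        e1[j] = y1[j] - beta1[cellx[j]] if miss[j] != 2 else 0.0
        e2[j] = y2[j] - beta2[cellx[j]] if miss[j] != 1 else 0.0
        v1 += e1[j] * e1[j]
        v2 += e2[j] * e2[j]
    v1 = v1 / n + 1e-3 if n > 0 else 1.0
    v2 = v2 / max(cnt2, 1.0) + 1e-3 if n > 0 else 1.0

    g11, g12, g22 = 0.25 * v1, 0.0, 0.25 * v2
    mm11, mm12, mm22 = 0.25 * v1, 0.0, 0.25 * v2
    p11, p12, p22 = 0.25 * v1, 0.0, 0.25 * v2
    cc11, cc12, cc22 = 0.25 * v1, 0.0, 0.25 * v2
    r11, r12, r22 = 0.5 * v1, 0.0, 0.5 * v2

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, 15))
    kept = 0
    lam4 = np.empty((4, 4))
    rhs4 = np.empty(4)
    x4 = np.empty(4)
    theta = np.empty(6)
    prop = np.empty(6)

    for it in range(1, n_iter + 1):
        gi11, gi12, gi22 = _inv2(g11, g12, g22)
        mi11, mi12, mi22 = _inv2(mm11, mm12, mm22)
        pi11, pi12, pi22 = _inv2(p11, p12, p22)
        ci11, ci12, ci22 = _inv2(cc11, cc12, cc22)
        ri11, ri12, ri22 = _inv2(r11, r12, r22)

        # --- impute residuals of missing traits from their conditionals
        b21 = r12 / r11
        sd2g1 = math.sqrt(max(r22 - r12 * r12 / r11, 1e-300))
        b12 = r12 / r22
        sd1g2 = math.sqrt(max(r11 - r12 * r12 / r22, 1e-300))
        for j in range(n):
            if miss[j] == 1:
                e2[j] = b21 * e1[j] + sd2g1 * np.random.standard_normal()
            elif miss[j] == 2:
                e1[j] = b12 * e2[j] + sd1g2 * np.random.standard_normal()

        # --- fixed-effect cell means (flat prior)
        for k in range(ncell):
            nk = cell_ptr[k + 1] - cell_ptr[k]
            if nk == 0:
                continue
            s1 = 0.0
            s2 = 0.0
            for jj in range(cell_ptr[k], cell_ptr[k + 1]):
                j = cell_idx[jj]
                s1 += e1[j] + beta1[k]
                s2 += e2[j] + beta2[k]
            new1, new2 = _sample_gauss2(
                nk * ri11, nk * ri12, nk * ri22,
                ri11 * s1 + ri12 * s2, ri12 * s1 + ri22 * s2,
            )
            d1 = beta1[k] - new1
            d2 = beta2[k] - new2
            for jj in range(cell_ptr[k], cell_ptr[k + 1]):
                j = cell_idx[jj]
                e1[j] += d1
                e2[j] += d2
            beta1[k] = new1
            beta2[k] = new2

        # --- additive + permanent-environment effects, one 4-dim block per
        #     animal (2-dim when the permanent term is off)
        for i in range(q):
            row = Ainv[i]
            s1 = 0.0
            s2 = 0.0
            for jdx in range(q):
                s1 += row[jdx] * a1[jdx]
                s2 += row[jdx] * a2[jdx]
            s1 -= row[i] * a1[i]
            s2 -= row[i] * a2[i]
            ni = anim_ptr[i + 1] - anim_ptr[i]
            aii = row[i]
            if use_p:
                r1 = 0.0
                r2 = 0.0
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    r1 += e1[j] + a1[i] + p1[i]
                    r2 += e2[j] + a2[i] + p2[i]
                d11 = ni * ri11
                d12 = ni * ri12
                d22 = ni * ri22
                lam4[0, 0] = d11 + aii * gi11
                lam4[1, 0] = d12 + aii * gi12
                lam4[1, 1] = d22 + aii * gi22
                lam4[2, 0] = d11
                lam4[2, 1] = d12
                lam4[3, 0] = d12
                lam4[3, 1] = d22
                lam4[2, 2] = d11 + pi11
                lam4[3, 2] = d12 + pi12
                lam4[3, 3] = d22 + pi22
                dr1 = ri11 * r1 + ri12 * r2
                dr2 = ri12 * r1 + ri22 * r2
                rhs4[0] = dr1 - (gi11 * s1 + gi12 * s2)
                rhs4[1] = dr2 - (gi12 * s1 + gi22 * s2)
                rhs4[2] = dr1
                rhs4[3] = dr2
                _chol_solve_sample4(lam4, rhs4, x4)
                d1 = (a1[i] + p1[i]) - (x4[0] + x4[2])
                d2 = (a2[i] + p2[i]) - (x4[1] + x4[3])
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    e1[j] += d1
                    e2[j] += d2
                a1[i] = x4[0]
                a2[i] = x4[1]
                p1[i] = x4[2]
                p2[i] = x4[3]
            else:
                r1 = 0.0
                r2 = 0.0
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    r1 += e1[j] + a1[i]
                    r2 += e2[j] + a2[i]
                new1, new2 = _sample_gauss2(
                    ni * ri11 + aii * gi11,
                    ni * ri12 + aii * gi12,
                    ni * ri22 + aii * gi22,
                    ri11 * r1 + ri12 * r2 - (gi11 * s1 + gi12 * s2),
                    ri12 * r1 + ri22 * r2 - (gi12 * s1 + gi22 * s2),
                )
                d1 = a1[i] - new1
                d2 = a2[i] - new2
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    e1[j] += d1
                    e2[j] += d2
                a1[i] = new1
                a2[i] = new2

        # --- maternal effects (i.i.d. across dams)
        if use_m:
            for d in range(ndam):
                nd = dam_ptr[d + 1] - dam_ptr[d]
                r1 = 0.0
                r2 = 0.0
                for jj in range(dam_ptr[d], dam_ptr[d + 1]):
                    j = dam_idx[jj]
                    r1 += e1[j] + m1[d]
                    r2 += e2[j] + m2[d]
                new1, new2 = _sample_gauss2(
                    nd * ri11 + mi11, nd * ri12 + mi12, nd * ri22 + mi22,
                    ri11 * r1 + ri12 * r2, ri12 * r1 + ri22 * r2,
                )
                d1 = m1[d] - new1
                d2 = m2[d] - new2
                for jj in range(dam_ptr[d], dam_ptr[d + 1]):
                    j = dam_idx[jj]
                    e1[j] += d1
                    e2[j] += d2
                m1[d] = new1
                m2[d] = new2

        # --- common environmental effects (herd)
        if use_c:
            for d in range(nherd):
                nd = herd_ptr[d + 1] - herd_ptr[d]
                r1 = 0.0
                r2 = 0.0
                for jj in range(herd_ptr[d], herd_ptr[d + 1]):
                    j = herd_idx[jj]
                    r1 += e1[j] + c1[d]
                    r2 += e2[j] + c2[d]
                new1, new2 = _sample_gauss2(
                    nd * ri11 + ci11, nd * ri12 + ci12, nd * ri22 + ci22,
                    ri11 * r1 + ri12 * r2, ri12 * r1 + ri22 * r2,
                )
                d1 = c1[d] - new1
                d2 = c2[d] - new2
                for jj in range(herd_ptr[d], herd_ptr[d + 1]):
                    j = herd_idx[jj]
                    e1[j] += d1
                    e2[j] += d2
                c1[d] = new1
                c2[d] = new2

        # --- additive/permanent covariance pair: collapsed Metropolis on
        #     (G0, P0) given u = a + p in the eigenbasis, then exact re-split
        if use_p:
            u1 = a1 + p1
            u2 = a2 + p2
            ut1 = np.dot(Q.T, u1)
            ut2 = np.dot(Q.T, u2)
            theta[0] = math.log(g11)
            theta[1] = math.log(g22)
            rho = g12 / math.sqrt(g11 * g22)
            theta[2] = math.atanh(min(max(rho, -0.999999), 0.999999))
            theta[3] = math.log(p11)
            theta[4] = math.log(p22)
            rho = p12 / math.sqrt(p11 * p22)
            theta[5] = math.atanh(min(max(rho, -0.999999), 0.999999))
            cur = _logpost_pair2(
                lam, ut1, ut2, g11, g12, g22, p11, p12, p22,
                prior_df[0], prior_s[0, 0], prior_s[0, 1], prior_s[0, 2],
                prior_df[2], prior_s[2, 0], prior_s[2, 1], prior_s[2, 2],
            ) + 1.5 * (theta[0] + theta[1] + theta[3] + theta[4]) \
              + math.log1p(-math.tanh(theta[2]) ** 2) \
              + math.log1p(-math.tanh(theta[5]) ** 2)
            for _ in range(mh_steps):
                for k in range(6):
                    prop[k] = theta[k] + mh_scale * np.random.standard_normal()
                ng11, ng12, ng22 = _theta_to_cov(prop[0], prop[1], prop[2])
                np11, np12, np22 = _theta_to_cov(prop[3], prop[4], prop[5])
                cand = _logpost_pair2(
                    lam, ut1, ut2, ng11, ng12, ng22, np11, np12, np22,
                    prior_df[0], prior_s[0, 0], prior_s[0, 1], prior_s[0, 2],
                    prior_df[2], prior_s[2, 0], prior_s[2, 1], prior_s[2, 2],
                ) + 1.5 * (prop[0] + prop[1] + prop[3] + prop[4]) \
                  + math.log1p(-math.tanh(prop[2]) ** 2) \
                  + math.log1p(-math.tanh(prop[5]) ** 2)
                if math.log(np.random.random() + 1e-300) < cand - cur:
                    for k in range(6):
                        theta[k] = prop[k]
                    cur = cand
            g11, g12, g22 = _theta_to_cov(theta[0], theta[1], theta[2])
            p11, p12, p22 = _theta_to_cov(theta[3], theta[4], theta[5])
            # re-split u into a and p in the eigenbasis
            at1 = np.empty(q)
            at2 = np.empty(q)
            for i in range(q):
                s11 = lam[i] * g11 + p11
                s12 = lam[i] * g12 + p12
                s22 = lam[i] * g22 + p22
                i11, i12, i22 = _inv2(s11, s12, s22)
                mg11 = lam[i] * g11
                mg12 = lam[i] * g12
                mg22 = lam[i] * g22
                k11 = mg11 * i11 + mg12 * i12
                k12 = mg11 * i12 + mg12 * i22
                k21 = mg12 * i11 + mg22 * i12
                k22 = mg12 * i12 + mg22 * i22
                mu1 = k11 * ut1[i] + k12 * ut2[i]
                mu2 = k21 * ut1[i] + k22 * ut2[i]
                cv11 = mg11 - (k11 * mg11 + k12 * mg12)
                cv12 = mg12 - (k11 * mg12 + k12 * mg22)
                cv22 = mg22 - (k21 * mg12 + k22 * mg22)
                n1, n2 = _draw_mvn2(cv11, cv12, cv22)
                at1[i] = mu1 + n1
                at2[i] = mu2 + n2
            a1 = np.dot(Q, at1)
            a2 = np.dot(Q, at2)
            p1 = u1 - a1
            p2 = u2 - a2
        else:
            u1a = np.dot(Ainv, a1)
            u2a = np.dot(Ainv, a2)
            g11, g12, g22 = _draw_invwishart2(
                prior_df[0] + q,
                prior_s[0, 0] + np.dot(a1, u1a),
                prior_s[0, 1] + np.dot(a1, u2a),
                prior_s[0, 2] + np.dot(a2, u2a),
            )

        # --- remaining covariance matrices: conjugate inverse-Wishart
        if use_m:
            mm11, mm12, mm22 = _draw_invwishart2(
                prior_df[1] + ndam,
                prior_s[1, 0] + np.dot(m1, m1),
                prior_s[1, 1] + np.dot(m1, m2),
                prior_s[1, 2] + np.dot(m2, m2),
            )
        if use_c:
            cc11, cc12, cc22 = _draw_invwishart2(
                prior_df[3] + nherd,
                prior_s[3, 0] + np.dot(c1, c1),
                prior_s[3, 1] + np.dot(c1, c2),
                prior_s[3, 2] + np.dot(c2, c2),
            )
        r11, r12, r22 = _draw_invwishart2(
            prior_df[4] + n,
            prior_s[4, 0] + np.dot(e1, e1),
            prior_s[4, 1] + np.dot(e1, e2),
            prior_s[4, 2] + np.dot(e2, e2),
        )

        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = g11
            out[kept, 1] = g12
            out[kept, 2] = g22
            out[kept, 3] = mm11 if use_m else 0.0
            out[kept, 4] = mm12 if use_m else 0.0
            out[kept, 5] = mm22 if use_m else 0.0
            out[kept, 6] = p11 if use_p else 0.0
            out[kept, 7] = p12 if use_p else 0.0
            out[kept, 8] = p22 if use_p else 0.0
            out[kept, 9] = cc11 if use_c else 0.0
            out[kept, 10] = cc12 if use_c else 0.0
            out[kept, 11] = cc22 if use_c else 0.0
            out[kept, 12] = r11
            out[kept, 13] = r12
            out[kept, 14] = r22
            kept += 1
    return out


# ---------------------------------------------------------------------------
# bivariate growth model: herd-block collapsed kernel (two-generation herds)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _block_logpost(
    zbar1, zbar2, wts,
    hd_ptr, hd_idx,               # dam levels grouped by herd
    fam_ptr, fam_idx,             # recorded kids grouped by dam level
    kid_sire_level,
    hs_ptr, hs_idx,               # sire levels grouped by herd
    sire_slot,                    # scratch: global sire level -> local slot
    lamb, rhsb,                   # scratch (maxdim, maxdim), (maxdim,)
    sacc, racc, used,             # scratch per-dam sire accumulators
    r11, r12, r22,
    g11, g12, g22, mm11, mm12, mm22, p11, p12, p22, cc11, cc12, cc22,
    prior_df, prior_s,
):
    """Collapsed log density of (G0, M0, P0, C0) over closed herd blocks.

    All herd-level random effects are integrated analytically in two stages:
    kid record means are N(c + 0.5 a_sire + h_dam, R0/n_k + 0.5 G0 + P0)
    with dam composites h = 0.5 a_dam + m ~ N(0, 0.25 G0 + M0) integrated
    per dam family, which reduces each herd to a small normal system in the
    herd intercept c ~ N(0, C0) and the sire halves 0.5 a_s ~ N(0, 0.25 G0).
    """
    q011 = 0.5 * g11 + p11
    q012 = 0.5 * g12 + p12
    q022 = 0.5 * g22 + p22
    sv11 = 0.25 * g11
    sv12 = 0.25 * g12
    sv22 = 0.25 * g22
    dv11 = 0.25 * g11 + mm11
    dv12 = 0.25 * g12 + mm12
    dv22 = 0.25 * g22 + mm22
    ldc = _logdet2(cc11, cc12, cc22)
    lds = _logdet2(sv11, sv12, sv22)
    ldd = _logdet2(dv11, dv12, dv22)
    if ldc <= -1e299 or lds <= -1e299 or ldd <= -1e299:
        return -1e300
    ci11, ci12, ci22 = _inv2(cc11, cc12, cc22)
    si11, si12, si22 = _inv2(sv11, sv12, sv22)
    di11, di12, di22 = _inv2(dv11, dv12, dv22)

    # kid-mean noise matrices depend only on the record count: cache them
    maxn = 0
    for i in range(wts.shape[0]):
        if wts[i] > maxn:
            maxn = int(wts[i])
    cb11 = np.empty(maxn + 1)
    cb12 = np.empty(maxn + 1)
    cb22 = np.empty(maxn + 1)
    cld = np.empty(maxn + 1)
    for nk in range(1, maxn + 1):
        b11 = r11 / nk + q011
        b12 = r12 / nk + q012
        b22 = r22 / nk + q022
        det = b11 * b22 - b12 * b12
        if det <= 0.0:
            return -1e300
        cb11[nk] = b22 / det
        cb12[nk] = -b12 / det
        cb22[nk] = b11 / det
        cld[nk] = math.log(det)

    nherd = hd_ptr.shape[0] - 1
    ll = 0.0
    for h in range(nherd):
        n_s = hs_ptr[h + 1] - hs_ptr[h]
        m = 2 * (1 + n_s)
        for t in range(hs_ptr[h], hs_ptr[h + 1]):
            sire_slot[hs_idx[t]] = 1 + (t - hs_ptr[h])
        for i in range(m):
            rhsb[i] = 0.0
            for j in range(i + 1):
                lamb[i, j] = 0.0
        lamb[0, 0] = ci11
        lamb[1, 0] = ci12
        lamb[1, 1] = ci22
        for t in range(n_s):
            o = 2 * (1 + t)
            lamb[o, o] = si11
            lamb[o + 1, o] = si12
            lamb[o + 1, o + 1] = si22
        ll += -0.5 * (ldc + n_s * lds)
        for td in range(hd_ptr[h], hd_ptr[h + 1]):
            d = hd_idx[td]
            # accumulate this dam family
            t11 = di11
            t12 = di12
            t22 = di22
            rc1 = 0.0
            rc2 = 0.0
            nu_ = 0
            for tk in range(fam_ptr[d], fam_ptr[d + 1]):
                i = fam_idx[tk]
                nk = int(wts[i])
                bi11 = cb11[nk]
                bi12 = cb12[nk]
                bi22 = cb22[nk]
                z1 = zbar1[i]
                z2 = zbar2[i]
                ll += -0.5 * cld[nk] - 0.5 * (
                    z1 * z1 * bi11 + 2.0 * z1 * z2 * bi12 + z2 * z2 * bi22
                )
                t11 += bi11
                t12 += bi12
                t22 += bi22
                rc1 += bi11 * z1 + bi12 * z2
                rc2 += bi12 * z1 + bi22 * z2
                sl = sire_slot[kid_sire_level[i]]
                found = -1
                for uu in range(nu_):
                    if used[uu] == sl:
                        found = uu
                        break
                if found < 0:
                    found = nu_
                    used[nu_] = sl
                    sacc[nu_, 0] = 0.0
                    sacc[nu_, 1] = 0.0
                    sacc[nu_, 2] = 0.0
                    racc[nu_, 0] = 0.0
                    racc[nu_, 1] = 0.0
                    nu_ += 1
                sacc[found, 0] += bi11
                sacc[found, 1] += bi12
                sacc[found, 2] += bi22
                racc[found, 0] += bi11 * z1 + bi12 * z2
                racc[found, 1] += bi12 * z1 + bi22 * z2
            det = t11 * t22 - t12 * t12
            if det <= 0.0:
                return -1e300
            ti11 = t22 / det
            ti12 = -t12 / det
            ti22 = t11 / det
            ll += -0.5 * (ldd + math.log(det))
            ll += 0.5 * (rc1 * rc1 * ti11 + 2.0 * rc1 * rc2 * ti12
                         + rc2 * rc2 * ti22)
            # direct + correction contributions to the (c, sires) system.
            # W rows: c gets Mtot = T - Dinv, sire sl gets S_sl.
            m11_ = t11 - di11
            m12_ = t12 - di12
            m22_ = t22 - di22
            # Ti products
            tm11 = ti11 * m11_ + ti12 * m12_
            tm12 = ti11 * m12_ + ti12 * m22_
            tm21 = ti12 * m11_ + ti22 * m12_
            tm22_ = ti12 * m12_ + ti22 * m22_
            tr1 = ti11 * rc1 + ti12 * rc2
            tr2 = ti12 * rc1 + ti22 * rc2
            # c block: direct M minus M Ti M ; rhs: r_c minus M Ti r_c
            lamb[0, 0] += m11_ - (m11_ * tm11 + m12_ * tm21)
            lamb[1, 0] += m12_ - (m11_ * tm12 + m12_ * tm22_)
            lamb[1, 1] += m22_ - (m12_ * tm12 + m22_ * tm22_)
            rhsb[0] += rc1 - (m11_ * tr1 + m12_ * tr2)
            rhsb[1] += rc2 - (m12_ * tr1 + m22_ * tr2)
            for uu in range(nu_):
                o = 2 * used[uu]
                s11_ = sacc[uu, 0]
                s12_ = sacc[uu, 1]
                s22_ = sacc[uu, 2]
                ts11 = ti11 * s11_ + ti12 * s12_
                ts12 = ti11 * s12_ + ti12 * s22_
                ts21 = ti12 * s11_ + ti22 * s12_
                ts22 = ti12 * s12_ + ti22 * s22_
                # [s, c] block: direct S minus S Ti M  (rows o.., cols 0..)
                lamb[o, 0] += s11_ - (s11_ * tm11 + s12_ * tm21)
                lamb[o, 1] += s12_ - (s11_ * tm12 + s12_ * tm22_)
                lamb[o + 1, 0] += s12_ - (s12_ * tm11 + s22_ * tm21)
                lamb[o + 1, 1] += s22_ - (s12_ * tm12 + s22_ * tm22_)
                rhsb[o] += racc[uu, 0] - (s11_ * tr1 + s12_ * tr2)
                rhsb[o + 1] += racc[uu, 1] - (s12_ * tr1 + s22_ * tr2)
                # [s, s'] blocks: direct (same sire only) minus S Ti S'
                for vv in range(nu_):
                    o2 = 2 * used[vv]
                    if o2 > o:
                        continue
                    w11 = sacc[vv, 0]
                    w12 = sacc[vv, 1]
                    w22 = sacc[vv, 2]
                    c11_ = ts11 * w11 + ts21 * w12
                    c12_ = ts11 * w12 + ts21 * w22
                    c21_ = ts12 * w11 + ts22 * w12
                    c22_ = ts12 * w12 + ts22 * w22
                    # note: (S Ti S')' entries; S Ti S' with S,S' symmetric
                    if o2 == o:
                        lamb[o, o] += s11_ - c11_
                        lamb[o + 1, o] += s12_ - c21_
                        lamb[o + 1, o + 1] += s22_ - c22_
                    else:
                        lamb[o, o2] += -c11_
                        lamb[o, o2 + 1] += -c12_
                        lamb[o + 1, o2] += -c21_
                        lamb[o + 1, o2 + 1] += -c22_
        for t in range(hs_ptr[h], hs_ptr[h + 1]):
            sire_slot[hs_idx[t]] = -1
        ok = _chol_lower(lamb, m)
        if not ok:
            return -1e300
        for i in range(m):
            ll -= math.log(lamb[i, i])
        acc = 0.0
        for i in range(m):
            s = rhsb[i]
            for k2 in range(i):
                s -= lamb[i, k2] * rhsb[k2]
            rhsb[i] = s / lamb[i, i]
            acc += rhsb[i] * rhsb[i]
        ll += 0.5 * acc
    # inverse-Wishart priors on the four covariance matrices
    for rep in range(4):
        if rep == 0:
            x11, x12, x22 = g11, g12, g22
            pi_ = 0
        elif rep == 1:
            x11, x12, x22 = mm11, mm12, mm22
            pi_ = 1
        elif rep == 2:
            x11, x12, x22 = p11, p12, p22
            pi_ = 2
        else:
            x11, x12, x22 = cc11, cc12, cc22
            pi_ = 3
        ld = _logdet2(x11, x12, x22)
        if ld <= -1e299:
            return -1e300
        i11, i12, i22 = _inv2(x11, x12, x22)
        ll += -0.5 * (prior_df[pi_] + 3.0) * ld - 0.5 * (
            prior_s[pi_, 0] * i11 + 2.0 * prior_s[pi_, 1] * i12
            + prior_s[pi_, 2] * i22
        )
    return ll


@njit(cache=True, inline="always")
def _chol_lower(M, m):
    """In-place lower Cholesky of the leading m x m block; False if not PD."""
    for i in range(m):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= M[i, k] * M[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                M[i, i] = math.sqrt(s)
            else:
                M[i, j] = s / M[j, j]
    return True


@njit(cache=True)
def growth_gibbs_block_kernel(
    y1, y2, miss,
    cellx, herdx_kid,               # herd level of each recorded kid (q,)
    cell_ptr, cell_idx,
    anim_ptr, anim_idx,
    kid_sire_level, kid_dam_level,  # (q,) level codes, -1 if not recorded
    sire_anim, dam_anim,            # level -> pedigree position
    fam_ptr, fam_idx,               # recorded kids by dam level
    hs_ptr, hs_idx, hd_ptr, hd_idx,  # sire/dam levels by herd level
    sire_of_anim, dam_of_anim,      # pedigree parent positions
    is_sire, is_dam,
    prior_df, prior_s,              # (5,), (5,3): order a, m, p, c, e
    n_iter, burn_in, thin, seed,
    mh_steps, mh_scale, maxdim, maxfam,
):
    """Collapsed Gibbs chain for closed two-generation herd data.

    Scan: impute missing-trait residuals; sample fixed cells; draw
    (G0, M0, P0, C0) by Metropolis from their joint conditional with every
    herd-level random effect integrated out (see _block_logpost); redraw all
    herd intercepts, sire and dam breeding values, maternal, Mendelian and
    permanent effects exactly from their Gaussian conditionals; conjugate
    inverse-Wishart draw for R0.  Sampling the covariances from their
    marginal is what lets the weakly identified additive/maternal/permanent/
    common split mix; conditioning on effect vectors cannot.
    """
    np.random.seed(seed)
    n = y1.shape[0]
    ncell = cell_ptr.shape[0] - 1
    q = anim_ptr.shape[0] - 1
    nsire = sire_anim.shape[0]
    ndam = dam_anim.shape[0]
    nherd = hd_ptr.shape[0] - 1

    beta1 = np.zeros(ncell)
    beta2 = np.zeros(ncell)
    a1 = np.zeros(q)
    a2 = np.zeros(q)
    p1 = np.zeros(q)
    p2 = np.zeros(q)
    m1 = np.zeros(ndam)
    m2 = np.zeros(ndam)
    c1 = np.zeros(nherd)
    c2 = np.zeros(nherd)
    e1 = np.zeros(n)
    e2 = np.zeros(n)

    tot2 = 0.0
    cnt2 = 0.0
    for j in range(n):
        if miss[j] != 1:
            tot2 += y2[j]
            cnt2 += 1.0
    glob2 = tot2 / cnt2 if cnt2 > 0 else 0.0
    for k in range(ncell):
        s1 = 0.0
        s2 = 0.0
        c2n = 0.0
        nk = cell_ptr[k + 1] - cell_ptr[k]
        for jj in range(cell_ptr[k], cell_ptr[k + 1]):
            j = cell_idx[jj]
            if miss[j] != 2:
                s1 += y1[j]
            if miss[j] != 1:
                s2 += y2[j]
                c2n += 1.0
        beta1[k] = s1 / nk if nk > 0 else 0.0
        beta2[k] = s2 / c2n if c2n > 0 else glob2
    v1 = 0.0
    v2 = 0.0
    for j in range(n):
        e1[j] = y1[j] - beta1[cellx[j]] if miss[j] != 2 else 0.0
        e2[j] = y2[j] - beta2[cellx[j]] if miss[j] != 1 else 0.0
        v1 += e1[j] * e1[j]
        v2 += e2[j] * e2[j]
    v1 = v1 / n + 1e-3
    v2 = v2 / max(cnt2, 1.0) + 1e-3

    g11, g12, g22 = 0.25 * v1, 0.0, 0.25 * v2
    mm11, mm12, mm22 = 0.15 * v1, 0.0, 0.15 * v2
    p11, p12, p22 = 0.25 * v1, 0.0, 0.25 * v2
    cc11, cc12, cc22 = 0.15 * v1, 0.0, 0.15 * v2
    r11, r12, r22 = 0.5 * v1, 0.0, 0.5 * v2

    sire_slot = np.full(nsire, -1, dtype=np.int64)
    lamb = np.zeros((maxdim, maxdim))
    rhsb = np.zeros(maxdim)
    wvec = np.zeros(maxdim)
    sacc = np.zeros((maxfam, 3))
    racc = np.zeros((maxfam, 2))
    used = np.zeros(maxfam, dtype=np.int64)
    zbar1 = np.zeros(q)
    zbar2 = np.zeros(q)
    told1 = np.zeros(q)
    told2 = np.zeros(q)
    wts = np.zeros(q)
    theta = np.empty(12)
    prop = np.empty(12)
    covs = np.empty(12)

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, 15))
    kept = 0

    for it in range(1, n_iter + 1):
        ri11, ri12, ri22 = _inv2(r11, r12, r22)

        # --- impute residuals of missing traits
        b21 = r12 / r11
        sd2g1 = math.sqrt(max(r22 - r12 * r12 / r11, 1e-300))
        b12 = r12 / r22
        sd1g2 = math.sqrt(max(r11 - r12 * r12 / r22, 1e-300))
        for j in range(n):
            if miss[j] == 1:
                e2[j] = b21 * e1[j] + sd2g1 * np.random.standard_normal()
            elif miss[j] == 2:
                e1[j] = b12 * e2[j] + sd1g2 * np.random.standard_normal()

        # --- fixed-effect cell means (flat prior)
        for k in range(ncell):
            nk = cell_ptr[k + 1] - cell_ptr[k]
            if nk == 0:
                continue
            s1 = 0.0
            s2 = 0.0
            for jj in range(cell_ptr[k], cell_ptr[k + 1]):
                j = cell_idx[jj]
                s1 += e1[j] + beta1[k]
                s2 += e2[j] + beta2[k]
            new1, new2 = _sample_gauss2(
                nk * ri11, nk * ri12, nk * ri22,
                ri11 * s1 + ri12 * s2, ri12 * s1 + ri22 * s2,
            )
            d1 = beta1[k] - new1
            d2 = beta2[k] - new2
            for jj in range(cell_ptr[k], cell_ptr[k + 1]):
                j = cell_idx[jj]
                e1[j] += d1
                e2[j] += d2
            beta1[k] = new1
            beta2[k] = new2

        # --- per-kid record means of everything except the fixed cells
        for i in range(q):
            dl = kid_dam_level[i]
            ni = anim_ptr[i + 1] - anim_ptr[i]
            if dl >= 0 and ni > 0:
                s1 = 0.0
                s2 = 0.0
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    s1 += e1[j]
                    s2 += e2[j]
                hl = herdx_kid[i]
                told1[i] = a1[i] + p1[i] + m1[dl] + c1[hl]
                told2[i] = a2[i] + p2[i] + m2[dl] + c2[hl]
                zbar1[i] = s1 / ni + told1[i]
                zbar2[i] = s2 / ni + told2[i]
                wts[i] = ni

        # --- Metropolis on (G0, M0, P0, C0) against the herd-block marginal
        covs[0], covs[1], covs[2] = g11, g12, g22
        covs[3], covs[4], covs[5] = mm11, mm12, mm22
        covs[6], covs[7], covs[8] = p11, p12, p22
        covs[9], covs[10], covs[11] = cc11, cc12, cc22
        jac = 0.0
        for blk in range(4):
            vv1 = covs[3 * blk]
            vv2 = covs[3 * blk + 2]
            rho = covs[3 * blk + 1] / math.sqrt(vv1 * vv2)
            rho = min(max(rho, -0.999999), 0.999999)
            theta[3 * blk] = math.log(vv1)
            theta[3 * blk + 1] = math.log(vv2)
            theta[3 * blk + 2] = math.atanh(rho)
            jac += 1.5 * (theta[3 * blk] + theta[3 * blk + 1]) \
                + math.log1p(-rho * rho)
        cur = _block_logpost(
            zbar1, zbar2, wts, hd_ptr, hd_idx, fam_ptr, fam_idx,
            kid_sire_level, hs_ptr, hs_idx, sire_slot,
            lamb, rhsb, sacc, racc, used,
            r11, r12, r22,
            g11, g12, g22, mm11, mm12, mm22, p11, p12, p22, cc11, cc12, cc22,
            prior_df, prior_s,
        ) + jac
        for _ in range(mh_steps):
            jac = 0.0
            for k in range(12):
                prop[k] = theta[k] + mh_scale * np.random.standard_normal()
            for blk in range(4):
                vv1 = math.exp(prop[3 * blk])
                vv2 = math.exp(prop[3 * blk + 1])
                rho = math.tanh(prop[3 * blk + 2])
                covs[3 * blk] = vv1
                covs[3 * blk + 1] = rho * math.sqrt(vv1 * vv2)
                covs[3 * blk + 2] = vv2
                jac += 1.5 * (prop[3 * blk] + prop[3 * blk + 1]) \
                    + math.log1p(-rho * rho)
            cand = _block_logpost(
                zbar1, zbar2, wts, hd_ptr, hd_idx, fam_ptr, fam_idx,
                kid_sire_level, hs_ptr, hs_idx, sire_slot,
                lamb, rhsb, sacc, racc, used,
                r11, r12, r22,
                covs[0], covs[1], covs[2], covs[3], covs[4], covs[5],
                covs[6], covs[7], covs[8], covs[9], covs[10], covs[11],
                prior_df, prior_s,
            ) + jac
            if math.log(np.random.random() + 1e-300) < cand - cur:
                for k in range(12):
                    theta[k] = prop[k]
                cur = cand
        for blk in range(4):
            vv1 = math.exp(theta[3 * blk])
            vv2 = math.exp(theta[3 * blk + 1])
            rho = math.tanh(theta[3 * blk + 2])
            covs[3 * blk] = vv1
            covs[3 * blk + 1] = rho * math.sqrt(vv1 * vv2)
            covs[3 * blk + 2] = vv2
        g11, g12, g22 = covs[0], covs[1], covs[2]
        mm11, mm12, mm22 = covs[3], covs[4], covs[5]
        p11, p12, p22 = covs[6], covs[7], covs[8]
        cc11, cc12, cc22 = covs[9], covs[10], covs[11]

        # --- exact redraw of every random effect, herd block by herd block
        q011 = 0.5 * g11 + p11
        q012 = 0.5 * g12 + p12
        q022 = 0.5 * g22 + p22
        qi11, qi12, qi22 = _inv2(q011, q012, q022)
        sv11 = 0.25 * g11
        sv12 = 0.25 * g12
        sv22 = 0.25 * g22
        si11, si12, si22 = _inv2(sv11, sv12, sv22)
        dv11 = 0.25 * g11 + mm11
        dv12 = 0.25 * g12 + mm12
        dv22 = 0.25 * g22 + mm22
        di11, di12, di22 = _inv2(dv11, dv12, dv22)
        ci11, ci12, ci22 = _inv2(cc11, cc12, cc22)
        # dam-split gain K = Sv @ Dv^-1 and conditional covariance
        kd11 = sv11 * di11 + sv12 * di12
        kd12 = sv11 * di12 + sv12 * di22
        kd21 = sv12 * di11 + sv22 * di12
        kd22 = sv12 * di12 + sv22 * di22
        cvd11 = sv11 - (kd11 * sv11 + kd12 * sv12)
        cvd12 = sv12 - (kd11 * sv12 + kd12 * sv22)
        cvd22 = sv22 - (kd21 * sv12 + kd22 * sv22)
        # kid-split gain for the Mendelian share Gm = 0.5 G0
        gm11 = 0.5 * g11
        gm12 = 0.5 * g12
        gm22 = 0.5 * g22
        kk11 = gm11 * qi11 + gm12 * qi12
        kk12 = gm11 * qi12 + gm12 * qi22
        kk21 = gm12 * qi11 + gm22 * qi12
        kk22 = gm12 * qi12 + gm22 * qi22
        cvk11 = gm11 - (kk11 * gm11 + kk12 * gm12)
        cvk12 = gm12 - (kk11 * gm12 + kk12 * gm22)
        cvk22 = gm22 - (kk21 * gm12 + kk22 * gm22)

        for h in range(nherd):
            n_s = hs_ptr[h + 1] - hs_ptr[h]
            m = 2 * (1 + n_s)
            for t in range(hs_ptr[h], hs_ptr[h + 1]):
                sire_slot[hs_idx[t]] = 1 + (t - hs_ptr[h])
            for i2 in range(m):
                rhsb[i2] = 0.0
                for j2 in range(i2 + 1):
                    lamb[i2, j2] = 0.0
            lamb[0, 0] = ci11
            lamb[1, 0] = ci12
            lamb[1, 1] = ci22
            for t in range(n_s):
                o = 2 * (1 + t)
                lamb[o, o] = si11
                lamb[o + 1, o] = si12
                lamb[o + 1, o + 1] = si22
            for td in range(hd_ptr[h], hd_ptr[h + 1]):
                d = hd_idx[td]
                t11 = di11
                t12 = di12
                t22 = di22
                rc1 = 0.0
                rc2 = 0.0
                nu_ = 0
                for tk in range(fam_ptr[d], fam_ptr[d + 1]):
                    i = fam_idx[tk]
                    nk = int(wts[i])
                    b11 = r11 / nk + q011
                    b12 = r12 / nk + q012
                    b22 = r22 / nk + q022
                    bi11, bi12, bi22 = _inv2(b11, b12, b22)
                    z1 = zbar1[i]
                    z2 = zbar2[i]
                    t11 += bi11
                    t12 += bi12
                    t22 += bi22
                    rc1 += bi11 * z1 + bi12 * z2
                    rc2 += bi12 * z1 + bi22 * z2
                    sl = sire_slot[kid_sire_level[i]]
                    found = -1
                    for uu in range(nu_):
                        if used[uu] == sl:
                            found = uu
                            break
                    if found < 0:
                        found = nu_
                        used[nu_] = sl
                        sacc[nu_, 0] = 0.0
                        sacc[nu_, 1] = 0.0
                        sacc[nu_, 2] = 0.0
                        racc[nu_, 0] = 0.0
                        racc[nu_, 1] = 0.0
                        nu_ += 1
                    sacc[found, 0] += bi11
                    sacc[found, 1] += bi12
                    sacc[found, 2] += bi22
                    racc[found, 0] += bi11 * z1 + bi12 * z2
                    racc[found, 1] += bi12 * z1 + bi22 * z2
                ti11, ti12, ti22 = _inv2(t11, t12, t22)
                m11_ = t11 - di11
                m12_ = t12 - di12
                m22_ = t22 - di22
                tm11 = ti11 * m11_ + ti12 * m12_
                tm12 = ti11 * m12_ + ti12 * m22_
                tm21 = ti12 * m11_ + ti22 * m12_
                tm22_ = ti12 * m12_ + ti22 * m22_
                tr1 = ti11 * rc1 + ti12 * rc2
                tr2 = ti12 * rc1 + ti22 * rc2
                lamb[0, 0] += m11_ - (m11_ * tm11 + m12_ * tm21)
                lamb[1, 0] += m12_ - (m11_ * tm12 + m12_ * tm22_)
                lamb[1, 1] += m22_ - (m12_ * tm12 + m22_ * tm22_)
                rhsb[0] += rc1 - (m11_ * tr1 + m12_ * tr2)
                rhsb[1] += rc2 - (m12_ * tr1 + m22_ * tr2)
                for uu in range(nu_):
                    o = 2 * used[uu]
                    s11_ = sacc[uu, 0]
                    s12_ = sacc[uu, 1]
                    s22_ = sacc[uu, 2]
                    ts11 = ti11 * s11_ + ti12 * s12_
                    ts12 = ti11 * s12_ + ti12 * s22_
                    ts21 = ti12 * s11_ + ti22 * s12_
                    ts22 = ti12 * s12_ + ti22 * s22_
                    lamb[o, 0] += s11_ - (s11_ * tm11 + s12_ * tm21)
                    lamb[o, 1] += s12_ - (s11_ * tm12 + s12_ * tm22_)
                    lamb[o + 1, 0] += s12_ - (s12_ * tm11 + s22_ * tm21)
                    lamb[o + 1, 1] += s22_ - (s12_ * tm12 + s22_ * tm22_)
                    rhsb[o] += racc[uu, 0] - (s11_ * tr1 + s12_ * tr2)
                    rhsb[o + 1] += racc[uu, 1] - (s12_ * tr1 + s22_ * tr2)
                    for vv in range(nu_):
                        o2 = 2 * used[vv]
                        if o2 > o:
                            continue
                        w11 = sacc[vv, 0]
                        w12 = sacc[vv, 1]
                        w22 = sacc[vv, 2]
                        c11_ = ts11 * w11 + ts21 * w12
                        c12_ = ts11 * w12 + ts21 * w22
                        c21_ = ts12 * w11 + ts22 * w12
                        c22_ = ts12 * w12 + ts22 * w22
                        if o2 == o:
                            lamb[o, o] += s11_ - c11_
                            lamb[o + 1, o] += s12_ - c21_
                            lamb[o + 1, o + 1] += s22_ - c22_
                        else:
                            lamb[o, o2] += -c11_
                            lamb[o, o2 + 1] += -c12_
                            lamb[o + 1, o2] += -c21_
                            lamb[o + 1, o2 + 1] += -c22_
            # draw (c, sire halves) jointly
            _chol_lower(lamb, m)
            for i2 in range(m):
                s = rhsb[i2]
                for k2 in range(i2):
                    s -= lamb[i2, k2] * rhsb[k2]
                rhsb[i2] = s / lamb[i2, i2]
            for i2 in range(m - 1, -1, -1):
                s = rhsb[i2]
                for k2 in range(i2 + 1, m):
                    s -= lamb[k2, i2] * rhsb[k2]
                rhsb[i2] = s / lamb[i2, i2]
            for i2 in range(m - 1, -1, -1):
                s = np.random.standard_normal()
                for k2 in range(i2 + 1, m):
                    s -= lamb[k2, i2] * wvec[k2]
                wvec[i2] = s / lamb[i2, i2]
            for i2 in range(m):
                wvec[i2] += rhsb[i2]
            c1[h] = wvec[0]
            c2[h] = wvec[1]
            for t in range(hs_ptr[h], hs_ptr[h + 1]):
                s_ = hs_idx[t]
                o = 2 * sire_slot[s_]
                sa = sire_anim[s_]
                a1[sa] = 2.0 * wvec[o]
                a2[sa] = 2.0 * wvec[o + 1]
            # dams given (c, sires), then kids given everything above
            for td in range(hd_ptr[h], hd_ptr[h + 1]):
                d = hd_idx[td]
                t11 = di11
                t12 = di12
                t22 = di22
                l1 = 0.0
                l2 = 0.0
                for tk in range(fam_ptr[d], fam_ptr[d + 1]):
                    i = fam_idx[tk]
                    nk = int(wts[i])
                    b11 = r11 / nk + q011
                    b12 = r12 / nk + q012
                    b22 = r22 / nk + q022
                    bi11, bi12, bi22 = _inv2(b11, b12, b22)
                    o = 2 * sire_slot[kid_sire_level[i]]
                    z1 = zbar1[i] - wvec[0] - wvec[o]
                    z2 = zbar2[i] - wvec[1] - wvec[o + 1]
                    t11 += bi11
                    t12 += bi12
                    t22 += bi22
                    l1 += bi11 * z1 + bi12 * z2
                    l2 += bi12 * z1 + bi22 * z2
                hd1, hd2 = _sample_gauss2(t11, t12, t22, l1, l2)
                # split dam composite into 0.5 a_dam and m_dam
                mu1 = kd11 * hd1 + kd12 * hd2
                mu2 = kd21 * hd1 + kd22 * hd2
                n1, n2 = _draw_mvn2(cvd11, cvd12, cvd22)
                da = dam_anim[d]
                a1[da] = 2.0 * (mu1 + n1)
                a2[da] = 2.0 * (mu2 + n2)
                m1[d] = hd1 - (mu1 + n1)
                m2[d] = hd2 - (mu2 + n2)
                for tk in range(fam_ptr[d], fam_ptr[d + 1]):
                    i = fam_idx[tk]
                    nk = wts[i]
                    o = 2 * sire_slot[kid_sire_level[i]]
                    d1 = zbar1[i] - wvec[0] - wvec[o] - hd1
                    d2 = zbar2[i] - wvec[1] - wvec[o + 1] - hd2
                    la11 = nk * ri11 + qi11
                    la12 = nk * ri12 + qi12
                    la22 = nk * ri22 + qi22
                    gg1, gg2 = _sample_gauss2(
                        la11, la12, la22,
                        nk * (ri11 * d1 + ri12 * d2),
                        nk * (ri12 * d1 + ri22 * d2),
                    )
                    mu1 = kk11 * gg1 + kk12 * gg2
                    mu2 = kk21 * gg1 + kk22 * gg2
                    n1, n2 = _draw_mvn2(cvk11, cvk12, cvk22)
                    sa = sire_anim[kid_sire_level[i]]
                    a1[i] = 0.5 * (a1[sa] + a1[da]) + mu1 + n1
                    a2[i] = 0.5 * (a2[sa] + a2[da]) + mu2 + n2
                    p1[i] = gg1 - (mu1 + n1)
                    p2[i] = gg2 - (mu2 + n2)
                    dt1 = told1[i] - (a1[i] + p1[i] + m1[d] + c1[h])
                    dt2 = told2[i] - (a2[i] + p2[i] + m2[d] + c2[h])
                    for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                        j = anim_idx[jj]
                        e1[j] += dt1
                        e2[j] += dt2
            for t in range(hs_ptr[h], hs_ptr[h + 1]):
                sire_slot[hs_idx[t]] = -1

        # --- founders without recorded kids and unrecorded kids
        for i in range(q):
            if is_sire[i] or is_dam[i] or kid_dam_level[i] >= 0:
                continue
            si = sire_of_anim[i]
            di_ = dam_of_anim[i]
            if si < 0 and di_ < 0:
                n1, n2 = _draw_mvn2(g11, g12, g22)
                a1[i] = n1
                a2[i] = n2
            else:
                mu1 = 0.0
                mu2 = 0.0
                fac = 1.0
                if si >= 0:
                    mu1 += 0.5 * a1[si]
                    mu2 += 0.5 * a2[si]
                    fac -= 0.25
                if di_ >= 0:
                    mu1 += 0.5 * a1[di_]
                    mu2 += 0.5 * a2[di_]
                    fac -= 0.25
                n1, n2 = _draw_mvn2(fac * g11, fac * g12, fac * g22)
                a1[i] = mu1 + n1
                a2[i] = mu2 + n2

        # --- residual covariance
        r11, r12, r22 = _draw_invwishart2(
            prior_df[4] + n,
            prior_s[4, 0] + np.dot(e1, e1),
            prior_s[4, 1] + np.dot(e1, e2),
            prior_s[4, 2] + np.dot(e2, e2),
        )

        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = g11
            out[kept, 1] = g12
            out[kept, 2] = g22
            out[kept, 3] = mm11
            out[kept, 4] = mm12
            out[kept, 5] = mm22
            out[kept, 6] = p11
            out[kept, 7] = p12
            out[kept, 8] = p22
            out[kept, 9] = cc11
            out[kept, 10] = cc12
            out[kept, 11] = cc22
            out[kept, 12] = r11
            out[kept, 13] = r12
            out[kept, 14] = r22
            kept += 1
    return out


# ---------------------------------------------------------------------------
# survival AFT model (log-normal errors, right censoring by augmentation)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _logpost_pair1(lam, ut, sa, se, nu_a, s_a, nu_e, s_e):
    """Collapsed log density of (s2_a, s2_e) given rotated sums (scalar)."""
    q = lam.shape[0]
    ll = 0.0
    for i in range(q):
        v = lam[i] * sa + se
        if v <= 0.0:
            return -1e300
        ll += -0.5 * math.log(v) - 0.5 * ut[i] * ut[i] / v
    ll += -(0.5 * nu_a + 1.0) * math.log(sa) - 0.5 * s_a / sa
    ll += -(0.5 * nu_e + 1.0) * math.log(se) - 0.5 * s_e / se
    return ll


@njit(cache=True)
def survival_gibbs_kernel(
    logt0, cens, x,
    animx, damx, grpx,
    anim_ptr, anim_idx,
    dam_ptr, dam_idx,
    grp_ptr, grp_idx,
    Q, lam,
    use_a, use_m, use_c,
    prior_df, prior_s,          # (4,), (4,): order a, m, c, e
    log_horizon,
    n_iter, burn_in, thin, seed,
    mh_steps, mh_scale,
):
    """Gibbs chain for log(ST) = b0 + b1*BW + a + m + c + e with censoring.

    Censored log-times are augmented from their truncated-normal full
    conditional above log(horizon).  With one survival record per animal the
    additive and residual variances are separated only by the pedigree, so
    (s2_a, s2_e) are drawn from their collapsed conditional given u = a + e
    in the eigenbasis of A, and a is then re-split exactly; animals without
    a record get an augmented residual.  Returns (samples (n_keep, 6): b0,
    b1, s2_a, s2_m, s2_c, s2_e; min augmented log-time).
    """
    np.random.seed(seed)
    n = logt0.shape[0]
    q = Q.shape[0]
    ndam = dam_ptr.shape[0] - 1
    ngrp = grp_ptr.shape[0] - 1

    logt = logt0.copy()
    a = np.zeros(q)
    m = np.zeros(ndam)
    c = np.zeros(ngrp)

    sx = 0.0
    sxx = 0.0
    st = 0.0
    for j in range(n):
        sx += x[j]
        sxx += x[j] * x[j]
        st += logt[j]
    b0 = st / n
    b1 = 0.0
    e = np.empty(n)
    ve = 0.0
    for j in range(n):
        e[j] = logt[j] - b0
        ve += e[j] * e[j]
    ve = ve / n + 1e-3
    s2a = 0.2 * ve if use_a else 0.0
    s2m = 0.2 * ve if use_m else 0.0
    s2c = 0.2 * ve if use_c else 0.0
    s2e = 0.4 * ve

    # map pedigree animal -> its (single) record, -1 if unrecorded
    rec_of = np.full(q, -1, dtype=np.int64)
    for i in range(q):
        if anim_ptr[i + 1] > anim_ptr[i]:
            rec_of[i] = anim_idx[anim_ptr[i]]

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, 6))
    kept = 0
    min_aug = 1e300
    u = np.empty(q)

    for it in range(1, n_iter + 1):
        sde = math.sqrt(s2e)
        # --- augment censored observations
        for j in range(n):
            if cens[j]:
                mu = logt[j] - e[j]
                new_lt = _tnorm_above(mu, sde, log_horizon)
                if new_lt < min_aug:
                    min_aug = new_lt
                logt[j] = new_lt
                e[j] = new_lt - mu

        # --- fixed regression (intercept + birth-weight slope), flat prior
        sw = 0.0
        swx = 0.0
        for j in range(n):
            w = e[j] + b0 + b1 * x[j]
            sw += w
            swx += w * x[j]
        ie = 1.0 / s2e
        new0, new1 = _sample_gauss2(n * ie, sx * ie, sxx * ie, sw * ie, swx * ie)
        for j in range(n):
            e[j] += (b0 - new0) + (b1 - new1) * x[j]
        b0 = new0
        b1 = new1

        # --- maternal effects
        if use_m:
            im = 1.0 / s2m
            for d_ in range(ndam):
                nd = dam_ptr[d_ + 1] - dam_ptr[d_]
                r = 0.0
                for jj in range(dam_ptr[d_], dam_ptr[d_ + 1]):
                    r += e[dam_idx[jj]] + m[d_]
                lamv = nd * ie + im
                mean = r * ie / lamv
                new = mean + np.random.standard_normal() / math.sqrt(lamv)
                d = m[d_] - new
                for jj in range(dam_ptr[d_], dam_ptr[d_ + 1]):
                    e[dam_idx[jj]] += d
                m[d_] = new

        # --- herd-year-season effects
        if use_c:
            ic = 1.0 / s2c
            for g in range(ngrp):
                ng = grp_ptr[g + 1] - grp_ptr[g]
                r = 0.0
                for jj in range(grp_ptr[g], grp_ptr[g + 1]):
                    r += e[grp_idx[jj]] + c[g]
                lamv = ng * ie + ic
                mean = r * ie / lamv
                new = mean + np.random.standard_normal() / math.sqrt(lamv)
                d = c[g] - new
                for jj in range(grp_ptr[g], grp_ptr[g + 1]):
                    e[grp_idx[jj]] += d
                c[g] = new

        # --- additive/residual pair: collapsed Metropolis then re-split
        if use_a:
            for i in range(q):
                if rec_of[i] >= 0:
                    u[i] = a[i] + e[rec_of[i]]
                else:
                    u[i] = a[i] + sde * np.random.standard_normal()
            ut = np.dot(Q.T, u)
            t0 = math.log(s2a)
            t1 = math.log(s2e)
            cur = _logpost_pair1(
                lam, ut, s2a, s2e, prior_df[0], prior_s[0], prior_df[3], prior_s[3]
            ) + t0 + t1
            for _ in range(mh_steps):
                c0 = t0 + mh_scale * np.random.standard_normal()
                c1_ = t1 + mh_scale * np.random.standard_normal()
                cand = _logpost_pair1(
                    lam, ut, math.exp(c0), math.exp(c1_),
                    prior_df[0], prior_s[0], prior_df[3], prior_s[3]
                ) + c0 + c1_
                if math.log(np.random.random() + 1e-300) < cand - cur:
                    t0 = c0
                    t1 = c1_
                    cur = cand
            s2a = math.exp(t0)
            s2e = math.exp(t1)
            at = np.empty(q)
            for i in range(q):
                v = lam[i] * s2a + s2e
                w = lam[i] * s2a / v
                at[i] = w * ut[i] + math.sqrt(max(w * s2e, 0.0)) * \
                    np.random.standard_normal()
            a = np.dot(Q, at)
            for i in range(q):
                if rec_of[i] >= 0:
                    e[rec_of[i]] = u[i] - a[i]
        else:
            s2e = _draw_invwishart1(prior_df[3] + n, prior_s[3] + np.dot(e, e))

        # --- remaining variances
        if use_m:
            s2m = _draw_invwishart1(prior_df[1] + ndam, prior_s[1] + np.dot(m, m))
        if use_c:
            s2c = _draw_invwishart1(prior_df[2] + ngrp, prior_s[2] + np.dot(c, c))

        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = b0
            out[kept, 1] = b1
            out[kept, 2] = s2a
            out[kept, 3] = s2m
            out[kept, 4] = s2c
            out[kept, 5] = s2e
            kept += 1
    return out, min_aug


# ---------------------------------------------------------------------------
# survival AFT model, exponential residual family (Metropolis-within-Gibbs)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _exp_ll(t, is_cens, eta):
    """Exponential AFT log-likelihood term: T ~ Exp(mean exp(eta))."""
    if is_cens:
        return -t * math.exp(-eta)
    return -eta - t * math.exp(-eta)


@njit(cache=True)
def survival_exponential_kernel(
    t_days, cens, x,
    animx, damx, grpx,
    anim_ptr, anim_idx,
    dam_ptr, dam_idx,
    grp_ptr, grp_idx,
    Ainv,
    use_a, use_m, use_c,
    prior_df, prior_s,          # (3,), (3,): order a, m, c
    n_iter, burn_in, thin, seed, step,
):
    """Exponential-error AFT animal model by random-walk MH location updates.

    Random effects stay Gaussian; only the residual family changes (no s2_e).
    Returns (samples (n_keep, 5): b0, b1, s2_a, s2_m, s2_c; acceptance rate).
    """
    np.random.seed(seed)
    n = t_days.shape[0]
    q = Ainv.shape[0]
    ndam = dam_ptr.shape[0] - 1
    ngrp = grp_ptr.shape[0] - 1

    a = np.zeros(q)
    m = np.zeros(ndam)
    c = np.zeros(ngrp)
    lt = 0.0
    for j in range(n):
        lt += math.log(max(t_days[j], 0.5))
    b0 = lt / n
    b1 = 0.0
    s2a = 0.1 if use_a else 0.0
    s2m = 0.1 if use_m else 0.0
    s2c = 0.1 if use_c else 0.0

    eta = np.empty(n)
    for j in range(n):
        eta[j] = b0 + b1 * x[j]

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, 5))
    kept = 0
    n_prop = 0.0
    n_acc = 0.0

    for it in range(1, n_iter + 1):
        for which in range(2):
            delta = step * np.random.standard_normal()
            dll = 0.0
            for j in range(n):
                shift = delta if which == 0 else delta * x[j]
                dll += _exp_ll(t_days[j], cens[j], eta[j] + shift) - _exp_ll(
                    t_days[j], cens[j], eta[j]
                )
            n_prop += 1.0
            if math.log(np.random.random() + 1e-300) < dll:
                n_acc += 1.0
                if which == 0:
                    b0 += delta
                    for j in range(n):
                        eta[j] += delta
                else:
                    b1 += delta
                    for j in range(n):
                        eta[j] += delta * x[j]

        if use_a:
            for i in range(q):
                delta = step * np.random.standard_normal()
                row = Ainv[i]
                s = 0.0
                for jdx in range(q):
                    s += row[jdx] * a[jdx]
                dll = -(delta * s + 0.5 * delta * delta * row[i]) / s2a
                for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                    j = anim_idx[jj]
                    dll += _exp_ll(t_days[j], cens[j], eta[j] + delta) - _exp_ll(
                        t_days[j], cens[j], eta[j]
                    )
                n_prop += 1.0
                if math.log(np.random.random() + 1e-300) < dll:
                    n_acc += 1.0
                    a[i] += delta
                    for jj in range(anim_ptr[i], anim_ptr[i + 1]):
                        eta[anim_idx[jj]] += delta
        if use_m:
            for d_ in range(ndam):
                delta = step * np.random.standard_normal()
                dll = -(delta * m[d_] + 0.5 * delta * delta) / s2m
                for jj in range(dam_ptr[d_], dam_ptr[d_ + 1]):
                    j = dam_idx[jj]
                    dll += _exp_ll(t_days[j], cens[j], eta[j] + delta) - _exp_ll(
                        t_days[j], cens[j], eta[j]
                    )
                n_prop += 1.0
                if math.log(np.random.random() + 1e-300) < dll:
                    n_acc += 1.0
                    m[d_] += delta
                    for jj in range(dam_ptr[d_], dam_ptr[d_ + 1]):
                        eta[dam_idx[jj]] += delta
        if use_c:
            for g in range(ngrp):
                delta = step * np.random.standard_normal()
                dll = -(delta * c[g] + 0.5 * delta * delta) / s2c
                for jj in range(grp_ptr[g], grp_ptr[g + 1]):
                    j = grp_idx[jj]
                    dll += _exp_ll(t_days[j], cens[j], eta[j] + delta) - _exp_ll(
                        t_days[j], cens[j], eta[j]
                    )
                n_prop += 1.0
                if math.log(np.random.random() + 1e-300) < dll:
                    n_acc += 1.0
                    c[g] += delta
                    for jj in range(grp_ptr[g], grp_ptr[g + 1]):
                        eta[grp_idx[jj]] += delta

        if use_a:
            u = np.dot(Ainv, a)
            s2a = _draw_invwishart1(prior_df[0] + q, prior_s[0] + np.dot(a, u))
        if use_m:
            s2m = _draw_invwishart1(prior_df[1] + ndam, prior_s[1] + np.dot(m, m))
        if use_c:
            s2c = _draw_invwishart1(prior_df[2] + ngrp, prior_s[2] + np.dot(c, c))

        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = b0
            out[kept, 1] = b1
            out[kept, 2] = s2a
            out[kept, 3] = s2m
            out[kept, 4] = s2c
            kept += 1
    return out, n_acc / max(n_prop, 1.0)
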