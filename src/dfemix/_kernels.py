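"""Numba kernels for the Metropolis-Hastings DFE samplers.

One scalar variable is proposed per iteration, cycling deterministically
through the model's variable blocks.  Likelihood changes are computed
incrementally from maintained sufficient statistics (per-observation
residuals, per-line residual sums, per-category counts, per-side magnitude
sums); the full likelihood is recomputed periodically to prevent
floating-point drift.  All proposal kernels are symmetric (additive uniform
or normal deviates, deterministic flips, log-scale walks paired with
scale-invariant variance priors), so the Hastings correction is 1.

Block ids (multicategory): 0 category assignments, 1 category effects,
2 category frequencies, 3 fixed effects, 4 plate effects, 5 plate variance,
6 per-line means, 7 residual variance.

Block ids (two-sided gamma): 0 side indicators, 1 magnitudes, 2 side
frequency, 3 gamma means, 4 gamma shapes, then 5-9 as 3-7 above.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)
REFRESH_EVERY = 2_000_000
MIN_MAGNITUDE = 1e-12


@njit(cache=True)
def _delta_shift(rows, resid, line, ybar, amount):
    """Change in the residual sum of squares if resid[rows] -= amount."""
    dS = 0.0
    for k in range(rows.shape[0]):
        i = rows[k]
        yb = ybar[line[i]]
        rn = resid[i] - amount
        dS += (rn - yb) * (rn - yb) - (resid[i] - yb) * (resid[i] - yb)
    return dS


@njit(cache=True)
def _commit_shift(rows, resid, line, ybar, amount, S_line, sum_resid):
    for k in range(rows.shape[0]):
        i = rows[k]
        li = line[i]
        yb = ybar[li]
        old = resid[i]
        new = old - amount
        S_line[li] += (new - yb) * (new - yb) - (old - yb) * (old - yb)
        sum_resid[li] += new - old
        resid[i] = new


@njit(cache=True)
def _plate_prior(p, Vp):
    if p.shape[0] == 0:
        return 0.0
    ssp = 0.0
    for k in range(p.shape[0]):
        ssp += p[k] * p[k]
    return -0.5 * p.shape[0] * (LOG2PI + math.log(Vp)) - ssp / (2.0 * Vp)


@njit(cache=True)
def _obs_term(n_b, S, Ve):
    if n_b == 0:
        return 0.0
    return -0.5 * n_b * (LOG2PI + math.log(Ve)) - S / (2.0 * Ve)


@njit(cache=True)
def _tune(scales, tries, accs, b, tune_interval):
    if tries[b] >= tune_interval:
        rate = accs[b] / tries[b]
        scales[b] *= math.exp(rate - 0.25)
        if scales[b] < 1e-8:
            scales[b] = 1e-8
        elif scales[b] > 1e6:
            scales[b] = 1e6
        tries[b] = 0
        accs[b] = 0


# ---------------------------------------------------------------------------
# multicategory model
# ---------------------------------------------------------------------------


@njit(cache=True)
def _refresh_multicat(
    ys, Fd, r, line, C, e, fvals, p, ybar, Ve, Vp, q, v, include_assign,
    resid, S_line, sum_resid,
):
    n_b = ys.shape[0]
    n_c = e.shape[0]
    n_f = fvals.shape[0]
    for li in range(S_line.shape[0]):
        S_line[li] = 0.0
        sum_resid[li] = 0.0
    for i in range(n_b):
        g = 0.0
        for k in range(n_c):
            g += C[i, k] * e[k]
        ff = 0.0
        for j in range(n_f):
            ff += Fd[i, j] * fvals[j]
        pe = p[r[i]] if p.shape[0] > 0 else 0.0
        resid[i] = ys[i] - g - ff - pe
        li = line[i]
        yb = ybar[li]
        S_line[li] += (resid[i] - yb) * (resid[i] - yb)
        sum_resid[li] += resid[i]
    S = 0.0
    for li in range(S_line.shape[0]):
        S += S_line[li]
    n_m = 0
    for k in range(n_c):
        n_m += v[k]
    terms = math.lgamma(n_m + 1)
    for k in range(n_c):
        terms -= math.lgamma(v[k] + 1)
        lq = math.log(q[k])
        terms += v[k] * lq
        if include_assign:
            terms += v[k] * lq
    logL = terms + _plate_prior(p, Vp) + _obs_term(n_b, S, Ve)
    return S, logL


@njit(cache=True)
def run_multicat_kernel(
    ys, Fd, r, line,
    mut_indptr, mut_rows, rowtot,
    f_indptr, f_rows,
    plate_indptr, plate_rows,
    line_indptr,  # not needed beyond counts; cnt per line
    n_c, n_lines, n_p,
    sweep_block, sweep_idx,
    burn_in, n_iter, thin,
    seed, include_assign, e_bound, tune_interval,
    scales,
    out_e, out_q, out_v, out_ybar, out_Ve, out_Vp, out_loglik,
    acc_out, try_out,
    final_e, final_q, final_m, final_f, final_p, final_ybar, final_scalars,
):
    np.random.seed(seed)
    n_b = ys.shape[0]
    n_m = mut_indptr.shape[0] - 1
    n_f = f_indptr.shape[0] - 1

    m = np.zeros(n_m, dtype=np.int64)
    e = np.zeros(n_c)
    q = np.full(n_c, 1.0 / n_c)
    v = np.zeros(n_c, dtype=np.int64)
    v[0] = n_m
    C = np.zeros((n_b, n_c), dtype=np.int64)
    for i in range(n_b):
        C[i, 0] = rowtot[i]
    fvals = np.zeros(n_f)
    p = np.zeros(n_p)
    ybar = np.zeros(n_lines)
    Ve = 1.0
    Vp = 0.1
    resid = np.zeros(n_b)
    S_line = np.zeros(max(n_lines, 1))
    sum_resid = np.zeros(max(n_lines, 1))
    cnt_line = np.zeros(max(n_lines, 1), dtype=np.int64)
    for i in range(n_b):
        cnt_line[line[i]] += 1

    S, logL = _refresh_multicat(
        ys, Fd, r, line, C, e, fvals, p, ybar, Ve, Vp, q, v, include_assign,
        resid, S_line, sum_resid,
    )

    n_blocks = 8
    tries = np.zeros(n_blocks, dtype=np.int64)
    accs = np.zeros(n_blocks, dtype=np.int64)
    sweep_len = sweep_block.shape[0]
    total = burn_in + n_iter
    qfac = 2.0 if include_assign else 1.0

    for it in range(total):
        if it > 0 and it % REFRESH_EVERY == 0:
            S, logL = _refresh_multicat(
                ys, Fd, r, line, C, e, fvals, p, ybar, Ve, Vp, q, v,
                include_assign, resid, S_line, sum_resid,
            )
        pos = it % sweep_len
        b = sweep_block[pos]
        idx = sweep_idx[pos]
        accepted = False

        if b == 0:  # category assignment of mutation idx
            old = m[idx]
            if n_c == 2:
                new = 1 - old
            else:
                t = np.random.randint(0, n_c - 1)
                new = t if t < old else t + 1
            u = np.random.rand()
            de = e[new] - e[old]
            rows = mut_rows[mut_indptr[idx]:mut_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, de)
            dlog = -dS / (2.0 * Ve)
            dlog += math.log(v[old] * 1.0) - math.log(v[new] + 1.0)
            dlog += qfac * (math.log(q[new]) - math.log(q[old]))
            if dlog >= 0.0 or u < math.exp(dlog):
                _commit_shift(rows, resid, line, ybar, de, S_line, sum_resid)
                S += dS
                for k in range(rows.shape[0]):
                    i = rows[k]
                    C[i, old] -= 1
                    C[i, new] += 1
                v[old] -= 1
                v[new] += 1
                m[idx] = new
                logL += dlog
                accepted = True

        elif b == 1:  # effect of category idx (idx >= 1)
            de = np.random.normal(0.0, scales[1])
            u = np.random.rand()
            new_e = e[idx] + de
            if -e_bound <= new_e <= e_bound:
                dS = 0.0
                for i in range(n_b):
                    c = C[i, idx]
                    if c != 0:
                        yb = ybar[line[i]]
                        rn = resid[i] - c * de
                        dS += (rn - yb) * (rn - yb) - (resid[i] - yb) * (resid[i] - yb)
                dlog = -dS / (2.0 * Ve)
                if dlog >= 0.0 or u < math.exp(dlog):
                    for i in range(n_b):
                        c = C[i, idx]
                        if c != 0:
                            li = line[i]
                            yb = ybar[li]
                            old_r = resid[i]
                            new_r = old_r - c * de
                            S_line[li] += (new_r - yb) * (new_r - yb) - (old_r - yb) * (old_r - yb)
                            sum_resid[li] += new_r - old_r
                            resid[i] = new_r
                    S += dS
                    e[idx] = new_e
                    logL += dlog
                    accepted = True

        elif b == 2:  # frequency of category idx (idx >= 1)
            dq = (2.0 * np.random.rand() - 1.0) * scales[2]
            u = np.random.rand()
            new_qk = q[idx] + dq
            new_q0 = q[0] - dq
            if new_qk > 0.0 and new_q0 > 0.0:
                dlog = qfac * (
                    v[idx] * (math.log(new_qk) - math.log(q[idx]))
                    + v[0] * (math.log(new_q0) - math.log(q[0]))
                )
                if dlog >= 0.0 or u < math.exp(dlog):
                    q[idx] = new_qk
                    q[0] = new_q0
                    logL += dlog
                    accepted = True

        elif b == 3:  # fixed effect idx
            df = np.random.normal(0.0, scales[3])
            u = np.random.rand()
            rows = f_rows[f_indptr[idx]:f_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, df)
            dlog = -dS / (2.0 * Ve)
            if dlog >= 0.0 or u < math.exp(dlog):
                _commit_shift(rows, resid, line, ybar, df, S_line, sum_resid)
                S += dS
                fvals[idx] += df
                logL += dlog
                accepted = True

        elif b == 4:  # plate effect idx
            dp = np.random.normal(0.0, scales[4])
            u = np.random.rand()
            rows = plate_rows[plate_indptr[idx]:plate_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, dp)
            new_p = p[idx] + dp
            dlog = -dS / (2.0 * Ve) - (new_p * new_p - p[idx] * p[idx]) / (2.0 * Vp)
            if dlog >= 0.0 or u < math.exp(dlog):
                _commit_shift(rows, resid, line, ybar, dp, S_line, sum_resid)
                S += dS
                p[idx] = new_p
                logL += dlog
                accepted = True

        elif b == 5:  # plate variance, log-scale walk, 1/V prior
            dl = np.random.normal(0.0, scales[5])
            u = np.random.rand()
            new_Vp = Vp * math.exp(dl)
            if 1e-12 < new_Vp < 1e12:
                dlog = _plate_prior(p, new_Vp) - _plate_prior(p, Vp)
                if dlog >= 0.0 or u < math.exp(dlog):
                    Vp = new_Vp
                    logL += dlog
                    accepted = True

        elif b == 6:  # per-line mean idx
            db = np.random.normal(0.0, scales[6])
            u = np.random.rand()
            li = idx
            dS = (
                -2.0 * db * (sum_resid[li] - cnt_line[li] * ybar[li])
                + cnt_line[li] * db * db
            )
            dlog = -dS / (2.0 * Ve)
            if dlog >= 0.0 or u < math.exp(dlog):
                ybar[li] += db
                S_line[li] += dS
                S += dS
                logL += dlog
                accepted = True

        else:  # b == 7, residual variance, log-scale walk, 1/V prior
            dl = np.random.normal(0.0, scales[7])
            u = np.random.rand()
            new_Ve = Ve * math.exp(dl)
            if 1e-12 < new_Ve < 1e12:
                dlog = _obs_term(n_b, S, new_Ve) - _obs_term(n_b, S, Ve)
                if dlog >= 0.0 or u < math.exp(dlog):
                    Ve = new_Ve
                    logL += dlog
                    accepted = True

        tries[b] += 1
        if accepted:
            accs[b] += 1
        if it < burn_in:
            if b != 0:
                _tune(scales, tries, accs, b, tune_interval)
            if it == burn_in - 1:
                for k in range(n_blocks):
                    tries[k] = 0
                    accs[k] = 0
        else:
            s = it - burn_in + 1
            if s % thin == 0:
                d = s // thin - 1
                for k in range(n_c):
                    out_e[d, k] = e[k]
                    out_q[d, k] = q[k]
                    out_v[d, k] = v[k]
                for li in range(n_lines):
                    out_ybar[d, li] = ybar[li]
                out_Ve[d] = Ve
                out_Vp[d] = Vp
                out_loglik[d] = logL

    for k in range(n_blocks):
        acc_out[k] = accs[k]
        try_out[k] = tries[k]
    for k in range(n_c):
        final_e[k] = e[k]
        final_q[k] = q[k]
    for j in range(n_m):
        final_m[j] = m[j]
    for j in range(n_f):
        final_f[j] = fvals[j]
    for k in range(n_p):
        final_p[k] = p[k]
    for li in range(n_lines):
        final_ybar[li] = ybar[li]
    final_scalars[0] = Ve
    final_scalars[1] = Vp
    final_scalars[2] = logL


# ---------------------------------------------------------------------------
# two-sided gamma model
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gamma_side_term(vc, sumE, sumlogE, mean, shape):
    if vc == 0:
        return 0.0
    rate = shape / mean
    return (
        vc * (shape * math.log(rate) - math.lgamma(shape))
        + (shape - 1.0) * sumlogE
        - rate * sumE
    )


@njit(cache=True)
def _refresh_gamma(
    ys, Fd, r, line, mut_indptr, mut_rows,
    mu, E, a, fvals, p, ybar, Ve, Vp, q0, mean, shape, include_assign,
    resid, S_line, sum_resid, vcnt, sumE, sumlogE,
):
    n_b = ys.shape[0]
    n_m = mu.shape[0]
    n_f = fvals.shape[0]
    vcnt[0] = 0
    vcnt[1] = 0
    for s in range(2):
        sumE[s] = 0.0
        sumlogE[s] = 0.0
    for j in range(n_m):
        s = mu[j]
        mag = E[s, j]
        a[j] = mag if s == 1 else -mag
        vcnt[s] += 1
        sumE[s] += mag
        sumlogE[s] += math.log(mag)
    g = np.zeros(n_b)
    for j in range(n_m):
        rows = mut_rows[mut_indptr[j]:mut_indptr[j + 1]]
        for k in range(rows.shape[0]):
            g[rows[k]] += a[j]
    for li in range(S_line.shape[0]):
        S_line[li] = 0.0
        sum_resid[li] = 0.0
    for i in range(n_b):
        ff = 0.0
        for j in range(n_f):
            ff += Fd[i, j] * fvals[j]
        pe = p[r[i]] if p.shape[0] > 0 else 0.0
        resid[i] = ys[i] - g[i] - ff - pe
        li = line[i]
        yb = ybar[li]
        S_line[li] += (resid[i] - yb) * (resid[i] - yb)
        sum_resid[li] += resid[i]
    S = 0.0
    for li in range(S_line.shape[0]):
        S += S_line[li]
    terms = _gamma_side_term(vcnt[0], sumE[0], sumlogE[0], mean[0], shape[0])
    terms += _gamma_side_term(vcnt[1], sumE[1], sumlogE[1], mean[1], shape[1])
    lq0 = math.log(q0)
    lq1 = math.log(1.0 - q0)
    terms += (
        math.lgamma(n_m + 1)
        - math.lgamma(vcnt[0] + 1)
        - math.lgamma(vcnt[1] + 1)
        + vcnt[0] * lq0
        + vcnt[1] * lq1
    )
    if include_assign:
        terms += vcnt[0] * lq0 + vcnt[1] * lq1
    logL = terms + _plate_prior(p, Vp) + _obs_term(n_b, S, Ve)
    return S, logL


@njit(cache=True)
def _gamma_logpdf1(x, mean, shape):
    rate = shape / mean
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


@njit(cache=True)
def run_gamma_kernel(
    ys, Fd, r, line,
    mut_indptr, mut_rows,
    f_indptr, f_rows,
    plate_indptr, plate_rows,
    n_lines, n_p,
    same_mean, same_shape,
    sweep_block, sweep_idx,
    burn_in, n_iter, thin,
    seed, include_assign, mean_bound, shape_lo, shape_hi, tune_interval,
    scales,
    out_mean, out_shape, out_q1, out_v0, out_ybar, out_Ve, out_Vp,
    out_loglik, out_effects,
    acc_out, try_out,
    final_mu, final_E, final_f, final_p, final_ybar, final_scalars,
):
    np.random.seed(seed)
    n_b = ys.shape[0]
    n_m = mut_indptr.shape[0] - 1
    n_f = f_indptr.shape[0] - 1

    mu = np.zeros(n_m, dtype=np.int64)
    for j in range(n_m):
        if np.random.rand() < 0.5:
            mu[j] = 1
    mean = np.full(2, 0.1)
    shape = np.full(2, 1.0)
    E = np.zeros((2, n_m))
    for s in range(2):
        for j in range(n_m):
            val = np.random.gamma(shape[s], mean[s] / shape[s])
            E[s, j] = val if val > MIN_MAGNITUDE else MIN_MAGNITUDE
    q0 = 0.5
    a = np.zeros(n_m)
    fvals = np.zeros(n_f)
    p = np.zeros(n_p)
    ybar = np.zeros(n_lines)
    Ve = 1.0
    Vp = 0.1
    resid = np.zeros(n_b)
    S_line = np.zeros(max(n_lines, 1))
    sum_resid = np.zeros(max(n_lines, 1))
    cnt_line = np.zeros(max(n_lines, 1), dtype=np.int64)
    for i in range(n_b):
        cnt_line[line[i]] += 1
    vcnt = np.zeros(2, dtype=np.int64)
    sumE = np.zeros(2)
    sumlogE = np.zeros(2)

    S, logL = _refresh_gamma(
        ys, Fd, r, line, mut_indptr, mut_rows,
        mu, E, a, fvals, p, ybar, Ve, Vp, q0, mean, shape, include_assign,
        resid, S_line, sum_resid, vcnt, sumE, sumlogE,
    )

    n_blocks = 10
    tries = np.zeros(n_blocks, dtype=np.int64)
    accs = np.zeros(n_blocks, dtype=np.int64)
    sweep_len = sweep_block.shape[0]
    total = burn_in + n_iter
    qfac = 2.0 if include_assign else 1.0

    for it in range(total):
        if it > 0 and it % REFRESH_EVERY == 0:
            S, logL = _refresh_gamma(
                ys, Fd, r, line, mut_indptr, mut_rows,
                mu, E, a, fvals, p, ybar, Ve, Vp, q0, mean, shape,
                include_assign, resid, S_line, sum_resid, vcnt, sumE, sumlogE,
            )
        pos = it % sweep_len
        b = sweep_block[pos]
        idx = sweep_idx[pos]
        accepted = False

        if b == 0:  # side flip for mutation idx
            # the side indicator flips deterministically; the newly active
            # magnitude is redrawn from that side's current gamma (its
            # density cancels against the proposal in the acceptance ratio,
            # keeping the target exact while making side switches ergodic)
            s = mu[idx]
            t = 1 - s
            Enew = np.random.gamma(shape[t], mean[t] / shape[t])
            if Enew < MIN_MAGNITUDE:
                Enew = MIN_MAGNITUDE
            u = np.random.rand()
            Eold = E[s, idx]
            lqs = math.log(q0) if s == 0 else math.log(1.0 - q0)
            lqt = math.log(q0) if t == 0 else math.log(1.0 - q0)
            dlog = qfac * (lqt - lqs)
            dlog += math.log(vcnt[s] * 1.0) - math.log(vcnt[t] + 1.0)
            a_old = a[idx]
            a_new = Enew if t == 1 else -Enew
            da = a_new - a_old
            rows = mut_rows[mut_indptr[idx]:mut_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, da)
            dlog += -dS / (2.0 * Ve)
            if dlog >= 0.0 or u < math.exp(dlog):
                # the maintained log likelihood tracks the target, which does
                # include the gamma-density change
                dlog += _gamma_logpdf1(Enew, mean[t], shape[t]) - _gamma_logpdf1(
                    Eold, mean[s], shape[s]
                )
                _commit_shift(rows, resid, line, ybar, da, S_line, sum_resid)
                S += dS
                vcnt[s] -= 1
                vcnt[t] += 1
                sumE[s] -= Eold
                sumlogE[s] -= math.log(Eold)
                sumE[t] += Enew
                sumlogE[t] += math.log(Enew)
                mu[idx] = t
                E[t, idx] = Enew
                a[idx] = a_new
                logL += dlog
                accepted = True

        elif b == 1:  # active magnitude of mutation idx
            de = np.random.normal(0.0, scales[1])
            u = np.random.rand()
            s = mu[idx]
            old = E[s, idx]
            new = old + de
            if new > MIN_MAGNITUDE:
                rate = shape[s] / mean[s]
                dlog = (shape[s] - 1.0) * (math.log(new) - math.log(old)) - rate * de
                da = de if s == 1 else -de
                rows = mut_rows[mut_indptr[idx]:mut_indptr[idx + 1]]
                dS = _delta_shift(rows, resid, line, ybar, da)
                dlog += -dS / (2.0 * Ve)
                if dlog >= 0.0 or u < math.exp(dlog):
                    _commit_shift(rows, resid, line, ybar, da, S_line, sum_resid)
                    S += dS
                    E[s, idx] = new
                    sumE[s] += de
                    sumlogE[s] += math.log(new) - math.log(old)
                    a[idx] += da
                    logL += dlog
                    accepted = True

        elif b == 2:  # frequency of negative-effect mutations
            dq = (2.0 * np.random.rand() - 1.0) * scales[2]
            u = np.random.rand()
            new_q0 = q0 + dq
            if 0.0 < new_q0 < 1.0:
                dlog = qfac * (
                    vcnt[0] * (math.log(new_q0) - math.log(q0))
                    + vcnt[1] * (math.log(1.0 - new_q0) - math.log(1.0 - q0))
                )
                if dlog >= 0.0 or u < math.exp(dlog):
                    q0 = new_q0
                    logL += dlog
                    accepted = True

        elif b == 3:  # gamma mean for side idx (both sides when tied)
            dm = np.random.normal(0.0, scales[3])
            u = np.random.rand()
            ok = True
            dlog = 0.0
            for s in range(2):
                if s != idx and not (same_mean and idx == 0):
                    continue
                new_mean = mean[s] + dm
                if not (0.0 < new_mean < mean_bound):
                    ok = False
                    break
                dlog += _gamma_side_term(
                    vcnt[s], sumE[s], sumlogE[s], new_mean, shape[s]
                ) - _gamma_side_term(vcnt[s], sumE[s], sumlogE[s], mean[s], shape[s])
            if ok and (dlog >= 0.0 or u < math.exp(dlog)):
                for s in range(2):
                    if s == idx or (same_mean and idx == 0):
                        mean[s] = mean[s] + dm
                logL += dlog
                accepted = True

        elif b == 4:  # gamma shape for side idx (both sides when tied)
            ds = np.random.normal(0.0, scales[4])
            u = np.random.rand()
            ok = True
            dlog = 0.0
            for s in range(2):
                if s != idx and not (same_shape and idx == 0):
                    continue
                new_shape = shape[s] + ds
                if not (shape_lo <= new_shape <= shape_hi):
                    ok = False
                    break
                dlog += _gamma_side_term(
                    vcnt[s], sumE[s], sumlogE[s], mean[s], new_shape
                ) - _gamma_side_term(vcnt[s], sumE[s], sumlogE[s], mean[s], shape[s])
            if ok and (dlog >= 0.0 or u < math.exp(dlog)):
                for s in range(2):
                    if s == idx or (same_shape and idx == 0):
                        shape[s] = shape[s] + ds
                logL += dlog
                accepted = True

        elif b == 5:  # fixed effect idx
            df = np.random.normal(0.0, scales[5])
            u = np.random.rand()
            rows = f_rows[f_indptr[idx]:f_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, df)
            dlog = -dS / (2.0 * Ve)
            if dlog >= 0.0 or u < math.exp(dlog):
                _commit_shift(rows, resid, line, ybar, df, S_line, sum_resid)
                S += dS
                fvals[idx] += df
                logL += dlog
                accepted = True

        elif b == 6:  # plate effect idx
            dp = np.random.normal(0.0, scales[6])
            u = np.random.rand()
            rows = plate_rows[plate_indptr[idx]:plate_indptr[idx + 1]]
            dS = _delta_shift(rows, resid, line, ybar, dp)
            new_p = p[idx] + dp
            dlog = -dS / (2.0 * Ve) - (new_p * new_p - p[idx] * p[idx]) / (2.0 * Vp)
            if dlog >= 0.0 or u < math.exp(dlog):
                _commit_shift(rows, resid, line, ybar, dp, S_line, sum_resid)
                S += dS
                p[idx] = new_p
                logL += dlog
                accepted = True

        elif b == 7:  # plate variance
            dl = np.random.normal(0.0, scales[7])
            u = np.random.rand()
            new_Vp = Vp * math.exp(dl)
            if 1e-12 < new_Vp < 1e12:
                dlog = _plate_prior(p, new_Vp) - _plate_prior(p, Vp)
                if dlog >= 0.0 or u < math.exp(dlog):
                    Vp = new_Vp
                    logL += dlog
                    accepted = True

        elif b == 8:  # per-line mean idx
            db = np.random.normal(0.0, scales[8])
            u = np.random.rand()
            li = idx
            dS = (
                -2.0 * db * (sum_resid[li] - cnt_line[li] * ybar[li])
                + cnt_line[li] * db * db
            )
            dlog = -dS / (2.0 * Ve)
            if dlog >= 0.0 or u < math.exp(dlog):
                ybar[li] += db
                S_line[li] += dS
                S += dS
                logL += dlog
                accepted = True

        else:  # b == 9, residual variance
            dl = np.random.normal(0.0, scales[9])
            u = np.random.rand()
            new_Ve = Ve * math.exp(dl)
            if 1e-12 < new_Ve < 1e12:
                dlog = _obs_term(n_b, S, new_Ve) - _obs_term(n_b, S, Ve)
                if dlog >= 0.0 or u < math.exp(dlog):
                    Ve = new_Ve
                    logL += dlog
                    accepted = True

        tries[b] += 1
        if accepted:
            accs[b] += 1
        if it < burn_in:
            if b != 0:
                _tune(scales, tries, accs, b, tune_interval)
            if it == burn_in - 1:
                for k in range(n_blocks):
                    tries[k] = 0
                    accs[k] = 0
        else:
            s_it = it - burn_in + 1
            if s_it % thin == 0:
                d = s_it // thin - 1
                out_mean[d, 0] = mean[0]
                out_mean[d, 1] = mean[1]
                out_shape[d, 0] = shape[0]
                out_shape[d, 1] = shape[1]
                out_q1[d] = 1.0 - q0
                out_v0[d] = vcnt[0]
                for li in range(n_lines):
                    out_ybar[d, li] = ybar[li]
                out_Ve[d] = Ve
                out_Vp[d] = Vp
                out_loglik[d] = logL
                for j in range(n_m):
                    out_effects[d, j] = a[j]

    for k in range(n_blocks):
        acc_out[k] = accs[k]
        try_out[k] = tries[k]
    for j in range(n_m):
        final_mu[j] = mu[j]
        final_E[0, j] = E[0, j]
        final_E[1, j] = E[1, j]
    for j in range(n_f):
        final_f[j] = fvals[j]
    for k in range(n_p):
        final_p[k] = p[k]
    for li in range(n_lines):
        final_ybar[li] = ybar[li]
    final_scalars[0] = Ve
    final_scalars[1] = Vp
    final_scalars[2] = logL
    final_scalars[3] = q0
    final_scalars[4] = mean[0]
    final_scalars[5] = mean[1]
    final_scalars[6] = shape[0]
    final_scalars[7] = shape[1]
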