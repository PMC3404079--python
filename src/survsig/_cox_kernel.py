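"""Numba kernels for Cox partial-likelihood fitting and backward elimination.

All kernels assume rows sorted by time ascending.  They are deliberately
allocation-light: the leave-one-out / permutation machinery upstream calls them
millions of times.  Status codes returned by the Newton solver:

    0  converged (gradient norm below tolerance)
    1  singular information matrix (``fail`` = offending pivot index)
    2  monotone likelihood / divergence, |beta| > DIVERGENCE_BOUND (``fail`` = column)
    3  iteration cap reached without convergence
"""

import math

import numpy as np
from numba import njit

DIVERGENCE_BOUND = 20.0

STATUS_OK = 0
STATUS_SINGULAR = 1
STATUS_DIVERGED = 2
STATUS_MAXITER = 3


@njit(cache=True)
def nll_grad_hess(X, time, event, beta, efron):
    """Negative log partial likelihood, gradient and Hessian (Efron or Breslow ties)."""
    n, p = X.shape
    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    eta = np.zeros(n)
    w = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * beta[j]
        eta[i] = s
        w[i] = math.exp(s)
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    d1 = np.zeros(p)
    d2 = np.zeros((p, p))
    zb = np.zeros(p)
    i = n - 1
    while i >= 0:
        j = i
        ti = time[i]
        while j >= 0 and time[j] == ti:
            j -= 1
        # fold tie group (j+1 .. i) into the risk-set sums
        for k in range(j + 1, i + 1):
            wk = w[k]
            s0 += wk
            for a in range(p):
                xa = X[k, a]
                s1[a] += wk * xa
                for b in range(a, p):
                    s2[a, b] += wk * xa * X[k, b]
        d0 = 0.0
        dcount = 0
        for a in range(p):
            d1[a] = 0.0
            for b in range(p):
                d2[a, b] = 0.0
        for k in range(j + 1, i + 1):
            if event[k] == 1:
                dcount += 1
                wk = w[k]
                d0 += wk
                nll -= eta[k]
                for a in range(p):
                    xa = X[k, a]
                    grad[a] -= xa
                    d1[a] += wk * xa
                    for b in range(a, p):
                        d2[a, b] += wk * xa * X[k, b]
        if dcount > 0:
            for l in range(dcount):
                f = l / dcount if efron else 0.0
                phi = s0 - f * d0
                if not phi > 0.0:
                    # exp underflow along a diverging search direction: signal
                    # an infinitely bad objective so the line search backs off
                    return np.inf, grad, hess
                nll += math.log(phi)
                for a in range(p):
                    zb[a] = (s1[a] - f * d1[a]) / phi
                    grad[a] += zb[a]
                for a in range(p):
                    for b in range(a, p):
                        hess[a, b] += (s2[a, b] - f * d2[a, b]) / phi - zb[a] * zb[b]
        i = j
    for a in range(p):
        for b in range(a):
            hess[a, b] = hess[b, a]
    return nll, grad, hess


@njit(cache=True)
def _chol_factor(H, L):
    """Cholesky of H into L; returns (ok, failing pivot index)."""
    p = H.shape[0]
    for i in range(p):
        for j in range(i + 1):
            s = H[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-10 * (abs(H[i, i]) + 1e-300):
                    return False, i
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True, -1


@njit(cache=True)
def _chol_solve(L, b):
    p = L.shape[0]
    y = np.zeros(p)
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    x = np.zeros(p)
    for i in range(p - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _chol_inverse(L):
    p = L.shape[0]
    inv = np.zeros((p, p))
    e = np.zeros(p)
    for j in range(p):
        for k in range(p):
            e[k] = 0.0
        e[j] = 1.0
        col = _chol_solve(L, e)
        for i in range(p):
            inv[i, j] = col[i]
    return inv


@njit(cache=True)
def newton_cox(X, time, event, beta0, efron, tol, max_iter):
    """Newton–Raphson maximizer of the Cox log partial likelihood.

    Returns (beta, cov, nll, grad_norm, n_iter, status, fail_index).
    ``cov`` is the inverse observed information at the returned beta (zeros when
    the factorization failed).
    """
    n, p = X.shape
    beta = beta0.copy()
    cov = np.zeros((p, p))
    L = np.zeros((p, p))
    nll, grad, hess = nll_grad_hess(X, time, event, beta, efron)
    if not np.isfinite(nll):
        worst = 0
        for a in range(p):
            if abs(beta[a]) > abs(beta[worst]):
                worst = a
        return beta, cov, nll, 0.0, 0, STATUS_DIVERGED, worst
    gnorm = 0.0
    for a in range(p):
        gnorm += grad[a] * grad[a]
    gnorm = math.sqrt(gnorm)
    status = STATUS_MAXITER
    fail = -1
    it = 0
    while it < max_iter:
        if gnorm < tol:
            status = STATUS_OK
            break
        worst = -1
        for a in range(p):
            if abs(beta[a]) > DIVERGENCE_BOUND:
                if worst < 0 or abs(beta[a]) > abs(beta[worst]):
                    worst = a
        if worst >= 0:
            return beta, cov, nll, gnorm, it, STATUS_DIVERGED, worst
        ok, fi = _chol_factor(hess, L)
        if not ok:
            return beta, cov, nll, gnorm, it, STATUS_SINGULAR, fi
        delta = _chol_solve(L, -grad)
        step = 1.0
        accepted = False
        for _ in range(40):
            nb = beta + step * delta
            nnll, ngrad, nhess = nll_grad_hess(X, time, event, nb, efron)
            if nnll <= nll + 1e-10 * (abs(nll) + 1.0):
                beta = nb
                nll = nnll
                grad = ngrad
                hess = nhess
                accepted = True
                break
            step *= 0.5
        it += 1
        if not accepted:
            # cannot improve: either at the optimum (small gradient) or stuck
            status = STATUS_OK if gnorm < 1e-5 else STATUS_MAXITER
            break
        gnorm = 0.0
        for a in range(p):
            gnorm += grad[a] * grad[a]
        gnorm = math.sqrt(gnorm)
    if status == STATUS_MAXITER and gnorm < tol:
        status = STATUS_OK
    worst = -1
    for a in range(p):
        if abs(beta[a]) > DIVERGENCE_BOUND:
            if worst < 0 or abs(beta[a]) > abs(beta[worst]):
                worst = a
    if worst >= 0:
        return beta, cov, nll, gnorm, it, STATUS_DIVERGED, worst
    ok, fi = _chol_factor(hess, L)
    if ok:
        cov = _chol_inverse(L)
    elif status == STATUS_OK:
        status = STATUS_SINGULAR
        fail = fi
    return beta, cov, nll, gnorm, it, status, fail


@njit(cache=True)
def wald_p(z):
    """Two-sided normal tail probability of a Wald z statistic."""
    return math.erfc(abs(z) / math.sqrt(2.0))


# backward-elimination flag bits
FLAG_FORCED_DROP = 1
FLAG_NONCONVERGED = 2
FLAG_EMPTY = 4


@njit(cache=True)
def backward_eliminate_core(X, time, event, active0, is_mandatory, name_rank,
                            p_remove, efron, tol, max_iter, beta_init):
    """Backward elimination over columns ``active0`` of X (rows time-sorted).

    Mandatory columns (``is_mandatory`` indexed by X column) are never eligible
    for removal.  Non-identifiable or diverging columns are force-dropped so the
    procedure always terminates.  Ties in the maximal Wald p are broken by
    removing the column with the larger ``name_rank`` (lexicographically last).
    ``beta_init`` (aligned with ``active0``) warm-starts the first fit; it only
    affects iteration counts, never the (unique) optimum.

    Returns (active, beta, se, pvals, nll, flags, forced, n_forced).
    """
    nact = active0.shape[0]
    active = active0.copy()
    n = X.shape[0]
    beta = beta_init.copy()
    se = np.zeros(nact)
    pvals = np.zeros(nact)
    forced = np.empty(nact if nact > 0 else 1, np.int64)
    n_forced = 0
    flags = 0
    nll = 0.0
    while nact > 0:
        Xa = np.empty((n, nact))
        for i in range(n):
            for j in range(nact):
                Xa[i, j] = X[i, active[j]]
        b, cov, nll, gnorm, it, status, fail = newton_cox(
            Xa, time, event, beta[:nact].copy(), efron, tol, max_iter)
        if status == STATUS_SINGULAR or status == STATUS_DIVERGED:
            # drop the offending column and refit; spare mandatory covariates
            # when any non-mandatory alternative exists
            drop = fail if fail >= 0 else nact - 1
            if is_mandatory[active[drop]]:
                alt = -1
                if status == STATUS_DIVERGED:
                    # worst-diverging non-mandatory coefficient
                    for j in range(nact):
                        if not is_mandatory[active[j]]:
                            if alt < 0 or abs(b[j]) > abs(b[alt]):
                                alt = j
                else:
                    # latest non-mandatory column entering the dependency
                    for j in range(drop - 1, -1, -1):
                        if not is_mandatory[active[j]]:
                            alt = j
                            break
                if alt >= 0:
                    drop = alt
            forced[n_forced] = active[drop]
            n_forced += 1
            flags |= FLAG_FORCED_DROP
            for j in range(drop, nact - 1):
                active[j] = active[j + 1]
                beta[j] = beta[j + 1] if status == STATUS_DIVERGED else 0.0
            nact -= 1
            continue
        if status == STATUS_MAXITER:
            flags |= FLAG_NONCONVERGED
        for j in range(nact):
            beta[j] = b[j]
            se[j] = math.sqrt(cov[j, j]) if cov[j, j] > 0 else 0.0
            if se[j] > 0:
                pvals[j] = wald_p(b[j] / se[j])
            else:
                pvals[j] = 1.0
        # most removable eligible variable
        best = -1
        best_p = -1.0
        best_rank = -1
        for j in range(nact):
            if is_mandatory[active[j]]:
                continue
            pj = pvals[j]
            rj = name_rank[active[j]]
            if pj > best_p or (pj == best_p and rj > best_rank):
                best = j
                best_p = pj
                best_rank = rj
        if best < 0 or best_p <= p_remove:
            break
        for j in range(best, nact - 1):
            active[j] = active[j + 1]
            beta[j] = beta[j + 1]
        nact -= 1
    if nact == 0:
        flags |= FLAG_EMPTY
    return (active[:nact], beta[:nact].copy(), se[:nact].copy(),
            pvals[:nact].copy(), nll, flags, forced[:n_forced], n_forced)


@njit(cache=True)
def loocv_assign(X, time, event, active0, is_mandatory, name_rank,
                 p_remove, efron, tol, max_iter):
    """Leave-one-out risk-group assignment on time-sorted data.

    For each held-out row the full backward-elimination model build is repeated
    on the remaining rows; the held-out subject is assigned high risk (1) iff
    its prognostic index is >= the median training prognostic index.

    Returns (group, pi, fold_flags) aligned with the sorted rows.
    """
    n, p = X.shape
    group = np.zeros(n, np.int64)
    pi = np.zeros(n)
    fold_flags = np.zeros(n, np.int64)
    Xf = np.empty((n - 1, p))
    tf = np.empty(n - 1)
    ef = np.empty(n - 1, event.dtype)
    # warm start every fold's first fit from the full-data solution over the
    # full candidate set (pure iteration-count optimization)
    beta_init = np.zeros(active0.shape[0])
    if active0.shape[0] > 0:
        Xa0 = np.empty((n, active0.shape[0]))
        for i in range(n):
            for j in range(active0.shape[0]):
                Xa0[i, j] = X[i, active0[j]]
        b0, cov0, nll0, g0, it0, st0, f0 = newton_cox(
            Xa0, time, event, beta_init.copy(), efron, tol, max_iter)
        if st0 == STATUS_OK:
            beta_init = b0
    for held in range(n):
        r = 0
        for i in range(n):
            if i == held:
                continue
            for j in range(p):
                Xf[r, j] = X[i, j]
            tf[r] = time[i]
            ef[r] = event[i]
            r += 1
        active, beta, se, pvals, nll, flags, forced, n_forced = backward_eliminate_core(
            Xf, tf, ef, active0, is_mandatory, name_rank,
            p_remove, efron, tol, max_iter, beta_init)
        fold_flags[held] = flags
        k = active.shape[0]
        if k == 0:
            pi[held] = 0.0
            group[held] = 1  # PI 0 >= median 0 -> high risk by the >= rule
            continue
        train_pi = np.zeros(n - 1)
        for i in range(n - 1):
            s = 0.0
            for j in range(k):
                s += Xf[i, active[j]] * beta[j]
            train_pi[i] = s
        med = np.median(train_pi)
        s = 0.0
        for j in range(k):
            s += X[held, active[j]] * beta[j]
        pi[held] = s
        group[held] = 1 if s >= med else 0
    return group, pi, fold_flags
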