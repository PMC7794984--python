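"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a route independent of the
implementation it checks: the SVR dual is solved by a generic constrained
optimizer, the interval consensus by a line-for-line transcription of the
published procedure, and the bias-corrected smoother by direct expansion
of the geometric weight sum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def qp_svr_predict(times, targets, C, gamma, epsilon, eval_times):
    """Solve the epsilon-SVR dual as a generic box-constrained QP.

    Variables z = [alpha; alpha_star] with 0 <= z <= C and
    sum(alpha - alpha_star) = 0; maximize
    -1/2 (a-a*)' K (a-a*) - eps * sum(a+a*) + y'(a-a*).
    The bias is recovered from the KKT interval (its midpoint; free
    support vectors pin it exactly).  SLSQP is accurate enough at n <= 15.
    """
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(targets, dtype=float).ravel()
    n = t.size
    K = np.exp(-gamma * (t[:, None] - t[None, :]) ** 2)

    def neg_dual(z):
        d = z[:n] - z[n:]
        return 0.5 * d @ K @ d + epsilon * z.sum() - y @ d

    def neg_dual_grad(z):
        d = z[:n] - z[n:]
        Kd = K @ d
        return np.concatenate([Kd + epsilon - y, -Kd + epsilon + y])

    cons = {"type": "eq",
            "fun": lambda z: z[:n].sum() - z[n:].sum(),
            "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(neg_dual, np.zeros(2 * n), jac=neg_dual_grad,
                   bounds=[(0.0, C)] * (2 * n), constraints=[cons],
                   method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success, res.message
    z = res.x
    d = z[:n] - z[n:]
    f_nob = K @ d

    # KKT bias interval: for free alpha_i, b = y_i - eps - f_nob_i; for free
    # alpha*_i, b = y_i + eps - f_nob_i; bound/zero multipliers give one-sided
    # constraints.  Intersect and take the midpoint.
    tol = 1e-6 * max(C, 1.0)
    lo, hi = -np.inf, np.inf
    for i in range(n):
        a, a_s = z[i], z[n + i]
        up = y[i] - epsilon - f_nob[i]      # b for points on the upper edge
        dn = y[i] + epsilon - f_nob[i]      # b for points on the lower edge
        if a > tol and a < C - tol:
            lo, hi = max(lo, up), min(hi, up)
        elif a_s > tol and a_s < C - tol:
            lo, hi = max(lo, dn), min(hi, dn)
        else:
            if a <= tol and a_s <= tol:        # inside the tube
                lo, hi = max(lo, up), min(hi, dn)
            elif a >= C - tol:                 # above the tube
                hi = min(hi, up)
            elif a_s >= C - tol:               # below the tube
                lo = max(lo, dn)
    if not np.isfinite(lo):
        lo = hi
    if not np.isfinite(hi):
        hi = lo
    b = (lo + hi) / 2.0

    ev = np.asarray(eval_times, dtype=float).ravel()
    Ke = np.exp(-gamma * (ev[:, None] - t[None, :]) ** 2)
    return Ke @ d + b, d, b


def naive_consensus(peak_times, tolerance=0.05, mode="tolerance"):
    """Line-for-line transcription of the published in-window procedure.

    m peaks -> m-1 intervals sorted largest-to-smallest into P; E holds
    the m-2 adjacent differences; repeatedly the smallest E(i) is retired
    to +inf and P(i), P(i+1) join H (each position once); in tolerance
    mode the loop stops when the smallest remaining difference exceeds the
    tolerance.  Returns (H, A) with A = mean(H) or NaN.
    """
    times = sorted(peak_times)
    m = len(times)
    assert m >= 3
    intervals = [times[i + 1] - times[i] for i in range(m - 1)]
    P = sorted(intervals, reverse=True)
    E = [P[i] - P[i + 1] for i in range(len(P) - 1)]
    in_H = [False] * len(P)
    while True:
        finite = [(e, i) for i, e in enumerate(E) if e != np.inf]
        if not finite:
            break
        emin, i = min(finite)
        if mode == "tolerance" and emin > tolerance:
            break
        E[i] = np.inf
        in_H[i] = True
        in_H[i + 1] = True
    H = [p for p, keep in zip(P, in_H) if keep]
    A = float(np.mean(H)) if H else float("nan")
    return H, A


def ewma_expansion(f, beta):
    """Bias-corrected EWMA by direct expansion of the geometric weights:
    F_t = sum_{k=1..t} (1-beta) beta^(t-k) f_k / (1 - beta^t)."""
    f = np.asarray(f, dtype=float)
    out = np.empty(f.size)
    for t in range(1, f.size + 1):
        weights = (1 - beta) * beta ** (t - np.arange(1, t + 1))
        out[t - 1] = float(weights @ f[:t]) / (1 - beta ** t)
    return out
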