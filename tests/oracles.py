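"""Independent brute-force oracles used by the tests.

Everything here is deliberately written in the most literal way possible
(explicit DP tables, element-wise loops, exhaustive enumeration) and shares
no code with the package implementation it checks.
"""

import numpy as np


def sw_dp_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Full Gotoh dynamic-programming Smith-Waterman.

    Affine gaps: a gap of length L costs gap_open + (L-1)*gap_extend.
    Returns the maximum over all cells of the match matrix H (0 included,
    so the empty alignment floors the score at zero).
    """
    la, lb = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nucleotide_score_fn(match: float, mismatch: float):
    def fn(x, y):
        return match if (x == y and x in "ACGT" and y in "ACGT") else mismatch

    return fn


def matrix_score_fn(matrix):
    """score_fn from a Biopython substitution_matrices Array."""

    def fn(x, y):
        return float(matrix[x, y])

    return fn


def plain_lmf_objective(U, V, Y, c, lambda_l, lambda_p):
    """Weighted logistic-MF loss with ridge terms only, element by element."""
    m, n = Y.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            x = float(np.dot(U[i], V[j]))
            w = 1.0 + c * Y[i, j] - Y[i, j]
            total += w * np.log1p(np.exp(-abs(x))) + w * max(x, 0.0)
            total -= c * Y[i, j] * x
    for i in range(m):
        total += 0.5 * lambda_l * float(np.dot(U[i], U[i]))
    for j in range(n):
        total += 0.5 * lambda_p * float(np.dot(V[j], V[j]))
    return total


def plain_lmf_gradients(U, V, Y, c, lambda_l, lambda_p):
    """Element-wise gradients of plain_lmf_objective."""
    m, n = Y.shape
    r = U.shape[1]
    dU = np.zeros_like(U)
    dV = np.zeros_like(V)
    for i in range(m):
        for j in range(n):
            x = float(np.dot(U[i], V[j]))
            p = 1.0 / (1.0 + np.exp(-x))
            w = 1.0 + c * Y[i, j] - Y[i, j]
            coeff = w * p - c * Y[i, j]
            for k in range(r):
                dU[i, k] += coeff * V[j, k]
                dV[j, k] += coeff * U[i, k]
    dU += lambda_l * U
    dV += lambda_p * V
    return dU, dV


def full_objective_loops(U, V, Y, A_l, A_p, c, lambda_l, lambda_p, alpha, beta):
    """Literal element-wise transcription of the regularized objective:
    weighted logistic data term plus ridge plus the neighborhood sums
    (alpha/2) sum a_imu ||u_i - u_mu||^2 and (beta/2) sum b_jv ||v_j - v_v||^2.
    """
    total = plain_lmf_objective(U, V, Y, c, lambda_l, lambda_p)
    m = U.shape[0]
    n = V.shape[0]
    for i in range(m):
        for mu in range(m):
            d = U[i] - U[mu]
            total += 0.5 * alpha * A_l[i, mu] * float(np.dot(d, d))
    for j in range(n):
        for v in range(n):
            d = V[j] - V[v]
            total += 0.5 * beta * A_p[j, v] * float(np.dot(d, d))
    return total


def laplacian_quadratic_form(A, U):
    """Brute-force double sum: sum_{i,mu} a_imu ||u_i - u_mu||^2."""
    q = A.shape[0]
    total = 0.0
    for i in range(q):
        for mu in range(q):
            d = U[i] - U[mu]
            total += A[i, mu] * float(np.dot(d, d))
    return total


def pair_counting_auc(labels, scores):
    """AUC by exhaustive positive-negative pair enumeration, ties 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_sweep_aupr(labels, scores):
    """Step-wise (non-interpolated) PR area by sweeping every distinct
    score as a descending threshold: sum over steps of
    (recall_k - recall_{k-1}) * precision_k."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = labels.sum()
    thresholds = np.unique(scores)[::-1]
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def finite_difference_gradients(f, U, V, step=1e-6):
    """Central finite differences of a scalar function f(U, V)."""
    dU = np.zeros_like(U)
    dV = np.zeros_like(V)
    for idx in np.ndindex(*U.shape):
        Up, Um = U.copy(), U.copy()
        Up[idx] += step
        Um[idx] -= step
        dU[idx] = (f(Up, V) - f(Um, V)) / (2 * step)
    for idx in np.ndindex(*V.shape):
        Vp, Vm = V.copy(), V.copy()
        Vp[idx] += step
        Vm[idx] -= step
        dV[idx] = (f(U, Vp) - f(U, Vm)) / (2 * step)
    return dU, dV
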