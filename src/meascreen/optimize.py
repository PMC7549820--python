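"""Inner weight optimizers for the greedy classifier search.

A compact (mu/mu_w, lambda) covariance-matrix-adaptation evolution
strategy (CMA-ES) following Hansen's standard formulation, plus a
deterministic coordinate pattern search used as a fast, reproducible
fallback in tests. Both minimise a black-box function over a box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class OptimizerResult:
    x: np.ndarray
    fun: float
    n_evals: int
    converged: bool


def cma_es(fun, x0, sigma0: float = 0.3, bounds: tuple = (-5.0, 5.0),
           max_evals: int = 200, popsize: int | None = None,
           stagnation_tol: float = 1e-4, stagnation_window: int = 20,
           rng=None) -> OptimizerResult:
    """Minimise ``fun`` with a small CMA-ES.

    Candidates are clipped to the ``bounds`` box. Stops at ``max_evals``
    or when the best value improves by less than ``stagnation_tol``
    over ``stagnation_window`` consecutive evaluations.
    """
    rng = np.random.default_rng(rng)
    mean = np.array(x0, dtype=float)
    n = mean.size
    lam = popsize or (4 + int(3 * math.log(n + 1e-12))) if n > 1 else (popsize or 6)
    lam = max(lam, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    sigma = float(sigma0)
    lo, hi = bounds

    best_x = mean.copy()
    best_f = math.inf
    history: list[float] = []
    n_evals = 0
    converged = False

    while n_evals < max_evals:
        try:
            A = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = np.eye(n)
            A = np.eye(n)
        z = rng.standard_normal((lam, n))
        xs = mean + sigma * z @ A.T
        xs = np.clip(xs, lo, hi)
        fs = np.empty(lam)
        for k in range(lam):
            fs[k] = fun(xs[k])
        n_evals += lam
        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()
        history.append(best_f)
        if len(history) * lam >= stagnation_window and len(history) >= 3:
            span = max(2, stagnation_window // lam)
            if history[-span] - history[-1] < stagnation_tol:
                converged = True
                break

        sel = xs[order[:mu]]
        y = (sel - mean) / sigma
        y_w = w @ y
        mean = mean + sigma * y_w

        c_inv_sqrt = np.linalg.inv(A).T @ np.linalg.inv(A)  # C^-1
        # use eigen route for C^{-1/2} p_s update
        evals_, evecs_ = np.linalg.eigh(C)
        evals_ = np.clip(evals_, 1e-20, None)
        inv_sqrt = evecs_ @ np.diag(evals_ ** -0.5) @ evecs_.T
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mu_eff) * inv_sqrt @ y_w
        hsig = (np.linalg.norm(ps)
                / math.sqrt(1 - (1 - cs) ** (2 * (n_evals // lam + 1)))
                < (1.4 + 2 / (n + 1)) * chi_n)
        pc = (1 - cc) * pc + (math.sqrt(cc * (2 - cc) * mu_eff) * y_w
                              if hsig else 0.0)
        rank1 = np.outer(pc, pc)
        rank_mu = sum(wk * np.outer(yk, yk) for wk, yk in zip(w, y))
        C = ((1 - c1 - cmu) * C + c1 * rank1 + cmu * rank_mu)
        C = (C + C.T) / 2
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, (hi - lo))

    return OptimizerResult(x=best_x, fun=best_f, n_evals=n_evals,
                           converged=converged)


def coordinate_search(fun, x0, step0: float = 0.5,
                      bounds: tuple = (-5.0, 5.0), max_evals: int = 200,
                      min_step: float = 1e-3, rng=None) -> OptimizerResult:
    """Deterministic coordinate pattern search (test fallback optimizer)."""
    lo, hi = bounds
    x = np.clip(np.array(x0, dtype=float), lo, hi)
    f = fun(x)
    n_evals = 1
    step = step0
    while step > min_step and n_evals < max_evals:
        improved = False
        for i in range(x.size):
            for d in (step, -step):
                if n_evals >= max_evals:
                    break
                cand = x.copy()
                cand[i] = np.clip(cand[i] + d, lo, hi)
                fc = fun(cand)
                n_evals += 1
                if fc < f - 1e-15:
                    x, f = cand, fc
                    improved = True
                    break
        if not improved:
            step /= 2
    return OptimizerResult(x=x, fun=f, n_evals=n_evals,
                           converged=step <= min_step)
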