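"""Bayesian maximum-entropy (BioEn) refinement of ensemble weights.

Given an ensemble of C conformers with reference weights w0 and a set of
observables with measured values Y_i, uncertainties sigma_i and per-chain
forward values y_i^c, BioEn minimizes the negative log posterior

    L(w) = theta * S_KL(w | w0) + chi2(w) / 2

over the weight simplex, where S_KL = sum_c w_c log(w_c / w0_c) and
chi2 = sum_i (Y_i - sum_c w_c y_i^c)^2 / sigma_i^2.  The confidence
parameter theta sets how strongly the refined weights are held near the
reference; it is chosen by an L-curve over theta.

The module also provides the importance-sampling diagnostic
S_KL^bias = sum_c w_c log(C w_c), the Kullback-Leibler divergence of the
refined weights from the uniform distribution: values well below 1 indicate
that biased chain growth placed the ensemble close to where the data want
it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "ObservableSet",
    "ReweightResult",
    "chi2",
    "s_kl",
    "s_kl_bias",
    "skl_free_energy",
    "optimize",
    "l_curve",
    "select_theta_f",
]


@dataclass
class ObservableSet:
    """Experimental observations plus the per-chain forward matrix.

    ``values`` (M,), ``sigmas`` (M,) in the observable's native units and
    ``forward`` (M, C): forward-model predictions per ensemble member.
    ``ids`` are free-form observable labels (e.g. ``"ca_shift:L284"``).
    """

    values: np.ndarray
    sigmas: np.ndarray
    forward: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        self.forward = np.atleast_2d(np.asarray(self.forward, dtype=float))
        m = len(self.values)
        if self.sigmas.shape != (m,):
            raise ValueError("values and sigmas must have equal length")
        if self.forward.shape[0] != m:
            raise ValueError(
                f"forward matrix has {self.forward.shape[0]} rows for {m} observables"
            )
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        if not self.ids:
            self.ids = [f"obs{i}" for i in range(m)]

    @property
    def n_observables(self) -> int:
        return len(self.values)

    @property
    def n_chains(self) -> int:
        return self.forward.shape[1]

    def subset(self, idx) -> "ObservableSet":
        idx = np.asarray(idx)
        return ObservableSet(
            self.values[idx],
            self.sigmas[idx],
            self.forward[idx],
            [self.ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class ReweightResult:
    weights: np.ndarray
    chi2: float
    s_kl: float
    theta: float
    converged: bool
    iterations: int
    objective: float

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "s_kl": self.s_kl,
            "theta": self.theta,
            "converged": self.converged,
            "iterations": self.iterations,
            "objective": self.objective,
        }


def _check_simplex(w: np.ndarray, name: str = "weights") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < -1e-12):
        raise ValueError(f"{name} must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1 (got {w.sum()})")
    return np.clip(w, 0.0, None)


def chi2(weights: np.ndarray, observables: ObservableSet) -> float:
    """Gaussian chi-square of the weighted ensemble averages.

    chi2 = sum_i (Y_i - <y_i>_w)^2 / sigma_i^2 with <y_i>_w = sum_c w_c y_i^c.
    """
    w = _check_simplex(weights)
    resid = observables.values - observables.forward @ w
    return float(np.sum((resid / observables.sigmas) ** 2))


def s_kl(weights: np.ndarray, reference_weights: np.ndarray) -> float:
    """Kullback-Leibler divergence sum_c w_c log(w_c / w0_c) in nats.

    0 * log 0 is treated as exactly 0.  A positive weight on a member with
    zero reference weight is an error (infinite divergence).
    """
    w = _check_simplex(weights)
    w0 = _check_simplex(np.asarray(reference_weights, dtype=float), "reference weights")
    pos = w > 0
    if np.any(w0[pos] == 0):
        raise ValueError("positive weight where reference weight is zero")
    return float(np.sum(w[pos] * np.log(w[pos] / w0[pos])))


def s_kl_bias(weights: np.ndarray, ensemble_size: int | None = None) -> float:
    """KL divergence of refined weights from uniform, sum_c w_c log(C w_c).

    Zero iff the weights are perfectly uniform; values <~ 1 indicate good
    overlap between the grown and the refined ensemble.
    """
    w = _check_simplex(weights)
    c = len(w) if ensemble_size is None else int(ensemble_size)
    if c != len(w):
        raise ValueError("ensemble_size does not match weight vector length")
    return s_kl(w, np.full(c, 1.0 / c))


def skl_free_energy(s_kl_value: float, temperature: float | None = None) -> float:
    """Mean potential-energy perturbation S_KL * k_B * T in kJ/mol.

    Interprets the entropy cost of reweighting as the average change in the
    underlying potential-energy function that would produce the refined
    ensemble directly.
    """
    from .constants import DEFAULT_TEMPERATURE, K_B_KJ_MOL

    t = DEFAULT_TEMPERATURE if temperature is None else float(temperature)
    return float(s_kl_value) * K_B_KJ_MOL * t


def _objective_pieces(g, w0, obs, theta):
    """Objective, gradient (in log-weight space) and weights for BioEn."""
    # w = w0 * exp(g) / Z, a softmax sharing one gauge degree of freedom
    logw = np.log(w0) + g
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    pos = w > 0
    skl = float(np.sum(w[pos] * np.log(w[pos] / w0[pos])))
    resid = (obs.values - obs.forward @ w) / obs.sigmas
    c2 = float(resid @ resid)
    f = theta * skl + 0.5 * c2
    # dL/dw_c, then project through the softmax Jacobian
    dw = theta * (np.log(np.clip(w / w0, 1e-300, None)) + 1.0)
    dw -= (resid / obs.sigmas) @ obs.forward
    grad = w * (dw - np.dot(w, dw))
    return f, grad, w, skl, c2


def optimize(
    observables: ObservableSet,
    reference_weights: np.ndarray,
    theta: float,
    max_iter: int = 20000,
) -> ReweightResult:
    """Minimize theta * S_KL(w|w0) + chi2(w)/2 over the weight simplex.

    The weights are parameterized as w_c = w0_c exp(g_c) / Z so the problem
    becomes smooth and unconstrained; the objective is convex in w, so the
    solution is independent of initialization.  Non-convergence is flagged
    on the result, never silent.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    w0 = _check_simplex(np.asarray(reference_weights, dtype=float), "reference weights")
    if np.any(w0 == 0):
        raise ValueError("reference weights must be strictly positive")
    if observables.n_chains != len(w0):
        raise ValueError("forward matrix width does not match ensemble size")

    g0 = np.zeros(len(w0))
    # normalize out the overall theta scale so the stopping tolerances act
    # on the same relative accuracy for any confidence level
    scale = 1.0 / max(1.0, theta)

    def fun(g):
        f, grad = _objective_pieces(g, w0, observables, theta)[:2]
        return scale * f, scale * grad

    res = minimize(
        fun,
        g0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12, "maxcor": 30},
    )
    f, grad, w, skl, c2 = _objective_pieces(res.x, w0, observables, theta)
    # gradient scale grows linearly with theta; test the scaled residual
    converged = bool(res.success or np.max(np.abs(grad)) < 1e-8 * max(1.0, theta))
    if not converged:
        logger.warning("BioEn optimizer did not converge: %s", res.message)
    return ReweightResult(
        weights=w,
        chi2=c2,
        s_kl=skl,
        theta=float(theta),
        converged=converged,
        iterations=int(res.nit),
        objective=f,
    )


def l_curve(
    observables: ObservableSet,
    reference_weights: np.ndarray,
    theta_grid,
) -> pd.DataFrame:
    """Optimize on a descending theta grid; rows are (theta, chi2, s_kl).

    As theta decreases, chi2 is non-increasing and S_KL non-decreasing; the
    curve's corner guides (but does not dictate) the choice of theta.
    """
    thetas = np.asarray(list(theta_grid), dtype=float)
    if np.any(thetas <= 0):
        raise ValueError("theta grid must be positive")
    if np.any(np.diff(thetas) > 0):
        raise ValueError("theta grid must be sorted descending")
    rows = []
    for th in thetas:
        r = optimize(observables, reference_weights, th)
        rows.append(
            {"theta": th, "chi2": r.chi2, "s_kl": r.s_kl, "converged": r.converged}
        )
    return pd.DataFrame(rows)


def select_theta_f(
    fragment_problems,
    theta_f_grid,
    global_theta: float,
    grow_and_score,
) -> tuple[float, pd.DataFrame]:
    """Pick the fragment-level confidence theta_f by the uniformity of the
    globally refined chain weights.

    ``fragment_problems`` is a list of ``(library, local_observables)``
    pairs; for each candidate theta_f all libraries are reweighted locally,
    then ``grow_and_score(libraries, global_theta) -> optimized weights``
    grows an ensemble from them and refines it globally.  The
    theta_f minimizing S_KL^bias of the refined weights is returned (ties
    broken toward the largest, i.e. gentlest, bias).
    """
    from .fragments import weight_fragments

    thetas = sorted(set(float(t) for t in theta_f_grid))
    if any(t <= 0 for t in thetas):
        raise ValueError("theta_f grid must be positive")
    rows = []
    for tf in thetas:
        libs = [
            weight_fragments(lib, data, tf) if data is not None else lib
            for lib, data in fragment_problems
        ]
        w_opt = grow_and_score(libs, global_theta)
        rows.append({"theta_f": tf, "s_kl_bias": s_kl_bias(w_opt)})
    table = pd.DataFrame(rows)
    best = table.loc[table["s_kl_bias"] <= table["s_kl_bias"].min() + 1e-12]
    chosen = float(best["theta_f"].max())
    return chosen, table
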