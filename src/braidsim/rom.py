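"""Non-intrusive reduced-order model: POD basis + per-coefficient GPR.

The snapshot matrix ``S`` (one displacement vector ``u_h`` per column) is
factorised by a thin SVD, ``S = U Sigma Z^T``.  The reduced basis ``V``
keeps the first ``L`` left singular vectors, with ``L`` either fixed or
chosen as the smallest integer whose cumulative singular-value fraction

    sum_{i<=L} sigma_i / sum_i sigma_i >= 1 - eps_pod

reaches the POD tolerance (first-power singular values; the squared
"energy" fraction is also reported in logs).  A solution is projected and
reconstructed as ``u_rb = V V^T u_h``.

The online surrogate maps parameters ``mu`` to reduced coefficients
``u_L = V^T u_h`` with ``L`` independent single-output Gaussian processes
(Matern 5/2 kernel, per-feature predictor and per-output target
standardisation).  Predicting an unseen ``mu*`` costs O(L x N_train),
independent of the full-order dimension; the per-coefficient predictive
variances can be sampled (independently - no cross-output correlation is
modelled) and mapped through ``V`` to visualise nodal uncertainty.

Accuracy is reported nodewise as Euclidean distances: the order-reduction
error ``E_rb = ||u_rb - u_h||``, the prediction error
``E_p = ||u_p - u_h||`` and the GPR error ``E_gpr = E_p - E_rb``; per-case
average (AE) and maximum (ME) over nodes, and dataset means/SDs with
exceedance counts against imaging resolutions (0.15 mm 3DRA, 0.4 mm CTA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from braidsim.dataset import Standardiser

__all__ = [
    "ReducedBasis",
    "GPRSurrogate",
    "ErrorReport",
    "AggregateErrors",
    "pod_basis",
    "cumulative_fraction",
    "project_reconstruct",
    "train_gpr",
    "predict_configuration",
    "rom_errors",
    "aggregate_errors",
]


@dataclass
class ReducedBasis:
    """Truncated POD basis with the full singular spectrum."""

    V: np.ndarray  # (N_h, L) orthonormal
    sigma: np.ndarray  # all singular values, non-increasing
    L: int
    eps_pod: float | None = None

    @property
    def singular_fraction(self) -> float:
        """Cumulative first-power singular-value fraction at L."""
        return cumulative_fraction(self.sigma, self.L)

    @property
    def energy_fraction(self) -> float:
        """Cumulative squared (energy) fraction at L, for logging."""
        s2 = self.sigma**2
        return float(s2[: self.L].sum() / s2.sum())


def cumulative_fraction(sigma: np.ndarray, L: int) -> float:
    """Fraction of the singular-value sum captured by the first L values."""
    sigma = np.asarray(sigma, dtype=float)
    return float(sigma[:L].sum() / sigma.sum())


def pod_basis(
    S: np.ndarray,
    eps_pod: float | None = None,
    L_fixed: int | None = None,
) -> ReducedBasis:
    """Extract the reduced basis from a snapshot matrix by thin SVD.

    Exactly one of ``eps_pod`` (0 < eps < 1) or ``L_fixed`` selects the
    truncation rank: with ``eps_pod``, L is the smallest integer whose
    cumulative singular-value fraction reaches ``1 - eps_pod``.

    Raises
    ------
    ValueError
        On an empty or all-zero snapshot matrix, or invalid truncation.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("snapshot matrix must be a non-empty 2-D array")
    if not np.any(S):
        raise ValueError("degenerate input: all-zero snapshot matrix")
    U, sigma, _ = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sigma > sigma[0] * 1e-14))
    if L_fixed is not None:
        if not (1 <= L_fixed <= len(sigma)):
            raise ValueError(f"L_fixed must lie in [1, {len(sigma)}]")
        L = min(L_fixed, rank)
        eps = None
    else:
        if eps_pod is None or not (0.0 < eps_pod < 1.0):
            raise ValueError("eps_pod must lie in (0, 1) when L_fixed is unset")
        frac = np.cumsum(sigma) / sigma.sum()
        L = int(np.searchsorted(frac, 1.0 - eps_pod) + 1)
        L = min(L, rank)
        eps = eps_pod
    return ReducedBasis(V=U[:, :L].copy(), sigma=sigma, L=L, eps_pod=eps)


def project_reconstruct(u_h: np.ndarray, basis: ReducedBasis):
    """Project onto the reduced space and reconstruct.

    Returns ``(u_L, u_rb)`` with ``u_L = V^T u_h`` and ``u_rb = V u_L``;
    the reconstruction norm never exceeds the input norm (orthogonal
    projection).
    """
    u_h = np.asarray(u_h, dtype=float)
    if u_h.shape[-1] != basis.V.shape[0] and u_h.shape[0] != basis.V.shape[0]:
        raise ValueError("dimension mismatch between u_h and basis")
    u_L = basis.V.T @ u_h
    u_rb = basis.V @ u_L
    return u_L, u_rb


@dataclass
class GPRSurrogate:
    """L independent single-output GPs mapping mu to reduced coefficients."""

    models: list
    mu_scaler: Standardiser
    out_scaler: Standardiser
    L: int

    def predict(self, mu_star: np.ndarray, return_std: bool = False):
        """Posterior mean (and optionally SD) of the L coefficients."""
        mu_star = np.atleast_2d(np.asarray(mu_star, dtype=float))
        Xs = self.mu_scaler.transform(mu_star)
        means = np.empty((len(mu_star), self.L))
        stds = np.empty((len(mu_star), self.L))
        for j, gp in enumerate(self.models):
            if return_std:
                m, s = gp.predict(Xs, return_std=True)
                stds[:, j] = s
            else:
                m = gp.predict(Xs)
            means[:, j] = m
        means = self.out_scaler.inverse(means)
        if return_std:
            stds = stds * self.out_scaler.std
            return means, stds
        return means


def train_gpr(
    mu_list: np.ndarray,
    uL_list: np.ndarray,
    seed: int = 0,
    noise: float = 1e-10,
) -> GPRSurrogate:
    """Fit one Matern-5/2 GP per reduced coefficient.

    Predictors and each output are standardised (statistics from the
    training set); kernel hyperparameters start at unit length-scale and
    variance with a small jitter and are optimised by marginal-likelihood
    maximisation.  Duplicated predictor rows with conflicting outputs make
    the Gram matrix ill-conditioned; a larger jitter fallback is applied
    with a warning.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    X = np.asarray(mu_list, dtype=float)
    Y = np.asarray(uL_list, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
        raise ValueError("mu_list and uL_list must be aligned 2-D arrays")
    if len(X) < 5:
        raise ValueError("at least 5 training points required")
    mu_scaler = Standardiser().fit(X)
    out_scaler = Standardiser().fit(Y)
    Xs = mu_scaler.transform(X)
    Ys = out_scaler.transform(Y)
    # duplicated predictor rows with conflicting outputs make the Gram
    # matrix singular up to jitter; fall back to a larger jitter with a
    # conditioning warning
    _, inv = np.unique(np.round(Xs, 12), axis=0, return_inverse=True)
    conflict = False
    for g in range(inv.max() + 1):
        rows = np.flatnonzero(inv == g)
        if len(rows) > 1 and np.ptp(Ys[rows], axis=0).max() > 1e-9:
            conflict = True
            break
    if conflict:
        warnings.warn(
            "duplicated predictors with conflicting outputs; "
            "ill-conditioned GP Gram matrix, using larger jitter",
            stacklevel=2,
        )
        noise = max(noise, 1e-6)
    models = []
    for j in range(Y.shape[1]):
        kernel = ConstantKernel(1.0, (1e-4, 1e4)) * Matern(
            length_scale=np.ones(X.shape[1]), nu=2.5,
            length_scale_bounds=(1e-3, 1e4),
        )
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=noise, normalize_y=False,
            random_state=seed, n_restarts_optimizer=0,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Xs, Ys[:, j])
        except np.linalg.LinAlgError:
            warnings.warn(
                "ill-conditioned GP Gram matrix; refitting with larger jitter",
                stacklevel=2,
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=max(noise, 1e-6), normalize_y=False,
                random_state=seed, n_restarts_optimizer=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Xs, Ys[:, j])
        models.append(gp)
    return GPRSurrogate(
        models=models, mu_scaler=mu_scaler, out_scaler=out_scaler,
        L=Y.shape[1],
    )


def predict_configuration(
    surrogate: GPRSurrogate,
    basis: ReducedBasis,
    mu_star: np.ndarray,
    n_samples: int = 0,
    seed: int = 0,
):
    """Predict the deployed configuration for unseen parameters.

    ``u_p = V @ u_L_hat`` with the GP posterior means.  With
    ``n_samples > 0``, coefficient-space samples are drawn from the
    per-coefficient posterior normals (independently; cross-output
    correlation is not modelled) and mapped through ``V``; returns
    ``(u_p, samples)`` with samples of shape ``(n_samples, N_h)``.
    Evaluation cost is independent of the snapshot count.
    """
    if surrogate.L != basis.L:
        raise ValueError("surrogate and basis disagree on L")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    mean, std = surrogate.predict(mu_star, return_std=True)
    u_p = basis.V @ mean[0]
    if n_samples == 0:
        return u_p
    rng = np.random.default_rng(seed)
    coeff = rng.normal(loc=mean[0], scale=std[0], size=(n_samples, basis.L))
    samples = coeff @ basis.V.T
    return u_p, samples


@dataclass
class ErrorReport:
    """Per-node and per-case errors of one test solution (mm)."""

    E_rb: np.ndarray
    E_p: np.ndarray
    E_gpr: np.ndarray
    AE_rb: float
    ME_rb: float
    AE_p: float
    ME_p: float


def rom_errors(u_h, u_rb, u_p) -> ErrorReport:
    """Nodewise Euclidean error fields and their per-case AE / ME.

    ``E_gpr = E_p - E_rb`` holds exactly, nodewise, by construction.
    """
    u_h, u_rb, u_p = (np.asarray(a, dtype=float) for a in (u_h, u_rb, u_p))
    if not (u_h.shape == u_rb.shape == u_p.shape) or u_h.size % 3:
        raise ValueError("displacement vectors must share a 3N length")
    d_rb = (u_rb - u_h).reshape(-1, 3)
    d_p = (u_p - u_h).reshape(-1, 3)
    e_rb = np.linalg.norm(d_rb, axis=1)
    e_p = np.linalg.norm(d_p, axis=1)
    return ErrorReport(
        E_rb=e_rb,
        E_p=e_p,
        E_gpr=e_p - e_rb,
        AE_rb=float(e_rb.mean()),
        ME_rb=float(e_rb.max()),
        AE_p=float(e_p.mean()),
        ME_p=float(e_p.max()),
    )


@dataclass
class AggregateErrors:
    """Dataset-level means/SDs of AE and ME with exceedance counts."""

    AE_rb_mean: float
    AE_rb_sd: float
    ME_rb_mean: float
    ME_rb_sd: float
    AE_p_mean: float
    AE_p_sd: float
    ME_p_mean: float
    ME_p_sd: float
    n_cases: int
    n_AE_p_above: dict
    n_ME_p_above: dict


def aggregate_errors(
    reports: list[ErrorReport],
    thresholds: tuple = (0.15, 0.4),
) -> AggregateErrors:
    """Aggregate per-case reports over a test set.

    ``thresholds`` are imaging resolutions (mm); the counts say in how
    many test cases AE_p / ME_p exceed each.
    """
    if not reports:
        raise ValueError("no error reports to aggregate")
    ae_rb = np.array([r.AE_rb for r in reports])
    me_rb = np.array([r.ME_rb for r in reports])
    ae_p = np.array([r.AE_p for r in reports])
    me_p = np.array([r.ME_p for r in reports])
    return AggregateErrors(
        AE_rb_mean=float(ae_rb.mean()), AE_rb_sd=float(ae_rb.std()),
        ME_rb_mean=float(me_rb.mean()), ME_rb_sd=float(me_rb.std()),
        AE_p_mean=float(ae_p.mean()), AE_p_sd=float(ae_p.std()),
        ME_p_mean=float(me_p.mean()), ME_p_sd=float(me_p.std()),
        n_cases=len(reports),
        n_AE_p_above={t: int(np.sum(ae_p > t)) for t in thresholds},
        n_ME_p_above={t: int(np.sum(me_p > t)) for t in thresholds},
    )
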