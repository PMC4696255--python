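"""Missing-value imputation by probabilistic PCA, quantile normalization,
and the move to log2 scale.

Probabilistic PCA models a d-dimensional observation y as

    y = W z + mu + eps,    z ~ N(0, I_q),    eps ~ N(0, sigma2 I_d)

and is fitted by EM with missing entries treated as additional latent
variables, exactly as in the pcaMethods tradition for expression matrices:
the arrays (here d = 6) are the variables and the probes are the
observations, since six observations of a ~26k-dimensional variable would
be hopelessly degenerate the other way around. Missing cells are replaced
by their posterior mean given the row's observed cells.

The pipeline-level convenience :func:`impute_normalize` applies the three
stages in the fixed order impute -> quantile normalize -> log2. The EM fit
itself runs on log2-transformed intensities (single-channel intensities
are log-normal, so the Gaussian factor model holds on that scale) and the
imputed values are exponentiated back before quantile normalization, which
operates on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import FlaggedMatrix


@dataclass
class PpcaModel:
    """Fitted PPCA parameters in the arrays-as-variables orientation.

    ``W`` is d x q (d = number of arrays/columns of the fitted matrix),
    ``mu`` the per-column mean, ``sigma2`` the isotropic residual variance.
    ``loglik_trace`` holds the observed-data log-likelihood at the start of
    each EM iteration and is non-decreasing up to numerical tolerance.
    """

    W: np.ndarray
    mu: np.ndarray
    sigma2: float
    n_components: int
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (few patterns when d is small)."""
    keys = {}
    for i, row in enumerate(mask):
        keys.setdefault(row.tobytes(), []).append(i)
    for key, rows in keys.items():
        obs = np.frombuffer(key, dtype=bool)
        yield np.array(rows), np.flatnonzero(obs), np.flatnonzero(~obs)


def fit_ppca(
    x: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> PpcaModel:
    """Fit the PPCA model by EM on a (rows x columns) matrix with NaNs.

    Every row and column must contain at least one observed value and
    ``n_components`` must be smaller than both dimensions. On reaching
    ``max_iter`` without meeting ``tol`` (relative parameter change) the
    model is returned with ``converged=False`` and a warning, not an
    exception.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    q = n_components
    if not 0 < q < min(n, d):
        raise ConfigError(f"n_components={q} must be in (0, min{n, d})")
    obs = ~np.isnan(x)
    if not obs.any(axis=1).all():
        raise DataError("rows with no observed value")
    if not obs.any(axis=0).all():
        raise DataError("columns with no observed value")

    rng = np.random.default_rng(seed)
    mu = np.nanmean(x, axis=0)
    total_var = float(np.nanvar(x - mu))
    if total_var == 0.0:
        total_var = 1.0
    sigma2 = total_var / 2.0
    W = rng.normal(0.0, np.sqrt(total_var / q), size=(d, q))
    floor = max(1e-12 * total_var, 1e-300)

    groups = list(_patterns(obs))
    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # observed-data log-likelihood under current parameters
        C = W @ W.T + sigma2 * np.eye(d)
        ll = 0.0
        for rows, o, _ in groups:
            Coo = C[np.ix_(o, o)]
            L = np.linalg.cholesky(Coo)
            yc = x[np.ix_(rows, o)] - mu[o]
            sol = np.linalg.solve(L, yc.T)
            ll += (
                -0.5 * rows.size * (o.size * np.log(2 * np.pi)
                                    + 2 * np.log(np.diag(L)).sum())
                - 0.5 * float((sol**2).sum())
            )
        loglik_trace.append(ll)

        # E-step sufficient statistics with augmented latent [z; 1]
        S_zz = np.zeros((q + 1, q + 1))
        S_yz = np.zeros((d, q + 1))
        sum_y2 = 0.0
        S_zz[q, q] = n
        for rows, o, miss in groups:
            r = rows.size
            Wo = W[o]
            M = Wo.T @ Wo + sigma2 * np.eye(q)
            Minv = np.linalg.inv(M)
            Yo = x[np.ix_(rows, o)]
            Ez = (Yo - mu[o]) @ Wo @ Minv.T
            Czz = sigma2 * Minv
            S_zz[:q, :q] += r * Czz + Ez.T @ Ez
            S_zz[:q, q] += Ez.sum(axis=0)
            S_zz[q, :q] += Ez.sum(axis=0)
            S_yz[o, :q] += Yo.T @ Ez
            S_yz[o, q] += Yo.sum(axis=0)
            sum_y2 += float((Yo**2).sum())
            if miss.size:
                Wm = W[miss]
                Eym = mu[miss] + Ez @ Wm.T
                S_yz[miss, :q] += r * (Wm @ Czz) + Eym.T @ Ez
                S_yz[miss, q] += Eym.sum(axis=0)
                var_m = sigma2 + np.einsum("ij,jk,ik->i", Wm, Czz, Wm)
                sum_y2 += float((Eym**2).sum()) + r * float(var_m.sum())

        # M-step: joint update of (W, mu) then sigma2
        Wt = np.linalg.solve(S_zz, S_yz.T).T  # d x (q+1)
        W_new, mu_new = Wt[:, :q], Wt[:, q]
        sigma2_new = max((sum_y2 - float(np.sum(Wt * S_yz))) / (n * d), floor)

        old = np.concatenate([W.ravel(), mu, [sigma2]])
        new = np.concatenate([W_new.ravel(), mu_new, [sigma2_new]])
        rel = np.linalg.norm(new - old) / (np.linalg.norm(old) + 1e-300)
        W, mu, sigma2 = W_new, mu_new, sigma2_new
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"PPCA EM did not converge in {max_iter} iterations "
            f"(last relative change {rel:.2e})",
            RuntimeWarning,
        )
    return PpcaModel(
        W=W, mu=mu, sigma2=sigma2, n_components=q,
        converged=converged, n_iter=it, loglik_trace=loglik_trace,
    )


def impute(x: np.ndarray, model: PpcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing cells by their PPCA posterior mean.

    Returns ``(completed, imputed_mask)``; observed cells are unchanged and
    the mask marks exactly the previously missing cells.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.W.shape[0]:
        raise DataError(
            f"matrix has {x.shape[1]} columns but model was fitted on "
            f"{model.W.shape[0]}"
        )
    out = x.copy()
    mask = np.isnan(x)
    q = model.n_components
    W, mu, sigma2 = model.W, model.mu, model.sigma2
    for rows, o, miss in _patterns(~mask):
        if miss.size == 0:
            continue
        Wo = W[o]
        M = Wo.T @ Wo + sigma2 * np.eye(q)
        Ez = (x[np.ix_(rows, o)] - mu[o]) @ Wo @ np.linalg.inv(M).T
        out[np.ix_(rows, miss)] = mu[miss] + Ez @ W[miss].T
    return out, mask


def quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Classic across-column quantile normalization.

    Each column is replaced by the mean order-statistic vector at its own
    ranks; tied entries receive the mean of their rank-block values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DataError("quantile normalization needs a matrix with >= 2 columns")
    if np.isnan(x).any():
        raise DataError("quantile normalization requires a complete matrix")
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        sorted_vals = x[order, j]
        # boundaries of tie blocks in the sorted column
        starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        block_sums = np.add.reduceat(mean_sorted, starts)
        block_lens = np.diff(np.r_[starts, n])
        block_means = block_sums / block_lens
        out[order, j] = np.repeat(block_means, block_lens)
    return out


def to_log2(x: np.ndarray) -> np.ndarray:
    """Elementwise log2; any non-positive value is a pipeline-order bug."""
    x = np.asarray(x, dtype=float)
    bad = np.argwhere(~(x > 0))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-positive value {x[i, j]!r} at cell ({i}, {j}); "
            "imputation and QC must precede the log2 transform"
        )
    return np.log2(x)


@dataclass
class NormalizedMatrix:
    """Complete probe x array log2 expression with imputation provenance."""

    values: pd.DataFrame  # probes x arrays, log2 scale, no missing
    imputed: pd.DataFrame  # boolean, same shape
    group_of: dict[str, str]

    def __post_init__(self):
        if self.values.isna().any().any():
            raise DataError("normalized matrix contains missing values")
        if self.values.shape != self.imputed.shape:
            raise DataError("provenance mask shape mismatch")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.values.columns:
            g = self.group_of.get(a)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, group: str) -> list[str]:
        return [a for a in self.values.columns if self.group_of.get(a) == group]


def impute_normalize(
    m: FlaggedMatrix,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[NormalizedMatrix, PpcaModel]:
    """Post-QC pipeline stage: impute -> quantile normalize -> log2.

    The PPCA fit runs on log2 intensities (where the Gaussian model is
    appropriate for log-normal single-channel data); imputed values are
    mapped back to the linear scale before quantile normalization so the
    stage order of the pipeline is preserved.
    """
    raw = m.intensities
    observed = ~np.isnan(raw)
    if (raw[observed] <= 0).any():
        raise DataError("non-positive intensities survive QC; run the cascade first")
    log2_raw = np.where(observed, np.log2(np.where(observed, raw, 1.0)), np.nan)
    model = fit_ppca(log2_raw, n_components=n_components, tol=tol,
                     max_iter=max_iter, seed=seed)
    if np.isnan(log2_raw).any():
        completed_log2, mask = impute(log2_raw, model)
    else:
        completed_log2, mask = log2_raw.copy(), np.zeros_like(log2_raw, dtype=bool)
    completed_linear = np.exp2(completed_log2)
    normalized = quantile_normalize(completed_linear)
    values = to_log2(normalized)
    return (
        NormalizedMatrix(
            values=pd.DataFrame(values, index=m.probe_ids, columns=m.array_ids),
            imputed=pd.DataFrame(mask, index=m.probe_ids, columns=m.array_ids),
            group_of=dict(m.group_of),
        ),
        model,
    )
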