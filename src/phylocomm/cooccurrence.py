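"""Compositional co-occurrence inference: SparCC and the checkerboard C-score.

SparCC estimates basis correlations of compositional count data from
log-ratio variances t_ij = Var(log(x_i/x_j)). Under the sparsity assumption
the basis variances ω² solve the linear system

    M ω² = t_rowsum,   M = (D−2)·I + J

and ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j), clipped to [−1, 1]. The most
strongly correlated pair is iteratively excluded from the system and the
solve repeated (each exclusion is the exact rank-1 downdate
M ← M − (e_i+e_j)(e_i+e_j)ᵀ, applied to the maintained inverse via
Sherman–Morrison). Counts are Dirichlet-smoothed (posterior draws from
counts + 1) per inner iteration and the median ρ over inner iterations is
reported. Permutation pseudo-p-values shuffle every OTU's counts across
samples independently.

The C-score is the mean number of checkerboard units over OTU pairs,
CU_ij = (r_i − S_ij)(r_j − S_ij); its null distribution comes from
fixed-fixed sequential checkerboard swaps (row and column totals preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

log = logging.getLogger(__name__)


@dataclass
class SparccResult:
    otu_ids: tuple[str, ...]
    rho: np.ndarray
    pvals: np.ndarray | None
    n_permutations: int
    settings: dict

    @property
    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.otu_ids)

    @property
    def pval_frame(self) -> pd.DataFrame | None:
        if self.pvals is None:
            return None
        return pd.DataFrame(self.pvals, index=self.otu_ids,
                            columns=self.otu_ids)


@dataclass
class CScoreResult:
    observed_c: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# SparCC

def _log_ratio_variances(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = Var(log x_i / log x_j) from the covariance of log fractions."""
    cov = np.cov(log_fracs, rowvar=False, ddof=1)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _initial_minv(d: int) -> np.ndarray:
    # closed-form inverse of M0 = (D-2) I + J
    a = 1.0 / (d - 2)
    b = -1.0 / ((d - 2) * (2 * d - 2))
    return a * np.eye(d) + b * np.ones((d, d))


def _rho_from_t(t: np.ndarray, minv: np.ndarray,
                t_rowsum: np.ndarray) -> np.ndarray:
    w = minv @ t_rowsum
    w = np.maximum(w, 1e-12)
    omega = np.sqrt(w)
    rho = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(omega, omega))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def _basis_rho_once(t: np.ndarray, excl_thresh: float,
                    excl_iters: int) -> np.ndarray:
    """One exclusion-loop pass from a log-ratio variance matrix."""
    d = t.shape[0]
    minv = _initial_minv(d)
    t_rowsum = t.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)
    excl_count = np.zeros(d, dtype=int)
    rho = _rho_from_t(t, minv, t_rowsum)
    for _ in range(excl_iters):
        cand = np.abs(rho)
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        if cand[i, j] <= excl_thresh:
            break
        if excl_count[i] >= d - 3 or excl_count[j] >= d - 3:
            log.warning("sparcc: exclusion would leave an OTU with too few "
                        "partners; stopping exclusion loop")
            break
        excluded[i, j] = excluded[j, i] = True
        excl_count[i] += 1
        excl_count[j] += 1
        t_rowsum = t_rowsum.copy()
        t_rowsum[i] -= t[i, j]
        t_rowsum[j] -= t[i, j]
        u = np.zeros(d)
        u[i] = u[j] = 1.0
        # Sherman–Morrison for M <- M - u u^T
        mu = minv @ u
        denom = 1.0 - u @ mu
        minv = minv + np.outer(mu, mu) / denom
        rho = _rho_from_t(t, minv, t_rowsum)
    return rho


def _dirichlet_log_fracs(counts: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_gamma(counts + 1.0)
    return np.log(g / g.sum(axis=1, keepdims=True))


def _sparcc_rho(counts: np.ndarray, rng: np.random.Generator,
                excl_thresh: float, excl_iters: int,
                inner_iters: int) -> np.ndarray:
    rhos = np.empty((inner_iters,) + (counts.shape[1],) * 2)
    for it in range(inner_iters):
        t = _log_ratio_variances(_dirichlet_log_fracs(counts, rng))
        rhos[it] = _basis_rho_once(t, excl_thresh, excl_iters)
    rho = np.median(rhos, axis=0)
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_correlations(counts: OtuTable | pd.DataFrame | np.ndarray,
                        excl_thresh: float = 0.1, excl_iters: int = 10,
                        inner_iters: int = 20, seed=None) -> SparccResult:
    """SparCC basis correlations (no p-values).

    Needs at least 4 samples and 4 OTUs. The +1 pseudocount (Dirichlet
    posterior draw) makes all-zero OTUs harmless but they carry no signal.
    """
    mat, otu_ids = _as_matrix(counts)
    n, d = mat.shape
    if n < 4 or d < 4:
        raise ValueError(f"SparCC needs >=4 samples and >=4 OTUs, got {n}x{d}")
    rng = np.random.default_rng(seed)
    rho = _sparcc_rho(mat, rng, excl_thresh, excl_iters, inner_iters)
    return SparccResult(otu_ids=otu_ids, rho=rho, pvals=None, n_permutations=0,
                        settings={"excl_thresh": excl_thresh,
                                  "excl_iters": excl_iters,
                                  "inner_iters": inner_iters,
                                  "seed": repr(seed)})


def sparcc_pvalues(counts: OtuTable | pd.DataFrame | np.ndarray,
                   n_perm: int = 999, seed=None, excl_thresh: float = 0.1,
                   excl_iters: int = 10, inner_iters: int = 20,
                   perm_inner_iters: int | None = None,
                   observed: SparccResult | None = None) -> SparccResult:
    """Two-sided permutation pseudo-p-values for SparCC correlations.

    Every permutation shuffles each OTU's counts across samples
    independently, breaking all inter-OTU association while keeping each
    OTU's count distribution;  p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1).
    ``perm_inner_iters`` lets the permuted re-estimates use fewer inner
    iterations than the observed estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mat, otu_ids = _as_matrix(counts)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_obs, s_perm = ss.spawn(2)
    if observed is None:
        observed = sparcc_correlations(mat if not isinstance(counts, (OtuTable, pd.DataFrame)) else counts,
                                       excl_thresh=excl_thresh,
                                       excl_iters=excl_iters,
                                       inner_iters=inner_iters, seed=s_obs)
    rho_obs = observed.rho
    pit = perm_inner_iters or inner_iters
    rng = np.random.default_rng(s_perm)
    n, d = mat.shape
    exceed = np.zeros((d, d))
    abs_obs = np.abs(rho_obs)
    for _ in range(n_perm):
        keys = rng.random((n, d))
        perm = np.take_along_axis(mat, np.argsort(keys, axis=0), axis=0)
        rho_p = _sparcc_rho(perm, rng, excl_thresh, excl_iters, pit)
        exceed += np.abs(rho_p) >= abs_obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0 / (n_perm + 1.0))
    settings = dict(observed.settings)
    settings["perm_inner_iters"] = pit
    return SparccResult(otu_ids=otu_ids, rho=rho_obs, pvals=pvals,
                        n_permutations=n_perm, settings=settings)


def _as_matrix(counts) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(counts, OtuTable):
        return counts.counts.astype(float), tuple(counts.otu_ids)
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), tuple(map(str, counts.columns))
    mat = np.asarray(counts, dtype=float)
    return mat, tuple(f"OTU_{i + 1}" for i in range(mat.shape[1]))


# ---------------------------------------------------------------------------
# C-score

def c_score(pa_matrix) -> float:
    """Mean checkerboard units over OTU pairs.

    ``pa_matrix`` is binary OTUs × samples (rows are taxa). For a pair
    (i, j): CU = (r_i − S)(r_j − S) with r the occupied-site counts and S the
    number of shared sites.
    """
    m = _as_binary(pa_matrix)
    if m.shape[0] < 2:
        raise ValueError("C-score needs at least 2 OTUs (rows)")
    r = m.sum(axis=1)
    s = m @ m.T
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(m.shape[0], k=1)
    return float(cu[iu].mean())


def _as_binary(pa_matrix) -> np.ndarray:
    m = np.asarray(pa_matrix.to_numpy() if hasattr(pa_matrix, "to_numpy")
                   else pa_matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary")
    return m.astype(np.int64)


def _swap_pass(m: np.ndarray, n_attempts: int,
               rng: np.random.Generator) -> int:
    """Sequential checkerboard swaps in place; returns successful swaps."""
    nr, nc = m.shape
    rows = rng.integers(0, nr, size=(n_attempts, 2))
    cols = rng.integers(0, nc, size=(n_attempts, 2))
    done = 0
    for (i1, i2), (j1, j2) in zip(rows, cols):
        if i1 == i2 or j1 == j2:
            continue
        a, b = m[i1, j1], m[i1, j2]
        c, d = m[i2, j1], m[i2, j2]
        if a == d and b == c and a != b:
            m[i1, j1], m[i1, j2] = b, a
            m[i2, j1], m[i2, j2] = d, c
            done += 1
    return done


def c_score_null_test(pa_matrix, n_null: int = 1000, seed=None) -> CScoreResult:
    """Fixed-fixed null-model test of the C-score.

    Null matrices preserve row and column totals exactly (sequential
    checkerboard swaps; burn-in 10 × fill attempts, thinning fill attempts
    between samples, fill = number of presences). Two-sided p from null
    ranks. A matrix without any swappable 2×2 submatrix is degenerate:
    reported with p = 1 and a flag rather than an exception.
    """
    m = _as_binary(pa_matrix).copy()
    if (m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any():
        raise ValueError("rows and columns must all have at least one presence")
    obs = c_score(m)
    fill = int(m.sum())
    rng = np.random.default_rng(seed)
    swapped = _swap_pass(m, 10 * fill, rng)
    null = np.empty(n_null)
    for k in range(n_null):
        swapped += _swap_pass(m, fill, rng)
        null[k] = c_score(m)
    if swapped == 0:
        log.warning("c_score_null_test: no swappable submatrix; degenerate")
        return CScoreResult(obs, obs, 0.0, float("nan"), 1.0, n_null,
                            degenerate=True)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    ses = (obs - mu) / sd if sd > 0 else float("nan")
    n_ge = int((null >= obs - 1e-12).sum())
    n_le = int((null <= obs + 1e-12).sum())
    p = min(1.0, 2.0 * min(1 + n_ge, 1 + n_le) / (n_null + 1))
    return CScoreResult(obs, mu, sd, ses, p, n_null,
                        degenerate=(sd == 0))
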