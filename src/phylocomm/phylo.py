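"""Phylogenetic community structure: MPD, NRI/βNRI and phylogenetic signal.

The abundance-weighted mean pairwise phylogenetic distance within a sample is

    αMPD_k = Σ_i f_ik · mean_{j≠i, f_jk>0} Δ_ij

with f_ik the relative abundance of OTU i in sample k and Δ the patristic
distance — weights sit on the focal taxon, the partner mean is unweighted.
The standardized effect size against a phylogeny-pool null (richness and the
abundance multiset preserved, taxa redrawn uniformly from all tips) gives

    NRI = −(αMPD_obs − mean(αMPD_null)) / sd(αMPD_null)

NRI > +2 is read as phylogenetic clustering (environmental filtering),
NRI < −2 as overdispersion (competitive exclusion), in between as
stochastic assembly. Between samples, βMPD is the fully abundance-weighted
cross-community pair mean Σ_i Σ_j f_ik f_jl Δ_ij, and
βNRI = (βMPD_obs − mean(βMPD_null)) / sd(βMPD_null); βNRI < −2 indicates
homogeneous selection, > +2 variable selection.

Phylogenetic signal of environmental preferences is tested with a Mantel
correlogram: phylogenetic distances partitioned into equal-width classes, a
(negated) Mantel statistic between class membership and environmental-optimum
distances per class, permutation p-values and progressive Holm correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

#: product of chunk size and squared richness kept below this many elements
_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic distance matrix with OTU ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distances must be >= 0 with zero diagonal")
        object.__setattr__(self, "values", v)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.ids)}

    def loc(self, ids) -> np.ndarray:
        idx = [self.index[i] for i in ids]
        return self.values[np.ix_(idx, idx)]


@dataclass
class SesResult:
    """Standardized effect size of αMPD for one sample."""

    sample_id: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    nri: float
    n_randomizations: int
    p_rank: float
    flagged: bool = False
    note: str = ""


@dataclass
class BetaSesResult:
    sample_i: str
    sample_j: str
    beta_mpd_observed: float
    null_mean: float
    null_sd: float
    beta_nri: float
    n_randomizations: int
    p_rank: float
    flagged: bool = False
    note: str = ""


@dataclass
class CorrelogramClass:
    index: int
    midpoint: float
    n_pairs: int
    mantel_r: float
    p_permutation: float
    p_corrected: float
    significant: bool


# ---------------------------------------------------------------------------
# distances and optima

def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances."""
    n_missing = sum(1 for node in tree.traverse(include_self=False)
                    if node.length is None)
    if n_missing:
        log.warning("%d branches lack lengths; treated as 0", n_missing)
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    if tree.count(tips=True) < 2:
        raise ValueError("need at least 2 tips for a distance matrix")
    dm = tree.tip_tip_distances()
    return DistanceMatrix(ids=tuple(str(i) for i in dm.ids),
                          values=np.asarray(dm.data, dtype=float))


def environmental_optimum(f_matrix: pd.DataFrame, env: pd.Series) -> pd.Series:
    """Abundance-weighted mean environment per OTU.

    ``f_matrix`` is samples × OTUs relative abundance; each OTU's column is
    renormalized over samples and dotted with the per-sample environmental
    values. OTUs absent from every sample are excluded (logged).
    """
    env = env.loc[f_matrix.index].astype(float)
    col_sums = f_matrix.sum(axis=0)
    absent = col_sums[col_sums == 0].index.tolist()
    if absent:
        log.info("environmental_optimum: %d OTUs absent everywhere excluded",
                 len(absent))
    present = col_sums[col_sums > 0].index
    fprime = f_matrix[present].div(col_sums[present], axis=1)
    return fprime.T.dot(env).rename("optimum")


def trait_distance_matrix(values: pd.Series) -> DistanceMatrix:
    """Absolute pairwise differences of a per-OTU trait/optimum."""
    v = values.to_numpy(dtype=float)
    return DistanceMatrix(ids=tuple(values.index),
                          values=np.abs(v[:, None] - v[None, :]))


# ---------------------------------------------------------------------------
# alpha diversity

def _align_row(f_row, dm: DistanceMatrix) -> np.ndarray:
    if isinstance(f_row, pd.Series):
        extra = set(f_row.index) - set(dm.ids)
        if extra:
            raise KeyError(f"taxa not in distance matrix: {sorted(extra)[:5]}")
        full = pd.Series(0.0, index=list(dm.ids))
        full[f_row.index] = f_row.astype(float)
        return full.to_numpy()
    f = np.asarray(f_row, dtype=float)
    if f.shape != (len(dm.ids),):
        raise ValueError("abundance vector length does not match matrix")
    return f


def alpha_mpd(f_row, dm: DistanceMatrix, mode: str = "focal") -> float:
    """Abundance-weighted mean pairwise distance of one sample.

    ``mode='focal'`` is the default (focal-taxon weights, unweighted partner
    mean); ``mode='pairwise'`` is the fully pairwise-weighted variant kept
    for sensitivity checks. Returns NaN (with a warning) for communities of
    fewer than two taxa.
    """
    f = _align_row(f_row, dm)
    mask = f > 0
    m = int(mask.sum())
    if m < 2:
        log.warning("alpha_mpd undefined for community with %d taxon", m)
        return float("nan")
    w = f[mask] / f[mask].sum()
    sub = dm.values[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
    if mode == "focal":
        partner_mean = sub.sum(axis=1) / (m - 1)
        return float(w @ partner_mean)
    if mode == "pairwise":
        ww = np.outer(w, w)
        np.fill_diagonal(ww, 0.0)
        return float((ww * sub).sum() / ww.sum())
    raise ValueError(f"unknown mode {mode!r}")


def phylogeny_pool_null(f_row: pd.Series, pool_ids, seed=None,
                        rng: np.random.Generator | None = None) -> pd.Series:
    """One phylogeny-pool randomization of a sample.

    Richness and the abundance multiset are preserved; the abundances are
    reassigned to taxa drawn uniformly without replacement from the pool.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = list(pool_ids)
    present = f_row[f_row > 0]
    if len(present) > len(pool):
        raise ValueError("sample richness exceeds pool size")
    chosen = rng.choice(len(pool), size=len(present), replace=False)
    values = present.to_numpy().copy()
    rng.shuffle(values)
    return pd.Series(values, index=[pool[i] for i in chosen], name=f_row.name)


def _random_subsets(rng, n_rand: int, pool: int, size: int) -> np.ndarray:
    """(n_rand, size) uniformly random distinct-index draws, random order."""
    return np.argsort(rng.random((n_rand, pool)), axis=1)[:, :size]


def _rank_p(null: np.ndarray, obs: float) -> float:
    n = len(null)
    p_le = (1 + int((null <= obs).sum())) / (n + 1)
    p_ge = (1 + int((null >= obs).sum())) / (n + 1)
    return min(1.0, 2.0 * min(p_le, p_ge))


def alpha_nri(f_row, dm: DistanceMatrix, pool_ids=None, n_rand: int = 1000,
              seed=None, mode: str = "focal",
              sample_id: str = "") -> SesResult:
    """SES of αMPD under the phylogeny-pool null; NRI = −SES.

    The null standard deviation is the sample sd (``ddof=1``) over the
    ``n_rand`` null αMPD values. A null sd of 0 yields a flagged result with
    undefined SES rather than an exception.
    """
    if isinstance(f_row, pd.Series) and not sample_id:
        sample_id = str(f_row.name or "")
    f = _align_row(f_row, dm)
    obs = alpha_mpd(f, dm, mode=mode)
    pool = ([dm.index[i] for i in pool_ids] if pool_ids is not None
            else np.arange(len(dm.ids)))
    pool = np.asarray(pool)
    mask = f > 0
    r = int(mask.sum())
    if r < 2 or not np.isfinite(obs):
        return SesResult(sample_id, obs, float("nan"), float("nan"),
                         float("nan"), float("nan"), n_rand, float("nan"),
                         flagged=True, note="alpha MPD undefined (richness < 2)")
    if r > len(pool):
        raise ValueError("sample richness exceeds pool size")
    w = f[mask] / f[mask].sum()
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    chunk = max(1, _CHUNK_BUDGET // (r * r))
    done = 0
    while done < n_rand:
        c = min(chunk, n_rand - done)
        idx = pool[_random_subsets(rng, c, len(pool), r)]
        sub = dm.values[idx[:, :, None], idx[:, None, :]]
        if mode == "focal":
            null[done:done + c] = (sub.sum(axis=2) / (r - 1)) @ w
        else:
            ww = np.outer(w, w)
            np.fill_diagonal(ww, 0.0)
            null[done:done + c] = (sub * ww).sum(axis=(1, 2)) / ww.sum()
        done += c
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return SesResult(sample_id, obs, mu, sd, float("nan"), float("nan"),
                         n_rand, float("nan"), flagged=True,
                         note="null sd is zero; SES undefined")
    ses = (obs - mu) / sd
    return SesResult(sample_id, obs, mu, sd, ses, -ses, n_rand,
                     _rank_p(null, obs))


# ---------------------------------------------------------------------------
# beta diversity

def beta_mpd(f_row_k, f_row_l, dm: DistanceMatrix) -> float:
    """Abundance-weighted between-sample MPD (comdist convention)."""
    fk = _align_row(f_row_k, dm)
    fl = _align_row(f_row_l, dm)
    if fk.sum() == 0 or fl.sum() == 0:
        raise ValueError("beta_mpd needs two non-empty samples")
    mk, ml = fk > 0, fl > 0
    wk = fk[mk] / fk[mk].sum()
    wl = fl[ml] / fl[ml].sum()
    cross = dm.values[np.ix_(mk.nonzero()[0], ml.nonzero()[0])]
    return float(wk @ cross @ wl)


def beta_nri(f_row_k, f_row_l, dm: DistanceMatrix, pool_ids=None,
             n_rand: int = 1000, seed=None,
             sample_i: str = "", sample_j: str = "") -> BetaSesResult:
    """βNRI: SES of βMPD with the phylogeny-pool null applied to both samples.

    Each randomization reassigns both communities' abundances independently
    to uniform draws from the pool (the α null extended to β).
    """
    if isinstance(f_row_k, pd.Series) and not sample_i:
        sample_i = str(f_row_k.name or "")
    if isinstance(f_row_l, pd.Series) and not sample_j:
        sample_j = str(f_row_l.name or "")
    fk = _align_row(f_row_k, dm)
    fl = _align_row(f_row_l, dm)
    obs = beta_mpd(fk, fl, dm)
    pool = ([dm.index[i] for i in pool_ids] if pool_ids is not None
            else np.arange(len(dm.ids)))
    pool = np.asarray(pool)
    mk, ml = fk > 0, fl > 0
    rk, rl = int(mk.sum()), int(ml.sum())
    if max(rk, rl) > len(pool):
        raise ValueError("sample richness exceeds pool size")
    wk = fk[mk] / fk[mk].sum()
    wl = fl[ml] / fl[ml].sum()
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    chunk = max(1, _CHUNK_BUDGET // (rk * rl))
    done = 0
    while done < n_rand:
        c = min(chunk, n_rand - done)
        ik = pool[_random_subsets(rng, c, len(pool), rk)]
        il = pool[_random_subsets(rng, c, len(pool), rl)]
        cross = dm.values[ik[:, :, None], il[:, None, :]]
        null[done:done + c] = np.einsum("i,cij,j->c", wk, cross, wl)
        done += c
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return BetaSesResult(sample_i, sample_j, obs, mu, sd, float("nan"),
                             n_rand, float("nan"), flagged=True,
                             note="null sd is zero; betaNRI undefined")
    return BetaSesResult(sample_i, sample_j, obs, mu, sd, (obs - mu) / sd,
                         n_rand, _rank_p(null, obs))


def group_mean_beta(results: list[BetaSesResult] | pd.DataFrame,
                    metadata, metric: str = "beta_mpd_observed") -> pd.DataFrame:
    """Mean ± sd of a β metric over the within-group sample pairs.

    ``metadata`` maps sample id → group (a SampleMetadata, Series or dict).
    Groups with fewer than 2 samples have no pairs and are skipped with a
    warning. The ``display`` column renders "mean ± sd" to three decimals.
    """
    if hasattr(metadata, "groups"):
        groups = metadata.groups
    else:
        groups = pd.Series(metadata)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([{
            "sample_i": r.sample_i, "sample_j": r.sample_j,
            "beta_mpd_observed": r.beta_mpd_observed, "beta_nri": r.beta_nri,
        } for r in results])
    rows = []
    for group in pd.unique(groups):
        members = set(groups[groups == group].index)
        if len(members) < 2:
            log.warning("group %s has fewer than 2 samples; skipped", group)
            continue
        within = df[df["sample_i"].isin(members) & df["sample_j"].isin(members)]
        if within.empty:
            log.warning("group %s has no within-group pairs in results", group)
            continue
        vals = within[metric].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"group": group, "n_pairs": len(vals), "mean": mean,
                     "sd": sd, "display": f"{mean:.3f} ± {sd:.3f}"})
    return pd.DataFrame(rows, columns=["group", "n_pairs", "mean", "sd",
                                       "display"])


# ---------------------------------------------------------------------------
# Mantel correlogram

def _condensed(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _holm_progressive(pvals: list[float]) -> list[float]:
    """Progressive Holm: class k corrected within the first k tests only."""
    out = []
    for k in range(1, len(pvals) + 1):
        sub = np.asarray(pvals[:k])
        order = np.argsort(sub)
        adj = np.empty(k)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (k - rank) * sub[idx]))
            adj[idx] = running
        out.append(float(adj[k - 1]))
    return out


def mantel_correlogram(dphy: DistanceMatrix, dopt: DistanceMatrix,
                       n_classes: int = 100, n_perm: int = 999, seed=None,
                       alpha: float = 0.05) -> list[CorrelogramClass]:
    """Mantel correlogram of phylogenetic vs environmental-optimum distances.

    Equal-width distance classes span the observed phylogenetic distances.
    Per class the Mantel statistic is the Pearson correlation between the
    class-membership indicator and the optimum distances over all pairs,
    negated so that positive r means pairs in the class are more similar
    than average (positive autocorrelation). Permutation p-values shuffle
    OTU labels of the optimum matrix; they are one-tailed in the direction
    of the observed sign and progressively Holm-corrected in increasing
    distance order. Classes without pairs are reported with NaN statistics,
    never raised.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if list(dphy.ids) != list(dopt.ids):
        try:
            dopt = DistanceMatrix(ids=dphy.ids, values=dopt.loc(dphy.ids))
        except KeyError as exc:
            raise ValueError("distance matrices must share OTU ids") from exc
    n = len(dphy.ids)
    dp = _condensed(dphy.values)
    dv = _condensed(dopt.values)
    edges = np.linspace(dp.min(), dp.max(), n_classes + 1)
    cls = np.clip(np.digitize(dp, edges[1:-1], right=False), 0, n_classes - 1)
    n_pairs = np.bincount(cls, minlength=n_classes)
    mids = 0.5 * (edges[:-1] + edges[1:])

    def class_r(vec: np.ndarray) -> np.ndarray:
        # Pearson r between class indicator and vec, computed from per-class
        # sums; the indicator sd and vec moments factor out per class.
        vbar, vsd = vec.mean(), vec.std()
        sums = np.bincount(cls, weights=vec, minlength=n_classes)
        p = n_pairs / len(vec)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sums / len(vec) - p * vbar
            r = cov / (np.sqrt(p * (1 - p)) * vsd)
        return -r

    r_obs = class_r(dv)
    rng = np.random.default_rng(seed)
    ge = np.zeros(n_classes)
    le = np.zeros(n_classes)
    iu = np.triu_indices(n, k=1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vperm = dopt.values[np.ix_(perm, perm)][iu]
        r_perm = class_r(vperm)
        ge += (r_perm >= r_obs - 1e-12)
        le += (r_perm <= r_obs + 1e-12)
    tested = [k for k in range(n_classes) if n_pairs[k] > 0
              and np.isfinite(r_obs[k])]
    p_raw = {}
    for k in tested:
        tail = ge[k] if r_obs[k] >= 0 else le[k]
        p_raw[k] = (1 + tail) / (n_perm + 1)
    p_adj = _holm_progressive([p_raw[k] for k in tested])
    p_corr = dict(zip(tested, p_adj))
    out = []
    for k in range(n_classes):
        if k in p_raw:
            out.append(CorrelogramClass(
                index=k, midpoint=float(mids[k]), n_pairs=int(n_pairs[k]),
                mantel_r=float(r_obs[k]), p_permutation=float(p_raw[k]),
                p_corrected=float(p_corr[k]),
                significant=bool(p_corr[k] <= alpha)))
        else:
            out.append(CorrelogramClass(
                index=k, midpoint=float(mids[k]), n_pairs=int(n_pairs[k]),
                mantel_r=float("nan"), p_permutation=float("nan"),
                p_corrected=float("nan"), significant=False))
    return out


def correlogram_frame(classes: list[CorrelogramClass]) -> pd.DataFrame:
    return pd.DataFrame([{
        "class": c.index, "midpoint": c.midpoint, "n_pairs": c.n_pairs,
        "mantel_r": c.mantel_r, "p_permutation": c.p_permutation,
        "p_corrected": c.p_corrected, "significant": c.significant,
    } for c in classes])


# ---------------------------------------------------------------------------
# convenience over whole tables

def alpha_nri_table(f_matrix: pd.DataFrame, dm: DistanceMatrix,
                    n_rand: int = 1000, seed=None,
                    mode: str = "focal") -> pd.DataFrame:
    """αMPD/αNRI for every row of a relative-abundance matrix."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seeds = ss.spawn(len(f_matrix))
    rows = []
    for (sid, row), s in zip(f_matrix.iterrows(), seeds):
        res = alpha_nri(row, dm, n_rand=n_rand, seed=s, mode=mode,
                        sample_id=str(sid))
        rows.append({
            "sample_id": res.sample_id, "richness": int((row > 0).sum()),
            "alpha_mpd": res.observed, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "ses": res.ses, "alpha_nri": res.nri,
            "p_rank": res.p_rank, "flagged": res.flagged,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def beta_nri_pairs(f_matrix: pd.DataFrame, dm: DistanceMatrix, pairs=None,
                   n_rand: int = 1000, seed=None) -> pd.DataFrame:
    """βMPD/βNRI over sample pairs (all pairs by default)."""
    if pairs is None:
        pairs = list(itertools.combinations(f_matrix.index, 2))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seeds = ss.spawn(len(pairs))
    rows = []
    for (a, b), s in zip(pairs, seeds):
        res = beta_nri(f_matrix.loc[a], f_matrix.loc[b], dm, n_rand=n_rand,
                       seed=s, sample_i=str(a), sample_j=str(b))
        rows.append({
            "sample_i": res.sample_i, "sample_j": res.sample_j,
            "beta_mpd_observed": res.beta_mpd_observed,
            "null_mean": res.null_mean, "null_sd": res.null_sd,
            "beta_nri": res.beta_nri, "p_rank": res.p_rank,
            "flagged": res.flagged,
        })
    return pd.DataFrame(rows)
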