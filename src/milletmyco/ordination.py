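"""Beta-diversity statistics: Bray-Curtis distances, non-metric
multidimensional scaling, PERMANOVA (sequential / Type-I, adonis-style),
multivariate dispersion homogeneity, environmental vector fitting, and the
shared Benjamini-Hochberg utility.

The permutation tests follow the classic conventions: whole samples are
shuffled, and p = (#{permuted statistic >= observed} + 1) / (n_perm + 1),
so p never reaches zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .io import CountTable, SampleMetadata

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)
    between sample columns."""
    X = table.counts.to_numpy(float).T
    if (X.sum(axis=1) == 0).any():
        bad = [s for s, tot in zip(table.sample_ids, X.sum(axis=1)) if tot == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    scores: pd.DataFrame  # samples x axes
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts_used: int


def kruskal_stress(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration: sqrt(sum (d - dhat)^2 / sum d^2)
    with dhat the isotonic (monotone) regression of configuration distances
    on the input dissimilarity ranks."""
    lower = np.tril_indices_from(dissim, k=-1)
    delta = dissim[lower]
    d = squareform(pdist(coords))[lower]
    dhat = IsotonicRegression().fit_transform(delta, d)
    denom = (d * d).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed=None,
) -> Ordination:
    """Non-metric MDS on a distance matrix, best of ``n_restarts`` random
    starts (SMACOF with monotone regression); the returned solution is the
    one with lowest Kruskal stress-1."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    converged = False
    for _ in range(n_restarts):
        rs = int(rng.integers(2**31 - 1))
        mds = MDS(
            n_components=k,
            metric="precomputed",
            metric_mds=False,
            init="random",
            n_init=1,
            max_iter=max_iter,
            random_state=rs,
            normalized_stress=True,
            eps=1e-7,
        )
        coords = mds.fit_transform(dist.values)
        s1 = kruskal_stress(dist.values, coords)
        if best is None or s1 < best[0]:
            best = (s1, coords)
            converged = mds.n_iter_ < max_iter
    if not converged:
        log.warning("nmds: no restart converged within %d iterations; best-so-far returned", max_iter)
    scores = pd.DataFrame(
        best[1], index=pd.Index(dist.sample_ids, name="sample_id"),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return Ordination(scores=scores, stress=best[0], converged=converged, n_restarts_used=n_restarts)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d * d
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str)).to_numpy(float)


def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = term.split(":")
        mats = [_dummies(meta[p]) for p in parts]
        cols = mats[0]
        for m in mats[1:]:
            cols = np.einsum("ij,ik->ijk", cols, m).reshape(len(meta), -1)
        return cols
    if term not in meta.columns:
        raise ValueError(f"unknown term {term!r}")
    if meta[term].nunique() < 2:
        raise ValueError(f"term {term!r} has a single level")
    return _dummies(meta[term])


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms, Residuals, Total; cols: df, SS, MS, F, R2, p
    n_permutations: int


def permanova(
    dist: DistanceMatrix,
    metadata: SampleMetadata,
    terms=("site", "plant_type", "site:plant_type"),
    n_perm: int = 999,
    seed=None,
    permutations=None,
) -> PermanovaResult:
    """Sequential (Type-I) partition of a distance matrix over model terms,
    in the given order, with permutation p-values.

    Sums of squares are traces of the Gower-centered inner-product matrix
    against nested projection differences; pseudo-F per term uses the
    residual mean square.  Permutations shuffle whole samples.  If an
    explicit ``permutations`` iterable of index arrays is given (e.g. the
    full enumeration for an exact test) it is used as the reference
    distribution instead of ``n_perm`` random draws.
    """
    meta = metadata.frame.loc[dist.sample_ids]
    n = dist.n
    G = _gower_center(dist.values)

    # nested projections
    X = np.ones((n, 1))
    hats = []  # H after adding each term
    dfs = []
    rank_prev = 1
    for term in terms:
        X = np.hstack([X, _term_columns(meta, term)])
        rank = int(np.linalg.matrix_rank(X, tol=1e-8))
        u, _, _ = np.linalg.svd(X, full_matrices=False)
        basis = u[:, :rank]
        hats.append(basis @ basis.T)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    if any(df < 1 for df in dfs):
        raise ValueError("a model term adds no degrees of freedom (aliased factor)")

    H_full = hats[-1]
    df_res = n - rank_prev
    ss_total = float(np.trace(G))

    def term_stats(Gm):
        prev = np.ones((n, n)) / n
        ss = []
        for H in hats:
            ss.append(float(((H - prev) * Gm).sum()))
            prev = H
        ss_res = float(np.trace(Gm)) - float((H_full * Gm).sum())
        F = [(s / df) / (ss_res / df_res) for s, df in zip(ss, dfs)]
        return np.array(ss), ss_res, np.array(F)

    ss_obs, ss_res_obs, F_obs = term_stats(G)

    if permutations is not None:
        perms = [np.asarray(p) for p in permutations]
        count = np.zeros(len(terms))
        for p in perms:
            _, _, Fp = term_stats(G[np.ix_(p, p)])
            count += Fp >= F_obs - 1e-12
        pvals = count / len(perms)
        n_used = len(perms)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, _, Fp = term_stats(G[np.ix_(p, p)])
            count += Fp >= F_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for term, df, ss, F, p in zip(terms, dfs, ss_obs, F_obs, pvals):
        rows.append({"term": term, "df": df, "SS": ss, "MS": ss / df,
                     "F": F, "R2": ss / ss_total, "p": p})
    rows.append({"term": "Residuals", "df": df_res, "SS": ss_res_obs,
                 "MS": ss_res_obs / df_res, "F": np.nan,
                 "R2": ss_res_obs / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "MS": np.nan,
                 "F": np.nan, "R2": 1.0, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_used)


# ---------------------------------------------------------------------------
# betadisper
# ---------------------------------------------------------------------------


@dataclass
class BetadisperResult:
    distances: pd.Series  # per-sample distance to group centroid
    F: float
    p: float
    group_means: pd.Series


def betadisper(dist: DistanceMatrix, groups, n_perm: int = 999, seed=None) -> BetadisperResult:
    """Homogeneity of multivariate dispersions.

    Samples are embedded by principal coordinates; negative eigenvalues are
    kept as imaginary axes and their squared contribution is subtracted
    from real squared distances (the standard correction).  The F statistic
    of a one-way ANOVA on distances-to-centroid is compared against
    group-label permutations.  Groups of size 1 are excluded from the test
    with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=dist.sample_ids)
    if groups.nunique() < 2:
        raise ValueError("betadisper needs >= 2 groups")
    G = _gower_center(dist.values)
    w, v = np.linalg.eigh(G)
    pos, neg = w > 1e-10, w < -1e-10
    Xp = v[:, pos] * np.sqrt(w[pos])
    Xn = v[:, neg] * np.sqrt(-w[neg])

    d2 = np.empty(dist.n)
    for g in groups.unique():
        idx = np.where(groups.to_numpy() == g)[0]
        cp, cn = Xp[idx].mean(axis=0), Xn[idx].mean(axis=0)
        d2[idx] = ((Xp[idx] - cp) ** 2).sum(axis=1) - ((Xn[idx] - cn) ** 2).sum(axis=1)
    dists = np.sqrt(np.clip(d2, 0, None))
    dser = pd.Series(dists, index=dist.sample_ids, name="dist_to_centroid")

    sizes = groups.value_counts()
    small = sizes[sizes < 2].index
    if len(small):
        log.warning("betadisper: excluding size-1 group(s) from test: %s", list(small))
    keep = ~groups.isin(small)
    y, lab = dists[keep.to_numpy()], groups[keep].to_numpy()

    def anova_F(y, lab):
        grand = y.mean()
        labs, inv = np.unique(lab, return_inverse=True)
        k = len(labs)
        ss_b = sum(
            (y[inv == i].mean() - grand) ** 2 * (inv == i).sum() for i in range(k)
        )
        ss_w = sum(((y[inv == i] - y[inv == i].mean()) ** 2).sum() for i in range(k))
        df_b, df_w = k - 1, len(y) - k
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    F_obs = anova_F(y, lab)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += anova_F(y, rng.permutation(lab)) >= F_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    means = pd.Series(y, index=dser.index[keep.to_numpy()]).groupby(groups[keep]).mean()
    return BetadisperResult(distances=dser, F=float(F_obs), p=float(p), group_means=means)


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------


def envfit(
    ordination: Ordination,
    metadata: SampleMetadata,
    variables=None,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Least-squares fit of each (numeric) soil variable onto the
    ordination scores.

    Per variable: direction cosines of the fitted vector on the ordination
    axes, squared multiple correlation r2, and a permutation p-value from
    shuffling the variable across samples.  Constant variables give
    r2 = 0, p = 1 with a warning.  Filter the output at p < 0.05 for the
    significant-vectors display.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = ordination.scores
    soil = metadata.soil().reindex(S.index)
    if variables is None:
        variables = list(soil.columns)
    axes = list(S.columns)

    rows = []
    for var in variables:
        v = soil[var]
        ok = v.notna()
        n_drop = int((~ok).sum())
        if n_drop:
            log.info("envfit: %s drops %d incomplete samples", var, n_drop)
        Sc = S[ok.to_numpy()].to_numpy(float)
        y = v[ok].to_numpy(float)
        Sc = Sc - Sc.mean(axis=0)
        yc = y - y.mean()

        def r2_of(yv):
            b, *_ = np.linalg.lstsq(Sc, yv, rcond=None)
            fitted = Sc @ b
            tot = (yv * yv).sum()
            return ((fitted * fitted).sum() / tot if tot > 0 else 0.0), b

        if np.ptp(y) == 0:
            log.warning("envfit: variable %r is constant; r2=0, p=1", var)
            rows.append({"variable": var, **{a: np.nan for a in axes}, "r2": 0.0, "p": 1.0})
            continue
        r2, b = r2_of(yc)
        norm = np.linalg.norm(b)
        cosines = b / norm if norm > 0 else b
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(yc)
            r2p, _ = r2_of(yp)
            count += r2p >= r2 - 1e-12
        p = (count + 1) / (n_perm + 1)
        rows.append(
            {"variable": var, **dict(zip(axes, cosines)), "r2": float(r2), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
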