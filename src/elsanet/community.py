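"""Composition-level statistics for the replicated community time series.

Covers the standard 16S workflow around the network analysis: rarefaction
to a common depth, Shannon diversity with pairwise Welch comparisons,
Bray-Curtis distances, principal coordinates (classical metric scaling),
a two-factor permutational MANOVA with sequential sums of squares in the
style of vegan's adonis, family-level aggregation, and the max-abundance
heatmap filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import AbundanceTable, ValidationError


# ---------------------------------------------------------------------------
# rarefaction & diversity
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    One multivariate-hypergeometric draw per sample (a single rarefied
    dataset, no averaging across draws).  Samples with fewer than ``depth``
    reads are a hard error — rarefy to the observed minimum to keep all.
    """
    if table.units != "counts":
        raise ValidationError("rarefy expects a counts table")
    counts = table.data.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    short = table.data.index[totals < depth].tolist()
    if short:
        raise ValidationError(f"samples with fewer than {depth} reads: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if totals[i] == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    rarefied = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(rarefied, table.metadata.copy(), "counts")


def shannon(counts_or_props) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of one sample."""
    v = np.asarray(counts_or_props, dtype=float)
    if v.ndim != 1 or np.any(v < 0):
        raise ValidationError("expected a 1-D nonnegative vector")
    total = v.sum()
    if total <= 0:
        raise ValidationError("all-zero vector has undefined diversity")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: AbundanceTable) -> pd.Series:
    return pd.Series(
        {s: shannon(table.data.loc[s].to_numpy()) for s in table.data.index}, name="shannon"
    )


def shannon_pairwise_tests(table: AbundanceTable) -> pd.DataFrame:
    """Welch two-sample t-tests on per-sample Shannon indices between treatments."""
    h = shannon_per_sample(table)
    treat = table.metadata["treatment"]
    rows = []
    for a, b in itertools.combinations(sorted(treat.unique()), 2):
        ha, hb = h[treat == a], h[treat == b]
        t, p = sstats.ttest_ind(ha, hb, equal_var=False)
        rows.append(
            {"treatment_a": a, "treatment_b": b, "mean_a": ha.mean(), "mean_b": hb.mean(),
             "t": float(t), "p_value": float(p)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances & ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) over sample pairs."""
    m = table.data.to_numpy(dtype=float)
    row_sums = m.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = table.data.index[row_sums <= 0].tolist()
        raise ValidationError(f"all-zero samples make Bray-Curtis undefined: {bad}")
    d = squareform(pdist(m, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(table.data.index))


@dataclass
class OrdinationResult:
    """Classical-scaling output: coordinates on axes with positive eigenvalues."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive, descending
    proportion_explained: np.ndarray  # fractions of the positive-eigenvalue total

    @property
    def percent_explained(self) -> np.ndarray:
        return 100.0 * self.proportion_explained


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and scales eigenvectors by
    the square roots of their eigenvalues.  Axes with nonpositive
    eigenvalues are dropped; variance fractions are taken over the positive
    eigenvalues only.
    """
    ids = list(d.ids)
    n = len(ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    D = d.data
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0]))
    pos = eigvals > tol
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    coords = eigvecs * np.sqrt(eigvals)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals / eigvals.sum(),
    )


# ---------------------------------------------------------------------------
# PERMANOVA (sequential, adonis-style)
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential distance-based ANOVA table with permutation p-values."""

    table: pd.DataFrame  # index: terms + Residual + Total; df, sum_sq, pseudo_F, p_value
    n_permutations: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _dummy(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype("category"), drop_first=True).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(1.0, diag.max())).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    factors: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    interaction: bool = True,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    Partitions the Gower-centered squared distances sequentially (Type-I)
    over the crossed factors in the order given, plus their interaction for
    two factors; pseudo-F per term; p-values from free permutation of the
    sample labels, p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    ids = list(d.ids)
    n = len(ids)
    meta = metadata.loc[ids]
    for f in factors:
        if meta[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single level")
    D = d.data
    G = _gower(D)
    # sequential design blocks: intercept, +f1, +f1+f2, ..., +interaction
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    terms: list[str] = []
    for f in factors:
        blocks.append(_dummy(meta[f]))
        terms.append(f)
    if interaction and len(factors) == 2:
        combo = meta[factors[0]].astype(str) + ":" + meta[factors[1]].astype(str)
        blocks.append(_dummy(combo))
        terms.append(f"{factors[0]}:{factors[1]}")
    hats, ranks = [], []
    X = np.empty((n, 0))
    for b in blocks:
        X = np.hstack([X, b])
        h, r = _hat(X)
        hats.append(h)
        ranks.append(r)
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    if any(df < 1 for df in dfs):
        raise ValidationError("model terms are confounded (zero df)")
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValidationError("no residual degrees of freedom")
    diff_hats = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_hat = np.eye(n) - hats[-1]

    def _stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((h * Gm).sum()) for h in diff_hats])
        ss_res = float((resid_hat * Gm).sum())
        return ss, ss_res

    ss_obs, ss_res_obs = _stats(G)
    f_obs = (ss_obs / dfs) / (ss_res_obs / df_res)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        ss_p, ss_res_p = _stats(G[np.ix_(p, p)])
        f_p = (ss_p / dfs) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    total_ss = float(G.trace())
    tab = pd.DataFrame(
        {
            "df": dfs + [df_res, n - 1],
            "sum_sq": list(ss_obs) + [ss_res_obs, total_ss],
            "pseudo_F": list(f_obs) + [np.nan, np.nan],
            "p_value": list(pvals) + [np.nan, np.nan],
        },
        index=terms + ["Residual", "Total"],
    )
    return PermanovaResult(table=tab, n_permutations=n_perm)


def _gower(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


# ---------------------------------------------------------------------------
# taxonomy aggregation & heatmap filter
# ---------------------------------------------------------------------------

def aggregate_families(
    table: AbundanceTable, taxonomy: Mapping[str, str], top_k: int = 7
) -> AbundanceTable:
    """Sum OTUs by family and keep the ``top_k`` most abundant families.

    Families are ranked by grand-mean relative abundance; everything below
    the cut is pooled into an "Other" column.  OTUs absent from the
    taxonomy are treated as "unclassified".
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    if table.units != "relative":
        raise ValidationError("aggregate_families expects relative abundances")
    fams = [taxonomy.get(o, "unclassified") for o in table.data.columns]
    by_family = table.data.T.groupby(np.asarray(fams)).sum().T
    ranked = by_family.mean(axis=0).sort_values(ascending=False)
    top = list(ranked.index[:top_k])
    out = by_family[top].copy()
    rest = [f for f in by_family.columns if f not in top]
    if rest:
        out["Other"] = by_family[rest].sum(axis=1)
    return AbundanceTable(out, table.metadata.copy(), "relative")


def heatmap_filter(table: AbundanceTable, max_threshold: float = 0.075) -> AbundanceTable:
    """Drop OTUs whose maximum abundance across samples is below the threshold."""
    if not 0 < max_threshold < 1:
        raise ValidationError(f"max_threshold must be in (0, 1), got {max_threshold}")
    if table.units != "relative":
        raise ValidationError("heatmap_filter expects relative abundances")
    keep = table.data.columns[table.data.max(axis=0) >= max_threshold]
    return AbundanceTable(table.data[list(keep)].copy(), table.metadata.copy(), "relative")
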