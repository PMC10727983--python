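"""Normalization, composition statistics and shared statistical utilities.

Covers the sample-level feature engineering used throughout the pipeline:

* median-of-ratios size factors and count normalization;
* per-sample Shannon entropy (bits) of each biotype / repeat superfamily;
* group abundance fractions ("repeat fraction" plots);
* per-feature Z-scores (R ``scale`` convention, n-1 denominator);
* PCA on centered/scaled log counts (rank capped at 50) and Pearson
  sample-sample correlation;
* rank-sum tests, Benjamini-Hochberg adjustment, K-means clustering;
* assembly of the eight classifier feature sets, with a guard that
  differential-expression-filtered sets were derived from training samples
  only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization


def size_factors(raw) -> pd.Series:
    """Median-of-ratios size factors.

    For every feature positive in all samples, compute its geometric mean
    across samples; each sample's factor is the median over those features
    of count / geometric mean.  Requires at least two samples and at least
    one feature with strictly positive counts everywhere.
    """
    df = _as_df(raw, expect_state="raw")
    if df.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    positive = (df > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature is positive in all samples; filter features or use a "
            "pseudo-reference fallback"
        )
    sub = df.loc[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    s = np.exp(ratios.median(axis=0))
    s.name = "size_factor"
    return s


def normalize(raw, s: pd.Series):
    """Divide each sample's counts by its size factor."""
    from .quantify import CountMatrix

    df = _as_df(raw)
    if not df.columns.equals(s.index):
        s = s.reindex(df.columns)
        if s.isna().any():
            raise ValueError("size factors missing for some samples")
    return CountMatrix(df.div(s, axis=1), state="normalized")


def log_transform(norm, pseudocount: float = 1.0):
    """log2(normalized count + pseudocount) — variance-stabilizing surrogate."""
    from .quantify import CountMatrix

    df = _as_df(norm)
    return CountMatrix(np.log2(df + pseudocount), state="log")


def _as_df(matrix, expect_state: str | None = None) -> pd.DataFrame:
    """Accept a CountMatrix or a plain DataFrame."""
    if isinstance(matrix, pd.DataFrame):
        return matrix
    if expect_state is not None and matrix.state != expect_state:
        logger.warning("expected %s-state matrix, got %s", expect_state, matrix.state)
    return matrix.data


# ---------------------------------------------------------------------------
# composition statistics


def shannon_entropy(norm, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample Shannon entropy H (bits) of each feature group.

    Within a group g and sample j, p_i = count_ij / sum over g of count_ij;
    H = -sum p_i log2 p_i with 0 log 0 = 0.  A group with zero total in a
    sample has undefined entropy, emitted as NaN with a warning.

    Returns a DataFrame indexed by sample with one column per group.
    """
    df = _as_df(norm)
    groups = pd.Series({f: grouping[f] for f in df.index if f in grouping})
    out: dict[str, pd.Series] = {}
    for g, feats in groups.groupby(groups).groups.items():
        sub = df.loc[list(feats)]
        totals = sub.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = sub.div(totals, axis=1)
            terms = -p * np.log2(p)
        h = terms.fillna(0.0).sum(axis=0)
        zero = totals == 0
        if zero.any():
            logger.warning(
                "entropy undefined for group %r in %d sample(s) with zero total", g, int(zero.sum())
            )
            h[zero] = np.nan
        out[str(g)] = h
    return pd.DataFrame(out)


def group_fractions(norm, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample fractional abundance of each group; rows sum to 1.

    Features without a group label are pooled under "other".
    """
    df = _as_df(norm)
    labels = pd.Series([grouping.get(f, "other") for f in df.index], index=df.index)
    sums = df.groupby(labels).sum().T  # samples x groups
    totals = sums.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts; fractions undefined")
    return sums.div(totals, axis=0)


def repeat_fraction(norm, grouping: Mapping[str, str], repeat_groups: Sequence[str]) -> pd.Series:
    """Per-sample total fraction attributed to the given repeat superfamilies."""
    frac = group_fractions(norm, grouping)
    cols = [g for g in repeat_groups if g in frac.columns]
    return frac[cols].sum(axis=1)


# ---------------------------------------------------------------------------
# scaling / unsupervised


def zscore(matrix) -> "object":
    """Per-feature Z-scores: mean 0, sd 1 with the n-1 denominator.

    Features with zero standard deviation are dropped beforehand.
    """
    from .quantify import CountMatrix

    df = _as_df(matrix)
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("zscore: dropping %d constant features", int((~keep).sum()))
    sub = df.loc[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return CountMatrix(z, state="zscore")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(matrix, rank: int = 50, scale: bool = True) -> PCAResult:
    """PCA of the features-x-samples matrix, treating samples as observations.

    Features with zero sd are removed; the matrix is centered (and scaled,
    by default) per feature; rank is capped at min(rank, n_samples - 1,
    n_features).  Computed by SVD.
    """
    df = _as_df(matrix)
    X = df.T  # samples x features
    sd = X.std(axis=0, ddof=1)
    X = X.loc[:, sd > 0]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / X.std(axis=0, ddof=1)
    k = min(rank, X.shape[0] - 1, X.shape[1])
    if k < 1:
        raise ValueError("not enough samples/features for PCA")
    U, S, Vt = np.linalg.svd(Xc.values, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    total_var = (Xc.values**2).sum() / (X.shape[0] - 1)
    evr = (S**2 / (X.shape[0] - 1)) / total_var
    comp = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        explained_variance_ratio=evr,
    )


def pearson_matrix(matrix) -> pd.DataFrame:
    """Sample-sample Pearson correlation of the features-x-samples matrix."""
    df = _as_df(matrix)
    return df.corr(method="pearson")


def kmeans_rows(matrix, k: int = 2, n_init: int = 25, seed: int = 0) -> pd.Series:
    """K-means cluster labels for matrix rows (features), for heat-map ordering."""
    df = _as_df(matrix)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(df.values)
    return pd.Series(labels, index=df.index, name="cluster")


# ---------------------------------------------------------------------------
# shared statistical utilities


def wilcoxon_rank_sum(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test: rank-sum (Mann-Whitney U) or signed-rank.

    Unpaired mode uses exact enumeration when both groups have n <= 8 and no
    ties straddle the groups, otherwise the tie-corrected normal
    approximation.  Paired mode drops zero differences (warning if all are
    zero, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        if np.all(d == 0):
            logger.warning("paired wilcoxon: all differences zero; p = 1")
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagated)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def significance_rank(p: float) -> str:
    """Symbolic significance rank for a p-value."""
    if np.isnan(p):
        return "NA"
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


# ---------------------------------------------------------------------------
# classifier feature sets


@dataclass
class FeatureSet:
    """A named feature list fed to the classifier, with provenance."""

    name: str
    category: str  # total | differential_expression | entropy
    feature_ids: list[str]
    provenance: str = ""


FEATURE_SET_NAMES = (
    "total_naive",
    "total_aware",
    "total_repeat_alone",
    "de_naive",
    "de_aware",
    "de_repeat_alone",
    "entropy_clade",
    "entropy_clade_plus_naive",
)


def build_feature_sets(
    aware_feature_ids: Sequence[str],
    naive_feature_ids: Sequence[str],
    entropy_groups: Sequence[str],
    de_result,
    train_sample_ids: Sequence[str],
    padj_cutoff: float = 0.01,
) -> dict[str, FeatureSet]:
    """Assemble the eight canonical classifier feature sets.

    Three "total" sets (repeat-naive, repeat-aware, repeat-alone counts),
    three differential-expression-filtered counterparts (features at
    padj < cutoff from a DE run on the training split only), and two entropy
    sets (repeat-clade entropy columns alone, and together with the
    repeat-naive count features).

    ``de_result`` must expose ``.table`` (with a padj column) and
    ``.sample_ids`` (the samples the DE was computed on); if that set is not
    a subset of ``train_sample_ids`` the DE leaked test samples and an error
    is raised.
    """
    from .annotation import REPEAT_PREFIX

    de_samples = set(de_result.sample_ids)
    if not de_samples <= set(train_sample_ids):
        leaked = sorted(de_samples - set(train_sample_ids))
        raise ValueError(
            f"differential expression was computed on non-training samples {leaked[:5]}; "
            "refusing to build leakage-prone feature sets"
        )
    tab = de_result.table
    de_feats = list(tab.index[tab["padj"] < padj_cutoff])
    provenance = f"DE on training split ({len(de_samples)} samples), padj<{padj_cutoff}"

    aware = list(aware_feature_ids)
    naive = list(naive_feature_ids)
    repeat_alone = [f for f in aware if f.startswith(REPEAT_PREFIX)]
    de_aware = [f for f in de_feats if f in set(aware)]
    de_naive = [f for f in de_feats if f in set(naive)]
    de_repeat = [f for f in de_feats if f.startswith(REPEAT_PREFIX)]
    entropy_cols = [f"entropy:{g}" for g in entropy_groups]

    sets = {
        "total_naive": FeatureSet("total_naive", "total", naive, "all repeat-naive features"),
        "total_aware": FeatureSet("total_aware", "total", aware, "all repeat-aware features"),
        "total_repeat_alone": FeatureSet(
            "total_repeat_alone", "total", repeat_alone, "repeat-subfamily features only"
        ),
        "de_naive": FeatureSet("de_naive", "differential_expression", de_naive, provenance),
        "de_aware": FeatureSet("de_aware", "differential_expression", de_aware, provenance),
        "de_repeat_alone": FeatureSet(
            "de_repeat_alone", "differential_expression", de_repeat, provenance
        ),
        "entropy_clade": FeatureSet(
            "entropy_clade", "entropy", entropy_cols, "per-clade entropy columns"
        ),
        "entropy_clade_plus_naive": FeatureSet(
            "entropy_clade_plus_naive",
            "entropy",
            entropy_cols + naive,
            "per-clade entropy plus repeat-naive counts",
        ),
    }
    assert tuple(sets) == FEATURE_SET_NAMES
    return sets
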