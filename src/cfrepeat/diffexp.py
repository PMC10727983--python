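"""Covariate-adjusted differential expression on feature-level counts.

Fits, per feature, a negative-binomial log-linear model with a log
size-factor offset and a design of the form

    ~ age + gender + input_volume + condition

where condition is a two-level factor and is always the last term.  The
condition coefficient is tested with a Wald z statistic (two-sided normal
p), and p-values are Benjamini-Hochberg adjusted; significance is called at
padj < 0.01.

This is a deliberately simple NB-GLM: dispersions come from per-feature
method-of-moments on normalized counts, there is no dispersion or fold-change
shrinkage, no independent filtering and no outlier refitting.  An import
path (:func:`read_de_table`) accepts externally computed tables in the
standard DESeq2 column dialect for users who prefer to run that package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import bh_adjust, size_factors as mor_size_factors

logger = logging.getLogger(__name__)

PADJ_CUTOFF = 0.01

#: DESeq2-dialect output columns, for interoperability
DE_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj"]


@dataclass
class DesignSpec:
    """Covariate-adjusted two-group design; condition enters last."""

    covariates: list[str] = field(default_factory=list)  # e.g. ["age", "gender", "input_volume"]
    condition: str = "condition"
    reference_level: str = "healthy"

    @classmethod
    def from_formula(cls, formula: str, reference_level: str = "healthy") -> "DesignSpec":
        """Parse "age + gender + condition" style formulas (optional leading ~)."""
        terms = [t.strip() for t in formula.lstrip("~").split("+") if t.strip()]
        if not terms:
            raise ValueError("empty design formula")
        return cls(covariates=terms[:-1], condition=terms[-1], reference_level=reference_level)


@dataclass
class DEResult:
    """Per-feature differential-expression table plus provenance.

    ``table`` is indexed by feature with columns baseMean, log2FoldChange,
    lfcSE, pvalue, padj and converged.  ``sample_ids`` records which samples
    the test used — downstream feature-set construction checks it against
    the training split to guard against leakage.
    """

    table: pd.DataFrame
    design: DesignSpec
    sample_ids: list[str]

    def significant(self, cutoff: float = PADJ_CUTOFF) -> pd.DataFrame:
        return self.table[self.table["padj"] < cutoff]

    def write_tsv(self, path: Union[str, Path]) -> None:
        out = self.table[DE_COLUMNS]
        out.to_csv(path, sep="\t", index_label="feature")


def read_de_table(path: Union[str, Path], sample_ids: Sequence[str] = ()) -> DEResult:
    """Import an externally computed DE table in the DESeq2 column dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    df["converged"] = True
    return DEResult(table=df, design=DesignSpec(), sample_ids=list(sample_ids))


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(counts, size_factors: pd.Series) -> pd.Series:
    """Per-feature NB dispersion by method of moments on normalized counts.

    alpha_i = max(0, (var_i - mean_i) / mean_i^2); features with zero mean
    are excluded (NaN).  Under Poisson sampling alpha is ~0.
    """
    from .features import _as_df

    df = _as_df(counts)
    norm = df.div(size_factors.reindex(df.columns), axis=1)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = alpha.clip(lower=0.0)
    alpha[mean == 0] = np.nan
    alpha.name = "dispersion"
    return alpha


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(
    metadata: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + standardized continuous covariates + dummy-coded factors +
    condition indicator (last column).

    Continuous covariates are centered/scaled; categorical covariates are
    dummy coded dropping the first level.  The condition column is 1 for the
    non-reference level.
    """
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names: list[str] = ["intercept"]
    for cov in design.covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} absent from metadata")
        col = metadata[cov]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            sd = v.std(ddof=1)
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    cond = metadata[design.condition].astype(str)
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"condition must have exactly 2 levels, got {levels}")
    if design.reference_level in levels:
        ref = design.reference_level
    else:
        ref = levels[0]
        logger.warning("reference level %r not found; using %r", design.reference_level, ref)
    other = [l for l in levels if l != ref][0]
    cols.append((cond == other).to_numpy(dtype=float))
    names.append(f"{design.condition}[{other}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    return X, names


# ---------------------------------------------------------------------------
# NB Wald test


def nb_wald_test(
    counts,
    metadata: pd.DataFrame,
    design: DesignSpec,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    padj_cutoff: float = PADJ_CUTOFF,
) -> DEResult:
    """Per-feature NB GLM Wald test of the condition effect.

    Counts are rounded to integers (NB likelihood); each feature is fit with
    a log link and log(size factor) offset.  The condition z = beta/se gives
    a two-sided normal p; BH runs over converged, tested features only.
    Features that fail to converge are flagged and excluded from the BH m.
    """
    from .features import _as_df

    df = _as_df(counts)
    metadata = metadata.loc[df.columns]
    if size_factors is None:
        size_factors = mor_size_factors(df)
    if dispersions is None:
        dispersions = estimate_dispersion(df, size_factors)
    X, names = build_design_matrix(metadata, design)
    offset = np.log(size_factors.reindex(df.columns).to_numpy(dtype=float))
    y_all = np.rint(df.to_numpy(dtype=float))

    n_feat = df.shape[0]
    base_mean = (df.div(size_factors.reindex(df.columns), axis=1)).mean(axis=1).to_numpy()
    log2fc = np.full(n_feat, np.nan)
    lfc_se = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)
    converged = np.zeros(n_feat, dtype=bool)
    ln2 = np.log(2.0)

    for i in range(n_feat):
        y = y_all[i]
        if y.sum() == 0:
            continue
        alpha = dispersions.iloc[i]
        if np.isnan(alpha):
            continue
        fam = (
            sm.families.Poisson()
            if alpha < 1e-8
            else sm.families.NegativeBinomial(alpha=float(alpha))
        )
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            beta = fit.params[-1]
            se = fit.bse[-1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0 and se < 15):
                raise ValueError("unstable fit")
        except Exception:
            logger.debug("feature %s: NB fit failed", df.index[i])
            continue
        converged[i] = True
        log2fc[i] = beta / ln2
        lfc_se[i] = se / ln2
        z = beta / se
        pval[i] = 2.0 * _norm_sf(abs(z))

    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": lfc_se,
            "pvalue": pval,
            "padj": padj,
            "converged": converged,
        },
        index=df.index,
    )
    n_failed = int((~converged).sum())
    if n_failed:
        logger.info("nb_wald_test: %d/%d features untested or non-converged", n_failed, n_feat)
    return DEResult(table=table, design=design, sample_ids=list(df.columns))


def _norm_sf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.sf(z))


# ---------------------------------------------------------------------------
# reporting


def volcano_table(de: DEResult, padj_cutoff: float = PADJ_CUTOFF) -> pd.DataFrame:
    """(feature, log2fc, -log10 padj, class) table for volcano plots.

    Classes partition tested features into up / down (padj < cutoff, by fold
    change sign) and ns; untested features are dropped.
    """
    tab = de.table.dropna(subset=["padj"])
    neglog = -np.log10(tab["padj"])
    cls = np.where(
        tab["padj"] < padj_cutoff,
        np.where(tab["log2FoldChange"] > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2FoldChange": tab["log2FoldChange"],
            "neg_log10_padj": neglog,
            "class": cls,
        },
        index=tab.index,
    )


def signature_overlap(
    de_results: Mapping[str, DEResult],
    repeat_only: bool = True,
    padj_cutoff: float = PADJ_CUTOFF,
) -> dict:
    """Shared/unique up- and down-regulated repeat signatures across diseases.

    For each disease, up = {features: padj < cutoff, log2fc > 0} (down
    analogous), optionally restricted to repeat-subfamily features.  Returns
    exclusive intersection cardinalities over every non-empty disease subset
    (UpSet-plot semantics) for both directions.
    """
    from .annotation import REPEAT_PREFIX

    def sig_set(de: DEResult, up: bool) -> set[str]:
        tab = de.table
        mask = (tab["padj"] < padj_cutoff) & (
            (tab["log2FoldChange"] > 0) if up else (tab["log2FoldChange"] < 0)
        )
        feats = set(tab.index[mask])
        if repeat_only:
            feats = {f for f in feats if f.startswith(REPEAT_PREFIX)}
        return feats

    diseases = list(de_results)
    out: dict = {"diseases": diseases, "up": {}, "down": {}}
    for direction in ("up", "down"):
        sets = {d: sig_set(de_results[d], direction == "up") for d in diseases}
        inter: dict[tuple[str, ...], int] = {}
        for r in range(1, len(diseases) + 1):
            for combo in combinations(diseases, r):
                members = set.intersection(*(sets[d] for d in combo)) if combo else set()
                outside = set.union(*(sets[d] for d in diseases if d not in combo), set())
                inter[combo] = len(members - outside)
        out[direction] = {"sets": sets, "exclusive_intersections": inter}
    return out
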