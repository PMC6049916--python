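"""Relating cell-type indices to donor covariates.

Implements the covariate-scan regressions (one ordinary-least-squares model
per cell-type index with all covariates entered simultaneously),
inverse-variance fixed-effects meta-analysis across datasets,
Benjamini-Hochberg FDR adjustment, Welch's unequal-variance t-test,
Cohen's d, and PCA-vs-index variance decomposition.

Three model presets mirror the covariate sets available in typical
post-mortem cohorts:

* ``eq1``: pH + agonal factor + PMI + age + sex + diagnosis + exsanguination
  (consortium-style data with coroner records);
* ``eq2``: pH + PMI + age + sex + diagnosis + RNA degradation (+ batch when
  present) (public GEO-style data);
* ``eq3``: pH + PMI + age + sex + diagnosis + RNA degradation + institution
  + manner of death (multi-site RNA-Seq-style data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from blendr.celltype_db import MarkerDatabase
from blendr.core import CellTypeIndexTable, ExpressionMatrix
from blendr.errors import InputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Default reference levels for treatment coding.
DEFAULT_REFERENCES: dict[str, str] = {
    "diagnosis": "CTRL",
    "sex": "F",
    "batch": "B1",
}

MODEL_PRESETS: dict[str, dict[str, Sequence[str]]] = {
    "eq1": {
        "required": ("brain_pH", "agonal_factor", "PMI", "age", "sex", "diagnosis",
                     "exsanguination"),
        "optional": (),
    },
    "eq2": {
        "required": ("brain_pH", "PMI", "age", "sex", "diagnosis", "rna_degradation"),
        "optional": ("batch",),
    },
    "eq3": {
        "required": ("brain_pH", "PMI", "age", "sex", "diagnosis", "rna_degradation",
                     "institution", "manner_of_death"),
        "optional": (),
    },
}


@dataclass
class CovariateTable:
    """Per-sample covariates with declared categorical reference levels."""

    data: pd.DataFrame
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = dict(DEFAULT_REFERENCES)
        ref.update(self.reference)
        self.reference = ref


@dataclass
class RegressionResult:
    """One OLS fit: per-term estimates plus whole-model summaries."""

    params: pd.DataFrame  # index = term; columns = beta, se, t, p
    n: int
    df_resid: int
    r2: float
    adj_r2: float
    aic: float
    bic: float
    residuals: np.ndarray


def build_design(
    covars: CovariateTable,
    terms: Sequence[str],
    index: pd.Index | None = None,
) -> pd.DataFrame:
    """Treatment-coded design matrix (with intercept) for the given terms.

    Numeric columns enter as-is; categorical columns contribute one 0/1
    indicator per non-reference level named ``col[level]``. Rows with any
    missing value among the terms are dropped (listwise deletion, logged).
    """
    data = covars.data if index is None else covars.data.loc[index]
    missing = [t for t in terms if t not in data.columns]
    if missing:
        raise SchemaError(f"covariate table is missing required column(s): {missing}")
    sub = data[list(terms)].copy()
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        logger.info("listwise deletion dropped %d samples", n_before - len(sub))
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(sub))}
    for t in terms:
        s = sub[t]
        if pd.api.types.is_numeric_dtype(s):
            cols[t] = s.to_numpy(dtype=float)
        else:
            levels = sorted(s.astype(str).unique())
            ref = covars.reference.get(t, levels[0])
            if ref not in levels:
                ref = levels[0]
            for level in levels:
                if level == ref:
                    continue
                cols[f"{t}[{level}]"] = (s.astype(str) == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=sub.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        suspects = []
        for j in range(arr.shape[1]):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                suspects.append(X.columns[j])
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {suspects}")


def fit_linear(y: pd.Series | np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of y on a prepared design matrix.

    AIC/BIC come from the full Gaussian log-likelihood (constants
    included), so differences are comparable across nested models.
    """
    yv = pd.Series(y).loc[X.index] if isinstance(y, pd.Series) else pd.Series(
        np.asarray(y, dtype=float), index=X.index
    )
    if yv.isna().any():
        keep = yv.notna()
        yv, X = yv[keep], X.loc[keep]
    n, p = X.shape
    if n <= p:
        raise InputError(f"n={n} samples cannot identify {p} parameters")
    _check_full_rank(X)
    model = sm.OLS(yv.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    params = pd.DataFrame(
        {
            "beta": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        },
        index=X.columns,
    )
    return RegressionResult(
        params=params,
        n=n,
        df_resid=int(model.df_resid),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        aic=float(model.aic),
        bic=float(model.bic),
        residuals=np.asarray(model.resid),
    )


def index_covariate_scan(
    indices: CellTypeIndexTable | pd.DataFrame,
    covars: CovariateTable,
    formula: str = "eq1",
) -> pd.DataFrame:
    """Fit one OLS model per cell-type index; return a tidy long table.

    Columns: cell_type, covariate, beta, se, t, p, q, n. The BH family is
    the entire scan (all cell types x covariate terms, intercept excluded).
    """
    table = indices.consolidated if isinstance(indices, CellTypeIndexTable) else indices
    if formula not in MODEL_PRESETS:
        raise ValueError(f"unknown model preset {formula!r}; use one of {list(MODEL_PRESETS)}")
    preset = MODEL_PRESETS[formula]
    terms = list(preset["required"]) + [
        t for t in preset["optional"] if t in covars.data.columns
    ]
    X = build_design(covars, terms, index=table.index)
    rows = []
    for cell_type in table.columns:
        res = fit_linear(table[cell_type], X)
        for term, r in res.params.iterrows():
            if term == "Intercept":
                continue
            rows.append(
                {
                    "cell_type": cell_type,
                    "covariate": term,
                    "beta": r["beta"],
                    "se": r["se"],
                    "t": r["t"],
                    "p": r["p"],
                    "n": res.n,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def meta_fixed(betas: Iterable[float], variances: Iterable[float]) -> dict[str, float]:
    """Inverse-variance fixed-effects pooling of per-study coefficients.

    Returns pooled b, SE = (sum 1/v)^(-1/2), z = b/SE, and the two-sided
    normal p-value.
    """
    b = np.asarray(list(betas), dtype=float)
    v = np.asarray(list(variances), dtype=float)
    if b.size == 0:
        raise InputError("meta-analysis needs at least one study")
    if b.shape != v.shape:
        raise ValueError("betas and variances must have equal length")
    if (v <= 0).any():
        raise ValidationError("all sampling variances must be positive")
    w = 1.0 / v
    pooled = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"b": pooled, "se": se, "z": z, "p": p}


def meta_scan(
    scans: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Meta-analyze tidy covariate-scan tables from several datasets.

    Pools beta/SE per (cell_type, covariate) across datasets with
    fixed-effects weights, then BH-adjusts over the pooled table.
    """
    frames = []
    for name, df in scans.items():
        d = df[["cell_type", "covariate", "beta", "se"]].copy()
        d["dataset"] = name
        frames.append(d)
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for (cell_type, covariate), grp in stacked.groupby(["cell_type", "covariate"]):
        pooled = meta_fixed(grp["beta"], grp["se"] ** 2)
        rows.append(
            {
                "cell_type": cell_type,
                "covariate": covariate,
                "b": pooled["b"],
                "se": pooled["se"],
                "z": pooled["z"],
                "p": pooled["p"],
                "n_studies": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; order-preserving.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(x: Iterable[float], y: Iterable[float]) -> dict[str, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise InputError("each group needs at least 2 observations")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx + vy == 0:
        raise InputError("both groups are constant; Welch's t is undefined")
    res = stats.ttest_ind(xa, ya, equal_var=False)
    sx, sy = vx / xa.size, vy / ya.size
    df = (sx + sy) ** 2 / (sx**2 / (xa.size - 1) + sy**2 / (ya.size - 1))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def cohens_d(x: Iterable[float], y: Iterable[float]) -> float:
    """Standardized mean difference with the classic pooled sd.

    pooled sd = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise InputError("each group needs at least 2 observations")
    pooled_var = ((xa.size - 1) * xa.var(ddof=1) + (ya.size - 1) * ya.var(ddof=1)) / (
        xa.size + ya.size - 2
    )
    if pooled_var <= 0:
        raise InputError("pooled standard deviation is zero; d is undefined")
    return float((xa.mean() - ya.mean()) / np.sqrt(pooled_var))


def pc_association(
    matrix: ExpressionMatrix,
    indices: CellTypeIndexTable | pd.DataFrame,
    n_pcs: int = 2,
    exclude_db_genes: bool = False,
    db: MarkerDatabase | None = None,
    combinations: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame | pd.Series]:
    """PCA of the expression matrix vs the cell-type indices.

    Rows (transcripts) are centered across samples before the singular
    value decomposition. Returns per-PC % variance, per-sample PC scores,
    and the simple-regression R^2 of each PC on each index column (plus any
    named index combinations, each defined as the mean of listed columns).
    """
    table = indices.consolidated if isinstance(indices, CellTypeIndexTable) else indices
    values = matrix.values
    if exclude_db_genes:
        if db is None:
            raise ValueError("exclude_db_genes requires a MarkerDatabase")
        if matrix.gene_symbols is None:
            raise InputError("exclude_db_genes requires a gene annotation")
        db_genes = {g.upper() for g in db.genes}
        keep = ~matrix.gene_symbols.astype(str).str.upper().isin(db_genes)
        values = values.loc[keep.to_numpy()]
        if values.empty:
            raise InputError("excluding database genes removed every row")
    if n_pcs > min(values.shape):
        raise InputError(
            f"n_pcs={n_pcs} exceeds min(genes, samples) = {min(values.shape)}"
        )
    arr = values.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var_explained = pd.Series(
        100.0 * (s**2) / (s**2).sum(),
        index=[f"PC{i + 1}" for i in range(s.size)],
        name="pct_variance",
    ).iloc[:n_pcs]
    scores = pd.DataFrame(
        (vt[:n_pcs].T * s[:n_pcs]),
        index=values.columns,
        columns=var_explained.index,
    )
    cols = {c: table[c] for c in table.columns}
    for name, members in (combinations or {}).items():
        cols[name] = table[list(members)].mean(axis=1)
    r2 = pd.DataFrame(index=var_explained.index, columns=list(cols), dtype=float)
    for pc in var_explained.index:
        for name, col in cols.items():
            aligned = col.loc[scores.index]
            r = np.corrcoef(scores[pc], aligned)[0, 1]
            r2.loc[pc, name] = r**2
    return {"variance_explained": var_explained, "scores": scores, "r2": r2}
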