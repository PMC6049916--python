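"""Per-gene differential expression under composition-aware model specs.

Five nested OLS specifications are compared gene by gene:

* M1: diagnosis only;
* M2: diagnosis + traditional covariates (pH, PMI, age, ...);
* M3: diagnosis + the five most prevalent cell-type indices
  (Astrocyte, Microglia, Oligodendrocyte, Neuron_Interneuron,
  Neuron_Projection — restricted to avoid multicollinearity);
* M4: M2's covariates + the prevalent indices;
* M5: M2's covariates + all ten indices.

If a gene's apparent diagnosis effect is driven by a diagnosis-linked shift
in cell composition, conditioning on the indices (M3-M5) attenuates the
diagnosis coefficient; a cell-intrinsic effect survives. Model fit is
summarized by AIC/BIC (optionally per-gene-centered so genes of different
noise levels are comparable), and models are contrasted on their ability to
replicate previously documented effects (direction, and direction plus
nominal p < 0.05) with Fisher's exact test on the detection counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from blendr.cohort_stats import CovariateTable, bh_adjust, build_design
from blendr.core import CellTypeIndexTable, ExpressionMatrix
from blendr.errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: The five most prevalent cortical cell types, used by the reduced models.
PREVALENT_TYPES: tuple[str, ...] = (
    "Astrocyte",
    "Microglia",
    "Oligodendrocyte",
    "Neuron_Interneuron",
    "Neuron_Projection",
)

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class ModelSpec:
    """One differential-expression model: diagnosis + optional term groups."""

    id: str
    covariates: tuple[str, ...] = ()
    indices: tuple[str, ...] = ()

    @property
    def terms(self) -> tuple[str, ...]:
        return ("diagnosis",) + self.covariates + self.indices


def standard_model_specs(
    traditional: Sequence[str],
    all_indices: Sequence[str],
    prevalent: Sequence[str] = PREVALENT_TYPES,
) -> list[ModelSpec]:
    """Build the M1-M5 ladder for a dataset's covariate list and indices."""
    prevalent = tuple(t for t in prevalent if t in all_indices)
    return [
        ModelSpec("M1"),
        ModelSpec("M2", covariates=tuple(traditional)),
        ModelSpec("M3", indices=prevalent),
        ModelSpec("M4", covariates=tuple(traditional), indices=prevalent),
        ModelSpec("M5", covariates=tuple(traditional), indices=tuple(all_indices)),
    ]


@dataclass
class DEResult:
    """Tidy per-(gene x model) differential-expression results.

    ``table`` columns: gene, model, beta, t, p, q, aic, bic; beta/t/p refer
    to the requested diagnosis contrast; q is BH within each model family.
    """

    table: pd.DataFrame
    contrast: str
    n: int
    excluded_genes: tuple[str, ...] = ()

    def for_model(self, model_id: str) -> pd.DataFrame:
        return self.table[self.table["model"] == model_id].set_index("gene")


def _ols_many(X: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """OLS of every column of Y (n x G) on the shared design X (n x p).

    Returns per-gene coefficient matrix plus t/p for every coefficient and
    Gaussian-likelihood AIC/BIC (statsmodels convention: k = p regressors).
    """
    n, p = X.shape
    if n <= p:
        raise InputError(f"n={n} samples cannot identify {p} parameters")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x G
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    df_resid = n - p
    # an (all but) exactly-fit gene has no residual scale: inference undefined
    scale = np.maximum(1.0, np.abs(Y).max(axis=0))
    degenerate = rss <= n * (1e-10 * scale) ** 2
    sigma2 = rss / df_resid
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    t[:, degenerate] = 0.0
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    with np.errstate(divide="ignore"):
        llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    aic = -2 * llf + 2 * p
    bic = -2 * llf + np.log(n) * p
    aic[degenerate] = -np.inf
    bic[degenerate] = -np.inf
    return {
        "beta": beta,
        "t": t,
        "p": pvals,
        "aic": aic,
        "bic": bic,
        "df_resid": df_resid,
        "degenerate": degenerate,
    }


def fit_de_models(
    matrix: ExpressionMatrix,
    covars: CovariateTable,
    indices: CellTypeIndexTable | pd.DataFrame,
    specs: Sequence[ModelSpec],
    contrast: str = "SCHIZ",
) -> DEResult:
    """Fit every model spec to every gene; extract the diagnosis contrast.

    All specs are fitted on the same listwise-complete sample set (the
    samples complete for the union of all terms) so AIC/BIC are comparable.
    BH adjustment is applied within each model family.
    """
    table = indices.consolidated if isinstance(indices, CellTypeIndexTable) else indices
    combined = CovariateTable(
        data=covars.data.join(table, how="inner"), reference=covars.reference
    )
    all_terms: list[str] = []
    for spec in specs:
        for t in spec.terms:
            if t not in all_terms:
                all_terms.append(t)
    shared = build_design(combined, all_terms, index=matrix.values.columns).index
    if len(shared) < 3:
        raise InputError("fewer than 3 listwise-complete samples")
    contrast_term = f"diagnosis[{contrast}]"
    frames = []
    excluded: set[str] = set()
    for spec in specs:
        X = build_design(combined, list(spec.terms)).loc[shared]
        if contrast_term not in X.columns:
            raise ValidationError(
                f"contrast level {contrast!r} not present in diagnosis column"
            )
        arr = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValidationError(f"design for {spec.id} is rank deficient")
        Y = matrix.values[shared].to_numpy(dtype=float).T  # n x G
        fit = _ols_many(arr, Y)
        j = list(X.columns).index(contrast_term)
        finite = np.isfinite(fit["aic"])
        excluded.update(np.asarray(matrix.values.index)[~finite])
        df = pd.DataFrame(
            {
                "gene": matrix.values.index,
                "model": spec.id,
                "beta": fit["beta"][j],
                "t": fit["t"][j],
                "p": fit["p"][j],
                "aic": fit["aic"],
                "bic": fit["bic"],
            }
        )
        df["q"] = bh_adjust(df["p"].to_numpy())
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if excluded:
        logger.info("flagged %d genes with degenerate fits", len(excluded))
    return DEResult(
        table=out, contrast=contrast, n=len(shared), excluded_genes=tuple(sorted(excluded))
    )


def model_fit_summary(
    res: DEResult,
    center: bool = False,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-model mean/median AIC and BIC over genes.

    With ``center=True``, each gene's AIC/BIC values are centered on that
    gene's across-model mean before aggregation, so per-gene offsets in
    residual scale cancel and only between-model differences remain.
    """
    df = res.table
    if genes is not None:
        genes = set(genes)
        df = df[df["gene"].isin(genes)]
    if df.empty:
        raise InputError("no genes to summarize")
    df = df[~df["gene"].isin(res.excluded_genes)].copy()
    if center:
        for col in ("aic", "bic"):
            df[col] = df[col] - df.groupby("gene")[col].transform("mean")
    return df.groupby("model").agg(
        mean_aic=("aic", "mean"),
        median_aic=("aic", "median"),
        mean_bic=("bic", "mean"),
        median_bic=("bic", "median"),
        n_genes=("gene", "nunique"),
    )


def replication_rates(
    res: DEResult,
    reference: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per model: fraction of reference genes with replicated direction,
    and fraction replicated with nominal p below the threshold.

    ``reference`` needs columns ``gene`` and ``direction`` (+/-). Reference
    genes absent from the fitted data are excluded from the denominator.
    """
    if not {"gene", "direction"}.issubset(reference.columns):
        raise ValidationError("reference needs 'gene' and 'direction' columns")
    bad = ~reference["direction"].isin(["+", "-"])
    if bad.any():
        raise ValidationError("reference directions must be '+' or '-'")
    expected = reference.set_index("gene")["direction"].map({"+": 1.0, "-": -1.0})
    rows = []
    for model_id, grp in res.table.groupby("model"):
        grp = grp.set_index("gene")
        present = expected.index.intersection(grp.index)
        if present.empty:
            raise InputError("no reference gene is present in the fitted results")
        n_absent = len(expected) - len(present)
        if n_absent:
            logger.info("%s: %d reference genes absent from dataset", model_id, n_absent)
        signs = np.sign(grp.loc[present, "beta"])
        replicated = signs == expected.loc[present]
        detected = replicated & (grp.loc[present, "p"] < p_threshold)
        rows.append(
            {
                "model": model_id,
                "n_reference": len(present),
                "frac_direction": float(replicated.mean()),
                "frac_detected": float(detected.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def fisher_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> dict[str, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sidedness by the probability-mass definition (sum over tables at
    least as extreme as observed under the hypergeometric null); the odds
    ratio is the conditional maximum-likelihood estimate.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("Fisher's exact test needs integer counts")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if arr.sum() == 0:
        raise InputError("all counts are zero")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    orr = odds_ratio(arr, kind="conditional")
    return {"p": float(p), "odds_ratio": float(orr.statistic)}


def enrichment_vs_background(
    hits_in_set: int,
    set_size: int,
    hits_in_background: int,
    background_size: int,
) -> dict[str, float]:
    """Fisher enrichment of significant genes in a set vs the background.

    Background counts are for genes *outside* the set; the 2x2 table is
    (in-set vs out-of-set) x (significant vs not).
    """
    if hits_in_set > set_size or hits_in_background > background_size:
        raise ValidationError("hits cannot exceed the group size")
    if min(hits_in_set, set_size, hits_in_background, background_size) < 0:
        raise ValidationError("counts must be non-negative")
    table = [
        [hits_in_set, set_size - hits_in_set],
        [hits_in_background, background_size - hits_in_background],
    ]
    return fisher_2x2(table)
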