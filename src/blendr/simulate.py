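"""Ground-truthed synthetic data: purified profiles, mixtures, cohorts.

The generator emulates the physical situation the index method targets:
each tissue sample is a mixture of cell populations whose transcripts
combine *linearly* in expression space, but the data are observed on a
log2(x+1) scale with additive Gaussian measurement noise, as is standard
for normalized microarray intensities. Cohort simulations additionally let
donor covariates (pH, agonal factor, PMI, age, sex, diagnosis, batch)
shift the per-sample cell proportions through a softmax link, providing
known effects against which covariate scans and differential-expression
models can be validated.

All randomness flows from a single integer seed through
``numpy.random.default_rng`` with documented child seeds (SeedSequence
spawning), so every artifact is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from blendr.celltype_db import CATEGORIES, MarkerDatabase, MarkerEntry
from blendr.core import ExpressionMatrix
from blendr.errors import InputError, ValidationError

#: Baseline per-type log-odds chosen to mimic a plausible cortical mix:
#: neurons and astrocytes common, vascular cells and RBC rare.
DEFAULT_BASE_LOGODDS: dict[str, float] = {
    "Astrocyte": 2.3,
    "Endothelial": 0.9,
    "Mural": 0.0,
    "Microglia": 1.4,
    "Oligodendrocyte": 2.0,
    "Oligodendrocyte_Immature": 0.4,
    "Neuron_All": 2.0,
    "Neuron_Interneuron": 1.6,
    "Neuron_Projection": 2.3,
    "RBC": 0.0,
}


@dataclass
class CellProfileSet:
    """Linear-scale mean expression profiles for a set of cell types.

    ``profiles`` is genes x types: marker genes take ``fold`` times their
    baseline in their own type and baseline elsewhere; non-markers take
    baseline in every type.
    """

    profiles: pd.DataFrame
    baseline: pd.Series
    marker_map: dict[str, str]
    fold: float
    seed: int

    @property
    def types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)


@dataclass
class MixtureDesign:
    """Samples x types proportion matrix; every row must lie on the simplex."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("mixture proportions must be non-negative")
        bad = np.abs(arr.sum(axis=1) - 1.0) > 1e-12
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} mixture row(s) do not sum to 1 (tolerance 1e-12)"
            )


@dataclass
class SyntheticCohort:
    """A simulated cohort: expression, covariates, and full ground truth."""

    expr: ExpressionMatrix
    metadata: pd.DataFrame
    true_proportions: pd.DataFrame
    true_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0


def make_profiles(
    n_genes: int,
    markers_per_type: int = 5,
    fold: float = 4.0,
    n_types: int = 10,
    seed: int = 0,
) -> CellProfileSet:
    """Draw purified cell-type expression profiles.

    Baselines are log-normal (median ~55 linear units, sigma 1 on the
    natural-log scale), a heavy-tailed positive distribution typical of
    expression levels. The first ``n_types * markers_per_type`` genes are
    assigned as disjoint marker blocks, one block per type. The default
    marker enrichment (4x over baseline) is typical of curated cell-type
    markers and keeps the log2-observed index approximately linear in the
    mixing proportion, the regime the index method assumes.
    """
    if not 1 <= n_types <= len(CATEGORIES):
        raise ValueError(f"n_types must be in 1..{len(CATEGORIES)}")
    if fold <= 1:
        raise ValidationError(f"marker fold enrichment must exceed 1, got {fold}")
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    if n_genes < n_types * markers_per_type:
        raise InputError(
            f"cannot allocate {n_types}x{markers_per_type} disjoint markers "
            f"from {n_genes} genes"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    types = list(CATEGORIES[:n_types])
    genes = [f"G{i:05d}" for i in range(n_genes)]
    baseline = pd.Series(rng.lognormal(mean=4.0, sigma=1.0, size=n_genes), index=genes)
    profiles = pd.DataFrame(
        np.tile(baseline.to_numpy()[:, None], (1, n_types)), index=genes, columns=types
    )
    marker_map: dict[str, str] = {}
    for k, t in enumerate(types):
        block = genes[k * markers_per_type : (k + 1) * markers_per_type]
        for g in block:
            marker_map[g] = t
        profiles.loc[block, t] *= fold
    return CellProfileSet(
        profiles=profiles, baseline=baseline, marker_map=marker_map, fold=fold, seed=seed
    )


def simulate_mixture(
    profiles: CellProfileSet,
    design: MixtureDesign,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mix profiles linearly per the design, observe as log2(x+1) + noise.

    Returns (expression matrix, ground-truth proportions). With
    ``noise_sd=0`` each sample is exactly log2 of its expected linear value
    plus one.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = set(design.proportions.columns) - set(profiles.types)
    if missing:
        raise ValidationError(f"design references unknown cell types: {sorted(missing)}")
    props = design.proportions[profiles.types] if set(design.proportions.columns) == set(
        profiles.types
    ) else design.proportions
    P = profiles.profiles[props.columns].to_numpy()  # genes x types
    W = props.to_numpy(dtype=float)  # samples x types
    linear = P @ W.T  # genes x samples
    obs = np.log2(linear + 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
        obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
    sample_ids = [str(s) for s in props.index]
    values = pd.DataFrame(obs, index=profiles.genes, columns=sample_ids)
    expr = ExpressionMatrix(
        values=values,
        gene_symbols=pd.Series(profiles.genes, index=profiles.genes),
    )
    truth = props.copy()
    truth.index = sample_ids
    return expr, truth


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate distributions modeled on post-mortem psychiatric cohorts."""
    meta = pd.DataFrame(index=[f"S{i:04d}" for i in range(n)])
    meta["brain_pH"] = rng.normal(6.7, 0.25, n).clip(5.8, 7.3)
    meta["agonal_factor"] = rng.choice(5, size=n, p=[0.55, 0.15, 0.12, 0.10, 0.08])
    meta["PMI"] = rng.normal(24.0, 8.0, n).clip(2.0, None)
    meta["age"] = rng.normal(50.0, 15.0, n).clip(18.0, 90.0)
    meta["sex"] = rng.choice(["F", "M"], size=n, p=[0.35, 0.65])
    meta["diagnosis"] = rng.choice(
        ["CTRL", "MDD", "BP", "SCHIZ"], size=n, p=[0.45, 0.26, 0.15, 0.14]
    )
    meta["batch"] = rng.choice(["B1", "B2", "B3"], size=n)
    meta["exsanguination"] = rng.choice([0, 1], size=n, p=[0.94, 0.06])
    meta["rna_degradation"] = rng.normal(0.0, 1.0, n)
    return meta


def _effect_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding used for proportion effects.

    Numeric covariates are standardized (sample mean/sd) so a log-odds
    shift of e.g. 0.5 means "per sd"; categorical covariates contribute a
    0/1 indicator per non-reference level, keyed ``covariate:level``.
    """
    cols: dict[str, np.ndarray] = {}
    for c in meta.columns:
        s = meta[c]
        if pd.api.types.is_numeric_dtype(s):
            sd = s.std(ddof=1)
            cols[c] = ((s - s.mean()) / sd).to_numpy() if sd > 0 else np.zeros(len(s))
        else:
            for level in sorted(s.unique()):
                if level in ("CTRL", "F", "B1"):  # reference levels
                    continue
                cols[f"{c}:{level}"] = (s == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.index)


def simulate_cohort(
    profiles: CellProfileSet,
    n_samples: int,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    base_logodds: Mapping[str, float] | None = None,
    logodds_sd: float = 0.5,
) -> SyntheticCohort:
    """Simulate a cohort whose cell proportions respond to covariates.

    Per sample, the proportion of each type is
    softmax(base log-odds + per-sample N(0, logodds_sd) heterogeneity +
    sum_c x_c * effect[c][type]); expression then follows
    :func:`simulate_mixture`. ``effects`` keys are covariate terms as
    produced by the internal encoding ("age", "diagnosis:MDD", ...).

    ``logodds_sd`` models the biological sample-to-sample variability in
    composition (dissection differences, individual anatomy) that
    dominates real macro-dissected tissue; set it to 0 for cohorts whose
    composition is a deterministic function of the covariates.
    """
    if n_samples < 2:
        raise InputError("a cohort needs at least 2 samples")
    effects = {k: dict(v) for k, v in (effects or {}).items()}
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_meta = np.random.default_rng(ss[0])
    meta = _draw_covariates(n_samples, rng_meta)
    design = _effect_design(meta)
    unknown = set(effects) - set(design.columns)
    if unknown:
        raise ValidationError(f"effects reference unknown covariate terms: {sorted(unknown)}")
    if logodds_sd < 0:
        raise ValueError("logodds_sd must be >= 0")
    base = dict(DEFAULT_BASE_LOGODDS if base_logodds is None else base_logodds)
    types = profiles.types
    logits = np.tile(
        np.array([base.get(t, 0.0) for t in types], dtype=float), (n_samples, 1)
    )
    if logodds_sd > 0:
        rng_het = np.random.default_rng(ss[1])
        logits = logits + rng_het.normal(0.0, logodds_sd, size=logits.shape)
    for term, per_type in effects.items():
        bad = set(per_type) - set(types)
        if bad:
            raise ValidationError(f"effects for {term!r} reference unknown types: {sorted(bad)}")
        x = design[term].to_numpy()
        for t, shift in per_type.items():
            logits[:, types.index(t)] += x * shift
    props = pd.DataFrame(_softmax(logits), index=meta.index, columns=types)
    expr, truth = simulate_mixture(
        profiles, MixtureDesign(props), noise_sd=noise_sd, seed=int(ss[2].generate_state(1)[0] % (2**31))
    )
    truth.index = meta.index
    expr.values.columns = meta.index
    return SyntheticCohort(
        expr=expr,
        metadata=meta,
        true_proportions=truth,
        true_effects={k: dict(v) for k, v in effects.items()},
        seed=seed,
    )


def make_synthetic_db(
    profiles: CellProfileSet,
    pubs_per_type: int = 1,
    overlap_genes: int = 0,
    seed: int = 0,
) -> MarkerDatabase:
    """Build a MarkerDatabase mirroring the curated-table structure.

    Each type's markers are split round-robin into ``pubs_per_type``
    publication tags; ``overlap_genes`` markers are additionally listed
    under a second category to exercise cross-category overlap removal.
    """
    if pubs_per_type < 1:
        raise ValueError("pubs_per_type must be >= 1")
    types = profiles.types
    markers_by_type: dict[str, list[str]] = {t: [] for t in types}
    for g, t in profiles.marker_map.items():
        markers_by_type[t].append(g)
    entries: list[MarkerEntry] = []
    for t in types:
        markers = sorted(markers_by_type[t])
        if len(markers) < pubs_per_type:
            raise InputError(
                f"type {t} has {len(markers)} markers; cannot split into "
                f"{pubs_per_type} publications"
            )
        for i, g in enumerate(markers):
            tag = f"{t}_SynthPub{i % pubs_per_type + 1}"
            entries.append(
                MarkerEntry(
                    gene_symbol=g,
                    primary_category=t,
                    publication_tag=tag,
                    species="synthetic",
                    brain_region="cortex",
                    platform="simulation",
                    citation="synthetic",
                )
            )
    if overlap_genes:
        all_markers = sorted(profiles.marker_map)
        if overlap_genes > len(all_markers):
            raise InputError(
                f"requested {overlap_genes} overlap genes but only "
                f"{len(all_markers)} markers exist"
            )
        if len(types) < 2:
            raise InputError("overlap genes require at least 2 cell types")
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
        chosen = rng.choice(all_markers, size=overlap_genes, replace=False)
        for g in chosen:
            home = profiles.marker_map[g]
            other = types[(types.index(home) + 1) % len(types)]
            entries.append(
                MarkerEntry(
                    gene_symbol=g,
                    primary_category=other,
                    publication_tag=f"{other}_SynthPub1",
                    species="synthetic",
                    brain_region="cortex",
                    platform="simulation",
                    citation="synthetic-overlap",
                )
            )
    return MarkerDatabase.from_entries(entries)
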