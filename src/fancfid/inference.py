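"""Model specification, design building and the null → level-1 → combined
model sequence for fidelity determinants.

Level-1 (woman) covariates and level-2 (health-post) covariates are named by
what they measure; cluster-level terms are joined onto women through the
cluster id.  Categorical covariates enter as treatment contrasts against the
stated reference levels (no formal education, no prior pregnancy problems).
Model fitting is complete-case: rows missing any used covariate are dropped
and the drop count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ModelSpecificationError, ValidationError
from .fidelity import Composition, woman_fidelity
from .lmm import RandomInterceptLM, RandomInterceptLMResults
from .records import CohortTable, MaternalEducation, PartnerEducation, facilitation_score

logger = logging.getLogger(__name__)

__all__ = [
    "LEVEL1_TERMS",
    "LEVEL2_TERMS",
    "ModelSpec",
    "Design",
    "cohort_frame",
    "build_design",
    "fit_spec",
    "model_sequence",
    "multilevel_decision",
    "default_model_specs",
]

#: Woman-level covariates and the design column(s) each produces.
LEVEL1_TERMS = {
    "age_years": ("age_years",),
    "prior_pregnancy_problems": ("prior_problems_yes",),
    "partner_education": ("partner_formal_1_8",),
    "maternal_education": ("maternal_formal",),
    "n_abortions": ("n_abortions",),
    "walk_minutes_to_health_post": ("walk_minutes_to_health_post",),
}

#: Health-post-level covariates (constant within cluster).
LEVEL2_TERMS = {
    "facilitation_score": ("facilitation_score",),
    "farthest_household_minutes": ("farthest_household_minutes",),
    "supplies_score": ("supplies_score",),
    "n_hews": ("n_hews",),
}


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification: response, terms at each level."""

    response: str = "fidelity"
    level1_terms: tuple[str, ...] = ()
    level2_terms: tuple[str, ...] = ()
    cluster_key: str = "cluster_id"
    estimation: str = "ml"
    name: str = "model"

    def __post_init__(self) -> None:
        terms = list(self.level1_terms) + list(self.level2_terms)
        if len(set(terms)) != len(terms):
            raise ValidationError(f"spec {self.name!r}: duplicate terms")
        bad1 = [t for t in self.level1_terms if t not in LEVEL1_TERMS]
        bad2 = [t for t in self.level2_terms if t not in LEVEL2_TERMS]
        if bad1 or bad2:
            raise ModelSpecificationError(
                f"spec {self.name!r}: unknown terms level1={bad1}, level2={bad2}"
            )
        if self.estimation.lower() not in {"ml", "reml"}:
            raise ValidationError("estimation must be 'ml' or 'reml'")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.level1_terms) + tuple(self.level2_terms)


@dataclass
class Design:
    """Design matrices plus the cluster index, ready for the LMM."""

    y: np.ndarray
    X: np.ndarray
    clusters: np.ndarray
    names: list[str]
    n_dropped: int
    dropped_terms: list[str] = field(default_factory=list)
    woman_ids: list[str] = field(default_factory=list)


def cohort_frame(
    cohort: CohortTable,
    composition: Composition | str = Composition.PRODUCT,
    response_values: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Tidy per-woman frame with covariates, cluster joins and the response.

    The ``fidelity`` column is computed from the records by the scorer unless
    an explicit response vector (aligned with cohort order) is supplied —
    e.g. the known-truth response of a linear-mode simulation.
    """
    rows = []
    for w in cohort.women:
        c = cohort.clusters[w.cluster_id]
        rows.append(
            {
                "woman_id": w.woman_id,
                "cluster_id": w.cluster_id,
                "fidelity": woman_fidelity(w, composition).fidelity,
                "age_years": w.age_years,
                "prior_problems_yes": (
                    None
                    if w.prior_pregnancy_problems is None
                    else float(w.prior_pregnancy_problems)
                ),
                "partner_formal_1_8": (
                    None
                    if w.partner_education is None
                    else float(w.partner_education is PartnerEducation.FORMAL_1_8)
                ),
                "maternal_formal": (
                    None
                    if w.maternal_education is None
                    else float(w.maternal_education is MaternalEducation.FORMAL)
                ),
                "n_abortions": w.n_abortions,
                "walk_minutes_to_health_post": w.walk_minutes_to_health_post,
                "facilitation_score": float(facilitation_score(c)),
                "farthest_household_minutes": c.farthest_household_minutes,
                "supplies_score": float(c.supplies_score),
                "n_hews": float(c.n_hews),
            }
        )
    df = pd.DataFrame(rows)
    if response_values is not None:
        resp = np.asarray(response_values, dtype=float).ravel()
        if resp.shape[0] != len(df):
            raise ValidationError("response_values length must match cohort size")
        df["fidelity"] = resp
    return df


def build_design(
    cohort: CohortTable,
    spec: ModelSpec,
    response_values: Optional[np.ndarray] = None,
    composition: Composition | str = Composition.PRODUCT,
    row_mask: Optional[np.ndarray] = None,
) -> Design:
    """Complete-case design matrices for one specification.

    Constant (rank-deficient) columns are dropped with a logged warning;
    a term whose column is entirely missing raises a specification error.
    ``row_mask`` restricts to a predetermined row set (used by
    :func:`model_sequence` to fit nested specs on identical rows).
    """
    frame = cohort_frame(cohort, composition, response_values)
    colnames: list[str] = []
    for t in spec.level1_terms:
        colnames.extend(LEVEL1_TERMS[t])
    for t in spec.level2_terms:
        colnames.extend(LEVEL2_TERMS[t])

    used = [spec.response, *colnames]
    for c in used:
        if frame[c].isna().all():
            raise ModelSpecificationError(f"term column {c!r} is entirely missing")

    keep = frame[used].notna().all(axis=1)
    if row_mask is not None:
        keep &= np.asarray(row_mask, dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "spec %r: dropped %d incomplete rows (complete-case)", spec.name, n_dropped
        )
    sub = frame.loc[keep]
    if len(sub) == 0:
        raise ValidationError(f"spec {spec.name!r}: no complete-case rows")

    names = ["intercept"]
    cols = [np.ones(len(sub))]
    dropped_terms: list[str] = []
    for c in colnames:
        v = sub[c].to_numpy(dtype=float)
        if np.all(v == v[0]):
            logger.warning(
                "spec %r: term column %r is constant on the analysis rows; "
                "dropped (rank deficiency)",
                spec.name,
                c,
            )
            dropped_terms.append(c)
            continue
        names.append(c)
        cols.append(v)
    X = np.column_stack(cols)
    return Design(
        y=sub[spec.response].to_numpy(dtype=float),
        X=X,
        clusters=sub[spec.cluster_key].to_numpy(),
        names=names,
        n_dropped=n_dropped,
        dropped_terms=dropped_terms,
        woman_ids=sub["woman_id"].tolist(),
    )


def fit_spec(
    cohort: CohortTable,
    spec: ModelSpec,
    response_values: Optional[np.ndarray] = None,
    composition: Composition | str = Composition.PRODUCT,
    row_mask: Optional[np.ndarray] = None,
) -> RandomInterceptLMResults:
    """Build the design for ``spec`` and fit the random-intercept model."""
    d = build_design(cohort, spec, response_values, composition, row_mask)
    model = RandomInterceptLM(d.y, d.X, d.clusters, exog_names=d.names)
    return model.fit(method=spec.estimation)


def model_sequence(
    cohort: CohortTable,
    specs: Sequence[ModelSpec],
    response_values: Optional[np.ndarray] = None,
    composition: Composition | str = Composition.PRODUCT,
) -> tuple[pd.DataFrame, dict[str, RandomInterceptLMResults]]:
    """Fit an ordered model sequence on one common complete-case row set.

    All specs must share response and cluster key.  The comparison table has
    one row per spec (loglik, AIC, BIC, ICC) and flags the AIC/BIC minimizer;
    a failed member fit is noted in the table rather than aborting the run.
    """
    if not specs:
        raise ValidationError("model_sequence needs at least one spec")
    responses = {s.response for s in specs}
    keys = {s.cluster_key for s in specs}
    if len(responses) != 1 or len(keys) != 1:
        raise ValidationError("all specs must share response and cluster key")

    frame = cohort_frame(cohort, composition, response_values)
    all_cols: list[str] = [specs[0].response]
    for s in specs:
        for t in s.level1_terms:
            all_cols.extend(LEVEL1_TERMS[t])
        for t in s.level2_terms:
            all_cols.extend(LEVEL2_TERMS[t])
    all_cols = list(dict.fromkeys(all_cols))
    mask = frame[all_cols].notna().all(axis=1).to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info(
            "model_sequence: %d rows dropped to fit all specs on identical rows",
            n_dropped,
        )

    rows = []
    fits: dict[str, RandomInterceptLMResults] = {}
    for s in specs:
        try:
            fit = fit_spec(cohort, s, response_values, composition, row_mask=mask)
            fits[s.name] = fit
            rows.append(
                {
                    "model": s.name,
                    "n_params": fit.n_params,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "icc": fit.icc,
                    "converged": fit.converged,
                    "note": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - partial table per contract
            rows.append(
                {
                    "model": s.name,
                    "n_params": np.nan,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "icc": np.nan,
                    "converged": False,
                    "note": f"fit failed: {exc}",
                }
            )
    table = pd.DataFrame(rows)
    if table["aic"].notna().any():
        best = table["aic"].idxmin()
        table["best_aic"] = False
        table.loc[best, "best_aic"] = True
    else:
        table["best_aic"] = False
    return table, fits


def multilevel_decision(null_fit: RandomInterceptLMResults, threshold: float = 0.05) -> bool:
    """Is multilevel modelling warranted?  True iff null-model ICC > threshold."""
    return null_fit.icc > threshold


def default_model_specs(estimation: str = "ml") -> list[ModelSpec]:
    """The shipped null → level-1 → combined sequence.

    The level-1 model carries the woman-level covariates (age, distance to
    the health post, maternal education, prior pregnancy problems, partner
    education, abortion count); the combined model keeps prior problems and
    partner education and adds the cluster facilitation-strategy score.
    """
    return [
        ModelSpec(name="null", estimation=estimation),
        ModelSpec(
            name="level1",
            estimation=estimation,
            level1_terms=(
                "age_years",
                "walk_minutes_to_health_post",
                "maternal_education",
                "prior_pregnancy_problems",
                "partner_education",
                "n_abortions",
            ),
        ),
        ModelSpec(
            name="combined",
            estimation=estimation,
            level1_terms=("prior_pregnancy_problems", "partner_education"),
            level2_terms=("facilitation_score",),
        ),
    ]
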