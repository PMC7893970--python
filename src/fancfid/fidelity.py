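"""Per-woman and cohort-level FANC intervention-fidelity scoring.

Fidelity is a composite of three components, each scaled to [0, 1]:

* coverage — did the woman have at least one ANC contact (0/1);
* frequency weight — visits relative to the recommended four, ``min(v, 4)/4``
  (more than four visits earns no bonus);
* content weight — delivered checklist items relative to the 17 recommended,
  ``k/17``.

The default composite is the product of the three (a non-attender scores 0,
and shortfalls in frequency and content both discount the score).  An
alternative equal-weight arithmetic-mean composite is available; it is never
smaller than the product for any record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .records import CohortTable, ContentChecklist, Provider, WomanRecord

__all__ = [
    "N_CONTENT_ITEMS",
    "RECOMMENDED_VISITS",
    "Composition",
    "Stratum",
    "FidelityComponents",
    "FidelityEstimate",
    "coverage_indicator",
    "frequency_weight",
    "content_weight",
    "woman_fidelity",
    "cohort_fidelity",
    "fidelity_frame",
]

N_CONTENT_ITEMS = 17
RECOMMENDED_VISITS = 4


class Composition(str, Enum):
    """How the three components combine into one score."""

    PRODUCT = "product"
    EQUAL_MEAN = "equal_mean"


class Stratum(str, Enum):
    """Denominator for cohort estimates.

    ALL averages over every sampled woman, attender or not; HEW and SKILLED
    average over attenders whose care came from that provider type.
    """

    ALL = "all"
    HEW = "hew"
    SKILLED = "skilled"


@dataclass(frozen=True)
class FidelityComponents:
    coverage: int
    frequency_weight: float
    content_weight: float
    fidelity: float


@dataclass(frozen=True)
class FidelityEstimate:
    mean: float
    ci_low: float
    ci_high: float
    n: int
    stratum: Stratum
    level: float = 0.95


def coverage_indicator(record: WomanRecord) -> int:
    """1 if the woman had at least one ANC contact, else 0."""
    return 1 if record.n_visits >= 1 else 0


def frequency_weight(n_visits: int) -> float:
    """Visits relative to the recommended four, capped at 1."""
    if n_visits < 0:
        raise ValueError("n_visits must be >= 0")
    return min(n_visits, RECOMMENDED_VISITS) / RECOMMENDED_VISITS


def content_weight(contents: ContentChecklist) -> float:
    """Delivered content items as a fraction of the 17 recommended."""
    return contents.n_delivered / N_CONTENT_ITEMS


def woman_fidelity(
    record: WomanRecord,
    composition: Composition | str = Composition.PRODUCT,
) -> FidelityComponents:
    """Score one woman; returns the components alongside the composite."""
    composition = Composition(composition)
    cov = coverage_indicator(record)
    # A non-attender has zero frequency and content by construction; keeping
    # the components explicitly zero makes both composites vanish with her.
    freq = frequency_weight(record.n_visits)
    cont = content_weight(record.contents)
    if composition is Composition.PRODUCT:
        fid = cov * freq * cont
    else:
        fid = (cov + freq + cont) / 3.0
    return FidelityComponents(
        coverage=cov, frequency_weight=freq, content_weight=cont, fidelity=fid
    )


def _stratum_records(cohort: CohortTable, stratum: Stratum) -> list[WomanRecord]:
    if stratum is Stratum.ALL:
        return list(cohort.women)
    provider = Provider.HEW if stratum is Stratum.HEW else Provider.SKILLED
    return [w for w in cohort.women if w.attended and w.provider is provider]


def cohort_fidelity(
    cohort: CohortTable,
    stratum: Stratum | str = Stratum.ALL,
    composition: Composition | str = Composition.PRODUCT,
    ci_level: float = 0.95,
    use_t: bool = False,
) -> FidelityEstimate:
    """Mean fidelity over a stratum with a large-sample CI on the mean.

    The interval is mean ± z·(sample SD/√n), clipped to [0, 1]; ``use_t``
    swaps the normal multiplier for Student's t with n−1 degrees of freedom.
    """
    stratum = Stratum(stratum)
    records = _stratum_records(cohort, stratum)
    if not records:
        raise ValidationError(f"empty cohort stratum {stratum.value!r}")
    values = np.array([woman_fidelity(w, composition).fidelity for w in records])
    n = values.size
    mean = float(values.mean())
    if n > 1:
        sd = float(values.std(ddof=1))
        if use_t:
            mult = float(stats.t.ppf(0.5 + ci_level / 2, df=n - 1))
        else:
            mult = float(stats.norm.ppf(0.5 + ci_level / 2))
        half = mult * sd / math.sqrt(n)
    else:
        half = 0.0
    return FidelityEstimate(
        mean=mean,
        ci_low=max(0.0, mean - half),
        ci_high=min(1.0, mean + half),
        n=n,
        stratum=stratum,
        level=ci_level,
    )


def fidelity_frame(
    cohort: CohortTable,
    composition: Composition | str = Composition.PRODUCT,
):
    """Per-woman component table (one row per woman, cohort order)."""
    import pandas as pd

    rows = []
    for w in cohort.women:
        comp = woman_fidelity(w, composition)
        rows.append(
            {
                "woman_id": w.woman_id,
                "cluster_id": w.cluster_id,
                "provider": w.provider.value,
                "n_visits": w.n_visits,
                "n_contents": w.contents.n_delivered,
                "coverage": comp.coverage,
                "frequency_weight": comp.frequency_weight,
                "content_weight": comp.content_weight,
                "fidelity": comp.fidelity,
            }
        )
    columns = [
        "woman_id",
        "cluster_id",
        "provider",
        "n_visits",
        "n_contents",
        "coverage",
        "frequency_weight",
        "content_weight",
        "fidelity",
    ]
    return pd.DataFrame(rows, columns=columns)
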