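"""Domain records for the FANC fidelity survey and their delimited-text I/O.

Two tables describe a study cohort: a *women* table (one row per surveyed
woman, nested in a health-post cluster) and a *clusters* table (one row per
audited health post).  Records are validated eagerly: a ``CohortTable`` can
only be constructed from internally consistent data, and the CSV readers
raise typed errors naming the offending row and column rather than returning
a partially built cohort.

The 17-item focused-antenatal-care content checklist follows the national
FANC package: measurements (weight, height, blood pressure), counselling
items (institutional birth, birth preparedness, danger signs, hygiene,
PMTCT, STI, bed net, nutrition, care seeking), HIV testing, adequate tetanus
toxoid vaccination, iron–folate supplementation, referral for institutional
birth, and being told the expected date of delivery.  ``tt_adequate`` is
derived from the recorded dose count (default: at least two doses, the
package's stated schedule; a threshold of one is configurable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ParseError, ReferentialIntegrityError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CONTENT_ITEMS",
    "FACILITATION_ITEMS",
    "DEFAULT_SUPPLY_ITEMS",
    "DEFAULT_TT_THRESHOLD",
    "Provider",
    "PartnerEducation",
    "MaternalEducation",
    "ContentChecklist",
    "WomanRecord",
    "ClusterRecord",
    "CohortTable",
    "facilitation_score",
    "read_cohort",
    "write_cohort",
    "load_schema",
    "tt_adequate",
]

#: The 17 content indicators, in checklist order.
CONTENT_ITEMS: tuple[str, ...] = (
    "weight_measured",
    "height_measured",
    "bp_measured",
    "advised_institutional_birth",
    "advised_bpcr",
    "advised_danger_signs",
    "advised_hygiene",
    "advised_pmtct",
    "advised_sti",
    "advised_bed_net",
    "hiv_tested",
    "advised_nutrition",
    "told_seek_care",
    "tt_adequate",
    "iron_folate",
    "referred_institutional_birth",
    "edd_told",
)

#: Facilitation-strategy items audited per health post (supervision and
#: support activities meant to enable HEW service delivery).
FACILITATION_ITEMS: tuple[str, ...] = (
    "weekly_hc_supervision",
    "monthly_woreda_supervision",
    "community_support",
    "hda_support",
    "onsite_assistance",
    "fanc_training",
    "recent_refresher",
)

#: Default auditable supply/equipment items for a health post.
DEFAULT_SUPPLY_ITEMS: tuple[str, ...] = (
    "bpcr_forms",
    "supervision_checklists",
    "bp_cuff",
    "registration_book",
    "stethoscope",
    "tape_measure",
    "weighing_scale",
    "iron_folate_stock",
)

#: FANC specifies two tetanus toxoid doses during pregnancy.
DEFAULT_TT_THRESHOLD = 2

_TRUE_TOKENS = {"1", "yes", "true"}
_FALSE_TOKENS = {"0", "no", "false"}


def tt_adequate(tt_doses: int, threshold: int = DEFAULT_TT_THRESHOLD) -> bool:
    """Whether the recorded tetanus toxoid dose count meets the schedule."""
    return tt_doses >= threshold


class Provider(str, Enum):
    """Who delivered antenatal care; NONE marks a non-attender."""

    HEW = "HEW"
    SKILLED = "SKILLED"
    NONE = "NONE"


class PartnerEducation(str, Enum):
    NO_FORMAL = "NO_FORMAL"
    FORMAL_1_8 = "FORMAL_1_8"


class MaternalEducation(str, Enum):
    NO_FORMAL = "NO_FORMAL"
    FORMAL = "FORMAL"


@dataclass(frozen=True)
class ContentChecklist:
    """The 17 FANC content indicators for one woman."""

    weight_measured: bool = False
    height_measured: bool = False
    bp_measured: bool = False
    advised_institutional_birth: bool = False
    advised_bpcr: bool = False
    advised_danger_signs: bool = False
    advised_hygiene: bool = False
    advised_pmtct: bool = False
    advised_sti: bool = False
    advised_bed_net: bool = False
    hiv_tested: bool = False
    advised_nutrition: bool = False
    told_seek_care: bool = False
    tt_adequate: bool = False
    iron_folate: bool = False
    referred_institutional_birth: bool = False
    edd_told: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in CONTENT_ITEMS}

    @classmethod
    def from_dict(cls, flags: Mapping[str, bool]) -> "ContentChecklist":
        unknown = set(flags) - set(CONTENT_ITEMS)
        if unknown:
            raise ValidationError(f"unknown content items: {sorted(unknown)}")
        return cls(**dict(flags))

    @property
    def n_delivered(self) -> int:
        """Count of delivered content items, in [0, 17]."""
        return sum(self.as_dict().values())

    def any(self) -> bool:
        return self.n_delivered > 0


@dataclass(frozen=True)
class WomanRecord:
    """One surveyed woman: cluster membership, ANC exposure, covariates.

    Covariates may be missing (``None``); ANC exposure fields may not.
    Structural invariants: ``provider`` is NONE exactly when ``n_visits`` is
    zero, and a non-attender has an all-false checklist, no TT doses and no
    first-visit month.
    """

    woman_id: str
    cluster_id: str
    n_visits: int
    contents: ContentChecklist
    provider: Provider
    tt_doses: int
    age_years: Optional[float] = None
    prior_pregnancy_problems: Optional[bool] = None
    partner_education: Optional[PartnerEducation] = None
    maternal_education: Optional[MaternalEducation] = None
    n_abortions: Optional[int] = None
    walk_minutes_to_health_post: Optional[float] = None
    first_visit_month: Optional[int] = None

    def __post_init__(self) -> None:
        wid = self.woman_id
        if not wid:
            raise ValidationError("woman_id must be non-empty")
        if not self.cluster_id:
            raise ValidationError(f"woman {wid!r}: cluster_id must be non-empty")
        if self.n_visits < 0:
            raise ValidationError(f"woman {wid!r}: n_visits must be >= 0")
        if self.tt_doses < 0:
            raise ValidationError(f"woman {wid!r}: tt_doses must be >= 0")
        if (self.provider is Provider.NONE) != (self.n_visits == 0):
            raise ValidationError(
                f"woman {wid!r}: provider must be NONE iff n_visits == 0 "
                f"(got provider={self.provider.value}, n_visits={self.n_visits})"
            )
        if self.n_visits == 0:
            if self.contents.any():
                raise ValidationError(
                    f"woman {wid!r}: zero ANC visits but content items marked delivered"
                )
            if self.first_visit_month is not None:
                raise ValidationError(
                    f"woman {wid!r}: zero ANC visits but first_visit_month present"
                )
        if self.age_years is not None and self.age_years < 12:
            raise ValidationError(f"woman {wid!r}: age_years must be >= 12")
        if self.n_abortions is not None and self.n_abortions < 0:
            raise ValidationError(f"woman {wid!r}: n_abortions must be >= 0")
        if (
            self.walk_minutes_to_health_post is not None
            and self.walk_minutes_to_health_post < 0
        ):
            raise ValidationError(f"woman {wid!r}: walk minutes must be >= 0")
        if self.first_visit_month is not None and not 1 <= self.first_visit_month <= 10:
            raise ValidationError(f"woman {wid!r}: first_visit_month must be in [1, 10]")

    @property
    def attended(self) -> bool:
        return self.n_visits >= 1


@dataclass(frozen=True)
class ClusterRecord:
    """Health-post audit: staffing, facilitation strategies, supplies."""

    cluster_id: str
    n_hews: int
    facilitation_items: Mapping[str, bool]
    supplies: Mapping[str, bool]
    farthest_household_minutes: float

    def __post_init__(self) -> None:
        if not self.cluster_id:
            raise ValidationError("cluster_id must be non-empty")
        if self.n_hews < 0:
            raise ValidationError(f"cluster {self.cluster_id!r}: n_hews must be >= 0")
        if self.farthest_household_minutes < 0:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: farthest_household_minutes must be >= 0"
            )
        missing = set(FACILITATION_ITEMS) - set(self.facilitation_items)
        if missing:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: missing facilitation items {sorted(missing)}"
            )
        unknown = set(self.facilitation_items) - set(FACILITATION_ITEMS)
        if unknown:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: unknown facilitation items {sorted(unknown)}"
            )
        object.__setattr__(self, "facilitation_items", dict(self.facilitation_items))
        object.__setattr__(self, "supplies", dict(self.supplies))

    @property
    def supplies_score(self) -> int:
        return sum(bool(v) for v in self.supplies.values())


def facilitation_score(
    cluster: ClusterRecord, items: Sequence[str] | None = None
) -> int:
    """Count of implemented facilitation-strategy items.

    The default score counts all seven audited items (unweighted, one point
    each); ``items`` selects a subset.  The combined-model coefficient is
    therefore interpretable per additional implemented item.
    """
    chosen = FACILITATION_ITEMS if items is None else tuple(items)
    unknown = set(chosen) - set(FACILITATION_ITEMS)
    if unknown:
        raise ValidationError(f"unknown facilitation items: {sorted(unknown)}")
    return sum(bool(cluster.facilitation_items[name]) for name in chosen)


@dataclass
class CohortTable:
    """Validated women-in-clusters cohort."""

    women: list[WomanRecord] = field(default_factory=list)
    clusters: dict[str, ClusterRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.women:
            if w.woman_id in seen:
                raise ValidationError(f"duplicate woman_id {w.woman_id!r}")
            seen.add(w.woman_id)
            if w.cluster_id not in self.clusters:
                raise ReferentialIntegrityError(
                    f"woman {w.woman_id!r} references unknown cluster {w.cluster_id!r}"
                )
        for cid, c in self.clusters.items():
            if c.cluster_id != cid:
                raise ValidationError(
                    f"cluster key {cid!r} disagrees with record id {c.cluster_id!r}"
                )

    @property
    def n_women(self) -> int:
        return len(self.women)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def attenders(self) -> list[WomanRecord]:
        return [w for w in self.women if w.attended]


# ---------------------------------------------------------------------------
# Column dictionary and delimited-text I/O
# ---------------------------------------------------------------------------

def load_schema() -> dict:
    """The machine-readable column dictionary shipped with the package."""
    with resources.files(__package__).joinpath("schema.json").open("r") as fh:
        return json.load(fh)


_WOMEN_BASE_COLUMNS = (
    "woman_id",
    "cluster_id",
    "age_years",
    "n_visits",
    "provider",
    "tt_doses",
    "prior_pregnancy_problems",
    "partner_education",
    "maternal_education",
    "n_abortions",
    "walk_minutes_to_health_post",
    "first_visit_month",
)
# tt_adequate is derived from tt_doses, so the women file stores the other 16
# checklist indicators explicitly.
_CONTENT_COLUMNS = tuple(c for c in CONTENT_ITEMS if c != "tt_adequate")
WOMEN_COLUMNS: tuple[str, ...] = _WOMEN_BASE_COLUMNS + _CONTENT_COLUMNS

CLUSTER_BASE_COLUMNS = (
    "cluster_id",
    "n_hews",
    "farthest_household_minutes",
)
CLUSTER_COLUMNS: tuple[str, ...] = CLUSTER_BASE_COLUMNS + FACILITATION_ITEMS


def _parse_bool(token: str, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"cannot parse boolean from {token!r}", row=row, column=column)


def _parse_int(token: str, row: int, column: str) -> int:
    try:
        return int(token.strip())
    except ValueError:
        raise ParseError(f"cannot parse integer from {token!r}", row=row, column=column) from None


def _parse_float(token: str, row: int, column: str) -> float:
    try:
        return float(token.strip())
    except ValueError:
        raise ParseError(f"cannot parse number from {token!r}", row=row, column=column) from None


def _parse_enum(enum_cls, token: str, row: int, column: str):
    try:
        return enum_cls(token.strip().upper())
    except ValueError:
        valid = [e.value for e in enum_cls]
        raise ParseError(
            f"cannot parse {token!r}; expected one of {valid}", row=row, column=column
        ) from None


def _read_table(path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{label} file {path} missing columns {missing}")
    return df


def read_cohort(
    women_path,
    clusters_path,
    *,
    tt_threshold: int = DEFAULT_TT_THRESHOLD,
) -> CohortTable:
    """Read and validate a cohort from two CSV files.

    Boolean cells accept 0/1/yes/no/true/false case-insensitively; empty
    covariate cells are kept as explicit missing values (never imputed).
    Unknown columns are ignored with a logged warning.  Any malformed cell
    raises :class:`ParseError` naming its row and column; broken cluster
    references raise :class:`ReferentialIntegrityError`.
    """
    cdf = _read_table(clusters_path, CLUSTER_BASE_COLUMNS + FACILITATION_ITEMS, "clusters")
    known_cluster_cols = set(CLUSTER_COLUMNS)
    supply_cols = [c for c in cdf.columns if c.startswith("supply_")]
    extra = [c for c in cdf.columns if c not in known_cluster_cols and c not in supply_cols]
    if extra:
        logger.warning("clusters file: ignoring unknown columns %s", extra)

    clusters: dict[str, ClusterRecord] = {}
    for i, row in enumerate(cdf.itertuples(index=False)):
        vals = dict(zip(cdf.columns, row))
        cid = vals["cluster_id"].strip()
        rec = ClusterRecord(
            cluster_id=cid,
            n_hews=_parse_int(vals["n_hews"], i, "n_hews"),
            facilitation_items={
                name: _parse_bool(vals[name], i, name) for name in FACILITATION_ITEMS
            },
            supplies={
                c[len("supply_"):]: _parse_bool(vals[c], i, c) for c in supply_cols
            },
            farthest_household_minutes=_parse_float(
                vals["farthest_household_minutes"], i, "farthest_household_minutes"
            ),
        )
        if cid in clusters:
            raise ValidationError(f"duplicate cluster_id {cid!r}")
        clusters[cid] = rec

    wdf = _read_table(women_path, WOMEN_COLUMNS, "women")
    extra = [c for c in wdf.columns if c not in set(WOMEN_COLUMNS) | {"tt_adequate"}]
    if extra:
        logger.warning("women file: ignoring unknown columns %s", extra)

    women: list[WomanRecord] = []
    for i, row in enumerate(wdf.itertuples(index=False)):
        vals = dict(zip(wdf.columns, row))
        tt_doses = _parse_int(vals["tt_doses"], i, "tt_doses")
        flags = {name: _parse_bool(vals[name], i, name) for name in _CONTENT_COLUMNS}
        n_visits = _parse_int(vals["n_visits"], i, "n_visits")
        # tt_adequate is derived from the dose count; a non-attender's doses
        # are not ANC-delivered content, so the item stays false at 0 visits.
        flags["tt_adequate"] = n_visits > 0 and tt_adequate(tt_doses, tt_threshold)
        if "tt_adequate" in vals and vals["tt_adequate"].strip() != "":
            stored = _parse_bool(vals["tt_adequate"], i, "tt_adequate")
            if stored != flags["tt_adequate"]:
                raise ParseError(
                    f"stored tt_adequate={stored} disagrees with tt_doses={tt_doses} "
                    f"at threshold {tt_threshold}",
                    row=i,
                    column="tt_adequate",
                )

        def opt(column: str, parser):
            tok = vals[column]
            return None if tok.strip() == "" else parser(tok, i, column)

        try:
            rec = WomanRecord(
                woman_id=vals["woman_id"].strip(),
                cluster_id=vals["cluster_id"].strip(),
                n_visits=n_visits,
                contents=ContentChecklist.from_dict(flags),
                provider=_parse_enum(Provider, vals["provider"], i, "provider"),
                tt_doses=tt_doses,
                age_years=opt("age_years", _parse_float),
                prior_pregnancy_problems=opt("prior_pregnancy_problems", _parse_bool),
                partner_education=opt(
                    "partner_education", lambda t, r, c: _parse_enum(PartnerEducation, t, r, c)
                ),
                maternal_education=opt(
                    "maternal_education", lambda t, r, c: _parse_enum(MaternalEducation, t, r, c)
                ),
                n_abortions=opt("n_abortions", _parse_int),
                walk_minutes_to_health_post=opt("walk_minutes_to_health_post", _parse_float),
                first_visit_month=opt("first_visit_month", _parse_int),
            )
        except ValidationError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ValidationError(f"women file row {i}: {exc}") from exc
        women.append(rec)

    return CohortTable(women=women, clusters=clusters)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(cohort: CohortTable, women_path, clusters_path) -> None:
    """Write a cohort to two CSV files; inverse of :func:`read_cohort`."""
    wrows = []
    for w in cohort.women:
        row = {
            "woman_id": w.woman_id,
            "cluster_id": w.cluster_id,
            "age_years": w.age_years,
            "n_visits": w.n_visits,
            "provider": w.provider,
            "tt_doses": w.tt_doses,
            "prior_pregnancy_problems": w.prior_pregnancy_problems,
            "partner_education": w.partner_education,
            "maternal_education": w.maternal_education,
            "n_abortions": w.n_abortions,
            "walk_minutes_to_health_post": w.walk_minutes_to_health_post,
            "first_visit_month": w.first_visit_month,
        }
        row.update({name: getattr(w.contents, name) for name in _CONTENT_COLUMNS})
        wrows.append({k: _fmt(v) for k, v in row.items()})
    wdf = pd.DataFrame(wrows, columns=list(WOMEN_COLUMNS))
    wdf.to_csv(women_path, index=False)

    supply_names = sorted({name for c in cohort.clusters.values() for name in c.supplies})
    crows = []
    for cid in cohort.clusters:
        c = cohort.clusters[cid]
        row = {
            "cluster_id": c.cluster_id,
            "n_hews": c.n_hews,
            "farthest_household_minutes": c.farthest_household_minutes,
        }
        row.update({name: c.facilitation_items[name] for name in FACILITATION_ITEMS})
        row.update({f"supply_{name}": c.supplies.get(name, False) for name in supply_names})
        crows.append({k: _fmt(v) for k, v in row.items()})
    ccols = list(CLUSTER_COLUMNS) + [f"supply_{n}" for n in supply_names]
    cdf = pd.DataFrame(crows, columns=ccols)
    cdf.to_csv(clusters_path, index=False)
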