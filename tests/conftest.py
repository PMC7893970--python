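import numpy as np
import pytest

from fancfid.records import (
    CONTENT_ITEMS,
    FACILITATION_ITEMS,
    ClusterRecord,
    CohortTable,
    ContentChecklist,
    MaternalEducation,
    PartnerEducation,
    Provider,
    WomanRecord,
)


def make_checklist(n_true: int) -> ContentChecklist:
    """Checklist with the first n_true items delivered."""
    flags = {name: i < n_true for i, name in enumerate(CONTENT_ITEMS)}
    return ContentChecklist.from_dict(flags)


def make_woman(
    woman_id: str,
    cluster_id: str = "hp01",
    n_visits: int = 2,
    n_contents: int = 5,
    provider: Provider | None = None,
    **kwargs,
) -> WomanRecord:
    if n_visits == 0:
        n_contents = 0
        provider = Provider.NONE
    elif provider is None:
        provider = Provider.HEW
    contents = make_checklist(n_contents)
    tt_doses = 2 if contents.tt_adequate else 0
    defaults = dict(
        age_years=28.0,
        prior_pregnancy_problems=False,
        partner_education=PartnerEducation.NO_FORMAL,
        maternal_education=MaternalEducation.NO_FORMAL,
        n_abortions=0,
        walk_minutes_to_health_post=30.0,
        first_visit_month=4 if n_visits else None,
    )
    defaults.update(kwargs)
    return WomanRecord(
        woman_id=woman_id,
        cluster_id=cluster_id,
        n_visits=n_visits,
        contents=contents,
        provider=provider,
        tt_doses=tt_doses,
        **defaults,
    )


def make_cluster(cluster_id: str = "hp01", n_fac: int = 3) -> ClusterRecord:
    fac = {name: i < n_fac for i, name in enumerate(FACILITATION_ITEMS)}
    return ClusterRecord(
        cluster_id=cluster_id,
        n_hews=2,
        facilitation_items=fac,
        supplies={"bp_cuff": True, "stethoscope": False},
        farthest_household_minutes=120.0,
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Four women in two clusters: a non-attender, two HEW, one skilled."""
    clusters = {c.cluster_id: c for c in (make_cluster("hp01", 3), make_cluster("hp02", 5))}
    women = [
        make_woman("w1", "hp01", n_visits=0),
        make_woman("w2", "hp01", n_visits=2, n_contents=8),
        make_woman("w3", "hp02", n_visits=4, n_contents=17),
        make_woman("w4", "hp02", n_visits=3, n_contents=9, provider=Provider.SKILLED),
    ]
    return CohortTable(women=women, clusters=clusters)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
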