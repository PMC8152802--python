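import datetime as dt

import pytest

from aedes_diapause.core import EggRecord, EggStatus
from aedes_diapause.simulate import SimConfig, simulate_season


def make_record(
    egg_id="e1",
    week=30,
    year=2019,
    status=EggStatus.HATCHED,
    reps=None,
    trap="T01",
):
    """One egg record collected on the Sunday of the given ISO week."""
    date = dt.date.fromisocalendar(year, week, 7)
    lw = reps or ((), ())
    return EggRecord(
        egg_id=egg_id,
        site_id="test",
        trap_id=trap,
        collection_date=date,
        status=status,
        length_reps_um=tuple(lw[0]),
        width_reps_um=tuple(lw[1]),
    )


SMALL_CONFIG = SimConfig(
    seed=7,
    years=(2019,),
    peak1_height=300.0,
    peak2_height=120.0,
    base_intensity=5.0,
    morph_fraction=0.3,
)


@pytest.fixture(scope="session")
def small_season():
    """A one-year, ~4000-egg synthetic season shared across tests."""
    return simulate_season(SMALL_CONFIG)
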