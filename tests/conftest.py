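import pytest
from hypothesis import HealthCheck, settings

from urchin_repro import GsiSeries, PipelineConfig
from urchin_repro.gsi import GsiPoint

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_MONTHS = [f"2013-{m:02d}" for m in range(6, 13)] + [f"2014-{m:02d}" for m in range(1, 6)]


def make_series(months, means, zone="HP", size_class="CS"):
    points = {m: GsiPoint(mean=v, se=0.2, n=8) for m, v in zip(months, means)}
    return GsiSeries(zone=zone, size_class=size_class, points=points)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def hp_cs_series():
    """Single build-up to a March peak then decline to a May trough."""
    months = [m for m in STUDY_MONTHS if m != "2013-11"]
    means = [5.5, 5.6, 5.8, 5.9, 6.0, 6.2, 6.3, 6.4, 6.6, 4.1, 1.6]
    return make_series(months, means)


@pytest.fixture
def lp_cs_series():
    """Two declines: June peak to December trough, February peak to April."""
    months = [m for m in STUDY_MONTHS if m != "2013-11"]
    means = [6.7, 6.0, 5.3, 4.6, 3.9, 2.5, 3.2, 5.4, 4.5, 2.5, 2.6]
    return make_series(months, means, zone="LP")
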