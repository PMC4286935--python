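import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from proteoring.formats import (  # noqa: E402
    ColorScheme,
    Experiment,
    ExperimentRecord,
    ProteinEntry,
    ProteinSet,
    Reference,
)


def make_reference(sets: dict[str, list[str]]) -> Reference:
    """Reference from {set name: [protein ids]} preserving insertion order."""
    return Reference(
        sets=[
            ProteinSet(name, [ProteinEntry("", pid, "") for pid in pids])
            for name, pids in sets.items()
        ]
    )


def make_experiment(bait: str, rows: list[tuple[str, str]]) -> Experiment:
    """Experiment from (arc_class, prey_id) rows."""
    return Experiment(bait, [ExperimentRecord(bait, cls, prey) for cls, prey in rows])


@pytest.fixture
def small_reference() -> Reference:
    return make_reference({"A": ["P1", "P2"], "B": ["P1"]})


@pytest.fixture
def rgb_scheme() -> ColorScheme:
    return ColorScheme([(255, 0, 0), (0, 0, 255)])
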