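import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def engine_factory(tmp_path):
    """Engines with a deterministic manual clock and a temp log dir."""
    from vge.farm import ManualClock
    from vge.master import Engine, EngineConfig

    def make(worker_count=4, **cfg_kwargs):
        cfg_kwargs.setdefault("log_dir", str(tmp_path / "logs"))
        clock = ManualClock()
        engine = Engine(
            EngineConfig(worker_count=worker_count, **cfg_kwargs), clock=clock
        )
        return engine, clock

    return make
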