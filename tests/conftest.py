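import numpy as np
import pytest
from hypothesis import settings

import wristpa as w

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_config():
    return w.StudyConfig()


#: generator settings for a deliberately small test study: one day with a
#: four-hour waking window, a guaranteed long non-wear gap and a dropout
SMALL_PLAN_KWARGS = dict(
    days=1,
    waking=(480, 700),
    p_nonwear_day=1.0,
    nonwear_dur=(90, 95),
    p_dropout_day=1.0,
    dropout_dur=(10, 20),
)


@pytest.fixture(scope="session")
def small_week_plan():
    return w.random_week_plan(seed=7, **SMALL_PLAN_KWARGS)


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """A two-participant synthetic study on disk (small plan)."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = w.SimConfig(seed=11)
    manifest = w.write_fixture_study(outdir, 2, cfg, plan_kwargs=SMALL_PLAN_KWARGS)
    return outdir, manifest


def gravity_stream(
    duration_s: int,
    fs: float = 100.0,
    g_dir=(0.0, 0.0, 1.0),
    device_id: str = "dev",
    start=np.datetime64("2021-03-01T00:00:00.000"),
) -> w.RawAccelStream:
    """A perfectly still stream resting along ``g_dir``."""
    n = round(duration_s * fs)
    data = np.tile(np.asarray(g_dir, dtype=float), (n, 1))
    return w.RawAccelStream(device_id, fs, [w.Segment(np.datetime64(start, "ms"), data)])
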