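import numpy as np
import pytest

import dndmotion as dm


@pytest.fixture(scope="session")
def clean_itug():
    return dm.generate_itug(noise=dm.NoiseModel.none())


@pytest.fixture(scope="session")
def noisy_itug():
    return dm.generate_itug(noise=dm.NoiseModel.table_defaults(), seed=11)


@pytest.fixture(scope="session")
def clean_walk():
    return dm.generate_t10m(
        dm.GaitProfile(cadence_spm=120.0, speed_mps=1.0), dm.NoiseModel.none()
    )


@pytest.fixture(scope="session")
def noisy_walk():
    return dm.generate_t10m(
        dm.GaitProfile(cadence_spm=120.0, speed_mps=1.0),
        dm.NoiseModel.table_defaults(),
        seed=11,
    )


def plant_sentinel(session):
    """Overwrite one raw sample with a distinctive mid-range value.

    Returns (marked_session, needle): the needle is the value's exact
    repr, searched for in serialised payloads.  Mid-range because a
    summary's min/max legitimately reveal extremal samples — the scan
    must flag raw retention, not the extrema a summary is allowed to
    publish.
    """
    marked = session.copy()
    az = marked.accel[:, 2]
    value = float((az.min() + az.max()) / 2.0)
    marked.accel[123, 2] = value
    return marked, repr(value)


@pytest.fixture
def marked_session(noisy_itug):
    """A session carrying a sentinel raw value, plus the scan needle."""
    session, _ = noisy_itug
    return plant_sentinel(session)


def summaries_close(a, b, rtol=1e-9):
    """Field-by-field comparison of two running summaries."""
    assert a.n == b.n
    for f in ("min_v", "max_v", "mean", "sample_sd", "sample_skewness"):
        x, y = getattr(a, f), getattr(b, f)
        if x is None or y is None:
            assert x == y, (f, x, y)
        else:
            assert x == pytest.approx(y, rel=rtol, abs=rtol), (f, x, y)


@pytest.fixture(scope="session")
def summary_compare():
    return summaries_close
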