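import pytest

from mibdyn import EventLog, EventRecord, ObserverProfile


def make_log(records, *, observer="obsA", trial="trial1", condition="cond",
             trial_duration=120.0):
    """Build an EventLog from (key, action, time) tuples."""
    recs = [
        EventRecord(observer, trial, condition, key, action, time)
        for key, action, time in records
    ]
    return EventLog(
        observer_id=observer,
        trial_id=trial,
        condition=condition,
        trial_duration=trial_duration,
        records=recs,
    )


@pytest.fixture
def zero_noise_observer():
    return ObserverProfile(
        "obsZ",
        latency_mean_press=0.0,
        latency_sd_press=0.0,
        latency_mean_release=0.0,
        latency_sd_release=0.0,
        seed=1,
    )


@pytest.fixture
def noisy_observer():
    return ObserverProfile(
        "obsN",
        latency_mean_press=0.35,
        latency_sd_press=0.05,
        latency_mean_release=0.35,
        latency_sd_release=0.05,
        seed=2,
    )
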