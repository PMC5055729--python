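from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, settings

from eventscan.models import EventClass, KeywordGroup, Tweet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_tweet(
    id: str = "t1",
    text: str = "hello world",
    day: date = date(2014, 5, 1),
    seconds: int = 0,
    user_id: str | None = None,
    lat: float = 53.48,
    lon: float = -2.24,
    is_retweet: bool = False,
) -> Tweet:
    return Tweet(
        id=id,
        timestamp=datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
        + timedelta(seconds=seconds),
        user_id=user_id if user_id is not None else f"user-{id}",
        lat=lat,
        lon=lon,
        text=text,
        is_retweet=is_retweet,
    )


@pytest.fixture
def symptom_groups() -> list[KeywordGroup]:
    return [
        KeywordGroup("vomit", ("throwing up", "being sick"), EventClass.SYMPTOM),
        KeywordGroup("sore throat", ("throat hurts",), EventClass.SYMPTOM),
        KeywordGroup("cough", ("coughing",), EventClass.SYMPTOM),
        KeywordGroup("flu", ("influenza",), EventClass.SYMPTOM),
    ]
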