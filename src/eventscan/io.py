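"""Reading and writing the pipeline's file formats.

Tweet streams and news corpora are JSON Lines; keyword groups are YAML or
JSON; cluster models, alarms and summaries are JSON.  Malformed records are
skipped (never fatal) and counted in a log summary, which is the pragmatic
contract for streaming social-media data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .models import (
    EventClass,
    KeywordGroup,
    NewsArticle,
    Tweet,
    validate_keyword_groups,
)

logger = logging.getLogger(__name__)

_DEFAULT_GROUPS_PATH = Path(__file__).parent / "data" / "keyword_groups.yaml"

# created_at format of the public Twitter API dialect
_TWITTER_TIME_FORMAT = "%a %b %d %H:%M:%S %z %Y"


@dataclass
class ReadReport:
    """Counts of records accepted and skipped while reading a JSON Lines file."""

    read: int = 0
    skipped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def _parse_timestamp(value: object) -> datetime:
    if isinstance(value, (int, float)):
        return datetime.fromtimestamp(value, tz=timezone.utc)
    if isinstance(value, str):
        try:
            ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
        except ValueError:
            ts = datetime.strptime(value, _TWITTER_TIME_FORMAT)
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        return ts.astimezone(timezone.utc)
    raise ValueError(f"unparseable timestamp: {value!r}")


def _tweet_from_record(obj: dict) -> Tweet:
    """Build a Tweet from either the flat internal schema or the public API dialect."""
    if "id_str" in obj or "created_at" in obj:
        coords = (obj.get("coordinates") or {}).get("coordinates")
        if not coords:
            raise KeyError("coordinates")
        lon, lat = coords  # GeoJSON ordering is [lon, lat]
        return Tweet(
            id=str(obj.get("id_str") or obj["id"]),
            timestamp=_parse_timestamp(obj["created_at"]),
            user_id=str(obj["user"]["id_str"]),
            lat=float(lat),
            lon=float(lon),
            text=obj["text"],
            is_retweet="retweeted_status" in obj or bool(obj.get("is_retweet")),
        )
    return Tweet(
        id=str(obj["id"]),
        timestamp=_parse_timestamp(obj["timestamp"]),
        user_id=str(obj["user_id"]),
        lat=float(obj["lat"]),
        lon=float(obj["lon"]),
        text=obj["text"],
        is_retweet=bool(obj.get("is_retweet", False)),
    )


def read_tweets(
    path: str | Path,
    drop_retweets: bool = True,
    report: ReadReport | None = None,
) -> list[Tweet]:
    """Read a JSON Lines tweet stream, sorted by timestamp.

    Accepts the flat internal schema (id, timestamp, user_id, lat, lon, text,
    is_retweet) and the public Twitter API dialect (id_str, created_at,
    user.id_str, coordinates.coordinates as [lon, lat], text).  Malformed
    lines and lines without coordinates are skipped and counted.
    """
    report = report if report is not None else ReadReport()
    tweets: list[Tweet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                report.skip("malformed_json")
                continue
            try:
                tweet = _tweet_from_record(obj)
            except (KeyError, TypeError, ValueError):
                report.skip("invalid_record")
                continue
            if drop_retweets and tweet.is_retweet:
                continue
            tweets.append(tweet)
            report.read += 1
    if report.skipped:
        logger.warning(
            "skipped %d malformed tweet lines (%s)", report.skipped, report.reasons
        )
    tweets.sort(key=lambda t: (t.timestamp, t.id))
    return tweets


def write_tweets(path: str | Path, tweets: Iterable[Tweet]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "id": t.id,
                        "timestamp": t.timestamp.isoformat(),
                        "user_id": t.user_id,
                        "lat": t.lat,
                        "lon": t.lon,
                        "text": t.text,
                        "is_retweet": t.is_retweet,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_keyword_groups(path: str | Path | None = None) -> list[KeywordGroup]:
    """Load keyword groups from YAML/JSON; packaged defaults when path is None.

    The file maps event classes (``symptom``/``emotion``) to mappings of
    primary keyword -> alias list.  Strings are lowercased and
    whitespace-normalised; duplicate primary keywords within a class are a
    fatal validation error.
    """
    src = Path(path) if path is not None else _DEFAULT_GROUPS_PATH
    with open(src, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("keyword group config must map event classes to groups")
    groups: list[KeywordGroup] = []
    seen: set[tuple[str, str]] = set()
    for cls_name, mapping in raw.items():
        cls = EventClass(cls_name)
        if mapping is None:
            continue
        for primary, aliases in mapping.items():
            primary_norm = " ".join(str(primary).lower().split())
            key = (cls.value, primary_norm)
            if key in seen:
                raise ValueError(
                    f"duplicate primary keyword {primary_norm!r} in class {cls.value!r}"
                )
            seen.add(key)
            groups.append(
                KeywordGroup(
                    primary_keyword=primary_norm,
                    aliases=tuple(str(a) for a in (aliases or [])),
                    event_class=cls,
                )
            )
    return validate_keyword_groups(groups)


def read_news_corpus(
    path: str | Path, report: ReadReport | None = None
) -> list[NewsArticle]:
    """Read a JSON Lines news corpus; records missing title or date are skipped."""
    report = report if report is not None else ReadReport()
    articles: list[NewsArticle] = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                report.skip("malformed_json")
                continue
            title = obj.get("title")
            raw_date = obj.get("date")
            if not title or not raw_date:
                report.skip("missing_title_or_date")
                continue
            try:
                day = date.fromisoformat(str(raw_date)[:10])
            except ValueError:
                report.skip("bad_date")
                continue
            articles.append(
                NewsArticle(
                    article_id=str(obj.get("article_id", obj.get("id", i))),
                    title=title,
                    body=obj.get("body", ""),
                    date=day,
                    source=obj.get("source", ""),
                    url=obj.get("url", ""),
                )
            )
    if report.skipped:
        logger.warning(
            "skipped %d malformed news lines (%s)", report.skipped, report.reasons
        )
    return articles


def write_news_corpus(path: str | Path, articles: Iterable[NewsArticle]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {
                        "article_id": a.article_id,
                        "title": a.title,
                        "body": a.body,
                        "date": a.date.isoformat(),
                        "source": a.source,
                        "url": a.url,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_event_report(path: str | Path, rows: Sequence[dict]) -> None:
    """TSV event report: one row per alarm with its decision."""
    columns = [
        "alarm_id",
        "group_id",
        "cluster_id",
        "start_date",
        "end_date",
        "mu_max",
        "tweet_user_ratio",
        "status",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
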