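"""Record types, file formats and run configuration.

Everything that crosses a process boundary lives here: day-stamped posts,
news/tweet streams and daily case counts (JSONL / CSV), the hedge-annotated
training corpus (JSONL or BIO-TSV), and the :class:`RunConfig` that is
serialized next to every run's outputs.  No numerical modelling happens in
this module.

Timestamps are held internally as seconds since the Unix epoch (UTC); day
identity throughout the package is the UTC calendar date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

UTC = dt.timezone.utc
SECONDS_PER_DAY = 86400


# ---------------------------------------------------------------------------
# timestamp helpers
# ---------------------------------------------------------------------------

def parse_timestamp(value: str | int | float) -> float:
    """Normalize a timestamp to float seconds since epoch, UTC.

    Accepts epoch numbers or ISO-8601 strings (a trailing ``Z`` is
    understood); naive datetimes are interpreted as UTC.
    """
    if isinstance(value, (int, float)):
        ts = float(value)
        if not (ts == ts and abs(ts) < 1e15):  # NaN / absurd values
            raise ValueError(f"unparseable timestamp: {value!r}")
        return ts
    if isinstance(value, str):
        text = value.strip().replace("Z", "+00:00")
        try:
            parsed = dt.datetime.fromisoformat(text)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp: {value!r}") from exc
        if parsed.tzinfo is None:
            parsed = parsed.replace(tzinfo=UTC)
        return parsed.timestamp()
    raise ValueError(f"unparseable timestamp: {value!r}")


def format_timestamp(ts: float) -> str:
    return dt.datetime.fromtimestamp(ts, tz=UTC).strftime("%Y-%m-%dT%H:%M:%SZ")


def timestamp_to_date(ts: float) -> dt.date:
    """UTC calendar date a timestamp falls on."""
    return dt.datetime.fromtimestamp(ts, tz=UTC).date()


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class PostRecord:
    """One social-media post with optional veracity / spread annotations.

    ``veracity_label``: real = 0, fake = 1.  ``spread_label``: low = 0
    (never retweeted), high = 1 (retweeted at least once).
    """

    id: str
    text: str
    created_time: float
    retweet_count: int | None = None
    veracity_label: int | None = None
    spread_label: int | None = None

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError(f"post {self.id!r}: empty text")
        if self.retweet_count is not None and self.retweet_count < 0:
            raise ValueError(f"post {self.id!r}: negative retweet_count")
        for name in ("veracity_label", "spread_label"):
            val = getattr(self, name)
            if val is not None and val not in (0, 1):
                raise ValueError(f"post {self.id!r}: {name} must be 0 or 1")
        if self.retweet_count is not None and self.spread_label is not None:
            if self.spread_label != int(self.retweet_count > 0):
                raise ValueError(
                    f"post {self.id!r}: spread_label inconsistent with retweet_count"
                )


@dataclass
class DocumentRecord:
    """A news item or ambient tweet forming part of an information environment."""

    id: str
    text: str
    created_time: float
    source_kind: str = "news"

    def __post_init__(self) -> None:
        if self.source_kind not in ("news", "tweet"):
            raise ValueError(f"document {self.id!r}: bad source_kind {self.source_kind!r}")


@dataclass
class CaseDayRecord:
    """Daily new-case count and daily news volume for one UTC calendar date."""

    date: dt.date
    n_cases: int
    n_news: int

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_news < 0:
            raise ValueError(f"{self.date}: negative count")


@dataclass
class HedgeSentence:
    """A sentence with token-level hedge-cue flags and a sentence-level flag.

    ``cue_flags[i] == 1`` marks token *i* as an uncertainty marker; a sentence
    containing any cue must carry ``uncertain == 1``.
    """

    tokens: list[str]
    lemmas: list[str]
    cue_flags: list[int]
    uncertain: int

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.lemmas) == len(self.cue_flags)):
            raise ValueError("tokens, lemmas and cue_flags must have equal length")
        if any(flag not in (0, 1) for flag in self.cue_flags):
            raise ValueError("cue_flags must be 0/1")
        if self.uncertain not in (0, 1):
            raise ValueError("uncertain must be 0/1")
        if any(self.cue_flags) and self.uncertain != 1:
            raise ValueError("sentence with a cue must be flagged uncertain")


@dataclass
class RunConfig:
    """All knobs of a run; serialized alongside outputs for reproducibility."""

    T: int = 3                     # environment window length, days
    r: float = 0.1                 # micro-environment extraction fraction
    c_min: int = 10                # floor on the micro-environment size
    hidden_dim: int = 32           # common channel dimension h
    embed_dim: int = 256           # text embedding dimension d
    baseline_dim: int = 64         # baseline feature dimension d_o
    confidence_lambda: float = 0.1
    encoder: str = "hashing"
    seed: int = 0
    learning_rate: float = 5e-4
    epochs: int = 150
    batch_size: int = 32
    patience: int = 15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not 0 < self.r < 1:
            raise ValueError("r must lie in (0,1)")
        if self.c_min <= 0:
            raise ValueError("c_min must be positive")
        if not 0 < self.confidence_lambda < 1:
            raise ValueError("confidence_lambda must lie in (0,1)")
        for name in ("hidden_dim", "embed_dim", "baseline_dim", "epochs", "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(str(source))
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in known})


# ---------------------------------------------------------------------------
# JSONL plumbing
# ---------------------------------------------------------------------------

def _iter_jsonl(path: str | Path) -> Iterable[tuple[int, dict]]:
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"{path}:{lineno}: expected a JSON object")
            yield lineno, obj


def _write_jsonl(path: str | Path, rows: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for row in rows:
            handle.write(json.dumps(row, sort_keys=True) + "\n")


def read_posts(path: str | Path, derive_spread_labels: bool = False) -> list[PostRecord]:
    """Read posts from JSONL, in file order.

    With ``derive_spread_labels`` the spread label is filled in from the
    retweet count (low = 0 retweets, high = at least one) for records that do
    not already carry one; precomputed labels are never overwritten.
    """
    records: list[PostRecord] = []
    seen: set[str] = set()
    for lineno, obj in _iter_jsonl(path):
        try:
            retweets = obj.get("retweet_count")
            spread = obj.get("spread_label")
            if spread is None and derive_spread_labels and retweets is not None:
                spread = int(int(retweets) > 0)
            record = PostRecord(
                id=str(obj["id"]),
                text=str(obj["text"]),
                created_time=parse_timestamp(obj["created_time"]),
                retweet_count=None if retweets is None else int(retweets),
                veracity_label=None if obj.get("veracity_label") is None else int(obj["veracity_label"]),
                spread_label=None if spread is None else int(spread),
            )
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing field {exc}") from exc
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if record.id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate post id {record.id!r}")
        seen.add(record.id)
        records.append(record)
    return records


def write_posts(path: str | Path, posts: Sequence[PostRecord]) -> None:
    def row(p: PostRecord) -> dict:
        out: dict = {"id": p.id, "text": p.text, "created_time": format_timestamp(p.created_time)}
        if p.retweet_count is not None:
            out["retweet_count"] = p.retweet_count
        if p.veracity_label is not None:
            out["veracity_label"] = p.veracity_label
        if p.spread_label is not None:
            out["spread_label"] = p.spread_label
        return out

    _write_jsonl(path, (row(p) for p in posts))


def read_documents(path: str | Path, source_kind: str | None = None) -> list[DocumentRecord]:
    """Read a news or tweet stream from JSONL."""
    records: list[DocumentRecord] = []
    seen: set[str] = set()
    for lineno, obj in _iter_jsonl(path):
        try:
            record = DocumentRecord(
                id=str(obj["id"]),
                text=str(obj["text"]),
                created_time=parse_timestamp(obj["created_time"]),
                source_kind=source_kind or obj.get("source_kind", "news"),
            )
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing field {exc}") from exc
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if record.id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate document id {record.id!r}")
        seen.add(record.id)
        records.append(record)
    return records


def write_documents(path: str | Path, docs: Sequence[DocumentRecord]) -> None:
    _write_jsonl(
        path,
        (
            {
                "id": d.id,
                "text": d.text,
                "created_time": format_timestamp(d.created_time),
                "source_kind": d.source_kind,
            }
            for d in docs
        ),
    )


# ---------------------------------------------------------------------------
# case series (CSV)
# ---------------------------------------------------------------------------

def read_case_series(path: str | Path, zero_fill: bool = False) -> list[CaseDayRecord]:
    """Read ``date,n_cases,n_news`` CSV, sorted ascending by date.

    Interior gaps are an error unless ``zero_fill`` inserts explicit
    zero-count days.
    """
    rows: list[CaseDayRecord] = []
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().strip().split(",")
        if header[:3] != ["date", "n_cases", "n_news"]:
            raise ValueError(f"{path}: expected header date,n_cases,n_news")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                rows.append(
                    CaseDayRecord(dt.date.fromisoformat(parts[0]), int(parts[1]), int(parts[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    rows.sort(key=lambda r: r.date)
    for a, b in zip(rows, rows[1:]):
        if a.date == b.date:
            raise ValueError(f"{path}: duplicate date {a.date}")
    if not rows:
        return rows
    filled: list[CaseDayRecord] = [rows[0]]
    for record in rows[1:]:
        gap = (record.date - filled[-1].date).days
        if gap > 1:
            if not zero_fill:
                raise ValueError(
                    f"{path}: gap between {filled[-1].date} and {record.date}"
                    " (pass zero_fill=True to insert zero-count days)"
                )
            for offset in range(1, gap):
                filled.append(CaseDayRecord(filled[-1].date + dt.timedelta(days=1), 0, 0))
        filled.append(record)
    return filled


def write_case_series(path: str | Path, series: Sequence[CaseDayRecord]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("date,n_cases,n_news\n")
        for record in series:
            handle.write(f"{record.date.isoformat()},{record.n_cases},{record.n_news}\n")


# ---------------------------------------------------------------------------
# hedge corpus (JSONL + BIO-TSV)
# ---------------------------------------------------------------------------

def read_hedge_corpus(path: str | Path, fmt: str | None = None) -> list[HedgeSentence]:
    """Read a hedge-annotated corpus (``jsonl`` or ``bio_tsv``).

    The format is inferred from the suffix when not given (.tsv -> BIO-TSV).
    """
    path = Path(path)
    if fmt is None:
        fmt = "bio_tsv" if path.suffix.lower() in (".tsv", ".bio") else "jsonl"
    if fmt == "jsonl":
        sentences = []
        for lineno, obj in _iter_jsonl(path):
            try:
                sentences.append(
                    HedgeSentence(
                        tokens=[str(t) for t in obj["tokens"]],
                        lemmas=[str(t) for t in obj["lemmas"]],
                        cue_flags=[int(f) for f in obj["cue_flags"]],
                        uncertain=int(obj["uncertain"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return sentences
    if fmt == "bio_tsv":
        return _read_bio_tsv(path)
    raise ValueError(f"unknown hedge corpus format {fmt!r}")


def _read_bio_tsv(path: Path) -> list[HedgeSentence]:
    """BIO-TSV dialect: ``#uncertain {0,1}`` header per sentence, then
    ``token<TAB>lemma<TAB>{B,I,O}`` lines, blank line between sentences."""
    sentences: list[HedgeSentence] = []
    tokens: list[str] = []
    lemmas: list[str] = []
    flags: list[int] = []
    uncertain: int | None = None

    def flush(lineno: int) -> None:
        nonlocal tokens, lemmas, flags, uncertain
        if not tokens and uncertain is None:
            return
        if uncertain is None:
            raise ValueError(f"{path}:{lineno}: sentence without #uncertain header")
        try:
            sentences.append(HedgeSentence(tokens, lemmas, flags, uncertain))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        tokens, lemmas, flags, uncertain = [], [], [], None

    with open(path, "r", encoding="utf-8") as handle:
        lineno = 0
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if line.startswith("#uncertain"):
                uncertain = int(line.split()[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("B", "I", "O"):
                raise ValueError(f"{path}:{lineno}: expected token<TAB>lemma<TAB>{{B,I,O}}")
            tokens.append(parts[0])
            lemmas.append(parts[1])
            flags.append(0 if parts[2] == "O" else 1)
        flush(lineno + 1)
    return sentences


def write_hedge_corpus(path: str | Path, corpus: Sequence[HedgeSentence]) -> None:
    _write_jsonl(
        path,
        (
            {
                "tokens": s.tokens,
                "lemmas": s.lemmas,
                "cue_flags": s.cue_flags,
                "uncertain": s.uncertain,
            }
            for s in corpus
        ),
    )


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(
    path: str | Path,
    ids: Sequence[str],
    task: str,
    probabilities,  # (n, 2) array-like
) -> None:
    """Write per-post class probabilities as JSONL, one object per post."""
    rows = []
    for post_id, (p0, p1) in zip(ids, probabilities):
        rows.append(
            {
                "id": post_id,
                "task": task,
                "p_class0": float(p0),
                "p_class1": float(p1),
                "predicted_label": int(p1 > p0),
            }
        )
    _write_jsonl(path, rows)


def read_predictions(path: str | Path) -> list[dict]:
    return [obj for _, obj in _iter_jsonl(path)]
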