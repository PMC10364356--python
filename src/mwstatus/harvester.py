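"""Enumerate and retrieve analysis files from a REST interface or a directory.

The harvester walks the repository's two-level Study -> Analysis hierarchy,
retrieving each analysis in both the plain-text and JSON formats.  It is
deliberately polite and total:

* consecutive REST requests are spaced by ``request_delay`` seconds
  (default 1 s) to minimize load on the repository's servers;
* transient transport failures are retried, and persistent ones degrade the
  file to ABSENT rather than aborting the run — the "Missing" status
  category absorbs them;
* a zero-byte response is RETRIEVED, not ABSENT: blank files must flow to
  the parser so a validation log can still be produced for them.

The HTTP layer is injectable (any object with ``get(url) -> (status, bytes)``)
so the whole pipeline is testable without a network; time sources are
injectable for the same reason.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator

from .model import ANALYSIS_ID_PATTERN, STUDY_ID_PATTERN, FetchOutcome, SourceFormat

logger = logging.getLogger(__name__)

#: default URL templates, matching the public Metabolomics Workbench REST
#: interface; overridable per source for mirrors and mock servers.
DEFAULT_LISTING_PATH = "/rest/study/study_id/ST/available"
DEFAULT_FILE_PATH = "/rest/study/analysis_id/{analysis_id}/mwtab/{fmt}"

MANIFEST_FILENAME = "manifest.json"


class SourceKind(str, Enum):
    REST = "rest"
    LOCAL_DIR = "local_dir"


class HarvestError(RuntimeError):
    """Fatal harvest problem: unreachable source or unwritable sink."""


@dataclass
class SourceConfig:
    """Where and how to harvest.

    ``location`` is a base URL for REST sources or a root path for local
    directories.  ``request_delay`` applies to REST requests only.
    """

    kind: SourceKind
    location: str
    request_delay: float = 1.0
    timeout: float = 30.0
    retries: int = 2
    listing_path: str = DEFAULT_LISTING_PATH
    file_path: str = DEFAULT_FILE_PATH

    def __post_init__(self) -> None:
        if self.request_delay < 0:
            raise ValueError("request_delay must be >= 0")
        if self.retries < 0:
            raise ValueError("retries must be >= 0")

    @classmethod
    def for_url(cls, base_url: str, **kwargs) -> "SourceConfig":
        return cls(kind=SourceKind.REST, location=base_url.rstrip("/"), **kwargs)

    @classmethod
    def for_directory(cls, root: str | Path, **kwargs) -> "SourceConfig":
        return cls(kind=SourceKind.LOCAL_DIR, location=str(root), **kwargs)


@dataclass
class FetchResult:
    analysis_id: str
    format: SourceFormat
    outcome: FetchOutcome
    content: bytes | None = None

    def __post_init__(self) -> None:
        if (self.outcome is FetchOutcome.RETRIEVED) != (self.content is not None):
            raise ValueError("content present iff outcome is RETRIEVED")


class UrllibTransport:
    """Minimal HTTP GET transport over the standard library."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def get(self, url: str) -> tuple[int, bytes]:
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.status, resp.read()
        except urllib.error.HTTPError as exc:
            return exc.code, b""


class RateLimiter:
    """Enforces a minimum spacing between consecutive calls to wait()."""

    def __init__(
        self,
        delay: float,
        monotonic: Callable[[], float] = time.monotonic,
        sleep: Callable[[float], None] = time.sleep,
    ):
        self.delay = delay
        self._monotonic = monotonic
        self._sleep = sleep
        self._last: float | None = None

    def wait(self) -> None:
        if self.delay > 0 and self._last is not None:
            remaining = self._last + self.delay - self._monotonic()
            if remaining > 0:
                self._sleep(remaining)
        self._last = self._monotonic()


def _local_manifest_inventory(root: Path) -> dict[str, list[str]] | None:
    manifest_path = root / MANIFEST_FILENAME
    if not manifest_path.is_file():
        return None
    data = json.loads(manifest_path.read_text(encoding="utf-8"))
    mapping: dict[str, list[str]] = {}
    for analysis_id, entry in data.get("analyses", {}).items():
        mapping.setdefault(entry["study_id"], []).append(analysis_id)
    return mapping


def _scan_directory(root: Path) -> dict[str, list[str]]:
    mapping: dict[str, set[str]] = {}
    for study_dir in root.iterdir():
        if not study_dir.is_dir():
            continue
        if not STUDY_ID_PATTERN.match(study_dir.name):
            logger.warning("skipping non-study directory %s", study_dir.name)
            continue
        for path in study_dir.iterdir():
            if path.suffix not in (".txt", ".json"):
                continue
            if not ANALYSIS_ID_PATTERN.match(path.stem):
                logger.warning("skipping malformed file name %s", path.name)
                continue
            mapping.setdefault(study_dir.name, set()).add(path.stem)
    return {st: sorted(ans) for st, ans in mapping.items()}


def list_study_analyses(source: SourceConfig, transport=None) -> dict[str, list[str]]:
    """Complete study -> analyses map, lexicographically ordered.

    For a local directory the corpus manifest (when present) is the listing
    authority — it can list analyses whose files are absent, just as the
    REST listing can name analyses that then 404.  Without a manifest the
    directory tree is scanned.
    """
    if source.kind is SourceKind.LOCAL_DIR:
        root = Path(source.location)
        if not root.is_dir():
            raise HarvestError(f"source directory {root} does not exist")
        mapping = _local_manifest_inventory(root)
        if mapping is None:
            mapping = _scan_directory(root)
    else:
        transport = transport or UrllibTransport(source.timeout)
        url = source.location + source.listing_path
        status, body = transport.get(url)
        if status != 200:
            raise HarvestError(f"listing endpoint {url} returned HTTP {status}")
        try:
            entries = json.loads(body.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise HarvestError(f"unreadable listing from {url}: {exc}") from exc
        mapping = {}
        if isinstance(entries, dict):
            entries = list(entries.values())
        for entry in entries:
            try:
                study_id = entry["study_id"]
                analysis_id = entry["analysis_id"]
            except (TypeError, KeyError):
                logger.warning("skipping malformed listing entry %r", entry)
                continue
            if not (
                STUDY_ID_PATTERN.match(study_id)
                and ANALYSIS_ID_PATTERN.match(analysis_id)
            ):
                logger.warning("skipping ill-formed ids %r/%r", study_id, analysis_id)
                continue
            mapping.setdefault(study_id, []).append(analysis_id)

    out: dict[str, list[str]] = {}
    seen: set[str] = set()
    for study_id in sorted(mapping):
        unique = sorted(a for a in set(mapping[study_id]) if a not in seen)
        seen.update(unique)
        out[study_id] = unique
    return out


def fetch_analysis(
    source: SourceConfig,
    analysis_id: str,
    fmt: SourceFormat,
    transport=None,
    limiter: RateLimiter | None = None,
    study_id: str | None = None,
) -> FetchResult:
    """Retrieve one analysis file: exact bytes, or ABSENT on 404/no file."""
    if not ANALYSIS_ID_PATTERN.match(analysis_id):
        raise ValueError(f"malformed analysis id {analysis_id!r}")
    if source.kind is SourceKind.LOCAL_DIR:
        root = Path(source.location)
        candidates = (
            [root / study_id / f"{analysis_id}.{fmt.value}"]
            if study_id
            else sorted(root.glob(f"*/{analysis_id}.{fmt.value}"))
            + [root / f"{analysis_id}.{fmt.value}"]
        )
        for path in candidates:
            if path.is_file():
                return FetchResult(
                    analysis_id, fmt, FetchOutcome.RETRIEVED, path.read_bytes()
                )
        return FetchResult(analysis_id, fmt, FetchOutcome.ABSENT)

    transport = transport or UrllibTransport(source.timeout)
    url = source.location + source.file_path.format(
        analysis_id=analysis_id, fmt=fmt.value
    )
    for attempt in range(source.retries + 1):
        if limiter is not None:
            limiter.wait()
        try:
            status, body = transport.get(url)
        except Exception as exc:  # noqa: BLE001 - degrade, never abort the run
            logger.warning(
                "transport failure for %s (attempt %d/%d): %s",
                url,
                attempt + 1,
                source.retries + 1,
                exc,
            )
            continue
        if status == 200:
            return FetchResult(analysis_id, fmt, FetchOutcome.RETRIEVED, body)
        if status == 404:
            return FetchResult(analysis_id, fmt, FetchOutcome.ABSENT)
        logger.warning("HTTP %d for %s (attempt %d)", status, url, attempt + 1)
    logger.warning("giving up on %s after %d attempts", url, source.retries + 1)
    return FetchResult(analysis_id, fmt, FetchOutcome.ABSENT)


def harvest(
    source: SourceConfig,
    sink: str | Path | None = None,
    transport=None,
    limiter: RateLimiter | None = None,
) -> Iterator[tuple[str, str, dict[SourceFormat, FetchResult]]]:
    """Yield (study_id, analysis_id, per-format results) in deterministic order.

    When ``sink`` is a directory, retrieved raw files are persisted there as
    ``<STUDY_ID>/<ANALYSIS_ID>.txt`` / ``.json``; otherwise content lives
    only in memory and is discarded after downstream processing.
    """
    if limiter is None and source.kind is SourceKind.REST:
        limiter = RateLimiter(source.request_delay)
    sink_path: Path | None = None
    if sink is not None:
        sink_path = Path(sink)
        try:
            sink_path.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise HarvestError(f"cannot create sink directory {sink_path}: {exc}")

    listing = list_study_analyses(source, transport=transport)
    for study_id, analysis_ids in listing.items():
        for analysis_id in analysis_ids:
            results: dict[SourceFormat, FetchResult] = {}
            for fmt in (SourceFormat.TEXT, SourceFormat.JSON):
                result = fetch_analysis(
                    source,
                    analysis_id,
                    fmt,
                    transport=transport,
                    limiter=limiter,
                    study_id=study_id,
                )
                results[fmt] = result
                if (
                    sink_path is not None
                    and result.outcome is FetchOutcome.RETRIEVED
                ):
                    target = sink_path / study_id / f"{analysis_id}.{fmt.value}"
                    try:
                        target.parent.mkdir(parents=True, exist_ok=True)
                        target.write_bytes(result.content)
                    except OSError as exc:
                        raise HarvestError(f"cannot write {target}: {exc}")
            yield study_id, analysis_id, results
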