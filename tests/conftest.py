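"""Shared fixtures: generated analyses, a fake HTTP transport, a fake clock."""

from __future__ import annotations

import pytest

from mwstatus.fixtures import generate_valid_analysis
from mwstatus.mwtab_io import write_mwtab_json, write_mwtab_text


@pytest.fixture
def ms_file():
    """A v1.5-valid mass-spectrometry analysis (2 samples x 3 metabolites)."""
    return generate_valid_analysis(
        seed=7,
        study_id="ST000001",
        analysis_id="AN000001",
        analysis_type="MS",
        n_samples=2,
        n_metabolites=3,
    )


@pytest.fixture
def nmr_file():
    return generate_valid_analysis(
        seed=11,
        study_id="ST000002",
        analysis_id="AN000002",
        analysis_type="NMR",
        n_samples=3,
        n_metabolites=4,
    )


@pytest.fixture
def ms_text(ms_file):
    return write_mwtab_text(ms_file)


@pytest.fixture
def ms_json(ms_file):
    return write_mwtab_json(ms_file)


class FakeTransport:
    """Canned (status, body) responses per URL; records every request."""

    def __init__(self, responses: dict[str, tuple[int, bytes]], default=(404, b"")):
        self.responses = dict(responses)
        self.default = default
        self.requests: list[str] = []
        self.errors_before_success: dict[str, int] = {}

    def get(self, url: str) -> tuple[int, bytes]:
        self.requests.append(url)
        remaining = self.errors_before_success.get(url, 0)
        if remaining > 0:
            self.errors_before_success[url] = remaining - 1
            raise ConnectionError(f"simulated transient failure for {url}")
        return self.responses.get(url, self.default)


class FakeClock:
    """Deterministic monotonic clock whose sleep() just advances time."""

    def __init__(self):
        self.now = 0.0
        self.sleeps: list[float] = []

    def monotonic(self) -> float:
        return self.now

    def sleep(self, seconds: float) -> None:
        self.sleeps.append(seconds)
        self.now += seconds


@pytest.fixture
def fake_clock():
    return FakeClock()
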