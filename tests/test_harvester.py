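"""Harvesting: listings, absent-vs-blank semantics, politeness, totality."""

from __future__ import annotations

import json

import pytest

from mwstatus.fixtures import generate_corpus
from mwstatus.harvester import (
    HarvestError,
    RateLimiter,
    SourceConfig,
    fetch_analysis,
    harvest,
    list_study_analyses,
)
from mwstatus.model import FetchOutcome, SourceFormat

from conftest import FakeTransport


def make_listing(entries):
    return (200, json.dumps(entries).encode())


@pytest.fixture
def corpus_dir(tmp_path):
    generate_corpus(seed=5, n_studies=3, output_dir=tmp_path / "corpus", n_analyses=9)
    return tmp_path / "corpus"


class TestLocalDirectory:
    def test_listing_matches_manifest_inventory(self, corpus_dir):
        from mwstatus.fixtures import DefectManifest

        manifest = DefectManifest.load(corpus_dir / "manifest.json")
        source = SourceConfig.for_directory(corpus_dir)
        assert list_study_analyses(source) == manifest.inventory()

    def test_listing_falls_back_to_scanning_without_manifest(self, corpus_dir):
        (corpus_dir / "manifest.json").unlink()
        source = SourceConfig.for_directory(corpus_dir)
        mapping = list_study_analyses(source)
        assert mapping
        for study_id, analyses in mapping.items():
            assert study_id.startswith("ST")
            assert analyses == sorted(analyses)

    def test_empty_directory_yields_empty_map(self, tmp_path):
        source = SourceConfig.for_directory(tmp_path)
        assert list_study_analyses(source) == {}

    def test_nonexistent_directory_is_fatal(self, tmp_path):
        source = SourceConfig.for_directory(tmp_path / "nope")
        with pytest.raises(HarvestError):
            list_study_analyses(source)

    def test_zero_byte_file_is_retrieved_not_absent(self, tmp_path):
        study = tmp_path / "ST000001"
        study.mkdir()
        (study / "AN000001.txt").write_bytes(b"")
        source = SourceConfig.for_directory(tmp_path)
        result = fetch_analysis(source, "AN000001", SourceFormat.TEXT)
        assert result.outcome is FetchOutcome.RETRIEVED
        assert result.content == b""
        assert (
            fetch_analysis(source, "AN000001", SourceFormat.JSON).outcome
            is FetchOutcome.ABSENT
        )

    def test_two_harvests_of_unchanged_directory_are_identical(self, corpus_dir):
        source = SourceConfig.for_directory(corpus_dir)
        first = [
            (st, an, {f: (r.outcome, r.content) for f, r in results.items()})
            for st, an, results in harvest(source)
        ]
        second = [
            (st, an, {f: (r.outcome, r.content) for f, r in results.items()})
            for st, an, results in harvest(source)
        ]
        assert first == second

    def test_sink_persists_only_retrieved_files(self, corpus_dir, tmp_path):
        from mwstatus.fixtures import DefectManifest

        manifest = DefectManifest.load(corpus_dir / "manifest.json")
        sink = tmp_path / "sink"
        results = list(harvest(SourceConfig.for_directory(corpus_dir), sink=sink))
        expected_files = sum(
            (r.outcome is FetchOutcome.RETRIEVED)
            for _, _, pair in results
            for r in pair.values()
        )
        written = list(sink.rglob("AN*.*"))
        assert len(written) == expected_files
        assert len(results) == len(manifest.entries)


class TestRest:
    BASE = "http://mock.example"

    def listing_url(self, source):
        return source.location + source.listing_path

    def file_url(self, source, analysis_id, fmt):
        return source.location + source.file_path.format(
            analysis_id=analysis_id, fmt=fmt.value
        )

    def test_canned_listing_maps_two_studies_by_two_analyses(self):
        source = SourceConfig.for_url(self.BASE)
        transport = FakeTransport(
            {
                self.listing_url(source): make_listing(
                    [
                        {"study_id": "ST000002", "analysis_id": "AN000003"},
                        {"study_id": "ST000002", "analysis_id": "AN000004"},
                        {"study_id": "ST000001", "analysis_id": "AN000001"},
                        {"study_id": "ST000001", "analysis_id": "AN000002"},
                    ]
                )
            }
        )
        mapping = list_study_analyses(source, transport=transport)
        assert mapping == {
            "ST000001": ["AN000001", "AN000002"],
            "ST000002": ["AN000003", "AN000004"],
        }

    def test_malformed_listing_entries_are_skipped(self):
        source = SourceConfig.for_url(self.BASE)
        transport = FakeTransport(
            {
                self.listing_url(source): make_listing(
                    [
                        {"study_id": "ST000001", "analysis_id": "AN000001"},
                        {"bogus": True},
                        {"study_id": "STX", "analysis_id": "AN000002"},
                    ]
                )
            }
        )
        mapping = list_study_analyses(source, transport=transport)
        assert mapping == {"ST000001": ["AN000001"]}

    def test_404_on_both_formats_yields_absent(self):
        source = SourceConfig.for_url(self.BASE, request_delay=0)
        transport = FakeTransport({})
        for fmt in SourceFormat:
            result = fetch_analysis(source, "AN004208", fmt, transport=transport)
            assert result.outcome is FetchOutcome.ABSENT

    def test_transient_failures_are_retried_then_succeed(self):
        source = SourceConfig.for_url(self.BASE, request_delay=0, retries=2)
        url = self.file_url(source, "AN000001", SourceFormat.TEXT)
        transport = FakeTransport({url: (200, b"payload")})
        transport.errors_before_success[url] = 2
        result = fetch_analysis(source, "AN000001", SourceFormat.TEXT, transport=transport)
        assert result.outcome is FetchOutcome.RETRIEVED
        assert result.content == b"payload"

    def test_persistent_failure_degrades_to_absent(self):
        source = SourceConfig.for_url(self.BASE, request_delay=0, retries=1)
        url = self.file_url(source, "AN000001", SourceFormat.TEXT)
        transport = FakeTransport({url: (200, b"payload")})
        transport.errors_before_success[url] = 99
        result = fetch_analysis(source, "AN000001", SourceFormat.TEXT, transport=transport)
        assert result.outcome is FetchOutcome.ABSENT

    def test_consecutive_fetches_respect_request_delay(self, fake_clock):
        """With the default 1 s delay, observed spacing between REST
        requests is at least the configured delay."""
        source = SourceConfig.for_url(self.BASE, request_delay=1.0)
        limiter = RateLimiter(
            source.request_delay,
            monotonic=fake_clock.monotonic,
            sleep=fake_clock.sleep,
        )
        transport = FakeTransport({})
        request_times = []

        class TimedTransport:
            def get(self, url):
                request_times.append(fake_clock.monotonic())
                return transport.get(url)

        for analysis_id in ("AN000001", "AN000002", "AN000003"):
            fetch_analysis(
                source,
                analysis_id,
                SourceFormat.TEXT,
                transport=TimedTransport(),
                limiter=limiter,
            )
        gaps = [b - a for a, b in zip(request_times, request_times[1:])]
        assert gaps and all(gap >= source.request_delay for gap in gaps)

    def test_no_throttling_for_local_reads(self, corpus_dir, fake_clock):
        source = SourceConfig.for_directory(corpus_dir, request_delay=1.0)
        list(harvest(source))
        assert fake_clock.sleeps == []


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [{"request_delay": -1}, {"retries": -1}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SourceConfig.for_url("http://x", **kwargs)

    def test_malformed_analysis_id_rejected(self, tmp_path):
        source = SourceConfig.for_directory(tmp_path)
        with pytest.raises(ValueError):
            fetch_analysis(source, "banana", SourceFormat.TEXT)
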