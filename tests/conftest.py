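"""Shared fixtures: synthetic slides built once per session.

The fabricated slide sets are treated as read-only by tests; anything
that patches bytes works on a copy (the anonymizer's default) directed
into a per-test output directory.
"""

from __future__ import annotations

import pytest

from wsianon import fixtures
from wsianon.detect import VendorFormat

SEED = 7


def fixture_id(key) -> str:
    fmt, bigtiff = key
    return fmt.value + ("_bigtiff" if bigtiff else "")


@pytest.fixture(scope="session")
def slide_sets(tmp_path_factory):
    """One fabricated slide per supported format (plus BigTIFF SVS)."""
    base = tmp_path_factory.mktemp("slides")
    out = {}
    for fmt, bigtiff in fixtures.FIXTURE_FORMATS:
        sub = base / fixture_id((fmt, bigtiff))
        out[(fmt, bigtiff)] = fixtures.make_fixture(fmt, sub, seed=SEED,
                                                    bigtiff=bigtiff)
    return out


@pytest.fixture(scope="session")
def svs_set(slide_sets):
    return slide_sets[(VendorFormat.APERIO_SVS, False)]


@pytest.fixture(scope="session")
def ndpi_set(slide_sets):
    return slide_sets[(VendorFormat.HAMAMATSU_NDPI, False)]


@pytest.fixture(scope="session")
def bif_set(slide_sets):
    return slide_sets[(VendorFormat.VENTANA_BIF, False)]


@pytest.fixture(scope="session")
def mirax_set(slide_sets):
    return slide_sets[(VendorFormat.MIRAX_MRXS, False)]


@pytest.fixture(scope="session")
def isyntax_set(slide_sets):
    return slide_sets[(VendorFormat.PHILIPS_ISYNTAX, False)]


def output_files(report):
    """Every file of an anonymized output (Mirax sets expand)."""
    out = report.output_path
    if out.suffix.lower() == ".mrxs":
        return [out] + sorted(out.with_suffix("").iterdir())
    return [out]
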