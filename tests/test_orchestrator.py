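"""End-to-end workflow: dispatch, safety, level policy, determinism."""

import hashlib
import io

import pytest
import tifffile

from wsianon import fixtures
from wsianon.detect import VendorFormat
from wsianon.orchestrator import (AnonymizationConfig, Level, Scope,
                                  UnsupportedFormatError, achieved_level,
                                  anonymize, is_supported)

from conftest import fixture_id, output_files


def test_is_supported_across_fixtures_and_rejects_text(slide_sets, tmp_path):
    for fx in slide_sets.values():
        ok, fmt = is_supported(fx.path)
        assert ok and fmt is fx.format
    txt = tmp_path / "notes.txt"
    txt.write_text("nothing slide-like here")
    ok, fmt = is_supported(txt)
    assert (ok, fmt) == (False, VendorFormat.UNSUPPORTED)


def test_unsupported_format_is_refused_with_reason(tmp_path):
    txt = tmp_path / "notes.txt"
    txt.write_text("nothing slide-like here")
    with pytest.raises(UnsupportedFormatError, match="unsupported"):
        anonymize(txt)


@pytest.mark.parametrize("key", fixtures.FIXTURE_FORMATS, ids=fixture_id)
def test_default_run_reaches_level_iv_with_no_residual_payloads(
        slide_sets, tmp_path, key):
    fx = slide_sets[key]
    report = anonymize(fx.path, AnonymizationConfig(output_dir=str(tmp_path)))
    assert report.achieved_level is Level.IV
    assert report.total_bytes_modified > 0
    assert fixtures.scan_for_payloads(output_files(report), fx.manifest) == []


def test_original_is_never_touched_by_a_default_run(svs_set, tmp_path):
    before = hashlib.sha256(svs_set.path.read_bytes()).hexdigest()
    anonymize(svs_set.path, AnonymizationConfig(output_dir=str(tmp_path)))
    assert hashlib.sha256(svs_set.path.read_bytes()).hexdigest() == before


def test_output_name_is_content_hash_derived_not_original(svs_set, tmp_path):
    report = anonymize(svs_set.path,
                       AnonymizationConfig(output_dir=str(tmp_path)))
    assert report.output_path.parent == tmp_path
    assert report.output_path.stem != svs_set.path.stem
    assert len(report.output_path.stem) == 12
    expected = hashlib.sha256(svs_set.path.read_bytes()).hexdigest()[:12]
    assert report.output_path.stem == expected


def test_explicit_new_name_is_honoured(svs_set, tmp_path):
    report = anonymize(svs_set.path, AnonymizationConfig(
        new_name="anon-001", output_dir=str(tmp_path)))
    assert report.output_path.name == "anon-001.svs"
    with pytest.raises(ValueError):
        AnonymizationConfig(new_name="../escape")


def test_dry_run_writes_nothing_but_plans_actions(slide_sets):
    for fx in slide_sets.values():
        digests = {p: hashlib.sha256(p.read_bytes()).hexdigest()
                   for p in fx.paths}
        report = anonymize(fx.path, AnonymizationConfig(dry_run=True))
        assert report.actions, "dry run must still report planned actions"
        assert report.output_path is None
        for p, digest in digests.items():
            assert hashlib.sha256(p.read_bytes()).hexdigest() == digest


def test_backup_keeps_original_bytes_under_original_name(svs_set, tmp_path):
    work = tmp_path / svs_set.path.name
    work.write_bytes(svs_set.path.read_bytes())
    anonymize(work, AnonymizationConfig(make_backup=True,
                                        output_dir=str(tmp_path / "out")))
    backup = tmp_path / "backup" / work.name
    assert backup.read_bytes() == svs_set.path.read_bytes()


def test_in_place_patches_the_input_itself(svs_set, tmp_path):
    work = tmp_path / svs_set.path.name
    work.write_bytes(svs_set.path.read_bytes())
    report = anonymize(work, AnonymizationConfig(in_place=True))
    assert report.output_path == work
    assert fixtures.scan_for_payloads([work], svs_set.manifest) == []
    assert work.read_bytes() != svs_set.path.read_bytes()


def test_run_is_deterministic_across_fresh_copies(svs_set, tmp_path):
    outs = []
    for i in range(2):
        d = tmp_path / f"run{i}"
        report = anonymize(svs_set.path, AnonymizationConfig(output_dir=str(d)))
        outs.append(report.output_path.read_bytes())
    assert outs[0] == outs[1]


def test_second_run_on_output_is_a_fixed_point(svs_set, tmp_path):
    report = anonymize(svs_set.path,
                       AnonymizationConfig(output_dir=str(tmp_path)))
    first = report.output_path.read_bytes()
    anonymize(report.output_path, AnonymizationConfig(in_place=True))
    assert report.output_path.read_bytes() == first


# ---------------------------------------------------------------------------
# policy ladder

def test_level_mapping_unlink_only_is_ii():
    config = AnonymizationConfig(blank_images=False, unlink_images=True)
    assert achieved_level(config, metadata_complete=True) is Level.II


def test_level_mapping_blank_subject_only_is_iii():
    config = AnonymizationConfig(scope=Scope.SUBJECT_ONLY)
    assert achieved_level(config, metadata_complete=False) is Level.III


def test_level_mapping_full_is_iv_and_rename_only_is_i():
    assert achieved_level(AnonymizationConfig(), True) is Level.IV
    config = AnonymizationConfig(blank_images=False, unlink_images=False)
    assert achieved_level(config, True) is Level.I


def test_unlink_only_run_reports_ii_and_leaves_pixels(svs_set, tmp_path):
    report = anonymize(svs_set.path, AnonymizationConfig(
        blank_images=False, unlink_images=True, output_dir=str(tmp_path)))
    assert report.achieved_level is Level.II
    hits = fixtures.scan_for_payloads(output_files(report), svs_set.manifest)
    roles = {h[0].role for h in hits}
    assert "LABEL_PIXELS" in roles, \
        "unlinking alone leaves image bytes recoverable"
    with tifffile.TiffFile(io.BytesIO(report.output_path.read_bytes())) as tf:
        assert len(tf.pages) == 2  # label and macro dereferenced


def test_keep_macro_on_svs_keeps_span_and_drops_label(svs_set, tmp_path):
    from wsianon import tiffcore, vendors
    tiff_before = None
    with svs_set.path.open("rb") as fh:
        tiff_before = tiffcore.parse_tiff(fh)
        (macro_ref,) = tiffcore.blob_refs(fh, tiff_before.header,
                                          tiff_before.ifds[3])
        fh.seek(macro_ref.offset)
        macro_bytes = fh.read(macro_ref.length)
    report = anonymize(svs_set.path, AnonymizationConfig(
        keep_macro=True, output_dir=str(tmp_path)))
    assert macro_bytes in report.output_path.read_bytes()
    hits = fixtures.scan_for_payloads(output_files(report), svs_set.manifest)
    assert {h[0].role for h in hits} == {"MACRO_PIXELS"}
    assert not report.warnings


@pytest.mark.parametrize("which", ["ndpi", "bif"])
def test_keep_macro_on_combined_formats_blanks_anyway_with_warning(
        which, request, tmp_path):
    fx = request.getfixturevalue(f"{which}_set")
    report = anonymize(fx.path, AnonymizationConfig(
        keep_macro=True, output_dir=str(tmp_path)))
    assert any("cannot be deleted separately" in w for w in report.warnings)
    assert fixtures.scan_for_payloads(output_files(report), fx.manifest) == []


def test_subject_only_scope_caps_at_level_iii(svs_set, tmp_path):
    report = anonymize(svs_set.path, AnonymizationConfig(
        scope=Scope.SUBJECT_ONLY, output_dir=str(tmp_path)))
    assert report.achieved_level is Level.III
    hits = fixtures.scan_for_payloads(output_files(report), svs_set.manifest)
    roles = {h[0].role for h in hits}
    assert "CASE_ID" not in roles and "BARCODE" not in roles
    assert "SCANNER_SERIAL" in roles  # acquisition data deliberately retained


def test_report_serializes_to_json(svs_set, tmp_path):
    import json
    report = anonymize(svs_set.path,
                       AnonymizationConfig(output_dir=str(tmp_path)))
    payload = json.loads(report.to_json())
    assert payload["achieved_level"] == "IV"
    assert payload["format"] == "aperio_svs"
    assert payload["total_bytes_modified"] == sum(
        a["bytes_modified"] for a in payload["actions"])


def test_generic_tiff_is_anonymizable_with_generic_profile(tmp_path):
    # a no-marker TIFF whose descriptions flag label/macro directories
    from wsianon import tiffcore
    w = fixtures.TiffWriter()
    rawA = bytes(range(256)) * 4
    w.add_ifd(fixtures._gray_ifd(32, 32, 1, [rawA], description=b"base\x00"))
    w.add_ifd(fixtures._gray_ifd(32, 32, 1, [rawA], description=b"label 32x32\x00"))
    w.add_ifd(fixtures._gray_ifd(32, 32, 1, [rawA], description=b"macro 32x32\x00"))
    p = tmp_path / "odd.tif"
    p.write_bytes(w.tobytes())
    report = anonymize(p, AnonymizationConfig(output_dir=str(tmp_path / "o")))
    assert report.format is VendorFormat.GENERIC_TIFF
    with report.output_path.open("rb") as fh:
        tiff = tiffcore.parse_tiff(fh)
    assert len(tiff.ifds) == 1
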