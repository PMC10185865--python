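"""TIFF structure parsing and the three in-place edits.

tifffile serves as the independent reader throughout: our parser's view
of the chain must agree with it before edits, and files must still open
after edits.
"""

import hashlib
import io
import shutil
import zlib

import pytest
import tifffile
from PIL import Image

from wsianon import fixtures, tiffcore


def open_rw(path):
    return path.open("r+b")


def parse_path(path):
    with path.open("rb") as fh:
        return tiffcore.parse_tiff(fh)


@pytest.fixture
def plain5(tmp_path):
    return fixtures.make_plain_tiff(tmp_path / "p5.tif", n_ifds=5, seed=1)


# ---------------------------------------------------------------------------
# parsing

@pytest.mark.parametrize("bigtiff", [False, True], ids=["classic", "bigtiff"])
@pytest.mark.parametrize("byteorder", ["<", ">"], ids=["little", "big"])
def test_chain_matches_independent_reader(tmp_path, bigtiff, byteorder):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=4, seed=2,
                                    bigtiff=bigtiff, byteorder=byteorder)
    tiff = parse_path(path)
    assert tiff.header.is_bigtiff == bigtiff
    assert tiff.header.offset_width == (8 if bigtiff else 4)
    with tifffile.TiffFile(io.BytesIO(path.read_bytes())) as tf:
        assert len(tf.pages) == len(tiff.ifds) == 4
        for page, ifd in zip(tf.pages, tiff.ifds):
            assert page.offset == ifd.offset
    assert tiff.ifds[-1].next_ifd_offset == 0


def test_single_ifd_chain_ends_at_null(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "one.tif", n_ifds=1)
    tiff = parse_path(path)
    assert len(tiff.ifds) == 1
    assert tiff.ifds[0].next_ifd_offset == 0


def test_entries_carry_their_own_file_offsets(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=1)
    tiff = parse_path(path)
    ifd = tiff.ifds[0]
    data = path.read_bytes()
    for entry in ifd.entries:
        stored = int.from_bytes(
            data[entry.entry_file_offset:entry.entry_file_offset + 2], "little")
        assert stored == entry.code
    codes = [e.code for e in ifd.entries]
    assert codes == sorted(codes)


def test_parser_is_pure(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=3)
    before = hashlib.sha256(path.read_bytes()).hexdigest()
    parse_path(path)
    assert hashlib.sha256(path.read_bytes()).hexdigest() == before


def test_bad_magic_is_format_error(tmp_path):
    p = tmp_path / "bad.tif"
    p.write_bytes(b"XX\x2a\x00" + b"\x00" * 16)
    with pytest.raises(tiffcore.TiffFormatError):
        parse_path(p)


def test_cyclic_chain_is_structure_error(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "c.tif", n_ifds=2)
    tiff = parse_path(path)
    # point the second IFD back at the first
    with open_rw(path) as fh:
        fh.seek(tiff.ifds[1].next_pointer_field_offset)
        fh.write(tiff.ifds[0].offset.to_bytes(4, "little"))
    with pytest.raises(tiffcore.TiffStructureError):
        parse_path(path)


def test_pointer_past_eof_is_truncation_error(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=1)
    size = path.stat().st_size
    with open_rw(path) as fh:
        fh.seek(4)
        fh.write((size + 100).to_bytes(4, "little"))
    with pytest.raises(tiffcore.TiffTruncationError):
        parse_path(path)


# ---------------------------------------------------------------------------
# blob references

def test_blob_refs_match_byte_count_tags(svs_set):
    tiff = parse_path(svs_set.path)
    with svs_set.path.open("rb") as fh:
        refs0 = tiffcore.blob_refs(fh, tiff.header, tiff.ifds[0])
        counts = tiffcore.read_tag_values(
            fh, tiff.header, tiff.ifds[0].tags[tiffcore.STRIP_BYTE_COUNTS])
    assert [r.length for r in refs0] == counts
    assert len(refs0) == 2  # two strips of 64 rows
    spans = sorted((r.offset, r.offset + r.length) for r in refs0)
    for (_, end), (start, _) in zip(spans, spans[1:]):
        assert end <= start, "strip regions must be disjoint"


def test_ifd_without_strips_yields_no_refs(tmp_path):
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures.IfdPlan(tags={
        tiffcore.IMAGE_WIDTH: (fixtures.LONG, [4]),
        tiffcore.IMAGE_LENGTH: (fixtures.LONG, [4]),
    }))
    p = tmp_path / "nostrips.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with p.open("rb") as fh:
        assert tiffcore.blob_refs(fh, tiff.header, tiff.ifds[0]) == []


def test_mismatched_offsets_and_counts_is_structure_error(tmp_path):
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures.IfdPlan(tags={
        tiffcore.IMAGE_WIDTH: (fixtures.LONG, [4]),
        tiffcore.IMAGE_LENGTH: (fixtures.LONG, [4]),
        tiffcore.STRIP_OFFSETS: (fixtures.LONG, [8, 16]),
        tiffcore.STRIP_BYTE_COUNTS: (fixtures.LONG, [8]),
    }))
    p = tmp_path / "mismatch.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with p.open("rb") as fh:
        with pytest.raises(tiffcore.TiffStructureError):
            tiffcore.blob_refs(fh, tiff.header, tiff.ifds[0])


# ---------------------------------------------------------------------------
# overwrite_blob

@pytest.mark.parametrize("payload_len,expect", [
    (100, "exact"), (60, "padded"), (101, "error")])
def test_overwrite_blob_respects_region_capacity(tmp_path, payload_len, expect):
    p = tmp_path / "blob.bin"
    p.write_bytes(bytes(range(256)) * 2)
    ref = tiffcore.BlobRef(offset=50, length=100)
    payload = b"\xab" * payload_len
    with open_rw(p) as fh:
        if expect == "error":
            with pytest.raises(tiffcore.CapacityError):
                tiffcore.overwrite_blob(fh, ref, payload)
            return
        tiffcore.overwrite_blob(fh, ref, payload)
    data = p.read_bytes()
    assert data[50:50 + payload_len] == payload
    assert data[50 + payload_len:150] == b"\x00" * (100 - payload_len)
    assert data[:50] == (bytes(range(256)) * 2)[:50]
    assert len(data) == 512


# ---------------------------------------------------------------------------
# blank_image

def test_blank_uncompressed_writes_white_raster(tmp_path):
    raw = bytes(range(256)) * 4  # 32x32
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures._gray_ifd(32, 32, tiffcore.COMPRESSION_NONE, [raw]))
    p = tmp_path / "g.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with open_rw(p) as fh:
        written = tiffcore.blank_image(fh, tiff, 0)
    assert written == 1024
    tiff2 = parse_path(p)
    with p.open("rb") as fh:
        (ref,) = tiffcore.blob_refs(fh, tiff2.header, tiff2.ifds[0])
        fh.seek(ref.offset)
        assert fh.read(ref.length) == b"\xff" * 1024


def test_blank_jpeg_decodes_to_uniform_image(svs_set, tmp_path):
    work = tmp_path / "s.svs"
    shutil.copy(svs_set.path, work)
    tiff = parse_path(work)
    label_index = 2
    with open_rw(work) as fh:
        tiffcore.blank_image(fh, tiff, label_index)
    tiff2 = parse_path(work)
    with work.open("rb") as fh:
        (ref,) = tiffcore.blob_refs(fh, tiff2.header, tiff2.ifds[label_index])
        fh.seek(ref.offset)
        blob = fh.read(ref.length)
    im = Image.open(io.BytesIO(blob))
    assert im.size == (64, 64)
    lo, hi = im.getextrema()
    assert hi - lo <= 1, "blank label must decode to a uniform image"


def test_blank_shrinks_byte_count_and_zero_fills_slack(tmp_path):
    raw = bytes(x % 251 for x in range(64 * 64))
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures._gray_ifd(64, 64, tiffcore.COMPRESSION_DEFLATE_ADOBE,
                                 [zlib.compress(raw)]))
    p = tmp_path / "d.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with p.open("rb") as fh:
        (orig,) = tiffcore.blob_refs(fh, tiff.header, tiff.ifds[0])
    size_before = p.stat().st_size
    with open_rw(p) as fh:
        tiffcore.blank_image(fh, tiff, 0)
    assert p.stat().st_size == size_before
    tiff2 = parse_path(p)
    with p.open("rb") as fh:
        (new,) = tiffcore.blob_refs(fh, tiff2.header, tiff2.ifds[0])
        assert new.offset == orig.offset
        assert new.length < orig.length
        fh.seek(new.offset)
        blob = fh.read(orig.length)
    assert zlib.decompress(blob[:new.length]) == b"\xff" * (64 * 64)
    assert blob[new.length:] == b"\x00" * (orig.length - new.length)


def test_blank_lzw_decodes_with_independent_reader(tmp_path):
    raw = bytes(x % 7 for x in range(48 * 48))
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures._gray_ifd(48, 48, tiffcore.COMPRESSION_LZW,
                                 [tiffcore._lzw_encode(raw)]))
    p = tmp_path / "l.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with open_rw(p) as fh:
        tiffcore.blank_image(fh, tiff, 0)
    arr = tifffile.imread(io.BytesIO(p.read_bytes()))
    assert arr.shape == (48, 48)
    assert arr.min() == arr.max() == 255


def test_unsupported_compression_raises_but_blobs_can_be_zeroed(tmp_path):
    w = fixtures.TiffWriter()
    plan = fixtures._gray_ifd(8, 8, 33005, [b"\x11" * 64])  # vendor codec
    w.add_ifd(plan)
    p = tmp_path / "u.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    with open_rw(p) as fh:
        with pytest.raises(tiffcore.UnsupportedCompressionError):
            tiffcore.blank_image(fh, tiff, 0)
        for ref in tiffcore.blob_refs(fh, tiff.header, tiff.ifds[0]):
            tiffcore.overwrite_blob(fh, ref, b"")
    data = p.read_bytes()
    assert b"\x11" * 8 not in data
    parse_path(p)  # structure survives the raw zeroing


# ---------------------------------------------------------------------------
# unlink_ifd

def test_unlink_middle_relinks_predecessor(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=3)
    tiff = parse_path(path)
    offsets = [i.offset for i in tiff.ifds]
    with open_rw(path) as fh:
        tiff2 = tiffcore.unlink_ifd(fh, tiff, 1)
    assert [i.offset for i in tiff2.ifds] == [offsets[0], offsets[2]]
    with tifffile.TiffFile(io.BytesIO(path.read_bytes())) as tf:
        assert [p.offset for p in tf.pages] == [offsets[0], offsets[2]]


def test_unlink_last_terminates_with_null_pointer(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=3)
    tiff = parse_path(path)
    with open_rw(path) as fh:
        tiff2 = tiffcore.unlink_ifd(fh, tiff, 2)
    assert len(tiff2.ifds) == 2
    assert tiff2.ifds[-1].next_ifd_offset == 0


def test_unlink_first_rewrites_header_field(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=3)
    tiff = parse_path(path)
    second = tiff.ifds[1].offset
    with open_rw(path) as fh:
        tiff2 = tiffcore.unlink_ifd(fh, tiff, 0)
    assert tiff2.header.first_ifd_offset == second
    assert len(tiff2.ifds) == 2


def test_unlink_sole_ifd_leaves_empty_chain(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "one.tif", n_ifds=1)
    tiff = parse_path(path)
    with open_rw(path) as fh:
        tiff2 = tiffcore.unlink_ifd(fh, tiff, 0)
    assert tiff2.header.first_ifd_offset == 0
    assert tiff2.ifds == []


def test_unlink_out_of_range_is_argument_error(plain5):
    tiff = parse_path(plain5)
    with open_rw(plain5) as fh:
        with pytest.raises(IndexError):
            tiffcore.unlink_ifd(fh, tiff, 5)


def test_unlink_preserves_file_size_and_unlinked_bytes(plain5):
    size = plain5.stat().st_size
    tiff = parse_path(plain5)
    dropped = tiff.ifds[2]
    with plain5.open("rb") as fh:
        fh.seek(dropped.offset)
        before = fh.read(64)
    with open_rw(plain5) as fh:
        tiffcore.unlink_ifd(fh, tiff, 2)
    assert plain5.stat().st_size == size
    with plain5.open("rb") as fh:
        fh.seek(dropped.offset)
        assert fh.read(64) == before, \
            "unlinking alone must not erase directory bytes"


# ---------------------------------------------------------------------------
# replace_tag_string

def test_replace_preserves_length_and_nul(tmp_path):
    path, expected = fixtures.make_string_tag_tiff(tmp_path / "s.tif", 8, seed=3)
    tiff = parse_path(path)
    with open_rw(path) as fh:
        for code in expected:
            tiffcore.replace_tag_string(fh, tiff, 0, code, "X")
    tiff2 = parse_path(path)
    with path.open("rb") as fh:
        for code, original in expected.items():
            entry = tiff2.ifds[0].tags[code]
            replaced = tiffcore.read_tag_bytes(fh, entry)
            assert len(replaced) == len(original)
            assert all(b == ord("X") for b in replaced.rstrip(b"\x00"))
            assert replaced.endswith(b"\x00") == original.endswith(b"\x00")
            assert entry.count == len(original)


def test_replace_inline_string_stays_inside_entry(tmp_path):
    w = fixtures.TiffWriter()
    w.add_ifd(fixtures._gray_ifd(
        4, 4, tiffcore.COMPRESSION_NONE, [b"\x00" * 16],
        extra={tiffcore.MAKE: (fixtures.ASCII, b"ab\x00")}))
    p = tmp_path / "i.tif"
    p.write_bytes(w.tobytes())
    tiff = parse_path(p)
    entry = tiff.ifds[0].tags[tiffcore.MAKE]
    assert entry.is_inline
    with open_rw(p) as fh:
        offset, length = tiffcore.replace_tag_string(fh, tiff, 0,
                                                     tiffcore.MAKE, "Z")
    assert offset == entry.value_field_offset
    assert length == 3
    data = p.read_bytes()
    assert data[offset:offset + 3] == b"ZZ\x00"


def test_replace_missing_tag_signals_not_found(svs_set, tmp_path):
    work = tmp_path / "s.svs"
    shutil.copy(svs_set.path, work)
    tiff = parse_path(work)
    with open_rw(work) as fh:
        with pytest.raises(tiffcore.TagNotFoundError):
            tiffcore.replace_tag_string(fh, tiff, 0, 62000, "X")


def test_replace_non_string_tag_is_type_error(svs_set, tmp_path):
    work = tmp_path / "s.svs"
    shutil.copy(svs_set.path, work)
    tiff = parse_path(work)
    with open_rw(work) as fh:
        with pytest.raises(tiffcore.TagTypeError):
            tiffcore.replace_tag_string(fh, tiff, 0, tiffcore.IMAGE_WIDTH, "X")


# ---------------------------------------------------------------------------
# idempotence

def test_blank_and_replace_are_idempotent(tmp_path):
    path = fixtures.make_plain_tiff(tmp_path / "t.tif", n_ifds=3)

    def apply():
        tiff = parse_path(path)
        with open_rw(path) as fh:
            tiffcore.blank_image(fh, tiff, 1)
            tiffcore.replace_tag_string(fh, tiff, 0,
                                        tiffcore.IMAGE_DESCRIPTION, "X")

    apply()
    first = path.read_bytes()
    apply()
    assert path.read_bytes() == first
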