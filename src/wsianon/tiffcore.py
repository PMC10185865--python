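"""TIFF/BigTIFF structure parsing and structure-preserving in-place edits.

Whole-slide images from Aperio/Leica, Hamamatsu and Ventana scanners are
TIFF (or BigTIFF) files whose associated label/macro photographs and
metadata strings live in ordinary image file directories (IFDs) and tag
entries.  Removing that content without invalidating the file means the
file is never rewritten: it is *patched*.  Three edits suffice:

* overwrite the image data blobs of a directory with an encoded blank
  image (so the pixels cannot be recovered from unreferenced bytes),
* unlink a directory from the IFD chain by pointing its predecessor's
  next-IFD field at its successor (or writing a null pointer at the end),
* replace a sensitive string held by a tag with a content-free string of
  the same byte length (string allocations are fixed-size; growing them
  corrupts the file).

The parser builds a complete picture of the chain — header, tag entries
with their own file offsets, strip/tile blob references — so every patch
target is a concrete byte address.  All multi-byte writes honour the byte
order declared in the file header.
"""

from __future__ import annotations

import io
import struct
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import BinaryIO, Sequence

__all__ = [
    "TiffError",
    "TiffFormatError",
    "TiffStructureError",
    "TiffTruncationError",
    "CapacityError",
    "TagTypeError",
    "UnsupportedCompressionError",
    "IfdRole",
    "TiffHeader",
    "TagEntry",
    "Ifd",
    "TiffStructure",
    "BlobRef",
    "parse_tiff",
    "blob_refs",
    "read_tag_values",
    "read_tag_bytes",
    "tag_scalar",
    "overwrite_blob",
    "blank_image",
    "unlink_ifd",
    "replace_tag_string",
    "replace_span",
    "encode_blank",
]


class TiffError(Exception):
    """Base class for TIFF parsing/patching failures."""


class TiffFormatError(TiffError):
    """The byte stream is not a classic TIFF or BigTIFF file."""


class TiffStructureError(TiffError):
    """The file has a valid header but an inconsistent structure."""


class TiffTruncationError(TiffStructureError):
    """A pointer or blob extends beyond the end of the file."""


class CapacityError(TiffError):
    """A replacement payload does not fit its fixed allocation."""


class TagTypeError(TiffError):
    """A tag does not hold the datatype the operation requires."""


class TagNotFoundError(TiffError, KeyError):
    """The requested tag is absent from the directory."""


class UnsupportedCompressionError(TiffError):
    """No blank-image encoder exists for the declared compression."""


# Standard tag codes used throughout the package.
IMAGE_WIDTH = 256
IMAGE_LENGTH = 257
BITS_PER_SAMPLE = 258
COMPRESSION = 259
PHOTOMETRIC = 262
IMAGE_DESCRIPTION = 270
MAKE = 271
MODEL = 272
STRIP_OFFSETS = 273
SAMPLES_PER_PIXEL = 277
ROWS_PER_STRIP = 278
STRIP_BYTE_COUNTS = 279
SOFTWARE = 305
DATETIME = 306
ARTIST = 315
TILE_WIDTH = 322
TILE_LENGTH = 323
TILE_OFFSETS = 324
TILE_BYTE_COUNTS = 325

# Compression codes with a blank-image encoder.
COMPRESSION_NONE = 1
COMPRESSION_LZW = 5
COMPRESSION_JPEG = 7
COMPRESSION_DEFLATE_ADOBE = 8
COMPRESSION_DEFLATE = 32946

ASCII = 2

_TYPE_SIZES = {
    1: 1, 2: 1, 3: 2, 4: 4, 5: 8, 6: 1, 7: 1, 8: 2, 9: 4, 10: 8,
    11: 4, 12: 8, 13: 4, 16: 8, 17: 8, 18: 8,
}
_TYPE_FMT = {
    1: "B", 3: "H", 4: "I", 6: "b", 8: "h", 9: "i",
    11: "f", 12: "d", 13: "I", 16: "Q", 17: "q", 18: "Q",
}

_MAX_IFDS = 65536


class IfdRole(Enum):
    """Functional role of a directory within a slide file."""

    BASELINE = "baseline"
    PYRAMID_LEVEL = "pyramid_level"
    LABEL = "label"
    MACRO = "macro"
    THUMBNAIL = "thumbnail"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TiffHeader:
    byteorder: str  # struct prefix: "<" or ">"
    is_bigtiff: bool
    first_ifd_offset: int
    # byte offset of the header field that stores first_ifd_offset
    first_ifd_field_offset: int

    @property
    def offset_width(self) -> int:
        return 8 if self.is_bigtiff else 4

    @property
    def endianness(self) -> str:
        return "little" if self.byteorder == "<" else "big"


@dataclass(frozen=True)
class TagEntry:
    code: int
    dtype: int
    count: int
    value_or_offset: int
    is_inline: bool
    entry_file_offset: int
    value_field_offset: int
    raw_value_field: bytes

    @property
    def payload_size(self) -> int:
        return _TYPE_SIZES.get(self.dtype, 1) * self.count

    def payload_offset(self) -> int:
        """File offset of the first payload byte (inline or out-of-line)."""
        return self.value_field_offset if self.is_inline else self.value_or_offset

    def element_offset(self, index: int) -> int:
        """File offset of the index-th payload element."""
        if not 0 <= index < self.count:
            raise IndexError(index)
        return self.payload_offset() + index * _TYPE_SIZES.get(self.dtype, 1)


@dataclass
class Ifd:
    offset: int
    entries: list[TagEntry]
    next_pointer_field_offset: int
    next_ifd_offset: int
    tags: dict[int, TagEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tags:
            self.tags = {e.code: e for e in self.entries}

    @property
    def entry_count(self) -> int:
        return len(self.entries)


@dataclass
class TiffStructure:
    header: TiffHeader
    ifds: list[Ifd]
    file_size: int
    roles: dict[int, IfdRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = {i: IfdRole.UNKNOWN for i in range(len(self.ifds))}


@dataclass(frozen=True)
class BlobRef:
    offset: int
    length: int


def _read_exact(stream: BinaryIO, offset: int, n: int) -> bytes:
    stream.seek(offset)
    data = stream.read(n)
    if len(data) != n:
        raise TiffTruncationError(
            f"wanted {n} bytes at offset {offset}, file ends early"
        )
    return data


def _write_uint(stream: BinaryIO, offset: int, value: int, width: int,
                byteorder: str) -> None:
    fmt = {2: "H", 4: "I", 8: "Q"}[width]
    stream.seek(offset)
    stream.write(struct.pack(byteorder + fmt, value))


def parse_header(stream: BinaryIO) -> TiffHeader:
    stream.seek(0)
    head = stream.read(8)
    if len(head) < 8:
        raise TiffFormatError("file too short for a TIFF header")
    if head[:2] == b"II":
        byteorder = "<"
    elif head[:2] == b"MM":
        byteorder = ">"
    else:
        raise TiffFormatError(f"bad byte-order mark {head[:2]!r}")
    version = struct.unpack(byteorder + "H", head[2:4])[0]
    if version == 42:
        first = struct.unpack(byteorder + "I", head[4:8])[0]
        return TiffHeader(byteorder, False, first, first_ifd_field_offset=4)
    if version == 43:
        offsize, zero = struct.unpack(byteorder + "HH", head[4:8])
        if offsize != 8 or zero != 0:
            raise TiffFormatError("malformed BigTIFF header")
        first = struct.unpack(byteorder + "Q", _read_exact(stream, 8, 8))[0]
        return TiffHeader(byteorder, True, first, first_ifd_field_offset=8)
    raise TiffFormatError(f"unknown TIFF version {version}")


def _parse_ifd(stream: BinaryIO, header: TiffHeader, offset: int,
               file_size: int) -> Ifd:
    bo = header.byteorder
    if header.is_bigtiff:
        count_width, entry_size, value_width = 8, 20, 8
        count_fmt, off_fmt = "Q", "Q"
    else:
        count_width, entry_size, value_width = 2, 12, 4
        count_fmt, off_fmt = "H", "I"
    n = struct.unpack(bo + count_fmt, _read_exact(stream, offset, count_width))[0]
    raw = _read_exact(stream, offset + count_width, n * entry_size + header.offset_width)
    entries: list[TagEntry] = []
    for i in range(n):
        chunk = raw[i * entry_size:(i + 1) * entry_size]
        code, dtype = struct.unpack(bo + "HH", chunk[:4])
        count = struct.unpack(bo + count_fmt if header.is_bigtiff else bo + "I",
                              chunk[4:4 + (8 if header.is_bigtiff else 4)])[0]
        vfield = chunk[-value_width:]
        value_int = struct.unpack(bo + off_fmt, vfield)[0]
        size = _TYPE_SIZES.get(dtype, 1) * count
        inline = size <= value_width
        entry_off = offset + count_width + i * entry_size
        entry = TagEntry(
            code=code, dtype=dtype, count=count, value_or_offset=value_int,
            is_inline=inline, entry_file_offset=entry_off,
            value_field_offset=entry_off + entry_size - value_width,
            raw_value_field=vfield,
        )
        if not inline and value_int + size > file_size:
            raise TiffTruncationError(
                f"tag {code} payload at {value_int}+{size} exceeds file size {file_size}"
            )
        entries.append(entry)
    next_field = offset + count_width + n * entry_size
    next_off = struct.unpack(bo + off_fmt, raw[n * entry_size:])[0]
    return Ifd(offset=offset, entries=entries,
               next_pointer_field_offset=next_field, next_ifd_offset=next_off)


def parse_tiff(stream: BinaryIO) -> TiffStructure:
    """Parse the full IFD chain into patchable addresses.

    Read-only: the stream position changes but no byte is written.
    Raises :class:`TiffFormatError` for a bad magic number,
    :class:`TiffStructureError` for a cyclic chain and
    :class:`TiffTruncationError` for pointers past end-of-file.
    """
    stream.seek(0, io.SEEK_END)
    file_size = stream.tell()
    header = parse_header(stream)
    ifds: list[Ifd] = []
    seen: set[int] = set()
    off = header.first_ifd_offset
    while off != 0:
        if off in seen:
            raise TiffStructureError(f"cyclic IFD chain at offset {off}")
        if off >= file_size:
            raise TiffTruncationError(f"IFD offset {off} beyond EOF {file_size}")
        seen.add(off)
        if len(ifds) >= _MAX_IFDS:
            raise TiffStructureError("IFD chain unreasonably long")
        ifd = _parse_ifd(stream, header, off, file_size)
        ifds.append(ifd)
        off = ifd.next_ifd_offset
    return TiffStructure(header=header, ifds=ifds, file_size=file_size)


def read_tag_values(stream: BinaryIO, header: TiffHeader,
                    entry: TagEntry) -> list:
    """Decode a tag's payload into Python numbers (or rational tuples)."""
    data = read_tag_bytes(stream, entry)
    bo = header.byteorder
    if entry.dtype in (2, 7):  # ASCII / UNDEFINED: caller wants bytes
        return [data]
    if entry.dtype in (5, 10):  # RATIONAL / SRATIONAL
        fmt = "I" if entry.dtype == 5 else "i"
        vals = struct.unpack(bo + fmt * (2 * entry.count), data)
        return [(vals[2 * i], vals[2 * i + 1]) for i in range(entry.count)]
    fmt = _TYPE_FMT.get(entry.dtype)
    if fmt is None:
        raise TagTypeError(f"cannot decode TIFF type {entry.dtype}")
    return list(struct.unpack(bo + fmt * entry.count, data))


def read_tag_bytes(stream: BinaryIO, entry: TagEntry) -> bytes:
    """Raw payload bytes of a tag, inline or out-of-line."""
    size = entry.payload_size
    if entry.is_inline:
        return entry.raw_value_field[:size]
    return _read_exact(stream, entry.value_or_offset, size)


def tag_scalar(stream: BinaryIO, header: TiffHeader, ifd: Ifd, code: int,
               default=None):
    entry = ifd.tags.get(code)
    if entry is None:
        return default
    values = read_tag_values(stream, header, entry)
    return values[0]


def blob_refs(stream: BinaryIO, header: TiffHeader, ifd: Ifd) -> list[BlobRef]:
    """One (offset, length) per strip or tile of the directory.

    Directories without strip/tile tags yield an empty list.  A mismatch
    between the offsets and byte-counts arities is a structure error.
    """
    if TILE_OFFSETS in ifd.tags:
        off_code, cnt_code = TILE_OFFSETS, TILE_BYTE_COUNTS
    elif STRIP_OFFSETS in ifd.tags:
        off_code, cnt_code = STRIP_OFFSETS, STRIP_BYTE_COUNTS
    else:
        return []
    off_entry = ifd.tags.get(off_code)
    cnt_entry = ifd.tags.get(cnt_code)
    if cnt_entry is None:
        raise TiffStructureError(f"tag {off_code} without byte-count tag")
    if off_entry.count != cnt_entry.count:
        raise TiffStructureError(
            f"{off_entry.count} offsets but {cnt_entry.count} byte counts"
        )
    offsets = read_tag_values(stream, header, off_entry)
    counts = read_tag_values(stream, header, cnt_entry)
    return [BlobRef(int(o), int(c)) for o, c in zip(offsets, counts)]


def overwrite_blob(stream: BinaryIO, ref: BlobRef, payload: bytes) -> int:
    """Overwrite a blob region in place; slack after the payload is zeroed.

    The file size never changes.  A payload longer than the region is a
    :class:`CapacityError` — growing a fixed allocation invalidates the
    format.
    """
    if len(payload) > ref.length:
        raise CapacityError(
            f"payload of {len(payload)} bytes exceeds region of {ref.length}"
        )
    stream.seek(ref.offset)
    stream.write(payload)
    stream.write(b"\x00" * (ref.length - len(payload)))
    return ref.length


def replace_span(stream: BinaryIO, offset: int, length: int,
                 replacement_char: str = "X") -> int:
    """Overwrite ``length`` bytes at ``offset`` with a repeated filler char."""
    if len(replacement_char) != 1 or not (0x20 <= ord(replacement_char) < 0x7F):
        raise ValueError("replacement_char must be one printable ASCII char")
    stream.seek(offset)
    stream.write(replacement_char.encode("ascii") * length)
    return length


def replace_tag_string(stream: BinaryIO, tiff: TiffStructure, ifd_index: int,
                       code: int, replacement_char: str = "X") -> tuple[int, int]:
    """Replace an ASCII tag's stored string with same-length filler.

    NUL bytes (terminators and multi-string separators) are preserved
    bit-exactly, so the tag count, the payload length and the file size
    are all unchanged.  Returns the (offset, length) span rewritten.
    """
    ifd = tiff.ifds[ifd_index]
    entry = ifd.tags.get(code)
    if entry is None:
        raise TagNotFoundError(code)
    if entry.dtype != ASCII:
        raise TagTypeError(f"tag {code} has type {entry.dtype}, not ASCII")
    current = read_tag_bytes(stream, entry)
    filler = replacement_char.encode("ascii")[0]
    replaced = bytes(filler if b != 0 else 0 for b in current)
    offset = entry.payload_offset()
    stream.seek(offset)
    stream.write(replaced)
    return offset, len(replaced)


# ---------------------------------------------------------------------------
# blank-image encoding

def _lzw_encode(data: bytes) -> bytes:
    """TIFF-flavoured LZW (MSB-first bit packing, early code-width change)."""
    CLEAR, EOI = 256, 257
    out = bytearray()
    bitbuf = 0
    nbits = 0
    width = 9

    def emit(code: int) -> None:
        nonlocal bitbuf, nbits
        bitbuf = (bitbuf << width) | code
        nbits += width
        while nbits >= 8:
            nbits -= 8
            out.append((bitbuf >> nbits) & 0xFF)

    table: dict[bytes, int] = {bytes([i]): i for i in range(256)}
    next_code = 258
    emit(CLEAR)
    w = b""
    for byte in data:
        c = bytes([byte])
        wc = w + c
        if wc in table:
            w = wc
            continue
        emit(table[w])
        table[wc] = next_code
        next_code += 1
        # code width grows when the next assignable code overflows it
        if next_code == (1 << width) and width < 12:
            width += 1
        if next_code >= 4094:
            emit(CLEAR)
            table = {bytes([i]): i for i in range(256)}
            next_code = 258
            width = 9
        w = c
    if w:
        emit(table[w])
    emit(EOI)
    if nbits:
        out.append((bitbuf << (8 - nbits)) & 0xFF)
    return bytes(out)


def _blank_raster(width: int, height: int, samples: int, bits: int,
                  photometric: int) -> bytes:
    if bits != 8:
        raise UnsupportedCompressionError(
            f"blank encoding only supports 8-bit samples, got {bits}"
        )
    # photometric 0 = WhiteIsZero: white pixels are stored as 0x00
    fill = 0x00 if photometric == 0 else 0xFF
    return bytes([fill]) * (width * height * samples)


def encode_blank(width: int, height: int, samples: int, bits: int,
                 photometric: int, compression: int) -> bytes:
    """Encode a uniform white image in the directory's own compression.

    Supported schemes: none, LZW, Deflate (both codes) and JPEG.  The
    result decodes with any baseline reader of the respective codec.
    """
    if compression == COMPRESSION_JPEG:
        from PIL import Image

        if samples == 3:
            im = Image.new("RGB", (width, height), (255, 255, 255))
        elif samples == 1:
            im = Image.new("L", (width, height), 255)
        else:
            raise UnsupportedCompressionError(
                f"no JPEG blank for {samples} samples/pixel"
            )
        buf = io.BytesIO()
        im.save(buf, format="JPEG", quality=75)
        return buf.getvalue()
    raster = _blank_raster(width, height, samples, bits, photometric)
    if compression == COMPRESSION_NONE:
        return raster
    if compression in (COMPRESSION_DEFLATE, COMPRESSION_DEFLATE_ADOBE):
        return zlib.compress(raster)
    if compression == COMPRESSION_LZW:
        return _lzw_encode(raster)
    raise UnsupportedCompressionError(f"compression code {compression}")


def _write_tag_count_and_value(stream: BinaryIO, header: TiffHeader,
                               entry: TagEntry, count: int, value: int) -> None:
    """Rewrite a tag entry's count field and inline value in place."""
    bo = header.byteorder
    if header.is_bigtiff:
        _write_uint(stream, entry.entry_file_offset + 4, count, 8, bo)
        _write_uint(stream, entry.value_field_offset, value, 8, bo)
    else:
        _write_uint(stream, entry.entry_file_offset + 4, count, 4, bo)
        _write_uint(stream, entry.value_field_offset, value, 4, bo)


def _write_element(stream: BinaryIO, header: TiffHeader, entry: TagEntry,
                   index: int, value: int) -> None:
    width = _TYPE_SIZES[entry.dtype]
    if width not in (2, 4, 8):
        raise TagTypeError(f"cannot patch element of type {entry.dtype}")
    if value >= 1 << (8 * width):
        raise CapacityError(
            f"value {value} does not fit tag type of {width} bytes"
        )
    _write_uint(stream, entry.element_offset(index), value, width,
                header.byteorder)


def blank_image(stream: BinaryIO, tiff: TiffStructure, index: int) -> int:
    """Overwrite a directory's image blobs with an encoded blank image.

    Each strip/tile is re-encoded blank at its declared geometry and
    written into its existing region; the byte-count tag is rewritten to
    the new (never larger) length and slack bytes are zeroed.  When a
    segment's blank encoding does not fit, the image falls back to a
    single-strip layout inside the first region, provided it fits there.
    Returns the number of region bytes rewritten.
    """
    header = tiff.header
    ifd = tiff.ifds[index]
    refs = blob_refs(stream, header, ifd)
    if not refs:
        return 0
    width = tag_scalar(stream, header, ifd, IMAGE_WIDTH)
    height = tag_scalar(stream, header, ifd, IMAGE_LENGTH)
    if width is None or height is None:
        raise TiffStructureError("directory lacks image dimensions")
    compression = tag_scalar(stream, header, ifd, COMPRESSION, COMPRESSION_NONE)
    photometric = tag_scalar(stream, header, ifd, PHOTOMETRIC, 1)
    samples = tag_scalar(stream, header, ifd, SAMPLES_PER_PIXEL, 1)
    bits = tag_scalar(stream, header, ifd, BITS_PER_SAMPLE, 8)

    tiled = TILE_OFFSETS in ifd.tags
    if tiled:
        tile_w = tag_scalar(stream, header, ifd, TILE_WIDTH)
        tile_h = tag_scalar(stream, header, ifd, TILE_LENGTH)
        segments = [(tile_w, tile_h)] * len(refs)
        cnt_entry = ifd.tags[TILE_BYTE_COUNTS]
    else:
        rows_per_strip = tag_scalar(stream, header, ifd, ROWS_PER_STRIP, height)
        segments = []
        for i in range(len(refs)):
            rows = min(rows_per_strip, height - i * rows_per_strip)
            segments.append((width, max(rows, 0)))
        cnt_entry = ifd.tags[STRIP_BYTE_COUNTS]

    encoded = [
        encode_blank(w, h, samples, bits, photometric, compression)
        for (w, h) in segments
    ]
    if all(len(e) <= r.length for e, r in zip(encoded, refs)):
        written = 0
        for i, (enc, ref) in enumerate(zip(encoded, refs)):
            written += overwrite_blob(stream, ref, enc)
            _write_element(stream, header, cnt_entry, i, len(enc))
        return written

    if tiled:
        raise CapacityError("blank tile encoding exceeds existing tile regions")

    # single-strip fallback: the whole blank image into the first region
    whole = encode_blank(width, height, samples, bits, photometric, compression)
    if len(whole) > refs[0].length:
        raise CapacityError(
            f"blank image of {len(whole)} bytes does not fit first strip "
            f"region of {refs[0].length}"
        )
    for ref in refs:
        overwrite_blob(stream, ref, b"")
    overwrite_blob(stream, refs[0], whole)
    off_entry = ifd.tags[STRIP_OFFSETS]
    value_width = 8 if header.is_bigtiff else 4
    if refs[0].offset >= 1 << (8 * value_width):
        raise CapacityError("strip offset does not fit inline value field")
    _write_tag_count_and_value(stream, header, off_entry, 1, refs[0].offset)
    _write_tag_count_and_value(stream, header, cnt_entry, 1, len(whole))
    rps_entry = ifd.tags.get(ROWS_PER_STRIP)
    if rps_entry is not None:
        _write_element(stream, header, rps_entry, 0, height)
    return sum(r.length for r in refs)


def unlink_ifd(stream: BinaryIO, tiff: TiffStructure, index: int) -> TiffStructure:
    """Remove a directory from the chain by relinking its predecessor.

    The predecessor's next-IFD pointer (or the header's first-IFD field
    for index 0) is overwritten with the target's own next pointer; for
    the last directory that pointer is the null terminator.  The
    directory's bytes stay physically present — blank them first if the
    content is sensitive.  Returns the re-parsed structure.
    """
    if not 0 <= index < len(tiff.ifds):
        raise IndexError(f"IFD index {index} out of range 0..{len(tiff.ifds) - 1}")
    header = tiff.header
    successor = tiff.ifds[index].next_ifd_offset
    if index == 0:
        field_offset = header.first_ifd_field_offset
    else:
        field_offset = tiff.ifds[index - 1].next_pointer_field_offset
    _write_uint(stream, field_offset, successor, header.offset_width,
                header.byteorder)
    stream.flush()
    return parse_tiff(stream)
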