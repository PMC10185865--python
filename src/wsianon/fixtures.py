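"""Fabricated slide files with known planted sensitive payloads.

No real scanner output can be redistributed, so every test input is
fabricated here: minimal but structurally faithful files for each
supported vendor format, each carrying a manifest of planted sensitive
payloads (case ID, barcode, scanner serial, acquisition date/time,
operator name, label/macro pixel signatures).  The manifest doubles as
the post-anonymization oracle: a byte-level scan over the emitted files
must find every payload before a run and none after a full run.

Generation is deterministic given the seed.  Tissue-level pixel data is
seeded pseudorandom noise; label and macro images carry an ASCII
signature spliced into the pixel bytes (uncompressed) or embedded in a
JPEG comment segment (compressed), so the signature survives into the
encoded byte stream and disappears when the image is blanked.

The module also provides neutral TIFF builders (`make_plain_tiff`,
`make_string_tag_tiff`) used to exercise chain unlinking and string
replacement in isolation.
"""

from __future__ import annotations

import base64
import io
import random
import struct
import zlib
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from PIL import Image

from .detect import VendorFormat
from . import tiffcore

__all__ = [
    "PlantedPayload",
    "FixtureSet",
    "make_fixture",
    "make_all_fixtures",
    "make_plain_tiff",
    "make_string_tag_tiff",
    "scan_for_payloads",
    "FIXTURE_FORMATS",
]

#: one spec per fixture the suite exercises: (format, bigtiff)
FIXTURE_FORMATS: tuple[tuple[VendorFormat, bool], ...] = (
    (VendorFormat.APERIO_SVS, False),
    (VendorFormat.APERIO_SVS, True),
    (VendorFormat.HAMAMATSU_NDPI, False),
    (VendorFormat.VENTANA_BIF, False),
    (VendorFormat.MIRAX_MRXS, False),
    (VendorFormat.PHILIPS_ISYNTAX, False),
)


@dataclass(frozen=True)
class PlantedPayload:
    role: str        # CASE_ID, BARCODE, SCANNER_SERIAL, ACQ_DATETIME, OPERATOR,
                     # LABEL_PIXELS, MACRO_PIXELS
    value: str       # ASCII byte string planted verbatim (>= 6 bytes, unique)
    kind: str        # "metadata" (registry-addressable) or "pixels"
    location: str    # human-readable address for debugging


@dataclass
class FixtureSet:
    format: VendorFormat
    path: Path                 # entry point handed to the anonymizer
    paths: list[Path]          # every emitted file
    manifest: list[PlantedPayload]
    bigtiff: bool = False

    def metadata_payloads(self) -> list[PlantedPayload]:
        return [p for p in self.manifest if p.kind == "metadata"]


# ---------------------------------------------------------------------------
# low-level TIFF writer

_TYPE_SIZES = {1: 1, 2: 1, 3: 2, 4: 4, 5: 8, 7: 1, 11: 4, 12: 8, 16: 8}
_TYPE_FMT = {1: "B", 3: "H", 4: "I", 11: "f", 16: "Q"}

ASCII = 2
SHORT = 3
LONG = 4
FLOAT = 11
LONG8 = 16


@dataclass
class IfdPlan:
    """Declarative description of one directory for the writer."""
    tags: dict[int, tuple[int, object]]   # code -> (dtype, values|bytes)
    blobs: list[bytes] = dataclass_field(default_factory=list)


class TiffWriter:
    """Append-only classic/BigTIFF serializer for fixture construction."""

    def __init__(self, bigtiff: bool = False, byteorder: str = "<"):
        self.bigtiff = bigtiff
        self.bo = byteorder
        self.buf = bytearray()
        order_mark = b"II" if byteorder == "<" else b"MM"
        if bigtiff:
            self.buf += order_mark + struct.pack(byteorder + "HHHQ", 43, 8, 0, 0)
            self.first_ifd_field = 8
        else:
            self.buf += order_mark + struct.pack(byteorder + "HI", 42, 0)
            self.first_ifd_field = 4
        self._pending_link: int | None = self.first_ifd_field

    def _align(self) -> None:
        if len(self.buf) % 2:
            self.buf += b"\x00"

    def _append(self, data: bytes) -> int:
        self._align()
        off = len(self.buf)
        self.buf += data
        return off

    def _encode_values(self, dtype: int, values) -> bytes:
        if dtype in (ASCII, 7):
            return bytes(values)
        fmt = _TYPE_FMT[dtype]
        return struct.pack(self.bo + fmt * len(values), *values)

    def add_ifd(self, plan: IfdPlan) -> int:
        offset_dtype = LONG8 if self.bigtiff else LONG
        tags = dict(plan.tags)
        if plan.blobs:
            blob_offsets = [self._append(b) for b in plan.blobs]
            off_code = (tiffcore.TILE_OFFSETS if tiffcore.TILE_WIDTH in tags
                        else tiffcore.STRIP_OFFSETS)
            cnt_code = (tiffcore.TILE_BYTE_COUNTS
                        if off_code == tiffcore.TILE_OFFSETS
                        else tiffcore.STRIP_BYTE_COUNTS)
            tags.setdefault(off_code, (offset_dtype, blob_offsets))
            tags.setdefault(cnt_code, (LONG, [len(b) for b in plan.blobs]))

        value_width = 8 if self.bigtiff else 4
        entry_size = 20 if self.bigtiff else 12
        count_fmt = "Q" if self.bigtiff else "H"
        cnt_width_fmt = "Q" if self.bigtiff else "I"

        # out-of-line payloads first so their offsets are known
        encoded: dict[int, tuple[int, int, bytes, int | None]] = {}
        for code in sorted(tags):
            dtype, values = tags[code]
            payload = self._encode_values(dtype, values)
            count = (len(payload) if dtype in (ASCII, 7)
                     else len(values))
            if len(payload) <= value_width:
                encoded[code] = (dtype, count, payload, None)
            else:
                encoded[code] = (dtype, count, payload, self._append(payload))

        self._align()
        ifd_offset = len(self.buf)
        self.buf += struct.pack(self.bo + count_fmt, len(encoded))
        for code in sorted(encoded):
            dtype, count, payload, out_off = encoded[code]
            entry = struct.pack(self.bo + "HH", code, dtype)
            entry += struct.pack(self.bo + cnt_width_fmt, count)
            if out_off is None:
                entry += payload.ljust(value_width, b"\x00")
            else:
                entry += struct.pack(self.bo + ("Q" if self.bigtiff else "I"),
                                     out_off)
            assert len(entry) == entry_size
            self.buf += entry
        next_field = len(self.buf)
        self.buf += b"\x00" * (8 if self.bigtiff else 4)

        if self._pending_link is not None:
            self._patch_offset(self._pending_link, ifd_offset)
        self._pending_link = next_field
        return ifd_offset

    def _patch_offset(self, field_offset: int, value: int) -> None:
        width = 8 if self.bigtiff else 4
        fmt = "Q" if self.bigtiff else "I"
        self.buf[field_offset:field_offset + width] = struct.pack(
            self.bo + fmt, value)

    def tobytes(self) -> bytes:
        return bytes(self.buf)


# ---------------------------------------------------------------------------
# payload fabrication helpers

def _tokens(seed: int) -> dict[str, str]:
    rng = random.Random(seed * 2654435761 % (2**31))
    def hx(n: int) -> str:
        return "".join(rng.choice("0123456789abcdef") for _ in range(n))
    y = rng.randrange(2015, 2023)
    mo, d = rng.randrange(1, 13), rng.randrange(1, 29)
    h, mi, s = rng.randrange(24), rng.randrange(60), rng.randrange(60)
    return {
        "case": f"CASE-{hx(8)}",
        "barcode": f"BC{hx(10).upper()}",
        "serial": f"SN-{hx(6).upper()}",
        "date": f"{mo:02d}/{d:02d}/{y % 100:02d}",
        "time": f"{h:02d}:{mi:02d}:{s:02d}",
        "datetime": f"{y:04d}:{mo:02d}:{d:02d} {h:02d}:{mi:02d}:{s:02d}",
        "dt14": f"{y:04d}{mo:02d}{d:02d}{h:02d}{mi:02d}{s:02d}",
        "operator": f"op_{hx(6)}",
        "labelpx": f"LBLPX_{hx(10)}",
        "macropx": f"MACPX_{hx(10)}",
    }


def _noise(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.integers(0, 256, size=shape, dtype=np.uint8)


def _jpeg_with_signature(rng: np.random.Generator, width: int, height: int,
                         signature: bytes, mode: str = "L") -> bytes:
    """A decodable JPEG whose byte stream contains ``signature`` verbatim.

    The signature rides in a COM segment directly after SOI, so blanking
    (re-encoding) removes it while any baseline decoder accepts the file.
    """
    shape = (height, width) if mode == "L" else (height, width, 3)
    im = Image.fromarray(_noise(rng, shape), mode=mode)
    buf = io.BytesIO()
    im.save(buf, format="JPEG", quality=90)
    data = buf.getvalue()
    com = b"\xff\xfe" + struct.pack(">H", len(signature) + 2) + signature
    return data[:2] + com + data[2:]


def _raw_with_signature(rng: np.random.Generator, nbytes: int,
                        signature: bytes, at: int = 64) -> bytes:
    raw = bytearray(_noise(rng, nbytes).tobytes())
    raw[at:at + len(signature)] = signature
    return bytes(raw)


def _gray_ifd(width: int, height: int, compression: int, blobs: list[bytes],
              description: bytes | None = None, rows_per_strip: int | None = None,
              samples: int = 1, extra: dict | None = None) -> IfdPlan:
    tags = {
        tiffcore.IMAGE_WIDTH: (LONG, [width]),
        tiffcore.IMAGE_LENGTH: (LONG, [height]),
        tiffcore.BITS_PER_SAMPLE: (SHORT, [8] * samples),
        tiffcore.COMPRESSION: (SHORT, [compression]),
        tiffcore.PHOTOMETRIC: (SHORT, [2 if samples == 3 else 1]),
        tiffcore.SAMPLES_PER_PIXEL: (SHORT, [samples]),
        tiffcore.ROWS_PER_STRIP: (LONG, [rows_per_strip or height]),
    }
    if description is not None:
        tags[tiffcore.IMAGE_DESCRIPTION] = (ASCII, description)
    if extra:
        tags.update(extra)
    return IfdPlan(tags=tags, blobs=blobs)


# ---------------------------------------------------------------------------
# per-format fixtures

def _strips(raw: bytes, width: int, rows_per_strip: int, height: int,
            samples: int = 1, compress=None) -> list[bytes]:
    row = width * samples
    out = []
    for start in range(0, height, rows_per_strip):
        rows = min(rows_per_strip, height - start)
        chunk = raw[start * row:(start + rows) * row]
        out.append(compress(chunk) if compress else chunk)
    return out


def _build_svs(out_dir: Path, seed: int, bigtiff: bool) -> FixtureSet:
    tok = _tokens(seed)
    rng = np.random.default_rng(seed)
    w = TiffWriter(bigtiff=bigtiff)

    desc0 = (
        "Aperio Image Library v12.0.15\r\n"
        "128x128 [0,0 128x128] (240x240) JPEG/RGB Q=30"
        f"|AppMag = 20|ScanScope ID = {tok['serial']}"
        f"|Filename = {tok['case']}|Date = {tok['date']}|Time = {tok['time']}"
        f"|User = {tok['operator']}|Barcode = {tok['barcode']}"
    ).encode() + b"\x00"
    base_raw = _noise(rng, 128 * 128).tobytes()
    lvl_raw = _noise(rng, 64 * 64).tobytes()
    w.add_ifd(_gray_ifd(
        128, 128, tiffcore.COMPRESSION_NONE,
        _strips(base_raw, 128, 64, 128),
        description=desc0, rows_per_strip=64,
        extra={tiffcore.MAKE: (ASCII, b"AP\x00"),
               tiffcore.SOFTWARE: (ASCII, b"ScanScope Console\x00")},
    ))
    w.add_ifd(_gray_ifd(
        64, 64, tiffcore.COMPRESSION_LZW,
        [tiffcore._lzw_encode(lvl_raw)],
        description=b"Aperio Image Library v12.0.15\r\n128x128 -> 64x64\x00",
    ))

    label = _jpeg_with_signature(rng, 64, 64, tok["labelpx"].encode())
    w.add_ifd(_gray_ifd(
        64, 64, tiffcore.COMPRESSION_JPEG, [label],
        description=b"Aperio Image Library v12.0.15\r\nlabel 64x64\x00",
    ))

    macro_raw = _raw_with_signature(rng, 64 * 48 * 3, tok["macropx"].encode())
    w.add_ifd(_gray_ifd(
        64, 48, tiffcore.COMPRESSION_NONE, [macro_raw], samples=3,
        description=b"Aperio Image Library v12.0.15\r\nmacro 64x48\x00",
    ))

    name = "slide_bigtiff.svs" if bigtiff else "slide.svs"
    path = out_dir / name
    path.write_bytes(w.tobytes())
    manifest = [
        PlantedPayload("CASE_ID", tok["case"], "metadata", "ifd0:description:Filename"),
        PlantedPayload("BARCODE", tok["barcode"], "metadata", "ifd0:description:Barcode"),
        PlantedPayload("SCANNER_SERIAL", tok["serial"], "metadata", "ifd0:description:ScanScope ID"),
        PlantedPayload("ACQ_DATETIME", tok["date"], "metadata", "ifd0:description:Date"),
        PlantedPayload("ACQ_DATETIME", tok["time"], "metadata", "ifd0:description:Time"),
        PlantedPayload("OPERATOR", tok["operator"], "metadata", "ifd0:description:User"),
        PlantedPayload("LABEL_PIXELS", tok["labelpx"], "pixels", "ifd2:jpeg-com"),
        PlantedPayload("MACRO_PIXELS", tok["macropx"], "pixels", "ifd3:raster"),
    ]
    return FixtureSet(VendorFormat.APERIO_SVS, path, [path], manifest, bigtiff)


NDPI_REFERENCE_TAG = 65427
NDPI_SERIAL_TAG = 65442


def _build_ndpi(out_dir: Path, seed: int) -> FixtureSet:
    tok = _tokens(seed + 1)
    rng = np.random.default_rng(seed + 1)
    w = TiffWriter()

    base_raw = _noise(rng, 128 * 128).tobytes()
    w.add_ifd(_gray_ifd(
        128, 128, tiffcore.COMPRESSION_NONE, _strips(base_raw, 128, 64, 128),
        rows_per_strip=64,
        extra={
            tiffcore.MODEL: (ASCII, b"NanoZoomer\x00"),
            tiffcore.DATETIME: (ASCII, tok["datetime"].encode() + b"\x00"),
            tiffcore.ARTIST: (ASCII, tok["operator"].encode() + b"\x00"),
            65420: (LONG, [1]),
            65421: (FLOAT, [20.0]),
            NDPI_REFERENCE_TAG: (ASCII, tok["barcode"].encode() + b"\x00"),
            NDPI_SERIAL_TAG: (ASCII, tok["serial"].encode() + b"\x00"),
        },
    ))
    lvl_raw = _noise(rng, 64 * 64).tobytes()
    w.add_ifd(_gray_ifd(64, 64, tiffcore.COMPRESSION_NONE, [lvl_raw],
                        extra={65420: (LONG, [1]), 65421: (FLOAT, [5.0])}))
    macro_raw = _raw_with_signature(rng, 96 * 64, tok["macropx"].encode())
    w.add_ifd(_gray_ifd(96, 64, tiffcore.COMPRESSION_NONE, [macro_raw],
                        extra={65420: (LONG, [1]), 65421: (FLOAT, [-1.0])}))

    path = out_dir / "slide.ndpi"
    path.write_bytes(w.tobytes())
    manifest = [
        PlantedPayload("BARCODE", tok["barcode"], "metadata", f"ifd0:tag:{NDPI_REFERENCE_TAG}"),
        PlantedPayload("SCANNER_SERIAL", tok["serial"], "metadata", f"ifd0:tag:{NDPI_SERIAL_TAG}"),
        PlantedPayload("ACQ_DATETIME", tok["datetime"], "metadata", "ifd0:tag:306"),
        PlantedPayload("OPERATOR", tok["operator"], "metadata", "ifd0:tag:315"),
        PlantedPayload("MACRO_PIXELS", tok["macropx"], "pixels", "ifd2:raster"),
    ]
    return FixtureSet(VendorFormat.HAMAMATSU_NDPI, path, [path], manifest)


def _build_bif(out_dir: Path, seed: int) -> FixtureSet:
    tok = _tokens(seed + 2)
    rng = np.random.default_rng(seed + 2)
    w = TiffWriter()

    desc0 = (
        f'<iScan UnitNumber="{tok["serial"]}" UserName="{tok["operator"]}" '
        f'ScanDate="{tok["dt14"]}" Barcode1D="{tok["barcode"]}" '
        f'Magnification="20" ScanMode="Regular" />'
    ).encode() + b"\x00"
    base_raw = _noise(rng, 128 * 128).tobytes()
    w.add_ifd(_gray_ifd(128, 128, tiffcore.COMPRESSION_NONE,
                        _strips(base_raw, 128, 64, 128),
                        description=desc0, rows_per_strip=64))
    lvl_raw = _noise(rng, 64 * 64).tobytes()
    w.add_ifd(_gray_ifd(64, 64, tiffcore.COMPRESSION_DEFLATE_ADOBE,
                        [zlib.compress(lvl_raw)],
                        description=b"Level 1\x00"))
    combined = _jpeg_with_signature(rng, 96, 64, tok["macropx"].encode())
    w.add_ifd(_gray_ifd(96, 64, tiffcore.COMPRESSION_JPEG, [combined],
                        description=b"Label Image\x00"))
    thumb_raw = _noise(rng, 48 * 32).tobytes()
    w.add_ifd(_gray_ifd(48, 32, tiffcore.COMPRESSION_NONE, [thumb_raw],
                        description=b"Thumbnail\x00"))

    path = out_dir / "slide.bif"
    path.write_bytes(w.tobytes())
    manifest = [
        PlantedPayload("SCANNER_SERIAL", tok["serial"], "metadata", "ifd0:xml:UnitNumber"),
        PlantedPayload("OPERATOR", tok["operator"], "metadata", "ifd0:xml:UserName"),
        PlantedPayload("ACQ_DATETIME", tok["dt14"], "metadata", "ifd0:xml:ScanDate"),
        PlantedPayload("BARCODE", tok["barcode"], "metadata", "ifd0:xml:Barcode1D"),
        PlantedPayload("MACRO_PIXELS", tok["macropx"], "pixels", "ifd2:jpeg-com"),
    ]
    return FixtureSet(VendorFormat.VENTANA_BIF, path, [path], manifest)


MIRAX_INDEX_MAGIC = b"MRXIDX01"
MIRAX_SUPPORTED_VERSION = "1.9"


def _build_mirax(out_dir: Path, seed: int) -> FixtureSet:
    tok = _tokens(seed + 3)
    rng = np.random.default_rng(seed + 3)
    slide_name = "slide"
    data_dir = out_dir / slide_name
    data_dir.mkdir(parents=True, exist_ok=True)

    label = _jpeg_with_signature(rng, 64, 64, tok["labelpx"].encode())
    macro = _jpeg_with_signature(rng, 96, 64, tok["macropx"].encode())
    barcode_blob = b"BARCODE:" + tok["barcode"].encode()
    dat0 = bytearray()
    spans0 = []
    for blob in (label, macro, barcode_blob):
        spans0.append((len(dat0), len(blob)))
        dat0 += blob
    tiles = [_noise(rng, 32 * 32).tobytes() for _ in range(4)]
    dat1 = bytearray()
    spans1 = []
    for t in tiles:
        spans1.append((len(dat1), len(t)))
        dat1 += t

    # records: (hier_type, layer_index, value_index, file_index, offset, length)
    records = [
        (1, 0, 0, 0, *spans0[0]),  # nonhier val 0: label
        (1, 0, 1, 0, *spans0[1]),  # nonhier val 1: thumbnail/macro
        (1, 0, 2, 0, *spans0[2]),  # nonhier val 2: barcode
    ] + [(0, 0, 0, 1, off, ln) for off, ln in spans1]
    index = bytearray(MIRAX_INDEX_MAGIC)
    index += struct.pack("<I", len(records))
    for rec in records:
        index += struct.pack("<IIIIQQ", *rec)

    slidedat = "\r\n".join([
        "[GENERAL]",
        f"SLIDE_VERSION = {MIRAX_SUPPORTED_VERSION}",
        f"SLIDE_ID = {tok['case']}",
        f"SLIDE_BARCODE = {tok['barcode']}",
        f"SLIDE_CREATIONDATETIME = {tok['dt14']}",
        f"SCANNER_HARDWARE_ID = {tok['serial']}",
        f"OPERATOR_NAME = {tok['operator']}",
        "IMAGENUMBER_X = 2",
        "IMAGENUMBER_Y = 2",
        "[HIERARCHICAL]",
        "HIER_COUNT = 1",
        "HIER_0_NAME = Slide zoom level",
        "HIER_0_COUNT = 1",
        "HIER_0_VAL_0 = ZoomLevel_0",
        "HIER_0_VAL_0_SECTION = LAYER_0_LEVEL_0_SECTION",
        "NONHIER_COUNT = 1",
        "NONHIER_0_NAME = Scan data layer",
        "NONHIER_0_COUNT = 3",
        "NONHIER_0_VAL_0 = ScanDataLayer_SlideLabel",
        "NONHIER_0_VAL_1 = ScanDataLayer_SlideThumbnail",
        "NONHIER_0_VAL_2 = ScanDataLayer_SlideBarcode",
        "[DATAFILE]",
        "FILE_COUNT = 2",
        "FILE_0 = Data0000.dat",
        "FILE_1 = Data0001.dat",
        "INDEX_FILE = Index.dat",
        "[LAYER_0_LEVEL_0_SECTION]",
        "IMAGE_FORMAT = RAW",
        "DIGITIZER_WIDTH = 32",
        "DIGITIZER_HEIGHT = 32",
        "",
    ])

    (data_dir / "Slidedat.ini").write_text(slidedat, newline="")
    (data_dir / "Index.dat").write_bytes(bytes(index))
    (data_dir / "Data0000.dat").write_bytes(bytes(dat0))
    (data_dir / "Data0001.dat").write_bytes(bytes(dat1))
    mrxs = out_dir / f"{slide_name}.mrxs"
    mrxs.write_bytes(b"MIRAX slide stub\x00")

    paths = [mrxs, data_dir / "Slidedat.ini", data_dir / "Index.dat",
             data_dir / "Data0000.dat", data_dir / "Data0001.dat"]
    manifest = [
        PlantedPayload("CASE_ID", tok["case"], "metadata", "slidedat:GENERAL:SLIDE_ID"),
        PlantedPayload("BARCODE", tok["barcode"], "metadata", "slidedat:GENERAL:SLIDE_BARCODE"),
        PlantedPayload("ACQ_DATETIME", tok["dt14"], "metadata", "slidedat:GENERAL:SLIDE_CREATIONDATETIME"),
        PlantedPayload("SCANNER_SERIAL", tok["serial"], "metadata", "slidedat:GENERAL:SCANNER_HARDWARE_ID"),
        PlantedPayload("OPERATOR", tok["operator"], "metadata", "slidedat:GENERAL:OPERATOR_NAME"),
        PlantedPayload("LABEL_PIXELS", tok["labelpx"], "pixels", "Data0000.dat:label"),
        PlantedPayload("MACRO_PIXELS", tok["macropx"], "pixels", "Data0000.dat:thumbnail"),
    ]
    return FixtureSet(VendorFormat.MIRAX_MRXS, mrxs, paths, manifest)


def _b64_signature(b64_text: str) -> str:
    """A scan-stable slice of a base64 payload (>= 6 chars, mid-stream)."""
    start = len(b64_text) // 3
    return b64_text[start:start + 24]


def _build_isyntax(out_dir: Path, seed: int) -> FixtureSet:
    tok = _tokens(seed + 4)
    rng = np.random.default_rng(seed + 4)

    def plain_jpeg(width, height):
        im = Image.fromarray(_noise(rng, (height, width)), mode="L")
        buf = io.BytesIO()
        im.save(buf, format="JPEG", quality=90)
        return buf.getvalue()

    label_b64 = base64.b64encode(plain_jpeg(128, 96)).decode()
    macro_b64 = base64.b64encode(plain_jpeg(96, 64)).decode()

    def attr(name, value, pmsvr="IString", constraint=None):
        c = f' Constraint="{constraint}"' if constraint else ""
        return (f'  <Attribute Name="{name}" Group="0x301D" PMSVR="{pmsvr}"{c}>'
                f"{value}</Attribute>")

    xml = "\n".join([
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<DataObject ObjectType="DPUfsImport">',
        attr("DICOM_ACCESSION_NUMBER", tok["case"]),
        attr("PIM_DP_UFS_BARCODE", tok["barcode"]),
        attr("DICOM_DEVICE_SERIAL_NUMBER", tok["serial"]),
        attr("DICOM_ACQUISITION_DATETIME", tok["dt14"],
             constraint="datetime:YYYYMMDDHHMMSS"),
        attr("PIIM_DP_SCANNER_OPERATOR_ID", tok["operator"]),
        attr("PIM_DP_SCANNER_RACK_NUMBER", "3", pmsvr="IUInt16",
             constraint="range:1,15"),
        '  <DataObject ObjectType="DPScannedImage">',
        attr("PIM_DP_IMAGE_TYPE", "LABELIMAGE"),
        attr("PIM_DP_IMAGE_DATA", label_b64),
        "  </DataObject>",
        '  <DataObject ObjectType="DPScannedImage">',
        attr("PIM_DP_IMAGE_TYPE", "MACROIMAGE"),
        attr("PIM_DP_IMAGE_DATA", macro_b64),
        "  </DataObject>",
        '  <DataObject ObjectType="DPScannedImage">',
        attr("PIM_DP_IMAGE_TYPE", "WSI"),
        "  </DataObject>",
        "</DataObject>",
        "",
    ])
    body = _noise(rng, 4096).tobytes()
    path = out_dir / "slide.isyntax"
    path.write_bytes(xml.encode() + b"\x04" + body)

    manifest = [
        PlantedPayload("CASE_ID", tok["case"], "metadata", "xml:DICOM_ACCESSION_NUMBER"),
        PlantedPayload("BARCODE", tok["barcode"], "metadata", "xml:PIM_DP_UFS_BARCODE"),
        PlantedPayload("SCANNER_SERIAL", tok["serial"], "metadata", "xml:DICOM_DEVICE_SERIAL_NUMBER"),
        PlantedPayload("ACQ_DATETIME", tok["dt14"], "metadata", "xml:DICOM_ACQUISITION_DATETIME"),
        PlantedPayload("OPERATOR", tok["operator"], "metadata", "xml:PIIM_DP_SCANNER_OPERATOR_ID"),
        PlantedPayload("LABEL_PIXELS", _b64_signature(label_b64), "pixels",
                       "xml:LABELIMAGE:base64"),
        PlantedPayload("MACRO_PIXELS", _b64_signature(macro_b64), "pixels",
                       "xml:MACROIMAGE:base64"),
    ]
    return FixtureSet(VendorFormat.PHILIPS_ISYNTAX, path, [path], manifest)


def make_fixture(fmt: VendorFormat, out_dir: str | Path, seed: int = 7,
                 bigtiff: bool = False) -> FixtureSet:
    """Fabricate one slide fixture; deterministic for a given seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bigtiff and fmt is not VendorFormat.APERIO_SVS:
        raise ValueError(f"bigtiff layout not defined for {fmt}")
    if fmt is VendorFormat.APERIO_SVS:
        return _build_svs(out_dir, seed, bigtiff)
    if fmt is VendorFormat.HAMAMATSU_NDPI:
        return _build_ndpi(out_dir, seed)
    if fmt is VendorFormat.VENTANA_BIF:
        return _build_bif(out_dir, seed)
    if fmt is VendorFormat.MIRAX_MRXS:
        return _build_mirax(out_dir, seed)
    if fmt is VendorFormat.PHILIPS_ISYNTAX:
        return _build_isyntax(out_dir, seed)
    raise ValueError(f"no fixture builder for {fmt}")


def make_all_fixtures(out_dir: str | Path, seed: int = 7) -> list[FixtureSet]:
    out_dir = Path(out_dir)
    sets = []
    for fmt, bigtiff in FIXTURE_FORMATS:
        sub = out_dir / (fmt.value + ("_bigtiff" if bigtiff else ""))
        sets.append(make_fixture(fmt, sub, seed=seed, bigtiff=bigtiff))
    return sets


# ---------------------------------------------------------------------------
# neutral TIFFs for structural tests

def make_plain_tiff(path: str | Path, n_ifds: int = 5, seed: int = 0,
                    bigtiff: bool = False, byteorder: str = "<") -> Path:
    """A generic multi-IFD grayscale TIFF with no vendor markers."""
    rng = np.random.default_rng(seed)
    w = TiffWriter(bigtiff=bigtiff, byteorder=byteorder)
    for i in range(n_ifds):
        side = 32 - 2 * i
        raw = _noise(rng, side * side).tobytes()
        w.add_ifd(_gray_ifd(side, side, tiffcore.COMPRESSION_NONE, [raw],
                            description=f"plain ifd {i}\x00".encode()))
    path = Path(path)
    path.write_bytes(w.tobytes())
    return path


def make_string_tag_tiff(path: str | Path, n_tags: int, seed: int = 0,
                         bigtiff: bool = False) -> tuple[Path, dict[int, bytes]]:
    """One-IFD TIFF holding many randomized ASCII tags.

    Tags mix inline and out-of-line storage and NUL-terminated and
    unterminated strings; returns the expected payload per tag code.
    """
    rng = random.Random(seed)
    nprng = np.random.default_rng(seed)
    w = TiffWriter(bigtiff=bigtiff)
    raw = _noise(nprng, 16 * 16).tobytes()
    expected: dict[int, bytes] = {}
    extra: dict[int, tuple[int, object]] = {}
    for i in range(n_tags):
        code = 60000 + i  # unassigned private range; no reader semantics
        length = rng.choice([1, 2, 3, 4, 5, 7, 8, 9, 15, 31, 64])
        s = bytes(rng.randrange(0x20, 0x7F) for _ in range(length))
        if rng.random() < 0.5:
            s += b"\x00"
        expected[code] = s
        extra[code] = (ASCII, s)
    w.add_ifd(_gray_ifd(16, 16, tiffcore.COMPRESSION_NONE, [raw], extra=extra))
    path = Path(path)
    path.write_bytes(w.tobytes())
    return path, expected


# ---------------------------------------------------------------------------
# byte-scan oracle

def scan_for_payloads(paths, manifest, kinds=("metadata", "pixels")):
    """Exhaustive substring scan for planted payloads over whole files.

    Scans every byte of every file (including unreferenced regions) and
    returns the list of (payload, path, offset) hits.  Used as the
    post-anonymization emptiness oracle.
    """
    hits = []
    for p in map(Path, paths):
        if p.is_dir():
            continue
        data = p.read_bytes()
        for payload in manifest:
            if payload.kind not in kinds:
                continue
            needle = payload.value.encode()
            start = 0
            while True:
                idx = data.find(needle, start)
                if idx < 0:
                    break
                hits.append((payload, p, idx))
                start = idx + 1
    return hits
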