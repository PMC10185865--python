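"""Vendor/file-format identification for whole-slide images.

Scanner vendors ship proprietary containers: Aperio/Leica SVS and
Ventana BIF are TIFF (or BigTIFF) files distinguished by their first
directory's ImageDescription, Hamamatsu NDPI is a TIFF dialect carrying
private tags, 3DHistech Mirax is a directory set next to a ``.mrxs``
stub, and Philips iSyntax opens with an XML header.  Detection is
read-only and constant-time: magic bytes first, extension second, then a
structural probe of at most the first 64 KiB plus the first IFD.  A TIFF
without any vendor marker is reported as GENERIC_TIFF so it can still be
anonymized with a generic profile; an extension alone never decides a
TIFF-family format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import tiffcore

__all__ = ["VendorFormat", "DetectionResult", "detect_format"]

_PROBE_BYTES = 64 * 1024

APERIO_MARKER = b"Aperio"
VENTANA_MARKER = b"iScan"
NDPI_FORMAT_FLAG_TAG = 65420  # Hamamatsu private marker tag
NDPI_SOURCE_LENS_TAG = 65421


class VendorFormat(Enum):
    APERIO_SVS = "aperio_svs"
    HAMAMATSU_NDPI = "hamamatsu_ndpi"
    VENTANA_BIF = "ventana_bif"
    MIRAX_MRXS = "mirax_mrxs"
    PHILIPS_ISYNTAX = "philips_isyntax"
    GENERIC_TIFF = "generic_tiff"
    UNSUPPORTED = "unsupported"


#: formats the anonymizer can process
SUPPORTED_FORMATS = frozenset({
    VendorFormat.APERIO_SVS,
    VendorFormat.HAMAMATSU_NDPI,
    VendorFormat.VENTANA_BIF,
    VendorFormat.MIRAX_MRXS,
    VendorFormat.PHILIPS_ISYNTAX,
    VendorFormat.GENERIC_TIFF,
})


@dataclass
class DetectionResult:
    format: VendorFormat
    evidence: list[str] = field(default_factory=list)
    is_bigtiff: bool = False  # meaningful for the TIFF family only


def _mirax_companion_dir(path: Path) -> Path | None:
    """The sibling data directory of a .mrxs stub, if structurally valid."""
    data_dir = path.with_suffix("")
    if data_dir.is_dir() and (data_dir / "Slidedat.ini").is_file():
        return data_dir
    return None


def _probe_tiff(path: Path, head: bytes) -> DetectionResult:
    evidence = []
    order = "II" if head[:2] == b"II" else "MM"
    try:
        with path.open("rb") as fh:
            header = tiffcore.parse_header(fh)
            fh.seek(0, io.SEEK_END)
            size = fh.tell()
            first_ifd = tiffcore._parse_ifd(fh, header, header.first_ifd_offset,
                                            size)
            evidence.append(
                f"TIFF magic {order}{'+BigTIFF' if header.is_bigtiff else '*'}"
            )
            desc = b""
            entry = first_ifd.tags.get(tiffcore.IMAGE_DESCRIPTION)
            if entry is not None and entry.dtype == tiffcore.ASCII:
                desc = tiffcore.read_tag_bytes(fh, entry)
    except tiffcore.TiffError as exc:
        return DetectionResult(VendorFormat.UNSUPPORTED,
                               [f"TIFF magic but unparseable: {exc}"])

    bigtiff = header.is_bigtiff
    if desc.startswith(APERIO_MARKER):
        evidence.append("ImageDescription starts with Aperio marker")
        return DetectionResult(VendorFormat.APERIO_SVS, evidence, bigtiff)
    if NDPI_FORMAT_FLAG_TAG in first_ifd.tags:
        evidence.append(f"NDPI private tag {NDPI_FORMAT_FLAG_TAG} present")
        return DetectionResult(VendorFormat.HAMAMATSU_NDPI, evidence, bigtiff)
    if VENTANA_MARKER in desc:
        evidence.append("ImageDescription contains Ventana iScan XML")
        return DetectionResult(VendorFormat.VENTANA_BIF, evidence, bigtiff)
    if path.suffix.lower() == ".ndpi":
        evidence.append(".ndpi extension on a plain TIFF")
        return DetectionResult(VendorFormat.HAMAMATSU_NDPI, evidence, bigtiff)
    evidence.append("no vendor marker in first IFD")
    return DetectionResult(VendorFormat.GENERIC_TIFF, evidence, bigtiff)


def _probe_isyntax(head: bytes) -> DetectionResult | None:
    stripped = head.lstrip()
    if not (stripped.startswith(b"<?xml") or stripped.startswith(b"<DataObject")):
        return None
    if b"DataObject" in head or b"isyntax" in head.lower():
        return DetectionResult(
            VendorFormat.PHILIPS_ISYNTAX,
            ["leading XML declaration", "iSyntax DataObject root"],
        )
    return DetectionResult(VendorFormat.UNSUPPORTED,
                           ["XML prolog but no iSyntax root"])


def detect_format(path: str | Path) -> DetectionResult:
    """Identify the vendor format of a slide file or Mirax slide set.

    Never modifies the input.  An unreadable path raises ``OSError``; a
    zero-length or unrecognized file yields ``UNSUPPORTED``.
    """
    path = Path(path)
    if path.is_dir():
        # a Mirax data directory given directly
        if (path / "Slidedat.ini").is_file():
            return DetectionResult(
                VendorFormat.MIRAX_MRXS,
                ["directory contains Slidedat.ini"],
            )
        return DetectionResult(VendorFormat.UNSUPPORTED, [])
    with path.open("rb") as fh:
        head = fh.read(_PROBE_BYTES)
    if not head:
        return DetectionResult(VendorFormat.UNSUPPORTED, [])

    if head[:4] in (b"II\x2a\x00", b"MM\x00\x2a", b"II\x2b\x00", b"MM\x00\x2b"):
        return _probe_tiff(path, head)

    xml = _probe_isyntax(head)
    if xml is not None:
        return xml

    if path.suffix.lower() == ".mrxs":
        companion = _mirax_companion_dir(path)
        if companion is not None:
            return DetectionResult(
                VendorFormat.MIRAX_MRXS,
                [".mrxs stub", f"companion directory {companion.name}/ with Slidedat.ini"],
            )
        return DetectionResult(VendorFormat.UNSUPPORTED,
                               [".mrxs stub without companion Slidedat.ini"])

    return DetectionResult(VendorFormat.UNSUPPORTED, [])
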