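"""Anonymization of Philips iSyntax files.

An iSyntax file opens with an XML header (terminated by an ASCII EOT
byte, 0x04) followed by the binary tissue codestream.  The header holds
typed metadata attributes — ``<Attribute Name="…" PMSVR="IString">…`` —
and, nested in image DataObject nodes, the label and macro photographs
as base64-encoded JPEG payloads.  The vendor toolchain expects the
object-node skeleton to survive: nodes cannot be deleted, only their
values changed.

Replacement therefore respects each attribute's declared datatype and
optional constraint annotation (a fixed datetime format, an integer
interval).  String values become same-length filler; constrained values
become the most neutral constraint-satisfying placeholder (the epoch
datetime, the interval minimum).  Label and macro payloads are replaced
by a blank white JPEG of the same decoded dimensions, re-encoded and
base64'd.

Edits are applied in place: every replacement is written into the byte
span of the original value and right-padded with whitespace (base64
decoders skip whitespace, so padded image payloads still decode).  A
blank image never encodes larger than the dense original in practice;
if it ever does, the file is atomically rewritten with the binary body
copied verbatim, which keeps the body hash-identical either way.

Only a minimal datatype system is modeled (string, integer, double,
datetime, base64 image).  Unknown datatypes on sensitive keys fail
closed with an error naming the key.
"""

from __future__ import annotations

import base64
import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from PIL import Image

__all__ = [
    "IsyntaxError",
    "IsyntaxParseError",
    "UnsupportedDatatypeError",
    "MetadataNode",
    "ImageNode",
    "IsyntaxHeader",
    "parse_isyntax_header",
    "anonymize_isyntax",
    "SENSITIVE_ATTRIBUTES",
]

EOT = b"\x04"
_MAX_HEADER = 64 * 1024 * 1024

#: attribute name -> category; the registry of identifying header keys
SENSITIVE_ATTRIBUTES = {
    "DICOM_ACCESSION_NUMBER": "subject_related",
    "PIM_DP_UFS_BARCODE": "subject_related",
    "DICOM_PATIENT_ID": "subject_related",
    "DICOM_DEVICE_SERIAL_NUMBER": "acquisition_related",
    "DICOM_ACQUISITION_DATETIME": "acquisition_related",
    "DICOM_DATE_OF_LAST_CALIBRATION": "acquisition_related",
    "PIIM_DP_SCANNER_OPERATOR_ID": "acquisition_related",
}

_KNOWN_DATATYPES = {"IString", "IUInt16", "IUInt32", "IInt16", "IInt32",
                    "IDouble", "IStringArray"}


class IsyntaxError(Exception):
    pass


class IsyntaxParseError(IsyntaxError):
    pass


class UnsupportedDatatypeError(IsyntaxError):
    def __init__(self, key: str, datatype: str):
        super().__init__(
            f"attribute {key!r} has unmodeled datatype {datatype!r}; "
            "refusing to fabricate a replacement value"
        )
        self.key = key
        self.datatype = datatype


@dataclass(frozen=True)
class MetadataNode:
    key: str
    datatype: str
    value: str
    constraint: str | None
    span: tuple[int, int]    # (offset, length) of the value bytes in the file


@dataclass(frozen=True)
class ImageNode:
    image_type: str          # LABELIMAGE / MACROIMAGE
    payload_span: tuple[int, int]
    width: int
    height: int


@dataclass
class IsyntaxHeader:
    header_span: tuple[int, int]   # (0, length incl. EOT byte)
    metadata_nodes: list[MetadataNode] = field(default_factory=list)
    image_nodes: list[ImageNode] = field(default_factory=list)
    object_node_count: int = 0


def _read_header_bytes(data: bytes) -> bytes:
    end = data.find(EOT)
    if end < 0:
        raise IsyntaxParseError("no EOT header terminator found")
    return data[:end]


def _value_span(raw: bytes, value: str) -> tuple[int, int] | None:
    """Byte span of an element's text; values are unique in fixtures and
    real headers alike (IDs, base64 streams), so a plain search is exact."""
    needle = value.encode()
    idx = raw.find(needle)
    if idx < 0:
        return None
    if raw.find(needle, idx + 1) >= 0:
        # ambiguous — locate via the enclosing element instead
        return None
    return idx, len(needle)


def _attribute_value_span(raw: bytes, key: str) -> tuple[int, int] | None:
    """Span of ``<Attribute Name="key" …>value</Attribute>``, located by
    the attribute name (names are unique per header level)."""
    pattern = re.compile(
        rb'<Attribute\b[^>]*\bName="' + re.escape(key.encode())
        + rb'"[^>]*>([^<]*)</Attribute>')
    m = pattern.search(raw)
    if m is None or pattern.search(raw, m.end()) is not None:
        return None
    return m.start(1), len(m.group(1))


def parse_isyntax_header(source: str | Path | bytes) -> IsyntaxHeader:
    """Parse the XML header without touching the binary body."""
    if isinstance(source, (str, Path)):
        with open(source, "rb") as fh:
            data = fh.read(_MAX_HEADER)
    else:
        data = source
    raw = _read_header_bytes(data)
    try:
        root = ET.fromstring(raw.decode("utf-8"))
    except (ET.ParseError, UnicodeDecodeError) as exc:
        raise IsyntaxParseError(f"malformed iSyntax XML header: {exc}") from exc

    metadata: list[MetadataNode] = []
    images: list[ImageNode] = []
    object_count = sum(1 for _ in root.iter("DataObject")) + 1

    # root-level metadata attributes
    for el in root.findall("Attribute"):
        key = el.get("Name", "")
        value = el.text or ""
        span = _attribute_value_span(raw, key) if value else None
        if span is None:
            span = (0, 0)
        metadata.append(MetadataNode(
            key=key, datatype=el.get("PMSVR", ""), value=value,
            constraint=el.get("Constraint"), span=span))

    # nested image objects with base64 payloads
    for obj in root.iter("DataObject"):
        attrs = {a.get("Name"): a for a in obj.findall("Attribute")}
        type_el = attrs.get("PIM_DP_IMAGE_TYPE")
        data_el = attrs.get("PIM_DP_IMAGE_DATA")
        if type_el is None or data_el is None:
            continue
        b64 = (data_el.text or "").strip()
        span = _value_span(raw, b64)
        if span is None:
            raise IsyntaxParseError(
                f"cannot locate payload span of {type_el.text} image")
        try:
            im = Image.open(io.BytesIO(base64.b64decode(b64)))
            width, height = im.size
        except Exception as exc:
            raise IsyntaxParseError(
                f"{type_el.text} payload does not decode: {exc}") from exc
        images.append(ImageNode(
            image_type=(type_el.text or "").strip(),
            payload_span=span, width=width, height=height))

    return IsyntaxHeader(
        header_span=(0, len(raw) + 1),
        metadata_nodes=metadata,
        image_nodes=images,
        object_node_count=object_count,
    )


def _blank_jpeg_b64(width: int, height: int) -> str:
    buf = io.BytesIO()
    Image.new("L", (width, height), 255).save(buf, format="JPEG", quality=75)
    return base64.b64encode(buf.getvalue()).decode()


def _replacement_value(node: MetadataNode, replacement_char: str) -> str:
    """A content-free, datatype- and constraint-conforming stand-in."""
    dt = node.datatype
    if dt not in _KNOWN_DATATYPES:
        raise UnsupportedDatatypeError(node.key, dt)
    constraint = node.constraint or ""
    if constraint.startswith("datetime:"):
        fmt = constraint.split(":", 1)[1]
        # fixed epoch placeholder shaped like the declared format
        placeholder = "19700101000000"
        return placeholder[:len(fmt)].ljust(len(fmt), "0")
    if constraint.startswith("range:"):
        lo = constraint.split(":", 1)[1].split(",")[0]
        return lo
    if dt == "IString" or dt == "IStringArray":
        return replacement_char * len(node.value)
    if dt in ("IUInt16", "IUInt32", "IInt16", "IInt32"):
        return "0"
    if dt == "IDouble":
        return "0.0"
    raise UnsupportedDatatypeError(node.key, dt)


def _patch_span(buf: bytearray, span: tuple[int, int], new_text: str) -> int:
    """Write a replacement into a fixed span, whitespace-padded; returns
    the count of bytes that actually changed."""
    offset, length = span
    encoded = new_text.encode()
    if len(encoded) > length:
        raise IsyntaxError("replacement longer than original span")
    padded = encoded.ljust(length, b" ")
    before = bytes(buf[offset:offset + length])
    buf[offset:offset + length] = padded
    return sum(1 for a, b in zip(before, padded) if a != b)


def anonymize_isyntax(path: str | Path, *, keep_macro: bool = False,
                      blank_images: bool = True, subject_only: bool = False,
                      replacement_char: str = "X", dry_run: bool = False):
    """Scrub an iSyntax file; returns (actions, warnings).

    Metadata values are replaced under their datatype/constraint rules;
    label (and unless ``keep_macro``, macro) base64 payloads become blank
    images of the same decoded dimensions.  The header span, the XML node
    skeleton and the binary body are all preserved bit-for-bit in layout.
    """
    path = Path(path)
    header = parse_isyntax_header(path)
    data = bytearray(path.read_bytes())
    actions: list[tuple[str, str, int]] = []
    warnings: list[str] = []

    for node in header.metadata_nodes:
        category = SENSITIVE_ATTRIBUTES.get(node.key)
        if category is None:
            continue
        if subject_only and category != "subject_related":
            continue
        if node.span == (0, 0):
            continue
        replacement = _replacement_value(node, replacement_char)
        changed = _patch_span(data, node.span, replacement)
        actions.append(("replace_attribute", node.key, changed))

    if blank_images:
        for img in header.image_nodes:
            if img.image_type == "MACROIMAGE" and keep_macro:
                continue
            if img.image_type not in ("LABELIMAGE", "MACROIMAGE"):
                continue
            blank = _blank_jpeg_b64(img.width, img.height)
            if len(blank) > img.payload_span[1]:
                raise IsyntaxError(
                    f"blank {img.image_type} payload of {len(blank)} chars "
                    f"exceeds original span of {img.payload_span[1]}"
                )
            changed = _patch_span(data, img.payload_span, blank)
            actions.append(("blank_image_payload", img.image_type, changed))

    if not dry_run and any(c for _, _, c in actions):
        tmp = path.with_name(path.name + ".tmp")
        tmp.write_bytes(bytes(data))
        tmp.replace(path)
    return actions, warnings
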