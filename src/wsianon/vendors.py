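"""Per-vendor sensitivity registries for the TIFF-family formats.

A :class:`VendorProfile` records, for one scanner format, which tag- or
description-held fields identify the patient (case ID, barcode) or the
acquisition (serial number, date/time, operator), how each is
neutralized, and how the directories of the file map onto roles
(baseline, pyramid level, label, macro).  Metadata is grouped into two
categories — subject-related and acquisition-related — because GDPR-style
policies treat them differently: removing subject data plus the label
image gives Level III, removing both categories gives Level IV.

The registries are reconstructed from public format knowledge:

* Aperio/Leica SVS stores ``Key = value`` fields inside the first
  directory's ImageDescription; label/macro directories announce
  themselves in their own descriptions.
* Hamamatsu NDPI uses private tags (65427 slide reference/barcode,
  65442 scanner serial) plus standard DateTime/Artist; the directory
  with source-lens value -1 is the combined label+macro photograph,
  which cannot be removed separately from the label.
* Ventana BIF embeds an ``<iScan …>`` XML fragment in the baseline
  ImageDescription; the associated photograph is likewise combined.

Vendors revise these formats continuously, so profiles are data, not
code: :func:`load_profile` reads the same structure from a JSON file.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import BinaryIO

from . import tiffcore
from .detect import (NDPI_FORMAT_FLAG_TAG, NDPI_SOURCE_LENS_TAG, VendorFormat)
from .tiffcore import Ifd, IfdRole, TiffStructure

__all__ = [
    "Locator",
    "Category",
    "Action",
    "SensitiveField",
    "SensitiveOccurrence",
    "VendorProfile",
    "default_profile",
    "load_profile",
    "profile_from_dict",
    "classify_roles",
    "sensitive_occurrences",
]

NDPI_REFERENCE_TAG = 65427
NDPI_SERIAL_TAG = 65442


class Locator(Enum):
    TAG = "tag"                      # whole ASCII TIFF tag
    DESCRIPTION_KEY = "description_key"  # `Key = value` inside ImageDescription
    XML_ATTRIBUTE = "xml_attribute"  # attribute inside an XML ImageDescription


class Category(Enum):
    SUBJECT_RELATED = "subject_related"
    ACQUISITION_RELATED = "acquisition_related"


class Action(Enum):
    SAME_LENGTH_REPLACE = "same_length_replace"
    BLANK_IMAGE = "blank_image"
    UNLINK = "unlink"
    ZERO = "zero"


@dataclass(frozen=True)
class SensitiveField:
    locator: Locator
    identifier: str | int   # tag code, description key, or XML attribute name
    category: Category
    action: Action = Action.SAME_LENGTH_REPLACE


@dataclass(frozen=True)
class SensitiveOccurrence:
    """A concrete, patchable location of a sensitive value in the file."""
    field: SensitiveField
    ifd_index: int
    offset: int      # absolute file offset of the value bytes
    length: int      # byte length of the value
    digest: str      # short content digest of the current value

    @property
    def category(self) -> Category:
        return self.field.category


@dataclass
class VendorProfile:
    format: VendorFormat
    sensitive_fields: list[SensitiveField] = field(default_factory=list)
    #: False where label and macro are one photograph that cannot be
    #: deleted separately (Hamamatsu NDPI, Ventana BIF)
    macro_separable: bool = True


_SVS_PROFILE = VendorProfile(
    format=VendorFormat.APERIO_SVS,
    macro_separable=True,
    sensitive_fields=[
        SensitiveField(Locator.DESCRIPTION_KEY, "Filename", Category.SUBJECT_RELATED),
        SensitiveField(Locator.DESCRIPTION_KEY, "Barcode", Category.SUBJECT_RELATED),
        SensitiveField(Locator.DESCRIPTION_KEY, "ScanScope ID", Category.ACQUISITION_RELATED),
        SensitiveField(Locator.DESCRIPTION_KEY, "Date", Category.ACQUISITION_RELATED),
        SensitiveField(Locator.DESCRIPTION_KEY, "Time", Category.ACQUISITION_RELATED),
        SensitiveField(Locator.DESCRIPTION_KEY, "User", Category.ACQUISITION_RELATED),
    ],
)

_NDPI_PROFILE = VendorProfile(
    format=VendorFormat.HAMAMATSU_NDPI,
    macro_separable=False,
    sensitive_fields=[
        SensitiveField(Locator.TAG, NDPI_REFERENCE_TAG, Category.SUBJECT_RELATED),
        SensitiveField(Locator.TAG, NDPI_SERIAL_TAG, Category.ACQUISITION_RELATED),
        SensitiveField(Locator.TAG, tiffcore.DATETIME, Category.ACQUISITION_RELATED),
        SensitiveField(Locator.TAG, tiffcore.ARTIST, Category.ACQUISITION_RELATED),
    ],
)

_BIF_PROFILE = VendorProfile(
    format=VendorFormat.VENTANA_BIF,
    macro_separable=False,
    sensitive_fields=[
        SensitiveField(Locator.XML_ATTRIBUTE, "Barcode1D", Category.SUBJECT_RELATED),
        SensitiveField(Locator.XML_ATTRIBUTE, "UnitNumber", Category.ACQUISITION_RELATED),
        SensitiveField(Locator.XML_ATTRIBUTE, "UserName", Category.ACQUISITION_RELATED),
        SensitiveField(Locator.XML_ATTRIBUTE, "ScanDate", Category.ACQUISITION_RELATED),
    ],
)

_GENERIC_PROFILE = VendorProfile(
    format=VendorFormat.GENERIC_TIFF,
    macro_separable=True,
    sensitive_fields=[],
)

_DEFAULTS = {
    VendorFormat.APERIO_SVS: _SVS_PROFILE,
    VendorFormat.HAMAMATSU_NDPI: _NDPI_PROFILE,
    VendorFormat.VENTANA_BIF: _BIF_PROFILE,
    VendorFormat.GENERIC_TIFF: _GENERIC_PROFILE,
}


def default_profile(fmt: VendorFormat) -> VendorProfile:
    """The built-in registry for a TIFF-family format."""
    try:
        return _DEFAULTS[fmt]
    except KeyError:
        raise ValueError(f"no TIFF-family profile for {fmt}") from None


def profile_from_dict(spec: dict) -> VendorProfile:
    """Build a profile from plain data (the JSON profile file schema).

    Schema::

        {"format": "aperio_svs",
         "macro_separable": true,
         "sensitive_fields": [
            {"locator": "tag" | "description_key" | "xml_attribute",
             "identifier": 306 | "Barcode",
             "category": "subject_related" | "acquisition_related",
             "action": "same_length_replace" (default)}, ...]}
    """
    fields = [
        SensitiveField(
            locator=Locator(f["locator"]),
            identifier=f["identifier"],
            category=Category(f["category"]),
            action=Action(f.get("action", "same_length_replace")),
        )
        for f in spec.get("sensitive_fields", [])
    ]
    return VendorProfile(
        format=VendorFormat(spec["format"]),
        sensitive_fields=fields,
        macro_separable=bool(spec.get("macro_separable", True)),
    )


def load_profile(path: str | Path) -> VendorProfile:
    return profile_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# role classification

def _description(stream: BinaryIO, tiff: TiffStructure, ifd: Ifd) -> bytes:
    entry = ifd.tags.get(tiffcore.IMAGE_DESCRIPTION)
    if entry is None or entry.dtype != tiffcore.ASCII:
        return b""
    return tiffcore.read_tag_bytes(stream, entry)


def _classify_by_description(stream, tiff, combined: bool) -> dict[int, IfdRole]:
    roles: dict[int, IfdRole] = {}
    have_label = have_macro = False
    for i, ifd in enumerate(tiff.ifds):
        desc = _description(stream, tiff, ifd).lower()
        if b"label" in desc and not combined and not have_label:
            roles[i] = IfdRole.LABEL
            have_label = True
        elif b"label" in desc and combined and not have_macro:
            # combined label+macro photograph: one image, classified macro
            roles[i] = IfdRole.MACRO
            have_macro = True
        elif b"macro" in desc and not have_macro:
            roles[i] = IfdRole.MACRO
            have_macro = True
        elif b"thumbnail" in desc:
            roles[i] = IfdRole.THUMBNAIL
        elif i == 0:
            roles[i] = IfdRole.BASELINE
        elif desc:
            roles[i] = IfdRole.PYRAMID_LEVEL
        else:
            roles[i] = IfdRole.UNKNOWN
    return roles


def _classify_ndpi(stream, tiff) -> dict[int, IfdRole]:
    roles: dict[int, IfdRole] = {}
    have_macro = False
    for i, ifd in enumerate(tiff.ifds):
        lens = tiffcore.tag_scalar(stream, tiff.header, ifd, NDPI_SOURCE_LENS_TAG)
        if lens is not None and lens < 0 and not have_macro:
            # source lens -1: the combined label+macro photograph
            roles[i] = IfdRole.MACRO
            have_macro = True
        elif i == 0:
            roles[i] = IfdRole.BASELINE
        elif lens is not None:
            roles[i] = IfdRole.PYRAMID_LEVEL
        else:
            roles[i] = IfdRole.UNKNOWN
    return roles


def _classify_generic(stream, tiff) -> dict[int, IfdRole]:
    roles: dict[int, IfdRole] = {}
    for i, ifd in enumerate(tiff.ifds):
        desc = _description(stream, tiff, ifd).lower()
        if b"label" in desc:
            roles[i] = IfdRole.LABEL
        elif b"macro" in desc:
            roles[i] = IfdRole.MACRO
        else:
            roles[i] = IfdRole.UNKNOWN
    return roles


def classify_roles(stream: BinaryIO, tiff: TiffStructure,
                   profile: VendorProfile) -> dict[int, IfdRole]:
    """Assign a role to every directory; at most one LABEL and one MACRO."""
    if profile.format is VendorFormat.HAMAMATSU_NDPI:
        roles = _classify_ndpi(stream, tiff)
    elif profile.format is VendorFormat.GENERIC_TIFF:
        roles = _classify_generic(stream, tiff)
    else:
        roles = _classify_by_description(
            stream, tiff, combined=not profile.macro_separable)
    tiff.roles = roles
    return roles


# ---------------------------------------------------------------------------
# sensitive-metadata location

def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:12]


_KEY_VALUE_RE = re.compile(rb"\|([^|=]+?) = ([^|\x00]*)")


def _description_key_spans(desc: bytes) -> dict[str, tuple[int, int]]:
    """Spans of the value part of each `|Key = value` field."""
    spans = {}
    for m in _KEY_VALUE_RE.finditer(desc):
        key = m.group(1).decode("ascii", "replace").strip()
        spans[key] = (m.start(2), len(m.group(2)))
    return spans


def _xml_attribute_spans(desc: bytes) -> dict[str, tuple[int, int]]:
    spans = {}
    for m in re.finditer(rb'([A-Za-z_][\w.]*)="([^"]*)"', desc):
        spans[m.group(1).decode()] = (m.start(2), len(m.group(2)))
    return spans


def sensitive_occurrences(stream: BinaryIO, tiff: TiffStructure,
                          profile: VendorProfile) -> list[SensitiveOccurrence]:
    """Locate every registry field present in the file, as byte spans.

    Each occurrence is an absolute (offset, length) address that the
    orchestrator can overwrite with same-length filler; tag-held values
    exclude their NUL terminator so string allocations stay intact.
    """
    out: list[SensitiveOccurrence] = []
    by_locator: dict[Locator, list[SensitiveField]] = {}
    for f in profile.sensitive_fields:
        by_locator.setdefault(f.locator, []).append(f)

    for i, ifd in enumerate(tiff.ifds):
        for f in by_locator.get(Locator.TAG, []):
            entry = ifd.tags.get(int(f.identifier))
            if entry is None or entry.dtype != tiffcore.ASCII:
                continue
            data = tiffcore.read_tag_bytes(stream, entry)
            trimmed = data.rstrip(b"\x00")
            if not trimmed:
                continue
            out.append(SensitiveOccurrence(
                f, i, entry.payload_offset(), len(trimmed), _digest(trimmed)))

        desc_fields = (by_locator.get(Locator.DESCRIPTION_KEY, [])
                       + by_locator.get(Locator.XML_ATTRIBUTE, []))
        if not desc_fields:
            continue
        entry = ifd.tags.get(tiffcore.IMAGE_DESCRIPTION)
        if entry is None or entry.dtype != tiffcore.ASCII:
            continue
        desc = tiffcore.read_tag_bytes(stream, entry)
        base = entry.payload_offset()
        key_spans = _description_key_spans(desc)
        xml_spans = _xml_attribute_spans(desc)
        for f in desc_fields:
            table = key_spans if f.locator is Locator.DESCRIPTION_KEY else xml_spans
            span = table.get(str(f.identifier))
            if span is None:
                continue
            rel, length = span
            if length == 0:
                continue
            value = desc[rel:rel + length]
            out.append(SensitiveOccurrence(
                f, i, base + rel, length, _digest(value)))
    return out
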