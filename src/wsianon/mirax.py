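"""Anonymization of 3DHistech Mirax slide sets.

A Mirax slide is a ``.mrxs`` stub next to a directory of the same stem
holding ``Slidedat.ini`` (human-readable metadata and the hierarchical
layout of the slide), ``Index.dat`` (a binary table of blob offsets and
lengths) and numbered ``Data####.dat`` payload files.  The label, the
macro overview ("thumbnail") and the decoded barcode live as blobs in
the data files, addressed by the index; identifying text (slide ID,
barcode, creation date/time, scanner hardware ID, operator) lives as
key/value pairs in the INI.

Anonymization zero-fills the label/macro/barcode blob spans inside the
data files (patched in place), value-replaces the sensitive INI keys and
rewrites ``Slidedat.ini`` — the one file whose length may change —
without any reference to the removed layers.  ``Index.dat`` is rewritten
consistently so the remaining records still resolve.  Tissue blobs are
never touched.

Mirax exists in several format versions that differ in where sensitive
data sits.  The module dispatches on the ``SLIDE_VERSION`` key and
refuses unknown versions outright rather than guessing: for a
confidentiality tool, failing closed beats a silent partial scrub.  The
index layout implemented here is the one produced by the package's own
fixture generator (magic ``MRXIDX01``, little-endian record table); the
version dispatch is the seam where further layouts plug in.
"""

from __future__ import annotations

import configparser
import struct
from enum import Enum
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "MiraxError",
    "MiraxParseError",
    "MiraxStructureError",
    "UnsupportedMiraxVersionError",
    "LayerKind",
    "LayerRef",
    "SlidedatModel",
    "IndexRecord",
    "IndexTable",
    "parse_slidedat",
    "serialize_slidedat",
    "parse_index",
    "serialize_index",
    "anonymize_mirax",
    "SENSITIVE_KEYS",
    "SUPPORTED_VERSIONS",
]

INDEX_MAGIC = b"MRXIDX01"
_RECORD_FMT = "<IIIIQQ"
_RECORD_SIZE = struct.calcsize(_RECORD_FMT)

SUPPORTED_VERSIONS = frozenset({"1.9"})

#: INI keys whose values identify the subject or the acquisition;
#: (section, key) -> category name
SENSITIVE_KEYS = {
    ("GENERAL", "SLIDE_ID"): "subject_related",
    ("GENERAL", "SLIDE_NAME"): "subject_related",
    ("GENERAL", "SLIDE_BARCODE"): "subject_related",
    ("GENERAL", "SLIDE_CREATIONDATETIME"): "acquisition_related",
    ("GENERAL", "SCANNER_HARDWARE_ID"): "acquisition_related",
    ("GENERAL", "OPERATOR_NAME"): "acquisition_related",
}


class MiraxError(Exception):
    pass


class MiraxParseError(MiraxError):
    pass


class MiraxStructureError(MiraxError):
    pass


class UnsupportedMiraxVersionError(MiraxError):
    def __init__(self, version: str):
        super().__init__(
            f"Slidedat.ini declares SLIDE_VERSION = {version!r}; this build "
            f"only understands versions {sorted(SUPPORTED_VERSIONS)} and "
            "refuses to guess blob locations for other layouts"
        )
        self.version = version


class LayerKind(Enum):
    TISSUE = "tissue"
    LABEL = "label"
    MACRO = "macro"     # Mirax calls it the slide thumbnail
    BARCODE = "barcode"
    OTHER = "other"


@dataclass(frozen=True)
class LayerRef:
    """One hierarchy entry of the Slidedat: a (non)hierarchical value."""
    hier_type: int      # 0 = hierarchical (tissue), 1 = non-hierarchical
    layer_index: int
    value_index: int
    name: str
    kind: LayerKind


@dataclass
class SlidedatModel:
    sections: dict[str, dict[str, str]]

    @property
    def version(self) -> str | None:
        return self.sections.get("GENERAL", {}).get("SLIDE_VERSION")

    @property
    def index_file(self) -> str:
        return self.sections.get("DATAFILE", {}).get("INDEX_FILE", "Index.dat")

    def data_files(self) -> list[str]:
        sec = self.sections.get("DATAFILE", {})
        n = int(sec.get("FILE_COUNT", "0"))
        return [sec[f"FILE_{i}"] for i in range(n)]

    def hierarchy(self) -> list[LayerRef]:
        sec = self.sections.get("HIERARCHICAL", {})
        out: list[LayerRef] = []
        for h in range(int(sec.get("HIER_COUNT", "0"))):
            for v in range(int(sec.get(f"HIER_{h}_COUNT", "0"))):
                name = sec.get(f"HIER_{h}_VAL_{v}", "")
                out.append(LayerRef(0, h, v, name, LayerKind.TISSUE))
        for h in range(int(sec.get("NONHIER_COUNT", "0"))):
            for v in range(int(sec.get(f"NONHIER_{h}_COUNT", "0"))):
                name = sec.get(f"NONHIER_{h}_VAL_{v}", "")
                out.append(LayerRef(1, h, v, name, _layer_kind(name)))
        return out


def _layer_kind(name: str) -> LayerKind:
    lowered = name.lower()
    if "label" in lowered:
        return LayerKind.LABEL
    if "thumbnail" in lowered or "macro" in lowered:
        return LayerKind.MACRO
    if "barcode" in lowered:
        return LayerKind.BARCODE
    return LayerKind.OTHER


@dataclass(frozen=True)
class IndexRecord:
    hier_type: int
    layer_index: int
    value_index: int
    file_index: int
    offset: int
    length: int


@dataclass
class IndexTable:
    records: list[IndexRecord] = field(default_factory=list)

    def for_layer(self, ref: LayerRef) -> list[IndexRecord]:
        return [r for r in self.records
                if (r.hier_type, r.layer_index, r.value_index)
                == (ref.hier_type, ref.layer_index, ref.value_index)]


def parse_slidedat(text: str) -> SlidedatModel:
    """Parse Slidedat.ini preserving key case and section order."""
    parser = configparser.RawConfigParser(delimiters=("=",), strict=True)
    parser.optionxform = str  # keys are case-sensitive
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise MiraxParseError(f"malformed Slidedat.ini: {exc}") from exc
    sections = {name: dict(parser.items(name)) for name in parser.sections()}
    return SlidedatModel(sections=sections)


def serialize_slidedat(model: SlidedatModel) -> str:
    lines: list[str] = []
    for name, items in model.sections.items():
        lines.append(f"[{name}]")
        for key, value in items.items():
            lines.append(f"{key} = {value}")
    lines.append("")
    return "\r\n".join(lines)


def parse_index(data: bytes, model: SlidedatModel,
                data_file_sizes: list[int] | None = None) -> IndexTable:
    """Decode the binary offset table for the model's declared version."""
    version = model.version
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedMiraxVersionError(str(version))
    if data[:len(INDEX_MAGIC)] != INDEX_MAGIC:
        raise MiraxStructureError("Index.dat magic mismatch")
    if len(data) < len(INDEX_MAGIC) + 4:
        raise MiraxStructureError("Index.dat truncated before record count")
    (count,) = struct.unpack_from("<I", data, len(INDEX_MAGIC))
    need = len(INDEX_MAGIC) + 4 + count * _RECORD_SIZE
    if len(data) < need:
        raise MiraxStructureError(
            f"Index.dat truncated: {count} records need {need} bytes, "
            f"have {len(data)}"
        )
    records = []
    pos = len(INDEX_MAGIC) + 4
    n_files = len(model.data_files())
    for _ in range(count):
        rec = IndexRecord(*struct.unpack_from(_RECORD_FMT, data, pos))
        pos += _RECORD_SIZE
        if rec.file_index >= n_files:
            raise MiraxStructureError(
                f"record references data file {rec.file_index}, "
                f"only {n_files} declared"
            )
        if data_file_sizes is not None:
            if rec.offset + rec.length > data_file_sizes[rec.file_index]:
                raise MiraxStructureError(
                    f"record span {rec.offset}+{rec.length} exceeds data "
                    f"file {rec.file_index} size "
                    f"{data_file_sizes[rec.file_index]}"
                )
        records.append(rec)
    return IndexTable(records=records)


def serialize_index(table: IndexTable) -> bytes:
    out = bytearray(INDEX_MAGIC)
    out += struct.pack("<I", len(table.records))
    for r in table.records:
        out += struct.pack(_RECORD_FMT, r.hier_type, r.layer_index,
                           r.value_index, r.file_index, r.offset, r.length)
    return bytes(out)


# ---------------------------------------------------------------------------
# anonymization

def _resolve_slide_dir(path: Path) -> Path:
    if path.is_dir():
        return path
    if path.suffix.lower() == ".mrxs":
        data_dir = path.with_suffix("")
        if data_dir.is_dir():
            return data_dir
    raise MiraxError(f"{path} is not a Mirax slide set")


def _zero_span(path: Path, offset: int, length: int) -> int:
    """Zero a span in place; returns the count of bytes actually changed."""
    with path.open("r+b") as fh:
        fh.seek(offset)
        before = fh.read(length)
        changed = sum(1 for b in before if b != 0)
        if changed:
            fh.seek(offset)
            fh.write(b"\x00" * length)
    return changed


def _remove_nonhier_value(model: SlidedatModel, ref: LayerRef) -> None:
    """Drop one non-hierarchical value and renumber the survivors."""
    sec = model.sections["HIERARCHICAL"]
    h = ref.layer_index
    count = int(sec[f"NONHIER_{h}_COUNT"])
    names = [sec[f"NONHIER_{h}_VAL_{v}"] for v in range(count)]
    # drop every key of this layer's value list, then rewrite the survivors
    for v in range(count):
        for suffix in ("", "_SECTION"):
            sec.pop(f"NONHIER_{h}_VAL_{v}{suffix}", None)
    survivors = [n for v, n in enumerate(names) if v != ref.value_index]
    for v, name in enumerate(survivors):
        sec[f"NONHIER_{h}_VAL_{v}"] = name
    sec[f"NONHIER_{h}_COUNT"] = str(len(survivors))


def anonymize_mirax(slide_path: str | Path, *, keep_macro: bool = False,
                    blank_images: bool = True, unlink_images: bool = True,
                    replacement_char: str = "X",
                    subject_only: bool = False,
                    dry_run: bool = False):
    """Scrub a Mirax slide set in place.

    Returns a list of (action, location, bytes_changed) tuples and the
    warnings produced.  Blob spans are zeroed in the data files; the
    Slidedat.ini and Index.dat are atomically rewritten with the removed
    layers unreferenced and sensitive keys value-replaced.  Running a
    second time changes zero additional bytes.
    """
    slide_path = Path(slide_path)
    slide_dir = _resolve_slide_dir(slide_path)
    ini_path = slide_dir / "Slidedat.ini"
    model = parse_slidedat(ini_path.read_text())
    if model.version not in SUPPORTED_VERSIONS:
        raise UnsupportedMiraxVersionError(str(model.version))
    data_files = [slide_dir / name for name in model.data_files()]
    sizes = [p.stat().st_size for p in data_files]
    index_path = slide_dir / model.index_file
    table = parse_index(index_path.read_bytes(), model, sizes)

    actions: list[tuple[str, str, int]] = []
    warnings: list[str] = []

    removed_kinds = set()
    if blank_images or unlink_images:
        removed_kinds = {LayerKind.LABEL, LayerKind.BARCODE}
        if not keep_macro:
            removed_kinds.add(LayerKind.MACRO)

    removal_refs = [ref for ref in model.hierarchy()
                    if ref.kind in removed_kinds]

    # 1. zero the blob spans of removed layers inside the data files
    if blank_images:
        for ref in removal_refs:
            for rec in table.for_layer(ref):
                target = data_files[rec.file_index]
                changed = 0
                if not dry_run:
                    changed = _zero_span(target, rec.offset, rec.length)
                actions.append((
                    "zero_blob",
                    f"{target.name}@{rec.offset}+{rec.length} ({ref.kind.value})",
                    changed,
                ))

    # 2. value-replace sensitive INI keys (any length: the INI is rewritten)
    for (section, key), category in SENSITIVE_KEYS.items():
        if subject_only and category != "subject_related":
            continue
        value = model.sections.get(section, {}).get(key)
        if value is None:
            continue
        replaced = replacement_char * len(value)
        if value != replaced:
            model.sections[section][key] = replaced
            actions.append(("replace_key", f"{section}:{key}", len(value)))

    # 3. unlink: rewrite Slidedat.ini and Index.dat without the removed layers
    if unlink_images:
        # renumbering shifts value indices; process per layer in one pass
        kept_records = []
        index_map: dict[tuple[int, int, int], tuple[int, int, int]] = {}
        removed_addr = {(r.hier_type, r.layer_index, r.value_index)
                        for r in removal_refs}
        # compute new value indices per (hier_type, layer)
        seen: dict[tuple[int, int], int] = {}
        for ref in model.hierarchy():
            addr = (ref.hier_type, ref.layer_index, ref.value_index)
            if addr in removed_addr:
                continue
            new_v = seen.get((ref.hier_type, ref.layer_index), 0)
            seen[(ref.hier_type, ref.layer_index)] = new_v + 1
            index_map[addr] = (ref.hier_type, ref.layer_index, new_v)
        for rec in table.records:
            addr = (rec.hier_type, rec.layer_index, rec.value_index)
            if addr in removed_addr:
                actions.append(("drop_index_record",
                                f"layer {addr}", _RECORD_SIZE))
                continue
            new_addr = index_map.get(addr, addr)
            kept_records.append(IndexRecord(
                new_addr[0], new_addr[1], new_addr[2],
                rec.file_index, rec.offset, rec.length))
        # remove the INI references (descending value index keeps numbering sane)
        for ref in sorted(removal_refs, key=lambda r: -r.value_index):
            if ref.hier_type == 1:
                _remove_nonhier_value(model, ref)
                actions.append(("unlink_layer", ref.name, 0))
        new_index = serialize_index(IndexTable(kept_records))
        if not dry_run and new_index != index_path.read_bytes():
            _atomic_write(index_path, new_index)

    new_ini = serialize_slidedat(model)
    if not dry_run and new_ini != ini_path.read_text():
        _atomic_write(ini_path, new_ini.encode())

    return actions, warnings


def _atomic_write(path: Path, data: bytes) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_bytes(data)
    tmp.replace(path)
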