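"""End-to-end anonymization workflow and level reporting.

The pipeline runs the same sequence for every format: detect the vendor
format, rename (filenames carry case IDs, so the original name never
survives by default), optionally back up, locate the sensitive image
blobs and metadata spans, then overwrite and unlink.  Per-format work is
dispatched to :mod:`tiffcore`/:mod:`vendors` (SVS, NDPI, BIF, generic
TIFF), :mod:`mirax` and :mod:`isyntax`.

The report grades the outcome on a four-step policy ladder:

* **I** — only the filename was neutralized.
* **II** — associated images were unlinked but their bytes remain.
* **III** — the label (and macro) images are blanked beyond recovery and
  subject-related metadata is gone; acquisition metadata may remain.
* **IV** — additionally every acquisition-related registry field
  (serial, date/time, operator) is neutralized; only tissue pixels and
  structural attributes remain.

By default the tool patches a copy named after the content hash of the
input; ``in_place=True`` opts into destructive editing.  Any error
leaves either the untouched original or a fully processed output —
patches are staged on the copy, and in-place runs stage on a temporary
sibling that replaces the original only on success.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import isyntax as isyntax_mod
from . import mirax as mirax_mod
from . import tiffcore, vendors
from .detect import SUPPORTED_FORMATS, VendorFormat, detect_format
from .tiffcore import IfdRole
from .vendors import Action, Category, Locator, VendorProfile

__all__ = [
    "Scope",
    "Level",
    "AnonymizationConfig",
    "ActionRecord",
    "AnonymizationReport",
    "UnsupportedFormatError",
    "is_supported",
    "anonymize",
    "achieved_level",
]


class UnsupportedFormatError(Exception):
    pass


class Scope(Enum):
    SUBJECT_ONLY = "subject"
    SUBJECT_AND_ACQUISITION = "all"


class Level(Enum):
    I = 1
    II = 2
    III = 3
    IV = 4


@dataclass(frozen=True)
class AnonymizationConfig:
    """Run parameters; defaults give the strongest (Level IV) scrub."""
    keep_macro: bool = False
    blank_images: bool = True      # overwrite image bytes with blank images
    unlink_images: bool = True     # additionally remove structural references
    make_backup: bool = False
    new_name: str | None = None    # default: content-hash-derived name
    dry_run: bool = False
    in_place: bool = False
    replacement_char: str = "X"
    scope: Scope = Scope.SUBJECT_AND_ACQUISITION
    profile: VendorProfile | None = None  # override the built-in registry
    output_dir: str | None = None  # default: alongside the input

    def __post_init__(self):
        ch = self.replacement_char
        if len(ch) != 1 or not (0x20 <= ord(ch) < 0x7F):
            raise ValueError("replacement_char must be one printable ASCII char")
        if self.new_name is not None and ("/" in self.new_name or "\\" in self.new_name):
            raise ValueError("new_name must not contain path separators")


@dataclass(frozen=True)
class ActionRecord:
    kind: str
    location: str
    bytes_modified: int


@dataclass
class AnonymizationReport:
    format: VendorFormat
    actions: list[ActionRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    achieved_level: Level = Level.I
    output_path: Path | None = None
    dry_run: bool = False

    @property
    def total_bytes_modified(self) -> int:
        return sum(a.bytes_modified for a in self.actions)

    def to_dict(self) -> dict:
        return {
            "format": self.format.value,
            "achieved_level": self.achieved_level.name,
            "total_bytes_modified": self.total_bytes_modified,
            "actions": [dataclasses.asdict(a) for a in self.actions],
            "warnings": list(self.warnings),
            "output_path": str(self.output_path) if self.output_path else None,
            "dry_run": self.dry_run,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def is_supported(path: str | Path) -> tuple[bool, VendorFormat]:
    """Whether the anonymizer can process the file, and as what."""
    result = detect_format(path)
    return result.format in SUPPORTED_FORMATS, result.format


def achieved_level(config: AnonymizationConfig,
                   metadata_complete: bool) -> Level:
    """Map a run's configuration and coverage onto the policy ladder."""
    if config.blank_images:
        if (config.scope is Scope.SUBJECT_AND_ACQUISITION
                and metadata_complete):
            return Level.IV
        return Level.III
    if config.unlink_images:
        return Level.II
    return Level.I


def _content_hash_name(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# TIFF-family pass

def _anonymize_tiff(path: Path, fmt: VendorFormat,
                    config: AnonymizationConfig,
                    report: AnonymizationReport) -> None:
    profile = config.profile or vendors.default_profile(fmt)
    mode = "rb" if config.dry_run else "r+b"
    with path.open(mode) as fh:
        tiff = tiffcore.parse_tiff(fh)
        roles = vendors.classify_roles(fh, tiff, profile)
        occurrences = vendors.sensitive_occurrences(fh, tiff, profile)

        removable: list[int] = []
        for idx, role in roles.items():
            if role is IfdRole.LABEL:
                removable.append(idx)
            elif role is IfdRole.MACRO:
                if config.keep_macro and profile.macro_separable:
                    continue
                if config.keep_macro and not profile.macro_separable:
                    report.warnings.append(
                        "label and macro are one image in this format and "
                        "cannot be deleted separately; blanking the combined "
                        "image despite keep_macro"
                    )
                removable.append(idx)

        metadata_complete = True
        forced_unlink: list[int] = []
        if config.blank_images:
            for idx in removable:
                try:
                    written = 0
                    if not config.dry_run:
                        written = tiffcore.blank_image(fh, tiff, idx)
                    report.actions.append(ActionRecord(
                        "blank_image", f"ifd{idx}:{roles[idx].value}", written))
                except tiffcore.UnsupportedCompressionError as exc:
                    # confidentiality over decodability: zero the raw blobs
                    written = 0
                    if not config.dry_run:
                        for ref in tiffcore.blob_refs(fh, tiff.header,
                                                      tiff.ifds[idx]):
                            written += tiffcore.overwrite_blob(fh, ref, b"")
                    report.actions.append(ActionRecord(
                        "zero_blobs", f"ifd{idx}:{roles[idx].value}", written))
                    report.warnings.append(
                        f"ifd{idx}: {exc}; blobs zeroed raw and directory "
                        "unlinked instead of blank-encoded"
                    )
                    forced_unlink.append(idx)

        for occ in occurrences:
            if (config.scope is Scope.SUBJECT_ONLY
                    and occ.category is not Category.SUBJECT_RELATED):
                metadata_complete = False
                continue
            if occ.field.action is not Action.SAME_LENGTH_REPLACE:
                continue
            if not config.dry_run:
                tiffcore.replace_span(fh, occ.offset, occ.length,
                                      config.replacement_char)
            loc = (occ.field.identifier if occ.field.locator is Locator.TAG
                   else str(occ.field.identifier))
            report.actions.append(ActionRecord(
                "replace_string", f"ifd{occ.ifd_index}:{loc}", occ.length))

        to_unlink = removable if config.unlink_images else forced_unlink
        for idx in sorted(to_unlink, reverse=True):
            if config.dry_run:
                report.actions.append(ActionRecord("unlink_ifd", f"ifd{idx}", 0))
            else:
                tiff = tiffcore.unlink_ifd(fh, tiff, idx)
                report.actions.append(ActionRecord(
                    "unlink_ifd", f"ifd{idx}", tiff.header.offset_width))

        if not config.dry_run:
            fh.flush()
            tiffcore.parse_tiff(fh)  # post-edit validity check

    report.achieved_level = achieved_level(config, metadata_complete)


# ---------------------------------------------------------------------------
# workflow

def _stage_copy(src: Path, is_mirax: bool, config: AnonymizationConfig,
                work_dir: Path) -> Path:
    """Copy the input (file or Mirax set) into the working directory under
    its anonymized name."""
    if config.new_name:
        stem = config.new_name
    elif is_mirax:
        stem = _content_hash_name(src.with_suffix("") / "Slidedat.ini")
    else:
        stem = _content_hash_name(src)
    if is_mirax:
        dst = work_dir / f"{stem}.mrxs"
        shutil.copy2(src, dst)
        shutil.copytree(src.with_suffix(""), work_dir / stem,
                        dirs_exist_ok=False)
        return dst
    dst = work_dir / (stem + src.suffix.lower())
    shutil.copy2(src, dst)
    return dst


def _make_backup(src: Path, is_mirax: bool) -> Path:
    backup_dir = src.parent / "backup"
    backup_dir.mkdir(exist_ok=True)
    dst = backup_dir / src.name
    shutil.copy2(src, dst)
    if is_mirax:
        shutil.copytree(src.with_suffix(""), backup_dir / src.stem,
                        dirs_exist_ok=True)
    return dst


def anonymize(path: str | Path,
              config: AnonymizationConfig | None = None) -> AnonymizationReport:
    """Anonymize one slide (file or Mirax set) and report what was done.

    Raises :class:`UnsupportedFormatError` for formats outside the
    supported set.  Unless ``in_place`` is set, the original is never
    modified: the patched output appears under a content-hash-derived
    (or ``new_name``) filename next to the input or in ``output_dir``.
    """
    config = config or AnonymizationConfig()
    src = Path(path)
    detection = detect_format(src)
    fmt = detection.format
    if fmt not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported format for {src.name}: {fmt.value} "
            f"(evidence: {detection.evidence or 'none'})"
        )
    report = AnonymizationReport(format=fmt, dry_run=config.dry_run)
    is_mirax = fmt is VendorFormat.MIRAX_MRXS
    if is_mirax and src.is_dir():
        # normalize on the .mrxs stub when handed the data directory
        stubs = sorted(src.parent.glob(f"{src.name}.mrxs"))
        if stubs:
            src = stubs[0]

    if config.make_backup and not config.dry_run:
        _make_backup(src, is_mirax)
        report.actions.append(ActionRecord("backup", "backup/", 0))

    staged_original: Path | None = None
    if config.dry_run:
        work_path = src
    elif config.in_place:
        if is_mirax:
            work_path = src  # Mirax edits are per-file atomic already
        else:
            staged = src.with_name(src.name + ".anon-tmp")
            shutil.copy2(src, staged)
            work_path = staged
            staged_original = src
    else:
        out_dir = Path(config.output_dir) if config.output_dir else src.parent
        out_dir.mkdir(parents=True, exist_ok=True)
        work_path = _stage_copy(src, is_mirax, config, out_dir)
        report.actions.append(ActionRecord(
            "rename", f"{src.name} -> {work_path.name}", 0))

    subject_only = config.scope is Scope.SUBJECT_ONLY
    if fmt is VendorFormat.MIRAX_MRXS:
        actions, warnings = mirax_mod.anonymize_mirax(
            work_path,
            keep_macro=config.keep_macro,
            blank_images=config.blank_images,
            unlink_images=config.unlink_images,
            replacement_char=config.replacement_char,
            subject_only=subject_only,
            dry_run=config.dry_run,
        )
        report.actions += [ActionRecord(*a) for a in actions]
        report.warnings += warnings
        report.achieved_level = achieved_level(config, not subject_only)
    elif fmt is VendorFormat.PHILIPS_ISYNTAX:
        actions, warnings = isyntax_mod.anonymize_isyntax(
            work_path,
            keep_macro=config.keep_macro,
            blank_images=config.blank_images,
            subject_only=subject_only,
            replacement_char=config.replacement_char,
            dry_run=config.dry_run,
        )
        report.actions += [ActionRecord(*a) for a in actions]
        report.warnings += warnings
        report.achieved_level = achieved_level(config, not subject_only)
    else:
        _anonymize_tiff(work_path, fmt, config, report)

    if staged_original is not None:
        work_path.replace(staged_original)
        work_path = staged_original

    report.output_path = None if config.dry_run else work_path
    return report
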