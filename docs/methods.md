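# Methods

## Scope and model

`wsianon` removes identifying content from whole-slide images while
keeping each file valid in its native vendor format. Two groups of
content are targeted:

* **associated images** — the slide-label photograph (case ID/barcode)
  and the macro overview of the glass slide;
* **metadata** — grouped into *subject-related* values (case ID,
  barcode, slide name) and *acquisition-related* values (scanner serial
  number, acquisition date/time, operator), because the two groups map
  onto different rungs of the policy ladder (Level III removes the
  first; Level IV removes both).

The core design constraint is that vendor software and reverse-
engineered readers (OpenSlide-style) validate file *structure*:
directory chains, fixed-size tag allocations, XML node skeletons.
Every edit therefore preserves structure — files are patched, never
converted or re-serialized, with the single exception of Mirax's
`Slidedat.ini`/`Index.dat`, whose formats are line-/record-oriented and
are atomically rewritten (write-temp-then-replace) because removing
layer references changes their length.

## TIFF family (SVS, NDPI, BIF, generic)

The parser builds the complete chain — header (both byte orders,
classic 32-bit and BigTIFF 64-bit offsets), every tag entry with the
file offset of the entry itself and of each payload element, and one
`(offset, length)` blob reference per strip or tile. Cyclic chains and
pointers past EOF are hard errors. Parsing is pure: it never writes.

Three edits:

* **blank_image** encodes a uniform white image per strip/tile in the
  directory's declared compression and writes it into the existing
  region, zero-filling slack and rewriting the byte-count tag (which
  can only shrink). If a segment's blank encoding is larger than its
  region — possible for tiny JPEG strips — the image falls back to a
  single-strip layout inside the first region, provided it fits;
  otherwise it is a capacity error. White means 0xFF for
  min-is-black/RGB data and 0x00 under a min-is-white photometric
  interpretation, so the decoded image is visually blank either way.
* **unlink_ifd** overwrites the predecessor's next-IFD pointer (or the
  header's first-IFD field for index 0) with the target's own next
  pointer; unlinking the last directory writes the null terminator.
  Unlinked bytes remain present by design — confidentiality comes from
  blanking them first, unlinking only removes reachability.
* **replace_tag_string / replace_span** overwrite ASCII values with a
  repeated printable filler of identical byte length. NUL bytes
  (terminators and multi-string separators) are preserved bit-exactly,
  so tag counts, allocations and the file size never change.

Codecs: uncompressed, Deflate (zlib, both TIFF codes), JPEG (encoded
via Pillow, interchange format with inline tables, quality 75 — blank
frames compress far below any real photograph, so they always fit), and
LZW. The LZW encoder is implemented in-module (MSB-first bit packing,
9→12-bit code widths growing when the next assignable code overflows
the current width, clear-and-reset near table exhaustion) because no
installed library exposes a raw TIFF-LZW codestream encoder with
controllable strip layout; its output is verified in the tests by
decoding through independent readers (tifffile, Pillow). An
unrecognized compression code in a label/macro directory fails the
blank encode; the orchestrator then zeroes the raw blobs and force-
unlinks the directory — confidentiality over decodability.

Vendor registries classify directories and locate metadata:

* **SVS** — roles from ImageDescription markers (`label`, `macro`);
  sensitive `Key = value` fields (`Filename`, `Barcode`,
  `ScanScope ID`, `Date`, `Time`, `User`) located as value spans inside
  the description text and replaced in place.
* **NDPI** — the directory whose source-lens tag (65421) is negative is
  the combined label+macro photograph; sensitive private tags 65427
  (slide reference/barcode) and 65442 (scanner serial) plus standard
  DateTime/Artist. The tag numbers are reconstructed from public
  format knowledge; the registry is data and can be overridden from a
  JSON profile without code changes.
* **BIF** — an `<iScan …>` XML fragment in the baseline description;
  sensitive XML attributes (`Barcode1D`, `UnitNumber`, `UserName`,
  `ScanDate`) located as attribute-value spans. The associated
  photograph (description `Label Image`) is combined label+macro.
* **generic TIFF** — no metadata registry; directories whose
  descriptions mention label/macro are blanked and unlinked, with the
  format reported as generic so operators know a vendor profile was not
  applied.

On the combined-image formats (NDPI, BIF) a `keep_macro` request cannot
be honored without keeping the label; the tool blanks the combined
image anyway and emits a warning rather than silently weakening the
scrub.

## Mirax

`Slidedat.ini` is parsed with case-preserving INI handling; the
hierarchical section yields layer references whose names identify
label, macro ("thumbnail") and barcode layers. `Index.dat` maps each
layer value to `(data file, offset, length)` records; records must lie
inside their data files. Blob spans of removed layers are zeroed in
place in the `Data####.dat` files; sensitive INI keys are value-
replaced; then both `Slidedat.ini` and `Index.dat` are rewritten with
the removed layers unreferenced and the surviving value indices
renumbered consistently. Tissue spans are never written.

Mirax exists in multiple format versions that differ in where sensitive
data sits, so the module dispatches on `SLIDE_VERSION` and refuses
unknown versions with a precise message instead of guessing — failing
closed is the only safe default for a confidentiality tool. The binary
index layout implemented (magic `MRXIDX01`, little-endian record table)
is the one the package's own fixture generator emits; the version
dispatch is the seam where additional real-world layouts plug in.

## iSyntax

The XML header (terminated by an ASCII EOT byte) is parsed with the
standard-library ElementTree; value byte spans are located by anchoring
on the unique attribute names. The datatype system is modeled
minimally — string, integer, double, datetime, base64 image — with
constraint annotations (`datetime:…` format, `range:lo,hi` interval).
Replacements conform to datatype and constraint: strings become
same-length filler, constrained datetimes a fixed epoch placeholder in
the declared shape, ranged integers the interval minimum. Unknown
datatypes on sensitive keys fail closed, naming the key. Label and
macro base64 payloads are replaced by a blank white JPEG of the same
decoded dimensions; shorter replacements are whitespace-padded inside
the original span (base64 decoders skip whitespace), so the header
span, the node skeleton, and the binary body are all preserved
bit-for-bit in layout.

## Workflow, safety, determinism

The orchestrator runs detect → rename → optional backup → locate →
patch. Detection is read-only and constant-time (magic bytes, then a
structural probe of at most the first 64 KiB plus the first IFD);
an extension alone never decides a TIFF-family format. By default the
tool patches a copy whose name is derived from the content hash of the
input (first 12 hex digits) — filenames carry case IDs, so the original
name never survives; `in_place` runs stage a temporary sibling that
replaces the original only on success. Dry runs write nothing and
report planned actions. Outputs are re-parsed as a post-edit validity
check before the run is reported successful.

All edits are deterministic functions of input bytes plus
configuration, and idempotent: a second run over an output is a
byte-identical no-op. The policy level is computed from the
configuration and registry coverage, not asserted: blank+both-
categories → IV, blank with subject-only scope → III, unlink-only → II,
rename-only → I.

## Synthetic test data

No real scanner output can be redistributed, so the fixture module
fabricates minimal but structurally complete slides: multi-directory
TIFFs (baseline, pyramid level, label, macro) with inline and
out-of-line string tags and at least one JPEG-compressed and one
uncompressed associated image; a BigTIFF SVS variant; a Mirax set with
label/macro/barcode blobs across data files; an iSyntax header with
typed, partly constrained attributes and base64 label/macro JPEGs over
an opaque random body. Every sensitive payload (case ID, barcode,
serial, date/time, operator, label/macro pixel signatures) is planted
as a unique ASCII byte string of at least six bytes and recorded in a
manifest; pixel signatures ride inside JPEG comment segments or raw
raster bytes so they survive into the encoded stream and vanish when
the image is blanked. For iSyntax images the manifest records a slice
of the base64 text, since raw pixel bytes never appear verbatim in
that container. Generation is deterministic in the seed. Slides are
kept small (kilobytes; baselines of 128×128 with two strips) so the
whole suite and the acceptance run finish in seconds — the edits under
test are O(metadata), not O(pixels), so miniature pyramids exercise
the same code paths as gigapixel files.

What the fixtures do *not* emulate: real vendor tag inventories across
scanner software versions (the registries are reconstructed from public
knowledge and deliberately overridable), vendor-specific codecs
(JPEG2000 etc. exercise only the zero-and-unlink path), the real Mirax
index layout and the real iSyntax datatype catalogue (both are modeled
representatively, with fail-closed seams). Passing tests therefore
demonstrate the mechanics — structure-preserving patching, exact
same-length replacement, chain relinking, reference closure — not
coverage of any particular vendor software release; on real archives
the registries must be curated per scanner model and version.

## Numerical and edge-case choices

* Blank JPEG quality 75; encoders are deterministic for a fixed Pillow
  version, which the determinism guarantees rely on.
* Tie-breaks in role classification: first matching directory wins; at
  most one LABEL and one MACRO per file.
* Zero-length files are reported unsupported rather than raised as
  errors; truncated structures, cyclic chains, arity mismatches between
  offsets and byte counts, and over-long replacements are hard errors.
* Patched integer fields always follow the file header's declared byte
  order; both orders are tested.
* Replacement filler must be a single printable ASCII character
  (default `X`).

## Known limitations

* Registries cover the common public fields; a vendor revision that
  moves sensitive data requires a profile update (the JSON profile file
  exists for exactly this reason).
* Tissue pixels themselves are out of scope: a slide can in principle
  be re-identified by matching tissue against the original glass, which
  no metadata scrub can prevent.
* OCR of text burned into macro/tissue pixels is not attempted.
* Conformance against proprietary vendor SDKs is untested without
  vendor data; validity is demonstrated against independent open
  readers.
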