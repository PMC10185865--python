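# wsianon

Structure-preserving anonymization of whole-slide images (WSIs) in their
native, proprietary scanner formats.

## The problem

Digitized pathology slides carry more than tissue. The scanner
photographs the slide label (case ID, barcode), stores a macro overview
of the glass, and records acquisition metadata — scanner serial number,
date and time, operator — inside vendor-specific containers. Sharing
such files for research or teaching risks re-identification, and
GDPR/HIPAA-style rules demand this data be gone. Converting to DICOM or
OME-TIFF loses compatibility with the viewers and pipelines that expect
the original format, so `wsianon` removes the sensitive content *inside*
the native file, leaving a file the vendor's own software still opens.

Supported formats:

| Vendor          | Format                | Notes |
|-----------------|-----------------------|-------|
| Leica/Aperio    | `.svs` (TIFF/BigTIFF) | separate label and macro directories |
| Hamamatsu       | `.ndpi` (TIFF dialect)| label+macro are one image, not separately removable |
| Roche/Ventana   | `.bif` (TIFF)         | label+macro are one image, not separately removable |
| 3DHistech       | `.mrxs` + data dir    | `Slidedat.ini`, `Index.dat`, `Data####.dat` |
| Philips         | `.isyntax`            | XML header with base64 label/macro |
| (generic TIFF)  | `.tif`                | fail-soft profile for unknown dialects |

## How it works

A file is never rewritten — it is patched. Three structure-preserving
edits cover the TIFF family:

1. **Blank the image blobs.** Each strip/tile of a label or macro
   directory is overwritten with a blank white image encoded in the
   directory's declared compression (none, LZW, Deflate, or JPEG), so
   the region still decodes but carries nothing. Slack bytes are
   zeroed; the byte-count tag is rewritten; the file size never changes.
2. **Unlink the directory.** TIFF stores its image file directories
   (IFDs) as a linked chain. The predecessor's next-IFD pointer (or the
   header's first-IFD field) is pointed at the successor; the last
   directory gets a null terminator. Readers no longer see the
   directory, and since its bytes were blanked first, nothing can be
   re-referenced by reverse engineering.
3. **Replace strings at fixed length.** Metadata strings live in
   fixed-size allocations; growing them corrupts the file. Each
   sensitive value is replaced by a content-free filler of identical
   byte length, preserving NUL terminators bit-exactly.

Mirax sets get the analogous treatment (blob spans zeroed in the data
files, `Slidedat.ini`/`Index.dat` rewritten without the removed layers),
and iSyntax headers get datatype- and constraint-aware value
replacement plus blank base64 image payloads, with the binary body
untouched.

Results are graded on a four-level policy ladder: **I** filename
scrubbed, **II** images dereferenced only, **III** label irrecoverably
blanked (GDPR-sufficient), **IV** additionally all subject- *and*
acquisition-related metadata neutralized. The default configuration
targets Level IV.

Which fields count as sensitive per vendor is data, not code: built-in
registries cover the common SVS/NDPI/BIF fields and can be replaced
with a JSON profile (`--profile`), because vendors revise their formats
continuously.

## Worked example

No real slides are needed: the package fabricates structurally faithful
fixtures with planted sensitive payloads.

```
$ wsianon fixtures make --format svs --seed 7 --out-dir .   # writes slide.svs
$ wsianon anonymize slide.svs --report json
{
  "format": "aperio_svs",
  "achieved_level": "IV",
  "total_bytes_modified": 12860,
  "actions": [
    {"kind": "rename",        "location": "slide.svs -> 683ee2ac0d91.svs", "bytes_modified": 0},
    {"kind": "blank_image",   "location": "ifd2:label",  "bytes_modified": 3577},
    {"kind": "blank_image",   "location": "ifd3:macro",  "bytes_modified": 9216},
    {"kind": "replace_string","location": "ifd0:Filename","bytes_modified": 13},
    {"kind": "replace_string","location": "ifd0:Barcode", "bytes_modified": 12},
    {"kind": "replace_string","location": "ifd0:ScanScope ID", "bytes_modified": 9},
    {"kind": "replace_string","location": "ifd0:Date",    "bytes_modified": 8},
    {"kind": "replace_string","location": "ifd0:Time",    "bytes_modified": 8},
    {"kind": "replace_string","location": "ifd0:User",    "bytes_modified": 9},
    {"kind": "unlink_ifd",    "location": "ifd3",         "bytes_modified": 4},
    {"kind": "unlink_ifd",    "location": "ifd2",         "bytes_modified": 4}
  ],
  "warnings": [],
  "output_path": "683ee2ac0d91.svs",
  "dry_run": false
}
```

Reading the report: the label (IFD 2, a 3,577-byte JPEG) and macro
(IFD 3, a 9,216-byte raster) were overwritten with blank images and
then removed from the directory chain (each unlink patches one 4-byte
pointer); six `Key = value` fields in the baseline ImageDescription
were replaced in place at identical length; the output carries a
content-hash-derived name so the original filename cannot leak. The
achieved level is IV: no subject- or acquisition-related data remains,
and the file still opens as an ordinary SVS.

Useful flags: `--keep-macro` (preserve the overview where the format
allows it), `--unlink-only` (Level II), `--scope subject` (Level III),
`--dry-run`, `--in-place`, `--backup`, `--report json`.

The same API is available from Python:

```python
from wsianon import anonymize, AnonymizationConfig
report = anonymize("slide.svs", AnonymizationConfig(keep_macro=True))
print(report.achieved_level, report.total_bytes_modified)
```

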