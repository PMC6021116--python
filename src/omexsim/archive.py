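"""OMEX container packing/unpacking (ZIP + COMBINE manifest).

Packing is bit-reproducible: entries are stored sorted by location with a
fixed 1980-01-01 timestamp, and the manifest lists itself under location
"." per the COMBINE convention.
"""

from __future__ import annotations

import io
import posixpath
import warnings
import zipfile
from dataclasses import dataclass, field

from lxml import etree

from .errors import ArchiveError

MANIFEST_NS = "http://identifiers.org/combine.specifications/omex-manifest"
FORMAT_MANIFEST = "http://identifiers.org/combine.specifications/omex-manifest"
FORMAT_SBML = "http://identifiers.org/combine.specifications/sbml"
FORMAT_SEDML = "http://identifiers.org/combine.specifications/sed-ml"
FORMAT_OCTET_STREAM = "application/octet-stream"

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass
class ArchiveEntry:
    location: str
    format_uri: str
    content: bytes
    master: bool = False

    def validate(self) -> None:
        loc = self.location
        if not loc or loc.startswith("/") or ".." in loc.split("/"):
            raise ArchiveError(f"invalid entry location {loc!r}")


@dataclass
class Archive:
    entries: list[ArchiveEntry] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        masters = 0
        for e in self.entries:
            e.validate()
            norm = posixpath.normpath(e.location)
            if norm in seen:
                raise ArchiveError(f"duplicate entry location {e.location!r}")
            seen.add(norm)
            masters += e.master
        if masters > 1:
            raise ArchiveError("more than one master entry")

    def get(self, location: str) -> ArchiveEntry | None:
        for e in self.entries:
            if e.location == location:
                return e
        return None

    def by_format(self, format_uri: str) -> list[ArchiveEntry]:
        return [e for e in self.entries if e.format_uri.startswith(format_uri)]


def _manifest_xml(archive: Archive) -> bytes:
    root = etree.Element(f"{{{MANIFEST_NS}}}omexManifest", nsmap={None: MANIFEST_NS})
    self_entry = etree.SubElement(root, f"{{{MANIFEST_NS}}}content")
    self_entry.set("location", ".")
    self_entry.set("format", FORMAT_MANIFEST)
    for e in sorted(archive.entries, key=lambda e: e.location):
        c = etree.SubElement(root, f"{{{MANIFEST_NS}}}content")
        c.set("location", "./" + e.location)
        c.set("format", e.format_uri)
        if e.master:
            c.set("master", "true")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def pack(archive: Archive) -> bytes:
    """Serialize an Archive to deterministic OMEX ZIP bytes."""
    archive.validate()
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("manifest.xml", date_time=_FIXED_DATE)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, _manifest_xml(archive))
        for e in sorted(archive.entries, key=lambda e: e.location):
            info = zipfile.ZipInfo(e.location, date_time=_FIXED_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, e.content)
    return buf.getvalue()


def unpack(data: bytes) -> Archive:
    """Parse OMEX ZIP bytes back into an Archive."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(data))
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"not a ZIP archive: {exc}") from None
    names = [n for n in zf.namelist() if not n.endswith("/")]
    if "manifest.xml" not in names:
        raise ArchiveError("missing manifest")
    root = etree.fromstring(zf.read("manifest.xml"))
    manifest: dict[str, tuple[str, bool]] = {}
    for c in root:
        if not isinstance(c.tag, str):
            continue
        loc = c.get("location", "")
        loc = loc[2:] if loc.startswith("./") else loc
        if loc in (".", "", "manifest.xml"):
            continue
        manifest[posixpath.normpath(loc)] = (c.get("format", FORMAT_OCTET_STREAM),
                                             c.get("master") == "true")
    archive = Archive()
    for name in names:
        if name == "manifest.xml":
            continue
        norm = posixpath.normpath(name)
        if norm in manifest:
            fmt, master = manifest.pop(norm)
        else:
            warnings.warn(f"archive entry {name!r} missing from manifest; "
                          f"treated as {FORMAT_OCTET_STREAM}", stacklevel=2)
            fmt, master = FORMAT_OCTET_STREAM, False
        archive.entries.append(ArchiveEntry(name, fmt, zf.read(name), master))
    if manifest:
        missing = ", ".join(sorted(manifest))
        raise ArchiveError(f"manifest references missing file(s): {missing}")
    archive.entries.sort(key=lambda e: e.location)
    archive.validate()
    return archive
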