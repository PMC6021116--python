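"""Inline OMEX documents: the human-readable twin of a COMBINE archive.

A document interleaves reaction-network models, written as ``model ... end``
blocks, with experiment statements in the global scope.  Maximal runs of
contiguous global statements form one simulation section each.  An optional
``%antimony <path>`` or ``%phrasedml <path>`` header line immediately before
a block pins the archive location of the corresponding SBML/SED-ML file;
sections without headers get deterministic default paths ("model1.xml",
"experiment1.xml", ...).

Converting to an Archive emits one SBML entry per model section and one
SED-ML entry per simulation section, plus the manifest; the first SED-ML
entry is flagged master.  Converting an archive back yields a document with
one section per recognized entry; unrecognized entries are kept in a
passthrough list and reattached on re-export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import model_lang, sbml_io, sedml_io, sim_lang
from .archive import (FORMAT_SBML, FORMAT_SEDML, Archive, ArchiveEntry)
from .errors import ParseError, ValidationError
from .model_lang import strip_comments


@dataclass
class Section:
    kind: str           # "model" | "simulation"
    archive_path: str
    text: str

    def validate(self) -> None:
        p = self.archive_path
        if not p or p.startswith("/") or ".." in p.split("/"):
            raise ValidationError(f"invalid archive path {p!r}")


@dataclass
class OmexDocument:
    sections: list[Section] = field(default_factory=list)
    passthrough: list[ArchiveEntry] = field(default_factory=list)

    def validate(self) -> None:
        paths: set[str] = set()
        for s in self.sections:
            s.validate()
            if s.archive_path in paths:
                raise ValidationError(f"duplicate archive path {s.archive_path!r}")
            paths.add(s.archive_path)

    def model_sections(self) -> list[Section]:
        return [s for s in self.sections if s.kind == "model"]

    def simulation_sections(self) -> list[Section]:
        return [s for s in self.sections if s.kind == "simulation"]


def default_path(kind: str, index: int) -> str:
    return (f"model{index}.xml" if kind == "model" else f"experiment{index}.xml")


# ---------------------------------------------------------------------------
# Text <-> OmexDocument
# ---------------------------------------------------------------------------

def parse_document(text: str) -> OmexDocument:
    """Split inline-OMEX source into model and simulation sections."""
    doc = OmexDocument()
    pending_header: tuple[str, str] | None = None   # (kind, path)
    model_lines: list[str] | None = None
    model_path: str | None = None
    sim_lines: list[str] = []
    sim_path: str | None = None
    model_count = 0
    sim_count = 0
    model_block_line = 0

    def flush_sim() -> None:
        nonlocal sim_lines, sim_path, sim_count
        if not any(ln.strip() for ln in sim_lines):
            sim_lines = []
            return
        sim_count += 1
        path = sim_path or default_path("simulation", sim_count)
        doc.sections.append(Section("simulation", path,
                                    "\n".join(sim_lines).strip("\n")))
        sim_lines, sim_path = [], None

    for lineno, raw in enumerate(strip_comments(text).splitlines(), start=1):
        line = raw.strip()
        if line.startswith("%antimony") or line.startswith("%phrasedml"):
            parts = line.split(None, 1)
            if len(parts) != 2 or not parts[1].strip():
                raise ParseError("header with missing path", line=lineno)
            kind = "model" if parts[0] == "%antimony" else "simulation"
            if model_lines is not None:
                raise ParseError("header inside a model block", line=lineno)
            flush_sim()
            pending_header = (kind, parts[1].strip())
            if kind == "simulation":
                sim_path = parts[1].strip()
                pending_header = None
            continue

        if model_lines is None and model_lang._MODEL_RE.match(line):
            flush_sim()
            model_lines = [raw]
            model_block_line = lineno
            if pending_header is not None:
                if pending_header[0] != "model":
                    raise ParseError("%phrasedml header precedes a model block",
                                     line=lineno)
                model_path = pending_header[1]
                pending_header = None
            continue

        if model_lines is not None:
            model_lines.append(raw)
            if model_lang._END_RE.match(line):
                model_count += 1
                path = model_path or default_path("model", model_count)
                doc.sections.append(Section("model", path,
                                            "\n".join(model_lines).strip("\n")))
                model_lines, model_path = None, None
            continue

        if pending_header is not None and line:
            raise ParseError("%antimony header must precede a model block",
                             line=lineno)
        sim_lines.append(raw)

    if model_lines is not None:
        raise ParseError("unterminated model block", line=model_block_line)
    flush_sim()
    doc.validate()
    return doc


def render_document(doc: OmexDocument) -> str:
    """Serialize a document; ``parse_document(render_document(doc)) == doc``."""
    doc.validate()
    chunks: list[str] = []
    model_count = 0
    sim_count = 0
    multi = len(doc.sections) > 1
    for s in doc.sections:
        if s.kind == "model":
            model_count += 1
            default = default_path("model", model_count)
            header = f"%antimony {s.archive_path}"
        else:
            sim_count += 1
            default = default_path("simulation", sim_count)
            header = f"%phrasedml {s.archive_path}"
        if multi or s.archive_path != default:
            chunks.append(header + "\n" + s.text)
        else:
            chunks.append(s.text)
    return "\n\n".join(chunks) + ("\n" if chunks else "")


# ---------------------------------------------------------------------------
# OmexDocument <-> Archive
# ---------------------------------------------------------------------------

def document_to_archive(doc: OmexDocument) -> Archive:
    """Compile every section to SBML/SED-ML and assemble an Archive."""
    doc.validate()
    archive = Archive()
    model_docs: dict[str, model_lang.ModelDoc] = {}
    model_paths: dict[str, str] = {}
    for s in doc.model_sections():
        try:
            mdoc = model_lang.parse_model(s.text)
        except ParseError as exc:
            raise ParseError(f"in model section {s.archive_path!r}: {exc}") from None
        model_docs[mdoc.id] = mdoc
        model_paths[mdoc.id] = s.archive_path
        archive.entries.append(ArchiveEntry(
            s.archive_path, FORMAT_SBML, sbml_io.write_sbml(mdoc).encode()))
    first_sedml = True
    for s in doc.simulation_sections():
        try:
            spec = sim_lang.parse_simulation(s.text, known_models=set(model_docs))
        except ParseError as exc:
            raise ParseError(f"in simulation section {s.archive_path!r}: {exc}") from None
        xml = sedml_io.write_sedml(spec, model_paths, model_docs=model_docs)
        archive.entries.append(ArchiveEntry(
            s.archive_path, FORMAT_SEDML, xml.encode(), master=first_sedml))
        first_sedml = False
    for extra in doc.passthrough:
        archive.entries.append(ArchiveEntry(extra.location, extra.format_uri,
                                            extra.content, False))
    archive.validate()
    return archive


def archive_to_document(archive: Archive) -> OmexDocument:
    """Render every recognized archive entry back to human-readable form."""
    archive.validate()
    doc = OmexDocument()
    path_to_model_id: dict[str, str] = {}
    sbml_entries = []
    sedml_entries = []
    for e in archive.entries:
        if e.format_uri.startswith(FORMAT_SBML):
            sbml_entries.append(e)
        elif e.format_uri.startswith(FORMAT_SEDML):
            sedml_entries.append(e)
        else:
            doc.passthrough.append(e)
    for e in sbml_entries:
        mdoc = sbml_io.read_sbml(e.content)
        path_to_model_id[e.location] = mdoc.id
        doc.sections.append(Section("model", e.location,
                                    model_lang.render_model(mdoc)))
    # master SED-ML entry first, mirroring document_to_archive's convention
    sedml_entries.sort(key=lambda e: not e.master)
    for e in sedml_entries:
        spec = sedml_io.read_sedml(e.content)
        for m in spec.model_refs:
            if m.source in path_to_model_id:
                m.source = path_to_model_id[m.source]
        doc.sections.append(Section("simulation", e.location,
                                    sim_lang.render_simulation(spec)))
    doc.validate()
    return doc
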