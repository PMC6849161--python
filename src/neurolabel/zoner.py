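"""Document zoning: split a report into clinical-details, body and conclusion.

Radiology reports conventionally open with the referring clinician's
details, continue with the findings, and close with the radiologist's
conclusion.  Section headers are matched case-insensitively at the start
of a line, with an optional trailing colon.  Hospitals differ in their
header vocabulary, so the header table is configurable; the shipped
default covers the common dictation dialects.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

from .model import ReportDocument, Section, SectionKind
from .resources import open_data

__all__ = ["DEFAULT_HEADERS", "load_header_config", "zone"]

HeaderTable = Sequence[tuple[str, SectionKind]]


def _default_headers() -> list[tuple[str, SectionKind]]:
    with open_data("headers.tsv") as fh:
        return _parse_header_lines(fh.read().splitlines(), "headers.tsv")


def _parse_header_lines(lines: Sequence[str], source: str) -> list[tuple[str, SectionKind]]:
    table: list[tuple[str, SectionKind]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{source} line {lineno}: expected pattern<TAB>kind")
        pattern, kind_s = parts
        try:
            kind = SectionKind(kind_s.strip())
        except ValueError:
            raise ValueError(f"{source} line {lineno}: unknown section kind "
                             f"{kind_s!r}")
        table.append((pattern.strip().lower(), kind))
    return table


def load_header_config(path: str | Path) -> list[tuple[str, SectionKind]]:
    """Load a header-pattern table from a two-column TSV file."""
    path = Path(path)
    return _parse_header_lines(path.read_text().splitlines(), str(path))


DEFAULT_HEADERS: list[tuple[str, SectionKind]] = []


def _headers() -> HeaderTable:
    global DEFAULT_HEADERS
    if not DEFAULT_HEADERS:
        DEFAULT_HEADERS = _default_headers()
    return DEFAULT_HEADERS


def _match_header(line: str, table: HeaderTable) -> Optional[SectionKind]:
    """Return the section kind opened by this line, if it is a header line."""
    text = line.strip().lower()
    # longest patterns first so "clinical history" beats "history"
    for pattern, kind in sorted(table, key=lambda p: -len(p[0])):
        if text.startswith(pattern):
            rest = text[len(pattern):]
            # header word must end here: allow ":" or whitespace, not more letters
            if not rest or not rest[0].isalnum():
                return kind
    return None


def zone(doc: ReportDocument, header_config: Optional[HeaderTable] = None) -> ReportDocument:
    """Partition ``raw_text`` into sections by line-initial headers.

    The header line belongs to the section it opens.  Text before the
    first recognised header becomes clinical details (the usual position
    of the referral preamble); a report with no recognisable headers
    becomes a single findings-body section.  Idempotent: an already-zoned
    document is returned unchanged.
    """
    if doc.sections:
        return doc
    table = header_config if header_config is not None else _headers()

    text = doc.raw_text
    line_starts = [0] + [m.end() for m in re.finditer(r"\n", text)]
    boundaries: list[tuple[int, SectionKind]] = []
    for start in line_starts:
        end = text.find("\n", start)
        line = text[start : end if end != -1 else len(text)]
        kind = _match_header(line, table)
        if kind is not None:
            boundaries.append((start, kind))

    sections: list[Section] = []
    if not boundaries:
        sections.append(Section(SectionKind.REPORT_BODY, 0, len(text)))
    else:
        first_start = boundaries[0][0]
        if first_start > 0:
            sections.append(Section(SectionKind.CLINICAL_DETAILS, 0, first_start))
        for i, (start, kind) in enumerate(boundaries):
            end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(text)
            if end > start:
                sections.append(Section(kind, start, end))
    doc.sections = sections
    return doc
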