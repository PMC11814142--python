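"""Read, write and validate request manifests (XML interchange format).

A manifest carries everything a node needs to decide on and execute a
query: identifier, single/series type, syntax, requester metadata,
reference and execution dates, the five-segment cover letter, and the
targeted node ids.
"""

from __future__ import annotations

import re
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .model import (
    COVER_LETTER_SEGMENTS,
    CoverLetter,
    InvalidManifest,
    RequestManifest,
    Requester,
)

__all__ = ["manifest_to_xml", "manifest_from_xml", "write_manifest", "read_manifest",
           "render_manifest"]

_DURATION_RE = re.compile(
    r"^P(?:(?P<days>\d+)D)?(?:T(?:(?P<hours>\d+)H)?(?:(?P<minutes>\d+)M)?"
    r"(?:(?P<seconds>\d+)S)?)?$"
)


def _format_duration(delta: timedelta) -> str:
    total = int(delta.total_seconds())
    days, rem = divmod(total, 86400)
    out = "P"
    if days:
        out += f"{days}D"
    if rem or not days:
        out += f"T{rem}S"
    return out


def _parse_duration(token: str) -> timedelta:
    m = _DURATION_RE.match(token.strip())
    if not m or token.strip() == "P":
        raise InvalidManifest(f"unparseable interval {token!r}")
    parts = {k: int(v) for k, v in m.groupdict().items() if v}
    return timedelta(
        days=parts.get("days", 0),
        hours=parts.get("hours", 0),
        minutes=parts.get("minutes", 0),
        seconds=parts.get("seconds", 0),
    )


def _format_dt(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _parse_dt(token: str) -> datetime:
    token = token.strip()
    if token.endswith("Z"):
        token = token[:-1] + "+00:00"
    ts = datetime.fromisoformat(token)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def manifest_to_xml(manifest: RequestManifest) -> etree._Element:
    root = etree.Element("request")
    etree.SubElement(root, "id").text = manifest.request_id
    etree.SubElement(root, "type").text = manifest.query_type
    if manifest.series_interval is not None:
        etree.SubElement(root, "interval").text = _format_duration(
            manifest.series_interval
        )
    if manifest.series_count is not None:
        etree.SubElement(root, "count").text = str(manifest.series_count)
    syntax = etree.SubElement(root, "syntax", language=manifest.syntax_language)
    syntax.text = manifest.syntax_body
    meta = etree.SubElement(root, "metadata")
    req = etree.SubElement(meta, "requester")
    etree.SubElement(req, "name").text = manifest.requester.name
    etree.SubElement(req, "affiliation").text = manifest.requester.affiliation
    etree.SubElement(req, "email").text = manifest.requester.email
    etree.SubElement(meta, "reference-date").text = _format_dt(manifest.reference_date)
    etree.SubElement(meta, "execution-date").text = _format_dt(manifest.execution_date)
    etree.SubElement(meta, "retroactive").text = (
        "true" if manifest.retroactive else "false"
    )
    letter = etree.SubElement(root, "cover-letter")
    for seg in COVER_LETTER_SEGMENTS:
        etree.SubElement(letter, seg.replace("_", "-")).text = getattr(
            manifest.cover_letter, seg
        )
    targets = etree.SubElement(root, "targets")
    for node_id in sorted(manifest.target_nodes):
        etree.SubElement(targets, "node").text = node_id
    return root


def _text(parent: etree._Element, tag: str, required: bool = True) -> str:
    el = parent.find(tag)
    if el is None:
        if required:
            raise InvalidManifest(f"missing element <{tag}>")
        return ""
    return el.text or ""


def manifest_from_xml(root: etree._Element) -> RequestManifest:
    if root.tag != "request":
        raise InvalidManifest(f"root element is <{root.tag}>, expected <request>")
    syntax = root.find("syntax")
    if syntax is None:
        raise InvalidManifest("missing element <syntax>")
    meta = root.find("metadata")
    if meta is None:
        raise InvalidManifest("missing element <metadata>")
    req_el = meta.find("requester")
    if req_el is None:
        raise InvalidManifest("missing element <requester>")
    letter_el = root.find("cover-letter")
    if letter_el is None:
        raise InvalidManifest("missing element <cover-letter>")
    segments = {
        seg: _text(letter_el, seg.replace("_", "-"), required=False)
        for seg in COVER_LETTER_SEGMENTS
    }
    interval_el = root.find("interval")
    count_el = root.find("count")
    targets_el = root.find("targets")
    targets = (
        frozenset(n.text or "" for n in targets_el.findall("node"))
        if targets_el is not None
        else frozenset()
    )
    manifest = RequestManifest(
        request_id=_text(root, "id"),
        query_type=_text(root, "type"),
        syntax_language=syntax.get("language", ""),
        syntax_body=syntax.text or "",
        requester=Requester(
            name=_text(req_el, "name"),
            affiliation=_text(req_el, "affiliation"),
            email=_text(req_el, "email"),
        ),
        reference_date=_parse_dt(_text(meta, "reference-date")),
        execution_date=_parse_dt(_text(meta, "execution-date")),
        cover_letter=CoverLetter(**segments),
        target_nodes=targets,
        series_interval=(
            _parse_duration(interval_el.text or "") if interval_el is not None else None
        ),
        series_count=int(count_el.text) if count_el is not None else None,
        retroactive=_text(meta, "retroactive", required=False).strip().lower()
        == "true",
    )
    manifest.check()
    return manifest


def write_manifest(manifest: RequestManifest, path: Union[str, Path]) -> None:
    tree = etree.ElementTree(manifest_to_xml(manifest))
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_manifest(path: Union[str, Path]) -> RequestManifest:
    tree = etree.parse(str(path))
    return manifest_from_xml(tree.getroot())


def render_manifest(manifest: RequestManifest) -> str:
    """Plain-text rendering in review order: id, metadata, letter, syntax."""
    lines = [
        f"Request {manifest.request_id} ({manifest.query_type})",
        f"  Requester:      {manifest.requester.name} "
        f"<{manifest.requester.email}>, {manifest.requester.affiliation}",
        f"  Reference date: {_format_dt(manifest.reference_date)}",
        f"  Execution date: {_format_dt(manifest.execution_date)}",
    ]
    if manifest.series_interval is not None:
        lines.append(f"  Series interval: {_format_duration(manifest.series_interval)}")
    lines.append("  Cover letter:")
    for seg in COVER_LETTER_SEGMENTS:
        title = seg.replace("_", " ").capitalize()
        body = getattr(manifest.cover_letter, seg).strip() or "(empty)"
        lines.append(f"    [{title}]")
        for ln in body.splitlines() or [""]:
            lines.append(f"      {ln}")
    lines.append(f"  Syntax ({manifest.syntax_language}):")
    for ln in manifest.syntax_body.strip().splitlines():
        lines.append(f"      {ln}")
    return "\n".join(lines)
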