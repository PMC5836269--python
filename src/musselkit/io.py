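"""Shared format readers/writers and run configuration.

Coordinate conventions: GFF3 is 1-based closed and BED 0-based half-open
on disk; both are converted to the internal 0-based half-open convention
at read time (and back on write).  All writers are atomic: content goes to
a temporary file in the target directory which is renamed into place, so a
failed run never leaves a partial output.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .curation import AlignmentEvidence, CurationError, GeneModel, RepeatTrack

__all__ = [
    "atomic_write",
    "read_gff3_models",
    "write_gff3_models",
    "read_bed_track",
    "write_bed_track",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "RunConfig",
    "write_provenance",
]


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


# ---------------------------------------------------------------------------
# GFF3 gene models (exon features grouped by Parent)


def read_gff3_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 ``exon`` features grouped by ``Parent``.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Exon strand conflicts within a model raise :class:`CurationError`.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    scaffolds: dict[str, str] = {}
    strands: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise CurationError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype.lower() != "exon":
                continue
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            parent = attr_map.get("Parent") or attr_map.get("gene_id") or attr_map.get("ID")
            if parent is None:
                raise CurationError(f"{path}:{lineno}: exon without Parent/gene_id/ID attribute")
            iv = (int(start) - 1, int(end))  # GFF3 1-based closed -> half-open
            if parent not in exons:
                exons[parent] = []
                scaffolds[parent] = seqid
                strands[parent] = strand if strand in {"+", "-"} else "+"
                order.append(parent)
            else:
                if scaffolds[parent] != seqid:
                    raise CurationError(f"{path}:{lineno}: model {parent!r} spans scaffolds")
            exons[parent].append(iv)
    return [
        GeneModel(id=mid, scaffold=scaffolds[mid], strand=strands[mid],
                  exons=tuple(sorted(exons[mid])))
        for mid in order
    ]


def write_gff3_models(models: Sequence[GeneModel], path: str | Path, source: str = "musselkit") -> None:
    """Write gene models as GFF3 ``gene`` + ``exon`` features."""
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.scaffold}\t{source}\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            for i, (a, b) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.scaffold}\t{source}\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.id}.exon{i};Parent={m.id}\n"
                )


# ---------------------------------------------------------------------------
# BED repeat tracks (native 0-based half-open)


def read_bed_track(path: str | Path) -> RepeatTrack:
    """Read a BED3+ file as a repeat track (coordinates used as-is)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CurationError(f"{path}:{lineno}: expected >= 3 BED columns")
            intervals.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return RepeatTrack(intervals)


def write_bed_track(track: RepeatTrack, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for scaffold in track.scaffolds:
            for a, b in track.intervals(scaffold):
                fh.write(f"{scaffold}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Alignment evidence (tabular BLAST outfmt-6-like)

_EVIDENCE_COLUMNS = ("qseqid", "sseqid", "qlen", "qstart", "qend", "evalue")


def read_evidence_tsv(path: str | Path) -> list[AlignmentEvidence]:
    """Read alignment evidence from a BLAST outfmt-6-like TSV.

    Columns: ``qseqid sseqid qlen qstart qend evalue`` (header line with
    ``#`` or the literal column names is skipped).  ``qstart``/``qend``
    follow the 1-based closed BLAST convention, so the aligned query span
    is ``qend - qstart + 1``.
    """
    out: list[AlignmentEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(_EVIDENCE_COLUMNS[0]):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CurationError(f"{path}:{lineno}: expected >= 6 columns")
            qseqid, sseqid, qlen, qstart, qend, evalue = fields[:6]
            out.append(
                AlignmentEvidence(
                    model_id=qseqid,
                    subject_id=sseqid,
                    query_length=int(qlen),
                    aligned_query_span=int(qend) - int(qstart) + 1,
                    e_value=float(evalue),
                )
            )
    return out


def write_evidence_tsv(evidence: Sequence[AlignmentEvidence], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for ev in evidence:
            fh.write(
                f"{ev.model_id}\t{ev.subject_id}\t{ev.query_length}\t1\t"
                f"{ev.aligned_query_span}\t{ev.e_value:g}\n"
            )


# ---------------------------------------------------------------------------
# Run configuration / provenance


@dataclass
class RunConfig:
    """Echo of the parameters a subcommand ran with, for provenance."""

    subcommand: str
    parameters: dict = field(default_factory=dict)

    _KNOWN = {"subcommand", "parameters"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(subcommand=data.get("subcommand", ""), parameters=data.get("parameters", {}))

    def to_dict(self) -> dict:
        return {"subcommand": self.subcommand, "parameters": dict(self.parameters)}


def write_provenance(path: str | Path, config: RunConfig) -> None:
    """Write a provenance JSON: package version, timestamp, full parameter echo.

    The timestamp is the only non-deterministic field in any output file.
    """
    from . import __version__

    payload = {
        "tool": "musselkit",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **config.to_dict(),
    }
    with atomic_write(path) as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
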