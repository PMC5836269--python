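"""Assembly summary statistics and BUSCO percentage arithmetic.

Computes the standard per-assembly summary set used in genome-report
comparison tables — scaffold counts, total size, longest/shortest, counts
and percentages above size thresholds, mean/median, N50, soft-masked
fraction — plus BUSCO completeness percentages from raw category counts.

Conventions
-----------
* Soft-masked positions are lowercase a/c/g/t; N/n positions are gaps and
  are counted separately (they are not masked).
* N50 is the first length, scanning scaffolds in decreasing size order, at
  which the cumulative size reaches 50% of the assembly.
* Displayed integers round half away from zero; displayed percentages use
  one decimal for the size-threshold rows and two decimals for the
  genome-fraction-in-large-scaffolds row.  BUSCO percentages are truncated
  to two decimals (trailing zeros trimmed), matching the convention of
  published BUSCO summary tables.  Internal values are never rounded.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ScaffoldRecord",
    "AssemblyStats",
    "BuscoCounts",
    "read_fasta_lengths",
    "nxx",
    "summarize",
    "busco_percentages",
    "comparison_table",
    "parse_comparison_table",
    "contig_lengths",
    "round_half_away",
    "display_mean",
    "display_pct1",
]

_GAP_BYTES = frozenset(b"Nn")


@dataclass(frozen=True)
class ScaffoldRecord:
    """One scaffold: length, soft-masked (lowercase) bases and N-gap bases."""

    id: str
    length: int
    masked_bases: int = 0
    gap_bases: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"scaffold {self.id!r}: length must be >= 1")
        if not 0 <= self.masked_bases <= self.length:
            raise ValueError(f"scaffold {self.id!r}: masked_bases out of range")
        if not 0 <= self.gap_bases <= self.length:
            raise ValueError(f"scaffold {self.id!r}: gap_bases out of range")


def _tally(record_id: str, seq: str) -> ScaffoldRecord:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size == 0:
        raise ValueError(f"zero-length record {record_id!r}")
    lower = (arr >= 97) & (arr <= 122)
    gaps = (arr == ord("N")) | (arr == ord("n"))
    masked = int(np.count_nonzero(lower & ~gaps))
    return ScaffoldRecord(
        id=record_id,
        length=int(arr.size),
        masked_bases=masked,
        gap_bases=int(np.count_nonzero(gaps)),
    )


def read_fasta_lengths(path: str | Path) -> list[ScaffoldRecord]:
    """One :class:`ScaffoldRecord` per FASTA sequence (plain or gzip).

    Lengths, lowercase (soft-masked) positions and N-gap positions are
    tallied in a single pass.  Duplicate ids and zero-length records raise
    ``ValueError``.  An empty file yields an empty list.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(_tally(rec.id, str(rec.seq)))
    return records


def nxx(lengths: Sequence[int], x: float = 50) -> int:
    """Nxx statistic: e.g. ``nxx(lengths, 50)`` is the N50.

    Sort lengths in decreasing order and accumulate; return the first
    length at which the cumulative sum reaches ``x`` percent of the total.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("Nxx of an empty length list is undefined")
    if not 0 < x < 100:
        raise ValueError(f"x must lie strictly between 0 and 100, got {x}")
    arr = np.sort(arr)[::-1]
    cum = np.cumsum(arr)
    # integer comparison cum*100 >= x*total avoids float thresholds
    idx = int(np.searchsorted(cum * 100, x * cum[-1], side="left"))
    return int(arr[idx])


@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics for one assembly (all values unrounded)."""

    n_scaffolds: int
    total_size: int
    longest: int
    shortest: int
    n_over_1kb: int
    pct_over_1kb: float
    n_over_1mb: int
    pct_over_1mb: float
    mean: float
    median: float
    n50: int
    percent_over_50kb: float
    masked_percent: float | None = None

    def __post_init__(self) -> None:
        if not self.shortest <= self.median <= self.longest:
            raise ValueError("median must lie between shortest and longest")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize(
    records: Iterable[ScaffoldRecord] | Sequence[int],
    *,
    kb_threshold: int = 1_000,
    mb_threshold: int = 1_000_000,
    large_threshold: int = 50_000,
) -> AssemblyStats:
    """Compute the full comparison-table statistic set for one assembly.

    Accepts either :class:`ScaffoldRecord` lists (masked percentage is then
    reported) or bare length lists (masked percentage is ``None``).
    Thresholds select the "> 1 Kb", "> 1 Mb" count rows and the
    genome-fraction-in-scaffolds-over-50-Kb row.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty assembly")
    if isinstance(records[0], ScaffoldRecord):
        lengths = np.array([r.length for r in records], dtype=np.int64)
        masked = int(sum(r.masked_bases for r in records))
        masked_percent: float | None = 100.0 * masked / int(lengths.sum())
    else:
        lengths = np.asarray(records, dtype=np.int64)
        masked_percent = None
    total = int(lengths.sum())
    n = int(lengths.size)
    n_kb = int(np.count_nonzero(lengths > kb_threshold))
    n_mb = int(np.count_nonzero(lengths > mb_threshold))
    large = int(lengths[lengths > large_threshold].sum())
    return AssemblyStats(
        n_scaffolds=n,
        total_size=total,
        longest=int(lengths.max()),
        shortest=int(lengths.min()),
        n_over_1kb=n_kb,
        pct_over_1kb=100.0 * n_kb / n,
        n_over_1mb=n_mb,
        pct_over_1mb=100.0 * n_mb / n,
        mean=total / n,
        median=float(np.median(lengths)),
        n50=nxx(lengths, 50),
        percent_over_50kb=100.0 * large / total,
        masked_percent=masked_percent,
    )


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for integer cells)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def display_mean(total_size: int, n_scaffolds: int) -> int:
    """Mean scaffold size as displayed in comparison tables (integer)."""
    return round_half_away(total_size / n_scaffolds)


def display_pct1(count: int, total: int) -> str:
    """Percentage at one decimal, with a trailing ``.0`` trimmed (``100``)."""
    pct = round(100.0 * count / total, 1)
    return str(int(pct)) if pct == int(pct) else f"{pct:.1f}"


# ---------------------------------------------------------------------------
# BUSCO arithmetic


@dataclass(frozen=True)
class BuscoCounts:
    """Raw BUSCO category counts for one assembly."""

    total_searched: int
    complete: int
    complete_single: int
    complete_duplicated: int
    fragmented: int
    missing: int

    def validate(self) -> None:
        failures = []
        if self.complete != self.complete_single + self.complete_duplicated:
            failures.append("complete != complete_single + complete_duplicated")
        if self.complete + self.fragmented + self.missing != self.total_searched:
            failures.append("complete + fragmented + missing != total_searched")
        if min(
            self.total_searched,
            self.complete,
            self.complete_single,
            self.complete_duplicated,
            self.fragmented,
            self.missing,
        ) < 0:
            failures.append("negative count")
        if failures:
            raise ValueError("invalid BUSCO counts: " + "; ".join(failures))


def _truncate_pct(count: int, total: int) -> float:
    # integer truncation to two decimals: 769/978 -> 78.62, not 78.63
    return (count * 10000 // total) / 100


def busco_percentages(c: BuscoCounts) -> list[tuple[str, int, float | None]]:
    """BUSCO summary rows ``(category, count, percent)``.

    Percentages are ``count / total_searched * 100`` truncated to two
    decimals (trailing zeros trimmed on display); the total row carries no
    percentage.
    """
    c.validate()
    t = c.total_searched
    return [
        ("Total BUSCO groups searched", t, None),
        ("Complete BUSCOs", c.complete, _truncate_pct(c.complete, t)),
        ("Complete and single-copy BUSCOs", c.complete_single, _truncate_pct(c.complete_single, t)),
        ("Complete and duplicated BUSCOs", c.complete_duplicated, _truncate_pct(c.complete_duplicated, t)),
        ("Fragmented BUSCOs", c.fragmented, _truncate_pct(c.fragmented, t)),
        ("Missing BUSCOs", c.missing, _truncate_pct(c.missing, t)),
    ]


def busco_table(c: BuscoCounts) -> str:
    """TSV rendering of :func:`busco_percentages`."""
    lines = ["category\tcount\tpercent"]
    for name, count, pct in busco_percentages(c):
        shown = "-" if pct is None else f"{pct:g}"
        lines.append(f"{name}\t{count}\t{shown}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cross-assembly comparison table

_ROW_ORDER = (
    "Number of scaffolds",
    "Total size of scaffolds",
    "Longest scaffold",
    "Shortest scaffold",
    "Number of scaffolds >1 K nt (%)",
    "Number of scaffolds >1 M nt (%)",
    "Mean scaffold size",
    "Median scaffold size",
    "N50 scaffold length",
)


def comparison_table(stats: Mapping[str, AssemblyStats], *, display: bool = True) -> str:
    """Multi-assembly comparison TSV (assemblies as columns, stats as rows).

    ``display=True`` applies the publication formatting conventions (integer
    means, one-decimal percentages); ``display=False`` emits full-precision
    values so the table round-trips numerically through
    :func:`parse_comparison_table`.
    """
    if not stats:
        raise ValueError("need at least one assembly")

    def fmt_num(x: float) -> str:
        if display:
            return str(round_half_away(x))
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    def fmt_count_pct(count: int, pct: float, total: int) -> str:
        if display:
            return f"{count} ({display_pct1(count, total)})"
        return f"{count} ({pct!r})"

    rows: dict[str, list[str]] = {label: [] for label in _ROW_ORDER}
    for s in stats.values():
        rows["Number of scaffolds"].append(str(s.n_scaffolds))
        rows["Total size of scaffolds"].append(str(s.total_size))
        rows["Longest scaffold"].append(str(s.longest))
        rows["Shortest scaffold"].append(str(s.shortest))
        rows["Number of scaffolds >1 K nt (%)"].append(
            fmt_count_pct(s.n_over_1kb, s.pct_over_1kb, s.n_scaffolds)
        )
        rows["Number of scaffolds >1 M nt (%)"].append(
            fmt_count_pct(s.n_over_1mb, s.pct_over_1mb, s.n_scaffolds)
        )
        rows["Mean scaffold size"].append(fmt_num(s.mean))
        rows["Median scaffold size"].append(fmt_num(s.median))
        rows["N50 scaffold length"].append(str(s.n50))

    lines = ["Statistic\t" + "\t".join(stats.keys())]
    for label in _ROW_ORDER:
        lines.append(label + "\t" + "\t".join(rows[label]))
    return "\n".join(lines) + "\n"


_PCT_CELL = re.compile(r"^(?P<count>\d+) \((?P<pct>[0-9.eE+-]+)\)$")


def parse_comparison_table(text: str) -> dict[str, dict[str, float | tuple[int, float]]]:
    """Parse a :func:`comparison_table` TSV back into per-assembly values.

    Count-with-percentage cells come back as ``(count, percent)`` tuples,
    everything else as floats.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    names = header[1:]
    out: dict[str, dict[str, float | tuple[int, float]]] = {name: {} for name in names}
    for line in lines[1:]:
        cells = line.split("\t")
        label = cells[0]
        for name, cell in zip(names, cells[1:]):
            m = _PCT_CELL.match(cell)
            if m:
                out[name][label] = (int(m.group("count")), float(m.group("pct")))
            else:
                out[name][label] = float(cell)
    return out


# ---------------------------------------------------------------------------
# Contigs within scaffolds


def contig_lengths(seq: str, n_split: int = 10) -> list[int]:
    """Lengths of the contigs obtained by splitting at runs of >= n_split N's.

    Shorter N runs stay inside their contig and count toward its length.
    """
    if n_split < 1:
        raise ValueError("n_split must be >= 1")
    parts = re.split("[Nn]{%d,}" % n_split, seq)
    return [len(p) for p in parts if p]


def contig_count_fasta(path: str | Path, n_split: int = 10) -> int:
    """Total contig count of a FASTA after N-run splitting."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    total = 0
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            total += len(contig_lengths(str(rec.seq), n_split))
    return total
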