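"""Gene-model curation cascade for ab initio predictor training sets.

Transcript-derived gene models are distilled into a high-confidence
training set by four successive filters:

1. **coverage** — keep a model only if its best protein hit aligns at
   least 90% of the query sequence ("90% or more of their sequences
   showing in the hit alignment"); models without any hit are rejected.
2. **exons** — keep only models with more than 3 exons (the default;
   configurable to "at least 3").
3. **redundancy** — among models whose exon-projected footprints overlap
   by 90% or more (of the shorter model), only the longest is retained.
4. **repeats** — keep only models whose exons are entirely free of
   annotated repeat intervals (any 1-base overlap disqualifies).

All coordinates are 0-based half-open; converters at the file boundary
(`musselkit.io`) handle GFF3's 1-based closed convention.  Strand is
carried on the models but interval logic is strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "CurationError",
    "GeneModel",
    "AlignmentEvidence",
    "RepeatTrack",
    "CurationConfig",
    "StageCount",
    "CurationReport",
    "REASON_NO_HIT",
    "REASON_LOW_COVERAGE",
    "REASON_FEW_EXONS",
    "REASON_REDUNDANT",
    "REASON_REPEAT",
    "best_hits",
    "coverage_filter",
    "exon_filter",
    "redundancy_filter",
    "repeat_filter",
    "curate",
]

logger = logging.getLogger(__name__)

REASON_NO_HIT = "no-hit"
REASON_LOW_COVERAGE = "low-coverage"
REASON_FEW_EXONS = "few-exons"
REASON_REDUNDANT = "redundant"
REASON_REPEAT = "repeat-overlap"


class CurationError(ValueError):
    """Inconsistent curation inputs (unknown ids, malformed intervals...)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene model as a set of exon intervals on a scaffold.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, sorted and
    non-overlapping; ``cds_length`` is the sum of exon spans.
    """

    id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CurationError(f"model {self.id!r}: strand must be '+' or '-'")
        if not self.exons:
            raise CurationError(f"model {self.id!r}: at least one exon required")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in exons:
            if a < 0 or b <= a:
                raise CurationError(f"model {self.id!r}: invalid exon interval ({a}, {b})")
            if prev_end is not None and a < prev_end:
                raise CurationError(f"model {self.id!r}: exons must be sorted and non-overlapping")
            prev_end = b
        object.__setattr__(self, "exons", exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class AlignmentEvidence:
    """Best-hit style alignment evidence for one model (protein query)."""

    model_id: str
    subject_id: str
    query_length: int
    aligned_query_span: int
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.aligned_query_span <= self.query_length:
            raise CurationError(
                f"evidence for {self.model_id!r}: aligned span must lie in [0, query_length]"
            )
        if self.e_value < 0:
            raise CurationError(f"evidence for {self.model_id!r}: negative e-value")

    @property
    def coverage(self) -> float:
        return self.aligned_query_span / self.query_length


class RepeatTrack:
    """Per-scaffold repeat intervals (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: dict[str, list[tuple[int, int]]] = {}
        for scaffold, ivs in intervals.items():
            pairs = sorted((int(a), int(b)) for a, b in ivs)
            for a, b in pairs:
                if a < 0 or b <= a:
                    raise CurationError(f"repeat track {scaffold!r}: invalid interval ({a}, {b})")
            self._intervals[scaffold] = pairs
            self._trees[scaffold] = IntervalTree.from_tuples(pairs) if pairs else IntervalTree()

    @property
    def scaffolds(self) -> list[str]:
        return sorted(self._intervals)

    def intervals(self, scaffold: str) -> list[tuple[int, int]]:
        return list(self._intervals.get(scaffold, []))

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any repeat interval (>= 1 base)."""
        tree = self._trees.get(scaffold)
        return bool(tree is not None and tree.overlaps(start, end))

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self._intervals


@dataclass(frozen=True)
class CurationConfig:
    """Tunable thresholds of the cascade.

    ``min_exons=4`` is the literal reading of "more than 3 exons"; set 3
    for the inclusive variant.  ``overlap_denominator`` selects what the
    pairwise shared exon-base count is divided by: the shorter model's
    cds length (default), the longer one's, or the union footprint.
    """

    min_cov: float = 0.90
    min_exons: int = 4
    min_overlap: float = 0.90
    overlap_denominator: str = "shorter"

    def __post_init__(self) -> None:
        if self.overlap_denominator not in {"shorter", "longer", "union"}:
            raise CurationError(
                f"overlap_denominator must be shorter|longer|union, got {self.overlap_denominator!r}"
            )


def best_hits(evidence: Iterable[AlignmentEvidence]) -> dict[str, AlignmentEvidence]:
    """Deterministic best hit per model: min e-value, then max span, then subject id."""
    best: dict[str, AlignmentEvidence] = {}
    for ev in evidence:
        cur = best.get(ev.model_id)
        if cur is None:
            best[ev.model_id] = ev
            continue
        key = (ev.e_value, -ev.aligned_query_span, ev.subject_id)
        cur_key = (cur.e_value, -cur.aligned_query_span, cur.subject_id)
        if key < cur_key:
            best[ev.model_id] = ev
    return best


def coverage_filter(
    models: Sequence[GeneModel],
    evidence: Iterable[AlignmentEvidence],
    min_cov: float = 0.90,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Keep models whose best hit covers >= ``min_cov`` of the query (inclusive).

    Models without evidence are rejected with reason ``"no-hit"``.  Evidence
    referencing an unknown model id raises :class:`CurationError`.
    """
    known = {m.id for m in models}
    evidence = list(evidence)
    unknown = sorted({ev.model_id for ev in evidence} - known)
    if unknown:
        raise CurationError(f"evidence references unknown model ids: {', '.join(unknown)}")
    best = best_hits(evidence)
    kept: list[GeneModel] = []
    rejected: dict[str, str] = {}
    for m in models:
        ev = best.get(m.id)
        if ev is None:
            rejected[m.id] = REASON_NO_HIT
        elif ev.coverage >= min_cov:
            kept.append(m)
        else:
            rejected[m.id] = REASON_LOW_COVERAGE
    return kept, rejected


def exon_filter(
    models: Sequence[GeneModel], min_exons: int = 4
) -> tuple[list[GeneModel], dict[str, str]]:
    """Keep models with at least ``min_exons`` exons (default 4, i.e. "more than 3")."""
    kept = [m for m in models if m.n_exons >= min_exons]
    rejected = {m.id: REASON_FEW_EXONS for m in models if m.n_exons < min_exons}
    return kept, rejected


def shared_exon_bases(a: GeneModel, b: GeneModel) -> int:
    """Bases shared by the exon projections of two models (same scaffold)."""
    if a.scaffold != b.scaffold:
        return 0
    total = 0
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        a0, a1 = a.exons[i]
        b0, b1 = b.exons[j]
        total += max(0, min(a1, b1) - max(a0, b0))
        if a1 < b1:
            i += 1
        else:
            j += 1
    return total


def _union_footprint(a: GeneModel, b: GeneModel) -> int:
    ivs = sorted(a.exons + b.exons)
    total = 0
    cur_a, cur_b = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = s, e
        else:
            cur_b = max(cur_b, e)
    return total + (cur_b - cur_a)


def _overlap_fraction(a: GeneModel, b: GeneModel, denominator: str) -> float:
    shared = shared_exon_bases(a, b)
    if shared == 0:
        return 0.0
    if denominator == "shorter":
        denom = min(a.cds_length, b.cds_length)
    elif denominator == "longer":
        denom = max(a.cds_length, b.cds_length)
    else:
        denom = _union_footprint(a, b)
    return shared / denom


def redundancy_filter(
    models: Sequence[GeneModel],
    min_overlap: float = 0.90,
    denominator: str = "shorter",
) -> tuple[list[GeneModel], dict[str, str]]:
    """Remove the shorter member of every pair overlapping >= ``min_overlap``.

    Removal runs to fixpoint; because only the shorter member of a pair is
    ever removed (length ties broken by keeping the lexicographically
    smaller id), the surviving set is independent of input order: a model
    survives iff no *surviving* longer model overlaps it at the threshold.
    Kept models are returned in their input order.
    """
    # longest first; ties keep the smaller id
    order = sorted(models, key=lambda m: (-m.cds_length, m.id))
    kept_by_scaffold: dict[str, list[GeneModel]] = {}
    removed: dict[str, str] = {}
    for m in order:
        peers = kept_by_scaffold.setdefault(m.scaffold, [])
        if any(_overlap_fraction(m, k, denominator) >= min_overlap for k in peers):
            removed[m.id] = REASON_REDUNDANT
        else:
            peers.append(m)
    kept = [m for m in models if m.id not in removed]
    return kept, removed


def repeat_filter(
    models: Sequence[GeneModel], repeats: RepeatTrack
) -> tuple[list[GeneModel], dict[str, str]]:
    """Keep models with no exon/repeat intersection (half-open; 1 base disqualifies).

    Models on scaffolds absent from the track are treated as repeat-free
    and logged at debug level.
    """
    kept: list[GeneModel] = []
    rejected: dict[str, str] = {}
    for m in models:
        if m.scaffold not in repeats:
            logger.debug("scaffold %s absent from repeat track; model %s treated as repeat-free",
                         m.scaffold, m.id)
            kept.append(m)
            continue
        if any(repeats.overlaps(m.scaffold, a, b) for a, b in m.exons):
            rejected[m.id] = REASON_REPEAT
        else:
            kept.append(m)
    return kept, rejected


@dataclass(frozen=True)
class StageCount:
    name: str
    n_in: int
    n_out: int


@dataclass(frozen=True)
class CurationReport:
    """Per-stage in/out counts, surviving ids, and per-model rejection reasons."""

    stages: tuple[StageCount, ...]
    survivors: tuple[str, ...]
    rejections: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["stage\tmodels_in\tmodels_out"]
        lines += [f"{s.name}\t{s.n_in}\t{s.n_out}" for s in self.stages]
        lines.append("")
        lines.append("model_id\tfate")
        for mid in self.survivors:
            lines.append(f"{mid}\tkept")
        for mid, reason in sorted(self.rejections.items()):
            lines.append(f"{mid}\trejected:{reason}")
        return "\n".join(lines) + "\n"


def curate(
    models: Sequence[GeneModel],
    evidence: Iterable[AlignmentEvidence],
    repeats: RepeatTrack,
    config: CurationConfig = CurationConfig(),
) -> tuple[list[GeneModel], CurationReport]:
    """Apply coverage -> exon -> redundancy -> repeat filters in order.

    Returns the surviving models (input order preserved) and a report with
    per-stage counts and a rejection reason for every discarded model.
    An empty input yields an empty output and a valid report.
    """
    rejections: dict[str, str] = {}
    stages: list[StageCount] = []

    evidence = list(evidence)
    current = list(models)
    for name, step in (
        ("coverage", lambda ms: coverage_filter(ms, evidence, config.min_cov)),
        ("exons", lambda ms: exon_filter(ms, config.min_exons)),
        ("redundancy", lambda ms: redundancy_filter(ms, config.min_overlap, config.overlap_denominator)),
        ("repeats", lambda ms: repeat_filter(ms, repeats)),
    ):
        n_in = len(current)
        current, rejected = step(current)
        rejections.update(rejected)
        stages.append(StageCount(name, n_in, len(current)))

    report = CurationReport(
        stages=tuple(stages),
        survivors=tuple(m.id for m in current),
        rejections=rejections,
    )
    return current, report
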