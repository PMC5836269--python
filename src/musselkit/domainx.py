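"""Protein-domain expansion/contraction analysis across genomes.

Given a genome x domain count matrix (e.g. Pfam-A assignments per
predicted proteome), the focal genome's count ``x`` for each domain is
compared against a Poisson expectation derived from the remaining genomes:
per-genome counts are first normalized to frequencies (dividing by each
genome's total domain count, which compensates for genome size and
annotation depth), the non-focal frequencies are averaged, and the average
is rescaled to the focal genome's total:

    lambda_d = mean_{g != focal}(count_{g,d} / N_g) * N_focal

One-sided Poisson tail probabilities ``P(X >= x | lambda)`` and
``P(X <= x | lambda)`` are Bonferroni-adjusted; a domain is called
*expanded* when the adjusted upper tail is significant with ``x > lambda``
and *contracted* when the adjusted lower tail is significant with
``x < lambda``.

For display, a log2-ratio matrix compares each genome's normalized count
with the cross-genome mean (a pseudocount keeps entries finite; it never
enters the test), and genomes/domains are grouped by complete-linkage
agglomeration on a length-normalized dot-product ("average dot product")
similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "DomainError",
    "DomainCountMatrix",
    "ExpansionResult",
    "Log2RatioMatrix",
    "Merge",
    "ClusterResult",
    "read_counts",
    "read_domtblout_counts",
    "expected_lambda",
    "expected_lambdas",
    "poisson_tails",
    "test_domains",
    "results_frame",
    "log2_ratio_matrix",
    "average_dot_similarity",
    "cluster",
]


class DomainError(ValueError):
    """Invalid domain-count input or test configuration."""


@dataclass
class DomainCountMatrix:
    """Genome x domain count matrix with per-genome totals.

    ``counts`` has genomes as the index and domain accessions as columns;
    entries are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise DomainError("duplicate genome or domain labels")
        if len(df.index) < 2:
            raise DomainError("need at least two genomes")
        arr = df.to_numpy()
        if np.any(arr < 0):
            raise DomainError("negative domain counts")
        self.counts = df.astype(np.int64)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Per-genome total domain count ``N_g`` (row sums)."""
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        """Per-genome domain frequencies (rows sum to 1 exactly)."""
        totals = self.totals
        if (totals == 0).any():
            zero = list(totals.index[totals == 0])
            raise DomainError(f"genomes with zero total counts: {zero}")
        return self.counts.div(totals, axis=0)

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["genome", "domain", "count"]
        return long

    def to_long_tsv(self, path: str | Path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            self.to_long().to_csv(fh, sep="\t", index=False)


def read_counts(source: str | Path | pd.DataFrame) -> DomainCountMatrix:
    """Build a count matrix from a long-format table (genome, domain, count).

    Accepts a TSV path or an equivalent DataFrame.  Missing (genome,
    domain) cells are zero-filled; duplicate cells and negative counts
    raise :class:`DomainError`.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = source.copy()
    required = {"genome", "domain", "count"}
    if not required.issubset(df.columns):
        raise DomainError(f"long table must have columns {sorted(required)}")
    if df.duplicated(subset=["genome", "domain"]).any():
        dups = df[df.duplicated(subset=["genome", "domain"], keep=False)]
        pairs = sorted(set(zip(dups["genome"], dups["domain"])))[:5]
        raise DomainError(f"duplicate (genome, domain) rows, e.g. {pairs}")
    if (df["count"] < 0).any():
        raise DomainError("negative domain counts")
    wide = df.pivot(index="genome", columns="domain", values="count").fillna(0)
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.index.name = None
    wide.columns.name = None
    return DomainCountMatrix(wide)


def read_domtblout_counts(
    paths: Mapping[str, str | Path], max_evalue: float = 1e-5
) -> DomainCountMatrix:
    """Count matrix from per-genome HMMER ``--domtblout``-style files.

    Rows are whitespace-separated; ``#`` lines are comments.  The domain
    label is the target accession (column 2) when present, otherwise the
    target name (column 1); the full-sequence e-value (column 7) is
    filtered at ``max_evalue`` before counting, one count per row.
    """
    rows = []
    for genome, path in paths.items():
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 7:
                    raise DomainError(f"{path}: expected >= 7 columns, got {len(fields)}")
                domain = fields[1] if fields[1] != "-" else fields[0]
                evalue = float(fields[6])
                if evalue <= max_evalue:
                    rows.append((genome, domain))
    if not rows:
        raise DomainError("no rows passed the e-value threshold")
    long = pd.DataFrame(rows, columns=["genome", "domain"])
    long = long.groupby(["genome", "domain"]).size().rename("count").reset_index()
    return read_counts(long)


def expected_lambdas(m: DomainCountMatrix, focal: str) -> pd.Series:
    """Poisson expectations for every domain in the focal genome.

    ``lambda_d = mean over non-focal genomes of (count_{g,d} / N_g) * N_focal``.
    """
    if focal not in m.counts.index:
        raise DomainError(f"unknown focal genome {focal!r}")
    freqs = m.frequencies()
    others = freqs.drop(index=focal)
    n_focal = int(m.totals.loc[focal])
    return others.mean(axis=0) * n_focal


def expected_lambda(m: DomainCountMatrix, focal: str, domain: str) -> float:
    """Expectation for a single domain (see :func:`expected_lambdas`)."""
    if domain not in m.counts.columns:
        raise DomainError(f"unknown domain {domain!r}")
    return float(expected_lambdas(m, focal).loc[domain])


def poisson_tails(x, lam):
    """One-sided Poisson tail probabilities ``(p_up, p_down)``.

    ``p_down = P(X <= x | lam)`` and ``p_up = P(X >= x | lam)``, so that
    ``p_up + p_down = 1 + pmf(x; lam)``.  ``lam = 0`` is the degenerate
    distribution at 0: ``p_down = 1`` and ``p_up = 1`` iff ``x = 0`` else 0.
    Accepts scalars or arrays.
    """
    x_arr = np.asarray(x)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(x_arr < 0) or np.any(lam_arr < 0):
        raise DomainError("counts and expectations must be non-negative")
    p_down = poisson.cdf(x_arr, lam_arr)
    p_up = poisson.sf(x_arr - 1, lam_arr)
    if np.isscalar(x) and np.isscalar(lam):
        return float(p_up), float(p_down)
    return p_up, p_down


@dataclass(frozen=True)
class ExpansionResult:
    """Per-domain test outcome in the focal genome."""

    domain: str
    observed: int
    expected: float
    p_up: float
    p_down: float
    p_adjusted: float
    call: str  # expanded | contracted | neutral


def test_domains(
    m: DomainCountMatrix,
    focal: str,
    alpha: float = 0.05,
    family_size: str = "directions",
    min_expected: float | None = None,
) -> list[ExpansionResult]:
    """Poisson tail tests with Bonferroni control for every informative domain.

    Domains with ``lambda > 0`` or a positive focal count are tested; raw
    one-sided p-values are multiplied by the Bonferroni family size and
    clipped at 1.  ``family_size="directions"`` (default) counts both
    one-sided families (2 x number of domains tested), which controls the
    family-wise error rate of the combined expanded+contracted call set at
    ``alpha``; ``"domains"`` counts each domain once.

    A plug-in expectation estimated from very few reference counts is
    unreliable; in the limit (all reference genomes at zero) the literal
    Poisson(0) model would declare any single focal count infinitely
    significant.  The test therefore floors the expectation at
    ``min_expected`` before computing tails — by default the rate implied
    by one pooled pseudo-count among the reference genomes,
    ``N_focal / sum(N_others)``.  Pass ``min_expected=0`` for the literal
    unfloored rule.  ``ExpansionResult.expected`` always reports the raw
    (unfloored) expectation.

    A domain is *expanded* when the adjusted upper tail is <= ``alpha`` and
    the observation exceeds its expectation, *contracted* symmetrically,
    otherwise *neutral*.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if family_size not in {"domains", "directions"}:
        raise DomainError("family_size must be 'domains' or 'directions'")
    lams = expected_lambdas(m, focal)
    obs = m.counts.loc[focal]
    tested = lams.index[(lams > 0) | (obs > 0)]
    n_tests = len(tested)
    factor = n_tests if family_size == "domains" else 2 * n_tests
    x = obs.loc[tested].to_numpy()
    lam = lams.loc[tested].to_numpy()
    if min_expected is None:
        totals = m.totals
        min_expected = float(totals.loc[focal]) / float(totals.drop(index=focal).sum())
    if min_expected < 0:
        raise DomainError("min_expected must be non-negative")
    lam_test = np.maximum(lam, min_expected)
    p_up, p_down = poisson_tails(x, lam_test)
    adj_up = np.minimum(1.0, p_up * factor)
    adj_down = np.minimum(1.0, p_down * factor)

    results = []
    for i, domain in enumerate(tested):
        if adj_up[i] <= alpha and x[i] > lam[i]:
            call, p_adj = "expanded", adj_up[i]
        elif adj_down[i] <= alpha and x[i] < lam[i]:
            call, p_adj = "contracted", adj_down[i]
        else:
            call, p_adj = "neutral", min(adj_up[i], adj_down[i])
        results.append(
            ExpansionResult(
                domain=str(domain),
                observed=int(x[i]),
                expected=float(lam[i]),
                p_up=float(p_up[i]),
                p_down=float(p_down[i]),
                p_adjusted=float(p_adj),
                call=call,
            )
        )
    return results


def results_frame(results: Sequence[ExpansionResult]) -> pd.DataFrame:
    """Results as a DataFrame (domain, observed, expected, tails, call)."""
    return pd.DataFrame(
        {
            "domain": [r.domain for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "p_up": [r.p_up for r in results],
            "p_down": [r.p_down for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "call": [r.call for r in results],
        }
    )


@dataclass(frozen=True)
class Log2RatioMatrix:
    """Display matrix of log2(normalized count / cross-genome mean)."""

    values: pd.DataFrame
    pseudocount: float
    reference_means: pd.Series
    scale_total: float

    def reconstructed_counts(self) -> pd.DataFrame:
        """Invert the transform back to normalized counts (algebraic check)."""
        return (2.0 ** self.values).mul(self.reference_means + self.pseudocount, axis=1) - self.pseudocount


def log2_ratio_matrix(
    m: DomainCountMatrix,
    pseudocount: float = 0.5,
    scale_total: float | None = None,
) -> Log2RatioMatrix:
    """Log2 ratio of each genome's normalized count to the cross-genome mean.

    Counts are frequency-normalized and rescaled to a common total
    (default: the mean per-genome total), then each entry is
    ``log2((norm + pc) / (mean_d + pc))`` with ``mean_d`` the cross-genome
    mean of the normalized counts for that domain.  The pseudocount only
    affects this display matrix, never the Poisson test.
    """
    if pseudocount < 0:
        raise DomainError("pseudocount must be non-negative")
    if scale_total is None:
        scale_total = float(m.totals.mean())
    norm = m.frequencies() * scale_total
    means = norm.mean(axis=0)
    values = np.log2(norm.add(pseudocount) .div(means + pseudocount, axis=1))
    return Log2RatioMatrix(
        values=values,
        pseudocount=pseudocount,
        reference_means=means,
        scale_total=scale_total,
    )


# ---------------------------------------------------------------------------
# Complete-linkage clustering on average-dot-product similarity


def average_dot_similarity(x: np.ndarray) -> np.ndarray:
    """Pairwise similarity ``S_ij = (x_i . x_j) / n_features``.

    The "average dot product": the mean elementwise product of the two
    rows' profiles (length-normalized so the scale does not grow with the
    number of domains).
    """
    x = np.asarray(x, dtype=float)
    return (x @ x.T) / x.shape[1]


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two clusters joined and their distance."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    distance: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[str, ...]
    merges: tuple[Merge, ...]
    newick: str


class _Node:
    __slots__ = ("members", "height", "newick", "rep")

    def __init__(self, members, height, newick, rep):
        self.members = members
        self.height = height
        self.newick = newick
        self.rep = rep


def cluster(
    data: Log2RatioMatrix | pd.DataFrame,
    axis: str = "genomes",
    similarity: str = "avg_dot",
) -> ClusterResult:
    """Complete-linkage agglomeration of rows or columns.

    Pairwise similarity is the average dot product (default) or cosine;
    it is converted to a non-negative distance by subtracting from the
    maximum similarity.  Inter-cluster distance is the maximum pairwise
    distance (complete linkage); equal-distance ties are broken by the
    lexicographic order of the clusters' representative (smallest member)
    labels, making the merge sequence deterministic.  Returns the merge
    order and an ultrametric Newick rendering.
    """
    df = data.values if isinstance(data, Log2RatioMatrix) else data
    if axis == "domains":
        df = df.T
    elif axis != "genomes":
        raise DomainError("axis must be 'genomes' or 'domains'")
    labels = [str(l) for l in df.index]
    if len(labels) < 2:
        raise DomainError("need at least two items to cluster")
    x = df.to_numpy(dtype=float)
    if similarity == "avg_dot":
        sim = average_dot_similarity(x)
    elif similarity == "cosine":
        norms = np.linalg.norm(x, axis=1)
        norms[norms == 0] = 1.0
        sim = (x @ x.T) / np.outer(norms, norms)
    else:
        raise DomainError("similarity must be 'avg_dot' or 'cosine'")
    dist = sim.max() - sim
    np.fill_diagonal(dist, 0.0)

    nodes = {
        i: _Node(members=(labels[i],), height=0.0, newick=labels[i], rep=labels[i])
        for i in range(len(labels))
    }
    # item-level distance matrix is fixed; cluster distance = max over members
    item_index = {label: i for i, label in enumerate(labels)}

    def cluster_distance(a: _Node, b: _Node) -> float:
        ia = [item_index[m] for m in a.members]
        ib = [item_index[m] for m in b.members]
        return float(dist[np.ix_(ia, ib)].max())

    merges: list[Merge] = []
    while len(nodes) > 1:
        best = None
        for ka in sorted(nodes, key=lambda k: nodes[k].rep):
            for kb in sorted(nodes, key=lambda k: nodes[k].rep):
                if nodes[ka].rep >= nodes[kb].rep:
                    continue
                d = cluster_distance(nodes[ka], nodes[kb])
                key = (d, nodes[ka].rep, nodes[kb].rep)
                if best is None or key < best[0]:
                    best = (key, ka, kb)
        (d, _, _), ka, kb = best
        a, b = nodes.pop(ka), nodes.pop(kb)
        merges.append(Merge(left=tuple(sorted(a.members)), right=tuple(sorted(b.members)), distance=d))
        la = max(d - a.height, 0.0)
        lb = max(d - b.height, 0.0)
        newick = f"({a.newick}:{la:.6g},{b.newick}:{lb:.6g})"
        nodes[ka] = _Node(
            members=a.members + b.members,
            height=d,
            newick=newick,
            rep=min(a.rep, b.rep),
        )
    root = next(iter(nodes.values()))
    return ClusterResult(labels=tuple(labels), merges=tuple(merges), newick=root.newick + ";")
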