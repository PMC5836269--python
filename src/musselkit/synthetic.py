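"""Synthetic data generators with recorded ground truth.

Every generator is deterministic given its parameters and seed, and
returns a :class:`SimTruth` record holding the planted parameters and the
expected downstream outcomes, so each analysis stage can be validated by
parameter recovery without external data.

Generators
----------
* :func:`sim_diploid_spectrum` — k-mer histograms of a diploid genome:
  a homozygous peak at the sequencing depth, a heterozygous peak near half
  that depth, and a steeply decaying error limb at low multiplicity.
* :func:`sim_scaffolds` — FASTA scaffold sets with known lengths,
  soft-masked fractions and N-gap runs.
* :func:`sim_gene_models` — gene-model sets with planted filter
  violations (low alignment coverage, too few exons, redundant pairs,
  repeat overlap, missing hits) and their expected curation fate.
* :func:`sim_domain_matrix` — genome x domain count matrices with planted
  fold-changes in a focal genome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .curation import AlignmentEvidence, GeneModel, RepeatTrack
from .domainx import DomainCountMatrix
from .spectra import KmerHistogram

__all__ = [
    "SimTruth",
    "sim_diploid_spectrum",
    "sim_scaffolds",
    "write_fasta",
    "sim_gene_models",
    "sim_domain_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# error k-mers: unique k-mers with geometric multiplicity, mean ~1.3;
# steep enough to leave a valley well below the heterozygous peak
_ERROR_GEOM_MEAN = 1.3


@dataclass
class SimTruth:
    """Planted parameters and expected outcomes of one simulated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(asdict(self), indent=indent, sort_keys=True, default=_jsonable)
        if path is not None:
            from .io import atomic_write

            with atomic_write(path) as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# k-mer spectra


def _histogram_from_multiplicities(parts: list[np.ndarray], k: int) -> KmerHistogram:
    top = max(int(p.max()) for p in parts if p.size)
    dense = np.zeros(top + 1, dtype=np.int64)
    for p in parts:
        if p.size:
            dense += np.bincount(p, minlength=top + 1)
    ms = np.nonzero(dense[1:])[0] + 1
    return KmerHistogram(k=k, multiplicities=ms, counts=dense[ms])


def _error_multiplicities(rng: np.random.Generator, n_err: int) -> list[np.ndarray]:
    parts = []
    p = 1.0 / _ERROR_GEOM_MEAN
    remaining = n_err
    while remaining > 0:  # chunk to bound peak memory
        chunk = min(remaining, 5_000_000)
        parts.append(rng.geometric(p, chunk).astype(np.int64))
        remaining -= chunk
    return parts


def sim_diploid_spectrum(
    genome_len: int,
    het_rate: float,
    coverage: float,
    error_rate: float = 0.01,
    k: int = 17,
    seed: int = 0,
    mode: str = "direct",
) -> tuple[KmerHistogram, SimTruth]:
    """Simulate the k-mer histogram of a diploid genome.

    ``coverage`` is the total sequencing depth, so homozygous k-mers (shared
    by both haplotypes) have Poisson(coverage) multiplicity and
    haplotype-specific k-mers Poisson(coverage/2).  A genome position's
    k-mer is haplotype-specific when any of its k bases is heterozygous,
    i.e. with probability ``1 - (1 - het_rate)^k``.  Sequencing errors add
    ``genome_len * coverage * error_rate * k`` unique k-mers with
    geometric multiplicities (mean ~1.3), producing the low-multiplicity
    error limb.

    ``mode="direct"`` samples the multiplicity of each distinct k-mer from
    this analytic model; ``mode="sequence"`` actually builds the two
    haplotype sequences, enumerates their k-mers (circularly) and samples
    per distinct k-mer — slower, used to validate the direct mode on small
    genomes.
    """
    if genome_len < 10 * k:
        raise ValueError(f"genome_len must be >= 10*k = {10 * k}")
    if not 0 <= het_rate < 0.05:
        raise ValueError(f"het_rate must lie in [0, 0.05), got {het_rate}")
    if coverage < 5:
        raise ValueError(f"coverage must be >= 5, got {coverage}")
    if mode not in {"direct", "sequence"}:
        raise ValueError("mode must be 'direct' or 'sequence'")

    rng = np.random.default_rng(seed)
    n_err = int(round(genome_len * coverage * error_rate * k))

    if mode == "direct":
        p_win = 1.0 - (1.0 - het_rate) ** k
        n_het_pos = int(rng.binomial(genome_len, p_win))
        d_het = 2 * n_het_pos
        d_hom = genome_len - n_het_pos
        parts = [
            rng.poisson(coverage, d_hom).astype(np.int64),
            rng.poisson(coverage / 2.0, d_het).astype(np.int64),
        ]
    else:
        hap_a = rng.integers(0, 4, genome_len, dtype=np.int8)
        snp = rng.random(genome_len) < het_rate
        hap_b = hap_a.copy()
        hap_b[snp] = (hap_a[snp] + rng.integers(1, 4, int(snp.sum()))) % 4
        codes = np.concatenate([_kmer_codes(hap_a, k), _kmer_codes(hap_b, k)])
        _, copy_numbers = np.unique(codes, return_counts=True)
        n_het_pos = int(snp.sum())
        d_het = int((copy_numbers == 1).sum())
        d_hom = int((copy_numbers > 1).sum())
        parts = [rng.poisson(copy_numbers * (coverage / 2.0)).astype(np.int64)]

    parts.extend(_error_multiplicities(rng, n_err))
    hist = _histogram_from_multiplicities(parts, k)

    truth = SimTruth(
        scenario="diploid-spectrum",
        seed=seed,
        params={
            "genome_len": genome_len,
            "het_rate": het_rate,
            "coverage": coverage,
            "error_rate": error_rate,
            "k": k,
            "mode": mode,
        },
        expected={
            "genome_size": genome_len,
            "heterozygosity": het_rate,
            "hom_peak_depth": coverage,
            "het_peak_depth": coverage / 2.0,
            "ploidy_call": "haploid-like" if het_rate == 0 else "diploid-heterozygous",
            "n_het_positions": n_het_pos,
            "distinct_het_kmers": d_het,
            "distinct_hom_kmers": d_hom,
            "n_error_kmers": n_err,
        },
    )
    return hist, truth


def _kmer_codes(seq: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit k-mer codes of a circular sequence (k <= 31)."""
    if k > 31:
        raise ValueError("sequence mode supports k <= 31")
    ext = np.concatenate([seq, seq[: k - 1]]).astype(np.uint64)
    codes = np.zeros(len(seq), dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | ext[j : j + len(seq)]
    return codes


# ---------------------------------------------------------------------------
# scaffold sets


def _draw_lengths(rng: np.random.Generator, n: int, length_law, min_length: int) -> np.ndarray:
    name, *params = length_law
    if name == "lognormal":
        mu, sigma = params
        lengths = rng.lognormal(mu, sigma, n)
    elif name == "uniform":
        lo, hi = params
        lengths = rng.uniform(lo, hi, n)
    elif name == "fixed":
        (value,) = params
        lengths = np.full(n, float(value))
    else:
        raise ValueError(f"unknown length law {name!r}")
    return np.maximum(np.round(lengths).astype(np.int64), min_length)


def sim_scaffolds(
    n: int,
    length_law: tuple = ("lognormal", 9.2, 1.3),
    masked_fraction: float = 0.0,
    seed: int = 0,
    min_length: int = 500,
    n_gap_runs: int = 0,
    gap_run_length: int = 20,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate a scaffold FASTA with known lengths, masking and gaps.

    Each scaffold is random A/C/G/T; a contiguous block of
    ``round(masked_fraction * length)`` bases is lowercased (soft-masked),
    and ``n_gap_runs`` runs of ``gap_run_length`` N's are inserted
    (replacing bases) at spaced positions.  Returns ``(records, truth)``
    where records are ``(id, sequence)`` pairs and the truth lists exact
    per-record lengths, masked and gap counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= masked_fraction <= 1.0:
        raise ValueError("masked_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, n, length_law, min_length)
    records: list[tuple[str, str]] = []
    per_record = []
    for i, length in enumerate(lengths):
        length = int(length)
        arr = _BASES[rng.integers(0, 4, length)].copy()
        n_gaps = 0
        if n_gap_runs > 0 and length > (gap_run_length + 2) * n_gap_runs:
            span = length // n_gap_runs
            for g in range(n_gap_runs):
                start = g * span + int(rng.integers(1, span - gap_run_length - 1))
                arr[start : start + gap_run_length] = ord("N")
                n_gaps += gap_run_length
        n_masked = int(round(masked_fraction * length))
        if n_masked > 0:
            start = int(rng.integers(0, length - n_masked + 1))
            block = arr[start : start + n_masked]
            is_base = block != ord("N")
            block[is_base] = block[is_base] + 32  # ASCII lowercase
            n_masked = int(is_base.sum())
        rec_id = f"scaffold_{i + 1:05d}"
        records.append((rec_id, arr.tobytes().decode("ascii")))
        per_record.append({"id": rec_id, "length": length, "masked": n_masked, "gaps": n_gaps})
    truth = SimTruth(
        scenario="scaffolds",
        seed=seed,
        params={
            "n": n,
            "length_law": list(length_law),
            "masked_fraction": masked_fraction,
            "min_length": min_length,
            "n_gap_runs": n_gap_runs,
            "gap_run_length": gap_run_length,
        },
        expected={
            "records": per_record,
            "total_size": int(lengths.sum()),
            "lengths": lengths.tolist(),
        },
    )
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(id, sequence)`` records as FASTA."""
    from .io import atomic_write

    with atomic_write(path) as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene-model sets with planted curation violations

_DEFAULT_MIX = {
    "clean": 0.5,
    "low_coverage": 0.1,
    "few_exon": 0.1,
    "redundant": 0.1,
    "repeat": 0.1,
    "no_hit": 0.1,
}


def sim_gene_models(
    n: int,
    violation_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[GeneModel], list[AlignmentEvidence], RepeatTrack, SimTruth]:
    """Simulate gene models with planted filter violations.

    Each model is placed on its own scaffold (so models never overlap by
    accident) and assigned one category from ``violation_mix``:

    * ``clean`` — >= 4 exons, best-hit coverage >= 0.92, no repeat overlap;
    * ``low_coverage`` — coverage drawn in [0.50, 0.88];
    * ``few_exon`` — 1-3 exons;
    * ``redundant`` — a strictly shorter copy of the latest clean model on
      the same scaffold (exon footprint fully contained), so the copy is
      removed at the redundancy stage (falls back to clean when no host
      exists yet);
    * ``repeat`` — a repeat interval overlapping the first exon;
    * ``no_hit`` — no alignment evidence at all.

    The truth records every model's expected fate and rejection reason
    under the default curation thresholds.
    """
    mix = dict(_DEFAULT_MIX if violation_mix is None else violation_mix)
    cats = sorted(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("violation_mix must have positive total weight")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    models: list[GeneModel] = []
    evidence: list[AlignmentEvidence] = []
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    fates: dict[str, str] = {}
    reasons: dict[str, str] = {}
    last_clean: GeneModel | None = None

    def make_exons(n_exons: int) -> tuple[tuple[int, int], ...]:
        pos = int(rng.integers(1_000, 5_000))
        exons = []
        for _ in range(n_exons):
            span = int(rng.integers(80, 300))
            exons.append((pos, pos + span))
            pos += span + int(rng.integers(50, 500))
        return tuple(exons)

    def add_evidence(model: GeneModel, cov_range: tuple[float, float]) -> None:
        qlen = max(model.cds_length // 3, 30)
        frac = float(rng.uniform(*cov_range))
        span = int(np.floor(frac * qlen))
        evidence.append(
            AlignmentEvidence(
                model_id=model.id,
                subject_id=f"sp|{model.id}",
                query_length=qlen,
                aligned_query_span=min(span, qlen),
                e_value=float(10.0 ** -rng.uniform(25, 80)),
            )
        )

    for i in range(n):
        category = cats[int(rng.choice(len(cats), p=probs))]
        if category == "redundant" and last_clean is None:
            category = "clean"
        mid = f"model_{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"

        if category == "redundant":
            host = last_clean
            # strictly shorter duplicate fully inside the host's footprint
            exons = list(host.exons)
            a, b = exons[-1]
            cut = max(1, (b - a) // 3)
            exons[-1] = (a, b - cut)
            model = GeneModel(id=mid, scaffold=host.scaffold, strand=host.strand, exons=tuple(exons))
            add_evidence(model, (0.93, 1.0))
            fates[mid] = "rejected"
            reasons[mid] = "redundant"
        elif category == "few_exon":
            model = GeneModel(id=mid, scaffold=f"scf_{i + 1:05d}", strand=strand,
                              exons=make_exons(int(rng.integers(1, 4))))
            add_evidence(model, (0.93, 1.0))
            fates[mid] = "rejected"
            reasons[mid] = "few-exons"
        else:
            model = GeneModel(id=mid, scaffold=f"scf_{i + 1:05d}", strand=strand,
                              exons=make_exons(int(rng.integers(4, 9))))
            if category == "clean":
                add_evidence(model, (0.93, 1.0))
                fates[mid] = "kept"
                last_clean = model
            elif category == "low_coverage":
                add_evidence(model, (0.50, 0.88))
                fates[mid] = "rejected"
                reasons[mid] = "low-coverage"
            elif category == "repeat":
                add_evidence(model, (0.93, 1.0))
                a, b = model.exons[0]
                repeat_intervals.setdefault(model.scaffold, []).append((a, min(a + 25, b)))
                fates[mid] = "rejected"
                reasons[mid] = "repeat-overlap"
            elif category == "no_hit":
                fates[mid] = "rejected"
                reasons[mid] = "no-hit"
        models.append(model)

    truth = SimTruth(
        scenario="gene-models",
        seed=seed,
        params={"n": n, "violation_mix": mix},
        expected={
            "survivors": [m.id for m in models if fates[m.id] == "kept"],
            "fates": fates,
            "reasons": reasons,
        },
    )
    return models, evidence, RepeatTrack(repeat_intervals), truth


# ---------------------------------------------------------------------------
# domain count matrices


def sim_domain_matrix(
    n_genomes: int = 10,
    n_domains: int = 2000,
    planted: Sequence[tuple[int, float]] = (),
    focal: str = "Lf",
    total_counts: int = 40_000,
    seed: int = 0,
    sampling: str = "multinomial",
    planted_lambda_range: tuple[float, float] = (20.0, 200.0),
    weight_shape: float = 1.0,
) -> tuple[DomainCountMatrix, SimTruth]:
    """Simulate a genome x domain count matrix with planted fold-changes.

    Defaults mirror a typical multi-genome Pfam comparison: 10 genomes,
    ~40 000 domain assignments each spread over a few thousand distinct
    families (so the mean per-family count is ~20, with an exponential
    tail of common families).  All genomes share baseline domain
    frequencies (gamma weights with shape ``weight_shape``, normalized).  Planted entries ``(domain_index, fold)``
    get a baseline expectation drawn uniformly from
    ``planted_lambda_range`` (in focal-scale counts), and the focal
    genome's frequency for them is multiplied by ``fold`` (renormalized).
    Counts are drawn per genome either multinomially at a fixed total or as
    independent Poissons (``sampling="poisson"``, the natural null for
    calibration studies).

    The truth records the planted folds, the baseline expectations, and the
    expected call (expanded for fold > 1, contracted for fold < 1) per
    planted domain.
    """
    if n_genomes < 2:
        raise ValueError("need at least two genomes")
    if sampling not in {"multinomial", "poisson"}:
        raise ValueError("sampling must be 'multinomial' or 'poisson'")
    planted = list(planted)
    idxs = [d for d, _ in planted]
    if len(set(idxs)) != len(idxs):
        raise ValueError("planted domains must be distinct")
    if any(f <= 0 for _, f in planted):
        raise ValueError("planted folds must be positive")
    if any(not 0 <= d < n_domains for d in idxs):
        raise ValueError("planted domain index out of range")

    import pandas as pd

    rng = np.random.default_rng(seed)
    genomes = [focal] + [f"G{i:02d}" for i in range(1, n_genomes)]
    domains = [f"PF{i + 1:05d}" for i in range(n_domains)]

    weights = rng.gamma(weight_shape, 1.0, n_domains)
    freqs = weights / weights.sum()
    if planted:
        lam_targets = rng.uniform(*planted_lambda_range, len(planted))
        target_freqs = lam_targets / total_counts
        others_mask = np.ones(n_domains, dtype=bool)
        others_mask[idxs] = False
        freqs[idxs] = target_freqs
        freqs[others_mask] *= (1.0 - target_freqs.sum()) / freqs[others_mask].sum()

    focal_freqs = freqs.copy()
    for (d, fold) in planted:
        focal_freqs[d] *= fold
    focal_freqs /= focal_freqs.sum()

    counts = np.zeros((n_genomes, n_domains), dtype=np.int64)
    for gi, genome in enumerate(genomes):
        f = focal_freqs if genome == focal else freqs
        if sampling == "multinomial":
            counts[gi] = rng.multinomial(total_counts, f)
        else:
            counts[gi] = rng.poisson(f * total_counts)

    matrix = DomainCountMatrix(pd.DataFrame(counts, index=genomes, columns=domains))
    expected_calls = {
        domains[d]: ("expanded" if fold > 1 else "contracted" if fold < 1 else "neutral")
        for d, fold in planted
    }
    truth = SimTruth(
        scenario="domain-matrix",
        seed=seed,
        params={
            "n_genomes": n_genomes,
            "n_domains": n_domains,
            "planted": [[domains[d], float(f)] for d, f in planted],
            "focal": focal,
            "total_counts": total_counts,
            "sampling": sampling,
            "weight_shape": weight_shape,
        },
        expected={
            "calls": expected_calls,
            "baseline_lambdas": {domains[d]: float(freqs[d] * total_counts) for d in idxs},
        },
    )
    return matrix, truth
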