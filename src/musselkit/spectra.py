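"""k-mer spectrum profiling: genome size, heterozygosity, and ploidy.

A k-mer spectrum is the table ``multiplicity -> number of distinct k-mers
observed at that multiplicity`` produced by counters such as Jellyfish
(``jellyfish histo``).  For a diploid genome sequenced to depth *c*, k-mers
shared by both haplotypes pile up near *c* (the homozygous peak) while
haplotype-specific k-mers created by heterozygous sites pile up near *c/2*
(the heterozygous peak).  Sequencing errors produce a steeply decaying limb
of (mostly unique) k-mers at low multiplicity.

This module implements the classical spectral estimators built on that
picture:

* the error threshold ``e`` is the first valley of the (smoothed) spectrum
  scanning upward from multiplicity 1;
* genome size ``G = (T - T_err) / c_hom`` where ``T`` is the total k-mer
  volume (sum of multiplicity x count), ``T_err`` the volume strictly below
  ``e`` and ``c_hom`` the homozygous peak depth;
* a double-peaked spectrum with peak depths in ratio ~2 is called
  diploid-heterozygous;
* the heterozygosity rate is estimated from the heterozygous-peak volume:
  every isolated heterozygous site turns ~k homozygous k-mers into ~2k
  haplotype-specific ones at the heterozygous depth, so with ``D_het``
  distinct k-mers under the het peak the number of heterozygous sites is
  ``H = D_het / (2k)`` and the rate is ``r = H / G``.

All estimators accept explicit overrides so that published parameter choices
(e.g. ``e = 12``, ``c_hom = 45``) can be reproduced exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SpectrumError",
    "NoValleyError",
    "KmerHistogram",
    "Peak",
    "SpectrumProfile",
    "read_histo",
    "write_histo",
    "total_volume",
    "smoothed_dense",
    "detect_error_threshold",
    "detect_peaks",
    "dominant_peaks",
    "classify_ploidy",
    "estimate_genome_size",
    "estimate_heterozygosity",
    "profile",
]


class SpectrumError(ValueError):
    """Invalid k-mer histogram or inconsistent spectrum parameters."""


class NoValleyError(SpectrumError):
    """The spectrum has no error/signal valley (e.g. monotonically decreasing)."""


@dataclass(frozen=True)
class KmerHistogram:
    """Sparse k-mer multiplicity histogram.

    Parameters
    ----------
    k
        k-mer length used to produce the histogram.
    multiplicities
        Strictly increasing array of multiplicities (>= 1).  Multiplicities
        absent from the array have an implicit count of zero.
    counts
        Number of distinct k-mers observed at each multiplicity (>= 0).
    """

    k: int
    multiplicities: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.multiplicities, dtype=np.int64)
        c = np.asarray(self.counts, dtype=np.int64)
        if int(self.k) < 1:
            raise SpectrumError(f"k must be a positive integer, got {self.k}")
        if m.ndim != 1 or c.shape != m.shape:
            raise SpectrumError("multiplicities and counts must be 1-D arrays of equal length")
        if m.size == 0:
            raise SpectrumError("empty histogram")
        if m[0] < 1:
            raise SpectrumError("multiplicities must be >= 1")
        if m.size > 1 and np.any(np.diff(m) <= 0):
            raise SpectrumError("multiplicities must be strictly increasing")
        if np.any(c < 0):
            raise SpectrumError("counts must be non-negative")
        if not np.any(c > 0):
            raise SpectrumError("histogram must contain at least one positive count")
        object.__setattr__(self, "k", int(self.k))
        object.__setattr__(self, "multiplicities", m)
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_entries(
        cls,
        k: int,
        entries: Mapping[int, int] | Iterable[tuple[int, int]],
        *,
        reorder: bool = True,
    ) -> "KmerHistogram":
        """Build a histogram from ``{multiplicity: count}`` pairs.

        With ``reorder`` (default) out-of-order input is sorted; otherwise
        out-of-order input raises :class:`SpectrumError`.
        """
        pairs = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
        if not pairs:
            raise SpectrumError("empty histogram")
        m = np.array([p[0] for p in pairs], dtype=np.int64)
        c = np.array([p[1] for p in pairs], dtype=np.int64)
        if reorder:
            order = np.argsort(m, kind="stable")
            m, c = m[order], c[order]
        return cls(k=k, multiplicities=m, counts=c)

    def entries(self) -> dict[int, int]:
        """Histogram as a plain ``{multiplicity: count}`` dict."""
        return {int(m): int(c) for m, c in zip(self.multiplicities, self.counts)}

    @property
    def max_multiplicity(self) -> int:
        return int(self.multiplicities[-1])

    def dense_counts(self) -> np.ndarray:
        """Counts on the dense grid 1..max multiplicity (index = multiplicity).

        Index 0 is unused (kept zero) so that ``dense[m]`` is the count at
        multiplicity ``m``; gaps in the sparse table are zero.
        """
        dense = np.zeros(self.max_multiplicity + 1, dtype=np.int64)
        dense[self.multiplicities] = self.counts
        return dense

    def scaled(self, factor: int) -> "KmerHistogram":
        """Histogram with every count multiplied by ``factor`` (testing aid)."""
        return KmerHistogram(self.k, self.multiplicities, self.counts * factor)


class Peak(NamedTuple):
    """A local maximum of the smoothed spectrum."""

    depth: int
    height: float


def read_histo(
    path: str | Path,
    k: int,
    *,
    reorder: bool = True,
    drop_last_bin: bool = False,
) -> KmerHistogram:
    """Read a Jellyfish-style two-column histogram (multiplicity, count).

    Whitespace-separated numeric text; blank lines and ``#`` comments are
    ignored.  ``drop_last_bin`` discards the final row, for counters that
    accumulate every multiplicity above the table limit into a catch-all
    last bin; by default that bin is kept at its nominal multiplicity.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = text.split()
            if len(fields) != 2:
                raise SpectrumError(
                    f"{path}:{lineno}: expected two whitespace-separated columns, got {len(fields)}"
                )
            try:
                m, c = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise SpectrumError(f"{path}:{lineno}: non-integer field ({exc})") from None
            pairs.append((m, c))
    if not pairs:
        raise SpectrumError(f"{path}: empty histogram file")
    if drop_last_bin and len(pairs) > 1:
        pairs = pairs[:-1]
    return KmerHistogram.from_entries(k, pairs, reorder=reorder)


def write_histo(h: KmerHistogram, path: str | Path) -> None:
    """Write a histogram in the two-column Jellyfish ``histo`` format."""
    from .io import atomic_write

    with atomic_write(path) as fh:
        for m, c in zip(h.multiplicities, h.counts):
            fh.write(f"{int(m)} {int(c)}\n")


def total_volume(h: KmerHistogram, lo: int = 1, hi: int | None = None) -> int:
    """Total k-mer volume ``sum(m * count(m))`` over multiplicities in [lo, hi].

    ``hi=None`` means unbounded above.  An empty range returns 0.
    """
    if hi is not None and lo > hi:
        raise SpectrumError(f"lo ({lo}) must be <= hi ({hi})")
    mask = h.multiplicities >= lo
    if hi is not None:
        mask &= h.multiplicities <= hi
    return int(np.sum(h.multiplicities[mask] * h.counts[mask]))


def smoothed_dense(h: KmerHistogram, window: int = 3) -> np.ndarray:
    """Centred moving average of the dense count curve.

    Returns a float array indexed by multiplicity (index 0 unused).  Edges
    use the partial window that fits inside the curve, so a window of 1
    returns the raw dense counts.
    """
    if window < 1 or window % 2 == 0:
        raise SpectrumError(f"smoothing window must be a positive odd integer, got {window}")
    dense = h.dense_counts().astype(float)
    vals = dense[1:]
    if window == 1 or vals.size == 1:
        return dense
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    # number of in-range taps contributing at each position
    ns = np.convolve(np.ones_like(vals), kernel, mode="same")
    out = np.zeros_like(dense)
    out[1:] = sums / ns
    return out


def detect_error_threshold(h: KmerHistogram, smooth_window: int = 3) -> int:
    """First valley of the (smoothed) spectrum scanning from multiplicity 1.

    Returns the multiplicity ``e`` of the first local minimum: the first
    ``m >= 2`` with ``s[m] <= s[m-1]`` and ``s[m] < s[m+1]``.  Raises
    :class:`NoValleyError` when the curve never turns back up (e.g. a
    monotonically decreasing histogram).
    """
    s = smoothed_dense(h, smooth_window)
    top = len(s) - 1
    for m in range(2, top):
        if s[m] <= s[m - 1] and s[m] < s[m + 1]:
            return m
    raise NoValleyError("no valley found between the error limb and the signal peak")


def _find_valley(s: np.ndarray, lo: int, hi: int) -> int:
    """Multiplicity of the minimum of ``s`` on [lo, hi] (first on ties)."""
    lo = max(lo, 1)
    hi = min(hi, len(s) - 1)
    if hi < lo:
        return lo
    return lo + int(np.argmin(s[lo : hi + 1]))


def detect_peaks(h: KmerHistogram, e: int, smooth_window: int = 3) -> list[Peak]:
    """Local maxima of the smoothed spectrum at multiplicities above ``e``.

    Returns peaks ordered by depth; on plateaus the first flat bin is the
    peak.  The last multiplicity counts as a peak only if the curve rises
    into it.  An empty list means no maxima above ``e``.
    """
    s = smoothed_dense(h, smooth_window)
    top = len(s) - 1
    peaks: list[Peak] = []
    for m in range(max(e + 1, 2), top + 1):
        left, val = s[m - 1], s[m]
        right = s[m + 1] if m < top else -np.inf
        if val > left and val >= right:
            peaks.append(Peak(depth=m, height=float(val)))
    return peaks


def dominant_peaks(peaks: Sequence[Peak], dominance: float = 0.15) -> list[Peak]:
    """Peaks at least ``dominance`` times as tall as the tallest peak."""
    if not peaks:
        return []
    hmax = max(p.height for p in peaks)
    return [p for p in peaks if p.height >= dominance * hmax]


def classify_ploidy(
    peaks: Sequence[Peak],
    ratio_tol: float = 0.35,
    dominance: float = 0.15,
) -> str:
    """Call ploidy from the peak list.

    ``"diploid-heterozygous"`` when exactly two dominant peaks have a
    deeper/shallower depth ratio within ``2 +- ratio_tol``;
    ``"haploid-like"`` for a single dominant peak; ``"ambiguous"``
    otherwise (including an empty peak list).
    """
    dom = dominant_peaks(peaks, dominance)
    if len(dom) == 1:
        return "haploid-like"
    if len(dom) == 2:
        lo, hi = sorted(p.depth for p in dom)
        ratio = hi / lo
        if 2.0 - ratio_tol <= ratio <= 2.0 + ratio_tol:
            return "diploid-heterozygous"
    return "ambiguous"


def estimate_genome_size(h: KmerHistogram, e: int, c_hom: int) -> float:
    """Genome size ``G = (T - T_err) / c_hom`` in bases.

    ``T`` is the total k-mer volume, ``T_err`` the volume at multiplicities
    strictly below the error threshold ``e`` (k-mers counted "from" ``e``
    upward are retained), and ``c_hom`` the homozygous peak depth.
    """
    if c_hom <= 0:
        raise SpectrumError(f"homozygous peak depth must be positive, got {c_hom}")
    if e < 1:
        raise SpectrumError(f"error threshold must be >= 1, got {e}")
    t = total_volume(h)
    t_err = total_volume(h, 1, e - 1) if e > 1 else 0
    return (t - t_err) / c_hom


def estimate_heterozygosity(
    h: KmerHistogram,
    e: int,
    c_het: int | None,
    c_hom: int,
    genome_size: float,
    smooth_window: int = 3,
) -> float:
    """Heterozygosity rate from the heterozygous-peak volume.

    The heterozygous window runs valley-to-valley around ``c_het``: from the
    minimum of the smoothed curve on [e, c_het) (usually ``e`` itself) to
    the minimum on (c_het, c_hom).  With window volume ``A_het``, the number
    of distinct heterozygous k-mers is ``D_het = A_het / c_het``, the number
    of heterozygous sites ``H = D_het / (2k)``, and the rate
    ``r = H / genome_size``.

    A missing het peak (``c_het is None``) returns 0.0 with a warning.
    """
    if c_het is None:
        warnings.warn("no heterozygous peak: heterozygosity reported as 0", stacklevel=2)
        return 0.0
    if c_het <= 0:
        raise SpectrumError(f"heterozygous peak depth must be positive, got {c_het}")
    if genome_size <= 0:
        raise SpectrumError(f"genome size must be positive, got {genome_size}")
    s = smoothed_dense(h, smooth_window)
    lo = _find_valley(s, e, c_het - 1)
    hi = _find_valley(s, c_het + 1, c_hom - 1)
    if hi <= c_het:
        hi = c_het
    a_het = total_volume(h, lo, min(hi, h.max_multiplicity))
    d_het = a_het / c_het
    het_sites = d_het / (2 * h.k)
    return het_sites / genome_size


@dataclass(frozen=True)
class SpectrumProfile:
    """Full spectrum profile: thresholds, peaks, size, heterozygosity, ploidy."""

    k: int
    error_threshold: int
    het_peak_depth: int | None
    hom_peak_depth: int | None
    total_volume: int
    error_volume: int
    genome_size: float | None
    heterozygosity: float
    ploidy_call: str
    peaks: tuple[Peak, ...] = ()
    overrides: Mapping[str, int] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.error_volume > self.total_volume:
            raise SpectrumError("error volume exceeds total volume")
        if self.genome_size is not None and self.genome_size <= 0:
            raise SpectrumError("genome size must be positive")
        if not 0.0 <= self.heterozygosity < 1.0:
            raise SpectrumError("heterozygosity must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "error_threshold": self.error_threshold,
            "het_peak_depth": self.het_peak_depth,
            "hom_peak_depth": self.hom_peak_depth,
            "total_volume": self.total_volume,
            "error_volume": self.error_volume,
            "genome_size": self.genome_size,
            "heterozygosity": self.heterozygosity,
            "ploidy_call": self.ploidy_call,
            "peaks": [[p.depth, p.height] for p in self.peaks],
            "overrides": dict(self.overrides),
            "flags": list(self.flags),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_tsv(self) -> str:
        """Human-readable two-column summary (field, value)."""
        rows = [
            ("k", self.k),
            ("error_threshold (multiplicity)", self.error_threshold),
            ("het_peak_depth (x coverage)", self.het_peak_depth),
            ("hom_peak_depth (x coverage)", self.hom_peak_depth),
            ("total_volume (k-mers)", self.total_volume),
            ("error_volume (k-mers)", self.error_volume),
            ("genome_size (bases)", None if self.genome_size is None else round(self.genome_size)),
            ("heterozygosity (fraction)", round(self.heterozygosity, 6)),
            ("ploidy_call", self.ploidy_call),
        ]
        lines = ["field\tvalue"]
        lines += [f"{name}\t{'' if value is None else value}" for name, value in rows]
        return "\n".join(lines) + "\n"


def profile(
    h: KmerHistogram,
    *,
    error_threshold: int | None = None,
    het_depth: int | None = None,
    hom_depth: int | None = None,
    smooth_window: int = 3,
    ratio_tol: float = 0.35,
    dominance: float = 0.15,
) -> SpectrumProfile:
    """Run the full profiling cascade: valley, peaks, ploidy, size, heterozygosity.

    Keyword overrides take precedence over detection and are recorded in the
    returned profile.  A spectrum without a detectable het peak yields
    heterozygosity 0 and a ``"no-het-peak"`` flag.
    """
    overrides: dict[str, int] = {}
    flags: list[str] = []

    if error_threshold is not None:
        e = int(error_threshold)
        overrides["error_threshold"] = e
    else:
        e = detect_error_threshold(h, smooth_window)

    peaks = detect_peaks(h, e, smooth_window)
    ploidy = classify_ploidy(peaks, ratio_tol, dominance)
    dom = dominant_peaks(peaks, dominance)

    c_het: int | None = None
    c_hom: int | None = None
    if len(dom) >= 2:
        best_two = sorted(sorted(dom, key=lambda p: -p.height)[:2], key=lambda p: p.depth)
        c_het, c_hom = best_two[0].depth, best_two[1].depth
    elif len(dom) == 1:
        c_hom = dom[0].depth
    if hom_depth is not None:
        c_hom = int(hom_depth)
        overrides["hom_depth"] = c_hom
    if het_depth is not None:
        c_het = int(het_depth)
        overrides["het_depth"] = c_het

    t = total_volume(h)
    t_err = total_volume(h, 1, e - 1) if e > 1 else 0

    genome_size = None
    if c_hom is not None:
        genome_size = estimate_genome_size(h, e, c_hom)

    het = 0.0
    if genome_size is not None and c_het is not None and c_het < c_hom:
        het = estimate_heterozygosity(h, e, c_het, c_hom, genome_size, smooth_window)
    else:
        flags.append("no-het-peak")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            het = 0.0

    return SpectrumProfile(
        k=h.k,
        error_threshold=e,
        het_peak_depth=c_het,
        hom_peak_depth=c_hom,
        total_volume=t,
        error_volume=t_err,
        genome_size=genome_size,
        heterozygosity=het,
        ploidy_call=ploidy,
        peaks=tuple(peaks),
        overrides=overrides,
        flags=tuple(flags),
    )


def plot_spectrum(h: KmerHistogram, prof: SpectrumProfile | None, path: str | Path) -> None:
    """Plot the spectrum (and detected features, if a profile is given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(h.multiplicities, h.counts, lw=1.2, color="steelblue")
    if prof is not None:
        ax.axvline(prof.error_threshold, color="grey", ls="--", lw=0.8, label=f"e={prof.error_threshold}")
        if prof.het_peak_depth:
            ax.axvline(prof.het_peak_depth, color="darkorange", ls=":", lw=1.0, label=f"het={prof.het_peak_depth}")
        if prof.hom_peak_depth:
            ax.axvline(prof.hom_peak_depth, color="firebrick", ls=":", lw=1.0, label=f"hom={prof.hom_peak_depth}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("multiplicity (x coverage)")
    ax.set_ylabel("distinct k-mers")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
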