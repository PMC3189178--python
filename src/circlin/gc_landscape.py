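"""Cumulative GC-skew profiling, origin-oriented genome rotation, and
low-G+C segmentation on circular chromosomes.

GC skew in a window is (G - C) / (G + C); its cumulative sum along a
prokaryotic chromosome conventionally switches slope at the replication
origin and terminus, with the global cumulative minimum marking the
origin. ``rotate_to_skew_minimum`` re-linearizes a circular genome so
that minimum becomes bp 1 — the convention used to orient deposited
archaeal/bacterial genome sequences.

Low-GC segmentation chains sliding windows whose GC content falls below
a threshold (the classic signature of laterally acquired clusters such
as LPS biosynthesis loci in a high-GC genome), merges nearby chains,
and discards short ones. N bases are excluded from every numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import CircularGenome


@dataclass(frozen=True)
class SkewProfile:
    window: int
    step: int
    centers: tuple[int, ...]  # 1-based bp positions
    window_skew: tuple[float, ...]
    cumulative: tuple[float, ...]
    min_position: int
    max_position: int


@dataclass(frozen=True)
class GCRegion:
    """A contiguous low/high-GC segment; start > end means it wraps the origin."""

    start: int  # 1-based inclusive
    end: int
    mean_gc: float
    length: int

    @property
    def wraps(self) -> bool:
        return self.start > self.end


def _base_indicators(genome: CircularGenome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    g = (seq == ord("G")).astype(np.int64)
    c = (seq == ord("C")).astype(np.int64)
    n = (seq == ord("N")).astype(np.int64)
    return g, c, n


def _window_counts(x: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    """Sum of x over circular windows [start, start+window) (0-based starts)."""
    ext = np.concatenate([x, x[: window]])
    cs = np.concatenate([[0], np.cumsum(ext)])
    return cs[starts + window] - cs[starts]


def gc_skew_profile(genome: CircularGenome, window: int = 1000, step: int = 1000) -> SkewProfile:
    """Windowed and cumulative (G-C)/(G+C) skew; windows wrap the circle.

    A window with no G or C (all A/T/N) gets skew 0 by convention. The
    reported min/max positions are the centers attaining the cumulative
    extrema, first occurrence winning ties.
    """
    L = genome.length
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > L:
        raise ValueError(f"window ({window}) exceeds genome length ({L})")
    g, c, _ = _base_indicators(genome)
    starts = np.arange(0, L, step)
    gw = _window_counts(g, starts, window)
    cw = _window_counts(c, starts, window)
    denom = gw + cw
    skew = np.where(denom > 0, (gw - cw) / np.maximum(denom, 1), 0.0)
    cum = np.cumsum(skew)
    centers = (starts + window // 2) % L + 1
    i_min = int(np.argmin(cum))
    i_max = int(np.argmax(cum))
    return SkewProfile(
        window=window,
        step=step,
        centers=tuple(int(p) for p in centers),
        window_skew=tuple(float(s) for s in skew),
        cumulative=tuple(float(s) for s in cum),
        min_position=int(centers[i_min]),
        max_position=int(centers[i_max]),
    )


def rotate_genome(genome: CircularGenome, new_start: int) -> CircularGenome:
    """Re-linearize a circular genome so the base at ``new_start`` becomes bp 1."""
    if not genome.is_circular:
        raise ValueError("cannot rotate a non-circular genome")
    if not (1 <= new_start <= genome.length):
        raise ValueError("new_start outside genome")
    k = new_start - 1
    return CircularGenome(
        id=genome.id, sequence=genome.sequence[k:] + genome.sequence[:k]
    )


def rotate_to_skew_minimum(genome: CircularGenome, profile: SkewProfile) -> CircularGenome:
    """Rotate so the cumulative-skew global minimum marks the sequence start."""
    return rotate_genome(genome, profile.min_position)


def low_gc_regions(
    genome: CircularGenome,
    threshold: float = 0.47,
    window: int = 2000,
    step: int = 500,
    min_length: int = 5000,
    merge_gap: int = 1000,
) -> list[GCRegion]:
    """Segments of the genome whose windowed GC content is below ``threshold``.

    Windows below threshold are chained; chains separated by at most
    ``merge_gap`` bp are merged; merged chains shorter than ``min_length``
    are discarded. The scan is circular: a region may span the origin and
    is then reported with start > end. All-N windows are skipped.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    L = genome.length
    if window > L:
        raise ValueError("window exceeds genome length")
    g, c, n = _base_indicators(genome)
    starts = np.arange(0, L, step)
    gcw = _window_counts(g + c, starts, window)
    nw = _window_counts(n, starts, window)
    informative = window - nw
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = gcw / informative
    qualifies = (informative > 0) & (frac < threshold)

    if not qualifies.any():
        return []

    # unwrapped intervals [start+1, start+window] in 1-based bp, may exceed L
    iv = [(int(s) + 1, int(s) + window) for s, q in zip(starts, qualifies) if q]
    merged: list[list[int]] = []
    for s, e in iv:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # circular closure: last region may reach around to the first
    if len(merged) > 1:
        gap_around = (merged[0][0] + L) - merged[-1][1] - 1
        if gap_around <= merge_gap:
            merged[-1][1] = max(merged[-1][1], merged[0][1] + L)
            merged.pop(0)
    elif merged and merged[0][1] - merged[0][0] + 1 >= L:
        merged[0] = [1, L]

    gc_arr = g + c
    n_arr = n
    regions = []
    for s, e in merged:
        span = min(e - s + 1, L)
        e = s + span - 1
        if span < min_length:
            continue
        idx = (np.arange(s - 1, e) % L)
        inf = span - int(n_arr[idx].sum())
        mean_gc = float(gc_arr[idx].sum() / inf) if inf > 0 else float("nan")
        s_mod = (s - 1) % L + 1
        e_mod = (e - 1) % L + 1
        regions.append(GCRegion(start=s_mod, end=e_mod, mean_gc=mean_gc, length=span))
    regions.sort(key=lambda r: r.start)
    return regions


def regions_to_bed(regions: list[GCRegion], genome: CircularGenome) -> str:
    """Serialize regions as BED (0-based half-open); wrapped regions split in two."""
    lines = []
    L = genome.length
    for i, r in enumerate(regions):
        name = f"lowgc_{i + 1}"
        score = f"{r.mean_gc:.4f}"
        if r.wraps:
            lines.append(f"{genome.id}\t{r.start - 1}\t{L}\t{name}_a\t{score}")
            lines.append(f"{genome.id}\t0\t{r.end}\t{name}_b\t{score}")
        else:
            lines.append(f"{genome.id}\t{r.start - 1}\t{r.end}\t{name}\t{score}")
    return "\n".join(lines) + ("\n" if lines else "")
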