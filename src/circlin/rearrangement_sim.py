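"""Synthetic data: circular gene orders under rearrangement, and circular
DNA sequences with a replichore GC-skew structure and low-GC islands.

The gene-order simulator produces pairs of circular genomes related by a
stated number of inversions and transpositions with partial ortholog
retention — exactly the structure the colinearity statistic assumes.
Events are unsigned (gene orientation is not tracked) because the
statistic ignores strand. Inversions act on the minor arc so a draw can
never be a degenerate full-circle flip.

The sequence simulator draws bases i.i.d. per position with a G-vs-C
bias of +amplitude on the replichore clockwise from the chosen origin
and -amplitude on the other, which plants a cumulative-skew minimum at
the origin; stated islands are resampled at their own GC level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .colinearity import OrthologPair, OrthologPairSet
from .genome_io import CircularGenome

PSEUDO_EVALUE = 1e-50  # simulated pairs must pass any sensible cutoff


@dataclass(frozen=True)
class GeneOrder:
    """A permutation of gene labels 1..n around a circle."""

    genome_id: str
    order: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.order)
        if n < 3:
            raise ValueError("need at least 3 genes on a circle")
        if sorted(self.order) != list(range(1, n + 1)):
            raise ValueError("order must be a permutation of 1..n")

    @property
    def n(self) -> int:
        return len(self.order)

    def canonical(self) -> "GeneOrder":
        """Rotate so gene 1 sits at index 0 (the serialization cut point)."""
        i = self.order.index(1)
        return replace(self, order=self.order[i:] + self.order[:i])


@dataclass(frozen=True)
class SimulationRecipe:
    n_genes: int
    n_inversions: int = 0
    n_transpositions: int = 0
    ortholog_retention: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.n_inversions < 0 or self.n_transpositions < 0:
            raise ValueError("event counts must be >= 0")
        if not (0 < self.ortholog_retention <= 1):
            raise ValueError("ortholog_retention must be in (0, 1]")


def apply_inversion(order: GeneOrder, i: int, j: int) -> GeneOrder:
    """Reverse the segment at indices i..j of the current linearization."""
    n = order.n
    if not (0 <= i <= j < n):
        raise ValueError(f"need 0 <= i <= j < {n}, got i={i}, j={j}")
    o = list(order.order)
    o[i : j + 1] = o[i : j + 1][::-1]
    return replace(order, order=tuple(o))


def apply_transposition(order: GeneOrder, i: int, j: int, k: int) -> GeneOrder:
    """Excise the segment i..j and reinsert it after position k (k outside i..j)."""
    n = order.n
    if not (0 <= i <= j < n):
        raise ValueError(f"need 0 <= i <= j < {n}, got i={i}, j={j}")
    if i <= k <= j:
        raise ValueError("insertion point k lies inside the excised segment")
    if not (-1 <= k < n):
        raise ValueError("k out of range")
    o = list(order.order)
    seg = o[i : j + 1]
    rest = o[:i] + o[j + 1 :]
    # position of k within rest after excision
    pos = k + 1 if k < i else k - (j - i + 1) + 1
    out = rest[:pos] + seg + rest[pos:]
    return replace(order, order=tuple(out))


def _random_inversion(o: np.ndarray, rng: np.random.Generator) -> None:
    n = o.size
    s = int(rng.integers(0, n))
    length = int(rng.integers(2, n // 2 + 1))  # minor arc only
    idx = (s + np.arange(length)) % n
    o[idx] = o[idx[::-1]]


def _random_transposition(o: np.ndarray, rng: np.random.Generator) -> None:
    n = o.size
    s = int(rng.integers(0, n))
    length = int(rng.integers(1, n // 2 + 1))
    lin = np.roll(o, -s)
    seg, rest = lin[:length], lin[length:]
    pos = int(rng.integers(1, rest.size))  # strictly inside -> real move
    out = np.concatenate([rest[:pos], seg, rest[pos:]])
    o[:] = np.roll(out, s)


def simulate_genome_pair(
    recipe: SimulationRecipe,
) -> tuple[GeneOrder, GeneOrder, OrthologPairSet]:
    """Genome A (identity order), genome B derived by random events, and the
    surviving ortholog pairs with their ranks in each genome."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_genes
    a = GeneOrder(genome_id="simA", order=tuple(range(1, n + 1)))

    o = np.arange(1, n + 1, dtype=np.int64)
    events = ["inv"] * recipe.n_inversions + ["trans"] * recipe.n_transpositions
    events = [events[i] for i in rng.permutation(len(events))]
    for ev in events:
        if ev == "inv":
            _random_inversion(o, rng)
        else:
            _random_transposition(o, rng)
    b = GeneOrder(genome_id="simB", order=tuple(int(v) for v in o))

    retained = rng.random(n) < recipe.ortholog_retention
    if retained.sum() < 2:
        raise ValueError(
            "fewer than 2 ortholog pairs survived retention; "
            "increase n_genes or ortholog_retention"
        )
    pos_in_b = np.empty(n + 1, dtype=np.int64)
    pos_in_b[o] = np.arange(1, n + 1)
    pairs = [
        OrthologPair(
            x_id=f"gA{g}", y_id=f"gB{g}",
            x_rank=int(g), y_rank=int(pos_in_b[g]),
            evalue=PSEUDO_EVALUE,
        )
        for g in range(1, n + 1)
        if retained[g - 1]
    ]
    pair_set = OrthologPairSet(
        pairs=pairs, O_x=n, O_y=n, query_id="simA", target_id="simB"
    )
    return a, b, pair_set


def simulate_sequence(
    length: int,
    gc: float = 0.55,
    origin: int = 1,
    skew_amplitude: float = 0.0,
    islands: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    genome_id: str = "sim",
) -> CircularGenome:
    """Circular DNA with controlled GC, a skew sign-switch at ``origin``
    (1-based), and optional low/high-GC islands given as (start, end, gc)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc <= 1):
        raise ValueError("gc must be in (0, 1]")
    if not (0 <= skew_amplitude < 1):
        raise ValueError("skew_amplitude must be in [0, 1)")
    if not (1 <= origin <= length):
        raise ValueError("origin must lie within the genome")
    islands = islands or []
    taken = np.zeros(length, dtype=bool)
    gc_per_pos = np.full(length, gc)
    for start, end, igc in islands:
        if not (1 <= start <= end <= length):
            raise ValueError(f"island {start}-{end} outside genome of {length} bp")
        if not (0 < igc <= 1):
            raise ValueError("island gc must be in (0, 1]")
        sl = slice(start - 1, end)
        if taken[sl].any():
            raise ValueError("overlapping islands")
        taken[sl] = True
        gc_per_pos[sl] = igc

    rng = np.random.default_rng(seed)
    # leading replichore: the half-circle clockwise from the origin
    offset = (np.arange(length) - (origin - 1)) % length
    leading = offset < (length + 1) // 2
    p_g_given_gc = np.where(leading, 0.5 * (1 + skew_amplitude), 0.5 * (1 - skew_amplitude))

    is_gc = rng.random(length) < gc_per_pos
    is_g = rng.random(length) < p_g_given_gc
    is_a = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(is_g, "G", "C"), np.where(is_a, "A", "T"))
    return CircularGenome(id=genome_id, sequence="".join(bases))
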