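"""The circular-genome colinearity statistic.

Two circular genomes are compared through their orthologs' ordinal
positions. For each pair of CDSs that are neighbours in the query
genome's gene order (ranks x_i, x_{i+1}), the ranks of their orthologs
in the target genome (y_i, y_{i+1}) give a circular distance

    D = min(|y_{i+1} - y_i|, O - |y_{i+1} - y_i|)

where O is the number of CDSs in the target genome. The colinearity
factor is C = sum(D) / O. Perfectly conserved gene order gives C near 1;
a fully shuffled genome gives C near n/4 where n is the number of
ortholog pairs.

Ortholog pairing uses reciprocal best hits (RBH) under an e-value cutoff
applied to both search directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CDSRecord, HitTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    x_id: str
    y_id: str
    x_rank: int
    y_rank: int
    evalue: float


@dataclass
class OrthologPairSet:
    """Ortholog pairs between two circular genomes, sorted by query rank.

    ``O_y`` is the target genome's CDS count — the O that normalizes C.
    """

    pairs: list[OrthologPair]
    O_x: int
    O_y: int
    query_id: str = "query"
    target_id: str = "target"

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda p: p.x_rank)
        x = [p.x_rank for p in self.pairs]
        y = [p.y_rank for p in self.pairs]
        if len(set(x)) != len(x):
            raise ValueError("x_ranks must be distinct")
        if len(set(y)) != len(y):
            raise ValueError("y_ranks must be distinct")
        if x and (min(x) < 1 or max(x) > self.O_x):
            raise ValueError("x_ranks outside 1..O_x")
        if y and (min(y) < 1 or max(y) > self.O_y):
            raise ValueError("y_ranks outside 1..O_y")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def y_ranks(self) -> np.ndarray:
        return np.array([p.y_rank for p in self.pairs], dtype=np.int64)


@dataclass(frozen=True)
class ColinearityResult:
    distances: tuple[int, ...]
    C: float
    n_pairs_used: int
    O: int
    wrap: bool


@dataclass(frozen=True)
class NullSummary:
    mean: float
    sd: float
    q025: float
    q975: float
    reps: int
    exact_mean: float


def circular_distance(y1: int, y2: int, O: int) -> int:
    """Shortest arc between two ordinal positions on a circle of O slots."""
    if not (1 <= y1 <= O and 1 <= y2 <= O):
        raise ValueError(f"ranks must lie in 1..{O}, got {y1}, {y2}")
    if y1 == y2:
        raise ValueError("two genes cannot share a rank")
    d = abs(y2 - y1)
    return min(d, O - d)


def _best_hits(hits: HitTable, valid_q: set[str], valid_s: set[str]) -> dict[str, tuple[str, float]]:
    """Best subject per query among ids present in the CDS lists.

    Ties on e-value go to the larger bit score, then the lexicographically
    smaller subject id, so output is deterministic.
    """
    df = hits.rows
    df = df[df["query_id"].isin(valid_q) & df["subject_id"].isin(valid_s)]
    if df.empty:
        return {}
    df = df.sort_values(
        ["query_id", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates("query_id", keep="first")
    return {
        q: (s, e)
        for q, s, e in zip(df["query_id"], df["subject_id"], df["evalue"])
    }


def pair_orthologs(
    hits_ab: HitTable,
    hits_ba: HitTable,
    cds_a: list[CDSRecord],
    cds_b: list[CDSRecord],
    evalue_cutoff: float = 1e-15,
    query_id: str = "query",
    target_id: str = "target",
) -> OrthologPairSet:
    """Reciprocal-best-hit ortholog pairs with both e-values below the cutoff."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    ids_a = [r.gene_id for r in cds_a]
    ids_b = [r.gene_id for r in cds_b]
    if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
        raise ValueError("duplicate gene ids in CDS lists")
    rank_a = {r.gene_id: r.rank for r in cds_a}
    rank_b = {r.gene_id: r.rank for r in cds_b}

    best_ab = _best_hits(hits_ab, set(ids_a), set(ids_b))
    best_ba = _best_hits(hits_ba, set(ids_b), set(ids_a))

    pairs = []
    for a, (b, e_ab) in best_ab.items():
        back = best_ba.get(b)
        if back is None or back[0] != a:
            continue
        e_ba = back[1]
        if e_ab < evalue_cutoff and e_ba < evalue_cutoff:
            pairs.append(
                OrthologPair(
                    x_id=a, y_id=b, x_rank=rank_a[a], y_rank=rank_b[b],
                    evalue=max(e_ab, e_ba),
                )
            )
    if not pairs:
        logger.warning("no reciprocal best hits passed the cutoff %g", evalue_cutoff)
    return OrthologPairSet(
        pairs=pairs, O_x=len(cds_a), O_y=len(cds_b),
        query_id=query_id, target_id=target_id,
    )


def _distances(y: np.ndarray, O: int, wrap: bool) -> np.ndarray:
    if wrap:
        y2 = np.roll(y, -1)
        d = np.abs(y2 - y)
    else:
        d = np.abs(np.diff(y))
    return np.minimum(d, O - d)


def colinearity_factor(pairs: OrthologPairSet, wrap: bool = False) -> ColinearityResult:
    """Compute C = sum(D)/O over neighbours in query gene order.

    With ``wrap`` the neighbour walk closes the circle (the last and first
    pairs are also neighbours), using n distances instead of n-1.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 ortholog pairs to compute C")
    O = pairs.O_y
    d = _distances(pairs.y_ranks, O, wrap)
    return ColinearityResult(
        distances=tuple(int(v) for v in d),
        C=float(d.sum() / O),
        n_pairs_used=len(d),
        O=O,
        wrap=wrap,
    )


def dotplot_table(pairs: OrthologPairSet) -> pd.DataFrame:
    """One row per ortholog pair, sorted by query rank; ready for plotting."""
    return pd.DataFrame(
        [(p.x_rank, p.y_rank, p.x_id, p.y_id) for p in pairs.pairs],
        columns=["x_rank", "y_rank", "x_id", "y_id"],
    )


def expected_null_distance(O: int) -> float:
    """Exact E[D] for a uniform pair of distinct ranks on a circle of O slots.

    Enumerates P(|delta| = k) = 2(O-k)/(O(O-1)) over k = 1..O-1 and takes
    the circular minimum.
    """
    if O < 2:
        raise ValueError("O must be >= 2")
    k = np.arange(1, O, dtype=np.float64)
    p = 2.0 * (O - k) / (O * (O - 1))
    return float(np.sum(p * np.minimum(k, O - k)))


def expected_null_C(n_pairs: int, O: int, wrap: bool = False) -> float:
    """Exact expectation of C under random distinct target ranks."""
    n_used = n_pairs if wrap else n_pairs - 1
    return n_used * expected_null_distance(O) / O


def random_null(
    n_pairs: int,
    O: int,
    reps: int = 1000,
    seed: int = 0,
    wrap: bool = False,
) -> NullSummary:
    """Monte-Carlo null distribution of C for random distinct target ranks."""
    if n_pairs > O:
        raise ValueError("n_pairs cannot exceed O")
    if n_pairs < 2 or reps < 1:
        raise ValueError("need n_pairs >= 2 and reps >= 1")
    rng = np.random.default_rng(seed)
    cs = np.empty(reps)
    for r in range(reps):
        y = rng.choice(O, size=n_pairs, replace=False) + 1
        cs[r] = _distances(y, O, wrap).sum() / O
    return NullSummary(
        mean=float(cs.mean()),
        sd=float(cs.std(ddof=1)) if reps > 1 else 0.0,
        q025=float(np.quantile(cs, 0.025)),
        q975=float(np.quantile(cs, 0.975)),
        reps=reps,
        exact_mean=expected_null_C(n_pairs, O, wrap),
    )
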