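"""Alpha diversity from taxon count tables: Shannon entropy, Simpson
diversity and evenness, and the Chao1 richness estimator, with read-depth
filtering and rarefaction.

Notation: for one sample, n_i is the count of taxon i, N = sum n_i the total
individuals, R the number of taxa with n_i > 0, p_i = n_i / N, S1 and S2 the
singleton and doubleton taxon counts. The indices are

    H' = -sum_i p_i ln p_i                      (Shannon entropy, nats)
    D  = 1 - sum_i n_i (n_i - 1) / (N (N - 1))  (Simpson diversity)
    E  = (1 / lambda) / R,  lambda = sum_i p_i^2  (Simpson evenness)
    C  = R + S1 (S1 - 1) / (2 (S2 + 1))         (bias-corrected Chao1)

Depth bias is removed by rarefying every retained sample, without
replacement, to a common depth (default: the smallest retained sample total)
and averaging each index over seeded replicate draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OtuTable:
    """Samples x taxa grid of non-negative integer counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("sample and taxon ids must be unique")
        arr = df.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OtuTable":
        """Read a TSV table; orientation is auto-detected from the header.

        A first header cell of ``taxon_id`` (or the classic ``#OTU ID``)
        marks taxa-in-rows and the table is transposed; ``sample_id`` marks
        samples-in-rows.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        flag = str(df.index.name or "").strip().lower()
        if flag in ("taxon_id", "#otu id", "otu_id"):
            df = df.T
        elif flag not in ("sample_id", "sample"):
            raise ValueError(
                f"cannot detect orientation from header flag {df.index.name!r}; "
                "use 'sample_id' or 'taxon_id'"
            )
        df.index.name = "sample_id"
        df.columns.name = None
        return cls(df)


@dataclass(frozen=True)
class RarefactionSpec:
    depth: int
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.replicates <= 0:
            raise ValueError("depth and replicates must be positive")


def filter_samples(t: OtuTable, min_reads: int = 1000) -> OtuTable:
    """Keep samples whose total count is strictly greater than min_reads.

    All-zero taxon columns that result are retained (as zero counts), so the
    taxon axis stays comparable across filtered tables.
    """
    totals = t.counts.sum(axis=1)
    kept = t.counts.loc[totals > min_reads]
    if kept.empty:
        raise ValueError(f"no sample has more than {min_reads} reads")
    return OtuTable(kept)


def rarefy(counts: np.ndarray, spec: RarefactionSpec) -> np.ndarray:
    """Subsample exactly `spec.depth` individuals without replacement.

    A multivariate-hypergeometric draw: the classic rarefaction step that
    equalises sequencing depth across samples. Seeded and reproducible.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < spec.depth:
        raise ValueError(f"sample total {total} below rarefaction depth {spec.depth}")
    rng = np.random.default_rng(spec.seed)
    return rng.multivariate_hypergeometric(counts, spec.depth)


def _positive(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all-zero count vector")
    return c[c > 0]


def shannon(counts: np.ndarray) -> float:
    """H' = -sum p_i ln p_i, natural log, over taxa with n_i > 0."""
    c = _positive(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson_d(counts: np.ndarray) -> float:
    """D = 1 - sum n_i (n_i - 1) / (N (N - 1)); requires N >= 2."""
    c = _positive(counts)
    n_total = c.sum()
    if n_total < 2:
        raise ValueError("Simpson diversity needs at least two individuals")
    return float(1.0 - (c * (c - 1.0)).sum() / (n_total * (n_total - 1.0)))


def simpson_evenness(counts: np.ndarray, eq3_literal: bool = False) -> float:
    """E = (1/lambda)/R with lambda = sum p_i^2; lies in (0, 1].

    ``eq3_literal=True`` returns the negated value -(1/lambda)/R for
    comparison with a published formula whose sign renders evenness negative.
    """
    c = _positive(counts)
    p = c / c.sum()
    lam = float((p * p).sum())
    e = (1.0 / lam) / len(c)
    return -e if eq3_literal else e


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: C = R + S1 (S1 - 1) / (2 (S2 + 1)) >= R."""
    c = _positive(counts)
    r = len(c)
    s1 = int((c == 1).sum())
    s2 = int((c == 2).sum())
    return float(r + s1 * (s1 - 1) / (2.0 * (s2 + 1)))


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample indices averaged over rarefaction replicates."""

    table: pd.DataFrame  # columns: H, D, E, C, depth, replicates
    depth: int
    replicates: int


def diversity_table(
    t: OtuTable,
    min_reads: int = 1000,
    depth: int | None = None,
    replicates: int = 10,
    seed: int = 0,
) -> DiversityResult:
    """Filter, rarefy, and compute all four indices per sample.

    Samples with totals <= min_reads are dropped; remaining samples are
    rarefied to `depth` (default: the minimum retained total — the largest
    depth all samples can share) and every index is the mean over
    `replicates` seeded draws.
    """
    kept = filter_samples(t, min_reads=min_reads)
    totals = kept.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth > int(totals.min()):
        raise ValueError(f"depth {depth} exceeds smallest retained total {int(totals.min())}")
    seeds = np.random.SeedSequence(seed).spawn(len(kept.counts))
    rows = []
    for (sid, counts), ss in zip(kept.counts.iterrows(), seeds):
        child = np.random.default_rng(ss)
        vals = np.empty((replicates, 4))
        for k in range(replicates):
            sub = child.multivariate_hypergeometric(counts.to_numpy(), depth)
            vals[k] = (shannon(sub), simpson_d(sub), simpson_evenness(sub), chao1(sub))
        rows.append([sid, *vals.mean(axis=0)])
    df = pd.DataFrame(rows, columns=["sample_id", "H", "D", "E", "C"]).set_index("sample_id")
    df["depth"] = depth
    df["replicates"] = replicates
    return DiversityResult(table=df, depth=depth, replicates=replicates)
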