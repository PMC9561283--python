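"""Agreement between technique-specific epitranscriptomes.

Different m6A profiling techniques (antibody pulldown, crosslinking,
enzymatic, editing-based...) report strikingly different site sets on the
same transcriptome.  This module quantifies pairwise agreement with the
min-normalized overlap score s(A,B) = |A n B| / min(|A|, |B|), builds the
full pairwise matrix for any number of techniques, and estimates how many
techniques must support a site before the support is unlikely under a
permutation null that re-places each technique's sites uniformly over the
candidate-motif universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TechniqueSet",
    "ConsistencyMatrix",
    "SupportProfile",
    "consistency_score",
    "pairwise_consistency",
    "permutation_fdr",
    "select_high_confidence",
    "support_counts",
    "HOUSEKEEPING_TECHNIQUE_COMPARISON",
]

Site = tuple[str, int, str]  # (chrom, pos, strand) at single-nucleotide resolution


@dataclass
class TechniqueSet:
    """A named set of single-nucleotide site identifiers for one technique."""

    name: str
    sites: frozenset[Site]

    def __init__(self, name: str, sites: Iterable[Site]) -> None:
        self.name = name
        self.sites = frozenset(tuple(s) for s in sites)

    def __len__(self) -> int:
        return len(self.sites)


def consistency_score(nA: int, nB: int, nAB: int) -> float:
    """Min-normalized overlap percentage 100 * |A n B| / min(|A|, |B|).

    Full precision is returned; round to two decimals for display.
    """
    if nA < 1 or nB < 1:
        raise ValueError("set sizes must be >= 1")
    if not 0 <= nAB <= min(nA, nB):
        raise ValueError(
            f"impossible overlap: |A n B|={nAB} exceeds min(|A|,|B|)={min(nA, nB)}"
        )
    return 100.0 * nAB / min(nA, nB)


@dataclass
class ConsistencyMatrix:
    """Square technique-by-technique table.

    Diagonal: set sizes.  Upper triangle: intersection counts.  Lower
    triangle: consistency percentages (full precision; display rounds to 2
    decimals).
    """

    names: list[str]
    table: pd.DataFrame

    @property
    def mean_consistency(self) -> float:
        """Mean of the lower-triangle percentages over all unordered pairs."""
        vals = [
            self.table.iat[i, j]
            for i in range(len(self.names))
            for j in range(i)
        ]
        return float(np.mean(vals))

    def score(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        if i == j:
            raise ValueError("a technique has no consistency with itself")
        i, j = max(i, j), min(i, j)
        return float(self.table.iat[i, j])

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        n = len(self.names)
        for i in range(n):
            for j in range(i):
                out.iat[i, j] = round(out.iat[i, j], 2)
        return out


def pairwise_consistency(
    sets: Sequence[TechniqueSet] | None = None,
    *,
    sizes: Optional[Sequence[int]] = None,
    intersections: Optional[Mapping[tuple[int, int], int]] = None,
    names: Optional[Sequence[str]] = None,
) -> ConsistencyMatrix:
    """Pairwise consistency matrix from site sets or from printed counts.

    Either pass ``sets`` (the counts are computed by set intersection) or
    pass ``sizes`` + ``intersections`` (e.g. the diagonal and upper triangle
    of a published comparison table) to recompute the percentages.
    """
    if sets is not None:
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate technique names")
        if len(sets) < 2:
            raise ValueError("need at least two technique sets")
        sizes = [len(s) for s in sets]
        intersections = {
            (i, j): len(sets[i].sites & sets[j].sites)
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        }
    if sizes is None or intersections is None:
        raise ValueError("pass either technique sets or sizes+intersections")
    n = len(sizes)
    names = list(names) if names is not None else [f"T{i+1}" for i in range(n)]
    mat = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        mat[i, i] = sizes[i]
    for (i, j), nab in intersections.items():
        i, j = min(i, j), max(i, j)
        mat[i, j] = nab
        mat[j, i] = consistency_score(sizes[i], sizes[j], nab)
    table = pd.DataFrame(mat, index=names, columns=names)
    return ConsistencyMatrix(names=names, table=table)


# ---------------------------------------------------------------------------
# support and permutation FDR


def support_counts(sets: Sequence[TechniqueSet]) -> dict[Site, int]:
    """Number of techniques supporting each site in the union."""
    counts: dict[Site, int] = {}
    for s in sets:
        for site in s.sites:
            counts[site] = counts.get(site, 0) + 1
    return counts


def select_high_confidence(
    sets: Sequence[TechniqueSet], k_min: int = 4
) -> TechniqueSet:
    """Sites supported by at least ``k_min`` techniques, tagged with counts."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    counts = support_counts(sets)
    kept = {site: k for site, k in counts.items() if k >= k_min}
    ts = TechniqueSet(f"support>={k_min}", kept.keys())
    ts.support = kept  # type: ignore[attr-defined]
    return ts


@dataclass
class SupportProfile:
    """Observed vs permuted support-count tail and the resulting FDR.

    ``n_obs[k]`` counts sites supported by at least k techniques; ``n_perm``
    is the corresponding mean over permutations of the null in which each
    technique re-places its sites uniformly over the candidate universe.
    FDR(k) = n_perm(>=k) / n_obs(>=k), capped at 1; missing where
    n_obs(>=k) = 0.
    """

    k: np.ndarray
    n_obs: np.ndarray
    n_perm: np.ndarray
    fdr: np.ndarray
    n_permutations: int

    def min_support_for(self, alpha: float = 0.05) -> Optional[int]:
        """Smallest k with defined FDR < alpha, or None."""
        for k, f in zip(self.k, self.fdr):
            if not np.isnan(f) and f < alpha:
                return int(k)
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "n_obs_ge_k": self.n_obs,
             "n_perm_ge_k": self.n_perm, "fdr": self.fdr}
        )


def permutation_fdr(
    sets: Sequence[TechniqueSet],
    universe: Sequence[Site],
    n_perm: int = 1000,
    seed: int = 0,
) -> SupportProfile:
    """Empirical-null FDR of multi-technique support over a motif universe.

    Under the null, each technique's site count is preserved but the sites
    are re-placed uniformly at random (without replacement) over the
    universe, independently across techniques.  The tail count N(>=k) of the
    permuted support distribution, averaged over permutations, estimates the
    support expected from technique-independent placement alone.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = list(dict.fromkeys(tuple(s) for s in universe))
    U = len(universe)
    index = {site: i for i, site in enumerate(universe)}
    counts_per_set = []
    for s in sets:
        missing = [site for site in s.sites if site not in index]
        if missing:
            raise ValueError(
                f"technique {s.name!r} reports {len(missing)} sites outside "
                f"the universe, e.g. {sorted(missing)[0]}"
            )
        counts_per_set.append(len(s.sites))
    K = len(sets)

    obs = np.zeros(U, dtype=np.int64)
    for s in sets:
        for site in s.sites:
            obs[index[site]] += 1
    ks = np.arange(1, K + 1)
    n_obs = np.array([(obs >= k).sum() for k in ks], dtype=np.float64)

    rng = np.random.default_rng(seed)
    tail_sums = np.zeros(K, dtype=np.float64)
    support = np.zeros(U, dtype=np.int32)
    for _ in range(n_perm):
        support[:] = 0
        for n_sites in counts_per_set:
            chosen = rng.choice(U, size=n_sites, replace=False)
            support[chosen] += 1
        for ki, k in enumerate(ks):
            tail_sums[ki] += (support >= k).sum()
    n_perm_mean = tail_sums / n_perm

    fdr = np.full(K, np.nan)
    nonzero = n_obs > 0
    fdr[nonzero] = np.minimum(n_perm_mean[nonzero] / n_obs[nonzero], 1.0)
    return SupportProfile(k=ks, n_obs=n_obs, n_perm=n_perm_mean, fdr=fdr,
                          n_permutations=n_perm)


# ---------------------------------------------------------------------------
# published nine-technique comparison on housekeeping genes (input data):
# diagonal = per-technique site counts, upper triangle = pairwise
# intersection counts.

HOUSEKEEPING_TECHNIQUE_COMPARISON: dict = {
    "names": [
        "m6A-seq", "PA-m6A-seq", "miCLIP", "m6A-CLIP-seq", "m6A-REF-seq",
        "MAZTER-seq", "DART-seq", "m6ACE-seq", "m6A-Label-seq",
    ],
    "sizes": [2980, 6828, 22499, 15649, 3736, 5265, 3714, 640, 1244],
    "intersections": {
        (0, 1): 325, (0, 2): 1743, (0, 3): 1474, (0, 4): 105, (0, 5): 2,
        (0, 6): 14, (0, 7): 69, (0, 8): 98,
        (1, 2): 2181, (1, 3): 1522, (1, 4): 202, (1, 5): 88, (1, 6): 160,
        (1, 7): 123, (1, 8): 134,
        (2, 3): 9005, (2, 4): 948, (2, 5): 265, (2, 6): 657, (2, 7): 466,
        (2, 8): 625,
        (3, 4): 742, (3, 5): 142, (3, 6): 456, (3, 7): 411, (3, 8): 581,
        (4, 5): 47, (4, 6): 103, (4, 7): 16, (4, 8): 67,
        (5, 6): 141, (5, 7): 0, (5, 8): 8,
        (6, 7): 10, (6, 8): 18,
        (7, 8): 37,
    },
}
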