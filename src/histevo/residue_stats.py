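"""Residue composition tables and genome-size-class rank statistics.

The Mann-Whitney U test is implemented here rather than imported: the
exact null distribution of U is computed by the standard
partition-counting recurrence whenever both samples are tie-free and
``n_a * n_b`` does not exceed ``exact_limit``; otherwise a normal
approximation with tie-corrected variance and a 0.5 continuity
correction is used. The two-sided p-value is ``min(1, 2 * min(one-sided
p's))``. U is reported for the first sample: U_a = (rank sum of a) -
n_a(n_a+1)/2 with midranks for ties, so U_a + U_b = n_a * n_b.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from histevo.sequence_io import AMINO_ACIDS, SpeciesRecord
from histevo.domains import DomainPartition

DEFAULT_EXACT_LIMIT = 100


@dataclass
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" or "normal_approx"


@dataclass
class SizeClassComparison:
    """Outcome of a rank test between two genome-size groups."""

    residue_set: tuple[str, ...]
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str


def residue_counts(domain_seq: str) -> dict[str, int]:
    """Exact counts of each of the 20 amino acids (mask X never counted)."""
    counter = Counter(domain_seq)
    return {aa: counter.get(aa, 0) for aa in AMINO_ACIDS}


def composition_table(partitions: Iterable[DomainPartition],
                      family: str = "H2A") -> pd.DataFrame:
    """Per-(species, family, domain) amino-acid counts.

    Adds the derived columns R_count, K_count and ST_count (= S + T).
    The 20 counts in each row sum to the domain length (X excluded).
    """
    rows = []
    for part in partitions:
        for domain, seq in (("NTD", part.ntd), ("fold", part.fold),
                            ("CTD", part.ctd)):
            counts = residue_counts(seq)
            rows.append({
                "species_id": part.species_id,
                "seq_id": part.seq_id,
                "family": family,
                "domain": domain,
                "length": len(seq.replace("X", "")),
                **counts,
                "R_count": counts["R"],
                "K_count": counts["K"],
                "ST_count": counts["S"] + counts["T"],
            })
    return pd.DataFrame(rows)


@lru_cache(maxsize=None)
def _exact_count(u: int, n: int, m: int) -> int:
    """Number of rank configurations of n-vs-m samples with U statistic u."""
    if u < 0 or u > n * m:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _exact_count(u - m, n - 1, m) + _exact_count(u, n, m - 1)


def _exact_cdf(u: int, n: int, m: int) -> float:
    total = math.comb(n + m, n)
    return sum(_exact_count(k, n, m) for k in range(u + 1)) / total


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float],
                   exact_limit: int = DEFAULT_EXACT_LIMIT) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (exact or tie-corrected normal)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    rank_sum_a = float(ranks[:n_a].sum())
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n_a * n_b <= exact_limit:
        u_int = int(round(u_a))
        p_less = _exact_cdf(u_int, n_a, n_b)
        p_greater = _exact_cdf(n_a * n_b - u_int, n_a, n_b)
        p = min(1.0, 2.0 * min(p_less, p_greater))
        return MannWhitneyResult(U=float(u_int), p_two_sided=p, method="exact")

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    tie_term = float((tie_counts ** 3 - tie_counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MannWhitneyResult(U=u_a, p_two_sided=1.0, method="normal_approx")
    sd = math.sqrt(var)
    p_less = norm.cdf((u_a - mu + 0.5) / sd)
    p_greater = norm.sf((u_a - mu - 0.5) / sd)
    p = min(1.0, 2.0 * min(p_less, p_greater))
    # keep p in (0, 1] even when the tail underflows
    p = max(p, float(np.finfo(float).tiny))
    return MannWhitneyResult(U=u_a, p_two_sided=p, method="normal_approx")


def _counts_by_class(table: pd.DataFrame, species: Sequence[SpeciesRecord],
                     residue_set: Iterable[str], domain: str,
                     family: str) -> dict[str, list[float]]:
    residue_set = tuple(residue_set)
    for aa in residue_set:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r}")
    size_class = {s.species_id: s.size_class for s in species}
    sub = table[(table["domain"] == domain) & (table["family"] == family)]
    out: dict[str, list[float]] = {"small": [], "medium": [], "large": []}
    for _, row in sub.iterrows():
        cls = size_class.get(row["species_id"])
        if cls is None:
            continue
        out[cls].append(float(sum(row[aa] for aa in residue_set)))
    return out


def compare_size_classes(table: pd.DataFrame, species: Sequence[SpeciesRecord],
                         residue_set: Iterable[str], domain: str = "NTD",
                         family: str = "H2A", group_a: str = "small",
                         group_b: str = "large",
                         exact_limit: int = DEFAULT_EXACT_LIMIT,
                         ) -> SizeClassComparison:
    """Rank-test per-species residue counts between two size classes."""
    by_class = _counts_by_class(table, species, residue_set, domain, family)
    sample_a, sample_b = by_class[group_a], by_class[group_b]
    for name, sample in ((group_a, sample_a), (group_b, sample_b)):
        if len(sample) < 2:
            raise ValueError(
                f"size class {name!r} has {len(sample)} species; need >= 2"
            )
    res = mann_whitney_u(sample_a, sample_b, exact_limit=exact_limit)
    return SizeClassComparison(
        residue_set=tuple(residue_set), group_a=group_a, group_b=group_b,
        n_a=len(sample_a), n_b=len(sample_b), U=res.U,
        p_two_sided=res.p_two_sided, method=res.method,
    )


def residue_sweep(table: pd.DataFrame, species: Sequence[SpeciesRecord],
                  domain: str = "NTD", family: str = "H2A",
                  group_a: str = "small", group_b: str = "large",
                  bonferroni: bool = False,
                  exact_limit: int = DEFAULT_EXACT_LIMIT) -> pd.DataFrame:
    """Run the size-class comparison for each of the 20 amino acids.

    Raw p-values are reported by default; ``bonferroni`` adds a
    ``p_adjusted`` column (p * 20, capped at 1).
    """
    rows = []
    for aa in AMINO_ACIDS:
        c = compare_size_classes(table, species, (aa,), domain=domain,
                                 family=family, group_a=group_a,
                                 group_b=group_b, exact_limit=exact_limit)
        row = {"residue": aa, "n_a": c.n_a, "n_b": c.n_b, "U": c.U,
               "p_two_sided": c.p_two_sided, "method": c.method}
        if bonferroni:
            row["p_adjusted"] = min(1.0, c.p_two_sided * len(AMINO_ACIDS))
        rows.append(row)
    return pd.DataFrame(rows)


def residue_presence_genome_test(species: Sequence[SpeciesRecord],
                                 presence: Mapping[str, bool],
                                 exact_limit: int = DEFAULT_EXACT_LIMIT,
                                 ) -> SizeClassComparison:
    """Compare genome sizes of species lacking vs possessing a feature.

    ``presence`` maps species_id to whether the H2A of that species
    carries the residue feature (e.g. an arginine at N-position 3).
    Sample a = genome sizes without the feature, sample b = with.
    """
    without = [s.genome_size_mbp for s in species
               if s.species_id in presence and not presence[s.species_id]]
    with_ = [s.genome_size_mbp for s in species
             if presence.get(s.species_id)]
    if not without or not with_:
        raise ValueError("both presence groups must be non-empty")
    res = mann_whitney_u(without, with_, exact_limit=exact_limit)
    return SizeClassComparison(
        residue_set=(), group_a="absent", group_b="present",
        n_a=len(without), n_b=len(with_), U=res.U,
        p_two_sided=res.p_two_sided, method=res.method,
    )


def violin_summary(counts_by_class: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Plot-ready distribution summaries per size class.

    One row per class with n, min, quartiles, median, max and a
    frequency-by-count mapping (violin width source). Deterministic.
    """
    rows = []
    for cls, values in counts_by_class.items():
        values = list(values)
        if not values:
            rows.append({"size_class": cls, "n": 0, "min": None, "q1": None,
                         "median": None, "q3": None, "max": None,
                         "frequencies": {}})
            continue
        arr = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        freq = dict(sorted(Counter(values).items()))
        rows.append({"size_class": cls, "n": len(values),
                     "min": float(arr.min()), "q1": float(q1),
                     "median": float(med), "q3": float(q3),
                     "max": float(arr.max()), "frequencies": freq})
    return pd.DataFrame(rows)
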