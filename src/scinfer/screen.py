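"""The synthetic-cytotoxicity (SC) pair screen.

For every unordered pair of sufficiently-often-disrupted genes, samples are
partitioned into four groups by the pair's disruption status -- both genes,
gene A only, gene B only, neither -- and the ln IC50 of the both-disrupted
group is compared against each of the other three groups with a one-sided
Wilcoxon rank-sum (Mann-Whitney) test. A pair is declared SC when all three
p-values fall below alpha and the both-group median is strictly the lowest of
the four: simultaneous disruption sensitises to the drug while single
disruption does not.

Screening rules (defaults):

* genes enter the screen only if disrupted in more than 5% of samples;
* a pair is tested only if each of the four groups holds at least
  ceil(2.5% x n) samples, otherwise it is reported as untested;
* tests are one-sided ("both" stochastically lower); a two-sided mode plus
  the median-direction requirement is available as an alternative reading;
* no multiple-testing correction by default (raw p < alpha); an optional
  Benjamini-Hochberg switch is provided as a documented deviation.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disruption import DisruptionMatrix
from .exceptions import DataError, ParameterError

__all__ = [
    "ScreenParams",
    "PairPartition",
    "RankSumResult",
    "SCPairResult",
    "partition_by_pair",
    "rank_sum_test",
    "evaluate_pair",
    "scan_pairs",
    "sc_pairs",
    "results_to_frame",
    "write_pairs_tsv",
    "write_screen_manifest",
]

GROUP_NAMES = ("both", "a_only", "b_only", "neither")


@dataclass(frozen=True)
class ScreenParams:
    """Knobs of the screen; defaults follow the published procedure."""

    alpha: float = 0.05
    min_gene_freq: float = 0.05           # strict: disrupted in MORE than 5% of samples
    min_group_frac: float = 0.025         # each group >= ceil(frac * n)
    alternative: str = "one_sided_less"   # or "two_sided"
    exact_cutoff: int = 25                # exact null enumeration up to this group size
    bh_correct: bool = False              # optional BH across pairs (off = raw p, as published)

    def __post_init__(self) -> None:
        for name in ("alpha", "min_gene_freq", "min_group_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.alternative not in ("one_sided_less", "two_sided"):
            raise ParameterError(f"unknown alternative '{self.alternative}'")
        if self.exact_cutoff < 1:
            raise ParameterError("exact_cutoff must be >= 1")


@dataclass(frozen=True)
class PairPartition:
    """Four-way split of the samples by a gene pair's disruption status."""

    gene_a: str
    gene_b: str
    both: tuple[str, ...]
    a_only: tuple[str, ...]
    b_only: tuple[str, ...]
    neither: tuple[str, ...]

    def sizes(self) -> tuple[int, int, int, int]:
        return (len(self.both), len(self.a_only), len(self.b_only), len(self.neither))


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class SCPairResult:
    """One candidate pair: group sizes, ln IC50 medians, three p-values, verdict."""

    gene_a: str
    gene_b: str
    group_sizes: tuple[int, int, int, int]
    group_medians: tuple[float, float, float, float]
    p_values: tuple[float, float, float] | None  # both vs a_only / b_only / neither
    is_sc: int
    tested: bool

    def as_pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def partition_by_pair(m: DisruptionMatrix, gene_a: str, gene_b: str) -> PairPartition:
    """Route every sample by (status_a, status_b) into both/a_only/b_only/neither."""
    if gene_a == gene_b:
        raise ParameterError("gene_a and gene_b must differ")
    a = m.column(gene_a)
    b = m.column(gene_b)
    samples = np.asarray(m.sample_ids, dtype=object)
    return PairPartition(
        gene_a=gene_a,
        gene_b=gene_b,
        both=tuple(samples[a & b]),
        a_only=tuple(samples[a & ~b]),
        b_only=tuple(samples[~a & b]),
        neither=tuple(samples[~a & ~b]),
    )


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "one_sided_less",
    exact_cutoff: int = 25,
) -> RankSumResult:
    """Wilcoxon rank-sum / Mann-Whitney U test of x against y.

    One-sided "less" tests the alternative that x is stochastically smaller
    than y. The exact null permutation distribution is used when both groups
    are small (``max(n_x, n_y) <= exact_cutoff``) and the pooled data are
    tie-free; otherwise a tie-corrected normal approximation with continuity
    correction is applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("rank_sum_test requires non-empty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("rank_sum_test requires finite values")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = max(x.size, y.size) <= exact_cutoff and not has_ties
    scipy_alt = "less" if alternative == "one_sided_less" else "two-sided"
    res = stats.mannwhitneyu(
        x, y, alternative=scipy_alt, method="exact" if use_exact else "asymptotic"
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        method="exact" if use_exact else "normal_approx",
    )


def _median(v: np.ndarray) -> float:
    return float(np.median(v)) if v.size else float("nan")


def _evaluate_pair_arrays(
    gene_a: str,
    gene_b: str,
    col_a: np.ndarray,
    col_b: np.ndarray,
    resp: np.ndarray,
    min_size: int,
    params: ScreenParams,
) -> SCPairResult:
    """Core pair evaluation on pre-aligned boolean columns and responses."""
    masks = (col_a & col_b, col_a & ~col_b, ~col_a & col_b, ~col_a & ~col_b)
    groups = [resp[mask] for mask in masks]
    sizes = tuple(int(g.size) for g in groups)
    medians = tuple(_median(g) for g in groups)

    if min(sizes) < min_size:
        return SCPairResult(gene_a, gene_b, sizes, medians, None, 0, tested=False)

    pvals = tuple(
        rank_sum_test(groups[0], g, params.alternative, params.exact_cutoff).p_value
        for g in groups[1:]
    )
    lowest = all(medians[0] < m for m in medians[1:])
    is_sc = int(lowest and all(p < params.alpha for p in pvals))
    return SCPairResult(gene_a, gene_b, sizes, medians, pvals, is_sc, tested=True)


def _align_response(m: DisruptionMatrix, response: pd.Series | pd.DataFrame, drug: str | None):
    """Restrict matrix and response to their common samples (matrix order)."""
    if isinstance(response, pd.DataFrame):
        frame = response
        if drug is not None:
            frame = frame.loc[frame["drug"] == drug]
        response = frame.set_index("sample_id")["ln_ic50"]
    response = response[~response.index.duplicated()]
    common = [s for s in m.sample_ids if s in response.index]
    if not common:
        raise DataError("no samples shared between disruption matrix and response table")
    sub = m.restrict_samples(common)
    return sub, response.loc[common].to_numpy(dtype=float)


def evaluate_pair(
    m: DisruptionMatrix,
    response: pd.Series | pd.DataFrame,
    gene_a: str,
    gene_b: str,
    params: ScreenParams = ScreenParams(),
    drug: str | None = None,
) -> SCPairResult:
    """Test one gene pair for synthetic cytotoxicity.

    ``response`` is either a Series of ln IC50 indexed by sample, or a long
    drug-response frame (then ``drug`` selects the agent). Samples lacking a
    response are excluded before partitioning. A pair whose partition leaves
    any group under ceil(min_group_frac x n) samples is reported untested.
    """
    if gene_a == gene_b:
        raise ParameterError("gene_a and gene_b must differ")
    sub, resp = _align_response(m, response, drug)
    min_size = math.ceil(params.min_group_frac * len(resp))
    return _evaluate_pair_arrays(
        gene_a, gene_b, sub.column(gene_a), sub.column(gene_b), resp, min_size, params
    )


def scan_pairs(
    m: DisruptionMatrix,
    response: pd.Series | pd.DataFrame,
    params: ScreenParams = ScreenParams(),
    drug: str | None = None,
) -> list[SCPairResult]:
    """Run the screen over every unordered pair of frequency-passing genes.

    Genes qualify when disrupted in strictly more than ``min_gene_freq`` of
    the samples carrying a response. Output is ordered lexicographically by
    gene symbols and is invariant to input row/column order.
    """
    sub, resp = _align_response(m, response, drug)
    freq = sub.frequency()
    passing = sorted(freq.index[freq > params.min_gene_freq])
    if len(passing) < 2:
        warnings.warn("fewer than two genes pass the disruption-frequency filter", stacklevel=2)
        return []
    min_size = math.ceil(params.min_group_frac * len(resp))
    cols = {g: sub.column(g) for g in passing}
    results = [
        _evaluate_pair_arrays(a, b, cols[a], cols[b], resp, min_size, params)
        for a, b in itertools.combinations(passing, 2)
    ]
    if params.bh_correct:
        results = _apply_bh(results, params.alpha)
    return results


def _apply_bh(results: list[SCPairResult], alpha: float) -> list[SCPairResult]:
    """Benjamini-Hochberg across tested pairs, on each pair's worst p-value.

    Optional deviation from the published raw-p rule: a pair keeps is_sc = 1
    only if the BH-adjusted maximum of its three p-values stays below alpha.
    """
    tested = [i for i, r in enumerate(results) if r.tested]
    if not tested:
        return results
    worst = np.array([max(results[i].p_values) for i in tested])
    order = np.argsort(worst)
    m = worst.size
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, worst[i] * m / (rank_pos + 1))
        adj[i] = running
    out = list(results)
    for pos, i in enumerate(tested):
        r = results[i]
        if r.is_sc and adj[pos] >= alpha:
            out[i] = SCPairResult(
                r.gene_a, r.gene_b, r.group_sizes, r.group_medians, r.p_values, 0, True
            )
    return out


def sc_pairs(results: Iterable[SCPairResult]) -> list[SCPairResult]:
    """The declared SC pairs among screen results."""
    return [r for r in results if r.is_sc]


def results_to_frame(results: Iterable[SCPairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "n_both": r.group_sizes[0],
            "n_a_only": r.group_sizes[1],
            "n_b_only": r.group_sizes[2],
            "n_neither": r.group_sizes[3],
            "median_both": r.group_medians[0],
            "median_a_only": r.group_medians[1],
            "median_b_only": r.group_medians[2],
            "median_neither": r.group_medians[3],
            "p_vs_a_only": r.p_values[0] if r.p_values else np.nan,
            "p_vs_b_only": r.p_values[1] if r.p_values else np.nan,
            "p_vs_neither": r.p_values[2] if r.p_values else np.nan,
            "tested": int(r.tested),
            "is_sc": r.is_sc,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_pairs_tsv(results: Iterable[SCPairResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def write_screen_manifest(params: ScreenParams, path, extra: dict | None = None) -> None:
    """Record every screen parameter as JSON for reproducibility."""
    manifest = asdict(params)
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
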