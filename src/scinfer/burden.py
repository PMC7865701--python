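"""SC burden: per-sample counts of satisfied SC pairs and their consequences.

A sample's burden is the number of declared SC pairs whose two genes are both
disrupted in that sample. Samples fall into four burden groups (defaults:
G1 = 0 pairs, G2 = 1-2, G3 = 3-9, G4 = >= 10), whose drug responses are
compared with a tie-corrected Kruskal-Wallis test. The cross-drug analysis
asks whether the burden grouping learned on one agent also separates
responses to other agents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disruption import DisruptionMatrix
from .exceptions import DataError, ParameterError
from .screen import SCPairResult, rank_sum_test

__all__ = [
    "BURDEN_GROUPS",
    "KruskalWallisResult",
    "compute_burden",
    "assign_burden_groups",
    "kruskal_wallis",
    "cross_drug_burden_test",
    "burden_long_table",
]

BURDEN_GROUPS = ("G1", "G2", "G3", "G4")


def _pair_tuples(pairs: Iterable) -> list[tuple[str, str]]:
    out = []
    for p in pairs:
        if isinstance(p, SCPairResult):
            out.append((p.gene_a, p.gene_b))
        else:
            a, b = p[0], p[1]
            out.append((a, b))
    return out


def compute_burden(m: DisruptionMatrix, sc_pairs: Iterable) -> pd.Series:
    """Count, per sample, the SC pairs with both genes disrupted.

    ``sc_pairs`` is a collection of :class:`~scinfer.screen.SCPairResult`
    (typically the is_sc = 1 subset) or plain (gene_a, gene_b) tuples.
    """
    pairs = _pair_tuples(sc_pairs)
    burden = np.zeros(m.n_samples, dtype=int)
    for a, b in pairs:
        burden += (m.column(a) & m.column(b)).astype(int)
    return pd.Series(burden, index=m.data.index, name="burden")


def assign_burden_groups(
    burdens: pd.Series, breakpoints: Sequence[int] = (0, 2, 9)
) -> pd.DataFrame:
    """Bin burdens into four ordered groups.

    With breakpoints (b1, b2, b3): G1 iff burden <= b1 (default: exactly 0),
    G2 iff b1 < burden <= b2, G3 iff b2 < burden <= b3, G4 iff burden > b3.
    Defaults reproduce the published bins 0 / 1-2 / 3-9 / >= 10.
    """
    bp = list(breakpoints)
    if len(bp) != 3 or any(b != int(b) or b < 0 for b in bp) or not (bp[0] < bp[1] < bp[2]):
        raise ParameterError("breakpoints must be three strictly increasing non-negative integers")
    bins = [-np.inf, bp[0], bp[1], bp[2], np.inf]
    group = pd.cut(burdens, bins=bins, labels=BURDEN_GROUPS, right=True)
    return pd.DataFrame(
        {
            "sample_id": burdens.index,
            "burden": burdens.to_numpy(),
            "group": pd.Categorical(group, categories=BURDEN_GROUPS, ordered=True),
        }
    ).set_index("sample_id")


@dataclass(frozen=True)
class KruskalWallisResult:
    h_statistic: float
    df: int
    p_value: float
    group_medians: tuple[float, ...]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("kruskal_wallis requires at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ParameterError("kruskal_wallis groups must all be non-empty")
    n = sum(a.size for a in arrays)
    if n < len(arrays) + 1:
        raise ParameterError("too few observations for a Kruskal-Wallis test")
    h, p = stats.kruskal(*arrays)
    return KruskalWallisResult(
        h_statistic=float(h),
        df=len(arrays) - 1,
        p_value=float(p),
        group_medians=tuple(float(np.median(a)) for a in arrays),
    )


def _response_series(resp: pd.Series | pd.DataFrame, drug: str | None) -> pd.Series:
    if isinstance(resp, pd.DataFrame):
        frame = resp
        if drug is not None:
            frame = frame.loc[frame["drug"] == drug]
        resp = frame.set_index("sample_id")["ln_ic50"]
    return resp[~resp.index.duplicated()]


def cross_drug_burden_test(
    assignments: pd.DataFrame,
    response: pd.Series | pd.DataFrame,
    drug: str = "",
) -> pd.DataFrame:
    """Compare consecutive burden groups on another drug's ln IC50.

    For each consecutive populated pair of groups (G1 vs G2, G2 vs G3,
    G3 vs G4) the higher-burden group is tested one-sided for lower ln IC50.
    Groups without response data are skipped (noted in the ``note`` column).

    Returns a frame with one row per attempted comparison:
    drug, comparison, n_low, n_high, median_low, median_high, p_value, note.
    """
    resp = _response_series(response, drug or None)
    merged = assignments.join(resp.rename("ln_ic50"), how="inner")
    if merged.empty:
        raise DataError("no overlap between burden assignments and responses")
    values = {
        g: merged.loc[merged["group"] == g, "ln_ic50"].to_numpy(dtype=float)
        for g in BURDEN_GROUPS
    }
    populated = [g for g in BURDEN_GROUPS if values[g].size > 0]
    rows = []
    skipped = [g for g in BURDEN_GROUPS if values[g].size == 0]
    for low, high in zip(populated[:-1], populated[1:]):
        res = rank_sum_test(values[high], values[low], alternative="one_sided_less")
        rows.append(
            {
                "drug": drug,
                "comparison": f"{low}_vs_{high}",
                "n_low": values[low].size,
                "n_high": values[high].size,
                "median_low": float(np.median(values[low])),
                "median_high": float(np.median(values[high])),
                "p_value": res.p_value,
                "note": f"skipped empty groups: {','.join(skipped)}" if skipped else "",
            }
        )
    if len(populated) < 2:
        raise DataError("need at least two populated burden groups with responses")
    return pd.DataFrame(rows)


def burden_long_table(
    assignments: pd.DataFrame, response: pd.Series | pd.DataFrame, drugs: Sequence[str]
) -> pd.DataFrame:
    """Boxplot-ready long table: sample, burden group, drug, ln IC50."""
    frames = []
    for drug in drugs:
        resp = _response_series(response, drug)
        merged = assignments.join(resp.rename("ln_ic50"), how="inner").reset_index()
        merged["drug"] = drug
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)
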