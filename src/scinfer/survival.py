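"""Patient-cohort validation: stratification, Firth-penalized Cox, Kaplan-Meier.

Candidate SC pairs found in cell lines are validated in a patient cohort by
stratifying patients on an *anchor* gene (a frequently mutated gene such as
TP53) and its SC *partners*, then asking whether the partner-disruption
burden predicts overall survival inside the anchor-mutant stratum but not
outside it.

Because the strata can be small and events sparse, ordinary Cox partial
likelihood may be monotone (all events in one arm), driving the MLE to
infinity. The fits here use Firth's penalized partial likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),

with l the Breslow-ties Cox partial log-likelihood and I its observed
information. The penalty guarantees finite estimates under separation.
Estimation follows Heinze & Schemper's modified-score Newton iteration with
step-halving; per-covariate p-values come from penalized likelihood-ratio
tests (the covariate profiled at zero), the recommended inference under
sparse events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .disruption import DisruptionMatrix
from .exceptions import DataError, ParameterError

__all__ = [
    "PAIR_GROUPS",
    "FirthCoxResult",
    "KMCurve",
    "stratify_pair_groups",
    "partner_burden",
    "make_pair_design",
    "encode_stage",
    "fit_firth_cox",
    "fit_multivariate",
    "firth_lrt",
    "kaplan_meier",
]

#: 2x2 stratification labels; both_mut is the regression reference level.
PAIR_GROUPS = ("both_mut", "anchor_only", "partner_only", "wild_type")


# ---------------------------------------------------------------------------
# stratification helpers
# ---------------------------------------------------------------------------

def stratify_pair_groups(m: DisruptionMatrix, anchor: str, partner: str) -> pd.Series:
    """Label each patient by (anchor, partner) disruption status.

    Same 2x2 routing as the cell-line screen partition; ``both_mut`` is the
    designated reference level for regression.
    """
    a = m.column(anchor)
    p = m.column(partner)
    labels = np.where(
        a & p, "both_mut", np.where(a, "anchor_only", np.where(p, "partner_only", "wild_type"))
    )
    return pd.Series(labels, index=m.data.index, name="pair_group")


def partner_burden(m: DisruptionMatrix, anchor: str, partners: Sequence[str]) -> pd.DataFrame:
    """Count disrupted partners per patient, flagged by anchor stratum.

    Returns a frame indexed by patient with ``burden`` (0..len(partners)) and
    ``anchor_mutant`` (bool). Patients keep their burden regardless of anchor
    status; the flag routes them to the with/without-anchor stratum.
    """
    if not partners:
        raise ParameterError("partners must be non-empty")
    burden = np.zeros(m.n_samples, dtype=int)
    for g in partners:
        burden += m.column(g).astype(int)
    return pd.DataFrame(
        {"burden": burden, "anchor_mutant": m.column(anchor)}, index=m.data.index
    )


def make_pair_design(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Survival design for the four-group pair stratification.

    Joins group labels with the clinical table (indexed or keyed by
    ``patient_id``) and dummy-codes the three non-reference groups against
    ``both_mut``, so hazard ratios > 1 read "worse survival than the
    double-disrupted group".
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    df = pd.DataFrame({"pair_group": labels}).join(clin, how="inner")
    out = pd.DataFrame(
        {"time": df["os_time"].astype(float), "event": df["os_event"].astype(int)},
        index=df.index,
    )
    for grp in PAIR_GROUPS[1:]:
        out[grp] = (df["pair_group"] == grp).astype(float)
    return out


_STAGE_CODE = {"I": 1, "II": 2, "III": 3, "IV": 4}


def encode_stage(stage: pd.Series, dummies: bool = False) -> pd.DataFrame:
    """Encode pathologic stage I-IV.

    Default is a single ordinal code (I=1 .. IV=4), which stays estimable at
    small subgroup sizes; ``dummies=True`` yields per-stage indicators
    (reference = stage I) instead.
    """
    cleaned = stage.astype("string").str.strip().str.replace("Stage ", "", regex=False)
    codes = cleaned.map(_STAGE_CODE)
    if not dummies:
        return pd.DataFrame({"stage_code": codes.astype(float)}, index=stage.index)
    out = pd.DataFrame(index=stage.index)
    for name, code in list(_STAGE_CODE.items())[1:]:
        out[f"stage_{name}"] = (codes == code).astype(float)
    return out


# ---------------------------------------------------------------------------
# Firth-penalized Cox partial likelihood
# ---------------------------------------------------------------------------

class _PartialLikelihood:
    """Breslow-ties Cox partial likelihood with analytic derivatives.

    At each distinct event time t_i with d_i deaths and death-covariate sum
    s_i, and risk set R_i = {j : t_j >= t_i} with weights w_j = exp(x_j'b):

        l  = sum_i [ s_i'b - d_i log S0_i ]
        U  = sum_i [ s_i - d_i S1_i/S0_i ]
        I  = sum_i d_i [ S2_i/S0_i - (S1_i/S0_i)(S1_i/S0_i)' ]

    where Sk_i are the weighted covariate moments over R_i. The third
    derivative tensor dI/db_r needed by the Firth modified score uses the
    weighted third moment S3 analogously.
    """

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> None:
        order = np.argsort(time, kind="stable")
        self.X = np.asarray(X, dtype=float)[order]
        self.time = np.asarray(time, dtype=float)[order]
        self.event = np.asarray(event, dtype=bool)[order]
        self.n, self.p = self.X.shape
        ev_times = self.time[self.event]
        if ev_times.size == 0:
            raise DataError("no events in the data; Cox regression is undefined")
        self.uniq, inv = np.unique(ev_times, return_inverse=True)
        self.d = np.bincount(inv).astype(float)
        self.s = np.zeros((self.uniq.size, self.p))
        np.add.at(self.s, inv, self.X[self.event])
        self.risk_start = np.searchsorted(self.time, self.uniq, side="left")

    def _moments(self, beta: np.ndarray, third: bool):
        eta = self.X @ beta
        c = eta.max()
        w = np.exp(eta - c)
        idx = self.risk_start
        S0 = np.cumsum(w[::-1])[::-1][idx]
        wX = w[:, None] * self.X
        S1 = np.cumsum(wX[::-1], axis=0)[::-1][idx]
        wXX = np.einsum("np,nq->npq", wX, self.X)
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1][idx]
        log_S0 = c + np.log(S0)
        E = S1 / S0[:, None]
        S2n = S2 / S0[:, None, None]
        S3n = None
        if third:
            wXXX = np.einsum("npq,nr->npqr", wXX, self.X)
            S3n = np.cumsum(wXXX[::-1], axis=0)[::-1][idx] / S0[:, None, None, None]
        return eta, log_S0, E, S2n, S3n

    def loglik(self, beta: np.ndarray) -> float:
        eta, log_S0, *_ = self._moments(beta, third=False)
        return float(eta[self.event].sum() - (self.d * log_S0).sum())

    def derivatives(self, beta: np.ndarray, third: bool = False):
        eta, log_S0, E, S2n, S3n = self._moments(beta, third)
        l = float(eta[self.event].sum() - (self.d * log_S0).sum())
        U = (self.s - self.d[:, None] * E).sum(axis=0)
        V = S2n - np.einsum("mp,mq->mpq", E, E)
        info = np.einsum("m,mpq->pq", self.d, V)
        dI = None
        if third:
            term = S3n.copy()
            term -= np.einsum("mpq,mr->mpqr", S2n, E)
            term -= np.einsum("mpr,mq->mpqr", S2n, E)
            term -= np.einsum("mqr,mp->mpqr", S2n, E)
            term += 2.0 * np.einsum("mp,mq,mr->mpqr", E, E, E)
            dI = np.einsum("m,mpqr->rpq", self.d, term)
        return l, U, info, dI

    def penalized_loglik(self, beta: np.ndarray) -> float:
        l, _, info, _ = self.derivatives(beta)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return l + 0.5 * logdet


@dataclass
class FirthCoxResult:
    """Fit of a Firth-penalized Cox model.

    ``p_value`` entries are penalized likelihood-ratio tests of each
    coefficient against zero (others profiled). ``hazard_ratio`` is
    exp(beta) exactly. ``loglik_path`` records the penalized log-likelihood
    at each accepted Newton step (non-decreasing).
    """

    covariates: tuple[str, ...]
    beta: np.ndarray
    hazard_ratio: np.ndarray
    p_value: np.ndarray
    penalized_loglik: float
    loglik_null: float
    converged: bool
    iterations: int
    n: int
    n_events: int
    loglik_path: list = field(default_factory=list, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "hazard_ratio": self.hazard_ratio,
                "p_value": self.p_value,
                "n": self.n,
                "events": self.n_events,
            }
        )


_MAX_STEP = 5.0


def _newton_fit(
    pl: _PartialLikelihood,
    free: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Maximize l* over the free coordinates (others held fixed).

    Modified-score Newton with step-halving; convergence when the penalized
    score over the free coordinates drops below ``tol`` in max-norm.
    """
    beta = beta0.astype(float).copy()
    path: list[float] = []
    converged = False
    iterations = 0
    if not free.any():
        return beta, pl.penalized_loglik(beta), True, 0, path

    for iterations in range(1, max_iter + 1):
        l, U, info, dI = pl.derivatives(beta, third=True)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            converged = False
            break
        lstar = l + 0.5 * logdet
        path.append(lstar)
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        u_star = U + 0.5 * np.einsum("pq,rqp->r", info_inv, dI)
        if np.max(np.abs(u_star[free])) < tol:
            converged = True
            break
        step = np.zeros_like(beta)
        sub = info[np.ix_(free, free)]
        try:
            step[free] = np.linalg.solve(sub, u_star[free])
        except np.linalg.LinAlgError:
            break
        biggest = np.max(np.abs(step))
        if biggest > _MAX_STEP:
            step *= _MAX_STEP / biggest
        accepted = False
        for _ in range(25):
            cand = beta + step
            if pl.penalized_loglik(cand) > lstar - 1e-10:
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            converged = np.max(np.abs(u_star[free])) < 1e-3
            break
        beta = cand
    return beta, pl.penalized_loglik(beta), converged, iterations, path


def _build_design(
    design: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str,
    event_col: str,
):
    for col in (duration_col, event_col, *covariates):
        if col not in design.columns:
            raise ParameterError(f"design is missing column '{col}'")
    df = design[[duration_col, event_col, *covariates]].dropna()
    X = df[list(covariates)].to_numpy(dtype=float)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=float)
    if (time < 0).any():
        raise DataError("negative survival times")
    if not np.isin(event, (0, 1)).all():
        raise DataError("event indicator must be 0/1")
    if event.sum() < 1:
        raise DataError("no events in the data; Cox regression is undefined")
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise DataError(f"covariate '{name}' is constant")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        raise DataError(
            f"collinear covariates among {list(covariates)}: design matrix is rank-deficient"
        )
    return X, time, event


def fit_firth_cox(
    design: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    max_iter: int = 100,
    tol: float = 1e-6,
    compute_pvalues: bool = True,
) -> FirthCoxResult:
    """Fit a Firth-penalized Cox proportional-hazards model.

    Parameters
    ----------
    design
        One row per subject with duration, event indicator, and covariates;
        rows with missing values in any used column are dropped.
    covariates
        Column names entering the linear predictor.

    Raises
    ------
    DataError
        If there are no events, a covariate is constant (named in the
        message), or covariates are collinear.
    """
    covariates = tuple(covariates)
    X, time, event = _build_design(design, covariates, duration_col, event_col)
    pl = _PartialLikelihood(X, time, event)
    p = X.shape[1]
    free = np.ones(p, dtype=bool)
    beta, lstar, converged, iters, path = _newton_fit(pl, free, np.zeros(p), max_iter, tol)
    loglik_null = pl.penalized_loglik(np.zeros(p))

    pvals = np.full(p, np.nan)
    if compute_pvalues:
        for r in range(p):
            free_r = free.copy()
            free_r[r] = False
            start = beta.copy()
            start[r] = 0.0
            _, lstar_r, _, _, _ = _newton_fit(pl, free_r, start, max_iter, tol)
            stat = max(0.0, 2.0 * (lstar - lstar_r))
            pvals[r] = stats.chi2.sf(stat, 1)

    return FirthCoxResult(
        covariates=covariates,
        beta=beta,
        hazard_ratio=np.exp(beta),
        p_value=pvals,
        penalized_loglik=lstar,
        loglik_null=loglik_null,
        converged=converged,
        iterations=iters,
        n=len(time),
        n_events=int(event.sum()),
        loglik_path=path,
    )


def firth_lrt(
    design: pd.DataFrame,
    covariates: Sequence[str],
    covariate: str,
    value: float = 0.0,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[float, float]:
    """Penalized LRT of ``beta_covariate = value`` (others profiled).

    Returns (statistic, p). With ``value=0`` this reproduces the
    per-covariate p-value of :func:`fit_firth_cox`; at other values it gives
    profile-likelihood interval membership (true value inside the 95% profile
    CI iff statistic <= chi2_{1,0.95}).
    """
    covariates = tuple(covariates)
    r = covariates.index(covariate)
    X, time, event = _build_design(design, covariates, duration_col, event_col)
    pl = _PartialLikelihood(X, time, event)
    p = X.shape[1]
    free = np.ones(p, dtype=bool)
    _, lstar_full, _, _, _ = _newton_fit(pl, free, np.zeros(p))
    free_r = free.copy()
    free_r[r] = False
    start = np.zeros(p)
    start[r] = value
    _, lstar_r, _, _, _ = _newton_fit(pl, free_r, start)
    stat = max(0.0, 2.0 * (lstar_full - lstar_r))
    return stat, float(stats.chi2.sf(stat, 1))


def fit_multivariate(
    design: pd.DataFrame,
    covariates: Sequence[str],
    stage_col: str = "stage",
    dummy_stage: bool = False,
    **kwargs,
) -> FirthCoxResult:
    """Firth Cox fit adjusted for pathologic stage.

    Stage is encoded per :func:`encode_stage` (ordinal by default) and
    appended to ``covariates``; everything else follows
    :func:`fit_firth_cox`.
    """
    stage = encode_stage(design[stage_col], dummies=dummy_stage)
    df = pd.concat([design.drop(columns=[stage_col]), stage], axis=1)
    return fit_firth_cox(df, tuple(covariates) + tuple(stage.columns), **kwargs)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve for one group, with an at-risk table."""

    label: str
    times: np.ndarray        # event/censoring timeline (increasing)
    survival: np.ndarray     # S(t), right-continuous step function, S(0)=1
    at_risk: np.ndarray      # subjects at risk just before each time
    risk_table: Mapping[float, int] | None = None

    def survival_at(self, t: float) -> float:
        """S(t): value of the step function at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(
    design: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str | None = None,
    risk_times: Sequence[float] | None = None,
) -> dict[str, KMCurve]:
    """Kaplan-Meier curves per group with optional risk tables.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i); subjects censored at t remain at
    risk at t (standard convention, as implemented by lifelines).
    """
    times_all = design[duration_col].to_numpy(dtype=float)
    if (times_all < 0).any():
        raise DataError("negative survival times")
    if group_col is None:
        grouped = [("all", design)]
    else:
        grouped = list(design.groupby(group_col, observed=True))
    curves: dict[str, KMCurve] = {}
    for label, df in grouped:
        if df.empty:
            raise ParameterError(f"group '{label}' is empty")
        durations = df[duration_col].to_numpy(dtype=float)
        events = df[event_col].to_numpy(dtype=int)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, events, label=str(label))
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([(durations >= t).sum() for t in timeline], dtype=int)
        table = None
        if risk_times is not None:
            table = {float(t): int((durations >= t).sum()) for t in risk_times}
        curves[str(label)] = KMCurve(str(label), timeline, surv, at_risk, table)
    return curves


def km_to_frame(curves: Mapping[str, KMCurve]) -> pd.DataFrame:
    """Plot-ready long table: group, time, survival, at_risk."""
    frames = [
        pd.DataFrame(
            {"group": c.label, "time": c.times, "survival": c.survival, "at_risk": c.at_risk}
        )
        for c in curves.values()
    ]
    return pd.concat(frames, ignore_index=True)
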