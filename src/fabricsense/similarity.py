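"""Cluster-model similarity statistics.

A motion class is summarised by stacking its M recorded signals (length P)
into a cluster matrix Psi (P×M) and taking the column mean psi as the class
prototype.  The similarity of a probe signal phi' to the class is the
Euclidean distance s = ||psi - phi'||; scores are min–max normalised over
the collection under comparison, and group differences are tested with
one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apparatus import MotionSignal

__all__ = [
    "ClusterMatrix",
    "ClusterModel",
    "SimilarityScore",
    "AnovaResult",
    "build_cluster",
    "cluster_mean",
    "similarity",
    "normalize_scores",
    "one_way_anova",
    "class_separation_report",
    "SeparationReport",
]


@dataclass
class ClusterMatrix:
    """P×M matrix whose columns are same-class signals."""

    entries: np.ndarray
    condition: str = ""
    sensor_id: str = ""

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("cluster matrix must be two-dimensional")
        if self.entries.shape[1] < 2:
            raise ValueError("cluster needs at least two columns (trials)")

    @property
    def P(self) -> int:
        return self.entries.shape[0]

    @property
    def M(self) -> int:
        return self.entries.shape[1]


@dataclass
class ClusterModel:
    """Class prototype: the column mean of a cluster matrix."""

    mean: np.ndarray
    source: ClusterMatrix | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()


@dataclass
class SimilarityScore:
    """Euclidean distance of one probe to a prototype, optionally min–max
    normalised within its scored collection."""

    raw: float
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.raw < 0:
            raise ValueError("raw similarity must be nonnegative")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _as_columns(signals: Sequence[MotionSignal | np.ndarray]) -> np.ndarray:
    cols = [np.asarray(getattr(s, "samples", s), dtype=float).ravel()
            for s in signals]
    lengths = {len(c) for c in cols}
    if len(lengths) > 1:
        raise ValueError(f"signals have ragged lengths {sorted(lengths)}")
    return np.column_stack(cols)


def build_cluster(signals: Sequence[MotionSignal | np.ndarray],
                  condition: str = "", sensor_id: str = "") -> ClusterMatrix:
    """Stack same-sensor, same-condition signals column-wise, trial order
    preserved."""
    if len(signals) < 2:
        raise ValueError("need at least two signals to form a cluster")
    return ClusterMatrix(_as_columns(signals), condition, sensor_id)


def cluster_mean(cluster: ClusterMatrix) -> ClusterModel:
    """Row-wise arithmetic mean over trials — the motion model psi."""
    return ClusterModel(cluster.entries.mean(axis=1), source=cluster)


def similarity(model: ClusterModel | np.ndarray,
               probe: MotionSignal | np.ndarray) -> SimilarityScore:
    """Euclidean distance between the prototype and the probe signal."""
    psi = model.mean if isinstance(model, ClusterModel) else model
    psi = np.asarray(psi, dtype=float).ravel()
    phi = np.asarray(getattr(probe, "samples", probe), dtype=float).ravel()
    if psi.shape != phi.shape:
        raise ValueError(f"length mismatch: model {psi.shape[0]}, "
                         f"probe {phi.shape[0]}")
    return SimilarityScore(raw=float(np.linalg.norm(psi - phi)))


def normalize_scores(scores: Iterable[SimilarityScore | float]
                     ) -> list[SimilarityScore]:
    """Min–max normalise raw distances over the collection: min→0, max→1.

    If all raws coincide the normalised values are defined as 0 (with a
    warning) — the comparison carries no contrast.
    """
    items = list(scores)
    raws = np.array([s.raw if isinstance(s, SimilarityScore) else float(s)
                     for s in items])
    if raws.size < 2:
        raise ValueError("need at least two scores to normalise")
    lo, hi = raws.min(), raws.max()
    if hi == lo:
        warnings.warn("all similarity scores identical; normalised values "
                      "set to 0", stacklevel=2)
        normed = np.zeros_like(raws)
    else:
        normed = (raws - lo) / (hi - lo)
    return [SimilarityScore(raw=r, normalized=float(z))
            for r, z in zip(raws, normed)]


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA from sums of squares.

    F = MS_between / MS_within; p is the upper tail of the F distribution.
    Zero within-group variance with unequal means yields F=inf, p=0.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    N = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w,
                           p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


# --------------------------------------------------------------------------
# class-separation report
# --------------------------------------------------------------------------

def _loo_scores(cols: np.ndarray) -> list[float]:
    """Leave-one-out in-class distances: each trial vs the mean of the rest
    (avoids the self-inclusion bias of scoring against the full model)."""
    M = cols.shape[1]
    total = cols.sum(axis=1)
    out = []
    for j in range(M):
        loo_mean = (total - cols[:, j]) / (M - 1)
        out.append(float(np.linalg.norm(loo_mean - cols[:, j])))
    return out


@dataclass
class SeparationReport:
    """Tidy per-trial scores plus per-(sensor, pair) summary statistics."""

    scores: pd.DataFrame
    summary: pd.DataFrame

    def separation(self, sensor_id: str, condition_a: str | None = None,
                   condition_b: str | None = None) -> float:
        rows = self.summary[self.summary.sensor == sensor_id]
        if condition_a is not None:
            rows = rows[(rows.condition_a == condition_a)
                        & (rows.condition_b == condition_b)]
        if len(rows) != 1:
            raise KeyError(f"no unique summary row for {sensor_id}")
        return float(rows.separation.iloc[0])

    def p_value(self, sensor_id: str) -> float:
        rows = self.summary[self.summary.sensor == sensor_id]
        if len(rows) != 1:
            raise KeyError(f"no unique summary row for {sensor_id}")
        return float(rows.p.iloc[0])


def class_separation_report(dataset, sensors: Sequence[str],
                            conditions: Sequence[str] | None = None
                            ) -> SeparationReport:
    """Score class contrast per sensor for every condition pair.

    For each sensor and ordered condition pair (A, B): trials of A are scored
    leave-one-out against their own class model (within), trials of B against
    the full A model and vice versa (between).  Scores are min–max normalised
    per (sensor, pair); the separation statistic is the mean normalised
    between-class minus within-class score.  The accompanying one-way ANOVA
    groups similarity scores to the class-A model by condition — the direct
    test of whether the two motions can be told apart from this sensor.
    """
    if conditions is None:
        conditions = dataset.labels
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to compare")
    records = []
    summaries = []
    for sensor in sensors:
        for ia in range(len(conditions)):
            for ib in range(ia + 1, len(conditions)):
                a, b = conditions[ia], conditions[ib]
                cols_a = _as_columns(dataset.signals(sensor, a))
                cols_b = _as_columns(dataset.signals(sensor, b))
                if cols_a.shape[1] < 2 or cols_b.shape[1] < 2:
                    raise ValueError("need >= 2 trials per class")
                model_a = cols_a.mean(axis=1)
                model_b = cols_b.mean(axis=1)
                within_a = _loo_scores(cols_a)
                within_b = _loo_scores(cols_b)
                between_ab = [float(np.linalg.norm(model_b - cols_a[:, j]))
                              for j in range(cols_a.shape[1])]
                between_ba = [float(np.linalg.norm(model_a - cols_b[:, j]))
                              for j in range(cols_b.shape[1])]
                raws, kinds, conds = [], [], []
                for vals, kind, cond in ((within_a, "within", a),
                                         (within_b, "within", b),
                                         (between_ab, "between", a),
                                         (between_ba, "between", b)):
                    raws.extend(vals)
                    kinds.extend([kind] * len(vals))
                    conds.extend([cond] * len(vals))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    normed = normalize_scores(raws)
                for i, sc in enumerate(normed):
                    records.append(dict(sensor=sensor, condition_a=a,
                                        condition_b=b, condition=conds[i],
                                        kind=kinds[i], trial=i,
                                        raw=sc.raw, normalized=sc.normalized))
                norm_vals = np.array([sc.normalized for sc in normed])
                kinds_arr = np.array(kinds)
                sep = (norm_vals[kinds_arr == "between"].mean()
                       - norm_vals[kinds_arr == "within"].mean())
                # scores to the class-A model, grouped by weight condition
                anova = one_way_anova([within_a, between_ba])
                summaries.append(dict(sensor=sensor, condition_a=a,
                                      condition_b=b, separation=float(sep),
                                      F=anova.F, p=anova.p,
                                      df_between=anova.df_between,
                                      df_within=anova.df_within))
    return SeparationReport(scores=pd.DataFrame.from_records(records),
                            summary=pd.DataFrame.from_records(summaries))


def material_separation_table(datasets: dict[str, object], sensor_id: str,
                              conditions: Sequence[str] | None = None
                              ) -> pd.DataFrame:
    """Compare class separation across fabric materials on one common scale.

    Each entry of ``datasets`` maps a material name to a two-condition
    dataset recorded with that fabric.  Raw within/between scores are pooled
    over all materials before min–max normalisation, so the materials'
    response amplitudes remain comparable (one experiment, one score range —
    the way a box-plot panel per material on a shared axis reads).
    """
    frames = {}
    for name, ds in datasets.items():
        rep = class_separation_report(ds, [sensor_id], conditions)
        frames[name] = rep
    pooled = np.concatenate([r.scores.raw.values for r in frames.values()])
    lo, hi = pooled.min(), pooled.max()
    span = hi - lo if hi > lo else 1.0
    rows = []
    for name, rep in frames.items():
        sc = rep.scores
        between = sc[sc.kind == "between"].raw.values
        within = sc[sc.kind == "within"].raw.values
        rows.append(dict(material=name, sensor=sensor_id,
                         separation=float((between.mean() - within.mean())
                                          / span),
                         mean_between_raw=float(between.mean()),
                         mean_within_raw=float(within.mean()),
                         p=float(rep.summary.p.iloc[0])))
    return pd.DataFrame.from_records(rows)
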