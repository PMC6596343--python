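"""Labeled-taxon detection for comparative amplicon-sequencing SIP (CAP-SIP).

The detection logic compares, per OTU and time point t_x, four relative
abundances (all in percent):

* ``R_a`` — heavy fractions of the ¹³C treatment at t_x,
* ``R_b`` — heavy fractions of the ¹²C treatment at t_x,
* ``R_c`` — light fractions of the ¹³C treatment at t_x,
* ``R_d`` — heavy fractions of the ¹³C treatment at t₀.

A significance threshold *T* is estimated from the t₀ baseline: the mean
per-OTU difference between heavy-¹³C and heavy-¹²C libraries plus three
times its standard deviation (a 3σ rule; under normal noise the implied
correct-detection rate is 2Φ(3) − 1 ≈ 99.73%). An OTU is scored
¹³C-labeled at t_x when

1. ``R_a − R_b > T``,
2. ``R_a − R_c > T``,
3. ``R_a − R_d > T``,

with a fourth, reported-but-not-required criterion ``R_cs > T`` where

    R_cs = (3·R_a − R_b − R_c − R_d) / 3

is the *R_cs score* (average relative CAP-SIP abundance), the per-OTU
labeling magnitude. All inequalities are strict; ties at exactly *T* fail.

The class at the center, :class:`CapSipClassifier`, follows the
scikit-learn estimator protocol: ``fit`` consumes the two t₀ baseline
columns (shape ``(n_otus, 2)``), ``predict`` consumes quadruple rows
``(R_a, R_b, R_c, R_d)`` and returns the labeled verdicts, and
``decision_function`` returns R_cs scores. The module-level functions are
thin wrappers around the same arithmetic operating on
:class:`~capsip.sip_tables.AbundanceTable` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .sip_tables import AbundanceTable, LibraryKey

__all__ = [
    "BaselineStats",
    "OtuQuadruple",
    "LabelCall",
    "CapSipClassifier",
    "compute_baseline",
    "r_cs",
    "evaluate_criteria",
    "call_labels",
    "replication_filter",
    "cumulative_rcs",
    "three_sigma_coverage_percent",
    "write_calls_tsv",
    "read_calls_tsv",
    "run_summary",
]


def three_sigma_coverage_percent() -> float:
    """Correct-detection rate implied by a mean + 3·SD threshold, in percent.

    Under Gaussian baseline noise, a symmetric 3σ band covers
    ``2Φ(3) − 1`` of unlabeled differences (≈ 99.73%).
    """
    return 100.0 * (2.0 * norm.cdf(3.0) - 1.0)


@dataclass(frozen=True)
class BaselineStats:
    """Baseline noise summary and significance threshold for one oxygen regime.

    ``threshold_T = mean_diff + 3 * sd_diff`` always holds (enforced to
    1e-9). Units are percent relative abundance throughout.
    """

    oxygen: str
    mean_diff: float
    sd_diff: float
    threshold_T: float
    mode: str = "signed"
    n_otus: int | None = None

    def __post_init__(self) -> None:
        if self.sd_diff < 0:
            raise ValueError("sd_diff must be non-negative")
        expected = self.mean_diff + 3.0 * self.sd_diff
        if abs(self.threshold_T - expected) > 1e-9:
            raise ValueError(
                f"threshold_T {self.threshold_T!r} != mean_diff + 3*sd_diff "
                f"({expected!r})"
            )
        if self.mode not in ("signed", "absolute"):
            raise ValueError(f"mode must be 'signed' or 'absolute', got {self.mode!r}")

    @classmethod
    def from_moments(
        cls, mean_diff: float, sd_diff: float, *, oxygen: str = "oxic", mode: str = "signed"
    ) -> "BaselineStats":
        """Build from already-computed baseline moments (percent)."""
        return cls(
            oxygen=oxygen,
            mean_diff=float(mean_diff),
            sd_diff=float(sd_diff),
            threshold_T=float(mean_diff) + 3.0 * float(sd_diff),
            mode=mode,
        )


@dataclass(frozen=True)
class OtuQuadruple:
    """The four relative abundances feeding one label decision."""

    otu_id: str
    day: float
    r_a: float
    r_b: float
    r_c: float
    r_d: float

    def __post_init__(self) -> None:
        for name in ("r_a", "r_b", "r_c", "r_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} outside [0, 100] percent")


@dataclass(frozen=True)
class LabelCall:
    """Verdict for one OTU at one time point."""

    otu_id: str
    day: float
    r_a: float
    r_b: float
    r_c: float
    r_d: float
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    r_cs: float
    labeled: bool
    threshold_used: float
    demoted_reason: str | None = None


def r_cs(q: OtuQuadruple) -> float:
    """R_cs score (average relative CAP-SIP abundance) of a quadruple.

    ``(3·R_a − R_b − R_c − R_d) / 3``; may be negative.
    """
    return (3.0 * q.r_a - q.r_b - q.r_c - q.r_d) / 3.0


class CapSipClassifier(BaseEstimator):
    """Scikit-learn style CAP-SIP labeled-taxon classifier.

    Parameters
    ----------
    baseline_mode : {"signed", "absolute"}, default "signed"
        Whether baseline per-OTU differences (heavy-¹³C minus heavy-¹²C at
        t₀) enter the mean/SD as signed values or as absolute values.
    require_c4 : bool, default False
        If True, the labeled verdict additionally requires criterion 4
        (``R_cs > T``); by default criterion 4 is computed and reported
        only.
    threshold : float or None, default None
        If set, ``fit`` is not required: the classifier uses this
        significance threshold directly (percent).

    Attributes
    ----------
    mean_diff_ : float
        Baseline mean per-OTU difference (percent).
    sd_diff_ : float
        Sample standard deviation (ddof=1) of baseline differences.
    threshold_ : float
        Significance threshold ``T = mean_diff_ + 3·sd_diff_``.
    n_features_in_ : int
        2 after ``fit``.
    """

    def __init__(
        self,
        baseline_mode: str = "signed",
        require_c4: bool = False,
        threshold: float | None = None,
    ) -> None:
        self.baseline_mode = baseline_mode
        self.require_c4 = require_c4
        self.threshold = threshold

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None) -> "CapSipClassifier":
        """Estimate the baseline threshold from t₀ heavy-fraction columns.

        ``X`` has shape ``(n_otus, 2)``: column 0 the heavy-¹³C and column
        1 the heavy-¹²C relative abundances (percent) at t₀, over the union
        of OTUs (absent OTUs as 0).
        """
        if self.baseline_mode not in ("signed", "absolute"):
            raise ValueError(
                f"baseline_mode must be 'signed' or 'absolute', got {self.baseline_mode!r}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n_otus, 2), got {X.shape}")
        if X.shape[0] < 2:
            raise ValueError("at least 2 OTUs are required (sample SD is undefined)")
        if np.any(~np.isfinite(X)) or np.any(X < 0) or np.any(X > 100):
            raise ValueError("baseline abundances must be finite percentages in [0, 100]")
        diffs = X[:, 0] - X[:, 1]
        if self.baseline_mode == "absolute":
            diffs = np.abs(diffs)
        self.mean_diff_ = float(np.mean(diffs))
        self.sd_diff_ = float(np.std(diffs, ddof=1))
        self.threshold_ = self.mean_diff_ + 3.0 * self.sd_diff_
        self.n_features_in_ = 2
        return self

    @classmethod
    def from_baseline(cls, baseline: BaselineStats, *, require_c4: bool = False) -> "CapSipClassifier":
        """Construct a ready-to-predict classifier from precomputed stats."""
        est = cls(baseline_mode=baseline.mode, require_c4=require_c4)
        est.mean_diff_ = baseline.mean_diff
        est.sd_diff_ = baseline.sd_diff
        est.threshold_ = baseline.threshold_T
        est.n_features_in_ = 2
        return est

    def _threshold(self) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        check_is_fitted(self, "threshold_")
        return self.threshold_

    def baseline_(self, oxygen: str = "oxic") -> BaselineStats:
        """Fitted baseline as a :class:`BaselineStats` record."""
        check_is_fitted(self, "threshold_")
        return BaselineStats(
            oxygen=oxygen,
            mean_diff=self.mean_diff_,
            sd_diff=self.sd_diff_,
            threshold_T=self.threshold_,
            mode=self.baseline_mode,
        )

    # -- prediction ------------------------------------------------------

    @staticmethod
    def _validate_quadruples(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError(
                f"X must have shape (n, 4) with columns (R_a, R_b, R_c, R_d), got {X.shape}"
            )
        if np.any(~np.isfinite(X)) or np.any(X < 0) or np.any(X > 100):
            raise ValueError("quadruple abundances must be finite percentages in [0, 100]")
        return X

    def criteria(self, X) -> np.ndarray:
        """Boolean matrix (n, 4) of the four strict-inequality criteria."""
        X = self._validate_quadruples(X)
        T = self._threshold()
        ra, rb, rc, rd = X.T
        rcs = (3.0 * ra - rb - rc - rd) / 3.0
        return np.column_stack([ra - rb > T, ra - rc > T, ra - rd > T, rcs > T])

    def decision_function(self, X) -> np.ndarray:
        """R_cs score per quadruple row (percent; may be negative)."""
        X = self._validate_quadruples(X)
        return (3.0 * X[:, 0] - X[:, 1] - X[:, 2] - X[:, 3]) / 3.0

    def predict(self, X) -> np.ndarray:
        """Labeled verdict per quadruple row (criteria 1–3, plus 4 if required)."""
        c = self.criteria(X)
        labeled = c[:, 0] & c[:, 1] & c[:, 2]
        if self.require_c4:
            labeled = labeled & c[:, 3]
        return labeled


# -- functional surface over AbundanceTable ------------------------------


def compute_baseline(
    heavy13_t0,
    heavy12_t0,
    *,
    oxygen: str = "oxic",
    mode: str = "signed",
) -> BaselineStats:
    """Baseline mean/SD of per-OTU t₀ differences and the 3σ threshold.

    Both inputs are percent-normalized heavy-fraction columns over the same
    (union) OTU index; absent OTUs contribute 0. The per-OTU difference is
    heavy-¹³C minus heavy-¹²C; the SD is the sample standard deviation
    (ddof=1). Fewer than 2 OTUs is an error.
    """
    a = np.asarray(heavy13_t0, dtype=float)
    b = np.asarray(heavy12_t0, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"column shapes differ: {a.shape} vs {b.shape}")
    est = CapSipClassifier(baseline_mode=mode).fit(np.column_stack([a, b]))
    stats = est.baseline_(oxygen)
    return replace(stats, n_otus=int(a.shape[0]))


def evaluate_criteria(
    q: OtuQuadruple, T: float, *, require_c4: bool = False
) -> LabelCall:
    """Apply the four labeling criteria to one quadruple at threshold ``T``."""
    if T < 0:
        raise ValueError(f"threshold T must be non-negative, got {T!r}")
    score = r_cs(q)
    c1 = q.r_a - q.r_b > T
    c2 = q.r_a - q.r_c > T
    c3 = q.r_a - q.r_d > T
    c4 = score > T
    labeled = c1 and c2 and c3 and (c4 if require_c4 else True)
    return LabelCall(
        otu_id=q.otu_id,
        day=q.day,
        r_a=q.r_a,
        r_b=q.r_b,
        r_c=q.r_c,
        r_d=q.r_d,
        c1=c1,
        c2=c2,
        c3=c3,
        c4=c4,
        r_cs=score,
        labeled=labeled,
        threshold_used=T,
    )


def _required_column(table: AbundanceTable, key: LibraryKey) -> np.ndarray:
    try:
        return table.column(key).to_numpy(dtype=float)
    except KeyError:
        raise KeyError(f"missing required library {key.token()}") from None


def call_labels(
    table: AbundanceTable,
    baseline: BaselineStats,
    *,
    t0: float | None = None,
    days: Sequence[float] | None = None,
    require_c4: bool = False,
) -> list[LabelCall]:
    """Score every OTU at every post-t₀ day of one oxygen treatment.

    ``table`` must be in percent units and contain, for each evaluated day,
    the heavy-¹³C, heavy-¹²C and light-¹³C libraries, plus the heavy-¹³C
    library at t₀ (default: the earliest day present). OTUs absent from a
    library contribute a relative abundance of 0 — the table's shared OTU
    index already encodes this. Output is sorted by (day, R_cs descending).
    """
    if table.units != "percent":
        raise ValueError("call_labels requires a percent-normalized table")
    oxy = baseline.oxygen
    sub = table.select(oxygen=oxy)
    all_days = sub.days()
    if not all_days:
        raise KeyError(f"no libraries for oxygen regime {oxy!r}")
    t0 = float(min(all_days)) if t0 is None else float(t0)
    eval_days = [d for d in (all_days if days is None else days) if d != t0]
    rd0 = _required_column(sub, LibraryKey("13C", oxy, t0, "heavy"))
    T = baseline.threshold_T
    est = CapSipClassifier.from_baseline(baseline, require_c4=require_c4)
    calls: list[LabelCall] = []
    otus = sub.otu_ids
    for day in eval_days:
        ra = _required_column(sub, LibraryKey("13C", oxy, day, "heavy"))
        rb = _required_column(sub, LibraryKey("12C", oxy, day, "heavy"))
        rc = _required_column(sub, LibraryKey("13C", oxy, day, "light"))
        X = np.column_stack([ra, rb, rc, rd0])
        crit = est.criteria(X)
        labeled = est.predict(X)
        scores = est.decision_function(X)
        order = np.argsort(-scores, kind="stable")
        for i in order:
            calls.append(
                LabelCall(
                    otu_id=otus[i],
                    day=float(day),
                    r_a=float(ra[i]),
                    r_b=float(rb[i]),
                    r_c=float(rc[i]),
                    r_d=float(rd0[i]),
                    c1=bool(crit[i, 0]),
                    c2=bool(crit[i, 1]),
                    c3=bool(crit[i, 2]),
                    c4=bool(crit[i, 3]),
                    r_cs=float(scores[i]),
                    labeled=bool(labeled[i]),
                    threshold_used=T,
                )
            )
    return calls


def replication_filter(calls: Iterable[LabelCall], min_days: int = 2) -> list[LabelCall]:
    """Demote OTUs not labeled on at least ``min_days`` distinct days.

    Labeling a taxon on several time points replicates the observation over
    time; OTUs labeled on fewer days than ``min_days`` are demoted to
    unlabeled with a recorded reason. ``min_days=1`` is the identity on the
    labeled set.
    """
    if min_days < 1:
        raise ValueError(f"min_days must be >= 1, got {min_days}")
    calls = list(calls)
    days_labeled: dict[str, set[float]] = {}
    for c in calls:
        if c.labeled:
            days_labeled.setdefault(c.otu_id, set()).add(c.day)
    out: list[LabelCall] = []
    for c in calls:
        n = len(days_labeled.get(c.otu_id, ()))
        if c.labeled and n < min_days:
            out.append(
                replace(
                    c,
                    labeled=False,
                    demoted_reason=f"labeled on {n} day(s) < min_days={min_days}",
                )
            )
        else:
            out.append(c)
    return out


def cumulative_rcs(calls: Iterable[LabelCall], day: float) -> float:
    """Sum of R_cs scores over OTUs labeled at ``day``.

    Negative R_cs of labeled OTUs (possible in principle) is included
    as-is. Raises if no calls were computed for that day.
    """
    calls = list(calls)
    day = float(day)
    at_day = [c for c in calls if c.day == day]
    if not at_day:
        evaluated = sorted({c.day for c in calls})
        raise KeyError(f"day {day:g} not evaluated (have {evaluated})")
    return float(sum(c.r_cs for c in at_day if c.labeled))


# -- reporting helpers ---------------------------------------------------

_CALL_COLUMNS = [
    "otu_id", "day", "r_a", "r_b", "r_c", "r_d",
    "c1", "c2", "c3", "c4", "r_cs", "labeled", "threshold_used", "demoted_reason",
]


def calls_to_frame(calls: Iterable[LabelCall]) -> pd.DataFrame:
    rows = [[getattr(c, col) for col in _CALL_COLUMNS] for c in calls]
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def write_calls_tsv(calls: Iterable[LabelCall], path: str | Path) -> None:
    """Write label calls as TSV (one row per OTU per day)."""
    df = calls_to_frame(calls)
    df["demoted_reason"] = df["demoted_reason"].fillna("")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_calls_tsv(path: str | Path) -> list[LabelCall]:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    calls = []
    for row in df.itertuples(index=False):
        reason = getattr(row, "demoted_reason", None)
        if reason is not None and (pd.isna(reason) or reason == ""):
            reason = None
        calls.append(
            LabelCall(
                otu_id=str(row.otu_id),
                day=float(row.day),
                r_a=float(row.r_a),
                r_b=float(row.r_b),
                r_c=float(row.r_c),
                r_d=float(row.r_d),
                c1=bool(row.c1),
                c2=bool(row.c2),
                c3=bool(row.c3),
                c4=bool(row.c4),
                r_cs=float(row.r_cs),
                labeled=bool(row.labeled),
                threshold_used=float(row.threshold_used),
                demoted_reason=reason,
            )
        )
    return calls


def run_summary(calls: Sequence[LabelCall], baseline: BaselineStats) -> dict:
    """JSON-serializable run summary: threshold, per-day counts, cumulative R_cs."""
    days = sorted({c.day for c in calls})
    return {
        "oxygen": baseline.oxygen,
        "baseline": {
            "mean_diff_percent": baseline.mean_diff,
            "sd_diff_percent": baseline.sd_diff,
            "threshold_T_percent": baseline.threshold_T,
            "mode": baseline.mode,
            "n_otus": baseline.n_otus,
        },
        "three_sigma_coverage_percent": three_sigma_coverage_percent(),
        "days": {
            f"{d:g}": {
                "n_labeled": sum(1 for c in calls if c.day == d and c.labeled),
                "cumulative_r_cs_percent": cumulative_rcs(calls, d),
            }
            for d in days
        },
        "n_calls": len(calls),
    }
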