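"""Performance evaluation against adjudicated chart review.

Note-level precision/recall/F from a confusion matrix, raw percent
inter-rater agreement, Cochran's sample-size formula with finite-population
correction for sizing the manual review, and seeded control sampling.

Two reporting styles are exposed for F: full precision (F computed from
exact P and R), and the chart-review convention of rounding P and R to two
decimals first and computing F from the rounded values — with counts
(tp=36, fp=4, fn=1) these give 0.935 and 0.93 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0  # carried for completeness; unused by precision/recall/F

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    precision: float | None
    recall: float | None
    f_measure: float | None


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision tp/(tp+fp), recall tp/(tp+fn), F = 2PR/(P+R).

    A zero denominator yields None (undefined is a value, not an exception).
    """
    p = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else None
    r = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else None
    f = None
    if p is not None and r is not None and (p + r) > 0:
        f = 2 * p * r / (p + r)
    elif p is not None and r is not None:
        f = 0.0 if (p + r) == 0 and counts.tp == 0 and (counts.fp or counts.fn) else None
    return Metrics(precision=p, recall=r, f_measure=f)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def paper_style_report(counts: ConfusionCounts) -> Metrics:
    """Chart-review-style rounded report: P and R to two decimals first,
    then F from the rounded values, itself rounded to two decimals."""
    m = metrics(counts)
    if m.precision is None or m.recall is None:
        return Metrics(
            precision=None if m.precision is None else _round2(m.precision),
            recall=None if m.recall is None else _round2(m.recall),
            f_measure=None,
        )
    p, r = _round2(m.precision), _round2(m.recall)
    f = _round2(2 * p * r / (p + r)) if (p + r) > 0 else None
    return Metrics(precision=p, recall=r, f_measure=f)


def percent_agreement(n_agree: int, n_total: int) -> float:
    """Raw inter-rater agreement as a percentage to one decimal (half-even)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_agree <= n_total:
        raise ValueError("n_agree must lie in [0, n_total]")
    q = Decimal(100) * Decimal(n_agree) / Decimal(n_total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class SampleSizeParams:
    N: int  # finite population size
    p: float  # anticipated prevalence
    z: float  # standard-normal quantile for the confidence level
    d: float  # absolute margin of error

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 0 < self.d < 1:
            raise ValueError("d must lie in (0, 1)")


def z_for_confidence(confidence: float) -> float:
    """Two-sided standard-normal quantile, e.g. 0.95 -> 1.96."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return float(norm.ppf((1 + confidence) / 2))


def review_sample_size(params: SampleSizeParams) -> int:
    """Cochran's formula with finite-population correction, rounded up:

        n = ceil( N z^2 p(1-p) / ( d^2 (N-1) + z^2 p(1-p) ) )

    At N=1057, p=0.05, z=1.96, d=0.05 this gives the 69-patient review.
    """
    pq = params.p * (1 - params.p)
    z2 = params.z**2
    n = params.N * z2 * pq / (params.d**2 * (params.N - 1) + z2 * pq)
    return ceil(n)


def infinite_population_sample_size(p: float, z: float, d: float) -> int:
    """Cochran's formula without the finite-population correction."""
    return ceil(z**2 * p * (1 - p) / d**2)


def sample_controls(negative_ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform sample without replacement, deterministic for a given seed."""
    ids = list(negative_ids)
    if n < 0 or n > len(ids):
        raise ValueError(f"cannot sample {n} of {len(ids)} controls")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in idx]


# --------------------------------------------------------------------------
# adjudication tables
# --------------------------------------------------------------------------

ADJUDICATION_COLUMNS = ("note_id", "reviewer_1", "reviewer_2", "consensus")


def load_adjudications(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"note_id": str})
    missing = [c for c in ADJUDICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"adjudication file missing column(s): {', '.join(missing)}")
    return df


def agreement_from_adjudications(adjudications: pd.DataFrame) -> float:
    """Percent agreement between the two reviewers over all adjudicated notes."""
    agree = int((adjudications["reviewer_1"] == adjudications["reviewer_2"]).sum())
    return percent_agreement(agree, len(adjudications))


def confusion_from_adjudications(
    predicted_positive: set[str] | Sequence[str], adjudications: pd.DataFrame
) -> ConfusionCounts:
    """Note-level confusion counts of predictions against consensus labels.

    Consensus labels are truthy strings "positive"/"negative".
    """
    predicted = set(predicted_positive)
    tp = fp = fn = tn = 0
    for row in adjudications.itertuples():
        truth = str(row.consensus).strip().lower() == "positive"
        pred = row.note_id in predicted
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
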