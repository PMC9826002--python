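"""Monotone multi-dose coverage via conditional-probability and ratio constructions.

For a three-dose series with coverage probabilities p1(s) >= p2(s) >= p3(s),
fitting three unconstrained spatial models cannot guarantee monotone maps.
Both constructions here model the reference dose directly and the remaining
doses through quantities confined to [0,1], so the composed surfaces are
monotone for every posterior draw by construction:

* CP (conditional probability): model p1, p2|1 = P(dose2 | dose1) and
  p3|2 = P(dose3 | dose2).  Data for the conditionals are (y1, y2) and
  (y2, y3) — trial sizes shrink down the series.
* RB (ratio based): model p1 and the ratios p21 = p2/p1, p32 = p3/p2 with
  pseudo binomial counts y21 = n*y2/y1 and y32 = n*y3/y2 on the full trial
  size n — larger point-level samples for the intermediate indicators.

Numerically p2|1 = p21 and p3|2 = p32; the approaches differ only in the
trial sizes attached to the intermediate indicators.  Either end of the
series may serve as reference: with the last dose as reference the series is
composed upward through complement ratios (see :func:`build_cp_datasets`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ClusterDataset, FormatError, IntegrityError

logger = logging.getLogger("vaxmono")

__all__ = [
    "IndicatorDataset",
    "TargetDraws",
    "CategoryProbs",
    "build_cp_datasets",
    "build_rb_datasets",
    "compose_targets",
    "category_probabilities",
]

#: labels of the modeled indicators, per approach and reference end
CP_LABELS = ("p1", "p2g1", "p3g2")
RB_LABELS = ("p1", "p21", "p32")
CP_LABELS_REV = ("p3", "q2g3", "q1g2")
RB_LABELS_REV = ("p3", "q23", "q12")


@dataclass
class IndicatorDataset:
    """(trial size, success count) rows for one modeled indicator."""

    indicator: str
    cluster_id: np.ndarray
    coords: np.ndarray
    trials: np.ndarray
    successes: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    approach: str = "CP"

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.successes = np.asarray(self.successes, dtype=float)
        if np.any(self.trials <= 0):
            raise IntegrityError(f"{self.indicator}: rows with trial_size <= 0 must be excluded")
        if np.any(self.successes < -1e-12) or np.any(self.successes > self.trials + 1e-9):
            raise IntegrityError(f"{self.indicator}: successes outside [0, trials]")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "trials": self.trials,
                "successes": self.successes,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


@dataclass
class TargetDraws:
    """Posterior draws of the target indicators (p1, p2, p3) at L locations."""

    locations: np.ndarray           # (L, 2)
    p1: np.ndarray                  # (S, L)
    p2: np.ndarray
    p3: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.p1, self.p2, self.p3):
            if a.shape != self.p1.shape:
                raise FormatError("target draw matrices must be conformable")
        stacked = np.stack([self.p1, self.p2, self.p3])
        if np.any(stacked < -1e-12) or np.any(stacked > 1 + 1e-12):
            raise IntegrityError("target draws outside [0, 1]")
        if np.any(self.p1 < self.p2 - 1e-12) or np.any(self.p2 < self.p3 - 1e-12):
            raise IntegrityError("monotonicity p1 >= p2 >= p3 violated")


@dataclass
class CategoryProbs:
    """Draws of the four exhaustive vaccination categories per location.

    ``never`` (no dose), ``dose1_only``, ``dose2_only`` (second but not
    third) and ``all_three``; the four sum to one for every draw/location.
    """

    locations: np.ndarray
    never: np.ndarray
    dose1_only: np.ndarray
    dose2_only: np.ndarray
    all_three: np.ndarray


def _rows(ds: ClusterDataset, mask: np.ndarray, trials, successes, label, approach) -> IndicatorDataset:
    excluded = int((~mask).sum())
    if excluded:
        logger.info("%s/%s: excluded %d clusters with zero trial size", approach, label, excluded)
    return IndicatorDataset(
        indicator=label,
        cluster_id=ds.cluster_id[mask],
        coords=ds.coords[mask],
        trials=np.asarray(trials, float)[mask],
        successes=np.asarray(successes, float)[mask],
        covariates=ds.covariates[mask],
        covariate_names=list(ds.covariate_names),
        approach=approach,
    )


def build_cp_datasets(ds: ClusterDataset, reference: str = "first"):
    """Construct the three CP modeled-indicator datasets.

    ``reference="first"`` (default): (n, y1) for p1; (y1, y2) for p2|1 where
    y1 > 0; (y2, y3) for p3|2 where y2 > 0.

    ``reference="last"``: the series is run from the final dose upward via
    complements — (n, y3) for p3; (n - y3, n - y2) for the probability of
    *missing* dose 2 given dose 3 was missed; (n - y2, n - y1) likewise for
    dose 1 — each again confined to [0,1], so upward composition stays
    monotone.  Clusters with zero trial size are excluded per indicator.
    """
    n, y1, y2, y3 = ds.n, ds.y[:, 0], ds.y[:, 1], ds.y[:, 2]
    if reference == "first":
        return (
            _rows(ds, n > 0, n, y1, CP_LABELS[0], "CP"),
            _rows(ds, y1 > 0, y1, y2, CP_LABELS[1], "CP"),
            _rows(ds, y2 > 0, y2, y3, CP_LABELS[2], "CP"),
        )
    if reference == "last":
        return (
            _rows(ds, n > 0, n, y3, CP_LABELS_REV[0], "CP"),
            _rows(ds, n - y3 > 0, n - y3, n - y2, CP_LABELS_REV[1], "CP"),
            _rows(ds, n - y2 > 0, n - y2, n - y1, CP_LABELS_REV[2], "CP"),
        )
    raise ValueError(f"reference must be 'first' or 'last', got {reference!r}")


def build_rb_datasets(ds: ClusterDataset, reference: str = "first"):
    """Construct the three RB modeled-indicator datasets with pseudo counts.

    ``reference="first"``: (n, y1) for p1; (n, n*y2/y1) for p21 where y1 > 0;
    (n, n*y3/y2) for p32 where y2 > 0.  Zero-denominator clusters carry no
    information about the ratio (0/0) and are excluded from that indicator
    only.  ``reference="last"`` mirrors the CP complement construction on the
    full trial size n.
    """
    n, y1, y2, y3 = ds.n, ds.y[:, 0], ds.y[:, 1], ds.y[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        if reference == "first":
            y21 = np.where(y1 > 0, n * y2 / np.where(y1 > 0, y1, 1.0), 0.0)
            y32 = np.where(y2 > 0, n * y3 / np.where(y2 > 0, y2, 1.0), 0.0)
            return (
                _rows(ds, n > 0, n, y1, RB_LABELS[0], "RB"),
                _rows(ds, y1 > 0, n, y21, RB_LABELS[1], "RB"),
                _rows(ds, y2 > 0, n, y32, RB_LABELS[2], "RB"),
            )
        if reference == "last":
            c3, c2, c1 = n - y3, n - y2, n - y1
            q23 = np.where(c3 > 0, n * c2 / np.where(c3 > 0, c3, 1.0), 0.0)
            q12 = np.where(c2 > 0, n * c1 / np.where(c2 > 0, c2, 1.0), 0.0)
            return (
                _rows(ds, n > 0, n, y3, RB_LABELS_REV[0], "RB"),
                _rows(ds, c3 > 0, n, q23, RB_LABELS_REV[1], "RB"),
                _rows(ds, c2 > 0, n, q12, RB_LABELS_REV[2], "RB"),
            )
    raise ValueError(f"reference must be 'first' or 'last', got {reference!r}")


def compose_targets(
    ref_draws: np.ndarray,
    mid_draws: np.ndarray,
    last_draws: np.ndarray,
    locations: np.ndarray | None = None,
    reference: str = "first",
) -> TargetDraws:
    """Compose target-indicator draws from modeled-indicator draws.

    With the first dose as reference: p2 = p1 * mid and p3 = p2 * last,
    elementwise per draw, where mid/last are the CP conditionals or the RB
    ratios (numerically identical).  With the last dose as reference the
    complements compose upward: 1-p2 = (1-p3) * mid, 1-p1 = (1-p2) * last.
    Monotonicity holds for every draw because all factors lie in [0,1].
    """
    ref_draws = np.asarray(ref_draws, float)
    mid_draws = np.asarray(mid_draws, float)
    last_draws = np.asarray(last_draws, float)
    if not (ref_draws.shape == mid_draws.shape == last_draws.shape):
        raise FormatError(
            f"draw matrices not conformable: {ref_draws.shape}, "
            f"{mid_draws.shape}, {last_draws.shape}"
        )
    for a in (ref_draws, mid_draws, last_draws):
        if np.any(a < 0) or np.any(a > 1):
            raise IntegrityError("modeled-indicator draws outside [0, 1]")
    if locations is None:
        locations = np.zeros((ref_draws.shape[-1], 2))
    if reference == "first":
        p1 = ref_draws
        p2 = p1 * mid_draws
        p3 = p2 * last_draws
    elif reference == "last":
        p3 = ref_draws
        p2 = 1.0 - (1.0 - p3) * mid_draws
        p1 = 1.0 - (1.0 - p2) * last_draws
    else:
        raise ValueError(f"reference must be 'first' or 'last', got {reference!r}")
    return TargetDraws(locations=np.asarray(locations), p1=p1, p2=p2, p3=p3)


def category_probabilities(t: TargetDraws) -> CategoryProbs:
    """Split monotone target draws into the four exhaustive categories.

    never = 1 - p1; dose1_only = p1 - p2; dose2_only = p2 - p3;
    all_three = p3.  The four sum to one exactly.
    """
    if np.any(t.p1 < t.p2 - 1e-12) or np.any(t.p2 < t.p3 - 1e-12):
        raise IntegrityError("category_probabilities requires monotone input")
    return CategoryProbs(
        locations=t.locations,
        never=1.0 - t.p1,
        dose1_only=t.p1 - t.p2,
        dose2_only=t.p2 - t.p3,
        all_three=t.p3,
    )
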