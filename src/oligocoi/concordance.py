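"""Morphology-vs-genetics concordance: regressions and class agreement.

For each metric (IOBS, % sensitive taxa, per-group percentages) the genetic
value y is regressed on the morphological value x by ordinary least squares
(y = a·x + b), reporting the slope a, intercept b, coefficient of
determination R² and the two-sided Pearson-test p-value. IOBS series are
log-linearized (natural log of both x and y; non-positive or undefined
values drop the pair) before regression. Quality-class agreement is
tabulated per site on the ordered scale bad < poor < medium < good <
very_good.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import QualityClass


@dataclass(frozen=True)
class PairedMetric:
    site_id: str
    x: float  # morphological
    y: float  # genetic
    metric_name: str


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    pearson_p: float


def linear_regression(pairs: Sequence[PairedMetric]) -> RegressionResult:
    """OLS of genetic (y) on morphological (x) with Pearson-test p-value."""
    if len(pairs) < 3:
        raise ValueError("insufficient pairs")
    x = np.array([p.x for p in pairs], dtype=float)
    y = np.array([p.y for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        n=len(pairs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        pearson_p=float(fit.pvalue),
    )


def log_linearize(pairs: Sequence[PairedMetric]) -> list[PairedMetric]:
    """Natural log of both series; pairs with a non-positive value are dropped."""
    kept: list[PairedMetric] = []
    dropped: list[str] = []
    for p in pairs:
        if p.x is None or p.y is None or p.x <= 0 or p.y <= 0:
            dropped.append(p.site_id)
            continue
        kept.append(
            PairedMetric(
                site_id=p.site_id,
                x=float(np.log(p.x)),
                y=float(np.log(p.y)),
                metric_name=p.metric_name,
            )
        )
    if dropped:
        warnings.warn(
            f"log-linearization dropped sites with non-positive values: {dropped}",
            stacklevel=2,
        )
    return kept


@dataclass(frozen=True)
class AgreementResult:
    identical: int
    genetic_higher: int
    genetic_lower: int
    per_site: pd.DataFrame  # site_id, morphological, genetic, delta

    @property
    def n_sites(self) -> int:
        return self.identical + self.genetic_higher + self.genetic_lower


def class_agreement(
    morph: Mapping[str, QualityClass | None],
    genetic: Mapping[str, QualityClass | None],
) -> AgreementResult:
    """Per-site quality-class comparison (delta in class steps, genetic - morph).

    Sites where either class is undefined are kept in the per-site table but
    excluded from the three counts.
    """
    if set(morph) != set(genetic):
        raise ValueError("unpaired sites")
    rows = []
    identical = higher = lower = 0
    for site in sorted(morph):
        m, g = morph[site], genetic[site]
        if m is None or g is None:
            rows.append(
                {"site_id": site, "morphological": _name(m), "genetic": _name(g), "delta": None}
            )
            continue
        delta = int(g) - int(m)
        if delta == 0:
            identical += 1
        elif delta > 0:
            higher += 1
        else:
            lower += 1
        rows.append(
            {"site_id": site, "morphological": m.name, "genetic": g.name, "delta": delta}
        )
    table = pd.DataFrame(rows, columns=["site_id", "morphological", "genetic", "delta"])
    return AgreementResult(
        identical=identical,
        genetic_higher=higher,
        genetic_lower=lower,
        per_site=table,
    )


def _name(cls: QualityClass | None) -> str:
    return cls.name if cls is not None else "undefined"
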