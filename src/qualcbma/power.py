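"""Noncentral-t power and the sample-size-based study-count adjustment.

Coordinate-based meta-analyses (CBMAs) pool peak coordinates from individual
neuroimaging experiments, so the number of *independent datasets* — not the
number of participants — is the primary driver of meta-analytic power.  A
common rule of thumb asks for at least 17 datasets (23 for structural MRI).
When a CBMA falls short, its evidence can still be contextualized by an
*adjusted* dataset count in which each study contributes

    count = min(power / 0.80, 1.25),

where ``power`` is the study's power to detect a one-sided very large effect
(Cohen's d = 1) at p = 0.001 in its own design, and studies contributing full
statistical maps (voxelwise t-values regardless of significance) count twice.
A one-sample study with 20 participants has ~80% power and counts as one
dataset; a study with 5 participants counts as 0.04; no study counts for more
than 1.25 datasets (2.5 with a map).

This module computes the exact noncentral-t power, per-study counts, the
adjusted dataset count of a study table, the published weight lookup table,
the dataset-count criterion itself, and the GRADE-style optimal information
size (OIS) arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "StudyRecord",
    "WeightResult",
    "AdjustedCount",
    "Criterion12Config",
    "Criterion12Result",
    "OisResult",
    "power_t",
    "study_count",
    "adjusted_dataset_count",
    "generate_weight_table",
    "evaluate_criterion12",
    "ois_total",
    "round_half_up",
]

ONE_SAMPLE = "one_sample"
TWO_SAMPLE = "two_sample"
_DESIGNS = (ONE_SAMPLE, TWO_SAMPLE)

MODALITIES = ("structural_mri", "other")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties away from zero (display only).

    The published weight table prints two decimals with half-up rounding;
    Python's built-in banker's rounding would disagree on ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PowerSpec:
    """Constants of the weighting convention.

    effect_size
        Cohen's d the power refers to. The convention fixes a "very large"
        effect, d = 1.
    alpha
        One-sided significance level of the hypothetical single-study test.
    target_power
        Reference power; a study at exactly this power counts as one dataset.
    cap
        Maximum per-study count before map doubling (1.25 = 1/0.80).
    map_factor
        Multiplier for studies providing statistical maps.
    """

    effect_size: float = 1.0
    alpha: float = 0.001
    target_power: float = 0.80
    cap: float = 1.25
    map_factor: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.target_power <= 1.0:
            raise ValueError(
                f"target_power must be in (0, 1], got {self.target_power}"
            )
        if self.cap <= 0.0:
            raise ValueError(f"cap must be positive, got {self.cap}")
        if self.map_factor < 1.0:
            raise ValueError(f"map_factor must be >= 1, got {self.map_factor}")


@dataclass(frozen=True)
class StudyRecord:
    """One dataset of a CBMA study table.

    ``n1`` is the total sample for one-sample designs and the first group for
    two-sample designs; ``n2`` is the second group and must be absent for
    one-sample records. ``has_map`` flags availability of the full statistical
    map.
    """

    id: str
    design: str
    n1: int
    n2: Optional[int] = None
    has_map: bool = False

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(
                f"study {self.id!r}: unknown design {self.design!r} "
                f"(expected one of {_DESIGNS})"
            )
        if int(self.n1) != self.n1 or self.n1 < 2:
            raise ValueError(
                f"study {self.id!r}: n1 must be an integer >= 2, got {self.n1}"
            )
        if self.design == ONE_SAMPLE:
            if self.n2 is not None:
                raise ValueError(
                    f"study {self.id!r}: one-sample records carry no n2"
                )
        else:
            if self.n2 is None:
                raise ValueError(f"study {self.id!r}: two-sample records need n2")
            if int(self.n2) != self.n2 or self.n2 < 2:
                raise ValueError(
                    f"study {self.id!r}: n2 must be an integer >= 2, got {self.n2}"
                )


@dataclass(frozen=True)
class WeightResult:
    """Per-study power and dataset count (full precision; round for display)."""

    power: float
    count: float
    capped: bool
    map_applied: bool

    @property
    def count_2dp(self) -> float:
        """The count at the table's printed precision (two decimals, half-up)."""
        return round_half_up(self.count, 2)


@dataclass(frozen=True)
class AdjustedCount:
    """Raw and sample-size-adjusted dataset counts of a study table."""

    raw: int
    adjusted: float
    per_study: tuple[WeightResult, ...]


@dataclass(frozen=True)
class Criterion12Config:
    """Thresholds for the dataset-count criterion.

    17 datasets is the default minimum; structural MRI may need 23 (advisory —
    the higher threshold is applied as a hard rule under
    ``modality='structural_mri'`` so the criterion stays binary). The adjusted
    count is contextual by default; set ``use_adjusted`` to gate on it.
    """

    threshold_default: int = 17
    threshold_structural: int = 23
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.threshold_default < 1 or self.threshold_structural < 1:
            raise ValueError("thresholds must be positive integers")
        if self.threshold_structural < self.threshold_default:
            raise ValueError(
                "structural-MRI threshold must be >= the default threshold"
            )


@dataclass(frozen=True)
class Criterion12Result:
    passed: bool
    threshold: int
    raw: int
    adjusted: float
    used_adjusted: bool = False


@dataclass(frozen=True)
class OisResult:
    """Optimal information size: total participants implied by k studies."""

    k: int
    per_study_n: int
    total: int


def _noncentral_t_power(
    df: np.ndarray | float, ncp: np.ndarray | float, alpha: float
) -> np.ndarray | float:
    """P(T' > t_{1-alpha, df}) for noncentral T' — vectorized core."""
    tcrit = stats.t.ppf(1.0 - alpha, df)
    ncp = np.asarray(ncp, dtype=float)
    # scipy's nct at ncp=0 is the central t up to quadrature noise; route
    # exact zeros through the central distribution so power(d=0) == alpha.
    if ncp.ndim == 0:
        if ncp == 0.0:
            return float(stats.t.sf(tcrit, df))
        return float(stats.nct.sf(tcrit, df, float(ncp)))
    out = np.asarray(stats.nct.sf(tcrit, df, ncp), dtype=float)
    zero = ncp == 0.0
    if np.any(zero):
        out[zero] = stats.t.sf(np.broadcast_to(tcrit, out.shape)[zero], df)
    return out


def power_t(
    design: str,
    n1: int,
    n2: Optional[int] = None,
    spec: PowerSpec | None = None,
) -> float:
    """Power of a one-sided t-test at the weighting convention's (d, alpha).

    One-sample: df = n1 - 1, ncp = d * sqrt(n1).
    Two-sample: df = n1 + n2 - 2, ncp = d * sqrt(n1 * n2 / (n1 + n2)); the
    published table is the equal-groups special case.
    """
    spec = spec or PowerSpec()
    rec = StudyRecord(id="<power_t>", design=design, n1=n1, n2=n2)
    if rec.design == ONE_SAMPLE:
        df = rec.n1 - 1
        ncp = spec.effect_size * np.sqrt(rec.n1)
    else:
        df = rec.n1 + rec.n2 - 2
        ncp = spec.effect_size * np.sqrt(rec.n1 * rec.n2 / (rec.n1 + rec.n2))
    return float(_noncentral_t_power(df, ncp, spec.alpha))


def study_count(record: StudyRecord, spec: PowerSpec | None = None) -> WeightResult:
    """Dataset count of one study: min(power / target, cap), doubled for maps.

    The cap applies to the power ratio *before* map doubling, so a map study's
    maximum is cap * map_factor (2.5 under the defaults).
    """
    spec = spec or PowerSpec()
    power = power_t(record.design, record.n1, record.n2, spec)
    ratio = power / spec.target_power
    capped = ratio > spec.cap
    count = min(ratio, spec.cap)
    if record.has_map:
        count *= spec.map_factor
    return WeightResult(
        power=power, count=count, capped=capped, map_applied=record.has_map
    )


def adjusted_dataset_count(
    records: Iterable[StudyRecord], spec: PowerSpec | None = None
) -> AdjustedCount:
    """Raw and adjusted dataset counts of a study table (order-invariant).

    The adjusted count sums full-precision per-study counts; round only for
    display.
    """
    spec = spec or PowerSpec()
    per_study = tuple(study_count(r, spec) for r in records)
    return AdjustedCount(
        raw=len(per_study),
        adjusted=float(sum(w.count for w in per_study)),
        per_study=per_study,
    )


def generate_weight_table(
    design: str,
    n_range: Sequence[int] | None = None,
    spec: PowerSpec | None = None,
) -> pd.DataFrame:
    """The per-study weight lookup table for a design.

    Returns a DataFrame with columns ``n`` (sample size, per group for
    two-sample), ``power``, ``count`` (full precision) and ``count_2dp`` (the
    printed two-decimal value). Defaults to the published ranges, 5-38
    (one-sample) and 5-69 (two-sample), where the count plateaus at 1.25.
    """
    spec = spec or PowerSpec()
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r} (expected one of {_DESIGNS})")
    if n_range is None:
        n_range = range(5, 39) if design == ONE_SAMPLE else range(5, 70)
    n = np.asarray(list(n_range), dtype=int)
    if len(n) == 0:
        raise ValueError("n_range is empty")
    if n.min() < 2:
        raise ValueError("sample sizes below 2 have nonpositive degrees of freedom")
    if design == ONE_SAMPLE:
        df = n - 1
        ncp = spec.effect_size * np.sqrt(n)
    else:
        df = 2 * n - 2
        ncp = spec.effect_size * np.sqrt(n / 2.0)
    power = np.asarray(_noncentral_t_power(df, ncp, spec.alpha))
    count = np.minimum(power / spec.target_power, spec.cap)
    return pd.DataFrame(
        {
            "n": n,
            "power": power,
            "count": count,
            "count_2dp": [round_half_up(c, 2) for c in count],
        }
    )


def evaluate_criterion12(
    records: Sequence[StudyRecord],
    modality: str,
    config: Criterion12Config | None = None,
    spec: PowerSpec | None = None,
) -> Criterion12Result:
    """The dataset-count criterion: >= 17 datasets (23 for structural MRI).

    Gates on the unadjusted count unless ``config.use_adjusted``; the adjusted
    count is always reported as context.
    """
    config = config or Criterion12Config()
    if modality not in MODALITIES:
        raise ValueError(
            f"unknown modality {modality!r} (expected one of {MODALITIES})"
        )
    threshold = (
        config.threshold_structural
        if modality == "structural_mri"
        else config.threshold_default
    )
    counts = adjusted_dataset_count(records, spec)
    effective = counts.adjusted if config.use_adjusted else counts.raw
    return Criterion12Result(
        passed=effective >= threshold,
        threshold=threshold,
        raw=counts.raw,
        adjusted=counts.adjusted,
        used_adjusted=config.use_adjusted,
    )


def ois_total(k: int, per_study_n: int) -> OisResult:
    """Optimal information size: a meta-analysis of k studies of n participants
    each carries k*n participants (per group for two-sample designs), to be
    compared with the sample size of one adequately powered study."""
    if k < 0 or per_study_n < 0:
        raise ValueError("k and per_study_n must be nonnegative")
    return OisResult(k=int(k), per_study_n=int(per_study_n), total=int(k) * int(per_study_n))
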