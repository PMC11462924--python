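"""Cross-platform / dose-group summary statistics.

These are the comparison statistics of a multi-platform duplex-sequencing
study: per-platform means of vehicle-control frequencies, cross-platform
mean-of-means and coefficient of variation (sample SD over the per-platform
means), Max−Min ranges, fold changes of dose groups against the
platform-matched vehicle mean, and the two-sample Student t-test.

Values may be ``decimal.Decimal``: means then stay exact, which matters
when reproducing published tables whose 2-decimal means land on exact .5
rounding boundaries. The reporting convention is round half to even.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .calling import FrequencyTable
from .spectra import Spectrum96
from .substitutions import CLASSES

__all__ = [
    "SampleRecord",
    "GroupStats",
    "summarize_groups",
    "range_stat",
    "fold_change",
    "t_test_platforms",
    "round_half_even",
    "mean_value",
    "cv",
]

VEHICLE = "vehicle"


def round_half_even(x, ndigits: int = 2) -> Decimal:
    """Banker's rounding at ``ndigits`` decimals.

    Exact for ``Decimal`` input; floats go through ``str`` first, so values
    sitting within float error of a .5 boundary should be supplied as
    ``Decimal`` when the printed digit matters.
    """
    d = x if isinstance(x, Decimal) else Decimal(str(x))
    return d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_EVEN)


def mean_value(values: Sequence):
    """Arithmetic mean; stays ``Decimal`` when every input is Decimal."""
    values = list(values)
    if not values:
        raise ValueError("mean of no values")
    if all(isinstance(v, Decimal) for v in values):
        return sum(values, Decimal(0)) / len(values)
    return float(np.mean([float(v) for v in values]))


def sample_sd(values: Sequence) -> float:
    """Sample (n−1) standard deviation."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("sample SD needs >= 2 values")
    return float(np.std(vals, ddof=1))


def cv(values: Sequence) -> float:
    """Coefficient of variation: sample SD / mean (mean must be nonzero)."""
    m = float(mean_value(values))
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return sample_sd(values) / m


def range_stat(values: Sequence) -> float:
    """Max − Min over the supplied values."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("range needs >= 2 values")
    return max(vals) - min(vals)


def fold_change(dose_value, vehicle_values: Sequence) -> float:
    """Dose-group frequency over the mean of its platform's vehicle values."""
    m = float(mean_value(vehicle_values))
    if m <= 0:
        raise ValueError("vehicle-control mean must be positive")
    return float(dose_value) / m


def t_test_platforms(
    group_a: Sequence, group_b: Sequence
) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance), two-sided.

    Raises on degenerate input where the pooled variance is zero and the
    means differ (the statistic would be infinite).
    """
    a = [float(v) for v in group_a]
    b = [float(v) for v in group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with differing means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class SampleRecord:
    """One (sample, platform) observation of a frequency table.

    ``dose`` is ``"vehicle"`` or a numeric dose label; ``frequencies`` maps
    the six classes plus ``"OM"`` to per-1e6-bp values (float or Decimal).
    """

    sample_id: str
    platform: str
    dose: str
    frequencies: Mapping[str, object]
    spectrum: Spectrum96 | None = None

    @classmethod
    def from_frequency_table(
        cls,
        sample_id: str,
        platform: str,
        dose: str,
        table: FrequencyTable,
        spectrum: Spectrum96 | None = None,
    ) -> "SampleRecord":
        freqs: dict[str, object] = dict(table.frequencies)
        freqs["OM"] = table.om_frequency
        return cls(sample_id, platform, dose, freqs, spectrum)

    def value(self, cls_name: str):
        return self.frequencies[cls_name]

    @property
    def is_vehicle(self) -> bool:
        return str(self.dose) == VEHICLE


@dataclass
class GroupStats:
    """Per-platform and cross-platform summaries for one class."""

    cls: str
    platform_means: dict[str, object]
    platform_sds: dict[str, float | None]
    platform_cvs: dict[str, float | None]
    grand_mean: object  # mean of the per-platform means
    grand_sd: float | None
    grand_cv: float | None  # missing when the grand mean is 0
    value_range: float | None  # Max − Min over all pooled values
    n_platforms: int = field(default=0)


def summarize_groups(
    records: Sequence[SampleRecord],
    cls_name: str,
    dose: str = VEHICLE,
) -> GroupStats:
    """Summarise one substitution class (or "OM") across platforms.

    Per-platform means are taken over the samples of the requested dose
    group; cross-platform mean, sample SD and CV are then computed over
    those per-platform means (n = number of platforms), matching the
    convention of multi-platform background-error comparisons.
    """
    if cls_name != "OM" and cls_name not in CLASSES:
        raise ValueError(f"unknown class {cls_name!r}")
    by_platform: dict[str, list] = {}
    for rec in records:
        if str(rec.dose) == str(dose):
            by_platform.setdefault(rec.platform, []).append(
                rec.value(cls_name)
            )
    if not by_platform:
        raise ValueError(f"no records for dose {dose!r}")

    means = {p: mean_value(v) for p, v in by_platform.items()}
    sds = {
        p: (sample_sd(v) if len(v) >= 2 else None)
        for p, v in by_platform.items()
    }
    cvs = {}
    for p, v in by_platform.items():
        if len(v) >= 2 and float(mean_value(v)) != 0:
            cvs[p] = cv(v)
        else:
            cvs[p] = None

    mean_list = list(means.values())
    grand_mean = mean_value(mean_list)
    grand_sd = sample_sd(mean_list) if len(mean_list) >= 2 else None
    grand_cv = (
        cv(mean_list)
        if len(mean_list) >= 2 and float(grand_mean) != 0
        else None
    )
    pooled = [v for vals in by_platform.values() for v in vals]
    value_range = range_stat(pooled) if len(pooled) >= 2 else None
    return GroupStats(
        cls=cls_name,
        platform_means=means,
        platform_sds=sds,
        platform_cvs=cvs,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        grand_cv=grand_cv,
        value_range=value_range,
        n_platforms=len(by_platform),
    )
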