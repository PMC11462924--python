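"""Published benchmark values from a four-platform duplex-sequencing study.

A public comparison of four sequencing platforms (HiSeq2500, NovaSeq6000,
NextSeq2000, DNBSEQ-G400) ran the same duplex-consensus protocol on mouse
bone-marrow DNA from animals given vehicle (olive oil) or 150 / 300
mg/kg/day benzo[a]pyrene. Its printed per-sample mutation frequencies are
the worked-example inputs for the cohort statistics here: platform-mean
overall mutation (OM) frequencies, the cross-platform G:C→T:A mean and CV,
the Max−Min range of the control G:C→T:A values, and dose-group fold
changes against the platform-matched vehicle means.

Values are stored as ``Decimal`` strings so derived means are exact — the
published 2-decimal means sit on exact .5 rounding boundaries that binary
floats would misround under the round-half-to-even convention.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Mapping

import pandas as pd

from .cohort import SampleRecord, fold_change, mean_value, round_half_even

__all__ = [
    "PLATFORMS",
    "DOSES",
    "OM_BY_SAMPLE",
    "GC_TA",
    "sample_records",
    "vehicle_om_means",
    "gc_ta_platform_vehicle_means",
    "gc_ta_cross_platform_mean_cv",
    "control_gc_ta_range",
    "fold_change_table",
    "min_fold_change",
]

PLATFORMS = ("HiSeq2500", "NovaSeq6000", "NextSeq2000", "DNBSEQ-G400")
DOSES = ("vehicle", "150", "300")

_D = Decimal

#: Overall mutation frequency (×1e-6 bp) per sample and platform.
#: Samples 1001/1002 are vehicle controls; 1201 = 150, 1301 = 300 mg/kg/day.
OM_BY_SAMPLE: Mapping[str, dict[str, Decimal]] = {
    "1001": dict(zip(PLATFORMS, map(_D, ("0.22", "0.32", "0.43", "0.32")))),
    "1002": dict(zip(PLATFORMS, map(_D, ("0.23", "0.40", "0.50", "0.21")))),
    "1201": dict(zip(PLATFORMS, map(_D, ("0.75", "0.85", "0.95", "0.81")))),
    "1301": dict(zip(PLATFORMS, map(_D, ("1.24", "1.32", "1.46", "1.38")))),
}

SAMPLE_DOSE = {"1001": "vehicle", "1002": "vehicle", "1201": "150", "1301": "300"}

#: G:C→T:A frequency (×1e-6 G:C bp) per dose group and platform.
GC_TA: Mapping[str, dict[str, tuple[Decimal, ...]]] = {
    "vehicle": {
        "HiSeq2500": (_D("0.124"), _D("0.137")),
        "NovaSeq6000": (_D("0.173"), _D("0.248")),
        "NextSeq2000": (_D("0.163"), _D("0.206")),
        "DNBSEQ-G400": (_D("0.144"), _D("0.085")),
    },
    "150": {
        "HiSeq2500": (_D("0.73"),),
        "NovaSeq6000": (_D("0.92"),),
        "NextSeq2000": (_D("0.88"),),
        "DNBSEQ-G400": (_D("0.86"),),
    },
    "300": {
        "HiSeq2500": (_D("1.69"),),
        "NovaSeq6000": (_D("1.72"),),
        "NextSeq2000": (_D("1.61"),),
        "DNBSEQ-G400": (_D("1.97"),),
    },
}


def sample_records() -> list[SampleRecord]:
    """The OM table as SampleRecord objects for the cohort API."""
    return [
        SampleRecord(
            sample_id=sid,
            platform=platform,
            dose=SAMPLE_DOSE[sid],
            frequencies={"OM": value},
        )
        for sid, row in OM_BY_SAMPLE.items()
        for platform, value in row.items()
    ]


def vehicle_om_means(ndigits: int = 2) -> dict[str, Decimal]:
    """Per-platform mean OM frequency of the two vehicle controls, rounded."""
    return {
        platform: round_half_even(
            mean_value(
                [OM_BY_SAMPLE["1001"][platform], OM_BY_SAMPLE["1002"][platform]]
            ),
            ndigits,
        )
        for platform in PLATFORMS
    }


def gc_ta_platform_vehicle_means() -> dict[str, Decimal]:
    """Exact per-platform means of the vehicle-control G:C→T:A values."""
    return {
        platform: mean_value(GC_TA["vehicle"][platform])
        for platform in PLATFORMS
    }


def gc_ta_cross_platform_mean_cv(
    ndigits: int = 2,
) -> tuple[Decimal, Decimal]:
    """Cross-platform G:C→T:A mean and CV over the four platform means.

    The CV uses the sample (n−1) standard deviation over n = 4 platform
    means — the convention that reproduces the published figures.
    """
    from .cohort import cv  # local import to keep module load cheap

    means = list(gc_ta_platform_vehicle_means().values())
    return (
        round_half_even(mean_value(means), ndigits),
        round_half_even(cv(means), ndigits),
    )


def control_gc_ta_range() -> Decimal:
    """Max − Min over the eight control G:C→T:A values (exact Decimal)."""
    values = [v for vals in GC_TA["vehicle"].values() for v in vals]
    return max(values) - min(values)


def fold_change_table() -> pd.DataFrame:
    """G:C→T:A fold change of each dose group vs its platform vehicle mean."""
    rows = []
    for platform in PLATFORMS:
        vehicle = GC_TA["vehicle"][platform]
        for dose in ("150", "300"):
            (value,) = GC_TA[dose][platform]
            rows.append(
                {
                    "platform": platform,
                    "dose_mg_kg": int(dose),
                    "frequency_per_1e6": float(value),
                    "vehicle_mean": float(mean_value(vehicle)),
                    "fold_change": fold_change(value, vehicle),
                }
            )
    return pd.DataFrame(rows)


def min_fold_change() -> float:
    """Smallest fold change across all platforms and doses."""
    return float(fold_change_table()["fold_change"].min())
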