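"""Herbicide intensity as the treatment frequency index (TFI).

One full registered dose of one product counts as 1.0; the TFI of a
field x treatment x cropping year is the sum of applied/registered
dose ratios over all its herbicide applications.  Tank-mix partners
are separate records (each product contributes its own ratio), and
follow-up treatments within the same cropping year simply add.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class ApplicationRecord:
    """One herbicide application on one field x treatment plot."""

    field: str
    treatment: str
    product: str
    applied_dose: float
    registered_dose: float
    season: str = "autumn"

    def __post_init__(self) -> None:
        if not self.applied_dose > 0:
            raise ValueError(
                f"applied dose must be positive for product {self.product!r} "
                f"(field {self.field!r}, treatment {self.treatment!r}): {self.applied_dose}"
            )
        if not self.registered_dose > 0:
            raise ValueError(
                f"registered dose must be positive for product {self.product!r} "
                f"(field {self.field!r}, treatment {self.treatment!r}): {self.registered_dose}"
            )
        if self.applied_dose > self.registered_dose:
            # authorized use should not exceed the registered dose; tolerate
            # but flag, since it may indicate a unit error in the input
            warnings.warn(
                f"applied dose exceeds registered dose for product {self.product!r} "
                f"(field {self.field!r}, treatment {self.treatment!r})",
                stacklevel=3,
            )

    @property
    def dose_ratio(self) -> float:
        return self.applied_dose / self.registered_dose


def compute_tfi(records: Iterable[ApplicationRecord]) -> float:
    """TFI of one field x treatment x cropping year.

    The empty record list (untreated control) gives 0.0.
    """
    return float(sum(r.dose_ratio for r in records))


def relative_biomass(treated_mean: float, untreated_mean: float,
                     report: bool = False) -> float:
    """Treated biomass as percent of the untreated control.

    With ``report=True`` the percentage is rounded half-away-from-zero
    to a whole number, the convention used in summary tables.
    """
    if not untreated_mean > 0:
        raise ValueError(f"untreated mean must be positive, got {untreated_mean}")
    if treated_mean < 0:
        raise ValueError(f"treated mean must be nonnegative, got {treated_mean}")
    pct = 100.0 * treated_mean / untreated_mean
    if report:
        return float(math.floor(pct + 0.5))
    return pct


# ---------------------------------------------------------------------------
# tabular interface

_APP_COLUMNS = ("field", "treatment", "product", "applied_dose", "registered_dose")


def records_from_table(df: pd.DataFrame) -> list[ApplicationRecord]:
    """Build validated records from an applications table."""
    missing = [c for c in _APP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"applications table lacks columns {missing}")
    season = df["season"] if "season" in df.columns else ["autumn"] * len(df)
    return [
        ApplicationRecord(str(f), str(t), str(p), float(a), float(r), str(s))
        for f, t, p, a, r, s in zip(df["field"], df["treatment"], df["product"],
                                    df["applied_dose"], df["registered_dose"], season)
    ]


def tfi_table(df: pd.DataFrame, fields: Sequence[str] | None = None,
              treatments: Sequence[str] | None = None) -> pd.DataFrame:
    """Per field x treatment TFI from a long applications table.

    ``fields``/``treatments`` may list the full design so that
    combinations without any application (untreated controls) appear
    with TFI 0.
    """
    records = records_from_table(df)
    totals: dict[tuple[str, str], float] = {}
    if fields is not None and treatments is not None:
        for f in fields:
            for t in treatments:
                totals[(str(f), str(t))] = 0.0
    for r in records:
        totals[(r.field, r.treatment)] = totals.get((r.field, r.treatment), 0.0) + r.dose_ratio
    out = pd.DataFrame(
        [(f, t, v) for (f, t), v in totals.items()],
        columns=["field", "treatment", "tfi"],
    )
    return out.sort_values(["field", "treatment"], ignore_index=True)


def treatment_means(tfi: pd.DataFrame) -> pd.Series:
    """Mean TFI per treatment over fields."""
    return tfi.groupby("treatment")["tfi"].mean()
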