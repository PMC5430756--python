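"""Absolute substitution-rate scaling from per-branch dS/dN and branch ages.

Per-branch synonymous (dS) and non-synonymous (dN) substitution estimates
(e.g. from a codon-model program) are combined with per-branch absolute ages
(e.g. from a fossil-calibrated chronogram) to yield a clade-wide absolute
silent substitution rate and a global dN/dS ratio:

    rate  = sum(dS_branch) / sum(age_branch)     [substitutions/site/year]
    dN/dS = sum(dN_branch) / sum(dS_branch)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BranchRates", "UndefinedRatioError", "absolute_rate", "read_rates_tsv"]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when sum(dS) == 0 but sum(dN) > 0."""


@dataclass(frozen=True)
class BranchRates:
    """Per-branch dS, dN (substitutions/site) and age (years)."""

    branch_ids: tuple[str, ...]
    ds: np.ndarray
    dn: np.ndarray
    age_years: np.ndarray

    def __post_init__(self):
        ds = np.asarray(self.ds, dtype=float)
        dn = np.asarray(self.dn, dtype=float)
        age = np.asarray(self.age_years, dtype=float)
        n = len(self.branch_ids)
        if not (ds.shape == dn.shape == age.shape == (n,)):
            raise ValueError("branch_ids, ds, dn and age_years must align")
        if n < 1:
            raise ValueError("at least one branch is required")
        if np.any(ds < 0) or np.any(dn < 0):
            raise ValueError("dS and dN must be non-negative")
        if np.any(age <= 0):
            raise ValueError("branch ages must be positive")
        object.__setattr__(self, "ds", ds)
        object.__setattr__(self, "dn", dn)
        object.__setattr__(self, "age_years", age)


def absolute_rate(rates: BranchRates) -> tuple[float, float]:
    """Global absolute dS rate (per year) and global dN/dS over all branches."""
    total_ds = float(rates.ds.sum())
    total_dn = float(rates.dn.sum())
    rate = total_ds / float(rates.age_years.sum())
    if total_ds == 0.0:
        if total_dn > 0.0:
            raise UndefinedRatioError("sum(dS)=0 with sum(dN)>0: dN/dS undefined")
        return rate, 0.0
    return rate, total_dn / total_ds


def read_rates_tsv(path) -> BranchRates:
    """Read a TSV with columns ``branch_id ds dn age_years``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("branch_id", "ds", "dn", "age_years"):
        if col not in df.columns:
            raise ValueError(f"rates table missing column {col!r}")
    return BranchRates(
        branch_ids=tuple(str(b) for b in df["branch_id"]),
        ds=df["ds"].to_numpy(float),
        dn=df["dn"].to_numpy(float),
        age_years=df["age_years"].to_numpy(float),
    )
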