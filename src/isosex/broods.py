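"""Brood filtering and chi-square classification of heterogametic systems.

Implements the decision procedure used to call a species' sex-determination
system from F1 sex ratios of neomale x sister crosses:

1. discard broods whose mother is *Wolbachia*-infected (feminization mimics
   the ZW signal);
2. discard broods whose sex ratio is not significantly different from 1:1
   (these crosses likely involved a mis-selected genetic male, not a
   neomale);
3. check sex-ratio homogeneity across the remaining broods, pool counts, and
   test the pooled ratio against 1:1, 1/3 male (ZW with inviable WW) and
   1/4 male (ZW with viable WW); zero-male broods are tested against the
   strict XY expectation with an exact binomial test, since the chi-square
   statistic is undefined at an expected proportion of zero.

All chi-square tests are Pearson goodness-of-fit / independence tests
without continuity correction; significance level defaults to 0.05.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BroodRecord",
    "FilterReport",
    "SpeciesCall",
    "NoDataError",
    "DegenerateExpectationError",
    "DegenerateTableError",
    "chisq_gof",
    "exact_zero_male_test",
    "filter_broods",
    "heterogeneity_test",
    "classify_species",
    "viability_power",
    "read_broods_tsv",
    "write_broods_tsv",
    "call_species_table",
    "calls_to_frame",
]

WolbachiaStatus = Literal["positive", "negative", "untested"]


class NoDataError(ValueError):
    """Raised when a species has no broods left to classify."""


class DegenerateExpectationError(ValueError):
    """Raised when the expected male proportion is 0 or 1 (chi-square undefined)."""


class DegenerateTableError(ValueError):
    """Raised when a heterogeneity table has a sex with zero total count."""


@dataclass(frozen=True)
class BroodRecord:
    """Sex counts of one F1 progeny plus the metadata used by the filters."""

    species: str
    brood_id: str
    n_male: int
    n_female: int
    mother_wolbachia: str = "untested"

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("sex counts must be non-negative")
        if self.n_male + self.n_female < 1:
            raise ValueError("a brood must contain at least one offspring")
        if self.mother_wolbachia not in ("positive", "negative", "untested"):
            raise ValueError(
                f"mother_wolbachia must be positive/negative/untested, "
                f"got {self.mother_wolbachia!r}"
            )

    @property
    def total(self) -> int:
        return self.n_male + self.n_female


@dataclass
class FilterReport:
    """Partition of the input broods into kept and discarded (with reasons)."""

    kept: list[BroodRecord]
    discarded: list[tuple[BroodRecord, str]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.discarded)

    def discard_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.discarded:
            out[reason] = out.get(reason, 0) + 1
        return out


@dataclass
class SpeciesCall:
    """Classification verdict for one species.

    ``system`` is one of ZW / XY / UNDETERMINED. ``ww_viability`` is only
    meaningful for ZW calls (viable / inviable / indeterminate); XY and
    UNDETERMINED calls carry ``not_applicable``. ``flags`` records decision
    anomalies (heterogeneous, male_excess, trimmed broods, low power, ...).
    """

    species: str
    n_broods: int
    pooled_m: int
    pooled_f: int
    p_balanced: float | None
    p_onethird: float | None
    p_onequarter: float | None
    p_xy: float | None
    heterogeneity_p: float | None
    system: str
    ww_viability: str
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "species", "n_broods", "pooled_m", "pooled_f", "p_balanced",
            "p_onethird", "p_onequarter", "p_xy", "heterogeneity_p",
            "system", "ww_viability")}
        d["flags"] = list(self.flags)
        return d


def chisq_gof(
    n_male: int,
    n_female: int,
    expected_male_prop: float,
    *,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson goodness-of-fit test of observed sex counts vs an expected ratio.

    One degree of freedom, no continuity correction by default (set
    ``correction=True`` for Yates). Returns ``(statistic, p)`` with the
    p-value from the upper tail of the chi-square distribution.
    """
    total = n_male + n_female
    if total <= 0:
        raise ValueError("at least one offspring is required")
    if not 0.0 < expected_male_prop < 1.0:
        raise DegenerateExpectationError(
            "expected male proportion must be strictly inside (0, 1); "
            "use exact_zero_male_test for the strict XY expectation"
        )
    observed = np.array([n_male, n_female], dtype=float)
    expected = np.array(
        [total * expected_male_prop, total * (1.0 - expected_male_prop)]
    )
    dev = np.abs(observed - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def exact_zero_male_test(
    n_male: int, n_female: int, male_leak_rate: float = 0.0
) -> float:
    """Exact binomial upper-tail test of the strict XY expectation.

    Under male heterogamety an XX neomale x XX female cross yields 100%
    females, so the expected male count is zero and the chi-square test is
    undefined. This test returns P(>= n_male males | Binomial(n, leak)),
    where ``male_leak_rate`` allows a small tolerated rate of stray males
    (default 0: any male falsifies strict XY, p = 0; no males, p = 1).
    """
    if not 0.0 <= male_leak_rate < 1.0:
        raise ValueError("male_leak_rate must be in [0, 1)")
    n = n_male + n_female
    if n <= 0:
        raise ValueError("at least one offspring is required")
    if male_leak_rate == 0.0:
        return 1.0 if n_male == 0 else 0.0
    return float(stats.binom.sf(n_male - 1, n, male_leak_rate))


def filter_broods(
    broods: Sequence[BroodRecord],
    alpha: float = 0.05,
    *,
    untested_policy: Literal["negative", "discard"] = "negative",
) -> FilterReport:
    """Apply the two-step brood filter: Wolbachia first, then the 1:1 test.

    Step 1 discards broods with a *Wolbachia*-positive mother (reason
    ``wolbachia``). Step 2 discards broods whose sex ratio does not differ
    significantly from 1:1 at ``alpha`` (reason ``balanced_sex_ratio``) —
    those crosses likely involved a genetic male instead of a neomale.
    Mothers of untested status are treated as negative by default
    (``untested_policy="discard"`` removes them instead); a warning is
    emitted either way.
    """
    if not broods:
        raise NoDataError("no broods to filter")
    kept: list[BroodRecord] = []
    discarded: list[tuple[BroodRecord, str]] = []
    n_untested = sum(1 for b in broods if b.mother_wolbachia == "untested")
    if n_untested:
        warnings.warn(
            f"{n_untested} brood(s) with untested Wolbachia status treated as "
            f"{'negative' if untested_policy == 'negative' else 'infected'}",
            stacklevel=2,
        )
    for b in broods:
        if b.mother_wolbachia == "positive" or (
            b.mother_wolbachia == "untested" and untested_policy == "discard"
        ):
            discarded.append((b, "wolbachia"))
            continue
        _, p = chisq_gof(b.n_male, b.n_female, 0.5)
        if p >= alpha:
            discarded.append((b, "balanced_sex_ratio"))
        else:
            kept.append(b)
    return FilterReport(kept=kept, discarded=discarded)


def _heterogeneity_table(broods: Sequence[BroodRecord]) -> np.ndarray:
    return np.array([[b.n_male, b.n_female] for b in broods], dtype=float)


def heterogeneity_test(broods: Sequence[BroodRecord]) -> float:
    """Chi-square test of sex-ratio homogeneity across broods.

    Pearson independence test on the broods x sex contingency table,
    df = (#broods - 1). A sex with zero total across all broods makes the
    table degenerate and raises :class:`DegenerateTableError`.
    """
    if len(broods) < 2:
        raise ValueError("heterogeneity requires at least two broods")
    table = _heterogeneity_table(broods)
    if np.any(table.sum(axis=0) == 0):
        raise DegenerateTableError(
            "one sex has zero total across all broods; homogeneity is trivial"
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _heterogeneity_contributions(broods: Sequence[BroodRecord]) -> np.ndarray:
    """Per-brood Pearson contribution to the homogeneity statistic."""
    table = _heterogeneity_table(broods)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return cells.sum(axis=1)


def classify_species(
    broods: Sequence[BroodRecord],
    alpha: float = 0.05,
    male_leak_rate: float = 0.0,
    *,
    heterogeneity_policy: Literal["trim", "block", "pool"] = "trim",
    max_trim_frac: float = 0.25,
) -> SpeciesCall:
    """Classify a species' heterogametic system from (already filtered) broods.

    Homogeneity across broods is checked before pooling. Under the default
    ``heterogeneity_policy="trim"``, broods with the largest contribution to
    a significant homogeneity statistic are dropped one at a time (at most
    ``max_trim_frac`` of the broods, never below two) — this recovers
    species whose brood set retains a stray genetic-male-sired brood that
    slipped past the 1:1 filter. ``"block"`` refuses to pool a heterogeneous
    set (system UNDETERMINED); ``"pool"`` pools regardless, with a flag.

    Pooled counts are then tested against 1:1 (``p_balanced``), 1/3 male
    (``p_onethird``), 1/4 male (``p_onequarter``) and the strict XY
    expectation (``p_xy``, exact binomial with ``male_leak_rate``):

    * significant male excess -> UNDETERMINED (outside all predictions);
    * XY compatible and both ZW ratios rejected -> XY;
    * zero males but ZW not excluded -> XY with a low-power flag;
    * otherwise ZW, with WW viability read off which ZW ratio survives:
      1/4 only -> viable, 1/3 only -> inviable, both -> indeterminate,
      neither (with XY also rejected) -> system UNDETERMINED.
    """
    if not broods:
        raise NoDataError("no broods to classify")
    species = broods[0].species
    if any(b.species != species for b in broods):
        raise ValueError("classify_species expects broods from a single species")

    work = list(broods)
    flags: list[str] = []
    het_p: float | None = None

    if len(work) >= 2:
        def _het(bs):
            try:
                return heterogeneity_test(bs)
            except DegenerateTableError:
                return 1.0  # all broods single-sex in the same direction
        het_p = _het(work)
        if het_p < alpha and heterogeneity_policy == "trim":
            max_trims = max(1, math.floor(len(work) * max_trim_frac))
            while het_p < alpha and max_trims > 0 and len(work) > 2:
                drop = int(np.argmax(_heterogeneity_contributions(work)))
                flags.append(f"trimmed:{work[drop].brood_id}")
                del work[drop]
                max_trims -= 1
                het_p = _het(work)
        if het_p < alpha and heterogeneity_policy in ("trim", "block"):
            flags.append("heterogeneous")
            m = sum(b.n_male for b in work)
            f = sum(b.n_female for b in work)
            return SpeciesCall(
                species=species, n_broods=len(work), pooled_m=m, pooled_f=f,
                p_balanced=None, p_onethird=None, p_onequarter=None, p_xy=None,
                heterogeneity_p=het_p, system="UNDETERMINED",
                ww_viability="not_applicable", flags=tuple(flags),
            )
        if het_p < alpha:  # policy == "pool"
            flags.append("heterogeneous_pooled")

    m = sum(b.n_male for b in work)
    f = sum(b.n_female for b in work)
    total = m + f
    _, p_bal = chisq_gof(m, f, 0.5)
    _, p_13 = chisq_gof(m, f, 1.0 / 3.0)
    _, p_14 = chisq_gof(m, f, 0.25)
    p_xy = exact_zero_male_test(m, f, male_leak_rate)

    system = "UNDETERMINED"
    viability = "not_applicable"
    if m / total > 0.5 and p_bal < alpha:
        # Male excess: outside every prediction (the A. assimile pattern).
        flags.append("male_excess")
    elif p_xy >= alpha and p_13 < alpha and p_14 < alpha:
        system = "XY"
    elif p_xy >= alpha and m == 0:
        # All-female but too few offspring to reject the ZW ratios.
        system = "XY"
        flags.append("low_power")
    else:
        if p_xy >= alpha:
            flags.append("xy_not_excluded")
        if p_13 < alpha <= p_14:
            system, viability = "ZW", "viable"
        elif p_14 < alpha <= p_13:
            system, viability = "ZW", "inviable"
        elif p_13 >= alpha and p_14 >= alpha:
            system, viability = "ZW", "indeterminate"
        else:
            flags.append("all_hypotheses_rejected")

    return SpeciesCall(
        species=species, n_broods=len(work), pooled_m=m, pooled_f=f,
        p_balanced=p_bal, p_onethird=p_13, p_onequarter=p_14, p_xy=p_xy,
        heterogeneity_p=het_p, system=system, ww_viability=viability,
        flags=tuple(flags),
    )


def viability_power(
    brood_total: int,
    true_male_prop: float,
    null_male_prop: float,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the pooled chi-square test at a given brood total.

    Draws ``n_sim`` binomial broods of size ``brood_total`` with male
    proportion ``true_male_prop`` and returns the fraction in which the
    goodness-of-fit test against ``null_male_prop`` rejects at ``alpha``.
    Motivated by the observation that ~30 offspring cannot separate the
    1/4 and 1/3 male ratios. Reproducible given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not (0.0 < true_male_prop < 1.0 and 0.0 < null_male_prop < 1.0):
        raise ValueError("proportions must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    males = rng.binomial(brood_total, true_male_prop, size=n_sim).astype(float)
    e_m = brood_total * null_male_prop
    e_f = brood_total * (1.0 - null_male_prop)
    stat = (males - e_m) ** 2 / e_m + ((brood_total - males) - e_f) ** 2 / e_f
    p = stats.chi2.sf(stat, df=1)
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# Tabular I/O and whole-table classification
# ---------------------------------------------------------------------------

_BROOD_COLUMNS = ["species", "brood_id", "n_male", "n_female", "mother_wolbachia"]


def read_broods_tsv(path) -> list[BroodRecord]:
    """Read a brood table (TSV with header species/brood_id/n_male/n_female/mother_wolbachia)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "brood_id": str})
    missing = [c for c in _BROOD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"brood table missing columns: {missing}")
    return [
        BroodRecord(
            species=row.species,
            brood_id=str(row.brood_id),
            n_male=int(row.n_male),
            n_female=int(row.n_female),
            mother_wolbachia=str(row.mother_wolbachia),
        )
        for row in df.itertuples()
    ]


def write_broods_tsv(broods: Iterable[BroodRecord], path) -> None:
    pd.DataFrame([b.__dict__ for b in broods], columns=_BROOD_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def call_species_table(
    broods: Sequence[BroodRecord],
    alpha: float = 0.05,
    male_leak_rate: float = 0.0,
    **classify_kwargs,
) -> tuple[dict[str, SpeciesCall], dict[str, FilterReport]]:
    """Filter and classify every species in a brood table.

    Returns ``(calls, filter_reports)`` keyed by species. Species whose
    broods are all discarded by the filters receive no call.
    """
    by_species: dict[str, list[BroodRecord]] = {}
    for b in broods:
        by_species.setdefault(b.species, []).append(b)
    calls: dict[str, SpeciesCall] = {}
    reports: dict[str, FilterReport] = {}
    for sp, bs in sorted(by_species.items()):
        report = filter_broods(bs, alpha)
        reports[sp] = report
        if report.kept:
            calls[sp] = classify_species(
                report.kept, alpha, male_leak_rate, **classify_kwargs
            )
    return calls, reports


def calls_to_frame(calls: dict[str, SpeciesCall]) -> pd.DataFrame:
    """Summarize species calls as a DataFrame (one row per species)."""
    rows = []
    for sp in sorted(calls):
        d = calls[sp].as_dict()
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def calls_to_json(
    calls: dict[str, SpeciesCall], reports: dict[str, FilterReport] | None = None
) -> str:
    """Full machine-readable report (counts, statistics, p-values, verdicts)."""
    payload: dict[str, dict] = {}
    for sp in sorted(set(calls) | set(reports or {})):
        entry: dict = {}
        if calls.get(sp):
            entry["call"] = calls[sp].as_dict()
        if reports and sp in reports:
            rep = reports[sp]
            entry["filter"] = {
                "n_input": rep.n_input,
                "n_kept": len(rep.kept),
                "discarded": [
                    {"brood_id": b.brood_id, "reason": r} for b, r in rep.discarded
                ],
            }
        payload[sp] = entry
    return json.dumps(payload, indent=2, sort_keys=True)
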