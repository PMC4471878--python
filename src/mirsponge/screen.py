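"""Screen scoring: viability hit-calling, flight scoring, benchmark concordance.

Viability is the percentage of eclosing experimental adults relative to
balancer-class siblings from the same cross, corrected for the
balancer's own contribution to lethality. Hits are called with a
stringent collection-wide cutoff: mean minus one sample standard
deviation of percent viability, inclusive.

Flight scoring drops flies past three concentric circles; landings in
the inner two circles are "non-fliers". A line is flight-impaired when
its mean non-flier fraction exceeds twice the sample s.d. of the
scramble control, confirmed by one-way ANOVA with a Tukey-Kramer
comparison against scramble.

The benchmark concordance classifier compares sponge viability calls
with independent null-mutant phenotypes, after excluding genes whose
null removes a multi-miRNA cluster, failed genetic validation, or was
never tested for lethality.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ScreenInputError

__all__ = [
    "ViabilityRecord",
    "FlightTrial",
    "BenchmarkEntry",
    "ConcordanceSummary",
    "FlightScreenResult",
    "IMPAIRED_PHENOTYPES",
    "CONCORDANCE_CATEGORIES",
    "correction_factor",
    "percent_viability",
    "classify_viability",
    "call_viability_hits",
    "nonflier_fraction",
    "flight_threshold",
    "call_flight_hits",
    "filter_comparable",
    "classify_concordance",
    "summarize_concordance",
]

#: Sponge phenotype classes counted as a viability impairment.
IMPAIRED_PHENOTYPES = frozenset({"lethal", "semilethal", "subviable"})
VIABILITY_CLASSES = ("lethal", "semilethal", "subviable", "viable")
CONCORDANCE_CATEGORIES = ("confirmed", "false_negative", "false_positive",
                          "family")
NULL_PHENOTYPES = frozenset({"impaired", "viable", "not_tested"})


@dataclass(frozen=True)
class ViabilityRecord:
    """Progeny counts for one sponge line in one cross batch.

    ``n_experimental`` counts eclosed driver/sponge adults,
    ``n_control`` their balancer-class siblings from the same cross.
    """

    line_id: str
    n_experimental: int
    n_control: int
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.n_experimental < 0 or self.n_control < 0:
            raise ScreenInputError(
                f"{self.line_id}: progeny counts must be >= 0")


@dataclass(frozen=True)
class FlightTrial:
    """One replicate drop of nominally 20 flies for one line."""

    line_id: str
    age_days: int
    replicate: str
    n_total: int
    n_inner: int
    n_middle: int
    n_outer: int
    n_target_miss: int

    def __post_init__(self) -> None:
        parts = (self.n_inner, self.n_middle, self.n_outer,
                 self.n_target_miss)
        if any(p < 0 for p in parts) or self.n_total < 0:
            raise ScreenInputError(f"{self.line_id}: counts must be >= 0")
        if sum(parts) != self.n_total:
            raise ScreenInputError(
                f"{self.line_id} replicate {self.replicate}: zone counts "
                f"{parts} do not sum to n_total={self.n_total}")


@dataclass(frozen=True)
class BenchmarkEntry:
    """Per-gene sponge phenotype paired with null-mutant information."""

    gene_id: str
    sponge_phenotype: str
    null_exists: bool
    null_phenotype: str = "not_tested"
    cluster_deletion: bool = False
    validated: bool = False
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.sponge_phenotype not in VIABILITY_CLASSES:
            raise ScreenInputError(
                f"{self.gene_id}: unknown sponge phenotype "
                f"{self.sponge_phenotype!r}")
        if self.null_exists and self.null_phenotype not in NULL_PHENOTYPES:
            raise ScreenInputError(
                f"{self.gene_id}: unknown null phenotype "
                f"{self.null_phenotype!r}")


@dataclass(frozen=True)
class ConcordanceSummary:
    """Counts and percentages per concordance category."""

    n_comparable: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]


@dataclass(frozen=True)
class FlightScreenResult:
    """Hit set plus the intermediate quantities of the flight screen."""

    hits: frozenset[str]
    threshold: float
    candidates: frozenset[str]
    p_values: Mapping[str, float]
    anova_p: float


def correction_factor(cs_non_balancer: int, cs_balancer: int) -> float:
    """Balancer correction from a wild-type cross.

    The ratio of non-balancer to balancer progeny in a control (Canton-S)
    cross estimates how far the sibling ratio deviates from 1 due to the
    balancer alone; percent viability is divided by it.
    """
    if cs_balancer <= 0:
        raise ScreenInputError("balancer-class count must be > 0")
    return cs_non_balancer / cs_balancer


def percent_viability(rec: ViabilityRecord, cf: float = 1.0) -> float:
    """100 x (experimental / control) / correction factor; may exceed 100."""
    if rec.n_control <= 0:
        raise ScreenInputError(
            f"{rec.line_id}: control count must be > 0 to compute a percent")
    if cf <= 0:
        raise ScreenInputError(f"correction factor must be > 0, got {cf}")
    return 100.0 * (rec.n_experimental / rec.n_control) / cf


def classify_viability(pct: float) -> str:
    """Bin a viability percent: lethal / semilethal / subviable / viable.

    Bins are [0, 5] lethal, (5, 50] semilethal, (50, 70] subviable and
    (70, inf) viable — half-open so that every percent falls in exactly
    one class.
    """
    if pct < 0 or math.isnan(pct):
        raise ScreenInputError(f"percent viability must be >= 0, got {pct}")
    if pct <= 5:
        return "lethal"
    if pct <= 50:
        return "semilethal"
    if pct <= 70:
        return "subviable"
    return "viable"


def call_viability_hits(percents: Mapping[str, float],
                        ) -> tuple[frozenset[str], float]:
    """Collection-wide stringent cutoff: mean minus one sample s.d.

    A line is a hit when its percent viability is less than or equal to
    the cutoff. A zero-variance collection is degenerate (the cutoff
    equals the mean and everything would qualify); it is flagged with a
    warning and returns no hits.
    """
    if len(percents) < 3:
        raise ScreenInputError(
            f"need >= 3 lines for a collection cutoff, got {len(percents)}")
    values = np.asarray(list(percents.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance viability collection; cutoff is "
                      "degenerate, returning no hits", stacklevel=2)
        return frozenset(), mean
    cutoff = mean - sd
    hits = frozenset(line for line, pct in percents.items()
                     if pct <= cutoff)
    return hits, cutoff


def nonflier_fraction(trial: FlightTrial) -> float:
    """Percent of dropped flies landing within the inner two circles."""
    if trial.n_total <= 0:
        raise ScreenInputError(
            f"{trial.line_id}: n_total must be > 0")
    return 100.0 * (trial.n_inner + trial.n_middle) / trial.n_total


def flight_threshold(scramble_fractions: Sequence[float]) -> float:
    """Twice the sample s.d. of the scramble-control non-flier fractions."""
    if len(scramble_fractions) < 2:
        raise ScreenInputError(
            "need >= 2 scramble replicates for a threshold")
    return 2.0 * float(np.std(np.asarray(scramble_fractions, float), ddof=1))


def call_flight_hits(line_fractions: Mapping[str, Sequence[float]],
                     scramble_fractions: Sequence[float],
                     alpha: float = 0.001) -> FlightScreenResult:
    """Threshold candidates, then confirm by ANOVA + Tukey-Kramer.

    A line is a *candidate* when its mean non-flier fraction exceeds the
    scramble threshold; a candidate is a *hit* when the one-way ANOVA
    across all lines (scramble included) is significant at ``alpha`` and
    the Tukey-Kramer comparison of that line against scramble has an
    adjusted p-value <= ``alpha``. ``alpha`` <= 0 disables hit calling
    (nothing can be significant at level zero).
    """
    threshold = flight_threshold(scramble_fractions)
    for line, fr in line_fractions.items():
        if len(fr) < 2:
            raise ScreenInputError(
                f"line {line!r}: need >= 2 replicates, got {len(fr)}")
    scr_label = "__scramble__"
    if scr_label in line_fractions:
        raise ScreenInputError(f"line id {scr_label!r} is reserved")

    candidates = frozenset(
        line for line, fr in line_fractions.items()
        if float(np.mean(fr)) > threshold)
    if not candidates or alpha <= 0:
        return FlightScreenResult(frozenset(), threshold, candidates, {},
                                  float("nan"))

    groups = dict(line_fractions)
    groups[scr_label] = list(scramble_fractions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input F-stat warnings
        f_stat, anova_p = stats.f_oneway(*groups.values())
    if not np.isfinite(anova_p) or anova_p > alpha:
        return FlightScreenResult(frozenset(), threshold, candidates, {},
                                  float(anova_p))

    values = np.concatenate([np.asarray(v, float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    unique = list(tukey.groupsunique)
    p_values: dict[str, float] = {}
    for (i, j), p in zip(itertools.combinations(range(len(unique)), 2),
                         tukey.pvalues):
        pair = {str(unique[i]), str(unique[j])}
        if scr_label in pair:
            (line,) = pair - {scr_label}
            p_values[line] = float(p)

    scr_mean = float(np.mean(scramble_fractions))
    hits = set()
    for line in candidates:
        p = p_values.get(line, float("nan"))
        if math.isnan(p):
            # zero pooled variance: means either coincide or differ exactly
            p = 0.0 if float(np.mean(line_fractions[line])) != scr_mean \
                else 1.0
            p_values[line] = p
        if p <= alpha:
            hits.add(line)
    return FlightScreenResult(frozenset(hits), threshold, candidates,
                              p_values, float(anova_p))


def filter_comparable(entries: Iterable[BenchmarkEntry],
                      ) -> list[BenchmarkEntry]:
    """Benchmark exclusion rules.

    Keep a gene only when a null allele exists, the null does not delete
    a cluster of several miRNA genes, the locus was genetically
    validated (non-complementation over a deficiency), and the null was
    actually tested for lethality.
    """
    return [e for e in entries
            if e.null_exists and not e.cluster_deletion and e.validated
            and e.null_phenotype != "not_tested"]


def classify_concordance(entry: BenchmarkEntry,
                         family_impaired: Mapping[str, bool]) -> str:
    """Concordance category of one comparable gene.

    Same impairment status in sponge and null -> confirmed. A viable
    sponge over an impaired null -> false_negative. An impaired sponge
    over a viable null is rescued to "family" when any same-family
    member's null is impaired (shared-seed redundancy), otherwise it is
    a false_positive.
    """
    sponge_impaired = entry.sponge_phenotype in IMPAIRED_PHENOTYPES
    null_impaired = entry.null_phenotype == "impaired"
    if sponge_impaired and null_impaired:
        return "confirmed"
    if not sponge_impaired and not null_impaired:
        return "confirmed"
    if not sponge_impaired and null_impaired:
        return "false_negative"
    if entry.family_id is not None and family_impaired.get(entry.family_id,
                                                           False):
        return "family"
    return "false_positive"


def _family_impaired_table(entries: Iterable[BenchmarkEntry],
                           ) -> dict[str, bool]:
    """family_id -> does any member (comparable or not) have an impaired null?

    Family evidence may come from a member that is itself excluded from
    the comparable set; what matters is the null phenotype on record.
    """
    table: dict[str, bool] = {}
    for e in entries:
        if e.family_id is None:
            continue
        impaired = e.null_exists and e.null_phenotype == "impaired"
        table[e.family_id] = table.get(e.family_id, False) or impaired
    return table


def summarize_concordance(entries: Sequence[BenchmarkEntry],
                          ) -> ConcordanceSummary:
    """Classify the comparable subset and tabulate category percentages."""
    comparable = filter_comparable(entries)
    if not comparable:
        raise ScreenInputError("no comparable entries after exclusions")
    family_impaired = _family_impaired_table(entries)
    counts = {cat: 0 for cat in CONCORDANCE_CATEGORIES}
    for entry in comparable:
        counts[classify_concordance(entry, family_impaired)] += 1
    n = len(comparable)
    percentages = {cat: round(100.0 * c / n, 1) for cat, c in counts.items()}
    return ConcordanceSummary(n, counts, percentages)
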