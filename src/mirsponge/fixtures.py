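"""Synthetic fixture generators emulating the screen's data shapes.

Every generator is a pure function of a :class:`FixtureSpec`: the RNG is
namespaced per generator (seeded from the spec seed plus a per-generator
tag) so adding one generator call never shifts another's stream.

Default conditions mirror the screens being emulated: a registry of 141
mature miRNAs of 21-23 nt; a viability table of 143 lines with 13
planted reduced-viability lines (non-hits around 100% viability, hits
reduced by 90 points, noise s.d. 5, control broods of ~100 progeny);
a flight table of 58 lines with 14 planted non-flier lines tested in
triplicate with 20 flies per drop.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .registry import MatureMiRNA, Registry
from .screen import BenchmarkEntry, FlightTrial, ViabilityRecord

__all__ = [
    "FixtureSpec",
    "FLIGHT_SPEC",
    "generate_registry",
    "generate_viability_table",
    "generate_flight_table",
    "generate_benchmark_table",
    "SCRAMBLE_LINE_ID",
]

SCRAMBLE_LINE_ID = "Scramble-SP"

#: Baseline per-fly non-flier probability for scramble and non-hit lines;
#: young controls show essentially no non-fliers, aged ones very few.
BASELINE_NONFLIER_P = 0.01


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic data: sizes, effect sizes, noise.

    ``hit_effect`` is the percent viability reduction for planted
    viability hits, or the percent non-flier fraction for planted
    flight hits.
    """

    rng_seed: int = 0
    n_mirnas: int = 141
    length_range: tuple[int, int] = (21, 23)
    n_lines: int = 143
    n_planted_hits: int = 13
    hit_effect: float = 90.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_planted_hits > self.n_lines:
            raise ValueError("n_planted_hits must be <= n_lines")
        if self.hit_effect < 0:
            raise ValueError("hit_effect must be >= 0")


#: Flight-screen scale: 58 muscle-expressed lines, 14 planted hits at
#: ~90% non-fliers (hit lines are essentially flightless).
FLIGHT_SPEC = FixtureSpec(n_lines=58, n_planted_hits=14, hit_effect=90.0)


def _rng(spec: FixtureSpec, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        [spec.rng_seed % 2**31, zlib.crc32(tag.encode()) % 2**31])


def generate_registry(spec: FixtureSpec) -> Registry:
    """Random RNA registry with ids syn-miR-1..n; deterministic per seed."""
    if spec.n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    rng = _rng(spec, "registry")
    lo, hi = spec.length_range
    entries = []
    for i in range(1, spec.n_mirnas + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        entries.append(MatureMiRNA(f"syn-miR-{i}", seq))
    return Registry(entries)


def _line_ids(n: int) -> list[str]:
    return [f"line-{i:03d}" for i in range(1, n + 1)]


def generate_viability_table(spec: FixtureSpec,
                             ) -> tuple[list[ViabilityRecord],
                                        frozenset[str]]:
    """Progeny-count table with planted reduced-viability lines.

    Non-hit lines eclose around 100% of the balancer-sibling class with
    Gaussian noise; planted hits are reduced by ``hit_effect`` points.
    Counts are realised as integers with control broods of ~100. The
    planted key is returned separately.
    """
    rng = _rng(spec, "viability")
    ids = _line_ids(spec.n_lines)
    planted = frozenset(map(str, rng.choice(
        ids, size=spec.n_planted_hits, replace=False)))
    records = []
    for line in ids:
        target = 100.0 - (spec.hit_effect if line in planted else 0.0)
        pct = max(0.0, rng.normal(target, spec.noise_sd))
        n_control = max(1, int(rng.poisson(100)))
        n_exp = max(0, int(round(n_control * pct / 100.0)))
        records.append(ViabilityRecord(line, n_exp, n_control, batch="b1"))
    return records, planted


def _split_zone_counts(rng: np.random.Generator, n_total: int,
                       nonflier_p: float) -> tuple[int, int, int, int]:
    n_nonflier = int(rng.binomial(n_total, nonflier_p))
    n_inner = int(rng.binomial(n_nonflier, 0.5))
    n_middle = n_nonflier - n_inner
    rest = n_total - n_nonflier
    n_outer = int(rng.binomial(rest, 0.7))
    return n_inner, n_middle, n_outer, rest - n_outer


def generate_flight_table(spec: FixtureSpec = FLIGHT_SPEC,
                          n_replicates: int = 3, n_flies: int = 20,
                          age_days: int = 30,
                          ) -> tuple[list[FlightTrial], frozenset[str]]:
    """Per-zone fly counts in triplicate, with planted non-flier lines.

    Scramble and non-hit lines land non-fliers at the baseline rate;
    planted lines at ``hit_effect`` percent. Includes the scramble
    control line itself (id ``Scramble-SP``).
    """
    rng = _rng(spec, "flight")
    ids = _line_ids(spec.n_lines)
    planted = frozenset(map(str, rng.choice(
        ids, size=spec.n_planted_hits, replace=False)))
    trials = []
    for line in [SCRAMBLE_LINE_ID] + ids:
        p = spec.hit_effect / 100.0 if line in planted \
            else BASELINE_NONFLIER_P
        for rep in range(1, n_replicates + 1):
            inner, middle, outer, miss = _split_zone_counts(rng, n_flies, p)
            trials.append(FlightTrial(line, age_days, f"r{rep}", n_flies,
                                      inner, middle, outer, miss))
    return trials, planted


def generate_benchmark_table(category_counts: dict[str, int],
                             n_excluded: int = 3) -> list[BenchmarkEntry]:
    """Inverse-construct a benchmark table with known classification.

    Fabricates per-gene entries whose classification by the concordance
    rules reproduces ``category_counts`` exactly on the comparable set,
    plus ``n_excluded`` entries exercising each exclusion rule in turn
    (no null allele / cluster deletion / not tested). Evidence for the
    "family" category is supplied by an excluded same-family entry with
    an impaired null, so it never perturbs the comparable counts.
    """
    for cat, n in category_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {cat!r}")
    entries: list[BenchmarkEntry] = []

    n_conf = category_counts.get("confirmed", 0)
    for i in range(n_conf):
        # alternate impaired/impaired with viable/viable concordance
        if i % 2 == 0:
            sponge, null = "lethal", "impaired"
        else:
            sponge, null = "viable", "viable"
        entries.append(BenchmarkEntry(
            f"conf-{i + 1}", sponge, True, null, False, True,
            family_id=f"fam-conf-{i + 1}"))

    for i in range(category_counts.get("false_negative", 0)):
        entries.append(BenchmarkEntry(
            f"fneg-{i + 1}", "viable", True, "impaired", False, True,
            family_id=f"fam-fneg-{i + 1}"))

    for i in range(category_counts.get("false_positive", 0)):
        entries.append(BenchmarkEntry(
            f"fpos-{i + 1}", "semilethal", True, "viable", False, True,
            family_id=f"fam-fpos-{i + 1}"))

    for i in range(category_counts.get("family", 0)):
        fam = f"fam-family-{i + 1}"
        entries.append(BenchmarkEntry(
            f"family-{i + 1}", "lethal", True, "viable", False, True,
            family_id=fam))
        # excluded family mate carrying the impaired-null evidence
        entries.append(BenchmarkEntry(
            f"family-mate-{i + 1}", "viable", True, "impaired", False,
            False, family_id=fam))

    exclusion_shapes = [
        dict(null_exists=False),
        dict(null_exists=True, null_phenotype="impaired",
             cluster_deletion=True, validated=True),
        dict(null_exists=True, null_phenotype="not_tested", validated=True),
    ]
    for i in range(n_excluded):
        shape = exclusion_shapes[i % len(exclusion_shapes)]
        entries.append(BenchmarkEntry(f"excluded-{i + 1}", "lethal",
                                      **shape))
    return entries
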