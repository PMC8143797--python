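"""Proximity-labeling (BioID) dotplot construction and the interactome
prioritization cascade.

Preys enter the dotplot when they reach >= ``min_count`` spectral counts in
at least one biological replicate and an iProphet protein probability of
>= ``min_probability``; common affinity-purification contaminants (trypsin,
biotin, streptavidin) are excluded.  The cascade then, per fusion bait,
(a) subtracts preys with decreased interaction relative to the cognate
full-length control, (b) subtracts known Hippo-pathway components,
(c) retains preys with increased interaction only, (d) intersects the two
fusions' lists, and (e) drops weak shared preys (lowest spectral-count and
relative-abundance category with BFDR > 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import PreyObservation

__all__ = [
    "DotplotEntry",
    "WeakRule",
    "CascadeReport",
    "build_dotplot",
    "compare_to_fulllength",
    "cascade_filter",
    "composition_summary",
    "DEFAULT_CONTAMINANTS",
]

DEFAULT_CONTAMINANTS = frozenset({"TRYPSIN", "BIOTIN", "STREPTAVIDIN"})


def bfdr_tier(bfdr: float) -> str:
    if bfdr <= 0.01:
        return "<=0.01"
    if bfdr <= 0.05:
        return "<=0.05"
    return ">0.05"


@dataclass(frozen=True)
class DotplotEntry:
    bait: str
    prey: str
    avg_count: float
    relative_abundance: float
    bfdr: float
    passes_detection: bool

    @property
    def bfdr_tier(self) -> str:
        return bfdr_tier(self.bfdr)


@dataclass(frozen=True)
class WeakRule:
    """Lowest-dotplot-bin definition for the final weak-prey subtraction.

    A prey is weak for a bait when its average spectral count and relative
    abundance both fall in the lowest display bin AND its BFDR exceeds
    ``max_bfdr``.
    """

    max_avg_count: float = 12.0
    max_rel_abundance: float = 1.0
    max_bfdr: float = 0.05

    def is_weak(self, entry: DotplotEntry) -> bool:
        return (
            entry.avg_count <= self.max_avg_count
            and entry.relative_abundance <= self.max_rel_abundance
            and entry.bfdr > self.max_bfdr
        )


@dataclass
class CascadeReport:
    """Per-step retained prey sets and counts for each fusion bait."""

    steps: list[tuple[str, dict[str, int]]]
    retained: list[tuple[str, dict[str, frozenset]]]
    shared: frozenset
    final: tuple[str, ...]

    def step_counts(self, bait: str) -> list[int]:
        return [counts[bait] for _, counts in self.steps if bait in counts]


def build_dotplot(
    observations: Sequence[PreyObservation],
    min_count: int = 10,
    min_probability: float = 0.95,
    contaminants: frozenset = DEFAULT_CONTAMINANTS,
) -> list[DotplotEntry]:
    """Filter prey observations into dotplot entries.

    The detection rule (>= min_count spectral counts in >= 1 replicate) is
    satisfied at prey level by any bait; the probability filter and the
    contaminant exclusion apply per observation.
    """
    if any(c < 0 for obs in observations for c in obs.counts):
        raise ValueError("negative spectral counts")
    passing = [
        obs
        for obs in observations
        if obs.probability >= min_probability and obs.prey.upper() not in contaminants
    ]
    detected_preys = {
        obs.prey for obs in passing if obs.counts and max(obs.counts) >= min_count
    }
    entries = []
    for obs in passing:
        if obs.prey not in detected_preys:
            continue
        entries.append(
            DotplotEntry(
                bait=obs.bait,
                prey=obs.prey,
                avg_count=sum(obs.counts) / len(obs.counts),
                relative_abundance=obs.relative_abundance,
                bfdr=obs.bfdr,
                passes_detection=bool(obs.counts) and max(obs.counts) >= min_count,
            )
        )
    return entries


def compare_to_fulllength(
    fusion_entries: Sequence[DotplotEntry],
    fulllength_entries: Sequence[DotplotEntry],
    delta: float = 0.0,
) -> dict[str, str]:
    """Classify each prey's interaction change, fusion vs full-length control.

    increased: fusion avg count > (1 + delta) x full-length (or prey absent
    from the full-length dotplot); decreased: < (1 - delta) x (or absent from
    the fusion dotplot); unchanged otherwise.  Preys in neither are excluded.
    """
    fusion = {e.prey: e.avg_count for e in fusion_entries}
    full = {e.prey: e.avg_count for e in fulllength_entries}
    out: dict[str, str] = {}
    for prey in fusion.keys() | full.keys():
        if prey not in full:
            out[prey] = "increased"
        elif prey not in fusion:
            out[prey] = "decreased"
        else:
            f, c = fusion[prey], full[prey]
            if f > (1 + delta) * c:
                out[prey] = "increased"
            elif f < (1 - delta) * c:
                out[prey] = "decreased"
            else:
                out[prey] = "unchanged"
    return out


def cascade_filter(
    tc_entries: Sequence[DotplotEntry],
    yt_entries: Sequence[DotplotEntry],
    taz_entries: Sequence[DotplotEntry],
    yap_entries: Sequence[DotplotEntry],
    hippo: Iterable[str],
    weak_rule: WeakRule = WeakRule(),
    delta: float = 0.0,
) -> CascadeReport:
    """Run the prioritization cascade on the two fusion interactomes."""
    for name, entries in [("TAZ-CAMTA1", tc_entries), ("YAP-TFE3", yt_entries)]:
        if entries is None:
            raise ValueError(f"missing dotplot for bait {name}")
    hippo_set = set(hippo)
    baits = {"TAZ-CAMTA1": tc_entries, "YAP-TFE3": yt_entries}
    classifications = {
        "TAZ-CAMTA1": compare_to_fulllength(tc_entries, taz_entries, delta),
        "YAP-TFE3": compare_to_fulllength(yt_entries, yap_entries, delta),
    }
    by_bait_prey = {
        bait: {e.prey: e for e in entries} for bait, entries in baits.items()
    }
    current = {bait: frozenset(by_bait_prey[bait]) for bait in baits}

    steps: list[tuple[str, dict[str, int]]] = []
    retained: list[tuple[str, dict[str, frozenset]]] = []

    def record(label: str) -> None:
        steps.append((label, {b: len(s) for b, s in current.items()}))
        retained.append((label, dict(current)))

    record("dotplot")
    current = {
        b: frozenset(p for p in s if classifications[b].get(p) != "decreased")
        for b, s in current.items()
    }
    record("minus_decreased")
    current = {b: frozenset(s - hippo_set) for b, s in current.items()}
    record("minus_hippo")
    current = {
        b: frozenset(p for p in s if classifications[b].get(p) == "increased")
        for b, s in current.items()
    }
    record("increased_only")
    shared = frozenset(current["TAZ-CAMTA1"] & current["YAP-TFE3"])
    steps.append(("intersection", {"shared": len(shared)}))
    retained.append(("intersection", {"shared": shared}))

    def weak_for(bait: str, prey: str) -> bool:
        entry = by_bait_prey[bait].get(prey)
        return entry is None or weak_rule.is_weak(entry)

    strong = frozenset(
        p for p in shared
        if not (weak_for("TAZ-CAMTA1", p) and weak_for("YAP-TFE3", p))
    )
    steps.append(("minus_weak", {"shared": len(strong)}))
    retained.append(("minus_weak", {"shared": strong}))

    def rank_key(prey: str) -> tuple[float, str]:
        total = sum(
            by_bait_prey[b][prey].avg_count for b in baits if prey in by_bait_prey[b]
        )
        return (-total, prey)

    return CascadeReport(
        steps=steps,
        retained=retained,
        shared=shared,
        final=tuple(sorted(strong, key=rank_key)),
    )


def composition_summary(
    preys: Iterable[str], category_map: Mapping[str, str]
) -> dict[str, float]:
    """Percentage of preys per functional class; unmapped preys are 'other'."""
    preys = list(preys)
    if not preys:
        raise ValueError("empty prey set")
    counts: dict[str, int] = {}
    for p in preys:
        cls = category_map.get(p, "other")
        counts[cls] = counts.get(cls, 0) + 1
    return {cls: 100.0 * c / len(preys) for cls, c in sorted(counts.items())}
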