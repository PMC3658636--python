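"""Community structure and methanogenesis-pathway potential from species tallies.

Rollups aggregate a count-weighted species tally to genus or order level;
pathway percentages classify the assigned reads by the metabolic capabilities
of their species (acetoclastic, hydrogenotrophic with or without formate,
methylotrophic). Denominator discipline matters and is fixed here once:
pathway and taxon percentages are fractions of *assigned* reads, while the
unassigned percentage is a fraction of the grand total (assigned +
unassigned). A multi-pathway species contributes its full count to every
pathway it carries, so pathway percentages need not sum to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Protocol

import pandas as pd

from .errors import DataError
from .reference import MetabolismCode, derive_genus


class SpeciesAnnotation(Protocol):
    """Anything carrying taxonomy + metabolism for a species label."""

    order: str
    genus: str
    metabolism: MetabolismCode | None


@dataclass
class PathwayBreakdown:
    """Percentages of assigned reads able to run each methanogenesis pathway."""

    assigned_total: int
    acetoclastic_pct: float
    hydrogenotrophic_pct: float
    formate_pct: float
    methylotrophic_pct: float
    formate_among_hydrogenotrophic_pct: float
    unassigned_pct_of_all: float

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if name.endswith("pct") or name.endswith("pct_of_all"):
                if not 0 <= val <= 100:
                    raise ValueError(f"{name} out of [0, 100]: {val}")


def rollup(
    tally: Mapping[str, int],
    annotations: Mapping[str, SpeciesAnnotation],
    level: str = "order",
) -> dict[str, tuple[int, float]]:
    """Aggregate a species tally to ``level`` in {'species','genus','order'}.

    Returns taxon -> (count, fraction of assigned reads). Every species in
    the tally must be annotated; the unassigned class is handled separately
    and must not appear here.
    """
    if level not in ("species", "genus", "order"):
        raise ValueError(f"unknown rollup level {level!r}")
    total = sum(tally.values())
    if total <= 0:
        raise DataError("rollup needs a non-empty tally")
    counts: dict[str, int] = {}
    for species, n in tally.items():
        if level == "species":
            taxon = species
        else:
            ann = annotations.get(species)
            if ann is None:
                raise DataError(f"species lacking annotation: {species!r}")
            taxon = ann.order if level == "order" else (ann.genus or derive_genus(species))
        counts[taxon] = counts.get(taxon, 0) + n
    return {t: (n, n / total) for t, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))}


def pathway_breakdown(
    tally: Mapping[str, int],
    annotations: Mapping[str, SpeciesAnnotation],
    unassigned: int = 0,
) -> PathwayBreakdown:
    """Classify assigned reads by the pathway capabilities of their species.

    Percentages use the assigned total as denominator, except
    ``formate_among_hydrogenotrophic_pct`` (hydrogenotrophic reads as
    denominator) and ``unassigned_pct_of_all`` (grand total).
    """
    assigned_total = sum(tally.values())
    if assigned_total <= 0:
        raise DataError("pathway breakdown needs a nonzero assigned total")
    sums = {"acetoclastic": 0, "co2_reduction": 0, "formate_capable": 0, "methylotrophic": 0}
    for species, n in tally.items():
        ann = annotations.get(species)
        if ann is None or ann.metabolism is None:
            raise DataError(f"no metabolism annotation for species {species!r}")
        met = ann.metabolism
        for key in sums:
            if getattr(met, key):
                sums[key] += n
    pct = lambda x, d: 100.0 * x / d if d else 0.0
    return PathwayBreakdown(
        assigned_total=assigned_total,
        acetoclastic_pct=pct(sums["acetoclastic"], assigned_total),
        hydrogenotrophic_pct=pct(sums["co2_reduction"], assigned_total),
        formate_pct=pct(sums["formate_capable"], assigned_total),
        methylotrophic_pct=pct(sums["methylotrophic"], assigned_total),
        formate_among_hydrogenotrophic_pct=pct(
            sums["formate_capable"], sums["co2_reduction"]
        ),
        unassigned_pct_of_all=pct(unassigned, assigned_total + unassigned),
    )


def unassigned_fraction(tally: Mapping[str, int], unassigned: int) -> float:
    """Unassigned reads as a percentage of all analyzed reads."""
    total = sum(tally.values()) + unassigned
    if total <= 0:
        raise DataError("unassigned_fraction needs a positive total")
    return 100.0 * unassigned / total


@dataclass
class CommunityProfile:
    """Per-primer and pooled species tallies with taxon-level fractions."""

    per_primer: dict[str, dict[str, int]]
    unassigned_per_primer: dict[str, int]
    pooled: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    order_fractions: dict[str, float] = field(default_factory=dict)
    genus_fractions: dict[str, float] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        per_primer: Mapping[str, Mapping[str, int]],
        unassigned_per_primer: Mapping[str, int],
        annotations: Mapping[str, SpeciesAnnotation],
    ) -> "CommunityProfile":
        pooled: dict[str, int] = {}
        for t in per_primer.values():
            for sp, n in t.items():
                pooled[sp] = pooled.get(sp, 0) + n
        unassigned = sum(unassigned_per_primer.values())
        orders = rollup(pooled, annotations, "order") if pooled else {}
        genera = rollup(pooled, annotations, "genus") if pooled else {}
        return cls(
            per_primer={k: dict(v) for k, v in per_primer.items()},
            unassigned_per_primer=dict(unassigned_per_primer),
            pooled=pooled,
            unassigned=unassigned,
            order_fractions={t: frac for t, (_, frac) in orders.items()},
            genus_fractions={t: frac for t, (_, frac) in genera.items()},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def per_primer_report(
    profile: CommunityProfile,
    annotations: Mapping[str, SpeciesAnnotation],
    level: str = "order",
) -> pd.DataFrame:
    """Side-by-side taxon fractions per primer set plus the pooled column.

    Adds ``detected_by`` (number of primer sets seeing the taxon) so taxa
    private to a single primer are easy to flag — the reason multiple
    degenerate primer sets are worth sequencing in the first place.
    """
    cols: dict[str, dict[str, float]] = {}
    for primer, t in profile.per_primer.items():
        cols[primer] = (
            {tax: frac for tax, (_, frac) in rollup(t, annotations, level).items()}
            if t
            else {}
        )
    if profile.pooled:
        cols["pooled"] = {
            tax: frac for tax, (_, frac) in rollup(profile.pooled, annotations, level).items()
        }
    df = pd.DataFrame(cols).fillna(0.0)
    primer_cols = [c for c in df.columns if c != "pooled"]
    df["detected_by"] = (df[primer_cols] > 0).sum(axis=1)
    return df.sort_values("pooled" if "pooled" in df else primer_cols[0], ascending=False)


def plot_order_bars(
    profile: CommunityProfile,
    annotations: Mapping[str, SpeciesAnnotation],
    path: str | Path,
) -> None:
    """Stacked order-level composition bars, one per primer set plus pooled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = per_primer_report(profile, annotations, "order").drop(columns="detected_by")
    ax = df.T.plot(kind="bar", stacked=True, figsize=(7, 4))
    ax.set_ylabel("fraction of assigned reads")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
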