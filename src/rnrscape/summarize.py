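"""Descriptive outputs: class-combination distribution and metadata cross-tabs.

Percentages are rounded half-up (so 128/685 prints as 18.7, not 18.686...),
and denominators are always explicit: combination distributions are reported
over the RNR-positive genomes, with the RNR-negative count carried
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .curation import COMBO_LABELS, GenomeClassProfile
from .formats_io import ENVIRONMENTS, OXYGEN_CLASSES, PHAGE_FAMILIES, MetadataRow

AXIS_LEVELS = {
    "family": list(PHAGE_FAMILIES),
    "environment": list(ENVIRONMENTS),
    "oxygen": list(OXYGEN_CLASSES),
    "combo": [c for c in COMBO_LABELS if c != "none"],
}


@dataclass
class CrossTab:
    axis1: str
    axis2: str
    counts: pd.DataFrame  # rows = axis1 levels, cols = axis2 levels

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * n / d`` rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def combo_distribution(
    profiles: Mapping[str, GenomeClassProfile] | Sequence[GenomeClassProfile],
) -> tuple[dict[str, int], int]:
    """Counts per combination label over RNR-positive genomes.

    Returns ``(counts, n_negative)``: genomes with combination ``none`` are
    excluded from the positive counts and reported via ``n_negative``.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    counts = {label: 0 for label in COMBO_LABELS if label != "none"}
    n_negative = 0
    for p in profiles:
        if p.combo == "none":
            n_negative += 1
        else:
            counts[p.combo] += 1
    return counts, n_negative


def _axis_value(profile: GenomeClassProfile, meta: MetadataRow, axis: str) -> str:
    if axis == "combo":
        return profile.combo
    return getattr(meta, axis)


def crosstab(
    profiles: Mapping[str, GenomeClassProfile],
    metadata: Mapping[str, MetadataRow],
    axis1: str,
    axis2: str,
) -> CrossTab:
    """Cross-tabulate genome counts over two axes (vocabulary-ordered levels).

    Axes: 'family', 'environment', 'oxygen' (metadata) or 'combo' (class
    combination). Genomes without a metadata row are tallied under 'unknown'.
    """
    for axis in (axis1, axis2):
        if axis not in AXIS_LEVELS:
            raise ValueError(f"unknown axis {axis!r}; choose from {sorted(AXIS_LEVELS)}")
    rows = []
    for gid in sorted(profiles):
        prof = profiles[gid]
        meta = metadata.get(gid) or MetadataRow(genome_id=gid)
        rows.append((_axis_value(prof, meta, axis1), _axis_value(prof, meta, axis2)))
    table = pd.DataFrame(
        0, index=pd.Index(AXIS_LEVELS[axis1], name=axis1),
        columns=pd.Index(AXIS_LEVELS[axis2], name=axis2),
    )
    for v1, v2 in rows:
        if v1 in table.index and v2 in table.columns:
            table.loc[v1, v2] += 1
    return CrossTab(axis1=axis1, axis2=axis2, counts=table)


def write_summaries(
    profiles: Mapping[str, GenomeClassProfile],
    metadata: Mapping[str, MetadataRow],
    out_dir: str | Path,
) -> None:
    """Write figure-style summary TSVs (combination counts and cross-tabs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, n_negative = combo_distribution(profiles)
    with open(out / "figure1_combos.tsv", "w") as fh:
        fh.write("combo\tn\n")
        for label, n in counts.items():
            fh.write(f"{label}\t{n}\n")
        fh.write(f"none\t{n_negative}\n")
    for a1, a2 in (("family", "combo"), ("environment", "combo"), ("oxygen", "combo")):
        ct = crosstab(profiles, metadata, a1, a2)
        ct.counts.to_csv(out / f"figure2_crosstab_{a1}_{a2}.tsv", sep="\t")
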