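"""Gene-order strings, operon grouping, and split-gene characterization.

RNR genes in cellular genomes typically sit together in operons (nrdAB,
nrdHIEF, nrdDG); phages rearrange, lose, and interrupt them. This module
extracts the 5'->3' gene-order string per genome, groups co-oriented
closely-spaced calls into operon-like runs, and detects split genes: two or
more same-family calls within a genomic window whose profile intervals cover
quasi-disjoint parts of the gene. Positive inter-fragment junctions (spacers)
are scanned for open reading frames carrying homing-endonuclease or intein
motifs; negative junctions are fragment overlaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .curation import CuratedCall, accepted, class_profile
from .formats_io import GenomeRecord
from .profile_engine import six_frame_orfs

DEFAULT_MAX_OPERON_GAP = 200  # nt
DEFAULT_SPLIT_WINDOW = 20000  # nt
DEFAULT_MIN_ORF_CODONS = 30
DUPLICATE_OVERLAP_FRACTION = 0.2  # profile-interval overlap >= this => duplicate, not split

FRAGMENT_LABELS = "abcdefgh"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class GeneOrder:
    genome_id: str
    order: list[str]  # family tokens by genomic start
    order_string: str  # 'nrd' prefix stripped, e.g. "GDBA"


@dataclass
class OperonGroup:
    genome_id: str
    members: list[CuratedCall]
    span: tuple[int, int]


@dataclass
class MotifDef:
    """A named amino-acid regular expression (illustrative, packaged patterns)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        self.regex = re.compile(self.pattern)


@dataclass
class InterveningReport:
    length: int
    orfs: list[tuple[str, int, int, str]]  # (orf id, nt start, nt end, strand) within the junction
    motif_hits: list[tuple[str, str]]  # (orf id, motif name)


@dataclass
class SplitGeneReport:
    genome_id: str
    family: str
    fragments: list[tuple[CuratedCall, tuple[int, int]]]  # (call, profile interval) by pf_from
    junctions: list[int]  # signed nt gaps in transcription orientation
    labels: list[str] = field(default_factory=list)
    intervening: dict[int, InterveningReport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [
                f"{self.family}-{FRAGMENT_LABELS[i]}" for i in range(len(self.fragments))
            ]


# ---------------------------------------------------------------------------
# Gene order & operons
# ---------------------------------------------------------------------------

def gene_order(calls: Sequence[CuratedCall]) -> GeneOrder:
    """5'->3' family order on the deposited orientation (sorted by start)."""
    acc = sorted(accepted(calls), key=lambda c: (c.start, c.end))
    if not acc:
        raise ValueError("gene_order requires at least one accepted call")
    ids = {c.genome_id for c in acc}
    if len(ids) > 1:
        raise ValueError("calls span multiple genomes")
    order = [c.family for c in acc]
    return GeneOrder(
        genome_id=acc[0].genome_id,
        order=order,
        order_string="".join(f.removeprefix("nrd") for f in order),
    )


def group_operons(
    calls: Sequence[CuratedCall], max_operon_gap: int = DEFAULT_MAX_OPERON_GAP
) -> list[OperonGroup]:
    """Maximal runs of accepted calls on one strand with gaps <= the cut-off."""
    acc = sorted(accepted(calls), key=lambda c: (c.start, c.end))
    groups: list[OperonGroup] = []
    run: list[CuratedCall] = []
    for c in acc:
        if run and c.strand == run[-1].strand and c.start - run[-1].end <= max_operon_gap:
            run.append(c)
        else:
            if run:
                groups.append(
                    OperonGroup(run[0].genome_id, run, (run[0].start, max(x.end for x in run)))
                )
            run = [c]
    if run:
        groups.append(OperonGroup(run[0].genome_id, run, (run[0].start, max(x.end for x in run))))
    return groups


# ---------------------------------------------------------------------------
# Split genes
# ---------------------------------------------------------------------------

def _profile_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1  # 1-based inclusive intervals
    if ov <= 0:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return ov / shorter


def detect_splits(
    calls: Sequence[CuratedCall], window: int = DEFAULT_SPLIT_WINDOW
) -> list[SplitGeneReport]:
    """Find same-family fragment sets within a genomic window.

    Fragments must carry profile coordinates and cover quasi-disjoint profile
    intervals (pairwise overlap < 20% of the shorter); otherwise the calls
    are considered duplicates and no report is produced. Junction *i* is the
    signed nucleotide gap between consecutive fragments in transcription
    orientation (negative = overlap).
    """
    acc = [c for c in accepted(calls) if c.pf_to >= c.pf_from > 0]
    by_key: dict[tuple[str, str], list[CuratedCall]] = {}
    for c in acc:
        by_key.setdefault((c.genome_id, c.family), []).append(c)

    reports: list[SplitGeneReport] = []
    for (gid, family), group in sorted(by_key.items()):
        if len(group) < 2:
            continue
        group.sort(key=lambda c: (c.start, c.end))
        # chain genomically proximate calls into clusters
        clusters: list[list[CuratedCall]] = [[group[0]]]
        for c in group[1:]:
            if c.start - clusters[-1][-1].end <= window:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cluster in clusters:
            if len(cluster) < 2:
                continue
            ivs = [(c.pf_from, c.pf_to) for c in cluster]
            quasi_disjoint = all(
                _profile_overlap_fraction(ivs[i], ivs[j]) < DUPLICATE_OVERLAP_FRACTION
                for i in range(len(ivs))
                for j in range(i + 1, len(ivs))
            )
            if not quasi_disjoint:
                continue
            frags = sorted(cluster, key=lambda c: c.pf_from)
            strand = frags[0].strand
            junctions = []
            for a, b in zip(frags, frags[1:]):
                if strand == "+":
                    junctions.append(b.start - a.end)
                else:
                    junctions.append(a.start - b.end)
            reports.append(
                SplitGeneReport(
                    genome_id=gid,
                    family=family,
                    fragments=[(c, (c.pf_from, c.pf_to)) for c in frags],
                    junctions=junctions,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# Intervening sequence characterization
# ---------------------------------------------------------------------------

def load_motifs(path: Optional[str | Path] = None) -> list[MotifDef]:
    """Load motif definitions from a two-column TSV (name, pattern).

    Without a path, the packaged illustrative patterns are used (these are
    versioned stand-ins shipped with the package, not a curated database).
    """
    if path is None:
        text = resources.files("rnrscape").joinpath("data/motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    seen = set()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, pattern = line.split("\t")[:2]
        if name in seen:
            raise ValueError(f"duplicate motif name {name}")
        seen.add(name)
        motifs.append(MotifDef(name=name, pattern=pattern))
    return motifs


def characterize_intervening(
    genome: GenomeRecord,
    interval: tuple[int, int],
    motifs: Sequence[MotifDef],
    min_orf: int = DEFAULT_MIN_ORF_CODONS,
) -> InterveningReport:
    """ORFs and motif content of a positive junction interval.

    Six-frame ORFs of at least ``min_orf`` codons inside the interval are
    listed and each translation is scanned with every motif pattern.
    """
    a, b = interval
    if b <= a:
        raise ValueError("characterize_intervening requires a positive junction")
    sub = genome.seq[a:b]
    orfs = []
    motif_hits = []
    for k, (prot, s, e, strand, _frame) in enumerate(six_frame_orfs(sub, min_codons=min_orf)):
        orf_id = f"{genome.id}:{a + s}-{a + e}:{strand}"
        orfs.append((orf_id, a + s, a + e, strand))
        for m in motifs:
            if m.regex.search(prot):
                motif_hits.append((orf_id, m.name))
    return InterveningReport(length=b - a, orfs=orfs, motif_hits=motif_hits)


def characterize_splits(
    reports: Sequence[SplitGeneReport],
    genomes: dict[str, GenomeRecord],
    motifs: Optional[Sequence[MotifDef]] = None,
    min_orf: int = DEFAULT_MIN_ORF_CODONS,
) -> list[SplitGeneReport]:
    """Fill in intervening-sequence reports for every positive junction."""
    if motifs is None:
        motifs = load_motifs()
    for rep in reports:
        genome = genomes[rep.genome_id]
        frags = [c for c, _ in rep.fragments]
        strand = frags[0].strand
        for i, jlen in enumerate(rep.junctions):
            if jlen <= 0:
                continue
            if strand == "+":
                interval = (frags[i].end, frags[i + 1].start)
            else:
                interval = (frags[i + 1].end, frags[i].start)
            rep.intervening[i] = characterize_intervening(genome, interval, motifs, min_orf=min_orf)
    return reports


# ---------------------------------------------------------------------------
# Figure-3-style tabulation
# ---------------------------------------------------------------------------

def combination_matrix(
    orders: Sequence[GeneOrder], calls_by_genome: Optional[dict[str, Sequence[CuratedCall]]] = None
) -> pd.DataFrame:
    """Counts of genomes per gene-order string, per class combination.

    Returns a tidy DataFrame with columns (combo, order_string, n); the sum
    of ``n`` equals the number of genomes tabulated.
    """
    rows = []
    for o in orders:
        if calls_by_genome is not None:
            combo = class_profile(list(calls_by_genome[o.genome_id]), genome_id=o.genome_id).combo
        else:
            from .curation import class_of

            classes = set()
            for fam in o.order:
                cls = class_of(fam)
                classes.add("I" if cls in ("Ia", "Ib") else cls)
            combo = "+".join(sorted(classes, key=("I", "II", "III").index)) or "none"
        rows.append((combo, o.order_string))
    if not rows:
        return pd.DataFrame(columns=["combo", "order_string", "n"])
    df = pd.DataFrame(rows, columns=["combo", "order_string"])
    out = df.value_counts().reset_index(name="n")
    return out.sort_values(["combo", "order_string"]).reset_index(drop=True)
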