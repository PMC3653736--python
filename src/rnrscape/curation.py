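"""Turn raw profile hits into curated RNR gene calls and per-genome class profiles.

The curation chain mirrors how a careful annotator filters homology-search
output for a gene family with known confounders:

1. E-value filter (inclusive cut-off, default 1e-4);
2. multi-hit resolution: when one locus hits several RNR families, keep the
   lowest E-value (ties: higher bit score, then lexicographic family);
3. genomic-context filter for the two ambiguous families — nrdH resembles
   thioredoxins/glutaredoxins and nrdG resembles pyruvate-formate-lyase
   activases, so calls to either are accepted only near an unambiguous RNR
   gene;
4. manual overrides (forced inclusions / exclusions).

Every input hit survives the chain exactly once, carrying an accepted /
rejected status and a reason, so curation decisions stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .formats_io import GenomeRecord
from .profile_engine import Hit

logger = logging.getLogger("rnrscape")

DEFAULT_EVALUE_CUTOFF = 1e-4
DEFAULT_WINDOW_NT = 5000
DEFAULT_WINDOW_GENES = 3

#: Families whose hits require genomic context (confounded by non-RNR genes).
AMBIGUOUS_FAMILIES = ("nrdH", "nrdG")

#: Fixed gene-family -> RNR class map.
CLASS_OF_FAMILY = {
    "nrdA": "Ia",
    "nrdB": "Ia",
    "nrdE": "Ib",
    "nrdF": "Ib",
    "nrdH": "Ib",
    "nrdI": "Ib",
    "nrdJ": "II",
    "nrdD": "III",
    "nrdG": "III",
}

COMBO_LABELS = ("none", "I", "II", "III", "I+II", "I+III", "II+III", "I+II+III")


def class_of(family: str) -> str:
    """RNR class of a gene family (Ia, Ib, II or III)."""
    try:
        return CLASS_OF_FAMILY[family]
    except KeyError:
        raise ValueError(f"unknown RNR gene family {family!r}") from None


@dataclass
class CuratedCall:
    """An accepted or rejected RNR gene call.

    ``start``/``end`` are genome nucleotides, 0-based half-open. For hits
    against annotated CDS features the call locus is the feature interval
    (the gene, as deposited), while the local-alignment envelope remains on
    the underlying :class:`Hit`.
    """

    genome_id: str
    family: str
    start: int
    end: int
    strand: str
    score: float
    evalue: float
    status: str = "accepted"
    reason: str = "pass"
    gene_id: Optional[str] = None
    pf_from: int = 0
    pf_to: int = 0
    hit: Optional[Hit] = field(default=None, repr=False)

    @property
    def rnr_class(self) -> str:
        return class_of(self.family)

    def __post_init__(self) -> None:
        accepted_reasons = {"pass", "override_include"}
        if (self.status == "accepted") != (self.reason in accepted_reasons):
            raise ValueError(f"inconsistent status/reason: {self.status}/{self.reason}")


@dataclass
class GenomeClassProfile:
    """Per-genome class presence booleans and the canonical combination label."""

    genome_id: str
    has_Ia: bool = False
    has_Ib: bool = False
    has_II: bool = False
    has_III: bool = False

    @property
    def combo(self) -> str:
        parts = []
        if self.has_Ia or self.has_Ib:
            parts.append("I")
        if self.has_II:
            parts.append("II")
        if self.has_III:
            parts.append("III")
        return "+".join(parts) if parts else "none"


def _call_from_hit(hit: Hit) -> CuratedCall:
    if hit.locus_start is not None and hit.locus_end is not None:
        start, end = hit.locus_start, hit.locus_end
    else:
        start, end = hit.q_from, hit.q_to
    return CuratedCall(
        genome_id=hit.query_id,
        family=hit.family,
        start=start,
        end=end,
        strand=hit.strand,
        score=hit.score,
        evalue=hit.evalue,
        gene_id=hit.gene_id,
        pf_from=hit.pf_from,
        pf_to=hit.pf_to,
        hit=hit,
    )


def _reject(call: CuratedCall, reason: str) -> None:
    call.status = "rejected"
    call.reason = reason


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_evalue(hits: Sequence[Hit], cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[CuratedCall]:
    """Partition hits at the E-value cut-off (boundary inclusive: E <= cutoff)."""
    calls = []
    for h in hits:
        call = _call_from_hit(h)
        if h.evalue > cutoff:
            _reject(call, "evalue_fail")
        calls.append(call)
    return calls


def _overlap_conflict(a: CuratedCall, b: CuratedCall) -> bool:
    """Two calls conflict when intervals overlap >= 50% of the shorter."""
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    shorter = min(a.end - a.start, b.end - b.start)
    return ov >= 0.5 * shorter


def resolve_multihit(calls: Sequence[CuratedCall]) -> list[CuratedCall]:
    """Within each group of locus-overlapping accepted calls spanning more than
    one family, keep only the lowest-E-value call.

    Ties break by higher bit score, then lexicographic family, so the outcome
    is independent of input order.
    """
    calls = list(calls)
    by_genome: dict[str, list[CuratedCall]] = {}
    for c in calls:
        if c.status == "accepted":
            by_genome.setdefault(c.genome_id, []).append(c)
    for group in by_genome.values():
        # connected components under the conflict relation
        parent = list(range(len(group)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if _overlap_conflict(group[i], group[j]):
                    parent[find(i)] = find(j)
        comps: dict[int, list[CuratedCall]] = {}
        for i, c in enumerate(group):
            comps.setdefault(find(i), []).append(c)
        for comp in comps.values():
            if len({c.family for c in comp}) < 2:
                continue
            winner = min(comp, key=lambda c: (c.evalue, -c.score, c.family))
            for c in comp:
                if c is not winner:
                    _reject(c, "superseded_by_lower_evalue")
    return calls


def _gap_between(a: CuratedCall, b: CuratedCall) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _genes_between(genome: GenomeRecord, a: CuratedCall, b: CuratedCall) -> int:
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    if lo >= hi:
        return 0
    return sum(1 for f in genome.features if f.start >= lo and f.end <= hi)


def context_filter(
    calls: Sequence[CuratedCall],
    genomes: Optional[dict[str, GenomeRecord]] = None,
    window_nt: int = DEFAULT_WINDOW_NT,
    window_genes: int = DEFAULT_WINDOW_GENES,
) -> list[CuratedCall]:
    """Require genomic context for nrdH / nrdG calls.

    An nrdH or nrdG call stays accepted only if an accepted call of a
    different, unambiguous family (not nrdH/nrdG) lies within ``window_nt``
    of its boundaries, or with at most ``window_genes`` annotated genes in
    between (gene counting needs the genome's feature table).
    """
    calls = list(calls)
    by_genome: dict[str, list[CuratedCall]] = {}
    for c in calls:
        if c.status == "accepted":
            by_genome.setdefault(c.genome_id, []).append(c)
    for gid, group in by_genome.items():
        anchors = [c for c in group if c.family not in AMBIGUOUS_FAMILIES]
        genome = genomes.get(gid) if genomes else None
        for c in group:
            if c.family not in AMBIGUOUS_FAMILIES:
                continue
            ok = False
            for anchor in anchors:
                if _gap_between(c, anchor) <= window_nt:
                    ok = True
                    break
                if genome is not None and _genes_between(genome, c, anchor) <= window_genes:
                    ok = True
                    break
            if not ok:
                _reject(c, "context_fail")
    return calls


# ---------------------------------------------------------------------------
# Overrides
# ---------------------------------------------------------------------------

def read_overrides(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    """Read an overrides TSV: genome_id, family, start, end, strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("genome_id"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            try:
                rows.append((fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
    return rows


def apply_overrides(
    calls: Sequence[CuratedCall],
    include_list: Iterable[tuple[str, str, int, int, str]] = (),
    exclude_list: Iterable[tuple[str, str, int, int, str]] = (),
) -> list[CuratedCall]:
    """Apply manual inclusions and exclusions.

    Inclusions append accepted calls with reason ``override_include``
    (idempotent: an already-present identical override is not duplicated);
    exclusions flip matching calls to rejected / ``override_exclude``.
    """
    calls = list(calls)
    for gid, family, start, end, strand in include_list:
        class_of(family)  # validates family
        dup = any(
            c.genome_id == gid and c.family == family and c.start == start
            and c.end == end and c.reason == "override_include"
            for c in calls
        )
        if dup:
            continue
        calls.append(
            CuratedCall(
                genome_id=gid, family=family, start=start, end=end, strand=strand,
                score=float("nan"), evalue=float("nan"),
                status="accepted", reason="override_include",
            )
        )
    for gid, family, start, end, strand in exclude_list:
        matched = False
        for c in calls:
            if c.genome_id == gid and c.family == family and c.start == start and c.end == end:
                _reject(c, "override_exclude")
                matched = True
        if not matched:
            logger.warning("exclude override matched nothing: %s %s %d..%d", gid, family, start, end)
    return calls


# ---------------------------------------------------------------------------
# Full chain and class profiles
# ---------------------------------------------------------------------------

def curate(
    hits: Sequence[Hit],
    genomes: Optional[dict[str, GenomeRecord]] = None,
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    include_list: Iterable[tuple[str, str, int, int, str]] = (),
    exclude_list: Iterable[tuple[str, str, int, int, str]] = (),
    window_nt: int = DEFAULT_WINDOW_NT,
    window_genes: int = DEFAULT_WINDOW_GENES,
) -> list[CuratedCall]:
    """The full curation chain: E-value -> multi-hit -> context -> overrides."""
    calls = filter_evalue(hits, cutoff=cutoff)
    calls = resolve_multihit(calls)
    calls = context_filter(calls, genomes=genomes, window_nt=window_nt, window_genes=window_genes)
    calls = apply_overrides(calls, include_list=include_list, exclude_list=exclude_list)
    return calls


def accepted(calls: Iterable[CuratedCall]) -> list[CuratedCall]:
    return [c for c in calls if c.status == "accepted"]


def class_profile(calls: Sequence[CuratedCall], genome_id: Optional[str] = None) -> GenomeClassProfile:
    """Class booleans and combination label from one genome's curated calls."""
    acc = accepted(calls)
    if genome_id is None:
        ids = {c.genome_id for c in acc} or {c.genome_id for c in calls}
        if len(ids) > 1:
            raise ValueError("calls span multiple genomes; pass genome_id")
        genome_id = next(iter(ids)) if ids else "unknown"
    profile = GenomeClassProfile(genome_id=genome_id)
    for c in acc:
        if c.genome_id != genome_id:
            continue
        cls = c.rnr_class
        if cls == "Ia":
            profile.has_Ia = True
        elif cls == "Ib":
            profile.has_Ib = True
        elif cls == "II":
            profile.has_II = True
        else:
            profile.has_III = True
    return profile


def class_profiles(calls: Sequence[CuratedCall]) -> dict[str, GenomeClassProfile]:
    """Class profile per genome over a mixed-set of curated calls."""
    by_genome: dict[str, list[CuratedCall]] = {}
    for c in calls:
        by_genome.setdefault(c.genome_id, []).append(c)
    return {gid: class_profile(group, genome_id=gid) for gid, group in sorted(by_genome.items())}


# ---------------------------------------------------------------------------
# Calls TSV
# ---------------------------------------------------------------------------

CALLS_HEADER = (
    "genome_id\tfamily\trnr_class\tstart\tend\tstrand\tscore\tevalue\t"
    "status\treason\tgene_id\tpf_from\tpf_to"
)


def write_calls(calls: Iterable[CuratedCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(CALLS_HEADER + "\n")
        for c in calls:
            fh.write(
                f"{c.genome_id}\t{c.family}\t{c.rnr_class}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{c.score:.4g}\t{c.evalue:.6g}\t{c.status}\t{c.reason}\t"
                f"{c.gene_id or ''}\t{c.pf_from}\t{c.pf_to}\n"
            )


def read_calls(path: str | Path) -> list[CuratedCall]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("genome_id"):
        raise ValueError(f"{path}: missing calls header")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(
            CuratedCall(
                genome_id=f[0], family=f[1], start=int(f[3]), end=int(f[4]), strand=f[5],
                score=float(f[6]), evalue=float(f[7]), status=f[8], reason=f[9],
                gene_id=f[10] or None, pf_from=int(f[11]), pf_to=int(f[12]),
            )
        )
    return out
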