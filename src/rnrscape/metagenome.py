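"""The viral-metagenome branch: reads -> ORFs -> hits -> normalized abundance.

Short environmental reads are de-replicated, translated in six frames into
stop-free protein fragments, and searched with the calibrated family
profiles. Raw per-family counts are normalized by the total metagenome size
(nucleotides after de-replication) and by the gene length (profile match
columns, in residues), so abundances are comparable across metagenomes of
different sequencing depth and across genes of different length:

    A[m][g] = C[m][g] / (size_nt[m] * L[g]) * 1e9

Class aggregate columns are exact sums of their member gene columns.
Metagenomes with five or fewer total RNR hits are flagged excluded, too
sparse for a robust profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .curation import CLASS_OF_FAMILY
from .formats_io import FAMILIES, SequenceRecord
from .profile_engine import (
    ProfileModel,
    _score_local_all,
    encode_protein,
    evalue,
    reverse_complement,
    translate,
)

DEFAULT_MIN_AA = 30
DEFAULT_EVALUE_CUTOFF = 1e-4
DEFAULT_MIN_HITS = 6  # rows with total raw hits <= min_hits - 1 are excluded
ABUNDANCE_SCALE = 1e9

RNR_CLASSES = ("Ia", "Ib", "II", "III")
CLASS_MEMBERS = {
    cls: tuple(f for f in FAMILIES if CLASS_OF_FAMILY[f] == cls) for cls in RNR_CLASSES
}


@dataclass
class Metagenome:
    """A de-replicated read set."""

    id: str
    reads: list[SequenceRecord]
    size_nt: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError(f"metagenome {self.id}: duplicate read ids")
        self.size_nt = sum(len(r) for r in self.reads)


@dataclass
class AbundanceMatrix:
    """Normalized abundance (metagenome x gene family + class aggregates)."""

    values: pd.DataFrame  # normalized, columns = families + class aggregates
    raw_counts: pd.DataFrame  # integer, columns = families
    excluded: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = pd.Series(False, index=self.values.index)


# ---------------------------------------------------------------------------
# De-replication and ORF calling
# ---------------------------------------------------------------------------

def dereplicate(reads: Sequence[SequenceRecord], metagenome_id: str = "metagenome",
                prefix_duplicates: bool = False) -> Metagenome:
    """Remove exact full-length duplicate sequences (case-insensitive).

    The first occurrence is kept. With ``prefix_duplicates`` a read that is an
    exact prefix of an earlier, longer read is also removed (454-style
    artificial duplicates); default off.
    """
    kept: list[SequenceRecord] = []
    seen: set[str] = set()
    for r in reads:
        key = r.seq.upper()
        if key in seen:
            continue
        if prefix_duplicates and any(k.startswith(key) for k in seen):
            continue
        seen.add(key)
        kept.append(r)
    return Metagenome(id=metagenome_id, reads=kept)


def call_read_orfs(read: SequenceRecord, min_aa: int = DEFAULT_MIN_AA) -> list[SequenceRecord]:
    """Protein fragments from all six frames of a read.

    Maximal stop-free runs, edge-truncated runs allowed (no start codon
    required), kept when at least ``min_aa`` residues.
    """
    out = []
    k = 0
    for strand, s in (("+", read.seq), ("-", reverse_complement(read.seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            for run in prot.split("*"):
                if len(run) >= min_aa:
                    k += 1
                    out.append(
                        SequenceRecord(id=f"{read.id}|{strand}{frame}|{k}", seq=run)
                    )
    return out


# ---------------------------------------------------------------------------
# Counting and normalization
# ---------------------------------------------------------------------------

def count_hits(
    metagenome: Metagenome,
    profiles: Sequence[ProfileModel],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_aa: int = DEFAULT_MIN_AA,
) -> dict[str, int]:
    """Raw hit counts per family: each ORF's best family, counted once.

    The best family is the lowest E-value (ties: higher score, then
    lexicographic family — the same tie-breaks as genome curation), counted
    only when E <= cutoff. ``n_comparisons`` = (ORFs) x (profiles).
    """
    for p in profiles:
        if p.calib is None:
            raise ValueError(f"profile {p.family} must be calibrated")
    orfs = [o for r in metagenome.reads for o in call_read_orfs(r, min_aa=min_aa)]
    counts = {p.family: 0 for p in profiles}
    if not orfs:
        return counts
    n_comparisons = len(orfs) * len(profiles)
    for orf in orfs:
        idx = encode_protein(orf.seq)
        best: Optional[tuple[float, float, str]] = None  # (evalue, -score, family)
        for p in profiles:
            hits = _score_local_all(p, idx.copy(), max_hits=1)
            if not hits:
                continue
            score = hits[0][0]
            ev = evalue(p, score, n_comparisons)
            cand = (ev, -score, p.family)
            if best is None or cand < best:
                best = cand
        if best is not None and best[0] <= cutoff:
            counts[best[2]] += 1
    return counts


def normalize(
    raw_counts: pd.DataFrame,
    sizes_nt: pd.Series,
    profile_lengths: dict[str, int],
) -> AbundanceMatrix:
    """Normalize raw counts by metagenome size and gene length.

    ``A = C / (size_nt * L_gene) * 1e9`` per gene column; class aggregate
    columns are exact sums over member genes.
    """
    if (sizes_nt <= 0).any():
        raise ValueError("metagenome sizes must be positive")
    fams = [f for f in FAMILIES if f in raw_counts.columns]
    vals = pd.DataFrame(index=raw_counts.index, dtype=float)
    for f in fams:
        L = profile_lengths[f]
        if L <= 0:
            raise ValueError(f"profile length for {f} must be positive")
        vals[f] = raw_counts[f] / (sizes_nt * L) * ABUNDANCE_SCALE
    for cls in RNR_CLASSES:
        members = [f for f in CLASS_MEMBERS[cls] if f in vals.columns]
        vals[f"class_{cls}"] = vals[members].sum(axis=1) if members else 0.0
    return AbundanceMatrix(values=vals, raw_counts=raw_counts[fams].copy())


def exclude_sparse(matrix: AbundanceMatrix, min_hits: int = DEFAULT_MIN_HITS) -> AbundanceMatrix:
    """Flag metagenomes with fewer than ``min_hits`` total raw hits.

    Values are retained; only the flag changes (default: a row with <= 5
    total hits is excluded).
    """
    totals = matrix.raw_counts.sum(axis=1)
    matrix.excluded = totals <= (min_hits - 1)
    return matrix


def heatmap_matrix(
    matrix: AbundanceMatrix,
    path: Optional[str | Path] = None,
    render: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Class-aggregate table over non-excluded metagenomes (heatmap input).

    Optionally written as TSV (numeric, bit-stable via repr-precision floats)
    and rendered as a cosmetic matplotlib heatmap.
    """
    cols = [f"class_{cls}" for cls in RNR_CLASSES]
    out = matrix.values.loc[~matrix.excluded, cols].copy()
    out.index.name = "metagenome"
    if path is not None:
        out.to_csv(path, sep="\t", float_format="%.12g", index_label="metagenome")
    if render is not None and len(out):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(out))))
        im = ax.imshow(out.to_numpy(), aspect="auto", cmap="coolwarm")
        ax.set_xticks(range(len(cols)), [c.removeprefix("class_") for c in cols])
        ax.set_yticks(range(len(out)), out.index)
        fig.colorbar(im, ax=ax, label="normalized abundance")
        fig.tight_layout()
        fig.savefig(render, dpi=120)
        plt.close(fig)
    return out


def read_heatmap_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="metagenome")


def profile_abundance(
    metagenomes: Sequence[Metagenome],
    profiles: Sequence[ProfileModel],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_aa: int = DEFAULT_MIN_AA,
    min_hits: int = DEFAULT_MIN_HITS,
) -> AbundanceMatrix:
    """End-to-end: counts, normalization and sparse-row flagging."""
    raw = pd.DataFrame(
        [count_hits(m, profiles, cutoff=cutoff, min_aa=min_aa) for m in metagenomes],
        index=[m.id for m in metagenomes],
    )
    sizes = pd.Series([m.size_nt for m in metagenomes], index=[m.id for m in metagenomes])
    lengths = {p.family: p.L for p in profiles}
    return exclude_sparse(normalize(raw, sizes, lengths), min_hits=min_hits)
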