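"""Readers and writers for every external representation the pipeline touches.

One internal coordinate convention is used throughout the package: 0-based,
half-open intervals on the forward strand, with strand stored separately.
Conversions to and from 1-based inclusive conventions (GenBank, HMMER profile
columns) happen only at these I/O boundaries.

Supported formats:

* multi-record FASTA (nucleotide or amino acid),
* a minimal GenBank flat-file dialect (LOCUS / FEATURES with CDS / ORIGIN),
* HMMER3 per-domain tabular output (``domtblout``),
* newick trees with branch lengths (via dendropy),
* TSV metadata tables with a header row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy

logger = logging.getLogger("rnrscape")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

FAMILIES = ("nrdA", "nrdB", "nrdD", "nrdE", "nrdF", "nrdG", "nrdH", "nrdI", "nrdJ")

PHAGE_FAMILIES = ("Myoviridae", "Siphoviridae", "Podoviridae", "unclassified")
ENVIRONMENTS = ("marine", "freshwater", "sewage", "hot_spring", "soil", "food", "unknown")
OXYGEN_CLASSES = ("aerobe", "facultative", "anaerobe", "unknown")


@dataclass
class SequenceRecord:
    """A named sequence (nucleotide or amino acid), upper-cased on read."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneFeature:
    """A CDS locus on a genome; interval is 0-based half-open in nucleotides."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.translation is not None and len(self.translation) * 3 > self.end - self.start + 3:
            raise ValueError(f"translation longer than locus for {self.gene_id}")


@dataclass
class GenomeRecord:
    """A genome sequence plus its ordered CDS features."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    metadata_key: str = ""

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.gene_id} [{f.start}, {f.end}) outside genome "
                    f"{self.id} of length {len(self.seq)}"
                )
        if not self.metadata_key:
            self.metadata_key = self.id


@dataclass
class MetadataRow:
    """One phage's metadata: taxonomy, isolation source, host oxygen use."""

    genome_id: str
    family: str = "unclassified"
    environment: str = "unknown"
    host: str = ""
    oxygen: str = "unknown"

    def __post_init__(self) -> None:
        if self.family not in PHAGE_FAMILIES:
            logger.warning("unknown phage family %r for %s -> 'unclassified'", self.family, self.genome_id)
            self.family = "unclassified"
        if self.environment not in ENVIRONMENTS:
            logger.warning("unknown environment %r for %s -> 'unknown'", self.environment, self.genome_id)
            self.environment = "unknown"
        if self.oxygen not in OXYGEN_CLASSES:
            logger.warning("unknown oxygen class %r for %s -> 'unknown'", self.oxygen, self.genome_id)
            self.oxygen = "unknown"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, nucleotide: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased; when ``nucleotide`` is true, ``U`` is mapped to
    ``T``. Duplicate ids and empty sequences are errors.
    """
    text = Path(path).read_text()
    if not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: not a FASTA file (no leading '>')")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        rid, _, desc = header.partition(" ")
        seq = "".join(chunks).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, seq=seq, description=desc.strip()))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            chunks = []
        else:
            chunks.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank-lite
# ---------------------------------------------------------------------------

_LOCATION_RE = re.compile(r"(\d+)\.\.(\d+)")


def _parse_location(loc: str) -> tuple[list[tuple[int, int]], str]:
    """Parse a CDS location string of the minimal dialect.

    Handles ``a..b``, ``complement(...)`` and ``join(...)`` of plain segments.
    Returns 1-based inclusive segments plus the strand.
    """
    strand = "+"
    loc = loc.strip()
    if loc.startswith("complement(") and loc.endswith(")"):
        strand = "-"
        loc = loc[len("complement(") : -1]
    if loc.startswith("join(") and loc.endswith(")"):
        loc = loc[len("join(") : -1]
    segments = [(int(a), int(b)) for a, b in _LOCATION_RE.findall(loc)]
    if not segments:
        raise ValueError(f"unparseable CDS location {loc!r}")
    return segments, strand


def read_genbank_lite(path: str | Path) -> GenomeRecord:
    """Read the minimal GenBank flat-file dialect (LOCUS, CDS features, ORIGIN).

    1-based inclusive coordinates become 0-based half-open; ``complement``
    becomes strand '-'; ``join`` segments become separate features sharing a
    gene_id. Qualifiers other than /gene, /product, /translation are ignored.
    """
    lines = Path(path).read_text().splitlines()
    genome_id = ""
    features_raw: list[tuple[str, dict[str, str]]] = []
    seq_chunks: list[str] = []
    mode = ""
    cur_loc: Optional[str] = None
    cur_quals: dict[str, str] = {}
    cur_key: Optional[str] = None

    def _close_feature() -> None:
        nonlocal cur_loc, cur_quals
        if cur_loc is not None:
            features_raw.append((cur_loc, cur_quals))
        cur_loc, cur_quals = None, {}

    for line in lines:
        if line.startswith("LOCUS"):
            parts = line.split()
            genome_id = parts[1] if len(parts) > 1 else "genome"
        elif line.startswith("FEATURES"):
            mode = "features"
        elif line.startswith("ORIGIN"):
            _close_feature()
            mode = "origin"
        elif line.startswith("//"):
            mode = ""
        elif mode == "features":
            stripped = line.strip()
            if not stripped:
                continue
            if line[:21].strip():  # a feature key in the key column
                _close_feature()
                key, _, loc = stripped.partition(" ")
                cur_key = key
                if key == "CDS":
                    cur_loc = loc.strip()
                else:
                    logger.debug("ignoring feature of type %s", key)
            elif cur_key == "CDS":
                if stripped.startswith("/"):
                    name, _, value = stripped[1:].partition("=")
                    cur_quals[name] = value.strip().strip('"')
                    cur_quals["_last"] = name
                elif cur_loc is not None and "_last" not in cur_quals:
                    cur_loc += stripped  # continuation of a long location
                else:
                    last = cur_quals.get("_last")
                    if last:  # continuation of a multi-line qualifier value
                        cur_quals[last] += stripped.rstrip('"')
        elif mode == "origin":
            seq_chunks.append("".join(c for c in line if c.isalpha()))

    seq = "".join(seq_chunks).upper().replace("U", "T")
    features: list[GeneFeature] = []
    for idx, (loc, quals) in enumerate(features_raw):
        segments, strand = _parse_location(loc)
        gene_id = quals.get("gene") or quals.get("locus_tag") or f"{genome_id}_cds{idx + 1}"
        translation = quals.get("translation", "").replace('"', "") or None
        for a, b in segments:
            if not (1 <= a <= b <= len(seq)):
                raise ValueError(f"{path}: CDS {gene_id} coordinates {a}..{b} outside ORIGIN length {len(seq)}")
        for seg_i, (a, b) in enumerate(segments):
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    start=a - 1,
                    end=b,
                    strand=strand,
                    product=quals.get("product", ""),
                    # a join()'s translation spans all segments; attach to the first only
                    translation=translation if (seg_i == 0 and len(segments) == 1) else None,
                )
            )
    return GenomeRecord(id=genome_id or "genome", seq=seq, features=features)


def write_genbank_lite(genome: GenomeRecord, path: str | Path) -> None:
    """Emit the same minimal dialect :func:`read_genbank_lite` consumes."""
    with open(path, "w") as fh:
        fh.write(f"LOCUS       {genome.id} {len(genome.seq)} bp DNA linear PHG\n")
        fh.write("FEATURES             Location/Qualifiers\n")
        for f in genome.features:
            loc = f"{f.start + 1}..{f.end}"
            if f.strand == "-":
                loc = f"complement({loc})"
            fh.write(f"     CDS             {loc}\n")
            fh.write(f'                     /gene="{f.gene_id}"\n')
            if f.product:
                fh.write(f'                     /product="{f.product}"\n')
            if f.translation:
                fh.write(f'                     /translation="{f.translation}"\n')
        fh.write("ORIGIN\n")
        seq = genome.seq.lower()
        for i in range(0, len(seq), 60):
            block = seq[i : i + 60]
            groups = " ".join(block[j : j + 10] for j in range(0, len(block), 10))
            fh.write(f"{i + 1:>9} {groups}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path) -> list["Hit"]:
    """Parse HMMER3 per-domain tabular output into :class:`Hit` objects.

    Field mapping: target name -> query_id, query name -> family, i-Evalue ->
    evalue, domain bit score -> score, hmm from/to -> profile columns (kept
    1-based inclusive), ali from/to -> 0-based half-open sequence coords.
    """
    from .profile_engine import Hit  # local import to avoid a cycle

    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(f"{path}:{lineno}: expected >= 22 columns, found {len(fields)}")
            try:
                evalue = float(fields[12])
                score = float(fields[13])
                pf_from, pf_to = int(fields[15]), int(fields[16])
                ali_from, ali_to = int(fields[17]), int(fields[18])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            hits.append(
                Hit(
                    query_id=fields[0],
                    family=fields[3],
                    score=score,
                    evalue=evalue,
                    q_from=ali_from - 1,
                    q_to=ali_to,
                    pf_from=pf_from,
                    pf_to=pf_to,
                    strand="+",
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy tree (unrooted)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from None
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths rounded to 6 decimals (canonical form)."""
    t = tree.clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.length is not None:
            edge.length = round(float(edge.length), 6)
    return t.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, MetadataRow]:
    """Read the phage metadata TSV (header required).

    Unknown category values are coerced to 'unknown'/'unclassified' with a
    warning rather than an error, mirroring the incompleteness of real phage
    metadata.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty metadata file")
    header = [h.strip() for h in lines[0].split("\t")]
    required = {"genome_id", "family", "environment", "host", "oxygen"}
    if not required.issubset(header):
        raise ValueError(f"{path}: metadata header must contain {sorted(required)}")
    idx = {name: header.index(name) for name in required}
    rows: dict[str, MetadataRow] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        row = MetadataRow(
            genome_id=fields[idx["genome_id"]].strip(),
            family=fields[idx["family"]].strip(),
            environment=fields[idx["environment"]].strip(),
            host=fields[idx["host"]].strip(),
            oxygen=fields[idx["oxygen"]].strip(),
        )
        rows[row.genome_id] = row
    return rows


def write_metadata(rows: Iterable[MetadataRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tfamily\tenvironment\thost\toxygen\n")
        for r in rows:
            fh.write(f"{r.genome_id}\t{r.family}\t{r.environment}\t{r.host}\t{r.oxygen}\n")
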