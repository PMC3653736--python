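"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of the study system rather
than real phage biology: seed alignments per RNR gene family (stand-ins for
curated family profiles), annotated phage genomes carrying RNR genes in
configured class combinations and gene orders (including split genes with
intervening sequences and planted motifs), decoy genes, metadata rows that
follow environment/oxygen trends, error-bearing short reads sampled from
genome pools, and pairs of gene alignments evolved along shared or
discordant trees.

Every generator is a pure function of (configuration, seed): identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import GeneFeature, GenomeRecord, MetadataRow, SequenceRecord, write_fasta
from .profile_engine import AMINO_ACIDS, CODON_TABLE, reverse_complement, six_frame_orfs

#: Match-region lengths per family (residues), scaled to desk size while
#: preserving relative lengths (nrdA/nrdJ/nrdD long, nrdH/nrdG short).
FAMILY_LENGTHS = {
    "nrdA": 260, "nrdB": 160, "nrdE": 240, "nrdF": 150, "nrdH": 70,
    "nrdI": 110, "nrdJ": 260, "nrdD": 240, "nrdG": 90,
}

LETTER_TO_FAMILY = {f.removeprefix("nrd"): f for f in FAMILY_LENGTHS}

#: Gene-order templates per class combination (letters are family tokens
#: with the 'nrd' prefix stripped). The II+III combination is never
#: generated by default.
ORDER_TEMPLATES = {
    "I": ("AB", "IEFH", "IEF"),
    "II": ("J",),
    "III": ("GD",),
    "I+III": ("GDBA", "ABGD"),
    "I+II": ("JH", "JIEF"),
}

#: Default strata: (phage family, environment, host oxygen, combo -> prob, weight).
DEFAULT_STRATA = (
    ("Myoviridae", "marine", "aerobe", {"I": 0.5, "II": 0.5}, 0.35),
    ("Myoviridae", "sewage", "facultative", {"I": 0.4, "I+III": 0.6}, 0.30),
    ("Siphoviridae", "soil", "aerobe", {"II": 0.5, "I+II": 0.5}, 0.25),
    ("Myoviridae", "sewage", "anaerobe", {"III": 1.0}, 0.10),
)

#: Literal exemplars matching the packaged motif patterns, used for planting.
MOTIF_EXEMPLARS = {
    "HNH_HEG": "HNHAGKSDLWQRTSYN",
    "GIY_YIG": "GIYACDEFGHIKYIG",
    "LAGLIDADG": "LAGLIDADG",
    "INTEIN_NTERM": "CLSGETV",
    "INTEIN_CTERM": "VHNCLAG",
}

_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()
STOP_CODONS = tuple(_CODONS_FOR_AA["*"])


@dataclass
class SplitSpec:
    """A planted split gene: fragment count, signed junction lengths (nt),
    and an optional motif name planted in the first positive junction."""

    family: str
    n_fragments: int
    junctions: tuple[int, ...]
    motif: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.junctions) != self.n_fragments - 1:
            raise ValueError("need n_fragments - 1 junctions")


@dataclass
class ScenarioConfig:
    n_genomes: int = 20
    divergence: float = 0.15  # per-site substitution prob from family consensus
    gc: float = 0.5
    family_lengths: dict[str, int] = field(default_factory=lambda: dict(FAMILY_LENGTHS))
    msa_rows: int = 12
    msa_divergence: float = 0.15
    strata: tuple = DEFAULT_STRATA
    split_specs: tuple[SplitSpec, ...] = ()
    intergenic_gap: int = 100
    n_decoys: int = 3
    decoy_len: tuple[int, int] = (150, 250)
    flank: int = 300

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must lie in [0, 0.5)")
        for _, _, _, probs, _ in self.strata:
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("stratum combo probabilities must sum to 1")


@dataclass
class PlantedCall:
    family: str
    start: int
    end: int
    strand: str
    fragment: Optional[str] = None  # e.g. "nrdD-b" for split fragments


@dataclass
class GenomeTruth:
    genome_id: str
    calls: list[PlantedCall]
    combo: str
    order_string: str
    splits: list[SplitSpec]
    metadata: MetadataRow
    overlaps: list[tuple[int, int]] = field(default_factory=list)  # negative-junction regions


@dataclass
class MetagenomeTruth:
    id: str
    sources: list[str]  # source genome id per emitted read
    n_duplicate_reads: int = 0


# ---------------------------------------------------------------------------
# Low-level sequence helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < divergence:
            choices = [a for a in AMINO_ACIDS if a != c]
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(c)
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice (codon bias is irrelevant here)."""
    return "".join(
        _CODONS_FOR_AA[aa][int(rng.integers(0, len(_CODONS_FOR_AA[aa])))] for aa in protein
    )


def _random_nt(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


#: Stop cassette: TAA at offsets 0/4/8 stops every forward frame; TTA at
#: offsets 11/15/19 puts TAA in every reverse-complement frame.
_STOP_CASSETTE = "TAAGTAAGTAA" + "TTACTTACTTA"


def _orf_free_filler(rng: np.random.Generator, length: int, min_codons: int = 30) -> str:
    """Random-looking nt with no stop-free run of >= min_codons in any frame.

    Stop cassettes are interleaved with short random chunks so every reading
    frame (both strands) is interrupted at least every ~25 codons; short
    non-coding spacers really are non-coding at the ORF caller's threshold.
    """
    if length < 3 * min_codons:
        return _random_nt(rng, length)
    pieces = [_random_nt(rng, 30)]
    n = 30
    while n < length:
        pieces.append(_STOP_CASSETTE)
        pieces.append(_random_nt(rng, 45))
        n += len(_STOP_CASSETTE) + 45
    cand = "".join(pieces)[:length]
    assert not six_frame_orfs(cand, min_codons=min_codons)
    return cand


def _motif_junction(rng: np.random.Generator, length: int, motif: str) -> str:
    """Junction filler containing one planted ORF carrying the motif exemplar."""
    exemplar = MOTIF_EXEMPLARS[motif]
    orf_aa_len = max(34, len(exemplar) + 10)
    orf_nt_len = 3 * orf_aa_len
    if length < orf_nt_len + 12:
        raise ValueError(f"junction of {length} nt too short to plant motif {motif}")
    flanks = length - orf_nt_len - 6  # two in-frame stop codons bracket the ORF
    left = flanks // 2
    prot = list(_random_protein(rng, orf_aa_len))
    ins = int(rng.integers(0, orf_aa_len - len(exemplar) + 1))
    prot[ins : ins + len(exemplar)] = exemplar
    orf_nt = _reverse_translate("".join(prot), rng)
    lpad = _orf_free_filler(rng, left, min_codons=30) if left else ""
    rpad = _orf_free_filler(rng, flanks - left, min_codons=30) if flanks - left else ""
    return lpad + "TAA" + orf_nt + "TAA" + rpad


# ---------------------------------------------------------------------------
# Seed alignments
# ---------------------------------------------------------------------------

def gen_seed_msa(
    family: str,
    L: int,
    n_rows: int,
    divergence: float,
    seed: int,
    gap_column_fraction: float = 0.05,
) -> tuple[list[SequenceRecord], str]:
    """A synthetic seed alignment plus its ancestral (consensus) sequence.

    Rows derive from a background-sampled ancestor by i.i.d. per-site
    substitution (to one of the 19 other residues) with probability
    ``divergence``; about 5% of columns are converted to majority-gap
    columns so profile construction exercises its match-column rule.
    """
    if L < 30 or n_rows < 2:
        raise ValueError("need L >= 30 and n_rows >= 2")
    rng = np.random.default_rng(seed)
    ancestral = _random_protein(rng, L)
    rows = [list(_mutate_protein(ancestral, divergence, rng)) for _ in range(n_rows)]
    n_gap_cols = int(round(gap_column_fraction * L))
    gap_cols = rng.choice(L, size=n_gap_cols, replace=False) if n_gap_cols else []
    for j in gap_cols:
        gapped = rng.choice(n_rows, size=max(1, int(0.7 * n_rows)), replace=False)
        for i in gapped:
            rows[i][j] = "-"
    records = [
        SequenceRecord(id=f"{family}_seed{i + 1:02d}", seq="".join(r)) for i, r in enumerate(rows)
    ]
    return records, ancestral


def gen_family_seeds(
    config: ScenarioConfig, seed: int, out_dir: Optional[str | Path] = None
) -> tuple[dict[str, list[SequenceRecord]], dict[str, str]]:
    """Seed alignments (and ancestral consensi) for all nine families."""
    msas: dict[str, list[SequenceRecord]] = {}
    ancestors: dict[str, str] = {}
    for k, (family, L) in enumerate(sorted(config.family_lengths.items())):
        msa, anc = gen_seed_msa(family, L, config.msa_rows, config.msa_divergence, seed + 100 + k)
        msas[family] = msa
        ancestors[family] = anc
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            write_fasta(msa, Path(out_dir) / f"{family}.afa")
    return msas, ancestors


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def _combo_of_template(template: str) -> str:
    from .curation import class_of

    classes = set()
    for letter in template:
        cls = class_of(LETTER_TO_FAMILY[letter])
        classes.add("I" if cls in ("Ia", "Ib") else cls)
    return "+".join(sorted(classes, key=("I", "II", "III").index))


def gen_genome(
    config: ScenarioConfig,
    ancestors: dict[str, str],
    template: str,
    seed: int,
    genome_id: str = "synth_genome",
    metadata: Optional[MetadataRow] = None,
    split_specs: Sequence[SplitSpec] = (),
) -> tuple[GenomeRecord, GenomeTruth]:
    """One annotated genome realizing a gene-order template.

    Genes are drawn from the family consensi at the configured divergence and
    reverse-translated; split specs replace the matching gene with fragments
    separated by the configured signed junctions (negative junctions overlap:
    the later fragment's nucleotides take precedence there, and the earlier
    fragment's stored translation is authoritative for its locus). Decoy
    hypothetical-protein genes are added downstream.
    """
    rng = np.random.default_rng(seed)
    splits_by_family = {s.family: s for s in split_specs}
    writes: list[tuple[int, str]] = []  # (position, nt) applied in order
    features: list[GeneFeature] = []
    planted: list[PlantedCall] = []
    overlaps: list[tuple[int, int]] = []
    used_splits: list[SplitSpec] = []

    cursor = config.flank
    for letter in template:
        family = LETTER_TO_FAMILY[letter]
        protein = _mutate_protein(ancestors[family], config.divergence, rng)
        spec = splits_by_family.get(family)
        if spec is not None and spec.n_fragments >= 2:
            used_splits.append(spec)
            bounds = np.linspace(0, len(protein), spec.n_fragments + 1).astype(int)
            frag_prots = [protein[bounds[k] : bounds[k + 1]] for k in range(spec.n_fragments)]
            motif_pending = spec.motif
            for k, fp in enumerate(frag_prots):
                nt = _reverse_translate(fp, rng) + "TAA"
                start, end = cursor, cursor + len(nt)
                writes.append((start, nt))
                label = f"{family}-{'abcdefgh'[k]}"
                features.append(
                    GeneFeature(
                        gene_id=f"{genome_id}_{label}", start=start, end=end, strand="+",
                        product=f"ribonucleotide reductase {family} fragment", translation=fp,
                    )
                )
                planted.append(PlantedCall(family, start, end, "+", fragment=label))
                cursor = end
                if k < spec.n_fragments - 1:
                    j = spec.junctions[k]
                    if j < 0:
                        overlaps.append((end + j, end))
                        cursor = end + j
                    elif j > 0:
                        if motif_pending is not None and j >= 120:
                            filler = _motif_junction(rng, j, motif_pending)
                            motif_pending = None
                        else:
                            filler = _orf_free_filler(rng, j)
                        writes.append((end, filler))
                        cursor = end + j
        else:
            nt = _reverse_translate(protein, rng) + "TAA"
            start, end = cursor, cursor + len(nt)
            writes.append((start, nt))
            features.append(
                GeneFeature(
                    gene_id=f"{genome_id}_{family}", start=start, end=end, strand="+",
                    product=f"ribonucleotide reductase {family}", translation=protein,
                )
            )
            planted.append(PlantedCall(family, start, end, "+"))
            cursor = end
        cursor += config.intergenic_gap

    for d in range(config.n_decoys):
        dlen = int(rng.integers(config.decoy_len[0], config.decoy_len[1] + 1))
        dprot = _random_protein(rng, dlen)
        nt = _reverse_translate(dprot, rng) + "TAA"
        cursor += config.intergenic_gap
        start, end = cursor, cursor + len(nt)
        writes.append((start, nt))
        features.append(
            GeneFeature(
                gene_id=f"{genome_id}_decoy{d + 1}", start=start, end=end, strand="+",
                product="hypothetical protein", translation=dprot,
            )
        )
        cursor = end

    total = cursor + config.flank
    seq = list(_random_nt(rng, total, gc=config.gc))
    for pos, nt in writes:
        seq[pos : pos + len(nt)] = nt
    genome = GenomeRecord(id=genome_id, seq="".join(seq), features=features)

    meta = metadata or MetadataRow(genome_id=genome_id)
    meta = replace(meta, genome_id=genome_id)
    order = sorted(planted, key=lambda c: (c.start, c.end))
    truth = GenomeTruth(
        genome_id=genome_id,
        calls=planted,
        combo=_combo_of_template(template),
        order_string="".join(c.family.removeprefix("nrd") for c in order),
        splits=used_splits,
        metadata=meta,
        overlaps=overlaps,
    )
    return genome, truth


def gen_cohort(
    config: ScenarioConfig, seed: int, ancestors: Optional[dict[str, str]] = None
) -> tuple[list[GenomeRecord], list[GenomeTruth]]:
    """A seeded cohort of genomes drawn from the configured strata."""
    rng = np.random.default_rng(seed)
    if ancestors is None:
        _, ancestors = gen_family_seeds(config, seed)
    weights = np.array([s[4] for s in config.strata], dtype=float)
    weights /= weights.sum()
    genomes: list[GenomeRecord] = []
    truths: list[GenomeTruth] = []
    for i in range(config.n_genomes):
        stratum = config.strata[int(rng.choice(len(config.strata), p=weights))]
        phage_family, environment, oxygen, combo_probs, _ = stratum
        combos = sorted(combo_probs)
        probs = np.array([combo_probs[c] for c in combos])
        combo = combos[int(rng.choice(len(combos), p=probs / probs.sum()))]
        templates = ORDER_TEMPLATES[combo]
        template = templates[int(rng.integers(0, len(templates)))]
        gid = f"synth_{i + 1:04d}"
        meta = MetadataRow(
            genome_id=gid, family=phage_family, environment=environment,
            host=f"host_{i + 1:04d}", oxygen=oxygen,
        )
        genome, truth = gen_genome(
            config, ancestors, template, seed=int(rng.integers(0, 2**31 - 1)),
            genome_id=gid, metadata=meta, split_specs=config.split_specs,
        )
        genomes.append(genome)
        truths.append(truth)
    return genomes, truths


# ---------------------------------------------------------------------------
# Metagenomes
# ---------------------------------------------------------------------------

def gen_metagenome(
    pool: Sequence[GenomeRecord],
    depths: Sequence[float],
    n_reads: int,
    read_len_mean: int = 334,
    err: float = 0.01,
    dup_rate: float = 0.0,
    seed: int = 0,
    metagenome_id: str = "meta",
) -> tuple[list[SequenceRecord], MetagenomeTruth]:
    """Error-bearing short reads sampled from a genome pool.

    Reads are drawn from genomes proportional to depth; lengths follow
    round(Normal(mean, 0.15 mean)) clipped to [60, 2 mean]; substitution
    errors are i.i.d. at rate ``err``; with probability ``dup_rate`` a read
    is an exact copy of an earlier read (exercises de-replication).
    """
    if not pool:
        raise ValueError("genome pool is empty")
    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=float)
    p = depths / depths.sum()
    reads: list[SequenceRecord] = []
    sources: list[str] = []
    n_dups = 0
    for k in range(n_reads):
        if reads and rng.random() < dup_rate:
            src = reads[int(rng.integers(0, len(reads)))]
            reads.append(SequenceRecord(id=f"{metagenome_id}_r{k + 1:06d}", seq=src.seq,
                                        description="duplicate"))
            sources.append(src.description or "duplicate")
            n_dups += 1
            continue
        gi = int(rng.choice(len(pool), p=p))
        genome = pool[gi]
        rl = int(round(rng.normal(read_len_mean, 0.15 * read_len_mean)))
        rl = max(60, min(rl, 2 * read_len_mean, len(genome.seq)))
        pos = int(rng.integers(0, len(genome.seq) - rl + 1))
        frag = genome.seq[pos : pos + rl]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        if err > 0:
            chars = list(frag)
            for i in range(len(chars)):
                if rng.random() < err:
                    alts = [b for b in "ACGT" if b != chars[i]]
                    chars[i] = alts[int(rng.integers(0, 3))]
            frag = "".join(chars)
        reads.append(SequenceRecord(id=f"{metagenome_id}_r{k + 1:06d}", seq=frag,
                                    description=genome.id))
        sources.append(genome.id)
    return reads, MetagenomeTruth(id=metagenome_id, sources=sources, n_duplicate_reads=n_dups)


# ---------------------------------------------------------------------------
# Gene trees (congruence fixtures)
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: Optional[str] = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def random_tree(labels: Sequence[str], rng: np.random.Generator,
                bl_range: tuple[float, float] = (0.08, 0.3)) -> _Node:
    """A random binary tree over the labels (random sequential coalescence)."""
    nodes = [_Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        merged = _Node(children=[
            (a, float(rng.uniform(*bl_range))),
            (b, float(rng.uniform(*bl_range))),
        ])
        nodes.pop(j)
        nodes.pop(i)
        nodes.append(merged)
    return nodes[0]


def tree_distances(root: _Node) -> dict[tuple[str, str], float]:
    """Additive leaf-to-leaf path distances of a branch-length tree."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: _Node) -> dict[str, float]:
        if not node.children:
            return {node.label: 0.0}
        below: list[dict[str, float]] = []
        for child, bl in node.children:
            d = {l: x + bl for l, x in walk(child).items()}
            below.append(d)
        for ai in range(len(below)):
            for bi in range(ai + 1, len(below)):
                for la, da in below[ai].items():
                    for lb, db in below[bi].items():
                        key = (min(la, lb), max(la, lb))
                        dists[key] = da + db
        out: dict[str, float] = {}
        for d in below:
            out.update(d)
        return out

    walk(root)
    return dists


def _evolve(root: _Node, n_sites: int, rng: np.random.Generator) -> dict[str, str]:
    """Evolve a protein along the tree; substitution prob 1 - exp(-t) per site."""
    seqs: dict[str, str] = {}
    root_seq = _random_protein(rng, n_sites)

    def walk(node: _Node, seq: str) -> None:
        if not node.children:
            seqs[node.label] = seq
            return
        for child, bl in node.children:
            p = 1 - np.exp(-bl)
            walk(child, _mutate_protein(seq, p, rng))

    walk(root, root_seq)
    return seqs


def gen_gene_trees(
    n_genomes: int,
    discordant: bool,
    seed: int,
    n_sites: int = 400,
) -> tuple[list[SequenceRecord], list[SequenceRecord], str, str]:
    """Two gene alignments evolved along shared or discordant planted trees.

    Returns (family-1 records, family-2 records, planted newick 1, planted
    newick 2); record ids are genome ids, shared across the two sets.
    """
    if n_genomes < 6:
        raise ValueError("need at least 6 genomes")
    rng = np.random.default_rng(seed)
    labels = [f"g{i + 1:02d}" for i in range(n_genomes)]
    t1 = random_tree(labels, rng)
    if discordant:
        from .phylo_lite import rf_distance
        from .formats_io import read_newick

        for _ in range(50):
            t2 = random_tree(labels, rng)
            raw, _ = rf_distance(read_newick(t1.newick() + ";"), read_newick(t2.newick() + ";"))
            if raw > 0:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a discordant topology")
    else:
        t2 = t1
    seqs1 = _evolve(t1, n_sites, rng)
    seqs2 = _evolve(t2, n_sites, rng)
    recs1 = [SequenceRecord(id=l, seq=seqs1[l]) for l in labels]
    recs2 = [SequenceRecord(id=l, seq=seqs2[l]) for l in labels]
    return recs1, recs2, t1.newick() + ";", t2.newick() + ";"
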