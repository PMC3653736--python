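"""Per-family scoring profiles: construction, local alignment, E-values, search.

A profile here is a position-specific scoring matrix (PSSM) of per-column
log-odds scores in bits, aligned to a query protein by Smith–Waterman-style
local dynamic programming with affine gap penalties. Statistical significance
comes from an empirical Gumbel (type-I extreme value) calibration against
background-sampled decoy sequences, so that a hit's E-value has the usual
meaning: the expected number of equal-or-better chance hits across all
profile × protein comparisons performed.

This deliberately trades the full profile-HMM machinery for a transparent,
fully testable scoring model; per-domain tables from an external HMMER run can
be imported through :func:`rnrscape.formats_io.read_domtblout` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .formats_io import FAMILIES, GeneFeature, GenomeRecord, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = {"-", "."}
EULER_GAMMA = 0.5772156649015329

DEFAULT_GAP_OPEN = 7.0  # bits
DEFAULT_GAP_EXTEND = 1.0  # bits
DEFAULT_EVALUE_CUTOFF = 1e-4
SUBOPT_FRACTION = 0.6  # report non-overlapping local hits >= this fraction of best
MIN_ORF_CODONS = 100  # six-frame search on unannotated genomes

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a nucleotide string; unknown codons become 'X'."""
    return "".join(CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """A PSSM for one RNR gene family with optional Gumbel calibration."""

    family: str
    S: np.ndarray  # (L, 20) log-odds scores in bits
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    calib: Optional[tuple[float, float]] = None  # (mu, beta)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.ndim != 2 or self.S.shape[1] != 20 or self.S.shape[0] < 1:
            raise ValueError("S must be an L x 20 matrix with L >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive bit costs")
        if np.any(np.asarray(self.background) <= 0):
            raise ValueError("background frequencies must be positive")
        if self.calib is not None and self.calib[1] <= 0:
            raise ValueError("Gumbel scale beta must be positive")

    @property
    def L(self) -> int:
        return int(self.S.shape[0])


@dataclass
class Hit:
    """A scored local match of a profile to a query sequence.

    ``q_from``/``q_to`` are 0-based half-open on the query (nucleotides for
    genome searches, residues for protein searches); ``pf_from``/``pf_to`` are
    1-based inclusive profile columns. For feature-based genome searches the
    annotated locus and protein-space envelope are carried alongside so that
    downstream curation can report gene boundaries.
    """

    query_id: str
    family: str
    score: float
    evalue: float
    q_from: int
    q_to: int
    pf_from: int
    pf_to: int
    strand: str = "+"
    frame: Optional[int] = None
    gene_id: Optional[str] = None
    locus_start: Optional[int] = None
    locus_end: Optional[int] = None
    aa_from: Optional[int] = None
    aa_to: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.score > 0 and not self.q_from < self.q_to:
            raise ValueError("q_from must be < q_to for a non-empty alignment")


def encode_protein(seq: str) -> np.ndarray:
    """Map residues to PSSM row indices; ambiguity codes get sentinel -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def build_profile(
    msa: Sequence[SequenceRecord],
    family: str,
    alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a PSSM from a seed alignment.

    Columns with a gap fraction strictly greater than ``max_gap_fraction`` are
    discarded as non-match columns. For a retained column with residue counts
    ``c_a`` over ``n`` non-gap rows the score for residue ``a`` is

        S[a] = log2( (c_a + alpha * b_a) / (n + alpha) / b_a )

    i.e. pseudocount-smoothed observed frequency over background frequency.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0].seq)
    if any(len(r.seq) != width for r in msa):
        raise ValueError("ragged alignment: rows differ in length")
    bg = np.full(20, 0.05) if background is None else np.asarray(background, dtype=float)

    columns = []
    n_rows = len(msa)
    for j in range(width):
        col = [r.seq[j].upper() for r in msa]
        gaps = sum(c in GAP_CHARS for c in col)
        if gaps / n_rows > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in col:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
        n = counts.sum()
        scores = np.log2((counts + alpha * bg) / (n + alpha) / bg)
        columns.append(scores)
    if not columns:
        raise ValueError(f"no match columns retained for family {family}")
    return ProfileModel(
        family=family,
        S=np.vstack(columns),
        gap_open=gap_open,
        gap_extend=gap_extend,
        background=bg,
    )


def consensus_sequence(profile: ProfileModel) -> str:
    """Highest-scoring residue per match column."""
    return "".join(AMINO_ACIDS[i] for i in profile.S.argmax(axis=1))


# ---------------------------------------------------------------------------
# Local alignment DP (numba kernels)
# ---------------------------------------------------------------------------

NEG_INF = -1e30


@njit(cache=True)
def _dp_fill(S, seq_idx, gap_open, gap_extend, mismatch):  # pragma: no cover - jitted
    """Fill affine-gap local DP matrices; returns (H, E, F).

    seq rows i = 1..n, profile columns j = 1..L. E = gap in the sequence
    (profile columns skipped), F = gap in the profile (residues skipped).
    Residues with index -1 (ambiguity codes) score ``mismatch[j]``.
    """
    n = seq_idx.shape[0]
    L = S.shape[0]
    H = np.zeros((n + 1, L + 1))
    E = np.full((n + 1, L + 1), NEG_INF)
    F = np.full((n + 1, L + 1), NEG_INF)
    for i in range(1, n + 1):
        ai = seq_idx[i - 1]
        for j in range(1, L + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            if ai >= 0:
                m = S[j - 1, ai]
            elif ai == -1:
                m = mismatch[j - 1]
            else:  # hard mask (-2): no alignment may cross this residue
                m = NEG_INF
            h = H[i - 1, j - 1] + m
            best = 0.0
            if h > best:
                best = h
            if e > best:
                best = e
            if f > best:
                best = f
            H[i, j] = best
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=True)
def _dp_score_only(S, seq_idx, gap_open, gap_extend, mismatch):  # pragma: no cover
    """Best local score only, O(L) memory; used for calibration decoys."""
    n = seq_idx.shape[0]
    L = S.shape[0]
    Hprev = np.zeros(L + 1)
    Fprev = np.full(L + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        ai = seq_idx[i - 1]
        Hcur = np.zeros(L + 1)
        Fcur = np.full(L + 1, NEG_INF)
        e = NEG_INF
        for j in range(1, L + 1):
            e = max(Hcur[j - 1] - gap_open, e - gap_extend)
            f = max(Hprev[j] - gap_open, Fprev[j] - gap_extend)
            m = S[j - 1, ai] if ai >= 0 else mismatch[j - 1]
            h = Hprev[j - 1] + m
            v = 0.0
            if h > v:
                v = h
            if e > v:
                v = e
            if f > v:
                v = f
            Hcur[j] = v
            Fcur[j] = f
            if v > best:
                best = v
        Hprev = Hcur
        Fprev = Fcur
    return best


def score_local(profile: ProfileModel, protein_seq: str) -> Hit:
    """Best local alignment of one protein against one profile (uncalibrated).

    Returns a score-0 hit with an empty span when no alignment scores
    positively.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    hits = _score_local_all(profile, encode_protein(protein_seq), max_hits=1)
    if hits:
        score, qf, qt, pf, pt = hits[0]
        return Hit(
            query_id="query", family=profile.family, score=score, evalue=0.0,
            q_from=qf, q_to=qt, pf_from=pf, pf_to=pt,
        )
    return Hit(
        query_id="query", family=profile.family, score=0.0, evalue=0.0,
        q_from=0, q_to=0, pf_from=0, pf_to=0,
    )


def _traceback(H, E, F, S, seq_idx, gap_open, gap_extend, mismatch, i, j):
    """Walk back from cell (i, j) to the start of its local alignment."""
    state = "H"
    while True:
        if state == "H":
            if H[i, j] <= 0:
                break
            ai = seq_idx[i - 1]
            if ai >= 0:
                m = S[j - 1, ai]
            elif ai == -1:
                m = mismatch[j - 1]
            else:
                m = NEG_INF
            if math.isclose(H[i, j], H[i - 1, j - 1] + m, rel_tol=1e-12, abs_tol=1e-9):
                i, j = i - 1, j - 1
                if H[i, j] <= 0:
                    break
            elif math.isclose(H[i, j], E[i, j], rel_tol=1e-12, abs_tol=1e-9):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if math.isclose(E[i, j], H[i, j - 1] - gap_open, rel_tol=1e-12, abs_tol=1e-9):
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            if math.isclose(F[i, j], H[i - 1, j] - gap_open, rel_tol=1e-12, abs_tol=1e-9):
                i -= 1
                state = "H"
            else:
                i -= 1
    return i, j


def _score_local_all(
    profile: ProfileModel,
    seq_idx: np.ndarray,
    max_hits: int = 8,
    subopt_fraction: float = SUBOPT_FRACTION,
) -> list[tuple[float, int, int, int, int]]:
    """Best hit plus non-overlapping suboptimal hits >= fraction of best.

    Implemented by iterative masking of the best hit's query span, so split
    genes produce one local hit per coding fragment. Returns tuples
    (score, q_from, q_to, pf_from 1-based, pf_to inclusive).
    """
    mismatch = profile.S.min(axis=1)
    idx = seq_idx.copy()
    out: list[tuple[float, int, int, int, int]] = []
    best_score = None
    for _ in range(max_hits):
        H, E, F = _dp_fill(profile.S, idx, profile.gap_open, profile.gap_extend, mismatch)
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        score = float(H[i, j])
        if score <= 0:
            break
        if best_score is None:
            best_score = score
        elif score < subopt_fraction * best_score:
            break
        i0, j0 = _traceback(H, E, F, profile.S, idx, profile.gap_open, profile.gap_extend, mismatch, i, j)
        out.append((score, i0, i, j0 + 1, j))
        idx[i0:i] = -2  # hard mask: kernels score -inf there, so later hits cannot overlap
    return out


def evalue(profile: ProfileModel, score: float, n_comparisons: int) -> float:
    """E-value of a bit score under the profile's Gumbel null.

    ``E = n * (1 - exp(-exp(-(score - mu) / beta)))`` — the expected number of
    comparisons (out of ``n_comparisons``) reaching the score by chance.
    """
    if profile.calib is None:
        raise ValueError(f"profile {profile.family} is not calibrated")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    mu, beta = profile.calib
    z = (score - mu) / beta
    # P(S >= s) under Gumbel; -expm1 keeps precision for large scores
    p = -math.expm1(-math.exp(-z))
    return n_comparisons * p


def calibrate(
    profile: ProfileModel,
    n_decoys: int = 200,
    decoy_len: int = 400,
    seed: int = 0,
) -> ProfileModel:
    """Fit a Gumbel null by method of moments on background-sampled decoys.

    beta = sd * sqrt(6) / pi, mu = mean - gamma * beta. Deterministic for a
    fixed seed.
    """
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys for a stable fit")
    rng = np.random.default_rng(seed)
    bg = np.asarray(profile.background) / np.asarray(profile.background).sum()
    mismatch = profile.S.min(axis=1)
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        idx = rng.choice(20, size=decoy_len, p=bg).astype(np.int64)
        scores[k] = _dp_score_only(profile.S, idx, profile.gap_open, profile.gap_extend, mismatch)
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError(f"degenerate profile {profile.family}: zero decoy score variance")
    beta = sd * math.sqrt(6.0) / math.pi
    mu = float(scores.mean()) - EULER_GAMMA * beta
    return replace(profile, calib=(mu, beta))


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit (exposed for calibration tests)."""
    scores = np.asarray(scores, dtype=float)
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance")
    beta = sd * math.sqrt(6.0) / math.pi
    return float(scores.mean()) - EULER_GAMMA * beta, beta


# ---------------------------------------------------------------------------
# Genome search
# ---------------------------------------------------------------------------

def six_frame_orfs(seq: str, min_codons: int = MIN_ORF_CODONS) -> list[tuple[str, int, int, str, int]]:
    """Maximal stop-free runs in all six frames.

    Returns (protein, nt_start, nt_end, strand, frame) with nucleotide
    coordinates 0-based half-open on the forward strand. Runs truncated by
    sequence edges are allowed (no start codon required).
    """
    out = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            start = 0
            for run in prot.split("*"):
                if len(run) >= min_codons:
                    a = frame + 3 * start  # on strand s
                    b = a + 3 * len(run)
                    if strand == "+":
                        out.append((run, a, b, "+", frame))
                    else:
                        out.append((run, n - b, n - a, "-", frame))
                start += len(run) + 1
    return out


def protein_to_nt(aa_from: int, aa_to: int, start: int, end: int, strand: str) -> tuple[int, int]:
    """Map a protein-space half-open span to forward-strand nt coordinates."""
    if strand == "+":
        return start + 3 * aa_from, start + 3 * aa_to
    return end - 3 * aa_to, end - 3 * aa_from


def nt_to_protein(nt_from: int, nt_to: int, start: int, end: int, strand: str) -> tuple[int, int]:
    """Inverse of :func:`protein_to_nt`."""
    if strand == "+":
        return (nt_from - start) // 3, (nt_to - start) // 3
    return (end - nt_to) // 3, (end - nt_from) // 3


def _feature_protein(genome: GenomeRecord, feat: GeneFeature) -> str:
    if feat.translation:
        return feat.translation
    nt = genome.seq[feat.start : feat.end]
    if feat.strand == "-":
        nt = reverse_complement(nt)
    return translate(nt).rstrip("*").replace("*", "X")


def search_genome(
    profiles: Sequence[ProfileModel],
    genome: GenomeRecord,
    use_features: bool = True,
    report_evalue: float = 1.0,
    min_orf_codons: int = MIN_ORF_CODONS,
) -> list[Hit]:
    """Search a genome with every calibrated profile.

    With ``use_features`` each annotated CDS translation is scored; otherwise
    six-frame ORFs of at least ``min_orf_codons`` codons are scored. Hit
    coordinates (``q_from``/``q_to``) are genome nucleotides on the forward
    strand; ``n_comparisons`` is (scored proteins) x (profiles).
    """
    for p in profiles:
        if p.calib is None:
            raise ValueError(f"profile {p.family} must be calibrated before search")

    if use_features:
        units = [
            (_feature_protein(genome, f), f.start, f.end, f.strand, None, f.gene_id)
            for f in genome.features
        ]
    else:
        units = [
            (prot, a, b, strand, frame, f"{genome.id}_orf{k + 1}")
            for k, (prot, a, b, strand, frame) in enumerate(
                six_frame_orfs(genome.seq, min_codons=min_orf_codons)
            )
        ]
    units = [u for u in units if u[0]]
    if not units:
        import logging

        logging.getLogger("rnrscape").warning("genome %s: no scorable proteins", genome.id)
        return []

    n_comparisons = len(units) * len(profiles)
    hits: list[Hit] = []
    for prot, start, end, strand, frame, gene_id in units:
        idx = encode_protein(prot)
        for profile in profiles:
            for score, qf, qt, pf, pt in _score_local_all(profile, idx.copy()):
                ev = evalue(profile, score, n_comparisons)
                if ev > report_evalue:
                    continue
                g_from, g_to = protein_to_nt(qf, qt, start, end, strand)
                hits.append(
                    Hit(
                        query_id=genome.id,
                        family=profile.family,
                        score=score,
                        evalue=ev,
                        q_from=g_from,
                        q_to=g_to,
                        pf_from=pf,
                        pf_to=pt,
                        strand=strand,
                        frame=frame,
                        gene_id=gene_id,
                        locus_start=start,
                        locus_end=end,
                        aa_from=qf,
                        aa_to=qt,
                    )
                )
    hits.sort(key=lambda h: (h.q_from, h.q_to, h.family))
    return hits


# ---------------------------------------------------------------------------
# Profile file serialization (versioned TSV)
# ---------------------------------------------------------------------------

PROFILE_FILE_VERSION = "rnrscape-profiles-1"


def write_profiles(profiles: Sequence[ProfileModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{PROFILE_FILE_VERSION}\n")
        for p in profiles:
            mu, beta = p.calib if p.calib else (float("nan"), float("nan"))
            fh.write(
                f">{p.family}\t{p.L}\t{mu:.10g}\t{beta:.10g}\t{p.gap_open:.10g}\t{p.gap_extend:.10g}\n"
            )
            for row in p.S:
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_profiles(path: str | Path) -> list[ProfileModel]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(f"#{PROFILE_FILE_VERSION}"):
        raise ValueError(f"{path}: unrecognized profile file version")
    profiles: list[ProfileModel] = []
    i = 1
    while i < len(lines):
        if not lines[i].startswith(">"):
            i += 1
            continue
        family, L, mu, beta, go, ge = lines[i][1:].split("\t")
        L = int(L)
        S = np.array([[float(x) for x in lines[i + 1 + k].split("\t")] for k in range(L)])
        calib = None
        if not math.isnan(float(mu)):
            calib = (float(mu), float(beta))
        profiles.append(
            ProfileModel(family=family, S=S, gap_open=float(go), gap_extend=float(ge), calib=calib)
        )
        i += 1 + L
    return profiles


def build_family_profiles(
    seed_dir: str | Path,
    families: Sequence[str] = FAMILIES,
    n_decoys: int = 200,
    decoy_len: int = 400,
    seed: int = 0,
) -> list[ProfileModel]:
    """Build and calibrate one profile per ``<family>.afa`` seed alignment."""
    from .formats_io import read_fasta

    profiles = []
    for k, fam in enumerate(families):
        msa = read_fasta(Path(seed_dir) / f"{fam}.afa")
        prof = build_profile(msa, fam)
        profiles.append(calibrate(prof, n_decoys=n_decoys, decoy_len=decoy_len, seed=seed + k))
    return profiles
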