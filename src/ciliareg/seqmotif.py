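"""Promoter extraction, position weight matrices, motif scanning and k-mer
over-representation.

Coordinates are 0-based, half-open throughout.  Promoters are taken upstream of
the translational start by default (700 bp), matching the convention used for
regulatory-sequence retrieval in nematode cis-regulatory analysis, where 5'UTRs
are short and trans-splicing makes transcription starts unreliable.

Scoring model
-------------
A PWM stores per-position log2 odds of each base against a background
distribution.  A window's score is the sum of its per-position log-odds; matches
are reported above a threshold given either as an absolute score or as a
fraction of the maximum attainable score.  Reverse-strand matches are scored
against the reverse-complemented matrix so that reported offsets always refer to
forward-strand coordinates.

The k-mer over-representation test is an order-0 binomial enumeration over
canonical k-mers (lexicographic minimum of a k-mer and its reverse complement),
with Benjamini-Hochberg control over all k-mers tested.  It stands in for de
novo motif discovery at word resolution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from ._utils import BASES, bh_adjust, encode_sequence, logger, reverse_complement

NEG_INF_SCORE = -1e9  # stand-in for log(0) when pseudocount is exactly zero


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: span, strand, transcription and translation starts.

    ``tss`` and ``tls`` are 0-based.  On the minus strand they denote the
    half-open boundary just 5' of the first transcribed/coding base in genome
    coordinates, so the upstream interval is always ``[anchor, anchor + L)``
    for minus-strand genes and ``[anchor - L, anchor)`` for plus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tls: int
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}) for {self.gene_id}")


def read_gene_models_tsv(path) -> list[GeneModel]:
    """Read the 5-column gene table (gene_id, chrom, strand, tss, tls).

    Optional 6th/7th columns give the gene span; otherwise the span is the
    tss..tls hull.
    """
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"malformed gene table line: {line!r}")
            tss = int(parts[idx["tss"]])
            tls = int(parts[idx["tls"]])
            start = int(parts[idx["start"]]) if "start" in idx else min(tss, tls)
            end = int(parts[idx["end"]]) if "end" in idx else max(tss, tls)
            models.append(
                GeneModel(
                    gene_id=parts[idx["gene_id"]],
                    chrom=parts[idx["chrom"]],
                    strand=parts[idx["strand"]],
                    tss=tss,
                    tls=tls,
                    start=start,
                    end=end,
                )
            )
    return models


def write_gene_models_tsv(models, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttls\tstart\tend\n")
        for m in models:
            fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.tss}\t{m.tls}\t{m.start}\t{m.end}\n")


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Extract gene-level models from GFF3: one model per gene feature, with the
    translational start taken from the first CDS base in transcript orientation.

    GFF3 is 1-based inclusive; converted to 0-based half-open on read.
    """
    genes: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, s1, e1, _score, strand, _frame, attrs = parts
            start, end = int(s1) - 1, int(e1)
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = tags.get("ID") or tags.get("gene_id")
                genes[gid] = dict(chrom=chrom, strand=strand, start=start, end=end)
            elif ftype == "mRNA":
                mrna_parent[tags.get("ID", "")] = tags.get("Parent", "")
            elif ftype == "CDS":
                parent = tags.get("Parent", "")
                gid = mrna_parent.get(parent, parent)
                cds.setdefault(gid, []).append((start, end))
    models = []
    for gid, info in genes.items():
        strand = info["strand"]
        if strand == "+":
            tss = info["start"]
            tls = min(s for s, _ in cds[gid]) if gid in cds else tss
        else:
            tss = info["end"]
            tls = max(e for _, e in cds[gid]) if gid in cds else tss
        models.append(
            GeneModel(gene_id=gid, chrom=info["chrom"], strand=strand,
                      tss=tss, tls=tls, start=info["start"], end=info["end"])
        )
    return models


# ---------------------------------------------------------------------------
# FASTA-backed genome
# ---------------------------------------------------------------------------

def read_genome(path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_promoters(
    genome: dict[str, str],
    models,
    upstream_len: int = 700,
    anchor: str = "tls",
) -> list[tuple[str, str]]:
    """Upstream regulatory sequences, one per gene model.

    Plus strand yields ``genome[anchor-L : anchor]``; minus strand yields the
    reverse complement of ``genome[anchor : anchor+L]``.  Sequences truncated at
    a chromosome edge are returned shorter, with a logged warning.
    """
    if anchor not in ("tls", "tss"):
        raise ValueError("anchor must be 'tls' or 'tss'")
    out = []
    n_truncated = 0
    for m in models:
        if m.chrom not in genome:
            raise KeyError(f"chromosome {m.chrom!r} not in genome")
        chrom_seq = genome[m.chrom]
        a = getattr(m, anchor)
        if not (0 <= a <= len(chrom_seq)):
            raise ValueError(f"anchor {a} outside chromosome {m.chrom} for {m.gene_id}")
        if m.strand == "+":
            lo, hi = a - upstream_len, a
            if lo < 0:
                n_truncated += 1
                lo = 0
            seq = chrom_seq[lo:hi]
        else:
            lo, hi = a, a + upstream_len
            if hi > len(chrom_seq):
                n_truncated += 1
                hi = len(chrom_seq)
            seq = reverse_complement(chrom_seq[lo:hi])
        out.append((m.gene_id, seq))
    if n_truncated:
        logger.warning("%d promoter(s) truncated at chromosome edges", n_truncated)
    return out


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix with log2-odds scores against a background model."""

    name: str
    log_odds: np.ndarray          # (width, 4)
    background: np.ndarray        # (4,)
    pseudocount: float
    source_counts: np.ndarray     # (width, 4) original count/frequency matrix

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be (width, 4)")
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds must be finite (use the -1e9 guard, not -inf)")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        """Maximum-likelihood string under the matrix."""
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name + "_rc",
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            source_counts=self.source_counts[::-1, ::-1].copy(),
        )


UNIFORM_BACKGROUND = np.full(4, 0.25)


def build_pwm(
    counts,
    background=None,
    pseudocount: float = 0.01,
    name: str = "pwm",
) -> PWM:
    """Build a log2-odds PWM from a count/frequency matrix.

    ``log_odds[i, b] = log2(p_ib / background_b)`` with
    ``p_ib = (counts[i,b] + pc * background_b) / sum_b'(counts[i,b'] + pc * background_b')``.
    With ``pseudocount == 0``, impossible bases score ``-1e9`` rather than -inf so
    scores stay finite.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] != 4:
        raise ValueError("counts must have 4 columns (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    adjusted = counts + pseudocount * bg
    col_sums = adjusted.sum(axis=1, keepdims=True)
    if np.any(col_sums == 0):
        raise ValueError("all-zero position with zero pseudocount")
    probs = adjusted / col_sums
    with np.errstate(divide="ignore"):
        lo = np.log2(probs / bg)
    lo[np.isneginf(lo)] = NEG_INF_SCORE
    return PWM(name=name, log_odds=lo, background=bg, pseudocount=pseudocount,
               source_counts=counts)


def read_jaspar(path, background=None, pseudocount: float = 0.01) -> PWM:
    """Read a JASPAR PFM file (``>name`` header then four ``A [ ... ]`` rows)."""
    name = Path(path).stem
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            nums = line[line.index("[") + 1 : line.index("]")] if "[" in line else line[1:]
            rows[base] = [float(x) for x in nums.split()]
    counts = np.array([rows[b] for b in BASES]).T
    return build_pwm(counts, background=background, pseudocount=pseudocount, name=name)


def write_jaspar(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pwm.source_counts[:, i])
            fh.write(f"{base} [ {vals} ]\n")


def read_meme(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read MEME minimal motif format; probabilities are used as counts."""
    pwms = []
    bg = UNIFORM_BACKGROUND
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq_parts = lines[i + 1].split()
            bg = np.array([float(freq_parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            mat = np.array(
                [[float(x) for x in lines[i + 1 + j].split()] for j in range(w)]
            )
            pwms.append(build_pwm(mat, background=bg, pseudocount=pseudocount, name=name))
            i += w + 1
            continue
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    offset: int       # 0-based start of match, forward coordinates
    strand: str
    score: float


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of len(log_odds) in an encoded sequence.

    Windows containing N (code 4) score -1e9.
    """
    w = log_odds.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    # pad the score table with a column for N so indexing stays vectorized
    table = np.hstack([log_odds, np.full((w, 1), NEG_INF_SCORE)])
    idx = np.arange(n)[:, None] + np.arange(w)[None, :]
    return table[np.arange(w)[None, :], codes[idx]].sum(axis=1)


def scan(
    pwm: PWM,
    sequence: str,
    threshold: float | None = None,
    threshold_fraction: float | None = None,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> list[MotifMatch]:
    """Report every window scoring at or above the threshold.

    The threshold is an absolute log-odds score, or a fraction of the maximum
    attainable score via ``threshold_fraction`` (default 0.8 when neither is
    given).  Reverse-strand matches are reported at forward coordinates.
    Sequences shorter than the motif return an empty list.
    """
    if threshold is None:
        frac = 0.8 if threshold_fraction is None else threshold_fraction
        threshold = frac * pwm.max_score
    elif threshold_fraction is not None:
        raise ValueError("give either threshold or threshold_fraction, not both")
    codes = encode_sequence(sequence)
    matches: list[MotifMatch] = []
    fwd = _window_scores(codes, pwm.log_odds)
    for off in np.flatnonzero(fwd >= threshold):
        matches.append(MotifMatch(sequence_id, int(off), "+", float(fwd[off])))
    if both_strands:
        rev = _window_scores(codes, pwm.reverse_complement().log_odds)
        for off in np.flatnonzero(rev >= threshold):
            matches.append(MotifMatch(sequence_id, int(off), "-", float(rev[off])))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


def best_match_score(pwm: PWM, sequence: str, both_strands: bool = True):
    """(best score, offset, strand) over all windows; (None, None, None) if no window."""
    codes = encode_sequence(sequence)
    fwd = _window_scores(codes, pwm.log_odds)
    if fwd.size == 0:
        return None, None, None
    best_score, best_off, best_strand = fwd.max(), int(fwd.argmax()), "+"
    if both_strands:
        rev = _window_scores(codes, pwm.reverse_complement().log_odds)
        if rev.max() > best_score:
            best_score, best_off, best_strand = rev.max(), int(rev.argmax()), "-"
    return float(best_score), best_off, best_strand


# ---------------------------------------------------------------------------
# k-mer over-representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerResult:
    kmer: str
    observed: int
    expected: float
    p_value: float
    q_value: float


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _base_frequencies(sequences) -> np.ndarray:
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases in sequence set")
    return counts / total


def kmer_enrichment(
    sequences,
    k: int = 6,
    background="order-0",
    alpha: float = 0.05,
) -> list[KmerResult]:
    """Binomial over-representation of canonical k-mers in a sequence set.

    ``background`` is ``"order-0"`` (base frequencies estimated from the input),
    a list of background sequences (genome-wide mode), or an explicit length-4
    array of base probabilities.  Each of the N total windows contributes one
    canonical k-mer; the null occurrence probability of a canonical k-mer is the
    sum of the i.i.d. probabilities of the k-mer and its reverse complement
    (counted once for palindromes).  One-sided binomial upper-tail p-values are
    BH-adjusted over all canonical k-mers; results are sorted by (q, p).
    """
    sequences = list(sequences)
    if k <= 0:
        raise ValueError("k must be positive")
    if not sequences:
        raise ValueError("empty sequence set")
    if k > min(len(s) for s in sequences):
        raise ValueError("k longer than the shortest sequence")

    if isinstance(background, str):
        if background != "order-0":
            raise ValueError(f"unknown background mode {background!r}")
        bg = _base_frequencies(sequences)
    elif background and isinstance(background[0], str):
        bg = _base_frequencies(background)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("explicit background must be 4 probabilities summing to 1")

    observed: dict[str, int] = {}
    n_windows = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            n_windows += 1
            canon = canonical_kmer(window)
            observed[canon] = observed.get(canon, 0) + 1

    def iid_prob(kmer: str) -> float:
        codes = encode_sequence(kmer)
        return float(np.prod(bg[codes]))

    canon_kmers = sorted(
        {canonical_kmer("".join(t)) for t in itertools.product(BASES, repeat=k)}
    )
    probs = np.empty(len(canon_kmers))
    for i, kmer in enumerate(canon_kmers):
        rc = reverse_complement(kmer)
        probs[i] = iid_prob(kmer) if rc == kmer else iid_prob(kmer) + iid_prob(rc)
    obs = np.array([observed.get(kmer, 0) for kmer in canon_kmers])
    pvals = stats.binom.sf(obs - 1, n_windows, np.minimum(probs, 1.0))
    qvals = bh_adjust(pvals)
    results = [
        KmerResult(kmer, int(o), float(n_windows * p), float(pv), float(qv))
        for kmer, o, p, pv, qv in zip(canon_kmers, obs, probs, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, -r.observed))
    return results
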