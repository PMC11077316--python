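"""Self-contained BLASTP stand-in.

Exact Smith-Waterman local alignment with affine gaps replaces heuristic
BLASTP at desk scale: proteomes here are small enough that exactness is
affordable and removes seeding heuristics as a confound. Statistical
significance of a raw score S for a query of length m against a database of
total length n uses the Karlin-Altschul form E = K * m * n * exp(-lambda * S),
with K and lambda treated as fixed calibration constants (ungapped BLOSUM62
style defaults). Screen decisions downstream depend only on threshold
ordering, not on the absolute E-value scale.

Real BLASTP tabular output (outfmt 6) can be read into the same
:class:`SimilarityHit` type, so a full-scale run with external BLAST is a
drop-in substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _alignment

#: canonical residue order used for integer encoding; X is a catch-all
#: unknown residue scored at the worst-case value.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
X_SCORE = -4

REG_CLASSES = ("WBR", "HRA", "LRA", "CONFIRM")


class ProteomeError(ValueError):
    """Invalid proteome structure or sequence content."""


# ---------------------------------------------------------------------------
# scoring scheme


@lru_cache(maxsize=8)
def _encoded_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    k = len(AA_ALPHABET)
    out = np.zeros((k, k), dtype=np.int8)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a == "X" or b == "X":
                out[i, j] = X_SCORE
            else:
                out[i, j] = int(mat[a][b])
    return out


_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _ENCODE_TABLE[ord(_c)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string into int8 codes over :data:`AA_ALPHABET`."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[arr]
    if (codes < 0).any():
        bad = sorted({c for c in seq if c not in AA_ALPHABET})
        raise ProteomeError(f"sequence contains non-amino-acid symbols: {bad}")
    return codes.astype(np.int8)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    K: float = 0.041
    lam: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return _encoded_matrix(self.matrix_name)

    @property
    def gap_first(self) -> int:
        """Cost of the first residue of a gap."""
        return self.gap_open + self.gap_extend


# ---------------------------------------------------------------------------
# proteomes


@dataclass
class Proteome:
    """One species' protein sequences with gene -> isoform structure."""

    species_id: str
    reg_class: str
    records: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def validate(self) -> "Proteome":
        if self.reg_class not in REG_CLASSES:
            raise ProteomeError(
                f"{self.species_id}: unknown regeneration class {self.reg_class!r}"
            )
        for gene, isoforms in self.records.items():
            if not isoforms:
                raise ProteomeError(f"{self.species_id}:{gene} has zero isoforms")
            for iso, seq in isoforms:
                if not seq:
                    raise ProteomeError(f"{self.species_id}:{gene}:{iso} empty sequence")
                encode_sequence(seq)  # raises on bad symbols
        return self

    @property
    def n_genes(self) -> int:
        return len(self.records)

    @property
    def is_reduced(self) -> bool:
        return all(len(v) == 1 for v in self.records.values())

    def total_length(self) -> int:
        return sum(len(seq) for isos in self.records.values() for _, seq in isos)

    def gene_sequence(self, gene: str) -> str:
        isos = self.records[gene]
        if len(isos) != 1:
            raise ProteomeError(f"{self.species_id}:{gene} is not isoform-reduced")
        return isos[0][1]

    # -- FASTA I/O; headers are `species|gene|isoform` -----------------------

    def write_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=f"{self.species_id}|{gene}|{iso}", description="")
            for gene, isos in self.records.items()
            for iso, seq in isos
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def read_fasta(
        cls, path: str | Path, reg_class: str, species_id: str | None = None
    ) -> "Proteome":
        records: dict[str, list[tuple[str, str]]] = {}
        sp = species_id
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) == 3:
                rsp, gene, iso = parts
            elif len(parts) == 2:
                rsp, gene, iso = parts[0], parts[1], "t1"
            else:
                rsp, gene, iso = species_id or "NA", rec.id, "t1"
            if sp is None:
                sp = rsp
            records.setdefault(gene, []).append((iso, str(rec.seq).upper()))
        if sp is None:
            raise ProteomeError(f"{path}: empty FASTA and no species_id given")
        return cls(species_id=sp, reg_class=reg_class, records=records).validate()


def select_longest_isoform(proteome: Proteome) -> Proteome:
    """Keep one maximal-length isoform per gene (ties: smallest isoform id)."""
    reduced: dict[str, list[tuple[str, str]]] = {}
    for gene, isoforms in proteome.records.items():
        if not isoforms:
            raise ProteomeError(f"{proteome.species_id}:{gene} has zero isoforms")
        best = min(isoforms, key=lambda p: (-len(p[1]), p[0]))
        reduced[gene] = [best]
    return replace(proteome, records=reduced)


# ---------------------------------------------------------------------------
# alignment + E-values


def local_align_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Optimal Smith-Waterman local alignment score (empty sequence -> 0)."""
    if not a or not b:
        return 0
    return int(
        _alignment.sw_score(
            encode_sequence(a),
            encode_sequence(b),
            scheme.matrix,
            scheme.gap_first,
            scheme.gap_extend,
        )
    )


def estimate_evalue(score: float, m: int, n: int, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def min_score_for_evalue(evalue_max: float, m: int, n: int, scheme: ScoringScheme) -> int:
    """Smallest integer score whose E-value is <= evalue_max."""
    if evalue_max <= 0:
        return np.iinfo(np.int32).max
    s = math.ceil(math.log(scheme.K * m * n / evalue_max) / scheme.lam)
    s = max(s, 0)
    while estimate_evalue(s, m, n, scheme) > evalue_max:
        s += 1
    return s


@dataclass(frozen=True)
class SimilarityHit:
    query_species: str
    query_gene: str
    subject_species: str
    subject_gene: str
    score: int
    evalue: float


@dataclass(frozen=True)
class MbhPair:
    """Symmetric mutual-best-hit pair between two species."""

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    score: int
    evalue: float


def _pack(proteome: Proteome) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes = sorted(proteome.records)
    seqs = [encode_sequence(proteome.gene_sequence(g)) for g in genes]
    bounds = np.zeros(len(seqs) + 1, dtype=np.int64)
    for i, s in enumerate(seqs):
        bounds[i + 1] = bounds[i] + len(s)
    flat = np.concatenate(seqs) if seqs else np.zeros(0, dtype=np.int8)
    return genes, flat, bounds


def pairwise_score_matrix(
    query: Proteome, subject: Proteome, scheme: ScoringScheme = ScoringScheme()
) -> tuple[list[str], list[str], np.ndarray]:
    """All-vs-all SW raw scores; rows = query genes, cols = subject genes.

    Both gene lists are sorted; symmetric in the sense that swapping the
    arguments transposes the matrix.
    """
    for p in (query, subject):
        if not p.is_reduced:
            raise ProteomeError(
                f"{p.species_id}: proteome must be isoform-reduced before search"
            )
    qgenes, qflat, qb = _pack(query)
    sgenes, sflat, sb = _pack(subject)
    scores = np.zeros((len(qgenes), len(sgenes)), dtype=np.int32)
    for i in range(len(qgenes)):
        scores[i] = _alignment.sw_score_rows(
            qflat[qb[i]:qb[i + 1]], sflat, sb, scheme.matrix, scheme.gap_first, scheme.gap_extend
        )
    return qgenes, sgenes, scores


def hits_from_matrix(
    query: Proteome,
    subject: Proteome,
    qgenes: Sequence[str],
    sgenes: Sequence[str],
    scores: np.ndarray,
    scheme: ScoringScheme,
    evalue_max: float,
) -> list[SimilarityHit]:
    n_db = subject.total_length()
    hits: list[SimilarityHit] = []
    same_species = query.species_id == subject.species_id
    for i, qg in enumerate(qgenes):
        m = len(query.gene_sequence(qg))
        for j, sg in enumerate(sgenes):
            if same_species and qg == sg:
                continue
            e = estimate_evalue(int(scores[i, j]), m, n_db, scheme)
            if e <= evalue_max:
                hits.append(
                    SimilarityHit(
                        query.species_id, qg, subject.species_id, sg, int(scores[i, j]), e
                    )
                )
    return hits


def all_vs_all(
    query: Proteome,
    subject: Proteome,
    scheme: ScoringScheme = ScoringScheme(),
    evalue_max: float = 1e-4,
) -> list[SimilarityHit]:
    """Every cross-gene pair with E <= evalue_max, ordered by (query, subject)."""
    qgenes, sgenes, scores = pairwise_score_matrix(query, subject, scheme)
    return hits_from_matrix(query, subject, qgenes, sgenes, scores, scheme, evalue_max)


def find_any_hit(
    query_seq: str,
    subject: Proteome,
    scheme: ScoringScheme,
    evalue_max: float,
) -> tuple[str, int, float] | None:
    """First subject gene (sorted order) hitting the query at E <= evalue_max.

    Early-exit scan used by the loss filter, where one qualifying hit anywhere
    disqualifies a whole orthogroup.
    """
    if not subject.records:
        return None
    n_db = subject.total_length()
    m = len(query_seq)
    score_min = min_score_for_evalue(evalue_max, m, n_db, scheme)
    genes, flat, bounds = _pack(subject)
    idx, score = _alignment.sw_first_at_least(
        encode_sequence(query_seq), flat, bounds, scheme.matrix,
        scheme.gap_first, scheme.gap_extend, score_min,
    )
    if idx < 0:
        return None
    gene = genes[int(idx)]
    return gene, int(score), estimate_evalue(int(score), m, n_db, scheme)


def _best_by_query(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_gene)
        if cur is None or (-h.score, h.evalue, h.subject_gene) < (
            -cur.score, cur.evalue, cur.subject_gene
        ):
            best[h.query_gene] = h
    return best


def mutual_best_hits(
    hits_ab: Sequence[SimilarityHit], hits_ba: Sequence[SimilarityHit]
) -> list[MbhPair]:
    """Pairs where each gene is the other's unique best hit.

    Best = max score, ties by min E-value, remaining ties by lexicographically
    smallest subject gene (a determinism convention).
    """
    best_ab = _best_by_query(hits_ab)
    best_ba = _best_by_query(hits_ba)
    pairs = []
    for ga, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_gene)
        if back is not None and back.subject_gene == ga:
            pairs.append(
                MbhPair(
                    species_a=hit.query_species,
                    gene_a=ga,
                    species_b=hit.subject_species,
                    gene_b=hit.subject_gene,
                    score=hit.score,
                    evalue=min(hit.evalue, back.evalue),
                )
            )
    return pairs


def mutual_best_from_matrix(
    a: Proteome, b: Proteome, scheme: ScoringScheme = ScoringScheme(),
    evalue_max: float = math.inf,
) -> list[MbhPair]:
    """MBH pairs from one score-matrix pass (SW scores are symmetric)."""
    agenes, bgenes, scores = pairwise_score_matrix(a, b, scheme)
    hits_ab = hits_from_matrix(a, b, agenes, bgenes, scores, scheme, evalue_max)
    hits_ba = hits_from_matrix(b, a, bgenes, agenes, scores.T, scheme, evalue_max)
    return mutual_best_hits(hits_ab, hits_ba)


# ---------------------------------------------------------------------------
# BLAST outfmt-6 style TSV I/O

_OUTFMT6_COLS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_hits_tsv(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    """Write hits as BLAST outfmt-6-style TSV (placeholders for unused columns).

    qseqid/sseqid are `species|gene`; bitscore column carries the raw SW score.
    """
    with open(path, "w") as fh:
        for h in hits:
            row = [
                f"{h.query_species}|{h.query_gene}",
                f"{h.subject_species}|{h.subject_gene}",
                "0", "0", "0", "0", "0", "0", "0", "0",
                f"{h.evalue:.3g}",
                str(h.score),
            ]
            fh.write("\t".join(row) + "\n")


def read_hits_tsv(
    path: str | Path,
    query_species: str | None = None,
    subject_species: str | None = None,
) -> list[SimilarityHit]:
    """Read outfmt-6 TSV (ours or real BLAST's) into SimilarityHit records."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: expected >=12 outfmt-6 columns, got {len(f)}")
            qsp, qg = f[0].split("|", 1) if "|" in f[0] else (query_species or "NA", f[0])
            ssp, sg = f[1].split("|", 1) if "|" in f[1] else (subject_species or "NA", f[1])
            hits.append(
                SimilarityHit(qsp, qg, ssp, sg, int(round(float(f[11]))), float(f[10]))
            )
    return hits
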