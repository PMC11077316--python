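"""Promoter motif scanning and target-vs-background enrichment.

JASPAR-format position frequency matrices are scanned over upstream windows
of target versus background genes with a MATCH-style rescaled log-odds
threshold; per-TF enrichment is a gene-level (>=1 hit per gene) two-sided
Fisher exact test, and the per-window top-k records are tallied by TF class
into a heatmap-ready class x window table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import fisher_exact

NUCLEOTIDES = "ACGT"

DEFAULT_WINDOWS = (100, 500, 1000, 3000, 5000, 7500)


class TfbsError(ValueError):
    pass


@dataclass
class PWMRecord:
    """Position frequency matrix with a TF-class annotation."""

    matrix_id: str
    tf_name: str
    tf_class: str
    counts: np.ndarray  # 4 x width, rows A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise TfbsError(f"{self.matrix_id}: counts must be a 4 x width matrix")
        if (self.counts < 0).any():
            raise TfbsError(f"{self.matrix_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise TfbsError(f"{self.matrix_id}: zero column sums")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class ScanParams:
    """Scanning parameters (MATCH-style rescaled log-odds threshold)."""

    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    score_fraction_threshold: float = 0.85
    window_lengths: tuple[int, ...] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if not (0 < self.score_fraction_threshold <= 1):
            raise TfbsError("score_fraction_threshold must lie in (0, 1]")
        if self.pseudocount < 0:
            raise TfbsError("pseudocount must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) <= 0:
            raise TfbsError("background frequencies must be positive and sum to 1")
        wl = self.window_lengths
        if any(w <= 0 for w in wl) or list(wl) != sorted(set(wl)):
            raise TfbsError("window_lengths must be positive and strictly increasing")


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start on the given (forward) sequence
    strand: str  # '+' or '-'
    score: float


@dataclass(frozen=True)
class EnrichmentRecord:
    matrix_id: str
    tf_class: str
    window_length: int
    n_target_hit: int
    n_target: int
    n_background_hit: int
    n_background: int
    p_value: float
    log2_enrichment: float


# ---------------------------------------------------------------------------
# JASPAR I/O (Bio.motifs does the parsing; we attach classes and name errors)


def read_jaspar(
    pfm_file: str | Path,
    class_annotation: Mapping[str, str] | str | Path | None = None,
) -> list[PWMRecord]:
    """Read a JASPAR-format PFM file (2016+ bracketed count rows).

    ``class_annotation`` maps matrix_id -> TF class, either directly or as a
    sidecar TSV with columns (matrix_id, tf_class); unknown ids get
    "Unclassified".
    """
    classes: dict[str, str] = {}
    if isinstance(class_annotation, (str, Path)):
        tab = pd.read_csv(class_annotation, sep="\t", header=None, comment="#")
        classes = dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(str)))
    elif class_annotation:
        classes = dict(class_annotation)
    _check_jaspar_structure(pfm_file)
    try:
        with open(pfm_file) as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
    except Exception as exc:  # re-raise with the file named
        raise TfbsError(f"{pfm_file}: JASPAR parse error: {exc}") from exc
    records = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in NUCLEOTIDES], dtype=float)
        mid = m.matrix_id or m.name
        try:
            records.append(
                PWMRecord(
                    matrix_id=mid,
                    tf_name=m.name or mid,
                    tf_class=classes.get(mid, "Unclassified"),
                    counts=counts,
                )
            )
        except TfbsError as exc:
            raise TfbsError(f"{pfm_file}: matrix {mid}: {exc}") from exc
    return records


def _check_jaspar_structure(pfm_file: str | Path) -> None:
    """Each '>' record needs exactly one count row per base, equal lengths.

    Bio.motifs silently fills absent rows, so structural problems are caught
    here, with the offending matrix named.
    """
    current: str | None = None
    rows: dict[str, int] = {}

    def flush() -> None:
        if current is None:
            return
        if sorted(rows) != ["A", "C", "G", "T"]:
            raise TfbsError(
                f"{pfm_file}: matrix {current}: expected one count row per base "
                f"A/C/G/T, found {sorted(rows) or 'none'}"
            )
        if len(set(rows.values())) != 1:
            raise TfbsError(f"{pfm_file}: matrix {current}: row length mismatch")

    with open(pfm_file) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0]
                rows = {}
            elif current is not None:
                base = line[0].upper()
                body = line[1:].strip().strip("[]").strip()
                if base in "ACGT":
                    if base in rows:
                        raise TfbsError(
                            f"{pfm_file}: matrix {current}: duplicate {base} row"
                        )
                    rows[base] = len(body.split())
    flush()


def write_jaspar(records: Sequence[PWMRecord], pfm_file: str | Path) -> None:
    with open(pfm_file, "w") as fh:
        for r in records:
            fh.write(f">{r.matrix_id} {r.tf_name}\n")
            for i, base in enumerate(NUCLEOTIDES):
                row = " ".join(
                    f"{int(v)}" if float(v).is_integer() else f"{v:.2f}"
                    for v in r.counts[i]
                )
                fh.write(f"{base}  [ {row} ]\n")


def write_class_annotation(records: Sequence[PWMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.matrix_id}\t{r.tf_class}\n")


# ---------------------------------------------------------------------------
# upstream extraction


@dataclass(frozen=True)
class UpstreamSeq:
    gene_id: str
    sequence: str
    truncated: bool


def extract_upstream(
    annotation: pd.DataFrame,
    genome: Mapping[str, str],
    L: int,
) -> dict[str, UpstreamSeq]:
    """The L bases 5' of each TSS on the coding strand (TSS base excluded).

    ``annotation`` needs columns gene_id, contig, tss (1-based), strand
    (+/-). Minus-strand upstream regions are reverse-complemented so the
    returned sequence always reads 5'->3' toward the TSS. Regions running off
    a contig edge are truncated and flagged.
    """
    if L <= 0:
        raise TfbsError("upstream window length must be positive")
    need = {"gene_id", "contig", "tss", "strand"}
    if not need <= set(annotation.columns):
        raise TfbsError(f"annotation must have columns {sorted(need)}")
    comp = str.maketrans("ACGTN", "TGCAN")
    out: dict[str, UpstreamSeq] = {}
    for row in annotation.itertuples(index=False):
        if row.contig not in genome:
            raise TfbsError(f"gene {row.gene_id}: contig {row.contig!r} not in genome")
        contig = genome[row.contig]
        tss = int(row.tss)
        if not (1 <= tss <= len(contig)):
            raise TfbsError(f"gene {row.gene_id}: TSS {tss} outside contig")
        if row.strand == "+":
            start = max(0, tss - 1 - L)
            seq = contig[start:tss - 1]
            truncated = tss - 1 - L < 0
        elif row.strand == "-":
            end = min(len(contig), tss + L)
            seq = contig[tss:end].translate(comp)[::-1]
            truncated = tss + L > len(contig)
        else:
            raise TfbsError(f"gene {row.gene_id}: strand must be '+' or '-'")
        out[row.gene_id] = UpstreamSeq(row.gene_id, seq.upper(), truncated)
    return out


# ---------------------------------------------------------------------------
# scanning

_NT_TABLE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES + "N"):
    _NT_TABLE[ord(_c)] = _i


def _log_odds(pwm: PWMRecord, params: ScanParams) -> np.ndarray:
    """5 x width log2-odds matrix; the extra N row scores 0 at every column."""
    bg = np.asarray(params.background)[:, None]
    colsum = pwm.counts.sum(axis=0, keepdims=True)
    freq = (pwm.counts + params.pseudocount * bg) / (colsum + params.pseudocount)
    lo = np.log2(freq / bg)
    return np.vstack([lo, np.zeros((1, pwm.width))])


def scan_sequence(
    pwm: PWMRecord, seq: str, params: ScanParams = ScanParams()
) -> list[MotifHit]:
    """All positions (both strands) scoring above the rescaled threshold.

    Hit iff score >= threshold * (max achievable - min achievable) + min
    achievable, where max/min are over ACGT words (N scores 0 and can fall
    anywhere in between). Positions are 0-based starts on the given sequence;
    minus-strand hits are reported at their forward-strand start.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    codes = _NT_TABLE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in seq.upper() if c not in NUCLEOTIDES + "N"})
        raise TfbsError(f"sequence contains non-nucleotide symbols: {bad}")
    lo = _log_odds(pwm, params)
    acgt = lo[:4]
    thr = params.score_fraction_threshold * (
        acgt.max(axis=0).sum() - acgt.min(axis=0).sum()
    ) + acgt.min(axis=0).sum()
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    cols = np.arange(w)
    fwd = lo[windows, cols].sum(axis=1)
    # reverse strand: scan the reverse-complemented matrix on the forward seq
    lo_rc = np.vstack([acgt[::-1, ::-1], np.zeros((1, w))])
    rev = lo_rc[windows, cols].sum(axis=1)
    hits = [
        MotifHit(int(p), "+", float(fwd[p])) for p in np.nonzero(fwd >= thr - 1e-12)[0]
    ] + [
        MotifHit(int(p), "-", float(rev[p])) for p in np.nonzero(rev >= thr - 1e-12)[0]
    ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_gene_set(
    pwm: PWMRecord,
    promoters: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> dict[str, list[MotifHit]]:
    return {g: scan_sequence(pwm, s, params) for g, s in promoters.items()}


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(
    targets: set[str],
    background: set[str],
    hits_by_gene: Mapping[str, Sequence[MotifHit]] | Mapping[str, bool],
    pwm: PWMRecord,
    window_length: int = 0,
) -> EnrichmentRecord:
    """Gene-level two-sided Fisher exact test of target vs background hits.

    A gene counts once if it has >= 1 hit. log2 enrichment is the log ratio
    of hit proportions, 0 exactly when the proportions are equal, with a 0.5
    continuity correction applied to zero cells otherwise.
    """
    if not targets or not background:
        raise TfbsError("targets and background must be nonempty")
    if targets & background:
        raise TfbsError("targets must be excluded from the background set")

    def has_hit(g: str) -> bool:
        return bool(hits_by_gene.get(g))

    t_hit = sum(1 for g in targets if has_hit(g))
    b_hit = sum(1 for g in background if has_hit(g))
    n_t, n_b = len(targets), len(background)
    table = [[t_hit, n_t - t_hit], [b_hit, n_b - b_hit]]
    _, p = fisher_exact(table, alternative="two-sided")
    p_t, p_b = t_hit / n_t, b_hit / n_b
    if p_t == p_b:
        log2_enr = 0.0
    else:
        ct = t_hit + 0.5 if t_hit == 0 or b_hit == 0 else t_hit
        cb = b_hit + 0.5 if t_hit == 0 or b_hit == 0 else b_hit
        log2_enr = float(np.log2((ct / n_t) / (cb / n_b)))
    return EnrichmentRecord(
        matrix_id=pwm.matrix_id,
        tf_class=pwm.tf_class,
        window_length=window_length,
        n_target_hit=t_hit,
        n_target=n_t,
        n_background_hit=b_hit,
        n_background=n_b,
        p_value=float(min(1.0, p)),
        log2_enrichment=log2_enr,
    )


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Enrichment records as a DataFrame with BH-adjusted p-values per window."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    def bh(p: pd.Series) -> pd.Series:
        order = p.sort_values().index
        m = len(p)
        adj = p[order].values * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        return pd.Series(np.minimum(adj, 1.0), index=order).reindex(p.index)
    df["p_adjusted"] = (
        df.groupby("window_length", group_keys=False)["p_value"].apply(bh)
    )
    return df


def compile_top_classes(
    records: Sequence[EnrichmentRecord], top_k: int = 10
) -> pd.DataFrame:
    """Class x window tally of the per-window top-k enrichment records.

    Per window, records rank by smallest p-value, ties by largest log2
    enrichment (then matrix id, for determinism); the TF classes of the
    winners are tallied. The result is heatmap-ready: one row per TF class,
    one column per window length.
    """
    by_window: dict[int, list[EnrichmentRecord]] = {}
    for r in records:
        by_window.setdefault(r.window_length, []).append(r)
    tallies: dict[int, dict[str, int]] = {}
    for w, recs in sorted(by_window.items()):
        if len(recs) < top_k:
            warnings.warn(
                f"window {w}: only {len(recs)} records for top_k={top_k}; using all"
            )
        ranked = sorted(recs, key=lambda r: (r.p_value, -r.log2_enrichment, r.matrix_id))
        tally: dict[str, int] = {}
        for r in ranked[:top_k]:
            tally[r.tf_class] = tally.get(r.tf_class, 0) + 1
        tallies[w] = tally
    classes = sorted({c for t in tallies.values() for c in t})
    data = {w: [t.get(c, 0) for c in classes] for w, t in tallies.items()}
    return pd.DataFrame(data, index=classes).rename_axis("tf_class")


def plot_class_tally(tally: pd.DataFrame, path: str | Path) -> None:
    """Basic heatmap of the class x window tally (matplotlib, no styling)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 + 0.8 * tally.shape[1], 1.0 + 0.45 * tally.shape[0])
    )
    im = ax.imshow(tally.values, cmap="viridis", aspect="auto")
    ax.set_xticks(range(tally.shape[1]), [str(c) for c in tally.columns])
    ax.set_yticks(range(tally.shape[0]), [str(i) for i in tally.index])
    ax.set_xlabel("upstream window (bp)")
    fig.colorbar(im, ax=ax, label="count in top-k")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
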