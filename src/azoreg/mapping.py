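"""Transposon insertion-site mapping from unidirectional Sanger reads.

A junction read produced by single-primer amplification of transposon ends
starts (or ends) with the transposon's terminal mosaic-end sequence followed
by genomic flank. Mapping proceeds in three steps:

1. *Trimming*: locate the mosaic end (allowing a few mismatches, on either
   strand and at either read end), cut it and everything outward, strip
   terminal ambiguous bases, and discard reads that are too short or too
   ambiguous.
2. *Local alignment*: exact affine-gap Smith-Waterman of the trimmed flank
   against the reference on both strands, with BLASTN-like scoring
   (match +2, mismatch -3, gap open 5, gap extend 2) and Karlin-Altschul
   E-values E = K*m*n*exp(-lambda*S).
3. *Reporting*: the highest-scoring alignment under the E-value cutoff gives
   the insertion coordinate (the reference base adjacent to the trimmed
   transposon end, strand-aware), annotated by interval containment against
   a gene table.

Coordinates are 0-based half-open internally and 1-based inclusive in all
reports. Identity and coverage percentages are integer truncations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

#: 19-bp Tn5 mosaic end, the terminus of Tn5-derived transposons.
TN5_MOSAIC_END = "CTGTCTCTTATACACATCT"

_COMP = str.maketrans("ACGTN", "TGCAN")

MIN_QUERY_LEN = 20


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# read trimming
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrimPolicy:
    transposon_end_seq: str = TN5_MOSAIC_END
    max_end_mismatches: int = 2
    min_remaining_len: int = MIN_QUERY_LEN
    max_internal_n_frac: float = 0.10

    def __post_init__(self):
        if self.min_remaining_len < 20:
            raise ValueError("min_remaining_len must be >= 20")
        if not 0 <= self.max_internal_n_frac <= 1:
            raise ValueError("max_internal_n_frac must be in [0, 1]")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    status: str  # "trimmed" | "untrimmed" | "discarded_quality"
    junction_side: str | None = None  # query end that abutted the transposon
    trim_span: tuple[int, int] | None = None  # removed-end span on input read


def _best_end_match(seq: str, pattern: str, max_mm: int) -> tuple[int, int] | None:
    """Best (pos, mismatches) occurrence of pattern in seq, or None.

    Ambiguous bases count as mismatches. Ties prefer the occurrence closest
    to a read end (junction reads carry the transposon end terminally).
    """
    L, P = len(seq), len(pattern)
    if P > L:
        return None
    best: tuple[int, int] | None = None
    for pos in range(L - P + 1):
        mm = sum(1 for a, b in zip(seq[pos : pos + P], pattern) if a != b or a == "N")
        if mm > max_mm:
            continue
        edge_dist = min(pos, L - P - pos)
        if best is None or (mm, edge_dist) < (best[1], min(best[0], L - P - best[0])):
            best = (pos, mm)
    return best


def trim_read(read_id: str, sequence: str, policy: TrimPolicy | None = None) -> TrimmedRead:
    """Remove the transposon end (and everything outward) from a read.

    The mosaic end is searched on both strands; whichever orientation matches
    with the fewest mismatches wins. A match in the 5' half trims the prefix
    (junction at the new 5' end); a match in the 3' half trims the suffix.
    Terminal N runs are then stripped; reads shorter than
    ``min_remaining_len`` or with too many internal Ns are discarded. Reads
    with no detectable transposon end pass through untrimmed with a warning
    status, since amplification products may begin past the end sequence.
    """
    policy = policy or TrimPolicy()
    seq = sequence.upper()
    if not seq:
        return TrimmedRead(read_id, "", "discarded_quality")
    end = policy.transposon_end_seq.upper()
    hits = []
    for pat, orient in ((end, "+"), (revcomp(end), "-")):
        h = _best_end_match(seq, pat, policy.max_end_mismatches)
        if h is not None:
            hits.append((h[1], h[0], orient))
    if hits:
        mm, pos, orient = min(hits)
        p_end = pos + len(end)
        if pos + p_end <= len(seq):  # match centre in the 5' half
            flank, side, span = seq[p_end:], "start", (0, p_end)
        else:
            flank, side, span = seq[:pos], "end", (pos, len(seq))
        status = "trimmed"
    else:
        flank, side, span, status = seq, None, None, "untrimmed"
    n_left = len(flank) - len(flank.lstrip("N"))
    flank = flank.strip("N")
    if side == "start" and span is not None:
        span = (span[0], span[1] + n_left)
    if len(flank) < policy.min_remaining_len:
        return TrimmedRead(read_id, flank, "discarded_quality", side, span)
    if flank.count("N") / len(flank) > policy.max_internal_n_frac:
        return TrimmedRead(read_id, flank, "discarded_quality", side, span)
    return TrimmedRead(read_id, flank, status, side, span)


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like affine-gap scoring plus Karlin-Altschul parameters.

    Defaults mimic the common nucleotide defaults (match +2, mismatch -3,
    gap open 5, gap extend 2; lambda 0.625, K 0.41). Exact agreement with
    any particular search program's statistics is NOT claimed; the E-value
    uses the plain formula E = K * m * n * exp(-lambda * S).
    """

    match: int = 2
    mismatch: int = 3  # stored as a penalty (positive)
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    k_param: float = 0.41

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.lam <= 0 or self.k_param <= 0:
            raise ValueError("Karlin-Altschul parameters must be > 0")


@dataclass
class LocalAlignment:
    query_id: str
    ref_id: str
    strand: str  # "+" | "-"
    q_start: int  # 0-based half-open, on the *original* query orientation
    q_end: int
    r_start: int
    r_end: int
    score: int
    identities: int
    aligned_len: int  # alignment columns, gaps included
    gaps: int
    query_len: int
    ref_len: int
    e_value: float = math.nan

    @property
    def identity_pct(self) -> int:
        return identity_percent(self.identities, self.aligned_len)

    @property
    def query_coverage_pct(self) -> int:
        return coverage_percent(self.q_end - self.q_start, self.query_len)

    @property
    def r_span_1based(self) -> tuple[int, int]:
        return (self.r_start + 1, self.r_end)

    @property
    def q_span_1based(self) -> tuple[int, int]:
        return (self.q_start + 1, self.q_end)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


@njit(cache=False)
def _sw_kernel(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap Smith-Waterman with traceback.

    Returns (score, q_start, q_end, r_start, r_end, identities, aligned_len,
    gaps). Code 4 (N) never matches. Best cell ties prefer the smallest
    reference coordinate.
    """
    m = q.shape[0]
    n = r.shape[0]
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)  # gap in query (consumes ref)
    F = np.full((m + 1, n + 1), NEG, np.int32)  # gap in ref (consumes query)
    # traceback: tb_h 0=stop,1=diag,2=E,3=F; tb_e/tb_f 1=open,0=extend
    tb_h = np.zeros((m + 1, n + 1), np.uint8)
    tb_e = np.zeros((m + 1, n + 1), np.uint8)
    tb_f = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                tb_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                tb_f[i, j] = 1
            else:
                F[i, j] = f_ext
            rj = r[j - 1]
            if qi == rj and qi != 4:
                s = match
            else:
                s = -mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            t = 0
            if diag > h:
                h = diag
                t = 1
            if E[i, j] > h:
                h = E[i, j]
                t = 2
            if F[i, j] > h:
                h = F[i, j]
                t = 3
            H[i, j] = h
            tb_h[i, j] = t
            if h > best or (h == best and h > 0 and j < bj):
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    identities = 0
    aligned_len = 0
    gaps = 0
    state = 0  # 0=H, 1=E, 2=F
    while not (state == 0 and tb_h[i, j] == 0):
        if state == 0:
            t = tb_h[i, j]
            if t == 1:
                aligned_len += 1
                if q[i - 1] == r[j - 1] and q[i - 1] != 4:
                    identities += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            aligned_len += 1
            gaps += 1
            opened = tb_e[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            aligned_len += 1
            gaps += 1
            opened = tb_f[i, j]
            i -= 1
            if opened == 1:
                state = 0
        if i == 0 or j == 0:
            break
    return best, i, bi, j, bj, identities, aligned_len, gaps


def local_align(
    query: str,
    reference: str,
    scoring: ScoringScheme | None = None,
    query_id: str = "query",
    ref_id: str = "ref",
    both_strands: bool = True,
) -> list[LocalAlignment]:
    """Best local alignment of the query on each reference strand.

    The minus strand is handled by aligning the query's reverse complement
    and mapping its coordinates back to the original orientation. Results
    are sorted by score (descending), ties by reference start.
    """
    scoring = scoring or ScoringScheme()
    if len(query) < MIN_QUERY_LEN:
        raise ValueError(f"query shorter than {MIN_QUERY_LEN} bp ({len(query)} bp)")
    if not reference:
        raise ValueError("empty reference")
    ref = _encode(reference)
    out: list[LocalAlignment] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        qv = _encode(qseq)
        score, qs, qe, rs, re_, ident, alen, gaps = _sw_kernel(
            qv, ref, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
        )
        if score <= 0:
            continue
        if strand == "-":  # map back to original query orientation
            qs, qe = len(query) - qe, len(query) - qs
        aln = LocalAlignment(
            query_id, ref_id, strand, int(qs), int(qe), int(rs), int(re_),
            int(score), int(ident), int(alen), int(gaps),
            len(query), len(reference),
        )
        aln.e_value = karlin_altschul_evalue(aln.score, len(query), len(reference), scoring)
        out.append(aln)
    out.sort(key=lambda a: (-a.score, a.r_start))
    return out


def identity_percent(identities: int, aligned_len: int) -> int:
    """Integer (truncated) identity percentage over alignment columns."""
    if aligned_len <= 0:
        raise ValueError("aligned_len must be > 0")
    if identities > aligned_len:
        raise ValueError("identities cannot exceed aligned_len")
    return (100 * identities) // aligned_len


def coverage_percent(aligned_query_span: int, query_len: int) -> int:
    """Integer (truncated) query coverage percentage."""
    if query_len <= 0:
        raise ValueError("query_len must be > 0")
    return (100 * aligned_query_span) // query_len


def karlin_altschul_evalue(score: int, query_len: int, ref_len: int,
                           scoring: ScoringScheme | None = None) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    scoring = scoring or ScoringScheme()
    return scoring.k_param * query_len * ref_len * math.exp(-scoring.lam * score)


def alignment_stats(
    aln: LocalAlignment, query_len: int, ref_len: int,
    scoring: ScoringScheme | None = None,
) -> tuple[int, int, int, float]:
    """(coverage %, identity %, gaps, E-value) for a local alignment."""
    cov = coverage_percent(aln.q_end - aln.q_start, query_len)
    ident = identity_percent(aln.identities, aln.aligned_len)
    e = karlin_altschul_evalue(aln.score, query_len, ref_len, scoring)
    return cov, ident, aln.gaps, e


# ---------------------------------------------------------------------------
# insertion reporting
# ---------------------------------------------------------------------------


@dataclass
class InsertionReport:
    read_id: str
    status: str  # "mapped" | "no_similarity" | "discarded_quality"
    alignment: LocalAlignment | None = None
    insertion_pos: int | None = None  # 1-based reference coordinate
    gene: str | None = None  # gene id or "intergenic"
    notes: list[str] = field(default_factory=list)


def _validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    for c in ("gene", "start", "end"):
        if c not in annotations.columns:
            raise ValueError(f"annotation table missing column {c!r}")
    ann = annotations.sort_values("start").reset_index(drop=True)
    prev_end = 0
    for _, row in ann.iterrows():
        if row["start"] > row["end"]:
            raise ValueError(f"gene {row['gene']!r}: start > end")
        if row["start"] <= prev_end:
            raise ValueError(f"gene {row['gene']!r}: overlapping annotation")
        prev_end = row["end"]
    return ann


def gene_at(annotations: pd.DataFrame, pos_1based: int) -> str:
    """Gene whose 1-based inclusive interval contains the position."""
    hit = annotations[(annotations["start"] <= pos_1based) & (annotations["end"] >= pos_1based)]
    if hit.empty:
        return "intergenic"
    return str(hit.iloc[0]["gene"])


def report_insertion(
    alignments: Sequence[LocalAlignment],
    annotations: pd.DataFrame,
    e_cutoff: float = 1e-5,
    junction_side: str | None = "start",
    read_id: str = "",
) -> InsertionReport:
    """Locate the insertion from the best qualifying alignment.

    The "first hit" is the highest-scoring alignment with E <= cutoff (ties
    by smaller reference coordinate). The insertion coordinate is the
    reference base aligned to the query end that abutted the trimmed
    transposon end: for a junction at the query's 5' end this is the
    alignment's reference start on the plus strand and its reference end on
    the minus strand (and vice versa for a 3' junction).
    """
    ann = _validate_annotations(annotations)
    best = next((a for a in alignments if a.e_value <= e_cutoff), None)
    if best is None:
        return InsertionReport(read_id, "no_similarity")
    side = junction_side or "start"
    at_ref_start = (side == "start") == (best.strand == "+")
    pos = best.r_start + 1 if at_ref_start else best.r_end
    report = InsertionReport(read_id, "mapped", best, pos, gene_at(ann, pos))
    if junction_side is None:
        report.notes.append("junction side unknown (untrimmed read); 5' end assumed")
    return report


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: str,
    annotations: pd.DataFrame,
    policy: TrimPolicy | None = None,
    scoring: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    ref_id: str = "ref",
) -> list[InsertionReport]:
    """Trim + align + report every read against an annotated reference."""
    policy = policy or TrimPolicy()
    scoring = scoring or ScoringScheme()
    reports = []
    for read_id, seq in reads:
        tr = trim_read(read_id, seq, policy)
        if tr.status == "discarded_quality":
            reports.append(InsertionReport(read_id, "discarded_quality"))
            continue
        alns = local_align(tr.sequence, reference, scoring, query_id=read_id, ref_id=ref_id)
        rep = report_insertion(
            alns, annotations, e_cutoff,
            junction_side=tr.junction_side if tr.status == "trimmed" else None,
            read_id=read_id,
        )
        reports.append(rep)
    return reports


def insertion_table(reports: Sequence[InsertionReport]) -> pd.DataFrame:
    """Tabular per-read report with BLAST-style columns."""
    rows = []
    for r in reports:
        if r.status != "mapped":
            rows.append({"read": r.read_id, "gene": None, "insertion_pos": None,
                         "query_coverage_pct": None, "e_value": None,
                         "gaps": None, "identity": None,
                         "status": "No similarity found" if r.status == "no_similarity"
                         else r.status})
            continue
        a = r.alignment
        rows.append({
            "read": r.read_id,
            "gene": r.gene,
            "insertion_pos": r.insertion_pos,
            "query_coverage_pct": a.query_coverage_pct,
            "e_value": a.e_value,
            "gaps": f"{a.gaps}/{a.aligned_len}",
            "identity": f"{a.identities}/{a.aligned_len} ({a.identity_pct}%)",
            "status": "mapped",
        })
    return pd.DataFrame(rows)


def to_bed(reports: Sequence[InsertionReport], ref_id: str = "ref") -> pd.DataFrame:
    """BED (0-based half-open) table of mapped insertion points."""
    rows = [
        {"chrom": ref_id, "start": r.insertion_pos - 1, "end": r.insertion_pos,
         "name": r.read_id, "score": r.alignment.score,
         "strand": r.alignment.strand}
        for r in reports
        if r.status == "mapped"
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
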