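"""Alignment-dissimilarity features.

A query protein is encoded as its vector of normalized bit scores against
every sequence in the TF database ("dissimilarity representation"): the
query is locally aligned to each database sequence under deliberately
relaxed thresholds (at most 10,000 hits, identity >= 20%, e-value <=
1e-10), each surviving hit's bit score is divided by the query's
self-alignment bit score, and absent hits encode as 0 (maximum distance).
The resulting queries x database matrix is the classifier input.

The built-in reference backend computes optimal local alignments
(Smith-Waterman with affine gaps, BLOSUM62 by default) via
Bio.Align.PairwiseAligner and converts raw scores to bit scores and
e-values with Karlin-Altschul statistics using standard gapped BLOSUM62
constants (lambda = 0.267, K = 0.041) and search space m x N, where m is
the query length and N the total database residue count. An external
blastp backend can be substituted for scale; both must satisfy the same
threshold contract.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .database import TFDatabase
from .errors import ConsistencyError, NumericError, ParameterError

HITS_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class AlignerParams:
    """Relaxed alignment constraints used for feature construction.

    Thresholds apply as identity >= min_identity_pct and
    e-value <= max_evalue.
    """

    max_hits: int = 10_000
    min_identity_pct: float = 20.0
    max_evalue: float = 1e-10
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of a length-k gap: gap_open + k * gap_extend
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    backend: str = "builtin"  # or "blast"


@dataclass(frozen=True)
class AlignmentHit:
    """One surviving local alignment between a query and a database sequence."""

    query_id: str
    subject_id: str
    bit_score: float
    identity_pct: float
    evalue: float
    raw_score: float = 0.0
    q_start: int = 0  # 0-based half-open spans
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    aln_length: int = 0
    n_mismatch: int = 0
    n_gapopen: int = 0


@dataclass
class FeatureMatrix:
    """Queries x database normalized-bit-score matrix, values in [0, 1]."""

    values: pd.DataFrame
    no_hit: list[str] = field(default_factory=list)

    @property
    def query_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_index(self) -> list[str]:
        return list(self.values.columns)


def _as_query_items(queries) -> list[tuple[str, str]]:
    if isinstance(queries, Mapping):
        return list(queries.items())
    return [(q[0], q[1]) for q in queries]


def make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_matrix)
    # first gapped position costs open + extend, matching the BLAST convention
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def raw_to_bits(raw_score: float, params: AlignerParams) -> float:
    """Karlin-Altschul conversion of a raw alignment score to bits."""
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2.0)


def bits_to_evalue(bits: float, query_len: int, db_residues: int) -> float:
    """Expect value for a bit score in an m x N search space."""
    return float(query_len) * float(db_residues) * math.pow(2.0, -bits)


def self_bit_score(sequence: str, params: AlignerParams) -> float:
    """Bit score of a sequence aligned to itself.

    The optimal self local alignment is the full diagonal (every BLOSUM62
    diagonal entry is positive), so the raw score is the sum of diagonal
    substitution scores.
    """
    matrix = substitution_matrices.load(params.substitution_matrix)
    raw = sum(matrix[a, a] for a in sequence)
    return raw_to_bits(raw, params)


def align_all(
    queries,
    db: TFDatabase,
    params: AlignerParams | None = None,
) -> list[AlignmentHit]:
    """Align every query to every database sequence under relaxed thresholds.

    Returns, per query, at most ``max_hits`` hits satisfying
    identity >= min_identity_pct and e-value <= max_evalue, ordered by
    (bit score descending, subject id ascending). Queries are processed
    in input order.
    """
    params = params or AlignerParams()
    items = _as_query_items(queries)
    if not items:
        raise ParameterError("queries must be non-empty")
    if len(db) == 0:
        raise ParameterError("database must be non-empty")
    if params.backend == "blast":
        return _align_all_blast(items, db, params)
    if params.backend != "builtin":
        raise ParameterError(f"unknown aligner backend {params.backend!r}")

    aligner = make_aligner(params)
    db_residues = sum(len(r.sequence) for r in db.records)
    hits: list[AlignmentHit] = []
    for qid, qseq in items:
        per_query: list[AlignmentHit] = []
        for rec in db.records:
            raw = aligner.score(qseq, rec.sequence)
            if raw <= 0:
                continue
            bits = raw_to_bits(raw, params)
            evalue = bits_to_evalue(bits, len(qseq), db_residues)
            if evalue > params.max_evalue:
                continue
            alignment = aligner.align(qseq, rec.sequence)[0]
            counts = alignment.counts()
            aln_length = counts.identities + counts.mismatches + counts.gaps
            identity_pct = 100.0 * counts.identities / aln_length
            if identity_pct < params.min_identity_pct:
                continue
            q_blocks, s_blocks = alignment.aligned
            per_query.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=rec.record_id,
                    bit_score=bits,
                    identity_pct=identity_pct,
                    evalue=evalue,
                    raw_score=float(raw),
                    q_start=int(q_blocks[0][0]),
                    q_end=int(q_blocks[-1][1]),
                    s_start=int(s_blocks[0][0]),
                    s_end=int(s_blocks[-1][1]),
                    aln_length=int(aln_length),
                    n_mismatch=int(counts.mismatches),
                    n_gapopen=max(len(q_blocks) - 1, 0),
                )
            )
        per_query.sort(key=lambda h: (-h.bit_score, h.subject_id))
        hits.extend(per_query[: params.max_hits])
    return hits


def _align_all_blast(items, db: TFDatabase, params: AlignerParams) -> list[AlignmentHit]:
    """blastp backend for large inputs; same threshold contract as builtin."""
    for tool in ("makeblastdb", "blastp"):
        if shutil.which(tool) is None:
            raise ParameterError(f"blast backend requested but {tool} is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fasta = tmp / "db.fasta"
        with open(db_fasta, "w") as fh:
            for rec in db.records:
                fh.write(f">{rec.record_id}\n{rec.sequence}\n")
        q_fasta = tmp / "q.fasta"
        with open(q_fasta, "w") as fh:
            for qid, qseq in items:
                fh.write(f">{qid}\n{qseq}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = subprocess.run(
            [
                "blastp",
                "-query", str(q_fasta),
                "-db", str(db_fasta),
                "-outfmt", "6 " + " ".join(HITS_COLUMNS),
                "-evalue", str(params.max_evalue),
                "-max_target_seqs", str(params.max_hits),
                "-matrix", params.substitution_matrix,
                "-gapopen", str(params.gap_open),
                "-gapextend", str(params.gap_extend),
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    raw_hits: dict[str, list[AlignmentHit]] = {qid: [] for qid, _ in items}
    for line in out.stdout.splitlines():
        f = line.split("\t")
        hit = AlignmentHit(
            query_id=f[0],
            subject_id=f[1],
            bit_score=float(f[11]),
            identity_pct=float(f[2]),
            evalue=float(f[10]),
            q_start=int(f[6]) - 1,
            q_end=int(f[7]),
            s_start=int(f[8]) - 1,
            s_end=int(f[9]),
            aln_length=int(f[3]),
            n_mismatch=int(f[4]),
            n_gapopen=int(f[5]),
        )
        if hit.identity_pct < params.min_identity_pct or hit.evalue > params.max_evalue:
            continue
        if hit.query_id in raw_hits:
            raw_hits[hit.query_id].append(hit)
    hits: list[AlignmentHit] = []
    for qid, _ in items:
        per_query = sorted(raw_hits[qid], key=lambda h: (-h.bit_score, h.subject_id))
        # keep the best hit per subject only (blast may report multiple HSPs)
        seen: set[str] = set()
        dedup = [h for h in per_query if not (h.subject_id in seen or seen.add(h.subject_id))]
        hits.extend(dedup[: params.max_hits])
    return hits


def normalized_bitscore(hit: AlignmentHit, self_score: float) -> float:
    """Bit score of a hit scaled by the query's self-alignment bit score.

    Bounded to [0, 1]; a database member hitting itself scores exactly 1.
    """
    if self_score <= 0:
        raise NumericError(f"self score must be positive, got {self_score}")
    return min(hit.bit_score / self_score, 1.0)


def build_feature_matrix(
    queries,
    db: TFDatabase,
    hits: Iterable[AlignmentHit],
    params: AlignerParams | None = None,
) -> FeatureMatrix:
    """Assemble the queries x database normalized-bit-score matrix.

    Rows follow query input order; columns follow database order (frozen
    at training time). Queries with zero surviving hits get an all-zero
    row and are flagged no-hit.
    """
    params = params or AlignerParams()
    items = _as_query_items(queries)
    query_ids = [qid for qid, _ in items]
    self_bits = {qid: self_bit_score(qseq, params) for qid, qseq in items}
    col_index = {r.record_id: j for j, r in enumerate(db.records)}
    row_index = {qid: i for i, qid in enumerate(query_ids)}
    values = np.zeros((len(query_ids), len(col_index)))
    with_hits: set[str] = set()
    for hit in hits:
        if hit.subject_id not in col_index:
            raise ConsistencyError(f"hit references unknown database record {hit.subject_id!r}")
        if hit.query_id not in row_index:
            raise ConsistencyError(f"hit references unknown query {hit.query_id!r}")
        values[row_index[hit.query_id], col_index[hit.subject_id]] = normalized_bitscore(
            hit, self_bits[hit.query_id]
        )
        with_hits.add(hit.query_id)
    df = pd.DataFrame(values, index=query_ids, columns=list(col_index))
    no_hit = [qid for qid in query_ids if qid not in with_hits]
    return FeatureMatrix(values=df, no_hit=no_hit)


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Export hits in the tabular 12-column format (1-based inclusive coords)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.3f}",
                        h.aln_length,
                        h.n_mismatch,
                        h.n_gapopen,
                        h.q_start + 1,
                        h.q_end,
                        h.s_start + 1,
                        h.s_end,
                        f"{h.evalue:.3e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def read_hits_tsv(path) -> list[AlignmentHit]:
    """Import hits written by :func:`write_hits_tsv` or an external aligner."""
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    bit_score=float(f[11]),
                    identity_pct=float(f[2]),
                    evalue=float(f[10]),
                    q_start=int(f[6]) - 1,
                    q_end=int(f[7]),
                    s_start=int(f[8]) - 1,
                    s_end=int(f[9]),
                    aln_length=int(f[3]),
                    n_mismatch=int(f[4]),
                    n_gapopen=int(f[5]),
                )
            )
    return hits
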