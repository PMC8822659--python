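"""End-to-end orchestration used by the CLI.

Nucleotide input runs six-frame translation, classifies the candidate
peptides, and maps TF calls back to exact contig regions; protein input
classifies records directly. Expression mapping takes the predicted
regions plus one alignment library per sample and produces per-sample
profiles, the family x sample matrix, and dendrograms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

from . import __version__
from .classifier import Prediction, TFModel, classify
from .errors import InputError
from .expression import ExpressionParams, cluster_matrix, crossref, family_matrix
from .features import AlignerParams
from .translate import (
    DEFAULT_MIN_PEPTIDE_LENGTH,
    NT_ALPHABET,
    peptide_to_region,
    query_id_for,
    six_frame_translate,
)

from dataclasses import replace as _dc_replace  # noqa: F401  (kept for callers)


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of stage parameters; hashed into output provenance."""

    aligner: AlignerParams = field(default_factory=AlignerParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH
    orf_split: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"tfscout={__version__} config={self.config_hash()} seed={self.seed}"


def detect_alphabet(sequences: Mapping[str, str]) -> str:
    """'nucleotide' when >= 95% of residues are in {A,C,G,T,N}, else 'protein'."""
    total = sum(len(s) for s in sequences.values())
    if total == 0:
        return "protein"
    nt = sum(1 for s in sequences.values() for c in s.upper() if c in NT_ALPHABET)
    return "nucleotide" if nt / total >= 0.95 else "protein"


def predict_proteins(
    model: TFModel,
    queries: Mapping[str, str],
    params: Optional[AlignerParams] = None,
) -> list[Prediction]:
    """Classify protein records directly."""
    if not queries:
        return []
    return classify(model, queries, params)


def predict_nucleotides(
    model: TFModel,
    contigs: Mapping[str, str],
    params: Optional[AlignerParams] = None,
    min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH,
    orf_split: bool = True,
) -> list[Prediction]:
    """Six-frame translate contigs, classify peptides, back-map TF regions.

    Every candidate peptide becomes a query named
    ``<contig>_<frame>_<k>``; predictions that call a TF (classified or
    not) carry the exact nucleotide region and strand.
    """
    peptide_meta: dict[str, tuple[str, int, int, int]] = {}
    queries: dict[str, str] = {}
    for contig_id, seq in contigs.items():
        for ft in six_frame_translate(contig_id, seq, min_peptide_length, orf_split):
            for k, (peptide, start_aa) in enumerate(ft.peptides):
                qid = query_id_for(contig_id, ft.frame, k)
                queries[qid] = peptide
                peptide_meta[qid] = (contig_id, ft.frame, start_aa, len(peptide))
    if not queries:
        return []
    predictions = classify(model, queries, params)
    out: list[Prediction] = []
    for p in predictions:
        if p.call == "non-TF":
            out.append(p)
            continue
        contig_id, frame, start_aa, length_aa = peptide_meta[p.query_id]
        region = peptide_to_region(
            contig_id, len(contigs[contig_id]), frame, start_aa, length_aa
        )
        out.append(
            Prediction(
                query_id=p.query_id,
                call=p.call,
                family=p.family,
                probability=p.probability,
                best_hit=p.best_hit,
                identity_pct=p.identity_pct,
                evalue=p.evalue,
                region=region,
            )
        )
    return out


def check_mode(sequences: Mapping[str, str], mode: str) -> str:
    """Resolve/validate the input mode against the detected alphabet."""
    detected = detect_alphabet(sequences)
    if mode == "auto":
        return detected
    if mode not in ("protein", "nucleotide"):
        raise InputError(f"unknown mode {mode!r}")
    if sequences and mode != detected:
        first = next(iter(sequences))
        raise InputError(
            f"mode {mode!r} requested but record {first!r} looks like {detected}; "
            "pass --mode to override only if you are sure"
        )
    return mode


def map_expression(
    regions_with_family,
    alignment_paths,
    params: Optional[ExpressionParams] = None,
    sample_ids: Optional[list[str]] = None,
):
    """Profile expression of predicted TF regions across samples.

    Returns (profiles, family x sample matrix, ClusterResult or None).
    The dendrogram is only built with at least two samples.
    """
    params = params or ExpressionParams()
    profiles = []
    for i, path in enumerate(alignment_paths):
        sid = sample_ids[i] if sample_ids else None
        profiles.append(crossref(path, regions_with_family, params, sample_id=sid))
    matrix = family_matrix(profiles)
    clusters = cluster_matrix(matrix) if len(profiles) >= 2 and not matrix.empty else None
    return profiles, matrix, clusters
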