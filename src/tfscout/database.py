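"""Curated bacterial transcription-factor database.

The database merges locally exported source records (a CollecTF-style dump
of experimentally validated TFs and a UniProtKB-style dump of mostly
putative TFs), drops entries without a family label, normalizes family
labels, de-duplicates, and supports leave-taxon-out subsetting used to
train models that are evaluated on unseen genera or taxonomic families.

Source exports are a FASTA file (bare record ids as headers) plus a TSV
metadata table. The TSV dialect is UTF-8, tab-separated, one header row,
no quoting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, EmptyDatabaseError, InputError, ParameterError

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DIALECTS = ("collectf-like", "uniprot-like")
_META_COLUMNS = ("record_id", "family", "species", "genus", "tax_family", "source", "evidence")

# characters seen in raw source headers that leak into family labels
_HEADER_ARTIFACTS = re.compile(r"[>|*#\"']")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class TFRecord:
    """One curated TF entry: sequence plus family/taxonomy metadata."""

    record_id: str
    sequence: str
    family: str = ""
    species: str = ""
    genus: str = ""
    tax_family: str = ""
    source: str = "synthetic"
    evidence: str = "PU"  # EV = experimentally validated, PU = putative


@dataclass
class TFDatabase:
    """A curated set of TFRecords with provenance counters.

    Invariants after curation: unique record ids, every record carries a
    family, and no two records share the same (sequence, family) pair.
    """

    records: list[TFRecord]
    provenance: dict = field(default_factory=dict)
    label: str = "full"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.family)
        return list(seen)

    def sequences(self) -> dict[str, str]:
        return {r.record_id: r.sequence for r in self.records}


def normalize_family(label: str) -> str:
    """Canonical form of a family label.

    Strips header-artifact characters, collapses whitespace, and
    case-folds, so that e.g. "LysR" and " lysr " compare equal.
    """
    label = _HEADER_ARTIFACTS.sub("", label)
    label = _WS.sub(" ", label).strip()
    return label.casefold()


def parse_source(fasta_path, tsv_path, dialect: str):
    """Parse one source export into records plus a rejects report.

    collectf-like entries default to evidence EV; uniprot-like entries
    default to PU unless the metadata carries an ``evidence`` column.
    Malformed rows (empty sequence, FASTA/TSV id mismatch, bad residues)
    are collected in the rejects list, never silently dropped.

    Returns ``(records, rejects)`` where rejects is a list of
    ``(record_id, reason)`` pairs.
    """
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    fasta_path, tsv_path = Path(fasta_path), Path(tsv_path)
    for p in (fasta_path, tsv_path):
        if not p.exists():
            raise InputError(f"source file not found: {p}")

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()

    default_evidence = "EV" if dialect == "collectf-like" else "PU"
    records: list[TFRecord] = []
    rejects: list[tuple[str, str]] = []
    with open(tsv_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        if "record_id" not in idx:
            raise InputError(f"{tsv_path}: metadata table lacks a record_id column")
        seen_ids = set()
        for line in fh:
            row = line.rstrip("\n").split("\t")

            def col(name: str, default: str = "") -> str:
                i = idx.get(name)
                return row[i].strip() if i is not None and i < len(row) else default

            rid = col("record_id")
            if not rid:
                rejects.append(("", "missing record_id"))
                continue
            if rid in seen_ids:
                rejects.append((rid, "duplicate record_id in metadata"))
                continue
            seen_ids.add(rid)
            seq = seqs.get(rid, "")
            if not seq:
                rejects.append((rid, "empty or missing sequence"))
                continue
            bad = set(seq) - AA_ALPHABET
            if bad:
                rejects.append((rid, f"non-amino-acid characters {sorted(bad)}"))
                continue
            records.append(
                TFRecord(
                    record_id=rid,
                    sequence=seq,
                    family=col("family"),
                    species=col("species"),
                    genus=col("genus"),
                    tax_family=col("tax_family"),
                    source=dialect,
                    evidence=col("evidence") or default_evidence,
                )
            )
    for rid in seqs:
        if rid not in seen_ids:
            rejects.append((rid, "sequence without metadata row"))
    return records, rejects


def merge_and_curate(record_sets: list[list[TFRecord]], n_rejects: int = 0) -> TFDatabase:
    """Merge source record sets into one curated database.

    Curation steps, in order: concatenate; drop records lacking a family
    label; normalize family labels; de-duplicate on (sequence, normalized
    family) keeping EV over PU and otherwise first-seen. Provenance
    counters satisfy merged == kept + dropped_no_family + dropped_duplicate.
    """
    if not record_sets:
        raise ParameterError("at least one record set is required")
    merged = [r for rs in record_sets for r in rs]

    canonical: dict[str, str] = {}  # normalized label -> first-seen display form
    kept: dict[tuple[str, str], TFRecord] = {}
    dropped_no_family = 0
    dropped_duplicate = 0
    used_ids: set[str] = set()
    for rec in merged:
        norm = normalize_family(rec.family)
        if not norm:
            dropped_no_family += 1
            continue
        display = canonical.setdefault(norm, _WS.sub(" ", _HEADER_ARTIFACTS.sub("", rec.family)).strip())
        rec = replace(rec, family=display)
        key = (rec.sequence, norm)
        prev = kept.get(key)
        if prev is None:
            if rec.record_id in used_ids:
                rec = replace(rec, record_id=_fresh_id(rec.record_id, used_ids))
            used_ids.add(rec.record_id)
            kept[key] = rec
        else:
            dropped_duplicate += 1
            if prev.evidence != "EV" and rec.evidence == "EV":
                used_ids.discard(prev.record_id)
                if rec.record_id in used_ids:
                    rec = replace(rec, record_id=_fresh_id(rec.record_id, used_ids))
                used_ids.add(rec.record_id)
                kept[key] = rec

    if not kept:
        raise EmptyDatabaseError("curation removed every record")
    records = list(kept.values())
    provenance = {
        "merged": len(merged),
        "kept": len(records),
        "dropped_no_family": dropped_no_family,
        "dropped_duplicate": dropped_duplicate,
        "parse_rejects": n_rejects,
        "n_families": len({normalize_family(r.family) for r in records}),
    }
    return TFDatabase(records=records, provenance=provenance)


def _fresh_id(base: str, used: set[str]) -> str:
    k = 2
    while f"{base}.{k}" in used:
        k += 1
    return f"{base}.{k}"


def exclude_taxon(db: TFDatabase, rank: str, name: str) -> TFDatabase:
    """Leave-taxon-out subset: drop every record of a genus or taxonomic family.

    Matching is case-insensitive and exact. The input database is left
    untouched; the subset is labeled ``no-<name>``. An absent name yields
    an unchanged copy with a logged notice, not an error.
    """
    if rank not in ("genus", "tax_family"):
        raise ParameterError(f"rank must be 'genus' or 'tax_family', got {rank!r}")
    target = name.casefold()
    keep = [r for r in db.records if getattr(r, rank).casefold() != target]
    n_removed = len(db.records) - len(keep)
    if n_removed == 0:
        logger.info("exclude_taxon: no records match %s=%r; database unchanged", rank, name)
    provenance = dict(db.provenance)
    provenance[f"excluded_{rank}"] = name
    provenance["excluded_records"] = n_removed
    return TFDatabase(records=keep, provenance=provenance, label=f"no-{name}")


def write_db(db: TFDatabase, out_dir) -> Path:
    """Persist a database as db.fasta + db.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in db.records
    ]
    SeqIO.write(seq_records, str(out_dir / "db.fasta"), "fasta")
    with open(out_dir / "db.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for r in db.records:
            fh.write(
                "\t".join(
                    (r.record_id, r.family, r.species, r.genus, r.tax_family, r.source, r.evidence)
                )
                + "\n"
            )
    with open(out_dir / "provenance.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"label\t{db.label}\n")
        for k, v in db.provenance.items():
            fh.write(f"{k}\t{v}\n")
    return out_dir


def read_db(in_dir) -> TFDatabase:
    """Load a database written by :func:`write_db`.

    Raises ConsistencyError when the FASTA and TSV disagree on record ids.
    """
    in_dir = Path(in_dir)
    fasta, tsv = in_dir / "db.fasta", in_dir / "db.tsv"
    for p in (fasta, tsv):
        if not p.exists():
            raise InputError(f"database file not found: {p}")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    records: list[TFRecord] = []
    with open(tsv, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _META_COLUMNS:
            raise InputError(f"{tsv}: unexpected metadata columns {header}")
        tsv_ids = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(_META_COLUMNS, vals))
            tsv_ids.append(row["record_id"])
            records.append(
                TFRecord(
                    record_id=row["record_id"],
                    sequence=seqs.get(row["record_id"], ""),
                    family=row["family"],
                    species=row["species"],
                    genus=row["genus"],
                    tax_family=row["tax_family"],
                    source=row["source"],
                    evidence=row["evidence"],
                )
            )
    only_tsv = [i for i in tsv_ids if i not in seqs]
    only_fasta = [i for i in seqs if i not in set(tsv_ids)]
    if only_tsv or only_fasta:
        raise ConsistencyError(
            f"FASTA/TSV id mismatch in {in_dir}: "
            f"metadata-only={only_tsv[:5]}, fasta-only={only_fasta[:5]}"
        )
    provenance: dict = {}
    label = "full"
    prov_path = in_dir / "provenance.tsv"
    if prov_path.exists():
        with open(prov_path, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                k, _, v = line.rstrip("\n").partition("\t")
                if k == "label":
                    label = v
                else:
                    provenance[k] = int(v) if v.lstrip("-").isdigit() else v
    return TFDatabase(records=records, provenance=provenance, label=label)
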