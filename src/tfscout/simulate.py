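"""Synthetic TF data generation.

Every downstream stage (database curation, feature alignment, classifier
training, six-frame translation, expression mapping) is testable without
downloads: protein families are grown by point-mutating a random
ancestor, genes are reverse-translated and embedded in contigs with
recorded truth coordinates, and single-end reads are placed over chosen
regions and written as plain SAM.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .database import TFRecord
from .errors import ParameterError
from .translate import Region, _CODON_TO_AA, reverse_complement

logger = logging.getLogger(__name__)

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT4 = np.array(list("ACGT"))

# deterministic taxonomy pool so leave-taxon-out tests have known partitions;
# each taxonomic family spans the listed genera
GENUS_POOL = ("GenusA", "GenusB", "GenusC", "GenusD", "GenusE")
TAX_FAMILY_OF = {
    "GenusA": "TaxfamAB",
    "GenusB": "TaxfamAB",
    "GenusC": "TaxfamCD",
    "GenusD": "TaxfamCD",
    "GenusE": "TaxfamE",
}

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()


@dataclass(frozen=True)
class FamilySpec:
    """Shape of one synthetic TF family."""

    family_name: str
    n_members: int
    ancestor_length: int
    mutation_rate: float  # per-site substitution probability

    def __post_init__(self):
        if self.n_members < 1:
            raise ParameterError(f"n_members must be >= 1, got {self.n_members}")
        if self.ancestor_length < 1:
            raise ParameterError(f"ancestor_length must be >= 1, got {self.ancestor_length}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ParameterError(f"mutation_rate must be in [0, 1], got {self.mutation_rate}")


@dataclass(frozen=True)
class TruthRegion:
    """Ground-truth placement of one embedded gene."""

    region: Region
    record_id: str
    family: str
    peptide: str


@dataclass
class ContigFixture:
    """One synthetic contig with its embedded-gene truth regions."""

    contig_id: str
    sequence: str
    truth_regions: list = field(default_factory=list)


def generate_family_set(specs: list[FamilySpec], seed: int) -> list[TFRecord]:
    """Grow synthetic TF families by point-mutating random ancestors.

    One random ancestor is drawn per family; each member is an
    independently mutated copy (substitutions only, so members stay
    length-aligned to the ancestor). Genus cycles through a fixed pool
    by member index, giving every family members from several genera;
    evidence class alternates EV/PU.
    """
    if not specs:
        raise ParameterError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[TFRecord] = []
    for spec in specs:
        ancestor = rng.choice(AA20, size=spec.ancestor_length)
        for i in range(spec.n_members):
            member = ancestor.copy()
            mutate = rng.random(spec.ancestor_length) < spec.mutation_rate
            if mutate.any():
                # draw replacements distinct from the current residue
                for pos in np.nonzero(mutate)[0]:
                    choices = AA20[AA20 != member[pos]]
                    member[pos] = rng.choice(choices)
            genus = GENUS_POOL[i % len(GENUS_POOL)]
            records.append(
                TFRecord(
                    record_id=f"{spec.family_name}_{i:03d}",
                    sequence="".join(member),
                    family=spec.family_name,
                    species=f"{genus} strain{i}",
                    genus=genus,
                    tax_family=TAX_FAMILY_OF[genus],
                    source="synthetic",
                    evidence="EV" if i % 2 == 0 else "PU",
                )
            )
    return records


def generate_negatives(n: int, length: int, seed: int) -> list[str]:
    """Random proteins with uniform residue composition (non-TF background)."""
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(AA20, size=length)) for _ in range(n)]


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniformly random synonymous codons for a peptide (standard code)."""
    codons = []
    for aa in peptide:
        options = _CODONS_FOR_AA.get(aa)
        if not options:
            raise ParameterError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def embed_genes_in_contigs(
    records: list[TFRecord],
    spacer_length: int,
    strands: str | list[str] = "random",
    seed: int = 0,
) -> list[ContigFixture]:
    """Place each protein, reverse-translated, on its own contig.

    Each gene sits between random spacers of ``spacer_length``
    nucleotides; '-' strand genes are reverse-complemented in place. The
    truth region records exact coordinates, strand, and frame.

    ``strands`` is "+", "-", "random", or a per-record list.
    """
    if not records:
        raise ParameterError("records must be non-empty")
    rng = np.random.default_rng(seed)
    if isinstance(strands, str):
        strand_list = [strands] * len(records)
    else:
        strand_list = list(strands)
        if len(strand_list) != len(records):
            raise ParameterError("strands list length must match records")
    contigs: list[ContigFixture] = []
    for rec, strand_choice in zip(records, strand_list):
        strand = strand_choice
        if strand == "random":
            strand = "+" if rng.random() < 0.5 else "-"
        if strand not in "+-":
            raise ParameterError(f"invalid strand {strand_choice!r}")
        gene = reverse_translate(rec.sequence, rng)
        if strand == "-":
            gene = reverse_complement(gene)
        left = "".join(rng.choice(NT4, size=spacer_length))
        right = "".join(rng.choice(NT4, size=spacer_length))
        sequence = left + gene + right
        start = spacer_length
        end = start + len(gene)
        if strand == "+":
            frame = (start % 3) + 1
        else:
            frame = 4 + (len(sequence) - end) % 3
        contig_id = f"contig_{rec.record_id}"
        region = Region(contig_id=contig_id, start=start, end=end, strand=strand, frame=frame)
        contigs.append(
            ContigFixture(
                contig_id=contig_id,
                sequence=sequence,
                truth_regions=[
                    TruthRegion(
                        region=region,
                        record_id=rec.record_id,
                        family=rec.family,
                        peptide=rec.sequence,
                    )
                ],
            )
        )
    return contigs


def simulate_reads(
    contigs: list[ContigFixture],
    expressed_region_ids: set,
    read_length: int,
    depth: int,
    seed: int,
    path=None,
) -> str:
    """Place single-end reads inside expressed truth regions; emit SAM.

    Regions are addressed by their source record id. Exactly ``depth``
    reads are placed uniformly inside each expressed region; regions
    shorter than the read length are skipped with a warning. Reads are
    written with flag 0, full-match CIGAR, and placeholder qualities.
    """
    if read_length < 1:
        raise ParameterError(f"read_length must be >= 1, got {read_length}")
    known_ids = {t.record_id for c in contigs for t in c.truth_regions}
    unknown = set(expressed_region_ids) - known_ids
    if unknown:
        raise ParameterError(f"expressed ids not among truth regions: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for contig in contigs:
        lines.append(f"@SQ\tSN:{contig.contig_id}\tLN:{len(contig.sequence)}")
    lines.append("@PG\tID:tfscout-simulate\tPN:tfscout")
    for contig in contigs:
        reads = []
        for truth in contig.truth_regions:
            if truth.record_id not in expressed_region_ids:
                continue
            region = truth.region
            if read_length > region.length:
                logger.warning(
                    "read length %d exceeds region %s (%d nt); region skipped",
                    read_length, region.region_id, region.length,
                )
                continue
            starts = region.start + rng.integers(
                0, region.length - read_length + 1, size=depth
            )
            for j, s in enumerate(sorted(int(s) for s in starts)):
                seq = contig.sequence[s : s + read_length]
                reads.append(
                    (
                        s,
                        "\t".join(
                            (
                                f"read_{truth.record_id}_{j}",
                                "0",
                                contig.contig_id,
                                str(s + 1),
                                "60",
                                f"{read_length}M",
                                "*",
                                "0",
                                "0",
                                seq,
                                "I" * read_length,
                            )
                        ),
                    )
                )
        reads.sort(key=lambda r: r[0])
        lines.extend(r[1] for r in reads)
    sam = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(sam, encoding="utf-8")
    return sam


def write_fasta(entries, path) -> None:
    """Write (id, sequence) pairs as FASTA (60-column wrap)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_truth_bed(contigs: list[ContigFixture], path) -> None:
    """Truth regions as BED6 (0-based half-open), score = 0."""
    with open(path, "w", encoding="utf-8") as fh:
        for contig in contigs:
            for t in contig.truth_regions:
                r = t.region
                fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{t.record_id}\t0\t{r.strand}\n")


def write_source_exports(records: list[TFRecord], out_dir, split: bool = True) -> dict:
    """Write records as database source exports.

    With ``split``, EV records go to a collectf-like export and PU
    records to a uniprot-like export (mirroring the provenance of the
    real source databases); otherwise everything lands in one
    uniprot-like export. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[TFRecord]] = {"collectf": [], "uniprot": []}
    for rec in records:
        if split and rec.evidence == "EV":
            groups["collectf"].append(rec)
        else:
            groups["uniprot"].append(rec)
    paths = {}
    for name, group in groups.items():
        fasta = out_dir / f"{name}.fasta"
        tsv = out_dir / f"{name}.tsv"
        write_fasta([(r.record_id, r.sequence) for r in group], fasta)
        with open(tsv, "w", encoding="utf-8") as fh:
            fh.write("record_id\tfamily\tspecies\tgenus\ttax_family\tevidence\n")
            for r in group:
                fh.write(
                    f"{r.record_id}\t{r.family}\t{r.species}\t{r.genus}\t{r.tax_family}\t{r.evidence}\n"
                )
        paths[name] = (fasta, tsv)
    return paths
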