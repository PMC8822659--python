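"""Six-frame translation and exact coordinate back-mapping.

Contigs are translated in all six frames with the standard genetic code
(frames 1-3: forward offsets 0-2; frames 4-6: reverse-complement offsets
0-2, following the EMBOSS transeq ``_1``..``_6`` suffix dialect). Each
frame translation is split at stop codons into candidate peptides; short
fragments are dropped before prediction. A protein-level prediction is
mapped back to its exact nucleotide region and strand, and the region
can be extracted so that re-translating it reproduces the peptide.

Coordinates are 0-based half-open internally; BED export keeps that
convention, GFF3 export converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import CoordinateError, InputError

NT_ALPHABET = frozenset("ACGTN")
DEFAULT_MIN_PEPTIDE_LENGTH = 60

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)


@dataclass(frozen=True)
class Region:
    """Nucleotide interval on a contig, 0-based half-open, with strand and frame."""

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 1..6

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise CoordinateError(
                f"degenerate region {self.start}-{self.end} on {self.contig_id}"
            )
        if (self.end - self.start) % 3 != 0:
            raise CoordinateError(
                f"region length {self.end - self.start} not divisible by 3"
            )
        if self.strand not in "+-" or not 1 <= self.frame <= 6:
            raise CoordinateError(f"invalid strand/frame: {self.strand}/{self.frame}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class FrameTranslation:
    """One frame's translation, split into candidate peptides.

    ``translation`` is the full frame translation with ``*`` marking
    stops; ``peptides`` holds (peptide, start offset in amino acids
    within the frame translation) pairs that survived the length filter.
    """

    contig_id: str
    frame: int
    translation: str
    peptides: list  # [(peptide, peptide_start_aa), ...]


def _check_alphabet(contig_id: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise InputError(
            f"contig {contig_id!r} contains non-nucleotide characters {sorted(bad)}"
        )
    return seq


def translate_codons(seq: str) -> str:
    """Translate a frame (standard code); codons containing N become X."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _CODON_TO_AA:
            out.append(_CODON_TO_AA[codon])
        elif codon in _STOPS:
            out.append("*")
        else:  # contains N
            out.append("X")
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def six_frame_translate(
    contig_id: str,
    sequence: str,
    min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH,
    orf_split: bool = True,
) -> list[FrameTranslation]:
    """Translate a contig in all six frames and split at stop codons.

    With ``orf_split`` off, each frame yields a single peptide spanning
    the whole frame translation with stops masked as X (coordinate
    round-tripping is only exact in split mode, where emitted peptides
    never contain stops).
    """
    sequence = _check_alphabet(contig_id, sequence)
    rc = reverse_complement(sequence)
    out: list[FrameTranslation] = []
    for frame in range(1, 7):
        offset = (frame - 1) % 3
        source = sequence if frame <= 3 else rc
        translation = translate_codons(source[offset:])
        if orf_split:
            peptides = []
            pos = 0
            for chunk in translation.split("*"):
                if len(chunk) >= max(min_peptide_length, 1):
                    peptides.append((chunk, pos))
                pos += len(chunk) + 1
        else:
            masked = translation.replace("*", "X")
            peptides = [(masked, 0)] if len(masked) >= max(min_peptide_length, 1) else []
        out.append(
            FrameTranslation(
                contig_id=contig_id, frame=frame, translation=translation, peptides=peptides
            )
        )
    return out


def query_id_for(contig_id: str, frame: int, k: int) -> str:
    return f"{contig_id}_{frame}_{k}"


def peptide_to_region(
    contig_id: str,
    contig_length: int,
    frame: int,
    peptide_start_aa: int,
    peptide_length_aa: int,
) -> Region:
    """Map a peptide inside a frame translation back to nucleotide coordinates.

    Frames 1-3 map directly; frames 4-6 apply the same arithmetic on the
    reverse complement and reflect the interval back onto the forward
    strand.
    """
    if peptide_length_aa <= 0:
        raise CoordinateError("peptide length must be positive")
    if frame <= 3:
        start = (frame - 1) + 3 * peptide_start_aa
        end = start + 3 * peptide_length_aa
        strand = "+"
    else:
        end = contig_length - ((frame - 4) + 3 * peptide_start_aa)
        start = end - 3 * peptide_length_aa
        strand = "-"
    if start < 0 or end > contig_length:
        raise CoordinateError(
            f"peptide (frame {frame}, start {peptide_start_aa} aa, "
            f"len {peptide_length_aa} aa) exceeds contig bounds 0-{contig_length}"
        )
    return Region(contig_id=contig_id, start=start, end=end, strand=strand, frame=frame)


def extract_region(sequence: str, region: Region) -> str:
    """Nucleotide subsequence of a region, reverse-complemented on '-'.

    Translating the returned sequence in frame 1 reproduces the peptide
    that generated the region.
    """
    if region.end > len(sequence):
        raise CoordinateError(
            f"region {region.region_id} exceeds contig length {len(sequence)}"
        )
    sub = sequence[region.start : region.end]
    return reverse_complement(sub) if region.strand == "-" else sub


def write_bed(entries: Iterable[tuple[Region, str, float]], path, provenance: Optional[str] = None) -> None:
    """BED6 export: name = query id, score = probability scaled to 0-1000."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"track name=tfscout description=\"{provenance}\"\n")
        for region, name, prob in entries:
            score = int(round(1000 * max(0.0, min(prob, 1.0))))
            fh.write(
                f"{region.contig_id}\t{region.start}\t{region.end}\t{name}\t{score}\t{region.strand}\n"
            )


def write_gff3(entries: Iterable[tuple[Region, str, float, str]], path, provenance: Optional[str] = None) -> None:
    """GFF3 export (1-based inclusive): one CDS-like feature per predicted TF."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        if provenance:
            fh.write(f"#!{provenance}\n")
        for region, name, prob, family in entries:
            attrs = f"ID={name};tf_family={family}" if family else f"ID={name}"
            fh.write(
                "\t".join(
                    (
                        region.contig_id,
                        "tfscout",
                        "protein_match",
                        str(region.start + 1),
                        str(region.end),
                        f"{prob:.4f}",
                        region.strand,
                        "0",
                        attrs,
                    )
                )
                + "\n"
            )


def read_bed(path, contig_lengths: Optional[dict] = None) -> list[tuple[Region, str, float]]:
    """Parse a BED6 file written by :func:`write_bed`.

    The frame is recovered from coordinates and strand; recovering the
    frame of a '-' strand region needs the contig length, so pass
    ``contig_lengths`` when exact frames matter (frame defaults to 4 for
    '-' regions otherwise).
    """
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            contig, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            start, end = int(start), int(end)
            if strand == "+":
                frame = (start % 3) + 1
            elif contig_lengths and contig in contig_lengths:
                frame = 4 + (contig_lengths[contig] - end) % 3
            else:
                frame = 4
            entries.append(
                (
                    Region(contig_id=contig, start=start, end=end, strand=strand, frame=frame),
                    name,
                    int(score) / 1000.0,
                )
            )
    return entries
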