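"""Six-frame ORF calling and bacterial translation (table 11).

This is a deterministic longest-ORF caller: on each of the six reading frames
an ORF runs from the first start codon (ATG/GTG/TTG) after the previous stop
to the next in-frame stop, stop codon included in the span. The downstream
analysis consumes ORF catalogs for homology search, so precise gene starts
(RBS scoring, GC-frame statistics of a trained gene finder) are deliberately
out of scope. Partial ORFs without a stop codon are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Data import CodonTable

from .seqio import PlasmidRecord, reverse_complement, write_fasta

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid, stops mapped to "*" (NCBI translation table 11)
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE11.stop_codons})

STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


class TranslationError(ValueError):
    pass


def translate(codon_string: str, initiator: bool = False) -> str:
    """Translate DNA with NCBI table 11.

    Codons containing N (or any non-ACGT character) become X; X never acts as
    a stop. With ``initiator=True`` the first codon is rendered as M when it
    is a valid bacterial start codon.
    """
    if len(codon_string) % 3 != 0:
        raise TranslationError(
            f"codon string length {len(codon_string)} is not a multiple of 3"
        )
    seq = codon_string.upper()
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aas.append(CODON_TO_AA.get(codon, "X"))
    if initiator and aas and seq[:3] in DEFAULT_START_CODONS:
        aas[0] = "M"
    return "".join(aas)


@dataclass(frozen=True)
class OrfRecord:
    """One predicted coding region, in forward-strand coordinates.

    ``start``/``end`` are 0-based half-open and include the stop codon, so the
    protein has (end-start)/3 - 1 residues. For origin-spanning ORFs on
    circular plasmids ``end`` may exceed the plasmid length.
    """

    orf_id: str
    plasmid_id: str
    start: int
    end: int
    strand: str
    protein: str


def _scan_frames(seq: str, min_length_nt: int, start_codons: tuple[str, ...]):
    """Yield (start, end) spans of ORFs on the forward strand of ``seq``."""
    n = len(seq)
    for frame in range(3):
        orf_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if orf_start is not None and pos + 3 - orf_start >= min_length_nt:
                    yield orf_start, pos + 3
                orf_start = None
            elif orf_start is None and codon in start_codons:
                orf_start = pos
        # ORFs running off the end lack a stop codon and are dropped


def find_orfs(
    plasmid: PlasmidRecord,
    min_length_nt: int = 90,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    circular_extension_nt: int = 3000,
) -> list[OrfRecord]:
    """Predict ORFs on both strands of a plasmid.

    Reverse-strand ORFs are reported in forward coordinates with strand "-".
    Results are sorted by start, then strand, then end; ``orf_id`` is
    ``<plasmid_id>_<running index>`` in that order. Nested and overlapping
    ORFs in different frames are all reported. When the plasmid is circular,
    the scan appends a junction-spanning extension so that ORFs crossing the
    origin are found; such ORFs keep ``start < length`` and ``end > length``.
    """
    if min_length_nt < 6 or min_length_nt % 3 != 0:
        raise ValueError("min_length_nt must be >= 6 and divisible by 3")
    starts = tuple(start_codons)
    seq = plasmid.sequence
    n = len(seq)
    scan_seq = seq
    if plasmid.topology == "circular" and n > 3:
        scan_seq = seq + seq[: min(circular_extension_nt, n)]
    m = len(scan_seq)

    spans: set[tuple[int, int, str]] = set()
    for s, e in _scan_frames(scan_seq, min_length_nt, starts):
        # spans starting inside the circular extension duplicate an ORF
        # already reported (or reportable) at start - n
        if s < n:
            spans.add((s, e, "+"))
        elif s - n + (e - s) > n:
            # wraps twice around a very short plasmid; ignore
            continue
    rc = reverse_complement(scan_seq)
    for s, e in _scan_frames(rc, min_length_nt, starts):
        fs, fe = m - e, m - s  # forward coords on the (possibly extended) scan
        if fs < n:
            spans.add((fs, fe, "-"))

    ordered = sorted(spans, key=lambda t: (t[0], t[2], t[1]))
    orfs = []
    for idx, (s, e, strand) in enumerate(ordered, start=1):
        if strand == "+":
            coding = scan_seq[s:e] if e <= m else seq[s:] + seq[: e - n]
        else:
            piece = scan_seq[s:e] if e <= m else seq[s:] + seq[: e - n]
            coding = reverse_complement(piece)
        protein = translate(coding[:-3], initiator=True)
        orfs.append(
            OrfRecord(
                orf_id=f"{plasmid.id}_{idx}",
                plasmid_id=plasmid.id,
                start=s,
                end=e,
                strand=strand,
                protein=protein,
            )
        )
    return orfs


def write_gff3(path: str | Path, orfs: Sequence[OrfRecord]) -> None:
    """Write ORFs as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for o in orfs:
            handle.write(
                f"{o.plasmid_id}\tplasbhr\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.orf_id}\n"
            )


def write_orf_fasta(path: str | Path, orfs: Sequence[OrfRecord]) -> None:
    write_fasta(path, [(o.orf_id, o.protein) for o in orfs])
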