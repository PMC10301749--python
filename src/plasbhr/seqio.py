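"""Sequence records and FASTA I/O for plasmids and reference panels.

Plasmid sequences are DNA over {A,C,G,T,N}; IUPAC ambiguity codes other than
N are accepted on input but collapsed to N, since every downstream computation
(GC content, ORF calling, alignment) treats them as unknown. Reference panels
are category-tagged: one FASTA per functional category, with the header
dialect ``id|family[|cognate_partner]`` (T-AT categories) or
``id|family[|antibiotic_class]`` (ARGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Category(str, Enum):
    """Functional categories screened on each plasmid."""

    REP = "REP"
    RELAXASE = "RELAXASE"
    T4SS = "T4SS"
    TOXIN = "TOXIN"
    ANTITOXIN = "ANTITOXIN"
    PAR = "PAR"
    PSI = "PSI"
    MPS = "MPS"
    MTASE = "MTASE"
    ARG = "ARG"
    VF = "VF"
    ORIT = "ORIT"
    RNA_ANTITOXIN = "RNA_ANTITOXIN"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


#: Categories searched at the nucleotide level (everything else is protein).
NUCLEOTIDE_CATEGORIES = frozenset({Category.ORIT, Category.RNA_ANTITOXIN})

#: The five host-range feature categories of the >=3-of-5 rule. The T-AT
#: feature draws on TOXIN + ANTITOXIN/RNA_ANTITOXIN jointly.
FEATURE_CATEGORIES = ("TAT", "PAR", "PSI", "MPS", "MTASE")

_DNA_STRICT = frozenset("ACGTN")
_DNA_IUPAC = frozenset("ACGTNURYSWKMBDHV")
_PROTEIN = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Malformed FASTA structure (reported with the offending line number)."""


class SequenceValidationError(ValueError):
    """A sequence violates the declared molecule alphabet or a record invariant."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, molecule: str) -> list[tuple[str, str]]:
    """Read a FASTA file, returning ``(id, sequence)`` pairs in file order.

    Sequences are uppercased and whitespace-stripped; U is folded to T for
    nucleotide files. Duplicate ids and residues illegal for the declared
    molecule are rejected.

    Parameters
    ----------
    path : file path
    molecule : ``"protein"`` or ``"nucleotide"``
    """
    if molecule not in ("protein", "nucleotide"):
        raise ValueError(f"molecule must be 'protein' or 'nucleotide', got {molecule!r}")
    alphabet = _PROTEIN if molecule == "protein" else _DNA_IUPAC

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks)
        if molecule == "nucleotide":
            seq = seq.replace("U", "T")
        bad = set(seq) - alphabet
        if bad:
            raise SequenceValidationError(
                f"record {current_id!r}: illegal {molecule} residue(s) "
                f"{''.join(sorted(bad))!r}"
            )
        records.append((current_id, seq))
        current_id, chunks = None, []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                rec_id = header.split()[0]
                if rec_id in seen:
                    raise FastaParseError(
                        f"{path}: duplicate record id {rec_id!r} at line {lineno}"
                    )
                seen.add(rec_id)
                current_id = rec_id
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.upper())
    _flush()
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def gc_content(sequence: str) -> float:
    """Fraction of G+C among unambiguous bases.

    N and other ambiguity codes are excluded from numerator and denominator.
    Returns NaN when the sequence contains no unambiguous base.
    """
    if not sequence:
        raise SequenceValidationError("gc_content of an empty sequence is undefined")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return float("nan")
    return gc / denom


@dataclass
class PlasmidRecord:
    """One input replicon sequence.

    ``length`` and ``gc_content`` are derived properties, recomputed from the
    sequence on access so they can never go stale.
    """

    id: str
    sequence: str
    topology: str = "linear"
    source_isolate: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - _DNA_IUPAC
        if bad:
            raise SequenceValidationError(
                f"plasmid {self.id!r}: illegal nucleotide(s) {''.join(sorted(bad))!r}"
            )
        # collapse non-N ambiguity codes to N for all downstream computation
        if not set(seq) <= _DNA_STRICT:
            seq = "".join(c if c in _DNA_STRICT else "N" for c in seq)
        if not seq:
            raise SequenceValidationError(f"plasmid {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise SequenceValidationError(
                f"plasmid {self.id!r}: topology must be linear or circular"
            )
        self.sequence = seq

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        return gc_content(self.sequence)


@dataclass
class ReferenceEntry:
    """One reference sequence tagged with its functional category and family."""

    id: str
    category: Category
    family: str
    molecule: str
    sequence: str
    cognate_partner: str | None = None
    arg_class: str | None = None

    def __post_init__(self) -> None:
        self.category = Category(self.category)
        expected = "nucleotide" if self.category in NUCLEOTIDE_CATEGORIES else "protein"
        if self.molecule != expected:
            raise SequenceValidationError(
                f"reference {self.id!r}: category {self.category} requires "
                f"{expected} molecule, got {self.molecule}"
            )
        alphabet = _PROTEIN if self.molecule == "protein" else _DNA_IUPAC
        bad = set(self.sequence) - alphabet
        if bad:
            raise SequenceValidationError(
                f"reference {self.id!r}: illegal {self.molecule} residue(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if self.category in (Category.TOXIN, Category.ANTITOXIN):
            if not self.cognate_partner:
                raise SequenceValidationError(
                    f"reference {self.id!r}: {self.category} entries require a "
                    "cognate_partner in the header (id|family|partner)"
                )
        elif self.cognate_partner:
            raise SequenceValidationError(
                f"reference {self.id!r}: cognate_partner only allowed for "
                "TOXIN/ANTITOXIN entries"
            )
        if not self.family:
            raise SequenceValidationError(f"reference {self.id!r}: empty family")


def load_reference_sets(paths: Mapping[Category | str, str | Path]) -> list[ReferenceEntry]:
    """Load per-category reference FASTAs into validated :class:`ReferenceEntry`.

    The map key supplies the category; headers are parsed with the
    ``id|family[|cognate_partner]`` dialect (third token is the antibiotic
    class for ARG files).
    """
    entries: list[ReferenceEntry] = []
    for key, path in paths.items():
        category = Category(key)
        molecule = "nucleotide" if category in NUCLEOTIDE_CATEGORIES else "protein"
        for rec_id, seq in read_fasta(path, molecule):
            parts = rec_id.split("|")
            entry_id = parts[0]
            family = parts[1] if len(parts) > 1 else parts[0]
            third = parts[2] if len(parts) > 2 else None
            partner = third if category in (Category.TOXIN, Category.ANTITOXIN) else None
            arg_class = third if category is Category.ARG else None
            entries.append(
                ReferenceEntry(
                    id=entry_id,
                    category=category,
                    family=family,
                    molecule=molecule,
                    sequence=seq,
                    cognate_partner=partner,
                    arg_class=arg_class,
                )
            )
    return entries


def reference_fasta_header(entry: ReferenceEntry) -> str:
    """Serialize an entry id back to the ``id|family[|third]`` header dialect."""
    third = entry.cognate_partner or entry.arg_class
    parts = [entry.id, entry.family] + ([third] if third else [])
    return "|".join(parts)


def build_cognate_map(refs: Iterable[ReferenceEntry]) -> dict[str, str]:
    """Map toxin family -> cognate antitoxin family, from TOXIN entries."""
    return {
        r.family: r.cognate_partner
        for r in refs
        if r.category is Category.TOXIN and r.cognate_partner
    }


def build_arg_class_map(refs: Iterable[ReferenceEntry]) -> dict[str, str]:
    """Map ARG family -> antibiotic class (families without a class omitted)."""
    return {
        r.family: r.arg_class for r in refs if r.category is Category.ARG and r.arg_class
    }


def write_plasmid_tsv(path: str | Path, plasmids: Sequence[PlasmidRecord]) -> None:
    with open(path, "w") as handle:
        handle.write("id\tlength_nt\tgc_content\ttopology\tsource_isolate\n")
        for p in plasmids:
            handle.write(
                f"{p.id}\t{p.length}\t{p.gc_content:.6g}\t{p.topology}\t"
                f"{p.source_isolate or ''}\n"
            )
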