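"""Protein FASTA reading/writing with UniProt-aware header parsing.

Parsing is delegated to Bio.SeqIO; this layer adds sequence sanitization
(uppercasing, trailing-stop stripping), validation against the tolerated
amino-acid alphabet, UniProt ``sp|ACC|NAME`` accession extraction, and
duplicate-accession detection.  Gzipped files are handled transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = ["ProteinRecord", "Proteome", "read_fasta", "write_fasta", "sanitize_sequence"]

# 20 standard residues plus tolerated ambiguity/rare codes.
# J (Leu/Ile ambiguity) is intentionally not tolerated.
ALLOWED_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZO")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, free-text description, sanitized sequence."""

    accession: str
    description: str
    sequence: str


@dataclass
class Proteome:
    """An ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: List[ProteinRecord] = field(default_factory=list)
    source_path: str = ""

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return self.n_records

    def accessions(self) -> List[str]:
        return [r.accession for r in self.records]


def _extract_accession(header_id: str) -> str:
    """UniProt ``sp|ACC|NAME`` / ``tr|ACC|NAME`` -> ``ACC``; else the id itself."""
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id


def sanitize_sequence(raw: str) -> str:
    """Uppercase and strip a single trailing stop character ('*').

    Idempotent; performs no validation (see :func:`validate_sequence`).
    """
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return seq


def validate_sequence(seq: str) -> str:
    """Return '' if ``seq`` is a valid sanitized sequence, else a reason."""
    if not seq:
        return "empty sequence"
    bad = sorted({c for c in seq if c not in ALLOWED_LETTERS})
    if bad:
        kinds = []
        for c in bad:
            if c == "*":
                kinds.append("internal stop '*'")
            elif c.isspace():
                kinds.append("whitespace")
            elif c.isdigit():
                kinds.append(f"digit {c!r}")
            else:
                kinds.append(f"illegal character {c!r}")
        return "; ".join(kinds)
    return ""


def read_fasta(path, on_invalid: str = "error") -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Parameters
    ----------
    path : str or Path
        FASTA file, optionally gzip-compressed.
    on_invalid : {"error", "skip"}
        What to do with records that fail validation (illegal characters,
        internal stops, empty sequences) or repeat an accession: raise, or
        drop them and log how many were dropped.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError(f"on_invalid must be 'error' or 'skip', got {on_invalid!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    opener = gzip.open if path.suffix == ".gz" else open
    records: List[ProteinRecord] = []
    seen = set()
    n_dropped = 0
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            accession = _extract_accession(rec.id)
            seq = sanitize_sequence(str(rec.seq))
            problem = validate_sequence(seq)
            if not problem and accession in seen:
                problem = "duplicate accession"
            if problem:
                if on_invalid == "error":
                    raise ValueError(f"record {accession!r}: {problem}")
                n_dropped += 1
                continue
            seen.add(accession)
            records.append(
                ProteinRecord(accession=accession, description=rec.description, sequence=seq)
            )
    if n_dropped:
        logger.warning("read_fasta(%s): dropped %d invalid record(s)", path, n_dropped)
    return Proteome(records=records, source_path=str(path))


def write_fasta(proteome: Proteome, path) -> Path:
    """Write ``proteome`` as standard FASTA wrapped at 60 columns.

    Round-trips with :func:`read_fasta` on (accession, sequence) pairs.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in proteome:
            header = rec.description if rec.description else rec.accession
            if not header.startswith(rec.accession) and "|" not in header:
                header = f"{rec.accession} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    return path
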