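"""Reading, validating and labelling fixed-length RNA sequence windows.

A-to-I editing predictors operate on short RNA windows (41 or 51 nt)
centred on a candidate adenosine.  This module loads such windows from
FASTA, normalizes them into RNA space (uppercase, T mapped to U), checks
the window-length contract, and pairs positive (editing site) and
negative (non-site) sequences into a labelled dataset carrying species
metadata.

All user-facing positions are 1-based; the centre of an odd-length
window of length L is position (L + 1) / 2.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Species tags used throughout the package.
SPECIES_TAGS = ("Hs", "Mm", "Dm", "other")

#: Window length (nt) conventionally used per species.
SPECIES_WINDOW_LENGTH = {"Hs": 51, "Mm": 41, "Dm": 51}

POSITIVE, NEGATIVE = "positive", "negative"


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending record."""


class SequenceValidationError(ValueError):
    """A residue outside {A,C,G,U,T} or a wrong-length window."""


def normalize_residues(raw: str) -> str:
    """Normalize a raw sequence string into RNA space.

    Uppercases and maps T (thymine, from DNA-space genome databases) to
    U.  Idempotent: ``normalize_residues(normalize_residues(s)) ==
    normalize_residues(s)``.
    """
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """A validated fixed-length RNA window.

    Parameters
    ----------
    id : str
        Free-text record identifier.
    residues : str
        Sequence over the alphabet {A, C, G, U}; already normalized.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = [(i + 1, ch) for i, ch in enumerate(self.residues) if ch not in RNA_ALPHABET]
        if bad:
            pos, ch = bad[0]
            raise SequenceValidationError(
                f"record {self.id!r}: invalid residue {ch!r} at position {pos} "
                f"(alphabet is A, C, G, U; T is accepted on input and mapped to U)"
            )
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def centre_index(self) -> int:
        """1-based centre position; defined only for odd lengths."""
        if len(self) % 2 == 0:
            raise ValueError(
                f"record {self.id!r}: even length {len(self)} has no unique centre"
            )
        return (len(self) + 1) // 2

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id=id, residues=normalize_residues(raw))


def check_centre_adenine(seq: RnaSequence) -> bool:
    """True iff the residue at the (odd-length) window centre is A."""
    return seq.residues[seq.centre_index - 1] == "A"


def read_fasta(
    path: str | Path,
    window_length: int | None = None,
    *,
    skip_invalid: bool = False,
) -> list[RnaSequence]:
    """Read RNA windows from a FASTA file.

    Every record is normalized (uppercased, T mapped to U) and validated
    against the RNA alphabet and, when given, ``window_length``.  Record
    order is preserved.

    Parameters
    ----------
    path : path-like
        FASTA file.
    window_length : int, optional
        Declared window length in nt; records of any other length raise.
    skip_invalid : bool
        Drop records that fail validation with a logged warning instead
        of raising.  Ambiguous bases (N, R, Y, ...) are always invalid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[RnaSequence] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;":
            raise FastaParseError(f"{path}: does not start with a FASTA header ('>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = RnaSequence.from_raw(rec.id, str(rec.seq))
            if window_length is not None and len(seq) != window_length:
                raise SequenceValidationError(
                    f"record {rec.id!r}: length {len(seq)} != declared window length "
                    f"{window_length}"
                )
        except SequenceValidationError:
            if skip_invalid:
                logger.warning("skipping invalid record %r in %s", rec.id, path)
                continue
            raise
        out.append(seq)
    return out


def write_fasta(sequences: Iterable[RnaSequence], path: str | Path) -> None:
    """Write normalized RNA windows to FASTA (60-column wrap)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class LabeledDataset:
    """Parallel sequences and binary labels with species metadata.

    Class balance is reported, never enforced: benchmark collections in
    this task are usually balanced but need not be (e.g. 125 positives
    vs 119 negatives for the small fly set).
    """

    sequences: list[RnaSequence]
    labels: list[str]
    species: str = "other"
    window_length: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        bad = set(self.labels) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"labels must be 'positive'/'negative', got {sorted(bad)}")
        if self.species not in SPECIES_TAGS:
            raise ValueError(f"unknown species tag {self.species!r}; use one of {SPECIES_TAGS}")
        if self.sequences:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise ValueError(f"mixed window lengths {sorted(lengths)}")
            (only,) = lengths
            if self.window_length == 0:
                self.window_length = only
            elif self.window_length != only:
                raise ValueError(
                    f"declared window_length {self.window_length} != sequence length {only}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return sum(1 for l in self.labels if l == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for l in self.labels if l == NEGATIVE)

    @property
    def y(self):
        """Labels as a 0/1 integer numpy array (positive = 1)."""
        import numpy as np

        return np.asarray([1 if l == POSITIVE else 0 for l in self.labels])

    def summary(self) -> dict:
        """JSON-serializable dataset summary (counts, length, species)."""
        n_centre_a = sum(
            1 for s in self.sequences if len(s) % 2 == 1 and check_centre_adenine(s)
        )
        return {
            "species": self.species,
            "window_length": self.window_length,
            "n_total": len(self),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_centre_adenine": n_centre_a,
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def build_dataset(
    pos: Sequence[RnaSequence],
    neg: Sequence[RnaSequence],
    species: str = "other",
) -> LabeledDataset:
    """Assemble a labelled dataset from positive and negative windows.

    Labels are assigned in input order (positives first).  All windows
    must share one length; the positive set must be non-empty.  Windows
    whose centre base is not adenosine are warned about, not rejected —
    prediction inputs may legitimately violate the training convention.
    """
    if not pos:
        raise ValueError("empty positive set")
    ds = LabeledDataset(
        sequences=list(pos) + list(neg),
        labels=[POSITIVE] * len(pos) + [NEGATIVE] * len(neg),
        species=species,
    )
    if ds.window_length % 2 == 1:
        off = [s.id for s in ds.sequences if not check_centre_adenine(s)]
        if off:
            warnings.warn(
                f"{len(off)} window(s) do not have adenosine at the centre "
                f"(first: {off[0]!r})",
                stacklevel=2,
            )
    return ds


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) manifest; tab- or whitespace-delimited."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two columns, got {len(parts)}")
        sid, label = parts
        label = label.lower()
        if label in {"1", "pos", "positive"}:
            label = POSITIVE
        elif label in {"0", "neg", "negative"}:
            label = NEGATIVE
        else:
            raise ValueError(f"{path}:{ln}: unrecognised label {parts[1]!r}")
        mapping[sid] = label
    return mapping


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the (id, label) manifest matching :func:`read_labels`."""
    with open(path, "w") as fh:
        for seq, label in zip(dataset.sequences, dataset.labels):
            fh.write(f"{seq.id}\t{label}\n")


def dataset_from_files(
    fasta_path: str | Path,
    labels_path: str | Path,
    species: str = "other",
    window_length: int | None = None,
    *,
    skip_invalid: bool = False,
) -> LabeledDataset:
    """Load a FASTA + label-manifest pair into a :class:`LabeledDataset`."""
    seqs = read_fasta(fasta_path, window_length, skip_invalid=skip_invalid)
    labels = read_labels(labels_path)
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise ValueError(f"no label for record(s): {missing[:5]}")
    pos = [s for s in seqs if labels[s.id] == POSITIVE]
    neg = [s for s in seqs if labels[s.id] == NEGATIVE]
    return build_dataset(pos, neg, species)
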