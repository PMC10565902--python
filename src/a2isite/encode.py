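"""RNA sequence descriptor encoders.

Eleven fixed-dimension numeric encodings of an RNA window, spanning
four descriptor families:

* nucleic acid composition — Kmer, CKSNAP (k-spaced pair composition),
  ASDC (adaptive skip dinucleotide composition), ENAC (sliding-window
  composition), NCP (nucleotide chemical properties);
* physicochemical — DPCP (frequency-weighted dinucleotide step
  parameters), DPCP2 (position-resolved step parameters);
* pseudo composition — PseDNC (dinucleotide composition plus
  sequence-order correlation factors);
* residue composition — Binary (per-base one-hot), DBE (dinucleotide
  binary encoding), PS2 (per-pair one-hot).

Each encoder maps a window of length L to a vector whose dimension is a
closed form in L, with deterministic, human-readable component names
(e.g. ``CKSNAP_AC_gap1``, ``DPCP2_Roll_pos26``).  ``encode_all``
concatenates encoder blocks over a labelled dataset into a
:class:`FeatureMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .properties import (
    ALL_PROPERTIES,
    DINUCLEOTIDES,
    DPCP2_PROPERTIES,
    PhysicochemicalTable,
    load_default_table,
)
from .seqio import LabeledDataset, RnaSequence

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

# 3-bit chemical coordinates: (ring structure: purine=1, functional
# group: amino=1, hydrogen bond: weak=1).
NCP_COORDINATES = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}

# 2-bit base code of the dinucleotide binary encoding.
DBE_BASE_CODE = {"A": (0, 0), "U": (0, 1), "C": (1, 0), "G": (1, 1)}

ENCODER_NAMES = (
    "Kmer",
    "CKSNAP",
    "ASDC",
    "ENAC",
    "NCP",
    "DPCP",
    "DPCP2",
    "PseDNC",
    "Binary",
    "DBE",
    "PS2",
)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered descriptor values with parallel component names."""

    values: np.ndarray
    names: tuple[str, ...]
    encoder: "EncoderSpec"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")


def _dinucleotide_counts(residues: str, gap: int = 0) -> np.ndarray:
    """Counts over the 16 pair types for pairs (i, i+gap+1)."""
    counts = np.zeros(16)
    step = gap + 1
    for i in range(len(residues) - step):
        counts[_DI_INDEX[residues[i] + residues[i + step]]] += 1
    return counts


def _adjacent_dinucleotide_freqs(residues: str) -> np.ndarray:
    """Adjacent-pair frequencies, count / (L - 1)."""
    return _dinucleotide_counts(residues, gap=0) / (len(residues) - 1)


def encode_kmer(seq: RnaSequence, k: int = 3, mode: str = "windows") -> FeatureVector:
    """k-mer composition: frequency of every length-k word (4**k values).

    ``mode`` selects the denominator: ``"windows"`` divides counts by
    the number of k-mer windows L - k + 1 so the vector sums to one;
    ``"length"`` divides by the sequence length L (the literal
    composition definition, which does not sum to one for k > 1).
    """
    if not 1 <= k <= len(seq):
        raise ValueError(f"k={k} out of range for length-{len(seq)} sequence")
    if mode not in ("windows", "length"):
        raise ValueError(f"mode must be 'windows' or 'length', got {mode!r}")
    res = seq.residues
    counts: dict[str, int] = {}
    for i in range(len(res) - k + 1):
        word = res[i : i + k]
        counts[word] = counts.get(word, 0) + 1
    denom = (len(res) - k + 1) if mode == "windows" else len(res)
    kmers = ["".join(p) for p in _product_words(k)]
    values = np.array([counts.get(t, 0) / denom for t in kmers])
    names = tuple(f"Kmer_{t}" for t in kmers)
    return FeatureVector(values, names, EncoderSpec("Kmer", {"k": k, "mode": mode}))


def _product_words(k: int) -> list[str]:
    words = [""]
    for _ in range(k):
        words = [w + b for w in words for b in BASES]
    return words


def encode_cksnap(seq: RnaSequence, gap_max: int = 2) -> FeatureVector:
    """Composition of k-spaced nucleic acid pairs.

    One 16-component frequency block per gap g = 0..gap_max, counting
    pairs of residues separated by g intervening positions; each block
    is normalized by its own pair count L - g - 1.
    """
    if len(seq) <= gap_max + 1:
        raise ValueError(
            f"length {len(seq)} too short for gap_max={gap_max} (need > gap_max + 1)"
        )
    blocks, names = [], []
    for g in range(gap_max + 1):
        counts = _dinucleotide_counts(seq.residues, gap=g)
        blocks.append(counts / (len(seq) - g - 1))
        names.extend(f"CKSNAP_{d}_gap{g}" for d in DINUCLEOTIDES)
    return FeatureVector(
        np.concatenate(blocks), tuple(names), EncoderSpec("CKSNAP", {"gap_max": gap_max})
    )


def encode_asdc(seq: RnaSequence) -> FeatureVector:
    """Adaptive skip dinucleotide composition (16 values summing to 1).

    Aggregates, over every skip distance g = 1..L-1, the counts of
    ordered base pairs at positions (p, p+g); g = 1 is the ordinary
    adjacent dinucleotide count.  Normalized by the grand total so the
    vector sums to one.
    """
    if len(seq) < 2:
        raise ValueError("ASDC needs length >= 2")
    total = np.zeros(16)
    for g in range(1, len(seq)):
        total += _dinucleotide_counts(seq.residues, gap=g - 1)
    values = total / total.sum()
    names = tuple(f"ASDC_{d}" for d in DINUCLEOTIDES)
    return FeatureVector(values, names, EncoderSpec("ASDC", {}))


def encode_enac(seq: RnaSequence, window: int = 2) -> FeatureVector:
    """Enhanced nucleic acid composition: per-window base fractions.

    A length-``window`` frame slides 5'→3'; at each of the
    L - window + 1 positions the four base counts inside the frame are
    divided by the frame size.  Dimension 4 * (L - window + 1).
    """
    if window > len(seq) or window < 1:
        raise ValueError(f"window={window} invalid for length {len(seq)}")
    res = seq.residues
    values, names = [], []
    for p in range(len(res) - window + 1):
        frame = res[p : p + window]
        for b in BASES:
            values.append(frame.count(b) / window)
            names.append(f"ENAC_{b}_win{p + 1}")
    return FeatureVector(
        np.array(values), tuple(names), EncoderSpec("ENAC", {"window": window})
    )


def encode_ncp(seq: RnaSequence) -> FeatureVector:
    """Nucleotide chemical property encoding, 3 bits per base (3L values).

    Coordinates (x, y, z) mark ring structure (purine), functional group
    (amino) and hydrogen-bonding strength (weak): A→(1,1,1), C→(0,1,0),
    G→(1,0,0), U→(0,0,1).
    """
    values = np.array([v for b in seq.residues for v in NCP_COORDINATES[b]], dtype=float)
    names = tuple(f"NCP_{i + 1}" for i in range(len(values)))
    return FeatureVector(values, names, EncoderSpec("NCP", {}))


def encode_dpcp(
    seq: RnaSequence, table: PhysicochemicalTable | None = None
) -> FeatureVector:
    """Dinucleotide physicochemical properties, 16 x 6 = 96 values.

    Component (i, u) = f(i) * P_u(i): the adjacent-pair frequency of
    dinucleotide i times its u-th step parameter (rise, roll, shift,
    slide, tilt, twist).  Pairs absent from the window contribute
    exactly zero.
    """
    table = (table or load_default_table()).subset(ALL_PROPERTIES)
    freqs = _adjacent_dinucleotide_freqs(seq.residues)
    prop_matrix = table.as_array()  # (16, 6)
    values = (freqs[:, None] * prop_matrix).ravel()
    names = tuple(
        f"DPCP_{d}_{p.capitalize()}" for d in DINUCLEOTIDES for p in table.properties
    )
    return FeatureVector(
        values, names, EncoderSpec("DPCP", {"properties": table.properties})
    )


def encode_dpcp2(
    seq: RnaSequence, table: PhysicochemicalTable | None = None
) -> FeatureVector:
    """Position-resolved dinucleotide step parameters, 4 x (L-1) values.

    For each property in (rise, roll, shift, slide) and each adjacent
    pair position p = 1..L-1, the raw parameter value of that pair.
    Flattened property-major, names like ``DPCP2_Roll_pos26``.
    """
    if len(seq) < 2:
        raise ValueError("DPCP2 needs length >= 2")
    table = (table or load_default_table()).subset(DPCP2_PROPERTIES)
    pairs = [seq.residues[i : i + 2] for i in range(len(seq) - 1)]
    values, names = [], []
    for prop in table.properties:
        for p, d in enumerate(pairs, start=1):
            values.append(table.lookup(d, prop))
            names.append(f"DPCP2_{prop.capitalize()}_pos{p}")
    return FeatureVector(
        np.array(values), tuple(names), EncoderSpec("DPCP2", {"properties": table.properties})
    )


def _psednc_theta(residues: str, lam: int, table_std: PhysicochemicalTable) -> np.ndarray:
    """Sequence-order correlation factors θ_1..θ_λ.

    θ_j averages, over all positions i, the correlation between the
    pairs at i and i+j, where the correlation of two dinucleotides is
    the mean squared difference of their standardized step parameters.
    """
    L = len(residues)
    props = table_std.as_array()  # (16, mu)
    pair_idx = np.array(
        [_DI_INDEX[residues[i : i + 2]] for i in range(L - 1)], dtype=int
    )
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        a = props[pair_idx[: L - 1 - j]]
        b = props[pair_idx[j:]]
        thetas[j - 1] = np.mean(np.sum((a - b) ** 2, axis=1) / props.shape[1])
    return thetas


def encode_psednc(
    seq: RnaSequence,
    lam: int = 2,
    w: float = 0.1,
    table: PhysicochemicalTable | None = None,
) -> FeatureVector:
    """Pseudo dinucleotide composition, 16 + λ values summing to 1.

    The first 16 components are adjacent-pair frequencies and the last
    λ are global sequence-order correlation factors, jointly normalized
    with weight ``w`` so the whole vector sums to one.  Requires
    λ < L - 1 so every correlation tier has at least one term.
    """
    if not 0 <= w <= 1:
        raise ValueError(f"weight w must be in [0, 1], got {w}")
    if lam < 0 or lam >= len(seq) - 1:
        raise ValueError(f"lambda={lam} must satisfy 0 <= lambda < L - 1 = {len(seq) - 1}")
    table = table or load_default_table()
    table_std = table.subset(ALL_PROPERTIES)
    if not table_std.standardized:
        table_std = table_std.standardize()
    freqs = _adjacent_dinucleotide_freqs(seq.residues)
    freqs = freqs / freqs.sum()
    thetas = _psednc_theta(seq.residues, lam, table_std) if lam else np.empty(0)
    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs / denom, w * thetas / denom])
    names = tuple(
        [f"PseDNC_{d}" for d in DINUCLEOTIDES]
        + [f"PseDNC_theta{j + 1}" for j in range(lam)]
    )
    return FeatureVector(
        values, names, EncoderSpec("PseDNC", {"lambda": lam, "w": w})
    )


def encode_binary(seq: RnaSequence) -> FeatureVector:
    """Per-base one-hot over (A, C, G, U), 4L values."""
    values = np.zeros(4 * len(seq))
    for i, b in enumerate(seq.residues):
        values[4 * i + _BASE_INDEX[b]] = 1.0
    names = tuple(f"Binary_{i + 1}" for i in range(len(values)))
    return FeatureVector(values, names, EncoderSpec("Binary", {}))


def encode_dbe(seq: RnaSequence) -> FeatureVector:
    """Dinucleotide binary encoding, 4 bits per adjacent pair.

    Each pair contributes the 2-bit codes of its two bases (A=00, U=01,
    C=10, G=11), first base first: AA→0000, AU→0001, AC→0010, GG→1111.
    """
    if len(seq) < 2:
        raise ValueError("DBE needs length >= 2")
    bits: list[int] = []
    for i in range(len(seq) - 1):
        bits.extend(DBE_BASE_CODE[seq.residues[i]])
        bits.extend(DBE_BASE_CODE[seq.residues[i + 1]])
    values = np.array(bits, dtype=float)
    names = tuple(f"DBE_{i + 1}" for i in range(len(values)))
    return FeatureVector(values, names, EncoderSpec("DBE", {}))


def encode_ps2(seq: RnaSequence) -> FeatureVector:
    """Position-specific pair one-hot: 16 bits per adjacent pair.

    Each of the L-1 adjacent pairs is one-hot over the 16 pair types in
    lexicographic (A, C, G, U) order; blocks concatenate 5'→3'.
    """
    if len(seq) < 2:
        raise ValueError("PS2 needs length >= 2")
    values = np.zeros(16 * (len(seq) - 1))
    for i in range(len(seq) - 1):
        values[16 * i + _DI_INDEX[seq.residues[i : i + 2]]] = 1.0
    names = tuple(f"PS2_{i + 1}" for i in range(len(values)))
    return FeatureVector(values, names, EncoderSpec("PS2", {}))


# ---------------------------------------------------------------------------
# Encoder registry / specs


@dataclass(frozen=True)
class EncoderSpec:
    """Named encoder plus its parameter map.

    Hashable and immutable so it can serve as provenance in a
    :class:`FeatureMatrix`.
    """

    name: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {self.name!r}; known: {ENCODER_NAMES}")
        object.__setattr__(self, "params", _frozen_params(self.params))

    def encode(self, seq: RnaSequence) -> FeatureVector:
        fn, kwargs = _resolve(self)
        return fn(seq, **kwargs)

    def dimension(self, window_length: int) -> int:
        """Closed-form output dimension for a window of the given length."""
        L = window_length
        p = dict(self.params)
        return {
            "Kmer": lambda: 4 ** int(p.get("k", 3)),
            "CKSNAP": lambda: 16 * (int(p.get("gap_max", 2)) + 1),
            "ASDC": lambda: 16,
            "ENAC": lambda: 4 * (L - int(p.get("window", 2)) + 1),
            "NCP": lambda: 3 * L,
            "DPCP": lambda: 96,
            "DPCP2": lambda: 4 * (L - 1),
            "PseDNC": lambda: 16 + int(p.get("lambda", 2)),
            "Binary": lambda: 4 * L,
            "DBE": lambda: 4 * (L - 1),
            "PS2": lambda: 16 * (L - 1),
        }[self.name]()

    def to_dict(self) -> dict:
        return {"name": self.name, "params": {k: v for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncoderSpec":
        return cls(d["name"], dict(d.get("params", {})))


class _frozen_params(dict):
    def __hash__(self):  # type: ignore[override]
        return hash(tuple(sorted((k, _hashable(v)) for k, v in self.items())))

    def __setitem__(self, *a):
        raise TypeError("EncoderSpec params are immutable")


def _hashable(v):
    return tuple(v) if isinstance(v, (list, tuple)) else v


def _resolve(spec: EncoderSpec) -> tuple[Callable, dict]:
    p = dict(spec.params)
    table = p.pop("table", None)
    if spec.name == "Kmer":
        return encode_kmer, {"k": int(p.get("k", 3)), "mode": p.get("mode", "windows")}
    if spec.name == "CKSNAP":
        return encode_cksnap, {"gap_max": int(p.get("gap_max", 2))}
    if spec.name == "ASDC":
        return encode_asdc, {}
    if spec.name == "ENAC":
        return encode_enac, {"window": int(p.get("window", 2))}
    if spec.name == "NCP":
        return encode_ncp, {}
    if spec.name == "DPCP":
        return encode_dpcp, {"table": table}
    if spec.name == "DPCP2":
        return encode_dpcp2, {"table": table}
    if spec.name == "PseDNC":
        return encode_psednc, {
            "lam": int(p.get("lambda", 2)),
            "w": float(p.get("w", 0.1)),
            "table": table,
        }
    if spec.name == "Binary":
        return encode_binary, {}
    if spec.name == "DBE":
        return encode_dbe, {}
    if spec.name == "PS2":
        return encode_ps2, {}
    raise ValueError(spec.name)


# ---------------------------------------------------------------------------
# Feature matrices


@dataclass
class FeatureMatrix:
    """Samples x named descriptors with encoder provenance.

    ``data`` is a rectangular DataFrame (rows: sample ids, columns:
    descriptor names, unique); ``specs`` records the encoders whose
    column blocks appear, in concatenation order.
    """

    data: pd.DataFrame
    specs: tuple[EncoderSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes[:5]}")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"unknown descriptor(s): {missing[:5]}")
        return FeatureMatrix(self.data[list(columns)], self.specs)

    def write(self, path: str | Path, sidecar: bool = True) -> None:
        """Write TSV (+ JSON sidecar with encoder provenance)."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="id")
        if sidecar:
            meta = {
                "encoders": [s.to_dict() for s in self.specs],
                "table_version": "rna_dinucleotide_steps.v1",
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2) + "\n"
            )

    @classmethod
    def read(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="id")
        sidecar = path.with_suffix(path.suffix + ".json")
        specs: tuple[EncoderSpec, ...] = ()
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            specs = tuple(EncoderSpec.from_dict(d) for d in meta.get("encoders", []))
        return cls(df, specs)


def encode_all(
    dataset: LabeledDataset, specs: Sequence[EncoderSpec]
) -> FeatureMatrix:
    """Encode every window in the dataset with each spec, concatenated.

    Column blocks appear in spec order; row order follows the dataset.
    Any per-encoder failure is re-raised with the sample id attached.
    """
    if not specs:
        raise ValueError("empty encoder spec list")
    rows, names = [], None
    for seq in dataset.sequences:
        vecs = []
        for spec in specs:
            try:
                vecs.append(spec.encode(seq))
            except Exception as exc:
                raise type(exc)(f"sample {seq.id!r}: {exc}") from exc
        rows.append(np.concatenate([v.values for v in vecs]))
        if names is None:
            names = [n for v in vecs for n in v.names]
    ids = [s.id for s in dataset.sequences]
    df = pd.DataFrame(np.vstack(rows), index=ids, columns=names)
    return FeatureMatrix(df, tuple(specs))


# ---------------------------------------------------------------------------
# Species presets

#: Encoder sets retained per species (selected-in-results composition).
SPECIES_ENCODERS = {
    "Hs": (
        EncoderSpec("NCP"),
        EncoderSpec("Binary"),
        EncoderSpec("DBE"),
        EncoderSpec("PS2"),
    ),
    "Mm": (
        EncoderSpec("NCP"),
        EncoderSpec("ENAC", {"window": 2}),
        EncoderSpec("Binary"),
        EncoderSpec("DBE"),
        EncoderSpec("DPCP2"),
    ),
    "Dm": (
        EncoderSpec("CKSNAP", {"gap_max": 2}),
        EncoderSpec("Kmer", {"k": 3}),
        EncoderSpec("ASDC"),
        EncoderSpec("PseDNC", {"lambda": 2, "w": 0.1}),
        EncoderSpec("DPCP"),
    ),
}


def species_feature_preset(species: str) -> tuple[EncoderSpec, ...]:
    """Encoder combination retained for a species (Hs, Mm or Dm)."""
    try:
        return SPECIES_ENCODERS[species]
    except KeyError:
        raise ValueError(
            f"no encoder preset for species {species!r}; known: {sorted(SPECIES_ENCODERS)}"
        ) from None
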