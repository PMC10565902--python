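"""Synthetic editing-site datasets with controllable positional signal.

Real editing-site benchmarks are fixed-length RNA windows centred on an
adenosine, where positive windows show position-specific base
enrichment around the centre (e.g. a guanosine preference immediately
downstream) and negatives approximate the background composition.  The
generator reproduces that structure: every window is drawn
position-by-position from a background composition, and positive
windows mix in a per-position enrichment distribution scaled by an
effect size in [0, 1].  Both classes carry a centre adenosine by
default, since negatives in the biological task are also candidate
adenosine sites.

``planted_feature_matrix`` is the matching abstraction one level up: a
numeric descriptor matrix with a known set of informative columns, used
to exercise the feature-selection machinery against a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encode import FeatureMatrix
from .seqio import LabeledDataset, RnaSequence, build_dataset

BASES = "ACGU"

#: Uniform background composition over (A, C, G, U).
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

#: G/C-enriched background mimicking the fly sequence context.
GC_RICH_BACKGROUND = (0.20, 0.30, 0.30, 0.20)


def _check_probs(p, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
        raise ValueError(f"{what} must be 4 non-negative probabilities summing to 1")
    return p


@dataclass(frozen=True)
class SignalModel:
    """Positional base-enrichment signal applied to positive windows.

    ``enrichment`` maps a 1-based window position to a base-probability
    vector over (A, C, G, U); at those positions a positive window draws
    from ``(1 - effect) * background + effect * enrichment``.  Effect 0
    makes the classes indistinguishable; effect 1 samples the enrichment
    distribution exactly.
    """

    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    enrichment: dict[int, tuple[float, float, float, float]] = field(default_factory=dict)
    effect: float = 0.5

    def __post_init__(self) -> None:
        _check_probs(self.background, "background")
        for pos, vec in self.enrichment.items():
            if pos < 1:
                raise ValueError("enrichment positions are 1-based")
            _check_probs(vec, f"enrichment at position {pos}")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect size must lie in [0, 1]")

    def position_probs(self, pos: int) -> np.ndarray:
        bg = np.asarray(self.background)
        if pos in self.enrichment:
            target = np.asarray(self.enrichment[pos])
            return (1 - self.effect) * bg + self.effect * target
        return bg


def default_signal(window_length: int, effect: float = 0.5) -> SignalModel:
    """An editing-like positional signal around the centre adenosine.

    Mirrors the qualitative neighbour preference of deaminated sites: a
    strong guanosine preference immediately 3' of the centre, a
    uridine/cytidine preference 5' of it, and weaker enrichment decaying
    over the surrounding positions — the structure (not the exact
    frequencies) of real two-sample logos.
    """
    centre = (window_length + 1) // 2
    enrichment: dict[int, tuple[float, float, float, float]] = {
        centre + 1: (0.03, 0.07, 0.85, 0.05),  # 3' G preference
        centre - 1: (0.03, 0.25, 0.07, 0.65),  # 5' U/C preference
    }
    # decaying flank enrichment, G/C-flavoured downstream, U-flavoured upstream
    for off, vec in (
        (2, (0.05, 0.15, 0.70, 0.10)),
        (3, (0.07, 0.20, 0.60, 0.13)),
        (4, (0.10, 0.25, 0.50, 0.15)),
        (5, (0.15, 0.25, 0.40, 0.20)),
    ):
        if centre + off <= window_length:
            enrichment[centre + off] = vec
        if centre - off >= 1:
            a, c, g, u = vec
            enrichment[centre - off] = (a, c, u, g)  # swap G/U upstream
    return SignalModel(
        background=UNIFORM_BACKGROUND, enrichment=enrichment, effect=effect
    )


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Sizes, window length, signal and seed of a synthetic dataset."""

    n_pos: int = 500
    n_neg: int = 500
    window_length: int = 51
    signal: SignalModel | None = None
    seed: int = 0
    centre_adenine: bool = True  # both classes get a centre A by default

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if self.window_length % 2 == 0:
            raise ValueError("window length must be odd (unique centre)")


def _draw_window(
    rng, spec: SyntheticDatasetSpec, signal: SignalModel, positive: bool
) -> str:
    L = spec.window_length
    centre = (L + 1) // 2
    background = np.asarray(signal.background)
    bases = []
    for pos in range(1, L + 1):
        if spec.centre_adenine and pos == centre:
            bases.append("A")
            continue
        p = signal.position_probs(pos) if positive else background
        bases.append(BASES[rng.choice(4, p=p)])
    return "".join(bases)


def generate_dataset(spec: SyntheticDatasetSpec) -> LabeledDataset:
    """Draw a labelled synthetic window dataset, reproducible from its seed.

    Positives are sampled from the signal-mixed positional distribution,
    negatives from the plain background; the centre base is fixed to A
    for both classes unless disabled in the spec.
    """
    rng = np.random.default_rng(spec.seed)
    signal = spec.signal or default_signal(spec.window_length, effect=0.5)
    pos = [
        RnaSequence(f"pos_{i + 1}", _draw_window(rng, spec, signal, True))
        for i in range(spec.n_pos)
    ]
    neg = [
        RnaSequence(f"neg_{i + 1}", _draw_window(rng, spec, signal, False))
        for i in range(spec.n_neg)
    ]
    return build_dataset(pos, neg, species="other")


def planted_feature_matrix(
    n: int,
    n_informative: int = 3,
    n_noise: int = 27,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Numeric matrix with known informative columns for selection tests.

    Balanced classes (n // 2 positives).  Informative columns are
    standard normal with the class means separated by ``effect``
    standard deviations; noise columns are class-independent standard
    normal.  Column names flag the ground truth (``inf_*`` vs
    ``noise_*``).
    """
    if n < 2 or n_informative < 1 or n_noise < 0:
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X_inf = rng.standard_normal((n, n_informative)) + np.outer(
        y * effect, np.ones(n_informative)
    )
    X_noise = rng.standard_normal((n, n_noise))
    data = np.hstack([X_inf, X_noise])
    names = [f"inf_{i + 1}" for i in range(n_informative)] + [
        f"noise_{i + 1}" for i in range(n_noise)
    ]
    # interleave deterministically so informative columns are not all first
    order = rng.permutation(len(names))
    df = pd.DataFrame(
        data[:, order],
        columns=[names[i] for i in order],
        index=[f"s{i + 1}" for i in range(n)],
    )
    return FeatureMatrix(df), y
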