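"""Seeded synthetic data: bioactivity tables and class-structured fingerprints.

Nothing here is chemically realistic — the generators are planted-signal
Bernoulli mixtures whose only job is to exercise every pipeline stage with
known structure and no downloads:

* :func:`generate_bioactivity_table` emulates a raw ChEMBL-style extract,
  with a configurable active fraction, an excluded intermediate potency
  band, and planted relation-symbol violations and duplicate rows so the
  curation filters have something to remove;
* :func:`generate_fingerprints` draws the five descriptor views as random
  bit matrices in which a subset of columns has class-dependent densities
  (the planted signal), the rest a shared background density, and every
  bit may be flipped with a noise probability.

The default fixture mirrors the study conditions of the real dataset: a
roughly 1:5 inactive:active imbalance and a moderately separable signal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .curation import RawBioactivityRow, pic50_to_ic50
from .descriptors import (
    VIEW_NAMES,
    VIEW_WIDTHS,
    FeatureView,
    FingerprintProvider,
    FusedFeatures,
    fuse_views,
)

__all__ = [
    "FixtureConfig",
    "generate_bioactivity_table",
    "generate_fingerprints",
    "SyntheticProvider",
]

_ATOMS = ("C", "N", "O", "S")


def _random_smiles(rng: np.random.Generator) -> str:
    """A short linear SMILES-like token (valid for simple chains)."""
    length = int(rng.integers(3, 12))
    return "".join(rng.choice(_ATOMS, size=length, p=(0.7, 0.1, 0.15, 0.05)))


def generate_bioactivity_table(
    n: int,
    active_frac: float = 0.8,
    intermediate_frac: float = 0.05,
    n_bad_relation: int = 5,
    n_duplicates: int = 3,
    seed: int = 0,
) -> list[RawBioactivityRow]:
    """Synthetic raw bioactivity rows for the curation stage.

    About ``active_frac`` of the ``n`` base compounds get pIC50 above 6
    (active), ``intermediate_frac`` land in the excluded [5, 6] band, and
    the rest below 5.  ``n_bad_relation`` extra rows carry non-"="
    relation symbols and ``n_duplicates`` rows duplicate existing ones, to
    exercise the filters.  Bit-reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[RawBioactivityRow] = []
    for i in range(n):
        u = rng.uniform()
        if u < active_frac:
            pic50 = rng.uniform(6.2, 9.0)
        elif u < active_frac + intermediate_frac:
            pic50 = rng.uniform(5.0, 6.0)
        else:
            pic50 = rng.uniform(3.5, 4.8)
        rows.append(
            RawBioactivityRow(
                compound_id=f"SYN{i:05d}",
                smiles=_random_smiles(rng),
                relation="=",
                ic50_nM=float(pic50_to_ic50(pic50)),
            )
        )
    base = list(rows)
    for j in range(n_bad_relation):
        src = base[int(rng.integers(len(base)))]
        rows.append(
            RawBioactivityRow(
                compound_id=f"SYNBAD{j:03d}",
                smiles=src.smiles,
                relation=str(rng.choice((">", "<", ">=", "<="))),
                ic50_nM=src.ic50_nM,
            )
        )
    for _ in range(n_duplicates):
        rows.append(base[int(rng.integers(len(base)))])
    return rows


@dataclass
class FixtureConfig:
    """Conditions of the synthetic fingerprint fixture.

    The defaults encode the study conditions used throughout the test
    suite: 500 active / 100 inactive compounds (≈1:5 imbalance, as in the
    curated training data this emulates), 80 class-discriminative bits per
    view with Bernoulli densities 0.5 (active) vs 0.1 (inactive), a shared
    background density of 0.2, and a 0.1 bit-flip noise applied to every
    bit.  At this operating point the planted signal occupies a small
    fraction of the 10,757 fused columns, which is what makes the
    imbalance bite: a model trained on the raw 1:5 data under-recalls the
    minority class while the balanced pipeline recovers it.
    """

    n_active: int = 500
    n_inactive: int = 100
    view_widths: dict[str, int] = field(default_factory=lambda: dict(VIEW_WIDTHS))
    signal_bits: int = 80
    active_density: float = 0.5
    inactive_density: float = 0.1
    background_density: float = 0.2
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dens in (
            ("active_density", self.active_density),
            ("inactive_density", self.inactive_density),
            ("background_density", self.background_density),
        ):
            if not 0.0 < dens < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {dens}")
        if self.signal_bits > min(self.view_widths.values()):
            raise ValueError("signal_bits must not exceed the narrowest view width")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")


def generate_fingerprints(cfg: FixtureConfig) -> tuple[FusedFeatures, np.ndarray]:
    """Draw the five views and labels; returns (fused features, labels).

    Labels are ``"active"`` / ``"inactive"`` strings.  In each view the
    first ``signal_bits`` columns use the class-dependent densities; all
    remaining columns share the background density.  After sampling, each
    bit is flipped independently with probability ``cfg.noise``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_inactive
    labels = np.array(["active"] * cfg.n_active + ["inactive"] * cfg.n_inactive)
    is_active = labels == "active"

    views = []
    for name in VIEW_NAMES:
        width = cfg.view_widths[name]
        dens = np.full((n, width), cfg.background_density)
        s = min(cfg.signal_bits, width)
        dens[is_active, :s] = cfg.active_density
        dens[~is_active, :s] = cfg.inactive_density
        bits = (rng.uniform(size=(n, width)) < dens).astype(float)
        if cfg.noise > 0:
            flips = rng.uniform(size=(n, width)) < cfg.noise
            bits = np.where(flips, 1.0 - bits, bits)
        views.append(FeatureView(name=name, matrix=bits, strict=False))

    order = rng.permutation(n)
    labels = labels[order]
    views = [FeatureView(name=v.name, matrix=v.matrix[order], strict=False) for v in views]
    return fuse_views(views), labels


class SyntheticProvider(FingerprintProvider):
    """Fingerprint provider serving seeded random bits per SMILES.

    Bits are derived deterministically from a hash of the SMILES string and
    the provider seed, so identical inputs give identical matrices across
    calls and views stay consistent per compound.
    """

    def __init__(self, seed: int = 0, density: float = 0.25):
        self.seed = seed
        self.density = density

    @property
    def available_views(self) -> tuple[str, ...]:
        return VIEW_NAMES

    def compute(self, smiles_list, view: str) -> np.ndarray:
        width = VIEW_WIDTHS[view]
        out = np.zeros((len(smiles_list), width))
        for i, smi in enumerate(smiles_list):
            digest = hashlib.blake2b(
                f"{self.seed}|{view}|{smi}".encode(), digest_size=4
            ).digest()
            r = np.random.default_rng(int.from_bytes(digest, "little"))
            out[i] = (r.uniform(size=width) < self.density).astype(float)
        return out
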