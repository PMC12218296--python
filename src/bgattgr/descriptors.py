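"""Multi-view molecular fingerprints and their fused concatenation.

Five descriptor views represent each compound: atom-pair 2D (AP2D, 780
bits), CDK extended (1024 bits), Klekota-Roth (4857 bits), Morgan circular
(2048 bits) and RDKit topological (2048 bits).  Concatenated in that fixed
order they give the 10,757-D "Fusion" feature vector.

Fingerprint computation sits behind a provider interface so the pipeline
runs with (a) precomputed per-view CSV matrices, (b) an RDKit backend for
the views RDKit can serve, or (c) a seeded synthetic generator.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VIEW_NAMES",
    "VIEW_WIDTHS",
    "FUSION_WIDTH",
    "FeatureView",
    "FusedFeatures",
    "FingerprintProvider",
    "FileProvider",
    "RDKitProvider",
    "compute_view",
    "fuse_views",
]

#: Canonical view order; fused column indices depend on it.
VIEW_NAMES: tuple[str, ...] = ("AP2D", "CDKExt", "KR", "Morgan", "RDKIT")

VIEW_WIDTHS: dict[str, int] = {
    "AP2D": 780,
    "CDKExt": 1024,
    "KR": 4857,
    "Morgan": 2048,
    "RDKIT": 2048,
}

FUSION_WIDTH: int = sum(VIEW_WIDTHS.values())  # 10757


@dataclass
class FeatureView:
    """One fingerprint matrix: ``n_compounds`` rows by ``d_view`` columns.

    ``strict`` (default) enforces the canonical width for the named view;
    reduced-width matrices (synthetic test fixtures) may opt out.
    """

    name: str
    matrix: np.ndarray
    strict: bool = True

    def __post_init__(self) -> None:
        if self.name not in VIEW_WIDTHS:
            raise ValueError(f"unknown view {self.name!r}; expected one of {VIEW_NAMES}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("view matrix must be 2-D")
        if self.strict and self.matrix.shape[1] != VIEW_WIDTHS[self.name]:
            raise ValueError(
                f"view {self.name} must have width {VIEW_WIDTHS[self.name]}, "
                f"got {self.matrix.shape[1]}"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"view {self.name} contains non-finite values")

    @property
    def d_view(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FusedFeatures:
    """Column-wise concatenation of the five views plus the column map."""

    matrix: np.ndarray
    view_offsets: dict[str, tuple[int, int]]

    def slice_view(self, name: str) -> np.ndarray:
        start, end = self.view_offsets[name]
        return self.matrix[:, start:end]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def fuse_views(views: Sequence[FeatureView]) -> FusedFeatures:
    """Concatenate the five views in the fixed order AP2D, CDKExt, KR, Morgan, RDKIT.

    Raises if a view is missing, duplicated, out of order, or the row counts
    disagree.
    """
    names = tuple(v.name for v in views)
    if names != VIEW_NAMES:
        raise ValueError(
            f"views must be exactly {VIEW_NAMES} in that order, got {names}"
        )
    n_rows = {v.n_compounds for v in views}
    if len(n_rows) != 1:
        raise ValueError(f"row-count mismatch across views: { {v.name: v.n_compounds for v in views} }")
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for v in views:
        offsets[v.name] = (start, start + v.d_view)
        start += v.d_view
    matrix = np.concatenate([v.matrix for v in views], axis=1)
    return FusedFeatures(matrix=matrix, view_offsets=offsets)


class FingerprintProvider(ABC):
    """Pluggable source of per-view fingerprint matrices."""

    @property
    @abstractmethod
    def available_views(self) -> tuple[str, ...]: ...

    @abstractmethod
    def compute(self, smiles_list: Sequence[str], view: str) -> np.ndarray:
        """Return an ``n x d_view`` matrix for the given view."""

    def parse_mask(self, smiles_list: Sequence[str]) -> np.ndarray:
        """Boolean mask of SMILES this provider can handle (default: all)."""
        return np.ones(len(smiles_list), dtype=bool)


def compute_view(
    smiles_list: Sequence[str], view: str, provider: FingerprintProvider
) -> FeatureView:
    """Compute one fingerprint view through a provider."""
    if view not in provider.available_views:
        raise ValueError(
            f"provider {type(provider).__name__} does not serve view {view!r}; "
            f"available: {provider.available_views}"
        )
    matrix = provider.compute(smiles_list, view)
    return FeatureView(name=view, matrix=np.asarray(matrix, dtype=float))


def compute_all_views(
    smiles_list: Sequence[str], provider: FingerprintProvider
) -> tuple[FusedFeatures, np.ndarray]:
    """Compute the five views and fuse them.

    Unparseable SMILES are dropped consistently across all views; the
    returned boolean mask marks the retained compounds.
    """
    mask = provider.parse_mask(smiles_list)
    kept = [s for s, ok in zip(smiles_list, mask) if ok]
    views = [compute_view(kept, name, provider) for name in VIEW_NAMES]
    return fuse_views(views), mask


class FileProvider(FingerprintProvider):
    """Reads precomputed per-view fingerprint CSVs (first column: compound id)."""

    def __init__(self, paths: Mapping[str, str | Path]):
        self._frames: dict[str, pd.DataFrame] = {}
        for name, path in paths.items():
            if name not in VIEW_WIDTHS:
                raise ValueError(f"unknown view {name!r}")
            df = pd.read_csv(path, index_col=0)
            df.index = df.index.astype(str)
            if df.shape[1] != VIEW_WIDTHS[name]:
                raise ValueError(
                    f"file for view {name} has {df.shape[1]} columns, "
                    f"expected {VIEW_WIDTHS[name]}"
                )
            self._frames[name] = df

    @property
    def available_views(self) -> tuple[str, ...]:
        return tuple(self._frames)

    def compute(self, ids: Sequence[str], view: str) -> np.ndarray:
        df = self._frames[view]
        missing = [i for i in ids if i not in df.index]
        if missing:
            raise KeyError(f"{len(missing)} compound ids absent from {view} file, e.g. {missing[:3]}")
        return df.loc[list(ids)].to_numpy(dtype=float)


class RDKitProvider(FingerprintProvider):
    """RDKit backend for the views RDKit can serve natively.

    Serves Morgan (radius 2, 2048 bits) and the RDKit topological
    fingerprint (2048 bits).  SMILES are canonicalized and the largest
    fragment kept (salt stripping) before fingerprinting.
    """

    def __init__(self) -> None:
        from rdkit import Chem  # deferred: optional dependency
        from rdkit.Chem import rdFingerprintGenerator

        self._Chem = Chem
        self._morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        self._rdk = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)

    @property
    def available_views(self) -> tuple[str, ...]:
        return ("Morgan", "RDKIT")

    def _mol(self, smiles: str):
        mol = self._Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        frags = self._Chem.GetMolFrags(mol, asMols=True)
        return max(frags, key=lambda m: m.GetNumAtoms())

    def parse_mask(self, smiles_list: Sequence[str]) -> np.ndarray:
        return np.array([self._mol(s) is not None for s in smiles_list], dtype=bool)

    def compute(self, smiles_list: Sequence[str], view: str) -> np.ndarray:
        gen = {"Morgan": self._morgan, "RDKIT": self._rdk}[view]
        out = np.zeros((len(smiles_list), 2048), dtype=float)
        for i, smi in enumerate(smiles_list):
            mol = self._mol(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES at row {i}: {smi!r}")
            fp = gen.GetFingerprint(mol)
            out[i, list(fp.GetOnBits())] = 1.0
        return out


def write_view_csv(view: FeatureView, ids: Sequence[str], path: str | Path) -> None:
    df = pd.DataFrame(view.matrix, index=list(ids))
    df.index.name = "id"
    df.columns = [f"{view.name}_{j}" for j in range(view.d_view)]
    df.to_csv(path)
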