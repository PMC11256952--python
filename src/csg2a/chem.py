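"""Chemical conditions and structure encoders.

A treatment condition is the triple (S, d, t): a compound structure given as a
SMILES string, a dose in micromolar and an exposure time in hours.  Dose and
time are rescaled to dimensionless units (100 µM and 72 h respectively) before
entering the model, so that typical screening conditions land near 1.

Structure embedding is a pluggable slot.  The default encoder hashes circular
substructures (Morgan fingerprint, radius 2) into a fixed-length bit vector;
the trainable projection that follows lives with the model parameters, not
here, so the encoder output is fully deterministic for a given molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Protocol, runtime_checkable

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DOSE_SCALE_UM = 100.0
TIME_SCALE_H = 72.0

#: dose/time convention for cell-viability records, which carry no explicit
#: treatment condition: 72 h exposure at 10 µM.
DEFAULT_DOSE_UM = 10.0
DEFAULT_TIME_H = 72.0


def scale_dose_time(dose_uM: float, time_h: float) -> tuple[float, float]:
    """Rescale dose and time to dimensionless units (dose/100 µM, time/72 h).

    Raises
    ------
    ValueError
        If either input is negative.
    """
    if dose_uM < 0 or time_h < 0:
        raise ValueError(
            f"dose and time must be nonnegative, got dose_uM={dose_uM}, time_h={time_h}"
        )
    return dose_uM / DOSE_SCALE_UM, time_h / TIME_SCALE_H


@dataclass(frozen=True)
class ChemicalCondition:
    """A treatment condition (S, d, t): SMILES, dose in µM, time in hours."""

    smiles: str
    dose_uM: float = DEFAULT_DOSE_UM
    time_h: float = DEFAULT_TIME_H

    def __post_init__(self) -> None:
        if self.dose_uM < 0 or self.time_h < 0:
            raise ValueError("dose_uM and time_h must be nonnegative")

    def scaled(self) -> tuple[float, float]:
        return scale_dose_time(self.dose_uM, self.time_h)


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES, so chemically identical strings encode identically."""
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@runtime_checkable
class StructureEncoder(Protocol):
    """Deterministic map from a SMILES string to a fixed-length real vector."""

    name: str
    n_features: int

    def encode(self, smiles: str) -> np.ndarray: ...


@dataclass
class MorganFingerprintEncoder:
    """Hashed circular-substructure fingerprint (radius 2 by default).

    Deterministic per canonical SMILES; the result is a 0/1 vector of length
    ``n_bits``.  Encodings are cached per instance.
    """

    n_bits: int = 128
    radius: int = 2
    name: str = field(default="morgan", init=False)

    def __post_init__(self) -> None:
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_features(self) -> int:
        return self.n_bits

    def encode(self, smiles: str) -> np.ndarray:
        can = canonical_smiles(smiles)
        hit = self._cache.get(can)
        if hit is not None:
            return hit
        mol = Chem.MolFromSmiles(can)
        fp = np.asarray(self._gen.GetFingerprint(mol), dtype=np.float64)
        self._cache[can] = fp
        return fp


def resolve_structure_encoder(spec: dict | StructureEncoder | None) -> StructureEncoder:
    """Build a structure encoder from a config mapping.

    ``{"type": "fingerprint", "bits": 128, "radius": 2}`` gives the default
    Morgan encoder; any object satisfying :class:`StructureEncoder` is passed
    through, which is the extension point for learned structure models.
    """
    if spec is None:
        return MorganFingerprintEncoder()
    if isinstance(spec, StructureEncoder) and not isinstance(spec, dict):
        return spec
    if isinstance(spec, dict):
        kind = spec.get("type", "fingerprint")
        if kind == "fingerprint":
            return MorganFingerprintEncoder(
                n_bits=int(spec.get("bits", 128)), radius=int(spec.get("radius", 2))
            )
        raise ValueError(f"unknown structure encoder type: {kind!r}")
    raise TypeError(f"cannot build a structure encoder from {spec!r}")


@lru_cache(maxsize=None)
def _shared_default_encoder(n_bits: int, radius: int) -> MorganFingerprintEncoder:
    return MorganFingerprintEncoder(n_bits=n_bits, radius=radius)
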