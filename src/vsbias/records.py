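"""Core data containers shared across the pipeline.

Molecules are "pseudo-molecules": a descriptor vector plus an embedded 3D
atom cloud with categorical atom-type codes. Real ligands/receptors read
from SDF/PDB fit the same containers (coordinates in Angstrom + type codes),
so the featurization and audit layers are agnostic to the data source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVE = "active"
DECOY = "decoy"


@dataclass
class AtomCloud:
    """A set of atoms: (n, 3) coordinates in Angstrom plus per-atom type codes."""

    coords: np.ndarray
    types: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.types) != len(self.coords):
            raise ValueError(
                f"coords has {len(self.coords)} atoms but {len(self.types)} type codes"
            )
        if np.isnan(self.coords).any():
            raise ValueError("atom coordinates contain NaN")

    def __len__(self) -> int:
        return len(self.coords)

    def translated(self, offset: np.ndarray) -> "AtomCloud":
        return AtomCloud(self.coords + np.asarray(offset, dtype=float), list(self.types))


@dataclass
class MoleculeRecord:
    """One ligand: identity, label, descriptor, embedded atoms, fingerprint.

    ``descriptor`` is the abstract feature vector the synthetic generator
    samples (property dims first, then topology dims). ``atoms`` is the
    pseudo-3D embedding consumed by voxelization; ``fingerprint`` is the
    fixed-length bit vector consumed by the KNN model. Either may be absent
    for molecules that have not passed through the corresponding step.
    """

    mol_id: str
    target_id: str
    label: str
    descriptor: np.ndarray | None = None
    atoms: AtomCloud | None = None
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in (ACTIVE, DECOY):
            raise ValueError(f"label must be {ACTIVE!r} or {DECOY!r}, got {self.label!r}")
        if self.descriptor is not None:
            self.descriptor = np.asarray(self.descriptor, dtype=float).ravel()
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            self.fingerprint = fp.astype(np.uint8).ravel()

    @property
    def is_active(self) -> bool:
        return self.label == ACTIVE


@dataclass
class TargetSet:
    """One protein target: receptor cloud, binding-site center, actives, decoys."""

    target_id: str
    family: str
    receptor_atoms: AtomCloud
    site_center: np.ndarray
    actives: list[MoleculeRecord] = field(default_factory=list)
    decoys: list[MoleculeRecord] = field(default_factory=list)
    interaction_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_center = np.asarray(self.site_center, dtype=float).reshape(3)
        for mol in self.actives + self.decoys:
            if mol.target_id != self.target_id:
                raise ValueError(
                    f"molecule {mol.mol_id} carries target_id {mol.target_id!r}, "
                    f"expected {self.target_id!r}"
                )
        ids = [m.mol_id for m in self.actives] + [m.mol_id for m in self.decoys]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate mol_id within target {self.target_id}")

    @property
    def molecules(self) -> list[MoleculeRecord]:
        return self.actives + self.decoys

    def by_id(self, mol_id: str) -> MoleculeRecord:
        for mol in self.molecules:
            if mol.mol_id == mol_id:
                return mol
        raise KeyError(mol_id)
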