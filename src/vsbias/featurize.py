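"""Atom-density voxel grids, receptor ablation and molecular fingerprints.

A protein–ligand complex is represented as a cubic grid of per-atom-type
densities centered on the binding site: receptor atoms populate the first
block of channels, ligand atoms the second, and optional extra channels
(e.g. precomputed water thermodynamic maps) can be appended. Each atom
spreads a truncated Gaussian kernel over nearby voxel centers.

Receptor ablation — replacing the receptor with an empty dummy
representation so all receptor channels are exactly zero — is the package's
primary probe for whether a model actually uses receptor information.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError, DimensionError, InputError, TypingError
from .records import AtomCloud, MoleculeRecord
from .synthgen import LIGAND_TYPES, RECEPTOR_TYPES

#: Default van der Waals-like radius (Angstrom) for synthetic atom types.
DEFAULT_ATOM_RADIUS = 1.6
#: Kernel support ends at CUTOFF_FACTOR * radius.
CUTOFF_FACTOR = 1.5


@dataclass(frozen=True)
class GridSpec:
    """Geometry and channel layout of a voxel grid.

    Defaults follow the standard grid-CNN setup: a 24 A cube of 48^3 voxels
    at 0.5 A resolution with 16 receptor + 19 ligand atom-type channels
    (35 total; 39 when four water-map channels are attached).
    """

    edge_length: float = 24.0
    voxels_per_edge: int = 48
    resolution: float = 0.5
    n_receptor_channels: int = 16
    n_ligand_channels: int = 19
    n_extra_channels: int = 0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels_per_edge < 1:
            raise ConfigError(f"voxels_per_edge must be >= 1, got {self.voxels_per_edge}")
        if not np.isclose(self.voxels_per_edge * self.resolution, self.edge_length):
            raise ConfigError(
                f"voxels_per_edge ({self.voxels_per_edge}) x resolution "
                f"({self.resolution}) must equal edge_length ({self.edge_length})"
            )
        if self.n_receptor_channels < 0 or self.n_ligand_channels < 1:
            raise ConfigError("channel counts must be nonnegative (>=1 ligand channel)")

    @property
    def n_channels(self) -> int:
        return self.n_receptor_channels + self.n_ligand_channels + self.n_extra_channels

    @property
    def shape(self) -> tuple[int, int, int, int]:
        n = self.voxels_per_edge
        return (self.n_channels, n, n, n)

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates; voxel (0,0,0) at the minimum corner."""
        n = self.voxels_per_edge
        offsets = (np.arange(n) + 0.5) * self.resolution - self.edge_length / 2.0
        c = np.asarray(self.center, dtype=float)
        return c[0] + offsets, c[1] + offsets, c[2] + offsets

    def recentered(self, center) -> "GridSpec":
        kw = {f.name: getattr(self, f.name) for f in fields(self)}
        kw["center"] = tuple(float(x) for x in np.asarray(center).reshape(3))
        return GridSpec(**kw)

    @classmethod
    def reduced(cls, **overrides) -> "GridSpec":
        """Coarse 24-voxel / 1.0 A grid for desk-scale experiments and tests."""
        kw = dict(edge_length=24.0, voxels_per_edge=24, resolution=1.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def synthetic(cls, **overrides) -> "GridSpec":
        """Reduced grid with channel counts matching the synthetic type map."""
        kw = dict(
            edge_length=24.0, voxels_per_edge=24, resolution=1.0,
            n_receptor_channels=len(RECEPTOR_TYPES),
            n_ligand_channels=len(LIGAND_TYPES),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class VoxelGrid:
    """Channelized density tensor plus its geometry."""

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.spec.shape:
            raise DimensionError(
                f"grid shape {self.values.shape} does not match spec {self.spec.shape}"
            )

    @property
    def receptor_values(self) -> np.ndarray:
        return self.values[: self.spec.n_receptor_channels]

    @property
    def ligand_values(self) -> np.ndarray:
        r = self.spec.n_receptor_channels
        return self.values[r : r + self.spec.n_ligand_channels]


@dataclass(frozen=True)
class TypeMap:
    """Maps atom-type codes to channel indices, separately per role."""

    receptor: dict[str, int]
    ligand: dict[str, int]
    radii: dict[str, float] = field(default_factory=dict)

    def radius(self, code: str) -> float:
        return self.radii.get(code, DEFAULT_ATOM_RADIUS)


def synthetic_type_map() -> TypeMap:
    """Type map for the generator's pseudo-atom codes (3 receptor + 3 ligand)."""
    return TypeMap(
        receptor={c: i for i, c in enumerate(RECEPTOR_TYPES)},
        ligand={c: i for i, c in enumerate(LIGAND_TYPES)},
    )


def kernel_density(d: np.ndarray, radius: float) -> np.ndarray:
    """Truncated atom-density kernel.

    Gaussian ``exp(-2 d^2 / r^2)`` for ``d <= r``, continued by the quadratic
    ``(4/(e^2 r^2)) d^2 - (12/(e^2 r)) d + 9/e^2`` (value- and
    slope-matched at ``d = r``) down to zero at ``d = 1.5 r``, zero beyond.
    """
    d = np.asarray(d, dtype=float)
    r = float(radius)
    e2 = np.exp(2.0)
    out = np.zeros_like(d)
    inner = d <= r
    out[inner] = np.exp(-2.0 * d[inner] ** 2 / r**2)
    shoulder = (d > r) & (d < CUTOFF_FACTOR * r)
    ds = d[shoulder]
    out[shoulder] = (4.0 / (e2 * r**2)) * ds**2 - (12.0 / (e2 * r)) * ds + 9.0 / e2
    return out


def _splat(values: np.ndarray, channel: int, xyz: np.ndarray, radius: float,
           spec: GridSpec) -> None:
    """Add one atom's kernel to ``values[channel]`` over its local voxel block."""
    cutoff = CUTOFF_FACTOR * radius
    xs, ys, zs = spec.voxel_centers_1d()
    n = spec.voxels_per_edge
    lo, hi = [], []
    for axis, centers in zip(range(3), (xs, ys, zs)):
        a = int(np.searchsorted(centers, xyz[axis] - cutoff, side="left"))
        b = int(np.searchsorted(centers, xyz[axis] + cutoff, side="right"))
        if a >= n or b <= 0:
            return  # atom entirely outside the box on this axis
        lo.append(max(a, 0))
        hi.append(min(b, n))
    dx = xs[lo[0]:hi[0]] - xyz[0]
    dy = ys[lo[1]:hi[1]] - xyz[1]
    dz = zs[lo[2]:hi[2]] - xyz[2]
    dist = np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    values[channel, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += kernel_density(dist, radius)


def voxelize(
    receptor_atoms: AtomCloud | None,
    ligand: MoleculeRecord | AtomCloud,
    spec: GridSpec,
    type_map: TypeMap,
) -> VoxelGrid:
    """Rasterize a (receptor, ligand) pair into a channelized density grid.

    Receptor atoms contribute only to receptor channels, ligand atoms only
    to ligand channels; extra channels stay zero (attach precomputed maps
    separately). Atoms whose kernel support lies entirely outside the box
    contribute nothing.
    """
    values = np.zeros(spec.shape, dtype=np.float64)
    lig_cloud = ligand.atoms if isinstance(ligand, MoleculeRecord) else ligand
    if isinstance(ligand, MoleculeRecord) and lig_cloud is None:
        raise InputError(f"molecule {ligand.mol_id} has no embedded atoms")

    if receptor_atoms is not None:
        for xyz, code in zip(receptor_atoms.coords, receptor_atoms.types):
            if code not in type_map.receptor:
                raise TypingError(f"unknown receptor atom type {code!r}")
            ch = type_map.receptor[code]
            if ch >= spec.n_receptor_channels:
                raise DimensionError(
                    f"receptor channel {ch} for type {code!r} exceeds spec "
                    f"({spec.n_receptor_channels} receptor channels)"
                )
            _splat(values, ch, xyz, type_map.radius(code), spec)
    for xyz, code in zip(lig_cloud.coords, lig_cloud.types):
        if code not in type_map.ligand:
            raise TypingError(f"unknown ligand atom type {code!r}")
        ch = type_map.ligand[code]
        if ch >= spec.n_ligand_channels:
            raise DimensionError(
                f"ligand channel {ch} for type {code!r} exceeds spec "
                f"({spec.n_ligand_channels} ligand channels)"
            )
        _splat(values, spec.n_receptor_channels + ch, xyz, type_map.radius(code), spec)
    return VoxelGrid(values, spec)


def ablate_receptor(grid: VoxelGrid) -> VoxelGrid:
    """Zero out every receptor channel, leaving ligand channels bit-identical.

    Equivalent to replacing the receptor by a single zero-density dummy atom.
    Idempotent.
    """
    values = grid.values.copy()
    values[: grid.spec.n_receptor_channels] = 0.0
    return VoxelGrid(values, grid.spec)


def _hash_bit(key: str, n_bits: int) -> int:
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_bits


_SIGN_TABLE_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _sign_tables(dim: int, n_bits: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed hash tables mapping sign patterns to bit indices."""
    key = (dim, n_bits)
    if key not in _SIGN_TABLE_CACHE:
        single = np.array(
            [[_hash_bit(f"s:{j}:{s}", n_bits) for s in (0, 1)] for j in range(dim)]
        )
        pair = np.zeros((dim, dim, 2, 2), dtype=np.int64)
        for j in range(dim):
            for k in range(j + 1, dim):
                for sj in (0, 1):
                    for sk in (0, 1):
                        pair[j, k, sj, sk] = _hash_bit(f"p:{j}:{k}:{sj}:{sk}", n_bits)
        _SIGN_TABLE_CACHE[key] = (single, pair)
    return _SIGN_TABLE_CACHE[key]


def fingerprint(molecule: MoleculeRecord, n_bits: int = 2048) -> np.ndarray:
    """Fixed-length bit-vector fingerprint of a molecule.

    Synthetic path: the descriptor's sign pattern is hashed into the bit
    vector — one bit per (dimension, sign) and one per (dimension pair,
    sign pair). Descriptors that agree in sign on most dimensions therefore
    share most bits, preserving neighborhood structure without chemistry
    software; it is a pure function of the descriptor.

    Real path: if the record carries an RDKit molecule in ``rdkit_mol``,
    the RDKit topological fingerprint of that structure is returned.
    """
    rd_mol = getattr(molecule, "rdkit_mol", None)
    if molecule.descriptor is None and rd_mol is None:
        raise InputError(
            f"molecule {molecule.mol_id} has neither a descriptor nor a chemical structure"
        )
    if molecule.descriptor is None:
        from rdkit.Chem import RDKFingerprint  # optional dependency

        fp = RDKFingerprint(rd_mol, fpSize=n_bits)
        return np.array([int(fp.GetBit(i)) for i in range(n_bits)], dtype=np.uint8)

    desc = np.asarray(molecule.descriptor, dtype=float)
    s = (desc >= 0).astype(np.int64)
    single, pair = _sign_tables(desc.size, n_bits)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[single[np.arange(desc.size), s]] = 1
    jj, kk = np.triu_indices(desc.size, k=1)
    bits[pair[jj, kk, s[jj], s[kk]]] = 1
    return bits


def add_fingerprints(targets, n_bits: int = 2048) -> None:
    """Populate ``fingerprint`` in place for every molecule of every target."""
    for tgt in targets:
        for mol in tgt.molecules:
            if mol.fingerprint is None or mol.fingerprint.size != n_bits:
                mol.fingerprint = fingerprint(mol, n_bits)


def save_grid(path, grid: VoxelGrid) -> None:
    """Cache a grid as HDF5: dataset ``values`` + GridSpec fields as attrs.

    Coordinate convention (recorded in the file): voxel (0,0,0) is the
    minimum corner of the box.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("values", data=grid.values, compression="gzip")
        for f in fields(grid.spec):
            dset.attrs[f.name] = getattr(grid.spec, f.name)
        dset.attrs["origin_convention"] = "voxel (0,0,0) at minimum corner"


def load_grid(path) -> VoxelGrid:
    import h5py

    with h5py.File(path, "r") as fh:
        dset = fh["values"]
        kw = {
            f.name: dset.attrs[f.name] for f in fields(GridSpec)
            if f.name in dset.attrs
        }
        kw["center"] = tuple(float(x) for x in np.asarray(kw["center"]).ravel())
        for name in ("voxels_per_edge", "n_receptor_channels", "n_ligand_channels",
                     "n_extra_channels"):
            if name in kw:
                kw[name] = int(kw[name])
        return VoxelGrid(dset[()], GridSpec(**kw))
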