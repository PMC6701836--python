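"""Synthetic multi-target virtual-screening datasets with tunable bias.

Benchmark sets like DUD-E pair each protein target with experimentally
confirmed actives and property-matched decoys. A classifier evaluated on
such a set can draw on three distinct information sources:

1. **Interaction signal** — genuine geometric/chemical complementarity
   between a ligand and its receptor.
2. **Analogue bias** — actives of a target (or of a protein family) resemble
   one another, so ligand similarity alone separates actives from decoys.
3. **Decoy bias** — the decoy-selection procedure leaves a systematic,
   learnable footprint on the decoys that is shared across targets.

This module generates pseudo-molecular datasets in which each source is an
independent knob, so the downstream diagnostic battery can be validated
against ground truth. Molecules are descriptor vectors (property dims then
topology dims) deterministically embedded as small 3D atom clouds; receptors
are atom clouds on a sphere around the binding site.

Generative model (per dataset, all randomness keyed off ``BiasConfig.seed``):

* family centroids ``F_k ~ N(0, centroid_scale^2 I)``;
* target centroid ``C_t = family_share * F_fam(t) + (1 - family_share) * G_t``
  with target-specific ``G_t ~ N(0, centroid_scale^2 I)``;
* active descriptor: ``C_t + intra_spread * eps`` (property dims first,
  then topology dims);
* decoy descriptor: property dims copied verbatim from a matched active
  (property matching); topology dims resampled from the *population*
  marginal ``N(0, centroid_scale^2 + intra_spread^2)`` (the decoy pool is
  topology-diverse by construction) and then displaced by
  ``decoy_shift * u`` along a direction ``u`` shared across all targets
  (decoy bias transfers across unrelated targets).

``interaction_strength`` shapes only the *receptor*: its binding-site atoms
encode the sign pattern of the target centroid — i.e. where that target's
actives live in topology space — so a model reading both receptor and
ligand can judge complementarity on a target it has never seen, while the
ligand marginals are untouched (pooled over random centroids, actives and
decoys are identically distributed, so ligand-only screening of a held-out
target is chance by construction).

With all three knobs at zero and ``family_share = 0``, active and decoy
descriptors are drawn from the same law, so no classifier can beat chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError, DimensionError, InputError
from .records import ACTIVE, DECOY, AtomCloud, MoleculeRecord, TargetSet

#: Ligand atom-type codes: LA/LB encode topology-dimension signs, LC property dims.
LIGAND_TYPES = ("LA", "LB", "LC")
#: Receptor atom-type codes: R0 scaffold, RP/RN encode interaction-profile signs.
RECEPTOR_TYPES = ("R0", "RP", "RN")

#: Radius (Angstrom) of the shell on which topology-dimension ligand atoms sit.
TOPOLOGY_SHELL_RADIUS = 5.5
#: Base radius for property-dimension ligand atoms; |value| extends it.
PROPERTY_BASE_RADIUS = 2.0
#: Receptor sphere radius around the binding-site center.
RECEPTOR_RADIUS = 8.0
#: Number of receptor atoms (topology-aligned slots + scaffold).
N_RECEPTOR_ATOMS = 40
#: Spatial jitter (Angstrom) applied to embedded ligand atoms.
EMBED_JITTER = 0.08


@dataclass
class BiasConfig:
    """Knobs of the synthetic dataset generator.

    The three bias knobs are ``intra_spread`` (smaller = tighter active
    clusters = stronger intra-target analogue bias), ``family_share``
    (inter-target analogue bias) and ``decoy_shift`` (decoy bias);
    ``interaction_strength`` controls how strongly a receptor geometrically
    complements its own actives (interaction signal).
    """

    n_targets: int = 12
    n_families: int = 4
    actives_per_target: int = 40
    decoys_per_target: int = 200
    descriptor_dim: int = 32
    n_property_dims: int = 8
    intra_spread: float = 0.4
    family_share: float = 0.5
    decoy_shift: float = 2.0
    interaction_strength: float = 0.0
    centroid_scale: float = 1.0
    shared_decoy_direction: bool = True
    seed: int = 0

    @property
    def n_topology_dims(self) -> int:
        return self.descriptor_dim - self.n_property_dims

    def validate(self) -> "BiasConfig":
        for name in ("n_targets", "n_families", "actives_per_target",
                     "decoys_per_target", "descriptor_dim", "n_property_dims"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_families > self.n_targets:
            raise ConfigError(
                f"n_families ({self.n_families}) must not exceed n_targets ({self.n_targets})"
            )
        if self.n_property_dims >= self.descriptor_dim:
            raise ConfigError(
                "n_property_dims must leave at least one topology dimension "
                f"(n_property_dims={self.n_property_dims}, descriptor_dim={self.descriptor_dim})"
            )
        for name in ("intra_spread", "decoy_shift", "interaction_strength", "centroid_scale"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be a nonnegative real, got {value!r}")
        if not 0.0 <= self.family_share <= 1.0:
            raise ConfigError(f"family_share must lie in [0, 1], got {self.family_share!r}")
        return self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic generator keyed by (seed, *key); independent per key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def fibonacci_directions(n: int, offset: float = 0.0) -> np.ndarray:
    """``n`` nearly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + 5.0 ** 0.5)
    theta = golden * i + offset
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def embed_molecule(
    descriptor: np.ndarray,
    seed: int,
    n_property_dims: int = 8,
) -> AtomCloud:
    """Deterministically embed a descriptor vector as a pseudo-3D atom cloud.

    Encoding rule (documented contract, used by tests):

    * topology dim ``j`` maps to a slot direction ``v_j`` (Fibonacci sphere
      over the topology dims) at radius 5.5 A. The slot holds
      ``1 + min(2, floor(|d_j|))`` atoms of type ``LA`` if ``d_j >= 0`` else
      ``LB``; extra atoms are offset 0.7 A along a fixed tangent.
    * property dim ``i`` maps to one ``LC`` atom along its own direction at
      radius ``2.0 + 0.5 * min(|d_i|, 4)`` — property values set the spatial
      extent of the core.
    * a small seeded jitter (sigma 0.08 A) is added to every atom; identical
      (descriptor, seed) pairs therefore yield identical clouds.

    The all-zero descriptor yields the minimal reference cloud: one ``LA``
    atom per topology slot plus one ``LC`` atom per property dim at base
    radius (before jitter).
    """
    d = np.asarray(descriptor, dtype=float).ravel()
    n_topo = d.size - n_property_dims
    if n_topo < 1:
        raise DimensionError(
            f"descriptor of length {d.size} leaves no topology dims "
            f"(n_property_dims={n_property_dims})"
        )
    prop, topo = d[:n_property_dims], d[n_property_dims:]

    topo_dirs = fibonacci_directions(n_topo)
    # fixed tangent per slot for multi-atom offsets
    up = np.array([0.0, 0.0, 1.0])
    tangents = np.cross(topo_dirs, up)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = np.where(norms > 1e-9, tangents / np.maximum(norms, 1e-9),
                        np.array([1.0, 0.0, 0.0]))

    coords: list[np.ndarray] = []
    types: list[str] = []
    for j, dj in enumerate(topo):
        count = 1 + min(2, int(np.floor(abs(dj))))
        code = "LA" if dj >= 0 else "LB"
        base = topo_dirs[j] * TOPOLOGY_SHELL_RADIUS
        for k in range(count):
            coords.append(base + 0.7 * k * tangents[j])
            types.append(code)
    prop_dirs = fibonacci_directions(n_property_dims, offset=1.0)
    for i, di in enumerate(prop):
        radius = PROPERTY_BASE_RADIUS + 0.5 * min(abs(di), 4.0)
        coords.append(prop_dirs[i] * radius)
        types.append("LC")

    xyz = np.asarray(coords)
    xyz = xyz + _rng(seed, 7).normal(0.0, EMBED_JITTER, size=xyz.shape)
    return AtomCloud(xyz, types)


def build_receptor(
    centroid_topo: np.ndarray,
    interaction_strength: float,
    site_center: np.ndarray,
) -> AtomCloud:
    """Receptor cloud: 40 atoms on a sphere of radius 8 A around the site.

    One slot atom per topology dimension sits on the same direction as the
    corresponding ligand slot. With ``interaction_strength > 0`` the slot
    atom's type encodes the sign of that centroid coordinate (``RP``/``RN``)
    and its radius is nudged by ``0.5 * tanh(strength * centroid_j)`` — the
    receptor geometrically complements its own actives, whose descriptors
    cluster around the centroid, and a model reading both sides can score
    complementarity. At zero strength every atom is scaffold type ``R0`` and
    the cloud is target-independent.
    """
    centroid_topo = np.asarray(centroid_topo, dtype=float).ravel()
    n_topo = centroid_topo.size
    dirs = fibonacci_directions(n_topo)
    coords: list[np.ndarray] = []
    types: list[str] = []
    site_center = np.asarray(site_center, dtype=float).reshape(3)
    for j in range(n_topo):
        if interaction_strength > 0:
            code = "RP" if centroid_topo[j] >= 0 else "RN"
            radius = RECEPTOR_RADIUS + 0.5 * np.tanh(
                interaction_strength * centroid_topo[j]
            )
        else:
            code = "R0"
            radius = RECEPTOR_RADIUS
        coords.append(site_center + dirs[j] * radius)
        types.append(code)
    n_scaffold = N_RECEPTOR_ATOMS - n_topo
    if n_scaffold > 0:
        for v in fibonacci_directions(n_scaffold, offset=2.0):
            coords.append(site_center + v * RECEPTOR_RADIUS)
            types.append("R0")
    return AtomCloud(np.asarray(coords), types)


def generate_dataset(config: BiasConfig) -> list[TargetSet]:
    """Generate a seeded multi-target dataset under the configured bias knobs.

    Returns one :class:`TargetSet` per target; targets are assigned to
    families round-robin so families are balanced. Reproducible bit-for-bit
    from the config alone.
    """
    cfg = config.validate()
    n_prop, n_topo = cfg.n_property_dims, cfg.n_topology_dims
    rho, sigma = cfg.centroid_scale, cfg.intra_spread
    # decoy topology background matches the actives' population marginal at
    # family_share = 0, which makes the all-knobs-zero dataset an exact null
    bg_sigma = float(np.hypot(rho, sigma))

    ds_rng = _rng(cfg.seed, 0)
    family_centroids = ds_rng.normal(0.0, rho, size=(cfg.n_families, cfg.descriptor_dim))
    shared_u = ds_rng.normal(size=n_topo)
    shared_u /= np.linalg.norm(shared_u)

    targets: list[TargetSet] = []
    for t in range(cfg.n_targets):
        fam_idx = t % cfg.n_families
        t_rng = _rng(cfg.seed, 1, t)
        own = t_rng.normal(0.0, rho, size=cfg.descriptor_dim)
        centroid = cfg.family_share * family_centroids[fam_idx] + (1.0 - cfg.family_share) * own
        if cfg.shared_decoy_direction:
            u = shared_u
        else:
            u = t_rng.normal(size=n_topo)
            u /= np.linalg.norm(u)

        target_id = f"T{t:02d}"
        family = f"F{fam_idx:02d}"
        profile = centroid.copy()

        actives: list[MoleculeRecord] = []
        for i in range(cfg.actives_per_target):
            desc = centroid + sigma * t_rng.normal(size=cfg.descriptor_dim)
            mol_seed = (cfg.seed * 1_000_003 + t * 10_007 + i) & 0x7FFFFFFF
            actives.append(
                MoleculeRecord(
                    mol_id=f"{target_id}_A{i:04d}",
                    target_id=target_id,
                    label=ACTIVE,
                    descriptor=desc,
                    atoms=embed_molecule(desc, mol_seed, n_prop),
                )
            )
        decoys: list[MoleculeRecord] = []
        for j in range(cfg.decoys_per_target):
            matched = actives[j % cfg.actives_per_target]
            desc = np.empty(cfg.descriptor_dim)
            desc[:n_prop] = matched.descriptor[:n_prop]
            desc[n_prop:] = t_rng.normal(0.0, bg_sigma, size=n_topo) + cfg.decoy_shift * u
            mol_seed = (cfg.seed * 1_000_003 + t * 10_007 + 5000 + j) & 0x7FFFFFFF
            decoys.append(
                MoleculeRecord(
                    mol_id=f"{target_id}_D{j:04d}",
                    target_id=target_id,
                    label=DECOY,
                    descriptor=desc,
                    atoms=embed_molecule(desc, mol_seed, n_prop),
                )
            )

        site_center = np.zeros(3)
        receptor = build_receptor(centroid[n_prop:], cfg.interaction_strength, site_center)
        targets.append(
            TargetSet(
                target_id=target_id,
                family=family,
                receptor_atoms=receptor,
                site_center=site_center,
                actives=actives,
                decoys=decoys,
                interaction_profile=profile,
            )
        )
    return targets


def surrogate_scorer(molecule: MoleculeRecord, target: TargetSet) -> float:
    """Pseudo binding affinity: negative Euclidean distance between the
    molecule's descriptor and the target's interaction profile.

    Stands in for a docking score when ranking other targets' actives during
    actives-as-decoys construction. Higher is better; a molecule matching
    the profile exactly scores the maximum, 0.
    """
    if molecule.descriptor is None:
        raise InputError(f"molecule {molecule.mol_id} has no descriptor")
    if target.interaction_profile is None:
        raise InputError(f"target {target.target_id} has no interaction profile")
    return float(-np.linalg.norm(molecule.descriptor - target.interaction_profile))
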