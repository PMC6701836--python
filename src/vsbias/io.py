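"""Readers and writers: dataset manifests, atom tables, splits, real-data formats.

The synthetic text format is a plain whitespace-free TSV family:

* ``manifest.tsv`` — one molecule per row: ``mol_id  target_id  family
  label  descriptor`` (descriptor inlined as comma-joined floats);
* ``targets.tsv`` — one target per row: ID, family, site center,
  interaction profile;
* ``*_atoms.tsv`` — the documented XYZ-with-types table: ``owner_id
  atom_index  atom_type  x  y  z`` with coordinates in Angstrom.

Real data enters through PDB (receptor atoms, via gemmi) and SDF (ligands,
via RDKit when available).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .records import AtomCloud, MoleculeRecord, TargetSet
from .splits import SplitSpec

_FLOAT_FMT = "%.10g"

MANIFEST_COLUMNS = ["mol_id", "target_id", "family", "label", "descriptor"]


def _fmt_vec(v: np.ndarray) -> str:
    return ",".join(_FLOAT_FMT % x for x in np.asarray(v, dtype=float).ravel())


def _parse_vec(s: str) -> np.ndarray:
    return np.array([float(x) for x in str(s).split(",")], dtype=float)


def write_dataset(targets: list[TargetSet], out_dir, include_atoms: bool = True) -> Path:
    """Persist a dataset as a directory of TSV tables (+ JSON metadata).

    Everything needed to reconstruct the dataset is written: the molecule
    manifest with inline descriptors, per-target metadata, receptor atoms,
    and (optionally) ligand atom clouds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    lig_atoms = []
    for tgt in targets:
        for mol in tgt.molecules:
            rows.append(
                dict(mol_id=mol.mol_id, target_id=mol.target_id, family=tgt.family,
                     label=mol.label, descriptor=_fmt_vec(mol.descriptor)
                     if mol.descriptor is not None else "")
            )
            if include_atoms and mol.atoms is not None:
                for i, (xyz, code) in enumerate(zip(mol.atoms.coords, mol.atoms.types)):
                    lig_atoms.append((mol.mol_id, i, code,
                                      *(_FLOAT_FMT % c for c in xyz)))
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )

    trows = []
    rec_atoms = []
    for tgt in targets:
        trows.append(
            dict(target_id=tgt.target_id, family=tgt.family,
                 site_center=_fmt_vec(tgt.site_center),
                 interaction_profile=_fmt_vec(tgt.interaction_profile)
                 if tgt.interaction_profile is not None else "")
        )
        for i, (xyz, code) in enumerate(zip(tgt.receptor_atoms.coords,
                                            tgt.receptor_atoms.types)):
            rec_atoms.append((tgt.target_id, i, code, *(_FLOAT_FMT % c for c in xyz)))
    pd.DataFrame(trows).to_csv(out / "targets.tsv", sep="\t", index=False)
    _write_atom_table(out / "receptor_atoms.tsv", rec_atoms)
    if include_atoms:
        _write_atom_table(out / "ligand_atoms.tsv", lig_atoms)
    return out


def _write_atom_table(path: Path, rows) -> None:
    pd.DataFrame(
        rows, columns=["owner_id", "atom_index", "atom_type", "x", "y", "z"]
    ).to_csv(path, sep="\t", index=False)


def _read_atom_table(path: Path) -> dict[str, AtomCloud]:
    df = pd.read_csv(path, sep="\t")
    for col in ("owner_id", "atom_index", "atom_type", "x", "y", "z"):
        if col not in df.columns:
            raise SchemaError(f"atom table {path.name} is missing column {col!r}")
    clouds = {}
    for owner, grp in df.groupby("owner_id", sort=False):
        grp = grp.sort_values("atom_index")
        clouds[str(owner)] = AtomCloud(
            grp[["x", "y", "z"]].to_numpy(float), [str(t) for t in grp["atom_type"]]
        )
    return clouds


def read_dataset(in_dir) -> list[TargetSet]:
    """Reconstruct a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    man = pd.read_csv(src / "manifest.tsv", sep="\t")
    for col in MANIFEST_COLUMNS:
        if col not in man.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    tmeta = pd.read_csv(src / "targets.tsv", sep="\t")
    receptors = _read_atom_table(src / "receptor_atoms.tsv")
    lig_path = src / "ligand_atoms.tsv"
    ligand_clouds = _read_atom_table(lig_path) if lig_path.exists() else {}

    targets = []
    for _, trow in tmeta.iterrows():
        tid = str(trow["target_id"])
        mols = man[man["target_id"] == tid]
        actives, decoys = [], []
        for _, row in mols.iterrows():
            desc = _parse_vec(row["descriptor"]) if isinstance(row["descriptor"], str) \
                and row["descriptor"] else None
            rec = MoleculeRecord(
                mol_id=str(row["mol_id"]), target_id=tid, label=str(row["label"]),
                descriptor=desc, atoms=ligand_clouds.get(str(row["mol_id"])),
            )
            (actives if rec.is_active else decoys).append(rec)
        profile = (_parse_vec(trow["interaction_profile"])
                   if isinstance(trow["interaction_profile"], str)
                   and trow["interaction_profile"] else None)
        targets.append(
            TargetSet(
                target_id=tid, family=str(trow["family"]),
                receptor_atoms=receptors[tid],
                site_center=_parse_vec(trow["site_center"]),
                actives=actives, decoys=decoys, interaction_profile=profile,
            )
        )
    return targets


# ---------------------------------------------------------------------------
# splits


def write_split(spec: SplitSpec, index, path_prefix) -> tuple[Path, Path]:
    """Serialize a split as TSV (mol_id, role, pool, label, donor_target)
    plus a JSON sidecar (kind, seed, caps)."""
    prefix = Path(path_prefix)
    rows = [
        dict(mol_id=i, role="train", pool="",
             label=spec.label_overrides.get(i, index[i].label), donor_target="")
        for i in spec.train_ids
    ]
    for pool, ids in spec.test_pools.items():
        rows += [
            dict(mol_id=i, role="test", pool=pool,
                 label=spec.label_overrides.get(i, index[i].label),
                 donor_target=spec.donor_map.get(i, ""))
            for i in ids
        ]
    tsv = prefix.with_suffix(".tsv")
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(json.dumps(
        dict(kind=spec.kind, seed=spec.seed, decoy_cap=spec.decoy_cap), indent=2
    ))
    return tsv, sidecar


def read_split(path_prefix) -> SplitSpec:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", keep_default_na=False)
    for col in ("mol_id", "role", "pool", "label", "donor_target"):
        if col not in df.columns:
            raise SchemaError(f"split table is missing column {col!r}")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    train_ids = [str(m) for m in df[df["role"] == "train"]["mol_id"]]
    test_pools: dict[str, list[str]] = {}
    donor_map: dict[str, str] = {}
    overrides: dict[str, str] = {}
    for _, row in df[df["role"] == "test"].iterrows():
        test_pools.setdefault(str(row["pool"]), []).append(str(row["mol_id"]))
        if row["donor_target"]:
            donor_map[str(row["mol_id"])] = str(row["donor_target"])
            overrides[str(row["mol_id"])] = str(row["label"])
    return SplitSpec(
        kind=meta["kind"], seed=int(meta["seed"]), train_ids=train_ids,
        test_pools=test_pools, donor_map=donor_map, label_overrides=overrides,
        decoy_cap=int(meta.get("decoy_cap", 1000)),
    )


# ---------------------------------------------------------------------------
# real-data readers


def read_pdb_receptor(path, heavy_only: bool = True) -> AtomCloud:
    """Receptor atoms from a PDB file; atom types are element symbols."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    coords, types = [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    el = atom.element.name
                    if heavy_only and el == "H":
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    types.append(el)
        break  # first model only
    return AtomCloud(np.asarray(coords), types)


def read_sdf_ligands(path, target_id: str = "", label: str = "active") -> list[MoleculeRecord]:
    """Ligands with 3D coordinates from an SDF file (requires RDKit).

    Atom types are element symbols; the RDKit molecule is attached as
    ``rdkit_mol`` so chemistry-based fingerprints remain available.
    """
    from rdkit import Chem

    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        types = [a.GetSymbol() for a in mol.GetAtoms()]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i:05d}"
        rec = MoleculeRecord(mol_id=name, target_id=target_id, label=label,
                             atoms=AtomCloud(coords, types))
        rec.rdkit_mol = mol  # type: ignore[attr-defined]
        out.append(rec)
    return out
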