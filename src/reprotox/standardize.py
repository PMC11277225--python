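"""Molecule standardization, dataset loading, and train/test/validation splits.

Standardization is: parse the SMILES, keep the largest fragment that contains
carbon (dropping counterions, solvents and salts), neutralize charges where a
simple proton transfer suffices, and emit the RDKit canonical SMILES with
implicit hydrogens.  Failures are reported as :class:`Rejection` values rather
than raised, so a batch load can account for every input row.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord", "Rejection", "DatasetSplit", "LoadReport",
    "standardize_record", "load_dataset", "split_dataset",
]

DEFAULT_SEED = 42


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule with a binary reproductive-toxicity label."""

    id: str
    smiles: str
    label: int | None = None
    source: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class Rejection:
    """A standardization failure with a machine-readable reason."""

    raw_smiles: str
    reason: str  # "parse_failure" | "no_organic_fragment"


@dataclass
class LoadReport:
    accepted: int = 0
    rejected: list[Rejection] = field(default_factory=list)
    duplicates: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test/validation partition of a record list."""

    train: tuple[MoleculeRecord, ...]
    test: tuple[MoleculeRecord, ...]
    validation: tuple[MoleculeRecord, ...]
    seed: int
    ratios: tuple[float, float, float]

    def parts(self):
        return {"train": self.train, "test": self.test,
                "validation": self.validation}


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize charged atoms where removing/adding a proton suffices.

    Standard pattern: an atom with nonzero formal charge and no oppositely
    charged neighbour (so zwitterionic quaternary centres are left alone)
    gains or loses hydrogens to cancel the charge.
    """
    pattern = Chem.MolFromSmarts("[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]")
    mol = Chem.RWMol(mol)
    for (idx,) in mol.GetSubstructMatches(pattern):
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        new_h = h - charge
        if new_h < 0:
            continue  # cannot fix by proton transfer (e.g. N+ with no H)
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(new_h)
        atom.SetNoImplicit(True)
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize_record(raw_smiles: str) -> str | Rejection:
    """Standardize one raw SMILES to its canonical parent form.

    Returns the canonical SMILES of the largest carbon-containing fragment
    after salt/solvent stripping and charge neutralization, or a
    :class:`Rejection` carrying the failure reason.  Idempotent on its own
    outputs.
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        return Rejection(str(raw_smiles), "parse_failure")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection(raw_smiles, "parse_failure")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags
               if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return Rejection(raw_smiles, "no_organic_fragment")
    # largest by heavy-atom count; ties broken by input order
    parent = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    try:
        Chem.SanitizeMol(parent)
        parent = _neutralize(parent)
    except Exception:
        return Rejection(raw_smiles, "parse_failure")
    return Chem.MolToSmiles(parent)


def load_dataset(path: str | Path, fmt: str = "csv",
                 labels_path: str | Path | None = None,
                 ) -> tuple[list[MoleculeRecord], LoadReport]:
    """Load and standardize a labeled molecule table.

    ``csv`` mode expects a header with ``smiles`` and ``label`` columns (an
    ``id`` column is optional); ``smi`` mode is one SMILES per line with an
    optional whitespace-separated id, labels then supplied via a sidecar CSV
    mapping id to label.  Rows whose canonical SMILES duplicates an earlier
    row are dropped (first occurrence kept) and counted in the report.
    """
    path = Path(path)
    if fmt not in ("csv", "smi"):
        raise ValueError(f"unknown format {fmt!r}")
    rows: list[tuple[str, str, int | None]] = []  # (id, raw_smiles, label)
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                warnings.warn(f"{path}: empty file")
                return [], LoadReport()
            cols = [c.strip().lower() for c in reader.fieldnames]
            if "smiles" not in cols:
                raise ValueError(f"{path}: missing 'smiles' column")
            if "label" not in cols:
                raise ValueError(f"{path}: missing 'label' column")
            for i, row in enumerate(reader):
                row = {k.strip().lower(): v for k, v in row.items() if k}
                rid = (row.get("id") or f"row{i}").strip()
                rows.append((rid, row["smiles"].strip(),
                             int(float(row["label"]))))
    else:
        sidecar: dict[str, int] = {}
        if labels_path is not None:
            with open(labels_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    row = {k.strip().lower(): v for k, v in row.items()}
                    sidecar[row["id"].strip()] = int(float(row["label"]))
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                rid = parts[1] if len(parts) > 1 else f"mol{i}"
                rows.append((rid, parts[0], sidecar.get(rid)))
    if not rows:
        warnings.warn(f"{path}: empty file")
        return [], LoadReport()

    report = LoadReport()
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    for rid, raw, label in rows:
        result = standardize_record(raw)
        if isinstance(result, Rejection):
            report.rejected.append(result)
            logger.info("rejected %s: %s", raw, result.reason)
            continue
        if result in seen:
            report.duplicates += 1
            continue
        seen.add(result)
        records.append(MoleculeRecord(id=rid, smiles=result, label=label,
                                      source=str(path)))
        report.accepted += 1
    return records, report


def _allocate(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to three parts."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for j in range(short):
        base[order[j]] += 1
    return base


def split_dataset(records: list[MoleculeRecord],
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = DEFAULT_SEED,
                  stratify: bool = True) -> DatasetSplit:
    """Partition records into train/test/validation at the given ratios.

    Deterministic under ``seed``.  With ``stratify`` (default), allocation is
    done per class so each part's class balance matches the whole within one
    molecule per class; stratification requires labels on every record.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("need three non-negative ratios")
    rng = np.random.default_rng(seed)
    parts: list[list[MoleculeRecord]] = [[], [], []]
    if stratify:
        if any(r.label is None for r in records):
            raise ValueError("stratified split requires labels on all records")
        groups = {}
        for rec in records:
            groups.setdefault(rec.label, []).append(rec)
        # per-class floor allocation, then leftovers distributed by largest
        # remainder while honoring the global part-size targets
        targets = _allocate(len(records), ratios)
        counts = {}
        for label in sorted(groups):
            n_c = len(groups[label])
            counts[label] = [int(np.floor(n_c * r)) for r in ratios]
        deficits = [t - sum(counts[lb][p] for lb in counts)
                    for p, t in enumerate(targets)]
        for label in sorted(groups):
            n_c = len(groups[label])
            leftover = n_c - sum(counts[label])
            remainders = [n_c * r - np.floor(n_c * r) for r in ratios]
            order = np.argsort([-x for x in remainders], kind="stable")
            for p in order:
                if leftover == 0:
                    break
                if deficits[p] > 0:
                    counts[label][p] += 1
                    deficits[p] -= 1
                    leftover -= 1
        for label in sorted(groups):
            members = groups[label]
            idx = rng.permutation(len(members))
            start = 0
            for p, c in enumerate(counts[label]):
                for i in idx[start:start + c]:
                    parts[p].append(members[i])
                start += c
    else:
        idx = rng.permutation(len(records))
        counts = _allocate(len(records), ratios)
        start = 0
        for p, c in enumerate(counts):
            for i in idx[start:start + c]:
                parts[p].append(records[i])
            start += c
    for p, r in zip(parts, ratios):
        if r > 0 and records and not p:
            raise ValueError("a requested nonempty part received no records")
    return DatasetSplit(train=tuple(parts[0]), test=tuple(parts[1]),
                        validation=tuple(parts[2]), seed=seed, ratios=ratios)
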