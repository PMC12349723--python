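"""Drug-like ligand libraries: loading, descriptor annotation, Lipinski–Veber filtering.

A screening library is an ordered collection of :class:`LigandRecord` objects,
each holding a SMILES structure plus the physicochemical descriptors used by
the drug-likeness filter (molecular weight, logP, TPSA, H-bond donor/acceptor
counts, rotatable bonds) and two reactive-group flags (aldehyde, thiol) that
define the "clean" subset.  Descriptors are supplied by a pluggable property
calculator so that alternative descriptor conventions can be substituted; the
default calculator uses RDKit.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Protocol

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "LigandRecord",
    "LigandLibrary",
    "PropertyCalculator",
    "RDKitPropertyCalculator",
    "load_ligands",
    "write_library",
    "compute_properties",
    "lipinski_veber_filter",
    "passes_lipinski_veber",
    "LIPINSKI_VEBER_CRITERIA",
]

# SMARTS for the reactive groups excluded from "clean" libraries.
_ALDEHYDE = Chem.MolFromSmarts("[CX3H1]=O")
_THIOL = Chem.MolFromSmarts("[SX2H]")

DESCRIPTOR_FIELDS = ("mw", "logp", "tpsa", "hbd", "hba", "rot_bonds",
                     "has_aldehyde", "has_thiol")


@dataclass
class LigandRecord:
    """One library molecule and its drug-likeness descriptors.

    ``mw`` is in g/mol, ``tpsa`` in Å²; ``logp`` is unitless.  Descriptor
    fields are ``None`` until populated by :func:`compute_properties` (or a
    file loader that carries them).
    """

    ligand_id: str
    structure: str
    mw: float | None = None
    logp: float | None = None
    tpsa: float | None = None
    hbd: int | None = None
    hba: int | None = None
    rot_bonds: int | None = None
    has_aldehyde: bool | None = None
    has_thiol: bool | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def has_descriptors(self) -> bool:
        return all(getattr(self, f) is not None for f in DESCRIPTOR_FIELDS)


@dataclass
class LigandLibrary:
    """Ordered ligand collection with provenance of sources and filters."""

    records: list[LigandRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("sources", [])
        self.provenance.setdefault("filters", [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LigandRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.ligand_id for r in self.records]

    def get(self, ligand_id: str) -> LigandRecord:
        for r in self.records:
            if r.ligand_id == ligand_id:
                return r
        raise KeyError(ligand_id)

    def subset(self, ids: Iterable[str]) -> "LigandLibrary":
        """Sub-library containing ``ids`` in this library's order."""
        wanted = set(ids)
        recs = [r for r in self.records if r.ligand_id in wanted]
        prov = dict(self.provenance)
        prov["filters"] = list(prov.get("filters", [])) + [
            {"name": "subset", "before": len(self.records), "after": len(recs)}
        ]
        return LigandLibrary(recs, prov)


class PropertyCalculator(Protocol):
    """Contract for descriptor calculators: SMILES in, descriptor dict out.

    ``__call__`` must return a dict with keys ``mw, logp, tpsa, hbd, hba,
    rot_bonds, has_aldehyde, has_thiol`` or raise ``ValueError`` for a
    molecule it cannot handle.
    """

    def __call__(self, structure: str) -> dict: ...


class RDKitPropertyCalculator:
    """Default descriptor calculator backed by RDKit.

    TPSA is topological polar surface area (Ertl); the rotatable-bond count
    uses RDKit's default definition (amide C–N bonds excluded).
    """

    name = "rdkit"

    def __call__(self, structure: str) -> dict:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable structure: {structure!r}")
        return {
            "mw": Descriptors.MolWt(mol),
            "logp": Crippen.MolLogP(mol),
            "tpsa": Descriptors.TPSA(mol),
            "hbd": Lipinski.NumHDonors(mol),
            "hba": Lipinski.NumHAcceptors(mol),
            "rot_bonds": Lipinski.NumRotatableBonds(mol),
            "has_aldehyde": mol.HasSubstructMatch(_ALDEHYDE),
            "has_thiol": mol.HasSubstructMatch(_THIOL),
        }


def _parses(structure: str) -> bool:
    return bool(structure) and Chem.MolFromSmiles(structure) is not None


def load_ligands(path: str | Path, format: str = "smiles-table",
                 smiles_col: str = "smiles", id_col: str = "ligand_id",
                 ) -> LigandLibrary:
    """Load a ligand library from a SMILES table, SDF, or CSV file.

    ``smiles-table`` is whitespace-delimited ``SMILES id`` lines.  Entries
    whose structure does not parse are counted in the provenance
    (``skipped``), never silently dropped.  Duplicate ligand ids and files
    with zero parseable records are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    entries: list[tuple[str, str]] = []  # (smiles, ligand_id)
    skipped = 0

    if format == "smiles-table":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2 or not _parses(parts[0]):
                skipped += 1
                continue
            entries.append((parts[0], parts[1]))
    elif format == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path))
        except OSError:
            raise ValueError(f"zero parseable records in {path}") from None
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            entries.append((Chem.MolToSmiles(mol), name or f"sdf_{i}"))
    elif format == "csv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                smi = (row.get(smiles_col) or "").strip()
                lid = (row.get(id_col) or "").strip()
                if not lid or not _parses(smi):
                    skipped += 1
                    continue
                entries.append((smi, lid))
    else:
        raise ValueError(f"unknown format {format!r}")

    if not entries:
        raise ValueError(f"zero parseable records in {path}")

    seen: set[str] = set()
    records = []
    for smi, lid in entries:
        if lid in seen:
            raise ValueError(f"duplicate ligand_id {lid!r} in {path}")
        seen.add(lid)
        records.append(LigandRecord(ligand_id=lid, structure=smi))

    return LigandLibrary(records, {"sources": [str(path)], "filters": [],
                                   "skipped": skipped})


def write_library(lib: LigandLibrary, path: str | Path,
                  history_path: str | Path | None = None) -> None:
    """Write a library as a SMILES table, optionally with a JSON history sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in lib.records:
            fh.write(f"{r.structure}\t{r.ligand_id}\n")
    if history_path is not None:
        with open(history_path, "w") as fh:
            json.dump(lib.provenance, fh, indent=2, default=str)
            fh.write("\n")


def compute_properties(lib: LigandLibrary,
                       calculator: PropertyCalculator | None = None,
                       ) -> LigandLibrary:
    """Populate descriptor fields for every record using ``calculator``.

    Records the calculator rejects are flagged ``descriptor_failed`` in their
    annotations (and excluded from downstream filtering); the failure count
    goes into the provenance.
    """
    calc = calculator or RDKitPropertyCalculator()
    out: list[LigandRecord] = []
    failed = 0
    for r in lib.records:
        try:
            desc = calc(r.structure)
        except ValueError:
            failed += 1
            rec = replace(r, annotations={**r.annotations,
                                          "descriptor_failed": True})
            out.append(rec)
            continue
        out.append(replace(r, **desc))
    prov = dict(lib.provenance)
    prov["descriptor_failed"] = failed
    prov["calculator"] = getattr(calc, "name", type(calc).__name__)
    return LigandLibrary(out, prov)


# Drug-likeness criteria: (name, predicate on a fully-annotated record).
# Bounds follow the oral-bioavailability rule used for "clean drug-like"
# libraries: strict inequalities everywhere except rotatable bonds (≤ 7);
# aldehydes and thiols are excluded outright.
LIPINSKI_VEBER_CRITERIA: list[tuple[str, callable]] = [
    ("mw", lambda r: 150.0 < r.mw < 500.0),
    ("logp", lambda r: r.logp < 5.0),
    ("tpsa", lambda r: r.tpsa < 150.0),
    ("hbd", lambda r: r.hbd < 5),
    ("hba", lambda r: r.hba < 10),
    ("rot_bonds", lambda r: r.rot_bonds <= 7),
    ("reactive", lambda r: not (r.has_aldehyde or r.has_thiol)),
]


def passes_lipinski_veber(record: LigandRecord) -> bool:
    """Brute re-evaluation of all seven drug-likeness criteria."""
    return all(pred(record) for _, pred in LIPINSKI_VEBER_CRITERIA)


def lipinski_veber_filter(lib: LigandLibrary) -> LigandLibrary:
    """Retain records meeting every Lipinski–Veber criterion.

    A record failing several criteria is counted once per criterion in the
    history but removed once.  Records flagged ``descriptor_failed`` are
    excluded and counted separately.  Idempotent.
    """
    retained: list[LigandRecord] = []
    rejected_by: dict[str, int] = {name: 0 for name, _ in LIPINSKI_VEBER_CRITERIA}
    descriptor_failed = 0
    for r in lib.records:
        if r.annotations.get("descriptor_failed"):
            descriptor_failed += 1
            continue
        if not r.has_descriptors:
            raise ValueError(
                f"record {r.ligand_id!r} lacks descriptors; "
                "run compute_properties first")
        ok = True
        for name, pred in LIPINSKI_VEBER_CRITERIA:
            if not pred(r):
                rejected_by[name] += 1
                ok = False
        if ok:
            retained.append(r)
    prov = dict(lib.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [{
        "name": "lipinski_veber",
        "before": len(lib.records),
        "after": len(retained),
        "rejected_by": rejected_by,
        "descriptor_failed": descriptor_failed,
    }]
    return LigandLibrary(retained, prov)
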