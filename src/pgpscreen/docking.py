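"""Receptor manifests, docking-output parsing, and a deterministic mock engine.

Docking itself (e.g. AutoDock Vina against multiple transporter
conformations) is external computation; this module describes the receptors
— which conformation, which domain (nucleotide binding domain, NBD, vs drug
binding domain, DBD), where the search box sits — and turns engine output
into :class:`DockingResult` records.  Three output dialects are supported:

``pdbqt-remark``
    Vina output PDBQT; each pose contributes a
    ``REMARK VINA RESULT: <energy> <rmsd_lb> <rmsd_ub>`` line.
``log-table``
    Vina's console log with the ``mode | affinity | ...`` table.
``score-tsv``
    Plain table with ligand_id, target_id, dg columns (one row per pose).

For pipeline testing without external software, :func:`mock_dock` generates
energies from a planted affinity landscape: a base ΔG per domain class plus a
per-ligand NBD-preference offset and Gaussian noise, fully reproducible from
a seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ligands import LigandLibrary

__all__ = [
    "ReceptorTarget",
    "DockingResult",
    "PlantedLandscape",
    "load_target_manifest",
    "validate_targets",
    "parse_vina_output",
    "parse_vina_directory",
    "write_docking_results",
    "read_score_table",
    "write_score_table",
    "mock_dock",
]

DOMAIN_CLASSES = ("NBD", "DBD")


@dataclass(frozen=True)
class ReceptorTarget:
    """One docking receptor: a conformation, a domain class, and a search box.

    ``pair_group`` links the DBD and NBD boxes of the same conformation that
    form a counter-selection ratio pair.  Box center/size are Å in the
    receptor frame.
    """

    target_id: str
    conformation: str
    domain_class: str
    box_center: tuple[float, float, float]
    box_size: tuple[float, float, float]
    pair_group: str

    def __post_init__(self):
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"target {self.target_id!r}: domain_class must "
                             f"be one of {DOMAIN_CLASSES}, "
                             f"got {self.domain_class!r}")
        if any(s <= 0 for s in self.box_size):
            raise ValueError(f"target {self.target_id!r}: non-positive box "
                             f"size {self.box_size}")


@dataclass(frozen=True)
class DockingResult:
    """Per-pose binding energies for one ligand×target docking run."""

    ligand_id: str
    target_id: str
    all_dg: tuple[float, ...]

    def __post_init__(self):
        if len(self.all_dg) < 1:
            raise ValueError(f"{self.ligand_id}×{self.target_id}: "
                             "at least one pose required")

    @property
    def best_dg(self) -> float:
        """Best (most negative) pose energy, kcal/mol."""
        return min(self.all_dg)

    @property
    def n_modes(self) -> int:
        return len(self.all_dg)


def validate_targets(targets: list[ReceptorTarget]) -> None:
    """Check id uniqueness and NBD+DBD completeness of every pair group."""
    seen: set[str] = set()
    for t in targets:
        if t.target_id in seen:
            raise ValueError(f"duplicate target_id {t.target_id!r}")
        seen.add(t.target_id)
    groups: dict[str, set[str]] = {}
    for t in targets:
        groups.setdefault(t.pair_group, set()).add(t.domain_class)
    for g, classes in groups.items():
        missing = set(DOMAIN_CLASSES) - classes
        if missing:
            raise ValueError(f"pair_group {g!r} lacks a "
                             f"{'/'.join(sorted(missing))} target")


def load_target_manifest(path: str | Path) -> list[ReceptorTarget]:
    """Load and validate a receptor manifest (YAML or JSON).

    The manifest is a mapping with a ``targets`` list; each entry declares
    target_id, conformation, domain_class, pair_group, box_center, box_size.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries = data["targets"] if isinstance(data, dict) else data
    targets = []
    for i, e in enumerate(entries):
        try:
            targets.append(ReceptorTarget(
                target_id=e["target_id"],
                conformation=e.get("conformation", e["target_id"]),
                domain_class=e["domain_class"],
                box_center=tuple(float(x) for x in e["box_center"]),
                box_size=tuple(float(x) for x in e["box_size"]),
                pair_group=e["pair_group"],
            ))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: target entry {i}: {exc}") from exc
    validate_targets(targets)
    return targets


# --- docking output parsing -------------------------------------------------

_REMARK_RE = re.compile(r"^REMARK VINA RESULT:\s+(\S+)\s+(\S+)\s+(\S+)")
_LOG_ROW_RE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")


def _ids_from_filename(path: Path, ligand_id, target_id):
    if ligand_id is not None and target_id is not None:
        return ligand_id, target_id
    stem = path.name.rsplit(".", 1)[0]
    if "__" not in stem:
        raise ValueError(
            f"{path}: cannot infer ligand/target ids; name files "
            "'<ligand>__<target>.<ext>' or pass ids explicitly")
    lig, tgt = stem.split("__", 1)
    return ligand_id or lig, target_id or tgt


def parse_vina_output(path: str | Path, dialect: str,
                      ligand_id: str | None = None,
                      target_id: str | None = None) -> list[DockingResult]:
    """Parse one docking output file into :class:`DockingResult` records.

    ``pdbqt-remark`` and ``log-table`` files describe a single ligand×target
    run (ids from the ``<ligand>__<target>.<ext>`` filename convention unless
    given explicitly); ``score-tsv`` files may hold many.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if dialect == "score-tsv":
        return read_score_table(path)

    energies: list[float] = []
    if dialect == "pdbqt-remark":
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            m = _REMARK_RE.match(line)
            if m is None:
                continue
            try:
                energies.append(float(m.group(1)))
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed energy "
                                 f"{m.group(1)!r}") from None
    elif dialect == "log-table":
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            m = _LOG_ROW_RE.match(line)
            if m is not None:
                energies.append(float(m.group(2)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not energies:
        raise ValueError(f"{path}: no docking result lines found")
    lig, tgt = _ids_from_filename(path, ligand_id, target_id)
    return [DockingResult(lig, tgt, tuple(energies))]


def parse_vina_directory(directory: str | Path, dialect: str,
                         pattern: str = "*") -> list[DockingResult]:
    """Parse every matching file in a directory (sorted for determinism)."""
    results: list[DockingResult] = []
    for p in sorted(Path(directory).glob(pattern)):
        if p.is_file():
            results.extend(parse_vina_output(p, dialect))
    return results


def read_score_table(path: str | Path) -> list[DockingResult]:
    """Read a TSV score table (ligand_id, target_id, dg; one row per pose)."""
    path = Path(path)
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: no docking result lines found")
    header = lines[0].rstrip("\n").split("\t")
    try:
        li, ti, di = (header.index(c) for c in ("ligand_id", "target_id", "dg"))
    except ValueError:
        raise ValueError(f"{path}: score table must have ligand_id, "
                         "target_id, dg columns") from None
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        key = (parts[li], parts[ti])
        try:
            dg = float(parts[di])
        except ValueError:
            raise ValueError(f"{path}:{ln}: malformed energy "
                             f"{parts[di]!r}") from None
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(dg)
    if not order:
        raise ValueError(f"{path}: no docking result lines found")
    return [DockingResult(l, t, tuple(grouped[(l, t)])) for l, t in order]


def write_score_table(results: list[DockingResult], path: str | Path) -> None:
    """Write results as a score TSV, one row per pose, re-parseable bit-exactly."""
    with open(Path(path), "w") as fh:
        fh.write("ligand_id\ttarget_id\tdg\n")
        for r in results:
            for dg in r.all_dg:
                fh.write(f"{r.ligand_id}\t{r.target_id}\t{dg!r}\n")


def write_docking_results(results: list[DockingResult], out: str | Path,
                          dialect: str) -> list[Path]:
    """Write results in any dialect; the files re-parse to identical records.

    ``score-tsv`` writes a single file at ``out``; the per-run dialects write
    one ``<ligand>__<target>.<ext>`` file each into the directory ``out``.
    """
    out = Path(out)
    if dialect == "score-tsv":
        write_score_table(results, out)
        return [out]
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in results:
        if dialect == "pdbqt-remark":
            p = out / f"{r.ligand_id}__{r.target_id}.pdbqt"
            with open(p, "w") as fh:
                for i, dg in enumerate(r.all_dg, 1):
                    fh.write(f"MODEL {i}\n")
                    fh.write(f"REMARK VINA RESULT:    {dg!r}      0.000      0.000\n")
                    fh.write("ENDMDL\n")
        elif dialect == "log-table":
            p = out / f"{r.ligand_id}__{r.target_id}.log"
            with open(p, "w") as fh:
                fh.write("mode |   affinity | dist from best mode\n"
                         "     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n"
                         "-----+------------+----------+----------\n")
                for i, dg in enumerate(r.all_dg, 1):
                    fh.write(f"   {i}       {dg!r}      0.000      0.000\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        paths.append(p)
    return paths


# --- mock docking engine ----------------------------------------------------

@dataclass(frozen=True)
class PlantedLandscape:
    """Planted affinity landscape for the mock docking engine.

    Every ligand docks at ``base_dg_dbd`` / ``base_dg_nbd`` on DBD / NBD
    boxes; ligands in ``planted_ids`` additionally get
    ``planted_offset_nbd`` (negative = NBD-preferring) on NBD boxes.
    Gaussian noise of SD ``noise_sd`` kcal/mol is added per ligand×target.
    """

    base_dg_nbd: float = -6.0
    base_dg_dbd: float = -6.0
    planted_ids: frozenset = field(default_factory=frozenset)
    planted_offset_nbd: float = -3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"negative noise_sd {self.noise_sd}")

    def noiseless_dg(self, ligand_id: str, target: ReceptorTarget) -> float:
        base = (self.base_dg_nbd if target.domain_class == "NBD"
                else self.base_dg_dbd)
        if ligand_id in self.planted_ids and target.domain_class == "NBD":
            base += self.planted_offset_nbd
        return base


# Decoy-pose offsets (kcal/mol) above the best pose, so n_modes > 1 and
# best-pose extraction is actually exercised.
_DECOY_OFFSETS = (0.4, 0.9)


def mock_dock(lib: LigandLibrary, targets: list[ReceptorTarget],
              landscape: PlantedLandscape,
              noise_sd: float | None = None,
              seed: int | None = None) -> list[DockingResult]:
    """Deterministic mock docking of every ligand against every target.

    The best pose is ``landscape.noiseless_dg + Normal(0, noise_sd)``; two
    decoy poses sit at fixed offsets above it.  ``noise_sd``/``seed``
    override the landscape's own values when given.
    """
    sd = landscape.noise_sd if noise_sd is None else noise_sd
    if sd < 0:
        raise ValueError(f"negative noise_sd {sd}")
    rng = np.random.default_rng(landscape.seed if seed is None else seed)
    results: list[DockingResult] = []
    for rec in lib.records:
        for tgt in targets:
            # one standard-normal draw per ligand×target regardless of sd,
            # so shrinking the noise converges to the planted landscape
            # without reshuffling the stream
            dg = landscape.noiseless_dg(rec.ligand_id, tgt) + sd * rng.normal()
            poses = (dg,) + tuple(dg + o for o in _DECOY_OFFSETS)
            results.append(DockingResult(rec.ligand_id, tgt.target_id, poses))
    return results
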