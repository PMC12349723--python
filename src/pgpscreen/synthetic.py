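"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here simulates docking physics or chemistry beyond what the pipeline
needs to be tested end to end: molecules are assembled from a small fragment
alphabet (aromatic rings joined by short polar linkers) so that fingerprints
and descriptors are well defined; clusters of similar molecules emulate the
redundancy that diversity subsets exploit; planted affinity landscapes give
some ligands a known NBD preference; and assay generators draw Gaussian
replicate noise around group means implied by a declared ground truth.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .assays import AccumulationSample
from .diversity import DEFAULT_SCHEME, FingerprintScheme, fingerprint, tanimoto
from .docking import (PlantedLandscape, ReceptorTarget, mock_dock,
                      write_docking_results)
from .ligands import LigandLibrary, LigandRecord, compute_properties

__all__ = [
    "PlantedLandscape",
    "AssayGroundTruth",
    "gen_ligand_library",
    "gen_docking_fixtures",
    "gen_assay_data",
    "reference_accumulation_panel",
    "example_target_manifest",
]

# Fragment alphabet. Rings keep the rotatable-bond count near the Veber
# bound; heteroatoms keep logP below 5. Sulfur is excluded so no thiol can
# appear, and carbonyls only occur inside amide units so no aldehyde can.
_RINGS = ("c1ccccc1", "c1ccncc1", "c1ccoc1")
_LINKS = ("C", "CC", "O", "N", "C(=O)N", "CO")
# Edits used to generate within-cluster variants, tried as candidates and
# scored by similarity to the cluster base.
_TAILS = ("C", "CC", "CCC", "N", "O")


def _random_base(rng: np.random.Generator, n_rings: int) -> list[str]:
    parts: list[str] = []
    for i in range(n_rings):
        parts.append(_RINGS[rng.integers(len(_RINGS))])
        if i < n_rings - 1:
            parts.append(_LINKS[rng.integers(len(_LINKS))])
    return parts


def _candidate_edits(base: list[str], rng: np.random.Generator,
                     n_candidates: int = 8) -> list[str]:
    """Candidate variant SMILES of a cluster base molecule."""
    cands: list[str] = []
    for _ in range(n_candidates):
        kind = rng.integers(4)
        parts = list(base)
        if kind == 0:            # append a small tail
            cands.append("".join(parts) + _TAILS[rng.integers(len(_TAILS))])
            continue
        if kind == 1 and len(parts) >= 1:   # swap last ring
            parts[-1] = _RINGS[rng.integers(len(_RINGS))]
        elif kind == 2 and len(parts) >= 2:  # swap last linker
            parts[-2] = _LINKS[rng.integers(len(_LINKS))]
        else:                    # swap an interior unit
            idx = int(rng.integers(len(parts)))
            pool = _RINGS if base[idx] in _RINGS else _LINKS
            parts[idx] = pool[rng.integers(len(pool))]
        cands.append("".join(parts))
    return [c for c in cands if Chem.MolFromSmiles(c) is not None]


def gen_ligand_library(n: int, n_clusters: int,
                       within_cluster_similarity: float = 0.9,
                       seed: int = 0,
                       violator_fraction: float = 0.0,
                       scheme: FingerprintScheme = DEFAULT_SCHEME,
                       ) -> tuple[LigandLibrary, list[int]]:
    """Synthetic ligand library with planted cluster structure.

    Builds ``n_clusters`` base molecules and fills each cluster with
    variants whose Tanimoto similarity to the base is as close as possible
    to ``within_cluster_similarity`` (each variant is the best of several
    candidate edits).  The first member of each cluster is the base
    molecule itself.  ``violator_fraction`` of the molecules get a long
    alkyl tail that pushes them outside the drug-likeness bounds.
    Returns the descriptor-annotated library and per-record cluster labels.
    """
    if not 1 <= n_clusters <= n:
        raise ValueError("need n ≥ n_clusters ≥ 1")
    if not 0.3 <= within_cluster_similarity <= 1.0:
        raise ValueError(
            f"within_cluster_similarity {within_cluster_similarity} "
            "infeasible for this fragment alphabet; use [0.3, 1.0]")
    rng = np.random.default_rng(seed)

    bases = []
    for _ in range(n_clusters):
        while True:
            base = _random_base(rng, int(rng.integers(3, 5)))
            if Chem.MolFromSmiles("".join(base)) is not None:
                bases.append(base)
                break

    # round-robin cluster sizes
    sizes = [n // n_clusters + (1 if i < n % n_clusters else 0)
             for i in range(n_clusters)]

    records: list[LigandRecord] = []
    labels: list[int] = []
    idx = 0
    for c, (base, size) in enumerate(zip(bases, sizes)):
        base_smiles = "".join(base)
        base_fp = fingerprint(base_smiles, scheme)
        for m in range(size):
            if m == 0:
                smiles = base_smiles
            else:
                cands = _candidate_edits(base, rng)
                best, best_gap = base_smiles, 1.0 - within_cluster_similarity
                for cand in cands:
                    s = tanimoto(base_fp, fingerprint(cand, scheme))
                    gap = abs(s - within_cluster_similarity)
                    if gap < best_gap:
                        best, best_gap = cand, gap
                smiles = best
            if violator_fraction > 0 and rng.random() < violator_fraction:
                smiles += "CCCCCCCCCCCC"  # MW/logP/rot-bond violator
            records.append(LigandRecord(ligand_id=f"SYN{idx:05d}",
                                        structure=smiles))
            labels.append(c)
            idx += 1

    lib = LigandLibrary(records, {"sources": [f"synthetic(seed={seed})"],
                                  "filters": []})
    return compute_properties(lib), labels


@dataclass
class AssayGroundTruth:
    """Declared truth behind generated assay datasets.

    Survival percentages are on the vehicle-normalized scale; inhibitors
    drop compound+chemo survival by ``inhibitor_decrease_pp`` percentage
    points below ``chemo_only_survival``.  Substrates accumulate
    ``substrate_fold``-fold more with the reference pump blocker; DAU
    enhancers raise DAU fluorescence by ``dau_fold``.  Replicate noise is
    Gaussian with SD = ``noise_cv`` × group mean.
    """

    compound_ids: list[str]
    inhibitor_ids: set[str] = field(default_factory=set)
    substrate_ids: set[str] = field(default_factory=set)
    dau_enhancer_ids: set[str] = field(default_factory=set)
    chemo_only_survival: float = 90.0
    inhibitor_decrease_pp: float = 50.0
    accumulation_base: float = 1.0
    substrate_fold: float = 3.0
    dau_fold: float = 2.0
    noise_cv: float = 0.10


def gen_docking_fixtures(landscape: PlantedLandscape, lib: LigandLibrary,
                         targets: list[ReceptorTarget], dialect: str,
                         out: str | Path) -> tuple[list[Path], pd.DataFrame]:
    """Write parseable docking outputs plus a noiseless truth table.

    Returns (written paths, truth DataFrame with ligand_id, target_id,
    noiseless_dg, best_dg).
    """
    results = mock_dock(lib, targets, landscape)
    paths = write_docking_results(results, out, dialect)
    truth = pd.DataFrame([
        {"ligand_id": r.ligand_id, "target_id": r.target_id,
         "noiseless_dg": landscape.noiseless_dg(
             r.ligand_id, next(t for t in targets
                               if t.target_id == r.target_id)),
         "best_dg": r.best_dg}
        for r in results])
    return paths, truth


def gen_assay_data(truth: AssayGroundTruth, n_replicates: int = 3,
                   seed: int = 0, outdir: str | Path | None = None,
                   ) -> dict[str, pd.DataFrame]:
    """Generate plate, LC-MS/MS and fluorescence datasets from ground truth.

    Vehicle-control survival is centered at 100%; inhibitors reduce
    compound+chemo survival by the declared effect; substrates show the
    declared +TQR accumulation fold; DAU enhancers the declared
    fluorescence fold.  Deterministic given ``seed``.  When ``outdir`` is
    given the three CSVs are also written there.
    """
    if n_replicates < 3:
        raise ValueError("n_replicates must be ≥ 3")
    rng = np.random.default_rng(seed)
    cv = truth.noise_cv

    def noisy(mean: float, n: int) -> np.ndarray:
        return mean + rng.normal(0.0, abs(mean) * cv, size=n) if cv > 0 \
            else np.full(n, mean)

    # --- MTT plate ---------------------------------------------------------
    plate_rows = []
    well = 0

    def add_wells(treatment: str, compound_id: str | None, mean_abs: float):
        nonlocal well
        for v in noisy(mean_abs, n_replicates):
            plate_rows.append({"well_id": f"W{well:04d}",
                               "cell_line": "resistant",
                               "treatment": treatment,
                               "compound_id": compound_id,
                               "absorbance": float(v)})
            well += 1

    # absorbance scale: vehicle mean 1.0 ⇒ percent survival == 100×absorbance
    add_wells("vehicle", None, 1.0)
    add_wells("chemo-only", None, truth.chemo_only_survival / 100.0)
    for cid in truth.compound_ids:
        surv = truth.chemo_only_survival
        if cid in truth.inhibitor_ids:
            surv -= truth.inhibitor_decrease_pp
        add_wells("compound+chemo", cid, surv / 100.0)
        add_wells("compound-only", cid, 0.98)
    plate = pd.DataFrame(plate_rows)

    # --- LC-MS/MS ----------------------------------------------------------
    lcms_rows = []
    for cid in truth.compound_ids:
        for trial in (1, 2):
            for condition, fold in (("minus_TQR", 1.0),
                                    ("plus_TQR",
                                     truth.substrate_fold
                                     if cid in truth.substrate_ids else 1.0)):
                mean = truth.accumulation_base * fold
                for ratio in noisy(mean, n_replicates):
                    # encode the target normalized ratio with unit IS/lysate
                    lcms_rows.append({
                        "compound_id": cid, "condition": condition,
                        "trial": trial,
                        "analyte_peak": float(max(ratio, 0.0) * 1e5),
                        "is_peak": 1e5, "lysate_mg_per_ml": 1.0})
    lcms = pd.DataFrame(lcms_rows)

    # --- DAU fluorescence --------------------------------------------------
    fluor_rows = []
    base_fluor = 1000.0
    for v in noisy(base_fluor, n_replicates * 3):
        fluor_rows.append({"compound_id": "DAU-alone",
                           "fluorescence": float(v)})
    for cid in truth.compound_ids:
        fold = truth.dau_fold if cid in truth.dau_enhancer_ids else 1.0
        for v in noisy(base_fluor * fold, n_replicates * 3):
            fluor_rows.append({"compound_id": cid, "fluorescence": float(v)})
    fluor = pd.DataFrame(fluor_rows)

    out = {"plate": plate, "lcms": lcms, "fluorescence": fluor}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plate.to_csv(outdir / "plate.csv", index=False,
                     float_format="%.17g")
        lcms.to_csv(outdir / "lcms.csv", index=False,
                    float_format="%.17g")
        fluor.to_csv(outdir / "fluorescence.csv", index=False,
                     float_format="%.17g")
    return out


def reference_accumulation_panel() -> pd.DataFrame:
    """The embedded published LC-MS/MS accumulation summary panel.

    Mean ± SD normalized ratios (n = 3 per group) for daunorubicin and nine
    experimental compounds, ±tariquidar, per independent trial, with the
    p-values as printed alongside the published panel.
    """
    ref = importlib.resources.files("pgpscreen.data") / \
        "lcms_reference_panel.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#", dtype={"compound_id": str,
                                                   "printed_p": str})
    df["indeterminate"] = df["indeterminate"].astype(bool)
    return df


def example_target_manifest() -> list[ReceptorTarget]:
    """A 14-box receptor manifest emulating a multi-conformation design.

    Three transporter conformations along a putative transport cycle
    (open-to-inside, transition, closed-to-inside) each pair one DBD box
    with per-NBD boxes; two extra crystallographic NBD conformations
    contribute additional NBD boxes to the open and closed pair groups,
    and the transition group carries an NBD dimer-interface box.
    """
    spec = [
        # (target_id, conformation, domain, pair_group)
        ("open_dbd", "open", "DBD", "open"),
        ("open_nbd_1", "open", "NBD", "open"),
        ("open_nbd_2", "open", "NBD", "open"),
        ("xtal_a_nbd_1", "xtal_a", "NBD", "open"),
        ("xtal_a_nbd_2", "xtal_a", "NBD", "open"),
        ("transition_dbd", "transition", "DBD", "transition"),
        ("transition_nbd_1", "transition", "NBD", "transition"),
        ("transition_nbd_2", "transition", "NBD", "transition"),
        ("transition_nbd_dimer", "transition", "NBD", "transition"),
        ("closed_dbd", "closed", "DBD", "closed"),
        ("closed_nbd_1", "closed", "NBD", "closed"),
        ("closed_nbd_2", "closed", "NBD", "closed"),
        ("xtal_b_nbd_1", "xtal_b", "NBD", "closed"),
        ("xtal_b_nbd_2", "xtal_b", "NBD", "closed"),
    ]
    return [ReceptorTarget(tid, conf, dom,
                           box_center=(float(10 * i), 0.0, 0.0),
                           box_size=(30.0, 30.0, 30.0), pair_group=pg)
            for i, (tid, conf, dom, pg) in enumerate(spec)]
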