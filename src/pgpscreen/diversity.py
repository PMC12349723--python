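"""Fingerprints, Tanimoto similarity, diversity subsets, similarity-band expansion.

Libraries of millions of molecules are made tractable for multi-receptor
docking by screening a chemically diverse subset instead of everything.  The
subset is built by sphere exclusion (the leader algorithm): walk the library
in a fixed order and retain a molecule only if its Tanimoto similarity to
every previously retained molecule is at or below a cutoff.  Excluded
molecules are assigned to the first retained molecule that covers them, which
is how promising hits are later expanded back out: a similarity band query
pulls every pool molecule within, e.g., 70–99% similarity of a top hit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem

from .ligands import LigandLibrary, LigandRecord

__all__ = [
    "FingerprintScheme",
    "Fingerprint",
    "fingerprint",
    "tanimoto",
    "DiversitySubset",
    "diversity_subset",
    "similarity_expand",
]


@dataclass(frozen=True)
class FingerprintScheme:
    """Hashed circular substructure fingerprint specification."""

    name: str = "morgan"
    radius: int = 2
    n_bits: int = 2048

    @property
    def label(self) -> str:
        return f"{self.name}-r{self.radius}-{self.n_bits}"


DEFAULT_SCHEME = FingerprintScheme()


@dataclass
class Fingerprint:
    """Fixed-length bit vector for one ligand under a declared scheme."""

    ligand_id: str
    bits: DataStructs.ExplicitBitVect
    scheme: FingerprintScheme = DEFAULT_SCHEME

    @classmethod
    def from_on_bits(cls, ligand_id: str, on_bits, n_bits: int = 2048,
                     scheme: FingerprintScheme | None = None) -> "Fingerprint":
        """Build a fingerprint from explicit on-bit indices (testing aid)."""
        bv = DataStructs.ExplicitBitVect(n_bits)
        for b in on_bits:
            bv.SetBit(int(b))
        sch = scheme or FingerprintScheme(name="explicit", radius=0,
                                          n_bits=n_bits)
        return cls(ligand_id, bv, sch)


def _mol_fp(structure: str, scheme: FingerprintScheme):
    mol = Chem.MolFromSmiles(structure)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable structure: {structure!r}")
    return AllChem.GetMorganFingerprintAsBitVect(mol, scheme.radius,
                                                 nBits=scheme.n_bits)


def fingerprint(record: LigandRecord | str,
                scheme: FingerprintScheme = DEFAULT_SCHEME,
                ligand_id: str | None = None) -> Fingerprint:
    """Deterministic circular fingerprint of one ligand.

    Accepts a :class:`LigandRecord` or a bare SMILES string (with an optional
    explicit ``ligand_id``).  Raises ``ValueError`` naming the ligand if the
    structure does not parse.
    """
    if isinstance(record, LigandRecord):
        smiles, lid = record.structure, record.ligand_id
    else:
        smiles, lid = record, (ligand_id or record)
    try:
        bv = _mol_fp(smiles, scheme)
    except ValueError:
        raise ValueError(f"cannot fingerprint ligand {lid!r}: "
                         f"unparseable structure {smiles!r}") from None
    return Fingerprint(lid, bv, scheme)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| in [0, 1].

    Two all-zero fingerprints are defined as identical (similarity 1.0):
    featureless molecules are treated as mutually redundant.
    """
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: "
                         f"{a.scheme.label} vs {b.scheme.label}")
    if a.bits.GetNumOnBits() == 0 and b.bits.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


@dataclass
class DiversitySubset:
    """Result of a sphere-exclusion pass.

    ``retained_ids`` preserve pass order; every excluded ligand maps to the
    first retained ligand whose similarity to it exceeds the cutoff.
    """

    retained_ids: list[str]
    cutoff: float
    assignment: dict[str, str] = field(default_factory=dict)
    similarities: dict[str, float] = field(default_factory=dict)
    order_seed: int | None = None
    scheme: FingerprintScheme = DEFAULT_SCHEME


def _library_fingerprints(lib: LigandLibrary, scheme: FingerprintScheme):
    return [fingerprint(r, scheme) for r in lib.records]


def diversity_subset(lib: LigandLibrary, cutoff: float,
                     order_seed: int | None = None,
                     scheme: FingerprintScheme = DEFAULT_SCHEME,
                     ) -> DiversitySubset:
    """Greedy sphere-exclusion (leader) diversity subset at ``cutoff``.

    Ligands are visited in input order, or in a seeded shuffle when
    ``order_seed`` is given; a ligand is retained iff its similarity to every
    previously retained ligand is ≤ cutoff.  Deterministic given
    (library, cutoff, order_seed).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    fps = _library_fingerprints(lib, scheme)
    order = list(range(len(fps)))
    if order_seed is not None:
        random.Random(order_seed).shuffle(order)

    retained: list[int] = []
    assignment: dict[str, str] = {}
    sims: dict[str, float] = {}
    for i in order:
        fp_i = fps[i]
        rep = None
        rep_sim = 0.0
        for j in retained:
            s = tanimoto(fp_i, fps[j])
            if s > cutoff:
                rep, rep_sim = fps[j].ligand_id, s
                break
        if rep is None:
            retained.append(i)
        else:
            assignment[fp_i.ligand_id] = rep
            sims[fp_i.ligand_id] = rep_sim
    return DiversitySubset(
        retained_ids=[fps[i].ligand_id for i in retained],
        cutoff=cutoff, assignment=assignment, similarities=sims,
        order_seed=order_seed, scheme=scheme)


def similarity_expand(queries, pool: LigandLibrary,
                      band: tuple[float, float] = (0.70, 0.99),
                      scheme: FingerprintScheme = DEFAULT_SCHEME,
                      ) -> dict[str, list[tuple[str, float]]]:
    """Pool neighbors of each query within an inclusive similarity band.

    For each query ligand, returns every pool ligand (excluding the query
    itself, by id) with ``low ≤ tanimoto ≤ high``, ordered by descending
    similarity with ties broken by ligand_id.  ``queries`` is an iterable of
    :class:`LigandRecord`.
    """
    low, high = band
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError(f"invalid similarity band {band}")
    if len(pool) == 0:
        import warnings
        warnings.warn("similarity_expand: empty pool", stacklevel=2)
        return {q.ligand_id: [] for q in queries}

    pool_fps = _library_fingerprints(pool, scheme)
    out: dict[str, list[tuple[str, float]]] = {}
    for q in queries:
        qfp = fingerprint(q, scheme)
        hits = []
        for pfp in pool_fps:
            if pfp.ligand_id == qfp.ligand_id:
                continue
            s = tanimoto(qfp, pfp)
            if low <= s <= high:
                hits.append((pfp.ligand_id, s))
        hits.sort(key=lambda t: (-t[1], t[0]))
        out[qfp.ligand_id] = hits
    return out
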