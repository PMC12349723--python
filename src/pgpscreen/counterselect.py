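"""Counter-selective ranking: ΔG → K_D, DBD/NBD ratios, two-round screening.

The screen looks for ligands predicted to bind the transporter's cytoplasmic
nucleotide binding domains (NBDs) while *not* binding the transmembrane drug
binding domains (DBDs), because DBD binders tend to be transport substrates
of the pump itself.  Docking energies are converted to estimated dissociation
constants via

    ΔG = R·T·ln(K_D)      (R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T = 310 K)

so K_D = exp(ΔG/RT), dimensionless relative to a 1 M standard state.  For
each receptor conformation pair the counter-selection ratio

    ratio = K_D^DBD / K_D^NBD = exp((ΔG^DBD − ΔG^NBD)/RT)

is large when the ligand is predicted to bind the NBDs tightly (small
K_D^NBD) and the DBDs weakly (large K_D^DBD).  Per-pair ratios are
aggregated across conformations (default: the minimum, i.e. the ligand must
prefer the NBDs in *every* conformation) and ligands are ranked by the
aggregate.  A two-round screen docks a diversity subset first, then expands
the top hits back into the full library through a chemical-similarity band
and re-docks the expansion.

K_D values here are estimates used only for ratio ranking, never as binding
affinity claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .diversity import FingerprintScheme, DEFAULT_SCHEME, diversity_subset, \
    similarity_expand
from .docking import DockingResult, ReceptorTarget
from .ligands import LigandLibrary

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BODY_TEMPERATURE_K",
    "AffinityEstimate",
    "RatioScore",
    "ScreenRanking",
    "ScreenOutcome",
    "kd_from_dg",
    "ratio_score",
    "aggregate_ratios",
    "score_ligands",
    "rank_and_select",
    "iterate_screen",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal·mol⁻¹·K⁻¹
BODY_TEMPERATURE_K = 310.0


def kd_from_dg(dg: float, temperature: float = BODY_TEMPERATURE_K,
               gas_constant: float = GAS_CONSTANT_KCAL) -> float:
    """Estimated dissociation constant (molar, 1 M standard state) from ΔG.

    Inverts ΔG = RT·ln(K_D); strictly increasing in ΔG, K_D(0) = 1.
    """
    if not math.isfinite(dg):
        raise ValueError(f"non-finite dg {dg}")
    if temperature <= 0:
        raise ValueError(f"non-positive temperature {temperature}")
    return math.exp(dg / (gas_constant * temperature))


@dataclass(frozen=True)
class AffinityEstimate:
    """Best docking energy and derived K_D for one ligand×target."""

    ligand_id: str
    target_id: str
    dg: float
    temperature: float = BODY_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL
    pair_group: str | None = None
    domain_class: str | None = None

    @property
    def kd(self) -> float:
        return kd_from_dg(self.dg, self.temperature, self.gas_constant)


def ratio_score(dbd: AffinityEstimate, nbd: AffinityEstimate) -> float:
    """Counter-selection ratio K_D^DBD / K_D^NBD for one receptor pair.

    Computed as exp((ΔG^DBD − ΔG^NBD)/RT) — depends only on the energy
    difference, so adding a common constant to both energies is a no-op.
    Ratio > 1 means tighter predicted NBD binding.
    """
    if dbd.ligand_id != nbd.ligand_id:
        raise ValueError(f"ligand mismatch: {dbd.ligand_id!r} vs "
                         f"{nbd.ligand_id!r}")
    if (dbd.temperature, dbd.gas_constant) != (nbd.temperature,
                                               nbd.gas_constant):
        raise ValueError("temperature/gas-constant mismatch between estimates")
    if dbd.pair_group is not None and nbd.pair_group is not None \
            and dbd.pair_group != nbd.pair_group:
        raise ValueError(f"pair_group mismatch: {dbd.pair_group!r} vs "
                         f"{nbd.pair_group!r}")
    rt = dbd.gas_constant * dbd.temperature
    return math.exp((dbd.dg - nbd.dg) / rt)


def aggregate_ratios(per_pair: dict[str, float], policy: str = "min",
                     missing_pairs: int = 0,
                     missing: str = "zero") -> float:
    """Aggregate per-pair ratios into one score.

    ``min`` is conservative — the ligand must prefer the NBDs in every
    conformation; ``geometric-mean`` is exp(mean(log ratios)).  Under the
    min policy, ``missing_pairs`` > 0 scores 0 unless ``missing='skip'``.
    """
    if not per_pair:
        raise ValueError("no per-pair ratios to aggregate")
    if policy == "min":
        if missing_pairs > 0 and missing == "zero":
            return 0.0
        return min(per_pair.values())
    if policy == "geometric-mean":
        return math.exp(sum(math.log(r) for r in per_pair.values())
                        / len(per_pair))
    raise ValueError(f"unknown aggregation policy {policy!r}")


@dataclass
class RatioScore:
    """Per-pair counter-selection ratios and their aggregate for one ligand."""

    ligand_id: str
    per_pair: dict[str, float]
    aggregate: float
    policy: str = "min"
    missing_pairs: int = 0


@dataclass
class ScreenRanking:
    """Deterministically ordered selection of ligands by aggregate ratio."""

    entries: list[RatioScore]  # aggregate desc, ties by ligand_id asc
    selection_size: int
    round_label: str = "round1"

    def ids(self) -> list[str]:
        return [e.ligand_id for e in self.entries]


def score_ligands(results: Sequence[DockingResult],
                  targets: Sequence[ReceptorTarget],
                  temperature: float = BODY_TEMPERATURE_K,
                  gas_constant: float = GAS_CONSTANT_KCAL,
                  policy: str = "min",
                  missing: str = "zero") -> list[RatioScore]:
    """Turn docking results into per-ligand counter-selection ratio scores.

    Within each pair group the tightest (minimum) best-pose ΔG per domain
    class is used, so a conformation with several NBD boxes contributes its
    best NBD energy.  A ligand missing either domain of a pair group gets no
    ratio for it; under the min policy any missing pair zeroes the aggregate
    (the ligand drops out of top-n contention).
    """
    by_target = {t.target_id: t for t in targets}
    groups = sorted({t.pair_group for t in targets})

    # ligand -> pair_group -> domain_class -> best dg
    best: dict[str, dict[str, dict[str, float]]] = {}
    order: list[str] = []
    for r in results:
        tgt = by_target.get(r.target_id)
        if tgt is None:
            raise ValueError(f"docking result for unknown target "
                             f"{r.target_id!r}")
        if r.ligand_id not in best:
            order.append(r.ligand_id)
        lig = best.setdefault(r.ligand_id, {})
        dom = lig.setdefault(tgt.pair_group, {})
        prev = dom.get(tgt.domain_class)
        if prev is None or r.best_dg < prev:
            dom[tgt.domain_class] = r.best_dg

    scores: list[RatioScore] = []
    for lid in order:
        per_pair: dict[str, float] = {}
        missing_pairs = 0
        for g in groups:
            dom = best[lid].get(g, {})
            if "DBD" in dom and "NBD" in dom:
                dbd = AffinityEstimate(lid, f"{g}:DBD", dom["DBD"],
                                       temperature, gas_constant, g, "DBD")
                nbd = AffinityEstimate(lid, f"{g}:NBD", dom["NBD"],
                                       temperature, gas_constant, g, "NBD")
                per_pair[g] = ratio_score(dbd, nbd)
            else:
                missing_pairs += 1
        if not per_pair:
            scores.append(RatioScore(lid, {}, 0.0, policy, missing_pairs))
            continue
        agg = aggregate_ratios(per_pair, policy, missing_pairs, missing)
        scores.append(RatioScore(lid, per_pair, agg, policy, missing_pairs))
    return scores


def rank_and_select(scores: Sequence[RatioScore], n: int = 100,
                    round_label: str = "round1") -> ScreenRanking:
    """Top-n ligands by aggregate (descending), ties by ligand_id ascending."""
    if n < 1:
        raise ValueError(f"selection size must be ≥ 1, got {n}")
    ordered = sorted(scores, key=lambda s: (-s.aggregate, s.ligand_id))
    if n > len(ordered):
        import warnings
        warnings.warn(f"requested top {n} of only {len(ordered)} scored "
                      "ligands; returning all", stacklevel=2)
        n = len(ordered)
    return ScreenRanking(ordered[:n], selection_size=n,
                         round_label=round_label)


@dataclass
class ScreenOutcome:
    """Rankings and provenance of a two-round iterative screen."""

    round1: ScreenRanking
    round2: ScreenRanking | None
    merged: ScreenRanking
    provenance: dict = field(default_factory=dict)


DockSource = Callable[[LigandLibrary, Sequence[ReceptorTarget]],
                      list[DockingResult]]


def iterate_screen(lib: LigandLibrary,
                   targets: Sequence[ReceptorTarget],
                   dock_source: DockSource,
                   cutoff: float = 0.95,
                   band: tuple[float, float] = (0.70, 0.99),
                   n_top: int = 100,
                   policy: str = "min",
                   order_seed: int | None = None,
                   temperature: float = BODY_TEMPERATURE_K,
                   scheme: FingerprintScheme = DEFAULT_SCHEME,
                   ) -> ScreenOutcome:
    """Two-round counter-selective screen over a ligand library.

    Round 1: sphere-exclusion diversity subset at ``cutoff`` → dock → ratio
    scores → top ``n_top``.  Round 2: expand the top hits into the full
    library through the inclusive similarity ``band``, dock the (previously
    undocked) expansion, and rank it.  The merged ranking deduplicates by
    ligand_id keeping each ligand's best aggregate; round-2 scores never
    overwrite round-1 scores.
    """
    subset = diversity_subset(lib, cutoff, order_seed=order_seed,
                              scheme=scheme)
    round1_lib = lib.subset(subset.retained_ids)
    r1_results = dock_source(round1_lib, list(targets))
    r1_scores = score_ligands(r1_results, targets, temperature=temperature,
                              policy=policy)
    round1 = rank_and_select(r1_scores, n_top, "round1")

    top_records = [lib.get(lid) for lid in round1.ids()]
    neighbors = similarity_expand(top_records, lib, band, scheme)
    docked_r1 = set(round1_lib.ids())
    expansion_ids: list[str] = []
    seen: set[str] = set()
    for q in round1.ids():
        for nid, _sim in neighbors[q]:
            if nid not in seen and nid not in docked_r1:
                seen.add(nid)
                expansion_ids.append(nid)

    round2 = None
    r2_scores: list[RatioScore] = []
    if expansion_ids:
        round2_lib = lib.subset(expansion_ids)
        r2_results = dock_source(round2_lib, list(targets))
        r2_scores = score_ligands(r2_results, targets,
                                  temperature=temperature, policy=policy)
        round2 = rank_and_select(r2_scores, min(n_top, len(r2_scores)),
                                 "round2")

    merged_best: dict[str, RatioScore] = {}
    for s in r1_scores + r2_scores:
        cur = merged_best.get(s.ligand_id)
        if cur is None or s.aggregate > cur.aggregate:
            merged_best[s.ligand_id] = s
    merged = rank_and_select(list(merged_best.values()),
                             min(n_top, len(merged_best)), "merged")

    provenance = {
        "library_size": len(lib),
        "cutoff": cutoff,
        "order_seed": order_seed,
        "subset_size": len(subset.retained_ids),
        "band": list(band),
        "n_top": n_top,
        "policy": policy,
        "temperature_K": temperature,
        "fingerprint_scheme": scheme.label,
        "expansion_size": len(expansion_ids),
        "expansion_per_query": {q: len(neighbors[q]) for q in round1.ids()},
        "docked_total": len(r1_results) + (len(expansion_ids) * len(targets)
                                           if expansion_ids else 0),
    }
    return ScreenOutcome(round1, round2, merged, provenance)
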