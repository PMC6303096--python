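"""Per-species metrics and diagnosability classification.

All distances at this layer are expressed in percent (substitutions/site
x 100), matching how barcode studies report them.

Classification rules:

* a non-singleton species is *monophyletic* iff its specimens form a clade
  of the midpoint-rooted tree (equivalently, whenever the root falls
  between species, iff some edge of the unrooted tree induces a
  bipartition with exactly its specimens on one side);
* otherwise, on the same rooted tree, it is *paraphyletic* iff the
  foreign leaves inside the smallest clade containing it form a single
  clade (so that pruning that clade restores monophyly), else
  *polyphyletic*;
* a *shared barcode* is a K2P distance of exactly zero to a heterospecific
  record (pairwise deletion, not string equality);
* *cluster-diagnostic*: monophyletic with no shared barcode, or a singleton
  whose nearest neighbor is at non-zero distance;
* *haplotype-diagnostic*: no shared barcode, regardless of monophyly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .distance import DistanceMatrix, k2p_distance
from .errors import (
    EmptyInputError,
    TreeLibraryMismatchError,
    UndefinedDistanceError,
)
from .library_io import ReferenceLibrary
from .tree import Tree
from .util import round_half_up

logger = logging.getLogger(__name__)

MONO_CLASSES = ("monophyletic", "paraphyletic", "polyphyletic", "singleton")
DEFAULT_CRYPTIC_THRESHOLDS = (2.0, 3.0)
DEFAULT_ID_THRESHOLD = 2.0


# ----------------------------------------------------------------------
# intraspecific stats
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class IntraStats:
    max_intra: Optional[float]  # percent; None for singletons
    mean_intra: Optional[float]
    n_undefined_pairs: int = 0


def intraspecific_stats(
    dm: DistanceMatrix, lib: ReferenceLibrary
) -> Dict[str, IntraStats]:
    """Max and mean K2P distance over all unordered conspecific pairs."""
    out: Dict[str, IntraStats] = {}
    for species, ids in lib.species_index.items():
        if len(ids) < 2:
            out[species] = IntraStats(None, None)
            continue
        vals: List[float] = []
        n_undef = 0
        for i in range(len(ids) - 1):
            for j in range(i + 1, len(ids)):
                d = dm.get(ids[i], ids[j])
                if d is None:
                    n_undef += 1
                else:
                    vals.append(100.0 * d)
        if n_undef:
            logger.warning(
                "species %s: %d undefined conspecific pair(s); stats over "
                "defined pairs only", species, n_undef,
            )
        if not vals:
            out[species] = IntraStats(None, None, n_undef)
        else:
            out[species] = IntraStats(max(vals), sum(vals) / len(vals), n_undef)
    return out


# ----------------------------------------------------------------------
# nearest neighbor / shared barcodes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborResult:
    nearest_neighbor: str  # primary (lexicographically first among ties)
    nn_distance: float  # percent
    tied_species: Tuple[str, ...]  # all species attaining the minimum
    shares_barcode_with: FrozenSet[str]  # heterospecific species at d == 0


def nearest_neighbor(
    dm: DistanceMatrix, lib: ReferenceLibrary
) -> Dict[str, NeighborResult]:
    """Per species: minimum heterospecific distance and zero-distance sharers."""
    if len(lib.species_index) < 2:
        raise ValueError("nearest-neighbor analysis requires >= 2 species")
    idx = {lbl: dm.index(lbl) for lbl in dm.labels}
    species_of = {r.specimen_id: r.species for r in lib.records}
    out: Dict[str, NeighborResult] = {}
    for species, ids in lib.species_index.items():
        best = np.inf
        attained: Dict[str, float] = {}
        shares = set()
        any_defined = False
        for sid in ids:
            row = dm.values[idx[sid]]
            for other_id, other_species in species_of.items():
                if other_species == species:
                    continue
                d = row[idx[other_id]]
                if np.isnan(d):
                    continue
                any_defined = True
                d_pct = 100.0 * float(d)
                if d == 0.0:
                    shares.add(other_species)
                if d_pct < best - 1e-12:
                    best = d_pct
                    attained = {other_species: d_pct}
                elif d_pct <= best + 1e-12:
                    attained[other_species] = min(
                        attained.get(other_species, d_pct), d_pct
                    )
        if not any_defined:
            raise UndefinedDistanceError(
                f"species {species}: every heterospecific distance is undefined"
            )
        tied = tuple(sorted(attained))
        out[species] = NeighborResult(
            nearest_neighbor=tied[0],
            nn_distance=best,
            tied_species=tied,
            shares_barcode_with=frozenset(shares),
        )
    return out


# ----------------------------------------------------------------------
# monophyly
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyResult:
    status: str  # one of MONO_CLASSES
    entangled_with: FrozenSet[str]  # species whose specimens interleave


def classify_monophyly(
    tree: Tree, lib: ReferenceLibrary, rooted: Optional[Tree] = None
) -> Dict[str, MonophylyResult]:
    """Classify every species on the tree.

    ``rooted`` may supply a pre-computed midpoint rooting; otherwise one is
    derived internally for the paraphyly/polyphyly distinction.
    """
    from .nj_tree import midpoint_root

    tree_leaves = set(tree.leaf_names())
    lib_ids = {r.specimen_id for r in lib.records}
    if tree_leaves != lib_ids:
        raise TreeLibraryMismatchError(
            f"tree/library leaf mismatch: {len(tree_leaves ^ lib_ids)} "
            "id(s) differ"
        )
    species_of = {r.specimen_id: r.species for r in lib.records}
    all_leaves = frozenset(tree_leaves)

    if rooted is None:
        rooted = midpoint_root(tree)
    clade_sets = set(rooted.leaf_sets().values())
    clade_sets.add(all_leaves)

    out: Dict[str, MonophylyResult] = {}
    for species, ids in lib.species_index.items():
        members = frozenset(ids)
        if len(members) == 1:
            out[species] = MonophylyResult("singleton", frozenset())
            continue
        if len(all_leaves - members) <= 1 or members in clade_sets:
            out[species] = MonophylyResult("monophyletic", frozenset())
            continue
        mrca = min(
            (s for s in clade_sets if members <= s), key=len
        )
        foreign = mrca - members
        foreign_species = frozenset(species_of[lid] for lid in foreign)
        foreign_mrca = min(
            (s for s in clade_sets if foreign <= s), key=len
        )
        # paraphyletic only when the intruders form one prunable clade
        if foreign_mrca == foreign:
            status = "paraphyletic"
        else:
            status = "polyphyletic"
        out[species] = MonophylyResult(status, foreign_species)
    return out


# ----------------------------------------------------------------------
# assessments
# ----------------------------------------------------------------------

@dataclass
class SpeciesAssessment:
    species: str
    n_specimens: int
    max_intra: Optional[float]
    mean_intra: Optional[float]
    nearest_neighbor: str
    nn_distance: float
    nn_tied_species: Tuple[str, ...]
    shares_barcode_with: FrozenSet[str]
    monophyly: str
    entangled_with: FrozenSet[str]
    cluster_diagnostic: bool
    haplotype_diagnostic: bool
    cryptic_flags: Dict[float, bool] = field(default_factory=dict)

    @property
    def cryptic_flag_2pct(self) -> bool:
        return self.cryptic_flags.get(2.0, False)

    @property
    def cryptic_flag_3pct(self) -> bool:
        return self.cryptic_flags.get(3.0, False)


def diagnosability(
    monophyly: Dict[str, MonophylyResult],
    neighbors: Dict[str, NeighborResult],
) -> Dict[str, Tuple[bool, bool]]:
    """(cluster_diagnostic, haplotype_diagnostic) per species."""
    out: Dict[str, Tuple[bool, bool]] = {}
    for species, mono in monophyly.items():
        nb = neighbors[species]
        shares = bool(nb.shares_barcode_with)
        haplo = not shares
        if mono.status == "singleton":
            cluster = not shares and nb.nn_distance > 0.0
        else:
            cluster = mono.status == "monophyletic" and not shares
        out[species] = (cluster, haplo)
    return out


def cryptic_flags(
    intra: Dict[str, IntraStats],
    thresholds: Sequence[float] = DEFAULT_CRYPTIC_THRESHOLDS,
) -> Dict[str, Dict[float, bool]]:
    """Flag species with max intraspecific divergence strictly over each
    threshold (percent). Singletons are never flagged."""
    out: Dict[str, Dict[float, bool]] = {}
    for species, st in intra.items():
        out[species] = {
            float(t): (st.max_intra is not None and st.max_intra > t)
            for t in thresholds
        }
    return out


@dataclass
class AuditReport:
    assessments: Dict[str, SpeciesAssessment]
    params: Dict[str, object]

    @property
    def n_species(self) -> int:
        return len(self.assessments)

    def count(self, status: str) -> int:
        return sum(1 for a in self.assessments.values() if a.monophyly == status)

    def summary(self) -> Dict[str, object]:
        n = self.n_species
        multis = [
            a.max_intra
            for a in self.assessments.values()
            if a.max_intra is not None
        ]
        thresholds = self.params.get("cryptic_thresholds", DEFAULT_CRYPTIC_THRESHOLDS)
        counts = {status: self.count(status) for status in MONO_CLASSES}
        summary = {
            "n_species": n,
            "n_specimens": sum(a.n_specimens for a in self.assessments.values()),
            "monophyly_counts": counts,
            "monophyly_percent": {k: 100.0 * v / n for k, v in counts.items()},
            "n_cluster_diagnostic": sum(
                a.cluster_diagnostic for a in self.assessments.values()
            ),
            "n_haplotype_diagnostic": sum(
                a.haplotype_diagnostic for a in self.assessments.values()
            ),
            "mean_max_intra": (sum(multis) / len(multis)) if multis else None,
            "mean_nn_distance": sum(
                a.nn_distance for a in self.assessments.values()
            ) / n,
            "cryptic_counts": {
                str(t): sum(
                    a.cryptic_flags.get(float(t), False)
                    for a in self.assessments.values()
                )
                for t in thresholds
            },
        }
        summary["cluster_diagnostic_percent"] = (
            100.0 * summary["n_cluster_diagnostic"] / n
        )
        summary["haplotype_diagnostic_percent"] = (
            100.0 * summary["n_haplotype_diagnostic"] / n
        )
        return summary

    def to_json(self) -> str:
        def ser(x):
            if isinstance(x, float):
                return round_half_up(x, 4)
            return x

        summary = self.summary()
        payload = {
            "schema_version": 1,
            "params": self.params,
            "summary": json.loads(
                json.dumps(summary, default=str),
                parse_float=lambda s: round_half_up(float(s), 4),
            ),
            "species": {
                sp: {
                    "n_specimens": a.n_specimens,
                    "max_intra": ser(a.max_intra),
                    "mean_intra": ser(a.mean_intra),
                    "nearest_neighbor": a.nearest_neighbor,
                    "nn_distance": ser(a.nn_distance),
                    "nn_tied_species": list(a.nn_tied_species),
                    "shares_barcode_with": sorted(a.shares_barcode_with),
                    "monophyly": a.monophyly,
                    "entangled_with": sorted(a.entangled_with),
                    "cluster_diagnostic": a.cluster_diagnostic,
                    "haplotype_diagnostic": a.haplotype_diagnostic,
                    "cryptic_flags": {
                        str(t): v for t, v in sorted(a.cryptic_flags.items())
                    },
                }
                for sp, a in sorted(self.assessments.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_tsv(self, path) -> None:
        cols = [
            "species", "n_specimens", "max_intra", "mean_intra",
            "nearest_neighbor", "nn_distance", "shares_barcode_with",
            "monophyly", "cluster_diagnostic", "haplotype_diagnostic",
        ]
        thresholds = sorted(
            {t for a in self.assessments.values() for t in a.cryptic_flags}
        )
        cols += [f"cryptic_over_{t:g}pct" for t in thresholds]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for sp in sorted(self.assessments):
                a = self.assessments[sp]
                row = [
                    a.species,
                    str(a.n_specimens),
                    "" if a.max_intra is None else f"{a.max_intra:.2f}",
                    "" if a.mean_intra is None else f"{a.mean_intra:.2f}",
                    a.nearest_neighbor,
                    f"{a.nn_distance:.2f}",
                    ";".join(sorted(a.shares_barcode_with)),
                    a.monophyly,
                    str(a.cluster_diagnostic),
                    str(a.haplotype_diagnostic),
                ]
                row += [str(a.cryptic_flags.get(t, False)) for t in thresholds]
                fh.write("\t".join(row) + "\n")


def audit_library(
    lib: ReferenceLibrary,
    dm: Optional[DistanceMatrix] = None,
    tree: Optional[Tree] = None,
    *,
    min_overlap: int = 100,
    cryptic_thresholds: Sequence[float] = DEFAULT_CRYPTIC_THRESHOLDS,
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> AuditReport:
    """Run the full per-species audit, computing any missing inputs."""
    from .distance import distance_matrix
    from .nj_tree import bootstrap_support, midpoint_root, nj_build

    if dm is None:
        dm = distance_matrix(lib, min_overlap=min_overlap)
    if tree is None:
        if bootstrap_replicates > 0:
            tree = bootstrap_support(
                lib, replicates=bootstrap_replicates, seed=seed,
                min_overlap=min_overlap,
            )
        else:
            tree = nj_build(dm)

    intra = intraspecific_stats(dm, lib)
    neighbors = nearest_neighbor(dm, lib)
    rooted = midpoint_root(tree) if tree.n_leaves() >= 2 else None
    mono = classify_monophyly(tree, lib, rooted=rooted)
    diag = diagnosability(mono, neighbors)
    cryptic = cryptic_flags(intra, cryptic_thresholds)

    assessments = {}
    for species, ids in lib.species_index.items():
        nb = neighbors[species]
        cluster, haplo = diag[species]
        assessments[species] = SpeciesAssessment(
            species=species,
            n_specimens=len(ids),
            max_intra=intra[species].max_intra,
            mean_intra=intra[species].mean_intra,
            nearest_neighbor=nb.nearest_neighbor,
            nn_distance=nb.nn_distance,
            nn_tied_species=nb.tied_species,
            shares_barcode_with=nb.shares_barcode_with,
            monophyly=mono[species].status,
            entangled_with=mono[species].entangled_with,
            cluster_diagnostic=cluster,
            haplotype_diagnostic=haplo,
            cryptic_flags=cryptic[species],
        )
    params = {
        "min_overlap": min_overlap,
        "cryptic_thresholds": [float(t) for t in cryptic_thresholds],
        "bootstrap_replicates": bootstrap_replicates,
        "seed": seed,
    }
    return AuditReport(assessments=assessments, params=params)


# ----------------------------------------------------------------------
# query identification
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class IdentificationResult:
    status: str  # "match" | "ambiguous" | "no_match"
    species: Tuple[str, ...]
    distance: Optional[float]  # percent, distance to nearest reference


def identify_query(
    query: str,
    lib: ReferenceLibrary,
    threshold: float = DEFAULT_ID_THRESHOLD,
    tie_margin: float = 0.0,
    min_overlap: int = 100,
) -> IdentificationResult:
    """Assign a query sequence to the species of its nearest reference.

    The nearest species wins when its distance is <= ``threshold`` percent
    and no second species lies within ``tie_margin`` percentage points of
    it; otherwise the result is "ambiguous" (tied species listed) or
    "no_match".
    """
    if len(lib) == 0:
        raise EmptyInputError("reference library is empty")
    best_by_species: Dict[str, float] = {}
    for r in lib.records:
        cmp = k2p_distance(query, r.sequence, min_overlap=min_overlap)
        if cmp.d is None:
            continue
        d_pct = 100.0 * cmp.d
        if r.species not in best_by_species or d_pct < best_by_species[r.species]:
            best_by_species[r.species] = d_pct
    if not best_by_species:
        return IdentificationResult("no_match", (), None)
    nearest = min(best_by_species.values())
    if nearest > threshold:
        return IdentificationResult("no_match", (), nearest)
    tied = tuple(
        sorted(s for s, d in best_by_species.items() if d <= nearest + tie_margin)
    )
    if len(tied) == 1:
        return IdentificationResult("match", tied, nearest)
    return IdentificationResult("ambiguous", tied, nearest)
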