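"""Integrative identification rates from confusability graphs.

A species is "difficult" under an evidence channel (barcode, male
morphology, female morphology) if it carries at least one confusion edge;
the "always possible" rate is (n - |difficult|)/n over the sequenced
species universe. Integrated channels intersect edge sets (a species pair
must be confusable under *both* channels to remain difficult), so the
integrated rate is always >= each parent channel's rate.

Morphology-difficulty annotations are expert input, not computable; they
ship as an editable packaged TSV fixture alongside the list of
barcode-problematic species groups for the Swiss diurnal Lepidoptera
library the package was validated against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .species_audit import AuditReport
from .util import round_half_up

Edge = FrozenSet[str]

CHANNELS = (
    "barcode",
    "morphology_male",
    "morphology_female",
    "integrated_male",
    "integrated_female",
)


@dataclass(frozen=True)
class ConfusabilityGraph:
    """Undirected graph over species; an edge means the pair is confusable
    under one evidence channel."""

    edges: FrozenSet[Edge]

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge must join two distinct species: {set(e)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "ConfusabilityGraph":
        return cls(frozenset(frozenset(p) for p in pairs))

    @classmethod
    def from_groups(cls, groups: Iterable[Sequence[str]]) -> "ConfusabilityGraph":
        """Each group becomes a clique (pairs stay pairs, trios 3-cliques)."""
        edges: Set[Edge] = set()
        for group in groups:
            for a, b in combinations(sorted(set(group)), 2):
                edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    def intersection(self, other: "ConfusabilityGraph") -> "ConfusabilityGraph":
        return ConfusabilityGraph(self.edges & other.edges)

    def difficult_species(self) -> FrozenSet[str]:
        return frozenset(s for e in self.edges for s in e)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MorphologyAnnotation:
    group: Tuple[str, ...]
    sex: str  # "male" | "female"
    difficult: bool
    note: str = ""

    def __post_init__(self):
        if len(self.group) < 2:
            raise ValueError("morphology group must list >= 2 species")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")


def read_morphology(path) -> List[MorphologyAnnotation]:
    """Morphology annotation TSV: columns members (semicolon-separated),
    sex, difficult, optional note."""
    out: List[MorphologyAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for col in ("members", "sex", "difficult"):
            if col not in cols:
                raise ValueError(f"morphology table missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                MorphologyAnnotation(
                    group=tuple(
                        s.strip() for s in parts[cols["members"]].split(";")
                    ),
                    sex=parts[cols["sex"]].strip(),
                    difficult=parts[cols["difficult"]].strip().lower()
                    in ("true", "1", "yes"),
                    note=parts[cols["note"]] if "note" in cols else "",
                )
            )
    return out


def morphology_graph(
    annotations: Iterable[MorphologyAnnotation], sex: str
) -> ConfusabilityGraph:
    return ConfusabilityGraph.from_groups(
        a.group for a in annotations if a.sex == sex and a.difficult
    )


def barcode_graph(audit: AuditReport) -> ConfusabilityGraph:
    """Edges between mutually entangled species: same para/polyphyletic
    complex (specimens interleaving on the tree) or sharing a barcode."""
    edges: Set[Edge] = set()
    for species, a in audit.assessments.items():
        for other in a.shares_barcode_with:
            edges.add(frozenset((species, other)))
        for other in a.entangled_with:
            edges.add(frozenset((species, other)))
    return ConfusabilityGraph(frozenset(edges))


# ----------------------------------------------------------------------
# rates
# ----------------------------------------------------------------------

@dataclass
class RateTable:
    n_species: int
    difficult: Dict[str, List[str]]  # per channel, sorted species
    rates_exact: Dict[str, float] = field(init=False)
    rates: Dict[str, float] = field(init=False)  # rounded to 1 decimal
    deltas: Dict[str, float] = field(init=False)

    def __post_init__(self):
        self.rates_exact = {
            ch: 100.0 * (self.n_species - len(sp)) / self.n_species
            for ch, sp in self.difficult.items()
        }
        self.rates = {
            ch: round_half_up(r, 1) for ch, r in self.rates_exact.items()
        }
        # improvement deltas between rounded (as-published) rates
        self.deltas = {
            "integrated_male_vs_barcode":
                round_half_up(self.rates["integrated_male"] - self.rates["barcode"], 1),
            "integrated_male_vs_morphology_male":
                round_half_up(
                    self.rates["integrated_male"] - self.rates["morphology_male"], 1
                ),
            "integrated_female_vs_barcode":
                round_half_up(
                    self.rates["integrated_female"] - self.rates["barcode"], 1
                ),
            "integrated_female_vs_morphology_female":
                round_half_up(
                    self.rates["integrated_female"] - self.rates["morphology_female"],
                    1,
                ),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "n_species": self.n_species,
                "n_difficult": {ch: len(sp) for ch, sp in self.difficult.items()},
                "difficult": self.difficult,
                "rate_always_possible": self.rates,
                "rate_always_possible_exact": {
                    ch: round_half_up(r, 6) for ch, r in self.rates_exact.items()
                },
                "improvement_deltas": self.deltas,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("channel\tn_difficult\trate_always_possible\tdifficult_species\n")
            for ch in CHANNELS:
                fh.write(
                    f"{ch}\t{len(self.difficult[ch])}\t{self.rates[ch]:.1f}\t"
                    + ";".join(self.difficult[ch])
                    + "\n"
                )


def rates(
    barcode: ConfusabilityGraph,
    morphology_male: ConfusabilityGraph,
    morphology_female: ConfusabilityGraph,
    n_species: int,
) -> RateTable:
    """Per-channel identification-success rates over a universe of
    ``n_species`` sequenced species.

    Graph nodes must all lie within the universe; ``n_species`` is the
    denominator for every channel.
    """
    all_nodes = (
        barcode.difficult_species()
        | morphology_male.difficult_species()
        | morphology_female.difficult_species()
    )
    if len(all_nodes) > n_species:
        raise ValueError(
            f"graphs mention {len(all_nodes)} species but universe has "
            f"{n_species}"
        )
    graphs = {
        "barcode": barcode,
        "morphology_male": morphology_male,
        "morphology_female": morphology_female,
        "integrated_male": barcode.intersection(morphology_male),
        "integrated_female": barcode.intersection(morphology_female),
    }
    difficult = {
        ch: sorted(g.difficult_species()) for ch, g in graphs.items()
    }
    return RateTable(n_species=n_species, difficult=difficult)


# ----------------------------------------------------------------------
# packaged fixture (Swiss diurnal Lepidoptera library)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeGroup:
    members: Tuple[str, ...]
    shares_barcodes: bool


@dataclass(frozen=True)
class Table1Fixture:
    n_species: int
    barcode_groups: Tuple[BarcodeGroup, ...]
    morphology: Tuple[MorphologyAnnotation, ...]

    @property
    def barcode(self) -> ConfusabilityGraph:
        return ConfusabilityGraph.from_groups(
            g.members for g in self.barcode_groups
        )

    @property
    def sharing(self) -> ConfusabilityGraph:
        """Only the groups whose members actually share barcodes, i.e. the
        species that remain non-diagnostic under the species-specific-
        haplotype criterion."""
        return ConfusabilityGraph.from_groups(
            g.members for g in self.barcode_groups if g.shares_barcodes
        )

    @property
    def non_sharing(self) -> ConfusabilityGraph:
        return ConfusabilityGraph.from_groups(
            g.members for g in self.barcode_groups if not g.shares_barcodes
        )

    @property
    def morphology_male(self) -> ConfusabilityGraph:
        return morphology_graph(self.morphology, "male")

    @property
    def morphology_female(self) -> ConfusabilityGraph:
        return morphology_graph(self.morphology, "female")

    def rate_table(self) -> RateTable:
        return rates(
            self.barcode,
            self.morphology_male,
            self.morphology_female,
            self.n_species,
        )

    def haplotype_criterion_rate(self) -> Tuple[float, float]:
        """(exact, rounded-1-decimal) success rate when only species in
        barcode-*sharing* groups count as non-diagnostic."""
        n_bad = len(self.sharing.difficult_species())
        exact = 100.0 * (self.n_species - n_bad) / self.n_species
        return exact, round_half_up(exact, 1)


FIXTURE_N_SPECIES = 217


def _data_path(name: str):
    return resources.files("barcodeaudit").joinpath("data", name)


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged species-group fixture (217 sequenced species)."""
    groups: List[BarcodeGroup] = []
    with resources.as_file(_data_path("table1_barcode_groups.tsv")) as p:
        with open(p, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                groups.append(
                    BarcodeGroup(
                        members=tuple(
                            s.strip() for s in parts[cols["members"]].split(";")
                        ),
                        shares_barcodes=parts[cols["shares_barcodes"]]
                        .strip()
                        .lower()
                        in ("true", "1", "yes"),
                    )
                )
    with resources.as_file(_data_path("table1_morphology.tsv")) as p:
        morph = tuple(read_morphology(p))
    return Table1Fixture(
        n_species=FIXTURE_N_SPECIES,
        barcode_groups=tuple(groups),
        morphology=morph,
    )
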