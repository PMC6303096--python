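"""Synthetic reference libraries with known ground truth.

The simulator draws a random coalescent-like species tree with equal tip
depths, scales it so the closest (sister) species pair sits at the
configured interspecific divergence, evolves a uniform-random ancestral
sequence along it under an exact K2P substitution process (closed-form
transition probabilities per branch, no Bernoulli approximation), and then
evolves each specimen from its species ancestor so that the expected
within-species pairwise distance matches the intraspecific target.

Introgression events copy a donor specimen's sequence onto a recipient
specimen, which keeps its recipient species label (mitochondrial capture).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .library_io import ReferenceLibrary, SequenceRecord

DEFAULT_SEQ_LENGTH = 658
DEFAULT_INTER = 0.05
DEFAULT_INTRA = 0.006
DEFAULT_KAPPA = 4.0

_BASES = "ACGT"


@dataclass(frozen=True)
class IntrogressionEvent:
    donor: str  # species name (or index-derived name)
    recipient: str
    n_specimens: int = 1
    post_copy_mutation: bool = False  # mutate the copy at intraspecific scale

    def __post_init__(self):
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")


@dataclass
class SimulationConfig:
    n_species: int = 10
    specimens_per_species: Union[int, Sequence[int]] = 4
    seq_length: int = DEFAULT_SEQ_LENGTH
    interspecific_divergence: float = DEFAULT_INTER
    intraspecific_divergence: float = DEFAULT_INTRA
    kappa: float = DEFAULT_KAPPA
    introgression_events: List[IntrogressionEvent] = field(default_factory=list)
    n_ambiguous_sites: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.interspecific_divergence < 0.7:
            raise ValueError("interspecific divergence must be in (0, 0.7)")
        if not 0.0 <= self.intraspecific_divergence < 0.7:
            raise ValueError("intraspecific divergence must be in [0, 0.7)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.counts()  # validates list length / positivity

    def counts(self) -> List[int]:
        if isinstance(self.specimens_per_species, int):
            return [self.specimens_per_species] * self.n_species
        counts = list(self.specimens_per_species)
        if len(counts) != self.n_species:
            raise ValueError(
                "specimens_per_species list length must equal n_species"
            )
        if any(c < 1 for c in counts):
            raise ValueError("every species needs >= 1 specimen")
        return counts

    def species_names(self) -> List[str]:
        width = max(2, len(str(self.n_species)))
        return [f"Species_{i + 1:0{width}d}" for i in range(self.n_species)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        events = [
            IntrogressionEvent(**ev) for ev in raw.pop("introgression_events", [])
        ]
        return cls(introgression_events=events, **raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_species": self.n_species,
            "specimens_per_species": (
                self.specimens_per_species
                if isinstance(self.specimens_per_species, int)
                else list(self.specimens_per_species)
            ),
            "seq_length": self.seq_length,
            "interspecific_divergence": self.interspecific_divergence,
            "intraspecific_divergence": self.intraspecific_divergence,
            "kappa": self.kappa,
            "n_ambiguous_sites": self.n_ambiguous_sites,
            "seed": self.seed,
            "introgression_events": [
                {
                    "donor": ev.donor,
                    "recipient": ev.recipient,
                    "n_specimens": ev.n_specimens,
                    "post_copy_mutation": ev.post_copy_mutation,
                }
                for ev in self.introgression_events
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthTable:
    species_of: Dict[str, str]  # specimen id -> true species
    lineage_of: Dict[str, str]  # "native" or "introgressed-from-<species>"
    expected_monophyletic: Dict[str, bool]  # per species

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("specimen_id\tspecies\tlineage\texpected_monophyletic\n")
            for sid in self.species_of:
                sp = self.species_of[sid]
                fh.write(
                    f"{sid}\t{sp}\t{self.lineage_of[sid]}\t"
                    f"{self.expected_monophyletic[sp]}\n"
                )


# ----------------------------------------------------------------------
# K2P substitution process
# ----------------------------------------------------------------------

def k2p_transition_probs(t: float, kappa: float) -> Tuple[float, float]:
    """(P_transition, P_transversion_total) after ``t`` expected subs/site.

    Rates are normalized so alpha + 2*beta = 1 with alpha/beta = kappa.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return p_ts, p_tv


def expected_pq_ratio(t: float, kappa: float) -> float:
    """Closed-form expected transition/transversion proportion ratio P/Q
    for two sequences separated by ``t`` expected substitutions/site."""
    p_ts, p_tv = k2p_transition_probs(t, kappa)
    return p_ts / p_tv


def evolve(seq: np.ndarray, t: float, kappa: float, rng) -> np.ndarray:
    """Evolve an encoded sequence (0..3) along a branch of length ``t``."""
    if t <= 0.0:
        return seq.copy()
    p_ts, p_tv = k2p_transition_probs(t, kappa)
    u = rng.random(seq.shape[0])
    out = seq.copy()
    # transition: XOR with 2 under the A=0,C=1,G=2,T=3 encoding
    ts_mask = u < p_ts
    out[ts_mask] ^= 2
    # transversion: two equiprobable targets, XOR with 1 or 3
    tv_mask = (u >= p_ts) & (u < p_ts + p_tv)
    flip = np.where(rng.random(seq.shape[0]) < 0.5, 1, 3).astype(seq.dtype)
    out[tv_mask] ^= flip[tv_mask]
    return out


def _decode(enc: np.ndarray) -> str:
    return "".join(_BASES[b] if b < 4 else "N" for b in enc)


# ----------------------------------------------------------------------
# species tree
# ----------------------------------------------------------------------

def _coalescent_heights(n: int, rng) -> Tuple[List[Tuple[int, int, int]], np.ndarray]:
    """Random coalescent-like topology over ``n`` tips with node heights.

    Pairs are merged in random order; the k-th merge sits at a jittered
    height proportional to sqrt(k), normalized so the first (shallowest)
    merge is at height 1. The resulting tip-pair distances therefore span
    roughly 1x..sqrt(n)x the sister-pair separation -- a compressed depth
    profile that keeps even the deepest pairs well away from K2P
    saturation, unlike raw Kingman waiting times. Tips are nodes 0..n-1 at
    height 0.
    """
    heights = np.zeros(2 * n - 1)
    raw = np.sqrt(np.arange(1, n)) * rng.uniform(0.85, 1.15, size=n - 1)
    raw = np.maximum.accumulate(raw)  # keep node heights monotone
    raw /= raw[0]
    active = list(range(n))
    merges = []
    nxt = n
    for k in range(n - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        left, right = active[i], active[j]
        heights[nxt] = raw[k]
        merges.append((left, right, nxt))
        active = [x for x in active if x not in (left, right)] + [nxt]
        nxt += 1
    return merges, heights


def _species_ancestors(cfg: SimulationConfig, rng) -> np.ndarray:
    """Simulate one ancestral sequence per species along a scaled species
    tree; returns an (n_species, L) encoded array."""
    n = cfg.n_species
    root_seq = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    if n == 1:
        return root_seq[None, :]
    merges, heights = _coalescent_heights(n, rng)

    # pairwise distance between two tips is 2 * height(MRCA); scale the
    # tree so the *closest* species pair (the most recent split) sits at
    # the configured divergence -- the target is a sister-species distance,
    # deeper pairs are further apart
    min_sep = 2.0 * heights[n]  # first coalescence
    heights *= cfg.interspecific_divergence / min_sep

    root_index = merges[-1][2]
    seqs: Dict[int, np.ndarray] = {root_index: root_seq}
    for left, right, new in reversed(merges):
        parent = seqs[new]
        for child in (left, right):
            branch = heights[new] - heights[child]
            seqs[child] = evolve(parent, branch, cfg.kappa, rng)
    return np.vstack([seqs[i] for i in range(n)])


# ----------------------------------------------------------------------
# library simulation
# ----------------------------------------------------------------------

def simulate_library(
    cfg: SimulationConfig,
) -> Tuple[ReferenceLibrary, TruthTable]:
    """Generate a library and its ground truth; deterministic given seed."""
    import warnings

    if cfg.intraspecific_divergence >= cfg.interspecific_divergence:
        warnings.warn(
            "intraspecific divergence >= interspecific divergence: species "
            "clusters will overlap",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    names = cfg.species_names()
    counts = cfg.counts()
    ancestors = _species_ancestors(cfg, rng)

    # expected pairwise specimen distance within a species is twice the
    # tip branch length
    tip_branch = cfg.intraspecific_divergence / 2.0

    seqs: Dict[str, np.ndarray] = {}
    specimen_ids: Dict[str, List[str]] = {name: [] for name in names}
    order: List[str] = []
    species_of: Dict[str, str] = {}
    lineage_of: Dict[str, str] = {}
    for si, name in enumerate(names):
        for k in range(counts[si]):
            sid = f"{name}_{k + 1:02d}"
            seqs[sid] = evolve(ancestors[si], tip_branch, cfg.kappa, rng)
            specimen_ids[name].append(sid)
            order.append(sid)
            species_of[sid] = name
            lineage_of[sid] = "native"

    expected_mono = {name: True for name in names}
    for ev in cfg.introgression_events:
        if ev.donor not in specimen_ids or ev.recipient not in specimen_ids:
            raise ValueError(
                f"unknown species in introgression event: {ev.donor}/{ev.recipient}"
            )
        native_recipients = [
            sid for sid in specimen_ids[ev.recipient]
            if lineage_of[sid] == "native"
        ]
        if len(native_recipients) < ev.n_specimens:
            raise ValueError(
                f"species {ev.recipient} has too few native specimens for "
                f"introgression event"
            )
        targets = list(
            rng.choice(native_recipients, size=ev.n_specimens, replace=False)
        )
        for sid in targets:
            donor_sid = str(rng.choice(specimen_ids[ev.donor]))
            copied = seqs[donor_sid].copy()
            if ev.post_copy_mutation:
                copied = evolve(copied, cfg.intraspecific_divergence, cfg.kappa, rng)
            seqs[sid] = copied
            lineage_of[sid] = f"introgressed-from-{ev.donor}"
        expected_mono[ev.donor] = False
        expected_mono[ev.recipient] = False

    if cfg.n_ambiguous_sites > 0:
        for sid in order:
            pos = rng.choice(
                cfg.seq_length,
                size=min(cfg.n_ambiguous_sites, cfg.seq_length),
                replace=False,
            )
            s = seqs[sid].copy()
            s[pos] = 255
            seqs[sid] = s

    records = [
        SequenceRecord(
            specimen_id=sid,
            species=species_of[sid],
            sequence=_decode(seqs[sid]),
        )
        for sid in order
    ]
    lib = ReferenceLibrary(records)
    truth = TruthTable(
        species_of=species_of,
        lineage_of=lineage_of,
        expected_monophyletic=expected_mono,
    )
    return lib, truth


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def summary_check(
    lib: ReferenceLibrary,
    truth: TruthTable,
    dm,
) -> Dict[str, Optional[float]]:
    """Realized summary statistics for comparison against config targets.

    Reports the mean per-species maximum intraspecific distance and the
    mean nearest-neighbor distance (both percent, with standard errors),
    plus the aggregate transition/transversion count ratio over all
    heterospecific pairs.
    """
    from .species_audit import intraspecific_stats, nearest_neighbor

    intra = intraspecific_stats(dm, lib)
    maxima = [st.max_intra for st in intra.values() if st.max_intra is not None]
    means = [st.mean_intra for st in intra.values() if st.mean_intra is not None]
    nn = nearest_neighbor(dm, lib) if len(lib.species_index) > 1 else {}
    nn_vals = [r.nn_distance for r in nn.values()]

    # aggregate transition/transversion counts across heterospecific pairs
    from .distance import k2p_distance

    ts_total = tv_total = 0
    recs = lib.records
    for i in range(len(recs) - 1):
        for j in range(i + 1, len(recs)):
            if recs[i].species == recs[j].species:
                continue
            cmp = k2p_distance(recs[i].sequence, recs[j].sequence, min_overlap=1)
            ts_total += cmp.transitions
            tv_total += cmp.transversions

    def mean_se(vals):
        if not vals:
            return None, None
        m = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return m, se

    mean_max, se_max = mean_se(maxima)
    mean_mean, se_mean = mean_se(means)
    mean_nn, se_nn = mean_se(nn_vals)
    return {
        "mean_max_intra": mean_max,
        "se_max_intra": se_max,
        "mean_mean_intra": mean_mean,
        "se_mean_intra": se_mean,
        "mean_nn_distance": mean_nn,
        "se_nn_distance": se_nn,
        "ts_tv_count_ratio": (ts_total / tv_total) if tv_total else None,
        "n_species_multi": len(maxima),
    }
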